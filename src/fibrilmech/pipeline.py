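"""Configured end-to-end analysis: window -> metrics -> quasi-harmonic ->
mode classification -> beam inversion, with TSV/JSON outputs.

The composition is also exposed as :func:`recover_mechanics`, the
programmatic route from a trajectory plus a beam geometry to recovered
rigidities and moduli (the round-trip used to validate the whole
pipeline against the synthetic generator's ground truth).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import beam, io, metrics, qha
from .errors import ConfigError, FibrilMechError
from .structures import Trajectory

logger = logging.getLogger(__name__)

ALPHA_VARIANTS = ("variance-fraction", "rmsf-ratio")


@dataclass
class AnalysisConfig:
    """Validated analysis configuration (defaults mirror the study protocol:
    T = 300 K, discard the first half, six rigid modes, 1.4 A probe)."""

    trajectory: str | None = None
    beam_spec: str | None = None
    temperature: float = 300.0
    discard_fraction: float = 0.5
    stride: int = 1
    n_rigid: int = 6
    align: bool = True
    calpha_mass: float | None = None  # Da; None = mean mass of selected atoms
    alpha_variant: str = "variance-fraction"
    op_variant: str = "variance"
    hbond_distance_cutoff: float = 3.5
    hbond_angle_cutoff: float = 150.0
    hbond_distance_only_cutoff: float = 3.2
    probe_radius: float = 1.4
    section_model: str = "envelope"  # "envelope" | "fixed" | "none"
    section_width: float | None = None  # m, fixed model
    section_height: float | None = None  # m, fixed model
    effective_radius: float = 1.7  # A, envelope model
    max_order: int = 4
    seed: int = 0
    output_dir: str = "fibrilmech_out"
    run_metrics: list[str] = field(
        default_factory=lambda: ["rmsd", "dihedral", "bend", "op"])

    def validate(self) -> None:
        if not 0 <= self.discard_fraction < 1:
            raise ConfigError("discard_fraction must be in [0, 1)")
        if self.stride < 1:
            raise ConfigError("stride must be >= 1")
        if self.temperature <= 0:
            raise ConfigError("temperature must be positive")
        if self.n_rigid < 0:
            raise ConfigError("n_rigid must be non-negative")
        if self.alpha_variant not in ALPHA_VARIANTS:
            raise ConfigError(f"alpha_variant must be one of {ALPHA_VARIANTS}")
        if self.op_variant not in metrics.OP_VARIANTS:
            raise ConfigError(
                f"op_variant must be one of {tuple(metrics.OP_VARIANTS)}")
        if self.probe_radius <= 0:
            raise ConfigError("probe_radius must be positive")
        if self.section_model not in ("envelope", "fixed", "none"):
            raise ConfigError("section_model must be envelope, fixed or none")
        if self.section_model == "fixed" and (
                self.section_width is None or self.section_height is None):
            raise ConfigError("fixed section model requires section_width and "
                              "section_height")
        unknown = set(self.run_metrics) - {"rmsd", "dihedral", "bend", "op",
                                           "hbond", "sasa"}
        if unknown:
            raise ConfigError(f"unknown metrics: {sorted(unknown)}")


def validate_config(source: str | Path | dict) -> AnalysisConfig:
    """Load and validate a YAML config file (or dict); unknown keys are rejected."""
    if isinstance(source, (str, Path)):
        path = Path(source)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        data = yaml.safe_load(path.read_text()) or {}
    else:
        data = dict(source)
    if not isinstance(data, dict):
        raise ConfigError("config must be a mapping")
    known = set(AnalysisConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    try:
        config = AnalysisConfig(**data)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc
    config.validate()
    return config


# ---------------------------------------------------------------------------
# mechanics recovery (the core composition)
# ---------------------------------------------------------------------------

@dataclass
class MechanicsResult:
    """Everything the quasi-harmonic + beam stage produces."""

    spectrum: qha.EigenSpectrum
    assignments: list[beam.ModeAssignment]
    properties: beam.MechanicalProperties
    geometry: beam.BeamGeometry
    frequencies: np.ndarray  # rad/s, retained modes
    family_contributions: dict[str, float]


def _pick_mode(assignments: list[beam.ModeAssignment], family: str,
               order: int = 1) -> beam.ModeAssignment | None:
    candidates = [a for a in assignments if a.family == family and a.order == order]
    return max(candidates, key=lambda a: a.overlap) if candidates else None


def recover_mechanics(traj: Trajectory, geometry: beam.BeamGeometry | None = None,
                      temperature: float = 300.0, n_rigid: int = 6,
                      align: bool = True, max_order: int = 4,
                      calpha_mass: float | None = None,
                      section_model: str = "envelope",
                      effective_radius: float = 1.7) -> MechanicsResult:
    """Quasi-harmonic analysis + mode classification + beam inversion.

    The trajectory should already be windowed/selected; ``geometry``
    defaults to an envelope cross-section estimated from the mean
    structure.  Order-1 modes of each deformation family (best overlap)
    supply the frequencies inverted into rigidities/moduli.
    """
    structure = traj.structure
    if calpha_mass is None:
        calpha_mass = float(structure.masses.mean())
    q = qha.fluctuation_matrix(traj, align=align)
    spectrum = qha.spectral_decompose(q, temperature=temperature,
                                      calpha_mass=calpha_mass)
    coords = qha.mean_structure(traj, align=align)
    if geometry is None:
        geometry = beam.estimate_cross_section(
            coords, structure.masses, model=section_model,
            stations=structure.layer_indices if structure.n_layers > 1 else None,
            effective_radius=effective_radius)
    stations = structure.layer_indices if structure.n_layers > 1 else None
    n_classify = min(spectrum.n_modes - n_rigid, 6 + 6 * max_order)
    assignments = beam.classify_modes(
        spectrum.eigenvectors, spectrum.eigenvalues, coords,
        stations=stations, n_modes=n_classify, max_order=max_order)
    omegas = qha.natural_frequencies(spectrum, n_rigid=n_rigid)

    def freq_of(family: str) -> tuple[float, int] | None:
        a = _pick_mode(assignments, family, order=1)
        if a is None or a.mode_index >= len(omegas):
            return None
        return float(omegas[a.mode_index]), a.mode_index

    soft = freq_of("soft-bend")
    stiff = freq_of("stiff-bend")
    if soft is None or stiff is None:
        raise FibrilMechError("could not identify both first-order bending modes")
    rig_soft, mod_soft = beam.invert_bending(soft[0], geometry, 1, plane="soft")
    rig_stiff, mod_stiff = beam.invert_bending(stiff[0], geometry, 1, plane="stiff")
    tor = freq_of("torsion")
    axi = freq_of("axial")
    g_t = beam.invert_torsion(tor[0], geometry, 1) if tor else None
    e_x = beam.invert_axial(axi[0], geometry, 1) if axi else None

    props = beam.MechanicalProperties(
        bending_rigidity_soft=rig_soft,
        bending_rigidity_stiff=rig_stiff,
        persistence_length=beam.persistence_length(rig_soft, temperature),
        torsional_shear_modulus=g_t,
        axial_elastic_modulus=e_x,
        bending_modulus_soft=mod_soft,
        bending_modulus_stiff=mod_stiff,
        temperature=temperature,
    )
    contrib = qha.mode_contributions(spectrum, n_rigid=n_rigid)
    family_contrib: dict[str, float] = {}
    for a in assignments:
        if a.family in ("rigid",) or a.mode_index >= len(contrib.alpha):
            continue
        family_contrib[a.family] = family_contrib.get(a.family, 0.0) + float(
            contrib.alpha[a.mode_index])
    return MechanicsResult(spectrum=spectrum, assignments=assignments,
                           properties=props, geometry=geometry,
                           frequencies=omegas,
                           family_contributions=family_contrib)


# ---------------------------------------------------------------------------
# full configured run
# ---------------------------------------------------------------------------

@dataclass
class RunReport:
    """Machine-readable outcome of one configured analysis run."""

    tables: dict[str, pd.DataFrame]
    summary: dict
    warnings: list[str]
    output_dir: Path | None = None


def _load_trajectory(config: AnalysisConfig) -> Trajectory:
    path = Path(config.trajectory)
    if path.suffix.lower() == ".xyz":
        return io.read_xyz_trajectory(path)
    _, traj = io.read_pdb(path)
    return traj


def run_analysis(config: AnalysisConfig, write: bool = True) -> RunReport:
    """Execute the full pipeline described by ``config``.

    Stages: load -> window -> geometry metrics -> quasi-harmonic ->
    classification -> inversion.  Tabular outputs are TSV with a
    unit-carrying header comment; a ``summary.json`` records provenance
    (config hash, seed) and the mechanics summary.
    """
    config.validate()
    if config.trajectory is None:
        raise ConfigError("config.trajectory is required")
    if not Path(config.trajectory).exists():
        raise ConfigError(f"trajectory file not found: {config.trajectory}")
    warnings: list[str] = []
    tables: dict[str, pd.DataFrame] = {}

    traj = _load_trajectory(config)
    traj = io.window_frames(traj, config.discard_fraction, config.stride)
    calpha = io.select_calpha(traj)
    structure = calpha.structure

    # --- geometry metrics ---------------------------------------------------
    time_ps = np.arange(traj.n_frames) * traj.time_per_frame
    if "rmsd" in config.run_metrics:
        tables["rmsd"] = pd.DataFrame(
            {"time_ps": time_ps, "rmsd_A": metrics.rmsd_series(calpha)})
    has_layers = structure.n_layers >= 2
    op_value = None
    if has_layers and {"dihedral", "op", "bend"} & set(config.run_metrics):
        dihedrals = np.array([
            metrics.layer_dihedral(frame, structure.layer_indices)
            for frame in calpha.frames])
        if "dihedral" in config.run_metrics:
            tables["dihedral"] = pd.DataFrame(
                {"time_ps": time_ps, "mean_dihedral_deg": dihedrals.mean(axis=1)})
        if "op" in config.run_metrics:
            op_fn = metrics.OP_VARIANTS[config.op_variant]
            ops = np.array([op_fn(d) for d in dihedrals])
            op_value = float(ops.mean())
            tables["op"] = pd.DataFrame({"time_ps": time_ps, "op": ops})
        if "bend" in config.run_metrics and structure.n_layers >= 3:
            bends = np.array([
                metrics.bending_angle(frame, structure.layer_indices)
                for frame in calpha.frames])
            tables["bend"] = pd.DataFrame(
                {"time_ps": time_ps, "bending_angle_deg": bends})
    elif {"dihedral", "op", "bend"} & set(config.run_metrics):
        warnings.append("layer topology unknown: dihedral/OP/bend skipped")
    if "hbond" in config.run_metrics:
        criteria = metrics.HBondCriteria(config.hbond_distance_cutoff,
                                         config.hbond_angle_cutoff,
                                         config.hbond_distance_only_cutoff)
        try:
            series = metrics.hbonds_per_residue(traj, criteria)
            tables["hbond"] = pd.DataFrame(
                {"time_ps": time_ps, "hbond_per_residue": series})
        except FibrilMechError as exc:
            warnings.append(f"hbond stage skipped: {exc}")
    if "sasa" in config.run_metrics:
        coords = traj.frames[-1]
        total, _ = metrics.sasa(coords, traj.structure.vdw_radii(),
                                probe=config.probe_radius)
        tables["sasa"] = pd.DataFrame({
            "frame": [traj.n_frames - 1], "sasa_A2": [total],
            "dG_np_kcal_mol": [metrics.nonpolar_solvation(
                total, metrics.SolvationParams(probe_radius=config.probe_radius))],
        })

    # --- quasi-harmonic + mechanics -----------------------------------------
    mech_summary: dict = {}
    try:
        geometry = None
        if config.section_model == "fixed":
            coords = qha.mean_structure(calpha, align=config.align)
            geometry = beam.estimate_cross_section(
                coords, structure.masses, model="fixed",
                width=config.section_width, height=config.section_height)
        result = recover_mechanics(
            calpha, geometry=geometry, temperature=config.temperature,
            n_rigid=config.n_rigid, align=config.align,
            max_order=config.max_order, calpha_mass=config.calpha_mass,
            section_model=("envelope" if config.section_model == "none"
                           else config.section_model),
            effective_radius=config.effective_radius)
        spectrum = result.spectrum
        contrib = qha.mode_contributions(spectrum, n_rigid=config.n_rigid,
                                         variant=config.alpha_variant)
        n_ret = len(contrib.alpha)
        fam = {a.mode_index: a for a in result.assignments}
        tables["spectrum"] = pd.DataFrame({
            "mode": np.arange(n_ret),
            "xi_A2": spectrum.eigenvalues[:n_ret],
            "omega_rad_s": result.frequencies,
            "nu_THz": result.frequencies / (2 * np.pi) / 1e12,
            "alpha": contrib.alpha,
            "family": [fam[j].family if j in fam else "" for j in range(n_ret)],
            "order": [fam[j].order if j in fam else 0 for j in range(n_ret)],
            "overlap": [fam[j].overlap if j in fam else np.nan
                        for j in range(n_ret)],
        })
        p = result.properties
        mech_summary = {
            "bending_rigidity_soft_Nm2": p.bending_rigidity_soft,
            "bending_rigidity_stiff_Nm2": p.bending_rigidity_stiff,
            "persistence_length_m": p.persistence_length,
            "torsional_shear_modulus_Pa": p.torsional_shear_modulus,
            "axial_elastic_modulus_Pa": p.axial_elastic_modulus,
            "bending_modulus_soft_Pa": p.bending_modulus_soft,
            "bending_modulus_stiff_Pa": p.bending_modulus_stiff,
            "rmsf_total_A": contrib.rmsf_total,
            "family_contributions": result.family_contributions,
        }
        tables["mechanics"] = pd.DataFrame([{
            k: v for k, v in mech_summary.items() if not isinstance(v, dict)}])
    except FibrilMechError as exc:
        warnings.append(f"mechanics stage skipped: {exc}")

    config_text = yaml.safe_dump(asdict(config), sort_keys=True)
    summary = {
        "config_sha256": hashlib.sha256(config_text.encode()).hexdigest(),
        "seed": config.seed,
        "n_frames_analysed": int(traj.n_frames),
        "n_calpha": int(structure.n_atoms),
        "alpha_variant": config.alpha_variant,
        "op_variant": config.op_variant,
        "order_parameter_mean": op_value,
        "mechanics": mech_summary,
        "warnings": warnings,
    }
    report = RunReport(tables=tables, summary=summary, warnings=warnings)
    if write:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, table in tables.items():
            target = out / f"{name}.tsv"
            with open(target, "w") as fh:
                fh.write(f"# fibrilmech {name} table; angles deg, lengths A, "
                         "SI for mechanics\n")
                table.to_csv(fh, sep="\t", index=False, float_format="%.10g")
        (out / "summary.json").write_text(json.dumps(summary, indent=2))
        report.output_dir = out
    return report
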