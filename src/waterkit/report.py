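"""End-to-end analysis orchestration from a declarative config.

A single :class:`AnalysisConfig` drives the pipeline: trajectory ingest →
water-topology assignment → the requested stages (structure, H-bonds,
diffusion, orientational relaxation, density). The resulting
:class:`SummaryReport` is a structured, versioned mapping in which every
number is traceable to the stage and parameters that produced it; the report
body is deterministic given the config and master seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import __version__
from .dynamics import (
    compute_msd,
    finite_size_correct,
    fit_diffusion,
    fit_relaxation_time,
    orientational_acf,
    unwrap_trajectory,
)
from .hbond import HBondCriterion, angle_distribution, hbond_stats
from .structure import compute_rdf, coordination_number, find_first_extrema
from .density import box_density
from .trajectory import Trajectory, assign_water_topology, read_cpmd_trajectory, read_xyz_trajectory

REPORT_SCHEMA_VERSION = 1

ALL_STAGES = ("rdf", "hbond", "diffusion", "acf", "density")


@dataclass
class AnalysisConfig:
    """Declarative description of one analysis run."""

    trajectory: str
    format: str = "xyz"  # xyz | cpmd
    box_edge: float = 0.0  # Å
    frame_spacing: float | None = None  # ps
    temperature: float | None = None  # K
    viscosity: float | None = None  # Pa·s
    element_order: list[str] | None = None  # cpmd only
    stages: list[str] = field(default_factory=lambda: list(ALL_STAGES))
    seed: int = 0
    output_dir: str | None = None
    # per-stage overrides
    rdf_bin_width: float = 0.01
    rdf_pairs: list[str] = field(default_factory=lambda: ["OO"])
    hbond_criterion: HBondCriterion = field(default_factory=HBondCriterion)
    msd_fit_window: tuple[float, float] | None = None
    acf_axes: list[str] = field(default_factory=lambda: ["OH"])
    acf_fit_start: float = 1.0
    deuterium: bool = False

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if self.box_edge <= 0:
            raise ValueError("box_edge must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text())
        crit = data.pop("hbond_criterion", None)
        cfg = cls(**data)
        if crit is not None:
            from .hbond import SwitchParams

            cfg.hbond_criterion = HBondCriterion(
                distance=SwitchParams(**crit["distance"]),
                path_excess=SwitchParams(**crit["path_excess"]),
                threshold=crit.get("threshold", 0.5),
            )
        return cfg


@dataclass
class SummaryReport:
    """Versioned structured results; values carry explicit unit suffixes."""

    schema_version: int
    provenance: dict[str, Any]
    results: dict[str, Any]
    failed_stages: dict[str, str]

    def to_yaml(self) -> str:
        def _clean(obj):
            if isinstance(obj, dict):
                return {k: _clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [_clean(v) for v in obj]
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            return obj

        return yaml.safe_dump(
            {
                "schema_version": self.schema_version,
                "provenance": _clean(self.provenance),
                "results": _clean(self.results),
                "failed_stages": self.failed_stages,
            },
            sort_keys=True,
        )

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_yaml())

    @property
    def ok(self) -> bool:
        return not self.failed_stages


def _load(config: AnalysisConfig) -> Trajectory:
    if config.format == "xyz":
        return read_xyz_trajectory(
            config.trajectory, config.box_edge, config.frame_spacing
        )
    if config.format == "cpmd":
        if not config.element_order:
            raise ValueError("cpmd format requires element_order")
        return read_cpmd_trajectory(
            config.trajectory,
            config.element_order,
            box_edge=config.box_edge,
            frame_spacing=config.frame_spacing,
        )
    raise ValueError(f"unknown trajectory format {config.format!r}")


def run_analysis(config: AnalysisConfig) -> SummaryReport:
    """Execute the requested stages in dependency order.

    A stage failure is recorded (stage name → message) and the remaining
    stages still run; callers should treat a non-empty ``failed_stages`` as a
    non-zero exit.
    """
    results: dict[str, Any] = {}
    failed: dict[str, str] = {}
    outdir = Path(config.output_dir) if config.output_dir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    traj = _load(config)
    topology = assign_water_topology(traj.frame(0), deuterium=config.deuterium)

    if "rdf" in config.stages:
        try:
            block: dict[str, Any] = {}
            for pair in config.rdf_pairs:
                rdf = compute_rdf(traj, topology, pair, bin_width=config.rdf_bin_width)
                if outdir:
                    rdf.write(outdir / f"rdf_{pair}.dat")
                entry: dict[str, Any] = {"bin_width_A": config.rdf_bin_width}
                if pair == "OO":
                    desc = find_first_extrema(rdf)
                    entry.update(
                        r_max1_A=desc.r_max1,
                        g_max1=desc.g_max1,
                        r_min1_A=desc.r_min1,
                        g_min1=desc.g_min1,
                        r_c_A=desc.r_c,
                    )
                    for conv in ("r2g_min", "g_min"):
                        try:
                            entry[f"n_OO_{conv}"] = coordination_number(rdf, conv)
                        except ValueError as exc:
                            entry[f"n_OO_{conv}"] = f"unavailable: {exc}"
                block[pair] = entry
            results["rdf"] = block
        except Exception as exc:  # noqa: BLE001 — stage isolation is the contract
            failed["rdf"] = str(exc)

    if "hbond" in config.stages:
        try:
            st = hbond_stats(traj, topology, config.hbond_criterion)
            ad = angle_distribution(traj, topology)
            if outdir:
                ad.write(outdir / "hbond_beta.dat")
                st.to_dataframe().to_csv(outdir / "hbond_counts.csv", index=False)
            results["hbond"] = {
                "h_per_molecule": st.h_per_molecule,
                "beta_file": "hbond_beta.dat" if outdir else None,
                "angle_samples": ad.n_samples,
            }
        except Exception as exc:  # noqa: BLE001
            failed["hbond"] = str(exc)

    if "diffusion" in config.stages:
        try:
            unwrapped = unwrap_trajectory(traj)
            msd = compute_msd(unwrapped, topology)
            est = fit_diffusion(msd, config.msd_fit_window)
            entry = {
                "D_L_A2_ps": est.D_L,
                "D_L_1e-9_m2_s": est.D_L_si,
                "fit_window_ps": list(est.fit_window),
                "stderr_A2_ps": est.stderr,
            }
            if config.temperature and config.viscosity:
                d_inf = finite_size_correct(
                    est.D_L, config.temperature, traj.box_edge, config.viscosity
                )
                entry["D_inf_A2_ps"] = d_inf
                entry["D_inf_1e-9_m2_s"] = d_inf * 10.0
            if outdir:
                msd.write(outdir / "msd.dat")
            results["diffusion"] = entry
        except Exception as exc:  # noqa: BLE001
            failed["diffusion"] = str(exc)

    if "acf" in config.stages:
        try:
            block = {}
            for axis in config.acf_axes:
                sub = {}
                for order in (1, 2):
                    acf = orientational_acf(traj, topology, axis, order)
                    if outdir:
                        acf.write(outdir / f"acf_{axis}_P{order}.dat")
                    try:
                        rt = fit_relaxation_time(acf, fit_start=config.acf_fit_start)
                        sub[f"tau{order}_ps"] = rt.tau
                        sub[f"tau{order}_converged"] = not rt.flagged_short
                    except ValueError as exc:
                        sub[f"tau{order}_ps"] = f"unavailable: {exc}"
                block[axis] = sub
            results["acf"] = block
        except Exception as exc:  # noqa: BLE001
            failed["acf"] = str(exc)

    if "density" in config.stages:
        # without an energy backend only the fixed-box density is reported;
        # scan-based equilibrium density needs a backend wired in code
        results["density"] = {
            "box_density_g_cm3": box_density(topology.n_molecules, traj.box_edge)
        }

    provenance = {
        "package_version": __version__,
        "schema_version": REPORT_SCHEMA_VERSION,
        "trajectory": str(config.trajectory),
        "format": config.format,
        "box_edge_A": config.box_edge,
        "frame_spacing_ps": config.frame_spacing,
        "n_frames": traj.n_frames,
        "n_molecules": topology.n_molecules,
        "temperature_K": config.temperature,
        "viscosity_Pa_s": config.viscosity,
        "seed": config.seed,
        "stages": list(config.stages),
    }
    report = SummaryReport(REPORT_SCHEMA_VERSION, provenance, results, failed)
    if outdir:
        report.write(outdir / "report.yaml")
    if failed:
        warnings.warn(f"stages failed: {sorted(failed)}")
    return report
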