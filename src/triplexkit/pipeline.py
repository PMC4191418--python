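"""Pipeline orchestration: configuration, demo data generation, staged
analyses, and a reproducible run manifest.

Every protocol constant of the umbrella/WHAM/SASA machinery appears as a
named default on :class:`PipelineConfig` (5-degree window spacing over the
full circle = 72 windows, production force constant 2000 kcal/(mol rad^2),
720 WHAM bins at tolerance 1e-6, SASA open/closed threshold 0.001 nm^2,
4 error blocks, 300 K).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .builder import (
    CANONICAL_A,
    CANONICAL_B,
    BiasedSamplerSpec,
    EnsembleSpec,
    StepParameterTarget,
    build_triplex,
    rebuild_helix,
    sample_biased_windows,
    sample_step_ensemble,
)
from .ensembles import (
    bend_angles,
    covariance_ellipse,
    groove_widths,
    pca_ensemble,
    region_statistics,
    variability_summary,
)
from .flipping import (
    DEFAULT_RADII_NM,
    UmbrellaWindow,
    barrier,
    delta_g_open,
    pmf_error,
    schedule_windows,
    wham,
    wrap_angle,
)
from .frames import helix_step_table
from .structure import (
    AtomicStructure,
    SystemDefinition,
    annotate_system,
    read_structure,
    triplex_30mer_system,
    write_structure,
)

__all__ = ["PipelineConfig", "run_pipeline", "generate_demo", "DEMO_PMF_PARAMS", "demo_pmf"]


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs; defaults are the protocol values."""

    output_dir: str = "triplexkit_out"
    seed: int = 0
    analyses: tuple[str, ...] = ("helix", "grooves", "bends", "variability", "pca", "pmf")
    # inputs (any may be None; the demo generator fills them in)
    duplex_pdb: str | None = None
    triplex_pdb: str | None = None
    windows_dir: str | None = None
    # system definition
    duplex_seq: str = "AACTGCTAAAGAGGGAGGGACTTGATGTAT"
    tfo_seq: str = "AGGGAGGGAG"
    tfo_target_start: int = 11
    # umbrella / WHAM protocol
    window_start: float = -180.0
    window_stop: float = 180.0
    window_spacing: float = 5.0  # -> 72 windows
    force_constant: float = 2000.0  # kcal/(mol rad^2)
    n_bins: int = 720
    wham_tolerance: float = 1e-6
    temperature: float = 300.0
    n_error_blocks: int = 4
    # SASA open/closed
    sasa_threshold_nm2: float = 0.001
    sasa_radii_nm: dict = field(default_factory=lambda: dict(DEFAULT_RADII_NM))
    # groove offsets
    minor_offset: int = -2
    major_offset: int = 2
    # PCA
    pca_fit_region: tuple[int, int] = (11, 20)

    def system(self) -> SystemDefinition:
        regions = {}
        if self.tfo_seq:
            lo = self.tfo_target_start
            hi = lo + len(self.tfo_seq) - 1
            regions = {
                "first duplex": (1, lo - 1),
                "homo-purine": (lo, hi),
                "second duplex": (hi + 1, len(self.duplex_seq)),
            }
        return SystemDefinition(
            duplex_seq=self.duplex_seq,
            tfo_seq=self.tfo_seq,
            tfo_target_start=self.tfo_target_start if self.tfo_seq else 0,
            regions=regions,
        )


# --------------------------------------------------------------------------
# Demo dataset
# --------------------------------------------------------------------------

# Double-well demo free-energy surface (kcal/mol): a deep closed-state well
# at 0 deg and a shallower open well around 180 deg, qualitatively like a
# base-flipping profile at reduced amplitude.
DEMO_PMF_PARAMS = {"a2": 2.5, "a1": -1.0}


def demo_pmf(x_deg):
    xr = np.radians(np.asarray(x_deg, dtype=float))
    return DEMO_PMF_PARAMS["a2"] * (1.0 - np.cos(2.0 * xr)) + DEMO_PMF_PARAMS[
        "a1"
    ] * np.cos(xr)


def _demo_ensemble_spec(seq: str, seed: int, n_frames: int, a_like_region=None):
    """Gaussian step-parameter spec around the canonical B values, with an
    optionally A-shifted (reduced twist, raised roll, negative slide)
    region emulating a bound homo-purine tract."""
    n_steps = len(seq) - 1
    means = np.tile(CANONICAL_B.as_array(), (n_steps, 1))
    if a_like_region is not None:
        lo, hi = a_like_region  # steps (1-based) fully inside the region
        for s in range(lo - 1, hi):
            means[s] = [0.0, -1.2, 3.30, 0.0, 5.6, 33.1]
    # modest thermal-like spreads: (shift, slide, rise, tilt, roll, twist)
    sd = np.array([0.35, 0.35, 0.25, 3.0, 4.5, 4.0])
    cov = np.diag(sd**2)
    # mild positive roll-slide coupling, as seen in step-parameter scatter
    cov[1, 4] = cov[4, 1] = 0.4 * sd[1] * sd[4]
    return EnsembleSpec(
        sequence=seq, means=means, covariances=cov, n_frames=n_frames, seed=seed
    )


def generate_demo(
    seed: int = 0,
    out_dir: str | Path = "demo_data",
    n_frames: int = 60,
    n_samples_per_window: int = 2000,
    config: PipelineConfig | None = None,
) -> dict[str, str]:
    """Write the demo dataset: fiber duplex and triplex PDBs, Gaussian
    duplex/triplex ensembles, and umbrella windows for the demo PMF.

    Deterministic for a fixed seed (byte-identical outputs).
    """
    cfg = config or PipelineConfig(seed=seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sysdef = triplex_30mer_system()

    duplex = rebuild_helix(sysdef.duplex_seq, CANONICAL_B)
    write_structure(duplex, out / "duplex_fiber.pdb")
    triplex = build_triplex(duplex, sysdef.tfo_seq, 11)
    write_structure(triplex, out / "triplex_fiber.pdb")

    ens_dup = sample_step_ensemble(
        _demo_ensemble_spec(sysdef.duplex_seq, seed, n_frames)
    )
    write_structure(ens_dup, out / "duplex_ensemble.pdb")
    ens_tri_duplex = sample_step_ensemble(
        _demo_ensemble_spec(sysdef.duplex_seq, seed + 1, n_frames, a_like_region=(11, 19))
    )
    ens_tri = build_triplex(ens_tri_duplex, sysdef.tfo_seq, 11)
    write_structure(ens_tri, out / "triplex_ensemble.pdb")

    centers = schedule_windows(cfg.window_start, cfg.window_stop, cfg.window_spacing)
    windows = sample_biased_windows(
        BiasedSamplerSpec(
            true_pmf=demo_pmf,
            window_centers=centers,
            force_constant=cfg.force_constant,
            n_samples=n_samples_per_window,
            temperature=cfg.temperature,
            seed=seed,
        )
    )
    wdir = out / "windows"
    wdir.mkdir(exist_ok=True)
    for i, w in enumerate(windows):
        np.savetxt(wdir / f"window_{i:03d}.dat", w.samples, fmt="%.6f")
    meta = {
        "force_constant": cfg.force_constant,
        "temperature": cfg.temperature,
        "centers": [w.center for w in windows],
        "acceptance": [w.acceptance for w in windows],
        "seed": seed,
    }
    (wdir / "windows.json").write_text(json.dumps(meta, indent=1))
    return {
        "duplex_pdb": str(out / "duplex_fiber.pdb"),
        "triplex_pdb": str(out / "triplex_fiber.pdb"),
        "duplex_ensemble_pdb": str(out / "duplex_ensemble.pdb"),
        "triplex_ensemble_pdb": str(out / "triplex_ensemble.pdb"),
        "windows_dir": str(wdir),
    }


def load_windows(windows_dir: str | Path) -> list[UmbrellaWindow]:
    """Read plain-text window series (one angle per line) + JSON sidecar."""
    wdir = Path(windows_dir)
    meta = json.loads((wdir / "windows.json").read_text())
    files = sorted(wdir.glob("window_*.dat"))
    if len(files) != len(meta["centers"]):
        raise ValueError("window file count does not match sidecar centers")
    return [
        UmbrellaWindow(
            center=float(c),
            force_constant=float(meta["force_constant"]),
            samples=np.loadtxt(f),
            temperature=float(meta["temperature"]),
        )
        for f, c in zip(files, meta["centers"])
    ]


# --------------------------------------------------------------------------
# Pipeline
# --------------------------------------------------------------------------


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the selected stages in dependency order.

    Writes CSV/JSON outputs plus ``manifest.json`` (config echo, seeds,
    versions, per-output hashes and collected warnings; stable across
    reruns with identical config) and ``run.log`` (timings).  Raises on
    missing inputs before any compute.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    needed = []
    if {"helix", "grooves", "bends", "variability", "pca"} & set(config.analyses):
        needed.append(("duplex_pdb", config.duplex_pdb))
    if "pmf" in config.analyses:
        needed.append(("windows_dir", config.windows_dir))
    missing = [name for name, val in needed if not val or not Path(val).exists()]
    if missing:
        raise FileNotFoundError(f"missing inputs: {missing}")

    sysdef = config.system()
    outputs: list[Path] = []
    log: list[str] = []
    caught: list[str] = []
    t_start = time.time()

    def stage(name):
        log.append(f"{name}: start +{time.time() - t_start:.1f}s")

    structures: dict[str, AtomicStructure] = {}
    with warnings.catch_warnings(record=True) as wrec:
        warnings.simplefilter("always")
        if config.duplex_pdb:
            structures["duplex"] = read_structure(config.duplex_pdb)
        if config.triplex_pdb and Path(config.triplex_pdb).exists():
            structures["triplex"] = read_structure(config.triplex_pdb)

        for label, st in structures.items():
            ann = annotate_system(st, sysdef)
            if "helix" in config.analyses:
                stage(f"helix[{label}]")
                tab = helix_step_table(st, ann)
                p = out / f"steps_{label}.csv"
                tab.to_csv(p, index=False)
                outputs.append(p)
                if st.n_frames >= 8:
                    rs = region_statistics(tab)
                    p = out / f"region_stats_{label}.csv"
                    rs.to_csv(p, index=False)
                    outputs.append(p)
                if st.n_frames >= 3:
                    var = variability_summary(tab) if "variability" in config.analyses else None
                    if var is not None:
                        p = out / f"variability_{label}.csv"
                        var.to_csv(p, index=False)
                        outputs.append(p)
                    rs_sub = tab[["roll", "slide"]].to_numpy()
                    ell = covariance_ellipse(rs_sub)
                    p = out / f"roll_slide_ellipse_{label}.json"
                    p.write_text(
                        json.dumps(
                            {
                                "center": ell.center.tolist(),
                                "covariance": ell.covariance.tolist(),
                                "score": ell.score,
                                "semi_axes": ell.semi_axes.tolist(),
                                "orientation_deg": ell.orientation_deg,
                            },
                            indent=1,
                        )
                    )
                    outputs.append(p)
            if "grooves" in config.analyses:
                stage(f"grooves[{label}]")
                gw = groove_widths(st, ann, config.minor_offset, config.major_offset)
                p = out / f"grooves_{label}.csv"
                gw.to_csv(p, index=False)
                outputs.append(p)
            if "bends" in config.analyses:
                stage(f"bends[{label}]")
                ba = bend_angles(st, ann)
                p = out / f"bend_angles_{label}.csv"
                ba.to_csv(p, index=False)
                outputs.append(p)
            if "pca" in config.analyses and st.n_frames >= 2:
                stage(f"pca[{label}]")
                # duplex atoms only (exclude any third strand)
                duplex_res = set(range(1, 2 * sysdef.n_bp + 1))
                idx = [
                    i
                    for i, a in enumerate(st.atoms)
                    if a.residue_index in duplex_res
                ]
                sub = AtomicStructure(
                    [st.atoms[i] for i in idx], st.coords[:, idx]
                )
                pca = pca_ensemble(sub, annotate_system(sub, sysdef),
                                   config.pca_fit_region)
                p = out / f"pca_{label}.csv"
                pd.DataFrame(
                    {
                        "eigenvalue": pca.eigenvalues[:25],
                        "variance_fraction": pca.variance_fractions[:25],
                    }
                ).to_csv(p, index=False)
                outputs.append(p)

        if "pmf" in config.analyses:
            stage("pmf")
            windows = load_windows(config.windows_dir)
            prof = wham(
                windows,
                n_bins=config.n_bins,
                tolerance=config.wham_tolerance,
                temperature=config.temperature,
            )
            errs = pmf_error(
                windows,
                n_blocks=config.n_error_blocks,
                n_bins=config.n_bins,
                tolerance=config.wham_tolerance,
                temperature=config.temperature,
            )
            p = out / "pmf.csv"
            pd.DataFrame(
                {
                    "angle_deg": prof.bin_centers,
                    "free_energy_kcal_mol": prof.free_energy,
                    "error_kcal_mol": errs,
                }
            ).to_csv(p, index=False)
            outputs.append(p)
            closed = np.abs(wrap_angle(prof.bin_centers)) < 90.0
            summary = {
                "delta_g_open_kcal_mol": delta_g_open(prof, closed),
                **barrier(prof, split_at=180.0),
                "n_windows": len(windows),
                "n_bins": config.n_bins,
                "temperature_K": config.temperature,
                "closed_partition": "|x| < 90 deg (fixed angular cut)",
            }
            p = out / "pmf_summary.json"
            p.write_text(json.dumps(summary, indent=1))
            outputs.append(p)
        caught = [str(w.message) for w in wrec]

    cfg_dict = dataclasses.asdict(config)
    manifest = {
        "triplexkit_version": __version__,
        "config": cfg_dict,
        "outputs": {p.name: _sha256(p) for p in sorted(outputs)},
        "warnings": caught,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    log.append(f"done +{time.time() - t_start:.1f}s")
    (out / "run.log").write_text("\n".join(log) + "\n")
    return manifest
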