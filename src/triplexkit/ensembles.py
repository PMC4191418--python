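"""Ensemble-level structural analyses.

Region-averaged step statistics with block-averaged errors, groove widths
from inter-strand phosphate distances, stacking overlap areas, bend angles
about the central base pair, Roll-Slide variability and covariance
ellipses, and all-atom PCA of a superposed ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import MultiPoint, Polygon
from shapely.ops import unary_union

from . import bases
from .frames import fit_base_frame, pair_frame, step_parameters
from .geometry import kabsch
from .structure import AtomicStructure, PairingAnnotation, StructureError

__all__ = [
    "block_sem",
    "region_statistics",
    "groove_widths",
    "overlap_areas",
    "bend_angles",
    "pca_ensemble",
    "PCAResult",
    "CovarianceEllipse",
    "covariance_ellipse",
    "variability_summary",
]

_MASS = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "P": 30.974}


# --------------------------------------------------------------------------
# Block averaging (Flyvbjerg-Petersen doubling scheme)
# --------------------------------------------------------------------------


def block_sem(series: np.ndarray, plateau_rtol: float = 0.05, min_blocks: int = 4):
    """Standard error of the mean of a (possibly correlated) series.

    Doubling scheme: the series is halved repeatedly by averaging adjacent
    pairs; at each level the naive SEM of the blocked series is computed.
    The reported SEM is taken at the first level where the change from the
    previous level falls below ``plateau_rtol`` (plateau detection); if no
    plateau is reached the largest-block estimate is returned.

    Returns ``(sem, level_sems)``.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be 1-D")
    n = len(x)
    if n < 2 * min_blocks:
        raise ValueError(f"need at least {2 * min_blocks} points for block averaging")
    sems = []
    while len(x) >= min_blocks:
        m = len(x)
        sems.append(float(np.std(x, ddof=1) / np.sqrt(m)))
        if m // 2 < min_blocks:
            break
        x = (x[: 2 * (m // 2) : 2] + x[1 : 2 * (m // 2) : 2]) / 2.0
    sems = np.array(sems)
    if np.all(sems == 0):
        return 0.0, sems
    for i in range(1, len(sems)):
        if sems[i - 1] > 0 and abs(sems[i] - sems[i - 1]) / sems[i - 1] < plateau_rtol:
            return float(sems[i]), sems
    return float(sems[-1]), sems


def region_statistics(
    step_table: pd.DataFrame,
    parameters: tuple[str, ...] = ("shift", "slide", "rise", "tilt", "roll", "twist"),
) -> pd.DataFrame:
    """Two-stage region averages with block-averaged SEM.

    Stage one: each step's parameter is time-averaged over frames.  Stage
    two: the region mean is the mean of the per-step time averages.  The
    SEM comes from block-averaging the per-frame region-average series
    (doubling scheme with plateau detection), which accounts for serial
    correlation.
    """
    if "region" not in step_table or "frame" not in step_table:
        raise ValueError("step table must carry 'region' and 'frame' columns")
    n_frames = step_table["frame"].nunique()
    if n_frames < 8:
        raise ValueError("need at least 8 frames for block-averaged errors")
    rows = []
    for region, sub in step_table.groupby("region", sort=False):
        if region is None:
            continue
        for p in parameters:
            per_step = sub.groupby("step")[p].mean()
            region_series = sub.groupby("frame")[p].mean().to_numpy()
            sem, _ = block_sem(region_series)
            rows.append(
                {
                    "region": region,
                    "parameter": p,
                    "mean": float(per_step.mean()),
                    "sem": sem,
                    "n_steps": int(per_step.size),
                    "n_frames": int(n_frames),
                }
            )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Groove widths
# --------------------------------------------------------------------------


def _p_coord(structure: AtomicStructure, res: int, frame: int):
    names, coords = structure.residue_coords(res, names=("P",), frame=frame)
    return coords[0] if names else None


def groove_widths(
    structure: AtomicStructure,
    annotation: PairingAnnotation,
    minor_offset: int = -2,
    major_offset: int = 2,
) -> pd.DataFrame:
    """Raw inter-strand P-P distances as minor/major groove widths.

    At base-pair index ``i`` the minor groove width is the distance from
    the leading-strand phosphate P(i) to the cross-strand phosphate of
    base pair ``i + minor_offset``, the major groove width to that of
    ``i + major_offset`` (offsets configurable; defaults -2/+2).  Raw
    distances, no phosphate-radius subtraction.  Terminal positions whose
    partner phosphate does not exist are NaN (flagged absent).  Output has
    per-frame values plus ensemble mean and SD per position.
    """
    pairs = dict(annotation.wc_pairs)
    n = len(pairs)
    rows = []
    for f in range(structure.n_frames):
        pl = {i: _p_coord(structure, i, f) for i in range(1, n + 1)}
        pc = {i: _p_coord(structure, pairs[i], f) for i in range(1, n + 1)}
        for i in range(1, n + 1):
            vals = {}
            for name, off in (("minor", minor_offset), ("major", major_offset)):
                j = i + off
                if pl[i] is None or j < 1 or j > n or pc.get(j) is None:
                    vals[name] = np.nan
                else:
                    vals[name] = float(np.linalg.norm(pl[i] - pc[j]))
            rows.append(
                {
                    "frame": f,
                    "position": i,
                    "region": annotation.region_of(i),
                    "minor": vals["minor"],
                    "major": vals["major"],
                }
            )
    df = pd.DataFrame(rows)
    return df


def groove_summary(widths: pd.DataFrame) -> pd.DataFrame:
    """Per-position ensemble mean and SD of minor/major groove widths."""
    return (
        widths.groupby(["position", "region"], dropna=False)[["minor", "major"]]
        .agg(["mean", "std"])
        .reset_index()
    )


# --------------------------------------------------------------------------
# Stacking overlap areas
# --------------------------------------------------------------------------


def _base_polygon_atoms(base: str, exocyclic: bool) -> tuple[str, ...]:
    ring = bases.RING_ATOMS[base]
    if not exocyclic:
        return ring
    return ring + bases.EXOCYCLIC_ATOMS[base]


def _projected_polygon(
    structure: AtomicStructure,
    res: int,
    frame_idx: int,
    mid_origin: np.ndarray,
    mid_rot: np.ndarray,
    exocyclic: bool,
):
    base = structure.residue_base(res)
    names = _base_polygon_atoms(base, exocyclic)
    got, coords = structure.residue_coords(res, names=set(names), frame=frame_idx)
    if len(got) < 3:
        raise StructureError(f"residue {res}: not enough polygon atoms")
    local = (coords - mid_origin) @ mid_rot  # columns of mid_rot are axes
    xy = local[:, :2]
    if exocyclic:
        # ring polygon extended by the hull over exocyclic substituents
        return MultiPoint(xy).convex_hull
    order = [got.index(n) for n in names if n in got]
    poly = Polygon(xy[order])
    if not poly.is_valid:
        poly = poly.buffer(0)  # even-odd repair of self-intersections
    return poly


def overlap_areas(
    structure: AtomicStructure,
    annotation: PairingAnnotation,
    step: int,
    frame: int = 0,
) -> dict[str, float]:
    """Endocyclic and exocyclic stacking overlap of one dinucleotide step.

    The two base pairs' polygons (union of the two bases' ring polygons,
    or their hull-extended versions including exocyclic N/O/C substituents)
    are projected onto the step mid-frame's xy-plane; the overlap is the
    polygon intersection area (A^2).
    """
    pairs = dict(annotation.wc_pairs)
    n = len(pairs)
    if not (1 <= step <= n - 1):
        raise ValueError(f"step must be in 1..{n - 1}")
    frames = {}
    for i in (step, step + 1):
        names_i, coords_i = structure.residue_coords(i, frame=frame)
        names_j, coords_j = structure.residue_coords(pairs[i], frame=frame)
        fi = fit_base_frame(names_i, coords_i, structure.residue_base(i))
        fj = fit_base_frame(names_j, coords_j, structure.residue_base(pairs[i]))
        frames[i] = pair_frame(fi, fj)
    sp = step_parameters(frames[step], frames[step + 1])
    mo, mr = sp.mid_frame.origin, sp.mid_frame.rotation
    out = {}
    for kind, exo in (("endocyclic", False), ("exocyclic", True)):
        polys = {}
        for i in (step, step + 1):
            p1 = _projected_polygon(structure, i, frame, mo, mr, exo)
            p2 = _projected_polygon(structure, pairs[i], frame, mo, mr, exo)
            polys[i] = unary_union([p1, p2])
        out[kind] = float(polys[step].intersection(polys[step + 1]).area)
    return out


# --------------------------------------------------------------------------
# Bend angles
# --------------------------------------------------------------------------


def _bp_com(structure: AtomicStructure, i: int, j: int, frame: int) -> np.ndarray:
    """Centre of mass of the heavy base atoms of a Watson-Crick pair."""
    acc, tot = np.zeros(3), 0.0
    for res in (i, j):
        base = structure.residue_base(res)
        names = bases.RING_ATOMS[base] + bases.EXOCYCLIC_ATOMS[base]
        got, coords = structure.residue_coords(res, names=set(names), frame=frame)
        for nm, c in zip(got, coords):
            el = next(
                a.element
                for a in structure.atoms
                if a.residue_index == res and a.name == nm
            )
            m = _MASS[el]
            acc += m * c
            tot += m
    return acc / tot


def bend_angles(
    structure: AtomicStructure,
    annotation: PairingAnnotation,
    vertex: int | None = None,
    distances=None,
) -> pd.DataFrame:
    """Angles at the central base pair between equidistant neighbours.

    For each distance d the angle at the vertex base pair v between the
    COM vectors to base pairs v-d and v+d, per frame, in degrees (180 =
    perfectly straight).
    """
    pairs = dict(annotation.wc_pairs)
    n = len(pairs)
    v = vertex if vertex is not None else (n + 1) // 2
    dmax = min(v - 1, n - v)
    ds = list(distances) if distances is not None else list(range(1, dmax + 1))
    bad = [d for d in ds if d < 1 or v - d < 1 or v + d > n]
    if bad:
        raise ValueError(f"distances out of range for vertex {v}: {bad}")
    rows = []
    for f in range(structure.n_frames):
        coms = {
            i: _bp_com(structure, i, pairs[i], f)
            for i in set([v] + [v - d for d in ds] + [v + d for d in ds])
        }
        for d in ds:
            u1 = coms[v - d] - coms[v]
            u2 = coms[v + d] - coms[v]
            c = np.dot(u1, u2) / (np.linalg.norm(u1) * np.linalg.norm(u2))
            rows.append(
                {
                    "frame": f,
                    "vertex": v,
                    "distance": d,
                    "triplet": (v - d, v, v + d),
                    "angle": float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0)))),
                }
            )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# PCA
# --------------------------------------------------------------------------


@dataclass
class PCAResult:
    """Spectral decomposition of the superposed ensemble's coordinate
    covariance: eigenvalues descending (A^2), eigenvectors as rows of
    shape (n_modes, 3 n_atoms), per-frame projections, variance fractions.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    projections: np.ndarray
    variance_fractions: np.ndarray
    mean_coords: np.ndarray

    @property
    def n_modes(self) -> int:
        return len(self.eigenvalues)


def pca_ensemble(
    structure: AtomicStructure,
    annotation: PairingAnnotation | None = None,
    fit_region: tuple[int, int] | None = (11, 20),
    n_modes: int | None = None,
    superpose: bool = True,
) -> PCAResult:
    """All-atom PCA after rigid superposition onto the first frame.

    Each frame is least-squares superposed onto the reference (frame 0)
    using the atoms of the fit region's base pairs (defaults to the
    mid-helix pairs 11-20); the covariance of all (unweighted) atomic
    coordinates is then diagonalized.  Eigenvector count equals
    3 x n_atoms (all modes retained unless ``n_modes`` caps them).
    """
    if structure.n_frames < 2:
        raise ValueError("PCA needs at least two frames")
    if annotation is not None and fit_region is not None:
        pairs = dict(annotation.wc_pairs)
        lo, hi = fit_region
        fit_res = set()
        for i in range(lo, hi + 1):
            if i not in pairs:
                raise ValueError(f"fit region base pair {i} not in annotation")
            fit_res.update((i, pairs[i]))
        fit_idx = np.array(
            [k for k, a in enumerate(structure.atoms) if a.residue_index in fit_res]
        )
    else:
        fit_idx = np.arange(structure.n_atoms)
    ref = structure.coords[0]
    if superpose:
        aligned = np.empty_like(structure.coords)
        for f in range(structure.n_frames):
            R, t, _ = kabsch(structure.coords[f][fit_idx], ref[fit_idx])
            aligned[f] = structure.coords[f] @ R.T + t
    else:  # frames already share one frame of reference
        aligned = structure.coords
    X = aligned.reshape(structure.n_frames, -1)
    mean = X.mean(axis=0)
    Xc = X - mean
    cov = (Xc.T @ Xc) / (structure.n_frames - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order].T  # rows are modes
    fractions = evals / evals.sum() if evals.sum() > 0 else np.zeros_like(evals)
    if n_modes is not None:
        evals_r, evecs_r = evals[:n_modes], evecs[:n_modes]
    else:
        evals_r, evecs_r = evals, evecs
    projections = Xc @ evecs_r.T
    return PCAResult(
        eigenvalues=evals_r,
        eigenvectors=evecs_r,
        projections=projections,
        variance_fractions=fractions[: len(evals_r)] if n_modes else fractions,
        mean_coords=mean.reshape(-1, 3),
    )


# --------------------------------------------------------------------------
# Roll-Slide covariance ellipse and variability
# --------------------------------------------------------------------------


@dataclass
class CovarianceEllipse:
    """Equal-probability ellipse of a 2-D Gaussian at a stated score.

    The contour is {x : (x-mu)^T Sigma^-1 (x-mu) = score^2}; semi-axes are
    score * sqrt(eigenvalues of Sigma).  Score 3 is the conventional
    3-sigma ellipse.
    """

    center: np.ndarray
    covariance: np.ndarray
    score: float
    semi_axes: np.ndarray
    orientation_deg: float
    degenerate: bool = False


def covariance_ellipse(samples: np.ndarray, score: float = 3.0) -> CovarianceEllipse:
    """Sample covariance ellipse of (roll, slide) pairs at the given score."""
    X = np.asarray(samples, dtype=float)
    if X.ndim != 2 or X.shape[1] != 2 or X.shape[0] < 3:
        raise ValueError("need at least three 2-D samples")
    mu = X.mean(axis=0)
    cov = np.cov(X.T, ddof=1)
    evals, evecs = np.linalg.eigh(cov)
    degenerate = bool(evals.min() <= 1e-12 * max(evals.max(), 1.0))
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    semi = score * np.sqrt(np.clip(evals, 0.0, None))
    angle = float(np.degrees(np.arctan2(evecs[1, 0], evecs[0, 0])))
    return CovarianceEllipse(
        center=mu,
        covariance=cov,
        score=score,
        semi_axes=semi,
        orientation_deg=angle,
        degenerate=degenerate,
    )


def points_inside_ellipse(samples: np.ndarray, ellipse: CovarianceEllipse) -> float:
    """Fraction of samples inside the ellipse (Mahalanobis <= score)."""
    X = np.asarray(samples, float) - ellipse.center
    inv = np.linalg.inv(ellipse.covariance)
    d2 = np.einsum("ni,ij,nj->n", X, inv, X)
    return float((d2 <= ellipse.score**2).mean())


def variability_summary(step_table: pd.DataFrame) -> pd.DataFrame:
    """Per-step SD of roll and slide over frames, with YR/RR/RY class."""
    req = {"step", "step_seq", "step_class", "roll", "slide"}
    if not req.issubset(step_table.columns):
        raise ValueError(f"step table must carry columns {sorted(req)}")
    g = step_table.groupby(["step", "step_seq", "step_class"], sort=True)
    out = g[["roll", "slide"]].std(ddof=1).reset_index()
    out = out.rename(columns={"roll": "roll_sd", "slide": "slide_sd"})
    return out
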