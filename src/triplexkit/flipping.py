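"""Base-flipping free-energy machinery.

The reaction coordinate is the pseudo-dihedral angle over four centres of
mass: the flipping base, its own sugar, the first neighbouring sugar, and
the first neighbouring base pair.  Umbrella windows along this periodic
coordinate are unbiased with a periodic WHAM into a potential of mean
force; open and closed states are told apart by the solvent accessibility
of the pair's buried reporter atom (H3 of a pyrimidine, N1 of a purine)
and the opening free energy follows from integrating the Boltzmann weight
over the two state regions.

Units: angles in degrees on (-180, 180], energies kcal/mol, SASA nm^2,
force constants kcal/(mol rad^2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .geometry import dihedral, rotation_about_axis
from .structure import AtomicStructure, StructureError

__all__ = [
    "PseudoDihedralSpec",
    "UmbrellaWindow",
    "PMFProfile",
    "OpenCloseDefinition",
    "pseudo_dihedral",
    "rotate_to_angle",
    "schedule_windows",
    "wham",
    "pmf_error",
    "sasa",
    "classify_open_closed",
    "delta_g_open",
    "barrier",
    "DEFAULT_RADII_NM",
    "wrap_angle",
]

KB_KCAL = 0.0019872041  # kcal/(mol K)

# Per-element radii (nm) used for the numerical accessibility calculation,
# rolled with a zero additional probe; nitrogen is not stated alongside the
# quoted C/O/P/H values and defaults to the oxygen value.
DEFAULT_RADII_NM: dict[str, float] = {
    "C": 0.14,
    "O": 0.13,
    "P": 0.13,
    "H": 0.10,
    "N": 0.13,
}

# Atomic masses for COM computation (g/mol)
_MASS = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "P": 30.974}


def wrap_angle(x):
    """Map angles (degrees) onto (-180, 180]."""
    return -((-np.asarray(x, dtype=float) + 180.0) % 360.0 - 180.0)


# --------------------------------------------------------------------------
# Reaction coordinate
# --------------------------------------------------------------------------


@dataclass
class PseudoDihedralSpec:
    """Four COM groups defining the flipping coordinate.

    Each group is a list of (residue_index, atom_name) pairs: the flipping
    base, its sugar, the first neighbouring sugar, and the first
    neighbouring base pair.  ``positive_is_major_groove`` records the sign
    convention (positive rotation carries the base toward the major
    groove); it is metadata used when reporting per-direction barriers.
    """

    base_group: list[tuple[int, str]]
    sugar_group: list[tuple[int, str]]
    neighbor_sugar_group: list[tuple[int, str]]
    neighbor_pair_group: list[tuple[int, str]]
    positive_is_major_groove: bool = True

    def __post_init__(self):
        groups = [
            self.base_group,
            self.sugar_group,
            self.neighbor_sugar_group,
            self.neighbor_pair_group,
        ]
        if any(len(g) == 0 for g in groups):
            raise ValueError("every COM group must be non-empty")
        seen: set[tuple[int, str]] = set()
        for g in groups:
            for item in g:
                if tuple(item) in seen:
                    raise ValueError(f"atom {item} appears in more than one group")
                seen.add(tuple(item))

    def groups(self):
        return (
            self.base_group,
            self.sugar_group,
            self.neighbor_sugar_group,
            self.neighbor_pair_group,
        )


def _group_com(structure: AtomicStructure, group, frame: int) -> np.ndarray:
    total = 0.0
    acc = np.zeros(3)
    index = {
        (a.residue_index, a.name): i for i, a in enumerate(structure.atoms)
    }
    for res, name in group:
        i = index.get((res, name))
        if i is None:
            raise StructureError(f"atom {name!r} of residue {res} not in structure")
        m = _MASS[structure.atoms[i].element]
        acc += m * structure.coords[frame, i]
        total += m
    return acc / total


def pseudo_dihedral(
    structure: AtomicStructure, spec: PseudoDihedralSpec, frame: int = 0
) -> float:
    """Pseudo-dihedral angle (degrees, (-180, 180]) over the four COMs."""
    coms = [_group_com(structure, g, frame) for g in spec.groups()]
    try:
        ang = dihedral(*coms)
    except ValueError as exc:
        raise StructureError(f"pseudo-dihedral undefined: {exc}") from exc
    return float(np.degrees(ang))


def rotate_to_angle(
    structure: AtomicStructure,
    spec: PseudoDihedralSpec,
    target_deg: float,
    frame: int = 0,
) -> AtomicStructure:
    """Rigidly rotate the flipping base about the sugar-sugar COM axis so
    the pseudo-dihedral equals ``target_deg`` (synthetic flipped states).

    Rotation about the axis through COM(sugar) and COM(neighbour sugar)
    changes the dihedral by exactly the rotation angle; only the flipping
    base's atoms move.
    """
    current = pseudo_dihedral(structure, spec, frame)
    p1 = _group_com(structure, spec.sugar_group, frame)
    p2 = _group_com(structure, spec.neighbor_sugar_group, frame)
    axis = p2 - p1
    delta = np.radians(wrap_angle(target_deg - current))
    # rotating the base by +a about the sugar->neighbour-sugar axis adds
    # +a to the dihedral (group 1 is upstream of the central bond)
    R = rotation_about_axis(axis, float(delta))
    coords = structure.coords.copy()
    base_res = {res for res, _ in spec.base_group}
    base_names = {(res, name) for res, name in spec.base_group}
    moved = [
        i
        for i, a in enumerate(structure.atoms)
        if (a.residue_index, a.name) in base_names
    ]
    if not moved:
        raise StructureError(f"no atoms of the flipping base {sorted(base_res)} found")
    coords[frame, moved] = (coords[frame, moved] - p1) @ R.T + p1
    out = AtomicStructure(structure.atoms, coords)
    return out


# --------------------------------------------------------------------------
# Umbrella windows and WHAM
# --------------------------------------------------------------------------


@dataclass
class UmbrellaWindow:
    """One umbrella window: harmonic bias centre, force constant, samples."""

    center: float  # degrees, in (-180, 180]
    force_constant: float  # kcal/(mol rad^2)
    samples: np.ndarray  # angles, degrees
    temperature: float = 300.0
    acceptance: float | None = None

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if not (-180.0 < self.center <= 180.0):
            raise ValueError("window center must lie in (-180, 180]")
        if self.force_constant < 0:
            raise ValueError("force constant must be >= 0")


@dataclass
class PMFProfile:
    """Periodic potential of mean force on a bin-centre grid."""

    bin_centers: np.ndarray  # degrees
    free_energy: np.ndarray  # kcal/mol, min = 0, NaN on masked bins
    errors: np.ndarray | None = None
    temperature: float = 300.0
    window_free_energies: np.ndarray | None = None  # converged WHAM constants

    def __post_init__(self):
        self.bin_centers = np.asarray(self.bin_centers, float)
        self.free_energy = np.asarray(self.free_energy, float)
        if self.errors is not None:
            self.errors = np.asarray(self.errors, float)
            if (self.errors[np.isfinite(self.errors)] < 0).any():
                raise ValueError("errors must be non-negative")

    @property
    def n_bins(self) -> int:
        return len(self.bin_centers)


def schedule_windows(start: float = -180.0, stop: float = 180.0, spacing: float = 5.0) -> np.ndarray:
    """Window centres on the periodic domain; -180 and +180 counted once.

    The stated defaults give 72 centres (-180 to 180 in 5-degree
    intervals).  Spacing must divide the span exactly.
    """
    span = stop - start
    n = span / spacing
    if abs(n - round(n)) > 1e-9:
        raise ValueError(f"spacing {spacing} does not divide the span {span}")
    n = int(round(n))
    centers = start + spacing * np.arange(n)  # excludes stop == start (periodic)
    return wrap_angle(centers)


def _bin_grid(n_bins: int) -> tuple[np.ndarray, np.ndarray, float]:
    edges = np.linspace(-180.0, 180.0, n_bins + 1)
    centers = (edges[:-1] + edges[1:]) / 2.0
    width = 360.0 / n_bins
    return edges, centers, width


def _bias_factor_matrix(K, cen, centers, width_deg, kT):
    """Boltzmann factor of each harmonic bias averaged analytically over
    each bin.  At stiff force constants the bias changes by more than kT
    within a bin, so evaluating at the bin centre would systematically
    distort the unbiasing; the erf-integrated average removes that.
    Minimum-image angular differences enforce periodicity.
    """
    from scipy.special import erf

    dx = np.radians(wrap_angle(centers[None, :] - cen[:, None]))  # (nw, nb)
    half = np.radians(width_deg) / 2.0
    out = np.empty_like(dx)
    for i in range(len(K)):
        if K[i] <= 0:
            out[i] = 1.0
            continue
        c = 0.5 * K[i] / kT
        sc = np.sqrt(c)
        out[i] = (
            np.sqrt(np.pi / c)
            / 2.0
            * (erf(sc * (dx[i] + half)) - erf(sc * (dx[i] - half)))
            / (2.0 * half)
        )
    return out


def wham(
    windows: list[UmbrellaWindow],
    n_bins: int = 720,
    tolerance: float = 1e-6,
    temperature: float = 300.0,
    max_iter: int = 100_000,
    refinement: int = 8,
) -> PMFProfile:
    """Periodic WHAM: self-consistent unbiasing of the window histograms.

    The window free-energy constants are obtained by minimizing the
    (convex) WHAM log-likelihood, then certified by fixed-point sweeps of
    the self-consistency equations until the largest change falls below
    ``tolerance`` (kcal/mol).  The bias uses the minimum-image periodic
    angular difference and is integrated analytically over each histogram
    bin; the self-consistency is solved on an internally refined grid
    (``refinement`` sub-bins per reported bin) to keep discretization
    error at stiff force constants negligible, and reported on the
    ``n_bins`` grid as W(x) = -kT ln p(x), anchored at min W = 0.  Bins
    never visited by any window are masked (NaN) with a warning.
    """
    from scipy.optimize import minimize
    from scipy.special import logsumexp

    if not windows:
        raise ValueError("need at least one window")
    if refinement < 1:
        raise ValueError("refinement must be >= 1")
    kT = KB_KCAL * temperature
    n_fine = n_bins * refinement
    edges_f, centers_f, width_f = _bin_grid(n_fine)
    nw = len(windows)
    counts = np.zeros((nw, n_fine))
    N = np.zeros(nw)
    for i, w in enumerate(windows):
        if len(w.samples) == 0:
            raise ValueError(f"window {i} has no samples")
        h, _ = np.histogram(wrap_angle(w.samples), bins=edges_f)
        counts[i] = h
        N[i] = h.sum()
    M = counts.sum(axis=0)  # (n_fine,)
    K = np.array([w.force_constant for w in windows])
    cen = np.array([w.center for w in windows])
    boltz = _bias_factor_matrix(K, cen, centers_f, width_f, kT)
    with np.errstate(divide="ignore"):
        log_c = np.log(boltz)  # -inf where factor underflows to 0
    logN = np.log(N)
    occupied = M > 0

    def objective(g):
        # F(g) = -sum_i N_i g_i + sum_b M_b ln sum_i N_i e^{g_i} c_ib
        a = (logN + g)[:, None] + log_c  # (nw, n_fine)
        logD = logsumexp(a, axis=0)
        F = -(N * g).sum() + (M[occupied] * logD[occupied]).sum()
        # grad_k = N_k (e^{g_k} sum_b M_b c_kb / D_b - 1)
        w_b = np.where(occupied, M, 0.0) * np.exp(-logD, where=np.isfinite(logD),
                                                  out=np.zeros_like(logD))
        s = (np.exp(log_c, where=np.isfinite(log_c), out=np.zeros_like(log_c)) * w_b).sum(axis=1)
        grad = N * (np.exp(g) * s - 1.0)
        return F, grad

    res = minimize(
        objective,
        np.zeros(nw),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": 5000, "ftol": 1e-14, "gtol": 1e-12},
    )
    g = res.x  # dimensionless beta*f up to gauge
    # fixed-point sweeps at the stated tolerance (certification / polish)
    f = kT * g
    f -= f[0]
    delta = np.inf
    for _ in range(max_iter):
        denom = (N[:, None] * np.exp(f[:, None] / kT) * boltz).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(denom > 0, M / denom, 0.0)
        z = (boltz * p[None, :]).sum(axis=1)
        f_new = -kT * np.log(z)
        f_new -= f_new[0]
        delta = np.abs(f_new - f).max()
        f = f_new
        if delta < tolerance:
            break
    else:
        raise RuntimeError(
            f"WHAM did not converge in {max_iter} iterations (residual {delta:.3e})"
        )
    denom = (N[:, None] * np.exp(f[:, None] / kT) * boltz).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(denom > 0, M / denom, 0.0)
    # aggregate fine-bin masses onto the reported grid
    p_coarse = p.reshape(n_bins, refinement).sum(axis=1)
    visited = M.reshape(n_bins, refinement).sum(axis=1) > 0
    _, centers, _ = _bin_grid(n_bins)
    if (~visited).any():
        warnings.warn(
            f"{int((~visited).sum())} of {n_bins} bins have no samples; masked",
            RuntimeWarning,
        )
    with np.errstate(divide="ignore"):
        W = np.where(
            visited & (p_coarse > 0),
            -kT * np.log(np.where(p_coarse > 0, p_coarse, 1.0)),
            np.nan,
        )
    W -= np.nanmin(W)
    return PMFProfile(
        bin_centers=centers,
        free_energy=W,
        temperature=temperature,
        window_free_energies=f,
    )


def pmf_error(
    windows: list[UmbrellaWindow],
    n_blocks: int = 4,
    n_bins: int = 720,
    tolerance: float = 1e-6,
    temperature: float = 300.0,
) -> np.ndarray:
    """Per-bin PMF error: split each window's series into ``n_blocks``
    contiguous parts, run WHAM per part, anchor all profiles at the same
    bin, and take the per-bin standard deviation.
    """
    min_len = min(len(w.samples) for w in windows)
    if min_len < n_blocks:
        raise ValueError(f"windows must have at least {n_blocks} samples each")
    profiles = []
    for b in range(n_blocks):
        part = [
            UmbrellaWindow(
                center=w.center,
                force_constant=w.force_constant,
                samples=w.samples[
                    (b * len(w.samples)) // n_blocks : ((b + 1) * len(w.samples)) // n_blocks
                ],
                temperature=w.temperature,
            )
            for w in windows
        ]
        profiles.append(
            wham(part, n_bins=n_bins, tolerance=tolerance, temperature=temperature)
        )
    W = np.stack([p.free_energy for p in profiles])
    # identical anchoring: zero every profile at the bin where the mean
    # profile is lowest, so block-to-block offsets do not inflate errors
    mean_prof = np.nanmean(W, axis=0)
    anchor = int(np.nanargmin(mean_prof))
    W = W - W[:, anchor][:, None]
    return np.nanstd(W, axis=0, ddof=1)


# --------------------------------------------------------------------------
# Solvent accessibility and open/closed classification
# --------------------------------------------------------------------------


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0**0.5) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def sasa(
    structure: AtomicStructure,
    radii_nm: dict[str, float] | None = None,
    probe_nm: float = 0.0,
    n_points: int = 960,
    frame: int = 0,
    atom_indices=None,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area (nm^2), numerical.

    Shrake-Rupley style: a deterministic quasi-uniform point set on each
    atom's expanded sphere (element radius + probe); a point is accessible
    if outside every neighbour's expanded sphere.  Identical inputs give
    bit-identical areas.  ``atom_indices`` restricts the computation to a
    subset of atoms (all atoms still occlude); other entries are NaN.
    """
    radii_nm = radii_nm if radii_nm is not None else DEFAULT_RADII_NM
    try:
        r = np.array([radii_nm[a.element] for a in structure.atoms]) + probe_nm
    except KeyError as exc:
        raise StructureError(f"no radius for element {exc.args[0]!r}") from exc
    xyz = structure.coords[frame] * 0.1  # Angstrom -> nm
    n = len(xyz)
    pts = _sphere_points(n_points)
    which = np.arange(n) if atom_indices is None else np.asarray(atom_indices, int)
    areas = np.full(n, np.nan)
    rmax = r.max()
    for i in which:
        d = np.linalg.norm(xyz - xyz[i], axis=1)
        nbr = np.where((d < r[i] + rmax) & (np.arange(n) != i))[0]
        surface = xyz[i] + r[i] * pts
        if len(nbr):
            d2 = ((surface[:, None, :] - xyz[nbr][None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (r[nbr] ** 2)[None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        areas[i] = 4.0 * np.pi * r[i] ** 2 * frac
    return areas


@dataclass
class OpenCloseDefinition:
    """SASA-based open/closed criterion for a breathing base pair.

    Classification rolls a water-sized probe (0.14 nm) over the atomic
    radii: with a bare zero-probe surface the reporter proton of even a
    perfectly paired base retains residual geometric accessibility through
    the inter-atomic gaps, and no intact pair would ever classify as
    closed under the stated threshold.
    """

    reporter: tuple[int, str]  # (residue_index, atom_name): H3 of T, N1 of A/G
    threshold_nm2: float = 0.001
    radii_nm: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_RADII_NM))
    probe_nm: float = 0.14

    def __post_init__(self):
        if self.threshold_nm2 <= 0:
            raise ValueError("threshold must be positive")


def classify_open_closed(
    structures: list[AtomicStructure] | AtomicStructure,
    definition: OpenCloseDefinition,
) -> np.ndarray:
    """Per-frame boolean labels, True = closed (reporter SASA < threshold)."""
    if isinstance(structures, AtomicStructure):
        frames = [(structures, f) for f in range(structures.n_frames)]
    else:
        frames = [(s, f) for s in structures for f in range(s.n_frames)]
    labels = np.zeros(len(frames), dtype=bool)
    res, name = definition.reporter
    for k, (s, f) in enumerate(frames):
        idx = [
            i
            for i, a in enumerate(s.atoms)
            if a.residue_index == res and a.name == name
        ]
        if not idx:
            raise StructureError(f"reporter atom {name!r} of residue {res} missing")
        areas = sasa(s, definition.radii_nm, definition.probe_nm, frame=f,
                     atom_indices=idx[:1])
        labels[k] = areas[idx[0]] < definition.threshold_nm2
    return labels


def closed_partition_from_labels(
    window_centers: np.ndarray, closed_labels: np.ndarray
) -> np.ndarray:
    """Angular partition from per-window majority labels.

    Returns a boolean mask over the window centres marking the closed
    state; downstream integration assigns each PMF bin the label of its
    nearest window centre (boundary bins therefore side with the closed
    windows around the closed interval's edges).
    """
    window_centers = np.asarray(window_centers, float)
    closed_labels = np.asarray(closed_labels, bool)
    if window_centers.shape != closed_labels.shape:
        raise ValueError("one label per window centre required")
    return closed_labels


def _bin_closed_mask(pmf: PMFProfile, window_centers, closed_labels) -> np.ndarray:
    """Assign each PMF bin the closed/open label of the nearest window."""
    centers = np.asarray(window_centers, float)
    labels = np.asarray(closed_labels, bool)
    d = np.abs(wrap_angle(pmf.bin_centers[:, None] - centers[None, :]))
    nearest = np.argmin(d, axis=1)
    mask = labels[nearest]
    # boundary bins (equidistant to a closed and an open window) -> closed
    d_sorted = np.sort(d, axis=1)
    tie = np.isclose(d_sorted[:, 0], d_sorted[:, 1])
    if tie.any():
        for b in np.where(tie)[0]:
            cands = np.where(np.isclose(d[b], d_sorted[b, 0]))[0]
            mask[b] = labels[cands].any()
    return mask


def delta_g_open(
    pmf: PMFProfile,
    closed_mask: np.ndarray | None = None,
    window_centers=None,
    closed_labels=None,
) -> float:
    """Opening free energy by Boltzmann integration over the two states.

    dG = -kT ln( integral_open exp(-W/kT) / integral_closed exp(-W/kT) ).
    The partition comes either from an explicit per-bin ``closed_mask`` or
    from per-window closed labels (nearest-window assignment).  Masked
    (NaN) bins carry zero weight.  Invariant under adding a constant to W.
    """
    if closed_mask is None:
        if window_centers is None or closed_labels is None:
            raise ValueError("need closed_mask or window centres + labels")
        closed_mask = _bin_closed_mask(pmf, window_centers, closed_labels)
    closed_mask = np.asarray(closed_mask, bool)
    if closed_mask.shape != pmf.bin_centers.shape:
        raise ValueError("closed_mask must have one entry per PMF bin")
    if closed_mask.all() or (~closed_mask).all():
        raise ValueError("both open and closed regions must be non-empty")
    kT = KB_KCAL * pmf.temperature
    w = np.nan_to_num(np.exp(-pmf.free_energy / kT), nan=0.0)
    z_closed = w[closed_mask].sum()
    z_open = w[~closed_mask].sum()
    if z_closed <= 0 or z_open <= 0:
        raise ValueError("empty open or closed Boltzmann weight")
    return float(-kT * np.log(z_open / z_closed))


def barrier(pmf: PMFProfile, split_at: float | None = None) -> dict[str, float]:
    """Flipping barrier: max(W) - min(W) over the profile.

    With ``split_at`` (degrees) the per-direction barriers are also
    reported: the maximum relative to the global minimum on each side of
    the split between the minimum and the split angle (positive rotation
    = toward the major groove by the default sign convention).
    """
    W = pmf.free_energy
    finite = np.isfinite(W)
    total = float(np.nanmax(W) - np.nanmin(W))
    out = {"barrier": total}
    if split_at is not None:
        x = pmf.bin_centers
        imin = int(np.nanargmin(np.where(finite, W, np.inf)))
        x0 = x[imin]
        rel_split = wrap_angle(split_at - x0)
        rel = wrap_angle(x - x0)
        pos = (rel >= 0) & (rel <= max(rel_split, 0)) if rel_split >= 0 else (rel >= 0)
        neg = (rel <= 0) & (rel >= min(rel_split, 0)) if rel_split < 0 else (rel <= 0)
        for name, side in (("barrier_major", pos), ("barrier_minor", neg)):
            vals = W[side & finite]
            out[name] = float(vals.max() - W[imin]) if len(vals) else np.nan
    return out
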