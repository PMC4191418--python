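"""Synthetic generation of every input the analysis pipeline consumes.

Four generators, all with exact known ground truth:

* :func:`rebuild_helix` — a duplex rebuilt from per-step rigid-body
  parameters; the frame-analysis layer recovers the construction targets
  exactly (mutual inverses).
* :func:`build_triplex` — a third strand placed onto the purine strand by a
  fixed, idealized reverse-Hoogsteen rigid transform per triplet type
  (G-G.C, A-A.T), frozen from an in-plane H-bond-geometry optimization;
  the construction is synthetic (no force field), validated by
  donor-acceptor distances and steric clearance.
* :func:`sample_step_ensemble` — a multi-frame ensemble with per-step
  Gaussian step-parameter fluctuations of declared mean and covariance.
* :func:`sample_biased_windows` — umbrella-sampling window series drawn
  from a declared periodic free-energy surface under harmonic biases, via
  an adaptive Metropolis walk on the scalar coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from . import bases
from .frames import (
    BaseFrame,
    StepParameters,
    _frames_from_step,
    compose_step,
    fit_base_frame,
    flip_frame,
)
from .structure import Atom, AtomicStructure, StructureError
from .flipping import UmbrellaWindow

__all__ = [
    "StepParameterTarget",
    "PairParameterTarget",
    "EnsembleSpec",
    "BiasedSamplerSpec",
    "CANONICAL_B",
    "CANONICAL_A",
    "rebuild_helix",
    "build_triplex",
    "sample_step_ensemble",
    "sample_biased_windows",
    "HOOGSTEEN_PLACEMENTS",
]

KB_KCAL = 0.0019872041  # Boltzmann constant, kcal/(mol K)


@dataclass(frozen=True)
class StepParameterTarget:
    """Six rigid-body step parameters: Angstrom / degrees."""

    shift: float = 0.0
    slide: float = 0.0
    rise: float = 3.32
    tilt: float = 0.0
    roll: float = 0.0
    twist: float = 36.0

    def __post_init__(self):
        vals = (self.shift, self.slide, self.rise, self.tilt, self.roll, self.twist)
        if not all(np.isfinite(vals)):
            raise ValueError("step parameters must be finite")
        if self.rise <= 0:
            raise ValueError(f"non-physical step: rise = {self.rise} must be > 0")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.shift, self.slide, self.rise, self.tilt, self.roll, self.twist]
        )


@dataclass(frozen=True)
class PairParameterTarget:
    """Intra-pair parameters; all-zero = planar Watson-Crick geometry."""

    shear: float = 0.0
    stretch: float = 0.0
    stagger: float = 0.0
    buckle: float = 0.0
    propeller: float = 0.0
    opening: float = 0.0


# Canonical fiber-model step parameters (Twist, Roll, Rise are the
# standard B-/A-form reference values: 36.0/31.1 deg, 0.6/8.0 deg,
# 3.32/3.31 A; Slide set to the conventional B ~ +0.4, A ~ -1.5 A).
CANONICAL_B = StepParameterTarget(shift=0.0, slide=0.37, rise=3.32, tilt=0.0, roll=0.6, twist=36.0)
CANONICAL_A = StepParameterTarget(shift=0.0, slide=-1.53, rise=3.31, tilt=0.0, roll=8.0, twist=31.1)


# --------------------------------------------------------------------------
# Helix rebuilding
# --------------------------------------------------------------------------


def _template(base: str):
    names, elements, coords = bases.residue_template(base)
    return names, elements, coords


def _strip_5prime(names, elements, coords):
    keep = [i for i, n in enumerate(names) if n not in ("P", "OP1", "OP2")]
    return (
        [names[i] for i in keep],
        [elements[i] for i in keep],
        coords[keep],
    )


def _pair_base_frames(pair_frame_triad: BaseFrame, pair: PairParameterTarget):
    """Leading and complementary base frames realizing the pair parameters
    about the given pair mid-frame (exact inverse of pair analysis)."""
    step_like = StepParameters(
        shift=pair.shear,
        slide=pair.stretch,
        rise=pair.stagger,
        tilt=pair.buckle,
        roll=pair.propeller,
        twist=pair.opening,
        mid_frame=pair_frame_triad,
    )
    f_comp_flipped, f_leading = _frames_from_step(step_like)
    return f_leading, flip_frame(f_comp_flipped)


def _helix_frames(
    n_bp: int,
    step_targets: Sequence[StepParameterTarget],
    pair_targets: Sequence[PairParameterTarget] | None,
    origin: BaseFrame | None,
):
    if len(step_targets) != n_bp - 1:
        raise ValueError(
            f"need one step target per dinucleotide step: {n_bp - 1}, got {len(step_targets)}"
        )
    pairs = list(pair_targets) if pair_targets is not None else [PairParameterTarget()] * n_bp
    if len(pairs) != n_bp:
        raise ValueError("need one pair target per base pair")
    pf = [origin or BaseFrame(np.zeros(3), np.eye(3))]
    for st in step_targets:
        pf.append(compose_step(pf[-1], *st.as_array()))
    return pf, pairs


def rebuild_helix(
    sequence: str,
    step_targets: Sequence[StepParameterTarget] | StepParameterTarget,
    pair_targets: Sequence[PairParameterTarget] | None = None,
    origin: BaseFrame | None = None,
) -> AtomicStructure:
    """Build a duplex from step parameters and standard base geometries.

    ``sequence`` is the leading strand 5'->3'; the complementary strand is
    generated Watson-Crick antiparallel.  A single ``StepParameterTarget``
    is broadcast to every step (fiber model).  Residues are numbered
    1..n (leading, chain A) and n+1..2n (complementary, chain B, its own
    5'->3' order); residue j pairs residue 2n+1-j.  5'-terminal residues
    carry no phosphate.
    """
    sequence = sequence.upper()
    n = len(sequence)
    if n < 2:
        raise ValueError("helix needs at least two base pairs")
    if isinstance(step_targets, StepParameterTarget):
        step_targets = [step_targets] * (n - 1)
    pf, pairs = _helix_frames(n, step_targets, pair_targets, origin)

    lead_frames: list[BaseFrame] = []
    comp_frames: list[BaseFrame] = []
    for i in range(n):
        fl, fc = _pair_base_frames(pf[i], pairs[i])
        lead_frames.append(fl)
        comp_frames.append(fc)

    atoms: list[Atom] = []
    coord_blocks: list[np.ndarray] = []

    def emit(res_idx, base, frame, chain, strip_p):
        names, elements, coords = _template(base)
        if strip_p:
            names, elements, coords = _strip_5prime(names, elements, coords)
        lab = coords @ frame.rotation.T + frame.origin
        res_name = {"A": "DA", "T": "DT", "G": "DG", "C": "DC"}[base]
        for nm, el in zip(names, elements):
            atoms.append(Atom(name=nm, element=el, residue_index=res_idx,
                              residue_name=res_name, chain_id=chain))
        coord_blocks.append(lab)

    for i in range(n):  # leading strand, residues 1..n
        emit(i + 1, sequence[i], lead_frames[i], "A", strip_p=(i == 0))
    for j in range(n):  # complementary strand 5'->3' = bp n..1, residues n+1..2n
        bp = n - 1 - j
        emit(n + 1 + j, bases.complement(sequence[bp]), comp_frames[bp], "B",
             strip_p=(j == 0))

    return AtomicStructure(atoms, np.vstack(coord_blocks)[None])


# --------------------------------------------------------------------------
# Reverse-Hoogsteen third-strand placement
# --------------------------------------------------------------------------

# Rigid placement of the third-strand base in the coordinates of the duplex
# purine's base frame: own frame = purine frame o (Rz(theta) . diag(1,-1,-1))
# with the stated in-plane translation (Angstrom).  Frozen from an idealized
# coplanar H-bond-geometry optimization (both donor-acceptor distances
# 2.90 A, steric clearance > 3.5 A, trans glycosidic arrangement):
#   A-A.T:  N6(tfo)...N7(wc) and N1(tfo)...N6(wc)
#   G-G.C:  N1(tfo)...N7(wc) and N2(tfo)...O6(wc)
HOOGSTEEN_PLACEMENTS: dict[str, tuple[float, tuple[float, float]]] = {
    "A": (114.78, (3.6262, 2.1242)),
    "G": (112.60, (2.8358, 5.0174)),
}


def _hoogsteen_frame(purine_frame: BaseFrame, base: str) -> BaseFrame:
    theta_deg, (tx, ty) = HOOGSTEEN_PLACEMENTS[base]
    th = np.radians(theta_deg)
    c, s = np.cos(th), np.sin(th)
    R_local = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]]) @ np.diag(
        [1.0, -1.0, -1.0]
    )
    R = purine_frame.rotation @ R_local
    origin = purine_frame.origin + purine_frame.rotation @ np.array([tx, ty, 0.0])
    return BaseFrame(origin, R)


def build_triplex(
    duplex: AtomicStructure,
    tfo_seq: str,
    target_start: int,
) -> AtomicStructure:
    """Attach an antiparallel reverse-Hoogsteen third strand to a duplex.

    ``tfo_seq`` is the third strand 5'->3'; its residue ``m`` (0-based)
    pairs leading-strand purine ``target_start + len(tfo_seq) - 1 - m``.
    The target region must be all purines and each TFO base must equal its
    target (G-G.C and A-A.T triplets).  TFO residues are numbered from
    ``2 n_bp + 1`` on chain C.  An empty ``tfo_seq`` returns the structure
    unchanged.
    """
    tfo_seq = tfo_seq.upper()
    if not tfo_seq:
        return AtomicStructure(duplex.atoms, duplex.coords.copy())
    res_indices = duplex.residue_indices()
    n_bp = max(res_indices) // 2
    hi = target_start + len(tfo_seq) - 1
    targets = list(range(target_start, hi + 1))
    bad = [i for i in targets if not bases.is_purine(duplex.residue_base(i))]
    if bad:
        raise StructureError(
            f"TFO target region contains pyrimidines at leading-strand positions {bad}"
        )
    for m, b in enumerate(tfo_seq):
        if b != duplex.residue_base(hi - m):
            raise StructureError(
                f"TFO base {b} at position {m + 1} does not match purine "
                f"{duplex.residue_base(hi - m)} at bp {hi - m} (antiparallel register)"
            )

    # assemble TFO atoms once (names/elements), coords per frame
    tfo_atoms: list[Atom] = []
    blocks_per_frame: list[list[np.ndarray]] = [[] for _ in range(duplex.n_frames)]
    for m, b in enumerate(tfo_seq):
        names, elements, coords = _template(b)
        if m == 0:
            names, elements, coords = _strip_5prime(list(names), list(elements), coords)
        res_idx = 2 * n_bp + 1 + m
        res_name = {"A": "DA", "G": "DG"}[b]
        for nm, el in zip(names, elements):
            tfo_atoms.append(Atom(name=nm, element=el, residue_index=res_idx,
                                  residue_name=res_name, chain_id="C"))
        purine_res = hi - m
        for f in range(duplex.n_frames):
            names_w, coords_w = duplex.residue_coords(purine_res, frame=f)
            pframe = fit_base_frame(names_w, coords_w, duplex.residue_base(purine_res))
            frame = _hoogsteen_frame(pframe, b)
            blocks_per_frame[f].append(coords @ frame.rotation.T + frame.origin)

    all_atoms = list(duplex.atoms) + tfo_atoms
    frames = [
        np.vstack([duplex.coords[f]] + blocks_per_frame[f])
        for f in range(duplex.n_frames)
    ]
    return AtomicStructure(all_atoms, np.stack(frames))


# --------------------------------------------------------------------------
# Gaussian step-parameter ensembles
# --------------------------------------------------------------------------


@dataclass
class EnsembleSpec:
    """Multi-frame helix ensemble with Gaussian step-parameter noise.

    ``means``: (n_steps, 6) per-step mean of (shift, slide, rise, tilt,
    roll, twist); ``covariances``: (n_steps, 6, 6), symmetric PSD.  A
    single 6-vector / 6x6 matrix is broadcast to every step.
    """

    sequence: str
    means: np.ndarray
    covariances: np.ndarray
    n_frames: int = 100
    seed: int = 0
    pair_targets: Sequence[PairParameterTarget] | None = None

    def __post_init__(self):
        self.sequence = self.sequence.upper()
        n_steps = len(self.sequence) - 1
        means = np.asarray(self.means, dtype=float)
        if means.ndim == 1:
            means = np.tile(means, (n_steps, 1))
        covs = np.asarray(self.covariances, dtype=float)
        if covs.ndim == 2:
            covs = np.tile(covs, (n_steps, 1, 1))
        if means.shape != (n_steps, 6) or covs.shape != (n_steps, 6, 6):
            raise ValueError("means must be (n_steps, 6), covariances (n_steps, 6, 6)")
        for c in covs:
            if not np.allclose(c, c.T, atol=1e-10):
                raise ValueError("covariance must be symmetric")
            if np.linalg.eigvalsh(c).min() < -1e-8:
                raise ValueError("covariance must be positive semi-definite")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        self.means = means
        self.covariances = covs


def sample_step_ensemble(spec: EnsembleSpec) -> AtomicStructure:
    """Draw per-frame step parameters and rebuild each frame.

    Every frame is an independent draw: step ``s`` of frame ``f`` is
    Gaussian with the spec's per-step mean and covariance.  Seeded and
    reproducible.  Draws with non-positive rise are rejected and redrawn
    (they would be unphysical helices); the redraw count is negligible for
    realistic specs.
    """
    rng = np.random.default_rng(spec.seed)
    n_steps = len(spec.sequence) - 1
    chols = []
    for c in spec.covariances:
        # PSD (possibly singular) Cholesky via eigendecomposition
        w, V = np.linalg.eigh(c)
        chols.append(V @ np.diag(np.sqrt(np.clip(w, 0.0, None))))
    structure0 = None
    frames = []
    atoms = None
    for f in range(spec.n_frames):
        params = []
        for s in range(n_steps):
            for _ in range(100):
                draw = spec.means[s] + chols[s] @ rng.standard_normal(6)
                if draw[2] > 0:
                    break
            else:
                raise ValueError(f"step {s}: could not draw a positive rise")
            params.append(StepParameterTarget(*draw))
        st = rebuild_helix(spec.sequence, params, pair_targets=spec.pair_targets)
        if atoms is None:
            atoms = st.atoms
            structure0 = st
        frames.append(st.coords[0])
    return AtomicStructure(atoms, np.stack(frames))


# --------------------------------------------------------------------------
# Umbrella-window sampling on a known periodic free-energy surface
# --------------------------------------------------------------------------


def _wrap_deg(x):
    """Map angles to (-180, 180]."""
    return -((-np.asarray(x, float) + 180.0) % 360.0 - 180.0)


@dataclass
class BiasedSamplerSpec:
    """Umbrella sampling from a declared periodic PMF under harmonic bias.

    ``true_pmf``: vectorized callable, degrees -> kcal/mol, periodic on
    (-180, 180].  ``force_constant`` in kcal/(mol rad^2) -- the bias is
    ``k/2 * dx^2`` with ``dx`` the minimum-image angular difference in
    radians.  ``n_samples`` recorded per window after ``n_burn`` adaptive
    burn-in sweeps.
    """

    true_pmf: Callable[[np.ndarray], np.ndarray]
    window_centers: np.ndarray
    force_constant: float = 2000.0
    n_samples: int = 5000
    temperature: float = 300.0
    seed: int = 0
    n_burn: int = 1000
    thin: int = 4  # sweeps between recorded samples (decorrelation)
    independence_fraction: float = 0.7  # share of independence proposals in production

    def __post_init__(self):
        self.window_centers = np.asarray(self.window_centers, dtype=float)
        if self.force_constant < 0:
            raise ValueError("force constant must be >= 0")
        if self.n_samples < 1:
            raise ValueError("must request at least one sample per window")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


def sample_biased_windows(spec: BiasedSamplerSpec) -> list[UmbrellaWindow]:
    """Markov-chain sampling of every window's biased distribution.

    All windows advance in lockstep (vectorized across windows); each
    window's chain starts at its center.  Burn-in uses a plain Metropolis
    random walk whose per-window step adapts toward 30-60% acceptance and
    which estimates each window's location and spread.  Production sweeps
    use a Metropolis-Hastings mixture of the random walk and an
    independence proposal built from those estimates, which decorrelates
    the chain in the harmonic-bias-dominated regime.  Production
    acceptance is recorded on each returned window.
    """
    kT = KB_KCAL * spec.temperature
    centers = spec.window_centers
    nw = len(centers)
    if nw == 0:
        raise ValueError("no windows")
    rng = np.random.default_rng(spec.seed)

    def energy(x):
        dx = np.radians(_wrap_deg(x - centers))
        return np.asarray(spec.true_pmf(x), float) + 0.5 * spec.force_constant * dx**2

    x = centers.astype(float).copy()
    e = energy(x)
    step = np.full(nw, 5.0)  # degrees
    acc_win = np.zeros(nw)
    block = 50
    # moment accumulators over the second half of burn-in
    s0, s1, s2 = 0, np.zeros(nw), np.zeros(nw)
    for sweep in range(spec.n_burn):
        prop = _wrap_deg(x + step * rng.standard_normal(nw))
        ep = energy(prop)
        accept = rng.random(nw) < np.exp(np.minimum(0.0, -(ep - e) / kT))
        x = np.where(accept, prop, x)
        e = np.where(accept, ep, e)
        acc_win += accept
        if (sweep + 1) % block == 0:
            rate = acc_win / block
            step = np.where(rate < 0.30, step * 0.7, step)
            step = np.where(rate > 0.60, np.minimum(step * 1.4, 120.0), step)
            acc_win[:] = 0.0
        if sweep >= spec.n_burn // 2:
            d = _wrap_deg(x - centers)  # accumulate relative to centre (periodic safe)
            s0 += 1
            s1 += d
            s2 += d**2
    if s0 > 1:
        mu = centers + s1 / s0
        var = np.maximum(s2 / s0 - (s1 / s0) ** 2, 1e-12)
        sig = np.minimum(np.sqrt(var) * 1.3, 104.0)  # inflated; capped near uniform
    else:
        mu, sig = centers.astype(float), np.full(nw, 104.0)

    log_sqrt2pi = 0.5 * np.log(2.0 * np.pi)

    def _log_wrapped_normal(delta, sigma):
        """log density of a wrapped Gaussian on the circle (degrees),
        summed over +-2 periodic images (sigma capped well below 360)."""
        d = _wrap_deg(delta)
        terms = np.stack([-0.5 * ((d + 360.0 * k) / sigma) ** 2 for k in (-2, -1, 0, 1, 2)])
        m = terms.max(axis=0)
        return (
            m
            + np.log(np.exp(terms - m).sum(axis=0))
            - np.log(sigma)
            - log_sqrt2pi
        )

    def log_q(y, xf):
        """Mixture proposal density q(y | xf) per window (log)."""
        lrw = _log_wrapped_normal(y - xf, step)
        lin = _log_wrapped_normal(y - mu, sig)
        m = np.maximum(lrw, lin)
        pi = spec.independence_fraction
        return m + np.log((1 - pi) * np.exp(lrw - m) + pi * np.exp(lin - m))

    samples = np.empty((nw, spec.n_samples))
    accepted = np.zeros(nw)
    n_sweeps = spec.n_samples * spec.thin
    for i in range(n_sweeps):
        use_ind = rng.random(nw) < spec.independence_fraction
        prop_rw = _wrap_deg(x + step * rng.standard_normal(nw))
        prop_in = _wrap_deg(mu + sig * rng.standard_normal(nw))
        prop = np.where(use_ind, prop_in, prop_rw)
        ep = energy(prop)
        log_alpha = -(ep - e) / kT + log_q(x, prop) - log_q(prop, x)
        accept = np.log(rng.random(nw)) < np.minimum(0.0, log_alpha)
        x = np.where(accept, prop, x)
        e = np.where(accept, ep, e)
        accepted += accept
        if (i + 1) % spec.thin == 0:
            samples[:, (i + 1) // spec.thin - 1] = x
    rates = accepted / n_sweeps
    return [
        UmbrellaWindow(
            center=float(centers[i]),
            force_constant=spec.force_constant,
            samples=samples[i],
            temperature=spec.temperature,
            acceptance=float(rates[i]),
        )
        for i in range(nw)
    ]
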