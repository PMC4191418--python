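"""Base frames, base-pair frames, step parameters, local helical parameters
and the Zp/Zp(h) phosphate projections.

The rotational decomposition follows the symmetric mid-frame convention:
the two triads are each rotated by half the "roll-tilt" hinge angle onto a
shared z-axis, twist is measured about that shared axis, and translations
are expressed in the mid-frame.  The construction is exactly invertible,
which the synthetic builder exploits; see :func:`compose_step`.

Conventions: triads are 3x3 matrices whose columns are the x, y, z axes;
distances in Angstrom, angles in degrees at the API surface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import bases
from .geometry import assert_rotation, axis_angle_of, kabsch, rotation_about_axis, signed_angle
from .structure import AtomicStructure, PairingAnnotation, StructureError

__all__ = [
    "BaseFrame",
    "PairFrame",
    "StepParameters",
    "HelicalParameters",
    "ZpMetrics",
    "FrameFitError",
    "fit_base_frame",
    "pair_frame",
    "step_parameters",
    "compose_step",
    "helical_parameters",
    "zp_metrics",
    "flip_frame",
    "helix_step_table",
]


class FrameFitError(StructureError):
    """Base-frame fitting failed (missing or degenerate ring atoms)."""


@dataclass
class BaseFrame:
    """Right-handed orthonormal frame fitted to one base."""

    origin: np.ndarray  # (3,) Angstrom
    rotation: np.ndarray  # (3,3), columns = x,y,z axes
    fit_rmsd: float = 0.0

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float)
        self.rotation = np.asarray(self.rotation, dtype=float)
        assert_rotation(self.rotation)
        if self.fit_rmsd < 0:
            raise ValueError("fit_rmsd must be non-negative")

    @property
    def x(self):
        return self.rotation[:, 0]

    @property
    def y(self):
        return self.rotation[:, 1]

    @property
    def z(self):
        return self.rotation[:, 2]


@dataclass
class PairFrame(BaseFrame):
    """Mid-frame of a base pair plus the six intra-pair parameters."""

    shear: float = 0.0
    stretch: float = 0.0
    stagger: float = 0.0
    buckle: float = 0.0
    propeller: float = 0.0
    opening: float = 0.0


@dataclass
class StepParameters:
    """Six rigid-body parameters of a dinucleotide step and its mid-frame."""

    shift: float
    slide: float
    rise: float
    tilt: float
    roll: float
    twist: float
    mid_frame: BaseFrame
    near_180: bool = False  # quality flag: twist within 5 deg of +-180

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.shift, self.slide, self.rise, self.tilt, self.roll, self.twist]
        )


@dataclass
class HelicalParameters:
    """Step parameters re-expressed about the local helical (screw) axis."""

    x_displacement: float
    y_displacement: float
    inclination: float
    tip: float
    helical_twist: float
    helical_rise: float
    axis_point: np.ndarray
    axis_direction: np.ndarray
    degenerate: bool = False  # zero net rotation: axis undefined


@dataclass
class ZpMetrics:
    """Inter-strand P->P vector projections (A/B/TA-DNA discriminators)."""

    zp: float
    zp_h: float


def fit_base_frame(
    atom_names,
    atom_coords,
    base: str,
    standard: bases.StandardBaseGeometry | None = None,
) -> BaseFrame:
    """Fit the standard base frame to observed ring atoms.

    Least-squares rigid superposition of the standard ring-atom geometry
    onto the observed ring atoms; the returned frame maps standard-frame
    coordinates into the lab (``lab = R @ std + origin``).  Exocyclic atoms
    are deliberately excluded from the fit.
    """
    std = standard or bases.standard_geometry(base)
    have = {n: i for i, n in enumerate(atom_names)}
    missing = [n for n in std.ring_atoms if n not in have]
    if missing:
        raise FrameFitError(f"base {base}: missing ring atoms {missing}")
    obs = np.asarray(atom_coords, dtype=float)[[have[n] for n in std.ring_atoms]]
    if len(obs) < 3:
        raise FrameFitError("need at least three ring atoms")
    centered = obs - obs.mean(axis=0)
    svals = np.linalg.svd(centered, compute_uv=False)
    if svals[1] < 1e-6:
        raise FrameFitError("ring atoms are collinear; frame is degenerate")
    R, t, rmsd = kabsch(std.ring_coords, obs)
    return BaseFrame(origin=t, rotation=R, fit_rmsd=rmsd)


def flip_frame(frame: BaseFrame) -> BaseFrame:
    """Reverse a frame's y and z axes (complementary-strand convention)."""
    F = frame.rotation.copy()
    F[:, 1] *= -1.0
    F[:, 2] *= -1.0
    return BaseFrame(origin=frame.origin.copy(), rotation=F, fit_rmsd=frame.fit_rmsd)


def _mid_frame_decompose(T1: np.ndarray, T2: np.ndarray, o1, o2):
    """Symmetric mid-frame decomposition of the rigid motion frame1 -> frame2.

    Returns (translations (3,), rotations (tilt-like, roll-like, twist) in
    degrees, mid origin, mid triad).
    """
    z1, z2 = T1[:, 2], T2[:, 2]
    cross = np.cross(z1, z2)
    norm = np.linalg.norm(cross)
    gamma = float(np.arctan2(norm, np.dot(z1, z2)))
    if norm < 1e-12:
        # z axes already parallel (or antiparallel): no hinge needed
        hinge = T1[:, 1]
    else:
        hinge = cross / norm
    T1p = rotation_about_axis(hinge, gamma / 2.0) @ T1
    T2p = rotation_about_axis(hinge, -gamma / 2.0) @ T2
    zm = T1p[:, 2]
    twist = signed_angle(T1p[:, 0], T2p[:, 0], zm)
    xm = T1p[:, 0] + T2p[:, 0]
    nx = np.linalg.norm(xm)
    if nx < 1e-12:  # twist = 180 deg exactly: bisector undefined
        xm = T1p[:, 0]
    else:
        xm = xm / nx
    ym = np.cross(zm, xm)
    Tm = np.column_stack([xm, ym, zm])
    # split the hinge angle into roll (about ym) and tilt (about xm)
    phi = signed_angle(hinge, ym, zm)
    roll = gamma * np.cos(phi)
    tilt = gamma * np.sin(phi)
    om = (np.asarray(o1) + np.asarray(o2)) / 2.0
    trans = Tm.T @ (np.asarray(o2) - np.asarray(o1))
    rot = np.degrees([tilt, roll, twist])
    return trans, rot, om, Tm


def pair_frame(frame_leading: BaseFrame, frame_complementary: BaseFrame) -> PairFrame:
    """Mid-frame and parameters of a Watson-Crick (or Hoogsteen) pair.

    The complementary base's frame is flipped (y, z negated) before the
    symmetric mid-frame average; parameters describe the leading base
    relative to the flipped complementary base: translations (shear,
    stretch, stagger) and rotations (buckle, propeller, opening).
    """
    f2 = flip_frame(frame_complementary)
    trans, rot, om, Tm = _mid_frame_decompose(
        f2.rotation, frame_leading.rotation, f2.origin, frame_leading.origin
    )
    return PairFrame(
        origin=om,
        rotation=Tm,
        fit_rmsd=max(frame_leading.fit_rmsd, frame_complementary.fit_rmsd),
        shear=float(trans[0]),
        stretch=float(trans[1]),
        stagger=float(trans[2]),
        buckle=float(rot[0]),
        propeller=float(rot[1]),
        opening=float(rot[2]),
    )


def step_parameters(frame_i: BaseFrame, frame_i1: BaseFrame) -> StepParameters:
    """Six step parameters between consecutive (pair) frames, 5'->3'."""
    trans, rot, om, Tm = _mid_frame_decompose(
        frame_i.rotation, frame_i1.rotation, frame_i.origin, frame_i1.origin
    )
    twist = float(rot[2])
    return StepParameters(
        shift=float(trans[0]),
        slide=float(trans[1]),
        rise=float(trans[2]),
        tilt=float(rot[0]),
        roll=float(rot[1]),
        twist=twist,
        mid_frame=BaseFrame(origin=om, rotation=Tm),
        near_180=bool(abs(abs(twist) - 180.0) < 5.0),
    )


def compose_step(
    frame_i: BaseFrame,
    shift: float,
    slide: float,
    rise: float,
    tilt: float,
    roll: float,
    twist: float,
) -> BaseFrame:
    """Exact inverse of :func:`step_parameters`: build frame i+1 from frame i.

    Rejects non-physical steps with ``rise <= 0``.
    """
    if rise <= 0:
        raise ValueError(f"non-physical step: rise = {rise} must be > 0")
    t = np.radians(tilt)
    r = np.radians(roll)
    w = np.radians(twist)
    gamma = float(np.hypot(t, r))
    T1 = frame_i.rotation
    if gamma < 1e-15:
        Tm = T1 @ rotation_about_axis([0, 0, 1], w / 2.0)
        T2 = T1 @ rotation_about_axis([0, 0, 1], w)
    else:
        phi = float(np.arctan2(t, r))
        # hinge axis in mid-frame coordinates: rotate ym by -phi about zm
        # reconstruct by composing local rotations (verified exact inverse)
        Rz = rotation_about_axis
        A = Rz([0, 0, 1], w / 2.0 - phi) @ Rz([0, 1, 0], gamma) @ Rz([0, 0, 1], w / 2.0 + phi)
        T2 = T1 @ A
        Tm = T1 @ Rz([0, 0, 1], w / 2.0 - phi) @ Rz([0, 1, 0], gamma / 2.0) @ Rz([0, 0, 1], phi)
    o2 = frame_i.origin + Tm @ np.array([shift, slide, rise])
    return BaseFrame(origin=o2, rotation=T2)


def _frames_from_step(step: StepParameters) -> tuple[BaseFrame, BaseFrame]:
    """Reconstruct the two bounding frames from a step's mid-frame + params.

    Inverse of the symmetric decomposition:
    ``Tm = T1 Rz(w/2-phi) Ry(gamma/2) Rz(phi)`` and the origins sit at
    ``om -/+ Tm (shift, slide, rise)/2``.
    """
    t = np.radians(step.tilt)
    r = np.radians(step.roll)
    w = np.radians(step.twist)
    gamma = float(np.hypot(t, r))
    Tm = step.mid_frame.rotation
    Rz = rotation_about_axis
    if gamma < 1e-15:
        T1 = Tm @ Rz([0, 0, 1], -w / 2.0)
    else:
        phi = float(np.arctan2(t, r))
        T1 = (
            Tm
            @ Rz([0, 0, 1], -phi)
            @ Rz([0, 1, 0], -gamma / 2.0)
            @ Rz([0, 0, 1], phi - w / 2.0)
        )
    if gamma < 1e-15:
        T2 = Tm @ Rz([0, 0, 1], w / 2.0)
    else:
        T2 = (
            Tm
            @ Rz([0, 0, 1], -phi)
            @ Rz([0, 1, 0], gamma / 2.0)
            @ Rz([0, 0, 1], phi + w / 2.0)
        )
    half = Tm @ (np.array([step.shift, step.slide, step.rise]) / 2.0)
    f1 = BaseFrame(step.mid_frame.origin - half, T1)
    f2 = BaseFrame(step.mid_frame.origin + half, T2)
    return f1, f2


def helical_parameters(step: StepParameters, frame_i: BaseFrame | None = None,
                       frame_i1: BaseFrame | None = None) -> HelicalParameters:
    """Local helical (screw-axis) parameters of one step.

    The step's rigid motion is decomposed as a screw: rotation by the
    helical twist about an axis plus translation (helical rise) along it.
    x/y-displacement locate the mid-frame origin relative to the axis in a
    frame whose z is the axis and whose x is the mid-frame x projected
    perpendicular to it; inclination and tip describe the mid-frame's
    orientation relative to the axis.

    If the original two frames are given they are used directly; otherwise
    they are reconstructed from the mid-frame and the step parameters.
    """
    if frame_i is None or frame_i1 is None:
        frame_i, frame_i1 = _frames_from_step(step)
    T1, T2 = frame_i.rotation, frame_i1.rotation
    o1, o2 = frame_i.origin, frame_i1.origin
    Rstep = T2 @ T1.T
    axis, angle = axis_angle_of(Rstep)
    if angle < 1e-9:
        return HelicalParameters(
            x_displacement=np.nan, y_displacement=np.nan,
            inclination=np.nan, tip=np.nan,
            helical_twist=0.0, helical_rise=float(np.dot(o2 - o1, step.mid_frame.z)),
            axis_point=np.full(3, np.nan), axis_direction=np.full(3, np.nan),
            degenerate=True,
        )
    if np.dot(axis, step.mid_frame.z) < 0:
        axis = -axis
        # keep the rotation angle signed about the chosen axis direction
        angle = -angle
    d = float(np.dot(o2 - o1, axis))
    # point p on the axis: o2 - d*axis = Rstep (o1 - p) + p
    rhs = (o2 - d * axis) - Rstep @ o1
    p, *_ = np.linalg.lstsq(np.eye(3) - Rstep, rhs, rcond=None)
    # remove any component of p along the axis relative to the mid origin
    om = step.mid_frame.origin
    p = p + np.dot(om - p, axis) * axis
    zh = axis
    xh = step.mid_frame.x - np.dot(step.mid_frame.x, zh) * zh
    nx = np.linalg.norm(xh)
    if nx < 1e-12:
        raise ValueError("mid-frame x parallel to helical axis; frame undefined")
    xh /= nx
    yh = np.cross(zh, xh)
    disp = om - p
    dx = float(np.dot(disp, xh))
    dy = float(np.dot(disp, yh))
    # orientation of the mid-frame relative to the helical frame:
    # inclination = rotation about x bringing the axis into the pair z;
    # tip = rotation about y.
    # small-rotation decomposition zm ~= Rx(incl) Ry(tip) zh:
    # zm.yh = -sin(incl), zm.xh = sin(tip)
    zm = step.mid_frame.z
    inclination = np.degrees(np.arcsin(np.clip(-np.dot(zm, yh), -1.0, 1.0)))
    tip = np.degrees(np.arcsin(np.clip(np.dot(zm, xh), -1.0, 1.0)))
    return HelicalParameters(
        x_displacement=dx,
        y_displacement=dy,
        inclination=float(inclination),
        tip=float(tip),
        helical_twist=float(np.degrees(angle)),
        helical_rise=d,
        axis_point=p,
        axis_direction=zh,
    )


def zp_metrics(
    step: StepParameters,
    helical: HelicalParameters,
    p_leading: np.ndarray | None,
    p_complementary: np.ndarray | None,
) -> ZpMetrics:
    """Zp and Zp(h): projections of the inter-strand P->P vector.

    ``zp`` is the z-component of the vector from the complementary-strand
    phosphorus to the leading-strand phosphorus in the middle-step frame;
    ``zp_h`` is the same vector's component along the local helical axis.
    Missing phosphates (5' termini) yield NaN, flagged absent rather than
    zero.
    """
    if p_leading is None or p_complementary is None:
        return ZpMetrics(zp=np.nan, zp_h=np.nan)
    v = np.asarray(p_leading, float) - np.asarray(p_complementary, float)
    zp = float(np.dot(v, step.mid_frame.z))
    if helical.degenerate:
        zph = np.nan
    else:
        zph = float(np.dot(v, helical.axis_direction))
    return ZpMetrics(zp=zp, zp_h=zph)


# --------------------------------------------------------------------------
# Whole-helix analysis
# --------------------------------------------------------------------------


def _base_frame_of_residue(structure: AtomicStructure, res: int, frame: int) -> BaseFrame:
    base = structure.residue_base(res)
    names, coords = structure.residue_coords(res, frame=frame)
    return fit_base_frame(names, coords, base)


def _phosphorus(structure: AtomicStructure, res: int, frame: int):
    names, coords = structure.residue_coords(res, names=("P",), frame=frame)
    if not names:
        return None
    return coords[0]


def helix_step_table(
    structure: AtomicStructure,
    annotation: PairingAnnotation,
    frames: range | None = None,
    strand: str = "wc",
) -> pd.DataFrame:
    """Per-frame, per-step parameter table for a duplex (or the TFO strand).

    For ``strand="wc"`` pair frames are built from the annotated WC pairs
    and steps run along the leading strand 5'->3'.  For ``strand="tfo"``
    steps are computed over the third-strand base frames alone, 5'->3' of
    the TFO.  One row per (frame, step) with the six step parameters, the
    local helical parameters, Zp metrics, intra-pair parameters, region
    label and quality flags.
    """
    if strand not in ("wc", "tfo"):
        raise ValueError("strand must be 'wc' or 'tfo'")
    frame_range = frames if frames is not None else range(structure.n_frames)
    rows = []
    if strand == "wc":
        pairs = sorted(annotation.wc_pairs)
        n = len(pairs)
        for f in frame_range:
            pair_frames = []
            for i, j in pairs:
                bf_i = _base_frame_of_residue(structure, i, f)
                bf_j = _base_frame_of_residue(structure, j, f)
                pair_frames.append(pair_frame(bf_i, bf_j))
            for s in range(n - 1):
                (i1, j1), (i2, j2) = pairs[s], pairs[s + 1]
                step = step_parameters(pair_frames[s], pair_frames[s + 1])
                hel = helical_parameters(step, pair_frames[s], pair_frames[s + 1])
                # inter-strand phosphorus pair of this step:
                # leading-strand P of bp s+1, complementary-strand P of bp s's partner
                pL = _phosphorus(structure, i2, f)
                pC = _phosphorus(structure, j1, f)
                z = zp_metrics(step, hel, pL, pC)
                base_step = (
                    structure.residue_base(i1) + structure.residue_base(i2)
                )
                rows.append(
                    {
                        "frame": f,
                        "step": s + 1,
                        "bp_i": i1,
                        "bp_j": i2,
                        "step_seq": base_step,
                        "step_class": step_class(base_step),
                        "region": annotation.region_of(s + 1),
                        "shift": step.shift,
                        "slide": step.slide,
                        "rise": step.rise,
                        "tilt": step.tilt,
                        "roll": step.roll,
                        "twist": step.twist,
                        "x_displacement": hel.x_displacement,
                        "y_displacement": hel.y_displacement,
                        "inclination": hel.inclination,
                        "tip": hel.tip,
                        "helical_twist": hel.helical_twist,
                        "helical_rise": hel.helical_rise,
                        "zp": z.zp,
                        "zp_h": z.zp_h,
                        "shear": pair_frames[s].shear,
                        "stretch": pair_frames[s].stretch,
                        "stagger": pair_frames[s].stagger,
                        "buckle": pair_frames[s].buckle,
                        "propeller": pair_frames[s].propeller,
                        "opening": pair_frames[s].opening,
                        "flag_near_180": step.near_180,
                        "flag_degenerate_axis": hel.degenerate,
                    }
                )
    else:
        tfo_res = sorted(t for t, _ in annotation.hoogsteen_pairs)
        if len(tfo_res) < 2:
            raise ValueError("TFO strand has fewer than two residues")
        for f in frame_range:
            bframes = [_base_frame_of_residue(structure, r, f) for r in tfo_res]
            for s in range(len(tfo_res) - 1):
                step = step_parameters(bframes[s], bframes[s + 1])
                hel = helical_parameters(step, bframes[s], bframes[s + 1])
                base_step = structure.residue_base(tfo_res[s]) + structure.residue_base(
                    tfo_res[s + 1]
                )
                rows.append(
                    {
                        "frame": f,
                        "step": s + 1,
                        "bp_i": tfo_res[s],
                        "bp_j": tfo_res[s + 1],
                        "step_seq": base_step,
                        "step_class": step_class(base_step),
                        "region": "tfo",
                        "shift": step.shift,
                        "slide": step.slide,
                        "rise": step.rise,
                        "tilt": step.tilt,
                        "roll": step.roll,
                        "twist": step.twist,
                        "x_displacement": hel.x_displacement,
                        "y_displacement": hel.y_displacement,
                        "inclination": hel.inclination,
                        "tip": hel.tip,
                        "helical_twist": hel.helical_twist,
                        "helical_rise": hel.helical_rise,
                        "flag_near_180": step.near_180,
                        "flag_degenerate_axis": hel.degenerate,
                    }
                )
    return pd.DataFrame(rows)


def step_class(step_seq: str) -> str:
    """YR / RR / RY / YY class of a dinucleotide step (leading strand)."""
    kinds = ["R" if bases.is_purine(b) else "Y" for b in step_seq]
    return "".join(kinds)
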