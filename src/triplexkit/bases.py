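"""Standard nucleobase geometries in the standard base reference frame.

Every base type carries an idealized planar geometry expressed in the
standard reference frame used throughout rigid-body DNA analysis: the
origin sits in the base plane near the centre of the ring system, +x points
away from the helix axis into the major-groove edge, +y runs along the long
axis of the base pair toward the leading-strand sugar, and +z completes a
right-handed set (the base plane is the z = 0 plane).

Two layers are provided:

* ``BASE_FRAME_ATOMS`` — the embedded ring + exocyclic heavy-atom
  coordinates of A, T, G, C in the standard frame.  These are the anchor
  for base-frame fitting and are exact by construction.
* :func:`residue_template` — a full-atom nucleotide (sugar, phosphate,
  hydrogens) assembled at run time by superposing the Chemical Component
  Dictionary ideal residue (DA/DT/DG/DC, shipped with biotite) onto the
  embedded base atoms and snapping the shared base atoms exactly onto the
  embedded coordinates.  Helices rebuilt from these templates therefore
  analyze back to their construction parameters exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .geometry import kabsch

__all__ = [
    "StandardBaseGeometry",
    "BASE_FRAME_ATOMS",
    "RING_ATOMS",
    "EXOCYCLIC_ATOMS",
    "SUGAR_ATOMS",
    "standard_geometry",
    "residue_template",
    "is_purine",
    "complement",
]

# Heavy atoms of each base in the standard reference frame (x, y, z / Angstrom).
# Ring atoms first, then exocyclic substituents.
BASE_FRAME_ATOMS: dict[str, dict[str, tuple[float, float, float]]] = {
    "A": {
        "N9": (-1.291, 4.498, 0.000),
        "C8": (0.024, 4.897, 0.000),
        "N7": (0.877, 3.902, 0.000),
        "C5": (0.071, 2.771, 0.000),
        "C6": (0.369, 1.398, 0.000),
        "N1": (-0.668, 0.532, 0.000),
        "C2": (-1.912, 1.023, 0.000),
        "N3": (-2.320, 2.290, 0.000),
        "C4": (-1.267, 3.124, 0.000),
        "N6": (1.611, 0.909, 0.000),
    },
    "G": {
        "N9": (-1.289, 4.551, 0.000),
        "C8": (0.023, 4.962, 0.000),
        "N7": (0.870, 3.969, 0.000),
        "C5": (0.071, 2.833, 0.000),
        "C6": (0.424, 1.460, 0.000),
        "N1": (-0.700, 0.641, 0.000),
        "C2": (-1.999, 1.087, 0.000),
        "N3": (-2.342, 2.364, 0.001),
        "C4": (-1.265, 3.177, 0.000),
        "O6": (1.554, 0.955, 0.000),
        "N2": (-2.949, 0.139, -0.001),
    },
    "C": {
        "N1": (-1.285, 4.542, 0.000),
        "C2": (-1.472, 3.158, 0.000),
        "N3": (-0.391, 2.344, 0.000),
        "C4": (0.837, 2.868, 0.000),
        "C5": (1.056, 4.275, 0.000),
        "C6": (-0.023, 5.068, 0.000),
        "O2": (-2.628, 2.709, 0.001),
        "N4": (1.875, 2.027, 0.001),
    },
    "T": {
        "N1": (-1.284, 4.500, 0.000),
        "C2": (-1.462, 3.135, 0.000),
        "N3": (-0.298, 2.407, 0.000),
        "C4": (0.994, 2.897, 0.000),
        "C5": (1.106, 4.338, 0.000),
        "C6": (-0.024, 5.057, 0.000),
        "O2": (-2.562, 2.608, 0.000),
        "O4": (1.944, 2.119, 0.000),
        "C7": (2.466, 4.961, 0.001),
    },
}

RING_ATOMS: dict[str, tuple[str, ...]] = {
    "A": ("N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4"),
    "G": ("N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4"),
    "C": ("N1", "C2", "N3", "C4", "C5", "C6"),
    "T": ("N1", "C2", "N3", "C4", "C5", "C6"),
}

EXOCYCLIC_ATOMS: dict[str, tuple[str, ...]] = {
    "A": ("N6",),
    "G": ("O6", "N2"),
    "C": ("O2", "N4"),
    "T": ("O2", "O4", "C7"),
}

# Sugar heavy atoms (deoxyribose); used for pseudo-dihedral COM groups.
SUGAR_ATOMS: tuple[str, ...] = ("C1'", "C2'", "C3'", "C4'", "O4'", "O3'", "C5'", "O5'")

_PDB_RES_NAME = {"A": "DA", "G": "DG", "C": "DC", "T": "DT"}
_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}
# CCD thymine names its methyl C7; older files say C5M.  We normalize to C7.
_NAME_ALIASES = {"C5M": "C7", "O1P": "OP1", "O2P": "OP2"}


def is_purine(base: str) -> bool:
    return base.upper() in ("A", "G")


def complement(base: str) -> str:
    return _COMPLEMENT[base.upper()]


@dataclass(frozen=True)
class StandardBaseGeometry:
    """Idealized geometry of one base type in the standard reference frame."""

    base: str
    atom_names: tuple[str, ...]
    coords: np.ndarray = field(repr=False)  # (n, 3), Angstrom
    ring_atoms: tuple[str, ...]
    exocyclic_atoms: tuple[str, ...]

    def coords_of(self, names) -> np.ndarray:
        idx = {n: i for i, n in enumerate(self.atom_names)}
        missing = [n for n in names if n not in idx]
        if missing:
            raise KeyError(f"standard {self.base} geometry lacks atoms {missing}")
        return self.coords[[idx[n] for n in names]]

    @property
    def ring_coords(self) -> np.ndarray:
        return self.coords_of(self.ring_atoms)


@lru_cache(maxsize=None)
def standard_geometry(base: str) -> StandardBaseGeometry:
    """Base-only standard geometry (ring + exocyclic heavy atoms)."""
    base = base.upper()
    table = BASE_FRAME_ATOMS[base]
    names = tuple(table)
    coords = np.array([table[n] for n in names], dtype=float)
    return StandardBaseGeometry(
        base=base,
        atom_names=names,
        coords=coords,
        ring_atoms=RING_ATOMS[base],
        exocyclic_atoms=EXOCYCLIC_ATOMS[base],
    )


# Atoms only present on chain termini in the CCD ideal residues; dropped so
# templates represent mid-chain residues.
_TERMINAL_ONLY = {"OP3", "HOP3", "HOP2", "HO3'", "HO5'"}


# Backbone atoms shared across base types (one consistent sugar-phosphate
# conformer, so fiber helices have uniform backbone geometry).
_BACKBONE = (
    "P", "OP1", "OP2", "O5'", "C5'", "C4'", "O4'", "C3'", "O3'", "C2'", "C1'",
    "H5'", "H5''", "H4'", "H3'", "H2'", "H2''", "H1'",
)


def _ccd_in_standard_frame(base: str):
    """CCD ideal residue superposed into the standard base frame via its ring."""
    import biotite.structure.info as info

    res = info.residue(_PDB_RES_NAME[base])
    names = [_NAME_ALIASES.get(n, n) for n in res.atom_name]
    keep = [i for i, n in enumerate(names) if n not in _TERMINAL_ONLY]
    names = [names[i] for i in keep]
    elements = [str(res.element[i]) for i in keep]
    coords = np.asarray(res.coord, dtype=float)[keep]

    std = standard_geometry(base)
    ring = std.ring_atoms
    ccd_ring = np.array([coords[names.index(n)] for n in ring])
    R, t, rmsd = kabsch(ccd_ring, std.coords_of(ring))
    if rmsd > 0.1:
        raise RuntimeError(f"CCD ring geometry deviates from standard ({rmsd:.3f} A)")
    coords = coords @ R.T + t
    # snap shared base atoms exactly onto the embedded standard coordinates
    for i, n in enumerate(names):
        if n in BASE_FRAME_ATOMS[base]:
            coords[i] = BASE_FRAME_ATOMS[base][n]
    return names, elements, coords


@lru_cache(maxsize=None)
def residue_template(base: str, with_hydrogens: bool = True):
    """Full-atom nucleotide template in the standard base reference frame.

    Returns ``(atom_names, elements, coords)``.  Base heavy atoms coincide
    exactly with :data:`BASE_FRAME_ATOMS`; base hydrogens come from the
    base's own CCD ideal residue; the sugar-phosphate backbone is one
    shared conformer (taken from the purine template) so every residue of
    a rebuilt helix carries an identical backbone in its base frame.
    """
    base = base.upper()
    bb_names, bb_elements, bb_coords = _ccd_in_standard_frame("A")
    names, elements, coords = _ccd_in_standard_frame(base)

    out_names: list[str] = []
    out_elements: list[str] = []
    out_coords: list[np.ndarray] = []
    for n, e in zip(bb_names, bb_elements):
        if n in _BACKBONE and (with_hydrogens or e != "H"):
            out_names.append(n)
            out_elements.append(e)
            out_coords.append(bb_coords[bb_names.index(n)])
    for n, e in zip(names, elements):
        if n not in _BACKBONE and (with_hydrogens or e != "H"):
            out_names.append(n)
            out_elements.append(e)
            out_coords.append(coords[names.index(n)])
    return tuple(out_names), tuple(out_elements), np.array(out_coords)
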