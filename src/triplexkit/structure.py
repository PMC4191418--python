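"""Atomistic data model, PDB I/O and duplex/triplex pairing annotation.

The in-memory container is :class:`AtomicStructure`: a fixed atom list plus
one coordinate set per frame, so a multi-model PDB file maps onto a
multi-frame conformational ensemble.  Pairing is *declared*, not detected:
a :class:`SystemDefinition` states the strands and the pair rule, and
:func:`annotate_system` checks it against the structure and emits the
Watson-Crick pairs, reverse-Hoogsteen pairs and named regions used by the
downstream analyses.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .bases import complement, is_purine

__all__ = [
    "Atom",
    "AtomicStructure",
    "PairingAnnotation",
    "SystemDefinition",
    "StructureError",
    "ParseError",
    "AnnotationError",
    "read_structure",
    "write_structure",
    "annotate_system",
    "triplex_30mer_system",
]

_ALLOWED_ELEMENTS = {"C", "N", "O", "P", "H"}
_RES_NAME_TO_BASE = {
    "DA": "A", "DT": "T", "DG": "G", "DC": "C",
    "A": "A", "T": "T", "G": "G", "C": "C",
}


class StructureError(ValueError):
    """Inconsistent structural data (mismatched models, bad elements...)."""


class ParseError(StructureError):
    """Unparseable PDB content; the message names the offending line."""


class AnnotationError(StructureError):
    """Declared system does not match the structure's residues."""


@dataclass(frozen=True)
class Atom:
    """One atom: PDB-convention name, element, residue identity."""

    name: str
    element: str
    residue_index: int
    residue_name: str
    chain_id: str = "A"

    def __post_init__(self):
        if self.element not in _ALLOWED_ELEMENTS:
            raise StructureError(
                f"element {self.element!r} of atom {self.name!r} not one of "
                f"{sorted(_ALLOWED_ELEMENTS)}"
            )


class AtomicStructure:
    """An ordered atom list with one or more coordinate frames (Angstrom)."""

    def __init__(self, atoms: list[Atom], coords: np.ndarray):
        coords = np.asarray(coords, dtype=float)
        if coords.ndim == 2:
            coords = coords[None]
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise StructureError("coords must have shape (n_frames, n_atoms, 3)")
        if coords.shape[1] != len(atoms):
            raise StructureError(
                f"coordinate array has {coords.shape[1]} atoms, atom list has {len(atoms)}"
            )
        if coords.shape[0] < 1:
            raise StructureError("structure needs at least one frame")
        if not np.isfinite(coords).all():
            raise StructureError("coordinates must be finite")
        self.atoms = list(atoms)
        self.coords = coords

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_frames(self) -> int:
        return int(self.coords.shape[0])

    def frame(self, i: int) -> "AtomicStructure":
        return AtomicStructure(self.atoms, self.coords[i][None])

    def residue_indices(self) -> list[int]:
        """Distinct residue indices in order of first appearance."""
        seen: dict[int, None] = {}
        for a in self.atoms:
            seen.setdefault(a.residue_index, None)
        return list(seen)

    def atom_mask(self, residue_index: int, names=None) -> np.ndarray:
        mask = np.array(
            [
                a.residue_index == residue_index
                and (names is None or a.name in names)
                for a in self.atoms
            ]
        )
        return mask

    def residue_coords(
        self, residue_index: int, names=None, frame: int = 0
    ) -> tuple[list[str], np.ndarray]:
        mask = self.atom_mask(residue_index, names)
        got = [a.name for a, m in zip(self.atoms, mask) if m]
        return got, self.coords[frame][mask]

    def residue_base(self, residue_index: int) -> str:
        for a in self.atoms:
            if a.residue_index == residue_index:
                base = _RES_NAME_TO_BASE.get(a.residue_name)
                if base is None:
                    raise StructureError(
                        f"residue {residue_index} has non-nucleotide name {a.residue_name!r}"
                    )
                return base
        raise KeyError(f"no residue with index {residue_index}")

    def sequence(self, residue_indices) -> str:
        return "".join(self.residue_base(i) for i in residue_indices)


@dataclass
class SystemDefinition:
    """Declarative strand layout: duplex (+ optional third strand) sequences.

    Numbering convention: leading strand ``1..n``, complementary strand
    ``n+1..2n`` with residue ``j`` pairing ``2n+1-j``, third strand following.
    The shipped 30-mer/10-mer triplex system uses 1-30 / 31-60 (pair rule
    i + j = 61) / 61-70.
    """

    duplex_seq: str
    tfo_seq: str = ""
    tfo_target_start: int = 0  # leading-strand index of the first targeted bp
    regions: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self):
        self.duplex_seq = self.duplex_seq.upper()
        self.tfo_seq = self.tfo_seq.upper()
        n = len(self.duplex_seq)
        if self.tfo_seq:
            if self.tfo_target_start < 1:
                raise ValueError("tfo_target_start must be set when a TFO is declared")
            lo = self.tfo_target_start
            hi = lo + len(self.tfo_seq) - 1
            if hi > n:
                raise ValueError("TFO target region exceeds the duplex")
            target = self.duplex_seq[lo - 1 : hi]
            if not all(is_purine(b) for b in target):
                raise ValueError(
                    f"TFO target region {lo}-{hi} ({target}) is not all-purine"
                )
            # antiparallel register: TFO residue m (0-based) pairs bp hi - m
            if self.tfo_seq != target[::-1]:
                raise ValueError(
                    "TFO sequence does not match the purine target read antiparallel"
                )

    @property
    def n_bp(self) -> int:
        return len(self.duplex_seq)

    def wc_partner(self, i: int) -> int:
        return 2 * self.n_bp + 1 - i

    def complementary_seq(self) -> str:
        """Complementary strand sequence in its own 5'->3' order (res n+1..2n)."""
        return "".join(complement(b) for b in self.duplex_seq[::-1])

    def tfo_residue_range(self) -> tuple[int, int]:
        start = 2 * self.n_bp + 1
        return start, start + len(self.tfo_seq) - 1

    def hoogsteen_pairs(self) -> list[tuple[int, int]]:
        if not self.tfo_seq:
            return []
        t0, _ = self.tfo_residue_range()
        hi = self.tfo_target_start + len(self.tfo_seq) - 1
        return [(t0 + m, hi - m) for m in range(len(self.tfo_seq))]


@dataclass
class PairingAnnotation:
    """Resolved pairing and region map for one structure."""

    wc_pairs: list[tuple[int, int]]
    hoogsteen_pairs: list[tuple[int, int]]
    regions: dict[str, tuple[int, int]]

    def __post_init__(self):
        seen: set[int] = set()
        for i, j in self.wc_pairs:
            if i in seen or j in seen:
                raise AnnotationError(f"residue in more than one WC pair: {(i, j)}")
            seen.update((i, j))
        spans = sorted(self.regions.values())
        for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
            if b0 <= a1:
                raise AnnotationError("regions overlap")

    def region_of(self, bp_index: int) -> str | None:
        for name, (lo, hi) in self.regions.items():
            if lo <= bp_index <= hi:
                return name
        return None


def triplex_30mer_system() -> SystemDefinition:
    """The 30-mer duplex / 10-mer TFO purine-motif study system.

    Leading strand 5'-AACTGCTAAA GAGGGAGGGA CTTGATGTAT-3' (bp 1-30),
    all-purine TFO target at bp 11-20, TFO 5'-AGGGAGGGAG-3' bound
    antiparallel (residues 61-70).
    """
    return SystemDefinition(
        duplex_seq="AACTGCTAAAGAGGGAGGGACTTGATGTAT",
        tfo_seq="AGGGAGGGAG",
        tfo_target_start=11,
        regions={
            "first duplex": (1, 10),
            "homo-purine": (11, 20),
            "second duplex": (21, 30),
        },
    )


# --------------------------------------------------------------------------
# PDB I/O (via biotite, with line-aware error reporting)
# --------------------------------------------------------------------------

_COORD_MAX = 9999.999  # PDB fixed-width %8.3f field limit


def _scan_for_bad_line(path) -> str | None:
    pat = re.compile(r"^(ATOM|HETATM)")
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if pat.match(line):
                if len(line.rstrip("\n")) < 54:
                    return f"line {lineno}: truncated ATOM record"
                for lo, hi, what in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
                    try:
                        float(line[lo:hi])
                    except ValueError:
                        return f"line {lineno}: unparseable {what} coordinate {line[lo:hi]!r}"
    return None


def read_structure(path) -> AtomicStructure:
    """Read a (possibly multi-model) PDB file into an AtomicStructure.

    Models become frames; atom lists must agree across models.
    """
    import biotite.structure as bst
    import biotite.structure.io.pdb as pdb

    try:
        pdb_file = pdb.PDBFile.read(str(path))
        stack = pdb_file.get_structure(model=None)
    except Exception as exc:  # biotite raises assorted exception types
        detail = _scan_for_bad_line(path)
        if detail is not None:
            raise ParseError(f"{path}: {detail}") from exc
        if isinstance(exc, bst.BadStructureError) or "same number of atoms" in str(exc):
            raise StructureError(f"{path}: inconsistent models: {exc}") from exc
        raise ParseError(f"{path}: {exc}") from exc

    first = stack[0]
    atoms = [
        Atom(
            name=str(first.atom_name[i]),
            element=str(first.element[i]).capitalize(),
            residue_index=int(first.res_id[i]),
            residue_name=str(first.res_name[i]),
            chain_id=str(first.chain_id[i]),
        )
        for i in range(first.array_length())
    ]
    return AtomicStructure(atoms, np.asarray(stack.coord, dtype=float))


def write_structure(structure: AtomicStructure, path) -> None:
    """Write a (multi-model) PDB file; exact round-trip at 1e-3 Angstrom."""
    import biotite.structure as bst
    import biotite.structure.io.pdb as pdb

    if np.abs(structure.coords).max() > _COORD_MAX:
        raise StructureError(
            f"coordinate magnitude exceeds the PDB fixed-width field ({_COORD_MAX} A)"
        )
    n = structure.n_atoms
    arr = bst.AtomArrayStack(structure.n_frames, n)
    arr.coord = structure.coords.copy()
    arr.atom_name = np.array([a.name for a in structure.atoms], dtype="U6")
    arr.element = np.array([a.element.upper() for a in structure.atoms], dtype="U2")
    arr.res_id = np.array([a.residue_index for a in structure.atoms], dtype=int)
    arr.res_name = np.array([a.residue_name for a in structure.atoms], dtype="U5")
    arr.chain_id = np.array([a.chain_id for a in structure.atoms], dtype="U4")
    arr.hetero = np.zeros(n, dtype=bool)
    pdb_file = pdb.PDBFile()
    pdb_file.set_structure(arr)
    pdb_file.write(str(path))


def annotate_system(
    structure: AtomicStructure, system: SystemDefinition
) -> PairingAnnotation:
    """Check the declared strands against the structure and emit the pairing.

    Raises :class:`AnnotationError` listing every residue whose base type
    disagrees with the declared sequences.
    """
    n = system.n_bp
    expected: dict[int, str] = {}
    for i, b in enumerate(system.duplex_seq, start=1):
        expected[i] = b
        expected[system.wc_partner(i)] = complement(b)
    present = set(structure.residue_indices())
    tfo_bound = False
    if system.tfo_seq:
        t0, t1 = system.tfo_residue_range()
        tfo_res = set(range(t0, t1 + 1))
        found = tfo_res & present
        if found and found != tfo_res:
            raise AnnotationError(
                f"third strand is incomplete: missing residues {sorted(tfo_res - found)}"
            )
        tfo_bound = bool(found)
        if tfo_bound:
            for m, b in enumerate(system.tfo_seq):
                expected[t0 + m] = b

    missing = sorted(set(expected) - present)
    if missing:
        raise AnnotationError(f"structure lacks declared residues {missing}")
    bad = []
    for idx, want in sorted(expected.items()):
        got = structure.residue_base(idx)
        if got != want:
            bad.append((idx, want, got))
    if bad:
        msg = ", ".join(f"res {i}: expected {w}, found {g}" for i, w, g in bad)
        raise AnnotationError(f"sequence mismatch: {msg}")

    wc_pairs = [(i, system.wc_partner(i)) for i in range(1, n + 1)]
    regions = dict(system.regions)
    if not regions:
        regions = {"helix": (1, n)}
    return PairingAnnotation(
        wc_pairs=wc_pairs,
        hoogsteen_pairs=system.hoogsteen_pairs() if tfo_bound else [],
        regions=regions,
    )
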