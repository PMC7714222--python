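"""File formats: CASP-style RR restraints, 3-state secondary
structure, and Cα-only PDB.

All on-disk residue numbering is 1-based; the in-memory trace is
0-based.  PDB reading is backed by gemmi; the Cα-only writer is
column-exact by construction.
"""
from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from typing import IO, Iterable, Optional

import gemmi
import numpy as np

from .exceptions import ChainTooShortError, FormatError, ShapeError
from .geometry import CaTrace

logger = logging.getLogger(__name__)

#: Header keywords tolerated (and skipped) in RR files.
RR_HEADER_KEYWORDS = {
    "PFRMAT", "TARGET", "AUTHOR", "METHOD", "MODEL", "REMARK", "END",
}

#: Chains longer than this get a soft warning: the engine still runs,
#: but this is beyond the size the method is intended for.
MAX_COMFORTABLE_LENGTH = 500

_SS_8_TO_3 = {
    "H": "H", "G": "H", "I": "H",
    "E": "E", "B": "E",
    "C": "C", "T": "C", "S": "C", "-": "C", " ": "C", "L": "C", ".": "C",
}


@dataclass(frozen=True)
class Restraint:
    """One bounded pair restraint: residues i < j (1-based) should lie
    between `lower` and `upper` Å apart, with a confidence in [0, 1]."""

    i: int
    j: int
    lower: float
    upper: float
    confidence: float = 1.0

    def __post_init__(self):
        if not self.i < self.j:
            raise FormatError(f"need i < j, got ({self.i}, {self.j})")
        if self.i < 1:
            raise FormatError("residue indices are 1-based")
        if self.lower < 0 or self.lower > self.upper:
            raise FormatError(
                f"need 0 <= lower <= upper, got [{self.lower}, {self.upper}]"
            )
        if not 0.0 <= self.confidence <= 1.0:
            raise FormatError(
                f"confidence must be in [0, 1], got {self.confidence}"
            )


class RestraintSet:
    """The target distance matrix as a collection of pair restraints.

    At most one restraint per unordered pair; `length` is the chain
    length L and every index must satisfy j <= L.
    """

    def __init__(self, length: int, restraints: Iterable[Restraint],
                 sequence: Optional[str] = None):
        restraints = list(restraints)
        seen = {}
        for r in restraints:
            key = (r.i, r.j)
            if key in seen:
                raise FormatError(f"duplicate restraint for pair {key}")
            seen[key] = r
        if restraints and max(r.j for r in restraints) > length:
            raise FormatError("restraint index exceeds chain length")
        if sequence is not None and len(sequence) != length:
            raise ShapeError("sequence length does not match chain length")
        self.length = int(length)
        self.restraints = sorted(seen.values(), key=lambda r: (r.i, r.j))
        self.sequence = sequence
        self._arrays = None

    def __len__(self) -> int:
        return len(self.restraints)

    def __eq__(self, other) -> bool:
        return (isinstance(other, RestraintSet)
                and self.length == other.length
                and self.sequence == other.sequence
                and self.restraints == other.restraints)

    def to_arrays(self):
        """0-based (i, j, lower, upper, confidence) numpy views for the
        numerical kernels; cached."""
        if self._arrays is None:
            n = len(self.restraints)
            i = np.empty(n, dtype=np.int64)
            j = np.empty(n, dtype=np.int64)
            lo = np.empty(n)
            up = np.empty(n)
            w = np.empty(n)
            for k, r in enumerate(self.restraints):
                i[k], j[k] = r.i - 1, r.j - 1
                lo[k], up[k], w[k] = r.lower, r.upper, r.confidence
            self._arrays = (i, j, lo, up, w)
        return self._arrays


@dataclass(frozen=True)
class SecondaryStructure:
    """3-state secondary structure: H (helix), E (strand), C (coil)."""

    states: str

    def __post_init__(self):
        bad = set(self.states) - set("HEC")
        if bad:
            raise FormatError(
                f"secondary structure may only contain H/E/C, got {bad}"
            )

    def __len__(self) -> int:
        return len(self.states)


def _as_text_stream(stream) -> IO[str]:
    if isinstance(stream, str):
        return io.StringIO(stream)
    return stream


def parse_rr(stream) -> RestraintSet:
    """Parse a CASP-style RR restraint stream.

    Header keywords (PFRMAT, TARGET, ...) are skipped; bare alphabetic
    lines are concatenated into the sequence; records are
    ``i j lower upper [confidence]`` with 1-based i < j.  The chain
    length is taken from the sequence when present, else ``max(j)``.
    Duplicate pairs keep the last record (with a warning).
    """
    stream = _as_text_stream(stream)
    sequence_parts: list[str] = []
    records: dict[tuple[int, int], Restraint] = {}
    for lineno, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line:
            continue
        first = line.split()[0].upper()
        if first in RR_HEADER_KEYWORDS:
            continue
        if line.replace(" ", "").isalpha():
            sequence_parts.append(line.replace(" ", "").upper())
            continue
        fields = line.split()
        if len(fields) not in (4, 5):
            raise FormatError(
                f"line {lineno}: expected 4 or 5 fields, got {len(fields)}"
            )
        try:
            i, j = int(fields[0]), int(fields[1])
            lower, upper = float(fields[2]), float(fields[3])
            conf = float(fields[4]) if len(fields) == 5 else 1.0
        except ValueError as exc:
            raise FormatError(f"line {lineno}: non-numeric field ({exc})")
        if i >= j:
            raise FormatError(f"line {lineno}: need i < j, got {i} >= {j}")
        if lower > upper:
            raise FormatError(
                f"line {lineno}: lower {lower} exceeds upper {upper}"
            )
        try:
            rec = Restraint(i, j, lower, upper, conf)
        except FormatError as exc:
            raise FormatError(f"line {lineno}: {exc}")
        if (i, j) in records:
            logger.warning("duplicate restraint for pair (%d, %d) at line "
                           "%d; keeping the last record", i, j, lineno)
        records[(i, j)] = rec
    if not records:
        raise FormatError("no restraints found")
    sequence = "".join(sequence_parts) or None
    length = len(sequence) if sequence else max(j for _, j in records)
    return RestraintSet(length, records.values(), sequence)


def write_rr(rs: RestraintSet, stream: IO[str]) -> None:
    """Write a RestraintSet in the RR dialect parse_rr reads back."""
    if not rs.restraints:
        raise FormatError("refusing to write an empty restraint set")
    if rs.sequence:
        for k in range(0, len(rs.sequence), 60):
            stream.write(rs.sequence[k:k + 60] + "\n")
    for r in rs.restraints:
        stream.write(f"{r.i} {r.j} {r.lower:.3f} {r.upper:.3f} "
                     f"{r.confidence:.3f}\n")


def parse_ss(stream) -> SecondaryStructure:
    """Parse a FASTA-like or bare secondary-structure string.

    8-state DSSP codes are collapsed to 3 states: G, I → H; B → E;
    T, S, L, '-', '.' → C.
    """
    stream = _as_text_stream(stream)
    chars: list[str] = []
    pos = 0
    for raw in stream:
        line = raw.rstrip("\n")
        if line.startswith(">"):
            continue
        for ch in line.strip():
            pos += 1
            mapped = _SS_8_TO_3.get(ch.upper())
            if mapped is None:
                raise FormatError(
                    f"unknown secondary-structure code {ch!r} at "
                    f"position {pos}"
                )
            chars.append(mapped)
    if not chars:
        raise FormatError("empty secondary-structure input")
    return SecondaryStructure("".join(chars))


def read_pdb_ca(stream, chain: Optional[str] = None):
    """Extract the Cα trace of one chain from PDB text.

    First MODEL only; first alternate location only (blank or 'A');
    residues are renumbered 1..L in order of appearance.  Returns
    ``(CaTrace, sequence)`` with 'X' for nonstandard residues.
    """
    if not isinstance(stream, str):
        stream = stream.read()
    structure = gemmi.read_pdb_string(stream)
    if len(structure) == 0:
        raise FormatError("no models in PDB input")
    model = structure[0]
    target = None
    for ch in model:
        if chain is None or ch.name == chain.strip():
            target = ch
            break
    if target is None:
        raise FormatError(f"chain {chain!r} not found")
    coords = []
    seq = []
    for res in target:
        for atom in res:
            if atom.name == "CA" and atom.altloc in ("\x00", "", "A"):
                coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                info = gemmi.find_tabulated_residue(res.name)
                one = info.one_letter_code.upper() if info else "x"
                seq.append(one if one.isalpha() and one != " " else "X")
                break
    if not coords:
        raise FormatError("no CA atoms found")
    if len(coords) < 2:
        raise ChainTooShortError("chain has fewer than 2 CA residues")
    return CaTrace(np.asarray(coords)), "".join(seq)


_AA3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
    "X": "UNK",
}


def write_pdb_ca(trace: CaTrace, sequence: Optional[str],
                 stream: IO[str]) -> None:
    """Write a Cα-only PDB (chain A, residues 1..L, 3-decimal coords).

    A missing sequence is written as poly-alanine.
    """
    L = len(trace)
    if sequence is None:
        sequence = "A" * L
    if len(sequence) != L:
        raise ShapeError(
            f"sequence length {len(sequence)} does not match chain "
            f"length {L}"
        )
    if L >= MAX_COMFORTABLE_LENGTH:
        logger.warning(
            "chain length %d: structures of length < %d are the "
            "intended working range", L, MAX_COMFORTABLE_LENGTH,
        )
    for idx, (aa, xyz) in enumerate(zip(sequence.upper(), trace.coords),
                                    start=1):
        res = _AA3.get(aa, "UNK")
        stream.write(
            f"ATOM  {idx:5d}  CA  {res:<3s} A{idx:4d}    "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00"
            f"           C\n"
        )
    stream.write(f"TER   {L + 1:5d}      {_AA3.get(sequence[-1].upper(), 'UNK'):<3s} A{L:4d}\n")
    stream.write("END\n")
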