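"""Session checkpoints: a single self-describing text file holding the
current trace, restraints, secondary structure and run history.

The format is line-oriented with ``[section]`` headers; numbers are
written with fixed precision so that a load → save round trip is
byte-identical.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np

from .exceptions import FormatError, ShapeError
from .formats import Restraint, RestraintSet, SecondaryStructure
from .geometry import CaTrace

_MAGIC = "dgfold-session 1"


@dataclass
class SessionState:
    """A resumable snapshot of one folding session."""

    trace: CaTrace
    restraints: RestraintSet
    ss: Optional[SecondaryStructure] = None
    history: List[str] = field(default_factory=list)
    seeds: List[int] = field(default_factory=list)

    def __post_init__(self):
        if self.restraints.length != len(self.trace):
            raise ShapeError("restraints and trace lengths differ")
        if self.ss is not None and len(self.ss) != len(self.trace):
            raise ShapeError("secondary structure and trace lengths differ")

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(_MAGIC + "\n")
            fh.write("[coords]\n")
            for xyz in self.trace.coords:
                fh.write(f"{xyz[0]:.6f} {xyz[1]:.6f} {xyz[2]:.6f}\n")
            fh.write("[restraints]\n")
            fh.write(f"length {self.restraints.length}\n")
            if self.restraints.sequence:
                fh.write(f"sequence {self.restraints.sequence}\n")
            for r in self.restraints.restraints:
                fh.write(f"{r.i} {r.j} {r.lower:.6f} {r.upper:.6f} "
                         f"{r.confidence:.6f}\n")
            if self.ss is not None:
                fh.write("[ss]\n")
                fh.write(self.ss.states + "\n")
            if self.history:
                fh.write("[history]\n")
                for entry in self.history:
                    fh.write(entry + "\n")
            if self.seeds:
                fh.write("[seeds]\n")
                fh.write(" ".join(str(s) for s in self.seeds) + "\n")

    @classmethod
    def load(cls, path) -> "SessionState":
        with open(path) as fh:
            lines = fh.read().splitlines()
        if not lines or lines[0] != _MAGIC:
            raise FormatError("not a dgfold session file")
        sections: dict[str, list[str]] = {}
        current = None
        for line in lines[1:]:
            if line.startswith("[") and line.endswith("]"):
                current = line[1:-1]
                sections[current] = []
            elif current is not None:
                sections[current].append(line)
            else:
                raise FormatError(f"content before first section: {line!r}")
        if "coords" not in sections or "restraints" not in sections:
            raise FormatError("session file missing coords or restraints")
        coords = np.array([[float(v) for v in ln.split()]
                           for ln in sections["coords"] if ln.strip()])
        length = None
        sequence = None
        restraints = []
        for ln in sections["restraints"]:
            parts = ln.split()
            if not parts:
                continue
            if parts[0] == "length":
                length = int(parts[1])
            elif parts[0] == "sequence":
                sequence = parts[1]
            else:
                i, j = int(parts[0]), int(parts[1])
                restraints.append(Restraint(i, j, float(parts[2]),
                                            float(parts[3]), float(parts[4])))
        if length is None:
            raise FormatError("session restraints section lacks a length")
        ss = None
        if "ss" in sections:
            ss = SecondaryStructure("".join(s.strip()
                                            for s in sections["ss"]))
        history = [ln for ln in sections.get("history", []) if ln]
        seeds = []
        for ln in sections.get("seeds", []):
            seeds.extend(int(v) for v in ln.split())
        return cls(CaTrace(coords), RestraintSet(length, restraints, sequence),
                   ss, history, seeds)
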