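"""Secondary-structure-assisted chirality detection and correction.

A distance matrix cannot distinguish a fold from its mirror image, so
a distance-based optimizer lands in either hand with roughly equal
probability.  Regular secondary structure breaks the tie: the Cα
pseudo-dihedral of a right-handed α-helix sits near +50° and that of a
(right-twisted) β-strand near −170°, and both flip sign in a mirror
image.  The heuristic cost below sums, over every tetrapeptide lying
entirely within one helix or one strand segment, the wrapped angular
distance between its pseudo-dihedral and the reference value for that
secondary-structure class; whichever of the model and its mirror has
the lower cost is the correctly handed one.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ShapeError
from .formats import SecondaryStructure
from .geometry import CaTrace, dihedral_angles, mirror_trace

#: Reference Cα pseudo-dihedrals, degrees.
TAU_REF = {"H": 50.0, "E": -170.0}


@dataclass(frozen=True)
class ChiralityReport:
    """Outcome of a chirality check."""

    cost_original: float
    cost_mirror: float
    flipped: bool
    n_tetrapeptides: int


def chirality_cost(trace: CaTrace, ss: SecondaryStructure):
    """Handedness cost of a trace given its secondary structure.

    Returns ``(cost, n_tetrapeptides)``; the cost is the sum of wrapped
    |τ − τ_ref| (degrees) over all 4-residue windows contained in a
    single H or E segment.  No eligible windows → cost 0.
    """
    if len(ss) != len(trace):
        raise ShapeError(
            f"secondary structure length {len(ss)} does not match "
            f"trace length {len(trace)}"
        )
    L = len(trace)
    if L < 4:
        return 0.0, 0
    tau = np.rad2deg(dihedral_angles(trace.coords))
    cost = 0.0
    count = 0
    for k in range(L - 3):
        window = ss.states[k:k + 4]
        state = window[0]
        if state in TAU_REF and window == state * 4:
            diff = abs((tau[k] - TAU_REF[state] + 180.0) % 360.0 - 180.0)
            cost += diff
            count += 1
    return float(cost), count


def fix_chirality(trace: CaTrace, ss: SecondaryStructure):
    """Return the better-handed of a trace and its mirror image.

    Ties (including the no-eligible-window case) keep the original, so
    the operation is idempotent.  Because the restraint energy is
    reflection-invariant, flipping never degrades restraint
    satisfaction.
    """
    cost_orig, n = chirality_cost(trace, ss)
    mirrored = mirror_trace(trace)
    cost_mirr, _ = chirality_cost(mirrored, ss)
    flipped = cost_mirr < cost_orig
    report = ChiralityReport(
        cost_original=cost_orig,
        cost_mirror=cost_mirr,
        flipped=flipped,
        n_tetrapeptides=n,
    )
    return (mirrored if flipped else trace), report
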