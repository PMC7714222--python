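"""Restraint-violation objective and its analytic Cartesian gradient.

The objective is a flat-bottom squared hinge: a pair restraint with
bounds [lower, upper] contributes nothing while its distance d lies
inside the bounds and w·(violation)² outside, where the violation is
the distance to the nearest bound and w is the restraint confidence
(or 1 when confidence weighting is off).  A harmonic connectivity term
keeps consecutive residues near the 3.8 Å virtual bond length during
Cartesian optimization; it is identically zero for chains built from
fixed-bond internal coordinates.

The energy is invariant under rigid motions *and* reflections of the
trace — distance information cannot see handedness, which is why
chirality is handled by a separate module.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .exceptions import ShapeError
from .formats import RestraintSet
from .geometry import CA_BOND_LENGTH, CaTrace

logger = logging.getLogger(__name__)

#: Default harmonic force constant for the connectivity term.
DEFAULT_K_BOND = 10.0


@dataclass(frozen=True)
class EnergyBreakdown:
    """Decomposition of the objective for one conformation."""

    total: float
    restraint_term: float
    connectivity_term: float
    n_satisfied: int
    n_violated: int


def _check(trace: CaTrace, rs: RestraintSet) -> None:
    if rs.length != len(trace):
        raise ShapeError(
            f"restraint set is for length {rs.length}, trace has "
            f"{len(trace)} residues"
        )


def restraint_energy(trace: CaTrace, rs: RestraintSet,
                     use_confidence: bool = False,
                     k_bond: float = DEFAULT_K_BOND,
                     bond_length: float = CA_BOND_LENGTH) -> EnergyBreakdown:
    """Evaluate the flat-bottom restraint energy plus connectivity."""
    _check(trace, rs)
    i, j, lo, up, conf = rs.to_arrays()
    w = conf if use_confidence else np.ones_like(conf)
    er, nv = _kernels.restraint_energy(trace.coords, i, j, lo, up, w)
    ec = _kernels.connectivity_energy(trace.coords, k_bond, bond_length)
    return EnergyBreakdown(
        total=er + ec,
        restraint_term=er,
        connectivity_term=ec,
        n_satisfied=len(rs) - nv,
        n_violated=nv,
    )


def restraint_gradient(trace: CaTrace, rs: RestraintSet,
                       use_confidence: bool = False,
                       k_bond: float = DEFAULT_K_BOND,
                       bond_length: float = CA_BOND_LENGTH) -> np.ndarray:
    """Exact (L, 3) gradient of the total energy w.r.t. coordinates.

    For a coincident restrained pair (d = 0) the hinge is not
    differentiable; its contribution is the zero subgradient, logged
    as a warning.
    """
    _check(trace, rs)
    i, j, lo, up, conf = rs.to_arrays()
    w = conf if use_confidence else np.ones_like(conf)
    _, _, _, grad, _, nz = _kernels.energy_and_gradient(
        trace.coords, i, j, lo, up, w, k_bond, bond_length
    )
    if nz:
        logger.warning(
            "%d restrained pair(s) coincident (d = 0); using the zero "
            "subgradient for them", nz,
        )
    return grad
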