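"""Cα-trace geometry.

A protein chain is reduced to one point per residue (the alpha
carbon).  Two equivalent parameterizations are supported:

* Cartesian: an (L, 3) array of coordinates in Å (:class:`CaTrace`);
* internal: virtual bond lengths, pseudo planar angles θ between three
  consecutive Cα, and pseudo dihedral angles τ over four consecutive
  Cα (:class:`InternalCoords`).

Internal coordinates determine the Cartesian trace up to a rigid
motion; the conversion here fixes a canonical frame (residue 0 at the
origin, residue 1 on +x, residue 2 in the xy-plane with positive y) so
chain construction is deterministic.  Angles are degrees at the API
boundary and radians internally.  The dihedral sign convention is the
IUPAC right-handed one, under which a right-handed α-helix has
τ ≈ +50°.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import squareform, pdist
from scipy.spatial.transform import Rotation

from . import _kernels
from .exceptions import (
    ChainTooShortError,
    DegenerateGeometryError,
    InsufficientPointsError,
    InvalidAngleError,
    ResidueIndexError,
    ShapeError,
)

#: Standard trans-peptide Cα–Cα virtual bond length, Å.
CA_BOND_LENGTH = 3.8

#: Angular tolerance (radians) below which three consecutive residues
#: are treated as collinear and the dihedral is undefined.
COLLINEAR_TOL_RAD = 1e-6


@dataclass(frozen=True)
class CaTrace:
    """Ordered Cα coordinates of one chain, Å, 0-based residue indices."""

    coords: np.ndarray

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ShapeError(f"coords must be (L, 3), got {coords.shape}")
        if coords.shape[0] < 2:
            raise ChainTooShortError("a trace needs at least 2 residues")
        if not np.all(np.isfinite(coords)):
            raise ShapeError("coordinates must be finite")
        object.__setattr__(self, "coords", coords)

    def __len__(self) -> int:
        return self.coords.shape[0]


@dataclass(frozen=True)
class InternalCoords:
    """Internal (angular) coordinates of a chain of L residues.

    ``bond_lengths`` has L-1 entries (Å), ``planar_angles`` L-2 entries
    in degrees strictly inside (0, 180) and ``dihedral_angles`` L-3
    entries in degrees in (-180, 180].
    """

    bond_lengths: np.ndarray
    planar_angles: np.ndarray
    dihedral_angles: np.ndarray

    def __post_init__(self):
        b = np.atleast_1d(np.asarray(self.bond_lengths, dtype=float))
        t = np.atleast_1d(np.asarray(self.planar_angles, dtype=float))
        p = np.atleast_1d(np.asarray(self.dihedral_angles, dtype=float))
        L = b.shape[0] + 1
        if L < 2:
            raise ChainTooShortError("need at least one bond")
        if t.shape[0] != max(L - 2, 0) or p.shape[0] != max(L - 3, 0):
            raise ShapeError(
                f"expected {L - 2} planar and {L - 3} dihedral angles, "
                f"got {t.shape[0]} and {p.shape[0]}"
            )
        if np.any(b <= 0):
            raise ShapeError("bond lengths must be positive")
        if t.size and (np.any(t <= 0.0) or np.any(t >= 180.0)):
            raise InvalidAngleError(
                "planar angles must lie strictly inside (0, 180) degrees"
            )
        for name, arr in (("bond_lengths", b), ("planar_angles", t),
                          ("dihedral_angles", p)):
            if not np.all(np.isfinite(arr)):
                raise ShapeError(f"{name} must be finite")
        object.__setattr__(self, "bond_lengths", b)
        object.__setattr__(self, "planar_angles", t)
        object.__setattr__(self, "dihedral_angles", p)

    def __len__(self) -> int:
        return self.bond_lengths.shape[0] + 1


@dataclass(frozen=True)
class Superposition:
    """A proper rigid motion x -> rotation @ x + translation, with the
    RMSD it achieves over the fitted subset."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        if R.shape != (3, 3) or abs(np.linalg.det(R) - 1.0) > 1e-9:
            raise ShapeError("rotation must be 3x3 with determinant +1")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def internal_to_cartesian(ic: InternalCoords) -> CaTrace:
    """Build the canonical-frame Cartesian trace from internal coords."""
    X = _kernels.build_chain(
        ic.bond_lengths,
        np.deg2rad(ic.planar_angles),
        np.deg2rad(ic.dihedral_angles),
    )
    return CaTrace(X)


def _wrap_deg(a):
    """Wrap angles into (-180, 180]."""
    a = np.asarray(a, dtype=float)
    w = -(-(a - 180.0) % 360.0) + 180.0
    return w if w.ndim else float(w)


def planar_angles(coords: np.ndarray) -> np.ndarray:
    """Pseudo planar angles (radians) at residues 1..L-2."""
    u = coords[:-2] - coords[1:-1]
    v = coords[2:] - coords[1:-1]
    c = np.einsum("ij,ij->i", u, v)
    c /= np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1)
    return np.arccos(np.clip(c, -1.0, 1.0))


def dihedral_angles(coords: np.ndarray) -> np.ndarray:
    """Pseudo dihedral angles (radians), IUPAC sign, for residue
    quadruples k..k+3."""
    b0 = coords[1:-2] - coords[:-3]
    b1 = coords[2:-1] - coords[1:-2]
    b2 = coords[3:] - coords[2:-1]
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    b1u = b1 / np.linalg.norm(b1, axis=1)[:, None]
    m1 = np.cross(n1, b1u)
    x = np.einsum("ij,ij->i", n1, n2)
    y = np.einsum("ij,ij->i", m1, n2)
    return np.arctan2(y, x)


def cartesian_to_internal(trace: CaTrace) -> InternalCoords:
    """Measure internal coordinates; inverse of
    :func:`internal_to_cartesian` up to a rigid motion."""
    X = trace.coords
    bonds = np.linalg.norm(np.diff(X, axis=0), axis=1)
    theta = planar_angles(X)
    bad = np.where(
        (theta < COLLINEAR_TOL_RAD) | (theta > np.pi - COLLINEAR_TOL_RAD)
    )[0]
    if bad.size:
        raise DegenerateGeometryError(
            f"residues {bad[0]}..{bad[0] + 2} are collinear; "
            "dihedral angles are undefined"
        )
    tau = dihedral_angles(X) if len(trace) >= 4 else np.empty(0)
    return InternalCoords(
        bonds,
        np.rad2deg(theta),
        _wrap_deg(np.rad2deg(np.atleast_1d(tau))),
    )


def pairwise_distances(trace: CaTrace) -> np.ndarray:
    """Symmetric L×L Euclidean distance matrix, zero diagonal, Å."""
    return squareform(pdist(trace.coords))


def mirror_trace(trace: CaTrace) -> CaTrace:
    """Reflection through the plane x = 0.

    An isometry (all pairwise distances preserved) that negates every
    pseudo dihedral, i.e. flips the handedness of the fold.
    """
    X = trace.coords.copy()
    X[:, 0] = -X[:, 0]
    return CaTrace(X)


def _rotate_downstream(X: np.ndarray, pivot: int, axis: np.ndarray,
                       angle_rad: float) -> np.ndarray:
    """Rigidly rotate residues pivot+1.. about `axis` through X[pivot]."""
    R = Rotation.from_rotvec(axis / np.linalg.norm(axis) * angle_rad)
    out = X.copy()
    out[pivot + 1:] = R.apply(X[pivot + 1:] - X[pivot]) + X[pivot]
    return out


def set_residue_angles(trace: CaTrace, i: int,
                       theta: float | None = None,
                       tau: float | None = None) -> CaTrace:
    """Set the pseudo planar and/or dihedral angle addressed by residue i.

    θ is the angle at residue i (defined for 1 ≤ i ≤ L-2); τ is the
    dihedral of residues i-2..i+1 (defined for 2 ≤ i ≤ L-2).  Residues
    0..i are left exactly where they are; residues after i rotate
    rigidly, which is the headless analog of dragging an angle slider
    for one residue.
    """
    L = len(trace)
    X = trace.coords
    if theta is not None:
        if not (1 <= i <= L - 2):
            raise ResidueIndexError(
                f"no planar angle at residue {i} (valid: 1..{L - 2})"
            )
        if not (0.0 < theta < 180.0):
            raise InvalidAngleError(
                f"theta must be in (0, 180) degrees, got {theta}"
            )
        u = X[i - 1] - X[i]
        v = X[i + 1] - X[i]
        axis = np.cross(u, v)
        if np.linalg.norm(axis) < 1e-12:
            raise DegenerateGeometryError(
                f"residues {i - 1}..{i + 1} are collinear"
            )
        cur = np.arccos(
            np.clip(u @ v / (np.linalg.norm(u) * np.linalg.norm(v)), -1, 1)
        )
        # rotating v about unit(u×v) by +φ changes the angle to cur+φ
        X = _rotate_downstream(X, i, axis, np.deg2rad(theta) - cur)
    if tau is not None:
        if not (2 <= i <= L - 2):
            raise ResidueIndexError(
                f"no dihedral angle at residue {i} (valid: 2..{L - 2})"
            )
        quad = X[i - 2:i + 2]
        cur = float(dihedral_angles(quad)[0])
        delta = np.deg2rad(_wrap_deg(tau - np.rad2deg(cur)))
        # positive τ change = right-hand rotation of the downstream
        # residues about the central bond axis (i-1 -> i)
        axis = X[i] - X[i - 1]
        X = _rotate_downstream(X, i, -axis, delta)
    return CaTrace(X)


def kabsch_superpose(model: CaTrace, reference: CaTrace,
                     subset: Sequence[int] | None = None) -> Superposition:
    """Least-squares proper-rotation superposition of model onto reference.

    Reflections are never used, so a mirror-image fold keeps a nonzero
    RMSD: that is the point of treating chirality separately.
    """
    A = model.coords
    B = reference.coords
    if subset is not None:
        idx = np.asarray(subset, dtype=int)
        if idx.shape[0] < 3:
            raise InsufficientPointsError(
                "superposition needs a subset of at least 3 points"
            )
        A = A[idx]
        B = B[idx]
    else:
        if A.shape != B.shape:
            raise ShapeError("model and reference lengths differ")
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    H = (A - ca).T @ (B - cb)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    resid = (A - ca) @ R.T - (B - cb)
    return Superposition(
        rotation=R,
        translation=cb - R @ ca,
        rmsd=float(np.sqrt(np.mean(np.sum(resid ** 2, axis=1)))),
    )
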