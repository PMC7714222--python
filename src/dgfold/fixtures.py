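"""Synthetic Cα structures: ideal helices, random clash-free chains,
and a compact α/β target with known secondary structure.

These generators replace downloaded experimental structures
everywhere in the test suite and in the bundled robustness study;
they are deterministic for a given seed.
"""
from __future__ import annotations

import numpy as np

from .exceptions import ChainTooShortError, GenerationError
from .formats import SecondaryStructure
from .geometry import (CA_BOND_LENGTH, CaTrace, InternalCoords,
                       dihedral_angles, internal_to_cartesian)
from ._kernels import build_chain

#: Ideal Cα pseudo-angles, degrees.
HELIX_THETA, HELIX_TAU = 91.0, 50.0
STRAND_THETA, STRAND_TAU = 120.0, -170.0

#: Minimum allowed distance between non-bonded residues (|i−j| ≥ 2), Å.
CLASH_DISTANCE = 3.5


def make_helix(L: int):
    """Ideal right-handed Cα α-helix (θ = 91°, τ = +50°) with an
    all-helix secondary-structure string."""
    if L < 4:
        raise ChainTooShortError("a helix fixture needs L >= 4")
    ic = InternalCoords(
        np.full(L - 1, CA_BOND_LENGTH),
        np.full(L - 2, HELIX_THETA),
        np.full(L - 3, HELIX_TAU),
    )
    return internal_to_cartesian(ic), SecondaryStructure("H" * L)


def _min_nonbonded_distance(X: np.ndarray) -> float:
    d = np.linalg.norm(X[:, None, :] - X[None, :, :], axis=-1)
    L = X.shape[0]
    iu = np.triu_indices(L, k=2)
    return float(d[iu].min()) if iu[0].size else np.inf


def make_compact_chain(L: int, seed: int) -> CaTrace:
    """Random self-avoiding chain grown residue by residue.

    Pseudo-angles are drawn uniformly (θ in [80°, 150°], τ in
    (−180°, 180°]); a residue placement that brings any non-bonded
    pair closer than 3.5 Å is rejected and redrawn, restarting the
    whole chain when a placement cannot be found.  Deterministic per
    seed.
    """
    if L < 4:
        raise ChainTooShortError("a compact chain needs L >= 4")
    rng = np.random.default_rng(seed)
    bonds = np.full(L - 1, CA_BOND_LENGTH)
    for _restart in range(100):
        theta = [np.deg2rad(rng.uniform(80.0, 150.0))]
        tau: list[float] = []
        ok = True
        for k in range(3, L):
            placed = False
            for _attempt in range(150):
                th = np.deg2rad(rng.uniform(80.0, 150.0))
                ta = np.deg2rad(rng.uniform(-180.0, 180.0))
                X = build_chain(bonds[:k], np.array(theta + [th]),
                                np.array(tau + [ta]))
                dists = np.linalg.norm(X[:-3] - X[-1], axis=1)
                if dists.size == 0 or dists.min() >= CLASH_DISTANCE:
                    theta.append(th)
                    tau.append(ta)
                    placed = True
                    break
            if not placed:
                ok = False
                break
        if ok:
            X = build_chain(bonds, np.array(theta), np.array(tau))
            return CaTrace(X)
    raise GenerationError(
        f"could not grow a clash-free chain of length {L} with seed "
        f"{seed}; try another seed"
    )


#: Secondary-structure layout of the synthetic 68-residue target:
#: helix – hairpin of two strands – helix – strand, joined by coils.
_TARGET_SS = ("CC" + "H" * 14 + "CCCC" + "E" * 6 + "CCC" + "E" * 6
              + "CCCC" + "H" * 12 + "CCC" + "E" * 6 + "CCCCCCCC")


def make_alpha_beta_target(seed: int = 0):
    """Synthetic compact 68-residue α/β Cα structure with known
    secondary structure.

    This is a synthetic stand-in for a small experimentally determined
    α/β protein: helix and strand segments carry ideal pseudo-angles
    (θ = 91°/τ = +50° and θ = 120°/τ = −170°), and the coil angles are
    set by a deterministic greedy search that compacts the chain
    (radius of gyration ≤ ~11 Å) while keeping non-bonded residues at
    least 3.5 Å apart.  Deterministic per seed.

    Returns ``(CaTrace, SecondaryStructure)``.
    """
    ss = _TARGET_SS
    L = len(ss)
    rng = np.random.default_rng(seed)
    bonds = np.full(L - 1, CA_BOND_LENGTH)

    theta = np.empty(L - 2)
    theta_free = np.ones(L - 2, dtype=bool)
    for a in range(L - 2):
        states = ss[a:a + 3]
        if states == "HHH":
            theta[a], theta_free[a] = HELIX_THETA, False
        elif states == "EEE":
            theta[a], theta_free[a] = STRAND_THETA, False
    tau = np.empty(L - 3)
    tau_free = np.ones(L - 3, dtype=bool)
    for m in range(L - 3):
        states = ss[m:m + 4]
        if states == "HHHH":
            tau[m], tau_free[m] = HELIX_TAU, False
        elif states == "EEEE":
            tau[m], tau_free[m] = STRAND_TAU, False

    theta[theta_free] = rng.uniform(80.0, 150.0, theta_free.sum())
    tau[tau_free] = rng.uniform(-180.0, 180.0, tau_free.sum())

    rg_target = 11.0

    def penalty(th, ta):
        X = build_chain(bonds, np.deg2rad(th), np.deg2rad(ta))
        d = np.linalg.norm(X[:, None, :] - X[None, :, :], axis=-1)
        iu = np.triu_indices(L, k=2)
        clash = np.maximum(CLASH_DISTANCE - d[iu], 0.0)
        rg = np.sqrt(np.mean(np.sum((X - X.mean(0)) ** 2, axis=1)))
        return 100.0 * float(np.sum(clash ** 2)) + max(rg - rg_target, 0.0) ** 2

    free_idx = ([("theta", a) for a in np.where(theta_free)[0]]
                + [("tau", m) for m in np.where(tau_free)[0]])
    cur = penalty(theta, tau)
    for _ in range(6000):
        kind, idx = free_idx[int(rng.integers(len(free_idx)))]
        if kind == "theta":
            old = theta[idx]
            theta[idx] = rng.uniform(80.0, 150.0)
        else:
            old = tau[idx]
            tau[idx] = rng.uniform(-180.0, 180.0)
        new = penalty(theta, tau)
        if new <= cur:
            cur = new
        elif kind == "theta":
            theta[idx] = old
        else:
            tau[idx] = old
        if cur == 0.0:
            break
    X = build_chain(bonds, np.deg2rad(theta), np.deg2rad(tau))
    if _min_nonbonded_distance(X) < CLASH_DISTANCE - 0.1:
        raise GenerationError(
            f"target generation left steric clashes (seed {seed}); "
            "try another seed"
        )
    return CaTrace(X), SecondaryStructure(ss)


def assign_secondary_structure(trace: CaTrace) -> SecondaryStructure:
    """Heuristic 3-state secondary structure from Cα geometry.

    Each residue inherits the class of the pseudo-dihedral window
    around it (helix-like near +50°, strand-like near −170°); runs
    shorter than 4 (helix) or 3 (strand) are relabelled coil.  This is
    a coarse Cα-only assignment meant for chirality checking, not a
    DSSP replacement.
    """
    L = len(trace)
    if L < 4:
        return SecondaryStructure("C" * L)
    tau = np.rad2deg(dihedral_angles(trace.coords))

    def classify(t):
        if abs((t - HELIX_TAU + 180.0) % 360.0 - 180.0) < 35.0:
            return "H"
        if abs((t - STRAND_TAU + 180.0) % 360.0 - 180.0) < 45.0:
            return "E"
        return "C"

    labels = ["C"] * L
    for i in range(L):
        m = min(max(i - 1, 0), L - 4)
        labels[i] = classify(tau[m])
    out = "".join(labels)
    for state, min_run in (("H", 4), ("E", 3)):
        cleaned = []
        i = 0
        while i < L:
            if out[i] != state:
                cleaned.append(out[i])
                i += 1
                continue
            j = i
            while j < L and out[j] == state:
                j += 1
            cleaned.append((state if j - i >= min_run else "C") * (j - i))
            i = j
        out = "".join(cleaned)
    return SecondaryStructure(out)
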