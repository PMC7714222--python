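"""Optimizers: Cartesian gradient descent, angular simulated
annealing, and the cascade runner that chains them.

Both optimizers minimize the flat-bottom restraint objective from
:mod:`dgfold.energy`, normalized per residue and regularized by a weak
pull toward each restraint's bound midpoint (see below).  Gradient
descent acts on Cartesian coordinates with a harmonic connectivity
term; simulated annealing acts on the pseudo-angle parameterization,
where chain connectivity is exact by construction, and ends with a
deterministic greedy quench.

Two normalization/regularization choices matter and are deliberate:

* **Per-residue scaling** — the optimizer objective is the total
  energy divided by the chain length L.  This keeps the per-atom
  gradient of order "mean violation", so the documented step sizes
  (0.005 coarse, 0.0001 fine) sit inside the stability region of
  steepest descent regardless of how many restraints the input has.
* **Bound centering** — the flat bottom leaves the solution free
  anywhere between the bounds; with 1 Å-wide bounds that slack
  accumulates along extended structures.  A centering term of weight
  ``centering`` (default 0.05) prefers the central solution of the
  feasible region without meaningfully competing with the hinge.

Cascades are expressed as a :class:`CascadeSpec`; the documented
presets ``"case-study"`` (one annealing run + three gradient-descent
runs) and ``"benchmark"`` (two gradient-descent runs, 65,000
iterations each, steps 0.005 then 0.0001) are available by name.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Optional, Union

import numpy as np

from . import _kernels
from .energy import DEFAULT_K_BOND
from .exceptions import (ChainTooShortError, ConfigError, DivergenceError,
                         ShapeError)
from .formats import RestraintSet, SecondaryStructure
from .geometry import (CA_BOND_LENGTH, CaTrace, InternalCoords,
                       cartesian_to_internal, internal_to_cartesian)

#: Energy above which gradient descent is declared divergent.
DIVERGENCE_LIMIT = 1e12

#: Default weight of the bound-centering regularizer.
CENTERING_WEIGHT = 0.05

#: Ideal pseudo-angles used for secondary-structure-guided proposals:
#: (reference, proposal width), degrees.
SS_ANGLE_REFS = {
    "H": {"theta": (91.0, 4.0), "tau": (50.0, 6.0)},
    "E": {"theta": (120.0, 8.0), "tau": (-170.0, 10.0)},
}

StopSignal = Union[Callable[[], bool], object, None]


def _stopped(stop: StopSignal) -> bool:
    if stop is None:
        return False
    if callable(stop):
        return bool(stop())
    return bool(stop.is_set())


@dataclass(frozen=True)
class GDConfig:
    """Gradient-descent stage parameters.

    The defaults are the documented coarse preset values: step size
    0.005 for 65,000 iterations.
    """

    step_size: float = 0.005
    iterations: int = 65000
    report_every: int = 1000
    centering: float = CENTERING_WEIGHT

    def __post_init__(self):
        if self.step_size <= 0:
            raise ConfigError("step_size must be positive")
        if self.iterations < 1 or self.report_every < 1:
            raise ConfigError("iterations and report_every must be >= 1")
        if self.centering < 0:
            raise ConfigError("centering must be >= 0")


@dataclass(frozen=True)
class SAConfig:
    """Simulated-annealing stage parameters.

    One angle is perturbed per move.  A dihedral proposal is a Gaussian
    step of width ``move_sigma_deg``, or with probability ``p_flip`` a
    sign flip τ → −τ (the move that escapes the locally mirrored traps
    distance information cannot see), or with probability ``p_fresh`` a
    fresh uniform draw.  When a secondary structure is supplied, moves
    on angles lying entirely within a helix or strand segment are,
    with probability ``p_guided``, drawn around the ideal angles for
    that segment type (the proposal is still Metropolis-filtered by the
    restraint energy, so wrong guidance is rejected, not imposed).
    Every ``relax_every`` moves a short burst of Cartesian gradient
    descent relaxes the state, kept only if it improves the energy.
    After the schedule a deterministic greedy quench (per-angle
    candidate sweeps, at most ``quench_sweeps``) polishes the result.
    Temperatures are per-residue energy units, cooled geometrically.
    """

    seed: int = 0
    iterations: int = 65000
    t_initial: float = 300.0
    t_final: float = 0.03
    move_sigma_deg: float = 8.0
    p_flip: float = 0.2
    p_fresh: float = 0.1
    p_guided: float = 0.5
    relax_every: int = 2000
    relax_iterations: int = 300
    quench_sweeps: int = 25
    cooling: str = "geometric"
    report_every: int = 100
    centering: float = CENTERING_WEIGHT

    def __post_init__(self):
        if not (self.t_initial >= self.t_final > 0):
            raise ConfigError("need t_initial >= t_final > 0")
        if self.move_sigma_deg <= 0:
            raise ConfigError("move_sigma_deg must be positive")
        if self.iterations < 1 or self.report_every < 1:
            raise ConfigError("iterations and report_every must be >= 1")
        if not (0.0 <= self.p_flip and 0.0 <= self.p_fresh
                and self.p_flip + self.p_fresh <= 1.0):
            raise ConfigError("need p_flip, p_fresh >= 0 with sum <= 1")
        if not 0.0 <= self.p_guided <= 1.0:
            raise ConfigError("p_guided must be in [0, 1]")
        if min(self.relax_every, self.relax_iterations,
               self.quench_sweeps) < 0:
            raise ConfigError("relax/quench parameters must be >= 0")
        if self.centering < 0:
            raise ConfigError("centering must be >= 0")
        if self.cooling != "geometric":
            raise ConfigError(f"unknown cooling schedule {self.cooling!r}")


@dataclass(frozen=True)
class CascadeSpec:
    """Ordered optimizer stages, each ("gd", GDConfig) or ("sa", SAConfig)."""

    stages: tuple

    def __post_init__(self):
        if not self.stages:
            raise ConfigError("a cascade needs at least one stage")
        for kind, cfg in self.stages:
            if kind == "gd" and isinstance(cfg, GDConfig):
                continue
            if kind == "sa" and isinstance(cfg, SAConfig):
                continue
            raise ConfigError(f"invalid stage ({kind!r}, {type(cfg).__name__})")


@dataclass(frozen=True)
class StageRecord:
    """Energy trace of one optimizer stage."""

    label: str
    iterations: np.ndarray
    energies: np.ndarray


@dataclass(frozen=True)
class OptimizationTrajectory:
    """Recorded energies plus the final conformation of a run."""

    stages: tuple
    final_trace: CaTrace

    def __post_init__(self):
        for st in self.stages:
            if not np.all(np.isfinite(st.energies)):
                raise ShapeError("trajectory energies must be finite")

    @property
    def energies(self) -> np.ndarray:
        return np.concatenate([st.energies for st in self.stages])

    @property
    def final_energy(self) -> float:
        return float(self.stages[-1].energies[-1])

    @property
    def initial_energy(self) -> float:
        return float(self.stages[0].energies[0])


def extended_state(L: int) -> CaTrace:
    """Deterministic unfolded starting conformation.

    A planar zig-zag: 3.8 Å bonds, θ = 135° everywhere, τ = 180°
    (+180° and −180° are the same angle); θ < 180° avoids the
    collinear degeneracy while staying maximally stretched for
    practical purposes.
    """
    if L < 2:
        raise ChainTooShortError("extended state needs L >= 2")
    ic = InternalCoords(
        np.full(L - 1, CA_BOND_LENGTH),
        np.full(max(L - 2, 0), 135.0),
        np.full(max(L - 3, 0), 180.0),
    )
    return internal_to_cartesian(ic)


def _objective_arrays(rs: RestraintSet, L: int, use_confidence: bool):
    """Weights and bond constant of the per-residue objective."""
    i, j, lo, up, conf = rs.to_arrays()
    w = (conf if use_confidence else np.ones_like(conf)) / L
    kb = DEFAULT_K_BOND / L
    return i, j, lo, up, w, kb


def _ss_reference_angles(ss: Optional[SecondaryStructure], L: int):
    """Per-angle guidance targets (NaN where no guidance applies)."""
    th_ref = np.full(max(L - 2, 0), np.nan)
    th_sig = np.zeros(max(L - 2, 0))
    ta_ref = np.full(max(L - 3, 0), np.nan)
    ta_sig = np.zeros(max(L - 3, 0))
    if ss is not None:
        s = ss.states
        for a in range(L - 2):
            win = s[a:a + 3]
            if win in ("HHH", "EEE"):
                th_ref[a], th_sig[a] = SS_ANGLE_REFS[win[0]]["theta"]
        for m in range(L - 3):
            win = s[m:m + 4]
            if win in ("HHHH", "EEEE"):
                ta_ref[m], ta_sig[m] = SS_ANGLE_REFS[win[0]]["tau"]
    return th_ref, th_sig, ta_ref, ta_sig


def gradient_descent(trace: CaTrace, rs: RestraintSet, cfg: GDConfig,
                     stop: StopSignal = None,
                     use_confidence: bool = False,
                     label: str = "gd") -> OptimizationTrajectory:
    """Fixed-step steepest descent on Cartesian coordinates.

    Deterministic (no randomness).  Energies are recorded every
    ``cfg.report_every`` iterations plus once at the end; the stop
    signal is polled between report intervals and the best-so-far
    result returned when it fires.
    """
    if rs.length != len(trace):
        raise ShapeError("restraint set and trace lengths differ")
    i, j, lo, up, w, kb = _objective_arrays(rs, len(trace), use_confidence)
    X = trace.coords.copy()
    its, es = [], []
    done = 0
    while done < cfg.iterations:
        n = min(cfg.report_every, cfg.iterations - done)
        e0, fail = _kernels.gd_run_reg(X, n, cfg.step_size, i, j, lo, up, w,
                                       kb, CA_BOND_LENGTH, cfg.centering,
                                       DIVERGENCE_LIMIT)
        its.append(done)
        es.append(e0)
        if fail >= 0:
            raise DivergenceError(
                f"gradient descent diverged at iteration {done + fail} "
                f"(energy non-finite or above {DIVERGENCE_LIMIT:g}); "
                f"try a smaller step_size than {cfg.step_size}"
            )
        done += n
        if _stopped(stop):
            break
    ef, _ = _kernels.restraint_energy_reg(X, i, j, lo, up, w, cfg.centering)
    ef += _kernels.connectivity_energy(X, kb, CA_BOND_LENGTH)
    its.append(done)
    es.append(ef)
    rec = StageRecord(label, np.asarray(its), np.asarray(es))
    return OptimizationTrajectory((rec,), CaTrace(X))


def _quench_angles(bonds, th_rad, ta_rad, i, j, lo, up, w, centering,
                   th_ref, ta_ref, max_sweeps):
    """Deterministic per-angle greedy sweeps (in place).

    Candidates per angle: small offsets, the sign flip (dihedrals) and
    the secondary-structure ideal where defined.  Returns the final
    energy.
    """
    n_theta, n_tau = th_rad.shape[0], ta_rad.shape[0]
    X = _kernels.build_chain(bonds, th_rad, ta_rad)
    e, _ = _kernels.restraint_energy_reg(X, i, j, lo, up, w, centering)
    deltas = np.deg2rad([2.0, -2.0, 5.0, -5.0, 10.0, -10.0])
    lo_th, hi_th = np.deg2rad(1.0), np.deg2rad(179.0)
    for _ in range(max_sweeps):
        improved = False
        for k in range(n_theta + n_tau):
            if k < n_theta:
                cur = th_rad[k]
                cands = [cur + d for d in deltas]
                if not np.isnan(th_ref[k]):
                    cands.append(np.deg2rad(th_ref[k]))
                best_e, best_v = e, cur
                for v in cands:
                    th_rad[k] = min(max(v, lo_th), hi_th)
                    en, _ = _kernels.restraint_energy_reg(
                        _kernels.build_chain(bonds, th_rad, ta_rad),
                        i, j, lo, up, w, centering)
                    if en < best_e:
                        best_e, best_v = en, th_rad[k]
                th_rad[k] = best_v
            else:
                m = k - n_theta
                cur = ta_rad[m]
                cands = [cur + d for d in deltas] + [-cur]
                if not np.isnan(ta_ref[m]):
                    cands.append(np.deg2rad(ta_ref[m]))
                best_e, best_v = e, cur
                for v in cands:
                    v = v - 2 * np.pi * np.floor((v + np.pi) / (2 * np.pi))
                    ta_rad[m] = np.pi if v == -np.pi else v
                    en, _ = _kernels.restraint_energy_reg(
                        _kernels.build_chain(bonds, th_rad, ta_rad),
                        i, j, lo, up, w, centering)
                    if en < best_e:
                        best_e, best_v = en, ta_rad[m]
                ta_rad[m] = best_v
            if best_e < e - 1e-15:
                improved = True
            e = best_e
        if not improved:
            break
    return e


def simulated_annealing(trace: CaTrace, rs: RestraintSet, cfg: SAConfig,
                        stop: StopSignal = None,
                        use_confidence: bool = False,
                        ss: Optional[SecondaryStructure] = None,
                        label: str = "sa") -> OptimizationTrajectory:
    """Metropolis annealing in angular space.

    The trace is converted to internal coordinates (bond lengths kept
    as measured, so connectivity is exact throughout); each iteration
    perturbs one uniformly chosen planar or dihedral angle (see
    :class:`SAConfig` for the move mix), clamping θ into (1°, 179°)
    and wrapping τ into (−180°, 180°], and accepts by the Metropolis
    rule on the per-residue restraint energy at the current
    temperature, which decays geometrically from ``t_initial`` to
    ``t_final``.  Bitwise reproducible for a fixed seed.
    """
    if rs.length != len(trace):
        raise ShapeError("restraint set and trace lengths differ")
    if ss is not None and len(ss) != len(trace):
        raise ShapeError("secondary structure and trace lengths differ")
    L = len(trace)
    if L < 3:
        raise ChainTooShortError("annealing needs at least 3 residues")
    i, j, lo, up, w, kb = _objective_arrays(rs, L, use_confidence)
    ic = cartesian_to_internal(trace)
    bonds = ic.bond_lengths.copy()
    th_rad = np.deg2rad(ic.planar_angles)
    ta_rad = np.deg2rad(ic.dihedral_angles)
    n_theta, n_tau = th_rad.shape[0], ta_rad.shape[0]
    n_angles = n_theta + n_tau
    th_ref, th_sig, ta_ref, ta_sig = _ss_reference_angles(ss, L)

    rng = np.random.default_rng(cfg.seed)
    iters = cfg.iterations
    ratio = ((cfg.t_final / cfg.t_initial) ** (1.0 / (iters - 1))
             if iters > 1 else 1.0)
    temps = cfg.t_initial * ratio ** np.arange(iters)

    X = _kernels.build_chain(bonds, th_rad, ta_rad)
    energy, _ = _kernels.restraint_energy_reg(X, i, j, lo, up, w,
                                              cfg.centering)
    its, es = [], []
    interrupted = False
    for it in range(iters):
        if it % cfg.report_every == 0:
            its.append(it)
            es.append(energy)
            if _stopped(stop):
                interrupted = True
                break
        if (cfg.relax_every and cfg.relax_iterations and it > 0
                and it % cfg.relax_every == 0):
            Xr = X.copy()
            _kernels.gd_run_reg(Xr, cfg.relax_iterations, 0.005, i, j, lo,
                                up, w, kb, CA_BOND_LENGTH, cfg.centering,
                                DIVERGENCE_LIMIT)
            icr = cartesian_to_internal(CaTrace(Xr))
            b_r = icr.bond_lengths
            th_r = np.deg2rad(icr.planar_angles)
            ta_r = np.deg2rad(icr.dihedral_angles)
            Xc = _kernels.build_chain(b_r, th_r, ta_r)
            er, _ = _kernels.restraint_energy_reg(Xc, i, j, lo, up, w,
                                                  cfg.centering)
            if er < energy:  # keep the relaxed basin only if it improves
                bonds, th_rad, ta_rad = b_r, th_r, ta_r
                X, energy = Xc, er
        k = int(rng.integers(n_angles))
        if k < n_theta:
            old = th_rad[k]
            if (not np.isnan(th_ref[k])
                    and rng.random() < cfg.p_guided):
                new = np.deg2rad(rng.normal(th_ref[k], th_sig[k]))
            else:
                new = old + rng.normal(0.0, np.deg2rad(cfg.move_sigma_deg))
            th_rad[k] = min(max(new, np.deg2rad(1.0)), np.deg2rad(179.0))
        else:
            m = k - n_theta
            old = ta_rad[m]
            if (not np.isnan(ta_ref[m])
                    and rng.random() < cfg.p_guided):
                new = np.deg2rad(rng.normal(ta_ref[m], ta_sig[m]))
            else:
                u = rng.random()
                if u < cfg.p_flip:
                    new = -old
                elif u < cfg.p_flip + cfg.p_fresh:
                    new = rng.uniform(-np.pi, np.pi)
                else:
                    new = old + rng.normal(0.0,
                                           np.deg2rad(cfg.move_sigma_deg))
            new = new - 2 * np.pi * np.floor((new + np.pi) / (2 * np.pi))
            ta_rad[m] = np.pi if new == -np.pi else new
        Xn = _kernels.build_chain(bonds, th_rad, ta_rad)
        en, _ = _kernels.restraint_energy_reg(Xn, i, j, lo, up, w,
                                              cfg.centering)
        de = en - energy
        # de/T > 700 would overflow exp(); acceptance probability is 0 there
        if de <= 0.0 or (de / temps[it] < 700.0
                         and rng.random() < np.exp(-de / temps[it])):
            energy = en
            X = Xn
        else:
            if k < n_theta:
                th_rad[k] = old
            else:
                ta_rad[k - n_theta] = old
    if cfg.quench_sweeps and not interrupted:
        energy = _quench_angles(bonds, th_rad, ta_rad, i, j, lo, up, w,
                                cfg.centering, th_ref, ta_ref,
                                cfg.quench_sweeps)
        X = _kernels.build_chain(bonds, th_rad, ta_rad)
    its.append(iters)
    es.append(energy)
    rec = StageRecord(label, np.asarray(its), np.asarray(es))
    return OptimizationTrajectory((rec,), CaTrace(X))


def run_cascade(rs: RestraintSet, spec: CascadeSpec,
                start: Optional[CaTrace] = None,
                stop: StopSignal = None,
                use_confidence: bool = False,
                ss: Optional[SecondaryStructure] = None
                ) -> OptimizationTrajectory:
    """Run the stages of a cascade in order, threading the trace.

    The start conformation defaults to the unfolded extended state; a
    secondary structure, when given, informs the annealing stages'
    proposal distribution (never the energy).
    """
    if isinstance(spec, str):
        spec = preset_cascade(spec)
    trace = start if start is not None else extended_state(rs.length)
    records = []
    for idx, (kind, cfg) in enumerate(spec.stages):
        label = f"{idx}:{kind}"
        if kind == "gd":
            traj = gradient_descent(trace, rs, cfg, stop=stop,
                                    use_confidence=use_confidence,
                                    label=label)
        else:
            traj = simulated_annealing(trace, rs, cfg, stop=stop,
                                       use_confidence=use_confidence,
                                       ss=ss, label=label)
        records.extend(traj.stages)
        trace = traj.final_trace
        if _stopped(stop):
            break
    return OptimizationTrajectory(tuple(records), trace)


def case_study_cascade(seed: int = 0) -> CascadeSpec:
    """One annealing run (given seed) followed by three repeated
    gradient-descent runs at default parameters."""
    return CascadeSpec((
        ("sa", SAConfig(seed=seed)),
        ("gd", GDConfig()),
        ("gd", GDConfig()),
        ("gd", GDConfig()),
    ))


def benchmark_cascade() -> CascadeSpec:
    """Two cascaded gradient-descent runs of 65,000 iterations each,
    step sizes 0.005 then 0.0001."""
    return CascadeSpec((
        ("gd", GDConfig(step_size=0.005, iterations=65000)),
        ("gd", GDConfig(step_size=0.0001, iterations=65000)),
    ))


PRESETS = {
    "case-study": case_study_cascade,
    "benchmark": benchmark_cascade,
}


def preset_cascade(name: str, seed: Optional[int] = None) -> CascadeSpec:
    """Look up a documented preset; an explicit seed reseeds every
    annealing stage (seed + stage index)."""
    try:
        factory = PRESETS[name]
    except KeyError:
        raise ConfigError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        )
    spec = factory()
    if seed is not None:
        stages = []
        for idx, (kind, cfg) in enumerate(spec.stages):
            if kind == "sa":
                cfg = replace(cfg, seed=seed + idx)
            stages.append((kind, cfg))
        spec = CascadeSpec(tuple(stages))
    return spec


def cascade_from_dict(data: dict) -> CascadeSpec:
    """Build a cascade from a config mapping.

    Schema: ``{"stages": [{"kind": "gd"|"sa", <config fields>...}]}``;
    or ``{"preset": "case-study"|"benchmark", "seed": int}``.
    """
    if "preset" in data:
        return preset_cascade(data["preset"], data.get("seed"))
    stages = []
    for entry in data.get("stages", []):
        entry = dict(entry)
        kind = entry.pop("kind", None)
        if kind == "gd":
            stages.append(("gd", GDConfig(**entry)))
        elif kind == "sa":
            stages.append(("sa", SAConfig(**entry)))
        else:
            raise ConfigError(f"stage kind must be 'gd' or 'sa', got {kind!r}")
    return CascadeSpec(tuple(stages))


def load_cascade(path) -> CascadeSpec:
    """Load a cascade from a YAML config file (see cascade_from_dict)."""
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigError("cascade config must be a mapping")
    return cascade_from_dict(data)
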