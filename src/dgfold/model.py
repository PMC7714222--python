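"""Model/results surface for distance-restraint folding.

:class:`CaFoldingModel` bundles the inputs of one folding problem — a
restraint set, optionally a secondary-structure string (used for
chirality correction) and a start conformation — and ``fit()`` runs an
optimizer cascade, returning a :class:`FoldingResults` that carries
the folded trace, the energy trajectory, restraint-satisfaction
diagnostics and a text ``summary()``.

Example
-------
>>> from dgfold import fixtures, perturb
>>> from dgfold.model import CaFoldingModel
>>> native, ss = fixtures.make_alpha_beta_target()
>>> rs = perturb.near_native_restraints(native)
>>> res = CaFoldingModel(rs, secondary_structure=ss).fit(seed=0)
>>> res.score(native).tm_score  # doctest: +SKIP
0.98...
"""
from __future__ import annotations

from typing import Optional, Union

from .chirality import ChiralityReport, fix_chirality
from .energy import EnergyBreakdown, restraint_energy
from .exceptions import ShapeError
from .formats import (RestraintSet, SecondaryStructure, parse_rr, parse_ss,
                      write_pdb_ca)
from .geometry import CaTrace
from .optimize import (CascadeSpec, OptimizationTrajectory, preset_cascade,
                       run_cascade)


class CaFoldingModel:
    """A distance-restraint folding problem for one Cα chain."""

    def __init__(self, restraints: RestraintSet,
                 secondary_structure: Optional[SecondaryStructure] = None,
                 start: Optional[CaTrace] = None,
                 use_confidence: bool = False):
        if secondary_structure is not None \
                and len(secondary_structure) != restraints.length:
            raise ShapeError(
                "secondary structure length does not match chain length"
            )
        if start is not None and len(start) != restraints.length:
            raise ShapeError("start trace length does not match chain length")
        self.restraints = restraints
        self.secondary_structure = secondary_structure
        self.start = start
        self.use_confidence = use_confidence

    @classmethod
    def from_files(cls, rr_path, ss_path=None, **kwargs) -> "CaFoldingModel":
        """Build a model from an RR restraint file and an optional
        secondary-structure file."""
        with open(rr_path) as fh:
            rs = parse_rr(fh)
        ss = None
        if ss_path is not None:
            with open(ss_path) as fh:
                ss = parse_ss(fh)
        return cls(rs, secondary_structure=ss, **kwargs)

    def fit(self, cascade: Union[str, CascadeSpec] = "case-study",
            seed: Optional[int] = None,
            fix_handedness: bool = True,
            stop=None) -> "FoldingResults":
        """Run the optimizer cascade and return the results.

        ``cascade`` is a preset name ("case-study" or "benchmark") or
        an explicit :class:`CascadeSpec`; ``seed`` reseeds the
        stochastic stages of a named preset.  Handedness is corrected
        after optimization when a secondary structure is available
        (distance restraints cannot see chirality), unless disabled.
        """
        if isinstance(cascade, str):
            cascade = preset_cascade(cascade, seed)
        trajectory = run_cascade(self.restraints, cascade, start=self.start,
                                 stop=stop, use_confidence=self.use_confidence,
                                 ss=self.secondary_structure)
        trace = trajectory.final_trace
        chirality = None
        if fix_handedness and self.secondary_structure is not None:
            trace, chirality = fix_chirality(trace, self.secondary_structure)
        return FoldingResults(self, cascade, trajectory, trace, chirality)


class FoldingResults:
    """Outcome of one folding run."""

    def __init__(self, model: CaFoldingModel, cascade: CascadeSpec,
                 trajectory: OptimizationTrajectory, trace: CaTrace,
                 chirality: Optional[ChiralityReport]):
        self.model = model
        self.cascade = cascade
        self.trajectory = trajectory
        self.trace = trace
        self.chirality = chirality

    @property
    def energy(self) -> EnergyBreakdown:
        """Energy decomposition of the final conformation (unnormalized
        flat-bottom sums)."""
        return restraint_energy(self.trace, self.model.restraints,
                                use_confidence=self.model.use_confidence)

    def score(self, native: CaTrace):
        """TM-score/RMSD report of the folded trace against a reference."""
        from .perturb import tm_score

        return tm_score(self.trace, native)

    def save_pdb(self, path, sequence: Optional[str] = None) -> None:
        """Write the folded trace as a Cα-only PDB file."""
        seq = sequence if sequence is not None else self.model.restraints.sequence
        with open(path, "w") as fh:
            write_pdb_ca(self.trace, seq, fh)

    def summary(self) -> str:
        """Human-readable run summary."""
        rs = self.model.restraints
        eb = self.energy
        lines = [
            "Distance-restraint folding results",
            "=" * 42,
            f"chain length          {rs.length}",
            f"restraints            {len(rs)}",
            f"cascade stages        "
            + " + ".join(kind for kind, _ in self.cascade.stages),
            f"initial objective     {self.trajectory.initial_energy:.6g}",
            f"final objective       {self.trajectory.final_energy:.6g}",
            f"restraint energy      {eb.restraint_term:.6g}",
            f"connectivity energy   {eb.connectivity_term:.6g}",
            f"satisfied restraints  {eb.n_satisfied}/{len(rs)}",
        ]
        if self.chirality is not None:
            c = self.chirality
            lines.append(
                f"chirality             "
                f"{'mirrored' if c.flipped else 'kept'} "
                f"(cost {c.cost_original:.1f} vs mirror "
                f"{c.cost_mirror:.1f}, {c.n_tetrapeptides} windows)"
            )
        return "\n".join(lines)
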