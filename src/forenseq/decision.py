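"""Forensic decision layer: per-method thresholds and the 3-of-4 rule.

Four assignment methods each produce normalised per-population scores for
a query sample: supervised admixture membership (Q), the frequency-based
and Bayesian assignment likelihoods, and DAPC posterior membership.  A
method *votes* for a population when its score meets that method's
threshold (Q >= 0.70; each of the two likelihood methods > 0.99; DAPC
>= 0.90 by default).  A sample is assigned to a population only when at
least three of the four methods vote for the same population; otherwise it
is reported as unassigned/admixed.  Samples that failed genotyping QC are
carried through as ``failed_qc``.

The module also ships the printed per-method scores of the study's
fourteen scored forensic samples as a packaged fixture, so the decision
rule can be exercised end-to-end on real published numbers.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from .assignment import PopScores

__all__ = [
    "METHODS",
    "MethodThresholds",
    "ForensicCall",
    "consensus_assign",
    "load_table1_fixture",
    "run_table1_fixture",
]

METHODS = ("structure_q", "frequency", "bayesian", "dapc")


@dataclass(frozen=True)
class MethodThresholds:
    """Per-method pass criteria for the consensus rule.

    Comparison operators follow each method's published criterion: the
    admixture Q uses >= (score of at least 70%), the two likelihood
    methods use strict > (probability above 0.99), DAPC uses >=.
    """

    structure_q_min: float = 0.70
    geneclass_min: float = 0.99
    dapc_min: float = 0.90
    methods_required: int = 3

    def __post_init__(self) -> None:
        for name in ("structure_q_min", "geneclass_min", "dapc_min"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.methods_required not in (1, 2, 3, 4):
            raise ValueError("methods_required must be between 1 and 4")

    def passes(self, method: str, score: float) -> bool:
        if method == "structure_q":
            return score >= self.structure_q_min
        if method in ("frequency", "bayesian"):
            return score > self.geneclass_min
        if method == "dapc":
            return score >= self.dapc_min
        raise ValueError(f"unknown method {method!r}")


@dataclass
class ForensicCall:
    sample: str
    status: str  # "assigned" | "unassigned_admixed" | "failed_qc"
    population: str | None = None
    supporting_methods: int = 0
    method_votes: dict[str, str | None] = field(default_factory=dict)

    @property
    def assigned(self) -> bool:
        return self.status == "assigned"


def _scores_dict(obj: PopScores | Mapping[str, float]) -> dict[str, float]:
    if isinstance(obj, PopScores):
        return dict(obj.scores)
    return dict(obj)


def consensus_assign(
    sample: str,
    scores: Mapping[str, PopScores | Mapping[str, float]],
    thresholds: MethodThresholds = MethodThresholds(),
) -> ForensicCall:
    """Apply the thresholded 3-of-4 agreement rule to one sample.

    ``scores`` maps each of the four method names to that method's
    per-population scores (a :class:`PopScores` or a plain mapping).  The
    sample is assigned to a population only when at least
    ``thresholds.methods_required`` methods pass their threshold for the
    *same* population.
    """
    missing = [m for m in METHODS if m not in scores]
    if missing:
        raise ValueError(f"sample {sample!r}: missing method scores {missing}")
    votes: dict[str, str | None] = {}
    tally: dict[str, int] = {}
    for method in METHODS:
        table = _scores_dict(scores[method])
        vote = None
        for pop, val in table.items():
            if thresholds.passes(method, float(val)):
                vote = pop
                break
        votes[method] = vote
        if vote is not None:
            tally[vote] = tally.get(vote, 0) + 1
    if tally:
        best_pop = max(tally, key=tally.get)
        if tally[best_pop] >= thresholds.methods_required:
            return ForensicCall(
                sample, "assigned", best_pop, tally[best_pop], votes
            )
    return ForensicCall(
        sample, "unassigned_admixed", None, max(tally.values(), default=0), votes
    )


# ---------------------------------------------------------------------------
# Packaged fixture of printed per-method scores
# ---------------------------------------------------------------------------

_POPS = ("BNP", "SWR", "CNP")


def load_table1_fixture() -> pd.DataFrame:
    """The 15 forensic samples' printed per-method scores.

    14 scored samples plus one sample whose genotyping failed QC (a
    two-contributor mixture) with empty score columns.  Columns:
    ``q_*``, ``freq_*``, ``bayes_*``, ``dapc_*`` for the three candidate
    populations, plus species, sex and the published call for reference.
    """
    ref = importlib.resources.files("forenseq") / "data" / "table1_scores.csv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path)


_COL_PREFIX = {
    "structure_q": "q",
    "frequency": "freq",
    "bayesian": "bayes",
    "dapc": "dapc",
}


def run_table1_fixture(
    thresholds: MethodThresholds = MethodThresholds(),
) -> dict:
    """Run the consensus rule over the packaged fixture.

    Returns per-sample calls plus summary counts: samples assigned per
    population, unassigned, failed.  Printed scores are compared against
    the thresholds exactly as printed (no renormalisation).
    """
    df = load_table1_fixture()
    calls: list[ForensicCall] = []
    for _, row in df.iterrows():
        if pd.isna(row["q_BNP"]):
            calls.append(ForensicCall(row["sample"], "failed_qc"))
            continue
        scores = {
            method: {pop: float(row[f"{prefix}_{pop}"]) for pop in _POPS}
            for method, prefix in _COL_PREFIX.items()
        }
        calls.append(consensus_assign(row["sample"], scores, thresholds))
    assigned_counts = {pop: 0 for pop in _POPS}
    unassigned = failed = 0
    for call in calls:
        if call.status == "assigned":
            assigned_counts[call.population] += 1
        elif call.status == "unassigned_admixed":
            unassigned += 1
        else:
            failed += 1
    return {
        "calls": calls,
        "assigned_per_pop": assigned_counts,
        "n_assigned": sum(assigned_counts.values()),
        "n_unassigned": unassigned,
        "n_failed": failed,
    }
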