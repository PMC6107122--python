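"""Multi-tube consensus genotyping from replicated PCR outcomes.

Low-quantity forensic DNA is genotyped in several independent PCR
replicates per locus; alleles can drop out (a heterozygote looking
homozygous) or spurious alleles can appear.  The calling rules here turn a
set of replicate outcomes into a consensus genotype:

* a homozygote call requires at least three replicates that are exactly
  ``a/a`` with no second allele confirmed;
* a heterozygote call requires each of the two alleles to be observed in at
  least two independent replicates with no third allele confirmed;
* an allele is *confirmed* when it is observed in at least two replicates —
  a single stray observation never drives a call or an exclusion.

Samples in which three or more alleles are confirmed at one or more loci
are flagged as putative mixtures (two contributors) and excluded from
downstream profiling.  Sex is called from triplicate amelogenin band
patterns: X and Y bands in at least two of three replicates means male, an
X-only pattern in all three replicates means female.

Genotyping error rates are scored per replicate against the consensus:
allelic dropout (ADO) as the fraction of replicates of
heterozygous-consensus loci that present as an apparent homozygote for
exactly one of the two consensus alleles, and false alleles (FA) as the
fraction of replicates at called loci containing any allele outside the
consensus genotype.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

from .genotypes import GenotypeMatrix, Locus

Replicate = tuple[int, ...] | None  # (a, b), single-allele (a,), or None=failed

__all__ = [
    "ReplicateSet",
    "ConsensusCall",
    "SampleConsensus",
    "ErrorRates",
    "call_consensus_locus",
    "call_consensus_sample",
    "call_sex",
    "estimate_error_rates",
    "consensus_to_matrix",
]


@dataclass
class ReplicateSet:
    """Replicate PCR outcomes for one sample.

    ``replicates[locus]`` is a list of outcomes: an unordered allele pair
    ``(a, b)``, a single-allele observation ``(a,)``, or ``None`` for a
    failed reaction.
    """

    sample: str
    replicates: dict[str, list[Replicate]] = field(default_factory=dict)

    def loci(self) -> list[str]:
        return list(self.replicates)


@dataclass
class ConsensusCall:
    status: Literal["homozygote", "heterozygote", "no_call"]
    alleles: tuple[int, ...]
    support: dict[int, int]
    extra_alleles: tuple[int, ...] = ()

    @property
    def called(self) -> bool:
        return self.status != "no_call"

    def genotype(self) -> tuple[int, int] | None:
        if self.status == "homozygote":
            return (self.alleles[0], self.alleles[0])
        if self.status == "heterozygote":
            return (self.alleles[0], self.alleles[1])
        return None


def _allele_support(reps: Sequence[Replicate]) -> Counter:
    """Number of replicates in which each allele was observed (not copies)."""
    support: Counter = Counter()
    for rep in reps:
        if rep is None:
            continue
        for a in set(rep):
            support[a] += 1
    return support


def call_consensus_locus(
    reps: Sequence[Replicate], min_het_obs: int = 2, min_hom_reps: int = 3
) -> ConsensusCall:
    """Apply the multi-tube rule to one (sample, locus) replicate list.

    Order of replicates never matters.  Degenerate input (empty list, all
    failed) yields a ``no_call``; it is not an error.
    """
    support = _allele_support(reps)
    confirmed = sorted(a for a, n in support.items() if n >= min_het_obs)
    if len(confirmed) >= 3:
        return ConsensusCall("no_call", (), dict(support), tuple(confirmed))
    if len(confirmed) == 2:
        return ConsensusCall("heterozygote", tuple(confirmed), dict(support))
    if len(confirmed) == 1:
        a = confirmed[0]
        exact_hom = sum(1 for rep in reps if rep is not None and set(rep) == {a} and len(rep) == 2)
        if exact_hom >= min_hom_reps:
            return ConsensusCall("homozygote", (a,), dict(support))
    return ConsensusCall("no_call", (), dict(support))


@dataclass
class SampleConsensus:
    sample: str
    calls: dict[str, ConsensusCall]
    flags: set[str] = field(default_factory=set)

    @property
    def excluded(self) -> bool:
        return "excluded_mixed" in self.flags

    def call_rate(self) -> float:
        if not self.calls:
            return 0.0
        return sum(c.called for c in self.calls.values()) / len(self.calls)


def call_consensus_sample(
    reps: ReplicateSet,
    mixed_locus_threshold: int = 1,
    completeness_threshold: float = 0.5,
) -> SampleConsensus:
    """Consensus-call every locus of a sample and attach QC flags.

    ``excluded_mixed`` fires when at least ``mixed_locus_threshold`` loci
    have three or more confirmed alleles (a two-contributor signature);
    ``low_success`` fires when the fraction of called loci does not exceed
    ``completeness_threshold`` (a sample with only half its loci amplified
    is flagged).
    """
    calls = {locus: call_consensus_locus(r) for locus, r in reps.replicates.items()}
    flags: set[str] = set()
    n_multi = sum(1 for c in calls.values() if len(c.extra_alleles) >= 3)
    if n_multi >= mixed_locus_threshold:
        flags.add("excluded_mixed")
    if calls and sum(c.called for c in calls.values()) / len(calls) <= completeness_threshold:
        flags.add("low_success")
    return SampleConsensus(reps.sample, calls, flags)


def call_sex(replicates: Sequence[frozenset | set | None]) -> str:
    """Call sex from amelogenin band patterns (subsets of {'X','Y'}).

    Male: X+Y bands in >=2 replicates.  Female: an X-only pattern in all
    three replicates (no failures, no Y anywhere).  Anything else is
    inconclusive.
    """
    patterns = [None if r is None else frozenset(r) for r in replicates]
    xy = sum(1 for p in patterns if p is not None and {"X", "Y"} <= p)
    if xy >= 2:
        return "male"
    x_only = sum(1 for p in patterns if p == frozenset({"X"}))
    any_y = any(p is not None and "Y" in p for p in patterns)
    if x_only == 3 and not any_y and len(patterns) == 3:
        return "female"
    return "inconclusive"


@dataclass
class ErrorRates:
    """Observed genotyping error rates with their denominators.

    ``ado_rate``/``fa_rate`` are pooled over loci; ``None`` when the
    denominator is zero (never reported as 0).  Per-locus breakdowns carry
    ``(numerator, denominator)`` pairs.
    """

    ado_rate: float | None
    fa_rate: float | None
    ado_by_locus: dict[str, tuple[int, int]]
    fa_by_locus: dict[str, tuple[int, int]]

    def locus_mean(self, which: str = "ado") -> float | None:
        table = self.ado_by_locus if which == "ado" else self.fa_by_locus
        rates = [num / den for num, den in table.values() if den > 0]
        return sum(rates) / len(rates) if rates else None


def estimate_error_rates(
    rep_sets: Iterable[ReplicateSet],
    consensus: Mapping[str, SampleConsensus],
) -> ErrorRates:
    """Score replicates against consensus genotypes.

    ADO: over non-failed replicates of heterozygous-consensus loci, the
    fraction presenting as an apparent homozygote for exactly one of the two
    consensus alleles.  FA: over non-failed replicates of called loci, the
    fraction containing at least one allele absent from the consensus
    genotype.
    """
    ado: dict[str, list[int]] = {}
    fa: dict[str, list[int]] = {}
    for reps in rep_sets:
        cons = consensus.get(reps.sample)
        if cons is None:
            continue
        for locus, rep_list in reps.replicates.items():
            call = cons.calls.get(locus)
            if call is None or not call.called:
                continue
            cons_set = set(call.alleles)
            a = ado.setdefault(locus, [0, 0])
            f = fa.setdefault(locus, [0, 0])
            for rep in rep_list:
                if rep is None:
                    continue
                obs = set(rep)
                f[1] += 1
                if obs - cons_set:
                    f[0] += 1
                if call.status == "heterozygote":
                    a[1] += 1
                    if len(obs) == 1 and obs < cons_set:
                        a[0] += 1
    ado_num = sum(v[0] for v in ado.values())
    ado_den = sum(v[1] for v in ado.values())
    fa_num = sum(v[0] for v in fa.values())
    fa_den = sum(v[1] for v in fa.values())
    return ErrorRates(
        ado_rate=ado_num / ado_den if ado_den else None,
        fa_rate=fa_num / fa_den if fa_den else None,
        ado_by_locus={k: (v[0], v[1]) for k, v in ado.items()},
        fa_by_locus={k: (v[0], v[1]) for k, v in fa.items()},
    )


def consensus_to_matrix(
    results: Sequence[SampleConsensus],
    locus_order: Sequence[str] | None = None,
    drop_excluded: bool = True,
) -> GenotypeMatrix:
    """Assemble consensus genotype rows into a query GenotypeMatrix."""
    kept = [r for r in results if not (drop_excluded and r.excluded)]
    if locus_order is None:
        seen: dict[str, None] = {}
        for r in kept:
            for name in r.calls:
                seen.setdefault(name)
        locus_order = list(seen)
    calls = {
        r.sample: {name: (r.calls[name].genotype() if name in r.calls else None) for name in locus_order}
        for r in kept
    }
    return GenotypeMatrix.from_calls(calls, locus_order=list(locus_order))
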