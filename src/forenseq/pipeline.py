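"""End-to-end orchestration: replicates -> consensus -> QC -> assignment.

Stages, mirroring the forensic workflow:

1. consensus-call each query sample from its PCR replicates and flag
   mixtures / low-success samples (failed QC ends the sample's analysis);
2. match surviving profiles against the reference database — an exact
   multi-locus match identifies a previously profiled individual and
   short-circuits to that individual's population;
3. score each query with the four assignment methods (supervised
   admixture Q, frequency likelihood, Bayesian likelihood, DAPC);
4. apply the thresholded 3-of-4 consensus rule.

One failing sample never aborts the batch: per-sample errors are caught
and reported in that sample's record.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .admixture import AdmixtureModel
from .assignment import BayesianAssigner, DAPC, FrequencyAssigner, PopScores
from .consensus import ReplicateSet, call_consensus_sample, consensus_to_matrix
from .decision import MethodThresholds, consensus_assign
from .genotypes import GenotypeMatrix
from .identity import match_genotypes

__all__ = ["PipelineOptions", "SampleReport", "full_pipeline"]


@dataclass(frozen=True)
class PipelineOptions:
    thresholds: MethodThresholds = MethodThresholds()
    mixed_locus_threshold: int = 1
    completeness_threshold: float = 0.5
    max_mismatch: int = 0
    min_match_loci: int = 6
    mcmc_burn_in: int = 2_000
    mcmc_reps: int = 8_000
    mcmc_thin: int = 10
    seed: int = 0


@dataclass
class SampleReport:
    sample: str
    status: str  # assigned | unassigned_admixed | failed_qc | error
    population: str | None = None
    qc_flags: list[str] = field(default_factory=list)
    matched_reference: str | None = None
    method_scores: dict[str, dict[str, float]] = field(default_factory=dict)
    supporting_methods: int = 0
    error: str | None = None

    def to_dict(self) -> dict:
        return {
            "sample": self.sample,
            "status": self.status,
            "population": self.population,
            "qc_flags": list(self.qc_flags),
            "matched_reference": self.matched_reference,
            "method_scores": self.method_scores,
            "supporting_methods": self.supporting_methods,
            "error": self.error,
        }


def full_pipeline(
    refs: GenotypeMatrix,
    replicates: Sequence[ReplicateSet],
    opts: PipelineOptions = PipelineOptions(),
) -> list[SampleReport]:
    """Run the complete forensic chain on a batch of replicate sets."""
    reports: dict[str, SampleReport] = {}

    # 1. consensus calling + QC
    consensus = []
    for reps in replicates:
        sc = call_consensus_sample(
            reps,
            mixed_locus_threshold=opts.mixed_locus_threshold,
            completeness_threshold=opts.completeness_threshold,
        )
        consensus.append(sc)
        reports[sc.sample] = SampleReport(
            sc.sample,
            status="failed_qc" if sc.excluded else "pending",
            qc_flags=sorted(sc.flags),
        )
    survivors = [sc for sc in consensus if not sc.excluded]
    if not survivors:
        return [reports[r.sample] for r in replicates]
    queries = consensus_to_matrix(survivors, locus_order=refs.locus_names)

    # 2. exact-match screen against the reference database
    try:
        matches = match_genotypes(
            queries, refs, max_mismatch=opts.max_mismatch, min_loci=opts.min_match_loci
        )
        for res in matches:
            if res.hits:
                hit = res.hits[0]
                rep = reports[res.query]
                rep.matched_reference = hit.reference
    except ValueError:
        matches = []

    # 3. the four assignment methods
    per_sample_scores: dict[str, dict[str, PopScores | dict[str, float]]] = {
        s: {} for s in queries.samples
    }
    errors: dict[str, str] = {}

    combined = GenotypeMatrix.concat([refs, queries])
    model = AdmixtureModel(
        k=len(refs.populations()),
        burn_in=opts.mcmc_burn_in,
        reps=opts.mcmc_reps,
        thin=opts.mcmc_thin,
        supervised=True,
        random_state=opts.seed,
    ).fit(combined)
    q_rows = {s: model.Q_[i] for i, s in enumerate(model.samples_)}
    for s in queries.samples:
        per_sample_scores[s]["structure_q"] = {
            lab: float(v) for lab, v in zip(model.cluster_labels_, q_rows[s])
        }

    assigners = {
        "frequency": FrequencyAssigner().fit(refs),
        "bayesian": BayesianAssigner().fit(refs),
        "dapc": DAPC().fit(refs),
    }
    for method, assigner in assigners.items():
        for s in queries.samples:
            try:
                ps = assigner.predict_proba_one(queries.subset(samples=[s]))
                per_sample_scores[s][method] = ps
            except Exception as exc:  # sample-level isolation
                errors[s] = f"{method}: {exc}"

    # 4. consensus decision
    for s in queries.samples:
        rep = reports[s]
        rep.method_scores = {
            m: dict(v.scores) if isinstance(v, PopScores) else dict(v)
            for m, v in per_sample_scores[s].items()
        }
        if s in errors:
            rep.status = "error"
            rep.error = errors[s]
            continue
        try:
            call = consensus_assign(s, per_sample_scores[s], opts.thresholds)
        except Exception as exc:
            rep.status = "error"
            rep.error = str(exc)
            continue
        rep.status = call.status
        rep.population = call.population
        rep.supporting_methods = call.supporting_methods
    return [reports[r.sample] for r in replicates]
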