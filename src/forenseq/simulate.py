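"""Synthetic microsatellite study generator with complete ground truth.

Emulates the study design the pipeline is built for: a small number of
geographically separated source populations genotyped at a handful of
polymorphic microsatellite loci, forensic queries of pure, admixed or
duplicated origin, and replicate-level PCR data with realistic allelic
dropout and false-allele rates.

Population allele frequencies follow the Balding-Nichols model: ancestral
frequencies ``p`` are drawn from a flat Dirichlet per locus and each
population's frequencies from ``Dirichlet(p * (1 - F) / F)``, giving an
expected fixation index of ``F`` between populations.  Genotypes are drawn
under Hardy-Weinberg equilibrium within populations.  No mutation model,
linkage or null alleles are simulated.

Replicate errors are injected per replicate: with probability ``ado_rate``
a heterozygous replicate drops one randomly chosen allele (an apparent
homozygote), and with probability ``fa_rate`` one allele copy is replaced
by a spurious ladder allele within one repeat unit of a true allele.
Mixed (two-contributor) samples draw each replicate's two alleles from the
union of both contributors' genotypes.  Everything is reproducible from
the mandatory seed, and every generated datum is traceable through
:class:`SimTruth`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .consensus import ReplicateSet
from .genotypes import GenotypeMatrix, Locus

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_reference",
    "simulate_queries",
    "simulate_replicates",
    "simulate_sex_replicates",
    "simulate_study",
]

REPEAT_UNIT = 4  # bp between ladder rungs; cosmetic only


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters for the generator.

    Defaults mirror the operating regime the pipeline assumes: three
    source populations, eight polymorphic loci with 6-10 alleles each,
    between-population F_ST of 0.15, and replicate error rates of 2.5%
    allelic dropout / 16% false alleles over four PCR replicates.
    """

    n_pops: int = 3
    n_per_pop: int = 30
    n_loci: int = 8
    alleles_per_locus: tuple[int, int] = (6, 10)
    fst: float = 0.15
    n_queries: int = 12
    admixed_fraction: float = 0.0
    mixing_proportions: tuple[float, ...] | None = None
    duplicate_fraction: float = 0.0
    ado_rate: float = 0.025
    fa_rate: float = 0.16
    n_replicates: int = 4
    mixed_sample_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "admixed_fraction",
            "duplicate_fraction",
            "mixed_sample_fraction",
            "ado_rate",
            "fa_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 <= self.fst < 1.0:
            raise ValueError("fst must be in [0, 1)")
        if self.seed is None:
            raise ValueError("a seed is mandatory")

    @property
    def pop_names(self) -> list[str]:
        return [f"pop{i + 1}" for i in range(self.n_pops)]


@dataclass
class SimTruth:
    """Ground truth for every generated datum."""

    ancestral_freqs: dict[str, dict[int, float]] = field(default_factory=dict)
    pop_freqs: dict[str, dict[str, dict[int, float]]] = field(default_factory=dict)
    origins: dict[str, dict[str, float]] = field(default_factory=dict)  # sample -> mixture
    true_genotypes: dict[str, dict[str, tuple[int, int]]] = field(default_factory=dict)
    duplicate_map: dict[str, str] = field(default_factory=dict)  # query -> reference
    mixed_map: dict[str, tuple[str, str]] = field(default_factory=dict)
    error_events: list[dict] = field(default_factory=list)

    def origin_of(self, sample: str) -> str | None:
        """Majority origin for pure samples, None for 50/50 mixtures."""
        mix = self.origins.get(sample)
        if not mix:
            return None
        best = max(mix, key=mix.get)
        return best if mix[best] > 0.5 else None


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


def _draw_loci(cfg: SimConfig, rng: np.random.Generator) -> list[Locus]:
    lo, hi = cfg.alleles_per_locus
    loci = []
    for j in range(cfg.n_loci):
        n_all = int(rng.integers(lo, hi + 1)) if hi > lo else lo
        base = 100 + 30 * j
        labels = tuple(base + REPEAT_UNIT * i for i in range(n_all))
        loci.append(Locus(f"L{j + 1:02d}", labels))
    return loci


def _genotype_from_freqs(
    loci: list[Locus],
    freqs: dict[str, dict[int, float]],
    rng: np.random.Generator,
) -> dict[str, tuple[int, int]]:
    out = {}
    for locus in loci:
        table = freqs[locus.name]
        alleles = np.array(list(table))
        p = np.array(list(table.values()))
        pair = rng.choice(alleles, size=2, p=p / p.sum())
        out[locus.name] = (int(min(pair)), int(max(pair)))
    return out


def simulate_reference(cfg: SimConfig) -> tuple[GenotypeMatrix, SimTruth]:
    """Reference populations under the Balding-Nichols model + HWE."""
    rng = _rng(cfg.seed)
    truth = SimTruth()
    loci = _draw_loci(cfg, rng)
    for locus in loci:
        p = rng.dirichlet(np.ones(len(locus.allele_labels)))
        truth.ancestral_freqs[locus.name] = {
            a: float(x) for a, x in zip(locus.allele_labels, p)
        }
    for pop in cfg.pop_names:
        truth.pop_freqs[pop] = {}
        for locus in loci:
            anc = np.array(list(truth.ancestral_freqs[locus.name].values()))
            if cfg.fst == 0.0:
                q = anc
            else:
                conc = anc * (1.0 - cfg.fst) / cfg.fst
                q = rng.dirichlet(np.clip(conc, 1e-9, None))
            truth.pop_freqs[pop][locus.name] = {
                a: float(x) for a, x in zip(locus.allele_labels, q)
            }
    samples, labels, calls = [], [], {}
    for pop in cfg.pop_names:
        for i in range(cfg.n_per_pop):
            sid = f"{pop}-R{i + 1:03d}"
            geno = _genotype_from_freqs(loci, truth.pop_freqs[pop], rng)
            truth.true_genotypes[sid] = geno
            truth.origins[sid] = {pop: 1.0}
            samples.append(sid)
            labels.append(pop)
            calls[sid] = geno
    g = GenotypeMatrix.from_calls(
        calls,
        locus_order=[l.name for l in loci],
        pop_labels=dict(zip(samples, labels)),
    )
    # keep full ladders on the loci even if some alleles went unobserved
    g.loci = loci
    g._augment_ladders()
    return g, truth


def simulate_queries(
    cfg: SimConfig, truth: SimTruth, reference: GenotypeMatrix
) -> tuple[GenotypeMatrix, SimTruth]:
    """Forensic queries: pure, admixed and planted-duplicate samples.

    Counts come from ``n_queries`` with ``duplicate_fraction`` and
    ``admixed_fraction``; pure queries cycle over the source populations.
    Admixed queries draw each gene copy's population of origin from the
    mixing proportions (default 50/50 over the first two populations).
    """
    rng = _rng(cfg.seed + 104_729)
    n_dup = int(round(cfg.duplicate_fraction * cfg.n_queries))
    n_adm = int(round(cfg.admixed_fraction * cfg.n_queries))
    if n_adm > 0 and cfg.n_pops < 2:
        raise ValueError("admixed queries need at least two populations")
    n_pure = cfg.n_queries - n_dup - n_adm
    if n_pure < 0:
        raise ValueError("duplicate_fraction + admixed_fraction exceed 1")
    mix = cfg.mixing_proportions
    if mix is None:
        mix = tuple(
            [0.5, 0.5] + [0.0] * (cfg.n_pops - 2) if cfg.n_pops >= 2 else [1.0]
        )
    loci = reference.loci
    calls: dict[str, dict[str, tuple[int, int]]] = {}
    q_idx = 0
    for i in range(n_pure):
        pop = cfg.pop_names[i % cfg.n_pops]
        sid = f"Q-{q_idx + 1:03d}"
        q_idx += 1
        geno = _genotype_from_freqs(loci, truth.pop_freqs[pop], rng)
        truth.true_genotypes[sid] = geno
        truth.origins[sid] = {pop: 1.0}
        calls[sid] = geno
    for _ in range(n_adm):
        sid = f"Q-{q_idx + 1:03d}"
        q_idx += 1
        # realized ancestry is conditioned on the mixture vector (a 50/50
        # query is F1-like: exactly half its gene copies from each parent
        # population), so planted admixture proportions are exact, not
        # Bernoulli-dispersed
        n_copies = 2 * len(loci)
        mix_arr = np.array(mix, dtype=float) / sum(mix)
        copy_counts = np.floor(mix_arr * n_copies).astype(int)
        frac_order = np.argsort(-(mix_arr * n_copies - copy_counts))
        for idx in frac_order[: n_copies - copy_counts.sum()]:
            copy_counts[idx] += 1
        copy_origins = np.repeat(np.arange(cfg.n_pops), copy_counts)
        rng.shuffle(copy_origins)
        geno = {}
        for j, locus in enumerate(loci):
            pair = []
            for c in (0, 1):
                pop = cfg.pop_names[int(copy_origins[2 * j + c])]
                table = truth.pop_freqs[pop][locus.name]
                alleles = np.array(list(table))
                p = np.array(list(table.values()))
                pair.append(int(rng.choice(alleles, p=p / p.sum())))
            geno[locus.name] = (min(pair), max(pair))
        truth.true_genotypes[sid] = geno
        truth.origins[sid] = {p: float(m) for p, m in zip(cfg.pop_names, mix_arr)}
        calls[sid] = geno
    dup_sources = rng.choice(reference.samples, size=n_dup, replace=False)
    for src in dup_sources:
        sid = f"Q-{q_idx + 1:03d}"
        q_idx += 1
        geno = dict(truth.true_genotypes[str(src)])
        truth.true_genotypes[sid] = geno
        truth.origins[sid] = dict(truth.origins[str(src)])
        truth.duplicate_map[sid] = str(src)
        calls[sid] = geno
    g = GenotypeMatrix.from_calls(calls, locus_order=[l.name for l in loci])
    g.loci = list(loci)
    g._augment_ladders()
    return g, truth


def _false_allele(
    true_pair: tuple[int, int], ladder: tuple[int, ...], rng: np.random.Generator
) -> int | None:
    """A spurious ladder allele, never one of the true pair.

    Drawn uniformly over the rest of the ladder: a narrower stutter-only
    pool (immediate ladder neighbours) lets the same false allele recur
    across replicates often enough to be confirmed into the consensus,
    which the multi-tube protocol is designed to prevent.
    """
    pool = sorted(set(ladder) - set(true_pair))
    if not pool:
        return None
    return int(rng.choice(pool))


def simulate_replicates(
    genotypes: GenotypeMatrix, cfg: SimConfig, truth: SimTruth
) -> list[ReplicateSet]:
    """Replicate PCR outcomes with injected dropout / false-allele errors.

    A fraction ``mixed_sample_fraction`` of the samples are overlaid with a
    second contributor drawn from the reference truth; their replicates
    sample two distinct alleles from the union of both genotypes.
    """
    rng = _rng(cfg.seed + 224_737)
    ladder = {l.name: l.allele_labels for l in genotypes.loci}
    n_mixed = int(round(cfg.mixed_sample_fraction * genotypes.n_samples))
    mixed_samples = list(
        rng.choice(genotypes.samples, size=n_mixed, replace=False)
    )
    all_truth_samples = [
        s for s in truth.true_genotypes if s not in genotypes.samples
    ] or list(truth.true_genotypes)
    out = []
    for sid in genotypes.samples:
        reps = ReplicateSet(sid)
        true_geno = truth.true_genotypes[sid]
        partner = None
        if sid in mixed_samples:
            partner = str(rng.choice(all_truth_samples))
            truth.mixed_map[sid] = (sid, partner)
        for locus_name, pair in true_geno.items():
            rep_list: list[tuple[int, ...] | None] = []
            if partner is not None:
                union = sorted(set(pair) | set(truth.true_genotypes[partner][locus_name]))
                for _ in range(cfg.n_replicates):
                    if len(union) <= 2:
                        rep_list.append(tuple(sorted(pair)))
                    else:
                        two = rng.choice(union, size=2, replace=False)
                        rep_list.append((int(min(two)), int(max(two))))
            else:
                for r in range(cfg.n_replicates):
                    a, b = pair
                    obs = [a, b]
                    if a != b and rng.random() < cfg.ado_rate:
                        dropped = int(rng.integers(2))
                        keep = obs[1 - dropped]
                        obs = [keep, keep]
                        truth.error_events.append(
                            {"sample": sid, "locus": locus_name, "rep": r, "type": "ado"}
                        )
                    if rng.random() < cfg.fa_rate:
                        fa = _false_allele(pair, ladder[locus_name], rng)
                        if fa is not None:
                            obs[int(rng.integers(2))] = fa
                            truth.error_events.append(
                                {
                                    "sample": sid,
                                    "locus": locus_name,
                                    "rep": r,
                                    "type": "fa",
                                    "allele": fa,
                                }
                            )
                    rep_list.append((min(obs), max(obs)))
            reps.replicates[locus_name] = rep_list
        out.append(reps)
    return out


def simulate_sex_replicates(
    sexes: dict[str, str], cfg: SimConfig, n_replicates: int = 3
) -> dict[str, list[frozenset]]:
    """Amelogenin band patterns: males {X, Y} with Y-dropout at ado_rate,
    females {X} always."""
    rng = _rng(cfg.seed + 15_485_863)
    out = {}
    for sid, sex in sexes.items():
        reps = []
        for _ in range(n_replicates):
            if sex == "male":
                reps.append(
                    frozenset({"X"}) if rng.random() < cfg.ado_rate else frozenset({"X", "Y"})
                )
            else:
                reps.append(frozenset({"X"}))
        out[sid] = reps
    return out


def simulate_study(
    cfg: SimConfig,
) -> tuple[GenotypeMatrix, GenotypeMatrix, list[ReplicateSet], SimTruth]:
    """Reference + queries + replicate data in one call."""
    refs, truth = simulate_reference(cfg)
    queries, truth = simulate_queries(cfg, truth, refs)
    reps = simulate_replicates(queries, cfg, truth)
    return refs, queries, reps, truth
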