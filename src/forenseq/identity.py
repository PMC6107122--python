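"""Individual identification and population-differentiation statistics.

Covers four tasks around a microsatellite reference database:

* profile matching between query and reference genotypes (exact or
  near-exact multi-locus matches identify re-sampled individuals);
* probability of identity, the chance that two individuals share a
  multi-locus genotype: unrelated individuals
  ``PID = 2(sum p_i^2)^2 - sum p_i^4`` per locus, and the conservative
  full-sibling variant
  ``PIDsib = 0.25 + 0.5*sum p_i^2 + 0.5*(sum p_i^2)^2 - 0.25*sum p_i^4``,
  multiplied over loci;
* Weir & Cockerham's theta (F_ST) from multi-allelic genotypes, variance
  components summed over alleles and loci;
* Nei's (1972) standard genetic distance between individuals (per-individual
  allele frequencies in {0, 0.5, 1}) with average-linkage (UPGMA) clustering
  for outlier screening.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .genotypes import MISSING, AlleleFreqTable, GenotypeMatrix

__all__ = [
    "MatchHit",
    "MatchResult",
    "IdentityStats",
    "DistanceMatrix",
    "match_genotypes",
    "probability_of_identity",
    "fst_weir_cockerham",
    "nei_distance_individuals",
    "upgma",
]

INF_DISTANCE = float("inf")


# ---------------------------------------------------------------------------
# Matching
# ---------------------------------------------------------------------------


@dataclass
class MatchHit:
    reference: str
    loci_compared: int
    mismatches: int


@dataclass
class MatchResult:
    query: str
    hits: list[MatchHit] = field(default_factory=list)


def match_genotypes(
    queries: GenotypeMatrix,
    refs: GenotypeMatrix,
    max_mismatch: int = 0,
    min_loci: int = 6,
) -> list[MatchResult]:
    """Report every (query, reference) pair matching at >= min_loci loci.

    Loci are compared by name; only loci non-missing in both profiles
    count.  A hit requires at least ``min_loci`` comparable loci and at
    most ``max_mismatch`` disagreeing loci (unordered pair equality).
    """
    shared = [n for n in queries.locus_names if n in refs.locus_names]
    if not shared:
        raise ValueError("query and reference share no loci")
    q = queries.subset(loci=shared)
    r = refs.subset(loci=shared)
    q_miss = q.missing_mask()
    r_miss = r.missing_mask()
    results = []
    for i, qs in enumerate(q.samples):
        res = MatchResult(qs)
        for k, rs in enumerate(r.samples):
            both = ~(q_miss[i] | r_miss[k])
            n_comp = int(both.sum())
            if n_comp < min_loci:
                continue
            mism = int(
                (~(q.calls[i, both] == r.calls[k, both]).all(axis=1)).sum()
            )
            if mism <= max_mismatch:
                res.hits.append(MatchHit(rs, n_comp, mism))
        results.append(res)
    return results


# ---------------------------------------------------------------------------
# Probability of identity
# ---------------------------------------------------------------------------


@dataclass
class IdentityStats:
    pid: float
    pid_sibs: float
    per_locus: dict[str, tuple[float, float]]
    uninformative_loci: list[str] = field(default_factory=list)


def _pid_locus(p: np.ndarray) -> tuple[float, float]:
    s2 = float(np.sum(p**2))
    s4 = float(np.sum(p**4))
    pid = 2.0 * s2**2 - s4
    pid_sib = 0.25 + 0.5 * s2 + 0.5 * s2**2 - 0.25 * s4
    return pid, pid_sib


def probability_of_identity(
    freqs: AlleleFreqTable,
    loci: list[str] | None = None,
    pop: str | None = None,
) -> IdentityStats:
    """Multi-locus PID and PID(sibs) from reference allele frequencies.

    ``pop`` selects which population's frequencies to use (default: the
    only/first population in the table).  Monomorphic loci contribute 1 and
    are flagged uninformative rather than dropped.
    """
    if pop is None:
        pops = freqs.populations
        if not pops:
            raise ValueError("empty frequency table")
        pop = pops[0]
    table = freqs.freqs.get(pop, {})
    if loci is None:
        loci = list(table)
    per_locus: dict[str, tuple[float, float]] = {}
    uninformative = []
    for name in loci:
        if name not in table:
            raise ValueError(f"no frequencies for locus {name!r} in population {pop!r}")
        p = np.array(list(table[name].values()))
        pid, pid_sib = _pid_locus(p)
        per_locus[name] = (pid, pid_sib)
        if len(p) < 2:
            uninformative.append(name)
    pid = float(np.prod([v[0] for v in per_locus.values()])) if per_locus else 1.0
    sib = float(np.prod([v[1] for v in per_locus.values()])) if per_locus else 1.0
    return IdentityStats(pid, sib, per_locus, uninformative)


# ---------------------------------------------------------------------------
# Weir & Cockerham theta
# ---------------------------------------------------------------------------


def fst_weir_cockerham(
    g: GenotypeMatrix, pops: tuple[str, str] | list[str] | None = None
) -> float:
    """Multi-allelic Weir-Cockerham theta over the named populations.

    Variance components a (among populations), b (among individuals within
    populations) and c (within individuals) are computed per allele per
    locus from sample sizes, allele frequencies and observed heterozygote
    frequencies, then summed: theta = sum(a) / sum(a + b + c).  Returns 0
    with a warning when there is no variation at all.
    """
    import warnings

    if pops is None:
        pops = g.populations()
    pops = list(pops)
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    idx_by_pop = [
        [i for i in range(g.n_samples) if g.pop_known[i] and g.pop_labels[i] == p]
        for p in pops
    ]
    r = len(pops)
    A_sum = 0.0
    ABC_sum = 0.0
    for j in range(g.n_loci):
        calls = g.calls[:, j, :]
        pop_calls = []
        for idx in idx_by_pop:
            sub = calls[idx]
            sub = sub[sub[:, 0] != MISSING]
            pop_calls.append(sub)
        n = np.array([len(s) for s in pop_calls], dtype=float)
        if (n < 2).any():
            continue  # spec requires >=2 genotyped individuals per pop
        alleles = sorted(set(int(a) for s in pop_calls for a in s.ravel()))
        if len(alleles) < 2:
            continue
        nbar = n.mean()
        nc = (r * nbar - (n**2).sum() / (r * nbar)) / (r - 1)
        for allele in alleles:
            p_i = np.array(
                [np.mean(s == allele) for s in pop_calls]
            )  # freq of allele per pop (mean over 2n entries)
            h_i = np.array(
                [
                    np.mean((s == allele).sum(axis=1) == 1) if len(s) else 0.0
                    for s in pop_calls
                ]
            )  # observed heterozygote freq for this allele
            pbar = (n * p_i).sum() / (r * nbar)
            s2 = (n * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
            hbar = (n * h_i).sum() / (r * nbar)
            a = (nbar / nc) * (
                s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
            )
            b = (nbar / (nbar - 1)) * (
                pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
            )
            c = hbar / 2
            A_sum += a
            ABC_sum += a + b + c
    if ABC_sum == 0.0:
        warnings.warn("no allelic variation between populations; theta set to 0")
        return 0.0
    return A_sum / ABC_sum


# ---------------------------------------------------------------------------
# Nei distance between individuals + UPGMA
# ---------------------------------------------------------------------------


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray
    meta: dict[str, str | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape mismatch")
        finite = v[np.isfinite(v)]
        if not np.allclose(v[np.isfinite(v)], v.T[np.isfinite(v.T)]):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix diagonal not zero")
        self.values = v

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])


def nei_distance_individuals(g: GenotypeMatrix) -> DistanceMatrix:
    """Nei's (1972) standard distance between individual profiles.

    Each individual is treated as a 'population' whose allele frequencies
    take values 0, 0.5 or 1.  D = -ln( Jxy / sqrt(Jx * Jy) ), with the J
    homozygosity/identity sums accumulated over loci and alleles; loci
    missing in either member of a pair are dropped for that pair.  Profiles
    sharing no alleles anywhere (Jxy = 0) get an infinite-distance sentinel.
    """
    n = g.n_samples
    if n < 2:
        raise ValueError("need at least two individuals")
    miss = g.missing_mask()
    d = np.zeros((n, n))
    # per-locus frequency dictionaries per individual
    profiles: list[list[dict[int, float] | None]] = []
    for i in range(n):
        row: list[dict[int, float] | None] = []
        for j in range(g.n_loci):
            if miss[i, j]:
                row.append(None)
                continue
            a, b = (int(x) for x in g.calls[i, j])
            row.append({a: 1.0} if a == b else {a: 0.5, b: 0.5})
        profiles.append(row)
    for i in range(n):
        for k in range(i + 1, n):
            jxy = jx = jy = 0.0
            shared = False
            for j in range(g.n_loci):
                fi, fk = profiles[i][j], profiles[k][j]
                if fi is None or fk is None:
                    continue
                shared = True
                jx += sum(v * v for v in fi.values())
                jy += sum(v * v for v in fk.values())
                jxy += sum(fi[a] * fk.get(a, 0.0) for a in fi)
            if not shared or jxy == 0.0:
                dist = INF_DISTANCE
            else:
                dist = -math.log(jxy / math.sqrt(jx * jy))
                dist = max(dist, 0.0)
            d[i, k] = d[k, i] = dist
    labels = list(g.samples)
    meta = {s: g.pop_labels[i] for i, s in enumerate(labels)}
    return DistanceMatrix(labels, d, meta)


def upgma(d: DistanceMatrix) -> str:
    """Average-linkage (UPGMA) tree as a newick string with branch lengths.

    Infinite distances are replaced by 1.5x the largest finite entry (with
    a warning).  Ties in the minimum pair are broken by the lexicographic
    order of the clusters' smallest labels, so output is deterministic.
    The result is rooted and ultrametric.
    """
    import warnings

    n = len(d.labels)
    if n < 2:
        raise ValueError("need at least two leaves")
    dist = d.values.copy()
    if np.isinf(dist).any():
        finite = dist[np.isfinite(dist)]
        cap = (finite.max() if finite.size else 1.0) * 1.5
        warnings.warn(f"infinite distances replaced by {cap:g} for clustering")
        dist[np.isinf(dist)] = cap

    clusters: dict[int, dict] = {
        i: {"newick": d.labels[i], "size": 1, "height": 0.0, "min_label": d.labels[i]}
        for i in range(n)
    }
    dmat = {(i, k): dist[i, k] for i in range(n) for k in range(i + 1, n)}
    next_id = n
    while len(clusters) > 1:
        # minimum pair; ties by lexicographic (min_label_i, min_label_k)
        best = None
        for (i, k), val in dmat.items():
            key = (
                val,
                *sorted((clusters[i]["min_label"], clusters[k]["min_label"])),
            )
            if best is None or key < best[0]:
                best = (key, i, k)
        _, i, k = best
        ci, ck = clusters.pop(i), clusters.pop(k)
        dmat.pop((min(i, k), max(i, k)))
        height = best[0][0] / 2.0
        # deterministic child order in the newick (does not affect linkage)
        cl, cr = sorted((ci, ck), key=lambda c: c["min_label"])
        bl = height - cl["height"]
        br = height - cr["height"]
        merged = {
            "newick": f"({cl['newick']}:{bl:.10g},{cr['newick']}:{br:.10g})",
            "size": ci["size"] + ck["size"],
            "height": height,
            "min_label": cl["min_label"],
        }
        new_d: dict[int, float] = {}
        for m in clusters:
            dmi = dmat.pop((min(i, m), max(i, m)))
            dmk = dmat.pop((min(k, m), max(k, m)))
            new_d[m] = (ci["size"] * dmi + ck["size"] * dmk) / merged["size"]
        clusters[next_id] = merged
        for m, val in new_d.items():
            dmat[(min(next_id, m), max(next_id, m))] = val
        next_id += 1
    root = next(iter(clusters.values()))
    return root["newick"] + ";"
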