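"""Matching, probability of identity, F_ST, Nei distance and UPGMA."""

import math
from itertools import product

import numpy as np
import pytest

from forenseq.genotypes import GenotypeMatrix, allele_frequencies
from forenseq.identity import (
    DistanceMatrix,
    fst_weir_cockerham,
    match_genotypes,
    nei_distance_individuals,
    probability_of_identity,
    upgma,
)
from forenseq.simulate import SimConfig, simulate_queries, simulate_reference


# ---------------------------------------------------------------------------
# Matching
# ---------------------------------------------------------------------------


class TestMatching:
    def _db(self):
        loci = [f"L{j}" for j in range(8)]
        base = {l: (150 + 4 * j, 154 + 4 * j) for j, l in enumerate(loci)}
        refs = GenotypeMatrix.from_calls(
            {"r1": base, "r2": {l: (v[0], v[0]) for l, v in base.items()}},
            pop_labels={"r1": "p", "r2": "p"},
        )
        return loci, base, refs

    def test_identical_profile_single_hit(self):
        _, base, refs = self._db()
        q = GenotypeMatrix.from_calls({"q": dict(base)})
        res = match_genotypes(q, refs)
        assert [h.reference for h in res[0].hits] == ["r1"]
        assert res[0].hits[0].mismatches == 0
        assert res[0].hits[0].loci_compared == 8

    def test_one_locus_difference_rejected_at_zero(self):
        loci, base, refs = self._db()
        q_calls = dict(base)
        q_calls[loci[0]] = (150, 150)
        q = GenotypeMatrix.from_calls({"q": q_calls})
        assert match_genotypes(q, refs, max_mismatch=0)[0].hits == []
        assert [h.reference for h in match_genotypes(q, refs, max_mismatch=1)[0].hits] == ["r1"]

    def test_min_loci_excludes_sparse_queries(self):
        loci, base, refs = self._db()
        q_calls = {l: (base[l] if j < 5 else None) for j, l in enumerate(loci)}
        q = GenotypeMatrix.from_calls({"q": q_calls}, locus_order=loci)
        assert match_genotypes(q, refs, min_loci=6)[0].hits == []
        assert match_genotypes(q, refs, min_loci=5)[0].hits != []

    def test_no_shared_loci_error(self):
        _, base, refs = self._db()
        q = GenotypeMatrix.from_calls({"q": {"X1": (1, 2)}})
        with pytest.raises(ValueError, match="no loci"):
            match_genotypes(q, refs)

    def test_planted_duplicate_recovered_exactly(self):
        """One planted re-sample in a 120-individual database is the only hit."""
        cfg = SimConfig(seed=5, n_per_pop=40, n_queries=1, duplicate_fraction=1.0)
        refs, truth = simulate_reference(cfg)
        queries, truth = simulate_queries(cfg, truth, refs)
        res = match_genotypes(queries, refs)
        (dup_query, dup_source), = truth.duplicate_map.items()
        assert res[0].query == dup_query
        assert [h.reference for h in res[0].hits] == [dup_source]

    def test_reflexive_and_symmetric_at_zero_mismatch(self):
        _, _, refs = self._db()
        res = match_genotypes(refs, refs)
        for r in res:
            assert r.query in [h.reference for h in r.hits]
        hits_ab = {
            (r.query, h.reference) for r in res for h in r.hits if r.query != h.reference
        }
        assert all((b, a) in hits_ab for a, b in hits_ab)


# ---------------------------------------------------------------------------
# Probability of identity
# ---------------------------------------------------------------------------


def _pid_enumeration(p: np.ndarray) -> float:
    """Sum over unordered genotypes of P(g)^2 under HWE."""
    k = len(p)
    tot = 0.0
    for i in range(k):
        for j in range(i, k):
            pg = p[i] ** 2 if i == j else 2 * p[i] * p[j]
            tot += pg * pg
    return tot


def _pidsib_enumeration(p: np.ndarray) -> float:
    """Enumerate parental genotypes; sibs draw one allele from each parent."""
    k = len(p)
    tot = 0.0
    for gm in product(range(k), repeat=2):
        pm = p[gm[0]] * p[gm[1]]
        for gf in product(range(k), repeat=2):
            pf = p[gf[0]] * p[gf[1]]
            off: dict[tuple[int, int], float] = {}
            for a in gm:
                for b in gf:
                    key = (min(a, b), max(a, b))
                    off[key] = off.get(key, 0.0) + 0.25
            tot += pm * pf * sum(v * v for v in off.values())
    return tot


class TestProbabilityOfIdentity:
    def _freq_table(self, freqs_by_locus):
        calls = {}
        # build a table directly rather than through genotypes
        from forenseq.genotypes import AlleleFreqTable

        t = AlleleFreqTable()
        t.freqs["pop"] = {}
        t.gene_copies["pop"] = {}
        for name, p in freqs_by_locus.items():
            t.freqs["pop"][name] = {100 + 4 * i: float(x) for i, x in enumerate(p)}
            t.gene_copies["pop"][name] = 100
            t.dataset_alleles[name] = tuple(t.freqs["pop"][name])
        return t

    def test_two_allele_closed_form(self):
        t = self._freq_table({"L1": [0.5, 0.5]})
        s = probability_of_identity(t)
        assert s.pid == pytest.approx(0.375)
        assert s.pid_sibs == pytest.approx(0.59375)

    def test_monomorphic_locus_is_one_and_flagged(self):
        t = self._freq_table({"L1": [1.0]})
        s = probability_of_identity(t)
        assert s.pid == 1.0 and s.pid_sibs == 1.0
        assert s.uninformative_loci == ["L1"]

    def test_multilocus_is_product(self):
        t = self._freq_table({"L1": [0.5, 0.5], "L2": [0.2, 0.3, 0.5]})
        s = probability_of_identity(t)
        assert s.pid == pytest.approx(s.per_locus["L1"][0] * s.per_locus["L2"][0])

    def test_matches_enumeration_oracle(self):
        """Closed forms equal exhaustive enumeration for random vectors."""
        rng = np.random.default_rng(9)
        for _ in range(20):
            k = int(rng.integers(2, 8))
            p = rng.dirichlet(np.ones(k))
            t = self._freq_table({"L1": p})
            s = probability_of_identity(t)
            assert s.pid == pytest.approx(_pid_enumeration(p), rel=1e-12)
            assert s.pid_sibs == pytest.approx(_pidsib_enumeration(p), rel=1e-12)

    def test_monotone_nonincreasing_in_loci_and_pid_le_sibs(self):
        rng = np.random.default_rng(11)
        freqs = {f"L{j}": rng.dirichlet(np.ones(6)) for j in range(8)}
        t = self._freq_table(freqs)
        names = list(freqs)
        prev_pid, prev_sib = 1.0, 1.0
        for n in range(1, 9):
            s = probability_of_identity(t, loci=names[:n])
            assert s.pid <= prev_pid + 1e-15
            assert s.pid_sibs <= prev_sib + 1e-15
            assert s.pid <= s.pid_sibs <= 1.0
            prev_pid, prev_sib = s.pid, s.pid_sibs


# ---------------------------------------------------------------------------
# Weir-Cockerham theta
# ---------------------------------------------------------------------------


class TestFst:
    def test_identical_populations_near_zero(self):
        rng = np.random.default_rng(0)
        calls = {}
        pops = {}
        for i in range(20):
            row = {f"L{j}": tuple(sorted(rng.choice([100, 104, 108], 2))) for j in range(6)}
            calls[f"a{i}"] = row
            calls[f"b{i}"] = dict(row)
            pops[f"a{i}"] = "p1"
            pops[f"b{i}"] = "p2"
        g = GenotypeMatrix.from_calls(calls, pop_labels=pops)
        assert abs(fst_weir_cockerham(g)) < 0.05

    def test_fixed_alternative_alleles_is_one(self):
        calls = {}
        pops = {}
        for i in range(10):
            calls[f"a{i}"] = {f"L{j}": (100, 100) for j in range(4)}
            calls[f"b{i}"] = {f"L{j}": (120, 120) for j in range(4)}
            pops[f"a{i}"] = "p1"
            pops[f"b{i}"] = "p2"
        g = GenotypeMatrix.from_calls(calls, pop_labels=pops)
        assert fst_weir_cockerham(g) == pytest.approx(1.0)

    def test_no_variation_warns_and_returns_zero(self):
        calls = {f"s{i}": {"L1": (100, 100)} for i in range(6)}
        pops = {f"s{i}": "p1" if i < 3 else "p2" for i in range(6)}
        g = GenotypeMatrix.from_calls(calls, pop_labels=pops)
        with pytest.warns(UserWarning, match="no allelic variation"):
            assert fst_weir_cockerham(g) == 0.0

    def test_balding_nichols_recovery(self):
        """theta-hat falls in the frozen central 95% simulation interval.

        Interval [0.115, 0.190] computed from 50 independent generator
        datasets at F=0.15, n=100/pop, 8 loci.
        """
        refs, _ = simulate_reference(SimConfig(seed=13, n_per_pop=100, fst=0.15))
        theta = fst_weir_cockerham(refs)
        assert 0.115 <= theta <= 0.190


# ---------------------------------------------------------------------------
# Nei distance + UPGMA
# ---------------------------------------------------------------------------


class TestNeiDistance:
    def test_identical_profiles_zero(self):
        g = GenotypeMatrix.from_calls(
            {"a": {"L1": (1, 2), "L2": (3, 3)}, "b": {"L1": (1, 2), "L2": (3, 3)}}
        )
        d = nei_distance_individuals(g)
        assert d.get("a", "b") == pytest.approx(0.0)

    def test_disjoint_profiles_infinite(self):
        g = GenotypeMatrix.from_calls({"a": {"L1": (1, 2)}, "b": {"L1": (3, 4)}})
        assert math.isinf(nei_distance_individuals(g).get("a", "b"))

    def test_three_individual_hand_computation(self):
        # a: het 1/2, b: hom 1/1 at one locus
        # Jx = 0.5, Jy = 1, Jxy = 0.5 -> D = -ln(0.5/sqrt(0.5)) = ln(sqrt(2))
        g = GenotypeMatrix.from_calls(
            {"a": {"L1": (1, 2)}, "b": {"L1": (1, 1)}, "c": {"L1": (2, 2)}}
        )
        d = nei_distance_individuals(g)
        assert d.get("a", "b") == pytest.approx(0.5 * math.log(2))
        assert d.get("a", "c") == pytest.approx(0.5 * math.log(2))
        assert math.isinf(d.get("b", "c"))

    def test_missing_loci_dropped_pairwise(self):
        g = GenotypeMatrix.from_calls(
            {
                "a": {"L1": (1, 2), "L2": (5, 6)},
                "b": {"L1": (1, 2), "L2": None},
            }
        )
        assert nei_distance_individuals(g).get("a", "b") == pytest.approx(0.0)

    def test_single_individual_rejected(self):
        g = GenotypeMatrix.from_calls({"a": {"L1": (1, 2)}})
        with pytest.raises(ValueError, match="two individuals"):
            nei_distance_individuals(g)


class TestUpgma:
    def test_two_leaves_closed_form(self):
        d = DistanceMatrix(["A", "B"], np.array([[0, 0.4], [0.4, 0]]))
        assert upgma(d) == "(A:0.2,B:0.2);"

    def test_minimum_pair_joins_first(self):
        m = np.array([[0, 0.2, 0.8], [0.2, 0, 0.9], [0.8, 0.9, 0]])
        nwk = upgma(DistanceMatrix(["A", "B", "C"], m))
        assert nwk.startswith("((A:0.1,B:0.1)")

    def test_matches_scipy_average_linkage(self):
        """Cophenetic distances equal scipy's 'average' linkage (oracle)."""
        from scipy.cluster.hierarchy import cophenet, linkage
        from scipy.spatial.distance import squareform
        import dendropy

        rng = np.random.default_rng(2)
        n = 8
        m = np.zeros((n, n))
        iu = np.triu_indices(n, 1)
        m[iu] = rng.uniform(0.1, 1.0, size=len(iu[0]))
        m = m + m.T
        labels = [f"T{i}" for i in range(n)]
        nwk = upgma(DistanceMatrix(labels, m))
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        mine = np.array(
            [
                [0.0 if i == j else pdm.distance(taxa[labels[i]], taxa[labels[j]]) for j in range(n)]
                for i in range(n)
            ]
        )
        coph = squareform(cophenet(linkage(squareform(m), method="average")))
        assert np.abs(mine - coph).max() < 1e-9

    def test_ultrametric_output(self):
        import dendropy

        rng = np.random.default_rng(3)
        n = 7
        m = np.zeros((n, n))
        iu = np.triu_indices(n, 1)
        m[iu] = rng.uniform(0.1, 1.0, size=len(iu[0]))
        m = m + m.T
        nwk = upgma(DistanceMatrix([f"T{i}" for i in range(n)], m))
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        depths = [leaf.distance_from_root() for leaf in tree.leaf_node_iter()]
        assert max(depths) - min(depths) < 1e-9

    def test_infinite_distances_capped_with_warning(self):
        m = np.array([[0, np.inf, 0.4], [np.inf, 0, 0.4], [0.4, 0.4, 0]])
        with pytest.warns(UserWarning, match="infinite"):
            nwk = upgma(DistanceMatrix(["A", "B", "C"], m))
        assert nwk.endswith(";")

    def test_single_leaf_rejected(self):
        with pytest.raises(ValueError, match="two leaves"):
            upgma(DistanceMatrix(["A"], np.zeros((1, 1))))
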