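"""Population-assignment engines for query genotypes.

Three independent estimators, all fit on a labelled reference
:class:`~forenseq.genotypes.GenotypeMatrix` and scoring query rows with a
normalised per-population membership in [0, 1]:

* :class:`FrequencyAssigner` — the frequency-based likelihood: per
  population, the product over loci of the Hardy-Weinberg genotype
  probability (``2 p_a p_b`` heterozygote, ``p_a^2`` homozygote) from the
  population's observed allele frequencies, with alleles unobserved in
  that population floored at a small frequency and the vector renormalised.
* :class:`BayesianAssigner` — the Dirichlet posterior-predictive
  likelihood: a symmetric Dirichlet(1/k) prior per locus (k = number of
  alleles observed dataset-wide) is updated with the population's allele
  counts, and the query genotype's posterior-predictive probability is
  multiplied over loci.
* :class:`DAPC` — discriminant analysis of principal components:
  individuals are dummy-encoded as per-allele relative frequencies
  (0/0.5/1), centred, reduced by PCA, and separated by linear discriminant
  analysis; query membership is a Gaussian posterior from squared
  Mahalanobis distances to group means under the pooled within-group
  covariance (uniform priors).

All estimators expose ``fit`` / ``predict`` / ``predict_proba`` /
``get_params`` / ``set_params`` and fitted attributes with trailing
underscores, so they compose with scikit-learn model selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .genotypes import MISSING, AlleleFreqTable, GenotypeMatrix, allele_frequencies

__all__ = [
    "PopScores",
    "FrequencyAssigner",
    "BayesianAssigner",
    "DAPC",
    "assign_frequency",
    "assign_bayesian",
    "dapc_fit",
    "dapc_predict",
]


@dataclass
class PopScores:
    """Normalised per-population membership scores for one sample."""

    sample: str
    method: str  # frequency | bayesian | dapc | structure_q
    scores: dict[str, float]
    log_likelihoods: dict[str, float] = field(default_factory=dict)

    def best(self) -> tuple[str, float]:
        pop = max(self.scores, key=self.scores.get)
        return pop, self.scores[pop]

    def __post_init__(self) -> None:
        total = sum(self.scores.values())
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"scores sum to {total}, expected 1")


def _check_query_loci(g: GenotypeMatrix) -> None:
    if g.missing_mask().all():
        raise ValueError("query genotype entirely missing")


def _normalise(loglik: dict[str, float]) -> dict[str, float]:
    pops = list(loglik)
    arr = np.array([loglik[p] for p in pops])
    norm = np.exp(arr - logsumexp(arr))
    norm = norm / norm.sum()
    return {p: float(v) for p, v in zip(pops, norm)}


# ---------------------------------------------------------------------------
# Frequency-based likelihood
# ---------------------------------------------------------------------------


class FrequencyAssigner:
    """Frequency-based assignment likelihood.

    Parameters
    ----------
    missing_allele_freq : float
        Floor applied to any allele unobserved in a candidate population;
        the population's frequency vector is renormalised after flooring so
        a query allele absent from the reference never zeroes the
        likelihood.
    """

    def __init__(self, missing_allele_freq: float = 0.01) -> None:
        self.missing_allele_freq = missing_allele_freq

    def get_params(self, deep: bool = True) -> dict:
        return {"missing_allele_freq": self.missing_allele_freq}

    def set_params(self, **params) -> "FrequencyAssigner":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, refs: GenotypeMatrix) -> "FrequencyAssigner":
        self.freqs_ = allele_frequencies(refs, by_pop=True)
        self.classes_ = self.freqs_.populations
        if not self.classes_:
            raise ValueError("reference matrix has no labelled populations")
        # floored + renormalised frequency vectors per (pop, locus)
        self.floored_: dict[str, dict[str, dict[int, float]]] = {}
        for pop in self.classes_:
            self.floored_[pop] = {}
            for locus, alleles in self.freqs_.dataset_alleles.items():
                if not self.freqs_.available(pop, locus):
                    continue
                v = np.array(
                    [self.freqs_.freq(pop, locus, a) for a in alleles], dtype=float
                )
                v[v == 0.0] = self.missing_allele_freq
                v = v / v.sum()
                self.floored_[pop][locus] = {a: float(x) for a, x in zip(alleles, v)}
        return self

    def predict_proba_one(self, row: GenotypeMatrix) -> PopScores:
        _check_query_loci(row)
        loglik: dict[str, float] = {}
        for pop in self.classes_:
            ll = 0.0
            for j, name in enumerate(row.locus_names):
                a, b = (int(x) for x in row.calls[0, j])
                if a == MISSING:
                    continue
                table = self.floored_.get(pop, {}).get(name)
                if table is None:
                    continue
                pa = table.get(a, self.missing_allele_freq)
                pb = table.get(b, self.missing_allele_freq)
                ll += np.log(pa * pa) if a == b else np.log(2.0 * pa * pb)
            loglik[pop] = ll
        return PopScores(row.samples[0], "frequency", _normalise(loglik), loglik)

    def predict_proba(self, queries: GenotypeMatrix) -> list[PopScores]:
        return [
            self.predict_proba_one(queries.subset(samples=[s])) for s in queries.samples
        ]

    def predict(self, queries: GenotypeMatrix) -> list[str]:
        return [ps.best()[0] for ps in self.predict_proba(queries)]


# ---------------------------------------------------------------------------
# Dirichlet posterior-predictive (Bayesian) likelihood
# ---------------------------------------------------------------------------


class BayesianAssigner:
    """Bayesian assignment via a Dirichlet(1/k) posterior-predictive.

    Per population and locus with allele counts ``n_a`` (total ``n``) and a
    symmetric prior of 1/k per allele (k alleles observed dataset-wide):

    * heterozygote {a,b}: ``2 (n_a + 1/k)(n_b + 1/k) / ((n+1)(n+2))``
    * homozygote {a,a}: ``(n_a + 1/k)(n_a + 1/k + 1) / ((n+1)(n+2))``

    multiplied over the query's non-missing loci and normalised across
    candidate populations.  An empty reference population falls back to the
    prior predictive.
    """

    def get_params(self, deep: bool = True) -> dict:
        return {}

    def set_params(self, **params) -> "BayesianAssigner":
        if params:
            raise ValueError(f"invalid parameters {sorted(params)!r}")
        return self

    def fit(self, refs: GenotypeMatrix) -> "BayesianAssigner":
        self.freqs_ = allele_frequencies(refs, by_pop=True)
        self.classes_ = self.freqs_.populations
        if not self.classes_:
            raise ValueError("reference matrix has no labelled populations")
        self.k_per_locus_ = {
            locus: max(len(alleles), 1)
            for locus, alleles in self.freqs_.dataset_alleles.items()
        }
        self.counts_: dict[str, dict[str, dict[int, int]]] = {
            pop: {
                locus: self.freqs_.counts(pop, locus)
                for locus in self.freqs_.dataset_alleles
                if self.freqs_.available(pop, locus)
            }
            for pop in self.classes_
        }
        return self

    def predict_proba_one(self, row: GenotypeMatrix) -> PopScores:
        _check_query_loci(row)
        loglik: dict[str, float] = {}
        for pop in self.classes_:
            ll = 0.0
            for j, name in enumerate(row.locus_names):
                a, b = (int(x) for x in row.calls[0, j])
                if a == MISSING or name not in self.k_per_locus_:
                    continue
                k = self.k_per_locus_[name]
                counts = self.counts_.get(pop, {}).get(name, {})
                n = sum(counts.values())
                na = counts.get(a, 0)
                prior = 1.0 / k
                if a == b:
                    prob = (na + prior) * (na + prior + 1.0) / ((n + 1.0) * (n + 2.0))
                else:
                    nb = counts.get(b, 0)
                    prob = 2.0 * (na + prior) * (nb + prior) / ((n + 1.0) * (n + 2.0))
                ll += np.log(prob)
            loglik[pop] = ll
        return PopScores(row.samples[0], "bayesian", _normalise(loglik), loglik)

    def predict_proba(self, queries: GenotypeMatrix) -> list[PopScores]:
        return [
            self.predict_proba_one(queries.subset(samples=[s])) for s in queries.samples
        ]

    def predict(self, queries: GenotypeMatrix) -> list[str]:
        return [ps.best()[0] for ps in self.predict_proba(queries)]


# ---------------------------------------------------------------------------
# DAPC
# ---------------------------------------------------------------------------


class DAPC:
    """Discriminant analysis of principal components.

    Parameters
    ----------
    n_pca : int, optional
        Number of principal axes retained.  Default: the smallest count
        reaching >=90% cumulative variance, capped at ``n_individuals // 3``.
    n_da : int, optional
        Number of discriminant axes (at most ``n_groups - 1``).

    Fitted attributes include the dummy-encoding column map, centring
    vector, PCA loadings, discriminant axes, per-group means and the pooled
    within-group covariance on discriminant space.  ``zero_within_variance_``
    flags perfectly separated (degenerate) groups, in which case the pooled
    covariance is pseudo-inverted.
    """

    def __init__(self, n_pca: int | None = None, n_da: int | None = None) -> None:
        self.n_pca = n_pca
        self.n_da = n_da

    def get_params(self, deep: bool = True) -> dict:
        return {"n_pca": self.n_pca, "n_da": self.n_da}

    def set_params(self, **params) -> "DAPC":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    # encoding ---------------------------------------------------------------

    def _encode(self, g: GenotypeMatrix, impute: str = "none") -> np.ndarray:
        cols = self.columns_
        X = np.full((g.n_samples, len(cols)), np.nan)
        col_index = {c: i for i, c in enumerate(cols)}
        for i in range(g.n_samples):
            for j, name in enumerate(g.locus_names):
                a, b = (int(x) for x in g.calls[i, j])
                if a == MISSING:
                    continue
                block = [c for c in self.locus_columns_.get(name, [])]
                for c in block:
                    X[i, col_index[c]] = 0.0
                for allele in (a, b):
                    key = (name, allele)
                    if key in col_index:
                        X[i, col_index[key]] += 0.5
        return X

    def fit(self, refs: GenotypeMatrix) -> "DAPC":
        pops = refs.populations()
        if len(pops) < 2:
            raise ValueError("DAPC needs at least two populations")
        labels = np.array(
            [refs.pop_labels[i] if refs.pop_known[i] else None for i in range(refs.n_samples)]
        )
        keep = [i for i in range(refs.n_samples) if labels[i] is not None]
        for pop in pops:
            if sum(1 for i in keep if labels[i] == pop) < 2:
                raise ValueError(f"population {pop!r} has fewer than 2 individuals")
        sub = refs.subset(samples=[refs.samples[i] for i in keep])
        y = np.array([sub.pop_labels[i] for i in range(sub.n_samples)])

        freqs = allele_frequencies(sub, by_pop=False)
        self.columns_: list[tuple[str, int]] = []
        self.locus_columns_: dict[str, list[tuple[str, int]]] = {}
        for locus, alleles in freqs.dataset_alleles.items():
            block = [(locus, a) for a in alleles]
            self.columns_.extend(block)
            self.locus_columns_[locus] = block
        X = self._encode(sub)
        # population-mean imputation of missing loci, then grand-mean fallback
        for pop in pops:
            rows = np.where(y == pop)[0]
            block = X[rows]
            col_mean = np.nanmean(np.where(np.isnan(block), np.nan, block), axis=0)
            col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
            nan_pos = np.isnan(block)
            block[nan_pos] = np.broadcast_to(col_mean, block.shape)[nan_pos]
            X[rows] = block
        self.grand_mean_impute_ = np.nanmean(X, axis=0)
        X = np.where(np.isnan(X), self.grand_mean_impute_, X)

        self.center_ = X.mean(axis=0)
        Xc = X - self.center_

        # PCA via SVD
        U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
        var = S**2
        nonzero = int((S > 1e-10).sum())
        if nonzero == 0:
            raise ValueError("reference data has no variation")
        if self.n_pca is None:
            cum = np.cumsum(var[:nonzero]) / var[:nonzero].sum()
            n_pca = int(np.searchsorted(cum, 0.90) + 1)
            n_pca = max(1, min(n_pca, sub.n_samples // 3, nonzero))
        else:
            n_pca = int(self.n_pca)
            if n_pca < 1 or n_pca > nonzero:
                raise ValueError(
                    f"n_pca={n_pca} outside the available range 1..{nonzero}"
                )
        self.n_pca_ = n_pca
        self.loadings_ = Vt[:n_pca].T  # (n_cols, n_pca)
        scores = Xc @ self.loadings_

        # LDA on retained PCA scores
        self.groups_ = pops
        n_da_max = len(pops) - 1
        n_da = n_da_max if self.n_da is None else min(int(self.n_da), n_da_max)
        if n_da < 1:
            raise ValueError("need at least one discriminant axis")
        overall = scores.mean(axis=0)
        Sw = np.zeros((n_pca, n_pca))
        Sb = np.zeros((n_pca, n_pca))
        for pop in pops:
            rows = scores[y == pop]
            mu = rows.mean(axis=0)
            centred = rows - mu
            Sw += centred.T @ centred
            dm = (mu - overall)[:, None]
            Sb += len(rows) * (dm @ dm.T)
        self.zero_within_variance_ = bool(np.allclose(Sw, 0.0))
        reg = Sw + 1e-9 * np.eye(n_pca) * max(np.trace(Sw) / n_pca, 1.0)
        eigvals, eigvecs = np.linalg.eig(np.linalg.solve(reg, Sb))
        order = np.argsort(eigvals.real)[::-1]
        self.discriminants_ = eigvecs.real[:, order[:n_da]]  # (n_pca, n_da)
        self.n_da_ = n_da
        da_scores = scores @ self.discriminants_

        self.group_means_ = {
            pop: da_scores[y == pop].mean(axis=0) for pop in pops
        }
        n_total = len(y)
        pooled = np.zeros((n_da, n_da))
        for pop in pops:
            rows = da_scores[y == pop] - self.group_means_[pop]
            pooled += rows.T @ rows
        denom = max(n_total - len(pops), 1)
        self.within_cov_ = pooled / denom
        if self.zero_within_variance_ or np.linalg.matrix_rank(self.within_cov_) < n_da:
            self.precision_ = np.linalg.pinv(self.within_cov_)
            self.zero_within_variance_ = True
        else:
            self.precision_ = np.linalg.inv(self.within_cov_)
        self.classes_ = pops
        return self

    def transform(self, g: GenotypeMatrix) -> np.ndarray:
        X = self._encode(g)
        X = np.where(np.isnan(X), self.grand_mean_impute_, X)
        return (X - self.center_) @ self.loadings_ @ self.discriminants_

    def predict_proba_one(self, row: GenotypeMatrix) -> PopScores:
        _check_query_loci(row)
        z = self.transform(row)[0]
        loglik = {}
        for pop in self.classes_:
            diff = z - self.group_means_[pop]
            loglik[pop] = float(-0.5 * diff @ self.precision_ @ diff)
        return PopScores(row.samples[0], "dapc", _normalise(loglik), loglik)

    def predict_proba(self, queries: GenotypeMatrix) -> list[PopScores]:
        return [
            self.predict_proba_one(queries.subset(samples=[s])) for s in queries.samples
        ]

    def predict(self, queries: GenotypeMatrix) -> list[str]:
        return [ps.best()[0] for ps in self.predict_proba(queries)]


# ---------------------------------------------------------------------------
# Functional wrappers
# ---------------------------------------------------------------------------


def assign_frequency(
    query: GenotypeMatrix,
    refs: GenotypeMatrix,
    missing_allele_freq: float = 0.01,
) -> list[PopScores]:
    return FrequencyAssigner(missing_allele_freq).fit(refs).predict_proba(query)


def assign_bayesian(query: GenotypeMatrix, refs: GenotypeMatrix) -> list[PopScores]:
    return BayesianAssigner().fit(refs).predict_proba(query)


def dapc_fit(
    refs: GenotypeMatrix, n_pca: int | None = None, n_da: int | None = None
) -> DAPC:
    return DAPC(n_pca=n_pca, n_da=n_da).fit(refs)


def dapc_predict(model: DAPC, query: GenotypeMatrix) -> list[PopScores]:
    return model.predict_proba(query)
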