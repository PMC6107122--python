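"""Bayesian admixture-model clustering of multi-allelic genotypes.

The model: each of K clusters has its own allele-frequency vector per
locus, drawn from a symmetric Dirichlet(lambda) prior (independent
frequencies across clusters); each individual i has admixture proportions
Q_i ~ Dirichlet(alpha, ..., alpha); each of the individual's 2L allele
copies chooses a cluster of origin z ~ Q_i and then an allele from that
cluster's frequencies.  A Gibbs sweep updates the latent origins Z, the
cluster frequencies P and the proportions Q from their conditionals, and
alpha by a Metropolis step with a uniform prior on (0, alpha_max].

In supervised mode, individuals with a known population keep Z fixed to
their labelled cluster so their allele copies anchor that cluster's
frequency updates; unknown (forensic) individuals are updated freely and
their posterior-mean Q is the membership score used for assignment.

Model selection across K uses the standard harmonic approximation
``L(K) = mean(lnL) - var(lnL)/2`` over retained sweeps, and the Evanno
second-difference statistic ``deltaK = mean_runs|L''(K)| / sd_runs(L(K))``.
Independent runs are label-aligned by exhaustive column permutation before
averaging.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import gammaln

from .genotypes import MISSING, GenotypeMatrix

__all__ = [
    "McmcOptions",
    "QMatrix",
    "DeltaKTable",
    "AdmixtureModel",
    "run_admixture",
    "run_admixture_replicates",
    "model_score",
    "evanno_delta_k",
    "align_runs",
]


@dataclass(frozen=True)
class McmcOptions:
    """Sampler controls.

    Defaults are desk-scale: 5,000 burn-in + 20,000 retained sweeps per
    chain; scale up for production runs.
    """

    k: int = 3
    burn_in: int = 5_000
    reps: int = 20_000
    n_runs: int = 10
    seed: int = 0
    alpha_init: float = 1.0
    alpha_max: float = 10.0
    alpha_proposal_sd: float = 0.05
    lambda_: float = 1.0
    supervised: bool = False
    thin: int = 10

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("K must be >= 1")
        if self.burn_in <= 0 or self.reps <= 0:
            raise ValueError("burn_in and reps must be positive")
        if self.lambda_ <= 0:
            raise ValueError("lambda must be positive")


@dataclass
class QMatrix:
    """Posterior-mean admixture proportions from one chain."""

    samples: list[str]
    q: np.ndarray  # (n_individuals, K), rows sum to 1
    cluster_labels: list[str]
    mean_loglik: float
    var_loglik: float
    loglik_trace: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def k(self) -> int:
        return self.q.shape[1]

    @property
    def model_score(self) -> float:
        return self.mean_loglik - self.var_loglik / 2.0


class AdmixtureModel:
    """Scikit-learn-style estimator wrapping one Gibbs chain.

    Parameters mirror :class:`McmcOptions`.  ``fit(g)`` runs the chain on a
    :class:`GenotypeMatrix`; fitted attributes:

    ``Q_`` : (n_samples, K) posterior-mean membership proportions
    ``loglik_trace_`` : retained-sweep log-likelihood values
    ``mean_loglik_``, ``var_loglik_``, ``model_score_``
    ``alpha_trace_`` : retained alpha values
    ``cluster_labels_`` : population names in supervised mode, else
    ``"cluster0"..``
    """

    def __init__(
        self,
        k: int = 3,
        burn_in: int = 5_000,
        reps: int = 20_000,
        alpha_init: float = 1.0,
        alpha_max: float = 10.0,
        alpha_proposal_sd: float = 0.05,
        lambda_: float = 1.0,
        supervised: bool = False,
        thin: int = 10,
        freq_model: str = "independent",
        random_state: int | None = None,
    ) -> None:
        self.freq_model = freq_model
        self.k = k
        self.burn_in = burn_in
        self.reps = reps
        self.alpha_init = alpha_init
        self.alpha_max = alpha_max
        self.alpha_proposal_sd = alpha_proposal_sd
        self.lambda_ = lambda_
        self.supervised = supervised
        self.thin = thin
        self.random_state = random_state

    # sklearn plumbing -------------------------------------------------------

    def get_params(self, deep: bool = True) -> dict:
        return {
            "freq_model": self.freq_model,
            "k": self.k,
            "burn_in": self.burn_in,
            "reps": self.reps,
            "alpha_init": self.alpha_init,
            "alpha_max": self.alpha_max,
            "alpha_proposal_sd": self.alpha_proposal_sd,
            "lambda_": self.lambda_,
            "supervised": self.supervised,
            "thin": self.thin,
            "random_state": self.random_state,
        }

    def set_params(self, **params) -> "AdmixtureModel":
        for key, val in params.items():
            if not hasattr(self, key):
                raise ValueError(f"invalid parameter {key!r}")
            setattr(self, key, val)
        return self

    # fitting ----------------------------------------------------------------

    def fit(self, g: GenotypeMatrix) -> "AdmixtureModel":
        if self.freq_model == "correlated":
            # F-model (drift-correlated cluster frequencies): extension point
            raise NotImplementedError(
                "the correlated-frequency (F) model is a planned extension; "
                "use freq_model='independent'"
            )
        if self.freq_model != "independent":
            raise ValueError(f"unknown freq_model {self.freq_model!r}")
        if g.n_samples == 0 or g.n_loci == 0:
            raise ValueError("empty genotype matrix")
        if self.k < 1:
            raise ValueError("K must be >= 1")
        rng = np.random.default_rng(self.random_state)
        K = self.k
        N, L = g.n_samples, g.n_loci

        # allele index encoding per locus
        allele_maps = []
        for j in range(L):
            obs = sorted(set(int(a) for a in g.calls[:, j, :].ravel() if a != MISSING))
            allele_maps.append({a: i for i, a in enumerate(obs)})
        n_alleles = np.array([max(len(m), 1) for m in allele_maps])
        Amax = int(n_alleles.max())
        X = np.full((N, L, 2), -1, dtype=np.int64)
        for j, amap in enumerate(allele_maps):
            for i in range(N):
                a, b = g.calls[i, j]
                if a != MISSING:
                    X[i, j, 0] = amap[int(a)]
                    X[i, j, 1] = amap[int(b)]
        obs_mask = X >= 0  # (N, L, 2)
        Xc = np.clip(X, 0, None)

        # supervised anchoring
        pops = g.populations()
        if self.supervised:
            if len(pops) > K:
                raise ValueError(
                    f"supervised mode: {len(pops)} labelled populations but K={K}"
                )
            cluster_labels = list(pops) + [
                f"cluster{c}" for c in range(len(pops), K)
            ]
            fixed = np.full(N, -1, dtype=np.int64)
            for i in range(N):
                if g.pop_known[i]:
                    fixed[i] = cluster_labels.index(g.pop_labels[i])
        else:
            cluster_labels = [f"cluster{c}" for c in range(K)]
            fixed = np.full(N, -1, dtype=np.int64)
        is_fixed = fixed >= 0

        if K == 1:
            self._finish_k1(g, rng, Xc, obs_mask, n_alleles, Amax, cluster_labels)
            return self

        # state init
        Z = rng.integers(0, K, size=(N, L, 2))
        Z[is_fixed] = fixed[is_fixed, None, None]
        alpha = float(self.alpha_init)
        Q = rng.dirichlet(np.ones(K), size=N)

        valid = np.zeros((L, Amax), dtype=bool)
        for j, na in enumerate(n_alleles):
            valid[j, :na] = True
        lgrid = np.broadcast_to(np.arange(L)[None, :, None], (N, L, 2))

        n_keep = self.reps // self.thin
        q_accum = np.zeros((N, K))
        n_accum = 0
        lnl_trace = np.zeros(n_keep)
        alpha_trace = np.zeros(n_keep)
        total = self.burn_in + self.reps

        def sample_P() -> np.ndarray:
            counts = np.zeros((K, L, Amax))
            np.add.at(
                counts,
                (Z[obs_mask], lgrid[obs_mask], Xc[obs_mask]),
                1.0,
            )
            shape = np.where(valid[None, :, :], self.lambda_ + counts, 0.0)
            gam = np.zeros_like(shape)
            pos = shape > 0
            gam[pos] = rng.gamma(shape[pos])
            tot = gam.sum(axis=2, keepdims=True)
            tot[tot == 0] = 1.0
            return gam / tot

        P = sample_P()
        kept = 0
        for sweep in range(total):
            # -- Z update (free individuals only)
            # w[i,l,c,k] = Q[i,k] * P[k, l, x]
            Pg = P[:, np.arange(L)[None, :, None], Xc]  # (K, N, L, 2)
            w = np.moveaxis(Pg, 0, -1) * Q[:, None, None, :]
            w_sum = w.sum(axis=-1, keepdims=True)
            w_sum[w_sum == 0] = 1.0
            cdf = np.cumsum(w / w_sum, axis=-1)
            u = rng.random(size=(N, L, 2, 1))
            Z_new = (cdf < u).sum(axis=-1)
            Z_new = np.minimum(Z_new, K - 1)
            Z = np.where(
                (is_fixed[:, None, None]) | (~obs_mask), Z, Z_new
            )
            Z[is_fixed] = fixed[is_fixed, None, None]

            # -- P update
            P = sample_P()

            # -- Q update
            cnt = np.zeros((N, K))
            np.add.at(
                cnt,
                (np.broadcast_to(np.arange(N)[:, None, None], (N, L, 2))[obs_mask], Z[obs_mask]),
                1.0,
            )
            gam = rng.gamma(alpha + cnt)
            Q = gam / gam.sum(axis=1, keepdims=True)
            Q = np.clip(Q, 1e-12, None)
            Q /= Q.sum(axis=1, keepdims=True)

            # -- alpha Metropolis update (free individuals only: label-fixed
            # reference rows have near-degenerate Q and would collapse alpha)
            alpha_prop = alpha + rng.normal(0.0, self.alpha_proposal_sd)
            n_free = int((~is_fixed).sum())
            if 0.0 < alpha_prop <= self.alpha_max and n_free > 0:
                logq_sum = float(np.log(Q[~is_fixed]).sum())
                cur = (
                    n_free * (gammaln(K * alpha) - K * gammaln(alpha))
                    + (alpha - 1) * logq_sum
                )
                prop = (
                    n_free * (gammaln(K * alpha_prop) - K * gammaln(alpha_prop))
                    + (alpha_prop - 1) * logq_sum
                )
                if np.log(rng.random()) < prop - cur:
                    alpha = float(alpha_prop)

            if sweep >= self.burn_in:
                s = sweep - self.burn_in
                q_accum += Q
                n_accum += 1
                if s % self.thin == 0 and kept < n_keep:
                    lnl_trace[kept] = self._loglik(Q, P, Xc, obs_mask)
                    alpha_trace[kept] = alpha
                    kept += 1

        self.Q_ = q_accum / max(n_accum, 1)
        self.Q_ /= self.Q_.sum(axis=1, keepdims=True)
        self.loglik_trace_ = lnl_trace[:kept]
        self.alpha_trace_ = alpha_trace[:kept]
        self.mean_loglik_ = float(self.loglik_trace_.mean())
        self.var_loglik_ = float(self.loglik_trace_.var())
        self.model_score_ = self.mean_loglik_ - self.var_loglik_ / 2.0
        self.cluster_labels_ = cluster_labels
        self.samples_ = list(g.samples)
        return self

    @staticmethod
    def _loglik(Q: np.ndarray, P: np.ndarray, Xc: np.ndarray, obs_mask: np.ndarray) -> float:
        L = P.shape[1]
        Pg = P[:, np.arange(L)[None, :, None], Xc]  # (K, N, L, 2)
        mix = np.einsum("ik,kilc->ilc", Q, Pg)
        mix = np.clip(mix, 1e-300, None)
        return float(np.log(mix[obs_mask]).sum())

    def _finish_k1(self, g, rng, Xc, obs_mask, n_alleles, Amax, cluster_labels) -> None:
        N, L = g.n_samples, g.n_loci
        n_keep = max(self.reps // self.thin, 1)
        trace = np.zeros(n_keep)
        valid = np.zeros((L, Amax), dtype=bool)
        for j, na in enumerate(n_alleles):
            valid[j, :na] = True
        counts = np.zeros((1, L, Amax))
        lgrid = np.broadcast_to(np.arange(L)[None, :, None], (N, L, 2))
        np.add.at(counts, (np.zeros(obs_mask.sum(), dtype=int), lgrid[obs_mask], Xc[obs_mask]), 1.0)
        Q = np.ones((N, 1))
        for s in range(n_keep):
            shape = np.where(valid[None], self.lambda_ + counts, 0.0)
            gam = np.zeros_like(shape)
            pos = shape > 0
            gam[pos] = rng.gamma(shape[pos])
            tot = gam.sum(axis=2, keepdims=True)
            tot[tot == 0] = 1.0
            P = gam / tot
            trace[s] = self._loglik(Q, P, Xc, obs_mask)
        self.Q_ = Q
        self.loglik_trace_ = trace
        self.alpha_trace_ = np.full(n_keep, self.alpha_init)
        self.mean_loglik_ = float(trace.mean())
        self.var_loglik_ = float(trace.var())
        self.model_score_ = self.mean_loglik_ - self.var_loglik_ / 2.0
        self.cluster_labels_ = cluster_labels
        self.samples_ = list(g.samples)

    def to_qmatrix(self) -> QMatrix:
        return QMatrix(
            samples=self.samples_,
            q=self.Q_.copy(),
            cluster_labels=list(self.cluster_labels_),
            mean_loglik=self.mean_loglik_,
            var_loglik=self.var_loglik_,
            loglik_trace=self.loglik_trace_.copy(),
        )


# ---------------------------------------------------------------------------
# Functional wrappers
# ---------------------------------------------------------------------------


def run_admixture(g: GenotypeMatrix, opts: McmcOptions) -> QMatrix:
    """Run one chain with the given options and return its QMatrix."""
    model = AdmixtureModel(
        k=opts.k,
        burn_in=opts.burn_in,
        reps=opts.reps,
        alpha_init=opts.alpha_init,
        alpha_max=opts.alpha_max,
        alpha_proposal_sd=opts.alpha_proposal_sd,
        lambda_=opts.lambda_,
        supervised=opts.supervised,
        thin=opts.thin,
        random_state=opts.seed,
    )
    return model.fit(g).to_qmatrix()


def run_admixture_replicates(g: GenotypeMatrix, opts: McmcOptions) -> list[QMatrix]:
    """Run ``opts.n_runs`` independent chains with per-run derived seeds."""
    runs = []
    for r in range(opts.n_runs):
        run_opts = replace(opts, seed=(opts.seed * 1_000 + 7 * r + 1) % (2**31 - 1))
        runs.append(run_admixture(g, run_opts))
    return runs


def model_score(run: QMatrix) -> float:
    """L(K) = mean(lnL) - var(lnL)/2 over retained sweeps."""
    return run.model_score


@dataclass
class DeltaKTable:
    ks: list[int]
    mean_l: dict[int, float]
    sd_l: dict[int, float]
    delta_k: dict[int, float | None]

    def best_k(self) -> int | None:
        defined = {k: v for k, v in self.delta_k.items() if v is not None}
        if not defined:
            return None
        return max(defined, key=defined.get)


def evanno_delta_k(scores: dict[int, list[float]]) -> DeltaKTable:
    """Evanno second-difference statistic from per-K, per-run L(K) values.

    deltaK(K) = mean over paired runs of |L(K+1) - 2 L(K) + L(K-1)| divided
    by the between-run sample SD of L(K); undefined (None) at the edges and
    wherever that SD is zero.
    """
    ks = sorted(scores)
    if len(ks) < 3:
        raise ValueError("need at least three consecutive K values")
    if any(len(scores[k]) < 2 for k in ks):
        raise ValueError("need >=2 runs per K for the between-run SD")
    if ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError("K values must be consecutive")
    mean_l = {k: float(np.mean(scores[k])) for k in ks}
    sd_l = {k: float(np.std(scores[k], ddof=1)) for k in ks}
    delta: dict[int, float | None] = {ks[0]: None, ks[-1]: None}
    n_runs = min(len(scores[k]) for k in ks)
    for k in ks[1:-1]:
        if sd_l[k] == 0.0:
            delta[k] = None
            continue
        second = [
            abs(scores[k + 1][r] - 2 * scores[k][r] + scores[k - 1][r])
            for r in range(n_runs)
        ]
        delta[k] = float(np.mean(second)) / sd_l[k]
    return DeltaKTable(ks, mean_l, sd_l, delta)


def align_runs(runs: list[QMatrix]) -> QMatrix:
    """Align label-switched chains to the first run and average.

    For each run after the first, the column permutation (exhaustive over
    K!) maximising the summed per-row dot product with the first run is
    applied; the aligned Q matrices are averaged element-wise and rows
    renormalised.
    """
    if not runs:
        raise ValueError("no runs to align")
    first = runs[0]
    K = first.k
    if K > 8:
        raise ValueError("exhaustive permutation alignment limited to K <= 8")
    for r in runs[1:]:
        if r.k != K or r.samples != first.samples:
            raise ValueError("runs differ in K or individual set")
    acc = first.q.copy()
    for r in runs[1:]:
        best_perm, best_score = None, -np.inf
        for perm in itertools.permutations(range(K)):
            score = float(np.sum(first.q * r.q[:, perm]))
            if score > best_score:
                best_perm, best_score = perm, score
        acc += r.q[:, best_perm]
    avg = acc / len(runs)
    avg /= avg.sum(axis=1, keepdims=True)
    return QMatrix(
        samples=list(first.samples),
        q=avg,
        cluster_labels=list(first.cluster_labels),
        mean_loglik=float(np.mean([r.mean_loglik for r in runs])),
        var_loglik=float(np.mean([r.var_loglik for r in runs])),
    )
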