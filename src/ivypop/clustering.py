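"""Bayesian admixture clustering with inbreeding, DIC model choice, and PCoA.

The model is a deliberately simplified relative of InStruct's admixture-
with-inbreeding MCMC, keeping the two features a highly selfing plant
requires — admixed ancestry *and* within-individual allele-copy correlation
— while dropping the subpopulation selfing-rate machinery:

* each individual i has admixture proportions q_i (Dirichlet(alpha) prior)
  and an inbreeding coefficient f_i in [0, 1] (uniform prior);
* at each SNP, with probability f_i the two allele copies are one draw from
  a single cluster of origin sampled from q_i (autozygous, so heterozygotes
  are impossible); otherwise the two copies have independent cluster
  origins from q_i and independent allele draws;
* cluster allele frequencies carry Beta(lambda, lambda) priors.

All updates are conjugate Gibbs draws (including f_i, via the autozygosity
indicators).  Model choice across K uses DIC = D-bar + pD with the
posterior-mean plug-in deviance.  With f_i fixed at 0 the likelihood
reduces exactly to the standard admixture model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from skbio import DistanceMatrix
from skbio.stats.ordination import pcoa as _skbio_pcoa

from .popdata import SnpMatrix

__all__ = [
    "AdmixtureInbreedingModel",
    "fit_clusters",
    "fit_k_range",
    "choose_k",
    "single_snp_per_locus_rerun",
    "align_clusters",
    "observed_loglik",
    "snp_distance_matrix",
    "pcoa",
    "PcoaResult",
]

_EPS = 1e-300


def _as_G(X) -> np.ndarray:
    if isinstance(X, SnpMatrix):
        return X.genotypes.astype(np.int8)
    return np.asarray(X, dtype=np.int8)


def observed_loglik(G: np.ndarray, Q: np.ndarray, P: np.ndarray,
                    f: np.ndarray) -> float:
    """Observed-data log-likelihood of dosage genotypes under the model."""
    pi = Q @ P  # (n, L) marginal allele-1 probability per copy
    f = f[:, None]
    lik2 = f * pi + (1 - f) * pi**2
    lik1 = (1 - f) * 2 * pi * (1 - pi)
    lik0 = f * (1 - pi) + (1 - f) * (1 - pi) ** 2
    ll = np.zeros_like(pi)
    for g, lik in ((0, lik0), (1, lik1), (2, lik2)):
        m = G == g
        ll[m] = np.log(np.clip(lik[m], _EPS, None))
    return float(ll[G >= 0].sum())


def _sample_categorical(W: np.ndarray, rng) -> np.ndarray:
    """One draw per row from unnormalized weights W (m, K)."""
    cum = np.cumsum(W, axis=1)
    u = rng.random(W.shape[0]) * cum[:, -1]
    return (cum < u[:, None]).sum(axis=1)


class AdmixtureInbreedingModel:
    """Gibbs sampler for the admixture-with-inbreeding model.

    Parameters
    ----------
    n_clusters : int
        Number of ancestral clusters K.
    n_iter, burn_in : int
        Total MCMC iterations and burn-in discarded from posterior means.
    n_chains : int
        Independent chains; the chain with the best mean posterior
        log-likelihood is kept and a Gelman–Rubin statistic on the
        log-likelihood traces flags non-convergence (> 1.2).
    allele_lambda, admixture_alpha : float
        Beta/Dirichlet hyperparameters for allele frequencies and admixture
        (alpha is fixed, not inferred).
    seed : int or Generator, optional

    Attributes (after ``fit``)
    --------------------------
    admixture_ : (n, K) posterior-mean admixture proportions (rows sum to 1)
    allele_freqs_ : (K, L, 2) posterior-mean allele probabilities
    inbreeding_ : (n,) posterior-mean f_i
    loglik_trace_ : per-iteration observed-data log-likelihood (kept chain)
    dic_, deviance_mean_, p_d_ : DIC decomposition
    gelman_rubin_ : float (NaN for a single chain)
    converged_ : bool
    """

    def __init__(self, n_clusters: int = 2, n_iter: int = 20000,
                 burn_in: int = 2000, n_chains: int = 1,
                 allele_lambda: float = 1.0, admixture_alpha: float = 1.0,
                 seed=None):
        self.n_clusters = n_clusters
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.n_chains = n_chains
        self.allele_lambda = allele_lambda
        self.admixture_alpha = admixture_alpha
        self.seed = seed

    # -- minimal sklearn estimator API ------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {
            "n_clusters": self.n_clusters, "n_iter": self.n_iter,
            "burn_in": self.burn_in, "n_chains": self.n_chains,
            "allele_lambda": self.allele_lambda,
            "admixture_alpha": self.admixture_alpha, "seed": self.seed,
        }

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def _run_chain(self, G, rng):
        n, L = G.shape
        K = self.n_clusters
        lam, alpha = self.allele_lambda, self.admixture_alpha

        het_i, het_l = np.nonzero(G == 1)
        h2_i, h2_l = np.nonzero(G == 2)
        h0_i, h0_l = np.nonzero(G == 0)
        hom_i = np.concatenate([h2_i, h0_i])
        n_nonmiss_hom = np.bincount(hom_i, minlength=n).astype(float)
        n_het_i = np.bincount(het_i, minlength=n).astype(float)

        Q = rng.dirichlet(np.full(K, alpha), size=n)
        P = rng.uniform(0.2, 0.8, size=(K, L))
        f = rng.uniform(size=n)

        trace = np.empty(self.n_iter)
        keep = self.n_iter - self.burn_in
        Q_sum = np.zeros_like(Q)
        P_sum = np.zeros_like(P)
        f_sum = np.zeros(n)
        dev_sum = 0.0

        for it in range(self.n_iter):
            # --- per-category origin weights (m, K)
            W_het1 = Q[het_i] * P[:, het_l].T
            W_het0 = Q[het_i] * (1.0 - P[:, het_l]).T
            W_h2 = Q[h2_i] * P[:, h2_l].T
            W_h0 = Q[h0_i] * (1.0 - P[:, h0_l]).T

            # --- autozygosity indicators for homozygous cells
            s2 = W_h2.sum(axis=1)
            s0 = W_h0.sum(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                pa2 = f[h2_i] * s2 / (f[h2_i] * s2 + (1 - f[h2_i]) * s2**2 + _EPS)
                pa0 = f[h0_i] * s0 / (f[h0_i] * s0 + (1 - f[h0_i]) * s0**2 + _EPS)
            a2 = rng.random(len(h2_i)) < pa2
            a0 = rng.random(len(h0_i)) < pa0

            # --- origin draws
            z_het1 = _sample_categorical(W_het1, rng) if len(het_i) else np.empty(0, int)
            z_het0 = _sample_categorical(W_het0, rng) if len(het_i) else np.empty(0, int)
            z2a = _sample_categorical(W_h2, rng) if len(h2_i) else np.empty(0, int)
            z2b = _sample_categorical(W_h2, rng) if len(h2_i) else np.empty(0, int)
            z0a = _sample_categorical(W_h0, rng) if len(h0_i) else np.empty(0, int)
            z0b = _sample_categorical(W_h0, rng) if len(h0_i) else np.empty(0, int)

            # copies actually drawn: autozygous homs contribute one copy
            one1_i = np.concatenate([het_i, h2_i, h2_i[~a2]])
            one1_l = np.concatenate([het_l, h2_l, h2_l[~a2]])
            one1_z = np.concatenate([z_het1, z2a, z2b[~a2]])
            one0_i = np.concatenate([het_i, h0_i, h0_i[~a0]])
            one0_l = np.concatenate([het_l, h0_l, h0_l[~a0]])
            one0_z = np.concatenate([z_het0, z0a, z0b[~a0]])

            # --- allele frequency update
            n1 = np.bincount(one1_z * L + one1_l, minlength=K * L).reshape(K, L)
            n0 = np.bincount(one0_z * L + one0_l, minlength=K * L).reshape(K, L)
            P = rng.beta(lam + n1, lam + n0)

            # --- admixture update
            oc = (
                np.bincount(one1_i * K + one1_z, minlength=n * K)
                + np.bincount(one0_i * K + one0_z, minlength=n * K)
            ).reshape(n, K)
            gam = rng.gamma(alpha + oc)
            Q = gam / gam.sum(axis=1, keepdims=True)

            # --- inbreeding update (conjugate Beta given indicators)
            n_auto = np.bincount(h2_i[a2], minlength=n) + np.bincount(h0_i[a0], minlength=n)
            n_non = n_nonmiss_hom - n_auto + n_het_i
            f = rng.beta(1.0 + n_auto, 1.0 + n_non)

            ll = observed_loglik(G, Q, P, f)
            trace[it] = ll
            if it >= self.burn_in:
                Q_sum += Q
                P_sum += P
                f_sum += f
                dev_sum += -2.0 * ll

        return {
            "Q": Q_sum / keep, "P": P_sum / keep, "f": f_sum / keep,
            "trace": trace, "dev_mean": dev_sum / keep,
        }

    def fit(self, X, y=None):
        G = _as_G(X)
        n, L = G.shape
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if self.n_clusters > n:
            raise ValueError(f"K = {self.n_clusters} exceeds {n} individuals")
        if self.n_iter <= self.burn_in:
            raise ValueError("n_iter must exceed burn_in")
        root = np.random.default_rng(self.seed) if not isinstance(self.seed, np.random.Generator) else self.seed
        chains = [self._run_chain(G, np.random.default_rng(root.integers(2**31)))
                  for _ in range(self.n_chains)]

        post = [c["trace"][self.burn_in:] for c in chains]
        if self.n_chains > 1:
            self.gelman_rubin_ = _gelman_rubin(post)
            self.converged_ = bool(self.gelman_rubin_ <= 1.2)
            if not self.converged_:
                warnings.warn(
                    f"chains not converged (Gelman-Rubin = {self.gelman_rubin_:.3f})"
                )
        else:
            self.gelman_rubin_ = float("nan")
            self.converged_ = True

        best = int(np.argmax([np.mean(p) for p in post]))
        ch = chains[best]
        self.admixture_ = ch["Q"]
        self.allele_freqs_ = np.stack([1.0 - ch["P"], ch["P"]], axis=-1)
        self.inbreeding_ = ch["f"]
        self.loglik_trace_ = ch["trace"]
        self.deviance_mean_ = ch["dev_mean"]
        d_hat = -2.0 * observed_loglik(G, ch["Q"], ch["P"], ch["f"])
        self.p_d_ = self.deviance_mean_ - d_hat
        self.dic_ = self.deviance_mean_ + self.p_d_
        self.n_features_in_ = L
        self.n_individuals_ = n
        return self

    def predict(self, X=None) -> np.ndarray:
        """Modal cluster assignment per individual (from posterior means)."""
        if not hasattr(self, "admixture_"):
            raise RuntimeError("model is not fitted")
        return np.argmax(self.admixture_, axis=1)

    def score(self, X) -> float:
        G = _as_G(X)
        return observed_loglik(G, self.admixture_,
                               self.allele_freqs_[..., 1], self.inbreeding_)


def _gelman_rubin(traces: list[np.ndarray]) -> float:
    m = len(traces)
    t = min(len(x) for x in traces)
    arr = np.stack([x[-t:] for x in traces])
    means = arr.mean(axis=1)
    W = arr.var(axis=1, ddof=1).mean()
    B = t * means.var(ddof=1)
    var_hat = (t - 1) / t * W + B / t
    return float(np.sqrt(var_hat / W)) if W > 0 else 1.0


def fit_clusters(snps, k: int, iterations: int = 20000, burn_in: int = 2000,
                 seed=None, n_chains: int = 1, **kwargs) -> AdmixtureInbreedingModel:
    """Fit the admixture-with-inbreeding model at a fixed K."""
    return AdmixtureInbreedingModel(
        n_clusters=k, n_iter=iterations, burn_in=burn_in, seed=seed,
        n_chains=n_chains, **kwargs,
    ).fit(snps)


def fit_k_range(snps, ks, iterations: int = 20000, burn_in: int = 2000,
                seed=None, n_chains: int = 1) -> list[AdmixtureInbreedingModel]:
    rng = np.random.default_rng(seed)
    return [
        fit_clusters(snps, k, iterations, burn_in, rng.integers(2**31), n_chains)
        for k in ks
    ]


def choose_k(models: list[AdmixtureInbreedingModel]):
    """DIC-based K selection.

    Returns a dict with the DIC-minimizing K, the smallest K within 2 DIC
    units of the minimum (parsimony report), and the full curve; models
    flagged non-converged are excluded with a warning.
    """
    if len(models) < 2:
        raise ValueError("need >= 2 fitted models")
    usable = []
    for m in models:
        if m.converged_:
            usable.append(m)
        else:
            warnings.warn(f"excluding non-converged model K={m.n_clusters}")
    if not usable:
        raise ValueError("no converged models")
    ks = np.array([m.n_clusters for m in usable])
    dics = np.array([m.dic_ for m in usable])
    best = int(np.argmin(dics))
    within2 = ks[dics <= dics[best] + 2.0]
    return {
        "k_min_dic": int(ks[best]),
        "k_parsimony": int(within2.min()),
        "dic_curve": pd.DataFrame({"k": ks, "dic": dics}),
    }


def align_clusters(reference: np.ndarray, other: np.ndarray) -> np.ndarray:
    """Greedy label alignment: permutation of `other`'s columns maximizing
    admixture overlap with `reference` (Hungarian assignment)."""
    overlap = reference.T @ other
    _, cols = linear_sum_assignment(-overlap)
    return other[:, cols]


def single_snp_per_locus_rerun(snps: SnpMatrix, k: int, seed=None,
                               iterations: int = 20000, burn_in: int = 2000,
                               full_model: AdmixtureInbreedingModel | None = None):
    """Refit on one randomly chosen SNP per locus.

    Returns ``(model, concordance, chosen_ids)`` where concordance is the
    fraction of individuals keeping their modal cluster relative to
    ``full_model`` (fitted here if not supplied) after label alignment.
    """
    rng = np.random.default_rng(seed)
    loci = snps.locus_ids
    chosen = [int(rng.choice(np.flatnonzero(loci == locus)))
              for locus in pd.unique(loci)]
    sub = snps.subset_snps(np.asarray(chosen))
    if full_model is None:
        full_model = fit_clusters(snps, k, iterations, burn_in,
                                  rng.integers(2**31))
    model = fit_clusters(sub, k, iterations, burn_in, rng.integers(2**31))
    aligned = align_clusters(full_model.admixture_, model.admixture_)
    concordance = float(np.mean(
        np.argmax(aligned, axis=1) == full_model.predict()
    ))
    return model, concordance, [snps.snp_ids[i] for i in chosen]


# ---------------------------------------------------------------------------
# Model-free cross-check: PCoA on a genetic distance matrix
# ---------------------------------------------------------------------------

def snp_distance_matrix(snps) -> np.ndarray:
    """Individual-by-individual mean absolute dosage distance
    (pairwise-complete over SNPs with data in both individuals)."""
    G = _as_G(snps).astype(float)
    G[G < 0] = np.nan
    n = G.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(G[i] - G[i + 1:])
        D[i, i + 1:] = D[i + 1:, i] = np.nanmean(diff, axis=1)
    return D


@dataclass
class PcoaResult:
    coordinates: np.ndarray  # (n, n_axes)
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray


def pcoa(dist, ids=None) -> PcoaResult:
    """Principal coordinates (Gower centering + eigendecomposition).

    Axes are ordered by decreasing eigenvalue with percent variance
    explained; an all-zero matrix degenerates to all points at the origin.
    """
    D = np.asarray(dist, dtype=float)
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    if np.allclose(D, 0):
        n = D.shape[0]
        return PcoaResult(np.zeros((n, 1)), np.zeros(1), np.zeros(1))
    ids = ids or [str(i) for i in range(D.shape[0])]
    res = _skbio_pcoa(DistanceMatrix(D, ids), method="eigh",
                      number_of_dimensions=D.shape[0])
    return PcoaResult(
        coordinates=res.samples.to_numpy(),
        eigenvalues=res.eigvals.to_numpy(),
        proportion_explained=res.proportion_explained.to_numpy(),
    )
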