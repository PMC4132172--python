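"""Neutrality tests: Tajima's D, Fu's Fs, Ramos-Onsins & Rozas R2.

Significance is assessed against coalescent nulls conditioned on the
observed number of segregating sites (the DnaSP convention): genealogies
are simulated under the chosen demography, exactly S mutations are placed
proportional to branch length, and empirical tail probabilities use the
(r + 1)/(reps + 1) add-one correction.

All statistics are computed *folded* (no outgroup): a singleton is an
allele observed exactly once regardless of ancestral state.

The multilocus test re-draws each locus's statistic from its own fixed-S
null and compares the observed cross-locus mean against the null means;
literally shuffling locus labels cannot change a mean across loci, so the
coalescent re-draw is the operative randomization (the convention of the
HKA program's multilocus D test).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .coalescent import DemographyModel, drop_fixed_s, simulate_tree
from .diversity import harmonic_a1, harmonic_a2, site_summary
from .popdata import HaplotypeAlignment

__all__ = [
    "NeutralityResult",
    "tajima_constants",
    "tajima_d",
    "tajima_d_from_parts",
    "fu_fs",
    "fu_fs_from_parts",
    "ewens_log_pmf",
    "r2_statistic",
    "r2_from_parts",
    "locus_stats_from_sim",
    "null_distribution",
    "coalescent_pvalue",
    "multilocus_d_test",
]


@dataclass
class NeutralityResult:
    """Observed statistic with its simulated null distribution."""

    statistic_name: str
    observed: float
    null_values: np.ndarray
    p_low: float
    p_high: float
    sim_mean: float

    @property
    def n_reps(self) -> int:
        return len(self.null_values)


# ---------------------------------------------------------------------------
# Tajima's D
# ---------------------------------------------------------------------------

def tajima_constants(n: int) -> tuple[float, float, float]:
    """(a1, e1, e2) from the 1989 variance approximation."""
    if n < 2:
        raise ValueError("n must be >= 2")
    a1, a2 = harmonic_a1(n), harmonic_a2(n)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    return a1, c1 / a1, c2 / (a1 * a1 + a2)


def tajima_d_from_parts(n: int, s: int, pi_total: float) -> float:
    """D from sample size, segregating sites and mean pairwise differences.

    Returns NaN when S = 0 (the statistic is undefined and is reported as
    NA, excluded from averages).
    """
    if n < 4:
        raise ValueError("Tajima's D requires n >= 4")
    if s == 0:
        return float("nan")
    a1, e1, e2 = tajima_constants(n)
    var = e1 * s + e2 * s * (s - 1)
    return (pi_total - s / a1) / np.sqrt(var)


def tajima_d(aln: HaplotypeAlignment, site_filter: str = "silent") -> float:
    summ = site_summary(aln, site_filter)
    return tajima_d_from_parts(summ.n_haplotypes, summ.s, summ.pi_total)


# ---------------------------------------------------------------------------
# Fu's Fs (Ewens sampling formula)
# ---------------------------------------------------------------------------

_STIRLING_CACHE: dict[int, np.ndarray] = {}


def _log_stirling_row(n: int) -> np.ndarray:
    """log |s(n, k)| for k = 0..n (unsigned Stirling numbers, first kind)."""
    if n in _STIRLING_CACHE:
        return _STIRLING_CACHE[n]
    row = np.full(2, -np.inf)
    row[1] = 0.0  # |s(1,1)| = 1
    for m in range(1, n):
        new = np.full(m + 2, -np.inf)
        # |s(m+1,k)| = m*|s(m,k)| + |s(m,k-1)|
        new[1:m + 2] = np.logaddexp(
            np.log(m) + np.pad(row[1:m + 1], (0, 1), constant_values=-np.inf),
            row[0:m + 1],
        )
        row = new
    _STIRLING_CACHE[n] = row
    return row


def ewens_log_pmf(n: int, theta: float) -> np.ndarray:
    """log P(K = k | theta, n) for k = 0..n under the Ewens sampling formula."""
    if theta <= 0:
        raise ValueError("theta must be > 0")
    row = _log_stirling_row(n)
    k = np.arange(n + 1)
    log_rising = np.sum(np.log(theta + np.arange(n)))
    return row + k * np.log(theta) - log_rising


def fu_fs_from_parts(n: int, k_obs: int, pi_total: float) -> float:
    """Fs = ln(S'/(1-S')), S' = P(K >= k_obs | theta-hat = pi_total).

    Returns +inf (with a warning) when every sample has at least k_obs
    haplotypes with probability 1, i.e. k_obs = 1, and -inf when S' underflows.
    """
    if not 1 <= k_obs <= n:
        raise ValueError("k_obs must be in [1, n]")
    if k_obs == 1:
        warnings.warn("k_obs = 1: S' = 1, Fs is +infinity")
        return float("inf")
    if pi_total <= 0:
        raise ValueError("Fu's Fs requires pi_total > 0")
    logp = ewens_log_pmf(n, pi_total)[1:]  # k = 1..n
    k = np.arange(1, n + 1)
    log_upper = logsumexp(logp[k >= k_obs])
    log_lower = logsumexp(logp[k < k_obs])
    fs = log_upper - log_lower
    if not np.isfinite(fs):
        warnings.warn("Fu's Fs at infinity sentinel (S' at numerical 0 or 1)")
    return float(fs)


def fu_fs(aln: HaplotypeAlignment, site_filter: str = "silent") -> float:
    summ = site_summary(aln, site_filter)
    return fu_fs_from_parts(summ.n_haplotypes, summ.n_haplotype_classes,
                            summ.pi_total)


# ---------------------------------------------------------------------------
# Ramos-Onsins & Rozas R2
# ---------------------------------------------------------------------------

def r2_from_parts(n: int, s: int, pi_total: float, singletons) -> float:
    """R2 = sqrt(mean_i (U_i - pi/2)^2) / S, U_i = singletons on sequence i."""
    if s < 1:
        return float("nan")
    u = np.asarray(singletons, dtype=float)
    if len(u) != n:
        raise ValueError("need one singleton count per haplotype")
    return float(np.sqrt(np.mean((u - pi_total / 2.0) ** 2)) / s)


def r2_statistic(aln: HaplotypeAlignment, site_filter: str = "silent") -> float:
    summ = site_summary(aln, site_filter)
    return r2_from_parts(summ.n_haplotypes, summ.s, summ.pi_total,
                         summ.singletons)


# ---------------------------------------------------------------------------
# Simulated-locus summaries and null distributions
# ---------------------------------------------------------------------------

def locus_stats_from_sim(locus) -> dict:
    """(S, pi_total, folded singleton counts, haplotype classes) for a
    simulated infinite-sites locus."""
    h = locus.haplotypes
    n, s = h.shape
    c = h.sum(axis=0)
    pairs = n * (n - 1) / 2.0
    pi_total = float(np.sum(c * (n - c)) / pairs)
    singles = np.zeros(n, dtype=int)
    for j in range(s):
        if c[j] == 1:
            singles[np.flatnonzero(h[:, j])[0]] += 1
        elif c[j] == n - 1:
            singles[np.flatnonzero(h[:, j] == 0)[0]] += 1
    k = len({tuple(row) for row in h}) if s else 1
    return {"n": n, "s": s, "pi_total": pi_total, "singletons": singles,
            "k_obs": k}


def _fast_tajima_null(n: int, s_obs: int, reps: int, rng,
                      model: DemographyModel | None) -> np.ndarray:
    """Fixed-S Tajima's D null without materializing haplotype matrices."""
    out = np.empty(reps)
    pairs = n * (n - 1) / 2.0
    for r in range(reps):
        tree = simulate_tree(n, model, rng)
        bl = tree.branch_lengths()
        ndesc = tree.n_descendants()
        nodes = rng.choice(tree.n_nodes, size=s_obs, p=bl / bl.sum())
        c = ndesc[nodes]
        pi_total = float(np.sum(c * (n - c)) / pairs)
        out[r] = tajima_d_from_parts(n, s_obs, pi_total)
    return out


def null_distribution(statistic: str, n: int, s_obs: int, reps: int,
                      seed=None, model: DemographyModel | None = None) -> np.ndarray:
    """Simulate the fixed-S null distribution of a neutrality statistic."""
    if s_obs < 1:
        raise ValueError("conditioning requires s_obs >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if statistic == "tajima_d":
        return _fast_tajima_null(n, s_obs, reps, rng, model)
    out = np.empty(reps)
    for r in range(reps):
        tree = simulate_tree(n, model, rng)
        locus = drop_fixed_s(tree, s_obs, rng)
        st = locus_stats_from_sim(locus)
        if statistic == "fu_fs":
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                out[r] = fu_fs_from_parts(n, st["k_obs"], st["pi_total"]) \
                    if st["pi_total"] > 0 else np.inf
        elif statistic == "r2":
            out[r] = r2_from_parts(n, s_obs, st["pi_total"], st["singletons"])
        else:
            raise ValueError(f"unknown statistic {statistic!r}")
    return out


def _empirical_tails(observed: float, null: np.ndarray) -> tuple[float, float]:
    reps = len(null)
    p_low = (np.sum(null <= observed) + 1) / (reps + 1)
    p_high = (np.sum(null >= observed) + 1) / (reps + 1)
    return float(p_low), float(p_high)


def coalescent_pvalue(observed: float, statistic: str, n: int, s_obs: int,
                      reps: int = 10000, seed=None,
                      model: DemographyModel | None = None) -> NeutralityResult:
    """Empirical p-values for an observed statistic against its fixed-S null.

    Ties count toward both tails, so p_low + p_high >= 1.
    """
    if reps < 1000:
        raise ValueError("use at least 1000 replicates")
    if not np.isfinite(observed):
        return NeutralityResult(statistic, float("nan"), np.empty(0),
                                float("nan"), float("nan"), float("nan"))
    null = null_distribution(statistic, n, s_obs, reps, seed, model)
    finite = null[np.isfinite(null)]
    p_low, p_high = _empirical_tails(observed, null)
    return NeutralityResult(
        statistic_name=statistic, observed=float(observed), null_values=null,
        p_low=p_low, p_high=p_high,
        sim_mean=float(finite.mean()) if len(finite) else float("nan"),
    )


def multilocus_d_test(per_locus: list[tuple[float, int, int]], reps: int = 10000,
                      seed=None, model: DemographyModel | None = None) -> NeutralityResult:
    """Randomization test for the cross-locus mean of Tajima's D.

    ``per_locus`` holds (observed D, n haplotypes, S) triples; loci with
    undefined D (S = 0) must be filtered out by the caller.
    """
    per_locus = [(d, n, s) for d, n, s in per_locus if np.isfinite(d)]
    if len(per_locus) < 2:
        raise ValueError("need >= 2 loci with defined D")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    observed = float(np.mean([d for d, _, _ in per_locus]))
    null_mat = np.empty((reps, len(per_locus)))
    for j, (_, n, s) in enumerate(per_locus):
        null_mat[:, j] = _fast_tajima_null(n, s, reps, rng, model)
    null_means = null_mat.mean(axis=1)
    p_low, p_high = _empirical_tails(observed, null_means)
    return NeutralityResult(
        statistic_name="multilocus_tajima_d", observed=observed,
        null_values=null_means, p_low=p_low, p_high=p_high,
        sim_mean=float(null_means.mean()),
    )
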