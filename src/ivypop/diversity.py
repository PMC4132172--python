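"""Silent-site nucleotide diversity estimators.

Watterson's theta (from the count of segregating sites) and pairwise theta
(mean pairwise differences) are reported per silent site, where the
effective silent length counts noncoding columns as 1 and coding columns by
their fractional codon degeneracy — the denominator needed to express
per-site values comparable across loci of different composition.

Missing or ambiguous characters are handled pairwise-complete: per-column
mean difference is computed over pairs with valid data at that column.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .popdata import (
    HaplotypeAlignment,
    SITE_EXCLUDED,
    classify_sites,
)

__all__ = [
    "DiversityEstimate",
    "SiteSummary",
    "harmonic_a1",
    "harmonic_a2",
    "site_summary",
    "watterson_theta",
    "pairwise_theta",
    "locus_diversity",
    "multilocus_average",
    "pooled_multilocus",
    "per_kb_differences",
]

_VALID = np.array(list("ACGT"))


def harmonic_a1(n: int) -> float:
    """a1 = sum_{i=1}^{n-1} 1/i."""
    return float(np.sum(1.0 / np.arange(1, n)))


def harmonic_a2(n: int) -> float:
    """a2 = sum_{i=1}^{n-1} 1/i^2."""
    return float(np.sum(1.0 / np.arange(1, n) ** 2))


@dataclass
class DiversityEstimate:
    """Per-site diversity for one analysis scope."""

    scope: str  # e.g. "population:VA12/locus:L1", "global/multilocus"
    n_haplotypes: int
    s_silent: int
    theta_w: float
    theta_pi: float
    silent_length: float

    def __post_init__(self):
        if self.silent_length < 0:
            raise ValueError("silent_length must be >= 0")


@dataclass
class SiteSummary:
    """Column-level summaries shared by the diversity and neutrality statistics.

    ``pi_total`` is the *unnormalized* mean number of pairwise differences
    (summed over columns); ``singletons`` counts, per haplotype, the columns
    where that haplotype carries an allele seen exactly once.
    """

    n_haplotypes: int
    s: int
    pi_total: float
    silent_length: float
    singletons: np.ndarray
    n_haplotype_classes: int


def _ensure_classified(aln: HaplotypeAlignment) -> HaplotypeAlignment:
    if aln.silent_weights is None:
        return classify_sites(aln, None)
    return aln


def _filtered_columns(aln: HaplotypeAlignment, site_filter: str) -> np.ndarray:
    if site_filter == "silent":
        return np.flatnonzero(aln.silent_columns())
    if site_filter == "all":
        return np.flatnonzero(aln.site_classes != SITE_EXCLUDED)
    raise ValueError(f"unknown site filter {site_filter!r}")


def site_summary(aln: HaplotypeAlignment, site_filter: str = "silent",
                 include_multiallelic: bool = False) -> SiteSummary:
    """Segregating sites, pairwise differences, singletons and haplotype count.

    Multiallelic columns are excluded from all counts by default (the same
    policy as SNP extraction), switchable with ``include_multiallelic``.
    """
    aln = _ensure_classified(aln)
    cols = _filtered_columns(aln, site_filter)
    n = aln.n_haplotypes
    if site_filter == "silent":
        length = float(aln.silent_weights[cols].sum())
    else:
        length = float(len(cols))

    s = 0
    pi_total = 0.0
    singles = np.zeros(n, dtype=int)
    kept_cols = []
    for j in cols:
        col = aln.sequences[:, j]
        valid = np.isin(col, _VALID)
        vals = col[valid]
        m = len(vals)
        if m < 2:
            continue
        states, counts = np.unique(vals, return_counts=True)
        if len(states) < 2:
            kept_cols.append(j)
            continue
        if len(states) > 2 and not include_multiallelic:
            continue
        kept_cols.append(j)
        s += 1
        pairs = m * (m - 1) / 2.0
        same = np.sum(counts * (counts - 1) / 2.0)
        pi_total += (pairs - same) / pairs * 1.0  # mean diff at this column
        for st, c in zip(states, counts):
            if c == 1:
                carrier = np.flatnonzero(valid)[np.flatnonzero(vals == st)[0]]
                singles[carrier] += 1

    if kept_cols:
        sub = aln.sequences[:, kept_cols]
        k = len({tuple(row) for row in sub})
    else:
        k = 1
    return SiteSummary(
        n_haplotypes=n, s=s, pi_total=pi_total, silent_length=length,
        singletons=singles, n_haplotype_classes=k,
    )


def watterson_theta(aln: HaplotypeAlignment, site_filter: str = "silent",
                    include_multiallelic: bool = False) -> float:
    """Per-site Watterson estimate S / (a1 * L)."""
    summ = site_summary(aln, site_filter, include_multiallelic)
    if summ.n_haplotypes < 2:
        raise ValueError("need at least 2 haplotypes")
    if summ.silent_length <= 0:
        raise ValueError("zero effective site length: estimate undefined")
    return summ.s / (harmonic_a1(summ.n_haplotypes) * summ.silent_length)


def pairwise_theta(aln: HaplotypeAlignment, site_filter: str = "silent",
                   include_multiallelic: bool = False) -> float:
    """Per-site mean pairwise difference (pi)."""
    summ = site_summary(aln, site_filter, include_multiallelic)
    if summ.n_haplotypes < 2:
        raise ValueError("need at least 2 haplotypes")
    if summ.silent_length <= 0:
        raise ValueError("zero effective site length: estimate undefined")
    return summ.pi_total / summ.silent_length


def locus_diversity(aln: HaplotypeAlignment, scope: str = "global",
                    site_filter: str = "silent") -> DiversityEstimate:
    summ = site_summary(aln, site_filter)
    if summ.silent_length <= 0:
        raise ValueError(f"{aln.locus_id}: zero effective site length")
    a1 = harmonic_a1(summ.n_haplotypes)
    return DiversityEstimate(
        scope=f"{scope}/locus:{aln.locus_id}",
        n_haplotypes=summ.n_haplotypes,
        s_silent=summ.s,
        theta_w=summ.s / (a1 * summ.silent_length),
        theta_pi=summ.pi_total / summ.silent_length,
        silent_length=summ.silent_length,
    )


def multilocus_average(estimates: list[DiversityEstimate],
                       weights=None) -> DiversityEstimate:
    """Length-weighted multilocus average of per-site estimates.

    With default weights (each locus's effective silent length) this equals
    the estimate computed on the pooled site set, so the "total" rows of
    reports use it directly.
    """
    if not estimates:
        raise ValueError("no estimates supplied")
    if weights is None:
        weights = [e.silent_length for e in estimates]
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be non-negative with positive sum")
    tw = np.asarray([e.theta_w for e in estimates])
    tp = np.asarray([e.theta_pi for e in estimates])
    return DiversityEstimate(
        scope="multilocus",
        n_haplotypes=int(max(e.n_haplotypes for e in estimates)),
        s_silent=int(sum(e.s_silent for e in estimates)),
        theta_w=float(np.average(tw, weights=w)),
        theta_pi=float(np.average(tp, weights=w)),
        silent_length=float(w.sum()),
    )


def pooled_multilocus(alns: list[HaplotypeAlignment], scope: str = "global",
                      site_filter: str = "silent") -> DiversityEstimate:
    """Multilocus estimate pooling all haplotypes and loci before averaging."""
    summaries = [site_summary(a, site_filter) for a in alns]
    L = sum(s.silent_length for s in summaries)
    if L <= 0:
        raise ValueError("zero pooled silent length")
    s_tot = sum(s.s for s in summaries)
    pi_tot = sum(s.pi_total for s in summaries)
    # per-locus a1 (sample sizes may differ between loci)
    theta_w = sum(s.s / harmonic_a1(s.n_haplotypes) for s in summaries) / L
    return DiversityEstimate(
        scope=f"{scope}/multilocus",
        n_haplotypes=int(max(s.n_haplotypes for s in summaries)),
        s_silent=s_tot,
        theta_w=theta_w,
        theta_pi=pi_tot / L,
        silent_length=L,
    )


def per_kb_differences(theta_pi: float) -> float:
    """Express per-site pairwise diversity as differences per 1000 bp."""
    if theta_pi < 0:
        raise ValueError("theta_pi must be >= 0")
    return 1000.0 * theta_pi
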