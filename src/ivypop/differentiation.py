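"""Hierarchical F-statistics, genetic distances, isolation-by-distance and LD.

F-statistics follow Weir & Cockerham (1984): per-SNP variance components
a (among populations), b (among individuals within populations) and c
(within individuals) are computed for each biallelic codominant SNP and
summed across SNPs for multilocus estimates, giving

    FST = a / (a + b + c),  FIS = b / (b + c),  FIT = (a + b) / (a + b + c).

The AMOVA report truncates negative summed components at zero before
percentages are formed (Excoffier convention); significance comes from
permuting individuals among populations (FST) and alleles among individuals
within populations (FIS).

Isolation-by-distance uses Mantel matrix-permutation tests of Nei's (1972)
standard distance, pairwise FST and linearized FST = FST/(1-FST) against
great-circle geographic distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .popdata import SnpMatrix

__all__ = [
    "AmovaResult",
    "DistanceMatrices",
    "SnpFstDistribution",
    "MantelResult",
    "wc_components",
    "weir_cockerham_fst",
    "multilocus_fst",
    "amova",
    "snp_fst_distribution",
    "nei_distance",
    "pairwise_fst_matrix",
    "linearized_fst",
    "geographic_distance",
    "mantel_test",
    "selfing_rate_from_fis",
    "ld_r2_matrix",
    "prune_ld_and_recompute",
    "outlier_percentile",
]

EARTH_RADIUS_KM = 6371.0


def _rng(seed):
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _as_genotypes(snps) -> np.ndarray:
    if isinstance(snps, SnpMatrix):
        return snps.genotypes
    g = np.asarray(snps)
    return g.reshape(len(g), -1) if g.ndim == 1 else g


def _labels_for(snps, meta) -> np.ndarray:
    """Population label per genotype row."""
    if isinstance(meta, pd.DataFrame):
        if isinstance(snps, SnpMatrix):
            lut = dict(zip(meta["individual_id"], meta["population_id"]))
            return np.asarray([lut[i] for i in snps.individuals], dtype=object)
        return np.asarray(meta["population_id"], dtype=object)
    return np.asarray(meta, dtype=object)


# ---------------------------------------------------------------------------
# Weir & Cockerham variance components
# ---------------------------------------------------------------------------

def wc_components(G: np.ndarray, labels: np.ndarray):
    """Per-SNP W&C (1984) components (a, b, c) for dosage genotypes.

    ``G`` is (n_individuals, n_snps) with entries 0/1/2 and -1 for missing.
    Populations absent at a SNP (all missing) drop from that SNP's r.
    """
    G = np.asarray(G)
    labels = np.asarray(labels)
    pops, inv = np.unique(labels, return_inverse=True)
    r_all = len(pops)
    n, S = G.shape
    Z = np.zeros((r_all, n))
    Z[inv, np.arange(n)] = 1.0

    valid = G >= 0
    Gv = np.where(valid, G, 0)
    n_i = Z @ valid  # (r, S) individuals with data
    dos = Z @ Gv
    het = Z @ ((G == 1) & valid)

    with np.errstate(invalid="ignore", divide="ignore"):
        p_i = dos / (2.0 * n_i)
        h_i = het / n_i
    present = n_i > 0
    r = present.sum(axis=0).astype(float)  # pops represented per SNP
    n_tot = n_i.sum(axis=0)

    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = n_tot / r
        nc = (n_tot - (n_i**2).sum(axis=0) / n_tot) / (r - 1)
        pbar = dos.sum(axis=0) / (2.0 * n_tot)
        dev2 = np.where(present, n_i * (np.where(present, p_i, 0) - pbar) ** 2, 0.0)
        s2 = dev2.sum(axis=0) / ((r - 1) * nbar)
        hbar = het.sum(axis=0) / n_tot

        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2.0
    bad = (r < 2) | (nbar <= 1)
    a[bad] = b[bad] = c[bad] = np.nan
    return a, b, c


def weir_cockerham_fst(snps, meta) -> float:
    """W&C theta-hat for a single biallelic SNP (NaN if monomorphic)."""
    G = _as_genotypes(snps)
    if G.shape[1] != 1:
        raise ValueError("weir_cockerham_fst expects exactly one SNP; "
                         "use multilocus_fst or snp_fst_distribution")
    a, b, c = wc_components(G, _labels_for(snps, meta))
    tot = a[0] + b[0] + c[0]
    if not np.isfinite(tot) or tot == 0:
        return float("nan")
    return float(a[0] / tot)


def multilocus_fst(snps, meta) -> float:
    """Multilocus theta-hat: components summed over SNPs before the ratio."""
    G = _as_genotypes(snps)
    a, b, c = wc_components(G, _labels_for(snps, meta))
    ok = np.isfinite(a)
    tot = np.sum(a[ok] + b[ok] + c[ok])
    return float(np.sum(a[ok]) / tot) if tot else float("nan")


def _f_stats_from_sums(a_sum, b_sum, c_sum, truncate=False):
    if truncate:
        a_sum, b_sum, c_sum = (max(x, 0.0) for x in (a_sum, b_sum, c_sum))
    tot = a_sum + b_sum + c_sum
    if tot == 0:
        return float("nan"), float("nan"), float("nan")
    fst = a_sum / tot
    fis = b_sum / (b_sum + c_sum) if (b_sum + c_sum) else float("nan")
    fit = (a_sum + b_sum) / tot
    return fst, fis, fit


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------

@dataclass
class AmovaResult:
    """Three-level AMOVA with permutation p-values.

    ``variance_components`` and ``percentages`` are ordered (among
    populations, among individuals within populations, within individuals).
    """

    variance_components: tuple[float, float, float]
    percentages: tuple[float, float, float]
    f_statistics: dict  # FST, FIS, FIT
    p_values: dict  # fst, fis
    n_permutations: int

    def summary(self) -> pd.DataFrame:
        rows = [
            ("among_populations", *map(float, (self.variance_components[0], self.percentages[0]))),
            ("among_individuals_within", *map(float, (self.variance_components[1], self.percentages[1]))),
            ("within_individuals", *map(float, (self.variance_components[2], self.percentages[2]))),
        ]
        return pd.DataFrame(rows, columns=["stratum", "variance", "percent"])


def _component_sums(G, labels):
    a, b, c = wc_components(G, labels)
    ok = np.isfinite(a)
    return float(a[ok].sum()), float(b[ok].sum()), float(c[ok].sum())


def _permute_alleles_within_pops(G, labels, rng):
    """Randomly re-pair allele copies among individuals within each population."""
    Gp = G.copy()
    for pop in np.unique(labels):
        rows = np.flatnonzero(labels == pop)
        sub = G[rows]  # (m, S)
        m, S = sub.shape
        alleles = np.zeros((2 * m, S), dtype=np.int8)
        half = np.clip(sub, 0, 2) // 2
        alleles[0::2] = np.where(sub >= 0, half, -1)
        alleles[1::2] = np.where(sub >= 0, sub - half, -1)
        if np.all(sub >= 0):
            keys = rng.random(alleles.shape)
            idx = np.argsort(keys, axis=0)
            shuffled = np.take_along_axis(alleles, idx, axis=0)
        else:
            shuffled = alleles.copy()
            for j in range(S):
                v = np.flatnonzero(alleles[:, j] >= 0)
                shuffled[v, j] = alleles[v[rng.permutation(len(v))], j]
        new = np.where(
            (shuffled[0::2] >= 0) & (shuffled[1::2] >= 0),
            shuffled[0::2] + shuffled[1::2],
            -1,
        )
        Gp[rows] = new
    return Gp


def amova(snps, meta, permutations: int = 999, seed=None,
          permute: tuple = ("fst", "fis")) -> AmovaResult:
    """Three-level AMOVA on biallelic SNP dosages.

    Populations represented by a single individual are excluded with a
    warning (their within-population level is empty).  ``permute`` selects
    which statistics get permutation p-values: individuals are shuffled
    among populations for FST, allele copies among individuals within
    populations for FIS.
    """
    G = _as_genotypes(snps)
    labels = _labels_for(snps, meta)
    pops, counts = np.unique(labels, return_counts=True)
    small = pops[counts < 2]
    if len(small):
        warnings.warn(f"excluding population(s) of size 1: {list(small)}")
        keep = ~np.isin(labels, small)
        G, labels = G[keep], labels[keep]
    if len(np.unique(labels)) < 2:
        raise ValueError("AMOVA needs >= 2 populations with >= 2 individuals")

    a_sum, b_sum, c_sum = _component_sums(G, labels)
    fst, fis, fit = _f_stats_from_sums(a_sum, b_sum, c_sum)

    trunc = tuple(max(x, 0.0) for x in (a_sum, b_sum, c_sum))
    tot = sum(trunc)
    percentages = tuple(100.0 * x / tot for x in trunc)

    rng = _rng(seed)
    fst_ge = fis_ge = 0
    for _ in range(permutations):
        if "fst" in permute:
            perm_labels = labels[rng.permutation(len(labels))]
            ap, bp, cp = _component_sums(G, perm_labels)
            f, _, _ = _f_stats_from_sums(ap, bp, cp)
            if f >= fst:
                fst_ge += 1
        if "fis" in permute:
            Gp = _permute_alleles_within_pops(G, labels, rng)
            ap, bp, cp = _component_sums(Gp, labels)
            _, f_is, _ = _f_stats_from_sums(ap, bp, cp)
            if f_is >= fis:
                fis_ge += 1
    p_values = {}
    if "fst" in permute:
        p_values["fst"] = (fst_ge + 1) / (permutations + 1)
    if "fis" in permute:
        p_values["fis"] = (fis_ge + 1) / (permutations + 1)

    return AmovaResult(
        variance_components=(a_sum, b_sum, c_sum),
        percentages=percentages,
        f_statistics={"FST": fst, "FIS": fis, "FIT": fit},
        p_values=p_values,
        n_permutations=permutations,
    )


# ---------------------------------------------------------------------------
# Per-SNP FST distribution / outlier machinery
# ---------------------------------------------------------------------------

@dataclass
class SnpFstDistribution:
    snp_ids: list
    per_snp_fst: np.ndarray
    per_snp_p: np.ndarray | None
    ld_flags: np.ndarray | None  # True: SNP in significant LD with any other

    def finite_values(self) -> np.ndarray:
        return self.per_snp_fst[np.isfinite(self.per_snp_fst)]


def snp_fst_distribution(snps: SnpMatrix, meta, permutations: int = 0,
                         seed=None, ld_alpha: float = 0.05) -> SnpFstDistribution:
    """Per-SNP W&C FST, optional permutation p-values, and LD flags."""
    G = _as_genotypes(snps)
    labels = _labels_for(snps, meta)
    a, b, c = wc_components(G, labels)
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = a / (a + b + c)

    per_snp_p = None
    if permutations:
        rng = _rng(seed)
        ge = np.zeros(G.shape[1])
        for _ in range(permutations):
            perm = labels[rng.permutation(len(labels))]
            ap, bp, cp = wc_components(G, perm)
            with np.errstate(invalid="ignore", divide="ignore"):
                fp = ap / (ap + bp + cp)
            ge += fp >= fst
        per_snp_p = (ge + 1) / (permutations + 1)

    flags = None
    if snps.n_snps >= 2:
        _, sig = ld_r2_matrix(snps, alpha=ld_alpha)
        flags = sig.any(axis=1)
    snp_ids = snps.snp_ids if isinstance(snps, SnpMatrix) else list(range(G.shape[1]))
    return SnpFstDistribution(snp_ids=snp_ids, per_snp_fst=fst,
                              per_snp_p=per_snp_p, ld_flags=flags)


def prune_ld_and_recompute(dist: SnpFstDistribution) -> SnpFstDistribution:
    """Restrict the FST distribution to SNPs not in significant LD with any
    other SNP (the original is left intact)."""
    if dist.ld_flags is None:
        raise ValueError("LD flags not computed")
    keep = ~dist.ld_flags
    if not keep.any():
        raise ValueError("all SNPs are in significant LD: nothing left")
    return SnpFstDistribution(
        snp_ids=[s for s, k in zip(dist.snp_ids, keep) if k],
        per_snp_fst=dist.per_snp_fst[keep],
        per_snp_p=None if dist.per_snp_p is None else dist.per_snp_p[keep],
        ld_flags=dist.ld_flags[keep],
    )


def outlier_percentile(dist, focal_fst: float) -> float:
    """Percentile of a focal FST in the per-SNP background distribution."""
    values = dist.finite_values() if isinstance(dist, SnpFstDistribution) \
        else np.asarray(dist, dtype=float)
    values = values[np.isfinite(values)]
    if len(values) == 0:
        raise ValueError("empty FST distribution")
    return 100.0 * float(np.mean(values < focal_fst))


# ---------------------------------------------------------------------------
# Distances and isolation-by-distance
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrices:
    nei_d: pd.DataFrame
    fst_pairwise: pd.DataFrame
    lin_fst: pd.DataFrame
    geo_km: pd.DataFrame


def _pop_freqs(G, labels):
    pops = np.unique(labels)
    freqs = np.full((len(pops), G.shape[1]), np.nan)
    for i, pop in enumerate(pops):
        sub = G[labels == pop]
        valid = sub >= 0
        with np.errstate(invalid="ignore"):
            freqs[i] = np.where(valid, sub, 0).sum(axis=0) / (2.0 * valid.sum(axis=0))
    return pops, freqs


def nei_distance(snps, meta) -> pd.DataFrame:
    """Nei (1972) standard genetic distance between populations over all SNPs."""
    G = _as_genotypes(snps)
    labels = _labels_for(snps, meta)
    pops, p = _pop_freqs(G, labels)
    q = 1.0 - p
    r = len(pops)
    D = np.zeros((r, r))
    for x in range(r):
        for y in range(x + 1, r):
            ok = np.isfinite(p[x]) & np.isfinite(p[y])
            jxy = np.mean(p[x, ok] * p[y, ok] + q[x, ok] * q[y, ok])
            jx = np.mean(p[x, ok] ** 2 + q[x, ok] ** 2)
            jy = np.mean(p[y, ok] ** 2 + q[y, ok] ** 2)
            D[x, y] = D[y, x] = np.inf if jxy == 0 else -np.log(jxy / np.sqrt(jx * jy))
    return pd.DataFrame(D, index=pops, columns=pops)


def pairwise_fst_matrix(snps, meta) -> pd.DataFrame:
    """Multilocus W&C FST for every population pair (negatives kept)."""
    G = _as_genotypes(snps)
    labels = _labels_for(snps, meta)
    pops = np.unique(labels)
    r = len(pops)
    out = np.zeros((r, r))
    for x in range(r):
        for y in range(x + 1, r):
            rows = np.isin(labels, [pops[x], pops[y]])
            out[x, y] = out[y, x] = multilocus_fst(G[rows], labels[rows])
    return pd.DataFrame(out, index=pops, columns=pops)


def linearized_fst(fst: pd.DataFrame) -> pd.DataFrame:
    """FST / (1 - FST); the Rousset transform expected linear in distance."""
    vals = np.asarray(fst, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        lin = np.where(vals < 1.0, vals / (1.0 - vals), np.inf)
    np.fill_diagonal(lin, 0.0)
    return pd.DataFrame(lin, index=fst.index, columns=fst.columns)


def geographic_distance(meta: pd.DataFrame) -> pd.DataFrame:
    """Great-circle (haversine) distance in km between population centroids."""
    cols = ["latitude", "longitude"]
    if meta[cols].isna().any().any():
        bad = meta.loc[meta[cols].isna().any(axis=1), "population_id"].unique()
        raise ValueError(f"missing coordinates for population(s): {list(bad)}")
    cent = meta.groupby("population_id")[cols].mean()
    lat = np.radians(cent["latitude"].to_numpy())
    lon = np.radians(cent["longitude"].to_numpy())
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    h = np.sin(dlat / 2) ** 2 + np.cos(lat[:, None]) * np.cos(lat[None, :]) * np.sin(dlon / 2) ** 2
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1)))
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=cent.index, columns=cent.index)


@dataclass
class MantelResult:
    r_xy: float
    p_value: float
    permutations: int


def mantel_test(mat_a, mat_b, permutations: int = 9999, seed=None,
                alternative: str = "greater") -> MantelResult:
    """Mantel matrix-correlation test with joint row/column permutations.

    ``r_xy`` is the Pearson correlation over lower-triangle entries; the
    default alternative is one-tailed upper.
    """
    A = np.asarray(mat_a, dtype=float)
    B = np.asarray(mat_b, dtype=float)
    if A.shape != B.shape or A.shape[0] != A.shape[1]:
        raise ValueError("matrices must be square and of equal shape")
    if not (np.allclose(A, A.T, equal_nan=True) and np.allclose(B, B.T, equal_nan=True)):
        raise ValueError("matrices must be symmetric")
    n = A.shape[0]
    il = np.tril_indices(n, k=-1)
    x, y = A[il], B[il]
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant distance matrix: correlation undefined")
    r_obs = float(np.corrcoef(x, y)[0, 1])

    rng = _rng(seed)
    count = 0
    for _ in range(permutations):
        perm = rng.permutation(n)
        xp = A[np.ix_(perm, perm)][il]
        r = float(np.corrcoef(xp, y)[0, 1])
        if alternative == "greater":
            count += r >= r_obs
        elif alternative == "less":
            count += r <= r_obs
        else:  # two-sided
            count += abs(r) >= abs(r_obs)
    return MantelResult(r_xy=r_obs, p_value=(count + 1) / (permutations + 1),
                        permutations=permutations)


# ---------------------------------------------------------------------------
# Selfing rate and linkage disequilibrium
# ---------------------------------------------------------------------------

def selfing_rate_from_fis(fis: float) -> float:
    """SR (percent) = 2*FIS / (1 + FIS) * 100 at inbreeding equilibrium."""
    if fis > 1:
        raise ValueError("FIS cannot exceed 1")
    if fis < 0:
        warnings.warn("negative FIS (outbreeding excess) clamped to 0")
        fis = 0.0
    return 200.0 * fis / (1.0 + fis)


def ld_r2_matrix(snps, alpha: float = 0.05):
    """Composite (dosage-correlation) r^2 between all SNP pairs.

    Under extreme inbreeding composite and gametic LD converge, so no phase
    assumption is needed.  Significance uses the chi-square approximation
    n * r^2 ~ chi2(1); pairs with a monomorphic member are NaN/not significant.
    """
    G = _as_genotypes(snps).astype(float)
    G[G < 0] = np.nan
    S = G.shape[1]
    if S < 2:
        raise ValueError("need at least 2 SNPs")
    r2 = np.full((S, S), np.nan)
    sig = np.zeros((S, S), dtype=bool)
    crit = sps.chi2.ppf(1.0 - alpha, df=1)
    for i in range(S):
        for j in range(i + 1, S):
            ok = np.isfinite(G[:, i]) & np.isfinite(G[:, j])
            n = ok.sum()
            if n < 3 or np.std(G[ok, i]) == 0 or np.std(G[ok, j]) == 0:
                continue
            r = np.corrcoef(G[ok, i], G[ok, j])[0, 1]
            r2[i, j] = r2[j, i] = r * r
            if n * r * r > crit:
                sig[i, j] = sig[j, i] = True
    return r2, sig
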