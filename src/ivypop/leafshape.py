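"""Leaf-shape locus: Mendelian genotype inference and outlier contrast.

Leaf shape in *Ipomoea hederacea* segregates as a single biallelic
codominant locus — lobed (LL), heterozygote (Ll) and entire (ll) leaves are
distinct phenotype classes — so a maternal plant's genotype can be read off
the segregation of leaf shapes among its selfed progeny.  The inferred
genotypes provide per-population allele frequencies and a single-locus FST
that is contrasted with the genome-wide SNP background to test for
divergent selection on the cline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .differentiation import (
    _component_sums,
    _f_stats_from_sums,
    outlier_percentile,
)
from .popdata import SnpMatrix

__all__ = [
    "ProgenyArray",
    "LeafLocusSummary",
    "GENOTYPES",
    "infer_maternal_genotype",
    "progeny_class_probs",
    "simulate_progeny_array",
    "read_progeny_arrays",
    "write_progeny_arrays",
    "leaf_allele_frequencies",
    "leaf_snp_matrix",
    "leaf_locus_fst",
]

GENOTYPES = ("LL", "Ll", "ll")
_DOSAGE = {"LL": 2, "Ll": 1, "ll": 0}


@dataclass
class ProgenyArray:
    """Phenotype counts (lobed, heterozygote, entire) among one maternal
    line's scored progeny."""

    maternal_id: str
    counts: tuple[int, int, int]
    family_size: int = 10

    def __post_init__(self):
        c = tuple(int(x) for x in self.counts)
        if any(x < 0 for x in c):
            raise ValueError("negative progeny counts")
        if sum(c) > self.family_size:
            raise ValueError(
                f"{self.maternal_id}: {sum(c)} progeny exceed family size "
                f"{self.family_size}"
            )
        self.counts = c

    @property
    def total(self) -> int:
        return sum(self.counts)


def progeny_class_probs(maternal: str, selfing_rate: float = 1.0,
                        pollen_l_freq: float = 0.5) -> np.ndarray:
    """P(lobed, het, entire) among progeny of a given maternal genotype.

    Selfed progeny follow the Mendelian segregation of the mother
    (LL -> all lobed; ll -> all entire; Ll -> 1/4 : 1/2 : 1/4); outcrossed
    progeny combine a maternal ovule allele with a pollen L allele at
    frequency ``pollen_l_freq``.
    """
    s = selfing_rate
    if not 0 <= s <= 1:
        raise ValueError("selfing rate must be in [0, 1]")
    p = pollen_l_freq
    selfed = {
        "LL": np.array([1.0, 0.0, 0.0]),
        "Ll": np.array([0.25, 0.5, 0.25]),
        "ll": np.array([0.0, 0.0, 1.0]),
    }[maternal]
    outcrossed = {
        "LL": np.array([p, 1 - p, 0.0]),
        "Ll": np.array([p / 2, 0.5, (1 - p) / 2]),
        "ll": np.array([0.0, p, 1 - p]),
    }[maternal]
    return s * selfed + (1 - s) * outcrossed


def infer_maternal_genotype(arr: ProgenyArray, selfing_rate: float = 1.0,
                            pollen_l_freq: float = 0.5):
    """Maximum-likelihood maternal genotype from a progeny array.

    Returns ``(genotype, log_likelihoods)``.  Under pure selfing (the
    default) a mixed-class array is only compatible with Ll; ties are broken
    toward Ll, the one genotype consistent with every progeny class.
    """
    counts = np.asarray(arr.counts, dtype=float)
    if counts.sum() < 1:
        raise ValueError(f"{arr.maternal_id}: empty progeny array")
    logliks = {}
    for g in GENOTYPES:
        probs = progeny_class_probs(g, selfing_rate, pollen_l_freq)
        ll = 0.0
        for c, p in zip(counts, probs):
            if c > 0:
                ll += c * np.log(p) if p > 0 else -np.inf
        logliks[g] = float(ll)
    best = max(logliks.values())
    winners = [g for g in GENOTYPES if logliks[g] == best]
    genotype = "Ll" if "Ll" in winners else winners[0]
    return genotype, logliks


def simulate_progeny_array(maternal: str, n_progeny: int = 10, seed=None,
                           selfing_rate: float = 1.0,
                           pollen_l_freq: float = 0.5,
                           maternal_id: str = "sim") -> ProgenyArray:
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    probs = progeny_class_probs(maternal, selfing_rate, pollen_l_freq)
    counts = rng.multinomial(n_progeny, probs)
    return ProgenyArray(maternal_id=maternal_id, counts=tuple(counts),
                        family_size=n_progeny)


def read_progeny_arrays(path, family_size: int = 10) -> list[ProgenyArray]:
    """CSV with columns maternal_id, n_lobed, n_het, n_entire."""
    df = pd.read_csv(path, dtype={"maternal_id": str})
    return [
        ProgenyArray(row.maternal_id, (row.n_lobed, row.n_het, row.n_entire),
                     family_size=family_size)
        for row in df.itertuples()
    ]


def write_progeny_arrays(arrays: list[ProgenyArray], path) -> None:
    pd.DataFrame(
        [(a.maternal_id, *a.counts) for a in arrays],
        columns=["maternal_id", "n_lobed", "n_het", "n_entire"],
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Population-level summaries
# ---------------------------------------------------------------------------

def leaf_allele_frequencies(meta: pd.DataFrame) -> pd.DataFrame:
    """Per-population frequencies of the lobed (L) and entire (l) alleles.

    Individuals with unknown genotype are excluded; populations with no
    genotyped individual get an NA row.
    """
    rows = []
    for pop, grp in meta.groupby("population_id"):
        known = grp[grp["leaf_genotype"].isin(GENOTYPES)]
        n = len(known)
        if n == 0:
            rows.append((pop, np.nan, np.nan, 0))
            continue
        l_count = sum(_DOSAGE[g] for g in known["leaf_genotype"])
        freq_L = l_count / (2.0 * n)
        rows.append((pop, freq_L, 1.0 - freq_L, n))
    return pd.DataFrame(rows, columns=["population_id", "freq_L", "freq_l",
                                       "n_genotyped"]).set_index("population_id")


def leaf_snp_matrix(meta: pd.DataFrame) -> SnpMatrix:
    """Recode leaf genotypes as a one-SNP dosage matrix (count of L)."""
    known = meta[meta["leaf_genotype"].isin(GENOTYPES)]
    if known.empty:
        raise ValueError("no genotyped individuals")
    dosage = np.asarray([[_DOSAGE[g]] for g in known["leaf_genotype"]], dtype=np.int8)
    return SnpMatrix(
        snp_ids=[("leaf_shape", 0)], genotypes=dosage,
        allele_labels=[("l", "L")], individuals=list(known["individual_id"]),
    )


@dataclass
class LeafLocusSummary:
    allele_freqs: pd.DataFrame
    leaf_fst: float
    fis: float
    percentages: tuple[float, float, float]  # among pops / among ind / within ind
    fold_vs_background: float | None = None
    percentile_in_background: float | None = None


def leaf_locus_fst(meta: pd.DataFrame, background=None) -> LeafLocusSummary:
    """W&C FST at the leaf-shape locus, with its AMOVA-style variance split.

    ``background`` may be a per-SNP FST distribution (or plain array of FST
    values); when given, the summary reports the leaf locus's fold change
    over the background mean and its percentile in the background.
    """
    snps = leaf_snp_matrix(meta)
    known = meta[meta["leaf_genotype"].isin(GENOTYPES)]
    pops_with_data = known["population_id"].nunique()
    if pops_with_data < 2:
        raise ValueError("need >= 2 populations with genotyped individuals")
    labels = np.asarray(
        [dict(zip(meta["individual_id"], meta["population_id"]))[i]
         for i in snps.individuals], dtype=object,
    )
    a, b, c = _component_sums(snps.genotypes, labels)
    fst, fis, _ = _f_stats_from_sums(a, b, c)
    if not np.isfinite(fst):
        raise ValueError("leaf locus monomorphic overall: FST undefined")
    trunc = [max(x, 0.0) for x in (a, b, c)]
    tot = sum(trunc)
    pct = tuple(100.0 * x / tot for x in trunc)

    fold = percentile = None
    if background is not None:
        values = background.finite_values() if hasattr(background, "finite_values") \
            else np.asarray(background, dtype=float)
        values = values[np.isfinite(values)]
        mean_bg = float(values.mean())
        fold = fst / mean_bg if mean_bg > 0 else float("inf")
        percentile = outlier_percentile(values, fst)

    return LeafLocusSummary(
        allele_freqs=leaf_allele_frequencies(meta),
        leaf_fst=fst, fis=fis, percentages=pct,
        fold_vs_background=fold, percentile_in_background=percentile,
    )
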