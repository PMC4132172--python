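"""Orchestration: run the full analysis and assemble report tables.

``run_pipeline`` executes the modules in order (io -> diversity ->
neutrality -> differentiation -> clustering -> leaf shape), records every
setting and seed, and degrades gracefully: a block whose inputs are missing
(e.g. no leaf genotypes) is reported as absent in the error manifest while
the remaining blocks complete.

Replicate counts default to full analysis scale (9,999 permutations,
10,000 coalescent replicates); ``fast_profile`` drops them to 999 / 1,000
for desk-scale runs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from . import clustering as clus
from . import differentiation as diff
from . import leafshape as leaf
from . import neutrality as neut
from .diversity import (
    locus_diversity,
    pooled_multilocus,
    per_kb_differences,
    site_summary,
)
from .popdata import assign_regions, extract_snps

__all__ = ["AnalysisReport", "default_config", "fast_profile", "run_pipeline",
           "kruskal_wallis", "diversity_geography_regression"]


def default_config(**overrides) -> dict:
    cfg = {
        "boundary_latitude": None,  # required unless meta carries `region`
        "coalescent_reps": 10000,
        "permutations": 9999,
        "mantel_permutations": 9999,
        "cluster_ks": [1, 2, 3, 4, 5],
        "cluster_iterations": 20000,
        "cluster_burn_in": 2000,
        "cluster_chains": 1,
        "ld_alpha": 0.05,
        "seed": 0,
    }
    cfg.update(overrides)
    return cfg


def fast_profile(**overrides) -> dict:
    fast = {
        "coalescent_reps": 1000, "permutations": 999,
        "mantel_permutations": 999, "cluster_ks": [1, 2, 3],
        "cluster_iterations": 1500, "cluster_burn_in": 300,
    }
    fast.update(overrides)
    return default_config(**fast)


@dataclass
class AnalysisReport:
    per_population: pd.DataFrame | None = None
    global_stats: dict = field(default_factory=dict)
    ibd: dict = field(default_factory=dict)
    snp_fst: diff.SnpFstDistribution | None = None
    snp_fst_pruned: diff.SnpFstDistribution | None = None
    leaf_summary: leaf.LeafLocusSummary | None = None
    cluster_assignments: pd.DataFrame | None = None
    cluster_diagnostics: dict = field(default_factory=dict)
    group_tests: dict = field(default_factory=dict)
    settings: dict = field(default_factory=dict)
    errors: dict = field(default_factory=dict)

    def to_dir(self, outdir) -> Path:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        if self.per_population is not None:
            self.per_population.to_csv(out / "per_population.csv", index=False)
        if self.snp_fst is not None:
            pd.DataFrame({
                "snp": [f"{a}:{b}" for a, b in self.snp_fst.snp_ids],
                "fst": self.snp_fst.per_snp_fst,
                "p": self.snp_fst.per_snp_p
                if self.snp_fst.per_snp_p is not None else np.nan,
                "in_ld": self.snp_fst.ld_flags
                if self.snp_fst.ld_flags is not None else False,
            }).to_csv(out / "snp_fst.csv", index=False)
        if self.cluster_assignments is not None:
            self.cluster_assignments.to_csv(out / "cluster_assignments.csv",
                                            index=False)
        scalars = {
            "global_stats": _jsonable(self.global_stats),
            "ibd": _jsonable(self.ibd),
            "group_tests": _jsonable(self.group_tests),
            "cluster_diagnostics": _jsonable(self.cluster_diagnostics),
            "settings": _jsonable(self.settings),
            "errors": self.errors,
        }
        with open(out / "report.json", "w") as fh:
            json.dump(scalars, fh, indent=2, sort_keys=True, default=str)
        return out


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (pd.DataFrame, pd.Series)):
        return json.loads(obj.to_json())
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def kruskal_wallis(values, groups) -> tuple[float, int, float]:
    """Rank-based Kruskal-Wallis H with tie correction.

    Returns (H, df, p); identical values everywhere give H = 0, p = 1.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("need >= 2 groups")
    samples = [values[groups == g] for g in labels]
    if any(len(s) < 1 for s in samples):
        raise ValueError("every group needs >= 1 value")
    if np.all(values == values[0]):
        return 0.0, len(labels) - 1, 1.0
    h, p = sps.kruskal(*samples)
    return float(h), len(labels) - 1, float(p)


def diversity_geography_regression(per_pop: pd.DataFrame,
                                   responses=("theta_pi", "theta_w")) -> dict:
    """OLS of per-population diversity on latitude and longitude separately.

    ``per_pop`` needs columns latitude, longitude and the response columns.
    Also reports the latitude-longitude correlation of the sampled
    populations.
    """
    if len(per_pop) < 3:
        raise ValueError("need >= 3 populations")
    rows = []
    for resp in responses:
        for pred in ("latitude", "longitude"):
            x = per_pop[pred].to_numpy(dtype=float)
            if np.all(x == x[0]):
                raise ValueError(f"constant predictor {pred}")
            y = per_pop[resp].to_numpy(dtype=float)
            if np.all(y == y[0]):
                rows.append({"response": resp, "predictor": pred,
                             "slope": 0.0, "r2": 0.0, "F": 0.0, "p": 1.0})
                continue
            fit = sm.OLS(y, sm.add_constant(x)).fit()
            rows.append({
                "response": resp, "predictor": pred,
                "slope": float(fit.params[1]), "r2": float(fit.rsquared),
                "F": float(fit.fvalue), "p": float(fit.f_pvalue),
            })
    lat, lon = per_pop["latitude"], per_pop["longitude"]
    r = float(np.corrcoef(lat, lon)[0, 1])
    return {"regressions": pd.DataFrame(rows), "lat_lon_r2": r * r}


def run_pipeline(alignments, meta, annotations=None, progeny=None,
                 config: dict | None = None) -> AnalysisReport:
    """Run every analysis stage on one dataset.

    ``alignments`` must already be site-classified (the dataset readers do
    this); ``meta`` is the population table.  Partial failure of one block
    is recorded in ``report.errors`` and the rest completes.
    """
    cfg = default_config(**(config or {}))
    rng = np.random.default_rng(cfg["seed"])
    report = AnalysisReport(settings=dict(cfg))

    if "region" not in meta.columns:
        if cfg["boundary_latitude"] is None:
            raise ValueError(
                "config must set boundary_latitude (the clinal boundary is "
                "imported from prior work, never assumed)"
            )
        meta = assign_regions(meta, cfg["boundary_latitude"])

    # --- maternal genotypes from progeny arrays where metadata lacks them
    if progeny and (meta["leaf_genotype"] == "unknown").any():
        calls = {
            arr.maternal_id: leaf.infer_maternal_genotype(arr)[0]
            for arr in progeny if arr.total > 0
        }
        unknown = meta["leaf_genotype"] == "unknown"
        meta.loc[unknown, "leaf_genotype"] = [
            calls.get(i, "unknown") for i in meta.loc[unknown, "individual_id"]
        ]

    reps = cfg["coalescent_reps"]
    pops = list(pd.unique(meta["population_id"]))

    # --- per-population diversity + Tajima's D with coalescent nulls
    leaf_freqs = leaf.leaf_allele_frequencies(meta)
    rows = []
    per_pop_div = []
    for pop in pops:
        inds = meta.loc[meta["population_id"] == pop, "individual_id"].tolist()
        sub = [a.subset_individuals(inds) for a in alignments]
        est = pooled_multilocus(sub, scope=f"population:{pop}")
        d_parts = []
        for a in sub:
            summ = site_summary(a)
            d = neut.tajima_d_from_parts(summ.n_haplotypes, summ.s, summ.pi_total)
            if np.isfinite(d):
                d_parts.append((d, summ.n_haplotypes, summ.s))
        mean_d = float(np.mean([d for d, _, _ in d_parts])) if d_parts else np.nan
        sim_mean = pct_low = pct_high = np.nan
        if len(d_parts) >= 2:
            res = neut.multilocus_d_test(d_parts, reps=reps, seed=rng)
            sim_mean = res.sim_mean
            pct_low, pct_high = 100 * res.p_low, 100 * res.p_high
        grp = meta[meta["population_id"] == pop]
        rows.append({
            "population": pop,
            "latitude": float(grp["latitude"].mean()),
            "region": grp["region"].iloc[0],
            "freq_L": leaf_freqs.loc[pop, "freq_L"],
            "freq_l": leaf_freqs.loc[pop, "freq_l"],
            "theta_w": est.theta_w, "theta_pi": est.theta_pi,
            "tajima_d": mean_d, "sim_d": sim_mean,
            "pct_low": pct_low, "pct_high": pct_high,
        })
        per_pop_div.append({"population": pop, "theta_w": est.theta_w,
                            "theta_pi": est.theta_pi,
                            "latitude": float(grp["latitude"].mean()),
                            "longitude": float(grp["longitude"].mean()),
                            "region": grp["region"].iloc[0]})
    report.per_population = pd.DataFrame(rows).sort_values("latitude").reset_index(drop=True)
    per_pop_div = pd.DataFrame(per_pop_div)

    # --- global diversity and neutrality
    g = report.global_stats
    pooled = pooled_multilocus(alignments, scope="global")
    g["theta_w"] = pooled.theta_w
    g["theta_pi"] = pooled.theta_pi
    g["diff_per_kb"] = per_kb_differences(pooled.theta_pi)
    g["s_silent"] = pooled.s_silent

    summaries = [site_summary(a) for a in alignments]
    d_parts = [
        (neut.tajima_d_from_parts(s.n_haplotypes, s.s, s.pi_total),
         s.n_haplotypes, s.s)
        for s in summaries if s.s > 0
    ]
    d_parts = [(d, n, s) for d, n, s in d_parts if np.isfinite(d)]
    if len(d_parts) >= 2:
        res = neut.multilocus_d_test(d_parts, reps=reps, seed=rng)
        g["multilocus_d"] = res.observed
        g["multilocus_d_sim_mean"] = res.sim_mean
        g["multilocus_d_p_low"] = res.p_low
        g["multilocus_d_p_high"] = res.p_high

    # population-wide Fs and R2 on the concatenated multilocus data
    try:
        order = list(meta["individual_id"])
        total_s = sum(s.s for s in summaries)
        pi_tot = sum(s.pi_total for s in summaries)
        n_hap = summaries[0].n_haplotypes
        singles = np.sum([s.singletons for s in summaries], axis=0)
        # distinct multilocus haplotypes: concatenate per-locus rows in a
        # fixed individual order (between-locus phase is arbitrary)
        keys = None
        for a in alignments:
            rows_of: dict[str, list[int]] = {}
            for i, ind in enumerate(a.individuals):
                rows_of.setdefault(ind, []).append(i)
            row_order = [r for ind in order for r in rows_of[ind]]
            sub = ["".join(r) for r in a.sequences[row_order]]
            keys = sub if keys is None else [k + s for k, s in zip(keys, sub)]
        k_obs = len(set(keys))
        g["fu_fs"] = neut.fu_fs_from_parts(n_hap, k_obs, pi_tot)
        g["r2"] = neut.r2_from_parts(n_hap, total_s, pi_tot, singles)
        if total_s > 0:
            for stat, obs in (("fu_fs", g["fu_fs"]), ("r2", g["r2"])):
                res = neut.coalescent_pvalue(obs, stat, n_hap, total_s,
                                             reps=max(reps, 1000), seed=rng)
                g[f"{stat}_sim_mean"] = res.sim_mean
                g[f"{stat}_p_low"] = res.p_low
                g[f"{stat}_p_high"] = res.p_high
    except Exception as exc:  # pragma: no cover - defensive manifest
        report.errors["multilocus_haplotype_stats"] = repr(exc)

    # --- SNP matrix, AMOVA, selfing rate, per-SNP FST, LD, leaf contrast
    snps = extract_snps(alignments, meta)
    g["n_snps"] = snps.n_snps
    try:
        am = diff.amova(snps, meta, permutations=cfg["permutations"], seed=rng)
        g["amova_percentages"] = am.percentages
        g["fst"] = am.f_statistics["FST"]
        g["fis"] = am.f_statistics["FIS"]
        g["fit"] = am.f_statistics["FIT"]
        g["fst_p"] = am.p_values["fst"]
        g["fis_p"] = am.p_values["fis"]
        g["selfing_rate_pct"] = diff.selfing_rate_from_fis(max(g["fis"], 0.0))
    except Exception as exc:
        report.errors["amova"] = repr(exc)

    try:
        dist = diff.snp_fst_distribution(
            snps, meta, permutations=cfg["permutations"], seed=rng,
            ld_alpha=cfg["ld_alpha"],
        )
        report.snp_fst = dist
        g["snp_fst_median"] = float(np.nanmedian(dist.per_snp_fst))
        if dist.per_snp_p is not None:
            g["snp_fst_pct_significant"] = 100.0 * float(
                np.mean(dist.per_snp_p[np.isfinite(dist.per_snp_fst)] <= 0.05))
        if dist.ld_flags is not None and (~dist.ld_flags).any() \
                and dist.ld_flags.any():
            report.snp_fst_pruned = diff.prune_ld_and_recompute(dist)
    except Exception as exc:
        report.errors["snp_fst"] = repr(exc)

    try:
        report.leaf_summary = leaf.leaf_locus_fst(meta, background=report.snp_fst)
        g["leaf_fst"] = report.leaf_summary.leaf_fst
        g["leaf_fst_percentile"] = report.leaf_summary.percentile_in_background
        g["leaf_fold_vs_background"] = report.leaf_summary.fold_vs_background
    except Exception as exc:
        report.errors["leaf"] = repr(exc)

    # --- isolation by distance
    try:
        geo = diff.geographic_distance(meta)
        nei = diff.nei_distance(snps, meta).loc[geo.index, geo.index]
        fstm = diff.pairwise_fst_matrix(snps, meta).loc[geo.index, geo.index]
        lin = diff.linearized_fst(fstm)
        mp = cfg["mantel_permutations"]
        report.ibd = {
            name: vars(diff.mantel_test(mat, geo, permutations=mp, seed=rng))
            for name, mat in (("nei_d", nei), ("fst", fstm), ("lin_fst", lin))
        }
    except Exception as exc:
        report.errors["ibd"] = repr(exc)

    # --- clustering
    try:
        models = clus.fit_k_range(
            snps, cfg["cluster_ks"], iterations=cfg["cluster_iterations"],
            burn_in=cfg["cluster_burn_in"], seed=rng.integers(2**31),
            n_chains=cfg["cluster_chains"],
        )
        sel = clus.choose_k(models)
        report.cluster_diagnostics = {
            "k_min_dic": sel["k_min_dic"], "k_parsimony": sel["k_parsimony"],
            "dic_curve": sel["dic_curve"],
        }
        chosen = next(m for m in models if m.n_clusters == sel["k_parsimony"])
        q = chosen.admixture_
        asn = meta[["individual_id", "population_id", "latitude"]].copy()
        for k in range(q.shape[1]):
            asn[f"q{k + 1}"] = q[:, k]
        asn["modal_cluster"] = chosen.predict() + 1
        asn["inbreeding"] = chosen.inbreeding_
        report.cluster_assignments = asn.sort_values("latitude").reset_index(drop=True)
        g["mean_inbreeding_mcmc"] = float(np.mean(chosen.inbreeding_))
        g["selfing_rate_pct_mcmc"] = diff.selfing_rate_from_fis(
            float(np.clip(np.mean(chosen.inbreeding_), 0, 1)))
    except Exception as exc:
        report.errors["clustering"] = repr(exc)

    # --- group comparisons
    try:
        h, dfree, p = kruskal_wallis(per_pop_div["theta_pi"],
                                     per_pop_div["region"])
        report.group_tests["kw_region_theta_pi"] = {"H": h, "df": dfree, "p": p}
        report.group_tests.update(
            diversity_geography_regression(per_pop_div))
    except Exception as exc:
        report.errors["group_tests"] = repr(exc)

    return report
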