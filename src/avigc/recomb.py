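"""Join ortholog composition statistics to recombination-map windows.

Orthologs are assigned to the window with maximal bp overlap (ties to the
lower start coordinate). Per-window and per-chromosome-class summaries
reproduce the structure of correlation/Wilcoxon tables relating the
between-species standard deviation and mean of GC3 (and intronic GC) to
crossover rate and chromosome size class.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .traitstats import rank_correlation, wilcoxon_rank_sum

logger = logging.getLogger(__name__)


def assign_windows(locations: pd.DataFrame, recomb_map: pd.DataFrame,
                   reference: str | None = None) -> pd.DataFrame:
    """Ortholog -> recombination window by maximal overlap.

    ``locations``: ortholog_id, reference, chrom, start, end (0-based
    half-open). ``recomb_map``: chrom, start, end, rate_cm_mb with
    non-overlapping windows. Orthologs with no overlap are dropped (count
    logged). Returns ortholog_id, chrom, win_start, win_end, rate_cm_mb,
    overlap_bp.
    """
    if reference is not None:
        map_ref = recomb_map.attrs.get("reference")
        loc_refs = set(locations["reference"].unique())
        if map_ref is not None and map_ref not in loc_refs:
            raise ValueError(
                f"reference mismatch: map is {map_ref!r}, locations cover "
                f"{sorted(loc_refs)}")
        locations = locations[locations["reference"] == reference]
    rows = []
    dropped = 0
    by_chrom = {c: g.sort_values("start").reset_index(drop=True)
                for c, g in recomb_map.groupby("chrom")}
    for loc in locations.itertuples(index=False):
        wins = by_chrom.get(str(loc.chrom))
        if wins is None:
            dropped += 1
            continue
        starts = wins["start"].values
        ends = wins["end"].values
        ov = np.minimum(ends, loc.end) - np.maximum(starts, loc.start)
        ov = np.maximum(ov, 0)
        if ov.max() <= 0:
            dropped += 1
            continue
        best = int(np.argmax(ov))   # argmax takes the first = lowest start
        rows.append({"ortholog_id": loc.ortholog_id, "chrom": str(loc.chrom),
                     "win_start": int(starts[best]),
                     "win_end": int(ends[best]),
                     "rate_cm_mb": float(wins["rate_cm_mb"].iloc[best]),
                     "overlap_bp": int(ov[best])})
    if dropped:
        logger.info("assign_windows: %d orthologs had no overlapping window",
                    dropped)
    return (pd.DataFrame(rows,
                         columns=["ortholog_id", "chrom", "win_start",
                                  "win_end", "rate_cm_mb", "overlap_bp"])
            .sort_values("ortholog_id").reset_index(drop=True))


def ortholog_gc_summary(composition: pd.DataFrame,
                        column: str = "gc3") -> pd.DataFrame:
    """Per-ortholog between-species mean and sd (n-1) of a GC column."""
    per = (composition.dropna(subset=[column])
           .groupby("ortholog_id")[column].agg(["mean", "std", "count"])
           .rename(columns={"mean": f"{column}_mean", "std": f"{column}_sd",
                            "count": "n_species"}))
    return per[per["n_species"] >= 2].reset_index()


def window_statistics(join: pd.DataFrame, composition: pd.DataFrame,
                      intron_composition: pd.DataFrame | None = None,
                      min_introns: int = 10):
    """Per-ortholog GC3 dispersion joined to window rates, plus the
    sd/mean-vs-rate correlations (structure of the recombination table).

    Intronic per-window GC is pooled over the introns in a window and
    suppressed where the window holds fewer than ``min_introns`` introns.
    Returns (per_ortholog table, correlations table, per_window intron
    table or None).
    """
    per = ortholog_gc_summary(composition, "gc3")
    merged = join.merge(per, on="ortholog_id", how="inner")
    corr_rows = []
    for stat_col, label in (("gc3_sd", "sd_gc3"), ("gc3_mean", "mean_gc3")):
        if merged[stat_col].notna().sum() < 3:
            continue
        res = rank_correlation(merged[stat_col], merged["rate_cm_mb"],
                               "spearman")
        corr_rows.append({"statistic": label, "vs": "rate_cm_mb",
                          "rho": res.estimate, "p_value": res.p_value,
                          "n": res.n})
    intron_windows = None
    if intron_composition is not None:
        ij = join.merge(intron_composition, on="ortholog_id", how="inner")
        grp = ij.groupby(["chrom", "win_start", "win_end", "rate_cm_mb"])
        intron_windows = grp.apply(_pool_intron_gc, include_groups=False
                                   ).reset_index()
        n_ok = intron_windows["n_introns"] >= min_introns
        intron_windows.loc[~n_ok, ["gci_mean", "gci_sd"]] = np.nan
        ok = intron_windows.dropna(subset=["gci_mean"])
        for stat_col, label in (("gci_sd", "sd_gci"), ("gci_mean",
                                                       "mean_gci")):
            if len(ok) >= 3 and ok[stat_col].notna().sum() >= 3:
                res = rank_correlation(ok[stat_col], ok["rate_cm_mb"],
                                       "spearman")
                corr_rows.append({"statistic": label, "vs": "rate_cm_mb",
                                  "rho": res.estimate, "p_value": res.p_value,
                                  "n": res.n})
    correlations = pd.DataFrame(corr_rows)
    return merged, correlations, intron_windows


def _pool_intron_gc(g: pd.DataFrame) -> pd.Series:
    """Pooled (count-weighted) intronic GC for one window."""
    sites = g["gci_sites"].sum()
    gc = (g["gci"] * g["gci_sites"]).sum()
    per_gene = g.groupby("ortholog_id")["gci"].mean()
    return pd.Series({
        "n_introns": g["ortholog_id"].nunique(),
        "gci_mean": gc / sites if sites > 0 else np.nan,
        "gci_sd": per_gene.std() if len(per_gene) >= 2 else np.nan,
    })


def chromosome_class_compare(join: pd.DataFrame, composition: pd.DataFrame,
                             large_chroms=None, small_chroms=None,
                             column: str = "gc3") -> pd.DataFrame:
    """Median and sd of per-ortholog GC by chromosome size class, with a
    two-sided Wilcoxon rank-sum between classes.

    Defaults mirror chicken: large = chromosomes 1-9, small = 10 and up.
    Returns one row per (statistic) with small/large values and p.
    """
    if large_chroms is None:
        large_chroms = {str(i) for i in range(1, 10)}
    if small_chroms is None:
        small_chroms = {str(i) for i in range(10, 40)}
    large_chroms = {str(c) for c in large_chroms}
    small_chroms = {str(c) for c in small_chroms}
    per = ortholog_gc_summary(composition, column)
    merged = join.merge(per, on="ortholog_id", how="inner")
    cls = np.where(merged["chrom"].isin(large_chroms), "large",
                   np.where(merged["chrom"].isin(small_chroms), "small",
                            "other"))
    merged = merged.assign(chrom_class=cls)
    small = merged[merged["chrom_class"] == "small"]
    large = merged[merged["chrom_class"] == "large"]
    if small.empty or large.empty:
        raise ValueError("empty chromosome class")
    rows = []
    for stat_col, name in ((f"{column}_mean", f"median_{column}"),
                           (f"{column}_sd", f"sd_{column}")):
        _, p, flags = wilcoxon_rank_sum(small[stat_col].dropna(),
                                        large[stat_col].dropna())
        rows.append({
            "statistic": name,
            "small_median": float(small[stat_col].median()),
            "large_median": float(large[stat_col].median()),
            "small_sd": float(small[stat_col].std()),
            "large_sd": float(large[stat_col].std()),
            "wilcoxon_p": p, "flags": ";".join(flags),
            "n_small": int(small[stat_col].notna().sum()),
            "n_large": int(large[stat_col].notna().sum()),
        })
    return pd.DataFrame(rows)


def cross_map_correlation(join_a: pd.DataFrame, join_b: pd.DataFrame):
    """Spearman correlation of two maps' window rates over shared
    orthologs (a conservation-of-recombination check)."""
    merged = join_a.merge(join_b, on="ortholog_id", suffixes=("_a", "_b"))
    if len(merged) < 3:
        raise ValueError("fewer than 3 shared orthologs")
    return rank_correlation(merged["rate_cm_mb_a"], merged["rate_cm_mb_b"],
                            "spearman")
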