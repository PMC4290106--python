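"""GC content by codon position and for introns.

GC fractions are counts of G+C over counted (non-gap, non-N) sites; pooling
across orthologs sums counts before dividing, so short sequences do not
introduce noise. Also: ranking of orthologs by between-species GC3 variance
and a composition-homogeneity classifier.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import OrthologAlignment, C, G

logger = logging.getLogger(__name__)

CLASSES = ("c1", "c2", "c3", "c12", "c123", "intron")

_CLASS_COLUMN = {"c1": "gc1", "c2": "gc2", "c3": "gc3", "c12": "gc12",
                 "c123": "gc123", "intron": "gci"}


def _class_columns(cls: str, length: int) -> np.ndarray:
    if cls == "intron":
        return np.arange(length)
    offsets = {"c1": [0], "c2": [1], "c3": [2], "c12": [0, 1],
               "c123": [0, 1, 2]}[cls]
    cols = np.sort(np.concatenate([np.arange(o, length, 3) for o in offsets]))
    return cols


def gc_counts(aln: OrthologAlignment, cls: str) -> pd.DataFrame:
    """Per-species GC and counted-site counts over the selected columns.

    Gaps and N are excluded from both numerator and denominator; a codon
    containing a gap still contributes its non-gap positions.
    """
    if cls not in CLASSES:
        raise ValueError(f"unknown site class {cls!r}")
    if cls == "intron":
        if aln.kind != "intron":
            raise ValueError("class 'intron' requires an intron alignment")
    elif aln.kind != "coding":
        raise ValueError(f"class {cls!r} requires a coding alignment")
    codes = aln.codes()[:, _class_columns(cls, aln.length)]
    gc = ((codes == G) | (codes == C)).sum(axis=1)
    counted = (codes < 4).sum(axis=1)  # A,C,G,T only
    return pd.DataFrame({"species": aln.species, "gc": gc, "sites": counted},
                        ).set_index("species")


def gc_by_class(aln: OrthologAlignment, cls: str) -> pd.DataFrame:
    """Per-species (gc_fraction, counted_sites); zero counted sites -> NaN."""
    df = gc_counts(aln, cls)
    with np.errstate(invalid="ignore"):
        frac = np.where(df["sites"] > 0, df["gc"] / df["sites"], np.nan)
    return pd.DataFrame({"gc_fraction": frac, "sites": df["sites"]},
                        index=df.index)


def composition_table(alignments: list[OrthologAlignment]) -> pd.DataFrame:
    """Long-format per-(ortholog, species) composition table.

    Columns: ortholog_id, species, then for each class a fraction column
    (gc1 ... gci) and a site-count column (gc1_sites ...). The gc123 count
    identity (gc123 numerator = gc1+gc2+gc3 numerators) holds exactly.
    """
    rows = []
    for aln in alignments:
        classes = ("c1", "c2", "c3", "c12", "c123") if aln.kind == "coding" \
            else ("intron",)
        per_aln = {"ortholog_id": aln.ortholog_id}
        frames = {}
        for cls in classes:
            frames[cls] = gc_by_class(aln, cls)
        for sp in aln.species:
            row = {"ortholog_id": aln.ortholog_id, "species": sp}
            for cls in classes:
                col = _CLASS_COLUMN[cls]
                row[col] = frames[cls].loc[sp, "gc_fraction"]
                row[col + "_sites"] = int(frames[cls].loc[sp, "sites"])
            rows.append(row)
        del per_aln
    df = pd.DataFrame(rows)
    return df.sort_values(["ortholog_id", "species"]).reset_index(drop=True)


def universal_ortholog_set(alignments: list[OrthologAlignment],
                           roster: list[str] | None = None) -> list[str]:
    """Ids of orthologs containing every species (the comparison universe).

    The species universe is the union over all alignments unless an explicit
    roster is supplied.
    """
    if roster is None:
        roster = set()
        for aln in alignments:
            roster.update(aln.species)
    roster = set(roster)
    ids = sorted(a.ortholog_id for a in alignments
                 if roster.issubset(a.species))
    if not ids:
        warnings.warn("no ortholog contains all species", stacklevel=2)
    return ids


def pooled_gc(alignments: list[OrthologAlignment], cls: str,
              species: list[str] | None = None) -> pd.Series:
    """Per-species pooled GC over an ortholog set: counts summed across
    orthologs before division (length-weighted, not mean-of-fractions).

    Every alignment must contain every species considered; pre-filter with
    :func:`universal_ortholog_set`.
    """
    if not alignments:
        raise ValueError("empty ortholog set")
    if species is None:
        species = sorted(alignments[0].species)
    row_of = {sp: i for i, sp in enumerate(species)}
    gc = np.zeros(len(species))
    sites = np.zeros(len(species))
    for aln in alignments:
        absent = set(species) - set(aln.species)
        if absent:
            raise ValueError(
                f"{aln.ortholog_id}: species {sorted(absent)} absent; "
                "restrict to the universal ortholog set first")
        if cls == "intron" and aln.kind != "intron":
            raise ValueError("class 'intron' requires intron alignments")
        if cls != "intron" and aln.kind != "coding":
            raise ValueError(f"class {cls!r} requires coding alignments")
        codes = aln.codes()[:, _class_columns(cls, aln.length)]
        rows = np.array([row_of[sp] for sp in aln.species])
        np.add.at(gc, rows, ((codes == G) | (codes == C)).sum(axis=1))
        np.add.at(sites, rows, (codes < 4).sum(axis=1))
    with np.errstate(invalid="ignore"):
        out = np.where(sites > 0, gc / np.where(sites > 0, sites, 1),
                       np.nan)
    return pd.Series(out, index=pd.Index(species, name="species"),
                     name=_CLASS_COLUMN[cls])


@dataclass
class VariancePartition:
    """Orthologs ranked by between-species variance of GC3."""

    ranking: pd.DataFrame      # ortholog_id, variance (descending)
    high: list[str]
    low: list[str]
    k: int


def variance_partition(table: pd.DataFrame, k: int) -> VariancePartition:
    """Top-k / bottom-k orthologs by between-species sample variance of gc3.

    ``table`` is a long composition table with ortholog_id, species, gc3.
    Ties are broken by ortholog id (lexicographic) for determinism.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    var = (table.dropna(subset=["gc3"])
                .groupby("ortholog_id")["gc3"].agg(["var", "count"]))
    var = var[var["count"] >= 2]
    n = len(var)
    if 2 * k > n:
        raise ValueError(f"2k={2*k} exceeds number of rankable orthologs {n}")
    ranking = (var.rename(columns={"var": "variance"})
                  .reset_index()
                  .sort_values(["variance", "ortholog_id"],
                               ascending=[False, True], kind="mergesort")
                  .reset_index(drop=True))
    high = ranking["ortholog_id"].head(k).tolist()
    low = ranking["ortholog_id"].tail(k).sort_values().tolist()
    return VariancePartition(ranking=ranking[["ortholog_id", "variance"]],
                             high=sorted(high), low=sorted(low), k=k)


def classify_homogeneity(aln: OrthologAlignment, alpha: float = 0.01):
    """Label an ortholog 'homogenous' or 'non-homogenous' in third-position
    base composition across species.

    A species x {strong, weak} contingency chi-square on third-position
    counts (df = n_species - 1). This is an interface-compatible stand-in
    for a nonstationary-vs-stationary model comparison; the likelihood-ratio
    hook is left as an extension point.

    Returns (label, p_value, flags).
    """
    if aln.kind != "coding":
        raise ValueError("homogeneity classification requires a coding "
                         "alignment")
    cnt = gc_counts(aln, "c3")
    usable = cnt[cnt["sites"] > 0]
    dropped = set(cnt.index) - set(usable.index)
    if dropped:
        warnings.warn(f"{aln.ortholog_id}: species with zero counted third "
                      f"positions excluded: {sorted(dropped)}", stacklevel=2)
    if len(usable) < 2:
        raise ValueError(f"{aln.ortholog_id}: fewer than 2 usable species")
    table = np.column_stack([usable["gc"],
                             usable["sites"] - usable["gc"]]).astype(float)
    flags = []
    # degenerate margins: no information, cannot reject
    if (table.sum(axis=0) == 0).any():
        flags.append("degenerate")
        return "homogenous", 1.0, flags
    if table.sum() < 5 * len(usable):
        flags.append("low_count")
    with np.errstate(invalid="ignore", divide="ignore"):
        stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    label = "homogenous" if p >= alpha else "non-homogenous"
    return label, float(p), flags


def homogeneity_table(alignments: list[OrthologAlignment],
                      alpha: float = 0.01) -> pd.DataFrame:
    rows = []
    for aln in alignments:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                label, p, flags = classify_homogeneity(aln, alpha)
        except ValueError:
            label, p, flags = "unclassifiable", np.nan, ["error"]
        rows.append({"ortholog_id": aln.ortholog_id, "label": label,
                     "p_value": p, "flags": ";".join(flags)})
    return pd.DataFrame(rows).sort_values("ortholog_id").reset_index(drop=True)
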