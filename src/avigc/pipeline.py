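"""Pipeline orchestration: composition -> trait statistics -> gamma ->
ancestral Ne -> GC3* -> recombination joins, from a single configuration.

Every stage writes flat TSVs keyed by ortholog/species/branch ids, and no
stage recomputes another's statistics: the composition table is computed
once and reused. A machine-readable report (row counts, parameter echo,
seed, wall clock) accompanies the outputs; identical config + inputs give
byte-identical stage tables.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as aio
from . import composition as comp
from . import traitstats as ts
from . import coalescent as coal
from . import recomb as rc
from . import substitution as subst

logger = logging.getLogger(__name__)

ALL_STAGES = ("composition", "traits", "gamma", "ne", "gcstar", "recomb")


@dataclass
class RunConfig:
    """Validated inputs and parameters for a pipeline run."""

    out_dir: str
    coding_dir: str | None = None
    intron_dir: str | None = None
    species_tree: str | None = None
    gene_trees_dir: str | None = None
    traits: str | None = None
    timespans: str | None = None
    recomb_maps: dict = field(default_factory=dict)   # ref -> path
    locations: str | None = None
    stages: tuple = ALL_STAGES

    k: int = 830
    alpha: float = 0.01
    min_coal_length: float = 0.1
    min_support: float = 50.0
    min_introns: int = 10
    n_randomizations: int = 1000
    max_fit_genes: int = 150
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["stages"] = tuple(raw.get("stages", ALL_STAGES))
        return cls(**raw)

    def validate(self):
        need = {
            "composition": ["coding_dir"],
            "traits": ["coding_dir", "traits"],
            "gamma": ["coding_dir", "traits", "species_tree"],
            "ne": ["species_tree", "gene_trees_dir", "timespans"],
            "gcstar": ["coding_dir", "species_tree"],
            "recomb": ["coding_dir", "locations"],
        }
        for stage in self.stages:
            if stage not in ALL_STAGES:
                raise ValueError(f"unknown stage {stage!r}")
            for attr in need[stage]:
                if getattr(self, attr) is None:
                    raise ValueError(f"stage {stage!r} requires {attr!r}")
                if not Path(getattr(self, attr)).exists():
                    raise FileNotFoundError(
                        f"{attr} path {getattr(self, attr)!r} does not exist")
        if self.stages and "recomb" in self.stages and not self.recomb_maps:
            raise ValueError("stage 'recomb' requires recomb_maps")
        for ref, path in self.recomb_maps.items():
            if not Path(path).exists():
                raise FileNotFoundError(f"recombination map {path!r}")
        if self.k <= 0 or not 0 < self.alpha < 1 or self.min_introns < 0:
            raise ValueError("parameter out of range")


def _depths(tree):
    """Node depth in branch-length units above the tips (ultrametric)."""
    depth = {}
    for node in tree.postorder():
        if node.is_leaf:
            depth[id(node)] = 0.0
        else:
            depth[id(node)] = max(
                depth[id(c)] + (c.length or 0.0) for c in node.children)
    return depth


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in dependency order; returns the report."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(
        filename=out / "run.log", level=logging.INFO, force=True,
        format="%(asctime)s %(levelname)s %(name)s: %(message)s")
    logger.info("pipeline start; seed=%d; stages=%s", config.seed,
                ",".join(config.stages))
    report = {"stages": {}, "parameters": asdict(config),
              "seed": config.seed}
    state: dict = {}
    t0 = time.time()
    for stage in ALL_STAGES:
        if stage not in config.stages:
            continue
        t1 = time.time()
        try:
            rows = _STAGE_FN[stage](config, state, out)
            report["stages"][stage] = {
                "status": "completed", "rows": rows,
                "seconds": round(time.time() - t1, 2)}
            logger.info("stage %s completed (%s rows)", stage, rows)
        except Exception as exc:                     # abort dependents
            report["stages"][stage] = {"status": "failed",
                                       "error": str(exc)}
            logger.error("stage %s failed: %s", stage, exc)
            break
    report["wall_clock_s"] = round(time.time() - t0, 2)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def _load_composition(config, state):
    if "alignments" not in state:
        state["alignments"] = aio.read_alignment_dir(config.coding_dir,
                                                     "coding")
        state["introns"] = (aio.read_alignment_dir(config.intron_dir,
                                                   "intron")
                            if config.intron_dir else [])
    if "comp" not in state:
        state["comp"] = comp.composition_table(state["alignments"])
        state["comp_introns"] = (comp.composition_table(state["introns"])
                                 if state["introns"] else None)
        state["universal"] = comp.universal_ortholog_set(state["alignments"])
    return state


def _stage_composition(config, state, out):
    _load_composition(config, state)
    aio.write_table(state["comp"], out / "composition.tsv",
                    ["ortholog_id", "species"])
    universal = [a for a in state["alignments"]
                 if a.ortholog_id in set(state["universal"])]
    pooled = pd.DataFrame({
        cls: comp.pooled_gc(universal, cls)
        for cls in ("c1", "c2", "c3", "c12", "c123")})
    pooled.columns = ["gc1", "gc2", "gc3", "gc12", "gc123"]
    if state["introns"]:
        sp = set.intersection(*[set(a.species) for a in state["introns"]])
        pooled["gci"] = comp.pooled_gc(state["introns"], "intron",
                                       sorted(sp))
    state["pooled"] = pooled
    aio.write_table(pooled.reset_index(), out / "pooled_composition.tsv",
                    ["species"])
    if state["comp_introns"] is not None:
        aio.write_table(state["comp_introns"],
                        out / "composition_introns.tsv",
                        ["ortholog_id", "species"])
    n_universal = len(state["universal"])
    k = min(config.k, n_universal // 2)
    part = comp.variance_partition(
        state["comp"][state["comp"]["ortholog_id"].isin(
            set(state["universal"]))], k) if k >= 1 else None
    homog = comp.homogeneity_table(universal, config.alpha)
    if part is not None:
        ranking = part.ranking.copy()
        ranking["variance_class"] = np.where(
            ranking["ortholog_id"].isin(set(part.high)), "high",
            np.where(ranking["ortholog_id"].isin(set(part.low)), "low",
                     "mid"))
        ranking = ranking.merge(homog, on="ortholog_id", how="left")
        aio.write_table(ranking, out / "variance_ranking.tsv",
                        ["ortholog_id"])
        state["partition"] = part
    state["homogeneity"] = homog
    return len(state["comp"])


def _stage_traits(config, state, out):
    _load_composition(config, state)
    if "pooled" not in state:
        _stage_composition(config, state, out)
    traits = aio.read_trait_table(config.traits)
    pooled = state["pooled"]
    merged = pooled.join(traits.set_index("species")[
        ["body_mass_g", "max_longevity_yr", "age_first_maturity_yr"]])
    rows = []
    for gc_col in [c for c in ("gc1", "gc2", "gc3", "gci")
                   if c in merged.columns]:
        for trait in ("body_mass_g", "max_longevity_yr",
                      "age_first_maturity_yr"):
            try:
                res = ts.rank_correlation(merged[trait], merged[gc_col])
            except ValueError:
                continue
            rows.append({"gc": gc_col, "trait": trait,
                         "rho": res.estimate, "p_value": res.p_value,
                         "n": res.n})
    # phylogenetic control for the headline association
    if config.species_tree:
        tree = aio.read_tree(config.species_tree, "my")
        common = [sp for sp in tree.tip_labels
                  if sp in merged.index
                  and np.isfinite(merged.loc[sp, "body_mass_g"])
                  and np.isfinite(merged.loc[sp, "gc3"])]
        if len(common) == tree.n_tips and len(common) >= 4:
            pic = ts.contrasts_correlation(
                tree,
                {sp: np.log10(merged.loc[sp, "body_mass_g"])
                 for sp in common},
                {sp: merged.loc[sp, "gc3"] for sp in common})
            rows.append({"gc": "gc3_contrasts", "trait": "log_body_mass",
                         "rho": pic.estimate, "p_value": pic.p_value,
                         "n": pic.n})
    corr = pd.DataFrame(rows)
    aio.write_table(corr, out / "trait_correlations.tsv", ["gc", "trait"])
    state["trait_correlations"] = corr
    state["traits_table"] = traits

    # homogenous-subset randomization: is the weaker correlation in the
    # homogenous set explained by its size alone?
    homog = state.get("homogeneity")
    rand_rows = []
    if homog is not None and "body_mass_g" in merged.columns:
        hom_ids = homog.loc[homog["label"] == "homogenous", "ortholog_id"]
        non_ids = homog.loc[homog["label"] == "non-homogenous",
                            "ortholog_id"].tolist()
        universal = {a.ortholog_id: a for a in state["alignments"]
                     if a.ortholog_id in set(state["universal"])}
        mass = merged["body_mass_g"]

        def rho_of_subset(ids):
            pooled_sub = comp.pooled_gc([universal[i] for i in ids], "c3")
            res = ts.rank_correlation(mass, pooled_sub.reindex(mass.index))
            return res.estimate

        if len(hom_ids) >= 3 and len(non_ids) >= len(hom_ids):
            observed = rho_of_subset(hom_ids.tolist())
            p, _ = ts.subset_randomization(
                non_ids, len(hom_ids), observed,
                config.n_randomizations, config.seed, rho_of_subset,
                direction="ge")   # less negative = weaker than observed?
            rand_rows.append({"test": "homogenous_subset", "observed_rho":
                              observed, "p_value": p,
                              "n_reps": config.n_randomizations})
    if rand_rows:
        aio.write_table(pd.DataFrame(rand_rows),
                        out / "randomization.tsv", ["test"])
    return len(corr)


def _stage_gamma(config, state, out):
    _load_composition(config, state)
    tree = aio.read_tree(config.species_tree, "my")
    depth = _depths(tree)
    tipsets = {}
    cand = []
    for node in tree.postorder():
        if node.is_leaf:
            tipsets[id(node)] = [node.label]
            continue
        tipsets[id(node)] = sum((tipsets[id(c)] for c in node.children), [])
        for i, c1 in enumerate(node.children):
            for c2 in node.children[i + 1:]:
                for a in tipsets[id(c1)]:
                    for b in tipsets[id(c2)]:
                        cand.append({"species_a": a, "species_b": b,
                                     "t": depth[id(node)]})
    pairs = ts.select_independent_pairs(pd.DataFrame(cand),
                                        min_t=1e-9)
    comp_tab = state["comp"]
    part = state.get("partition")
    if part is not None:
        use_ids = set(part.high)          # highest-variance orthologs
    else:
        use_ids = set(state["universal"])
    sub = comp_tab[comp_tab["ortholog_id"].isin(use_ids)]
    gc3 = sub.pivot_table(index="ortholog_id", columns="species",
                          values="gc3")
    traits = state.get("traits_table")
    rows = []
    for row in pairs.itertuples(index=False):
        try:
            pc = ts.gc3_conservation_index(gc3[row.species_a],
                                           gc3[row.species_b],
                                           t=row.t,
                                           species_a=row.species_a,
                                           species_b=row.species_b)
        except (ValueError, KeyError):
            continue
        rec = {"species_a": pc.species_a, "species_b": pc.species_b,
               "t_my": pc.t, "tau": pc.tau, "gamma": pc.gamma,
               "n_genes": pc.n_genes, "flags": ";".join(pc.flags)}
        if traits is not None:
            m = traits.set_index("species")["body_mass_g"]
            rec["pair_mean_mass_g"] = float(np.nanmean(
                [m.get(pc.species_a, np.nan), m.get(pc.species_b, np.nan)]))
        rows.append(rec)
    gdf = pd.DataFrame(rows)
    if len(gdf) >= 3 and "pair_mean_mass_g" in gdf.columns:
        ok = gdf[np.isfinite(gdf["gamma"])
                 & np.isfinite(gdf["pair_mean_mass_g"])]
        if len(ok) >= 3:
            res = ts.rank_correlation(ok["pair_mean_mass_g"], ok["gamma"])
            gdf.attrs["mass_gamma_rho"] = res.estimate
            aio.write_table(pd.DataFrame([{
                "test": "gamma_vs_pair_mass", "rho": res.estimate,
                "p_value": res.p_value, "n": res.n}]),
                out / "gamma_mass_correlation.tsv", ["test"])
    aio.write_table(gdf, out / "gamma_pairs.tsv",
                    ["species_a", "species_b"])
    state["gamma"] = gdf
    return len(gdf)


def _stage_ne(config, state, out):
    species_tree = aio.read_tree(config.species_tree, "my")
    gene_trees = aio.read_tree_dir(config.gene_trees_dir)
    if not gene_trees:
        raise ValueError(f"no gene trees in {config.gene_trees_dir}")
    stats = coal.coalescent_branch_lengths(species_tree, gene_trees)
    timespans = aio.read_timespan_table(config.timespans)
    table = coal.ne_table(stats, timespans)
    kept = coal.filter_branches(stats, config.min_coal_length,
                                config.min_support, cherry_only=True)
    table["passes_filters"] = table["branch_id"].isin(
        {r.branch_id for r in kept})
    aio.write_table(table, out / "ancestral_ne.tsv", ["branch_id"])
    state["ne_table"] = table
    # descendant GC3 vs N for filtered cherries, if composition available
    if "pooled" in state:
        tree_nodes = {coal.branch_id(n): n
                      for n in species_tree.postorder() if not n.is_leaf}
        pooled = state["pooled"]["gc3"]
        rows = []
        for r in kept:
            node = tree_nodes.get(r.branch_id)
            if node is None:
                continue
            desc = [t.label for t in node.children if t.is_leaf]
            vals = pooled.reindex(desc).dropna()
            n_hat = table.set_index("branch_id")["n_hat"].get(r.branch_id)
            if len(vals) and np.isfinite(n_hat):
                rows.append({"branch_id": r.branch_id, "n_hat": n_hat,
                             "descendant_gc3": float(vals.mean())})
        if len(rows) >= 3:
            df = pd.DataFrame(rows)
            res = ts.rank_correlation(df["n_hat"], df["descendant_gc3"])
            aio.write_table(pd.DataFrame([{
                "test": "ne_vs_descendant_gc3", "rho": res.estimate,
                "p_value": res.p_value, "n": res.n}]),
                out / "ne_gc3_correlation.tsv", ["test"])
    return len(table)


def _stage_gcstar(config, state, out):
    _load_composition(config, state)
    if "pooled" not in state:
        _stage_composition(config, state, out)
    tree = aio.read_tree(config.species_tree, "my")
    universal = [a for a in state["alignments"]
                 if a.ortholog_id in set(state["universal"])]
    rng = np.random.default_rng(config.seed)
    if len(universal) > config.max_fit_genes:
        pick = rng.choice(len(universal), config.max_fit_genes,
                          replace=False)
        universal = [universal[i] for i in sorted(pick)]
    taxa = sorted(set.intersection(*[set(a.species) for a in universal]))
    from .composition import _class_columns
    blocks = [a.codes(taxa)[:, _class_columns("c3", a.length)]
              for a in universal]
    codes = np.concatenate(blocks, axis=1)
    model = subst.T92Model(codes, taxa, tree)
    fit = model.fit(estimate_scale=True)
    (out / "t92_fit.txt").write_text(fit.summary() + "\n")
    counts = fit.map_substitutions()
    star = subst.gc3_star(counts, "per_tip_root_path")
    gc3 = state["pooled"]["gc3"]
    side = pd.DataFrame({"gc3_star": star, "gc3": gc3}).dropna()
    slope = np.nan
    if len(side) >= 3 and side["gc3"].var() > 0:
        slope = float(np.polyfit(side["gc3"], side["gc3_star"], 1)[0])
    side = side.reset_index().rename(columns={"index": "species"})
    aio.write_table(side, out / "gc3_star.tsv", ["species"])
    aio.write_table(counts.table, out / "branch_substitutions.tsv",
                    ["branch_id"])
    with open(out / "gc3_star_summary.json", "w") as fh:
        json.dump({"theta": fit.theta, "kappa": fit.kappa,
                   "scale": fit.scale, "slope_star_on_gc3": slope,
                   "frac_star_above_gc3": float(
                       (side["gc3_star"] > side["gc3"]).mean())}, fh,
                  indent=2)
    state["gc3_star"] = side
    return len(side)


def _stage_recomb(config, state, out):
    _load_composition(config, state)
    locations = aio.read_locations(config.locations)
    joins = {}
    for ref, path in config.recomb_maps.items():
        rmap = aio.read_recomb_map(path, reference=ref)
        join = rc.assign_windows(locations, rmap, reference=ref)
        joins[ref] = join
        per, corr, intron_windows = rc.window_statistics(
            join, state["comp"], state.get("comp_introns"),
            config.min_introns)
        aio.write_table(per, out / f"window_join_{ref}.tsv",
                        ["ortholog_id"])
        aio.write_table(corr, out / f"window_correlations_{ref}.tsv",
                        ["statistic"])
        classes = rc.chromosome_class_compare(join, state["comp"])
        aio.write_table(classes, out / f"chromosome_classes_{ref}.tsv",
                        ["statistic"])
    if len(joins) >= 2:
        refs = sorted(joins)
        res = rc.cross_map_correlation(joins[refs[0]], joins[refs[1]])
        aio.write_table(pd.DataFrame([{
            "test": f"rate_{refs[0]}_vs_{refs[1]}", "rho": res.estimate,
            "p_value": res.p_value, "n": res.n}]),
            out / "cross_map_correlation.tsv", ["test"])
    return sum(len(j) for j in joins.values())


_STAGE_FN = {
    "composition": _stage_composition,
    "traits": _stage_traits,
    "gamma": _stage_gamma,
    "ne": _stage_ne,
    "gcstar": _stage_gcstar,
    "recomb": _stage_recomb,
}
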