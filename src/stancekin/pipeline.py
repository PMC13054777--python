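"""Orchestration of the full stance-phase analysis.

Stages: per-species angular metrics -> descriptive tables -> factor-wise
group tests -> correlations -> AUI quadrant analysis -> phylogenetic checks
(PGLS of TAE and AUI% on log10 body mass; phylogenetic ANOVA of TAE by
posture). Each stage is a plain function over DataFrames so it can be used
from Python or through the CLI; `run_full` wires them together, logs every
exclusion and writes a manifest so a run is reproducible byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .errors import ConfigError, StanceKinError
from .io import read_species_table, write_csv
from .kinematics import (
    FORELIMB_JOINTS,
    HINDLIMB_JOINTS,
    JOINTS,
    SpeciesRecord,
    summarize_limb,
)
from .phylo import Phylogeny, parse_newick, pgls_fit, phyl_anova
from .quadrants import assign_quadrants, quadrant_enrichment
from .stats import (
    GroupedSample,
    kruskal_dunn,
    levene_median,
    pearson_ci,
    posthoc_pairwise,
    welch_anova,
)

log = logging.getLogger(__name__)

FACTORS = ("posture", "mass_class", "speed_class", "habit")
LIMB_SUFFIX = {"forelimb": "fore", "hindlimb": "hind"}


@dataclass
class RunConfig:
    species_table: Path
    out_dir: Path
    tree: Optional[Path] = None
    omnibus: str = "welch"  # welch | kruskal
    alpha: float = 0.05
    n_sim: int = 1000
    seed: int = 0
    ci_level: float = 0.95
    stride_norm_exponent: float = 1.0 / 3.0
    run_phylo: bool = True

    def __post_init__(self):
        self.species_table = Path(self.species_table)
        self.out_dir = Path(self.out_dir)
        if self.tree is not None:
            self.tree = Path(self.tree)
        if not (0 < self.alpha < 1) or not (0 < self.ci_level < 1):
            raise ConfigError("alpha and ci_level must lie in (0, 1)")
        if self.omnibus not in ("welch", "kruskal"):
            raise ConfigError("omnibus must be 'welch' or 'kruskal'")


# ---------------------------------------------------------------------------
# metrics stage
# ---------------------------------------------------------------------------

def compute_metrics(records: Sequence[SpeciesRecord]) -> pd.DataFrame:
    """Per species x limb: JAE per joint, sum JAE, TAE, AUI%, relative JAE."""
    rows = []
    for rec in records:
        for limb in ("forelimb", "hindlimb"):
            lr = rec.limb(limb)
            if lr is None:
                continue
            s = summarize_limb(lr)
            row = {
                "species": rec.species_id,
                "limb": limb,
                "body_mass_kg": rec.body_mass_kg,
                "log10_mass": math.log10(rec.body_mass_kg),
                "posture": rec.posture,
                "mass_class": rec.mass_class,
                "speed_class": rec.speed_class,
                "habit": rec.habit,
                "stride_length": rec.stride_length,
                "sum_jae": s.sum_jae,
                "tae": s.tae,
                "aui_pct": s.aui_pct,
            }
            for j, v in s.jae_per_joint.items():
                row[f"jae_{j}"] = v
            for j, v in s.relative_jae_pct.items():
                row[f"rel_jae_{j}"] = v
            rows.append(row)
    return pd.DataFrame(rows)


def species_event_angles(records: Sequence[SpeciesRecord]) -> pd.DataFrame:
    """Long table of raw event angles: species, joint, event, angle."""
    rows = []
    for rec in records:
        for limb in ("forelimb", "hindlimb"):
            lr = rec.limb(limb)
            if lr is None:
                continue
            for pose in lr.poses:
                for ev, angle in pose.angles.items():
                    if angle is not None:
                        rows.append(
                            {"species": rec.species_id, "joint": pose.joint_name,
                             "event": ev, "angle": angle}
                        )
    return pd.DataFrame(rows)


def table1_like(records: Sequence[SpeciesRecord], metrics: pd.DataFrame) -> pd.DataFrame:
    """Per-joint descriptives: mean +/- SD of TD/MS/TO angles, JAE, relative JAE."""
    angles = species_event_angles(records)
    rows = []
    for joint in JOINTS:
        jcol = f"jae_{joint}"
        sub = metrics[metrics[jcol].notna()] if jcol in metrics else pd.DataFrame()
        row: dict = {"joint": joint, "n": int(len(sub))}
        for ev in ("td", "ms", "to"):
            vals = angles[(angles["joint"] == joint) & (angles["event"] == ev)]["angle"]
            row[f"mean_{ev}"] = vals.mean() if len(vals) else np.nan
            row[f"sd_{ev}"] = vals.std(ddof=1) if len(vals) > 1 else np.nan
        row["mean_jae"] = sub[jcol].mean() if len(sub) else np.nan
        row["sd_jae"] = sub[jcol].std(ddof=1) if len(sub) > 1 else np.nan
        rcol = f"rel_jae_{joint}"
        rel = metrics[metrics.get(rcol, pd.Series(dtype=float)).notna()] if rcol in metrics else pd.DataFrame()
        row["mean_rel_jae"] = rel[rcol].mean() if len(rel) else np.nan
        row["sd_rel_jae"] = rel[rcol].std(ddof=1) if len(rel) > 1 else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def table2_like(metrics: pd.DataFrame) -> pd.DataFrame:
    """Per factor x category x limb: mean +/- SD (with n) of TAE, sum JAE, AUI%."""
    rows = []
    for factor in FACTORS:
        for limb in ("forelimb", "hindlimb"):
            sub = metrics[(metrics["limb"] == limb) & metrics[factor].notna()]
            for cat, grp in sub.groupby(factor, observed=True):
                row = {"factor": factor, "category": cat, "limb": limb}
                for mcol in ("tae", "sum_jae", "aui_pct"):
                    vals = grp[mcol].dropna()
                    row[f"n_{mcol}"] = int(len(vals))
                    row[f"mean_{mcol}"] = vals.mean() if len(vals) else np.nan
                    row[f"sd_{mcol}"] = vals.std(ddof=1) if len(vals) > 1 else np.nan
                rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# group tests stage
# ---------------------------------------------------------------------------

def run_group_tests(
    metrics: pd.DataFrame,
    omnibus: str = "welch",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Factor-wise omnibus + post hoc tests for TAE, sum JAE and AUI% per limb.

    Tidy output: one omnibus row per metric x factor x limb (empty pair
    columns) followed by its pairwise rows. Groups with n < 2 are dropped;
    metrics with fewer than two usable groups are skipped with a log entry.
    """
    rows = []
    for metric in ("tae", "sum_jae", "aui_pct"):
        for limb in ("forelimb", "hindlimb"):
            for factor in FACTORS:
                sub = metrics[(metrics["limb"] == limb)][[factor, metric]].dropna()
                groups = [
                    (str(cat), grp[metric].to_numpy())
                    for cat, grp in sub.groupby(factor, observed=True)
                    if len(grp) >= 2 and np.var(grp[metric].to_numpy()) > 0
                ]
                if len(groups) < 2:
                    log.info("group test skipped: %s %s by %s (too few groups)",
                             limb, metric, factor)
                    continue
                sample = GroupedSample(factor_name=factor, groups=groups)
                base = {"metric": metric, "limb": limb, "factor": factor}
                if omnibus == "welch":
                    res = welch_anova(sample)
                    _, p_lev = levene_median(sample)
                    homog = p_lev >= alpha
                    pairwise = posthoc_pairwise(sample, variance_homogeneous=homog)
                    method = "welch_anova+" + ("tukey_hsd" if homog else "dunnett_t3")
                else:
                    res = kruskal_dunn(sample)
                    pairwise = res.pairwise
                    method = "kruskal_wallis+dunn"
                rows.append({
                    **base, "method": method, "statistic": res.statistic,
                    "df1": res.df1, "df2": res.df2, "p": res.p_value,
                    "pair_a": "", "pair_b": "", "p_adj": np.nan,
                })
                for pw in pairwise:
                    rows.append({
                        **base, "method": method, "statistic": pw.statistic,
                        "df1": np.nan, "df2": np.nan, "p": np.nan,
                        "pair_a": pw.label_a, "pair_b": pw.label_b,
                        "p_adj": pw.p_adjusted,
                    })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# correlations stage
# ---------------------------------------------------------------------------

def run_correlations(
    metrics: pd.DataFrame,
    ci_level: float = 0.95,
    stride_norm_exponent: float = 1.0 / 3.0,
    stratify_by: Sequence[str] = (),
) -> pd.DataFrame:
    """Pearson correlations of excursion metrics with mass and stride length.

    Pairs: each joint JAE vs log10 mass; TAE vs log10 mass; each joint JAE vs
    stride length and vs mass-normalized stride length
    (stride / mass^exponent). Optionally stratified by factors. Pairs with
    fewer than 4 complete observations are skipped and logged.
    """
    rows = []

    def corr(frame: pd.DataFrame, xcol: str, ycol: str, stratum: str):
        pair = frame[[xcol, ycol]].dropna()
        n = len(pair)
        if n < 4 or pair[xcol].nunique() < 2 or pair[ycol].nunique() < 2:
            log.info("correlation skipped: %s vs %s [%s] (n=%d)", ycol, xcol, stratum, n)
            return
        r, lo, hi, p = pearson_ci(pair[xcol], pair[ycol], level=ci_level)
        rows.append({"x": xcol, "y": ycol, "stratum": stratum, "n": n,
                     "r": r, "ci_lo": lo, "ci_hi": hi, "p": p})

    frame = metrics.copy()
    if "stride_length" in frame and frame["stride_length"].notna().any():
        frame["stride_norm"] = frame["stride_length"] / (
            frame["body_mass_kg"] ** stride_norm_exponent
        )
    strata: list[tuple[str, pd.DataFrame]] = [("all", frame)]
    for factor in stratify_by:
        for cat, grp in frame.groupby(factor, observed=True):
            strata.append((f"{factor}={cat}", grp))

    for name, f in strata:
        for limb, joints in (("forelimb", FORELIMB_JOINTS), ("hindlimb", HINDLIMB_JOINTS)):
            sub = f[f["limb"] == limb]
            for joint in joints:
                corr(sub, "log10_mass", f"jae_{joint}", name)
                if "stride_length" in sub:
                    corr(sub, "stride_length", f"jae_{joint}", name)
                if "stride_norm" in sub:
                    corr(sub, "stride_norm", f"jae_{joint}", name)
            corr(sub, "log10_mass", "tae", name)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# quadrant stage
# ---------------------------------------------------------------------------

def run_quadrants(metrics: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame, list[dict]]:
    """Quadrant assignments and factor-wise contingency tests.

    Returns (quadrants table, tests table, exclusions).
    """
    wide = metrics.pivot_table(
        index="species", columns="limb", values="aui_pct", aggfunc="first"
    )
    aui_by_species = {
        sp: (
            wide.loc[sp].get("forelimb") if not pd.isna(wide.loc[sp].get("forelimb", np.nan)) else None,
            wide.loc[sp].get("hindlimb") if not pd.isna(wide.loc[sp].get("hindlimb", np.nan)) else None,
        )
        for sp in wide.index
    }
    assignments, excluded = assign_quadrants(aui_by_species)
    exclusions = [
        {"species": sp, "stage": "quadrants", "reason": "missing limb AUI"}
        for sp in excluded
    ]
    qdf = pd.DataFrame(
        [{"species": a.species_id, "fl_aui": a.fl_aui, "hl_aui": a.hl_aui,
          "quadrant": a.quadrant} for a in assignments]
    ).sort_values("species").reset_index(drop=True)

    factor_of = (
        metrics.drop_duplicates("species").set_index("species")[list(FACTORS)]
    )
    test_rows = []
    for factor in FACTORS:
        levels = factor_of[factor].dropna().to_dict()
        usable = [a for a in assignments if a.species_id in levels]
        if len({levels[a.species_id] for a in usable}) < 2:
            log.info("quadrant test skipped for %s (single category)", factor)
            continue
        table = quadrant_enrichment(usable, levels, factor)
        for e in table.enrichments:
            test_rows.append({
                "factor": factor, "chi2": table.chi2, "df": table.df, "p": table.p,
                "category": e.category, "quadrant": e.quadrant, "n": e.count,
                "odds_ratio": e.odds_ratio, "fisher_p": e.fisher_p,
                "direction": e.direction,
            })
    return qdf, pd.DataFrame(test_rows), exclusions


# ---------------------------------------------------------------------------
# phylogenetic stage
# ---------------------------------------------------------------------------

def run_pgls(
    metrics: pd.DataFrame, tree: Phylogeny
) -> tuple[pd.DataFrame, list[dict]]:
    """PGLS (lambda = 1) of TAE and AUI% on log10 body mass, per limb."""
    rows, exclusions = [], []
    for limb in ("forelimb", "hindlimb"):
        suffix = LIMB_SUFFIX[limb]
        sub = metrics[metrics["limb"] == limb].set_index("species")
        for metric in ("tae", "aui_pct"):
            usable = sub[sub[metric].notna() & sub["log10_mass"].notna()]
            keep = [sp for sp in usable.index if sp in tree.tip_labels]
            dropped = set(usable.index) - set(keep)
            for sp in sorted(dropped):
                exclusions.append({"species": sp, "stage": "pgls",
                                   "reason": "not in tree"})
            if len(keep) < 4:
                log.info("pgls skipped: %s %s (n=%d)", limb, metric, len(keep))
                continue
            sub_tree = tree.prune_to(keep)
            order = list(sub_tree.tip_labels)
            C = sub_tree.bm_covariance(perturb_zero_length=True)
            fit = pgls_fit(
                usable.loc[order, metric].to_numpy(),
                usable.loc[order, "log10_mass"].to_numpy(),
                C,
            )
            rows.append({
                "response": f"{metric}_{suffix}", "predictor": "log10_mass",
                "n": fit.n, "slope": fit.slope, "intercept": fit.intercept,
                "se_slope": fit.se_slope, "t": fit.t_stat, "df": fit.df,
                "p": fit.p, "r2": fit.r2, "lambda": fit.lam,
            })
    return pd.DataFrame(rows), exclusions


def run_phylanova(
    metrics: pd.DataFrame,
    tree: Phylogeny,
    factor: str = "posture",
    n_sim: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Phylogenetic ANOVA of TAE by a factor (default posture), per limb."""
    rows = []
    for i, limb in enumerate(("forelimb", "hindlimb")):
        sub = metrics[(metrics["limb"] == limb) & metrics["tae"].notna()]
        sub = sub[sub[factor].notna()].set_index("species")
        keep = [sp for sp in sub.index if sp in tree.tip_labels]
        if len(keep) < 4 or sub.loc[keep, factor].nunique() < 2:
            log.info("phylanova skipped for %s (insufficient data)", limb)
            continue
        sub_tree = tree.prune_to(keep)
        order = list(sub_tree.tip_labels)
        res = phyl_anova(
            sub.loc[order, "tae"].to_dict(),
            sub.loc[order, factor].to_dict(),
            sub_tree,
            n_sim=n_sim,
            rng=np.random.default_rng([seed, i]),
        )
        base = {"response": f"tae_{LIMB_SUFFIX[limb]}", "factor": factor,
                "n_sim": res.n_sim}
        rows.append({**base, "f_obs": res.f_obs, "df1": res.df1, "df2": res.df2,
                     "p_phyl": res.p_phyl, "pair_a": "", "pair_b": "",
                     "t": np.nan, "p_adj": np.nan})
        for a, b, t, p_adj in res.pairwise:
            rows.append({**base, "f_obs": np.nan, "df1": np.nan, "df2": np.nan,
                         "p_phyl": np.nan, "pair_a": a, "pair_b": b,
                         "t": t, "p_adj": p_adj})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# full run
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_full(config: RunConfig) -> Path:
    """Execute all stages, write every output table, the exclusion log and a
    manifest. Re-running with the same config and inputs reproduces every
    output byte for byte."""
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    if not config.species_table.exists():
        raise ConfigError(f"species table not found: {config.species_table}")
    tree = None
    if config.run_phylo:
        if config.tree is None or not config.tree.exists():
            raise ConfigError("phylogenetic stage requested but no tree file")
        tree = parse_newick(config.tree.read_text())

    records, exclusions = read_species_table(config.species_table)
    if not records:
        raise StanceKinError("no usable species records")

    metrics = compute_metrics(records)
    write_csv(metrics, out / "metrics.csv")
    write_csv(table1_like(records, metrics), out / "table1_like.csv")
    write_csv(table2_like(metrics), out / "table2_like.csv")

    write_csv(
        run_group_tests(metrics, omnibus=config.omnibus, alpha=config.alpha),
        out / "group_tests.csv",
    )
    write_csv(
        run_correlations(
            metrics,
            ci_level=config.ci_level,
            stride_norm_exponent=config.stride_norm_exponent,
        ),
        out / "correlations.csv",
    )
    qdf, qtests, q_excl = run_quadrants(metrics)
    exclusions += q_excl
    write_csv(qdf, out / "quadrants.csv")
    write_csv(qtests, out / "quadrant_tests.csv")

    if tree is not None:
        pgls_df, p_excl = run_pgls(metrics, tree)
        exclusions += p_excl
        write_csv(pgls_df, out / "pgls.csv")
        write_csv(
            run_phylanova(metrics, tree, n_sim=config.n_sim, seed=config.seed),
            out / "phylanova.csv",
        )

    write_csv(pd.DataFrame(exclusions, columns=["species", "stage", "reason"]),
              out / "exclusions.csv")

    manifest = {
        "package": "stancekin",
        "version": __version__,
        "seed": config.seed,
        "omnibus": config.omnibus,
        "alpha": config.alpha,
        "ci_level": config.ci_level,
        "n_sim": config.n_sim,
        "stride_norm_exponent": config.stride_norm_exponent,
        "inputs": {
            "species_table": _sha256(config.species_table),
            "tree": _sha256(config.tree) if tree is not None else None,
        },
        "outputs": sorted(p.name for p in out.glob("*.csv")),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return out
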