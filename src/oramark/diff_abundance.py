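"""Rank-wise aggregation, Wilcoxon screening, LDA effect-size scoring and
disease-activity trend tests.

The screening protocol mirrors the common 16S case-control recipe: sum
counts to a taxonomic rank, convert to relative abundance, test each
taxon with a two-sided Wilcoxon rank-sum test (exact enumeration for
small tie-free groups, otherwise normal approximation with midranks and
tie-corrected variance) and flag taxa at raw p < alpha.  No
multiple-testing correction is applied by default; Benjamini-Hochberg
adjusted p-values are available by flag.

The LDA effect-size score is a simplified two-class LEfSe: a
Kruskal-Wallis screen at p < 0.05 followed by bootstrapped
one-dimensional linear-discriminant effect sizes on abundances scaled
to [0, 1e6], reported as log10 and thresholded (3 by default, the
threshold used for tongue-coating biomarker discovery).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import CohortMetadata, OtuTable, RANKS, TaxonomyMap, ValidationError

__all__ = [
    "aggregate_rank",
    "wilcoxon_rank_sum",
    "wilcoxon_screen",
    "lda_effect_size",
    "activity_trend",
]

LEFSE_SCALE = 1e6  # per-sample normalisation target, LEfSe convention


def aggregate_rank(table: OtuTable, tax: TaxonomyMap, rank: str) -> OtuTable:
    """Sum OTU counts to a taxonomic rank.

    Unclassified lineages keep their parent-derived names (e.g.
    ``Micrococcaceae_unclassified``), so distinct parents stay distinct.
    Per-sample totals are preserved exactly.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    tax.require(table.otu_ids)
    names = [tax.name_at_rank(o, rank) for o in table.otu_ids]
    grouped = table.counts.T.groupby(pd.Index(names, name=rank), sort=True).sum().T
    return OtuTable(grouped, relative=table.relative)


def wilcoxon_rank_sum(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value and U statistic.

    Exact enumeration when both groups have <= 12 observations and the
    pooled data is tie-free; otherwise the normal approximation with
    midranks and tie-corrected variance (no continuity correction).
    A taxon constant across all samples is degenerate: p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0, len(x) * len(y) / 2.0
    tie_free = len(np.unique(pooled)) == len(pooled)
    if len(x) <= 12 and len(y) <= 12 and tie_free:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=False
        )
    return float(res.pvalue), float(res.statistic)


@dataclass
class DiffAbundanceResult:
    """Per-taxon screening results; ``table`` has columns taxon, rank,
    mean_case, mean_control, statistic, p_value, adjusted_p (optional),
    direction, significant, degenerate."""

    table: pd.DataFrame
    alpha: float
    rank: str

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]


def wilcoxon_screen(
    table: OtuTable,
    meta: CohortMetadata,
    alpha: float = 0.05,
    rank: str = "otu",
    adjust: bool = False,
) -> DiffAbundanceResult:
    """Per-taxon two-sided Wilcoxon rank-sum screen on relative abundances.

    Direction is ``enriched_case`` / ``enriched_control`` by group mean
    relative abundance.  With ``adjust=True`` a Benjamini-Hochberg
    column is added and used for the significance flag.
    """
    labels = meta.group_labels(table.sample_ids)
    case_ids = labels.index[labels == "case"]
    ctrl_ids = labels.index[labels == "control"]
    if len(case_ids) < 2 or len(ctrl_ids) < 2:
        raise ValidationError("each group needs >= 2 samples for the Wilcoxon screen")
    rel = table.relative_abundance() if not table.relative else table.counts
    rows = []
    for taxon in rel.columns:
        x = rel.loc[case_ids, taxon].to_numpy()
        y = rel.loc[ctrl_ids, taxon].to_numpy()
        p, u = wilcoxon_rank_sum(x, y)
        mx, my = float(x.mean()), float(y.mean())
        rows.append(
            {
                "taxon": taxon,
                "rank": rank,
                "mean_case": mx,
                "mean_control": my,
                "statistic": u,
                "p_value": p,
                "direction": "enriched_case" if mx >= my else "enriched_control",
                "degenerate": bool(np.all(np.concatenate([x, y]) == x[0])),
            }
        )
    out = pd.DataFrame(rows).set_index("taxon")
    if adjust:
        out["adjusted_p"] = multipletests(out["p_value"], method="fdr_bh")[1]
        out["significant"] = out["adjusted_p"] < alpha
    else:
        out["significant"] = out["p_value"] < alpha
    return DiffAbundanceResult(out, alpha=alpha, rank=rank)


@dataclass
class LdaEffectResult:
    """Per-taxon LDA effect sizes; ``table`` columns: enriched class,
    kw_p, lda_score_log10, passes."""

    table: pd.DataFrame
    threshold: float

    @property
    def passing(self) -> pd.DataFrame:
        return self.table[self.table["passes"]]


def lda_effect_size(
    table: OtuTable,
    meta: CohortMetadata,
    threshold: float = 3.0,
    n_boot: int = 30,
    subsample_frac: float = 2.0 / 3.0,
    seed: int = 0,
    kw_alpha: float = 0.05,
) -> LdaEffectResult:
    """Two-class LEfSe-style LDA effect-size scoring.

    1. Kruskal-Wallis screen at ``kw_alpha`` on per-taxon abundances
       scaled to sum 1e6 per sample (taxa failing the screen get no
       score).
    2. For each of ``n_boot`` bootstrap subsamples (fraction
       ``subsample_frac`` of each class), the one-dimensional
       linear-discriminant effect size of each surviving taxon — the
       absolute between-class mean difference on the scaled axis.
    3. Score = log10 of the bootstrap-mean effect size; a taxon passes
       at score >= ``threshold``.

    The per-sample scaling makes scores invariant to multiplying all
    abundances by a constant.
    """
    labels = meta.group_labels(table.sample_ids)
    case_ids = labels.index[labels == "case"]
    ctrl_ids = labels.index[labels == "control"]
    if len(case_ids) < 3 or len(ctrl_ids) < 3:
        raise ValidationError("each class needs >= 3 samples for LDA effect size")
    rel = table.relative_abundance() if not table.relative else table.counts
    scaled = rel.div(rel.sum(axis=1), axis=0) * LEFSE_SCALE
    rng = np.random.default_rng(seed)
    rows = []
    survivors = []
    for taxon in scaled.columns:
        x = scaled.loc[case_ids, taxon].to_numpy()
        y = scaled.loc[ctrl_ids, taxon].to_numpy()
        if np.all(np.concatenate([x, y]) == x[0]):
            kw_p = 1.0
        else:
            kw_p = float(stats.kruskal(x, y).pvalue)
        enriched = "case" if x.mean() >= y.mean() else "control"
        rows.append({"taxon": taxon, "enriched": enriched, "kw_p": kw_p})
        if kw_p < kw_alpha:
            survivors.append(taxon)
    out = pd.DataFrame(rows).set_index("taxon")
    out["lda_score_log10"] = np.nan
    if survivors:
        sub = scaled[survivors]
        n_case = max(int(round(subsample_frac * len(case_ids))), 2)
        n_ctrl = max(int(round(subsample_frac * len(ctrl_ids))), 2)
        effects = np.zeros((n_boot, len(survivors)))
        for b in range(n_boot):
            ci = rng.choice(len(case_ids), size=n_case, replace=False)
            hi = rng.choice(len(ctrl_ids), size=n_ctrl, replace=False)
            xc = sub.loc[case_ids[ci]].to_numpy()
            xh = sub.loc[ctrl_ids[hi]].to_numpy()
            effects[b] = np.abs(xc.mean(axis=0) - xh.mean(axis=0))
        mean_effect = effects.mean(axis=0)
        with np.errstate(divide="ignore"):
            out.loc[survivors, "lda_score_log10"] = np.log10(
                np.maximum(mean_effect, 1e-30)
            )
    out["passes"] = out["lda_score_log10"] >= threshold
    out["passes"] = out["passes"].fillna(False)
    return LdaEffectResult(out, threshold=threshold)


def activity_trend(table: OtuTable, meta: CohortMetadata) -> pd.DataFrame:
    """Per-taxon trend across SLEDAI disease-activity strata.

    Kruskal-Wallis p across mild/moderate/severe case samples plus a
    direction from the Spearman correlation of abundance with the
    ordinal activity level.  With only two non-empty strata the test
    falls back to Wilcoxon rank-sum (with a warning).
    """
    if "activity" not in meta.frame.columns:
        raise ValidationError("metadata has no activity (SLEDAI) information")
    activity = meta.frame.loc[
        [s for s in table.sample_ids if s in meta.frame.index], "activity"
    ].dropna()
    strata = [
        activity.index[activity == lvl] for lvl in ("mild", "moderate", "severe")
    ]
    nonempty = [idx for idx in strata if len(idx) > 0]
    if len(nonempty) < 2:
        raise ValidationError("activity trend needs >= 2 non-empty strata")
    if len(nonempty) == 2:
        warnings.warn(
            "only two activity strata present; falling back to Wilcoxon rank-sum",
            stacklevel=2,
        )
    rel = table.relative_abundance() if not table.relative else table.counts
    level = activity.map({"mild": 0, "moderate": 1, "severe": 2})
    rows = []
    for taxon in rel.columns:
        groups = [rel.loc[idx, taxon].to_numpy() for idx in nonempty]
        pooled = np.concatenate(groups)
        if np.all(pooled == pooled[0]):
            p = 1.0
        elif len(nonempty) == 2:
            p, _ = wilcoxon_rank_sum(groups[0], groups[1])
        else:
            p = float(stats.kruskal(*groups).pvalue)
        abund = rel.loc[activity.index, taxon]
        if np.all(abund.to_numpy() == abund.iloc[0]):
            rho = 0.0
        else:
            rho = float(stats.spearmanr(abund, level.loc[activity.index]).statistic)
        rows.append(
            {
                "taxon": taxon,
                "kw_p": p,
                "spearman_rho": rho,
                "direction": "increasing" if rho > 0 else ("decreasing" if rho < 0 else "flat"),
            }
        )
    return pd.DataFrame(rows).set_index("taxon")
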