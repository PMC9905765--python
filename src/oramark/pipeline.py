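"""End-to-end orchestration of the case-control workflow.

Stage order: alpha diversity -> OTU overlap -> rank-wise Wilcoxon ->
LDA effect size -> marker selection -> final model -> POD/ROC per
cohort -> activity trends -> OTU-clinical correlations -> clinical
table.  Every stage writes a TSV under the output directory and its
headline numbers are collected into ``summary.json`` together with the
resolved configuration.  A single global seed is expanded into
per-stage substreams so toggling one stage does not shift another's
randomness.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import clinical, diff_abundance, diversity, io, markers
from .containers import CohortMetadata, OtuTable, TaxonomyMap, ValidationError

logger = logging.getLogger("oramark")

__all__ = ["RunConfig", "run_pipeline"]

STAGES = (
    "diversity",
    "overlap",
    "diff",
    "lefse",
    "classifier",
    "trend",
    "correlate",
    "clinical",
)


@dataclass
class RunConfig:
    """Resolved pipeline configuration.

    Either in-memory objects (``table``/``meta``/``tax``) or file paths
    (``table_path``/``meta_path``/``tax_path``) may be supplied; paths
    are read at run time.
    """

    out_dir: str | Path = "oramark_out"
    table: OtuTable | None = None
    meta: CohortMetadata | None = None
    tax: TaxonomyMap | None = None
    table_path: str | Path | None = None
    meta_path: str | Path | None = None
    tax_path: str | Path | None = None
    stages: tuple[str, ...] = STAGES
    alpha: float = 0.05
    lda_threshold: float = 3.0
    n_folds: int = 5
    n_repeats: int = 5
    n_trees_rank: int = 1000
    n_trees_cv: int = 200
    n_trees_final: int = 1000
    max_set_size: int | None = 30
    ranks: tuple[str, ...] = ("phylum", "genus")
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s) {sorted(unknown)}; allowed: {STAGES}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    def resolve(self) -> tuple[OtuTable, CohortMetadata, TaxonomyMap | None]:
        table = self.table
        if table is None:
            if self.table_path is None:
                raise ValueError("neither table nor table_path supplied")
            table = io.read_otu_table(self.table_path)
        meta = self.meta
        if meta is None:
            if self.meta_path is None:
                raise ValueError("neither meta nor meta_path supplied")
            meta = io.read_metadata(self.meta_path)
        tax = self.tax
        if tax is None and self.tax_path is not None:
            tax = io.read_taxonomy(self.tax_path)
        return table, meta, tax

    def public_params(self) -> dict:
        return {
            "alpha": self.alpha,
            "lda_threshold": self.lda_threshold,
            "n_folds": self.n_folds,
            "n_repeats": self.n_repeats,
            "n_trees_rank": self.n_trees_rank,
            "n_trees_cv": self.n_trees_cv,
            "n_trees_final": self.n_trees_final,
            "max_set_size": self.max_set_size,
            "ranks": list(self.ranks),
            "stages": list(self.stages),
            "seed": self.seed,
        }


def _substream(seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31 derived from the global seed."""
    ss = np.random.SeedSequence([seed, abs(hash(stage)) % (2 ** 31)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and return the JSON-serialisable
    summary (also written to ``<out_dir>/summary.json``)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table, meta, tax = config.resolve()
    summary: dict = {"params": config.public_params()}
    cohorts_present = (
        sorted(set(meta.frame.get("cohort", pd.Series(dtype=str)).dropna()))
        if "cohort" in meta.frame.columns
        else []
    )
    if cohorts_present:
        deriv_ids = meta.samples_in(cohort="derivation")
        deriv_ids = [s for s in deriv_ids if s in table.counts.index]
    else:
        deriv_ids = table.sample_ids
    if not deriv_ids:
        raise ValidationError("no derivation-cohort samples found")
    deriv_table = table.subset_samples(deriv_ids)
    deriv_meta = meta.subset(deriv_ids)

    if "diversity" in config.stages:
        logger.info("stage diversity: %d derivation samples", len(deriv_ids))
        alpha_res = diversity.alpha_diversity(deriv_table)
        io.write_result_table(alpha_res, out / "alpha_diversity.tsv")
        groups = deriv_meta.group_labels(deriv_table.sample_ids)
        means = alpha_res.groupby(groups).mean()
        summary["alpha_diversity"] = {
            "mean_shannon_case": float(means.loc["case", "shannon"]),
            "mean_shannon_control": float(means.loc["control", "shannon"]),
        }
        dm = diversity.bray_curtis(deriv_table)
        pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids)).to_csv(
            out / "bray_curtis.tsv", sep="\t", float_format="%.12g"
        )
        ord_res = diversity.pcoa(dm, k=2)
        io.write_result_table(ord_res.coordinates, out / "pcoa.tsv")
        summary["pcoa_explained"] = [float(e) for e in ord_res.explained]

    if "overlap" in config.stages:
        overlap = diversity.otu_overlap(deriv_table, deriv_meta)
        summary["otu_overlap"] = {
            k: overlap[k] for k in ("shared", "unique_case", "unique_control", "total_observed")
        }

    screen = None
    if "diff" in config.stages:
        screen = diff_abundance.wilcoxon_screen(deriv_table, deriv_meta, alpha=config.alpha)
        io.write_result_table(screen.table, out / "wilcoxon_otu.tsv")
        summary["n_significant_otus"] = int(screen.table["significant"].sum())
        if tax is not None:
            summary["n_significant_by_rank"] = {}
            for rank in config.ranks:
                rank_table = diff_abundance.aggregate_rank(deriv_table, tax, rank)
                rank_screen = diff_abundance.wilcoxon_screen(
                    rank_table, deriv_meta, alpha=config.alpha, rank=rank
                )
                io.write_result_table(rank_screen.table, out / f"wilcoxon_{rank}.tsv")
                summary["n_significant_by_rank"][rank] = int(
                    rank_screen.table["significant"].sum()
                )

    if "lefse" in config.stages:
        lda = diff_abundance.lda_effect_size(
            deriv_table,
            deriv_meta,
            threshold=config.lda_threshold,
            seed=_substream(config.seed, "lefse"),
        )
        io.write_result_table(lda.table, out / "lda_effect_size.tsv")
        summary["n_lda_passing"] = int(lda.table["passes"].sum())

    if "classifier" in config.stages:
        if screen is None:
            screen = diff_abundance.wilcoxon_screen(
                deriv_table, deriv_meta, alpha=config.alpha
            )
        candidates = list(screen.significant.index)
        if not candidates:
            raise ValidationError("no Wilcoxon-significant candidate OTUs to rank")
        ranking = markers.rank_importance(
            deriv_table,
            deriv_meta,
            candidates,
            n_trees=config.n_trees_rank,
            seed=_substream(config.seed, "rank"),
        )
        io.write_result_table(ranking, out / "importance.tsv")
        selection = markers.cv_error_curves(
            deriv_table,
            deriv_meta,
            ranking,
            n_folds=config.n_folds,
            n_repeats=config.n_repeats,
            n_trees=config.n_trees_cv,
            seed=_substream(config.seed, "cv"),
            max_set_size=config.max_set_size,
        )
        curve_frame = pd.DataFrame(
            selection.cv_curves.T,
            index=pd.Index(range(1, len(selection.mean_curve) + 1), name="set_size"),
            columns=[f"repeat_{r + 1}" for r in range(selection.cv_curves.shape[0])],
        )
        curve_frame["mean"] = selection.mean_curve
        curve_frame["sd"] = selection.sd_curve
        io.write_result_table(curve_frame, out / "cv_error_curves.tsv")
        summary["marker_selection"] = {
            "cutoff": selection.cutoff,
            "optimal_set": selection.optimal_set,
            "optimal_set_size": len(selection.optimal_set),
        }
        model = markers.fit_final_model(
            deriv_table,
            deriv_meta,
            selection.optimal_set,
            n_trees=config.n_trees_final,
            seed=_substream(config.seed, "final"),
        )
        summary["auc"] = {}
        eval_cohorts = cohorts_present or ["derivation"]
        for cohort in eval_cohorts:
            ids = (
                meta.samples_in(cohort=cohort) if cohorts_present else table.sample_ids
            )
            ids = [s for s in ids if s in table.counts.index]
            if not ids:
                logger.warning("cohort %s has no samples; skipped", cohort)
                continue
            sub = table.subset_samples(ids)
            sub_meta = meta.subset(ids)
            if cohort == "derivation" or not cohorts_present:
                pod = model.pod(sub)
                roc = markers.roc_auc(pod, sub_meta)
            else:
                pod, roc = markers.validate_external(model, sub, sub_meta)
            io.write_result_table(pod, out / f"pod_{cohort}.tsv")
            io.write_result_table(roc.curve, out / f"roc_{cohort}.tsv")
            summary["auc"][cohort] = {
                "auc": roc.auc,
                "ci_low": roc.ci_low,
                "ci_high": roc.ci_high,
                "n_case": roc.n_case,
                "n_control": roc.n_control,
            }

    if "trend" in config.stages and "activity" in meta.frame.columns:
        case_ids = [
            s for s in table.sample_ids
            if s in meta.frame.index and meta.frame.loc[s, "group"] == "case"
        ]
        case_meta = meta.subset(case_ids)
        if case_meta.frame["activity"].notna().sum() >= 4:
            trend_table = table.subset_samples(case_ids)
            if tax is not None:
                trend_table = diff_abundance.aggregate_rank(trend_table, tax, "genus")
            trend = diff_abundance.activity_trend(trend_table, case_meta)
            io.write_result_table(trend, out / "activity_trend.tsv")
            summary["n_trend_significant"] = int((trend["kw_p"] < config.alpha).sum())
        else:
            logger.warning("too few SLEDAI-scored cases; trend stage skipped")

    if "correlate" in config.stages:
        corr = clinical.spearman_matrix(
            deriv_table, deriv_meta, alpha=config.alpha, group="case"
        )
        io.write_result_table(corr.set_index("otu"), out / "otu_clinical_spearman.tsv")
        sig = corr[corr["significant"]]
        summary["correlation"] = {
            "n_significant_pairs": int(len(sig)),
            "n_otus_with_link": int(sig["otu"].nunique()),
        }

    if "clinical" in config.stages:
        rows = []
        for index, normal in (
            ("age", False), ("bmi", False), ("wbc", False), ("rbc", True),
            ("hb", True), ("plt", False), ("lyn", False), ("glb", False),
        ):
            if index in deriv_meta.frame.columns:
                rows.append(clinical.compare_groups(deriv_meta, index, normal=normal))
        if "gender" in deriv_meta.frame.columns:
            tab = pd.crosstab(
                deriv_meta.frame["group"], deriv_meta.frame["gender"]
            ).reindex(index=["case", "control"], fill_value=0)
            res = clinical.compare_categorical(tab.to_numpy())
            rows.append({"index": "gender", **res})
        if rows:
            frame = pd.DataFrame(rows).set_index("index")
            io.write_result_table(frame, out / "clinical_table.tsv")
            summary["clinical_p_values"] = {
                r: float(p) for r, p in frame["p_value"].items()
            }

    io.write_run_manifest(out / "manifest.json", config.seed, config.public_params())
    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=str) + "\n")
    return summary
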