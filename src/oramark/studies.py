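"""Multi-seed simulation studies over the full pipeline.

These drive the package end-to-end on synthetic cohorts with known
ground truth: marker-set recovery and cross-cohort AUC under the
three-cohort design, the label-permuted null, and generator
calibration.  The analysis scripts, the test suite and the acceptance
script all import from here so every reported number comes from the
same code path.

Problem sizes (300 OTUs, 10 planted 4-fold markers, cohorts
100/200 + 40/80 + 42/80, modest forest sizes) are chosen so a full
10-seed study runs in a few minutes on one CPU while leaving the
marker-recovery and AUC behaviour of the full-scale design intact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import diff_abundance, diversity, markers
from .containers import CohortMetadata, OtuTable
from .synthetic import SyntheticConfig, default_study_config, simulate_cohort

__all__ = [
    "study_config",
    "run_marker_selection_once",
    "marker_selection_study",
    "null_permutation_study",
    "generator_calibration_study",
]

MAX_SEED = 2 ** 31 - 1


def study_config(seed: int, n_otus: int = 300, **overrides) -> SyntheticConfig:
    """Three-cohort study configuration at analysis scale (300 OTUs,
    10 planted 4-fold markers)."""
    return default_study_config(seed=seed % MAX_SEED, n_otus=n_otus, **overrides)


@dataclass
class MarkerStudyResult:
    seed: int
    optimal_set: list[str]
    n_extra: int  # optimal-set members outside the planted marker set
    recovered: bool  # optimal set within planted + <= 1 extra
    auc_derivation: float
    auc_validation: float
    auc_cross_regional: float


def run_marker_selection_once(
    table: OtuTable,
    meta: CohortMetadata,
    seed: int,
    alpha: float = 0.05,
    rank_trees: int = 300,
    cv_trees: int = 50,
    final_trees: int = 500,
    max_set_size: int = 15,
    permute_labels: bool = False,
) -> tuple[list[str], dict[str, markers.RocResult]]:
    """Screen -> rank -> CV curves -> optimal set -> final model -> POD/ROC
    on every cohort present.  With ``permute_labels`` the derivation
    labels are shuffled (seeded) before the whole procedure, giving the
    null control."""
    rng = np.random.default_rng(seed % MAX_SEED)
    deriv_ids = meta.samples_in(cohort="derivation")
    deriv = table.subset_samples(deriv_ids)
    dmeta = meta.subset(deriv_ids)
    if permute_labels:
        frame = dmeta.frame.copy()
        frame["group"] = rng.permutation(frame["group"].to_numpy())
        dmeta = CohortMetadata(frame)
    screen = diff_abundance.wilcoxon_screen(deriv, dmeta, alpha=alpha)
    candidates = list(screen.significant.index)
    if not candidates:  # null runs can come up empty; fall back to top-p OTUs
        candidates = list(screen.table.sort_values("p_value").index[:5])
    ranking = markers.rank_importance(
        deriv, dmeta, candidates, n_trees=rank_trees,
        seed=int(rng.integers(MAX_SEED)),
    )
    selection = markers.cv_error_curves(
        deriv, dmeta, ranking, n_trees=cv_trees,
        seed=int(rng.integers(MAX_SEED)), max_set_size=max_set_size,
    )
    model = markers.fit_final_model(
        deriv, dmeta, selection.optimal_set, n_trees=final_trees,
        seed=int(rng.integers(MAX_SEED)),
    )
    rocs: dict[str, markers.RocResult] = {}
    pod = model.pod(deriv)
    rocs["derivation"] = markers.roc_auc(pod, dmeta)
    for cohort in ("validation", "cross_regional"):
        ids = meta.samples_in(cohort=cohort)
        if not ids:
            continue
        _, rocs[cohort] = markers.validate_external(
            model, table.subset_samples(ids), meta.subset(ids)
        )
    return selection.optimal_set, rocs


def marker_selection_study(base_seed: int, n_seeds: int = 10) -> pd.DataFrame:
    """Marker recovery and per-cohort AUC over ``n_seeds`` independent
    simulated studies."""
    rows = []
    for i in range(n_seeds):
        seed = (base_seed + 1000 * i + 1) % MAX_SEED
        table, meta, truth = simulate_cohort(study_config(seed))
        optimal, rocs = run_marker_selection_once(table, meta, seed=seed + 7)
        extra = [o for o in optimal if o not in truth.marker_otus]
        rows.append(
            MarkerStudyResult(
                seed=seed,
                optimal_set=optimal,
                n_extra=len(extra),
                recovered=len(extra) <= 1,
                auc_derivation=rocs["derivation"].auc,
                auc_validation=rocs["validation"].auc,
                auc_cross_regional=rocs["cross_regional"].auc,
            ).__dict__
        )
    return pd.DataFrame(rows)


def null_permutation_study(base_seed: int, n_seeds: int = 10) -> pd.DataFrame:
    """External (validation-cohort) AUC after training on label-permuted
    derivation cohorts; should hover around 0.5."""
    rows = []
    for i in range(n_seeds):
        seed = (base_seed + 1000 * i + 17) % MAX_SEED
        table, meta, _ = simulate_cohort(study_config(seed))
        _, rocs = run_marker_selection_once(
            table, meta, seed=seed + 3, permute_labels=True, max_set_size=10
        )
        rows.append({"seed": seed, "auc_validation": rocs["validation"].auc})
    return pd.DataFrame(rows)


def generator_calibration_study(base_seed: int, n_seeds: int = 10) -> dict:
    """Realized marker log-fold-changes and the case-vs-control Shannon
    gap in single derivation cohorts (100 case / 200 control)."""
    log_fold_errors = []
    realized_folds = []
    shannon_gaps = []
    for i in range(n_seeds):
        seed = (base_seed + 1000 * i + 29) % MAX_SEED
        cfg = study_config(seed)
        cfg.cohorts = [cfg.cohorts[0]]  # derivation only
        table, meta, truth = simulate_cohort(cfg)
        rel = table.relative_abundance()
        groups = meta.group_labels(table.sample_ids)
        mean_case = rel[groups == "case"].mean()
        mean_ctrl = rel[groups == "control"].mean()
        for otu, fold in truth.marker_otus.items():
            realized = mean_case[otu] / mean_ctrl[otu]
            realized_folds.append(realized)
            log_fold_errors.append(abs(np.log(realized) - np.log(fold)) / abs(np.log(fold)))
        alpha = diversity.alpha_diversity(table)
        shannon_gaps.append(
            float(alpha.loc[groups == "case", "shannon"].mean()
                  - alpha.loc[groups == "control", "shannon"].mean())
        )
    return {
        "mean_log_fold_rel_error": float(np.mean(log_fold_errors)),
        "realized_folds": realized_folds,
        "shannon_gaps": shannon_gaps,
        "mean_shannon_gap": float(np.mean(shannon_gaps)),
    }
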