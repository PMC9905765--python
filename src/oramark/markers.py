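"""Random-forest marker selection, the POD (probability of disease)
index, and ROC validation.

The procedure, applied to Wilcoxon-screen survivors in a derivation
cohort:

1. Rank candidate OTUs by Mean Decrease Accuracy — out-of-bag
   permutation importance of a random forest fitted on relative
   abundances.
2. For marker-set sizes m = 1..M (top-m ranked OTUs), run repeated
   stratified cross-validation and record the held-out
   misclassification error, giving one error curve per repeat.
3. Cut-off rule: minimum of the mean curve plus the across-repeat
   standard deviation at that minimum; the optimal marker set is the
   smallest m whose mean error is below the cut-off (``<=`` when the
   standard deviation is zero, so the argmin always qualifies).
4. A final forest restricted to the optimal set yields the POD index —
   the share of decision trees voting the case class — and ROC/AUC with
   DeLong 95% confidence intervals, on the derivation cohort and on
   frozen-model external cohorts.

Importance ranking is computed once on the full derivation set before
cross-validation (as published); ``rerank_in_folds=True`` re-ranks
within each training fold to remove that source of optimism.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .containers import CohortMetadata, OtuTable, ValidationError

__all__ = [
    "rank_importance",
    "cv_error_curves",
    "select_optimal_set",
    "fit_final_model",
    "compute_pod",
    "roc_auc",
    "validate_external",
    "MarkerSelectionResult",
    "PodModel",
    "RocResult",
]


def _encode_labels(meta: CohortMetadata, sample_ids) -> np.ndarray:
    labels = meta.group_labels(sample_ids)
    y = (labels == "case").to_numpy().astype(int)
    if y.min() == y.max():
        raise ValidationError("both case and control samples are required")
    return y


def _rel_columns(table: OtuTable, columns: list[str]) -> pd.DataFrame:
    """Whole-community relative abundances restricted to ``columns``
    (missing OTUs filled as 0).  Normalisation happens before the
    restriction so a marker's abundance is its share of the full
    community, not of the marker panel."""
    rel = table.counts if table.relative else table.relative_abundance()
    return rel.reindex(columns=columns, fill_value=0.0)


def _forest(n_trees: int, seed: int) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=n_trees,
        random_state=int(seed),
        n_jobs=1,
        oob_score=False,
    )


def oob_permutation_importance(
    forest: RandomForestClassifier, x: np.ndarray, y: np.ndarray, seed: int
) -> np.ndarray:
    """Mean Decrease Accuracy: per tree, the drop in out-of-bag accuracy
    when one feature column is permuted among that tree's OOB samples;
    averaged over trees."""
    rng = np.random.default_rng(seed)
    n_samples, n_features = x.shape
    decreases = np.zeros((len(forest.estimators_), n_features))
    used = np.zeros(len(forest.estimators_), dtype=bool)
    for t, (tree, inbag) in enumerate(
        zip(forest.estimators_, forest.estimators_samples_)
    ):
        oob = np.setdiff1d(np.arange(n_samples), inbag)
        if oob.size == 0:
            continue
        used[t] = True
        x_oob = x[oob]
        base = (tree.predict(x_oob) == y[oob]).mean()
        for j in range(n_features):
            perm = rng.permutation(oob.size)
            x_perm = x_oob.copy()
            x_perm[:, j] = x_oob[perm, j]
            decreases[t, j] = base - (tree.predict(x_perm) == y[oob]).mean()
    if not used.any():
        raise ValidationError("no tree has out-of-bag samples; increase sample size")
    return decreases[used].mean(axis=0)


def rank_importance(
    table: OtuTable,
    meta: CohortMetadata,
    candidates: list[str] | None = None,
    n_trees: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Rank candidate OTUs by Mean Decrease Accuracy (descending).

    ``candidates`` defaults to all OTUs but is expected to be the
    Wilcoxon-screen survivors.  Returns a DataFrame indexed by OTU id
    with an ``importance`` column, sorted descending (ties broken by
    OTU id for determinism).
    """
    if candidates is None:
        candidates = table.otu_ids
    candidates = list(candidates)
    if len(candidates) == 0:
        raise ValidationError("candidate OTU set is empty")
    rel = _rel_columns(table, candidates).to_numpy()
    y = _encode_labels(meta, table.sample_ids)
    forest = _forest(n_trees, seed)
    forest.fit(rel, y)
    imp = oob_permutation_importance(forest, rel, y, seed=seed + 1)
    out = pd.DataFrame({"importance": imp}, index=pd.Index(candidates, name="otu"))
    return out.sort_values(
        ["importance", "otu"], ascending=[False, True], kind="mergesort"
    )


@dataclass
class MarkerSelectionResult:
    """Importance ranking, CV-error curves, cut-off and optimal set."""

    ranked_otus: list[str]
    importance: pd.Series
    cv_curves: np.ndarray  # n_repeats x M held-out error
    mean_curve: np.ndarray  # length M
    sd_curve: np.ndarray  # across-repeat sd, length M
    cutoff: float = field(init=False)
    candidate_sizes: list[int] = field(init=False)
    optimal_set: list[str] = field(init=False)

    def __post_init__(self) -> None:
        if not (0 <= self.cv_curves.min() and self.cv_curves.max() <= 1):
            raise ValidationError("CV errors must lie in [0, 1]")
        argmin = int(np.argmin(self.mean_curve))
        sd_at_min = float(self.sd_curve[argmin])
        self.cutoff = float(self.mean_curve[argmin]) + sd_at_min
        if sd_at_min > 0:
            qualifying = np.nonzero(self.mean_curve < self.cutoff)[0]
        else:  # degenerate sd: use <= so the argmin set qualifies
            qualifying = np.nonzero(self.mean_curve <= self.cutoff)[0]
        best_m = int(qualifying.min()) + 1
        self.candidate_sizes = (qualifying + 1).tolist()
        self.optimal_set = self.ranked_otus[:best_m]


def cv_error_curves(
    table: OtuTable,
    meta: CohortMetadata,
    ranked: pd.DataFrame | list[str],
    n_folds: int = 5,
    n_repeats: int = 5,
    n_trees: int = 200,
    seed: int = 0,
    max_set_size: int | None = None,
    rerank_in_folds: bool = False,
    rank_n_trees: int = 500,
) -> MarkerSelectionResult:
    """Repeated stratified CV error as a function of marker-set size.

    For each of ``n_repeats`` seeded repetitions of stratified
    ``n_folds``-fold CV and each m = 1..M, the mean held-out
    misclassification error of a forest on the top-m ranked OTUs.  The
    mean curve averages the repeat curves; the sd at each m is across
    repeats.  With ``rerank_in_folds`` the importance ranking is
    recomputed inside every training fold (removing the published
    protocol's ranking leak) and the global ranking is used only for
    reporting.
    """
    if isinstance(ranked, pd.DataFrame):
        ranked_ids = list(ranked.index)
        importance = ranked["importance"]
    else:
        ranked_ids = list(ranked)
        importance = pd.Series(np.nan, index=ranked_ids)
    if len(ranked_ids) == 0:
        raise ValidationError("ranked OTU list is empty")
    m_max = len(ranked_ids) if max_set_size is None else min(max_set_size, len(ranked_ids))
    y = _encode_labels(meta, table.sample_ids)
    if min(np.bincount(y)) < n_folds:
        raise ValidationError(
            f"smallest class has fewer samples than n_folds={n_folds}"
        )
    rel_frame = _rel_columns(table, ranked_ids)
    rng = np.random.default_rng(seed)
    curves = np.zeros((n_repeats, m_max))
    for r in range(n_repeats):
        skf = StratifiedKFold(
            n_splits=n_folds, shuffle=True, random_state=int(rng.integers(2 ** 31 - 1))
        )
        fold_errors = np.zeros((n_folds, m_max))
        for f, (train, test) in enumerate(skf.split(rel_frame.to_numpy(), y)):
            if rerank_in_folds:
                fold_table = table.subset_samples([table.sample_ids[i] for i in train])
                fold_meta = meta.subset(fold_table.sample_ids)
                fold_rank = rank_importance(
                    fold_table, fold_meta, ranked_ids,
                    n_trees=rank_n_trees, seed=int(rng.integers(2 ** 31 - 1)),
                )
                order = list(fold_rank.index)
            else:
                order = ranked_ids
            x = rel_frame[order].to_numpy()
            for m in range(1, m_max + 1):
                forest = _forest(n_trees, int(rng.integers(2 ** 31 - 1)))
                forest.fit(x[train, :m], y[train])
                pred = forest.predict(x[test, :m])
                fold_errors[f, m - 1] = (pred != y[test]).mean()
        curves[r] = fold_errors.mean(axis=0)
    mean_curve = curves.mean(axis=0)
    sd_curve = curves.std(axis=0, ddof=1) if n_repeats > 1 else np.zeros(m_max)
    return MarkerSelectionResult(
        ranked_otus=ranked_ids[:m_max],
        importance=importance.loc[ranked_ids[:m_max]],
        cv_curves=curves,
        mean_curve=mean_curve,
        sd_curve=sd_curve,
    )


def select_optimal_set(
    mean_curve: np.ndarray | list[float],
    sd_curve: np.ndarray | list[float] | float,
    ranked_otus: list[str] | None = None,
) -> tuple[float, int, list[str] | None]:
    """Apply the cut-off rule to an explicit mean curve.

    cutoff = min(mean_curve) + sd at the argmin; returns (cutoff,
    optimal set size, optimal ids if ``ranked_otus`` given).  The
    comparison is strict (<) except when the sd at the minimum is zero,
    where it relaxes to <= so the argmin always qualifies.
    """
    mean_curve = np.asarray(mean_curve, dtype=float)
    if np.isscalar(sd_curve) or np.ndim(sd_curve) == 0:
        sd_arr = np.full_like(mean_curve, float(sd_curve))
    else:
        sd_arr = np.asarray(sd_curve, dtype=float)
    argmin = int(np.argmin(mean_curve))
    cutoff = float(mean_curve[argmin] + sd_arr[argmin])
    if sd_arr[argmin] > 0:
        qualifying = np.nonzero(mean_curve < cutoff)[0]
    else:
        qualifying = np.nonzero(mean_curve <= cutoff)[0]
    best_m = int(qualifying.min()) + 1
    ids = ranked_otus[:best_m] if ranked_otus is not None else None
    return cutoff, best_m, ids


@dataclass
class PodModel:
    """A frozen random-forest vote model over a fixed marker OTU set."""

    forest: RandomForestClassifier
    marker_otus: list[str]
    training_sample_ids: list[str]
    n_trees: int
    seed: int

    def pod(self, table: OtuTable) -> pd.DataFrame:
        """POD index per sample: share of trees voting the case class.

        OTUs absent from ``table`` are treated as relative abundance 0
        (with a warning) so a frozen model applies across cohorts.  The
        odds form (case votes / control votes) is emitted alongside; it
        is a monotone transform of the vote share, so ROC analyses are
        unaffected by the choice.
        """
        missing = [o for o in self.marker_otus if o not in table.counts.columns]
        if missing:
            warnings.warn(
                f"marker OTU(s) absent from table, treated as zero: {missing}",
                stacklevel=2,
            )
        rel_full = table.counts if table.relative else table.relative_abundance()
        rel = rel_full.reindex(columns=self.marker_otus, fill_value=0.0).to_numpy()
        case_idx = int(np.nonzero(self.forest.classes_ == 1)[0][0])
        votes = np.stack(
            [tree.predict(rel) == self.forest.classes_[case_idx] for tree in self.forest.estimators_]
        )
        case_votes = votes.sum(axis=0).astype(float)
        total = float(len(self.forest.estimators_))
        with np.errstate(divide="ignore"):
            odds = np.where(
                case_votes < total, case_votes / (total - case_votes), np.inf
            )
        return pd.DataFrame(
            {"pod": case_votes / total, "pod_odds": odds},
            index=table.sample_ids,
        )


def fit_final_model(
    table: OtuTable,
    meta: CohortMetadata,
    optimal_set: list[str],
    n_trees: int = 1000,
    seed: int = 0,
) -> PodModel:
    """Train the final vote forest on the derivation cohort restricted to
    the optimal marker set."""
    if len(optimal_set) == 0:
        raise ValidationError("optimal marker set is empty")
    rel = _rel_columns(table, list(optimal_set)).to_numpy()
    y = _encode_labels(meta, table.sample_ids)
    forest = _forest(n_trees, seed)
    forest.fit(rel, y)
    return PodModel(
        forest=forest,
        marker_otus=list(optimal_set),
        training_sample_ids=list(table.sample_ids),
        n_trees=n_trees,
        seed=seed,
    )


def compute_pod(model: PodModel, table: OtuTable) -> pd.DataFrame:
    return model.pod(table)


@dataclass
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    n_case: int
    n_control: int
    curve: pd.DataFrame  # fpr, tpr, threshold

    def __post_init__(self) -> None:
        assert 0 <= self.auc <= 1
        assert self.ci_low <= self.auc <= self.ci_high


def _placement_values(case: np.ndarray, ctrl: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    cmp = (case[:, None] > ctrl[None, :]).astype(float)
    cmp += 0.5 * (case[:, None] == ctrl[None, :])
    return cmp.mean(axis=1), cmp.mean(axis=0)


def roc_auc(pod: pd.DataFrame | pd.Series, meta: CohortMetadata) -> RocResult:
    """AUC with DeLong 95% confidence interval.

    AUC is the Mann-Whitney probability (ties count 1/2) that a case
    sample's POD exceeds a control sample's.  The CI uses the DeLong
    placement-value variance S10/m + S01/n with a normal quantile,
    truncated to [0, 1].
    """
    scores = pod["pod"] if isinstance(pod, pd.DataFrame) else pod
    labels = meta.group_labels(list(scores.index))
    case = scores[labels == "case"].to_numpy(dtype=float)
    ctrl = scores[labels == "control"].to_numpy(dtype=float)
    if len(case) == 0 or len(ctrl) == 0:
        raise ValidationError("ROC needs both case and control samples")
    v10, v01 = _placement_values(case, ctrl)
    auc = float(v10.mean())
    if len(case) > 1 and len(ctrl) > 1:
        var = v10.var(ddof=1) / len(case) + v01.var(ddof=1) / len(ctrl)
    else:
        var = 0.0
    z = stats.norm.ppf(0.975)
    half = z * np.sqrt(var)
    ci_low = max(0.0, auc - half)
    ci_high = min(1.0, auc + half)
    thresholds = np.unique(np.concatenate([scores.to_numpy(dtype=float), [np.inf]]))[::-1]
    tpr = [(case >= t).mean() for t in thresholds]
    fpr = [(ctrl >= t).mean() for t in thresholds]
    curve = pd.DataFrame({"threshold": thresholds, "fpr": fpr, "tpr": tpr})
    return RocResult(
        auc=auc,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        n_case=len(case),
        n_control=len(ctrl),
        curve=curve,
    )


def validate_external(
    model: PodModel, table_ext: OtuTable, meta_ext: CohortMetadata
) -> tuple[pd.DataFrame, RocResult]:
    """Apply a frozen model to an external cohort (no refitting).

    Raises if any external sample id overlaps the training cohort
    (leakage guard).
    """
    overlap = set(table_ext.sample_ids) & set(model.training_sample_ids)
    if overlap:
        raise ValidationError(
            f"external cohort shares sample id(s) with training: {sorted(overlap)[:5]}"
        )
    pod = model.pod(table_ext)
    return pod, roc_auc(pod, meta_ext)
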