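"""Group comparisons of clinical indices and OTU-clinical Spearman
correlation.

Continuous indices are compared with a pooled-variance t-test (normal)
or Wilcoxon rank-sum (non-normal, caller decides); categorical indices
with Pearson chi-square WITHOUT continuity correction, switching to
Fisher's exact test when any expected cell is < 1 or more than 20% of
cells are < 5.  OTU-clinical association uses Spearman's rho with
midranks; for n <= 9 tie-free pairs the p-value comes from full
permutation enumeration.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CohortMetadata, OtuTable, ValidationError
from .diff_abundance import wilcoxon_rank_sum

__all__ = ["compare_groups", "compare_categorical", "spearman", "spearman_matrix"]

EXACT_SPEARMAN_MAX_N = 9


def compare_groups(meta: CohortMetadata, index: str, normal: bool) -> dict:
    """Compare one continuous clinical index between case and control.

    ``normal=True`` uses a two-sided pooled-variance t-test and reports
    mean +/- sd per group; otherwise a Wilcoxon rank-sum with
    median (IQR) summaries.  Missing values are dropped per group.
    """
    if index not in meta.frame.columns:
        raise ValidationError(f"clinical index {index!r} not in metadata")
    values = pd.to_numeric(meta.frame[index], errors="coerce")
    labels = meta.frame["group"]
    x = values[labels == "case"].dropna().to_numpy()
    y = values[labels == "control"].dropna().to_numpy()
    if len(x) < 2 or len(y) < 2:
        raise ValidationError(f"index {index!r} has < 2 observed values in a group")
    if normal:
        stat, p = stats.ttest_ind(x, y, equal_var=True)
        summary = {
            "case": f"{x.mean():.2f} ± {x.std(ddof=1):.2f}",
            "control": f"{y.mean():.2f} ± {y.std(ddof=1):.2f}",
        }
        test = "t"
    else:
        p, stat = wilcoxon_rank_sum(x, y)
        summary = {
            "case": _median_iqr(x),
            "control": _median_iqr(y),
        }
        test = "wilcoxon"
    return {
        "index": index,
        "test": test,
        "statistic": float(stat),
        "p_value": float(p),
        "summary_case": summary["case"],
        "summary_control": summary["control"],
        "n_case": len(x),
        "n_control": len(y),
    }


def _median_iqr(v: np.ndarray) -> str:
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return f"{med:.2f} ({q1:.2f}, {q3:.2f})"


def compare_categorical(
    contingency: np.ndarray | list[list[int]], method: str = "chi_square"
) -> dict:
    """Test association in a contingency table.

    ``chi_square`` (default) is the Pearson chi-square WITHOUT
    continuity correction — the form that reproduces published
    case-control gender-split p-values.  ``auto`` switches to Fisher's
    exact test when expected counts are sparse (any cell < 1 or > 20%
    of cells < 5; Fisher requires a 2x2 table); ``fisher`` forces it.
    """
    obs = np.asarray(contingency, dtype=float)
    if obs.ndim != 2 or (obs < 0).any():
        raise ValidationError("contingency table must be a non-negative 2-D array")
    if method not in ("chi_square", "fisher", "auto"):
        raise ValueError("method must be 'chi_square', 'fisher' or 'auto'")
    chi2, p, dof, expected = stats.chi2_contingency(obs, correction=False)
    sparse = (expected < 1).any() or (expected < 5).mean() > 0.2
    use_fisher = method == "fisher" or (method == "auto" and sparse)
    if use_fisher:
        if obs.shape != (2, 2):
            raise ValidationError("Fisher's exact test requires a 2x2 table")
        stat, p = stats.fisher_exact(obs.astype(int))
        return {"test": "fisher", "statistic": float(stat), "p_value": float(p), "dof": 1}
    return {"test": "chi_square", "statistic": float(chi2), "p_value": float(p), "dof": int(dof)}


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact p by enumerating all rank permutations (tie-free,
    n <= 9)."""
    n = len(x)
    ry = stats.rankdata(y)
    count = 0
    total = 0
    rx_all = np.array(list(permutations(range(1, n + 1))), dtype=float)
    rhos = 1 - 6 * ((rx_all - ry) ** 2).sum(axis=1) / (n * (n ** 2 - 1))
    count = int((np.abs(rhos) >= abs(rho_obs) - 1e-12).sum())
    total = len(rhos)
    return count / total


def spearman(x, y, exact_max_n: int = EXACT_SPEARMAN_MAX_N) -> tuple[float, float]:
    """Spearman rho (midranks) with a two-sided p-value.

    Exact permutation enumeration for tie-free pairs with n <=
    ``exact_max_n``; otherwise the t-distribution approximation.
    Returns (rho, p); a constant vector yields (nan, nan).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = ~(np.isnan(x) | np.isnan(y))
    x, y = x[mask], y[mask]
    if len(x) < 4:
        raise ValidationError("Spearman needs >= 4 pairwise-complete observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return np.nan, np.nan
    rho = float(stats.spearmanr(x, y).statistic)
    tie_free = len(np.unique(x)) == len(x) and len(np.unique(y)) == len(y)
    if tie_free and len(x) <= exact_max_n:
        return rho, _exact_spearman_p(x, y, rho)
    if abs(rho) >= 1.0:
        return rho, 0.0
    n = len(x)
    t = rho * np.sqrt((n - 2) / (1 - rho ** 2))
    p = 2 * stats.t.sf(abs(t), df=n - 2)
    return rho, float(p)


def spearman_matrix(
    table: OtuTable,
    meta: CohortMetadata,
    otus: list[str] | None = None,
    indices: list[str] | None = None,
    alpha: float = 0.05,
    group: str | None = "case",
) -> pd.DataFrame:
    """Spearman rho/p grid between OTU relative abundances and clinical
    indices.

    By default only case samples enter (the published correlations use
    patients' clinical data); ``group=None`` pools both groups.  Gender
    is encoded F=0, M=1.  Returns a long-format frame (otu, index, rho,
    p_value, significant) with constant-vector cells flagged as
    undefined (NaN rho).
    """
    if otus is None:
        otus = table.otu_ids
    if indices is None:
        indices = [
            c for c in meta.frame.columns
            if c not in ("group", "cohort", "activity", "sledai")
        ]
    sample_ids = [s for s in table.sample_ids if s in meta.frame.index]
    if group is not None:
        labels = meta.group_labels(sample_ids)
        sample_ids = [s for s in sample_ids if labels[s] == group]
    rel = (table.counts if table.relative else table.relative_abundance()).loc[sample_ids]
    rows = []
    for idx_name in indices:
        raw = meta.frame.loc[sample_ids, idx_name]
        if idx_name == "gender":
            vals = raw.map({"F": 0.0, "M": 1.0})
        else:
            vals = pd.to_numeric(raw, errors="coerce")
        for otu in otus:
            x = rel[otu].to_numpy(dtype=float)
            y = vals.to_numpy(dtype=float)
            mask = ~(np.isnan(x) | np.isnan(y))
            if mask.sum() < 4:
                rho, p = np.nan, np.nan
            else:
                rho, p = spearman(x[mask], y[mask])
            rows.append(
                {
                    "otu": otu,
                    "index": idx_name,
                    "rho": rho,
                    "p_value": p,
                    "n": int(mask.sum()),
                    "significant": bool(p < alpha) if not np.isnan(p) else False,
                }
            )
    return pd.DataFrame(rows)
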