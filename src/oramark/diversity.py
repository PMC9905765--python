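"""Alpha diversity, sample-accumulation curves, beta-diversity distances
and ordination.

Alpha indices follow the classical estimator definitions:

* Shannon  H = -sum p_i log p_i (natural log by default; base is a
  parameter).
* Simpson  D = sum n_i(n_i-1) / (N(N-1)), the finite-sample
  probability-of-identity form.  Both D and the Simpson diversity 1-D
  are reported; "simpson" columns downstream refer to 1-D, the form in
  which diversity increases with evenness.
* Chao1 (bias-corrected)  S_obs + F1(F1-1) / (2(F2+1)).
* ACE with rare/abundant threshold 10.

Distances are Bray-Curtis on relative abundances and unweighted UniFrac
(fraction of branch length unique to one of two communities, presence =
count > 0) computed through scikit-bio.  Ordinations: classical-scaling
PCoA, non-metric MDS minimising Kruskal stress-1, and PCA on relative
abundances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import skbio
from skbio.diversity import beta_diversity
from sklearn.decomposition import PCA
from sklearn.isotonic import IsotonicRegression
from sklearn.manifold import MDS

from .containers import CohortMetadata, OtuTable, ValidationError

__all__ = [
    "alpha_diversity",
    "rarefy",
    "accumulation_curve",
    "bray_curtis",
    "unweighted_unifrac",
    "pcoa",
    "nmds",
    "pca",
    "otu_overlap",
    "OrdinationResult",
    "AccumulationCurve",
]

ACE_RARE_THRESHOLD = 10


def _shannon(counts: np.ndarray, base: float | None) -> float:
    pos = counts[counts > 0]
    p = pos / pos.sum()
    h = float(-(p * np.log(p)).sum())
    return h / np.log(base) if base is not None else h


def _simpson_d(counts: np.ndarray) -> float:
    n = counts[counts > 0].astype(float)
    total = n.sum()
    if total < 2:
        raise ValidationError("Simpson index undefined for sample with N < 2")
    return float((n * (n - 1)).sum() / (total * (total - 1)))


def _chao1(counts: np.ndarray) -> float:
    obs = int((counts > 0).sum())
    f1 = int((counts == 1).sum())
    f2 = int((counts == 2).sum())
    return obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def _ace(counts: np.ndarray) -> float:
    pos = counts[counts > 0]
    rare = pos[pos <= ACE_RARE_THRESHOLD]
    s_abund = int((pos > ACE_RARE_THRESHOLD).sum())
    s_rare = len(rare)
    if s_rare == 0:
        return float(s_abund)
    n_rare = int(rare.sum())
    f1 = int((rare == 1).sum())
    if n_rare == f1:  # C_ace = 0: estimator degenerate
        return np.nan
    c_ace = 1.0 - f1 / n_rare
    freqs = np.arange(1, ACE_RARE_THRESHOLD + 1)
    fi = np.array([(rare == i).sum() for i in freqs])
    gamma2 = (s_rare / c_ace) * (freqs * (freqs - 1) @ fi) / (n_rare * (n_rare - 1.0)) - 1.0
    gamma2 = max(gamma2, 0.0)
    return s_abund + s_rare / c_ace + f1 * gamma2 / c_ace


def alpha_diversity(table: OtuTable, base: float | None = None) -> pd.DataFrame:
    """Per-sample alpha-diversity indices.

    Returns a DataFrame indexed by sample id with columns
    ``observed_otus``, ``shannon``, ``simpson_d`` (probability of
    identity), ``simpson`` (1-D), ``chao`` and ``ace``.  Chao1 and ACE
    are abundance-based richness estimators and refuse non-integer
    (relative-abundance) tables.
    """
    if table.relative:
        raise ValidationError(
            "Chao/ACE richness estimators require integer counts; "
            "got a relative-abundance table"
        )
    rows = {}
    for sample_id, counts in table.counts.iterrows():
        c = counts.to_numpy()
        d = _simpson_d(c)
        rows[sample_id] = {
            "observed_otus": int((c > 0).sum()),
            "shannon": _shannon(c, base),
            "simpson_d": d,
            "simpson": 1.0 - d,
            "chao": _chao1(c),
            "ace": _ace(c),
        }
    return pd.DataFrame.from_dict(rows, orient="index").loc[table.sample_ids]


def rarefy(table: OtuTable, depth: int | None = None, seed: int = 0) -> OtuTable:
    """Subsample every sample without replacement to an even depth
    (default: the minimum library size)."""
    totals = table.counts.sum(axis=1)
    if depth is None:
        depth = int(totals.min())
    if depth < 1:
        raise ValueError("rarefaction depth must be >= 1")
    if (totals < depth).any():
        shallow = totals.index[totals < depth].tolist()
        raise ValidationError(f"sample(s) shallower than depth {depth}: {shallow}")
    rng = np.random.default_rng(seed)
    out = np.zeros_like(table.counts.to_numpy())
    for i, (_, counts) in enumerate(table.counts.iterrows()):
        c = counts.to_numpy()
        pool = np.repeat(np.arange(len(c)), c)
        take = rng.choice(pool, size=depth, replace=False)
        out[i] = np.bincount(take, minlength=len(c))
    return OtuTable(pd.DataFrame(out, index=table.counts.index, columns=table.counts.columns))


@dataclass
class AccumulationCurve:
    """Sample-based OTU accumulation: mean/sd of distinct OTUs observed in
    the first n samples over random sample orderings."""

    n_samples: np.ndarray
    mean_otus: np.ndarray
    sd_otus: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"n_samples": self.n_samples, "mean_otus": self.mean_otus, "sd_otus": self.sd_otus}
        )


def accumulation_curve(table: OtuTable, n_perm: int = 100, seed: int = 0) -> AccumulationCurve:
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if table.n_samples < 2:
        raise ValidationError("accumulation curve needs >= 2 samples")
    presence = (table.counts.to_numpy() > 0)
    n = presence.shape[0]
    rng = np.random.default_rng(seed)
    richness = np.empty((n_perm, n))
    for p in range(n_perm):
        order = rng.permutation(n)
        seen = np.logical_or.accumulate(presence[order], axis=0)
        richness[p] = seen.sum(axis=1)
    return AccumulationCurve(
        n_samples=np.arange(1, n + 1),
        mean_otus=richness.mean(axis=0),
        sd_otus=richness.std(axis=0, ddof=0),
    )


def bray_curtis(table: OtuTable) -> skbio.DistanceMatrix:
    """Bray-Curtis dissimilarity on relative abundances."""
    rel = table.relative_abundance().to_numpy()
    return beta_diversity("braycurtis", rel, ids=table.sample_ids)


def unweighted_unifrac(table: OtuTable, tree: skbio.TreeNode) -> skbio.DistanceMatrix:
    """Unweighted UniFrac: per pair, the fraction of union branch length
    leading only to leaves present (count > 0) in exactly one sample."""
    tips = {tip.name for tip in tree.tips()}
    present = table.counts.columns[(table.counts > 0).any(axis=0)]
    missing = [o for o in present if o not in tips]
    if missing:
        raise KeyError(f"OTU(s) with nonzero counts absent from tree: {missing}")
    return beta_diversity(
        "unweighted_unifrac",
        table.counts.to_numpy(),
        ids=table.sample_ids,
        taxa=table.otu_ids,
        tree=tree,
        validate=True,
    )


@dataclass
class OrdinationResult:
    """Low-dimensional embedding of samples.

    ``explained`` holds per-axis explained-variance proportions (PCoA /
    PCA); ``stress`` holds Kruskal stress-1 (NMDS); ``converged`` flags
    NMDS runs that stopped at the iteration cap.
    """

    coordinates: pd.DataFrame
    method: str
    explained: np.ndarray | None = None
    stress: float | None = None
    converged: bool = True


def pcoa(dm: skbio.DistanceMatrix, k: int = 2) -> OrdinationResult:
    """Classical (Torgerson) scaling of a distance matrix.

    Double-centers -0.5 * J D^2 J, eigendecomposes, and scales
    eigenvectors by sqrt(eigenvalue).  Explained proportions are over
    positive eigenvalues only; axes beyond the positive spectrum are
    dropped (with a warning) rather than fabricated.
    """
    d = dm.data
    n = d.shape[0]
    if not 1 <= k <= n - 1:
        raise ValueError(f"k must be in [1, {n - 1}], got {k}")
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(abs(eigvals[0]), 1.0) * 1e-12
    n_pos = int((eigvals > tol).sum())
    if n_pos == 0:
        raise ValidationError("distance matrix has no positive eigenvalues")
    if k > n_pos:
        import warnings

        warnings.warn(
            f"only {n_pos} positive eigenvalue(s); reducing k from {k} to {n_pos}",
            stacklevel=2,
        )
        k = n_pos
    coords = eigvecs[:, :k] * np.sqrt(eigvals[:k])
    explained = eigvals[:k] / eigvals[:n_pos].sum()
    frame = pd.DataFrame(
        coords, index=list(dm.ids), columns=[f"PC{i + 1}" for i in range(k)]
    )
    return OrdinationResult(frame, method="pcoa", explained=explained)


def kruskal_stress(dm: skbio.DistanceMatrix, coords: np.ndarray) -> float:
    """Kruskal stress-1 of a configuration against observed dissimilarities:
    sqrt( sum (dhat - f(d))^2 / sum dhat^2 ) with f the best monotone
    (isotonic) regression of configuration distances on observed ranks."""
    iu = np.triu_indices(dm.shape[0], k=1)
    d_obs = dm.data[iu]
    diff = coords[:, None, :] - coords[None, :, :]
    d_emb = np.sqrt((diff ** 2).sum(-1))[iu]
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    fitted = iso.fit_transform(d_obs, d_emb)
    denom = (d_emb ** 2).sum()
    if denom == 0:
        return 0.0
    return float(np.sqrt(((d_emb - fitted) ** 2).sum() / denom))


def nmds(
    dm: skbio.DistanceMatrix,
    k: int = 2,
    seed: int = 0,
    n_restarts: int = 20,
    max_iter: int = 300,
    tol: float = 1e-7,
) -> OrdinationResult:
    """Non-metric MDS: best of ``n_restarts`` runs (the first initialised
    from PCoA, the rest random), scored by Kruskal stress-1."""
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    n = dm.shape[0]
    if not 1 <= k <= n - 1:
        raise ValueError(f"k must be in [1, {n - 1}], got {k}")
    rng = np.random.default_rng(seed)
    inits = [pcoa(dm, k=min(k, n - 1)).coordinates.to_numpy()]
    if inits[0].shape[1] < k:  # pad if positive spectrum was short
        pad = np.zeros((n, k - inits[0].shape[1]))
        inits[0] = np.hstack([inits[0], pad])
    for _ in range(n_restarts - 1):
        inits.append(rng.normal(size=(n, k)))
    best_coords, best_stress = None, np.inf
    for init in inits:
        mds = MDS(
            n_components=k,
            metric="precomputed",
            metric_mds=False,
            init="random",  # overridden by the explicit init below
            n_init=1,
            max_iter=max_iter,
            eps=tol,
            normalized_stress=True,
            random_state=int(rng.integers(2 ** 31 - 1)),
        )
        coords = mds.fit_transform(dm.data, init=init)
        stress = kruskal_stress(dm, coords)
        if stress < best_stress:
            best_coords, best_stress = coords, stress
    frame = pd.DataFrame(
        best_coords, index=list(dm.ids), columns=[f"NMDS{i + 1}" for i in range(k)]
    )
    return OrdinationResult(frame, method="nmds", stress=best_stress)


def pca(table: OtuTable, k: int = 2) -> OrdinationResult:
    """PCA of centered relative abundances (singular decomposition)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    rel = table.relative_abundance().to_numpy()
    k = min(k, min(rel.shape))
    model = PCA(n_components=k, svd_solver="full")
    coords = model.fit_transform(rel)
    frame = pd.DataFrame(
        coords, index=table.sample_ids, columns=[f"PC{i + 1}" for i in range(k)]
    )
    return OrdinationResult(frame, method="pca", explained=model.explained_variance_ratio_)


def otu_overlap(table: OtuTable, meta: CohortMetadata) -> dict:
    """Venn-style OTU overlap between case and control groups.

    An OTU is present in a group if it has a nonzero count in at least
    one sample of that group.  Returns shared / per-group-unique counts
    and id lists partitioning the observed OTU set.
    """
    labels = meta.group_labels(table.sample_ids)
    result: dict = {}
    presence = {}
    for group in ("case", "control"):
        ids = labels.index[labels == group]
        if len(ids) == 0:
            raise ValidationError(f"group {group!r} has zero samples")
        presence[group] = set(
            table.counts.columns[(table.counts.loc[ids] > 0).any(axis=0)]
        )
    shared = presence["case"] & presence["control"]
    result["shared"] = len(shared)
    result["shared_ids"] = sorted(shared)
    for group in ("case", "control"):
        unique = presence[group] - shared
        result[f"unique_{group}"] = len(unique)
        result[f"unique_{group}_ids"] = sorted(unique)
    result["total_observed"] = len(presence["case"] | presence["control"])
    return result
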