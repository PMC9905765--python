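"""Dirichlet-multinomial simulator of case-control tongue-coating
cohorts with known ground truth.

The generative model mirrors the statistical structure the analysis
assumes:

* a log-normal baseline composition over ``n_otus`` OTUs (few dominant
  taxa, a long rare tail);
* ``n_markers`` planted differentially abundant OTUs, half
  case-enriched by ``marker_fold`` and half case-depleted by
  1/``marker_fold``, drawn from the mid-abundance range where real
  biomarker OTUs live;
* per-sample compositions drawn Dirichlet around the group profile with
  concentration ``dispersion`` (overdispersion between subjects), the
  case-group concentration inflated by ``1 + evenness_shift`` so case
  communities are more even — reproducing the direction of the
  increased-diversity finding;
* integer counts drawn multinomially at a negative-binomial
  (gamma-Poisson) library size;
* derivation / validation / cross-regional cohort structure, the
  cross-regional cohort perturbed by a multiplicative log-normal batch
  shift shared by its samples;
* a three-level SLEDAI disease-activity gradient in cases, with
  ``activity_markers`` OTUs scaled monotonically across strata;
* clinical indices with group-level shifts, plus Gaussian-copula links
  tying chosen OTUs to chosen indices at a target Spearman rho.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import skbio

from .containers import CohortMetadata, GroundTruth, OtuTable

__all__ = [
    "CohortSpec",
    "SyntheticConfig",
    "simulate_cohort",
    "default_study_config",
    "random_taxonomy",
    "random_tree",
]

# Group-level clinical distributions (mean, sd) chosen to echo the
# direction and rough scale of published SLE-vs-control blood indices:
# lower leukocyte/erythrocyte/haemoglobin/platelet/lymphocyte values and
# higher globulin in cases.
CLINICAL_PARAMS: dict[str, dict[str, tuple[float, float]]] = {
    "age": {"case": (34.0, 8.0), "control": (33.0, 7.0)},
    "bmi": {"case": (21.9, 2.6), "control": (22.0, 2.0)},
    "wbc": {"case": (5.3, 1.8), "control": (6.1, 1.5)},
    "rbc": {"case": (4.02, 0.53), "control": (4.71, 0.49)},
    "hb": {"case": (120.2, 17.8), "control": (138.2, 16.0)},
    "plt": {"case": (210.0, 60.0), "control": (235.0, 50.0)},
    "lyn": {"case": (1.25, 0.50), "control": (2.0, 0.50)},
    "glb": {"case": (30.1, 4.5), "control": (26.8, 3.3)},
}
FEMALE_FRACTION = 0.94

SLEDAI_RANGES = {"mild": (0, 6), "moderate": (7, 11), "severe": (12, 20)}


@dataclass
class CohortSpec:
    name: str  # derivation | validation | cross_regional
    n_case: int
    n_control: int
    batch_shift_sd: float = 0.0  # log-scale multiplicative profile noise


@dataclass
class SyntheticConfig:
    cohorts: list[CohortSpec]
    n_otus: int = 800
    n_markers: int = 10
    marker_fold: float = 4.0
    base_logmean_sd: float = 2.0
    dispersion: float = 50.0  # Dirichlet concentration
    depth_mean: float = 20000.0
    depth_shape: float = 10.0
    evenness_shift: float = 0.3
    activity_markers: int = 4
    activity_fold: float = 2.0
    activity_proportions: tuple[float, float, float] = (0.5, 0.4, 0.1)
    clinical_link: list[tuple[int, str, float]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_markers > self.n_otus:
            raise ValueError("n_markers must be <= n_otus")
        if self.marker_fold <= 1:
            raise ValueError("marker_fold must be > 1")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        for spec in self.cohorts:
            if spec.n_case < 1 or spec.n_control < 1:
                raise ValueError(f"cohort {spec.name!r} must have positive group sizes")
        for _, index, rho in self.clinical_link:
            if abs(rho) >= 1:
                raise ValueError(f"infeasible target rho {rho} for index {index!r}")
            if index not in CLINICAL_PARAMS:
                raise ValueError(f"unknown clinical index {index!r}")
        if abs(sum(self.activity_proportions) - 1.0) > 1e-9:
            raise ValueError("activity_proportions must sum to 1")


def default_study_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """Default three-cohort study design: derivation 100 case / 200
    control, validation 40/80, cross-regional 42/80 with a batch shift;
    800 OTUs."""
    params = dict(
        cohorts=[
            CohortSpec("derivation", 100, 200, 0.0),
            CohortSpec("validation", 40, 80, 0.0),
            CohortSpec("cross_regional", 42, 80, 0.35),
        ],
        n_otus=800,
        n_markers=10,
        marker_fold=4.0,
        clinical_link=[(0, "wbc", -0.4), (1, "glb", 0.4), (2, "hb", -0.35)],
        seed=seed,
    )
    params.update(overrides)
    return SyntheticConfig(**params)


def _pick_markers(rng: np.random.Generator, p_base: np.ndarray, n: int) -> np.ndarray:
    """Sample marker OTUs from the mid-abundance band (baseline relative
    abundance between roughly 2e-3 and 2e-2), widening the band if it is
    too narrow."""
    lo, hi = 2e-3, 2e-2
    candidates = np.nonzero((p_base >= lo) & (p_base <= hi))[0]
    while len(candidates) < n:
        lo *= 0.5
        hi *= 1.5
        candidates = np.nonzero((p_base >= lo) & (p_base <= hi))[0]
    return rng.choice(candidates, size=n, replace=False)


def simulate_cohort(config: SyntheticConfig) -> tuple[OtuTable, CohortMetadata, GroundTruth]:
    """Simulate all configured cohorts; fully reproducible by seed.

    Returns the combined count table (rows ordered cohort by cohort,
    cases first), the matching metadata (group, cohort, SLEDAI-derived
    activity, gender, clinical indices) and the planted ground truth.
    """
    rng = np.random.default_rng(config.seed)
    otu_ids = [f"OTU{i + 1}" for i in range(config.n_otus)]

    log_base = rng.normal(0.0, config.base_logmean_sd, size=config.n_otus)
    p_base = np.exp(log_base)
    p_base /= p_base.sum()

    marker_idx = _pick_markers(rng, p_base, config.n_markers)
    n_up = config.n_markers - config.n_markers // 2
    folds = np.where(
        np.arange(config.n_markers) < n_up, config.marker_fold, 1.0 / config.marker_fold
    )

    non_marker = np.setdiff1d(np.arange(config.n_otus), marker_idx)
    if config.activity_markers:
        band = non_marker[
            (p_base[non_marker] >= 5e-4) & (p_base[non_marker] <= 5e-3)
        ]
        if len(band) < config.activity_markers:
            band = non_marker
        act_idx = rng.choice(band, size=config.activity_markers, replace=False)
    else:
        act_idx = np.array([], dtype=int)
    n_act_up = len(act_idx) - len(act_idx) // 2
    act_dir = np.where(np.arange(len(act_idx)) < n_act_up, 1, -1)

    # Plant folds exactly on the composition scale: marker abundances are
    # set to p_base * fold and the non-marker block is rescaled to fill
    # the remainder (the compositional spillover lands on non-markers).
    case_profile = p_base.copy()
    case_profile[marker_idx] = p_base[marker_idx] * folds
    marker_mass = case_profile[marker_idx].sum()
    if marker_mass >= 1.0:
        raise ValueError("planted marker mass exceeds the whole composition")
    case_profile[non_marker] *= (1.0 - marker_mass) / p_base[non_marker].sum()
    profiles = {"case": case_profile, "control": p_base}

    counts_rows, meta_rows, index_rows = [], [], []
    for spec in config.cohorts:
        shift = (
            np.exp(rng.normal(0.0, spec.batch_shift_sd, size=config.n_otus))
            if spec.batch_shift_sd > 0
            else np.ones(config.n_otus)
        )
        for group, n_samples in (("case", spec.n_case), ("control", spec.n_control)):
            profile = profiles[group] * shift
            profile /= profile.sum()
            conc = config.dispersion * (
                1.0 + (config.evenness_shift if group == "case" else 0.0)
            )
            if group == "case":
                levels = rng.choice(
                    3, size=n_samples, p=list(config.activity_proportions)
                )
            else:
                levels = np.full(n_samples, -1)
            for i in range(n_samples):
                sample_profile = profile
                if group == "case" and len(act_idx):
                    sample_profile = profile.copy()
                    sample_profile[act_idx] *= config.activity_fold ** (
                        act_dir * levels[i]
                    )
                    act_mass = sample_profile[act_idx].sum()
                    rest = np.setdiff1d(np.arange(config.n_otus), act_idx)
                    sample_profile[rest] *= (1.0 - act_mass) / sample_profile[rest].sum()
                theta = rng.dirichlet(np.maximum(conc * sample_profile, 1e-9))
                lam = rng.gamma(
                    config.depth_shape, config.depth_mean / config.depth_shape
                )
                depth = max(int(rng.poisson(lam)), 500)
                counts_rows.append(rng.multinomial(depth, theta))
                sample_id = f"{spec.name[:5]}_{group[:4]}_{i + 1:03d}"
                index_rows.append(sample_id)
                row: dict = {"group": group, "cohort": spec.name}
                if group == "case":
                    stratum = ("mild", "moderate", "severe")[levels[i]]
                    lo, hi = SLEDAI_RANGES[stratum]
                    row["sledai"] = int(rng.integers(lo, hi + 1))
                else:
                    row["sledai"] = np.nan
                row["gender"] = "F" if rng.random() < FEMALE_FRACTION else "M"
                meta_rows.append(row)

    counts = pd.DataFrame(np.array(counts_rows), index=index_rows, columns=otu_ids)
    meta_frame = pd.DataFrame(meta_rows, index=index_rows)

    rel = counts.div(counts.sum(axis=1), axis=0)
    linked = {index for _, index, _ in config.clinical_link}
    n_total = len(index_rows)
    for name, by_group in CLINICAL_PARAMS.items():
        link = next(
            ((oi, rho) for oi, idx, rho in config.clinical_link if idx == name), None
        )
        if link is not None and name in linked:
            otu_i, rho = link
            otu_id = otu_ids[marker_idx[otu_i]] if otu_i < config.n_markers else otu_ids[otu_i]
            ranks = rel[otu_id].rank(method="average").to_numpy()
            z = _normal_scores(ranks)
            eps = rng.normal(size=n_total)
            mean = np.mean([m for m, _ in by_group.values()])
            sd = np.mean([s for _, s in by_group.values()])
            meta_frame[name] = mean + sd * (rho * z + np.sqrt(1 - rho ** 2) * eps)
        else:
            values = np.empty(n_total)
            for g in ("case", "control"):
                mask = (meta_frame["group"] == g).to_numpy()
                m, s = by_group[g]
                values[mask] = rng.normal(m, s, size=mask.sum())
            meta_frame[name] = values

    truth = GroundTruth(
        marker_otus={otu_ids[i]: float(f) for i, f in zip(marker_idx, folds)},
        activity_otus={otu_ids[i]: int(d) for i, d in zip(act_idx, act_dir)},
        clinical_links=[
            (
                otu_ids[marker_idx[oi]] if oi < config.n_markers else otu_ids[oi],
                idx,
                rho,
            )
            for oi, idx, rho in config.clinical_link
        ],
    )
    return OtuTable(counts), CohortMetadata(meta_frame), truth


def _normal_scores(ranks: np.ndarray) -> np.ndarray:
    from scipy import stats

    return stats.norm.ppf((ranks - 0.5) / len(ranks))


# Common oral-microbiome genera with their upper lineages, used to dress
# synthetic OTUs in plausible SILVA-style taxonomy.
_GENUS_LINEAGES = {
    "Prevotella": ("Bacteroidota", "Bacteroidia", "Bacteroidales", "Prevotellaceae"),
    "Alloprevotella": ("Bacteroidota", "Bacteroidia", "Bacteroidales", "Prevotellaceae"),
    "Porphyromonas": ("Bacteroidota", "Bacteroidia", "Bacteroidales", "Porphyromonadaceae"),
    "Streptococcus": ("Firmicutes", "Bacilli", "Lactobacillales", "Streptococcaceae"),
    "Granulicatella": ("Firmicutes", "Bacilli", "Lactobacillales", "Carnobacteriaceae"),
    "Abiotrophia": ("Firmicutes", "Bacilli", "Lactobacillales", "Aerococcaceae"),
    "Gemella": ("Firmicutes", "Bacilli", "Staphylococcales", "Gemellaceae"),
    "Veillonella": ("Firmicutes", "Negativicutes", "Veillonellales", "Veillonellaceae"),
    "Megasphaera": ("Firmicutes", "Negativicutes", "Veillonellales", "Veillonellaceae"),
    "Solobacterium": ("Firmicutes", "Erysipelotrichia", "Erysipelotrichales", "Erysipelotrichaceae"),
    "Rothia": ("Actinobacteriota", "Actinobacteria", "Micrococcales", "Micrococcaceae"),
    "Actinomyces": ("Actinobacteriota", "Actinobacteria", "Actinomycetales", "Actinomycetaceae"),
    "Neisseria": ("Proteobacteria", "Gammaproteobacteria", "Burkholderiales", "Neisseriaceae"),
    "Haemophilus": ("Proteobacteria", "Gammaproteobacteria", "Pasteurellales", "Pasteurellaceae"),
    "Sphingomonas": ("Proteobacteria", "Alphaproteobacteria", "Sphingomonadales", "Sphingomonadaceae"),
    "Phyllobacterium": ("Proteobacteria", "Alphaproteobacteria", "Hyphomicrobiales", "Phyllobacteriaceae"),
    "Fusobacterium": ("Fusobacteriota", "Fusobacteriia", "Fusobacteriales", "Fusobacteriaceae"),
    "Leptotrichia": ("Fusobacteriota", "Fusobacteriia", "Fusobacteriales", "Leptotrichiaceae"),
    "Campylobacter": ("Campilobacterota", "Campylobacteria", "Campylobacterales", "Campylobacteraceae"),
    "Capnocytophaga": ("Bacteroidota", "Bacteroidia", "Flavobacteriales", "Flavobacteriaceae"),
}


def random_taxonomy(otu_ids: list[str], seed: int = 0, unclassified_frac: float = 0.15):
    """Assign each OTU a plausible oral-bacterial lineage.

    A fraction of OTUs is truncated at the family level (their genus
    becomes ``<family>_unclassified``), mimicking incomplete reference
    annotation.  Returns a TaxonomyMap.
    """
    import pandas as pd

    from .containers import RANKS, TaxonomyMap

    rng = np.random.default_rng(seed)
    genera = list(_GENUS_LINEAGES)
    rows = {}
    for otu in otu_ids:
        genus = genera[int(rng.integers(len(genera)))]
        phylum, cls, order, family = _GENUS_LINEAGES[genus]
        lineage = {
            "domain": "Bacteria",
            "phylum": phylum,
            "class": cls,
            "order": order,
            "family": family,
            "genus": genus,
        }
        if rng.random() < unclassified_frac:
            lineage["genus"] = f"{family}_unclassified"
        rows[otu] = lineage
    frame = pd.DataFrame.from_dict(rows, orient="index")[list(RANKS)]
    return TaxonomyMap(frame)


def random_tree(otu_ids: list[str], seed: int = 0, branch_scale: float = 1.0) -> skbio.TreeNode:
    """Random rooted binary tree over the given leaves with exponential
    branch lengths — a synthetic stand-in phylogeny for UniFrac testing
    (no evolutionary realism intended)."""
    rng = np.random.default_rng(seed)
    nodes = [skbio.TreeNode(name=o, length=float(rng.exponential(branch_scale)))
             for o in otu_ids]
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        a, b = nodes[i], nodes[j]
        parent = skbio.TreeNode(length=float(rng.exponential(branch_scale)))
        parent.extend([a, b])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    root = nodes[0]
    root.length = None
    return root
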