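import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from oramark.containers import CohortMetadata, OtuTable, TaxonomyMap
from oramark.io import read_taxonomy

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def toy_table() -> OtuTable:
    """Four samples x five OTUs with known presence structure."""
    counts = pd.DataFrame(
        [
            [5, 5, 5, 5, 0],
            [10, 0, 0, 0, 0],
            [1, 1, 2, 3, 5],
            [0, 0, 4, 4, 2],
        ],
        index=["s1", "s2", "s3", "s4"],
        columns=["o1", "o2", "o3", "o4", "o5"],
    )
    return OtuTable(counts)


@pytest.fixture
def toy_meta() -> CohortMetadata:
    frame = pd.DataFrame(
        {
            "group": ["case", "case", "control", "control"],
            "cohort": ["derivation"] * 4,
            "sledai": [4, 13, np.nan, np.nan],
            "gender": ["F", "F", "F", "M"],
            "age": [30.0, 41.0, 28.0, 35.0],
        },
        index=["s1", "s2", "s3", "s4"],
    )
    return CohortMetadata(frame)


@pytest.fixture
def toy_taxonomy(tmp_path) -> TaxonomyMap:
    lines = [
        "o1\td__Bacteria;p__Proteobacteria;c__Alphaproteobacteria;o__Sphingomonadales;f__Sphingomonadaceae;g__Sphingomonas",
        "o2\td__Bacteria;p__Actinobacteriota;c__Actinobacteria;o__Micrococcales;f__Micrococcaceae",
        "o3\td__Bacteria;p__Actinobacteriota;c__Actinobacteria;o__Micrococcales;f__Micrococcaceae;g__Rothia",
        "o4\td__Bacteria;p__Firmicutes;c__Bacilli;o__Lactobacillales;f__Streptococcaceae;g__Streptococcus",
        "o5\td__Bacteria",
    ]
    path = tmp_path / "tax.tsv"
    path.write_text("\n".join(lines) + "\n")
    return read_taxonomy(path)


@pytest.fixture(scope="session")
def small_cohort():
    """A small three-cohort synthetic study for cross-module tests."""
    from oramark.synthetic import CohortSpec, SyntheticConfig, simulate_cohort

    cfg = SyntheticConfig(
        cohorts=[
            CohortSpec("derivation", 25, 50, 0.0),
            CohortSpec("validation", 15, 30, 0.0),
            CohortSpec("cross_regional", 15, 30, 0.35),
        ],
        n_otus=120,
        n_markers=6,
        marker_fold=4.0,
        clinical_link=[(0, "wbc", -0.4)],
        seed=42,
    )
    return simulate_cohort(cfg)
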