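#!/usr/bin/env python
"""Simulate the three-cohort case-control study used by the downstream
analysis steps.

Writes, under results/analysis/: the combined OTU count table
(542 samples: derivation 100 case / 200 control, validation 40/80,
batch-shifted cross-regional 42/80; 300 OTUs), sample metadata with
SLEDAI-derived activity strata and clinical indices, a synthetic
taxonomy, and the planted ground truth (10 marker OTUs at 4-fold,
activity-trend OTUs, OTU-clinical links).
"""

import json
from pathlib import Path

from oramark import io
from oramark.studies import study_config
from oramark.synthetic import random_taxonomy, simulate_cohort

SEED = 101
OUT = Path(__file__).resolve().parent.parent / "results" / "analysis"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = study_config(SEED)
    table, meta, truth = simulate_cohort(cfg)
    io.write_otu_table(table, OUT / "otu_table.tsv")
    io.write_metadata(meta, OUT / "metadata.tsv")
    io.write_taxonomy(random_taxonomy(table.otu_ids, seed=SEED), OUT / "taxonomy.tsv")
    (OUT / "ground_truth.json").write_text(json.dumps(truth.to_dict(), indent=2) + "\n")
    io.write_run_manifest(OUT / "simulate_manifest.json", SEED, {"n_otus": cfg.n_otus})
    sizes = meta.frame.groupby(["cohort", "group"]).size()
    print(f"wrote {table.n_samples} samples x {table.n_otus} OTUs to {OUT}")
    print(sizes.to_string())
    print(f"planted markers: {sorted(truth.marker_otus)}")


if __name__ == "__main__":
    main()
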