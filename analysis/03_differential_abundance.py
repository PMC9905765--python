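#!/usr/bin/env python
"""Screen for differentially abundant taxa in the derivation cohort.

Per-OTU and rank-wise (phylum, genus) two-sided Wilcoxon rank-sum
screens at raw p < 0.05, plus the two-class LDA effect-size scoring
(Kruskal-Wallis screen, bootstrapped linear-discriminant effect on the
per-million scale, log10 threshold 3).  Reports how many of the ten
planted marker OTUs the screen recovers.
"""

import json
from pathlib import Path

from oramark import diff_abundance, io

OUT = Path(__file__).resolve().parent.parent / "results" / "analysis"


def main() -> None:
    table = io.read_otu_table(OUT / "otu_table.tsv")
    meta = io.read_metadata(OUT / "metadata.tsv")
    tax = io.read_taxonomy(OUT / "taxonomy.tsv")
    truth = json.loads((OUT / "ground_truth.json").read_text())
    deriv_ids = meta.samples_in(cohort="derivation")
    deriv = table.subset_samples(deriv_ids)
    dmeta = meta.subset(deriv_ids)

    screen = diff_abundance.wilcoxon_screen(deriv, dmeta, alpha=0.05)
    io.write_result_table(screen.table, OUT / "wilcoxon_otu.tsv")
    sig = set(screen.significant.index)
    planted = set(truth["marker_otus"])
    print(
        f"OTU screen: {len(sig)} significant of {deriv.n_otus}; "
        f"recovers {len(sig & planted)}/{len(planted)} planted markers"
    )

    for rank in ("phylum", "genus"):
        rank_table = diff_abundance.aggregate_rank(deriv, tax, rank)
        rank_screen = diff_abundance.wilcoxon_screen(rank_table, dmeta, rank=rank)
        io.write_result_table(rank_screen.table, OUT / f"wilcoxon_{rank}.tsv")
        up = (rank_screen.significant["direction"] == "enriched_case").sum()
        down = (rank_screen.significant["direction"] == "enriched_control").sum()
        print(f"{rank} screen: {up} case-enriched, {down} control-enriched taxa")

    lda = diff_abundance.lda_effect_size(deriv, dmeta, threshold=3.0, seed=13)
    io.write_result_table(lda.table, OUT / "lda_effect_size.tsv")
    passing = set(lda.passing.index)
    print(
        f"LDA effect size: {len(passing)} taxa pass log10 >= 3; "
        f"{len(passing & planted)} are planted markers"
    )


if __name__ == "__main__":
    main()
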