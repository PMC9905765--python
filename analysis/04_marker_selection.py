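#!/usr/bin/env python
"""Select the optimal marker-OTU set and validate the classifier.

On the derivation cohort: rank Wilcoxon-significant OTUs by
out-of-bag Mean Decrease Accuracy, build five repeated five-fold
CV-error curves over growing top-m marker sets, apply the
minimum-plus-standard-deviation cutoff, fit the final vote forest on
the optimal set, and compute the POD (probability of disease) index
and AUC with DeLong 95% CI on the derivation, independent-validation
and batch-shifted cross-regional cohorts.
"""

import json
from pathlib import Path

import pandas as pd

from oramark import diff_abundance, io, markers

OUT = Path(__file__).resolve().parent.parent / "results" / "analysis"
SEED = 707


def main() -> None:
    table = io.read_otu_table(OUT / "otu_table.tsv")
    meta = io.read_metadata(OUT / "metadata.tsv")
    truth = json.loads((OUT / "ground_truth.json").read_text())
    deriv_ids = meta.samples_in(cohort="derivation")
    deriv = table.subset_samples(deriv_ids)
    dmeta = meta.subset(deriv_ids)

    screen = diff_abundance.wilcoxon_screen(deriv, dmeta, alpha=0.05)
    candidates = list(screen.significant.index)
    ranking = markers.rank_importance(deriv, dmeta, candidates, n_trees=500, seed=SEED)
    io.write_result_table(ranking, OUT / "importance_ranking.tsv")

    selection = markers.cv_error_curves(
        deriv, dmeta, ranking, n_trees=100, seed=SEED + 1, max_set_size=20
    )
    curves = pd.DataFrame(
        selection.cv_curves.T,
        index=pd.Index(range(1, len(selection.mean_curve) + 1), name="set_size"),
        columns=[f"repeat_{r + 1}" for r in range(selection.cv_curves.shape[0])],
    )
    curves["mean"] = selection.mean_curve
    curves["sd"] = selection.sd_curve
    io.write_result_table(curves, OUT / "cv_error_curves.tsv")

    planted = set(truth["marker_otus"])
    extra = [o for o in selection.optimal_set if o not in planted]
    print(
        f"cutoff {selection.cutoff:.4f}; optimal set "
        f"({len(selection.optimal_set)} OTUs): {', '.join(selection.optimal_set)}"
    )
    print(f"{len(selection.optimal_set) - len(extra)} planted, {len(extra)} extra")

    model = markers.fit_final_model(
        deriv, dmeta, selection.optimal_set, n_trees=1000, seed=SEED + 2
    )
    rows = []
    for cohort in ("derivation", "validation", "cross_regional"):
        ids = meta.samples_in(cohort=cohort)
        sub, sub_meta = table.subset_samples(ids), meta.subset(ids)
        if cohort == "derivation":
            pod = model.pod(sub)
            roc = markers.roc_auc(pod, sub_meta)
        else:
            pod, roc = markers.validate_external(model, sub, sub_meta)
        io.write_result_table(pod, OUT / f"pod_{cohort}.tsv")
        io.write_result_table(roc.curve, OUT / f"roc_{cohort}.tsv")
        rows.append(
            {"cohort": cohort, "auc": roc.auc, "ci_low": roc.ci_low,
             "ci_high": roc.ci_high, "n_case": roc.n_case, "n_control": roc.n_control}
        )
        print(
            f"{cohort}: AUC {roc.auc:.4f} (95% CI {roc.ci_low:.4f}-{roc.ci_high:.4f}, "
            f"{roc.n_case} case vs {roc.n_control} control)"
        )
    io.write_result_table(pd.DataFrame(rows).set_index("cohort"), OUT / "auc_summary.tsv")


if __name__ == "__main__":
    main()
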