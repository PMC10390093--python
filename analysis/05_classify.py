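"""Classify grade with cross-validated SVMs and rank the features by AUC.

Each of the 15 FD features is evaluated as a single-feature classifier, and
each region's five texture features are evaluated as a group, using the best
of three kernels (linear / polynomial / RBF) over five repeated stratified
70/30 splits.

Reads results/features.csv; writes results/classification.csv.
"""

import pandas as pd

from fracmorph.classification import select_best_kernel
from fracmorph.types import (
    REGIONS,
    TEXTURE_FEATURES,
    fd_feature_names,
    texture_feature_name,
)

SEED = 7


def main() -> None:
    table = pd.read_csv("results/features.csv")
    labels = table["label"].to_numpy()
    reports = []
    for col in fd_feature_names():
        rep = select_best_kernel(table[[col]].to_numpy(), labels, seed=SEED,
                                 feature_set=col)
        reports.append(rep)
    for region in REGIONS:
        cols = [texture_feature_name(region, f) for f in TEXTURE_FEATURES]
        rep = select_best_kernel(table[cols].to_numpy(), labels, seed=SEED,
                                 feature_set=f"tex_{region}")
        reports.append(rep)

    frame = pd.DataFrame([
        {k: v for k, v in r.as_dict().items() if k != "folds"}
        for r in reports
    ]).sort_values("auc", ascending=False)
    frame.to_csv("results/classification.csv", index=False)
    print(frame[["feature_set", "kernel", "accuracy", "sensitivity",
                 "specificity", "auc"]].round(1).to_string(index=False))
    top = frame.iloc[0]
    print(f"\ntop-ranked: {top.feature_set} "
          f"(AUC {top.auc:.0f}%, accuracy {top.accuracy:.0f}%)")


if __name__ == "__main__":
    main()
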