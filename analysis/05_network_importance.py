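#!/usr/bin/env python
"""Network-level reading of the selected model: node importance, the
storage-vs-retrieval contrast, selection enrichment, and sign-adjusted
(interpretable) weights.

Reads results/prediction/ and results/connectomes/, writes
results/importance/.
"""

import json
from pathlib import Path

import pandas as pd

from sofnet import io as sio
from sofnet.netstats import (
    node_importance,
    selection_enrichment,
    sign_adjusted_weights,
    storage_retrieval_test,
)

OUT = Path("results/importance")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    with open("results/prediction/lasso_report.json") as fh:
        betas = {k: float(v) for k, v in json.load(fh)["selected_beta"].items()}

    imp = node_importance(betas)
    imp.table.to_csv(OUT / "importance.csv", index_label="network")
    mean, sd, t, dof, p = storage_retrieval_test(imp)
    if t is None:
        print("storage importances have zero variance; t undefined")
    else:
        print(f"storage-network importance: M = {mean:.3f}, SD = {sd:.3f}, "
              f"t({dof}) = {t:.3f}, p = {p:.3f}")
    retrieval_mean = imp.by_group("Retrieval").mean()
    print(f"retrieval-network importance mean: {retrieval_mean:.3f}")

    enrich = selection_enrichment(list(betas), within_dmn="exclude")
    print(f"probability that a uniform draw is as storage-pure: {enrich:.4f}")

    group_mean = sio.read_matrix("results/connectomes/group_mean_partial.csv",
                                 kind="partial")
    adjusted = sign_adjusted_weights(betas, group_mean)
    pd.DataFrame(
        {"edge": list(adjusted), "signed_weight": list(adjusted.values()),
         "beta": [betas[e] for e in adjusted]}
    ).to_csv(OUT / "signed_weights.csv", index=False)
    n_pos = sum(w > 0 for w in adjusted.values())
    print(f"sign-adjusted weights: {n_pos}/{len(adjusted)} edges where more "
          f"connectivity predicts faster forgetting")
    print(f"wrote {OUT}/importance.csv and signed_weights.csv")


if __name__ == "__main__":
    main()
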