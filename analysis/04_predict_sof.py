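#!/usr/bin/env python
"""Predict the speed of forgetting from connectivity features with the
L1-penalized model and run the full validation battery: LOO prediction,
remove-all and remove-one refits, VIF, and a 200-shuffle permutation null.

Reads results/phenotypes/ and results/connectomes/, writes
results/prediction/lasso_report.json.
"""

import json
from pathlib import Path

import pandas as pd

from sofnet.prediction import (
    feature_removal_test,
    final_fit_and_report,
    permutation_test,
    vif,
)

OUT = Path("results/prediction")
N_PERMUTATIONS = 200


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    feats = pd.read_csv("results/connectomes/features.csv",
                        index_col="participant")
    pheno = pd.read_csv("results/phenotypes/phenotypes.csv",
                        index_col="participant")
    y = pheno.loc[feats.index, "sof"].to_numpy()
    X, names = feats.to_numpy(), list(feats.columns)

    report = final_fit_and_report(X, y, names)
    print(f"λ = {report.lambda_selected:.4g}; {report.n_selected} edges selected")
    print(f"fitted r = {report.fitted_r:.3f}; LOO r = {report.loo_r:.3f}")

    print("removing the selected support and re-running the λ search ...")
    reduced = feature_removal_test(X, y, report.selected, names)
    print("  -> intercept-only model" if reduced.is_null
          else f"  -> alternative support of {reduced.n_selected} edges")

    one_out = {}
    for edge in report.selected:
        refit = feature_removal_test(X, y, [edge], names)
        one_out[edge] = {
            "null": refit.is_null,
            "n_selected": refit.n_selected,
            "keeps_rest": set(report.selected) - {edge} <= set(refit.selected),
        }

    sel_idx = [names.index(f) for f in report.selected]
    vifs = (vif(X[:, sel_idx], report.selected)
            if 2 <= len(sel_idx) <= len(y) - 2 else {})
    if vifs:
        print(f"VIF: max {max(vifs.values()):.2f} over {len(vifs)} predictors")

    perm = permutation_test(X, y, N_PERMUTATIONS, seed=0,
                            observed_fitted_r=report.fitted_r)
    print(f"permutation null ({N_PERMUTATIONS} shuffles): "
          f"{perm.frac_null_models:.1%} intercept-only, "
          f"{perm.frac_comparable:.1%} comparable fits, "
          f"empirical p = {perm.empirical_p:.4f}")

    payload = {
        "lambda": report.lambda_selected,
        "selected_beta": {f: float(report.beta[f]) for f in report.selected},
        "intercept": report.intercept,
        "fitted_r": report.fitted_r,
        "loo_r": report.loo_r,
        "remove_all_null": bool(reduced.is_null),
        "remove_one": one_out,
        "vif": vifs,
        "permutation": {
            "n_shuffles": perm.n_shuffles,
            "frac_null_models": perm.frac_null_models,
            "frac_comparable": perm.frac_comparable,
            "empirical_p": perm.empirical_p,
        },
    }
    with open(OUT / "lasso_report.json", "w") as fh:
        json.dump(payload, fh, indent=2, default=str)
        fh.write("\n")
    print(f"wrote {OUT}/lasso_report.json")


if __name__ == "__main__":
    main()
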