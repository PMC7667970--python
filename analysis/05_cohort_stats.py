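"""Group statistics and correlations for both demo cohorts.

Joins the mucus readouts onto the mouse tables, runs the normality-gated
two-group comparisons for every variable (mucus readouts and metabolic
covariates incl. HOMA-IR), and tests correlations of penetrability and
growth rate against the metabolic phenotype across all mice.
"""

from pathlib import Path

import pandas as pd

from mucolab.stats import compare_groups, correlate, homa_ir

ROOT = Path(__file__).resolve().parents[1] / "results"

VARIABLES = ("auc_um", "rate_um_per_min", "thickness_avg_um", "body_weight_g",
             "fasting_glucose_mM", "fasting_insulin_uU_ml", "homa_ir")
METABOLIC = ("fasting_glucose_mM", "fasting_insulin_uU_ml", "body_weight_g",
             "homa_ir")


def load_mice(name: str) -> pd.DataFrame:
    d = ROOT / "cohorts" / name
    truth = pd.read_csv(d / "mice_truth.tsv", sep="\t")
    pen = pd.read_csv(d / "penetrability_mice.tsv", sep="\t").drop(columns="group")
    gr = pd.read_csv(d / "growth_rates.tsv", sep="\t").drop(columns="group")
    mice = truth.merge(pen, on="mouse").merge(gr, on="mouse")
    mice["homa_ir"] = homa_ir(mice["fasting_glucose_mM"],
                              mice["fasting_insulin_uU_ml"])
    return mice


def main() -> None:
    for name in ("separated", "cohoused"):
        mice = load_mice(name)
        rows = []
        for var in VARIABLES:
            cmp = compare_groups(mice, var)
            rows.append({"variable": var, "test": cmp.test.method,
                         "mean_a": cmp.means[0], "mean_b": cmp.means[1],
                         "sd_a": cmp.sds[0], "sd_b": cmp.sds[1],
                         "p_value": cmp.test.p_value})
        stats = pd.DataFrame(rows)
        stats.to_csv(ROOT / "cohorts" / name / "group_comparisons.tsv",
                     sep="\t", index=False, float_format="%.6g")
        sig = stats.set_index("variable")["p_value"]
        print(f"{name}: p-values — penetrability "
              f"{sig['auc_um']:.4g}, growth rate "
              f"{sig['rate_um_per_min']:.4g}, HOMA-IR {sig['homa_ir']:.4g}")

        corr_rows = []
        for readout in ("auc_um", "rate_um_per_min"):
            for covar in METABOLIC:
                res = correlate(mice[covar], mice[readout])
                corr_rows.append({"readout": readout, "covariate": covar,
                                  "method": res.method,
                                  "coefficient": res.coefficient,
                                  "p_value": res.p_value,
                                  "slope": res.slope,
                                  "intercept": res.intercept})
        pd.DataFrame(corr_rows).to_csv(
            ROOT / "cohorts" / name / "correlations.tsv", sep="\t",
            index=False, float_format="%.6g")
    print("correlation tables written (regression line only where p <= 0.05)")


if __name__ == "__main__":
    main()
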