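"""Per-stack and per-mouse normalized penetrability for both demo cohorts.

Reads the bead-distance tables written by 01_simulate_cohorts.py, runs the
histogram → normalize → align → crop → AUC chain on every stack, aggregates
per mouse (median AUC, median bead frequency curve), and plots the per-mouse
median curves by group.
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from mucolab.io import read_bead_table
from mucolab.penetrability import aggregate_mouse, compute_penetrability

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    for name in ("separated", "cohoused"):
        d = ROOT / "cohorts" / name
        sets, _ = read_bead_table(d / "bead_distances.tsv")
        truth = pd.read_csv(d / "mice_truth.tsv", sep="\t")
        group_of = dict(zip(truth["mouse"], truth["group"]))

        stack_rows, mouse_rows, curves_by_mouse = [], [], {}
        by_mouse: dict[str, list] = {}
        for ds in sets:
            by_mouse.setdefault(ds.mouse_id, []).append(ds)
        for mouse, dss in by_mouse.items():
            results, curves = zip(*(compute_penetrability(ds) for ds in dss))
            for r in results:
                stack_rows.append({"mouse": mouse, "stack": r.stack_id,
                                   "auc_um": r.auc_um,
                                   "thickness_avg_um": r.thickness_avg_um,
                                   "n_beads": r.n_beads})
            agg = aggregate_mouse(list(results), list(curves), mouse_id=mouse)
            mouse_rows.append({"mouse": mouse, "group": group_of[mouse],
                               "auc_um": agg.auc_um,
                               "thickness_avg_um": agg.thickness_avg_um})
            curves_by_mouse[mouse] = (agg.median_curve_x_um, agg.median_curve_f)

        pd.DataFrame(stack_rows).to_csv(d / "penetrability_stacks.tsv",
                                        sep="\t", index=False, float_format="%.8g")
        mice = pd.DataFrame(mouse_rows)
        mice.to_csv(d / "penetrability_mice.tsv", sep="\t", index=False,
                    float_format="%.8g")

        fig, ax = plt.subplots(figsize=(5, 3.5))
        colors = {g: c for g, c in zip(sorted(mice["group"].unique()),
                                       ("tab:blue", "tab:red"))}
        for mouse, (x, f) in curves_by_mouse.items():
            ax.plot(x, f, color=colors[group_of[mouse]], alpha=0.6, lw=1)
        for g, c in colors.items():
            ax.plot([], [], color=c, label=g)
        ax.set_xlabel("depth below mucus surface (µm)")
        ax.set_ylabel("normalized bead frequency")
        ax.set_title(f"median bead frequency per mouse — {name}")
        ax.legend()
        fig.tight_layout()
        fig.savefig(d / "median_curves.png", dpi=150)
        plt.close(fig)

        means = mice.groupby("group")["auc_um"].agg(["mean", "std"])
        print(f"{name}: per-mouse normalized penetrability (µm)")
        print(means.round(2).to_string(), "\n")


if __name__ == "__main__":
    main()
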