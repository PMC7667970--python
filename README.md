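# mucolab

Quantification of intestinal mucus barrier function from confocal bead
assays and ex vivo kinetics, with a ground-truthed synthetic-data
generator for validating the entire chain.

## The problem

The inner colonic mucus layer normally excludes bacteria-sized particles.
A standard ex vivo assay overlays live intestinal tissue with 1-µm
fluorescent beads, images a two-channel confocal z-stack (tissue +
beads), and asks how deep the beads sank.  This package implements the
full analysis for that assay and its companions, for researchers studying
mucus barrier defects in metabolic disease models (e.g. lean vs ob/ob
littermates, normoglycemic vs diabetic NOD mice):

- **Normalized penetrability** — per stack, the tissue-to-bead axial
  distances d_i are binned (width b = 5 µm); the frequency curve is
  normalized to its maximum, re-anchored at the mucus surface (the modal
  bin, outermost on ties), cropped above the surface, and integrated:

      AUC = ∫ f(x) dx,   f(x) = counts(x) / max counts,
      x = depth below mucus surface (µm)

  0 µm for an impenetrable layer, up to (T − b) for a uniformly
  penetrated layer of thickness T.  Per mouse: median across stacks.
- **Mucus thickness** — mean tissue-to-bead distance per stack.
- **Mucus growth rate** — OLS slope (µm/min) of micromanipulator
  thickness read every 15 min at five locations for up to 45 min.
- **Cohort statistics** — HOMA-IR = glucose·insulin/22.5, the >14.5 mM
  diabetes label, normality-gated test dispatch (unpaired t vs
  Mann–Whitney U, D'Agostino–Pearson gate), and normality-gated
  Pearson/Spearman correlation with conditional regression lines.
- **Synthetic data** — tissue surfaces, mixture bead populations
  (fraction p penetrates to a random depth in the layer), rendered
  two-channel TIFF stacks, thickness series, and whole two-group cohorts
  with known ground truth, plus a closed-form expectation of the AUC
  statistic used as an analytic oracle.

See `docs/methods.md` for the model, conventions, and limitations.

## Worked example

```python
import mucolab as m

# a defective mucus layer: 60% of beads penetrate an 80-µm layer
model = m.MucusModel(thickness_um=80, penetration_fraction=0.6)
ds = m.sample_bead_distances(model, n_beads=300, seed=1)
result, curve = m.compute_penetrability(ds, bin_width_um=5)
print(f"normalized penetrability {result.auc_um:.2f} µm, "
      f"thickness {result.thickness_avg_um:.1f} µm from {result.n_beads} beads")
print(f"analytic expectation {m.expected_penetrability(model, 5):.2f} µm")
```

prints

```
normalized penetrability 9.63 µm, thickness 56.5 µm from 300 beads
analytic expectation 9.77 µm
```

The sampled statistic (9.63 µm) sits within sampling error of its
closed-form expectation (9.77 µm); the mean bead distance (56.5 µm)
reflects that 60% of beads sank below the 80-µm surface.  An
impenetrable layer (`penetration_fraction=0`) scores 0 µm.

The numbered scripts under `analysis/` run the full study arc — simulate
the genotype-separated and co-housed demo cohorts, validate the imaging
chain, compute penetrability and growth rates, and run the group
statistics — writing tables under `results/`:

```sh
python analysis/01_simulate_cohorts.py
python analysis/02_stack_recovery.py
python analysis/03_penetrability.py
python analysis/04_growth_rates.py
python analysis/05_cohort_stats.py
```

On the default seed the separated cohort shows the obese-group barrier
defect (per-mouse penetrability 18.2 vs 6.8 µm, growth rate 0.99 vs
2.01 µm/min, p = 1.4e-7 and 8.5e-6) while the co-housed cohort shows
none (p = 0.64 and 0.88) — with the metabolic differences (HOMA-IR,
p = 3.4e-7) intact in both.  A CLI exposes the same steps (`mucolab simulate`,
`analyze-stack`, `penetrability`, `growth-rate`, `cohort-stats`, `run`).

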