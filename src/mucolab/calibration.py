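"""Simulation-based validation of the pipeline against known ground truth.

Each function here runs one calibration experiment end to end: agreement of
the sampled penetrability AUC with its closed-form expectation, monotone
response to the true penetration fraction, recovery of bead distances from
rendered stacks, growth-rate estimator bias and coverage, type-I error and
power of the group comparison, and reproduction of the study's qualitative
shape (separated cohorts differ in mucus readouts, co-housed cohorts do
not).  The acceptance script and the test suite both drive these.
"""

from __future__ import annotations

from dataclasses import replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .io import RunConfig, analyze_cohort, load_run_config
from .kinetics import fit_growth_rate
from .penetrability import compute_penetrability
from .stacks import compute_bead_distances, detect_beads, extract_tissue_surface
from .stats import compare_groups
from .synthetic import (
    MucusModel,
    RenderConfig,
    SurfaceConfig,
    expected_penetrability,
    generate_bead_population,
    generate_cohort,
    generate_thickness_series,
    generate_tissue_surface,
    render_zstack,
    sample_bead_distances,
)

__all__ = [
    "demo_config",
    "oracle_agreement",
    "monotone_response",
    "endtoend_recovery",
    "growth_rate_recovery",
    "type_one_error",
    "power_separated",
    "demo_significance",
]


def demo_config(name: str) -> RunConfig:
    """Load a packaged demo cohort configuration ('separated' or 'cohoused')."""
    ref = resources.files("mucolab") / "configs" / f"{name}_demo.yaml"
    with resources.as_file(ref) as path:
        return load_run_config(path)


def oracle_agreement(
    p_levels: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75, 1.0),
    n_beads: int = 10**6,
    thickness_um: float = 50.0,
    bin_width_um: float = 5.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Pipeline AUC on large bead samples vs the closed-form expectation.

    Returns one row per penetration fraction with the sampled and analytic
    AUC and their relative error (absolute error where the expectation is
    zero).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for p in p_levels:
        model = MucusModel(thickness_um=thickness_um, penetration_fraction=p)
        ds = sample_bead_distances(model, n_beads, seed=int(rng.integers(2**31)))
        res, _ = compute_penetrability(ds, bin_width_um)
        exp = expected_penetrability(model, bin_width_um)
        err = abs(res.auc_um - exp) / exp if exp > 0 else abs(res.auc_um - exp)
        rows.append(
            {"p": p, "auc_um": res.auc_um, "expected_um": exp, "rel_error": err}
        )
    return pd.DataFrame(rows)


def monotone_response(
    p_levels: tuple[float, ...] = (0.0, 0.2, 0.4, 0.6, 0.8),
    n_beads: int = 10**4,
    n_seeds: int = 20,
    thickness_um: float = 50.0,
    bin_width_um: float = 5.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean AUC across seeds at each true penetration fraction."""
    rows = []
    for p in p_levels:
        model = MucusModel(thickness_um=thickness_um, penetration_fraction=p)
        aucs = []
        for s in range(n_seeds):
            ds = sample_bead_distances(model, n_beads, seed=seed + 1000 * s + int(p * 100))
            res, _ = compute_penetrability(ds, bin_width_um)
            aucs.append(res.auc_um)
        rows.append({"p": p, "mean_auc_um": float(np.mean(aucs))})
    return pd.DataFrame(rows)


def endtoend_recovery(
    seed: int = 0,
    grid: int = 256,
    pixel_size_um: float = 1.0,
    z_step_um: float = 2.0,
    n_beads: int = 50,
    thickness_um: float = 80.0,
    penetration_fraction: float = 0.5,
) -> dict:
    """Render → detect → distances on a noise-free phantom vs ground truth.

    Beads are placed with a pairwise separation large enough that rendered
    blobs cannot merge, so the detected count must match exactly; distance
    recovery is summarized as the RMS error of the sorted detected vs true
    distance sets.
    """
    surface = generate_tissue_surface(
        SurfaceConfig(
            grid_nx=grid, grid_ny=grid, pixel_size_um=pixel_size_um,
            mean_z_um=40.0, amplitude_um=5.0, correlation_length_um=25.0,
            seed=seed,
        )
    )
    model = MucusModel(
        thickness_um=thickness_um, penetration_fraction=penetration_fraction
    )
    beads = generate_bead_population(
        surface, model, n_beads, seed=seed + 1, min_separation_um=6 * z_step_um
    )
    rendered = render_zstack(
        surface, beads, RenderConfig(z_step_um=z_step_um, seed=seed + 2)
    )
    surf = extract_tissue_surface(rendered.stack)
    det = detect_beads(rendered.stack)
    ds = compute_bead_distances(det, surf)
    rms = float("nan")
    if len(ds) == len(beads):
        true_sorted = np.sort(beads.true_distance_um)
        det_sorted = np.sort(ds.distances_um)
        rms = float(np.sqrt(np.mean((true_sorted - det_sorted) ** 2)))
    return {
        "n_true": len(beads),
        "n_detected": len(det),
        "n_clipped": int(rendered.clipped_bead_ids.size),
        "rms_error_um": rms,
        "z_step_um": z_step_um,
        "stack_shape": rendered.stack.intensities.shape,
    }


def growth_rate_recovery(
    n_mice: int = 200,
    rate_um_per_min: float = 1.5,
    initial_um: float = 400.0,
    noise_sigma_um: float = 10.0,
    seed: int = 0,
) -> dict:
    """Slope recovery across synthetic thickness series.

    Reports the mean fitted rate, its relative bias, and the fraction of
    fits whose true rate lies within ±2 standard errors.
    """
    rates, covered = [], 0
    for i in range(n_mice):
        ts = generate_thickness_series(
            initial_um, rate_um_per_min, noise_sigma_um, seed=seed + i
        )
        fit = fit_growth_rate(ts)
        rates.append(fit.rate_um_per_min)
        if abs(fit.rate_um_per_min - rate_um_per_min) <= 2 * fit.rate_std_error:
            covered += 1
    mean_rate = float(np.mean(rates))
    return {
        "mean_rate_um_min": mean_rate,
        "true_rate_um_min": rate_um_per_min,
        "bias_fraction": abs(mean_rate - rate_um_per_min) / rate_um_per_min,
        "coverage_2se": covered / n_mice,
        "n_mice": n_mice,
    }


def _mouse_aucs(
    model: MucusModel,
    n_mice: int,
    rng: np.random.Generator,
    n_stacks: int = 3,
    beads_per_stack: int = 300,
    bin_width_um: float = 5.0,
    noise_um: float = 2.0,
) -> np.ndarray:
    """Per-mouse penetrability (median across stacks) for calibration runs."""
    out = np.empty(n_mice)
    for i in range(n_mice):
        aucs = [
            compute_penetrability(
                sample_bead_distances(
                    model, beads_per_stack, seed=int(rng.integers(2**31)),
                    measurement_noise_um=noise_um,
                ),
                bin_width_um,
            )[0].auc_um
            for _ in range(n_stacks)
        ]
        out[i] = np.median(aucs)
    return out


def type_one_error(
    n_replicates: int = 1000,
    n_per_group: int = 10,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """False-positive rate of the group comparison on null cohorts.

    Both groups draw per-mouse penetrability from the same mucus model, so
    every rejection at level alpha is a type-I error.
    """
    rng = np.random.default_rng(seed)
    model = MucusModel(thickness_um=80.0, penetration_fraction=0.35,
                       surface_jitter_um=2.0)
    hits = 0
    for _ in range(n_replicates):
        a = _mouse_aucs(model, n_per_group, rng)
        b = _mouse_aucs(model, n_per_group, rng)
        table = pd.DataFrame(
            {"group": ["a"] * n_per_group + ["b"] * n_per_group,
             "auc": np.concatenate([a, b])}
        )
        if compare_groups(table, "auc").test.p_value <= alpha:
            hits += 1
    return {"type_one_error": hits / n_replicates, "n_replicates": n_replicates,
            "alpha": alpha}


def power_separated(
    n_replicates: int = 100,
    n_per_group: int = 10,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Rejection rate at the separated-cohort effect size.

    Group mucus models use the packaged separated demo parameters
    (penetration fraction 0.1 vs 0.6).
    """
    cfg = demo_config("separated").cohort
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_replicates):
        a = _mouse_aucs(cfg.groups[0].mucus, n_per_group, rng,
                        cfg.n_stacks_per_mouse, cfg.beads_per_stack,
                        noise_um=cfg.distance_noise_um)
        b = _mouse_aucs(cfg.groups[1].mucus, n_per_group, rng,
                        cfg.n_stacks_per_mouse, cfg.beads_per_stack,
                        noise_um=cfg.distance_noise_um)
        table = pd.DataFrame(
            {"group": ["a"] * n_per_group + ["b"] * n_per_group,
             "auc": np.concatenate([a, b])}
        )
        if compare_groups(table, "auc").test.p_value <= alpha:
            hits += 1
    return {"power": hits / n_replicates, "n_replicates": n_replicates,
            "alpha": alpha}


def demo_significance(
    n_seeds: int = 50,
    alpha: float = 0.05,
    seed: int = 0,
    variables: tuple[str, ...] = ("penetrability_auc_um", "growth_rate_um_min"),
) -> dict:
    """Qualitative study shape across seeds on the packaged demo cohorts.

    For each seed, both demo cohorts are simulated and analyzed; reported
    are, per variable, the fraction of seeds in which the separated-cohort
    contrast is significant and the co-housed contrast is not.
    """
    sep = demo_config("separated")
    coh = demo_config("cohoused")
    sig = {("separated", v): 0 for v in variables}
    sig.update({("cohoused", v): 0 for v in variables})
    for s in range(n_seeds):
        for name, cfg in (("separated", sep), ("cohoused", coh)):
            cohort = generate_cohort(replace(cfg.cohort, seed=seed + s))
            report = analyze_cohort(cohort, cfg.bin_width_um, variables)
            for v in variables:
                if report.summary["contrasts"][v]["p_value"] <= alpha:
                    sig[(name, v)] += 1
    out = {"n_seeds": n_seeds, "alpha": alpha}
    for v in variables:
        out[f"separated_significant_fraction_{v}"] = sig[("separated", v)] / n_seeds
        out[f"cohoused_nonsignificant_fraction_{v}"] = 1 - sig[("cohoused", v)] / n_seeds
    return out
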