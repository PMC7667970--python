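"""Normalized mucus penetrability from tissue-to-bead z distances.

The mucus barrier readout is computed from the axial distances between the
epithelial surface and 1-µm beads sedimented onto (and into) the mucus
layer.  For each confocal z-stack the distances are binned into a frequency
distribution, normalized to its maximum frequency (so stacks with different
bead numbers are comparable), re-anchored so that depth 0 is the mucus
surface (the modal bin: beads accumulate at the surface of an intact
layer), cropped to exclude beads above the surface, and integrated.  The
trapezoidal area under the resulting curve, in µm, is the *normalized
penetrability*: 0 for an impenetrable layer that concentrates every bead in
the surface bin, and up to (thickness − bin width) for a uniformly
penetrated layer.

Mean bead distance doubles as a bead-derived estimate of mucus thickness.
Per-mouse summaries use medians across that mouse's stacks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DistanceSet",
    "DistanceDistribution",
    "NormalizedDistribution",
    "PenetrabilityResult",
    "MousePenetrability",
    "build_distance_histogram",
    "normalize_and_align",
    "penetrability_auc",
    "thickness_from_beads",
    "compute_penetrability",
    "aggregate_mouse",
    "DEFAULT_BIN_WIDTH_UM",
]

#: Histogram bin width in µm.  Comparable to the axial sampling of a 20x
#: confocal stack and coarse enough to give a stable modal (surface) bin.
DEFAULT_BIN_WIDTH_UM = 5.0


@dataclass
class DistanceSet:
    """Tissue-to-bead axial distances for one z-stack.

    ``distances_um`` are signed: positive above the tissue surface,
    negative (rare, from noisy surface extraction) below it.
    ``n_excluded`` counts beads dropped upstream, e.g. beads over surface
    cells where no tissue was detected.
    """

    distances_um: np.ndarray
    mouse_id: str = ""
    stack_id: str = ""
    n_excluded: int = 0

    def __post_init__(self) -> None:
        self.distances_um = np.asarray(self.distances_um, dtype=float)
        if self.distances_um.ndim != 1:
            raise ValueError("distances must be one-dimensional")
        if self.distances_um.size and not np.all(np.isfinite(self.distances_um)):
            raise ValueError("distances must be finite")

    def __len__(self) -> int:
        return self.distances_um.size


@dataclass
class DistanceDistribution:
    """Binned bead-distance frequency distribution (uniform bins from 0)."""

    bin_edges_um: np.ndarray
    counts: np.ndarray
    n_clamped_below: int = 0

    @property
    def bin_width_um(self) -> float:
        return float(self.bin_edges_um[1] - self.bin_edges_um[0])

    @property
    def bin_centers_um(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_um[:-1] + self.bin_edges_um[1:])

    @property
    def n_beads(self) -> float:
        return float(self.counts.sum())


@dataclass
class NormalizedDistribution:
    """Max-normalized, surface-aligned, cropped frequency curve.

    ``x_um`` is depth below the mucus surface (0 at the surface, increasing
    toward the tissue, bin-width spacing); ``f`` is frequency normalized to
    the modal bin, so ``max(f) == 1`` exactly.
    """

    x_um: np.ndarray
    f: np.ndarray
    surface_bin_distance_um: float
    n_cropped_above: float
    bin_width_um: float

    def __post_init__(self) -> None:
        if self.f.size == 0:
            raise ValueError("normalized curve must contain at least one bin")


@dataclass
class PenetrabilityResult:
    """Per-stack mucus readouts."""

    auc_um: float
    thickness_avg_um: float
    n_beads: int
    n_cropped_above: float
    bin_width_um: float
    mouse_id: str = ""
    stack_id: str = ""


@dataclass
class MousePenetrability:
    """Per-mouse summary: median AUC and pointwise-median display curve."""

    mouse_id: str
    auc_um: float
    thickness_avg_um: float
    n_stacks: int
    median_curve_x_um: np.ndarray = field(repr=False, default=None)
    median_curve_f: np.ndarray = field(repr=False, default=None)


def build_distance_histogram(
    ds: DistanceSet, bin_width_um: float = DEFAULT_BIN_WIDTH_UM
) -> DistanceDistribution:
    """Bin bead distances into uniform half-open bins [j·b, (j+1)·b).

    Bins run from 0 (the tissue) past the largest distance; a distance
    landing exactly on an edge belongs to the upper bin.  Distances below
    the tissue surface (d < 0) are clamped into the first bin and reported
    via ``n_clamped_below`` rather than silently dropped.
    """
    if len(ds) == 0:
        raise ValueError("no beads detected: cannot build a distance histogram")
    if bin_width_um <= 0:
        raise ValueError("bin width must be positive")
    d = ds.distances_um
    n_clamped = int(np.count_nonzero(d < 0))
    d = np.maximum(d, 0.0)
    n_bins = int(d.max() // bin_width_um) + 1
    edges = np.arange(n_bins + 1) * bin_width_um
    counts, _ = np.histogram(d, bins=edges)
    return DistanceDistribution(edges, counts.astype(float), n_clamped)


#: Bins whose count is within this relative tolerance of the maximum count
#: are treated as tied for the mode.  Exact ties occur in expectation for a
#: fully penetrated layer; in finite samples the same flat-top regime shows
#: up as counts differing only by multinomial noise, so near-ties must
#: resolve the same way (outermost bin) or the surface anchor would jump to
#: a random bin.
MODAL_TIE_REL_TOL = 0.05


def normalize_and_align(
    dist: DistanceDistribution, modal_tie_rel_tol: float = MODAL_TIE_REL_TOL
) -> NormalizedDistribution:
    """Max-normalize, anchor at the mucus surface, crop above it.

    The mucus surface is the modal bin of the distance distribution; ties —
    exact or within ``modal_tie_rel_tol`` of the maximum count — break
    toward the outermost bin (largest distance), since the surface is
    by construction the outermost bead accumulation.  Bins above the
    surface are dropped and their bead count recorded.  The curve ends at
    the deepest occupied bin: trailing bins in which no bead was observed
    carry no information and are trimmed, so a fully impenetrable layer
    reduces to the single surface point (and a uniform shift of all
    distances by whole bins leaves the curve unchanged).
    """
    counts = np.asarray(dist.counts, dtype=float)
    if counts.sum() <= 0:
        raise ValueError("all-zero histogram: nothing to normalize")
    peak = counts.max()
    # outermost bin tied (exactly or statistically) for the mode
    modal = int(np.flatnonzero(counts >= peak * (1.0 - modal_tie_rel_tol))[-1])
    centers = dist.bin_centers_um
    s = float(centers[modal])
    n_cropped = float(counts[modal + 1 :].sum())
    # x = s - center, ascending from the surface toward the tissue
    f = counts[modal::-1] / peak
    x = s - centers[modal::-1]
    deepest = int(np.flatnonzero(f > 0)[-1])
    f = f[: deepest + 1]
    x = x[: deepest + 1]
    return NormalizedDistribution(
        x_um=x,
        f=f,
        surface_bin_distance_um=s,
        n_cropped_above=n_cropped,
        bin_width_um=dist.bin_width_um,
    )


def penetrability_auc(nd: NormalizedDistribution) -> float:
    """Trapezoidal area under the normalized curve, in µm.

    A single-point curve (an impenetrable layer: all beads in the surface
    bin) integrates to 0.
    """
    if nd.x_um.size < 2:
        return 0.0
    return float(np.trapezoid(nd.f, nd.x_um))


def thickness_from_beads(ds: DistanceSet) -> float:
    """Mucus thickness as the average tissue-to-bead axial distance (µm)."""
    if len(ds) == 0:
        raise ValueError("no beads: cannot estimate thickness")
    return float(np.mean(ds.distances_um))


def compute_penetrability(
    ds: DistanceSet, bin_width_um: float = DEFAULT_BIN_WIDTH_UM
) -> tuple[PenetrabilityResult, NormalizedDistribution]:
    """Full per-stack chain: histogram → normalize/align/crop → AUC."""
    hist = build_distance_histogram(ds, bin_width_um)
    nd = normalize_and_align(hist)
    result = PenetrabilityResult(
        auc_um=penetrability_auc(nd),
        thickness_avg_um=thickness_from_beads(ds),
        n_beads=len(ds),
        n_cropped_above=nd.n_cropped_above,
        bin_width_um=bin_width_um,
        mouse_id=ds.mouse_id,
        stack_id=ds.stack_id,
    )
    return result, nd


def median_curve(
    curves: list[NormalizedDistribution],
) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise median of normalized curves on the union depth grid.

    Beyond a curve's own extent its frequency is taken as 0 (no beads were
    observed that deep in that stack).
    """
    if not curves:
        raise ValueError("need at least one curve")
    b = curves[0].bin_width_um
    for c in curves:
        if not np.isclose(c.bin_width_um, b):
            raise ValueError("curves must share a bin width to be aggregated")
    n_max = max(c.x_um.size for c in curves)
    grid = np.arange(n_max) * b
    stacked = np.zeros((len(curves), n_max))
    for i, c in enumerate(curves):
        stacked[i, : c.f.size] = c.f
    return grid, np.median(stacked, axis=0)


def aggregate_mouse(
    results: list[PenetrabilityResult],
    curves: list[NormalizedDistribution],
    mouse_id: str | None = None,
) -> MousePenetrability:
    """Per-mouse summary: median of per-stack AUCs and thicknesses, plus
    the pointwise-median bead frequency distribution for display."""
    if not results:
        raise ValueError("need at least one stack per mouse")
    if len(results) != len(curves):
        raise ValueError("results and curves must align")
    grid, med = median_curve(curves)
    return MousePenetrability(
        mouse_id=mouse_id if mouse_id is not None else results[0].mouse_id,
        auc_um=float(np.median([r.auc_um for r in results])),
        thickness_avg_um=float(np.median([r.thickness_avg_um for r in results])),
        n_stacks=len(results),
        median_curve_x_um=grid,
        median_curve_f=med,
    )
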