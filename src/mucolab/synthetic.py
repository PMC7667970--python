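"""Ground-truthed synthetic inputs for the mucus-barrier pipeline.

The generative model mirrors the ex vivo measurement geometry: an
epithelial tissue surface in a perfusion chamber, overlaid by a mucus layer
of thickness ``T``, onto which 1-µm fluorescent beads sediment.  An intact
inner mucus layer keeps beads at its surface; a defective layer lets a
fraction ``p`` of beads penetrate to a random depth.  Bead axial positions
are therefore a two-component mixture:

    depth = 0 (+ surface jitter)          with probability 1 − p
    depth ~ law truncated to [0, T]       with probability p

and the tissue-to-bead distance is ``d = T − depth``.  The generator emits
tissue surfaces, labeled bead populations, rendered two-channel voxel
stacks, micromanipulator-style thickness time series (linear growth plus
noise, five locations, 15-min intervals up to 45 min), and whole cohorts of
mice (lean vs genetically obese ob/ob, or normoglycemic vs diabetic NOD)
with metabolic covariates — everything carrying its ground truth so the
analysis can be validated against known parameters.

``expected_penetrability`` evaluates the large-sample expectation of the
penetrability AUC statistic in closed form, the analytic oracle the
pipeline is checked against.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .penetrability import (
    DEFAULT_BIN_WIDTH_UM,
    DistanceDistribution,
    DistanceSet,
    normalize_and_align,
    penetrability_auc,
)
from .stacks import TissueSurfaceMap, VoxelStack

__all__ = [
    "MucusModel",
    "SurfaceConfig",
    "RenderConfig",
    "GroupConfig",
    "CohortConfig",
    "BeadSet",
    "RenderResult",
    "Cohort",
    "generate_tissue_surface",
    "generate_bead_population",
    "sample_bead_distances",
    "render_zstack",
    "generate_thickness_series",
    "generate_cohort",
    "expected_penetrability",
]


@dataclass(frozen=True)
class MucusModel:
    """Ground-truth mucus layer: thickness and bead penetration behavior.

    ``penetration_fraction`` is the knob the AUC statistic must track:
    0 = fully impenetrable (all beads at the surface), 1 = every bead
    penetrates.  ``depth_law`` sets how deep penetrant beads go: "uniform"
    over the layer or "exponential" (surface-weighted) with
    ``depth_scale_um``, truncated to the layer.
    """

    thickness_um: float = 80.0
    penetration_fraction: float = 0.1
    surface_jitter_um: float = 0.0
    depth_law: str = "uniform"
    depth_scale_um: float | None = None

    def __post_init__(self) -> None:
        if self.thickness_um <= 0:
            raise ValueError("mucus thickness must be positive")
        if not 0 <= self.penetration_fraction <= 1:
            raise ValueError("penetration fraction must lie in [0, 1]")
        if self.surface_jitter_um < 0:
            raise ValueError("surface jitter must be non-negative")
        if self.depth_law not in ("uniform", "exponential"):
            raise ValueError("depth law must be 'uniform' or 'exponential'")
        if self.depth_law == "exponential":
            if self.depth_scale_um is None or self.depth_scale_um <= 0:
                raise ValueError("exponential depth law needs a positive scale")


@dataclass(frozen=True)
class SurfaceConfig:
    """Smooth epithelial surface: correlated height field on an (x, y) grid."""

    grid_nx: int = 64
    grid_ny: int = 64
    pixel_size_um: float = 2.0
    mean_z_um: float = 50.0
    amplitude_um: float = 0.0
    correlation_length_um: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_nx < 1 or self.grid_ny < 1:
            raise ValueError("grid dimensions must be >= 1")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be positive")
        if self.amplitude_um < 0:
            raise ValueError("amplitude must be non-negative")
        if self.mean_z_um - self.amplitude_um <= 0:
            raise ValueError("surface must stay above z = 0")


@dataclass(frozen=True)
class RenderConfig:
    """Voxelization of the chamber: z sampling, bead size, intensities."""

    z_step_um: float = 2.0
    bead_diameter_um: float = 1.0  # 1-µm bacteria-sized beads
    tissue_intensity: float = 100.0
    bead_intensity: float = 100.0
    background_noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.z_step_um <= 0 or self.bead_diameter_um <= 0:
            raise ValueError("z step and bead diameter must be positive")
        if min(self.tissue_intensity, self.bead_intensity) <= self.background_noise_sigma:
            raise ValueError("signal intensities must exceed the noise sigma")


@dataclass
class BeadSet:
    """Bead population with ground truth: positions, depth, and label."""

    x_um: np.ndarray
    y_um: np.ndarray
    z_um: np.ndarray
    depth_um: np.ndarray
    label: np.ndarray  # "surface" or "penetrant"
    surface_z_um: np.ndarray
    model: MucusModel

    def __len__(self) -> int:
        return self.x_um.size

    @property
    def true_distance_um(self) -> np.ndarray:
        """Ground-truth tissue-to-bead axial distance ``z − surface_z``."""
        return self.z_um - self.surface_z_um

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bead": np.arange(len(self)),
                "x_um": self.x_um,
                "y_um": self.y_um,
                "z_um": self.z_um,
                "true_depth_um": self.depth_um,
                "label": self.label,
            }
        )


def generate_tissue_surface(cfg: SurfaceConfig) -> TissueSurfaceMap:
    """Correlated random surface, peak-normalized to ``mean_z ± amplitude``.

    White noise is smoothed with a Gaussian kernel of the configured
    correlation length and rescaled so the largest excursion equals the
    amplitude; every height is therefore within ``mean_z ± amplitude``
    (a fortiori within ±3·amplitude).  Deterministic under the seed.
    """
    rng = np.random.default_rng(cfg.seed)
    if cfg.amplitude_um == 0:
        z = np.full((cfg.grid_ny, cfg.grid_nx), cfg.mean_z_um)
    else:
        noise = rng.standard_normal((cfg.grid_ny, cfg.grid_nx))
        sigma_px = cfg.correlation_length_um / cfg.pixel_size_um
        field2d = ndimage.gaussian_filter(noise, sigma=sigma_px, mode="wrap")
        span = np.abs(field2d).max()
        if span == 0:  # degenerate: filter flattened everything
            field2d = np.zeros_like(field2d)
        else:
            field2d = field2d / span * cfg.amplitude_um
        z = cfg.mean_z_um + field2d
    mask = np.ones_like(z, dtype=bool)
    return TissueSurfaceMap(z, mask, (cfg.pixel_size_um, cfg.pixel_size_um))


def _sample_depths(model: MucusModel, n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Mixture depths and penetrant flags for ``n`` beads."""
    penetrant = rng.random(n) < model.penetration_fraction
    depth = np.zeros(n)
    if model.surface_jitter_um > 0:
        depth[~penetrant] = rng.normal(
            0.0, model.surface_jitter_um, size=int(np.count_nonzero(~penetrant))
        )
    k = int(np.count_nonzero(penetrant))
    if k:
        T = model.thickness_um
        if model.depth_law == "uniform":
            depth[penetrant] = rng.uniform(0.0, T, size=k)
        else:
            s = model.depth_scale_um
            u = rng.uniform(size=k)
            # inverse CDF of Exp(scale s) truncated to [0, T]
            depth[penetrant] = -s * np.log1p(-u * (1.0 - np.exp(-T / s)))
    return depth, penetrant


def generate_bead_population(
    surface: TissueSurfaceMap,
    model: MucusModel,
    n_beads: int,
    seed: int = 0,
    min_separation_um: float | None = None,
) -> BeadSet:
    """Sediment beads onto/into the mucus layer over a tissue surface.

    Lateral positions are uniform over the field; the axial position is
    ``z = surface_z(x, y) + T − depth`` with the mixture depth law of the
    model.  When ``min_separation_um`` is given, lateral positions are
    drawn by rejection so that beads are pairwise separated by at least
    that distance (guaranteeing separability in any rendering), which makes
    detection counts well-defined.
    """
    if n_beads < 1:
        raise ValueError("need at least one bead")
    rng = np.random.default_rng(seed)
    ly, lx = surface.extent_um
    if min_separation_um is None:
        x = rng.uniform(0.0, lx, n_beads)
        y = rng.uniform(0.0, ly, n_beads)
    else:
        xs: list[float] = []
        ys: list[float] = []
        attempts = 0
        while len(xs) < n_beads:
            attempts += 1
            if attempts > 1000 * n_beads:
                raise RuntimeError(
                    "could not place beads with the requested separation"
                )
            cx = rng.uniform(0.0, lx)
            cy = rng.uniform(0.0, ly)
            if all(
                (cx - px) ** 2 + (cy - py) ** 2 >= min_separation_um**2
                for px, py in zip(xs, ys)
            ):
                xs.append(cx)
                ys.append(cy)
        x = np.array(xs)
        y = np.array(ys)
    surf_z = surface.interpolator()(np.column_stack([y, x]))
    depth, penetrant = _sample_depths(model, n_beads, rng)
    z = surf_z + model.thickness_um - depth
    label = np.where(penetrant, "penetrant", "surface")
    return BeadSet(x, y, z, depth, label, surf_z, model)


def sample_bead_distances(
    model: MucusModel,
    n_beads: int,
    seed: int = 0,
    measurement_noise_um: float = 0.0,
    mouse_id: str = "",
    stack_id: str = "",
) -> DistanceSet:
    """Draw tissue-to-bead distances ``d = T − depth`` directly.

    Bypasses surface geometry and rendering; used for cohort-scale
    simulation and for large-n validation of the AUC statistic.
    """
    if n_beads < 1:
        raise ValueError("need at least one bead")
    rng = np.random.default_rng(seed)
    depth, _ = _sample_depths(model, n_beads, rng)
    d = model.thickness_um - depth
    if measurement_noise_um > 0:
        d = d + rng.normal(0.0, measurement_noise_um, n_beads)
    return DistanceSet(d, mouse_id, stack_id)


@dataclass
class RenderResult:
    stack: VoxelStack
    clipped_bead_ids: np.ndarray  # beads outside the rendered volume


def render_zstack(
    surface: TissueSurfaceMap,
    beads: BeadSet,
    cfg: RenderConfig,
    n_z: int | None = None,
) -> RenderResult:
    """Voxelize tissue and beads into a two-channel stack.

    Channel 0 (tissue) fills every voxel whose center lies at or below the
    local surface height; channel 1 (beads) renders one spherical blob per
    bead.  A voxel is lit when the bead sphere touches it (center within
    the bead radius plus half the voxel diagonal), so a 1-µm bead spans
    several voxels even at coarse sampling — a stand-in for the in-plane
    broadening that makes sub-voxel beads visible in real stacks — and at
    least one voxel is always lit.  Gaussian background noise is added to
    both channels.  Beads outside the rendered volume are listed in the
    clipping report, never silently dropped.
    """
    rng = np.random.default_rng(cfg.seed)
    dz = cfg.z_step_um
    dy, dx = surface.pixel_size_um
    ny, nx = surface.surface_z_um.shape
    if n_z is None:
        z_top = max(
            float(np.max(beads.z_um)) + cfg.bead_diameter_um,
            float(np.max(surface.surface_z_um[surface.valid_mask])),
        )
        n_z = int(np.ceil(z_top / dz)) + 2
    tissue = np.zeros((n_z, ny, nx), dtype=np.float32)
    zc = (np.arange(n_z) + 0.5) * dz
    tissue[zc[:, None, None] <= surface.surface_z_um[None, :, :]] = cfg.tissue_intensity

    bead_ch = np.zeros_like(tissue)
    # footprint: sphere dilated by the voxel half-diagonal (voxel-touch test)
    r = cfg.bead_diameter_um / 2.0 + 0.5 * float(np.sqrt(dx**2 + dy**2 + dz**2))
    clipped = []
    for i in range(len(beads)):
        bx, by, bz = beads.x_um[i], beads.y_um[i], beads.z_um[i]
        if not (0 <= bx <= nx * dx and 0 <= by <= ny * dy and 0 <= bz <= n_z * dz):
            clipped.append(i)
        # voxel index window around the bead
        ix = np.arange(
            max(0, int((bx - r) / dx - 1)), min(nx, int((bx + r) / dx + 2))
        )
        iy = np.arange(
            max(0, int((by - r) / dy - 1)), min(ny, int((by + r) / dy + 2))
        )
        iz = np.arange(
            max(0, int((bz - r) / dz - 1)), min(n_z, int((bz + r) / dz + 2))
        )
        if ix.size == 0 or iy.size == 0 or iz.size == 0:
            continue
        gx = (ix + 0.5) * dx - bx
        gy = (iy + 0.5) * dy - by
        gz = (iz + 0.5) * dz - bz
        dist2 = (
            gz[:, None, None] ** 2 + gy[None, :, None] ** 2 + gx[None, None, :] ** 2
        )
        blob = dist2 <= r**2
        if not blob.any():
            # sub-voxel bead: light the nearest voxel
            k = np.unravel_index(np.argmin(dist2), dist2.shape)
            blob[k] = True
        sub = bead_ch[np.ix_(iz, iy, ix)]
        sub[blob] = cfg.bead_intensity
        bead_ch[np.ix_(iz, iy, ix)] = sub

    data = np.stack([tissue, bead_ch])
    if cfg.background_noise_sigma > 0:
        data = data + rng.normal(0.0, cfg.background_noise_sigma, data.shape).astype(
            np.float32
        )
    stack = VoxelStack(data, (dz, dy, dx))
    return RenderResult(stack, np.array(clipped, dtype=int))


def generate_thickness_series(
    initial_thickness_um: float,
    rate_um_per_min: float,
    noise_sigma_um: float = 0.0,
    n_locations: int = 5,
    times_min: tuple[float, ...] = (0.0, 15.0, 30.0, 45.0),
    seed: int = 0,
    mouse_id: str = "",
) -> pd.DataFrame:
    """Micromanipulator-style thickness series: linear growth plus noise.

    Five locations measured every 15 min up to 45 min by default.  Returns
    a tidy frame with columns location, time_min, thickness_um.
    """
    if initial_thickness_um <= 0:
        raise ValueError("initial thickness must be positive")
    rng = np.random.default_rng(seed)
    loc, t = np.meshgrid(np.arange(n_locations), np.asarray(times_min), indexing="ij")
    thick = initial_thickness_um + rate_um_per_min * t
    if noise_sigma_um > 0:
        thick = thick + rng.normal(0.0, noise_sigma_um, thick.shape)
    out = pd.DataFrame(
        {
            "location": loc.ravel(),
            "time_min": t.ravel(),
            "thickness_um": thick.ravel(),
        }
    )
    if mouse_id:
        out.insert(0, "mouse", mouse_id)
    return out


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupConfig:
    """One experimental group: metabolic covariates and mucus ground truth.

    Covariates are (mean, SD) pairs for Gaussian draws; units are grams
    (body weight), mM (fasting glucose), and µU/ml (fasting insulin) so
    HOMA-IR uses the standard constant.
    """

    label: str
    n: int
    body_weight_g: tuple[float, float]
    fasting_glucose_mM: tuple[float, float]
    fasting_insulin_uU_ml: tuple[float, float]
    mucus: MucusModel
    growth_rate_um_min: tuple[float, float]
    initial_thickness_um: tuple[float, float]

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"group '{self.label}' needs n >= 2")
        for name in (
            "body_weight_g",
            "fasting_glucose_mM",
            "fasting_insulin_uU_ml",
            "growth_rate_um_min",
            "initial_thickness_um",
        ):
            mean, sd = getattr(self, name)
            if sd < 0:
                raise ValueError(f"{name}: SD must be non-negative")
            if name != "growth_rate_um_min" and mean <= 0:
                raise ValueError(f"{name}: mean must be positive")


@dataclass(frozen=True)
class CohortConfig:
    """Two-group cohort design (e.g. lean vs ob/ob).

    ``housing='cohoused'`` models microbiota exchange through coprophagy:
    both groups' mucus parameters (penetration fraction, thickness, growth
    rate) converge toward the across-group mean by the ``convergence``
    factor (1 = full convergence, the default, matching the observed
    abrogation of barrier differences), while metabolic covariates remain
    genotype-specific.
    """

    groups: tuple[GroupConfig, GroupConfig]
    housing: str = "separated"
    convergence: float = 1.0
    n_stacks_per_mouse: int = 3
    beads_per_stack: int = 300
    distance_noise_um: float = 2.0
    thickness_noise_um: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.groups) != 2:
            raise ValueError("a cohort has exactly two groups")
        if self.housing not in ("separated", "cohoused"):
            raise ValueError("housing must be 'separated' or 'cohoused'")
        if not 0 <= self.convergence <= 1:
            raise ValueError("convergence must lie in [0, 1]")


@dataclass
class Cohort:
    """Simulated cohort: table of mice plus per-mouse raw measurements."""

    table: pd.DataFrame
    distance_sets: dict[str, list[DistanceSet]]
    thickness_series: dict[str, pd.DataFrame]
    config: CohortConfig


def _converged_models(cfg: CohortConfig) -> tuple[MucusModel, MucusModel]:
    """Effective per-group mucus models under the housing scenario."""
    if cfg.housing == "separated" or cfg.convergence == 0:
        return cfg.groups[0].mucus, cfg.groups[1].mucus
    c = cfg.convergence
    a, b = cfg.groups[0].mucus, cfg.groups[1].mucus
    mean_p = 0.5 * (a.penetration_fraction + b.penetration_fraction)
    mean_T = 0.5 * (a.thickness_um + b.thickness_um)

    def mix(m: MucusModel) -> MucusModel:
        return replace(
            m,
            penetration_fraction=(1 - c) * m.penetration_fraction + c * mean_p,
            thickness_um=(1 - c) * m.thickness_um + c * mean_T,
        )

    return mix(a), mix(b)


def _converged_rates(cfg: CohortConfig) -> tuple[tuple[float, float], tuple[float, float]]:
    if cfg.housing == "separated" or cfg.convergence == 0:
        return cfg.groups[0].growth_rate_um_min, cfg.groups[1].growth_rate_um_min
    c = cfg.convergence
    (m0, s0), (m1, s1) = (g.growth_rate_um_min for g in cfg.groups)
    mean_r = 0.5 * (m0 + m1)
    return ((1 - c) * m0 + c * mean_r, s0), ((1 - c) * m1 + c * mean_r, s1)


def generate_cohort(cfg: CohortConfig) -> Cohort:
    """Simulate a cohort: covariates, bead distances, thickness series.

    Each mouse draws covariates from its group's distributions and mucus
    data from its group's (housing-adjusted) mucus model: several stacks
    of bead distances plus one thickness time series.  The returned table
    carries the true generative parameters as a ground-truth sidecar.
    """
    rng = np.random.default_rng(cfg.seed)
    models = _converged_models(cfg)
    rates = _converged_rates(cfg)
    rows = []
    distance_sets: dict[str, list[DistanceSet]] = {}
    series: dict[str, pd.DataFrame] = {}
    for gi, grp in enumerate(cfg.groups):
        model = models[gi]
        rate_mean, rate_sd = rates[gi]
        for mi in range(grp.n):
            mouse = f"{grp.label}-{mi + 1:02d}"
            bw = rng.normal(*grp.body_weight_g)
            glu = rng.normal(*grp.fasting_glucose_mM)
            ins = rng.normal(*grp.fasting_insulin_uU_ml)
            # covariates are physiological quantities; keep them positive
            bw, glu, ins = (max(v, 1e-3) for v in (bw, glu, ins))
            rate = rng.normal(rate_mean, rate_sd)
            t0 = max(rng.normal(*grp.initial_thickness_um), 1.0)
            sets = [
                DistanceSet(
                    sample_bead_distances(
                        model,
                        cfg.beads_per_stack,
                        seed=rng.integers(2**31),
                        measurement_noise_um=cfg.distance_noise_um,
                    ).distances_um,
                    mouse_id=mouse,
                    stack_id=f"stack{si + 1}",
                )
                for si in range(cfg.n_stacks_per_mouse)
            ]
            distance_sets[mouse] = sets
            series[mouse] = generate_thickness_series(
                t0,
                rate,
                cfg.thickness_noise_um,
                seed=int(rng.integers(2**31)),
                mouse_id=mouse,
            )
            rows.append(
                {
                    "mouse": mouse,
                    "group": grp.label,
                    "housing": cfg.housing,
                    "body_weight_g": bw,
                    "fasting_glucose_mM": glu,
                    "fasting_insulin_uU_ml": ins,
                    "true_penetration_fraction": model.penetration_fraction,
                    "true_thickness_um": model.thickness_um,
                    "true_growth_rate_um_min": rate,
                    "true_initial_thickness_um": t0,
                }
            )
    table = pd.DataFrame(rows)
    return Cohort(table, distance_sets, series, cfg)


# ---------------------------------------------------------------------------
# Analytic oracle for the AUC statistic
# ---------------------------------------------------------------------------


def expected_penetrability(
    model: MucusModel, bin_width_um: float = DEFAULT_BIN_WIDTH_UM
) -> float:
    """Large-sample expectation of the penetrability AUC, in closed form.

    Expected per-bin probability mass of the distance distribution is
    computed analytically (no sampling) and pushed through the same
    normalize/align/crop/integrate rules as the pipeline.  Assumes zero
    surface jitter and a layer thickness that is an integer multiple of the
    bin width, so surface beads (d = T) land exactly in the outermost bin.

    Surface beads sit exactly at d = T, which under half-open binning is
    the lower edge of bin k = T/b: that bin carries mass ``1 − p``, while
    penetrant beads fill bins 0..k−1 (each with mass ``p·b/T`` for the
    uniform law).  If the configuration moves the modal bin away from the
    surface the statistic's surface anchor shifts; this regime change is
    flagged with a warning.
    """
    b = bin_width_um
    T = model.thickness_um
    p = model.penetration_fraction
    if b >= T:
        raise ValueError("bin width must be smaller than the layer thickness")
    k = T / b
    if abs(k - round(k)) > 1e-9:
        raise ValueError(
            "closed form requires thickness to be an integer multiple of "
            "the bin width"
        )
    if model.surface_jitter_um > 0:
        warnings.warn(
            "closed form assumes zero surface jitter; result is approximate"
        )
    k = int(round(k))
    # distance bin j < k covers d in [j*b, (j+1)*b) == depth in (T-(j+1)b, T-jb];
    # bin k holds the surface spike at d = T (depth exactly 0)
    mass = np.zeros(k + 1)
    if model.depth_law == "uniform":
        mass[:k] = p / k
    else:
        s = model.depth_scale_um
        depth_hi = T - np.arange(k) * b  # upper depth edge of distance bin j
        depth_lo = depth_hi - b
        norm = 1.0 - np.exp(-T / s)
        mass[:k] = p * (np.exp(-depth_lo / s) - np.exp(-depth_hi / s)) / norm
    mass[k] = 1.0 - p
    edges = np.arange(k + 2) * b
    dist = DistanceDistribution(edges, mass)
    surface_bin = k if p < 1 else k - 1
    modal = len(mass) - 1 - int(np.argmax(mass[::-1]))
    if modal != surface_bin:
        warnings.warn(
            "modal bin is not the surface bin: the statistic's surface "
            "anchor has moved (regime change)"
        )
    nd = normalize_and_align(dist)
    return penetrability_auc(nd)
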