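"""Synthetic field-trial thermal data with the structure the analysis assumes.

The generative model is additive on the Celsius scale:

    T(plot p, image i) = baseline_i + g(geno(p)) + d(geno(p))
                         + plot_noise(p) + obs_noise(p, i)

where ``baseline_i`` is an image-level environmental level (irradiance, wind,
cloud cover — everything that shifts a whole image), ``g`` is a stable
genotype effect (default SD 0.4 °C, giving a genotype range of roughly 2 °C),
``d`` an optional genotype-by-day perturbation, ``plot_noise`` a per-plot
(replicate) deviation constant across images, and ``obs_noise`` independent
per observation.  The image-mean normalisation downstream removes exactly the
additive image term, so this simulator realises the assumption under which
that normalisation is unbiased; a multiplicative genotype-by-irradiance
interaction can be switched on to probe robustness when the assumption fails.

Image acquisition is emulated as a camera footprint (up to 9 plots wide,
3–4 rows deep) swept over the field grid with an advance smaller than the
footprint, plus integer jitter — deliberate but non-systematic overlap, so
most plots appear in two or more images.  Optionally each capture can be
rendered to a pixel frame (default 320 x 240) with per-plot canopy polygons
on a hotter soil background.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .trial_design import PlotKey, PlotObservation, TrialDesign

__all__ = [
    "BaselineSeries",
    "SimulationScenario",
    "ImageCapture",
    "ThermalFrame",
    "HarvestTraits",
    "simulate_baselines",
    "plan_acquisition",
    "default_polygons",
    "make_scenario",
    "simulate_plot_observations",
    "simulate_occasion",
    "render_thermal_frame",
    "simulate_harvest_traits",
    "observations_to_frame",
    "observations_from_frame",
]

OBS_CSV_COLUMNS = [
    "image_id", "trial_id", "row", "col", "genotype", "replicate", "temperature_C",
]

#: Default camera frame dimensions in pixels (width, height).
FRAME_WIDTH = 320
FRAME_HEIGHT = 240


class BaselineSeries(NamedTuple):
    """Per-image environmental baseline (°C) plus the cloud-event log."""

    values: np.ndarray
    step_events: np.ndarray  # image indices at which a cloud step occurred


@dataclass
class SimulationScenario:
    """Everything that determines one simulated imaging occasion.

    ``sigma_plot`` is the SD of the per-plot deviation shared by all images of
    a plot (soil and canopy heterogeneity between replicate plots);
    ``sigma_obs`` the SD of the independent per-observation measurement noise;
    ``sigma_day`` the SD of a genotype-by-day perturbation (0 keeps rankings
    perfectly stable across days).
    """

    genotype_effects: dict[str, float]
    image_baselines: np.ndarray
    sigma_plot: float = 0.3
    sigma_obs: float = 0.15
    sigma_day: float = 0.0
    interaction_scale: float = 0.0  # multiplicative genotype x baseline term, off by default
    seed: int = 0

    def __post_init__(self) -> None:
        self.image_baselines = np.asarray(self.image_baselines, dtype=float)
        for name in ("sigma_plot", "sigma_obs", "sigma_day"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class ImageCapture:
    """One planned thermal image: which plots it covers, and where."""

    image_id: str
    trial_id: str
    capture_index: int
    covered_plots: frozenset[PlotKey]
    row0: int
    col0: int
    footprint_rows: int
    footprint_cols: int
    polygons: dict[PlotKey, np.ndarray] | None = None


@dataclass
class ThermalFrame:
    """A single-channel temperature raster (°C)."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D array")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("frame contains non-finite temperatures")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class HarvestTraits:
    """End-of-season traits for one genotype.

    yield_kg is fresh tuber mass per plot (kg per 5 plants); maturity is an
    ordinal 1–9 score with 9 = least mature (latest).
    """

    genotype: str
    yield_kg: float
    height_cm: float
    maturity: int

    def __post_init__(self) -> None:
        if self.yield_kg < 0:
            raise ValueError("yield must be >= 0")
        if not 1 <= self.maturity <= 9:
            raise ValueError("maturity score must be in 1..9")


# ---------------------------------------------------------------------------
# environmental baselines

def simulate_baselines(
    n_images: int,
    drift_sd: float,
    cloud_step_prob: float,
    cloud_step_size: float,
    seed: int,
    start: float = 0.0,
) -> BaselineSeries:
    """Random-walk image baselines with occasional cloud steps.

    The baseline drifts by N(0, drift_sd) per image; with probability
    ``cloud_step_prob`` per image the sky state toggles, subtracting
    ``cloud_step_size`` °C when cloud arrives and adding it back when it
    clears — emulating the several-degree drops seen in real image sequences.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    if drift_sd < 0 or cloud_step_size < 0:
        raise ValueError("drift_sd and cloud_step_size must be >= 0")
    if not 0.0 <= cloud_step_prob <= 1.0:
        raise ValueError("cloud_step_prob must be in [0, 1]")

    rng = np.random.default_rng(seed)
    drifts = rng.normal(0.0, drift_sd, size=n_images) if drift_sd > 0 else np.zeros(n_images)
    toggles = rng.random(n_images) < cloud_step_prob
    toggles[0] = False  # the first image defines the starting state

    values = np.empty(n_images)
    level = start
    cloudy = False
    events = []
    for i in range(n_images):
        if i > 0:
            level += drifts[i]
            if toggles[i]:
                cloudy = not cloudy
                level += -cloud_step_size if cloudy else cloud_step_size
                events.append(i)
        values[i] = level
    return BaselineSeries(values=values, step_events=np.array(events, dtype=int))


# ---------------------------------------------------------------------------
# acquisition planning

def _anchors(extent: int, footprint: int, advance: int) -> list[int]:
    stops = list(range(0, extent - footprint + 1, advance))
    if stops[-1] != extent - footprint:
        stops.append(extent - footprint)
    return stops


def plan_acquisition(
    design: TrialDesign,
    footprint_cols: int,
    footprint_rows: int,
    advance_cols: int,
    advance_rows: int,
    jitter: int,
    seed: int,
) -> list[ImageCapture]:
    """Plan a sweep of overlapping images covering every plot of the design.

    The footprint is anchored on a grid with the given advances, then each
    anchor is jittered by an integer offset in ``[-jitter, jitter]`` (clamped
    to the field).  Any plot left uncovered by the jittered sweep is covered
    by an appended patch image, so full coverage is guaranteed; with
    ``advance < footprint`` the overlap gives most plots two or more
    observations.
    """
    if not 1 <= footprint_cols <= 9:
        raise ValueError("footprint_cols must be in 1..9 (camera geometry)")
    if not 1 <= footprint_rows <= 4:
        raise ValueError("footprint_rows must be in 1..4 (camera geometry)")
    if footprint_cols > design.plots_per_row or footprint_rows > design.n_rows:
        raise ValueError("footprint exceeds design dimensions")
    if advance_cols < 1 or advance_rows < 1:
        raise ValueError("advances must be >= 1")
    if jitter < 0:
        raise ValueError("jitter must be >= 0")

    rng = np.random.default_rng(seed)
    captures: list[ImageCapture] = []

    def add_capture(r0: int, c0: int) -> None:
        r0 = int(np.clip(r0, 0, design.n_rows - footprint_rows))
        c0 = int(np.clip(c0, 0, design.plots_per_row - footprint_cols))
        idx = len(captures)
        covered = frozenset(
            PlotKey(design.trial_id, r, c)
            for r in range(r0, r0 + footprint_rows)
            for c in range(c0, c0 + footprint_cols)
        )
        captures.append(
            ImageCapture(
                image_id=f"{design.trial_id}_img{idx:03d}",
                trial_id=design.trial_id,
                capture_index=idx,
                covered_plots=covered,
                row0=r0,
                col0=c0,
                footprint_rows=footprint_rows,
                footprint_cols=footprint_cols,
            )
        )

    for r0 in _anchors(design.n_rows, footprint_rows, advance_rows):
        for c0 in _anchors(design.plots_per_row, footprint_cols, advance_cols):
            jr = int(rng.integers(-jitter, jitter + 1)) if jitter else 0
            jc = int(rng.integers(-jitter, jitter + 1)) if jitter else 0
            add_capture(r0 + jr, c0 + jc)

    covered_all: set[PlotKey] = set()
    for cap in captures:
        covered_all |= cap.covered_plots
    for key in design.plots():
        if key not in covered_all:
            add_capture(key.row - footprint_rows // 2, key.col - footprint_cols // 2)
            covered_all |= captures[-1].covered_plots
    return captures


def default_polygons(
    capture: ImageCapture,
    width: int = FRAME_WIDTH,
    height: int = FRAME_HEIGHT,
    margin_frac: float = 0.22,
) -> dict[PlotKey, np.ndarray]:
    """Axis-aligned canopy rectangles, one per covered plot.

    The frame is split into a footprint_rows x footprint_cols grid of cells;
    each plot's polygon is its cell eroded by ``margin_frac`` on every side,
    emulating drawing well inside the canopy away from plot edges and bare
    ground.  Vertices are (x, y) pixel coordinates, 0-based.
    """
    cell_w = width / capture.footprint_cols
    cell_h = height / capture.footprint_rows
    mx, my = margin_frac * cell_w, margin_frac * cell_h
    polygons: dict[PlotKey, np.ndarray] = {}
    for key in sorted(capture.covered_plots):
        i = key.row - capture.row0
        j = key.col - capture.col0
        x0, y0 = j * cell_w + mx, i * cell_h + my
        x1, y1 = (j + 1) * cell_w - mx, (i + 1) * cell_h - my
        polygons[key] = np.array([[x0, y0], [x1, y0], [x1, y1], [x0, y1]])
    return polygons


# ---------------------------------------------------------------------------
# plot-level observations

def make_scenario(
    design: TrialDesign,
    n_images: int,
    seed: int,
    sigma_g: float = 0.4,
    drift_sd: float = 0.2,
    cloud_step_prob: float = 0.05,
    cloud_step_size: float = 4.0,
    base_temp: float = 22.0,
    sigma_plot: float = 0.3,
    sigma_obs: float = 0.15,
    sigma_day: float = 0.0,
    genotype_effects: dict[str, float] | None = None,
) -> SimulationScenario:
    """Build the default study scenario for one imaging occasion.

    Genotype effects are drawn N(0, sigma_g) unless supplied (supply the same
    map across occasions to simulate stable genotype rankings over days).
    """
    rng = np.random.default_rng(seed)
    if genotype_effects is None:
        genos = design.genotypes
        genotype_effects = dict(zip(genos, rng.normal(0.0, sigma_g, size=len(genos))))
    baselines = simulate_baselines(
        n_images, drift_sd, cloud_step_prob, cloud_step_size,
        seed=int(rng.integers(2**31)), start=base_temp,
    )
    return SimulationScenario(
        genotype_effects=dict(genotype_effects),
        image_baselines=baselines.values,
        sigma_plot=sigma_plot,
        sigma_obs=sigma_obs,
        sigma_day=sigma_day,
        seed=int(rng.integers(2**31)),
    )


def simulate_plot_observations(
    design: TrialDesign,
    plan: Sequence[ImageCapture],
    scenario: SimulationScenario,
) -> list[PlotObservation]:
    """Realise the additive generative model over an acquisition plan.

    Each capture yields one observation per covered plot.  The per-plot noise
    is drawn once per plot (constant across images); the per-observation noise
    independently for every (plot, image) pair.  Output is bitwise
    reproducible from (design, plan, scenario).
    """
    if len(scenario.image_baselines) != len(plan):
        raise ValueError(
            f"scenario has {len(scenario.image_baselines)} baselines for "
            f"{len(plan)} planned images"
        )
    rng = np.random.default_rng(scenario.seed)
    all_plots = design.plots()
    plot_noise = dict(
        zip(all_plots, rng.normal(0.0, scenario.sigma_plot, size=len(all_plots)))
        if scenario.sigma_plot > 0
        else zip(all_plots, np.zeros(len(all_plots)))
    )
    genos = sorted(scenario.genotype_effects)
    day_shift = dict(
        zip(genos, rng.normal(0.0, scenario.sigma_day, size=len(genos)))
        if scenario.sigma_day > 0
        else zip(genos, np.zeros(len(genos)))
    )

    observations: list[PlotObservation] = []
    for cap, baseline in zip(plan, scenario.image_baselines):
        for key in sorted(cap.covered_plots):
            if (key.row, key.col) not in design.assignments:
                raise ValueError(f"plot {key} in acquisition plan absent from design")
            geno = design.genotype_of(key)
            if geno not in scenario.genotype_effects:
                raise ValueError(f"genotype {geno} missing from scenario effects")
            g = scenario.genotype_effects[geno] + day_shift[geno]
            if scenario.interaction_scale:
                g *= 1.0 + scenario.interaction_scale * (baseline - scenario.image_baselines.mean())
            noise = rng.normal(0.0, scenario.sigma_obs) if scenario.sigma_obs > 0 else 0.0
            temp = baseline + g + plot_noise[key] + noise
            observations.append(PlotObservation(plot=key, image_id=cap.image_id, ipt=temp))
    return observations


def simulate_occasion(
    design: TrialDesign,
    seed: int,
    footprint_cols: int = 8,
    footprint_rows: int = 3,
    advance_cols: int = 4,
    advance_rows: int = 2,
    jitter: int = 1,
    genotype_effects: dict[str, float] | None = None,
    **scenario_kwargs,
) -> tuple[list[ImageCapture], SimulationScenario, list[PlotObservation]]:
    """One-call simulation of a full imaging occasion under study defaults.

    Default acquisition (8 x 3 footprint advancing 4 columns / 2 rows with
    jitter 1) covers every plot with a mean of about two images per plot.
    """
    rng = np.random.default_rng(seed)
    plan = plan_acquisition(
        design,
        min(footprint_cols, design.plots_per_row),
        min(footprint_rows, design.n_rows),
        advance_cols, advance_rows, jitter,
        seed=int(rng.integers(2**31)),
    )
    scenario = make_scenario(
        design, n_images=len(plan), seed=int(rng.integers(2**31)),
        genotype_effects=genotype_effects, **scenario_kwargs,
    )
    return plan, scenario, simulate_plot_observations(design, plan, scenario)


# ---------------------------------------------------------------------------
# pixel-level rendering

def render_thermal_frame(
    capture: ImageCapture,
    plot_temperatures: dict[PlotKey, float],
    soil_temp: float = 35.0,
    pixel_noise_sd: float = 0.5,
    seed: int = 0,
    width: int = FRAME_WIDTH,
    height: int = FRAME_HEIGHT,
) -> tuple[ThermalFrame, dict[PlotKey, np.ndarray]]:
    """Render a capture as a pixel frame of canopy polygons on hot soil.

    Pixels whose centres fall inside a plot's polygon take that plot's
    temperature plus N(0, pixel_noise_sd); all other pixels take the (hotter,
    sunlit) soil temperature plus the same noise.  Returns the frame together
    with the polygons used, which must be pairwise disjoint.
    """
    from .image_extraction import polygon_mask  # deferred: avoids import cycle

    polygons = capture.polygons or default_polygons(capture, width=width, height=height)
    rng = np.random.default_rng(seed)
    pixels = np.full((height, width), float(soil_temp))
    occupancy = np.zeros((height, width), dtype=int)
    for key in sorted(polygons):
        if key not in plot_temperatures:
            raise ValueError(f"no temperature supplied for covered plot {key}")
        mask = polygon_mask(polygons[key], width=width, height=height)
        if not mask.any():
            raise ValueError(f"degenerate polygon for plot {key}: no interior pixels")
        occupancy += mask
        pixels[mask] = plot_temperatures[key]
    if (occupancy > 1).any():
        raise ValueError("plot polygons overlap; plots are spatially disjoint")
    if pixel_noise_sd > 0:
        pixels = pixels + rng.normal(0.0, pixel_noise_sd, size=pixels.shape)
    return ThermalFrame(pixels=pixels), polygons


# ---------------------------------------------------------------------------
# harvest traits

def simulate_harvest_traits(
    genotype_effects: dict[str, float],
    seed: int,
    slope_yield: float = -2.0,
    slope_height: float = -15.0,
    slope_maturity: float = 1.0,
    base_yield: float = 10.0,
    base_height: float = 60.0,
    base_maturity: float = 5.0,
    sigma_yield: float = 1.25,
    sigma_height: float = 15.0,
    sigma_maturity: float = 1.5,
) -> list[HarvestTraits]:
    """Harvest traits linearly coupled to the genotype temperature effect.

    Warmer genotypes yield less (kg per 5-plant plot), are shorter, and score
    higher on the 1–9 maturity scale (9 = least mature), with Gaussian noise
    on each trait; maturity is rounded and clipped to the scale.
    """
    rng = np.random.default_rng(seed)
    out = []
    for geno in sorted(genotype_effects):
        eff = genotype_effects[geno]
        y = base_yield + slope_yield * eff + (rng.normal(0, sigma_yield) if sigma_yield else 0.0)
        h = base_height + slope_height * eff + (rng.normal(0, sigma_height) if sigma_height else 0.0)
        m = base_maturity + slope_maturity * eff + (rng.normal(0, sigma_maturity) if sigma_maturity else 0.0)
        out.append(
            HarvestTraits(
                genotype=geno,
                yield_kg=max(0.0, y),
                height_cm=h,
                maturity=int(np.clip(round(m), 1, 9)),
            )
        )
    return out


def traits_to_frame(traits: Sequence[HarvestTraits]) -> pd.DataFrame:
    return pd.DataFrame(
        [(t.genotype, t.yield_kg, t.height_cm, t.maturity) for t in traits],
        columns=["genotype", "yield_kg", "height_cm", "maturity"],
    )


# ---------------------------------------------------------------------------
# observations CSV dialect (shared with image_extraction)

def observations_to_frame(
    observations: Sequence[PlotObservation], design: TrialDesign
) -> pd.DataFrame:
    """Observations as the tidy CSV dialect (1-based row/col)."""
    records = []
    for obs in observations:
        geno, rep, _ = design.assignments[(obs.plot.row, obs.plot.col)]
        records.append(
            (obs.image_id, obs.plot.trial_id, obs.plot.row + 1, obs.plot.col + 1,
             geno, rep, obs.ipt)
        )
    return pd.DataFrame(records, columns=OBS_CSV_COLUMNS)


def observations_from_frame(frame: pd.DataFrame) -> list[PlotObservation]:
    missing = set(OBS_CSV_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"observations table missing columns: {sorted(missing)}")
    return [
        PlotObservation(
            plot=PlotKey(str(rec.trial_id), int(rec.row) - 1, int(rec.col) - 1),
            image_id=str(rec.image_id),
            ipt=float(rec.temperature_C),
        )
        for rec in frame.itertuples()
    ]


def write_frame_tiff(frame: ThermalFrame, path) -> None:
    import tifffile

    tifffile.imwrite(path, frame.pixels.astype(np.float32))


def read_frame_tiff(path) -> ThermalFrame:
    import tifffile

    return ThermalFrame(pixels=tifffile.imread(path).astype(float))


def write_frame_text(frame: ThermalFrame, path) -> None:
    np.savetxt(path, frame.pixels, fmt="%.4f")


def read_frame_text(path) -> ThermalFrame:
    return ThermalFrame(pixels=np.loadtxt(path))


def polygons_to_frame(polygons: dict[PlotKey, np.ndarray]) -> pd.DataFrame:
    """Polygon vertex table: pixel coordinates, 0-based, row-major order."""
    records = []
    for key in sorted(polygons):
        for i, (x, y) in enumerate(polygons[key]):
            records.append((key.trial_id, key.row + 1, key.col + 1, i, float(x), float(y)))
    return pd.DataFrame(
        records, columns=["trial_id", "row", "col", "vertex", "x_px", "y_px"]
    )


def polygons_from_frame(frame: pd.DataFrame) -> dict[PlotKey, np.ndarray]:
    out: dict[PlotKey, np.ndarray] = {}
    for (trial, row, col), grp in frame.groupby(["trial_id", "row", "col"], sort=True):
        grp = grp.sort_values("vertex")
        out[PlotKey(str(trial), int(row) - 1, int(col) - 1)] = grp[["x_px", "y_px"]].to_numpy(float)
    return out
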