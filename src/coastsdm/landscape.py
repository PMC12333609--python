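"""Seed-reproducible synthetic coastal study areas with known truth.

The generator emulates the structure of a small coastal Special Area of
Conservation: a wavy coastline, a bathymetric gradient running offshore,
chlorophyll-a elevated around point "aquaculture" attractors, a smooth and
independent SST-anomaly field, and a narrow study band (~159 km^2) hugging
the coast.  True habitat suitability is an inverse-logit combination of
standardized chlorophyll-a (positive), standardized SST anomaly (negative),
distance to the nearest aquaculture point (negative, exponential in scale
``dist_aqua_scale``), and a Gaussian preference bump in seabed slope —
shapes chosen to mirror how such drivers behave in coastal dolphin habitat:
suitability rising with productivity, decaying away from fish farms within
the first few kilometres, and peaking at gentle slopes.

Smooth random fields are seeded white noise convolved with a Gaussian
kernel and standardized, a simple stationary stand-in for the spatial
autocorrelation of real oceanographic layers.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from ._rng import rng_for
from .grid import (
    FeatureGeometry,
    InvalidInputError,
    PredictorStack,
    RasterGrid,
    derive_slope_aspect,
    distance_surface,
)
from .occurrences import OccurrenceSet

__all__ = [
    "LandscapeParams",
    "SyntheticTruth",
    "generate_landscape",
    "sample_occurrences",
    "make_survey_bias",
    "make_citizen_bias",
    "simulate_study",
]

DEFAULT_COEFFICIENTS = {
    "chl": 3.0,              # per SD of chlorophyll-a (logit scale)
    "sst_anom": 0.75,        # per SD of SST anomaly, entering negatively
    "dist_aqua_scale": 1250.0,  # m; scale of the distance penalty (steep
    #   decline over the first few km away from the farms)
    "slope_peak": 2.75,      # degrees; center of the slope preference bump
    "slope_width": 1.0,      # degrees; bump width
    "slope_amp": 1.0,        # bump height (logit units)
    "intercept": -3.5,       # low baseline: suitable habitat is a restricted
    #   nearshore core, not the typical condition of the study band
}


@dataclass
class LandscapeParams:
    n_rows: int = 120
    n_cols: int = 180
    cell_size: float = 250.0         # m
    n_aquaculture: int = 3
    coefficients: dict = dc_field(default_factory=lambda: dict(DEFAULT_COEFFICIENTS))
    noise_sd: float = 1.0            # multiplier on all smooth-field amplitudes
    seed: int = 0
    correlation_length: float = 10.0  # cells, Gaussian kernel sigma
    chl_correlation_length: float = 4.0  # cells; chl varies at finer scale
    band_width: float = 3550.0       # m; offshore extent of the study area
    coast_base: float = 4000.0       # m; mean coastline y
    coast_amp: float = 1200.0        # m; coastline sinuosity amplitude
    coast_wavelength: float = 22500.0  # m

    def __post_init__(self) -> None:
        if self.n_rows < 20 or self.n_cols < 20:
            raise InvalidInputError("grid must be at least 20x20")
        if self.cell_size <= 0:
            raise InvalidInputError("cell_size must be positive")
        coeffs = dict(DEFAULT_COEFFICIENTS)
        coeffs.update(self.coefficients)
        self.coefficients = coeffs
        if self.coefficients["slope_width"] <= 0:
            raise InvalidInputError("slope_width must be positive")


@dataclass
class SyntheticTruth:
    true_suitability: RasterGrid
    generating_params: LandscapeParams
    aquaculture_points: FeatureGeometry
    study_area: FeatureGeometry
    component_sd: dict[str, float] = dc_field(default_factory=dict)

    @property
    def coast_y(self):
        p = self.generating_params
        return lambda x: p.coast_base + p.coast_amp * np.sin(
            2 * np.pi * np.asarray(x, float) / p.coast_wavelength
        )


def _smooth_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Unit-variance stationary Gaussian random field (smoothed white noise)."""
    z = gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="reflect")
    sd = z.std()
    return z / sd if sd > 0 else z


def generate_landscape(params: LandscapeParams) -> tuple[PredictorStack, SyntheticTruth]:
    p = params
    rng = rng_for(p.seed, "landscape")
    nr, nc, cs = p.n_rows, p.n_cols, p.cell_size
    transform = (0.0, cs, 0.0, nr * cs, 0.0, -cs)
    base = RasterGrid(np.zeros((nr, nc)), transform, nodata_mask=np.zeros((nr, nc), bool))
    xs, ys = base.cell_centers()

    coast_y = p.coast_base + p.coast_amp * np.sin(2 * np.pi * xs / p.coast_wavelength)
    offshore = ys - coast_y  # >0 at sea, <0 on land

    # Bathymetry over the full grid (land gets positive elevation) so that
    # slope is well-defined on every study-band cell.
    noise = p.noise_sd * 20.0 * _smooth_field(rng, (nr, nc), p.correlation_length)
    depth_vals = np.where(
        offshore > 0,
        -(5.0 + 170.0 * offshore / p.band_width),
        -offshore / 50.0,
    ) + noise
    depth_full = base.with_values(depth_vals, np.zeros((nr, nc), bool))
    slope_full, _aspect_full = derive_slope_aspect(depth_full)

    band = (offshore > 0) & (offshore <= p.band_width) & ~slope_full.nodata_mask

    # Aquaculture attractors: spread along the coast, inside the band.
    ax, ay = [], []
    for i in range(p.n_aquaculture):
        x = (i + 0.5) / p.n_aquaculture * nc * cs + rng.uniform(-2000.0, 2000.0)
        x = float(np.clip(x, cs, nc * cs - cs))
        y = float(p.coast_base + p.coast_amp * np.sin(2 * np.pi * x / p.coast_wavelength)
                  + rng.uniform(500.0, min(2500.0, p.band_width - 500.0)))
        ax.append(x)
        ay.append(y)
    aqua = FeatureGeometry("points", list(zip(ax, ay)), label="aquaculture")

    dist_aqua_full = distance_surface(base, aqua)

    chl_vals = (
        0.15
        + 0.10 * p.noise_sd * _smooth_field(rng, (nr, nc), p.chl_correlation_length)
        + 0.35 * np.exp(-dist_aqua_full.values / 1500.0)
    )
    chl_vals = np.maximum(chl_vals, 0.005)
    sst_vals = 0.6 * p.noise_sd * _smooth_field(rng, (nr, nc), p.correlation_length)

    nodata = ~band

    def layer(vals: np.ndarray) -> RasterGrid:
        v = np.where(band, vals, np.nan)
        return base.with_values(v, nodata.copy())

    stack = PredictorStack({
        "depth": layer(depth_vals),
        "slope": layer(slope_full.values),
        "chl": layer(chl_vals),
        "sst_anom": layer(sst_vals),
        "dist_aqua": layer(dist_aqua_full.values),
    })

    # True suitability on the study band.
    c = p.coefficients

    def std_on_band(v: np.ndarray) -> np.ndarray:
        vb = v[band]
        sd = vb.std()
        return (v - vb.mean()) / (sd if sd > 0 else 1.0)

    comp = {
        "chl": c["chl"] * std_on_band(chl_vals),
        "sst_anom": -c["sst_anom"] * std_on_band(sst_vals),
        "dist_aqua": -dist_aqua_full.values / c["dist_aqua_scale"],
        "slope": c["slope_amp"] * np.exp(
            -((slope_full.values - c["slope_peak"]) ** 2) / (2.0 * c["slope_width"] ** 2)
        ),
    }
    logit_true = c["intercept"] + sum(comp.values())
    suit = layer(expit(logit_true))
    component_sd = {k: float(v[band].std()) for k, v in comp.items()}

    # Study-area polygon: coastline swept offshore by the band width.
    xs_line = np.linspace(0.0, nc * cs, 2 * nc + 1)
    yline = p.coast_base + p.coast_amp * np.sin(2 * np.pi * xs_line / p.coast_wavelength)
    coords = list(zip(xs_line, yline)) + list(zip(xs_line[::-1], yline[::-1] + p.band_width))
    study = FeatureGeometry("polygon", coords, label="SAC")

    truth = SyntheticTruth(suit, p, aqua, study, component_sd)
    return stack, truth


def make_survey_bias(truth: SyntheticTruth, coverage_fraction: float = 0.62,
                     corridor_offsets=(1000.0, 2500.0), corridor_sd: float = 600.0) -> RasterGrid:
    """Trackline-corridor effort: bands parallel to the coast, western part only."""
    grid = truth.true_suitability
    xs, ys = grid.cell_centers()
    offshore = ys - truth.coast_y(xs)
    d = np.min([np.abs(offshore - o) for o in corridor_offsets], axis=0)
    bias = np.exp(-(d**2) / (2.0 * corridor_sd**2))
    p = truth.generating_params
    bias[xs > coverage_fraction * p.n_cols * p.cell_size] = 0.0
    bias[grid.nodata_mask] = np.nan
    return grid.with_values(bias)


def make_citizen_bias(truth: SyntheticTruth,
                      harbor_fractions=(0.13, 0.47, 0.8, 0.95),
                      hotspot_sd: float = 2500.0) -> RasterGrid:
    """Harbor-centered hotspot effort, including an eastern harbor the
    survey corridors do not reach (spatially complementary coverage)."""
    grid = truth.true_suitability
    p = truth.generating_params
    xs, ys = grid.cell_centers()
    bias = np.zeros(grid.shape)
    for f in harbor_fractions:
        hx = f * p.n_cols * p.cell_size
        hy = float(truth.coast_y(hx)) + 400.0
        bias += np.exp(-((xs - hx) ** 2 + (ys - hy) ** 2) / (2.0 * hotspot_sd**2))
    bias[grid.nodata_mask] = np.nan
    return grid.with_values(bias)


def sample_occurrences(
    truth: SyntheticTruth,
    n_survey: int,
    n_citizen: int,
    survey_bias: RasterGrid,
    citizen_bias: RasterGrid,
    seed: int,
    replace: bool = False,
) -> OccurrenceSet:
    """Draw presence points with cell probability ∝ suitability × bias.

    Points are jittered uniformly within their cell; survey records carry
    sequential summer dates and Poisson-distributed group sizes.
    """
    suit = truth.true_suitability
    frames = []
    for i, (n, bias, source) in enumerate(
        ((n_survey, survey_bias, "survey"), (n_citizen, citizen_bias, "citizen"))
    ):
        if n == 0:
            continue
        if not bias.aligned_with(suit):
            raise InvalidInputError("bias surface is not aligned with the truth grid")
        w = np.where(
            suit.nodata_mask | bias.nodata_mask, 0.0,
            np.nan_to_num(suit.values, nan=0.0) * np.nan_to_num(bias.values, nan=0.0),
        ).ravel()
        if (w < 0).any() or w.sum() <= 0:
            raise InvalidInputError("bias surface must be non-negative and not all zero")
        pos = int((w > 0).sum())
        if not replace and n > pos:
            raise InvalidInputError(f"requested {n} cells but only {pos} have positive probability")
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(i,)))
        cells = rng.choice(w.size, size=n, replace=replace, p=w / w.sum())
        rows, cols = np.unravel_index(cells, suit.shape)
        cx, cy = suit.xy(rows, cols)
        x = cx + (rng.random(n) - 0.5) * abs(suit.dx)
        y = cy + (rng.random(n) - 0.5) * abs(suit.dy)
        dates = pd.date_range("2024-06-01", periods=n, freq="D")
        frames.append(pd.DataFrame({
            "x": x, "y": y, "date": dates, "source": source,
            "validated": True, "group_size": 1 + rng.poisson(3.8, size=n),
        }))
    if not frames:
        raise InvalidInputError("requested zero occurrences")
    return OccurrenceSet(pd.concat(frames, ignore_index=True))


def simulate_study(
    params: LandscapeParams | None = None,
    n_survey: int = 20,
    n_citizen: int = 49,
    seed: int | None = None,
):
    """Convenience: landscape + bias surfaces + sampled occurrences.

    Returns ``(stack, truth, survey_bias, citizen_bias, occurrences)``.
    """
    params = params or LandscapeParams()
    if seed is not None:
        params.seed = seed
    stack, truth = generate_landscape(params)
    sb = make_survey_bias(truth)
    cb = make_citizen_bias(truth)
    occ = sample_occurrences(truth, n_survey, n_citizen, sb, cb,
                             seed=rng_for(params.seed, "occurrences").integers(2**31))
    return stack, truth, sb, cb, occ
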