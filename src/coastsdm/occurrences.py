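"""Occurrence handling, sampling-bias surfaces, background draws, and folds.

Presence-only habitat models are sensitive to where observers looked, not
only to where the animals were.  The standard correction implemented here
draws background / pseudo-absence points from a *bias surface*: a kernel
density estimate of the sightings, focal-smoothed, and constrained to a
buffer around the sightings and the protected-area (SAC) boundary, so the
background carries the same spatial sampling bias as the presences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import shapely
from scipy.ndimage import uniform_filter
from scipy.spatial.distance import cdist

from .grid import FeatureGeometry, InvalidInputError, RasterGrid

__all__ = [
    "OccurrenceSet",
    "BackgroundSet",
    "FoldAssignment",
    "merge_occurrences",
    "build_bias_surface",
    "draw_background",
    "subsample_pseudo_absences",
    "stratified_kfold",
    "encounter_rate",
]


class DegenerateSurfaceError(InvalidInputError):
    """Raised when a bias surface has no positive cells."""


@dataclass
class OccurrenceSet:
    """Presence records with source labels and validation flags.

    ``records`` is a DataFrame with columns
    ``x, y, date, source, validated, group_size``.
    """

    records: pd.DataFrame

    REQUIRED = ("x", "y", "date", "source", "validated", "group_size")

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.records).copy()
        for col, default in (("date", pd.NaT), ("source", "survey"),
                             ("validated", True), ("group_size", np.nan)):
            if col not in df:
                df[col] = default
        missing = {"x", "y"} - set(df.columns)
        if missing:
            raise InvalidInputError(f"occurrence table missing columns {sorted(missing)}")
        self.records = df[list(self.REQUIRED)].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def xy(self) -> tuple[np.ndarray, np.ndarray]:
        return self.records["x"].to_numpy(float), self.records["y"].to_numpy(float)

    def counts_by_source(self) -> dict[str, int]:
        return self.records["source"].value_counts().to_dict()

    def subset_source(self, source: str) -> "OccurrenceSet":
        return OccurrenceSet(self.records[self.records["source"] == source])

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "OccurrenceSet":
        return cls(pd.read_csv(path, parse_dates=["date"]))


@dataclass
class BackgroundSet:
    """Background / pseudo-absence points drawn from a bias surface."""

    points: pd.DataFrame  # columns x, y
    parent_pool_size: int
    seed: int

    def __post_init__(self) -> None:
        self.points = pd.DataFrame(self.points, columns=["x", "y"]).reset_index(drop=True)
        if len(self.points) > self.parent_pool_size:
            raise InvalidInputError("background set larger than its parent pool")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def xy(self) -> tuple[np.ndarray, np.ndarray]:
        return self.points["x"].to_numpy(float), self.points["y"].to_numpy(float)

    def to_csv(self, path) -> None:
        self.points.to_csv(path, index=False)


@dataclass
class FoldAssignment:
    """Stratified fold ids: one integer in [0, k) per record."""

    fold_id: np.ndarray
    k: int
    seed: int

    def __post_init__(self) -> None:
        self.fold_id = np.asarray(self.fold_id, dtype=int)
        if self.fold_id.size and (self.fold_id.min() < 0 or self.fold_id.max() >= self.k):
            raise InvalidInputError("fold ids out of range")

    def test_mask(self, fold: int) -> np.ndarray:
        return self.fold_id == fold


def merge_occurrences(
    survey: OccurrenceSet, citizen: OccurrenceSet, study_area: FeatureGeometry
) -> tuple[OccurrenceSet, dict]:
    """Concatenate validated, in-area records from the two sources.

    Returns the merged set plus a report of counts kept / rejected per
    source (records with missing coordinates or outside the study-area
    polygon are dropped with a logged reason).
    """
    poly = study_area.to_shapely()
    shapely.prepare(poly)
    kept_frames, report = [], {}
    for name, occ in (("survey", survey), ("citizen", citizen)):
        df = occ.records
        has_xy = df["x"].notna() & df["y"].notna()
        validated = df["validated"].fillna(False).astype(bool)
        inside = np.zeros(len(df), dtype=bool)
        idx = has_xy.to_numpy()
        if idx.any():
            inside[idx] = shapely.intersects_xy(
                poly, df.loc[has_xy, "x"].to_numpy(float), df.loc[has_xy, "y"].to_numpy(float)
            )
        keep = has_xy.to_numpy() & validated.to_numpy() & inside
        kept_frames.append(df[keep])
        report[name] = {
            "input": int(len(df)),
            "kept": int(keep.sum()),
            "rejected_missing_xy": int((~has_xy).sum()),
            "rejected_unvalidated": int((has_xy & ~validated).sum()),
            "rejected_outside": int((has_xy.to_numpy() & validated.to_numpy() & ~inside).sum()),
        }
    merged = OccurrenceSet(pd.concat(kept_frames, ignore_index=True))
    report["total"] = int(len(merged))
    return merged, report


def _focal_mean(values: np.ndarray, valid: np.ndarray, window: int) -> np.ndarray:
    """Mean filter that ignores invalid cells (normalized box filter)."""
    filled = np.where(valid, values, 0.0)
    num = uniform_filter(filled, size=window, mode="constant")
    den = uniform_filter(valid.astype(float), size=window, mode="constant")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[den == 0] = 0.0
    return out


def build_bias_surface(
    occ: OccurrenceSet,
    sac: FeatureGeometry,
    grid: RasterGrid,
    bandwidth: float = 6000.0,
    buffer: float = 2000.0,
    focal_window: int = 3,
) -> RasterGrid:
    """Sampling-effort surface in [0, 1] on the reference grid.

    Gaussian KDE of the sightings at cell centers, focal-mean smoothed,
    masked to the union of a ``buffer`` around every sighting and around
    the SAC polygon, then rescaled to max 1 with a 1e-6 floor inside the
    mask.  Cells outside the mask are exactly 0.
    """
    if len(occ) == 0:
        raise InvalidInputError("need at least one occurrence")
    if bandwidth <= 0 or buffer <= 0:
        raise InvalidInputError("bandwidth and buffer must be positive")

    xs, ys = grid.cell_centers()
    centers = np.column_stack([xs.ravel(), ys.ravel()])
    pts = np.column_stack(occ.xy)
    d2 = cdist(centers, pts, "sqeuclidean")
    dens = np.exp(-d2 / (2.0 * bandwidth**2)).sum(axis=1).reshape(grid.shape)

    valid = ~grid.nodata_mask
    dens = _focal_mean(dens, valid, focal_window)

    sac_geom = sac.to_shapely()
    buffered = shapely.union(sac_geom.buffer(buffer), shapely.MultiPoint(pts).buffer(buffer))
    shapely.prepare(buffered)
    in_buffer = shapely.contains_xy(buffered, centers[:, 0], centers[:, 1]).reshape(grid.shape)

    mask_in = in_buffer & valid
    if not mask_in.any():
        raise DegenerateSurfaceError("bias surface is empty after masking")
    out = np.zeros(grid.shape)
    out[mask_in] = dens[mask_in]
    peak = out.max()
    if peak <= 0:
        raise DegenerateSurfaceError("bias surface has no positive weight")
    out /= peak
    out[mask_in] = np.maximum(out[mask_in], 1e-6)
    out[grid.nodata_mask] = np.nan
    return grid.with_values(out)


def draw_background(bias: RasterGrid, n: int, seed: int) -> BackgroundSet:
    """Draw ``n`` points with replacement, cell probability ∝ bias weight.

    Points are placed uniformly at random within the drawn cell.
    """
    if n < 0:
        raise InvalidInputError("n must be non-negative")
    w = np.where(bias.nodata_mask, 0.0, np.nan_to_num(bias.values, nan=0.0)).ravel()
    total = w.sum()
    if n > 0 and total <= 0:
        raise DegenerateSurfaceError("bias surface has no positive cells")
    rng = np.random.default_rng(seed)
    if n == 0:
        return BackgroundSet(pd.DataFrame(columns=["x", "y"]), parent_pool_size=0, seed=seed)
    cells = rng.choice(w.size, size=n, replace=True, p=w / total)
    rows, cols = np.unravel_index(cells, bias.shape)
    cx, cy = bias.xy(rows, cols)
    jx = (rng.random(n) - 0.5) * abs(bias.dx)
    jy = (rng.random(n) - 0.5) * abs(bias.dy)
    pts = pd.DataFrame({"x": cx + jx, "y": cy + jy})
    return BackgroundSet(pts, parent_pool_size=n, seed=seed)


def subsample_pseudo_absences(
    pool: BackgroundSet, n_presences: int, ratio: float, seed: int
) -> BackgroundSet:
    """Uniform without-replacement subsample of round(ratio * n_presences)."""
    n = int(round(ratio * n_presences))
    if n > len(pool):
        raise InvalidInputError(f"requested {n} pseudo-absences from a pool of {len(pool)}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pool), size=n, replace=False)
    return BackgroundSet(pool.points.iloc[np.sort(idx)], parent_pool_size=len(pool), seed=seed)


def stratified_kfold(labels: Sequence[int], k: int, seed: int) -> FoldAssignment:
    """Class-stratified folds: seeded shuffle then round-robin per class."""
    labels = np.asarray(labels)
    if k < 1:
        raise InvalidInputError("k must be >= 1")
    rng = np.random.default_rng(seed)
    fold = np.empty(labels.shape[0], dtype=int)
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if len(idx) < k:
            raise InvalidInputError(f"class {cls!r} has fewer than k={k} members")
        perm = rng.permutation(len(idx))
        fold[idx[perm]] = np.arange(len(idx)) % k
    return FoldAssignment(fold, k=k, seed=seed)


def encounter_rate(n_events: float, effort_km: float, per_km: float = 100.0) -> float:
    """Events per ``per_km`` kilometers of on-effort trackline."""
    if effort_km <= 0:
        raise InvalidInputError("effort must be positive")
    return per_km * n_events / effort_km
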