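"""Synthetic yield-monitor data with the geometric and statistical structure of
on-farm green-manure trials.

A harvested field is an axis-aligned rectangle tiled into polygons whose area is
``swath_width x harvester_speed x measurement_interval`` (edge polygons are
truncated so the tiling conserves total field area).  Each polygon carries one
dry-yield measurement built from four components: a per-group mean (baseline,
plus an additive treatment effect for test fields), a spatially smooth fertility
surface with a controlled correlation length, independent measurement noise, and
rare gross outliers emulating yield-monitor sensor faults.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

TEST = "test"
CONTROL = "control"
GROUPS = (TEST, CONTROL)

#: column order of the measurement table / CSV dialect
MEASUREMENT_COLUMNS = ["field_id", "group", "x", "y", "area_m2", "dry_yield_kg_ha"]


class DegenerateGeometryError(ValueError):
    """Field too small to hold a single harvest polygon in some dimension."""


@dataclass(frozen=True)
class FieldLayout:
    """One rectangular field: ``width`` across the harvest direction (x),
    ``length`` along it (y), anchored at ``origin`` (lower-left corner, m)."""

    field_id: str
    group: str
    origin: tuple[float, float] = (0.0, 0.0)
    width: float = 200.0
    length: float = 450.0

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if not (self.width > 0 and self.length > 0):
            raise ValueError("width and length must be positive")

    @property
    def area_m2(self) -> float:
        return self.width * self.length


@dataclass
class SimulationConfig:
    """Geometry and statistical parameters of one simulated harvest.

    Units: metres, seconds, kg/ha.  ``treatment_effect`` is the additive shift
    applied to the mean yield of test fields.  ``fertility_scale`` is the
    correlation length of the smooth within-field fertility surface and
    ``fertility_sd`` its marginal standard deviation.  With probability
    ``outlier_rate`` a measurement's noise term is replaced by a gross error of
    ``outlier_magnitude`` noise standard deviations (random sign).
    """

    swath_width: float = 7.0
    harvester_speed: float = 1.75
    measurement_interval: float = 7.0
    baseline_mean: float = 2550.0
    treatment_effect: float = 990.0
    fertility_scale: float = 80.0
    fertility_sd: float = 300.0
    noise_sd: float = 400.0
    outlier_rate: float = 0.002
    outlier_magnitude: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("swath_width", "harvester_speed", "measurement_interval",
                     "fertility_scale"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("fertility_sd", "noise_sd", "outlier_magnitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.outlier_rate <= 1.0:
            raise ValueError("outlier_rate must lie in [0, 1]")

    @property
    def polygon_area(self) -> float:
        """Nominal (untruncated) polygon area in m^2."""
        return self.swath_width * self.harvester_speed * self.measurement_interval

    @property
    def polygon_length(self) -> float:
        """Along-track polygon dimension in m (speed x interval)."""
        return self.harvester_speed * self.measurement_interval

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown simulation keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _edges(total: float, step: float, name: str) -> np.ndarray:
    if total < step:
        raise DegenerateGeometryError(
            f"field {name} dimension {total} m is smaller than one polygon ({step} m)"
        )
    n_full = int(np.floor(total / step + 1e-9))
    edges = step * np.arange(n_full + 1, dtype=float)
    if total - edges[-1] > 1e-9 * max(total, 1.0):
        edges = np.append(edges, total)  # truncated edge strip
    else:
        edges[-1] = total
    return edges


def segment_polygons(layout: FieldLayout, config: SimulationConfig) -> pd.DataFrame:
    """Tile ``layout`` into harvest polygons.

    Columns of the result: ``x``, ``y`` (centroid, m), ``area_m2``.  Interior
    polygons have area ``swath_width x speed x interval``; the last row/column
    is truncated to the field boundary so the areas sum exactly to the field
    area.
    """
    xe = _edges(layout.width, config.swath_width, layout.field_id)
    ye = _edges(layout.length, config.polygon_length, layout.field_id)
    xw = np.diff(xe)
    yw = np.diff(ye)
    xc = layout.origin[0] + (xe[:-1] + xe[1:]) / 2
    yc = layout.origin[1] + (ye[:-1] + ye[1:]) / 2
    X, Y = np.meshgrid(xc, yc)
    A = np.outer(yw, xw)
    return pd.DataFrame({
        "x": X.ravel(), "y": Y.ravel(), "area_m2": A.ravel(),
    })


class FertilitySurface:
    """Smooth, seeded random surface of baseline-yield offsets (kg/ha).

    A lattice of iid standard-normal node values covering ``bounds`` (padded by
    three correlation lengths) is smoothed with a Gaussian kernel of bandwidth
    ``fertility_scale``; the kernel-weighted sum is renormalised pointwise so
    the marginal standard deviation equals ``fertility_sd`` everywhere, while
    points closer than the correlation length share most of their kernel
    support and are therefore positively correlated.
    """

    def __init__(self, bounds: tuple[float, float, float, float],
                 config: SimulationConfig, rng: np.random.Generator):
        self.scale = float(config.fertility_scale)
        self.sd = float(config.fertility_sd)
        xmin, ymin, xmax, ymax = bounds
        pad = 3.0 * self.scale
        spacing = self.scale
        nx = max(int(np.ceil((xmax - xmin + 2 * pad) / spacing)) + 1, 2)
        ny = max(int(np.ceil((ymax - ymin + 2 * pad) / spacing)) + 1, 2)
        gx = xmin - pad + spacing * np.arange(nx)
        gy = ymin - pad + spacing * np.arange(ny)
        GX, GY = np.meshgrid(gx, gy)
        self._nodes = np.column_stack([GX.ravel(), GY.ravel()])
        self._z = rng.standard_normal(len(self._nodes))

    def __call__(self, x, y) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        if self.sd == 0.0:
            return np.zeros_like(x)
        out = np.empty_like(x)
        # chunked: n_points x n_nodes kernel matrix can be large
        step = max(1, int(2e7) // max(len(self._nodes), 1))
        for i in range(0, len(x), step):
            dx = x[i:i + step, None] - self._nodes[None, :, 0]
            dy = y[i:i + step, None] - self._nodes[None, :, 1]
            w = np.exp(-(dx * dx + dy * dy) / (2.0 * self.scale ** 2))
            denom = np.sqrt((w * w).sum(axis=1))
            denom[denom == 0] = 1.0
            out[i:i + step] = self.sd * (w @ self._z) / denom
        return out


def simulate_fertility_surface(layouts, config: SimulationConfig,
                               rng: np.random.Generator | None = None) -> FertilitySurface:
    """Build the shared fertility surface spanning all ``layouts``."""
    if isinstance(layouts, FieldLayout):
        layouts = [layouts]
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(3)[0])
    xmin = min(f.origin[0] for f in layouts)
    ymin = min(f.origin[1] for f in layouts)
    xmax = max(f.origin[0] + f.width for f in layouts)
    ymax = max(f.origin[1] + f.length for f in layouts)
    return FertilitySurface((xmin, ymin, xmax, ymax), config, rng)


def simulate_measurements(layouts, config: SimulationConfig) -> pd.DataFrame:
    """Simulate one yield-monitor dataset over ``layouts``.

    Each polygon's dry yield is ``baseline_mean + treatment_effect·1[test]
    + fertility(x, y) + noise``, with the noise term replaced by a gross
    ``±outlier_magnitude x noise_sd`` error with probability ``outlier_rate``,
    and the result clipped at zero (dry yield is physical).  The single
    ``config.seed`` drives independent substreams for the surface, the noise
    and the outlier process, so each component is individually reproducible.
    """
    layouts = list(layouts)
    if not layouts:
        raise ValueError("at least one field layout is required")
    groups = {f.group for f in layouts}
    if groups != set(GROUPS):
        raise ValueError("need at least one test and one control field")
    ids = [f.field_id for f in layouts]
    if len(set(ids)) != len(ids):
        raise ValueError("field_id values must be unique")

    ss_surface, ss_noise, ss_outlier = np.random.SeedSequence(config.seed).spawn(3)
    surface = simulate_fertility_surface(layouts, config,
                                         np.random.default_rng(ss_surface))
    rng_noise = np.random.default_rng(ss_noise)
    rng_out = np.random.default_rng(ss_outlier)

    frames = []
    n_clipped = 0
    for layout in layouts:
        polys = segment_polygons(layout, config)
        n = len(polys)
        mean = config.baseline_mean + (
            config.treatment_effect if layout.group == TEST else 0.0)
        noise = rng_noise.standard_normal(n) * config.noise_sd
        is_outlier = rng_out.random(n) < config.outlier_rate
        signs = np.where(rng_out.random(n) < 0.5, -1.0, 1.0)
        noise = np.where(is_outlier,
                         signs * config.outlier_magnitude * config.noise_sd,
                         noise)
        yields = mean + surface(polys["x"].to_numpy(), polys["y"].to_numpy()) + noise
        clipped = yields < 0
        n_clipped += int(clipped.sum())
        yields = np.clip(yields, 0.0, None)
        frames.append(pd.DataFrame({
            "field_id": layout.field_id,
            "group": layout.group,
            "x": polys["x"],
            "y": polys["y"],
            "area_m2": polys["area_m2"],
            "dry_yield_kg_ha": yields,
        }))
    if n_clipped:
        logger.info("clipped %d negative simulated yields to 0", n_clipped)
    return pd.concat(frames, ignore_index=True)[MEASUREMENT_COLUMNS]


def make_layouts(n_test: int, n_control: int, width: float = 200.0,
                 length: float = 450.0, gap: float = 30.0) -> list[FieldLayout]:
    """Lay out ``n_test`` + ``n_control`` rectangular fields in a strip,
    alternating groups so that each test field neighbours a control field
    (the paired-neighbour design that lets shared local conditions cancel)."""
    if n_test < 1 or n_control < 1:
        raise ValueError("need at least one field per group")
    labels = []
    t = c = 0
    for i in range(n_test + n_control):
        if (i % 2 == 0 and t < n_test) or c >= n_control:
            labels.append(TEST)
            t += 1
        else:
            labels.append(CONTROL)
            c += 1
    counters = {TEST: 0, CONTROL: 0}
    layouts = []
    for i, g in enumerate(labels):
        counters[g] += 1
        prefix = "T" if g == TEST else "C"
        layouts.append(FieldLayout(
            field_id=f"{prefix}{counters[g]:02d}",
            group=g,
            origin=(i * (width + gap), 0.0),
            width=width,
            length=length,
        ))
    return layouts
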