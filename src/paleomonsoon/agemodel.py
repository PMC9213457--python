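"""Tie-point age-depth models with instantaneous-deposition layers.

Ages are assigned by piecewise-linear interpolation between externally
supplied tie points.  Event layers (rapid/instantaneous deposition, e.g. a
homogeneous mud bed) are excised: the layer's thickness is removed from the
depth axis, so every depth inside the layer maps to the age of its top.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class TiePoint:
    depth: float  # m below seafloor
    age: float    # ka

    def __post_init__(self):
        if self.depth < 0 or self.age < 0:
            raise ValueError("tie-point depth and age must be nonnegative")


@dataclass(frozen=True)
class EventLayer:
    top_depth: float
    bottom_depth: float

    def __post_init__(self):
        if not self.top_depth < self.bottom_depth:
            raise ValueError("event layer requires top_depth < bottom_depth")

    @property
    def thickness(self) -> float:
        return self.bottom_depth - self.top_depth


@dataclass
class AgeDepthModel:
    tie_points: list[TiePoint]
    event_layers: list[EventLayer] = field(default_factory=list)

    def __post_init__(self):
        self.tie_points = sorted(self.tie_points, key=lambda t: t.depth)
        depths = np.array([t.depth for t in self.tie_points])
        ages = np.array([t.age for t in self.tie_points])
        if len(depths) < 2:
            raise ValueError("need at least two tie points")
        if not np.all(np.diff(depths) > 0):
            raise ValueError("tie-point depths must be strictly increasing")
        if not np.all(np.diff(ages) > 0):
            raise ValueError("tie-point ages must be strictly increasing "
                             "(monotonic age model)")
        self.event_layers = sorted(self.event_layers, key=lambda e: e.top_depth)

    # -- depth-axis collapse -------------------------------------------------
    def _collapse(self, depth):
        """Map true depth to event-free depth (layer thickness removed).

        Depths inside a layer collapse onto the layer top, so the whole
        interval shares one age.
        """
        d = np.atleast_1d(np.asarray(depth, dtype=float)).copy()
        removed = np.zeros_like(d)
        for lay in self.event_layers:
            inside = (d > lay.top_depth) & (d < lay.bottom_depth)
            below = d >= lay.bottom_depth
            removed[inside] += d[inside] - lay.top_depth
            removed[below] += lay.thickness
        return d - removed

    @property
    def _collapsed_tie_depths(self) -> np.ndarray:
        return self._collapse([t.depth for t in self.tie_points])

    @property
    def _tie_ages(self) -> np.ndarray:
        return np.array([t.age for t in self.tie_points])

    # -- operations ----------------------------------------------------------
    def age_at_depth(self, depth, extrapolate: bool = False):
        """Age (ka) at depth (mbsf); piecewise linear between tie points."""
        d = np.atleast_1d(np.asarray(depth, dtype=float))
        lo, hi = self.tie_points[0].depth, self.tie_points[-1].depth
        if not extrapolate and (np.any(d < lo) or np.any(d > hi)):
            raise ValueError(
                f"depth outside tie-point span [{lo:g}, {hi:g}] mbsf; "
                "pass extrapolate=True to extend at the end-interval rates")
        cd = self._collapse(d)
        ctie = self._collapsed_tie_depths
        ages = self._tie_ages
        out = np.interp(cd, ctie, ages)
        if extrapolate:
            # constant end-interval sedimentation rate beyond the span
            r0 = (ages[1] - ages[0]) / (ctie[1] - ctie[0])
            rn = (ages[-1] - ages[-2]) / (ctie[-1] - ctie[-2])
            below = cd < ctie[0]
            above = cd > ctie[-1]
            out[below] = ages[0] + (cd[below] - ctie[0]) * r0
            out[above] = ages[-1] + (cd[above] - ctie[-1]) * rn
        return out if np.ndim(depth) else float(out[0])

    def stratigraphic_mar(self, depths, dry_bulk_density: float):
        """Age-model (stratigraphic) mass accumulation rate, g/cm2/kyr.

        MAR is constant within each tie-point interval:
        density * collapsed thickness / age difference.  Event-layer
        thickness is excluded (its deposition is treated as instantaneous).
        Note this MAR scales with any sediment-focusing factor, unlike
        constant-flux-proxy MARs.
        """
        if dry_bulk_density <= 0:
            raise ValueError("dry bulk density must be positive")
        d = np.atleast_1d(np.asarray(depths, dtype=float))
        lo, hi = self.tie_points[0].depth, self.tie_points[-1].depth
        if np.any(d < lo) or np.any(d > hi):
            raise ValueError(f"depth outside tie-point span [{lo:g}, {hi:g}] mbsf")
        ctie = self._collapsed_tie_depths
        ages = self._tie_ages
        dage = np.diff(ages)
        if np.any(dage <= 0):
            raise ZeroDivisionError("zero age difference between tie points")
        # m/kyr * (g/cm3) * 100 cm/m = g/cm2/kyr
        rates = 100.0 * dry_bulk_density * np.diff(ctie) / dage
        idx = np.clip(np.searchsorted(ctie, self._collapse(d), side="right") - 1,
                      0, len(rates) - 1)
        out = rates[idx]
        return out if np.ndim(depths) else float(out[0])


def read_tie_points(path) -> list[TiePoint]:
    df = pd.read_csv(path)
    return [TiePoint(r.depth_mbsf, r.age_ka) for r in df.itertuples()]


def read_event_layers(path) -> list[EventLayer]:
    df = pd.read_csv(path)
    return [EventLayer(r.top_mbsf, r.bottom_mbsf) for r in df.itertuples()]
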