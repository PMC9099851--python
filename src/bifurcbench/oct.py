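"""OCT-pullback style measurements on synthetic frame series.

A pullback is an ordered series of cross-sectional frames (0.1 mm apart for a
10 mm/s pullback imaged at 100 frames/s; 540 frames cover 54 mm).  Each frame
carries maximal/minimal lumen diameters, per-strut records (measured wall gap,
ostium flag, strut thickness) and a thrombus area.  The measurements mirror
the manual OCT analysis of stented bifurcations:

* strut classification - floating if the strut lies in the SB ostium opening;
  malapposed if it protrudes farther than one strut thickness from the wall
  (strictly greater); well-apposed otherwise;
* elliptical index - the mean over analysed frames (default every 10th, i.e.
  1 mm intervals) of Dmax/Dmin in the proximal segment;
* thrombus burden - the mean of the three largest per-frame thrombus areas in
  the bifurcation region;
* proximal lumen summary - min/mean/max diameter and mean lumen area.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "PullbackConfig",
    "StrutRecord",
    "PullbackFrame",
    "PullbackSeries",
    "StrutClassification",
    "classify_struts",
    "elliptical_index",
    "thrombus_area_top3",
    "proximal_summary",
]


@dataclass(frozen=True)
class PullbackConfig:
    frame_interval_mm: float = 0.1  # 10 mm/s at 100 frames/s
    n_frames: int = 540  # 54 mm pullback
    analysis_stride: int = 10  # every 10th frame = 1 mm intervals
    resolution_um: float = 15.0


@dataclass(frozen=True)
class StrutRecord:
    wall_gap_um: float
    in_ostium: bool
    thickness_um: float


@dataclass
class PullbackFrame:
    z_mm: float
    Dmax_mm: float
    Dmin_mm: float
    strut_records: list[StrutRecord] = field(default_factory=list)
    thrombus_area_mm2: float = 0.0
    in_bifurcation_region: bool = False
    in_proximal_region: bool = False
    lumen_area_mm2: float | None = None

    def __post_init__(self):
        if not self.Dmax_mm >= self.Dmin_mm > 0:
            raise ValueError("frame requires Dmax >= Dmin > 0")
        if self.thrombus_area_mm2 < 0:
            raise ValueError("thrombus area must be non-negative")
        if self.lumen_area_mm2 is None:
            # ellipse with the measured principal diameters
            self.lumen_area_mm2 = float(np.pi * self.Dmax_mm * self.Dmin_mm / 4.0)


@dataclass
class PullbackSeries:
    frames: list[PullbackFrame]
    config: PullbackConfig = field(default_factory=PullbackConfig)

    def __iter__(self):
        return iter(self.frames)

    def __len__(self):
        return len(self.frames)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for f in self.frames:
            rows.append(
                {
                    "z_mm": f.z_mm,
                    "Dmax_mm": f.Dmax_mm,
                    "Dmin_mm": f.Dmin_mm,
                    "thrombus_area_mm2": f.thrombus_area_mm2,
                    "in_bifurcation_region": f.in_bifurcation_region,
                    "in_proximal_region": f.in_proximal_region,
                    "lumen_area_mm2": f.lumen_area_mm2,
                    "n_struts": len(f.strut_records),
                }
            )
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        return json.dumps(
            [
                {
                    **{k: v for k, v in asdict(f).items() if k != "strut_records"},
                    "strut_records": [asdict(s) for s in f.strut_records],
                }
                for f in self.frames
            ]
        )

    @classmethod
    def from_json(cls, text: str, config: PullbackConfig | None = None):
        frames = []
        for d in json.loads(text):
            recs = [StrutRecord(**s) for s in d.pop("strut_records")]
            frames.append(PullbackFrame(**d, strut_records=recs))
        return cls(frames, config or PullbackConfig())


@dataclass(frozen=True)
class StrutClassification:
    n_WA: int
    n_MA: int
    n_floating: int

    @property
    def total(self) -> int:
        return self.n_WA + self.n_MA + self.n_floating

    @property
    def pct_WA(self) -> float:
        return 100.0 * self.n_WA / self.total if self.total else 0.0

    @property
    def pct_MA(self) -> float:
        return 100.0 * self.n_MA / self.total if self.total else 0.0

    @property
    def pct_floating(self) -> float:
        return 100.0 * self.n_floating / self.total if self.total else 0.0


def _frames(series) -> list[PullbackFrame]:
    return list(series.frames) if isinstance(series, PullbackSeries) else list(series)


def classify_struts(series: PullbackSeries | Iterable[PullbackFrame]) -> StrutClassification:
    """Count WA/MA/floating struts over all frame strut records.

    Floating iff the strut sits in the SB opening; malapposed iff its wall gap
    strictly exceeds the strut thickness; well-apposed otherwise (a gap equal
    to the thickness is still apposed).  Frames without strut records simply
    contribute nothing.
    """
    n_wa = n_ma = n_fl = 0
    for f in _frames(series):
        for s in f.strut_records:
            if s.in_ostium:
                n_fl += 1
            elif s.wall_gap_um > s.thickness_um:
                n_ma += 1
            else:
                n_wa += 1
    return StrutClassification(n_wa, n_ma, n_fl)


def elliptical_index(
    series: PullbackSeries | Iterable[PullbackFrame],
    stride: int | None = None,
    mode: str = "frame_mean",
) -> tuple[float, np.ndarray]:
    """Elliptical index of the proximal segment.

    ``frame_mean`` (default): mean over analysed frames of per-frame
    Dmax/Dmin.  ``global_extrema``: global max diameter over global min - an
    alternative reading of "standardized for the length of the stent"; both
    agree with the reference values at printed precision.

    Returns (EI, per-frame ratios).  EI >= 1 with equality iff every analysed
    frame is circular.
    """
    frames = _frames(series)
    if stride is None:
        stride = (
            series.config.analysis_stride
            if isinstance(series, PullbackSeries)
            else PullbackConfig().analysis_stride
        )
    prox = [f for f in frames if f.in_proximal_region] or frames
    analysed = prox[::stride] if stride > 1 else prox
    if not analysed:
        raise ValueError("no analysable frames in the proximal segment")
    if any(f.Dmin_mm <= 0 for f in analysed):
        raise ValueError("frame with non-positive Dmin")
    ratios = np.array([f.Dmax_mm / f.Dmin_mm for f in analysed])
    if mode == "frame_mean":
        ei = float(ratios.mean())
    elif mode == "global_extrema":
        ei = float(
            max(f.Dmax_mm for f in analysed) / min(f.Dmin_mm for f in analysed)
        )
    else:
        raise ValueError("mode must be 'frame_mean' or 'global_extrema'")
    return ei, ratios


def thrombus_area_top3(series: PullbackSeries | Iterable[PullbackFrame]) -> float:
    """Mean of the three largest thrombus areas among bifurcation-region frames."""
    areas = sorted(
        (f.thrombus_area_mm2 for f in _frames(series) if f.in_bifurcation_region),
        reverse=True,
    )
    if not areas:
        raise ValueError("no frames flagged in the bifurcation region")
    if len(areas) < 3:
        warnings.warn(
            f"only {len(areas)} bifurcation-region frames available; "
            "averaging what is there",
            stacklevel=2,
        )
    return float(np.mean(areas[:3]))


def proximal_summary(
    series: PullbackSeries | Iterable[PullbackFrame],
) -> tuple[float, float, float, float]:
    """(Dmin, Dmean, Dmax, mean lumen area) over proximal frames.

    Per-frame diameter is the mean of the two principal diameters; the
    extrema/mean are then taken across frames.
    """
    frames = [f for f in _frames(series) if f.in_proximal_region] or _frames(series)
    if not frames:
        raise ValueError("no proximal frames")
    dmean = np.array([(f.Dmax_mm + f.Dmin_mm) / 2.0 for f in frames])
    area = np.array([f.lumen_area_mm2 for f in frames])
    return float(dmean.min()), float(dmean.mean()), float(dmean.max()), float(area.mean())
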