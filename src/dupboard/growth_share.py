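"""BCG growth/share statistics, quadrants, traffic lights and control region.

Each hospital's recent rate series is reduced to two numbers: *growth*
(Pearson correlation of the series with the time index — the Y axis) and
*share* (the series mean, a momentum measure — the X axis). The (growth,
share) plane is cut into the four classic portfolio quadrants, mapped to
traffic-light colors and BCG mascots, and a mean +/- 2 SD rectangle over
all hospitals flags extreme performers.

Two series modes are provided. ``raw`` (default) applies growth/share to
the last ``window_outputs`` raw quarters, which is the reading under which
the published worked examples reproduce. ``moving_sd`` first converts the
last ``2 * window_outputs`` quarters into ``window_outputs`` moving sample
SDs (24 points -> 12 SDs) and applies growth/share to that derived series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel_io import IndicatorPanel

QUADRANTS = ("I", "II", "III", "IV")

#: quadrant -> traffic-light color; lower duplication is better, so any
#: negative growth is "excellent" (green) and only rising level+trend is red
QUADRANT_COLOR = {"I": "red", "II": "yellow", "III": "green", "IV": "green"}

#: quadrant -> classic BCG mascot
QUADRANT_MASCOT = {
    "I": "star",
    "II": "problem_child",
    "III": "dog",
    "IV": "cash_cow",
}


@dataclass(frozen=True)
class SeriesMode:
    """How a hospital's quarter series is reduced before growth/share."""

    mode: str = "raw"
    window_outputs: int = 12

    def __post_init__(self) -> None:
        if self.mode not in ("raw", "moving_sd"):
            raise ValueError(f"mode must be 'raw' or 'moving_sd', got {self.mode!r}")
        if self.window_outputs < 3:
            raise ValueError("window_outputs must be >= 3")

    @property
    def required_span(self) -> int:
        return self.window_outputs if self.mode == "raw" else 2 * self.window_outputs


@dataclass(frozen=True)
class GrowthShareResult:
    hospital_id: str
    growth: float
    share: float
    quadrant: str
    color: str
    mascot: str
    in_control: bool = True


def moving_sd_series(series, window_outputs: int = 12) -> np.ndarray:
    """Sliding-window sample SDs arranged so N points yield ``window_outputs`` SDs.

    The window length is ``N - window_outputs + 1``: with 24 points and 12
    outputs each SD covers 13 consecutive points, and the i-th output is the
    SD of the window starting at position i.
    """
    x = np.asarray(series, dtype=float)
    if np.isnan(x).any():
        raise ValueError("series contains missing values")
    n = x.size
    if n <= window_outputs:
        raise ValueError(
            f"need more than window_outputs={window_outputs} points, got {n}"
        )
    width = n - window_outputs + 1
    windows = np.lib.stride_tricks.sliding_window_view(x, width)
    return windows.std(axis=1, ddof=1)


def growth(series) -> float:
    """Trend statistic: Pearson correlation with the time index 1..T.

    A constant series has no trend and returns 0 by convention.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 3:
        raise ValueError(f"need >= 3 points, got {x.size}")
    if np.isnan(x).any():
        raise ValueError("series contains missing values")
    t = np.arange(1, x.size + 1, dtype=float)
    sx = x.std()
    if sx == 0:
        return 0.0
    return float(np.corrcoef(t, x)[0, 1])


def share(series) -> float:
    """Momentum statistic: the arithmetic mean of the series."""
    x = np.asarray(series, dtype=float)
    if x.size < 1:
        raise ValueError("empty series")
    if np.isnan(x).any():
        raise ValueError("series contains missing values")
    return float(x.mean())


def classify_quadrant(g: float, s: float) -> str:
    """Quadrant of a (growth, share) point.

    Boundary ties (g=0 or s=0) go to the non-red side: zero trend is not
    "increasing growth", so I requires strictly positive g and s.
    """
    if not (np.isfinite(g) and np.isfinite(s)):
        raise ValueError(f"growth/share must be finite, got ({g}, {s})")
    if g > 0:
        return "I" if s > 0 else "II"
    return "IV" if s > 0 else "III"


def assign_color(quadrant: str) -> str:
    return QUADRANT_COLOR[quadrant]


def assign_mascot(quadrant: str) -> str:
    return QUADRANT_MASCOT[quadrant]


def control_region(points) -> tuple[tuple[float, float], tuple[float, float], np.ndarray]:
    """Mean +/- 2 SD rectangle on both axes ("95% CI" control area).

    Parameters
    ----------
    points : array-like of shape (n, 2)
        (growth, share) pairs, n >= 2.

    Returns
    -------
    center : (mean_g, mean_s)
    half_widths : (2*sd_g, 2*sd_s)
    in_control : boolean array; True when the point is inside or on the
        rectangle boundary.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("expected an (n, 2) array of (growth, share) points")
    if pts.shape[0] < 2:
        raise ValueError("need >= 2 hospitals for a control region")
    center = pts.mean(axis=0)
    half = 2.0 * pts.std(axis=0, ddof=1)
    inside = np.all(np.abs(pts - center) <= half + 1e-12, axis=1)
    return (float(center[0]), float(center[1])), (float(half[0]), float(half[1])), inside


def _reduced_series(values: np.ndarray, mode: SeriesMode) -> np.ndarray:
    span = mode.required_span
    if values.size < span:
        raise ValueError(
            f"panel span {values.size} shorter than required {span} quarters"
        )
    recent = values[-span:]
    if mode.mode == "raw":
        return recent
    return moving_sd_series(recent, mode.window_outputs)


def analyze_panel(panel: IndicatorPanel, mode: SeriesMode | None = None) -> list[GrowthShareResult]:
    """Growth/share classification for every hospital in a complete panel."""
    mode = mode or SeriesMode()
    gs = []
    for hospital in panel.hospitals:
        values = panel.rates.loc[hospital.id].to_numpy(dtype=float)
        reduced = _reduced_series(values, mode)
        g = growth(reduced)
        s = share(reduced)
        gs.append((hospital.id, g, s))
    if len(gs) >= 2:
        _, _, inside = control_region([(g, s) for _, g, s in gs])
    else:
        inside = np.ones(len(gs), dtype=bool)
    results = []
    for (hid, g, s), ok in zip(gs, inside):
        quadrant = classify_quadrant(g, s)
        results.append(
            GrowthShareResult(
                hospital_id=hid,
                growth=g,
                share=s,
                quadrant=quadrant,
                color=assign_color(quadrant),
                mascot=assign_mascot(quadrant),
                in_control=bool(ok),
            )
        )
    return results


def results_frame(results: list[GrowthShareResult]) -> pd.DataFrame:
    """Results as a DataFrame (the CSV export layout)."""
    return pd.DataFrame(
        {
            "hospital_id": [r.hospital_id for r in results],
            "growth": [r.growth for r in results],
            "share": [r.share for r in results],
            "quadrant": [r.quadrant for r in results],
            "color": [r.color for r in results],
            "mascot": [r.mascot for r in results],
            "in_control": [r.in_control for r in results],
        }
    )


class GrowthShareModel:
    """Portfolio model for one panel: ``GrowthShareModel(panel).fit()``."""

    def __init__(self, panel: IndicatorPanel, mode: str = "raw", window_outputs: int = 12):
        self.panel = panel
        self.mode = SeriesMode(mode=mode, window_outputs=window_outputs)

    def fit(self) -> "GrowthShareResults":
        return GrowthShareResults(self.panel, self.mode, analyze_panel(self.panel, self.mode))


class GrowthShareResults:
    """Per-hospital growth/share results with the panel control region."""

    def __init__(self, panel, mode, results):
        self.panel = panel
        self.mode = mode
        self.results = results
        pts = [(r.growth, r.share) for r in results]
        if len(pts) >= 2:
            self.center, self.half_widths, _ = control_region(pts)
        else:
            self.center = self.half_widths = None

    @property
    def frame(self) -> pd.DataFrame:
        return results_frame(self.results)

    def color_counts(self) -> dict[str, int]:
        counts = {"red": 0, "yellow": 0, "green": 0}
        for r in self.results:
            counts[r.color] += 1
        return counts

    def summary(self) -> str:
        counts = self.color_counts()
        quad = {q: sum(1 for r in self.results if r.quadrant == q) for q in QUADRANTS}
        lines = [
            f"Growth/share portfolio: {self.panel.drug} "
            f"({len(self.results)} hospitals, mode={self.mode.mode})",
            "-" * 64,
            "Quadrants  " + "  ".join(f"{q}:{quad[q]}" for q in QUADRANTS),
            "Colors     " + "  ".join(f"{c}:{n}" for c, n in counts.items()),
        ]
        if self.center is not None:
            lines.append(
                f"Control region center (g,s)=({self.center[0]:.3f},{self.center[1]:.3f}) "
                f"half-widths ({self.half_widths[0]:.3f},{self.half_widths[1]:.3f})"
            )
            lines.append(
                f"Out of control: {sum(1 for r in self.results if not r.in_control)}"
            )
        return "\n".join(lines)

    def plot(self, ax=None):
        """Scatter of (share, growth) colored by traffic light, with the
        control rectangle; requires matplotlib."""
        import matplotlib.pyplot as plt
        from matplotlib.patches import Rectangle

        if ax is None:
            _, ax = plt.subplots()
        for r in self.results:
            ax.scatter(r.share, r.growth, c=r.color, edgecolors="k", zorder=3)
        if self.center is not None:
            (cg, cs), (hg, hs) = self.center, self.half_widths
            ax.add_patch(
                Rectangle(
                    (cs - hs, cg - hg), 2 * hs, 2 * hg,
                    fill=False, linestyle="--", edgecolor="gray",
                )
            )
        ax.axhline(0, color="k", lw=0.5)
        ax.axvline(0, color="k", lw=0.5)
        ax.set_xlabel("share (mean rate, %)" if self.mode.mode == "raw" else "share (mean moving SD)")
        ax.set_ylabel("growth (trend correlation)")
        return ax
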