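"""Dashboard export: GeoJSON features and a self-contained offline HTML page.

The page embeds all data inline (no network calls, no commercial map API):
a growth/share scatter with the 2-SD control rectangle, a lon/lat bubble map
over a coarse Taiwan outline, per-hospital traditional and moving-SD control
charts, a traffic-light legend and hospital-type/color toggles. Rendering is
deterministic — identical input and title produce a byte-identical file.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .growth_share import GrowthShareResult, moving_sd_series, growth as growth_stat
from .panel_io import Hospital, IndicatorPanel

logger = logging.getLogger(__name__)

#: default traffic-light hex colors (overridable via DashboardSpec)
DEFAULT_HEX = {"red": "#d7191c", "yellow": "#fdae61", "green": "#1a9641"}

#: coarse clockwise outline of Taiwan's main island, (lon, lat)
TAIWAN_OUTLINE = [
    (121.0, 25.3), (121.6, 25.3), (121.9, 25.0), (121.6, 24.4),
    (121.4, 23.1), (120.9, 21.9), (120.7, 22.0), (120.2, 23.0),
    (120.1, 23.7), (120.6, 24.6), (121.0, 25.3),
]


def bubble_radius(share: float, bubble_scale: float = 8.0) -> float:
    """Bubble radius, strictly increasing in |share| (area ~ momentum)."""
    return float(bubble_scale * np.sqrt(abs(share)))


@dataclass
class DashboardSpec:
    title: str
    results: list[GrowthShareResult]
    hospitals: list[Hospital]
    bubble_scale: float = 8.0
    show_control_region: bool = True
    hex_colors: dict = field(default_factory=lambda: dict(DEFAULT_HEX))
    #: hospital_id -> (traditional chart dict, moving chart dict)
    charts: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.bubble_scale <= 0:
            raise ValueError("bubble_scale must be positive")


def to_geojson(results: list[GrowthShareResult], hospitals: list[Hospital]) -> dict:
    """One RFC 7946 Point feature per hospital with coordinates.

    Coordinates are WGS84 in [lon, lat] order; hospitals without
    coordinates are skipped with a log message.
    """
    meta = {h.id: h for h in hospitals}
    features = []
    for r in results:
        h = meta.get(r.hospital_id)
        if h is None or not h.has_coordinates:
            logger.warning("skipping %s: no coordinates", r.hospital_id)
            continue
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [h.lon, h.lat]},
                "properties": {
                    "id": h.id,
                    "name": h.name,
                    "htype": h.htype,
                    "region": h.region,
                    "growth": r.growth,
                    "share": r.share,
                    "quadrant": r.quadrant,
                    "color": r.color,
                    "mascot": r.mascot,
                    "in_control": r.in_control,
                },
            }
        )
    return {"type": "FeatureCollection", "features": features}


def control_charts(series, window_outputs: int = 12) -> tuple[dict, dict | None]:
    """Chart payloads for one hospital's quarter series.

    The *traditional* chart shows the last 8 quarters (a 2-year trend) with
    mean +/- 2 SD limits computed from the full series. The *moving* chart
    shows the moving-SD series over the last ``2 * window_outputs``
    quarters with a least-squares trend line whose slope sign matches the
    sign of the growth statistic of that derived series. If the series is
    too short for the moving chart, only the traditional chart is returned
    (flagged in its payload).
    """
    x = np.asarray(series, dtype=float)
    if np.isnan(x).any():
        raise ValueError("series contains missing values")
    mean = float(x.mean())
    sd = float(x.std(ddof=1)) if x.size > 1 else 0.0
    recent = x[-8:]
    traditional = {
        "kind": "traditional",
        "values": [float(v) for v in recent],
        "center": mean,
        "upper": mean + 2 * sd,
        "lower": mean - 2 * sd,
        "short_series": bool(x.size < 2 * window_outputs),
    }
    if x.size < 2 * window_outputs:
        return traditional, None
    msd = moving_sd_series(x[-2 * window_outputs:], window_outputs)
    t = np.arange(1, msd.size + 1, dtype=float)
    slope, intercept = np.polyfit(t, msd, 1)
    moving = {
        "kind": "moving_sd",
        "values": [float(v) for v in msd],
        "trend_slope": float(slope),
        "trend_intercept": float(intercept),
        "growth": growth_stat(msd),
    }
    return traditional, moving


def build_spec(
    panel: IndicatorPanel,
    results: list[GrowthShareResult],
    title: str,
    window_outputs: int = 12,
    **kwargs,
) -> DashboardSpec:
    """Assemble a DashboardSpec with per-hospital chart payloads."""
    charts = {}
    for h in panel.hospitals:
        series = panel.rates.loc[h.id].to_numpy(dtype=float)
        charts[h.id] = control_charts(series, window_outputs)
    return DashboardSpec(
        title=title, results=results, hospitals=panel.hospitals, charts=charts, **kwargs
    )


def _svg_scatter(spec: DashboardSpec) -> str:
    """Growth/share scatter panel with the 2-SD control rectangle (SVG)."""
    width, height, pad = 420, 320, 40
    gs = [(r.share, r.growth) for r in spec.results]
    xs = [p[0] for p in gs]
    ys = [p[1] for p in gs]
    xlo, xhi = min(xs + [0]) - 0.1, max(xs + [0]) + 0.1
    ylo, yhi = min(ys + [-1]) - 0.1, max(ys + [1]) + 0.1

    def sx(v):
        return pad + (v - xlo) / (xhi - xlo) * (width - 2 * pad)

    def sy(v):
        return height - pad - (v - ylo) / (yhi - ylo) * (height - 2 * pad)

    parts = [
        f'<svg class="scatter" width="{width}" height="{height}" '
        'xmlns="http://www.w3.org/2000/svg">'
    ]
    parts.append(
        f'<line x1="{sx(xlo):.1f}" y1="{sy(0):.1f}" x2="{sx(xhi):.1f}" '
        f'y2="{sy(0):.1f}" stroke="#999"/>'
    )
    parts.append(
        f'<line x1="{sx(0):.1f}" y1="{sy(ylo):.1f}" x2="{sx(0):.1f}" '
        f'y2="{sy(yhi):.1f}" stroke="#999"/>'
    )
    if spec.show_control_region and len(gs) >= 2:
        arr = np.asarray(gs)
        center = arr.mean(axis=0)
        half = 2 * arr.std(axis=0, ddof=1)
        x0, x1 = sx(center[0] - half[0]), sx(center[0] + half[0])
        y0, y1 = sy(center[1] + half[1]), sy(center[1] - half[1])
        parts.append(
            f'<rect class="control-region" x="{x0:.1f}" y="{y0:.1f}" '
            f'width="{x1 - x0:.1f}" height="{y1 - y0:.1f}" fill="none" '
            'stroke="#555" stroke-dasharray="4 3"/>'
        )
    for r in spec.results:
        hexcol = spec.hex_colors[r.color]
        radius = max(2.0, bubble_radius(r.share, spec.bubble_scale))
        parts.append(
            f'<circle class="bubble scatter-bubble" data-id="{r.hospital_id}" '
            f'data-color="{r.color}" cx="{sx(r.share):.1f}" cy="{sy(r.growth):.1f}" '
            f'r="{radius:.1f}" fill="{hexcol}" fill-opacity="0.7" stroke="#333"/>'
        )
    parts.append("</svg>")
    return "".join(parts)


def _svg_map(spec: DashboardSpec) -> str:
    """Bubble map over the embedded Taiwan outline (plain lon/lat SVG)."""
    width, height, pad = 360, 460, 20
    lon_lo, lon_hi, lat_lo, lat_hi = 119.9, 122.1, 21.8, 25.4

    def sx(lon):
        return pad + (lon - lon_lo) / (lon_hi - lon_lo) * (width - 2 * pad)

    def sy(lat):
        return height - pad - (lat - lat_lo) / (lat_hi - lat_lo) * (height - 2 * pad)

    pts = " ".join(f"{sx(lon):.1f},{sy(lat):.1f}" for lon, lat in TAIWAN_OUTLINE)
    parts = [
        f'<svg class="map" width="{width}" height="{height}" '
        'xmlns="http://www.w3.org/2000/svg">',
        f'<polygon points="{pts}" fill="#eef4ee" stroke="#888"/>',
    ]
    meta = {h.id: h for h in spec.hospitals}
    for r in spec.results:
        h = meta.get(r.hospital_id)
        if h is None or not h.has_coordinates:
            continue
        hexcol = spec.hex_colors[r.color]
        radius = max(2.0, bubble_radius(r.share, spec.bubble_scale))
        parts.append(
            f'<circle class="bubble map-bubble" data-id="{r.hospital_id}" '
            f'data-htype="{h.htype}" data-color="{r.color}" '
            f'cx="{sx(h.lon):.1f}" cy="{sy(h.lat):.1f}" r="{radius:.1f}" '
            f'fill="{hexcol}" fill-opacity="0.7" stroke="#333">'
            f"<title>{h.name} ({r.mascot})</title></circle>"
        )
    parts.append("</svg>")
    return "".join(parts)


_PAGE = """<!DOCTYPE html>
<html lang="en">
<head>
<meta charset="utf-8">
<title>{title}</title>
<style>
body {{ font-family: sans-serif; margin: 1em; }}
.legend span {{ padding: 0.2em 0.6em; margin-right: 0.4em; color: #fff; }}
.panel {{ display: inline-block; vertical-align: top; margin-right: 1em; }}
.toggles label {{ margin-right: 1em; }}
#charts {{ margin-top: 1em; font-size: 0.85em; }}
</style>
</head>
<body>
<h1>{title}</h1>
{body}
<script id="dashboard-data" type="application/json">{payload}</script>
<script>
(function () {{
  var data = JSON.parse(document.getElementById("dashboard-data").textContent);
  document.querySelectorAll(".toggles input").forEach(function (box) {{
    box.addEventListener("change", function () {{
      var attr = box.dataset.attr, value = box.dataset.value;
      document.querySelectorAll(".bubble").forEach(function (el) {{
        if (el.dataset[attr] === value) {{
          el.style.display = box.checked ? "" : "none";
        }}
      }});
    }});
  }});
  document.querySelectorAll(".bubble").forEach(function (el) {{
    el.addEventListener("click", function () {{
      var charts = data.charts[el.dataset.id];
      document.getElementById("charts").textContent =
        el.dataset.id + ": " + JSON.stringify(charts);
    }});
  }});
}})();
</script>
</body>
</html>
"""


def render_dashboard(spec: DashboardSpec, out) -> None:
    """Write the dashboard as one self-contained HTML file."""
    if not spec.results:
        body = '<p class="no-data">No data to display.</p>'
        payload = json.dumps({"charts": {}}, sort_keys=True)
    else:
        counts = {"red": 0, "yellow": 0, "green": 0}
        for r in spec.results:
            counts[r.color] += 1
        legend = "".join(
            f'<span class="legend-{c}" style="background:{spec.hex_colors[c]}">'
            f"{c}: {counts[c]}</span>"
            for c in ("red", "yellow", "green")
        )
        htypes = sorted({h.htype for h in spec.hospitals})
        toggles = "".join(
            f'<label><input type="checkbox" checked data-attr="htype" '
            f'data-value="{t}">{t}</label>'
            for t in htypes
        ) + "".join(
            f'<label><input type="checkbox" checked data-attr="color" '
            f'data-value="{c}">{c}</label>'
            for c in ("red", "yellow", "green")
        )
        charts_payload = {}
        for hid, (traditional, moving) in spec.charts.items():
            charts_payload[hid] = {"traditional": traditional, "moving": moving}
        payload = json.dumps({"charts": charts_payload}, sort_keys=True)
        body = (
            f'<div class="legend">{legend}</div>'
            f'<div class="toggles">{toggles}</div>'
            f'<div class="panel">{_svg_map(spec)}</div>'
            f'<div class="panel">{_svg_scatter(spec)}</div>'
            '<div id="charts">Click a bubble to show its control charts.</div>'
        )
    html = _PAGE.format(title=spec.title, body=body, payload=payload)
    with open(out, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(html)
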