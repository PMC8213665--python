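"""Rose-plot geometry and single-page report rendering.

The rose plot shows one sector per region, grouped by lobe, with a
log-scale radial axis: a percentile p maps to radius
(log10(p) + 2) / 4, so the axis spans 0.01 -> 100 and the clinically
interesting low percentiles occupy most of the radius.  Traffic-light
colours flag low percentiles (default breakpoints 1 / 5 / 25).

Rendering is plain string assembly into SVG embedded in HTML: identical
bundles produce byte-identical documents, which makes report output
diffable and testable.  The report deliberately shows no clinical or
identifying data beyond age and sex, mirroring rater blinding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Mapping, Sequence

from .exceptions import QReportError, ValidationError
from .io import RegionMap

if TYPE_CHECKING:  # pragma: no cover
    from .normative import QReportBundle

#: Default colour breakpoints: p < 1 red, 1-5 orange, 5-25 yellow, >= 25 green.
DEFAULT_COLOUR_THRESHOLDS = (1.0, 5.0, 25.0)

#: Radial gridlines drawn on the rose plot, in percentile units.
DEFAULT_GRIDLINES = (1.0, 5.0, 25.0, 50.0, 100.0)

_COLOUR_HEX = {"green": "#3a9e4d", "yellow": "#e6c229", "orange": "#e8871e",
               "red": "#d03a2b"}


def rose_radius(p: float) -> float:
    """Log-scale radial extent in [0, 1] for a percentile in [0.01, 100]."""
    if not (0.01 <= p <= 100.0):
        raise ValidationError(f"percentile {p} outside [0.01, 100]")
    return (math.log10(p) + 2.0) / 4.0


def rose_colour(p: float,
                thresholds: Sequence[float] = DEFAULT_COLOUR_THRESHOLDS) -> str:
    """Traffic-light colour class for a percentile.

    ``thresholds`` are the ascending breakpoints (red|orange, orange|yellow,
    yellow|green); a percentile at a breakpoint takes the higher class.
    """
    if not (0.01 <= p <= 100.0):
        raise ValidationError(f"percentile {p} outside [0.01, 100]")
    t1, t2, t3 = thresholds
    if not (t1 < t2 < t3):
        raise ValidationError(f"colour thresholds must be ascending, got {thresholds}")
    if p >= t3:
        return "green"
    if p >= t2:
        return "yellow"
    if p >= t1:
        return "orange"
    return "red"


@dataclass
class Sector:
    region: str
    lobe: str
    theta_start: float  # degrees, clockwise from 12 o'clock
    theta_end: float
    radius: float       # in [0, 1]
    colour: str


@dataclass
class RosePlotGeometry:
    """Ordered sectors partitioning the circle, plus radial gridlines."""
    sectors: list[Sector]
    gridlines: tuple[float, ...] = DEFAULT_GRIDLINES


def build_rose_geometry(percentiles: Mapping[str, float], region_map: RegionMap,
                        thresholds: Sequence[float] = DEFAULT_COLOUR_THRESHOLDS,
                        gridlines: Sequence[float] = DEFAULT_GRIDLINES,
                        ) -> RosePlotGeometry:
    """Lay out one equal-angle sector per region, in region-map order."""
    regions = region_map.regions
    missing = [r for r in regions if r not in percentiles]
    if missing:
        raise KeyError(f"percentile missing for regions: {missing}")
    lobe_of = region_map.lobe_of
    span = 360.0 / len(regions)
    sectors = []
    for i, region in enumerate(regions):
        p = percentiles[region]
        sectors.append(Sector(
            region=region, lobe=lobe_of[region],
            theta_start=i * span, theta_end=(i + 1) * span,
            radius=rose_radius(p), colour=rose_colour(p, thresholds),
        ))
    return RosePlotGeometry(sectors=sectors, gridlines=tuple(float(g) for g in gridlines))


# ---------------------------------------------------------------------------
# SVG assembly


def _polar(cx: float, cy: float, r: float, theta_deg: float) -> tuple[float, float]:
    # 0 deg at 12 o'clock, increasing clockwise
    rad = math.radians(theta_deg - 90.0)
    return cx + r * math.cos(rad), cy + r * math.sin(rad)


def _fmt(x: float) -> str:
    return f"{x:.3f}"


def _sector_path(cx: float, cy: float, r: float, t0: float, t1: float) -> str:
    x0, y0 = _polar(cx, cy, r, t0)
    x1, y1 = _polar(cx, cy, r, t1)
    large = 1 if (t1 - t0) > 180.0 else 0
    return (f"M {_fmt(cx)} {_fmt(cy)} L {_fmt(x0)} {_fmt(y0)} "
            f"A {_fmt(r)} {_fmt(r)} 0 {large} 1 {_fmt(x1)} {_fmt(y1)} Z")


def _rose_svg(rose: RosePlotGeometry, size: int = 360) -> str:
    cx = cy = size / 2.0
    rmax = size / 2.0 - 30.0
    parts = [f'<svg width="{size}" height="{size}" viewBox="0 0 {size} {size}" '
             f'xmlns="http://www.w3.org/2000/svg">']
    for s in rose.sectors:
        path = _sector_path(cx, cy, s.radius * rmax, s.theta_start, s.theta_end)
        parts.append(f'<path d="{path}" fill="{_COLOUR_HEX[s.colour]}" '
                     f'stroke="#ffffff" stroke-width="1"><title>'
                     f'{s.lobe}/{s.region}</title></path>')
    for g in rose.gridlines:
        r = rose_radius(g) * rmax
        parts.append(f'<circle cx="{_fmt(cx)}" cy="{_fmt(cy)}" r="{_fmt(r)}" '
                     f'fill="none" stroke="#555555" stroke-width="0.7" '
                     f'stroke-dasharray="3 3"/>')
        parts.append(f'<text x="{_fmt(cx + 3)}" y="{_fmt(cy - r - 2)}" '
                     f'font-size="9" fill="#333333">{g:g}</text>')
    # sector boundary spokes
    for s in rose.sectors:
        x, y = _polar(cx, cy, rmax, s.theta_start)
        parts.append(f'<line x1="{_fmt(cx)}" y1="{_fmt(cy)}" x2="{_fmt(x)}" '
                     f'y2="{_fmt(y)}" stroke="#cccccc" stroke-width="0.5"/>')
    parts.append("</svg>")
    return "".join(parts)


def _bpf_panel_svg(bundle: "QReportBundle", width: int = 360, height: int = 240) -> str:
    curves = bundle.bpf_curves
    ages = [a for pts in curves.values() for a, _ in pts] + [bundle.subject.age]
    vals = [v for pts in curves.values() for _, v in pts] + [bundle.bpf]
    a0, a1 = min(ages), max(ages)
    v0, v1 = min(vals), max(vals)
    pad_v = 0.05 * (v1 - v0 or 1.0)
    v0, v1 = v0 - pad_v, v1 + pad_v
    ml, mr, mt, mb = 46, 10, 10, 30

    def sx(a: float) -> float:
        return ml + (a - a0) / (a1 - a0 or 1.0) * (width - ml - mr)

    def sy(v: float) -> float:
        return height - mb - (v - v0) / (v1 - v0) * (height - mt - mb)

    parts = [f'<svg width="{width}" height="{height}" viewBox="0 0 {width} {height}" '
             f'xmlns="http://www.w3.org/2000/svg">']
    parts.append(f'<rect x="{ml}" y="{mt}" width="{width - ml - mr}" '
                 f'height="{height - mt - mb}" fill="none" stroke="#888888"/>')
    for p in sorted(curves):
        pts = " ".join(f"{_fmt(sx(a))},{_fmt(sy(v))}" for a, v in curves[p])
        parts.append(f'<polyline points="{pts}" fill="none" stroke="#7f9fc4" '
                     f'stroke-width="1"/>')
        a_last, v_last = curves[p][-1]
        parts.append(f'<text x="{_fmt(sx(a_last) + 2)}" y="{_fmt(sy(v_last) + 3)}" '
                     f'font-size="8" fill="#46688f">{p:g}</text>')
    parts.append(f'<circle cx="{_fmt(sx(bundle.subject.age))}" '
                 f'cy="{_fmt(sy(bundle.bpf))}" r="4" fill="#d03a2b"/>')
    parts.append(f'<text x="{width // 2}" y="{height - 8}" font-size="10" '
                 f'text-anchor="middle" fill="#333333">age (years)</text>')
    parts.append(f'<text x="12" y="{height // 2}" font-size="10" fill="#333333" '
                 f'transform="rotate(-90 12 {height // 2})" '
                 f'text-anchor="middle">BPF</text>')
    parts.append("</svg>")
    return "".join(parts)


def render_report(bundle: "QReportBundle", region_map: RegionMap,
                  out: str | Path | None = None) -> str:
    """Assemble the single-page report (SVG panels embedded in HTML).

    Panels: demographics (age and sex only — the report is blinded to
    everything else), hippocampal percentiles, BPF against the normative
    percentile curves, QC metrics, and the rose plot.  Output is
    deterministic: identical bundles give byte-identical documents.
    """
    if bundle.bpf is None or bundle.bpf_percentile is None:
        raise ValidationError("bundle has no BPF; cannot render the BPF panel")
    if not bundle.bpf_curves:
        raise ValidationError("bundle has no normative BPF curves")
    missing = [r for r in region_map.regions if r not in bundle.percentiles]
    if missing:
        raise KeyError(f"bundle lacks percentiles for regions: {missing}")
    if bundle.rose is None:
        bundle.rose = build_rose_geometry(bundle.percentiles, region_map)

    def pct(v: float | None) -> str:
        return "n/a" if v is None else f"{v:.1f}"

    qc_rows = ""
    if bundle.qc is not None:
        qc_rows = (f"<tr><td>SNR</td><td>{bundle.qc['snr']:.1f}</td></tr>"
                   f"<tr><td>CNR</td><td>{bundle.qc['cnr']:.1f}</td></tr>")
    else:
        qc_rows = '<tr><td colspan="2">not available</td></tr>'

    html = f"""<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>Quantitative volumetry report</title>
<style>
body {{ font-family: Helvetica, Arial, sans-serif; margin: 24px; color: #222; }}
table {{ border-collapse: collapse; margin-bottom: 12px; }}
td, th {{ border: 1px solid #bbb; padding: 3px 8px; font-size: 13px; }}
.panel {{ display: inline-block; vertical-align: top; margin-right: 24px; }}
h2 {{ font-size: 15px; }}
</style></head><body>
<h1>Quantitative volumetry report</h1>
<div class="panel">
<h2>Demographics</h2>
<table>
<tr><td>Age</td><td>{bundle.subject.age:.0f} y</td></tr>
<tr><td>Sex</td><td>{bundle.subject.sex}</td></tr>
</table>
<h2>Hippocampal volume percentiles</h2>
<table>
<tr><td>Left</td><td>{pct(bundle.hippocampus_left)}</td></tr>
<tr><td>Right</td><td>{pct(bundle.hippocampus_right)}</td></tr>
</table>
<h2>Brain parenchymal fraction</h2>
<table>
<tr><td>BPF</td><td>{bundle.bpf:.3f}</td></tr>
<tr><td>Percentile</td><td>{bundle.bpf_percentile:.1f}</td></tr>
</table>
<h2>Quality control</h2>
<table>{qc_rows}</table>
</div>
<div class="panel">
<h2>BPF vs normative population</h2>
{_bpf_panel_svg(bundle)}
</div>
<div class="panel">
<h2>Regional grey-matter percentiles</h2>
{_rose_svg(bundle.rose)}
</div>
</body></html>
"""
    if out is not None:
        Path(out).write_text(html, encoding="utf-8")
    return html
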