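"""Static SVG rendering: co-cluster matrix heatmap (with core, cohesion and
base-mask overlays), similarity ladder, overview bar charts, and the
parallel-partitions ribbon plot.

Rendering is pure: the same inputs produce byte-identical SVG, which makes
the figures diffable and structurally testable (element counts mirror the
data: one ``cell`` rect per non-zero matrix cell, one ``ribbon`` polygon
per shared item per adjacent band pair, and so on).  Colors follow the
conventions of the interactive views this mirrors: co-cluster values ramp
from near-white (1) to saturated red (k), optional black background for
never-co-clustered pairs, green core outlines, blue cohesion overlays whose
side scales as cohesion/(1+cohesion), and one stable hue per clustering
used identically in every view.
"""

from __future__ import annotations

import colorsys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from ._format import fmt
from .cocluster import BaseMask, CoClusterMatrix
from .layout import BandLayout
from .reordering import Ordering
from .similarity import DISTANCE_METRICS, Ladder

__all__ = [
    "RenderSpec",
    "clustering_hues",
    "render_matrix",
    "render_parallel_partitions",
    "render_overview",
    "render_ladder",
]


@dataclass(frozen=True)
class RenderSpec:
    """Rendering options shared by all views.

    ``cell`` is the pixel size of one matrix cell / item unit;
    ``black_background`` paints never-co-clustered cells black instead of
    white; ``hues`` maps clustering name → CSS color and must be identical
    across views so a clustering keeps its color everywhere.
    """

    format: str = "svg"
    cell: int = 4
    black_background: bool = False
    low_color: tuple = (255, 235, 235)  # A⁺ value 1: light pink
    high_color: tuple = (178, 24, 43)  # A⁺ value k: saturated red
    hues: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.format != "svg":
            raise ValueError(
                f"unsupported format {self.format!r}: only 'svg' is implemented"
            )


def clustering_hues(names: Sequence) -> dict:
    """One stable, evenly spaced hue per clustering (by position)."""
    out = {}
    k = len(names)
    for i, name in enumerate(names):
        r, g, b = colorsys.hls_to_rgb(i / max(k, 1), 0.55, 0.65)
        out[name] = f"#{int(r*255):02x}{int(g*255):02x}{int(b*255):02x}"
    return out


def _value_color(v: int, k: int, spec: RenderSpec) -> str:
    frac = 1.0 if k <= 1 else (v - 1) / (k - 1)
    lo, hi = spec.low_color, spec.high_color
    rgb = tuple(round(l + frac * (h - l)) for l, h in zip(lo, hi))
    return f"#{rgb[0]:02x}{rgb[1]:02x}{rgb[2]:02x}"


def _svg(width: float, height: float, body: list) -> str:
    head = (
        '<?xml version="1.0" encoding="UTF-8"?>\n'
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{fmt(width)}" '
        f'height="{fmt(height)}" viewBox="0 0 {fmt(width)} {fmt(height)}">'
    )
    return head + "\n" + "\n".join(body) + "\n</svg>\n"


def _write(text: str, path) -> str:
    if path is not None:
        Path(path).write_text(text)
    return text


def render_matrix(
    aplus: CoClusterMatrix,
    ordering: Ordering,
    cores: Optional[Sequence] = None,
    base_mask: Optional[BaseMask] = None,
    spec: RenderSpec = RenderSpec(),
    path=None,
) -> str:
    """Heatmap of A⁺ in reordered coordinates with optional overlays.

    Non-zero cells are drawn as rects colored by value; under a base mask,
    non-kept non-zero cells turn gray.  Cores are outlined in green; a
    cohesion-annotated core gets a centered blue overlay square of side
    core_side × cohesion/(1+cohesion).
    """
    c = spec.cell
    n = aplus.n
    size = n * c
    pos = np.asarray(ordering.positions)
    body = []
    bg = "#000000" if spec.black_background else "#ffffff"
    body.append(
        f'<rect class="background" x="0" y="0" width="{fmt(size)}" '
        f'height="{fmt(size)}" fill="{bg}"/>'
    )
    iu, ju = np.nonzero(aplus.values)
    for i, j in zip(iu.tolist(), ju.tolist()):
        v = int(aplus.values[i, j])
        x, y = int(pos[j]) * c, int(pos[i]) * c
        if base_mask is not None and (min(i, j), max(i, j)) not in base_mask.keep:
            fill, cls = "#9e9e9e", "cell masked"
        else:
            fill, cls = _value_color(v, aplus.k, spec), "cell"
        body.append(
            f'<rect class="{cls}" x="{fmt(x)}" y="{fmt(y)}" width="{fmt(c)}" '
            f'height="{fmt(c)}" fill="{fill}"/>'
        )
    for core in cores or []:
        x = (core.p - 1) * c
        side = core.size * c
        body.append(
            f'<rect class="core" x="{fmt(x)}" y="{fmt(x)}" width="{fmt(side)}" '
            f'height="{fmt(side)}" fill="none" stroke="#2e8b57" stroke-width="1.5"/>'
        )
        if core.cohesion is not None:
            frac = 1.0 if core.cohesion == float("inf") else core.cohesion / (
                1.0 + core.cohesion
            )
            o_side = side * frac
            off = x + (side - o_side) / 2.0
            body.append(
                f'<rect class="cohesion" x="{fmt(off)}" y="{fmt(off)}" '
                f'width="{fmt(o_side)}" height="{fmt(o_side)}" '
                f'fill="#1f77b4" fill-opacity="0.45"/>'
            )
    return _write(_svg(size, size, body), path)


def render_parallel_partitions(
    layout: BandLayout,
    highlight: Optional[frozenset] = None,
    has_overlap: Optional[dict] = None,
    spec: RenderSpec = RenderSpec(),
    path=None,
) -> str:
    """Parallel-partitions plot: bands of module blocks joined by ribbons.

    One semi-transparent ribbon connects each item shared by two vertically
    adjacent bands (first occurrence when an item is duplicated across
    overlapping modules); highlighted items are traced in red on top.
    Bands whose clustering has overlapping modules get a striped fill,
    the grab bag is gray.
    """
    c = spec.cell
    band_h = 6 * c
    gap_h = 10 * c
    highlight = highlight or frozenset()
    has_overlap = has_overlap or {}
    width = max(b.width for b in layout.bands) * c
    height = len(layout.bands) * (band_h + gap_h) - gap_h
    body = ['<defs><pattern id="stripe" width="6" height="6" '
            'patternUnits="userSpaceOnUse" patternTransform="rotate(45)">'
            '<rect width="6" height="6" fill="#ffffff"/>'
            '<rect width="3" height="6" fill="#00000033"/></pattern></defs>']
    ys = {}
    for b_idx, band in enumerate(layout.bands):
        y = b_idx * (band_h + gap_h)
        ys[b_idx] = y
        hue = spec.hues.get(band.name, "#888888")
        for pm in band.modules:
            x = pm.start * c
            w = pm.width * c
            fill = "#bdbdbd" if pm.is_grab_bag else hue
            body.append(
                f'<rect class="module" x="{fmt(x)}" y="{fmt(y)}" width="{fmt(w)}" '
                f'height="{fmt(band_h)}" fill="{fill}"/>'
            )
            if not pm.is_grab_bag and has_overlap.get(band.name, False):
                body.append(
                    f'<rect class="module-stripes" x="{fmt(x)}" y="{fmt(y)}" '
                    f'width="{fmt(w)}" height="{fmt(band_h)}" fill="url(#stripe)"/>'
                )
    ribbons, traces = [], []
    for b_idx in range(len(layout.bands) - 1):
        top, bot = layout.bands[b_idx], layout.bands[b_idx + 1]

        def first_positions(band):
            seen = {}
            for pm in band.modules:
                for off, item in enumerate(pm.items):
                    seen.setdefault(item, pm.start + off)
            return seen

        pos_top, pos_bot = first_positions(top), first_positions(bot)
        y0 = ys[b_idx] + band_h
        y1 = ys[b_idx + 1]
        for item in sorted(set(pos_top) & set(pos_bot)):
            x0 = pos_top[item] * c
            x1 = pos_bot[item] * c
            pts = (
                f"{fmt(x0)},{fmt(y0)} {fmt(x0 + c)},{fmt(y0)} "
                f"{fmt(x1 + c)},{fmt(y1)} {fmt(x1)},{fmt(y1)}"
            )
            if item in highlight:
                traces.append(
                    f'<polygon class="ribbon highlight" points="{pts}" '
                    f'fill="#d62728" fill-opacity="0.85"/>'
                )
            else:
                ribbons.append(
                    f'<polygon class="ribbon" points="{pts}" '
                    f'fill="#777777" fill-opacity="0.25"/>'
                )
    body.extend(ribbons)
    body.extend(traces)  # red traces on top
    return _write(_svg(width, height, body), path)


def render_overview(stats: Sequence, spec: RenderSpec = RenderSpec(), path=None) -> str:
    """One bar chart per overview statistic; striped bars mark overlap."""
    charts = (
        ("n_modules", lambda s: s.n_modules),
        ("avg_module_size", lambda s: s.avg_module_size),
        ("n_items", lambda s: s.n_items_clustered),
        ("entropy_bits", lambda s: s.entropy),
        ("pct_overlapping", lambda s: s.pct_overlapping),
    )
    bar_w, bar_max_h, pad = 18, 80, 30
    chart_w = pad + len(stats) * (bar_w + 4)
    body = ['<defs><pattern id="stripe" width="6" height="6" '
            'patternUnits="userSpaceOnUse" patternTransform="rotate(45)">'
            '<rect width="6" height="6" fill="#ffffff"/>'
            '<rect width="3" height="6" fill="#00000033"/></pattern></defs>']
    for c_idx, (title, get) in enumerate(charts):
        y_base = (c_idx + 1) * (bar_max_h + pad)
        vals = [get(s) for s in stats]
        top = max(max(vals), 1e-12)
        body.append(
            f'<text class="title" x="4" y="{fmt(y_base - bar_max_h - 6)}" '
            f'font-size="10">{title}</text>'
        )
        for s_idx, s in enumerate(stats):
            h = bar_max_h * (vals[s_idx] / top)
            x = pad + s_idx * (bar_w + 4)
            hue = spec.hues.get(s.name, "#888888")
            body.append(
                f'<rect class="bar" x="{fmt(x)}" y="{fmt(y_base - h)}" '
                f'width="{fmt(bar_w)}" height="{fmt(h)}" fill="{hue}"/>'
            )
            if s.has_overlap:
                body.append(
                    f'<rect class="bar-stripes" x="{fmt(x)}" y="{fmt(y_base - h)}" '
                    f'width="{fmt(bar_w)}" height="{fmt(h)}" fill="url(#stripe)"/>'
                )
    return _write(_svg(chart_w, len(charts) * (bar_max_h + pad) + pad, body), path)


def render_ladder(ladder: Ladder, spec: RenderSpec = RenderSpec(), path=None) -> str:
    """Lower-triangular blue heatmap; darker always means more similar.

    Distance metrics (Mirkin, VI) are inverted before coloring so the
    darker-is-more-similar convention holds for every metric.
    """
    k = len(ladder.names)
    cell = 16
    vals = {}
    for i in range(k):
        for j in range(i):
            vals[(i, j)] = ladder.cell(i, j)
    vmax = max(list(vals.values()) + [1e-12])
    body = []
    for (i, j), v in sorted(vals.items()):
        frac = v / vmax if vmax > 0 else 0.0
        if ladder.metric in DISTANCE_METRICS:
            frac = 1.0 - frac
        rgb = tuple(round(255 + frac * (c - 255)) for c in (8, 48, 107))
        body.append(
            f'<rect class="lcell" x="{fmt(j * cell)}" y="{fmt(i * cell)}" '
            f'width="{fmt(cell)}" height="{fmt(cell)}" '
            f'fill="#{rgb[0]:02x}{rgb[1]:02x}{rgb[2]:02x}"/>'
        )
    return _write(_svg(k * cell, k * cell, body), path)
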