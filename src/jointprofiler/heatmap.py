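"""Self-contained HTML heatmaps of joint-feature abundances.

Cell colours interpolate linearly between a low anchor (default red,
lowest abundance) and a high anchor (default green, highest) after an
optional log1p transform; abundance matrices are right-skewed, so log1p
is the default.
"""

from __future__ import annotations

import html
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from ._version import __version__
from .tables import FeatureTable, format_key

__all__ = ["HeatmapSpec", "render_heatmap"]

COLOR_LOW = (0xD7, 0x30, 0x27)  # red
COLOR_HIGH = (0x1A, 0x98, 0x50)  # green


@dataclass
class HeatmapSpec:
    table: FeatureTable
    sample_order: Sequence[str] | None = None
    color_low: tuple[int, int, int] = COLOR_LOW
    color_high: tuple[int, int, int] = COLOR_HIGH
    transform: Literal["linear", "log1p"] = "log1p"
    title: str = "Joint feature heatmap"


def _interpolate(t: float, low: tuple[int, int, int], high: tuple[int, int, int]) -> str:
    rgb = tuple(round(lo + t * (hi - lo)) for lo, hi in zip(low, high))
    return "#{:02x}{:02x}{:02x}".format(*rgb)


def render_heatmap(spec: HeatmapSpec) -> str:
    """Render the table as a self-contained HTML heatmap string.

    One <td class="cell"> per (feature, sample), background colour set
    inline from the interpolation parameter (v - min) / (max - min) of
    the transformed values; a degenerate all-equal table maps every cell
    to the midpoint colour.
    """
    if not spec.color_low or not spec.color_high:
        raise ValueError("colour anchors must be non-empty RGB triples")
    table = spec.table
    samples = list(spec.sample_order) if spec.sample_order is not None else table.sample_ids
    unknown = [s for s in samples if s not in table.sample_ids]
    if unknown:
        raise ValueError(f"sample_order references unknown samples: {unknown}")
    sub = table.subset(samples=samples) if samples else table
    values = sub.values
    trans = np.log1p(values) if spec.transform == "log1p" else values.astype(float)
    if trans.size:
        vmin, vmax = float(trans.min()), float(trans.max())
    else:
        vmin = vmax = 0.0
    span = vmax - vmin

    rows_html: list[str] = []
    for (taxon, gene), raw_row, t_row in zip(sub.feature_keys, values, trans):
        cells = []
        for value, tval in zip(raw_row, t_row):
            t = 0.5 if span == 0 else (tval - vmin) / span
            color = _interpolate(t, spec.color_low, spec.color_high)
            cells.append(
                f'<td class="cell" style="background-color:{color}" '
                f'title="{value:.6g}">{value:.3g}</td>'
            )
        label = html.escape(format_key(taxon, gene))
        rows_html.append(f'<tr><th class="feature">{label}</th>' + "".join(cells) + "</tr>")

    header = "".join(f'<th class="sample">{html.escape(s)}</th>' for s in samples)
    return (
        "<!DOCTYPE html>\n"
        f"<!-- jointprofiler {__version__} -->\n"
        "<html><head><meta charset=\"utf-8\"/>"
        f"<title>{html.escape(spec.title)}</title>"
        "<style>"
        "table{border-collapse:collapse;font-family:sans-serif;font-size:12px}"
        "td.cell{padding:4px 8px;text-align:right;color:#000}"
        "th{padding:4px 8px;text-align:left}"
        "</style></head><body>"
        f"<h1>{html.escape(spec.title)}</h1>"
        "<table><thead><tr><th></th>" + header + "</tr></thead><tbody>"
        + "".join(rows_html)
        + "</tbody></table></body></html>"
    )
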