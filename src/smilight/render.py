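"""SVG panel and HTML gallery rendering.

One panel per molecule, three stacked components: the molecule diagram drawn
over per-atom heatmap layers (one layer for positive, one for negative
scores), a bar chart with one bar per SMILES token, and an optional
attributes table.  Colors of the heatmap marks equal the bar colors of the
corresponding atom tokens.

Everything is emitted as plain strings with fixed float formatting, so a
panel renders to byte-identical SVG for identical inputs.  Hover behaviour
(token <-> substructure highlighting) is embedded as a precomputed JSON map
plus hidden overlay rings; a short generated script in the HTML gallery only
toggles classes — it makes no structural decisions at runtime.
"""

from __future__ import annotations

import json
import statistics
from dataclasses import dataclass
from typing import Mapping, Sequence
from xml.sax.saxutils import escape

from rdkit import Chem
from rdkit.Chem.Draw import rdMolDraw2D

from .scoring import (
    ScoredTokens,
    VisualConfig,
    default_domain,
    guide_fractions,
    normalize,
    score_to_color,
    threshold_cutoffs,
)
from .structure import AtomLayout, export_hover_map, layout_and_tokens
from .tokenizer import TokenKind

__all__ = [
    "Panel",
    "render_bar_chart",
    "render_molecule_panel",
    "render_attribute_table",
    "compose_panel",
    "render_gallery",
]

#: stroke used for the outer hover ring; contrasts with both palette ends
HIGHLIGHT_COLOR = "#ffcc00"
MARGIN = 10


def _f(x: float) -> str:
    """Fixed two-decimal float formatting (deterministic output)."""
    return f"{x:.2f}"


@dataclass(frozen=True)
class Panel:
    """A fully rendered molecule panel: geometry, SVG text, hover map."""

    width: float
    height: float
    svg: str
    hover_map: dict


def _resolved_domain(scores: ScoredTokens, config: VisualConfig):
    return config.domain if config.domain is not None else default_domain(scores)


# ---------------------------------------------------------------------------
# bar chart


def bar_chart_size(scores: ScoredTokens, config: VisualConfig) -> tuple[float, float]:
    n = len(scores.seq.tokens)
    width = max(n * (config.bar_width + config.bar_gap) - config.bar_gap, 1)
    height = config.bar_chart_height + 2 * config.font_size + 6
    return float(width), float(height)


def render_bar_chart(
    scores: ScoredTokens, config: VisualConfig, panel_id: str = "p0"
) -> str:
    """Bar-chart group: one bar per token, in token order.

    Bar height is ``|normalized score| * chart height`` and bar fill is the
    score's palette color; the token text sits beneath its bar with a "-"
    marker under negative-score bars.  Horizontal guide lines mark the
    threshold fractions (or 0.5 and 1.0 when no thresholds are set), so with
    a deliberately tiny domain every nonzero bar saturates to full height
    and the chart shows sign only.
    """
    domain = _resolved_domain(scores, config)
    H = float(config.bar_chart_height)
    bw, gap, fs = config.bar_width, config.bar_gap, config.font_size
    width, _ = bar_chart_size(scores, config)
    parts = [f'<g class="bar-chart" id="{panel_id}-bars">']
    for frac in guide_fractions(config.thresholds):
        y = _f(H * (1.0 - frac))
        parts.append(
            f'<line class="guide" x1="0" y1="{y}" x2="{_f(width)}" y2="{y}" '
            f'stroke="#999999" stroke-dasharray="3,3" stroke-width="0.75"/>'
        )
    for i, (tok, s) in enumerate(zip(scores.seq.tokens, scores.scores)):
        x = i * (bw + gap)
        t = normalize(s, domain)
        h = abs(t) * H
        fill = score_to_color(s, domain, config.palette)
        cx = _f(x + bw / 2)
        parts.append(f'<g class="tok" id="{panel_id}-tok-{i}">')
        parts.append(
            f'<rect x="{_f(x)}" y="{_f(H - h)}" width="{_f(bw)}" '
            f'height="{_f(h)}" fill="{fill}"/>'
        )
        parts.append(
            f'<text class="tok-label" x="{cx}" y="{_f(H + fs)}" '
            f'font-size="{fs - 2}" text-anchor="middle" '
            f'font-family="monospace">{escape(tok.text)}</text>'
        )
        if s < 0:
            parts.append(
                f'<text class="neg-sign" x="{cx}" y="{_f(H + 2 * fs)}" '
                f'font-size="{fs - 2}" text-anchor="middle" '
                f'font-family="monospace">&#8722;</text>'
            )
        parts.append("</g>")
    parts.append("</g>")
    return "\n".join(parts)


# ---------------------------------------------------------------------------
# molecule panel


def _draw_structure(
    layout: AtomLayout, config: VisualConfig
) -> tuple[str, list[tuple[float, float]]]:
    """RDKit structure drawing (inner SVG) and per-atom pixel coordinates."""
    mol = Chem.Mol(layout.mol)
    drawer = rdMolDraw2D.MolDraw2DSVG(config.mol_width, config.mol_height)
    opts = drawer.drawOptions()
    opts.clearBackground = False
    if config.black_atoms:
        opts.useBWAtomPalette()
    drawer.DrawMolecule(mol)
    drawer.FinishDrawing()
    svg = drawer.GetDrawingText()
    body = svg.split("<!-- END OF HEADER -->", 1)[1]
    body = body.rsplit("</svg>", 1)[0].strip()
    pts = [drawer.GetDrawCoords(i) for i in range(layout.n_atoms)]
    return body, [(p.x, p.y) for p in pts]


def _median_bond_px(layout: AtomLayout, pts: Sequence[tuple[float, float]]) -> float:
    if not layout.bonds:
        return 40.0  # single atoms / disconnected dots: a typical bond length
    lengths = [
        ((pts[a][0] - pts[b][0]) ** 2 + (pts[a][1] - pts[b][1]) ** 2) ** 0.5
        for a, b in layout.bonds
    ]
    return statistics.median(lengths)


def render_molecule_panel(
    layout: AtomLayout,
    scores: ScoredTokens,
    config: VisualConfig,
    panel_id: str = "p0",
) -> str:
    """Molecule-diagram group: heatmap layers, threshold rings, structure.

    Document order is negative heatmap, positive heatmap, threshold circles,
    then the skeletal structure — color fields sit beneath the bond lines so
    the drawing stays legible.  Each atom's heatmap mark is a radial
    gradient whose color equals the atom's bar color and whose opacity is
    proportional to the normalized score magnitude; atoms whose |score|
    meets a threshold cutoff get a white-stroked circle growing with the
    distance above the threshold.  Hidden two-ring hover overlays are
    emitted last for the gallery script to toggle.
    """
    domain = _resolved_domain(scores, config)
    inner, pts = _draw_structure(layout, config)
    bond_px = _median_bond_px(layout, pts)
    radius = 0.9 * bond_px
    atom_scores = scores.atom_scores()
    norms = [normalize(s, domain) for s in atom_scores]
    colors = [score_to_color(s, domain, config.palette) for s in atom_scores]

    defs, neg, pos = [], [], []
    for a, (s, t, col) in enumerate(zip(atom_scores, norms, colors)):
        if t == 0.0:
            continue
        alpha = 0.75 * abs(t)
        gid = f"{panel_id}-hm-{a}"
        defs.append(
            f'<radialGradient id="{gid}">'
            f'<stop offset="0%" stop-color="{col}" stop-opacity="{_f(alpha)}"/>'
            f'<stop offset="100%" stop-color="{col}" stop-opacity="0"/>'
            f"</radialGradient>"
        )
        x, y = pts[a]
        mark = (
            f'<circle cx="{_f(x)}" cy="{_f(y)}" r="{_f(radius)}" '
            f'fill="url(#{gid})"/>'
        )
        (neg if s < 0 else pos).append(mark)

    rings = []
    fractions = config.thresholds
    cutoffs = threshold_cutoffs(fractions, domain)
    for frac, cut in zip(fractions, cutoffs):
        for a, s in enumerate(atom_scores):
            if abs(s) >= cut:
                r = config.font_size + bond_px * (abs(norms[a]) - frac)
                x, y = pts[a]
                rings.append(
                    f'<circle class="thr" cx="{_f(x)}" cy="{_f(y)}" '
                    f'r="{_f(r)}" fill="none" stroke="#ffffff" '
                    f'stroke-width="2"/>'
                )

    labels = []
    if config.show_score_labels:
        off = 0.35 * bond_px
        for a, ((x, y), s) in enumerate(zip(pts, atom_scores)):
            labels.append(
                f'<text class="score-label" x="{_f(x + off)}" '
                f'y="{_f(y - off)}" font-size="{config.font_size - 3}" '
                f'font-family="sans-serif" fill="#444444">{s:.2f}</text>'
            )

    overlay = []
    for a, (x, y) in enumerate(pts):
        sign_color = colors[a] if norms[a] != 0 else "#888888"
        r0 = config.font_size * 0.9
        overlay.append(
            f'<g class="atomhl" id="{panel_id}-atom-{a}">'
            f'<circle cx="{_f(x)}" cy="{_f(y)}" r="{_f(r0)}" fill="none" '
            f'stroke="{sign_color}" stroke-width="2.5"/>'
            f'<circle cx="{_f(x)}" cy="{_f(y)}" r="{_f(r0 + 3)}" fill="none" '
            f'stroke="{HIGHLIGHT_COLOR}" stroke-width="2"/>'
            f'<circle class="hit" cx="{_f(x)}" cy="{_f(y)}" r="{_f(r0)}" '
            f'fill="#000000" fill-opacity="0" stroke="none"/>'
            f"</g>"
        )

    parts = [f'<g class="molecule" id="{panel_id}-mol">']
    if defs:
        parts.append("<defs>" + "".join(defs) + "</defs>")
    parts.append(f'<g class="heatmap-neg">{"".join(neg)}</g>')
    parts.append(f'<g class="heatmap-pos">{"".join(pos)}</g>')
    parts.append(f'<g class="thresholds">{"".join(rings)}</g>')
    parts.append(f'<g class="structure">{inner}</g>')
    parts.append(f'<g class="score-labels">{"".join(labels)}</g>')
    parts.append(f'<g class="hover-overlay">{"".join(overlay)}</g>')
    parts.append("</g>")
    return "\n".join(parts)


# ---------------------------------------------------------------------------
# attributes table


def render_attribute_table(
    attributes: Mapping[str, str], config: VisualConfig | None = None
) -> str:
    """Attribute rows (key: value), one per entry in insertion order; an
    empty mapping yields an empty string (the table is optional)."""
    if not attributes:
        return ""
    config = config or VisualConfig()
    fs = config.font_size
    rh = config.table_row_height
    parts = ['<g class="attributes">']
    for i, (key, value) in enumerate(attributes.items()):
        y = _f((i + 1) * rh)
        parts.append(
            f'<text x="0" y="{y}" font-size="{fs - 2}" font-family="sans-serif">'
            f"<tspan font-weight=\"bold\">{escape(str(key))}:</tspan> "
            f"{escape(str(value))}</text>"
        )
    parts.append("</g>")
    return "\n".join(parts)


# ---------------------------------------------------------------------------
# panel composition


def _hover_map_json(seq, layout) -> dict:
    hm = export_hover_map(seq, layout)
    tokens = {
        str(i): {
            "kind": hs.kind.value,
            "tokens": sorted(hs.token_indices),
            "atoms": sorted(hs.atom_indices),
        }
        for i, hs in hm["tokens"].items()
    }
    atoms = {str(a): i for a, i in hm["atoms"].items()}
    return {
        "tokens": tokens,
        "atoms": atoms,
        "highlight_color": HIGHLIGHT_COLOR,
    }


def compose_panel(record, config: VisualConfig | None = None, panel_id: str = "p0") -> Panel:
    """Render one molecule record to a complete standalone SVG document.

    The document stacks molecule diagram, bar chart and attributes table and
    embeds the precomputed hover map in a ``<metadata>`` element.  Output is
    byte-identical for identical (record, config).  Parse and score-shape
    errors are re-raised with the record's id prefixed.
    """
    from .scoring import attach_scores

    config = config or VisualConfig()
    if record.config_override:
        config = config.with_overrides(**record.config_override)
    try:
        seq, layout = layout_and_tokens(record.smiles)
        scored = attach_scores(seq, record.scores)
    except ValueError as exc:
        raise type(exc)(f"record {record.id!r}: {exc}") from exc

    hover_map = _hover_map_json(seq, layout)

    mol_g = render_molecule_panel(layout, scored, config, panel_id)
    bar_g = render_bar_chart(scored, config, panel_id)
    bw, bh = bar_chart_size(scored, config)
    table_g = render_attribute_table(record.attributes, config)
    th = (len(record.attributes) + 0.5) * config.table_row_height if record.attributes else 0.0

    width = max(config.mol_width, bw) + 2 * MARGIN
    height = config.mol_height + bh + th + 4 * MARGIN
    meta = escape(
        json.dumps(hover_map, sort_keys=True, separators=(",", ":"))
    )
    style = (
        f"#{panel_id} .atomhl circle{{visibility:hidden}}"
        f"#{panel_id} .atomhl circle.hit{{visibility:visible;pointer-events:all}}"
        f"#{panel_id} .atomhl.hl circle{{visibility:visible}}"
        f"#{panel_id} .tok.hl text{{font-weight:bold}}"
        f"#{panel_id} .tok.hl rect{{stroke:{HIGHLIGHT_COLOR};stroke-width:2}}"
    )
    doc = "\n".join(
        [
            f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
            f'id="{panel_id}" data-panel="{panel_id}" '
            f'width="{_f(width)}" height="{_f(height)}" '
            f'viewBox="0 0 {_f(width)} {_f(height)}">',
            f'<metadata id="{panel_id}-hovermap" data-role="hover-map">{meta}</metadata>',
            f"<style>{style}</style>",
            f'<g transform="translate({MARGIN},{MARGIN})">{mol_g}</g>',
            f'<g transform="translate({MARGIN},{_f(config.mol_height + 2 * MARGIN)})">{bar_g}</g>',
            (
                f'<g transform="translate({MARGIN},'
                f'{_f(config.mol_height + bh + 3 * MARGIN)})">{table_g}</g>'
                if table_g
                else ""
            ),
            "</svg>",
        ]
    )
    return Panel(width, height, doc, hover_map)


# ---------------------------------------------------------------------------
# gallery

_GALLERY_SCRIPT = """
function smilightBind(svg) {
  var meta = svg.querySelector('metadata[data-role="hover-map"]');
  if (!meta) return;
  var map = JSON.parse(meta.textContent);
  var pid = svg.getAttribute('data-panel');
  function setHl(tokens, atoms, on) {
    tokens.forEach(function (i) {
      var el = svg.getElementById(pid + '-tok-' + i);
      if (el) el.classList.toggle('hl', on);
    });
    atoms.forEach(function (a) {
      var el = svg.getElementById(pid + '-atom-' + a);
      if (el) el.classList.toggle('hl', on);
    });
  }
  Object.keys(map.tokens).forEach(function (i) {
    var el = svg.getElementById(pid + '-tok-' + i);
    if (!el) return;
    var hs = map.tokens[i];
    el.addEventListener('mouseenter', function () { setHl(hs.tokens, hs.atoms, true); });
    el.addEventListener('mouseleave', function () { setHl(hs.tokens, hs.atoms, false); });
  });
  Object.keys(map.atoms).forEach(function (a) {
    var el = svg.getElementById(pid + '-atom-' + a);
    if (!el) return;
    var tok = map.atoms[a];
    el.addEventListener('mouseenter', function () { setHl([tok], [Number(a)], true); });
    el.addEventListener('mouseleave', function () { setHl([tok], [Number(a)], false); });
  });
}
document.querySelectorAll('svg[data-panel]').forEach(smilightBind);
"""


def render_gallery(records: Sequence, config: VisualConfig | None = None) -> str:
    """Self-contained HTML gallery: one panel per record, side by side.

    All highlight decisions come from the per-panel hover maps computed at
    render time; the embedded script only toggles CSS classes.  The document
    references no external resources.
    """
    if not records:
        raise ValueError("gallery requires at least one record")
    config = config or VisualConfig()
    panels = [
        compose_panel(rec, config, panel_id=f"m{i}")
        for i, rec in enumerate(records)
    ]
    body = "\n".join(
        f'<div class="panel"><div class="panel-title">{escape(str(rec.id))}</div>'
        f"{panel.svg}</div>"
        for rec, panel in zip(records, panels)
    )
    return (
        "<!DOCTYPE html>\n<html><head><meta charset='utf-8'>"
        "<title>SMILES attribution gallery</title>"
        "<style>body{font-family:sans-serif;background:#fafafa}"
        ".panel{display:inline-block;vertical-align:top;margin:8px;"
        "padding:6px;background:#ffffff;border:1px solid #dddddd}"
        ".panel-title{font-size:12px;color:#555555;margin-bottom:4px}"
        "</style></head><body>\n"
        + body
        + f"\n<script>{_GALLERY_SCRIPT}</script></body></html>\n"
    )
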