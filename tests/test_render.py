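"""Rendering: panel structure, coordination invariants, determinism."""

import json
import xml.etree.ElementTree as ET

import pytest

from smilight.records import MoleculeRecord
from smilight.render import (
    compose_panel,
    render_attribute_table,
    render_bar_chart,
    render_gallery,
    render_molecule_panel,
)
from smilight.scoring import VisualConfig, attach_scores
from smilight.structure import layout_and_tokens

SVG_NS = "{http://www.w3.org/2000/svg}"


def _record(smiles="C1CC1", scores=(0.1, -0.2, 0.3), **kw):
    return MoleculeRecord(smiles=smiles, scores=list(scores), id="r0", **kw)


def _parse_group(xml_text):
    return ET.fromstring(f'<svg xmlns="http://www.w3.org/2000/svg">{xml_text}</svg>')


# ---------------------------------------------------------------------------
# bar chart


def test_one_bar_per_token_in_order():
    seq, _ = layout_and_tokens("C1CC1")
    scored = attach_scores(seq, [0.1, 0.2, 0.3])
    root = _parse_group(render_bar_chart(scored, VisualConfig()))
    groups = root.findall(f".//{SVG_NS}g[@class='tok']")
    assert len(groups) == 5
    labels = [g.find(f"{SVG_NS}text").text for g in groups]
    assert labels == ["C", "1", "C", "C", "1"]
    assert all(g.find(f"{SVG_NS}rect") is not None for g in groups)


def test_full_height_at_domain_max():
    cfg = VisualConfig(bar_chart_height=100)
    seq, _ = layout_and_tokens("CCO")
    scored = attach_scores(seq, [0.5, 0.5, -0.5])
    root = _parse_group(render_bar_chart(scored, cfg))
    heights = [
        float(r.get("height"))
        for r in root.findall(f".//{SVG_NS}g[@class='tok']/{SVG_NS}rect")
    ]
    assert heights == [100.0, 100.0, 100.0]


def test_sign_only_mode_saturates_all_bars():
    # a tiny user-set domain turns the chart into a sign display
    cfg = VisualConfig(domain=(-1e-9, 1e-9), bar_chart_height=100)
    seq, _ = layout_and_tokens("CCO")
    scored = attach_scores(seq, [0.01, -0.2, 3.0])
    root = _parse_group(render_bar_chart(scored, cfg))
    heights = [
        float(r.get("height"))
        for r in root.findall(f".//{SVG_NS}g[@class='tok']/{SVG_NS}rect")
    ]
    assert heights == [100.0, 100.0, 100.0]


def test_negative_sign_markers():
    seq, _ = layout_and_tokens("CCO")
    scored = attach_scores(seq, [0.3, -0.3, 0.0])
    svg = render_bar_chart(scored, VisualConfig())
    root = _parse_group(svg)
    signs = root.findall(f".//{SVG_NS}text[@class='neg-sign']")
    assert len(signs) == 1
    # the marker sits under bar 1, not bar 0
    groups = root.findall(f".//{SVG_NS}g[@class='tok']")
    assert groups[1].find(f"{SVG_NS}text[@class='neg-sign']") is not None
    assert groups[0].find(f"{SVG_NS}text[@class='neg-sign']") is None


def test_default_guide_lines_at_half_and_full():
    cfg = VisualConfig(bar_chart_height=100)
    seq, _ = layout_and_tokens("CCO")
    scored = attach_scores(seq, [0.3, -0.3, 0.0])
    root = _parse_group(render_bar_chart(scored, cfg))
    ys = sorted(
        float(l.get("y1")) for l in root.findall(f".//{SVG_NS}line[@class='guide']")
    )
    assert ys == [0.0, 50.0]  # fractions 1.0 and 0.5 of the 100-unit chart


def test_threshold_guide_lines_follow_thresholds():
    cfg = VisualConfig(bar_chart_height=100, thresholds=(0.25,))
    seq, _ = layout_and_tokens("CCO")
    scored = attach_scores(seq, [0.3, -0.3, 0.0])
    root = _parse_group(render_bar_chart(scored, cfg))
    ys = [float(l.get("y1")) for l in root.findall(f".//{SVG_NS}line[@class='guide']")]
    assert ys == [75.0]


# ---------------------------------------------------------------------------
# molecule panel


def test_all_zero_scores_empty_heatmaps():
    seq, layout = layout_and_tokens("CCO")
    scored = attach_scores(seq, [0.0, 0.0, 0.0])
    root = _parse_group(render_molecule_panel(layout, scored, VisualConfig()))
    for cls in ("heatmap-neg", "heatmap-pos"):
        (group,) = root.findall(f".//{SVG_NS}g[@class='{cls}']")
        assert len(list(group)) == 0


def test_heatmap_marks_split_by_sign():
    seq, layout = layout_and_tokens("CCO")
    scored = attach_scores(seq, [0.5, -0.5, 0.0])
    root = _parse_group(render_molecule_panel(layout, scored, VisualConfig()))
    (neg,) = root.findall(f".//{SVG_NS}g[@class='heatmap-neg']")
    (pos,) = root.findall(f".//{SVG_NS}g[@class='heatmap-pos']")
    assert len(neg.findall(f"{SVG_NS}circle")) == 1
    assert len(pos.findall(f"{SVG_NS}circle")) == 1


def test_single_threshold_circle():
    seq, layout = layout_and_tokens("CCO")
    scored = attach_scores(seq, [1.0, 0.1, 0.0])
    cfg = VisualConfig(domain=(-1, 1), thresholds=(0.75,))
    root = _parse_group(render_molecule_panel(layout, scored, cfg))
    (thr,) = root.findall(f".//{SVG_NS}g[@class='thresholds']")
    assert len(thr.findall(f"{SVG_NS}circle")) == 1


def test_labels_without_thresholds():
    seq, layout = layout_and_tokens("CCO")
    scored = attach_scores(seq, [0.5, -0.25, 0.0])
    cfg = VisualConfig(show_score_labels=True)
    svg = render_molecule_panel(layout, scored, cfg)
    root = _parse_group(svg)
    (thr,) = root.findall(f".//{SVG_NS}g[@class='thresholds']")
    assert len(list(thr)) == 0  # no circles
    assert "0.50" in svg and "-0.25" in svg  # numeric labels, 2 decimals


def test_heatmap_precedes_structure():
    seq, layout = layout_and_tokens("CCO")
    scored = attach_scores(seq, [0.5, -0.5, 0.0])
    svg = render_molecule_panel(layout, scored, VisualConfig())
    assert svg.index('class="heatmap-neg"') < svg.index('class="structure"')
    assert svg.index('class="heatmap-pos"') < svg.index('class="structure"')


def test_bar_and_heatmap_colors_agree():
    """The fill of an atom token's bar equals its heatmap mark color."""
    seq, layout = layout_and_tokens("C1CC1")
    scored = attach_scores(seq, [0.6, -0.3, 0.2])
    cfg = VisualConfig()
    bars = _parse_group(render_bar_chart(scored, cfg))
    mol = render_molecule_panel(layout, scored, cfg)
    groups = bars.findall(f".//{SVG_NS}g[@class='tok']")
    for tok, group in zip(scored.seq.tokens, groups):
        if tok.atom_index is None:
            continue
        bar_fill = group.find(f"{SVG_NS}rect").get("fill")
        assert f'stop-color="{bar_fill}"' in mol


# ---------------------------------------------------------------------------
# attributes table


def test_attribute_table_rows():
    svg = render_attribute_table({"method": "CDDD-Substitution", "pred": "3.2"})
    root = _parse_group(svg)
    texts = root.findall(f".//{SVG_NS}text")
    assert len(texts) == 2
    assert render_attribute_table({}) == ""


def test_attribute_table_preserves_order():
    attrs = {"d": "4", "a": "1", "c": "3", "b": "2"}
    root = _parse_group(render_attribute_table(attrs))
    keys = [t.find(f"{SVG_NS}tspan").text.rstrip(":") for t in
            root.findall(f".//{SVG_NS}text")]
    assert keys == ["d", "a", "c", "b"]


# ---------------------------------------------------------------------------
# composed panel and gallery


def test_panel_is_wellformed_and_deterministic():
    rec = _record()
    p1 = compose_panel(rec)
    p2 = compose_panel(rec)
    ET.fromstring(p1.svg)
    assert p1.svg == p2.svg


def test_panel_bar_count_for_per_atom_scores():
    rec = _record("C1CC1", [0.1, 0.2, 0.3])  # 3 atom scores, 5 tokens
    panel = compose_panel(rec)
    root = ET.fromstring(panel.svg)
    assert len(root.findall(f".//{SVG_NS}g[@class='tok']")) == 5


def test_panel_embeds_hover_map():
    panel = compose_panel(_record("CC(C)O", [0.1, 0.2, 0.3, 0.4]))
    root = ET.fromstring(panel.svg)
    (meta,) = root.findall(f".//{SVG_NS}metadata")
    hover = json.loads(meta.text)
    assert set(hover["tokens"]) == {str(i) for i in range(6)}
    assert hover["tokens"]["2"]["atoms"] == [2]  # "(" highlights the branch atom


def test_panel_error_names_record():
    rec = _record("C(", [0.1])
    with pytest.raises(ValueError, match="r0"):
        compose_panel(rec)


def test_gallery_contains_all_panels_in_order():
    recs = [
        MoleculeRecord(smiles="CCO", scores=[0.1, 0.2, 0.3], id=f"mol{i}")
        for i in range(3)
    ]
    html = render_gallery(recs)
    positions = [html.index(f'data-panel="m{i}"') for i in range(3)]
    assert positions == sorted(positions)
    assert "http://" not in html.replace("http://www.w3.org/", "")


def test_gallery_two_configs_same_hover_map():
    rec = _record("CC(C)O", [0.1, 0.2, 0.3, 0.4])
    p1 = compose_panel(rec, VisualConfig(palette="red_blue"))
    p2 = compose_panel(rec, VisualConfig(palette="purple_orange",
                                         thresholds=(0.5,)))
    assert p1.svg != p2.svg
    assert p1.hover_map == p2.hover_map


def test_gallery_empty_rejected():
    with pytest.raises(ValueError):
        render_gallery([])


def test_record_config_override_applies():
    rec = _record("CCO", [0.1, -0.2, 0.3],
                  config_override={"black_atoms": True})
    base = compose_panel(_record("CCO", [0.1, -0.2, 0.3]))
    over = compose_panel(rec)
    assert base.svg != over.svg
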