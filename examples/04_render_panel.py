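"""Render one molecule record to a standalone SVG panel.

The panel stacks the molecule diagram (over positive/negative heatmap
layers), the per-token bar chart and an attributes table, and embeds the
precomputed hover map.  Output goes to scratch/aspirin.svg.
"""

from pathlib import Path

from smilight import MoleculeRecord, VisualConfig, compose_panel, crippen_scores

smiles = "CC(=O)Oc1ccccc1C(=O)O"  # aspirin
scores = crippen_scores(smiles)
record = MoleculeRecord(
    smiles=smiles,
    scores=scores,
    attributes={"method": "Crippen logP contributions",
                "logP": f"{sum(scores):.3f}"},
    id="aspirin",
)
config = VisualConfig(thresholds=(0.5,), show_score_labels=True)
panel = compose_panel(record, config)

out = Path("scratch")
out.mkdir(exist_ok=True)
(out / "aspirin.svg").write_text(panel.svg)
print(f"wrote {out / 'aspirin.svg'} ({len(panel.svg)} bytes, "
      f"{panel.width:.0f}x{panel.height:.0f})")
print("per-atom logP contributions sum:", f"{sum(scores):.3f}")
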