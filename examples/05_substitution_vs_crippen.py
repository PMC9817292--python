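"""Compare substitution sensitivity scores against Crippen contributions.

The substitution method scores every token of the string (including
parentheses and ring digits) by occluding it against a vocabulary; the
Crippen contributions are an additive per-atom ground-truth-style
comparator.  Both are rendered side by side into an HTML gallery at
scratch/compare.html.
"""

from pathlib import Path

from smilight import (
    CrippenLogPPredictor,
    MoleculeRecord,
    VisualConfig,
    crippen_scores,
    render_gallery,
    substitution_attribution,
    tokenize,
)

smiles = "CC(C)Cc1ccc(cc1)C(C)C(=O)O"  # ibuprofen
predictor = CrippenLogPPredictor()

records = [
    MoleculeRecord(
        smiles=smiles,
        scores=crippen_scores(smiles),
        attributes={"method": "Crippen contributions"},
        id="crippen",
    ),
    MoleculeRecord(
        smiles=smiles,
        scores=substitution_attribution(predictor, smiles),
        attributes={"method": "substitution (toy logP predictor)",
                    "pred": f"{predictor(smiles):.3f}"},
        id="substitution",
    ),
]

html = render_gallery(records, VisualConfig(thresholds=(0.75,)))
out = Path("scratch")
out.mkdir(exist_ok=True)
(out / "compare.html").write_text(html)
print(f"wrote {out / 'compare.html'} ({len(html)} bytes)")

seq = tokenize(smiles)
subs = records[1].scores
top = sorted(zip(seq.texts, subs), key=lambda p: -abs(p[1]))[:5]
print("most sensitive tokens (token, score):")
for text, s in top:
    print(f"   {text:<4} {s:+.3f}")
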