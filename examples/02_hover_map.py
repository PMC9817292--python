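"""Resolve what each token of a SMILES highlights on the molecule diagram.

Hovering a parenthesis highlights the whole branch, a ring-closure digit
highlights its ring, and any token of a bracket group highlights the group's
atom.  Everything is precomputed as plain index sets.
"""

from smilight import resolve_hover, tokenize
from smilight.structure import layout_and_tokens

smiles = "CC(C)c1ccc(cc1)[N+](=O)[O-]"
seq, layout = layout_and_tokens(smiles)
for i, tok in enumerate(seq):
    hs = resolve_hover(seq, layout, i)
    atoms = sorted(hs.atom_indices)
    print(f"token {i:>2} {tok.text:<4} -> {hs.kind.value.lower():<6} "
          f"atoms {atoms}")
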