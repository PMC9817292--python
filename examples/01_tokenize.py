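"""Tokenize a SMILES string and show the atom/non-atom split.

The bracket group [N+] contributes one atom token (N) and three structural
tokens ([, +, ]) — structural tokens carry attribution scores of their own in
SMILES-based models but have no atom on the molecule diagram.
"""

from smilight import TokenKind, tokenize

for smiles in ("[N+]", "ClCBr", "CC(=O)Oc1ccccc1C(=O)O"):
    seq = tokenize(smiles)
    non_atom = sum(1 for t in seq if t.kind is not TokenKind.ATOM)
    print(f"{smiles!r}: {len(seq.tokens)} tokens = "
          f"{seq.n_atoms} atom + {non_atom} non-atom")
    for tok in seq:
        atom = f"atom {tok.atom_index}" if tok.atom_index is not None else ""
        print(f"   {tok.text:<4} {tok.kind.value:<13} {atom}")
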