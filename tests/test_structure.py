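"""Structure mapping: layout construction and hover-substructure semantics."""

import pytest
from rdkit import Chem

from smilight.structure import (
    HighlightKind,
    StructureError,
    build_atom_layout,
    MoleculeParseError,
    export_hover_map,
    layout_and_tokens,
    match_parens,
    resolve_atom_hover,
    resolve_hover,
    ring_partners,
)
from smilight.tokenizer import TokenKind, tokenize


# ---------------------------------------------------------------------------
# layout


def test_layout_basic():
    layout = build_atom_layout("CCO")
    assert layout.n_atoms == 3
    assert len(layout.coords) == 3
    assert sorted(map(sorted, layout.bonds)) == [[0, 1], [1, 2]]


def test_layout_single_atom():
    layout = build_atom_layout("C")
    assert layout.n_atoms == 1 and len(layout.coords) == 1


def test_layout_ring_perception():
    layout = build_atom_layout("C1CC1")
    assert layout.rings == [frozenset({0, 1, 2})]


def test_layout_atom_order_follows_string():
    # first atom in the string is node 0 of the graph
    layout = build_atom_layout("OC(=O)C")
    assert layout.mol.GetAtomWithIdx(0).GetSymbol() == "O"
    assert layout.mol.GetAtomWithIdx(3).GetSymbol() == "C"


def test_layout_keeps_explicit_hydrogens():
    seq, layout = layout_and_tokens("[2H]OC")
    assert layout.n_atoms == seq.n_atoms == 3


def test_layout_parse_error():
    with pytest.raises(MoleculeParseError):
        build_atom_layout("C(")


# ---------------------------------------------------------------------------
# hover semantics


def test_branch_hover():
    seq, layout = layout_and_tokens("CC(C)O")
    hs = resolve_hover(seq, layout, 2)  # "("
    assert hs.kind is HighlightKind.BRANCH
    assert hs.token_indices == frozenset({2, 3, 4})  # "(C)"
    assert hs.atom_indices == frozenset({2})


def test_branch_hover_includes_nested():
    seq, layout = layout_and_tokens("CC(C(F)F)O")
    open_idx = seq.texts.index("(")
    hs = resolve_hover(seq, layout, open_idx)
    # all atoms of the branch, nested branch included
    assert hs.atom_indices == frozenset({2, 3, 4})


def test_branch_symmetry(all_fixture_smiles):
    for smiles in all_fixture_smiles:
        seq, layout = layout_and_tokens(smiles)
        for i, tok in enumerate(seq.tokens):
            if tok.kind is TokenKind.BRANCH_OPEN:
                j = match_parens(seq)[i]
                assert resolve_hover(seq, layout, i) == resolve_hover(
                    seq, layout, j
                )


def test_ring_hover_cyclohexane():
    seq, layout = layout_and_tokens("C1CCCCC1")
    hs = resolve_hover(seq, layout, 1)  # first "1"
    assert hs.kind is HighlightKind.RING
    assert hs.token_indices == frozenset({1, 7})
    assert hs.atom_indices == frozenset(range(6))


def test_ring_hover_smallest_ring():
    # fused naphthalene: a closure digit highlights one 6-ring, not all 10 atoms
    seq, layout = layout_and_tokens("c1ccc2ccccc2c1")
    for i, tok in enumerate(seq.tokens):
        if tok.kind is TokenKind.RING_BOND:
            hs = resolve_hover(seq, layout, i)
            assert len(hs.atom_indices) == 6


def test_group_hover():
    seq, layout = layout_and_tokens("[N+](C)(C)(C)C")
    for i in range(4):  # "[", "N", "+", "]"
        hs = resolve_hover(seq, layout, i)
        assert hs.kind is HighlightKind.GROUP
        assert hs.token_indices == frozenset({0, 1, 2, 3})
        assert hs.atom_indices == frozenset({0})


def test_bond_hover_adjacent_atoms():
    seq, layout = layout_and_tokens("C=O")
    hs = resolve_hover(seq, layout, 1)
    assert hs.token_indices == frozenset({1})
    assert hs.atom_indices == frozenset({0, 1})


def test_dot_hover_no_atoms():
    seq, layout = layout_and_tokens("[Na+].[Cl-]")
    dot = seq.texts.index(".")
    assert resolve_hover(seq, layout, dot).atom_indices == frozenset()


def test_unmatched_paren_raises():
    seq = tokenize("CC(")
    layout = build_atom_layout("CCC")  # placeholder layout, same atom count
    with pytest.raises(StructureError):
        resolve_hover(seq, layout, 2)


def test_unpaired_ring_digit_raises():
    seq = tokenize("C1CC")
    layout = build_atom_layout("CCC")
    with pytest.raises(StructureError):
        resolve_hover(seq, layout, 1)


def test_atom_hover_examples():
    seq, _ = layout_and_tokens("CCO")
    assert resolve_atom_hover(seq, 2).token_indices == frozenset({2})
    seq2, _ = layout_and_tokens("[N+]C")
    assert resolve_atom_hover(seq2, 0).token_indices == frozenset({1})
    with pytest.raises(IndexError):
        resolve_atom_hover(seq, 3)


def test_atom_token_inversion(all_fixture_smiles):
    """Hovering an atom returns the token that highlights that atom."""
    for smiles in all_fixture_smiles[::5]:
        seq, _ = layout_and_tokens(smiles)
        for i, tok in enumerate(seq.tokens):
            if tok.kind is TokenKind.ATOM:
                hs = resolve_atom_hover(seq, tok.atom_index)
                assert hs.token_indices == frozenset({i})


# ---------------------------------------------------------------------------
# oracle equivalence on the whole fixture set


def _char_stack_parens(smiles: str) -> dict[int, int]:
    """Brute-force character-level parenthesis matcher (independent oracle)."""
    pairs, stack = {}, []
    for i, c in enumerate(smiles):
        if c == "(":
            stack.append(i)
        elif c == ")":
            j = stack.pop()
            pairs[i], pairs[j] = j, i
    assert not stack
    return pairs


def _char_ring_pairs(smiles: str) -> dict[int, int]:
    """Independent character-scan ring-digit pairing (skips brackets, %nn)."""
    pairs, open_by_num = {}, {}
    i, in_bracket = 0, False
    while i < len(smiles):
        c = smiles[i]
        if c == "[":
            in_bracket = True
        elif c == "]":
            in_bracket = False
        elif not in_bracket and (c.isdigit() or c == "%"):
            if c == "%":
                num, width = int(smiles[i + 1 : i + 3]), 3
            else:
                num, width = int(c), 1
            if num in open_by_num:
                j = open_by_num.pop(num)
                pairs[i], pairs[j] = j, i
            else:
                open_by_num[num] = i
            i += width
            continue
        i += 1
    return pairs


def test_paren_matching_equals_char_oracle(all_fixture_smiles):
    for smiles in all_fixture_smiles:
        seq = tokenize(smiles)
        token_pairs = match_parens(seq)
        char_pairs = _char_stack_parens(smiles)
        mapped = {
            seq.tokens[i].char_start: seq.tokens[j].char_start
            for i, j in token_pairs.items()
        }
        assert mapped == char_pairs, smiles


def test_ring_pairing_equals_char_oracle(all_fixture_smiles):
    for smiles in all_fixture_smiles:
        seq = tokenize(smiles)
        token_pairs = ring_partners(seq)
        # partner symmetry
        for i, j in token_pairs.items():
            assert token_pairs[j] == i
        mapped = {
            seq.tokens[i].char_start: seq.tokens[j].char_start
            for i, j in token_pairs.items()
        }
        assert mapped == _char_ring_pairs(smiles), smiles


def test_bracket_span_equals_char_positions(all_fixture_smiles):
    for smiles in all_fixture_smiles:
        seq, layout = layout_and_tokens(smiles)
        for i, tok in enumerate(seq.tokens):
            if tok.kind is TokenKind.BRACKET_OPEN:
                hs = resolve_hover(seq, layout, i)
                lo = min(hs.token_indices)
                hi = max(hs.token_indices)
                assert smiles[seq.tokens[lo].char_start] == "["
                assert smiles[seq.tokens[hi].char_end - 1] == "]"
                assert len(hs.atom_indices) == 1


# ---------------------------------------------------------------------------
# hover-map export


def test_export_counts():
    seq, layout = layout_and_tokens("CCO")
    hm = export_hover_map(seq, layout)
    assert len(hm["tokens"]) == 3 and len(hm["atoms"]) == 3


def test_export_ring_partners_share_atoms():
    seq, layout = layout_and_tokens("C1CC1")
    hm = export_hover_map(seq, layout)
    assert len(hm["tokens"]) == 5
    ring_entries = [
        hs for hs in hm["tokens"].values() if hs.kind is HighlightKind.RING
    ]
    assert len(ring_entries) == 2
    assert ring_entries[0].atom_indices == ring_entries[1].atom_indices


def test_export_branch_entries_equal():
    seq, layout = layout_and_tokens("CC(C)O")
    hm = export_hover_map(seq, layout)
    assert hm["tokens"][2] == hm["tokens"][4]
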