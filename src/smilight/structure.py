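"""Mapping between SMILES tokens and the depicted molecular graph.

The bar chart shows tokens, the diagram shows atoms; this module binds the
two.  Atom *i* of the RDKit graph corresponds to the *i*-th ATOM token of the
string (the string is parsed as written, never re-canonicalized), and every
token resolves to an explicit highlight set:

* an atom token highlights its atom;
* a parenthesis highlights the whole branch it delimits (nested branches
  included);
* a bracket, or any token inside a ``[...]`` group, highlights the group's
  single atom;
* a ring-closure digit highlights its partner digit and the atoms of the
  smallest perceived ring closed by that bond;
* a bond or dot token highlights the atom tokens adjacent to it in the
  string (none for an isolated dot).

Highlight sets are plain data (token-index and atom-index sets), so the
interactive behaviour of the HTML output is fully precomputed and testable.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

from rdkit import Chem
from rdkit.Chem import rdDepictor

from .tokenizer import Token, TokenKind, TokenSequence, tokenize

__all__ = [
    "HighlightKind",
    "HighlightSet",
    "AtomLayout",
    "StructureError",
    "MoleculeParseError",
    "build_atom_layout",
    "resolve_hover",
    "resolve_atom_hover",
    "export_hover_map",
]


class MoleculeParseError(ValueError):
    """The cheminformatics toolkit rejected the SMILES string."""


class StructureError(ValueError):
    """A structural span (parenthesis, bracket, ring digit) is unmatched."""

    def __init__(self, message: str, token_index: int):
        super().__init__(f"{message} (token {token_index})")
        self.token_index = token_index


class HighlightKind(enum.Enum):
    ATOM = "ATOM"
    RING = "RING"
    GROUP = "GROUP"
    BRANCH = "BRANCH"
    BOND = "BOND"


@dataclass(frozen=True)
class HighlightSet:
    """A resolved substructure as explicit token and atom index sets."""

    kind: HighlightKind
    token_indices: frozenset[int]
    atom_indices: frozenset[int]


@dataclass
class AtomLayout:
    """2-D depiction geometry of a parsed SMILES: per-atom coordinates, bonds
    as atom-index pairs, and the perceived ring systems.  Atom index *i* is
    the *i*-th ATOM token of the source string."""

    n_atoms: int
    coords: list[tuple[float, float]]
    bonds: list[tuple[int, int]]
    rings: list[frozenset[int]]
    mol: Chem.Mol = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if len(self.coords) != self.n_atoms:
            raise ValueError("coords length must equal n_atoms")
        for a, b in self.bonds:
            if not (0 <= a < self.n_atoms and 0 <= b < self.n_atoms):
                raise ValueError(f"bond ({a},{b}) references invalid atom index")


def parse_mol(smiles: str) -> Chem.Mol:
    """Parse a SMILES as written, keeping explicit hydrogens so atom order
    matches the atom-token order of the string."""
    params = Chem.SmilesParserParams()
    params.removeHs = False
    mol = Chem.MolFromSmiles(smiles, params)
    if mol is None:
        raise MoleculeParseError(f"toolkit could not parse SMILES {smiles!r}")
    return mol


def build_atom_layout(smiles: str) -> AtomLayout:
    """Parse and depict a SMILES, returning its :class:`AtomLayout`.

    Coordinates come straight from the toolkit's 2-D conformer (drawing
    units); the first atom of the string is node 0.
    """
    mol = parse_mol(smiles)
    rdDepictor.Compute2DCoords(mol)
    conf = mol.GetConformer()
    coords = [
        (conf.GetAtomPosition(i).x, conf.GetAtomPosition(i).y)
        for i in range(mol.GetNumAtoms())
    ]
    bonds = [
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in mol.GetBonds()
    ]
    rings = [frozenset(r) for r in mol.GetRingInfo().AtomRings()]
    return AtomLayout(mol.GetNumAtoms(), coords, bonds, rings, mol)


# ---------------------------------------------------------------------------
# span matching


def match_parens(seq: TokenSequence) -> dict[int, int]:
    """Map each BRANCH_OPEN/CLOSE token index to its partner's index.

    Raises :class:`StructureError` on the first unmatched parenthesis.
    """
    pairs: dict[int, int] = {}
    stack: list[int] = []
    for i, tok in enumerate(seq.tokens):
        if tok.kind is TokenKind.BRANCH_OPEN:
            stack.append(i)
        elif tok.kind is TokenKind.BRANCH_CLOSE:
            if not stack:
                raise StructureError("unmatched ')'", i)
            j = stack.pop()
            pairs[j] = i
            pairs[i] = j
    if stack:
        raise StructureError("unmatched '('", stack[-1])
    return pairs


def match_brackets(seq: TokenSequence) -> dict[int, int]:
    """Map each BRACKET_OPEN/CLOSE token index to its partner's index."""
    pairs: dict[int, int] = {}
    open_idx: Optional[int] = None
    for i, tok in enumerate(seq.tokens):
        if tok.kind is TokenKind.BRACKET_OPEN:
            if open_idx is not None:
                raise StructureError("nested '['", i)
            open_idx = i
        elif tok.kind is TokenKind.BRACKET_CLOSE:
            if open_idx is None:
                raise StructureError("unmatched ']'", i)
            pairs[open_idx] = i
            pairs[i] = open_idx
            open_idx = None
    if open_idx is not None:
        raise StructureError("unmatched '['", open_idx)
    return pairs


def ring_partners(seq: TokenSequence) -> dict[int, int]:
    """Pair up ring-closure tokens by number, honouring number reuse.

    Unpaired digits are simply absent from the mapping; hovering one raises.
    """
    pairs: dict[int, int] = {}
    open_by_number: dict[int, int] = {}
    for i, tok in enumerate(seq.tokens):
        if tok.kind is not TokenKind.RING_BOND:
            continue
        number = int(tok.text.lstrip("%"))
        if number in open_by_number:
            j = open_by_number.pop(number)
            pairs[j] = i
            pairs[i] = j
        else:
            open_by_number[number] = i
    return pairs


def _owning_atom(seq: TokenSequence, token_index: int) -> Optional[int]:
    """Atom index of the last ATOM token at or before ``token_index``."""
    for i in range(token_index, -1, -1):
        if seq.tokens[i].kind is TokenKind.ATOM:
            return seq.tokens[i].atom_index
    return None


def _next_atom(seq: TokenSequence, token_index: int) -> Optional[int]:
    for i in range(token_index + 1, len(seq.tokens)):
        if seq.tokens[i].kind is TokenKind.ATOM:
            return seq.tokens[i].atom_index
    return None


def _ring_atoms_for_closure(
    layout: AtomLayout, a: int, b: int
) -> frozenset[int]:
    """Atoms of the smallest perceived ring containing the closure bond a-b.

    Ties between equally small rings break toward the lowest atom-index sum,
    which is deterministic.  Falls back to the bond's two atoms if ring
    perception (unexpectedly) finds no containing ring.
    """
    candidates = [r for r in layout.rings if a in r and b in r]
    if not candidates:
        return frozenset({a, b})
    return min(candidates, key=lambda r: (len(r), sum(r)))


def resolve_hover(
    seq: TokenSequence, layout: AtomLayout, token_index: int
) -> HighlightSet:
    """Resolve the substructure a hovered token highlights.

    See the module docstring for the four semantics (atom, branch, group,
    ring) plus the bond/dot fallback.  Raises :class:`StructureError` for
    tokens inside malformed spans and :class:`IndexError` for an invalid
    token index.
    """
    if not 0 <= token_index < len(seq.tokens):
        raise IndexError(f"token index {token_index} out of range")
    tok = seq.tokens[token_index]

    if tok.kind is TokenKind.ATOM:
        # an atom inside a bracket group highlights the whole group
        span = _enclosing_bracket_span(seq, token_index)
        if span is not None:
            return _group_highlight(seq, span)
        return HighlightSet(
            HighlightKind.ATOM,
            frozenset({token_index}),
            frozenset({tok.atom_index}),
        )

    if tok.kind in (TokenKind.BRANCH_OPEN, TokenKind.BRANCH_CLOSE):
        pairs = match_parens(seq)
        j = pairs[token_index]
        lo, hi = min(token_index, j), max(token_index, j)
        atoms = frozenset(
            t.atom_index
            for t in seq.tokens[lo : hi + 1]
            if t.kind is TokenKind.ATOM
        )
        return HighlightSet(
            HighlightKind.BRANCH, frozenset(range(lo, hi + 1)), atoms
        )

    if tok.kind in (
        TokenKind.BRACKET_OPEN,
        TokenKind.BRACKET_CLOSE,
        TokenKind.ISOTOPE,
        TokenKind.CHIRALITY,
        TokenKind.HCOUNT,
        TokenKind.CHARGE,
    ):
        span = _enclosing_bracket_span(seq, token_index)
        if span is None:
            raise StructureError("token outside any bracket group", token_index)
        return _group_highlight(seq, span)

    if tok.kind is TokenKind.RING_BOND:
        pairs = ring_partners(seq)
        if token_index not in pairs:
            raise StructureError("unpaired ring-closure digit", token_index)
        partner = pairs[token_index]
        a = _owning_atom(seq, token_index)
        b = _owning_atom(seq, partner)
        if a is None or b is None:
            raise StructureError("ring digit not preceded by an atom", token_index)
        atoms = _ring_atoms_for_closure(layout, a, b)
        return HighlightSet(
            HighlightKind.RING, frozenset({token_index, partner}), atoms
        )

    # BOND or DOT: the token itself plus the string-adjacent atoms it joins
    atoms: set[int] = set()
    if tok.kind is TokenKind.BOND:
        for atom in (_owning_atom(seq, token_index), _next_atom(seq, token_index)):
            if atom is not None:
                atoms.add(atom)
    return HighlightSet(
        HighlightKind.BOND, frozenset({token_index}), frozenset(atoms)
    )


def _enclosing_bracket_span(
    seq: TokenSequence, token_index: int
) -> Optional[tuple[int, int]]:
    """(open, close) token indices of the bracket group containing the token,
    or None if it lies outside every bracket group."""
    pairs = match_brackets(seq)
    tok = seq.tokens[token_index]
    if tok.kind is TokenKind.BRACKET_OPEN:
        return token_index, pairs[token_index]
    if tok.kind is TokenKind.BRACKET_CLOSE:
        return pairs[token_index], token_index
    for open_idx, close_idx in pairs.items():
        if seq.tokens[open_idx].kind is TokenKind.BRACKET_OPEN:
            if open_idx < token_index < close_idx:
                return open_idx, close_idx
    return None


def _group_highlight(seq: TokenSequence, span: tuple[int, int]) -> HighlightSet:
    lo, hi = span
    atoms = frozenset(
        t.atom_index for t in seq.tokens[lo : hi + 1] if t.kind is TokenKind.ATOM
    )
    return HighlightSet(HighlightKind.GROUP, frozenset(range(lo, hi + 1)), atoms)


def resolve_atom_hover(seq: TokenSequence, atom_index: int) -> HighlightSet:
    """Inverse of :func:`resolve_hover` for atoms: the single ATOM token
    bound to ``atom_index``."""
    for i, tok in enumerate(seq.tokens):
        if tok.kind is TokenKind.ATOM and tok.atom_index == atom_index:
            return HighlightSet(
                HighlightKind.ATOM, frozenset({i}), frozenset({atom_index})
            )
    raise IndexError(f"atom index {atom_index} out of range")


def export_hover_map(
    seq: TokenSequence, layout: AtomLayout
) -> dict[str, dict[int, object]]:
    """Precompute the full interactivity table for one molecule.

    Returns ``{"tokens": {token_index: HighlightSet}, "atoms":
    {atom_index: token_index}}`` — everything the static HTML needs to drive
    token<->substructure highlighting without runtime structure analysis.
    """
    tokens = {
        i: resolve_hover(seq, layout, i) for i in range(len(seq.tokens))
    }
    atoms = {
        t.atom_index: i
        for i, t in enumerate(seq.tokens)
        if t.kind is TokenKind.ATOM
    }
    return {"tokens": tokens, "atoms": atoms}


def layout_and_tokens(smiles: str) -> tuple[TokenSequence, AtomLayout]:
    """Convenience: tokenize and depict in one call, checking parity."""
    seq = tokenize(smiles)
    layout = build_atom_layout(smiles)
    if seq.n_atoms != layout.n_atoms:
        raise MoleculeParseError(
            f"atom-token count {seq.n_atoms} != toolkit atom count "
            f"{layout.n_atoms} for {smiles!r}"
        )
    return seq, layout
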