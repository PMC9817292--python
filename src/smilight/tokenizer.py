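"""Lossless lexing of SMILES strings into typed tokens.

A SMILES string mixes atom symbols (``C``, ``Cl``, ``n``) with structural
syntax: branch parentheses, ring-closure digits, bond symbols and bracket-atom
modifiers (isotope, chirality, hydrogen count, charge).  Attribution methods
that operate on SMILES emit one score per *token*, so the visualization layer
needs a tokenizer whose atom tokens line up one-to-one with the atoms of the
molecular graph, and whose token texts concatenate back to the exact input
string.

The grammar implemented here:

* outside brackets, an atom token is an organic-subset symbol
  (``B C N O P S F I Cl Br``), an aromatic symbol (``b c n o s p``) or ``*``;
  the two-character halogens are single tokens;
* a bracket group ``[...]`` contains exactly one atom token; isotope digits,
  ``@``/``@@`` chirality marks, ``H``-counts (``H``, ``H2``) and charge groups
  (``+``, ``-``, ``+2``, ``++``) are separate non-atom tokens;
* a ring closure is one token: a single digit or ``%`` followed by two digits;
* bond symbols (``- = # $ : / \\``) and the dot disconnect are one token each.

Atom-map suffixes (``[CH3:1]``) are not part of the grammar and raise.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterator, Optional

__all__ = [
    "TokenKind",
    "Token",
    "TokenSequence",
    "TokenizationError",
    "tokenize",
    "atom_token_positions",
]


class TokenizationError(ValueError):
    """Raised when a character cannot be lexed; carries the 0-based position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (position {position})")
        self.position = position


class TokenKind(enum.Enum):
    ATOM = "ATOM"
    BOND = "BOND"
    RING_BOND = "RING_BOND"
    BRANCH_OPEN = "BRANCH_OPEN"
    BRANCH_CLOSE = "BRANCH_CLOSE"
    BRACKET_OPEN = "BRACKET_OPEN"
    BRACKET_CLOSE = "BRACKET_CLOSE"
    ISOTOPE = "ISOTOPE"
    CHIRALITY = "CHIRALITY"
    HCOUNT = "HCOUNT"
    CHARGE = "CHARGE"
    DOT = "DOT"


@dataclass(frozen=True)
class Token:
    """One lexical unit: its text, kind, character span and (for atoms) the
    0-based index of the corresponding atom in the molecular graph."""

    text: str
    kind: TokenKind
    char_start: int
    char_end: int
    atom_index: Optional[int] = None

    def __post_init__(self) -> None:
        if self.char_end <= self.char_start:
            raise ValueError("token span must be non-empty")
        if (self.atom_index is not None) != (self.kind is TokenKind.ATOM):
            raise ValueError("atom_index present iff kind is ATOM")


@dataclass(frozen=True)
class TokenSequence:
    """Ordered tokens of one SMILES string; lossless w.r.t. the source text."""

    smiles: str
    tokens: tuple[Token, ...]

    def __len__(self) -> int:
        return len(self.tokens)

    def __iter__(self) -> Iterator[Token]:
        return iter(self.tokens)

    def __getitem__(self, i: int) -> Token:
        return self.tokens[i]

    @property
    def n_atoms(self) -> int:
        return sum(1 for t in self.tokens if t.kind is TokenKind.ATOM)

    @property
    def texts(self) -> list[str]:
        return [t.text for t in self.tokens]

    @property
    def kinds(self) -> list[TokenKind]:
        return [t.kind for t in self.tokens]


# All IUPAC element symbols, used for longest-match inside brackets
# (so that [Sc] lexes as scandium, not sulfur + aromatic carbon).
_ELEMENTS = frozenset(
    """H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Sc Ti V Cr Mn Fe Co
    Ni Cu Zn Ga Ge As Se Br Kr Rb Sr Y Zr Nb Mo Tc Ru Rh Pd Ag Cd In Sn Sb Te
    I Xe Cs Ba La Ce Pr Nd Pm Sm Eu Gd Tb Dy Ho Er Tm Yb Lu Hf Ta W Re Os Ir
    Pt Au Hg Tl Pb Bi Po At Rn Fr Ra Ac Th Pa U Np Pu Am Cm Bk Cf Es Fm Md No
    Lr Rf Db Sg Bh Hs Mt Ds Rg Cn Nh Fl Mc Lv Ts Og""".split()
)

_ORGANIC_SINGLE = frozenset("BCNOPSFI")
_AROMATIC_SINGLE = frozenset("bcnops")
_AROMATIC_TWO = frozenset({"se", "as", "te"})
_BOND_CHARS = frozenset("-=#$:/\\")


def tokenize(smiles: str) -> TokenSequence:
    """Lex a SMILES string into a lossless :class:`TokenSequence`.

    The count of ATOM tokens equals the atom count of the molecular graph
    encoded by the string (including explicit bracket hydrogens), and atom
    tokens are numbered 0..n-1 in order of appearance — the same order the
    cheminformatics toolkit assigns to graph nodes.

    Raises :class:`TokenizationError` on any character the grammar does not
    recognize, naming the character and its position.
    """
    tokens: list[Token] = []
    atom_counter = 0
    i = 0
    n = len(smiles)

    def emit(text: str, kind: TokenKind) -> None:
        nonlocal i, atom_counter
        idx = None
        if kind is TokenKind.ATOM:
            idx = atom_counter
            atom_counter += 1
        tokens.append(Token(text, kind, i, i + len(text), idx))
        i += len(text)

    while i < n:
        c = smiles[i]
        if c == "[":
            emit(c, TokenKind.BRACKET_OPEN)
            i = _lex_bracket_body(smiles, i, emit)
        elif c == "(":
            emit(c, TokenKind.BRANCH_OPEN)
        elif c == ")":
            emit(c, TokenKind.BRANCH_CLOSE)
        elif c.isdigit():
            emit(c, TokenKind.RING_BOND)
        elif c == "%":
            if i + 2 < n and smiles[i + 1].isdigit() and smiles[i + 2].isdigit():
                emit(smiles[i : i + 3], TokenKind.RING_BOND)
            else:
                raise TokenizationError(
                    "'%' must be followed by two ring-closure digits", i
                )
        elif c in _BOND_CHARS:
            emit(c, TokenKind.BOND)
        elif c == ".":
            emit(c, TokenKind.DOT)
        elif smiles[i : i + 2] in ("Cl", "Br"):
            emit(smiles[i : i + 2], TokenKind.ATOM)
        elif c in _ORGANIC_SINGLE or c in _AROMATIC_SINGLE or c == "*":
            emit(c, TokenKind.ATOM)
        else:
            raise TokenizationError(f"unrecognizable character {c!r}", i)

    return TokenSequence(smiles, tuple(tokens))


def _lex_bracket_body(smiles: str, start: int, emit) -> int:
    """Lex the interior of a bracket-atom group plus the closing bracket.

    ``start`` is the first character after ``[``; returns the index just
    past ``]``.  Exactly one ATOM token is produced per bracket group; ``H``
    is the atom only when it sits in the element position (``[H]``,
    ``[2H+]``), otherwise it is an HCOUNT token.
    """
    n = len(smiles)
    i = start
    seen_atom = False
    while i < n:
        c = smiles[i]
        if c == "]":
            if not seen_atom:
                raise TokenizationError("bracket group contains no atom symbol", i)
            emit(c, TokenKind.BRACKET_CLOSE)
            return i + 1
        if c.isdigit() and not seen_atom:
            j = i
            while j < n and smiles[j].isdigit():
                j += 1
            emit(smiles[i:j], TokenKind.ISOTOPE)
            i = j
        elif c == "@":
            text = "@@" if smiles[i : i + 2] == "@@" else "@"
            emit(text, TokenKind.CHIRALITY)
            i += len(text)
        elif c == "H" and seen_atom:
            j = i + 1
            while j < n and smiles[j].isdigit():
                j += 1
            emit(smiles[i:j], TokenKind.HCOUNT)
            i = j
        elif c in "+-":
            j = i + 1
            while j < n and smiles[j] == c:  # ++ / --
                j += 1
            while j < n and smiles[j].isdigit():  # +2 / -3
                j += 1
            emit(smiles[i:j], TokenKind.CHARGE)
            i = j
        elif not seen_atom:
            text = _match_element(smiles, i)
            if text is None:
                raise TokenizationError(
                    f"unrecognizable character {c!r} in bracket group", i
                )
            emit(text, TokenKind.ATOM)
            seen_atom = True
            i += len(text)
        else:
            raise TokenizationError(
                f"unrecognizable character {c!r} in bracket group", i
            )
    raise TokenizationError("unterminated bracket group", start - 1)


def _match_element(smiles: str, i: int) -> Optional[str]:
    """Longest-match an element or aromatic symbol at position ``i``."""
    two = smiles[i : i + 2]
    if two in _AROMATIC_TWO:
        return two
    if len(two) == 2 and two[0].isupper() and two[1].islower() and two in _ELEMENTS:
        return two
    c = smiles[i]
    if c == "*" or c in _AROMATIC_SINGLE or (c.isupper() and c in _ELEMENTS):
        return c
    return None


def atom_token_positions(seq: TokenSequence) -> list[int]:
    """Positions (token indices) of ATOM tokens, in atom-index order."""
    return [i for i, t in enumerate(seq.tokens) if t.kind is TokenKind.ATOM]
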