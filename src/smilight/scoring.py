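"""Score binding, colormap-domain normalization and diverging-color mapping.

Attribution vectors arrive in one of two lengths: one value per atom
(PER_ATOM) or one value per SMILES token (PER_TOKEN).  Per-atom vectors are
spread onto the atom tokens in order, with 0.0 on every non-atom token, so
downstream code always sees one score per token.

Scores are mapped to colors through a *colormap domain* ``(min, 0, max)``:
positive scores are divided by ``max``, negatives by ``|min|``, and the
result is clamped to [-1, 1] — anything outside the domain gets the
endpoint color and a full-height bar.  By default the domain is symmetric at
the molecule's maximum absolute score.  *Thresholds* are fractions of the
domain maximum; a threshold t highlights every atom with
``|score| >= t * max``.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

from .palettes import get_palette, score_to_color as _palette_color
from .tokenizer import TokenKind, TokenSequence

logger = logging.getLogger(__name__)

__all__ = [
    "LengthMode",
    "ScoredTokens",
    "VisualConfig",
    "ScoreShapeError",
    "attach_scores",
    "default_domain",
    "normalize",
    "threshold_cutoffs",
    "guide_fractions",
    "highlighted_atoms",
    "score_to_color",
]

#: Default bar-chart guide-line fractions when no thresholds are set.
DEFAULT_GUIDE_FRACTIONS: tuple[float, float] = (0.5, 1.0)


class ScoreShapeError(ValueError):
    """Score-vector length matches neither the atom nor the token count."""


class LengthMode(enum.Enum):
    PER_ATOM = "PER_ATOM"
    PER_TOKEN = "PER_TOKEN"


@dataclass(frozen=True)
class ScoredTokens:
    """A token sequence with one attribution score per token."""

    seq: TokenSequence
    scores: tuple[float, ...]
    source_length_mode: LengthMode

    def __post_init__(self) -> None:
        if len(self.scores) != len(self.seq.tokens):
            raise ValueError("scores length must equal token count")

    def atom_scores(self) -> list[float]:
        """Scores of ATOM tokens in atom-index order."""
        return [
            s
            for s, t in zip(self.scores, self.seq.tokens)
            if t.kind is TokenKind.ATOM
        ]


def _as_domain(domain: Sequence[float]) -> tuple[float, float]:
    """Accept (min, max) or (min, 0, max); return the validated pair."""
    if len(domain) == 3:
        if domain[1] != 0:
            raise ValueError("three-element domain must have 0 midpoint")
        domain = (domain[0], domain[2])
    if len(domain) != 2:
        raise ValueError("domain must be (min, max) or (min, 0, max)")
    lo, hi = float(domain[0]), float(domain[1])
    if not (lo < 0 < hi):
        raise ValueError(f"domain must straddle 0, got ({lo}, {hi})")
    return lo, hi


@dataclass(frozen=True)
class VisualConfig:
    """Rendering parameters: palette, domain, thresholds, flags, geometry.

    Geometry values are SVG user units (pixels at 1:1).
    """

    palette: str | Sequence[str] = "red_blue"
    domain: tuple[float, float] | None = None  # None: per-molecule max |s|
    thresholds: tuple[float, ...] = ()
    show_score_labels: bool = False
    black_atoms: bool = False
    # geometry
    mol_width: int = 300
    mol_height: int = 250
    bar_width: int = 14
    bar_gap: int = 4
    bar_chart_height: int = 110
    font_size: int = 12
    table_row_height: int = 18

    def __post_init__(self) -> None:
        if self.domain is not None:
            object.__setattr__(self, "domain", _as_domain(self.domain))
        thr = tuple(sorted(float(t) for t in self.thresholds))
        for t in thr:
            if not 0.0 <= t <= 1.0:
                raise ValueError(f"threshold {t} outside [0, 1]")
        object.__setattr__(self, "thresholds", thr)
        get_palette(self.palette)  # validate early

    def with_overrides(self, **kwargs) -> "VisualConfig":
        return replace(self, **kwargs)


def attach_scores(seq: TokenSequence, raw: Sequence[float]) -> ScoredTokens:
    """Bind a raw score vector to a token sequence.

    A vector of atom-count length is spread onto ATOM tokens in order with
    0.0 on non-atom tokens; a vector of token-count length maps positionally.
    Any other length raises :class:`ScoreShapeError` naming both admissible
    lengths.  (When the string has no non-atom tokens the two modes coincide
    and PER_TOKEN is reported.)
    """
    raw = [float(x) for x in raw]
    n_tokens = len(seq.tokens)
    n_atoms = seq.n_atoms
    if len(raw) == n_tokens:
        return ScoredTokens(seq, tuple(raw), LengthMode.PER_TOKEN)
    if len(raw) == n_atoms:
        it = iter(raw)
        spread = tuple(
            next(it) if t.kind is TokenKind.ATOM else 0.0 for t in seq.tokens
        )
        return ScoredTokens(seq, spread, LengthMode.PER_ATOM)
    raise ScoreShapeError(
        f"score vector of length {len(raw)} matches neither the atom count "
        f"({n_atoms}) nor the token count ({n_tokens}) of {seq.smiles!r}"
    )


def default_domain(scores: ScoredTokens) -> tuple[float, float]:
    """Symmetric domain (-m, m) with m the molecule's max absolute score.

    All-zero score vectors fall back to (-1, 1) with a logged warning.
    """
    m = max((abs(s) for s in scores.scores), default=0.0)
    if m == 0.0:
        logger.warning(
            "all scores are zero for %r; using colormap domain (-1, 1)",
            scores.seq.smiles,
        )
        return (-1.0, 1.0)
    return (-m, m)


def normalize(score: float, domain: Sequence[float]) -> float:
    """Map a score into [-1, 1] against the domain, clamping outside values.

    Positive scores scale by the domain maximum, negative by the magnitude
    of the domain minimum, so asymmetric domains normalize each sign against
    its own bound.
    """
    lo, hi = _as_domain(domain)
    if score > 0:
        return min(score / hi, 1.0)
    if score < 0:
        return max(score / -lo, -1.0)
    return 0.0


def threshold_cutoffs(
    thresholds: Sequence[float], domain: Sequence[float]
) -> list[float]:
    """Absolute highlight cutoffs implied by threshold fractions.

    ``cutoff_i = threshold_i * domain_max``; an atom is highlighted when
    ``|score| >= cutoff`` (the negative side is symmetric through the
    absolute value).  An empty threshold list yields no cutoffs — the bar
    chart then falls back to :func:`guide_fractions` guide lines and the
    diagram draws no highlight.
    """
    _, hi = _as_domain(domain)
    cutoffs = []
    for t in thresholds:
        t = float(t)
        if not 0.0 <= t <= 1.0:
            raise ValueError(f"threshold {t} outside [0, 1]")
        cutoffs.append(t * hi)
    return cutoffs


def guide_fractions(thresholds: Sequence[float]) -> tuple[float, ...]:
    """Bar-chart guide-line fractions: the thresholds themselves, or the
    default (0.5, 1.0) when none are set."""
    if thresholds:
        return tuple(float(t) for t in thresholds)
    return DEFAULT_GUIDE_FRACTIONS


def highlighted_atoms(
    scores: ScoredTokens, cutoffs: Sequence[float]
) -> list[set[int]]:
    """Per-cutoff sets of atom indices with ``|score| >= cutoff``.

    An exactly-zero score is never highlighted (a cutoff of 0 selects every
    atom with a nonzero attribution).  Sets are (weakly) nested: a larger
    cutoff selects a subset of a smaller one.
    """
    atom_scores = scores.atom_scores()
    return [
        {i for i, s in enumerate(atom_scores) if s != 0.0 and abs(s) >= c}
        for c in cutoffs
    ]


def score_to_color(
    score: float,
    domain: Sequence[float],
    palette: str | Sequence[str] = "red_blue",
) -> str:
    """Hex color for a score under a diverging palette and a domain.

    Zero maps to the palette's neutral middle; scores at or beyond the
    domain bounds map to the endpoint colors; in between, colors are
    interpolated in CIELAB with lightness forced to decrease monotonically
    from the neutral middle toward each endpoint.
    """
    t = normalize(score, domain)
    if math.isnan(t):
        raise ValueError("score is NaN")
    return _palette_color(t, palette)
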