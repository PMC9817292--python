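"""Attribution-score generation: substitution sensitivity and Crippen logP.

The *substitution* (occlusion) method scores each SMILES token of a
black-box predictor's input: replace the token's text by every token in a
vocabulary, predict each substituted string, and report

    score_i = f(original) - mean_v f(replace token i by v)

A positive score means the prediction is expected to drop when the token is
disturbed, i.e. the token supports the predicted value.  Substitution acts
on the raw string, so some substituted strings are not valid SMILES; those
are skipped (and if every substitution at a position is invalid the score is
0.0 with a logged warning).

Wildman-Crippen per-atom logP contributions serve as an additive
ground-truth-style comparator: the per-atom values (with each implicit
hydrogen's contribution folded into its heavy atom) sum exactly to the
molecule-level Crippen logP.
"""

from __future__ import annotations

import logging
import math
from typing import Protocol, Sequence, runtime_checkable

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import Crippen, rdMolDescriptors

from .records import MoleculeRecord
from .structure import parse_mol
from .tokenizer import TokenKind, tokenize

logger = logging.getLogger(__name__)

__all__ = [
    "Predictor",
    "CrippenLogPPredictor",
    "AttributionError",
    "substitution_attribution",
    "crippen_scores",
    "make_fixtures",
]


class AttributionError(ValueError):
    """The predictor rejected the original SMILES string."""


@runtime_checkable
class Predictor(Protocol):
    """Black-box SMILES -> real prediction with a finite token vocabulary.

    Must be deterministic for a fixed input and may signal an invalid SMILES
    by raising any exception.
    """

    vocabulary: Sequence[str]

    def __call__(self, smiles: str) -> float: ...


class CrippenLogPPredictor:
    """Toy deterministic predictor: Crippen logP of the parsed string.

    The vocabulary is atom tokens only, so substitutions at
    symmetry-equivalent positions of a symmetric molecule yield isomorphic
    molecules and hence exactly equal sensitivity scores.
    """

    vocabulary: tuple[str, ...] = (
        "C", "N", "O", "S", "F", "Cl", "Br", "I", "c", "n", "o", "s",
    )

    def __call__(self, smiles: str) -> float:
        RDLogger.DisableLog("rdApp.error")
        try:
            mol = parse_mol(smiles)
        finally:
            RDLogger.EnableLog("rdApp.error")
        return Crippen.MolLogP(mol)


def substitution_attribution(
    predictor: Predictor,
    smiles: str,
    vocabulary: Sequence[str] | None = None,
) -> list[float]:
    """Per-token substitution sensitivity scores for ``smiles``.

    ``vocabulary`` defaults to ``predictor.vocabulary``.  The original token
    is substituted as well when it occurs in the vocabulary (no exclusion).
    Substituted strings the predictor rejects are dropped from the mean; a
    position where every substitution is rejected scores 0.0 with a warning.
    Means use exact summation, so scores are independent of vocabulary
    order.

    Raises :class:`AttributionError` if the predictor rejects the original
    string and :class:`ValueError` on an empty vocabulary.
    """
    if vocabulary is None:
        vocabulary = tuple(predictor.vocabulary)
    if not vocabulary:
        raise ValueError("substitution vocabulary is empty")
    seq = tokenize(smiles)
    try:
        base = predictor(smiles)
    except Exception as exc:
        raise AttributionError(
            f"predictor rejected the original SMILES {smiles!r}: {exc}"
        ) from exc

    scores: list[float] = []
    for i, tok in enumerate(seq.tokens):
        preds: list[float] = []
        for v in vocabulary:
            candidate = smiles[: tok.char_start] + v + smiles[tok.char_end :]
            try:
                preds.append(predictor(candidate))
            except Exception:
                continue
        if not preds:
            logger.warning(
                "every substitution at token %d (%r) of %r was rejected; "
                "scoring 0.0",
                i,
                tok.text,
                smiles,
            )
            scores.append(0.0)
        else:
            scores.append(base - math.fsum(preds) / len(preds))
    return scores


def crippen_scores(smiles: str) -> list[float]:
    """Wildman-Crippen per-atom logP contributions, in atom-index order.

    Contributions are computed on the hydrogen-complete molecule and each
    explicit-from-implicit hydrogen's share is folded into its heavy
    neighbour, so the returned vector sums to the molecule-level Crippen
    logP.
    """
    mol = parse_mol(smiles)
    n_heavy = mol.GetNumAtoms()
    molh = Chem.AddHs(mol)
    contribs = rdMolDescriptors._CalcCrippenContribs(molh)
    per_atom = [0.0] * n_heavy
    for atom in molh.GetAtoms():
        logp = contribs[atom.GetIdx()][0]
        if atom.GetIdx() >= n_heavy:  # hydrogen added by AddHs
            per_atom[atom.GetNeighbors()[0].GetIdx()] += logp
        else:
            per_atom[atom.GetIdx()] += logp
    return per_atom


def crippen_record(smiles: str, record_id: str = "crippen") -> MoleculeRecord:
    """Per-atom Crippen contributions packaged as a PER_ATOM record."""
    scores = crippen_scores(smiles)
    return MoleculeRecord(
        smiles=smiles,
        scores=list(scores),
        attributes={
            "method": "Crippen logP contributions",
            "logP": f"{math.fsum(scores):.3f}",
        },
        id=record_id,
    )


def make_fixtures(
    n: int, seed: int, method: str = "crippen"
) -> list[MoleculeRecord]:
    """Deterministic demo records: ``n`` molecules from the built-in
    drug-like list with scores from one of three generators.

    ``method``:

    * ``"crippen"`` — per-atom Wildman-Crippen logP contributions;
    * ``"substitution"`` — per-token sensitivity scores against the bundled
      Crippen-logP toy predictor;
    * ``"random"`` — seeded standard-normal per-token scores.

    Record *i* depends only on (seed, i), so extending ``n`` keeps earlier
    records identical.
    """
    from .fixtures import DRUG_SMILES

    if n < 1:
        raise ValueError("n must be >= 1")
    if method not in ("crippen", "substitution", "random"):
        raise ValueError(f"unknown method {method!r}")
    predictor = CrippenLogPPredictor()
    records = []
    for i in range(n):
        smiles = DRUG_SMILES[i % len(DRUG_SMILES)]
        rid = f"{method}-{i}"
        if method == "crippen":
            rec = crippen_record(smiles, rid)
        elif method == "substitution":
            scores = substitution_attribution(predictor, smiles)
            rec = MoleculeRecord(
                smiles=smiles,
                scores=scores,
                attributes={
                    "method": "substitution (toy Crippen predictor)",
                    "pred": f"{predictor(smiles):.3f}",
                },
                id=rid,
            )
        else:
            rng = np.random.default_rng([seed, i])
            seq = tokenize(smiles)
            scores = rng.standard_normal(len(seq.tokens)).round(4).tolist()
            rec = MoleculeRecord(
                smiles=smiles,
                scores=scores,
                attributes={"method": "random"},
                id=rid,
            )
        records.append(rec)
    return records
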