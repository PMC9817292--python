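"""JSON input schema: molecule records with scores, attributes and config.

The on-disk format is versioned and deliberately small::

    {
      "schema_version": 1,
      "molecules": [
        {
          "id": "mol-0",                # optional; defaults to record index
          "smiles": "CC(=O)Oc1ccccc1C(=O)O",
          "scores": [0.1, -0.2, ...],   # atom-count or token-count length
          "attributes": {"method": "substitution", "pred": "3.2"},
          "config": {"palette": "red_blue", "thresholds": [0.5]}
        }
      ]
    }

A bare JSON array of molecule objects is accepted as shorthand.  Validation
checks the score-vector length against both admissible lengths (atom count
and token count of the SMILES as written); by default invalid records are
skipped with a logged warning, while strict mode raises on the first
failure.  Unknown fields are preserved and written back on save.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

from .structure import MoleculeParseError, parse_mol
from .tokenizer import TokenizationError, tokenize

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1

__all__ = [
    "MoleculeRecord",
    "RecordValidationError",
    "load_records",
    "save_records",
]


class RecordValidationError(ValueError):
    """A record failed schema validation; carries the record id."""

    def __init__(self, record_id: str, reason: str):
        super().__init__(f"record {record_id!r}: {reason}")
        self.record_id = record_id
        self.reason = reason


@dataclass
class MoleculeRecord:
    """One molecule: SMILES, raw score vector, attribute rows, overrides."""

    smiles: str
    scores: list[float]
    attributes: dict[str, str] = field(default_factory=dict)
    config_override: dict[str, Any] = field(default_factory=dict)
    id: str = ""
    extra: dict[str, Any] = field(default_factory=dict)

    def to_json(self) -> dict[str, Any]:
        obj: dict[str, Any] = {"id": self.id, "smiles": self.smiles,
                               "scores": list(self.scores)}
        if self.attributes:
            obj["attributes"] = dict(self.attributes)
        if self.config_override:
            obj["config"] = dict(self.config_override)
        obj.update(self.extra)
        return obj


def _validate_one(obj: dict[str, Any], index: int) -> MoleculeRecord:
    rid = str(obj.get("id", index))
    if not isinstance(obj, dict):
        raise RecordValidationError(rid, "record must be a JSON object")
    smiles = obj.get("smiles")
    if not isinstance(smiles, str) or not smiles:
        raise RecordValidationError(rid, "missing or empty 'smiles'")
    scores = obj.get("scores")
    if not isinstance(scores, list) or not all(
        isinstance(x, (int, float)) and not isinstance(x, bool) for x in scores
    ):
        raise RecordValidationError(rid, "'scores' must be a list of numbers")
    try:
        seq = tokenize(smiles)
        mol = parse_mol(smiles)
    except (TokenizationError, MoleculeParseError) as exc:
        raise RecordValidationError(rid, str(exc)) from exc
    n_atoms, n_tokens = mol.GetNumAtoms(), len(seq.tokens)
    if len(scores) not in (n_atoms, n_tokens):
        raise RecordValidationError(
            rid,
            f"scores length {len(scores)} matches neither the atom count "
            f"({n_atoms}) nor the token count ({n_tokens})",
        )
    attributes = obj.get("attributes", {})
    if not isinstance(attributes, dict):
        raise RecordValidationError(rid, "'attributes' must be an object")
    config = obj.get("config", {})
    if not isinstance(config, dict):
        raise RecordValidationError(rid, "'config' must be an object")
    known = {"id", "smiles", "scores", "attributes", "config"}
    extra = {k: v for k, v in obj.items() if k not in known}
    return MoleculeRecord(
        smiles=smiles,
        scores=[float(x) for x in scores],
        attributes={str(k): str(v) for k, v in attributes.items()},
        config_override=config,
        id=rid,
        extra=extra,
    )


def load_records(path: str | Path, strict: bool = False) -> list[MoleculeRecord]:
    """Load and validate molecule records from a JSON file.

    Default mode skips invalid records with a logged warning; ``strict``
    raises :class:`RecordValidationError` on the first failure.  Malformed
    JSON raises ``json.JSONDecodeError`` and an empty molecule list raises
    ``ValueError``.
    """
    path = Path(path)
    with open(path) as fh:
        doc = json.load(fh)
    if isinstance(doc, dict):
        molecules = doc.get("molecules")
        if not isinstance(molecules, list):
            raise ValueError(f"{path}: top-level object lacks a 'molecules' array")
    elif isinstance(doc, list):
        molecules = doc
    else:
        raise ValueError(f"{path}: expected a JSON object or array")
    if not molecules:
        raise ValueError(f"{path}: no molecule records")

    records: list[MoleculeRecord] = []
    for i, obj in enumerate(molecules):
        try:
            records.append(_validate_one(obj, i))
        except RecordValidationError as exc:
            if strict:
                raise
            logger.warning("skipping invalid record: %s", exc)
    if not records:
        raise ValueError(f"{path}: every record failed validation")
    return records


def save_records(records: Sequence[MoleculeRecord], path: str | Path) -> None:
    """Write records as a versioned JSON document (inverse of load)."""
    doc = {
        "schema_version": SCHEMA_VERSION,
        "molecules": [r.to_json() for r in records],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")
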