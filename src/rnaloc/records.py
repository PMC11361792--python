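"""Core record types: an RNA sequence with optional structures and labels.

The six localization compartments are fixed in the order used throughout the
package (label tables, prediction CSVs, model outputs):
Nucleus, Exosome, Cytosol, Ribosome, Membrane, ER.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import MalformedRecordError, StructureMismatchError

logger = logging.getLogger(__name__)

LABEL_NAMES: tuple[str, ...] = (
    "nucleus",
    "exosome",
    "cytosol",
    "ribosome",
    "membrane",
    "er",
)
N_LABELS = len(LABEL_NAMES)

ALPHABET = "ACGUN"
_SANITIZE_TABLE = {c: c for c in "ACGU"}
_SANITIZE_TABLE["T"] = "U"


def sanitize_sequence(raw: str) -> str:
    """Normalize a raw nucleotide string to the {A,C,G,U,N} alphabet.

    Uppercases, maps T to U (DNA input is accepted), and maps every other
    character to N. Length is preserved.

    Raises
    ------
    MalformedRecordError
        If `raw` is empty.
    """
    if not raw:
        raise MalformedRecordError("empty sequence")
    return "".join(_SANITIZE_TABLE.get(c, "N") for c in raw.upper())


@dataclass
class RnaRecord:
    """An identified RNA sequence with optional structures and labels.

    Attributes
    ----------
    id : str
        Unique identifier (first whitespace token of the FASTA header).
    sequence : str
        Sanitized sequence over {A, C, G, U, N}.
    structures : dict[str, str]
        Dot-bracket strings keyed by the source that produced them
        (e.g. ``"nussinov"``, ``"rnafold"``); each must match the sequence
        length. The model consumes two structure sources; when only one is
        available it is reused for both graph branches.
    labels : np.ndarray | None
        Binary vector of length 6 in the fixed compartment order, or None.
    """

    id: str
    sequence: str
    structures: dict[str, str] = field(default_factory=dict)
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.sequence = sanitize_sequence(self.sequence)
        for source, db in self.structures.items():
            self._check_structure(source, db)
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int64)
            if self.labels.shape != (N_LABELS,):
                raise MalformedRecordError(
                    f"record {self.id!r}: labels must have length {N_LABELS}"
                )
            if not np.isin(self.labels, (0, 1)).all():
                raise MalformedRecordError(f"record {self.id!r}: labels must be 0/1")
            if not self.labels.any():
                logger.info("record %s has an all-zero label vector", self.id)

    def _check_structure(self, source: str, db: str) -> None:
        if len(db) != len(self.sequence):
            raise StructureMismatchError(
                f"record {self.id!r}: structure from {source!r} has length "
                f"{len(db)} but sequence has length {len(self.sequence)}"
            )

    def set_structure(self, source: str, db: str) -> None:
        self._check_structure(source, db)
        self.structures[source] = db

    def __len__(self) -> int:
        return len(self.sequence)
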