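"""Readers and writers for the package's plain-text formats.

* FASTA (via Biopython): record id = first whitespace token of the header.
* Structure file (Vienna-style): per record a ``>id`` line, the sequence
  line, and the dot-bracket line (an optional trailing energy in parentheses
  is ignored).
* Labels: TSV with header ``id nucleus exosome cytosol ribosome membrane er``
  and 0/1 cells.
* Predictions: CSV with six probability columns (6 decimal places) and six
  binarized label columns.
"""

from __future__ import annotations

import csv
import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import DataError, MalformedRecordError
from .metrics import binarize
from .records import LABEL_NAMES, RnaRecord

logger = logging.getLogger(__name__)


def read_fasta(path: str | Path) -> list[RnaRecord]:
    """Read FASTA into records (order-preserving, sequences sanitized).

    Duplicate ids are an error; an empty file yields an empty list with a
    warning.
    """
    path = Path(path)
    records: list[RnaRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise MalformedRecordError(f"duplicate record id {entry.id!r} in {path}")
        seen.add(entry.id)
        if not str(entry.seq):
            raise MalformedRecordError(f"record {entry.id!r} has an empty sequence")
        records.append(RnaRecord(id=entry.id, sequence=str(entry.seq)))
    if not records:
        logger.warning("no records found in %s", path)
    return records


def write_fasta(records: list[RnaRecord], path: str | Path,
                width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


_ENERGY_SUFFIX = re.compile(r"\s*\([-+0-9.\s]+\)\s*$")


def read_structures(path: str | Path, records: list[RnaRecord],
                    source: str) -> list[RnaRecord]:
    """Attach dot-bracket structures from a Vienna-style file.

    Each block is ``>id`` / sequence / dot-bracket; ids must refer to known
    records. A trailing energy annotation on the structure line is stripped.
    """
    by_id = {rec.id: rec for rec in records}
    lines = Path(path).read_text().splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if not line.startswith(">"):
            raise DataError(f"{path}: expected '>' header at line {i + 1}")
        rid = line[1:].split()[0]
        if i + 2 >= len(lines):
            raise DataError(f"{path}: truncated record {rid!r} at line {i + 1}")
        db = _ENERGY_SUFFIX.sub("", lines[i + 2].strip())
        if rid not in by_id:
            raise DataError(f"{path}: unknown record id {rid!r} at line {i + 1}")
        by_id[rid].set_structure(source, db)
        i += 3
    return records


def write_structures(records: list[RnaRecord], path: str | Path,
                     source: str) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n{rec.structures[source]}\n")


def read_labels(path: str | Path) -> dict[str, np.ndarray]:
    """Read the 6-label TSV into a map id -> binary vector.

    Extra columns are ignored with a warning; a non-binary cell is an error
    naming the offending cell.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    expected = ["id", *LABEL_NAMES]
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing required columns {missing}")
    extra = [c for c in df.columns if c not in expected]
    if extra:
        logger.warning("%s: ignoring extra columns %s", path, extra)
    out: dict[str, np.ndarray] = {}
    for row_idx, row in df.iterrows():
        values = []
        for name in LABEL_NAMES:
            cell = str(row[name]).strip()
            if cell not in ("0", "1"):
                raise DataError(
                    f"{path}: non-binary value {cell!r} in column {name!r}, "
                    f"row {row_idx + 2} (id {row['id']!r})"
                )
            values.append(int(cell))
        if row["id"] in out:
            raise DataError(f"{path}: duplicate id {row['id']!r}")
        out[str(row["id"])] = np.array(values, dtype=np.int64)
    return out


def attach_labels(records: list[RnaRecord],
                  labels: dict[str, np.ndarray]) -> list[RnaRecord]:
    """Attach label vectors to records by id; a missing id is a data error."""
    for rec in records:
        if rec.id not in labels:
            raise DataError(f"no labels for record id {rec.id!r}")
        rec.labels = labels[rec.id]
    return records


def write_labels(records: list[RnaRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(LABEL_NAMES) + "\n")
        for rec in records:
            fh.write(rec.id + "\t" + "\t".join(str(int(v)) for v in rec.labels)
                     + "\n")


def write_predictions(
    records: list[RnaRecord],
    probs: np.ndarray,
    path: str | Path,
    threshold: float | np.ndarray = 0.5,
) -> None:
    """CSV: id, six probabilities (6 decimals), six binarized labels."""
    Z = binarize(probs, threshold)
    header = (
        ["id"]
        + [f"{name}_prob" for name in LABEL_NAMES]
        + list(LABEL_NAMES)
    )
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for rec, p, z in zip(records, probs, Z):
            writer.writerow(
                [rec.id] + [f"{v:.6f}" for v in p] + [int(v) for v in z]
            )


def read_predictions(path: str | Path) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Read a predictions CSV back into (ids, probabilities, labels)."""
    df = pd.read_csv(path)
    ids = [str(v) for v in df["id"]]
    probs = df[[f"{n}_prob" for n in LABEL_NAMES]].to_numpy(dtype=float)
    labels = df[list(LABEL_NAMES)].to_numpy(dtype=np.int64)
    return ids, probs, labels
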