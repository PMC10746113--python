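"""AAindex1 flat-file parsing and the usable-index pool.

AAindex1 assigns one real value per standard amino acid for each of a
few hundred physicochemical/biochemical properties.  Records are
terminated by ``//``; the ``I`` record carries two rows of ten values in
the canonical column order A/L R/K N/M D/F C/P Q/S E/T G/W H/Y I/V.
Entries with missing (``NA``) values are retained but excluded from the
*usable* pool that downstream encoding draws from.
"""

from __future__ import annotations

import difflib
import math
from dataclasses import dataclass, field
from typing import IO, Iterator

RESIDUES = "ARNDCQEGHILKMFPSTWYV"
#: column order of the I record: row 1 gives the first residue of each
#: pair, row 2 the second.
_I_ROW1 = "ARNDCQEGHI"
_I_ROW2 = "LKMFPSTWYV"


class AAIndexParseError(ValueError):
    """Raised when an AAindex1 record is structurally malformed."""


class UnknownAccessionError(KeyError):
    """Raised on lookup of an accession absent from the pool."""


@dataclass(frozen=True)
class AminoAcidIndex:
    """One AAindex1 entry.

    ``values`` maps each one-letter residue code to its index value;
    missing values are NaN and make the entry incomplete.  ``extra``
    preserves the non-numeric record lines (references, correlations)
    as opaque text.
    """

    accession: str
    description: str
    values: dict[str, float]
    extra: tuple[str, ...] = field(default_factory=tuple, repr=False)

    @property
    def complete(self) -> bool:
        return all(
            aa in self.values and math.isfinite(self.values[aa]) for aa in RESIDUES
        )

    def value_array(self):
        import numpy as np

        return np.array([self.values[aa] for aa in RESIDUES], dtype=float)


class IndexPool:
    """Ordered collection of AAindex entries with deterministic (file) order."""

    def __init__(self, entries: list[AminoAcidIndex]):
        self.entries = list(entries)
        seen: set[str] = set()
        for e in self.entries:
            if not e.accession:
                raise AAIndexParseError("entry with empty accession")
            if e.accession in seen:
                raise AAIndexParseError(f"duplicate accession {e.accession!r}")
            seen.add(e.accession)
        self._by_acc = {e.accession: e for e in self.entries}

    @property
    def usable(self) -> list[AminoAcidIndex]:
        return [e for e in self.entries if e.complete]

    @property
    def usable_accessions(self) -> list[str]:
        return [e.accession for e in self.entries if e.complete]

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[AminoAcidIndex]:
        return iter(self.entries)

    def __contains__(self, accession: str) -> bool:
        return accession in self._by_acc

    def __getitem__(self, accession: str) -> AminoAcidIndex:
        return get_index(self, accession)

    def pool_order(self, accessions) -> list[str]:
        """Sort accessions into file order (the canonical descriptor order)."""
        rank = {e.accession: i for i, e in enumerate(self.entries)}
        return sorted(accessions, key=lambda a: rank[a])

    def to_flatfile(self) -> str:
        return "".join(_format_record(e) for e in self.entries)

    def to_frame(self):
        """Normalized table: accession, description, 20 residue columns, complete."""
        import pandas as pd

        rows = []
        for e in self.entries:
            row = {"accession": e.accession, "description": e.description}
            for aa in RESIDUES:
                row[aa] = e.values.get(aa, float("nan"))
            row["complete"] = e.complete
            rows.append(row)
        return pd.DataFrame(rows)


def parse_aaindex(stream: IO[str] | str) -> IndexPool:
    """Parse an AAindex1 flat file (text stream, file path, or raw text).

    Returns every record; entries with ``NA`` or non-numeric values are
    flagged incomplete and excluded from :attr:`IndexPool.usable`.
    Raises :class:`AAIndexParseError` naming the offending accession on
    a malformed record (missing H line, wrong value count).
    """
    if hasattr(stream, "read"):
        text = stream.read()
    else:
        text = str(stream)
        if "\n" not in text and text.strip() and not text.lstrip().startswith("H "):
            # a file path rather than flat-file content
            with open(text, encoding="utf-8") as fh:
                text = fh.read()

    entries: list[AminoAcidIndex] = []
    for record in _split_records(text):
        entries.append(_parse_record(record))
    return IndexPool(entries)


def get_index(pool: IndexPool, accession: str) -> AminoAcidIndex:
    """Exact-accession lookup; unknown accessions report nearest matches."""
    try:
        return pool._by_acc[accession]
    except KeyError:
        near = difflib.get_close_matches(accession, pool._by_acc, n=3, cutoff=0.6)
        hint = f"; nearest: {', '.join(near)}" if near else ""
        raise UnknownAccessionError(
            f"accession {accession!r} not in pool{hint}"
        ) from None


def _split_records(text: str) -> Iterator[list[str]]:
    record: list[str] = []
    for line in text.splitlines():
        if line.startswith("//"):
            if any(l.strip() for l in record):
                yield record
            record = []
        else:
            record.append(line)
    if any(l.strip() for l in record):
        yield record


def _parse_record(lines: list[str]) -> AminoAcidIndex:
    accession = ""
    description_parts: list[str] = []
    value_rows: list[list[str]] = []
    extra: list[str] = []
    key = ""
    for line in lines:
        if line[:2].rstrip() and not line.startswith(" "):
            key = line[0]
            body = line[2:]
        else:
            body = line.lstrip()
        if key == "H":
            accession = body.strip()
        elif key == "D":
            description_parts.append(body.strip())
        elif key == "I":
            if body.strip() and not body.lstrip().startswith("A/L"):
                value_rows.append(body.split())
        else:
            extra.append(line)
    if not accession:
        snippet = next((l for l in lines if l.strip()), "")[:40]
        raise AAIndexParseError(f"record missing H line (starts {snippet!r})")
    if len(value_rows) != 2 or any(len(r) != 10 for r in value_rows):
        raise AAIndexParseError(
            f"entry {accession}: I record must carry 2 rows of 10 values, "
            f"got rows of {[len(r) for r in value_rows]}"
        )
    values: dict[str, float] = {}
    for residues, row in zip((_I_ROW1, _I_ROW2), value_rows):
        for aa, tok in zip(residues, row):
            try:
                values[aa] = float(tok)
            except ValueError:
                values[aa] = float("nan")
    return AminoAcidIndex(
        accession=accession,
        description=" ".join(description_parts),
        values=values,
        extra=tuple(extra),
    )


def _format_record(e: AminoAcidIndex) -> str:
    def fmt(v: float) -> str:
        return "NA" if not math.isfinite(v) else f"{v:.17g}"

    row1 = "    ".join(fmt(e.values.get(aa, float("nan"))) for aa in _I_ROW1)
    row2 = "    ".join(fmt(e.values.get(aa, float("nan"))) for aa in _I_ROW2)
    lines = [f"H {e.accession}", f"D {e.description}"]
    lines += list(e.extra)
    lines += [
        "I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V",
        f"     {row1}",
        f"     {row2}",
        "//",
    ]
    return "\n".join(lines) + "\n"
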