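"""Dataset IO: wild-type FASTA, variant CSV tables, the packaged study table.

The packaged table (``data/table4.csv``) holds the 21 measured AT-ATA
variants (wild type plus point-mutation combinations of 10 sites) with
thermal half-lives at 40 °C in minutes, and membership flags for the
two overlapping study datasets: dataset 1 (13 variants) and dataset 2
(all 21).  Positions are 1-based on the user-supplied wild-type FASTA.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .model import SarDataset
from .mutations import Variant, parse_label


def load_wild_type(fasta_path: str | Path) -> str:
    """Read the single-record wild-type FASTA; returns the sequence."""
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(records) != 1:
        raise ValueError(
            f"{fasta_path}: expected exactly one FASTA record, found {len(records)}"
        )
    return str(records[0].seq).upper()


def load_variant_table(csv_path: str | Path) -> pd.DataFrame:
    """Read a variant CSV (columns: label, half_life_min, optional flags)."""
    frame = pd.read_csv(csv_path)
    missing = {"label", "half_life_min"} - set(frame.columns)
    if missing:
        raise ValueError(f"{csv_path}: missing columns {sorted(missing)}")
    return frame


def load_table4(dataset: int | None = None) -> pd.DataFrame:
    """The packaged 21-variant study table; ``dataset`` 1 or 2 filters rows."""
    with resources.files("fftsar.data").joinpath("table4.csv").open() as fh:
        frame = pd.read_csv(fh)
    if dataset is None:
        return frame
    if dataset not in (1, 2):
        raise ValueError(f"dataset must be 1 or 2, got {dataset}")
    return frame[frame[f"dataset{dataset}"] == 1].reset_index(drop=True)


def build_dataset(
    wt_sequence: str, table: pd.DataFrame, name: str = ""
) -> SarDataset:
    """Materialize a SarDataset: parse labels, apply mutations to the WT."""
    variants = []
    for row in table.itertuples(index=False):
        muts = parse_label(row.label)
        variants.append(
            Variant.from_mutations(wt_sequence, muts, half_life=float(row.half_life_min))
        )
    return SarDataset(variants=tuple(variants), name=name)
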