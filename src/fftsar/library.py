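"""Combinatorial mutant libraries and half-life prediction.

Given the n distinct single-point mutations observed in a study, the
full library is every subset of them: 2^n variants including the wild
type.  A persisted model predicts each variant's half-life; variants
already measured are flagged observed, the rest are novel candidates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .aaindex import IndexPool
from .descriptors import feature_matrix
from .model import ModelError, PLSPredictor, SarDataset
from .mutations import MutationSpec, MutationError, Variant
from .spectra import SpectrumOptions


@dataclass
class PredictionTable:
    """Per-variant predictions plus library bookkeeping."""

    frame: pd.DataFrame  # label, predicted_half_life_min, observed
    n_total: int
    n_observed: int
    n_novel: int
    threshold_min: float | None = None
    n_above_threshold: int | None = None

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def enumerate_library(
    single_mutations: Sequence[MutationSpec],
    wt_sequence: str,
) -> list[Variant]:
    """All 2^n combinations of the observed single mutations.

    Variants come in deterministic bitmask order (bit i = mutation i of
    the input list, ascending mask), starting with the wild type; labels
    are canonical.  Singles must sit at distinct positions.
    """
    singles = list(single_mutations)
    positions = [m.position for m in singles]
    if len(set(positions)) != len(positions):
        raise MutationError("single mutations must be at distinct positions")
    out: list[Variant] = []
    for mask in range(2 ** len(singles)):
        chosen = frozenset(m for i, m in enumerate(singles) if mask >> i & 1)
        out.append(Variant.from_mutations(wt_sequence, chosen))
    return out


def predict_library(
    predictor: PLSPredictor,
    accessions: Sequence[str],
    library: Sequence[Variant],
    dataset: SarDataset,
    pool: IndexPool,
    options: SpectrumOptions | None = None,
    threshold_min: float | None = None,
    strict_threshold: bool = True,
) -> PredictionTable:
    """Predict half-life for every library variant and flag observed ones.

    ``threshold_min`` additionally counts variants predicted above it
    (strictly by default).  Negative predictions are possible under
    linear extrapolation and are reported with a warning, not clipped.
    """
    if not library:
        raise ValueError("empty library")
    lengths = {len(v.sequence) for v in library}
    if lengths != {dataset.seq_length}:
        raise ModelError(
            f"library sequence lengths {sorted(lengths)} do not match "
            f"training length {dataset.seq_length}"
        )
    X = feature_matrix([v.sequence for v in library], accessions, pool, options)
    preds = predictor.predict(X)
    if np.any(preds < 0):
        warnings.warn(
            f"{int(np.sum(preds < 0))} variants predicted with negative "
            "half-life (linear extrapolation); values reported unclipped",
            stacklevel=2,
        )
    observed_labels = set(dataset.labels)
    observed = np.array([v.label in observed_labels for v in library])
    frame = pd.DataFrame(
        {
            "label": [v.label for v in library],
            "predicted_half_life_min": preds,
            "observed": observed,
        }
    )
    n_above = None
    if threshold_min is not None:
        if strict_threshold:
            n_above = int(np.sum(preds > threshold_min))
        else:
            n_above = int(np.sum(preds >= threshold_min))
    return PredictionTable(
        frame=frame,
        n_total=len(library),
        n_observed=int(observed.sum()),
        n_novel=int((~observed).sum()),
        threshold_min=threshold_min,
        n_above_threshold=n_above,
    )


def dataset_single_mutations(dataset: SarDataset) -> list[MutationSpec]:
    """Distinct single-point mutations occurring anywhere in a dataset,
    ordered by position."""
    seen: dict[int, MutationSpec] = {}
    for v in dataset.variants:
        for m in v.mutations:
            if m.position in seen and seen[m.position] != m:
                raise MutationError(
                    f"two different mutations at position {m.position}: "
                    f"{seen[m.position]} vs {m}"
                )
            seen[m.position] = m
    return [seen[p] for p in sorted(seen)]
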