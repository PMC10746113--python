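"""Descriptor search: single-index screen, top-K combination, greedy iteration.

Three strategies of increasing ambition:

* ``single`` — LOOCV every usable index alone and rank by cvRMSE.
* ``combine`` — take the top-K single indices and exhaustively LOOCV
  every subset of size <= Q (31 candidates for K = Q = 5); report
  ranked by R^2, then cvRMSE.
* ``iterate`` — greedy forward selection: start from the best single
  index, then repeatedly extend the incumbent chain with whichever
  remaining index most lowers cvRMSE, for Q rounds.  The pool shrinks
  by one per round.

Selection always minimizes cvRMSE; both metrics are always reported.
Ties break by pool (file) order for determinism.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .aaindex import IndexPool, get_index
from .descriptors import enumerate_combinations
from .model import ModelFit, SarDataset, loocv_evaluate
from .spectra import SpectrumOptions, spectral_features


class SelectionError(ValueError):
    pass


@dataclass(frozen=True)
class SelectionConfig:
    """Strategy knobs.

    max_connections (Q) defaults to 5 for ``combine`` and 3 for
    ``iterate`` when left as None.  ``early_stop`` lets the greedy
    search keep the incumbent when no extension improves cvRMSE instead
    of always running Q rounds.
    """

    strategy: str = "single"
    top_k: int = 5
    max_connections: int | None = None
    n_components: int | str = "auto"
    early_stop: bool = False
    record_candidates: bool = False

    def __post_init__(self):
        if self.strategy not in ("single", "combine", "iterate"):
            raise SelectionError(f"unknown strategy {self.strategy!r}")
        if self.top_k < 1:
            raise SelectionError("top_k must be >= 1")
        if self.max_connections is not None and self.max_connections < 1:
            raise SelectionError("max_connections must be >= 1")

    @property
    def q(self) -> int:
        if self.max_connections is not None:
            return self.max_connections
        return 3 if self.strategy == "iterate" else 5


@dataclass
class RoundRecord:
    round: int
    n_candidates: int
    winner: str
    cvrmse: float
    r2: float
    improved: bool
    candidates: list[tuple[str, float, float]] = field(default_factory=list)


@dataclass
class SelectionTrace:
    rounds: list[RoundRecord]
    final: ModelFit


class SpectraCache:
    """Per-accession spectra matrices for one dataset, built on demand.

    The selection strategies evaluate hundreds of descriptors over the
    same variants; each index's (variants x bins) block is computed once
    and candidate feature matrices are horizontal stacks.
    """

    def __init__(self, dataset: SarDataset, pool: IndexPool, options: SpectrumOptions | None = None):
        self.dataset = dataset
        self.pool = pool
        self.options = options
        self._blocks: dict[str, np.ndarray] = {}

    def block(self, accession: str) -> np.ndarray:
        if accession not in self._blocks:
            index = get_index(self.pool, accession)
            self._blocks[accession] = np.vstack(
                [spectral_features(s, index, self.options) for s in self.dataset.sequences]
            )
        return self._blocks[accession]

    def matrix(self, accessions: Sequence[str]) -> np.ndarray:
        return np.hstack([self.block(a) for a in accessions])

    def evaluate(self, accessions: Sequence[str], n_components) -> ModelFit:
        return loocv_evaluate(
            self.dataset, accessions, self.pool, n_components, self.options,
            X=self.matrix(accessions),
        )


def screen_single_indices(
    dataset: SarDataset,
    pool: IndexPool,
    n_components: int | str = "auto",
    options: SpectrumOptions | None = None,
    cache: SpectraCache | None = None,
) -> list[ModelFit]:
    """LOOCV each usable index alone; ranked ascending by cvRMSE.

    Ties keep pool (file) order: the sort is stable over the pool
    iteration order.
    """
    accs = pool.usable_accessions
    if not accs:
        raise SelectionError("no usable (complete) indices in pool")
    cache = cache or SpectraCache(dataset, pool, options)
    fits = [cache.evaluate((acc,), n_components) for acc in accs]
    return sorted(fits, key=lambda f: f.cvrmse)


def combine_top_indices(
    dataset: SarDataset,
    pool: IndexPool,
    config: SelectionConfig | None = None,
    options: SpectrumOptions | None = None,
) -> list[ModelFit]:
    """Exhaustive subsets of the top-K single indices, ranked by R^2.

    Screens singles by cvRMSE, keeps the top K, evaluates all non-empty
    subsets of size <= Q (each subset in canonical pool order), and
    ranks descending by R^2 then ascending by cvRMSE.
    """
    config = config or SelectionConfig(strategy="combine")
    cache = SpectraCache(dataset, pool, options)
    singles = screen_single_indices(dataset, pool, config.n_components, options, cache)
    if config.top_k > len(singles):
        raise SelectionError(
            f"top_k={config.top_k} exceeds the {len(singles)} usable indices"
        )
    top = [f.accessions[0] for f in singles[: config.top_k]]
    subsets = enumerate_combinations(pool.pool_order(top), config.q)
    fits = [cache.evaluate(subset, config.n_components) for subset in subsets]
    return sorted(fits, key=lambda f: (-f.r2, f.cvrmse))


def iterative_connection(
    dataset: SarDataset,
    pool: IndexPool,
    config: SelectionConfig | None = None,
    options: SpectrumOptions | None = None,
) -> SelectionTrace:
    """Greedy forward chain growth, Q rounds, minimizing cvRMSE.

    Round 1 picks the best single index; round r+1 evaluates the
    incumbent chain extended by each remaining pool index and keeps the
    best extension.  With ``early_stop`` the trace stops at the first
    round that fails to improve and the incumbent is returned;
    otherwise all Q rounds run (improvement flags are recorded either
    way).
    """
    config = config or SelectionConfig(strategy="iterate")
    usable = pool.usable_accessions
    if not usable:
        raise SelectionError("no usable (complete) indices in pool")
    q = min(config.q, len(usable))
    cache = SpectraCache(dataset, pool, options)

    remaining = list(usable)
    incumbent: list[str] = []
    incumbent_fit: ModelFit | None = None
    rounds: list[RoundRecord] = []

    for r in range(1, q + 1):
        best_fit, best_acc = None, None
        candidates: list[tuple[str, float, float]] = []
        for acc in remaining:
            fit = cache.evaluate(tuple(incumbent) + (acc,), config.n_components)
            if config.record_candidates:
                candidates.append((acc, fit.cvrmse, fit.r2))
            if best_fit is None or fit.cvrmse < best_fit.cvrmse:
                best_fit, best_acc = fit, acc
        improved = incumbent_fit is None or best_fit.cvrmse < incumbent_fit.cvrmse
        rounds.append(
            RoundRecord(
                round=r,
                n_candidates=len(remaining),
                winner=best_acc,
                cvrmse=best_fit.cvrmse,
                r2=best_fit.r2,
                improved=improved,
                candidates=candidates,
            )
        )
        if config.early_stop and not improved:
            break
        incumbent.append(best_acc)
        remaining.remove(best_acc)
        incumbent_fit = best_fit

    return SelectionTrace(rounds=rounds, final=incumbent_fit)


def results_to_frame(fits: Sequence[ModelFit]):
    """Ranked results as a table: accession chain, cvRMSE, R^2."""
    import pandas as pd

    return pd.DataFrame(
        {
            "descriptor": [f.label for f in fits],
            "n_indices": [len(f.accessions) for f in fits],
            "cvrmse": [f.cvrmse for f in fits],
            "r2": [f.r2 for f in fits],
            "n_components": [f.n_components for f in fits],
        }
    )
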