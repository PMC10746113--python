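"""Extended-sequence descriptors: concatenated protein spectra.

An extended descriptor chains the spectra of one variant under several
indices into a single feature vector.  Descriptor identity is the
accession *set*: chaining spectrum_i then spectrum_j and the reverse
carry the same information to a linear model, so enumeration emits each
subset once, in canonical (pool/file) order.  The number of candidate
descriptors from a pool of N indices with at most Q connections is

    sum_{q=1..Q} C(N, q)   ( = 2^N - 1 when Q = N ).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .aaindex import IndexPool, get_index
from .spectra import SpectrumOptions, spectral_features

#: enumerating subsets of a pool larger than this requires an explicit
#: override -- 2^N grows past anything a screen should materialize.
MAX_ENUMERABLE_POOL = 20


@dataclass(frozen=True)
class ExtendedDescriptor:
    """Ordered accession chain plus the concatenated feature vector."""

    accessions: tuple[str, ...]
    features: np.ndarray
    block_lengths: tuple[int, ...]

    def __post_init__(self):
        if not self.accessions:
            raise ValueError("descriptor needs at least one accession")
        if len(set(self.accessions)) != len(self.accessions):
            raise ValueError(f"duplicate accessions in descriptor: {self.accessions}")
        if len(self.features) != sum(self.block_lengths):
            raise ValueError("feature length does not match block lengths")

    @property
    def label(self) -> str:
        return "-".join(self.accessions)


@dataclass(frozen=True)
class CombinationSpace:
    """Pool size N and the cap Q on spectra per descriptor."""

    pool_size: int
    max_connections: int

    def __post_init__(self):
        if not (1 <= self.max_connections <= self.pool_size):
            raise ValueError(
                f"need 1 <= max_connections <= pool_size, got "
                f"Q={self.max_connections}, N={self.pool_size}"
            )


def make_ext_seq(
    variant_sequence: str,
    accessions: Sequence[str],
    pool: IndexPool,
    options: SpectrumOptions | None = None,
    variant_label: str = "",
) -> ExtendedDescriptor:
    """Concatenate the variant's spectra under each accession, in order."""
    accessions = tuple(accessions)
    if len(set(accessions)) != len(accessions):
        raise ValueError(f"duplicate accessions: {accessions}")
    blocks = [
        spectral_features(variant_sequence, get_index(pool, acc), options, variant_label)
        for acc in accessions
    ]
    return ExtendedDescriptor(
        accessions=accessions,
        features=np.concatenate(blocks),
        block_lengths=tuple(len(b) for b in blocks),
    )


def feature_matrix(
    sequences: Sequence[str],
    accessions: Sequence[str],
    pool: IndexPool,
    options: SpectrumOptions | None = None,
) -> np.ndarray:
    """(variants x features) matrix for one descriptor over a dataset."""
    return np.vstack(
        [make_ext_seq(s, accessions, pool, options).features for s in sequences]
    )


def count_combinations(space: CombinationSpace | int, max_connections: int | None = None) -> int:
    """Number of non-empty index subsets of size <= Q from a pool of N."""
    if not isinstance(space, CombinationSpace):
        space = CombinationSpace(int(space), int(max_connections))
    return sum(math.comb(space.pool_size, q) for q in range(1, space.max_connections + 1))


def enumerate_combinations(
    accessions: Sequence[str],
    max_connections: int,
    allow_large: bool = False,
) -> list[tuple[str, ...]]:
    """All non-empty subsets of size <= Q, by size then lexicographic position.

    Each subset keeps the input (pool) order internally, so two
    orderings of one accession set never both appear.
    """
    accessions = list(accessions)
    if len(set(accessions)) != len(accessions):
        raise ValueError("accessions must be distinct")
    if len(accessions) > MAX_ENUMERABLE_POOL and not allow_large:
        raise ValueError(
            f"refusing to enumerate subsets of a {len(accessions)}-index pool "
            f"(> {MAX_ENUMERABLE_POOL}); pass allow_large=True to override"
        )
    q_max = min(max_connections, len(accessions))
    out: list[tuple[str, ...]] = []
    for q in range(1, q_max + 1):
        out.extend(itertools.combinations(accessions, q))
    return out


def iter_combinations(
    accessions: Sequence[str], max_connections: int
) -> Iterable[tuple[str, ...]]:
    """Lazy counterpart of :func:`enumerate_combinations` (no size guard)."""
    q_max = min(max_connections, len(accessions))
    for q in range(1, q_max + 1):
        yield from itertools.combinations(list(accessions), q)
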