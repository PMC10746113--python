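"""Mutation strings and variant sequences.

A mutation is written ``<wt><position><new>`` with a 1-based residue
position on the supplied wild-type sequence (e.g. ``F115L``); multi-site
variants join specs with underscores, sorted by ascending position
(``F115L_L118T``).  The wild type itself is labeled ``WT``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

WT_LABEL = "WT"

_MUTATION_RE = re.compile(r"^([A-Za-z])(\d+)([A-Za-z])$")


class MutationError(ValueError):
    """Malformed mutation string or inconsistent application."""


@dataclass(frozen=True, order=True)
class MutationSpec:
    """Single point substitution: wild-type residue, 1-based position, new residue."""

    position: int
    wt_residue: str
    new_residue: str

    def __post_init__(self):
        if self.wt_residue == self.new_residue:
            raise MutationError(
                f"no-op mutation {self.wt_residue}{self.position}{self.new_residue}"
            )
        if self.position < 1:
            raise MutationError(f"position must be >= 1, got {self.position}")

    def __str__(self) -> str:
        return f"{self.wt_residue}{self.position}{self.new_residue}"


@dataclass(frozen=True)
class Variant:
    """A variant: canonical label, mutation set, derived sequence, optional T1/2 (min)."""

    label: str
    mutations: frozenset[MutationSpec]
    sequence: str
    half_life: float | None = None

    @classmethod
    def from_mutations(
        cls,
        wt_sequence: str,
        mutations: frozenset[MutationSpec] | set[MutationSpec],
        half_life: float | None = None,
    ) -> "Variant":
        muts = frozenset(mutations)
        return cls(
            label=canonical_label(muts),
            mutations=muts,
            sequence=apply_mutations(wt_sequence, muts),
            half_life=half_life,
        )


def parse_mutation(text: str) -> MutationSpec:
    """Parse one ``<letter><digits><letter>`` mutation string."""
    m = _MUTATION_RE.match(text.strip())
    if not m:
        raise MutationError(f"malformed mutation string {text!r}")
    wt, pos, new = m.group(1).upper(), int(m.group(2)), m.group(3).upper()
    return MutationSpec(position=pos, wt_residue=wt, new_residue=new)


def parse_label(label: str) -> frozenset[MutationSpec]:
    """Parse a variant label (``WT`` or underscore-joined mutations)."""
    label = label.strip()
    if label.upper() == WT_LABEL:
        return frozenset()
    specs = [parse_mutation(tok) for tok in label.split("_")]
    positions = [s.position for s in specs]
    if len(set(positions)) != len(positions):
        raise MutationError(f"label {label!r} mutates one position twice")
    return frozenset(specs)


def canonical_label(mutations: frozenset[MutationSpec] | set[MutationSpec]) -> str:
    """``WT`` for the empty set, else specs joined by ``_`` in ascending position."""
    if not mutations:
        return WT_LABEL
    return "_".join(str(m) for m in sorted(mutations))


def apply_mutations(wt_sequence: str, specs) -> str:
    """Apply substitutions to the wild type; verifies each wt residue.

    The empty set returns the wild type unchanged.  Errors name the
    position and expected/found residues on mismatch, and reject two
    specs at one position.
    """
    specs = list(specs)
    positions = [s.position for s in specs]
    if len(set(positions)) != len(positions):
        dup = next(p for p in positions if positions.count(p) > 1)
        raise MutationError(f"conflicting mutations at position {dup}")
    seq = list(wt_sequence)
    for s in specs:
        if s.position > len(seq):
            raise MutationError(
                f"position {s.position} beyond sequence length {len(seq)}"
            )
        found = seq[s.position - 1]
        if found != s.wt_residue:
            raise MutationError(
                f"wild-type mismatch at position {s.position}: "
                f"mutation {s} expects {s.wt_residue!r}, sequence has {found!r}"
            )
        seq[s.position - 1] = s.new_residue
    return "".join(seq)
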