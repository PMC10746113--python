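"""Synthetic index pools and sequence-activity datasets with known truth.

Every downstream module is testable without the real AAindex database:
this module fabricates complete (and optionally incomplete) index
entries, a random wild type, a set of single substitutions, and
half-lives that are an exact linear function of the spectral features
of chosen "planted" indices plus Gaussian noise.  Because the signal is
planted in the model's own feature space, recovery tests (does the
screen rank the planted index first? does greedy search find both
planted indices?) are well-posed.

Defaults mirror the study conditions this pipeline targets: a wild
type of 325 residues, 10 mutated sites, 21 measured variants, and a
noise floor of ~1 min against a signal spread of several minutes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .aaindex import RESIDUES, AminoAcidIndex, IndexPool
from .model import SarDataset
from .mutations import MutationSpec, Variant, parse_label
from .spectra import SpectrumOptions, spectral_features


def make_index_pool(
    n_indices: int,
    seed: int,
    n_incomplete: int = 0,
    prefix: str = "SYN",
) -> IndexPool:
    """Synthetic pool: values i.i.d. standard normal per residue.

    ``n_incomplete`` appends entries with one NA hole each; they count
    in ``entries`` but not in ``usable``.  Accessions are 10
    characters, e.g. ``SYN0000001``.
    """
    if n_indices < 1:
        raise ValueError("n_indices must be >= 1")
    rng = np.random.default_rng(seed)
    entries = []
    total = n_indices + n_incomplete
    for i in range(total):
        acc = f"{prefix}{i + 1:0{10 - len(prefix)}d}"
        vals = {aa: float(v) for aa, v in zip(RESIDUES, rng.standard_normal(20))}
        if i >= n_indices:  # punch one hole
            hole = RESIDUES[int(rng.integers(20))]
            vals[hole] = float("nan")
        entries.append(
            AminoAcidIndex(
                accession=acc,
                description=f"synthetic standard-normal index {i + 1}",
                values=vals,
            )
        )
    return IndexPool(entries)


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one sequence-activity dataset with planted signal.

    weights maps planted accession -> per-feature coefficient vector
    (or None to draw random weights scaled so the planted signal has
    standard deviation ``signal_sd`` across variants).
    """

    wt_length: int = 325
    n_singles: int = 10
    n_variants: int = 21
    planted_accessions: tuple[str, ...] = ()
    weights: dict | None = None
    signal_sd: float = 5.0
    noise_sd: float = 1.0
    seed: int = 0
    spectrum: SpectrumOptions = field(default_factory=SpectrumOptions)


def make_sar_dataset(
    spec: SyntheticSpec, pool: IndexPool
) -> tuple[SarDataset, dict]:
    """Generate a dataset whose y is linear in planted spectral features.

    Returns (dataset, ground_truth).  The variant set is the wild type,
    every single mutant, and random combinations of the singles up to
    ``n_variants``.  y_i = sum_a w_a . features_a(variant_i) + eps_i,
    then shifted to positivity (y <- y - min(y) + 5); the shift is part
    of the returned ground truth.
    """
    for acc in spec.planted_accessions:
        if acc not in pool:
            raise ValueError(f"planted accession {acc} not in pool")
    rng = np.random.default_rng(spec.seed)

    wt = "".join(rng.choice(list(RESIDUES), size=spec.wt_length))
    positions = 1 + rng.choice(spec.wt_length, size=spec.n_singles, replace=False)
    singles = []
    for pos in sorted(int(p) for p in positions):
        wt_aa = wt[pos - 1]
        new_aa = str(rng.choice([aa for aa in RESIDUES if aa != wt_aa]))
        singles.append(MutationSpec(position=pos, wt_residue=wt_aa, new_residue=new_aa))

    combos: list[frozenset[MutationSpec]] = [frozenset()]
    combos += [frozenset({m}) for m in singles]
    seen = set(combos)
    while len(combos) < spec.n_variants:
        size = int(rng.integers(2, max(3, spec.n_singles + 1)))
        pick = frozenset(
            singles[i] for i in rng.choice(spec.n_singles, size=min(size, spec.n_singles), replace=False)
        )
        if pick not in seen:
            seen.add(pick)
            combos.append(pick)
    combos = combos[: spec.n_variants]

    sequences = []
    variants_raw = []
    for muts in combos:
        v = Variant.from_mutations(wt, muts)
        variants_raw.append(v)
        sequences.append(v.sequence)

    # planted linear signal in spectral-feature space
    signal = np.zeros(len(sequences))
    weights_used: dict[str, np.ndarray] = {}
    if spec.planted_accessions:
        blocks = {
            acc: np.vstack(
                [spectral_features(s, pool[acc], spec.spectrum) for s in sequences]
            )
            for acc in spec.planted_accessions
        }
        for acc in spec.planted_accessions:
            B = blocks[acc]
            if spec.weights and acc in spec.weights:
                w = np.asarray(spec.weights[acc], dtype=float)
            else:
                w = rng.standard_normal(B.shape[1])
            contrib = B @ w
            sd = contrib.std()
            if spec.weights is None or acc not in (spec.weights or {}):
                # scale each planted index to contribute signal_sd (split evenly)
                target = spec.signal_sd / np.sqrt(len(spec.planted_accessions))
                if sd > 0:
                    w = w * (target / sd)
                    contrib = B @ w
            weights_used[acc] = w
            signal = signal + contrib

    noise = rng.normal(0.0, spec.noise_sd, size=len(sequences))
    y_raw = signal + noise
    shift = float(-y_raw.min() + 5.0)
    y = y_raw + shift

    variants = tuple(
        Variant(label=v.label, mutations=v.mutations, sequence=v.sequence, half_life=float(yi))
        for v, yi in zip(variants_raw, y)
    )
    dataset = SarDataset(variants=variants, name=f"synthetic-seed{spec.seed}")
    ground_truth = {
        "wild_type": wt,
        "singles": [str(m) for m in singles],
        "planted_accessions": list(spec.planted_accessions),
        "weights": {a: w.tolist() for a, w in weights_used.items()},
        "noise_sd": spec.noise_sd,
        "shift": shift,
        "seed": spec.seed,
    }
    return dataset, ground_truth


def compatible_wild_type(labels, length: int, seed: int = 0) -> str:
    """Random wild type consistent with the wt residues of the given labels.

    Lets the packaged study table be applied without the real enzyme
    sequence: every mutated position carries the label's wild-type
    residue, everything else is random.
    """
    rng = np.random.default_rng(seed)
    seq = list(rng.choice(list(RESIDUES), size=length))
    for label in labels:
        for m in parse_label(label):
            if m.position > length:
                raise ValueError(f"length {length} < mutation position {m.position}")
            seq[m.position - 1] = m.wt_residue
    return "".join(seq)


def write_fixture(
    out_dir: str | Path, spec: SyntheticSpec, pool: IndexPool
) -> dict:
    """Emit FASTA + CSV + AAindex flat file + ground-truth JSON to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dataset, truth = make_sar_dataset(spec, pool)
    (out / "wild_type.fasta").write_text(
        ">synthetic_wild_type\n" + truth["wild_type"] + "\n"
    )
    lines = ["label,half_life_min"]
    lines += [f"{v.label},{v.half_life:.6f}" for v in dataset.variants]
    (out / "variants.csv").write_text("\n".join(lines) + "\n")
    (out / "indices.aaindex1").write_text(pool.to_flatfile())
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=1))
    return truth
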