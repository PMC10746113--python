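"""Physicochemical encoding and the discrete-Fourier protein spectrum.

A variant sequence of length N becomes a real signal s(n) by replacing
each residue with its value under one amino-acid index.  Its protein
spectrum is the modulus of the DFT,

    |S(k)|,  S(k) = sum_n s(n) exp(-2 pi i k n / N),

retained for k = 0..floor(N/2) (the non-redundant half-spectrum of a
real signal).  No windowing, detrending or zero-padding is applied:
point-mutation variants of one study share the wild-type length, so
spectra are directly comparable bin by bin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .aaindex import RESIDUES, AminoAcidIndex


class EncodingError(ValueError):
    """Non-standard residue or unusable index."""


@dataclass(frozen=True)
class SpectrumOptions:
    """Spectrum configuration.

    mode
        ``"half"`` keeps k = 0..floor(N/2) (default); ``"full"`` keeps
        all N amplitude bins for comparison.
    drop_dc
        remove the k = 0 (sequence-sum) term.  Off by default: the DC
        term carries composition information and there is no reason to
        discard it for equal-length variants.
    zscore_index
        z-score the 20 index values across residues before encoding.
        Off by default; raw AAindex values feed the DFT directly.
    """

    mode: str = "half"
    drop_dc: bool = False
    zscore_index: bool = False

    def __post_init__(self):
        if self.mode not in ("half", "full"):
            raise ValueError(f"spectrum mode must be 'half' or 'full', got {self.mode!r}")

    def n_bins(self, seq_length: int) -> int:
        n = seq_length // 2 + 1 if self.mode == "half" else seq_length
        return n - 1 if self.drop_dc else n


@dataclass(frozen=True)
class NumericSequence:
    """Index-encoded signal s(n) for one variant under one index."""

    values: np.ndarray
    source_accession: str = ""
    source_variant: str = ""

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class ProteinSpectrum:
    """Amplitude spectrum |S(k)| of one encoded variant."""

    amplitudes: np.ndarray
    n_input: int
    source_accession: str = ""
    source_variant: str = ""

    def __len__(self) -> int:
        return len(self.amplitudes)


def encode(
    sequence: str,
    index: AminoAcidIndex,
    variant_label: str = "",
    options: SpectrumOptions | None = None,
) -> NumericSequence:
    """Encode an amino-acid string as the signal of index values.

    Rejects non-standard residues (B, Z, X, U, O, gaps) naming the
    1-based position, and incomplete indices.
    """
    if not index.complete:
        raise EncodingError(
            f"index {index.accession} is incomplete (missing residue values)"
        )
    values = dict(index.values)
    if options is not None and options.zscore_index:
        arr = np.array([values[aa] for aa in RESIDUES])
        mu, sd = arr.mean(), arr.std()
        if sd == 0:
            sd = 1.0
        values = {aa: (values[aa] - mu) / sd for aa in RESIDUES}
    out = np.empty(len(sequence), dtype=float)
    for pos, aa in enumerate(sequence):
        try:
            out[pos] = values[aa]
        except KeyError:
            raise EncodingError(
                f"non-standard residue {aa!r} at position {pos + 1}"
                + (f" of variant {variant_label}" if variant_label else "")
            ) from None
    return NumericSequence(out, index.accession, variant_label)


def spectrum(
    seq: NumericSequence | np.ndarray,
    options: SpectrumOptions | None = None,
) -> ProteinSpectrum:
    """Amplitude spectrum of an encoded signal (errors on empty input)."""
    if isinstance(seq, NumericSequence):
        values, acc, var = seq.values, seq.source_accession, seq.source_variant
    else:
        values, acc, var = np.asarray(seq, dtype=float), "", ""
    n = len(values)
    if n == 0:
        raise ValueError("cannot take the spectrum of an empty signal")
    options = options or SpectrumOptions()
    if options.mode == "half":
        amps = np.abs(np.fft.rfft(values))
    else:
        amps = np.abs(np.fft.fft(values))
    if options.drop_dc:
        amps = amps[1:]
    return ProteinSpectrum(amps, n, acc, var)


def spectral_features(
    sequence: str,
    index: AminoAcidIndex,
    options: SpectrumOptions | None = None,
    variant_label: str = "",
) -> np.ndarray:
    """encode → spectrum in one step; returns the amplitude vector."""
    return spectrum(encode(sequence, index, variant_label, options), options).amplitudes
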