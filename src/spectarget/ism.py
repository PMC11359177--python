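"""Informational Spectrum Method (ISM) primitives.

The ISM predicts long-range molecular interaction between two molecules from
shared periodicities in their electron-ion interaction potential (EIIP)
profiles.  A molecule is encoded as a numeric series (one EIIP value per
residue, or a precomputed per-atom profile for a small molecule), the series
is mean-subtracted, zero-padded and discrete-Fourier-transformed into an
amplitude spectrum (the *informational spectrum*, IS), and two molecules are
compared through the element-wise product of their spectra (the
*cross-spectrum*, CS).  A pronounced common peak — a dominant CS frequency
with high signal-to-noise — is the interaction signature.

Conventions used throughout:

* the series is mean-subtracted before the transform and the DC bin is
  excluded, so constant sequences carry no signal;
* the spectrum is the DFT *amplitude* (magnitude), evaluated at normalized
  frequencies ``k / n_fft`` for ``k = 1 .. n_fft/2``;
* S/N of a peak is its amplitude divided by the mean amplitude over the whole
  grid, the standard definition in the ISM literature;
* ties in the dominant peak are broken toward the lowest frequency.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "STANDARD_RESIDUES",
    "EIIPTable",
    "NumericSeries",
    "AmplitudeSpectrum",
    "CrossSpectrum",
    "encode_protein",
    "encode_ligand_profile",
    "write_series",
    "informational_spectrum",
    "cross_spectrum",
    "dominant_frequency",
    "snr",
    "pair_n_fft",
    "write_spectrum",
]

STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

#: ambiguity / non-standard one-letter codes handled by the ``table_mean`` policy
NONSTANDARD_CODES = set("XBZUOJ*")


@dataclass(frozen=True)
class EIIPTable:
    """Per-residue electron-ion interaction potential lookup table.

    Parameters
    ----------
    residue_values
        Mapping from one-letter amino-acid code to EIIP value (Rydbergs).
        Must cover all 20 standard residues with finite values.
    unknown_policy
        How to encode non-standard codes (X, B, Z, U, O, J): ``"table_mean"``
        substitutes the arithmetic mean of the 20 standard values (with a
        warning), ``"error"`` raises.
    """

    residue_values: Mapping[str, float]
    unknown_policy: str = "table_mean"

    def __post_init__(self) -> None:
        vals = {str(k).upper(): float(v) for k, v in self.residue_values.items()}
        missing = sorted(set(STANDARD_RESIDUES) - set(vals))
        if missing:
            raise ValueError(f"EIIP table missing standard residues: {missing}")
        if not all(math.isfinite(v) for v in vals.values()):
            raise ValueError("EIIP table contains non-finite values")
        if self.unknown_policy not in ("table_mean", "error"):
            raise ValueError(f"unknown_policy must be 'table_mean' or 'error', got {self.unknown_policy!r}")
        object.__setattr__(self, "residue_values", vals)

    @property
    def mean(self) -> float:
        """Arithmetic mean of the 20 standard-residue values."""
        return sum(self.residue_values[r] for r in STANDARD_RESIDUES) / 20.0

    @property
    def value_range(self) -> tuple[float, float]:
        vals = [self.residue_values[r] for r in STANDARD_RESIDUES]
        return min(vals), max(vals)

    def __getitem__(self, residue: str) -> float:
        return self.residue_values[residue]

    @classmethod
    def from_file(cls, path: str | Path, unknown_policy: str = "table_mean") -> "EIIPTable":
        """Load a two-column (residue, value) text table; '#' starts a comment."""
        values: dict[str, float] = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.replace(",", "\t").split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'residue value', got {raw!r}")
            try:
                values[parts[0].upper()] = float(parts[1])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric value {parts[1]!r}") from exc
        return cls(values, unknown_policy=unknown_policy)

    @classmethod
    def default(cls, unknown_policy: str = "table_mean") -> "EIIPTable":
        """The packaged EIIP table (Rydberg units)."""
        with resources.as_file(resources.files("spectarget.data") / "eiip.tsv") as p:
            return cls.from_file(p, unknown_policy=unknown_policy)


@dataclass(frozen=True)
class NumericSeries:
    """A molecule represented as an ordered series of real values."""

    molecule_id: str
    values: np.ndarray
    source: str = "protein"  # "protein" | "ligand_profile"

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 1 or arr.size < 2:
            raise ValueError("NumericSeries requires a 1-D series of length >= 2")
        if not np.all(np.isfinite(arr)):
            raise ValueError("NumericSeries values must be finite")
        if self.source not in ("protein", "ligand_profile"):
            raise ValueError(f"source must be 'protein' or 'ligand_profile', got {self.source!r}")
        object.__setattr__(self, "values", arr)

    def __len__(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True)
class AmplitudeSpectrum:
    """DFT amplitude spectrum on the normalized-frequency grid ``k/n_fft``."""

    n_fft: int
    frequencies: np.ndarray
    amplitudes: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        a = np.asarray(self.amplitudes, dtype=float)
        if f.shape != a.shape or f.ndim != 1:
            raise ValueError("frequencies and amplitudes must be 1-D arrays of equal length")
        if f.size != self.n_fft // 2:
            raise ValueError("spectrum must have n_fft/2 bins (DC excluded)")
        if np.any(np.diff(f) <= 0) or f[0] <= 0 or f[-1] > 0.5 + 1e-12:
            raise ValueError("frequencies must be strictly increasing within (0, 0.5]")
        if np.any(a < 0):
            raise ValueError("amplitudes must be non-negative")
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "amplitudes", a)


@dataclass(frozen=True)
class CrossSpectrum:
    """Element-wise product of two amplitude spectra.

    ``dominant_frequency`` and ``snr`` are ``None`` when the cross-spectrum is
    identically zero (``degenerate`` is then True).
    """

    n_fft: int
    frequencies: np.ndarray
    amplitudes: np.ndarray
    dominant_frequency: float | None
    snr: float | None
    degenerate: bool = False


def encode_protein(sequence: str, table: EIIPTable | None = None,
                   molecule_id: str = "protein") -> NumericSeries:
    """Replace each residue of a primary sequence by its EIIP value.

    Non-standard codes are handled according to ``table.unknown_policy``.
    """
    table = table or EIIPTable.default()
    seq = "".join(sequence.split()).upper()
    if not seq:
        raise ValueError("empty sequence")
    values = np.empty(len(seq), dtype=float)
    mean = table.mean
    n_subst = 0
    for i, res in enumerate(seq):
        v = table.residue_values.get(res)
        if v is None:
            if res not in NONSTANDARD_CODES:
                raise ValueError(f"unknown residue {res!r} at position {i + 1}")
            if table.unknown_policy == "error":
                raise ValueError(f"non-standard residue {res!r} at position {i + 1}")
            v = mean
            n_subst += 1
        values[i] = v
    if n_subst:
        warnings.warn(
            f"{molecule_id}: replaced {n_subst} non-standard residue(s) by the table mean",
            stacklevel=2,
        )
    return NumericSeries(molecule_id, values, source="protein")


def encode_ligand_profile(path: str | Path, molecule_id: str | None = None) -> NumericSeries:
    """Read a precomputed ligand numeric profile from a two-column text file.

    Rows are ``index value`` (whitespace or comma separated, '#' comments
    allowed); indices must run consecutively from 1.  The encoding of a small
    molecule into such a profile is an external concern — this function only
    ingests the result.
    """
    path = Path(path)
    rows: list[float] = []
    expected = 1
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.replace(",", " ").split()
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 'index value', got {raw!r}")
        try:
            idx = int(parts[0])
            val = float(parts[1])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-numeric row {raw!r}") from exc
        if not math.isfinite(val):
            raise ValueError(f"{path}:{lineno}: non-finite value")
        if idx != expected:
            raise ValueError(f"{path}:{lineno}: index {idx}, expected {expected} (indices must be consecutive from 1)")
        rows.append(val)
        expected += 1
    if len(rows) < 2:
        raise ValueError(f"{path}: ligand profile needs at least 2 rows, found {len(rows)}")
    return NumericSeries(molecule_id or path.stem, np.asarray(rows), source="ligand_profile")


def write_series(series: NumericSeries, path: str | Path) -> None:
    """Write a numeric series in the two-column (index, value) profile dialect."""
    lines = [f"{i}\t{float(v)!r}" for i, v in enumerate(series.values, start=1)]
    Path(path).write_text("\n".join(lines) + "\n")


def pair_n_fft(*lengths: int, n_fft_min: int = 512) -> int:
    """Common FFT size for a set of series: ``max(n_fft_min, next pow2 >= longest)``."""
    longest = max(lengths)
    return max(n_fft_min, 1 << (longest - 1).bit_length())


def informational_spectrum(series: NumericSeries, n_fft: int) -> AmplitudeSpectrum:
    """Amplitude spectrum of a mean-subtracted, zero-padded numeric series.

    Returns amplitudes at bins ``1 .. n_fft/2`` (DC excluded), i.e. at
    normalized frequencies ``k/n_fft`` in (0, 0.5].
    """
    n = len(series)
    if n_fft % 2:
        raise ValueError("n_fft must be even")
    if n_fft < n:
        raise ValueError(f"n_fft={n_fft} is smaller than the series length {n}")
    x = series.values - series.values.mean()
    spec = np.fft.rfft(x, n=n_fft)
    amplitudes = np.abs(spec[1 : n_fft // 2 + 1])
    frequencies = np.arange(1, n_fft // 2 + 1, dtype=float) / n_fft
    return AmplitudeSpectrum(n_fft, frequencies, amplitudes)


def dominant_frequency(frequencies: np.ndarray, amplitudes: np.ndarray) -> float:
    """Frequency of the maximum amplitude; ties resolve to the lowest frequency."""
    amplitudes = np.asarray(amplitudes, dtype=float)
    if not np.any(amplitudes > 0):
        raise ValueError("all-zero amplitudes: dominant frequency undefined")
    # np.argmax returns the first (lowest-frequency) index among ties
    return float(np.asarray(frequencies, dtype=float)[int(np.argmax(amplitudes))])


def snr(frequencies: np.ndarray, amplitudes: np.ndarray, at: float) -> float:
    """Signal-to-noise of the peak at frequency ``at``: A(at) / mean(A)."""
    frequencies = np.asarray(frequencies, dtype=float)
    amplitudes = np.asarray(amplitudes, dtype=float)
    idx = np.flatnonzero(np.isclose(frequencies, at, rtol=0, atol=1e-12))
    if idx.size == 0:
        raise ValueError(f"frequency {at} is not on the spectrum grid")
    mean_amp = float(amplitudes.mean())
    if mean_amp == 0:
        raise ValueError("zero-mean spectrum: S/N undefined")
    return float(amplitudes[idx[0]] / mean_amp)


def cross_spectrum(a: AmplitudeSpectrum, b: AmplitudeSpectrum) -> CrossSpectrum:
    """Element-wise product of two informational spectra.

    Both spectra must share the same ``n_fft`` (re-pad both series to a common
    FFT size, e.g. via :func:`pair_n_fft`, before calling).  The returned
    object carries the dominant frequency of the product and its S/N; a
    cross-spectrum that is identically zero is flagged degenerate.
    """
    if a.n_fft != b.n_fft:
        raise ValueError(
            f"frequency grids differ (n_fft {a.n_fft} vs {b.n_fft}); "
            "re-pad both series to a common n_fft before computing the cross-spectrum"
        )
    amplitudes = a.amplitudes * b.amplitudes
    if not np.any(amplitudes > 0):
        return CrossSpectrum(a.n_fft, a.frequencies, amplitudes, None, None, degenerate=True)
    dom = dominant_frequency(a.frequencies, amplitudes)
    return CrossSpectrum(
        a.n_fft, a.frequencies, amplitudes, dom, snr(a.frequencies, amplitudes, dom)
    )


def write_spectrum(spectrum: AmplitudeSpectrum | CrossSpectrum, path: str | Path) -> None:
    """Export a spectrum as tab-separated (frequency, amplitude), 6 significant digits."""
    lines = [
        f"{f:.6g}\t{a:.6g}"
        for f, a in zip(spectrum.frequencies, spectrum.amplitudes)
    ]
    Path(path).write_text("\n".join(lines) + "\n")
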