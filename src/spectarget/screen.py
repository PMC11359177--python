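"""Batch ISM screening of a FASTA proteome against a ligand profile.

Each protein is paired with the ligand on a per-pair frequency grid, the
cross-spectrum is computed, and proteins whose dominant cross-spectrum peak
falls within a small window of a target normalized frequency are kept and
ranked by signal-to-noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

from .ism import (
    EIIPTable,
    NumericSeries,
    cross_spectrum,
    encode_protein,
    informational_spectrum,
    pair_n_fft,
)

__all__ = [
    "ScreenConfig",
    "ScreenHit",
    "ScreenSummary",
    "read_fasta",
    "write_fasta",
    "screen_proteome",
    "write_hits",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScreenConfig:
    """Configuration of the frequency-filter screen.

    ``target_frequency`` is snapped to the nearest grid bin of each pair's
    FFT grid; a protein passes when its dominant cross-spectrum bin lies
    within ``tolerance_bins`` of that target bin.
    """

    target_frequency: float = 0.016
    tolerance_bins: int = 1
    min_length: int = 8
    n_fft_min: int = 512

    def __post_init__(self) -> None:
        if not 0.0 < self.target_frequency <= 0.5:
            raise ValueError("target_frequency must lie in (0, 0.5]")
        if self.tolerance_bins < 0:
            raise ValueError("tolerance_bins must be >= 0")
        if self.n_fft_min < 2 or self.n_fft_min % 2:
            raise ValueError("n_fft_min must be a positive even integer")


@dataclass(frozen=True)
class ScreenHit:
    protein_id: str
    length: int
    n_fft: int
    dominant_frequency: float
    snr: float


@dataclass(frozen=True)
class ScreenSummary:
    n_screened: int
    n_skipped: int
    n_passed: int


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA records as (id, sequence) pairs.

    Ids are the first whitespace token of each header; sequences are
    uppercased with gap characters and whitespace stripped.  Duplicate ids
    and empty files are errors.
    """
    records: list[tuple[str, str]] = []
    seen: dict[str, int] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace("-", "").replace(".", "").replace(" ", "")
        records.append((rec.id, seq))
        seen[rec.id] = seen.get(rec.id, 0) + 1
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    dups = sorted(i for i, c in seen.items() if c > 1)
    if dups:
        raise ValueError(f"{path}: duplicate record ids: {dups}")
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _target_bin(target_frequency: float, n_fft: int) -> int:
    """Nearest on-grid bin to the requested target frequency."""
    return int(min(max(round(target_frequency * n_fft), 1), n_fft // 2))


def screen_proteome(
    records: Sequence[tuple[str, str]],
    ligand: NumericSeries,
    cfg: ScreenConfig = ScreenConfig(),
    table: EIIPTable | None = None,
) -> tuple[list[ScreenHit], ScreenSummary]:
    """Screen protein records against a ligand profile.

    Returns hits (frequency-filter passers) sorted by S/N descending, then id
    ascending, plus a summary of screened/skipped/passed counts.  Records
    shorter than ``cfg.min_length`` are skipped with a logged warning; if
    every record is skipped the screen fails.
    """
    if not records:
        raise ValueError("no records to screen")
    table = table or EIIPTable.default()
    ligand_spectra: dict[int, object] = {}  # n_fft -> AmplitudeSpectrum cache
    hits: list[ScreenHit] = []
    n_skipped = 0
    for rid, seq in records:
        if len(seq) < cfg.min_length:
            logger.warning("skipping %s: length %d < min_length %d", rid, len(seq), cfg.min_length)
            n_skipped += 1
            continue
        protein = encode_protein(seq, table, molecule_id=rid)
        n_fft = pair_n_fft(len(protein), len(ligand), n_fft_min=cfg.n_fft_min)
        if n_fft not in ligand_spectra:
            ligand_spectra[n_fft] = informational_spectrum(ligand, n_fft)
        cs = cross_spectrum(informational_spectrum(protein, n_fft), ligand_spectra[n_fft])
        if cs.degenerate:
            continue
        dom_bin = int(round(cs.dominant_frequency * n_fft))
        if abs(dom_bin - _target_bin(cfg.target_frequency, n_fft)) <= cfg.tolerance_bins:
            hits.append(ScreenHit(rid, len(seq), n_fft, cs.dominant_frequency, cs.snr))
    if n_skipped == len(records):
        raise ValueError("all records skipped (shorter than min_length)")
    hits.sort(key=lambda h: (-h.snr, h.protein_id))
    summary = ScreenSummary(len(records) - n_skipped, n_skipped, len(hits))
    logger.info(
        "screened %d, skipped %d, passed %d", summary.n_screened, summary.n_skipped, summary.n_passed
    )
    return hits, summary


def write_hits(hits: Iterable[ScreenHit], path: str | Path) -> None:
    """Write the hit table as TSV: protein_id, length, n_fft, dominant_frequency, snr."""
    lines = ["protein_id\tlength\tn_fft\tdominant_frequency\tsnr"]
    for h in hits:
        lines.append(f"{h.protein_id}\t{h.length}\t{h.n_fft}\t{h.dominant_frequency:.6g}\t{h.snr:.6g}")
    Path(path).write_text("\n".join(lines) + "\n")
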