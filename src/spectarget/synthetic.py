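"""Ground-truthed synthetic inputs for every pipeline stage.

Generators emulate the study conditions each analysis stage expects:

* proteomes in which a known subset of sequences carries a planted EIIP
  periodicity at a chosen normalized frequency (screening positives) among
  random-residue background sequences (negatives);
* ligand numeric profiles built as noise plus a cosine at a planted
  frequency;
* toy bipartite seed/interactor PPI networks with bookkept per-seed hit
  counts;
* grouped single-cell IR spectra assembled from the six Amide I/II reference
  sub-bands on a convex baseline with Gaussian noise, with treatment presets
  that scale band amplitudes and shift band centers.

Every generator is a pure function of (spec, seed): identical calls produce
identical output, and each emitted record appears exactly once in its
ground-truth sidecar.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import erf

from .ftir import DEFAULT_BANDS, Spectrum
from .ism import EIIPTable, NumericSeries, STANDARD_RESIDUES, informational_spectrum, pair_n_fft

__all__ = [
    "PlantedProteomeSpec",
    "BandSpec",
    "BandMixSpec",
    "TreatmentEffectSpec",
    "DEFAULT_BAND_MIX",
    "generate_proteome",
    "generate_ligand_profile",
    "generate_network",
    "generate_cell_spectra",
    "treatment_presets",
    "analytic_band_area",
    "write_sidecar",
]


def _spawn(seed: int, n: int) -> list[np.random.Generator]:
    """Expand one global seed into independent per-stream generators."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


# ---------------------------------------------------------------------------
# proteomes and ligand profiles

@dataclass(frozen=True)
class PlantedProteomeSpec:
    """A proteome with a planted periodic EIIP component in some sequences.

    ``planted_amplitude`` is in EIIP units (Rydbergs); the signal is realized
    by residue quantization (see :func:`generate_proteome`) so it cannot
    exceed half the spread of the EIIP table.
    """

    n_background: int = 50
    n_planted: int = 10
    length_range: tuple[int, int] = (60, 300)
    planted_frequency: float = 0.015625
    planted_amplitude: float = 0.06
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.planted_frequency < 0.5:
            raise ValueError("planted_frequency must lie in (0, 0.5)")
        if self.planted_amplitude < 0:
            raise ValueError("planted_amplitude must be >= 0")
        if self.length_range[0] < 8 or self.length_range[0] > self.length_range[1]:
            raise ValueError("length_range must satisfy 8 <= min <= max")
        if self.n_background < 0 or self.n_planted < 0:
            raise ValueError("sequence counts must be >= 0")


def generate_proteome(
    spec: PlantedProteomeSpec, table: EIIPTable | None = None
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Generate FASTA records plus a ground-truth sidecar.

    Background sequences draw residues i.i.d. uniformly over the 20 standard
    amino acids.  Planted sequences realize the target EIIP series
    ``midpoint + amplitude * cos(2*pi*f*n + phase)`` (random phase per
    sequence) by picking, at each position, the residue whose EIIP value is
    nearest the target — the emitted FASTA therefore stays a legal protein
    sequence, and the quantization error is recorded in the sidecar.

    The sidecar lists, per record: id, class, length, the realized dominant
    IS frequency, and the quantization RMSE (planted records only).
    """
    table = table or EIIPTable.default()
    vmin, vmax = table.value_range
    if spec.planted_amplitude > (vmax - vmin) / 2 + 1e-12:
        raise ValueError(
            f"planted_amplitude {spec.planted_amplitude} exceeds the realizable "
            f"half-range {(vmax - vmin) / 2:.4f} of the EIIP table"
        )
    residues = sorted(STANDARD_RESIDUES, key=lambda r: (table[r], r))
    res_values = np.array([table[r] for r in residues])
    center = (vmax + vmin) / 2.0

    rng_bg, rng_pl = _spawn(spec.seed, 2)
    records: list[tuple[str, str]] = []
    rows = []

    def realized_dominant(seq: str) -> float:
        series = NumericSeries("tmp", np.array([table[r] for r in seq]))
        n_fft = pair_n_fft(len(seq))
        is_ = informational_spectrum(series, n_fft)
        return float(is_.frequencies[int(np.argmax(is_.amplitudes))])

    for i in range(spec.n_planted):
        length = int(rng_pl.integers(spec.length_range[0], spec.length_range[1] + 1))
        phase = float(rng_pl.uniform(0, 2 * math.pi))
        n = np.arange(length)
        target = center + spec.planted_amplitude * np.cos(
            2 * math.pi * spec.planted_frequency * n + phase
        )
        nearest = np.argmin(np.abs(res_values[None, :] - target[:, None]), axis=1)
        seq = "".join(residues[j] for j in nearest)
        rid = f"planted_{i + 1:03d}"
        records.append((rid, seq))
        rmse = float(np.sqrt(np.mean((res_values[nearest] - target) ** 2)))
        rows.append(
            {
                "molecule_id": rid,
                "class": "planted",
                "length": length,
                "dominant_frequency": realized_dominant(seq),
                "quantization_rmse": rmse,
            }
        )

    for i in range(spec.n_background):
        length = int(rng_bg.integers(spec.length_range[0], spec.length_range[1] + 1))
        seq = "".join(
            STANDARD_RESIDUES[j] for j in rng_bg.integers(0, 20, size=length)
        )
        rid = f"background_{i + 1:03d}"
        records.append((rid, seq))
        rows.append(
            {
                "molecule_id": rid,
                "class": "background",
                "length": length,
                "dominant_frequency": realized_dominant(seq),
                "quantization_rmse": float("nan"),
            }
        )

    return records, pd.DataFrame(rows)


def generate_ligand_profile(
    length: int = 128,
    planted_frequency: float = 0.015625,
    amplitude: float = 1.0,
    noise_sd: float = 0.01,
    seed: int = 0,
    molecule_id: str = "ligand",
) -> NumericSeries:
    """A ligand numeric profile: Gaussian noise plus a planted cosine.

    With ``amplitude`` well above ``noise_sd`` the profile's dominant IS
    frequency is the grid bin nearest ``planted_frequency``; with
    ``amplitude = 0`` the profile is pure noise.  The default length of 128
    samples spans two periods of the default planted frequency; much shorter
    profiles let spectral leakage from the zero-padded window displace the
    dominant bin by one, depending on the cosine phase.
    """
    if length < 8:
        raise ValueError("ligand profile length must be >= 8")
    rng = np.random.default_rng(seed)
    n = np.arange(length)
    values = noise_sd * rng.standard_normal(length) + amplitude * np.cos(
        2 * math.pi * planted_frequency * n
    )
    return NumericSeries(molecule_id, values, source="ligand_profile")


# ---------------------------------------------------------------------------
# toy PPI networks

def generate_network(
    n_seeds: int = 10,
    n_interactors: int = 100,
    hit_fraction: float = 0.3,
    seed: int = 0,
    max_degree: int = 20,
) -> tuple[list[str], list[tuple[str, str, float]], dict[str, float], pd.DataFrame]:
    """Random bipartite seed/interactor network with known per-seed hit counts.

    Returns (seed ids, scored edge rows, hit -> S/N map, sidecar).  Each seed
    attaches to a random subset of interactors; a ``hit_fraction`` of the
    interactor pool is designated as screen hits with random S/N values.  The
    sidecar records the true number of hit neighbours of every seed.
    """
    if n_seeds < 1 or n_interactors < 1:
        raise ValueError("network sizes must be >= 1")
    if not 0.0 <= hit_fraction <= 1.0:
        raise ValueError("hit_fraction must lie in [0, 1]")
    rng_top, rng_hits = _spawn(seed, 2)
    seeds = [f"SEED{i + 1:03d}" for i in range(n_seeds)]
    interactors = [f"PROT{i + 1:04d}" for i in range(n_interactors)]
    n_hits = int(round(hit_fraction * n_interactors))
    hit_ids = sorted(rng_hits.choice(interactors, size=n_hits, replace=False).tolist())
    hits = {h: float(rng_hits.uniform(5.0, 15.0)) for h in hit_ids}
    hit_set = set(hit_ids)

    edges: list[tuple[str, str, float]] = []
    rows = []
    for s in seeds:
        degree = int(rng_top.integers(1, min(max_degree, n_interactors) + 1))
        nbrs = rng_top.choice(interactors, size=degree, replace=False)
        for nb in nbrs:
            edges.append((s, str(nb), float(rng_top.uniform(0.4, 1.0))))
        rows.append(
            {
                "seed_id": s,
                "degree": degree,
                "true_hit_count": int(sum(1 for nb in nbrs if str(nb) in hit_set)),
            }
        )
    return seeds, edges, hits, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cell IR spectra

@dataclass(frozen=True)
class BandSpec:
    center: float
    fwhm: float
    amplitude: float
    shape: str = "gaussian"  # "gaussian" | "lorentzian"

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValueError("FWHM must be > 0")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.shape not in ("gaussian", "lorentzian"):
            raise ValueError(f"unknown band shape {self.shape!r}")

    def evaluate(self, w: np.ndarray) -> np.ndarray:
        if self.shape == "gaussian":
            sigma = self.fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
            return self.amplitude * np.exp(-((w - self.center) ** 2) / (2 * sigma**2))
        gamma = self.fwhm / 2.0
        return self.amplitude / (1.0 + ((w - self.center) / gamma) ** 2)


#: Base Amide I/II mixture: the six reference sub-bands, FWHM 25 cm-1.
#: The Amide I alpha-helix component dominates; the remaining components are
#: comparable in magnitude so that, as in measured cell spectra, all six
#: sub-bands stay resolvable in the second derivative despite band overlap.
_DEFAULT_BAND_PARAMS: tuple[tuple[float, float], ...] = (
    (1685.0, 0.60),
    (1656.0, 1.00),
    (1635.0, 0.70),
    (1543.0, 0.80),
    (1515.0, 0.50),
    (1495.0, 0.40),
)


@dataclass(frozen=True)
class BandMixSpec:
    """A cell spectrum model: bands + convex polynomial baseline + noise.

    ``baseline_coeffs`` are polynomial coefficients (constant first) in
    ``u = wavenumber - grid midpoint``; the polynomial must be convex over
    the grid.  ``noise_sd`` is expressed as a fraction of the tallest band
    amplitude.
    """

    bands: tuple[BandSpec, ...] = tuple(
        BandSpec(c, 25.0, a) for c, a in _DEFAULT_BAND_PARAMS
    )
    baseline_coeffs: tuple[float, ...] = (0.15, 0.0, 2e-7)
    noise_sd: float = 0.01
    grid: tuple[float, float, float] = (900.0, 1800.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi, step = self.grid
        if step <= 0 or lo >= hi:
            raise ValueError("grid must be (lo, hi, step) with lo < hi and step > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for b in self.bands:
            if not lo <= b.center <= hi:
                raise ValueError(f"band center {b.center} outside grid [{lo}, {hi}]")
        w = self.wavenumbers()
        poly = np.polynomial.Polynomial(self.baseline_coeffs)
        if np.any(poly.deriv(2)(w - w.mean()) < -1e-12):
            raise ValueError("baseline polynomial must be convex over the grid")

    def wavenumbers(self) -> np.ndarray:
        lo, hi, step = self.grid
        return lo + step * np.arange(int(round((hi - lo) / step)) + 1)

    def baseline(self, w: np.ndarray) -> np.ndarray:
        return np.polynomial.Polynomial(self.baseline_coeffs)(w - self.wavenumbers().mean())

    @property
    def max_amplitude(self) -> float:
        return max(b.amplitude for b in self.bands)


DEFAULT_BAND_MIX = BandMixSpec()


@dataclass(frozen=True)
class TreatmentEffectSpec:
    """Per-group modification of the base band mixture."""

    group_label: str
    amplitude_scale: Mapping[float, float] = field(default_factory=dict)
    center_shift: Mapping[float, float] = field(default_factory=dict)
    n_cells: int = 28

    def __post_init__(self) -> None:
        if self.n_cells < 2:
            raise ValueError("n_cells must be >= 2")
        if any(m < 0 for m in self.amplitude_scale.values()):
            raise ValueError("amplitude multipliers must be >= 0")

    def apply(self, bands: Sequence[BandSpec]) -> tuple[BandSpec, ...]:
        out = []
        for b in bands:
            out.append(
                BandSpec(
                    b.center + float(self.center_shift.get(b.center, 0.0)),
                    b.fwhm,
                    b.amplitude * float(self.amplitude_scale.get(b.center, 1.0)),
                    b.shape,
                )
            )
        return tuple(out)


def treatment_presets(delta: float = 0.3, n_cells: int = 28) -> dict[str, TreatmentEffectSpec]:
    """Treatment-group presets encoding the study's reported structural effects.

    * ``control`` — untreated cells (identity).
    * ``rucn`` — the bare ruthenium complex: alpha-helix content up
      (1656, 1543 bands scaled by 1+delta), parallel beta-sheet down
      (1635 scaled by 1-delta).
    * ``rucn_cd`` — complex on a plain carbon-dot carrier: no structural
      effect (identity).
    * ``rucn_ncd`` — complex on an N-doped carbon-dot carrier: parallel
      beta-sheet up, alpha-helix down, Tyr band up, and the whole Amide I
      band (its three sub-band centers) downshifted by 3 cm-1, reproducing
      the reported 1651 -> 1648 cm-1 downshift of the Amide I maximum.
    """
    return {
        "control": TreatmentEffectSpec("control", n_cells=n_cells),
        "rucn": TreatmentEffectSpec(
            "rucn",
            amplitude_scale={1656.0: 1 + delta, 1543.0: 1 + delta, 1635.0: 1 - delta},
            n_cells=n_cells,
        ),
        "rucn_cd": TreatmentEffectSpec("rucn_cd", n_cells=n_cells),
        "rucn_ncd": TreatmentEffectSpec(
            "rucn_ncd",
            amplitude_scale={1635.0: 1 + delta, 1656.0: 1 - delta, 1515.0: 1 + delta},
            center_shift={1685.0: -3.0, 1656.0: -3.0, 1635.0: -3.0},
            n_cells=n_cells,
        ),
    }


def generate_cell_spectra(
    base: BandMixSpec = DEFAULT_BAND_MIX,
    groups: Sequence[TreatmentEffectSpec] = (TreatmentEffectSpec("control"),),
    seed: int | None = None,
) -> tuple[list[Spectrum], pd.DataFrame]:
    """Grouped per-cell spectra plus a ground-truth sidecar.

    Each cell is ``baseline + sum of (group-modified) bands + i.i.d.
    Gaussian noise`` with sd ``base.noise_sd * tallest base band``.  The
    sidecar records, per cell, the true amplitude and center of every band
    and the analytic Amide I band area over 1600-1700 cm-1.
    """
    seed = base.seed if seed is None else seed
    w = base.wavenumbers()
    lo, hi, _ = base.grid
    baseline = base.baseline(w)
    sd = base.noise_sd * base.max_amplitude
    rngs = _spawn(seed, max(len(groups), 1))
    spectra: list[Spectrum] = []
    rows = []
    for g, rng in zip(groups, rngs):
        bands = g.apply(base.bands)
        for b in bands:
            if not lo <= b.center <= hi:
                raise ValueError(
                    f"group {g.group_label!r}: shifted band center {b.center} outside grid"
                )
        clean = baseline + np.sum([b.evaluate(w) for b in bands], axis=0)
        for i in range(g.n_cells):
            y = clean + sd * rng.standard_normal(w.size) if sd > 0 else clean.copy()
            cell_id = f"{g.group_label}_c{i + 1:03d}"
            spectra.append(Spectrum(w, y, cell_id=cell_id, group=g.group_label))
            row: dict[str, object] = {"cell_id": cell_id, "group": g.group_label}
            for b0, b in zip(base.bands, bands):
                row[f"amp_{b0.center:.0f}"] = b.amplitude
                row[f"center_{b0.center:.0f}"] = b.center
            row["amide_area_true"] = analytic_band_area(bands, 1600.0, 1700.0)
            rows.append(row)
    return spectra, pd.DataFrame(rows)


def analytic_band_area(bands: Sequence[BandSpec], lo: float, hi: float) -> float:
    """Closed-form integral of a band sum over [lo, hi] (baseline excluded)."""
    total = 0.0
    for b in bands:
        if b.shape == "gaussian":
            sigma = b.fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
            total += (
                b.amplitude
                * sigma
                * math.sqrt(2.0 * math.pi)
                * 0.5
                * (erf((hi - b.center) / (sigma * math.sqrt(2))) - erf((lo - b.center) / (sigma * math.sqrt(2))))
            )
        else:
            gamma = b.fwhm / 2.0
            total += b.amplitude * gamma * (
                math.atan((hi - b.center) / gamma) - math.atan((lo - b.center) / gamma)
            )
    return float(total)


# ---------------------------------------------------------------------------
# sidecar I/O

def write_sidecar(df: pd.DataFrame, spec: object, path: str | Path) -> None:
    """Write a ground-truth sidecar as TSV with a '# spec:' header echoing
    all generator parameters."""
    header = f"# spec: {spec!r}\n"
    Path(path).write_text(header + df.to_csv(sep="\t", index=False))
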