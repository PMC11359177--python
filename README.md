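# spectarget

Target screening and protein secondary-structure readout for a candidate
metallodrug, in one tested Python package:

* **Informational Spectrum Method (ISM) screening** — predict which proteins
  of a proteome a small molecule may interact with, from shared periodicities
  in electron-ion interaction potential (EIIP) profiles, and count the
  predicted targets inside protein-protein interaction (PPI) networks of
  disease genes.
* **microFTIR pipeline** — quantify treatment-induced changes in cellular
  protein secondary structure from single-cell infrared spectra via
  second-derivative analysis of the Amide I/II region.

It is written for computational biologists and spectroscopists who want both
analysis tracks scriptable, reproducible, and validated against independent
oracles, with synthetic ground-truthed data generators for every stage.

## The methods

**ISM.** A protein sequence is mapped to a numeric series by replacing each
residue with its EIIP value (Rydbergs). The series is mean-subtracted,
zero-padded to `n_fft` and Fourier-transformed; the amplitudes at normalized
frequencies `k/n_fft`, `k = 1..n_fft/2`, form the informational spectrum
(IS). For a protein-ligand pair the cross-spectrum (CS) is the element-wise
product of the two ISs; a shared dominant peak signals potential long-range
interaction. A proteome screen keeps proteins whose dominant CS frequency
falls within a small bin window of a target frequency (e.g. 0.016, the
dominant IS peak of the ruthenium-complex profile) and ranks them by
`S/N = A(peak) / mean(A)`. Per-seed PPI hit counting then intersects each
disease gene's network neighbourhood with the hit set.

**microFTIR.** Per-cell spectra are cropped to the Amide I/II region
(1480-1700 cm⁻¹), rubber-band baseline-corrected (lower convex hull),
vector-normalized, and differentiated twice with a Savitzky-Golay filter
(15 points, order 3). Overlapped sub-bands appear as second-derivative
minima at the reference positions 1685 (antiparallel β-sheet), 1656
(α-helix), 1635 (parallel β-sheet), 1543 (α-helix, Amide II), 1515 (Tyr) and
1495 cm⁻¹ (Phe). Band intensities and Amide I areas (1600-1700 cm⁻¹) are
compared across treatment groups by one-way ANOVA.

## Worked example

Generate a small synthetic study and screen it:

```python
from spectarget.synthetic import (PlantedProteomeSpec, generate_proteome,
                                  generate_ligand_profile)
from spectarget.screen import ScreenConfig, screen_proteome

records, truth = generate_proteome(PlantedProteomeSpec(
    n_background=20, n_planted=3, seed=1))
ligand = generate_ligand_profile(seed=1)   # noise + cosine at 0.015625
hits, summary = screen_proteome(records, ligand, ScreenConfig())
for h in hits[:4]:
    print(h.protein_id, h.dominant_frequency, round(h.snr, 1))
```

prints

```
planted_001 0.015625 107.5
planted_002 0.015625 77.6
planted_003 0.015625 52.4
background_020 0.017578125 46.4
```

All three sequences carrying the planted EIIP periodicity rank on top, at
the planted frequency 0.015625 (the 512-grid bin nearest 0.016), with S/N
well above every background sequence. The same screen is available from the
shell:

```bash
spectarget screen --fasta proteome.fasta --ligand ligand.txt \
    --target-freq 0.016 --tolerance-bins 1 --out hits.tsv
```

The bundled ovarian-neoplasm worked example reproduces the published
per-network hit counts:

```python
from spectarget.network import (load_ovarian_example, count_hits_per_seed,
                                hit_multiplicity)
seeds, edges, hits = load_ovarian_example()
reports = count_hits_per_seed(seeds, edges, hits)
print([(r.seed_id, r.hit_count) for r in reports[:3]])
print(hit_multiplicity(reports)["TERF2IP"])
```

```
[('MDM2', 6), ('PRKN', 6), ('AKT1', 5)]
(4, ['BRCA1', 'MRE11', 'NBN', 'RAD50'])
```

For the FTIR track, `spectarget ftir --spectra cells.csv --out bands.tsv
--amide-area` quantifies the six sub-bands per cell and prints the
Amide I area ANOVA; on a synthetic two-group study (28 control cells vs 28
cells with the N-doped-carrier treatment preset) it prints

```
control: n=28 mean=6.69381 sd=0.0415996
rucn_ncd: n=28 mean=6.65806 sd=0.0460155
one-way ANOVA: F=9.3 p=0.003547
```

i.e. a significant Amide I area difference between the groups.

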