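# Methods

## ISM core

A molecule enters the analysis as an ordered real series: proteins via the
packaged EIIP table (Rydberg units, one value per standard residue), small
molecules via a precomputed two-column numeric profile (the per-atom
encoding of a ligand is outside this package's scope; any profile on the
same normalized-frequency convention can be supplied).

The informational spectrum is computed as follows: subtract the series
mean, zero-pad to `n_fft`, take the DFT, and keep the amplitudes at bins
`1..n_fft/2` (the DC bin is excluded). Mean subtraction plus DC exclusion
guarantees that a constant series carries no signal, which is what makes
"the dominant peak" a meaningful statistic. Amplitude (not power) spectra
are used throughout; since the cross-spectrum is a product and the S/N a
ratio, the choice changes peak contrast but not peak location, and
amplitude spectra keep S/N linear in each molecule's signal amplitude.

Conventions that the literature leaves open were fixed as:

* **S/N** = amplitude at the query frequency divided by the mean amplitude
  over the whole grid. It is dimensionless and invariant under uniform
  rescaling of the series.
* **Common grid**: a protein-ligand pair is evaluated at
  `n_fft = max(512, next power of two >= longer series)`. The floor of 512
  puts a bin at 8/512 = 0.015625, the nearest representable frequency to
  the screening target 0.016; per-pair padding (rather than one global
  grid) preserves resolution across proteins spanning two orders of
  magnitude in length.
* **Frequency matching** is done in bins: the target frequency is snapped
  to the nearest bin of the pair's grid and a protein passes when its
  dominant cross-spectrum bin is within `tolerance_bins` (default 1) of it.
* **Ties** in the dominant peak resolve to the lowest frequency
  (deterministic, and first-index argmax makes it free).
* **Non-standard residues** (X, B, Z, U, O, J) are replaced by the table
  mean with a warning by default; a strict policy raises instead.

## Proteome screen

Hits are ranked by S/N descending (id ascending as tie-break), matching how
candidate interactor tables are usually presented. Records shorter than
`min_length` (default 8) are skipped with a warning — real proteomes contain
fragments — and the screen fails only if nothing remains. A summary object
reports screened/skipped/passed counts, and identical inputs yield
byte-identical hit tables.

One statistical caveat is documented as behaviour, not hidden: when the
ligand's spectrum is strongly peaked, the cross-spectrum argmax of *any*
protein is biased toward the ligand's peak, so the frequency filter's
background pass rate rises far above the chance level `(2*tol+1)/(n_fft/2)`
and the S/N ranking carries the discrimination. The chance-level
calibration holds for independent (protein, ligand) draws, and the null
test suite verifies it in exactly that design.

## Network annotation

Per-seed hit counting is plain set intersection between a seed's
neighbourhood and the hit id set, with the seed itself excluded (the
convention adopted here; the alternative is a one-off difference for seeds
that are themselves hits). Identifier matching is exact and case-sensitive:
alias resolution belongs to the upstream database export, not to this
package. Seeds missing from the edge list are reported with count 0 so the
output conserves the input seed-list length. Edge lists accept an optional
score column; when present, at most `max_neighbors` highest-scoring
partners per query protein are retained, mirroring how STRING exports cap
the interactors shown.

A packaged worked example (`load_ovarian_example`) encodes the published
per-network memberships of ISM-predicted ruthenium-complex targets within
STRING neighbourhoods of ovarian-neoplasm genes, and the test suite checks
the full counting logic against it (MDM2 = 6, PRKN = 6, AKT1 = 5; TERF2IP
present in 4 networks; exactly three seeds with >= 5 hits).

## microFTIR pipeline

Processing order is fixed by the pipeline runner: **crop → rubber-band
baseline → vector normalization → Savitzky-Golay second derivative**. The
baseline must be estimated on the analysis region, and normalization has to
see baseline-free absorbance, so the order is part of the contract, not a
configuration.

* **Crop**: default region 1480-1700 cm⁻¹ (Amide I + II).
* **Rubber-band baseline**: the lower convex hull of (wavenumber,
  absorbance), interpolated linearly between hull vertices and subtracted.
  Endpoints are hull vertices by construction, so the corrected spectrum
  is exactly zero there and non-negative up to float error everywhere.
  Collinear input (e.g. a pure linear ramp) degenerates to the chord and
  maps to zeros.
* **Vector normalization**: unit Euclidean norm, removing path-length and
  concentration scale.
* **Second derivative**: Savitzky-Golay, window 15 *points* on the
  instrument grid (not cm⁻¹), polynomial order 3, derivative order 2 with
  respect to wavenumber (units absorbance·cm²). The output is trimmed to
  interior points where the full window fits (7 points per side at the
  default window); the Amide analysis windows sit well inside the trimmed
  range on any realistic grid, and trimming avoids polynomial edge-fit
  artifacts. On a 1 cm⁻¹ grid the filter is exact on quadratics and cubics,
  which the tests assert.
* **Band detection**: for each reference band, the deepest local minimum of
  the second derivative within ±8 cm⁻¹ of the nominal center (half the
  smallest inter-band gap, 1656-1635 = 21 cm⁻¹, preventing
  cross-assignment); a band with no local minimum in its window is reported
  absent. Band "intensity" is the absolute second-derivative value at the
  minimum, the usual convention where sub-bands appear as minima.
* **Amide I area**: trapezoidal integral over 1600-1700 cm⁻¹, computed
  after normalization by default (configurable), since group comparisons of
  areas are only meaningful on thickness-corrected spectra.
* **Group comparison**: one-way fixed-effects ANOVA (scipy) with per-group
  descriptives; degenerate inputs (zero pooled within-group variance,
  groups of size < 2) are rejected rather than returning NaN.

Spectra I/O uses a two-header CSV (cell ids, then group labels) with a
`wavenumber_cm-1` first column; descending grids are reversed on read, and
unequal grids are not silently resampled — the caller decides.

## Synthetic data

The generators are first-class, tested code and define the conditions under
which the pipeline's statistical claims are made.

**Proteomes.** Background sequences draw residues i.i.d. uniformly over the
20 standard amino acids. Planted sequences realize the EIIP-domain target
`midpoint + a·cos(2πf·n + φ)` (random phase per sequence) by *residue
quantization*: at each position the residue whose EIIP value is nearest the
target is chosen, so the emitted FASTA stays a legal protein sequence and
the quantization error (recorded per sequence in the sidecar) plays the
role of background noise. Amplitudes above half the table's value spread
are unrealizable and rejected. Default: 50 background + 10 planted
sequences of 60-300 aa, planted frequency 0.015625, amplitude 0.06 (just
under the 0.0632 maximum).

**Ligand profiles.** Gaussian noise (sd 0.01) plus a cosine at the planted
frequency, default amplitude 1.0 and length 128 (two periods of the
default frequency). The length matters: a 64-sample phase-zero cosine
zero-padded to 512 has its spectral peak displaced one bin by leakage
interference between the positive- and negative-frequency kernels, so
shorter profiles do not reliably peak at the planted bin. A regression test
pins this behaviour.

**Networks.** Random bipartite seed/interactor attachment with bookkept
per-seed true hit counts; degenerate fractions (0, 1) give exact counts (0,
degree).

**Cell spectra.** Each cell is `convex quadratic baseline + Σ bands +
i.i.d. Gaussian noise` on a 900-1800 cm⁻¹ grid at 1 cm⁻¹. The six
reference bands default to Gaussians of FWHM 25 cm⁻¹ with amplitudes
0.60/1.00/0.70/0.80/0.50/0.40 (1685/1656/1635/1543/1515/1495): the Amide I
α-helix dominates, and the components are comparable enough that all six
stay resolvable as second-derivative minima despite overlap — as they are
in measured cell spectra. Noise sd is expressed as a fraction of the
tallest band (default 1%). Treatment presets encode the reported effects:
the bare complex raises α-helix (1656, 1543 ×(1+δ)) and lowers parallel
β-sheet (1635 ×(1−δ)); the plain-carrier preset is the identity; the
N-doped-carrier preset raises 1635 and 1515 by (1+δ), lowers 1656 by
(1−δ), and rigidly downshifts the three Amide I sub-band centers by
3 cm⁻¹, reproducing the observed 1651 → 1648 cm⁻¹ downshift of the Amide I
maximum (shifting only the 1656 component would move the envelope maximum
by ~5 cm⁻¹ because it also changes the overlap geometry). Default group
size is 28 cells. One global seed expands to independent per-stream
generators, so groups can be regenerated independently.

## Problem sizes used in the validation suite

The statistical suites run at: 2000 (protein, ligand) pairs for the null
calibration of the frequency filter; 10 planted + 50 background sequences
for screen sensitivity; 200 replicate two-group experiments of 28 cells
per group for ANOVA power (δ = 0.3 on the 1635 band, noise 1%) and for the
null rejection rate of the identity preset; 100 random series against the
O(N²) direct-summation DFT oracle.

## What passing tests do and do not show

The synthetic spectra are sums of ideal Gaussian bands on a smooth convex
baseline with white noise: they contain no water-vapour lines, no
Mie-scattering distortion, no detector drift, and the band shapes are
exactly the model family the detector assumes. Passing the recovery tests
therefore validates the algorithmic chain (baseline, normalization,
differentiation, detection, testing), not robustness to instrument
artifacts — atmospheric correction and scattering correction (e.g. EMSC)
are explicitly out of scope. Similarly, planted proteome positives carry an
idealized single-frequency EIIP periodicity; real interactor sets are not
generated by that mechanism, so screen sensitivity on synthetic positives
does not estimate biological sensitivity. The ovarian worked example
validates counting logic on published memberships, not the upstream
database retrieval.

## Known limitations

* The small-molecule EIIP-profile encoding is not implemented; a profile
  file is required.
* S/N values depend on the padding and S/N conventions above; published
  S/N numbers computed under other (unstated) conventions are not
  comparable digit-for-digit.
* ANOVA is fixed-effects and per-measure; no multiple-testing correction
  across bands is applied (six bands ⇒ interpret per-band p-values
  accordingly).
* PCA, curve-fitting deconvolution of Amide I, and alias-aware identifier
  mapping are out of scope.
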