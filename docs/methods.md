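# Methods

## Mass arithmetic

Monoisotopic masses are summed from the NIST isotope table bundled with
pyteomics (most abundant isotope per element, ≥9 decimals). Adduct m/z is

    m/z = (M + Σ Δelement masses − z·m_e) / |z|

with the CODATA electron mass m_e = 5.48579909×10⁻⁴ Da. The electron-mass
correction is required for 4-decimal agreement with reference values: it
shifts a sodiated ion by −0.0005 Da.

Two display conventions are deliberate and load-bearing:

* **Rounding** is half-away-from-zero at the displayed precision
  (4 decimals for m/z, 1 for ppm); internal values are never rounded.
* **ppm deviations** are computed as (calcd − observed)/calcd × 10⁶ using
  the *displayed* (4-decimal) calculated m/z, not the full-precision one.
  This is the convention under which all reference deviations reproduce
  (e.g. observed 547.2215 vs calcd 547.2238 → +4.2 ppm; the full-precision
  calcd 547.22385 would give +4.3). `adduct_mz` itself always returns full
  precision; only `mass_match` records display values.

Degrees of unsaturation use DBE = C + 1 + N/2 − H/2, with halogens counted
like H, P like N, and divalent O/S ignored. Printed formulas for
deprotonated ions appear in two dialects (neutral formula vs ion formula
with one H removed); both are handled by applying the `[M−H]−` adduct rule
to the neutral composition.

## ECD simulation

Bands are Gaussian in the energy domain because the bandwidth ζ is an
energy (default 0.16 eV); the curve is evaluated at the energies
corresponding to the wavelength grid and the rigid Δλ = +1 nm shift is
applied to the final curve (for a uniform shift, per-transition and
final-curve application are indistinguishable). ζ is interpreted as the
1/e half-width σ; an FWHM interpretation is available via
`BandShapeParams(zeta_is_fwhm=True)`. The normalization constant
c₀ = 2.297×10⁻³⁹ converts E[eV]·R[cgs] into Δε in M⁻¹cm⁻¹ (standard
chiroptical convention); all comparison scores are invariant to it because
spectra are normalized before scoring.

Default grid: 180–400 nm at 0.5 nm, covering the 195–283 nm region where
the diagnostic bands of the compound class fall, with margin. Conformers
are re-referenced so the most stable sits at ΔG = 0, truncated at
ΔG ≤ 4 kcal/mol (inclusive), and weighted at 298.15 K by default — the
standard temperature for Gibbs-energy populations; it is configurable
since upstream thermochemistry defines it. Degenerate conformers are all
retained with equal weights; no symmetry-number corrections are applied.

Averaging requires identical grids and raises on mismatch rather than
resampling silently; resampling is an explicit operation
(`resample_to_common_grid`: linear interpolation onto the overlap range at
the finer step).

## Spectrum comparison and assignment

Reference-band scaling divides by |Δε(λ_peak)| at the maximum *positive*
value within 205–230 nm. In `assign_configuration`, spectra lacking a
positive band there (possible for arbitrary ensembles and for strongly
negative-biased mixtures) are normalized by max |Δε| instead and the
result is flagged in its `error` field rather than dropped — cosine
scores are invariant to the normalization choice, so the ranking is
unaffected; only an identically zero spectrum is unscorable.

The combined score is the mean of the curve cosine and the
first-derivative cosine (central differences, one-sided at the ends). The
derivative term penalizes curves whose extrema sit at shifted wavelengths
even when broad band patterns agree. Extrema are CD band extremes —
positive maxima and negative minima with prominence ≥ 5% of max |Δε| by
default (a positive-valued dip between two positive bands is not a band);
matching tolerance is |Δλ| ≤ 5 nm, configurable.

Mixture search is restricted to two components on a discrete ratio grid
(default steps of 0.1). Score ties — exact for enantiomer pairs, whose
non-racemic mixtures are scalar multiples of the dominant component after
scaling and hence shape-identical — resolve toward the pure isomer, then
alphabetically. This is why an enantiomer-mixture ratio can be genuinely
unidentifiable from a scaled ECD curve: the full ratio-similarity profile
is returned instead of a forced unique ratio.

## LC/MS profiles

The 1% noise rule removes peaks with area/total × 100 strictly below the
threshold, relative to the *pre-filter* total (a peak at exactly 1.0%
survives). The relative-area basis is the per-sample total ion area.
Polarity zones are half-open [lower, upper), boundaries at 9, 21 and
39 min by default, with RT exactly on a boundary assigned upward and peaks
before the first boundary collected in a pre-gradient bucket, so zone
counts and areas always conserve table totals.

The profile matrix matches features across samples by feature id when
present, else by greedy nearest-RT matching within tolerance (default
0.2 min, 10 ppm), deterministically in input order. Cells are relative
areas (rows sum to 1); the heat-map transform is log10 with absent
features floored at −6 (pseudo relative area 10⁻⁶). PCA runs on the log
matrix with per-feature mean centering only (no unit-variance scaling);
both the log transform and the matrix basis are configurable because
reasonable analyses differ here. The noise filter belongs to the LC/UV
zone bookkeeping stage and is *not* applied before the profile matrix:
the multivariate stage uses all detected features, and filtering would
inject spurious presence/absence contrasts among otherwise similar
conditions. k-means (k = 2 by default, matching the typical
outlier-vs-rest outcome) uses 10 seeded restarts and canonicalizes labels
by first occurrence, making runs bitwise reproducible for a seed.

## Synthetic data

`gen_ensemble` draws conformer ΔG from an exponential distribution
(mean 1.5 kcal/mol — several conformers populated under the 4 kcal/mol
cutoff, as for a flexible natural product), transition wavelengths
uniformly over 185–320 nm, and rotatory strengths from a centered normal
(scale 30×10⁻⁴⁰ cgs), 95 transitions per conformer and 8 conformers by
default. Chirality only flips every rotatory-strength sign, so enantiomer
pairs are exact mirrors by construction. `gen_experimental_spectrum` adds
white Gaussian noise (σ = noise_fraction × peak |Δε|) and an optional slow
quadratic baseline.

`gen_peak_tables` emulates a five-condition comparison (labels
Pv0/PvMg/PvFe/PvZn/PvNi): 12 shared features with log-normal area noise
(CV 0.3) around feature-specific base areas spread over ~1.5 orders of
magnitude, one exclusive feature per ordinary condition, and an outlier
condition (PvFe) with three exclusive features and all areas multiplied
by 5. Note the global multiplier cancels in the row-normalized relative
areas; the outlier's separation in PCA/k-means is carried by its
presence/absence structure, which is also what distinguishes such an
extract in practice (new metabolites appearing, others vanishing).

What the generators do *not* emulate: correlated (pink) spectrometer
noise, wavelength-calibration error, solvent cutoff artifacts below
~190 nm, retention-time drift between runs, detector saturation, and any
real metal-stress biology. Passing recovery tests therefore demonstrate
the statistical machinery under idealized noise, not instrument-grade
robustness.

## Problem sizes and determinism

The recovery benchmarks use 200 seeded ensembles (6 conformers × 95
transitions, 1 nm grid, 10% noise) for chirality recovery and 100 seeded
table sets for the clustering benchmark; both complete in seconds and
their rates are stable under seed-offset changes. All randomness flows
through `numpy.random.default_rng` seeded per call; no global state.

## Known limitations

* UV (oscillator-strength) spectra, vibronic structure and solvent-shift
  modeling are out of scope; ζ and Δλ absorb such effects empirically.
* The mass module covers C, H, N, O, S, P, Na, K and the halogens;
  isotope-pattern simulation and formula inference from mass are not
  provided.
* One reference calcd value (the saroclazine A sodium adduct) is printed
  as 417.1278 in the source annotations but is arithmetically 417.1277 —
  the accompanying −0.2 ppm deviation is only consistent with the latter.
  The package reports the computed value.
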