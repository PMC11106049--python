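# osmactools

Computational support for OSMAC-style natural-products studies ("One
Strain Many Compounds": varying culture conditions to elicit different
secondary metabolites from a single microbial strain). The package covers
the three desk-work stages of such a study:

1. **HRESIMS arithmetic** — given a molecular formula, compute the
   monoisotopic mass, adduct m/z (`[M+H]+`, `[M+Na]+`, `[M−H]−`, with
   electron-mass correction), the ppm deviation from an observed ion, and
   the degrees of unsaturation.
2. **ECD simulation and absolute-configuration assignment** — turn
   TDDFT transition lists for a conformer ensemble into Boltzmann-averaged
   electronic circular dichroism curves, and rank stereoisomer hypotheses
   (including enantiomer mixtures) against a measured spectrum.
3. **LC/MS profile comparison** — noise-filter peak tables, summarize
   retention-time polarity zones, build the log relative-area matrix behind
   condition×metabolite heat maps, and run PCA and k-means over
   cultivation conditions.

A synthetic-data module generates seeded conformer ensembles, noisy
"experimental" spectra and multi-condition peak tables with known ground
truth, so every stage is testable end to end without quantum-chemistry
software or instrument data.

## The model in brief

Conformer populations follow Boltzmann statistics over relative Gibbs free
energies (kcal/mol), after discarding conformers above a ΔG cutoff
(default 4 kcal/mol):

    g_i = exp(−ΔG_i / RT) / Σ_j exp(−ΔG_j / RT),   R = 1.98720×10⁻³ kcal/(mol·K)

Each electronic transition (energy E_i in eV, rotatory strength R_i in
10⁻⁴⁰ cgs) contributes a Gaussian band in the energy domain,

    Δε_i(E) = E_i R_i / (c₀ √π σ) · exp(−((E − E_i)/σ)²),   c₀ = 2.297×10⁻³⁹

with bandwidth σ = ζ (default 0.16 eV). The summed, population-averaged
curve is shifted by Δλ = +1 nm and, for comparisons, scaled to its positive
reference band: Δε_sc(λ) = Δε(λ)/|Δε(λ_peak)| with λ_peak in 205–230 nm.
Agreement between calculated and experimental curves is quantified by the
cosine similarity of the scaled spectra, the cosine similarity of the first
derivatives dΔε/dλ, and the number of band extrema matched within 5 nm.

## Worked example

`python examples/hresims_check.py` verifies formula assignments for four
isolated compounds:

```
compound       formula       adduct     observed      calcd   dppm  DBE
helvamide B    C34H32N2O5    [M+Na]+    571.2193   571.2203   +1.8   20
helvamide B    C34H32N2O5    [M-H]-     547.2215   547.2238   +4.2   20
helvamide C    C31H34N2O5    [M+Na]+    537.2358   537.2360   +0.4   16
helvamide C    C31H34N2O5    [M-H]-     513.2405   513.2395   -1.9   16
saroclazine A  C19H26N2O3S2  [M+Na]+    417.1278   417.1277   -0.2    8
guaiane diol   C15H24O2      [M+Na]+    259.1669   259.1669   +0.0    4
guaiane diol   C15H24O2      [M-H]-     235.1701   235.1704   +1.3    4
```

Each row compares an observed ion with the calculated adduct m/z; the ppm
column is (calcd − observed)/calcd × 10⁶ and the DBE column the rings plus
π-bonds implied by the neutral formula. `examples/ecd_assignment.py` runs
the full configuration-assignment workflow on a synthetic ensemble (the
true chirality ranks first with combined similarity +0.80 at 5% noise;
its enantiomer ranks last near −0.80), and `examples/osmac_profiles.py`
reproduces the profile-comparison pipeline on five synthetic cultivation
conditions, where the intensity-boosted, feature-distinct condition forms
its own k-means cluster.

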