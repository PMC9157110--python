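# Methods

## Scope and data model

`pollenomics` implements the post-acquisition quantification workflow of a
targeted multi-omics experiment on in-vitro grown tobacco pollen tubes under
five temperature regimes — 3 h at room temperature (RT3), 6 h at RT (RT6),
3 h RT + 3 h heat stress at 37°C (HS3+3), 3 h RT + 6 h HS (HS3+6) and heat
stress relief (HSR, 3+3+3 h). It starts from integrated peak areas (MRM
transitions for lipids, GC-FID/GC–MS peaks for fatty acids and metabolites,
read counts for transcripts); chromatogram processing, spectral matching,
alignment and differential-expression model fitting are upstream tools and
out of scope. Differential-expression flags are therefore an *input*
(per-gene log2FC and FDR), never computed here.

## Lipid species model

Species are identified by shorthand nomenclature (`PC 34:2`,
`PC 16:0_18:2`, `HexCer 18:1;O2(d4)/24:0;O(2OH)`, `SE cholesterol/18:2`).
The subclass registry (YAML, editable) records for each subclass its
category, chain count, ionization polarity and net backbone/headgroup
element contributions. Elemental formulas are assembled as

    backbone + headgroup + steryl residue + Σ free-chain formulas
    − one H2O per ester/amide-bound acyl chain,

with headgroup residues stored already condensed. Sum-composition species
use a generic di-/triacyl skeleton with the stated total carbons and double
bonds; this is exact for carbon counting (which is all the isotope
correction needs) and approximate only in the unobservable chain split.
Positional features (Δ4/Δ8 base double bonds, base C4-OH, acyl C2-OH) are
parsed when annotated and recorded as *unresolved* otherwise — they are
never imputed, because the MRM data often cannot place a hydroxyl or double
bond unambiguously. Δ4 desaturation and C4 hydroxylation are mutually
exclusive by construction.

## Isotopic correction

The isotopic correction factor converts a monoisotopic (M0) peak area to a
total-species abundance. Under an independent-atoms binomial model with
natural ¹³C abundance p = 0.0107 (configurable), a species with n carbons
has M0 fraction (1−p)ⁿ, so

    icf = (1 − p)^(−n),

a type-I correction only: M+2 overlap deconvolution between species is
deliberately not modeled. The factor is applied per transition before
summation; because it is constant per species, applying it per species
after summation would give identical results.

## Quantification chain

1. corrected_area = raw_area × icf (unparseable species go to a rejects
   report, never silently dropped; missing transitions are zeros and
   propagate);
2. species area = Σ corrected transition areas;
3. subclass total = Σ species areas; relative abundance = total divided by
   the **mean** of the RT3 replicate totals (so the RT3 mean is 1 by
   construction); species mol% = 100 × species area / subclass total.

Peak areas are treated as proportional to molar amounts after isotope
correction; per-species response factors are not applied, mirroring the
source workflow. The "major species" display rule marks species whose
condition-mean mol% strictly exceeds 1% in at least one condition.

Saturation classes count double bonds in the *fatty-acyl* residues only
(sphingoid-base double bonds are modifications, not acyl desaturation):
0 = saturated, 1 = monounsaturated, ≥2 = polyunsaturated; abundances per
class are converted to fractions that sum to 1.

Sphingolipid modification occurrence is the share of a subclass total
carried by species bearing a feature (base C4-OH, Δ4, Δ8, acyl C2-OH,
VLCFA = acyl C ≥ 20). Abundance weighting is the default; a
species-count weighting is available because "percentage of species" can be
read either way. Species whose feature state is unresolved are excluded
from the numerator and reported separately as an unresolved share.

## Absolute quantification

TG: GC-FID FAME areas against 0.05 mg triheptadecanoate (the 17:0 FAME).
FID response is assumed mass-proportional and equal across FAMEs, so
mass_i = area_i/area_IS × 0.05 mg; the TG amount is reported as the sum of
FAME-equivalent fatty-acid masses per mg dry pollen (default 20 mg), with
per-FA contributions. Glycerol-backbone mass reconstruction is not applied.

Metabolites: quant-ion areas against 0.0125 mg allo-inositol per sample;
response = area/IS area, folded to the RT3 mean. A per-row dilution factor
undoes deliberate dilution runs (sucrose is measured at one-tenth
concentration, factor 10).

## Statistics

Multi-condition comparisons: classical one-way ANOVA (α = 0.05) followed by
all-pairs Tukey HSD. The studentized-range statistic uses the Tukey–Kramer
form q = |m_i − m_j| / sqrt(MSE/2 × (1/n_i + 1/n_j)); its p-value comes
from `scipy.stats.studentized_range` (numerical integration of the range
distribution). Letters are assigned by the insert-and-absorb algorithm:
starting from one letter covering all groups, each significant pair splits
the letters containing both, absorbed subsets are removed, and letters are
ordered a, b, c… by descending group mean (ties by input order). Two groups
share a letter iff their adjusted p > α. Degenerate inputs (zero MSE) yield
p = 0 for unequal means and p = 1 for equal means, flagged.

Two-condition comparisons use the pooled-variance Student t (Welch by
flag) with stars * P < 0.05, ** P < 0.01, *** P < 0.005.

## Transcript aggregation

CPM = count/library size × 1e6 with library sizes = column sums unless
supplied; the detection filter keeps genes with CPM strictly > 0.5 in ≥ 2
libraries. RPKM = count/(length/1000)/(library size/1e6) with union-exon
gene lengths in bp. GO-term quantification sums RPKM over a term's detected
member genes per sample, then takes log2 of the ratio of condition means
and a Student t on the per-sample sums. DEG tallies use strict thresholds
|log2FC| > 1, FDR < 0.005.

Note an inherent property of this statistic: because library sizes include
the regulated genes, a uniform 2^d shift of a gene set recovers d minus the
log2 change of total library size (composition effect). The tests verify
recovery exactly after accounting for this renormalization.

## Synthetic data

The generator reproduces the study design: 5 conditions × 5 replicates for
lipids/FAMEs/metabolites, 3 conditions × 3 replicates for counts. Replicate
noise is multiplicative lognormal parameterized by CV (default 0.15,
mean 1); effects are injected as

* subclass abundance folds relative to RT3, defaulting to the reported
  magnitudes (SPBP 5.8× HS3+3 vs RT6 and 2.8× HS3+6 vs HSR, HexCer +30%,
  sterylglycosides +84%, TG 2×, sterol esters down);
* saturation shifts (+15 percentage points saturated under HS for PC and
  MGDG, a realistic magnitude for heat-stressed membrane lipids) moving
  mass from polyunsaturated to saturated species **within** the subclass,
  so abundance and saturation effects are independently testable;
* modification shifts moving HexCer mass from Δ4- to C4-OH-carrying
  species (+31% C4-OH occurrence under HS on a 90% baseline Δ4 share);
* metabolite folds (sucrose 2×, sedoheptulose 3× under HS);
* a DE gene fraction (10%, 65% up) with log2 effect 2 in HS3+3 and the
  first GO terms enriched in upregulated genes.

Truth areas are divided by the species icf and split over 1–3 mass
transitions before emission, so the pipeline recovers every injected effect
*exactly* at CV = 0. Counts are negative binomial (dispersion 0.1 by
default); dispersion 0 returns the continuous expected means (noise-free
mode). All generators are deterministic under a fixed integer seed.

What the generator does **not** emulate: per-species response-factor
differences, retention-time and integration artifacts, censoring at the
detection limit, correlated noise between co-eluting species, and
count-depth differences between libraries. Passing recovery tests therefore
demonstrate correctness of the arithmetic chain under the assumed error
model, not robustness to instrument-level artifacts.

## Numerical choices, problem sizes, limitations

* Zero subclass totals make mol% and normalization undefined; results carry
  NaN and a flagged list rather than raising.
* The major-species and CPM thresholds are strict (`>`), DEG thresholds
  strict (`>` / `<`), matching the stated rules; boundary cases are tested.
* Recovery simulations use 200 seeds at the study design; the ANOVA null
  calibration uses 10,000 simulated datasets (5 groups × n = 5); the
  transcript recovery runs use 300-gene matrices, sizes chosen to keep the
  suite fast while leaving Monte-Carlo error well below the tested margins.
* The saturation-shift estimator (difference of condition means of the
  saturated fraction, n = 5) has a per-run SD of ≈1.6 percentage points at
  CV 0.15, so single-run estimates scatter a few points around the injected
  value; recovery is asserted via the empirical 95% interval over seeds and
  exactness in the noise-free limit.
* Letter displays are minimal under insert-and-absorb but, as for any CLD,
  not guaranteed unique; ordering rules make them deterministic.
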