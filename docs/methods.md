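# Methods

This note records the quantitative model implemented by `nifquant`, the
numerical conventions, the scope of the synthetic data generator, and the
known limitations.

## Sequence arithmetic

Tryptic digestion cleaves C-terminal to K or R except when the next
residue is proline; missed-cleavage enumeration returns every fragment
spanning at most *m* retained internal sites. Peptide coordinates are
1-based inclusive against the parent sequence; promoter motif positions
(the σ54 scan for TGGC-N7-TTGC) are 0-based half-open.

Monoisotopic masses use per-residue monoisotopic values plus one water
(18.010565 Da) per peptide. Ion m/z is `(M + z·1.007276)/z`. The heavy
label adds 8.0142 Da per K or R (¹³C₆ plus ¹⁵N₂); uridylylation adds
306.0253 Da. y-ions are the C-terminal fragment series, `y_n` of an
*n*-residue peptide coinciding with the singly protonated full peptide.
All mass arithmetic is implemented in-package; the test suite
cross-checks it against pyteomics as an independent oracle.

## Standard design

Candidate signature peptides must be unique in the proteome (checked
against all tryptic peptides with up to one missed cleavage), 5–25
residues long, with a 2+ precursor inside 50–1800 m/z, more than 3
usable y-ions, and no His/Met/Cys. Two soft filters — KK/RR double-basic
context and proline adjacency — are relaxed in that order if fewer than
the required number of candidates survive. Each selected peptide is
embedded in the concatamer with its native three-residue flanks;
BSA control peptides terminate the construct. Assembly fails unless an
in-silico digest of the full concatamer releases every signature peptide
exactly once.

Transition lists pair each peptide's light and heavy precursors with its
highest-index in-range y-ions. Collision energy and declustering
potential are linear functions of precursor m/z (defaults
`0.044·m/z + 5.5` and `0.061·m/z + 50.5`), with 3 ms dwell and a 270 s
retention window.

## Quantification

For each peptide in each sample, light and heavy areas are summed over
the shared validated transition set (at least two transitions); the
summed-area ratio — equivalent to a heavy-area-weighted mean of
per-transition ratios — scales the known spiked standard amount
(`µg mL⁻¹ / MW × digest volume`). Copies per cell divide the endogenous
amount by the cell count in the digest:
`OD600 × culture mL × 10⁹ cells mL⁻¹ OD⁻¹ × aliquot/resuspension`.
Proteins are rolled up as the mean over peptides (median optional);
single-peptide values carry a flag. Modifiable PTM-site peptides are
excluded from copy rollups (they are partially modified), and PTM
occupancy is computed only from them, as modified/(modified+unmodified)
light areas.

Transition validation regresses the light/heavy ratio on extract
dilution (r² ≥ 0.98 over at least four levels); the LOD is the lowest
assayed concentration whose fitted light signal exceeds the blank mean
plus three standard deviations, required to be ≤ 1 nM.

## Metabolites

Amino-acid standard curves are least-squares lines; low levels are
dropped one at a time until the remaining region is linear (r² ≥ 0.99)
and every level back-calculates within ±20% of nominal; the LOQ is the
lowest retained level. Sample areas convert through the curve, the
derivatisation dilution and extract volume to moles, then to
intracellular molarity over the cell count at an assumed 1 fL cell
volume (1 µM intracellular ≈ 602 molecules per cell). Below-LOQ values
are flagged, not dropped. Fold changes use each amino acid's base mean
(the mean of per-time-point means, so fold changes average to exactly
1); strain contrasts use two-sample t-tests with Benjamini–Hochberg
adjustment across the amino-acid × time grid.

## Physiology

Growth rate is `ln(OD₂/OD₁)/Δt` over a window. The ammonium assay is a
linear absorbance curve over 78–5000 µM; readings below the lowest
standard are reported censored ("< 78 µM") rather than extrapolated.
Acetylene-reduction corrects ethylene areas for headspace sampling
losses via the concomitant acetylene dilution (`E(t)·A(0)/A(t)`), then
reports interval rates in nmol OD⁻¹ mL⁻¹ h⁻¹.

## Resource allocation

Net synthesis rates are copy-number differences across the
transition window (default 7.5–12.5 h) divided by elapsed seconds;
declining copy numbers are flagged rather than truncated (degradation is
not modelled). Per-amino-acid demand multiplies each rate by residue
counts; the total equals the rate-weighted sum of lengths exactly. Pool
support time is pool size over demand. Assembled nitrogenase is limited
by the least abundant subunit at 4:2:2 NifH:NifD:NifK; glutamine
synthetase assembles as a dodecamer. The N-fixation rate is
complexes × k_cat (5 s⁻¹) × 2 N atoms per turnover. Proteome fraction
divides Nif residues by an assumed 7.6×10⁷ total polymerised residues;
ribosome occupancy divides total demand by 8000 active ribosomes × 5
residues s⁻¹. Both return an over-capacity warning flag when they exceed 1.

## Synthetic scenario

The generator is phenomenological: logistic copy-number induction,
Hill-of-ammonium PII uridylylation, first-order pool relaxation. The
culture model consumes ammonium at a fixed yield during exponential
pre-growth, arrests below 10 µM, and (wild type only) resumes growth at
a rate saturating in the active nitrogenase count. Structural subunits
(NifHDK) induce later but far higher than accessory Nif proteins, so
their ratio rises through the transition. Three strains are produced:
wild type; a regulatory deletion with zero nif expression; and a
truncation mutant expressing nif at 10% of wild type (no fixed-nitrogen
feedback) with zero nitrogenase activity.

The noiseless skeleton — proteome sequences, kinetics, per-transition
response factors, per-analyte response slopes — is fixed by an internal
seed and independent of the user-facing seed, which drives measurement
noise only (mean-unbiased multiplicative lognormal areas, Gaussian OD
and absorbance noise). Identical seeds reproduce outputs exactly;
distinct seeds share identical ground truth.

## Numerical conventions

- Avogadro 6.022×10²³ mol⁻¹; proton 1.007276 Da; water 18.010565 Da.
- Headline figures are reported alongside a two-significant-figure
  convenience rounding (`round_sig`).
- Time integration of the culture model uses explicit Euler at 0.01 h;
  sampled quantities are read at the sampling grid.
- Output tables carry provenance headers (version, seed, config hash).

## Limitations

- The Nif proteome fraction computed from the synthetic end-point copy
  numbers exceeds 1 (≈2.4) against the assumed 7.6×10⁷-residue proteome.
  This over-unity result is reported with an explicit warning flag
  rather than silently rescaled: the measured copy numbers, the assumed
  proteome size and the per-cell normalisation cannot all be
  simultaneously consistent, and the package surfaces that tension
  instead of hiding it.
- Protein degradation and dilution by growth are not modelled; synthesis
  rates are net rates and demand may be underestimated.
- The scenario generator does not model the ntr signalling cascade
  mechanistically; it provides known ground truth with realistic noise
  structure for validating the measurement pipeline, not a systems model.
- Calibration simulation adds a small additive baseline to light areas
  only; detector saturation and chromatographic interference are out of
  scope.
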