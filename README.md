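# nifquant

Absolute protein quantification and nitrogen resource-allocation modelling
for the bacterial transition to diazotrophy.

When a free-living diazotroph such as *Klebsiella oxytoca* exhausts its
supply of fixed nitrogen, it faces a bootstrapping problem: expressing
nitrogenase — one of the most resource-expensive enzyme systems known —
requires enormous quantities of amino acids precisely when nitrogen for
amino-acid synthesis has run out. `nifquant` implements the complete
computational workflow for studying this transition quantitatively:

- **QconCAT standard design** — selection of proteotypic tryptic peptides,
  assembly of artificial concatamer standards with native sequence flanks,
  and generation of SRM/MRM transition lists (precursor and y-ion m/z for
  light and heavy isotope states, collision energies, dwell times).
- **Isotope-dilution SRM quantification** — conversion of transition-level
  peak areas into absolute protein copies per cell via the light/heavy
  ratio against the spiked heavy-labelled standard, with
  calibration-curve validation (linearity, LOD) and PTM site-occupancy
  estimation for the uridylylated PII proteins GlnB/GlnK.
- **Amino-acid pool quantification** — external standard curves with
  automatic LOQ location, conversion to intracellular molarity and
  molecules per cell, base-mean fold changes, and
  Benjamini–Hochberg-adjusted strain contrasts.
- **Culture physiology** — growth rates, the colorimetric ammonium assay
  (with censoring below the lowest standard), and acetylene-reduction
  rates with headspace-dilution correction.
- **Resource allocation** — protein synthesis rates, per-amino-acid
  substrate demand, pool support times, assembled nitrogenase complexes
  (limited by the least abundant subunit at 4:2:2 NifH:NifD:NifK
  stoichiometry), implied N-fixation rates, and proteome/ribosome
  capacity fractions.
- **Synthetic data generation** — a ground-truth scenario generator
  (ammonium run-out, delayed nif induction, three strains including
  regulatory-deletion and truncation mutants) used to validate the entire
  pipeline by parameter recovery.

## Quick start

Run the complete workflow on the default synthetic scenario:

```
nifquant run-all --seed 1 --outdir out/
```

This writes provenance-stamped TSV tables (protein copies, PTM occupancy,
amino-acid pools, fold changes, strain contrasts, culture time course,
acetylene-reduction rates) and `allocation_summary.json`. Individual
stages are available as `simulate`, `design`, `quantify`, `metabolites`,
`physiology` and `allocate`; a YAML config (`--config`) can override any
scenario or constants parameter.

## Worked example

From transition areas to copies per cell, in a few lines:

```python
from nifquant.sequences import ion_mz
from nifquant.srm import (PeakMeasurement, SampleMeta,
                          quantify_peptide, protein_copies_per_cell)

# SRM coordinates of a signature peptide (2+ precursor, 1+ y6)
ion_mz("GAFTGAVR", 2, "precursor")          # 389.7139
ion_mz("GAFTGAVR", 2, "precursor", "heavy") # 393.7210  (+8.0142 Da / z)
ion_mz("GAFTGAVR", 1, "y6")                 # 650.3620

# light/heavy summed-area ratio x known standard amount
measurements = [
    PeakMeasurement("t10_r1", "GAFTGAVR", "y5", "light", "none", 8.1e4),
    PeakMeasurement("t10_r1", "GAFTGAVR", "y6", "light", "none", 1.9e5),
    PeakMeasurement("t10_r1", "GAFTGAVR", "y5", "heavy", "none", 5.4e4),
    PeakMeasurement("t10_r1", "GAFTGAVR", "y6", "heavy", "none", 1.3e5),
]
amount = quantify_peptide(measurements, standard_conc_ug_ml=0.7,
                          qconcat_mw_da=55000.0, digest_volume_ul=300.0)
# 5623.518 fmol  (ratio 1.473 x 3818 fmol spiked standard)

# per-cell conversion: OD 0.2 x 15 mL x 1e9 cells/mL/OD x 30/500 aliquot
meta = SampleMeta("t10_r1", "wild_type", 10.0, od600=0.2)
meta.cells_in_digest()                      # 1.8e8 cells
q = protein_copies_per_cell({"GAFTGAVR": amount,
                             "LVSDFTK": amount * 1.1}, meta)
q.copies_per_cell                           # 19754.5 (mean of 2 peptides)
```

The headline allocation arithmetic is equally direct:

```python
from nifquant.allocation import (NITROGENASE_STOICHIOMETRY, complex_count,
                                 fixation_rate, ribosome_occupancy)

complex_count({"NifH": 290_000, "NifD": 114_000, "NifK": 70_745},
              NITROGENASE_STOICHIOMETRY)    # 35372.5 (NifK-limited)
fixation_rate(35_000)                       # 350000.0 N atoms per second
ribosome_occupancy(19_000)                  # (0.475, False)
```

## Package layout

| Module | Contents |
| --- | --- |
| `nifquant.sequences` | tryptic digestion, monoisotopic masses, ion m/z, σ54 promoter motif scan, FASTA I/O |
| `nifquant.design` | proteotypic peptide filters, QconCAT assembly and release verification, transition lists |
| `nifquant.srm` | report parsing, calibration validation, isotope-dilution quantification, PTM occupancy |
| `nifquant.metabolites` | amino-acid standard curves, per-cell pools, fold-change statistics |
| `nifquant.physiology` | growth rates, ammonium assay, acetylene-reduction rates |
| `nifquant.allocation` | synthesis rates, amino-acid demand, complex counts, capacity fractions |
| `nifquant.simulate` | ground-truth scenario generator and measurement-channel simulators |
| `nifquant.pipeline` / `nifquant.cli` | orchestration, provenance-stamped outputs, CLI |

See `docs/methods.md` for the quantitative model, parameter choices and
known limitations.
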