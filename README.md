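# qconkit

Absolute quantification of low-abundance serum proteins by **QconCAT /
isotope-dilution mass spectrometry (IDMS)**, with a synthetic LC-MS
simulator standing in for the instrument so the whole workflow runs and is
testable at desk scale.

The package is written for proteomics method developers and bioinformaticians
who quantify biomarkers (the model analytes here are the colorectal-cancer
serum markers DcR3 and GDF15) by spiking a known amount of a ¹⁵N-metabolically
labelled internal standard into a serum digest and measuring light/heavy
signal ratios.

## The method

A *QconCAT* is an artificial protein concatenating tryptic "fingerprint"
peptides of the target proteins.  Trypsin releases each peptide in a strict
1:1 molar ratio to the concatamer, so a spike of *S* fmol of the
¹⁵N-labelled concatamer digest adds *S* fmol of every heavy standard
peptide.  Expressing the standard on a ¹⁵N-only nitrogen source shifts each
peptide by

&nbsp;&nbsp;&nbsp;&nbsp;Δm = N × (m(¹⁵N) − m(¹⁴N)) = N × 0.997035 Da,

where *N* is the peptide's nitrogen count, cleanly separating light
(endogenous) from heavy (standard) while keeping chemistry and retention
time identical.  For each fingerprint peptide an extracted ion chromatogram
(XIC; 0.3 Th m/z window, 4 min retention-time window) is integrated for the
light and heavy species at the chosen charge state, and the analyte amount
and serum concentration follow from

&nbsp;&nbsp;&nbsp;&nbsp;amount = S · A_light / A_heavy,&nbsp;&nbsp;&nbsp;
C = amount / (V_serum · ∏ aliquot fractions).

Around that core the package provides: in-silico tryptic digestion (K/R,
proline rule, missed cleavages), fingerprint-candidate scoring
(8–15 aa preference, proline/di-basic avoidance, cleavage-context-aware
uniqueness screening against a background proteome), peptide-mass-fingerprint
identification with sequence coverage, spike-in calibration fitting, cohort
statistics, and a seeded LC-MS simulator producing mzML with isotope
envelopes and multiplicative noise.

## Worked example

Quantify a DcR3-like analyte at healthy-serum concentration from a simulated
run (50 fmol heavy spike, 3 % multiplicative noise, 0.1 ml serum):

```python
from qconkit import (SpeciesSpec, RunSpec, simulate_run, measure_pair,
                     peptide_mass, heavy_mass, nitrogen_count, mz)

pep = "LLQALR"                       # DcR3 fingerprint peptide, 10 nitrogens
print(peptide_mass(pep), mz(peptide_mass(pep), 2))   # 712.4595 Da, 357.2370 Th
print(heavy_mass(pep), mz(heavy_mass(pep), 2))       # 722.4299 Da, 362.2222 Th

spec = RunSpec(
    species=(SpeciesSpec(pep, "light", 2, 2.723),    # 27.23 fmol/ml x 0.1 ml
             SpeciesSpec(pep, "heavy", 2, 50.0)),    # internal standard
    seed=1, noise_cv=0.03,
)
m = measure_pair(simulate_run(spec), pep, 2, spike_fmol=50.0)
print(f"{m.ratio:.4f}  {m.analyte_fmol:.3f} fmol  {m.concentration_fmol_per_ml:.2f} fmol/ml")
```

prints

```
712.4595449999999 357.23704949999996
722.429895 362.22222374999996
0.0546  2.732 fmol  27.32 fmol/ml
```

— the light/heavy area ratio 0.0546 times the 50 fmol spike recovers
2.732 fmol in the analysed sample, i.e. 27.32 fmol/ml of the 27.23 fmol/ml
ground truth (0.3 % error at this noise level and seed).

The same workflow is available from the shell:

```sh
qconkit simulate --mode run --seed 5 --out sim/
qconkit quantify --run sim/run.mzml --assay assay.yaml --out results.csv
qconkit calibrate --seed 1 --out calibration.csv
qconkit pipeline --assay assay.yaml --runs sim/run.mzml --out results/
```

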