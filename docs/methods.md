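# Methods

This note records the models, conventions and numerical choices behind
qconkit, in the spirit of a package methods appendix.  It states nothing the
test suite or `scripts/acceptance.py` does not itself compute.

## Chemistry and digestion

Peptide masses are sums of residue masses plus water (monoisotopic
18.010565 Da), from a built-in table of the 20 standard amino acids carrying
monoisotopic mass, average mass and elemental composition per residue.  The
table is dumpable and overridable for audit; masses cross-check against an
independent elemental-composition implementation (pyteomics) in the tests.
Constants are fixed to at least six decimals — proton 1.007276 Da,
¹⁵N−¹⁴N 0.997035 Da — so derived values are bit-stable.  Charge states
follow [M + z·H]^z+: m/z = (M + z × 1.007276)/z.

Trypsin cleaves C-terminal to K and R except before proline; the K·P rule
is applied to both K and R sites (the standard convention).  Digestion
enumerates all fragments with up to a configured number of internal missed
cleavages; the 0-missed fragments tile the parent exactly, and the
implementation is verified against a brute-force enumerator over all
candidate cut points.  Nonstandard letters (B, Z, X, U) are rejected with
the offending position named — a silently wrong mass is worse than a hard
failure.

¹⁵N metabolic labelling is modelled as complete: heavy mass = light mass +
N × 0.997035 Da, with the same per-atom shift used for average masses (the
approximation error is orders of magnitude below the 0.3 Da tolerances used
throughout).  Incomplete labelling is handled downstream by an optional
ratio correction (below).

Variable modifications are a small registry — oxidation on M
(+15.994915 Da) and nitration on Y (+44.985078 Da) — matching the
modifications considered during identification.

## Fingerprint-peptide design

Candidate rules are *scored preferences, not hard filters*: preferred length
8–15 aa, no K/R·P junction involved in release, no adjacent basic residues
(KK/KR/RK/RR) inside or straddling the peptide.  A short peptide can still
be a perfectly good fingerprint (the DcR3 peptide LLQALR, 6 aa, is the
canonical example), so candidates are ranked by rules satisfied, ties broken
by parent position.

The uniqueness screen is cleavage-context aware: an exact sequence hit in a
background protein only conflicts if trypsin could liberate it there — the
residue immediately N-terminal to the hit is K or R, or the hit begins the
protein (counted liberable, erring toward declaring conflicts).  Matching is
sequence-exact; I/L equivalence is deliberately not applied (the
quantification chemistry distinguishes copies only through liberation
context, not isobaric identity) and would be a one-line extension.

QconCAT assembly requires every peptide to end in K/R and not begin with P,
then verifies by digestion that each peptide is released; the concatamer's
molar mass is its average-mass peptide mass, used for μg ↔ pmol conversion
(pmol = μg/M × 10⁶).

With an unlabelled fraction *f* in the standard, the measured heavy area
represents (1−f) of the spike and the leak adds f/(1−f)·A_heavy to the light
channel; the corrected ratio is (A_light − f·A_heavy/(1−f))/(A_heavy/(1−f)).
The default f = 0 reproduces the no-correction behaviour appropriate when
the unlabelled residue is below ~1%.  A correction that drives the light
area negative flags the measurement instead of returning a negative ratio.

## Identification (PMF)

Observed mass lists are treated as singly protonated monoisotopic masses
(MALDI-TOF convention).  The theoretical list enumerates digest peptides
(default ≤ 1 missed cleavage) × variable-modification combinations (capped
at 3 simultaneous modifications per peptide to bound the combinatorics).
Each observed mass is assigned greedily to the closest theoretical mass
within tolerance (default 0.3 Da); ties prefer fewer modifications, then
fewer missed cleavages, then the N-terminal-most peptide.  Greedy
assignment is not a globally optimal bipartite matching — a documented
limitation, immaterial on the sparse lists of purified fractions at this
tolerance.  Coverage is the percentage of protein residues under the union
of matched spans.  No probabilistic search-engine score is computed;
coverage and match count are the quantities the workflow consumes.

## Quantification

XICs sum per-scan centroid intensity within |m/z − target| ≤ width/2
(default full width 0.3 Th — a stated "0.3 mass range" is read as a total
range, i.e. ±0.15) over a retention-time window (default full width 4 min).
The RT window centres on the configured expected RT when given; otherwise
on the apex of the heavy standard's whole-run trace, since the standard is
always present and co-elutes with the analyte.

Peak integration: apex = global maximum (ties → earliest RT); bounds walk
outward until intensity falls to the baseline threshold — trace median +
3 × median absolute deviation — or to 0.1 % of apex height above the
median (a smooth peak approaches zero only asymptotically; the cutoff
truncates ≲0.05 % of a Gaussian's area), or to the window edge
(flagged `edge-clipped`).  A linear baseline between the bound points is
subtracted and the remainder integrated trapezoidally; an apex at or below
the threshold is `no-peak` with area 0.  Noiseless Gaussians reproduce
A·σ·√2π within 1 %, with or without a constant offset.

**Envelope normalisation.**  A 0.3 Th XIC captures only the monoisotopic
peak of a peptide's isotope envelope, and a fully ¹⁵N-labelled species
concentrates *more* of its signal there than its light counterpart
(nitrogen leaves the isotope convolution).  Ratioing raw mono areas would
therefore bias the result by P(all N = ¹⁴N) ≈ 0.9964^N — about 4 % for a
10-nitrogen peptide.  `measure_pair` divides each area by the species'
monoisotopic-envelope fraction, computed exactly from the elemental
composition, before ratioing.  The correction is on by default and
configurable off.

Amounts convert to serum concentrations through an explicit volume ledger:
serum volume (default 0.1 ml) and per-step aliquot fractions in (0, 1]
(default none, i.e. the analysed sample represents the whole draw — the
assumption is exposed rather than buried).  ng/ml ↔ fmol/ml conversion is
fmol/ml = ng/ml / M × 10⁶.

## Statistics

Replicate summaries use the sample SD (n−1) — verified to reproduce known
triplet statistics exactly — and CV = 100·SD/mean.  Quartiles use linear
interpolation (type 7); the convention is documented because it is not
universal.  Calibration linearity is OLS of area ratio on spike level, by
default over raw replicate points (per-level means are an option, since
either reading of a "fit over the series" is defensible); the correlation
coefficient is reported to 3 decimals.  Method comparison offers Pearson
and Spearman with two-sided p-values; Spearman is the default.  The
depletion→enrichment bookkeeping exposes both the nominal convention
(x % depletion ≡ x-fold enrichment, scaled by recovery) and the strict
concentration ratio 1/(1−d); the nominal form is the workflow's own
arithmetic, the strict form is there for honesty.  qPCR relative expression
is 2^(Ct_ref − Ct_target).

## Simulator

The simulator emulates exactly what the quantifier consumes: paired
light/heavy Gaussian elution peaks (default σ = 0.1 min, comfortably inside
4-min windows), centroided spectra at the isotopologue m/z positions
(envelope truncated at 5 isotopologues, adequate below ~2 kDa; spacing
1.003355 Da), intensity proportional to amount (default response
10⁴ per fmol — inter-peptide response differences are unknowable a priori
and left as free parameters), per-species per-scan multiplicative
log-normal noise at a stated CV, and an optional additive floor.  Scan
interval defaults to 0.05 min (~3 s, ion-trap-like).  Output is in-memory
or mzML (a minimal self-contained writer/reader pair; round-trips are exact
and the writer's output is validated against an external mzML
implementation in the tests).

Cohort generation draws per-sample concentrations from truncated-at-zero
normal distributions (means ± SD only are known for the groups, so a normal
is the least-committal choice; log-normal would be a plausible alternative
and is a documented configuration point).  Defaults are the serum
concentration structure of the two model biomarkers: DcR3 healthy
27.23 ± 9.47, tumour 116.94 ± 57.37 fmol/ml; GDF15 98.11 ± 34.96 and
164.44 ± 79.31 fmol/ml.  Concentrations push through the volume ledger to
per-run amounts so that quantifying the runs recovers the generated values;
at 5 % noise the recovered-vs-true correlation exceeds 0.9 and the median
relative error stays within 10 %.  Every generator takes a mandatory seed;
identical seeds give byte-identical mzML.

**What the simulator does not model** — and hence what passing tests do not
show about real data: ionisation-efficiency physics and inter-peptide
response variation, chromatographic tailing and retention drift across
runs, co-eluting interferences and chimeric envelopes, detector saturation,
and electronic/chemical background beyond the simple additive floor.
End-to-end recoveries here demonstrate the correctness of the arithmetic
chain, not instrument-level accuracy.

## Problem sizes

Tests and the acceptance script run desk-scale configurations: runs of
~60–80 scans with ≤ 10 centroids per scan, 4-level calibration series, and
cohorts of a handful of samples per group — large enough to exercise every
code path and property, small enough to run the full suite in seconds.

## Known limitations

Greedy PMF assignment (above); no MS2/SRM quantification; no
retention-time alignment across runs; no chromatographic deconvolution of
overlapping peaks; no semi-tryptic digestion; no isotope fine structure.
The shipped example QconCAT peptides are illustrative toys — the historical
Q1 concatamer's full sequence is not public, so analyses here demonstrate
the method, not a reconstruction of that reagent.
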