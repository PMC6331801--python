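# Methods

`protostane` implements a two-instrument analytical workflow for the
protostane (alisol-type) triterpenoids of *Alismatis Rhizoma* (AMR, the dried
rhizome of *Alisma orientale*): qualitative profiling from HPLC‑DAD‑QTOF
peak lists and targeted quantification from UPLC‑QqQ MRM peak areas. The
pipeline starts where instrument vendor software ends — at centroided peak
lists and integrated areas — and everything upstream of that (peak picking,
integration) is out of scope. A synthetic-data generator with known ground
truth stands in for the instruments.

## Qualitative model

**Accurate mass.** All mass arithmetic uses fixed monoisotopic constants
(C 12.000000, H 1.00782503, O 15.99491462 Da) so results are bit-stable.
The protonated ion `[M+H]+` can be computed under two conventions: adding
the mass of a neutral hydrogen atom (1.007825 Da) or of a bare proton
(1.007276 Da, electron-corrected). The hydrogen-atom convention is the
default because it reproduces the packaged library's printed 1-decimal mass
errors for the majority of entries; the printed errors are in fact
internally inconsistent across conventions (some entries match one, some
the other), so no single choice reproduces every row. Mass error is
reported as signed ppm, rounded half away from zero to one decimal.

**Formula assignment.** Candidate elemental compositions for an observed
`[M+H]+` come from exhaustive enumeration over a CHO box (C 5–40, H 10–64
even, O 0–10, ring-plus-double-bond equivalents 0–15) filtered at a ppm
tolerance (default 5 ppm, the conventional QTOF acceptance). The box is
wide enough for C30–C32 triterpenoids and small enough that brute-force
search is instantaneous; results are ordered by |ppm|, then formula string,
so output is deterministic. The even-H restriction encodes the
even-electron species constraint for singly protonated molecules.

**Neutral-loss annotation.** Alisols fragment by successive/simultaneous
losses of H2O (18 Da) and acetic acid (HAc, 60 Da) plus C-23–C-24
side-chain losses (C2H2O, C4H8O, C4H10O2, C6H10O2, C6H12O3); that seven-loss
vocabulary is the default. Each fragment is explained by the shortest
multiset of vocabulary losses (breadth-first, depth ≤ 4) whose cumulative
mass matches the precursor-fragment gap within a fragment tolerance of
15 ppm with a 3 mDa absolute floor (QTOF product ions are less accurate
than MS1; the floor protects low-mass fragments). Ties break by chain
length, |ppm|, then lexicographic labels. Chain masses are computed from
the summed elemental composition, so exactly mass-degenerate chains
(C4H8O + H2O ≡ C4H10O2; C6H12O3 + H2O ≡ C4H10O2 + HAc) canonicalise
deterministically; such chains are indistinguishable by mass alone and the
package makes no claim to resolve them chemically.

**Seven-type classification.** Dissociation of the C-23–C-24 bond leaves a
skeleton ion diagnostic of the ring-system oxidation pattern. The rules
store the empirical skeleton ion values (397.2745 for types I/II, 383.2983
for III, 339.2684 for IV, 385.3102 for V, 399.2896 for VI/VII), matched at
±15 ppm, rather than masses recomputed from nominal loss compositions —
fragment formulas are not assigned, and recomputation disagrees with the
type III family by ~8 ppm, so the empirical values are authoritative. The
UV band disambiguates the shared-ion pairs: 287 ± 5 nm (the fully
conjugated 11,12,13(17),16 system) means type I or VII's partner is
excluded; 245 ± 5 nm (the 11,13(17) diene) means type II or VII; no maximum
above 200 nm means the unconjugated types III–VI. Rules are evaluated in
the order IV, V, III, VI/VII, I/II (rarer, less-shared ions first),
stopping at the first UV-consistent hit; features passing no rule are
unclassified.

**Library identification.** The packaged library holds 25 reference
compounds (21 confirmed against isolated standards, 14 of them quantified
in the MRM assay). A candidate must co-elute within ±0.5 min and agree
either on the precursor formula (≤ 5 ppm) or on ≥ 2 expected product ions;
the best candidate is the one with the most fragment evidence. A
standard-confirmed candidate with sufficient fragment evidence yields a
*standard match*; in that case a precursor-mass discrepancy is recorded as
a diagnostic rather than vetoing the retention-time + product-ion evidence
(one library entry carries an internally inconsistent printed precursor m/z
— flagged `mz_anomalous` in the fixture — and is identified exactly this
way). Otherwise the feature is *tentative* (library candidate without
standard-level evidence, or a de novo enumerated formula plus type), else
*unidentified*.

## Quantitative model

Calibration is unweighted ordinary least squares of the area ratio
Y = area(analyte)/area(IS) against concentration X (μg/mL) in the injected
solution, with Pearson r; 1/x and 1/x² weighting exist as options but are
off by default because the assay was validated unweighted. Back-calculation
is X = (Y − b)/a with a below/in/above flag against the validated linear
range.

X refers to the *post IS-mix* solution. The preparation constants are
0.20 g powder extracted into 25 mL acetonitrile, then mixed 1:1 with the
internal-standard working solution (glycyrrhetinic acid, transition
471.32→317.28), so

    content (mg/g) = X · 2 · 25 / (0.20 · 1000) = 0.25 · X.

This reading (rather than X being the pre-mix extract concentration) is the
one under which the maximum observed batch contents back-project inside the
validated linear ranges — e.g. 2.032 mg/g of alisol B 23-acetate maps to
8.13 μg/mL, inside its 0.294–9.790 μg/mL range — and a fixture sanity test
asserts this consistency for every non-ND cell.

Replicate injections (n = 3) are averaged on the back-calculated
concentration scale, with the replicate RSD logged. A mean concentration
below the analyte's LOD is reported as the literal `ND` and excluded from
all downstream summaries and tests (pairwise, not row-deleted).
LOD and LOQ are the concentrations where S/N crosses 3 and 10, located by
log-linear interpolation along a dilution ladder; the assay's reported
"about 3 and 10" fixes no procedure, so interpolation between bracketing
steps is this package's choice, and a series that does not bracket both
thresholds is an error rather than an extrapolation.

## Validation statistics and batch comparison

Precision (intra-day n = 6, inter-day 2 × 3 days), repeatability (6
independent preparations), stability (7 timepoints over 24 h) are all
reported as RSD = sd/mean × 100 with the sample (n−1) denominator. Spike
recovery is (detected − original) × 100 / added, reported as mean ± sd and
RSD; the spike level defaults to 100% of native content (the validated
design states no level; this is the common mid-level choice).

Origin comparison runs a two-sided two-sample t-test per analyte between
groups (pooled-variance Student's t by default, matching the original
analysis; Welch is an option), flagging p < 0.05. No multiple-testing
correction is applied by default, again matching the original analysis; a
Benjamini–Hochberg option would be the first thing to enable for a new
study. Analytes with fewer than two non-ND values in a group are skipped
and marked, not silently dropped.

## Synthetic data

The generators emulate the study conditions with the simplest noise models
consistent with the instruments' reported performance:

- **QTOF features**: precursor m/z = theoretical `[M+H]+` × (1 + ε),
  ε ~ N(0, 2 ppm); fragments are the library's expected ions with N(0, 5 ppm)
  jitter and Bernoulli dropout (p = 0.2); retention-time jitter ±0.1 min;
  UV maxima copied from the library entry.
- **MRM areas**: injected concentration is the exact inverse of the content
  conversion; the area ratio follows the packaged calibration line; analyte
  and IS areas get independent multiplicative Gaussian noise at 5% CV,
  3 replicate injections per sample (replication is modelled at the
  injection level, not the extraction level).
- **Batch contents**: lognormal per analyte and origin group around the
  packaged 43-batch group means (CV 0.3), 21/22 samples per group, so
  simulated effect sizes match the study's; an explicit per-analyte group
  ratio can override the second group's means.
- **Dilution ladders**: 2-fold steps with signal = response × concentration
  over a constant noise floor, so the S/N = 3 crossing is analytically
  known and LOD recovery can be checked against a closed form.
- **Validation arms**: every arm is truth × multiplicative N(0, 2% CV),
  with optional linear stability drift.

One global seed expands into independent per-stage substreams
(`SeedSequence.spawn`), so every generator is a pure function of (inputs,
seed) and any stage can be regenerated alone; identical seeds give
byte-identical output files.

What the simulator does **not** model: chromatographic peak shapes,
isotope envelopes, co-elution and matrix effects, carryover, detector
saturation, and extraction-level variability. Passing tests therefore
demonstrate the correctness of the pipeline's arithmetic and decision
rules under the stated noise models, not robustness to real-matrix
artefacts.

## Numerical choices and edge cases

- ppm reporting rounds half away from zero (string-table convention);
  internal comparisons are unrounded.
- Formula enumeration applies the exact |ppm| ≤ tol criterion after a
  slightly widened absolute prefilter, so the result equals the brute-force
  definition bit-for-bit.
- Zero-slope or single-concentration calibration designs, zero-mean RSD
  inputs, non-positive added amounts, non-bracketing dilution series, and
  missing IS areas are all explicit errors (or per-measurement skips with a
  diagnostic row), never silent NaNs.
- The packaged table transcriptions keep printed values verbatim, including
  a handful of internally inconsistent fragment m/z values and one
  inconsistent precursor; these are flagged in the fixture and excluded
  from round-trip assertions, and the identification logic is designed to
  still name those compounds from retention time + product ions.

## Problem sizes in the test suite

The shipped tests run the full 25-compound library and the full 43 × 14
batch matrix; stochastic properties use 20 seeds (200 for the RSD
sampling-distribution check), which keeps the whole suite under a few
minutes on one CPU while still giving sub-percent Monte-Carlo error on the
quantities asserted.

## Known limitations

- Only CHO (plus optional N in the ring-double-bond rule) enumeration;
  sodium adducts are recorded in transcriptions but not scored.
- Type rules are specific to the protostane skeleton families packaged
  here; new skeleton types need new (ion, UV) rules.
- Calibration slopes, correlation coefficients and the original
  validation-table RSDs cannot be reproduced without the raw instrument
  data; they are covered by structural checks and simulation-based
  properties instead.
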