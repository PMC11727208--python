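# Methods

This note records the models, conventions and design choices behind
`sulfoglyco`, in the order data flows through the package.

## Mass model for permethylated, sulfated N-glycans

Compositions are counts of the four residue classes a MALDI-TOF mass can
distinguish — Hex, HexNAc, dHex (written `Fuc`), NeuAc — plus a sulfate
count (`Sulf`). The neutral monoisotopic mass of a permethylated glycan
with a free reducing end is the sum of permethylated residue masses
(Hex 204.0998, HexNAc 245.1263, dHex 174.0892, NeuAc 361.1737 Da) plus a
closure of 46.0419 Da (C2H6O: the reducing-end and non-reducing termini of
the methylated chain) and +65.9412 Da (SO3 − CH2) per sulfate, because a
sulfated hydroxyl escapes methylation. `scripts/derive_masses.py` rebuilds
each residue mass from IUPAC monoisotopic atomic masses and elemental
formulas; note that the permethylated NeuAc residue is C16H27NO8 (the
Neu5Ac residue plus five methylenes: four O-methyls and the methyl ester).

Ion conventions, all singly charged (reflector MALDI-TOF):

| pool | mode | species | rule |
|---|---|---|---|
| neutral/sialylated | positive | `[M+Na]+` | M + Na |
| sulfated, n sulfates | negative | `[M−nH+(n−1)Na]−` | M − nH + (n−1)Na |
| sulfated, n sulfates | positive | `[M+(n+1)Na−(n+1)H]+` | M − nH + (n+1)Na |

The negative-mode rule deliberately removes *all* n sulfate protons and
adds n−1 sodium counterions on the free-acid mass. Written with M as the
free acid, the superficially similar "M − H + (n−1)Na" bookkeeping sits
1 Da high for di-sulfated species; the adopted rule reproduces the mono-
and di-sulfated peak ladder and its +87.9231 Da spacing (nearest integer
88), which is also the offset used to flag di-sulfation satellites. The
electron mass is ignored (< 1 mDa, absorbed by every tolerance in use).
Only monoisotopic masses are modelled: no isotope envelopes, no average
masses, no multiple charging, no phosphorylated species.

Printed integer peak labels are matched with |computed − printed| ≤ 1.0 Da
because published labels mix floor and round conventions (1579.78 is
labelled "1579" while 2040.94 is labelled "2041").

## Classification from composition

A composition with HexNAc ≥ 2 and Hex ≥ 3 is treated as an N-glycan
(trimannosyl-chitobiose core). Categories: oligomannose (HexNAc = 2,
Hex ≥ 5), paucimannose (HexNAc = 2, Hex ≤ 4), hybrid (HexNAc = 3,
Hex ≥ 5), otherwise complex. Antennarity counts HexNAc beyond the core,
capped at 4 — and discounted by one when the composition is a *bisect
candidate* (HexNAc − 2 > Hex − 3, i.e. more HexNAc than galactosylatable
antennae), since a bisecting GlcNAc raises the HexNAc count without adding
an antenna. The flag is deliberately named "candidate": composition alone
cannot prove bisection, only fragment evidence can. Likewise any dHex is
mapped to *core* fucosylation, the dominant placement in thyroid tissue;
antennary fucose is not distinguishable at MS1. Tri- vs tetra-antennary
readings of LacNAc-extended compositions are genuinely ambiguous; the
annotator keeps all candidates and only ranks them.

In-silico desialylation removes all NeuAc for the broad-spectrum
sialidase (A) and only the α2-3-linked share for the S enzyme. The default
α2-3 fraction is 0: thyroid N-glycan sialylation is α2-6-dominant, so
sialidase S is modelled as a no-op unless a linkage profile is supplied.

## Annotation

Peak lists are delimited text with columns `mz,intensity[,snr]`; a missing
S/N column is imputed as intensity over median intensity (logged). Peaks
with S/N < 2 or outside m/z 1000–6000 are discarded. Each retained peak is
matched by *constrained enumeration*: every composition within bounds
(defaults Hex ≤ 12, HexNAc ≤ 10, dHex ≤ 4, NeuAc ≤ 6, Sulf ≤ 3; core
constraint on; plausibility rules NeuAc ≤ HexNAc − 2 and Sulf ≤ Hex − 2)
whose predicted ion m/z lies within ±0.5 Da is a candidate. The 0.5 Da
default reflects an externally calibrated reflector TOF; it is
configurable. Candidates are ranked by |mass error| with a parsimony
tie-break (fewer residues, then fewer sulfates, then canonical string) —
a policy, not a reconstruction of manual curation. Peaks without
candidates stay in the report as unassigned. Satellite links (−14.0157 Da
under-permethylation; +87.9231 Da di-sulfation, sulfated pool only, both
at ±0.3 Da) are annotations and never alter ranking.

The neutral/sialylated pool is searched with positive sodiated species
only and the sulfated pool with negative sulfated species only, mirroring
the acquisition design; a polarity/fraction mismatch is an error.

## MS/MS fragments and the sulfo-linkage logic

Glycosidic B/C/Y/Z fragments are enumerated from a rooted topology
(Domon–Costello: B/C keep the non-reducing side, Y/Z the reducing side).
End-group conventions, frozen only after reproducing all printed fragment
ions of the m/z 2286/2332 precursor pair within ±1 Da
(`scripts/derive_masses.py` re-checks them):

- positive B with k sulfates in the fragment: Σresidues + 15.0229 +
  (1 + k)(Na − H) — one sodiation plus one sodium per sulfate salt;
- positive Y after losing a subtree with k sulfates: precursor − Σlost −
  14.0157 − k(Na − H);
- negative, sulfate-retaining B: the positive oxocarbenium − 2H; negative
  Y only when the lost subtree is unsulfated (the charge stays on the
  retained sulfate);
- C = B + H2O, Z = Y − H2O.

These conventions satisfy B + Y = precursor + Na for every single
cleavage. Double cleavages (capped at two) add internal B-with-Y-loss and
double-Y-loss ions, used opportunistically for matching only. General
cross-ring (A/X) enumeration is *not* implemented: the three
linkage-diagnostic masses for 3-O-sulfo-galactose (m/z 153 cross-ring
2,4A1; 181 and 253 E-type elimination ions) are curated constants with
citation strings, because E-ion chemistry of permethylated glycans is an
empirical signature rather than a desk-derivable mass rule. The m/z 283
ion is stored as a B-type single-residue sulfo-Gal fragment although
source spectra label it "B2" — a nomenclature discrepancy, noted here.

The decision chain: m/z 97 (HSO4−) ⇒ sulfate present; 97 + 528 ⇒
sulfo-LacNAc antenna; 283 ⇒ sulfate on the terminal Gal rather than the
internal GlcNAc; 97 plus any of {153, 181, 253} ⇒ 3-O linkage on Gal.
Anything not positively established is reported indeterminate — including
the di-sulfated-LacNAc isomer question, which the available ions cannot
resolve. Positive-mode spectra contribute complementary B/Y confirmation
only and never a linkage call.

## Differential statistics

Per sample, TIC-normalized class fractions are computed over rank-1
assigned intensity: the four categories partition assigned intensity, and
overlapping feature fractions (branched = antennarity ≥ 3, bisect
candidate, sialylated, core-fucosylated, sulfated, di-sulfated) are
reported alongside. Glycan classes are compared between groups with the
classic pooled-variance two-sample t-test (Welch available); expression
(RPKM) with the paired t-test, i.e. a one-sample t on per-patient
differences. All tests are two-sided with p < 0.05 flagged significant.
RPKM is tested untransformed by default (log2(x+1) optional); no
multiple-testing correction is applied by default (Benjamini–Hochberg
optional). Degenerate inputs are explicit: zero variance with equal means
raises; zero variance with unequal means reports p = 0 with a warning.

## Synthetic data: what it emulates and what it does not

The spectrum generator emulates centroided reflector-TOF peak lists: one
peak per library composition at its predicted ion m/z plus Gaussian error
(σ = 0.05 Da), log-normal abundances (σ = 1 on the natural log),
under-permethylation satellites with probability 0.3 at 20% of the parent
intensity, +88 Da di-sulfation satellites with probability 0.2 in the
sulfated pool, and Poisson(20) noise peaks drawn uniformly over the range
with S/N in (0.5, 1.9) — below the filter threshold by construction,
while signal peaks draw S/N in (3, 50). The default libraries are the
compositions behind the profiled thyroid peaks: the oligomannose series
Hex5–9HexNAc2, the (sialylated) biantennary Hex5HexNAc4Fuc1 ± NeuAc1/2,
tri/tetra-antennary and bisect-candidate species for the neutral pool;
the mono-antennary (1662/1836/1866/2041), bi/tri-antennary
(2112/2286/2647/2735/3096) and di-sulfated (2374, 3272) species for the
sulfated pool.

The cohort generator plants tumor-vs-normal class-level multipliers
(defaults: branched ×1.8, bisect candidate ×1.8, sialylated ×0.7,
di-sulfated ×0.4, everything else ×1) with a paired structure: each
patient draws a per-glycan log-abundance baseline (the library spread,
σ = 1) shared by both samples, a per-patient offset (σ = 0.3), and a
within-pair residual (σ = 0.25) per spectrum. Without the shared baseline
there is no paired design and the planted shifts would be swamped. The
default of 5 pairs matches the tissue cohort size the workflow targets.

The expression generator draws RPKM = exp(gene baseline + patient effect
+ group shift + noise) with baseline ≈ ln 30 (gene spread σ = 0.5),
patient σ = 0.3, residual σ = 0.3, n = 20 pairs, and planted log2
fold-changes with the directions reported for the PTC glycogene panel
(MGAT3 +1, MGAT4B +0.8, ST6GAL1 −1, MAN1A1 −1, MAN1B1 +0.8, GAL3ST3 0,
GAL3ST4 +0.8, B4GALT3/5/6 +0.5). A 2-fold MGAT3 shift at these noise
levels is detected by the paired test in essentially every seed.

What passing tests on these generators show: the annotation, profiling
and testing stages are correct and calibrated under the stated noise
model. What they do not show: performance on real tissue spectra, which
additionally contain isotope envelopes, baseline and calibration drift,
in-source decay, overlapping isomer peaks and matrix clusters — none of
which are emulated. Annotation recovery on simulated sulfated-pool
spectra is limited by a genuine near-isobar: exchanging Hex + HexNAc for
NeuAc + sulfate shifts an ion by only 0.13 Da, inside the 0.5 Da
tolerance, so a small fraction of peaks rank the wrong composition first
at σ = 0.05 Da. This ambiguity is real, not an artifact.

## Numerical and testing choices

All generators are pure functions of (config, seed); fixed seeds give
byte-identical output tables, which the test suite asserts at the byte
level. Enumeration is deterministic, with ties broken as described. The
enumeration path is validated against an exhaustive nested-loop oracle
written with independently restated constants. Null calibration of both
t-test stages uses 10,000 replicates (empirical type-I error required to
sit in [0.04, 0.06] at α = 0.05); power and direction checks run over
seed grids (40 seeds for the expression path, 5-patient cohorts across 6
seeds for the glycan path). Simulation sizes in the test suite (5–10
spectra per recovery check, 100 oracle targets) are chosen so the whole
suite completes in well under a minute while keeping binomial noise far
from the asserted thresholds.

## Known limitations

- Composition-level flags (bisect candidate, core fucosylation) are
  heuristics; only fragment data can confirm them, and the package never
  claims more than the candidate status.
- The diagnostic table covers 3-O-sulfated galactose on LacNAc; other
  sulfation positions (e.g. 6-O, internal GlcNAc) have no curated
  signature here and come out indeterminate.
- O-glycans, glycosaminoglycans, anomeric configuration and
  glycopeptide-level site mapping are out of scope.
- The positive-mode ions at m/z 474 and 574 are matched opportunistically
  (they fall out of the Y/B conventions) but no structural claim is tied
  to them.
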