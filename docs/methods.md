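# Methods

## Scope and data model

The package operates on *signal sheets*: dense feature × sample intensity
matrices produced after chromatographic peak integration, with per-feature
coordinates (m/z in Da, retention time in minutes) and per-sample metadata
(role: analytical / blank / QC; compartment; phenotype; QC stock and
dilution level). Intensities are arbitrary instrument counts; no unit
conversion is performed anywhere. Missing values are encoded as 0 and mean
"no signal" — the presence rule downstream is "signal > 0", so zero and
absent are operationally identical. Peak picking and raw-file conversion
are out of scope; the sheet is the entry point.

## Target library

Lipid identities are carried at sum-composition level (class, total
carbons *n*, total double bonds *d*); positional isomers are
indistinguishable in single-stage positive-mode LCMS and are not modelled.
Formula rules per class:

| class | formula |
|---|---|
| TG  | C(n+3) H(2n−2d+2) O6 |
| DG  | C(n+3) H(2n−2d+4) O5 |
| PC  | C(n+8) H(2n−2d+16) N O8 P |
| PE  | C(n+5) H(2n−2d+10) N O8 P |
| PG  | C(n+6) H(2n−2d+11) O10 P |
| PI  | C(n+9) H(2n−2d+15) O13 P |
| PS  | C(n+6) H(2n−2d+10) N O10 P |
| Cer | C(n) H(2n−2d+1) N O3 (sphingoid included in n, d) |

Monoisotopic masses are summed from an internal registry of CODATA/IUPAC
atomic masses (C, H, N, O, P, Na to ≥ 6 d.p.). Adduct m/z is
(M + shift)/z with the electron mass included in the shift (0.00055 Da
matters at three decimal places): [M+H]⁺ 1.007276, [M+NH₄]⁺ 18.033826,
[M+Na]⁺ 22.989221. The test suite cross-checks every generated m/z against
an independent atom-summation oracle (pyteomics) to < 5 × 10⁻⁴ Da.

Default ranges — TG 38–68 carbons × 0–12 double bonds, phospholipids 26–44
× 0–8, Cer 26–48 × 0–4, all three adducts, mass range 400–1200 Da — were
chosen to span animal, plant and fungal lipidomes and yield a library of
order 7.5k entries (7197 with the defaults). Species with d > n/2 are
skipped as chemically implausible. Triglycerides additionally emit DG-like
in-source fragment entries, [M+H − RCOOH]⁺ for the dominant acyl losses
(C16/C18/C20, 0–2 double bonds), each carrying a `parent_id`; when such an
entry wins a match the feature is annotated with the *parent TG* identity,
so fragment variables are pooled with their intact TG throughout the
traffic analysis.

Matching uses ±0.001 Da absolute m/z tolerance by default — the
"three decimal places" convention of the processing software, not ppm; a
ppm mode is available. Retention time must fall inside the entry's
class-level window (windows are user-supplied; the defaults are wide bands
inside the 0.5–18.5 min acquisition span, since instrument-specific values
must be calibrated from standards). Ties are broken by smallest |Δm/z|,
then smallest |ΔRt| to the window centre; exact ties are flagged ambiguous
and left unassigned. Features whose maximum intensity is below the area
threshold (100 000 counts by default) are excluded before matching.

## Quality filters

Two preset chains reflect the two common processing routes:

* **matched** (ID-matched data): blank-ratio test — mean analytical
  intensity strictly > 3× mean blank intensity (a zero blank mean passes
  iff there is any analytical signal); QC linearity — per feature and per
  QC stock, Pearson correlation of raw intensity against the numeric
  dilution fraction (0.25/0.5/1.0) over all of that stock's replicates
  (3 per level, so 9 points per stock), passing iff r > 0.75 for **at
  least one** stock. Zero-variance vectors have undefined r and fail.
* **unmatched** (feature tables without IDs): blank ratio at 5×, plus
  prevalence — intensity > 0 in ≥ 90% of the samples of at least one
  sample type.

Every threshold is a strict inequality except the prevalence and presence
fractions, which are inclusive (≥), matching how each rule is stated.
Pearson on raw intensities is the default (Spearman and log-log variants
are flags); blanks are averaged globally, since plate structure varies
between studies.

CV tables report 100·sd/mean per feature per stratum using the sample
(n−1) standard deviation; entries with mean 0 or n < 2 are recorded as
missing, never as 0, and excluded from the "< 15%" / "< 20%" summary
denominators. Total-signal comparisons between groups use Student's
two-sample t-test (equal variances); the degenerate zero-variance case is
reported as t = ±∞, p = 0 when the means differ and t = 0, p = 1 when they
do not.

## Traffic analysis

A lipid variable is **present** in a (phenotype, compartment) group iff
the fraction of that group's samples with intensity > 0 is ≥ 0.66. The
threshold is used literally as 0.66 (not 2/3) and inclusively, so 33 of 50
counts as present. Presence is monotone in intensity by construction.

Classification over a compartment network (undirected, no self-loops,
≥ 2 compartments):

* **A-type** — present in every compartment;
* **U-type** — present in exactly one;
* **N₂-type** — present in exactly two non-adjacent compartments;
* **B-type** — on each edge both of whose endpoints contain it.

B-sets exclude A-type lipids by default: otherwise every ubiquitous lipid
would sit on every edge and the contrast between the ubiquitous pie and
the per-edge pies would collapse. A flag restores the inclusive reading.
Lipids in three or more (but not all) compartments that cover no edge go
to a residual `other` set and are reported, not dropped. The test suite
proves the classifier equivalent to a brute-force transcription of the
definitions over every connected 3–5-compartment topology and every
presence pattern.

### Switch statistics

For each category the two phenotypes' sets are compared with the
Jaccard–Tanimoto coefficient J = |∩|/|∪| (defined as 1 with an "empty"
flag when both sets are empty). The p-value uses a permutation null:
variable sets of the observed sizes drawn uniformly from the universe of
variables detected in either phenotype for that lipid class. Under this
null the intersection size is hypergeometric, which is sampled directly
(equivalent to drawing the subsets, and much faster); for universes of
≤ 200 variables the hypergeometric pmf is summed exactly instead of
sampled. Significance is two-sided relative to the null mean of J:
p = (1 + #{null J at least as extreme}) / (n_perm + 1).

Because J is discrete, ties between null draws and the observed value have
positive probability, and the tie-inclusive rule above is deliberately
conservative: P(p ≤ α) ≤ α under the null, with the inequality strict at
most levels. A `ties="randomized"` variant splits ties uniformly and is
exactly uniform under the null; it is the right choice for calibration
studies and is what the calibration test uses, while the conservative rule
remains the reporting default. The null model itself (fixed sizes, uniform
draws) is one documented choice among several defensible ones and is
seeded and swappable.

### Rendering

Switch diagrams are written as plain SVG with fixed-precision coordinates:
compartments on a circle, solid adjacency edges, dashed connectors for
compared non-adjacent pairs, one pie per non-empty category with segments
proportional to (unique-to-1, shared, unique-to-2), annotated with J and
p. Identical inputs produce byte-identical files.

## Synthetic studies

The generator emulates the plate design the pipeline expects: per
(phenotype, compartment) analytical wells, extraction blanks, and two
pooled QC stocks at 25/50/100% dilution with three technical replicates
each — two stocks so the "at least one stock" disjunction in the QC test
is genuinely exercised. Lipids are planted per category instance (the A
pattern; each edge; each compartment; each non-adjacent pair) with a
configurable count and between-phenotype overlap fraction, so the expected
switch counts and J are known in closed form.

Present cells draw log-normal intensities with mean `base_intensity` and
the stated CV (σ² = ln(1 + cv²), mean-corrected); dropout then zeroes
present cells independently at `dropout_rate`, modelling detection
failure — this is what stresses the presence rule. Blank wells carry a low
background (base/1000) for genuine lipids; contaminant features have the
same mean in blanks and analytical wells, so they fail the 3× blank test,
and are level-independent in QC wells, so they fail the linearity test.
Dropout is not applied to QC or blank wells: it models detection failure
of analyte at biological abundance, and the QC invariant (noiseless wells
give r = 1 exactly) is part of the generator's contract. One master seed
drives a single generator stream; identical configurations are
byte-identical.

Defaults are the study conditions used throughout the tests: a
three-compartment path network, two phenotypes, 6 samples per group,
base intensity 10⁶, 20% CV, 20% dropout, 10 planted A lipids and 6 per
B/U/N₂ instance with 0.5 overlap, 5 contaminants, 6 blanks.

What the generator does *not* emulate: retention-time drift, correlated
(batch/plate) noise, intensity-dependent dropout, isotope patterns and
co-eluting near-isobars, or class-dependent response factors. Passing
recovery tests on these synthetic sheets therefore demonstrates the
correctness of the *logic* (filters, presence rule, classification,
statistics), not robustness to every artefact of real instrument data.

### Recovery under the default conditions

With n = 6 samples per group and 20% dropout, a planted presence call
succeeds iff Binomial(6, 0.8) ≥ 4, i.e. with probability ≈ 0.90 per
compartment. Category recovery compounds this per compartment: an A-type
lipid on the three-compartment path needs all three calls (≈ 0.73), B and
N₂ need two (≈ 0.81). Measured macro-averaged precision/recall over 20
seeds at these conditions is ≈ 0.89/0.85 — an inherent property of the
0.66 rule at this sample size, not an implementation defect; the noiseless
configuration recovers ground truth exactly. With 12 samples per group and
10% dropout the same pipeline exceeds 0.9 on both, which the regression
suite asserts. Sample sizes in the tests and the acceptance script (60–96
wells, ~75 features, 20 replicates) keep every run well inside interactive
timescales.

## Numerical conventions

* Presence, prevalence: inclusive ≥ on fractions; all other thresholds
  strictly >.
* CV uses ddof = 1; undefined values are NaN, never 0.
* Matching tie-break order: |Δm/z|, |ΔRt|, then flagged ambiguous (no
  assignment).
* All Monte Carlo draws go through `numpy.random.default_rng` seeded from
  one integer; the switch analysis derives one stream per run and the
  pipeline offsets the seed per lipid class.
* The undefined "signal corrected" normalisation sometimes applied to
  log-scale figures of reference datasets is intentionally not
  implemented; only log10(x + pseudocount) is provided.

## Known limitations

* Sum-composition identification only; no MS/MS, isotope scoring or
  negative-mode adducts.
* Two-phenotype switch analyses only; multi-group designs require
  pairwise runs.
* The permutation null ignores any correlation structure between lipids
  (e.g. shared acyl pools); its p-values describe exchangeability of
  variable identities, not biological independence.
* Blank means are global, not per plate; batch correction and imputation
  are out of scope.
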