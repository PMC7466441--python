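# Methods

This note documents the models, rules and defaults implemented in
`dsrna-forge`, the reasoning behind the open design choices, and what the
synthetic-data generators do and do not emulate.

## Off-target screen (`offtarget`)

**Model.** An ingested long dsRNA is processed by Dicer into ~21-nt siRNAs,
so cross-species risk is evaluated at 21-mer granularity: every 21-mer of
the target transcript is tested for a *perfect, ungapped, contiguous exact
match of length ≥ 20* anywhere in a panel of non-target transcriptomes, on
either strand. This deterministic contract replaces alignment-based
screening of short queries, whose reported hits for 21-nt queries are in
practice (near-)full-length exact matches but whose scoring depends on
tool version and database size. Because every length-20 window of a 21-nt
query is one of its two terminal 20-mers, the screen reduces to three O(1)
set lookups per 21-mer against canonical k-mer hash sets built from the
panel.

**Strandedness.** dsRNA presents both strands, so matches on either panel
strand count. Both strands are handled by storing each k-mer in canonical
form (lexicographic minimum of the k-mer and its reverse complement)
rather than by doubling the index; this halves memory with identical
semantics.

**N handling.** `N` is legal in stored sequences, but no k-mer containing
`N` is enumerated or indexed, and every target 21-mer window containing an
`N` is added to the exclusion mask: a base that cannot be verified can
neither be matched nor declared species-specific.

**Index choice.** A hash-set index, not a suffix array or FM-index. Panel
transcriptomes at the scale of a handful of species fit comfortably in
memory, and membership is O(1). The index round-trips through a sorted
text format (header line, one canonical k-mer per line).

**Limits.** No mismatch-tolerant (seed-and-extend) search, no statistical
match scores, and no miRNA-seed off-target model; partial-complementarity
silencing through the miRNA pathway is explicitly outside what an exact
≥20-nt screen can exclude.

## dsRNA design (`designer`)

The complement of the exclusion mask gives the specific regions; the
longest one (leftmost on ties) becomes the design template. Candidate
windows of 350–500 nt (step 10) are enumerated inside it — the range
brackets typical synthesized long-dsRNA fragments, including the 417-bp
fragment used for bacterial production in this system — and the full
region is always evaluated too when it fits under the maximum.

Each candidate is scored by the fraction of its 19-mer windows (advancing
1 nt, mirroring the all-possible-21-mers philosophy of the screen) that
pass a Reynolds-style rational-design rubric; external web services used
for such designs do not publish their internals, so the rubric is this
package's documented, testable stand-in, with every weight configurable:

| criterion (sense strand, 1-based)      | points |
|----------------------------------------|--------|
| GC fraction in [0.30, 0.52]            | +1     |
| each A/U at positions 15–19            | +1 (≤5)|
| A at position 19                       | +1     |
| A at position 3                        | +1     |
| U at position 10                       | +1     |
| G or C at position 19                  | −1     |
| G at position 13                       | −1     |
| no inverted repeat with stem ≥ 5       | +1     |

Score range is −2 to +10; a window is "efficient" at score ≥ 6. The
inverted-repeat criterion is a hairpin proxy: no pair of non-overlapping
5-nt substrings that are reverse complements of each other (stem length
configurable); the published criterion for such designs is an internal-
repeat melting temperature, which requires a thermodynamic model this
rubric deliberately avoids.

Ranking: efficient fraction (descending), then GC fraction closest to
0.45, then smallest start, then shortest window — a total order, so
identical inputs always give identical rankings. Non-specific control
dsRNAs (e.g. a GFP fragment) are designed with screening disabled
(`--no-screen`), since a deliberate non-target sequence has no specific
region by construction.

## Survival analysis (`bioassay`)

**Kaplan–Meier.** Standard product-limit estimator
S(t) = ∏_{t_i ≤ t} (1 − d_i/n_i) over distinct event times; subjects
censored at t_i remain at risk at t_i (deaths processed before censorings
at tied times). With no censoring it reduces exactly to 1 − ECDF.

**Cox proportional hazards.** Arm indicators versus a chosen reference
arm; the partial likelihood is maximized by Newton–Raphson with
step-halving (tolerance 1e-8 on the score norm, at most 25 iterations).
Feeding trials are observed daily, so event times are heavily tied; the
Efron tie correction is therefore the default (matching the default of
the standard R implementation), with Breslow available for cross-checks —
the two agree exactly when no event times are tied. Likelihood-ratio and
per-term Wald tests are reported. Monotone likelihood (complete
separation, e.g. one arm with no deaths) is detected when any |β| exceeds
10 or the information matrix becomes singular; it is reported via
`converged=False` and a `monotone_likelihood` flag rather than an
exception, because an all-surviving control arm is a perfectly plausible
trial outcome. An optional `strata="trial"` fits separate baseline
hazards per trial with shared coefficients; egg-mass trials are treated
as independent larvae (no frailty/cluster term), a documented limitation.

**Field metrics.** Henderson–Tilton corrected mortality
100·(1 − (Ta·Cb)/(Tb·Ca)) is left unclamped (negative values signal
treated plots outgaining controls). Aggregation: each treated plot is
corrected against the mean before/after counts of its location's control
plots, per-location means are reported, and the pooled figure is the mean
of location means — pairing granularity is this package's choice, since
per-plot pairing conventions vary between trial designs. Leaf-damage
increase is final minus initial percent defoliation; adult emergence rate
is a simple percentage with count provenance.

## qPCR quantification (`qpcr`)

Cq is linear in log10 template amount: Cq = a·log10(x) + b, fitted by OLS
over a five-point 10-fold serial dilution; amplification efficiency is
E = 10^(−1/a) (E = 2 at the perfect-doubling slope −3.3219) and a
non-negative slope is rejected as an invalid assay.

**LOQ rule (this package's concrete rendering):** the smallest dilution at
which every replicate amplified and the mean absolute residual from the
fitted line is ≤ 0.5 cycles. Back-calculated amounts below the LOQ are
flagged and excluded from group means by default; `loq_impute="half"`
substitutes LOQ/2. **Inhibition QC:** amounts back-calculated from two
dilutions of the same sample must agree after dilution correction; a
ratio deviating from 1 by more than 30% (configurable) is called
inhibited, and any below-LOQ member makes the pair unevaluable. These
cutoffs are stand-ins for the quantification software used in practice,
whose exact rules are published separately; they are defaults, not claims
of identity.

**Normalization** divides target copies by the geometric mean of three
endogenous control genes (arithmetic-mean and single-reference modes exist
for sensitivity analysis); the geometric mean is the standard choice for
multi-reference normalization because it damps single-gene outliers.
Group **knockdown** is 100·(1 − mean(treated)/mean(control)) on normalized
values, invariant to common rescaling.

## Synthetic data (`simfix`)

All generators are pure functions of their seed (one `numpy` Generator per
call, no global state), so outputs are bit-reproducible.

- **Transcriptomes**: uniform-ACGT target (2 kb) and panel (3 × 5 kb); at
  10 well-separated target positions a 20-mer is copied into a random
  panel sequence on a random strand. Panel bases flanking each insert are
  adjusted so the exact match cannot extend to 21 nt, and an independent
  canonical-set intersection check rejects (and regenerates on) any
  accidental extra ≥20-mer sharing — the planted truth is exact, not
  probabilistic. Real transcriptomes are not uniform-random (repeats,
  shared domains, codon bias), so passing recovery tests shows the screen
  logic is correct, not that real panels yield this few exclusions.
- **Feeding trials**: exponential event times per arm (defaults: control
  hazard 0.03/day vs 0.15/day, hazard ratio 5 — chosen to produce the
  clear separation seen in effective feeding trials), rounded **up** to
  whole days to emulate daily inspection and deliberately induce ties,
  administrative censoring at day 14. Exponential hazards are a
  convenience; real dsRNA mortality has an onset lag, so these data test
  estimator correctness, not hazard-shape realism.
- **Field trials**: per-plant baseline infestation Poisson(20) truncated
  to ≥ 15 (the enrolment threshold), binomial per-larva survival
  (defaults: control 0.9, dsRNA 0.07, positive-control insecticide 0.02,
  matching the order of corrected-mortality outcomes reported for such
  trials), leaf damage increasing with surviving herbivory plus Gaussian
  noise, clipped to [0, 100]. Larval migration between plots is not
  modelled.
- **qPCR**: Cq = b + a·log10(copies·dilution) + N(0, σ) with σ = 0.2
  cycles by default, two replicates of two dilutions per sample, and
  five-point standards per gene; the knockdown experiment adds lognormal
  biological scatter (CV 10%) and a true knockdown of 70%. Inhibition,
  pipetting outliers and dropouts are not simulated unless injected
  explicitly.

## Numerical choices and problem sizes

Tolerances: Cox score norm 1e-8; brute-force partial-likelihood agreement
asserted at 1e-4 (the resolution of the bounded scalar search oracle);
noiseless qPCR round-trips at 1e-9 relative. Test problem sizes (50
random screen/oracle pairs at ≤1.2 kb targets, 200 Cox replicates at
500 subjects/arm, 100–200 seeds for the Monte-Carlo means) keep the whole
suite around a minute on one CPU while leaving Monte-Carlo standard
errors well inside the asserted bands.

## Known limitations

- The screen is exact-match only; it neither models thermodynamic
  off-target strength nor miRNA-seed effects.
- The siRNA rubric is a rational-design heuristic, not a trained
  efficacy predictor.
- Cox fits assume proportional hazards and independent subjects; no
  diagnostics beyond the monotone-likelihood flag are provided.
- The qPCR LOQ and inhibition cutoffs are documented defaults, not
  instrument- or software-specific reproductions.
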