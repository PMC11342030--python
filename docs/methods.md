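# Methods

## Scope and pipeline

`pahrisk` implements a deterministic screening-level assessment of PAH-
contaminated surface soil: compound summary statistics → composition
profiles → BaP-equivalent toxicity (TEQ) → multi-route incremental lifetime
cancer risk (ILCR) and hazard quotient (HQ) for adult and child receptors.
There is no statistical estimation step: every output is an algebraic
function of the input concentrations and the exposure configuration, which
is why the package is organised as composable pipeline stages rather than
as a fitted-model object.

## Compound registry

The registry covers the 16 USEPA priority PAHs with Nisbet & LaGoy (1992)
TEFs (0.001 for most low-potency compounds; 0.01 for anthracene, chrysene
and benzo[g,h,i]perylene; 0.1 for benzo[a]anthracene, benzo[b]- and
benzo[k]fluoranthene and indeno[1,2,3-cd]pyrene; 1 for benzo[a]pyrene and
dibenzo[a,h]anthracene). Seven compounds (BaA, CHR, BbF, BkF, BaP, IcP,
DhA) form the carcinogenic set. Molecular-weight class is a pure function
of ring count: 2–3 rings LMW, 4 rings MMW, 5–6 rings HMW.

Two registry choices were genuinely open:

- **Benzo[g,h,i]perylene** is present in the bundled reference survey with
  zero concentration but is absent from that survey's ring lists; it is
  registered as a 6-ring compound with TEF 0.01 (standard chemistry; the
  zero concentration makes it numerically inert).
- **Benzo[e]pyrene** is named in some 16-compound lists but has no
  reference data row; it is shipped behind an opt-in flag
  (`default_registry(include_bep=True)`) with TEF 0 and is excluded by
  default so registry-wide totals cover exactly the 16 priority compounds.

The registry is a packaged CSV, so alternative TEF schemes can be swapped
in via `CompoundRegistry.from_csv` or the CLI `--registry` flag without
code changes.

## Summary statistics and composition profiles

Per-compound mean, std, min, max and percent-of-total are computed over
sampling locations. The standard deviation uses the sample (n−1)
denominator by default — conventional for small field campaigns — with
`ddof=0` available. Single-location tables return std = 0 with a warning
instead of failing, to keep toy examples runnable. Missing cells (NaN) are
excluded from statistics; values below a detection limit can be substituted
by 0, DL/2 or DL (`substitute_nondetects`, default 0, matching
no-blank-correction reporting). Percentages are carried at full precision;
rounding happens only in the report layer.

## Exposure and risk equations

The three ILCR routes and the EDI/HQ pair are implemented exactly as given
in the README. Numerical conventions:

- The body-weight rescaling (BW/70)^(1/3) is applied in **all three**
  routes, including inhalation.
- The averaging time AT = 25,550 days (70 y) is used for the carcinogenic
  and the non-carcinogenic calculation alike, following the exposure table
  the defaults were taken from. (Common regulatory practice instead uses
  ED × 365 d for non-cancer averaging; users can override `at` in a custom
  config, but note the packaged RfD was calibrated under AT = 25,550.)
- The driving concentration C is, by default, the **sum of the per-compound
  mean concentrations** (`concentration_basis="total"`); a
  BaP-equivalent basis (`"teq"`) is provided for sensitivity analysis.
  Using the total was verified by reverse computation against all four
  published ingestion/dermal risk cells of the reference survey.
- The RfD is not published alongside the reference survey. The packaged
  default, RfD = 2.0×10⁻³ with CF = 1, is the unique value that reproduces
  both the adult and the child published hazard quotients to two decimals
  from one shared dose — a non-circular consistency check, since one scalar
  must satisfy two independent cells. RfD and CF are mandatory config
  fields so users can substitute compound-specific regulatory RfDs.
- The child inhalation rate is 10 m³/day in the packaged defaults (the
  exposure table value; an accompanying text value of 9.6 m³/day exists —
  both give the same risk to one significant figure). Every parameter
  actually used is echoed in the report's provenance block to guard against
  this kind of config drift.
- Threshold classification is strict: ILCR > 10⁻⁶, HQ > 1; values exactly
  at a threshold do not flag.
- Report rounding: ILCRs to 2 significant figures, HQ to 2 decimals.

## Known reproduction limits of the reference survey

The bundled reference survey's published tables contain internal
inconsistencies; the package always reports the recomputed value:

- The 16 published means sum to 98.37 μg/g, while the published total row
  reads 98.34. All pipeline outputs use the recomputed 98.37; only the
  published-total-driven HQ check uses 98.34 as an explicit input.
- The published TEQ total is 16.49 μg/g; the published TEQ column (and the
  recomputation from means) sums to 16.484.
- The adult inhalation ILCR recomputes to ≈3.0×10⁻⁸ versus a published
  3.2×10⁻⁸ (the published value matches omitting the cube-root body-weight
  term in that one cell).
- The child ingestion ILCR recomputes to 4.35×10⁻⁴ versus a published
  4.4×10⁻⁴ (≈1.2% apart; no single parameter convention reproduces that
  cell together with the other three ingestion/dermal cells).
- The published child **total** ILCR, 9.8×10⁻⁵, is inconsistent with the
  published child route values, which sum to ≈9.8×10⁻⁴ — an apparent
  order-of-magnitude slip. The package reports the route sum.
- The survey's ring-class and weight-class percentage figures (39.37/23.77/
  23.23/11.67/1.97 and 25.2/23.77/51.03) are not derivable from the
  published means (recomputation gives ≈47.7/17.8/26.9/5.9/1.7 and
  28.6/17.8/53.6); they were presumably computed over unpublished
  per-location data. Only the ordinal claims (5-ring class largest, HMW
  dominant) are reproducible, and only those are asserted in tests.
  Likewise the per-location TEQ range (8.57–16.6 μg/g) requires unpublished
  per-location data and is not reproduced.

## Synthetic-site generator

The generator emulates the structure the analysis assumes: per-location,
per-compound concentrations with right-skewed, non-negative marginals.
Each cell is an independent lognormal parameterized by its **arithmetic**
mean m and log-scale shape σ (μ = ln m − σ²/2, so E[X] = m exactly),
matching the "mean concentration" semantics of survey summary tables.
Defaults: the 16 reference-survey means as targets (an HMW-dominant
mixture), σ = 0.5 — a moderate right skew (coefficient of variation ≈ 0.53)
typical of within-site contaminant variability — and 5 locations, the size
of a small workshop campaign. σ = 0 degenerates every location to the mean;
zero-mean compounds are identically zero; a fixed seed gives bit-identical
tables.

What the generator does **not** emulate: cross-compound correlation (real
PAH profiles are strongly correlated through shared sources; no covariance
information was available to calibrate one), spatial autocorrelation,
censoring at detection limits, and measurement error of the analytical
step. Passing parameter-recovery tests therefore demonstrates that the
pipeline's arithmetic is self-consistent under the assumed marginals, not
that it is robust to the dependence structure of real field data.

Validation sizes used in the test suite: marginal-distribution cross-checks
against scipy's lognormal at n = 2000, law-of-large-numbers mean recovery
at n = 10,000, and end-to-end pipeline recovery (ΣTEQ, ILCRs, HQ within 5%
of target-mean values) at n = 2000 — sizes at which sampling error is a
fraction of the tolerances being asserted.

## Degenerate inputs and error handling

Negative or non-finite concentrations, unknown compound columns, empty
CSVs and non-numeric cells are rejected at read time with named offenders.
Exposure profiles validate positivity, ABS ∈ (0, 1], EF ≤ 366 d/yr and
AT ≥ EF × ED. The CLI exits 2 on validation errors and 3 on I/O errors.
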