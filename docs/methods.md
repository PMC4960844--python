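# Methods

## Model and procedure

Two instruments rate the same n subjects on categorical scales with m and q
levels; the paired outcomes form an m×q contingency table with counts
x_ij, joint probabilities P(x_ij) = x_ij / n and marginals P(x_i·), P(x_·j).
The analysis assumes the table arises from multinomial sampling of
independent subjects (one draw per subject over the m·q cells).

Mutual information in bits,

    I = Σ_ij L_ij,    L_ij = P(x_ij) log2[ P(x_ij) / (P(x_i·) P(x_·j)) ],

measures association without direction. Direction comes from the *section
map* w ∈ [0,1]^{m×q}: each cell is an agreement section (w = 1), a
disagreement section (w = 0) or a partial mixture. The decomposition

    I_agreement = Σ w_ij L_ij,    I_disagreement = Σ (1 − w_ij) L_ij

is exact for any weight map (the two components always sum to I, a property
the test suite asserts to 1e-12). For binary weights it reduces to plain
sums over the two cell sets. The default map is the diagonal, which is only
constructed when the table is square with identical, identically-ordered
category labels on both axes; anything else requires an explicit map —
silent label alignment is a classic source of silent error.

Significance uses the likelihood-ratio identity: G = 2 n ln2 · I equals
2 Σ O ln(O/E) and is asymptotically χ² with ν = (m−1)(q−1) degrees of
freedom under independence. Rows or columns with zero marginals are dropped
(with a warning) before computing ν, since empty categories carry no
information and would deflate the reference distribution.

Verdict rule: p ≥ α ⇒ inconclusive (the procedure cannot distinguish true
independence from insufficient data, and the report says so); otherwise
agreement if I_agreement > I_disagreement, disagreement if the reverse. An
exact tie with significant I (measure-zero for real data, but reachable with
symmetric half-weight maps) is reported as inconclusive with a
direction-tie note, since the rule uses strict inequality. Verdicts are
computed at full precision; the rendered 3-decimal report never feeds back
into the classification.

## Comparator measures

- Raw agreement: Σ w_ij x_ij / n.
- Cohen's kappa: (P(a) − P(e)) / (1 − P(e)) with P(a) the diagonal mass and
  P(e) = Σ_i P(x_i·) P(x_·i); restricted to square tables with matching
  labels (two raters on one scale), undefined when P(e) = 1. Significance is
  a large-sample z test of κ against 0 using the null-hypothesis standard
  error computed from the marginals (Fleiss–Cohen–Everitt form). The source
  studies report kappa significance flags without a formula, so this is the
  package's own documented choice and the flags are matched qualitatively
  only.
- Odds ratio (2×2 only): x11·x22 / (x12·x21). One zero in the denominator
  gives +infinity with an explanatory tag — deliberately, so published
  infinite ORs reproduce; the Haldane–Anscombe +0.5 correction is available
  but **off by default** for the same reason. Significance is a Wald z test
  on ln(OR) with SE = √(Σ 1/x_ij), undefined with a zero cell unless the
  correction is enabled; again the package's own choice.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `alpha` | 0.05 | MI significance level; a first-class knob because applied reports sometimes use 0.1 |
| section weights | diagonal | per-cell agreement weight in [0, 1] |
| `haldane` | off | +0.5 odds-ratio correction |
| `rule` (dichotomize) | `ge` | score ≥ cutoff ⇒ positive; `gt` for strict. Severity-scale convention (e.g. delirium-severity cut-offs of 16 or 17 on a 0–39 scale); the choice is exposed because either convention is defensible |

All information quantities are reported in bits; the natural-log factor
lives only inside the G conversion (2 n ln2). Counts may be non-negative
reals so pooled or weighted tables work; the χ² test warns on non-integer
totals because its multinomial sampling assumption then fails. The
convention 0·log2(0/p) = 0 is applied exactly; the p·log2(p/0) = ∞ branch is
unreachable from count tables (a zero marginal forces zero cells) and raises
a flagged `DegenerateInputError` when inconsistent probability/marginal
pairs are injected directly.

## Simulation studies

`diagonal_sweep(total, k)` builds the family (x11, k, k, total − x11) for
x11 = 1 … total−1: total agreement is fixed while its split between
positive-positive and negative-negative shifts, with k disagreements per
off-diagonal cell. It shows both MI and kappa peaking at the even split for
every k, with peak MI decreasing in k — but MI rising smoothly toward the
peak where kappa saturates early. The published anchor table
(499, 1, 1, 499) gives κ = 0.996 and I = 0.979 bits. (The published sweep
narration increments x11 1→1000 while decrementing x22 1000→1, which sums to
1001 and cannot reach x11 = x22 = 499 exactly; this package fixes
x22 = total − x11 and anchors on the printed table's values directly.)

`random_table_study` draws seeded 2×2 tables: cell probabilities from a
symmetric Dirichlet over the four cells (default α = 1, uniform on the
simplex), counts multinomial with n_per_table per table, tables with a zero
marginal resampled and counted. With `independence=True` the cell
probabilities are a fixed product of marginals — an exact null used for
calibration: over 2000 tables at n = 200 the MI test rejects at the nominal
5 % within ±2 points, and the mean null MI sits at the chi-square bias level
1/(2 n ln2). The published measure-correlation figures came from an
unspecified sample population, so the study makes no claim to reproduce
their correlation coefficients numerically; it checks the qualitative
findings (positive correlation of MI with log-OR and with kappa under an
agreement-skewed prior; OR spanning orders of magnitude while MI stays ≤ 1).
Plotting is left thin by design: sweeps and studies are written as CSV so
figures are reproducible with any tool.

### What the synthetic generator does and does not emulate

The generator reproduces the *sampling* structure of a two-instrument
comparison: multinomial tables of independent subjects at realistic study
sizes (tens to hundreds). It does not emulate clustered or repeated
assessments of the same patient, rater drift over time, missing or partially
completed instruments, or ordinal severity structure beyond the
dichotomization step. Passing tests therefore validate the estimators and
the test's calibration under clean multinomial sampling, not robustness to
those real-data features.

## Numerical choices

- MI is clipped at 0 to absorb ≤1e-15 float noise on exactly independent
  tables; the entropy-identity oracle (I = H(row) + H(col) − H(joint)) is
  matched to 1e-10 in tests.
- Chi-square and normal tail probabilities come from scipy.stats; Pearson r
  delegates to scipy.stats.pearsonr, with zero-variance series returning
  NaN ("undefined") rather than raising.
- Deterministic JSON reports: sorted keys, full-precision floats, infinities
  serialized as the string "Infinity".
- All randomness flows through `numpy.random.default_rng(seed)`; studies
  record their seed.

## Problem sizes

The default verification runs use sweeps of total 200–998, correlation
studies of 300–500 tables, and a 2000-table calibration study at n = 200 —
sizes chosen to keep Monte-Carlo error well inside the asserted tolerances
while the whole suite runs in seconds.

## Known limitations

- Two instruments only; multi-rater generalizations (e.g. Fleiss' kappa) are
  out of scope.
- The χ² approximation is asymptotic; no exact/permutation MI test is
  provided, so p-values on very sparse tables inherit the usual
  small-expected-count caveats.
- The inconclusive verdict cannot separate "truly independent" from "not
  enough data"; no discriminating statistic exists in this framework, so the
  report states both readings.
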