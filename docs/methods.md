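# Methods

## Model and procedure

The package tests equality of k population locations when each
observation is an indeterminacy interval `[X_L, X_U]` (lower = determinate
part, upper = determinate + indeterminate part; a degenerate interval is
an exact classical observation). The procedure is the classical
tie-corrected Kruskal–Wallis test applied twice, once per component:

1. Pool the n lower endpoints of all groups and midrank them (average
   ranks for ties, exact comparison on the stored doubles — no epsilon);
   independently do the same for the n upper endpoints.
2. Form per-group rank sums R_i and compute, per component,
   `H = (n−1)(S_k² − C)/(S_r² − C)` with `S_k² = Σ R_i²/n_i`,
   `S_r² = Σ r_ij²` and `C = n(n+1)²/4`. `S_r²` is always the actual sum
   of squared midranks, so the tie correction is implicit; without ties it
   equals `n(n+1)(2n+1)/6` and H reduces to the familiar uncorrected form
   (an identity the test suite checks to 1e-10 relative).
3. Report the pair (H_L, H_U), per-component p-values, the neutrosophic
   form `H_L + H_U·I` with `I ∈ [0, (H_U − H_L)/H_U]`, and a three-valued
   decision against the chi-square critical value at level α: reject iff
   both components exceed it, fail to reject iff neither does, otherwise
   indeterminate.

Component-wise pooling is the scheme under which the interval test
reduces exactly to the classical test on degenerate data, which is the
design anchor of the whole construction. Ranking intervals by midpoint or
by an interval order would break that reduction and is deliberately not
offered.

### Assumptions

Groups are mutually independent random samples; observations are
exchangeable within groups (a "day" index in the reference data is just
an observation label). The test is robust to scattered ties; `validate()`
warns when more than half of a component's pooled values are involved in
ties, a deliberately cheap, conservative proxy for the qualitative
assumption that ties should not be concentrated.

## p-values

- `chi_square` (default): upper tail of χ² with k − 1 degrees of freedom,
  adequate when every group has more than five observations (`validate()`
  warns otherwise).
- `permutation`: the group labels are shuffled over the pooled
  observations. Midranks are permutation-invariant, so only the
  assignment of ranks to groups is re-drawn. Exhaustive enumeration is
  allowed while the multinomial count n!/(Π n_i!) is at most 200,000
  (the observed assignment is part of the enumeration, so p > 0);
  Monte-Carlo sampling otherwise, with the +1/+1 correction
  `(1 + #{H* ≥ H}) / (1 + B)` for the same guarantee. A relative jitter
  guard of 1e-12 is used when comparing permuted H values to the observed
  one, since tied statistics must count as "at least as extreme".

The permutation route replaces printed small-sample critical-value
tables: it is reproducible (seeded), table-free and handles arbitrary
group sizes and tie patterns.

## Edge cases and numerical choices

- `S_r² == C` means every pooled value is identical; H is then undefined
  and raised as `DegenerateSampleError` (except inside the permutation
  null, where every relabeling trivially gives the same statistic and
  p = 1).
- H_U = 0 with H_L ≠ 0 (perfect balance in one component only) leaves the
  relative indeterminacy without a finite value; the orchestrated result
  records NaN there while the low-level `indeterminacy_measure` raises.
  Random permutation-based simulations do hit this state.
- Derived statistic pairs are not forced to be ordered intervals: with
  ties the upper-component S_r² can legitimately fall below the
  lower-component one (it does on the reference dataset), so only input
  observations enforce lower ≤ upper.
- The indeterminacy denominator is the upper component,
  `|H_U − H_L|/|H_U|`, with absolute values guarding unordered pairs.
- Display convention: H is truncated toward zero at two decimals and the
  indeterminacy at three (24.1785 → 24.17), matching how the reference
  analysis prints its results; JSON output always carries full double
  precision.
- The decision uses strict inequality against the critical value, so a
  component exactly at the boundary does not reject.

## Synthetic-data generator

`generate_dataset` draws, for group i, lower endpoints from a base
distribution (normal, lognormal, or uniform; scale parameter in the units
of the measurement) shifted by a per-group location offset, and adds an
independent nonnegative width (constant, uniform on [0, w], or
exponential with mean w) to form the upper endpoint. Defaults — three
groups of 20, standard-normal base, uniform widths on [0, 0.2], i.e.
interval widths around a fifth of the within-group spread — mirror the
reference dataset's shape: moderate k, equal n_i = 20, and intervals
narrow relative to between-group separation. Replicates are individually
reproducible via per-replicate streams seeded as (master seed, replicate
index).

What the generator does not emulate: correlated determinate/indeterminate
noise, serial dependence between days, heteroscedastic groups, or
measurement-level ties (ties are measure-zero under continuous bases
unless injected). Passing simulation checks therefore demonstrates
calibration and power under clean exchangeable sampling, not robustness
to those real-data features.

`run_simulation` tallies the three-valued decisions over B replicates
(type-I error under zero shifts, power under nonzero shifts, plus the
indeterminate rate and per-component rejection rates) and reports the
binomial Monte-Carlo standard error √(r(1−r)/B). Simulation-based test
properties use B = 1000–2000 with n_i = 20, where the chi-square null is
accurate and one run takes a few seconds.

## Known limitations

- No post-hoc pairwise comparisons; the omnibus test is the product.
- Missing values are rejected, not imputed: the method defines no
  missing-data behavior.
- The chi-square null treats the two components separately; no joint
  (bivariate) null distribution for (H_L, H_U) is attempted.
- The three-valued decision rule is the minimal total extension of the
  classical rule to interval statistics; other resolutions of the
  straddling case (e.g. midpoint-based) are not implemented.
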