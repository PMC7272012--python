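# Methods

## The model

A run chart plots a time series against a centre line. `runbox` works in
the setting where the centre is **fixed and known in advance** (for
example a median from historical data) and the observations are
independent with a common continuous distribution. Each useful point
(one not exactly on the centre) then falls above the centre with some
probability `p`, independently of the others. Two statistics of the
resulting side sequence carry the runs-analysis information for a chart
with `N` useful points:

* `C` — number of centre-line crossings (adjacent points on opposite
  sides), between 0 and `N − 1`;
* `L` — longest run (maximal stretch of same-side points), between 1 and
  `N`.

A persistent shift of the process mean by `δ` standard deviations moves
the success probability to `p = Φ(δ)`, the standard normal CDF. Under a
shift, runs grow longer and crossings fewer, so rules that flag charts
with small `C` or large `L` detect shifts.

The joint pmf of `(C, L)` is computed exactly by conditioning on the
length `k` of the first run. Writing `f_s(m)` for the sub-distribution
of an `m`-point sequence whose first point lies on side `s` (with side
probabilities `p_a = p`, `p_b = 1 − p`):

```
f_s(m)(C, L) = p_s^m · 1[C = 0, L = m]
             + Σ_{k=1}^{m−1} p_s^k · f_s'(m−k)(C − 1, L'),   L = max(k, L')
```

and the full pmf is `f_a(m) + f_b(m)`. One pass of this recursion yields
every chart length up to `N`; the library exposes that via
`joint_cl_distributions`, so a whole table costs no more than its largest
`N`. The support of the pmf is exactly
`⌈N/(C+1)⌉ ≤ L ≤ N − C`: a chart with `C` crossings has `C + 1` runs, so
the longest is at least the average run length and at most `N` minus one
point for each other run.

An independent oracle, `brute_force_joint`, enumerates all `2^n` side
sequences (capped at `n ≤ 16`) with weights `p^(#above) (1−p)^(#below)`;
the test suite checks the recursion against it cell by cell for every
`n ≤ 12` at four shifts.

## Arithmetic and precision

* **No shift (`p = 1/2`).** All cell probabilities are dyadic rationals.
  The recursion runs on integer counts in the *times representation* —
  probabilities scaled by `2^(N−1)` — and results are exposed as exact
  `Fraction`s. Sums, region probabilities and serialisation round-trips
  are exact; the `N = 11` acceptance region really is `974/1024`.
* **Shifted charts.** `p = Φ(δ)` is irrational, so the recursion runs on
  `mpmath` floats with a configurable mantissa (default 128 bits, above
  the 120-bit floor the published computations used). Every operation in
  the recursion is a product or sum of non-negative terms — there is no
  cancellation — so even 53-bit arithmetic would carry far more than the
  4 decimals reported; the extended precision removes any doubt at
  `N = 100`, where individual cell masses reach `10^{-30}` and below.
  A distribution whose total mass strays from 1 by more than `10^{-12}`
  raises instead of degrading silently.
* **Rounding.** All published-style values are rounded half-away-from-zero
  to 4 decimals, and only at reporting; feasibility comparisons inside
  the optimisers use full precision.

## Rules and regions

The Anhøj rules declare non-random variation when `C < c` or `L > l`
with

* `c` = smallest integer whose cumulative `b(N−1, 1/2)` binomial
  probability is ≥ 0.05 (evaluated in exact integer arithmetic:
  `20 · Σ_{i≤c} C(N−1, i) ≥ 2^{N−1}`), and
* `l` = `log2(N) + 3` rounded to the nearest integer (never a
  half-integer for integer `N`, so the rounding convention is
  immaterial).

The acceptance region is the *box* `C ≥ c, L ≤ l`; its corner `(c, l)`
is the most extreme cell still considered random.

**Best box.** Given a target specificity (default 0.925) and target
shift (default 0.8 SD), `best_box` searches all `N(N+1)/2`-odd boxes
exhaustively using a cumulative box-probability table (each candidate
evaluated in O(1)) and returns the box with maximal sensitivity at the
target shift among those whose no-shift probability meets the floor.
Ties on sensitivity prefer higher specificity, then fewer support cells,
then larger `c`; ties only arise between boxes whose support cells
coincide, so the choice does not affect operating characteristics.

**Cut box.** `cut_box` trims cells from the best box, starting at the
corner and staying contiguous with it along the two borders (up the
rightmost column `L = l`, left along the topmost row `C = c`). The cut
grows **greedily, one cell at a time**: at each step the two frontier
cells are examined, the ones whose removal would drop specificity below
the floor are discarded, and of the remainder the cell with the larger
mass under the target-shift distribution (the larger sensitivity gain)
is cut; the procedure stops when neither frontier cell is feasible. If
even the corner is infeasible, no cut is made and the region equals the
best box. The retained border parts are reported as `C ≥ Cbord` (column)
and `L ≤ Lbord` (row), absent when uncut.

The stepwise rule is deliberate: a global search over all contiguous
border cuts can reach strictly higher sensitivity at the same
specificity floor (at `N = 26`, for instance, cutting four column cells
instead of the corner plus one row cell lifts sensitivity from 0.6298 to
0.6365), but the greedy procedure is the one whose output the published
reference table tabulates, and this package reproduces that table
verbatim — all 91 rows of limits exactly and all operating
characteristics to 4 decimals. The greedy tie-break (equal sensitivity
gain on both frontiers) prefers the column cell; no exact tie occurs for
`N` = 10–100 at the default targets, so this is a determinism choice
only.

Note the three acceptance regions are **not nested**: the best box can
accept cells the Anhøj box rejects (for `N = 11`, the cell
`C = 3, L = 7`), so a single series can signal under the Anhøj rules yet
pass the best box.

## Diagnostics

For a region `R`, specificity = `P(R)` under the no-shift distribution,
sensitivity = `1 − P(R)` under a shifted one, and the likelihood ratios
are `LR+ = sens/(1 − spec)`, `LR− = (1 − sens)/spec`, with infinities at
the degenerate endpoints by convention. `diagnostics_table` assembles
per-`N` rows (limits plus spec/sens at the target shift) and a
long-format grid of signal probabilities over a shift range (default
0–3 SD in 0.2 steps). The grid stores likelihood ratios on the log scale
to avoid precision loss at large `N`, where `LR+` grows into the
thousands; the CSV writer adds exponentiated columns for presentation.

## Synthetic data

`simulate_series` draws i.i.d. `N(δ, 1)` observations around a fixed
centre at 0 — exactly the model under which the joint distribution is
derived, so simulated operating characteristics must converge on the
exact ones and the Monte-Carlo tests are genuine cross-checks, not
calibrations. Continuity means points never land on the centre, so the
generator exercises no tie handling. What it does **not** emulate:
estimated (empirical-median) centre lines, autocorrelation, trends, or
non-normal noise — passing Monte-Carlo tests therefore validate the
probability calculus, not the applicability of the fixed-centre model to
any particular real series. Randomness comes from NumPy's PCG64
generator; a `SimulationConfig` seed makes runs bit-reproducible.

Default test problem sizes: distribution cross-checks at `n ≤ 12`
(enumeration bound), Monte-Carlo checks at `n = 11` with `10^5`
replications (binomial SEs ≈ 0.0015, tight enough to detect a wrong cell
at the third decimal), full-table checks over `N` = 10–100.

## Known limitations

* The fixed-centre assumption: when the centre is the median of the
  plotted data themselves, the exact probabilities do not apply
  (`classify` still computes verdicts; the published operating
  characteristics do not transfer). An empirical-centre joint
  distribution is out of scope.
* Published validation covers `N` = 10–100; other lengths compute with a
  logged warning.
* Observations exactly equal to the centre are excluded with no epsilon
  tolerance; users with heavily rounded data should round the centre the
  same way. Runs interrupted only by on-centre points continue across
  them (exclude-then-concatenate).
* Only box and border-cut region shapes are searched; arbitrary cell
  subsets are not.
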