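# runbox

Exact runs analysis for statistical process control run charts.

Quality-improvement teams read run charts — a time series with a centre
line — to decide whether a process has shifted. The Anhøj rules signal a
shift when the curve crosses the centre unusually few times (`C` below a
binomial limit) or contains an unusually long run (`L` above
`round(log2 N + 3)`). Because both statistics are discrete, the rules'
false-alarm rate jumps around as the number of data points changes.
`runbox` computes the **exact joint distribution of `C` and `L`** for a
chart with a fixed, known centre, and uses it to

* evaluate specificity, sensitivity and likelihood ratios of the Anhøj
  rules for any chart length and shift size;
* derive the **best box** (the rectangular acceptance region
  `C ≥ c, L ≤ l` with maximal sensitivity at a target shift, subject to a
  specificity floor) and the **cut box** (the best box with corner cells
  greedily trimmed to push specificity toward the floor), which smooth
  the operating characteristics across chart lengths;
* classify observed series under any of the three rule sets;
* cross-check everything by brute-force enumeration and Monte-Carlo
  simulation.

Arithmetic is exact (integer/rational) for the no-shift case and uses
128-bit extended-precision floats for shifted charts, so a number like
the 11-point chart's specificity is literally `974/1024 = 0.9512`.

## Worked example: an 11-point chart

```python
from runbox import (SuccessModel, joint_cl_distribution, anhoej_box,
                    best_box, cut_box, specificity, sensitivity,
                    likelihood_ratios, times_representation, round_half_away)

null = joint_cl_distribution(11, SuccessModel.from_shift(0))
shifted = joint_cl_distribution(11, SuccessModel.from_shift(0.8))

box = anhoej_box(11)                     # Box(c_min=2, l_max=6)
spec = specificity(box, null)            # Fraction(487, 512)
sens = sensitivity(box, shifted)
print(times_representation(null).region_count(box))   # 974
print(round_half_away(spec), round_half_away(sens))   # 0.9512 0.3493
print(likelihood_ratios(spec, sens))    # (7.154..., 0.684...)

bb = best_box(11, null, shifted)         # Box(c_min=3, l_max=7)
cb = cut_box(11, bb, null, shifted)      # corner cut: Cbord=4, Lbord=6
print(bb, cb.cbord, cb.lbord)
```

Reading: with 11 useful points and no shift, 974 of the 1024 equally
likely side patterns fall inside the Anhøj acceptance box, so the rules'
specificity is 0.9512; a persistent 0.8 SD shift is flagged with
probability 0.3493. A positive test multiplies the odds of a real shift
by about 7, a negative test divides them by about 1.5. The best box for
a 0.925 specificity target moves the limits to `C ≥ 3, L ≤ 7`
(sensitivity 0.3887), and the cut box additionally signals on the corner
cell `C = 3, L = 7` (sensitivity 0.4211 at specificity 0.9297).

The same computations are available from the shell:

```sh
runbox limits --n 11 --rules cutbox
# n=11 rules=cutbox C=3 L=7 Cbord=4 Lbord=6
runbox table --n-min 10 --n-max 100 --out table.csv --grid-out grid.csv
runbox analyze my_series.csv --centre 3.2 --rules anhoej,bestbox,cutbox
runbox simulate --n 11 --shift 0.8 --reps 100000 --seed 1 --out sim.json
```

`runbox table` writes one row per chart length with the Anhøj, best-box
and cut-box limits (`c_anhoej, l_anhoej, c_best, l_best, cbord, lbord`)
and their specificities/sensitivities at the target shift, plus an
optional long-format grid (`n, shift, rule, power, log_lr_plus,
log_lr_minus, lr_plus, lr_minus`) over any set of shifts.

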