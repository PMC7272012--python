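"""Diagnostic value of run-chart rules: specificity, sensitivity, LRs.

A run-chart rule set is a diagnostic test for non-random variation:

* specificity = P(no signal | no shift) — the acceptance-region
  probability under the no-shift joint (C, L) distribution;
* sensitivity = P(signal | shift) — one minus the acceptance-region
  probability under the shifted distribution;
* LR+ = sensitivity / (1 - specificity), LR- = (1 - sensitivity) /
  specificity.

The table builder assembles, per chart length, the limits and operating
characteristics of the three rule sets (Anhøj, best box, cut box) and a
long-format grid of signal probabilities and likelihood ratios over a
range of shifts.  Likelihood ratios are stored on the log scale in the
grid to preserve precision; rounding to 4 decimals (half away from zero)
is applied only when formatting results.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Mapping, Optional, Sequence, Union

import mpmath
import pandas as pd

from .boxopt import OptimizationTargets, best_box, cut_box
from .jointdist import (DEFAULT_PRECISION, JointDistribution, SuccessModel,
                        joint_cl_distributions)
from .rules import Box, CutRegion, anhoej_box

__all__ = [
    "RuleDiagnostics",
    "TableRow",
    "DiagnosticsResult",
    "specificity",
    "sensitivity",
    "likelihood_ratios",
    "diagnostics_table",
    "round_half_away",
]

RULES = ("anhoej", "bestbox", "cutbox")


def round_half_away(x, ndigits: int = 4) -> float:
    """Round a non-negative value with halves away from zero, as in the
    published tables (exact for rationals, extended precision otherwise)."""
    scale = 10 ** ndigits
    if isinstance(x, (Fraction, int)):
        s = Fraction(x) * scale
        return int((2 * s.numerator + s.denominator) // (2 * s.denominator)) / scale
    return float(mpmath.floor(mpmath.mpf(x) * scale + mpmath.mpf("0.5"))) / scale


def _check_n(region, dist: JointDistribution) -> None:
    box = region.box if isinstance(region, CutRegion) else region
    if isinstance(box, Box):
        if box.l_max > dist.n_useful or box.c_min > dist.n_useful - 1:
            raise ValueError(f"region limits {box} exceed the support of an "
                             f"n = {dist.n_useful} chart")


def specificity(region, dist_null: JointDistribution):
    """P(no signal | no shift): acceptance-region mass under the null."""
    if dist_null.model.shift != 0:
        raise ValueError("specificity requires the no-shift distribution")
    _check_n(region, dist_null)
    return dist_null.region_probability(region)


def sensitivity(region, dist_shift: JointDistribution):
    """P(signal | shift): one minus acceptance mass under the shifted pmf."""
    _check_n(region, dist_shift)
    return 1 - dist_shift.region_probability(region)


def likelihood_ratios(spec, sens) -> tuple[float, float]:
    """(LR+, LR-) from specificity and sensitivity.

    Perfect specificity yields an infinite LR+; zero specificity yields an
    infinite LR- (a degenerate, always-signalling rule).
    """
    spec_f, sens_f = float(spec), float(sens)
    for name, v in (("specificity", spec_f), ("sensitivity", sens_f)):
        if not (0 <= v <= 1):
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    lr_plus = math.inf if spec_f == 1 else sens_f / (1 - spec_f)
    lr_minus = math.inf if spec_f == 0 else (1 - sens_f) / spec_f
    return lr_plus, lr_minus


@dataclass(frozen=True)
class RuleDiagnostics:
    """Operating characteristics of one rule set at one chart length."""

    n: int
    rule_set: str
    region: Union[Box, CutRegion]
    specificity: float
    sensitivity_by_shift: Mapping[float, float]

    @property
    def lr_plus_by_shift(self) -> dict[float, float]:
        return {s: likelihood_ratios(self.specificity, v)[0]
                for s, v in self.sensitivity_by_shift.items()}

    @property
    def lr_minus_by_shift(self) -> dict[float, float]:
        return {s: likelihood_ratios(self.specificity, v)[1]
                for s, v in self.sensitivity_by_shift.items()}


@dataclass(frozen=True)
class TableRow:
    """One chart length's limits and operating characteristics: the layout
    of the published reference table (spec/sens at the target shift)."""

    n: int
    anhoej: Box
    bestbox: Box
    cut: CutRegion
    spec_anhoej: float
    spec_best: float
    spec_cut: float
    sens_anhoej: float
    sens_best: float
    sens_cut: float

    def __post_init__(self) -> None:
        if self.spec_cut > self.spec_best or self.sens_cut < self.sens_best:
            raise AssertionError(f"cut box must trade specificity for "
                                 f"sensitivity at n = {self.n}")

    def as_record(self) -> dict:
        return {
            "n": self.n,
            "c_anhoej": self.anhoej.c_min, "l_anhoej": self.anhoej.l_max,
            "c_best": self.bestbox.c_min, "l_best": self.bestbox.l_max,
            "cbord": self.cut.cbord, "lbord": self.cut.lbord,
            "spec_anhoej": round_half_away(self.spec_anhoej),
            "spec_best": round_half_away(self.spec_best),
            "spec_cut": round_half_away(self.spec_cut),
            "sens_anhoej": round_half_away(self.sens_anhoej),
            "sens_best": round_half_away(self.sens_best),
            "sens_cut": round_half_away(self.sens_cut),
        }


@dataclass(frozen=True)
class DiagnosticsResult:
    """Full diagnostics: per-n rows plus the long-format shift grid."""

    rows: tuple[TableRow, ...]
    grid: pd.DataFrame
    targets: OptimizationTargets

    def table_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.as_record() for r in self.rows])

    def to_csv(self, table_path, grid_path=None) -> None:
        self.table_frame().to_csv(table_path, index=False)
        if grid_path is not None:
            grid = self.grid.copy()
            grid["lr_plus"] = [math.exp(v) if math.isfinite(v) else math.inf
                               for v in grid["log_lr_plus"]]
            grid["lr_minus"] = [math.exp(v) if math.isfinite(v) else 0.0
                                for v in grid["log_lr_minus"]]
            grid.to_csv(grid_path, index=False)


def _log_or_inf(x: float) -> float:
    if x == 0:
        return -math.inf
    if math.isinf(x):
        return math.inf
    return math.log(x)


def diagnostics_table(n_range: Iterable[int] = range(10, 101),
                      shifts: Optional[Sequence[float]] = None,
                      targets: OptimizationTargets = OptimizationTargets(),
                      precision: int = DEFAULT_PRECISION) -> DiagnosticsResult:
    """Limits and operating characteristics over chart lengths and shifts.

    For every ``n`` the Anhøj box, best box and cut box are derived (the
    latter two under ``targets``); the table rows carry spec/sens at the
    target shift, the grid carries P(signal) and log likelihood ratios for
    every requested shift (default 0 to 3 SD in 0.2 steps).
    """
    ns = sorted(set(int(n) for n in n_range))
    if shifts is None:
        shifts = [round(0.2 * i, 1) for i in range(16)]
    shifts = list(dict.fromkeys(float(s) for s in shifts))
    if any(s < 0 for s in shifts):
        raise ValueError("shifts must be >= 0")

    null = SuccessModel.from_shift(0)
    dn = joint_cl_distributions(ns, null)
    by_shift: dict[float, dict[int, JointDistribution]] = {}
    for s in {targets.target_shift, *shifts}:
        if s == 0:
            by_shift[0.0] = dn
        else:
            by_shift[s] = joint_cl_distributions(
                ns, SuccessModel.from_shift(s, precision), precision)

    rows = []
    grid_records = []
    d_target = by_shift[targets.target_shift]
    for n in ns:
        regions = {"anhoej": anhoej_box(n)}
        regions["bestbox"] = best_box(n, dn[n], d_target[n], targets)
        regions["cutbox"] = cut_box(n, regions["bestbox"], dn[n], d_target[n],
                                    targets)
        spec = {r: specificity(regions[r], dn[n]) for r in RULES}
        sens_t = {r: sensitivity(regions[r], d_target[n]) for r in RULES}
        rows.append(TableRow(
            n=n, anhoej=regions["anhoej"], bestbox=regions["bestbox"],
            cut=regions["cutbox"],
            spec_anhoej=float(spec["anhoej"]), spec_best=float(spec["bestbox"]),
            spec_cut=float(spec["cutbox"]), sens_anhoej=float(sens_t["anhoej"]),
            sens_best=float(sens_t["bestbox"]), sens_cut=float(sens_t["cutbox"])))
        for s in shifts:
            for r in RULES:
                power = (float(1 - spec[r]) if s == 0
                         else float(sensitivity(regions[r], by_shift[s][n])))
                lr_p, lr_m = likelihood_ratios(spec[r], power if s > 0 else 0.0)
                grid_records.append({
                    "n": n, "shift": s, "rule": r, "power": power,
                    "specificity": float(spec[r]),
                    "log_lr_plus": _log_or_inf(lr_p) if s > 0 else math.nan,
                    "log_lr_minus": _log_or_inf(lr_m) if s > 0 else math.nan,
                })
    grid = pd.DataFrame.from_records(grid_records)
    return DiagnosticsResult(rows=tuple(rows), grid=grid, targets=targets)
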