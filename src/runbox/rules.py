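"""Anhøj run-chart rules: signal limits, acceptance regions, series statistics.

The Anhøj rules declare non-random variation (a signal) in an ``n``-point
run chart when the curve crosses the centre line unusually few times or
contains an unusually long run.  Both critical values depend only on the
number of useful points ``n`` (points not exactly on the centre line):

* crossings limit: the lower 5th percentile of the binomial ``b(n-1, 1/2)``
  distribution of crossings — the smallest ``c`` with ``P(C <= c) >= 0.05``;
  random variation requires ``C >= c``;
* longest-run limit: ``round(log2(n) + 3)``; random variation requires
  ``L <= l``.

Together the two limits delimit a rectangular acceptance region (a *box*)
in the ``(C, L)`` grid.  The cut-box refinement additionally trims border
cells from the box corner (see :mod:`runbox.boxopt`); this module defines
the region geometry and the extraction of ``C`` and ``L`` from data.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping, Optional, Sequence

__all__ = [
    "VALIDATED_RANGE",
    "Box",
    "CutRegion",
    "SeriesAnalysis",
    "anhoej_crossings_limit",
    "anhoej_longest_run_limit",
    "anhoej_box",
    "useful_observations",
    "count_crossings",
    "longest_run",
    "classify",
]

logger = logging.getLogger(__name__)

#: Chart lengths for which the published limits have been validated.
VALIDATED_RANGE = (10, 100)

ABOVE, BELOW = 1, -1


@dataclass(frozen=True)
class Box:
    """Rectangular acceptance region ``C >= c_min and L <= l_max``.

    The *corner* is the cell ``(c_min, l_max)``: fewest crossings and
    longest run still considered random.
    """

    c_min: int
    l_max: int

    def __post_init__(self) -> None:
        if self.c_min < 0:
            raise ValueError(f"c_min must be >= 0, got {self.c_min}")
        if self.l_max < 1:
            raise ValueError(f"l_max must be >= 1, got {self.l_max}")

    @property
    def corner(self) -> tuple[int, int]:
        return (self.c_min, self.l_max)

    def accepts(self, c: int, l: int) -> bool:
        """True when the cell counts as random variation (no signal)."""
        return c >= self.c_min and l <= self.l_max

    def signals(self, c: int, l: int) -> bool:
        return not self.accepts(c, l)


@dataclass(frozen=True)
class CutRegion:
    """A best box with contiguous border cells removed from its corner.

    On the rightmost column ``L = l_max`` only cells with ``C >= cbord``
    remain accepted; on the topmost row ``C = c_min`` only cells with
    ``L <= lbord`` remain.  When no cells are cut, ``cbord`` and ``lbord``
    are both absent and the region coincides with the box.
    """

    box: Box
    cbord: Optional[int] = None
    lbord: Optional[int] = None

    def __post_init__(self) -> None:
        if (self.cbord is None) != (self.lbord is None):
            raise ValueError("cbord and lbord must be jointly present or absent")
        if self.cbord is not None:
            if not (self.box.c_min < self.cbord):
                raise ValueError(f"cbord {self.cbord} must exceed c_min "
                                 f"{self.box.c_min} (the corner is always cut)")
            if not (self.lbord < self.box.l_max):
                raise ValueError(f"lbord {self.lbord} must be below l_max "
                                 f"{self.box.l_max} (the corner is always cut)")
            if self.lbord < 1:
                raise ValueError(f"lbord must be >= 1, got {self.lbord}")

    @property
    def is_cut(self) -> bool:
        return self.cbord is not None

    def cut_cells(self) -> set[tuple[int, int]]:
        """Cells removed from the box (empty when uncut)."""
        if not self.is_cut:
            return set()
        col = {(c, self.box.l_max) for c in range(self.box.c_min, self.cbord)}
        row = {(self.box.c_min, l) for l in range(self.lbord + 1, self.box.l_max + 1)}
        return col | row

    def accepts(self, c: int, l: int) -> bool:
        if not self.box.accepts(c, l):
            return False
        if not self.is_cut:
            return True
        if l == self.box.l_max and c < self.cbord:
            return False
        if c == self.box.c_min and l > self.lbord:
            return False
        return True

    def signals(self, c: int, l: int) -> bool:
        return not self.accepts(c, l)


def anhoej_crossings_limit(n: int) -> int:
    """Lower limit for the number of crossings in an ``n``-point chart.

    Crossings are binomial ``b(n-1, 1/2)``; the limit is the smallest
    ``c`` whose cumulative probability reaches 0.05, evaluated in exact
    integer arithmetic: the smallest ``c`` with
    ``20 * sum_{i<=c} binom(n-1, i) >= 2^(n-1)``.
    """
    if n < 1:
        raise ValueError(f"chart length must be >= 1, got {n}")
    m = n - 1
    threshold = 2 ** m  # compare 20 * cumsum >= 2^m  <=>  cdf >= 1/20
    acc = 0
    for c in range(m + 1):
        acc += math.comb(m, c)
        if 20 * acc >= threshold:
            return c
    return m  # unreachable: cdf reaches 1


def anhoej_longest_run_limit(n: int) -> int:
    """Upper limit for the longest run: ``log2(n) + 3`` rounded to the
    nearest integer (never a half-integer for integer ``n > 1``)."""
    if n < 1:
        raise ValueError(f"chart length must be >= 1, got {n}")
    return int(math.floor(math.log2(n) + 3 + 0.5))


def _warn_outside_validated(n: int) -> None:
    lo, hi = VALIDATED_RANGE
    if not (lo <= n <= hi):
        logger.warning("chart length %d is outside the validated range %d-%d; "
                       "limits are computed from the same formulas but have "
                       "not been checked against published values", n, lo, hi)


def anhoej_box(n: int) -> Box:
    """The Anhøj acceptance box for ``n`` useful points."""
    _warn_outside_validated(n)
    return Box(anhoej_crossings_limit(n), anhoej_longest_run_limit(n))


def useful_observations(values: Sequence[float], centre: float) -> list[int]:
    """Sides (+1 above / -1 below) of the useful observations.

    Points exactly equal to the centre are excluded (no epsilon
    tolerance); the remaining sides are concatenated in order, so a run
    interrupted only by on-centre points continues across them.
    """
    if len(values) == 0:
        raise ValueError("series is empty")
    sides = [ABOVE if v > centre else BELOW for v in values if v != centre]
    if not sides:
        raise ValueError("no useful observations: every value falls exactly "
                         "on the centre line")
    return sides


def count_crossings(sides: Sequence[int]) -> int:
    """Number of transitions between sides (adjacent unequal pairs)."""
    if len(sides) == 0:
        raise ValueError("side sequence is empty")
    return sum(1 for a, b in zip(sides, sides[1:]) if a != b)


def longest_run(sides: Sequence[int]) -> int:
    """Length of the longest stretch of identical sides."""
    if len(sides) == 0:
        raise ValueError("side sequence is empty")
    best = run = 1
    for a, b in zip(sides, sides[1:]):
        run = run + 1 if a == b else 1
        if run > best:
            best = run
    return best


@dataclass(frozen=True)
class SeriesAnalysis:
    """Runs analysis of one observed series: centre, useful points,
    observed (C, L), the applied limits, and the per-rule-set verdicts
    (True = signal, i.e. non-random variation)."""

    values: tuple[float, ...]
    centre: float
    n_useful: int
    crossings: int
    longest_run: int
    verdicts: Mapping[str, bool]
    regions: Mapping[str, object] = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {
            "values": list(self.values),
            "centre": self.centre,
            "n_useful": self.n_useful,
            "crossings": self.crossings,
            "longest_run": self.longest_run,
            "verdicts": dict(self.verdicts),
            "limits": {},
        }
        for name, region in self.regions.items():
            box = region if isinstance(region, Box) else region.box
            entry = {"c_min": box.c_min, "l_max": box.l_max}
            if isinstance(region, CutRegion) and region.is_cut:
                entry["cbord"] = region.cbord
                entry["lbord"] = region.lbord
            out["limits"][name] = entry
        return out


RULE_SETS = ("anhoej", "bestbox", "cutbox")


def classify(values: Sequence[float], centre: Optional[float] = None,
             rule_set="anhoej", limits=None, targets=None,
             precision: Optional[int] = None) -> SeriesAnalysis:
    """Classify a series as random / non-random under one or more rule sets.

    ``centre`` defaults to the median of the values (the run chart's usual
    reference); note the probability model behind the published operating
    characteristics assumes a fixed, pre-determined centre.  ``rule_set``
    may be a single name or a sequence drawn from ``anhoej``, ``bestbox``,
    ``cutbox``; ``limits`` may supply a pre-computed :class:`Box` or
    :class:`CutRegion` (single rule set only), otherwise limits are
    derived for ``n_useful`` (best/cut boxes via :mod:`runbox.boxopt`
    under ``targets``).
    """
    import statistics

    if centre is None:
        centre = statistics.median(values)
    sides = useful_observations(values, centre)
    n = len(sides)
    c, l = count_crossings(sides), longest_run(sides)
    if n < VALIDATED_RANGE[0]:
        logger.warning("only %d useful points; published limits cover "
                       "N >= %d — verdicts are computed but not validated",
                       n, VALIDATED_RANGE[0])

    names = (rule_set,) if isinstance(rule_set, str) else tuple(rule_set)
    for name in names:
        if name not in RULE_SETS:
            raise ValueError(f"unknown rule set {name!r}; expected one of {RULE_SETS}")
    regions: dict[str, object] = {}
    if limits is not None:
        if len(names) != 1:
            raise ValueError("explicit limits apply to a single rule set")
        regions[names[0]] = limits
    else:
        need_boxes = any(name in ("bestbox", "cutbox") for name in names)
        if "anhoej" in names:
            regions["anhoej"] = anhoej_box(n)
        if need_boxes:
            from . import boxopt
            from .jointdist import SuccessModel, joint_cl_distributions
            from .boxopt import OptimizationTargets
            targets = targets or OptimizationTargets()
            null = SuccessModel.from_shift(0)
            shifted = SuccessModel.from_shift(targets.target_shift)
            dist_null = joint_cl_distributions([n], null)[n]
            dist_shift = joint_cl_distributions([n], shifted, precision)[n]
            best = boxopt.best_box(n, dist_null, dist_shift, targets)
            if "bestbox" in names:
                regions["bestbox"] = best
            if "cutbox" in names:
                regions["cutbox"] = boxopt.cut_box(n, best, dist_null, dist_shift,
                                                   targets)
    verdicts = {name: regions[name].signals(c, l) for name in names}
    return SeriesAnalysis(values=tuple(float(v) for v in values), centre=float(centre),
                          n_useful=n, crossings=c, longest_run=l,
                          verdicts=verdicts, regions=regions)
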