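"""Best-box and cut-box adjustments of the run-chart signal limits.

The Anhøj limits fix the acceptance box from two marginal formulas, which
makes the chart's specificity jump around as ``n`` changes.  Working from
the exact joint distribution of crossings and longest run, two refinements
smooth this out toward chosen targets (default specificity 0.925 at a
target shift of 0.8 SD):

* *best box* — among all rectangular regions ``C >= c, L <= l`` whose
  probability under the no-shift distribution (specificity) is at least
  the target, the one with the highest signal probability under the
  target-shift distribution (sensitivity);
* *cut box* — the best box with cells trimmed from its corner along the
  topmost row and rightmost column, again maximising sensitivity subject
  to the specificity floor.  The retained parts of the borders are
  reported as ``C >= cbord`` (column) and ``L <= lbord`` (row).

Specificity comparisons use the full available precision of the
distributions; rounding to 4 decimals happens only when reporting.
"""

from __future__ import annotations

from dataclasses import dataclass

from .jointdist import JointDistribution, support_bounds
from .rules import Box, CutRegion

__all__ = ["OptimizationTargets", "best_box", "cut_box"]


@dataclass(frozen=True)
class OptimizationTargets:
    """Targets of the box search: the specificity floor and the shift (SD
    units) at which sensitivity is maximised."""

    target_specificity: float = 0.925
    target_shift: float = 0.8

    def __post_init__(self) -> None:
        if not (0 < self.target_specificity < 1):
            raise ValueError(f"target specificity must lie in (0, 1), got "
                             f"{self.target_specificity}")
        if self.target_shift <= 0:
            raise ValueError(f"target shift must be > 0, got {self.target_shift}")


def _check_pair(n: int, dist_null: JointDistribution, dist_shift: JointDistribution,
                targets: OptimizationTargets) -> None:
    if dist_null.n_useful != n or dist_shift.n_useful != n:
        raise ValueError(f"distributions cover n = {dist_null.n_useful} and "
                         f"{dist_shift.n_useful}; expected both = {n}")
    if dist_null.model.shift != 0:
        raise ValueError("dist_null must be the no-shift distribution")
    if dist_shift.model.shift != targets.target_shift:
        raise ValueError(f"dist_shift has shift {dist_shift.model.shift}; the "
                         f"targets specify {targets.target_shift}")


def _box_cell_count(n: int, c_min: int, l_max: int) -> int:
    """Number of support cells inside the box (zero-mass cells excluded)."""
    count = 0
    for c in range(c_min, n):
        lo, hi = support_bounds(n, c)
        hi = min(hi, l_max)
        if hi >= lo:
            count += hi - lo + 1
    return count


def best_box(n: int, dist_null: JointDistribution, dist_shift: JointDistribution,
             targets: OptimizationTargets = OptimizationTargets()) -> Box:
    """Exhaustive search for the box with maximal sensitivity at the target
    shift among boxes meeting the specificity floor.

    Ties on sensitivity prefer higher specificity, then fewer acceptance
    cells, then larger ``c_min`` (a deterministic, conservative order).
    """
    _check_pair(n, dist_null, dist_shift, targets)
    B_null = dist_null.box_probability_table()
    B_shift = dist_shift.box_probability_table()
    floor = targets.target_specificity
    best = None  # (sens, spec, -cells, c_min, l_max)
    for c in range(n):
        for l in range(1, n + 1):
            spec = B_null[c][l]
            if spec < floor:
                continue
            sens = 1 - B_shift[c][l]
            key = (sens, spec, -_box_cell_count(n, c, l), c)
            if best is None or key > best[0]:
                best = (key, Box(c, l))
    if best is None:  # full-support box has specificity 1 > any valid floor
        raise RuntimeError("no feasible box found — specificity floor >= 1?")
    return best[1]


def cut_box(n: int, box: Box, dist_null: JointDistribution,
            dist_shift: JointDistribution,
            targets: OptimizationTargets = OptimizationTargets()) -> CutRegion:
    """Trim border cells from the best box's corner to raise sensitivity
    while keeping specificity at or above the target.

    The cut grows one cell at a time, always contiguous with the corner:
    the frontier consists of the next uncut cell on the rightmost column
    (increasing ``C``) and the next uncut cell on the topmost row
    (decreasing ``L``).  At each step, among the frontier cells whose
    removal keeps specificity at or above the floor, the cell with the
    larger sensitivity gain (its mass under the shifted distribution) is
    cut; on an exact tie the column cell is preferred.  The procedure
    stops when neither frontier cell can be cut.  This stepwise rule can
    retain less sensitivity than an exhaustive search over all border
    cuts, but it is the procedure whose output the published limit tables
    tabulate.  When even the corner cannot be cut, the borders are
    reported absent and the region equals the box.
    """
    _check_pair(n, dist_null, dist_shift, targets)
    reference = best_box(n, dist_null, dist_shift, targets)
    if box != reference:
        raise ValueError(f"box {box} is not the best box for n = {n} under "
                         f"these targets (expected {reference})")

    c_min, l_max = box.c_min, box.l_max
    # support extents of the two borders (cells with positive mass)
    col_cs = [c for c in range(c_min, n)
              if support_bounds(n, c)[0] <= l_max <= support_bounds(n, c)[1]]
    row_lo, _ = support_bounds(n, c_min)
    row_ls = list(range(min(support_bounds(n, c_min)[1], l_max), row_lo - 1, -1))

    spec = dist_null.box_probability_table()[c_min][l_max]
    floor = targets.target_specificity

    # corner first; infeasible corner means no cut at all
    if not col_cs or spec - dist_null[box.corner] < floor:
        return CutRegion(box=box)
    spec = spec - dist_null[box.corner]
    col_i, row_i = 1, 1  # frontier indices past the corner

    while True:
        col_cell = (col_cs[col_i], l_max) if col_i < len(col_cs) else None
        row_cell = (c_min, row_ls[row_i]) if row_i < len(row_ls) else None
        col_ok = col_cell is not None and spec - dist_null[col_cell] >= floor
        row_ok = row_cell is not None and spec - dist_null[row_cell] >= floor
        if not col_ok and not row_ok:
            break
        if col_ok and (not row_ok or
                       dist_shift[col_cell] >= dist_shift[row_cell]):
            spec = spec - dist_null[col_cell]
            col_i += 1
        else:
            spec = spec - dist_null[row_cell]
            row_i += 1

    cbord = col_cs[col_i] if col_i < len(col_cs) else col_cs[-1] + 1
    lbord = row_ls[row_i] if row_i < len(row_ls) else row_ls[-1]
    return CutRegion(box=box, cbord=cbord, lbord=lbord)
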