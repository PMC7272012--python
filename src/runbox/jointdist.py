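"""Exact joint distribution of centre-line crossings and longest run.

A run chart with *n* useful data points (points not falling exactly on the
centre line) induces a binary sequence of sides (above/below centre).  Two
statistics of that sequence drive runs analysis: the number of crossings
``C`` (adjacent points on opposite sides; 0 .. n-1) and the longest run
``L`` (maximal stretch of same-side points; 1 .. n).  This module computes
the exact joint probability mass function of ``(C, L)`` for independent,
identically distributed sides with ``P(above) = p``.

The computation conditions on the length ``k`` of the first run: writing
``f_s(m)`` for the sub-distribution of an ``m``-point sequence whose first
point lies on side ``s``,

    f_s(m)(C, L) = p_s^m * 1[C = 0, L = m]
                 + sum_{k=1}^{m-1} p_s^k * f_s'(m-k)(C - 1, L'),

with the final ``L = max(k, L')`` and ``s'`` the opposite side.  One pass
of this recursion yields the distributions for every length up to ``n``.

Arithmetic is exact (integer "times" counts, i.e. probabilities scaled by
``2^(n-1)``) in the symmetric case ``p = 1/2`` and uses ``mpmath``
arbitrary-precision floats (default 128-bit mantissa) otherwise, so that
results are reliable well beyond the 4 decimals at which they are reported.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Callable, Iterable, Mapping, Union

import mpmath
import pandas as pd

__all__ = [
    "DEFAULT_PRECISION",
    "BRUTE_FORCE_CAP",
    "SuccessModel",
    "JointDistribution",
    "TimesMatrix",
    "shift_to_success_prob",
    "joint_cl_distribution",
    "joint_cl_distributions",
    "brute_force_joint",
    "times_representation",
    "region_probability",
    "support_bounds",
]

#: Default mantissa size (bits) for shifted-chart computations.
DEFAULT_PRECISION = 128

#: Largest chart length accepted by the 2^n brute-force oracle.
BRUTE_FORCE_CAP = 16

Number = Union[Fraction, mpmath.mpf]
RegionLike = Union[Callable[[int, int], bool], "object"]

_HALF = Fraction(1, 2)


def shift_to_success_prob(shift: float, precision: int = DEFAULT_PRECISION) -> Number:
    """Map a process shift (in SD units) to the probability of a point
    falling above the fixed centre line.

    The process is modelled as normal with unit SD around a fixed, known
    centre; a mean shift of ``shift`` SD therefore puts each point above
    centre with probability ``Phi(shift)``.  Returns the exact
    ``Fraction(1, 2)`` for ``shift = 0`` and an ``mpmath`` float with
    ``precision`` bits otherwise.
    """
    if not math.isfinite(shift):
        raise ValueError(f"shift must be finite, got {shift!r}")
    if shift < 0:
        raise ValueError(f"shift must be >= 0 (SD units), got {shift!r}")
    if shift == 0:
        return _HALF
    with mpmath.workprec(precision):
        return mpmath.ncdf(mpmath.mpf(shift))


@dataclass(frozen=True)
class SuccessModel:
    """Side model for one chart point: shift in SD units and P(above centre).

    ``p_above`` is derived from ``shift`` via the standard normal CDF; a
    zero shift gives exactly 1/2.
    """

    shift: float
    p_above: Number
    precision: int = DEFAULT_PRECISION

    @classmethod
    def from_shift(cls, shift: float, precision: int = DEFAULT_PRECISION) -> "SuccessModel":
        return cls(shift=float(shift), p_above=shift_to_success_prob(shift, precision),
                   precision=precision)

    def __post_init__(self) -> None:
        p = self.p_above
        if not (0 < p < 1):
            raise ValueError(f"p_above must lie in (0, 1), got {p}")
        if self.shift == 0 and p != _HALF:
            raise ValueError("shift = 0 requires p_above = 1/2 exactly")

    @property
    def is_symmetric(self) -> bool:
        return self.p_above == _HALF


def support_bounds(n: int, c: int) -> tuple[int, int]:
    """Inclusive range ``(lo, hi)`` of longest-run values attainable with
    ``c`` crossings in ``n`` points.

    A chart with ``c`` crossings has ``c + 1`` runs, so the longest run is
    at least the ceiling of the average run length, ``ceil(n / (c + 1))``,
    and at most ``n - c`` (every other run contributing a single point).
    """
    return -(-n // (c + 1)), n - c


def _accepts(region: RegionLike) -> Callable[[int, int], bool]:
    if callable(region):
        return region
    accepts = getattr(region, "accepts", None)
    if accepts is None:
        raise TypeError(f"region must be callable or expose .accepts, got {region!r}")
    return accepts


def _count_matrices_half(n_max: int) -> list:
    """Single-side integer times counts for p = 1/2, all lengths up to n_max.

    ``F[m][c][l]`` counts the sequences of length ``m`` starting above the
    centre with ``c`` crossings and longest run ``l``; by symmetry the
    below-start counts are identical, so ``F[m]`` summed over cells equals
    ``2^(m-1)`` and is exactly the published times representation.
    """
    F: list = [None]
    cums: list = [None]
    for m in range(1, n_max + 1):
        A = [[0] * (m + 2) for _ in range(m)]
        A[0][m] = 1
        for k in range(1, m):
            j = m - k
            G, CUM = F[j], cums[j]
            for c in range(j):
                lo, hi = support_bounds(j, c)
                out = A[c + 1]
                s = CUM[c][min(k, hi)]
                if s:
                    out[k] += s
                row = G[c]
                for l in range(max(k + 1, lo), hi + 1):
                    v = row[l]
                    if v:
                        out[l] += v
        F.append(A)
        cum = []
        for c in range(m):
            row, acc, crow = A[c], 0, [0] * (m + 1)
            for l in range(1, m + 1):
                acc += row[l]
                crow[l] = acc
            cum.append(crow)
        cums.append(cum)
    return F


def _mass_matrices_general(n_max: int, p: mpmath.mpf) -> list:
    """Two-sided probability mass matrices for arbitrary p, lengths 1..n_max."""
    q = 1 - p
    pow_p = [mpmath.mpf(1)]
    pow_q = [mpmath.mpf(1)]
    for _ in range(n_max):
        pow_p.append(pow_p[-1] * p)
        pow_q.append(pow_q[-1] * q)

    zero = mpmath.mpf(0)
    sides: dict = {"a": [None], "b": [None]}   # F keyed by starting side
    cums: dict = {"a": [None], "b": [None]}
    for m in range(1, n_max + 1):
        for s, pw, other in (("a", pow_p, "b"), ("b", pow_q, "a")):
            A = [[zero] * (m + 2) for _ in range(m)]
            A[0][m] = pw[m]
            for k in range(1, m):
                j = m - k
                G, CUM = sides[other][j], cums[other][j]
                pk = pw[k]
                for c in range(j):
                    lo, hi = support_bounds(j, c)
                    out = A[c + 1]
                    s_cum = CUM[c][min(k, hi)]
                    if s_cum:
                        out[k] += pk * s_cum
                    row = G[c]
                    for l in range(max(k + 1, lo), hi + 1):
                        v = row[l]
                        if v:
                            out[l] += pk * v
            sides[s].append(A)
            cum = []
            for c in range(m):
                row, acc, crow = A[c], zero, [zero] * (m + 1)
                for l in range(1, m + 1):
                    acc = acc + row[l]
                    crow[l] = acc
                cum.append(crow)
            cums[s].append(cum)
    # combine sides into total mass matrices
    out = [None]
    for m in range(1, n_max + 1):
        Fa, Fb = sides["a"][m], sides["b"][m]
        out.append([[Fa[c][l] + Fb[c][l] for l in range(m + 2)] for c in range(m)])
    return out


class JointDistribution:
    """Exact pmf of ``(C, L)`` for an ``n``-point chart under a side model.

    ``mass`` maps support cells ``(c, l)`` to probabilities; the
    representation is ``"rational"`` (``Fraction`` masses, exact) for the
    symmetric model and ``"float"`` (``mpmath`` extended precision)
    otherwise.
    """

    def __init__(self, n_useful: int, model: SuccessModel,
                 mass: Mapping[tuple[int, int], Number], representation: str):
        if n_useful < 1:
            raise ValueError(f"n_useful must be >= 1, got {n_useful}")
        if representation not in ("rational", "float"):
            raise ValueError(f"unknown representation {representation!r}")
        self.n_useful = int(n_useful)
        self.model = model
        self.mass = dict(mass)
        self.representation = representation
        self._check_total()

    def _check_total(self) -> None:
        total = self.total_mass()
        if self.representation == "rational":
            if total != 1:
                raise ArithmeticError(f"exact masses sum to {total}, not 1")
        elif abs(total - 1) > mpmath.mpf("1e-12"):
            raise ArithmeticError(
                f"masses sum to {total}; precision loss beyond 1e-12 — "
                f"increase the working precision")

    def total_mass(self) -> Number:
        vals = list(self.mass.values())
        if not vals:
            return Fraction(0)
        acc = vals[0]
        for v in vals[1:]:
            acc = acc + v
        return acc

    def __getitem__(self, key: tuple[int, int]) -> Number:
        zero = Fraction(0) if self.representation == "rational" else mpmath.mpf(0)
        return self.mass.get(key, zero)

    def cells(self) -> Iterable[tuple[int, int, Number]]:
        for (c, l), v in sorted(self.mass.items()):
            yield c, l, v

    def region_probability(self, region: RegionLike) -> Number:
        accepts = _accepts(region)
        zero = Fraction(0) if self.representation == "rational" else mpmath.mpf(0)
        acc = zero
        for (c, l), v in sorted(self.mass.items()):
            if accepts(c, l):
                acc = acc + v
        return acc

    def box_probability_table(self):
        """Matrix ``B[c][l] = P(C >= c and L <= l)`` for all box corners.

        ``B`` has shape ``(n+1) x (n+1)`` indexed by ``c`` in 0..n and
        ``l`` in 0..n; row ``c = n`` and column ``l = 0`` are zero.  Used
        by the box-optimisation search, which needs every box probability.
        """
        n = self.n_useful
        zero = Fraction(0) if self.representation == "rational" else mpmath.mpf(0)
        B = [[zero] * (n + 1) for _ in range(n + 1)]
        for c in range(n - 1, -1, -1):
            acc = zero
            for l in range(1, n + 1):
                acc = acc + self.mass.get((c, l), zero)
                B[c][l] = B[c + 1][l] + acc
        return B

    # -- serialization -------------------------------------------------

    def _cell_str(self, v: Number) -> str:
        if self.representation == "rational":
            return f"{v.numerator}/{v.denominator}"
        return mpmath.nstr(v, 17)

    def to_frame(self) -> pd.DataFrame:
        """Wide table with rows C, columns L; rational cells as 'num/den'."""
        n = self.n_useful
        data = {l: [self._cell_str(self[(c, l)]) if (c, l) in self.mass else "0"
                    for c in range(n)]
                for l in range(1, n + 1)}
        return pd.DataFrame(data, index=pd.Index(range(n), name="C")).rename_axis(
            columns="L")

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)

    def to_json(self, path=None) -> str:
        payload = {
            "n_useful": self.n_useful,
            "shift": self.model.shift,
            "representation": self.representation,
            "mass": [{"c": c, "l": l, "p": self._cell_str(v)}
                     for c, l, v in self.cells()],
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, text: str, precision: int = DEFAULT_PRECISION) -> "JointDistribution":
        payload = json.loads(text)
        rep = payload["representation"]
        model = SuccessModel.from_shift(payload["shift"], precision)
        mass: dict[tuple[int, int], Number] = {}
        for cell in payload["mass"]:
            raw = cell["p"]
            value: Number
            if rep == "rational":
                num, den = raw.split("/")
                value = Fraction(int(num), int(den))
            else:
                with mpmath.workprec(precision):
                    value = mpmath.mpf(raw)
            mass[(cell["c"], cell["l"])] = value
        return cls(payload["n_useful"], model, mass, rep)


@dataclass(frozen=True)
class TimesMatrix:
    """Integer representation of the symmetric joint pmf: probability times
    ``2^(n-1)``, so every cell is a whole number of sequence pairs."""

    n_useful: int
    counts: Mapping[tuple[int, int], int]

    def __post_init__(self) -> None:
        total = sum(self.counts.values())
        if total != 2 ** (self.n_useful - 1):
            raise ArithmeticError(
                f"times counts sum to {total}, expected 2^{self.n_useful - 1}")

    def total(self) -> int:
        return 2 ** (self.n_useful - 1)

    def region_count(self, region: RegionLike) -> int:
        accepts = _accepts(region)
        return sum(v for (c, l), v in self.counts.items() if accepts(c, l))

    def to_frame(self) -> pd.DataFrame:
        n = self.n_useful
        data = {l: [self.counts.get((c, l), 0) for c in range(n)]
                for l in range(1, n + 1)}
        return pd.DataFrame(data, index=pd.Index(range(n), name="C")).rename_axis(
            columns="L")

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)


def _matrix_to_mass(n: int, M, rep: str, denom: int | None = None) -> dict:
    mass = {}
    for c in range(n):
        lo, hi = support_bounds(n, c)
        for l in range(lo, hi + 1):
            v = M[c][l]
            if rep == "rational":
                mass[(c, l)] = Fraction(2 * v, 2 ** n)  # both sides, exact
            else:
                mass[(c, l)] = v
    return mass


def joint_cl_distribution(n: int, model: SuccessModel,
                          precision: int | None = None) -> JointDistribution:
    """Exact joint pmf of (C, L) for an ``n``-point chart.

    Exact rational arithmetic when ``model`` is symmetric (p = 1/2);
    extended-precision floats otherwise (``precision`` bits of mantissa,
    defaulting to the model's own precision setting).
    """
    return joint_cl_distributions([n], model, precision)[n]


def joint_cl_distributions(n_values: Iterable[int], model: SuccessModel,
                           precision: int | None = None) -> dict[int, JointDistribution]:
    """Joint pmfs for several chart lengths from a single recursion pass.

    The first-run recursion builds every length up to ``max(n_values)``
    anyway, so requesting a whole range costs no more than its maximum.
    """
    ns = sorted(set(int(n) for n in n_values))
    if not ns:
        return {}
    if ns[0] < 1:
        raise ValueError(f"chart length must be >= 1, got {ns[0]}")
    n_max = ns[-1]
    out: dict[int, JointDistribution] = {}
    if model.is_symmetric:
        F = _count_matrices_half(n_max)
        for n in ns:
            out[n] = JointDistribution(n, model, _matrix_to_mass(n, F[n], "rational"),
                                       "rational")
    else:
        prec = precision if precision is not None else model.precision
        with mpmath.workprec(prec):
            p = +mpmath.mpf(model.p_above)
            M = _mass_matrices_general(n_max, p)
            for n in ns:
                out[n] = JointDistribution(n, model, _matrix_to_mass(n, M[n], "float"),
                                           "float")
    return out


def brute_force_joint(n: int, model: SuccessModel,
                      precision: int | None = None) -> JointDistribution:
    """Independent oracle: the joint pmf by enumerating all 2^n sequences.

    Each sequence is weighted ``p^(#above) * (1-p)^(#below)``; crossings
    and the longest run are counted directly.  Capped at n <= 16.
    """
    if n < 1:
        raise ValueError(f"chart length must be >= 1, got {n}")
    if n > BRUTE_FORCE_CAP:
        raise ValueError(f"brute force capped at n <= {BRUTE_FORCE_CAP}, got {n}")
    if model.is_symmetric:
        counts: dict[tuple[int, int], int] = {}
        for bits in range(2 ** n):
            c, l = _crossings_longest(bits, n)
            counts[(c, l)] = counts.get((c, l), 0) + 1
        mass = {k: Fraction(v, 2 ** n) for k, v in counts.items()}
        return JointDistribution(n, model, mass, "rational")
    prec = precision if precision is not None else model.precision
    with mpmath.workprec(prec):
        p = +mpmath.mpf(model.p_above)
        q = 1 - p
        wt = [q ** n]
        for a in range(1, n + 1):
            wt.append(wt[-1] / q * p)
        mass_f: dict[tuple[int, int], mpmath.mpf] = {}
        for bits in range(2 ** n):
            c, l = _crossings_longest(bits, n)
            w = wt[bits.bit_count()]
            key = (c, l)
            mass_f[key] = mass_f.get(key, mpmath.mpf(0)) + w
        return JointDistribution(n, model, mass_f, "float")


def _crossings_longest(bits: int, n: int) -> tuple[int, int]:
    c = 0
    longest = run = 1
    prev = bits & 1
    for i in range(1, n):
        cur = (bits >> i) & 1
        if cur == prev:
            run += 1
            if run > longest:
                longest = run
        else:
            c += 1
            run = 1
        prev = cur
    return c, longest


def times_representation(dist: JointDistribution) -> TimesMatrix:
    """Integer times matrix (probability x 2^(n-1)) of a symmetric pmf."""
    if dist.representation != "rational" or not dist.model.is_symmetric:
        raise ValueError("times representation requires the exact symmetric "
                         "(p = 1/2) distribution")
    scale = 2 ** (dist.n_useful - 1)
    counts = {}
    for c, l, v in dist.cells():
        scaled = v * scale
        if scaled.denominator != 1:
            raise ArithmeticError(f"cell ({c}, {l}) mass {v} is not a multiple "
                                  f"of 2^-(n-1)")
        counts[(c, l)] = scaled.numerator
    return TimesMatrix(dist.n_useful, counts)


def region_probability(dist: JointDistribution, region: RegionLike) -> Number:
    """Total mass of the cells where ``region`` holds (callable or object
    with ``.accepts(c, l)``)."""
    return dist.region_probability(region)
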