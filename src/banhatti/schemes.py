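"""Edge-weight schemes, index values and index polynomials.

Eight built-in degree-based weight functions phi(d1, d2), each defining a
topological index  I(G) = sum over edges of phi(deg u, deg v)  and an index
polynomial  I(G, x) = sum over edges of x**phi(deg u, deg v):

========  =============================  =========================
name      weight phi(d1, d2)             index
========  =============================  =========================
B1        d1 + d2                        first K-Banhatti
B2        d1 * d2                        second K-Banhatti
HB1       (d1 + d2)**2                   first hyper K-Banhatti
HB2       (d1 * d2)**2                   second hyper K-Banhatti
ReZG1     (d1 + d2) / (d1 * d2)          first redefined Zagreb
ReZG2     (d1 * d2) / (d1 + d2)          second redefined Zagreb
ReZG3     (d1 * d2) * (d1 + d2)          third redefined Zagreb
ABS       sqrt((d1+d2-2) / (d1+d2))      atom-bond sum-connectivity
========  =============================  =========================

The seven rational schemes are evaluated in exact rational arithmetic
(`fractions.Fraction`); ABS is evaluated in floating point, with an exact
symbolic surd available via :meth:`WeightScheme.exact_weight` for
verification.  All operations are scheme-generic: a user-defined scheme is
any symmetric positive function of the two endpoint degrees.
"""

from __future__ import annotations

import math
import warnings
from collections.abc import Callable, Mapping
from dataclasses import dataclass, field
from fractions import Fraction
from numbers import Real

import sympy

from .graph import EdgePartition, MolecularGraph

__all__ = [
    "SchemeDomainError",
    "WeightScheme",
    "SCHEMES",
    "SCHEME_NAMES",
    "get_scheme",
    "weight",
    "index_value",
    "index_value_from_graph",
    "IndexPolynomial",
    "index_polynomial",
    "all_indices",
]


class SchemeDomainError(ValueError):
    """A degree pair lies outside a weight scheme's domain."""


@dataclass(frozen=True)
class WeightScheme:
    """A named symmetric edge-weight function of the endpoint degrees.

    ``func`` returns the numeric weight (Fraction for rational schemes,
    float otherwise); ``exact_func`` returns the same weight as an exact
    sympy expression and defaults to ``sympy.nsimplify`` of the numeric one.
    ``domain`` may reject degree pairs (ABS rejects (1, 1), where the weight
    would be zero).
    """

    name: str
    func: Callable[[int, int], Real]
    exact_func: Callable[[int, int], sympy.Expr] | None = None
    domain: Callable[[int, int], bool] = field(default=lambda d1, d2: True)
    description: str = ""

    def _check(self, d1: int, d2: int) -> tuple[int, int]:
        d1, d2 = int(d1), int(d2)
        if d1 < 1 or d2 < 1:
            raise SchemeDomainError(f"{self.name}: degrees must be >= 1, got ({d1},{d2})")
        if not self.domain(d1, d2):
            raise SchemeDomainError(f"{self.name}: degree pair ({d1},{d2}) outside domain")
        return (min(d1, d2), max(d1, d2))

    def weight(self, d1: int, d2: int) -> Real:
        """Numeric weight; symmetric by canonicalization of the pair."""
        d1, d2 = self._check(d1, d2)
        return self.func(d1, d2)

    def exact_weight(self, d1: int, d2: int) -> sympy.Expr:
        """Weight as an exact sympy expression (rational or surd)."""
        d1, d2 = self._check(d1, d2)
        if self.exact_func is not None:
            return self.exact_func(d1, d2)
        value = self.func(d1, d2)
        if isinstance(value, Fraction):
            return sympy.Rational(value.numerator, value.denominator)
        return sympy.nsimplify(value)

    def in_domain(self, d1: int, d2: int) -> bool:
        try:
            self._check(d1, d2)
        except SchemeDomainError:
            return False
        return True

    def is_rational(self) -> bool:
        return isinstance(self.func(2, 3), Fraction)

    def scaled(self, factor: Real, name: str | None = None) -> "WeightScheme":
        """Same scheme with the weight multiplied by a positive constant."""
        if factor <= 0:
            raise SchemeDomainError("scale factor must be positive")
        return WeightScheme(
            name=name or f"{self.name}*{factor}",
            func=lambda d1, d2: self.func(d1, d2) * factor,
            domain=self.domain,
            description=f"{self.description} (scaled by {factor})",
        )

    @classmethod
    def from_function(
        cls, name: str, func: Callable[[int, int], Real], **kwargs
    ) -> "WeightScheme":
        """Wrap a user-supplied symmetric function of (d1, d2)."""
        return cls(name=name, func=func, **kwargs)


def _abs_ok(d1: int, d2: int) -> bool:
    return d1 + d2 > 2


SCHEMES: dict[str, WeightScheme] = {
    "B1": WeightScheme(
        "B1", lambda a, b: Fraction(a + b), description="first K-Banhatti: d1+d2"
    ),
    "B2": WeightScheme(
        "B2", lambda a, b: Fraction(a * b), description="second K-Banhatti: d1*d2"
    ),
    "HB1": WeightScheme(
        "HB1", lambda a, b: Fraction((a + b) ** 2),
        description="first hyper K-Banhatti: (d1+d2)^2",
    ),
    "HB2": WeightScheme(
        "HB2", lambda a, b: Fraction((a * b) ** 2),
        description="second hyper K-Banhatti: (d1*d2)^2",
    ),
    "ReZG1": WeightScheme(
        "ReZG1", lambda a, b: Fraction(a + b, a * b),
        description="first redefined Zagreb: (d1+d2)/(d1*d2)",
    ),
    "ReZG2": WeightScheme(
        "ReZG2", lambda a, b: Fraction(a * b, a + b),
        description="second redefined Zagreb: (d1*d2)/(d1+d2)",
    ),
    "ReZG3": WeightScheme(
        "ReZG3", lambda a, b: Fraction(a * b * (a + b)),
        description="third redefined Zagreb: (d1*d2)(d1+d2)",
    ),
    "ABS": WeightScheme(
        "ABS",
        lambda a, b: math.sqrt((a + b - 2) / (a + b)),
        exact_func=lambda a, b: sympy.sqrt(sympy.Rational(a + b - 2, a + b)),
        domain=_abs_ok,
        description="atom-bond sum-connectivity: sqrt((d1+d2-2)/(d1+d2))",
    ),
}

SCHEME_NAMES: tuple[str, ...] = tuple(SCHEMES)


def get_scheme(scheme: str | WeightScheme) -> WeightScheme:
    if isinstance(scheme, WeightScheme):
        return scheme
    try:
        return SCHEMES[scheme]
    except KeyError:
        raise SchemeDomainError(
            f"unknown scheme {scheme!r}; built-ins are {', '.join(SCHEME_NAMES)}"
        ) from None


def weight(scheme: str | WeightScheme, d1: int, d2: int) -> Real:
    """Edge weight phi(d1, d2) under a scheme."""
    return get_scheme(scheme).weight(d1, d2)


def index_value(partition: EdgePartition, scheme: str | WeightScheme) -> Real:
    """Index value  sum over classes of count * phi(d1, d2).

    Exact Fraction for the rational schemes, float for ABS.
    """
    sch = get_scheme(scheme)
    total: Real = Fraction(0) if sch.is_rational() else 0.0
    for (d1, d2), count in partition.items():
        total += count * sch.weight(d1, d2)
    return total


def index_value_from_graph(graph: MolecularGraph, scheme: str | WeightScheme) -> Real:
    """Brute-force route: sum the weight over every edge individually.

    Serves as the per-edge oracle against the partition-based
    :func:`index_value`; the two agree exactly for any valid graph.
    """
    sch = get_scheme(scheme)
    total: Real = Fraction(0) if sch.is_rational() else 0.0
    for u, v in graph.edges:
        total += sch.weight(graph.degree(u), graph.degree(v))
    return total


@dataclass(frozen=True)
class IndexPolynomial:
    """Sparse polynomial  sum of coeff * x**exponent  with exact exponents.

    Exponents are Fractions for rational schemes and exact sympy surds for
    ABS; coefficients are non-negative integers summing to the edge total of
    the source partition.  The derivative at x = 1 recovers the index value.
    """

    terms: Mapping = field(default_factory=dict)
    scheme_name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "terms", dict(self.terms))

    def coefficient_sum(self) -> int:
        return sum(self.terms.values())

    def derivative_at_one(self) -> Real:
        """sum coeff * exponent — equals the index value of the same partition."""
        total = 0
        for exponent, coeff in self.terms.items():
            total = total + coeff * exponent
        if isinstance(total, sympy.Expr):
            return total
        return total

    def __call__(self, x: Real) -> Real:
        return sum(coeff * x ** float(exponent) for exponent, coeff in self.terms.items())

    def items(self) -> list:
        return sorted(self.terms.items(), key=lambda kv: sympy.sympify(kv[0]))


def index_polynomial(
    partition: EdgePartition, scheme: str | WeightScheme
) -> IndexPolynomial:
    """Build the index polynomial, aggregating classes of equal weight.

    Rational schemes key terms by exact Fraction exponents; ABS keys them by
    exact sympy surds (irrational exponents are never merged through floats).
    """
    sch = get_scheme(scheme)
    terms: dict = {}
    for (d1, d2), count in partition.items():
        if count == 0:
            continue
        exponent = sch.weight(d1, d2) if sch.is_rational() else sch.exact_weight(d1, d2)
        terms[exponent] = terms.get(exponent, 0) + count
    return IndexPolynomial(terms=terms, scheme_name=sch.name)


def all_indices(
    partition: EdgePartition, schemes: tuple[str, ...] = SCHEME_NAMES
) -> dict[str, Real]:
    """All built-in index values for one partition.

    A scheme whose domain excludes a present class (ABS on (1,1)) is omitted
    with a warning rather than raising.
    """
    out: dict[str, Real] = {}
    for name in schemes:
        sch = get_scheme(name)
        bad = [pair for pair, c in partition.items() if c > 0 and not sch.in_domain(*pair)]
        if bad:
            warnings.warn(
                f"scheme {sch.name} skipped: class(es) {bad} outside its domain",
                stacklevel=2,
            )
            continue
        out[sch.name] = index_value(partition, sch)
    return out
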