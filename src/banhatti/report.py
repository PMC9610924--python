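"""Golden-table reproduction, discrepancy bookkeeping and the verification suite.

The published numeric tables for the two structure families are stored here
verbatim (commas stripped, printed precision preserved as strings) and
re-derived from the edge-partition models:

* the NbO2 table reproduces cell-for-cell from the partition sums — apart
  from three typographic errata recorded in :data:`NBO2_TABLE_ERRATA` — with
  the ABS column matching only under the documented table-variant weight set;
* the MOF table is reproducible only in its B2 and HB1 columns (and the
  (2,2) ReG1 cell); the remaining columns follow erroneous printed closed
  forms and are flagged against the symbolic ledger rather than reproduced.

:func:`run_verification_suite` wires every package invariant — handshake
identities, partition totals, closed-form/grid equality, the
derivative-at-one identity, per-edge oracle equivalence, entropy bounds and
invariances, and the golden tables — into one deterministic pass/fail report.
"""

from __future__ import annotations

import logging
import math
import random
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction

import pandas as pd
import sympy

from .entropy import entropy, entropy_from_graph, entropy_report_all
from .families import (
    FAMILIES,
    MOF,
    NBO2,
    S,
    T,
    FamilySpec,
    abs_table_variant_value,
    closed_form,
    compare_printed_forms,
    get_family,
    handshake_identity,
)
from .graph import EdgePartition, partition_to_graph, random_bounded_degree_graph, validate_handshake
from .schemes import (
    SCHEME_NAMES,
    get_scheme,
    index_polynomial,
    index_value,
    index_value_from_graph,
)

logger = logging.getLogger("banhatti")

__all__ = [
    "TABLE_COLUMNS", "COLUMN_TO_SCHEME", "PRINTED_TABLE_NBO2", "PRINTED_TABLE_MOF",
    "NBO2_TABLE_ERRATA", "EXPECTED_CLOSED_FORM_MISMATCHES", "MOF_REPRODUCIBLE_CELLS",
    "CellComparison", "reproduce_table", "golden_table_comparison",
    "CheckResult", "VerificationReport", "run_verification_suite",
]

#: Column order of the published tables.
TABLE_COLUMNS: tuple[str, ...] = ("B1", "B2", "HB1", "HB2", "ReG1", "ReG2", "ReG3", "ABS")

#: Published column name -> scheme registry name.
COLUMN_TO_SCHEME: dict[str, str] = {
    "B1": "B1", "B2": "B2", "HB1": "HB1", "HB2": "HB2",
    "ReG1": "ReZG1", "ReG2": "ReZG2", "ReG3": "ReZG3", "ABS": "ABS",
}

#: Published NbO2 index table, diagonal grid (2,2)..(12,12), printed precision
#: preserved (thousands separators stripped).
PRINTED_TABLE_NBO2: dict[tuple[int, int], dict[str, str]] = {
    (2, 2): {"B1": "552", "B2": "872", "HB1": "3528", "HB2": "9320",
             "ReG1": "58", "ReG2": "136.34", "ReG3": "5680", "ABS": "75.920117"},
    (3, 3): {"B1": "1180", "B2": "1944", "HB1": "7860", "HB2": "22344",
             "ReG1": "113", "ReG2": "291.77", "ReG3": "13152", "ABS": "160.400806"},
    (4, 4): {"B1": "2040", "B2": "3432", "HB1": "13880", "HB2": "408872",
             "ReG1": "186", "ReG2": "504.34", "ReG3": "23664", "ABS": "275.748201"},
    (5, 5): {"B1": "3132", "B2": "5336", "HB1": "21588", "HB2": "64904",
             "ReG1": "277", "ReG2": "774.058", "ReG3": "37216", "ABS": "421.962304"},
    (6, 6): {"B1": "4456", "B2": "7656", "HB1": "30984", "HB2": "94440",
             "ReG1": "386", "ReG2": "1100.91", "ReG3": "53808", "ABS": "599.043115"},
    (7, 7): {"B1": "6012", "B2": "10392", "HB1": "42068", "HB2": "129480",
             "ReG1": "513", "ReG2": "1484.9", "ReG3": "73440", "ABS": "806.990632"},
    (8, 8): {"B1": "7800", "B2": "13544", "HB1": "54840", "HB2": "170024",
             "ReG1": "658", "ReG2": "1926.1", "ReG3": "96112", "ABS": "1045.804857"},
    (9, 9): {"B1": "9820", "B2": "17112", "HB1": "69300", "HB2": "216072",
             "ReG1": "821", "ReG2": "2424.3", "ReG3": "121824", "ABS": "1315.48579"},
    (10, 10): {"B1": "12072", "B2": "21096", "HB1": "85448", "HB2": "267624",
               "ReG1": "1002", "ReG2": "2979.7", "ReG3": "150576", "ABS": "1616.03343"},
    (11, 11): {"B1": "14556", "B2": "25496", "HB1": "103284", "HB2": "324680",
               "ReG1": "1201", "ReG2": "3592.3", "ReG3": "182368", "ABS": "1947.447777"},
    (12, 12): {"B1": "17272", "B2": "30312", "HB1": "122808", "HB2": "387240",
               "ReG1": "1418", "ReG2": "4262.1", "ReG3": "217200", "ABS": "2309.728831"},
}

#: Published MOF table, diagonal grid (2,2)..(12,12).
PRINTED_TABLE_MOF: dict[tuple[int, int], dict[str, str]] = {
    (2, 2): {"B1": "1868", "B2": "2529", "HB1": "10542", "HB2": "21573",
             "ReG1": "296", "ReG2": "307.03", "ReG3": "14832", "ABS": "27339.22"},
    (3, 3): {"B1": "4264", "B2": "5793", "HB1": "24122", "HB2": "49725",
             "ReG1": "444", "ReG2": "700.71", "ReG3": "34008", "ABS": "27686.67"},
    (4, 4): {"B1": "7636", "B2": "10401", "HB1": "43286", "HB2": "89685",
             "ReG1": "592", "ReG2": "1256.40", "ReG3": "61152", "ABS": "28173.03"},
    (5, 5): {"B1": "11984", "B2": "16353", "HB1": "68034", "HB2": "141453",
             "ReG1": "740", "ReG2": "1974.09", "ReG3": "96264", "ABS": "28798.29"},
    (6, 6): {"B1": "17308", "B2": "23649", "HB1": "98366", "HB2": "205029",
             "ReG1": "888", "ReG2": "2853.77", "ReG3": "139344", "ABS": "29562.45"},
    (7, 7): {"B1": "23608", "B2": "32289", "HB1": "134282", "HB2": "280413",
             "ReG1": "1036", "ReG2": "3895.46", "ReG3": "190392", "ABS": "30465.50"},
    (8, 8): {"B1": "30884", "B2": "42273", "HB1": "175782", "HB2": "367605",
             "ReG1": "1184", "ReG2": "5099.14", "ReG3": "249408", "ABS": "31507.46"},
    (9, 9): {"B1": "39136", "B2": "53601", "HB1": "222866", "HB2": "466605",
             "ReG1": "1332", "ReG2": "6464.83", "ReG3": "316392", "ABS": "32688.32"},
    (10, 10): {"B1": "48364", "B2": "66273", "HB1": "275534", "HB2": "577413",
               "ReG1": "1480", "ReG2": "7992.51", "ReG3": "391344", "ABS": "34008.08"},
    (11, 11): {"B1": "58568", "B2": "80289", "HB1": "333786", "HB2": "700029",
               "ReG1": "1628", "ReG2": "9682.20", "ReG3": "474264", "ABS": "35466.73"},
    (12, 12): {"B1": "69748", "B2": "95649", "HB1": "397622", "HB2": "834453",
               "ReG1": "1776", "ReG2": "11533.89", "ReG3": "565152", "ABS": "37064.29"},
}

#: NbO2 table cells that do not reproduce because of typographic errata in
#: the published table: cell -> (computed value as printed here, explanation).
NBO2_TABLE_ERRATA: dict[tuple[int, int, str], tuple[str, str]] = {
    (4, 4, "HB2"): ("40872", "printed 408,872; misplaced comma for 40,872"),
    (5, 5, "ReG2"): ("774.06", "printed 774.058; exact value 27092/35 = 774.0571..."),
    (10, 10, "ReG2"): ("2979.77", "printed 2979.7; exact value 104292/35 = 2979.7714..."),
}

#: Expected symbolic-ledger verdicts: (family, scheme) pairs whose printed
#: closed form disagrees with the exact expansion of the class counts.
EXPECTED_CLOSED_FORM_MISMATCHES: frozenset[tuple[str, str]] = frozenset({
    ("NbO2", "ReZG2"), ("NbO2", "ReZG3"), ("NbO2", "ABS"),
    ("MOF", "B1"), ("MOF", "HB2"), ("MOF", "ReZG1"),
    ("MOF", "ReZG2"), ("MOF", "ReZG3"),
})

#: MOF table cells that DO reproduce from the partition: the B2 and HB1
#: columns everywhere, plus ReG1 at (2,2) (the one cell where the published
#: linear-in-s sequence coincides with the quadratic 74st).
MOF_REPRODUCIBLE_CELLS: frozenset[tuple[int, int, str]] = frozenset(
    {(s, s, col) for s in range(2, 13) for col in ("B2", "HB1")} | {(2, 2, "ReG1")}
)


def _round_half_up(value: Fraction | float, decimals: int = 2) -> Decimal:
    quantum = Decimal(1).scaleb(-decimals)
    if isinstance(value, Fraction):
        dec = Decimal(value.numerator) / Decimal(value.denominator)
    else:
        dec = Decimal(repr(float(value)))
    return dec.quantize(quantum, rounding=ROUND_HALF_UP)


def _compute_cell(partition: EdgePartition, column: str, s: int, t: int,
                  family_name: str, abs_mode: str) -> Fraction | float:
    if column == "ABS" and abs_mode == "table_variant":
        if family_name != "NbO2":
            raise ValueError("the ABS table-variant weights are defined for NbO2 only")
        return abs_table_variant_value(s, t)
    return index_value(partition, COLUMN_TO_SCHEME[column])


@dataclass(frozen=True)
class CellComparison:
    """One table cell: computed-from-partition value vs the printed one."""

    s: int
    t: int
    column: str
    computed: str
    printed: str
    match: bool
    known_erratum: bool = False
    note: str = ""


def reproduce_table(
    family: str | FamilySpec,
    grid: list[tuple[int, int]],
    abs_mode: str = "standard",
) -> pd.DataFrame:
    """Recompute the published index table on a parameter grid.

    One row per (s, t) with the eight descriptor columns in published order.
    Integer-valued cells are exact integers; fractional ones are printed
    rounded half-up to 2 decimals with the exact rational retained in a
    companion ``*_exact`` column.  ``abs_mode`` selects the standard ABS
    weights or, for NbO2, the documented table-variant replication weights.
    """
    if abs_mode not in {"standard", "table_variant"}:
        raise ValueError(f"unknown abs_mode {abs_mode!r}")
    fam = get_family(family)
    rows = []
    for s, t in grid:
        partition = fam.partition(s, t)
        row: dict[str, object] = {"s": s, "t": t}
        for column in TABLE_COLUMNS:
            value = _compute_cell(partition, column, s, t, fam.name, abs_mode)
            if isinstance(value, Fraction):
                if value.denominator == 1:
                    row[column] = int(value)
                else:
                    row[column] = float(_round_half_up(value, 2))
                    row[f"{column}_exact"] = f"{value.numerator}/{value.denominator}"
            else:
                row[column] = float(value)
        rows.append(row)
    frame = pd.DataFrame(rows)
    lead = ["s", "t", *TABLE_COLUMNS]
    extras = [c for c in frame.columns if c not in lead]
    return frame[lead + extras] if rows else pd.DataFrame(columns=lead)


def golden_table_comparison(
    family: str | FamilySpec, abs_mode: str = "table_variant"
) -> list[CellComparison]:
    """Compare every published table cell with the partition-derived value.

    A cell matches when the computed value agrees with the printed one at the
    printed precision (half-unit-in-the-last-place tolerance; exact equality
    for integer cells).  Known NbO2 errata are annotated, not silently passed.
    """
    fam = get_family(family)
    printed_table = PRINTED_TABLE_NBO2 if fam.name == "NbO2" else PRINTED_TABLE_MOF
    out: list[CellComparison] = []
    for (s, t), row in sorted(printed_table.items()):
        partition = fam.partition(s, t)
        for column in TABLE_COLUMNS:
            mode = abs_mode if fam.name == "NbO2" else "standard"
            value = _compute_cell(partition, column, s, t, fam.name, mode)
            printed = row[column]
            if "." in printed:
                decimals = len(printed.split(".")[1])
                tol = Decimal(5).scaleb(-(decimals + 1))
                computed_dec = _round_half_up(value, decimals)
                match = abs(computed_dec - Decimal(printed)) <= tol
                computed_str = str(computed_dec)
            else:
                if isinstance(value, Fraction) and value.denominator == 1:
                    computed_str = str(int(value))
                    match = int(value) == int(printed)
                else:
                    computed_str = str(_round_half_up(value, 6))
                    match = False
            key = (s, t, column)
            erratum = fam.name == "NbO2" and key in NBO2_TABLE_ERRATA
            note = NBO2_TABLE_ERRATA[key][1] if erratum else ""
            if erratum and not match:
                logger.warning("documented erratum at %s %s: %s", fam.name, key, note)
            out.append(CellComparison(s, t, column, computed_str, printed, match,
                                      known_erratum=erratum, note=note))
    return out


# ---------------------------------------------------------------------------
# verification suite

@dataclass(frozen=True)
class CheckResult:
    name: str
    passed: bool
    detail: str = ""


@dataclass
class VerificationReport:
    checks: list[CheckResult] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return all(c.passed for c in self.checks)

    def summary(self) -> str:
        lines = [f"{'PASS' if c.passed else 'FAIL'}  {c.name}: {c.detail}"
                 for c in self.checks]
        lines.append(f"{'ALL CHECKS PASS' if self.passed else 'FAILURES PRESENT'} "
                     f"({sum(c.passed for c in self.checks)}/{len(self.checks)})")
        return "\n".join(lines)


def run_verification_suite(
    base: float = math.e,
    nbo2: FamilySpec = NBO2,
    mof: FamilySpec = MOF,
    oracle_seeds: tuple[int, ...] = tuple(range(1, 21)),
    grid_max: int = 6,
) -> VerificationReport:
    """Deterministic end-to-end verification of every package invariant.

    Covers: the NbO2 symbolic handshake identity, both families' partition
    totals, closed-form/partition equality on the integer grid, the
    polynomial derivative-at-one identity, per-edge oracle equivalence on
    seeded random fixtures, entropy bounds / base-change / scale invariance /
    formulation equivalence, golden-table reproduction (documented errata
    reported as expected, with a WARN), and the closed-form discrepancy
    ledger.  Injecting a corrupted family spec makes the affected checks fail
    (negative control).
    """
    report = VerificationReport()
    grid = [(s, t) for s in range(1, grid_max + 1) for t in range(1, grid_max + 1)]
    rational = [n for n in SCHEME_NAMES if n != "ABS"]

    def add(name: str, passed: bool, detail: str) -> None:
        (logger.info if passed else logger.warning)("%s: %s (%s)", name,
                                                    "pass" if passed else "FAIL", detail)
        report.checks.append(CheckResult(name, passed, detail))

    # 1. symbolic handshake for NbO2 + evaluation on the grid
    try:
        deg_side, edge_side, sym_ok = handshake_identity(nbo2)
        grid_ok = all(
            sum(d * n for d, n in nbo2.vertex_classes(s, t).items())
            == 2 * nbo2.partition(s, t).edge_total
            for s, t in grid
        )
        add("nbo2_handshake_identity", sym_ok and grid_ok,
            f"sum d*n_d = {deg_side} vs 2|E| = {edge_side}")
    except Exception as exc:  # corrupted spec may lack vertex classes
        add("nbo2_handshake_identity", False, f"error: {exc}")

    # 2. partition totals as polynomial identities
    for fam in (nbo2, mof):
        diff = sympy.expand(sum(fam.class_exprs.values()) - fam.bond_total_expr)
        add(f"{fam.name.lower()}_partition_total", diff == 0,
        f"sum of class counts - stated bond total = {diff}")

    # 3. closed forms equal partition sums on the grid, exactly
    for fam in (nbo2, mof):
        bad = []
        forms = {n: closed_form(fam, n) for n in rational}
        for s, t in grid:
            partition = fam.partition(s, t)
            for n in rational:
                expected = index_value(partition, n)
                got = forms[n].subs({S: s, T: t})
                if sympy.Rational(expected.numerator, expected.denominator) != got:
                    bad.append((s, t, n))
        add(f"{fam.name.lower()}_closed_form_grid", not bad,
            f"{len(grid) * len(rational)} evaluations, {len(bad)} disagreements")

    # 4. derivative-at-one identity
    bad = []
    for fam in (nbo2, mof):
        for s, t in [(1, 1), (2, 2), (2, 5), (grid_max, grid_max)]:
            partition = fam.partition(s, t)
            for name in SCHEME_NAMES:
                sch = get_scheme(name)
                if not all(sch.in_domain(*p) for p, c in partition.items() if c > 0):
                    continue
                poly = index_polynomial(partition, sch)
                deriv = poly.derivative_at_one()
                value = index_value(partition, sch)
                if sch.is_rational():
                    ok = deriv == value
                else:
                    ok = abs(float(deriv) - float(value)) <= 1e-10 * max(1.0, abs(float(value)))
                if not ok:
                    bad.append((fam.name, s, t, name))
    add("derivative_at_one_identity", not bad, f"{len(bad)} failures")

    # 5. oracle equivalence on seeded random fixtures (index + entropy)
    bad = []
    for seed in oracle_seeds:
        graph = random_bounded_degree_graph(60, 4, seed)
        partition = graph.degree_pair_partition()
        if partition.edge_total == 0:
            continue
        hs = validate_handshake(graph)
        if not hs.passed:
            bad.append((seed, "handshake"))
        for name in SCHEME_NAMES:
            sch = get_scheme(name)
            if not all(sch.in_domain(*p) for p, c in partition.items() if c > 0):
                continue
            via_graph = index_value_from_graph(graph, sch)
            via_partition = index_value(partition, sch)
            if sch.is_rational():
                ok = via_graph == via_partition
            else:
                ok = math.isclose(via_graph, via_partition, rel_tol=0, abs_tol=1e-10)
            if not ok:
                bad.append((seed, name, "index"))
            e1 = entropy_from_graph(graph, sch, base=base).value
            e2 = entropy(partition, sch, base=base).value
            if not math.isclose(e1, e2, rel_tol=0, abs_tol=1e-10):
                bad.append((seed, name, "entropy"))
    add("oracle_equivalence", not bad,
        f"{len(oracle_seeds)} seeded fixtures, {len(bad)} disagreements")

    # 6. entropy bounds + formulation equivalence on family partitions
    bad = []
    for fam in (nbo2, mof):
        for s, t in grid:
            partition = fam.partition(s, t).canonical()
            m = partition.edge_total
            reports = entropy_report_all(partition, base=base)
            for name, rep in reports.items():
                if not (-1e-12 <= rep.value <= rep.max_entropy + 1e-12):
                    bad.append((fam.name, s, t, name, "bound"))
                # direct -sum p log p over an explicit per-edge weight list
                sch = get_scheme(name)
                weights = [float(sch.weight(*pair))
                           for pair, c in partition.items() for _ in range(c)]
                total = sum(weights)
                direct = -sum(w / total * math.log(w / total) for w in weights)
                if not math.isclose(rep.value, direct / math.log(base),
                                    rel_tol=0, abs_tol=1e-10):
                    bad.append((fam.name, s, t, name, "formulation"))
    add("entropy_bounds_and_formulation", not bad, f"{len(bad)} failures")

    # 7. base-change, scale invariance, uniform-weight equality
    bad = []
    probe = nbo2.partition(2, 3)
    uniform = EdgePartition({(3, 3): 17})
    for name in SCHEME_NAMES:
        nat = entropy(probe, name).value
        for b in (2.0, 10.0):
            if not math.isclose(entropy(probe, name, base=b).value, nat / math.log(b),
                                rel_tol=0, abs_tol=1e-12):
                bad.append((name, b, "base"))
        scaled = get_scheme(name).scaled(Fraction(7, 3) if get_scheme(name).is_rational() else 7 / 3)
        if not math.isclose(entropy(probe, scaled).value, nat, rel_tol=0, abs_tol=1e-10):
            bad.append((name, "scale"))
        rep = entropy(uniform, name)
        if not math.isclose(rep.value, rep.max_entropy, rel_tol=0, abs_tol=1e-12):
            bad.append((name, "uniform"))
    add("entropy_base_scale_uniform", not bad, f"{len(bad)} failures")

    # 8/9. golden tables
    if nbo2 is NBO2:
        cells = golden_table_comparison("NbO2", abs_mode="table_variant")
        unexpected = [c for c in cells if not c.match and not c.known_erratum]
        missed_errata = [c for c in cells if c.known_erratum and c.match]
        add("golden_table_nbo2",
            not unexpected and not missed_errata,
            f"{len(cells)} cells; {len(unexpected)} unexpected mismatches; "
            f"{sum(1 for c in cells if c.known_erratum)} documented errata")
        cells = golden_table_comparison("MOF")
        got = {(c.s, c.t, c.column) for c in cells if c.match}
        add("golden_table_mof", got == set(MOF_REPRODUCIBLE_CELLS),
            f"reproducible cells {len(got)}/88, expected {len(MOF_REPRODUCIBLE_CELLS)}")

    # 10. closed-form discrepancy ledger
    verdicts = {
        (c.family, c.scheme): c
        for fam in (nbo2, mof)
        for c in compare_printed_forms(fam)
    }
    mismatches = {k for k, c in verdicts.items() if not c.match}
    ok = mismatches == set(EXPECTED_CLOSED_FORM_MISMATCHES)
    for key in sorted(mismatches):
        logger.warning("expected erratum — printed closed form differs for %s/%s: %s",
                       key[0], key[1], verdicts[key].difference)
    add("closed_form_ledger", ok,
        f"{len(mismatches)} mismatches "
        f"({'as expected' if ok else 'UNEXPECTED set: ' + str(sorted(mismatches))})")

    # partition realization round-trip on a small fixture
    try:
        fixture = partition_to_graph(nbo2.partition(1, 1), seed=oracle_seeds[0])
        ok = fixture.degree_pair_partition() == nbo2.partition(1, 1)
        add("partition_realization_roundtrip", ok,
            f"{fixture.num_edges}-edge realization round-trips: {ok}")
    except Exception as exc:
        add("partition_realization_roundtrip", False, f"error: {exc}")

    return report
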