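"""Taxon x elongation-factor presence/absence tables and association testing.

The central object is a :class:`FactorTable`: one row per taxon, one
three-valued state (present / divergent / absent) for each of the three
factors eEF1A, eEF1Balpha and EFL.  Divergent means a recognisable but
degrading homolog — a gene caught in the act of loss — and every analysis is
run under both conventions for it (counted as present, counted as absent).

The association between EFL presence and retention of the eEF1A:eEF1Balpha
system is assessed with a two-sided Fisher exact test computed here from the
hypergeometric mass function (minimum-likelihood rule), so that the test
itself is open to independent verification by enumeration.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.special import gammaln

__all__ = [
    "State",
    "Convention",
    "Comparison",
    "FactorTable",
    "AssociationResult",
    "read_factor_table",
    "parse_factor_table",
    "binarize",
    "contingency",
    "exact_association_test",
    "association_report",
    "FactorTableError",
]

FACTORS = ("eEF1A", "eEF1Ba", "EFL")

#: accepted spellings for the GEF subunit column header
_EEF1BA_ALIASES = {"eef1ba", "eef1balpha", "eef1bα", "eef1bα"}


class FactorTableError(ValueError):
    """Raised for malformed factor-table input."""


class State(enum.Enum):
    PRESENT = "present"
    DIVERGENT = "divergent"
    ABSENT = "absent"


class Convention(enum.Enum):
    """How a DIVERGENT (degrading) gene is scored in binary analyses."""

    DIVERGENT_AS_PRESENT = "present"
    DIVERGENT_AS_ABSENT = "absent"


class Comparison(enum.Enum):
    """Which factor (or conjunction) EFL presence is tabulated against."""

    EFL_VS_EEF1A = "eEF1A"
    EFL_VS_EEF1BA = "eEF1Ba"
    EFL_VS_BOTH = "both"


_STATE_TOKENS = {
    "present": State.PRESENT,
    "divergent": State.DIVERGENT,
    "absent": State.ABSENT,
    "1": State.PRESENT,
    "0.5": State.DIVERGENT,
    "0": State.ABSENT,
}


@dataclass
class FactorTable:
    """Ordered taxon x {eEF1A, eEF1Balpha, EFL} state matrix.

    ``states[i]`` is the (eEF1A, eEF1Balpha, EFL) triple for ``taxa[i]``;
    ``lineage[i]`` is an optional group label (e.g. "Fungi").
    """

    taxa: list[str]
    states: list[tuple[State, State, State]]
    lineage: list[str | None] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.lineage:
            self.lineage = [None] * len(self.taxa)
        if not (len(self.taxa) == len(self.states) == len(self.lineage)):
            raise FactorTableError("taxa, states and lineage lengths differ")
        seen: set[str] = set()
        for t in self.taxa:
            key = " ".join(t.split())
            if key in seen:
                raise FactorTableError(f"duplicate taxon {t!r}")
            seen.add(key)
        for t, triple in zip(self.taxa, self.states):
            if len(triple) != 3 or any(not isinstance(s, State) for s in triple):
                raise FactorTableError(f"bad state triple for taxon {t!r}")

    def __len__(self) -> int:
        return len(self.taxa)

    def collapse_by_lineage(self) -> "FactorTable":
        """Reduce each lineage label to one majority-state pseudo-taxon.

        Taxa without a lineage label are kept as-is.  Majority is per factor;
        ties resolve in the order present > divergent > absent.
        """
        order = [State.PRESENT, State.DIVERGENT, State.ABSENT]
        groups: dict[str, list[tuple[State, State, State]]] = {}
        taxa, states, lineages = [], [], []
        for t, s, g in zip(self.taxa, self.states, self.lineage):
            if g is None:
                taxa.append(t)
                states.append(s)
                lineages.append(None)
            else:
                groups.setdefault(g, []).append(s)
        for g, rows in groups.items():
            triple = []
            for k in range(3):
                counts = {st: sum(1 for r in rows if r[k] is st) for st in order}
                triple.append(max(order, key=lambda st: (counts[st], -order.index(st))))
            taxa.append(g)
            states.append(tuple(triple))
            lineages.append(g)
        return FactorTable(taxa=taxa, states=states, lineage=lineages)


def parse_factor_table(lines: Iterable[str], source: str = "<string>") -> FactorTable:
    """Parse TSV lines into a validated :class:`FactorTable`.

    Header names the three factors ("eEF1Ba"/"eEF1Balpha" accepted for the
    Greek-lettered subunit); an optional ``lineage`` column may precede them.
    State tokens are case-insensitive {present, divergent, absent} or
    {1, 0.5, 0}.
    """
    rows = [ln.rstrip("\n") for ln in lines]
    rows = [r for r in rows if r.strip() and not r.lstrip().startswith("#")]
    if not rows:
        raise FactorTableError(f"{source}: empty factor table")
    header = [h.strip() for h in rows[0].split("\t")]
    cols = {}
    for i, h in enumerate(header):
        low = h.lower()
        if low == "eef1a":
            cols["eEF1A"] = i
        elif low in _EEF1BA_ALIASES:
            cols["eEF1Ba"] = i
        elif low == "efl":
            cols["EFL"] = i
        elif low == "lineage":
            cols["lineage"] = i
        elif low == "taxon":
            cols["taxon"] = i
    missing = [f for f in FACTORS if f not in cols]
    if missing:
        raise FactorTableError(f"{source}: header missing factor column(s) {missing}")
    taxon_col = cols.get("taxon", 0)

    taxa, states, lineage = [], [], []
    for lineno, row in enumerate(rows[1:], start=2):
        fields = [f.strip() for f in row.split("\t")]
        if len(fields) <= max(cols.values()):
            raise FactorTableError(f"{source}:{lineno}: too few columns")
        taxon = fields[taxon_col]
        triple = []
        for fac in FACTORS:
            tok = fields[cols[fac]].lower()
            if tok not in _STATE_TOKENS:
                raise FactorTableError(
                    f"{source}:{lineno}: unknown state token {tok!r} in column {fac}"
                )
            triple.append(_STATE_TOKENS[tok])
        taxa.append(taxon)
        states.append(tuple(triple))
        lineage.append(fields[cols["lineage"]] or None if "lineage" in cols else None)
    return FactorTable(taxa=taxa, states=states, lineage=lineage)


def read_factor_table(path) -> FactorTable:
    """Load a factor table from a TSV file."""
    with open(path, encoding="utf-8") as fh:
        return parse_factor_table(fh, source=str(path))


def binarize(
    table: FactorTable, convention: Convention
) -> list[tuple[bool, bool, bool]]:
    """Map three-valued states to booleans under a divergent-handling rule."""
    as_present = convention is Convention.DIVERGENT_AS_PRESENT

    def b(s: State) -> bool:
        if s is State.PRESENT:
            return True
        if s is State.ABSENT:
            return False
        return as_present

    return [tuple(b(s) for s in triple) for triple in table.states]


def contingency(
    table: FactorTable, convention: Convention, comparison: Comparison
) -> np.ndarray:
    """2x2 counts: rows EFL present/absent, columns comparison factor(s) present/absent.

    ``EFL_VS_BOTH`` scores the column as present only when eEF1A AND
    eEF1Balpha are both present.
    """
    if len(table) == 0:
        raise FactorTableError("contingency of an empty table")
    counts = np.zeros((2, 2), dtype=int)
    for a, b_, efl in binarize(table, convention):
        if comparison is Comparison.EFL_VS_EEF1A:
            other = a
        elif comparison is Comparison.EFL_VS_EEF1BA:
            other = b_
        else:
            other = a and b_
        counts[0 if efl else 1, 0 if other else 1] += 1
    return counts


@dataclass
class AssociationResult:
    convention: Convention
    comparison: Comparison
    table: np.ndarray
    p_two_sided: float
    odds_ratio: float
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "convention": self.convention.name,
            "comparison": self.comparison.name,
            "table": [[int(x) for x in row] for row in self.table],
            "p_two_sided": self.p_two_sided,
            "odds_ratio": self.odds_ratio,
            "degenerate": self.degenerate,
        }


# relative tolerance for the minimum-likelihood tie rule: a table whose point
# probability exceeds the observed one by at most this factor still counts as
# "as extreme"
_TIE_RTOL = 1e-12


def _log_hypergeom_pmf(x: np.ndarray, r1: int, r2: int, c1: int) -> np.ndarray:
    """log P(X = x) for X ~ Hypergeom with margins (r1, r2 | c1, c2).

    Computed from log-gamma so tables with n > 170 do not overflow.
    """
    n = r1 + r2
    return (
        gammaln(r1 + 1)
        - gammaln(x + 1)
        - gammaln(r1 - x + 1)
        + gammaln(r2 + 1)
        - gammaln(c1 - x + 1)
        - gammaln(r2 - (c1 - x) + 1)
        - (gammaln(n + 1) - gammaln(c1 + 1) - gammaln(n - c1 + 1))
    )


def exact_association_test(
    counts,
    convention: Convention | None = None,
    comparison: Comparison | None = None,
) -> AssociationResult:
    """Two-sided Fisher exact test on a 2x2 table, minimum-likelihood rule.

    p is the sum of hypergeometric probabilities, over all tables sharing the
    observed margins, of those tables whose point probability does not exceed
    the observed table's (to relative tolerance 1e-12).  The odds ratio is
    ad/bc, infinite when bc = 0 with a, d > 0.  A table with any zero margin
    carries no information: p = 1 with the degenerate flag set.
    """
    counts = np.asarray(counts, dtype=int)
    if counts.shape != (2, 2) or (counts < 0).any():
        raise ValueError("counts must be a nonnegative 2x2 table")
    a, b = int(counts[0, 0]), int(counts[0, 1])
    c, d = int(counts[1, 0]), int(counts[1, 1])
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d

    if b * c == 0:
        odds = math.inf if (a > 0 and d > 0) else math.nan
    else:
        odds = (a * d) / (b * c)
    if a * d == 0 and b * c > 0:
        odds = 0.0

    if min(r1, r2, c1, c2) == 0:
        return AssociationResult(convention, comparison, counts, 1.0, odds, True)

    lo, hi = max(0, c1 - r2), min(r1, c1)
    support = np.arange(lo, hi + 1)
    logpmf = _log_hypergeom_pmf(support, r1, r2, c1)
    log_obs = float(logpmf[a - lo])
    keep = logpmf <= log_obs + math.log1p(_TIE_RTOL)
    # log-sum-exp over the kept tables
    m = float(np.max(logpmf[keep]))
    p = float(math.exp(m) * np.sum(np.exp(logpmf[keep] - m)))
    p = min(p, 1.0)
    return AssociationResult(convention, comparison, counts, p, odds, False)


def association_report(
    table: FactorTable, collapse_by_lineage: bool = False
) -> list[AssociationResult]:
    """All 3 comparisons under both divergent conventions: 6 results."""
    if collapse_by_lineage:
        table = table.collapse_by_lineage()
    results = []
    for conv in Convention:
        for comp in Comparison:
            counts = contingency(table, conv, comp)
            results.append(exact_association_test(counts, conv, comp))
    return results


def report_to_tsv(results: Sequence[AssociationResult]) -> str:
    lines = ["convention\tcomparison\ta\tb\tc\td\tp_two_sided\todds_ratio\tdegenerate"]
    for r in results:
        (a, b), (c, d) = r.table
        lines.append(
            f"{r.convention.name}\t{r.comparison.name}\t{a}\t{b}\t{c}\t{d}"
            f"\t{r.p_two_sided:.6g}\t{r.odds_ratio:.6g}\t{int(r.degenerate)}"
        )
    return "\n".join(lines) + "\n"


def report_to_json(results: Sequence[AssociationResult]) -> str:
    return json.dumps([r.to_dict() for r in results], indent=2)
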