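"""Tiered consensus calling and differential-conservation profiling.

Two protein families — here eEF1A (family A) and its GEF-independent paralog
EFL (family B) — share one alignment column space.  For each family a tiered
consensus string is computed: an uppercase residue marks a column where one
residue reaches the high conservation threshold (70% by default), a lowercase
residue marks a plurality residue between the low and high thresholds, ``.``
marks an unconserved column and ``-`` a column dominated by gaps.  Comparing
the two consensus profiles column by column classifies sites into the
categories used for differential-conservation maps: strongly differentially
conserved (conserved in both families but as different residues),
conserved-in-one-family-only, identically conserved, unconserved, and indel
columns, from which conserved insertion/deletion runs and C-terminal
extensions are derived.

Conservation fractions use ALL family sequences as denominator, gaps
included: a column that is half gaps can never reach a 70% residue consensus.
``X`` (unknown residue) likewise counts toward the denominator but can never
be the consensus letter.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

__all__ = [
    "AMINO_ACIDS",
    "CHEMICAL_CLASSES",
    "LabelledAlignment",
    "ConsensusProfile",
    "SiteCategory",
    "SiteClassification",
    "IndelRun",
    "IndelReport",
    "AlignmentError",
    "read_alignment",
    "consensus",
    "classify_sites",
    "chemical_difference",
    "detect_indels",
    "map_column",
    "cterm_extension",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_ALPHABET = set(AMINO_ACIDS) | {"X", "-"}

#: Fixed 7-group chemical partition of the 20 residues: aliphatic/thioether,
#: aromatic, polar uncharged, basic, acidic, and glycine and proline each as
#: their own class (their backbone behaviour is unlike any other residue).
CHEMICAL_CLASSES = ("AVLIMC", "FWYH", "STNQ", "KR", "DE", "G", "P")
_CLASS_OF = {aa: i for i, grp in enumerate(CHEMICAL_CLASSES) for aa in grp}


class AlignmentError(ValueError):
    """Raised for malformed alignment input."""


@dataclass
class LabelledAlignment:
    """Equal-length aligned protein sequences, each labelled A or B."""

    ids: list[str]
    sequences: list[str]
    families: list[str]  # "A" or "B" per sequence

    def __post_init__(self) -> None:
        if len({len(s) for s in self.sequences}) > 1:
            lens = {i: len(s) for i, s in zip(self.ids, self.sequences)}
            raise AlignmentError(f"ragged alignment: row lengths {sorted(set(lens.values()))}")
        if not self.sequences or len(self.sequences[0]) == 0:
            raise AlignmentError("empty alignment")
        if len(set(self.ids)) != len(self.ids):
            raise AlignmentError("duplicate sequence ids")
        for sid, seq in zip(self.ids, self.sequences):
            bad = set(seq) - _ALPHABET
            if bad:
                raise AlignmentError(f"illegal character(s) {sorted(bad)} in sequence {sid!r}")
        for fam in ("A", "B"):
            if sum(1 for f in self.families if f == fam) < 2:
                raise AlignmentError(f"family {fam} needs at least 2 sequences")
        unknown = {f for f in self.families} - {"A", "B"}
        if unknown:
            raise AlignmentError(f"unknown family label(s) {sorted(unknown)}")
        for col in range(self.length):
            if all(s[col] == "-" for s in self.sequences):
                raise AlignmentError(f"column {col + 1} is entirely gaps")

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    def family_rows(self, family: str) -> list[str]:
        return [s for s, f in zip(self.sequences, self.families) if f == family]


def read_alignment(path, family_map) -> LabelledAlignment:
    """Read an aligned FASTA and attach family labels.

    ``family_map`` may be a dict {id: "A"|"B"}, a path to a two-column TSV
    (``id<TAB>family``), or a pair of id prefixes ``(prefix_A, prefix_B)``.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"{path}: no FASTA records")
    ids = [r.id for r in records]
    seqs = [str(r.seq).upper() for r in records]

    if isinstance(family_map, (str, Path)):
        mapping = {}
        with open(family_map, encoding="utf-8") as fh:
            for ln in fh:
                if not ln.strip() or ln.startswith("#"):
                    continue
                sid, fam = ln.split("\t")[:2]
                mapping[sid.strip()] = fam.strip().upper()
    elif isinstance(family_map, tuple) and len(family_map) == 2:
        pa, pb = family_map
        mapping = {}
        for sid in ids:
            if sid.startswith(pa):
                mapping[sid] = "A"
            elif sid.startswith(pb):
                mapping[sid] = "B"
    else:
        mapping = dict(family_map)

    families = []
    for sid in ids:
        if sid not in mapping:
            raise AlignmentError(f"sequence id {sid!r} has no family assignment")
        families.append(mapping[sid])
    return LabelledAlignment(ids=ids, sequences=seqs, families=families)


@dataclass
class ConsensusProfile:
    """Per-column tiered consensus of one family.

    symbols[i] is uppercase when the top residue's fraction (over all family
    rows, gaps included) is >= threshold_high, lowercase when the plurality
    residue reaches threshold_low but not threshold_high, '.' when no residue
    reaches threshold_low, and '-' when the gap fraction is >= threshold_high.
    """

    family: str
    threshold_high: float
    threshold_low: float
    symbols: str
    counts: list[Counter] = field(repr=False)
    n_sequences: int = 0

    def __len__(self) -> int:
        return len(self.symbols)


def consensus(
    aln: LabelledAlignment,
    family: str,
    threshold_high: float = 0.70,
    threshold_low: float = 0.50,
) -> ConsensusProfile:
    """Tiered consensus of one family over the shared column space.

    Deterministic: plurality ties break alphabetically.
    """
    if not (0 < threshold_high <= 1) or not (0 < threshold_low < threshold_high):
        raise ValueError("need 0 < threshold_low < threshold_high <= 1")
    rows = aln.family_rows(family)
    if len(rows) < 2:
        raise AlignmentError(f"family {family} needs at least 2 sequences")
    n = len(rows)
    symbols = []
    counts = []
    for col in range(aln.length):
        tally = Counter(row[col] for row in rows)
        counts.append(tally)
        if tally.get("-", 0) / n >= threshold_high:
            symbols.append("-")
            continue
        residues = [(aa, tally[aa]) for aa in sorted(tally) if aa in _CLASS_OF]
        if not residues:
            symbols.append(".")
            continue
        best_aa, best_n = max(residues, key=lambda kv: (kv[1], -ord(kv[0])))
        frac = best_n / n
        if frac >= threshold_high:
            symbols.append(best_aa)
        elif frac >= threshold_low:
            symbols.append(best_aa.lower())
        else:
            symbols.append(".")
    return ConsensusProfile(
        family=family,
        threshold_high=threshold_high,
        threshold_low=threshold_low,
        symbols="".join(symbols),
        counts=counts,
        n_sequences=n,
    )


class SiteCategory(enum.Enum):
    STRONG_DIFFERENTIAL = "strong_differential"
    CONSERVED_A_ONLY = "conserved_A_only"
    CONSERVED_B_ONLY = "conserved_B_only"
    IDENTICALLY_CONSERVED = "identically_conserved"
    UNCONSERVED = "unconserved"
    INDEL = "indel"


@dataclass
class SiteClassification:
    """Per-column category from comparing two consensus profiles."""

    categories: list[SiteCategory]
    chemical_flags: list[bool]

    def __len__(self) -> int:
        return len(self.categories)

    def counts(self) -> Counter:
        return Counter(self.categories)


def chemical_difference(res_a: str, res_b: str) -> bool:
    """True when two residues fall in different chemical classes.

    'X' is indeterminate and treated as not-different.
    """
    res_a, res_b = res_a.upper(), res_b.upper()
    if res_a == "X" or res_b == "X":
        return False
    if res_a not in _CLASS_OF or res_b not in _CLASS_OF:
        raise ValueError(f"not amino acids: {res_a!r}, {res_b!r}")
    return _CLASS_OF[res_a] != _CLASS_OF[res_b]


def classify_sites(
    cons_a: ConsensusProfile, cons_b: ConsensusProfile
) -> SiteClassification:
    """Column-by-column differential-conservation categories.

    A site is STRONG_DIFFERENTIAL when both families are conserved at the
    high tier but as different residues; the chemical flag additionally marks
    those pairs that cross chemical classes.
    """
    if len(cons_a) != len(cons_b):
        raise AlignmentError(
            f"profile length mismatch: {len(cons_a)} vs {len(cons_b)}"
        )
    categories = []
    flags = []
    for sa, sb in zip(cons_a.symbols, cons_b.symbols):
        flag = False
        gap_a, gap_b = sa == "-", sb == "-"
        up_a, up_b = sa.isupper() and sa != "-", sb.isupper() and sb != "-"
        if gap_a != gap_b:
            cat = SiteCategory.INDEL
        elif up_a and up_b:
            if sa == sb:
                cat = SiteCategory.IDENTICALLY_CONSERVED
            else:
                cat = SiteCategory.STRONG_DIFFERENTIAL
                flag = chemical_difference(sa, sb)
        elif up_a and not gap_b:
            cat = SiteCategory.CONSERVED_A_ONLY
        elif up_b and not gap_a:
            cat = SiteCategory.CONSERVED_B_ONLY
        else:
            cat = SiteCategory.UNCONSERVED
        categories.append(cat)
        flags.append(flag)
    return SiteClassification(categories=categories, chemical_flags=flags)


@dataclass
class IndelRun:
    """Half-open column interval where exactly one profile is gapped."""

    start: int  # 0-based, inclusive
    end: int  # 0-based, exclusive
    direction: str  # "insertion_in_B" (A gapped) or "deletion_in_B" (B gapped)
    conserved: bool

    @property
    def length(self) -> int:
        return self.end - self.start

    def as_1based(self) -> tuple[int, int]:
        return self.start + 1, self.end


@dataclass
class IndelReport:
    runs: list[IndelRun]

    def __iter__(self):
        return iter(self.runs)

    def __len__(self) -> int:
        return len(self.runs)


def detect_indels(
    cons_a: ConsensusProfile,
    cons_b: ConsensusProfile,
    min_conserved_fraction: float = 0.5,
) -> IndelReport:
    """Maximal runs of columns gapped in exactly one family's consensus.

    A run is flagged conserved when at least ``min_conserved_fraction`` of
    its columns carry a (upper- or lowercase) consensus residue in the
    non-gapped family.
    """
    if len(cons_a) != len(cons_b):
        raise AlignmentError("profile length mismatch")
    runs: list[IndelRun] = []
    i = 0
    n = len(cons_a)
    while i < n:
        sa, sb = cons_a.symbols[i], cons_b.symbols[i]
        if (sa == "-") == (sb == "-"):
            i += 1
            continue
        direction = "insertion_in_B" if sa == "-" else "deletion_in_B"
        j = i
        while j < n:
            ta, tb = cons_a.symbols[j], cons_b.symbols[j]
            here = (
                "insertion_in_B"
                if ta == "-" and tb != "-"
                else "deletion_in_B"
                if tb == "-" and ta != "-"
                else None
            )
            if here != direction:
                break
            j += 1
        carrier = cons_b if direction == "insertion_in_B" else cons_a
        letters = sum(1 for k in range(i, j) if carrier.symbols[k].isalpha())
        runs.append(
            IndelRun(
                start=i,
                end=j,
                direction=direction,
                conserved=letters / (j - i) >= min_conserved_fraction,
            )
        )
        i = j
    return IndelReport(runs=runs)


def map_column(aln: LabelledAlignment, seq_id: str, column: int) -> int | None:
    """Alignment column (1-based) -> residue position (1-based) in one row.

    Returns the count of non-gap characters up to and including the column,
    or None when the row carries a gap there.
    """
    try:
        row = aln.sequences[aln.ids.index(seq_id)]
    except ValueError:
        raise KeyError(f"unknown sequence id {seq_id!r}") from None
    if not (1 <= column <= aln.length):
        raise IndexError(f"column {column} outside 1..{aln.length}")
    if row[column - 1] == "-":
        return None
    return sum(1 for ch in row[:column] if ch != "-")


def cterm_extension(
    aln: LabelledAlignment,
    threshold_high: float = 0.70,
    threshold_low: float = 0.50,
) -> float:
    """Mean number of family-A residues C-terminal to family B's consensus end.

    For each family-A sequence, residues strictly beyond the last column where
    the family-B consensus is non-gap are counted; the mean over family-A
    sequences is returned.
    """
    cons_b = consensus(aln, "B", threshold_high, threshold_low)
    last = max(
        (i for i, s in enumerate(cons_b.symbols) if s != "-"), default=-1
    )
    rows_a = aln.family_rows("A")
    tails = [sum(1 for ch in row[last + 1 :] if ch != "-") for row in rows_a]
    return float(sum(tails) / len(tails))


def classification_to_tsv(
    cons_a: ConsensusProfile, cons_b: ConsensusProfile, cls: SiteClassification
) -> str:
    """Per-column TSV: column (1-based), consA, consB, category, chemical flag."""
    lines = ["column\tconsA\tconsB\tcategory\tchemical_flag"]
    for i, (sa, sb, cat, fl) in enumerate(
        zip(cons_a.symbols, cons_b.symbols, cls.categories, cls.chemical_flags)
    ):
        lines.append(f"{i + 1}\t{sa}\t{sb}\t{cat.value}\t{int(fl)}")
    return "\n".join(lines) + "\n"


def indels_to_tsv(report: IndelReport) -> str:
    lines = ["start\tend\tdirection\tlength\tconserved"]
    for run in report:
        s1, e1 = run.as_1based()
        lines.append(f"{s1}\t{e1}\t{run.direction}\t{run.length}\t{int(run.conserved)}")
    return "\n".join(lines) + "\n"
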