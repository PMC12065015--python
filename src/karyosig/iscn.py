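"""Extraction of two-way translocations from ISCN-style karyotype strings.

A clonal karyotype such as ``46,XX,t(9;22)(q34;q11)/47,XX,t(9;22)(q34;q11),+8``
describes one or more clones separated by ``/``, each a comma-separated list
of abnormality terms.  This module recognises reciprocal translocation terms
``t(c1;c2)(bands)`` and reduces them to whole-chromosome *translocation types*
— unordered pairs of distinct, non-homologous, non-Y chromosomes — the unit of
all downstream frequency analysis.  Band-level detail is parsed past and
discarded.

Exclusion rules applied during extraction:

* three-or-more-way translocations, e.g. ``t(1;2;5)``, are skipped;
* homologous translocations, e.g. ``t(1;1)``, are skipped;
* anything involving the Y chromosome is skipped;
* a ``t(...)`` embedded in a derivative term, e.g. ``der(16)t(1;16)``, marks
  an unbalanced rearrangement and is skipped by default (``count_nested``
  opts in);
* a ``?`` in a chromosome position is unparseable (``?`` inside the band
  parenthetical is tolerated, since bands are discarded anyway).

Every rejected ``t(...)`` occurrence is reported as a :class:`SkippedEvent`
with a machine-readable reason code.  A type is counted at most once per
case, however many clones repeat it.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Optional, Sequence

import pandas as pd

AUTOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23))
#: Chromosomes that may appear in a countable translocation type.
COUNTABLE_CHROMOSOMES: tuple[str, ...] = AUTOSOMES + ("X",)
_VALID_TOKENS = frozenset(COUNTABLE_CHROMOSOMES) | {"Y"}

# skip reason codes
THREE_OR_MORE_WAY = "three_or_more_way"
HOMOLOGOUS = "homologous"
Y_INVOLVED = "y_involved"
UNPARSEABLE = "unparseable"
NESTED_IN_DERIVATIVE = "nested_in_derivative"

SKIP_REASONS = (
    THREE_OR_MORE_WAY,
    HOMOLOGOUS,
    Y_INVOLVED,
    UNPARSEABLE,
    NESTED_IN_DERIVATIVE,
)

# a lexical t-term: "t(" not preceded by a letter, capturing the chromosome
# parenthetical only (the band parenthetical, if any, follows separately)
_T_TERM_RE = re.compile(r"(?<![A-Za-z])[tT]\(([^()]*)\)")


def chromosome_sort_key(chrom: str) -> tuple[int, int]:
    """Sort key for canonical labels: X precedes all autosomes (ISCN writes
    ``t(X;18)``); autosomes order numerically."""
    if chrom == "X":
        return (0, 0)
    return (1, int(chrom))


def canonical_label(chrom_a: str, chrom_b: str) -> str:
    """Canonical text form ``t(a;b)`` of an unordered chromosome pair.

    Symmetric in its arguments; X is written first when present, otherwise
    the smaller autosome first: ``t(X;18)``, ``t(9;22)``.

    Raises
    ------
    ValueError
        For a homologous pair, a Y chromosome, or an unknown token.
    """
    a, b = _normalise_chrom(chrom_a), _normalise_chrom(chrom_b)
    for c in (a, b):
        if c == "Y":
            raise ValueError("Y not countable")
        if c not in COUNTABLE_CHROMOSOMES:
            raise ValueError(f"unknown chromosome {c!r}")
    if a == b:
        raise ValueError("homologous pair")
    a, b = sorted((a, b), key=chromosome_sort_key)
    return f"t({a};{b})"


def _normalise_chrom(chrom: str) -> str:
    return str(chrom).strip().upper()


@dataclass(frozen=True, slots=True)
class TranslocationType:
    """An unordered pair of distinct non-Y chromosomes from {1..22, X}.

    Exactly 253 distinct values exist.  Construction canonicalises member
    order, so ``TranslocationType("22", "9") == TranslocationType("9", "22")``.
    """

    chrom_a: str
    chrom_b: str

    def __post_init__(self) -> None:
        label = canonical_label(self.chrom_a, self.chrom_b)  # validates
        a, b = label[2:-1].split(";")
        object.__setattr__(self, "chrom_a", a)
        object.__setattr__(self, "chrom_b", b)

    @property
    def label(self) -> str:
        return f"t({self.chrom_a};{self.chrom_b})"

    @classmethod
    def from_label(cls, label: str) -> "TranslocationType":
        m = re.fullmatch(r"[tT]\(([^;()]+);([^;()]+)\)", label.strip())
        if m is None:
            raise ValueError(f"not a translocation label: {label!r}")
        return cls(m.group(1), m.group(2))

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


class SkippedEvent(NamedTuple):
    """A rejected ``t(...)`` occurrence and the rule that rejected it."""

    fragment: str
    reason: str


@dataclass(slots=True)
class CaseRecord:
    """One neoplasm case: labels, raw karyotype, and extracted types."""

    case_id: str
    entity: str
    karyotype: str
    group: Optional[str] = None
    sex: Optional[str] = None
    translocations: frozenset[TranslocationType] = field(default_factory=frozenset)
    skipped_events: list[SkippedEvent] = field(default_factory=list)


def _split_top_level(text: str, sep: str) -> list[str]:
    """Split on `sep` outside any parentheses."""
    parts: list[str] = []
    depth = 0
    buf: list[str] = []
    for ch in text:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth = max(0, depth - 1)
        if ch == sep and depth == 0:
            parts.append("".join(buf))
            buf = []
        else:
            buf.append(ch)
    parts.append("".join(buf))
    return parts


def _classify_t_content(content: str) -> tuple[Optional[TranslocationType], Optional[str]]:
    """Map the chromosome parenthetical of a t-term to a type or skip reason."""
    tokens = [_normalise_chrom(t) for t in content.split(";")]
    if len(tokens) >= 3:
        return None, THREE_OR_MORE_WAY
    if len(tokens) != 2:
        return None, UNPARSEABLE
    if any(t not in _VALID_TOKENS for t in tokens):
        return None, UNPARSEABLE
    if "Y" in tokens:
        return None, Y_INVOLVED
    if tokens[0] == tokens[1]:
        return None, HOMOLOGOUS
    return TranslocationType(tokens[0], tokens[1]), None


def parse_karyotype(
    karyotype: str, *, count_nested: bool = False
) -> tuple[frozenset[TranslocationType], list[SkippedEvent]]:
    """Extract the set of countable two-way translocation types from an
    ISCN-style karyotype string.

    Parameters
    ----------
    karyotype
        Raw ISCN-style text; clones separated by ``/``, abnormality terms by
        top-level commas.  Terms other than translocations (gains, losses,
        inversions, markers, the sex-chromosome constitution, ``idem`` ...)
        are passed over silently.
    count_nested
        Count ``t(...)`` embedded in ``der(...)``/``ider(...)`` compound
        terms as if standalone.  Off by default: such events are unbalanced
        derivatives, not reciprocal translocations.

    Returns
    -------
    (types, skipped)
        ``types`` holds every distinct accepted type found in any clone
        (duplicates across clones collapse to one); ``skipped`` lists every
        rejected ``t(...)`` occurrence with its reason code.

    Raises
    ------
    ValueError
        If the input is empty or whitespace only.
    """
    if not karyotype or not karyotype.strip():
        raise ValueError("empty karyotype")
    text = re.sub(r"\s+", "", karyotype)

    accepted: set[TranslocationType] = set()
    skipped: list[SkippedEvent] = []
    for clone in _split_top_level(text, "/"):
        for term in _split_top_level(clone, ","):
            for m in _T_TERM_RE.finditer(term):
                # a t() preceded by another token in the same term (der(16)t(1;16),
                # ider(...)t(...)) belongs to a compound derivative; a bare
                # prefix like "+" does not make it nested
                nested = bool(re.search(r"[A-Za-z)]", term[: m.start()]))
                if nested and not count_nested:
                    skipped.append(SkippedEvent(term, NESTED_IN_DERIVATIVE))
                    continue
                ttype, reason = _classify_t_content(m.group(1))
                if ttype is not None:
                    accepted.add(ttype)
                else:
                    skipped.append(SkippedEvent(term, reason))
    return frozenset(accepted), skipped


# ---------------------------------------------------------------------------
# tabular interface


def read_case_table(path: str | Path, *, delimiter: str = "\t") -> pd.DataFrame:
    """Read a per-case table (UTF-8 TSV/CSV) with required columns
    ``case_id``, ``entity``, ``karyotype`` and optional ``group``, ``sex``."""
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    missing = {"case_id", "entity", "karyotype"} - set(df.columns)
    if missing:
        raise ValueError(f"missing required columns: {sorted(missing)}")
    return df


def _normalise_sex(value: Optional[str]) -> Optional[str]:
    if value is None:
        return None
    v = str(value).strip().upper()
    if v in ("F", "FEMALE"):
        return "F"
    if v in ("M", "MALE"):
        return "M"
    if v == "":
        return None
    return "unknown"


def parse_cases(
    table: pd.DataFrame, *, count_nested: bool = False
) -> list[CaseRecord]:
    """Parse every karyotype in a case table into a :class:`CaseRecord`."""
    records: list[CaseRecord] = []
    has_group = "group" in table.columns
    has_sex = "sex" in table.columns
    for row in table.itertuples(index=False):
        types, skips = parse_karyotype(row.karyotype, count_nested=count_nested)
        records.append(
            CaseRecord(
                case_id=str(row.case_id),
                entity=str(row.entity),
                karyotype=row.karyotype,
                group=(str(row.group) or None) if has_group else None,
                sex=_normalise_sex(row.sex) if has_sex else None,
                translocations=types,
                skipped_events=skips,
            )
        )
    return records


def annotate_table(
    table: pd.DataFrame, *, count_nested: bool = False
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Augment a case table with extracted canonical labels and return it
    with a skip report.

    Returns
    -------
    (annotated, skip_report)
        ``annotated`` is the input plus a ``translocations`` column of
        semicolon-joined canonical labels; ``skip_report`` has columns
        ``case_id``, ``fragment``, ``reason``, one row per rejected term.
    """
    records = parse_cases(table, count_nested=count_nested)
    annotated = table.copy()
    annotated["translocations"] = [
        ";".join(sorted(t.label for t in rec.translocations)) for rec in records
    ]
    skip_rows = [
        {"case_id": rec.case_id, "fragment": ev.fragment, "reason": ev.reason}
        for rec in records
        for ev in rec.skipped_events
    ]
    skip_report = pd.DataFrame(skip_rows, columns=["case_id", "fragment", "reason"])
    return annotated, skip_report
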