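"""Pairwise comparison of translocation spectra by coefficient of
determination (R2).

For a pair of entities, every type accounting for strictly more than the
cutoff percentage (default 10%) of either entity's translocations — a
*characteristic* translocation such as t(9;22) in chronic myeloid leukemia or
t(X;18) in synovial sarcoma — is excluded, and R2 is the squared Pearson
correlation of the two percentage vectors over the retained coordinates.
Because Pearson correlation is invariant to positive rescaling of either
vector, it makes no difference whether percentages are renormalised over the
retained coordinates or left as computed over all 253.

Strength classes are assigned on R2 rounded to one decimal:
insignificant/very weak (0.0-0.3), weak/moderate (0.4-0.6), strong/very
strong (0.7-1.0).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .iscn import TranslocationType
from .spectrum import N_TYPES, EntitySpectrum, enumerate_types

STRENGTH_INSIGNIFICANT = "insignificant/very weak"
STRENGTH_MODERATE = "weak/moderate"
STRENGTH_STRONG = "strong/very strong"
NOT_COMPUTABLE = "not_computable"

#: (low, high, label) on the one-decimal-rounded R2; the bins tile [0, 1].
DEFAULT_STRENGTH_BINS: tuple[tuple[float, float, str], ...] = (
    (0.0, 0.3, STRENGTH_INSIGNIFICANT),
    (0.4, 0.6, STRENGTH_MODERATE),
    (0.7, 1.0, STRENGTH_STRONG),
)


@dataclass(frozen=True, slots=True)
class ComparisonConfig:
    """Settings for a pairwise comparison.

    ``cutoff_pct`` is the characteristic-translocation threshold in percent,
    strict: a type at exactly the cutoff is retained.
    """

    cutoff_pct: float = 10.0
    strength_bins: tuple[tuple[float, float, str], ...] = DEFAULT_STRENGTH_BINS

    def __post_init__(self) -> None:
        if not 0 < self.cutoff_pct <= 100:
            raise ValueError("cutoff_pct must be in (0, 100]")


def classify_strength(
    r2: float, bins: Sequence[tuple[float, float, str]] = DEFAULT_STRENGTH_BINS
) -> str:
    """Strength class of an R2 value, judged after rounding to one decimal."""
    rounded = round(r2, 1)
    for lo, hi, label in bins:
        if lo - 1e-9 <= rounded <= hi + 1e-9:
            return label
    raise ValueError(f"R2 {r2} outside all strength bins")


def r_squared(x: Sequence[float], y: Sequence[float]) -> float:
    """Squared Pearson product-moment correlation of two equal-length vectors.

    Equivalent to the OLS coefficient of determination of y on x (or x on y);
    symmetric and sign-blind.

    Raises
    ------
    ValueError
        On length mismatch, fewer than 3 points, or zero variance in either
        vector (reported as not computable, never as 0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    if x.size < 3:
        raise ValueError("need at least 3 coordinates")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("degenerate spectrum")
    r = stats.pearsonr(x, y).statistic
    return float(r * r)


def exclude_characteristic(
    spectrum_a: EntitySpectrum,
    spectrum_b: EntitySpectrum,
    cutoff_pct: float = 10.0,
) -> frozenset[TranslocationType]:
    """Types whose percentage strictly exceeds the cutoff in EITHER spectrum.

    The threshold is evaluated on each entity's own spectrum and the union of
    offenders is dropped from both vectors, keeping them aligned.
    """
    for s in (spectrum_a, spectrum_b):
        if s.n_translocations == 0:
            raise ValueError(f"spectrum {s.label!r} has no observations")
    mask = (spectrum_a.pct_freq > cutoff_pct) | (spectrum_b.pct_freq > cutoff_pct)
    universe = enumerate_types()
    return frozenset(universe[i] for i in np.flatnonzero(mask))


@dataclass(frozen=True, slots=True)
class ComparisonResult:
    """Outcome of one pairwise spectrum comparison.

    ``r2`` is None (with ``strength`` = ``not_computable`` and ``error`` set)
    when the retained vectors are too short or degenerate; a flagged cell,
    not an abort.
    """

    label_a: str
    label_b: str
    cutoff_pct: float
    excluded_types: frozenset[TranslocationType]
    n_retained: int
    r2: Optional[float]
    strength: str
    error: Optional[str] = None

    @property
    def computable(self) -> bool:
        return self.r2 is not None


def compare_pair(
    spectrum_a: EntitySpectrum,
    spectrum_b: EntitySpectrum,
    config: ComparisonConfig | None = None,
) -> ComparisonResult:
    """Compare two spectra: exclude characteristic types, then R2 over the
    retained percentage coordinates.

    Raises
    ------
    ValueError
        If fewer than 3 coordinates remain or a retained vector is constant
        (zero variance).  Use :func:`pairwise_matrix` for flagged-cell
        handling instead of exceptions.
    """
    config = config or ComparisonConfig()
    excluded = exclude_characteristic(spectrum_a, spectrum_b, config.cutoff_pct)
    mask = (spectrum_a.pct_freq <= config.cutoff_pct) & (
        spectrum_b.pct_freq <= config.cutoff_pct
    )
    n_retained = int(mask.sum())
    assert n_retained + len(excluded) == N_TYPES
    r2 = r_squared(spectrum_a.pct_freq[mask], spectrum_b.pct_freq[mask])
    return ComparisonResult(
        label_a=spectrum_a.label,
        label_b=spectrum_b.label,
        cutoff_pct=config.cutoff_pct,
        excluded_types=excluded,
        n_retained=n_retained,
        r2=r2,
        strength=classify_strength(r2, config.strength_bins),
    )


def pairwise_matrix(
    spectra: Sequence[EntitySpectrum],
    config: ComparisonConfig | None = None,
) -> list[ComparisonResult]:
    """Compare all unordered pairs of spectra: n(n-1)/2 results, in the order
    of the upper triangle.  Per-pair errors become flagged results rather
    than aborting the matrix."""
    if len(spectra) < 2:
        raise ValueError("need at least 2 spectra")
    config = config or ComparisonConfig()
    results: list[ComparisonResult] = []
    for a, b in combinations(spectra, 2):
        try:
            results.append(compare_pair(a, b, config))
        except ValueError as exc:
            results.append(
                ComparisonResult(
                    label_a=a.label,
                    label_b=b.label,
                    cutoff_pct=config.cutoff_pct,
                    excluded_types=frozenset(),
                    n_retained=0,
                    r2=None,
                    strength=NOT_COMPUTABLE,
                    error=str(exc),
                )
            )
    return results


@dataclass(frozen=True, slots=True)
class StrengthSummary:
    """Tallies of a comparison matrix by strength class and by the
    conventional reporting thresholds R2 <= 0.3 and R2 < 0.1 (evaluated on
    the unrounded values)."""

    n_total: int
    n_computable: int
    by_class: dict[str, int]
    n_le_03: int
    n_lt_01: int

    @property
    def pct_le_03(self) -> int:
        """Percentage of computable comparisons at R2 <= 0.3, integer-rounded."""
        if self.n_computable == 0:
            return 0
        return round(100 * self.n_le_03 / self.n_computable)


def strength_summary(results: Iterable[ComparisonResult]) -> StrengthSummary:
    results = list(results)
    by_class: dict[str, int] = {
        STRENGTH_INSIGNIFICANT: 0,
        STRENGTH_MODERATE: 0,
        STRENGTH_STRONG: 0,
        NOT_COMPUTABLE: 0,
    }
    n_le_03 = 0
    n_lt_01 = 0
    n_computable = 0
    for res in results:
        by_class[res.strength] = by_class.get(res.strength, 0) + 1
        if res.r2 is not None:
            n_computable += 1
            if res.r2 <= 0.3:
                n_le_03 += 1
            if res.r2 < 0.1:
                n_lt_01 += 1
    return StrengthSummary(
        n_total=len(results),
        n_computable=n_computable,
        by_class=by_class,
        n_le_03=n_le_03,
        n_lt_01=n_lt_01,
    )


def cutoff_sensitivity(
    spectrum_a: EntitySpectrum,
    spectrum_b: EntitySpectrum,
    cutoffs: Sequence[float] = (10.0, 5.0, 2.0, 1.0),
    config: ComparisonConfig | None = None,
) -> list[ComparisonResult]:
    """Re-run one comparison at progressively stricter cutoffs.

    ``n_retained`` is non-increasing as the cutoff decreases; per-cutoff
    failures are flagged, not raised."""
    base = config or ComparisonConfig()
    results = []
    for cutoff in cutoffs:
        cfg = ComparisonConfig(cutoff_pct=cutoff, strength_bins=base.strength_bins)
        try:
            results.append(compare_pair(spectrum_a, spectrum_b, cfg))
        except ValueError as exc:
            results.append(
                ComparisonResult(
                    label_a=spectrum_a.label,
                    label_b=spectrum_b.label,
                    cutoff_pct=cutoff,
                    excluded_types=frozenset(),
                    n_retained=0,
                    r2=None,
                    strength=NOT_COMPUTABLE,
                    error=str(exc),
                )
            )
    return results


# ---------------------------------------------------------------------------
# tabular exports


def results_to_long_frame(results: Iterable[ComparisonResult]) -> pd.DataFrame:
    """Long-format pair table: one row per comparison."""
    rows = []
    for res in results:
        rows.append(
            {
                "label_a": res.label_a,
                "label_b": res.label_b,
                "cutoff_pct": res.cutoff_pct,
                "n_retained": res.n_retained,
                "excluded": ";".join(sorted(t.label for t in res.excluded_types)),
                "r2": round(res.r2, 3) if res.r2 is not None else None,
                "strength": res.strength,
                "error": res.error or "",
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "label_a", "label_b", "cutoff_pct", "n_retained",
            "excluded", "r2", "strength", "error",
        ],
    )


def results_to_triangle(
    results: Sequence[ComparisonResult], *, decimals: int = 3
) -> pd.DataFrame:
    """Upper-triangular R2 matrix (rows: all labels but the last; columns:
    all labels but the first), as printed in comparative tables."""
    labels: list[str] = []
    for res in results:
        for lab in (res.label_a, res.label_b):
            if lab not in labels:
                labels.append(lab)
    tri = pd.DataFrame("", index=labels[:-1], columns=labels[1:], dtype=object)
    for res in results:
        value = f"{res.r2:.{decimals}f}" if res.r2 is not None else "n.c."
        tri.loc[res.label_a, res.label_b] = value
    return tri
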