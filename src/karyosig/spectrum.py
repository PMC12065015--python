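"""Frequency spectra over the 253 translocation types.

The analysis universe is every unordered pair of distinct chromosomes from
{1..22, X} — 23 x 22 / 2 = 253 types, running t(1;2) through t(X;22).  An
:class:`EntitySpectrum` holds, for one tumor entity (or group, or stratum),
the absolute count and percentage of each type, where a case contributes a
type at most once.  Entities enter the comparative analysis only when at
least 100 cases and at least 100 translocations are available.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .iscn import AUTOSOMES, CaseRecord, TranslocationType

N_TYPES = 253


@lru_cache(maxsize=1)
def enumerate_types() -> tuple[TranslocationType, ...]:
    """The ordered universe of all 253 translocation types.

    The 231 autosome-autosome pairs come first in lexicographic order
    t(1;2), t(1;3), ..., t(21;22), followed by the 22 X pairs t(X;1) through
    t(X;22), so the list runs "t(1;2) through t(X;22)".
    """
    types: list[TranslocationType] = []
    for i, a in enumerate(AUTOSOMES):
        for b in AUTOSOMES[i + 1 :]:
            types.append(TranslocationType(a, b))
    for b in AUTOSOMES:
        types.append(TranslocationType("X", b))
    assert len(types) == N_TYPES
    return tuple(types)


@lru_cache(maxsize=1)
def type_index() -> dict[TranslocationType, int]:
    """Map each type to its 0-based position in :func:`enumerate_types`."""
    return {t: i for i, t in enumerate(enumerate_types())}


def type_labels() -> list[str]:
    return [t.label for t in enumerate_types()]


@dataclass(slots=True)
class EntitySpectrum:
    """Absolute and percentage translocation-type frequencies for one label.

    Attributes
    ----------
    label : name of the entity / group / stratum.
    n_cases : number of cases behind the spectrum.
    n_translocations : total type observations; equals ``abs_freq.sum()``.
    abs_freq : 253-vector of counts aligned to :func:`enumerate_types`.
    pct_freq : 253-vector of percentages (all zero when no observations).
    """

    label: str
    n_cases: int
    n_translocations: int
    abs_freq: np.ndarray
    pct_freq: np.ndarray

    def __post_init__(self) -> None:
        self.abs_freq = np.asarray(self.abs_freq, dtype=np.int64)
        self.pct_freq = np.asarray(self.pct_freq, dtype=float)
        if self.abs_freq.shape != (N_TYPES,) or self.pct_freq.shape != (N_TYPES,):
            raise ValueError(f"frequency vectors must have length {N_TYPES}")
        if int(self.abs_freq.sum()) != self.n_translocations:
            raise ValueError("abs_freq does not sum to n_translocations")

    @property
    def is_empty(self) -> bool:
        """True when the spectrum carries no observations (valid but flagged)."""
        return self.n_translocations == 0

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per type (index 1-253, label, abs, pct)."""
        return pd.DataFrame(
            {
                "index": np.arange(1, N_TYPES + 1),
                "type": type_labels(),
                "abs": self.abs_freq,
                "pct": self.pct_freq,
            }
        )


def build_spectrum(cases: Sequence[CaseRecord], label: str) -> EntitySpectrum:
    """Count each case's deduplicated translocation types into a spectrum.

    Raises
    ------
    ValueError
        On an empty case list.  A non-empty list with zero translocations is
        valid: the spectrum is returned with all-zero percentages.
    """
    if len(cases) == 0:
        raise ValueError("empty case list")
    idx = type_index()
    abs_freq = np.zeros(N_TYPES, dtype=np.int64)
    for case in cases:
        for t in case.translocations:
            abs_freq[idx[t]] += 1
    return spectrum_from_counts(abs_freq, label=label, n_cases=len(cases))


def spectrum_from_counts(
    abs_freq: np.ndarray, *, label: str, n_cases: int
) -> EntitySpectrum:
    """Build a spectrum from a ready-made 253-vector of counts."""
    abs_freq = np.asarray(abs_freq, dtype=np.int64)
    total = int(abs_freq.sum())
    if total > 0:
        pct = 100.0 * abs_freq / total
    else:
        pct = np.zeros(N_TYPES)
    return EntitySpectrum(
        label=label,
        n_cases=int(n_cases),
        n_translocations=total,
        abs_freq=abs_freq,
        pct_freq=pct,
    )


def apply_inclusion_filter(
    spectra: Iterable[EntitySpectrum],
    min_cases: int = 100,
    min_translocations: int = 100,
) -> tuple[list[EntitySpectrum], list[EntitySpectrum]]:
    """Partition spectra into (included, excluded) by the study's inclusion
    rule: at least `min_cases` cases AND at least `min_translocations`
    translocations (both bounds inclusive)."""
    included, excluded = [], []
    for s in spectra:
        if s.n_cases >= min_cases and s.n_translocations >= min_translocations:
            included.append(s)
        else:
            excluded.append(s)
    return included, excluded


@dataclass(frozen=True, slots=True)
class FrequencyCategorySummary:
    """Counts of types by percentage band: 0%, (0,1)%, [1,10]%, >10%."""

    n_zero: int
    n_lt1: int
    n_1to10: int
    n_gt10: int

    @property
    def total(self) -> int:
        return self.n_zero + self.n_lt1 + self.n_1to10 + self.n_gt10


def frequency_categories(spectrum: EntitySpectrum) -> FrequencyCategorySummary:
    """Bin the 253 percentages into the reporting categories.

    Bounds are exact: 0; (0, 1); [1, 10]; (10, 100].  The 1% boundary belongs
    to the middle band and 10% is retained in it; only strictly more than 10%
    falls in the top band.
    """
    if spectrum.n_translocations == 0:
        raise ValueError("no observations")
    p = spectrum.pct_freq
    n_zero = int(np.sum(p == 0))
    n_lt1 = int(np.sum((p > 0) & (p < 1)))
    n_1to10 = int(np.sum((p >= 1) & (p <= 10)))
    n_gt10 = int(np.sum(p > 10))
    return FrequencyCategorySummary(n_zero, n_lt1, n_1to10, n_gt10)


def cases_vs_translocations_r2(spectra: Sequence[EntitySpectrum]) -> float:
    """Squared Pearson correlation between the number of cases and the number
    of translocations across entities.

    Raises
    ------
    ValueError
        With fewer than 3 spectra or when either quantity has zero variance.
    """
    if len(spectra) < 3:
        raise ValueError("need at least 3 spectra")
    x = np.array([s.n_cases for s in spectra], dtype=float)
    y = np.array([s.n_translocations for s in spectra], dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("degenerate")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def spectra_to_matrix(spectra: Sequence[EntitySpectrum], *, pct: bool = False) -> pd.DataFrame:
    """Wide matrix export: rows are the 253 types, one column per spectrum."""
    data = {
        s.label: (s.pct_freq if pct else s.abs_freq) for s in spectra
    }
    out = pd.DataFrame(data, index=type_labels())
    out.insert(0, "index", np.arange(1, N_TYPES + 1))
    out.index.name = "type"
    return out
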