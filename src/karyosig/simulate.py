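"""Synthetic cohorts of ISCN-karyotyped cases with known signature structure.

Each entity's translocation signature is a probability vector over the 253
types drawn from a sparse symmetric Dirichlet, optionally spiked with a
high-mass characteristic translocation (emulating, e.g., t(9;22) in chronic
myeloid leukemia).  Cases carry 0-k two-way translocations: the per-case
count follows a zero-inflated Poisson, types are drawn i.i.d. from the
signature and deduplicated within the case, and the case is rendered as an
ISCN-style karyotype string.  Every emitted type is logged, so the generator
doubles as a ground-truth oracle for the parser and the spectrum builder:
re-parsing the rendered karyotypes must reproduce the emission log exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .iscn import CaseRecord, TranslocationType
from .spectrum import (
    N_TYPES,
    EntitySpectrum,
    enumerate_types,
    spectrum_from_counts,
    type_index,
)

_MAX_REDRAWS = 100  # per within-case collision
_BAND_ARMS = ("p", "q")
_BAND_NUMBERS = ("11", "12", "13", "21", "22", "23", "24", "31", "32", "34")


@dataclass(slots=True)
class SignatureModel:
    """Ground-truth generative parameters for one synthetic entity.

    ``probs`` sums to 1 and already includes the spike mass, when present.
    The per-case translocation count is zero-inflated Poisson: with
    probability ``p_zero`` a case has no translocation, otherwise the count
    is Poisson(``lam``).
    """

    entity: str
    probs: np.ndarray
    spike: Optional[tuple[TranslocationType, float]]
    n_cases: int
    p_zero: float
    lam: float
    sex_ratio: float
    seed: int

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (N_TYPES,):
            raise ValueError(f"probs must have length {N_TYPES}")
        if np.any(self.probs < 0) or abs(self.probs.sum() - 1.0) > 1e-12:
            raise ValueError("probs must be a probability vector")


def make_signature(
    universe: Sequence[TranslocationType] | None = None,
    concentration: float = 0.05,
    spike: Optional[tuple[TranslocationType, float]] = None,
    seed: int = 0,
    *,
    entity: str = "entity",
    n_cases: int = 1000,
    p_zero: float = 0.3,
    lam: float = 1.2,
    sex_ratio: float = 0.5,
) -> SignatureModel:
    """Draw a sparse signature from a symmetric Dirichlet and optionally
    assign an exact spike mass to one characteristic type.

    With ``concentration`` well below 1 the vector is dominated by a few
    types and most carry probability below 1%, mirroring the long tail of
    rare translocations seen in real tumor entities.  Deterministic given
    ``seed``.
    """
    if universe is None:
        universe = enumerate_types()
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    rng = np.random.default_rng(seed)
    probs = rng.dirichlet(np.full(len(universe), concentration))
    if spike is not None:
        spike_type, mass = spike
        if not 0 <= mass < 1:
            raise ValueError("spike mass must be in [0, 1)")
        try:
            spike_idx = type_index()[spike_type]
        except KeyError:
            raise ValueError(f"spike type {spike_type!r} not in universe") from None
        probs[spike_idx] = 0.0
        probs *= (1.0 - mass) / probs.sum()
        probs[spike_idx] = mass
    return SignatureModel(
        entity=entity,
        probs=probs,
        spike=spike,
        n_cases=n_cases,
        p_zero=p_zero,
        lam=lam,
        sex_ratio=sex_ratio,
        seed=seed,
    )


@dataclass(slots=True)
class SyntheticCohort:
    """A rendered cohort plus its generative truth and emission log."""

    cases: list[CaseRecord]
    truth: SignatureModel
    emission_log: np.ndarray  # per-type emitted counts, length 253

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "case_id": [c.case_id for c in self.cases],
                "entity": [c.entity for c in self.cases],
                "sex": [c.sex or "" for c in self.cases],
                "karyotype": [c.karyotype for c in self.cases],
            }
        )

    def spectrum(self, label: Optional[str] = None) -> EntitySpectrum:
        """Observed spectrum of the cohort, built from the emission log
        (identical to rebuilding from the parsed cases)."""
        return spectrum_from_counts(
            self.emission_log,
            label=label or self.truth.entity,
            n_cases=len(self.cases),
        )


def _render_bands(rng: np.random.Generator, random_bands: bool) -> str:
    if not random_bands:
        return "(q11;q22)"
    a = _BAND_ARMS[rng.integers(2)] + _BAND_NUMBERS[rng.integers(len(_BAND_NUMBERS))]
    b = _BAND_ARMS[rng.integers(2)] + _BAND_NUMBERS[rng.integers(len(_BAND_NUMBERS))]
    return f"({a};{b})"


def sample_cohort(
    model: SignatureModel, *, random_bands: bool = False
) -> SyntheticCohort:
    """Sample a full cohort of cases from a signature model.

    Per case: sex from ``sex_ratio``, translocation count from the
    zero-inflated Poisson, then that many distinct types i.i.d. from
    ``probs`` with bounded redraw on within-case collision.  Karyotypes are
    rendered as ``46,XX,t(a;b)(q11;q22),...``; bands are fixed placeholders
    unless ``random_bands`` exercises parser tolerance.  Deterministic given
    ``model.seed``.
    """
    rng = np.random.default_rng(model.seed)
    universe = enumerate_types()
    cum = np.cumsum(model.probs)
    cum[-1] = 1.0  # guard against float round-off at the top end

    is_female = rng.random(model.n_cases) < model.sex_ratio
    zero_mask = rng.random(model.n_cases) < model.p_zero
    counts = rng.poisson(model.lam, size=model.n_cases)
    counts[zero_mask] = 0

    emission_log = np.zeros(N_TYPES, dtype=np.int64)
    cases: list[CaseRecord] = []
    for i in range(model.n_cases):
        k = int(counts[i])
        chosen: list[int] = []
        seen: set[int] = set()
        for _ in range(k):
            for _attempt in range(_MAX_REDRAWS):
                idx = int(np.searchsorted(cum, rng.random(), side="right"))
                if idx not in seen:
                    seen.add(idx)
                    chosen.append(idx)
                    break
            else:
                raise RuntimeError(
                    "redraw bound exceeded: probability vector too concentrated "
                    "for the requested per-case translocation count"
                )
        sex = "F" if is_female[i] else "M"
        constitution = "XX" if sex == "F" else "XY"
        terms = [
            f"{universe[j].label}{_render_bands(rng, random_bands)}" for j in chosen
        ]
        karyotype = ",".join(["46", constitution] + terms)
        emission_log[chosen] += 1
        cases.append(
            CaseRecord(
                case_id=f"{model.entity}-{i:05d}",
                entity=model.entity,
                karyotype=karyotype,
                sex=sex,
                translocations=frozenset(universe[j] for j in chosen),
            )
        )
    return SyntheticCohort(cases=cases, truth=model, emission_log=emission_log)


def make_study(
    n_entities: int,
    shared_pairs: int = 0,
    seed: int = 0,
    *,
    n_cases: int = 1000,
    concentration: float = 0.05,
    spikes: Optional[dict[int, tuple[TranslocationType, float]]] = None,
    p_zero: float = 0.3,
    lam: float = 1.2,
    sex_ratio: float = 0.5,
    random_bands: bool = False,
) -> list[SyntheticCohort]:
    """Generate a multi-entity study: independent signatures for all
    entities except ``shared_pairs`` designated pairs that reuse one
    signature (entities 0&1 share, then 2&3, ...), emulating same-disease
    splits such as the female/male comparison within one leukemia type.

    ``spikes`` maps entity index to a (type, mass) characteristic spike.
    Deterministic given ``seed``.
    """
    if n_entities < 2:
        raise ValueError("need at least 2 entities")
    if shared_pairs < 0 or 2 * shared_pairs > n_entities:
        raise ValueError("shared_pairs exceeds available pairs")
    spikes = spikes or {}
    ss = np.random.SeedSequence(seed)
    sig_seeds, cohort_seeds = (
        [int(s) for s in ss.generate_state(n_entities)],
        [int(s) % (2**31) for s in ss.generate_state(2 * n_entities)[n_entities:]],
    )
    cohorts: list[SyntheticCohort] = []
    for e in range(n_entities):
        sig_source = e - 1 if (e % 2 == 1 and e // 2 < shared_pairs) else e
        model = make_signature(
            concentration=concentration,
            spike=spikes.get(sig_source),
            seed=sig_seeds[sig_source] % (2**31),
            entity=f"E{e + 1:02d}",
            n_cases=n_cases,
            p_zero=p_zero,
            lam=lam,
            sex_ratio=sex_ratio,
        )
        model.seed = cohort_seeds[e]  # cohort sampling varies even for shared signatures
        cohorts.append(sample_cohort(model, random_bands=random_bands))
    return cohorts


def study_to_frame(cohorts: Sequence[SyntheticCohort]) -> pd.DataFrame:
    """Concatenate cohort tables into one per-case table."""
    return pd.concat([c.to_frame() for c in cohorts], ignore_index=True)


def truth_to_dict(cohorts: Sequence[SyntheticCohort]) -> dict:
    """Machine-readable sidecar describing the generative truth."""
    out = {}
    for c in cohorts:
        m = c.truth
        out[m.entity] = {
            "seed": m.seed,
            "n_cases": m.n_cases,
            "p_zero": m.p_zero,
            "lambda": m.lam,
            "sex_ratio": m.sex_ratio,
            "spike": (
                {"type": m.spike[0].label, "mass": m.spike[1]} if m.spike else None
            ),
            "top_types": {
                enumerate_types()[i].label: float(m.probs[i])
                for i in np.argsort(m.probs)[::-1][:10]
            },
        }
    return out
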