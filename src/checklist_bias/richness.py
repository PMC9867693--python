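"""Nonparametric species-richness estimation for abundance samples.

A single sample is one survey event — a citizen-science checklist, or one
structured point-count visit pooled across its points.  The Chao1 estimator
uses the counts of singletons (species seen exactly once, ``f1``) and
doubletons (seen exactly twice, ``f2``) to put a lower bound on the number
of species present but undetected:

    classic:     S_chao1 = S_obs + f1^2 / (2 f2)                 (f2 > 0)
                 S_chao1 = S_obs + f1 (f1 - 1) / 2               (f2 = 0)
    corrected:   the added term is multiplied by (n - 1) / n

The ``small_sample_corrected`` variant (the convention of the iNEXT /
SpadeR software family) is the default.  Estimates are never rounded here;
rounding is a reporting concern.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Tuple

import pandas as pd

VARIANTS = ("classic", "small_sample_corrected")


@dataclass(frozen=True)
class AbundanceSample:
    """Species counts for one survey event plus the Chao1 sufficient statistics."""

    counts: Mapping[str, int]
    s_obs: int = field(init=False)
    f1: int = field(init=False)
    f2: int = field(init=False)
    n: int = field(init=False)

    def __post_init__(self) -> None:
        for sp, c in self.counts.items():
            if not isinstance(c, (int,)) or isinstance(c, bool) or c <= 0:
                raise ValueError(f"count for species {sp!r} must be a positive integer, got {c!r}")
        object.__setattr__(self, "s_obs", len(self.counts))
        object.__setattr__(self, "f1", sum(1 for c in self.counts.values() if c == 1))
        object.__setattr__(self, "f2", sum(1 for c in self.counts.values() if c == 2))
        object.__setattr__(self, "n", sum(self.counts.values()))


@dataclass(frozen=True)
class RichnessEstimate:
    """Chao1 point estimate with the statistics it was computed from."""

    estimate: float
    variant: str
    s_obs: int
    f1: int
    f2: int
    n: int
    empty: bool = False


def make_sample(observations: Iterable[Tuple[str, int]]) -> AbundanceSample:
    """Tally (species, count) rows into an :class:`AbundanceSample`.

    Duplicate species entries are summed before the singleton/doubleton
    tally, so a species reported twice with counts 2 and 1 is a single
    species with count 3, not a doubleton plus a singleton.
    """
    totals: Counter = Counter()
    for sp, c in observations:
        if not isinstance(c, int) or isinstance(c, bool) or c <= 0:
            raise ValueError(f"count for species {sp!r} must be a positive integer, got {c!r}")
        totals[sp] += c
    return AbundanceSample(dict(totals))


def chao1(sample: AbundanceSample, variant: str = "small_sample_corrected") -> RichnessEstimate:
    """Chao1 lower-bound richness estimate for one abundance sample.

    An empty sample yields estimate 0 flagged ``empty`` rather than an
    error; with no singletons the estimate equals observed richness.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    s, f1, f2, n = sample.s_obs, sample.f1, sample.f2, sample.n
    if n == 0:
        return RichnessEstimate(0.0, variant, 0, 0, 0, 0, empty=True)
    if f2 > 0:
        added = f1 * f1 / (2.0 * f2)
    else:
        added = f1 * (f1 - 1) / 2.0
    if variant == "small_sample_corrected":
        added *= (n - 1) / n
    return RichnessEstimate(float(s + added), variant, s, f1, f2, n)


def singleton_percentage(sample: AbundanceSample) -> float:
    """Percentage of observed species that are singletons, 100*f1/S_obs.

    Undefined for an empty sample; returned as NaN so batch tables can
    carry it as missing.
    """
    if sample.s_obs == 0:
        return math.nan
    return 100.0 * sample.f1 / sample.s_obs


def richness_table(
    samples: Mapping[str, AbundanceSample], variant: str = "small_sample_corrected"
) -> pd.DataFrame:
    """Batch interface: one row per unit with counts, Chao1 and singleton %."""
    rows = []
    for unit_id, sample in samples.items():
        est = chao1(sample, variant)
        rows.append(
            {
                "unit_id": unit_id,
                "S_obs": est.s_obs,
                "f1": est.f1,
                "f2": est.f2,
                "n": est.n,
                "chao1": est.estimate,
                "variant": variant,
                "singleton_pct": singleton_percentage(sample),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["unit_id", "S_obs", "f1", "f2", "n", "chao1", "variant", "singleton_pct"],
    )
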