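"""Extrapolating bias directions to small families (1-4 members).

A small family or isolate carries too little data for a direct test, but it
can be read as the sole survivor(s) of a larger unknown family.  Within each
geo-linguistic area the large families supply two probabilities:

* ``Pr(bias)`` — that a family has a bias in any direction, estimated by
  Laplace's Rule of Succession (k+1)/(n+2) from the large-family estimates,
  which keeps the probability away from an unrealistic 1; and
* ``Pr(deviation)`` — that a surviving member deviates from its family's
  bias, taken as one minus the mean bias strength in the area's biased large
  families (a mean 90% bias yields Pr(deviation) = .1).

Each extrapolation replicate then draws, per small family: biased or not
(Pr(bias)); if biased, the direction from the survivors' majority value
(fair coin on ties); and deviate or not (Pr(deviation)), a deviate being
assigned the opposite direction.  Counts are averaged over many replicates
(10,000 by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .corpus import FamilyDataset
from .setbias import AGAINST, NONE, TOWARD, BiasEstimate

DIRECTIONS = (NONE, AGAINST, TOWARD)


@dataclass
class AreaBiasModel:
    """Area-level bias and deviation probabilities from large families."""

    area: str
    pr_bias: float
    pr_deviation: float
    n_large: int
    n_large_biased: int
    mean_strength: float


@dataclass
class AreaBiasSummary:
    """Mean counts (and SEs) of families per area and bias direction.

    ``mean`` and ``se`` are area x {none, A, E} tables; ``counts`` keeps the
    raw per-replicate integer counts (n_reps x areas x 3) when available so
    conservation can be checked replicate by replicate.
    """

    mean: pd.DataFrame
    se: pd.DataFrame
    n_reps: int
    family_ids: list[str] = field(default_factory=list)
    counts: np.ndarray | None = None

    @property
    def areas(self) -> list[str]:
        return list(self.mean.index)


def laplace_rule(k: int, n: int) -> float:
    """Rule of Succession: posterior mean (k+1)/(n+2) of a Bernoulli rate."""
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    return (k + 1) / (n + 2)


def estimate_area_model(
    large_estimates: Sequence[BiasEstimate], area: str
) -> AreaBiasModel:
    """Estimate Pr(bias) and Pr(deviation) for one area from large families.

    Mean strength averages over *biased* large families only (strength is
    undefined as a bias property for unbiased ones).  With no biased large
    family in the area, mean strength defaults to 1 (no deviation) with a
    warning.
    """
    ests = [e for e in large_estimates if not e.area or e.area == area]
    n = len(ests)
    biased = [e for e in ests if e.biased]
    k = len(biased)
    pr_bias = laplace_rule(k, n)
    if biased:
        mean_strength = float(np.mean([e.strength for e in biased]))
    else:
        warnings.warn(f"area {area!r}: no biased large families; "
                      "Pr(deviation) defaults to 0")
        mean_strength = 1.0
    return AreaBiasModel(
        area=area, pr_bias=pr_bias, pr_deviation=1.0 - mean_strength,
        n_large=n, n_large_biased=k, mean_strength=mean_strength,
    )


def small_family_direction(family: FamilyDataset, rng: np.random.Generator) -> str:
    """Majority trait value of the survivors; a fair coin breaks exact ties."""
    k = sum(family.trials)
    n = family.n_trials
    if 2 * k > n:
        return TOWARD
    if 2 * k < n:
        return AGAINST
    return TOWARD if rng.random() < 0.5 else AGAINST


def extrapolate(
    small_families: Sequence[FamilyDataset],
    area_models: Mapping[str, AreaBiasModel],
    n_reps: int = 10_000,
    seed: int = 0,
    force: bool = False,
    keep_counts: bool = True,
) -> AreaBiasSummary:
    """Monte-Carlo extrapolation of bias directions for small families.

    Every replicate uses its own RNG stream spawned from the master seed, so
    single replicates are reproducible independently of ordering.  Returns
    per-area mean counts over replicates with SE = sd/sqrt(n_reps).
    """
    if n_reps < 100 and not force:
        raise ValueError("n_reps < 100 gives unreliable SEs (pass force=True)")
    for fam in small_families:
        if fam.is_large:
            raise ValueError(f"family {fam.family_id!r} is not small")
        if fam.area not in area_models:
            raise ValueError(f"no area model for {fam.area!r}")

    areas = sorted({f.area for f in small_families} | set(area_models))
    area_idx = {a: i for i, a in enumerate(areas)}
    n_fam = len(small_families)
    fam_area = np.array([area_idx[f.area] for f in small_families], dtype=np.intp)
    pr_bias = np.array([area_models[f.area].pr_bias for f in small_families])
    pr_dev = np.array([area_models[f.area].pr_deviation for f in small_families])
    # base direction: 1 = E majority, 0 = A majority, -1 = tie (coin per rep)
    base = np.empty(n_fam, dtype=np.int8)
    for i, f in enumerate(small_families):
        k, n = sum(f.trials), f.n_trials
        base[i] = 1 if 2 * k > n else (0 if 2 * k < n else -1)

    counts = np.zeros((n_reps, len(areas), 3), dtype=np.int32)
    streams = np.random.SeedSequence(seed).spawn(n_reps)
    dir_col = {NONE: 0, AGAINST: 1, TOWARD: 2}
    for r in range(n_reps):
        rng = np.random.default_rng(streams[r])
        biased = rng.random(n_fam) < pr_bias
        d = base.copy()
        ties = d == -1
        if ties.any():
            d[ties] = rng.random(int(ties.sum())) < 0.5
        deviate = rng.random(n_fam) < pr_dev
        d = np.where(deviate, 1 - d, d)
        final = np.where(biased, np.where(d == 1, 2, 1), 0)  # 0 none,1 A,2 E
        for j in range(3):
            np.add.at(counts[r, :, j], fam_area[final == j], 1)
    mean = counts.mean(axis=0)
    se = counts.std(axis=0, ddof=0) / np.sqrt(n_reps)
    cols = list(DIRECTIONS)
    mean_df = pd.DataFrame(mean, index=areas, columns=cols)
    se_df = pd.DataFrame(se, index=areas, columns=cols)
    return AreaBiasSummary(
        mean=mean_df, se=se_df, n_reps=n_reps,
        family_ids=[f.family_id for f in small_families],
        counts=counts if keep_counts else None,
    )


def combine_counts(
    large_estimates: Sequence[BiasEstimate],
    small_summary: AreaBiasSummary,
) -> AreaBiasSummary:
    """Total per-area counts: deterministic large families + small-family means.

    Large families contribute 1 to their estimated direction (including
    ``none``); their SE contribution is zero, so the total SEs are carried
    over from the small-family component.
    """
    overlap = set(e.family_id for e in large_estimates) & set(small_summary.family_ids)
    if overlap:
        raise ValueError(f"families in both inputs: {sorted(overlap)}")
    areas = sorted(set(small_summary.areas) | {e.area for e in large_estimates})
    cols = list(DIRECTIONS)
    large = pd.DataFrame(0.0, index=areas, columns=cols)
    for e in large_estimates:
        large.loc[e.area, e.direction] += 1
    mean = large.add(small_summary.mean.reindex(areas, fill_value=0.0))
    se = small_summary.se.reindex(areas, fill_value=0.0)
    return AreaBiasSummary(
        mean=mean, se=se, n_reps=small_summary.n_reps,
        family_ids=[e.family_id for e in large_estimates] + small_summary.family_ids,
    )
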