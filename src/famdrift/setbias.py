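"""Set-based bias detection: exact binomial tests on a family's trial values.

The set-based method treats every trait value at the tips of a family as one
independent binomial trial in the family's history and reads a significant
majority as a directed bias — either the proto-language had the value and
the family preferentially kept it, or it was innovated early or repeatedly.
No tree, and no branch lengths, are assumed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from scipy.stats import binomtest

from .corpus import FamilyDataset

#: direction codes: A = against ergatives, E = towards ergatives
AGAINST = "A"
TOWARD = "E"
NONE = "none"


@dataclass
class BiasEstimate:
    """Direction, strength and evidence of one family's estimated bias.

    ``strength`` is the proportion of the majority value among the trials
    (>= 0.5 by construction); it is reported even when ``direction`` is
    ``"none"`` but unused downstream in that case.  ``evidence`` is a
    p-value for the set-based and ML methods and a log Bayes factor for the
    MCMC method.
    """

    family_id: str
    method: str  # set_binomial | tree_ml | tree_mcmc
    direction: str  # A | E | none
    strength: float
    evidence: float
    n_trials: int
    area: str = ""
    taxonomy: str = ""

    @property
    def biased(self) -> bool:
        return self.direction != NONE


def family_bias_binomial(
    trials: Sequence[int],
    alpha: float = 0.05,
    p0: float = 0.5,
    alternative: str = "two-sided",
) -> BiasEstimate:
    """Exact binomial test of one family's trials against chance.

    ``k`` ergative trials out of ``n`` are tested against success probability
    ``p0`` (default 0.5).  If the test is significant at ``alpha`` the
    direction is the majority value's side (E when ergatives dominate,
    A otherwise); otherwise no bias is called.  Strength is
    ``max(k, n-k)/n``, the majority proportion.
    """
    n = len(trials)
    if n == 0:
        raise ValueError("empty trial list")
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0,1), got {alpha}")
    k = int(sum(trials))
    p = binomtest(k, n, p0, alternative=alternative).pvalue
    strength = max(k, n - k) / n
    if p <= alpha:
        direction = TOWARD if k > n - k else AGAINST
    else:
        direction = NONE
    return BiasEstimate(
        family_id="",
        method="set_binomial",
        direction=direction,
        strength=strength,
        evidence=p,
        n_trials=n,
    )


def classify_large_families(
    families: Sequence[FamilyDataset],
    alpha: float = 0.05,
    p0: float = 0.5,
) -> list[BiasEstimate]:
    """Apply the set-based test to every large family; deterministic."""
    out = []
    for fam in families:
        if not fam.is_large:
            raise ValueError(
                f"family {fam.family_id!r} has {fam.n_languages} languages; "
                f"set-based classification expects large families (>= {fam.cutoff})"
            )
        est = family_bias_binomial(fam.trials, alpha=alpha, p0=p0)
        est.family_id = fam.family_id
        est.area = fam.area
        est.taxonomy = fam.taxonomy
        out.append(est)
    return out
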