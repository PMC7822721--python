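"""Activity-period extraction and morningness-eveningness ranking.

Each fitted mixture component is one daily activity period: its mean is
the peak hour of call activity, its standard deviation the period's
spread, and its mixing proportion the share of the person's calls it
accounts for.  Ranking the periods by descending mixing proportion
identifies the time of day when the person is most socially active.

No morningness/eveningness label is assigned here: the label comes from
cluster membership downstream, not from a clock threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .rhythm_model import MixtureFit

#: mixing proportions closer than this are considered tied
WEIGHT_TIE_TOL = 1e-9


@dataclass(frozen=True)
class ActivityPeriod:
    """One daily activity period: peak hour mu_k in [0, 24), spread
    sigma_k in hours, and mixing proportion pi_k."""

    peak_hour: float
    spread: float
    weight: float

    def __post_init__(self) -> None:
        if not 0.0 < self.weight <= 1.0:
            raise ValueError("weight must lie in (0, 1]")
        if self.spread <= 0:
            raise ValueError("spread must be positive")


@dataclass
class ModeRanking:
    """A person's activity periods in descending order of weight."""

    person_id: str
    periods: list[ActivityPeriod]

    @property
    def primary(self) -> ActivityPeriod:
        return self.periods[0]

    @property
    def secondary(self) -> ActivityPeriod:
        if len(self.periods) < 2:
            raise ValueError(f"{self.person_id}: no secondary period (K=1 fit)")
        return self.periods[1]


def extract_modes(fit: MixtureFit) -> list[ActivityPeriod]:
    """One :class:`ActivityPeriod` per mixture component, carrying
    (mean, sqrt(variance), weight) verbatim from the fit."""
    return [
        ActivityPeriod(
            peak_hour=float(mu), spread=float(np.sqrt(var)), weight=float(w)
        )
        for mu, var, w in zip(fit.means, fit.variances, fit.weights)
    ]


def rank_modes(periods: list[ActivityPeriod], person_id: str = "") -> ModeRanking:
    """Sort periods by descending mixing proportion.

    Weights within 1e-9 of each other are tied; the tie goes to the
    earlier peak hour so that the ranking is deterministic.
    """
    if not periods:
        raise ValueError("cannot rank an empty period list")
    # quantize weights at the tie tolerance so near-equal weights
    # compare as equal, then fall back to the earlier peak
    ordered = sorted(
        periods,
        key=lambda p: (-round(p.weight / WEIGHT_TIE_TOL), p.peak_hour),
    )
    return ModeRanking(person_id=person_id, periods=ordered)
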