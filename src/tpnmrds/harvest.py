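"""Harvest-rate estimation from reported legal harvest and abundance.

Where hunting is open only every other regulatory year (a biennial scheme),
annual harvest is reported as the mean of the closed and open years.  The
legal harvest rate against a post-hunt abundance estimate N̂ is

    r = H / (H + N̂),

its 95% interval comes from the abundance interval by the same monotone map
(upper rate limit from the lower abundance limit and vice versa), and its
standard error applies the abundance CV to the rate.  Unreported harvest is
not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

__all__ = ["HarvestInput", "HarvestRate", "effective_annual_harvest", "harvest_rate"]


@dataclass
class HarvestInput:
    """Reported legal harvest counts for one stratum.

    ``scheme`` is ``"annual"`` (one year's count) or ``"biennial"``
    (exactly two consecutive regulatory years, averaged).
    """

    counts: Sequence[int]
    scheme: str = "annual"

    def __post_init__(self):
        if any(c < 0 or int(c) != c for c in self.counts):
            raise ValueError("harvest counts must be non-negative integers")
        if self.scheme not in ("annual", "biennial"):
            raise ValueError(f"unknown harvest scheme {self.scheme!r}")
        if self.scheme == "biennial" and len(self.counts) != 2:
            raise ValueError("biennial scheme requires exactly 2 consecutive years")
        if self.scheme == "annual" and len(self.counts) != 1:
            raise ValueError("annual scheme takes a single year's count")


@dataclass
class HarvestRate:
    rate: float
    se: float
    lower95: float
    upper95: float
    harvest: float
    abundance: float

    def as_percent(self) -> dict:
        return {"rate_pct": 100 * self.rate, "se_pct": 100 * self.se,
                "lower95_pct": 100 * self.lower95, "upper95_pct": 100 * self.upper95}


def effective_annual_harvest(inp: HarvestInput) -> float:
    """Bears per year: the single count, or the biennial (closed+open)/2 mean."""
    if inp.scheme == "biennial":
        return sum(inp.counts) / 2.0
    return float(inp.counts[0])


def harvest_rate(harvest: float, abundance: float, cv: float,
                 lower95: float, upper95: float) -> HarvestRate:
    """Harvest rate H/(H + N̂) with CI inherited from the abundance CI.

    ``abundance``/``cv``/``lower95``/``upper95`` describe the post-hunt
    abundance estimate (e.g. a :class:`~tpnmrds.mrds_estimator.StratumEstimate`'s
    fields).  The rate interval maps the abundance interval monotonically:
    a smaller population means a larger rate.
    """
    if harvest < 0:
        raise ValueError("harvest must be >= 0")
    if harvest == 0 and abundance == 0:
        raise ValueError("harvest rate undefined: no harvest and no animals")
    rate = harvest / (harvest + abundance)
    return HarvestRate(
        rate=rate,
        se=cv * rate,
        lower95=harvest / (harvest + upper95) if harvest > 0 else 0.0,
        upper95=harvest / (harvest + lower95) if harvest > 0 else 0.0,
        harvest=harvest,
        abundance=abundance,
    )
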