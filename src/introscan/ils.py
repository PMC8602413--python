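"""Incomplete-lineage-sorting tract-length null model.

Under neutral coalescence, a tract shared between two species through
retained ancestral polymorphism is broken up by recombination; its
expected length is L = 1/(r * t), with r the per-bp per-generation
recombination rate and t the branch length in generations since the
species split. The length of such a tract follows (approximately) a
Gamma distribution with shape 2 and rate 1/L, so the probability that a
shared tract is at least m bp long is the Erlang-2 survival function

    P(length >= m) = 1 - GammaCDF(m; shape=2, rate=1/L)
                   = exp(-m/L) * (1 + m/L).

An observed putatively introgressed tract far longer than L, with a
negligible survival probability, cannot plausibly be explained by
incomplete lineage sorting. Probabilities below the double-precision
floor are reported as exactly 0.

t is taken as divergence_years / generation_time; set ``two_branches``
to double it (counting both descending branches of the split).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from scipy.stats import gamma

__all__ = ["ILSQuery", "expected_tract_length", "ils_survival_probability",
           "generations_to_years", "evaluate_query"]

log = logging.getLogger(__name__)


def expected_tract_length(r: float, divergence_years: float,
                          generation_time: float,
                          two_branches: bool = False) -> float:
    """Expected shared ancestral tract length L = 1/(r*t) in bp.

    t = divergence_years / generation_time generations (doubled when
    ``two_branches`` counts both post-split branches).
    """
    if r <= 0 or divergence_years <= 0 or generation_time <= 0:
        raise ValueError("all parameters must be positive")
    t = divergence_years / generation_time
    if two_branches:
        t *= 2.0
    return 1.0 / (r * t)


def ils_survival_probability(m: float, L: float) -> float:
    """P(shared ancestral tract length >= m) under the Gamma(2, rate=1/L)
    null; equals exp(-m/L) * (1 + m/L). Monotone decreasing in m."""
    if L <= 0:
        raise ValueError("expected tract length L must be positive")
    if m < 0:
        raise ValueError("tract length m must be non-negative")
    p = float(gamma.sf(m, a=2.0, scale=L))
    if p == 0.0:
        log.info("ILS survival underflows double precision (m/L = %.3g); "
                 "reporting 0", m / L)
    return p


def generations_to_years(generations: float, generation_time: float) -> float:
    """Convert an age in generations to years BP."""
    if generations < 0 or generation_time <= 0:
        raise ValueError("generations must be >= 0 and generation time > 0")
    return generations * generation_time


@dataclass
class ILSQuery:
    """One ILS evaluation: recombination rate r (per bp per generation),
    species divergence in years, generation time in years, and an observed
    tract length m in bp."""

    r: float
    divergence_years: float
    generation_time: float
    m: float
    two_branches: bool = False

    @property
    def t_generations(self) -> float:
        t = self.divergence_years / self.generation_time
        return 2.0 * t if self.two_branches else t

    @property
    def expected_length(self) -> float:
        return expected_tract_length(self.r, self.divergence_years,
                                     self.generation_time, self.two_branches)


def evaluate_query(q: ILSQuery) -> dict:
    """L and ILS survival probability for one query, as a flat record."""
    L = q.expected_length
    return {"r": q.r, "divergence_years": q.divergence_years,
            "generation_time": q.generation_time, "m": q.m,
            "t_generations": q.t_generations, "L_bp": L,
            "p_ils": ils_survival_probability(q.m, L)}
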