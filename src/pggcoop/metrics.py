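"""Outcome measures: cooperation trajectories, asymptotic cooperation
levels, CCC-strategy distributions, and the two closed-form noise-limit
predictions (beta = 0 coin tossing, beta = infinity perfect information).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Binning",
    "SummaryStats",
    "cooperation_level",
    "asymptotic_cooperation",
    "ccc_distribution",
    "summarize",
    "expected_coop_beta_zero",
    "expected_coop_beta_inf",
]


class Binning(enum.Enum):
    EXACT = "exact"  # one bin per integer CCC value
    TENS = "tens"  # CCC=0 separate, then (0,10], (10,20], ...


@dataclass(frozen=True)
class SummaryStats:
    """Replicate-aggregated summary of one experimental condition.

    ``asymptotic_coop`` is the mean cooperation level over the final window
    of each replicate, averaged over replicates (a fraction in [0, 1]);
    ``asymptotic_sd`` the between-replicate standard deviation of those
    window means.  The CCC histogram and the zero / >50 fractions describe
    all agents (altruists included) at the final generation.
    """

    asymptotic_coop: float
    asymptotic_sd: float
    ccc_hist: dict
    frac_ccc_zero: float
    frac_ccc_gt50: float


def cooperation_level(contributions: np.ndarray) -> float:
    """Fraction of agents with a non-zero contribution."""
    c = np.asarray(contributions)
    if c.size == 0:
        raise ValueError("empty contribution vector")
    return float(np.count_nonzero(c) / c.size)


def _window_means(trajectories, window: int) -> np.ndarray:
    means = []
    for t in trajectories:
        if window > len(t.coop_levels):
            raise ValueError(
                f"window {window} exceeds trajectory length "
                f"{len(t.coop_levels)}"
            )
        means.append(float(np.mean(t.coop_levels[-window:])))
    return np.asarray(means)


def asymptotic_cooperation(trajectories, window: int) -> tuple[float, float]:
    """Mean and between-replicate sd of the final-window cooperation level.

    Each replicate contributes the mean of its last ``window`` generations;
    the sd is over those per-replicate means (ddof=1 when possible).
    """
    means = _window_means(trajectories, window)
    sd = float(np.std(means, ddof=1)) if len(means) > 1 else 0.0
    return float(np.mean(means)), sd


def ccc_distribution(
    trajectories, binning: Binning = Binning.EXACT
) -> tuple[dict, float, float]:
    """Final-generation CCC histogram pooled over replicates.

    Returns (histogram, frac_ccc_zero, frac_ccc_gt50).  With EXACT binning
    the keys are integer CCC values; with TENS, the key ``0`` holds the
    CCC=0 spike on its own and ``"(lo,hi]"`` keys hold 10-wide bins.
    Fractions are of all agents, altruists included.
    """
    all_ccc = np.concatenate([np.asarray(t.final_ccc) for t in trajectories])
    n_total = all_ccc.size
    frac_zero = float(np.count_nonzero(all_ccc == 0) / n_total)
    frac_gt50 = float(np.count_nonzero(all_ccc > 50) / n_total)

    if binning is Binning.EXACT:
        values, counts = np.unique(all_ccc, return_counts=True)
        hist = {int(v): float(c / n_total) for v, c in zip(values, counts)}
    else:
        hist = {0: frac_zero}
        top = int(all_ccc.max()) if n_total else 0
        for lo in range(0, max(top, 1), 10):
            hi = lo + 10
            frac = float(
                np.count_nonzero((all_ccc > lo) & (all_ccc <= hi)) / n_total
            )
            hist[f"({lo},{hi}]"] = frac
    return hist, frac_zero, frac_gt50


def summarize(trajectories, window: int) -> SummaryStats:
    """Reduce an experiment's trajectories to a :class:`SummaryStats`."""
    mean, sd = asymptotic_cooperation(trajectories, window)
    hist, frac_zero, frac_gt50 = ccc_distribution(trajectories)
    return SummaryStats(
        asymptotic_coop=mean,
        asymptotic_sd=sd,
        ccc_hist=hist,
        frac_ccc_zero=frac_zero,
        frac_ccc_gt50=frac_gt50,
    )


def expected_coop_beta_zero(altruist_fraction: float, n_agents: int = 100) -> float:
    """Analytic cooperation level in the maximal-noise limit (beta = 0).

    Altruists always contribute while every other agent tosses a coin, so
    the expected contributor fraction is alpha + (1 - alpha) / 2.
    """
    if not (0 <= altruist_fraction <= 1):
        raise ValueError("altruist_fraction must lie in [0, 1]")
    return altruist_fraction + (1.0 - altruist_fraction) / 2.0


def expected_coop_beta_inf(altruist_fraction: float) -> float:
    """Analytic cooperation level in the noise-free limit (beta = infinity)
    with fully stubborn altruists: every conditional cooperator ends up free
    riding, so cooperation equals the altruist fraction."""
    if not (0 <= altruist_fraction <= 1):
        raise ValueError("altruist_fraction must lie in [0, 1]")
    return float(altruist_fraction)
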