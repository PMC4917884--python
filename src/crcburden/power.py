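"""Simulation-based power of the case/control design.

Power is estimated over a carrier-frequency x relative-risk grid under a
dominant single-locus model.  The control carrier frequency is the baseline;
the case frequency is a weighted average of the enrichment in cases with one,
two and three affected first-degree relatives.  For a case whose family holds
``k`` affected first-degree relatives, Bayes' rule under the dominant model
with allele-sharing probability 1/2 gives the carrier frequency

    f_k = p0 * RR * lam_c**k / (p0 * RR * lam_c**k + (1 - p0)),
    lam_c = (1 + RR) / 2

since each affected relative of a carrier case carries the allele (and its
RR-fold risk) with probability 1/2, while relatives of non-carriers are at
baseline risk.  Each grid cell draws carrier counts binomially, applies a
one-sided Fisher test, and reports the rejection fraction at exome-wide
alpha.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, norm

FREQ_RANGE = (0.00001, 0.01)
RR_RANGE = (1.75, 4.0)
DEFAULT_REPS = 10_000
DEFAULT_ALPHA = 8.0e-7
DEFAULT_FH_WEIGHTS = (0.85, 0.12, 0.03)


@dataclass(frozen=True)
class EnrichmentModel:
    """Dominant-model case-frequency enrichment by family-history stratum."""
    p0: float
    rr: float
    fh_weights: Tuple[float, float, float] = DEFAULT_FH_WEIGHTS

    def stratum_frequency(self, k: int) -> float:
        """Carrier frequency among cases with ``k`` affected first-degree
        relatives."""
        lam_c = (1.0 + self.rr) / 2.0
        num = self.p0 * self.rr * lam_c ** k
        return num / (num + (1.0 - self.p0))

    def case_frequency(self) -> float:
        f = sum(w * self.stratum_frequency(k + 1)
                for k, w in enumerate(self.fh_weights))
        if f > 1.0:
            raise ValueError("enrichment model yields case frequency > 1")
        return f


def case_frequency(p0: float, rr: float,
                   fh_weights: Sequence[float] = DEFAULT_FH_WEIGHTS) -> float:
    """Weighted-average case carrier frequency across family-history strata."""
    if not (0.0 < p0 < 0.5):
        raise ValueError("baseline frequency must lie in (0, 0.5)")
    if rr < 1.0:
        raise ValueError("relative risk must be >= 1")
    if abs(sum(fh_weights) - 1.0) > 1e-9:
        raise ValueError("family-history weights must sum to 1")
    return EnrichmentModel(p0, rr, tuple(fh_weights)).case_frequency()


def one_sided_fisher_p(k_case, k_control, n_cases: int, n_controls: int):
    """Vectorised one-sided (case-enrichment) Fisher P on carrier counts."""
    k_case = np.asarray(k_case)
    K = k_case + np.asarray(k_control)
    N = n_cases + n_controls
    return hypergeom.sf(k_case - 1, N, K, n_cases)


def simulate_power_cell(p_case: float, p_control: float, n_cases: int,
                        n_controls: int, alpha: float = DEFAULT_ALPHA,
                        reps: int = DEFAULT_REPS, seed=0):
    """Monte-Carlo rejection rate of the one-sided Fisher test for one cell.

    Returns ``(power, mc_se)`` with ``mc_se = sqrt(p(1-p)/reps)``.
    """
    if not (0.0 < p_case < 1.0 and 0.0 < p_control < 1.0):
        raise ValueError("frequencies must lie in (0,1)")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    k_case = rng.binomial(n_cases, p_case, size=reps)
    k_ctrl = rng.binomial(n_controls, p_control, size=reps)
    p = one_sided_fisher_p(k_case, k_ctrl, n_cases, n_controls)
    power = float((p <= alpha).mean())
    return power, float(np.sqrt(power * (1.0 - power) / reps))


def analytic_power(p_case: float, p_control: float, n_cases: int,
                   n_controls: int, alpha: float = DEFAULT_ALPHA) -> float:
    """Normal-approximation power of the one-sided two-proportion test;
    used as an independent cross-check of the simulation for cells with
    adequate expected counts."""
    p_bar = (n_cases * p_case + n_controls * p_control) / (n_cases + n_controls)
    se0 = np.sqrt(p_bar * (1 - p_bar) * (1 / n_cases + 1 / n_controls))
    se1 = np.sqrt(p_case * (1 - p_case) / n_cases
                  + p_control * (1 - p_control) / n_controls)
    z_a = norm.isf(alpha)
    return float(norm.sf((z_a * se0 - (p_case - p_control)) / se1))


def power_surface(freqs: Sequence[float], rrs: Sequence[float],
                  n_cases: int = 1006, n_controls: int = 1609,
                  alpha: float = DEFAULT_ALPHA, reps: int = DEFAULT_REPS,
                  fh_weights: Sequence[float] = DEFAULT_FH_WEIGHTS,
                  seed=0) -> pd.DataFrame:
    """Fill the frequency x relative-risk power grid.

    Returns a table with columns ``freq, rr, p_case, power, mc_se, reps,
    alpha, powered`` where ``powered`` flags cells with power >= 0.8.
    """
    root = np.random.SeedSequence(seed)
    children = iter(root.spawn(len(freqs) * len(rrs)))
    rows = []
    for f in freqs:
        for rr in rrs:
            pc = case_frequency(f, rr, fh_weights)
            power, se = simulate_power_cell(
                pc, f, n_cases, n_controls, alpha, reps, next(children))
            rows.append((f, rr, pc, power, se, reps, alpha, power >= 0.8))
    return pd.DataFrame(rows, columns=["freq", "rr", "p_case", "power",
                                       "mc_se", "reps", "alpha", "powered"])
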