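"""Molecular-clock arithmetic and the net-divergence split-time estimator."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .types import GenotypeTable, MISSING

__all__ = [
    "ClockParams",
    "CalibrationPrior",
    "cp_clock_time",
    "generations_to_years",
    "find_ne_minima",
    "net_divergence",
    "net_divergence_split_time",
    "build_calibration",
]


@dataclass
class ClockParams:
    """Mutation clock: per-year rate, or per-generation rate + generation
    time in years."""

    mutation_rate_per_year: Optional[float] = None
    mutation_rate_per_generation: Optional[float] = None
    generation_time: Optional[float] = None
    n_sites: Optional[int] = None

    @property
    def mu_per_year(self) -> float:
        if self.mutation_rate_per_year is not None:
            mu = self.mutation_rate_per_year
        elif (
            self.mutation_rate_per_generation is not None
            and self.generation_time is not None
        ):
            if self.generation_time <= 0:
                raise ValueError("generation_time must be > 0")
            mu = self.mutation_rate_per_generation / self.generation_time
        else:
            raise ValueError(
                "need mutation_rate_per_year or (mutation_rate_per_generation "
                "and generation_time)"
            )
        if mu <= 0:
            raise ValueError("mutation rate must be > 0")
        return mu


def cp_clock_time(k: float, params: ClockParams) -> float:
    """Divergence time in years from ``k`` mutation steps: t = k / (2 mu L)."""
    if k < 0:
        raise ValueError("mutation steps must be >= 0")
    if not params.n_sites or params.n_sites <= 0:
        raise ValueError("params.n_sites must be a positive site count")
    return k / (2.0 * params.mu_per_year * params.n_sites)


def generations_to_years(g_count: float, gen_time: float) -> float:
    """Plain product: generations x years-per-generation."""
    if g_count < 0 or gen_time < 0:
        raise ValueError("inputs must be non-negative")
    return g_count * gen_time


def find_ne_minima(
    trajectory: Sequence[tuple[float, float]],
    ignore_recent: float = 1000.0,
) -> list[tuple[float, float]]:
    """Local minima of log N_e over steps older than ``ignore_recent``.

    ``trajectory`` is ordered (generations-before-present, N_e) with
    strictly increasing times.  Interior strict minima only.
    """
    t = np.array([x[0] for x in trajectory], dtype=float)
    ne = np.array([x[1] for x in trajectory], dtype=float)
    if t.size < 3:
        raise ValueError("trajectory needs >= 3 steps")
    if (np.diff(t) <= 0).any():
        raise ValueError("times must be strictly increasing")
    if (ne <= 0).any():
        raise ValueError("N_e must be > 0")
    log_ne = np.log(ne)
    out = []
    for i in range(1, t.size - 1):
        if t[i] <= ignore_recent:
            continue
        if log_ne[i] < log_ne[i - 1] and log_ne[i] < log_ne[i + 1]:
            out.append((float(t[i]), float(ne[i])))
    return out


# ----------------------------------------------------------------------
# net-divergence estimator
# ----------------------------------------------------------------------
def _per_site_stats(
    table: GenotypeTable, samples_a: Sequence[str], samples_b: Sequence[str]
) -> tuple[float, float, float]:
    """(d_xy, pi_a, pi_b) per bp, requiring ``table.seq_length``."""
    if table.seq_length is None:
        raise ValueError("table.seq_length required for per-bp scaling")
    ia = [table.sample_index(s) for s in samples_a]
    ib = [table.sample_index(s) for s in samples_b]
    ga = table.genotypes[:, ia]
    gb = table.genotypes[:, ib]
    if (ga == MISSING).any() or (gb == MISSING).any():
        raise ValueError("net divergence requires complete genotype calls")

    def _freq_and_pi(g: np.ndarray) -> tuple[np.ndarray, float]:
        n = g.shape[1] * 2
        alt = (g > 0).sum(axis=(1, 2)).astype(float)
        p = alt / n
        pi = (2.0 * alt * (n - alt) / (n * (n - 1.0))).sum() / table.seq_length
        return p, float(pi)

    pa, pi_a = _freq_and_pi(ga)
    pb, pi_b = _freq_and_pi(gb)
    dxy = float((pa * (1 - pb) + pb * (1 - pa)).sum() / table.seq_length)
    return dxy, pi_a, pi_b


def net_divergence(
    table: GenotypeTable, samples_a: Sequence[str], samples_b: Sequence[str]
) -> float:
    """d_a = d_xy - (pi_A + pi_B) / 2, per bp."""
    dxy, pi_a, pi_b = _per_site_stats(table, samples_a, samples_b)
    return dxy - (pi_a + pi_b) / 2.0


def net_divergence_split_time(
    table: GenotypeTable,
    samples_a: Sequence[str],
    samples_b: Sequence[str],
    params: ClockParams,
) -> float:
    """Split time in years: T = d_a / (2 mu_per_year); clipped at 0.

    A negative d_a (drift noise around very recent splits) returns 0.
    """
    da = net_divergence(table, samples_a, samples_b)
    if da < 0:
        import warnings

        warnings.warn("negative net divergence; returning 0 (drift noise)")
        return 0.0
    return da / (2.0 * params.mu_per_year)


@dataclass
class CalibrationPrior:
    """Lognormal node-age calibration: real-space mean (mya) and log-space
    standard deviation."""

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.mean <= 0 or self.sd <= 0:
            raise ValueError("mean and sd must be > 0")

    @property
    def _dist(self):
        # real-space mean m with log-sd s  =>  log-mean = ln(m) - s^2/2
        mu_log = np.log(self.mean) - self.sd**2 / 2.0
        return sps.lognorm(self.sd, scale=np.exp(mu_log))

    def density(self, x: float) -> float:
        return float(self._dist.pdf(x))

    def quantile(self, q: float) -> float:
        return float(self._dist.ppf(q))

    @property
    def median(self) -> float:
        return self.quantile(0.5)


def build_calibration(mean: float, sd: float) -> CalibrationPrior:
    """Record a lognormal calibration prior for reporting."""
    return CalibrationPrior(mean=mean, sd=sd)


def dating_report(rows: Sequence[dict]) -> pd.DataFrame:
    """Assemble a dating-result table (node, method, years, extras)."""
    return pd.DataFrame(rows)
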