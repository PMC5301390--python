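"""Convergence diagnostics and burn-in estimation for single MCMC chains.

Three standard diagnostics are provided:

* **Geweke** — compares the mean of the first 10% of the chain with the
  mean of the last 50%, standardised by autocorrelation-adjusted standard
  errors.  Under stationarity the statistic is asymptotically N(0, 1).
  The adjusted variance of each window is ``s^2 * n / ESS``, reusing the
  initial-positive-sequence ESS estimator rather than a windowed
  periodogram.
* **Gelman-Rubin** — the potential scale reduction factor (PSRF)
  comparing between- and within-chain variance across parallel chains;
  values near 1 indicate convergence.  Applied to a single chain, the
  post-burn-in series is split into first/second halves as two
  pseudo-chains.
* **ESS-maximising burn-in** — evaluates candidate burn-ins on a grid
  and picks the one that maximises the effective sample size of the
  remaining samples, in the spirit of Hohna-Sahlin style automatic
  burn-in selection.

``verdict`` combines all three into a per-parameter convergence call with
the conventional thresholds |z| < 1.96, PSRF < 1.1 and ESS >= 200.  The
ESS >= 200 rule of thumb has no theoretical justification — an ESS of 200
still implies a computational uncertainty near 28% of the posterior SD —
so the threshold is configurable and the report carries every component
for callers wanting stricter rules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from .summary_stats import NumericSeries, Z_975, ess, _as_array

__all__ = [
    "DiagnosticsReport",
    "GewekeBurnin",
    "geweke",
    "gelman_rubin",
    "estimate_burnin_ess",
    "estimate_burnin_geweke",
    "verdict",
]

PSRF_MAX_DEFAULT = 1.1
ESS_MIN_DEFAULT = 200


@dataclass
class DiagnosticsReport:
    """Per-parameter convergence diagnostics at the suggested burn-in."""

    parameter: str
    geweke_z: float
    psrf: float
    burnin_geweke: int
    burnin_ess: int
    burnin_suggested: int
    ess_at_suggested: float
    converged: bool
    thresholds: dict


class GewekeBurnin(NamedTuple):
    burnin: int
    passed: bool


def _adjusted_se2(window: np.ndarray) -> float:
    """Autocorrelation-adjusted squared standard error of a window mean:
    s^2 * (n/ESS) / n = s^2 / ESS."""
    s2 = float(np.var(window, ddof=1))
    if s2 == 0.0:
        return 0.0
    return s2 / ess(window)


def geweke(
    series: "NumericSeries | Sequence[float]",
    first: float = 0.1,
    last: float = 0.5,
) -> float:
    """Geweke convergence z-score comparing early and late window means.

    Windows default to the classical first 10% / last 50%.  Requires at
    least 100 samples so each window supports an ESS estimate.  Returns
    0.0 when both windows have zero variance.
    """
    x = _as_array(series)
    n = len(x)
    if n < 100:
        raise ValueError(f"geweke requires at least 100 samples, got {n}")
    a = x[: int(first * n)]
    b = x[n - int(last * n):]
    se2 = _adjusted_se2(a) + _adjusted_se2(b)
    if se2 == 0.0:
        return 0.0
    return float((a.mean() - b.mean()) / math.sqrt(se2))


def gelman_rubin(chains: Sequence["NumericSeries | Sequence[float]"]) -> float:
    """Potential scale reduction factor over length-matched parallel chains.

    PSRF = sqrt(((n-1)/n * W + B/n) / W) with W the mean within-chain
    variance and B/n the (ddof=1) variance of the chain means.  Identical
    chains give the floor sqrt((n-1)/n); zero within-chain variance with
    differing means returns +inf as a divergence signal.
    """
    arrays = [_as_array(c) for c in chains]
    if len(arrays) < 2:
        raise ValueError("gelman_rubin requires at least 2 chains")
    n = len(arrays[0])
    if n < 10:
        raise ValueError("chains must have length >= 10")
    if any(len(a) != n for a in arrays):
        raise ValueError("chains must be length-matched")
    w = float(np.mean([np.var(a, ddof=1) for a in arrays]))
    b_over_n = float(np.var([a.mean() for a in arrays], ddof=1))
    if w == 0.0:
        return 1.0 if b_over_n == 0.0 else math.inf
    return math.sqrt(((n - 1) / n * w + b_over_n) / w)


def _burnin_grid(n: int, grid_step: float, max_burnin_frac: float) -> list[int]:
    fracs = np.arange(0.0, max_burnin_frac + 1e-12, grid_step)
    grid = sorted({int(round(f * n)) for f in fracs})
    return [b for b in grid if b < n]


def estimate_burnin_ess(
    series: "NumericSeries | Sequence[float]",
    grid_step: float = 0.01,
    max_burnin_frac: float = 0.5,
) -> int:
    """Burn-in that maximises the ESS of the retained samples.

    Candidates are the grid {0, step, 2*step, ..., max_frac} * n; ties
    break toward the smaller burn-in.  Deterministic given the series.
    """
    x = _as_array(series)
    n = len(x)
    if n < 200:
        raise ValueError(f"estimate_burnin_ess requires >= 200 samples, got {n}")
    best_b, best_e = 0, -math.inf
    for b in _burnin_grid(n, grid_step, max_burnin_frac):
        e = ess(x[b:])
        if e > best_e:
            best_b, best_e = b, e
    return best_b


def estimate_burnin_geweke(
    series: "NumericSeries | Sequence[float]",
    grid_step: float = 0.01,
    max_burnin_frac: float = 0.5,
    z_crit: float = Z_975,
) -> GewekeBurnin:
    """Smallest grid burn-in whose retained samples pass the Geweke test.

    If no candidate passes, returns ``max_burnin_frac * n`` with
    ``passed=False`` (the chain is flagged non-converged).
    """
    x = _as_array(series)
    n = len(x)
    if n < 200:
        raise ValueError(f"estimate_burnin_geweke requires >= 200 samples, got {n}")
    last = 0
    for b in _burnin_grid(n, grid_step, max_burnin_frac):
        if n - b < 100:
            break
        last = b
        if abs(geweke(x[b:])) < z_crit:
            return GewekeBurnin(b, True)
    return GewekeBurnin(last, False)


def verdict(
    series: "NumericSeries | Sequence[float]",
    ess_min: int = ESS_MIN_DEFAULT,
    grid_step: float = 0.01,
    name: str | None = None,
) -> DiagnosticsReport:
    """Combined convergence verdict for one parameter.

    The suggested burn-in is the maximum of the Geweke and ESS-based
    suggestions (conservative).  ``converged`` requires |z| < 1.96 at the
    suggested burn-in, PSRF < 1.1 on a half-split of the retained
    samples, and ESS >= ``ess_min``.
    """
    if isinstance(series, NumericSeries) and name is None:
        name = series.name
    x = _as_array(series)
    n = len(x)
    bg = estimate_burnin_geweke(x, grid_step=grid_step)
    be = estimate_burnin_ess(x, grid_step=grid_step)
    b = max(bg.burnin, be)
    tail = x[b:]
    z = geweke(tail)
    half = len(tail) // 2
    psrf = gelman_rubin([tail[:half], tail[half : 2 * half]])
    e = ess(tail)
    converged = (abs(z) < Z_975) and (psrf < PSRF_MAX_DEFAULT) and (e >= ess_min)
    return DiagnosticsReport(
        parameter=name or "",
        geweke_z=z,
        psrf=psrf,
        burnin_geweke=bg.burnin,
        burnin_ess=be,
        burnin_suggested=b,
        ess_at_suggested=e,
        converged=converged,
        thresholds={"z_crit": Z_975, "psrf_max": PSRF_MAX_DEFAULT, "ess_min": ess_min},
    )
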