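"""Subsampling sensitivity analysis of flyway maps.

How representative is a flyway map built from n tracked birds?  For
each subsample size k (1, 4, 7, ... up to n) the analysis aggregates a
random sample of up to 100 distinct k-individual combinations into
partial flyway UDs and measures their mean percent volume of
intersection (%VI) with the full-sample flyway UD.  If the map were
saturated the curve would asymptote near 100% well before k = n; a
curve still climbing at k = n indicates the sample under-represents
the real flyway.

%VI between two UDs p and q on a shared grid is the standard volume of
intersection index: 100 * sum_cells min(p, q).  It is symmetric, lies
in [0, 100], and equals 100 exactly when the two distributions are
cell-wise identical.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np

from .aggregation import aggregate_uds
from .dbbmm import UtilizationDistribution

logger = logging.getLogger("flywaymap")


def percent_vi(p: UtilizationDistribution, q: UtilizationDistribution) -> float:
    """Percent volume of intersection between two UDs (0..100)."""
    if p.grid != q.grid:
        raise ValueError("percent_vi requires UDs on the same GridSpec")
    return float(100.0 * np.minimum(p.mass, q.mass).sum())


def loess_smooth(
    x: np.ndarray, y: np.ndarray, span: float = 0.75, degree: int = 2
) -> np.ndarray:
    """Locally weighted polynomial regression (tricube weights).

    At each point the ``ceil(span * n)`` nearest neighbours are fitted
    with a weighted degree-``degree`` polynomial.  With fewer points
    than the polynomial needs, the degree is reduced locally.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n == 0:
        return y.copy()
    q = max(min(int(math.ceil(span * n)), n), degree + 1, 2)
    q = min(q, n)
    out = np.empty(n)
    for i in range(n):
        d = np.abs(x - x[i])
        idx = np.argsort(d, kind="stable")[:q]
        dmax = d[idx].max()
        if dmax == 0:
            out[i] = y[idx].mean()
            continue
        w = (1 - (d[idx] / dmax) ** 3) ** 3
        w = np.clip(w, 1e-12, None)
        deg = min(degree, len(idx) - 1)
        X = np.vander(x[idx] - x[i], deg + 1, increasing=True)
        W = np.sqrt(w)
        beta, *_ = np.linalg.lstsq(X * W[:, None], y[idx] * W, rcond=None)
        out[i] = beta[0]
    return out


@dataclass
class SensitivityCurve:
    """Mean %VI against subsample size k, with its LOESS smooth."""

    k: np.ndarray
    mean_pvi: np.ndarray
    n_combos: np.ndarray
    loess_pvi: np.ndarray
    rng_seed: int
    n_individuals: int

    def as_table(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "k": self.k,
                "n_combos": self.n_combos,
                "mean_pvi": self.mean_pvi,
                "loess_pvi": self.loess_pvi,
            }
        )


def _k_grid(n: int, step: int) -> list[int]:
    ks = list(range(1, n + 1, step))
    if ks[-1] != n:
        ks.append(n)  # the full-sample point anchors the curve at 100% VI
    return ks


def _sample_combinations(
    n: int, k: int, max_combos: int, rng: np.random.Generator
) -> list[tuple[int, ...]]:
    total = math.comb(n, k)
    if total <= max_combos:
        logger.debug("k=%d: exhaustive enumeration of %d combinations", k, total)
        return list(combinations(range(n), k))
    seen: set[tuple[int, ...]] = set()
    while len(seen) < max_combos:
        seen.add(tuple(sorted(map(int, rng.choice(n, size=k, replace=False)))))
    return sorted(seen)


def sensitivity_curve(
    individual_uds: Sequence[UtilizationDistribution],
    durations: Sequence[float],
    rng_seed: int,
    max_combos: int = 100,
    step: int = 3,
    span: float = 0.75,
    degree: int = 2,
    full_ud: UtilizationDistribution | None = None,
) -> SensitivityCurve:
    """Mean %VI between k-individual UDs and the full flyway UD.

    For each k in 1, 1+step, ... (plus the k = n endpoint) a seeded
    random sample of up to ``max_combos`` distinct k-combinations of
    individuals is aggregated with duration weights and compared to
    the full-sample flyway UD (built from all individuals with the
    same weights unless ``full_ud`` is supplied).  The curve is
    smoothed with tricube-weighted local regression.
    """
    n = len(individual_uds)
    if n < 2:
        raise ValueError("sensitivity analysis needs at least 2 individuals")
    if len(durations) != n:
        raise ValueError("durations must match individual_uds")
    rng = np.random.default_rng(rng_seed)
    if full_ud is None:
        full_ud = aggregate_uds(list(zip(individual_uds, durations)))

    ks = _k_grid(n, step)
    means, counts = [], []
    for k in ks:
        combos = _sample_combinations(n, k, max_combos, rng)
        vis = []
        for combo in combos:
            sub = aggregate_uds([(individual_uds[i], durations[i]) for i in combo])
            vis.append(percent_vi(sub, full_ud))
        means.append(float(np.mean(vis)))
        counts.append(len(combos))

    k_arr = np.array(ks, dtype=int)
    mean_arr = np.array(means)
    smooth = loess_smooth(k_arr.astype(float), mean_arr, span=span, degree=degree)
    return SensitivityCurve(
        k=k_arr,
        mean_pvi=mean_arr,
        n_combos=np.array(counts, dtype=int),
        loess_pvi=smooth,
        rng_seed=int(rng_seed),
        n_individuals=n,
    )


@dataclass
class AsymptoteVerdict:
    verdict: str  # "ASYMPTOTIC" or "INCREASING"
    final_slope: float  # %VI per unit k over the final LOESS segment
    increments: np.ndarray  # the LOESS increments examined


def asymptote_check(
    curve: SensitivityCurve, window: int = 3, tol: float = 2.0
) -> AsymptoteVerdict:
    """Has the %VI curve levelled off before the full sample?

    ASYMPTOTIC if each of the last ``window`` LOESS increments is below
    ``tol`` percentage points, else INCREASING (the sample is too small
    to saturate the flyway map).  Also reports the slope of the final
    LOESS segment for comparing curves between datasets.
    """
    if len(curve.k) < 3:
        raise ValueError("asymptote check needs at least 3 k points")
    inc = np.diff(curve.loess_pvi)
    tail = inc[-window:]
    slope = float(
        (curve.loess_pvi[-1] - curve.loess_pvi[-2]) / (curve.k[-1] - curve.k[-2])
    )
    verdict = "ASYMPTOTIC" if np.all(tail < tol) else "INCREASING"
    return AsymptoteVerdict(verdict=verdict, final_slope=slope, increments=tail)
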