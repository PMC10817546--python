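"""Hill-number diversity: observed and asymptotic, with bootstrap CIs.

Hill numbers qD unify richness (q=0), exponential Shannon entropy (q=1) and
inverse Simpson concentration (q=2) on a common effective-species scale.
Asymptotic (sample-size -> infinity) values use Chao-type estimators built
from singleton/doubleton counts, and confidence intervals come from a
coverage-adjusted multinomial bootstrap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "AbundanceVector",
    "HillEstimate",
    "hill_observed",
    "hill_asymptotic",
    "sample_coverage",
    "bootstrap_ci",
    "estimate",
]


@dataclass
class AbundanceVector:
    """Per-taxon positive counts with singleton/doubleton bookkeeping."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.counts = self.counts[self.counts > 0]
        if self.counts.size == 0:
            raise ValueError("abundance vector must contain at least one positive count")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def s_obs(self) -> int:
        return int(self.counts.size)

    @property
    def f1(self) -> int:
        return int(np.sum(self.counts == 1))

    @property
    def f2(self) -> int:
        return int(np.sum(self.counts == 2))


@dataclass
class HillEstimate:
    q: float
    observed: float
    asymptotic: float
    ci_low: float
    ci_high: float
    coverage: float


def hill_observed(p: Sequence[float], q: float) -> float:
    """Hill number of order q for a relative-abundance vector.

    qD = (sum p_i^q)^(1/(1-q)); the q=1 limit is exp of Shannon entropy.
    """
    if q < 0:
        raise ValueError("diversity order q must be >= 0")
    p = np.asarray(p, dtype=float)
    p = p[p > 0]
    if not math.isclose(float(p.sum()), 1.0, rel_tol=0, abs_tol=1e-8):
        raise ValueError("relative abundances must sum to 1")
    if abs(q - 1.0) < 1e-12:
        return float(np.exp(-np.sum(p * np.log(p))))
    return float(np.sum(p**q) ** (1.0 / (1.0 - q)))


def _chao1(x: AbundanceVector) -> float:
    n, f1, f2 = x.n, x.f1, x.f2
    if f2 > 0:
        return x.s_obs + (n - 1) / n * f1 * f1 / (2 * f2)
    return x.s_obs + (n - 1) / n * f1 * (f1 - 1) / 2


def _chao_jost_entropy(x: AbundanceVector) -> float:
    """Asymptotic Shannon entropy with the rare-species tail correction."""
    counts = x.counts
    n, f1, f2 = x.n, x.f1, x.f2
    # sum over observed taxa of x/n * (H(n-1) - H(x-1)) via the 1/k series
    h = 0.0
    inv = np.cumsum(1.0 / np.arange(1, n))  # inv[k-1] = sum_{j=1..k} 1/j
    for xi in counts:
        if xi < n:
            # sum_{k=xi}^{n-1} 1/k
            s = inv[n - 2] - (inv[xi - 2] if xi >= 2 else 0.0)
            h += xi / n * s
    if f1 > 0:
        if f2 > 0:
            a = 2 * f2 / ((n - 1) * f1 + 2 * f2)
        elif f1 > 1:
            a = 2 / ((n - 1) * (f1 - 1) + 2)
        else:
            a = 1.0
        if a < 1.0:
            r = np.arange(1, n)
            tail = np.sum((1 - a) ** r / r)
            h += f1 / n * (1 - a) ** (1 - n) * (-np.log(a) - tail)
    return h


def hill_asymptotic(x: AbundanceVector, q: float) -> float:
    """Asymptotic Hill number of order q in {0, 1, 2}.

    q=0 is Chao1 richness; q=1 exponentiates the bias-corrected entropy;
    q=2 uses the unbiased Simpson concentration 1 / sum x(x-1)/(n(n-1)).
    """
    n = x.n
    if n < 2:
        raise ValueError("asymptotic estimation needs n >= 2")
    if q == 0:
        return _chao1(x)
    if q == 1:
        return float(np.exp(_chao_jost_entropy(x)))
    if q == 2:
        denom = float(np.sum(x.counts * (x.counts - 1))) / (n * (n - 1))
        if denom <= 0:
            raise ValueError("q=2 asymptotic undefined: no taxon observed twice")
        return 1.0 / denom
    raise ValueError("asymptotic estimators implemented for q in {0, 1, 2}")


def sample_coverage(x: AbundanceVector) -> float:
    """Estimated fraction of the community's individuals belonging to observed taxa."""
    n, f1, f2 = x.n, x.f1, x.f2
    if n < 1:
        raise ValueError("empty sample")
    if f1 == 0:
        return 1.0
    denom = (n - 1) * f1 + 2 * f2
    if denom == 0:
        return 0.0
    return 1.0 - (f1 / n) * ((n - 1) * f1 / denom)


def _bootstrap_community(x: AbundanceVector) -> np.ndarray:
    """Coverage-adjusted relative abundances, augmented with undetected taxa."""
    n = x.n
    c = sample_coverage(x)
    p = x.counts / n
    # shrink observed probabilities so they sum to the estimated coverage
    w = (1 - p) ** n
    denom = float(np.sum(p * w))
    lam = (1 - c) / denom if denom > 0 else 0.0
    p_adj = p * (1 - lam * w)
    f0 = max(int(math.ceil(_chao1(x) - x.s_obs)), 0)
    if f0 > 0 and c < 1.0:
        p_aug = np.concatenate([p_adj, np.full(f0, (1 - c) / f0)])
    else:
        p_aug = p_adj
    p_aug = np.clip(p_aug, 0, None)
    return p_aug / p_aug.sum()


def bootstrap_ci(
    x: AbundanceVector,
    q: float,
    n_boot: int = 200,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Percentile bootstrap CI for the asymptotic Hill number of order q.

    Resamples multinomially at the observed depth from the coverage-adjusted
    abundance model (observed taxa shrunk to the estimated coverage, the
    remainder spread over Chao1-many undetected taxa).
    """
    if x.n < 2:
        raise ValueError("bootstrap needs n >= 2")
    if x.s_obs == 1 and x.counts[0] > 1:
        point = hill_asymptotic(x, q)
        return (point, point)
    rng = np.random.default_rng(seed)
    p_aug = _bootstrap_community(x)
    vals = []
    for _ in range(n_boot):
        draw = rng.multinomial(x.n, p_aug)
        draw = draw[draw > 0]
        if draw.size == 0:
            continue
        bx = AbundanceVector(draw)
        try:
            vals.append(hill_asymptotic(bx, q))
        except ValueError:
            continue
    if not vals:
        point = hill_asymptotic(x, q)
        return (point, point)
    lo, hi = np.percentile(vals, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def estimate(
    counts: Sequence[int],
    q: float,
    n_boot: int = 200,
    seed: int = 0,
) -> HillEstimate:
    """Observed + asymptotic Hill number with coverage and a 95% bootstrap CI."""
    x = AbundanceVector(np.asarray(counts))
    obs = hill_observed(x.counts / x.n, q)
    asym = hill_asymptotic(x, q)
    lo, hi = bootstrap_ci(x, q, n_boot=n_boot, seed=seed)
    lo, hi = min(lo, asym), max(hi, asym)
    return HillEstimate(q, obs, asym, lo, hi, sample_coverage(x))
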