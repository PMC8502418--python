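"""Poisson quantification and limit-of-blank estimation.

Droplets partition the template at random, so the per-droplet occupancy is
Poisson and the positive fraction p relates to the mean copies per droplet
as p = 1 - exp(-lambda). The point estimate inverts that map; the interval
transforms an exact binomial (Clopper-Pearson) interval on p through the
same map, so coverage is inherited from the exact construction.

The limit of blank (LOB) is the highest positive-droplet count plausibly
produced by template-free wells at confidence 1 - alpha. Two estimators are
provided: "empirical" takes the (1 - alpha) quantile of the observed blank
counts (the smallest count c such that at least a 1 - alpha fraction of
blanks is <= c), and "poisson" fits the blank mean and takes the fitted
(1 - alpha) Poisson quantile. Empirical is the default. Blank wells with
different droplet totals are treated as exchangeable counts: the blank
false-positive rate is taken as independent of input DNA amount.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
from scipy import stats as sps

from .performance import clopper_pearson
from .records import SaturationError, ValidationError

__all__ = [
    "LambdaEstimate",
    "LobEstimate",
    "poisson_lambda",
    "copies_per_microliter",
    "estimate_lob",
]

LOB_METHODS = ("empirical", "poisson")


@dataclass(frozen=True)
class LambdaEstimate:
    """Mean copies per droplet with a transformed exact binomial interval."""

    lam: float
    ci: Tuple[float, float]
    n_positive: int
    n_droplets: int
    conf: float


@dataclass(frozen=True)
class LobEstimate:
    marker: str
    lob: int
    alpha: float
    n_blanks: int
    method: str


def poisson_lambda(n_positive: int, n_droplets: int, conf: float = 0.95) -> LambdaEstimate:
    """Estimate mean copies per droplet from a positive-droplet count."""
    if n_droplets < 1 or n_positive < 0:
        raise ValidationError("need n_droplets >= 1 and n_positive >= 0")
    if n_positive > n_droplets:
        raise ValidationError("n_positive exceeds n_droplets")
    if n_positive == n_droplets:
        raise SaturationError("all droplets positive; concentration not estimable")
    p = n_positive / n_droplets
    lo, hi = clopper_pearson(n_positive, n_droplets, conf)
    # hi < 1 is guaranteed because n_positive < n_droplets
    return LambdaEstimate(
        lam=-math.log1p(-p),
        ci=(-math.log1p(-lo), -math.log1p(-hi)),
        n_positive=n_positive,
        n_droplets=n_droplets,
        conf=conf,
    )


def copies_per_microliter(
    estimate: LambdaEstimate,
    droplet_volume_nl: float,
    dilution_factor: float = 1.0,
) -> Tuple[float, Tuple[float, float]]:
    """Convert copies per droplet into copies per microliter of input.

    1 µL = 1000 nL, so the concentration is lambda / volume_nl * 1000,
    scaled by any dilution applied before partitioning. The interval is
    transformed by the same linear map.
    """
    if droplet_volume_nl <= 0:
        raise ValidationError("droplet volume must be positive")
    if dilution_factor <= 0:
        raise ValidationError("dilution factor must be positive")
    scale = 1000.0 * dilution_factor / droplet_volume_nl
    return (
        estimate.lam * scale,
        (estimate.ci[0] * scale, estimate.ci[1] * scale),
    )


def estimate_lob(
    blank_counts: Sequence[int],
    alpha: float = 0.05,
    method: str = "empirical",
    marker: str = "",
) -> LobEstimate:
    """Limit of blank from replicate template-free wells."""
    counts = [int(c) for c in blank_counts]
    if len(counts) < 2:
        raise ValidationError("LOB estimation needs at least 2 blank wells")
    if any(c < 0 for c in counts):
        raise ValidationError("blank counts must be non-negative")
    if not 0 < alpha < 1:
        raise ValidationError("alpha must be in (0, 1)")
    if method not in LOB_METHODS:
        raise ValidationError(f"method must be one of {LOB_METHODS}")

    if method == "empirical":
        xs = sorted(counts)
        n = len(xs)
        # smallest c with #(counts <= c) / n >= 1 - alpha
        k = math.ceil((1.0 - alpha) * n)
        lob = xs[k - 1]
    else:
        mean = float(np.mean(counts))
        lob = int(sps.poisson.ppf(1.0 - alpha, mean)) if mean > 0 else 0
    return LobEstimate(
        marker=marker, lob=int(lob), alpha=alpha, n_blanks=len(counts), method=method
    )
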