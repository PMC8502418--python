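"""Droplet gating and spill-over compensation.

Raw two-channel fluorescence amplitudes are turned into per-channel
positive/negative counts. Optical crosstalk between detection channels is
removed first by linear unmixing with the inverse of a forward spill-over
matrix; gating then applies a per-channel amplitude threshold, either given
manually or derived automatically from the data.

The automatic threshold is the midpoint between the two cluster centers of
the best two-group split of the 1-D amplitude distribution, where "best"
minimizes total within-group variance (the exact 1-D two-means partition,
found by scanning split points of the sorted amplitudes). A well whose
best split separates the cluster centers by less than ``min_separation``
pooled within-cluster standard deviations is treated as a single (negative)
cluster: without an absolute fluorescence reference a lone cluster cannot be
told positive, so the conservative call is all-negative.

Droplets exactly at the threshold count as negative (strict inequality),
which is conservative toward specificity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Tuple, Union

import numpy as np

from .records import CountRecord, DegenerateDataError, ValidationError

__all__ = [
    "DropletSet",
    "SpilloverMatrix",
    "GateResult",
    "compensate",
    "gate_droplets",
    "estimate_spillover",
]


@dataclass(frozen=True)
class DropletSet:
    """Per-droplet fluorescence amplitude pairs for one well.

    ``amplitudes`` is an (n, 2) array; column k is detection channel k+1 and
    ``channel_labels[k]`` names the marker read in that channel.
    """

    well_id: str
    amplitudes: np.ndarray
    channel_labels: Tuple[str, str]
    sample_id: str = ""

    def __post_init__(self) -> None:
        amps = np.asarray(self.amplitudes, dtype=float)
        if amps.ndim != 2 or amps.shape[1] != 2:
            raise ValidationError("amplitudes must be an (n, 2) array")
        if amps.shape[0] < 1:
            raise ValidationError("a droplet set needs at least one droplet")
        if not np.all(np.isfinite(amps)):
            raise ValidationError("amplitudes must be finite")
        object.__setattr__(self, "amplitudes", amps)

    @property
    def n_droplets(self) -> int:
        return int(self.amplitudes.shape[0])


@dataclass(frozen=True)
class SpilloverMatrix:
    """Forward crosstalk matrix: entry (i, j) is the fraction of channel-j
    signal bleeding into channel i. Diagonal is 1 by construction."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (2, 2):
            raise ValidationError("spillover matrix must be 2x2")
        if not np.allclose(np.diag(m), 1.0):
            raise ValidationError("spillover matrix diagonal must be 1")
        off = np.array([m[0, 1], m[1, 0]])
        if np.any(off < 0) or np.any(off >= 1):
            raise ValidationError("off-diagonal spillover must be in [0, 1)")
        if abs(np.linalg.det(m)) < 1e-12:
            raise ValidationError("spillover matrix is singular")
        object.__setattr__(self, "matrix", m)

    @classmethod
    def identity(cls) -> "SpilloverMatrix":
        return cls(np.eye(2))

    @classmethod
    def from_bleed(cls, ch2_into_ch1: float = 0.0, ch1_into_ch2: float = 0.0) -> "SpilloverMatrix":
        return cls(np.array([[1.0, ch2_into_ch1], [ch1_into_ch2, 1.0]]))


@dataclass(frozen=True)
class GateResult:
    """Counts per channel plus the thresholds actually applied."""

    counts: Tuple[CountRecord, CountRecord]
    thresholds: Tuple[float, float]


def compensate(droplets: DropletSet, spill: SpilloverMatrix) -> DropletSet:
    """Remove optical crosstalk by applying the inverse spill-over matrix.

    Observed amplitudes are modeled as ``observed = S @ true`` per droplet;
    this returns the droplets with ``true = S^-1 @ observed``. Droplet count
    and order are preserved. Linear, hence not idempotent for S != I.
    """
    inv = np.linalg.inv(spill.matrix)
    comp = droplets.amplitudes @ inv.T
    return DropletSet(
        well_id=droplets.well_id,
        amplitudes=comp,
        channel_labels=droplets.channel_labels,
        sample_id=droplets.sample_id,
    )


def _two_means_split(x: np.ndarray) -> Tuple[float, float, float]:
    """Exact 1-D two-cluster partition minimizing within-group variance.

    Returns (low mean, high mean, pooled within-cluster SD). Raises
    DegenerateDataError on constant input.
    """
    xs = np.sort(x)
    n = xs.size
    if n < 2:
        raise DegenerateDataError("auto gating needs at least 2 droplets")
    if xs[0] == xs[-1]:
        raise DegenerateDataError("no cluster structure: constant amplitudes")
    csum = np.cumsum(xs)
    csq = np.cumsum(xs * xs)
    k = np.arange(1, n)  # size of the low group
    s1, s2 = csum[k - 1], csum[-1] - csum[k - 1]
    q1, q2 = csq[k - 1], csq[-1] - csq[k - 1]
    within = (q1 - s1 * s1 / k) + (q2 - s2 * s2 / (n - k))
    i = int(np.argmin(within))
    kb = i + 1
    mu_lo = s1[i] / kb
    mu_hi = (csum[-1] - s1[i]) / (n - kb)
    pooled_sd = float(np.sqrt(max(within[i], 0.0) / n))
    return float(mu_lo), float(mu_hi), pooled_sd


def _auto_threshold(x: np.ndarray, min_separation: float) -> float:
    mu_lo, mu_hi, sd = _two_means_split(x)
    if sd > 0 and (mu_hi - mu_lo) / sd < min_separation:
        # single cluster: no positive population identifiable
        return float(np.inf)
    return 0.5 * (mu_lo + mu_hi)


def gate_droplets(
    droplets: DropletSet,
    thresholds: Union[str, Sequence[float]] = "auto",
    min_separation: float = 3.5,
) -> GateResult:
    """Count positive droplets per channel.

    Parameters
    ----------
    droplets
        Amplitudes to gate (compensate first if crosstalk is present).
    thresholds
        ``"auto"`` to derive each channel's threshold from the two-cluster
        split, or an explicit pair of amplitude cutoffs.
    min_separation
        Auto mode only: minimum distance between cluster centers, in pooled
        within-cluster SD units, for the split to count as two clusters.

    A droplet is positive iff its amplitude is strictly above the threshold.
    Counts are invariant to droplet order.
    """
    amps = droplets.amplitudes
    if isinstance(thresholds, str):
        if thresholds != "auto":
            raise ValidationError(f"unknown threshold mode {thresholds!r}")
        if amps.shape[0] < 2:
            raise ValidationError("auto gating needs at least 2 droplets")
        thr = tuple(_auto_threshold(amps[:, c], min_separation) for c in (0, 1))
    else:
        thr = tuple(float(t) for t in thresholds)
        if len(thr) != 2:
            raise ValidationError("need one threshold per channel")

    counts = []
    for c in (0, 1):
        n_pos = int(np.sum(amps[:, c] > thr[c]))
        counts.append(
            CountRecord(
                well_id=droplets.well_id,
                sample_id=droplets.sample_id,
                marker=droplets.channel_labels[c],
                n_droplets=droplets.n_droplets,
                n_positive=n_pos,
            )
        )
    return GateResult(counts=(counts[0], counts[1]), thresholds=(thr[0], thr[1]))


def estimate_spillover(
    single_positive_wells: Sequence[Tuple[DropletSet, int]],
    min_separation: float = 3.5,
) -> SpilloverMatrix:
    """Estimate the forward spill-over matrix from single-positive control wells.

    Each item is ``(droplets, source_channel)`` where only the marker read in
    ``source_channel`` (0 or 1) is present. Positive droplets are identified
    by auto-gating the source channel; the bleed fraction is the slope of the
    bleed-channel amplitude regressed on the source-channel amplitude over
    those droplets, with each channel's negative-cluster baseline removed.
    Returns the identity if no wells are supplied.
    """
    m = np.eye(2)
    for droplets, src in single_positive_wells:
        if src not in (0, 1):
            raise ValidationError("source_channel must be 0 or 1")
        dst = 1 - src
        amps = droplets.amplitudes
        thr = _auto_threshold(amps[:, src], min_separation)
        pos = amps[:, src] > thr
        if pos.sum() < 2 or (~pos).sum() < 1:
            raise DegenerateDataError(
                f"well {droplets.well_id!r}: cannot separate positives for "
                "spillover estimation"
            )
        base_src = float(np.mean(amps[~pos, src]))
        base_dst = float(np.mean(amps[~pos, dst]))
        x = amps[pos, src] - base_src
        y = amps[pos, dst] - base_dst
        denom = float(np.dot(x, x))
        if denom <= 0:
            raise DegenerateDataError("zero variance in source channel positives")
        m[dst, src] = max(0.0, float(np.dot(x, y) / denom))
    return SpilloverMatrix(m)
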