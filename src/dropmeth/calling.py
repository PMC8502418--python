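"""Positivity calling: per-marker droplet thresholds and the combined call.

A marker is called positive in a sample when its positive-droplet count
reaches the marker's positivity threshold (inclusive ``>=``). The default
panel follows the published assay: NPY read in the Cyanine 5 channel with
threshold >= 1 droplet, WIF1 in Cyanine 3 with threshold >= 5 droplets, each
threshold equal to the marker's limit of blank. The sample-level call
combines markers with an OR rule ("any", the headline classifier) or an AND
rule ("both").

Note the deliberate tension kept from the published design: a count equal to
the LOB is still "plausible" under the blank null yet is called positive.
``MarkerConfig(threshold=lob + 1)`` gives the conservative variant;
``allow_threshold_below_lob`` permits thresholds under the LOB for
exploration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Tuple

from .records import CountRecord, ValidationError

__all__ = [
    "MarkerConfig",
    "MarkerCall",
    "CallResult",
    "default_panel",
    "call_marker",
    "call_sample",
    "call_cohort",
]

RULES = ("any", "both")


@dataclass(frozen=True)
class MarkerConfig:
    """A marker's detection channel, limit of blank and positivity threshold."""

    marker: str
    channel: str
    lob: int
    positivity_threshold: int
    allow_threshold_below_lob: bool = False

    def __post_init__(self) -> None:
        if self.lob < 0:
            raise ValidationError(f"{self.marker}: LOB must be >= 0")
        if self.positivity_threshold < 1:
            raise ValidationError(f"{self.marker}: positivity threshold must be >= 1")
        if self.positivity_threshold < self.lob and not self.allow_threshold_below_lob:
            raise ValidationError(
                f"{self.marker}: threshold {self.positivity_threshold} below "
                f"LOB {self.lob}; set allow_threshold_below_lob to override"
            )


def default_panel() -> Dict[str, MarkerConfig]:
    """The published two-marker panel."""
    return {
        "NPY": MarkerConfig(marker="NPY", channel="Cyanine 5", lob=1, positivity_threshold=1),
        "WIF1": MarkerConfig(marker="WIF1", channel="Cyanine 3", lob=5, positivity_threshold=5),
    }


@dataclass(frozen=True)
class MarkerCall:
    marker: str
    n_positive: int
    threshold: int
    call: bool


@dataclass(frozen=True)
class CallResult:
    """Sample-level methylation call with per-marker detail."""

    sample_id: str
    marker_calls: Tuple[MarkerCall, ...]
    combined_call: bool
    rule: str
    missing_markers: Tuple[str, ...] = ()


def call_marker(count: CountRecord, cfg: MarkerConfig) -> bool:
    """Positive iff the well's positive-droplet count reaches the threshold."""
    if count.marker != cfg.marker:
        raise ValidationError(
            f"marker mismatch: count is {count.marker!r}, config is {cfg.marker!r}"
        )
    return count.n_positive >= cfg.positivity_threshold


def call_sample(
    sample_id: str,
    marker_calls: Sequence[MarkerCall],
    rule: str = "any",
    missing_markers: Sequence[str] = (),
) -> CallResult:
    """Combine per-marker calls into one sample-level call."""
    if rule not in RULES:
        raise ValidationError(f"rule must be one of {RULES}, got {rule!r}")
    if not marker_calls:
        raise ValidationError(f"sample {sample_id!r}: no marker calls to combine")
    flags = [mc.call for mc in marker_calls]
    combined = any(flags) if rule == "any" else all(flags)
    return CallResult(
        sample_id=sample_id,
        marker_calls=tuple(marker_calls),
        combined_call=combined,
        rule=rule,
        missing_markers=tuple(missing_markers),
    )


def call_cohort(
    counts: Sequence[CountRecord],
    panel: Mapping[str, MarkerConfig],
    rule: str = "any",
) -> Tuple[CallResult, ...]:
    """Call every sample in a count table against a marker panel.

    Counts for markers not in the panel are ignored. A sample missing a
    panel marker's well is still called over the markers it has, with the
    absent markers recorded in ``missing_markers`` — never silently treated
    as negative.
    """
    by_sample: Dict[str, Dict[str, CountRecord]] = {}
    for rec in counts:
        if rec.marker in panel:
            prev = by_sample.setdefault(rec.sample_id, {})
            if rec.marker in prev:
                raise ValidationError(
                    f"sample {rec.sample_id!r}: duplicate well for marker {rec.marker!r}"
                )
            prev[rec.marker] = rec

    results = []
    for sample_id, recs in by_sample.items():
        mcs = [
            MarkerCall(
                marker=m,
                n_positive=recs[m].n_positive,
                threshold=panel[m].positivity_threshold,
                call=call_marker(recs[m], panel[m]),
            )
            for m in panel
            if m in recs
        ]
        missing = tuple(m for m in panel if m not in recs)
        results.append(call_sample(sample_id, mcs, rule=rule, missing_markers=missing))
    return tuple(results)
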