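"""Shared record types and errors for the droplet-methylation pipeline.

The central carrier is :class:`CountRecord` — one well, one marker, how many
droplets were analyzed and how many were called positive. Everything
downstream of gating (quantification, calling, performance) consumes these.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional


class ValidationError(ValueError):
    """Invalid input values or inconsistent records."""


class DegenerateDataError(ValueError):
    """Data without the structure an operation requires (e.g. constant amplitudes)."""


class SaturationError(ValueError):
    """All droplets positive; Poisson concentration not estimable."""


#: closed vocabulary of sample classes used for truth labels
SAMPLE_CLASSES = ("tumor_tissue", "adjacent_tissue", "crc_plasma", "control_plasma")

STAGES = ("I", "II", "III", "IV")


@dataclass(frozen=True)
class CountRecord:
    """Per-well droplet totals for one marker channel."""

    well_id: str
    sample_id: str
    marker: str
    n_droplets: int
    n_positive: int

    def __post_init__(self) -> None:
        if self.n_droplets < 1:
            raise ValidationError(
                f"well {self.well_id!r}: n_droplets must be >= 1, got {self.n_droplets}"
            )
        if not 0 <= self.n_positive <= self.n_droplets:
            raise ValidationError(
                f"well {self.well_id!r}: n_positive={self.n_positive} outside "
                f"[0, {self.n_droplets}]"
            )

    @property
    def positive_fraction(self) -> float:
        return self.n_positive / self.n_droplets


@dataclass(frozen=True)
class SampleMeta:
    """Sample identity and clinical annotation.

    ``sample_class`` is one of :data:`SAMPLE_CLASSES`; cases and controls for
    diagnostic performance are selected by class.
    """

    sample_id: str
    sample_class: str
    stage: Optional[str] = None
    histology: Optional[str] = None
    dna_conc_ng_per_ul: Optional[float] = None

    def __post_init__(self) -> None:
        if self.sample_class not in SAMPLE_CLASSES:
            raise ValidationError(
                f"sample {self.sample_id!r}: class {self.sample_class!r} not in "
                f"{SAMPLE_CLASSES}"
            )
        if self.stage is not None and self.stage not in STAGES:
            raise ValidationError(
                f"sample {self.sample_id!r}: stage {self.stage!r} not in {STAGES}"
            )
        if self.dna_conc_ng_per_ul is not None and self.dna_conc_ng_per_ul < 0:
            raise ValidationError(
                f"sample {self.sample_id!r}: negative DNA concentration"
            )
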