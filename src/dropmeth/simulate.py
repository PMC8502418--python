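"""Synthetic droplet data with the statistical structure the analysis assumes.

The generative model, bottom up:

* Template partitioning is Poisson: with mean occupancy ``lambda_true``
  copies per droplet, a droplet holds at least one copy — and hence can
  amplify — with probability ``1 - exp(-lambda_true)``. Positive-droplet
  counts are Binomial in the number of droplets.
* Blank wells produce channel-specific false-positive droplets, Poisson
  with a small per-well mean, independent of input DNA amount.
* Fluorescence amplitudes form two homoscedastic Gaussian clusters per
  channel (negative baseline and positive), ``cluster_separation`` SDs
  apart, with optical crosstalk applied by a forward spill-over matrix.
* Cohorts share a per-sample latent tumor-DNA load, log-normal across
  samples, that scales both markers' expected counts — inducing the
  positive cross-marker correlation seen in real tumor panels.

All randomness flows from a single integer seed; each well gets its own
deterministic substream (the well index is mixed into the seed), so adding
wells never perturbs earlier ones and identical configs are bit-identical.

Blank false-positive means default to 0.2 (NPY channel) and 2.4 (WIF1
channel): over 12 blank wells the empirical 95% limit of blank is then
modally 1 and 5 droplets. These, like every fluorescence constant here,
are stand-ins chosen to be realistic — no instrument raw data underlies
them (see docs/methods.md).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .gating import DropletSet, SpilloverMatrix
from .records import CountRecord, SampleMeta, ValidationError

__all__ = [
    "SimConfig",
    "CohortSpec",
    "DILUTION_CONCENTRATIONS_NG_PER_UL",
    "simulate_counts",
    "simulate_blanks",
    "simulate_fluorescence",
    "simulate_dilution_series",
    "simulate_cohort",
]

# fluorescence cluster constants (arbitrary instrument units)
_NEG_MEAN = 2000.0
_CLUSTER_SD = 250.0

#: the dilution-series design: 10%-methylated control DNA at these inputs
DILUTION_CONCENTRATIONS_NG_PER_UL = (0.5, 0.25, 0.1, 0.05, 0.01)

#: mean copies per droplet contributed by 1 ng/µL of the 10%-methylated
#: dilution standard (per marker; NPY needs 11 co-methylated CpGs vs 5 for
#: WIF1, so its effective template density is lower)
_DILUTION_LAMBDA_PER_NG_UL = {"NPY": 0.045, "WIF1": 0.06}


@dataclass(frozen=True)
class SimConfig:
    """Instrument- and assay-level simulation parameters."""

    n_droplets_per_well: int = 25_000
    droplet_volume_nl: float = 0.59
    fp_rate_npy: float = 0.2
    fp_rate_wif1: float = 2.4
    spillover: SpilloverMatrix = field(default_factory=SpilloverMatrix.identity)
    cluster_separation: float = 8.0
    n_blank_wells: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_droplets_per_well < 1:
            raise ValidationError("n_droplets_per_well must be >= 1")
        if self.droplet_volume_nl <= 0:
            raise ValidationError("droplet volume must be positive")
        if self.fp_rate_npy < 0 or self.fp_rate_wif1 < 0:
            raise ValidationError("false-positive rates must be >= 0")
        if self.cluster_separation <= 0:
            raise ValidationError("cluster_separation must be positive")
        if self.n_blank_wells < 2:
            raise ValidationError("need at least 2 blank wells")

    def fp_rate(self, marker: str) -> float:
        return {"NPY": self.fp_rate_npy, "WIF1": self.fp_rate_wif1}.get(marker, 0.0)


def _default_mean_load() -> Dict[str, Dict[str, float]]:
    # tumor/adjacent tissue means match the published class means; plasma
    # means are invented at a plausible ctDNA scale (no per-sample data exists)
    return {
        "tumor_tissue": {"NPY": 6021.0, "WIF1": 6776.0},
        "adjacent_tissue": {"NPY": 115.0, "WIF1": 81.0},
        "crc_plasma": {"NPY": 35.0, "WIF1": 60.0},
        "control_plasma": {"NPY": 0.0, "WIF1": 0.0},
    }


@dataclass(frozen=True)
class CohortSpec:
    """Cohort composition and per-class expected positive-droplet counts.

    Defaults mirror the validation cohort: 11 tumor/adjacent tissue pairs,
    22 CRC plasmas, 10 control plasmas.
    """

    n_tumor_tissue: int = 11
    n_adjacent: int = 11
    n_crc_plasma: int = 22
    n_control_plasma: int = 10
    mean_load: Mapping[str, Mapping[str, float]] = field(default_factory=_default_mean_load)
    shared_load_dispersion: float = 1.0

    def __post_init__(self) -> None:
        for n in (self.n_tumor_tissue, self.n_adjacent, self.n_crc_plasma, self.n_control_plasma):
            if n < 0:
                raise ValidationError("class sizes must be non-negative")
        if self.shared_load_dispersion <= 0:
            raise ValidationError("shared_load_dispersion must be positive")
        for cls, per_marker in self.mean_load.items():
            for marker, m in per_marker.items():
                if not (m >= 0 and math.isfinite(m)):
                    raise ValidationError(f"mean_load[{cls}][{marker}] must be finite and >= 0")

    @property
    def total(self) -> int:
        return self.n_tumor_tissue + self.n_adjacent + self.n_crc_plasma + self.n_control_plasma


def _substream(seed: int, index: int) -> np.random.Generator:
    """Deterministic per-well/per-sample substream of the master seed."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(index,)))


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def simulate_counts(
    lambda_true: float,
    fp_rate: float,
    n_droplets: int,
    seed,
    well_id: str = "w0",
    sample_id: str = "",
    marker: str = "",
) -> CountRecord:
    """Draw one well's positive-droplet count.

    True positives are Binomial(n_droplets, 1 - exp(-lambda_true)); false
    positives add an independent Poisson(fp_rate) count. The total is capped
    at the number of droplets.
    """
    if lambda_true < 0 or fp_rate < 0:
        raise ValidationError("lambda_true and fp_rate must be >= 0")
    if n_droplets < 1:
        raise ValidationError("n_droplets must be >= 1")
    rng = _rng(seed)
    p = -math.expm1(-lambda_true)
    true_pos = int(rng.binomial(n_droplets, p)) if p > 0 else 0
    false_pos = int(rng.poisson(fp_rate)) if fp_rate > 0 else 0
    return CountRecord(
        well_id=well_id,
        sample_id=sample_id,
        marker=marker,
        n_droplets=n_droplets,
        n_positive=min(true_pos + false_pos, n_droplets),
    )


def simulate_blanks(config: SimConfig, marker: str) -> List[CountRecord]:
    """Template-free replicate wells for one marker channel (LOB design)."""
    out = []
    # channel-specific offset keeps the two markers' substreams independent
    offset = 0 if marker == "NPY" else 1000
    for w in range(config.n_blank_wells):
        rng = _substream(config.seed, offset + w)
        out.append(
            simulate_counts(
                0.0,
                config.fp_rate(marker),
                config.n_droplets_per_well,
                rng,
                well_id=f"blank_{marker}_{w:02d}",
                sample_id=f"blank_{w:02d}",
                marker=marker,
            )
        )
    return out


def simulate_fluorescence(
    counts,
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
) -> DropletSet:
    """Emit per-droplet two-channel amplitudes consistent with given counts.

    ``counts`` is one CountRecord or a pair (one per channel, same well and
    droplet total). Positive droplets in a channel draw from the high
    Gaussian cluster, negatives from the baseline cluster; the forward
    spill-over matrix then mixes channels, and droplet order is randomized.
    """
    if isinstance(counts, CountRecord):
        records: Sequence[CountRecord] = (counts,)
    else:
        records = tuple(counts)
    if not 1 <= len(records) <= 2:
        raise ValidationError("need counts for one or two channels")
    n = records[0].n_droplets
    well_id = records[0].well_id
    for rec in records:
        if rec.n_droplets != n:
            raise ValidationError("channel records disagree on droplet total")
        if rec.n_positive > n:
            raise ValidationError("positives exceed total droplets")
    if rng is None:
        rng = _rng(config.seed)

    labels = [rec.marker or f"ch{i + 1}" for i, rec in enumerate(records)]
    while len(labels) < 2:
        labels.append("unused")

    pos_mean = _NEG_MEAN + config.cluster_separation * _CLUSTER_SD
    true_amps = rng.normal(_NEG_MEAN, _CLUSTER_SD, size=(n, 2))
    for c, rec in enumerate(records):
        if rec.n_positive:
            idx = rng.choice(n, size=rec.n_positive, replace=False)
            true_amps[idx, c] += pos_mean - _NEG_MEAN
    observed = true_amps @ config.spillover.matrix.T
    observed = observed[rng.permutation(n)]
    return DropletSet(
        well_id=well_id,
        amplitudes=observed,
        channel_labels=(labels[0], labels[1]),
        sample_id=records[0].sample_id,
    )


def simulate_dilution_series(
    config: SimConfig,
    markers: Sequence[str] = ("NPY", "WIF1"),
    n_replicates: int = 3,
    concentrations: Sequence[float] = DILUTION_CONCENTRATIONS_NG_PER_UL,
) -> List[CountRecord]:
    """Wells for the 10%-methylated dilution series at the standard inputs."""
    out = []
    idx = 10_000  # substream offset keeps dilution wells disjoint from blanks
    for marker in markers:
        per_ng = _DILUTION_LAMBDA_PER_NG_UL.get(marker, 0.05)
        for conc in concentrations:
            for rep in range(n_replicates):
                rng = _substream(config.seed, idx)
                idx += 1
                out.append(
                    simulate_counts(
                        per_ng * conc,
                        config.fp_rate(marker),
                        config.n_droplets_per_well,
                        rng,
                        well_id=f"dil_{marker}_{conc}_{rep}",
                        sample_id=f"dil_{conc}_{rep}",
                        marker=marker,
                    )
                )
    return out


_STAGE_CYCLE_TISSUE = ("II", "III", "I", "IV")
_HISTOLOGY_CYCLE = ("ADC-WD", "ADC-PD")


def _plasma_stage(i: int, n: int) -> str:
    # mostly stage IV, with early-stage samples first (mirrors a cohort
    # dominated by metastatic disease)
    if i == 0:
        return "I"
    if i == 1 and n > 10:
        return "III"
    return "IV"


def simulate_cohort(
    spec: CohortSpec, config: SimConfig
) -> Tuple[List[SampleMeta], List[CountRecord]]:
    """Generate a full cohort: metadata plus one count record per marker.

    Both markers in a sample share a latent log-normal tumor-DNA load with
    unit mean and log-scale SD ``shared_load_dispersion``, so expected
    counts hit the class means while markers stay positively correlated
    across samples. Control plasmas carry false positives only. DNA
    concentration is generated to co-vary with the latent load.
    """
    markers = ("NPY", "WIF1")
    metas: List[SampleMeta] = []
    counts: List[CountRecord] = []
    sigma = spec.shared_load_dispersion

    plan = (
        [("tumor_tissue", i) for i in range(spec.n_tumor_tissue)]
        + [("adjacent_tissue", i) for i in range(spec.n_adjacent)]
        + [("crc_plasma", i) for i in range(spec.n_crc_plasma)]
        + [("control_plasma", i) for i in range(spec.n_control_plasma)]
    )
    for global_idx, (cls, i) in enumerate(plan):
        rng = _substream(config.seed, 100_000 + global_idx)
        sample_id = f"{cls}_{i:03d}"
        if cls == "control_plasma":
            load = 0.0
        else:
            load = float(np.exp(rng.normal(-0.5 * sigma**2, sigma)))

        if cls in ("tumor_tissue", "adjacent_tissue"):
            stage = _STAGE_CYCLE_TISSUE[i % len(_STAGE_CYCLE_TISSUE)]
            histology = _HISTOLOGY_CYCLE[i % len(_HISTOLOGY_CYCLE)]
            base_conc = 20.0
        elif cls == "crc_plasma":
            stage = _plasma_stage(i, spec.n_crc_plasma)
            histology = None
            base_conc = 5.0
        else:
            stage = None
            histology = None
            base_conc = 3.0
        conc = base_conc * (max(load, 0.05) ** 0.5) * float(np.exp(rng.normal(0, 0.3)))

        metas.append(
            SampleMeta(
                sample_id=sample_id,
                sample_class=cls,
                stage=stage,
                histology=histology,
                dna_conc_ng_per_ul=round(conc, 3),
            )
        )
        per_marker = spec.mean_load.get(cls, {})
        n = config.n_droplets_per_well
        for marker in markers:
            mean_pos = per_marker.get(marker, 0.0) * load
            frac = min(mean_pos / n, 0.999)
            lam = -math.log1p(-frac) if frac > 0 else 0.0
            counts.append(
                simulate_counts(
                    lam,
                    config.fp_rate(marker),
                    n,
                    rng,
                    well_id=f"{sample_id}_{marker}",
                    sample_id=sample_id,
                    marker=marker,
                )
            )
    return metas, counts
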