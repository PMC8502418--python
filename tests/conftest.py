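"""Shared fixtures: simulation configs and the published-cohort encoding."""

from __future__ import annotations

import pytest

from dropmeth.calling import default_panel
from dropmeth.records import CountRecord, SampleMeta
from dropmeth.simulate import SimConfig

N_DROPLETS = 25_000


@pytest.fixture
def sim_config():
    return SimConfig(seed=11)


@pytest.fixture
def panel():
    return default_panel()


def _crc_counts(i: int, npy: int, wif1: int):
    sid = f"crc_plasma_{i:03d}"
    return [
        CountRecord(f"{sid}_NPY", sid, "NPY", N_DROPLETS, npy),
        CountRecord(f"{sid}_WIF1", sid, "WIF1", N_DROPLETS, wif1),
    ]


@pytest.fixture
def published_plasma_cohort():
    """The reported liquid-biopsy outcome encoded as count records.

    22 CRC plasmas: 17 positive for both markers (77.3%), 2 NPY-only,
    2 WIF1-only (21 of 22 positive for at least one marker; the single
    all-negative sample is the low-DNA stage-I patient), and 10 control
    plasmas with no methylation signal. Only the per-sample call pattern is
    reported in print; the droplet counts here are arbitrary values on the
    correct side of each threshold.
    """
    counts, metas = [], []
    i = 0
    for _ in range(17):  # both markers positive
        counts += _crc_counts(i, npy=12, wif1=30)
        i += 1
    for _ in range(2):  # NPY only (WIF1 below its 5-droplet threshold)
        counts += _crc_counts(i, npy=3, wif1=2)
        i += 1
    for _ in range(2):  # WIF1 only
        counts += _crc_counts(i, npy=0, wif1=8)
        i += 1
    counts += _crc_counts(i, npy=0, wif1=0)  # the stage-I negative
    metas += [
        SampleMeta(f"crc_plasma_{j:03d}", "crc_plasma", stage="I" if j == 21 else "IV")
        for j in range(22)
    ]
    for j in range(10):
        sid = f"control_plasma_{j:03d}"
        counts += [
            CountRecord(f"{sid}_NPY", sid, "NPY", N_DROPLETS, 0),
            CountRecord(f"{sid}_WIF1", sid, "WIF1", N_DROPLETS, 1),
        ]
        metas.append(SampleMeta(sid, "control_plasma"))
    truth = {m.sample_id: m.sample_class == "crc_plasma" for m in metas}
    return counts, metas, truth
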