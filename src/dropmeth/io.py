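"""Readers and writers for the pipeline's CSV/YAML/JSON dialects.

All tables are comma-separated UTF-8 with a mandatory header row and no
index column. Malformed rows are reported with their file line number
(header = line 1). Dialects:

* counts:   well_id, sample_id, marker, n_droplets, n_positive
* metadata: sample_id, class, stage, histology, dna_conc_ng_per_ul
* droplets: well_id, droplet_id, ch1_amplitude, ch2_amplitude
* panel:    YAML ``markers: {NAME: {channel, lob, threshold}}``
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Mapping, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .calling import CallResult, MarkerConfig
from .gating import DropletSet
from .records import CountRecord, SampleMeta, ValidationError

__all__ = [
    "read_counts",
    "write_counts",
    "read_metadata",
    "write_metadata",
    "read_droplets",
    "write_droplets",
    "read_panel",
    "write_panel",
    "write_calls",
    "write_report",
]

PathLike = Union[str, Path]

COUNT_COLUMNS = ["well_id", "sample_id", "marker", "n_droplets", "n_positive"]
META_COLUMNS = ["sample_id", "class", "stage", "histology", "dna_conc_ng_per_ul"]
DROPLET_COLUMNS = ["well_id", "droplet_id", "ch1_amplitude", "ch2_amplitude"]


def _load_table(path: PathLike, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required column(s) {missing}")
    return df


def read_counts(path: PathLike) -> List[CountRecord]:
    df = _load_table(path, COUNT_COLUMNS)
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            records.append(
                CountRecord(
                    well_id=row.well_id,
                    sample_id=row.sample_id,
                    marker=row.marker,
                    n_droplets=int(row.n_droplets),
                    n_positive=int(row.n_positive),
                )
            )
        except (ValueError, ValidationError) as exc:
            raise ValidationError(f"{path}: line {i}: {exc}") from exc
    return records


def write_counts(records: Sequence[CountRecord], path: PathLike) -> None:
    pd.DataFrame(
        [
            {
                "well_id": r.well_id,
                "sample_id": r.sample_id,
                "marker": r.marker,
                "n_droplets": r.n_droplets,
                "n_positive": r.n_positive,
            }
            for r in records
        ],
        columns=COUNT_COLUMNS,
    ).to_csv(path, index=False)


def read_metadata(path: PathLike) -> List[SampleMeta]:
    df = _load_table(path, META_COLUMNS[:2])
    metas = []
    seen = set()
    for i, row in enumerate(df.to_dict(orient="records"), start=2):
        sid = row["sample_id"]
        if sid in seen:
            raise ValidationError(f"{path}: line {i}: duplicate sample_id {sid!r}")
        seen.add(sid)
        conc_raw = row.get("dna_conc_ng_per_ul", "")
        try:
            metas.append(
                SampleMeta(
                    sample_id=sid,
                    sample_class=row["class"],
                    stage=row.get("stage", "") or None,
                    histology=row.get("histology", "") or None,
                    dna_conc_ng_per_ul=float(conc_raw) if conc_raw != "" else None,
                )
            )
        except (ValueError, ValidationError) as exc:
            raise ValidationError(f"{path}: line {i}: {exc}") from exc
    return metas


def write_metadata(metas: Sequence[SampleMeta], path: PathLike) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": m.sample_id,
                "class": m.sample_class,
                "stage": m.stage or "",
                "histology": m.histology or "",
                "dna_conc_ng_per_ul": "" if m.dna_conc_ng_per_ul is None else m.dna_conc_ng_per_ul,
            }
            for m in metas
        ],
        columns=META_COLUMNS,
    ).to_csv(path, index=False)


def read_droplets(path: PathLike, channel_labels=("ch1", "ch2")) -> List[DropletSet]:
    """Read a per-droplet table; one DropletSet per well, in file order."""
    df = _load_table(path, DROPLET_COLUMNS)
    out = []
    for well_id, grp in df.groupby("well_id", sort=False):
        try:
            amps = np.column_stack(
                [grp["ch1_amplitude"].astype(float), grp["ch2_amplitude"].astype(float)]
            )
        except ValueError as exc:
            raise ValidationError(f"{path}: well {well_id!r}: {exc}") from exc
        out.append(
            DropletSet(
                well_id=str(well_id),
                amplitudes=amps,
                channel_labels=(channel_labels[0], channel_labels[1]),
            )
        )
    return out


def write_droplets(droplet_sets: Sequence[DropletSet], path: PathLike) -> None:
    frames = []
    for ds in droplet_sets:
        frames.append(
            pd.DataFrame(
                {
                    "well_id": ds.well_id,
                    "droplet_id": np.arange(ds.n_droplets),
                    "ch1_amplitude": np.round(ds.amplitudes[:, 0], 3),
                    "ch2_amplitude": np.round(ds.amplitudes[:, 1], 3),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_panel(path: PathLike) -> Dict[str, MarkerConfig]:
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "markers" not in doc or not isinstance(doc["markers"], dict):
        raise ValidationError(f"{path}: panel YAML must contain a 'markers' mapping")
    panel = {}
    for name, cfg in doc["markers"].items():
        if not isinstance(cfg, dict):
            raise ValidationError(f"{path}: marker {name!r} entry must be a mapping")
        unknown = set(cfg) - {"channel", "lob", "threshold", "allow_threshold_below_lob"}
        if unknown:
            raise ValidationError(f"{path}: marker {name!r}: unknown keys {sorted(unknown)}")
        try:
            panel[name] = MarkerConfig(
                marker=name,
                channel=str(cfg.get("channel", "")),
                lob=int(cfg["lob"]),
                positivity_threshold=int(cfg["threshold"]),
                allow_threshold_below_lob=bool(cfg.get("allow_threshold_below_lob", False)),
            )
        except KeyError as exc:
            raise ValidationError(f"{path}: marker {name!r}: missing key {exc}") from exc
    if not panel:
        raise ValidationError(f"{path}: empty marker panel")
    return panel


def write_panel(panel: Mapping[str, MarkerConfig], path: PathLike) -> None:
    doc = {
        "markers": {
            name: {
                "channel": cfg.channel,
                "lob": cfg.lob,
                "threshold": cfg.positivity_threshold,
            }
            for name, cfg in panel.items()
        }
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def write_calls(calls: Sequence[CallResult], path: PathLike) -> None:
    """Wide per-sample call table: one count/call column pair per marker."""
    markers: List[str] = []
    for c in calls:
        for mc in c.marker_calls:
            if mc.marker not in markers:
                markers.append(mc.marker)
    rows = []
    for c in calls:
        row: Dict[str, object] = {"sample_id": c.sample_id}
        per = {mc.marker: mc for mc in c.marker_calls}
        for m in markers:
            key = m.lower()
            row[f"{key}_count"] = per[m].n_positive if m in per else ""
            row[f"{key}_call"] = per[m].call if m in per else ""
        row["combined"] = c.combined_call
        row["rule"] = c.rule
        row["missing_markers"] = "|".join(c.missing_markers)
        rows.append(row)
    cols = ["sample_id"]
    for m in markers:
        cols += [f"{m.lower()}_count", f"{m.lower()}_call"]
    cols += ["combined", "rule", "missing_markers"]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def write_report(report: Mapping, path: PathLike) -> None:
    """Deterministic JSON (sorted keys, fixed separators) for reproducibility."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
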