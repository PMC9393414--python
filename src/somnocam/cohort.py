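"""On-disk cohort layout: per-night CSVs plus a YAML manifest.

A cohort directory holds one feature CSV and one hypnogram CSV per night
and a ``cohort.yaml`` listing, for each recording, its id, age group and
the two file paths.  This is the interchange point between feature
extraction and classifier evaluation.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .classify import Hypnogram, Recording
from .features import read_feature_csv, write_feature_csv

#: Single-letter tokens used in hypnogram CSVs.
_STAGE_TOKEN = {"Wake": "W", "Light": "L", "Deep": "D", "REM": "R"}


def write_hypnogram_csv(hypnogram: Hypnogram, path: str | Path) -> None:
    pd.DataFrame(
        {
            "epoch_index": range(1, len(hypnogram) + 1),
            "stage": [_STAGE_TOKEN[s] for s in hypnogram.stages],
        }
    ).to_csv(path, index=False)


def read_hypnogram_csv(path: str | Path) -> Hypnogram:
    """Read a hypnogram CSV; AASM tokens (W/N1/N2/N3/R) are auto-collapsed."""
    df = pd.read_csv(path)
    if "stage" not in df.columns:
        raise ValueError(f"hypnogram CSV {path} must have a 'stage' column")
    if "epoch_index" in df.columns:
        df = df.sort_values("epoch_index")
    return Hypnogram(list(df["stage"].astype(str)))


def write_cohort(recordings: list[Recording], out_dir: str | Path) -> Path:
    """Write per-night CSVs and the manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = []
    for rec in recordings:
        feat_path = out_dir / f"{rec.recording_id}_features.csv"
        hyp_path = out_dir / f"{rec.recording_id}_hypnogram.csv"
        write_feature_csv(rec.features, feat_path)
        write_hypnogram_csv(rec.hypnogram, hyp_path)
        manifest.append(
            {
                "recording_id": rec.recording_id,
                "age_group": rec.age_group,
                "features": feat_path.name,
                "hypnogram": hyp_path.name,
            }
        )
    manifest_path = out_dir / "cohort.yaml"
    with open(manifest_path, "w") as fh:
        yaml.safe_dump({"recordings": manifest}, fh, sort_keys=False)
    return manifest_path


def read_cohort(manifest_path: str | Path, age_group: str | None = None) -> list[Recording]:
    """Load the recordings listed in a cohort manifest.

    Relative paths in the manifest resolve against the manifest's directory.
    ``age_group`` filters to one group when given.
    """
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)
    recordings = []
    for entry in manifest["recordings"]:
        if age_group is not None and entry["age_group"] != age_group:
            continue
        recordings.append(
            Recording(
                recording_id=str(entry["recording_id"]),
                age_group=str(entry["age_group"]),
                features=read_feature_csv(base / entry["features"]),
                hypnogram=read_hypnogram_csv(base / entry["hypnogram"]),
            )
        )
    return recordings
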