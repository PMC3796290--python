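"""Distance-table and configuration I/O.

The interchange format is a comma-separated table with header
``subject_id,group,hemisphere,distance_mm``, one row per GM voxel,
distances in millimeters with five decimal places.  Tables written by
this package carry leading comment lines (``#``) naming the units and
the software version; the reader skips them.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .geometry import DistanceSet

TABLE_COLUMNS = ["subject_id", "group", "hemisphere", "distance_mm"]


def write_distance_table(sets: list[DistanceSet], path) -> None:
    """Write per-subject distance sets as one CSV table."""
    from . import __version__

    frames = [
        pd.DataFrame({
            "subject_id": s.subject_id,
            "group": s.group,
            "hemisphere": s.hemisphere,
            "distance_mm": s.distances,
        })
        for s in sets
    ]
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=TABLE_COLUMNS)
    with open(path, "w") as fh:
        fh.write(f"# units: mm; lcdmcensor {__version__}\n")
        df.to_csv(fh, index=False, float_format="%.5f")


def read_distance_table(path) -> list[DistanceSet]:
    """Read a distance table, grouping rows by (subject, group, hemisphere)."""
    df = pd.read_csv(path, comment="#")
    missing = set(TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    bad = ~np.isfinite(pd.to_numeric(df["distance_mm"], errors="coerce"))
    if bad.any():
        line = int(df.index[bad][0]) + 2  # header occupies line 1
        raise ValueError(f"{path}: non-numeric distance at data line {line}")
    sets = []
    for (subj, group, hemi), sub in df.groupby(
            ["subject_id", "group", "hemisphere"], sort=True):
        sets.append(DistanceSet(str(subj), str(group), str(hemi),
                                np.empty((0, 3), dtype=int),
                                sub["distance_mm"].to_numpy(dtype=float)))
    return sets


def write_table(df: pd.DataFrame, path) -> None:
    """Write a result table (sweep, runs, MC curves) with the unit header."""
    from . import __version__

    with open(path, "w") as fh:
        fh.write(f"# units: mm; lcdmcensor {__version__}\n")
        df.to_csv(fh, index=False)


def load_config(path) -> dict:
    """Load a YAML/JSON key-value configuration file."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if doc is None:
        return {}
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return doc


def dump_config(config: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)


def merge_config(defaults: dict, config: dict, explicit: dict) -> dict:
    """Defaults < config file < explicitly given flags."""
    out = dict(defaults)
    out.update({k: v for k, v in config.items() if k in defaults})
    out.update({k: v for k, v in explicit.items() if v is not None})
    return out
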