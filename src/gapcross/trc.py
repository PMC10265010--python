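"""TRC-style tab-separated marker table IO and session manifests.

The on-disk format follows the common TRC layout: three header lines
(file type, field names, field values including frame rate, frame count,
marker count and units), a two-line column header naming each marker over
its X/Y/Z triplet, then one row per frame of ``frame  time  x y z ...``.
Missing samples (marker dropout) are written as empty cells and read back
as NaN.
"""
from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .types import MarkerTrajectorySet, Obstacle, Participant, TrialSpec

__all__ = ["write_trc", "read_trc", "write_manifest", "read_manifest"]


def write_trc(markers: MarkerTrajectorySet, path) -> None:
    path = Path(path)
    labels = markers.labels
    n = markers.n_frames
    time = markers.time
    with open(path, "w", newline="") as fh:
        fh.write(f"PathFileType\t4\t(X/Y/Z)\t{path.name}\n")
        fh.write(
            "DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\t"
            "OrigDataRate\tOrigDataStartFrame\tOrigNumFrames\n"
        )
        fh.write(
            f"{markers.frame_rate:g}\t{markers.frame_rate:g}\t{n}\t{len(labels)}\t"
            f"m\t{markers.frame_rate:g}\t1\t{n}\n"
        )
        head1 = ["Frame#", "Time"]
        head2 = ["", ""]
        for i, lb in enumerate(labels, start=1):
            head1 += [lb, "", ""]
            head2 += [f"X{i}", f"Y{i}", f"Z{i}"]
        fh.write("\t".join(head1) + "\n")
        fh.write("\t".join(head2) + "\n")
        data = np.column_stack([markers[lb] for lb in labels])
        for f in range(n):
            row = [str(f + 1), f"{time[f]:.6f}"]
            row += ["" if np.isnan(v) else f"{v:.6f}" for v in data[f]]
            fh.write("\t".join(row) + "\n")


def read_trc(path, participant: Participant, meta: dict | None = None) -> MarkerTrajectorySet:
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) < 6:
        raise ValueError(f"{path} is not a marker table (too short)")
    vals = lines[2].split("\t")
    frame_rate = float(vals[0])
    units = vals[4]
    scale = 0.001 if units.lower() == "mm" else 1.0
    labels = [v for v in lines[3].split("\t")[2:] if v]
    n_cols = 2 + 3 * len(labels)
    rows = []
    for line in lines[5:]:
        if not line.strip():
            continue
        parts = line.split("\t")
        parts += [""] * (n_cols - len(parts))
        rows.append([float(v) if v else np.nan for v in parts[2:n_cols]])
    data = np.asarray(rows) * scale
    markers = {
        lb: data[:, 3 * i : 3 * i + 3] for i, lb in enumerate(labels)
    }
    return MarkerTrajectorySet(frame_rate, markers, participant, meta)


_MANIFEST_COLS = [
    "trial_id",
    "participant",
    "mass",
    "leg_length",
    "depth_rel",
    "length_rel",
    "strategy",
    "condition",
    "steps_in_base",
    "approach_speed_target",
    "seed",
    "dropout_marker",
    "dropout_start",
    "dropout_end",
    "obstacle_x0",
    "path",
]


def write_manifest(entries: list[tuple[TrialSpec, str, float]], path) -> None:
    """Write a session manifest CSV.

    ``entries`` holds (spec, trc relative path, obstacle leading-edge x)
    tuples.
    """
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_MANIFEST_COLS)
        for spec, trc_path, x0 in entries:
            drop = spec.dropout or ("", "", "")
            writer.writerow(
                [
                    spec.trial_id,
                    spec.participant.id,
                    spec.participant.mass,
                    spec.participant.leg_length,
                    spec.obstacle.depth_rel,
                    spec.obstacle.length_rel,
                    spec.strategy,
                    spec.condition,
                    spec.steps_in_base,
                    spec.approach_speed_target,
                    spec.seed,
                    drop[0],
                    drop[1],
                    drop[2],
                    x0,
                    trc_path,
                ]
            )


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=False, na_values=[])
    missing = set(_MANIFEST_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    return df


def manifest_row_to_spec(row) -> TrialSpec:
    part = Participant(str(row["participant"]), float(row["mass"]), float(row["leg_length"]))
    dropout = None
    if str(row["dropout_marker"]):
        dropout = (
            str(row["dropout_marker"]),
            int(row["dropout_start"]),
            int(row["dropout_end"]),
        )
    return TrialSpec(
        participant=part,
        obstacle=Obstacle(float(row["depth_rel"]), float(row["length_rel"]), part.leg_length),
        strategy=str(row["strategy"]),  # type: ignore[arg-type]
        condition=str(row["condition"]),  # type: ignore[arg-type]
        approach_speed_target=float(row["approach_speed_target"]),
        steps_in_base=int(row["steps_in_base"]),
        dropout=dropout,
        seed=int(row["seed"]),
        trial_id=str(row["trial_id"]),
    )
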