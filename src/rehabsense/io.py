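"""CSV input/output for recordings and label sidecars.

One CSV per recording with header ``t,ax,ay,az``; a sidecar
``labels.csv`` with header ``recording_id,action,level,subject`` maps
recording files to their labels.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import SignalRecording

__all__ = ["write_dataset", "read_dataset", "read_recording"]


def write_dataset(recordings: list[SignalRecording], out_dir) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in recordings:
        rid = rec.recording_id or f"rec{len(rows):04d}"
        df = pd.DataFrame({"t": rec.t, "ax": rec.acc[:, 0],
                           "ay": rec.acc[:, 1], "az": rec.acc[:, 2]})
        df.to_csv(out / f"{rid}.csv", index=False, float_format="%.6f")
        rows.append({"recording_id": rid, "action": rec.action_label,
                     "level": rec.level_label, "subject": rec.subject})
    pd.DataFrame(rows).to_csv(out / "labels.csv", index=False)
    return out


def read_recording(path, action: int = 0, level: int = 0,
                   subject: int = 0) -> SignalRecording:
    df = pd.read_csv(path)
    missing = {"t", "ax", "ay", "az"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return SignalRecording(
        t=df["t"].to_numpy(), acc=df[["ax", "ay", "az"]].to_numpy(),
        action_label=action, level_label=level,
        recording_id=Path(path).stem, subject=subject)


def read_dataset(in_dir) -> list[SignalRecording]:
    in_dir = Path(in_dir)
    labels = pd.read_csv(in_dir / "labels.csv")
    recs = []
    for row in labels.itertuples(index=False):
        recs.append(read_recording(in_dir / f"{row.recording_id}.csv",
                                   action=int(row.action),
                                   level=int(row.level),
                                   subject=int(row.subject)))
    return recs
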