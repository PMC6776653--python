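"""Plain-text I/O: TAC TSVs, schedule JSON, atlas JSON, subject and BP_ND CSVs.

The analysis is ROI-level throughout, so all interchange formats are tabular
text: one TSV per subject with columns ``frame_start_s``, ``frame_duration_s``
and one activity column per region; CSV matrices for BP_ND (subjects x
regions); JSON for schedule, atlas and provenance sidecars.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .atlas import RegionAtlas  # noqa: F401  (re-exported for callers)
from .kinetics import FrameSchedule, TimeActivityCurve

__all__ = [
    "write_subject_tacs",
    "read_subject_tacs",
    "write_bpnd_csv",
    "read_bpnd_csv",
    "write_subjects_csv",
    "read_subjects_csv",
    "tac_path",
]

_FLOAT_FMT = "%.10g"  # fixed precision => byte-identical reruns


def tac_path(tacs_dir, subject_id: str) -> Path:
    return Path(tacs_dir) / f"sub-{subject_id}_tacs.tsv"


def write_subject_tacs(tacs_dir, subject_id: str,
                       tacs: dict[str, TimeActivityCurve]) -> Path:
    """Write one subject's regional TACs as a single TSV."""
    first = next(iter(tacs.values()))
    sched = first.schedule
    cols = {"frame_start_s": sched.frame_starts,
            "frame_duration_s": sched.frame_durations}
    cols.update({region: tac.values for region, tac in tacs.items()})
    df = pd.DataFrame(cols)
    path = tac_path(tacs_dir, subject_id)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    return path


def read_subject_tacs(path) -> tuple[str, FrameSchedule, dict[str, TimeActivityCurve]]:
    """Read a subject TAC TSV; the subject id is parsed from the filename."""
    path = Path(path)
    name = path.name
    if name.startswith("sub-") and name.endswith("_tacs.tsv"):
        subject_id = name[len("sub-"):-len("_tacs.tsv")]
    else:
        subject_id = path.stem
    df = pd.read_csv(path, sep="\t")
    sched = FrameSchedule(df["frame_start_s"].to_numpy(), df["frame_duration_s"].to_numpy())
    tacs = {
        col: TimeActivityCurve(sched, df[col].to_numpy(), region_id=col, subject_id=subject_id)
        for col in df.columns
        if col not in ("frame_start_s", "frame_duration_s")
    }
    return subject_id, sched, tacs


def write_bpnd_csv(path, bpnd: pd.DataFrame) -> None:
    """Subjects x regions BP_ND matrix with region-name headers."""
    bpnd.to_csv(path, index_label="subject_id", float_format=_FLOAT_FMT)


def read_bpnd_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="subject_id")


def write_subjects_csv(path, subjects: pd.DataFrame) -> None:
    subjects.to_csv(path, index_label="subject_id", float_format=_FLOAT_FMT)


def read_subjects_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="subject_id")
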