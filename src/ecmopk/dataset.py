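"""Study dataset model and the flat CSV dataset dialect.

One row per dose or observation, NONMEM-convention columns:

``ID,TIME,AMT,DUR,DV,EVID,BLQ,AGE,SEX,WT,SCR,CRCL,RRT,ECMO``

* ``EVID`` 1 = dose (AMT, DUR populated; DV empty), 0 = observation
  (DV populated; AMT, DUR empty).
* ``TIME`` hours from each subject's first dose.
* ``BLQ`` 1 marks observations below the quantification limit.
* ``SEX`` is ``M``/``F``; ``SCR`` umol/L; ``CRCL`` mL/min, may be empty
  for RRT-dependent subjects.

Rows are sorted by (ID, TIME, EVID descending) so a dose precedes an
observation at the same time.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .covariates import PatientCovariates
from .pk import DoseEvent

__all__ = [
    "Observation",
    "Subject",
    "StudyDataset",
    "DatasetValidationError",
    "read_dataset",
    "write_dataset",
]

COLUMNS = [
    "ID", "TIME", "AMT", "DUR", "DV", "EVID", "BLQ",
    "AGE", "SEX", "WT", "SCR", "CRCL", "RRT", "ECMO",
]


class DatasetValidationError(ValueError):
    """Malformed dataset; message carries offending row numbers."""


@dataclass(frozen=True)
class Observation:
    time: float
    dv: float
    blq: bool = False

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(f"observation time must be >= 0, got {self.time}")


@dataclass
class Subject:
    id: str
    covariates: PatientCovariates
    doses: list[DoseEvent] = field(default_factory=list)
    observations: list[Observation] = field(default_factory=list)

    def validate(self) -> None:
        if not self.doses:
            raise DatasetValidationError(f"subject {self.id} has no dose events")
        if not self.observations:
            raise DatasetValidationError(f"subject {self.id} has no observations")

    @property
    def quantified_observations(self) -> list[Observation]:
        return [o for o in self.observations if not o.blq]


@dataclass
class StudyDataset:
    subjects: list[Subject] = field(default_factory=list)

    def validate(self) -> None:
        if not self.subjects:
            raise DatasetValidationError("dataset contains no subjects")
        for s in self.subjects:
            s.validate()

    def __len__(self) -> int:
        return len(self.subjects)

    def n_observations(self, include_blq: bool = True) -> int:
        return sum(
            len(s.observations if include_blq else s.quantified_observations)
            for s in self.subjects
        )

    def subset(self, indices: Sequence[int], relabel: bool = True) -> "StudyDataset":
        """New dataset from subject indices (repeats allowed, for bootstrap)."""
        subjects = []
        for new_idx, i in enumerate(indices):
            src = self.subjects[i]
            sid = f"{new_idx + 1}" if relabel else src.id
            subjects.append(
                Subject(sid, src.covariates, list(src.doses), list(src.observations))
            )
        return StudyDataset(subjects)


def _fmt(x: Optional[float]) -> str:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return ""
    if float(x) == int(x):
        return str(int(x))
    return f"{float(x):.10g}"


def write_dataset(dataset: StudyDataset, path: str | Path) -> None:
    """Write the canonical flat CSV form."""
    rows = []
    for s in dataset.subjects:
        cov = s.covariates
        base = {
            "AGE": cov.age,
            "SEX": "M" if cov.sex == "male" else "F",
            "WT": cov.weight,
            "SCR": cov.serum_creatinine,
            "CRCL": cov.crcl,
            "RRT": int(cov.rrt),
            "ECMO": int(cov.ecmo),
        }
        for d in s.doses:
            rows.append({
                "ID": s.id, "TIME": d.start_time, "AMT": d.amount,
                "DUR": d.infusion_duration, "DV": None, "EVID": 1, "BLQ": 0,
                **base,
            })
        for o in s.observations:
            rows.append({
                "ID": s.id, "TIME": o.time, "AMT": None, "DUR": None,
                "DV": o.dv, "EVID": 0, "BLQ": int(o.blq), **base,
            })
    frame = pd.DataFrame(rows, columns=COLUMNS)
    order = np.lexsort((-frame["EVID"].to_numpy(), frame["TIME"].to_numpy()))
    # stable subject-block order: subjects already grouped; sort within subject
    frame["_subj_order"] = frame["ID"].map(
        {s.id: i for i, s in enumerate(dataset.subjects)}
    )
    frame = frame.sort_values(
        ["_subj_order", "TIME", "EVID"], ascending=[True, True, False],
        kind="stable",
    ).drop(columns="_subj_order")
    buf = io.StringIO()
    buf.write(",".join(COLUMNS) + "\n")
    for _, row in frame.iterrows():
        vals = [
            str(row["ID"]), _fmt(row["TIME"]), _fmt(row["AMT"]), _fmt(row["DUR"]),
            _fmt(row["DV"]), str(int(row["EVID"])), str(int(row["BLQ"])),
            _fmt(row["AGE"]), str(row["SEX"]), _fmt(row["WT"]), _fmt(row["SCR"]),
            _fmt(row["CRCL"]), str(int(row["RRT"])), str(int(row["ECMO"])),
        ]
        buf.write(",".join(vals) + "\n")
    Path(path).write_text(buf.getvalue())


def read_dataset(path: str | Path) -> StudyDataset:
    """Parse and validate the flat CSV dataset."""
    path = Path(path)
    text = path.read_text().strip()
    if not text:
        raise DatasetValidationError(f"{path}: empty dataset file")
    frame = pd.read_csv(
        path, dtype={"ID": str, "SEX": str}, keep_default_na=True,
    )
    unknown = [c for c in frame.columns if c not in COLUMNS]
    if unknown:
        raise DatasetValidationError(f"{path}: unknown columns {unknown}")
    missing = [c for c in COLUMNS if c not in frame.columns]
    if missing:
        raise DatasetValidationError(f"{path}: missing columns {missing}")
    if frame.empty:
        raise DatasetValidationError(f"{path}: no data rows")

    problems: list[str] = []
    for idx, row in frame.iterrows():
        rowno = idx + 2  # header is line 1
        evid = row["EVID"]
        if evid not in (0, 1):
            problems.append(f"row {rowno}: EVID must be 0 or 1, got {evid}")
            continue
        has_amt = not pd.isna(row["AMT"])
        has_dv = not pd.isna(row["DV"])
        if evid == 1 and (not has_amt or has_dv):
            problems.append(
                f"row {rowno}: dose row must populate AMT (not DV)"
            )
        if evid == 0 and (has_amt or not has_dv):
            problems.append(
                f"row {rowno}: observation row must populate DV (not AMT)"
            )
        if evid == 1 and row["BLQ"] == 1:
            problems.append(f"row {rowno}: BLQ=1 is only valid on observation rows")
        if row["TIME"] < 0:
            problems.append(f"row {rowno}: negative TIME")

    dup = frame.duplicated(subset=["ID", "TIME", "EVID"], keep=False)
    for idx in frame.index[dup & frame.duplicated(subset=["ID", "TIME", "EVID"])]:
        problems.append(f"row {idx + 2}: duplicate (ID, TIME, EVID) record")

    # sortedness: within the file, each subject's block must be sorted by
    # (TIME asc, EVID desc)
    for sid, grp in frame.groupby("ID", sort=False):
        key = list(zip(grp["TIME"], -grp["EVID"]))
        if key != sorted(key):
            problems.append(
                f"subject {sid}: rows not sorted by (TIME, EVID desc)"
            )
    if problems:
        raise DatasetValidationError(
            f"{path}: {len(problems)} problem(s):\n  " + "\n  ".join(problems)
        )

    subjects = []
    for sid, grp in frame.groupby("ID", sort=False):
        first = grp.iloc[0]
        crcl = None if pd.isna(first["CRCL"]) else float(first["CRCL"])
        cov = PatientCovariates(
            age=float(first["AGE"]),
            sex="male" if str(first["SEX"]).upper().startswith("M") else "female",
            weight=float(first["WT"]),
            serum_creatinine=float(first["SCR"]),
            crcl=crcl,
            rrt=bool(int(first["RRT"])),
            ecmo=bool(int(first["ECMO"])),
        )
        doses = [
            DoseEvent(float(r["AMT"]), float(r["TIME"]), float(r["DUR"]))
            for _, r in grp[grp["EVID"] == 1].iterrows()
        ]
        obs = [
            Observation(float(r["TIME"]), float(r["DV"]), bool(int(r["BLQ"])))
            for _, r in grp[grp["EVID"] == 0].iterrows()
        ]
        subjects.append(Subject(str(sid), cov, doses, obs))
    ds = StudyDataset(subjects)
    ds.validate()
    return ds
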