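"""On-disk layout for simulated cohorts.

A cohort directory holds one subdirectory per subject::

    DIR/
      manifest.csv            # subject_id, group
      truth.csv               # generating parameters (simulated cohorts only)
      <subject_id>/
        pib_plasma.csv        # time_min, activity_kBq_per_mL, parent_fraction
        water_blood.csv       # time_min, activity_kBq_per_mL
        pib_tac.csv           # frame_start_min, frame_end_min, <region>...
        water_tac.csv

All files are plain UTF-8 CSV with a header row and "." decimal.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .curves import PlasmaCurve, read_tac_table, write_tac_table
from .exceptions import InvalidInputError
from .synthetic import Cohort, SubjectRecord

__all__ = ["write_cohort", "read_cohort"]


def write_cohort(cohort: Cohort, directory) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = []
    for subject in cohort.subjects:
        sdir = directory / subject.subject_id
        sdir.mkdir(exist_ok=True)
        subject.pib_plasma.to_csv(sdir / "pib_plasma.csv")
        subject.water_blood.to_csv(sdir / "water_blood.csv")
        write_tac_table(subject.pib_tacs, sdir / "pib_tac.csv")
        write_tac_table(subject.water_tacs, sdir / "water_tac.csv")
        manifest.append({"subject_id": subject.subject_id, "group": subject.group})
    pd.DataFrame(manifest).to_csv(directory / "manifest.csv", index=False)
    if cohort.truth is not None and len(cohort.truth):
        cohort.truth.to_csv(directory / "truth.csv", index=False)
    return directory


def read_cohort(directory) -> Cohort:
    directory = Path(directory)
    manifest_path = directory / "manifest.csv"
    if not manifest_path.exists():
        raise InvalidInputError(f"no manifest.csv in {directory}")
    manifest = pd.read_csv(manifest_path)
    subjects = []
    for _, row in manifest.iterrows():
        sdir = directory / str(row["subject_id"])
        subjects.append(
            SubjectRecord(
                subject_id=str(row["subject_id"]),
                group=str(row["group"]),
                pib_plasma=PlasmaCurve.from_csv(sdir / "pib_plasma.csv", "PiB"),
                water_blood=PlasmaCurve.from_csv(sdir / "water_blood.csv", "water"),
                pib_tacs=read_tac_table(sdir / "pib_tac.csv"),
                water_tacs=read_tac_table(sdir / "water_tac.csv"),
            )
        )
    truth_path = directory / "truth.csv"
    truth = pd.read_csv(truth_path) if truth_path.exists() else pd.DataFrame()
    return Cohort(subjects=subjects, truth=truth)
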