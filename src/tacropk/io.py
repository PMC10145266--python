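"""CSV input/output contracts.

Three flat UTF-8 comma-delimited tables describe a cohort:

* concentrations: ``subject_id,time_h,conc_ng_ml`` (one row per sample; an
  empty concentration cell marks a below-quantification sample),
* dosing: ``subject_id,dose_mg`` (dose per 12-h interval),
* genotypes: ``subject_id,cyp3a5,cyp3a4`` with strings like ``*1/*3``.

Readers validate schema and values with row context; writers emit full
precision so a write/read round trip is lossless to float repr.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .nca import ConcProfile
from .pgx import GenotypeRecord
from .simulate import SubjectTruth

CONC_COLUMNS = ["subject_id", "time_h", "conc_ng_ml"]
DOSE_COLUMNS = ["subject_id", "dose_mg"]
GENO_COLUMNS = ["subject_id", "cyp3a5", "cyp3a4"]
TRUTH_COLUMNS = ["subject_id", "cyp3a5", "cyp3a4", "true_clf", "true_vf", "dose_mg"]


def _read_table(path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"input file not found: {path}")
    df = pd.read_csv(path, dtype={"subject_id": str})
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {', '.join(missing)}")
    if df["subject_id"].isna().any():
        row = int(df.index[df["subject_id"].isna()][0]) + 2
        raise ValidationError(f"{path}: empty subject_id at line {row}")
    return df


def read_concentrations(path) -> pd.DataFrame:
    df = _read_table(path, CONC_COLUMNS)
    for col in ("time_h", "conc_ng_ml"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    if df["time_h"].isna().any():
        row = int(df.index[df["time_h"].isna()][0]) + 2
        raise ValidationError(f"{path}: non-numeric time_h at line {row}")
    if (df["conc_ng_ml"].dropna() < 0).any():
        bad = df.index[df["conc_ng_ml"] < 0][0]
        raise ValidationError(
            f"{path}: negative concentration at line {int(bad) + 2}"
        )
    return df[CONC_COLUMNS]


def read_doses(path) -> pd.DataFrame:
    df = _read_table(path, DOSE_COLUMNS)
    df["dose_mg"] = pd.to_numeric(df["dose_mg"], errors="coerce")
    bad = df["dose_mg"].isna() | (df["dose_mg"] <= 0)
    if bad.any():
        row = int(df.index[bad][0]) + 2
        raise ValidationError(f"{path}: missing or non-positive dose_mg at line {row}")
    if df["subject_id"].duplicated().any():
        dup = df.loc[df["subject_id"].duplicated(), "subject_id"].iloc[0]
        raise ValidationError(f"{path}: duplicate subject_id {dup!r}")
    return df[DOSE_COLUMNS]


def read_genotypes(path) -> list[GenotypeRecord]:
    df = _read_table(path, GENO_COLUMNS)
    if df["subject_id"].duplicated().any():
        dup = df.loc[df["subject_id"].duplicated(), "subject_id"].iloc[0]
        raise ValidationError(f"{path}: duplicate subject_id {dup!r}")
    return [
        GenotypeRecord(subject_id=row.subject_id, cyp3a5=row.cyp3a5, cyp3a4=row.cyp3a4)
        for row in df.itertuples()
    ]


def profiles_from_frames(conc: pd.DataFrame, dose: pd.DataFrame) -> list[ConcProfile]:
    """Assemble per-subject profiles, pairing every subject with its dose."""
    doses = dict(zip(dose["subject_id"], dose["dose_mg"]))
    missing = sorted(set(conc["subject_id"]) - set(doses))
    if missing:
        raise ValidationError(
            f"subjects present in concentrations but absent from dosing: {', '.join(missing)}"
        )
    profiles = []
    for sid, grp in conc.groupby("subject_id", sort=True):
        grp = grp.sort_values("time_h")
        profiles.append(
            ConcProfile(
                subject_id=str(sid),
                times=grp["time_h"].to_numpy(dtype=float),
                concs=grp["conc_ng_ml"].to_numpy(dtype=float),
                dose=float(doses[sid]),
            )
        )
    return profiles


def write_concentrations(profiles: list[ConcProfile], path) -> None:
    rows = [
        {"subject_id": p.subject_id, "time_h": t, "conc_ng_ml": c}
        for p in profiles
        for t, c in zip(p.times, p.concs)
    ]
    pd.DataFrame(rows, columns=CONC_COLUMNS).to_csv(path, index=False)


def write_doses(profiles: list[ConcProfile], path) -> None:
    rows = [{"subject_id": p.subject_id, "dose_mg": p.dose} for p in profiles]
    pd.DataFrame(rows, columns=DOSE_COLUMNS).to_csv(path, index=False)


def write_genotypes(records: list[GenotypeRecord], path) -> None:
    rows = [
        {"subject_id": r.subject_id, "cyp3a5": r.cyp3a5, "cyp3a4": r.cyp3a4}
        for r in records
    ]
    pd.DataFrame(rows, columns=GENO_COLUMNS).to_csv(path, index=False)


def write_truths(truths: list[SubjectTruth], path) -> None:
    rows = [
        {
            "subject_id": t.subject_id,
            "cyp3a5": t.cyp3a5_genotype,
            "cyp3a4": t.cyp3a4_genotype,
            "true_clf": t.true_clf,
            "true_vf": t.true_vf,
            "dose_mg": t.dose,
        }
        for t in truths
    ]
    pd.DataFrame(rows, columns=TRUTH_COLUMNS).to_csv(path, index=False)


def genotypes_from_truths(truths: list[SubjectTruth]) -> list[GenotypeRecord]:
    return [
        GenotypeRecord(subject_id=t.subject_id, cyp3a5=t.cyp3a5_genotype,
                       cyp3a4=t.cyp3a4_genotype)
        for t in truths
    ]


def nca_table_to_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def nca_table_from_csv(path) -> pd.DataFrame:
    df = _read_table(path, ["subject_id", "auc_0_12"])
    return df
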