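"""Subject event-table CSV dialect: reading, validation, writing.

The dialect is a flat event table, one row per dose or observation:

    ID, EVID, TIME, DUR, AMT, OUT, SS, II,
    AGE, WT, HT, SEX, SCR, CRCL, BMI, SEPSIS, SAPS3, SOFA, MODS

EVID 1 marks a dose row (AMT mg over DUR h, OUT empty), EVID 0 an
observation row (OUT mg/L, AMT empty).  TIME is in decimal hours relative
to the subject's first dose.  SS=1 on a dose row marks steady-state
context (the schedule repeats every II hours and was running before
TIME 0).  Covariates repeat on every row of a subject; '.' or an empty
field is missing.  Files are RFC-4180 comma-separated with '.' decimal
points — comma-decimal (locale) files are rejected with a clear message.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .covariates import PatientCovariates
from .pk import DoseEvent, Regimen
from .records import SubjectRecord

__all__ = ["SubjectTableError", "read_subject_table", "write_subject_table"]

_COLUMNS = [
    "ID", "EVID", "TIME", "DUR", "AMT", "OUT", "SS", "II",
    "AGE", "WT", "HT", "SEX", "SCR", "CRCL", "BMI", "SEPSIS",
    "SAPS3", "SOFA", "MODS",
]
_NA = {".", ""}


class SubjectTableError(ValueError):
    """Validation failure in a subject event table.

    ``code`` is a stable machine-readable identifier; the message carries
    the offending row (1-based, counting the header as row 1).
    """

    def __init__(self, code: str, message: str):
        super().__init__(message)
        self.code = code


def _num(raw, row: int, col: str) -> float | None:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return None
    s = str(raw).strip()
    if s in _NA:
        return None
    try:
        return float(s)
    except ValueError:
        if "," in s:
            raise SubjectTableError(
                "comma_decimal",
                f"row {row}: value {s!r} in column {col} looks like a "
                "comma-decimal locale file; use '.' decimal points",
            ) from None
        raise SubjectTableError(
            "bad_number", f"row {row}: cannot parse {s!r} in column {col}"
        ) from None


def read_subject_table(path, strict: bool = True) -> list[SubjectRecord]:
    """Read and validate a subject event-table CSV.

    ``strict`` additionally rejects observations occurring before any dose
    and requires the CRCL covariate (needed by the renal covariate model).
    Distinct validation failures raise :class:`SubjectTableError` with
    distinct codes and 1-based row numbers.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False, skipinitialspace=True)
    missing_cols = {"ID", "EVID", "TIME"} - set(df.columns)
    if missing_cols:
        raise SubjectTableError(
            "missing_columns", f"required columns missing: {sorted(missing_cols)}"
        )

    subjects: list[SubjectRecord] = []
    for sid, group in df.groupby("ID", sort=False):
        doses: list[DoseEvent] = []
        obs_t: list[float] = []
        obs_c: list[float] = []
        ss_flag = False
        interval = None
        cov_row = None
        last_time = -np.inf
        for idx, row in group.iterrows():
            rno = idx + 2  # 1-based with header
            evid = str(row["EVID"]).strip()
            t = _num(row["TIME"], rno, "TIME")
            if t is None:
                raise SubjectTableError("missing_time", f"row {rno}: TIME is missing")
            if t < 0:
                raise SubjectTableError(
                    "negative_time", f"row {rno}: negative TIME {t}"
                )
            if t < last_time:
                raise SubjectTableError(
                    "time_order",
                    f"row {rno}: TIME decreases within subject {sid!r}",
                )
            last_time = t
            amt = _num(row.get("AMT"), rno, "AMT")
            out = _num(row.get("OUT"), rno, "OUT")
            if evid == "1":
                if amt is None or amt <= 0:
                    raise SubjectTableError(
                        "bad_dose_amount", f"row {rno}: dose row needs AMT > 0"
                    )
                if out is not None:
                    raise SubjectTableError(
                        "out_on_dose_row",
                        f"row {rno}: OUT must be empty on a dose row",
                    )
                dur = _num(row.get("DUR"), rno, "DUR") or 0.0
                doses.append(DoseEvent(t, amt, dur))
                ss = _num(row.get("SS"), rno, "SS")
                if ss:
                    ss_flag = True
                    interval = _num(row.get("II"), rno, "II")
                    if not interval or interval <= 0:
                        raise SubjectTableError(
                            "missing_interval",
                            f"row {rno}: SS=1 requires a positive II (interval)",
                        )
            elif evid == "0":
                if amt is not None:
                    raise SubjectTableError(
                        "amt_on_obs_row",
                        f"row {rno}: AMT must be empty on an observation row",
                    )
                if out is None or out < 0:
                    raise SubjectTableError(
                        "bad_observation", f"row {rno}: observation row needs OUT >= 0"
                    )
                if strict and not doses and not _truthy(row.get("SS")):
                    raise SubjectTableError(
                        "obs_before_dose",
                        f"row {rno}: observation before any dose for subject {sid!r}",
                    )
                obs_t.append(t)
                obs_c.append(out)
            else:
                raise SubjectTableError(
                    "unknown_evid", f"row {rno}: unknown EVID {evid!r}"
                )
            if cov_row is None:
                cov_row = (row, rno)

        covariates = _covariates_of(cov_row[0], cov_row[1], strict, sid)
        regimen = None
        if ss_flag and doses:
            first = doses[0]
            regimen = Regimen(first.amount, interval, first.duration)
        subjects.append(
            SubjectRecord(
                subject_id=str(sid),
                doses=doses,
                obs_times=np.array(obs_t),
                obs_conc=np.array(obs_c),
                covariates=covariates,
                steady_state=ss_flag,
                regimen=regimen,
            )
        )
    if not subjects:
        raise SubjectTableError("empty_table", "no subjects in table")
    return subjects


def _truthy(raw) -> bool:
    return str(raw).strip() not in ({"0"} | _NA)


def _covariates_of(row, rno, strict, sid) -> PatientCovariates | None:
    vals = {c: _num(row.get(c), rno, c) for c in ("AGE", "WT", "HT", "SCR", "CRCL", "BMI")}
    if strict and vals["CRCL"] is None:
        raise SubjectTableError(
            "missing_crcl",
            f"subject {sid!r}: covariate CRCL is required for the renal "
            "covariate model (strict mode)",
        )
    if vals["AGE"] is None or vals["WT"] is None or vals["HT"] is None:
        return None
    sex_raw = str(row.get("SEX", "")).strip().lower()
    sex = {"m": "male", "male": "male", "1": "male",
           "f": "female", "female": "female", "0": "female"}.get(sex_raw)
    if sex is None:
        return None
    sepsis = str(row.get("SEPSIS", "")).strip()
    ints = {c: _num(row.get(c), rno, c) for c in ("SAPS3", "SOFA", "MODS")}
    return PatientCovariates(
        age=vals["AGE"],
        weight=vals["WT"],
        height=vals["HT"],
        sex=sex,
        serum_creatinine=vals["SCR"],
        crcl=vals["CRCL"],
        bmi=vals["BMI"],
        sepsis=None if sepsis in _NA else sepsis not in ("0", "false", "False"),
        saps3=None if ints["SAPS3"] is None else int(ints["SAPS3"]),
        sofa=None if ints["SOFA"] is None else int(ints["SOFA"]),
        mods=None if ints["MODS"] is None else int(ints["MODS"]),
    )


def write_subject_table(subjects: list[SubjectRecord], path) -> None:
    """Write subjects in the event-table dialect (lossless round trip with
    :func:`read_subject_table` for records carrying full covariates)."""
    rows = []
    for s in subjects:
        cov = s.covariates
        cov_fields = {
            "AGE": _fmt(cov.age if cov else None),
            "WT": _fmt(cov.weight if cov else None),
            "HT": _fmt(cov.height if cov else None),
            "SEX": (cov.sex if cov else "."),
            "SCR": _fmt(cov.serum_creatinine if cov else None),
            "CRCL": _fmt(cov.crcl if cov else None),
            "BMI": _fmt(cov.bmi if cov else None),
            "SEPSIS": "." if cov is None or cov.sepsis is None else int(cov.sepsis),
            "SAPS3": "." if cov is None or cov.saps3 is None else cov.saps3,
            "SOFA": "." if cov is None or cov.sofa is None else cov.sofa,
            "MODS": "." if cov is None or cov.mods is None else cov.mods,
        }
        for d in s.doses:
            rows.append(
                {
                    "ID": s.subject_id, "EVID": 1, "TIME": _fmt(d.start_time),
                    "DUR": _fmt(d.duration), "AMT": _fmt(d.amount), "OUT": ".",
                    "SS": int(s.steady_state),
                    "II": _fmt(s.regimen.interval) if s.steady_state else ".",
                    **cov_fields,
                }
            )
        for t, c in zip(s.obs_times, s.obs_conc):
            rows.append(
                {
                    "ID": s.subject_id, "EVID": 0, "TIME": _fmt(t), "DUR": ".",
                    "AMT": ".", "OUT": _fmt(c), "SS": 0, "II": ".",
                    **cov_fields,
                }
            )
        rows.sort(key=lambda r: (r["ID"], float(r["TIME"]), -int(r["EVID"])))
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, index=False)


def _fmt(x) -> str:
    if x is None:
        return "."
    return repr(float(x))
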