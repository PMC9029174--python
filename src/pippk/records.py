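"""Subject-level data containers shared across the fitting and simulation
modules."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .covariates import PatientCovariates
from .pk import DoseEvent, Regimen

__all__ = ["SubjectRecord"]


@dataclass
class SubjectRecord:
    """Dose events, concentration observations and covariates for one patient.

    Times are hours relative to the first listed dose.  ``steady_state=True``
    marks that the listed doses sit on top of an established periodic steady
    state (e.g. sampling on treatment day 5): the pre-dose state at t=0 is
    then the steady-state trough of ``regimen`` rather than zero.
    """

    subject_id: str
    doses: list[DoseEvent]
    obs_times: np.ndarray
    obs_conc: np.ndarray
    covariates: PatientCovariates | None = None
    steady_state: bool = False
    regimen: Regimen | None = None
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.obs_times = np.asarray(self.obs_times, dtype=float)
        self.obs_conc = np.asarray(self.obs_conc, dtype=float)
        if self.obs_times.shape != self.obs_conc.shape or self.obs_times.ndim != 1:
            raise ValueError(
                f"subject {self.subject_id}: observation times and concentrations "
                "must be 1-D arrays of equal length"
            )
        if not self.doses:
            raise ValueError(f"subject {self.subject_id}: no dose events")
        if np.any(self.obs_times < 0):
            raise ValueError(f"subject {self.subject_id}: negative observation time")
        if np.any(self.obs_conc < 0):
            raise ValueError(f"subject {self.subject_id}: negative concentration")
        self.doses = sorted(self.doses, key=lambda d: d.start_time)
        if self.steady_state and self.regimen is None:
            # infer the repeating schedule from the first dose event
            first = self.doses[0]
            if len(self.doses) > 1:
                interval = self.doses[1].start_time - first.start_time
            else:
                raise ValueError(
                    f"subject {self.subject_id}: steady-state context needs a "
                    "regimen (or at least two dose events to infer the interval)"
                )
            self.regimen = Regimen(first.amount, interval, first.duration)

    @property
    def n_obs(self) -> int:
        return int(self.obs_times.shape[0])

    @property
    def crcl(self) -> float:
        if self.covariates is None or self.covariates.crcl is None:
            raise ValueError(
                f"subject {self.subject_id}: creatinine clearance (CRCL) missing "
                "but required by the covariate model"
            )
        return self.covariates.crcl
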