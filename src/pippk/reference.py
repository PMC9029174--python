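"""Reference defaults for piperacillin in critically ill adults.

Published population moments (mean, SD) of the final covariate model for
piperacillin in a critically ill ICU cohort, the residual-error model that
accompanied it, and the default search box for population fitting.  These
are the defaults used by the synthetic-cohort generator and by the
moments-mode Monte Carlo dosing simulations; any of them can be overridden.

``TVCL`` is the typical clearance at the reference renal function
CRCL = 60 mL/min/1.73 m2; individual clearance follows the covariate link
CL = TVCL * (CRCL / 60).
"""

from __future__ import annotations

__all__ = [
    "POPULATION_MOMENTS",
    "CRCL_REFERENCE",
    "FINAL_ERROR_MODEL_KWARGS",
    "DEFAULT_BOUNDS",
    "UNBOUND_FRACTION",
    "PA_BREAKPOINT_MG_L",
    "ASSAY_RANGE_MG_L",
]

# (mean, SD) per structural parameter; units: TVCL L/h, V L, KCP/KPC 1/h
POPULATION_MOMENTS: dict[str, tuple[float, float]] = {
    "tvcl": (3.33, 1.24),
    "v": (10.69, 4.50),
    "kcp": (1.15, 0.15),
    "kpc": (0.08, 0.09),
}

#: renal-function normalisation point of the clearance link, mL/min/1.73 m2
CRCL_REFERENCE: float = 60.0

#: residual SD = gamma * (C0 + C1 * concentration) = 5 * (1 + 0.1 * C) mg/L
FINAL_ERROR_MODEL_KWARGS: dict = {
    "c0": 1.0,
    "c1": 0.1,
    "mode": "multiplicative_gamma",
    "gamma": 5.0,
}

#: default population-fit search box (spans the reference moments +/- 3 SD
#: and literature ranges for critically ill adults)
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "tvcl": (0.3, 15.0),
    "v": (2.0, 50.0),
    "kcp": (1e-3, 5.0),
    "kpc": (1e-3, 5.0),
}

#: unbound (free) fraction of piperacillin: 30% protein binding
UNBOUND_FRACTION: float = 0.70

#: EUCAST clinical breakpoint for P. aeruginosa, mg/L
PA_BREAKPOINT_MG_L: float = 16.0

#: validated concentration range of the HPLC-UV assay, mg/L
ASSAY_RANGE_MG_L: tuple[float, float] = (2.5, 100.0)
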