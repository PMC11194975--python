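"""Health states of the anticoagulation Markov model.

The model follows a cohort of non-valvular atrial fibrillation (NVAF)
patients on oral anticoagulation. Clinical events (stroke, systemic
embolism, bleeds, myocardial infarction, cardiovascular hospitalisation)
are *tunnel* states occupied for exactly one cycle; survivors then return
to anticoagulated AF, to AF without anticoagulation, or to a chronic
post-event state. Death is the single absorbing state.
"""

from __future__ import annotations

from enum import Enum


class StateKind(str, Enum):
    TRANSIENT = "transient"
    TUNNEL = "tunnel"
    ABSORBING = "absorbing"


class HealthState(str, Enum):
    """Named health states, in canonical matrix order."""

    AF = "AF"
    ISCHEMIC_STROKE = "ISCHEMIC_STROKE"
    SE = "SE"
    ICH = "ICH"
    OTHER_MB = "OTHER_MB"
    CRNMB = "CRNMB"
    MI = "MI"
    CV_HOSP = "CV_HOSP"
    AF_NO_AC = "AF_NO_AC"
    POST_EVENT = "POST_EVENT"
    DEAD = "DEAD"


#: Canonical state order used by every matrix and trace in the package.
STATE_ORDER: tuple[str, ...] = tuple(s.value for s in HealthState)

#: Acute clinical events, in the column order of the tunnel states.
EVENTS: tuple[str, ...] = (
    "ischemic_stroke",
    "se",
    "ich",
    "other_mb",
    "crnmb",
    "mi",
    "cv_hosp",
)

#: Tunnel state reached by each event.
EVENT_STATE: dict[str, str] = {
    "ischemic_stroke": HealthState.ISCHEMIC_STROKE.value,
    "se": HealthState.SE.value,
    "ich": HealthState.ICH.value,
    "other_mb": HealthState.OTHER_MB.value,
    "crnmb": HealthState.CRNMB.value,
    "mi": HealthState.MI.value,
    "cv_hosp": HealthState.CV_HOSP.value,
}

STATE_KIND: dict[str, StateKind] = {
    HealthState.AF.value: StateKind.TRANSIENT,
    HealthState.AF_NO_AC.value: StateKind.TRANSIENT,
    HealthState.POST_EVENT.value: StateKind.TRANSIENT,
    HealthState.DEAD.value: StateKind.ABSORBING,
    **{EVENT_STATE[e]: StateKind.TUNNEL for e in EVENTS},
}

#: Treatment strategies compared by the model. ``vka`` is warfarin.
STRATEGIES: tuple[str, ...] = ("apixaban", "rivaroxaban", "vka")

#: Human-readable strategy labels for reports.
STRATEGY_LABEL: dict[str, str] = {
    "apixaban": "Apixaban",
    "rivaroxaban": "Rivaroxaban",
    "vka": "Warfarin",
}
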