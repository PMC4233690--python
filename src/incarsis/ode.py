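"""Mean-field SIS analysis: steady state, critical sentence length, calibration.

Under random mixing and a homogeneous transmission rate the agent model
reduces to the classic SIS ordinary differential equation; ignoring births
and deaths its steady-state prevalence is

    I* = 0               if p * s <= 1,
    I* = 1 - 1 / (p s)   otherwise,

where ``p`` is the mean number of transmissions per infected person per
month and ``s`` the sentence length in months.  The bifurcation at the
critical sentence s_c = 1/p is what lets a three-month sentencing
difference separate extinction from a multi-percent steady state.

``calibrate_mean_rate`` recovers a population-wide ``p`` from agent-model
event logs as (contact infections) / (incarcerated person-months), so the
simulated epidemic provides its own mean-field summary.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


class OdeError(ValueError):
    pass


def steady_state_prevalence(p: float, s: float) -> float:
    """SIS steady state max(0, 1 - 1/(p*s)); 0 below the critical point."""
    if p < 0 or s < 0:
        raise OdeError("p and s must be non-negative")
    ps = p * s
    if ps <= 1.0:
        return 0.0
    return 1.0 - 1.0 / ps


def critical_sentence(p: float) -> float:
    """Critical duration of infectivity s_c = 1/p."""
    if p <= 0:
        raise OdeError("no finite critical sentence for p <= 0")
    return 1.0 / p


def calibrate_mean_rate(event_logs) -> float:
    """Population-wide mean transmission rate from one or more event logs.

    p_hat = (# contact-source infections) / (total incarcerated
    person-months actually served), pooled over all provided logs and
    replicates.  Person-months count every spell's served duration
    (end_month - start_month), whatever its end reason.
    """
    if isinstance(event_logs, pd.DataFrame):
        event_logs = [event_logs]
    contact = 0
    person_months = 0
    for log in event_logs:
        contact += int((log["source"] == "contact").sum())
        person_months += int((log["end_month"] - log["start_month"]).sum())
    if person_months == 0:
        raise OdeError("event logs contain no incarcerated person-months")
    return contact / person_months


def bifurcation_sweep(p: float, s_lo: float = 1.0, s_hi: float = 40.0,
                      step: float = 0.1) -> pd.DataFrame:
    """Steady-state prevalence over a grid of sentence lengths (for plotting)."""
    s = np.arange(s_lo, s_hi + step / 2, step)
    prev = np.where(p * s <= 1.0, 0.0, 1.0 - 1.0 / np.maximum(p * s, 1e-300))
    return pd.DataFrame({"sentence_months": s, "steady_state_prevalence": prev})
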