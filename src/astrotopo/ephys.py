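"""Passive membrane properties and I/V phenotype from voltage-step recordings.

In the whole-cell configuration the total input resistance is the series
resistance plus the membrane resistance, R_In = R_S + R_M.  From a small
hyperpolarizing test step (−85 → −90 mV, ΔU = −5 mV):

    R_In = (U2 − U1) / (I2 − I1)        (steady-state currents)
    R_S  = (U2 − U1) / (I_peak − I1)    (peak of the initial transient)
    R_M  = R_In − R_S

Recordings with R_S > 15 MΩ fail quality control (insufficient electrical
and diffusional access).  The I/V relationship over the full step family
(−150 … +50 mV) separates passive astrocytes (PA, Ohmic/linear I/V) from
non-passive astrocytes (nPA, voltage-activated outward currents giving an
outwardly rectifying I/V); the distinction is quantified by a
rectification index — the chord conductance at the depolarized end of the
I/V divided by that at the hyperpolarized end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "VoltageStepProtocol",
    "CurrentTraceSet",
    "PassiveProperties",
    "IVCurve",
    "compute_passive_properties",
    "extract_iv_curve",
    "classify_phenotype",
]

RS_QC_LIMIT_MOHM = 15.0


@dataclass
class VoltageStepProtocol:
    """The standard voltage-step protocol.

    Holding −85 mV (near the astrocyte resting potential); steps from
    −150 mV to +50 mV in 10 mV increments, 50 ms each, sampled at 50 kHz.
    ``baseline_ms`` is the pre-step holding segment included in each trace.
    """

    holding: float = -85.0       # mV
    step_start: float = -150.0   # mV
    step_end: float = 50.0       # mV
    increment: float = 10.0      # mV
    duration: float = 50.0       # ms
    sampling_rate: float = 50.0  # kHz
    baseline_ms: float = 10.0    # ms of pre-step holding

    def validate(self) -> None:
        if self.increment <= 0:
            raise ValueError("increment must be positive")
        if self.duration <= 0 or self.sampling_rate <= 0:
            raise ValueError("duration and sampling_rate must be positive")
        span = self.step_end - self.step_start
        if not np.isclose(span % self.increment, 0.0) and not np.isclose(
            span % self.increment, self.increment
        ):
            raise ValueError("(step_end - step_start) must be divisible by increment")
        if self.baseline_ms < 0:
            raise ValueError("baseline_ms must be non-negative")

    def command_voltages(self) -> np.ndarray:
        n = int(round((self.step_end - self.step_start) / self.increment)) + 1
        return self.step_start + self.increment * np.arange(n)


@dataclass
class CurrentTraceSet:
    """Current responses to a voltage-step family.

    ``currents_na`` has one row per command voltage; ``step_onset_ms``
    marks where the baseline ends and the step begins.
    """

    time_ms: np.ndarray
    currents_na: np.ndarray
    command_voltages: np.ndarray
    step_onset_ms: float = 10.0

    def __post_init__(self) -> None:
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.currents_na = np.atleast_2d(np.asarray(self.currents_na, dtype=float))
        self.command_voltages = np.asarray(self.command_voltages, dtype=float)
        if self.currents_na.shape[0] != len(self.command_voltages):
            raise ValueError("one current trace per command voltage is required")
        if self.currents_na.shape[1] != len(self.time_ms):
            raise ValueError("trace length must match the time vector")
        if len(self.time_ms) >= 2:
            dt = np.diff(self.time_ms)
            if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6):
                raise ValueError("time vector must be uniformly increasing")

    def trace_at(self, command_mv: float) -> np.ndarray:
        idx = np.flatnonzero(np.isclose(self.command_voltages, command_mv, atol=1e-6))
        if idx.size == 0:
            raise ValueError(f"no trace for command voltage {command_mv} mV")
        return self.currents_na[idx[0]]


@dataclass
class PassiveProperties:
    r_in: float   # MΩ
    r_s: float    # MΩ
    r_m: float    # MΩ
    qc_pass: bool
    i1_na: float = float("nan")
    i2_na: float = float("nan")
    i_peak_na: float = float("nan")


@dataclass
class IVCurve:
    voltages: np.ndarray              # mV
    steady_state_currents: np.ndarray  # nA, mean over the final 10% of the step
    linearity_r2: float
    rectification_index: float
    phenotype: str                    # "PA" or "nPA"


def _steady_window(traces: CurrentTraceSet, duration_ms: float) -> np.ndarray:
    """Sample mask for the final 10% of the voltage step."""
    t0 = traces.step_onset_ms + 0.9 * duration_ms
    t1 = traces.step_onset_ms + duration_ms
    mask = (traces.time_ms >= t0) & (traces.time_ms <= t1 + 1e-9)
    if not mask.any():
        raise ValueError("no samples in the steady-state window")
    return mask


def compute_passive_properties(
    traces: CurrentTraceSet,
    protocol: VoltageStepProtocol | None = None,
    test_step: float = -5.0,
) -> PassiveProperties:
    """Input, series and membrane resistance from the hyperpolarizing test step.

    ``test_step`` is the step amplitude relative to holding (−5 mV by
    default, i.e. the −85 → −90 mV step).  I1 is the baseline steady
    current at holding, I2 the mean current over the final 10% of the step,
    and I_peak the extremal current of the initial transient.  The QC flag
    is True iff R_S ≤ 15 MΩ.
    """
    protocol = protocol or VoltageStepProtocol()
    u1 = protocol.holding
    u2 = protocol.holding + test_step
    trace = traces.trace_at(u2)  # raises if the test step is missing
    if not np.all(np.isfinite(trace)):
        raise ValueError("trace contains non-finite samples")

    base_mask = traces.time_ms < traces.step_onset_ms
    if not base_mask.any():
        raise ValueError("no baseline segment precedes the step")
    i1 = float(trace[base_mask].mean())

    i2 = float(trace[_steady_window(traces, protocol.duration)].mean())

    # initial transient: first 20% of the step (or at least 1 ms)
    t_win = max(0.2 * protocol.duration, 1.0)
    trans = (traces.time_ms >= traces.step_onset_ms) & (
        traces.time_ms <= traces.step_onset_ms + t_win
    )
    seg = trace[trans]
    i_peak = float(seg[np.argmax(np.abs(seg - i1))])

    du = u2 - u1
    if i2 == i1 or i_peak == i1:
        raise ValueError("zero current change; resistances are undefined")
    r_in = du / (i2 - i1)   # mV / nA = MΩ
    r_s = du / (i_peak - i1)
    r_m = r_in - r_s
    return PassiveProperties(
        r_in=r_in, r_s=r_s, r_m=r_m, qc_pass=bool(r_s <= RS_QC_LIMIT_MOHM),
        i1_na=i1, i2_na=i2, i_peak_na=i_peak,
    )


def extract_iv_curve(
    traces: CurrentTraceSet,
    protocol: VoltageStepProtocol | None = None,
    ri_threshold: float = 1.2,
) -> IVCurve:
    """Steady-state I/V relationship with linearity and rectification measures.

    Steady-state current per step is the mean over the final 10% of the
    step.  ``linearity_r2`` is the R² of a straight-line fit of I on V;
    the rectification index is the chord conductance over the two most
    depolarized steps divided by the chord conductance over the two most
    hyperpolarized steps (1 for an Ohmic cell, > 1 for outward
    rectification).
    """
    protocol = protocol or VoltageStepProtocol()
    if not np.all(np.isfinite(traces.currents_na)):
        raise ValueError("traces contain non-finite samples")
    if len(traces.command_voltages) < 4:
        raise ValueError("need at least 4 steps for an I/V curve")

    order = np.argsort(traces.command_voltages)
    v = traces.command_voltages[order]
    mask = _steady_window(traces, protocol.duration)
    i_ss = traces.currents_na[order][:, mask].mean(axis=1)

    slope, intercept = np.polyfit(v, i_ss, 1)
    resid = i_ss - (slope * v + intercept)
    ss_tot = float(np.sum((i_ss - i_ss.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else float("nan")

    g_depol = (i_ss[-1] - i_ss[-2]) / (v[-1] - v[-2])
    g_hyper = (i_ss[1] - i_ss[0]) / (v[1] - v[0])
    if g_hyper == 0:
        raise ValueError("zero hyperpolarized chord conductance")
    ri = float(g_depol / g_hyper)

    iv = IVCurve(v, i_ss, float(r2), ri, phenotype="")
    iv.phenotype = classify_phenotype(iv, ri_threshold)
    return iv


def classify_phenotype(iv: IVCurve, ri_threshold: float = 1.2) -> str:
    """nPA iff the rectification index strictly exceeds the threshold, else PA."""
    return "nPA" if iv.rectification_index > ri_threshold else "PA"
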