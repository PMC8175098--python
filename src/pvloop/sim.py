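"""Time-varying elastance ventricle with Windkessel afterload.

This module is the package's synthetic-data generator.  It emulates the
physiology of a chronic pulmonary-artery-banding (PAB) experiment in
juvenile pigs: a single-ventricle time-varying elastance chamber ejecting
into a three-element Windkessel, filled from a constant-pressure venous
reservoir through a filling resistance.  Each simulated animal carries an
independent right-heart (pulmonary circuit) and left-heart (systemic
circuit) system; the leftward septal shift of pulmonary hypertension is
represented by a reduction of the left-sided filling pressure rather than
by an explicit septum (a preload-coupling surrogate).

Ventricular pressure follows

    P(V, t) = [Emin + (Emax - Emin) e(t)] (V - V0)
              + (1 - e(t)) k_passive max(V - V_passive, 0)

with a dimensionless activation e(t) rising as a half-cosine to 1 at
``t_peak`` and decaying exponentially with time constant ``relax_tau``.
At the activation peak the pressure lies exactly on the end-systolic line
``Emax (V - V0)``, so end-systolic points logged at the peak recover the
ESPVR by construction; in late diastole the chamber relaxes onto a
near-zero pressure floor (``Emin`` is kept small), which is what makes the
zero-asymptote Weiss tau a faithful estimate of ``relax_tau``.

Caval occlusion is modelled as a per-beat linear ramp of the venous
pressure; drugs act multiplicatively on contractility, heart rate,
peripheral resistance and venous pressure through saturating Hill-type
dose responses.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .trace import PVTrace

__all__ = [
    "VentricleParams",
    "CircuitParams",
    "DrugModel",
    "DRUG_MODELS",
    "SimResult",
    "activation",
    "activation_curve",
    "simulate_stage",
    "simulate_occlusion",
    "apply_drug",
    "pab_transform",
    "PabEffects",
]


@dataclass(frozen=True)
class VentricleParams:
    """Chamber parameters of the time-varying elastance ventricle.

    Emax/Emin in mmHg/ml, V0 (volume-axis intercept of the end-systolic
    line) in ml, period and t_peak in s, relax_tau in s, passive_stiffness
    in mmHg/ml and passive_v0 (volume at which passive pressure engages)
    in ml.
    """

    Emax: float
    Emin: float
    V0: float
    period: float
    t_peak: float
    relax_tau: float
    passive_stiffness: float
    passive_v0: float = 0.0

    def __post_init__(self) -> None:
        if not (self.Emax > self.Emin > 0):
            raise ValueError(f"need Emax > Emin > 0, got {self.Emax}, {self.Emin}")
        if not (0 < self.t_peak < self.period):
            raise ValueError("need 0 < t_peak < period")
        if self.relax_tau <= 0:
            raise ValueError("relax_tau must be positive")
        if self.passive_stiffness < 0:
            raise ValueError("passive_stiffness must be non-negative")


@dataclass(frozen=True)
class CircuitParams:
    """Windkessel afterload and venous filling circuit.

    R_char: characteristic (valve + proximal artery) resistance, mmHg·s/ml.
    R_periph: peripheral resistance draining the arterial compliance.
    C_art: arterial compliance, ml/mmHg.
    P_venous: filling (atrial/venous) pressure, mmHg.
    R_fill: inflow resistance, mmHg·s/ml.
    """

    R_char: float
    R_periph: float
    C_art: float
    P_venous: float
    R_fill: float

    def __post_init__(self) -> None:
        for name in ("R_char", "R_periph", "C_art", "P_venous", "R_fill"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def activation(t: float, params: VentricleParams) -> float:
    """Dimensionless activation e(t) in [0, 1] for 0 <= t < period.

    Half-cosine rise from 0 to 1 at ``t_peak``, then exponential decay with
    ``relax_tau``.
    """
    if not (0 <= t < params.period):
        raise ValueError("t must satisfy 0 <= t < period")
    if t <= params.t_peak:
        return 0.5 * (1.0 - math.cos(math.pi * t / params.t_peak))
    return math.exp(-(t - params.t_peak) / params.relax_tau)


def activation_curve(params: VentricleParams, dt: float) -> np.ndarray:
    """Sampled activation over one period; t_peak is snapped to the grid.

    Snapping guarantees that one sample per beat sits exactly at the
    elastance maximum, so ground-truth end-systolic points lie exactly on
    the Emax line.
    """
    n = int(round(params.period / dt))
    k_peak = int(round(params.t_peak / dt))
    k_peak = min(max(k_peak, 1), n - 1)
    t = np.arange(n) * dt
    e = np.empty(n)
    rise = t[: k_peak + 1]
    e[: k_peak + 1] = 0.5 * (1.0 - np.cos(np.pi * rise / (k_peak * dt)))
    e[k_peak] = 1.0
    e[k_peak + 1 :] = np.exp(-(t[k_peak + 1 :] - k_peak * dt) / params.relax_tau)
    return e


class SteadyStateError(RuntimeError):
    """Raised when the simulated beat train does not settle."""


#: Soft lower bound on chamber volume, ml.  A linear ESPVR extrapolated to
#: its (often negative) volume intercept would let a strongly stimulated
#: chamber eject to nonphysical volumes; real ventricles stop short of
#: emptying.  Ejection flow is suppressed below this volume.
V_FLOOR_ML = 3.0


@dataclass
class BeatTruth:
    """Per-beat ground truth logged by the simulator."""

    EDV: float          # volume at beat onset, ml
    ESV: float          # volume at the elastance peak, ml
    ESP: float          # pressure at the elastance peak, mmHg (= Emax*(ESV-V0))
    SV: float           # EDV of this beat minus minimum volume reached, ml
    Pmax: float         # peak ventricular pressure over the beat, mmHg
    P_venous: float     # filling pressure during this beat, mmHg


@dataclass
class SimResult:
    """A simulated trace with its ground-truth log."""

    trace: PVTrace
    beats: list  # list[BeatTruth]
    arterial_pressure: np.ndarray  # Pa(t) aligned with the trace samples
    vparams: VentricleParams
    cparams: CircuitParams

    @property
    def SAP(self) -> float:
        return float(self.arterial_pressure.max())

    @property
    def DAP(self) -> float:
        return float(self.arterial_pressure.min())

    @property
    def MAP(self) -> float:
        return float(self.arterial_pressure.mean())

    @property
    def heart_rate(self) -> float:
        return 60.0 / self.vparams.period

    @property
    def stroke_volume(self) -> float:
        return float(np.mean([b.SV for b in self.beats]))

    @property
    def cardiac_output(self) -> float:
        """L/min, from mean stroke volume and the pacing rate."""
        return self.stroke_volume * self.heart_rate / 1000.0


def _integrate(vp: VentricleParams, cp: CircuitParams, n_beats: int, dt: float,
               *, warmup_max: int = 50, sv_tol: float = 0.01,
               pven_ramp: float = 0.0, require_steady: bool = True,
               ventricle: str = "LV", stage_label: str = "") -> SimResult:
    """Euler-integrate the chamber + Windkessel system.

    Runs warm-up beats until the stroke volume of consecutive beats agrees
    within ``sv_tol`` (relative), then records ``n_beats`` beats.  When
    ``pven_ramp`` > 0 the venous pressure is lowered by that many mmHg at
    each recorded beat boundary (caval occlusion); the ramp stops (with the
    remaining beats truncated) if it would drive the venous pressure to zero.
    """
    if dt > 1e-3:
        raise ValueError("dt must be <= 1 ms")
    if n_beats < 3:
        raise ValueError("n_beats must be >= 3")
    e_curve = activation_curve(vp, dt)
    n_per = e_curve.size
    k_peak = int(np.argmax(e_curve))
    Emin, Emax, V0 = vp.Emin, vp.Emax, vp.V0
    ks, Vp = vp.passive_stiffness, vp.passive_v0
    Rc, Rp, Ca, Rf = cp.R_char, cp.R_periph, cp.C_art, cp.R_fill
    Pven = cp.P_venous

    # start near a plausible diastolic operating point
    V = max(V0 + 1.0, Vp + Pven / max(ks, 1e-6) if ks > 0 else V0 + 30.0)
    Pa = Pven + 20.0

    def run_beat(V, Pa, Pven, record):
        p_out = v_out = pa_out = None
        if record:
            p_out = np.empty(n_per)
            v_out = np.empty(n_per)
            pa_out = np.empty(n_per)
        EDV = V
        Vmin = V
        Pmax = -np.inf
        ESV = ESP = np.nan
        for k in range(n_per):
            e = e_curve[k]
            el = Emin + (Emax - Emin) * e
            Pv = el * (V - V0)
            if ks > 0.0 and V > Vp:
                Pv += (1.0 - e) * ks * (V - Vp)
            if record:
                p_out[k] = Pv
                v_out[k] = V
                pa_out[k] = Pa
            if k == k_peak:
                ESV = V
                ESP = Emax * (V - V0)
            q_out = (Pv - Pa) / Rc if (Pv > Pa and V > V_FLOOR_ML) else 0.0
            q_in = (Pven - Pv) / Rf if Pven > Pv else 0.0
            V += (q_in - q_out) * dt
            Pa += (q_out - Pa / Rp) / Ca * dt
            if V < Vmin:
                Vmin = V
        truth = BeatTruth(EDV=EDV, ESV=ESV, ESP=ESP, SV=EDV - Vmin,
                          Pmax=float(p_out.max()) if record else Pmax,
                          P_venous=Pven)
        return V, Pa, truth, (p_out, v_out, pa_out)

    # warm-up to periodic steady state
    prev_sv = None
    steady = False
    for _ in range(warmup_max):
        V, Pa, truth, _arr = run_beat(V, Pa, Pven, record=False)
        sv = truth.SV
        if prev_sv is not None and sv > 0 and abs(sv - prev_sv) <= sv_tol * sv:
            steady = True
            break
        prev_sv = sv
    if require_steady and not steady:
        raise SteadyStateError(f"no steady state within {warmup_max} beats")

    pressures, volumes, arterials, truths = [], [], [], []
    for b in range(n_beats):
        if pven_ramp > 0.0 and b > 0:
            if Pven - pven_ramp <= 0.0:
                break  # truncate: occlusion would exhaust the venous reservoir
            Pven -= pven_ramp
        V, Pa, truth, (p, v, pa) = run_beat(V, Pa, Pven, record=True)
        pressures.append(p)
        volumes.append(v)
        arterials.append(pa)
        truths.append(truth)

    p = np.concatenate(pressures)
    v = np.concatenate(volumes)
    pa = np.concatenate(arterials)
    fs = 1.0 / dt
    t = np.arange(p.size) / fs
    trace = PVTrace(t, p, v, sampling_rate=fs, ventricle=ventricle,
                    stage_label=stage_label)
    return SimResult(trace=trace, beats=truths, arterial_pressure=pa,
                     vparams=vp, cparams=cp)


def simulate_stage(vparams: VentricleParams, cparams: CircuitParams,
                   n_beats: int = 8, dt: float = 5e-4, *,
                   ventricle: str = "LV", stage_label: str = "") -> SimResult:
    """Simulate ``n_beats`` beats at periodic steady state.

    Steady state means consecutive beats' stroke volumes agree within 1%;
    failure to settle within 50 beats raises :class:`SteadyStateError`.
    """
    return _integrate(vparams, cparams, n_beats, dt,
                      ventricle=ventricle, stage_label=stage_label)


def simulate_occlusion(vparams: VentricleParams, cparams: CircuitParams,
                       n_beats: int = 22, dt: float = 5e-4,
                       ramp_rate: float = 0.25, *,
                       ventricle: str = "LV",
                       stage_label: str = "") -> SimResult:
    """Simulate a caval-occlusion run: venous pressure drops ``ramp_rate``
    mmHg per beat after an initial steady beat.

    The ground-truth log carries the true end-diastolic volume and the true
    end-systolic point (at the elastance peak) of every beat, so occlusion
    analysis can be validated against the generating ESPVR.
    """
    return _integrate(vparams, cparams, n_beats, dt, pven_ramp=ramp_rate,
                      ventricle=ventricle, stage_label=stage_label)


# ---------------------------------------------------------------------------
# pharmacology


@dataclass(frozen=True)
class DrugModel:
    """Saturating dose–response coefficients for one drug.

    Each gain g maps a dose d to a multiplier 1 + g * d / (d + EC50)
    (identity at zero dose, 1 + g in the high-dose limit).  ``Emax_gain``
    scales contractility, ``HR_gain`` heart rate, ``Rp_gain`` systemic
    peripheral resistance, ``Pven_gain`` venous (filling) pressure.
    ``rp_pulmonary_fraction`` attenuates the resistance effect on the
    pulmonary circuit relative to the systemic one.  Doses and EC50 in
    µg/kg/min; coefficients are phenomenological, tuned once to the
    qualitative pharmacology (vasopressor vs inodilator), not claimed to be
    physiological constants.
    """

    name: str
    Emax_gain: float
    HR_gain: float
    Rp_gain: float
    Pven_gain: float
    EC50: float
    dose_grid: tuple
    rp_pulmonary_fraction: float = 0.4

    def __post_init__(self) -> None:
        if self.EC50 <= 0:
            raise ValueError("EC50 must be positive")

    def multiplier(self, gain: float, dose: float) -> float:
        if dose < 0:
            raise ValueError("dose must be >= 0")
        return 1.0 + gain * dose / (dose + self.EC50)


#: Default drug library.  Norepinephrine: strong vasopressor (resistance and
#: venous-tone gains dominate) with modest direct inotropy; dobutamine:
#: strong inotrope/chronotrope with mild vasodilation.  Dose grids follow
#: the incremental-infusion protocol being emulated.
DRUG_MODELS: dict[str, DrugModel] = {
    "norepinephrine": DrugModel(
        name="norepinephrine",
        Emax_gain=0.35, HR_gain=0.30, Rp_gain=0.40, Pven_gain=1.00,
        EC50=0.15, dose_grid=(0.05, 0.1, 0.25, 0.5),
    ),
    "dobutamine": DrugModel(
        name="dobutamine",
        Emax_gain=0.7, HR_gain=0.35, Rp_gain=-0.20, Pven_gain=0.05,
        EC50=3.0, dose_grid=(1.0, 2.5, 5.0, 10.0),
    ),
}


def apply_drug(vparams: VentricleParams, cparams: CircuitParams,
               drug: str | DrugModel, dose: float, *,
               pulmonary: bool = False) -> tuple[VentricleParams, CircuitParams]:
    """Return drug-modified copies of the ventricle and circuit parameters.

    ``pulmonary=True`` marks the right-heart system: the peripheral
    resistance effect is attenuated by ``rp_pulmonary_fraction`` and the
    venous-tone effect applies to the systemic venous return on both sides.
    """
    if isinstance(drug, str):
        try:
            model = DRUG_MODELS[drug]
        except KeyError:
            raise ValueError(f"unknown drug {drug!r}; known: {sorted(DRUG_MODELS)}")
    else:
        model = drug
    m_emax = model.multiplier(model.Emax_gain, dose)
    m_hr = model.multiplier(model.HR_gain, dose)
    rp_gain = model.Rp_gain * (model.rp_pulmonary_fraction if pulmonary else 1.0)
    m_rp = model.multiplier(rp_gain, dose)
    m_pven = model.multiplier(model.Pven_gain, dose)
    new_period = vparams.period / m_hr
    vp = replace(vparams, Emax=vparams.Emax * m_emax,
                 period=new_period,
                 t_peak=vparams.t_peak * min(1.0, 1.0 / m_hr ** 0.5),
                 relax_tau=vparams.relax_tau / m_hr ** 0.5)
    cp = replace(cparams, R_periph=cparams.R_periph * m_rp,
                 P_venous=cparams.P_venous * m_pven)
    return vp, cp


# ---------------------------------------------------------------------------
# pulmonary artery banding


@dataclass(frozen=True)
class PabEffects:
    """Multipliers turning a control animal into a banded one.

    ``rv_rp_mult`` raises pulmonary resistance (the band), ``rv_emax_mult``
    the compensatory RV hypertrophy, and ``lv_preload_mult`` lowers the
    left-sided filling pressure (septal-shift surrogate reducing LV EDV).
    """

    rv_rp_mult: float = 1.6
    rv_emax_mult: float = 1.7
    lv_preload_mult: float = 0.57


def pab_transform(rv: tuple[VentricleParams, CircuitParams],
                  lv: tuple[VentricleParams, CircuitParams],
                  effects: PabEffects | None = None):
    """Apply the banding transform to a (RV system, LV system) pair."""
    effects = effects or PabEffects()
    rv_v, rv_c = rv
    lv_v, lv_c = lv
    rv_v = replace(rv_v, Emax=rv_v.Emax * effects.rv_emax_mult)
    rv_c = replace(rv_c, R_periph=rv_c.R_periph * effects.rv_rp_mult)
    lv_c = replace(lv_c, P_venous=lv_c.P_venous * effects.lv_preload_mult)
    return (rv_v, rv_c), (lv_v, lv_c)


# ---------------------------------------------------------------------------
# default porcine parameter sets (≈ 38 kg pig under general anaesthesia)

#: Left ventricle + systemic circulation defaults.
LV_CONTROL = (
    VentricleParams(Emax=1.50, Emin=0.04, V0=-22.0, period=0.75, t_peak=0.30,
                    relax_tau=0.045, passive_stiffness=0.16, passive_v0=40.0),
    CircuitParams(R_char=0.045, R_periph=1.05, C_art=1.45, P_venous=10.0,
                  R_fill=0.015),
)

#: Right ventricle + pulmonary circulation defaults.
RV_CONTROL = (
    VentricleParams(Emax=0.50, Emin=0.05, V0=-18.0, period=0.75, t_peak=0.32,
                    relax_tau=0.085, passive_stiffness=0.16, passive_v0=30.0),
    CircuitParams(R_char=0.030, R_periph=0.40, C_art=3.0, P_venous=7.0,
                  R_fill=0.015),
)

def recovery_benchmark_params(emax: float, r_periph: float):
    """A chamber/circuit pair used for parameter-recovery benchmarking.

    Designed so the analysis pipeline's estimators are unbiased at zero
    noise: the passive curve engages only above the end-systolic volume
    range (the diastolic pressure floor stays near zero, so the
    zero-asymptote Weiss tau matches ``relax_tau``), and the occlusion
    keeps end-diastolic volume above the passive knee (the EDPVR stays
    linear at ``passive_stiffness``).
    """
    return (
        VentricleParams(Emax=emax, Emin=0.005, V0=5.0, period=0.75,
                        t_peak=0.30, relax_tau=0.045,
                        passive_stiffness=0.30, passive_v0=65.0),
        CircuitParams(R_char=0.045, R_periph=r_periph, C_art=1.45,
                      P_venous=10.0, R_fill=0.015),
    )


#: Default caval-occlusion venous ramp, mmHg per beat, per ventricle.  Chosen
#: to shed roughly a quarter of the end-diastolic volume over a 20-beat run
#: while keeping end-systolic volumes well away from zero.
OCCLUSION_RAMP = {"LV": 0.22, "RV": 0.11}

#: Occlusion ramp as a fraction of the prevailing venous pressure per beat —
#: used by the study generator so drug-induced venous-tone changes do not
#: alter the relative depth of the maneuver.
OCCLUSION_RAMP_FRAC = {"LV": 0.022, "RV": 0.016}
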