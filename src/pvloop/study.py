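"""Crossover study emitter: the full synthetic experiment.

Generates the dataset of a two-group, two-drug crossover dose-response
study: control and pulmonary-artery-banded animals, each measured at a
pre-treatment baseline, four incremental doses of the first drug, a
post-washout second baseline, and four incremental doses of the second
drug (drug order randomised per subject).  Every measurement point
carries steady-state PV traces and caval-occlusion runs for both
ventricles plus a systemic hemodynamic panel; a ground-truth log of the
generating parameters rides along for validation.

All randomness (inter-subject parameter jitter, drug-order permutation,
washout drift, measurement noise) flows from a single integer seed, so a
study specification reproduces byte-identically.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np

from .panel import HemoPanel, bsa_from_weight
from .sim import (
    DRUG_MODELS,
    LV_CONTROL,
    OCCLUSION_RAMP_FRAC,
    RV_CONTROL,
    CircuitParams,
    PabEffects,
    SimResult,
    VentricleParams,
    apply_drug,
    pab_transform,
    simulate_occlusion,
    simulate_stage,
)
from .trace import PVTrace, write_trace

__all__ = ["CrossoverStudySpec", "StageData", "SubjectData", "StudyDataset",
           "generate_study", "write_study", "load_study"]


@dataclass(frozen=True)
class CrossoverStudySpec:
    """Study-design knobs; defaults reproduce the emulated experiment."""

    n_control: int = 6
    n_pab: int = 5
    drugs: tuple = ("norepinephrine", "dobutamine")
    pab_effects: PabEffects = field(default_factory=PabEffects)
    pressure_sd: float = 0.2        # additive Gaussian, mmHg per sample
    volume_sd: float = 0.5          # additive Gaussian, ml per sample
    subject_jitter: float = 0.05    # lognormal sigma on subject parameters
    washout_drift_sd: float = 0.02  # lognormal sigma on post-washout state
    n_beats_stage: int = 8
    n_beats_occlusion: int = 22
    dt: float = 5e-4
    seed: int = 0
    randomize_order: bool = True

    def __post_init__(self) -> None:
        if self.n_control < 1 or self.n_pab < 1:
            raise ValueError("group sizes must be >= 1")
        if self.pressure_sd < 0 or self.volume_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        if len(self.drugs) != 2:
            raise ValueError("crossover needs exactly two drugs")


@dataclass
class StageData:
    """One measurement point of one subject."""

    label: str
    drug: str           # "" at baselines
    dose: float
    traces: dict        # ventricle -> PVTrace (steady state)
    occlusions: dict    # ventricle -> PVTrace (caval occlusion)
    panel: HemoPanel
    truth: dict         # ground-truth scalars and per-beat logs


@dataclass
class SubjectData:
    subject_id: str
    group: str          # "control" | "PAB"
    weight: float
    bsa: float
    drug_order: tuple
    params: dict        # ventricle -> (VentricleParams, CircuitParams), pre-drug
    stages: list = field(default_factory=list)


@dataclass
class StudyDataset:
    spec: CrossoverStudySpec
    subjects: list

    @property
    def manifest(self) -> dict:
        return {
            "provenance": {"seed": self.spec.seed, "generator": "pvloop.study"},
            "subjects": [
                {
                    "id": s.subject_id,
                    "group": s.group,
                    "weight_kg": round(s.weight, 3),
                    "drug_order": list(s.drug_order),
                    "stages": [
                        {"label": st.label, "drug": st.drug, "dose": st.dose}
                        for st in s.stages
                    ],
                }
                for s in self.subjects
            ],
        }


def _jitter_params(rng: np.random.Generator, sigma: float,
                   vp: VentricleParams, cp: CircuitParams):
    """Multiplicative lognormal jitter on the physiologically variable knobs."""
    if sigma <= 0:
        return vp, cp
    j = lambda: float(rng.lognormal(0.0, sigma))
    period = vp.period * j()
    vp = replace(vp, Emax=vp.Emax * j(), period=period,
                 t_peak=min(vp.t_peak * j(), 0.8 * period),
                 relax_tau=vp.relax_tau * j(),
                 passive_stiffness=vp.passive_stiffness * j())
    cp = replace(cp, R_periph=cp.R_periph * j(), P_venous=cp.P_venous * j(),
                 C_art=cp.C_art * j())
    return vp, cp


def _add_noise(trace: PVTrace, rng: np.random.Generator,
               p_sd: float, v_sd: float) -> PVTrace:
    if p_sd == 0 and v_sd == 0:
        return trace
    return PVTrace(trace.time,
                   trace.pressure + rng.normal(0.0, p_sd, len(trace)),
                   trace.volume + rng.normal(0.0, v_sd, len(trace)),
                   sampling_rate=trace.sampling_rate,
                   ventricle=trace.ventricle, stage_label=trace.stage_label)


def _svo2(co_l_min: float, weight: float, hb_g_dl: float = 9.0,
          sao2: float = 98.0, vo2_ml_kg_min: float = 3.4) -> float:
    """Fick-style mixed venous saturation from CO and an assumed VO2."""
    o2_delivery = 1.34 * hb_g_dl * 10.0 * co_l_min  # ml O2 / min
    extraction = 100.0 * vo2_ml_kg_min * weight / max(o2_delivery, 1e-9)
    return float(np.clip(sao2 - extraction, 15.0, sao2))


def _simulate_point(systems: dict, spec: CrossoverStudySpec,
                    rng: np.random.Generator, label: str, drug: str,
                    dose: float, subject) -> StageData:
    """Simulate both ventricles at one measurement point."""
    traces, occl, truth = {}, {}, {}
    results: dict[str, SimResult] = {}
    for vent in ("RV", "LV"):
        vp, cp = systems[vent]
        if drug:
            vp, cp = apply_drug(vp, cp, drug, dose, pulmonary=(vent == "RV"))
        st = simulate_stage(vp, cp, n_beats=spec.n_beats_stage, dt=spec.dt,
                            ventricle=vent, stage_label=label)
        oc = simulate_occlusion(vp, cp, n_beats=spec.n_beats_occlusion,
                                dt=spec.dt,
                                ramp_rate=OCCLUSION_RAMP_FRAC[vent] * cp.P_venous,
                                ventricle=vent, stage_label=label + "_occl")
        results[vent] = st
        traces[vent] = _add_noise(st.trace, rng, spec.pressure_sd, spec.volume_sd)
        occl[vent] = _add_noise(oc.trace, rng, spec.pressure_sd, spec.volume_sd)
        truth[vent] = {
            "Emax": vp.Emax, "V0": vp.V0, "relax_tau_ms": vp.relax_tau * 1e3,
            "R_periph": cp.R_periph, "P_venous": cp.P_venous,
            "EDV": float(np.mean([b.EDV for b in st.beats])),
            "ESV": float(np.mean([b.ESV for b in st.beats])),
            "ESP": float(np.mean([b.ESP for b in st.beats])),
            "SV": st.stroke_volume,
            "HR": st.heart_rate,
        }

    lv, rv = results["LV"], results["RV"]
    co = lv.cardiac_output * float(rng.lognormal(0.0, 0.02))
    sap = lv.SAP + float(rng.normal(0.0, 1.0))
    dap = lv.DAP + float(rng.normal(0.0, 1.0))
    map_ = np.clip(lv.MAP + float(rng.normal(0.0, 1.0)),
                   min(sap, dap) + 0.1, max(sap, dap) - 0.1)
    cvp = max(rv.cparams.P_venous - 0.5 + float(rng.normal(0.0, 0.3)), 0.5)
    panel = HemoPanel(
        MAP=float(map_), SAP=float(max(sap, dap)), DAP=float(min(sap, dap)),
        CVP=cvp, CO=max(co, 0.1), HR=lv.heart_rate,
        SvO2=_svo2(co, subject.weight), weight=subject.weight,
        BSA=subject.bsa,
        RV_Pmean=float(rv.trace.pressure.mean()),
        LV_Pmin=float(lv.trace.pressure.min()),
        NT_proBNP=subject._nt_probnp, lactate=subject._lactate,
    )
    truth["CO"] = lv.cardiac_output
    truth["MAP"] = lv.MAP
    return StageData(label=label, drug=drug, dose=dose, traces=traces,
                     occlusions=occl, panel=panel, truth=truth)


def generate_study(spec: CrossoverStudySpec | None = None,
                   seed: int | None = None) -> StudyDataset:
    """Emit the full crossover dataset described by ``spec``.

    ``seed`` overrides ``spec.seed``.  Identical spec + seed yields an
    identical dataset (and identical manifest) on every run.
    """
    spec = spec or CrossoverStudySpec()
    if seed is not None:
        spec = replace(spec, seed=int(seed))
    rng = np.random.default_rng(spec.seed)
    subjects = []
    groups = ["control"] * spec.n_control + ["PAB"] * spec.n_pab
    for i, group in enumerate(groups):
        sid = f"{'C' if group == 'control' else 'P'}{i + 1:02d}"
        weight = float(rng.normal(37.7, 2.0 if group == "control" else 4.0))
        weight = max(weight, 20.0)
        rv = _jitter_params(rng, spec.subject_jitter, *RV_CONTROL)
        lv = _jitter_params(rng, spec.subject_jitter, *LV_CONTROL)
        # both ventricles of one animal share the pacing rate
        lv = (replace(lv[0], period=rv[0].period), lv[1])
        if group == "PAB":
            rv, lv = pab_transform(rv, lv, spec.pab_effects)
            nt = float(rng.lognormal(np.log(18.0), 0.45))
            lact = float(rng.normal(1.7, 0.3))
        else:
            nt = float(rng.lognormal(np.log(5.0), 0.8))
            lact = float(rng.normal(1.0, 0.3))
        order = tuple(spec.drugs)
        if spec.randomize_order and rng.random() < 0.5:
            order = order[::-1]
        subj = SubjectData(subject_id=sid, group=group, weight=weight,
                           bsa=bsa_from_weight(weight), drug_order=order,
                           params={"RV": rv, "LV": lv})
        subj._nt_probnp = nt
        subj._lactate = max(lact, 0.2)
        subjects.append(subj)

        systems = {"RV": rv, "LV": lv}
        subj.stages.append(_simulate_point(systems, spec, rng, "baseline1",
                                           "", 0.0, subj))
        drug_a, drug_b = subj.drug_order
        for dose in DRUG_MODELS[drug_a].dose_grid:
            subj.stages.append(_simulate_point(
                systems, spec, rng, f"{drug_a}_{dose:g}", drug_a, dose, subj))
        # washout: return to baseline physiology with a small seeded drift
        if spec.washout_drift_sd > 0:
            drift = lambda: float(rng.lognormal(0.0, spec.washout_drift_sd))
            systems = {
                v: (replace(vp, Emax=vp.Emax * drift()),
                    replace(cp, P_venous=cp.P_venous * drift()))
                for v, (vp, cp) in systems.items()
            }
        subj.stages.append(_simulate_point(systems, spec, rng, "baseline2",
                                           "", 0.0, subj))
        for dose in DRUG_MODELS[drug_b].dose_grid:
            subj.stages.append(_simulate_point(
                systems, spec, rng, f"{drug_b}_{dose:g}", drug_b, dose, subj))
    return StudyDataset(spec=spec, subjects=subjects)


def write_study(dataset: StudyDataset, out_dir) -> Path:
    """Write trace CSVs, ``manifest.json`` and ``truth.json`` under a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = dataset.manifest
    truth_log = {}
    for subj in dataset.subjects:
        sdir = out / subj.subject_id
        sdir.mkdir(exist_ok=True)
        for entry, st in zip(
                manifest["subjects"][dataset.subjects.index(subj)]["stages"],
                subj.stages):
            files = {}
            for vent in ("RV", "LV"):
                f_tr = f"{st.label}_{vent}.csv"
                f_oc = f"{st.label}_{vent}_occl.csv"
                write_trace(st.traces[vent], sdir / f_tr,
                            header_comment=f"seed={dataset.spec.seed}")
                write_trace(st.occlusions[vent], sdir / f_oc,
                            header_comment=f"seed={dataset.spec.seed}")
                files[vent] = {"trace": f"{subj.subject_id}/{f_tr}",
                               "occlusion": f"{subj.subject_id}/{f_oc}"}
            entry["files"] = files
            entry["panel"] = {k: round(float(v), 6)
                              for k, v in asdict(st.panel).items()}
            truth_log[f"{subj.subject_id}/{st.label}"] = {
                k: (v if isinstance(v, dict) else float(v))
                for k, v in st.truth.items()}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    (out / "truth.json").write_text(json.dumps(truth_log, indent=1))
    return out


def load_study(in_dir) -> StudyDataset:
    """Load a written study back from ``manifest.json`` + trace CSVs.

    Ground-truth parameters are not part of the manifest; loaded stages
    carry the truth log from ``truth.json`` when present, else empty dicts.
    """
    from .trace import read_trace

    root = Path(in_dir)
    manifest = json.loads((root / "manifest.json").read_text())
    truth_path = root / "truth.json"
    truth_log = json.loads(truth_path.read_text()) if truth_path.exists() else {}
    seed = int(manifest.get("provenance", {}).get("seed", 0))
    subjects = []
    seen_ids = set()
    for sm in manifest["subjects"]:
        if sm["id"] in seen_ids:
            raise ValueError(f"duplicate subject id {sm['id']!r} in manifest")
        seen_ids.add(sm["id"])
        if sorted(sm["drug_order"]) != sorted(set(sm["drug_order"])) or \
                len(sm["drug_order"]) != 2:
            raise ValueError(
                f"subject {sm['id']}: drug_order must be a permutation of "
                f"two distinct drugs, got {sm['drug_order']}")
        subj = SubjectData(subject_id=sm["id"], group=sm["group"],
                           weight=sm["weight_kg"],
                           bsa=bsa_from_weight(sm["weight_kg"]),
                           drug_order=tuple(sm["drug_order"]), params={})
        panel0 = None
        for st in sm["stages"]:
            traces, occl = {}, {}
            for vent, files in st["files"].items():
                for key, store in (("trace", traces), ("occlusion", occl)):
                    path = root / files[key]
                    if not path.exists():
                        raise FileNotFoundError(f"manifest references missing file {path}")
                    store[vent] = read_trace(path, ventricle=vent,
                                             stage_label=st["label"])
            panel = HemoPanel(**st["panel"])
            subj.stages.append(StageData(
                label=st["label"], drug=st["drug"], dose=st["dose"],
                traces=traces, occlusions=occl, panel=panel,
                truth=truth_log.get(f"{sm['id']}/{st['label']}", {})))
        subjects.append(subj)
    spec = CrossoverStudySpec(
        n_control=sum(1 for s in subjects if s.group == "control"),
        n_pab=sum(1 for s in subjects if s.group == "PAB"), seed=seed)
    return StudyDataset(spec=spec, subjects=subjects)
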