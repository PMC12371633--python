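"""Synthetic cohorts with the statistical structure the analysis assumes.

Each patient owns a latent CMC parameterization composed of a shared
seizure (ictal) operating point, effect-coded group-level shifts on
inhibitory coupling, and an idiosyncratic between-patient deviation drawn
once per patient::

    theta(patient, condition) = base + resp * beta_resp
                              + post * (beta_bzp + is_resp * beta_interaction)
                              + delta_patient

with resp = +1 for responders / -1 for nonresponders, post = 1 after (0
before) medication and is_resp = 1 for responders only: before treatment no
drug is on board, and the interaction is the extra drug effect expressed
only in responders.  The packaged default effects (baseline gamma_ii-ss
difference, shared BZP-driven gamma_ii-ss increase, interaction-driven
extra increase plus a slight gamma_ii-dp decrease) are synthetic
conventions chosen for identifiability at 300-s spectra — only their signs
are constrained by the group-level physiology being emulated.
:meth:`GroundTruth.effect_coded_beta` converts them to the +/-1
effect-coded basis the second-level design uses.

Outputs are either noisy power spectra (multiplicative log-normal
observation noise) or 22-minute recordings with medication events, plus a
ground-truth record sufficient to reconstruct every latent parameter.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .cmc import build_jacobian, predict_spectrum, simulate_timeseries
from .parameters import CMCParameters, default_parameters
from .spectra import Recording, SpectralData, default_grid

__all__ = ["CohortConfig", "Patient", "CohortDataset", "GroundTruth",
           "generate_cohort", "cohort_manifest", "save_cohort", "load_cohort"]

#: ictal operating point: faster inhibitory/deep kernels and strong deep
#: pyramidal inhibition place the column within reach of a ~25-Hz
#: oscillatory instability (the seizure-termination boundary sits about
#: 0.7 log-units below in gamma_ii-ss)
DEFAULT_BASE_STATE = {"tau_ii": -0.6, "tau_dp": -0.6, "g_ii_dp": 1.2, "g_ii_ss": 0.25}

#: group-level effects in log-units: resp = half the responder-nonresponder
#: baseline difference; bzp = shared pre-to-post change; resp_x_bzp =
#: additional pre-to-post change expressed in responders only
DEFAULT_EFFECTS = {
    "resp": {"g_ii_ss": -0.5, "g_ii_sp": -0.4},
    "bzp": {"g_ii_ss": 0.2, "g_ii_sp": 0.2},
    "resp_x_bzp": {"g_ii_ss": 1.0, "g_ii_sp": 0.7, "g_ii_dp": -0.2},
}


@dataclass(frozen=True)
class CohortConfig:
    n_responders: int = 8
    n_nonresponders: int = 9
    effects: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_EFFECTS.items()}
    )
    base_state: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_BASE_STATE))
    between_patient_sd: float = 0.05
    output: str = "spectra"          # spectra | timeseries
    noise_sd: float = 0.1            # log-units (spectra) ; channel noise is built in for timeseries
    duration_s: float = 300.0        # epoch length for spectra mode
    fs: float = 256.0
    seed: int = 0
    max_retries: int = 20            # redraw unstable patient deviations

    def __post_init__(self):
        if self.n_responders < 1 or self.n_nonresponders < 1:
            raise ValueError("cohort needs at least one patient per group")
        if self.between_patient_sd < 0 or self.noise_sd < 0:
            raise ValueError("standard deviations must be nonnegative")
        if self.output not in ("spectra", "timeseries"):
            raise ValueError("output must be 'spectra' or 'timeseries'")


@dataclass(frozen=True)
class Patient:
    patient_id: str
    group: str
    params_pre: CMCParameters
    params_post: CMCParameters
    spectra: Mapping[str, SpectralData] | None = None
    recording: Recording | None = None


@dataclass(frozen=True)
class CohortDataset:
    patients: tuple
    freqs: np.ndarray
    config: CohortConfig

    def patient(self, patient_id: str) -> Patient:
        return next(p for p in self.patients if p.patient_id == patient_id)


@dataclass(frozen=True)
class GroundTruth:
    """Latent generative record: per-patient parameters, true effects, seed."""

    true_beta: dict                  # regressor -> parameter -> log-units
    patient_deviations: dict         # patient_id -> parameter -> log-units
    base_state: dict
    seed: int
    retries: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    def effect_coded_beta(self) -> dict:
        """True second-level effects in the +/-1 effect-coded design basis.

        With resp and bzp coded +/-1, the generator's cell-style effects
        (baseline half-difference r, shared change s, responder-only extra
        change x) map to b_resp = r + x/4, b_bzp = s/2 + x/4 and
        b_interaction = x/4 (plus an intercept term absorbed elsewhere).
        """
        params = sorted(
            {p for effs in self.true_beta.values() for p in effs}
        )
        out = {"resp": {}, "bzp": {}, "resp_x_bzp": {}}
        for par in params:
            r = self.true_beta.get("resp", {}).get(par, 0.0)
            s = self.true_beta.get("bzp", {}).get(par, 0.0)
            x = self.true_beta.get("resp_x_bzp", {}).get(par, 0.0)
            out["resp"][par] = r + x / 4.0
            out["bzp"][par] = s / 2.0 + x / 4.0
            out["resp_x_bzp"][par] = x / 4.0
        return out


def _compose(template: CMCParameters, cfg: CohortConfig, resp: float, post: float,
             deviation: Mapping[str, float]) -> CMCParameters:
    changes: dict[str, float] = dict(cfg.base_state)
    is_resp = 1.0 if resp > 0 else 0.0
    weights = {"resp": resp, "bzp": post, "resp_x_bzp": post * is_resp}
    for reg, effs in cfg.effects.items():
        w = weights.get(reg)
        if w is None:
            raise ValueError(f"unknown effect regressor {reg!r}; expected {sorted(weights)}")
        for par, val in effs.items():
            changes[par] = changes.get(par, 0.0) + w * float(val)
    for par, val in deviation.items():
        changes[par] = changes.get(par, 0.0) + float(val)
    return template.update(changes)


def generate_cohort(config: CohortConfig | None = None) -> tuple[CohortDataset, GroundTruth]:
    """Draw a fully seeded cohort; returns the dataset and its ground truth.

    Patient deviations that put either condition beyond the stability
    boundary are redrawn (bounded retries, recorded in the ground truth).
    """
    cfg = config or CohortConfig()
    template = default_parameters()
    for par in cfg.base_state:
        template.update({par: 0.0})  # raises on unknown names
    for effs in cfg.effects.values():
        template.update({par: 0.0 for par in effs})
    rng = np.random.default_rng(cfg.seed)
    freqs = default_grid()
    var_names = template.variable_names
    patients = []
    deviations: dict[str, dict] = {}
    retries: dict[str, int] = {}
    labels = [("r", "responder", i) for i in range(cfg.n_responders)] + [
        ("n", "nonresponder", i) for i in range(cfg.n_nonresponders)
    ]
    for prefix, group, i in labels:
        pid = f"{prefix}{i + 1:02d}"
        resp = 1.0 if group == "responder" else -1.0
        for attempt in range(cfg.max_retries + 1):
            dev = {n: rng.normal(0.0, cfg.between_patient_sd) for n in var_names}
            p_pre = _compose(template, cfg, resp, 0.0, dev)
            p_post = _compose(template, cfg, resp, 1.0, dev)
            if build_jacobian(p_pre).stable and build_jacobian(p_post).stable:
                break
        else:
            raise RuntimeError(f"could not draw a stable parameterization for {pid}")
        deviations[pid] = {k: float(v) for k, v in dev.items()}
        if attempt:
            retries[pid] = attempt
        spectra = recording = None
        if cfg.output == "spectra":
            spectra = {}
            for cond, prm in (("pre", p_pre), ("post", p_post)):
                clean = predict_spectrum(prm, freqs)
                noisy = clean.values * np.exp(rng.normal(0.0, cfg.noise_sd, freqs.size))
                spectra[cond] = SpectralData(
                    freqs, noisy, {"patient_id": pid, "group": group, "condition": cond}
                )
        else:
            recording = _synthesize_recording(p_pre, p_post, group, cfg, rng)
            recording = Recording(
                recording.signal, recording.fs, recording.events,
                {"patient_id": pid, "group": group},
            )
        patients.append(Patient(pid, group, p_pre, p_post, spectra, recording))
    dataset = CohortDataset(tuple(patients), freqs, cfg)
    truth = GroundTruth(
        true_beta={k: dict(v) for k, v in cfg.effects.items()},
        patient_deviations=deviations,
        base_state=dict(cfg.base_state),
        seed=cfg.seed,
        retries=retries,
    )
    return dataset, truth


#: event layout for synthesized recordings (seconds)
ADMIN_TIME = 600.0
TERMINATION_TIME = 800.0
RECORDING_DURATION = 1320.0


def _synthesize_recording(p_pre, p_post, group, cfg: CohortConfig, rng) -> Recording:
    switch = TERMINATION_TIME if group == "responder" else ADMIN_TIME
    seed_pre, seed_post = rng.integers(0, 2**31, size=2)
    pre = simulate_timeseries(p_pre, switch, cfg.fs, seed=int(seed_pre))
    post = simulate_timeseries(p_post, RECORDING_DURATION - switch, cfg.fs, seed=int(seed_post))
    sig = np.concatenate([pre.signal, post.signal])
    events = [(ADMIN_TIME, "bzp_admin")]
    if group == "responder":
        events.append((TERMINATION_TIME, "se_termination"))
    return Recording(sig, cfg.fs, tuple(events), {})


def cohort_manifest(dataset: CohortDataset) -> pd.DataFrame:
    """Manifest consumable by the inversion batch driver and the PEB design.

    One row per patient x condition, sorted to a canonical order.  ``path``
    names the serialized per-condition spectrum relative to the manifest's
    own directory (as written by :func:`save_cohort`), keeping the manifest
    reproducible byte-for-byte across output locations.
    """
    rows = []
    for p in dataset.patients:
        for cond in ("pre", "post"):
            rows.append(
                {"patient_id": p.patient_id, "group": p.group, "condition": cond,
                 "other_asm": False, "path": f"{p.patient_id}_{cond}.csv"}
            )
    df = pd.DataFrame(rows)
    return df.sort_values(
        ["patient_id", "condition"], ascending=[True, False], ignore_index=True
    )


def save_cohort(dataset: CohortDataset, truth: GroundTruth, out_dir: str | Path) -> Path:
    """Write spectra/recordings as CSV, the manifest, and the ground truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for p in dataset.patients:
        if p.spectra is not None:
            for cond, spec in p.spectra.items():
                spec.to_csv(out / f"{p.patient_id}_{cond}.csv")
        if p.recording is not None:
            p.recording.to_csv(out / f"{p.patient_id}_recording.csv")
    manifest = cohort_manifest(dataset)
    manifest.to_csv(out / "manifest.csv", index=False)
    (out / "ground_truth.json").write_text(truth.to_json())
    return out


def load_cohort(manifest_path: str | Path) -> pd.DataFrame:
    """Read a manifest, resolving spectra paths against its own directory."""
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    required = {"patient_id", "group", "condition", "path"}
    if not required <= set(df.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    df["path"] = [str(manifest_path.parent / p) for p in df["path"]]
    return df
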