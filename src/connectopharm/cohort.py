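"""Synthetic multi-subject, multi-session BOLD cohort with known ground truth.

The generator emulates a placebo-controlled pharmaco-fMRI crossover study:
a control group scanned once and a patient group scanned in three sessions
(placebo, a noradrenergic drug, a serotonergic drug) with drug order
counter-balanced in blocks of six.  Node signals follow a modular factor
model: each module has a latent AR(1) time course band-limited to the
resting-state range, non-hub nodes load on their home module only, and hub
nodes additionally load on every other module.  Disease and drug effects act
multiplicatively on these loadings, so induced correlation changes stay in
[-1, 1] by construction, and the factors actually applied are recorded per
subject-session for parameter-recovery tests.

Session-level effects:

* noradrenergic drug - hub cross-module loading scaled by
  ``1 + drug_effect_atomoxetine * z`` with ``z`` the standardized plasma
  concentration (stronger hub coupling at higher drug levels);
* serotonergic drug - within-module loading scaled by
  ``1 - drug_effect_citalopram * (UPDRS - updrs_pivot)`` (segregation rises
  in mild disease, falls beyond the pivot severity);
* disease - hub loadings of patients scaled by ``1 - disease_effect``.

Cognitive outcomes (category fluency, stop-signal reaction time) are linear
functions of the injected hub-coupling change plus noise, so brain-behaviour
regressions downstream have recoverable ground truth.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field, fields as dc_fields

import numpy as np

from .connectivity import TimeSeriesMatrix
from .motion import MotionTrace

__all__ = [
    "CohortSpec",
    "SubjectRecord",
    "GroundTruth",
    "generate_cohort",
    "simulate_timeseries",
    "simulate_motion",
]

SESSIONS = ("placebo", "atomoxetine", "citalopram")
_SESSION_CODE = {"none": 0, "placebo": 1, "atomoxetine": 2, "citalopram": 3}


@dataclass
class CohortSpec:
    """Parameters of the simulated study.

    Defaults reproduce the emulated study design: 75 controls scanned once,
    30 patients in three counter-balanced sessions, 473 usable nodes,
    145 volumes at TR 2 s.  Covariate distributions follow the emulated design's
    baseline characteristics table (UPDRS-III 22.6 (6.8); levodopa
    equivalent dose 870 (469) mg/day; plasma 372.1 (167.4) ng/ml for the
    noradrenergic drug and 35.6 (14.7) ng/ml for the serotonergic drug).
    """

    n_controls: int = 75
    n_patients: int = 30
    n_nodes: int = 473
    n_volumes: int = 145
    tr_seconds: float = 2.0
    n_modules: int = 20
    hub_fraction: float = 0.05
    within_module_loading: float = 1.0
    hub_cross_loading: float = 0.35
    noise_sd: float = 1.0
    ar_coefficient: float = 0.6
    drug_effect_atomoxetine: float = 0.5
    drug_effect_citalopram: float = 0.02
    updrs_pivot: float = 30.0
    disease_effect: float = 0.2
    updrs_mean: float = 22.6
    updrs_sd: float = 6.8
    led_mean: float = 870.0
    led_sd: float = 469.0
    atomoxetine_plasma_mean: float = 372.1
    atomoxetine_plasma_sd: float = 167.4
    citalopram_plasma_mean: float = 35.6
    citalopram_plasma_sd: float = 14.7
    age_mean_patients: float = 67.0
    age_sd_patients: float = 7.3
    age_mean_controls: float = 67.1
    age_sd_controls: float = 8.4
    fluency_mean_patients: float = 18.3
    fluency_sd_patients: float = 5.5
    fluency_mean_controls: float = 24.3
    fluency_sd_controls: float = 6.2
    ssrt_mean_patients: float = 198.0
    ssrt_sd_patients: float = 73.0
    ssrt_mean_controls: float = 164.0
    ssrt_sd_controls: float = 39.0
    fluency_effect_gain: float = 8.0
    ssrt_effect_gain: float = 60.0
    fluency_session_noise_sd: float = 2.0
    ssrt_session_noise_sd: float = 20.0
    motion_spike_prob: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_controls", "n_patients", "n_nodes", "n_modules"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.n_volumes <= 5:
            raise ValueError(f"n_volumes must be > 5, got {self.n_volumes}")
        if self.tr_seconds <= 0:
            raise ValueError(f"tr_seconds must be > 0, got {self.tr_seconds}")
        if not 0 < self.hub_fraction < 0.5:
            raise ValueError(f"hub_fraction must be in (0, 0.5), got {self.hub_fraction}")
        for name in ("within_module_loading", "hub_cross_loading"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.noise_sd <= 0:
            raise ValueError(f"noise_sd must be > 0, got {self.noise_sd}")
        if not 0 <= self.ar_coefficient < 1:
            raise ValueError(f"ar_coefficient must be in [0, 1), got {self.ar_coefficient}")
        if not 0 <= self.motion_spike_prob <= 1:
            raise ValueError(
                f"motion_spike_prob must be in [0, 1], got {self.motion_spike_prob}"
            )
        if self.n_modules > self.n_nodes:
            raise ValueError("n_modules cannot exceed n_nodes")
        if round(self.hub_fraction * self.n_nodes) < 1:
            raise ValueError("hub_fraction * n_nodes rounds to zero hubs")

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}


@dataclass
class SubjectRecord:
    """One scan session of one participant."""

    subject_id: str
    group: str  # control | patient
    session: str  # none | placebo | atomoxetine | citalopram
    updrs_iii: float
    led_mg_day: float
    plasma_ng_ml: float
    category_fluency: float
    ssrt_ms: float
    age_years: float

    def __post_init__(self) -> None:
        if self.group not in ("control", "patient"):
            raise ValueError(f"group must be control|patient, got {self.group!r}")
        if self.session not in _SESSION_CODE:
            raise ValueError(f"unknown session {self.session!r}")


@dataclass
class GroundTruth:
    """What the generator actually planted, for parameter-recovery tests."""

    module_assignment: np.ndarray  # node -> module index
    hub_nodes: np.ndarray  # sorted hub node indices
    injected: dict = field(default_factory=dict)
    # injected[(subject_id, session)] = {"lambda_factor", "eta_factor",
    #                                    "disease_factor"}

    def __post_init__(self) -> None:
        self.module_assignment = np.asarray(self.module_assignment, dtype=int)
        self.hub_nodes = np.asarray(sorted(set(np.asarray(self.hub_nodes, dtype=int).tolist())))
        n = self.module_assignment.size
        if self.hub_nodes.size and (self.hub_nodes.min() < 0 or self.hub_nodes.max() >= n):
            raise ValueError("hub node index outside the node set")

    def is_hub(self) -> np.ndarray:
        mask = np.zeros(self.module_assignment.size, dtype=bool)
        mask[self.hub_nodes] = True
        return mask


# ---------------------------------------------------------------------------


def _subject_index(subject_id: str) -> int:
    m = re.search(r"(\d+)$", subject_id)
    if m is None:
        raise ValueError(f"subject id {subject_id!r} must end in digits")
    base = int(m.group(1))
    return base + (100_000 if subject_id.startswith("control") else 0)


def _record_rng(spec: CohortSpec, subject_id: str, session: str, stream: int = 0):
    """Deterministic per-(subject, session, stream) generator."""
    ss = np.random.SeedSequence(
        entropy=spec.seed,
        spawn_key=(_subject_index(subject_id), _SESSION_CODE[session], stream),
    )
    return np.random.default_rng(ss)


def session_factors(subject: SubjectRecord, spec: CohortSpec) -> dict:
    """Multiplicative loading factors implied by a subject-session.

    Returns ``lambda_factor`` (within-module loading, all nodes),
    ``eta_factor`` (hub cross-module loading) and ``disease_factor``
    (applied to hub loadings of patients).
    """
    lam_f, eta_f = 1.0, 1.0
    if subject.session == "atomoxetine":
        z = (subject.plasma_ng_ml - spec.atomoxetine_plasma_mean) / spec.atomoxetine_plasma_sd
        eta_f = max(0.0, 1.0 + spec.drug_effect_atomoxetine * z)
    elif subject.session == "citalopram":
        lam_f = max(
            0.0, 1.0 - spec.drug_effect_citalopram * (subject.updrs_iii - spec.updrs_pivot)
        )
    disease_f = 1.0 - spec.disease_effect if subject.group == "patient" else 1.0
    return {"lambda_factor": lam_f, "eta_factor": eta_f, "disease_factor": disease_f}


def generate_cohort(spec: CohortSpec) -> tuple[list[SubjectRecord], GroundTruth]:
    """Draw the cohort: subject records plus planted ground truth.

    Controls have exactly one record (session ``none``); each patient has one
    record per session, sharing subject-level covariates, with drug order
    counter-balanced as the six permutations of the three sessions within
    blocks of six successive patients.
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=spec.seed, spawn_key=(0,)))

    n_hubs = int(round(spec.hub_fraction * spec.n_nodes))
    module_assignment = np.arange(spec.n_nodes) % spec.n_modules
    hub_nodes = np.arange(n_hubs)  # node i belongs to module i % M: round-robin hubs
    truth = GroundTruth(module_assignment=module_assignment, hub_nodes=hub_nodes)

    records: list[SubjectRecord] = []

    for i in range(spec.n_controls):
        rec = SubjectRecord(
            subject_id=f"control{i:03d}",
            group="control",
            session="none",
            updrs_iii=np.nan,
            led_mg_day=np.nan,
            plasma_ng_ml=0.0,
            category_fluency=rng.normal(spec.fluency_mean_controls, spec.fluency_sd_controls),
            ssrt_ms=rng.normal(spec.ssrt_mean_controls, spec.ssrt_sd_controls),
            age_years=rng.normal(spec.age_mean_controls, spec.age_sd_controls),
        )
        records.append(rec)
        truth.injected[(rec.subject_id, "none")] = session_factors(rec, spec)

    all_orders = list(itertools.permutations(SESSIONS))  # 6 session orders
    for i in range(spec.n_patients):
        if i % 6 == 0:
            block = rng.permutation(6)
        order = all_orders[block[i % 6]]

        age = rng.normal(spec.age_mean_patients, spec.age_sd_patients)
        updrs = max(5.0, rng.normal(spec.updrs_mean, spec.updrs_sd))
        led = max(0.0, rng.normal(spec.led_mean, spec.led_sd))
        fluency0 = rng.normal(spec.fluency_mean_patients, spec.fluency_sd_patients)
        ssrt0 = rng.normal(spec.ssrt_mean_patients, spec.ssrt_sd_patients)
        plasma = {
            "placebo": 0.0,
            "atomoxetine": max(
                10.0, rng.normal(spec.atomoxetine_plasma_mean, spec.atomoxetine_plasma_sd)
            ),
            "citalopram": max(
                2.0, rng.normal(spec.citalopram_plasma_mean, spec.citalopram_plasma_sd)
            ),
        }

        sid = f"patient{i:03d}"
        for session in order:
            rec = SubjectRecord(
                subject_id=sid,
                group="patient",
                session=session,
                updrs_iii=updrs,
                led_mg_day=led,
                plasma_ng_ml=plasma[session],
                category_fluency=fluency0,
                ssrt_ms=ssrt0,
                age_years=age,
            )
            fac = session_factors(rec, spec)
            # cognitive outcome rides on the injected hub-coupling change
            eta_excess = fac["eta_factor"] - 1.0
            rec.category_fluency = (
                fluency0
                + spec.fluency_effect_gain * eta_excess
                + rng.normal(0.0, spec.fluency_session_noise_sd)
            )
            rec.ssrt_ms = (
                ssrt0
                - spec.ssrt_effect_gain * eta_excess
                + rng.normal(0.0, spec.ssrt_session_noise_sd)
            )
            records.append(rec)
            truth.injected[(sid, session)] = fac

    return records, truth


def _module_latents(rng, spec: CohortSpec) -> np.ndarray:
    """AR(1) latent time course per module, unit stationary variance."""
    phi = spec.ar_coefficient
    innov_sd = np.sqrt(1.0 - phi**2)
    g = np.empty((spec.n_modules, spec.n_volumes))
    g[:, 0] = rng.standard_normal(spec.n_modules)
    eps = rng.standard_normal((spec.n_modules, spec.n_volumes - 1)) * innov_sd
    for t in range(1, spec.n_volumes):
        g[:, t] = phi * g[:, t - 1] + eps[:, t - 1]
    return g


def simulate_timeseries(
    subject: SubjectRecord, truth: GroundTruth, spec: CohortSpec
) -> TimeSeriesMatrix:
    """Node x time BOLD-like signals for one subject-session.

    Node ``i`` is ``lam_i * g_{m(i)}(t) + [hub] sum_{k != m(i)} eta * g_k(t)
    + noise``; the loading factors come from :func:`session_factors` and are
    identical to those recorded in ``GroundTruth.injected``.  Deterministic
    given (subject, truth, spec).
    """
    if truth.module_assignment.size != spec.n_nodes:
        raise ValueError("ground truth node count does not match spec.n_nodes")
    rng = _record_rng(spec, subject.subject_id, subject.session, stream=1)
    fac = session_factors(subject, spec)

    g = _module_latents(rng, spec)
    hub_mask = truth.is_hub()

    lam = np.full(spec.n_nodes, spec.within_module_loading) * fac["lambda_factor"]
    lam[hub_mask] *= fac["disease_factor"]
    eta = spec.hub_cross_loading * fac["eta_factor"] * fac["disease_factor"]

    x = lam[:, None] * g[truth.module_assignment]
    if hub_mask.any() and eta > 0:
        g_total = g.sum(axis=0)
        x[hub_mask] += eta * (g_total[None, :] - g[truth.module_assignment[hub_mask]])
    x += rng.standard_normal(x.shape) * spec.noise_sd
    return TimeSeriesMatrix(x, spec.tr_seconds)


def simulate_motion(
    subject: SubjectRecord,
    spec: CohortSpec,
    outlier: bool = False,
    outlier_scale: float = 6.0,
) -> MotionTrace:
    """Rigid-body motion trace for one subject-session.

    Translations are zero except for occasional single-volume spikes
    (``motion_spike_prob`` per volume), so a spike-free, non-outlier trace
    has exactly zero RMS displacement.  With ``outlier=True`` the spikes are
    inflated by ``outlier_scale`` and a translational random walk is added,
    emulating a high-motion participant that the QC stage should flag.
    Rotations follow a small random walk throughout (they do not enter the
    RMS displacement statistic).
    """
    rng = _record_rng(spec, subject.subject_id, subject.session, stream=2)
    n = spec.n_volumes

    translations = np.zeros((n, 3))
    spikes = rng.random(n) < spec.motion_spike_prob
    spikes[0] = False
    scale = outlier_scale if outlier else 1.0
    translations[spikes] += rng.normal(0.0, 0.3 * scale, size=(int(spikes.sum()), 3))
    if outlier:
        steps = rng.normal(0.0, 0.04 * outlier_scale, size=(n, 3))
        steps[0] = 0.0
        translations += np.cumsum(steps, axis=0)

    rot_steps = rng.normal(0.0, 3e-4, size=(n, 3))
    rot_steps[0] = 0.0
    rotations = np.cumsum(rot_steps, axis=0)
    return MotionTrace(translations, rotations)
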