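"""Seedable synthetic EHR cohorts for end-to-end pipeline testing.

The generator emulates a regional audit cohort: a set of general
practices observed over several extraction waves, each practice holding
record-level data (encounters, diagnoses, observations, prescriptions)
for its patient panel.  Between-practice heterogeneity is modelled by
drawing each practice's per-indicator fulfilment probability from a
Beta distribution — optionally quantile-matched to published (Q1,
median, Q3) dispersion triples — and within-practice variation by
independent patient-level Bernoulli events.  Wave effects shift the
practice probabilities on the log-odds scale, preserving the paired
structure the longitudinal analysis relies on.

A ground-truth sidecar records every practice's true probabilities so
parameter-recovery tests can compare computed achievement against the
generating process.  All randomness flows from the single spec seed.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy import optimize, stats
from scipy.special import expit, logit

from .engine import (
    ALL_KINDS,
    HBA1C_TARGET,
    HBA1C_WINDOW_MONTHS,
    ELIGIBILITY_WINDOW_MONTHS,
    PREVALENCE_ONLY,
    Observation,
    PatientRecord,
    PracticeExtract,
    Prescription,
    months_before,
)
from .registry import Disease, IndicatorKind, IndicatorRegistry, load_registry

__all__ = [
    "BetaFit",
    "fit_beta_to_quantiles",
    "WaveSpec",
    "PatientCountSpec",
    "FulfilmentSpec",
    "CohortSpec",
    "PracticeProfile",
    "SyntheticCohort",
    "default_cohort_spec",
    "draw_profiles",
    "generate_practice",
    "generate_cohort",
]

_P_CLIP = 1e-4  # keep practice probabilities away from 0/1 for the logit
_INACTIVE_FRACTION = 0.05  # extra lapsed patients outside the visit window


# --------------------------------------------------------------------------
# Beta quantile matching
# --------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class BetaFit:
    """A fitted Beta distribution with its achieved quantiles (percent)."""

    alpha: float
    beta: float
    achieved_q1: float
    achieved_median: float
    achieved_q3: float
    target_q1: float
    target_median: float
    target_q3: float

    @property
    def max_quantile_error(self) -> float:
        return max(
            abs(self.achieved_q1 - self.target_q1),
            abs(self.achieved_median - self.target_median),
            abs(self.achieved_q3 - self.target_q3),
        )


def fit_beta_to_quantiles(q1: float, median: float, q3: float) -> BetaFit:
    """Quantile-match a Beta distribution to (Q1, median, Q3) percentages.

    Minimises the summed squared error of the Beta's 25/50/75 %
    quantiles against the targets (on the probability scale) over
    (log α, log β).  Degenerate triples (all equal) are rejected: they
    describe a point mass, not a dispersion.
    """
    if not 0.0 <= q1 <= median <= q3 <= 100.0:
        raise ValueError(
            f"quantile triple must satisfy 0 <= q1 <= median <= q3 <= 100, "
            f"got ({q1}, {median}, {q3})"
        )
    if q1 == q3:
        raise ValueError(
            "degenerate quantile triple (no dispersion); specify the "
            "fulfilment as a point mass instead"
        )
    targets = np.array([q1, median, q3]) / 100.0

    def objective(log_ab: np.ndarray) -> float:
        a, b = np.exp(np.clip(log_ab, -12.0, 12.0))
        q = stats.beta.ppf([0.25, 0.5, 0.75], a, b)
        return float(np.sum((q - targets) ** 2))

    # moment-based start (mean ~ median, spread from the IQR) plus fixed
    # fallbacks; extreme triples (median at 0 or 100) leave the moment
    # start in a flat region of the objective
    m = min(max(median / 100.0, 0.02), 0.98)
    sd = max((q3 - q1) / 134.9, 0.01)  # IQR of a normal = 1.349 sd
    nu = max(m * (1 - m) / sd**2 - 1.0, 0.1)
    starts = [
        np.log([max(m * nu, 1e-3), max((1 - m) * nu, 1e-3)]),
        np.log([1.0, 1.0]),
        np.log([0.5, 2.0]),
        np.log([2.0, 0.5]),
        np.log([5.0, 5.0]),
    ]
    best = None
    for x0 in starts:
        res = optimize.minimize(
            objective, x0, method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-12, "maxiter": 2000},
        )
        if best is None or res.fun < best.fun:
            best = res
    a, b = np.exp(np.clip(best.x, -12.0, 12.0))
    aq1, amed, aq3 = 100.0 * stats.beta.ppf([0.25, 0.5, 0.75], a, b)
    return BetaFit(
        alpha=float(a),
        beta=float(b),
        achieved_q1=float(aq1),
        achieved_median=float(amed),
        achieved_q3=float(aq3),
        target_q1=q1,
        target_median=median,
        target_q3=q3,
    )


# --------------------------------------------------------------------------
# cohort specification
# --------------------------------------------------------------------------

class WaveSpec(BaseModel):
    model_config = ConfigDict(frozen=True)
    label: str
    reference_date: dt.date


class PatientCountSpec(BaseModel):
    """Lognormal panel size: ``mean`` patients with multiplicative spread."""

    model_config = ConfigDict(frozen=True)
    mean: float = Field(gt=0)
    dispersion: float = Field(ge=0, default=0.25)


class FulfilmentSpec(BaseModel):
    """Per-indicator fulfilment distribution across practices.

    Either Beta parameters directly (``alpha``/``beta``), a
    (``q1``/``median``/``q3``) percent triple to be quantile-matched,
    or a point mass ``prob`` on [0, 1] (no between-practice spread).
    """

    model_config = ConfigDict(frozen=True)
    alpha: Optional[float] = Field(default=None, gt=0)
    beta: Optional[float] = Field(default=None, gt=0)
    q1: Optional[float] = None
    median: Optional[float] = None
    q3: Optional[float] = None
    prob: Optional[float] = Field(default=None, ge=0, le=1)

    @model_validator(mode="after")
    def _one_parameterisation(self) -> "FulfilmentSpec":
        has_ab = self.alpha is not None and self.beta is not None
        has_q = all(v is not None for v in (self.q1, self.median, self.q3))
        if not (has_ab or has_q or self.prob is not None):
            raise ValueError(
                "fulfilment needs alpha+beta, a q1/median/q3 triple, or prob"
            )
        return self

    def draw(self, rng: np.random.Generator) -> float:
        """One practice-level fulfilment probability."""
        if self.prob is not None:
            return float(self.prob)
        if self.alpha is not None and self.beta is not None:
            a, b = self.alpha, self.beta
        else:
            fit = fit_beta_to_quantiles(self.q1, self.median, self.q3)
            a, b = fit.alpha, fit.beta
        return float(rng.beta(a, b))


class CohortSpec(BaseModel):
    """Everything needed to generate a multi-wave synthetic cohort."""

    model_config = ConfigDict(frozen=True)

    n_gps: int = Field(ge=2)
    waves: tuple[WaveSpec, ...]
    patients_per_practice: PatientCountSpec
    prevalence_pct: dict[str, float]
    fulfilment: dict[str, FulfilmentSpec]
    wave_effects: dict[str, tuple[float, ...]] = {}
    visit_coverage: float = Field(gt=0, le=1, default=1.0)
    prevalence_only_fraction: float = Field(ge=0, le=1, default=0.0)
    region: str = "synthetic"
    seed: int = 0

    @model_validator(mode="after")
    def _validate(self) -> "CohortSpec":
        if len(self.waves) < 1:
            raise ValueError("at least one wave required")
        labels = [w.label for w in self.waves]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate wave labels")
        for disease, pct in self.prevalence_pct.items():
            Disease(disease)
            if not 0.0 <= pct <= 100.0:
                raise ValueError(f"prevalence for {disease} outside [0, 100]")
        for ind, shifts in self.wave_effects.items():
            if len(shifts) != len(self.waves):
                raise ValueError(
                    f"wave_effects[{ind}] must have one entry per wave"
                )
        return self

    def wave_shift(self, indicator_id: str, wave_index: int) -> float:
        shifts = self.wave_effects.get(indicator_id)
        return 0.0 if shifts is None else float(shifts[wave_index])

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortSpec":
        return cls(**yaml.safe_load(Path(path).read_text()))


def default_cohort_spec(**overrides) -> CohortSpec:
    """The shipped default spec: a 20-practice cohort calibrated to the
    published baseline dispersion (per-indicator quartile triples) and
    prevalences of the published order of magnitude."""
    doc = yaml.safe_load(
        resources.files("qibench.data")
        .joinpath("default_cohort_spec.yaml")
        .read_text()
    )
    doc.update(overrides)
    return CohortSpec(**doc)


# --------------------------------------------------------------------------
# practice profiles (persist across waves -> paired structure)
# --------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class PracticeProfile:
    """Latent per-practice state shared by all waves."""

    gp_id: str
    capability: frozenset[IndicatorKind]
    n_patients_base: int
    baseline_probs: Mapping[str, float]  # indicator_id -> fulfilment prob


def draw_profiles(
    spec: CohortSpec,
    registry: IndicatorRegistry,
    rng: np.random.Generator,
) -> list[PracticeProfile]:
    params: dict[str, tuple] = {}
    for ind, f in spec.fulfilment.items():
        if f.prob is not None:
            params[ind] = ("point", f.prob)
        elif f.alpha is not None and f.beta is not None:
            params[ind] = ("beta", f.alpha, f.beta)
        else:
            fit = fit_beta_to_quantiles(f.q1, f.median, f.q3)
            params[ind] = ("beta", fit.alpha, fit.beta)
    n_prev_only = int(round(spec.prevalence_only_fraction * spec.n_gps))
    prev_only = set(
        rng.choice(spec.n_gps, size=n_prev_only, replace=False).tolist()
    )
    profiles = []
    for i in range(spec.n_gps):
        n_pat = int(
            np.round(
                spec.patients_per_practice.mean
                * rng.lognormal(
                    -spec.patients_per_practice.dispersion**2 / 2,
                    spec.patients_per_practice.dispersion,
                )
            )
        )
        probs = {}
        for d in registry.scored:
            par = params.get(d.indicator_id)
            if par is None:
                continue
            if par[0] == "point":
                probs[d.indicator_id] = float(par[1])
            else:
                probs[d.indicator_id] = float(rng.beta(par[1], par[2]))
        profiles.append(
            PracticeProfile(
                gp_id=f"gp{i + 1:02d}",
                capability=PREVALENCE_ONLY if i in prev_only else ALL_KINDS,
                n_patients_base=max(n_pat, 20),
                baseline_probs=probs,
            )
        )
    return profiles


# --------------------------------------------------------------------------
# record generation
# --------------------------------------------------------------------------

def _uniform_date_in_window(
    rng: np.random.Generator, ref: dt.date, lookback_months: int
) -> dt.date:
    start = months_before(ref, lookback_months)  # exclusive lower edge
    span = (ref - start).days
    return ref - dt.timedelta(days=int(rng.integers(0, span)))


def _uniform_date_before_window(
    rng: np.random.Generator, ref: dt.date, lookback_months: int
) -> dt.date:
    start = months_before(ref, lookback_months)
    return start - dt.timedelta(days=int(rng.integers(0, 365)))


_CRITERION_EVENT = {
    # criterion -> (record kind, obs type / drug class)
    "bmi_recorded": ("obs", "bmi"),
    "bp_recorded": ("obs", "blood_pressure"),
    "smoking_recorded": ("obs", "smoking_status"),
    "creatinine_done": ("obs", "creatinine"),
    "spirometry_recorded": ("obs", "spirometry"),
    "statin_rx": ("rx", "statin"),
    "beta_blocker_rx": ("rx", "beta_blocker"),
    "ace_arb_rx": ("rx", "ace_arb"),
    "antithrombotic_rx": ("rx", "antithrombotic"),
}

_HBA1C_CHAIN = ("hba1c_done", "hba1c_below_target", "metformin_if_high")


def _obs_value(rng: np.random.Generator, obs_type: str) -> float | str | None:
    if obs_type == "bmi":
        return float(np.round(rng.normal(28.0, 4.5), 1))
    if obs_type == "blood_pressure":
        return float(np.round(rng.normal(138.0, 15.0), 0))  # systolic mmHg
    if obs_type == "smoking_status":
        return "smoker" if rng.random() < 0.25 else "non-smoker"
    if obs_type == "creatinine":
        return float(np.round(rng.normal(0.95, 0.2), 2))  # mg/dl
    return None  # spirometry: presence of the record is the datum


def _wave_probs(
    spec: CohortSpec, profile: PracticeProfile, wave_index: int
) -> dict[str, float]:
    probs = {}
    for ind, p0 in profile.baseline_probs.items():
        shift = spec.wave_shift(ind, wave_index)
        if shift != 0.0:
            # clip before the logit so point masses at 0/1 stay shiftable
            p0 = float(np.clip(p0, _P_CLIP, 1 - _P_CLIP))
            p0 = float(expit(logit(p0) + shift))
        probs[ind] = p0
    return probs


def generate_practice(
    spec: CohortSpec,
    wave_index: int,
    rng: np.random.Generator,
    profile: PracticeProfile | None = None,
    registry: IndicatorRegistry | None = None,
) -> tuple[PracticeExtract, dict[str, float]]:
    """Generate one practice extract for one wave.

    Returns ``(extract, true_pct)`` where ``true_pct`` maps each
    indicator to the practice's expected achievement in percent at this
    wave — 100 × the fulfilment probability for scored indicators, the
    adjusted prevalence for prevalence indicators (the
    parameter-recovery ground truth).  If no ``profile`` is given a
    fresh one is drawn from ``rng``.

    Patients are assigned diseases independently (comorbidity allowed);
    a patient's record is shared across diseases, so for criteria that
    several of the patient's diseases monitor a single fulfilment draw
    is made using one of the applicable disease probabilities chosen at
    random (the record either holds the observation or it does not).
    """
    registry = registry or load_registry()
    if profile is None:
        profile = draw_profiles(spec, registry, rng)[0]
    wave = spec.waves[wave_index]
    ref = wave.reference_date
    probs = _wave_probs(spec, profile, wave_index)

    # visitor-based (raw) prevalence targets; spec prevalences are
    # population values, deflated among visitors by the coverage
    raw_prev = {
        Disease(d): min(pct / 100.0 / spec.visit_coverage, 1.0)
        for d, pct in spec.prevalence_pct.items()
    }
    by_disease: dict[Disease, list] = {}
    for d in registry.scored:
        by_disease.setdefault(d.disease, []).append(d)

    n_active = profile.n_patients_base
    n_inactive = int(round(_INACTIVE_FRACTION * n_active))
    patients = []
    for j in range(n_active + n_inactive):
        pid = f"{profile.gp_id}_w{wave.label}_p{j + 1:05d}"
        active = j < n_active
        if active:
            n_enc = int(rng.integers(1, 7))
            encounters = frozenset(
                _uniform_date_in_window(rng, ref, ELIGIBILITY_WINDOW_MONTHS)
                for _ in range(n_enc)
            )
        else:
            # lapsed patient: last contact before the visit window
            encounters = frozenset(
                {_uniform_date_before_window(rng, ref, ELIGIBILITY_WINDOW_MONTHS)}
            )
        diseases = [d for d, p in raw_prev.items() if rng.random() < p]
        diagnoses = frozenset(
            (d, ref - dt.timedelta(days=int(rng.integers(400, 4000))))
            for d in diseases
        )
        observations: list[Observation] = []
        prescriptions: list[Prescription] = []
        if diseases:
            # one fulfilment draw per criterion event type: the record is
            # shared across the patient's diseases
            seen_events: set[str] = set()
            hba1c_owner = Disease.DM2 in diseases
            for disease in diseases:
                for d in by_disease.get(disease, []):
                    if d.criterion in _HBA1C_CHAIN:
                        continue  # handled as a chain below
                    kind, token = _CRITERION_EVENT[d.criterion]
                    if token in seen_events:
                        continue
                    seen_events.add(token)
                    # pick the probability of a random applicable disease
                    applicable = [
                        probs[dd.indicator_id]
                        for dis in diseases
                        for dd in by_disease.get(dis, [])
                        if dd.criterion == d.criterion
                        and dd.indicator_id in probs
                    ]
                    if not applicable:
                        continue
                    p = applicable[int(rng.integers(0, len(applicable)))]
                    fulfilled = rng.random() < p
                    if fulfilled:
                        date = _uniform_date_in_window(
                            rng, ref, d.lookback_months or 120
                        )
                    elif rng.random() < 0.5 and d.lookback_months is not None:
                        date = _uniform_date_before_window(
                            rng, ref, d.lookback_months
                        )
                    else:
                        continue
                    if kind == "obs":
                        observations.append(
                            Observation(token, _obs_value(rng, token), date)
                        )
                    else:
                        prescriptions.append(Prescription(token, date))
            if hba1c_owner:
                p_done = probs.get("dm2_hba1c_done")
                p_below = probs.get("dm2_hba1c_lt_7_5")
                p_met = probs.get("dm2_metformin_if_high")
                if p_done is not None and rng.random() < p_done:
                    date = _uniform_date_in_window(rng, ref, HBA1C_WINDOW_MONTHS)
                    below = p_below is not None and rng.random() < p_below
                    if below:
                        value = float(np.round(rng.uniform(5.5, 7.4), 1))
                    else:
                        value = float(np.round(rng.uniform(7.6, 11.0), 1))
                    observations.append(Observation("hba1c", value, date))
                    if not below and p_met is not None and rng.random() < p_met:
                        prescriptions.append(
                            Prescription(
                                "metformin",
                                _uniform_date_in_window(rng, ref, 3),
                            )
                        )
                elif p_done is not None and rng.random() < 0.3:
                    # stale measurement outside the 9-month window
                    observations.append(
                        Observation(
                            "hba1c",
                            float(np.round(rng.uniform(5.5, 11.0), 1)),
                            _uniform_date_before_window(
                                rng, ref, HBA1C_WINDOW_MONTHS
                            ),
                        )
                    )
        patients.append(
            PatientRecord(
                patient_id=pid,
                encounter_dates=encounters,
                diagnoses=diagnoses,
                observations=tuple(observations),
                prescriptions=tuple(prescriptions),
            )
        )
    extract = PracticeExtract(
        gp_id=profile.gp_id,
        region=spec.region,
        wave=wave.label,
        reference_date=ref,
        patients=tuple(patients),
        capability=profile.capability,
    )
    # ground truth on the achievement scale (percent)
    true_pct = {ind: 100.0 * p for ind, p in probs.items()}
    for d in registry:
        if d.kind is IndicatorKind.PREVALENCE and d.disease in raw_prev:
            true_pct[d.indicator_id] = (
                100.0 * raw_prev[d.disease] * spec.visit_coverage
            )
    return extract, true_pct


@dataclasses.dataclass
class SyntheticCohort:
    """Generated multi-wave cohort plus its ground truth."""

    spec: CohortSpec
    extracts: dict[str, list[PracticeExtract]]  # wave label -> extracts
    true_pct: dict[tuple[str, str, str], float]  # (wave, gp, indicator) -> expected %

    @property
    def wave_labels(self) -> list[str]:
        return [w.label for w in self.spec.waves]


def generate_cohort(
    spec: CohortSpec, registry: IndicatorRegistry | None = None
) -> SyntheticCohort:
    """Generate all waves of a cohort; deterministic given ``spec.seed``.

    The same practices (ids, capabilities, latent fulfilment
    probabilities) persist across waves; wave effects shift their
    probabilities on the log-odds scale.  Patient panels are redrawn per
    wave (full turnover), which leaves the practice-level quantities the
    analysis consumes untouched.
    """
    registry = registry or load_registry()
    ss = np.random.SeedSequence(spec.seed)
    profile_seed, *wave_seeds = ss.spawn(1 + len(spec.waves))
    profiles = draw_profiles(
        spec, registry, np.random.default_rng(profile_seed)
    )
    extracts: dict[str, list[PracticeExtract]] = {}
    truth: dict[tuple[str, str, str], float] = {}
    for w, wave in enumerate(spec.waves):
        gp_seeds = wave_seeds[w].spawn(len(profiles))
        wave_extracts = []
        for profile, gp_seed in zip(profiles, gp_seeds):
            extract, probs = generate_practice(
                spec,
                w,
                np.random.default_rng(gp_seed),
                profile=profile,
                registry=registry,
            )
            wave_extracts.append(extract)
            for ind, p in probs.items():
                truth[(wave.label, profile.gp_id, ind)] = p
        extracts[wave.label] = wave_extracts
    return SyntheticCohort(spec=spec, extracts=extracts, true_pct=truth)
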