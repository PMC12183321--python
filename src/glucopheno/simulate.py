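"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates a metabolic-subphenotyping study: each participant
carries a four-dimensional latent state — muscle insulin resistance (as an
SSPG value), beta-cell secretory capacity, incretin contribution to
secretion, and hepatic insulin-resistance severity — drawn from a Gaussian
copula whose correlations mirror the pairwise structure observed between
the measured subphenotype axes (muscle and hepatic IR strongly related,
beta-cell deficiency moderately related to muscle IR, everything else
weakly).  The latent state shapes:

* a 16-point plasma OGTT curve: a gamma-shaped response kernel
  ``G0 + A (t/tau)^k exp(k (1 - t/tau))`` whose amplitude rises with muscle
  IR and incretin deficiency, whose decay slows (raising 2-h glucose) with
  beta-cell deficiency, and whose baseline rises with hepatic IR;
* paired OGTT/IIGI C-peptide series produced by pushing a secretion rate
  proportional to capacity x glucose excursion through the two-compartment
  C-peptide kinetic model (the IV test is an exact (1 - ie) rescaling of
  the oral response, so the measured incretin effect recovers the
  programmed fraction);
* an OGTT insulin series whose amplitude carries the hepatic-IR signal
  into the hepatic index;
* noisy at-home CGM replicates at 5-minute sampling with sensor lag and a
  per-test level shift calibrated to a target between-test coefficient of
  variation.

Every sampler draws from a counter-based per-participant stream derived
from one global seed, so enlarging a cohort never reshuffles the
participants already generated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .curves import (
    ANALYTES,
    CANONICAL_GRID,
    CGM_GRID,
    CPEPTIDE_GRID,
    INCRETIN_GRID,
    AnalyteSeries,
    GlucoseCurve,
)
from . import kinetics as kin

__all__ = [
    "LatentState",
    "SimulationConfig",
    "sample_covariates",
    "sample_latent_state",
    "simulate_ogtt_glucose",
    "simulate_cpeptide_pair",
    "simulate_cgm",
    "generate_cohort",
    "CohortSimulator",
]

_STREAMS = {
    "covariates": 0,
    "latent": 1,
    "glucose": 2,
    "cpeptide": 3,
    "insulin": 4,
    "incretin": 5,
    "cgm": 6,
    "clinic_cgm": 7,
}

LATENT_AXES = ("muscle", "beta", "incretin", "hepatic")


def _participant_rng(seed: int, index: int, stream: str) -> np.random.Generator:
    """Counter-split stream: (global seed, participant index, stream id)."""
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(index, _STREAMS[stream]))
    return np.random.default_rng(ss)


@dataclass(frozen=True)
class LatentState:
    """Ground-truth metabolic state of one simulated participant."""

    sspg: float  # mg/dl, muscle IR severity (40-300)
    beta_capacity: float  # dimensionless secretion multiplier, > 0
    ie_frac: float  # true incretin contribution, in [0, 1]
    hep_ir: float  # dimensionless hepatic-IR severity (standardized)
    z: tuple = (0.0, 0.0, 0.0, 0.0)  # underlying copula scores

    def __post_init__(self):
        if not 40.0 <= self.sspg <= 300.0:
            raise ValueError("sspg outside the plausible 40-300 mg/dl range")
        if not 0.0 <= self.ie_frac <= 1.0:
            raise ValueError("ie_frac must lie in [0, 1]")
        if self.beta_capacity <= 0:
            raise ValueError("beta_capacity must be positive")


def _default_correlations() -> np.ndarray:
    """Latent correlations: (muscle, beta, incretin, hepatic)."""
    C = np.full((4, 4), 0.2)
    np.fill_diagonal(C, 1.0)
    C[0, 3] = C[3, 0] = 0.7  # muscle - hepatic
    C[0, 1] = C[1, 0] = 0.6  # muscle - beta deficiency
    return C


@dataclass
class SimulationConfig:
    """Knobs of the synthetic cohort.

    Effect sizes are per standard deviation of the latent trait; noise SDs
    in mg/dl; the CGM level shift is calibrated internally to hit
    ``cgm_cv_target`` percent between-test variation.
    """

    n_participants: int = 200
    seed: int = 0

    # latent structure
    latent_correlations: np.ndarray = field(default_factory=_default_correlations)
    bmi_loading: float = 0.25  # shared BMI loading on muscle & hepatic axes
    sspg_center: float = 132.0
    sspg_scale: float = 52.0
    beta_capacity_log_sd: float = 0.5
    ie_intercept: float = 0.135
    ie_slope: float = 0.85

    # glucose response kernel
    baseline_glucose: float = 88.0
    baseline_per_sd_hepatic: float = 4.0
    baseline_per_sd_muscle: float = 2.0
    peak_amplitude: float = 58.0
    peak_per_sd_muscle: float = 14.0
    peak_per_sd_incretin: float = 8.0
    peak_per_sd_beta: float = 6.0
    peak_time: float = 42.0
    peak_time_per_sd_beta: float = 8.0
    peak_time_per_sd_muscle: float = 4.0
    kernel_shape: float = 2.2
    plasma_noise_sd: float = 2.5

    # C-peptide / insulin generation
    basal_cpeptide: float = 650.0  # pmol/l at latent zero
    basal_cpeptide_log_per_sd: float = 0.25  # muscle loading; hepatic half
    secretion_per_mgdl: float = 0.155  # pmol/kg/min per mg/dl excursion
    cpeptide_noise_cv: float = 4.0  # %
    fasting_insulin_mean: float = 10.0  # uIU/ml
    fasting_insulin_log_sd: float = 0.35
    insulin_excursion_gain: float = 0.045  # per mg/dl glucose excursion
    insulin_log_per_sd_hepatic: float = 0.5
    insulin_log_per_sd_muscle: float = 0.25
    insulin_scale: float = 1.55
    insulin_noise_cv: float = 6.0  # %

    # CGM sensor model
    cgm_noise_sd: float = 7.0  # mg/dl
    cgm_lag: float = 5.0  # min
    cgm_cv_target: float = 11.0  # %
    sspg_assay_sd: float = 4.0

    def __post_init__(self):
        C = np.asarray(self.latent_correlations, dtype=float)
        if C.shape != (4, 4) or not np.allclose(C, C.T):
            raise ValueError("latent correlation matrix must be 4x4 symmetric")
        if np.min(np.linalg.eigvalsh(C)) < -1e-10:
            raise ValueError("latent correlation matrix must be PSD")
        if self.plasma_noise_sd < 0 or self.cgm_noise_sd < 0:
            raise ValueError("noise SDs must be non-negative")
        self.latent_correlations = C


def sample_covariates(n: int, seed: int = 0) -> pd.DataFrame:
    """Baseline covariate table for n participants.

    Marginals emulate a middle-aged cohort enriched for early glucose
    dysregulation: age ~ N(55, 10); BMI ~ N(26, 5) truncated to the
    eligibility window [23, 40]; balanced sex; HDL ~ N(60, 22) floored at
    20 mg/dl; fasting glucose ~ N(98, 14) within [65, 160]; fasting insulin
    log-normal with mean 10 uIU/ml; HbA1c ~ N(5.6, 0.4); a
    polygenic score correlated with HbA1c.  Deterministic under the seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rows = []
    for i in range(n):
        rng = _participant_rng(seed, i, "covariates")
        sex = int(rng.random() < 0.5)
        age = float(rng.normal(55.0, 10.0))
        bmi = float(_truncnorm(rng, 26.0, 5.0, 23.0, 40.0))
        hdl = float(_truncnorm(rng, 60.0, 22.0, 20.0, np.inf))
        fpg = float(_truncnorm(rng, 98.0, 14.0, 65.0, 160.0))
        log_sd = 0.6
        fpi = float(np.exp(rng.normal(np.log(10.0) - log_sd**2 / 2, log_sd)))
        hba1c = float(_truncnorm(rng, 5.6, 0.4, 4.5, 7.5))
        ethnicity = int(rng.choice(4, p=[0.72, 0.25, 0.02, 0.01]))
        family_history = int(rng.random() < 0.3)
        height_cm = rng.normal(176.0, 7.0) if sex else rng.normal(163.0, 7.0)
        height_m = float(height_cm) / 100.0
        weight = bmi * height_m**2
        prs = 0.5 * (hba1c - 5.6) / 0.4 + np.sqrt(1 - 0.25) * rng.normal()
        rows.append(
            dict(
                participant_id=f"S{i:04d}",
                age=age, sex=sex, bmi=bmi, ethnicity=ethnicity,
                family_history=family_history, hba1c=hba1c, fpg=fpg,
                fasting_insulin=fpi, hdl=hdl, height_m=height_m,
                weight_kg=weight, prs=float(prs),
            )
        )
    return pd.DataFrame(rows).set_index("participant_id")


def _truncnorm(rng, mu, sd, lo, hi):
    a, b = (lo - mu) / sd, (hi - mu) / sd
    return stats.truncnorm.rvs(a, b, loc=mu, scale=sd, random_state=rng)


def _residual_correlations(C: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Copula residual correlations after removing a shared BMI loading."""
    denom = np.sqrt(np.outer(1 - b**2, 1 - b**2))
    R = (C - np.outer(b, b)) / denom
    np.fill_diagonal(R, 1.0)
    if np.min(np.linalg.eigvalsh(R)) < -1e-10:
        raise ValueError("BMI loading incompatible with latent correlations")
    return R


def sample_latent_state(
    covariates: pd.DataFrame, config: SimulationConfig
) -> pd.DataFrame:
    """Latent metabolic states, one row per participant.

    Gaussian copula with the configured 4x4 correlation matrix over
    (muscle, beta-deficiency, incretin-deficiency, hepatic) severities; a
    small shared loading on standardized BMI ties insulin resistance to
    adiposity while preserving the target correlations.  Marginals: SSPG
    affine in the muscle score (clipped to [40, 300]); beta capacity
    log-normal; incretin fraction logistic in the incretin score.
    """
    b = np.array([config.bmi_loading, 0.0, 0.0, config.bmi_loading])
    R = _residual_correlations(config.latent_correlations, b)
    L = np.linalg.cholesky(R + 1e-12 * np.eye(4))
    # standardize BMI by its truncated-normal moments so the copula algebra
    # (which assumes a unit-variance loading variable) stays exact
    a_t, b_t = (23.0 - 26.0) / 5.0, (40.0 - 26.0) / 5.0
    bmi_mu = stats.truncnorm.mean(a_t, b_t, loc=26.0, scale=5.0)
    bmi_sd = stats.truncnorm.std(a_t, b_t, loc=26.0, scale=5.0)
    z_bmi = (covariates["bmi"].to_numpy() - bmi_mu) / bmi_sd
    rows = []
    for i, (pid, z_b) in enumerate(zip(covariates.index, z_bmi)):
        rng = _participant_rng(config.seed, i, "latent")
        e = L @ rng.standard_normal(4)
        z = b * z_b + np.sqrt(1 - b**2) * e
        sspg = float(np.clip(
            config.sspg_center + config.sspg_scale * z[0], 40.0, 300.0
        ))
        beta_capacity = float(np.exp(-config.beta_capacity_log_sd * z[1]))
        ie_frac = float(
            1.0 / (1.0 + np.exp(-(config.ie_intercept - config.ie_slope * z[2])))
        )
        rows.append(
            dict(
                participant_id=pid,
                sspg=sspg,
                beta_capacity=beta_capacity,
                ie_frac=ie_frac,
                hep_ir=float(z[3]),
                z_muscle=float(z[0]),
                z_beta=float(z[1]),
                z_incretin=float(z[2]),
                z_hepatic=float(z[3]),
            )
        )
    return pd.DataFrame(rows).set_index("participant_id")


def _kernel(t: np.ndarray, g0: float, amp: float, tau: float, k: float) -> np.ndarray:
    g = np.full_like(t, g0, dtype=float)
    pos = t > 0
    x = t[pos] / tau
    g[pos] = g0 + amp * x**k * np.exp(k * (1.0 - x))
    return g


def simulate_ogtt_glucose(
    state: "LatentState | pd.Series",
    grid: np.ndarray = CANONICAL_GRID,
    seed: int = 0,
    config: SimulationConfig | None = None,
    participant_index: int = 0,
    participant_id: str = "S0000",
) -> GlucoseCurve:
    """Plasma OGTT glucose curve for one latent state.

    baseline + gamma-shaped response kernel with amplitude/timing linear in
    the standardized latent traits, plus additive assay noise; values are
    floored at 40 mg/dl so concentrations stay physiologic.
    """
    cfg = config or SimulationConfig(seed=seed)
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) <= 0) or not np.any(np.isclose(grid, 0.0)):
        raise ValueError("grid must be strictly increasing and include t=0")
    zm, zb, zi, zh = _latent_scores(state)
    g0 = (
        cfg.baseline_glucose
        + cfg.baseline_per_sd_hepatic * zh
        + cfg.baseline_per_sd_muscle * zm
    )
    amp = max(
        cfg.peak_amplitude
        + cfg.peak_per_sd_muscle * zm
        + cfg.peak_per_sd_incretin * zi
        + cfg.peak_per_sd_beta * zb,
        12.0,
    )
    tau = max(
        cfg.peak_time
        + cfg.peak_time_per_sd_beta * zb
        + cfg.peak_time_per_sd_muscle * zm,
        20.0,
    )
    clean = _kernel(grid, g0, amp, tau, cfg.kernel_shape)
    rng = _participant_rng(seed, participant_index, "glucose")
    noisy = clean + rng.normal(0.0, cfg.plasma_noise_sd, size=grid.size) \
        if cfg.plasma_noise_sd > 0 else clean
    return GlucoseCurve(
        participant_id, "plasma", "ogtt", grid, np.maximum(noisy, 40.0)
    )


def _latent_scores(state) -> tuple[float, float, float, float]:
    if isinstance(state, LatentState):
        return state.z if any(state.z) else (
            (state.sspg - 132.0) / 52.0,
            -np.log(state.beta_capacity) / 0.5,
            0.0,
            state.hep_ir,
        )
    return (
        float(state["z_muscle"]),
        float(state["z_beta"]),
        float(state["z_incretin"]),
        float(state["z_hepatic"]),
    )


def _state_fields(state) -> tuple[float, float]:
    if isinstance(state, LatentState):
        return state.beta_capacity, state.ie_frac
    return float(state["beta_capacity"]), float(state["ie_frac"])


def simulate_cpeptide_pair(
    state,
    glucose: GlucoseCurve,
    kinetic_params: kin.KineticParameters,
    seed: int = 0,
    config: SimulationConfig | None = None,
    weight_kg: float = 75.0,
    participant_index: int = 0,
) -> tuple[AnalyteSeries, AnalyteSeries]:
    """Paired OGTT / IIGI C-peptide series through the kinetic model.

    The oral secretion rate is basal + capacity x glucose excursion; the
    isoglycaemic IV response is the oral one scaled by (1 - ie_frac), so a
    noise-free pair returns exactly the programmed incretin fraction when
    measured by the C-peptide AUC ratio.
    """
    if not glucose.is_canonical:
        raise ValueError("glucose curve must be on the canonical grid")
    cfg = config or SimulationConfig(seed=seed)
    beta_capacity, ie_frac = _state_fields(state)
    zm, _, _, zh = _latent_scores(state)

    c_basal = cfg.basal_cpeptide * np.exp(
        cfg.basal_cpeptide_log_per_sd * zm
        + cfg.basal_cpeptide_log_per_sd / 2.0 * zh
    )
    s_basal = kinetic_params.k01 * kinetic_params.volume * c_basal  # pmol/min

    # piecewise-constant secretion on a 5-min grid from the glucose excursion
    fine_t = np.arange(0.0, 181.0, 5.0)
    g0 = glucose.values[np.isclose(glucose.times, 0.0)][0]
    post = glucose.times >= 0
    g_fine = np.interp(fine_t, glucose.times[post], glucose.values[post])
    excursion = np.maximum(g_fine - g0, 0.0)
    s_oral = s_basal + (
        cfg.secretion_per_mgdl * beta_capacity * excursion * weight_kg
    )

    c_ogtt = kin.forward_cpeptide(
        fine_t, s_oral, kinetic_params, CPEPTIDE_GRID, c0=c_basal
    )
    # IV test: exact (1 - ie) rescaling of the oral secretion and state
    c_iigi = (1.0 - ie_frac) * c_ogtt

    rng = _participant_rng(seed, participant_index, "cpeptide")
    if cfg.cpeptide_noise_cv > 0:
        cv = cfg.cpeptide_noise_cv / 100.0
        c_ogtt = c_ogtt * np.exp(rng.normal(0, cv, c_ogtt.size) - cv**2 / 2)
        c_iigi = c_iigi * np.exp(rng.normal(0, cv, c_iigi.size) - cv**2 / 2)
    pid = glucose.participant_id
    return (
        AnalyteSeries(pid, "OGTT", "cpeptide", CPEPTIDE_GRID, c_ogtt),
        AnalyteSeries(pid, "IIGI", "cpeptide", CPEPTIDE_GRID, c_iigi),
    )


def simulate_insulin_series(
    state,
    glucose: GlucoseCurve,
    fasting_insulin: float,
    seed: int = 0,
    config: SimulationConfig | None = None,
    participant_index: int = 0,
) -> AnalyteSeries:
    """OGTT insulin series; amplitude carries hepatic/muscle IR loadings."""
    cfg = config or SimulationConfig(seed=seed)
    zm, _, _, zh = _latent_scores(state)
    post = glucose.times >= 0
    g = np.interp(CPEPTIDE_GRID, glucose.times[post], glucose.values[post])
    g0 = glucose.values[np.isclose(glucose.times, 0.0)][0]
    excursion = np.maximum(g - g0, 0.0)
    level = (
        cfg.insulin_scale
        * fasting_insulin
        * (1.0 + cfg.insulin_excursion_gain * excursion)
        * np.exp(cfg.insulin_log_per_sd_hepatic * zh
                 + cfg.insulin_log_per_sd_muscle * zm)
    )
    rng = _participant_rng(seed, participant_index, "insulin")
    if cfg.insulin_noise_cv > 0:
        cv = cfg.insulin_noise_cv / 100.0
        level = level * np.exp(rng.normal(0, cv, level.size) - cv**2 / 2)
    return AnalyteSeries(
        glucose.participant_id, "OGTT", "insulin", CPEPTIDE_GRID, level
    )


def simulate_incretin_series(
    state,
    seed: int = 0,
    config: SimulationConfig | None = None,
    participant_index: int = 0,
) -> tuple[AnalyteSeries, AnalyteSeries]:
    """2-h GIP and GLP-1 concentrations rising with the incretin fraction."""
    cfg = config or SimulationConfig(seed=seed)
    _, ie_frac = _state_fields(state)
    rng = _participant_rng(seed, participant_index, "incretin")
    shape = np.array([0.25, 1.0, 0.85, 0.6])  # relative time course
    gip_2h = (45.0 + 55.0 * ie_frac) * np.exp(rng.normal(0, 0.2))
    glp1_2h = (8.0 + 14.0 * ie_frac) * np.exp(rng.normal(0, 0.25))
    pid = getattr(state, "name", "S0000")
    gip = AnalyteSeries(pid, "OGTT", "GIP", INCRETIN_GRID,
                        gip_2h * shape / shape[-1])
    glp1 = AnalyteSeries(pid, "OGTT", "GLP1", INCRETIN_GRID,
                         glp1_2h * shape / shape[-1])
    return gip, glp1


def _c4(n: int) -> float:
    """Unbiasing constant of the sample SD under normality."""
    return float(
        np.sqrt(2.0 / (n - 1)) * np.exp(gammaln(n / 2) - gammaln((n - 1) / 2))
    )


def simulate_cgm(
    plasma: GlucoseCurve,
    n_tests: int,
    config: SimulationConfig | None = None,
    seed: int = 0,
    participant_index: int = 0,
    source: str = "cgm_home",
) -> list[GlucoseCurve]:
    """At-home CGM replicates of one participant's OGTT response.

    Each test interpolates the plasma curve to 5-min sampling, applies the
    sensor lag, adds white sensor noise, and shifts the whole test by a
    level offset whose SD is calibrated so the expected between-test
    sample CV at a timepoint matches ``cgm_cv_target`` percent.
    """
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    cfg = config or SimulationConfig(seed=seed)
    post = plasma.times >= 0
    t_ref, v_ref = plasma.times[post], plasma.values[post]
    rng = _participant_rng(
        seed, participant_index, "cgm" if source == "cgm_home" else "clinic_cgm"
    )
    lagged_clean = np.interp(CGM_GRID - cfg.cgm_lag, t_ref, v_ref)
    # per-timepoint CV averages E[SD_t / G_t]; invert the harmonic mean so
    # the across-test SD hits the target CV on average
    level = 1.0 / float(np.mean(1.0 / lagged_clean))
    target_sd = cfg.cgm_cv_target / 100.0 * level / _c4(max(n_tests, 2))
    shift_sd = np.sqrt(max(target_sd**2 - cfg.cgm_noise_sd**2, 0.0))
    out = []
    for test in range(n_tests):
        lagged = lagged_clean
        values = lagged.copy()
        if cfg.cgm_noise_sd > 0:
            values = values + rng.normal(0, cfg.cgm_noise_sd, CGM_GRID.size)
        if shift_sd > 0:
            values = values + rng.normal(0, shift_sd)
        out.append(
            GlucoseCurve(
                plasma.participant_id, source, f"home{test + 1}"
                if source == "cgm_home" else "clinic",
                CGM_GRID, np.maximum(values, 40.0),
            )
        )
    return out


@dataclass
class SyntheticCohort:
    """In-memory result of a cohort simulation."""

    covariates: pd.DataFrame
    latent: pd.DataFrame
    glucose: pd.DataFrame  # long format
    analytes: pd.DataFrame  # long format
    config: SimulationConfig


class CohortSimulator:
    """End-to-end generator wiring the per-participant samplers together."""

    def __init__(self, config: SimulationConfig | None = None):
        self.config = config or SimulationConfig()

    def run(self) -> SyntheticCohort:
        cfg = self.config
        cov = sample_covariates(cfg.n_participants, cfg.seed)
        latent = sample_latent_state(cov, cfg)
        # observed SSPG: gold-standard test with small assay noise
        sspg_obs = []
        glucose_rows, analyte_rows = [], []
        for i, pid in enumerate(cov.index):
            row_cov = cov.loc[pid]
            row_lat = latent.loc[pid]
            rng_cov = _participant_rng(cfg.seed, i, "covariates")
            sspg_obs.append(
                float(np.clip(
                    row_lat["sspg"] + rng_cov.normal(0, cfg.sspg_assay_sd),
                    40.0, 300.0,
                ))
            )
            plasma = simulate_ogtt_glucose(
                row_lat, CANONICAL_GRID, cfg.seed, cfg, i, pid
            )
            glucose_rows.extend(_glucose_records(plasma))

            g120 = plasma.values[np.isclose(plasma.times, 120.0)][0]
            k_class = kin.assign_kinetic_class(
                row_cov["fpg"], g120, row_cov["hba1c"], row_cov["bmi"]
            )
            params = kin.parameters_for(
                k_class, row_cov["weight_kg"], row_cov["height_m"]
            )
            c_ogtt, c_iigi = simulate_cpeptide_pair(
                row_lat, plasma, params, cfg.seed, cfg,
                row_cov["weight_kg"], i,
            )
            insulin = simulate_insulin_series(
                row_lat, plasma, row_cov["fasting_insulin"], cfg.seed, cfg, i
            )
            gip, glp1 = simulate_incretin_series(row_lat, cfg.seed, cfg, i)
            for s in (c_ogtt, c_iigi, insulin, gip, glp1):
                analyte_rows.extend(_analyte_records(s, pid))

            for curve in simulate_cgm(plasma, 2, cfg, cfg.seed, i, "cgm_home"):
                glucose_rows.extend(_glucose_records(curve))
            for curve in simulate_cgm(plasma, 1, cfg, cfg.seed, i, "cgm_clinic"):
                glucose_rows.extend(_glucose_records(curve))

        cov = cov.copy()
        cov["sspg"] = sspg_obs
        return SyntheticCohort(
            covariates=cov,
            latent=latent,
            glucose=pd.DataFrame(glucose_rows),
            analytes=pd.DataFrame(analyte_rows),
            config=cfg,
        )


def _glucose_records(curve: GlucoseCurve) -> list[dict]:
    return [
        dict(
            participant_id=curve.participant_id,
            source=curve.source,
            test_id=curve.test_id,
            time_min=float(t),
            glucose_mg_dl=float(v),
        )
        for t, v in zip(curve.times, curve.values)
    ]


def _analyte_records(series: AnalyteSeries, pid: str) -> list[dict]:
    return [
        dict(
            participant_id=pid,
            test_type=series.test_type,
            analyte=series.analyte,
            time_min=float(t),
            value=float(v),
        )
        for t, v in zip(series.times, series.values)
    ]


def generate_cohort(config: SimulationConfig, outdir) -> dict:
    """Simulate a cohort and write it to ``outdir`` as CSV + manifest.

    Files: glucose.csv, analytes.csv, covariates.csv, latent_truth.csv and
    manifest.yaml (config + seed).  Latent truth is kept separate from the
    observables.  Reruns with the same config are byte-identical.
    """
    import yaml
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = CohortSimulator(config).run()
    paths = {
        "glucose": out / "glucose.csv",
        "analytes": out / "analytes.csv",
        "covariates": out / "covariates.csv",
        "latent_truth": out / "latent_truth.csv",
        "manifest": out / "manifest.yaml",
    }
    fmt = "%.10g"
    cohort.glucose.to_csv(paths["glucose"], index=False, float_format=fmt)
    cohort.analytes.to_csv(paths["analytes"], index=False, float_format=fmt)
    cohort.covariates.to_csv(paths["covariates"], float_format=fmt)
    cohort.latent.to_csv(paths["latent_truth"], float_format=fmt)
    manifest = {
        "generator": "glucopheno.simulate",
        "seed": config.seed,
        "n_participants": config.n_participants,
        "config": _config_dict(config),
    }
    with open(paths["manifest"], "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return {k: str(v) for k, v in paths.items()}


def _config_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["latent_correlations"] = np.asarray(
        d["latent_correlations"]
    ).round(10).tolist()
    return d
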