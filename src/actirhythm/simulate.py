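"""Synthetic multi-day actigraphy with fully known component structure.

The generator emulates the statistical structure the downstream analysis
assumes: a smooth unimodal diurnal mean curve, four orthonormal deviation
components (amplitude, early rise, activity-window length, biphasic mid-day
dip) with participant scores of configured variances, covariate shifts on
those scores, weekday/weekend score correlation, day-level and epoch-level
noise, non-wear missingness, log-normal survey weights, and a logistic
self-rated-health outcome driven by standardized scores.  Everything is
seeded and bit-reproducible, and every latent quantity is returned as ground
truth so parameter recovery can be asserted exactly.

No published generative model exists for this kind of data; all defaults
here are this package's own choices (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .errors import ConfigurationError
from .fpca import N_EPOCHS, EPOCH_HOURS, epoch_midpoints

MINUTES_PER_DAY = 1440
WEEKEND_DAYS = (1, 7)  # 1=Sunday, 7=Saturday

# Marginal level frequencies for the six sociodemographic covariates of a
# US-adult-style cohort (25+): six age groups, two genders, six race/ethnicity
# groups, four education and income levels, three work-status levels.
COVARIATE_LEVELS: dict[str, list[str]] = {
    "age_group": ["25-29", "30-39", "40-49", "50-59", "60-69", "70+"],
    "gender": ["male", "female"],
    "race_ethnicity": ["NH White", "NH Black", "Mexican American",
                       "Other Hispanic", "NH Asian", "other"],
    "education": ["<HS", "HS grad", "some college", "college grad+"],
    "income": ["<$20k", "$20k-$44.9k", "$45k-$74.9k", ">=$75k"],
    "work_status": ["did not work", "<40 h", "40+ h"],
}

COVARIATE_FREQS: dict[str, list[float]] = {
    "age_group": [0.10, 0.20, 0.20, 0.20, 0.17, 0.13],
    "gender": [0.48, 0.52],
    "race_ethnicity": [0.44, 0.22, 0.12, 0.09, 0.10, 0.03],
    "education": [0.17, 0.22, 0.31, 0.30],
    "income": [0.18, 0.29, 0.22, 0.31],
    "work_status": [0.38, 0.16, 0.46],
}


@dataclass(frozen=True)
class MeanCurveParams:
    """Smooth diurnal mean m(t) = night + (day-night) * s((t-r)/s) * s((d-t)/s).

    ``rise_time`` and ``decline_time`` are the half-activation times of the
    morning rise and evening decline (hours); ``steepness`` sets the width of
    both transitions.  Units of the levels are MIMS per minute.
    """

    night_level: float = 2.0
    day_level: float = 12.0
    rise_time: float = 7.0
    decline_time: float = 21.5
    steepness: float = 1.0


@dataclass(frozen=True)
class GeneratorConfig:
    """Every knob of the synthetic cohort; defaults are the study conditions."""

    n_participants: int = 500
    seed: int = 0
    n_days: int = 7
    period: float = 24.0
    epoch_minutes: int = 5
    mean_curve: MeanCurveParams = field(default_factory=MeanCurveParams)
    component_variances: tuple[float, ...] = (4.0, 2.0, 1.0, 0.5)
    covariate_effects: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: {
            "gender=female": (0.3, 0.0, 0.0, 0.1),
            "age_group=60-69": (-0.5, 0.5, 0.2, 0.0),
            "age_group=70+": (-0.8, 0.8, 0.3, 0.0),
            "work_status=did not work": (-0.4, -0.3, 0.5, -0.2),
            "education=<HS": (0.3, 0.2, 0.0, -0.3),
        }
    )
    weekday_weekend_corr: tuple[float, float, float, float] = (0.72, 0.65, 0.5, 0.14)
    epoch_noise_sd: float = 0.5
    #: day-level offsets act in the constant-curve direction; after averaging
    #: the n_we=2 weekend days their coefficient-space variance is
    #: 24 * sd^2 / 2, which must stay below the smallest component variance
    #: for the four components to remain identifiable (0.12 < 0.5 at default)
    day_effect_sd: float = 0.1
    nonwear_rate: float = 0.05
    nonwear_block_mean: float = 60.0
    zero_actigraphy_fraction: float = 0.0
    #: floor activity at zero, as real MIMS values are; disable only for
    #: exact-recovery oracles (clipping is a nonlinearity fPCA cannot undo)
    clip_at_zero: bool = True
    health_intercept: float = float(logit(0.15))
    health_effects: tuple[float, float, float, float] = (-0.5, 0.0, 0.25, -0.2)
    weight_log_sd: float = 0.5
    informative_weights: bool = False
    #: project the component shapes onto a Fourier span of this many harmonics
    #: before orthonormalization, so the analysis basis can represent them
    #: exactly; None keeps the raw (full-resolution) shapes
    band_limit_harmonics: int | None = 9
    #: force the sampled score residuals to have *exactly* zero sample mean
    #: and the configured covariance (fixed-moments simulation); used by
    #: parameter-recovery oracles where sampling rotation must vanish
    exact_score_moments: bool = False

    def __post_init__(self) -> None:
        lam = self.component_variances
        if len(lam) != 4 or not all(
            lam[k] > lam[k + 1] for k in range(3)
        ) or lam[3] <= 0:
            raise ConfigurationError(
                "component variances must satisfy l1 > l2 > l3 > l4 > 0"
            )
        if any(abs(r) > 1 for r in self.weekday_weekend_corr):
            raise ConfigurationError("weekday/weekend correlations must lie in [-1, 1]")
        if not 0 <= self.nonwear_rate < 1:
            raise ConfigurationError("nonwear_rate must lie in [0, 1)")
        if not 0 <= self.zero_actigraphy_fraction < 1:
            raise ConfigurationError("zero_actigraphy_fraction must lie in [0, 1)")
        p = self.mean_curve
        if not 0 < p.rise_time < p.decline_time < self.period:
            raise ConfigurationError("need 0 < rise_time < decline_time < period")
        if not np.isfinite([a for a in (self.epoch_noise_sd, self.day_effect_sd,
                                        self.health_intercept, *self.health_effects)]).all():
            raise ConfigurationError("noise and health parameters must be finite")
        if self.exact_score_moments and self.n_participants < 10:
            raise ConfigurationError("exact_score_moments needs at least 10 participants")

    @classmethod
    def exact_recovery(cls, n_participants: int = 500, seed: int = 0, **overrides):
        """Noise-free configuration under which the pipeline recovers the
        generator's components exactly: no epoch/day noise, no clipping, no
        missingness, no covariate score shifts, identical weekday and weekend
        scores, band-limited components, and exactly-moment-matched scores."""
        defaults = dict(
            n_participants=n_participants,
            seed=seed,
            epoch_noise_sd=0.0,
            day_effect_sd=0.0,
            nonwear_rate=0.0,
            clip_at_zero=False,
            covariate_effects={},
            weekday_weekend_corr=(1.0, 1.0, 1.0, 1.0),
            exact_score_moments=True,
        )
        defaults.update(overrides)
        return cls(**defaults)


@dataclass
class GroundTruth:
    """Latent quantities behind one simulated cohort."""

    participant_ids: np.ndarray
    mean_curve: np.ndarray                 # m(t_j) on the 288 grid
    component_curves: np.ndarray           # 4 x 288, orthonormal in L2
    true_scores: dict[str, np.ndarray]     # stratum -> (n, 4)
    true_weights: np.ndarray
    day_of_week: np.ndarray                # (n, n_days), 1=Sunday..7=Saturday
    true_health_probability: np.ndarray | None = None


@dataclass
class SimulatedCohort:
    """Generator output: observed tables plus ground truth.

    ``day_epoch_values`` holds the day-level 5-min epoch values (n, n_days,
    288) from which the minute table replicates each value five times; tests
    that do not need the minute dialect can consume it directly.
    """

    minute_records: pd.DataFrame | None
    covariates: pd.DataFrame
    truth: GroundTruth
    day_epoch_values: np.ndarray


def mean_curve(t: np.ndarray, params: MeanCurveParams) -> np.ndarray:
    """Evaluate the diurnal mean activity curve at times t (hours)."""
    u = expit((t - params.rise_time) / params.steepness)
    v = expit((params.decline_time - t) / params.steepness)
    return params.night_level + (params.day_level - params.night_level) * u * v


def make_component_basis(config: GeneratorConfig) -> np.ndarray:
    """Four orthonormal deviation components on the 288-epoch grid.

    Raw shapes, orthonormalized by Gram-Schmidt in this fixed order:

    1. amplitude   — the centered mean curve (uniform up/down scaling),
    2. early rise  — minus the time derivative of m (a small time advance),
    3. window      — sensitivity of m to symmetric widening of the active
       period (rise earlier, decline later),
    4. biphasic    — a negative mid-day Gaussian bump (13.5 h, sd 2 h)
       restricted to the active period (a mid-day dip).

    Orthonormality is under the L2 inner product with 288-point quadrature,
    <f, g> = dt * sum f g, dt = 1/12 h.
    """
    p = config.mean_curve
    t = epoch_midpoints(config.period)
    s = p.steepness
    u = expit((t - p.rise_time) / s)
    v = expit((p.decline_time - t) / s)
    span = p.day_level - p.night_level
    m = p.night_level + span * u * v

    du = u * (1 - u) / s       # d/dt sigma((t-r)/s)
    dv = -v * (1 - v) / s      # d/dt sigma((d-t)/s)
    raw = np.empty((4, t.size))
    raw[0] = m - m.mean()
    raw[1] = -span * (du * v + u * dv)
    # widening derivative: r -> r - w lowers the rise argument's offset,
    # d -> d + w raises the decline's, both increasing m inside transitions
    raw[2] = span * (u * (1 - u) * v + u * v * (1 - v)) / s
    raw[3] = -np.exp(-((t - 13.5) ** 2) / (2 * 2.0**2)) * u * v

    if not np.isfinite(raw).all():
        raise ConfigurationError("degenerate mean-curve parameters produced non-finite shapes")

    dt = config.period / N_EPOCHS
    if config.band_limit_harmonics is not None:
        # project each shape onto the Fourier span the analysis uses, so the
        # components are exactly representable by the downstream smoother
        from .fpca import FourierBasis

        phi_mat = FourierBasis(config.period, config.band_limit_harmonics).design(t)
        coef, *_ = np.linalg.lstsq(phi_mat, raw.T, rcond=None)
        raw = (phi_mat @ coef).T
    basis = np.empty_like(raw)
    for k in range(4):
        w = raw[k].copy()
        for j in range(k):
            w -= dt * (basis[j] @ w) * basis[j]
        norm = np.sqrt(dt * (w @ w))
        if norm < 1e-10:
            raise ConfigurationError(f"component {k + 1} is degenerate after orthogonalization")
        basis[k] = w / norm
    return basis


def _draw_covariates(n: int, rng: np.random.Generator) -> pd.DataFrame:
    data = {"participant_id": np.arange(100001, 100001 + n, dtype=np.int64)}
    for name, levels in COVARIATE_LEVELS.items():
        data[name] = rng.choice(levels, size=n, p=COVARIATE_FREQS[name])
    return pd.DataFrame(data)


def _score_shifts(covariates: pd.DataFrame, config: GeneratorConfig) -> np.ndarray:
    """Per-participant mean shift gamma_k(x_i) for each component -> (n, 4)."""
    n = len(covariates)
    gamma = np.zeros((n, 4))
    for key, effect in config.covariate_effects.items():
        cov, _, level = key.partition("=")
        if cov not in COVARIATE_LEVELS:
            raise ConfigurationError(f"unknown covariate in effects: {cov!r}")
        if level not in COVARIATE_LEVELS[cov]:
            raise ConfigurationError(f"unknown level in effects: {key!r}")
        mask = (covariates[cov] == level).to_numpy()
        gamma[mask] += np.asarray(effect, dtype=float)
    return gamma


def _draw_score_residuals(
    rng: np.random.Generator,
    n: int,
    lam: np.ndarray,
    rho: np.ndarray,
    exact: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """Weekday/weekend score residuals, component-wise bivariate normal.

    With ``exact`` the latent draws are whitened so their *sample* mean is
    exactly zero and their sample covariance exactly matches the target
    (diagonal across components, lambda_k [[1, rho_k], [rho_k, 1]] within a
    component); otherwise the moments hold only in distribution.
    """
    z1 = rng.standard_normal((n, 4))
    z2 = rng.standard_normal((n, 4))
    sd = np.sqrt(lam)
    if not exact:
        e_wd = sd * z1
        e_we = sd * (rho * z1 + np.sqrt(1 - rho**2) * z2)
        return e_wd, e_we
    degenerate = np.abs(rho) == 1.0
    cols = []
    for k in range(4):
        cols.append(z1[:, k])
        if not degenerate[k]:
            cols.append(z2[:, k])
    Z = np.column_stack(cols)
    Z = Z - Z.mean(axis=0)
    L = np.linalg.cholesky(Z.T @ Z / (n - 1))
    Z = np.linalg.solve(L, Z.T).T        # sample covariance exactly identity
    e_wd = np.empty((n, 4))
    e_we = np.empty((n, 4))
    j = 0
    for k in range(4):
        if degenerate[k]:
            e_wd[:, k] = sd[k] * Z[:, j]
            e_we[:, k] = rho[k] * e_wd[:, k]
            j += 1
        else:
            Lk = np.linalg.cholesky(lam[k] * np.array([[1.0, rho[k]], [rho[k], 1.0]]))
            pair = Z[:, j : j + 2] @ Lk.T
            e_wd[:, k] = pair[:, 0]
            e_we[:, k] = pair[:, 1]
            j += 2
    return e_wd, e_we


def simulate_participants(
    config: GeneratorConfig, expand_minutes: bool = True
) -> SimulatedCohort:
    """Simulate a cohort: minute records, covariates, weights, ground truth.

    Per participant i, component k, the weekday and weekend scores are drawn
    bivariate normal with common mean gamma_k(x_i), variance lambda_k and
    correlation rho_k; the day-d curve is

        y_id(t_j) = m(t_j) + sum_k xi_ik(stratum(d)) phi_k(t_j) + b_id + e_idj

    with day effect b ~ N(0, day_effect_sd^2) and epoch noise
    e ~ N(0, epoch_noise_sd^2).  Minutes replicate their epoch value.  The
    "overall" true score is the day-count-weighted mix of the stratum scores.
    """
    n = config.n_participants
    if n < 5 * 4:
        import warnings

        warnings.warn(
            "fewer than 5 participants per structured component; downstream "
            "fPCA may be rank-deficient",
            stacklevel=2,
        )
    rng = np.random.default_rng(config.seed)
    covariates = _draw_covariates(n, rng)
    gamma = _score_shifts(covariates, config)
    phi = make_component_basis(config)
    t = epoch_midpoints(config.period)
    m = mean_curve(t, config.mean_curve)

    lam = np.asarray(config.component_variances)
    rho = np.asarray(config.weekday_weekend_corr)
    e_wd, e_we = _draw_score_residuals(rng, n, lam, rho, config.exact_score_moments)
    xi_wd = gamma + e_wd
    xi_we = gamma + e_we

    start = rng.integers(1, 8, size=n)  # uniform starting day-of-week
    dow = (start[:, None] + np.arange(config.n_days)[None, :] - 1) % 7 + 1
    is_weekend = np.isin(dow, WEEKEND_DAYS)
    n_we = is_weekend.sum(axis=1)
    n_wd = config.n_days - n_we
    with np.errstate(invalid="ignore"):
        xi_overall = (n_wd[:, None] * xi_wd + n_we[:, None] * xi_we) / config.n_days

    # day-level curves (n, n_days, 288)
    xi_day = np.where(is_weekend[:, :, None], xi_we[:, None, :], xi_wd[:, None, :])
    y = m[None, None, :] + np.einsum("idk,kj->idj", xi_day, phi)
    y += rng.standard_normal((n, config.n_days, 1))[..., :] * config.day_effect_sd
    y += rng.standard_normal(y.shape) * config.epoch_noise_sd
    if config.clip_at_zero:
        np.clip(y, 0.0, None, out=y)

    raw_w = rng.lognormal(mean=0.0, sigma=config.weight_log_sd, size=n)
    if config.informative_weights:
        # older groups get systematically larger weights, so the weighted and
        # unweighted estimands separate whenever effects vary with age
        age_rank = covariates["age_group"].map(
            {lvl: i for i, lvl in enumerate(COVARIATE_LEVELS["age_group"])}
        ).to_numpy()
        raw_w = raw_w * (1.0 + 0.6 * age_rank)
    weights = raw_w / raw_w.mean()
    covariates["exam_weight"] = weights

    truth = GroundTruth(
        participant_ids=covariates["participant_id"].to_numpy(),
        mean_curve=m,
        component_curves=phi,
        true_scores={"weekday": xi_wd, "weekend": xi_we, "overall": xi_overall},
        true_weights=weights,
        day_of_week=dow,
    )

    minute_records = _expand_to_minutes(y, truth, config) if expand_minutes else None
    return SimulatedCohort(minute_records, covariates, truth, y)


def _expand_to_minutes(
    y: np.ndarray, truth: GroundTruth, config: GeneratorConfig
) -> pd.DataFrame:
    """Replicate each 5-min epoch value across its minutes -> long table."""
    n, n_days, _ = y.shape
    activity = np.repeat(y, config.epoch_minutes, axis=2).reshape(-1)
    t_min = np.arange(MINUTES_PER_DAY)
    hours = t_min / 60.0
    # simple wear-state labelling: night minutes are sleep wear, day wake wear
    p = config.mean_curve
    sleep = (hours < p.rise_time - 1.0) | (hours >= p.decline_time + 1.0)
    wear_day = np.where(sleep, "sleep_wear", "wake_wear")
    return pd.DataFrame(
        {
            "participant_id": np.repeat(truth.participant_ids, n_days * MINUTES_PER_DAY),
            "day_index": np.tile(
                np.repeat(np.arange(1, n_days + 1, dtype=np.int16), MINUTES_PER_DAY), n
            ),
            "day_of_week": np.repeat(
                truth.day_of_week.astype(np.int16).reshape(-1), MINUTES_PER_DAY
            ),
            "minute_of_day": np.tile(t_min.astype(np.int16), n * n_days),
            "activity": activity.astype(np.float64),
            "wear_state": np.tile(wear_day, n * n_days),
        }
    )


def inject_missingness(
    records: pd.DataFrame, config: GeneratorConfig, seed: int | None = None
) -> pd.DataFrame:
    """Flag contiguous minute blocks as non-wear and whole participants as invalid.

    Block starts are uniform over rows; block lengths are geometric with the
    configured mean and are clipped at the participant-day boundary.  Blocks
    are added until the flagged fraction reaches ``nonwear_rate``.  A
    ``zero_actigraphy_fraction`` share of participants has every minute
    flagged invalid (no usable actigraphy at all).
    """
    if config.nonwear_rate == 0 and config.zero_actigraphy_fraction == 0:
        return records
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    out = records.copy()
    n_rows = len(out)
    wear = out["wear_state"].to_numpy(dtype=object, copy=True)
    minute = out["minute_of_day"].to_numpy()

    flagged = np.zeros(n_rows, dtype=bool)
    target = int(round(config.nonwear_rate * n_rows))
    p_geo = 1.0 / config.nonwear_block_mean
    while flagged.sum() < target:
        need = target - flagged.sum()
        n_blocks = max(8, int(need / config.nonwear_block_mean * 1.25))
        starts = rng.integers(0, n_rows, size=n_blocks)
        lengths = rng.geometric(p_geo, size=n_blocks)
        for s0, length in zip(starts, lengths):
            stop = min(s0 + min(length, MINUTES_PER_DAY - minute[s0]), n_rows)
            flagged[s0:stop] = True
            if flagged.sum() >= target:
                break
    wear[flagged] = "non_wear"

    k_zero = int(round(config.zero_actigraphy_fraction * out["participant_id"].nunique()))
    if k_zero > 0:
        ids = np.sort(out["participant_id"].unique())
        chosen = rng.choice(ids, size=k_zero, replace=False)
        wear[np.isin(out["participant_id"].to_numpy(), chosen)] = "invalid"
    out["wear_state"] = wear
    return out


def simulate_health(truth: GroundTruth, config: GeneratorConfig,
                    seed: int | None = None) -> np.ndarray:
    """Bernoulli poor/fair self-rated-health outcome driven by overall scores.

    Scores are standardized to unit variance (dividing by sqrt(lambda_k))
    before the log-odds alpha + sum_k theta_k * xi*_ik are applied.  The
    per-participant probability is stored on the ground truth.
    """
    theta = np.asarray(config.health_effects, dtype=float)
    if not np.isfinite(theta).all():
        raise ConfigurationError("health effects must be finite")
    rng = np.random.default_rng(config.seed + 2 if seed is None else seed)
    std = truth.true_scores["overall"] / np.sqrt(np.asarray(config.component_variances))
    prob = expit(config.health_intercept + std @ theta)
    truth.true_health_probability = prob
    return (rng.uniform(size=prob.size) < prob).astype(np.int64)


def attach_health_labels(
    covariates: pd.DataFrame, poor_fair: np.ndarray, seed: int = 0
) -> pd.DataFrame:
    """Map the binary outcome to five-level self-rated-health labels.

    Participants with the poor/fair outcome are split between "fair" and
    "poor"; the rest between "excellent", "very good" and "good".  The
    dichotomy (fair/poor vs the rest) is exactly the simulated outcome.
    """
    rng = np.random.default_rng(seed)
    out = covariates.copy()
    n = len(out)
    bad = rng.choice(["fair", "poor"], size=n, p=[0.7, 0.3])
    good = rng.choice(["excellent", "very good", "good"], size=n, p=[0.25, 0.35, 0.4])
    out["self_rated_health"] = np.where(poor_fair == 1, bad, good)
    return out


def simulate_cohort(config: GeneratorConfig, expand_minutes: bool = True) -> SimulatedCohort:
    """Full generator: participants + missingness + health labels."""
    cohort = simulate_participants(config, expand_minutes=expand_minutes)
    if cohort.minute_records is not None:
        cohort.minute_records = inject_missingness(cohort.minute_records, config)
    y = simulate_health(cohort.truth, config)
    cohort.covariates = attach_health_labels(cohort.covariates, y, seed=config.seed + 3)
    return cohort
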