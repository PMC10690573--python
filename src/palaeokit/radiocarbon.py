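"""Radiocarbon conversion, blank correction, replicate combination,
calibration, and a one-phase outlier model.

Conventions: uncalibrated ages are conventional radiocarbon years BP
(before AD 1950) computed with the Libby mean life (8033 yr) from F14C;
calibrated ages are cal BP. Replicates from one extract are combined by
inverse-variance weighting with a chi-squared agreement test (the
Ward & Wilson criterion); calibrated ranges are 95.4% highest-density
sets with endpoints rounded outward to 10 years.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .io import CalCurve

__all__ = [
    "LIBBY_MEAN_LIFE",
    "F14CMeasurement",
    "RadiocarbonAge",
    "CombineResult",
    "CalibratedDensity",
    "PhaseModelResult",
    "f14c_to_age",
    "age_to_f14c",
    "blank_correct",
    "combine_replicates",
    "calibrate",
    "hpd_ranges",
    "phase_outlier_model",
]

LIBBY_MEAN_LIFE = 8033.0  # conventional 14C age scale: t = -8033 ln(F14C)

# extra relative uncertainty folded into blank-corrected F14C, by AMS source
EXTRA_REL_UNCERTAINTY = {"graphite": 0.0016, "gas": 0.004}
BLANK_REL_ERROR = 0.30


class ValidationError(ValueError):
    pass


class RangeError(ValueError):
    """A measurement falls outside the calibration curve's coverage."""


@dataclass(frozen=True)
class F14CMeasurement:
    """Fraction-modern measurement with 1-sigma error and AMS source."""

    f14c: float
    sigma_f: float
    source: str = "graphite"
    below_background: bool = False

    def __post_init__(self) -> None:
        if self.f14c < 0:
            raise ValidationError("F14C must be >= 0")
        if self.sigma_f <= 0:
            raise ValidationError("sigma_f must be > 0")
        if self.source not in ("graphite", "gas"):
            raise ValidationError("source must be 'graphite' or 'gas'")


@dataclass(frozen=True)
class RadiocarbonAge:
    """An uncalibrated measurement x +/- sigma in 14C yr BP."""

    lab_id: str
    age_bp: float
    sigma: float
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValidationError("sigma must be > 0")


@dataclass(frozen=True)
class CombineResult:
    mean_bp: float
    sigma_bp: float
    chi2_stat: float
    dof: int
    passed: bool
    alpha: float = 0.05


@dataclass(frozen=True)
class CalibratedDensity:
    """Normalized posterior over calendar age on a 1-yr grid."""

    grid: np.ndarray  # cal BP, ascending
    prob: np.ndarray  # sums to 1
    hpd: tuple[tuple[float, float, float], ...] = ()  # (older, younger, mass)


@dataclass(frozen=True)
class PhaseModelResult:
    start_draws: np.ndarray  # cal BP (older boundary)
    end_draws: np.ndarray  # cal BP (younger boundary)
    span_draws: np.ndarray  # start - end, years
    outlier_prob: np.ndarray  # posterior P(outlier) per date
    theta_draws: np.ndarray  # (n_draws, n_dates) calendar ages
    lab_ids: tuple[str, ...] = ()
    warnings: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# F14C <-> age

def f14c_to_age(m: F14CMeasurement) -> RadiocarbonAge:
    """Convert fraction modern to conventional 14C age (t = -8033 ln F)."""
    if m.f14c <= 0:
        raise ValidationError("F14C <= 0 has no finite age")
    age = -LIBBY_MEAN_LIFE * math.log(m.f14c)
    sigma = LIBBY_MEAN_LIFE * m.sigma_f / m.f14c
    return RadiocarbonAge(lab_id="", age_bp=age, sigma=sigma)


def age_to_f14c(age_bp: float) -> float:
    return math.exp(-age_bp / LIBBY_MEAN_LIFE)


def blank_correct(
    m: F14CMeasurement,
    blank: F14CMeasurement,
    extra_rel_uncertainty: float | None = None,
) -> F14CMeasurement:
    """Background-correct a measurement against a 14C-dead processing blank.

    F_c = (F_m - F_b) / (1 - F_b), first-order error propagation with a
    30% relative error on the blank, then an extra relative uncertainty
    (0.16% graphite / 0.4% gas by default) added in quadrature.
    """
    if blank.f14c >= 1:
        raise ValidationError("blank F14C must be < 1")
    fm, fb = m.f14c, blank.f14c
    sigma_b = BLANK_REL_ERROR * fb
    fc = (fm - fb) / (1.0 - fb)
    dfm = 1.0 / (1.0 - fb)
    dfb = (fm - 1.0) / (1.0 - fb) ** 2
    var = (dfm * m.sigma_f) ** 2 + (dfb * sigma_b) ** 2
    if extra_rel_uncertainty is None:
        extra_rel_uncertainty = EXTRA_REL_UNCERTAINTY[m.source]
    if fc > 0:
        var += (extra_rel_uncertainty * fc) ** 2
    below = fm < fb - 3.0 * sigma_b
    return F14CMeasurement(
        f14c=max(fc, 0.0) if below else fc,
        sigma_f=math.sqrt(var),
        source=m.source,
        below_background=below,
    )


# ---------------------------------------------------------------------------
# chi-squared replicate combination (Ward & Wilson)

def combine_replicates(
    ages: Sequence[RadiocarbonAge], alpha: float = 0.05
) -> CombineResult:
    """Inverse-variance weighted mean with a chi-squared agreement test.

    T = sum((x_i - mu)^2 / sigma_i^2) is compared against the upper-alpha
    quantile of chi2(n-1); ``passed`` records whether the replicates agree.
    """
    if len(ages) < 2:
        raise ValidationError("need >= 2 replicates to combine")
    x = np.array([a.age_bp for a in ages])
    s = np.array([a.sigma for a in ages])
    w = 1.0 / s**2
    mean = float(np.sum(w * x) / np.sum(w))
    sigma = float(1.0 / math.sqrt(np.sum(w)))
    t_stat = float(np.sum(w * (x - mean) ** 2))
    dof = len(ages) - 1
    crit = stats.chi2.ppf(1.0 - alpha, dof)
    return CombineResult(
        mean_bp=mean,
        sigma_bp=sigma,
        chi2_stat=t_stat,
        dof=dof,
        passed=bool(t_stat <= crit),
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# calibration

def _posterior_on_grid(
    age_bp: float, sigma: float, curve: CalCurve, grid: np.ndarray
) -> np.ndarray:
    mu, sig_c = curve.interp(grid)
    var = sigma**2 + sig_c**2
    log_p = -0.5 * (age_bp - mu) ** 2 / var - 0.5 * np.log(var)
    log_p -= log_p.max()
    p = np.exp(log_p)
    return p / p.sum()


def calibrate(
    age: RadiocarbonAge, curve: CalCurve, hpd_mass: float = 0.954
) -> CalibratedDensity:
    """Calibrate one measurement against a curve on a 1-yr grid.

    p(theta) is proportional to a normal likelihood of the measured age at
    the interpolated curve mean, with measurement and curve variances
    added.
    """
    lo, hi = float(curve.c14_bp.min()), float(curve.c14_bp.max())
    if not (lo - 10 * age.sigma) <= age.age_bp <= (hi + 10 * age.sigma):
        raise RangeError(
            f"age {age.age_bp:.0f} BP outside curve coverage [{lo:.0f}, {hi:.0f}] +/- 10 sigma"
        )
    grid = np.arange(curve.cal_bp.min(), curve.cal_bp.max() + 1.0)
    prob = _posterior_on_grid(age.age_bp, age.sigma, curve, grid)
    d = CalibratedDensity(grid=grid, prob=prob)
    return CalibratedDensity(grid=grid, prob=prob, hpd=hpd_ranges(d, hpd_mass))


def hpd_ranges(
    d: CalibratedDensity, mass: float = 0.954, round_to: int = 10
) -> tuple[tuple[float, float, float], ...]:
    """Highest-density calendar ranges containing >= ``mass`` probability.

    Grid points are added in descending probability until the target mass
    is reached; contiguous runs are merged and reported (older, younger,
    mass) with endpoints rounded outward to ``round_to`` years.
    """
    if not 0.0 < mass <= 1.0:
        raise ValidationError("mass must be in (0, 1]")
    p = d.prob
    order = np.argsort(p)[::-1]
    csum = np.cumsum(p[order])
    k = int(np.searchsorted(csum, mass)) + 1
    included = np.zeros(len(p), dtype=bool)
    included[order[:k]] = True
    ranges = []
    i = 0
    n = len(p)
    while i < n:
        if included[i]:
            j = i
            while j + 1 < n and included[j + 1]:
                j += 1
            seg_mass = float(p[i : j + 1].sum())
            younger = math.floor(d.grid[i] / round_to) * round_to
            older = math.ceil(d.grid[j] / round_to) * round_to
            ranges.append((float(older), float(younger), seg_mass))
            i = j + 1
        else:
            i += 1
    # report oldest range first, OxCal-style
    ranges.sort(key=lambda r: -r[0])
    return tuple(ranges)


# ---------------------------------------------------------------------------
# one-phase t-type outlier model

def _shift_prior_density(s_grid: np.ndarray, nu: int = 5, u_max: float = 4.0) -> np.ndarray:
    """Marginal density of the outlier shift s = t * 10^u, t ~ Student-t(nu),
    u ~ Uniform(0, u_max), evaluated on ``s_grid`` (14C years)."""
    u = np.linspace(0.0, u_max, 161)
    scale = 10.0**u
    dens = stats.t.pdf(s_grid[:, None] / scale[None, :], df=nu) / scale[None, :]
    return np.trapezoid(dens, u, axis=1) / u_max


def _outlier_kernel(var: float, nu: int = 5, u_max: float = 4.0,
                    r_max: float = 80_000.0, r_step: float = 25.0):
    """log of m(r) = integral N(r; s, var) p(s) ds on a residual grid.

    This is the marginal likelihood contribution of an active outlier with
    measurement residual r (14C yr). Returned as (r_grid, log_m) for
    interpolation inside the sampler.
    """
    half = np.geomspace(1.0, 60_000.0, 400)
    s_grid = np.concatenate([-half[::-1], [0.0], half])
    p_s = _shift_prior_density(s_grid, nu=nu, u_max=u_max)
    w = np.gradient(s_grid) * p_s
    r_grid = np.arange(-r_max, r_max + r_step, r_step)
    # direct convolution: (n_r, n_s) Gaussian matrix against prior weights
    gauss = np.exp(-0.5 * (r_grid[:, None] - s_grid[None, :]) ** 2 / var)
    m = gauss @ w / math.sqrt(2.0 * math.pi * var)
    return r_grid, np.log(np.clip(m, 1e-300, None))


def phase_outlier_model(
    dates: Sequence[RadiocarbonAge],
    curve: CalCurve,
    prior_outlier: Sequence[float] | float = 0.05,
    iterations: int = 50_000,
    burn_in: int = 10_000,
    seed: int = 0,
    thin: int = 1,
) -> PhaseModelResult:
    """One-phase uniform model with per-date t-type outlier shifts.

    Each date's calendar age theta_i is uniform within unknown phase
    boundaries (start older than end). With its prior probability each
    date is an outlier, in which case its measurement is displaced in
    14C-age space by a shift drawn from Student-t(nu=5) scaled by 10^u,
    u ~ Uniform(0, 4) years. The outlier indicator and shift are
    marginalized analytically (the shifted likelihood is a fixed
    convolution of the Gaussian with the shift prior, precomputed on a
    residual grid), so the sampler only moves the calendar ages
    (vectorized random-walk Metropolis) and the boundaries (exact Gibbs
    under the uniform-phase prior). Posterior outlier probabilities are
    Rao-Blackwellized over the kept draws. Deterministic under ``seed``.
    """
    n = len(dates)
    if n < 2:
        raise ValidationError("phase model needs >= 2 dates")
    priors = np.full(n, prior_outlier, dtype=float) if np.isscalar(prior_outlier) else np.asarray(
        prior_outlier, dtype=float
    )
    if len(priors) != n or np.any((priors < 0) | (priors > 1)):
        raise ValidationError("prior outlier probabilities must be in [0, 1] per date")
    if iterations <= burn_in:
        raise ValidationError("iterations must exceed burn_in")

    rng = np.random.default_rng(seed)
    x = np.array([d.age_bp for d in dates])
    sig = np.array([d.sigma for d in dates])

    cal_lo, cal_hi = float(curve.cal_bp.min()), float(curve.cal_bp.max())

    # Outlier kernels: the curve error varies slowly, so each date's kernel
    # uses its measurement variance plus the median curve variance; the
    # non-outlier Gaussian term keeps the exact theta-dependent variance.
    med_cvar = float(np.median(curve.err)) ** 2
    kernels = [_outlier_kernel(s**2 + med_cvar) for s in sig]

    log_q = np.log(np.clip(priors, 1e-300, None))
    log_1mq = np.log(np.clip(1.0 - priors, 1e-300, None))

    def log_components(theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Per-date log of the non-outlier and outlier likelihood terms."""
        mu, sc = curve.interp(theta)
        var = sig**2 + sc**2
        r = x - mu
        ll_gauss = -0.5 * r**2 / var - 0.5 * np.log(2.0 * math.pi * var)
        ll_out = np.array(
            [np.interp(r[i], kernels[i][0], kernels[i][1]) for i in range(n)]
        )
        return ll_gauss, ll_out

    def loglik(theta: np.ndarray) -> np.ndarray:
        lg, lo = log_components(theta)
        return np.logaddexp(log_1mq + lg, log_q + lo)

    # initialize calendar ages at the curve point closest to each measurement
    theta = np.empty(n)
    for i in range(n):
        theta[i] = curve.cal_bp[np.argmin(np.abs(curve.c14_bp - x[i]))]
    start = theta.max() + 10.0
    end = theta.min() - 10.0
    step = np.maximum(2.0 * sig, 20.0)

    keep = (iterations - burn_in) // thin
    start_draws = np.empty(keep)
    end_draws = np.empty(keep)
    theta_draws = np.empty((keep, n))
    o_sum = np.zeros(n)
    kept = 0

    ll = loglik(theta)
    for it in range(iterations):
        # --- boundaries: exact Gibbs under p(start,end) ~ 1, theta uniform in phase
        a = theta.max()
        b = theta.min()
        start = end + (a - end) * rng.random() ** (-1.0 / (n - 1))
        end = start - (start - b) * rng.random() ** (-1.0 / (n - 1))

        # --- calendar ages: vectorized random-walk Metropolis; an occasional
        # large proposal lets a date jump between the phase interior and a
        # position explained by an outlier shift
        scale = np.where(rng.random(n) < 0.1, 20.0, 1.0)
        prop = theta + rng.normal(0.0, step * scale)
        inside = (prop >= max(end, cal_lo)) & (prop <= min(start, cal_hi))
        ll_prop = loglik(prop)
        accept = inside & (np.log(rng.random(n)) < (ll_prop - ll))
        theta = np.where(accept, prop, theta)
        ll = np.where(accept, ll_prop, ll)

        if it >= burn_in and (it - burn_in) % thin == 0 and kept < keep:
            start_draws[kept] = start
            end_draws[kept] = end
            theta_draws[kept] = theta
            lg, lo = log_components(theta)
            # P(outlier | theta, data), averaged over the chain
            o_sum += np.exp(
                log_q + lo - np.logaddexp(log_1mq + lg, log_q + lo)
            )
            kept += 1

    outlier_prob = np.where(priors >= 1.0, 1.0, np.where(priors <= 0.0, 0.0, o_sum / kept))
    return PhaseModelResult(
        start_draws=start_draws[:kept],
        end_draws=end_draws[:kept],
        span_draws=start_draws[:kept] - end_draws[:kept],
        outlier_prob=outlier_prob,
        theta_draws=theta_draws[:kept],
        lab_ids=tuple(d.lab_id for d in dates),
    )


def sample_hpd_interval(draws: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ``mass`` of the sampled values."""
    if not 0.0 < mass < 1.0:
        raise ValidationError("mass must be in (0, 1)")
    srt = np.sort(np.asarray(draws))
    n = len(srt)
    k = max(1, int(math.ceil(mass * n)))
    if k >= n:
        return float(srt[0]), float(srt[-1])
    widths = srt[k:] - srt[: n - k]
    i = int(np.argmin(widths))
    return float(srt[i]), float(srt[i + k])
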