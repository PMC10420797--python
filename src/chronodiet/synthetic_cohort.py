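"""Synthetic item-level cohorts with known ("latent") truth.

The generator emulates the reference marginal distributions and
standardized effects of a cross-sectional adolescent/young-adult cohort
(n = 1277, 72.8% female, three cities, regular/remote study modes) so the
full scoring-and-analysis pipeline can be exercised end to end and its
parameter recovery audited, without any real data.

Structure
---------
Demographics are drawn from configured category proportions.  Age is a
two-component uniform mixture (school 16-16.7 / university 24.3-25 years)
solved to match the target mean 19.91 and SD 4.11 — a single smooth law
on 16-25 cannot reach that SD.  Daily melatonin intake is log-normal via
FMT1_day ~ N(7.01, 1.13); the dinner share of intake has a Beta marginal
whose log-moments are solved exactly (digamma/trigamma) from the
configured FMT1_dinner mean/SD, coupled to FMT1_day through a Gaussian
copula calibrated by quadrature.  Each outcome is linear-Gaussian in the
standardized predictors,

    y = mean + sd * (sum_j beta_j z_j + sqrt(1 - sum beta_j^2) * eps),

with the configured standardized coefficients; predictors are mutually
independent by construction, so the residual scale is exact and an
infeasible coefficient set (sum beta^2 >= 1) is rejected at config time.

``items_from_targets`` inverts the instrument scoring: it builds sleep
schedules (5-minute grid), PSQI items, ZSDS items and FFQ responses whose
scores recover the latent targets exactly (PSQI, ZSDS) or within the
instrument quantum (5 min for MCTQ times; one frequency-category /
quarter-serving step for FMT).  Latent targets are first clipped into
each instrument's representable range and the *clipped* values are
stored as the truth to recover.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .fmt_ffq import FREQUENCY_PER_DAY, SERVINGS_OPTIONS, load_product_table
from .questionnaire_scoring import ZSDS_REVERSE_ITEMS

# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

#: outcome -> (marginal mean, marginal SD, {predictor: standardized beta})
DEFAULT_OUTCOME_EQUATIONS: dict[str, tuple[float, float, dict[str, float]]] = {
    "whtrc": (0.42, 0.06, {"agec": 0.180, "sex": 0.144, "fmt1_day": -0.082}),
    "msf_sc": (4.65, 1.52, {"agec": -0.091, "fmt1_day": -0.088}),
    "sjl": (1.21, 1.26, {"agec": -0.084, "fmt1_day": -0.068}),
    "sld": (7.09, 1.39, {}),
    "sle": (87.36, 9.00, {}),
    "psqi": (6.31, 2.80, {"sex": -0.183, "fmt1_day": -0.056}),
    "zsdsi": (47.36, 12.25, {"sex": -0.232, "fmt1_day": -0.111}),
    "gpa": (4.30, 0.51, {}),
}


@dataclass
class GeneratorConfig:
    n: int = 1277
    seed: int = 0
    sex_female_prop: float = 0.7283
    city_props: tuple[float, float, float] = (0.2192, 0.2060, 0.5748)
    mode_props: tuple[float, float] = (0.7267, 0.2733)
    # age mixture: school U(16, 16+age_width) vs university U(25-age_width, 25)
    age_school_prop: float = 0.5710843373493976
    age_width: float = 0.7
    fmt1_day_mean: float = 7.01
    fmt1_day_sd: float = 1.13
    fmt1_dinner_mean: float = 5.68
    fmt1_dinner_sd: float = 1.50
    day_dinner_corr: float = 0.8
    bmi_mean: float = 21.72
    bmi_sd: float = 3.68
    height_mean: tuple[float, float] = (1.65, 1.78)  # (female, male)
    height_sd: tuple[float, float] = (0.06, 0.07)
    outcome_equations: dict[str, tuple[float, float, dict[str, float]]] = field(
        default_factory=lambda: {
            k: (m, s, dict(b)) for k, (m, s, b) in DEFAULT_OUTCOME_EQUATIONS.items()
        }
    )
    ffq_products: tuple[str, ...] = ("cherry", "walnut", "oats")
    free_days: int = 2

    def without_fmt_effects(self) -> "GeneratorConfig":
        """Copy of the config with every FMT coefficient set to zero
        (null-calibration runs)."""
        eqs = {
            k: (m, s, {p: (0.0 if p.startswith("fmt") else b) for p, b in bs.items()})
            for k, (m, s, bs) in self.outcome_equations.items()
        }
        return replace(self, outcome_equations=eqs)


class _Plan:
    """Derived, validated quantities: predictor population moments, the
    Beta law of the dinner share and the copula correlation."""

    def __init__(self, cfg: GeneratorConfig):
        for name, props in (("city_props", cfg.city_props),
                            ("mode_props", cfg.mode_props)):
            p = np.asarray(props, dtype=float)
            if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-6:
                raise ValueError(f"{name} must be non-negative and sum to 1")
        if not 0 < cfg.sex_female_prop < 1:
            raise ValueError("sex_female_prop must lie in (0, 1)")

        # exact moments of agec = exp(-age) under the uniform mixture
        p, w = cfg.age_school_prop, cfg.age_width
        lo1, hi1 = 16.0, 16.0 + w
        lo2, hi2 = 25.0 - w, 25.0
        m1 = p * _exp_neg_mom(lo1, hi1, 1) + (1 - p) * _exp_neg_mom(lo2, hi2, 1)
        m2 = p * _exp_neg_mom(lo1, hi1, 2) + (1 - p) * _exp_neg_mom(lo2, hi2, 2)
        self.agec_mean = m1
        self.agec_sd = math.sqrt(m2 - m1 * m1)
        self.age_bounds = (lo1, hi1, lo2, hi2)

        pf = cfg.sex_female_prop
        self.sex_mean = 2.0 - pf
        self.sex_sd = math.sqrt(pf * (1.0 - pf))

        for name, (mean, sd, betas) in cfg.outcome_equations.items():
            ss = sum(b * b for b in betas.values())
            if ss >= 1.0:
                raise ValueError(
                    f"outcome {name!r}: sum of squared betas {ss:.3f} >= 1 "
                    "leaves no residual variance"
                )
            unknown = set(betas) - {"agec", "sex", "fmt1_day", "fmt1_dinner"}
            if unknown:
                raise ValueError(f"outcome {name!r}: unknown predictors {unknown}")

        # dinner share: Beta law matched to the implied log-share moments
        mu_ls = cfg.fmt1_dinner_mean - cfg.fmt1_day_mean
        cov_ds = (
            cfg.day_dinner_corr * cfg.fmt1_day_sd * cfg.fmt1_dinner_sd
            - cfg.fmt1_day_sd**2
        )
        var_ls = cfg.fmt1_dinner_sd**2 - cfg.fmt1_day_sd**2 - 2.0 * cov_ds
        if mu_ls >= 0 or var_ls <= 0:
            raise ValueError(
                "infeasible FMT1 day/dinner configuration: log dinner share "
                "needs negative mean and positive variance"
            )
        self.share_alpha, self.share_beta = _solve_beta_log_moments(mu_ls, var_ls)
        corr_day_ls = cov_ds / (cfg.fmt1_day_sd * math.sqrt(var_ls))
        L = _normal_score_corr(self.share_alpha, self.share_beta)
        rho = corr_day_ls / L
        if abs(rho) > 1:
            raise ValueError(
                "day_dinner_corr is not attainable with the configured marginals"
            )
        self.share_copula_rho = rho

        sigma = math.sqrt(math.log(1.0 + (cfg.bmi_sd / cfg.bmi_mean) ** 2))
        self.bmi_log_mu = math.log(cfg.bmi_mean) - sigma**2 / 2.0
        self.bmi_log_sigma = sigma


def _exp_neg_mom(a: float, b: float, k: int) -> float:
    """E[exp(-k X)] for X ~ Uniform(a, b)."""
    return (math.exp(-k * a) - math.exp(-k * b)) / (k * (b - a))


def _solve_beta_log_moments(mu: float, var: float) -> tuple[float, float]:
    """(alpha, beta) of a Beta law with E[ln X] = mu, Var[ln X] = var,
    using the digamma/trigamma expressions of the log-moments."""

    def eqs(logab):
        a, b = np.exp(logab)
        return [
            special.digamma(a) - special.digamma(a + b) - mu,
            special.polygamma(1, a) - special.polygamma(1, a + b) - var,
        ]

    sol, info, ier, msg = optimize.fsolve(
        eqs, x0=np.log([1.5, 4.0]), full_output=True
    )
    if ier != 1 or np.max(np.abs(info["fvec"])) > 1e-9:
        raise ValueError(f"could not match Beta log-moments: {msg}")
    a, b = np.exp(sol)
    return float(a), float(b)


def _normal_score_corr(alpha: float, beta: float, order: int = 200) -> float:
    """Corr(Z, ln Beta^{-1}(Phi(Z))) by Gauss-Hermite quadrature; the
    copula correlation is rescaled by this factor so the configured
    *linear* day/log-share correlation is achieved."""
    x, w = np.polynomial.hermite.hermgauss(order)
    z = math.sqrt(2.0) * x
    wt = w / math.sqrt(math.pi)
    u = np.clip(stats.norm.cdf(z), 1e-15, 1 - 1e-15)
    g = np.log(stats.beta.ppf(u, alpha, beta))
    eg = float(np.sum(wt * g))
    vg = float(np.sum(wt * (g - eg) ** 2))
    ezg = float(np.sum(wt * z * g))
    return ezg / math.sqrt(vg)


# --------------------------------------------------------------------------
# latent cohort
# --------------------------------------------------------------------------


@dataclass
class SyntheticCohort:
    participants: pd.DataFrame  # item-level records, one row per person
    ffq: pd.DataFrame           # long-format FFQ responses
    latent: pd.DataFrame        # targets and latent continuous variables
    config: GeneratorConfig


def generate_latent(
    config: GeneratorConfig, rng: Optional[np.random.Generator] = None
) -> pd.DataFrame:
    """Latent continuous cohort: demographics, exposures and outcomes
    drawn from the configured linear-Gaussian system (no items yet)."""
    plan = _Plan(config)
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = config.n

    sex = np.where(rng.random(n) < config.sex_female_prop, 1, 2)
    city = rng.choice([1, 2, 3], size=n, p=config.city_props)
    mode = rng.choice([1, 2], size=n, p=config.mode_props)
    lo1, hi1, lo2, hi2 = plan.age_bounds
    school = rng.random(n) < config.age_school_prop
    age = np.where(
        school, rng.uniform(lo1, hi1, n), rng.uniform(lo2, hi2, n)
    )
    agec = np.exp(-age)

    z_day = rng.standard_normal(n)
    fmt1_day = config.fmt1_day_mean + config.fmt1_day_sd * z_day
    rho = plan.share_copula_rho
    u = stats.norm.cdf(rho * z_day + math.sqrt(1 - rho**2) * rng.standard_normal(n))
    share = stats.beta.ppf(
        np.clip(u, 1e-12, 1 - 1e-12), plan.share_alpha, plan.share_beta
    )
    fmt1_dinner = fmt1_day + np.log(share)

    z = {
        "agec": (agec - plan.agec_mean) / plan.agec_sd,
        "sex": (sex - plan.sex_mean) / plan.sex_sd,
        "fmt1_day": z_day,
        "fmt1_dinner": (fmt1_dinner - config.fmt1_dinner_mean)
        / config.fmt1_dinner_sd,
    }

    out = {
        "participant_id": np.arange(1, n + 1),
        "sex": sex, "city": city, "mode": mode, "age": age, "agec": agec,
        "fmt1_day": fmt1_day, "fmt_day": np.exp(fmt1_day),
        "fmt1_dinner": fmt1_dinner, "fmt_dinner": np.exp(fmt1_dinner),
        "dinner_share": share,
    }
    for name, (mean, sd, betas) in config.outcome_equations.items():
        lin = np.zeros(n)
        ss = 0.0
        for pred, b in betas.items():
            lin += b * z[pred]
            ss += b * b
        eps = rng.standard_normal(n)
        out[name] = mean + sd * (lin + math.sqrt(1.0 - ss) * eps)

    bmi = np.exp(plan.bmi_log_mu + plan.bmi_log_sigma * rng.standard_normal(n))
    height = np.where(
        sex == 1,
        config.height_mean[0] + config.height_sd[0] * rng.standard_normal(n),
        config.height_mean[1] + config.height_sd[1] * rng.standard_normal(n),
    )
    height = np.clip(height, 1.40, 2.10)
    out["bmi"] = bmi
    out["height_m"] = height
    out["weight_kg"] = bmi * height**2
    out["waist_cm"] = np.clip(out["whtrc"], 0.30, 0.80) * height * 100.0
    return pd.DataFrame(out)


# --------------------------------------------------------------------------
# inverse scoring: items from targets
# --------------------------------------------------------------------------

_FREQ_LABELS = [k for k in FREQUENCY_PER_DAY if k != "never"]
_FREQ_RATES = np.array([FREQUENCY_PER_DAY[k] for k in _FREQ_LABELS])
_SERVINGS = np.array(SERVINGS_OPTIONS)

# the 42-point occasions x servings grid, log-sorted, with option indices
_GRID_VALS = (_FREQ_RATES[:, None] * _SERVINGS[None, :]).ravel()
_GRID_ORDER = np.argsort(_GRID_VALS, kind="stable")
_GRID_SORTED = _GRID_VALS[_GRID_ORDER]
_GRID_FREQ_IDX = (np.arange(_GRID_VALS.size) // _SERVINGS.size)[_GRID_ORDER]
_GRID_SERV_IDX = (np.arange(_GRID_VALS.size) % _SERVINGS.size)[_GRID_ORDER]

#: largest half-gap (nats) between adjacent grid points: the log-scale
#: quantization quantum of the FFQ instrument.
FFQ_LOG_QUANTUM = float(np.max(np.diff(np.log(_GRID_SORTED))) / 2.0)


def _nearest_grid(rates: np.ndarray) -> np.ndarray:
    """Index into the sorted grid of the log-nearest achievable rate."""
    lr = np.log(np.clip(rates, _GRID_SORTED[0], _GRID_SORTED[-1]))
    lg = np.log(_GRID_SORTED)
    j = np.searchsorted(lg, lr).clip(1, lg.size - 1)
    left_closer = (lr - lg[j - 1]) <= (lg[j] - lr)
    return np.where(left_closer, j - 1, j)


def _quantize_clock(t: np.ndarray) -> np.ndarray:
    """Round decimal hours to the 5-minute grid."""
    return np.round(t * 12.0) / 12.0


def items_from_targets(
    latent: pd.DataFrame,
    config: GeneratorConfig,
    products: Optional[dict] = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Construct item-level records whose scores recover the targets.

    Returns (participants, ffq_long, targets).  Targets outside the
    instrument-representable ranges raise a ``ValueError`` naming the
    instrument; use :func:`clip_targets` first when feeding raw latent
    draws.  The ``targets`` frame holds the values the scoring pipeline
    should reproduce (exactly for PSQI/ZSDS; to 5 minutes for MCTQ; to
    one log-grid / quarter-serving quantum for FMT).
    """
    n = len(latent)
    tgt = pd.DataFrame({"participant_id": latent["participant_id"].to_numpy()})

    # ---- MCTQ: equal work/free durations, phase offset carries SJL ----
    msf_sc = latent["msf_sc"].to_numpy(dtype=float)
    sjl = latent["sjl"].to_numpy(dtype=float)
    sld = latent["sld"].to_numpy(dtype=float)
    sle = latent["sle"].to_numpy(dtype=float)
    if np.any((msf_sc < 1.0) | (msf_sc > 11.0)):
        raise ValueError("MCTQ: chronotype target outside 1-11 h")
    if np.any((sld < 3.5) | (sld > 13.0)):
        raise ValueError("MCTQ: sleep duration target outside 3.5-13 h")
    if np.any((sjl < -5.0) | (sjl > 7.0)):
        raise ValueError("MCTQ: social jetlag target outside -5..7 h")

    msf_u = 24.0 + msf_sc  # SlD_F == SlD, so no sleep-debt correction applies
    onset_f = _quantize_clock(msf_u - sld / 2.0)
    wake_f = _quantize_clock(msf_u + sld / 2.0)
    onset_w = _quantize_clock(msf_u - sjl - sld / 2.0)
    wake_w = _quantize_clock(msf_u - sjl + sld / 2.0)
    # target ranges above guarantee every time lies on the 0-48 axis
    assert float(min(onset_w.min(), onset_f.min())) >= 0.0
    assert float(max(wake_w.max(), wake_f.max())) < 48.0
    sle_c = np.clip(sle, 55.0, 135.0)
    tib = _quantize_clock(sld / (sle_c / 100.0))

    participants = pd.DataFrame(
        {
            "participant_id": latent["participant_id"].to_numpy(),
            "sex": latent["sex"].to_numpy(),
            "age": latent["age"].to_numpy(),
            "city": latent["city"].to_numpy(),
            "mode": latent["mode"].to_numpy(),
            "height_m": latent["height_m"].to_numpy(),
            "weight_kg": latent["weight_kg"].to_numpy(),
            "waist_cm": latent["waist_cm"].to_numpy(),
            "gpa": np.clip(np.round(latent["gpa"].to_numpy()), 2, 5),
            "onset_work": onset_w % 48.0,
            "wake_work": wake_w % 48.0,
            "onset_free": onset_f % 48.0,
            "wake_free": wake_f % 48.0,
            "free_days": config.free_days,
            "alarm_free": False,
            "tib_work": tib,
            "tib_free": tib,
        }
    )
    # recover targets at instrument precision
    tgt["msf_sc"] = (onset_f + (wake_f - onset_f) / 2.0) % 24.0
    tgt["sjl"] = (onset_f + (wake_f - onset_f) / 2.0) - (
        onset_w + (wake_w - onset_w) / 2.0
    )
    tgt["sld"] = wake_f - onset_f
    tgt["msf_sc_latent"] = msf_sc
    tgt["sjl_latent"] = sjl
    tgt["sld_latent"] = sld

    # ---- PSQI: distribute the global target over the seven components ----
    psqi_t = latent["psqi"].to_numpy(dtype=float)
    psqi_t = np.round(psqi_t).astype(int)
    if np.any((psqi_t < 0) | (psqi_t > 21)):
        raise ValueError("PSQI: global target outside 0-21")
    comps = np.clip(psqi_t[:, None] - 3 * np.arange(7)[None, :], 0, 3)
    c1, c2, c3, c4, c5, c6, c7 = comps.T
    lat_by_c2 = np.array([10.0, 20.0, 45.0, 90.0])
    t30_by_c2 = np.array([0, 0, 1, 3])
    hours_by_c3 = np.array([8.0, 6.5, 5.5, 4.0])
    eff_by_c4 = np.array([0.90, 0.80, 0.70, 0.55])
    dsum_by_c5 = np.array([0, 1, 10, 19])
    sleepy_by_c7 = np.array([0, 1, 2, 3])
    enth_by_c7 = np.array([0, 0, 1, 3])

    hours = hours_by_c3[c3]
    tib_psqi = hours / eff_by_c4[c4]
    participants["psqi_bedtime"] = 23.0
    participants["psqi_latency_min"] = lat_by_c2[c2]
    participants["psqi_wake"] = (23.0 + tib_psqi) % 24.0
    participants["psqi_hours"] = hours
    participants["psqi_trouble"] = t30_by_c2[c2]
    dsum = dsum_by_c5[c5]
    for i in range(9):
        participants[f"psqi_dist{i + 1}"] = np.clip(dsum - 3 * i, 0, 3)
    participants["psqi_quality"] = c1
    participants["psqi_med"] = c6
    participants["psqi_sleepy"] = sleepy_by_c7[c7]
    participants["psqi_enth"] = enth_by_c7[c7]
    tgt["psqi"] = psqi_t

    # ---- ZSDS: keyed scores summing to the raw target ----
    zsdsi_t = latent["zsdsi"].to_numpy(dtype=float)
    raw_t = np.clip(np.round(zsdsi_t / 1.25), 20, 80).astype(int)
    keyed = 1 + np.clip((raw_t - 20)[:, None] - 3 * np.arange(20)[None, :], 0, 3)
    answers = keyed.copy()
    ridx = np.asarray(ZSDS_REVERSE_ITEMS) - 1
    answers[:, ridx] = 5 - answers[:, ridx]
    for i in range(20):
        participants[f"zsds_{i + 1}"] = answers[:, i]
    tgt["zsds_raw"] = raw_t
    tgt["zsdsi"] = raw_t * 1.25
    tgt["gpa"] = np.clip(np.round(latent["gpa"].to_numpy()), 2, 5)

    # ---- FFQ: intake split over products proportional to their serving
    # melatonin content, one shared frequency/servings choice ----
    products = products or load_product_table()
    ks = np.array([products[p].ng_per_serving for p in config.ffq_products])
    k_total = ks.sum()
    fmt_day_t = latent["fmt_day"].to_numpy(dtype=float)
    share_t = latent["dinner_share"].to_numpy(dtype=float)
    if np.any(fmt_day_t < 0):
        raise ValueError("FFQ: negative daily intake target")
    if np.any((share_t < 0) | (share_t > 1)):
        raise ValueError("FFQ: dinner share target outside [0, 1]")
    rate_req = fmt_day_t / k_total
    gi = _nearest_grid(rate_req)
    freq = np.array(_FREQ_LABELS, dtype=object)[_GRID_FREQ_IDX[gi]]
    servings = _SERVINGS[_GRID_SERV_IDX[gi]]
    achieved_rate = _GRID_SORTED[gi]
    per_product = achieved_rate[:, None] * ks[None, :]  # (n, n_products)
    total = per_product.sum(axis=1)

    # greedy quarter-steps, largest product first, to hit the dinner share
    order = np.argsort(-ks)
    rem = share_t * total
    dps = np.zeros((n, ks.size))
    for j in order:
        a = per_product[:, j]
        dp = np.round(4.0 * np.clip(rem / a, 0.0, 1.0)) / 4.0
        dps[:, j] = dp
        rem = rem - dp * a

    ffq_rows = []
    pid = latent["participant_id"].to_numpy()
    for j, prod in enumerate(config.ffq_products):
        ffq_rows.append(
            pd.DataFrame(
                {
                    "participant_id": pid,
                    "product_id": prod,
                    "frequency_category": freq,
                    "servings": servings,
                    "dinner_percent": (dps[:, j] * 100).astype(int),
                }
            )
        )
    ffq = (
        pd.concat(ffq_rows, ignore_index=True)
        .sort_values(["participant_id", "product_id"], kind="stable")
        .reset_index(drop=True)
    )
    tgt["fmt_day"] = np.clip(
        fmt_day_t, _GRID_SORTED[0] * k_total, _GRID_SORTED[-1] * k_total
    )
    tgt["fmt_day_achieved"] = total
    tgt["dinner_share"] = share_t
    tgt["fmt_dinner_achieved"] = (dps * per_product).sum(axis=1)
    return participants, ffq, tgt


def generate_cohort(
    config: GeneratorConfig, rng: Optional[np.random.Generator] = None
) -> SyntheticCohort:
    """Full synthetic cohort: latent truth plus item-level records.

    Deterministic for a fixed seed (all randomness flows through one
    generator object; ``items_from_targets`` itself is deterministic).
    """
    latent = generate_latent(config, rng)
    clipped = clip_targets(latent)
    participants, ffq, tgt = items_from_targets(clipped, config)
    merged = latent.merge(
        tgt.add_prefix("target_").rename(
            columns={"target_participant_id": "participant_id"}
        ),
        on="participant_id",
    )
    return SyntheticCohort(participants, ffq, merged, config)


def clip_targets(latent: pd.DataFrame) -> pd.DataFrame:
    """Clip raw latent draws into the instrument-representable ranges
    (Gaussian tails exceed what bounded questionnaires can encode)."""
    out = latent.copy()
    out["msf_sc"] = out["msf_sc"].clip(1.0, 11.0)
    out["sjl"] = out["sjl"].clip(-5.0, 7.0)
    out["sld"] = out["sld"].clip(3.5, 13.0)
    out["psqi"] = out["psqi"].clip(0.0, 21.0)
    out["zsdsi"] = out["zsdsi"].clip(25.0, 100.0)
    out["gpa"] = out["gpa"].clip(2.0, 5.0)
    return out
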