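"""Instrument scoring for sleep-wake timing, sleep quality, depression and
anthropometry.

Four instruments are scored here:

* the Munich Chronotype Questionnaire (MCTQ): weekly sleep duration,
  sleep efficiency, mid-sleep on work and free days, the sleep-debt
  corrected free-day mid-sleep (MSF_sc, the chronotype phase marker) and
  social jetlag (SJL);
* the Pittsburgh Sleep Quality Index (PSQI): seven component scores and
  the 0-21 global score, with the conventional >5 poor-sleep flag;
* the Zung Self-Rating Depression Scale (ZSDS): 20-item raw sum (20-80)
  converted to the 25-100 index and banded into four severity levels;
* anthropometrics: BMI, sex/age-adjusted BMI percentile from an LMS
  growth reference, waist-to-height ratio and the WHtR >= 0.5 central
  adiposity flag.

Clock-time convention
---------------------
All clock times are decimal hours on an "unrolled" 0-48 h axis: a sleep
onset after midnight is encoded as 24 + h (e.g. 01:30 -> 25.5), which
removes midnight-crossing ambiguity.  Wake times given on the 0-24 dial
are unrolled automatically (24 h added whenever wake <= onset).
Mid-sleep points are reported modulo 24.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

#: Reverse-keyed (positively worded) ZSDS items, 1-based, per the standard
#: instrument key.  Overridable wherever a key set is accepted.
ZSDS_REVERSE_ITEMS: tuple[int, ...] = (2, 5, 6, 11, 12, 14, 16, 17, 18, 20)

#: BMI-percentile cut points for the four weight-status categories
#: (underweight / normal / overweight / obese).
BMI_CATEGORY_PERCENTILES: tuple[float, float, float] = (5.0, 85.0, 95.0)


@dataclass
class MctqConfig:
    """Switches for the scoring conventions the literature leaves open.

    sle_formula
        ``"standard"`` computes sleep efficiency as SlD / TiB x 100 (the
        conventional definition, consistent with efficiencies below 100%);
        ``"as_printed"`` computes TiB / SlD x 100.
    msfsc_correction
        ``"conditional"`` applies the sleep-debt correction
        MSF - 0.5 x (SlD_F - SlD) only when free-day sleep exceeds
        work-day sleep and no alarm is used on free days (the original
        MCTQ rule); ``"unconditional"`` always applies it.
    sjl_absolute
        Report |SJL| instead of the signed value (phase-advanced sleepers
        have negative signed SJL).
    """

    sle_formula: str = "standard"
    msfsc_correction: str = "conditional"
    sjl_absolute: bool = False

    def __post_init__(self) -> None:
        if self.sle_formula not in ("standard", "as_printed"):
            raise ValueError(f"unknown sle_formula: {self.sle_formula!r}")
        if self.msfsc_correction not in ("conditional", "unconditional"):
            raise ValueError(
                f"unknown msfsc_correction: {self.msfsc_correction!r}"
            )


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------


@dataclass
class SleepScheduleRaw:
    """One respondent's sleep timing answers.

    Times are decimal hours on the 0-48 h axis (>= 24 encodes after
    midnight); ``free_days_per_week`` is the number of work-free days
    (FD, 0-7); ``time_in_bed_*`` are durations in hours and may be left
    ``None`` when sleep efficiency is not needed.
    """

    onset_work: float
    wake_work: float
    onset_free: float
    wake_free: float
    free_days_per_week: int
    alarm_free_days: bool = False
    time_in_bed_work: Optional[float] = None
    time_in_bed_free: Optional[float] = None


@dataclass
class MctqDerived:
    sld_work: float
    sld_free: float
    sld: float
    sle: float  # percent; NaN when time in bed was not reported
    msw: float  # decimal hours after midnight
    msf: float
    msf_sc: float
    sjl: float


@dataclass
class PsqiResponse:
    """Scorable answers of the 19-item PSQI (bed-partner items excluded).

    ``bedtime``/``wake_time`` are decimal clock hours (0-48 axis),
    ``latency_minutes`` the usual minutes to fall asleep, ``hours_slept``
    the usual actual sleep hours.  ``trouble_30min`` is the "cannot get
    to sleep within 30 minutes" frequency item; ``disturbances`` the nine
    remaining disturbance frequency items; ``quality``, ``medication``,
    ``daytime_sleepy`` and ``daytime_enthusiasm`` are the usual 0-3 codes.
    """

    bedtime: float
    latency_minutes: float
    wake_time: float
    hours_slept: float
    trouble_30min: int
    disturbances: Sequence[int]
    quality: int
    medication: int
    daytime_sleepy: int
    daytime_enthusiasm: int


@dataclass
class PsqiScore:
    components: tuple[int, int, int, int, int, int, int]
    global_score: int
    quality_flag: int  # 1 iff global > 5 (poor sleep)


@dataclass
class ZsdsScore:
    raw: int          # 20-80, keyed sum
    index: float      # raw x 1.25, full precision
    index_rounded: int  # half-away-from-zero presentation value
    level: int        # 1..4 severity band
    level_flag: int   # 1 iff index >= 60 (moderate or worse)


@dataclass
class Anthropometrics:
    height_m: float
    weight_kg: float
    waist_cm: float
    age_years: float
    sex: str  # "female" | "male"
    bmi: float
    bmi_percentile: float
    bmi_category: int  # 1 underweight .. 4 obese
    whtr: float
    whtr_category: int  # 1: <0.40, 2: 0.40-0.49, 3: >=0.50
    central_adiposity_flag: int  # 1 iff whtr >= 0.5


# --------------------------------------------------------------------------
# MCTQ
# --------------------------------------------------------------------------


def _unroll_wake(onset: np.ndarray, wake: np.ndarray) -> np.ndarray:
    """Add 24 h to wake times given on the 0-24 dial that fall at or
    before the (possibly after-midnight) onset."""
    return np.where(wake <= onset, wake + 24.0, wake)


def mctq_from_arrays(
    onset_work,
    wake_work,
    onset_free,
    wake_free,
    free_days,
    alarm_free,
    tib_work=None,
    tib_free=None,
    config: MctqConfig | None = None,
) -> dict[str, np.ndarray]:
    """Vectorised MCTQ scoring over parallel arrays.

    Returns a dict of arrays: sld_work, sld_free, sld, sle, msw, msf,
    msf_sc, sjl.  Raises ``ValueError`` on invalid FD or non-positive
    sleep durations, naming the day type.
    """
    cfg = config or MctqConfig()
    ow = np.asarray(onset_work, dtype=float)
    ww = np.asarray(wake_work, dtype=float)
    of = np.asarray(onset_free, dtype=float)
    wf = np.asarray(wake_free, dtype=float)
    fd = np.asarray(free_days)
    alarm = np.asarray(alarm_free, dtype=bool)

    if np.any((fd < 0) | (fd > 7) | (fd != np.floor(fd))):
        raise ValueError("free_days_per_week must be an integer in 0..7")
    fd = fd.astype(float)
    for name, t in (("onset_work", ow), ("wake_work", ww),
                    ("onset_free", of), ("wake_free", wf)):
        if np.any((t < 0) | (t >= 48)):
            raise ValueError(f"{name} must lie in [0, 48) decimal hours")

    ww = _unroll_wake(ow, ww)
    wf = _unroll_wake(of, wf)
    sld_w = ww - ow
    sld_f = wf - of
    if np.any(sld_w <= 0):
        raise ValueError("non-positive sleep duration on work days")
    if np.any(sld_f <= 0):
        raise ValueError("non-positive sleep duration on free days")

    msw_u = ow + sld_w / 2.0  # unrolled mid-sleep points
    msf_u = of + sld_f / 2.0
    sld = (sld_w * (7.0 - fd) + sld_f * fd) / 7.0
    sjl = msf_u - msw_u
    if cfg.sjl_absolute:
        sjl = np.abs(sjl)

    msf = np.mod(msf_u, 24.0)
    msw = np.mod(msw_u, 24.0)

    correction = 0.5 * (sld_f - sld)
    if cfg.msfsc_correction == "conditional":
        apply = (sld_f > sld_w) & (~alarm)
        msf_sc = np.where(apply, msf - correction, msf)
    else:
        msf_sc = msf - correction

    if tib_work is None or tib_free is None:
        sle = np.full_like(sld, np.nan)
    else:
        tw = np.asarray(tib_work, dtype=float)
        tf = np.asarray(tib_free, dtype=float)
        if np.any(tw <= 0) or np.any(tf <= 0):
            raise ValueError("time in bed must be strictly positive")
        tib = (tw * (7.0 - fd) + tf * fd) / 7.0
        if cfg.sle_formula == "standard":
            sle = sld / tib * 100.0
        else:
            sle = tib / sld * 100.0

    return {
        "sld_work": sld_w, "sld_free": sld_f, "sld": sld, "sle": sle,
        "msw": msw, "msf": msf, "msf_sc": msf_sc, "sjl": sjl,
    }


def score_mctq(
    schedule: SleepScheduleRaw, config: MctqConfig | None = None
) -> MctqDerived:
    """Score one respondent's sleep schedule."""
    out = mctq_from_arrays(
        [schedule.onset_work], [schedule.wake_work],
        [schedule.onset_free], [schedule.wake_free],
        [schedule.free_days_per_week], [schedule.alarm_free_days],
        None if schedule.time_in_bed_work is None else [schedule.time_in_bed_work],
        None if schedule.time_in_bed_free is None else [schedule.time_in_bed_free],
        config,
    )
    return MctqDerived(**{k: float(v[0]) for k, v in out.items()})


# --------------------------------------------------------------------------
# PSQI
# --------------------------------------------------------------------------

_PSQI_ITEM_NAMES = (
    "bedtime", "latency_minutes", "wake_time", "hours_slept",
    "trouble_30min", "disturbances", "quality", "medication",
    "daytime_sleepy", "daytime_enthusiasm",
)


def _band(x: np.ndarray, edges: Sequence[float]) -> np.ndarray:
    """Score 0..len(edges) by counting how many (ascending) edges x exceeds."""
    out = np.zeros(np.shape(x), dtype=int)
    for e in edges:
        out += (np.asarray(x) > e).astype(int)
    return out


def psqi_components_from_arrays(
    bedtime, latency_minutes, wake_time, hours_slept, trouble_30min,
    disturbances, quality, medication, daytime_sleepy, daytime_enthusiasm,
) -> np.ndarray:
    """Vectorised PSQI component scoring -> (n, 7) integer array.

    Components follow the published scoring sheet: subjective quality,
    latency, duration, habitual efficiency, disturbances, medication use
    and daytime dysfunction, each 0-3.
    """
    bed = np.asarray(bedtime, float)
    lat = np.asarray(latency_minutes, float)
    wake = np.asarray(wake_time, float)
    hrs = np.asarray(hours_slept, float)
    t30 = np.asarray(trouble_30min, int)
    dist = np.asarray(disturbances, int)
    if dist.ndim == 1:
        dist = dist[None, :]
    qual = np.asarray(quality, int)
    med = np.asarray(medication, int)
    slpy = np.asarray(daytime_sleepy, int)
    enth = np.asarray(daytime_enthusiasm, int)

    if np.any(lat < 0):
        raise ValueError("latency_minutes must be >= 0")
    if np.any(hrs <= 0):
        raise ValueError("hours_slept must be > 0")
    for name, arr in (("trouble_30min", t30), ("disturbances", dist),
                      ("quality", qual), ("medication", med),
                      ("daytime_sleepy", slpy),
                      ("daytime_enthusiasm", enth)):
        if np.any((arr < 0) | (arr > 3)):
            raise ValueError(f"PSQI item {name!r} outside 0..3")
    if dist.shape[-1] != 9:
        raise ValueError("disturbances must have 9 items")

    c1 = qual
    lat_score = _band(lat, (15, 30, 60))
    c2 = np.ceil((lat_score + t30) / 2.0).astype(int)
    c3 = np.select([hrs > 7, hrs >= 6, hrs >= 5], [0, 1, 2], default=3)
    wake_u = _unroll_wake(bed, wake)
    tib = wake_u - bed
    eff = hrs / tib * 100.0
    c4 = np.select([eff >= 85, eff >= 75, eff >= 65], [0, 1, 2], default=3)
    dsum = dist.sum(axis=-1)
    c5 = np.select([dsum == 0, dsum <= 9, dsum <= 18], [0, 1, 2], default=3)
    c6 = med
    c7 = np.ceil((slpy + enth) / 2.0).astype(int)
    return np.stack(
        [np.broadcast_to(c, np.shape(c2)) for c in (c1, c2, c3, c4, c5, c6, c7)],
        axis=-1,
    ).astype(int)


def score_psqi(resp: PsqiResponse) -> PsqiScore:
    """Score one PSQI response; global score is the sum of the seven
    components and the quality flag marks global > 5 (poor sleep)."""
    for name in _PSQI_ITEM_NAMES:
        if getattr(resp, name) is None:
            raise ValueError(f"missing PSQI item: {name}")
    comps = psqi_components_from_arrays(
        [resp.bedtime], [resp.latency_minutes], [resp.wake_time],
        [resp.hours_slept], [resp.trouble_30min],
        np.asarray(resp.disturbances)[None, :], [resp.quality],
        [resp.medication], [resp.daytime_sleepy],
        [resp.daytime_enthusiasm],
    )[0]
    g = int(comps.sum())
    return PsqiScore(tuple(int(c) for c in comps), g, int(g > 5))


# --------------------------------------------------------------------------
# ZSDS
# --------------------------------------------------------------------------


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def zsds_raw_from_items(
    items, reverse_items: Sequence[int] = ZSDS_REVERSE_ITEMS
) -> np.ndarray:
    """Keyed raw sum (20-80) from (n, 20) answers coded 1-4; 1-based
    ``reverse_items`` are scored 5 - answer."""
    arr = np.asarray(items, dtype=int)
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.shape[-1] != 20:
        raise ValueError("ZSDS requires exactly 20 items")
    if np.any((arr < 1) | (arr > 4)):
        raise ValueError("ZSDS item codes must lie in 1..4")
    keyed = arr.copy()
    idx = np.asarray(reverse_items, dtype=int) - 1
    keyed[:, idx] = 5 - keyed[:, idx]
    return keyed.sum(axis=-1)


def zsds_level_from_index(index) -> np.ndarray:
    """Severity band 1..4 from the 25-100 index: <=50 none, 51-59 minimal
    to mild, 60-69 moderate to significant, >=70 severe to extreme."""
    ix = np.asarray(index, dtype=float)
    return np.select([ix <= 50, ix < 60, ix < 70], [1, 2, 3], default=4)


def score_zsds(
    items, reverse_items: Sequence[int] = ZSDS_REVERSE_ITEMS
) -> ZsdsScore:
    raw = int(zsds_raw_from_items(items, reverse_items)[0])
    index = raw * 1.25
    level = int(zsds_level_from_index(index))
    return ZsdsScore(
        raw=raw,
        index=index,
        index_rounded=_round_half_away(index),
        level=level,
        level_flag=int(index >= 60),
    )


# --------------------------------------------------------------------------
# anthropometrics
# --------------------------------------------------------------------------

_SEX_CODES = {"female": 1, "male": 2, 1: 1, 2: 2}


def load_lms_reference(path=None) -> pd.DataFrame:
    """Load an LMS BMI-for-age reference (columns: sex, age_months, L, M, S;
    sex coded 1 female / 2 male).  Without ``path`` the packaged synthetic
    reference is used — smooth curves in the range of published adolescent
    growth charts, shipped so the pipeline runs self-contained; substitute
    an official chart for real analyses."""
    if path is None:
        with resources.files("chronodiet.data").joinpath(
            "lms_bmi_synthetic.csv"
        ).open() as fh:
            ref = pd.read_csv(fh, comment="#")
    else:
        ref = pd.read_csv(path, comment="#")
    required = {"sex", "age_months", "L", "M", "S"}
    if not required.issubset(ref.columns):
        raise ValueError(f"LMS reference must have columns {sorted(required)}")
    return ref.sort_values(["sex", "age_months"]).reset_index(drop=True)


def bmi_percentile_from_arrays(
    bmi, age_years, sex_code, ref: pd.DataFrame,
    adult_uses_oldest: bool = True,
) -> np.ndarray:
    """BMI percentile via the LMS z-score, z = ((BMI/M)^L - 1) / (L S),
    mapped through the normal CDF.  Ages above the reference ceiling use
    the oldest column when ``adult_uses_oldest`` (growth charts end at 19
    but young-adult cohorts extend past it); ages below the floor raise."""
    bmi = np.asarray(bmi, dtype=float)
    age_m = np.asarray(age_years, dtype=float) * 12.0
    sex = np.asarray(sex_code)
    pct = np.empty_like(bmi)
    for code in (1, 2):
        sel = sex == code
        if not np.any(sel):
            continue
        sub = ref[ref["sex"] == code]
        if sub.empty:
            raise ValueError(f"LMS reference has no rows for sex code {code}")
        ages = sub["age_months"].to_numpy(dtype=float)
        if np.any(age_m[sel] < ages.min() - 6.0):
            raise ValueError(
                "age below LMS reference coverage; no extrapolation performed"
            )
        a = age_m[sel]
        if adult_uses_oldest:
            a = np.minimum(a, ages.max())
        elif np.any(a > ages.max() + 6.0):
            raise ValueError(
                "age above LMS reference coverage; no extrapolation performed"
            )
        idx = np.abs(a[:, None] - ages[None, :]).argmin(axis=1)
        L = sub["L"].to_numpy()[idx]
        M = sub["M"].to_numpy()[idx]
        S = sub["S"].to_numpy()[idx]
        with np.errstate(divide="ignore"):
            z = np.where(
                L != 0,
                ((bmi[sel] / M) ** L - 1.0) / (L * S),
                np.log(bmi[sel] / M) / S,
            )
        pct[sel] = norm.cdf(z) * 100.0
    return pct


def whtr_band(whtr) -> np.ndarray:
    """3-band WHtR code: 1 below 0.40, 2 for 0.40-0.49, 3 at or above 0.50."""
    w = np.asarray(whtr, dtype=float)
    return np.select([w < 0.40, w < 0.50], [1, 2], default=3)


def bmi_category_from_percentile(pct) -> np.ndarray:
    p = np.asarray(pct, dtype=float)
    lo, mid, hi = BMI_CATEGORY_PERCENTILES
    return np.select([p < lo, p < mid, p < hi], [1, 2, 3], default=4)


def score_anthropometrics(
    height_m: float,
    weight_kg: float,
    waist_cm: float,
    age_years: float,
    sex,
    ref: pd.DataFrame | None = None,
    adult_uses_oldest: bool = True,
) -> Anthropometrics:
    if min(height_m, weight_kg, waist_cm, age_years) <= 0:
        raise ValueError("height, weight, waist and age must be positive")
    code = _SEX_CODES.get(sex if not isinstance(sex, str) else sex.lower())
    if code is None:
        raise ValueError(f"unknown sex: {sex!r}")
    if ref is None:
        ref = load_lms_reference()
    bmi = weight_kg / height_m**2
    whtr = waist_cm / (height_m * 100.0)
    pct = float(
        bmi_percentile_from_arrays(
            [bmi], [age_years], [code], ref, adult_uses_oldest
        )[0]
    )
    return Anthropometrics(
        height_m=height_m,
        weight_kg=weight_kg,
        waist_cm=waist_cm,
        age_years=age_years,
        sex="female" if code == 1 else "male",
        bmi=bmi,
        bmi_percentile=pct,
        bmi_category=int(bmi_category_from_percentile([pct])[0]),
        whtr=whtr,
        whtr_category=int(whtr_band([whtr])[0]),
        central_adiposity_flag=int(whtr >= 0.5),
    )
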