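"""Analysis-ready cohort table: transforms and categorical codings.

Continuous variables that departed from normality in the source cohort
are carried in transformed form alongside the raw values: Agec =
1/exp(age) (stored at full precision; its magnitude for ages 16-25 is
~1e-11..1e-7, so reports may apply a display multiplier but model inputs
are never rescaled — standardized coefficients are scale-invariant),
FMT1 = ln(FMT), SlEc = sleep efficiency winsorized at 100, and WHtRc =
the continuous waist-to-height ratio.

Categorical codes (all integer):

==========  =====================================================
sex         1 female, 2 male
city        1 Syktyvkar, 2 Kirov, 3 Tyumen
mode        1 regular, 2 remote study
whtr_band   1: <0.40, 2: 0.40-0.49, 3: >=0.50
whtrc1      central adiposity, 1 iff WHtR >= 0.5
bmic        1 underweight .. 4 obese (BMI-percentile bands)
ovob        1 iff bmic in {3, 4}
slec_band   1: <80, 2: 80-89, 3: 90-99, 4: >=100
sjlc        1 iff SJL >= 1 h
psqic       1 iff PSQI global > 5 (poor sleep)
zsdsic      1 iff ZSDS index >= 60 (moderate or worse depression)
==========  =====================================================
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .questionnaire_scoring import bmi_category_from_percentile, whtr_band


def transform_age(age_years) -> np.ndarray:
    """Agec = 1/exp(age), a strictly decreasing normality-improving
    transform of age; rejects non-positive ages."""
    a = np.asarray(age_years, dtype=float)
    if np.any(a <= 0):
        raise ValueError("age must be positive")
    return np.exp(-a)


def slec_band(sle) -> np.ndarray:
    """4-band sleep-efficiency code with edges at 80, 90 and 100%."""
    s = np.asarray(sle, dtype=float)
    return np.select([s < 80, s < 90, s < 100], [1, 2, 3], default=4)


#: column -> (source column, rule description) for the JSON sidecar
COLUMN_DICTIONARY: dict[str, str] = {
    "agec": "1/exp(age), full precision",
    "whtrc": "continuous waist-to-height ratio (normality-improving form)",
    "slec": "sleep efficiency winsorized at 100%",
    "whtr_band": "1: <0.40, 2: 0.40-0.49, 3: >=0.50",
    "whtrc1": "1 iff WHtR >= 0.5 (central adiposity)",
    "bmic": "1 underweight, 2 normal, 3 overweight, 4 obese",
    "ovob": "1 iff bmic in {3,4}",
    "slec_band": "1: <80, 2: 80-89, 3: 90-99, 4: >=100",
    "sjlc": "1 iff SJL >= 1 h",
    "psqic": "1 iff PSQI > 5",
    "zsdsic": "1 iff ZSDSI >= 60",
}


def categorize(cohort: pd.DataFrame) -> pd.DataFrame:
    """Append all categorical codes to a scored cohort table.

    Required inputs per code are taken from the scored columns (whtr, sle,
    bmi_pct, sjl, psqi, zsdsi); a missing input column leaves its codes
    out, a NaN input yields a NaN code (pandas nullable ints).
    """
    out = cohort.copy()

    def _code(src: str, dst: str, fn) -> None:
        if src in out.columns:
            vals = out[src].to_numpy(dtype=float)
            codes = np.asarray(fn(vals), dtype=float)
            codes[~np.isfinite(vals)] = np.nan
            out[dst] = codes

    _code("whtr", "whtr_band", whtr_band)
    _code("whtr", "whtrc1", lambda w: (w >= 0.5).astype(int))
    _code("bmi_pct", "bmic", bmi_category_from_percentile)
    if "bmic" in out.columns:
        out["ovob"] = (out["bmic"] >= 3).astype(float)
    _code("sle", "slec_band", slec_band)
    _code("sjl", "sjlc", lambda s: (s >= 1.0).astype(int))
    _code("psqi", "psqic", lambda p: (p > 5).astype(int))
    _code("zsdsi", "zsdsic", lambda z: (z >= 60).astype(int))
    return out


def build_derived_cohort(scored: pd.DataFrame) -> pd.DataFrame:
    """Scored table -> analysis table: adds agec, whtrc, slec and all
    categorical codes; column order is fixed so repeated builds are
    byte-identical."""
    out = scored.copy()
    out["agec"] = transform_age(out["age"].to_numpy())
    if "whtr" in out.columns:
        out["whtrc"] = out["whtr"]
    if "sle" in out.columns:
        out["slec"] = np.minimum(out["sle"].to_numpy(dtype=float), 100.0)
    out = categorize(out)
    ordered = [c for c in _CANONICAL_ORDER if c in out.columns]
    rest = [c for c in out.columns if c not in ordered]
    return out[ordered + rest]


_CANONICAL_ORDER = [
    "participant_id", "sex", "age", "agec", "city", "mode", "gpa",
    "height_m", "weight_kg", "waist_cm", "bmi", "bmi_pct", "whtr", "whtrc",
    "whtr_band", "whtrc1", "bmic", "ovob",
    "sld_work", "sld_free", "sld", "sle", "slec", "slec_band",
    "msw", "msf", "msf_sc", "sjl", "sjlc",
    "psqi", "psqic", "zsds_raw", "zsdsi", "zsdsic",
    "fmt_day", "fmt_dinner", "fmt1_day", "fmt1_dinner",
]


def column_dictionary_json() -> str:
    return json.dumps(COLUMN_DICTIONARY, indent=2)
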