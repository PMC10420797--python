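"""Semi-quantitative dietary melatonin exposure from a food-frequency
questionnaire.

Each questionnaire item asks, for one melatonin-containing product, the
consumption frequency over the past month (eight closed categories),
servings per meal (0.5-5) and the percentage eaten at dinner (0-100 in
quarters).  With a product reference table giving serving mass (g) and
mean melatonin content (ng/g, or ng per serving), the daily intake for a
product is

    ng/day = occasions/day x servings x serving_mass x content

and the per-day / per-dinner totals (FMT_day, FMT_dinner, in ng) are the
sums over products, the dinner sum weighted by the dinner percentage.
Log-transformed totals FMT1 = ln(FMT) are carried alongside because the
raw totals are strongly right-skewed; zero totals yield missing logs,
never -inf.

The frequency categories are mapped to occasions/day by interval
midpoints (a month taken as 30.44 days, the open-ended top category
floored at 5/day); the mapping is exposed as ``FREQUENCY_PER_DAY`` so
alternative mappings stay auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

DAYS_PER_MONTH = 30.44

#: Occasions-per-day midpoint mapping for the closed frequency categories.
FREQUENCY_PER_DAY: dict[str, float] = {
    "never": 0.0,
    "1-2/month": 1.5 / DAYS_PER_MONTH,
    "3-4/month": 3.5 / DAYS_PER_MONTH,
    "2-3/week": 2.5 / 7.0,
    "4-6/week": 5.0 / 7.0,
    "1-2/day": 1.5,
    "3-4/day": 3.5,
    ">4/day": 5.0,
}

SERVINGS_OPTIONS = (0.5, 1.0, 2.0, 3.0, 4.0, 5.0)
DINNER_PERCENT_OPTIONS = (0, 25, 50, 75, 100)


@dataclass
class ProductReference:
    """One row of the melatonin product table."""

    product_id: str
    name: str
    serving_mass: float  # grams
    melatonin_content: float  # ng per gram unless units == "ng_per_serving"
    units: str = "ng_per_g"

    def __post_init__(self) -> None:
        if self.serving_mass <= 0:
            raise ValueError(f"{self.product_id}: serving_mass must be > 0")
        if self.melatonin_content < 0:
            raise ValueError(f"{self.product_id}: melatonin_content < 0")
        if self.units not in ("ng_per_g", "ng_per_serving"):
            raise ValueError(f"{self.product_id}: unknown units {self.units!r}")

    @property
    def ng_per_serving(self) -> float:
        if self.units == "ng_per_serving":
            return self.melatonin_content
        return self.serving_mass * self.melatonin_content


@dataclass
class FfqItemResponse:
    product_id: str
    frequency_category: str
    servings_per_meal: float
    dinner_percent: int

    def __post_init__(self) -> None:
        if self.frequency_category not in FREQUENCY_PER_DAY:
            raise ValueError(
                f"unknown frequency category {self.frequency_category!r}"
            )
        if self.servings_per_meal not in SERVINGS_OPTIONS:
            raise ValueError(
                f"servings_per_meal must be one of {SERVINGS_OPTIONS}"
            )
        if self.dinner_percent not in DINNER_PERCENT_OPTIONS:
            raise ValueError(
                f"dinner_percent must be one of {DINNER_PERCENT_OPTIONS}"
            )


@dataclass
class FmtExposure:
    per_product_day: dict[str, float]
    fmt_day: float
    fmt_dinner: float
    fmt1_day: Optional[float]      # ln(fmt_day); None when total is zero
    fmt1_dinner: Optional[float]   # ln(fmt_dinner); None when total is zero


def load_product_table(path=None) -> dict[str, ProductReference]:
    """Load a product reference table from CSV (columns product_id, name,
    serving_mass, melatonin_content[, units]).  The packaged default is an
    illustrative literature-informed table, not an authoritative source."""
    if path is None:
        with resources.files("chronodiet.data").joinpath(
            "products_default.csv"
        ).open() as fh:
            df = pd.read_csv(fh, comment="#")
    else:
        df = pd.read_csv(path, comment="#")
    out: dict[str, ProductReference] = {}
    for row in df.itertuples(index=False):
        ref = ProductReference(
            product_id=str(row.product_id),
            name=str(row.name),
            serving_mass=float(row.serving_mass),
            melatonin_content=float(row.melatonin_content),
            units=str(getattr(row, "units", "ng_per_g")),
        )
        if ref.product_id in out:
            raise ValueError(f"duplicate product_id {ref.product_id!r}")
        out[ref.product_id] = ref
    return out


def frequency_to_daily(
    frequency_category: str,
    mapping: Mapping[str, float] = FREQUENCY_PER_DAY,
) -> float:
    """Occasions per day for one closed frequency category."""
    try:
        return mapping[frequency_category]
    except KeyError:
        raise ValueError(
            f"unknown frequency category {frequency_category!r}"
        ) from None


def score_fmt(
    responses: Sequence[FfqItemResponse],
    products: Mapping[str, ProductReference],
    frequency_map: Mapping[str, float] = FREQUENCY_PER_DAY,
) -> FmtExposure:
    """Total melatonin intake per day and at dinner for one respondent."""
    per_product: dict[str, float] = {}
    dinner = 0.0
    for resp in responses:
        if resp.product_id not in products:
            raise KeyError(
                f"product {resp.product_id!r} not in the reference table"
            )
        prod = products[resp.product_id]
        rate = frequency_to_daily(resp.frequency_category, frequency_map)
        ng_day = rate * resp.servings_per_meal * prod.ng_per_serving
        per_product[resp.product_id] = per_product.get(resp.product_id, 0.0) + ng_day
        dinner += ng_day * resp.dinner_percent / 100.0
    total = float(sum(per_product.values()))
    return FmtExposure(
        per_product_day=per_product,
        fmt_day=total,
        fmt_dinner=float(dinner),
        fmt1_day=float(np.log(total)) if total > 0 else None,
        fmt1_dinner=float(np.log(dinner)) if dinner > 0 else None,
    )


def score_fmt_table(
    ffq: pd.DataFrame,
    products: Mapping[str, ProductReference],
    frequency_map: Mapping[str, float] = FREQUENCY_PER_DAY,
) -> pd.DataFrame:
    """Vectorised exposure scoring over a long-format FFQ table.

    ``ffq`` columns: participant_id, product_id, frequency_category,
    servings, dinner_percent.  Returns one row per participant with
    fmt_day, fmt_dinner, fmt1_day, fmt1_dinner (logs NaN when the
    corresponding total is zero).
    """
    missing = set(ffq["product_id"].unique()) - set(products)
    if missing:
        raise KeyError(
            f"products not in the reference table: {sorted(missing)}"
        )
    rate = ffq["frequency_category"].map(frequency_map)
    if rate.isna().any():
        bad = ffq.loc[rate.isna(), "frequency_category"].unique()
        raise ValueError(f"unknown frequency categories: {sorted(bad)}")
    ngs = ffq["product_id"].map({k: p.ng_per_serving for k, p in products.items()})
    day = rate.to_numpy() * ffq["servings"].to_numpy() * ngs.to_numpy()
    dinner = day * ffq["dinner_percent"].to_numpy() / 100.0
    agg = pd.DataFrame(
        {"participant_id": ffq["participant_id"], "fmt_day": day,
         "fmt_dinner": dinner}
    ).groupby("participant_id", sort=True).sum()
    with np.errstate(divide="ignore"):
        agg["fmt1_day"] = np.where(
            agg["fmt_day"] > 0, np.log(agg["fmt_day"]), np.nan
        )
        agg["fmt1_dinner"] = np.where(
            agg["fmt_dinner"] > 0, np.log(agg["fmt_dinner"]), np.nan
        )
    return agg.reset_index()


@dataclass
class TertileAssignment:
    codes: np.ndarray          # 1..3 per value
    boundaries: pd.DataFrame   # per-tertile n, min, max
    degenerate: bool           # True when quantiles coincide


def assign_tertiles(values) -> TertileAssignment:
    """Equal-frequency thirds of an exposure vector.

    Cut points sit at the empirical 1/3 and 2/3 quantiles taken as order
    statistics (ranks ceil(n/3) and ceil(2n/3)); ties at a cut point all
    fall in the lower tertile, so intervals are [low, high) half-open from
    above.  Fewer than 3 finite values is an error; fully tied input is
    flagged degenerate (everything in tertile 1).
    """
    v = np.asarray(values, dtype=float)
    finite = np.isfinite(v)
    if finite.sum() < 3:
        raise ValueError("tertile assignment needs at least 3 finite values")
    vf = v[finite]
    n = vf.size
    srt = np.sort(vf)
    b1 = srt[int(np.ceil(n / 3)) - 1]
    b2 = srt[int(np.ceil(2 * n / 3)) - 1]
    codes = np.full(v.shape, np.nan)
    codes[finite] = np.select([vf <= b1, vf <= b2], [1, 2], default=3)
    degenerate = b1 == b2
    rows = []
    for k in (1, 2, 3):
        sel = codes == k
        rows.append(
            {
                "tertile": k,
                "n": int(sel.sum()),
                "min": float(v[sel].min()) if sel.any() else np.nan,
                "max": float(v[sel].max()) if sel.any() else np.nan,
            }
        )
    return TertileAssignment(codes, pd.DataFrame(rows), bool(degenerate))
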