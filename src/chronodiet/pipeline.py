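"""Pipeline orchestration: simulate -> score -> derive -> analyze.

Each stage consumes and emits plain CSV tables so any stage can be run
on external data; a JSON manifest records the seed, row counts at every
stage (invited -> excluded -> analyzed) and exclusion reasons, and the
analyze stage renders a markdown report with four panels: tertile
descriptives of the melatonin exposures, ANCOVA tables for both exposure
tertiles, stepwise linear regression models and stepwise logistic
models.  Numbers are rendered at 2 decimals (3 for standardized
coefficients) so side-by-side comparison with published tables is
mechanical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import association_stats as stats_mod
from . import derived_variables as dv
from . import fmt_ffq, questionnaire_scoring as qs
from .synthetic_cohort import GeneratorConfig, generate_cohort

log = logging.getLogger("chronodiet")

LINEAR_OUTCOMES = ["bmi_pct", "whtrc", "msf_sc", "sjl", "sld", "slec",
                   "psqi", "zsdsi", "gpa"]
LOGISTIC_OUTCOMES = ["ovob", "whtrc1", "sjlc", "psqic", "zsdsic"]
ANCOVA_OUTCOMES = ["bmi_pct", "whtrc", "sld", "psqi", "msf_sc", "sjl",
                   "zsdsi", "gpa"]
BASE_CANDIDATES = ["agec", "sex", "city", "mode"]
ANCOVA_COVARIATES = ["agec", "sex", "city", "mode"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run; round-trips through YAML."""

    seed: int = 0
    outdir: str = "results"
    stages: tuple[str, ...] = ("simulate", "score", "derive", "analyze")
    n: int = 1277
    n_invited: int = 1455
    participants_path: Optional[str] = None  # used when not simulating
    ffq_path: Optional[str] = None
    products_path: Optional[str] = None
    lms_path: Optional[str] = None
    sle_formula: str = "standard"
    msfsc_correction: str = "conditional"
    sjl_absolute: bool = False
    entry_p: float = 0.05
    removal_p: float = 0.10
    vif_limit: float = 5.0
    strict_paper: bool = True

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["stages"] = list(d["stages"])
        Path(path).write_text(yaml.safe_dump(d))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)


# --------------------------------------------------------------------------
# stages
# --------------------------------------------------------------------------

_SCORING_REQUIRED = [
    "participant_id", "sex", "age", "height_m", "weight_kg", "waist_cm",
    "onset_work", "wake_work", "onset_free", "wake_free", "free_days",
    "psqi_bedtime", "psqi_latency_min", "psqi_wake", "psqi_hours",
]


def score_participants(
    participants: pd.DataFrame,
    ffq: pd.DataFrame,
    products=None,
    lms_ref: pd.DataFrame | None = None,
    mctq_config: qs.MctqConfig | None = None,
) -> tuple[pd.DataFrame, int]:
    """Score all instruments for a cohort table; returns (scored table,
    number of rows dropped for missing scorable items)."""
    df = participants.copy()
    zsds_cols = [f"zsds_{i}" for i in range(1, 21)]
    psqi_item_cols = (
        ["psqi_trouble", "psqi_quality", "psqi_med", "psqi_sleepy", "psqi_enth"]
        + [f"psqi_dist{i}" for i in range(1, 10)]
    )
    required = _SCORING_REQUIRED + zsds_cols + psqi_item_cols
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise ValueError(f"scoring input lacks columns: {missing_cols}")
    complete = df[required].notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        log.info("dropping %d rows with missing scorable items", n_dropped)
    df = df[complete].reset_index(drop=True)

    mctq = qs.mctq_from_arrays(
        df["onset_work"], df["wake_work"], df["onset_free"], df["wake_free"],
        df["free_days"], df.get("alarm_free", pd.Series(False, index=df.index)),
        df["tib_work"] if "tib_work" in df else None,
        df["tib_free"] if "tib_free" in df else None,
        mctq_config,
    )
    scored = df[
        ["participant_id", "sex", "age", "city", "mode", "gpa",
         "height_m", "weight_kg", "waist_cm"]
    ].copy()
    for k in ("sld_work", "sld_free", "sld", "sle", "msw", "msf",
              "msf_sc", "sjl"):
        scored[k] = mctq[k]

    comps = qs.psqi_components_from_arrays(
        df["psqi_bedtime"], df["psqi_latency_min"], df["psqi_wake"],
        df["psqi_hours"], df["psqi_trouble"],
        df[[f"psqi_dist{i}" for i in range(1, 10)]].to_numpy(),
        df["psqi_quality"], df["psqi_med"], df["psqi_sleepy"],
        df["psqi_enth"],
    )
    scored["psqi"] = comps.sum(axis=1)

    raw = qs.zsds_raw_from_items(df[zsds_cols].to_numpy())
    scored["zsds_raw"] = raw
    scored["zsdsi"] = raw * 1.25

    scored["bmi"] = df["weight_kg"] / df["height_m"] ** 2
    scored["whtr"] = df["waist_cm"] / (df["height_m"] * 100.0)
    ref = lms_ref if lms_ref is not None else qs.load_lms_reference()
    scored["bmi_pct"] = qs.bmi_percentile_from_arrays(
        scored["bmi"], df["age"], df["sex"], ref
    )

    exposure = fmt_ffq.score_fmt_table(
        ffq[ffq["participant_id"].isin(scored["participant_id"])],
        products or fmt_ffq.load_product_table(),
    )
    scored = scored.merge(exposure, on="participant_id", how="left")
    for c in ("fmt_day", "fmt_dinner"):
        scored[c] = scored[c].fillna(0.0)
    return scored, n_dropped


def _tertile_descriptives(derived: pd.DataFrame) -> pd.DataFrame:
    """Table of per-tertile M, SD, min, max for the raw and log exposures."""
    rows = []
    for var, logvar in (("fmt_day", "fmt1_day"), ("fmt_dinner", "fmt1_dinner")):
        vals = derived[logvar]
        tert = fmt_ffq.assign_tertiles(vals.to_numpy())
        for shown in (var, logvar):
            for k in (1, 2, 3):
                sel = tert.codes == k
                v = derived.loc[sel, shown]
                rows.append(
                    {
                        "parameter": shown, "tertile": k, "n": int(sel.sum()),
                        "M": v.mean(), "SD": v.std(ddof=1),
                        "min": v.min(), "max": v.max(),
                    }
                )
    return pd.DataFrame(rows)


def analyze(derived: pd.DataFrame, cfg: RunConfig) -> dict:
    """All association analyses on a derived cohort table.

    Returns a dict of result tables: tertile descriptives, two ANCOVA
    panels, the linear regression panel and the logistic panel.
    """
    out: dict = {}
    out["tertiles"] = _tertile_descriptives(derived)

    d = derived.copy()
    for logvar, col in (("fmt1_day", "tertile_day"), ("fmt1_dinner", "tertile_dinner")):
        d[col] = fmt_ffq.assign_tertiles(d[logvar].to_numpy()).codes

    ancova_rows = []
    posthoc_rows = []
    for factor, col in (("fmt1_day", "tertile_day"), ("fmt1_dinner", "tertile_dinner")):
        for outc in ANCOVA_OUTCOMES:
            if outc not in d.columns:
                continue
            res = stats_mod.ancova_by_tertile(d, outc, col, ANCOVA_COVARIATES)
            for g in res.groups.itertuples(index=False):
                ancova_rows.append(
                    {"factor": factor, "outcome": outc, "tertile": g.tertile,
                     "n": g.n, "adj_mean": g.adj_mean, "sd": g.sd,
                     "F": res.f, "P": res.p, "eta_sq": res.eta_sq}
                )
            for pr in res.posthoc.itertuples(index=False):
                posthoc_rows.append(
                    {"factor": factor, "outcome": outc, "pair": pr.pair,
                     "diff": pr.diff, "p": pr.p, "tier": pr.tier}
                )
    out["ancova"] = pd.DataFrame(ancova_rows)
    out["ancova_posthoc"] = pd.DataFrame(posthoc_rows)

    lin_rows = []
    for outc in LINEAR_OUTCOMES:
        if outc not in d.columns:
            continue
        for fmt_var in ("fmt1_day", "fmt1_dinner"):
            spec = stats_mod.ModelSpec(
                outcome=outc, candidates=BASE_CANDIDATES + [fmt_var],
                entry_p=cfg.entry_p, removal_p=cfg.removal_p,
                vif_limit=cfg.vif_limit, strict_paper=cfg.strict_paper,
            )
            res = stats_mod.stepwise_ols(d, spec)
            if res.empty:
                lin_rows.append(
                    {"outcome": outc, "fmt_variant": fmt_var, "predictor": None,
                     "B": np.nan, "beta": np.nan, "R2_cum": 0.0, "dR2": 0.0,
                     "p_bonf": np.nan, "VIF": np.nan, "n": res.n}
                )
            for r in res.table.itertuples(index=False):
                lin_rows.append(
                    {"outcome": outc, "fmt_variant": fmt_var,
                     "predictor": r.predictor, "B": r.B, "beta": r.beta,
                     "R2_cum": r.R2_cum, "dR2": r.dR2, "p_bonf": r.p_bonf,
                     "VIF": r.VIF, "n": res.n}
                )
    out["linear"] = pd.DataFrame(lin_rows)

    logi_rows = []
    for outc in LOGISTIC_OUTCOMES:
        if outc not in d.columns or d[outc].nunique() < 2:
            continue
        for fmt_var in ("fmt1_day", "fmt1_dinner"):
            spec = stats_mod.ModelSpec(
                outcome=outc, candidates=BASE_CANDIDATES + [fmt_var],
                entry_p=cfg.entry_p, removal_p=cfg.removal_p,
                vif_limit=cfg.vif_limit, strict_paper=cfg.strict_paper,
            )
            res = stats_mod.stepwise_logistic(d, spec)
            if res.empty:
                logi_rows.append(
                    {"outcome": outc, "fmt_variant": fmt_var, "predictor": None,
                     "B": np.nan, "OR": np.nan, "ci_low": np.nan,
                     "ci_high": np.nan, "p_bonf": np.nan,
                     "omnibus_chi2": res.omnibus_chi2, "omnibus_p": res.omnibus_p,
                     "hl_chi2": res.hl_chi2, "hl_p": res.hl_p, "n": res.n}
                )
            for r in res.table.itertuples(index=False):
                logi_rows.append(
                    {"outcome": outc, "fmt_variant": fmt_var,
                     "predictor": r.predictor, "B": r.B, "OR": r.OR,
                     "ci_low": r.ci_low, "ci_high": r.ci_high,
                     "p_bonf": r.p_bonf, "omnibus_chi2": res.omnibus_chi2,
                     "omnibus_p": res.omnibus_p, "hl_chi2": res.hl_chi2,
                     "hl_p": res.hl_p, "n": res.n}
                )
    out["logistic"] = pd.DataFrame(logi_rows)
    return out


# --------------------------------------------------------------------------
# report rendering
# --------------------------------------------------------------------------


def _fmt_table(df: pd.DataFrame, decimals: dict[str, int]) -> str:
    d = df.copy()
    for c, k in decimals.items():
        if c in d.columns:
            d[c] = d[c].map(lambda x: "" if pd.isna(x) else f"{x:.{k}f}")
    cols = list(d.columns)
    lines = ["| " + " | ".join(cols) + " |",
             "|" + "|".join("---" for _ in cols) + "|"]
    for row in d.itertuples(index=False):
        lines.append(
            "| " + " | ".join("" if pd.isna(v) else str(v) for v in row) + " |"
        )
    return "\n".join(lines)


def render_report(results: dict, manifest: dict) -> str:
    parts = ["# Cohort analysis report", ""]
    parts += [
        "Rows: "
        f"{manifest['rows_invited']} invited, "
        f"{manifest['rows_excluded']} excluded "
        f"({manifest['exclusion_pct']}%), "
        f"{manifest['rows_analyzed']} analyzed.",
        "",
    ]
    parts += ["## Exposure tertiles", "",
              _fmt_table(results["tertiles"],
                         {"M": 2, "SD": 2, "min": 2, "max": 2}), ""]
    parts += ["## ANCOVA by exposure tertile", "",
              _fmt_table(results["ancova"],
                         {"adj_mean": 2, "sd": 2, "F": 3, "P": 3, "eta_sq": 3}),
              "", "### Post hoc pairwise comparisons", "",
              _fmt_table(results["ancova_posthoc"], {"diff": 3, "p": 4}), ""]
    parts += ["## Stepwise linear regression", "",
              _fmt_table(results["linear"],
                         {"B": 3, "beta": 3, "R2_cum": 3, "dR2": 3,
                          "p_bonf": 3, "VIF": 3}), ""]
    parts += ["## Stepwise logistic regression", "",
              _fmt_table(results["logistic"],
                         {"B": 3, "OR": 3, "ci_low": 3, "ci_high": 3,
                          "p_bonf": 3, "omnibus_chi2": 3, "omnibus_p": 3,
                          "hl_chi2": 3, "hl_p": 3}), ""]
    return "\n".join(parts)


# --------------------------------------------------------------------------
# driver
# --------------------------------------------------------------------------


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the configured stages; writes CSVs, report.md and
    manifest.json under ``cfg.outdir`` and returns the manifest."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": cfg.seed, "stages": list(cfg.stages)}
    stage = "init"
    try:
        if "simulate" in cfg.stages:
            stage = "simulate"
            gen_cfg = GeneratorConfig(n=cfg.n, seed=cfg.seed)
            cohort = generate_cohort(gen_cfg)
            participants, ffq = cohort.participants, cohort.ffq
            participants.to_csv(outdir / "participants.csv", index=False)
            ffq.to_csv(outdir / "ffq.csv", index=False)
            cohort.latent.to_csv(outdir / "latent_truth.csv", index=False)
        else:
            stage = "load"
            participants = pd.read_csv(cfg.participants_path)
            ffq = pd.read_csv(cfg.ffq_path)
        manifest["rows_invited"] = int(cfg.n_invited)
        manifest["rows_received"] = len(participants)
        manifest["rows_excluded_nonresponse"] = int(
            cfg.n_invited - len(participants)
        )
        if manifest["rows_excluded_nonresponse"] < 0:
            raise ValueError("n_invited smaller than the received cohort")

        stage = "score"
        scored, n_dropped = score_participants(
            participants, ffq,
            products=fmt_ffq.load_product_table(cfg.products_path),
            lms_ref=qs.load_lms_reference(cfg.lms_path),
            mctq_config=qs.MctqConfig(
                cfg.sle_formula, cfg.msfsc_correction, cfg.sjl_absolute
            ),
        )
        if "score" in cfg.stages or "derive" in cfg.stages:
            scored.to_csv(outdir / "scored.csv", index=False)
        manifest["rows_dropped_scoring"] = n_dropped

        stage = "derive"
        derived = dv.build_derived_cohort(scored)
        derived.to_csv(outdir / "derived.csv", index=False)
        (outdir / "column_dictionary.json").write_text(
            dv.column_dictionary_json()
        )
        manifest["rows_analyzed"] = len(derived)
        manifest["rows_excluded"] = (
            manifest["rows_invited"] - manifest["rows_analyzed"]
        )
        manifest["exclusion_pct"] = int(
            round(100.0 * manifest["rows_excluded"] / manifest["rows_invited"])
        )

        if "analyze" in cfg.stages:
            stage = "analyze"
            results = analyze(derived, cfg)
            for name, df in results.items():
                df.to_csv(outdir / f"{name}.csv", index=False)
            (outdir / "report.md").write_text(render_report(results, manifest))
    except Exception as exc:
        raise RuntimeError(
            f"pipeline stage {stage!r} failed "
            f"(rows so far: { {k: v for k, v in manifest.items() if k.startswith('rows')} })"
        ) from exc

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
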