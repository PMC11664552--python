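"""End-to-end orchestration: soil -> leaf -> response fits -> limitation.

Stages exchange plain CSV tables so any stage can also be run standalone
from files.  A run manifest (YAML) records the configuration, seed and
every constant actually used, plus a hash for reproducibility checks.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd
import yaml

from . import soil_water
from .drought_response import (
    LinearPlateauFit,
    compare_thresholds,
    fit_linear,
    fit_linear_plateau,
    select_response_model,
)
from .kinetics import KINETICS_PRESETS, PhotosyntheticKinetics
from .leaf_exchange import (
    CI_FILTER,
    CalibrationResult,
    aggregate_daily_means,
    derive_states,
    fit_alpha_beta_psii,
)
from .limitation import (
    DEFAULT_VPD_REW,
    VpdRewRelation,
    evaluate_curves,
    fit_vpd_rew,
    summarize,
)
from .presets import CS_CHAMBER, MIN_OBSERVED_REW

logger = logging.getLogger(__name__)

RESPONSE_VARIABLES = ["a_sat", "g_s", "g_m_25", "v_cmax_25", "g_1", "ci_over_cs"]

FITS_CSV_COLUMNS = [
    "variable", "y_max", "slope_a", "intercept_b", "rew_th",
    "sd_y_max", "sd_a", "sd_b", "sd_rew_th", "r2",
]


@dataclass
class PipelineConfig:
    """Paths, constants and options of one pipeline run."""

    out_dir: Path
    gas_exchange_csv: Optional[Path] = None
    calibration_csv: Optional[Path] = None
    soil_moisture_csv: Optional[Path] = None
    retention_csv: Optional[Path] = None
    kinetics_basis: str = "cc"
    cs: float = CS_CHAMBER
    ci_filter: tuple = CI_FILTER
    rew_min: float = MIN_OBSERVED_REW
    n_grid: int = 200
    seed: Optional[int] = None
    horizon_override: Optional[tuple] = None  # (theta_wp, theta_fc) in percent

    @property
    def kinetics(self) -> PhotosyntheticKinetics:
        return KINETICS_PRESETS[self.kinetics_basis]


def fits_to_frame(fits: Dict[str, LinearPlateauFit]) -> pd.DataFrame:
    rows = []
    for name, f in fits.items():
        rows.append(
            {
                "variable": name,
                "y_max": f.y_max,
                "slope_a": f.slope_a,
                "intercept_b": f.intercept_b,
                "rew_th": f.rew_th,
                "sd_y_max": f.sd_y_max,
                "sd_a": f.sd_a,
                "sd_b": f.sd_b,
                "sd_rew_th": f.sd_rew_th,
                "r2": f.r2,
            }
        )
    return pd.DataFrame(rows)


def frame_to_fits(df: pd.DataFrame) -> Dict[str, LinearPlateauFit]:
    df = df.copy()
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in ("variable", "y_max", "slope_a", "rew_th") if c not in df.columns]
    if missing:
        raise KeyError(f"fits table is missing columns: {missing}")
    fits = {}
    for _, row in df.iterrows():
        name = str(row["variable"])
        y_max, a, th = float(row["y_max"]), float(row["slope_a"]), float(row["rew_th"])
        b = float(row["intercept_b"]) if "intercept_b" in row else y_max - a * th
        fits[name] = LinearPlateauFit(
            variable=name,
            y_max=y_max,
            slope_a=a,
            intercept_b=b,
            rew_th=th,
            sd_y_max=float(row.get("sd_y_max", np.nan)),
            sd_a=float(row.get("sd_a", np.nan)),
            sd_b=float(row.get("sd_b", np.nan)),
            sd_rew_th=float(row.get("sd_rew_th", np.nan)),
            r2=float(row.get("r2", np.nan)),
        )
    return fits


def soil_stage(cfg: PipelineConfig) -> pd.DataFrame:
    """Retention fit (or override) -> horizon constants -> daily REW."""
    if cfg.horizon_override is not None:
        consts = soil_water.SoilHorizonConstants(*cfg.horizon_override)
    else:
        samples = soil_water.read_retention_csv(cfg.retention_csv)
        fitted = [soil_water.fit_van_genuchten(s) for s in samples]
        horizons = [soil_water.derive_wp_fc(p) for p in fitted]
        consts = soil_water.SoilHorizonConstants(
            theta_wp=float(np.mean([h.theta_wp for h in horizons])),
            theta_fc=float(np.mean([h.theta_fc for h in horizons])),
        )
    rew = soil_water.rew_timeseries(cfg.soil_moisture_csv, consts)
    rew.attrs["theta_wp"] = consts.theta_wp
    rew.attrs["theta_fc"] = consts.theta_fc
    return rew


def leaf_stage(cfg: PipelineConfig) -> tuple:
    cal_points = pd.read_csv(cfg.calibration_csv)
    cal = fit_alpha_beta_psii(cal_points)
    records = pd.read_csv(cfg.gas_exchange_csv)
    states = derive_states(records, cal, cfg.kinetics, cfg.ci_filter)
    means = aggregate_daily_means(states)
    return cal, states, means


def response_stage(means: pd.DataFrame, rew_by_day: pd.DataFrame) -> tuple:
    """Join group means with REW and fit linear-plateau + linear per variable.

    ``rew_by_day`` needs columns (dae, treatment, rew); irrigated groups may
    instead carry a constant rew column.
    """
    joined = means.merge(rew_by_day[["dae", "treatment", "rew"]], on=["dae", "treatment"])
    fits, selections = {}, {}
    for var in RESPONSE_VARIABLES:
        sub = joined[["rew", var]].dropna()
        if len(sub) < 6:
            logger.warning("%s: only %d means, skipping fit", var, len(sub))
            continue
        seg = fit_linear_plateau(sub["rew"].to_numpy(), sub[var].to_numpy(), variable=var)
        lin = fit_linear(sub["rew"].to_numpy(), sub[var].to_numpy(), variable=var)
        fits[var] = seg
        selections[var] = select_response_model(seg, lin)
    # threshold comparison matrix
    names = list(fits)
    pmat = pd.DataFrame(index=names, columns=names, dtype=float)
    for i, n1 in enumerate(names):
        for n2 in names[: i]:
            try:
                p = compare_thresholds(fits[n1], fits[n2])
            except ValueError:
                p = np.nan
            pmat.loc[n1, n2] = pmat.loc[n2, n1] = p
    return joined, fits, selections, pmat


def limitation_stage(
    cfg: PipelineConfig,
    fits: Dict[str, LinearPlateauFit],
    vpd_rel: VpdRewRelation = DEFAULT_VPD_REW,
):
    return evaluate_curves(
        fits, vpd_rel=vpd_rel, kin=cfg.kinetics, rew_min=cfg.rew_min, cs=cfg.cs, n_grid=cfg.n_grid
    )


def _manifest(cfg: PipelineConfig, extra: dict) -> dict:
    payload = {
        "kinetics_basis": cfg.kinetics_basis,
        "kinetics": {
            "kc_25": cfg.kinetics.kc_25,
            "ko_25": cfg.kinetics.ko_25,
            "gamma_star_25": cfg.kinetics.gamma_star_25,
            "o2_mixing": cfg.kinetics.o2_mixing,
            "r_d": cfg.kinetics.r_d,
        },
        "cs": cfg.cs,
        "ci_filter": list(cfg.ci_filter),
        "rew_min": cfg.rew_min,
        "n_grid": cfg.n_grid,
        "seed": cfg.seed,
    }
    payload.update(extra)
    digest = hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()
    payload["manifest_hash"] = digest
    return payload


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Full soil -> leaf -> response -> limitation run with persisted artifacts."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    rew = soil_stage(cfg)
    rew.to_csv(out / "rew_timeseries.csv", index=False)

    cal, states, means = leaf_stage(cfg)
    states.to_csv(out / "derived_states.csv", index=False)
    means.to_csv(out / "group_means.csv", index=False)

    # attach REW per (day, treatment): non-irrigated follows the soil series;
    # the irrigated control is pinned near field capacity
    rew_days = rew.copy()
    rew_days["dae"] = np.arange(len(rew_days)) if "dae" not in rew_days.columns else rew_days["dae"]
    if "time" in rew_days.columns:
        t0 = pd.to_datetime(rew_days["time"]).min()
        rew_days["dae"] = (pd.to_datetime(rew_days["time"]) - t0).dt.days
    rew_map = pd.concat(
        [
            rew_days.assign(treatment="non_irrigated")[["dae", "treatment", "rew"]],
            rew_days.assign(treatment="irrigated", rew=1.0)[["dae", "treatment", "rew"]],
        ]
    )
    joined, fits, selections, pmat = response_stage(means, rew_map)
    joined.to_csv(out / "means_with_rew.csv", index=False)
    fits_df = fits_to_frame(fits)
    fits_df["chosen_model"] = [selections[v].chosen for v in fits_df["variable"]]
    fits_df["aicc_segmented"] = [selections[v].aicc_segmented for v in fits_df["variable"]]
    fits_df["aicc_linear"] = [selections[v].aicc_linear for v in fits_df["variable"]]
    fits_df.to_csv(out / "response_fits.csv", index=False)
    pmat.to_csv(out / "threshold_pvalues.csv")

    vpd_means = (
        pd.read_csv(cfg.gas_exchange_csv)
        .groupby(["dae", "treatment"])["vpd_leaf"]
        .mean()
        .reset_index()
    )
    vpd_joined = joined.merge(vpd_means, on=["dae", "treatment"])
    vpd_rel = fit_vpd_rew(vpd_joined["vpd_leaf"], vpd_joined["rew"])

    missing = [v for v in RESPONSE_VARIABLES if v not in fits]
    result = {
        "rew": rew,
        "calibration": cal,
        "states": states,
        "means": joined,
        "fits": fits,
        "selections": selections,
        "pvalues": pmat,
        "vpd_relation": vpd_rel,
    }
    if missing:
        logger.warning("limitation stage skipped, missing fits: %s", missing)
    else:
        rew_min = max(cfg.rew_min, float(joined["rew"].min()))
        curves = evaluate_curves(
            fits, vpd_rel=vpd_rel, kin=cfg.kinetics, rew_min=rew_min, cs=cfg.cs, n_grid=cfg.n_grid
        )
        curves.table.to_csv(out / "limitation_curves.csv", index=False)
        (out / "limitation_summary.json").write_text(
            json.dumps(summarize(curves), indent=2, default=float)
        )
        result["curves"] = curves

    manifest = _manifest(
        cfg,
        {
            "alpha_beta": cal.alpha_beta,
            "theta_wp": rew.attrs.get("theta_wp"),
            "theta_fc": rew.attrs.get("theta_fc"),
            "n_records": int(len(states)),
            "vpd_rew_slope": vpd_rel.slope,
        },
    )
    (out / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))
    result["manifest"] = manifest
    return result


def run_from_published_fits(
    fits_csv, cfg: PipelineConfig, vpd_rel: VpdRewRelation = DEFAULT_VPD_REW
) -> dict:
    """Limitation stage alone, from a fits table (no raw data required)."""
    df = pd.read_csv(fits_csv) if not isinstance(fits_csv, pd.DataFrame) else fits_csv
    fits = frame_to_fits(df)
    curves = limitation_stage(cfg, fits, vpd_rel)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    curves.table.to_csv(out / "limitation_curves.csv", index=False)
    summary = summarize(curves)
    (out / "limitation_summary.json").write_text(json.dumps(summary, indent=2, default=float))
    manifest = _manifest(cfg, {"mode": "from_fits", "n_fits": len(fits)})
    (out / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))
    return {"fits": fits, "curves": curves, "summary": summary, "manifest": manifest}
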