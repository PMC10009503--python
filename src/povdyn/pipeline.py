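"""End-to-end pipeline orchestration and report-shaped outputs.

``run_pipeline`` takes raw household records plus a conversion table
(in memory or from a panel directory), computes indicators, strata,
trajectories and all summary products, runs the statistical tests, and
writes the output bundle:

* ``indicators.csv`` — per household x round derived indicators
* ``strata.csv`` / ``trajectories.csv`` — classifications and the nine
  trajectory groups
* ``flow_matrix.json`` — 3x3 stratum-to-stratum counts plus
  rising/steady/falling shares (Sankey-ready)
* ``share_table.csv`` — per-stratum shares of population, land and
  farm-produce value with the value:land ratio
* ``strata_description.csv`` — median household members, land and TLU
  per round x stratum with post-hoc letters
* ``performance_table.csv`` — median component values and intensity
  metrics per round x stratum with post-hoc letters
* ``composition.csv`` — average TVA component shares per round x stratum
* ``net_change.csv`` — median round-2 minus round-1 changes per
  trajectory group
* ``welfare_validation.json`` — welfare indicators compared across
  strata (round 2)
* ``dynamics_tests.json`` — McNemar tests on both dichotomisations
  (overall and per site) and the Wilcoxon movement test
* ``regressions.json`` — asset -> income and education -> income models
* ``manifest.json`` — config hash, seed, package and library versions

Statistical comparisons are only ever made between strata within the
same round, never across rounds.  All tests consume untrimmed data.
Given the same config and seed the pipeline is idempotent and its
outputs byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import __version__
from .conversions import ConversionTable
from .indicators import indicator_table
from .panel_stats import (ComparisonResult, STRATUM_CODES, anova_posthoc,
                          asset_income_regression, education_income_analysis,
                          mcnemar_paired, wilcoxon_strata_movement)
from .records import HouseholdRecord
from .strata import (CALORIE_LINE, POVERTY_LINE, STRATA, assign_strata,
                     assign_trajectories, flow_matrix,
                     net_change_by_trajectory, share_table,
                     strata_proportions)
from .survey_io import read_household_table, write_panel
from .welfare import load_synthetic_scorecard, validate_strata, welfare_scores

__all__ = ["RunConfig", "run_pipeline", "make_table"]

TVA_COMPONENTS = ["value_consumed_crops", "value_sold_crops",
                  "value_consumed_livestock", "value_sold_livestock",
                  "off_farm_income"]

DESCRIPTION_METRICS = ["n_members", "land_cultivated", "tlu"]
PERFORMANCE_METRICS = ["crop_value", "crop_intensity", "livestock_value",
                       "livestock_intensity", "off_farm_income",
                       "offfarm_intensity"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    output_dir: Union[str, Path]
    input_dir: Optional[Union[str, Path]] = None
    conversion_path: Optional[Union[str, Path]] = None
    calorie_line: float = CALORIE_LINE       # kcal / MAE / day
    poverty_line: float = POVERTY_LINE       # $PPP / MAE / day
    per_capita: bool = False                 # evaluate thresholds per person
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.calorie_line <= 0 or self.poverty_line <= 0:
            raise ValueError("thresholds must be > 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    def to_jsonable(self) -> dict:
        d = asdict(self)
        d["output_dir"] = str(self.output_dir)
        d["input_dir"] = None if self.input_dir is None else str(self.input_dir)
        d["conversion_path"] = (None if self.conversion_path is None
                                else str(self.conversion_path))
        return d


def _result_jsonable(res: ComparisonResult) -> dict:
    return {
        "test": res.test,
        "statistic": None if np.isnan(res.statistic) else float(res.statistic),
        "p_value": None if np.isnan(res.p_value) else float(res.p_value),
        "groups": list(res.groups),
        "n": res.n,
        "estimates": res.estimates,
        "letters": res.letters,
        "pairwise": (None if res.pairwise is None
                     else res.pairwise.to_dict(orient="records")),
        "alpha": res.alpha,
        "degenerate": res.degenerate,
    }


def _letters_table(indicators: pd.DataFrame, assignments: pd.DataFrame,
                   metrics: Sequence[str], alpha: float,
                   exclusion_log: list[dict]) -> pd.DataFrame:
    """Median per round x stratum per metric with within-round Tukey letters."""
    merged = indicators.merge(
        assignments[["household_id", "round", "stratum"]],
        on=["household_id", "round"])
    rows = []
    for rnd, grp in merged.groupby("round"):
        for stratum in STRATA:
            sub = grp[grp["stratum"] == stratum]
            row = {"round": rnd, "stratum": stratum, "n": len(sub)}
            for metric in metrics:
                vals = sub[metric].dropna()
                dropped = len(sub) - len(vals)
                if dropped:
                    exclusion_log.append({
                        "round": int(rnd), "stratum": stratum,
                        "metric": metric, "excluded_missing": int(dropped),
                    })
                row[metric] = float(vals.median()) if len(vals) else np.nan
            rows.append(row)
        for metric in metrics:
            vals = grp[["stratum", metric]].dropna()
            counts = vals.groupby("stratum").size().reindex(STRATA, fill_value=0)
            if (counts < 2).any() or counts.gt(0).sum() < 2:
                letters = {s: "" for s in STRATA}
            else:
                res = anova_posthoc(vals[metric], vals["stratum"],
                                    method="tukey_hsd", alpha=alpha)
                letters = res.letters
            for row in rows:
                if row["round"] == rnd:
                    row[f"{metric}_letters"] = letters.get(row["stratum"], "")
    return pd.DataFrame(rows)


def make_table(kind: str, bundle: dict) -> pd.DataFrame:
    """Formatted report table from a pipeline bundle.

    ``kind`` is ``"strata_description"`` (median members/land/TLU with
    letters), ``"shares"`` (population/land/value shares with the
    value:land ratio at 2 dp, no letters), or ``"performance"`` (median
    component values and intensities with letters).  Comparisons are
    within-round only.
    """
    if kind == "shares":
        df = bundle["share_table"].copy()
        df["value_land_ratio"] = df["value_land_ratio"].round(2)
        return df
    if kind == "strata_description":
        return bundle["strata_description"].copy()
    if kind == "performance":
        return bundle["performance_table"].copy()
    raise ValueError(f"unknown table kind {kind!r}")


def run_pipeline(config: RunConfig,
                 records: Optional[Sequence[HouseholdRecord]] = None,
                 conversion_table: Optional[ConversionTable] = None) -> dict:
    """Run the full analysis and write the output bundle.

    Records and the conversion table may be passed in memory; otherwise
    they are read from ``config.input_dir`` (which must contain the
    panel CSVs and ``conversions.yaml`` unless ``conversion_path`` is
    given).  Returns the bundle as a dict of frames/dicts.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    exclusion_log: list[dict] = []

    if records is None:
        if config.input_dir is None:
            raise ValueError("need records or config.input_dir")
        records, errors = read_household_table(config.input_dir)
        for e in errors:
            exclusion_log.append({"household_id": e.household_id,
                                  "round": e.round, "reason": e.message})
    if conversion_table is None:
        path = (Path(config.conversion_path) if config.conversion_path
                else Path(config.input_dir) / "conversions.yaml")
        conversion_table = ConversionTable.from_yaml(path)

    records = list(records)
    indicators = indicator_table(records, conversion_table)
    if config.per_capita:
        # thresholds per person instead of per MAE
        scale = indicators["mae"] / indicators["n_members"]
        indicators["tva_per_mae_day"] *= scale
        indicators["fa"] *= scale

    assignments = assign_strata(indicators,
                                calorie_line=config.calorie_line,
                                poverty_line=config.poverty_line)
    trajectories = assign_trajectories(assignments)
    proportions = strata_proportions(assignments)
    flows, direction_shares = flow_matrix(trajectories)
    shares = share_table(assignments, indicators)

    ind_r1 = indicators[indicators["round"] == 1]
    ind_r2 = indicators[indicators["round"] == 2]
    matched = set(ind_r1["household_id"]) & set(ind_r2["household_id"])
    for df, rnd in ((ind_r1, 1), (ind_r2, 2)):
        for hid in set(df["household_id"]) - matched:
            exclusion_log.append({"household_id": hid, "round": rnd,
                                  "reason": "unmatched panel id"})
    deltas, net_change = net_change_by_trajectory(ind_r1, ind_r2, trajectories)

    # Fig.2-style composition: average per-household TVA component shares
    comp_rows = []
    merged = indicators.merge(
        assignments[["household_id", "round", "stratum"]],
        on=["household_id", "round"])
    positive = merged[merged["tva"] > 0]
    for (rnd, stratum), grp in positive.groupby(["round", "stratum"]):
        shares_hh = grp[TVA_COMPONENTS].div(grp["tva"], axis=0)
        comp_rows.append({"round": rnd, "stratum": stratum, "n": len(grp),
                          **shares_hh.mean().to_dict()})
    composition = pd.DataFrame(comp_rows)

    description = _letters_table(indicators, assignments,
                                 DESCRIPTION_METRICS, config.alpha,
                                 exclusion_log)
    performance = _letters_table(indicators, assignments,
                                 PERFORMANCE_METRICS, config.alpha,
                                 exclusion_log)

    # paired dynamics tests on the matched subsample
    a1 = assignments[assignments["round"] == 1].set_index("household_id")
    a2 = assignments[assignments["round"] == 2].set_index("household_id")
    common = sorted(a1.index.intersection(a2.index))
    a1, a2 = a1.loc[common], a2.loc[common]
    dynamics: dict = {"direction_shares": direction_shares}
    for name, col, line in (("poverty_line", "tva_per_mae_day",
                             config.poverty_line),
                            ("calorie_line", "fa", config.calorie_line)):
        above1 = (a1[col] >= line).to_numpy()
        above2 = (a2[col] >= line).to_numpy()
        dynamics[f"mcnemar_{name}"] = _result_jsonable(
            mcnemar_paired(above1, above2))
        per_site = {}
        sites1 = pd.Series([r.site for r in records if r.round == 1],
                           index=[r.household_id for r in records
                                  if r.round == 1])
        for site in sorted(sites1.unique()):
            mask = sites1.reindex(common).to_numpy() == site
            if mask.sum():
                per_site[site] = _result_jsonable(
                    mcnemar_paired(above1[mask], above2[mask], exact=True))
        dynamics[f"mcnemar_{name}_by_site"] = per_site
    codes1 = a1["stratum"].map(STRATUM_CODES).to_numpy()
    codes2 = a2["stratum"].map(STRATUM_CODES).to_numpy()
    dynamics["wilcoxon_movement"] = _result_jsonable(
        wilcoxon_strata_movement(codes1, codes2))

    # welfare validation (round 2)
    scores = welfare_scores(records, scorecard=load_synthetic_scorecard())
    welfare_val = validate_strata(scores, assignments, alpha=config.alpha)
    welfare_json = {
        ind: ({"skipped": True, "reason": res["reason"]} if res["skipped"]
              else {
                  "skipped": False,
                  "comparison": _result_jsonable(res["comparison"]),
                  "medians": res["medians"],
                  "higher_is_better": res["higher_is_better"],
                  "direction_ok": res["direction_ok"],
              })
        for ind, res in welfare_val.items()
    }

    # regressions: round-2 farm income on round-1 assets
    regressions: dict = {}
    r1i = ind_r1.set_index("household_id").loc[sorted(matched)]
    r2i = ind_r2.set_index("household_id").loc[sorted(matched)]
    farm_income2 = (r2i["crop_value"] + r2i["livestock_value"])
    predictors = pd.DataFrame({
        "land_r1": r1i["land_cultivated"],
        "tlu_r1": r1i["tlu"],
        "off_farm_r1": r1i["off_farm_income"],
    })
    if len(matched) > predictors.shape[1] + 1:
        fit = asset_income_regression(farm_income2, predictors)
        regressions["asset_income"] = {
            "params": {k: float(v) for k, v in fit.params.items()},
            "p_values": {k: float(v) for k, v in fit.pvalues.items()},
            "std_errors": {k: float(v) for k, v in fit.bse.items()},
            "r_squared": float(fit.rsquared),
            "n": int(fit.nobs),
        }
    education = pd.Series({r.household_id: r.education for r in records
                           if r.round == 2 and r.education is not None})
    if not education.empty:
        common_e = sorted(set(education.index) & matched)
        edu_res = education_income_analysis(
            education.loc[common_e].to_numpy(),
            (r2i.loc[common_e, "crop_value"]
             + r2i.loc[common_e, "livestock_value"]).to_numpy(),
            r2i.loc[common_e, "off_farm_income"].to_numpy(),
            alpha=config.alpha)
        regressions["education_income"] = {
            k: (None if v is None else _result_jsonable(v))
            for k, v in edu_res.items()
        }

    bundle = {
        "indicators": indicators,
        "assignments": assignments,
        "trajectories": trajectories,
        "proportions": proportions,
        "flow_matrix": flows,
        "direction_shares": direction_shares,
        "share_table": shares,
        "strata_description": description,
        "performance_table": performance,
        "composition": composition,
        "net_change": net_change,
        "net_change_deltas": deltas,
        "welfare_scores": scores,
        "welfare_validation": welfare_val,
        "dynamics": dynamics,
        "regressions": regressions,
        "exclusion_log": exclusion_log,
    }
    _write_bundle(bundle, welfare_json, config, outdir)
    return bundle


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True,
                               allow_nan=True) + "\n", encoding="utf-8")


def _write_bundle(bundle: dict, welfare_json: dict, config: RunConfig,
                  outdir: Path) -> None:
    bundle["indicators"].to_csv(outdir / "indicators.csv", index=False)
    bundle["assignments"].to_csv(outdir / "strata.csv", index=False)
    bundle["trajectories"].to_csv(outdir / "trajectories.csv", index=False)
    make_table("shares", bundle).to_csv(outdir / "share_table.csv",
                                        index=False)
    make_table("strata_description", bundle).to_csv(
        outdir / "strata_description.csv", index=False)
    make_table("performance", bundle).to_csv(
        outdir / "performance_table.csv", index=False)
    bundle["composition"].to_csv(outdir / "composition.csv", index=False)
    bundle["net_change"].to_csv(outdir / "net_change.csv")
    flows = bundle["flow_matrix"]
    _json_dump({
        "strata": list(STRATA),
        "counts": flows.to_numpy().tolist(),
        "links": [
            {"source": f, "target": t, "value": int(flows.loc[f, t])}
            for f in STRATA for t in STRATA if flows.loc[f, t] > 0
        ],
        "direction_shares": bundle["direction_shares"],
        "proportions": {
            str(rnd): row.to_dict()
            for rnd, row in bundle["proportions"].iterrows()
        },
    }, outdir / "flow_matrix.json")
    _json_dump(welfare_json, outdir / "welfare_validation.json")
    _json_dump(bundle["dynamics"], outdir / "dynamics_tests.json")
    _json_dump(bundle["regressions"], outdir / "regressions.json")
    _json_dump(bundle["exclusion_log"], outdir / "exclusion_log.json")

    cfg = config.to_jsonable()
    cfg_hash = hashlib.sha256(
        json.dumps(cfg, sort_keys=True).encode()).hexdigest()
    import pandas, numpy, scipy, statsmodels
    _json_dump({
        "config": cfg,
        "config_sha256": cfg_hash,
        "seed": config.seed,
        "versions": {
            "povdyn": __version__,
            "numpy": numpy.__version__,
            "pandas": pandas.__version__,
            "scipy": scipy.__version__,
            "statsmodels": statsmodels.__version__,
        },
    }, outdir / "manifest.json")
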