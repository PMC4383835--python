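"""Publication-style rendering of cohort analyses.

Builds the three standard outputs of a diary-cohort comparison — a
characteristics table (with ANOVA / chi-square tests), a physical-activity
region-comparison table (raw and covariate-adjusted), and a standardized-
coefficient regression table — plus distribution histograms. Every number
is computed by the scoring/statistics modules; this layer only arranges
and formats.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .diary import AREAS
from .stats import (
    chi_square_table,
    one_way_ancova,
    one_way_anova,
    standardized_regression,
)

ADJUST_COVARIATES = ["age", "sex", "occupation", "income_band", "marital_status"]

#: the behaviour subcategories entered as regression predictors
REGRESSION_BEHAVIORS = [
    "work_standing",
    "work_vigorous",
    "sport_exercise",
    "cooking",
    "cleaning",
    "cycling_transport",
    "car_wash_gardening",
    "childcare",
    "commute_walk",
    "work_walking",
]


def format_p(p: float) -> str:
    """Journal-style p: '<.001' below .001, 3 decimals below .01,
    else 2 decimals, always without the leading zero."""
    if p < 0.001:
        return "<.001"
    digits = 3 if p < 0.01 else 2
    return f"{p:.{digits}f}".lstrip("0")


def format_mean_sd(mean: float, sd: float, decimals: int = 1) -> str:
    return f"{mean:.{decimals}f} ({sd:.{decimals}f})"


def format_n_pct(n: int, total: int) -> str:
    return f"{n} ({100.0 * n / total:.1f})"


def characteristics_table(table: pd.DataFrame) -> pd.DataFrame:
    """Per-area cohort characteristics with a test per row family:
    one-way ANOVA for continuous rows, chi-square for categorical ones."""
    areas = [a for a in AREAS if a in set(table["area"])]
    rows = []
    for var in ("age", "weight", "bmi"):
        r = one_way_anova(table, var, "area")
        row = {"characteristic": var, "type": "mean_sd", "p_value": r.p_value}
        for a in areas:
            sub = table.loc[table["area"] == a, var]
            row[a] = format_mean_sd(sub.mean(), sub.std(ddof=1))
        rows.append(row)
    for var in ("sex", "exercise_habit", "occupation", "income_band", "marital_status"):
        counts = pd.crosstab(table[var], table["area"])[areas]
        _, _, p = chi_square_table(counts.to_numpy())
        first = True
        for level, cnt in counts.iterrows():
            row = {"characteristic": f"{var}={level}", "type": "n_pct",
                   "p_value": p if first else np.nan}
            for a in areas:
                row[a] = format_n_pct(int(cnt[a]), int(counts[a].sum()))
            rows.append(row)
            first = False
    out = pd.DataFrame(rows)
    out["p_display"] = out["p_value"].map(lambda p: "" if pd.isna(p) else format_p(p))
    return out


_TABLE2_ROWS = [
    ("mean_met", "24-hour mean MET", 2),
    ("met_hours", "24-hour MET-hours/day", 1),
    ("mvpa_met_hours", "MVPA MET-hours/day (>=3.0 MET)", 1),
    ("cat_met_hours_household", "Household MET-hours/day", 1),
    ("cat_minutes_household", "Household time (min)", 1),
    ("cat_met_hours_transportation", "Transportation MET-hours/day", 1),
    ("cat_minutes_transportation", "Transportation time (min)", 1),
    ("cat_met_hours_work", "Working MET-hours/day", 1),
    ("cat_minutes_work", "Working time (min)", 1),
    ("cat_met_hours_leisure_sports", "Leisure/sports MET-hours/day", 1),
    ("cat_minutes_leisure_sports", "Leisure/sports time (min)", 1),
    ("sub_minutes_commute_walk", "Walking time while commuting (min)", 1),
    ("sub_minutes_commute_transit", "Public transit while commuting (min)", 1),
    ("sub_minutes_commute_car_sitting", "Sitting in a car while commuting (min)", 1),
    ("sub_minutes_work_sitting", "Sitting time at work (min)", 1),
    ("sub_minutes_work_standing", "Standing time at work (min)", 1),
]


def region_comparison_table(table: pd.DataFrame, adjusted: bool = True) -> pd.DataFrame:
    """Region comparison of activity metrics: mean (SD) per area with the
    one-way ANOVA F/df/p, plus covariate-adjusted means and the ANCOVA
    partial F when ``adjusted``."""
    areas = [a for a in AREAS if a in set(table["area"])]
    rows = []
    for metric, label, dec in _TABLE2_ROWS:
        r = one_way_anova(table, metric, "area")
        row = {"metric": metric, "label": label,
               "f_stat": r.f_stat, "df1": r.df_between, "df2": r.df_within,
               "p_value": r.p_value, "p_display": format_p(r.p_value)}
        for a in areas:
            sub = table.loc[table["area"] == a, metric]
            row[a] = format_mean_sd(sub.mean(), sub.std(ddof=1), dec)
        if adjusted:
            rc = one_way_ancova(table, metric, "area", ADJUST_COVARIATES)
            row.update(
                adj_f=rc.f_stat, adj_df1=rc.df1, adj_df2=rc.df2,
                adj_p=rc.p_value, adj_p_display=format_p(rc.p_value),
                **{f"adj_{a}": round(rc.adjusted_means[a], dec) for a in areas},
            )
        rows.append(row)
    return pd.DataFrame(rows)


def regression_table(table: pd.DataFrame, outcome: str = "mvpa_met_hours") -> pd.DataFrame:
    """Standardized βs of the outcome on the behaviour subcategories, for
    the total sample and per sex."""
    preds = [f"sub_met_hours_{b}" for b in REGRESSION_BEHAVIORS]
    frames = []
    for name, sub in [("total", table),
                      ("men", table[table["sex"] == "man"]),
                      ("women", table[table["sex"] == "woman"])]:
        res = standardized_regression(sub, outcome, preds)
        frames.append(
            pd.DataFrame(
                {
                    "sample": name,
                    "behavior": REGRESSION_BEHAVIORS,
                    "beta": [res.standardized_betas[p] for p in preds],
                    "p_value": [res.pvalues[p] for p in preds],
                    "r_squared": res.r_squared,
                    "see": res.see,
                    "n": res.n,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def plot_histograms(table: pd.DataFrame, out_dir: str | Path) -> list[Path]:
    """Distribution plots of the weighted 24-h mean MET and MVPA."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    specs = [
        ("mean_met", np.arange(1.0, 2.9, 0.1), "24-hour mean MET", "mean_met_hist.png"),
        ("mvpa_met_hours", np.arange(0, 42.5, 2.5), "24-hour MVPA (MET-hours/day)", "mvpa_hist.png"),
    ]
    for metric, bins, xlabel, fname in specs:
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.hist(table[metric], bins=bins, edgecolor="black", color="#6699cc")
        ax.set_xlabel(xlabel)
        ax.set_ylabel("Participants")
        fig.tight_layout()
        path = out_dir / fname
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    return written


def write_analysis(table: pd.DataFrame, out_dir: str | Path) -> dict[str, Path]:
    """Write table1/table2/regression CSVs with JSON metadata sidecars."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    artifacts = {}

    t1 = characteristics_table(table)
    t2 = region_comparison_table(table)
    reg = regression_table(table)
    for name, frame, meta in [
        ("table1", t1, {"tests": ["one_way_anova", "chi_square"], "n": int(len(table))}),
        ("table2", t2, {"tests": ["one_way_anova", "one_way_ancova", "tukey_hsd"],
                        "covariates": ADJUST_COVARIATES, "n": int(len(table))}),
        ("regression", reg, {"outcome": "mvpa_met_hours",
                             "predictors": REGRESSION_BEHAVIORS, "n": int(len(table))}),
    ]:
        path = out_dir / f"{name}.csv"
        frame.to_csv(path, index=False)
        (out_dir / f"{name}.meta.json").write_text(json.dumps(meta, indent=1))
        artifacts[name] = path
    return artifacts
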