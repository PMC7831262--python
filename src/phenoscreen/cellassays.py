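"""Monolayer viability/proliferation time courses, marker proportions,
in-vivo co-label densities, and the shared group-comparison contract.

Viability is read from EthD-1 labelling (membrane-impermeant, marks dead
cells): live fraction = 1 - EthD-1+/total. Proliferation is read from an
EdU pulse (S-phase incorporation): EdU fraction = EdU+/total, reported
both raw and as fold of the control condition at the same day, with the
day of peak labelling. Differentiation outputs are percent-positive per
retinal cell-type marker. In-vivo sections are quantified as co-labelled
cells per unit tissue area (Pax6+EdU per ciliary epithelium area) or as
proportions of all EdU+ cells (ERG+EdU, CD68+EdU).

The replicate unit is the well in vitro and the eye in vivo; group
comparisons go through :func:`group_compare` (Welch t for two groups,
one-/two-way ANOVA with Holm-Sidak — or optionally Fisher LSD — pairwise
post hocs for more).
"""

from __future__ import annotations

import itertools
import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InputConsistencyError, InsufficientReplicatesError

logger = logging.getLogger(__name__)


def _sem(x: np.ndarray) -> float:
    return float(x.std(ddof=1) / np.sqrt(x.size)) if x.size > 1 else float("nan")


def viability_fractions(records: pd.DataFrame) -> pd.DataFrame:
    """Per (condition, day): mean live fraction (1 - EthD-1+/total) and SE.

    Fractions are computed per well then averaged within condition x day;
    wells with total = 0 are excluded with a warning.
    """
    df = records.copy()
    zero = df["total"] <= 0
    if zero.any():
        logger.warning("excluding %d well(s) with zero total nuclei", int(zero.sum()))
        df = df[~zero]
    bad = (df["ethd1_pos"] < 0) | (df["ethd1_pos"] > df["total"])
    if bad.any():
        raise InputConsistencyError("EthD-1 counts outside [0, total]")
    df = df.assign(live=1.0 - df["ethd1_pos"] / df["total"])
    out = (
        df.groupby(["condition", "day"], sort=True)["live"]
        .agg(live_fraction="mean", se=lambda x: _sem(x.to_numpy()), n="size")
        .reset_index()
    )
    return out


def proliferation_fractions(
    records: pd.DataFrame, control_condition: str = "control"
) -> pd.DataFrame:
    """Per (condition, day): EdU fraction and fold vs the control condition.

    fold = condition mean fraction / control mean fraction at the same
    day. Where the control fraction is zero the fold is undefined and
    returned as NaN with ``fold_undefined`` set (never infinity).
    """
    df = records[records["total"] > 0].copy()
    bad = (df["edu_pos"] < 0) | (df["edu_pos"] > df["total"])
    if bad.any():
        raise InputConsistencyError("EdU counts outside [0, total]")
    df = df.assign(frac=df["edu_pos"] / df["total"])
    out = (
        df.groupby(["condition", "day"], sort=True)["frac"]
        .agg(edu_fraction="mean", se=lambda x: _sem(x.to_numpy()), n="size")
        .reset_index()
    )
    ctrl = out[out["condition"] == control_condition].set_index("day")["edu_fraction"]
    missing = set(out["day"]) - set(ctrl.index)
    if missing:
        raise InputConsistencyError(f"control condition missing at days {sorted(missing)}")
    ctrl_at = out["day"].map(ctrl)
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = out["edu_fraction"] / ctrl_at
    out["fold_vs_control"] = np.where(ctrl_at > 0, fold, np.nan)
    out["fold_undefined"] = ~(ctrl_at > 0)
    return out


def peak_timepoint(per_day_fractions: Mapping[int, float]) -> dict:
    """Day of maximum fraction, with all tied days listed."""
    if not per_day_fractions:
        raise ValueError("need at least one day")
    best = max(per_day_fractions.values())
    ties = sorted(d for d, v in per_day_fractions.items() if v == best)
    return {"day": ties[0], "ties": ties, "value": float(best)}


def marker_proportions(marker_counts: pd.DataFrame) -> pd.DataFrame:
    """Per (condition, marker): mean percent-positive across replicates, SE.

    Input rows are one replicate each with ``condition, marker, positive,
    total``; replicates with total = 0 are excluded.
    """
    df = marker_counts.copy()
    zero = df["total"] <= 0
    if zero.any():
        logger.warning("excluding %d replicate(s) with zero total", int(zero.sum()))
        df = df[~zero]
    if ((df["positive"] < 0) | (df["positive"] > df["total"])).any():
        raise InputConsistencyError("positive counts outside [0, total]")
    df = df.assign(pct=100.0 * df["positive"] / df["total"])
    return (
        df.groupby(["condition", "marker"], sort=True)["pct"]
        .agg(percent_positive="mean", se=lambda x: _sem(x.to_numpy()), n="size")
        .reset_index()
    )


def colabel_density(records: pd.DataFrame) -> pd.DataFrame:
    """Per condition: Pax6+EdU density per unit area and EdU co-label shares.

    Each input row is one eye: ``condition, region_area, pax6_edu,
    erg_edu, cd68_edu, total_edu``. Densities are per-eye pax6_edu/area;
    proportions are per-eye component/total_edu; both are averaged within
    condition with SE across eyes. Area units are the caller's and are
    passed through unchanged.
    """
    df = records.copy()
    if (df["region_area"] <= 0).any():
        raise ValueError("region areas must be positive")
    comp_cols = ["erg_edu", "cd68_edu"]
    over = df[comp_cols].gt(df["total_edu"], axis=0).any(axis=1)
    if over.any():
        raise InputConsistencyError("co-label counts exceed total EdU count")
    if ((df["total_edu"] == 0) & df[comp_cols].sum(axis=1).gt(0)).any():
        raise InputConsistencyError("nonzero co-labels with zero total EdU")
    df = df.assign(pax6_density=df["pax6_edu"] / df["region_area"])
    for c in comp_cols:
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = df[c] / df["total_edu"]
        df[f"{c}_prop"] = np.where(df["total_edu"] > 0, frac, 0.0)
    rows = []
    for cond, g in df.groupby("condition", sort=True):
        row = {"condition": cond, "n_eyes": len(g)}
        for col, out in (
            ("pax6_density", "pax6_edu_per_area"),
            ("erg_edu_prop", "erg_edu_proportion"),
            ("cd68_edu_prop", "cd68_edu_proportion"),
        ):
            x = g[col].to_numpy(dtype=float)
            row[out] = float(x.mean())
            row[f"{out}_se"] = _sem(x)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Group comparison contract
# ---------------------------------------------------------------------------

def _holm_sidak(pvals: Sequence[float]) -> np.ndarray:
    return multipletests(pvals, method="holm-sidak")[1]


def group_compare(
    values_by_group: Mapping[str, Sequence[float]],
    design: str = "one_way",
    posthoc: str = "holm-sidak",
    equal_var: bool = False,
    data: pd.DataFrame | None = None,
    formula: str | None = None,
) -> dict:
    """Compare groups per the study's statistical contract.

    * ``design="two_group"`` — two-tailed t test (Welch by default; set
      ``equal_var=True`` for the pooled form).
    * ``design="one_way"`` — one-way ANOVA F, plus pairwise post hocs:
      ``posthoc="holm-sidak"`` (Welch pairwise t, Holm-Sidak adjusted) or
      ``posthoc="fisher-lsd"`` (pooled-MSE t tests, unadjusted).
    * ``design="two_way"`` — two-way factorial ANOVA with type-II sums of
      squares; pass a long-format ``data`` frame and a patsy ``formula``
      (e.g. ``"y ~ C(drug) * C(day)"``) instead of ``values_by_group``.

    Returns a report dict that names the method actually used.
    """
    if design == "two_way":
        if data is None or formula is None:
            raise ValueError("two_way design requires data= and formula=")
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        fit = smf.ols(formula, data=data).fit()
        table = anova_lm(fit, typ=2)
        return {"method": "two-way ANOVA (type II)", "anova_table": table}

    groups = {k: np.asarray(list(v), dtype=float) for k, v in values_by_group.items()}
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    for name, x in groups.items():
        if x.size < 2:
            raise InsufficientReplicatesError(f"group {name!r} has < 2 observations")

    if design == "two_group":
        (na, a), (nb, b) = groups.items()
        res = stats.ttest_ind(a, b, equal_var=equal_var)
        return {
            "method": f"{'pooled' if equal_var else 'Welch'} t test (two-tailed)",
            "groups": [na, nb],
            "t": float(res.statistic),
            "df": float(res.df),
            "p": float(res.pvalue),
        }
    if design != "one_way":
        raise ValueError(f"unknown design {design!r}")

    names = list(groups)
    arrays = [groups[n] for n in names]
    f, p = stats.f_oneway(*arrays)
    k = len(arrays)
    n_total = sum(x.size for x in arrays)
    report = {
        "method": "one-way ANOVA",
        "F": float(f),
        "df": (k - 1, n_total - k),
        "p": float(p),
    }
    pairs = list(itertools.combinations(names, 2))
    if posthoc == "holm-sidak":
        raw = [
            float(stats.ttest_ind(groups[a], groups[b], equal_var=False).pvalue)
            for a, b in pairs
        ]
        adj = _holm_sidak(raw)
        report["posthoc"] = {
            "method": "Holm-Sidak (pairwise Welch t)",
            "comparisons": [
                {"pair": pr, "p_raw": r, "p_adj": float(a_)}
                for pr, r, a_ in zip(pairs, raw, adj)
            ],
        }
    elif posthoc == "fisher-lsd":
        gm = {n: groups[n].mean() for n in names}
        sse = sum(((groups[n] - gm[n]) ** 2).sum() for n in names)
        df_err = n_total - k
        mse = sse / df_err
        comps = []
        for a, b in pairs:
            se = np.sqrt(mse * (1 / groups[a].size + 1 / groups[b].size))
            t = (gm[a] - gm[b]) / se
            comps.append(
                {"pair": (a, b), "t": float(t),
                 "p": float(2 * stats.t.sf(abs(t), df_err))}
            )
        report["posthoc"] = {"method": "Fisher LSD (pooled MSE)", "comparisons": comps}
    else:
        raise ValueError(f"unknown posthoc {posthoc!r}")
    return report
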