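"""Marker dichotomization, Kaplan-Meier curves, log-rank tests and hazard ratios.

IHC markers split at the staining-score rule (0-1 low, 2-3 high);
expression markers split at the cohort median by default (ties to low),
with quantile and fixed-value rules available. Two markers combine into a
4-level label whose extreme cells (adverse-high/protective-low against
the protective reference) carry the combined prognostic contrast.

Estimation is delegated to lifelines (product-limit curves, multivariate
log-rank, Cox fits on indicator contrasts).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from coexsurv.io import IHCTable, SurvivalTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MarkerStatus:
    """Per-sample low/high classification for one marker."""

    marker: str
    levels: pd.Series  # index: sample id, values in {"low", "high"}
    rule: str

    def __post_init__(self):
        if not self.levels.isin(["low", "high"]).all():
            raise ValueError("levels must be 'low' or 'high'")
        if self.levels.index.duplicated().any():
            raise ValueError("duplicate sample ids in marker status")


def dichotomize_ihc(ihc: IHCTable, marker: str) -> MarkerStatus:
    """High iff staining score >= 2 (moderate or strong)."""
    scores = ihc.marker_scores(marker)
    if scores.empty:
        raise ValueError(f"marker {marker!r} not present in the IHC table")
    levels = pd.Series(np.where(scores >= 2, "high", "low"), index=scores.index)
    return MarkerStatus(marker=marker, levels=levels, rule="IHC score >= 2 is high")


def dichotomize_expression(values: pd.Series, rule="median", marker: str | None = None) -> MarkerStatus:
    """Split an expression vector into low/high.

    ``rule`` is "median" (high iff value > cohort median; ties go low),
    ("quantile", q) with q in (0, 1), or ("value", v) for a fixed split
    point. An all-equal vector classifies everything low with a warning.
    """
    name = marker or str(values.name or "marker")
    v = values.astype(float)
    if v.nunique() <= 1:
        logger.warning("marker %s: constant expression; every sample classified low", name)
        levels = pd.Series("low", index=v.index)
        return MarkerStatus(marker=name, levels=levels, rule="constant input, all low")
    if rule == "median":
        split, desc = float(v.median()), "value > cohort median is high"
    elif isinstance(rule, tuple) and rule[0] == "quantile":
        q = float(rule[1])
        if not (0 < q < 1):
            raise ValueError("quantile must lie in (0, 1)")
        split, desc = float(v.quantile(q)), f"value > {q} quantile is high"
    elif isinstance(rule, tuple) and rule[0] == "value":
        split, desc = float(rule[1]), f"value > {rule[1]} is high"
    else:
        raise ValueError(f"unknown dichotomization rule: {rule!r}")
    levels = pd.Series(np.where(v > split, "high", "low"), index=v.index)
    return MarkerStatus(marker=name, levels=levels, rule=desc)


def _join(surv: SurvivalTable, labels: pd.Series) -> pd.DataFrame:
    df = surv.frame.set_index("sample")
    common = [s for s in labels.index if s in df.index]
    n_dropped = len(labels) - len(common)
    if n_dropped:
        logger.info("dropped %d labelled samples without survival records", n_dropped)
    out = df.loc[common, ["time", "event"]].copy()
    out["group"] = labels.loc[common].to_numpy()
    return out.reset_index(names="sample")


def km_estimate(surv: SurvivalTable, groups) -> dict[str, pd.DataFrame]:
    """Product-limit survival curve per group.

    ``groups`` is a MarkerStatus or a sample-indexed Series of labels.
    Each curve is a DataFrame (time, survival, at_risk) starting at
    S(0) = 1. Groups without any event are still estimated (flat curve);
    empty groups are skipped with a warning.
    """
    labels = groups.levels if isinstance(groups, MarkerStatus) else groups
    df = _join(surv, labels)
    curves = {}
    for label, sub in df.groupby("group", sort=True):
        if len(sub) == 0:
            logger.warning("group %s is empty; skipped", label)
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], event_observed=sub["event"])
        table = kmf.event_table
        curve = pd.DataFrame({
            "time": kmf.survival_function_.index.to_numpy(float),
            "survival": kmf.survival_function_.iloc[:, 0].to_numpy(float),
            "at_risk": table["at_risk"].reindex(kmf.survival_function_.index).to_numpy(float),
        })
        curves[str(label)] = curve
    return curves


def logrank_test(surv: SurvivalTable, groups) -> tuple[float, float]:
    """Log-rank chi-square and p over 2+ groups ((k-1) degrees of freedom)."""
    labels = groups.levels if isinstance(groups, MarkerStatus) else groups
    df = _join(surv, labels)
    sizes = df["group"].value_counts()
    if len(sizes) < 2:
        raise ValueError("log-rank test needs at least 2 non-empty groups")
    if df["event"].sum() < 2:
        raise ValueError("log-rank test needs at least 2 events")
    res = multivariate_logrank_test(df["time"], df["group"], df["event"])
    return float(res.test_statistic), float(res.p_value)


def combine_markers(status_a: MarkerStatus, status_b: MarkerStatus) -> pd.Series:
    """Cross two dichotomized markers into 4-level labels.

    Labels are "a-high/b-low" etc.; samples classified for only one
    marker are excluded with a logged count.
    """
    common = status_a.levels.index.intersection(status_b.levels.index)
    n_dropped = len(status_a.levels) + len(status_b.levels) - 2 * len(common)
    if n_dropped:
        logger.info("excluded %d samples missing one of the two markers", n_dropped)
    la = status_a.levels.loc[common]
    lb = status_b.levels.loc[common]
    return pd.Series([f"a-{a}/b-{b}" for a, b in zip(la, lb)], index=common)


def cox_hr_groups(surv: SurvivalTable, labels: pd.Series, reference_label: str) -> pd.DataFrame:
    """Hazard ratio with 95% CI for every non-reference label.

    Fits a Cox model on indicator contrasts against the reference group.
    Labels without subjects are omitted with a warning.
    """
    df = _join(surv, labels)
    present = sorted(df["group"].unique())
    if reference_label not in present:
        raise ValueError(f"reference label {reference_label!r} has no subjects")
    ref = df[df["group"] == reference_label]
    if ref["event"].sum() < 1:
        raise ValueError("reference group must contain at least one event")
    if df["event"].sum() < 2:
        raise ValueError("need at least 2 events overall")
    others = [g for g in present if g != reference_label]
    design = pd.DataFrame({"time": df["time"], "event": df["event"]})
    for g in others:
        design[f"grp::{g}"] = (df["group"] == g).astype(float)
    cph = CoxPHFitter()
    cph.fit(design, duration_col="time", event_col="event")
    summ = cph.summary
    rows = []
    for g in others:
        row = summ.loc[f"grp::{g}"]
        rows.append({
            "group": g,
            "reference": reference_label,
            "hr": float(np.exp(row["coef"])),
            "ci_low": float(np.exp(row["coef lower 95%"])),
            "ci_high": float(np.exp(row["coef upper 95%"])),
            "p": float(row["p"]),
            "n": int((df["group"] == g).sum()),
        })
    return pd.DataFrame(rows)
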