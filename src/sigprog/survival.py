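"""Cohort grouping and signature-exposure survival stratification.

Samples are partitioned into four five-year-outcome groups:

* G1 — survival strictly greater than 60 months (any vital status),
* G2 — survival under 60 months ending in death,
* G3 — survival under 60 months, alive at last follow-up (right-censored),
* G4 — no usable survival information.

Stratifying a cohort on a signature's relative exposure (high arm: fraction
strictly above the threshold, the headline cut being 20%) yields per-arm
Kaplan-Meier curves and a two-sided log-rank test; G4 samples are excluded
from the analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

FIVE_YEARS_MONTHS = 60.0


class Group(str, Enum):
    G1 = "G1"
    G2 = "G2"
    G3 = "G3"
    G4 = "G4"


@dataclass
class StratifiedKMResult:
    threshold: float
    n_high: int
    n_low: int
    logrank_statistic: float | None
    p_value: float | None
    median_high: float | None
    median_low: float | None
    undefined: bool = False  # True when an arm was empty / test not run
    km_high: pd.DataFrame | None = None
    km_low: pd.DataFrame | None = None


def _clean_clinical(clinical: pd.DataFrame) -> pd.DataFrame:
    df = clinical.copy()
    df["sample_id"] = df["sample_id"].astype(str)
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample_id(s) in clinical table: {dups[:5]}")
    df["survival_months"] = pd.to_numeric(df["survival_months"], errors="coerce")
    df["event"] = df["event"].astype(str).str.lower()
    return df


def assign_groups(clinical: pd.DataFrame) -> pd.DataFrame:
    """Partition a clinical table into groups G1-G4.

    ``clinical`` needs columns sample_id, survival_months, event (one of
    "dead"/"alive"/"unknown").  Exactly 60 months is not ">5 years", so it
    falls to G2/G3 by status.  Returns a frame with sample_id and group.
    """
    df = _clean_clinical(clinical)
    known = df["survival_months"].notna() & df["event"].isin(("dead", "alive"))
    groups = np.full(len(df), Group.G4.value, dtype=object)
    t = df["survival_months"].to_numpy()
    dead = (df["event"] == "dead").to_numpy()
    groups[known & (t > FIVE_YEARS_MONTHS)] = Group.G1.value
    groups[known & (t <= FIVE_YEARS_MONTHS) & dead] = Group.G2.value
    groups[known & (t <= FIVE_YEARS_MONTHS) & ~dead] = Group.G3.value
    return pd.DataFrame({"sample_id": df["sample_id"], "group": groups})


def _km_table(fitter: KaplanMeierFitter) -> pd.DataFrame:
    ev = fitter.event_table
    surv = fitter.survival_function_.iloc[:, 0]
    return pd.DataFrame(
        {
            "time": ev.index,
            "at_risk": ev["at_risk"].to_numpy(),
            "events": ev["observed"].to_numpy(),
            "survival": surv.reindex(ev.index).to_numpy(),
        }
    )


def stratify_by_exposure(
    relative_exposure: pd.Series,
    clinical: pd.DataFrame,
    threshold: float = 0.20,
) -> StratifiedKMResult:
    """Two-arm Kaplan-Meier / log-rank analysis split on exposure fraction.

    ``relative_exposure`` maps sample_id to the fraction of that sample's
    mutations attributed to one signature.  The high arm is exposure
    strictly greater than ``threshold``.  Samples without survival
    information (G4) are excluded; G3 samples are right-censored at last
    follow-up.  With an empty arm the result carries ``undefined=True``
    instead of a test.
    """
    if not (0 < threshold < 1):
        raise ValueError("threshold must be a fraction in (0, 1)")
    df = _clean_clinical(clinical)
    df["group"] = assign_groups(df)["group"].to_numpy()
    df = df[df["group"] != Group.G4.value]
    expo = relative_exposure.copy()
    expo.index = expo.index.astype(str)
    df = df[df["sample_id"].isin(expo.index)]

    df["high"] = expo.reindex(df["sample_id"]).to_numpy() > threshold
    df["observed"] = df["event"] == "dead"

    hi = df[df["high"]]
    lo = df[~df["high"]]
    if len(hi) < 2 or len(lo) < 2:
        return StratifiedKMResult(
            threshold=threshold,
            n_high=len(hi),
            n_low=len(lo),
            logrank_statistic=None,
            p_value=None,
            median_high=None,
            median_low=None,
            undefined=True,
        )

    km_hi, km_lo = KaplanMeierFitter(), KaplanMeierFitter()
    km_hi.fit(hi["survival_months"], hi["observed"], label="high")
    km_lo.fit(lo["survival_months"], lo["observed"], label="low")
    res = logrank_test(
        hi["survival_months"],
        lo["survival_months"],
        event_observed_A=hi["observed"],
        event_observed_B=lo["observed"],
    )

    def _median(km):
        m = km.median_survival_time_
        return None if np.isinf(m) else float(m)

    return StratifiedKMResult(
        threshold=threshold,
        n_high=len(hi),
        n_low=len(lo),
        logrank_statistic=float(res.test_statistic),
        p_value=float(res.p_value),
        median_high=_median(km_hi),
        median_low=_median(km_lo),
        km_high=_km_table(km_hi),
        km_low=_km_table(km_lo),
    )


def read_clinical(path) -> pd.DataFrame:
    """Read a clinical TSV (sample_id, survival_months, vital_status)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "vital_status" in df.columns and "event" not in df.columns:
        df = df.rename(columns={"vital_status": "event"})
    need = {"sample_id", "survival_months", "event"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"clinical table missing column(s): {sorted(missing)}")
    return df
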