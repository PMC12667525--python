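"""Control-normalized serial efficacy/toxicity quantification.

Fibrosis (integrated reporter fluorescence) and cell number (nuclei count)
are normalized per day to the mean of the normal-control (NC) organoids at
that day, so treatment effects are expressed as fold change vs control and
per-batch gain drift cancels. Per (treatment, day), normalized values are
compared to the reference group with a Welch two-sample t-test;
Benjamini-Hochberg adjustment is applied across all comparisons of a run
and significance tiers assigned at adjusted p < 0.05 / 0.01 / 0.001 /
0.0001 (ns / * / ** / *** / ****). A treatment is flagged as toxic at a
day when its mean normalized cell number falls below a threshold (default
0.7) *and* the drop is significant vs control.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .features import FeatureMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "TIER_THRESHOLDS",
    "normalize_to_control",
    "compare_treatments",
    "toxicity_flag",
]

# adjusted-p thresholds for the significance tiers, most stringent last
TIER_THRESHOLDS = (
    (0.0001, "****"),
    (0.001, "***"),
    (0.01, "**"),
    (0.05, "*"),
)

FIBROSIS_FEATURE = "fibrosis_intden"
CELLNUM_FEATURE = "nuclei_count"


def significance_tier(adjusted_p: float) -> str:
    for thresh, tier in TIER_THRESHOLDS:
        if adjusted_p < thresh:
            return tier
    return "ns"


@dataclass(frozen=True)
class NormalizationError(Exception):
    day: int
    message: str

    def __str__(self) -> str:
        return f"day {self.day}: {self.message}"


def normalize_to_control(
    matrix: FeatureMatrix,
    control_label: str = "NC",
    batch_means: bool = False,
) -> pd.DataFrame:
    """Per-day normalization of fibrosis and cell number to the control mean.

    Requires a raw (unscaled) matrix. Returns one row per observation with
    columns (treatment, day, batch, fibrosis_raw, cellnum_raw,
    fibrosis_norm, cellnum_norm). fibrosis_norm = fibrosis_raw / mean of
    the control's fibrosis_raw at the same day (likewise cellnum); days
    where the control is absent are excluded with a warning; a control
    whose per-day mean is zero is an error (undefined normalization).

    With ``batch_means=True`` observations are first aggregated to batch
    means, matching designs where the batch is the replication unit.
    """
    if matrix.scaled:
        raise ValueError("normalization operates on raw (unscaled) features")
    df = pd.DataFrame(
        {
            "treatment": matrix.labels["treatment"],
            "day": matrix.labels["day"],
            "batch": matrix.labels["batch"],
            "fibrosis_raw": matrix.values[FIBROSIS_FEATURE],
            "cellnum_raw": matrix.values[CELLNUM_FEATURE],
        }
    )
    if batch_means:
        df = (
            df.groupby(["treatment", "day", "batch"], as_index=False)[
                ["fibrosis_raw", "cellnum_raw"]
            ].mean()
        )
    else:
        df = df.reset_index()

    out = []
    for day, day_df in df.groupby("day", sort=True):
        nc = day_df[day_df["treatment"] == control_label]
        if nc.empty:
            logger.warning("day %s has no %r organoids; excluded", day, control_label)
            continue
        nc_fib = float(nc["fibrosis_raw"].mean())
        nc_cell = float(nc["cellnum_raw"].mean())
        if nc_fib <= 0 or nc_cell <= 0:
            raise NormalizationError(
                int(day), f"control mean is zero ({control_label}); normalization undefined"
            )
        day_df = day_df.assign(
            fibrosis_norm=day_df["fibrosis_raw"] / nc_fib,
            cellnum_norm=day_df["cellnum_raw"] / nc_cell,
        )
        out.append(day_df)
    if not out:
        raise ValueError(f"no day contains the control {control_label!r}")
    return pd.concat(out, ignore_index=True)


def compare_treatments(
    points: pd.DataFrame,
    reference_label: str = "NC",
    value: str = "fibrosis_norm",
) -> pd.DataFrame:
    """Welch tests of each (treatment, day) group against the reference.

    Returns one row per comparison with the effect (ratio of group means),
    raw Welch p-value, Benjamini-Hochberg adjusted p across all comparisons
    of the run, and the significance tier. Groups with fewer than 2
    observations (on either side) are skipped and logged.
    """
    rows = []
    for day, day_df in points.groupby("day", sort=True):
        ref = day_df.loc[day_df["treatment"] == reference_label, value].to_numpy()
        for treatment, sub in day_df.groupby("treatment", sort=True):
            if treatment == reference_label:
                continue
            x = sub[value].to_numpy(dtype=np.float64)
            if len(x) < 2 or len(ref) < 2:
                logger.warning(
                    "skipping %s day %s: <2 observations in a group", treatment, day
                )
                continue
            if np.array_equal(x, ref):
                t_p = 1.0  # identical data: no evidence of a difference
            else:
                t_p = float(stats.ttest_ind(x, ref, equal_var=False).pvalue)
                if np.isnan(t_p):  # zero variance in both groups, unequal means
                    t_p = 0.0 if x.mean() != ref.mean() else 1.0
            ref_mean = float(ref.mean())
            rows.append(
                {
                    "treatment": treatment,
                    "day": int(day),
                    "effect": float(x.mean()) / ref_mean if ref_mean != 0 else np.inf,
                    "p_value": t_p,
                    "n_treatment": len(x),
                    "n_reference": len(ref),
                }
            )
    result = pd.DataFrame(rows)
    if result.empty:
        return result.reindex(
            columns=["treatment", "day", "effect", "p_value", "adjusted_p",
                     "significance_tier", "n_treatment", "n_reference"]
        )
    result["adjusted_p"] = multipletests(result["p_value"], method="fdr_bh")[1]
    result["significance_tier"] = result["adjusted_p"].map(significance_tier)
    return result


def toxicity_flag(
    points: pd.DataFrame,
    reference_label: str = "NC",
    threshold: float = 0.7,
) -> pd.DataFrame:
    """Flag (treatment, day) groups with a significant drop in cell number.

    A group is toxic when its mean normalized cell number is below
    ``threshold`` and the Welch/BH comparison of cellnum_norm vs the
    reference has adjusted p < 0.05. Returns one row per (treatment, day)
    with mean_cellnum_norm, adjusted_p and the flag.
    """
    comparisons = compare_treatments(points, reference_label, value="cellnum_norm")
    means = (
        points[points["treatment"] != reference_label]
        .groupby(["treatment", "day"], as_index=False)["cellnum_norm"]
        .mean()
        .rename(columns={"cellnum_norm": "mean_cellnum_norm"})
    )
    if comparisons.empty:
        means["adjusted_p"] = np.nan
        means["toxic"] = False
        return means
    out = means.merge(
        comparisons[["treatment", "day", "adjusted_p", "effect"]],
        on=["treatment", "day"],
        how="left",
    )
    out["toxic"] = (
        (out["mean_cellnum_norm"] < threshold)
        & (out["effect"] < 1.0)
        & (out["adjusted_p"] < 0.05)
    ).fillna(False)
    return out
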