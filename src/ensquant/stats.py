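"""Cohort statistics: Welch's t-test and relative qPCR quantification.

Group comparisons use Welch's unequal-variance t-test with the
Welch-Satterthwaite degrees of freedom, matching the convention of
reporting means +/- s.e.m. with significance stars.  Gene expression is
summarised by the ddCT method: per-sample dCT = CT_target - CT_reference,
baselined to the control-group mean dCT, fold change 2^(-ddCT); group
significance is assessed on dCT values (not folds) by Welch's t-test.
"""

from __future__ import annotations

from collections import namedtuple

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["welch_t", "significance_stars", "ddct_fold_change"]

WelchResult = namedtuple("WelchResult", "t df p")

STAR_LEVELS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


def welch_t(sample_a, sample_b) -> WelchResult:
    """Welch's two-sided unequal-variance t-test.

    t = (mean_a - mean_b) / sqrt(s_a^2/n_a + s_b^2/n_b), with
    Welch-Satterthwaite degrees of freedom.  Two samples that are exactly
    identical (both variances zero, equal means) give t = 0, p = 1; zero
    variance with distinct means gives an infinite t, p = 0.
    """
    a = np.asarray(sample_a, dtype=np.float64)
    b = np.asarray(sample_b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("samples must be finite")
    na, nb = a.size, b.size
    va, vb = a.var(ddof=1), b.var(ddof=1)
    diff = a.mean() - b.mean()
    if va == 0.0 and vb == 0.0:
        if diff == 0.0:
            return WelchResult(0.0, float(na + nb - 2), 1.0)
        return WelchResult(float(np.sign(diff) * np.inf), float(na + nb - 2), 0.0)
    se2 = va / na + vb / nb
    t = diff / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return WelchResult(float(t), float(df), float(min(p, 1.0)))


def significance_stars(p: float) -> str:
    """Stars at the 0.05 / 0.01 / 0.001 / 0.0001 levels; 'ns' otherwise."""
    for level, stars in STAR_LEVELS:
        if p <= level:
            return stars
    return "ns"


def ddct_fold_change(
    table: pd.DataFrame,
    control_group: str,
    reference_gene: str = "Gapdh",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Relative expression by the ddCT method.

    ``table`` has one row per (sample, gene) with columns ``sample``,
    ``group``, ``gene``, ``ct``; a not-detected target is an NaN ``ct``.
    Every sample must have a CT for ``reference_gene``.

    Returns ``(per_sample, summary)``.  Per sample and target gene:
    dCT = CT_target - CT_reference, ddCT = dCT - mean(control dCT),
    fold = 2^(-ddCT) (0.0, flagged, when not detected).  The summary's
    point fold estimate is 2^(-mean ddCT), which is exactly 1 for the
    control group by construction; Welch's t-test compares dCT values of
    each group against the control.
    """
    required = {"sample", "group", "gene", "ct"}
    if not required.issubset(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    if control_group not in set(table["group"]):
        raise ValueError(f"control group {control_group!r} not present")
    ref = table[table["gene"] == reference_gene].set_index("sample")["ct"]
    if ref.isna().any() or ref.empty:
        raise ValueError(f"reference gene {reference_gene!r} missing or not detected")
    targets = [g for g in table["gene"].unique() if g != reference_gene]
    per_rows, sum_rows = [], []
    for gene in targets:
        sub = table[table["gene"] == gene].copy()
        missing = set(sub["sample"]) - set(ref.index)
        if missing:
            raise ValueError(f"samples {sorted(missing)} lack reference CT")
        sub["dct"] = sub["ct"].to_numpy() - ref.loc[sub["sample"]].to_numpy()
        ctrl_dct = sub.loc[sub["group"] == control_group, "dct"]
        detected_ctrl = ctrl_dct.dropna()
        baseline = detected_ctrl.mean() if len(detected_ctrl) else np.nan
        sub["ddct"] = sub["dct"] - baseline
        sub["detected"] = sub["ct"].notna()
        sub["fold"] = np.where(sub["detected"], np.power(2.0, -sub["ddct"]), 0.0)
        per_rows.append(sub)
        for grp, gdf in sub.groupby("group", sort=True):
            folds = gdf["fold"].to_numpy()
            detected = gdf["detected"].to_numpy()
            mean_ddct = gdf.loc[gdf["detected"], "ddct"].mean()
            if not detected.any():
                point = 0.0
            elif grp == control_group:
                point = 1.0  # baselined to its own mean dCT by construction
            else:
                point = float(2.0 ** (-mean_ddct))
            if grp == control_group or not detected.any():
                p = np.nan if grp == control_group else _nd_p(gdf, ctrl_dct)
            else:
                ctrl = detected_ctrl.to_numpy()
                this = gdf.loc[gdf["detected"], "dct"].to_numpy()
                p = (
                    welch_t(this, ctrl).p
                    if len(this) >= 2 and len(ctrl) >= 2
                    else np.nan
                )
            sem = folds.std(ddof=1) / np.sqrt(len(folds)) if len(folds) > 1 else 0.0
            sum_rows.append(
                {
                    "gene": gene,
                    "group": grp,
                    "n": len(gdf),
                    "fold_point": point if detected.any() else 0.0,
                    "fold_mean": float(folds.mean()),
                    "fold_sem": float(sem),
                    "detected_fraction": float(detected.mean()),
                    "welch_p_dct": p,
                }
            )
    per_sample = pd.concat(per_rows, ignore_index=True)
    summary = pd.DataFrame(sum_rows)
    return per_sample, summary


def _nd_p(gdf: pd.DataFrame, ctrl_dct: pd.Series) -> float:
    # all-not-detected target group: no dCT to test against
    return np.nan
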