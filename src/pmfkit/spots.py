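"""Differential 2D-gel spot screening on replicate spot-quantity tables.

Spot quantities are intensity x area in ppm of total gel signal, one column
per replicate gel, with each gel belonging to one of two groups.  A spot is
of interest when its between-group fold change exceeds a threshold (default
1.5) *and* a two-sample t-test rejects at a given level (default 0.05).  The
t-test is computed on log-transformed quantities by default, which is the
natural scale for gel densitometry; no multiple-testing correction is
applied by default, with Benjamini-Hochberg available as an option.

The follow-up ranking that shortlists selected spots by intensity,
between-group ratio and within-replicate consistency is a reconstruction
with configurable weights, not a calibrated score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DEFAULT_FOLD_THRESHOLD = 1.5
DEFAULT_P_THRESHOLD = 0.05

#: Default ranking weights: spot intensity, |log fold change|, and
#: within-group coefficient of variation (consistency) count equally.
DEFAULT_RANK_WEIGHTS: dict[str, float] = {
    "intensity": 1.0, "fold": 1.0, "consistency": 1.0}


@dataclass(frozen=True)
class SpotTable:
    """Replicate spot quantities for a two-group comparison.

    ``quantities`` is spots x samples (non-negative, ppm units); ``groups``
    assigns each sample column to one of exactly two group labels.  NaN marks
    a spot not quantified on a given gel.
    """

    quantities: pd.DataFrame
    groups: Mapping[str, str]  # sample column -> group label

    def __post_init__(self) -> None:
        q = self.quantities
        missing = [c for c in q.columns if c not in self.groups]
        if missing:
            raise ValueError(f"samples without a group label: {missing}")
        labels = sorted(set(self.groups[c] for c in q.columns))
        if len(labels) != 2:
            raise ValueError(f"exactly two groups required, got {labels}")
        if (q.values[~np.isnan(q.values.astype(float))] < 0).any():
            raise ValueError("spot quantities must be non-negative")
        for g in labels:
            n = sum(1 for c in q.columns if self.groups[c] == g)
            if n < 2:
                raise ValueError(
                    f"group {g!r} has {n} replicate(s); need >= 2 for testing")
        object.__setattr__(self, "groups", dict(self.groups))

    @property
    def group_labels(self) -> tuple[str, str]:
        return tuple(sorted(set(self.groups[c] for c in self.quantities.columns)))

    def columns_of(self, group: str) -> list[str]:
        return [c for c in self.quantities.columns if self.groups[c] == group]


def screen_spots(
    table: SpotTable,
    fold_threshold: float = DEFAULT_FOLD_THRESHOLD,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    log_transform: bool = True,
    equal_var: bool = True,
    fdr: bool = False,
) -> pd.DataFrame:
    """Fold-change + t-test screen; one row per spot.

    Columns: ``mean_<group>`` for both groups, ``fold_change`` (larger group
    mean over smaller, always >= 1), ``direction`` (the higher group's
    label), ``p_value`` (two-sided two-sample t-test; Welch when
    ``equal_var=False``), ``cv_<group>`` (within-group coefficient of
    variation on the raw scale), ``selected`` (fold > fold_threshold AND
    p < p_threshold), and ``excluded_reason`` (non-empty when a spot could
    not be tested: zero signal in both groups or fewer than two complete
    replicates in a group).  With ``fdr=True`` a ``q_value`` column
    (Benjamini-Hochberg) is added and used in place of the raw p for
    selection.

    Spots with missing values are analysed on their complete replicates and
    flagged in ``excluded_reason`` only if a group drops below two.
    """
    ga, gb = table.group_labels
    cols_a, cols_b = table.columns_of(ga), table.columns_of(gb)
    q = table.quantities.astype(float)
    A = q[cols_a].to_numpy()
    B = q[cols_b].to_numpy()

    def analyse(a: np.ndarray, b: np.ndarray) -> dict:
        rec: dict = {f"mean_{ga}": np.nan, f"mean_{gb}": np.nan,
                     "fold_change": np.nan, "direction": "",
                     "p_value": np.nan,
                     f"cv_{ga}": np.nan, f"cv_{gb}": np.nan,
                     "n_complete": len(a) + len(b),
                     "excluded_reason": ""}
        if len(a) < 2 or len(b) < 2:
            rec["excluded_reason"] = "fewer than 2 complete replicates in a group"
            return rec
        ma, mb = a.mean(), b.mean()
        rec[f"mean_{ga}"], rec[f"mean_{gb}"] = ma, mb
        if ma == 0 and mb == 0:
            rec["excluded_reason"] = "zero mean quantity in both groups"
            return rec
        rec[f"cv_{ga}"] = a.std(ddof=1) / ma if ma > 0 else np.inf
        rec[f"cv_{gb}"] = b.std(ddof=1) / mb if mb > 0 else np.inf
        hi, lo = (ma, mb) if ma >= mb else (mb, ma)
        rec["fold_change"] = np.inf if lo == 0 else hi / lo
        rec["direction"] = ga if ma >= mb else gb
        if log_transform:
            if (a <= 0).any() or (b <= 0).any():
                rec["excluded_reason"] = "zero quantity prevents log transform"
                return rec
            a, b = np.log(a), np.log(b)
        rec["p_value"] = float(stats.ttest_ind(a, b, equal_var=equal_var).pvalue)
        return rec

    complete = ~np.isnan(A).any(axis=1) & ~np.isnan(B).any(axis=1)
    positive = np.ones(len(q), dtype=bool)
    if log_transform:
        positive = (np.nan_to_num(A, nan=1.0) > 0).all(axis=1) & \
                   (np.nan_to_num(B, nan=1.0) > 0).all(axis=1)
    fast = complete & positive & ~((A == 0).all(axis=1) & (B == 0).all(axis=1))

    records: list[dict] = [None] * len(q)  # type: ignore[list-item]
    if fast.any():
        a_f, b_f = A[fast], B[fast]
        ma, mb = a_f.mean(axis=1), b_f.mean(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            cv_a = np.where(ma > 0, a_f.std(axis=1, ddof=1) / ma, np.inf)
            cv_b = np.where(mb > 0, b_f.std(axis=1, ddof=1) / mb, np.inf)
            fold = np.where(np.minimum(ma, mb) > 0,
                            np.maximum(ma, mb) / np.minimum(ma, mb), np.inf)
        ta, tb = (np.log(a_f), np.log(b_f)) if log_transform else (a_f, b_f)
        pvals = stats.ttest_ind(ta, tb, axis=1, equal_var=equal_var).pvalue
        for pos, i in enumerate(np.flatnonzero(fast)):
            records[i] = {
                f"mean_{ga}": ma[pos], f"mean_{gb}": mb[pos],
                "fold_change": fold[pos],
                "direction": ga if ma[pos] >= mb[pos] else gb,
                "p_value": float(pvals[pos]),
                f"cv_{ga}": cv_a[pos], f"cv_{gb}": cv_b[pos],
                "n_complete": A.shape[1] + B.shape[1],
                "excluded_reason": ""}
    for i in np.flatnonzero(~fast):
        records[i] = analyse(A[i][~np.isnan(A[i])], B[i][~np.isnan(B[i])])

    result = pd.DataFrame(records, index=q.index.rename("spot"))
    testable = result["excluded_reason"].eq("") & result["p_value"].notna()
    p_for_selection = result["p_value"].copy()
    if fdr:
        q_values = pd.Series(np.nan, index=result.index)
        if testable.any():
            q_values.loc[testable] = multipletests(
                result.loc[testable, "p_value"], method="fdr_bh")[1]
        result["q_value"] = q_values
        p_for_selection = q_values
    result["selected"] = (
        testable
        & (result["fold_change"] > fold_threshold)
        & (p_for_selection < p_threshold)
    )
    result.attrs["fold_threshold"] = fold_threshold
    result.attrs["p_threshold"] = p_threshold
    result.attrs["log_transform"] = log_transform
    result.attrs["equal_var"] = equal_var
    result.attrs["groups"] = (ga, gb)
    return result


def rank_spots(
    result: pd.DataFrame,
    weights: Mapping[str, float] | None = None,
    selected_only: bool = True,
) -> pd.DataFrame:
    """Composite ranking of screened spots.

    Each spot gets three per-metric ranks — mean intensity (higher is
    better), |log fold change| (higher is better), and the worse of the two
    within-group coefficients of variation (lower is better) — combined as a
    weighted average; the output is sorted by that composite, ties broken by
    spot id.  Adds ``rank`` (1 = best) and ``rank_score`` columns.
    """
    weights = dict(DEFAULT_RANK_WEIGHTS, **(weights or {}))
    unknown = set(weights) - set(DEFAULT_RANK_WEIGHTS)
    if unknown:
        raise ValueError(f"unknown ranking weights: {sorted(unknown)}")
    pool = result[result["selected"]] if selected_only else result
    pool = pool[pool["excluded_reason"].eq("")]
    if pool.empty:
        out = pool.copy()
        out["rank_score"] = pd.Series(dtype=float)
        out["rank"] = pd.Series(dtype=int)
        return out
    ga, gb = result.attrs.get(
        "groups",
        tuple(c.removeprefix("mean_") for c in result.columns
              if c.startswith("mean_"))[:2],
    )
    mean_intensity = (pool[f"mean_{ga}"] + pool[f"mean_{gb}"]) / 2
    log_fold = np.log(pool["fold_change"].replace(np.inf, np.nan))
    log_fold = log_fold.fillna(log_fold.max() if log_fold.notna().any() else 0.0)
    worst_cv = pool[[f"cv_{ga}", f"cv_{gb}"]].max(axis=1)

    # rank 1 = best on each metric; average ranks keep ties symmetric
    r_int = mean_intensity.rank(ascending=False)
    r_fold = log_fold.abs().rank(ascending=False)
    r_cv = worst_cv.rank(ascending=True)
    total_w = sum(weights.values())
    if total_w <= 0:
        raise ValueError("ranking weights must not all be zero")
    score = (weights["intensity"] * r_int + weights["fold"] * r_fold
             + weights["consistency"] * r_cv) / total_w
    out = pool.copy()
    out["rank_score"] = score
    # ties broken by spot id: stable sort on score after an index sort
    out = out.sort_index(kind="stable").sort_values("rank_score", kind="stable")
    out["rank"] = np.arange(1, len(out) + 1)
    return out
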