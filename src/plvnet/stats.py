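"""Group-difference and brain-behavior inference.

Non-parametric permutation tests (statistic: group mean difference,
two-sided), Pearson correlations, and the classical demographic tests
(pooled-variance t, Pearson chi-square without continuity correction).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import (
    InvalidParameterError,
    SubjectMismatchError,
    UndefinedCorrelationError,
)

__all__ = [
    "PermutationResult",
    "CorrelationResult",
    "permutation_test",
    "pearson_correlation",
    "two_sample_t",
    "chi_square_2x2",
    "group_contrast_sweep",
    "rt_metric_correlations",
    "demographic_tests",
]

GLOBAL_METRICS = ("L", "C", "Eglobal", "Elocal")


@dataclass(frozen=True)
class PermutationResult:
    observed: float
    p_value: float
    n_permutations: int
    seed: int | None
    tail: str = "two-sided"


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_value: float
    n: int


def permutation_test(
    values_a,
    values_b,
    n_permutations: int = 10_000,
    seed: int | None = None,
) -> PermutationResult:
    """Two-sided permutation test of the group mean difference.

    p = (#{|perm stat| >= |observed|} + 1) / (n_permutations + 1), so p is
    never smaller than 1/(n_permutations + 1).  Deterministic given seed.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InvalidParameterError("both samples must be non-empty")
    if n_permutations < 1:
        raise InvalidParameterError("n_permutations must be >= 1")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        warnings.warn("zero variance in pooled sample; p = 1", stacklevel=2)
        return PermutationResult(0.0, 1.0, n_permutations, seed)
    observed = a.mean() - b.mean()
    rng = np.random.default_rng(seed)
    n_a = a.size
    perms = rng.permuted(
        np.broadcast_to(pooled, (n_permutations, pooled.size)), axis=1
    )
    stats = perms[:, :n_a].mean(axis=1) - perms[:, n_a:].mean(axis=1)
    count = int(np.sum(np.abs(stats) >= abs(observed) - 1e-12))
    p = (count + 1) / (n_permutations + 1)
    return PermutationResult(float(observed), float(p), n_permutations, seed)


def pearson_correlation(x, y) -> CorrelationResult:
    """Pearson r with a two-sided t-distribution p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidParameterError("x and y must be equal-length 1-D")
    if x.size < 3:
        raise InvalidParameterError("need n >= 3 for a correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("correlation undefined for constant input")
    res = sps.pearsonr(x, y)
    return CorrelationResult(float(res.statistic), float(res.pvalue), x.size)


def two_sample_t(values_a, values_b) -> tuple[float, float]:
    """Pooled-variance (equal-variance) two-sample t-test."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InvalidParameterError("need n >= 2 per group")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        raise InvalidParameterError("zero pooled variance")
    t, p = sps.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def chi_square_2x2(table) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, 1 df, no continuity correction."""
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise InvalidParameterError("table must be 2x2")
    if np.any(obs < 0):
        raise InvalidParameterError("counts must be non-negative")
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise InvalidParameterError("zero marginal total")
    chi2, p, _, _ = sps.chi2_contingency(obs, correction=False)
    return float(chi2), float(p)


# ---------------------------------------------------------------------------
# Sweep-level contrasts
# ---------------------------------------------------------------------------


def _split_by_group(
    df: pd.DataFrame, cohort: pd.DataFrame, value_col: str
) -> tuple[np.ndarray, np.ndarray]:
    merged = df.merge(cohort[["subject_id", "group"]], on="subject_id", how="left")
    if merged["group"].isna().any():
        missing = merged.loc[merged["group"].isna(), "subject_id"].unique()
        raise SubjectMismatchError(f"subjects missing from cohort: {missing}")
    groups = sorted(merged["group"].unique())
    if len(groups) != 2:
        raise SubjectMismatchError(f"need exactly 2 groups, got {groups}")
    # TC first when present so `observed` reads TC - control
    if "TC" in groups:
        groups = ["TC"] + [g for g in groups if g != "TC"]
    a = merged.loc[merged["group"] == groups[0], value_col].to_numpy()
    b = merged.loc[merged["group"] == groups[1], value_col].to_numpy()
    return a, b


def group_contrast_sweep(
    metric_table: pd.DataFrame,
    cohort: pd.DataFrame,
    n_permutations: int = 10_000,
    seed: int | None = None,
    nodal_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Permutation contrasts per band for every metric.

    For each band, tests the across-grid mean of each global metric
    ("range" rows) and every grid point ("threshold" rows); if a nodal
    table is given, also contrasts each channel's across-grid mean degree.
    Emits uncorrected p plus Benjamini-Hochberg-adjusted p across the grid
    (within band x metric).

    Output columns: ``band, level, sparsity, metric, stat, p, p_bh``.
    """
    required = {"subject_id", "band", "sparsity", *GLOBAL_METRICS}
    if not required.issubset(metric_table.columns):
        raise InvalidParameterError(
            f"metric table missing columns {required - set(metric_table.columns)}"
        )
    rows = []
    rng = np.random.default_rng(seed)
    for band, band_df in metric_table.groupby("band", sort=True):
        for metric in GLOBAL_METRICS:
            # range level: across-grid mean per subject
            per_subject = (
                band_df.groupby("subject_id", as_index=False)[metric].mean()
            )
            a, b = _split_by_group(per_subject, cohort, metric)
            res = permutation_test(
                a, b, n_permutations, int(rng.integers(2**31))
            )
            rows.append(
                {
                    "band": band,
                    "level": "range",
                    "sparsity": np.nan,
                    "metric": metric,
                    "stat": res.observed,
                    "p": res.p_value,
                }
            )
            for s, s_df in band_df.groupby("sparsity", sort=True):
                a, b = _split_by_group(
                    s_df[["subject_id", metric]], cohort, metric
                )
                res = permutation_test(
                    a, b, n_permutations, int(rng.integers(2**31))
                )
                rows.append(
                    {
                        "band": band,
                        "level": "threshold",
                        "sparsity": s,
                        "metric": metric,
                        "stat": res.observed,
                        "p": res.p_value,
                    }
                )
        if nodal_table is not None:
            mean_deg = nodal_table[
                (nodal_table["band"] == band)
                & (nodal_table["sparsity"] == "mean")
            ]
            for ch, ch_df in mean_deg.groupby("channel", sort=True):
                a, b = _split_by_group(
                    ch_df[["subject_id", "degree"]], cohort, "degree"
                )
                res = permutation_test(
                    a, b, n_permutations, int(rng.integers(2**31))
                )
                rows.append(
                    {
                        "band": band,
                        "level": "nodal",
                        "sparsity": np.nan,
                        "metric": f"degree:{ch}",
                        "stat": res.observed,
                        "p": res.p_value,
                    }
                )
    out = pd.DataFrame(rows)
    out["p_bh"] = np.nan
    thr = out["level"] == "threshold"
    for (_, _), idx in out[thr].groupby(["band", "metric"]).groups.items():
        out.loc[idx, "p_bh"] = multipletests(
            out.loc[idx, "p"].to_numpy(), method="fdr_bh"
        )[1]
    return out


def rt_metric_correlations(
    metric_table: pd.DataFrame, cohort: pd.DataFrame
) -> pd.DataFrame:
    """Within-group Pearson correlation of mean RT vs. each global metric.

    Metrics are the per-subject across-grid means, per band.  Output
    columns: ``band, group, metric, r, p, n``.
    """
    rows = []
    merged_cols = cohort[["subject_id", "group", "rt_ms"]]
    for band, band_df in metric_table.groupby("band", sort=True):
        per_subject = band_df.groupby("subject_id", as_index=False)[
            list(GLOBAL_METRICS)
        ].mean()
        merged = per_subject.merge(merged_cols, on="subject_id", how="inner")
        for group, g_df in merged.groupby("group", sort=True):
            for metric in GLOBAL_METRICS:
                if len(g_df) < 3:
                    continue
                try:
                    res = pearson_correlation(
                        g_df["rt_ms"].to_numpy(), g_df[metric].to_numpy()
                    )
                except UndefinedCorrelationError:
                    continue
                rows.append(
                    {
                        "band": band,
                        "group": group,
                        "metric": metric,
                        "r": res.r,
                        "p": res.p_value,
                        "n": res.n,
                    }
                )
    return pd.DataFrame(rows)


def demographic_tests(
    cohort: pd.DataFrame,
    n_permutations: int = 10_000,
    seed: int | None = None,
) -> dict:
    """Age t-test, sex chi-square, and RT/questionnaire permutation tests."""
    groups = sorted(cohort["group"].unique())
    if "TC" in groups:
        groups = ["TC"] + [g for g in groups if g != "TC"]
    g_a = cohort[cohort["group"] == groups[0]]
    g_b = cohort[cohort["group"] == groups[1]]
    out: dict = {"groups": groups}
    t, p = two_sample_t(g_a["age"], g_b["age"])
    out["age_t"] = {"t": t, "p": p}
    table = [
        [(g["sex"] == "M").sum(), (g["sex"] == "F").sum()] for g in (g_a, g_b)
    ]
    chi2, p = chi_square_2x2(table)
    out["sex_chi2"] = {"chi2": chi2, "p": p, "table": table}
    rng = np.random.default_rng(seed)
    for col in ("rt_ms", "psycap_total"):
        if col in cohort.columns:
            res = permutation_test(
                g_a[col].to_numpy(),
                g_b[col].to_numpy(),
                n_permutations,
                int(rng.integers(2**31)),
            )
            out[col] = {"observed": res.observed, "p": res.p_value}
    return out
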