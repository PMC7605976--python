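"""Cohort-level statistics for body-composition studies.

Sex-stratified group summaries (mean/SD per age band), one-way fixed-effects
ANOVA across age groups, and Pearson correlations between the fat-related
muscle components (LAMA, IMAT, myosteatosis) and muscle densities or fat
areas.  Correlation magnitudes are reported with the interpretation bands
conventional in this literature: |r| < 0.1 negligible, 0.1–0.4 weak,
0.4–0.7 moderate, 0.7–0.9 strong, 0.9–1 very strong (a tie at a cutpoint
goes to the higher band; the sign is reported separately).

No multiple-testing correction is applied — each test is reported at the
nominal level, noted in the output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from musclemap.errors import InputError, SchemaError, StatsError

__all__ = [
    "GroupComparisonResult",
    "CorrelationResult",
    "one_way_anova",
    "pearson",
    "correlation_band",
    "summarize_cohort",
]

DEFAULT_ALPHA = 0.05

#: (lower |r| cutpoint, band label), highest first; ties go up
_BANDS = (
    (0.9, "very strong"),
    (0.7, "strong"),
    (0.4, "moderate"),
    (0.1, "weak"),
    (0.0, "negligible"),
)


@dataclass(frozen=True)
class GroupComparisonResult:
    variable: str
    group_ns: tuple[int, ...]
    group_means: tuple[float, ...]
    group_sds: tuple[float, ...]
    f: float
    df_between: int
    df_within: int
    p: float
    alpha: float = DEFAULT_ALPHA

    @property
    def significant(self) -> bool:
        return bool(np.isfinite(self.p) and self.p < self.alpha)


@dataclass(frozen=True)
class CorrelationResult:
    x_name: str
    y_name: str
    r: float
    p: float
    band: str
    n: int
    alpha: float = DEFAULT_ALPHA

    @property
    def significant(self) -> bool:
        return bool(np.isfinite(self.p) and self.p < self.alpha)


def one_way_anova(
    groups, variable: str = "", alpha: float = DEFAULT_ALPHA
) -> GroupComparisonResult:
    """Classical fixed-effects one-way ANOVA.

    F = MS_between / MS_within with df (k-1, N-k); the p-value is the upper
    tail of the F distribution.  With zero between-group *and* zero
    within-group variance F is undefined and reported as NaN; zero
    within-group variance alone gives F = inf, p = 0.
    """
    arrays = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(arrays) < 2:
        raise InputError("ANOVA needs at least 2 groups")
    for i, a in enumerate(arrays):
        if a.size < 2:
            raise InputError(f"ANOVA group {i} has fewer than 2 observations")
        if not np.all(np.isfinite(a)):
            raise InputError(f"ANOVA group {i} contains non-finite values")

    k = len(arrays)
    ns = np.array([a.size for a in arrays])
    n_total = int(ns.sum())
    means = np.array([a.mean() for a in arrays])
    grand = np.concatenate(arrays).mean()
    ssb = float(np.sum(ns * (means - grand) ** 2))
    ssw = float(sum(np.sum((a - m) ** 2) for a, m in zip(arrays, means)))
    df_b, df_w = k - 1, n_total - k

    if ssw == 0.0 and ssb == 0.0:
        f = np.nan
        p = np.nan
    elif ssw == 0.0:
        f = np.inf
        p = 0.0
    else:
        f = (ssb / df_b) / (ssw / df_w)
        p = float(stats.f.sf(f, df_b, df_w))
    return GroupComparisonResult(
        variable=variable,
        group_ns=tuple(int(n) for n in ns),
        group_means=tuple(float(m) for m in means),
        group_sds=tuple(float(a.std(ddof=1)) for a in arrays),
        f=float(f),
        df_between=df_b,
        df_within=df_w,
        p=float(p),
        alpha=alpha,
    )


def correlation_band(r: float) -> str:
    """Magnitude band of a correlation coefficient, from |r|."""
    mag = abs(float(r))
    if not np.isfinite(mag) or mag > 1.0 + 1e-12:
        raise InputError(f"|r| must be in [0, 1], got {r!r}")
    mag = min(mag, 1.0)
    for cut, label in _BANDS:
        if mag >= cut:
            return label
    return "negligible"  # pragma: no cover — cut 0.0 always matches


def pearson(
    x,
    y,
    x_name: str = "x",
    y_name: str = "y",
    alpha: float = DEFAULT_ALPHA,
) -> CorrelationResult:
    """Pearson product-moment correlation with a two-sided t-test p-value.

    Requires equal lengths >= 3 and non-constant inputs (the correlation of
    a constant is undefined).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise InputError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 3:
        raise InputError("Pearson correlation needs at least 3 pairs")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise InputError("non-finite values in correlation input")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = float(np.sqrt(np.sum(xc**2)))
    sy = float(np.sqrt(np.sum(yc**2)))
    if sx == 0.0 or sy == 0.0:
        raise StatsError("correlation undefined for constant input")
    r = float(np.clip(np.sum(xc * yc) / (sx * sy), -1.0, 1.0))
    n = int(x.size)
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return CorrelationResult(
        x_name=x_name, y_name=y_name, r=r, p=p, band=correlation_band(r), n=n, alpha=alpha
    )


# ---------------------------------------------------------------------------
# cohort summaries
# ---------------------------------------------------------------------------

SUMMARY_VARIABLES = ("tama_cm2", "nama_cm2", "lama_cm2", "imat_cm2", "myosteatosis_cm2")
CORR_COMPONENTS = ("lama_cm2", "imat_cm2", "myosteatosis_cm2")
CORR_AGAINST = ("mean_tama_density_hu", "mean_sma_density_hu", "vfa_cm2", "sfa_cm2")


def summarize_cohort(
    records: pd.DataFrame,
    stratify: str = "sex",
    group: str = "age_band",
    variables=SUMMARY_VARIABLES,
    alpha: float = DEFAULT_ALPHA,
) -> dict[str, pd.DataFrame]:
    """Per-sex, per-age-band summary tables plus correlation matrices.

    Returns three DataFrames:

    * ``groups`` — one row per stratum x variable x band: n, mean, sd;
    * ``anova`` — one row per stratum x variable: F, df, p, significance
      across bands;
    * ``correlations`` — one row per stratum x fat-component x covariate:
      r, p, magnitude band, n.

    Missing columns raise :class:`SchemaError` naming the column.  Strata
    with a single band get no ANOVA row (nothing to compare).
    """
    required = {stratify, group, *variables, *CORR_COMPONENTS, *CORR_AGAINST}
    missing = sorted(required - set(records.columns))
    if missing:
        raise SchemaError(f"cohort records missing required column(s): {missing}")

    group_rows, anova_rows, corr_rows = [], [], []
    for stratum, sub in records.groupby(stratify, sort=False):
        bands = list(dict.fromkeys(sub[group]))
        for var in variables:
            samples = [sub.loc[sub[group] == b, var].to_numpy() for b in bands]
            for b, s in zip(bands, samples):
                group_rows.append(
                    {
                        stratify: stratum,
                        "variable": var,
                        group: b,
                        "n": len(s),
                        "mean": float(np.mean(s)) if len(s) else np.nan,
                        "sd": float(np.std(s, ddof=1)) if len(s) > 1 else np.nan,
                    }
                )
            if len(bands) >= 2 and all(len(s) >= 2 for s in samples):
                res = one_way_anova(samples, variable=var, alpha=alpha)
                anova_rows.append(
                    {
                        stratify: stratum,
                        "variable": var,
                        "f": res.f,
                        "df_between": res.df_between,
                        "df_within": res.df_within,
                        "p": res.p,
                        "significant": res.significant,
                    }
                )
        for comp in CORR_COMPONENTS:
            for against in CORR_AGAINST:
                res = pearson(
                    sub[comp], sub[against], x_name=comp, y_name=against, alpha=alpha
                )
                corr_rows.append(
                    {
                        stratify: stratum,
                        "component": comp,
                        "against": against,
                        "r": res.r,
                        "p": res.p,
                        "band": res.band,
                        "n": res.n,
                    }
                )
    return {
        "groups": pd.DataFrame(group_rows),
        "anova": pd.DataFrame(anova_rows),
        "correlations": pd.DataFrame(corr_rows),
    }
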