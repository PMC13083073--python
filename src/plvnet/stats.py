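"""Planned group contrasts, coherence-behavior regressions, FDR correction,
and the 3-D coherence feature embedding.

Contrasts are Welch two-sample tests with small-sample bias-corrected
standardized mean differences (Hedges' g) and BCa bootstrap confidence
intervals for the mean difference; families are corrected with
Benjamini-Hochberg FDR. Regressions are ordinary least squares on z-scored
outcome and predictors, so the coherence coefficient is the standardized
beta; age enters as a covariate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .classify import bca_interval

__all__ = [
    "ContrastResult", "RegressionResult", "Embedding3D",
    "hedges_g", "planned_contrasts", "fit_association", "bh_fdr", "embed3d",
]


def hedges_g(sample_a, sample_b) -> float:
    """Bias-corrected standardized mean difference, J * (mA - mB) / s_pooled,
    with J = 1 - 3/(4(nA + nB - 2) - 1)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("need at least 2 observations per sample")
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if sp2 <= 0:
        raise ValueError("zero pooled variance")
    j = 1 - 3 / (4 * (na + nb - 2) - 1)
    return float(j * (a.mean() - b.mean()) / np.sqrt(sp2))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class ContrastResult:
    groups: tuple[str, str]
    mean_a: float
    mean_b: float
    hedges_g: float
    p_raw: float
    q_fdr: float = np.nan
    ci: tuple[float, float] = (np.nan, np.nan)
    n: tuple[int, int] = (0, 0)


def planned_contrasts(
    values: pd.DataFrame,
    group_pairs: list[tuple[str, str]],
    value_col: str = "plv_mean",
    group_col: str = "group",
    n_boot: int = 5000,
    rng: np.random.Generator | int | None = None,
) -> list[ContrastResult]:
    """Welch test + Hedges' g + BCa CI per planned pair, BH-FDR over the family.

    Degenerate contrasts (identical samples, zero variance) get g = 0 and
    p = 1 rather than an error so whole families stay reportable.
    """
    rng = np.random.default_rng(rng)
    results = []
    for ga, gb in group_pairs:
        a = values.loc[values[group_col] == ga, value_col].to_numpy(float)
        b = values.loc[values[group_col] == gb, value_col].to_numpy(float)
        if len(a) < 2 or len(b) < 2:
            raise ValueError(f"group too small for contrast {ga} vs {gb}")
        if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
            g = 0.0
            p = 1.0 if a.mean() == b.mean() else 0.0
            ci = (float(a.mean() - b.mean()),) * 2
        else:
            g = hedges_g(a, b)
            p = float(sps.ttest_ind(a, b, equal_var=False).pvalue)
            ci = bca_interval(
                lambda xa, xb: np.mean(xa) - np.mean(xb), (a, b),
                n_boot=n_boot, rng=rng,
            )
        results.append(ContrastResult(
            groups=(ga, gb), mean_a=float(a.mean()), mean_b=float(b.mean()),
            hedges_g=g, p_raw=p, ci=ci, n=(len(a), len(b)),
        ))
    qs = bh_fdr([r.p_raw for r in results])
    for r, q in zip(results, qs):
        r.q_fdr = float(q)
    return results


@dataclass
class RegressionResult:
    outcome: str
    beta_std: float
    r2: float
    p_raw: float
    n: int
    beta_age: float = np.nan
    q_fdr: float = np.nan
    ci: tuple[float, float] = (np.nan, np.nan)


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("constant predictor cannot be standardized")
    return (x - x.mean()) / sd


def fit_association(outcome, coherence, age=None, outcome_name: str = "outcome"
                    ) -> RegressionResult:
    """OLS of z-scored outcome on z-scored coherence (plus z-scored age).

    Reports the standardized coherence coefficient, model R-squared, the
    coherence coefficient's p-value and 95% CI.
    """
    y = np.asarray(outcome, dtype=float)
    x = np.asarray(coherence, dtype=float)
    cols = [x]
    if age is not None:
        cols.append(np.asarray(age, dtype=float))
    mask = np.isfinite(y)
    for c in cols:
        mask &= np.isfinite(c)
    y, cols = y[mask], [c[mask] for c in cols]
    if len(y) < len(cols) + 3:
        raise ValueError("too few complete cases")
    if len(cols) == 2 and abs(np.corrcoef(cols[0], cols[1])[0, 1]) >= 1 - 1e-12:
        raise ValueError("collinear predictors")
    design = sm.add_constant(np.column_stack([_zscore(c) for c in cols]))
    fit = sm.OLS(_zscore(y), design).fit()
    ci = fit.conf_int()[1]
    return RegressionResult(
        outcome=outcome_name,
        beta_std=float(fit.params[1]),
        r2=float(fit.rsquared),
        p_raw=float(fit.pvalues[1]),
        n=len(y),
        beta_age=float(fit.params[2]) if len(cols) == 2 else np.nan,
        ci=(float(ci[0]), float(ci[1])),
    )


@dataclass
class Embedding3D:
    axis_pairs: list[str]
    coords: pd.DataFrame                  # subject, group, one column per axis pair
    group_ellipsoids: pd.DataFrame        # group x axis -> mean, sd
    separation: pd.DataFrame = field(default_factory=pd.DataFrame)


def embed3d(table: pd.DataFrame, ranked_pairs: list[str],
            reference_group: str = "HC") -> Embedding3D:
    """Project subjects onto the coherence of the top-3 ranked pairs.

    Coordinates are the raw PLV values (identity projection). Ellipsoids are
    axis-aligned per-group mean +/- 1 SD. Separation regresses each axis on
    a group indicator (each non-reference group vs the reference),
    z-scoring the axis, with BH-FDR across the axis family per group.
    """
    if len(ranked_pairs) < 3:
        raise ValueError("need at least 3 ranked pairs")
    axes = list(ranked_pairs[:3])
    wide = table.pivot_table(index=["subject", "group"], columns="pair",
                             values="plv").reset_index()
    missing = [a for a in axes if a not in wide.columns or wide[a].isna().any()]
    if missing:
        raise ValueError(f"subjects missing values for axis pairs {missing}")
    coords = wide[["subject", "group", *axes]]
    ell = (coords.melt(id_vars=["subject", "group"], value_vars=axes,
                       var_name="axis", value_name="value")
           .groupby(["group", "axis"], as_index=False)["value"]
           .agg(mean="mean", sd=lambda v: v.std(ddof=1)))
    sep_rows = []
    other_groups = [g for g in coords["group"].unique() if g != reference_group]
    for grp in other_groups:
        sub = coords[coords["group"].isin([reference_group, grp])]
        indicator = (sub["group"] == grp).astype(float).to_numpy()
        ps = []
        for axis in axes:
            design = sm.add_constant(indicator)
            fit = sm.OLS(_zscore(sub[axis].to_numpy(float)), design).fit()
            sep_rows.append({"group": grp, "axis": axis,
                             "beta_std": float(fit.params[1]),
                             "p_raw": float(fit.pvalues[1])})
            ps.append(float(fit.pvalues[1]))
        qs = bh_fdr(ps)
        for row, q in zip(sep_rows[-len(axes):], qs):
            row["q_fdr"] = float(q)
    return Embedding3D(axis_pairs=axes, coords=coords, group_ellipsoids=ell,
                       separation=pd.DataFrame(sep_rows))
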