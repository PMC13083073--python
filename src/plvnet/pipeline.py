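"""Stage orchestration: chains preprocessing, connectivity, network metrics,
association statistics and classification over a cohort of epoch sets.

Each function is pure given its inputs and a seed, so repeated runs with the
same configuration are identical; the CLI is a thin wrapper around this
module.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .classify import COMPARISONS, ModelReport, run_comparison
from .config import AnalysisConfig
from .connectivity import aggregate, build_bank, pair_plv_table, plv_matrix
from .epochs import EpochArray
from .montage import Montage, load_montage
from .netmetrics import build_graph, subject_graph_metrics
from .pairs import PairSet, default_pairset
from .preprocess import csd, iqr_exclude, reject_amplitude
from .stats import embed3d, fit_association, planned_contrasts

__all__ = [
    "preprocess_epochs", "connectivity_table", "feature_matrix",
    "network_metrics_table", "association_stats", "classification_reports",
    "rank_pairs_by_group_variance", "iqr_filter_subjects",
]


def preprocess_epochs(epochs: EpochArray, montage: Montage,
                      cfg: AnalysisConfig) -> EpochArray:
    """Amplitude-threshold artifact rejection followed by the CSD transform."""
    cleaned = reject_amplitude(epochs, cfg.amplitude_threshold)
    return csd(cleaned, montage, m=cfg.csd.spline_order,
               n_leg=cfg.csd.legendre_degree, lam=cfg.csd.lam)


def connectivity_table(
    epoch_sets: list[EpochArray],
    band: str,
    cfg: AnalysisConfig | None = None,
    pairset: PairSet | None = None,
    montage: Montage | None = None,
    apply_preprocess: bool = True,
) -> pd.DataFrame:
    """Tidy pair-level PLV table over every subject/condition in the cohort."""
    cfg = cfg or AnalysisConfig()
    montage = montage or load_montage("default30")
    pairset = pairset or default_pairset(montage)
    bank = build_bank(tuple(cfg.bands[band]), n_bins=cfg.n_freq_bins,
                      cycles=cfg.wavelet_cycles, fs=cfg.fs)
    tables = []
    for ep in epoch_sets:
        if apply_preprocess:
            ep = preprocess_epochs(ep, montage, cfg)
        tables.append(pair_plv_table(ep, bank, pairset, band))
    return pd.concat(tables, ignore_index=True)


def feature_matrix(table: pd.DataFrame, band: str,
                   condition: str = "target") -> pd.DataFrame:
    """Subject x pair wide PLV matrix (classification features)."""
    sel = table[(table["band"] == band) & (table["condition"] == condition)]
    wide = sel.pivot_table(index=["subject", "group"], columns="pair",
                           values="plv").reset_index()
    wide.columns.name = None
    return wide


def network_metrics_table(
    epoch_sets: list[EpochArray],
    band: str,
    cfg: AnalysisConfig | None = None,
    montage: Montage | None = None,
    rng: np.random.Generator | int | None = None,
    condition: str = "target",
    apply_preprocess: bool = True,
) -> pd.DataFrame:
    """Per-subject thresholded-graph metric panel (GE, LE, C, L, sigma)."""
    cfg = cfg or AnalysisConfig()
    montage = montage or load_montage("default30")
    rng = np.random.default_rng(rng)
    bank = build_bank(tuple(cfg.bands[band]), n_bins=cfg.n_freq_bins,
                      cycles=cfg.wavelet_cycles, fs=cfg.fs)
    if cfg.network.node_set == "pairset":
        node_set = default_pairset(montage).electrodes()
    else:
        node_set = list(montage.labels)
    rows = []
    for ep in epoch_sets:
        if ep.condition != condition:
            continue
        if apply_preprocess:
            ep = preprocess_epochs(ep, montage, cfg)
        w, labels = plv_matrix(ep, bank, band, channels=node_set)
        graph = build_graph(w, labels)
        metrics = subject_graph_metrics(graph, density=cfg.network.density,
                                        n_random=cfg.network.n_random, rng=rng)
        rows.append({"subject": ep.subject_id, "group": ep.group, "band": band,
                     **metrics})
    return pd.DataFrame(rows)


def iqr_filter_subjects(df: pd.DataFrame, value_col: str,
                        group_col: str = "group") -> pd.DataFrame:
    """Drop per-group outliers in one measure using the 3xIQR rule."""
    kept = []
    for _, sub in df.groupby(group_col):
        if len(sub) < 4:
            kept.append(sub)
            continue
        res = iqr_exclude(sub[value_col].to_numpy(float))
        kept.append(sub.iloc[res.kept])
    return pd.concat(kept, ignore_index=True)


def rank_pairs_by_group_variance(table: pd.DataFrame, band: str,
                                 condition: str = "target") -> list[str]:
    """Pairs ranked by the variance of their group-mean PLV (descending)."""
    sel = table[(table["band"] == band) & (table["condition"] == condition)]
    gm = sel.groupby(["pair", "group"])["plv"].mean().unstack()
    return list(gm.var(axis=1, ddof=0).sort_values(ascending=False).index)


def association_stats(
    table: pd.DataFrame,
    covariates: pd.DataFrame,
    pairset: PairSet,
    band: str,
    cfg: AnalysisConfig | None = None,
    rng: np.random.Generator | int | None = None,
    n_boot: int | None = None,
    apply_iqr: bool = True,
) -> dict:
    """Hemisphere contrasts, coherence-behavior regressions, and the 3-D
    embedding for one band. Returns a dict of tidy DataFrames."""
    cfg = cfg or AnalysisConfig()
    rng = np.random.default_rng(rng)
    n_boot = n_boot if n_boot is not None else cfg.resampling.n_boot
    hemi, subj = aggregate(table[table["band"] == band], pairset)
    hemi_all = (hemi[hemi["condition"] == "target"]
                .groupby(["subject", "group"], as_index=False)["plv_mean"].mean())
    if apply_iqr:
        hemi_all = iqr_filter_subjects(hemi_all, "plv_mean")
    groups = [g for g in ("PD_MCI", "PDD", "DLB") if g in set(hemi_all["group"])]
    contrasts = planned_contrasts(hemi_all, [("HC", g) for g in groups],
                                  n_boot=n_boot, rng=rng)
    contrast_df = pd.DataFrame([{
        "band": band, "contrast": f"{a}_vs_{b}", "mean_HC": r.mean_a,
        "mean_other": r.mean_b, "hedges_g": r.hedges_g, "p": r.p_raw,
        "q_fdr": r.q_fdr, "ci_low": r.ci[0], "ci_high": r.ci[1],
    } for r, (a, b) in zip(contrasts, [c.groups for c in contrasts])])
    merged = subj.merge(covariates, left_on="subject", right_on="subject_id")
    reg_rows = []
    for outcome in ("mmse", "error_score"):
        res = fit_association(merged[outcome], merged["coherence"],
                              age=merged["age"], outcome_name=outcome)
        reg_rows.append({"band": band, "outcome": outcome, "beta_std": res.beta_std,
                         "r2": res.r2, "p": res.p_raw, "n": res.n,
                         "ci_low": res.ci[0], "ci_high": res.ci[1]})
    ranked = rank_pairs_by_group_variance(table, band)
    emb = embed3d(table[(table["band"] == band) & (table["condition"] == "target")],
                  ranked)
    return {
        "contrasts": contrast_df,
        "regressions": pd.DataFrame(reg_rows),
        "embedding_coords": emb.coords,
        "embedding_ellipsoids": emb.group_ellipsoids,
        "embedding_separation": emb.separation,
        "subject_coherence": subj,
    }


def classification_reports(
    table: pd.DataFrame,
    band: str,
    cfg: AnalysisConfig | None = None,
    rng: np.random.Generator | int | None = None,
    comparisons: list[str] | None = None,
    n_boot: int = 1000,
    n_perm: int = 1000,
) -> dict[str, ModelReport]:
    """run_comparison for every requested group comparison in one band."""
    cfg = cfg or AnalysisConfig()
    rng = np.random.default_rng(rng)
    feats = feature_matrix(table, band)
    present = set(feats["group"])
    out = {}
    for name in comparisons or list(COMPARISONS):
        ref, pos = COMPARISONS[name]
        if ref not in present or pos not in present:
            continue
        out[name] = run_comparison(
            feats, name, band, rng=rng, cv_folds=cfg.cv_folds,
            n_lambda=cfg.lasso_n_lambda, lambda_min_ratio=cfg.lasso_lambda_min_ratio,
            bolasso_B=cfg.resampling.bolasso_B,
            bolasso_threshold=cfg.resampling.bolasso_threshold,
            bolasso_folds=min(cfg.cv_folds, 5),
            n_boot=n_boot, n_perm=n_perm,
        )
    return out
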