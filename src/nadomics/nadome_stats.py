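"""Downstream NADome analysis: redox ratios, fold changes, testing, PCA.

Redox state is summarized by four per-sample ratios (NADH/NAD+, NADPH/NADP+,
NADP+/NAD+, NADPH/NADH). Condition effects are expressed as log2 fold changes
of each later timepoint against the aerobic reference, with significance
from a per-analyte one-way ANOVA followed by Tukey's HSD, and
Benjamini-Hochberg FDR applied across analytes within each timepoint
contrast. Multivariate structure is inspected with PCA on autoscaled data
(mean-centered, divided by the per-variable SD).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from statsmodels.stats.libqsturng import psturng
from statsmodels.stats.multitest import multipletests

__all__ = [
    "RATIO_PAIRS",
    "redox_ratios",
    "log2_fold_changes",
    "one_way_anova_tukey",
    "significance_stars",
    "autoscale_pca",
    "PCAResult",
]

#: numerator, denominator pairs of the reported redox/phosphorylation ratios
RATIO_PAIRS = {
    "NADH/NAD+": ("NADH", "NAD+"),
    "NADPH/NADP+": ("NADPH", "NADP+"),
    "NADP+/NAD+": ("NADP+", "NAD+"),
    "NADPH/NADH": ("NADPH", "NADH"),
}


def _usable(quant: pd.DataFrame) -> pd.DataFrame:
    mask = pd.Series(True, index=quant.index)
    if "censored" in quant.columns:
        mask &= ~quant["censored"].astype(bool)
    if "outlier" in quant.columns:
        mask &= ~quant["outlier"].astype(bool)
    return quant[mask]


def redox_ratios(quant: pd.DataFrame) -> pd.DataFrame:
    """Per-sample element-wise ratios for the four defined cofactor pairs.

    ``quant`` is a long frame with ``analyte``, ``sample_id``,
    ``conc_nmol_per_gcdw`` (and optional ``censored``/``outlier`` flags).
    Samples where either member is censored, flagged, or the denominator is
    zero are skipped for that ratio.
    """
    usable = _usable(quant)
    wide = usable.pivot_table(
        index="sample_id", columns="analyte", values="conc_nmol_per_gcdw",
        aggfunc="mean",
    )
    meta_cols = [c for c in ("timepoint", "bio_rep") if c in quant.columns]
    meta = quant.drop_duplicates("sample_id").set_index("sample_id")[meta_cols]
    rows = []
    for name, (num, den) in RATIO_PAIRS.items():
        if num not in wide.columns or den not in wide.columns:
            continue
        sub = wide[[num, den]].dropna()
        sub = sub[sub[den] > 0]
        for sample_id, (n_val, d_val) in sub.iterrows():
            row = {"ratio": name, "sample_id": sample_id, "value": n_val / d_val}
            row.update(meta.loc[sample_id].to_dict() if sample_id in meta.index else {})
            rows.append(row)
    return pd.DataFrame(rows)


def significance_stars(p: float) -> str:
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


@dataclass
class AnovaTukeyResult:
    f_statistic: float
    p_value: float
    pairwise: pd.DataFrame  # columns: group1, group2, meandiff, p_tukey


def one_way_anova_tukey(groups: dict[str, np.ndarray]) -> AnovaTukeyResult:
    """One-way ANOVA with Tukey HSD pairwise comparisons.

    ``groups`` maps group label -> replicate values; needs >= 2 groups with
    >= 2 values each. Degenerate zero-variance-everywhere data with unequal
    means is reported as p = 0 (infinitely strong evidence under the model);
    identical groups give F = 0, p = 1.

    Pairwise p-values use the studentized-range distribution via the
    standard table interpolation (statsmodels ``psturng``, accurate to about
    1e-3 and clipped to [0.001, 0.9] — ample for the 0.05/0.01/0.001 star
    thresholds and BH-FDR at 0.05).
    """
    labels = list(groups)
    arrays = [np.asarray(groups[g], dtype=float) for g in labels]
    if len(arrays) < 2 or any(len(a) < 2 for a in arrays):
        raise ValueError("need >= 2 groups with >= 2 values each")
    values = np.concatenate(arrays)

    grand = values.mean()
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    ss_between = sum(len(a) * (a.mean() - grand) ** 2 for a in arrays)
    pairs = [
        (g1, g2) for i, g1 in enumerate(labels) for g2 in labels[i + 1:]
    ]
    meandiffs = [float(np.mean(groups[g2]) - np.mean(groups[g1])) for g1, g2 in pairs]
    if ss_within == 0:
        if ss_between == 0:
            f_stat, p = 0.0, 1.0
        else:
            f_stat, p = float("inf"), 0.0
        pairwise = pd.DataFrame({
            "group1": [g1 for g1, _ in pairs],
            "group2": [g2 for _, g2 in pairs],
            "meandiff": meandiffs,
            "p_tukey": [1.0 if d == 0 else 0.0 for d in meandiffs],
        })
        return AnovaTukeyResult(f_stat, p, pairwise)

    f_stat, p = stats.f_oneway(*arrays)
    k, n_total = len(arrays), len(values)
    df_err = n_total - k
    mse = ss_within / df_err
    ns = {g: len(a) for g, a in zip(labels, arrays)}
    q_stats = np.array([
        abs(d) / np.sqrt(mse / 2.0 * (1.0 / ns[g1] + 1.0 / ns[g2]))
        for (g1, g2), d in zip(pairs, meandiffs)
    ])
    p_tukey = np.atleast_1d(psturng(np.clip(q_stats, 1e-9, None), k, df_err))
    pairwise = pd.DataFrame({
        "group1": [g1 for g1, _ in pairs],
        "group2": [g2 for _, g2 in pairs],
        "meandiff": meandiffs,
        "p_tukey": np.asarray(p_tukey, dtype=float),
    })
    return AnovaTukeyResult(float(f_stat), float(p), pairwise)


def log2_fold_changes(
    quant: pd.DataFrame,
    reference: str = "T1",
    fdr_alpha: float = 0.05,
    min_replicates: int = 2,
) -> pd.DataFrame:
    """log2 fold change of each timepoint vs the reference, with adjusted p.

    Technical replicates are averaged within each biological replicate first;
    fold changes and tests operate on the biological-replicate means. For
    each analyte a one-way ANOVA + Tukey HSD yields per-contrast p-values;
    BH-FDR is then applied across analytes within each timepoint contrast.

    Returns a frame with ``analyte``, ``timepoint``, ``log2fc``,
    ``p_tukey``, ``p_adjusted``, ``stars``.
    """
    usable = _usable(quant)
    bio = (
        usable.groupby(["analyte", "timepoint", "bio_rep"])["conc_nmol_per_gcdw"]
        .mean()
        .reset_index()
    )
    rows = []
    for analyte, grp in bio.groupby("analyte"):
        groups = {
            tp: sub["conc_nmol_per_gcdw"].to_numpy()
            for tp, sub in grp.groupby("timepoint")
        }
        if reference not in groups:
            continue
        groups = {tp: v for tp, v in groups.items() if len(v) >= min_replicates}
        if reference not in groups or len(groups) < 2:
            continue
        res = one_way_anova_tukey(groups)
        ref_mean = groups[reference].mean()
        for tp, vals in groups.items():
            if tp == reference:
                continue
            mean = vals.mean()
            if ref_mean <= 0 or mean <= 0:
                log2fc = np.nan
            else:
                log2fc = float(np.log2(mean / ref_mean))
            pw = res.pairwise
            hit = pw[
                ((pw["group1"] == reference) & (pw["group2"] == tp))
                | ((pw["group1"] == tp) & (pw["group2"] == reference))
            ]
            p_tukey = float(hit["p_tukey"].iloc[0]) if len(hit) else np.nan
            rows.append({
                "analyte": analyte, "timepoint": tp,
                "log2fc": log2fc, "p_tukey": p_tukey,
            })
    out = pd.DataFrame(rows)
    if out.empty:
        return out.assign(p_adjusted=[], stars=[])
    out["p_adjusted"] = np.nan
    for tp, idx in out.groupby("timepoint").groups.items():
        pvals = out.loc[idx, "p_tukey"].to_numpy()
        ok = np.isfinite(pvals)
        if ok.any():
            adj = multipletests(pvals[ok], alpha=fdr_alpha, method="fdr_bh")[1]
            out.loc[np.asarray(idx)[ok], "p_adjusted"] = adj
    out["stars"] = out["p_adjusted"].map(
        lambda p: significance_stars(p) if np.isfinite(p) else "na"
    )
    return out


@dataclass
class PCAResult:
    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # analytes x components
    variance_explained: np.ndarray = field(default_factory=lambda: np.array([]))  # percent


def autoscale_pca(
    wide: pd.DataFrame,
    scaling: str = "sd",
) -> PCAResult:
    """PCA of an autoscaled samples-x-analytes concentration matrix.

    Each variable is mean-centered and divided by its standard deviation
    (``scaling='sd'``); ``scaling='sqrt_sd'`` divides by the square root of
    the SD instead (a Pareto-like softer scaling, offered as an option).
    Missing values are mean-imputed per column (with a warning);
    zero-variance columns are dropped (with a warning). The decomposition is
    full rank, so the variance-explained percentages sum to 100.
    """
    if len(wide) < 3:
        raise ValueError("PCA needs >= 3 samples")
    X = wide.copy().astype(float)
    if X.isna().any().any():
        warnings.warn("missing values mean-imputed per analyte before PCA", stacklevel=2)
        X = X.fillna(X.mean())
    sd = X.std(ddof=1)
    zero_var = sd[sd == 0].index.tolist()
    if zero_var:
        warnings.warn(f"zero-variance analytes dropped from PCA: {zero_var}", stacklevel=2)
        X = X.drop(columns=zero_var)
        sd = sd.drop(zero_var)
    if scaling == "sd":
        Z = (X - X.mean()) / sd
    elif scaling == "sqrt_sd":
        Z = (X - X.mean()) / np.sqrt(sd)
    else:
        raise ValueError(f"unknown scaling {scaling!r}")
    pca = PCA(n_components=None, svd_solver="full")
    scores = pca.fit_transform(Z.to_numpy())
    comp_names = [f"PC{i + 1}" for i in range(pca.n_components_)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=X.index, columns=comp_names),
        loadings=pd.DataFrame(pca.components_.T, index=X.columns, columns=comp_names),
        variance_explained=100.0 * pca.explained_variance_ratio_,
    )
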