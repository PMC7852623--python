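"""Developmental expression screen: robust age trends per gene x brain region.

For each gene and fetal brain region the expression level is regressed on
post-conceptional age (pcw) with a Huber M-estimator, so that a handful of
aberrant specimens cannot flip the sign of a developmental trend.  Two-sided
p-values for the slope use a t reference with n - 2 df on the robust
standard error.  Benjamini-Hochberg FDR is applied jointly across the full
gene x region grid and the screen keeps cells below the adjusted-p threshold
(default 0.01), recording each trend's direction (up/down-regulated with age).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: anatomical ordering of the fetal brain-region labels used for reporting
REGION_ORDER = [
    "AMY", "HIP", "A1C", "ACC", "DFC", "IPC", "ITC",
    "M1C", "OFC", "S1C", "STC", "V1C", "VFC",
]

#: Huber tuning constant: 95% Gaussian efficiency
HUBER_C = 1.345


@dataclass
class ExpressionMatrix:
    """Expression values (samples x genes) with per-sample region and age."""

    data: pd.DataFrame  # samples x genes
    meta: pd.DataFrame  # columns sample_id, region, age_pcw; same row order

    def __post_init__(self):
        if len(self.data) != len(self.meta):
            raise ValueError("data and meta must have one row per sample")
        required = {"sample_id", "region", "age_pcw"}
        if not required.issubset(self.meta.columns):
            raise ValueError(f"meta must have columns {sorted(required)}")

    @property
    def genes(self) -> list:
        return list(self.data.columns)

    @property
    def regions(self) -> list:
        seen = pd.unique(self.meta["region"])
        return sorted(seen, key=lambda r: (REGION_ORDER.index(r)
                                           if r in REGION_ORDER else 99, r))

    def to_tsv(self, path) -> None:
        wide = pd.concat(
            [self.meta.reset_index(drop=True), self.data.reset_index(drop=True)],
            axis=1,
        )
        wide.to_csv(path, sep="\t", index=False, float_format="%.10g")


def load_expression_tsv(path) -> ExpressionMatrix:
    """Read expression TSV, auto-detecting wide or long layout.

    Wide: sample_id, region, age_pcw, then one column per gene.
    Long: sample_id, region, age_pcw, gene_id, expression.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "region", "age_pcw"}
    if not required.issubset(df.columns):
        raise ValueError(f"expression TSV must carry columns {sorted(required)}")
    if {"gene_id", "expression"}.issubset(df.columns):
        wide = df.pivot_table(
            index=["sample_id", "region", "age_pcw"],
            columns="gene_id",
            values="expression",
        ).reset_index()
        meta = wide[["sample_id", "region", "age_pcw"]]
        data = wide.drop(columns=["sample_id", "region", "age_pcw"])
        data.columns.name = None
        return ExpressionMatrix(data=data, meta=meta)
    meta = df[["sample_id", "region", "age_pcw"]]
    data = df.drop(columns=["sample_id", "region", "age_pcw"])
    return ExpressionMatrix(data=data, meta=meta)


def restrict_to_expressed(gene_list, X: ExpressionMatrix) -> tuple[list, int]:
    """Keep genes from a curated list that carry expression data.

    Returns (kept_genes, n_dropped); genes absent from the matrix, or present
    only as all-missing columns, are dropped with a logged count.
    """
    kept = []
    for g in gene_list:
        if g in X.data.columns and X.data[g].notna().any():
            kept.append(g)
    n_dropped = len(gene_list) - len(kept)
    if n_dropped:
        logger.info("dropped %d genes without fetal expression data", n_dropped)
    return kept, n_dropped


# ---------------------------------------------------------------------------
# Huber IRLS


def _huber_irls(ages: np.ndarray, Y: np.ndarray, c: float = HUBER_C,
                tol: float = 1e-8, max_iter: int = 200):
    """Vectorized Huber M-estimation of slope/intercept for many responses.

    ages: (n,); Y: (n, m) response columns sharing the design.  Returns
    (intercept, slope, se_slope, scale, n_iter) each of shape (m,).  Scale is
    re-estimated each iteration as MAD(resid)/0.6745; the slope covariance
    uses the Huber sandwich with the MASS-style small-sample correction and
    is exactly the OLS covariance when no residual exceeds the tuning
    constant.
    """
    ages = np.asarray(ages, dtype=float)
    Y = np.asarray(Y, dtype=float)
    single = Y.ndim == 1
    Y = Y.reshape(len(ages), -1)
    n, m = Y.shape
    if n < 3:
        raise ValueError("need at least 3 samples")
    if np.ptp(ages) == 0:
        raise ValueError("degenerate design: constant ages")

    x = ages
    # start from OLS
    sw = np.ones((n, m))
    b0 = np.empty(m)
    b1 = np.empty(m)
    for it in range(max_iter):
        s0 = sw.sum(axis=0)
        sx = (sw * x[:, None]).sum(axis=0)
        sxx = (sw * (x**2)[:, None]).sum(axis=0)
        sy = (sw * Y).sum(axis=0)
        sxy = (sw * x[:, None] * Y).sum(axis=0)
        det = s0 * sxx - sx**2
        new_b1 = (s0 * sxy - sx * sy) / det
        new_b0 = (sy - new_b1 * sx) / s0
        resid = Y - new_b0[None, :] - new_b1[None, :] * x[:, None]
        scale = np.median(np.abs(resid), axis=0) / 0.6744897501960817
        if it > 0:
            denom = np.maximum(np.abs(b1) + np.abs(b0), 1.0)
            if np.all(np.abs(new_b1 - b1) + np.abs(new_b0 - b0) <= tol * denom):
                b0, b1 = new_b0, new_b1
                break
        b0, b1 = new_b0, new_b1
        safe = np.where(scale > 0, scale, 1.0)
        u = np.abs(resid) / safe[None, :]
        sw = np.minimum(1.0, c / np.maximum(u, 1e-300))
        sw[:, scale == 0] = 1.0

    # robust covariance (Huber 1981 proposal 2, as in MASS::summary.rlm)
    resid = Y - b0[None, :] - b1[None, :] * x[:, None]
    p = 2
    se1 = np.empty(m)
    exact = scale <= 1e-12 * np.maximum(np.abs(Y).max(axis=0), 1.0)
    safe = np.where(scale > 0, scale, 1.0)
    u = resid / safe[None, :]
    psi = np.clip(u, -c, c)
    dpsi = (np.abs(u) <= c).astype(float)
    mean_dpsi = dpsi.mean(axis=0)
    var_dpsi = dpsi.var(axis=0)
    kappa = 1.0 + p / n * var_dpsi / np.maximum(mean_dpsi, 1e-12) ** 2
    s2 = (safe**2) * (psi**2).sum(axis=0) / (n - p)
    var_scale = kappa**2 * s2 / np.maximum(mean_dpsi, 1e-12) ** 2
    xc = x - x.mean()
    inv_xx = 1.0 / (xc**2).sum()  # (X'X)^{-1} slope entry
    se1 = np.sqrt(var_scale * inv_xx)
    se1[exact] = 0.0
    return (b0, b1, se1, scale) if not single else (
        b0[0], b1[0], se1[0], scale[0])


def fit_robust_trend(expr, ages, gene_id: str = "", region: str = "",
                     c: float = HUBER_C) -> dict:
    """Huber-robust regression of one expression trajectory on age (pcw).

    Returns a TrendFit record: slope, slope_se, t_stat, two-sided p (t
    reference, n - 2 df), direction ('up' iff slope > 0), n_samples.
    """
    expr = np.asarray(expr, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if expr.shape != ages.shape:
        raise ValueError("expr and ages must have equal length")
    if len(expr) < 3:
        raise ValueError("need at least 3 samples")
    if np.unique(ages).size < 2:
        raise ValueError("degenerate design: constant ages")
    if np.isnan(expr).any() or np.isnan(ages).any():
        raise ValueError("missing values must be dropped by the caller")
    b0, b1, se, scale = _huber_irls(ages, expr[:, None], c=c)
    b0, b1, se, scale = b0[0], b1[0], se[0], scale[0]
    n = len(expr)
    if se == 0:
        t_stat = np.inf if b1 != 0 else 0.0
        p = 0.0 if b1 != 0 else 1.0
    else:
        t_stat = b1 / se
        p = 2.0 * stats.t.sf(abs(t_stat), n - 2)
    return dict(
        gene_id=gene_id, region=region, intercept=b0, slope=b1,
        slope_se=se, t_stat=t_stat, p_value=p, n_samples=n,
        direction="up" if b1 > 0 else "down",
    )


def screen_all(X: ExpressionMatrix, min_samples: int = 3,
               c: float = HUBER_C) -> tuple[pd.DataFrame, dict]:
    """Robust trend fit for every gene x region cell with enough samples.

    Returns (fits table, audit).  Cells with fewer than ``min_samples``
    complete observations or a constant-age design are skipped and counted.
    """
    if X.data.shape[1] == 0 or len(X.data) == 0:
        raise ValueError("empty expression matrix")
    rows = []
    skipped = []
    region_col = X.meta["region"].to_numpy()
    ages_all = X.meta["age_pcw"].to_numpy(dtype=float)
    for region in X.regions:
        sel = region_col == region
        ages = ages_all[sel]
        block = X.data.loc[sel]
        for gene in X.data.columns:
            y = block[gene].to_numpy(dtype=float)
            ok = ~np.isnan(y)
            if ok.sum() < max(min_samples, 3) or np.unique(ages[ok]).size < 2:
                skipped.append((gene, region))
                continue
            rows.append((gene, region, ages[ok], y[ok]))
    if skipped:
        logger.info("screen skipped %d gene x region cells", len(skipped))
    # group fits by identical design for vectorized IRLS
    fits = []
    from itertools import groupby

    rows.sort(key=lambda r: (r[1], len(r[2])))
    for _, grp in groupby(rows, key=lambda r: (r[1], tuple(r[2]))):
        grp = list(grp)
        ages = grp[0][2]
        Y = np.column_stack([g[3] for g in grp])
        b0, b1, se, scale = _huber_irls(ages, Y, c=c)
        n = len(ages)
        with np.errstate(divide="ignore", invalid="ignore"):
            t_stat = np.where(se > 0, b1 / np.where(se > 0, se, 1.0),
                              np.where(b1 != 0, np.inf, 0.0))
        p = np.where(np.isinf(t_stat), 0.0, 2.0 * stats.t.sf(np.abs(t_stat), n - 2))
        p = np.where((se == 0) & (b1 == 0), 1.0, p)
        for i, (gene, region, _, _) in enumerate(grp):
            fits.append(dict(
                gene_id=gene, region=region, intercept=b0[i], slope=b1[i],
                slope_se=se[i], t_stat=t_stat[i], p_value=p[i], n_samples=n,
                direction="up" if b1[i] > 0 else "down",
            ))
    table = pd.DataFrame(fits)
    if len(table):
        table = table.sort_values(["region", "gene_id"],
                                  key=_region_sort_key).reset_index(drop=True)
    audit = {"n_fits": len(table), "n_skipped": len(skipped),
             "skipped_cells": skipped}
    return table, audit


def _region_sort_key(col: pd.Series) -> pd.Series:
    if col.name == "region":
        return col.map(lambda r: (REGION_ORDER.index(r)
                                  if r in REGION_ORDER else 99, r))
    return col


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests

    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def adjust_screen(table: pd.DataFrame, per_region: bool = False) -> pd.DataFrame:
    """Append BH-adjusted p-values; one joint pass over the grid by default."""
    out = table.copy()
    if len(out) == 0:
        out["p_adj"] = []
        return out
    if per_region:
        out["p_adj"] = out.groupby("region")["p_value"].transform(
            lambda s: bh_fdr(s.to_numpy()))
    else:
        out["p_adj"] = bh_fdr(out["p_value"].to_numpy())
    return out


def select_region_genes(fits: pd.DataFrame, q: float = 0.01) -> dict:
    """RegionGeneMap: region -> [(gene_id, direction, p_adj)] with p_adj < q."""
    if "p_adj" not in fits.columns:
        raise ValueError("fits must carry adjusted p-values (run adjust_screen)")
    hits = fits[fits["p_adj"] < q]
    out = {}
    for region in sorted(hits["region"].unique(),
                         key=lambda r: (REGION_ORDER.index(r)
                                        if r in REGION_ORDER else 99, r)):
        sub = hits[hits["region"] == region].sort_values("gene_id")
        out[region] = [
            (row.gene_id, row.direction, float(row.p_adj))
            for row in sub.itertuples()
        ]
    return out
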