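"""Genetic expression score (GES) and simple-slope post hoc analysis.

When a gene's SNP set shows a significant interaction with the prenatal
environment, the direction of moderation is unpacked by scoring each subject
on the gene's predicted expression: the GES sums, over the gene's
eQTL-linked SNPs, the dosage of the expression-increasing allele (the minor
allele when no effect direction is annotated), so a higher GES indicates a
higher predicted expression level.  The association of the brain measure
with the environment is then contrasted between high-GES (mean + 1 SD) and
low-GES (mean - 1 SD) subjects, either at evaluation points of a moderated
regression (Aiken-West simple slopes, the default) or within the literal
+-1 SD subgroups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

EQTL_COLUMNS = ["snp_id", "gene_id", "is_eqtl", "direction"]


def load_eqtl_annotation(path) -> pd.DataFrame:
    """eQTL annotation TSV: snp_id, gene_id, is_eqtl (0/1), direction (+1/-1/NA)."""
    ann = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "gene_id": str})
    if not {"snp_id", "gene_id", "is_eqtl"}.issubset(ann.columns):
        raise ValueError("eQTL annotation needs snp_id, gene_id, is_eqtl columns")
    if "direction" not in ann.columns:
        ann["direction"] = np.nan
    return ann


def compute_ges(G, ann: pd.DataFrame, gene_id: str) -> np.ndarray:
    """Per-subject genetic expression score for one gene.

    Sums the oriented dosage over the gene's eQTL-flagged SNPs: where an
    expression-effect direction is annotated, the expression-increasing
    allele is counted (direction -1 contributes 2 - dosage); otherwise the
    minor-allele dosage is used as loaded.
    """
    sub = ann[(ann["gene_id"] == gene_id) & (ann["is_eqtl"].astype(int) == 1)]
    if len(sub) == 0:
        raise ValueError(f"no eQTL-flagged SNPs annotated for gene {gene_id!r}")
    snp_idx = {s: j for j, s in enumerate(G.snps["snp_id"])}
    present = sub[sub["snp_id"].isin(snp_idx)]
    if len(present) == 0:
        raise ValueError(
            f"none of the eQTL SNPs of {gene_id!r} are in the genotype set")
    ges = np.zeros(G.n_subjects)
    for row in present.itertuples():
        d = G.dosage[:, snp_idx[row.snp_id]]
        direction = getattr(row, "direction", np.nan)
        if pd.notna(direction) and float(direction) < 0:
            d = 2.0 - d
        ges = ges + d
    return ges


def split_groups(ges) -> tuple[np.ndarray, np.ndarray, dict]:
    """High/low GES masks at mean +- 1 SD; middle subjects fall in neither.

    Returns (high_mask, low_mask, thresholds).  Raises when GES is constant
    or either group would be empty (the evaluation-point mode needs no
    grouping and is the fallback to suggest).
    """
    ges = np.asarray(ges, dtype=float)
    mu = ges.mean()
    sd = ges.std(ddof=1)
    if sd <= 0:
        raise ValueError("GES is constant; groups are undefined")
    high = ges >= mu + sd
    low = ges <= mu - sd
    if not high.any() or not low.any():
        raise ValueError(
            "empty GES group at mean +- 1 SD; use evaluation_point mode")
    return high, low, {"mean": float(mu), "sd": float(sd),
                       "high": float(mu + sd), "low": float(mu - sd)}


def standardize_measure(y) -> np.ndarray:
    """z-score a brain measure (mean 0, sd 1 with ddof=1)."""
    y = np.asarray(y, dtype=float)
    sd = y.std(ddof=1)
    if sd <= 0:
        raise ValueError("cannot standardize a constant measure")
    return (y - y.mean()) / sd


def _ols(y: np.ndarray, D: np.ndarray):
    beta, *_ = np.linalg.lstsq(D, y, rcond=None)
    resid = y - D @ beta
    df = len(y) - np.linalg.matrix_rank(D)
    sigma2 = resid @ resid / df
    cov = sigma2 * np.linalg.pinv(D.T @ D)
    return beta, cov, df


@dataclass
class SimpleSlopeResult:
    gene_id: str
    measure_id: str
    group: str  # "high" | "low"
    slope: float
    se: float
    p: float
    n_effective: int
    mode: str


def simple_slopes(y, X, E, ges, mode: str = "evaluation_point",
                  gene_id: str = "", measure_id: str = "",
                  standardize_y: bool = True) -> list[SimpleSlopeResult]:
    """Environment slope on the brain measure at high and low GES.

    evaluation_point (default): a single moderated regression
    Y ~ 1 + X + E + GES + E*GES; the simple slope at GES = mean +- sd is
    beta_E + (+-sd) beta_int with delta-method SE (GES is centered
    internally, so the evaluation offsets are +-sd).  group_subset: separate
    regressions Y ~ 1 + X + E within the literal +-1 SD subgroups.  Y is
    z-scored before fitting unless standardize_y=False.
    """
    y = np.asarray(y, dtype=float).ravel()
    E = np.asarray(E, dtype=float).ravel()
    ges = np.asarray(ges, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if np.isnan(np.concatenate([y, E, ges])).any() or np.isnan(X).any():
        raise ValueError("post hoc inputs must be complete")
    if standardize_y:
        y = standardize_measure(y)
    sd = ges.std(ddof=1)
    if sd <= 0:
        raise ValueError("GES is constant")
    out = []
    if mode == "evaluation_point":
        gc = ges - ges.mean()
        D = np.column_stack([np.ones_like(y), X, E, gc, E * gc])
        beta, cov, df = _ols(y, D)
        iE, iI = X.shape[1] + 1, X.shape[1] + 3
        for group, v in (("high", sd), ("low", -sd)):
            slope = beta[iE] + v * beta[iI]
            var = cov[iE, iE] + v**2 * cov[iI, iI] + 2 * v * cov[iE, iI]
            se = float(np.sqrt(max(var, 0.0)))
            if se == 0:
                p = 0.0 if slope != 0 else 1.0
            else:
                p = 2.0 * stats.t.sf(abs(slope) / se, df)
            out.append(SimpleSlopeResult(gene_id, measure_id, group,
                                         float(slope), se, float(p),
                                         len(y), mode))
    elif mode == "group_subset":
        high, low, _ = split_groups(ges)
        for group, mask in (("high", high), ("low", low)):
            if mask.sum() < X.shape[1] + 3:
                raise ValueError(
                    f"{group}-GES group too small for the covariate set")
            D = np.column_stack([np.ones(mask.sum()), X[mask], E[mask]])
            beta, cov, df = _ols(y[mask], D)
            iE = D.shape[1] - 1
            se = float(np.sqrt(max(cov[iE, iE], 0.0)))
            slope = float(beta[iE])
            if se == 0:
                p = 0.0 if slope != 0 else 1.0
            else:
                p = 2.0 * stats.t.sf(abs(slope) / se, df)
            out.append(SimpleSlopeResult(gene_id, measure_id, group,
                                         slope, se, float(p),
                                         int(mask.sum()), mode))
    else:
        raise ValueError(f"unknown simple-slopes mode {mode!r}")
    return out


def plot_simple_slopes(results: list[SimpleSlopeResult], e_range=(0.0, 20.0),
                       ax=None):
    """Two-line simple-slope figure (high vs low GES)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    es = np.linspace(*e_range, 50)
    colors = {"high": "tab:blue", "low": "black"}
    for r in results:
        ax.plot(es, r.slope * (es - es.mean()), color=colors.get(r.group),
                label=f"{r.group} GES (b={r.slope:.3f}, p={r.p:.3f})")
    ax.set_xlabel("prenatal depressive symptoms (EPDS)")
    ax.set_ylabel("standardized brain measure")
    ax.legend(frameon=False, fontsize=8)
    return ax
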