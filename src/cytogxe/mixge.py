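"""MixGE: gene-set mixed-effect gene-environment interaction test.

The model for one brain measure Y and one gene's SNP dosages G is

    Y = Z beta + diag(E) G pi + diag(E) G delta,    Z = [X, E, G],

where E is the environment score (prenatal maternal depressive symptoms),
pi is a single fixed "accumulative" interaction effect shared by the gene's
SNPs, and delta are SNP-specific random "heterogeneous" interaction
deviations with Var(delta_j) = tau.  The null of no interaction is tested in
two parts and combined:

* burden (accumulative) test of pi: the regressor E * rowsum(centered G) is
  added to the null model and its coefficient t-tested;
* variance-component (heterogeneous) score test of tau = 0: with
  M = diag(E) G_c, the statistic Q = r' M M' r / sigma^2 is referred to its
  null law, a weighted mixture of 1-df chi-squares with weights the nonzero
  eigenvalues of M' P0 M (P0 the null residual projection), evaluated by
  exact characteristic-function inversion with a Liu moment fallback;
* the two p-values are combined by Fisher's statistic calibrated with
  Freedman-Lane permutation of the null residuals (or a fast Bonferroni
  bound on the minimum p).

Note the unusual feature that the SNP main effects G sit in the null design:
the interaction test is conditional on all main effects.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import qr as _qr

from ._quadform import StudentizedQSF, quadform_ratio_sf

logger = logging.getLogger(__name__)

_TINY_P = 1e-300


@dataclass
class NullFit:
    """Least-squares fit of Y on the null design Z = [1, X, E, G]."""

    Z: np.ndarray          # full-rank reduced design
    Qbasis: np.ndarray     # orthonormal basis of span(Z), n x rank
    beta: np.ndarray
    fitted: np.ndarray
    resid: np.ndarray
    sigma2: float
    df_resid: int
    rank: int
    dropped_cols: list

    @property
    def n(self) -> int:
        return self.Z.shape[0]

    def project_out(self, v: np.ndarray) -> np.ndarray:
        """Residualize columns of v against the null design."""
        return v - self.Qbasis @ (self.Qbasis.T @ v)


def _as_2d(X) -> np.ndarray:
    if X is None:
        return np.empty((0, 0))
    arr = np.asarray(X, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr


def fit_null_model(y, X, E, G, column_names: list | None = None) -> NullFit:
    """OLS fit of Y on [intercept, X, E, G], dropping rank-deficient columns.

    Residuals are orthogonal to every retained column; dropped column indices
    (within the assembled design) are logged and recorded.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = _as_2d(X)
    G = _as_2d(G)
    E = np.asarray(E, dtype=float).ravel()
    n = y.shape[0]
    parts = [np.ones((n, 1))]
    if X.size:
        parts.append(X)
    parts.append(E[:, None])
    parts.append(G)
    Z = np.column_stack(parts)
    if np.isnan(Z).any() or np.isnan(y).any():
        raise ValueError("missing values in MixGE inputs")
    ncol = Z.shape[1]
    if n <= ncol:
        raise ValueError(
            f"insufficient df: n={n} <= {ncol} design columns")
    Rfac, piv = _qr(Z, mode="r", pivoting=True)
    diag = np.abs(np.diag(Rfac))
    tol = diag.max() * max(Z.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    kept = np.sort(piv[:rank])
    dropped = sorted(set(range(ncol)) - set(kept))
    if dropped:
        names = (
            [column_names[i] for i in dropped] if column_names else dropped)
        logger.info("dropped rank-deficient design columns: %s", names)
    Zr = Z[:, kept]
    Qb, _ = np.linalg.qr(Zr)
    beta, *_ = np.linalg.lstsq(Zr, y, rcond=None)
    fitted = Zr @ beta
    resid = y - fitted
    df = n - rank
    sigma2 = float(resid @ resid / df)
    # orthogonality sanity (normal equations)
    scale = max(np.abs(y).max(), 1.0) * max(np.abs(Zr).max(), 1.0) * n
    if np.abs(Zr.T @ resid).max() > 1e-8 * scale:
        raise RuntimeError("null-model residuals not orthogonal to design")
    return NullFit(Z=Zr, Qbasis=Qb, beta=beta, fitted=fitted, resid=resid,
                   sigma2=sigma2, df_resid=df, rank=rank, dropped_cols=dropped)


def _interaction_parts(nf: NullFit, E, G, center_e: bool = True):
    """Projected burden regressor b_t and VC kernel columns M_t."""
    E = np.asarray(E, dtype=float).ravel()
    G = _as_2d(G)
    Gc = G - G.mean(axis=0, keepdims=True)
    Ec = E - E.mean() if center_e else E
    b = Ec * Gc.sum(axis=1)
    M = Ec[:, None] * Gc
    return nf.project_out(b), nf.project_out(M)


def burden_test(nf: NullFit, E, G, center_e: bool = True) -> dict:
    """Added-regressor t-test of the accumulative interaction effect pi.

    Returns dict(pi_hat, se, t, p, df, degenerate).  A numerically constant
    burden regressor yields p = 1 with the degeneracy flag set.
    """
    b_t, _ = _interaction_parts(nf, E, G, center_e)
    bb = float(b_t @ b_t)
    rss0 = float(nf.resid @ nf.resid)
    scale = max(np.abs(b_t).max(initial=0.0), 0.0)
    if bb <= (1e-10 * max(scale, 1.0)) ** 2 * nf.n or nf.df_resid < 2:
        return dict(pi_hat=0.0, se=np.nan, t=0.0, p=1.0,
                    df=nf.df_resid - 1, degenerate=True)
    u = float(b_t @ nf.resid)
    pi_hat = u / bb
    rss1 = max(rss0 - u * u / bb, 0.0)
    df1 = nf.df_resid - 1
    se = np.sqrt(rss1 / df1 / bb)
    if se == 0:
        return dict(pi_hat=pi_hat, se=0.0, t=np.inf, p=0.0, df=df1,
                    degenerate=False)
    t = pi_hat / se
    p = 2.0 * stats.t.sf(abs(t), df1)
    return dict(pi_hat=pi_hat, se=se, t=t, p=p, df=df1, degenerate=False)


def variance_component_test(nf: NullFit, E, G, center_e: bool = True) -> dict:
    """Score test of the heterogeneous interaction variance tau = 0.

    Q = r' M M' r / sigma-hat^2 with kernel weights lambda_k, the nonzero
    eigenvalues of M' P0 M.  The null law accounts for the estimated
    residual variance: P(Q > q) is the exact studentized mixture
    P(sum_k (lambda_k - q/df) chi2_1 - (q/df) chi2_{df-m} > 0), evaluated
    by characteristic-function inversion; with one SNP this is exactly the
    classical single-term F(1, df-1) interaction test, and as df grows it
    converges to the familiar sum-lambda_k-chi2 reference.  Returns
    dict(Q, p, lambdas, method, degenerate).
    """
    _, M_t = _interaction_parts(nf, E, G, center_e)
    K = M_t.T @ M_t
    lam = np.linalg.eigvalsh(K)
    lam = lam[lam > max(lam.max(initial=0.0), 0.0) * 1e-12]
    q_num = float(((M_t.T @ nf.resid) ** 2).sum())
    Q = q_num / nf.sigma2
    if lam.size == 0:
        return dict(Q=0.0, p=1.0, lambdas=lam, method="degenerate",
                    degenerate=True)
    p, method = quadform_ratio_sf(Q, lam, nf.df_resid)
    return dict(Q=Q, p=p, lambdas=lam, method=method, degenerate=False)


def _freedman_lane_draws(nf: NullFit, b_t, M_t, n_perm: int,
                         rng: np.random.Generator):
    """Permutation draws of the burden |t| / p and VC Q / p under the null.

    Freedman-Lane: the null residuals are permuted, re-projected onto the
    null-model residual space, and both component statistics recomputed with
    their own re-estimated residual variance.
    """
    n = nf.n
    order = np.argsort(rng.random((n_perm, n)), axis=1)
    R = nf.resid[order]                        # (B, n) permuted residuals
    C = R @ nf.Qbasis                          # components inside span(Z)
    rr = float(nf.resid @ nf.resid)
    rss0 = np.maximum(rr - (C**2).sum(axis=1), 1e-300)
    df0 = nf.df_resid
    bb = float(b_t @ b_t)
    if bb > 0:
        u = R @ b_t
        rss1 = np.maximum(rss0 - u**2 / bb, 1e-300)
        t_abs = np.abs(u) / np.sqrt(bb) / np.sqrt(rss1 / (df0 - 1))
        p_b = 2.0 * stats.t.sf(t_abs, df0 - 1)
    else:
        t_abs = np.zeros(n_perm)
        p_b = np.ones(n_perm)
    W = R @ M_t
    q_stat = (W**2).sum(axis=1) / (rss0 / df0)
    sf_obj = StudentizedQSF(np.linalg.eigvalsh(M_t.T @ M_t), df0)
    p_v = sf_obj.sf_batch(q_stat)
    return t_abs, p_b, q_stat, p_v


def combined_test(p_burden: float, p_vc: float, nf: NullFit, E, G,
                  mode: str = "fisher_perm", n_perm: int = 2000,
                  rng=None, center_e: bool = True) -> dict:
    """Combine the burden and variance-component p-values.

    fisher_perm (default): T = -2(log p_burden + log p_vc) calibrated by
    Freedman-Lane permutation of the null residuals, both components
    recomputed per draw.  min_p_bonf: 2 min(p) capped at 1.
    """
    if mode == "min_p_bonf":
        return dict(p=float(min(1.0, 2.0 * min(p_burden, p_vc))),
                    mode=mode, n_perm_used=0)
    if mode != "fisher_perm":
        raise ValueError(f"unknown combination mode {mode!r}")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(rng)
    b_t, M_t = _interaction_parts(nf, E, G, center_e)
    _, p_b, _, p_v = _freedman_lane_draws(nf, b_t, M_t, n_perm, rng)
    T_obs = -2.0 * (np.log(max(p_burden, _TINY_P))
                    + np.log(max(p_vc, _TINY_P)))
    T_perm = -2.0 * (np.log(np.maximum(p_b, _TINY_P))
                     + np.log(np.maximum(p_v, _TINY_P)))
    n_ge = int((T_perm >= T_obs - 1e-12).sum())
    return dict(p=(1.0 + n_ge) / (1.0 + n_perm), mode=mode,
                n_perm_used=n_perm)


def permutation_oracle(y, X, E, G, n_perm: int = 2000, seed=0,
                       center_e: bool = True) -> dict:
    """Empirical Freedman-Lane p-values for burden, VC, and combined tests.

    Empirical p = (1 + #{T_perm >= T_obs}) / (1 + n_perm); deterministic
    given the seed.  Serves as the ground-truth calibration oracle for the
    analytic tests.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    nf = fit_null_model(y, X, E, G)
    b_t, M_t = _interaction_parts(nf, E, G, center_e)
    bres = burden_test(nf, E, G, center_e)
    vres = variance_component_test(nf, E, G, center_e)
    t_abs, p_b, q_stat, p_v = _freedman_lane_draws(nf, b_t, M_t, n_perm, rng)
    t_obs = abs(bres["t"]) if np.isfinite(bres["t"]) else np.inf
    p_burden_perm = (1.0 + (t_abs >= t_obs - 1e-12).sum()) / (1.0 + n_perm)
    p_vc_perm = (1.0 + (q_stat >= vres["Q"] - 1e-12).sum()) / (1.0 + n_perm)
    T_obs = -2.0 * (np.log(max(bres["p"], _TINY_P))
                    + np.log(max(vres["p"], _TINY_P)))
    T_perm = -2.0 * (np.log(np.maximum(p_b, _TINY_P))
                     + np.log(np.maximum(p_v, _TINY_P)))
    p_comb_perm = (1.0 + (T_perm >= T_obs - 1e-12).sum()) / (1.0 + n_perm)
    return dict(p_burden=p_burden_perm, p_vc=p_vc_perm,
                p_combined=p_comb_perm, n_perm=n_perm,
                analytic=dict(p_burden=bres["p"], p_vc=vres["p"]))


@dataclass
class MixGEResult:
    gene_id: str
    measure_id: str
    n_snps: int
    pi_hat: float
    p_burden: float
    Q_stat: float
    p_vc: float
    p_combined: float
    method_flags: str
    n_perm_used: int


def mixge_test(y, X, E, G, gene_id: str = "", measure_id: str = "",
               combine_mode: str = "fisher_perm", n_perm: int = 2000,
               rng=None, center_e: bool = True) -> MixGEResult:
    """Full MixGE test of one (gene, brain measure) pair."""
    G = _as_2d(G)
    nf = fit_null_model(y, X, E, G)
    bres = burden_test(nf, E, G, center_e)
    vres = variance_component_test(nf, E, G, center_e)
    cres = combined_test(bres["p"], vres["p"], nf, E, G,
                         mode=combine_mode, n_perm=n_perm, rng=rng,
                         center_e=center_e)
    flags = [vres["method"]]
    if bres["degenerate"]:
        flags.append("burden_degenerate")
    if vres["degenerate"]:
        flags.append("vc_degenerate")
    return MixGEResult(
        gene_id=gene_id, measure_id=measure_id, n_snps=G.shape[1],
        pi_hat=bres["pi_hat"], p_burden=bres["p"], Q_stat=vres["Q"],
        p_vc=vres["p"], p_combined=cres["p"],
        method_flags="+".join(flags), n_perm_used=cres["n_perm_used"])


def _stable_child_seed(seed: int, *keys: str) -> np.random.Generator:
    parts = [int(seed)] + [zlib.crc32(k.encode()) for k in keys]
    return np.random.default_rng(parts)


def run_scan(region_gene_map: dict, G, X, E, measures: pd.DataFrame,
             region_measures: dict, combine_mode: str = "fisher_perm",
             n_perm: int = 2000, seed: int = 0, center_e: bool = True,
             adjust: bool = False) -> pd.DataFrame:
    """MixGE scan over every (gene, measure) pair defined by the region map.

    region_gene_map: region -> [(gene_id, direction, p_adj)] from the screen.
    region_measures: region -> list of measure column names in ``measures``
    (left/right measures are separate outcomes).  Raw p-values are reported;
    a BH column across the scan is appended only when ``adjust`` is True.
    """
    from .genotype import GenotypeSet  # noqa: F401  (duck-typed)

    genes_by_region = {r: [g for g, *_ in v] for r, v in region_gene_map.items()}
    missing_genes = sorted(
        {g for gs in genes_by_region.values() for g in gs}
        - set(G.snps["gene_id"]))
    if missing_genes:
        raise KeyError(f"genes without QC-passing SNPs: {missing_genes}")
    missing_regions = sorted(set(genes_by_region) - set(region_measures))
    if missing_regions:
        raise KeyError(f"regions without brain measures: {missing_regions}")
    bad_measures = sorted(
        {m for r in genes_by_region for m in region_measures[r]}
        - set(measures.columns))
    if bad_measures:
        raise KeyError(f"measure columns absent from table: {bad_measures}")

    Xmat = np.asarray(X, dtype=float)
    E = np.asarray(E, dtype=float).ravel()
    rows = []
    for region, genes in genes_by_region.items():
        for gene in genes:
            Gmat = G.gene_matrix(gene)
            for meas in region_measures[region]:
                y = measures[meas].to_numpy(dtype=float)
                rng = _stable_child_seed(seed, gene, meas)
                res = mixge_test(
                    y, Xmat, E, Gmat, gene_id=gene, measure_id=meas,
                    combine_mode=combine_mode, n_perm=n_perm, rng=rng,
                    center_e=center_e)
                hemi = ("L" if meas.endswith("_L")
                        else "R" if meas.endswith("_R") else "NA")
                rows.append(dict(
                    gene_id=gene, region=region, measure=meas,
                    hemisphere=hemi, n_snps=res.n_snps, pi_hat=res.pi_hat,
                    p_burden=res.p_burden, Q=res.Q_stat, p_vc=res.p_vc,
                    p_combined=res.p_combined, flags=res.method_flags,
                    n_perm_used=res.n_perm_used))
    table = pd.DataFrame(rows)
    if adjust and len(table):
        from .screen import bh_fdr

        table["p_combined_adj"] = bh_fdr(table["p_combined"].to_numpy())
    return table
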