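"""Synthetic data generators emulating every pipeline input with known truth.

The generators mirror the statistical structure of the study design this
pipeline targets: a fetal developmental expression matrix (specimens aged
8-26 post-conceptional weeks, measured in 12 brain regions, with linear age
trends per gene x region), LD-correlated SNP sets in Hardy-Weinberg
equilibrium grouped into candidate genes, a mother-child cohort table with
EPDS item responses (total ~ 8.6 +- 4.5, internal consistency ~ 0.82),
demographic covariates and neonatal brain measures with realistic marginals,
and outcome columns generated under the MixGE interaction model with
returned ground truth so recovery is testable.

Every generator is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import EPDS_ITEMS, EPDS_REVERSED, EDUCATION_LEVELS, score_epds
from .genotype import GenotypeSet
from .screen import REGION_ORDER, ExpressionMatrix

#: default fetal brain regions of the expression screen (12 of the 13
#: anatomical labels; VFC, last in the listed order, is left out so the
#: default grid is genes x 12)
DEFAULT_REGIONS = REGION_ORDER[:12]

#: cytokine/chemokine genes named in the worked analyses, used to seed the
#: default synthetic gene list
NAMED_GENES = [
    "TGFBR1", "IL17RB", "TNFRSF19", "BMPR1B",
    "IL1RAP", "CXCR4", "CXCL14", "TGFB3",
]

#: brain-measure marginals (mean, SD): subcortical volumes in mm^3 for AMY
#: and HIP, cortical thickness in mm elsewhere; left/right generated
#: separately
BRAIN_MEASURES = {
    "AMY_L": (211.13, 34.60), "AMY_R": (186.57, 33.83),
    "HIP_L": (779.07, 107.11), "HIP_R": (783.87, 111.16),
    "A1C_L": (2.665, 0.297), "A1C_R": (2.603, 0.281),
    "ACC_L": (2.176, 0.31), "ACC_R": (1.704, 0.37),
    "DFC_L": (2.473, 0.301), "DFC_R": (2.573, 0.248),
    "IPC_L": (2.517, 0.277), "IPC_R": (2.718, 0.295),
    "ITC_L": (2.36, 0.265), "ITC_R": (2.589, 0.26),
    "M1C_L": (2.428, 0.205), "M1C_R": (2.493, 0.216),
    "OFC_L": (2.632, 0.267), "OFC_R": (2.432, 0.221),
    "S1C_L": (2.662, 0.256), "S1C_R": (2.844, 0.297),
    "STC_L": (2.664, 0.277), "STC_R": (2.635, 0.285),
    "V1C_L": (3.407, 0.475), "V1C_R": (3.014, 0.374),
    "VFC_L": (2.732, 0.289), "VFC_R": (2.741, 0.289),
}

ETHNICITY_PROBS = {"chinese": 0.4534, "malay": 0.4162, "indian": 0.1304}
EDUCATION_PROBS = [0.0373, 0.3354, 0.4471, 0.1429, 0.0373]

# EPDS item generator: one latent factor with loading _EPDS_LOADING, scored
# item categories cut at _EPDS_CUTS on the item latents.  Calibrated once by
# simulation to a total of mean ~ 8.6, SD ~ 4.5 and Cronbach alpha ~ 0.82.
_EPDS_LOADING = 0.617
_EPDS_CUTS = (-0.455, 0.996, 2.030)


def default_gene_list(n: int = 208) -> list:
    genes = list(NAMED_GENES[:n])
    i = 1
    while len(genes) < n:
        genes.append(f"CYTK{i:03d}")
        i += 1
    return genes


# ---------------------------------------------------------------------------
# expression


@dataclass
class GeneTrend:
    """Planted linear age trend of one gene in one region."""

    gene_id: str
    region: str
    slope: float  # expression units per pcw
    intercept: float = 5.0
    noise_sd: float = 1.0
    outlier_fraction: float = 0.0
    outlier_sd: float = 5.0


@dataclass
class ExpressionSimSpec:
    n_samples: int = 14  # specimens, each measured in every region
    age_range: tuple = (8.0, 26.0)  # post-conceptional weeks
    genes: list = field(default_factory=list)  # GeneTrend entries
    all_genes: list | None = None  # full gene set; None -> genes in `genes`
    regions: list = field(default_factory=lambda: list(DEFAULT_REGIONS))
    background_intercept: float = 5.0
    background_noise_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 3:
            raise ValueError("n_samples must be >= 3")
        if not self.age_range[0] < self.age_range[1]:
            raise ValueError("age_range: min must be < max")
        if self.background_noise_sd <= 0:
            raise ValueError("background_noise_sd must be > 0")
        for g in self.genes:
            if g.noise_sd <= 0:
                raise ValueError(f"noise_sd must be > 0 (gene {g.gene_id})")
            if not 0 <= g.outlier_fraction < 0.5:
                raise ValueError(
                    f"outlier_fraction must be in [0, 0.5) (gene {g.gene_id})")
            if g.region not in self.regions:
                raise ValueError(
                    f"region {g.region!r} of gene {g.gene_id} not in regions")


def simulate_expression(spec: ExpressionSimSpec) -> ExpressionMatrix:
    """Expression matrix with per-(gene, region) linear age trajectories.

    Specimen ages are evenly spaced over the age range; each specimen is
    measured in every region.  Listed (gene, region) cells follow their
    planted slope; all other cells are flat background.  A fraction
    outlier_fraction of points receives extra Gaussian noise of sd
    outlier_sd.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    ages = np.linspace(*spec.age_range, spec.n_samples)
    genes = list(spec.all_genes) if spec.all_genes is not None else []
    for g in spec.genes:
        if g.gene_id not in genes:
            genes.append(g.gene_id)
    if not genes:
        raise ValueError("no genes to simulate")
    planted = {(g.gene_id, g.region): g for g in spec.genes}
    meta_rows = []
    blocks = []
    for region in spec.regions:
        block = np.empty((spec.n_samples, len(genes)))
        for j, gene in enumerate(genes):
            g = planted.get((gene, region))
            if g is None:
                mu = spec.background_intercept
                y = mu + rng.normal(0.0, spec.background_noise_sd,
                                    spec.n_samples)
            else:
                y = (g.intercept + g.slope * ages
                     + (rng.normal(0.0, g.noise_sd, spec.n_samples)
                        if g.noise_sd > 0 else 0.0))
                if g.outlier_fraction > 0:
                    hit = rng.random(spec.n_samples) < g.outlier_fraction
                    y = y + hit * rng.normal(0.0, g.outlier_sd,
                                             spec.n_samples)
            block[:, j] = y
        blocks.append(block)
        for i in range(spec.n_samples):
            meta_rows.append(dict(sample_id=f"S{i + 1:03d}", region=region,
                                  age_pcw=ages[i]))
    data = pd.DataFrame(np.vstack(blocks), columns=genes)
    meta = pd.DataFrame(meta_rows)
    return ExpressionMatrix(data=data, meta=meta)


# ---------------------------------------------------------------------------
# genotypes


@dataclass
class GeneSnpSpec:
    gene_id: str
    n_snps: int
    maf_range: tuple = (0.05, 0.5)
    ld_rho: float = 0.0


@dataclass
class GenotypeSimSpec:
    n_subjects: int
    genes: list  # GeneSnpSpec entries
    missing_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        for g in self.genes:
            lo, hi = g.maf_range
            if not (0 < lo <= hi <= 0.5):
                raise ValueError(
                    f"maf_range must lie in (0, 0.5] (gene {g.gene_id})")
            if not abs(g.ld_rho) < 1:
                raise ValueError(f"|ld_rho| must be < 1 (gene {g.gene_id})")
            if g.n_snps > 1 and g.ld_rho < -1.0 / (g.n_snps - 1):
                raise ValueError(
                    f"exchangeable ld_rho >= -1/(n_snps-1) required "
                    f"(gene {g.gene_id})")


def simulate_genotypes(spec: GenotypeSimSpec) -> GenotypeSet:
    """LD-correlated dosages via a latent Gaussian copula.

    Within each gene the latent normals share exchangeable correlation
    ld_rho; each SNP's latent is cut at the Hardy-Weinberg genotype
    frequencies of its drawn MAF, so marginal genotype frequencies are
    (1-p)^2, 2p(1-p), p^2 with the alt (counted) allele the minor one.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    cols, rows = [], []
    for gi, g in enumerate(spec.genes):
        mafs = rng.uniform(*g.maf_range, g.n_snps)
        k = g.n_snps
        if k == 1 or g.ld_rho == 0:
            Z = rng.standard_normal((n, k))
        elif g.ld_rho > 0:
            shared = rng.standard_normal((n, 1))
            Z = (np.sqrt(g.ld_rho) * shared
                 + np.sqrt(1 - g.ld_rho) * rng.standard_normal((n, k)))
        else:
            cov = np.full((k, k), g.ld_rho)
            np.fill_diagonal(cov, 1.0)
            Z = rng.multivariate_normal(np.zeros(k), cov, size=n,
                                        method="cholesky")
        t0 = stats.norm.ppf((1.0 - mafs) ** 2)
        t1 = stats.norm.ppf(1.0 - mafs**2)
        dos = (Z > t0[None, :]).astype(float) + (Z > t1[None, :])
        if spec.missing_rate > 0:
            dos[rng.random((n, k)) < spec.missing_rate] = np.nan
        cols.append(dos)
        for j in range(k):
            rows.append(dict(
                snp_id=f"{g.gene_id}_rs{j + 1}", chrom=str(gi + 1),
                pos=1000 * (j + 1), ref_allele="A", alt_allele="C",
                gene_id=g.gene_id))
    subjects = [f"D{i + 1:04d}" for i in range(n)]
    return GenotypeSet(subjects=subjects, snps=pd.DataFrame(rows),
                       dosage=np.column_stack(cols)).with_stats()


# ---------------------------------------------------------------------------
# cohort


def _simulate_epds_items(n: int, rng: np.random.Generator) -> np.ndarray:
    """Scored EPDS items (n x 10) from a one-factor thresholded latent model."""
    lam = _EPDS_LOADING
    f = rng.standard_normal((n, 1))
    x = lam * f + np.sqrt(1 - lam**2) * rng.standard_normal((n, 10))
    scored = np.zeros((n, 10))
    for cut in _EPDS_CUTS:
        scored += x > cut
    return scored


def simulate_cohort(n: int, seed: int = 0,
                    exclusion_fractions: dict | None = None) -> pd.DataFrame:
    """Mother-child dyad table with EPDS items, covariates and brain measures.

    EPDS totals approximate a mean of 8.6 and SD of 4.5 in [0, 30] with item
    consistency ~ 0.82; sex, ethnicity (3 levels), maternal education
    (5-level ladder), age at MRI and total brain volume follow the cohort's
    descriptive marginals.  ``exclusion_fractions`` plants failures for the
    inclusion cascade (keys: genotype, epds, demographics, apgar,
    gestational_age, birth_weight), all 0 by default.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    fr = {k: 0.0 for k in ("genotype", "epds", "demographics", "apgar",
                           "gestational_age", "birth_weight")}
    fr.update(exclusion_fractions or {})
    rng = np.random.default_rng(seed)
    scored = _simulate_epds_items(n, rng)
    raw = scored.copy()
    rev = [i - 1 for i in EPDS_REVERSED]
    raw[:, rev] = 3.0 - raw[:, rev]
    df = pd.DataFrame({EPDS_ITEMS[i]: raw[:, i].astype(float)
                       for i in range(10)})
    df.insert(0, "dyad_id", [f"D{i + 1:04d}" for i in range(n)])
    df["epds_total"] = np.clip(score_epds(raw), 0, 30)
    df["sex"] = np.where(rng.random(n) < 87 / 161, "M", "F")
    df["ethnicity"] = rng.choice(list(ETHNICITY_PROBS), size=n,
                                 p=list(ETHNICITY_PROBS.values()))
    df["maternal_education"] = rng.choice(EDUCATION_LEVELS, size=n,
                                          p=EDUCATION_PROBS)
    df["age_at_mri_weeks"] = np.clip(rng.normal(1.41, 0.52, n), 0.5, 3.0)
    df["gestational_age_weeks"] = np.clip(rng.normal(38.9, 1.1, n),
                                          34.0, 41.5)
    df["birth_weight_g"] = np.clip(rng.normal(3087.1, 372.1, n), 2010, 4500)
    df["apgar_5min"] = rng.choice([9.0, 10.0], size=n, p=[0.4, 0.6])
    df["has_genotype"] = True
    tbv_z = rng.standard_normal(n)
    df["total_brain_volume_cm3"] = 548.71 + 43.49 * tbv_z
    # brain measures: mildly coupled to total brain volume
    for name, (mu, sd) in BRAIN_MEASURES.items():
        z = 0.4 * tbv_z + np.sqrt(1 - 0.16) * rng.standard_normal(n)
        df[name] = mu + sd * z
    # planted inclusion failures
    def _mask(p):
        return rng.random(n) < p

    df.loc[_mask(fr["genotype"]), "has_genotype"] = False
    epds_out = _mask(fr["epds"])
    df.loc[epds_out, EPDS_ITEMS] = np.nan
    df.loc[epds_out, "epds_total"] = np.nan
    df.loc[_mask(fr["demographics"]), "ethnicity"] = np.nan
    df.loc[_mask(fr["apgar"]), "apgar_5min"] = rng.choice([7.0, 8.0])
    df.loc[_mask(fr["gestational_age"]), "gestational_age_weeks"] = \
        rng.uniform(30.0, 33.8)
    df.loc[_mask(fr["birth_weight"]), "birth_weight_g"] = \
        rng.uniform(1500.0, 1990.0)
    return df


# ---------------------------------------------------------------------------
# outcome under the MixGE generative model


@dataclass
class OutcomeSimSpec:
    """Ground-truth parameters of the MixGE generative model.

    pi is the shared (accumulative) interaction effect; tau the variance of
    the SNP-specific interaction deviations delta_j (drawn once per
    dataset); sigma the residual SD.
    """

    beta_X: float | np.ndarray = 0.0
    beta_E: float = 0.0
    beta_G: float | np.ndarray = 0.0
    pi: float = 0.0
    tau: float = 0.0
    sigma: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.tau < 0:
            raise ValueError("tau must be >= 0")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")


def simulate_outcome(G, cohort: pd.DataFrame, spec: OutcomeSimSpec,
                     column: str = "y_sim",
                     covariate_matrix: pd.DataFrame | None = None):
    """Append an outcome column generated under the MixGE model.

    Y = X beta_X + E beta_E + G beta_G + pi * E * rowsum(G)
        + sum_j E * G_j * delta_j + eps,
    delta_j ~ N(0, tau) drawn once per dataset, eps ~ N(0, sigma^2).

    G may be a GenotypeSet (aligned on dyad_id) or a complete dosage matrix.
    Returns (cohort with the new column, truth dict incl. the drawn delta).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    if isinstance(G, GenotypeSet):
        ids = list(cohort["dyad_id"])
        Gm = G.subset_subjects(ids).dosage
    else:
        Gm = np.asarray(G, dtype=float)
    if Gm.shape[0] != len(cohort):
        raise ValueError("genotypes and cohort are not aligned")
    if np.isnan(Gm).any():
        raise ValueError("outcome simulation needs complete dosages")
    if covariate_matrix is None:
        from .cohort import encode_covariates

        covariate_matrix = encode_covariates(cohort)
    X = covariate_matrix.to_numpy(dtype=float)
    E = cohort["epds_total"].to_numpy(dtype=float)
    if np.isnan(E).any():
        raise ValueError("cohort has missing EPDS totals; exclude them first")
    n, k = Gm.shape
    beta_X = np.broadcast_to(np.atleast_1d(np.asarray(spec.beta_X, float)),
                             (X.shape[1],))
    beta_G = np.broadcast_to(np.atleast_1d(np.asarray(spec.beta_G, float)),
                             (k,))
    delta = rng.normal(0.0, np.sqrt(spec.tau), k) if spec.tau > 0 \
        else np.zeros(k)
    eps = rng.normal(0.0, spec.sigma, n)
    y = (X @ beta_X + spec.beta_E * E + Gm @ beta_G
         + spec.pi * E * Gm.sum(axis=1) + E * (Gm @ delta) + eps)
    out = cohort.copy()
    out[column] = y
    truth = dict(pi=spec.pi, tau=spec.tau, delta=delta,
                 beta_E=spec.beta_E, sigma=spec.sigma)
    return out, truth


# ---------------------------------------------------------------------------
# fixture bundle


def write_fixture_bundle(outdir, seed: int = 0, n_subjects: int = 200,
                         n_genes: int = 60, n_samples: int = 14,
                         n_snps_per_gene: int = 8, ld_rho: float = 0.3,
                         planted_slope: float = 0.6,
                         planted_pi: float = 0.05) -> dict:
    """Write a complete, mutually consistent input bundle with known truth.

    Emits expression.tsv, cohort.csv, genotypes.vcf, dosages.tsv,
    gene_snp_map.tsv, eqtl.tsv and truth.json under ``outdir``.  Six named
    genes carry planted expression trends in their regions; they are the
    genotyped genes, and the first of them carries a planted accumulative
    interaction on its region's right-hemisphere measure.
    """
    import json
    from pathlib import Path

    from .genotype import write_dosage_tsv, write_gene_map, write_vcf

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    s_expr, s_geno, s_cohort, s_out, s_eqtl = ss.spawn(5)

    genes = default_gene_list(n_genes)
    planted = [
        GeneTrend("TNFRSF19", "HIP", -planted_slope, noise_sd=0.5),
        GeneTrend("IL17RB", "HIP", -planted_slope, noise_sd=0.5),
        GeneTrend("TGFBR1", "AMY", -planted_slope, noise_sd=0.5),
        GeneTrend("BMPR1B", "A1C", planted_slope, noise_sd=0.5),
        GeneTrend("IL1RAP", "OFC", planted_slope, noise_sd=0.5),
        GeneTrend("CXCR4", "DFC", planted_slope, noise_sd=0.5),
    ]
    expr = simulate_expression(ExpressionSimSpec(
        n_samples=n_samples, genes=planted, all_genes=genes,
        seed=s_expr.generate_state(1)[0] % 2**31))
    expr.to_tsv(outdir / "expression.tsv")

    geno_genes = [GeneSnpSpec(g.gene_id, n_snps_per_gene, (0.1, 0.5), ld_rho)
                  for g in planted]
    G = simulate_genotypes(GenotypeSimSpec(
        n_subjects=n_subjects, genes=geno_genes, missing_rate=0.01,
        seed=s_geno.generate_state(1)[0] % 2**31))
    cohort = simulate_cohort(
        n_subjects, seed=s_cohort.generate_state(1)[0] % 2**31,
        exclusion_fractions={"genotype": 0.03, "epds": 0.03, "apgar": 0.02})
    cohort.loc[~cohort["has_genotype"], :]  # flags only; genotypes still written

    # planted interaction: first planted gene on its region's right measure
    target_gene = planted[0].gene_id
    target_measure = f"{planted[0].region}_R"
    Gm = G.gene_matrix(target_gene)
    Gm_complete = np.where(np.isnan(Gm),
                           np.nanmean(Gm, axis=0, keepdims=True), Gm)
    ok = cohort["epds_total"].notna()
    rng_out = np.random.default_rng(s_out.generate_state(1)[0] % 2**31)
    mu, sd = BRAIN_MEASURES[target_measure]
    E = cohort.loc[ok, "epds_total"].to_numpy()
    signal = planted_pi * (E - E.mean()) * (
        Gm_complete[ok.to_numpy()] - Gm_complete[ok.to_numpy()].mean(0)
    ).sum(axis=1)
    base = cohort.loc[ok, target_measure].to_numpy()
    cohort.loc[ok, target_measure] = base + sd * signal

    cohort.to_csv(outdir / "cohort.csv", index=False, float_format="%.8g")
    write_vcf(G, outdir / "genotypes.vcf")
    write_dosage_tsv(G, outdir / "dosages.tsv")
    write_gene_map(G, outdir / "gene_snp_map.tsv")

    rng_eqtl = np.random.default_rng(s_eqtl.generate_state(1)[0] % 2**31)
    ann = G.snps[["snp_id", "gene_id"]].copy()
    ann["is_eqtl"] = (np.arange(len(ann)) % 2 == 0).astype(int)
    ann["direction"] = np.where(ann["is_eqtl"] == 1,
                                rng_eqtl.choice([1, -1], len(ann)), np.nan)
    ann.to_csv(outdir / "eqtl.tsv", sep="\t", index=False)

    truth = dict(planted_trends=[vars(g) for g in planted],
                 interaction=dict(gene=target_gene, measure=target_measure,
                                  pi_scaled=planted_pi))
    (outdir / "truth.json").write_text(json.dumps(truth, indent=2))
    return truth
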