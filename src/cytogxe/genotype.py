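"""Genotype loading, QC and gene-set grouping.

Genotypes are held as a subjects x SNPs dosage matrix counting a designated
allele (0/1/2 for hard calls, fractional for imputed dosages), with NaN for
missing entries.  QC follows the usual candidate-gene workflow: call-rate and
minor-allele-frequency filters, a Hardy-Weinberg exact test corrected for
multiple comparisons across all SNPs, minor-allele orientation, and per-SNP
mean imputation of the surviving missing entries so downstream set tests see
complete data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

SNP_META_COLUMNS = ["snp_id", "chrom", "pos", "ref_allele", "alt_allele", "gene_id"]


@dataclass
class GenotypeSet:
    """Subject x SNP dosage matrix plus per-SNP metadata.

    dosage counts the alt allele as loaded; after :func:`orient_minor_allele`
    it counts the minor allele.  Missing entries are NaN until
    :func:`qc_filter` mean-imputes them.
    """

    subjects: list
    snps: pd.DataFrame  # columns SNP_META_COLUMNS (+ maf, call_rate once computed)
    dosage: np.ndarray  # float, subjects x SNPs, NaN = missing
    imputed: bool = False

    def __post_init__(self):
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.subjects), len(self.snps)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} inconsistent with "
                f"{len(self.subjects)} subjects x {len(self.snps)} SNPs"
            )

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def with_stats(self) -> "GenotypeSet":
        """Return a copy whose metadata carries empirical maf and call_rate."""
        snps = self.snps.copy()
        with np.errstate(invalid="ignore"):
            af = np.nanmean(self.dosage, axis=0) / 2.0
        snps["maf"] = np.minimum(af, 1.0 - af)
        snps["alt_freq"] = af
        snps["call_rate"] = 1.0 - np.isnan(self.dosage).mean(axis=0)
        return replace(self, snps=snps)

    def take_snps(self, mask_or_idx) -> "GenotypeSet":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return replace(
            self,
            snps=self.snps.iloc[idx].reset_index(drop=True),
            dosage=self.dosage[:, idx],
        )

    def gene_matrix(self, gene_id: str) -> np.ndarray:
        """Dosage columns of one gene, in SNP metadata order."""
        idx = np.flatnonzero((self.snps["gene_id"] == gene_id).to_numpy())
        if idx.size == 0:
            raise KeyError(f"no SNPs assigned to gene {gene_id!r}")
        return self.dosage[:, idx]

    def subset_subjects(self, ids) -> "GenotypeSet":
        lookup = {s: i for i, s in enumerate(self.subjects)}
        missing = [s for s in ids if s not in lookup]
        if missing:
            raise KeyError(f"subjects absent from genotype set: {missing[:5]}")
        rows = [lookup[s] for s in ids]
        return replace(self, subjects=list(ids), dosage=self.dosage[rows])


# ---------------------------------------------------------------------------
# loading


def load_gene_map(path) -> pd.DataFrame:
    """gene -> SNP annotation TSV with columns gene_id, snp_id."""
    gm = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene_id", "snp_id"}
    if not required.issubset(gm.columns):
        raise ValueError(f"gene map must have columns {sorted(required)}")
    return gm[["gene_id", "snp_id"]]


def _attach_genes(snps: pd.DataFrame, dosage: np.ndarray, gene_map: pd.DataFrame):
    assign = dict(zip(gene_map["snp_id"], gene_map["gene_id"]))
    snps = snps.copy()
    snps["gene_id"] = snps["snp_id"].map(assign)
    keep = snps["gene_id"].notna().to_numpy()
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropped %d SNPs without a gene assignment", n_dropped)
    return snps.loc[keep].reset_index(drop=True), dosage[:, keep], n_dropped


def load_genotypes(path, fmt: str, gene_map) -> GenotypeSet:
    """Load a GenotypeSet from ``vcf`` (GT/DS fields) or ``dosage_tsv``.

    gene_map may be a path or a DataFrame with gene_id, snp_id.  SNPs without
    a gene assignment and multiallelic VCF records are dropped with a logged
    count.
    """
    if not isinstance(gene_map, pd.DataFrame):
        gene_map = load_gene_map(gene_map)
    if fmt == "vcf":
        subjects, snps, dosage = _read_vcf(str(path))
    elif fmt == "dosage_tsv":
        subjects, snps, dosage = _read_dosage_tsv(path)
    else:
        raise ValueError(f"unknown genotype format {fmt!r}")
    snps, dosage, _ = _attach_genes(snps, dosage, gene_map)
    if len(snps) == 0:
        raise ValueError("no SNPs remain after gene assignment")
    return GenotypeSet(subjects=subjects, snps=snps, dosage=dosage).with_stats()


def _read_vcf(path: str):
    from cyvcf2 import VCF

    vcf = VCF(path)
    subjects = list(vcf.samples)
    rows, dosages = [], []
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        fmts = var.FORMAT
        if "DS" in fmts and "GT" not in fmts:
            ds = np.asarray(var.format("DS"), dtype=float).ravel()
        else:
            gt = np.asarray(var.genotype.array())  # n x (ploidy+1), -1 = missing
            alleles = gt[:, :2].astype(float)
            alleles[alleles < 0] = np.nan
            ds = alleles.sum(axis=1)
        rows.append(
            dict(
                snp_id=var.ID or f"{var.CHROM}:{var.POS}",
                chrom=str(var.CHROM),
                pos=int(var.POS),
                ref_allele=var.REF,
                alt_allele=var.ALT[0],
            )
        )
        dosages.append(ds)
    if n_multi:
        logger.info("rejected %d multiallelic VCF records", n_multi)
    if not rows:
        raise ValueError(f"no biallelic SNP records in {path}")
    snps = pd.DataFrame(rows)
    return subjects, snps, np.column_stack(dosages)


def _read_dosage_tsv(path):
    df = pd.read_csv(path, sep="\t", index_col=0)
    subjects = [str(s) for s in df.index]
    snps = pd.DataFrame(
        dict(
            snp_id=df.columns,
            chrom="NA",
            pos=np.arange(1, df.shape[1] + 1),
            ref_allele="A",
            alt_allele="B",
        )
    )
    return subjects, snps, df.to_numpy(dtype=float)


def write_vcf(G: GenotypeSet, path) -> None:
    """Write hard-call genotypes as a minimal VCF v4.2 text file (GT field)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(G.snps["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(str(s) for s in G.subjects)
            + "\n"
        )
        gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        order = np.lexsort((G.snps["pos"].to_numpy(), G.snps["chrom"].to_numpy()))
        for j in order:
            row = G.snps.iloc[j]
            calls = [
                "./." if np.isnan(d) else gt_map[round(d)]
                for d in G.dosage[:, j]
            ]
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.snp_id}\t{row.ref_allele}\t"
                f"{row.alt_allele}\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n"
            )


def write_dosage_tsv(G: GenotypeSet, path) -> None:
    df = pd.DataFrame(G.dosage, index=G.subjects, columns=G.snps["snp_id"])
    df.to_csv(path, sep="\t", float_format="%.6g")


def write_gene_map(G: GenotypeSet, path) -> None:
    G.snps[["gene_id", "snp_id"]].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# QC


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact Hardy-Weinberg test.

    Conditional on the allele counts, sums the probabilities of all
    heterozygote counts no more likely than the observed one (the standard
    SNP exact test of Wigginton, Cutler & Abecasis).
    """
    counts = (n_AA, n_Aa, n_aa)
    if any(c < 0 or c != int(c) for c in counts):
        raise ValueError("genotype counts must be nonnegative integers")
    n = sum(counts)
    if n < 1:
        raise ValueError("total genotype count must be >= 1")
    n_rare = 2 * min(n_AA, n_aa) + n_Aa
    if n_rare == 0:
        return 1.0
    # heterozygote count shares the parity of the rare-allele count
    het_obs = n_Aa
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    # unnormalized log probabilities of each heterozygote count
    from scipy.special import gammaln

    n_hom_rare = (n_rare - hets) // 2
    n_hom_common = n - hets - n_hom_rare
    logp = (
        hets * np.log(2.0)
        - gammaln(hets + 1)
        - gammaln(n_hom_rare + 1)
        - gammaln(n_hom_common + 1)
    )
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()
    p_obs = prob[hets == het_obs][0]
    return float(min(1.0, prob[prob <= p_obs * (1 + 1e-12)].sum()))


def orient_minor_allele(G: GenotypeSet) -> GenotypeSet:
    """Flip SNPs so dosage counts the minor allele (maf <= 0.5 afterwards).

    Ties at frequency exactly 0.5 keep the alt allele as counted.  Idempotent.
    """
    G = G.with_stats()
    flip = (G.snps["alt_freq"] > 0.5).to_numpy()
    if not flip.any():
        return G
    dosage = G.dosage.copy()
    dosage[:, flip] = 2.0 - dosage[:, flip]
    snps = G.snps.copy()
    ref = snps.loc[flip, "ref_allele"].copy()
    snps.loc[flip, "ref_allele"] = snps.loc[flip, "alt_allele"].to_numpy()
    snps.loc[flip, "alt_allele"] = ref.to_numpy()
    out = replace(G, snps=snps, dosage=dosage)
    return out.with_stats()


def qc_filter(
    G: GenotypeSet,
    min_maf: float = 0.01,
    max_missing: float = 0.05,
    hwe_correction: str = "bonferroni",
    hwe_alpha: float = 0.05,
) -> tuple[GenotypeSet, dict]:
    """Remove SNPs failing call-rate, MAF, or corrected-HWE rules.

    Rules are applied in order (call rate, MAF, HWE); the audit attributes
    each removed SNP to the first failing rule.  Surviving missing dosages
    are mean-imputed per SNP and the set is oriented to the minor allele.
    """
    if not (0 <= min_maf <= 0.5 and 0 <= max_missing <= 1):
        raise ValueError("QC thresholds out of range")
    if hwe_correction not in ("bonferroni", "bh"):
        raise ValueError("hwe_correction must be 'bonferroni' or 'bh'")
    G = G.with_stats()
    n_in = G.n_snps
    miss_fail = (1.0 - G.snps["call_rate"].to_numpy()) > max_missing
    maf_fail = G.snps["maf"].to_numpy() < min_maf

    hwe_p = np.ones(n_in)
    hard = np.all(np.isnan(G.dosage) | (np.abs(G.dosage - np.round(G.dosage)) < 1e-9), axis=0)
    for j in range(n_in):
        if not hard[j]:
            continue  # fractional dosages carry no genotype counts to test
        d = G.dosage[:, j]
        d = d[~np.isnan(d)]
        counts = [(np.round(d) == g).sum() for g in (0, 1, 2)]
        hwe_p[j] = hwe_exact_test(*counts)
    if hwe_alpha <= 0:
        hwe_fail = np.zeros(n_in, dtype=bool)
    elif hwe_correction == "bonferroni":
        hwe_fail = hwe_p < hwe_alpha / n_in
    else:
        from statsmodels.stats.multitest import multipletests

        hwe_fail = multipletests(hwe_p, alpha=hwe_alpha, method="fdr_bh")[0]

    first_fail = np.select(
        [miss_fail, maf_fail & ~miss_fail, hwe_fail & ~miss_fail & ~maf_fail],
        ["call_rate", "maf", "hwe"],
        default="",
    )
    audit = {
        "input_snps": n_in,
        "removed_call_rate": int((first_fail == "call_rate").sum()),
        "removed_maf": int((first_fail == "maf").sum()),
        "removed_hwe": int((first_fail == "hwe").sum()),
    }
    keep = first_fail == ""
    audit["kept_snps"] = int(keep.sum())
    if audit["kept_snps"] == 0:
        raise ValueError(
            "all SNPs removed by QC; relax min_maf/max_missing/hwe_alpha"
        )
    out = G.take_snps(keep)
    out = orient_minor_allele(out)
    # mean-impute remaining missing dosages
    dosage = out.dosage.copy()
    nan_mask = np.isnan(dosage)
    if nan_mask.any():
        col_means = np.nanmean(dosage, axis=0)
        dosage[nan_mask] = np.take(col_means, np.nonzero(nan_mask)[1])
    out = replace(out, dosage=dosage, imputed=True).with_stats()
    return out, audit


def hwe_chi2_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """One-df chi-square HWE test (asymptotic reference for the exact test)."""
    n = n_AA + n_Aa + n_aa
    p = (2 * n_AA + n_Aa) / (2 * n)
    exp = np.array([n * p**2, 2 * n * p * (1 - p), n * (1 - p) ** 2])
    obs = np.array([n_AA, n_Aa, n_aa], dtype=float)
    if np.any(exp == 0):
        return 1.0
    x2 = ((obs - exp) ** 2 / exp).sum()
    return float(stats.chi2.sf(x2, 1))
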