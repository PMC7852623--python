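"""End-to-end orchestration: screen -> cohort -> genotype QC -> scan -> post hoc.

A single configuration drives the full analysis: the developmental
expression screen selects (gene, region) cells, the cohort table is scored
and filtered through the inclusion cascade, genotypes pass QC, the MixGE
scan tests each screen-passing gene against its region's left/right brain
measures, and significant interactions are unpacked with the GES simple
slopes.  Every filter logs counts into an audit chain whose totals must
conserve, and a JSON manifest (config hash, seed, versions, audits) makes
each run reproducible byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import (InclusionCriteria, apply_exclusions, cronbach_alpha,
                     encode_covariates, load_cohort_csv, EPDS_ITEMS)
from .genotype import load_genotypes, qc_filter
from .ges import compute_ges, load_eqtl_annotation, simple_slopes
from .mixge import run_scan
from .screen import (REGION_ORDER, adjust_screen, load_expression_tsv,
                     screen_all, select_region_genes)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """All knobs of one pipeline run; seed is mandatory."""

    expression: str
    cohort: str
    genotypes: str
    gene_map: str
    eqtl: str
    out_dir: str
    seed: int
    genotype_format: str = "vcf"
    screen_q: float = 0.01
    screen_per_region: bool = False
    qc_min_maf: float = 0.01
    qc_max_missing: float = 0.05
    hwe_correction: str = "bonferroni"
    hwe_alpha: float = 0.05
    scan_alpha: float = 0.05
    combine_mode: str = "fisher_perm"
    n_perm: int = 2000
    scan_adjust: bool = False
    posthoc_mode: str = "evaluation_point"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        flat = {}
        for key, val in raw.items():
            if isinstance(val, dict):
                flat.update(val)
            else:
                flat[key] = val
        return cls(**flat)

    def analysis_params(self) -> dict:
        """Config dict without the output location (which is not an
        analysis parameter; hash + seed determine every output byte)."""
        d = asdict(self)
        d.pop("out_dir")
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.analysis_params(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _write_tsv(df: pd.DataFrame, path: Path, provenance: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {provenance}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def make_descriptives(cohort: pd.DataFrame, measures: list) -> pd.DataFrame:
    """Mean (SD) and range for continuous fields, percentages for
    categorical fields, and per-measure mean (SD) for the brain measures."""
    rows = []
    continuous = ["gestational_age_weeks", "birth_weight_g",
                  "age_at_mri_weeks", "epds_total", "total_brain_volume_cm3"]
    for f in continuous:
        if f not in cohort.columns:
            continue
        v = cohort[f].astype(float)
        rows.append(dict(field=f, stat="mean_sd",
                         value=f"{v.mean():.2f} ({v.std(ddof=1):.2f})"))
        rows.append(dict(field=f, stat="range",
                         value=f"{v.min():.2f}-{v.max():.2f}"))
    for f in ("sex", "ethnicity", "maternal_education"):
        if f not in cohort.columns:
            continue
        pct = cohort[f].value_counts(normalize=True).sort_index() * 100
        for level, p in pct.items():
            rows.append(dict(field=f, stat=f"pct_{level}",
                             value=f"{p:.2f}"))
    for m in measures:
        v = cohort[m].astype(float)
        rows.append(dict(field=m, stat="mean_sd",
                         value=f"{v.mean():.3f} ({v.std(ddof=1):.3f})"))
    return pd.DataFrame(rows)


def make_heatmap_tables(screen: pd.DataFrame, scan: pd.DataFrame,
                        alpha: float = 0.05) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long-format tables behind the screen and interaction heatmaps.

    Screen: gene x region with -log10 adjusted p.  Scan: gene x measure with
    the combined interaction p and a significance marker at ``alpha``.  Rows
    follow the anatomical region order, then gene id.
    """
    def _region_rank(r):
        return REGION_ORDER.index(r) if r in REGION_ORDER else 99

    if len(screen):
        s = screen.copy()
        s["neglog10_p_adj"] = -np.log10(np.maximum(s["p_adj"], 1e-300))
        s["significant"] = s["p_adj"] < alpha
        s = s.assign(_rk=s["region"].map(_region_rank)).sort_values(
            ["_rk", "region", "gene_id"]).drop(columns="_rk")
        screen_hm = s[["region", "gene_id", "neglog10_p_adj", "significant"]]
        screen_hm = screen_hm.reset_index(drop=True)
    else:
        screen_hm = pd.DataFrame(
            columns=["region", "gene_id", "neglog10_p_adj", "significant"])
    if len(scan):
        t = scan.copy()
        t["significant"] = t["p_combined"] < alpha
        t = t.assign(_rk=t["region"].map(_region_rank)).sort_values(
            ["_rk", "region", "gene_id", "measure"]).drop(columns="_rk")
        scan_hm = t[["region", "gene_id", "measure", "p_combined",
                     "significant"]].reset_index(drop=True)
    else:
        scan_hm = pd.DataFrame(
            columns=["region", "gene_id", "measure", "p_combined",
                     "significant"])
    return screen_hm, scan_hm


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full pipeline; returns the manifest dict.

    Any stage failure removes this run's partial outputs and raises
    PipelineError naming the stage.
    """
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    created: list[Path] = []
    manifest = dict(config=cfg.analysis_params(),
                    config_hash=cfg.config_hash(),
                    seed=cfg.seed, version=__version__, audits={})
    prov = f"cytogxe {__version__} run {cfg.config_hash()} seed {cfg.seed}"

    def _emit(df, name):
        path = out_dir / name
        _write_tsv(df, path, prov)
        created.append(path)

    stage = "load_expression"
    try:
        expr = load_expression_tsv(cfg.expression)

        stage = "expression_screen"
        fits, screen_audit = screen_all(expr)
        fits = adjust_screen(fits, per_region=cfg.screen_per_region)
        region_map = select_region_genes(fits, q=cfg.screen_q)
        manifest["audits"]["screen"] = {
            "n_fits": screen_audit["n_fits"],
            "n_skipped": screen_audit["n_skipped"],
            "n_selected": int(sum(len(v) for v in region_map.values())),
        }
        _emit(fits, "screen_table.tsv")
        map_path = out_dir / "region_gene_map.json"
        map_path.write_text(json.dumps(
            {r: [[g, d, p] for g, d, p in v] for r, v in region_map.items()},
            indent=2))
        created.append(map_path)

        stage = "cohort"
        cohort = load_cohort_csv(cfg.cohort)
        included, excl_audit = apply_exclusions(cohort, InclusionCriteria())
        manifest["audits"]["exclusions"] = excl_audit
        if set(EPDS_ITEMS).issubset(included.columns):
            from .cohort import reverse_score_items

            scored_items = reverse_score_items(
                included[EPDS_ITEMS].to_numpy(dtype=float))
            manifest["epds_cronbach_alpha"] = round(
                cronbach_alpha(scored_items), 4)
        X = encode_covariates(included)

        stage = "genotype_qc"
        G = load_genotypes(cfg.genotypes, cfg.genotype_format, cfg.gene_map)
        G = G.subset_subjects(list(included["dyad_id"]))
        G, qc_audit = qc_filter(
            G, min_maf=cfg.qc_min_maf, max_missing=cfg.qc_max_missing,
            hwe_correction=cfg.hwe_correction, hwe_alpha=cfg.hwe_alpha)
        manifest["audits"]["genotype_qc"] = qc_audit

        stage = "scan"
        genotyped = set(G.snps["gene_id"])
        scan_map, dropped_genes = {}, []
        region_measures = {}
        for region, entries in region_map.items():
            keep = [e for e in entries if e[0] in genotyped]
            dropped_genes += [e[0] for e in entries if e[0] not in genotyped]
            meas = [m for m in (f"{region}_L", f"{region}_R")
                    if m in included.columns]
            if keep and meas:
                scan_map[region] = keep
                region_measures[region] = meas
        manifest["audits"]["scan"] = {
            "genes_without_genotypes": sorted(set(dropped_genes)),
            "n_pairs": int(sum(len(v) * len(region_measures[r])
                               for r, v in scan_map.items())),
        }
        scan = run_scan(scan_map, G, X,
                        included["epds_total"].to_numpy(dtype=float),
                        included, region_measures,
                        combine_mode=cfg.combine_mode, n_perm=cfg.n_perm,
                        seed=cfg.seed, adjust=cfg.scan_adjust)
        _emit(scan, "scan_table.tsv")

        stage = "posthoc"
        ann = load_eqtl_annotation(cfg.eqtl)
        hits = scan[scan["p_combined"] < cfg.scan_alpha] if len(scan) else scan
        rows, skipped = [], []
        for hit in hits.itertuples():
            try:
                ges = compute_ges(G, ann, hit.gene_id)
                res = simple_slopes(
                    included[hit.measure].to_numpy(dtype=float),
                    X.to_numpy(dtype=float),
                    included["epds_total"].to_numpy(dtype=float),
                    ges, mode=cfg.posthoc_mode, gene_id=hit.gene_id,
                    measure_id=hit.measure)
            except ValueError as exc:
                skipped.append([hit.gene_id, hit.measure, str(exc)])
                continue
            for r in res:
                rows.append(dict(gene_id=r.gene_id, measure=r.measure_id,
                                 group=r.group, slope=r.slope, se=r.se,
                                 p=r.p, n_effective=r.n_effective,
                                 mode=r.mode))
        posthoc = pd.DataFrame(
            rows, columns=["gene_id", "measure", "group", "slope", "se",
                           "p", "n_effective", "mode"])
        manifest["audits"]["posthoc"] = {
            "n_hits": int(len(hits)), "skipped": skipped}
        _emit(posthoc, "posthoc_table.tsv")

        stage = "report"
        measures = sorted({m for v in region_measures.values() for m in v})
        _emit(make_descriptives(included, measures), "descriptives.tsv")
        screen_hm, scan_hm = make_heatmap_tables(fits, scan, cfg.scan_alpha)
        _emit(screen_hm, "screen_heatmap.tsv")
        _emit(scan_hm, "scan_heatmap.tsv")

        man_path = out_dir / "manifest.json"
        man_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        created.append(man_path)
    except Exception as exc:
        for path in created:
            path.unlink(missing_ok=True)
        raise PipelineError(stage, exc) from exc
    return manifest
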