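"""End-to-end orchestration: filters -> karyotype -> reduction -> RDA ->
permutation tests -> outliers -> (optional) annotation.

Three dataset variants are supported, mirroring the analytical designs a
karyotype-GEA study runs:

* ``with_karyotype``    — all samples with a chromosome count; 2n enters
  the genotype matrix as one extra pseudo-locus.
* ``without_karyotype`` — same samples and SNPs, no pseudo-locus; the
  SNP-level results should match the first variant.
* ``cytotype_subsample`` — one sample per (population, cytotype) pair,
  karyotype included; probes whether the association survives when
  within-population cytotype replication is removed.

SNP filters run on the full sample set before any variant-specific
subsetting, so every variant analyses the same loci.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotation as ann
from .data import (GenotypeMatrix, PredictorTable, SampleTable,
                   append_karyotype, filter_coverage, filter_maf,
                   impute_missing, subsample_one_per_cytotype)
from .outliers import assign_predictor, detect_outliers, karyotype_status
from .rda import fit_rda
from .reduction import reduce_predictors, vif
from .significance import significant_axes, test_axes, test_global, test_terms

logger = logging.getLogger(__name__)

VARIANTS = ("with_karyotype", "without_karyotype", "cytotype_subsample")


@dataclass
class PipelineConfig:
    """All thresholds of the analysis in one place.

    Defaults are the study-protocol values: coverage in >=100 samples,
    MAF >= 0.10, predictor clustering cut 0.3 (|r| > 0.7), VIF < 10,
    1000 permutations, axis alpha 0.01, 2.5% loading tails, 50 kbp gene
    windows.
    """

    variant: str = "with_karyotype"
    min_called: int = 100
    maf_min: float = 0.10
    cut: float = 0.3
    vif_threshold: float = 10.0
    n_perm: int = 1000
    alpha: float = 0.01
    tail: float = 0.025
    window: int = 50_000
    karyotype_scaling: str = "standardized"
    impute: bool = True
    strata: str | None = None  # "population" restricts global permutations
    seed: int = 0

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")


@dataclass
class RunReport:
    """Machine-readable record of one pipeline run."""

    variant: str
    seed: int
    n_samples_in: int
    n_samples_analyzed: int
    n_loci_in: int
    n_loci_after_coverage: int
    n_loci_after_maf: int
    n_imputed_cells: int
    retained_predictors: list[str]
    vif_values: dict[str, float]
    vif_pass: bool
    total_inertia: float
    constrained_inertia: float
    proportion_constrained: float
    eigenvalues: list[float]
    pve: list[float]
    global_F: float
    global_p: float
    term_p: dict[str, float]
    axis_p: dict[str, float]
    significant_axes: list[int]
    n_outliers: int
    outliers_per_predictor: dict[str, int]
    karyotype_flagged: bool | None
    karyotype_axis: int | None
    karyotype_predictor: str | None
    karyotype_r: float | None
    runtime_s: float = 0.0
    config: dict = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2, default=_jsonify)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "RunReport":
        p = Path(str(source))
        text = p.read_text() if p.exists() else str(source)
        return cls(**json.loads(text))

    def summary(self) -> str:
        lines = [
            f"variant: {self.variant} (seed {self.seed})",
            f"samples analysed: {self.n_samples_analyzed} / {self.n_samples_in}",
            f"loci: {self.n_loci_in} -> {self.n_loci_after_coverage} "
            f"(coverage) -> {self.n_loci_after_maf} (MAF)",
            f"retained predictors: {', '.join(self.retained_predictors)}",
            f"constrained inertia: {100 * self.proportion_constrained:.1f}% "
            f"of total {self.total_inertia:.2f}",
            f"global F = {self.global_F:.3f} (p = {self.global_p:.4g})",
            f"significant axes: {self.significant_axes}",
            f"outliers: {self.n_outliers} "
            f"({', '.join(f'{k}: {v}' for k, v in self.outliers_per_predictor.items())})",
        ]
        if self.karyotype_flagged is not None:
            if self.karyotype_flagged:
                lines.append(
                    f"karyotype: OUTLIER on RDA{self.karyotype_axis}, "
                    f"best predictor {self.karyotype_predictor} "
                    f"(r = {self.karyotype_r:+.3f})")
            else:
                lines.append("karyotype: not an outlier")
        return "\n".join(lines)


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


@dataclass
class PipelineResult:
    """Report plus the heavyweight intermediates for further inspection."""

    report: RunReport
    model: object
    outlier_table: pd.DataFrame
    genotypes: GenotypeMatrix
    samples: SampleTable
    predictors_retained: PredictorTable
    annotated: pd.DataFrame | None = None


def run_pipeline(genotypes: GenotypeMatrix, samples: SampleTable,
                 predictors: PredictorTable, config: PipelineConfig,
                 genes: dict[str, pd.DataFrame] | None = None
                 ) -> PipelineResult:
    """Run the full GEA analysis and return the report + intermediates."""
    t0 = time.perf_counter()
    cfg = config
    n_in, L_in = genotypes.n_samples, genotypes.n_loci

    # --- locus filters (full sample set, shared across variants) -------
    g = filter_coverage(genotypes, cfg.min_called)
    n_cov = g.n_loci
    g = filter_maf(g, cfg.maf_min)
    n_maf = g.n_loci
    if g.n_loci == 0:
        raise RuntimeError("stage filters: no loci survive")
    n_missing = int((g.values == -1).sum())
    if cfg.impute:
        g = impute_missing(g)
    elif n_missing:
        raise RuntimeError("stage filters: missing calls present and "
                           "impute=False")

    # --- variant-specific sample handling ------------------------------
    meta = samples
    if cfg.variant == "cytotype_subsample":
        g, meta = subsample_one_per_cytotype(g, samples, seed=cfg.seed)
    if cfg.variant in ("with_karyotype", "cytotype_subsample"):
        g = append_karyotype(g, meta, scaling=cfg.karyotype_scaling)
        meta = SampleTable(meta.aligned_to(g.sample_ids))

    # --- predictor reduction -------------------------------------------
    pred_aligned = PredictorTable(
        predictors.table.set_index("sample_id").loc[g.sample_ids]
        .reset_index(), predictors.classes)
    red = reduce_predictors(pred_aligned, cut=cfg.cut)
    retained = pred_aligned.subset(red.retained)
    vif_series, vif_ok = vif(retained, threshold=cfg.vif_threshold)
    if not vif_ok:
        logger.warning("VIF check failed: %s", vif_series.to_dict())

    # --- ordination and tests ------------------------------------------
    model = fit_rda(g, retained)
    f_global = test_global(g, retained, n_perm=cfg.n_perm, seed=cfg.seed,
                           strata=(meta.aligned_to(g.sample_ids)["population"]
                                   if cfg.strata == "population" else None))
    terms = test_terms(g, retained, n_perm=cfg.n_perm, seed=cfg.seed + 1)
    axes = test_axes(g, retained, n_perm=cfg.n_perm, seed=cfg.seed + 2,
                     alpha=cfg.alpha)
    sig = significant_axes(axes, alpha=cfg.alpha)

    # --- outliers -------------------------------------------------------
    if sig:
        table = detect_outliers(model, sig, tail=cfg.tail)
        table = assign_predictor(table, g, retained)
    else:
        logger.warning("no significant axes; outlier table is empty")
        from .outliers import REPORT_COLUMNS
        table = pd.DataFrame(columns=REPORT_COLUMNS)

    k_status = None
    if g.karyotype_col is not None:
        k_status = karyotype_status(table, g)

    annotated = None
    if genes is not None and len(table):
        annotated = ann.annotate_outliers(table, g.locus_map, genes,
                                          window=cfg.window)

    per_pred = (table[~table["is_karyotype"].astype(bool)]
                .groupby("best_predictor")["locus_id"].count().to_dict()
                if len(table) else {})
    report = RunReport(
        variant=cfg.variant,
        seed=cfg.seed,
        n_samples_in=n_in,
        n_samples_analyzed=g.n_samples,
        n_loci_in=L_in,
        n_loci_after_coverage=n_cov,
        n_loci_after_maf=n_maf,
        n_imputed_cells=n_missing if cfg.impute else 0,
        retained_predictors=red.retained,
        vif_values={k: float(v) for k, v in vif_series.items()},
        vif_pass=vif_ok,
        total_inertia=model.total_inertia,
        constrained_inertia=model.constrained_inertia,
        proportion_constrained=model.proportion_constrained,
        eigenvalues=[float(e) for e in model.eigenvalues],
        pve=[float(v) for v in model.pve],
        global_F=f_global.observed_F,
        global_p=f_global.p_value,
        term_p={r.target.split(":", 1)[1]: r.p_value for r in terms},
        axis_p={r.target.split(":", 1)[1]: r.p_value for r in axes},
        significant_axes=sig,
        n_outliers=int(len(table)),
        outliers_per_predictor={str(k): int(v) for k, v in per_pred.items()},
        karyotype_flagged=None if k_status is None else k_status.flagged,
        karyotype_axis=None if k_status is None else k_status.axis,
        karyotype_predictor=None if k_status is None else k_status.best_predictor,
        karyotype_r=None if k_status is None else k_status.r_best,
        runtime_s=time.perf_counter() - t0,
        config=asdict(cfg),
    )
    logger.info("pipeline done in %.1fs: %s", report.runtime_s,
                report.summary().replace("\n", " | "))
    return PipelineResult(report=report, model=model, outlier_table=table,
                          genotypes=g, samples=meta,
                          predictors_retained=retained, annotated=annotated)
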