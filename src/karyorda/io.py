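"""Readers and writers for genotypes, sample metadata and predictors.

Genotypes arrive either as VCF (parsed with cyvcf2) or as a tab-separated
012 matrix with a sidecar locus map.  All writers emit deterministic
column order so round trips are byte-stable.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .data import MISSING, GenotypeMatrix, PredictorTable, SampleTable

logger = logging.getLogger(__name__)

# cyvcf2 gt_types codes
_HOM_REF, _HET, _UNKNOWN, _HOM_ALT = 0, 1, 2, 3

#: bioclim naming convention: which BIO variables summarise quarters /
#: single months; everything else (annual means, ranges, seasonality) is
#: tagged "other".
BIOCLIM_CLASSES: dict[str, str] = {
    **{f"BIO{i}": "quarterly" for i in (8, 9, 10, 11, 16, 17, 18, 19)},
    **{f"BIO{i}": "monthly" for i in (5, 6, 13, 14)},
    **{f"BIO{i}": "other" for i in (1, 2, 3, 4, 7, 12, 15)},
}


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a VCF into a minor-allele-count matrix.

    Multiallelic sites are dropped (logged).  Counts are oriented so that
    2 means two copies of the *minor* allele at that site; a 50/50 tie
    keeps the alternate-allele orientation.  Missing genotypes become -1.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    if not sample_ids:
        raise ValueError(f"{path}: VCF has no samples")
    cols: list[np.ndarray] = []
    loci: list[dict] = []
    n_multi = 0
    for v in vcf:
        if len(v.ALT) != 1:
            n_multi += 1
            continue
        gt = np.asarray(v.gt_types)
        col = np.full(gt.shape, MISSING, dtype=np.int8)
        col[gt == _HOM_REF] = 0
        col[gt == _HET] = 1
        col[gt == _HOM_ALT] = 2
        called = col != MISSING
        if called.any():
            alt_freq = col[called].sum() / (2.0 * called.sum())
            if alt_freq > 0.5:  # ties keep alt orientation
                col[called] = 2 - col[called]
        cols.append(col)
        lid = v.ID if v.ID not in (None, ".") else f"{v.CHROM}_{v.POS}"
        loci.append({"locus_id": lid, "contig": v.CHROM, "position": v.POS})
    if n_multi:
        logger.info("dropped %d multiallelic sites", n_multi)
    if not cols:
        raise ValueError(f"{path}: no biallelic sites found")
    values = np.column_stack(cols)
    return GenotypeMatrix(values, pd.DataFrame(loci), sample_ids)


def write_vcf(g: GenotypeMatrix, path: str | Path) -> None:
    """Write SNP columns as a minimal VCF v4.2 (REF=A, ALT=T placeholders).

    Counts are emitted as ALT-allele dosage, so a matrix that is already
    minor-oriented round-trips unchanged.  The karyotype pseudo-locus is
    not a variant and is skipped.
    """
    g = g.take_loci(g.snp_mask())
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(g.sample_ids) + "\n")
        for j, row in g.locus_map.iterrows():
            gts = "\t".join(gt_map[int(v)] for v in g.values[:, j])
            fh.write(f"{row.contig}\t{row.position}\t{row.locus_id}"
                     f"\tA\tT\t.\tPASS\t.\tGT\t{gts}\n")


def read_012(matrix_path: str | Path, loci_path: str | Path) -> GenotypeMatrix:
    """Read a 012 matrix TSV (sample_id + one column per locus, -1 missing)
    with its sidecar locus map (locus_id, contig, position)."""
    mat = pd.read_csv(matrix_path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in mat.columns:
        raise ValueError(f"{matrix_path}: no sample_id column")
    if len(mat) == 0:
        raise ValueError(f"{matrix_path}: zero samples")
    loci = pd.read_csv(loci_path, sep="\t", dtype={"locus_id": str, "contig": str})
    need = {"locus_id", "contig", "position"}
    if not need.issubset(loci.columns):
        raise ValueError(f"{loci_path}: locus map needs columns {sorted(need)}")
    locus_cols = [c for c in mat.columns if c != "sample_id"]
    if locus_cols != list(loci["locus_id"]):
        raise ValueError("012 matrix columns do not match the locus map")
    values = mat[locus_cols].to_numpy(np.int16)
    karyo = None
    from .data import KARYOTYPE_ID
    if KARYOTYPE_ID in locus_cols:
        karyo = locus_cols.index(KARYOTYPE_ID)
    return GenotypeMatrix(values, loci.reset_index(drop=True),
                          list(mat["sample_id"]), karyotype_col=karyo)


def write_012(g: GenotypeMatrix, matrix_path: str | Path,
              loci_path: str | Path) -> None:
    out = pd.DataFrame(g.values, columns=g.locus_ids)
    out.insert(0, "sample_id", g.sample_ids)
    out.to_csv(matrix_path, sep="\t", index=False)
    g.locus_map.to_csv(loci_path, sep="\t", index=False)


def read_samples(path: str | Path) -> SampleTable:
    """Sample metadata TSV: sample_id, population, species, lat, lon, two_n."""
    t = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "population": str})
    return SampleTable(t)


def write_samples(s: SampleTable, path: str | Path) -> None:
    s.table[list(SampleTable.REQUIRED)].to_csv(path, sep="\t", index=False)


def read_predictors(path: str | Path,
                    classes_path: str | Path | None = None,
                    use_bioclim_classes: bool = True) -> PredictorTable:
    """Predictor TSV (sample_id + numeric columns) plus optional class-tag
    file (predictor <tab> class).  Without a tag file, BIO* names fall back
    to the bioclim monthly/quarterly convention."""
    t = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    classes: dict[str, str] = {}
    if classes_path is not None:
        ct = pd.read_csv(classes_path, sep="\t", header=None,
                         names=["predictor", "class"])
        classes = dict(zip(ct["predictor"], ct["class"]))
    elif use_bioclim_classes:
        classes = {c: BIOCLIM_CLASSES[c] for c in t.columns if c in BIOCLIM_CLASSES}
    return PredictorTable(t, classes)


def write_predictors(p: PredictorTable, path: str | Path,
                     classes_path: str | Path | None = None) -> None:
    p.table[["sample_id"] + p.names].to_csv(path, sep="\t", index=False)
    if classes_path is not None:
        with open(classes_path, "w") as fh:
            for name in p.names:
                fh.write(f"{name}\t{p.class_of(name)}\n")
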