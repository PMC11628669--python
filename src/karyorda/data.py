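"""Core containers and matrix-level operations for karyotype-aware GEA.

The analysis works on a samples x loci matrix of minor-allele counts
(0/1/2, missing = -1).  The diploid chromosome number (2n) can be appended
as one extra "pseudo-locus" column so that constrained ordination treats
the karyotype exactly like a SNP; that column is exempt from the SNP
filters and may be standardized before entering the ordination.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: sentinel for a missing genotype call
MISSING = -1

#: name given to the appended chromosome-number pseudo-locus
KARYOTYPE_ID = "KARYOTYPE"


@dataclass
class GenotypeMatrix:
    """Samples x loci minor-allele count matrix with a locus map.

    Parameters
    ----------
    values
        Integer array of shape (n_samples, n_loci); entries in {0, 1, 2}
        or :data:`MISSING`.  The karyotype column, when present, holds raw
        2n counts.
    locus_map
        DataFrame with columns ``locus_id``, ``contig``, ``position``
        (1-based bp), one row per column of ``values``.
    sample_ids
        Ordered unique sample identifiers.
    karyotype_col
        Column index of the chromosome-number pseudo-locus, or None.
    karyotype_scaling
        "standardized" (default) centers the karyotype column to unit
        variance when the analysis matrix is built; "raw" leaves the 2n
        scale untouched.
    """

    values: np.ndarray
    locus_map: pd.DataFrame
    sample_ids: list[str]
    karyotype_col: int | None = None
    karyotype_scaling: str = "standardized"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D samples x loci array")
        n, L = self.values.shape
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} rows")
        if len(self.locus_map) != L:
            raise ValueError(f"{len(self.locus_map)} locus rows for {L} columns")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample_ids are not unique")
        if self.locus_map["locus_id"].duplicated().any():
            raise ValueError("locus_ids are not unique")
        snp = self.snp_values()
        bad = (snp != MISSING) & ((snp < 0) | (snp > 2))
        if bad.any():
            raise ValueError("SNP genotype entries must be in {0,1,2} or missing")

    # -- basic accessors ---------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_loci(self) -> int:
        return self.values.shape[1]

    @property
    def locus_ids(self) -> list[str]:
        return list(self.locus_map["locus_id"])

    def snp_mask(self) -> np.ndarray:
        """Boolean mask over columns that are true SNPs (not the karyotype)."""
        mask = np.ones(self.n_loci, dtype=bool)
        if self.karyotype_col is not None:
            mask[self.karyotype_col] = False
        return mask

    def snp_values(self) -> np.ndarray:
        return self.values[:, self.snp_mask()]

    def take_loci(self, keep: np.ndarray) -> "GenotypeMatrix":
        """Subset columns by boolean mask or index array, tracking karyotype."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep
        new_k = None
        if self.karyotype_col is not None:
            pos = np.flatnonzero(idx == self.karyotype_col)
            new_k = int(pos[0]) if pos.size else None
        return replace(
            self,
            values=self.values[:, idx],
            locus_map=self.locus_map.iloc[idx].reset_index(drop=True),
            karyotype_col=new_k,
        )

    def take_samples(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return replace(
            self,
            values=self.values[idx],
            sample_ids=[self.sample_ids[i] for i in idx],
        )

    # -- analysis matrix ---------------------------------------------------

    def analysis_matrix(self) -> np.ndarray:
        """Float matrix that enters the ordination.

        SNP columns are the raw 0/1/2 counts; the karyotype column is
        standardized to zero mean / unit variance when
        ``karyotype_scaling == "standardized"``.  Requires a complete
        (imputed) matrix.
        """
        if (self.values == MISSING).any():
            raise ValueError("matrix contains missing entries; impute first")
        Y = self.values.astype(float)
        k = self.karyotype_col
        if k is not None and self.karyotype_scaling == "standardized":
            col = Y[:, k]
            sd = col.std(ddof=1)
            if sd == 0:
                raise ValueError("karyotype column has zero variance")
            Y[:, k] = (col - col.mean()) / sd
        return Y


@dataclass
class SampleTable:
    """Per-sample metadata: population, species, coordinates, 2n."""

    table: pd.DataFrame

    REQUIRED = ("sample_id", "population", "species", "lat", "lon", "two_n")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"sample table lacks columns: {missing}")
        if self.table["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_id in sample table")
        self.table = self.table.reset_index(drop=True)

    def aligned_to(self, sample_ids: list[str]) -> pd.DataFrame:
        t = self.table.set_index("sample_id")
        missing = [s for s in sample_ids if s not in t.index]
        if missing:
            raise ValueError(f"samples absent from sample table: {missing[:5]}")
        return t.loc[sample_ids].reset_index()


@dataclass
class PredictorTable:
    """Per-sample environmental predictors with a class tag per column.

    ``classes`` maps predictor name to "monthly", "quarterly" or "other";
    unlisted predictors default to "other".  Population-level tables are
    broadcast to samples before construction.
    """

    table: pd.DataFrame  # sample_id + numeric predictor columns
    classes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if "sample_id" not in self.table.columns:
            raise ValueError("predictor table needs a sample_id column")
        if self.table.columns.duplicated().any():
            raise ValueError("duplicate predictor names")
        num = self.table.drop(columns="sample_id")
        if num.isna().any().any():
            raise ValueError("predictor table contains missing values")
        self.table = self.table.reset_index(drop=True)
        for name, cls in self.classes.items():
            if cls not in ("monthly", "quarterly", "other"):
                raise ValueError(f"bad class {cls!r} for predictor {name}")

    @property
    def names(self) -> list[str]:
        return [c for c in self.table.columns if c != "sample_id"]

    def class_of(self, name: str) -> str:
        return self.classes.get(name, "other")

    def matrix(self, names: list[str] | None = None,
               sample_ids: list[str] | None = None) -> np.ndarray:
        t = self.table
        if sample_ids is not None:
            t = t.set_index("sample_id").loc[sample_ids].reset_index()
        return t[names or self.names].to_numpy(float)

    def subset(self, names: list[str]) -> "PredictorTable":
        return PredictorTable(
            self.table[["sample_id"] + list(names)].copy(),
            {n: self.class_of(n) for n in names},
        )


# ---------------------------------------------------------------------------
# filters and matrix edits
# ---------------------------------------------------------------------------

def filter_coverage(g: GenotypeMatrix, min_called: int) -> GenotypeMatrix:
    """Keep SNP columns called in at least ``min_called`` samples.

    The karyotype pseudo-locus is always retained; column order is
    preserved.
    """
    if min_called > g.n_samples:
        raise ValueError("min_called exceeds the number of samples")
    called = (g.values != MISSING).sum(axis=0)
    keep = called >= min_called
    if g.karyotype_col is not None:
        keep[g.karyotype_col] = True
    dropped = int((~keep).sum())
    if dropped:
        logger.info("coverage filter: dropped %d of %d loci", dropped, g.n_loci)
    return g.take_loci(keep)


def minor_allele_frequency(g: GenotypeMatrix) -> np.ndarray:
    """Per-SNP minor allele frequency over non-missing calls.

    Counts are oriented to the minor allele at read time, but filtering
    can change which allele is rarer, so the frequency is folded:
    ``min(f, 1 - f)``.  Karyotype column (if any) gets NaN.
    """
    vals = g.values
    called = vals != MISSING
    with np.errstate(invalid="ignore"):
        f = np.where(called, vals, 0).sum(axis=0) / (2.0 * called.sum(axis=0))
    maf = np.minimum(f, 1.0 - f)
    if g.karyotype_col is not None:
        maf = maf.astype(float)
        maf[g.karyotype_col] = np.nan
    return maf


def filter_maf(g: GenotypeMatrix, maf_min: float) -> GenotypeMatrix:
    """Keep SNP columns with minor allele frequency >= ``maf_min``."""
    if not 0 <= maf_min <= 0.5:
        raise ValueError("maf_min must lie in [0, 0.5]")
    maf = minor_allele_frequency(g)
    with np.errstate(invalid="ignore"):
        keep = maf >= maf_min  # NaN compares False
    if g.karyotype_col is not None:
        keep[g.karyotype_col] = True
    dropped = int((~keep).sum())
    if dropped:
        logger.info("MAF filter (>=%.3g): dropped %d of %d loci",
                    maf_min, dropped, g.n_loci)
    return g.take_loci(keep)


def impute_missing(g: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing calls with the per-locus modal genotype.

    Ties between equally common genotypes resolve to the smallest count
    value.  Raises if any column is entirely missing.
    """
    vals = g.values.copy()
    n_missing = int((vals == MISSING).sum())
    for j in range(vals.shape[1]):
        col = vals[:, j]
        miss = col == MISSING
        if not miss.any():
            continue
        obs = col[~miss]
        if obs.size == 0:
            raise ValueError(
                f"locus {g.locus_map['locus_id'].iloc[j]!r} is entirely missing")
        uniq, counts = np.unique(obs, return_counts=True)
        col[miss] = uniq[np.argmax(counts)]
    if n_missing:
        logger.info("imputed %d missing cells (%.2f%% of matrix)",
                    n_missing, 100.0 * n_missing / vals.size)
    return replace(g, values=vals)


def append_karyotype(g: GenotypeMatrix, samples: SampleTable,
                     scaling: str = "standardized") -> GenotypeMatrix:
    """Append the diploid chromosome number as one extra pseudo-locus.

    Samples without a chromosome count are dropped (with a log line).
    The new column is flagged so filters skip it; under
    ``scaling="standardized"`` it is rescaled only when the analysis
    matrix is built, keeping raw 2n values inspectable.
    """
    if scaling not in ("standardized", "raw"):
        raise ValueError("scaling must be 'standardized' or 'raw'")
    if g.karyotype_col is not None:
        raise ValueError("matrix already has a karyotype column")
    meta = samples.aligned_to(g.sample_ids)
    two_n = meta["two_n"].to_numpy(float)
    have = ~np.isnan(two_n)
    if not have.any():
        raise ValueError("no sample has a chromosome number")
    if not have.all():
        dropped = [s for s, h in zip(g.sample_ids, have) if not h]
        logger.info("dropping %d samples without chromosome counts: %s",
                    len(dropped), dropped)
        g = g.take_samples(np.flatnonzero(have))
        two_n = two_n[have]
    if np.ptp(two_n) == 0:
        raise ValueError("karyotype column would have zero variance")
    new_vals = np.column_stack([g.values, two_n.astype(g.values.dtype)])
    new_map = pd.concat(
        [g.locus_map,
         pd.DataFrame([{"locus_id": KARYOTYPE_ID, "contig": ".", "position": 0}])],
        ignore_index=True)
    return replace(g, values=new_vals, locus_map=new_map,
                   karyotype_col=g.n_loci, karyotype_scaling=scaling)


def subsample_one_per_cytotype(
    g: GenotypeMatrix, samples: SampleTable, seed: int
) -> tuple[GenotypeMatrix, SampleTable]:
    """Keep one sample per (population, 2n) combination.

    When a chromosome number is carried by several samples of one
    population, one is chosen at random (reproducibly under ``seed``).
    The output size equals the number of distinct (population, cytotype)
    pairs regardless of seed.
    """
    meta = samples.aligned_to(g.sample_ids)
    if meta["two_n"].isna().any():
        raise ValueError("all samples need a chromosome number to subsample")
    rng = np.random.default_rng(seed)
    keep: list[int] = []
    for (_, _), grp in meta.groupby(["population", "two_n"], sort=True):
        keep.append(int(rng.choice(grp.index.to_numpy())))
    keep = sorted(keep)
    sub_g = g.take_samples(np.array(keep))
    sub_meta = meta.iloc[keep].reset_index(drop=True)
    return sub_g, SampleTable(sub_meta)
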