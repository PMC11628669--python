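"""Tail-based outlier detection on RDA loadings and predictor assignment.

Candidate loci for local adaptation are those whose loadings fall in the
extreme tails (default 2.5% per side) of the empirical loading
distribution on each significant constrained axis.  Each candidate is
then assigned the environmental predictor with which its genotype column
correlates most strongly.  The karyotype pseudo-locus competes like any
SNP, so a chromosome-number cline that tracks the environment is
recoverable as an "outlier locus".
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import KARYOTYPE_ID, GenotypeMatrix, PredictorTable
from .rda import RDAModel

logger = logging.getLogger(__name__)

#: columns of the outlier report table
REPORT_COLUMNS = ["locus_id", "axis", "loading", "tail", "is_karyotype",
                  "best_predictor", "r_best"]


def detect_outliers(model: RDAModel, sig_axes: list[int],
                    tail: float = 0.025) -> pd.DataFrame:
    """Flag loci in the upper/lower loading tails of each significant axis.

    Parameters
    ----------
    model
        Fitted RDA; raw-eigenvector locus loadings are used.
    sig_axes
        1-based axes to scan (from the axis permutation tests).
    tail
        Fraction per tail; quantiles are empirical order statistics
        with linear interpolation, and exceedance is strict, so tied
        loadings at the boundary are not flagged.

    The quantile pool is the SNP loadings; the karyotype pseudo-locus is
    judged against those SNP-derived thresholds but does not shift them,
    so the SNP candidate list is the same whether or not the karyotype
    entered the ordination.

    Returns the outlier report table (one row per locus, deduplicated
    across axes to the axis of largest absolute loading), with
    ``best_predictor``/``r_best`` left to :func:`assign_predictor`.
    """
    if not 0 < tail < 0.5:
        raise ValueError("tail must lie in (0, 0.5)")
    if not sig_axes:
        raise ValueError("no significant axes supplied")
    L = model.locus_scores.shape[0]
    if L < int(np.ceil(1.0 / tail)):
        warnings.warn(f"only {L} loci for tail={tail}; tails may be empty")
    snp_pool = np.array([lid != KARYOTYPE_ID for lid in model.locus_ids])
    rows = []
    for axis in sig_axes:
        if not 1 <= axis <= model.n_axes:
            raise ValueError(f"axis {axis} outside 1..{model.n_axes}")
        load = model.locus_scores[:, axis - 1]
        lo = np.quantile(load[snp_pool], tail)
        hi = np.quantile(load[snp_pool], 1.0 - tail)
        for j in np.flatnonzero((load < lo) | (load > hi)):
            rows.append({
                "locus_id": model.locus_ids[j],
                "axis": axis,
                "loading": float(load[j]),
                "tail": "lower" if load[j] < lo else "upper",
                "is_karyotype": model.locus_ids[j] == KARYOTYPE_ID,
            })
    report = pd.DataFrame(rows, columns=REPORT_COLUMNS[:5])
    if report.empty:
        report["best_predictor"] = pd.Series(dtype=object)
        report["r_best"] = pd.Series(dtype=float)
        return report
    # deduplicate across axes: keep the axis with the largest |loading|
    report = (report.assign(_abs=report["loading"].abs())
              .sort_values(["_abs", "axis"], ascending=[False, True])
              .drop_duplicates("locus_id", keep="first")
              .drop(columns="_abs")
              .sort_values(["axis", "locus_id"])
              .reset_index(drop=True))
    report["best_predictor"] = pd.NA
    report["r_best"] = np.nan
    return report


def assign_predictor(report: pd.DataFrame, Y: GenotypeMatrix,
                     X: PredictorTable) -> pd.DataFrame:
    """Assign each outlier the predictor its genotype column tracks best.

    Correlations are Pearson r between the (imputed) genotype column —
    the karyotype column on its analysis scale — and each retained
    predictor; the largest |r| wins, ties broken alphabetically.
    """
    if report.empty:
        return report
    Ymat = Y.analysis_matrix()
    Xmat = X.matrix(sample_ids=Y.sample_ids)
    names = X.names
    col_of = {lid: j for j, lid in enumerate(Y.locus_ids)}
    out = report.copy()
    for i, row in out.iterrows():
        lid = row["locus_id"]
        if lid not in col_of:
            raise ValueError(f"outlier locus {lid!r} not in genotype matrix")
        y = Ymat[:, col_of[lid]]
        if y.std(ddof=1) == 0:
            raise ValueError(f"locus {lid!r} has zero variance")
        rs = {}
        for j, name in enumerate(names):
            rs[name] = float(np.corrcoef(y, Xmat[:, j])[0, 1])
        best = sorted(rs, key=lambda nm: (-abs(rs[nm]), nm))[0]
        near = [nm for nm in rs
                if nm != best and abs(abs(rs[nm]) - abs(rs[best])) < 1e-12]
        if near:
            logger.info("locus %s: correlation tie between %s and %s; "
                        "alphabetical winner kept", lid, best, near)
        out.at[i, "best_predictor"] = best
        out.at[i, "r_best"] = rs[best]
    return out


@dataclass
class KaryotypeStatus:
    """Whether the chromosome-number pseudo-locus was flagged, and how."""

    flagged: bool
    axis: int | None = None
    loading: float | None = None
    tail: str | None = None
    best_predictor: str | None = None
    r_best: float | None = None

    def summary(self) -> str:
        if not self.flagged:
            return "karyotype pseudo-locus not flagged as an outlier"
        return (f"karyotype flagged on axis RDA{self.axis} "
                f"({self.tail} tail, loading {self.loading:+.4f}), "
                f"best predictor {self.best_predictor} (r={self.r_best:+.3f})")


def karyotype_status(report: pd.DataFrame,
                     g: GenotypeMatrix) -> KaryotypeStatus:
    """Report whether the karyotype column landed in the outlier set."""
    if g.karyotype_col is None:
        raise ValueError("genotype matrix has no karyotype column")
    hit = report[report["is_karyotype"]] if not report.empty else report
    if hit is None or len(hit) == 0:
        return KaryotypeStatus(flagged=False)
    row = hit.iloc[0]
    return KaryotypeStatus(
        flagged=True,
        axis=int(row["axis"]),
        loading=float(row["loading"]),
        tail=str(row["tail"]),
        best_predictor=None if pd.isna(row["best_predictor"])
        else str(row["best_predictor"]),
        r_best=None if pd.isna(row["r_best"]) else float(row["r_best"]),
    )
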