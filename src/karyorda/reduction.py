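"""Collinearity reduction for environmental predictors.

Bioclim-style predictor sets are heavily inter-correlated, which breaks
regression-based ordination.  Predictors are clustered by complete
linkage on the distance 1 - |r|; clusters tighter than a cut height
(default 0.3, i.e. |r| > 0.7) are collapsed to one representative.
Quarterly summaries are preferred over monthly ones, monthly over other
derived variables.  A variance-inflation-factor check verifies that the
retained set is usable in a linear model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .data import PredictorTable

logger = logging.getLogger(__name__)

#: class ranking used to pick a cluster representative (best first)
DEFAULT_PREFERENCE: tuple[str, ...] = ("quarterly", "monthly", "other")


@dataclass
class ReductionResult:
    """Outcome of predictor clustering.

    ``clusters`` lists the member names of every cluster; ``retained``
    holds the chosen representative of each, in input-column order.
    """

    retained: list[str]
    clusters: list[list[str]] = field(default_factory=list)
    representatives: list[str] = field(default_factory=list)
    distance_matrix: pd.DataFrame | None = None
    cut_height: float = 0.3

    def to_dict(self) -> dict:
        return {
            "retained": self.retained,
            "clusters": self.clusters,
            "representatives": self.representatives,
            "cut_height": self.cut_height,
        }


def correlation_matrix(p: PredictorTable) -> pd.DataFrame:
    """Pearson correlation matrix of the predictor columns.

    Raises on a zero-variance column, naming it.
    """
    if len(p.names) < 2:
        raise ValueError("need at least two predictors")
    X = p.matrix()
    sd = X.std(axis=0, ddof=1)
    for name, s in zip(p.names, sd):
        if s == 0:
            raise ValueError(f"predictor {name!r} has zero variance")
    R = np.corrcoef(X, rowvar=False)
    R = np.clip(R, -1.0, 1.0)
    np.fill_diagonal(R, 1.0)
    return pd.DataFrame(R, index=p.names, columns=p.names)


def reduce_predictors(
    p: PredictorTable,
    cut: float = 0.3,
    preference: tuple[str, ...] = DEFAULT_PREFERENCE,
) -> ReductionResult:
    """Complete-linkage clustering of predictors at distance 1 - |r|.

    Two predictors end up in one cluster only when every pairwise
    distance inside the merged group is below ``cut`` (complete linkage,
    strict inequality at the boundary).  One representative per cluster
    is retained, chosen by

    1. class preference (quarterly > monthly > other by default),
    2. lowest mean |r| with predictors *outside* the cluster (the least
       redundant stand-in for the rest of the table),
    3. input column order.

    Complete linkage guarantees pairwise |r| <= 1 - cut *within* each
    cluster's merge heights; representatives of different clusters can
    in principle still correlate above the threshold, which the VIF
    check downstream guards against.
    """
    if not 0 < cut < 1:
        raise ValueError("cut must lie in (0, 1)")
    R = correlation_matrix(p)
    names = list(R.columns)
    D = 1.0 - R.abs().to_numpy()
    np.fill_diagonal(D, 0.0)
    Z = linkage(squareform(D, checks=False), method="complete")
    # fcluster's 'distance' criterion merges at height <= t; nudge below
    # the cut so a pair exactly at the boundary stays separate.
    labels = fcluster(Z, t=np.nextafter(cut, 0.0), criterion="distance")

    clusters: list[list[str]] = []
    representatives: list[str] = []
    rank = {cls: i for i, cls in enumerate(preference)}
    for lab in sorted(set(labels)):
        members = [names[i] for i in np.flatnonzero(labels == lab)]
        clusters.append(members)
        if len(members) == 1:
            representatives.append(members[0])
            continue
        outside = [n for n in names if n not in members]

        def key(name: str) -> tuple:
            cls_rank = rank.get(p.class_of(name), len(preference))
            if outside:
                mean_out = float(R.loc[name, outside].abs().mean())
            else:
                mean_out = 0.0
            return (cls_rank, mean_out, names.index(name))

        rep = min(members, key=key)
        representatives.append(rep)
        logger.info("cluster %s -> retained %s", members, rep)
    retained = [n for n in names if n in representatives]
    return ReductionResult(
        retained=retained,
        clusters=clusters,
        representatives=representatives,
        distance_matrix=pd.DataFrame(D, index=names, columns=names),
        cut_height=cut,
    )


def vif(p: PredictorTable, retained: list[str] | None = None,
        threshold: float = 10.0) -> tuple[pd.Series, bool]:
    """Variance inflation factors of the (retained) predictors.

    VIF_j = 1 / (1 - R²_j), with R²_j from regressing predictor j on all
    the others plus an intercept.  Exact collinearity reports ``inf``.
    Returns the per-predictor series and a pass flag
    (max VIF < ``threshold``).
    """
    names = retained if retained is not None else p.names
    if len(names) < 2:
        raise ValueError("need at least two predictors for VIF")
    X = p.matrix(names)
    X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    out = {}
    for j, name in enumerate(names):
        others = np.delete(X, j, axis=1)
        y = X[:, j]
        beta, *_ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ beta
        ss_res = float(resid @ resid)
        ss_tot = float(y @ y)  # columns are centered
        r2 = 1.0 - ss_res / ss_tot
        if ss_res / max(ss_tot, 1e-300) < 1e-12:
            out[name] = np.inf
        else:
            out[name] = 1.0 / (1.0 - r2)
    series = pd.Series(out, name="VIF")
    ok = bool(np.isfinite(series).all() and series.max() < threshold)
    return series, ok
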