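"""Redundancy analysis (RDA): constrained ordination of a genotype matrix.

RDA regresses a column-centered response matrix Y (samples x loci) on a
column-standardized predictor matrix X, then eigendecomposes the fitted
values.  Constrained axes are the directions of genetic variance that
are linear combinations of the environmental predictors; their summed
eigenvalues are the "constrained inertia", the share of total genetic
variance the environment explains.

Inertia is defined as the summed column variances of centered Y with
divisor n - 1 throughout.  Other ordination software may scale by n or
by total inertia; any consistent divisor cancels in the proportion of
variance explained and in the pseudo-F statistic, but absolute
eigenvalues differ by that factor.

Axis signs are fixed so that the largest-magnitude locus loading on each
axis is positive, making reports reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import GenotypeMatrix, PredictorTable

#: relative eigenvalue threshold below which an axis is numerical noise
_EIG_RTOL = 1e-12


@dataclass
class RDAModel:
    """Fitted redundancy analysis.

    Attributes
    ----------
    eigenvalues
        Constrained-axis eigenvalues, descending.
    eigenvalues_unconstrained
        Residual (unconstrained) axis eigenvalues, descending.
    total_inertia, constrained_inertia, unconstrained_inertia
        Variance decomposition (divisor n - 1); constrained +
        unconstrained = total.
    locus_scores
        L x k raw-eigenvector loadings ("species scores"); the input to
        outlier detection.
    sample_scores
        n x k linear-combination site scores (projections of the fitted
        values; Yhat @ V).
    biplot_scores
        p x k correlations of each standardized predictor with each
        axis's sample scores.
    pve
        Per-axis proportion of *constrained* variance
        (eigenvalue / constrained inertia).
    """

    eigenvalues: np.ndarray
    eigenvalues_unconstrained: np.ndarray
    total_inertia: float
    constrained_inertia: float
    unconstrained_inertia: float
    locus_scores: np.ndarray
    sample_scores: np.ndarray
    biplot_scores: np.ndarray
    pve: np.ndarray
    locus_ids: list[str] = field(default_factory=list)
    sample_ids: list[str] = field(default_factory=list)
    predictor_names: list[str] = field(default_factory=list)
    n: int = 0
    p: int = 0

    @property
    def n_axes(self) -> int:
        return len(self.eigenvalues)

    @property
    def proportion_constrained(self) -> float:
        """Constrained / total inertia — the headline '% of genetic
        variation explained by the environment'."""
        return self.constrained_inertia / self.total_inertia

    def species_scores(self, scaling: str = "none") -> np.ndarray:
        """Locus loadings under the requested scaling.

        "none" returns the raw eigenvectors (unit length per axis);
        "correlation" scales each axis by sqrt(eigenvalue) so loading
        magnitudes reflect axis importance.
        """
        if scaling == "none":
            return self.locus_scores
        if scaling == "correlation":
            return self.locus_scores * np.sqrt(self.eigenvalues)
        raise ValueError("scaling must be 'none' or 'correlation'")

    def population_scores(self, populations: list[str]) -> pd.DataFrame:
        """Per-population means of the sample scores (for map-style plots)."""
        df = pd.DataFrame(self.sample_scores,
                          columns=[f"RDA{k + 1}" for k in range(self.n_axes)])
        df["population"] = list(populations)
        return df.groupby("population").mean()


@dataclass
class PseudoF:
    """Pseudo-F ratio for constrained ordination."""

    statistic: float
    df_model: int
    df_resid: int


def _as_matrices(Y, X) -> tuple[np.ndarray, np.ndarray, list, list, list]:
    """Accept (GenotypeMatrix, PredictorTable) or plain arrays."""
    if isinstance(Y, GenotypeMatrix):
        locus_ids = Y.locus_ids
        sample_ids = Y.sample_ids
        Ym = Y.analysis_matrix()
    else:
        Ym = np.asarray(Y, dtype=float)
        locus_ids = [f"L{j}" for j in range(Ym.shape[1])]
        sample_ids = [f"S{i}" for i in range(Ym.shape[0])]
    if isinstance(X, PredictorTable):
        names = X.names
        Xm = X.matrix(sample_ids=sample_ids if isinstance(Y, GenotypeMatrix) else None)
    else:
        Xm = np.asarray(X, dtype=float)
        names = [f"X{j}" for j in range(Xm.shape[1])]
    return Ym, Xm, locus_ids, sample_ids, names


def center(Y: np.ndarray) -> np.ndarray:
    return Y - Y.mean(axis=0)


def standardize(X: np.ndarray, names: list[str] | None = None) -> np.ndarray:
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [names[j] if names else str(j) for j in np.flatnonzero(sd == 0)]
        raise ValueError(f"zero-variance predictors: {bad}")
    return (X - X.mean(axis=0)) / sd


def fit_rda(Y, X) -> RDAModel:
    """Fit a simple (unconditioned) RDA of genotypes on predictors.

    Parameters
    ----------
    Y
        Complete :class:`GenotypeMatrix` (no missing calls) or an
        (n, L) float array.  Columns are centered; SNP counts keep
        their common 0-2 scale (the karyotype pseudo-locus is
        standardized upstream by the container).
    X
        :class:`PredictorTable` or (n, p) array; columns are
        standardized to zero mean, unit variance.

    Raises on rank-deficient X, naming the dependent columns.
    """
    Ym, Xm, locus_ids, sample_ids, names = _as_matrices(Y, X)
    n, L = Ym.shape
    p = Xm.shape[1]
    if Xm.shape[0] != n:
        raise ValueError(f"X has {Xm.shape[0]} rows for {n} samples")
    if n < p + 1:
        raise ValueError(f"need n >= p + 1 samples (n={n}, p={p})")

    Yc = center(Ym)
    Xs = standardize(Xm, names)
    Q, R = np.linalg.qr(Xs)
    diag = np.abs(np.diag(R))
    if np.any(diag < 1e-10 * diag.max()):
        bad = [names[j] for j in np.flatnonzero(diag < 1e-10 * diag.max())]
        raise ValueError(f"predictors are collinear; dependent columns: {bad}")

    # fitted values live in the span of Q; SVD of the p x L projection
    # gives the constrained axes without forming Yhat explicitly
    C = Q.T @ Yc
    U, s, Vt = np.linalg.svd(C, full_matrices=False)
    eig = s**2 / (n - 1)
    k = int(np.sum(eig > _EIG_RTOL * max(eig.max(initial=0.0), 1e-300)))
    k = min(k, p, n - 1, L)
    eig = eig[:k]

    total = float(np.sum(Yc**2)) / (n - 1)
    constrained = float(np.sum(s**2)) / (n - 1)
    resid = Yc - Q @ C
    s_res = np.linalg.svd(resid, compute_uv=False)
    eig_res = s_res**2 / (n - 1)
    eig_res = eig_res[eig_res > _EIG_RTOL * max(eig_res.max(initial=0.0), 1e-300)]
    unconstrained = total - constrained

    locus_scores = Vt[:k].T                    # L x k raw eigenvectors
    sample_scores = (Q @ U[:, :k]) * s[:k]     # n x k, equals Yhat @ V

    # sign convention: largest-|loading| locus positive on every axis
    for a in range(k):
        j = int(np.argmax(np.abs(locus_scores[:, a])))
        if locus_scores[j, a] < 0:
            locus_scores[:, a] *= -1
            sample_scores[:, a] *= -1

    biplot = _biplot(Xs, sample_scores)
    pve = eig / eig.sum() if k else eig

    return RDAModel(
        eigenvalues=eig,
        eigenvalues_unconstrained=eig_res,
        total_inertia=total,
        constrained_inertia=constrained,
        unconstrained_inertia=unconstrained,
        locus_scores=locus_scores,
        sample_scores=sample_scores,
        biplot_scores=biplot,
        pve=pve,
        locus_ids=locus_ids,
        sample_ids=sample_ids,
        predictor_names=names,
        n=n,
        p=p,
    )


def _biplot(Xs: np.ndarray, sample_scores: np.ndarray) -> np.ndarray:
    """Correlation of each predictor with each axis's sample scores."""
    k = sample_scores.shape[1]
    p = Xs.shape[1]
    out = np.zeros((p, k))
    for a in range(k):
        sc = sample_scores[:, a]
        if sc.std(ddof=1) == 0:
            continue
        for j in range(p):
            out[j, a] = float(np.corrcoef(Xs[:, j], sc)[0, 1])
    return out


def predictor_axis_projection(model: RDAModel, X) -> np.ndarray:
    """Biplot scores for an arbitrary predictor table against a fitted
    model: Pearson r of each predictor with each axis's sample scores."""
    if isinstance(X, PredictorTable):
        Xm = X.matrix(sample_ids=model.sample_ids if model.sample_ids else None)
    else:
        Xm = np.asarray(X, dtype=float)
    Xs = standardize(Xm)
    return _biplot(Xs, model.sample_scores)


def pseudo_f(model: RDAModel, n: int | None = None,
             p: int | None = None) -> PseudoF:
    """Pseudo-F = (constrained/p) / (unconstrained/(n - p - 1)).

    The permutation-test statistic for constrained ordination; any
    consistent inertia divisor cancels.
    """
    n = n if n is not None else model.n
    p = p if p is not None else model.p
    if n <= p + 1:
        raise ValueError(f"no residual degrees of freedom (n={n}, p={p})")
    if model.unconstrained_inertia <= 0:
        raise ValueError("unconstrained inertia is zero; F undefined")
    stat = (model.constrained_inertia / p) / (
        model.unconstrained_inertia / (n - p - 1))
    return PseudoF(statistic=float(stat), df_model=p, df_resid=n - p - 1)


def save_model(model: RDAModel, outdir) -> None:
    """Serialize a fitted model to a directory of TSVs + inertia.json."""
    import json
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    axes = [f"RDA{k + 1}" for k in range(model.n_axes)]
    pd.DataFrame({"axis": axes, "eigenvalue": model.eigenvalues,
                  "pve": model.pve}).to_csv(out / "eigenvalues.tsv",
                                            sep="\t", index=False)
    pd.DataFrame(model.locus_scores, columns=axes,
                 index=pd.Index(model.locus_ids, name="locus_id")
                 ).to_csv(out / "locus_scores.tsv", sep="\t")
    pd.DataFrame(model.sample_scores, columns=axes,
                 index=pd.Index(model.sample_ids, name="sample_id")
                 ).to_csv(out / "sample_scores.tsv", sep="\t")
    pd.DataFrame(model.biplot_scores, columns=axes,
                 index=pd.Index(model.predictor_names, name="predictor")
                 ).to_csv(out / "biplot_scores.tsv", sep="\t")
    with open(out / "inertia.json", "w") as fh:
        json.dump({"total": model.total_inertia,
                   "constrained": model.constrained_inertia,
                   "unconstrained": model.unconstrained_inertia,
                   "proportion_constrained": model.proportion_constrained,
                   "n": model.n, "p": model.p}, fh, indent=2)
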