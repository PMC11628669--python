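"""Synthetic datasets with the structure the karyotype-GEA analysis assumes.

The generator emulates a sedge-like study system: ~34 populations
(~153 samples, heavily unbalanced) along a latitudinal gradient, with

* neutral biallelic SNPs drawn from a Balding-Nichols model (population
  allele frequencies Beta-distributed around an ancestral frequency,
  parameterized by FST),
* adaptive SNPs whose population allele frequency follows a logistic
  cline in one named environmental predictor,
* a bioclim-style predictor table with built-in collinear clusters
  (one quarterly anchor plus correlated monthly/derived satellites per
  cluster) so the reduction step has real work to do, and
* a diploid chromosome-number series (2n = 69-84 by default) with an
  optional environmental cline and within-population dispersion.

Ground truth (which loci are adaptive, which predictor each tracks) is
returned alongside, enabling power/FDR evaluation of the full pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import KARYOTYPE_ID, MISSING, GenotypeMatrix, PredictorTable, SampleTable

#: per-population sample sizes: 34 populations, 153 samples,
#: min 1 / median 3 / max 17 — the unbalanced design of a field study
#: that samples the cytogenetically variable core species most densely.
DEFAULT_POP_SIZES: tuple[int, ...] = (
    17, 14, 10, 9, 8, 7, 7, 6, 6, 5, 5, 5, 4, 4, 4, 4,
    3, 3, 3, 3, 3, 3, 3, 2, 2, 2, 2, 2, 2, 1, 1, 1, 1, 1,
)

#: predictor clusters: quarterly anchor first, then correlated satellites
#: (name, class, loading on the anchor).  Negative loadings make the
#: satellite anti-correlated, exercising the |r| in the distance.
_PREDICTOR_CLUSTERS: tuple[tuple[str, tuple[tuple[str, str, float], ...]], ...] = (
    ("BIO10", (("BIO5", "monthly", 0.93), ("BIO1", "other", 0.88))),
    ("BIO11", (("BIO6", "monthly", 0.93), ("BIO4", "other", -0.88))),
    ("BIO16", (("BIO13", "monthly", 0.93), ("BIO12", "other", 0.88))),
    ("BIO17", (("BIO14", "monthly", 0.93), ("BIO15", "other", -0.88))),
)

#: display-scale affine transforms (offset, scale) per anchor, loosely
#: bioclim-like units so the tables read plausibly
_ANCHOR_UNITS = {"BIO10": (18.0, 3.0), "BIO11": (4.0, 3.5),
                 "BIO16": (350.0, 120.0), "BIO17": (60.0, 35.0)}

ANCHOR_NAMES = tuple(name for name, _ in _PREDICTOR_CLUSTERS)

#: share of adaptive loci tied to each anchor.  Field GEA scans find a
#: strongly dominant gradient (here winter temperature, which also
#: carries the karyotype cline) with minor contributions from the
#: others; the imbalance also keeps the leading eigenvalue well
#: separated, so constrained axes have stable identities.
ANCHOR_WEIGHTS: dict[str, float] = {
    "BIO11": 0.60, "BIO17": 0.20, "BIO16": 0.10, "BIO10": 0.10,
}


@dataclass
class SimConfig:
    """Generator settings; defaults mirror the emulated study design."""

    n_pops: int = 34
    pop_sizes: tuple[int, ...] | None = DEFAULT_POP_SIZES
    n_neutral: int = 650
    n_adaptive: int = 50
    fst: float = 0.15
    effect_size: float = 1.5          # |beta| of the logistic cline
    karyotype_range: tuple[int, int] = (69, 84)
    karyotype_slope: float = 3.0      # chromosomes per SD of the linked predictor
    karyotype_dispersion: float = 1.5  # within-population SD, chromosomes
    karyotype_predictor: str = "BIO11"
    spatial_sd: float = 0.8           # SD of per-locus latitudinal logit slopes
    missing_rate: float = 0.10
    maf_floor: float = 0.05
    lat_range: tuple[float, float] = (36.0, 48.0)
    n_contigs: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pop_sizes is not None and len(self.pop_sizes) != self.n_pops:
            raise ValueError("pop_sizes length must equal n_pops")
        if not 0 < self.fst < 1:
            raise ValueError("fst must lie in (0, 1)")
        if not 0 < self.maf_floor < 0.5:
            raise ValueError("maf_floor must lie in (0, 0.5)")
        if self.karyotype_range[0] >= self.karyotype_range[1]:
            raise ValueError("karyotype range must be ordered")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.n_neutral < 1 or self.n_adaptive < 0:
            raise ValueError("locus counts must be positive")
        if self.karyotype_predictor not in ANCHOR_NAMES:
            raise ValueError(
                f"karyotype_predictor must be one of {ANCHOR_NAMES}")


def _logit(p: np.ndarray) -> np.ndarray:
    return np.log(p / (1.0 - p))


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _population_environment(cfg: SimConfig, rng: np.random.Generator
                            ) -> tuple[np.ndarray, pd.DataFrame]:
    """Latitudes plus standardized anchor gradients at population level.

    Winter temperature tracks latitude strongly (the cline the karyotype
    rides); the other anchors mix a weaker latitudinal component with
    independent noise so anchors stay below the |r| = 0.7 merge bound.
    """
    n = cfg.n_pops
    lat = np.linspace(*cfg.lat_range, n) + rng.normal(0, 0.3, n)
    zlat = (lat - lat.mean()) / lat.std(ddof=1)
    u = rng.normal(size=(4, n))
    # latitude loadings: winter temperature rides the gradient hardest;
    # the others share it moderately (pairwise anchor |r| stays well
    # below the 0.7 merge bound) so one climatic super-gradient
    # dominates, as in Mediterranean-Atlantic transects
    anchors = pd.DataFrame({
        "BIO10": -0.45 * zlat + np.sqrt(1 - 0.45**2) * u[0],
        "BIO11": -0.85 * zlat + np.sqrt(1 - 0.85**2) * u[1],
        "BIO16": 0.45 * zlat + np.sqrt(1 - 0.45**2) * u[2],
        "BIO17": -0.40 * zlat + np.sqrt(1 - 0.40**2) * u[3],
    })
    return lat, anchors


def _predictor_table(anchors: pd.DataFrame, sample_pop: np.ndarray,
                     sample_ids: list[str],
                     rng: np.random.Generator) -> PredictorTable:
    cols: dict[str, np.ndarray] = {}
    classes: dict[str, str] = {}
    n = len(anchors)
    for anchor, satellites in _PREDICTOR_CLUSTERS:
        off, scale = _ANCHOR_UNITS[anchor]
        z = anchors[anchor].to_numpy()
        cols[anchor] = off + scale * z
        classes[anchor] = "quarterly"
        for name, cls, load in satellites:
            noise = rng.normal(size=n)
            sat = load * z + np.sqrt(1 - load**2) * noise
            cols[name] = off + scale * sat
            classes[name] = cls
    pop_table = pd.DataFrame(cols)
    broadcast = pop_table.iloc[sample_pop].reset_index(drop=True)
    broadcast.insert(0, "sample_id", sample_ids)
    return PredictorTable(broadcast, classes)


def simulate(cfg: SimConfig) -> tuple[GenotypeMatrix, SampleTable,
                                      PredictorTable, pd.DataFrame]:
    """Generate one dataset plus its truth table.

    Returns ``(genotypes, samples, predictors, truth)``; ``truth`` has
    one row per locus and one for the karyotype, with columns
    ``locus_id``, ``class`` (neutral/adaptive/karyotype),
    ``linked_predictor`` and ``beta``.  Fully reproducible from
    ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    sizes = (np.asarray(cfg.pop_sizes) if cfg.pop_sizes is not None
             else rng.integers(1, 8, cfg.n_pops))
    n_samples = int(sizes.sum())
    sample_pop = np.repeat(np.arange(cfg.n_pops), sizes)
    pop_ids = [f"P{i + 1:02d}" for i in range(cfg.n_pops)]
    sample_ids = []
    for p, size in enumerate(sizes):
        sample_ids += [f"{pop_ids[p]}_{i + 1:02d}" for i in range(size)]

    lat, anchors = _population_environment(cfg, rng)
    predictors = _predictor_table(anchors, sample_pop, sample_ids, rng)

    # --- allele frequencies -------------------------------------------
    L = cfg.n_neutral + cfg.n_adaptive
    p0 = rng.uniform(cfg.maf_floor, 1 - cfg.maf_floor, L)
    F = cfg.fst
    a = p0 * (1 - F) / F
    b = (1 - p0) * (1 - F) / F
    pop_freq = rng.beta(a, b, size=(cfg.n_pops, L))
    if cfg.spatial_sd > 0:
        # isolation-by-distance-like structure: every locus drifts along
        # the latitudinal axis with its own random slope, so neutral
        # differentiation is spatially autocorrelated (a postglacial
        # recolonization signature), not isotropic noise
        zlat = (lat - lat.mean()) / lat.std(ddof=1)
        delta = rng.normal(0.0, cfg.spatial_sd, L)
        pop_freq = _logistic(_logit(pop_freq) + np.outer(zlat, delta))

    # adaptive loci split across anchors by the dominance weights
    counts = {a: int(round(w * cfg.n_adaptive))
              for a, w in ANCHOR_WEIGHTS.items()}
    while sum(counts.values()) > cfg.n_adaptive:
        counts[max(counts, key=counts.get)] -= 1
    while sum(counts.values()) < cfg.n_adaptive:
        counts[max(ANCHOR_WEIGHTS, key=ANCHOR_WEIGHTS.get)] += 1
    anchor_of: list[str] = [a for a in ANCHOR_NAMES for _ in range(counts[a])]

    truth_rows = []
    for j in range(L):
        if j < cfg.n_neutral:
            truth_rows.append({"locus_id": f"snp{j + 1:04d}",
                               "class": "neutral",
                               "linked_predictor": pd.NA, "beta": 0.0})
        else:
            pred = anchor_of[j - cfg.n_neutral]
            beta = cfg.effect_size * (1 if (j - cfg.n_neutral) % 2 == 0 else -1)
            z = anchors[pred].to_numpy()
            z = (z - z.mean()) / z.std(ddof=1)
            pop_freq[:, j] = _logistic(_logit(pop_freq[:, j]) + beta * z)
            truth_rows.append({"locus_id": f"snp{j + 1:04d}",
                               "class": "adaptive",
                               "linked_predictor": pred, "beta": beta})

    # --- genotypes -----------------------------------------------------
    geno = rng.binomial(2, pop_freq[sample_pop, :]).astype(np.int8)
    if cfg.missing_rate > 0:
        mask = rng.random(geno.shape) < cfg.missing_rate
        geno[mask] = MISSING

    # orient to the minor allele (as a VCF reader would)
    called = geno != MISSING
    with np.errstate(invalid="ignore"):
        freq = np.where(called, geno, 0).sum(0) / (2.0 * called.sum(0))
    flip = freq > 0.5
    geno[:, flip] = np.where(called[:, flip], 2 - geno[:, flip], MISSING)

    contigs = rng.integers(1, cfg.n_contigs + 1, L)
    positions = rng.integers(1, 5_000_000, L)
    locus_map = pd.DataFrame({
        "locus_id": [r["locus_id"] for r in truth_rows],
        "contig": [f"scaffold_{c}" for c in contigs],
        "position": positions,
    })
    genotypes = GenotypeMatrix(geno, locus_map, sample_ids)

    # --- karyotype -----------------------------------------------------
    lo, hi = cfg.karyotype_range
    zk = anchors[cfg.karyotype_predictor].to_numpy()
    zk = (zk - zk.mean()) / zk.std(ddof=1)
    base = (lo + hi) / 2.0
    two_n = np.round(base + cfg.karyotype_slope * zk[sample_pop]
                     + rng.normal(0, cfg.karyotype_dispersion, n_samples))
    two_n = np.clip(two_n, lo, hi).astype(int)
    truth_rows.append({"locus_id": KARYOTYPE_ID, "class": "karyotype",
                       "linked_predictor": (cfg.karyotype_predictor
                                            if cfg.karyotype_slope != 0 else pd.NA),
                       "beta": cfg.karyotype_slope})

    # --- sample metadata ----------------------------------------------
    species = np.array(["C_laevigata"] * cfg.n_pops, dtype=object)
    if cfg.n_pops >= 8:  # few satellite species, sparsely sampled
        species[-6:-3] = "C_binervis"
        species[-3:-1] = "C_camposii"
        species[-1] = "C_paulo_vargasii"
    lon = np.linspace(-9.0, 3.0, cfg.n_pops) + rng.normal(0, 0.2, cfg.n_pops)
    samples = SampleTable(pd.DataFrame({
        "sample_id": sample_ids,
        "population": [pop_ids[p] for p in sample_pop],
        "species": species[sample_pop],
        "lat": np.round(lat[sample_pop], 4),
        "lon": np.round(lon[sample_pop], 4),
        "two_n": two_n,
    }))

    truth = pd.DataFrame(truth_rows)
    return genotypes, samples, predictors, truth


@dataclass
class DetectionMetrics:
    """Power/FDR summary of an outlier report against the truth table."""

    tpr: float
    fdr: float
    karyotype_detected: bool
    n_flagged: int
    n_adaptive: int
    fdr_defined: bool = True
    extra: dict = field(default_factory=dict)


def evaluate_detection(report: pd.DataFrame,
                       truth: pd.DataFrame) -> DetectionMetrics:
    """TPR = flagged adaptive / all adaptive; FDR = flagged neutral / flagged.

    An empty report gives TPR 0 and FDR 0 with ``fdr_defined=False``.
    Raises when the report names loci the truth table does not know.
    """
    truth_class = dict(zip(truth["locus_id"], truth["class"]))
    flagged = list(report["locus_id"]) if len(report) else []
    unknown = [lid for lid in flagged if lid not in truth_class]
    if unknown:
        raise ValueError(f"loci absent from the truth table: {unknown[:5]}")
    n_adaptive = int((truth["class"] == "adaptive").sum())
    if not flagged:
        return DetectionMetrics(0.0, 0.0, False, 0, n_adaptive,
                                fdr_defined=False)
    tp = sum(truth_class[lid] == "adaptive" for lid in flagged)
    fp = sum(truth_class[lid] == "neutral" for lid in flagged)
    karyo = any(truth_class[lid] == "karyotype" for lid in flagged)
    tpr = tp / n_adaptive if n_adaptive else 0.0
    return DetectionMetrics(tpr=tpr, fdr=fp / len(flagged),
                            karyotype_detected=karyo,
                            n_flagged=len(flagged), n_adaptive=n_adaptive)
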