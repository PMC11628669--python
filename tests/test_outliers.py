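"""Tail-rule outlier detection and predictor assignment."""

import numpy as np
import pandas as pd
import pytest

from karyorda import (KARYOTYPE_ID, assign_predictor, detect_outliers,
                      fit_rda, karyotype_status)
from karyorda.rda import RDAModel

from conftest import make_genotypes, make_predictors, make_samples
from karyorda import append_karyotype, impute_missing


def model_from_loadings(loadings: np.ndarray) -> RDAModel:
    """Minimal model carrying given locus loadings (L x k)."""
    L, k = loadings.shape
    return RDAModel(
        eigenvalues=np.ones(k), eigenvalues_unconstrained=np.ones(1),
        total_inertia=2.0 * k, constrained_inertia=float(k),
        unconstrained_inertia=float(k),
        locus_scores=loadings, sample_scores=np.zeros((2, k)),
        biplot_scores=np.zeros((1, k)), pve=np.full(k, 1 / k),
        locus_ids=[f"L{j + 1}" for j in range(L)], n=2, p=1)


def test_exact_tail_counts_on_continuous_loadings():
    """1000 distinct loadings, one axis, 2.5% tails: 25 + 25 flagged,
    matching a sort-and-slice oracle."""
    rng = np.random.default_rng(0)
    load = rng.normal(size=1000)
    m = model_from_loadings(load.reshape(-1, 1))
    rep = detect_outliers(m, [1], tail=0.025)
    assert len(rep) == 50
    assert (rep["tail"] == "lower").sum() == 25
    assert (rep["tail"] == "upper").sum() == 25
    order = np.argsort(load)
    expect = {f"L{j + 1}" for j in np.concatenate([order[:25], order[-25:]])}
    assert set(rep["locus_id"]) == expect


def test_tied_loadings_flag_nothing():
    m = model_from_loadings(np.full((100, 1), 0.3))
    rep = detect_outliers(m, [1], tail=0.025)
    assert len(rep) == 0


def test_flagged_set_matches_sort_and_slice_across_tails():
    rng = np.random.default_rng(1)
    load = rng.normal(size=400)
    m = model_from_loadings(load.reshape(-1, 1))
    for tail in (0.01, 0.025, 0.05, 0.1):
        rep = detect_outliers(m, [1], tail=tail)
        lo = np.quantile(load, tail)
        hi = np.quantile(load, 1 - tail)
        expect = {f"L{j + 1}" for j in np.flatnonzero((load < lo) | (load > hi))}
        assert set(rep["locus_id"]) == expect
        assert len(rep) <= 2 * tail * 400 + 2


def test_sign_flip_swaps_tails_same_loci():
    rng = np.random.default_rng(2)
    load = rng.normal(size=300).reshape(-1, 1)
    r1 = detect_outliers(model_from_loadings(load), [1], 0.025)
    r2 = detect_outliers(model_from_loadings(-load), [1], 0.025)
    assert set(r1["locus_id"]) == set(r2["locus_id"])
    merged = r1.set_index("locus_id")["tail"].map({"upper": "lower",
                                                   "lower": "upper"})
    assert merged.equals(r2.set_index("locus_id").loc[merged.index, "tail"])


def test_dedup_across_axes_keeps_largest_loading():
    load = np.array([[5.0, -4.0],
                     [0.1, 6.0],
                     [0.0, 0.1],
                     [-0.1, 0.0],
                     [0.2, -0.2]] + [[0.0, 0.0]] * 35)
    m = model_from_loadings(load)
    rep = detect_outliers(m, [1, 2], tail=0.05)
    row = rep[rep["locus_id"] == "L1"].iloc[0]
    assert row["axis"] == 1 and row["loading"] == 5.0
    row2 = rep[rep["locus_id"] == "L2"].iloc[0]
    assert row2["axis"] == 2
    assert rep["locus_id"].is_unique


def test_few_loci_warns_but_computes():
    m = model_from_loadings(np.arange(10.0).reshape(-1, 1))
    with pytest.warns(UserWarning, match="tails may be empty"):
        rep = detect_outliers(m, [1], tail=0.025)
    assert len(rep) == 0 or set(rep.columns) >= {"locus_id", "axis"}


def test_bad_arguments():
    m = model_from_loadings(np.arange(100.0).reshape(-1, 1))
    with pytest.raises(ValueError, match="tail"):
        detect_outliers(m, [1], tail=0.6)
    with pytest.raises(ValueError, match="axes"):
        detect_outliers(m, [], tail=0.025)
    with pytest.raises(ValueError, match="axis"):
        detect_outliers(m, [5], tail=0.025)


# ---------------------------------------------------------------------------
# predictor assignment
# ---------------------------------------------------------------------------

def test_assignment_matches_exhaustive_correlation_table():
    rng = np.random.default_rng(3)
    n, L = 50, 30
    vals = rng.integers(0, 3, size=(n, L)).astype(np.int8)
    g = make_genotypes(vals)
    X = {f"B{j}": rng.normal(size=n) for j in range(4)}
    p = make_predictors(X)
    report = pd.DataFrame({
        "locus_id": [f"L{j + 1}" for j in range(0, L, 3)],
        "axis": 1, "loading": 1.0, "tail": "upper", "is_karyotype": False})
    out = assign_predictor(report, g, p)
    for _, row in out.iterrows():
        j = int(row["locus_id"][1:]) - 1
        rs = {name: abs(np.corrcoef(vals[:, j], X[name])[0, 1]) for name in X}
        assert row["best_predictor"] == max(sorted(rs), key=lambda k: rs[k])
        assert abs(row["r_best"]) == pytest.approx(rs[row["best_predictor"]])


def test_assignment_perfect_correlation_and_tie_break():
    n = 20
    x = np.linspace(0, 2, n)
    vals = np.clip(np.round(x), 0, 2).astype(np.int8).reshape(-1, 1)
    g = make_genotypes(vals)
    p = make_predictors({"BIO6": vals[:, 0].astype(float),
                         "BIO9": -vals[:, 0].astype(float),
                         "Z": np.random.default_rng(0).normal(size=n)})
    report = pd.DataFrame({"locus_id": ["L1"], "axis": [1], "loading": [1.0],
                           "tail": ["upper"], "is_karyotype": [False]})
    out = assign_predictor(report, g, p)
    # BIO6 and BIO9 tie at |r| = 1; alphabetical winner
    assert out.iloc[0]["best_predictor"] == "BIO6"
    assert out.iloc[0]["r_best"] == pytest.approx(1.0)


def test_zero_variance_locus_errors():
    g = make_genotypes(np.ones((10, 1), dtype=np.int8))
    p = make_predictors({"A": np.arange(10.0), "B": np.arange(10.0)[::-1]})
    report = pd.DataFrame({"locus_id": ["L1"], "axis": [1], "loading": [1.0],
                           "tail": ["upper"], "is_karyotype": [False]})
    with pytest.raises(ValueError, match="zero variance"):
        assign_predictor(report, g, p)


# ---------------------------------------------------------------------------
# karyotype status
# ---------------------------------------------------------------------------

def _fit_with_karyotype(two_n, env, seed=0):
    rng = np.random.default_rng(seed)
    n = len(two_n)
    vals = rng.integers(0, 3, size=(n, 60)).astype(np.int8)
    g = make_genotypes(vals)
    s = make_samples(n, two_n=two_n)
    gk = append_karyotype(g, s)
    p = make_predictors({"TEMP": env, "NOISE": rng.normal(size=n)})
    m = fit_rda(gk, p)
    return gk, p, m


def test_karyotype_cline_flagged_and_assigned():
    """A chromosome series riding a temperature gradient is retrieved as
    an outlier locus tied to that predictor."""
    rng = np.random.default_rng(4)
    n = 80
    env = np.linspace(-2, 2, n) + 0.1 * rng.normal(size=n)
    two_n = np.clip(np.round(76 + 3 * env + rng.normal(0, 1, n)), 69, 84)
    gk, p, m = _fit_with_karyotype(two_n, env)
    rep = detect_outliers(m, [1], tail=0.025)
    rep = assign_predictor(rep, gk, p)
    status = karyotype_status(rep, gk)
    assert status.flagged
    assert status.best_predictor == "TEMP"
    assert abs(status.r_best) > 0.8


def test_karyotype_median_loading_not_flagged():
    """Karyotype independent of the environment sits mid-distribution."""
    rng = np.random.default_rng(5)
    n = 80
    env = np.linspace(-2, 2, n)
    two_n = rng.integers(69, 85, size=n)  # no cline
    gk, p, m = _fit_with_karyotype(two_n, env, seed=6)
    rep = detect_outliers(m, [1], tail=0.025)
    rep = assign_predictor(rep, gk, p)
    status = karyotype_status(rep, gk)
    # not guaranteed unflagged for any draw, but this seed is mid-pack
    assert not status.flagged


def test_karyotype_status_requires_column():
    g = make_genotypes(np.zeros((4, 2), dtype=np.int8))
    with pytest.raises(ValueError, match="karyotype"):
        karyotype_status(pd.DataFrame(), g)
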