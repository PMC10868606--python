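"""Pairwise metrics against brute-force formulas; SMACOF behaviour."""

import logging
import math

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from bgcnovelty import (
    METRICS,
    PairwiseMatrix,
    export_plot_data,
    mds_smacof,
    pairwise_distances,
    pairwise_from_membership,
    stratified_embeddings,
)
from bgcnovelty.embedding import stress_1
from bgcnovelty.novelty_scoring import NoveltyRecord


# --- independent double-loop reference implementations ---------------------

def _brute(metric, a, b):
    if metric in ("euclidean", "l2"):
        return math.sqrt(sum((x - y) ** 2 for x, y in zip(a, b)))
    if metric == "cityblock":
        return sum(abs(x - y) for x, y in zip(a, b))
    if metric == "chebyshev":
        return max(abs(x - y) for x, y in zip(a, b))
    if metric == "braycurtis":
        return sum(abs(x - y) for x, y in zip(a, b)) / sum(
            abs(x + y) for x, y in zip(a, b)
        )
    if metric == "canberra":
        total = 0.0
        for x, y in zip(a, b):
            denom = abs(x) + abs(y)
            if denom > 0:
                total += abs(x - y) / denom
        return total
    if metric == "cosine":
        na = math.sqrt(sum(x * x for x in a))
        nb = math.sqrt(sum(y * y for y in b))
        if na == 0 and nb == 0:
            return 0.0
        if na == 0 or nb == 0:
            return 1.0
        return 1.0 - sum(x * y for x, y in zip(a, b)) / (na * nb)
    if metric == "correlation":
        ma, mb = sum(a) / len(a), sum(b) / len(b)
        da = [x - ma for x in a]
        db = [y - mb for y in b]
        return _brute("cosine", da, db)
    raise AssertionError(metric)


@pytest.mark.parametrize("metric", METRICS)
def test_metrics_match_brute_force(metric):
    rng = np.random.default_rng(202)
    for _ in range(10):
        n, d = rng.integers(2, 10), rng.integers(2, 20)
        X = rng.uniform(0, 1, size=(n, d))
        P = pairwise_distances(X, metric)
        for i in range(n):
            for j in range(n):
                expected = 0.0 if i == j else _brute(metric, X[i], X[j])
                assert P.M[i, j] == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize(
    "a, b, metric, expected",
    [
        ((1, 2, 3), (2, 4, 6), "cosine", 0.0),
        ((1, 2, 3), (2, 4, 6), "chebyshev", 3.0),
        ((1, 0), (0, 1), "braycurtis", 1.0),
        ((1, 0), (0, 1), "cityblock", 2.0),
    ],
)
def test_closed_form_examples(a, b, metric, expected):
    P = pairwise_distances(np.array([a, b], dtype=float), metric)
    assert P.M[0, 1] == pytest.approx(expected, abs=1e-12)


def test_euclidean_identical_to_l2():
    X = np.random.default_rng(0).uniform(size=(6, 5))
    np.testing.assert_array_equal(
        pairwise_distances(X, "euclidean").M, pairwise_distances(X, "l2").M
    )


def test_chebyshev_bounded_by_cityblock():
    X = np.random.default_rng(1).uniform(size=(8, 7))
    assert np.all(
        pairwise_distances(X, "chebyshev").M
        <= pairwise_distances(X, "cityblock").M + 1e-12
    )


@pytest.mark.parametrize("metric", METRICS)
def test_matrix_invariants(metric):
    X = np.random.default_rng(2).uniform(0, 100, size=(7, 9))
    P = pairwise_distances(X, metric)
    assert np.allclose(P.M, P.M.T)
    assert np.all(np.diag(P.M) == 0)
    assert np.all(P.M >= 0)


def test_degenerate_cosine_policy(caplog):
    X = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 2.0]])
    with caplog.at_level(logging.WARNING):
        P = pairwise_distances(X, "cosine")
    assert P.M[0, 1] == 0.0  # both degenerate
    assert P.M[0, 2] == 1.0  # one degenerate
    assert "degenerate" in caplog.text


def test_degenerate_correlation_policy():
    X = np.array([[5.0, 5.0, 5.0], [1.0, 2.0, 3.0], [7.0, 7.0, 7.0]])
    P = pairwise_distances(X, "correlation")
    assert P.M[0, 2] == 0.0  # both zero-variance
    assert P.M[0, 1] == 1.0


def test_unknown_metric_rejected():
    with pytest.raises(ValueError, match="unknown metric"):
        pairwise_distances(np.eye(3), "manhattan")


# --- SMACOF ----------------------------------------------------------------

def _pairwise_from_points(pts, ids=None):
    pts = np.asarray(pts, dtype=float)
    M = squareform(pdist(pts))
    ids = ids or [str(i) for i in range(len(pts))]
    return PairwiseMatrix(ids=tuple(ids), M=M, metric_name="euclidean")


def test_right_triangle_recovery():
    P = _pairwise_from_points([[0, 0], [3, 0], [0, 4]])
    emb = mds_smacof(P, seed=0)
    assert emb.stress < 1e-6
    recovered = sorted(pdist(emb.coords))
    assert recovered == pytest.approx([3.0, 4.0, 5.0], abs=1e-4)

def test_collinear_points_recovery():
    P = _pairwise_from_points([[0.0], [1.0], [2.0], [3.0]])
    emb = mds_smacof(P, seed=0)
    assert emb.stress < 1e-6
    assert sorted(pdist(emb.coords))[-1] == pytest.approx(3.0, abs=1e-4)


def test_stress_non_increasing_on_random_instances():
    rng = np.random.default_rng(99)
    for _ in range(5):
        pts = rng.normal(size=(10, 5))
        P = _pairwise_from_points(pts)
        emb = mds_smacof(P, seed=int(rng.integers(2**31)), n_restarts=1)
        h = emb.stress_history
        assert all(h[i + 1] <= h[i] + 1e-9 for i in range(len(h) - 1))
        # final stress no worse than the Torgerson initialization
        assert h[-1] <= h[0] + 1e-12


def test_all_zero_distances_coincide():
    P = PairwiseMatrix(ids=("a", "b", "c"), M=np.zeros((3, 3)),
                       metric_name="euclidean")
    emb = mds_smacof(P, seed=0)
    assert emb.stress == 0.0
    assert np.allclose(pdist(emb.coords), 0.0)


def test_stress_rigid_motion_invariance():
    rng = np.random.default_rng(4)
    pts = rng.normal(size=(8, 2))
    P = _pairwise_from_points(pts)
    theta = 0.83
    R = np.array([[np.cos(theta), -np.sin(theta)],
                  [np.sin(theta), np.cos(theta)]])
    moved = pts @ R.T + np.array([5.0, -2.0])
    assert stress_1(pts, P.M) == pytest.approx(stress_1(moved, P.M), abs=1e-12)
    reflected = pts * np.array([-1.0, 1.0])
    assert stress_1(pts, P.M) == pytest.approx(
        stress_1(reflected, P.M), abs=1e-12
    )


def test_seeded_determinism():
    rng = np.random.default_rng(8)
    P = _pairwise_from_points(rng.normal(size=(12, 6)))
    e1 = mds_smacof(P, seed=7)
    e2 = mds_smacof(P, seed=7)
    np.testing.assert_array_equal(e1.coords, e2.coords)


def test_invalid_pairwise_matrix_rejected():
    with pytest.raises(ValueError, match="symmetric"):
        PairwiseMatrix(ids=("a", "b"), M=np.array([[0.0, 1.0], [2.0, 0.0]]),
                       metric_name="x")
    with pytest.raises(ValueError, match="non-negative"):
        PairwiseMatrix(ids=("a", "b"), M=np.array([[0.0, -1.0], [-1.0, 0.0]]),
                       metric_name="x")


# --- stratification and plot data ------------------------------------------

def test_stratified_grid_and_skip(fixture_data, caplog):
    records, matrix, _, _ = fixture_data
    # restrict to two categories to keep it quick
    keep = [r for r in records if r.category in ("Siderophore", "Saccharide")]
    ids = [r.bgc_id for r in keep]
    sub = matrix.subset(ids)
    embs = stratified_embeddings(keep, sub, metrics=("chebyshev", "cosine"),
                                 seed=1, max_iter=50)
    assert len(embs) == 4
    strata = {(e.stratum, e.metric_name) for e in embs}
    assert ("Siderophore", "chebyshev") in strata

    # a 2-member stratum is skipped with a notice
    sid = [r for r in keep if r.category == "Siderophore"][:2]
    sac = [r for r in keep if r.category == "Saccharide"]
    tiny = sid + sac
    with caplog.at_level(logging.INFO):
        embs2 = stratified_embeddings(
            tiny, matrix.subset([r.bgc_id for r in tiny]),
            metrics=("chebyshev",), seed=1, max_iter=50,
        )
    assert {e.stratum for e in embs2} == {"Saccharide"}
    assert "skipping stratum" in caplog.text


def test_stratified_planted_structure_separates_categories():
    """With full type coherence, same-category BGCs land closer together."""
    from bgcnovelty import (
        SimulationConfig,
        generate_collection,
        generate_membership,
    )
    from bgcnovelty.synthetic_data import GenusSpec

    cfg = SimulationConfig(
        genera=(GenusSpec("Micromonospora", 3, 908.0),),
        type_coherence=1.0, seed=21,
    )
    coll, truth = generate_collection(cfg)
    matrix, _ = generate_membership(coll, truth, cfg)
    P = pairwise_from_membership(matrix, "chebyshev")
    emb = mds_smacof(P, seed=0, max_iter=100)
    cats = [r.category for r in coll]
    D = squareform(pdist(emb.coords))
    same = [D[i, j] for i in range(len(cats)) for j in range(i)
            if cats[i] == cats[j]]
    diff = [D[i, j] for i in range(len(cats)) for j in range(i)
            if cats[i] != cats[j]]
    assert np.mean(same) < np.mean(diff)


def _nov(bgc_id, score):
    return NoveltyRecord(bgc_id=bgc_id, top_hits=(("g", score),),
                         topk_mean=score, category="unclustered")


def _embedding(ids):
    coords = np.arange(2 * len(ids), dtype=float).reshape(len(ids), 2)
    from bgcnovelty.embedding import Embedding

    return Embedding(ids=tuple(ids), coords=coords, stress=0.0,
                     metric_name="chebyshev", stratum="Terpene")


def test_plot_data_degenerate_scores_midpoint():
    emb = _embedding(["a", "b"])
    nov = {b: _nov(b, 42.0) for b in emb.ids}
    df = export_plot_data(emb, nov, s_min=10, s_max=30)
    assert set(df["marker_size"]) == {20.0}
    assert set(df["hue_value"]) == {0.5}


def test_plot_data_normalized_hues():
    emb = _embedding(["a", "b", "c"])
    nov = {"a": _nov("a", 100.0), "b": _nov("b", 200.0), "c": _nov("c", 300.0)}
    df = export_plot_data(emb, nov)
    assert list(df["hue_value"]) == pytest.approx([0.0, 0.5, 1.0])


def test_plot_data_sizes_monotone_in_score(fixture_data):
    records, matrix, catalog, _ = fixture_data
    from bgcnovelty import build_novelty_records

    ids = [r.bgc_id for r in records if r.category == "Siderophore"][:10]
    nov = {
        r.bgc_id: r
        for r in build_novelty_records(matrix.subset(ids), catalog)
    }
    P = pairwise_from_membership(matrix, "chebyshev", bgc_ids=ids)
    emb = mds_smacof(P, seed=0, max_iter=50)
    emb.stratum = "Siderophore"
    df = export_plot_data(emb, nov)
    order_by_score = df.sort_values("topk_mean")["marker_size"].to_numpy()
    assert np.all(np.diff(order_by_score) >= -1e-12)


def test_plot_data_missing_record_rejected():
    emb = _embedding(["a", "b"])
    with pytest.raises(ValueError, match="missing novelty"):
        export_plot_data(emb, {"a": _nov("a", 1.0)})
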