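"""Spatially corrected tests: effective sample size behavior, permutation
validity, and invariances."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from macrogd import spatial_stats as sp


@pytest.fixture(scope="module")
def coords():
    return np.random.default_rng(1).uniform(0, 1000, size=(100, 2))


def _gp_chol(coords, range_):
    k = np.exp(-cdist(coords, coords) / range_)
    return np.linalg.cholesky(k + 1e-10 * np.eye(len(coords)))


def test_perfect_correlation(coords, rng):
    x = rng.standard_normal(100)
    res = sp.modified_ttest(x, x * 2 + 1, coords)
    assert res.r == pytest.approx(1.0)
    assert res.p < 1e-10


def test_constant_input_rejected(coords):
    with pytest.raises(ValueError):
        sp.modified_ttest(np.ones(100), np.arange(100.0), coords)


def test_effective_n_near_n_for_iid(coords, rng):
    dofs = [
        sp.modified_ttest(rng.standard_normal(100), rng.standard_normal(100), coords).dof
        for _ in range(60)
    ]
    assert 88 <= np.mean(dofs) <= 98


def test_autocorrelation_shrinks_effective_n(coords, rng):
    chol = _gp_chol(coords, 400.0)
    dofs = [
        sp.modified_ttest(chol @ rng.standard_normal(100), chol @ rng.standard_normal(100), coords).dof
        for _ in range(30)
    ]
    assert np.mean(dofs) < 40


def test_affine_invariance(coords, rng):
    x = rng.standard_normal(100)
    y = 0.3 * x + rng.standard_normal(100)
    a = sp.modified_ttest(x, y, coords)
    b = sp.modified_ttest(5.0 * x - 3.0, -2.0 * y + 7.0, coords)
    assert a.p == pytest.approx(b.p, rel=1e-9)
    assert abs(a.r) == pytest.approx(abs(b.r), rel=1e-12)
    m1 = sp.morans_i(y, coords=coords, n_perm=199, seed=3)
    m2 = sp.morans_i(4.0 * y + 1.0, coords=coords, n_perm=199, seed=3)
    assert m1.I == pytest.approx(m2.I, rel=1e-9) and m1.p == m2.p


def test_quadratic_latitude_detects_planted_hump(coords, rng):
    lats = rng.uniform(-60, 60, size=100)
    # subtropical hump symmetric about the equator
    response = -((np.abs(lats) - 30.0) ** 2) / 900.0 + rng.normal(0, 0.05, 100)
    res = sp.quadratic_latitude_test(response, lats, coords)
    quad, lin = res["quadratic"], res["linear"]
    assert quad.r < 0
    assert abs(quad.r) > abs(lin.r)


def test_morans_checkerboard_negative():
    side = 10
    vals = (np.add.outer(np.arange(side), np.arange(side)) % 2).astype(float).ravel()
    vals += np.random.default_rng(0).normal(0, 1e-6, vals.size)
    w = np.zeros((side * side, side * side))
    for i in range(side):
        for j in range(side):
            for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                ii, jj = i + di, j + dj
                if 0 <= ii < side and 0 <= jj < side:
                    w[i * side + j, ii * side + jj] = 1.0
    w /= w.sum(axis=1, keepdims=True)
    res = sp.morans_i(vals, weights=w, n_perm=499, seed=1)
    assert res.I < 0
    assert res.expected == pytest.approx(-1.0 / 99.0)


def test_morans_smooth_gradient_positive(coords):
    vals = coords[:, 0] + 0.5 * coords[:, 1]
    res = sp.morans_i(vals, coords=coords, n_perm=999, seed=2)
    assert res.I > 0
    assert res.p == pytest.approx(1.0 / 1000.0)


def test_morans_permutation_null_mean(coords, rng):
    """Mean of I over label permutations equals -1/(n-1) to 3 decimals."""
    z = rng.standard_normal(100)
    w = sp.knn_weights(coords, k=8)
    perms = [
        sp.morans_i(z[rng.permutation(100)], weights=w, n_perm=1, seed=i).I for i in range(3000)
    ]
    assert np.mean(perms) == pytest.approx(-1.0 / 99.0, abs=1e-3 * 3)


def test_morans_constant_rejected(coords):
    with pytest.raises(ValueError):
        sp.morans_i(np.ones(100), coords=coords)


def test_sampling_checks_structure(small_world):
    from macrogd import diversity
    from macrogd.gridding import GridSpec, assign_cells

    recs = assign_cells(small_world.records, GridSpec(cell_size=small_world.truth["cell_size"]))
    summ, otu = diversity.summarize_cells(recs, min_otus=10)
    tab = sp.pearson_sampling_checks(summ, otu)
    assert "pi_vs_copies" in set(tab["pair"])
    assert len(tab) == 7
    # constant input surfaces as missing, not an exception
    summ2 = summ.copy()
    summ2["n_individuals"] = 5
    tab2 = sp.pearson_sampling_checks(summ2, otu)
    assert np.isnan(tab2.loc[tab2["pair"] == "gdm_vs_individuals", "r"]).all()
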