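"""Distance matrix regression: Gower centering, pseudo statistics,
permutation inference, and equivalence with classical references."""

from itertools import permutations

import numpy as np
import pandas as pd
import pytest

from capnoseq.dmr import (
    DesignMatrix,
    bivariate_dmr,
    build_design,
    gower_center,
    mdmra_fit,
)

from .oracles import anova_f


def euclid_d(points):
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.shape[0] == 1:
        points = points.T
    diff = points[:, None, :] - points[None, :, :]
    return np.sqrt((diff**2).sum(-1))


def test_gower_two_point_hand_matrix():
    G = gower_center(np.array([[0.0, 2.0], [2.0, 0.0]]))
    assert np.allclose(G, [[1, -1], [-1, 1]])
    assert np.trace(G) == pytest.approx(4 / 2)


def test_gower_zeros():
    assert np.allclose(gower_center(np.zeros((5, 5))), 0.0)


def test_gower_trace_equals_total_discrepancy(rng):
    for _ in range(20):
        n = int(rng.integers(3, 15))
        pts = rng.normal(size=(n, 3))
        D = euclid_d(pts)
        G = gower_center(D)
        iu = np.triu_indices(n, 1)
        assert np.trace(G) == pytest.approx(np.sum(D[iu] ** 2) / n, abs=1e-9)


def test_gower_equals_centered_gram_for_euclidean_points(rng):
    pts = rng.normal(size=(8, 2))
    centered = pts - pts.mean(axis=0)
    assert np.allclose(gower_center(euclid_d(pts)), centered @ centered.T, atol=1e-9)


def make_design(x, categorical=False, name="x"):
    df = pd.DataFrame({"patient_id": [str(i) for i in range(len(x))], name: x})
    return build_design(
        df, numeric=[] if categorical else [name],
        categorical=[name] if categorical else [],
    )


def test_pseudo_f_equals_classical_anova_f(rng):
    """For D built from 1-D Euclidean data and a binary covariate, the total
    pseudo-F is the one-way ANOVA F on the underlying data."""
    for _ in range(10):
        y = rng.normal(size=30)
        g = rng.integers(0, 2, size=30)
        g[:2] = [0, 1]  # both levels present
        res = mdmra_fit(euclid_d(y), make_design(g, categorical=True), n_perm=0)
        assert res.total.pseudo_F == pytest.approx(anova_f(y, g), abs=1e-9)


def test_bivariate_r2_matches_linear_regression(rng):
    """x equal to one coordinate of the Euclidean embedding: pseudo-R2 is
    the OLS R-squared of that coordinate regression."""
    pts = rng.normal(size=(25, 2))
    x = pts[:, 0] + rng.normal(scale=0.5, size=25)
    res = bivariate_dmr(euclid_d(pts), x, n_perm=0)
    # reference: R2 summed over both coordinate responses
    X = np.column_stack([np.ones(25), (x - x.mean()) / x.std()])
    H = X @ np.linalg.inv(X.T @ X) @ X.T
    C = pts - pts.mean(axis=0)
    r2 = np.trace(H @ C @ C.T @ H) / np.trace(C @ C.T)
    assert res.total.pseudo_R2 == pytest.approx(r2, abs=1e-9)


def test_decomposition_and_consistency_invariants(rng):
    """SS_expl + SS_res = SS_T, term shares are R2_v / R2_total, and all
    R2 lie in [0, 1]."""
    n = 40
    pts = rng.normal(size=(n, 3))
    D = euclid_d(pts)
    cov = pd.DataFrame(
        {
            "patient_id": [str(i) for i in range(n)],
            "a": rng.normal(size=n),
            "b": rng.normal(size=n),
            "c": rng.choice(["u", "v", "w"], size=n),
        }
    )
    design = build_design(cov, numeric=["a", "b"], categorical=["c"])
    res = mdmra_fit(D, design, n_perm=49, seed=1)
    G = gower_center(D)
    ss_t = np.trace(G)
    ss_expl = res.total.pseudo_R2 * ss_t
    # recover the residual through the F-statistic identity
    m = design.X.shape[1]
    ss_res = (ss_expl / m) / res.total.pseudo_F * (n - m - 1)
    assert ss_expl + ss_res == pytest.approx(ss_t, abs=1e-9)
    for t in res.terms:
        assert 0 - 1e-12 <= t.pseudo_R2 <= 1
        assert t.proportion_explained == pytest.approx(
            t.pseudo_R2 / res.total.pseudo_R2, abs=1e-9
        )
        assert 0 < t.p_value <= 1


def test_intercept_only_model_explains_nothing(rng):
    D = euclid_d(rng.normal(size=12))
    design = DesignMatrix(ids=[str(i) for i in range(12)], X=np.zeros((12, 0)), terms={})
    res = mdmra_fit(D, design, n_perm=0)
    assert res.total.pseudo_R2 == 0.0


def test_constant_covariate_rejected(rng):
    with pytest.raises(ValueError, match="zero variance"):
        make_design(np.ones(10))


def test_rank_deficient_design_rejected(rng):
    x = rng.normal(size=15)
    df = pd.DataFrame(
        {"patient_id": [str(i) for i in range(15)], "a": x, "b": 2 * x}
    )
    with pytest.raises(ValueError, match="rank-deficient"):
        build_design(df, numeric=["a", "b"], categorical=[])


def test_listwise_deletion_counted():
    df = pd.DataFrame(
        {
            "patient_id": list("abcdefgh"),
            "a": [1.0, 2, np.nan, 4, 5, 1, 3, 2],
            "c": ["u", "v", "u", "v", None, "u", "v", "u"],
        }
    )
    design = build_design(df, numeric=["a"], categorical=["c"])
    assert design.n_dropped == 2
    assert design.n == 6


def test_permutation_p_matches_full_enumeration(rng):
    """n=6 with a binary covariate: the sampled permutation p agrees with the
    exact p from all 6! identity permutations within binomial error."""
    y = rng.normal(size=6)
    D = euclid_d(y)
    g = np.array([0, 0, 0, 1, 1, 1])
    design = make_design(g, categorical=True)
    obs = mdmra_fit(D, design, n_perm=0).total.pseudo_F
    count = total = 0
    for perm in permutations(range(6)):
        Dp = D[np.ix_(perm, perm)]
        f = mdmra_fit(Dp, design, n_perm=0).total.pseudo_F
        count += f >= obs - 1e-12
        total += 1
    exact = count / total
    sampled = mdmra_fit(D, design, n_perm=499, seed=7).total.p_value
    # binomial 99.9% envelope around the exact p at 499 draws
    se = np.sqrt(exact * (1 - exact) / 499)
    assert abs(sampled - exact) <= max(3.5 * se, 2 / 499)


def test_permutation_seed_reproducible(rng):
    D = euclid_d(rng.normal(size=20))
    x = rng.normal(size=20)
    a = bivariate_dmr(D, x, n_perm=99, seed=5)
    b = bivariate_dmr(D, x, n_perm=99, seed=5)
    assert a.total.p_value == b.total.p_value
    assert [t.p_value for t in a.terms] == [t.p_value for t in b.terms]


def test_pseudo_f_matches_skbio_permanova(rng):
    """Independent cross-check: one-factor pseudo-F equals scikit-bio's
    PERMANOVA statistic on the same distance matrix."""
    skbio = pytest.importorskip("skbio")
    from skbio.stats.distance import permanova

    pts = rng.normal(size=(24, 3))
    D = euclid_d(pts)
    g = rng.choice(["a", "b", "c"], size=24)
    g[:3] = ["a", "b", "c"]
    ours = mdmra_fit(D, make_design(g, categorical=True), n_perm=0).total.pseudo_F
    theirs = permanova(
        skbio.DistanceMatrix(D, ids=[str(i) for i in range(24)]), g, permutations=0
    )["test statistic"]
    assert ours == pytest.approx(float(theirs), abs=1e-9)
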