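"""Multivariate allometry estimation, imputation, bootstrap and classes."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pterowing import synthetic
from pterowing.allometry import (
    AllometryError,
    analyze_taxon,
    bootstrap_bound,
    classify_allometry,
    estimate_allometry,
    impute_log_missing,
)
from pterowing.specimens import DimensionConfig, Specimen, SpecimenTable

from conftest import make_table

DIMS4 = ("humerus", "ulna_radius", "femur", "wingspan")


def rank1_table(b, a, s, dims=DIMS4, taxon="T"):
    """Noiseless log-linear table: log Y_ij = a_j + b_j s_i."""
    rows = []
    for i, si in enumerate(s):
        rows.append(
            (f"sp{i}", {d: float(np.exp(a[j] + b[j] * si))
                        for j, d in enumerate(dims)})
        )
    return make_table(taxon, rows)


class TestImputation:
    def test_complete_matrix_unchanged(self, rng):
        X = rng.normal(size=(5, 3))
        W, rep = impute_log_missing(X)
        assert np.array_equal(W, X)
        assert rep.cells_imputed == 0 and rep.converged

    def test_rank1_cells_recovered(self, rng):
        a = np.array([1.0, 2.0, 0.5, 3.0])
        b = np.array([0.8, 1.2, 1.0, 0.9])
        s = rng.uniform(-1, 1, 30)
        X = a + np.outer(s, b)
        miss = rng.uniform(size=X.shape) < 0.1
        miss[:, 0] &= ~np.all(miss[:, 1:], axis=1)  # keep rows nonempty
        Xm = X.copy()
        Xm[miss] = np.nan
        W, rep = impute_log_missing(Xm, tol=1e-10)
        assert rep.converged
        assert np.allclose(W[miss], X[miss], atol=1e-6)

    def test_single_cell_matches_closed_form(self):
        # rank-1 consistency: deleted cell of a noiseless log-linear 3x3
        # matrix must be restored to its generating value
        a = np.array([0.0, 1.0, -1.0])
        b = np.array([1.0, 2.0, 0.5])
        s = np.array([-1.0, 0.2, 0.9])
        X = a + np.outer(s, b)
        Xm = X.copy()
        Xm[1, 2] = np.nan
        W, rep = impute_log_missing(Xm, tol=1e-12)
        assert W[1, 2] == pytest.approx(X[1, 2], abs=1e-8)

    def test_empty_column_rejected(self):
        X = np.ones((4, 2))
        X[:, 1] = np.nan
        with pytest.raises(AllometryError, match="column"):
            impute_log_missing(X)


class TestEstimate:
    def test_isometric_data_gives_all_ones(self):
        s = np.linspace(-1, 1, 12)
        table = rank1_table(np.ones(4), np.array([1, 2, 0.5, 3.0]), s)
        ac = estimate_allometry(table, DimensionConfig(DIMS4))
        assert np.allclose(list(ac.values()), 1.0, atol=1e-9)

    def test_two_dimensions_slope_two_hand_eigenvector(self):
        # log y2 = 2 log y1 + c: covariance is rank 1 with loading (1, 2),
        # so AC = sqrt(2) * (1, 2) / sqrt(5)
        s = np.linspace(0.0, 1.0, 10)
        table = rank1_table(
            np.array([1.0, 2.0]), np.array([0.0, 0.3]), s,
            dims=("humerus", "wingspan"),
        )
        ac = estimate_allometry(
            table, DimensionConfig(("humerus", "wingspan")))
        expected = np.sqrt(2) * np.array([1.0, 2.0]) / np.sqrt(5)
        assert ac["humerus"] == pytest.approx(expected[0], abs=1e-9)
        assert ac["wingspan"] == pytest.approx(expected[1], abs=1e-9)
        assert ac["wingspan"] / ac["humerus"] == pytest.approx(2.0, abs=1e-9)

    def test_unit_norm_gauge(self, presets):
        table = synthetic.generate_taxon(presets["Pterodactylus"])
        ac = np.array(list(estimate_allometry(table).values()))
        assert np.sum((ac / np.sqrt(ac.size)) ** 2) == pytest.approx(1.0, abs=1e-9)

    @given(c=st.floats(0.01, 100.0))
    @settings(max_examples=20, deadline=None)
    def test_scale_invariance_per_dimension(self, c):
        s = np.linspace(-0.5, 0.5, 8)
        b = np.array([0.9, 1.1, 1.0, 1.0])
        table = rank1_table(b, np.zeros(4), s)
        scaled_rows = [
            (sp.specimen_id,
             {d: (c if d == "femur" else 1.0) * v
              for d, v in sp.measurements.items()})
            for sp in table.specimens
        ]
        ac1 = estimate_allometry(table, DimensionConfig(DIMS4))
        ac2 = estimate_allometry(make_table("T", scaled_rows), DimensionConfig(DIMS4))
        for d in DIMS4:
            assert ac2[d] == pytest.approx(ac1[d], rel=1e-9)

    def test_too_few_specimens_rejected(self):
        s = np.array([0.0, 1.0])
        table = rank1_table(np.ones(4), np.zeros(4), s)
        with pytest.raises(AllometryError, match="3"):
            estimate_allometry(table, DimensionConfig(DIMS4))

    def test_zero_variance_dimension_named(self):
        rows = [(f"sp{i}", {"humerus": 5.0, "wingspan": 10.0 + i, "femur": 2.0 + i})
                for i in range(5)]
        table = make_table("T", rows)
        with pytest.raises(AllometryError, match="humerus"):
            estimate_allometry(
                table, DimensionConfig(("humerus", "wingspan", "femur")))

    def test_sum_normalization_also_isometric(self):
        s = np.linspace(-1, 1, 10)
        table = rank1_table(np.ones(4), np.zeros(4), s)
        ac = estimate_allometry(table, DimensionConfig(DIMS4), normalization="sum")
        assert np.allclose(list(ac.values()), 1.0, atol=1e-9)


class TestBootstrap:
    def test_bound_sides_follow_point_estimate(self, presets):
        cfg = synthetic.with_overrides(
            presets["Rhamphorhynchus"], n=40, sigma=0.05, missing_rate=0.0, seed=3
        )
        table = synthetic.generate_taxon(cfg)
        config = DimensionConfig()
        ac = estimate_allometry(table, config)
        bounds = bootstrap_bound(table, config, B=100, seed=0)
        for d, (bound, side) in bounds.items():
            assert side == ("upper" if ac[d] < 1 else "lower")

    def test_isometric_bounds_near_one(self):
        s = np.linspace(-1, 1, 25)
        table = rank1_table(np.ones(4), np.array([1, 2, 0.5, 3.0]), s)
        bounds = bootstrap_bound(table, DimensionConfig(DIMS4), B=50, seed=1)
        for d, (bound, side) in bounds.items():
            assert bound == pytest.approx(1.0, abs=1e-6)

    def test_one_sided_coverage(self, presets):
        # the 95% one-sided bound should exclude the true coefficient in
        # roughly 5% of repeats (complete data, so each repeat is fast)
        cfg0 = presets["Rhamphorhynchus"]
        truth = synthetic.population_ac(cfg0.b)
        excl = []
        for rep in range(40):
            cfg = synthetic.with_overrides(
                cfg0, n=60, sigma=0.05, missing_rate=0.0, seed=1000 + rep
            )
            table = synthetic.generate_taxon(cfg)
            bounds = bootstrap_bound(table, DimensionConfig(), B=200, seed=rep)
            b, side = bounds["humerus"]
            t = truth["humerus"]
            excl.append((t > b) if side == "upper" else (t < b))
        rate = np.mean(excl)
        assert rate <= 0.25  # ~5% expected; generous binomial slack at 40 reps


class TestClassify:
    @pytest.mark.parametrize("ac,bound,side,expected", [
        (0.86, 0.88, "upper", "-"),
        (1.01, 0.97, "lower", "="),
        (1.05, 1.03, "lower", "+"),
        (0.99, 1.02, "upper", "="),
    ])
    def test_published_examples(self, ac, bound, side, expected):
        assert classify_allometry(ac, bound, side) == expected


def test_analyze_taxon_records_consistent(presets):
    cfg = synthetic.with_overrides(
        presets["Sinopterus"], n=20, missing_rate=0.05, seed=5
    )
    table = synthetic.generate_taxon(cfg)
    res = analyze_taxon(table, DimensionConfig(), B=80, seed=2)
    assert res.n_used == 20 and res.B == 80
    acs = np.array([r.ac for r in res.records])
    assert np.sum((acs / np.sqrt(res.p_used)) ** 2) == pytest.approx(1.0, abs=1e-9)
    for r in res.records:
        assert r.klass == classify_allometry(r.ac, r.bound, r.bound_side)
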