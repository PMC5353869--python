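"""I/S ratio computation, cassette filter and LOESS smoothing."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from exoncorr.errors import CompletenessError, ConfigurationError, DomainError
from exoncorr.splicing_quant import (
    SmootherConfig,
    build_ratio_matrix,
    cassette_filter,
    compute_is_ratio,
    loess_hat_matrix,
    loess_smooth,
)


class TestComputeIsRatio:
    @pytest.mark.parametrize(
        "i,s,expected",
        [(0, 0, 0.0), (5, 5, 0.0), (9, 4, np.log(2)), (4, 9, -np.log(2))],
    )
    def test_values(self, i, s, expected):
        assert compute_is_ratio(i, s) == pytest.approx(expected, abs=1e-12)

    def test_antisymmetric(self):
        rng = np.random.default_rng(0)
        a, b = rng.uniform(0, 100, 50), rng.uniform(0, 100, 50)
        np.testing.assert_allclose(
            compute_is_ratio(a, b), -compute_is_ratio(b, a), atol=1e-12
        )

    def test_sign_tracks_dominant_transcript(self):
        assert compute_is_ratio(10, 2) > 0 > compute_is_ratio(2, 10)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(
        i=st.floats(min_value=0, max_value=1e6, allow_nan=False),
        s=st.floats(min_value=0, max_value=1e6, allow_nan=False),
    )
    def test_antisymmetry_property(self, i, s):
        assert compute_is_ratio(i, s) == pytest.approx(-compute_is_ratio(s, i),
                                                       abs=1e-12)
        assert (compute_is_ratio(i, s) > 0) == (i > s)

    @pytest.mark.parametrize("i,s", [(-1, 2), (2, -1), (np.nan, 1), (np.inf, 1)])
    def test_domain_errors(self, i, s):
        with pytest.raises(DomainError):
            compute_is_ratio(i, s)


def _quants(values):
    """values: {exon: [(fpkm_I, fpkm_S) per sample]}"""
    rows = []
    for exon, series in values.items():
        for t, (i, s) in enumerate(series):
            rows.append((exon, f"s{t}", i, s))
    return pd.DataFrame(rows, columns=["exon_id", "sample_id", "fpkm_I", "fpkm_S"])


class TestCassetteFilter:
    def test_skipping_never_expressed_is_dropped(self):
        q = _quants({"e1": [(5, 0), (3, 0)], "e2": [(5, 1), (0, 0)]})
        assert cassette_filter(q) == ["e2"]

    def test_inclusion_never_expressed_is_dropped(self):
        q = _quants({"e1": [(0, 2), (0, 1)]})
        assert cassette_filter(q) == []

    def test_positivity_may_come_from_different_samples(self):
        q = _quants({"e1": [(5, 0), (0, 3)]})
        assert cassette_filter(q) == ["e1"]

    def test_incomplete_table_rejected(self):
        q = _quants({"e1": [(5, 1), (3, 1)]})
        q = pd.concat([q, _quants({"e2": [(1, 1)]})], ignore_index=True)
        with pytest.raises(CompletenessError):
            cassette_filter(q)

    def test_planted_non_cassette_count(self, small_bundle):
        truth = small_bundle.truth
        for fpkm in (small_bundle.fpkm_fly, small_bundle.fpkm_worm):
            n_total = fpkm["exon_id"].nunique()
            kept = cassette_filter(fpkm)
            assert n_total - len(kept) == truth.n_non_cassette()


class TestLoess:
    def test_constant_series_unchanged(self):
        y = np.full(20, 3.7)
        np.testing.assert_allclose(loess_smooth(y), y, atol=1e-10)

    @pytest.mark.parametrize("span", [0.2, 0.3, 0.5, 1.0])
    def test_global_quadratic_reproduced_exactly(self, span):
        i = np.arange(1, 31, dtype=float)
        y = 2 + 0.5 * i + 0.1 * i**2
        out = loess_smooth(y, SmootherConfig(span=span, degree=2))
        np.testing.assert_allclose(out, y, atol=1e-8)

    def test_matches_per_point_weighted_least_squares_oracle(self):
        rng = np.random.default_rng(11)
        n = 30
        y = np.sin(np.arange(n) / 4) + rng.normal(0, 0.3, n)
        cfg = SmootherConfig(span=0.3, degree=2)
        got = loess_smooth(y, cfg)
        # brute-force oracle: per-point tricube-weighted polynomial fit
        x = np.arange(1, n + 1, dtype=float)
        q = max(cfg.degree + 1, int(np.floor(cfg.span * n)))
        expected = np.empty(n)
        for t in range(n):
            d = np.abs(x - x[t])
            dmax = np.sort(d)[q - 1]
            w = np.clip(1 - (d / dmax) ** 3, 0, None) ** 3
            coef = np.polynomial.polynomial.polyfit(
                x - x[t], y, deg=cfg.degree, w=np.sqrt(w)
            )
            expected[t] = coef[0]
        np.testing.assert_allclose(got, expected, atol=1e-6)

    def test_commutes_with_affine_transforms(self):
        rng = np.random.default_rng(2)
        y = rng.normal(0, 1, 25)
        cfg = SmootherConfig()
        base = loess_smooth(y, cfg)
        np.testing.assert_allclose(loess_smooth(3.5 * y - 2.0, cfg), 3.5 * base - 2.0,
                                   atol=1e-9)

    def test_short_series_returned_unchanged(self, caplog):
        y = np.array([1.0, 2.0, 5.0])
        with caplog.at_level("WARNING"):
            out = loess_smooth(y, SmootherConfig(degree=2))
        np.testing.assert_array_equal(out, y)
        assert any("too short" in r.message for r in caplog.records)

    def test_hat_matrix_rows_sum_to_one(self):
        hat = loess_hat_matrix(15, SmootherConfig())
        np.testing.assert_allclose(hat.sum(axis=1), np.ones(15), atol=1e-10)

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigurationError):
            SmootherConfig(span=0.0)
        with pytest.raises(ConfigurationError):
            SmootherConfig(degree=3)


def _meta(samples, cls="stage"):
    return pd.DataFrame(
        {"sample_id": samples, "class": cls, "stage_rank": range(1, len(samples) + 1)}
    )


class TestBuildRatioMatrix:
    def test_unsmoothed_row_equals_elementwise_ratio(self):
        q = _quants({"e1": [(9, 4), (0, 0), (4, 9)]})
        mat = build_ratio_matrix(q, _meta(["s0", "s1", "s2"]), smoother=None)
        np.testing.assert_allclose(
            mat.values.loc["e1"].to_numpy(), [np.log(2), 0.0, -np.log(2)], atol=1e-12
        )

    def test_identical_fpkm_gives_identical_rows(self):
        series = [(9, 4), (2, 7), (5, 5), (8, 1)]
        q = _quants({"e1": series, "e2": series})
        mat = build_ratio_matrix(q, _meta([f"s{t}" for t in range(4)]))
        np.testing.assert_array_equal(
            mat.values.loc["e1"].to_numpy(), mat.values.loc["e2"].to_numpy()
        )

    def test_row_order_invariance(self):
        q = _quants({"e1": [(9, 4), (2, 7), (5, 5)], "e2": [(1, 2), (3, 4), (5, 6)]})
        meta = _meta(["s0", "s1", "s2"])
        m1 = build_ratio_matrix(q, meta)
        m2 = build_ratio_matrix(q.sample(frac=1, random_state=0), meta)
        pd.testing.assert_frame_equal(m1.values, m2.values)

    def test_duplicate_cells_rejected(self):
        q = _quants({"e1": [(9, 4), (2, 7)]})
        dup = pd.concat([q, q.iloc[[0]]], ignore_index=True)
        with pytest.raises(CompletenessError):
            build_ratio_matrix(dup, _meta(["s0", "s1"]))

    def test_tissue_columns_left_unsmoothed(self):
        rng = np.random.default_rng(4)
        series = [(float(v), 1.0) for v in rng.uniform(0, 50, 14)]
        q = _quants({"e1": series})
        meta = _meta([f"s{t}" for t in range(14)])
        meta.loc[12:, "class"] = "tissue"
        meta.loc[12:, "stage_rank"] = np.nan
        mat = build_ratio_matrix(q, meta, SmootherConfig(span=0.5))
        raw = compute_is_ratio(
            np.array([i for i, _ in series]), np.array([s for _, s in series])
        )
        np.testing.assert_allclose(mat.values.loc["e1", ["s12", "s13"]], raw[12:],
                                   atol=1e-12)
        assert not np.allclose(mat.values.loc["e1", ["s0", "s1"]], raw[:2])

    def test_noise_free_planted_ratio_recovered_exactly(self):
        import exoncorr as xc

        cfg = xc.SimConfig(
            n_pairs=30, n_fly_stages=8, n_worm_stages=8, noise_sd=0.0,
            frac_non_cassette=0.0, seed=5,
        )
        b = xc.generate(cfg)
        mat = build_ratio_matrix(b.fpkm_fly, b.samples_fly, smoother=None)
        sig = b.truth.signal_pairs.iloc[0]
        row = mat.values.loc[sig["fly_exon_id"]].to_numpy()
        t = int(sig["planted_fly_stage"])
        inside = range(max(t - 1, 0), min(t + 1, 7) + 1)
        outside = [i for i in range(8) if i not in inside]
        sign = 1.0 if sig["planted_status"] == "HIGH" else -1.0
        # constant baseline + exact planted shift in the window
        assert np.ptp(row[outside]) == pytest.approx(0.0, abs=1e-9)
        for i in inside:
            assert row[i] - row[outside[0]] == pytest.approx(sign * cfg.effect_size,
                                                             abs=1e-9)
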