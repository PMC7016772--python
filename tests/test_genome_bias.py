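"""Genome-mode normalization, binned profile, quadratic fit, feature ratios."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pysam
import pytest

from gclens import (
    BiasModel,
    FeatureInterval,
    amplicon_read_ratio,
    bin_profile,
    feature_background_ratio,
    fit_quadratic,
    make_windows,
    normalize_windows,
    simulate_depth,
)


def _table(gc_bins, depths):
    gc_bins = np.asarray(gc_bins)
    return pd.DataFrame(
        {
            "contig": "c1",
            "start": np.arange(len(gc_bins)) * 500,
            "end": (np.arange(len(gc_bins)) + 1) * 500,
            "gc_percent": gc_bins.astype(float),
            "gc_bin": gc_bins,
            "mean_depth": np.asarray(depths, dtype=float),
            "n_unambiguous": 500,
        }
    )


class TestNormalizeWindows:
    def test_uniform_depth_normalizes_to_one(self):
        table = _table([49, 49, 49, 30, 60], [7, 7, 7, 7, 7])
        normalized = normalize_windows(table)
        assert (normalized["mean_depth"] == 1.0).all()

    def test_reference_bin_mean_is_exactly_one(self):
        table = _table([49, 49, 49, 30, 30], [18, 20, 22, 2, 2])
        normalized = normalize_windows(table)
        ref = normalized[normalized["gc_bin"] == 49]["mean_depth"]
        assert ref.mean() == pytest.approx(1.0, abs=1e-15)
        assert np.log10(ref.mean()) == pytest.approx(0.0, abs=1e-15)

    def test_two_bin_arithmetic(self):
        table = _table([30, 49, 49, 49], [2, 20, 20, 20])
        normalized = normalize_windows(table)
        assert normalized["mean_depth"].iloc[0] == pytest.approx(0.1)
        assert np.log10(normalized["mean_depth"].iloc[0]) == pytest.approx(-1.0)

    def test_underpopulated_reference_bin_names_candidates(self):
        table = _table([49, 30, 30, 30, 30], [10, 5, 5, 5, 5])
        with pytest.raises(ValueError, match=r"candidate bins: \[30\]"):
            normalize_windows(table)

    def test_matches_brute_force_on_simulation(self, gradient_assembly):
        tracks = simulate_depth(
            gradient_assembly, BiasModel(kind="quadratic", a=-0.0015, b=0.165),
            30.0, seed=4,
        )
        table = make_windows(gradient_assembly, tracks)
        normalized = normalize_windows(table)
        ref_depths = table.loc[
            (table["gc_bin"] == 49) & (table["mean_depth"] > 0), "mean_depth"
        ]
        expected = table["mean_depth"].to_numpy() / ref_depths.mean()
        np.testing.assert_allclose(
            normalized["mean_depth"].to_numpy(), expected, rtol=1e-12
        )


class TestBinProfile:
    def test_constant_bin_stats(self):
        table = _table([40] * 3 + [49] * 3 + [60] * 3, [1.0] * 9)
        profile = bin_profile(table, min_windows_per_bin=3)
        row = profile.set_index("gc_bin").loc[40]
        assert row["mean_norm"] == 1.0
        assert row["sd_norm"] == 0.0
        assert row["n_windows"] == 3

    def test_underpopulated_bins_dropped(self):
        gc = [40] * 3 + [50] * 3 + [60] * 3 + [70] * 2
        table = _table(gc, [1.0] * 11)
        profile = bin_profile(table, min_windows_per_bin=3)
        assert 70 not in set(profile["gc_bin"])

    def test_too_few_bins_is_error(self):
        table = _table([40] * 3 + [50] * 3, [1.0] * 6)
        with pytest.raises(ValueError, match="GC bins"):
            bin_profile(table, min_windows_per_bin=3)

    def test_matches_groupby_oracle(self, rng):
        gc = rng.integers(30, 70, size=400)
        depths = rng.uniform(0.1, 3.0, size=400)
        table = _table(gc, depths)
        profile = bin_profile(table).set_index("gc_bin")
        for b in np.unique(gc):
            values = depths[gc == b]
            if len(values) < 3:
                assert b not in profile.index
                continue
            assert profile.loc[b, "n_windows"] == len(values)
            assert profile.loc[b, "mean_norm"] == pytest.approx(values.mean(), rel=1e-12)
            assert profile.loc[b, "sd_norm"] == pytest.approx(
                values.std(ddof=1), rel=1e-12
            )
            assert profile.loc[b, "log10_mean"] == pytest.approx(
                np.log10(values.mean()), rel=1e-12
            )


def _profile_from(g, y, w):
    return pd.DataFrame(
        {
            "gc_bin": g,
            "n_windows": w,
            "mean_norm": np.power(10.0, np.asarray(y, dtype=float)),
            "sd_norm": 0.0,
            "log10_mean": np.asarray(y, dtype=float),
        }
    )


class TestFitQuadratic:
    def test_exact_interpolation_of_noiseless_parabola(self):
        g = np.arange(30, 71)
        y = -0.002 * (g - 55.0) ** 2
        fit = fit_quadratic(_profile_from(g, y, np.ones_like(g)))
        assert fit.a == pytest.approx(-0.002, abs=1e-12)
        assert fit.vertex == pytest.approx(55.0, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_constant_profile_fits_flat(self):
        g = np.arange(30, 71)
        fit = fit_quadratic(_profile_from(g, np.zeros_like(g, dtype=float), np.ones_like(g)))
        assert fit.a == pytest.approx(0.0, abs=1e-12)
        assert fit.b == pytest.approx(0.0, abs=1e-12)
        assert fit.c == pytest.approx(0.0, abs=1e-12)

    def test_matches_closed_form_normal_equations(self, rng):
        g = np.arange(25, 76).astype(float)
        y = -0.0018 * g**2 + 0.19 * g - 4.7 + rng.normal(0, 0.05, size=len(g))
        w = rng.integers(3, 400, size=len(g)).astype(float)
        fit = fit_quadratic(_profile_from(g, y, w))
        # independent closed-form weighted normal equations
        X = np.column_stack([g**2, g, np.ones_like(g)])
        beta = np.linalg.solve(X.T @ np.diag(w) @ X, X.T @ np.diag(w) @ y)
        assert fit.a == pytest.approx(beta[0], rel=1e-9)
        assert fit.b == pytest.approx(beta[1], rel=1e-9)
        assert fit.c == pytest.approx(beta[2], rel=1e-9)
        resid = y - X @ beta
        wmean = np.average(y, weights=w)
        r2 = 1 - (w * resid**2).sum() / (w * (y - wmean) ** 2).sum()
        assert fit.r_squared == pytest.approx(r2, rel=1e-9)

    def test_rank_deficient_design_rejected(self):
        profile = _profile_from([40, 40, 40], [0.0, 0.1, 0.2], [5, 5, 5])
        with pytest.raises(ValueError, match="rank-deficient|distinct"):
            fit_quadratic(profile)

    def test_fit_scale_invariant_after_normalization(self, gradient_assembly):
        tracks = simulate_depth(
            gradient_assembly, BiasModel(kind="quadratic", a=-0.0015, b=0.165),
            30.0, seed=4,
        )
        table = make_windows(gradient_assembly, tracks)
        fit1 = fit_quadratic(bin_profile(normalize_windows(table)))
        scaled = table.copy()
        scaled["mean_depth"] = scaled["mean_depth"] * 13.0
        fit2 = fit_quadratic(bin_profile(normalize_windows(scaled)))
        assert fit2.a == pytest.approx(fit1.a, rel=1e-9)
        assert fit2.b == pytest.approx(fit1.b, rel=1e-9)
        assert fit2.c == pytest.approx(fit1.c, rel=1e-9)


class TestTrendInvariance:
    def test_curvature_sign_stable_across_window_widths(self, gradient_assembly):
        """The fitted bias-curve shape is qualitatively unchanged for window
        widths 50-5000 nt.  Narrow windows cannot populate odd GC bins (50-nt
        windows have 2%-granular GC), so this sweep normalizes by the overall
        mean coverage instead of the 49% anchor bin."""
        tracks = simulate_depth(
            gradient_assembly, BiasModel(kind="quadratic", a=-0.0015, b=0.165),
            30.0, seed=23,
        )
        signs = []
        for width in (50, 500, 5000):
            table = make_windows(gradient_assembly, tracks, width=width)
            scaled = table.copy()
            scaled["mean_depth"] = scaled["mean_depth"] / scaled["mean_depth"].mean()
            fit = fit_quadratic(bin_profile(scaled))
            signs.append(np.sign(fit.a))
        assert signs == [-1.0, -1.0, -1.0]


class TestFeatureBackgroundRatio:
    def test_uniform_depth_gives_ratio_one(self):
        tracks = {"c1": np.full(1000, 12)}
        fr = feature_background_ratio(tracks, [FeatureInterval("c1", 100, 200)])
        assert fr.ratio == pytest.approx(1.0)

    def test_eightfold_feature(self):
        depths = np.full(1000, 10)
        depths[100:200] = 80
        fr = feature_background_ratio(
            {"c1": depths}, [FeatureInterval("c1", 100, 200)]
        )
        assert fr.ratio == pytest.approx(8.0)

    def test_matches_mask_and_mean_oracle(self, rng):
        depths = rng.integers(0, 100, size=5000)
        intervals = [
            FeatureInterval("c1", 100, 400),
            FeatureInterval("c1", 1000, 1800),
            FeatureInterval("c1", 4000, 4500),
        ]
        fr = feature_background_ratio({"c1": depths}, intervals)
        mask = np.zeros(5000, dtype=bool)
        for iv in intervals:
            mask[iv.start : iv.end] = True
        assert fr.feature_mean_depth == pytest.approx(depths[mask].mean(), rel=1e-12)
        assert fr.background_mean_depth == pytest.approx(depths[~mask].mean(), rel=1e-12)

    def test_empty_features_rejected(self):
        with pytest.raises(ValueError):
            feature_background_ratio({"c1": np.ones(10)}, [])

    def test_interval_beyond_track_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            feature_background_ratio(
                {"c1": np.ones(10)}, [FeatureInterval("c1", 5, 20)]
            )


class TestAmpliconReadRatio:
    def _two_ref_bam(self, tmp_path, n_a, n_b, extra_flags=()):
        header = {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": "ampA", "LN": 5300}, {"SN": "ampB", "LN": 5300}],
        }
        path = tmp_path / "amp.bam"
        with pysam.AlignmentFile(str(path), "wb", header=header) as out:
            i = 0
            for ref_id, n in ((0, n_a), (1, n_b)):
                for _ in range(n):
                    a = pysam.AlignedSegment()
                    a.query_name = f"r{i}"
                    a.flag = 0
                    a.reference_id = ref_id
                    a.reference_start = 10
                    a.mapping_quality = 60
                    a.cigarstring = "100M"
                    a.query_sequence = "A" * 100
                    out.write(a)
                    i += 1
            # extra records may be out of coordinate order; the counter
            # streams the file, so no index is needed
            for flag in extra_flags:
                a = pysam.AlignedSegment()
                a.query_name = f"x{flag}"
                a.flag = flag
                a.reference_id = 0
                a.reference_start = 10
                a.mapping_quality = 60
                a.cigarstring = "100M"
                a.query_sequence = "A" * 100
                out.write(a)
        return path

    def test_fourfold_ratio(self, tmp_path):
        path = self._two_ref_bam(tmp_path, 100, 25)
        assert amplicon_read_ratio(path, ("ampA", "ampB")) == pytest.approx(4.0)

    def test_secondary_and_supplementary_not_counted(self, tmp_path):
        path = self._two_ref_bam(tmp_path, 10, 10, extra_flags=(0x100, 0x800))
        assert amplicon_read_ratio(path, ("ampA", "ampB")) == pytest.approx(1.0)

    def test_zero_denominator_is_infinite_with_warning(self, tmp_path):
        path = self._two_ref_bam(tmp_path, 5, 0)
        with pytest.warns(UserWarning, match="infinite"):
            assert amplicon_read_ratio(path, ("ampA", "ampB")) == float("inf")
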