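"""Pulse-chase normalization, background term, decay fitting, stability metric."""
import numpy as np
import pandas as pd
import pytest

from lysorna import (
    SimulationConfig,
    average_replicates,
    background_z,
    filter_fits,
    fit_decay,
    fit_timecourse,
    half_life,
    nluc_normalize,
    simulate_pulse_chase,
    simulate_transcriptome,
    stability_metric,
    stability_table,
    t0_normalize,
)

from oracles import decay_sse, fit_filter_oracle, grid_search_sse

LN2 = np.log(2.0)
TIMEPOINTS = np.array([0.0, 1.0, 2.0, 4.0, 8.0, 28.0])


def tc_frame(rows):
    return pd.DataFrame(
        rows, columns=["gene_id", "genotype", "treatment", "replicate", "time_h", "count"]
    )


class TestNlucNormalize:
    def base_rows(self, nluc=5.0):
        rows = []
        for t in (0.0, 1.0):
            rows.append(("g1", "WT", "none", 1, t, 10.0))
            rows.append(("nLuc", "WT", "none", 1, t, nluc))
        return tc_frame(rows)

    def test_unit_nluc_is_identity(self):
        out = nluc_normalize(self.base_rows(nluc=1.0))
        assert (out["count"] == 10.0).all()
        assert "nLuc" not in set(out["gene_id"])

    def test_divides_by_per_sample_nluc(self):
        out = nluc_normalize(self.base_rows(nluc=5.0))
        assert (out["count"] == 2.0).all()

    def test_scaling_one_sample_leaves_normalized_values_unchanged(self):
        tc = self.base_rows()
        scaled = tc.copy()
        mask = scaled["time_h"] == 1.0
        scaled.loc[mask, "count"] *= 7.3
        pd.testing.assert_frame_equal(nluc_normalize(tc), nluc_normalize(scaled))

    def test_zero_nluc_names_the_sample(self):
        tc = self.base_rows()
        tc.loc[(tc["gene_id"] == "nLuc") & (tc["time_h"] == 1.0), "count"] = 0.0
        with pytest.raises(ValueError, match="t=1.0"):
            nluc_normalize(tc)


class TestT0Normalize:
    def test_divides_by_t0(self):
        out = t0_normalize([8.0, 4.0, 2.0], [0.0, 1.0, 2.0])
        np.testing.assert_array_equal(out, [1.0, 0.5, 0.25])

    def test_constant_series_becomes_ones(self):
        out = t0_normalize([3.0, 3.0, 3.0], [0.0, 2.0, 4.0])
        np.testing.assert_array_equal(out, [1.0, 1.0, 1.0])

    def test_zero_t0_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            t0_normalize([0.0, 1.0], [0.0, 1.0])

    def test_missing_t0_rejected(self):
        with pytest.raises(ValueError, match="no t = 0"):
            t0_normalize([1.0, 2.0], [1.0, 2.0])


class TestBackgroundZ:
    def test_floor_dominated(self):
        assert background_z([0.0, 0.0, 0.0, 0.0], 0.001) == pytest.approx(0.005)

    def test_mock_dominated(self):
        assert background_z([0.001, 0.01, 0.002, 0.0], 1.0) == pytest.approx(0.01)

    def test_matches_formula_over_random_inputs(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            mocks = rng.uniform(0, 1e-3, 4)
            t0 = rng.uniform(1e-4, 10)
            assert background_z(mocks, t0) == pytest.approx(
                max(mocks.max(), 5e-6) / t0
            )
            assert background_z(mocks, t0, z_mode="floor_quotient") == pytest.approx(
                max(mocks.max(), 5e-6 / t0)
            )

    def test_nonpositive_t0_rejected(self):
        with pytest.raises(ValueError):
            background_z([0.0] * 4, 0.0)


def synth_series(C, k, z_lin=0.0, timepoints=TIMEPOINTS):
    """Noiseless t0-normalized log2 series from the linear-space model."""
    signal = C * np.exp(-k * timepoints) + z_lin
    return np.log2(signal / signal[0] * (C + z_lin))


@pytest.mark.parametrize("background_mode", ["log_offset", "linear_plateau"])
def test_fit_recovers_exact_model_parameters(background_mode):
    y = np.log2(1.0 * np.exp(-0.3 * TIMEPOINTS))
    fit = fit_decay(TIMEPOINTS, y, z=0.0, background_mode=background_mode)
    assert fit.C == pytest.approx(1.0, rel=1e-6)
    assert fit.k == pytest.approx(0.3, rel=1e-6)
    assert fit.converged


def test_fit_starting_values_do_not_bias_large_C():
    y = np.log2(40.0 * np.exp(-1.2 * TIMEPOINTS))
    fit = fit_decay(TIMEPOINTS, y, z=0.0)
    assert fit.C == pytest.approx(40.0, rel=1e-5)
    assert fit.k == pytest.approx(1.2, rel=1e-5)


def test_fixed_c_is_returned_bit_exactly():
    rng = np.random.default_rng(1)
    y = np.log2(np.exp(-0.2 * TIMEPOINTS)) + rng.normal(0, 0.2, len(TIMEPOINTS))
    fit = fit_decay(TIMEPOINTS, y, z=0.0, c_fixed=0.87)
    assert fit.C == 0.87
    assert fit.c_was_fixed
    assert np.isnan(fit.p_C)


def test_fit_rejects_insufficient_points():
    with pytest.raises(ValueError, match="timepoints"):
        fit_decay([0.0, 1.0], [0.0, -1.0], z=0.0)
    # two points suffice when C is fixed
    fit = fit_decay([0.0, 1.0], [0.0, -1.0], z=0.0, c_fixed=1.0)
    assert fit.k == pytest.approx(LN2, rel=1e-6)


def test_synthesis_rate_is_c_times_k():
    y = np.log2(2.0 * np.exp(-0.5 * TIMEPOINTS))
    fit = fit_decay(TIMEPOINTS, y, z=0.0)
    assert fit.synthesis == pytest.approx(fit.C * fit.k)


@pytest.mark.parametrize("background_mode", ["log_offset", "linear_plateau"])
def test_optimum_beats_grid_search_oracle(background_mode):
    rng = np.random.default_rng(42)
    for _ in range(5):
        k = rng.uniform(0.05, 1.0)
        y = np.log2(np.exp(-k * TIMEPOINTS)) + rng.normal(0, 0.15, len(TIMEPOINTS))
        z = 1e-4
        fit = fit_decay(TIMEPOINTS, y, z=z, background_mode=background_mode)
        own = decay_sse(fit.C, fit.k, z, TIMEPOINTS, y, background_mode)
        grid = grid_search_sse(TIMEPOINTS, y, z, background_mode, n_grid=200)
        assert own <= grid * (1 + 1e-9) + 1e-12
        assert fit.sse == pytest.approx(own, rel=1e-9)


class TestHalfLife:
    def test_unit_rate(self):
        assert half_life(LN2) == pytest.approx(1.0)

    def test_slow_decay_capped_at_ceiling(self):
        assert half_life(1e-6) == 50.0

    def test_zero_rate_maps_to_cap(self):
        assert half_life(0.0) == 50.0

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            half_life(-0.1)


def test_filter_keeps_significant_converged_fits():
    fits = pd.DataFrame(
        [
            {"p_k": 0.01, "p_C": 0.01, "c_was_fixed": False, "converged": True},
            {"p_k": 0.2, "p_C": 0.01, "c_was_fixed": False, "converged": True},
            {"p_k": 0.01, "p_C": 0.2, "c_was_fixed": False, "converged": True},
            {"p_k": 0.01, "p_C": np.nan, "c_was_fixed": True, "converged": True},
            {"p_k": 0.01, "p_C": 0.01, "c_was_fixed": False, "converged": False},
        ]
    )
    kept = filter_fits(fits)
    assert list(kept.index) == [0, 1]
    assert kept.iloc[0]["p_k"] == 0.01 and not kept.iloc[0]["c_was_fixed"]
    assert kept.iloc[1]["c_was_fixed"]


@pytest.mark.parametrize("seed", range(5))
def test_filter_matches_bruteforce_scan(seed):
    rng = np.random.default_rng(300 + seed)
    rows = [
        {
            "p_k": rng.uniform(0, 0.1),
            "p_C": rng.uniform(0, 0.1),
            "c_was_fixed": bool(rng.integers(2)),
            "converged": bool(rng.integers(2)),
        }
        for _ in range(40)
    ]
    fits = pd.DataFrame(rows)
    kept = filter_fits(fits, alpha=0.05)
    assert list(kept.index) == list(range(len(fit_filter_oracle(rows, 0.05))))
    oracle_rows = [rows[i] for i in fit_filter_oracle(rows, 0.05)]
    pd.testing.assert_frame_equal(kept, pd.DataFrame(oracle_rows), check_dtype=False)


def test_replicate_averaging_is_arithmetic_mean():
    fits = pd.DataFrame(
        {
            "gene_id": ["g", "g", "h"],
            "genotype": ["WT"] * 3,
            "treatment": ["none"] * 3,
            "halflife_h": [4.0, 6.0, 9.0],
        }
    )
    out = average_replicates(fits).set_index("gene_id")
    assert out.loc["g", "halflife_h"] == 5.0
    assert out.loc["g", "n_replicates"] == 2
    assert out.loc["h", "halflife_h"] == 9.0
    assert out.loc["h", "n_replicates"] == 1


class TestStabilityMetric:
    def test_no_effect_gives_unity(self):
        assert stability_metric(7.0, 7.0, 7.0, 7.0) == 1.0

    def test_wt_specific_destabilization(self):
        assert stability_metric(10.0, 5.0, 10.0, 10.0) == 0.5

    def test_missing_halflife_undefined(self):
        assert np.isnan(stability_metric(10.0, 5.0, np.nan, 10.0))

    def test_genotype_relabeling_inverts_exactly(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            a, b, c, d = rng.uniform(0.5, 50, 4)
            forward = stability_metric(a, b, c, d)
            swapped = stability_metric(c, d, a, b)
            # inversion is exact up to one ulp of the final division
            assert swapped == pytest.approx(1.0 / forward, rel=1e-12)
            assert swapped * forward == pytest.approx(1.0, rel=1e-12)


def run_decay_pipeline(cfg, truth=None, background_mode="linear_plateau"):
    truth = simulate_transcriptome(cfg) if truth is None else truth
    tc, mock = simulate_pulse_chase(truth, cfg)
    fits = fit_timecourse(tc, mock, background_mode=background_mode)
    return truth, fits


def test_halflife_recovery_on_noisy_timecourses():
    cfg = SimulationConfig(
        n_genes=100, seed=23,
        torin_effect_by_genotype={"WT": 1.0}, n_replicates=2,
    )
    truth, fits = run_decay_pipeline(cfg)
    retained = filter_fits(fits)
    merged = average_replicates(retained).merge(
        truth[["gene_id", "true_k"]], on="gene_id"
    )
    merged = merged[merged["treatment"] == "none"]
    true_hl = LN2 / merged["true_k"]
    rel_err = np.abs(merged["halflife_h"] - true_hl) / true_hl
    assert (rel_err <= 0.2).mean() >= 0.9


def test_very_stable_transcripts_report_exactly_the_cap():
    cfg = SimulationConfig(
        n_genes=20, seed=29, true_halflife_range_h=(500.0, 2000.0),
        torin_effect_by_genotype={"WT": 1.0}, n_replicates=2,
    )
    truth, fits = run_decay_pipeline(cfg)
    assert (fits["halflife_h"] == 50.0).all()


def test_torin_fits_share_untreated_c():
    cfg = SimulationConfig(n_genes=10, seed=31)
    truth, fits = run_decay_pipeline(cfg)
    key = ["gene_id", "genotype", "replicate"]
    wide = fits.pivot_table(index=key, columns="treatment", values="C", aggfunc="first")
    np.testing.assert_array_equal(wide["none"].to_numpy(), wide["torin1"].to_numpy())
    assert fits.loc[fits["treatment"] == "torin1", "c_was_fixed"].all()


def test_null_simulation_gives_calibrated_stability():
    cfg = SimulationConfig(
        n_genes=150, seed=37,
        torin_effect_by_genotype={"WT": 1.0, "ATG7_KO": 1.0},
    )
    truth, fits = run_decay_pipeline(cfg)
    retained = filter_fits(fits)
    stab = stability_table(average_replicates(retained))
    med = stab["stability"].median()
    assert 0.95 <= med <= 1.05
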