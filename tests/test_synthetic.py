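"""Synthetic spectrum generator and filtration process simulator."""

import numpy as np
import pytest

from ramanpat.qc import detect_defective
from ramanpat.spectra import average_block
from ramanpat.synthetic import (GeneratorConfig, generate_process_spectra,
                                generate_spectrum, generate_stock_series,
                                simulate_cff_process)


@pytest.fixture(scope="module")
def noiseless():
    return GeneratorConfig(seed=0).noiseless()


class TestGenerateSpectrum:
    def test_blank_is_deterministic_buffer_spectrum(self, noiseless):
        rng = np.random.default_rng(0)
        comp = {"sulfate": 0.0, "tris": 1.0, "water_oh": 1.0}
        a = generate_spectrum(comp, 175.0, noiseless, rng)
        b = generate_spectrum(comp, 175.0, noiseless, np.random.default_rng(0))
        np.testing.assert_array_equal(a.intensities, b.intensities)
        assert a.intensities.max() > 0
        # no sulfate signal at the 980 band beyond the flat background
        assert a.intensity_at(980.0) < 0.01 * a.intensities.max()

    def test_intensities_double_with_exposure_below_saturation(self, noiseless):
        rng = np.random.default_rng(0)
        comp = {"sulfate": 0.1, "ammonium": 0.1, "water_oh": 1.0}
        a = generate_spectrum(comp, 100.0, noiseless, rng)
        b = generate_spectrum(comp, 200.0, noiseless, rng)
        np.testing.assert_allclose(b.intensities, 2.0 * a.intensities,
                                   rtol=1e-12)

    def test_linear_in_concentration_without_noise(self, noiseless):
        rng = np.random.default_rng(0)
        def spec(c):
            return generate_spectrum({"sulfate": c, "water_oh": 1.0}, 175.0,
                                     noiseless, rng).intensities
        base, one, two = spec(0.0), spec(0.4), spec(0.8)
        np.testing.assert_allclose(two - base, 2.0 * (one - base), rtol=1e-9,
                                   atol=1e-9)

    def test_split_peak_appears_only_at_high_exposure(self, gen_config):
        rng = np.random.default_rng(0)
        comp = {"sulfate": 0.6, "ammonium": 0.6, "water_oh": 1.0}
        config = gen_config
        hot = generate_spectrum(comp, 1250.0, config.noiseless(), rng)
        cold = generate_spectrum(comp, 175.0, config.noiseless(), rng)
        wn = hot.axis.values
        band = (wn >= 940) & (wn <= 1020)

        def n_local_maxima(y):
            interior = np.arange(1, y.size - 1)
            return int(np.sum((y[interior] >= y[interior - 1])
                              & (y[interior] > y[interior + 1])))

        assert n_local_maxima(hot.intensities[band]) >= 2
        assert n_local_maxima(cold.intensities[band]) == 1
        # interior minimum between the two flank maxima
        yb = hot.intensities[band]
        assert yb.min() < yb.max()
        assert hot.intensities.max() <= config.clip_level

    def test_negative_concentration_rejected(self, gen_config):
        with pytest.raises(ValueError, match="negative"):
            generate_spectrum({"sulfate": -0.1}, 175.0, gen_config,
                              np.random.default_rng(0))


class TestStockSeries:
    def test_series_counting_and_reference(self, gen_config):
        levels = np.linspace(0, 1.1, 12)
        spectra = generate_stock_series("AMS", levels, 50, 175.0, gen_config,
                                        seed=3)
        assert len(spectra) == 600
        assert spectra.reference.shape == (600,)
        assert spectra.analyte == "AMS"

    def test_same_seed_is_bit_identical(self, gen_config):
        a = generate_stock_series("AMS", [0.0, 1.1], 3, 175.0, gen_config, seed=9)
        b = generate_stock_series("AMS", [0.0, 1.1], 3, 175.0, gen_config, seed=9)
        np.testing.assert_array_equal(a.intensity_matrix, b.intensity_matrix)

    def test_vlp_series_shows_residual_sulfate_and_protein_scaling(self, gen_config):
        spectra = generate_stock_series("VLP", [0.0, 2.2], 1, 1250.0,
                                        gen_config.noiseless(), seed=4)
        lo, hi = spectra.spectra
        # residual precipitant: sulfate band present even at zero product
        assert lo.intensity_at(980.0) > 50 * lo.intensity_at(900.0)
        # protein band grows with the product level
        assert hi.intensity_at(1341.0) > 2.0 * lo.intensity_at(1341.0)

    def test_out_of_range_level_rejected(self, gen_config):
        with pytest.raises(ValueError, match="outside"):
            generate_stock_series("AMS", [1.5], 1, 175.0, gen_config, seed=0)

    def test_nonpositive_reps_rejected(self, gen_config):
        with pytest.raises(ValueError, match="reps"):
            generate_stock_series("AMS", [0.5], 0, 175.0, gen_config, seed=0)


class TestProcessSimulation:
    def test_unit_rho_matches_closed_form_cascade(self):
        # rho=1 linear cascade: C2(v) = c0 * v * exp(-v), peak c0/e at v=1
        c0 = 1.1
        trace = simulate_cff_process(c0, 0.0, rho=1.0, dv_max=7.0, dt=0.01)
        df = trace.phase == "DF"
        v = trace.dv_grid[df]
        np.testing.assert_allclose(trace.c_ams_stage2[df], c0 * v * np.exp(-v),
                                   atol=1e-7)
        i_peak = np.argmax(trace.c_ams_stage2[df])
        assert v[i_peak] == pytest.approx(1.0, abs=0.02)
        assert trace.c_ams_stage2[df][i_peak] == pytest.approx(c0 / np.e,
                                                               rel=1e-4)

    def test_zero_inlet_gives_zero_trace(self):
        trace = simulate_cff_process(0.0, 1.0, rho=0.7, dv_max=5.0)
        np.testing.assert_array_equal(trace.c_ams_stage2, 0.0)

    def test_peak_location_matches_analytic_solution(self):
        # two-compartment cascade peaks at ln(rho)/(rho-1)
        rho = 0.55
        trace = simulate_cff_process(1.1, 0.0, rho=rho, dv_max=7.0, dt=0.001)
        df = trace.phase == "DF"
        v_peak = trace.dv_grid[df][np.argmax(trace.c_ams_stage2[df])]
        assert v_peak == pytest.approx(np.log(rho) / (rho - 1.0), abs=0.01)

    def test_stage2_bounded_by_inlet_concentration(self):
        trace = simulate_cff_process(1.1, 1.5, rho=0.55, dv_max=9.0)
        assert np.all(trace.c_ams_stage2 >= 0)
        assert np.all(trace.c_ams_stage2 <= 1.1)
        df = trace.phase == "DF"
        assert trace.c_ams_stage2[df][-1] < 0.05  # washed out at high DV

    def test_uf_concentrates_product_and_shrinks_volume(self):
        trace = simulate_cff_process(1.1, 1.5, rho=0.55, dv_max=7.0,
                                     uf_factor=2.5)
        uf = trace.phase == "UF"
        df = trace.phase == "DF"
        assert trace.volume[uf][-1] == pytest.approx(25.0 / 2.5)
        assert np.all(np.diff(trace.volume[df]) == 0)
        assert trace.c_vlp_stage2[uf][-1] == pytest.approx(
            2.5 * trace.c_vlp_stage2[df][-1], rel=1e-9)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            simulate_cff_process(1.1, 1.0, rho=0.0, dv_max=5.0)
        with pytest.raises(ValueError):
            simulate_cff_process(1.1, 1.0, rho=1.0, dv_max=0.5)


@pytest.fixture(scope="module")
def trace():
    return simulate_cff_process(1.1, 1.5, rho=0.55, dv_max=2.0, dt=0.5,
                                uf_span=1.0)


class TestProcessSpectra:

    def test_continuous_mode_covers_every_step(self, trace, gen_config):
        spectra = generate_process_spectra(trace, "continuous", 1250.0,
                                           gen_config, seed=1, reps=3)
        assert len(spectra) == trace.dv_grid.size * 3
        averaged = average_block(spectra, 3)
        assert len(averaged) == trace.dv_grid.size

    def test_semi_continuous_mode_restricts_to_windows(self, trace, gen_config):
        spectra = generate_process_spectra(trace, "semi_continuous", 175.0,
                                           gen_config, seed=1, reps=2)
        dvs = sorted({s.dv for s in spectra})
        assert 0 < len(dvs) < trace.dv_grid.size
        assert 0.5 in dvs and 1.0 in dvs

    def test_defective_window_outside_trace_rejected(self, trace, gen_config):
        with pytest.raises(ValueError, match="defective_window"):
            generate_process_spectra(trace, "continuous", 1250.0, gen_config,
                                     inject={"defective_window": (10.0, 11.0)},
                                     seed=1, reps=2)

    def test_injected_defects_detected_in_their_window(self, gen_config):
        trace = simulate_cff_process(1.1, 1.5, rho=0.55, dv_max=7.0, dt=0.1)
        spectra = generate_process_spectra(
            trace, "continuous", 1250.0, gen_config,
            inject={"defective_window": (0.7, 1.8)}, seed=2, reps=2)
        averaged = average_block(spectra, 2)
        report = detect_defective(averaged, window=61, k=6.0)
        dvs = np.array([s.dv for s in averaged])
        flagged = np.array(report.flags) == "defective"
        in_window = (dvs >= 0.7) & (dvs <= 1.8)
        assert np.all(flagged[in_window])
        # no false flags elsewhere in the diafiltration phase
        df_outside = ~in_window & (dvs <= 7.0)
        assert not np.any(flagged[df_outside])

    def test_fouling_inflates_protein_signal_with_dv(self, gen_config):
        trace = simulate_cff_process(1.1, 1.5, rho=0.55, dv_max=4.0, dt=1.0)
        clean = generate_process_spectra(trace, "continuous", 1250.0,
                                         gen_config.noiseless(), seed=3, reps=1)
        fouled = generate_process_spectra(trace, "continuous", 1250.0,
                                          gen_config.noiseless(),
                                          inject={"fouling": True}, seed=3, reps=1)
        excess = [f.intensity_at(1341.0) - c.intensity_at(1341.0)
                  for c, f in zip(clean, fouled)]
        assert all(np.diff(excess) > 0)  # bias grows monotonically with dv
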