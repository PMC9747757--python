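"""Avalanche extraction and exponent estimation."""

import numpy as np
import pytest
from scipy import stats as spstats

from quasicrit.avalanches import (
    AvalancheCatalog,
    ExponentFit,
    ExponentPair,
    dcc,
    duration_cutoff,
    extract_avalanches,
    fit_gamma,
    fit_power_law,
    scaling_fraction,
)
from quasicrit.cbm import Raster
from quasicrit.errors import FitFailureError, InvalidArgumentError


def catalog_from(sizes, durations):
    sizes = np.asarray(sizes)
    durations = np.asarray(durations)
    return AvalancheCatalog(
        sizes=sizes,
        durations=durations,
        start_bins=np.arange(sizes.size),
        first_bin_counts=np.ones_like(sizes),
        second_bin_counts=np.zeros_like(sizes),
    )


class TestExtractAvalanches:
    def test_empty_raster_gives_empty_catalog(self):
        cat = extract_avalanches(Raster(data=np.zeros((3, 10), dtype=np.uint8)))
        assert len(cat) == 0

    def test_two_runs_separated_by_silence(self):
        # five units, two cascades of 4 bins each separated by one empty
        # bin: sizes 4 and 5, durations 4 and 4
        data = np.zeros((5, 11), dtype=np.uint8)
        for t, units in zip(range(1, 5), [[0], [1], [2], [3]]):
            data[units, t] = 1
        for t, units in zip(range(6, 10), [[0], [1, 2], [3], [4]]):
            data[units, t] = 1
        cat = extract_avalanches(Raster(data=data))
        assert cat.sizes.tolist() == [4, 5]
        assert cat.durations.tolist() == [4, 4]

    def test_small_pattern_against_run_enumeration(self):
        # rows [1,1,0,1], [0,1,0,1] padded with empty edge bins; runs are
        # bins 1-2 (3 events) and bin 4 (2 events)
        data = np.array(
            [[0, 1, 1, 0, 1, 0], [0, 0, 1, 0, 1, 0]], dtype=np.uint8
        )
        cat = extract_avalanches(Raster(data=data))
        assert list(zip(cat.sizes.tolist(), cat.durations.tolist())) == [(3, 2), (2, 1)]

    def test_edge_touching_runs_are_discarded(self):
        data = np.array([[1, 1, 0, 1, 0, 1]], dtype=np.uint8)
        cat = extract_avalanches(Raster(data=data))
        assert cat.sizes.tolist() == [1]  # only the interior run survives

    def test_event_conservation(self, rng):
        counts = rng.poisson(0.7, size=5000)
        cat = extract_avalanches(counts)
        nz = counts > 0
        edges = 0
        if nz[0]:
            run_end = np.argmin(nz) if not nz.all() else counts.size
            edges += counts[:run_end].sum()
        if nz[-1]:
            run_start = counts.size - np.argmin(nz[::-1])
            edges += counts[run_start:].sum()
        assert cat.sizes.sum() == counts.sum() - edges

    def test_first_and_second_bin_counts(self):
        counts = np.array([0, 3, 2, 5, 0, 4, 0])
        cat = extract_avalanches(counts)
        assert cat.first_bin_counts.tolist() == [3, 4]
        assert cat.second_bin_counts.tolist() == [2, 0]


class TestFitPowerLaw:
    def test_recovers_zipf_exponent(self):
        # independent sampling oracle: scipy's zeta-distribution sampler
        x = spstats.zipf.rvs(1.6, size=100_000, random_state=7)
        fit = fit_power_law(x, n_boot=0)
        assert fit.exponent == pytest.approx(1.6, abs=0.03)
        assert fit.n_tail >= 10

    def test_degenerate_and_tiny_samples_fail(self):
        with pytest.raises(FitFailureError):
            fit_power_law(np.full(500, 7))
        with pytest.raises(FitFailureError):
            fit_power_law(np.arange(1, 6))

    def test_subsample_stability(self):
        x = spstats.zipf.rvs(1.8, size=40_000, random_state=11)
        full = fit_power_law(x, n_boot=60, seed=1)
        half = fit_power_law(x[::2], xmin=full.xmin, n_boot=60, seed=2)
        assert abs(half.exponent - full.exponent) < 3 * max(half.stderr, full.stderr)

    def test_truncated_window_restricts_tail(self):
        x = spstats.zipf.rvs(1.6, size=50_000, random_state=3)
        fit = fit_power_law(x, xmin=1, xmax=100, n_boot=0)
        assert fit.xmax == 100
        assert fit.exponent == pytest.approx(1.6, abs=0.05)

    def test_lsq_alternative_agrees_roughly(self):
        x = spstats.zipf.rvs(1.6, size=50_000, random_state=5)
        fit = fit_power_law(x, method="lsq")
        assert fit.method == "lsq"
        assert fit.exponent == pytest.approx(1.6, abs=0.15)


class TestGammaFit:
    def test_exact_power_relation(self):
        durations = np.repeat(np.arange(1, 101), 12)
        sizes = np.round(durations ** 1.5).astype(np.int64)
        g = fit_gamma(catalog_from(sizes, durations))
        assert g.gamma == pytest.approx(1.5, abs=0.01)

    def test_linear_relation_gives_unit_slope(self):
        durations = np.repeat(np.arange(1, 40), 15)
        g = fit_gamma(catalog_from(durations.copy(), durations))
        assert g.gamma == pytest.approx(1.0, abs=1e-10)

    def test_insufficient_durations_fail(self):
        cat = catalog_from([1, 2, 3, 4], [1, 1, 2, 2])
        with pytest.raises(FitFailureError):
            fit_gamma(cat)

    def test_duration_cutoff_at_system_size(self):
        durations = np.repeat(np.arange(1, 30), 20)
        sizes = (10.0 * durations).astype(np.int64)  # <S>(T) = 10 T
        cat = catalog_from(sizes, durations)
        assert duration_cutoff(cat, system_size=100) == 10


class TestScalingRelation:
    def test_reference_pairs(self):
        assert scaling_fraction(1.8, 1.6)[0] == pytest.approx(4.0 / 3.0)
        assert scaling_fraction(2.0, 2.0)[0] == 1.0
        assert scaling_fraction(1.84, 1.54)[0] == pytest.approx(1.5555, abs=1e-3)

    def test_identity_along_the_line(self):
        # fraction(gamma*(x-1)+1, x) == gamma for every x > 1
        for gamma in (1.2, 4.0 / 3.0, 1.7):
            for x in np.linspace(1.05, 3.0, 17):
                val, _ = scaling_fraction(gamma * (x - 1) + 1, x)
                assert val == pytest.approx(gamma, abs=1e-12)

    def test_undefined_at_unit_tau_s(self):
        with pytest.raises(InvalidArgumentError):
            scaling_fraction(1.5, 1.0)

    def test_error_propagation_first_order(self):
        val, err = scaling_fraction(1.8, 1.6, 0.06, 0.02)
        expected = np.hypot(0.06 / 0.6, (0.8 / 0.6) * 0.02 / 0.6)
        assert err == pytest.approx(expected, abs=1e-12)


class TestDcc:
    def _pair(self, tau_s, tau_t, gamma):
        fit_s = ExponentFit(exponent=tau_s, stderr=0.0, xmin=1, n_tail=100)
        fit_t = ExponentFit(exponent=tau_t, stderr=0.0, xmin=1, n_tail=100)
        return ExponentPair(tau_S=fit_s, tau_T=fit_t, gamma_fit=gamma, gamma_stderr=0.0)

    def test_zero_when_relation_holds(self):
        assert dcc(self._pair(2.0, 2.5, 1.5)) == pytest.approx(0.0)

    def test_reference_arithmetic(self):
        # |(1.84-1)/(1.54-1) - 1.54| and |(1.88-1)/(1.61-1) - 1.53|
        assert dcc(self._pair(1.54, 1.84, 1.54)) == pytest.approx(0.0156, abs=1e-3)
        assert dcc(self._pair(1.61, 1.88, 1.53)) == pytest.approx(0.0870, abs=1e-3)


def test_noise_concatenation_lowers_size_exponent():
    # catalogs simulated with stronger spontaneous drive cannot show a
    # larger fitted size exponent (avalanche merging fattens the tail)
    from quasicrit.cbm import CBMConfig, simulate_counts

    taus = []
    for p_s in (1e-3, 1e-2):
        cfg = CBMConfig(kappa=0.9, bias=0.6, p_s=p_s, seed=31, n_steps=300_000)
        counts = simulate_counts(cfg)
        fit = fit_power_law(extract_avalanches(counts).sizes, xmin=1, n_boot=0)
        taus.append(fit.exponent)
    assert taus[1] <= taus[0]
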