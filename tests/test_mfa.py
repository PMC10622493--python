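"""Box-counting estimator against closed-form cascade oracles."""

import numpy as np
import pytest

import mfspec as m
from mfspec.mfa import (
    MfaError,
    _moment_curves,
    box_probabilities,
    make_box_sizes,
    partition_moments,
    scale_series,
)
from conftest import BINOMIAL_W, DYADIC_CFG, MULTINOMIAL_W


class TestBoxSizes:
    def test_paper_defaults_on_trace_canvas(self):
        sizes = make_box_sizes((128, 1024), m.MfaConfig())
        assert sizes[0] == 10 and sizes[-1] == 76  # floor(0.60 * 128)
        assert np.all(np.diff(sizes) > 0)
        assert sizes.size <= 100

    def test_geometric_three_sizes(self):
        sizes = make_box_sizes((40, 40), m.MfaConfig(n_sizes=3, max_image_frac=1.0))
        assert sizes.tolist() == [10, 20, 40]

    def test_infeasible_range_rejected(self):
        with pytest.raises(MfaError):
            make_box_sizes((12, 12), m.MfaConfig())  # 0.6*12 < 10


class TestBoxProbabilities:
    def test_uniform_four_boxes(self):
        field = m.MassField(np.ones((4, 4)))
        P = box_probabilities(field, 2)
        np.testing.assert_allclose(sorted(P), [0.25] * 4)
        np.testing.assert_allclose(box_probabilities(field, 4), [1.0])

    def test_cascade_dyadic_aggregation_matches_construction(self):
        """Boxes of size 2^k hold exactly the cascade's level-(n-k) masses."""
        spec = m.CascadeSpec(BINOMIAL_W, depth=6)
        field = m.binomial_measure_1d(spec)
        for k in (1, 2, 3):
            P = box_probabilities(field, 2**k)
            expect = m.binomial_measure_1d(
                m.CascadeSpec(BINOMIAL_W, depth=6 - k)
            ).mass
            np.testing.assert_allclose(np.sort(P), np.sort(expect), atol=1e-12)

    def test_partial_boxes_kept_or_dropped(self):
        field = m.MassField(np.ones(10))
        assert box_probabilities(field, 4).size == 3      # 4+4+2
        assert box_probabilities(field, 4, include_partial=False).size == 2

    def test_origin_shifts_grid(self):
        field = m.MassField(np.ones(8))
        P = box_probabilities(field, 4, origin=2)  # 2+4+2 cells
        np.testing.assert_allclose(sorted(P), [0.25, 0.25, 0.5])


class TestPartitionMoments:
    @pytest.mark.parametrize(
        "P,q,z_expected",
        [
            ([0.25, 0.25, 0.25, 0.25], 2.0, 0.25),
            ([0.1, 0.4, 0.5], 0.0, 3.0),          # Z at q=0 counts boxes
            ([0.625, 0.375], 2.0, 0.53125),
        ],
    )
    def test_z_values(self, P, q, z_expected):
        Z, _, _ = partition_moments(np.asarray(P), q)
        assert Z == pytest.approx(z_expected, abs=1e-12)

    def test_mu_normalization_via_identity(self):
        P = np.array([0.625, 0.375])
        Z, s_num, s_den = partition_moments(P, 3.0)
        mu = P**3 / Z
        assert mu.sum() == pytest.approx(1.0, abs=1e-12)
        assert s_den == pytest.approx(float(mu @ np.log(mu)), abs=1e-12)

    def test_extreme_q_stays_finite(self):
        # P as small as one pixel in a large image, |q| = 20
        P = np.array([1e-6, 1 - 1e-6])
        for q in (-20.0, 20.0):
            Z, s_num, s_den = partition_moments(P, q)
            assert np.isfinite([Z, s_num, s_den]).all()


class TestMassExponents:
    def test_uniform_plane_tau(self, uniform_2d_spectrum):
        ms = uniform_2d_spectrum
        assert ms.at('tau', 2.0) == pytest.approx(2.0, abs=1e-9)
        assert ms.at('tau', 0.0) == pytest.approx(-2.0, abs=1e-9)

    def test_binomial_tau_matches_closed_form(self, binomial_spectrum):
        ms = binomial_spectrum
        assert ms.at('tau', 2.0) == pytest.approx(
            m.theory_tau(BINOMIAL_W, 2.0), abs=1e-6
        )
        assert ms.at('tau', 0.0) == pytest.approx(-1.0, abs=1e-9)

    def test_degenerate_scales_rejected(self, binomial_field):
        sizes = np.array([4, 8, 16])
        series = scale_series(binomial_field, sizes)
        series.sizes = np.array([8, 8, 8])  # force equal scales
        with pytest.raises(MfaError):
            m.mass_exponents([series], m.MfaConfig())


class TestGeneralizedDimensions:
    def test_uniform_plane_flat_at_two(self, uniform_2d_spectrum):
        np.testing.assert_allclose(uniform_2d_spectrum.d, 2.0, atol=1e-9)

    def test_binomial_information_dimension(self, binomial_spectrum):
        d1_theory = m.theory_dimension(BINOMIAL_W, 1.0)  # 0.81128 binary entropy
        assert binomial_spectrum.d1 == pytest.approx(d1_theory, abs=1e-6)

    def test_symmetric_cascade_collapses_to_line(self):
        field = m.binomial_measure_1d(m.CascadeSpec((0.5, 0.5), depth=12))
        ms = m.analyze(field, DYADIC_CFG)
        np.testing.assert_allclose(ms.d, 1.0, atol=1e-9)
        assert ms.delta_alpha <= 1e-9

    def test_q1_continuity(self, binomial_spectrum):
        """The entropy-limit D(1) interpolates its tau-ratio neighbours."""
        ms = binomial_spectrum
        i = np.argmin(np.abs(ms.q - 1.0))
        assert ms.d[i - 1] + 1e-9 >= ms.d[i] >= ms.d[i + 1] - 1e-9
        # and each matches the closed form at its own grid point
        for j in (i - 1, i, i + 1):
            assert ms.d[j] == pytest.approx(
                m.theory_dimension(BINOMIAL_W, ms.q[j]), abs=1e-6
            )


class TestChhabraJensen:
    def test_uniform_plane(self, uniform_2d_spectrum):
        ms = uniform_2d_spectrum
        np.testing.assert_allclose(ms.alpha, 2.0, atol=1e-9)
        np.testing.assert_allclose(ms.f, 2.0, atol=1e-9)

    def test_binomial_alpha_limits(self, binomial_spectrum):
        ms = binomial_spectrum
        # q -> +10 approaches -log2(max w); q -> -10 approaches -log2(min w)
        assert ms.at('alpha', 10.0) == pytest.approx(-np.log2(0.75), abs=1e-3)
        assert ms.at('alpha', -10.0) == pytest.approx(-np.log2(0.25), abs=1e-3)

    def test_matches_theory_across_grid(self, binomial_spectrum):
        ms = binomial_spectrum
        alpha_t, f_t = m.theory_alpha_f(BINOMIAL_W, ms.q)
        np.testing.assert_allclose(ms.alpha, alpha_t, atol=1e-6)
        np.testing.assert_allclose(ms.f, f_t, atol=1e-6)


class TestLegendre:
    def test_linear_tau_gives_point_spectrum(self):
        q = np.arange(-10, 10.25, 0.25)
        alpha, f = m.legendre_spectrum(2.0 * (q - 1.0), q)
        np.testing.assert_allclose(alpha, 2.0, atol=1e-12)
        np.testing.assert_allclose(f, 2.0, atol=1e-12)

    def test_analytic_tau_recovers_theory_alpha_f(self):
        q = np.arange(-5, 5.25, 0.25)
        tau = m.theory_tau(BINOMIAL_W, q)
        alpha, f = m.legendre_spectrum(tau, q)
        alpha_t, f_t = m.theory_alpha_f(BINOMIAL_W, q)
        # central differences: O(q_step^2) away from the ends
        np.testing.assert_allclose(alpha[1:-1], alpha_t[1:-1], atol=0.02)
        np.testing.assert_allclose(f[1:-1], f_t[1:-1], atol=0.02)

    def test_f_at_q0_equals_d0(self, binomial_spectrum):
        ms = binomial_spectrum
        assert ms.at('f_leg', 0.0) == pytest.approx(ms.d0, abs=1e-6)


class TestAnalyze:
    def test_image_to_mass_field_counts(self):
        img = m.BinaryImage(np.ones((4, 4), dtype=np.uint8))
        assert m.image_to_mass_field(img).total_mass == 16
        one = np.zeros((4, 4), dtype=np.uint8)
        one[2, 2] = 1
        assert m.image_to_mass_field(m.BinaryImage(one)).total_mass == 1

    def test_trace_dimension_between_line_and_plane(self, cell_spectrum):
        ms = m.analyze(m.spectrum_to_binary(cell_spectrum))
        assert 1.0 <= ms.d0 <= 2.0

    def test_multinomial_entropy_dimension(self, multinomial_spectrum):
        ms = multinomial_spectrum
        assert ms.d0 == pytest.approx(2.0, abs=1e-6)
        assert ms.d1 == pytest.approx(m.theory_dimension(MULTINOMIAL_W, 1.0), abs=1e-6)

    def test_grid_origin_averaging_is_seeded(self, binomial_field):
        cfg = m.MfaConfig(dyadic_sizes=True, min_box_px=2, n_grid_origins=3, seed=9)
        a = m.analyze(binomial_field, cfg)
        b = m.analyze(binomial_field, cfg)
        np.testing.assert_array_equal(a.tau, b.tau)
        c = m.analyze(binomial_field, m.with_options(cfg, seed=10))
        assert not np.array_equal(a.tau, c.tau)

    def test_determinism_bitwise(self, cell_spectrum):
        img = m.spectrum_to_binary(cell_spectrum)
        a, b = m.analyze(img), m.analyze(img)
        for name in ("tau", "d", "alpha", "f"):
            np.testing.assert_array_equal(getattr(a, name), getattr(b, name))

    def test_shuffled_cascade_same_spectrum(self):
        det = m.analyze(
            m.binomial_measure_1d(m.CascadeSpec(BINOMIAL_W, 11)), DYADIC_CFG
        )
        shuf = m.analyze(
            m.binomial_measure_1d(m.CascadeSpec(BINOMIAL_W, 11, shuffle=True, seed=4)),
            DYADIC_CFG,
        )
        sl = np.abs(det.q) <= 5
        np.testing.assert_allclose(det.d[sl], shuf.d[sl], atol=0.05)
        np.testing.assert_allclose(det.alpha[sl], shuf.alpha[sl], atol=0.05)

    def test_summary_serialization(self, binomial_spectrum):
        df = binomial_spectrum.to_frame()
        assert list(df.columns) == [
            "q", "tau", "d", "alpha", "f", "r2_tau", "r2_alpha", "r2_f"
        ]
        summ = binomial_spectrum.summary_dict()
        assert summ["d0"] == pytest.approx(1.0, abs=1e-9)
        assert isinstance(summ["config_hash"], str)


def test_moment_identity_logz_from_snum_sden(binomial_field):
    """ln Z = q*S_num - S_den holds at every scale and order."""
    sizes = make_box_sizes(binomial_field.dims, DYADIC_CFG)
    series = scale_series(binomial_field, sizes)
    q = np.array([-3.0, 0.5, 2.5])
    logZ, s_num, s_den = _moment_curves([series], q)
    np.testing.assert_allclose(logZ, q[None, :] * s_num - s_den, atol=1e-9)
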