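import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import fretpg as f
from fretpg.errors import AlignmentError, CollinearityError, DegenerateReferenceError
from fretpg.unmixing import ChannelBasis, ReferenceBasis

from conftest import basis_from_spectra, mix_spectrum


def gaussian_spectrum(sample_id, exc, grid_start, grid_stop, center, width, amp, base=0.0,
                      role="fret_sample"):
    wl = np.arange(grid_start, grid_stop + 1.0)
    y = base + amp * np.exp(-0.5 * ((wl - center) / width) ** 2)
    return f.EmissionSpectrum(sample_id, exc, wl, y, role=role)


class TestBufferSubtraction:
    def test_self_subtraction_is_zero(self):
        s = gaussian_spectrum("s", 541, 550, 700, 600, 20, 5.0, base=2.0)
        out = f.subtract_buffer(s, s)
        np.testing.assert_array_equal(out.intensities, 0.0)

    def test_recovers_added_band_exactly(self):
        buf = gaussian_spectrum("buffer", 541, 550, 700, 0, 1, 0.0, base=3.0, role="buffer")
        band = 7.0 * np.exp(-0.5 * ((buf.wavelengths - 610) / 15) ** 2)
        sample = buf.with_intensities(buf.intensities + band)
        out = f.subtract_buffer(sample, buf)
        np.testing.assert_allclose(out.intensities, band, atol=1e-12)

    def test_grid_mismatch_raises(self):
        a = gaussian_spectrum("a", 541, 550, 700, 600, 20, 1.0)
        b = gaussian_spectrum("b", 541, 560, 710, 600, 20, 1.0, role="buffer")
        with pytest.raises(AlignmentError):
            f.subtract_buffer(a, b)

    def test_channel_mismatch_raises(self):
        a = gaussian_spectrum("a", 541, 600, 700, 640, 20, 1.0)
        b = gaussian_spectrum("b", 587, 600, 700, 640, 20, 1.0)
        with pytest.raises(AlignmentError):
            f.subtract_background_reference(a, b)

    def test_excess_negativity_flagged(self):
        buf = gaussian_spectrum("buffer", 541, 550, 700, 0, 1, 0.0, base=5.0, role="buffer")
        sample = buf.with_intensities(buf.intensities - 1.0)
        out = f.subtract_buffer(sample, buf)
        assert "qc_negative_fraction" in out.meta


class TestBasisConstruction:
    def test_recovered_shapes_match_generator(self, clean_cfg, clean_basis):
        from fretpg.synthetic import emission_shape

        dch = clean_basis.donor_channel
        for name, model in (("donor", clean_cfg.donor), ("acceptor", clean_cfg.acceptor)):
            col = dch.matrix[:, dch.component_names.index(name)]
            truth = emission_shape(model, dch.grid)
            cos = col @ truth / (np.linalg.norm(col) * np.linalg.norm(truth))
            assert cos > 0.999

    def test_crosstalk_rho_matches_excitation_ratio(self, clean_cfg, clean_basis):
        # generator amplitudes are expressed on the same unit-norm shapes the
        # analyzer fits, so at zero noise rho is exactly the excitation ratio
        ratio = clean_cfg.acceptor.excitation(541.0) / clean_cfg.acceptor.excitation(587.0)
        np.testing.assert_allclose(clean_basis.crosstalk_rho, ratio, rtol=1e-9)

    def test_identical_acceptor_reference_in_both_channels_gives_rho_one(self):
        spectra = []
        for exc in (521.0, 531.0):
            wl = np.arange(540.0, 701.0)
            flat = np.full(wl.size, 2.0)
            bg = 50.0 * np.exp(-(wl - wl[0]) / 60.0)
            acc = 300.0 * np.exp(-0.5 * ((wl - 610) / 20) ** 2)
            don = 300.0 * np.exp(-0.5 * ((wl - 560) / 12) ** 2)
            spectra += [
                f.EmissionSpectrum("buffer", exc, wl, flat, role="buffer"),
                f.EmissionSpectrum("empty", exc, wl, flat + bg, role="empty_cell"),
                f.EmissionSpectrum("aref", exc, wl, flat + bg + acc, role="acceptor_ref"),
            ]
            if exc == 521.0:
                spectra.append(
                    f.EmissionSpectrum("dref", exc, wl, flat + bg + don, role="donor_ref")
                )
        basis = basis_from_spectra(spectra)
        np.testing.assert_allclose(basis.crosstalk_rho, 1.0, rtol=1e-9)

    def test_acceptor_reference_without_donor_channel_signal_is_degenerate(self, clean_cfg):
        panel = f.simulate_panel([("tandem", {})], clean_cfg)
        spectra = []
        for s in panel.spectra:
            if s.role == "acceptor_ref" and s.excitation_nm == 541.0:
                empty = next(
                    e for e in panel.spectra
                    if e.role == "empty_cell" and e.excitation_nm == 541.0
                )
                s = s.with_intensities(empty.intensities)
            spectra.append(s)
        with pytest.raises(DegenerateReferenceError):
            basis_from_spectra(spectra)

    def test_empty_cell_equal_to_reference_is_degenerate(self, clean_cfg):
        panel = f.simulate_panel([("tandem", {})], clean_cfg)
        spectra = [
            s.with_intensities(
                next(
                    e for e in panel.spectra
                    if e.role == "empty_cell" and e.excitation_nm == s.excitation_nm
                ).intensities
            )
            if s.role == "donor_ref"
            else s
            for s in panel.spectra
        ]
        with pytest.raises(DegenerateReferenceError):
            basis_from_spectra(spectra)


class TestUnmixing:
    def test_exact_recovery_of_constructed_mixture(self, clean_basis):
        s = mix_spectrum(clean_basis, 541.0, [2.0, 3.0, 1.5])
        res = f.unmix_spectrum(s, clean_basis)
        np.testing.assert_allclose(
            [res.amplitudes[k] for k in ("background", "donor", "acceptor")],
            [2.0, 3.0, 1.5],
            rtol=1e-9,
        )
        assert res.r_squared > 1.0 - 1e-12

    def test_pure_negative_component_hits_constraint(self, clean_basis):
        ch = clean_basis.channel(541.0)
        y = -1.0 * ch.matrix[:, ch.component_names.index("donor")]
        s = f.EmissionSpectrum("neg", 541.0, ch.grid, y)
        res = f.unmix_spectrum(s, clean_basis)
        assert res.amplitudes["donor"] == 0.0
        assert np.max(np.abs(res.residuals)) > 0.1
        assert np.isfinite(res.r_squared)

    def test_matches_unconstrained_least_squares_when_oracle_nonnegative(self, clean_basis):
        rng = np.random.default_rng(42)
        ch = clean_basis.channel(541.0)
        checked = 0
        for _ in range(200):
            truth = rng.uniform(0.5, 5.0, 3)
            y = ch.matrix @ truth
            y = y + rng.normal(0.0, 0.01 * y.max(), y.size)
            oracle, *_ = np.linalg.lstsq(ch.matrix, y, rcond=None)
            s = f.EmissionSpectrum("m", 541.0, ch.grid, y)
            res = f.unmix_spectrum(s, clean_basis)
            fitted = np.array([res.amplitudes[k] for k in ch.component_names])
            if np.all(oracle >= 0):
                np.testing.assert_allclose(fitted, oracle, rtol=1e-8)
                checked += 1
        assert checked > 150  # the oracle should be interior almost always here

    def test_amplitude_estimates_near_truth_under_noise(self, clean_basis):
        rng = np.random.default_rng(7)
        ch = clean_basis.channel(541.0)
        errors = []
        for _ in range(200):
            truth = rng.uniform(0.5, 5.0, 3)
            y = ch.matrix @ truth
            sigma = 0.01 * y.max()
            y = y + rng.normal(0.0, sigma, y.size)
            res = f.unmix_spectrum(f.EmissionSpectrum("m", 541.0, ch.grid, y), clean_basis)
            fitted = np.array([res.amplitudes[k] for k in ch.component_names])
            cov = sigma**2 * np.linalg.inv(ch.matrix.T @ ch.matrix)
            errors.append((fitted - truth) / np.sqrt(np.diag(cov)))
        # pooled standardized errors: |mean error| within 3 pooled SEs of zero
        z = np.array(errors)
        assert np.all(np.abs(z.mean(axis=0)) < 3.0 / np.sqrt(len(z)) * z.std(axis=0, ddof=1))

    @given(c=st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_equivariance(self, clean_basis, c):
        s = mix_spectrum(clean_basis, 541.0, [1.0, 2.0, 0.5])
        base = f.unmix_spectrum(s, clean_basis)
        scaled = f.unmix_spectrum(s.with_intensities(c * s.intensities), clean_basis)
        for k in base.amplitudes:
            np.testing.assert_allclose(scaled.amplitudes[k], c * base.amplitudes[k], rtol=1e-8)

    def test_collinear_basis_rejected(self, clean_basis):
        ch = clean_basis.channel(541.0)
        col = ch.matrix[:, 1]
        bad = ChannelBasis(
            excitation_nm=541.0,
            grid=ch.grid,
            component_names=["background", "donor", "acceptor"],
            matrix=np.column_stack([ch.matrix[:, 0], col, col]),
        )
        basis = ReferenceBasis(
            donor_channel=bad,
            acceptor_channel=clean_basis.acceptor_channel,
            crosstalk_rho=1.0,
        )
        s = mix_spectrum(clean_basis, 541.0, [1.0, 1.0, 1.0])
        with pytest.raises(CollinearityError):
            f.unmix_spectrum(s, basis)
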