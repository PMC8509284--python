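"""Phantom geometry, heterogeneity mixture and calibration tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

from renalqmri import phantom as ph


class TestLabelMap:
    def test_structure(self):
        labels = ph.make_label_map((128, 128))
        counts = {c: (labels == c).sum() for c in (ph.CORTEX, ph.OSOM, ph.ISOM)}
        assert set(np.unique(labels)) == {0, 1, 2, 3}
        assert counts[ph.CORTEX] > counts[ph.OSOM] > 0
        assert all(n >= 100 for n in counts.values())
        # ISOM is the innermost band, cortex the outermost tissue band
        assert labels[64, 64] == ph.ISOM
        tissue_cols = np.flatnonzero(labels[64, :] > 0)
        assert labels[64, tissue_cols[0]] == ph.CORTEX
        # whole kidney is a single connected component
        _, n_comp = ndimage.label(labels > 0)
        assert n_comp == 1

    def test_composite_regions(self):
        labels = ph.make_label_map((128, 128))
        om = ph.region_mask(labels, "om")
        wk = ph.region_mask(labels, "whole_kidney")
        assert np.array_equal(om, (labels == ph.OSOM) | (labels == ph.ISOM))
        assert np.array_equal(wk, labels > 0)
        with pytest.raises(KeyError):
            ph.region_mask(labels, "medulla")

    @pytest.mark.parametrize(
        "geometry",
        [
            ph.EllipseGeometry(isom_outer_frac=0.0),  # zero-width ISOM
            ph.EllipseGeometry(osom_outer_frac=0.45, isom_outer_frac=0.45),  # zero-width OSOM
            ph.EllipseGeometry(osom_outer_frac=1.0),  # zero-width cortex
            ph.EllipseGeometry(semi_axes_frac=(0.0, 0.5)),
        ],
    )
    def test_degenerate_geometry_rejected(self, geometry):
        with pytest.raises(ValueError):
            ph.make_label_map((128, 128), geometry)

    def test_too_small_grid_rejected(self):
        with pytest.raises(ValueError):
            ph.make_label_map((32, 32))

    def test_deterministic(self):
        a = ph.make_label_map((128, 128))
        b = ph.make_label_map((128, 128))
        assert np.array_equal(a, b)

    @given(
        isom=st.floats(0.1, 0.6),
        osom=st.floats(0.65, 0.95),
        nx=st.integers(64, 160),
    )
    @settings(max_examples=20, deadline=None)
    def test_labels_exhaustive_and_exclusive(self, isom, osom, nx):
        geom = ph.EllipseGeometry(osom_outer_frac=osom, isom_outer_frac=isom)
        labels = ph.make_label_map((nx, nx), geom)
        assert labels.shape == (nx, nx)
        assert set(np.unique(labels)) <= {0, 1, 2, 3}
        # every voxel has exactly one code by construction; tissue present
        assert (labels > 0).sum() > 0


class TestHeterogeneityField:
    base = {1: 1.5, 2: 1.5, 3: 1.5}

    def test_degenerate_mixture_equals_base(self, label_map_128):
        settings_ = ph.Heterogeneity(enabled=True, adc_delta=0.0, within_patch_sd=0.0)
        fld = ph.make_heterogeneity_field(label_map_128, self.base, settings_, seed=3)
        tissue = label_map_128 > 0
        assert np.allclose(fld[tissue], 1.5)
        assert np.all(fld[~tissue] == 0)

    def test_requires_enabled_and_nonneg_delta(self, label_map_128):
        with pytest.raises(ValueError):
            ph.make_heterogeneity_field(label_map_128, self.base, ph.Heterogeneity(enabled=False), 0)
        with pytest.raises(ValueError):
            ph.make_heterogeneity_field(
                label_map_128, self.base, ph.Heterogeneity(enabled=True, adc_delta=-0.1), 0
            )

    def test_sd_converges_to_mixture_closed_form(self):
        # >= 1e5 tissue voxels: empirical SD within 1% of sqrt(delta^2+sigma^2)
        labels = np.full((350, 350), ph.CORTEX, dtype=np.int16)
        delta, sigma = 0.315, 0.10
        settings_ = ph.Heterogeneity(
            enabled=True, adc_delta=delta, within_patch_sd=sigma, patch_scale_vox=3.0
        )
        fld = ph.make_heterogeneity_field(labels, self.base, settings_, seed=11)
        sd = fld[labels > 0].std()
        assert sd == pytest.approx(np.hypot(delta, sigma), rel=0.01)


class TestMixtureClosedForms:
    def test_sd_and_delta_inversion(self):
        assert ph.mixture_sd(0.315, 0.10) == pytest.approx(0.330492, abs=1e-5)
        assert ph.calibrate_adc_delta(0.33, 0.10) == pytest.approx(0.314484, abs=1e-5)
        with pytest.raises(ValueError):
            ph.calibrate_adc_delta(0.09, 0.10)

    def test_iqr_well_separated(self):
        # strongly bimodal: quartiles sit at the class means, IQR -> 2*delta
        assert ph.mixture_iqr(0.315, 0.10) == pytest.approx(0.630, abs=1e-3)
        # Monte-Carlo cross-check (frozen from a 2e6-draw run: 0.6298)
        rng = np.random.default_rng(5)
        draws = rng.normal(rng.choice([-0.315, 0.315], 200_000), 0.10)
        assert np.subtract(*np.percentile(draws, [75, 25])) == pytest.approx(0.630, abs=0.01)

    def test_iqr_gaussian_limit(self):
        # delta = 0 reduces to the normal IQR, 1.349 sigma
        assert ph.mixture_iqr(0.0, 1.0) == pytest.approx(1.349, abs=1e-3)

    def test_joint_calibration(self):
        delta, sigma = ph.calibrate_mixture(0.33, 0.45)
        assert np.hypot(delta, sigma) == pytest.approx(0.33, abs=1e-9)
        assert ph.mixture_iqr(delta, sigma) == pytest.approx(0.45, abs=1e-6)
        assert delta == pytest.approx(0.1478, abs=2e-4)

    def test_joint_calibration_degenerates_to_gaussian(self):
        # a target IQR below 1.349*SD cannot be widened by a symmetric
        # mixture; the calibration falls back to a single Gaussian
        delta, sigma = ph.calibrate_mixture(0.32, 0.40)
        assert delta == 0.0 and sigma == 0.32

    def test_joint_calibration_unreachable(self):
        with pytest.raises(ValueError):
            ph.calibrate_mixture(0.1, 0.5)  # IQR beyond 2*SD


class TestMakePhantom:
    def test_control_truth_is_compartment_values(self, control_params):
        p = ph.make_phantom(control_params, (128, 128), seed=1)
        cortex = p.label_map == ph.CORTEX
        assert p.truth_t1[cortex].mean() == 1304.0
        assert np.all(p.truth_t1[cortex] == 1304.0)  # compartment purity
        assert np.all(p.truth_t2[p.label_map == ph.ISOM] == 54.0)
        assert np.all(p.truth_adc[~p.tissue_mask] == 0.0)
        # piecewise-constant: no dispersion beyond compartment differences
        assert np.unique(p.truth_adc[p.tissue_mask]).size <= 2

    def test_reproducible_and_seed_sensitive(self, control_params):
        a = ph.make_phantom(control_params, (128, 128), seed=7)
        b = ph.make_phantom(control_params, (128, 128), seed=7)
        assert all(
            np.array_equal(getattr(a, f), getattr(b, f))
            for f in ("label_map", "truth_t1", "truth_t2", "truth_adc")
        )
        het = ph.TissueParameterSet(
            group="allogenic", timepoint="w3",
            t1_ms=control_params.t1_ms, t2_ms=control_params.t2_ms,
            adc_um2_per_ms=control_params.adc_um2_per_ms,
            heterogeneity=ph.Heterogeneity(enabled=True, adc_delta=0.3, within_patch_sd=0.1),
        )
        c = ph.make_phantom(het, (128, 128), seed=7)
        d = ph.make_phantom(het, (128, 128), seed=8)
        assert not np.array_equal(c.truth_adc, d.truth_adc)

    def test_allograft_truth_sd_matches_calibration(self):
        from renalqmri.presets import tissue_parameters

        params = tissue_parameters("allogenic", "w3")
        design_sd = ph.mixture_sd(
            params.heterogeneity.adc_delta, params.heterogeneity.within_patch_sd
        )
        sds = [
            ph.make_phantom(params, (128, 128), seed=s).truth_adc[
                ph.make_label_map((128, 128)) > 0
            ].std()
            for s in range(3)
        ]
        assert np.mean(sds) == pytest.approx(design_sd, rel=0.02)
        # and the design target itself sits within 3% of the printed 0.33
        assert design_sd == pytest.approx(0.33, rel=0.03)

    def test_parameter_validation(self, control_params):
        bad = ph.TissueParameterSet(
            group="control", timepoint="none",
            t1_ms={1: 40.0, 2: 1283.0, 3: 1808.0},  # T1 < T2 in cortex
            t2_ms=control_params.t2_ms, adc_um2_per_ms=control_params.adc_um2_per_ms,
        )
        with pytest.raises(ValueError, match="T1"):
            bad.validate()
        het_on_control = ph.TissueParameterSet(
            group="control", timepoint="none",
            t1_ms=control_params.t1_ms, t2_ms=control_params.t2_ms,
            adc_um2_per_ms=control_params.adc_um2_per_ms,
            heterogeneity=ph.Heterogeneity(enabled=True),
        )
        with pytest.raises(ValueError, match="allogenic"):
            het_on_control.validate()
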