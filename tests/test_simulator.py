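"""Forward projection, FBP reconstruction and the real-domain emulator."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from pcdmd import phantom as ph
from pcdmd import simulator as sim
from pcdmd import spectral as sp
from pcdmd.calibration import extract_pairs


def _chord_oracle(geometry, center, radius):
    theta = np.arange(geometry.n_views) * np.pi / geometry.n_views
    s = (np.arange(geometry.detector_rows) - geometry.detector_rows // 2) * geometry.detector_pitch
    th, ss = np.meshgrid(theta, s, indexing="ij")
    d = np.abs(ss - (center[0] * np.cos(th) - center[1] * np.sin(th)))
    return 2.0 * np.sqrt(np.clip(radius**2 - d**2, 0.0, None))


class TestForwardProject:
    def test_open_beam_rays_give_zero_projections(self, spectrum, desk_grid, desk_geometry):
        """Rays missing the phantom log-transform to exactly zero, all bins."""
        phant = ph.PhantomSpec(base_radius=60.0, inserts=(), grid=desk_grid)
        sino = sim.forward_project(phant, spectrum, geometry=desk_geometry)
        edge = np.concatenate([sino.p[:, :, :8], sino.p[:, :, -8:]], axis=-1)
        assert np.abs(edge).max() < 1e-12

    def test_monochromatic_chord_law(self, mono60, desk_grid, desk_geometry):
        """Single-disk projections match mu * chord to 1e-9 (Beer-Lambert)."""
        spec, bins = mono60
        phant = ph.PhantomSpec(base_radius=80.0, grid=desk_grid)
        sino = sim.forward_project(phant, spec, bins, desk_geometry)
        expected = sp.lac("water", 0.0, 60.0) * _chord_oracle(desk_geometry, (0.0, 0.0), 80.0) / 10.0
        assert np.abs(sino.p[0] - expected).max() < 1e-9

    def test_multi_disk_chord_law(self, mono60, desk_grid, desk_geometry):
        spec, bins = mono60
        ins = ph.InsertSpec("calcium", 500.0, (25.0, -18.0), 12.0)
        phant = ph.PhantomSpec(base_radius=80.0, inserts=(ins,), grid=desk_grid)
        sino = sim.forward_project(phant, spec, bins, desk_geometry)
        mu_w = sp.lac("water", 0.0, 60.0)
        mu_sol = sp.load_material_table("calcium")(60.0) * 0.5
        expected = (
            mu_w * _chord_oracle(desk_geometry, (0.0, 0.0), 80.0)
            + mu_sol * _chord_oracle(desk_geometry, ins.center, ins.radius)
        ) / 10.0
        assert np.abs(sino.p[0] - expected).max() < 1e-9

    def test_beam_hardening_reduces_central_log_transform(self, spectrum, desk_grid, desk_geometry):
        """Polychromatic p along the central ray is below thickness x effective LAC."""
        phant = ph.PhantomSpec(base_radius=100.0, grid=desk_grid)
        sino = sim.forward_project(phant, spectrum, geometry=desk_geometry)
        j = desk_geometry.detector_rows // 2  # central detector: full diameter chord
        eff = sp.effective_bin_lac(spectrum, 0, "water", 0.0)
        assert np.all(sino.p[0][:, j] < 20.0 * eff)

    def test_seeded_noise_reproducible(self, spectrum, desk_grid, desk_geometry):
        phant = ph.sample_phantom(5, grid=desk_grid)
        a = sim.forward_project(phant, spectrum, geometry=desk_geometry, flux=1e5, rng_seed=11)
        b = sim.forward_project(phant, spectrum, geometry=desk_geometry, flux=1e5, rng_seed=11)
        assert np.array_equal(a.p, b.p)

    def test_nonpositive_flux_rejected(self, spectrum, desk_grid, desk_geometry):
        with pytest.raises(ValueError):
            sim.forward_project(
                ph.PhantomSpec(grid=desk_grid), spectrum, geometry=desk_geometry, flux=0.0
            )


class TestFbpReconstruct:
    def test_water_disk_recovers_effective_lac(self, spectrum):
        """Noiseless FBP of a small water disk lands within 3% of the per-bin
        effective LAC in a central ROI (beam hardening bounds the bias)."""
        grid = ph.ImageGrid(128, 100.0 / 128)
        geo = sim.Geometry(fov=100.0, n_views=120, detector_rows=128)
        phant = ph.PhantomSpec(base_radius=30.0, grid=grid)
        img = sim.fbp_reconstruct(sim.forward_project(phant, spectrum, geometry=geo), geo, "ramp")
        c = (np.arange(128) - 64) * grid.pitch_mm
        xx, yy = np.meshgrid(c, c)
        roi = xx**2 + yy**2 <= 15.0**2
        for b in range(3):
            eff = sp.effective_bin_lac(spectrum, b, "water", 0.0)
            assert abs(img.data[b][roi].mean() / eff - 1) < 0.03

    def test_zero_sinogram_gives_zero_image(self, desk_geometry):
        sino = sim.BinnedSinogram(
            p=np.zeros((3, 60, 64)), flux_per_bin=np.full(3, np.inf),
            geometry=desk_geometry, bin_set=sp.EnergyBinSet.default(),
        )
        img = sim.fbp_reconstruct(sino, desk_geometry)
        assert np.allclose(img.data, 0.0)

    def test_linearity(self, mono60, desk_grid, desk_geometry):
        """FBP of a sum of sinograms equals the sum of FBPs (noiseless)."""
        spec, bins = mono60
        s1 = sim.forward_project(ph.PhantomSpec(base_radius=60.0, grid=desk_grid), spec, bins, desk_geometry)
        s2 = sim.forward_project(ph.PhantomSpec(base_radius=90.0, grid=desk_grid), spec, bins, desk_geometry)
        from dataclasses import replace

        s12 = replace(s1, p=s1.p + s2.p)
        a = sim.fbp_reconstruct(s12, desk_geometry).data
        b = sim.fbp_reconstruct(s1, desk_geometry).data + sim.fbp_reconstruct(s2, desk_geometry).data
        assert np.abs(a - b).max() < 1e-10

    def test_shape_mismatch_rejected(self, desk_geometry):
        sino = sim.BinnedSinogram(
            p=np.zeros((3, 60, 64)), flux_per_bin=np.full(3, np.inf),
            geometry=desk_geometry, bin_set=sp.EnergyBinSet.default(),
        )
        with pytest.raises(ValueError):
            sim.fbp_reconstruct(sino, sim.Geometry.desk(128, 60))

    def test_unknown_filter_rejected(self, desk_geometry):
        sino = sim.BinnedSinogram(
            p=np.zeros((3, 60, 64)), flux_per_bin=np.full(3, np.inf),
            geometry=desk_geometry, bin_set=sp.EnergyBinSet.default(),
        )
        with pytest.raises(ValueError):
            sim.fbp_reconstruct(sino, desk_geometry, filter_name="shepp")


class TestSimulateScan:
    def test_roi_means_rank_with_concentration(self, spectrum, desk_grid, desk_geometry):
        """Insert ROI means preserve the concentration ordering in every bin."""
        phant = ph.PhantomSpec(
            base_radius=100.0,
            inserts=(
                ph.InsertSpec("calcium", 100.0, (-50.0, 0.0), 15.0),
                ph.InsertSpec("calcium", 300.0, (50.0, 0.0), 15.0),
            ),
            grid=desk_grid,
        )
        img, _ = sim.simulate_scan(phant, spectrum, geometry=desk_geometry, flux=np.inf)
        pairs = extract_pairs(img, img, phant)
        for b in range(3):
            by_bin = sorted((p for p in pairs if p.bin_index == b), key=lambda p: p.concentration)
            assert by_bin[0].lac_sim < by_bin[1].lac_sim

    def test_iodine_contrast_largest_in_bin1(self, spectrum, desk_grid, desk_geometry):
        phant = ph.PhantomSpec(
            base_radius=100.0,
            inserts=(ph.InsertSpec("iodine", 15.0, (40.0, 0.0), 15.0),),
            grid=desk_grid,
        )
        img, lab = sim.simulate_scan(phant, spectrum, geometry=desk_geometry, flux=np.inf)
        contrast = [img.data[b][lab == 3].mean() - img.data[b][lab == 1].mean() for b in range(3)]
        assert contrast[0] > contrast[1] > contrast[2]

    def test_scan_determinism(self, spectrum, desk_grid, desk_geometry):
        phant = ph.sample_phantom(9, grid=desk_grid)
        a, la = sim.simulate_scan(phant, spectrum, geometry=desk_geometry, flux=1e5, rng_seed=3)
        b, lb = sim.simulate_scan(phant, spectrum, geometry=desk_geometry, flux=1e5, rng_seed=3)
        assert np.array_equal(a.data, b.data) and np.array_equal(la, lb)

    def test_noise_decreases_with_flux(self, spectrum, desk_grid, desk_geometry):
        """ROI standard deviation is strictly decreasing along a flux ladder."""
        phant = ph.PhantomSpec(base_radius=100.0, grid=desk_grid)
        fluxes = [1e3, 1e4, 1e5, 1e6]
        sds = []
        for k, f in enumerate(fluxes):
            img, lab = sim.simulate_scan(phant, spectrum, geometry=desk_geometry, flux=f, rng_seed=k)
            sds.append(img.data[0][lab == 1].std())
        rho, _ = spearmanr(fluxes, sds)
        assert rho == -1.0

    def test_insert_alignment_with_labels(self, spectrum, desk_grid, desk_geometry):
        """Reconstructed insert contrast sits exactly on the labelled pixels."""
        phant = ph.PhantomSpec(
            base_radius=100.0,
            inserts=(ph.InsertSpec("calcium", 500.0, (40.0, 15.0), 14.0),),
            grid=desk_grid,
        )
        img, lab = sim.simulate_scan(phant, spectrum, geometry=desk_geometry, flux=np.inf)
        assert img.data[0][lab == 2].mean() > 1.5 * img.data[0][lab == 1].mean()


class TestGeometry:
    def test_full_protocol_detector(self):
        geo = sim.Geometry.full_protocol()
        assert geo.detector.modules == 48
        assert geo.detector.row_pixels == 3840
        assert geo.n_views == 1440
        assert geo.source_to_isocenter == 227.5
        assert geo.fov == 250.0

    def test_fan_requires_clearance(self):
        with pytest.raises(ValueError):
            sim.Geometry(mode="fan", source_to_isocenter=100.0, fov=250.0)

    def test_fan_reconstruction_smoke(self, mono60):
        """Fan-beam rebinning reconstructs a centred water disk value."""
        spec, bins = mono60
        grid = ph.ImageGrid(64, 250.0 / 64)
        geo = sim.Geometry(mode="fan", n_views=240, detector_rows=64)
        phant = ph.PhantomSpec(base_radius=60.0, grid=grid)
        img = sim.fbp_reconstruct(sim.forward_project(phant, spec, bins, geo), geo, "ramp")
        center = img.data[0][28:37, 28:37].mean()
        assert abs(center / sp.lac("water", 0.0, 60.0) - 1) < 0.05


class TestEmulateRealDomain:
    def test_identity_gap(self, reference_scan):
        _, img, _ = reference_scan
        gap = sim.GapConfig(a=0.0, b=1.0, c=0.0, noise_sigma=0.0, ring_amplitude=0.0)
        out = sim.emulate_real_domain(img, gap, rng_seed=0)
        # a=0, c=0 wipes the signal; the identity-preserving zero gap is a+c=0 with b->0
        assert np.allclose(out.data, 0.0)
        gap2 = sim.GapConfig(a=-1e6, b=1e-6, c=1e6, noise_sigma=0.0)
        out2 = sim.emulate_real_domain(img, gap2, rng_seed=0)
        assert np.allclose(out2.data, img.data, atol=1e-4)

    def test_rank_order_preserved(self, reference_scan):
        """The default monotone gap keeps concentration ordering of ROI means."""
        spec, img, _ = reference_scan
        real = sim.emulate_real_domain(img, sim.GapConfig(noise_sigma=0.0), rng_seed=0)
        pairs = extract_pairs(img, real, spec)
        ca = sorted((p for p in pairs if p.material == "calcium" and p.bin_index == 0),
                    key=lambda p: p.concentration)
        assert ca[0].lac_real < ca[1].lac_real

    def test_domain_tag(self, reference_scan):
        _, img, _ = reference_scan
        out = sim.emulate_real_domain(img, rng_seed=0)
        assert out.domain == "real_emulated"
        with pytest.raises(ValueError):
            sim.emulate_real_domain(out, rng_seed=0)

    def test_ring_artifact_applied(self, reference_scan):
        _, img, _ = reference_scan
        gap = sim.GapConfig(noise_sigma=0.0, ring_amplitude=0.05)
        base = sim.emulate_real_domain(img, sim.GapConfig(noise_sigma=0.0), rng_seed=0)
        ringed = sim.emulate_real_domain(img, gap, rng_seed=0)
        assert not np.allclose(base.data, ringed.data)
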