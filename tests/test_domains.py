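"""2D density maps, the 2/3-max rule and domain classification."""

import numpy as np
import pytest

from memdomain.builder import default_box
from memdomain.domains import (
    dimer_center_xy,
    CODES,
    LD_CODES,
    LO_CODES,
    DensityMap2D,
    classify_domains,
    density_map,
    protein_centered_overlay,
    protein_domain_location,
)
from memdomain.synth import (
    DomainModel,
    InterfaceModel,
    Patch,
    SynthParams,
    generate_system,
)


def flat_map(value, shape=(8, 8), cls="CHOL"):
    return DensityMap2D(cls, np.full(shape, float(value)), (0.5, 0.5), (0.0, 100.0), 2, 1.0)


@pytest.fixture(scope="module")
def patched_system(small_spec):
    box = default_box(max(small_spec.leaflet_totals()))
    r = 0.3 * box[0]
    center = (0.35 * box[0], 0.35 * box[1])
    params = SynthParams(
        n_frames=200,
        frame_stride=10.0,
        seed=17,
        domains=DomainModel(patches=[Patch(center, r)]),
        dimer_placement="out-patch",
        interface=InterfaceModel(schedule=[(0.0, 2000.0, "nmr")]),
    )
    traj, truth = generate_system(params, small_spec)
    return traj, truth, r


class TestDensityMap:
    def test_conservation_invariant_is_exact(self, small_spec):
        params = SynthParams(
            n_frames=10, seed=3, interface=InterfaceModel(schedule=[(0.0, 500.0, "nmr")])
        )
        traj, _ = generate_system(params, small_spec)
        m = density_map(traj, "CHOL")
        cell_area = m.cell_size[0] * m.cell_size[1]
        # density * cell area * frames = binned bead count over the window
        assert m.density.sum() * cell_area * m.n_frames == pytest.approx(m.total_count)

    def test_all_beads_in_one_cell(self, make_topology, make_traj):
        top = make_topology([("CHOL", "outer")] * 5)
        coords = np.zeros((2, top.n_beads, 3))
        coords[:, :, :2] = 3.14
        traj = make_traj(top, coords, box=(8.0, 8.0, 10.0))
        m = density_map(traj, "CHOL", cell_size=1.0)
        h = m.density * (m.cell_size[0] * m.cell_size[1])
        assert h.max() == pytest.approx(5.0)  # 5 reference beads per frame
        assert np.count_nonzero(h) == 1

    def test_window_outside_span_rejected(self, make_topology, make_traj):
        top = make_topology([("CHOL", "outer")])
        traj = make_traj(top, np.zeros((3, top.n_beads, 3)) + 1)
        with pytest.raises(ValueError, match="window"):
            density_map(traj, "CHOL", window=(1e6, 2e6))


class TestEnrichmentRule:
    def test_uniform_map_is_fully_enriched(self):
        assert flat_map(2.0).enriched().all()

    def test_two_thirds_threshold_arithmetic(self):
        d = np.full((4, 4), 0.5)
        d[1, 2] = 1.0
        m = DensityMap2D("CHOL", d, (0.5, 0.5), (0.0, 1.0), 1, 1.0)
        mask = m.enriched()
        assert mask[1, 2]
        assert mask.sum() == 1  # 0.5 < 2/3 of the max

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        d = rng.uniform(size=(10, 10))
        m1 = DensityMap2D("poly", d, (0.5, 0.5), (0.0, 1.0), 1, 1.0)
        m2 = DensityMap2D("poly", 7.3 * d, (0.5, 0.5), (0.0, 1.0), 1, 1.0)
        np.testing.assert_array_equal(m1.enriched(), m2.enriched())


class TestClassification:
    def test_every_cell_gets_exactly_one_code(self):
        rng = np.random.default_rng(1)
        maps = [
            DensityMap2D(c, rng.uniform(size=(12, 12)), (0.5, 0.5), (0.0, 1.0), 1, 1.0)
            for c in ("CHOL", "satmono", "poly")
        ]
        cm = classify_domains(*maps)
        assert set(np.unique(cm.codes)) <= set(CODES.values())
        # partition: fractions over all codes sum to one
        total = sum(cm.area_fraction((c,)) for c in CODES.values())
        assert total == pytest.approx(1.0)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            classify_domains(flat_map(1.0, (8, 8)), flat_map(1.0, (9, 9)), flat_map(1.0, (8, 8)))

    def test_protein_mask_takes_precedence(self):
        chol, sat, poly = (flat_map(1.0, cls=c) for c in ("CHOL", "satmono", "poly"))
        prot = flat_map(0.0, cls="protein")
        prot.density[2, 2] = 1.0
        cm = classify_domains(chol, sat, poly, prot)
        assert cm.codes[2, 2] == CODES["protein"]
        assert cm.codes[0, 0] == CODES["all_mix"]

    def test_planted_disc_is_classified_lo_like(self, patched_system):
        traj, truth, r = patched_system
        maps = {
            c: density_map(traj, c, (0.0, 2000.0), cell_size=1.0)
            for c in ("CHOL", "satmono", "poly")
        }
        cm = classify_domains(maps["CHOL"], maps["satmono"], maps["poly"])
        box = traj.boxes[0, :2]
        center = truth.patch_centers.mean(axis=0)[0]
        nx, ny = cm.codes.shape
        xs = (np.arange(nx) + 0.5) * box[0] / nx
        ys = (np.arange(ny) + 0.5) * box[1] / ny
        X, Y = np.meshgrid(xs, ys, indexing="ij")
        dx = X - center[0]
        dx -= box[0] * np.round(dx / box[0])
        dy = Y - center[1]
        dy -= box[1] * np.round(dy / box[1])
        inside = dx**2 + dy**2 < (r - 1.0) ** 2
        lo = np.isin(cm.codes, LO_CODES)
        assert lo[inside].mean() >= 0.9


class TestProteinLocation:
    def test_out_patch_dimer_resides_in_ld(self, patched_system):
        traj, _, _ = patched_system
        loc = protein_domain_location(traj, window_ns=2000.0, cell_size=1.0)
        assert loc["ld_fraction"] == 1.0
        assert loc["lo_fraction"] == 0.0

    def test_in_patch_dimer_resides_in_lo(self, small_spec):
        box = default_box(max(small_spec.leaflet_totals()))
        r = 0.3 * box[0]
        params = SynthParams(
            n_frames=200,
            frame_stride=10.0,
            seed=19,
            domains=DomainModel(patches=[Patch((0.35 * box[0], 0.35 * box[1]), r)]),
            dimer_placement="in-patch",
            interface=InterfaceModel(schedule=[(0.0, 2000.0, "nmr")]),
        )
        traj, _ = generate_system(params, small_spec)
        loc = protein_domain_location(traj, window_ns=2000.0, cell_size=1.0)
        assert loc["lo_fraction"] == 1.0


class TestOverlay:
    def test_single_frame_overlay_equals_recentred_map(self, small_spec):
        params = SynthParams(
            n_frames=1, seed=5, interface=InterfaceModel(schedule=[(0.0, 50.0, "nmr")])
        )
        traj, truth = generate_system(params, small_spec)
        overlay = protein_centered_overlay([traj], window_ns=50.0, classes=("CHOL",))
        box = traj.boxes[0, :2]
        shift = box / 2.0 - dimer_center_xy(traj)
        direct = density_map(traj, "CHOL", shift=shift)
        np.testing.assert_allclose(overlay["CHOL"].density, direct.density)

    def test_translation_invariance(self, small_spec):
        params = SynthParams(
            n_frames=5, seed=6, interface=InterfaceModel(schedule=[(0.0, 250.0, "nmr")])
        )
        traj, _ = generate_system(params, small_spec)
        o1 = protein_centered_overlay([traj], window_ns=250.0, classes=("poly",))
        shifted = traj
        shifted.coords = traj.coords.copy()
        shifted.coords[:, :, 0] = np.mod(shifted.coords[:, :, 0] + 3.7, traj.boxes[0, 0])
        o2 = protein_centered_overlay([shifted], window_ns=250.0, classes=("poly",))
        np.testing.assert_allclose(o1["poly"].density, o2["poly"].density, atol=1e-9)

    def test_poly_preferring_dimer_enriches_centre(self, patched_system):
        traj, _, _ = patched_system
        overlay = protein_centered_overlay([traj], window_ns=2000.0, cell_size=1.0)
        d = overlay["poly"].density
        nx, ny = d.shape
        c = d[nx // 2 - 2 : nx // 2 + 2, ny // 2 - 2 : ny // 2 + 2].mean()
        assert c > d.mean()
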