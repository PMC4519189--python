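"""Hydration shells, binding runs and residue occupancy."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from memdomain.model_io import CompositionSpec
from memdomain.protein_lipid import (
    ShellDefinition,
    _max_run,
    max_binding_time,
    protein_lipid_rdf,
    residue_occupancy,
    shell_composition,
)
from memdomain.synth import InterfaceModel, SynthParams, generate_system


def distance_track_traj(make_topology, make_traj, distances, stride=0.5):
    """One lipid whose lateral distance to a point-like protein follows the
    given per-frame series."""
    top = make_topology([("PROTEIN", "none"), ("PROTEIN", "none"),
                         ("PC_16:0/18:2", "outer")])
    F = len(distances)
    coords = np.zeros((F, top.n_beads, 3))
    coords[:, :, :2] = 10.0  # protein beads all at (10, 10)
    lip = top.mol_start[2]
    for f, d in enumerate(distances):
        coords[f, lip : lip + 7, 0] = 10.0 + d
        coords[f, lip : lip + 7, 1] = 10.0
    return make_traj(top, coords, stride=stride, box=(20.0, 20.0, 10.0))


class TestShellDefinition:
    def test_orders_must_increase(self):
        with pytest.raises(ValueError):
            ShellDefinition(0.9, 0.6, 1.1)

    def test_defaults_are_the_rdf_minima(self):
        s = ShellDefinition()
        assert (s.r1, s.r2, s.r3) == (0.658, 0.918, 1.178)


class TestBinding:
    def test_hand_distance_series(self, make_topology, make_traj):
        """(0.5, 0.5, 0.7, 0.5) nm at 0.5 ns stride with cutoff 0.658:
        the longest bound run is two frames = 1.0 ns."""
        traj = distance_track_traj(make_topology, make_traj, [0.5, 0.5, 0.7, 0.5])
        rec = max_binding_time(traj, cutoff=0.658)
        assert rec.per_species["max_bound_ns"].iloc[0] == pytest.approx(1.0)

    def test_never_bound_is_zero(self, make_topology, make_traj):
        traj = distance_track_traj(make_topology, make_traj, [2.0, 3.0, 2.5])
        rec = max_binding_time(traj)
        assert rec.per_species["max_bound_ns"].iloc[0] == 0.0

    @given(st.lists(st.floats(0.1, 2.0), min_size=2, max_size=20))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_monotone_in_cutoff(self, distances):
        from conftest import build_topology, build_traj

        traj = distance_track_traj(build_topology, build_traj, distances)
        previous = -1.0
        for cutoff in (0.4, 0.658, 1.0, 2.5):
            v = max_binding_time(traj, cutoff=cutoff).per_species["max_bound_ns"].iloc[0]
            assert v >= previous
            previous = v

    def test_max_run_against_enumeration(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            mask = rng.uniform(size=25) < 0.5
            best = 0
            cur = 0
            for b in mask:
                cur = cur + 1 if b else 0
                best = max(best, cur)
            assert _max_run(mask) == best

    def test_planted_sticky_species_dominates(self, small_spec):
        params = SynthParams(
            n_frames=600,
            frame_stride=0.5,
            seed=21,
            sticky=("CHOL", 50.0, 150.0),
            interface=InterfaceModel(schedule=[(0.0, 300.0, "nmr")]),
        )
        traj, truth = generate_system(params, small_spec)
        rec = max_binding_time(traj)
        by = rec.per_species.set_index("species")["max_bound_ns"]
        assert by["CHOL"] == pytest.approx(150.0, abs=1.0)
        assert by["CHOL"] > 2 * by.drop("CHOL").max()


class TestShellComposition:
    def test_single_species_membrane_is_neutral(self, make_topology, make_traj):
        entries = [("PROTEIN", "none"), ("PROTEIN", "none")]
        entries += [("PC_16:0/18:2", "outer")] * 30
        top = make_topology(entries)
        rng = np.random.default_rng(2)
        coords = np.zeros((5, top.n_beads, 3))
        coords[:, :, :2] = 10.0
        for m in range(2, top.n_molecules):
            s, e = top.mol_start[m], top.mol_stop[m]
            xy = rng.uniform(0, 20.0, size=(5, 2))
            coords[:, s:e, 0] = xy[:, 0][:, None]
            coords[:, s:e, 1] = xy[:, 1][:, None]
        traj = make_traj(top, coords, box=(20.0, 20.0, 10.0))
        enr = shell_composition(traj)
        sub = enr.query("leaflet == 'outer' and species == 'PC_16:0/18:2'")
        filled = sub.dropna(subset=["ratio"])
        assert (filled["ratio"] == pytest.approx(1.0)).all()
        assert (filled["direction"] == "neutral").all()

    def test_shell_fractions_sum_to_one(self, small_spec):
        params = SynthParams(
            n_frames=30, seed=8, interface=InterfaceModel(schedule=[(0.0, 1500.0, "nmr")])
        )
        traj, _ = generate_system(params, small_spec)
        enr = shell_composition(traj)
        sums = enr.groupby(["leaflet", "shell"])["shell_fraction"].sum().dropna()
        np.testing.assert_allclose(sums, 1.0)

    def test_planted_halo_enriches_cholesterol_shell1(self, small_spec):
        params = SynthParams(
            n_frames=80,
            seed=9,
            chol_halo=(8, 1.5),
            interface=InterfaceModel(schedule=[(0.0, 4000.0, "nmr")]),
        )
        traj, _ = generate_system(params, small_spec)
        enr = shell_composition(traj)
        chol1 = enr.query("species == 'CHOL' and shell == 1")
        assert (chol1["ratio"] > 1.0).all()
        assert (chol1["direction"] == "increased").all()


class TestRDF:
    def test_empty_species_filter_rejected(self, small_spec):
        params = SynthParams(
            n_frames=5, seed=1, interface=InterfaceModel(schedule=[(0.0, 250.0, "nmr")])
        )
        traj, _ = generate_system(params, small_spec)
        with pytest.raises(ValueError, match="empty species"):
            protein_lipid_rdf(traj, species=[])

    def test_uniform_placement_gives_flat_g(self, small_spec):
        params = SynthParams(
            n_frames=120,
            seed=2,
            interface=InterfaceModel(schedule=[(0.0, 6000.0, "nmr")]),
        )
        traj, _ = generate_system(params, small_spec)
        rdf = protein_lipid_rdf(traj)
        sel = (rdf.r > 2.5) & (rdf.r < 0.45 * traj.boxes[0, 0])
        assert np.abs(rdf.g[sel].mean() - 1.0) < 0.1

    def test_planted_depletion_ring_minimum(self, make_topology, make_traj):
        """Lipids placed everywhere except an annulus around the protein:
        a local RDF minimum must be detected inside the ring."""
        entries = [("PROTEIN", "none"), ("PROTEIN", "none")]
        entries += [("PC_16:0/18:2", "outer")] * 150
        top = make_topology(entries)
        rng = np.random.default_rng(7)
        F = 30
        coords = np.zeros((F, top.n_beads, 3))
        center = np.array([10.0, 10.0])
        coords[:, :, :2] = center  # protein at the centre
        ring = (3.0, 4.0)
        for m in range(2, top.n_molecules):
            s, e = top.mol_start[m], top.mol_stop[m]
            for f in range(F):
                while True:
                    xy = rng.uniform(0, 20.0, size=2)
                    d = np.hypot(*(xy - center))
                    if not ring[0] < d < ring[1]:
                        break
                coords[f, s:e, 0] = xy[0]
                coords[f, s:e, 1] = xy[1]
        traj = make_traj(top, coords, box=(20.0, 20.0, 10.0))
        rdf = protein_lipid_rdf(traj, bin_width=0.1)
        assert any(ring[0] < m < ring[1] for m in rdf.minima)


class TestOccupancy:
    def test_absent_partner_is_zero(self, small_spec):
        params = SynthParams(
            n_frames=5, seed=3, interface=InterfaceModel(schedule=[(0.0, 250.0, "nmr")])
        )
        traj, _ = generate_system(params, small_spec)
        occ = residue_occupancy(traj, [5], ["PC_18:0/18:1"])
        assert occ[5] == 0.0

    def test_tethered_cholesterol_gives_full_occupancy(self):
        spec = CompositionSpec(rows=[("CHOL", 2, 2), ("PC_16:0/18:2", 10, 10)])
        params = SynthParams(
            n_frames=40,
            seed=4,
            box=(14.0, 14.0, 10.0),
            tether=(13, 1.0),
            interface=InterfaceModel(schedule=[(0.0, 2000.0, "nmr")]),
        )
        traj, truth = generate_system(params, spec)
        occ = residue_occupancy(traj, [13], ["CHOL"])
        assert occ[13] == 1.0

    def test_planted_95_percent_schedule(self):
        spec = CompositionSpec(rows=[("CHOL", 2, 2), ("PC_16:0/18:2", 10, 10)])
        params = SynthParams(
            n_frames=400,
            seed=6,
            box=(14.0, 14.0, 10.0),
            tether=(13, 0.95),
            interface=InterfaceModel(schedule=[(0.0, 20000.0, "nmr")]),
        )
        traj, truth = generate_system(params, spec)
        occ = residue_occupancy(traj, [13], ["CHOL"])
        assert occ[13] == pytest.approx(0.95, abs=0.02)

    def test_missing_sidechain_bead_rejected(self, small_spec):
        params = SynthParams(
            n_frames=3, seed=1, interface=InterfaceModel(schedule=[(0.0, 150.0, "nmr")])
        )
        traj, _ = generate_system(params, small_spec)
        with pytest.raises(ValueError, match="side-chain"):
            residue_occupancy(traj, [999], ["CHOL"])
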