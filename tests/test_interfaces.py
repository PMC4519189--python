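"""Contact maps, Dice clustering, condition comparison, interface survival."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import dice as scipy_dice

from memdomain.interfaces import (
    APART,
    ContactMap,
    cluster_interfaces,
    compare_conditions,
    contact_map,
    dice_dissimilarity,
    nmr_trace,
)
from memdomain.model_io import Frame, Topology


def protein_frame(offset_b=(2.4, 0.0, 0.0), box=(20.0, 20.0, 10.0), n_res=4):
    """Two minimal chains: every residue's beads sit on the backbone line."""
    top = Topology.from_molecules(
        [("PROTEIN", "none"), ("PROTEIN", "none")], n_res_protein=n_res
    )
    coords = np.zeros((top.n_beads, 3))
    for b in range(top.n_beads):
        res = top.bead_residue[b]
        base = np.array([0.0, 0.0, res * 1.0])
        if top.bead_chain[b] == "B":
            base = base + np.asarray(offset_b)
        coords[b] = base + 5.0
    return top, Frame(0.0, np.asarray(box), coords)


class TestContactMap:
    def test_close_residues_contact(self):
        top, frame = protein_frame(offset_b=(0.3, 0.0, 0.0))
        cm = contact_map(frame, top, cutoff=0.6)
        assert (0, 0) in cm.pairs
        assert (0, 1) not in cm.pairs  # residues 1 nm apart in z

    def test_dissociated_dimer_is_empty(self):
        top, frame = protein_frame(offset_b=(5.0, 0.0, 0.0))
        assert len(contact_map(frame, top, cutoff=0.6)) == 0

    def test_lateral_minimum_image(self):
        # chain B placed across the periodic boundary, 0.4 nm away
        top, frame = protein_frame(offset_b=(19.6, 0.0, 0.0))
        cm = contact_map(frame, top, cutoff=0.6)
        assert (0, 0) in cm.pairs

    def test_empty_chain_rejected(self):
        top = Topology.from_molecules([("PROTEIN", "none")])
        frame = Frame(0.0, np.ones(3), np.zeros((top.n_beads, 3)))
        with pytest.raises(ValueError, match="chain"):
            contact_map(frame, top)


class TestDice:
    def test_identical_nonempty_is_zero(self):
        s = frozenset({(1, 1), (2, 3)})
        assert dice_dissimilarity(s, s) == 0.0

    def test_disjoint_nonempty_is_one(self):
        assert dice_dissimilarity(frozenset({(1, 1)}), frozenset({(2, 2)})) == 1.0

    def test_hand_value_one_third(self):
        a = frozenset({(1, 1), (2, 2)})
        b = frozenset({(1, 1)})
        assert dice_dissimilarity(a, b) == pytest.approx(1 / 3)

    def test_both_empty_is_zero_by_convention(self):
        assert dice_dissimilarity(frozenset(), frozenset()) == 0.0

    @given(
        st.sets(st.integers(0, 9), max_size=8),
        st.sets(st.integers(0, 9), max_size=8),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_matches_scipy_on_indicator_vectors(self, a, b):
        """Independent oracle: scipy's Dice dissimilarity on boolean
        indicator vectors over the pair universe."""
        if not a and not b:
            return
        sa = frozenset((x, x) for x in a)
        sb = frozenset((x, x) for x in b)
        va = np.array([x in a for x in range(10)])
        vb = np.array([x in b for x in range(10)])
        expected = scipy_dice(va, vb)
        assert dice_dissimilarity(sa, sb) == pytest.approx(expected, abs=1e-12)

    @given(
        st.sets(st.integers(0, 9), min_size=1, max_size=8),
        st.sets(st.integers(0, 9), min_size=1, max_size=8),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_semimetric_properties(self, a, b):
        sa = frozenset((x, x) for x in a)
        sb = frozenset((x, x) for x in b)
        d = dice_dissimilarity(sa, sb)
        assert 0.0 <= d <= 1.0
        assert d == dice_dissimilarity(sb, sa)
        assert (d == 0.0) == (sa == sb)


def maps_from_sets(sets):
    return [ContactMap(50.0 * k, frozenset(s)) for k, s in enumerate(sets)]


class TestClustering:
    A = {(1, 1), (2, 2), (3, 3)}
    B = {(7, 7), (8, 8)}
    C = {(5, 5)}

    def test_identical_maps_form_one_full_cluster(self):
        cl = cluster_interfaces(maps_from_sets([self.A] * 6))
        assert list(cl.frequencies.columns) == ["C1"]
        assert cl.frequencies.iloc[0, 0] == 1.0

    def test_two_planted_templates_recovered_with_scheduled_frequencies(self):
        cl = cluster_interfaces(maps_from_sets([self.A] * 6 + [self.B] * 4))
        assert cl.frequencies.shape[1] == 2
        np.testing.assert_allclose(sorted(cl.frequencies.iloc[0]), [0.4, 0.6])
        assert cl.representatives["C1"].pairs == frozenset(self.A)

    def test_frequent_flag_uses_ten_percent_rule(self):
        sets = [self.A] * 6 + [self.B] * 3 + [self.C] * 1
        cl = cluster_interfaces(maps_from_sets(sets))
        flags = [cl.frequent[c] for c in cl.frequencies.columns]
        assert flags == [True, True, False]

    def test_empty_maps_are_apart_and_excluded(self):
        sets = [self.A] * 3 + [set()] * 2 + [self.B] * 3
        cl = cluster_interfaces(maps_from_sets(sets))
        assert (cl.labels[3:5] == APART).all()
        np.testing.assert_allclose(cl.frequencies.iloc[0].sum(), 1.0)
        np.testing.assert_allclose(sorted(cl.frequencies.iloc[0]), [0.5, 0.5])

    def test_frequencies_sum_to_one_per_run(self):
        sets = [self.A] * 5 + [self.B] * 5
        cl = cluster_interfaces(maps_from_sets(sets), run_ids=[0] * 5 + [1] * 5)
        np.testing.assert_allclose(cl.frequencies.sum(axis=1), [1.0, 1.0])


class TestCompareConditions:
    def test_identical_vectors(self):
        fv = {"C1": 0.6, "C2": 0.3, "C3": 0.1}
        assert compare_conditions(fv, fv) == pytest.approx(1.0)

    def test_anticorrelated_vectors(self):
        assert compare_conditions({"a": 1.0, "b": 0.0}, {"a": 0.0, "b": 1.0}) == (
            pytest.approx(-1.0)
        )

    def test_hand_computed_pearson(self):
        v1 = np.array([0.5, 0.3, 0.2])
        v2 = np.array([0.4, 0.4, 0.2])
        expected = float(
            ((v1 - v1.mean()) * (v2 - v2.mean())).sum()
            / np.sqrt(((v1 - v1.mean()) ** 2).sum() * ((v2 - v2.mean()) ** 2).sum())
        )
        got = compare_conditions(dict(zip("abc", v1)), dict(zip("abc", v2)))
        assert got == pytest.approx(expected)

    def test_union_alignment_fills_zero(self):
        r = compare_conditions({"a": 1.0}, {"b": 1.0})
        # aligned vectors (1,0) vs (0,1)
        assert r == pytest.approx(-1.0)

    def test_zero_variance_is_nan(self):
        assert np.isnan(compare_conditions({"a": 0.5, "b": 0.5}, {"a": 1.0, "b": 0.0}))

    def test_invariant_to_consistent_relabelling(self):
        fv1 = {"a": 0.6, "b": 0.3, "c": 0.1}
        fv2 = {"a": 0.2, "b": 0.5, "c": 0.3}
        perm = {"a": "z", "b": "y", "c": "x"}
        p1 = {perm[k]: v for k, v in fv1.items()}
        p2 = {perm[k]: v for k, v in fv2.items()}
        assert compare_conditions(fv1, fv2) == pytest.approx(compare_conditions(p1, p2))


REF = frozenset({(1, 1), (2, 2)})
OTHER = frozenset({(9, 9)})


def presence_maps(pattern):
    """'P' -> reference map, 'A' -> a disjoint map."""
    return maps_from_sets([REF if ch == "P" else OTHER for ch in pattern])


class TestNMRTrace:
    def test_always_present_single_episode(self):
        tr = nmr_trace(presence_maps("PPPP"), REF)
        assert len(tr.episodes) == 1
        assert tr.reformations == []
        assert tr.durations[0] == pytest.approx(200.0)

    def test_reformation_after_half_microsecond_gap(self):
        """P,P then nine absent frames then P at 50 ns stride: the interface
        was gone for 0.5 us, so the return counts as a reformation."""
        tr = nmr_trace(presence_maps("PP" + "A" * 9 + "P"), REF, gap_ns=500.0)
        assert len(tr.episodes) == 2
        assert len(tr.reformations) == 1

    def test_short_gap_is_not_a_reformation(self):
        tr = nmr_trace(presence_maps("PP" + "A" * 8 + "P"), REF, gap_ns=500.0)
        assert len(tr.episodes) == 2
        assert len(tr.reformations) == 0

    def test_survival_curve_empirical_fraction(self):
        # episodes of 2, 2 and 4 frames
        tr = nmr_trace(presence_maps("PPA" + "PPA" + "PPPP" + "A"), REF)
        assert sorted(tr.durations) == [100.0, 100.0, 200.0]
        assert tr.survival(150.0) == pytest.approx(1 / 3)
        assert tr.survival(50.0) == pytest.approx(1.0)

    @given(st.lists(st.booleans(), min_size=2, max_size=60))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_episodes_match_brute_force_enumeration(self, pattern):
        """Oracle: directly enumerate maximal present runs and gaps."""
        text = "".join("P" if p else "A" for p in pattern)
        tr = nmr_trace(presence_maps(text), REF, gap_ns=150.0)
        # brute force
        episodes = []
        start = None
        for i, ch in enumerate(text):
            if ch == "P" and start is None:
                start = i
            if ch == "A" and start is not None:
                episodes.append((start, i - 1))
                start = None
        if start is not None:
            episodes.append((start, len(text) - 1))
        durations = [(e - s + 1) * 50.0 for s, e in episodes]
        reformations = sum(
            1
            for (s1, e1), (s2, e2) in zip(episodes, episodes[1:])
            if (s2 - e1) * 50.0 >= 150.0
        )
        assert len(tr.episodes) == len(episodes)
        assert sorted(tr.durations) == sorted(durations)
        assert len(tr.reformations) == reformations
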