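"""Event algebra, minimal event distances, Sankoff reconstruction."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from karyoevol import (
    Event,
    EventError,
    EventKind,
    EventModel,
    KaryotypeState,
    MorphClass,
    apply_event,
    event_distance,
    neighbors,
    sankoff_reconstruct,
    scenario_report,
)

DEFAULT = EventModel()
SYMMETRIC = EventModel(fission_cost=1.0)


def small_states(max_n=6):
    """All karyotype states with haploid number 1..max_n."""
    out = []
    for n in range(1, max_n + 1):
        for m in range(n + 1):
            for sm in range(n - m + 1):
                for stc in range(n - m - sm + 1):
                    out.append(KaryotypeState(m=m, sm=sm, st=stc, t=n - m - sm - stc))
    return out


state_strategy = (
    st.tuples(
        st.integers(0, 4), st.integers(0, 4), st.integers(0, 4), st.integers(0, 10)
    )
    .filter(lambda c: sum(c) >= 1)
    .map(lambda c: KaryotypeState(*c))
)


class TestApplyEvent:
    def test_fusion(self):
        s = apply_event(KaryotypeState(t=21), Event(EventKind.CENTRIC_FUSION, target=MorphClass.M))
        assert s == KaryotypeState(m=1, t=19)

    def test_fission_inverts_fusion(self):
        s = apply_event(
            KaryotypeState(m=2, t=18), Event(EventKind.CENTRIC_FISSION, source=MorphClass.M)
        )
        assert s == KaryotypeState(m=1, t=20)

    def test_inversion_reclassifies(self):
        s = apply_event(
            KaryotypeState(m=1, st=1, t=18),
            Event(EventKind.PERICENTRIC_INVERSION, source=MorphClass.ST, target=MorphClass.SM),
        )
        assert s == KaryotypeState(m=1, sm=1, t=18)

    def test_input_state_unmodified(self):
        s = KaryotypeState(t=21)
        apply_event(s, Event(EventKind.CENTRIC_FUSION, target=MorphClass.SM))
        assert s == KaryotypeState(t=21)

    @pytest.mark.parametrize(
        ("state", "event", "missing"),
        [
            (KaryotypeState(m=1, t=1), Event(EventKind.CENTRIC_FUSION, target=MorphClass.M), "two telocentrics"),
            (KaryotypeState(t=4), Event(EventKind.CENTRIC_FISSION, source=MorphClass.SM), "sm"),
            (KaryotypeState(t=4), Event(EventKind.PERICENTRIC_INVERSION, source=MorphClass.M, target=MorphClass.T), "m"),
        ],
    )
    def test_inapplicable_event_names_prerequisite(self, state, event, missing):
        with pytest.raises(EventError, match=missing):
            apply_event(state, event)

    @given(s=state_strategy)
    @settings(max_examples=200, deadline=None)
    def test_conservation_laws(self, s):
        """Fusion/fission move 2n by -/+2 conserving FN; reclassification
        conserves 2n and moves FN by -2, 0 or +2."""
        for ev, t in neighbors(s, DEFAULT):
            if ev.kind is EventKind.CENTRIC_FUSION:
                assert t.diploid_number == s.diploid_number - 2
                assert t.fundamental_number == s.fundamental_number
            elif ev.kind is EventKind.CENTRIC_FISSION:
                assert t.diploid_number == s.diploid_number + 2
                assert t.fundamental_number == s.fundamental_number
            else:
                assert t.diploid_number == s.diploid_number
                assert t.fundamental_number - s.fundamental_number in (-2, 0, 2)


class TestNeighbors:
    def test_all_telocentric_complement(self):
        # 3 fusion products + 3 reclassification targets for a t element
        moves = neighbors(KaryotypeState(t=21), DEFAULT)
        assert len(moves) == 6
        kinds = sorted(str(ev.kind) for ev, _ in moves)
        assert kinds.count("centric_fusion") == 3

    def test_two_telocentrics(self):
        results = {t for _, t in neighbors(KaryotypeState(t=2), DEFAULT)}
        assert KaryotypeState(m=1) in results  # fusion
        assert KaryotypeState(st=1, t=1) in results  # inversion of one t

    def test_single_metacentric(self):
        results = {t for _, t in neighbors(KaryotypeState(m=1), DEFAULT)}
        assert KaryotypeState(t=2) in results  # fission

    @given(s=state_strategy)
    @settings(max_examples=100, deadline=None)
    def test_no_duplicate_moves(self, s):
        moves = neighbors(s, DEFAULT)
        keyed = {(ev.kind, t) for ev, t in moves}
        assert len(keyed) == len(moves)


class TestEventDistance:
    def test_two_fusions_to_homopholis(self):
        # 2n=40 two-metacentric ancestor down to the 2n=36 karyotype
        cost, path = event_distance(
            KaryotypeState(m=2, t=18), KaryotypeState(m=4, t=14), DEFAULT
        )
        assert cost == 2
        assert all(ev.kind is EventKind.CENTRIC_FUSION for ev in path)

    def test_two_inversions_within_homopholis(self):
        # FN 44 -> FN 40 at constant 2n=36
        cost, path = event_distance(
            KaryotypeState(m=4, t=14), KaryotypeState(m=2, t=16), DEFAULT
        )
        assert cost == 2
        assert all(
            ev.kind in (EventKind.PERICENTRIC_INVERSION, EventKind.CENTROMERE_REPOSITIONING)
            for ev in path
        )

    def test_identity(self):
        s = KaryotypeState(m=1, sm=2, t=5)
        assert event_distance(s, s, DEFAULT) == (0.0, [])

    def test_path_is_valid(self):
        a, b = KaryotypeState(t=21), KaryotypeState(m=1, st=1, t=18)
        cost, path = event_distance(a, b, DEFAULT)
        s = a
        for ev in path:
            s = apply_event(s, ev)
        assert s == b
        assert cost == pytest.approx(sum(DEFAULT.cost(ev.kind) for ev in path))

    def test_bound_violation_rejected(self):
        with pytest.raises(ValueError, match="max_n"):
            event_distance(KaryotypeState(t=4), KaryotypeState(t=6), DEFAULT, max_n=5)

    @given(
        a=st.sampled_from(small_states(6)),
        b=st.sampled_from(small_states(6)),
    )
    @settings(max_examples=40, deadline=None)
    def test_symmetry_under_symmetric_costs(self, a, b):
        d_ab, _ = event_distance(a, b, SYMMETRIC, max_n=10)
        d_ba, _ = event_distance(b, a, SYMMETRIC, max_n=10)
        assert d_ab == pytest.approx(d_ba)

    def test_triangle_inequality_sampled(self):
        rng = np.random.default_rng(0)
        states = small_states(5)
        idx = rng.integers(0, len(states), size=(25, 3))
        for i, j, k in idx:
            a, b, c = states[i], states[j], states[k]
            d_ac = event_distance(a, c, DEFAULT, max_n=8)[0]
            d_ab = event_distance(a, b, DEFAULT, max_n=8)[0]
            d_bc = event_distance(b, c, DEFAULT, max_n=8)[0]
            assert d_ac <= d_ab + d_bc + 1e-9

    def test_raising_a_cost_never_decreases_distance(self):
        rng = np.random.default_rng(1)
        states = small_states(5)
        pricier = [
            EventModel(fusion_cost=2.0),
            EventModel(fission_cost=7.0),
            EventModel(inversion_cost=2.0, repositioning_cost=2.0),
        ]
        for i, j in rng.integers(0, len(states), size=(20, 2)):
            a, b = states[i], states[j]
            base = event_distance(a, b, DEFAULT, max_n=8)[0]
            for model in pricier:
                assert event_distance(a, b, model, max_n=8)[0] >= base - 1e-9


class TestSankoff:
    def test_single_known_tip(self, toy_tree):
        tree = toy_tree("((a,b),c);")
        s = KaryotypeState(m=2, t=18)
        res = sankoff_reconstruct(tree, {"a": s, "b": None, "c": None}, DEFAULT)
        assert res.total_cost == 0
        assert s in res.node_states[res.root_label]

    def test_two_tip_tree_matches_bruteforce(self, toy_tree):
        a, b = KaryotypeState(t=6), KaryotypeState(m=2, t=2)
        res = sankoff_reconstruct(toy_tree("(a,b);"), {"a": a, "b": b}, DEFAULT)
        brute = min(
            event_distance(r, a, DEFAULT, max_n=10)[0]
            + event_distance(r, b, DEFAULT, max_n=10)[0]
            for r in small_states(8)
        )
        assert res.total_cost == pytest.approx(brute)

    def test_tip_order_invariance(self, toy_tree):
        t1 = toy_tree("((a,b),(c,d));")
        t2 = toy_tree("((d,c),(b,a));")
        states = {
            "a": KaryotypeState(t=8),
            "b": KaryotypeState(m=1, t=6),
            "c": KaryotypeState(m=2, t=4),
            "d": None,
        }
        r1 = sankoff_reconstruct(t1, states, DEFAULT)
        r2 = sankoff_reconstruct(t2, states, DEFAULT)
        assert r1.total_cost == pytest.approx(r2.total_cost)

    def test_unknown_tip_padding_is_neutral(self, toy_tree):
        states = {"a": KaryotypeState(t=8), "b": KaryotypeState(m=2, t=4)}
        r1 = sankoff_reconstruct(toy_tree("(a,b);"), states, DEFAULT)
        r2 = sankoff_reconstruct(
            toy_tree("((a,x),b);"), {**states, "x": None}, DEFAULT
        )
        assert r1.total_cost == pytest.approx(r2.total_cost)

    def test_unknown_tip_label_rejected(self, toy_tree):
        with pytest.raises(ValueError, match="absent"):
            sankoff_reconstruct(
                toy_tree("(a,b);"), {"a": KaryotypeState(t=4), "zz": None}, DEFAULT
            )

    def test_state_space_missing_tip_state_rejected(self, toy_tree):
        with pytest.raises(ValueError, match="does not contain"):
            sankoff_reconstruct(
                toy_tree("(a,b);"),
                {"a": KaryotypeState(t=4), "b": KaryotypeState(t=6)},
                DEFAULT,
                state_space=[KaryotypeState(t=4)],
            )

    def test_designated_labeling_is_consistent(self, case_result):
        res = case_result
        assert sum(res.branch_costs.values()) == pytest.approx(res.total_cost)
        for label, s in res.designated.items():
            assert s in res.node_states[label]


class TestScenarioReport:
    def test_costs_sum_to_total(self, case_result):
        rep = scenario_report(case_result)
        assert sum(b["cost"] for b in rep["branches"]) == pytest.approx(
            rep["total_cost"]
        )

    def test_root_line_reports_2n_and_fn(self, case_result):
        rep = scenario_report(case_result)
        root = [n for n in rep["nodes"] if n["is_root"]]
        assert len(root) == 1
        assert root[0]["diploid_number"] == 2 * sum(root[0]["state"].values())
        assert root[0]["fundamental_number"] >= root[0]["diploid_number"]

    def test_identical_tips_no_events(self, toy_tree):
        s = KaryotypeState(m=2, t=18)
        res = sankoff_reconstruct(toy_tree("(a,b);"), {"a": s, "b": s}, DEFAULT)
        rep = scenario_report(res)
        assert all(b["n_events"] == 0 for b in rep["branches"])
        assert rep["total_cost"] == 0
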