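import numpy as np
import pytest

from conftest import grid_positions, make_annotation
from roifinder.roi import (
    ROIParams,
    ROISite,
    aggregate_sequential,
    associate_cycle,
    detect_roi,
    focal_test,
    radial_spread_test,
    roi_sites_to_rows,
)


def neighbor_train(base_lats, offset):
    return [t + offset for t in base_lats]


class TestAssociateAndFocal:
    def setup_method(self):
        self.ids, self.pos, self.graph = grid_positions()

    def _table(self, center_morph="QS", offsets=(8.0, 12.0, 15.0, 10.0)):
        lats = [300.0, 500.0, 700.0]
        anns = {"e5": make_annotation("e5", lats, center_morph)}
        for nbr, off in zip(sorted(self.graph["e5"]), offsets):
            anns[nbr] = make_annotation(nbr, neighbor_train(lats, off))
        for eid in self.ids:
            anns.setdefault(eid, make_annotation(eid, []))
        return anns

    def test_neighbors_bound_with_offsets(self):
        anns = self._table(offsets=(8.0, 12.0, 15.0, 10.0))
        ev = anns["e5"].events[0]
        ctx = associate_cycle(anns, self.graph, ev)
        assert ctx.valid_neighbor_count == 4
        assert sorted(round(v, 1) for v in ctx.offsets_ms.values()) == [8.0, 10.0, 12.0, 15.0]

    def test_early_neighbor_bound_with_negative_offset(self):
        anns = self._table(offsets=(-5.0, 12.0, 15.0, 10.0))
        ev = anns["e5"].events[0]
        ctx = associate_cycle(anns, self.graph, ev)
        assert min(ctx.offsets_ms.values()) == pytest.approx(-5.0)
        fa = focal_test(ctx, ev)
        assert fa.status == "not_focal" and not fa.leading

    def test_all_neighbors_failed_makes_candidate_ineligible(self):
        lats = [300.0, 500.0]
        anns = {"e5": make_annotation("e5", lats, "QS")}
        for nbr in self.graph["e5"]:
            anns[nbr] = make_annotation(nbr, [], passed=False)
        ev = anns["e5"].events[0]
        ctx = associate_cycle(anns, self.graph, ev)
        assert ctx.valid_neighbor_count == 0
        assert focal_test(ctx, ev).status == "ineligible"

    def test_qs_and_leading_is_focal(self):
        anns = self._table()
        ev = anns["e5"].events[0]
        fa = focal_test(associate_cycle(anns, self.graph, ev), ev)
        assert fa.is_focal

    def test_non_qs_leader_not_focal(self):
        anns = self._table(center_morph="non_QS")
        ev = anns["e5"].events[0]
        fa = focal_test(associate_cycle(anns, self.graph, ev), ev)
        assert fa.status == "not_focal" and fa.leading and not fa.qs


class TestDetectROI:
    def setup_method(self):
        self.ids, self.pos, self.graph = grid_positions()

    def _annotations(self, center_morphs, cl=200.0, n_cycles=8):
        lats = [200.0 + cl * i for i in range(n_cycles)]
        anns = {"e5": make_annotation("e5", lats, center_morphs)}
        for nbr in sorted(self.graph["e5"]):
            anns[nbr] = make_annotation(nbr, neighbor_train(lats, 9.0))
        for eid in self.ids:
            if eid not in anns:
                anns[eid] = make_annotation(eid, neighbor_train(lats, 18.0))
        return anns

    def test_run_of_three_detected(self):
        """QS-leading on cycles 3-5 only -> one site whose runs include 3."""
        morphs = ["non_QS", "non_QS", "QS", "QS", "QS", "non_QS", "non_QS", "non_QS"]
        anns = self._annotations(morphs)
        sites = detect_roi(anns, self.graph, self.pos)
        assert len(sites) == 1
        assert sites[0].electrode_id == "e5"
        assert 3 in sites[0].runs and sites[0].occurrences >= 1

    def test_planar_sweep_no_sites(self):
        lats = [200.0 + 200.0 * i for i in range(8)]
        anns = {}
        for i, eid in enumerate(self.ids):
            r, c = divmod(i, 3)
            anns[eid] = make_annotation(eid, neighbor_train(lats, 6.0 * c))
        sites = detect_roi(anns, self.graph, self.pos)
        assert sites == []

    def test_single_focal_cycle_not_enough(self):
        morphs = ["non_QS"] * 3 + ["QS"] + ["non_QS"] * 4
        anns = self._annotations(morphs)
        assert detect_roi(anns, self.graph, self.pos) == []

    def test_gap_breaks_run(self):
        """Two QS-leading beats far apart in time are separate length-1 runs."""
        anns = {"e5": make_annotation("e5", [200.0, 400.0, 3000.0, 3200.0, 3400.0],
                                      ["QS", "non_QS", "non_QS", "non_QS", "QS"])}
        for nbr in sorted(self.graph["e5"]):
            anns[nbr] = make_annotation(
                nbr, neighbor_train([200.0, 400.0, 3000.0, 3200.0, 3400.0], 9.0)
            )
        for eid in self.ids:
            anns.setdefault(eid, make_annotation(eid, []))
        assert detect_roi(anns, self.graph, self.pos) == []

    def test_min_consecutive_monotonicity(self):
        """Raising min_consecutive never yields more sites."""
        rng = np.random.default_rng(11)
        for _ in range(10):
            anns = {}
            lats = [200.0 + 150.0 * i for i in range(20)]
            for i, eid in enumerate(self.ids):
                morphs = rng.choice(["QS", "non_QS"], size=20, p=[0.4, 0.6])
                anns[eid] = make_annotation(
                    eid, neighbor_train(lats, rng.uniform(0, 30)), list(morphs)
                )
            counts = [
                len(detect_roi(anns, self.graph, self.pos, ROIParams(min_consecutive=m)))
                for m in (2, 3, 4, 5)
            ]
            assert counts == sorted(counts, reverse=True)

    def test_detection_deterministic_export(self, focal_sim):
        from roifinder import run_roi_pipeline

        a = run_roi_pipeline(focal_sim.recording)
        b = run_roi_pipeline(focal_sim.recording)
        assert roi_sites_to_rows(a.sites) == roi_sites_to_rows(b.sites)


class TestRadialSpread:
    def test_monotone_rings_radial(self):
        ids, pos, graph = grid_positions()
        lats = [500.0]
        anns = {"e5": make_annotation("e5", lats, "QS")}
        for nbr, off in zip(sorted(graph["e5"]), (6.0, 7.0, 8.0, 7.5)):
            anns[nbr] = make_annotation(nbr, [500.0 + off])
        ring2 = set(ids) - set(graph["e5"]) - {"e5"}
        for eid in ring2:
            anns[eid] = make_annotation(eid, [514.0])
        wc = radial_spread_test(anns, graph, "e5", 500.0)
        assert wc.radial and not wc.insufficient_coverage

    def test_planar_not_radial(self):
        ids, pos, graph = grid_positions()
        anns = {}
        for i, eid in enumerate(ids):
            r, c = divmod(i, 3)
            anns[eid] = make_annotation(eid, [500.0 + 6.0 * c])
        wc = radial_spread_test(anns, graph, "e5", 506.0)
        assert not wc.radial

    def test_insufficient_coverage_flagged(self):
        ids, pos, graph = grid_positions()
        anns = {eid: make_annotation(eid, [], passed=False) for eid in ids}
        anns["e5"] = make_annotation("e5", [500.0], "QS")
        wc = radial_spread_test(anns, graph, "e5", 500.0)
        assert wc.insufficient_coverage and not wc.radial


class TestAggregateSequential:
    def mk_site(self, xyz, occurrences=1, eid="e"):
        return ROISite(eid, np.asarray(xyz, float), [2] * occurrences, 0.0, 1000.0)

    def test_nearby_sites_merge_and_pool(self):
        sites = [
            self.mk_site([0, 0, 0], 2, "a"),
            self.mk_site([4, 0, 0], 1, "b"),
            self.mk_site([0, 6, 0], 1, "c"),
        ]
        out = aggregate_sequential(sites)
        assert len(out) == 1
        assert out[0].occurrences == 4

    def test_distant_sites_stay_separate(self):
        out = aggregate_sequential([self.mk_site([0, 0, 0]), self.mk_site([25.0, 0, 0])])
        assert len(out) == 2

    def test_empty_input(self):
        assert aggregate_sequential([]) == []
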