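import numpy as np
import pandas as pd
import pytest

import mscope as m
from mscope import MscopeError
from mscope.selection import survivors


def stats_from(values_by_cat):
    ids, vals, rows = [], [], []
    nid = 1
    for (h, lb), values in values_by_cat.items():
        for v in values:
            ids.append(nid)
            vals.append(v)
            rows.append({"node_id": nid, "hemisphere": h, "lobe": lb,
                         "gyrus": "G"})
            nid += 1
    field = m.FieldVector(node_id=ids, value=vals)
    labels = m.AtlasLabelTable(pd.DataFrame(rows))
    return m.lobe_statistics(field, labels)


TARGET = ("left", "parietal")


class TestPrinciple1:
    def test_off_target_max_filtered_out(self):
        st = stats_from({("left", "frontal"): [1.0, 1.0],
                         ("left", "parietal"): [0.2, 0.2]})
        entries = m.principle1_screen({"only": st}, TARGET)
        assert survivors(entries) == []
        assert not entries[0].passes_target

    def test_ranked_by_spread(self):
        # focal: target plus one extra lobe above avg
        focal = stats_from({("left", "parietal"): [1.0] * 3,
                            ("left", "frontal"): [0.5] * 3,
                            ("left", "temporal"): [0.1] * 3,
                            ("left", "occipital"): [0.1] * 3,
                            ("right", "frontal"): [0.05] * 3})
        # diffuse: three extra lobes above avg
        diffuse = stats_from({("left", "parietal"): [1.0] * 3,
                              ("left", "frontal"): [0.9] * 3,
                              ("left", "temporal"): [0.9] * 3,
                              ("left", "occipital"): [0.9] * 3,
                              ("right", "frontal"): [0.05] * 3})
        entries = m.principle1_screen({"diffuse": diffuse, "focal": focal},
                                      TARGET)
        assert [e.montage_name for e in entries] == ["focal", "diffuse"]
        assert entries[0].spread_count < entries[1].spread_count

    def test_shared_max_excluded(self):
        shared = stats_from({("left", "parietal"): [1.0] * 3,
                             ("left", "temporal"): [1.0] * 3,
                             ("left", "frontal"): [0.1] * 3})
        entries = m.principle1_screen({"shared": shared}, TARGET)
        assert survivors(entries) == []
        assert entries[0].excluded_shared_max

    def test_synthetic_dorsal_set_screening(self, small_head, layout):
        """All five CP5-anode synthetic montages peak at the left parietal
        lobe; the CZ-cathode analog outranks every extracephalic-cathode
        analog on spread."""
        cloud, labels = small_head
        stats = {}
        for spec in m.enumerate_paper_montages(5, 5):
            if spec.anode_label != "CP5":
                continue
            fv = m.simulate_field(spec, cloud, layout).restrict(
                labels.node_id)
            stats[spec.name] = m.lobe_statistics(fv, labels)
        entries = m.principle1_screen(stats, TARGET)
        order = [e.montage_name for e in entries]
        assert set(survivors(entries)) == set(stats)
        assert order.index("CP5_CZ_5_5") < order.index("CP5_SO_5_5")
        assert order.index("CP5_CZ_5_5") < order.index("CP5_Maxilla_5_5")
        assert order.index("CP5_CZ_5_5") < order.index("CP5_Neck_5_5")


class TestPrinciple2:
    def test_least_overlap_row_wins(self):
        counts = {"TP7_CZ": 903, "TP7_SO": 298, "TP7_Maxilla": 405,
                  "TP7_TP8": 205, "TP7_Neck": 57}
        matrix = [m.OverlapResult(pair=("CP5_CZ", name), n_overlap=n,
                                  p=n / 1695)
                  for name, n in counts.items()]
        pair, nmin, tied = m.principle2_best_pair(matrix)
        assert pair == ("CP5_CZ", "TP7_Neck")
        assert nmin == 57
        assert not tied

    def test_all_equal_flags_tie(self):
        matrix = [m.OverlapResult(pair=(d, v), n_overlap=5, p=0.5)
                  for d in ("b", "a") for v in ("y", "x")]
        pair, _, tied = m.principle2_best_pair(matrix)
        assert pair == ("a", "x")
        assert tied

    def test_matches_exhaustive_scan(self, rng):
        matrix = [m.OverlapResult(pair=(f"d{i}", f"v{j}"),
                                  n_overlap=int(rng.integers(0, 100)),
                                  p=0.1)
                  for i in range(3) for j in range(3)]
        pair, nmin, _ = m.principle2_best_pair(matrix)
        best = min(matrix, key=lambda r: (r.n_overlap, r.pair))
        assert (pair, nmin) == (best.pair, best.n_overlap)


class TestPrinciple3:
    def _clusters(self):
        return [m.GyrusCluster("Supramarginal Gyrus", "left", 5, 10.0, 1),
                m.GyrusCluster("Angular Gyrus", "left", 4, 8.0, 2),
                m.GyrusCluster("Precentral Gyrus", "left", 3, 2.0, 3)]

    def test_rank_one_target_verified(self):
        out = m.principle3_verify(self._clusters(),
                                  {"Supramarginal Gyrus"}, top_k=3)
        assert out.verified
        assert out.found == {"Supramarginal Gyrus": 1}

    def test_absent_target_not_verified(self):
        out = m.principle3_verify(self._clusters(), {"Lingual Gyrus"},
                                  top_k=3)
        assert not out.verified

    def test_target_below_top_k_not_verified(self):
        out = m.principle3_verify(self._clusters(), {"Precentral Gyrus"},
                                  top_k=2)
        assert not out.verified

    def test_synthetic_ventral_winner_verified(self, small_head, layout):
        cloud, labels = small_head
        fv = m.simulate_field(m.parse_montage_name("TP7_Neck_5_5"), cloud,
                              layout).restrict(labels.node_id)
        clusters = m.cluster_by_gyrus(m.threshold_field(fv, 0.5), fv, labels)
        out = m.principle3_verify(
            clusters, {"Middle Temporal Gyrus", "Inferior Temporal Gyrus"},
            top_k=3, montage_name="TP7_Neck_5_5")
        assert out.verified


class TestSelect:
    def _fields(self, small_head, layout, names):
        cloud, labels = small_head
        out = {}
        for spec in m.enumerate_paper_montages(5, 5):
            if spec.name in names:
                out[spec.name] = m.simulate_field(
                    spec, cloud, layout).restrict(labels.node_id)
        return out

    def test_single_qualifying_pair_selected(self, small_head, layout):
        _, labels = small_head
        dorsal = self._fields(small_head, layout, {"CP5_CZ_5_5"})
        ventral = self._fields(small_head, layout, {"TP7_Neck_5_5"})
        rep = m.select(dorsal, ventral, labels)
        assert rep.final_pair == ("CP5_CZ_5_5", "TP7_Neck_5_5")
        assert len(rep.principle2_matrix) == 1

    def test_nonexistent_target_gyrus_gives_none(self, small_head, layout):
        _, labels = small_head
        dorsal = self._fields(small_head, layout, {"CP5_CZ_5_5"})
        ventral = self._fields(small_head, layout, {"TP7_Neck_5_5"})
        targets = m.SelectionTargets(
            dorsal_target_gyri=frozenset({"No Such Gyrus"}))
        rep = m.select(dorsal, ventral, labels, targets)
        assert rep.final_pair is None
        assert any("principle 3" in n for n in rep.notes)

    def test_report_deterministic(self, small_head, layout):
        _, labels = small_head
        dorsal = self._fields(small_head, layout,
                              {"CP5_CZ_5_5", "CP5_SO_5_5"})
        ventral = self._fields(small_head, layout,
                               {"TP7_Neck_5_5", "TP7_SO_5_5"})
        a = m.select(dorsal, ventral, labels)
        b = m.select(dorsal, ventral, labels)
        assert a.to_dict() == b.to_dict()

    def test_winner_has_minimal_overlap_among_survivor_pairs(
            self, small_head, layout):
        _, labels = small_head
        dorsal = self._fields(small_head, layout,
                              {"CP5_CZ_5_5", "CP5_SO_5_5"})
        ventral = self._fields(small_head, layout,
                               {"TP7_Neck_5_5", "TP7_Maxilla_5_5"})
        rep = m.select(dorsal, ventral, labels)
        assert rep.winning_n_overlap == min(
            r.n_overlap for r in rep.principle2_matrix)

    def test_removing_non_winning_montage_keeps_pair(self, small_head,
                                                     layout):
        _, labels = small_head
        dorsal = self._fields(small_head, layout,
                              {"CP5_CZ_5_5", "CP5_SO_5_5"})
        ventral = self._fields(small_head, layout,
                               {"TP7_Neck_5_5", "TP7_Maxilla_5_5"})
        full = m.select(dorsal, ventral, labels)
        assert full.final_pair is not None
        loser = next(n for n in ventral if n != full.final_pair[1])
        ventral.pop(loser)
        reduced = m.select(dorsal, ventral, labels)
        assert reduced.final_pair == full.final_pair

    def test_empty_pathway_rejected(self, small_head, layout):
        _, labels = small_head
        with pytest.raises(MscopeError):
            m.select({}, self._fields(small_head, layout, {"TP7_Neck_5_5"}),
                     labels)
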