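import numpy as np
import pytest

import mscope as m
from mscope import MscopeError
from mscope.synth import arc_points


class TestHeadModel:
    def test_paper_scale_node_count(self):
        cloud, labels = m.build_head_model(35057, seed=1)
        assert len(cloud) == 35057
        assert len(labels) == 35057

    def test_same_seed_identical(self):
        a, la = m.build_head_model(2500, seed=7)
        b, lb = m.build_head_model(2500, seed=7)
        assert np.array_equal(a.coords, b.coords)
        assert la.table.equals(lb.table)

    def test_different_seed_differs(self):
        a, _ = m.build_head_model(500, seed=1)
        b, _ = m.build_head_model(500, seed=2)
        assert not np.array_equal(a.coords, b.coords)

    def test_all_twelve_categories_populated(self, small_head):
        _, labels = small_head
        assert set(labels.categories_present()) == set(m.CATEGORIES)

    def test_per_lobe_counts_match_partition_oracle(self):
        """Lobe counts agree with brute-force re-application of the
        partition predicate to the emitted coordinates."""
        cloud, labels = m.build_head_model(5000, seed=3)
        atlas = m.SyntheticAtlas()
        expected = {}
        for c in cloud.coords:
            h, lb, _ = atlas.label_one(c)
            expected[(h, lb)] = expected.get((h, lb), 0) + 1
        got = labels.table.groupby(["hemisphere", "lobe"],
                                   observed=True).size().to_dict()
        assert got == expected

    def test_required_gyri_present(self, small_head):
        _, labels = small_head
        gyri = set(labels.table["gyrus"])
        for g in ("Supramarginal Gyrus", "Angular Gyrus",
                  "Inferior Parietal Lobule", "Superior Parietal Lobule",
                  "Superior Temporal Gyrus", "Middle Temporal Gyrus",
                  "Inferior Temporal Gyrus", "Fusiform Gyrus",
                  "Lingual Gyrus", "Precentral Gyrus",
                  "Superior Frontal Gyrus"):
            assert g in gyri

    def test_too_few_nodes_rejected(self):
        with pytest.raises(MscopeError):
            m.build_head_model(50, seed=1)


class TestElectrodeLayout:
    def test_cz_at_apex(self, layout):
        assert np.allclose(layout["CZ"], [0.0, 0.0, layout.head_radius])

    def test_laterality_convention(self, layout):
        assert layout["CP5"][0] < 0
        assert layout["TP7"][0] < 0
        assert layout["P7"][0] < 0
        assert layout["C3"][0] < 0
        assert layout["TP8"][0] > 0
        assert layout["CP6"][0] > 0

    def test_cephalic_sites_on_sphere(self, layout):
        for site, pos in layout.positions.items():
            assert np.linalg.norm(pos) == pytest.approx(
                layout.head_radius, abs=1e-6)

    def test_extracephalic_below_equator(self, layout):
        for site in ("maxilla_contra", "neck_nape"):
            assert layout[site][2] < 0

    def test_invalid_radius_rejected(self):
        with pytest.raises(MscopeError):
            m.layout_electrodes(-1.0)


class TestMontageNames:
    def test_parse_cp5_cz(self):
        spec = m.parse_montage_name("CP5_CZ_5_5")
        assert spec.anode_label == "CP5"
        assert spec.cathode_label == "CZ"
        assert (spec.size_l, spec.size_b) == (5.0, 5.0)
        assert spec.current == 2.0

    def test_parse_extracephalic_and_size(self):
        spec = m.parse_montage_name("TP7_Neck_5_7")
        assert spec.anode_label == "TP7"
        assert spec.cathode_label == "neck_nape"
        assert (spec.size_l, spec.size_b) == (5.0, 7.0)

    @pytest.mark.parametrize("bad", ["CP5", "CP5_CZ_5", "CP5_CZ_a_5",
                                     "XX9_CZ_5_5", "CP5_QQ_5_5"])
    def test_malformed_names_rejected(self, bad):
        with pytest.raises(MscopeError):
            m.parse_montage_name(bad)

    def test_enumerate_ten_montages(self):
        specs = m.enumerate_paper_montages(5, 5)
        assert len(specs) == 10
        assert sum(s.anode_label == "CP5" for s in specs) == 5
        assert sum(s.anode_label == "TP7" for s in specs) == 5

    def test_enumerate_other_size(self):
        specs = m.enumerate_paper_montages(3, 3)
        assert {(s.size_l, s.size_b) for s in specs} == {(3.0, 3.0)}
        pairs55 = {(s.anode_label, s.cathode_label)
                   for s in m.enumerate_paper_montages(5, 5)}
        assert {(s.anode_label, s.cathode_label) for s in specs} == pairs55

    def test_names_round_trip(self):
        for spec in m.enumerate_paper_montages(5, 7):
            assert m.parse_montage_name(spec.name) == spec


class TestSimulateField:
    def test_deterministic_with_noise(self, small_head, layout):
        cloud, _ = small_head
        spec = m.parse_montage_name("CP5_CZ_5_5")
        params = m.SimulationParams(noise_sd=0.05)
        a = m.simulate_field(spec, cloud, layout, params, seed=9)
        b = m.simulate_field(spec, cloud, layout, params, seed=9)
        assert np.array_equal(a.value, b.value)
        c = m.simulate_field(spec, cloud, layout, params, seed=10)
        assert not np.array_equal(a.value, c.value)

    def test_linear_in_current(self, small_head, layout):
        cloud, _ = small_head
        f2 = m.simulate_field(m.MontageSpec("CP5", "CZ", current=2.0),
                              cloud, layout)
        f1 = m.simulate_field(m.MontageSpec("CP5", "CZ", current=1.0),
                              cloud, layout)
        assert np.array_equal(2.0 * f1.value, f2.value)

    def test_nonnegative_even_with_noise(self, small_head, layout):
        cloud, _ = small_head
        params = m.SimulationParams(noise_sd=0.5)
        fv = m.simulate_field(m.MontageSpec("CP5", "CZ"), cloud, layout,
                              params, seed=4)
        assert np.all(fv.value >= 0)

    def test_peak_under_anode(self, layout):
        """Brute-force argmax lies within sigma0 (geodesic) of the cortical
        projection of the anode."""
        cloud, _ = m.build_head_model(10000, seed=5)
        params = m.SimulationParams()
        fv = m.simulate_field(m.parse_montage_name("CP5_CZ_5_5"), cloud,
                              layout, params)
        peak = cloud.coords[int(np.argmax(fv.value))]
        rc = np.linalg.norm(cloud.coords, axis=1).max()
        a = layout["CP5"] / np.linalg.norm(layout["CP5"])
        geo = rc * np.arccos(np.clip(
            np.dot(peak / np.linalg.norm(peak), a), -1, 1))
        assert geo < params.sigma0

    def test_smaller_pad_sharper_peak(self, small_head, layout):
        cloud, _ = small_head
        f55 = m.simulate_field(m.MontageSpec("CP5", "CZ", 5, 5), cloud,
                               layout)
        f33 = m.simulate_field(m.MontageSpec("CP5", "CZ", 3, 3), cloud,
                               layout)
        assert f33.value.max() > f55.value.max()

    def test_mirror_symmetry(self, small_head, layout):
        cloud, _ = small_head
        reflected = m.NodeCloud(cloud.node_id,
                                cloud.coords * np.array([-1.0, 1.0, 1.0]),
                                space=cloud.space)
        f = m.simulate_field(m.MontageSpec("CP5", "CZ"), cloud, layout)
        fr = m.simulate_field(m.MontageSpec("CP6", "CZ"), reflected, layout)
        assert np.abs(f.value - fr.value).max() < 1e-9

    def test_cathode_pull(self, small_head, layout):
        """Nodes near the anode->cathode arc gain field mass when the
        path-leak term is on."""
        cloud, _ = small_head
        rc = np.linalg.norm(cloud.coords, axis=1).max()
        arc = arc_points(layout, "CP5", "CZ", rc, 64)
        d_arc = np.min(np.linalg.norm(
            cloud.coords[:, None, :] - arc[None], axis=2), axis=1)
        near = d_arc < 2 * 25.0
        spec = m.MontageSpec("CP5", "CZ")
        f0 = m.simulate_field(spec, cloud, layout,
                              m.SimulationParams(leak_fraction=0.0))
        f5 = m.simulate_field(spec, cloud, layout,
                              m.SimulationParams(leak_fraction=0.5))
        assert f5.value[near].mean() > f0.value[near].mean()

    def test_unknown_site_rejected(self, small_head, layout):
        cloud, _ = small_head
        with pytest.raises(MscopeError, match="absent from layout"):
            m.simulate_field(m.MontageSpec("CP5", "nowhere"), cloud, layout)
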