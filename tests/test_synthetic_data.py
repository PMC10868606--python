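"""Generator statistical structure, determinism, planted truth, fixture."""

import numpy as np
import pytest

from bgcnovelty import (
    GenusSpec,
    SimulationConfig,
    build_novelty_records,
    generate_collection,
    generate_families,
    generate_membership,
    summarize_families,
)
from bgcnovelty.synthetic_data import draw_best_distances, reference_fixture


def _one_genus(median=908.0, n_strains=1, **kwargs):
    return SimulationConfig(
        genera=(GenusSpec("Micromonospora", n_strains, median),), **kwargs
    )


class TestGenerateCollection:
    def test_degenerate_range_gives_exact_count(self):
        cfg = _one_genus(bgc_range=(13, 13), seed=1)
        coll, _ = generate_collection(cfg)
        assert len(coll) == 13

    def test_counts_within_configured_range(self):
        cfg = SimulationConfig(seed=2)
        coll, _ = generate_collection(cfg)
        per_strain = {}
        for rec in coll:
            per_strain[rec.strain_id] = per_strain.get(rec.strain_id, 0) + 1
        assert len(per_strain) == 35  # 29 + 6 strains
        assert all(13 <= n <= 34 for n in per_strain.values())

    def test_same_seed_identical(self):
        c1, t1 = generate_collection(SimulationConfig(seed=5))
        c2, t2 = generate_collection(SimulationConfig(seed=5))
        assert c1 == c2
        assert t1.home_gcf == t2.home_gcf
        assert t1.home_distance == t2.home_distance

    def test_different_seed_differs(self):
        c1, _ = generate_collection(SimulationConfig(seed=5))
        c2, _ = generate_collection(SimulationConfig(seed=6))
        assert c1 != c2

    def test_category_frequencies_match_weights(self):
        # ~700 strains -> ~16k BGCs; binomial check at 3 sigma
        cfg = _one_genus(n_strains=700, seed=9)
        coll, _ = generate_collection(cfg)
        n = len(coll)
        counts = {}
        for rec in coll:
            counts[rec.category] = counts.get(rec.category, 0) + 1
        for cat, w in cfg.category_weights.items():
            se = (n * w * (1 - w)) ** 0.5
            assert abs(counts.get(cat, 0) - n * w) < 3 * se

    def test_empty_genera_rejected(self):
        with pytest.raises(ValueError, match="genera"):
            SimulationConfig(genera=())

    def test_bad_weights_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            SimulationConfig(category_weights={"Terpene": 0.5})


class TestGenerateMembership:
    def test_home_is_always_best(self):
        cfg = _one_genus(n_strains=3, seed=12)
        coll, truth = generate_collection(cfg)
        matrix, _ = generate_membership(coll, truth, cfg)
        for rec in coll:
            row = matrix.row(rec.bgc_id)
            home_col = matrix.gcf_ids.index(truth.home_gcf[rec.bgc_id])
            assert row[home_col] == pytest.approx(
                truth.home_distance[rec.bgc_id]
            )
            assert row.min() == row[home_col]
            assert (row > row[home_col]).sum() == len(row) - 1

    def test_tiny_spread_pins_best_to_median(self):
        cfg = _one_genus(median=700.0, n_strains=2, home_sigma=1e-9, seed=3)
        coll, truth = generate_collection(cfg)
        assert all(
            d == pytest.approx(700.0, rel=1e-6)
            for d in truth.home_distance.values()
        )

    def test_genus_medians_recovered(self):
        cfg = SimulationConfig(
            genera=(
                GenusSpec("A", 40, 700.0),
                GenusSpec("B", 40, 1200.0),
            ),
            seed=4,
        )
        coll, truth = generate_collection(cfg)
        for genus, target in (("A", 700.0), ("B", 1200.0)):
            best = [
                truth.home_distance[r.bgc_id] for r in coll if r.genus == genus
            ]
            assert len(best) > 500
            assert np.median(best) == pytest.approx(target, rel=0.05)

    def test_lognormal_median_closed_form(self):
        rng = np.random.default_rng(0)
        draws = draw_best_distances(1004.0, 0.5, 4000, rng)
        assert np.median(draws) == pytest.approx(1004.0, rel=0.05)

    def test_background_below_home_rejected(self):
        cfg = _one_genus(median=908.0, background_median=500.0, seed=1)
        coll, truth = generate_collection(cfg)
        with pytest.raises(ValueError, match="background_median"):
            generate_membership(coll, truth, cfg)

    def test_novelty_flags_consistent_with_threshold(self):
        cfg = _one_genus(n_strains=5, seed=8)
        coll, truth = generate_collection(cfg)
        matrix, catalog = generate_membership(coll, truth, cfg)
        nov = build_novelty_records(matrix, catalog, threshold=cfg.threshold)
        for rec in nov:
            assert (rec.category == "unclustered") == truth.novel[rec.bgc_id]


class TestGenerateFamilies:
    def _mini(self, homes, mibig=()):
        from bgcnovelty.containers import BGCRecord
        from bgcnovelty.synthetic_data import SyntheticTruth

        coll = [
            BGCRecord(f"s{i}", "region001", ("terpene",), "G")
            for i in range(len(homes))
        ]
        truth = SyntheticTruth(
            home_gcf={r.bgc_id: h for r, h in zip(coll, homes)},
            home_distance={}, novel={}, genus_location={},
        )
        catalog = {h: (h in mibig) for h in homes}
        return coll, truth, catalog

    def test_distinct_homes_are_singletons(self):
        coll, truth, catalog = self._mini(["g1", "g2", "g3"])
        fams = generate_families(coll, truth, catalog)
        assert summarize_families(fams).n_singletons == 3

    def test_shared_home_forms_family(self):
        coll, truth, catalog = self._mini(["g1", "g1"])
        fams = generate_families(coll, truth, catalog)
        s = summarize_families(fams)
        assert (s.n_singletons, s.n_families) == (0, 1)

    def test_mibig_home_gets_reference_node(self):
        coll, truth, catalog = self._mini(["g1", "g1"], mibig={"g1"})
        fams = generate_families(coll, truth, catalog)
        fam = fams.family_of[coll[0].bgc_id]
        assert fams.mibig_members(fam) == ["BGC0000001"]
        assert summarize_families(fams).n_families_mibig == 1


class TestReferenceFixture:
    def test_deterministic(self):
        r1, m1, c1, f1 = reference_fixture()
        r2, m2, c2, f2 = reference_fixture()
        assert r1 == r2
        np.testing.assert_array_equal(m1.values, m2.values)
        assert c1 == c2 and f1.family_of == f2.family_of

    def test_collection_shape(self, fixture_data):
        records, matrix, catalog, _ = fixture_data
        assert len(records) == 779
        strains = {r.strain_id for r in records}
        assert len(strains) == 38
        per_strain = {}
        for r in records:
            per_strain[r.strain_id] = per_strain.get(r.strain_id, 0) + 1
        assert all(13 <= n <= 34 for n in per_strain.values())
        assert matrix.shape[0] == 779

    def test_genus_sample_sizes(self, fixture_data):
        records, _, _, _ = fixture_data
        by_genus = {}
        for r in records:
            by_genus[r.genus] = by_genus.get(r.genus, 0) + 1
        assert by_genus["Micromonospora"] == 570
        assert by_genus["Micromonospora_E"] == 147

    def test_best_distance_counts(self, fixture_data):
        records, matrix, _, _ = fixture_data
        best = matrix.values.min(axis=1)
        assert int((best > 900).sum()) == 413
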