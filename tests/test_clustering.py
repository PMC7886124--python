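"""The five-step typing cascade."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst
from sklearn.metrics import adjusted_rand_score

from rgctypes import clustering, synthetic, workflow
from rgctypes.clustering import (
    CellRecord,
    TemplateLibrary,
    assign_step1,
    assign_step5,
    cluster_step4,
    group_step3,
    run_pipeline,
    similarity,
)
from rgctypes.indices import CellProfile
from rgctypes.metrics import ChirpSpectrum


def _spectrum(high=1.0, low=0.0):
    f = np.arange(0.5, 8.001, 0.125)
    ratio = np.where(f >= 4.25, high, low).astype(float)
    return ChirpSpectrum(freqs=f, ratio=ratio, raw_ratio=ratio)


def _profile(pol, trans):
    return CellProfile(unit_id="u", polarity=pol, transiency_ms=trans)


class TestStep1Rules:
    @pytest.mark.parametrize("pol,trans,high,low,expected", [
        ("ON", 200.0, 0.8, 0.3, 1),       # transient ON
        ("OFF", 150.0, 0.9, 0.2, 2),      # transient OFF
        ("ON", 900.0, 0.5, 0.45, 3),      # sustained ON, high-low < 0.2
        ("OFF", 900.0, 0.1, 0.9, 4),      # sustained OFF, any high/low
        ("ON-OFF", 120.0, 0.7, 0.2, 5),   # transient ON-OFF
        ("ON-OFF", 900.0, 0.7, 0.2, None),  # no rule matches
        ("ON", 200.0, 0.3, 0.8, None),    # transient ON with low preference
        ("ON", 900.0, 0.9, 0.3, None),    # sustained ON but high-low >= 0.2
        ("none", 100.0, 0.9, 0.1, None),
    ])
    def test_assignment_rules(self, pol, trans, high, low, expected):
        prof = _profile(pol, trans)
        assert assign_step1(prof, _spectrum(high, low)) == expected


class TestSimilarity:
    def test_identical_traces(self):
        x = np.linspace(0, 1, 50)
        assert similarity(x, x) == 0.0

    def test_one_minus_template(self):
        rng = np.random.default_rng(1)
        t = rng.uniform(size=64)
        assert similarity(1 - t, t) == pytest.approx(np.abs(1 - 2 * t).sum())

    @settings(max_examples=30, derandomize=True)
    @given(hst.integers(min_value=0, max_value=10_000))
    def test_symmetric(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.uniform(size=32), rng.uniform(size=32)
        assert similarity(a, b) == similarity(b, a)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            similarity(np.ones(5), np.ones(6))


def _record(unit_id, chirp_trace, profile=None, **kw):
    return CellRecord(unit_id=unit_id,
                      profile=profile or CellProfile(unit_id=unit_id),
                      chirp_trace=chirp_trace, **kw)


class TestStep2:
    @pytest.fixture()
    def library(self):
        lib = TemplateLibrary(templates=synthetic.make_templates())
        # populate plausible per-cluster statistics directly
        for c in range(1, 6):
            lib.stats[c] = (20.0, 10.0)
        return lib

    def test_identical_to_template_assigned(self, library):
        tpl = library.template_for(3).chirp_values
        rec = _record("u", tpl / tpl.max())
        c, sim = clustering.assign_step2(rec, library)
        assert c == 3 and sim == pytest.approx(0.0)

    def test_all_similarities_above_threshold_unassigned(self, library):
        n = library.template_for(1).chirp_values.size
        rec = _record("u", np.full(n, 1000.0))
        c, _ = clustering.assign_step2(rec, library)
        assert c is None

    def test_empty_cluster_skipped_with_warning(self):
        lib = TemplateLibrary(templates=synthetic.make_templates())
        lib.stats = {1: (20.0, 10.0)}  # clusters 2-5 unpopulated
        n = lib.template_for(1).chirp_values.size
        with pytest.warns(UserWarning):
            clustering.assign_step2(_record("u", np.zeros(n)), lib)

    def test_flashless_sustained_on_reaches_cluster_3(self):
        """A simulated sustained-ON cell never probed with the flash is
        recovered through template matching in step 2."""
        dominants = synthetic.make_archetypes()[:5]
        config = synthetic.PopulationConfig(
            cells_per_archetype=3, noise=0.0, include_gratings=False,
            include_bars=False)
        trains, labels = synthetic.generate_population(config, archetypes=dominants,
                                                       seed=21)
        flashless_cfg = synthetic.PopulationConfig(
            cells_per_archetype=2, noise=0.0, include_gratings=False,
            include_flash=False, include_bars=False)
        extra, extra_labels = synthetic.generate_population(
            flashless_cfg, archetypes=[dominants[2]], seed=22)
        for i, t in enumerate(extra):
            t.unit_id = f"x{i}"
        analyses = workflow.analyze_population(list(trains) + list(extra))
        result = workflow.cluster_population(analyses, seed=0, repetitions=50)
        by_unit = {a.unit_id: a for a in result.assignments}
        for i in range(len(extra)):
            a = by_unit[f"x{i}"]
            assert a.step == 2
            assert a.cluster == 3


class TestStep3:
    def test_flash_polarity_routing(self):
        assert group_step3(_record("u", None, _profile("ON", 100.0)))[0] == 6
        assert group_step3(_record("u", None, _profile("OFF", 100.0)))[0] == 7
        assert group_step3(_record("u", None, _profile("none", None)))[0] == 8

    def test_on_off_routed_by_peak_and_logged(self):
        c, note = group_step3(_record("u", None, _profile("ON-OFF", 100.0)))
        assert c in (6, 7)
        assert "ON-OFF" in note


class TestStep4:
    def test_model_selection_on_separated_archetypes(self, separated_maps):
        X, truth = separated_maps
        model = cluster_step4(list(X), seed=0, repetitions=200)
        assert model.k == 3
        assert adjusted_rand_score(truth, model.labels) == 1.0

    def test_identical_maps_degenerate(self):
        maps = [np.ones(24)] * 10
        with pytest.raises(ValueError):
            cluster_step4(maps, seed=0)

    def test_same_seed_identical_labels(self, separated_maps):
        X, _ = separated_maps
        a = cluster_step4(list(X), seed=3, repetitions=20)
        b = cluster_step4(list(X), seed=3, repetitions=20)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_thousand_restarts_match_brute_force_optimum(self):
        """k-means with many restarts attains the global 2-partition optimum
        found by exhaustive enumeration (n = 10 points)."""
        rng = np.random.default_rng(8)
        pts = rng.uniform(0, 1, size=(10, 2))
        best_sse = np.inf
        for assignment in itertools.product([0, 1], repeat=9):
            labels = np.array((0,) + assignment)
            if labels.max() == 0:
                continue
            sse = sum(((pts[labels == g] - pts[labels == g].mean(0)) ** 2).sum()
                      for g in (0, 1))
            best_sse = min(best_sse, sse)
        from sklearn.cluster import KMeans
        km = KMeans(n_clusters=2, n_init=1000, random_state=0).fit(pts)
        assert km.inertia_ == pytest.approx(best_sse, rel=1e-9)


class TestStep5:
    def test_map_equal_to_cluster_mean_assigned(self):
        means = {9: np.full(24, 0.5), 10: np.zeros(24)}
        sims = {9: np.array([1.0, 2.0, 3.0]), 10: np.array([1.0, 1.0])}
        c, sim = assign_step5(np.full(24, 0.5), means, sims)
        assert c == 9 and sim == 0.0

    def test_beyond_percentile_unassigned(self):
        means = {9: np.zeros(24)}
        sims = {9: np.array([0.1, 0.2, 0.3])}
        c, sim = assign_step5(np.full(24, 1.0), means, sims)
        assert c is None and sim == pytest.approx(24.0)

    def test_small_clusters_excluded(self):
        means = {9: np.zeros(24)}
        sims = {9: np.array([0.1])}  # fewer than 2 members
        c, _ = assign_step5(np.zeros(24), means, sims)
        assert c is None

    def test_held_out_cells_rejoin_their_archetype_cluster(self):
        """Noise-free held-out grating-only cells, never probed with the chirp,
        are assigned by step 5 to the cluster of their archetype mates."""
        grating_only = [a for a in synthetic.make_archetypes()
                        if not a.responds_to_fullfield]
        config = synthetic.PopulationConfig(cells_per_archetype=6, noise=0.3,
                                            include_bars=False)
        trains, labels = synthetic.generate_population(config,
                                                       archetypes=grating_only,
                                                       seed=31)
        held_cfg = synthetic.PopulationConfig(
            cells_per_archetype=3, noise=0.0, include_chirp=False,
            include_contrast_ramp=False, include_flash=False, include_bars=False)
        held, held_labels = synthetic.generate_population(
            held_cfg, archetypes=grating_only, seed=32)
        for i, t in enumerate(held):
            t.unit_id = f"h{i:02d}"
        analyses = workflow.analyze_population(list(trains) + list(held))
        result = workflow.cluster_population(analyses, seed=0, repetitions=100,
                                             k_range=(2, 6))
        by_unit = {a.unit_id: a for a in result.assignments}
        main_cluster = {}
        for a, l in zip(result.assignments[:len(trains)], labels):
            main_cluster.setdefault(l.true_cluster, []).append(a.cluster)
        majority = {k: max(set(v), key=v.count) for k, v in main_cluster.items()}
        hits = sum(
            1 for i, l in enumerate(held_labels)
            if by_unit[f"h{i:02d}"].cluster == majority[l.true_cluster]
        )
        assert hits >= 0.9 * len(held)


class TestPipeline:
    def test_partition_property(self, mixed_population):
        _, _, analyses = mixed_population
        result = workflow.cluster_population(analyses, seed=0, repetitions=50)
        assert len(result.assignments) == len(analyses)
        assert len({a.unit_id for a in result.assignments}) == len(analyses)
        for a in result.assignments:
            if a.cluster is not None:
                lo, hi = {1: (1, 5), 2: (1, 5), 3: (6, 8),
                          4: (9, 16), 5: (1, 16)}[a.step]
                assert lo <= a.cluster <= hi
        total = sum(result.step_counts.values())
        assert total == len(analyses)

    def test_chirp_unprobed_cells_go_through_step5(self, mixed_population):
        _, _, analyses = mixed_population
        records = workflow.records_from_analyses(analyses)
        moved = 0
        for r in records:
            if r.responds_to_gratings and moved < 4:
                r.chirp_probed = False
                r.responds_to_chirp = False
                moved += 1
        library = TemplateLibrary(templates=synthetic.make_templates())
        result = run_pipeline(records, library, seed=0, repetitions=50)
        by_unit = {a.unit_id: a for a in result.assignments}
        for r in records:
            if not r.chirp_probed:
                a = by_unit[r.unit_id]
                assert a.step in (5, None)

    def test_empty_input(self):
        library = TemplateLibrary(templates=synthetic.make_templates())
        result = run_pipeline([], library, seed=0)
        assert result.assignments == []

    def test_dominant_only_population_stops_at_step2(self):
        dominants = synthetic.make_archetypes()[:5]
        config = synthetic.PopulationConfig(
            cells_per_archetype=2, noise=0.0, include_gratings=False,
            include_bars=False)
        trains, _ = synthetic.generate_population(config, archetypes=dominants,
                                                  seed=17)
        analyses = workflow.analyze_population(trains)
        result = workflow.cluster_population(analyses, seed=0, repetitions=50)
        c = result.step_counts
        assert c["step1"] + c["step2"] + c["step3"] == 10
        assert c["step4"] == 0 and c["step5"] == 0
        # the overwhelming majority match by rule already in step 1
        assert c["step1"] >= 8
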