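"""Classification, multiplex resolution and curve clustering."""

import numpy as np
import pytest

from meltid import synthdata
from meltid.assign import (
    Assignment,
    ClusterResult,
    build_reference_library,
    classify,
    cluster_groups,
    curve_distance,
    multiplex_resolve,
)
from meltid.meltproc import DifferenceCurve, MeltCurve, call_tm, process_dataset


def curve(values, sid="c", grid=None, **kw):
    values = np.asarray(values, dtype=float)
    if grid is None:
        grid = 65.0 + 0.1 * np.arange(values.size)
    return MeltCurve(np.asarray(grid, float), values, sid, **kw)


class TestCurveDistance:
    def test_identity_is_zero(self):
        a = curve([1.0, 2.0, 3.0])
        assert curve_distance(a, a) == 0.0

    def test_euclidean_3_4_5(self):
        a = curve([0.0, 0.0], grid=[65.0, 65.1])
        b = curve([3.0, 4.0], grid=[65.0, 65.1])
        assert curve_distance(a, b) == pytest.approx(5.0)

    def test_max_abs(self):
        a = curve([0.0, 0.0], grid=[65.0, 65.1])
        b = curve([3.0, 4.0], grid=[65.0, 65.1])
        assert curve_distance(a, b, metric="max_abs") == pytest.approx(4.0)

    def test_tm_delta(self):
        a = curve([0, 1, 0], sid="a"); a.tm = 70.0
        b = curve([0, 1, 0], sid="b"); b.tm = 72.5
        assert curve_distance(a, b, metric="tm_delta") == pytest.approx(2.5)

    def test_grid_mismatch_and_unknown_metric(self):
        a = curve([0.0, 0.0], grid=[65.0, 65.1])
        b = curve([0.0, 0.0], grid=[65.0, 65.2])
        with pytest.raises(ValueError, match="grid"):
            curve_distance(a, b)
        with pytest.raises(ValueError, match="metric"):
            curve_distance(a, a, metric="cosine")

    def test_symmetry(self):
        a = curve([1.0, 5.0, 2.0])
        b = curve([0.0, 1.0, 9.0])
        for m in ("euclidean", "max_abs"):
            assert curve_distance(a, b, metric=m) == curve_distance(b, a, metric=m)


class TestBuildReferenceLibrary:
    def test_eight_labels_five_replicates(self, eight_species_fixture):
        curves = process_dataset(eight_species_fixture["dataset"])
        lib = build_reference_library(curves)
        assert len(lib.entries) == 8
        assert lib.replicate_spread is not None and lib.replicate_spread > 0

    def test_single_labeled_curve(self):
        c = curve([0, 1, 0], sid="w", label="x")
        lib = build_reference_library([c])
        assert lib.labels == ["x"] and lib.replicate_spread is None

    def test_conflicting_grids_rejected(self):
        a = curve([0, 1, 0], sid="a", label="x")
        b = MeltCurve(np.array([65.0, 65.2, 65.4]), np.array([0.0, 1.0, 0.0]), "b", label="x")
        with pytest.raises(ValueError):
            build_reference_library([a, b])

    def test_unlabeled_curve_rejected(self):
        with pytest.raises(ValueError, match="unlabeled"):
            build_reference_library([curve([0, 1, 0])])


def toy_library():
    grid = np.linspace(70, 85, 151)
    def peak(tm):
        return np.exp(-((grid - tm) ** 2) / 0.5)
    curves = []
    for label, tm in [("near", 74.0), ("far", 80.0)]:
        for r in range(3):
            curves.append(MeltCurve(grid, peak(tm), f"{label}{r}", label=label))
    return build_reference_library(curves), grid, peak


class TestClassify:
    def test_exact_library_member_assigned(self):
        lib, grid, peak = toy_library()
        q = MeltCurve(grid, peak(74.0), "q")
        a = classify(q, lib, reject=1.0, margin=0.5)
        assert a.status == "assigned" and a.best_label == "near"
        assert a.candidates[0][1] == pytest.approx(0.0)

    def test_midpoint_query_ambiguous(self):
        lib, grid, peak = toy_library()
        q = MeltCurve(grid, 0.5 * (peak(74.0) + peak(80.0)), "q")
        a = classify(q, lib, reject=10.0, margin=0.5)
        assert a.status == "ambiguous"
        assert len(a.candidates) == 2

    def test_distant_query_unassigned(self):
        lib, grid, peak = toy_library()
        q = MeltCurve(grid, 50.0 + 0 * grid, "q")
        a = classify(q, lib, reject=1.0, margin=0.5)
        assert a.status == "unassigned" and a.best_label is None

    def test_scale_consistency(self):
        """Scaling curves by c scales distances by c; assignments survive
        when thresholds are scaled likewise."""
        lib, grid, peak = toy_library()
        q = MeltCurve(grid, peak(74.3), "q")
        a1 = classify(q, lib, reject=2.0, margin=0.5)
        c = 7.0
        scaled_entries = []
        for label, e in lib.entries.items():
            for r in range(2):
                scaled_entries.append(MeltCurve(grid, c * e.dneg, f"{label}s{r}", label=label))
        lib2 = build_reference_library(scaled_entries)
        q2 = MeltCurve(grid, c * peak(74.3), "q")
        a2 = classify(q2, lib2, reject=2.0 * c, margin=0.5 * c)
        assert a1.status == a2.status == "assigned"
        assert a1.best_label == a2.best_label
        assert a2.candidates[0][1] == pytest.approx(c * a1.candidates[0][1])

    def test_abstention_monotone_in_margin(self):
        """Raising the ambiguity margin never turns ambiguous into assigned."""
        lib, grid, peak = toy_library()
        q = MeltCurve(grid, peak(76.0), "q")
        statuses = [classify(q, lib, reject=100.0, margin=m).status
                    for m in (0.01, 0.5, 2.0, 10.0)]
        seen_ambiguous = False
        for s in statuses:
            if seen_ambiguous:
                assert s == "ambiguous"
            seen_ambiguous = seen_ambiguous or s == "ambiguous"

    def test_200_seeded_queries_100pct_correct(self, eight_species_fixture):
        fx = eight_species_fixture
        lib = build_reference_library(process_dataset(fx["dataset"]))
        params = synthdata.MeltModelParams(
            noise_sd=fx["dataset"].meta["noise_sd"], seed=12345)
        qds, _ = synthdata.simulate_melt_plate(fx["amplicons"], params, replicates=25)
        queries = process_dataset(qds)
        assert len(queries) == 200
        for q in queries:
            a = classify(q, lib)
            assert a.status == "assigned" and a.best_label == q.label


class TestMultiplexResolve:
    def ambiguous(self):
        return Assignment("s1", "ambiguous", "cali",
                          [("cali", 0.1), ("longa", 0.12)], margin=0.02)

    def rule(self):
        return {"cali": (75.0, 76.0), "longa": (72.0, 73.0)}

    def mx_curve(self, tm):
        grid = np.linspace(65, 95, 301)
        y = np.exp(-((grid - tm) ** 2) / 0.5)
        return call_tm(MeltCurve(grid, y, "s1_mx"))

    def test_peak_in_one_window_assigns(self):
        r = multiplex_resolve(self.ambiguous(), self.mx_curve(75.4), self.rule())
        assert r.status == "assigned" and r.best_label == "cali"
        assert r.method == "multiplex"

    def test_no_peak_unassigns(self):
        grid = np.linspace(65, 95, 301)
        flat = MeltCurve(grid, np.linspace(0, 1, 301), "s1_mx")
        call_tm(flat)
        r = multiplex_resolve(self.ambiguous(), flat, self.rule())
        assert r.status == "unassigned"

    def test_tm_between_windows_stays_out(self):
        r = multiplex_resolve(self.ambiguous(), self.mx_curve(74.0), self.rule())
        assert r.status == "unassigned"

    def test_overlapping_windows_keep_ambiguous(self):
        rule = {"cali": (74.0, 76.0), "longa": (75.0, 77.0)}
        r = multiplex_resolve(self.ambiguous(), self.mx_curve(75.5), rule)
        assert r.status == "ambiguous"

    def test_rule_with_foreign_label_rejected(self):
        rule = {"cali": (75.0, 76.0), "other": (60.0, 61.0)}
        with pytest.raises(ValueError, match="absent"):
            multiplex_resolve(self.ambiguous(), self.mx_curve(75.4), rule)

    def test_non_ambiguous_input_rejected(self):
        a = Assignment("s1", "assigned", "cali", [("cali", 0.1)], margin=1.0)
        with pytest.raises(ValueError, match="ambiguous"):
            multiplex_resolve(a, self.mx_curve(75.4), self.rule())

    def test_fixture_ambiguity_resolved_end_to_end(self, ambiguity_fixture):
        fx = ambiguity_fixture
        lib = build_reference_library(process_dataset(fx["dataset"]))
        unknowns = process_dataset(fx["unknown_dataset"])
        mx = {c.source_id: c for c in process_dataset(fx["multiplex_dataset"])}
        for q in unknowns:
            a = classify(q, lib)
            assert a.status == "ambiguous"
            base = q.source_id.rsplit("_r", 1)[0]
            resolved = multiplex_resolve(a, mx[f"{base}_mx_r1"], fx["multiplex_rule"])
            assert resolved.status == "assigned"
            assert resolved.best_label == fx["unknown_truth"][base]


class TestClusterGroups:
    def planted(self, tms, n_each=5, noise=0.01, seed=0):
        params = synthdata.MeltModelParams(
            noise_sd=noise / synthdata.DERIVATIVE_NOISE_GAIN, seed=seed)
        labels = {f"t{i}": tm for i, tm in enumerate(tms)}
        ds, truth = synthdata.simulate_melt_plate(labels, params, replicates=n_each)
        curves = process_dataset(ds)
        from meltid.meltproc import difference_curves
        return difference_curves(curves), truth

    def test_three_planted_clusters_recovered(self):
        diffs, truth = self.planted([74.0, 75.0, 76.0], seed=21)
        res = cluster_groups(diffs)
        assert res.n_groups == 3
        well_label = dict(zip(truth["well"], truth["label"]))
        for g in range(1, 4):
            labels = {well_label[w] for w in res.members(g)}
            assert len(labels) == 1  # perfect membership

    def test_identical_curves_one_group(self):
        grid = np.linspace(70, 80, 101)
        diffs = [DifferenceCurve(grid, np.zeros(101), f"w{i}") for i in range(4)]
        assert cluster_groups(diffs, cut=0.5).n_groups == 1

    def test_single_curve_rejected(self):
        grid = np.linspace(70, 80, 101)
        with pytest.raises(ValueError, match="at least 2"):
            cluster_groups([DifferenceCurve(grid, np.zeros(101), "w")])

    def test_permutation_invariant_partition(self):
        diffs, _ = self.planted([74.0, 76.0], n_each=3, seed=5)
        res1 = cluster_groups(diffs)
        res2 = cluster_groups(list(reversed(diffs)))
        # same partition, indices canonical by first occurrence
        def partition(res):
            groups = {}
            for sid, g in res.groups.items():
                groups.setdefault(g, set()).add(sid)
            return {frozenset(v) for v in groups.values()}
        assert partition(res1) == partition(res2)
        assert res2.groups[diffs[-1].source_id] == 1

    def test_chlorotica_fixture_three_groups(self, chlorotica_fixture):
        curves = process_dataset(chlorotica_fixture["dataset"])
        from meltid.meltproc import difference_curves
        res = cluster_groups(difference_curves(curves))
        assert res.n_groups == 3
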