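"""Hungarian matching, detection metrics, PR curves and xi selection."""

from itertools import permutations

import numpy as np
import pytest

from micronet.evaluation import (
    MatchReport,
    aggregate,
    match,
    metrics,
    pooled_metrics,
    pr_curve,
    select_xi,
)


def oracle_match_counts(dets, anns, radius):
    """Exhaustive assignment oracle: maximize the number of pairs within
    ``radius``, tie-broken by minimal total distance.  Returns (tp, total
    distance)."""
    if not dets or not anns:
        return 0, 0.0
    d = np.asarray(dets, float)
    a = np.asarray(anns, float)
    dist = np.sqrt(((d[:, None] - a[None]) ** 2).sum(-1))
    n, m = len(dets), len(anns)
    best = (0, 0.0)
    if n <= m:
        for perm in permutations(range(m), n):
            pairs = [(i, j) for i, j in enumerate(perm) if dist[i, j] <= radius]
            tp = len(pairs)
            total = sum(dist[i, j] for i, j in pairs)
            if tp > best[0] or (tp == best[0] and (best[0] == 0 or total < best[1])):
                best = (tp, total)
    else:
        for perm in permutations(range(n), m):
            pairs = [(i, j) for j, i in enumerate(perm) if dist[i, j] <= radius]
            tp = len(pairs)
            total = sum(dist[i, j] for i, j in pairs)
            if tp > best[0] or (tp == best[0] and (best[0] == 0 or total < best[1])):
                best = (tp, total)
    return best


class TestMatch:
    def test_exact_hit(self):
        report = match([(5.0, 5.0)], [(5.0, 5.0)])
        assert report.tp == 1 and not report.fp and not report.fn
        assert report.tp_pairs[0][2] == 0.0

    def test_sixteen_pixel_rule(self):
        # a detection 17 px from the only annotation is outside the gold disk
        report = match([(0.0, 17.0)], [(0.0, 0.0)], radius=16.0)
        assert (report.tp, len(report.fp), len(report.fn)) == (0, 1, 1)
        inside = match([(0.0, 15.5)], [(0.0, 0.0)], radius=16.0)
        assert inside.tp == 1

    def test_worked_example_vs_bruteforce(self):
        anns = [(10.0, 10.0), (30.0, 30.0)]
        dets = [(12.0, 10.0), (29.0, 31.0), (50.0, 50.0)]
        report = match(dets, anns, radius=16.0)
        assert report.tp == 2
        dists = sorted(d for _, _, d in report.tp_pairs)
        assert dists == pytest.approx([np.sqrt(2.0), 2.0])
        assert report.fp == [(50.0, 50.0)]
        tp, total = oracle_match_counts(dets, anns, 16.0)
        assert tp == report.tp
        assert total == pytest.approx(sum(d for _, _, d in report.tp_pairs))

    def test_empty_inputs(self):
        assert match([], [], radius=16.0).tp == 0
        r = match([], [(1.0, 1.0)])
        assert len(r.fn) == 1
        r = match([(1.0, 1.0)], [])
        assert len(r.fp) == 1

    def test_invalid_radius(self):
        with pytest.raises(ValueError):
            match([], [], radius=0.0)

    @pytest.mark.parametrize("seed", range(30))
    def test_count_conservation_and_optimality(self, seed):
        rng = np.random.default_rng(seed)
        n, m = rng.integers(0, 6, 2)
        dets = [tuple(rng.uniform(0, 60, 2)) for _ in range(n)]
        anns = [tuple(rng.uniform(0, 60, 2)) for _ in range(m)]
        report = match(dets, anns, radius=16.0)
        assert report.tp + len(report.fn) == m
        assert report.tp + len(report.fp) == n
        assert all(d <= 16.0 for _, _, d in report.tp_pairs)
        tp, total = oracle_match_counts(dets, anns, 16.0)
        assert report.tp == tp
        assert sum(d for _, _, d in report.tp_pairs) == pytest.approx(total)

    def test_symmetric_under_reordering(self):
        rng = np.random.default_rng(5)
        dets = [tuple(rng.uniform(0, 40, 2)) for _ in range(5)]
        anns = [tuple(rng.uniform(0, 40, 2)) for _ in range(4)]
        a = match(dets, anns)
        b = match(dets[::-1], anns[::-1])
        assert a.tp == b.tp
        assert sorted(d for *_, d in a.tp_pairs) == pytest.approx(
            sorted(d for *_, d in b.tp_pairs)
        )


class TestMetrics:
    def test_printed_formulas(self):
        report = MatchReport(
            tp_pairs=[((0, 0), (0, 0), 1.0)] * 8,
            fp=[(0, 0)] * 2,
            fn=[(0, 0)] * 2,
        )
        s = metrics(report)
        assert (s.precision, s.recall, s.f1) == (0.8, 0.8, pytest.approx(0.8))
        assert s.mean_ed == 1.0

    def test_no_detections_convention(self):
        s = metrics(MatchReport(fn=[(0, 0), (1, 1)]))
        assert (s.precision, s.recall, s.f1) == (0.0, 0.0, 0.0)

    def test_empty_scene_convention(self):
        s = metrics(MatchReport())
        assert (s.precision, s.recall, s.f1) == (1.0, 1.0, 1.0)

    def test_perfect_detection(self):
        report = MatchReport(tp_pairs=[((1, 1), (1, 1), 0.0)] * 3)
        s = metrics(report)
        assert (s.precision, s.recall, s.f1, s.mean_ed) == (1.0, 1.0, 1.0, 0.0)

    def test_f1_is_harmonic_mean(self):
        report = MatchReport(
            tp_pairs=[((0, 0), (0, 0), 2.0)] * 6, fp=[(0, 0)] * 4, fn=[(0, 0)]
        )
        s = metrics(report)
        assert s.f1 == pytest.approx(2 * s.precision * s.recall / (s.precision + s.recall))

    def test_pooled_micro_average(self):
        r1 = MatchReport(tp_pairs=[((0, 0), (0, 0), 1.0)], fp=[(0, 0)])
        r2 = MatchReport(tp_pairs=[((0, 0), (0, 0), 3.0)] * 3, fn=[(0, 0)])
        s = pooled_metrics([r1, r2])
        assert s.tp == 4 and s.fp == 1 and s.fn == 1
        assert s.precision == pytest.approx(4 / 5)
        assert s.mean_ed == pytest.approx(2.5)


class TestXiSelectionAndCurves(object):
    def test_single_grid_point(self, desk_run):
        samples = desk_run["corpus"]["val"][:5]
        net = desk_run["network"]
        curve = pr_curve(net, samples, [0.3])
        assert len(curve) == 1
        assert select_xi(net, samples, [0.3]) == 0.3

    def test_recall_nonincreasing_in_xi(self, desk_run):
        grid = [0.05, 0.2, 0.4, 0.6, 0.8, 0.95]
        curve = pr_curve(desk_run["network"], desk_run["corpus"]["val"][:8], grid)
        recalls = [r for _, _, r in curve]
        assert all(b <= a + 1e-12 for a, b in zip(recalls, recalls[1:]))

    def test_selected_xi_is_grid_argmax(self, desk_run):
        from micronet.evaluation import _evaluate_grid

        net = desk_run["network"]
        samples = desk_run["corpus"]["val"][:8]
        grid = [0.1, 0.3, 0.5, 0.7]
        xi = select_xi(net, samples, grid)
        summaries = _evaluate_grid(net, samples, grid, 16.0, 6)
        best = max(s.f1 for s in summaries)
        chosen = dict(zip(grid, summaries))[xi].f1
        assert chosen == pytest.approx(best)

    def test_tie_breaks_toward_larger_xi(self, monkeypatch):
        import micronet.evaluation as ev

        class S:
            f1 = 0.5

        monkeypatch.setattr(ev, "_evaluate_grid", lambda *a, **k: [S(), S(), S()])
        assert ev.select_xi(object(), [1], [0.1, 0.2, 0.3]) == 0.3


class TestAggregate:
    def test_single_dataset_sd_zero(self):
        from micronet.evaluation import MetricSummary

        s = MetricSummary(0.9, 0.8, 0.85, 2.0, 9, 1, 2)
        agg = aggregate([s])
        assert agg["f1"] == (0.85, 0.0)

    def test_identical_summaries(self):
        from micronet.evaluation import MetricSummary

        s = MetricSummary(0.9, 0.8, 0.85, 2.0, 9, 1, 2)
        assert aggregate([s, s, s])["precision"] == (pytest.approx(0.9), pytest.approx(0.0))

    def test_matches_two_pass_mean_sd(self):
        from micronet.evaluation import MetricSummary

        f1s = [0.7, 0.8, 0.9, 0.6]
        summaries = [MetricSummary(0.5, 0.5, f, 1.0, 1, 1, 1) for f in f1s]
        mean, sd = aggregate(summaries)["f1"]
        n = len(f1s)
        m = sum(f1s) / n
        var = sum((v - m) ** 2 for v in f1s) / (n - 1)
        assert mean == pytest.approx(m)
        assert sd == pytest.approx(var**0.5)
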