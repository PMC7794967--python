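"""Normalisation, weighted PSR composition and natural-breaks classing."""

import itertools

import numpy as np
import pytest

from karsthealth.composite import (HEALTH_CLASSES, WeightEntry, WeightScheme,
                                   classify, classify_esh, compute_esh, esh,
                                   jenks_breaks, layer_subscore, normalize)
from karsthealth.grid import IndicatorLayer


def layer(values, name="x", epoch=2000):
    return IndicatorLayer(name, epoch, np.asarray(values, dtype=float))


class TestNormalize:
    def test_boundary_cases(self):
        pos = normalize([layer([2.0, 4.0, 10.0])], "positive")[0].values
        assert pos[0] == 0.0 and pos[2] == 1.0
        neg = normalize([layer([2.0, 4.0, 10.0])], "negative")[0].values
        assert neg[0] == 1.0 and neg[2] == 0.0

    def test_midpoint_is_half(self):
        for direction in ("positive", "negative"):
            q = normalize([layer([0.0, 5.0, 10.0])], direction)[0].values
            assert q[1] == pytest.approx(0.5)

    def test_pool_example(self):
        q = normalize([layer([2.0, 4.0, 10.0])], "positive")[0].values
        assert np.allclose(q, [0.0, 0.25, 1.0])

    def test_min_max_pooled_across_epochs(self):
        layers = [layer([0.0, 1.0], epoch=1990), layer([3.0, 4.0], epoch=2000)]
        q90, q00 = normalize(layers, "positive")
        assert q90.values[0] == 0.0
        assert q00.values[1] == 1.0
        assert q90.values[1] == pytest.approx(0.25)

    def test_missing_propagates(self):
        q = normalize([layer([1.0, np.nan, 3.0])], "positive")[0].values
        assert np.isnan(q[1]) and q[2] == 1.0

    def test_constant_indicator_degenerates_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            q = normalize([layer([5.0, 5.0])], "positive")[0].values
        assert np.allclose(q, 0.5)


class TestWeightScheme:
    def test_defaults_sum_to_one_and_layer_subtotals(self):
        w = WeightScheme()
        assert sum(e.weight for e in w.entries) == pytest.approx(1.0, abs=1e-12)
        assert w.layer_weight("pressure") == pytest.approx(0.42)
        assert w.layer_weight("state") == pytest.approx(0.43)
        assert w.layer_weight("response") == pytest.approx(0.15)

    def test_non_unit_sum_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            WeightScheme([WeightEntry("a", "pressure", "positive", 0.5)])

    def test_pressure_indicators_carry_negative_direction(self):
        w = WeightScheme()
        for e in w.layer_entries("pressure"):
            assert e.direction == "negative"


class TestComposition:
    def test_all_q_one_recovers_layer_totals_and_unit_esh(self):
        w = WeightScheme()
        ones = {e.indicator: layer(np.ones(4), name=e.indicator)
                for e in w.entries}
        p = layer_subscore(ones, w, "pressure")
        s = layer_subscore(ones, w, "state")
        r = layer_subscore(ones, w, "response")
        assert np.allclose(p.values, 0.42)
        assert np.allclose(s.values, 0.43)
        assert np.allclose(r.values, 0.15)
        assert np.allclose(esh(p, s, r).values, 1.0)

    def test_all_q_zero_gives_zero(self):
        w = WeightScheme()
        zeros = {e.indicator: layer(np.zeros(3), name=e.indicator)
                 for e in w.entries}
        assert np.allclose(
            layer_subscore(zeros, w, "state").values, 0.0)

    def test_published_buffer_rows_sum(self):
        """The additive combiner reproduces the printed buffer-zone health
        values from their printed subscores."""
        p, s, r = layer([0.321]), layer([0.240]), layer([0.071])
        assert esh(p, s, r).values[0] == pytest.approx(0.632, abs=5e-4)
        p, s, r = layer([0.336]), layer([0.251]), layer([0.067])
        assert esh(p, s, r).values[0] == pytest.approx(0.654, abs=5e-4)

    def test_missing_indicator_rejected_by_name(self):
        w = WeightScheme()
        partial = {e.indicator: layer(np.ones(2), name=e.indicator)
                   for e in w.entries if e.indicator != "esv"}
        with pytest.raises(ValueError, match="esv"):
            layer_subscore(partial, w, "state")

    def test_esh_monotone_in_every_indicator(self):
        rng = np.random.default_rng(21)
        w = WeightScheme()
        base = {e.indicator: layer(rng.uniform(0, 1, 5), name=e.indicator)
                for e in w.entries}
        def total(q):
            return esh(layer_subscore(q, w, "pressure"),
                       layer_subscore(q, w, "state"),
                       layer_subscore(q, w, "response")).values
        t0 = total(base)
        for name in list(base):
            bumped = dict(base)
            bumped[name] = base[name].with_values(
                np.minimum(base[name].values + 0.1, 1.0))
            assert (total(bumped) >= t0 - 1e-12).all()

    def test_compute_esh_end_to_end_bounds(self):
        rng = np.random.default_rng(22)
        w = WeightScheme()
        series = {e.indicator: [layer(rng.uniform(0, 10, 6), name=e.indicator,
                                      epoch=y) for y in (1990, 2000)]
                  for e in w.entries}
        results = compute_esh(series, w)
        for res in results:
            assert np.all((res.esh.values >= -1e-12)
                          & (res.esh.values <= 1 + 1e-12))
            assert np.allclose(res.esh.values,
                               res.pressure.values + res.state.values
                               + res.response.values, atol=1e-12)


def bruteforce_jenks(values, k):
    """Exhaustive search over all contiguous partitions of the sorted values."""
    v = np.sort(np.asarray(values, dtype=float))
    n = v.size
    best_cost, best_breaks = np.inf, None
    for cuts in itertools.combinations(range(1, n), k - 1):
        edges = [0, *cuts, n]
        cost = sum(float(np.sum((v[a:b] - v[a:b].mean()) ** 2))
                   for a, b in zip(edges, edges[1:]))
        if cost < best_cost - 1e-12:
            best_cost = cost
            best_breaks = [v[c - 1] for c in cuts]
    return best_cost, best_breaks


class TestJenks:
    def test_two_clusters_split_at_gap(self):
        breaks = jenks_breaks([1, 2, 3, 10, 11, 12], k=2)
        assert len(breaks) == 1
        assert 3 <= breaks[0] < 10

    def test_saturated_partition(self):
        breaks = jenks_breaks([1.0, 5.0, 9.0], k=3)
        assert np.allclose(breaks, [1.0, 5.0])

    @pytest.mark.parametrize("n,k", [(6, 2), (8, 3), (10, 4), (12, 5)])
    def test_matches_exhaustive_optimum(self, n, k):
        rng = np.random.default_rng(n * 100 + k)
        for _ in range(5):
            v = rng.uniform(0, 100, n)
            breaks = jenks_breaks(v, k)
            cost_dp = _partition_cost(v, breaks)
            cost_bf, _ = bruteforce_jenks(v, k)
            assert cost_dp == pytest.approx(cost_bf, abs=1e-8)

    def test_too_few_distinct_values_reduces_k(self):
        with pytest.warns(UserWarning, match="distinct"):
            breaks = jenks_breaks([1.0, 1.0, 2.0], k=5)
        assert len(breaks) == 1


def _partition_cost(values, breaks):
    v = np.sort(np.asarray(values, dtype=float))
    cls = np.searchsorted(np.asarray(breaks), v, side="left")
    return sum(((v[cls == c] - v[cls == c].mean()) ** 2).sum()
               for c in np.unique(cls))


class TestClassify:
    def test_extremes_and_partition(self):
        breaks = np.array([0.2, 0.4, 0.6, 0.8])
        vals = np.array([0.1, 0.5, 0.9, np.nan])
        cls = classify(vals, breaks)
        assert HEALTH_CLASSES[cls[0]] == "ill"
        assert HEALTH_CLASSES[cls[1]] == "middle"
        assert HEALTH_CLASSES[cls[2]] == "excellent healthy"
        assert cls[3] == -1

    def test_boundary_value_goes_to_lower_class(self):
        cls = classify(np.array([0.2]), np.array([0.2, 0.4, 0.6, 0.8]))
        assert cls[0] == 0

    def test_class_shares_partition_non_missing(self):
        rng = np.random.default_rng(30)
        vals = rng.uniform(0, 1, 200)
        breaks = jenks_breaks(vals, 5)
        cls = classify(vals, breaks)
        assert (cls >= 0).all()
        assert np.bincount(cls, minlength=5).sum() == 200
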