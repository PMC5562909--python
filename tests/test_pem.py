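"""PEM kernel interpolation: distances, weights, prediction, validation."""

import numpy as np
import pytest

from pemnet.clustering import fit_patterns
from pemnet.pem import (
    ReferenceEntry,
    ReferenceSet,
    general_distance,
    load_references,
    pem_predict,
    pem_predict_charges,
    pem_weights,
    predict_timeseries,
    save_references,
    select_references,
    validate,
)


def _refs_from_arrays(x, t, charges=None, patterns=None, circular=True):
    entries = []
    for i in range(len(x)):
        entries.append(ReferenceEntry(
            descriptors=np.asarray(x[i], float),
            properties={"e": float(t[i])},
            charges=None if charges is None else np.asarray(charges[i], float),
            pattern=0 if patterns is None else int(patterns[i]),
        ))
    return ReferenceSet(entries=entries, circular=circular)


def _naive_shepard(x, xr, t, p_w, circular=True):
    """Independent direct-summation oracle for the ensemble prediction."""
    from pemnet.descriptors import wrap_difference
    u = []
    for row in xr:
        d = wrap_difference(x, row) if circular else np.asarray(x) - row
        u.append(np.sqrt(np.sum(np.asarray(d) ** 2)))
    u = np.array(u)
    if np.any(u == 0):
        w = (u == 0) / np.sum(u == 0)
    else:
        w = u ** (-p_w) / np.sum(u ** (-p_w))
    return float(np.sum(w * t)), w


class TestGeneralDistance:
    def test_zero_at_identity(self):
        assert general_distance([10.0, -30.0], [10.0, -30.0]) == 0.0

    def test_pythagorean(self):
        assert general_distance([3.0, 4.0, 7.0], [0.0, 0.0, 7.0],
                                circular=False) == pytest.approx(5.0)

    def test_wrapped_difference_across_seam(self):
        assert general_distance([179.0], [-179.0]) == pytest.approx(2.0)
        # raw mode sees the artificial 358-degree gap
        assert general_distance([179.0], [-179.0],
                                circular=False) == pytest.approx(358.0)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            general_distance([1.0], [1.0, 2.0])


class TestPemWeights:
    def test_single_reference_weight_one(self):
        refs = _refs_from_arrays([[0.0, 0.0]], [1.0])
        w = pem_weights([30.0, 40.0], refs)
        assert w.weights == pytest.approx([1.0])

    def test_equidistant_references_split_evenly(self):
        refs = _refs_from_arrays([[10.0], [-10.0]], [0.0, 1.0])
        for p_w in (1.0, 2.0, 4.0):
            w = pem_weights([0.0], refs, p_w=p_w)
            assert w.weights == pytest.approx([0.5, 0.5])

    def test_distance_1_and_2_pw4(self):
        """Direct evaluation: w = (1, 1/16)/(1 + 1/16) = (16/17, 1/17)."""
        refs = _refs_from_arrays([[1.0], [2.0]], [0.0, 1.0])
        w = pem_weights([0.0], refs, mode="shepard", p_w=4.0)
        assert w.weights == pytest.approx([16 / 17, 1 / 17])

    def test_exact_match_takes_all_weight(self):
        refs = _refs_from_arrays([[5.0], [50.0]], [3.0, 9.0])
        w = pem_weights([5.0], refs)
        assert w.weights == pytest.approx([1.0, 0.0])

    def test_tied_exact_matches_split_equally(self):
        refs = _refs_from_arrays([[5.0, 0.0], [5.0, 0.0], [90.0, 0.0]],
                                 [1.0, 2.0, 3.0])
        w = pem_weights([5.0, 0.0], refs)
        assert w.weights == pytest.approx([0.5, 0.5, 0.0])

    def test_shepard_weights_sum_to_one(self, rng):
        refs = _refs_from_arrays(rng.uniform(-170, 170, (20, 4)), rng.normal(size=20))
        for _ in range(50):
            w = pem_weights(rng.uniform(-180, 180, 4), refs)
            assert w.weights.sum() == pytest.approx(1.0, abs=1e-12)
            assert np.all(w.weights >= 0)

    def test_as_printed_literal_form(self, rng):
        """Exponent 1 numerator over sum of fourth powers, unnormalised."""
        x = rng.uniform(-90, 90, 3)
        xr = rng.uniform(-90, 90, (6, 3))
        refs = _refs_from_arrays(xr, np.zeros(6))
        w = pem_weights(x, refs, mode="as-printed")
        from pemnet.descriptors import wrap_difference
        u = np.sqrt(np.sum(wrap_difference(x, xr) ** 2, axis=1))
        expected = (1.0 / u) / np.sum((1.0 / u) ** 4)
        assert w.weights == pytest.approx(expected, rel=1e-12)


class TestPemPredict:
    def test_interpolation_consistency_at_references(self, rng):
        xr = rng.uniform(-170, 170, (8, 3))
        t = rng.normal(2.3, 0.5, 8)
        refs = _refs_from_arrays(xr, t)
        for i in range(8):
            assert pem_predict(xr[i], refs, "e") == pytest.approx(t[i], abs=1e-12)

    def test_equidistant_average(self):
        refs = _refs_from_arrays([[20.0], [-20.0]], [1.0, 3.0])
        assert pem_predict([0.0], refs, "e") == pytest.approx(2.0)

    def test_matches_naive_oracle(self, rng):
        for _ in range(30):
            xr = rng.uniform(-179, 179, (5, 3))
            t = rng.normal(size=5)
            refs = _refs_from_arrays(xr, t)
            x = rng.uniform(-180, 180, 3)
            expected, _ = _naive_shepard(x, xr, t, 4.0)
            assert pem_predict(x, refs, "e") == pytest.approx(expected, abs=1e-12)

    def test_convexity_in_shepard_mode(self, rng):
        xr = rng.uniform(-170, 170, (10, 2))
        t = rng.normal(size=10)
        refs = _refs_from_arrays(xr, t)
        for _ in range(200):
            v = pem_predict(rng.uniform(-180, 180, 2), refs, "e")
            assert t.min() - 1e-12 <= v <= t.max() + 1e-12

    def test_continuity_across_exact_match(self):
        """Scanning through a reference point produces no jump."""
        refs = _refs_from_arrays([[0.0], [40.0]], [1.0, 2.0])
        eps = 1e-6
        v_at = pem_predict([0.0], refs, "e")
        v_near = pem_predict([eps], refs, "e")
        assert abs(v_at - v_near) < 1e-3

    def test_monotone_locality_limit_nearest_neighbour(self, rng):
        xr = rng.uniform(-120, 120, (6, 2))
        t = rng.normal(size=6)
        refs = _refs_from_arrays(xr, t)
        x = rng.uniform(-150, 150, 2)
        from pemnet.descriptors import wrap_difference
        u = np.sqrt(np.sum(wrap_difference(x, xr) ** 2, axis=1))
        nearest = t[np.argmin(u)]
        errs = [abs(pem_predict(x, refs, "e", p_w=pw) - nearest)
                for pw in (2.0, 8.0, 32.0, 128.0)]
        assert all(b <= a + 1e-12 for a, b in zip(errs, errs[1:]))
        assert errs[-1] < 1e-6

    def test_unknown_property_rejected(self):
        refs = _refs_from_arrays([[0.0]], [1.0])
        with pytest.raises(KeyError, match="unknown property"):
            pem_predict([0.0], refs, "nope")


class TestPredictCharges:
    def test_constant_charge_vector_returned(self, rng):
        q = np.array([0.3, -0.2, -0.1])
        refs = _refs_from_arrays(rng.uniform(-90, 90, (4, 2)),
                                 np.zeros(4), charges=[q] * 4)
        out = pem_predict_charges(rng.uniform(-90, 90, 2), refs)
        assert out == pytest.approx(q, abs=1e-12)

    def test_componentwise_equals_scalar_prediction(self, rng):
        xr = rng.uniform(-170, 170, (6, 2))
        qm = rng.normal(size=(6, 4))
        refs = _refs_from_arrays(xr, np.zeros(6), charges=list(qm))
        x = rng.uniform(-180, 180, 2)
        pred = pem_predict_charges(x, refs)
        for a in range(4):
            ra = _refs_from_arrays(xr, qm[:, a])
            assert pred[a] == pytest.approx(pem_predict(x, ra, "e"), abs=1e-12)

    def test_renormalisation_hits_net_charge(self, rng):
        xr = rng.uniform(-170, 170, (5, 2))
        qm = rng.normal(size=(5, 6))
        refs = _refs_from_arrays(xr, np.zeros(5), charges=list(qm))
        for net in (0.0, -1.0):
            out = pem_predict_charges(rng.uniform(-180, 180, 2), refs,
                                      renormalize=True, net_charge=net)
            assert out.sum() == pytest.approx(net, abs=1e-12)

    def test_inconsistent_charge_lengths_rejected(self):
        refs = _refs_from_arrays([[0.0], [10.0]], [0.0, 0.0],
                                 charges=[np.zeros(3), np.zeros(4)])
        with pytest.raises(ValueError, match="inconsistent"):
            pem_predict_charges([5.0], refs)


class TestSelectReferences:
    def _fitted(self, rng, sizes=(25, 12)):
        xs, labels = [], []
        centers = [[-60.0, 60.0], [60.0, -60.0]]
        for c, (size, center) in enumerate(zip(sizes, centers)):
            xs.append(np.degrees(rng.vonmises(np.radians(center), 100,
                                              size=(size, 2))))
            labels += [c] * size
        x = np.concatenate(xs)
        model = fit_patterns(x, k=2, seed=0)
        props = [{"e": float(i)} for i in range(len(x))]
        return model, x, props

    def test_batch_keeps_everyone(self, rng):
        model, x, props = self._fitted(rng, sizes=(5, 7))
        refs = select_references(model, x, props, mode="batch")
        assert len(refs.entries) == 12

    def test_minibatch_caps_at_n(self, rng):
        model, x, props = self._fitted(rng, sizes=(25, 4))
        refs = select_references(model, x, props, mode="mini-batch", n=10, seed=1)
        by_pat = {}
        for e in refs.entries:
            by_pat[e.pattern] = by_pat.get(e.pattern, 0) + 1
        assert sorted(by_pat.values()) == [4, 10]  # small cluster fully used

    def test_stochastic_one_per_pattern(self, rng):
        model, x, props = self._fitted(rng)
        refs = select_references(model, x, props, mode="stochastic", seed=3)
        assert len(refs.entries) == 2
        assert refs.M == 2

    def test_seeded_selection_reproducible(self, rng):
        model, x, props = self._fitted(rng)
        r1 = select_references(model, x, props, mode="mini-batch", n=5, seed=9)
        r2 = select_references(model, x, props, mode="mini-batch", n=5, seed=9)
        assert [e.frame for e in r1.entries] == [e.frame for e in r2.entries]

    def test_propertyless_pattern_dropped(self, rng):
        model, x, props = self._fitted(rng, sizes=(25, 12))
        # strip properties from pattern of frame 0's cluster
        pat0 = model.labels[0]
        props = [({} if l == pat0 else p)
                 for p, l in zip(props, model.labels)]
        refs = select_references(model, x, props, mode="batch")
        assert all(e.pattern != pat0 for e in refs.entries)

    def test_all_dropped_raises(self, rng):
        model, x, _ = self._fitted(rng)
        with pytest.raises(ValueError, match="dropped"):
            select_references(model, x, [{}] * len(x), mode="batch")


class TestValidateAndTimeseries:
    def test_perfect_predictions_ratio(self):
        x = np.array([1.0, 2.0, 3.0])
        rep = validate(x, x, mode="ratio")
        assert rep.fit.mu == pytest.approx(1.0) and rep.fit.sigma == 0.0

    def test_zero_reference_excluded(self):
        rep = validate(np.array([1.0, 2.0]), np.array([1.0, 0.0]), mode="ratio")
        assert rep.excluded == 1 and len(rep.series) == 1

    def test_deviation_mode_charges_per_atom(self, rng):
        pred = rng.normal(size=(10, 3))
        rep = validate(pred, pred, mode="deviation")
        assert np.all(rep.series == 0)
        assert rep.per_atom == pytest.approx(np.zeros(3))

    def test_timeseries_equals_framewise_calls(self, rng):
        xr = rng.uniform(-170, 170, (6, 2))
        refs = _refs_from_arrays(xr, rng.normal(size=6))
        series = rng.uniform(-180, 180, (15, 2))
        out = predict_timeseries(series, refs, "e")
        assert len(out) == 15
        for i in range(15):
            assert out[i] == pem_predict(series[i], refs, "e")

    def test_frozen_trajectory_constant_series(self, rng):
        xr = rng.uniform(-170, 170, (4, 2))
        t = rng.normal(size=4)
        refs = _refs_from_arrays(xr, t)
        series = np.tile(xr[2], (8, 1))
        out = predict_timeseries(series, refs, "e")
        assert out == pytest.approx(np.full(8, t[2]), abs=1e-12)


class TestSkillOnPlantedSurface:
    def test_minibatch_beats_global_mean(self, two_state):
        """PEM tracks a smooth planted surface better than its mean."""
        ds, expect = two_state
        n_train = ds.n_traj - 4
        train_x = np.concatenate(ds.descriptors[:n_train])
        test_x = np.concatenate(ds.descriptors[n_train:])
        test_y = np.concatenate(ds.properties[n_train:])
        train_y = np.concatenate(ds.properties[:n_train])
        model = fit_patterns(train_x, k=expect["k"], seed=0)
        props = [{"e": float(v)} for v in train_y]
        refs = select_references(model, train_x, props, mode="mini-batch",
                                 n=10, seed=0)
        pred = predict_timeseries(test_x, refs, "e")
        rmse = np.sqrt(np.mean((pred - test_y) ** 2))
        baseline = np.sqrt(np.mean((train_y.mean() - test_y) ** 2))
        assert rmse < baseline
        rep = validate(pred, test_y, mode="ratio")
        base_rep = validate(np.full_like(test_y, train_y.mean()), test_y,
                            mode="ratio")
        assert rep.fit.sigma < base_rep.fit.sigma


class TestPersistence:
    def test_reference_set_roundtrip(self, rng, tmp_path):
        xr = rng.uniform(-170, 170, (6, 2))
        refs = _refs_from_arrays(xr, rng.normal(size=6),
                                 charges=list(rng.normal(size=(6, 3))))
        save_references(refs, tmp_path / "refs.json")
        back = load_references(tmp_path / "refs.json")
        assert np.allclose(back.descriptor_matrix, refs.descriptor_matrix)
        assert np.allclose(back.charge_matrix(), refs.charge_matrix())
        x = rng.uniform(-180, 180, 2)
        assert pem_predict(x, back, "e") == pem_predict(x, refs, "e")
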