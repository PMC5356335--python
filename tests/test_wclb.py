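import numpy as np
import pytest

from collabboost import (CollaborationLog, GentleBoostModel, LabeledDataset,
                         Stump, SynthSpec, WclbConfig, gaussian_blobs, margin,
                         model_to_dict, predict_raw,
                         select_strongest_correct, select_weakest_correct,
                         stratified_subsample, train_multimodel, train_wclb)
from collabboost.wclb import _Booster, wclb_round

from conftest import random_dataset


def _one_stump_model(value=1.0):
    return GentleBoostModel([Stump(0, 0.0, -value, value)])


class TestMargin:
    def test_sign_follows_label(self):
        model = _one_stump_model(0.8)
        x = np.array([1.0])
        assert margin(model, (x, 1.0)) == pytest.approx(0.8)
        assert margin(model, (x, -1.0)) == pytest.approx(-0.8)

    def test_matches_predict_raw_loop(self, overlap_blobs):
        from collabboost import train
        model = train(overlap_blobs, T=6)
        for x, y in zip(overlap_blobs.features[:25], overlap_blobs.labels[:25]):
            assert margin(model, (x, y)) == \
                pytest.approx(y * predict_raw(model, x), abs=1e-12)


class TestSelection:
    def test_weakest_and_strongest_on_known_margins(self):
        # stump with leaves -1/+1 at threshold 0; features pick the side
        model = GentleBoostModel([Stump(0, 0.0, -1.0, 1.0)])
        X = np.array([[1.0], [1.0], [-1.0], [-1.0]])
        y = np.array([1.0, -1.0, -1.0, 1.0])  # margins: 1, -1, 1, -1
        ds = LabeledDataset(X, y, ids=np.array([10, 11, 12, 13]))
        assert select_weakest_correct(model, ds, 2) == [10, 12]
        assert select_strongest_correct(model, ds, 1) == [10]  # tie -> low id

    def test_all_wrong_yields_empty_selection(self):
        model = GentleBoostModel([Stump(0, 0.0, -1.0, 1.0)])
        ds = LabeledDataset(np.array([[1.0], [-1.0]]), np.array([-1.0, 1.0]))
        assert select_weakest_correct(model, ds, 3) == []
        assert select_strongest_correct(model, ds, 3) == []

    def test_matches_brute_force_on_random_models(self, rng):
        from collabboost import train
        for _ in range(40):
            ds = random_dataset(rng, n=25, d=2)
            model = train(ds, T=3)
            m = ds.labels * predict_raw(model, ds.features)
            correct = [(float(m[i]), int(ds.ids[i])) for i in range(ds.n)
                       if m[i] > 0]
            k = int(rng.integers(1, 6))
            weak = [i for _, i in sorted(correct)][:k]
            strong = [i for _, i in sorted(correct,
                                           key=lambda t: (-t[0], t[1]))][:k]
            assert select_weakest_correct(model, ds, k) == weak
            assert select_strongest_correct(model, ds, k) == strong


class TestWclbScheduling:
    def _boosters(self, data, S, eta, seed, T):
        plan = stratified_subsample(data, S, eta, seed)
        boosters = [_Booster(data.take(idx)) for idx in plan.subsets]
        from collabboost import boost_round
        for b in boosters:
            for _ in range(T):
                b.model, b.w = boost_round(b.model, b.data, b.w)
        return boosters

    def test_pc_zero_never_fires(self, small_blobs):
        cfg = WclbConfig(p_c=0.0, n_exc=3)
        _, log = train_wclb(small_blobs,
                            stratified_subsample(small_blobs, 3, 0.7, 0),
                            T=5, cfg=cfg)
        assert log.tentative == 0
        assert log.events == []

    def test_pc_one_fires_T_times_n_exc(self, small_blobs):
        cfg = WclbConfig(p_c=1.0, n_exc=2)
        _, log = train_wclb(small_blobs,
                            stratified_subsample(small_blobs, 3, 0.7, 0),
                            T=5, cfg=cfg)
        assert log.tentative == 10  # T * p_c * n_exc

    def test_mean_tentative_count_follows_schedule_law(self):
        """E[tentative] = T*p_c*n_exc over repeated seeded runs."""
        ds = gaussian_blobs(SynthSpec(n=16, d=1, overlap=3.0, seed=9))
        plan = stratified_subsample(ds, 2, 0.75, 0)
        T, p_c, n_exc, runs = 20, 0.1, 3, 300
        counts = []
        for s in range(runs):
            cfg = WclbConfig(p_c=p_c, n_exc=n_exc, rng_seed=s)
            _, log = train_wclb(ds, plan, T, cfg)
            counts.append(log.tentative)
        expect = T * p_c * n_exc
        se = np.sqrt(T * n_exc * p_c * (1 - p_c) / runs)
        assert abs(np.mean(counts) - expect) < 3 * se


class TestWclbExchanges:
    def test_subset_sizes_and_weights_conserved(self, overlap_blobs):
        plan = stratified_subsample(overlap_blobs, 3, 0.5, 1)
        p = len(plan.subsets[0])
        cfg = WclbConfig(p_c=1.0, n_exc=1, rng_seed=4)
        boosters, log = train_wclb(overlap_blobs, plan, T=10, cfg=cfg)
        assert log.tentative == 10
        for b in boosters:
            assert b.data.n == p
            assert b.w.sum() == pytest.approx(1.0, abs=1e-9)
            assert len(np.unique(b.data.ids)) == p

    def test_only_correct_instances_removed(self, overlap_blobs):
        plan = stratified_subsample(overlap_blobs, 4, 0.5, 2)
        cfg = WclbConfig(p_c=1.0, n_exc=2, rng_seed=7)
        _, log = train_wclb(overlap_blobs, plan, T=8, cfg=cfg)
        applied = [e for e in log.events if e.successful]
        assert applied  # the run must actually exercise exchanges
        for e in log.events:
            if e.removed_id != -1:
                assert e.removed_margin > 0
                assert e.added_margin > 0

    def test_duplicate_guard_with_full_overlap_subsets(self, small_blobs):
        """eta = 1 makes every subset the full dataset, so any incoming id is
        already present and every exchange must be skipped."""
        plan = stratified_subsample(small_blobs, 2, 1.0, 0)
        cfg = WclbConfig(p_c=1.0, n_exc=1, rng_seed=0)
        boosters, log = train_wclb(small_blobs, plan, T=4, cfg=cfg)
        assert log.tentative == 4
        assert log.successful == 0
        assert all(not e.successful for e in log.events)
        for b, idx in zip(boosters, plan.subsets):
            np.testing.assert_array_equal(np.sort(b.data.ids),
                                          np.sort(small_blobs.ids[idx]))

    def test_final_ids_stay_within_parent(self, overlap_blobs):
        plan = stratified_subsample(overlap_blobs, 3, 0.4, 3)
        cfg = WclbConfig(p_c=1.0, n_exc=1, rng_seed=1)
        boosters, log = train_wclb(overlap_blobs, plan, T=6, cfg=cfg)
        assert any(e.successful for e in log.events)
        for b in boosters:
            assert set(int(i) for i in b.data.ids) <= \
                set(int(i) for i in overlap_blobs.ids)

    def test_swap_variant_conserves_sizes(self, overlap_blobs):
        plan = stratified_subsample(overlap_blobs, 3, 0.4, 3)
        cfg = WclbConfig(p_c=1.0, n_exc=1, rng_seed=1, transfer="swap")
        boosters, _ = train_wclb(overlap_blobs, plan, T=6, cfg=cfg)
        for b, idx in zip(boosters, plan.subsets):
            assert b.data.n == len(idx)
            assert len(np.unique(b.data.ids)) == b.data.n

    def test_requires_two_ensembles(self, small_blobs):
        plan = stratified_subsample(small_blobs, 1, 0.7, 0)
        with pytest.raises(ValueError, match="S >= 2"):
            train_wclb(small_blobs, plan, 3, WclbConfig(p_c=0.5, n_exc=1))

    def test_pc_zero_bitwise_equals_plain_subbagging(self, overlap_blobs):
        m0, _ = train_multimodel(overlap_blobs, 3, 8, 0.6, "none", seed=5)
        m1, _ = train_multimodel(overlap_blobs, 3, 8, 0.6, "wclb",
                                 p_c=0.0, n_exc=2, seed=5)
        assert model_to_dict(m0)["ensembles"] == model_to_dict(m1)["ensembles"]

    def test_determinism_of_full_wclb_run(self, overlap_blobs):
        kw = dict(p_c=0.3, n_exc=2, seed=9)
        m1, l1 = train_multimodel(overlap_blobs, 3, 6, 0.5, "wclb", **kw)
        m2, l2 = train_multimodel(overlap_blobs, 3, 6, 0.5, "wclb", **kw)
        assert model_to_dict(m1) == model_to_dict(m2)
        assert l1.to_frame().equals(l2.to_frame())

    def test_config_validation(self):
        with pytest.raises(ValueError):
            WclbConfig(p_c=1.5, n_exc=1)
        with pytest.raises(ValueError):
            WclbConfig(p_c=0.5, n_exc=0)
        with pytest.raises(ValueError):
            WclbConfig(p_c=0.5, n_exc=1, transfer="teleport")
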