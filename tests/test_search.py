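import warnings

import numpy as np
import pandas as pd
import pytest

from umed import (SearchConfig, UMED, cophenetic_correlation, cut_tree,
                  classify_optimal, feature_matrix, grid_search,
                  incremental_classify, linkage_average, make_windows,
                  nmi, s_dbw, select_min_window, synth)


def small_signal(seed=0, T=4096):
    cond = synth.study_conditions()
    cond.update(T=T, Q=2)
    cond["events"] = [synth.RegimeSpec("resonant", (1.6, -0.9),
                                       duration=512, occurrences=2)]
    sig, truth = synth.generate(**cond, seed=seed)
    return sig, truth


class TestGate:
    def test_gate_equals_componentwise_thresholding(self):
        sig, _ = small_signal()
        cfg = SearchConfig(candidate_sizes=(16, 32, 64, 96), U=0.85)
        chosen = select_min_window(sig, cfg)
        expected = None
        for L in cfg.candidate_sizes:
            fv = feature_matrix(sig, make_windows(sig, L, cfg.d))
            ccc = cophenetic_correlation(fv, linkage_average(fv))
            if ccc >= cfg.U - cfg.ccc_tolerance:
                expected = L
                break
        assert chosen == expected

    def test_all_pass_returns_smallest(self):
        sig, _ = small_signal()
        cfg = SearchConfig(candidate_sizes=(64, 96, 128), U=0.05)
        assert select_min_window(sig, cfg) == 64

    def test_no_candidate_passes_lists_all(self):
        sig, _ = small_signal()
        cfg = SearchConfig(candidate_sizes=(16, 24), U=0.9999,
                           ccc_tolerance=0.0)
        with pytest.raises(ValueError, match=r"L_w=16.*L_w=24"):
            select_min_window(sig, cfg)

    def test_candidates_must_increase(self):
        sig, _ = small_signal()
        with pytest.raises(ValueError):
            select_min_window(sig, SearchConfig(candidate_sizes=(64, 64)))


class TestGridSearch:
    def test_single_size_grid(self):
        sig, _ = small_signal()
        cfg = SearchConfig(N_L=0, N_G=5)
        scan = grid_search(sig, 64, cfg)
        assert scan.L_w_opt == 64
        assert len(scan.entries) == 1

    def test_scan_invariants(self, study_fit):
        _, _, res = study_fit
        scan = res.scan
        table = scan.to_frame()
        # the optimum is the smallest recorded MIn among valid sizes
        assert scan.MIn_opt == pytest.approx(table.MIn.min())
        assert table.loc[table.MIn.idxmin(), "L_w"] == scan.L_w_opt
        # each MIn is the value of the first well-surrounded minimum
        for e in scan.entries:
            gs = sorted(e.sdbw)
            first = next(g for g, g1 in zip(gs, gs[1:])
                         if e.sdbw[g] <= e.sdbw[g1])
            assert e.No == first
            assert e.MIn == pytest.approx(e.sdbw[first])

    def test_classification_equals_recut(self, study_fit):
        _, _, res = study_fit
        labels = classify_optimal(res.scan)
        np.testing.assert_array_equal(
            labels, cut_tree(res.scan.tree_opt, res.scan.No_opt))
        np.testing.assert_array_equal(labels, res.labels)

    def test_recovers_planted_regime_count(self, study_fit):
        _, truth, res = study_fit
        assert res.No_opt == 4
        gt = pd.factorize(truth.interval_labels(res.L_w_opt, 32))[0] + 1
        assert nmi(res.labels, gt) >= 0.9

    def test_grid_exceeding_signal_rejected(self):
        sig, _ = small_signal(T=2048)
        with pytest.raises(ValueError, match="grid exceeds"):
            grid_search(sig, 1024, SearchConfig(N_L=6, D_L=200))


class TestDeterminism:
    def test_repeated_fits_identical(self):
        sig, _ = small_signal(seed=3)
        kw = dict(candidate_sizes=(64, 96), D_L=8, N_L=2, N_G=4, ipt=512)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = UMED(sig, **kw).fit()
            b = UMED(sig, **kw).fit()
        assert a.scan_table().equals(b.scan_table())
        np.testing.assert_array_equal(a.labels, b.labels)
        assert a.report() == b.report()


class TestSyntheticPrefix:
    def test_unknown_ipt_pads_and_clips(self):
        sig, _ = small_signal(seed=4)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = UMED(sig, candidate_sizes=(64, 96), D_L=8, N_L=2, N_G=4,
                       ipt=None).fit()
        assert res.prefix_samples > 0
        for s in res.events.states:
            assert s.start_sample >= 0.0
            assert s.end_sample <= sig.n_samples + res.model.config.d


def three_blobs(rng, n=20, sep=10.0):
    centers = np.array([[0.0, 0.0], [sep, 0.0], [0.0, sep]])
    X = np.vstack([c + 0.4 * rng.standard_normal((n, 2)) for c in centers])
    labels = np.repeat([1, 2, 3], n)
    return X, labels


class TestIncremental:
    def test_known_rows_inherit_labels(self, rng):
        X, labels = three_blobs(rng)
        new = X[20:25] + 0.05  # near blob 2
        out = incremental_classify(None, new, reference=X,
                                   reference_labels=labels)
        assert list(out.labels) == [2] * 5
        assert not out.is_new.any()
        assert out.n_groups == 3
        assert out.updated_reference.shape == X.shape

    def test_novel_regime_flagged_and_retained(self, rng):
        X, labels = three_blobs(rng)
        new = np.array([[25.0, 25.0], [25.2, 24.8], [24.8, 25.1]])
        out = incremental_classify(None, new, reference=X,
                                   reference_labels=labels)
        assert out.is_new.all()
        assert set(out.labels) == {4}
        assert out.n_groups == 4
        assert out.updated_reference.shape[0] == X.shape[0] + 3
        assert list(out.updated_labels[-3:]) == [4, 4, 4]

    def test_stopping_index_matches_exhaustive_scan(self, rng):
        X, labels = three_blobs(rng)
        new = np.array([[25.0, 25.0], [25.3, 24.7]])
        out = incremental_classify(None, new, reference=X,
                                   reference_labels=labels)
        combined = np.vstack([X, new])
        tree = linkage_average(combined)
        vals = {g: s_dbw(combined, cut_tree(tree, g)) for g in range(3, 10)}
        expected = next(g for g in range(3, 9) if vals[g] < vals[g + 1])
        assert out.n_groups == expected

    def test_dimension_mismatch(self, rng):
        X, labels = three_blobs(rng)
        with pytest.raises(ValueError, match="dimension"):
            incremental_classify(None, np.zeros((2, 5)), reference=X,
                                 reference_labels=labels)

    def test_batch_size_check(self, rng):
        X, labels = three_blobs(rng)
        with pytest.raises(ValueError, match="expected 3"):
            incremental_classify(None, X[:2], n_int=3, reference=X,
                                 reference_labels=labels)
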