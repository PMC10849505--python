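"""PCA untangling, element-pair decorrelation and drift curves."""

import numpy as np
import pytest

from conftest import simulate_pe_session
from seqexpect import popgeom
from seqexpect.align import extract_trials, time_average
from seqexpect.schedule import select_events


class TestPCAUntangle:
    def test_rank_one_data(self):
        rng = np.random.default_rng(0)
        pattern = rng.random(20)
        traces = {s: np.outer(pattern, rng.random(30))
                  for s in ("ABCD", "ABBD", "ACBD")}
        # rank-1 per sequence but shared cell pattern: one component total
        base = rng.random(20)
        traces = {s: np.outer(base, rng.random(30)) for s in traces}
        dec = popgeom.pca_untangle(traces)
        assert dec.n_components_90 == 1
        assert dec.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_block_structure_matches_brute_force_eigendecomposition(self):
        """Four disjoint equal-amplitude cell groups, one per element:
        explained variances must match a direct eigendecomposition of the
        covariance, and 90% variance needs at most 4 components."""
        n_per = 5
        T = 8
        X = np.zeros((4 * T, 4 * n_per))     # time x cells
        for g in range(4):
            X[g * T:(g + 1) * T, g * n_per:(g + 1) * n_per] = 1.0
        traces = {"ABCD": X.T[:, :2 * T], "ABBD": X.T[:, 2 * T:3 * T],
                  "ACBD": X.T[:, 3 * T:]}
        dec = popgeom.pca_untangle(traces)

        Xc = X - X.mean(axis=0)
        eig = np.linalg.eigvalsh(Xc.T @ Xc)[::-1]
        expected = eig / eig.sum()
        np.testing.assert_allclose(
            dec.explained_variance_ratio[:4], expected[:4], atol=1e-10)
        assert dec.n_components_90 <= 4

    def test_cell_permutation_invariance(self):
        rng = np.random.default_rng(1)
        traces = {s: rng.random((12, 10)) for s in ("ABCD", "ABBD", "ACBD")}
        perm = rng.permutation(12)
        permuted = {s: t[perm] for s, t in traces.items()}
        a = popgeom.pca_untangle(traces).explained_variance_ratio
        b = popgeom.pca_untangle(permuted).explained_variance_ratio
        np.testing.assert_allclose(a, b, atol=1e-10)

    def test_variance_ratios_sum_to_one(self, small_session, small_events):
        _, activity = small_session
        traces = popgeom.sequence_traces(activity, small_events)
        dec = popgeom.pca_untangle(traces)
        evr = dec.explained_variance_ratio
        assert np.all(np.diff(evr) <= 1e-12)
        assert evr.sum() == pytest.approx(1.0)
        # scores re-split by sequence keep the per-sequence time lengths
        assert all(s.shape[0] == traces[k].shape[1]
                   for k, s in dec.scores.items())

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValueError, match="2 cells"):
            popgeom.pca_untangle({"ABCD": np.ones((1, 5))})


class TestElementCorrelations:
    def test_six_pairs_per_presentation(self, small_session, small_events):
        _, activity = small_session
        out = popgeom.element_correlations(activity, small_events, "ABCD")
        assert len(out) == 100 * 6
        assert set(out["pair"]) == {"1-2", "1-3", "1-4", "2-3", "2-4", "3-4"}

    def test_identical_vectors_correlate_perfectly(self):
        cells, events, act = simulate_pe_session("baseline", rho=1.0,
                                                 n_cells=8, seed=2, noise=0.0,
                                                 drift_eta=0.0)
        # make every element window identical across positions
        act.values[:] = np.tile(np.linspace(1, 2, act.n_cells)[:, None],
                                (1, act.n_frames))
        out = popgeom.element_correlations(act, events, "ABBD")
        assert np.allclose(out["r"], 1.0)

    def test_anticorrelated_vectors(self):
        """Population patterns that are sign-flipped about their mean give
        r = -1 for the corresponding element pair."""
        cells, events, act = simulate_pe_session("baseline", rho=1.0,
                                                 n_cells=6, seed=2, noise=0.0,
                                                 drift_eta=0.0)
        from seqexpect.schedule import event_frame_bounds
        pattern = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        flipped = 2 * pattern.mean() - pattern
        elems = events[events["kind"] == "element"]
        first, last = event_frame_bounds(elems, 30.0)
        act.values[:] = 0.0
        pos = elems["position"].to_numpy()
        for f, l, p in zip(first, last, pos):
            act.values[:, f:l] = (pattern if p in (1, 2) else flipped)[:, None]
        out = popgeom.element_correlations(act, events, "ABBD")
        r12 = out[out["pair"] == "1-2"]["r"]
        r13 = out[out["pair"] == "1-3"]["r"]
        assert np.allclose(r12, 1.0) and np.allclose(r13, -1.0)

    def test_zero_variance_pairs_dropped(self):
        cells, events, act = simulate_pe_session("baseline", rho=1.0,
                                                 n_cells=4, seed=2, noise=0.0,
                                                 drift_eta=0.0)
        act.values[:] = 1.0      # flat: every vector has zero variance
        out = popgeom.element_correlations(act, events, "ABBD")
        assert len(out) == 0 and out.attrs["n_dropped"] == 50 * 6


class TestDriftCurve:
    def _response_vectors(self, eta, seed=0, n_cells=60):
        cells, events, act = simulate_pe_session(
            "baseline", rho=1.0, n_cells=n_cells, block_size=20, seed=seed,
            drift_eta=eta)
        sel = select_events(events, kind="element", element="B", position=2)
        resp = time_average(extract_trials(act, sel, offset_frames=2,
                                           mode="truncate"))
        return resp.values

    def test_three_trials_three_pairs(self):
        X = np.random.default_rng(0).random((3, 5))
        curve = popgeom.drift_curve(X, bin_width=1)
        assert curve.table["n_pairs"].sum() == 3

    def test_no_drift_is_flat(self):
        X = self._response_vectors(eta=0.0)
        curve = popgeom.drift_curve(X, bin_width=25)
        r = curve.table["mean_r"]
        assert r.max() - r.min() < 0.05

    def test_planted_drift_decreases_monotonically(self):
        X = self._response_vectors(eta=0.05)
        curve = popgeom.drift_curve(X, bin_width=25)
        r = curve.table["mean_r"].to_numpy()
        assert len(r) >= 3
        assert np.all(np.diff(r) < 0)

    def test_single_trial_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            popgeom.drift_curve(np.ones((1, 4)))
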