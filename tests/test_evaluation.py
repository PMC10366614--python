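import numpy as np
import pytest
import scipy.optimize
import scipy.spatial

import tvmanifold as tm
from tvmanifold.containers import Embedding
from tvmanifold.evaluation import (
    GroupEmbedding,
    classify_windows,
    concat_embed,
    embed_procrustes,
    procrustes_fit,
    scan_embed,
    silhouette_index,
    stability_study,
)


def _emb(coords, labels, subject="sub-01"):
    return Embedding(coords=np.asarray(coords, float), method="LE",
                     window_labels=list(labels), subject_id=subject)


class TestSilhouette:
    def test_hand_evaluated_two_cluster_case(self):
        emb = _emb([[0.0], [0.1], [10.0], [10.1]], ["A", "A", "B", "B"])
        rep = silhouette_index(emb, "task")
        # per-point silhouettes: (10.05-0.1)/10.05 twice, (9.95-0.1)/9.95 twice
        expected = (2 * (9.95 / 10.05) + 2 * (9.85 / 9.95)) / 4
        assert rep.value == pytest.approx(expected, abs=1e-9)
        assert rep.value == pytest.approx(0.990, abs=1e-2)

    def test_random_labels_in_one_cluster_score_near_zero(self):
        rng = np.random.default_rng(0)
        coords = rng.standard_normal((200, 3))
        labels = list(rng.choice(["A", "B"], size=200))
        rep = silhouette_index(_emb(coords, labels), "task")
        assert abs(rep.value) < 0.1

    def test_mixed_windows_excluded_for_task_scoring(self):
        emb = _emb([[0.0], [0.1], [5.0], [10.0], [10.1]], ["A", "A", "mixed", "B", "B"])
        rep = silhouette_index(emb, "task")
        assert rep.n_used == 4 and rep.excluded == 1

    def test_single_label_rejected(self):
        with pytest.raises(ValueError):
            silhouette_index(_emb([[0.0], [1.0]], ["A", "A"]), "task")

    def test_ambient_space_scoring_accepts_tvfc(self, small_tvfc):
        rep = silhouette_index(small_tvfc, "task")
        assert -1 <= rep.value <= 1

    def test_invariant_under_similarity_transform(self, two_clusters):
        x, labels = two_clusters
        rep0 = silhouette_index(_emb(x, labels), "task")
        theta = 0.7
        R = np.eye(4)
        R[:2, :2] = [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        moved = 3.0 * x @ R + 7.0
        rep1 = silhouette_index(_emb(moved, labels), "task")
        assert rep0.value == pytest.approx(rep1.value, abs=1e-9)


class TestProcrustes:
    def test_recovers_known_similarity_transform(self):
        rng = np.random.default_rng(1)
        src = rng.standard_normal((40, 3))
        theta = 0.5
        R = np.array(
            [[np.cos(theta), -np.sin(theta), 0], [np.sin(theta), np.cos(theta), 0], [0, 0, 1]]
        )
        tgt = 2.5 * src @ R + np.array([1.0, -2.0, 0.5])
        tr, disparity = procrustes_fit(src, tgt)
        assert disparity < 1e-10
        assert tr.scale == pytest.approx(2.5, abs=1e-9)
        assert np.allclose(tr.rotation, R, atol=1e-9)
        assert np.allclose(tr.apply(src), tgt, atol=1e-9)

    def test_identity_when_source_equals_target(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((20, 2))
        tr, disparity = procrustes_fit(x, x)
        assert disparity == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(tr.rotation, np.eye(2), atol=1e-9)
        assert tr.scale == pytest.approx(1.0)

    def test_disparity_matches_scipy_and_numerical_minimizer(self):
        rng = np.random.default_rng(3)
        src = rng.standard_normal((12, 2))
        tgt = rng.standard_normal((12, 2))
        _, disparity = procrustes_fit(src, tgt)
        _, _, scipy_disp = scipy.spatial.procrustes(tgt, src)
        assert disparity == pytest.approx(scipy_disp, abs=1e-9)

        # brute-force oracle over parameterized similarity transforms
        xt = tgt - tgt.mean(0)
        xs = src - src.mean(0)

        def cost(p, reflect):
            s, th, tx, ty = p
            R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
            if reflect:
                R = R @ np.diag([1.0, -1.0])
            return np.sum((s * xs @ R + [tx, ty] - xt) ** 2)

        best = min(
            scipy.optimize.minimize(cost, [1.0, th0, 0, 0], args=(refl,), method="Nelder-Mead").fun
            for th0 in np.linspace(0, 2 * np.pi, 8)
            for refl in (False, True)
        )
        assert disparity * np.sum(xt**2) == pytest.approx(best, rel=1e-3)

    def test_degenerate_configuration_rejected(self):
        with pytest.raises(ValueError):
            procrustes_fit(np.zeros((5, 2)), np.random.default_rng(0).standard_normal((5, 2)))


@pytest.fixture(scope="module")
def fingerprint_group():
    cfg = tm.fingerprint_config(seed=3)
    data = tm.generate_dataset(cfg)
    spec = tm.WindowSpec(30, 5)
    return [tm.compute_tvfc(ts, spec, sch) for ts, sch, _ in data]


class TestGroupEmbeddings:
    def test_single_scan_concat_equals_scan_embedding(self, small_tvfc):
        grp = concat_embed([small_tvfc], "LE", {"k": 30, "m": 3}, metric="correlation")
        scan = scan_embed(small_tvfc, "LE", {"k": 30, "m": 3}, metric="correlation")
        assert np.allclose(grp.coords, scan.coords, atol=1e-10)

    def test_normalization_removes_subject_identifiability(self, fingerprint_group):
        raw = concat_embed(fingerprint_group, "LE", {"k": 50, "m": 3}, normalize=False)
        nrm = concat_embed(fingerprint_group, "LE", {"k": 50, "m": 3}, normalize=True)
        si_raw = silhouette_index(raw, "subject").value
        si_nrm = silhouette_index(nrm, "subject").value
        assert si_raw > si_nrm
        assert si_nrm < 0.1

    def test_mismatched_connection_indices_rejected(self, fingerprint_group, small_tvfc):
        other = tm.TvfcMatrix(
            values=small_tvfc.values[:10],
            connection_index=small_tvfc.connection_index[:10],
            window_starts=small_tvfc.window_starts,
            spec=small_tvfc.spec,
            window_labels=small_tvfc.window_labels,
        )
        with pytest.raises(ValueError):
            concat_embed([fingerprint_group[0], other], "LE", {"k": 10, "m": 2})

    def test_self_alignment_is_identity(self, small_tvfc):
        emb = scan_embed(small_tvfc, "LE", {"k": 30, "m": 3}, metric="correlation")
        grp = embed_procrustes([emb, emb], align_dims=3, reference=0)
        assert np.allclose(grp.coords[: emb.n], emb.coords, atol=1e-10)

    def test_window_count_mismatch_rejected(self, small_tvfc, default_tvfc):
        e1 = scan_embed(small_tvfc, "LE", {"k": 20, "m": 2})
        e2 = scan_embed(default_tvfc, "LE", {"k": 20, "m": 2})
        with pytest.raises(ValueError):
            embed_procrustes([e1, e2], align_dims=2)

    def test_generalized_mode_runs_and_aligns(self, fingerprint_group):
        embs = [scan_embed(t, "LE", {"k": 25, "m": 5}, metric="correlation")
                for t in fingerprint_group]
        grp = embed_procrustes(embs, align_dims=5, generalized=True)
        assert grp.coords.shape == (sum(e.n for e in embs), 5)
        assert silhouette_index(grp, "subject").value < 0.2


class TestClassification:
    def _separable_group(self):
        rng = np.random.default_rng(8)
        coords, labels, subs = [], [], []
        centers = {"w": [0, 0], "x": [8, 0], "y": [0, 8], "z": [8, 8]}
        for s in range(4):
            # interleave classes in time so both split halves contain them all
            for rep in range(4):
                for lab, c in centers.items():
                    pts = rng.standard_normal((5, 2)) * 0.4 + c
                    coords.append(pts)
                    labels += [lab] * 5
                    subs += [f"sub-{s}"] * 5
        return GroupEmbedding(
            coords=np.vstack(coords), scan_ids=subs, subject_ids=subs,
            window_labels=labels, strategy="concat_embed",
        )

    def test_separable_clusters_reach_high_f1(self):
        rep = classify_windows(self._separable_group(), m_used=2, scheme="split_half")
        assert rep.f1_average > 0.95
        assert set(rep.f1_per_class) == {"w", "x", "y", "z"}

    def test_shuffled_labels_fall_to_chance(self):
        grp = self._separable_group()
        rng = np.random.default_rng(0)
        grp.window_labels = list(rng.permutation(grp.window_labels))
        rep = classify_windows(grp, m_used=2, scheme="split_half")
        # chance for 4 balanced classes is 0.25 under random prediction; an L1
        # classifier may also collapse to near-constant predictions, which
        # scores even lower — either way far below the separable case
        assert rep.f1_average < 0.35

    def test_loso_has_one_fold_per_subject(self):
        rep = classify_windows(self._separable_group(), m_used=2, scheme="leave_one_subject_out")
        assert rep.folds == 4
        assert rep.f1_average > 0.95

    def test_f1_improves_with_dimensions_on_procrustes_group(self, fingerprint_group):
        embs = [scan_embed(t, "LE", {"k": 25, "m": 20}, metric="correlation")
                for t in fingerprint_group]
        grp = embed_procrustes(embs, align_dims=20)
        f1 = {m: classify_windows(grp, m_used=m, scheme="split_half").f1_average
              for m in (2, 5)}
        assert f1[5] > f1[2]


class TestStability:
    def test_deterministic_method_has_zero_iqr(self, small_tvfc):
        res = stability_study(small_tvfc, "LE", {"k": 30, "m": 3}, n_reps=3, seed=0,
                              metric="correlation")
        assert res["iqr"] == pytest.approx(0.0, abs=1e-12)

    def test_identical_seeds_give_identical_si(self, small_tvfc):
        a = stability_study(small_tvfc, "UMAP", {"k": 30, "m": 2, "n_epochs": 50},
                            n_reps=2, seed=5)
        b = stability_study(small_tvfc, "UMAP", {"k": 30, "m": 2, "n_epochs": 50},
                            n_reps=2, seed=5)
        assert a["si_task"] == b["si_task"]
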