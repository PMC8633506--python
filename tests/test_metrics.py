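"""Distance-preservation, superposition RMSD, MMD, EMD and the
benchmark harness, checked against brute-force and library oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import pearsonr, spearmanr

from mdvae import metrics as M
from mdvae import models as Mo


def _rank_oracle(values):
    """Average ranks by explicit enumeration (independent of scipy)."""
    values = list(values)
    ranks = []
    for v in values:
        less = sum(1 for u in values if u < v)
        equal = sum(1 for u in values if u == v)
        ranks.append(less + (equal + 1) / 2.0)
    return np.array(ranks)


def _all_pair_distances(X):
    n = len(X)
    return np.array(
        [np.linalg.norm(X[i] - X[j]) for i, j in itertools.combinations(range(n), 2)]
    )


class TestSpearman:
    def test_monotone_map_gives_plus_one(self, rng):
        high = rng.normal(size=(10, 6))
        d = _all_pair_distances(high)
        assert len(np.unique(d)) == len(d)
        # a low-dim space whose distances are a strictly increasing
        # function of the high-dim ones: scale the same points
        low = 3.0 * high
        assert M.spearman_distance_preservation(high, low) == pytest.approx(1.0)

    def test_reverse_ordered_distances_give_minus_one(self):
        # direct formula check on synthetic paired distance lists via ranks
        d_high = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        d_low = d_high[::-1]
        rh, rl = _rank_oracle(d_high), _rank_oracle(d_low)
        n = len(d_high)
        rho = 1 - 6 * np.sum((rh - rl) ** 2) / (n * (n**2 - 1))
        assert rho == -1.0

    def test_matches_brute_force_oracle_on_random_instance(self, rng):
        high = rng.normal(size=(15, 8))
        low = rng.normal(size=(15, 2))
        dh, dl = _all_pair_distances(high), _all_pair_distances(low)  # 105 pairs
        rh, rl = _rank_oracle(dh), _rank_oracle(dl)
        n = len(dh)
        expected = 1 - 6 * np.sum((rh - rl) ** 2) / (n * (n**2 - 1))
        got = M.spearman_distance_preservation(high, low)
        assert got == pytest.approx(expected, abs=1e-12)
        # independent library cross-check
        assert got == pytest.approx(spearmanr(dh, dl).statistic, abs=1e-12)

    def test_tie_handling_matches_pearson_of_ranks(self):
        # integer coordinates force tied distances
        high = np.array([[0.0], [1.0], [2.0], [3.0], [4.0]])
        low = np.array([[0.0], [2.0], [4.0], [6.0], [7.0]])
        dh, dl = _all_pair_distances(high), _all_pair_distances(low)
        assert len(np.unique(dh)) < len(dh)
        got = M.spearman_distance_preservation(high, low)
        assert got == pytest.approx(spearmanr(dh, dl).statistic, abs=1e-12)

    def test_too_few_frames_rejected(self, rng):
        with pytest.raises(ValueError):
            M.spearman_distance_preservation(rng.normal(size=(2, 3)), rng.normal(size=(2, 2)))

    def test_degenerate_distances_flagged(self):
        square = np.array([[0.0, 0], [1, 0], [0, 1], [1, 1]]) * 0  # all-equal points
        other = np.random.default_rng(0).normal(size=(4, 2))
        with pytest.warns(UserWarning):
            assert np.isnan(M.spearman_distance_preservation(square, other))


class TestPearson:
    def test_isometric_embedding_gives_plus_one(self, rng):
        high = rng.normal(size=(12, 5))
        # isometric linear embedding: orthogonal transform preserves distances
        Q, _ = np.linalg.qr(rng.normal(size=(5, 5)))
        low = high @ Q
        assert M.pearson_distance_preservation(high, low) == pytest.approx(1.0)

    def test_negative_affine_relation_gives_minus_one(self, rng):
        x = rng.random(20)
        y = -2.0 * x + 3.0
        assert M.pearson_correlation(x, y) == pytest.approx(-1.0)

    def test_matches_direct_formula_oracle(self, rng):
        high = rng.normal(size=(12, 7))
        low = rng.normal(size=(12, 2))
        dh, dl = _all_pair_distances(high), _all_pair_distances(low)
        xm, ym = dh.mean(), dl.mean()
        expected = np.sum((dh - xm) * (dl - ym)) / np.sqrt(
            np.sum((dh - xm) ** 2) * np.sum((dl - ym) ** 2)
        )
        got = M.pearson_distance_preservation(high, low)
        assert got == pytest.approx(expected, abs=1e-12)
        assert got == pytest.approx(pearsonr(dh, dl).statistic, abs=1e-12)

    def test_pair_subsampling_is_seeded_and_close_to_full(self, rng):
        high = rng.normal(size=(300, 4))
        low = high[:, :2]
        full = M.pearson_distance_preservation(high, low)
        sub1 = M.pearson_distance_preservation(high, low, max_pairs=5000, seed=1)
        sub2 = M.pearson_distance_preservation(high, low, max_pairs=5000, seed=1)
        assert sub1 == sub2
        assert sub1 == pytest.approx(full, abs=0.05)


class TestSuperpositionRMSD:
    def test_identical_structures_give_zero(self, rng):
        x = rng.normal(size=(6, 3))
        assert M.superposition_rmsd(x, x) == pytest.approx(0.0, abs=1e-12)

    def test_rigid_transform_invariance(self, rng):
        x = rng.normal(size=(9, 3))
        theta = 0.7
        R = np.array(
            [[np.cos(theta), -np.sin(theta), 0],
             [np.sin(theta), np.cos(theta), 0],
             [0, 0, 1]]
        )
        moved = x @ R.T + np.array([4.0, -2.0, 1.0])
        assert M.superposition_rmsd(moved, x) < 1e-9

    def test_symmetry(self, rng):
        a, b = rng.normal(size=(7, 3)), rng.normal(size=(7, 3))
        assert M.superposition_rmsd(a, b) == pytest.approx(
            M.superposition_rmsd(b, a), abs=1e-9
        )

    def test_matches_rotation_grid_search_oracle(self, rng):
        # 4-atom toy pair: global minimum over a fine Euler-angle grid
        # (optimal translation is centroid matching, applied analytically)
        from scipy.spatial.transform import Rotation

        a = rng.normal(size=(4, 3))
        b = rng.normal(size=(4, 3))
        got = M.superposition_rmsd(a, b)
        ac = a - a.mean(axis=0)
        bc = b - b.mean(axis=0)
        step = np.deg2rad(3.0)
        alphas = np.arange(0, 2 * np.pi, step)
        betas = np.arange(0, np.pi, step)
        gammas = np.arange(0, 2 * np.pi, step)
        grid = np.stack(np.meshgrid(alphas, betas, gammas, indexing="ij"), axis=-1)
        Rs = Rotation.from_euler("zyz", grid.reshape(-1, 3)).as_matrix()
        rot = np.einsum("nij,aj->nai", Rs, ac)
        rmsds = np.sqrt(np.mean(np.sum((rot - bc) ** 2, axis=2), axis=1))
        oracle_min = rmsds.min()
        assert got <= oracle_min + 1e-9  # analytic minimum cannot exceed grid
        assert oracle_min - got < 0.05  # and the grid gets within resolution

    def test_agrees_with_mdanalysis(self, rng):
        from MDAnalysis.analysis.rms import rmsd as mda_rmsd

        a, b = rng.normal(size=(10, 3)), rng.normal(size=(10, 3))
        assert M.superposition_rmsd(a, b) == pytest.approx(
            mda_rmsd(a, b, center=True, superposition=True), abs=1e-9
        )

    def test_atom_count_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="mismatch"):
            M.superposition_rmsd(rng.normal(size=(4, 3)), rng.normal(size=(5, 3)))


class TestDecoderRMSD:
    def test_identity_model_gives_all_zeros(self, small_trained_vae, monkeypatch):
        fm = small_trained_vae["features"]
        model = small_trained_vae["model"]
        monkeypatch.setattr(
            M._models, "encode",
            lambda m, v, allow_untrained=False: Mo.LatentEmbedding(
                np.asarray(v)[:, :2].copy()
            ),
        )
        monkeypatch.setattr(
            M._models, "decode",
            lambda m, z, allow_untrained=False: fm.values[: len(z)].copy(),
        )
        per_frame, mean = M.decoder_rmsd_profile(model, fm.values[:5], fm.scaler)
        assert np.abs(per_frame).max() < 1e-9

    def test_overtrained_model_memorises_few_frames(self):
        from mdvae import features as F

        rng = np.random.default_rng(0)
        x = rng.random((4, 30))
        scaler = F.FeatureScaler(np.zeros(30), np.ones(30))
        spec = Mo.ModelSpec(
            model_kind="ae", input_dim=30, encoder_layer_sizes=(16, 8),
            epochs=800, batch_size=4, seed=1,
        )
        model = Mo.train(Mo.build_model(spec), x)
        _, mean = M.decoder_rmsd_profile(model, x, scaler)
        assert mean < 0.05  # memorisation: far below the O(0.3) data scale

    def test_untrained_worse_than_trained(self, small_trained_vae):
        model = small_trained_vae["model"]
        fm = small_trained_vae["features"]
        untrained = Mo.build_model(model.spec)
        _, mean_trained = M.decoder_rmsd_profile(model, fm.values[:50], fm.scaler)
        _, mean_untrained = M.decoder_rmsd_profile(
            untrained, fm.values[:50], fm.scaler, allow_untrained=True
        )
        assert mean_untrained > mean_trained


class TestMMD:
    def test_identical_samples_give_zero(self, rng):
        x = rng.normal(size=500)
        assert M.mmd(x, x) < 1e-6

    def test_null_calibration_against_permutation_oracle(self):
        # same-distribution MMD should fall below the permutation-null
        # 95th percentile in ~95% of runs
        failures = 0
        n_runs, n = 20, 300
        for seed in range(n_runs):
            rng = np.random.default_rng(seed)
            p = rng.normal(size=n)
            q = rng.normal(size=n)
            obs = M.mmd(p, q)
            pooled = np.concatenate([p, q])
            null = []
            for _ in range(60):
                rng.shuffle(pooled)
                null.append(M.mmd(pooled[:n], pooled[n:]))
            if obs > np.percentile(null, 95):
                failures += 1
        # binomial(20, 0.05): >= 5 failures has probability < 3e-3
        assert failures < 5

    def test_separated_distributions_score_higher(self, rng):
        p = rng.normal(size=1000)
        q_same = rng.normal(size=1000)
        q_far = rng.normal(loc=3.0, size=1000)
        assert M.mmd(p, q_far) > M.mmd(p, q_same)

    def test_symmetry_and_nonnegativity(self, rng):
        p, q = rng.normal(size=200), rng.normal(loc=1.0, size=200)
        assert M.mmd(p, q) >= 0
        assert M.mmd(p, q) == pytest.approx(M.mmd(q, p), abs=1e-12)

    def test_explicit_bandwidth_and_errors(self, rng):
        p, q = rng.normal(size=50), rng.normal(size=50)
        assert M.mmd(p, q, bandwidth=1.0) >= 0
        with pytest.raises(ValueError):
            M.mmd(p, q, bandwidth=-1.0)
        with pytest.raises(ValueError):
            M.mmd(np.array([]), q)


class TestEMD:
    def test_identical_samples_give_zero(self, rng):
        x = rng.normal(size=100)
        assert M.emd(x, x) == 0.0

    def test_point_masses_unit_apart(self):
        assert M.emd(np.zeros(5), np.ones(5)) == pytest.approx(1.0)

    @given(c=st.floats(min_value=-50, max_value=50))
    @settings(max_examples=30, deadline=None)
    def test_translation_property(self, c):
        rng = np.random.default_rng(7)
        x = rng.normal(size=200)
        assert M.emd(x, x + c) == pytest.approx(abs(c), abs=1e-9)

    def test_triangle_inequality_on_random_triples(self, rng):
        for _ in range(10):
            a = rng.normal(size=80)
            b = rng.normal(loc=rng.normal(), size=80)
            c = rng.normal(loc=rng.normal(), size=80)
            assert M.emd(a, c) <= M.emd(a, b) + M.emd(b, c) + 1e-9

    def test_empty_sample_rejected(self, rng):
        with pytest.raises(ValueError):
            M.emd(np.array([]), rng.normal(size=5))


class TestPermutationInvariance:
    def test_joint_frame_permutation_leaves_metrics_unchanged(self, rng):
        high = rng.normal(size=(30, 6))
        low = rng.normal(size=(30, 2))
        perm = rng.permutation(30)
        assert M.spearman_distance_preservation(
            high, low
        ) == pytest.approx(
            M.spearman_distance_preservation(high[perm], low[perm]), abs=1e-9
        )
        assert M.pearson_distance_preservation(
            high, low
        ) == pytest.approx(
            M.pearson_distance_preservation(high[perm], low[perm]), abs=1e-9
        )


class TestBenchmark:
    def test_single_replicate_report_is_finite(self, toy_trajectory):
        from mdvae import features as F

        traj, _ = toy_trajectory
        fm = F.fit_transform(F.align_to_first_frame(traj))
        split = F.stride_split(fm.n_frames, 4)
        spec = Mo.ModelSpec(
            model_kind="vae", input_dim=fm.n_features,
            encoder_layer_sizes=(24, 10), epochs=15, seed=0,
        )
        table = M.benchmark_models([spec], fm, split, n_replicates=1)
        row = table[table["replicate"] == 0].iloc[0]
        for col in ("spearman", "pearson", "mean_rmsd", "mmd", "emd"):
            assert np.isfinite(row[col])
        assert (table["replicate"] == "mean").sum() == 1

    def test_trained_spec_dominates_untrained(self, toy_trajectory):
        from mdvae import features as F

        traj, _ = toy_trajectory
        fm = F.fit_transform(F.align_to_first_frame(traj))
        split = F.stride_split(fm.n_frames, 4)
        base = dict(
            model_kind="ae", input_dim=fm.n_features,
            encoder_layer_sizes=(24, 10), seed=0,
        )
        trained = Mo.ModelSpec(epochs=40, **base)
        frozen = Mo.ModelSpec(epochs=0, **base)
        table = M.benchmark_models([trained, frozen], fm, split, n_replicates=1)
        rows = table[table["replicate"] == 0]
        rmsd_trained, rmsd_frozen = rows["mean_rmsd"].to_numpy()
        assert rmsd_trained < rmsd_frozen

    def test_rerun_reproduces_table(self, toy_trajectory):
        from mdvae import features as F

        traj, _ = toy_trajectory
        fm = F.fit_transform(F.align_to_first_frame(traj))
        split = F.stride_split(fm.n_frames, 4)
        spec = Mo.ModelSpec(
            model_kind="vae", input_dim=fm.n_features,
            encoder_layer_sizes=(24, 10), epochs=10, seed=5,
        )
        t1 = M.benchmark_models([spec], fm, split, n_replicates=2)
        t2 = M.benchmark_models([spec], fm, split, n_replicates=2)
        for col in ("spearman", "pearson", "mean_rmsd", "mmd", "emd"):
            assert (t1[col].to_numpy() == t2[col].to_numpy()).all()
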