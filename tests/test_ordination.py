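"""Ordination kernels, PCNM, forward selection, variation partitioning."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from elevassembly.containers import DistanceMatrix, ValidationError
from elevassembly.ordination import (
    adjusted_r2,
    bootstrap_fraction_test,
    cca,
    dbrda,
    forward_select,
    nmds,
    pcnm,
    pcoa,
    variation_partition,
)

from conftest import euclidean_dm


def _gower_eig(d):
    a = -0.5 * d**2
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return np.linalg.eigvalsh(j @ a @ j)[::-1]


class TestPcoa:
    def test_collinear_points_single_axis(self):
        pos = np.array([0.0, 3.0, 4.0])
        dm = DistanceMatrix(["a", "b", "c"], np.abs(pos[:, None] - pos[None, :]))
        res = pcoa(dm)
        eig = res.eigenvalues
        assert (eig > 1e-10).sum() == 1
        rec = squareform(pdist(res.scores))
        np.testing.assert_allclose(rec, dm.values, atol=1e-10)

    def test_all_zero_distances(self):
        dm = DistanceMatrix(["a", "b", "c"], np.zeros((3, 3)))
        res = pcoa(dm)
        assert np.abs(res.eigenvalues).max() < 1e-12
        assert res.scores.shape[1] == 0

    def test_euclidean_identity(self):
        rng = np.random.default_rng(2)
        pts = rng.standard_normal((12, 4))
        dm = euclidean_dm(pts)
        res = pcoa(dm)
        np.testing.assert_allclose(squareform(pdist(res.scores)), dm.values, atol=1e-8)
        centered = pts - pts.mean(axis=0)
        assert res.total_inertia == pytest.approx((centered**2).sum(), abs=1e-8)

    def test_matches_dense_oracle_eigenvalues(self):
        rng = np.random.default_rng(3)
        pts = rng.standard_normal((9, 3))
        dm = euclidean_dm(pts)
        oracle = _gower_eig(dm.values)
        np.testing.assert_allclose(np.sort(pcoa(dm).eigenvalues), np.sort(oracle), atol=1e-8)

    def test_rejects_similarity_kind(self):
        dm = DistanceMatrix(["a", "b"], [[0, 0.5], [0.5, 0]], kind="similarity")
        with pytest.raises(ValidationError):
            pcoa(dm)


class TestNmds:
    def test_embeddable_triangle_zero_stress(self):
        dm = euclidean_dm(np.array([[0.0, 0.0], [3.0, 0.0], [0.0, 4.0]]))
        res = nmds(dm, k=2, n_starts=5, seed=0)
        assert res.stress < 1e-4

    def test_configuration_centered_unit_rms(self):
        rng = np.random.default_rng(4)
        dm = euclidean_dm(rng.random((8, 3)))
        res = nmds(dm, k=2, n_starts=5, seed=1)
        assert np.abs(res.scores.mean(axis=0)).max() < 1e-8
        assert (res.scores**2).sum() / 8 == pytest.approx(1.0)

    def test_k_too_large(self):
        dm = euclidean_dm(np.random.default_rng(0).random((4, 2)))
        with pytest.raises(ValidationError):
            nmds(dm, k=4)

    def test_matches_independent_smacof_oracle(self):
        # independent nonmetric MDS implementation at small n
        sklearn_manifold = pytest.importorskip("sklearn.manifold")
        rng = np.random.default_rng(5)
        pts = rng.standard_normal((10, 5))
        dm = euclidean_dm(pts)
        ours = nmds(dm, k=2, n_starts=30, seed=2)
        mds = sklearn_manifold.MDS(
            n_components=2, metric=False, dissimilarity="precomputed",
            n_init=30, max_iter=500, random_state=0, normalized_stress=False,
        )
        emb = mds.fit_transform(dm.values)
        # evaluate both configurations under the same Kruskal stress-1
        def stress1(cfg):
            from sklearn.isotonic import isotonic_regression

            iu = np.triu_indices(10, 1)
            dflat = dm.values[iu]
            cd = squareform(pdist(cfg))[iu]
            order = np.lexsort((cd, dflat))
            disp = np.empty_like(cd)
            disp[order] = isotonic_regression(cd[order])
            return np.sqrt(((cd - disp) ** 2).sum() / (cd**2).sum())

        assert ours.stress <= stress1(emb) + 1e-3

    def test_stress_invariant_to_rigid_motion_of_input_scale(self):
        rng = np.random.default_rng(6)
        pts = rng.standard_normal((9, 3))
        d1 = euclidean_dm(pts)
        d2 = DistanceMatrix(d1.ids, 3.7 * d1.values)  # uniform dilation
        s1 = nmds(d1, k=2, n_starts=10, seed=3).stress
        s2 = nmds(d2, k=2, n_starts=10, seed=3).stress
        assert s1 == pytest.approx(s2, abs=1e-6)


class TestCca:
    def test_total_inertia_is_chi_square_over_total(self):
        rng = np.random.default_rng(7)
        y = rng.integers(1, 10, (6, 4))
        x = pd.DataFrame({"x": rng.standard_normal(6)})
        res = cca(y, x)
        from scipy.stats import chi2_contingency

        chi2 = chi2_contingency(y, correction=False).statistic
        assert res.total_inertia == pytest.approx(chi2 / y.sum(), abs=1e-10)

    def test_orthogonal_predictor_explains_nothing(self):
        rng = np.random.default_rng(8)
        y = rng.integers(1, 10, (10, 5)).astype(float)
        # build a predictor orthogonal (in the row-weight metric) to the
        # chi-square residual response
        grand = y.sum()
        p = y / grand
        r = p.sum(axis=1)
        c = p.sum(axis=0)
        qbar = (p - np.outer(r, c)) / np.sqrt(np.outer(r, c))
        x = rng.standard_normal(10)
        xw = x * np.sqrt(r)
        # project out every response column
        q, _ = np.linalg.qr(qbar)
        xw_orth = xw - q @ (q.T @ xw)
        x_orth = xw_orth / np.sqrt(r)
        res = cca(y, pd.DataFrame({"x": x_orth}))
        assert res.constrained_inertia == pytest.approx(0.0, abs=1e-10)

    def test_matches_vegan_reference(self, tmp_path):
        import shutil
        import subprocess

        rng = np.random.default_rng(0)
        y = rng.integers(0, 10, (6, 4))
        y[y.sum(axis=1) == 0, 0] = 1
        x = rng.standard_normal(6)
        res = cca(y, pd.DataFrame({"x": x}))
        np.savetxt(tmp_path / "Y.csv", y, delimiter=",", fmt="%d")
        np.savetxt(tmp_path / "x.csv", x[:, None], delimiter=",")
        script = tmp_path / "cca.R"
        script.write_text(
            'suppressMessages(library(vegan))\n'
            f'Y <- as.matrix(read.csv("{tmp_path}/Y.csv", header=FALSE))\n'
            f'x <- scan("{tmp_path}/x.csv", quiet=TRUE)\n'
            'm <- cca(Y ~ x)\n'
            'cat(sprintf("%.15g", c(m$CCA$eig, m$tot.chi)), sep="\\n")\n'
        )
        out = subprocess.run(
            [shutil.which("Rscript") or "Rscript", str(script)],
            capture_output=True, text=True, check=True,
        )
        eig_ref, total_ref = map(float, out.stdout.split())
        assert res.eigenvalues[0] == pytest.approx(eig_ref, abs=1e-8)
        assert res.total_inertia == pytest.approx(total_ref, abs=1e-8)

    def test_constant_predictor_rejected(self):
        y = np.ones((5, 3), dtype=int)
        with pytest.raises(ValidationError, match="constant"):
            cca(y, pd.DataFrame({"x": np.ones(5)}))


class TestDbrda:
    def test_self_explanation(self):
        rng = np.random.default_rng(9)
        dm = euclidean_dm(rng.standard_normal((10, 3)))
        axes = pcoa(dm).scores
        res = dbrda(dm, pd.DataFrame(axes, columns=[f"a{i}" for i in range(axes.shape[1])]))
        assert res.r2 == pytest.approx(1.0, abs=1e-8)

    def test_exact_linear_response(self):
        rng = np.random.default_rng(10)
        x = rng.standard_normal(12)
        resp = np.column_stack([2 * x, -x])
        dm = euclidean_dm(resp)
        res = dbrda(dm, pd.DataFrame({"x": x}))
        assert res.r2 == pytest.approx(1.0, abs=1e-10)

    def test_matches_vegan_adjusted_r2(self, tmp_path):
        import shutil
        import subprocess

        rng = np.random.default_rng(1)
        pts = rng.standard_normal((10, 4))
        dm = euclidean_dm(pts)
        x = rng.standard_normal((10, 2))
        res = dbrda(dm, pd.DataFrame(x, columns=["a", "b"]))
        np.savetxt(tmp_path / "D.csv", dm.values, delimiter=",")
        np.savetxt(tmp_path / "X.csv", x, delimiter=",")
        script = tmp_path / "cap.R"
        script.write_text(
            'suppressMessages(library(vegan))\n'
            f'D <- as.dist(as.matrix(read.csv("{tmp_path}/D.csv", header=FALSE)))\n'
            f'X <- as.data.frame(read.csv("{tmp_path}/X.csv", header=FALSE))\n'
            'colnames(X) <- c("a","b")\n'
            'm <- capscale(D ~ a + b, data=X)\n'
            'r <- RsquareAdj(m)\n'
            'cat(sprintf("%.15g", c(r$r.squared, r$adj.r.squared)), sep="\\n")\n'
        )
        out = subprocess.run(
            [shutil.which("Rscript") or "Rscript", str(script)],
            capture_output=True, text=True, check=True,
        )
        r2_ref, adj_ref = map(float, out.stdout.split())
        assert res.r2 == pytest.approx(r2_ref, abs=1e-8)
        assert res.adj_r2 == pytest.approx(adj_ref, abs=1e-8)

    def test_null_permutation_p_calibrated(self):
        rng = np.random.default_rng(11)
        rejections = 0
        n_sim = 200
        for s in range(n_sim):
            pts = rng.standard_normal((12, 3))
            dm = euclidean_dm(pts)
            x = pd.DataFrame({"x": rng.standard_normal(12)})
            res = dbrda(dm, x, n_permutations=99, seed=s)
            rejections += res.p_value <= 0.05
        assert 0.01 <= rejections / n_sim <= 0.11

    def test_too_many_predictors(self):
        rng = np.random.default_rng(12)
        dm = euclidean_dm(rng.standard_normal((5, 2)))
        x = pd.DataFrame(rng.standard_normal((5, 5)), columns=list("abcde"))
        with pytest.raises(ValidationError):
            dbrda(dm, x)

    def test_deviation_matrix_shift_recorded(self):
        rng = np.random.default_rng(13)
        z = rng.standard_normal((8, 8))
        z = (z + z.T) / 2
        np.fill_diagonal(z, 0)
        dm = DistanceMatrix([f"s{i}" for i in range(8)], z, kind="deviation")
        res = dbrda(dm, pd.DataFrame({"x": rng.standard_normal(8)}))
        assert res.details["deviation_shift"] == pytest.approx(z.max())


class TestPcnm:
    def test_collinear_equidistant_oracle(self):
        pos = np.arange(4, dtype=float)
        d = np.abs(pos[:, None] - pos[None, :])
        dm = DistanceMatrix(list("abcd"), d)
        basis = pcnm(dm)
        assert basis.truncation_km == pytest.approx(1.0)
        # dense oracle: eigendecomposition of the truncated matrix
        trunc = np.where(d > 1.0, 4.0, d)
        np.fill_diagonal(trunc, 0.0)
        oracle = _gower_eig(trunc)
        np.testing.assert_allclose(basis.eigenvalues, oracle[: len(basis.eigenvalues)], atol=1e-8)
        # orthonormality
        g = basis.eigenvectors.T @ basis.eigenvectors
        np.testing.assert_allclose(g, np.eye(g.shape[0]), atol=1e-8)

    def test_duplicated_location_keeps_threshold(self):
        pos = np.array([0.0, 1.0, 2.0, 2.0])
        d = np.abs(pos[:, None] - pos[None, :])
        basis = pcnm(DistanceMatrix(list("abcd"), d))
        assert basis.truncation_km == pytest.approx(1.0)

    def test_identical_points_rejected(self):
        with pytest.raises(ValidationError):
            pcnm(DistanceMatrix(list("abc"), np.zeros((3, 3))))


class TestAdjustedR2:
    def test_reference_values(self):
        assert adjusted_r2(1.0, 20, 3) == pytest.approx(1.0)
        assert adjusted_r2(0.5, 10, 1) == pytest.approx(0.4375)
        assert adjusted_r2(0.0, 10, 2) < 0

    def test_never_exceeds_r2(self):
        rng = np.random.default_rng(14)
        for _ in range(50):
            r2 = rng.random()
            n = int(rng.integers(5, 50))
            p = int(rng.integers(0, n - 2))
            adj = adjusted_r2(r2, n, p)
            assert adj <= r2 + 1e-12
            if p == 0:
                assert adj == pytest.approx(r2)

    def test_insufficient_samples(self):
        with pytest.raises(ValidationError):
            adjusted_r2(0.5, 4, 3)


class TestForwardSelect:
    def _signal_data(self, seed, n=30, n_signal=2, n_noise=3):
        rng = np.random.default_rng(seed)
        x = pd.DataFrame(
            rng.standard_normal((n, n_signal + n_noise)),
            columns=[f"sig{i}" for i in range(n_signal)] + [f"noise{i}" for i in range(n_noise)],
        )
        resp = x.iloc[:, :n_signal].to_numpy() @ rng.uniform(1, 2, n_signal)
        resp = np.column_stack([resp, 0.1 * rng.standard_normal(n)])
        return euclidean_dm(resp), x

    def test_null_data_selects_nothing(self):
        rng = np.random.default_rng(15)
        dm = euclidean_dm(rng.standard_normal((20, 3)))
        x = pd.DataFrame(rng.standard_normal((20, 3)), columns=list("abc"))
        assert forward_select(dm, x, n_permutations=199, seed=0) == []

    def test_perfect_predictor_selected(self):
        rng = np.random.default_rng(16)
        x = rng.standard_normal(20)
        dm = euclidean_dm(np.column_stack([x, 2 * x]))
        sel = forward_select(dm, pd.DataFrame({"x": x}), n_permutations=199, seed=0)
        assert sel == ["x"]

    def test_signal_selected_noise_excluded(self):
        dm, x = self._signal_data(seed=17)
        sel = forward_select(dm, x, n_permutations=199, seed=1)
        assert sel  # the strong gradient is detected
        assert set(sel) <= {"sig0", "sig1"}
        assert not any(c.startswith("noise") for c in sel)

    def test_matches_independent_stepwise_oracle(self):
        # reimplement the double-stopping greedy selection from scratch
        # (lstsq fits instead of QR projections) on the same permutation
        # streams and require the identical selected sequence
        from elevassembly.ordination import pcoa, adjusted_r2

        dm, x = self._signal_data(seed=29, n=25)
        n_perm, seed = 99, 3
        sel = forward_select(dm, x, n_permutations=n_perm, seed=seed)

        y = pcoa(dm).scores
        n = y.shape[0]
        total = (y**2).sum()

        def r2_of(cols, yy):
            xm = x[list(cols)].to_numpy()
            xm = (xm - xm.mean(0)) / xm.std(0)
            coef, *_ = np.linalg.lstsq(xm, yy, rcond=None)
            return ((xm @ coef) ** 2).sum() / total, np.linalg.matrix_rank(xm)

        def stream(step):
            return np.random.default_rng(np.random.SeedSequence([seed, step]))

        cols = list(x.columns)
        r2f, mf = r2_of(cols, y)
        adj_full = adjusted_r2(r2f, n, mf)
        fobs = (r2f / mf) / ((1 - r2f) / (n - 1 - mf))
        rng = stream(0)
        exceed = sum(
            (lambda rp: (rp / mf) / ((1 - rp) / (n - 1 - mf)))(r2_of(cols, y[rng.permutation(n)])[0])
            >= fobs
            for _ in range(n_perm)
        )
        expected: list[str] = []
        if (exceed + 1) / (n_perm + 1) <= 0.05:
            chosen, r2_sel, m_sel, step = list(cols), 0.0, 0, 0
            remaining = list(cols)
            while remaining:
                step += 1
                scored = []
                for cand in remaining:
                    r2c, mc = r2_of(expected + [cand], y)
                    scored.append((adjusted_r2(r2c, n, mc), cand, r2c, mc))
                adj_c, cand, r2c, mc = max(scored)
                if adj_c > adj_full + 1e-12:
                    break
                dnum, dden = mc - m_sel, n - 1 - mc
                fpart = ((r2c - r2_sel) / dnum) / ((1 - r2c) / dden)
                rng = stream(step)
                exceed = 0
                for _ in range(n_perm):
                    yp = y[rng.permutation(n)]
                    r2cp, _ = r2_of(expected + [cand], yp)
                    r2sp = r2_of(expected, yp)[0] if expected else 0.0
                    if ((r2cp - r2sp) / dnum) / ((1 - r2cp) / dden) >= fpart:
                        exceed += 1
                if (exceed + 1) / (n_perm + 1) > 0.05:
                    break
                expected.append(cand)
                remaining.remove(cand)
                r2_sel, m_sel = r2c, mc
        assert sel == expected

    def test_seed_reproducible(self):
        dm, x = self._signal_data(seed=18)
        a = forward_select(dm, x, n_permutations=99, seed=5)
        b = forward_select(dm, x, n_permutations=99, seed=5)
        assert a == b


class TestVariationPartition:
    def test_identical_blocks_all_shared(self):
        rng = np.random.default_rng(19)
        dm = euclidean_dm(rng.standard_normal((15, 3)))
        x = pd.DataFrame({"v": rng.standard_normal(15)})
        x2 = x.rename(columns={"v": "w"})
        part = variation_partition(dm, x, x2)
        assert part.a == pytest.approx(0.0, abs=1e-10)
        assert part.c == pytest.approx(0.0, abs=1e-10)
        assert part.b == pytest.approx(part.adj_r2_env, abs=1e-10)

    def test_env_only_response(self):
        rng = np.random.default_rng(20)
        purity = []
        for s in range(20):
            n = 30
            env = rng.standard_normal((n, 2))
            space = rng.standard_normal((n, 2))
            # orthogonalize space against env
            q, _ = np.linalg.qr(np.column_stack([np.ones(n), env]))
            space = space - q @ (q.T @ space)
            resp = env @ np.array([[1.0, 0.3], [0.5, -1.0]]) + 0.2 * rng.standard_normal((n, 2))
            part = variation_partition(
                euclidean_dm(resp),
                pd.DataFrame(env, columns=["e1", "e2"]),
                pd.DataFrame(space, columns=["s1", "s2"]),
            )
            purity.append((part.a, part.c))
        a_mean = np.mean([p[0] for p in purity])
        c_mean = np.mean([p[1] for p in purity])
        assert a_mean > 0.5
        assert abs(c_mean) < 0.1

    def test_identity_exact(self):
        rng = np.random.default_rng(21)
        dm = euclidean_dm(rng.standard_normal((12, 4)))
        env = pd.DataFrame(rng.standard_normal((12, 2)), columns=["e1", "e2"])
        space = pd.DataFrame(rng.standard_normal((12, 2)), columns=["s1", "s2"])
        part = variation_partition(dm, env, space)
        assert part.a + part.b + part.c + part.d == pytest.approx(1.0, abs=1e-10)


class TestBootstrapFractionTest:
    def test_identical_blocks_p_one(self):
        rng = np.random.default_rng(22)
        dm = euclidean_dm(rng.standard_normal((12, 3)))
        x = pd.DataFrame({"v": rng.standard_normal(12)})
        res = bootstrap_fraction_test(dm, x, x.rename(columns={"v": "w"}),
                                      n_bootstrap=99, seed=0)
        assert res.p_value == pytest.approx(1.0)

    def test_strong_env_signal_detected(self):
        rng = np.random.default_rng(23)
        n = 60
        env = rng.standard_normal(n)
        space = rng.standard_normal(n)
        resp = np.column_stack([env, 0.5 * env]) + 0.1 * rng.standard_normal((n, 2))
        res = bootstrap_fraction_test(
            euclidean_dm(resp), pd.DataFrame({"e": env}), pd.DataFrame({"s": space}),
            n_bootstrap=199, seed=1,
        )
        assert res.observed_diff > 0
        assert res.p_value < 0.05

    def test_seed_determinism(self):
        rng = np.random.default_rng(24)
        dm = euclidean_dm(rng.standard_normal((10, 2)))
        env = pd.DataFrame({"e": rng.standard_normal(10)})
        space = pd.DataFrame({"s": rng.standard_normal(10)})
        p1 = bootstrap_fraction_test(dm, env, space, n_bootstrap=99, seed=7).p_value
        p2 = bootstrap_fraction_test(dm, env, space, n_bootstrap=99, seed=7).p_value
        assert p1 == p2

    def test_too_few_samples(self):
        rng = np.random.default_rng(25)
        dm = euclidean_dm(rng.standard_normal((6, 2)))
        with pytest.raises(ValidationError):
            bootstrap_fraction_test(dm, pd.DataFrame({"e": rng.standard_normal(6)}),
                                    pd.DataFrame({"s": rng.standard_normal(6)}),
                                    n_bootstrap=9, seed=0)
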