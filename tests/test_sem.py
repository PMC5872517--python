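"""Gaussian SEM semantics: path diagrams, implied moments, likelihood
factorization and the algebraic conditional-independence check."""

import numpy as np
import pytest
from scipy import stats

from rgsem.graph import global_markov_query
from rgsem.sem import (GeneralSEM, IntegrativeSEMParams, OmicsDataset,
                       cis_mask, conditional_moments, gaussian_ci,
                       joint_gaussian, load_params, loglik, path_diagram,
                       save_params)


def fig_config_sem(value=0.5):
    """SEM whose path diagram is the worked five-node example: Y1⇄Y2,
    X1→Y1, X2→Y2, X3→Y2, Ψ coupling X2−X3."""
    A = np.array([[0.0, value], [value, 0.0]])
    B = np.array([[value, 0.0, 0.0], [0.0, value, value]])
    Psi = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, value], [0.0, value, 1.0]])
    return GeneralSEM(A=A, B=B, Psi=Psi, err_var=np.ones(2))


def random_sem(rng, p, q, coef_low=0.3, coef_high=0.9, max_tries=50):
    """Random sparse SEM with coefficients bounded away from zero and a
    well-conditioned I−A; Ψ is block diagonal with 2-blocks."""
    for _ in range(max_tries):
        A = np.zeros((p, p))
        off = ~np.eye(p, dtype=bool)
        mask = (rng.random((p, p)) < 0.3) & off
        A[mask] = rng.uniform(coef_low, coef_high, mask.sum()) * rng.choice(
            [-1, 1], mask.sum())
        B = np.zeros((p, q))
        bmask = rng.random((p, q)) < 0.3
        B[bmask] = rng.uniform(coef_low, coef_high, bmask.sum()) * rng.choice(
            [-1, 1], bmask.sum())
        Psi = np.eye(q)
        for k in range(0, q - 1, 2):
            if rng.random() < 0.5:
                rho = rng.uniform(coef_low, 0.7) * rng.choice([-1, 1])
                Psi[k, k + 1] = Psi[k + 1, k] = rho
        m = np.eye(p) - A
        sv = np.linalg.svd(m, compute_uv=False)
        if sv[-1] / sv[0] > 1e-3:
            return GeneralSEM(A=A, B=B, Psi=Psi,
                              err_var=rng.uniform(0.5, 1.5, p))
    raise RuntimeError("no well-conditioned SEM found")


def random_integrative_params(rng, p=3):
    off = ~np.eye(p, dtype=bool)
    def sparse(shape, mask, scale=0.6):
        m = np.zeros(shape)
        sel = (rng.random(shape) < 0.4) & mask
        m[sel] = rng.uniform(0.3, scale, sel.sum()) * rng.choice([-1, 1], sel.sum())
        return m
    while True:
        A = sparse((p, p), off)
        C = sparse((p, p), off)
        D = sparse((p, p), np.ones((p, p), dtype=bool))
        B = sparse((p, 2 * p), cis_mask(p), scale=1.0)
        try:
            return IntegrativeSEMParams(
                A=A, B=B, C=C, D=D,
                sigma=rng.uniform(0.2, 1.0, p), lam=rng.uniform(0.2, 1.0, p))
        except ValueError:
            continue


def stacked_mvn_loglik(params, data):
    """Independent oracle: density of the stacked (Y, Z) vector given X
    under the joint Gaussian implied by the two-layer model."""
    p, n = data.p, data.n
    ia = np.linalg.inv(np.eye(p) - params.A)
    ic = np.linalg.inv(np.eye(p) - params.C)
    mean_y = ia @ params.B @ data.X
    mean_z = ic @ params.D @ mean_y
    v_y = ia @ np.diag(params.sigma) @ ia.T
    cross = v_y @ params.D.T @ ic.T
    v_z = ic @ (params.D @ v_y @ params.D.T + np.diag(params.lam)) @ ic.T
    cov = np.block([[v_y, cross], [cross.T, v_z]])
    cov = 0.5 * (cov + cov.T)
    stacked = np.vstack([data.Y, data.Z])
    means = np.vstack([mean_y, mean_z])
    mvn = stats.multivariate_normal(mean=np.zeros(2 * p), cov=cov)
    return float(np.sum(mvn.logpdf((stacked - means).T)))


class TestPathDiagram:
    def test_worked_configuration_gives_five_node_graph(self, fig_graph):
        assert path_diagram(fig_config_sem()) == fig_graph

    def test_empty_sem_gives_edgeless_graph(self):
        sem = GeneralSEM(A=np.zeros((2, 2)), B=np.zeros((2, 2)),
                         Psi=np.eye(2), err_var=np.ones(2))
        g = path_diagram(sem)
        assert not g.directed_edges and not g.undirected_edges

    def test_edges_round_trip_nonzero_pattern(self):
        rng = np.random.default_rng(10)
        for _ in range(20):
            sem = random_sem(rng, 3, 4)
            g = path_diagram(sem)
            dir_expected = set()
            for i in range(3):
                for j in range(3):
                    if sem.A[i, j] != 0:
                        dir_expected.add((f"Y{j+1}", f"Y{i+1}"))
                for j in range(4):
                    if sem.B[i, j] != 0:
                        dir_expected.add((f"X{j+1}", f"Y{i+1}"))
            und_expected = {
                frozenset((f"X{i+1}", f"X{j+1}"))
                for i in range(4) for j in range(i + 1, 4)
                if sem.Psi[i, j] != 0}
            assert set(g.directed_edges) == dir_expected
            assert {frozenset(e) for e in g.undirected_edges} == und_expected


class TestConditionalMoments:
    def test_identity_inverse_when_a_zero(self):
        p = 3
        rng = np.random.default_rng(0)
        params = IntegrativeSEMParams(
            A=np.zeros((p, p)), B=np.where(cis_mask(p), 1.0, 0.0),
            C=np.zeros((p, p)), D=np.zeros((p, p)),
            sigma=np.full(p, 0.5), lam=np.ones(p))
        X = rng.standard_normal((2 * p, 4))
        mean, cov = conditional_moments(params, "Y|X", X)
        np.testing.assert_allclose(mean, params.B @ X)
        np.testing.assert_allclose(cov, np.diag(params.sigma))

    def test_two_gene_feedback_against_explicit_inverse(self):
        a = 0.5
        params = IntegrativeSEMParams(
            A=np.array([[0.0, a], [a, 0.0]]), B=np.zeros((2, 4)),
            C=np.zeros((2, 2)), D=np.zeros((2, 2)),
            sigma=np.ones(2), lam=np.ones(2))
        _, cov = conditional_moments(params, "Y|X", np.zeros((4, 1)))
        inv = np.linalg.inv(np.array([[1.0, -a], [-a, 1.0]]))
        np.testing.assert_allclose(cov, inv @ inv.T, atol=1e-12)
        # closed form: (I-A)^-1 = [[1, a], [a, 1]]/(1-a^2)
        expected = np.array([[1 + a * a, 2 * a],
                             [2 * a, 1 + a * a]]) / (1 - a * a) ** 2
        np.testing.assert_allclose(cov, expected, atol=1e-12)

    def test_monte_carlo_covariance_agreement(self):
        rng = np.random.default_rng(11)
        params = random_integrative_params(rng)
        p, n = params.p, 100000
        ey = rng.standard_normal((p, n)) * np.sqrt(params.sigma)[:, None]
        Y = np.linalg.solve(np.eye(p) - params.A, ey)
        _, cov = conditional_moments(params, "Y|X", np.zeros((2 * p, 1)))
        emp = np.cov(Y)
        assert np.max(np.abs(emp - cov)) < 10 * np.max(np.abs(cov)) / np.sqrt(n) * 3 + 0.05

    def test_singular_structural_matrix_names_layer(self):
        params = IntegrativeSEMParams(
            A=np.zeros((2, 2)), B=np.zeros((2, 4)), C=np.zeros((2, 2)),
            D=np.zeros((2, 2)), sigma=np.ones(2), lam=np.ones(2))
        params.A = np.array([[0.0, 1.0], [1.0, 0.0]])  # det(I-A) = 0
        with pytest.raises(ValueError, match="Y|X"):
            conditional_moments(params, "Y|X", np.zeros((4, 1)))


class TestLoglik:
    def test_standard_normal_case(self):
        p = 2
        params = IntegrativeSEMParams(
            A=np.zeros((p, p)), B=np.zeros((p, 2 * p)), C=np.zeros((p, p)),
            D=np.zeros((p, p)), sigma=np.ones(p), lam=np.ones(p))
        rng = np.random.default_rng(1)
        y = rng.standard_normal((p, 1))
        z = rng.standard_normal((p, 1))
        data = OmicsDataset([f"g{i}" for i in range(p)],
                            np.zeros((2 * p, 1)), y, z)
        expected = (-(2 * p / 2) * np.log(2 * np.pi)
                    - 0.5 * (np.sum(y ** 2) + np.sum(z ** 2)))
        assert loglik(params, data) == pytest.approx(expected, abs=1e-10)

    def test_matches_stacked_joint_gaussian_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(25):
            params = random_integrative_params(rng)
            p = params.p
            n = 7
            data = OmicsDataset(
                [f"g{i}" for i in range(p)],
                rng.standard_normal((2 * p, n)),
                rng.standard_normal((p, n)),
                rng.standard_normal((p, n)))
            assert loglik(params, data) == pytest.approx(
                stacked_mvn_loglik(params, data), abs=1e-8)

    def test_invariant_to_x_shift_when_b_zero(self):
        rng = np.random.default_rng(13)
        params = random_integrative_params(rng)
        params.B[:] = 0.0
        p, n = params.p, 9
        data = OmicsDataset([f"g{i}" for i in range(p)],
                            rng.standard_normal((2 * p, n)),
                            rng.standard_normal((p, n)),
                            rng.standard_normal((p, n)))
        shifted = OmicsDataset(list(data.gene_labels), data.X + 5.0,
                               data.Y, data.Z)
        assert loglik(params, data) == pytest.approx(
            loglik(params, shifted), abs=1e-10)

    def test_invariant_to_masked_b_entries(self):
        # cis-masked entries are structurally zero, so they cannot move
        rng = np.random.default_rng(14)
        params = random_integrative_params(rng)
        p, n = params.p, 5
        data = OmicsDataset([f"g{i}" for i in range(p)],
                            rng.standard_normal((2 * p, n)),
                            rng.standard_normal((p, n)),
                            rng.standard_normal((p, n)))
        base = loglik(params, data)
        perturbed = params.B.copy()
        perturbed[~cis_mask(p)] += rng.standard_normal((~cis_mask(p)).sum())
        with pytest.raises(ValueError):
            IntegrativeSEMParams(A=params.A, B=perturbed, C=params.C,
                                 D=params.D, sigma=params.sigma,
                                 lam=params.lam)
        assert loglik(params, data) == base


class TestJointGaussian:
    def test_block_diagonal_when_no_edges(self):
        sem = GeneralSEM(A=np.zeros((2, 2)), B=np.zeros((2, 3)),
                         Psi=np.eye(3), err_var=np.array([2.0, 3.0]))
        cov = joint_gaussian(sem)
        np.testing.assert_allclose(cov[:2, :2], np.diag([2.0, 3.0]))
        np.testing.assert_allclose(cov[2:, 2:], np.eye(3))
        np.testing.assert_allclose(cov[:2, 2:], 0.0)

    def test_worked_configuration_zero_pattern(self):
        # X1 is marginally independent of X2 and X3 in the implied law
        cov = joint_gaussian(fig_config_sem())
        # index order (Y1, Y2, X1, X2, X3)
        assert cov[2, 3] == pytest.approx(0.0, abs=1e-12)
        assert cov[2, 4] == pytest.approx(0.0, abs=1e-12)
        assert cov[3, 4] != 0.0

    def test_matches_forward_simulation(self):
        rng = np.random.default_rng(15)
        sem = random_sem(rng, 3, 4)
        n = 100000
        X = np.linalg.cholesky(sem.Psi) @ rng.standard_normal((4, n))
        E = np.sqrt(sem.err_var)[:, None] * rng.standard_normal((3, n))
        Y = np.linalg.solve(np.eye(3) - sem.A, sem.B @ X + E)
        emp = np.cov(np.vstack([Y, X]))
        cov = joint_gaussian(sem)
        scale = np.sqrt(np.outer(np.diag(cov), np.diag(cov)))
        assert np.max(np.abs(emp - cov) / scale) < 0.05

    def test_positive_definite(self):
        rng = np.random.default_rng(16)
        for _ in range(20):
            cov = joint_gaussian(random_sem(rng, 3, 4))
            assert np.all(np.linalg.eigvalsh(cov) > 0)


class TestGaussianCI:
    def test_diagonal_cov_everything_independent(self):
        cov = np.diag([1.0, 2.0, 3.0, 4.0])
        assert gaussian_ci(cov, [0], [1], [])
        assert gaussian_ci(cov, [0], [2, 3], [1])

    def test_worked_configuration_marginal_independence(self):
        cov = joint_gaussian(fig_config_sem())
        assert gaussian_ci(cov, [2], [3, 4], [])          # X1 vs X2,X3
        assert gaussian_ci(cov, [2], [3, 4], [0, 1])      # given Y1,Y2
        assert not gaussian_ci(cov, [3], [4], [0, 1, 2])  # X2-X3 coupled

    def test_full_conditioning_matches_precision_zero_pattern(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            cov = joint_gaussian(random_sem(rng, 3, 3))
            prec = np.linalg.inv(cov)
            d = np.sqrt(np.diag(prec))
            pcorr = prec / np.outer(d, d)
            k = cov.shape[0]
            for i in range(k):
                for j in range(i + 1, k):
                    others = [m for m in range(k) if m not in (i, j)]
                    assert gaussian_ci(cov, [i], [j], others) == (
                        abs(pcorr[i, j]) < 1e-8)

    def test_rejects_non_positive_definite(self):
        with pytest.raises(ValueError, match="positive definite"):
            gaussian_ci(np.array([[1.0, 2.0], [2.0, 1.0]]), [0], [1], [])


class TestPathDiagramMarkovEquivalence:
    def test_separation_implies_vanishing_partial_covariance(self):
        """Graphical independence statements read off the path diagram hold
        in the implied Gaussian law; the converse holds generically."""
        rng = np.random.default_rng(18)
        agree_converse = 0
        total_ci = 0
        for _ in range(60):
            p = int(rng.integers(1, 4))
            q = int(rng.integers(2, 9 - p))
            sem = random_sem(rng, p, q)
            g = path_diagram(sem)
            cov = joint_gaussian(sem)
            labels = list(g.nodes)
            idx = {lab: k for k, lab in enumerate(
                [f"Y{i+1}" for i in range(p)] + [f"X{j+1}" for j in range(q)])}
            nodes = list(idx)
            for _ in range(20):
                rng.shuffle(nodes)
                a, b = {nodes[0]}, {nodes[1]}
                c = set(nodes[2: 2 + int(rng.integers(0, len(nodes) - 1))])
                sep = global_markov_query(g, a, b, c)
                ci = gaussian_ci(cov, [idx[v] for v in a],
                                 [idx[v] for v in b], [idx[v] for v in c])
                if sep:
                    assert ci  # the guaranteed direction
                if ci:
                    total_ci += 1
                    agree_converse += sep
        assert total_ci > 0
        assert agree_converse / total_ci >= 0.99


class TestSerialization:
    def test_params_json_round_trip(self, tmp_path):
        rng = np.random.default_rng(19)
        params = random_integrative_params(rng)
        path = tmp_path / "params.json"
        save_params(params, path)
        loaded = load_params(path)
        for name in ("A", "B", "C", "D", "sigma", "lam"):
            np.testing.assert_array_equal(getattr(loaded, name),
                                          getattr(params, name))
        assert loaded.gene_labels == params.gene_labels


class TestOmicsDataset:
    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="matching sample counts"):
            OmicsDataset(["g1", "g2"], np.zeros((4, 3)), np.zeros((2, 3)),
                         np.zeros((2, 4)))

    def test_non_finite_rejected(self):
        X = np.zeros((4, 3))
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            OmicsDataset(["g1", "g2"], X, np.zeros((2, 3)), np.zeros((2, 3)))

    def test_standardize_gives_unit_variance_rows(self):
        rng = np.random.default_rng(20)
        data = OmicsDataset(["g1", "g2"], 3 * rng.standard_normal((4, 50)) + 2,
                            rng.standard_normal((2, 50)),
                            5 * rng.standard_normal((2, 50)))
        std = data.standardize()
        for blk in (std.X, std.Y, std.Z):
            np.testing.assert_allclose(blk.mean(axis=1), 0.0, atol=1e-12)
            np.testing.assert_allclose(blk.std(axis=1, ddof=1), 1.0,
                                       atol=1e-12)
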