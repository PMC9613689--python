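"""Coexpression networks: adjacency/TOM oracles, module detection and the VRM."""

import numpy as np
import pandas as pd
import pytest

from parawasp.coexpression import (
    Network,
    adjacency,
    detect_modules,
    identify_vrm,
    kme,
    module_eigengene,
    module_shift_analysis,
    tom,
    vrm_absence_check,
)
from parawasp.simulate import gen_expression_pair


def block_matrix(rng, sizes, within_cor, n_samples=12, scale=1.0):
    """Genes in the same block share a latent factor with the given
    within-block correlation; blocks are mutually independent."""
    rows = []
    w = np.sqrt(within_cor)
    for b, size in enumerate(sizes):
        factor = rng.normal(size=n_samples)
        for _ in range(size):
            noise = rng.normal(size=n_samples)
            rows.append(w * factor + np.sqrt(1 - within_cor) * noise)
    genes = [f"g{i:04d}" for i in range(sum(sizes))]
    return pd.DataFrame(scale * (np.array(rows) + 5.0),
                        index=genes, columns=[f"s{j}" for j in range(n_samples)])


class TestAdjacency:
    def test_perfect_correlation_gives_one(self):
        expr = pd.DataFrame(
            [[1.0, 2, 3, 4], [2.0, 4, 6, 8], [4, 3, 2, 1]],
            index=["a", "b", "c"], columns=list("wxyz"),
        )
        net = adjacency(expr, beta=4)
        i, j = net.genes.index("a"), net.genes.index("b")
        assert net.adjacency[i, j] == pytest.approx(1.0)

    def test_negative_half_correlation_fourth_power(self):
        # |cor|^4 at cor = -0.5 must equal 0.0625 (checked elementwise)
        rng = np.random.default_rng(1)
        x = rng.normal(size=200)
        e = rng.normal(size=200)
        # construct y with exact sample correlation -0.5
        xz = (x - x.mean()) / x.std()
        ez = e - e.mean()
        ez -= xz * (xz @ ez) / (xz @ xz)  # orthogonalise
        ez /= ez.std()
        y = -0.5 * xz + np.sqrt(1 - 0.25) * ez
        expr = pd.DataFrame([x, y], index=["a", "b"],
                            columns=[f"s{i}" for i in range(200)])
        net = adjacency(expr, beta=4)
        assert net.adjacency[0, 1] == pytest.approx(0.0625, abs=1e-12)

    def test_elementwise_oracle_on_toy_matrix(self, rng):
        expr = pd.DataFrame(
            rng.normal(size=(3, 8)) + 5,
            index=["a", "b", "c"], columns=[f"s{i}" for i in range(8)],
        )
        net = adjacency(expr, beta=4)
        mat = expr.to_numpy()
        for i in range(3):
            for j in range(3):
                expected = 0.0 if i == j else abs(np.corrcoef(mat[i], mat[j])[0, 1]) ** 4
                assert net.adjacency[i, j] == pytest.approx(expected)

    def test_constant_gene_dropped_with_warning(self, rng):
        expr = pd.DataFrame(
            np.vstack([rng.normal(size=(2, 6)) + 5, np.full(6, 3.0)]),
            index=["a", "b", "const"], columns=[f"s{i}" for i in range(6)],
        )
        with pytest.warns(UserWarning, match="constant"):
            net = adjacency(expr)
        assert net.genes == ["a", "b"]

    def test_all_zero_genes_filtered(self, rng):
        expr = pd.DataFrame(
            np.vstack([rng.normal(size=(2, 6)) + 5, np.zeros(6)]),
            index=["a", "b", "zero"], columns=[f"s{i}" for i in range(6)],
        )
        assert "zero" not in adjacency(expr).genes


class TestTom:
    def uniform_network(self, n, a):
        adj = np.full((n, n), a, dtype=float)
        np.fill_diagonal(adj, 0.0)
        return Network(genes=[f"g{i}" for i in range(n)], adjacency=adj)

    def test_three_node_uniform_half(self):
        t = tom(self.uniform_network(3, 0.5))
        assert t[0, 1] == pytest.approx(0.5)  # (0.25 + 0.5) / (1 + 1 - 0.5)
        assert np.allclose(np.diag(t), 1.0)

    def test_empty_network_gives_zero_overlap(self):
        t = tom(self.uniform_network(3, 0.0))
        off = t[~np.eye(3, dtype=bool)]
        assert np.allclose(off, 0.0)

    def test_complete_network_gives_one(self):
        t = tom(self.uniform_network(3, 1.0))
        assert t[0, 1] == pytest.approx(1.0)  # (1 + 1) / (2 + 1 - 1)

    def test_matches_brute_force_triple_loop(self, rng):
        n = 15
        adj = rng.uniform(0, 1, size=(n, n))
        adj = (adj + adj.T) / 2
        np.fill_diagonal(adj, 0.0)
        net = Network(genes=[f"g{i}" for i in range(n)], adjacency=adj)
        t = tom(net)
        k = adj.sum(axis=1)
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                shared = sum(adj[i, u] * adj[u, j] for u in range(n))
                expected = (shared + adj[i, j]) / (min(k[i], k[j]) + 1 - adj[i, j])
                assert t[i, j] == pytest.approx(expected, abs=1e-12)
        assert np.all((t >= 0) & (t <= 1 + 1e-12))


class TestModuleEigengene:
    def test_identical_profiles_explain_all_variance(self):
        profile = np.array([1.0, 5.0, 2.0, 8.0, 3.0, 4.0])
        expr = pd.DataFrame(
            [profile, 2 * profile, 0.5 * profile],
            index=["a", "b", "c"], columns=[f"s{i}" for i in range(6)],
        )
        me = module_eigengene(expr, ["a", "b", "c"])
        z = (profile - profile.mean()) / profile.std()
        assert abs(np.corrcoef(me, z)[0, 1]) == pytest.approx(1.0)
        assert np.corrcoef(me, profile)[0, 1] > 0  # sign convention

    def test_sign_convention_is_deterministic(self, rng):
        expr = pd.DataFrame(
            rng.normal(size=(6, 10)) + 5,
            index=[f"g{i}" for i in range(6)],
            columns=[f"s{i}" for i in range(10)],
        )
        me1 = module_eigengene(expr, list(expr.index))
        me2 = module_eigengene(expr.iloc[::-1], list(expr.index)[::-1])
        assert np.allclose(me1.to_numpy(), me2.to_numpy())

    def test_single_gene_module_returns_standardized_profile(self):
        expr = pd.DataFrame([[1.0, 2.0, 3.0, 4.0]], index=["a"],
                            columns=list("wxyz"))
        me = module_eigengene(expr, ["a"])
        assert np.allclose(me.mean(), 0.0) and me.iloc[-1] > 0

    def test_factor_recovery_under_noise(self, rng):
        factor = rng.normal(size=20)
        rows = [factor + rng.normal(0, 0.2, size=20) for _ in range(40)]
        expr = pd.DataFrame(rows, index=[f"g{i}" for i in range(40)],
                            columns=[f"s{i}" for i in range(20)])
        me = module_eigengene(expr, list(expr.index))
        assert abs(np.corrcoef(me, factor)[0, 1]) > 0.95


class TestKme:
    def test_self_and_anti(self):
        me = np.array([1.0, 2.0, -1.0, 0.5, 3.0])
        assert kme(me, me) == pytest.approx(1.0)
        assert kme(-me, me) == pytest.approx(-1.0)

    def test_matches_direct_correlation(self, rng):
        g = rng.normal(size=5)
        m = rng.normal(size=5)
        assert kme(g, m) == pytest.approx(np.corrcoef(g, m)[0, 1])

    def test_constant_input_is_nan(self):
        assert np.isnan(kme([1, 1, 1], [1, 2, 3]))


class TestDetectModules:
    def test_two_planted_blocks_recovered(self, rng):
        expr = block_matrix(rng, [40, 40], within_cor=0.9)
        modules = detect_modules(expr)
        labels = modules.labels
        blocks = [set(labels.index[:40]), set(labels.index[40:])]
        found = [set(modules.members(m)) for m in modules.module_names()]
        assert len(found) == 2
        assert {frozenset(b) for b in blocks} == {frozenset(f) for f in found}

    def test_small_block_stays_unassigned(self, rng):
        expr = block_matrix(rng, [40, 10], within_cor=0.9)
        modules = detect_modules(expr)
        small = expr.index[40:]
        assert set(modules.labels.loc[small]) == {"grey"}

    def test_rand_index_on_planted_partition(self, rng):
        from sklearn.metrics import rand_score

        expr = block_matrix(rng, [50, 50, 50, 50], within_cor=0.8, n_samples=12)
        modules = detect_modules(expr)
        truth = np.repeat(np.arange(4), 50)
        pred = pd.factorize(modules.labels)[0]
        assert rand_score(truth, pred) >= 0.95

    def test_highly_correlated_modules_merge(self, rng):
        # two blocks driven by nearly the same factor merge under the
        # eigengene-correlation >= 0.75 rule
        n_samples = 12
        factor = rng.normal(size=n_samples)
        rows = []
        for _ in range(80):
            rows.append(0.97 * factor + 0.15 * rng.normal(size=n_samples))
        expr = pd.DataFrame(rows, index=[f"g{i}" for i in range(80)],
                            columns=[f"s{j}" for j in range(n_samples)])
        modules = detect_modules(expr)
        assert len(modules.module_names()) == 1

    def test_fewer_genes_than_min_size_all_unassigned(self, rng):
        expr = block_matrix(rng, [10], within_cor=0.9)
        with pytest.warns(UserWarning):
            modules = detect_modules(expr)
        assert set(modules.labels) == {"grey"}


class TestVrm:
    def test_argmax_and_fraction(self, rng):
        expr = block_matrix(rng, [40, 40], within_cor=0.9)
        modules = detect_modules(expr)
        venom = list(expr.index[:36]) + list(expr.index[40:44])
        vrm, frac = identify_vrm(modules, venom)
        assert set(modules.members(vrm)) == set(expr.index[:40])
        assert frac == pytest.approx(0.9)

    def test_tie_breaks_to_smaller_label(self, rng):
        expr = block_matrix(rng, [40, 40], within_cor=0.9)
        modules = detect_modules(expr)
        venom = list(expr.index[:5]) + list(expr.index[40:45])
        with pytest.warns(UserWarning, match="tie"):
            vrm, frac = identify_vrm(modules, venom)
        assert vrm == min(modules.module_names())

    def test_no_assigned_venom_gene_raises(self, rng):
        expr = block_matrix(rng, [40], within_cor=0.9)
        modules = detect_modules(expr)
        with pytest.raises(ValueError):
            identify_vrm(modules, ["not_a_gene"])


@pytest.fixture(scope="module")
def sim():
    return gen_expression_pair(n_genes=500, seed=13)


@pytest.fixture(scope="module")
def modules_pair(sim):
    return detect_modules(sim["expr_a"]), detect_modules(sim["expr_b"])


class TestPlantedPipeline:
    def test_planted_module_recovered(self, sim, modules_pair):
        mod_a, _ = modules_pair
        truth = sim["truth"]
        vrm, frac = identify_vrm(mod_a, truth["venom_genes_a"])
        members = set(mod_a.members(vrm))
        planted = set(truth["module_genes_a"])
        assert len(members & planted) / len(planted) >= 0.9
        assert frac >= 0.9

    def test_member_kme_exceeds_nonmember_kme(self, sim, modules_pair):
        mod_a, _ = modules_pair
        truth = sim["truth"]
        vrm, _ = identify_vrm(mod_a, truth["venom_genes_a"])
        me = mod_a.eigengenes[vrm]
        planted = set(truth["module_genes_a"])
        inside = [abs(kme(sim["expr_a"].loc[g], me)) for g in planted]
        outside = [
            abs(kme(sim["expr_a"].loc[g], me))
            for g in sim["expr_a"].index[:200]
            if g not in planted
        ]
        assert np.median(inside) > np.median(outside)

    def test_vrm_dispersal_without_venom_gland_samples(self, sim):
        report = vrm_absence_check(
            sim["expr_a"], sim["sample_labels"], sim["truth"]["venom_genes_a"]
        )
        assert report["dispersed"]
        assert report["max_venom_fraction"] < 0.5

    def test_missing_vg_label_raises(self, sim):
        labels = {s: "larva" for s in sim["expr_a"].columns}
        with pytest.raises(ValueError):
            vrm_absence_check(sim["expr_a"], labels, sim["truth"]["venom_genes_a"])

    def test_periphery_shift_pattern(self, sim, modules_pair):
        mod_a, mod_b = modules_pair
        truth = sim["truth"]
        vrm_a, _ = identify_vrm(mod_a, truth["venom_genes_a"])
        vrm_b, _ = identify_vrm(mod_b, truth["venom_genes_b"])
        report = module_shift_analysis(
            mod_a, mod_b, sim["ortholog_map"], truth["venom_genes_a"], vrm_a, vrm_b
        )
        # planted shifts sit in the low-connectivity periphery
        assert np.median(report["shifted_kme"]) < np.median(report["conserved_kme"])
        # planted module shifts are non-venom-biased: shift rate of venom
        # genes is below that of non-venom members
        table = report["shift_table"]
        venom_rate = table[0, 0] / table[0].sum()
        nonvenom_rate = table[1, 0] / table[1].sum()
        assert venom_rate < nonvenom_rate

    def test_chi2_matches_closed_form_on_shift_table(self, sim, modules_pair):
        from parawasp.stats import chi2_2x2

        mod_a, mod_b = modules_pair
        truth = sim["truth"]
        vrm_a, _ = identify_vrm(mod_a, truth["venom_genes_a"])
        vrm_b, _ = identify_vrm(mod_b, truth["venom_genes_b"])
        report = module_shift_analysis(
            mod_a, mod_b, sim["ortholog_map"], truth["venom_genes_a"], vrm_a, vrm_b
        )
        t = report["shift_table"].astype(float)
        a, b = t[0]
        c, d = t[1]
        n = t.sum()
        expected = n * (a * d - b * c) ** 2 / (
            (a + b) * (c + d) * (a + c) * (b + d)
        )
        assert report["shift_chi2"].chi2 == pytest.approx(expected, abs=1e-10)
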