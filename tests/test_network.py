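import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import perturbome as pb
from perturbome.network import (
    CoexpressionModules,
    classify_modules,
    detect_modules,
    merge_modules,
    module_eigengene,
    module_trait_correlation,
    pick_soft_power,
    scale_free_fit,
    tom_from_expression,
)


def orthogonal_genes():
    """Genes with pairwise-zero correlation except a perfect pair (g1, g2)."""
    return pd.DataFrame(
        {
            "s1": [1, 1, 1, 1],
            "s2": [-1, -1, 1, -1],
            "s3": [1, 1, -1, -1],
            "s4": [-1, -1, -1, 1],
        },
        index=["g1", "g2", "g3", "g4"],
        dtype=float,
    )


def tom_oracle(expr, beta):
    """Element-by-element evaluation of the unsigned TOM formula."""
    a = np.abs(np.corrcoef(expr.to_numpy())) ** beta
    np.fill_diagonal(a, 1.0)
    n = a.shape[0]
    tom = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            ki = sum(a[i, u] for u in range(n) if u != i)
            kj = sum(a[j, u] for u in range(n) if u != j)
            tom[i, j] = (l + a[i, j]) / (min(ki, kj) + 1 - a[i, j])
    return tom


def modular_design(seed, n_genes=500, sizes=(120, 100, 80, 60, 40), growth_idx=1):
    return pb.SyntheticDesign(
        n_genes=n_genes,
        genome_length=n_genes * 1000,
        module_sizes=sizes,
        growth_module_index=growth_idx,
        frac_affected_G=0,
        frac_affected_S=0,
        frac_affected_E=0,
        noise_sd=0.2,
        replicates=2,
        seed=seed,
    )


class TestTom:
    def test_perfect_pair(self):
        tom = tom_from_expression(orthogonal_genes(), beta=12)
        assert tom[0, 1] == pytest.approx(1.0)
        assert tom[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_all_orthogonal_gives_zero_offdiag(self):
        expr = orthogonal_genes().iloc[1:]  # drop the duplicate gene
        tom = tom_from_expression(expr, beta=2)
        off = tom[~np.eye(3, dtype=bool)]
        assert np.allclose(off, 0.0, atol=1e-12)

    @pytest.mark.parametrize("n_genes", [6, 8, 10])
    def test_matches_direct_formula(self, n_genes, rng):
        expr = pd.DataFrame(rng.normal(0, 1, (n_genes, 8)))
        tom = tom_from_expression(expr, beta=6)
        assert np.abs(tom - tom_oracle(expr, 6)).max() < 1e-10

    def test_range_and_symmetry(self, rng):
        expr = pd.DataFrame(rng.normal(0, 1, (12, 6)))
        tom = tom_from_expression(expr, beta=12)
        assert tom.min() >= 0 and tom.max() <= 1
        assert np.allclose(tom, tom.T)
        assert np.allclose(np.diag(tom), 1.0)

    def test_constant_gene_error(self, rng):
        expr = pd.DataFrame(rng.normal(0, 1, (4, 5)), index=list("abcd"))
        expr.loc["c"] = 3.0
        with pytest.raises(ValueError, match="c"):
            tom_from_expression(expr, beta=2)


class TestSoftPower:
    def test_zero_target_returns_smallest_power(self, small_dataset):
        _, expr, _ = small_dataset
        beta, _, reached = pick_soft_power(expr.iloc[:200], r2_target=0.0,
                                           candidate_powers=(2, 4, 6))
        assert beta == 2 and reached

    def test_power_law_connectivity_fits_well(self, rng):
        k = (rng.pareto(1.5, 4000) + 1) * 3
        assert scale_free_fit(k) > 0.9

    def test_matches_independent_sweep(self, rng):
        design = modular_design(5)
        expr, _ = pb.generate_expression(design)
        powers = tuple(range(2, 15))
        beta, _, _ = pick_soft_power(expr, r2_target=0.9, candidate_powers=powers)
        # independent sweep applying the documented rule
        c = np.abs(np.corrcoef(expr.to_numpy()))
        best = None
        for b in powers:
            k = (c**b).sum(axis=0) - 1
            r2 = scale_free_fit(k)
            if r2 >= 0.9:
                best = b
                break
            if best is None or r2 > best_r2:
                best, best_r2 = b, r2
        assert abs(beta - best) <= 2


class TestDetectModules:
    def test_two_perfect_blocks(self, rng):
        f1, f2 = rng.normal(0, 1, 10), rng.normal(0, 1, 10)
        genes = [f1 * l for l in rng.uniform(0.5, 1.5, 60)] + [
            f2 * l for l in rng.uniform(0.5, 1.5, 60)
        ]
        expr = pd.DataFrame(genes) + rng.normal(0, 1e-6, (120, 10))
        tom = tom_from_expression(expr, beta=6)
        labels = detect_modules(tom, min_module_size=30)
        truth = np.repeat([1, 2], 60)
        assert adjusted_rand_score(truth, labels) == pytest.approx(1.0)

    def test_noise_goes_to_module_zero(self):
        unassigned = []
        for s in range(3):
            expr = pd.DataFrame(np.random.default_rng(s).normal(0, 1, (200, 12)))
            tom = tom_from_expression(expr, beta=12)
            labels = detect_modules(tom, min_module_size=30)
            unassigned.append(np.mean(labels == 0))
        assert np.mean(unassigned) > 0.7

    def test_permutation_equivariance(self, rng):
        design = modular_design(9, n_genes=200, sizes=(60, 50, 40), growth_idx=None)
        expr, _ = pb.generate_expression(design)
        tom = tom_from_expression(expr, beta=6)
        labels = detect_modules(tom, min_module_size=30)
        perm = rng.permutation(len(expr))
        labels_p = detect_modules(tom[np.ix_(perm, perm)], min_module_size=30)
        assert adjusted_rand_score(labels[perm], labels_p) == pytest.approx(1.0)


class TestEigengene:
    def test_identical_genes(self, rng):
        profile = rng.normal(0, 1, 8)
        expr = pd.DataFrame([profile] * 5, index=[f"g{i}" for i in range(5)])
        e = module_eigengene(expr, expr.index)
        z = (profile - profile.mean()) / profile.std()
        assert np.allclose(e, z, atol=1e-9)

    def test_sign_alignment_deterministic(self, rng):
        expr = pd.DataFrame(rng.normal(0, 1, (6, 8)))
        e1 = module_eigengene(expr, expr.index)
        e2 = module_eigengene(-expr, expr.index)
        assert np.allclose(e1, -e2, atol=1e-9)

    def test_recovers_latent_factor(self):
        design = modular_design(3)
        expr, truth = pb.generate_expression(design)
        for m in (1, 2, 3):
            genes = expr.index[truth.module_labels == m]
            e = module_eigengene(expr, genes)
            f = truth.factors[f"F{m}"].to_numpy()
            assert abs(np.corrcoef(e, f)[0, 1]) >= 0.95

    def test_singular_module_error(self):
        expr = pd.DataFrame(np.ones((3, 5)), index=list("abc"))
        with pytest.raises(ValueError):
            module_eigengene(expr, expr.index)


class TestMerge:
    def test_split_halves_of_one_factor_merge(self, rng):
        f = rng.normal(0, 1, 12)
        genes = np.array([f * l for l in rng.uniform(0.5, 1.5, 80)])
        expr = pd.DataFrame(genes + rng.normal(0, 0.05, genes.shape))
        labels = np.repeat([1, 2], 40)  # artificial split of one module
        merged = merge_modules(expr, labels, merge_height=0.25)
        assert len(np.unique(merged)) == 1

    def test_distinct_factors_not_merged(self, rng):
        f1 = rng.normal(0, 1, 12)
        f2 = rng.normal(0, 1, 12)
        f2 -= f2 @ f1 / (f1 @ f1) * f1  # orthogonal: eigengene cor ~ 0
        genes = [f1 * l for l in rng.uniform(0.5, 1.5, 40)] + [
            f2 * l for l in rng.uniform(0.5, 1.5, 40)
        ]
        expr = pd.DataFrame(np.array(genes) + rng.normal(0, 0.05, (80, 12)))
        labels = np.repeat([1, 2], 40)
        merged = merge_modules(expr, labels.copy(), merge_height=0.25)
        assert adjusted_rand_score(labels, merged) == pytest.approx(1.0)

    def test_idempotent(self):
        design = modular_design(4)
        expr, _ = pb.generate_expression(design)
        tom = tom_from_expression(expr, beta=6)
        labels = detect_modules(tom, min_module_size=30)
        once = merge_modules(expr, labels, 0.25)
        twice = merge_modules(expr, once, 0.25)
        assert np.array_equal(once, twice)


class TestTraitCorrelation:
    def test_eigengene_equals_trait(self, rng):
        t = rng.normal(0, 1, 10)
        eg = pd.DataFrame({"M1": (t - t.mean()) / t.std()})
        res = module_trait_correlation(eg, t)
        assert res.loc["M1", "r"] == pytest.approx(1.0)
        assert res.loc["M1", "significant"]

    def test_orthogonal_eigengene(self):
        t = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        e = np.array([1.0, 1.0, -1.0, -1.0, 1.0, 1.0])
        e = e - e @ t / (t @ t) * t
        res = module_trait_correlation(pd.DataFrame({"M1": e}), t)
        assert res.loc["M1", "r"] == pytest.approx(0.0, abs=1e-12)
        assert res.loc["M1", "p"] == pytest.approx(1.0)

    def test_constant_trait_error(self, rng):
        eg = pd.DataFrame({"M1": rng.normal(0, 1, 5)})
        with pytest.raises(ValueError):
            module_trait_correlation(eg, np.ones(5))

    def test_growth_module_flagged_exclusively(self):
        design = modular_design(6)
        expr, truth = pb.generate_expression(design)
        model = CoexpressionModules(soft_power=6, min_module_size=30).fit(expr.T)
        trait = np.array(
            [truth.growth_rate[c] for c in truth.design_table["condition"]]
        )
        res = model.correlate_trait(trait)
        sig = set(res.index[res["significant"]])
        growth_label = None
        for m in np.unique(model.labels_):
            if m and np.mean(truth.module_labels[model.labels_ == m] == 2) > 0.5:
                growth_label = f"M{m}"
        assert sig == {growth_label}


class TestClassify:
    def _table(self, sig_map):
        rows = []
        for module, contrasts in sig_map.items():
            for c in ("dG", "dS", "dE", "dGS", "dGE", "dES"):
                rows.append({"module": module, "contrast": c,
                             "significant": c in contrasts})
        return pd.DataFrame(rows).set_index(["module", "contrast"])

    def test_three_way_rule(self):
        table = self._table(
            {"M1": set(), "M6": {"dS"}, "M2": {"dG", "dGS"}, "M9": {"dS", "dGE"}}
        )
        cls = classify_modules(table)
        assert cls["M1"] == "conserved"
        assert cls["M6"] == "epistatic"
        assert cls["M2"] == "responsive"
        assert cls["M9"] == "epistatic"  # dGE is not a stress-containing dual

    def test_stress_dual_cancels_epistatic_call(self):
        cls = classify_modules(self._table({"M4": {"dS", "dGS"}}))
        assert cls["M4"] == "responsive"

    def test_missing_contrast_error(self):
        table = self._table({"M1": set()}).drop(index=("M1", "dES"))
        with pytest.raises(ValueError, match="dES"):
            classify_modules(table)


class TestEstimatorPipeline:
    def test_planted_module_recovery(self):
        design = modular_design(8)
        expr, truth = pb.generate_expression(design)
        model = CoexpressionModules(soft_power=6, min_module_size=30).fit(expr.T)
        mask = truth.module_labels > 0
        ari = adjusted_rand_score(truth.module_labels[mask], model.labels_[mask])
        assert ari >= 0.8
        assert sum(model.module_sizes_.values()) >= 0.9 * mask.sum()
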