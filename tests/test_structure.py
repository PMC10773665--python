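"""PCA, p-distance/NJ, Nei's D, and LD-based Ne."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from selectwatch.io import MISSING, GenotypeMatrix
from selectwatch.simulate import simulate_wf_genotypes
from selectwatch.structure import (
    _expected_sample_r2,
    _ne_from_r2drift,
    burrows_r2_matrix,
    ld_ne,
    neis_d,
    neis_d_from_genotypes,
    nj_tree,
    p_distance,
    p_distance_matrix,
    pca,
)

from conftest import make_gm


class TestPca:
    def test_two_populations_separate_on_pc1(self):
        """Two diverged populations: PC1 separates them without overlap in
        most replicates."""
        sep = 0
        reps = 20
        for seed in range(reps):
            rng = np.random.default_rng(seed)
            n_snps = 500
            p1 = rng.uniform(0.1, 0.9, n_snps)
            # perturb frequencies to give F_ST ~ 0.1
            shift = rng.normal(0, np.sqrt(0.1 * p1 * (1 - p1)))
            p2 = np.clip(p1 + shift, 0.02, 0.98)
            g1 = rng.binomial(2, p1, size=(25, n_snps))
            g2 = rng.binomial(2, p2, size=(25, n_snps))
            gm = make_gm(np.vstack([g1, g2]).astype(np.int8))
            coords, _ = pca(gm)
            a = coords["PC1"][:25].to_numpy()
            b = coords["PC1"][25:].to_numpy()
            sep += (a.max() < b.min()) or (b.max() < a.min())
        assert sep / reps >= 0.9

    def test_duplicate_samples_identical_coordinates(self):
        rng = np.random.default_rng(1)
        calls = rng.integers(0, 3, size=(10, 300)).astype(np.int8)
        calls[1] = calls[0]
        coords, _ = pca(make_gm(calls), n_components=3)
        # leading, well-separated components only: trailing eigenvectors of
        # a rank-deficient GRM are arbitrary within their null space
        c0 = coords.loc[coords["sample"] == "x0", ["PC1", "PC2", "PC3"]].to_numpy(float)
        c1 = coords.loc[coords["sample"] == "x1", ["PC1", "PC2", "PC3"]].to_numpy(float)
        np.testing.assert_allclose(c0, c1, atol=1e-8)

    def test_panmictic_pc1_not_dominant(self):
        """In one random-mating population PC1 should not dwarf PC2: its
        explained variance stays under 3x a permutation-null PC1."""
        rng = np.random.default_rng(2)
        calls = rng.binomial(2, 0.4, size=(40, 800)).astype(np.int8)
        gm = make_gm(calls)
        _, explained = pca(gm)
        perm = calls.copy()
        for j in range(perm.shape[1]):
            rng.shuffle(perm[:, j])
        _, explained_perm = pca(make_gm(perm))
        assert explained[0] < 3 * explained_perm[0]

    def test_missing_mean_imputed(self):
        rng = np.random.default_rng(3)
        calls = rng.integers(0, 3, size=(12, 100)).astype(np.int8)
        calls[0, :5] = MISSING
        coords, _ = pca(make_gm(calls))
        assert np.isfinite(coords.iloc[:, 1:].to_numpy(float)).all()


class TestPDistance:
    def test_identical_zero(self):
        gm = make_gm(np.ones((2, 50), dtype=np.int8))
        assert p_distance(gm, 0, 1) == 0.0

    def test_quarter_mismatch(self):
        calls = np.zeros((2, 100), dtype=np.int8)
        calls[1, :25] = 1
        assert p_distance(make_gm(calls), 0, 1) == 0.25

    def test_complete_cases_only(self):
        calls = np.array([[0, 1, 2, MISSING], [0, 2, MISSING, 1]], dtype=np.int8)
        # shared non-missing: SNPs 0,1 -> 1 mismatch of 2
        assert p_distance(make_gm(calls), 0, 1) == 0.5

    def test_no_shared_sites_raises(self):
        calls = np.array([[0, MISSING], [MISSING, 1]], dtype=np.int8)
        with pytest.raises(ValueError, match="shared"):
            p_distance(make_gm(calls), 0, 1)

    def test_matrix_symmetric(self):
        rng = np.random.default_rng(4)
        gm = make_gm(rng.integers(0, 3, size=(6, 80)).astype(np.int8))
        dm = p_distance_matrix(gm)
        assert np.allclose(dm, dm.T)
        assert np.all(np.diag(dm) == 0)


def newick_distances(newick: str):
    """Leaf-to-leaf path lengths via scikit-bio (independent parser)."""
    import io as _io

    import skbio

    tree = skbio.TreeNode.read(_io.StringIO(newick))
    return tree


class TestNjTree:
    CAT = pd.DataFrame(
        [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]],
        index=list("abcd"), columns=list("abcd"), dtype=float)

    def test_four_taxon_additive_recovery(self):
        """Additive matrix from a known tree: exact topology and branch
        lengths back (a:1, b:2 joined; c:3, d:4; internal 1)."""
        nwk = nj_tree(self.CAT)
        tree = newick_distances(nwk)
        tips = {t.name for t in tree.tips()}
        assert tips == set("abcd")
        for x, y in [("a", "b"), ("a", "c"), ("a", "d"), ("b", "c"), ("b", "d"), ("c", "d")]:
            assert tree.find(x).distance(tree.find(y)) == pytest.approx(self.CAT.loc[x, y])

    def test_three_taxa_exact(self):
        dm = pd.DataFrame([[0, 2, 3], [2, 0, 5], [3, 5, 0]],
                          index=list("xyz"), columns=list("xyz"), dtype=float)
        tree = newick_distances(nj_tree(dm))
        assert tree.find("x").distance(tree.find("y")) == pytest.approx(2)
        assert tree.find("x").distance(tree.find("z")) == pytest.approx(3)
        assert tree.find("y").distance(tree.find("z")) == pytest.approx(5)

    def test_equal_distances_deterministic(self):
        dm = pd.DataFrame(np.ones((4, 4)) - np.eye(4),
                          index=list("abcd"), columns=list("abcd"))
        assert nj_tree(dm) == nj_tree(dm)

    def test_asymmetric_raises(self):
        dm = self.CAT.copy()
        dm.iloc[0, 1] = 99
        with pytest.raises(ValueError, match="symmetric"):
            nj_tree(dm)

    def test_matches_skbio_on_random_additive_trees(self):
        """Random additive trees (n<=8): our NJ and scikit-bio's NJ both
        recover all pairwise path lengths exactly."""
        import skbio

        rng = np.random.default_rng(5)
        for trial in range(10):
            n = int(rng.integers(4, 9))
            labels = [f"t{i}" for i in range(n)]
            # build a random additive tree by sequential attachment
            d = np.zeros((2, 2))
            d[0, 1] = d[1, 0] = rng.uniform(0.5, 2)
            pts = 2
            dm_full = np.zeros((n, n))
            dm_full[:2, :2] = d
            while pts < n:
                # attach new leaf to a random existing leaf with two branches
                anchor = int(rng.integers(pts))
                stem = rng.uniform(0.1, 1)
                leaf = rng.uniform(0.5, 2)
                for j in range(pts):
                    if j == anchor:
                        dm_full[pts, j] = dm_full[j, pts] = stem + leaf + 0
                    else:
                        dm_full[pts, j] = dm_full[j, pts] = dm_full[anchor, j] + stem + leaf
                pts += 1
            dm = pd.DataFrame(dm_full, index=labels, columns=labels)
            ours = newick_distances(nj_tree(dm))
            theirs = skbio.tree.nj(skbio.DistanceMatrix(dm_full, ids=labels))
            for i in range(n):
                for j in range(i + 1, n):
                    a, b = labels[i], labels[j]
                    assert ours.find(a).distance(ours.find(b)) == pytest.approx(dm_full[i, j], abs=1e-8)
                    assert theirs.find(a).distance(theirs.find(b)) == pytest.approx(dm_full[i, j], abs=1e-8)


class TestNeisD:
    def test_identity_zero(self):
        f = [np.array([0.3, 0.7]), np.array([0.5, 0.5])]
        assert neis_d(f, f) == pytest.approx(0.0)

    def test_worked_ln2(self):
        x = [np.array([1.0, 0.0]), np.array([1.0, 0.0])]
        y = [np.array([0.0, 1.0]), np.array([1.0, 0.0])]
        assert neis_d(x, y) == pytest.approx(math.log(2))

    @given(st.lists(st.floats(0.01, 0.99), min_size=3, max_size=8),
           st.lists(st.floats(0.01, 0.99), min_size=3, max_size=8))
    @settings(max_examples=50, deadline=None)
    def test_symmetric_and_nonnegative(self, ps, qs):
        L = min(len(ps), len(qs))
        x = [np.array([p, 1 - p]) for p in ps[:L]]
        y = [np.array([q, 1 - q]) for q in qs[:L]]
        d_xy = neis_d(x, y)
        assert d_xy == pytest.approx(neis_d(y, x))
        assert d_xy >= -1e-12
        assert neis_d(x, x) == pytest.approx(0.0, abs=1e-12)

    def test_from_genotypes_matches_direct(self):
        rng = np.random.default_rng(6)
        gm = make_gm(rng.integers(0, 3, size=(20, 40)).astype(np.int8))
        ids_x, ids_y = gm.samples[:10], gm.samples[10:]
        d = neis_d_from_genotypes(gm, ids_x, ids_y)
        px = gm.subset(sample_ids=ids_x).allele_freq()
        py = gm.subset(sample_ids=ids_y).allele_freq()
        direct = neis_d([[1 - p, p] for p in px], [[1 - q, q] for q in py])
        assert d == pytest.approx(direct)


class TestLdNe:
    def test_duplicate_locus_r2_near_one(self):
        rng = np.random.default_rng(7)
        g = rng.binomial(2, 0.4, size=(50, 2)).astype(float)
        g[:, 1] = g[:, 0]
        r2 = burrows_r2_matrix(g)
        assert r2[0, 1] == pytest.approx(1.0, rel=0.05)

    def test_nonpositive_drift_signal_is_infinite(self):
        assert _ne_from_r2drift(0.0, 40) == math.inf
        assert _ne_from_r2drift(-0.01, 40) == math.inf

    def test_sampling_correction_monotone_in_s(self):
        ss = np.arange(10, 200, 5)
        es = [_expected_sample_r2(s) for s in ss]
        assert all(a > b for a, b in zip(es, es[1:]))

    def test_single_chromosome_raises(self):
        gm = simulate_wf_genotypes(n_snps=100, n_chroms=1, generations=2, seed=8)
        with pytest.raises(ValueError, match="chromosome"):
            ld_ne(gm, gm.samples)

    def test_parameter_recovery_true_ne_50(self):
        """Closed population at Ne_eff=50 for 10 generations, S=40, 2,000
        unlinked-pair SNPs: median estimate within [30, 80] (subset of the
        full replicate set; the acceptance run uses 20)."""
        ests = []
        for seed in range(6):
            gm = simulate_wf_genotypes(n_males=25, n_females=25, generations=10,
                                       n_snps=2000, n_chroms=4, seed=seed)
            samp = list(np.random.default_rng(1000 + seed).choice(
                gm.samples, size=40, replace=False))
            ests.append(ld_ne(gm, samp, maf_floor=0.01, seed=seed).ne_hat)
        assert 30 <= float(np.median(ests)) <= 80

    @staticmethod
    def _one_per_litter(pop, idx, n, rng):
        # LD-Ne presumes unrelated samples; keep one pup per litter as the
        # relative-pruning stage of the full pipeline would
        seen, out = set(), []
        for i in rng.permutation(idx):
            fam = (int(pop.sire[i]), int(pop.dam[i]))
            if fam not in seen:
                seen.add(fam)
                out.append(int(i))
            if len(out) == n:
                break
        return out

    def test_widened_pool_raises_ne(self):
        """Cohorts bred from a widened post-selection pool estimate a
        larger contemporary Ne than pre-selection cohorts in a majority of
        replicate simulations."""
        from selectwatch.simulate import breed_forward, simulate_founders, study_scenario

        wins = 0
        seeds = range(11, 20)
        for seed in seeds:
            cfg = study_scenario(seed=seed, n_snps=3000, n_dams_per_year=16,
                                 n_dams_post=64, carrier_breeding_penalty=0.4,
                                 chrom_len_bp=4_000_000, focal_pos_bp=2_000_000,
                                 years=(2014, 2021), selection_start_year=2017)
            pop = breed_forward(simulate_founders(cfg), cfg)
            gm = GenotypeMatrix(pop.markers, pop.ids, pop.genotypes())
            rng = np.random.default_rng(seed)
            pre = self._one_per_litter(pop, np.flatnonzero(np.isin(pop.birth_year, [2015, 2016])), 30, rng)
            post = self._one_per_litter(pop, np.flatnonzero(np.isin(pop.birth_year, [2020, 2021])), 45, rng)
            ne_pre = ld_ne(gm, [pop.ids[i] for i in pre], seed=0).ne_hat
            ne_post = ld_ne(gm, [pop.ids[i] for i in post], seed=0).ne_hat
            wins += ne_post > ne_pre
        assert wins / len(seeds) > 0.5
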