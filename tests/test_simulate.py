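"""Simulator correctness: founding conditions, Mendelian transmission,
neutral drift behaviour, selection policies, and cohort export."""

import json

import numpy as np
import pytest

from selectwatch.io import qc_filter, read_metadata, read_ped_map
from selectwatch.simulate import (
    GroupUnavailableError,
    SimConfig,
    breed_forward,
    export_cohorts,
    simulate_founders,
    simulate_wf_genotypes,
)


class TestFounders:
    def test_focal_frequency_within_binomial_band(self):
        cfg = SimConfig(n_founders=1000, n_snps=200, focal_q0=0.5, seed=3)
        pop = simulate_founders(cfg)
        q = pop.focal_freq_by_year()
        realized = np.mean(list(q.values()) if len(q) > 1 else list(q.values()))
        g = pop.focal_genotype()
        overall = g.sum() / (2 * len(g))
        # 99% binomial band for 2000 draws at 0.5 is ~0.5 +/- 0.029
        assert abs(overall - 0.5) < 0.05

    def test_pool_of_two_forces_template_haplotypes(self):
        # switch rate 0: founder haplotypes are exact template copies
        cfg = SimConfig(n_founders=30, n_snps=400, ancestral_pool_size=2,
                        founder_mosaic_switch_rate=0.0, seed=4)
        pop = simulate_founders(cfg)
        for s, e in pop.chrom_bounds:
            block = pop.haps[:, :, s:e].reshape(-1, e - s)
            # mask out the focal column, which is assigned independently
            cols = np.ones(e - s, dtype=bool)
            if s <= pop.focal_index < e:
                cols[pop.focal_index - s] = False
            uniq = np.unique(block[:, cols], axis=0)
            assert len(uniq) <= 2

    def test_determinism(self):
        cfg = SimConfig(n_founders=20, n_snps=300, seed=5)
        a = simulate_founders(cfg)
        b = simulate_founders(cfg)
        assert np.array_equal(a.haps, b.haps)
        assert a.ids == b.ids

    def test_too_few_founders(self):
        with pytest.raises(ValueError, match="founders"):
            simulate_founders(SimConfig(n_founders=3))


class TestBreeding:
    def test_mendelian_consistency(self, small_sim):
        assert small_sim.mendelian_ok()

    def test_determinism(self, small_sim_cfg, small_sim):
        again = breed_forward(simulate_founders(small_sim_cfg), small_sim_cfg)
        assert np.array_equal(again.haps, small_sim.haps)
        assert again.ids == small_sim.ids

    def test_neutral_focal_frequency_is_martingale(self):
        """Mean final frequency over replicate neutral runs stays within
        3 SE of the founding frequency."""
        finals, starts = [], []
        for seed in range(60):
            cfg = SimConfig(n_founders=40, n_snps=60, n_chroms=2, focal_q0=0.4,
                            n_dams_per_year=10, years=(2016, 2020), seed=100 + seed)
            pop = breed_forward(simulate_founders(cfg), cfg)
            fq = pop.focal_freq_by_year()
            finals.append(fq[2020])
            g0 = pop.focal_genotype()[np.array(pop.sire) == -1]
            starts.append(g0.sum() / (2 * len(g0)))
        drift = np.array(finals) - np.array(starts)
        se = drift.std(ddof=1) / np.sqrt(len(drift))
        assert abs(drift.mean()) < 3 * se

    def test_avoidance_policy_lowers_mutant_genotype(self):
        """Mutant-homozygote frequency among post-policy cohorts drops
        below pre-policy cohorts in nearly all replicates."""
        lower = 0
        reps = 20
        for seed in range(reps):
            cfg = SimConfig(n_founders=40, n_snps=60, focal_q0=0.4,
                            n_dams_per_year=12, years=(2016, 2021),
                            selection_start_year=2019,
                            selection_policy="avoid_mutant_matings", seed=300 + seed)
            pop = breed_forward(simulate_founders(cfg), cfg)
            g = pop.focal_genotype()
            by = pop.birth_year
            pre = (g[(by >= 2016) & (by < 2019)] == 2).mean()
            post = (g[by >= 2020] == 2).mean()
            lower += post < pre
        assert lower / reps >= 0.95

    def test_avoidance_policy_no_carrier_carrier_litter(self, small_sim, small_sim_cfg):
        carrier = small_sim.haps[:, :, small_sim.focal_index].sum(axis=1) > 0
        born_after = small_sim.birth_year >= small_sim_cfg.selection_start_year
        for d in np.flatnonzero(born_after):
            s, m = small_sim.sire[d], small_sim.dam[d]
            if s >= 0 and m >= 0:
                assert not (carrier[s] and carrier[m])

    def test_single_sire_year_gives_first_degree_kinship(self):
        from selectwatch.io import GenotypeMatrix, king_kinship

        # wide ancestral pool: founders effectively outbred, so the KING
        # first-degree window applies cleanly
        # wide pool + mid-frequency markers + rare risk haplotype: founders
        # close to outbred HWE, where the first-degree window applies
        cfg = SimConfig(n_founders=30, n_snps=3000, n_dams_per_year=6,
                        ancestral_pool_size=200, founder_maf_beta=(5, 5),
                        focal_q0=0.05,
                        male_fraction_breeding=0.15, years=(2016, 2016), seed=9)
        pop = breed_forward(simulate_founders(cfg), cfg)
        year_kids = np.flatnonzero(pop.birth_year == 2016)
        sires = set(int(pop.sire[d]) for d in year_kids)
        assert len(sires) == 1
        sire = sires.pop()
        gm = GenotypeMatrix(pop.markers, [str(i) for i in range(pop.n_dogs)],
                            pop.genotypes())
        for d in year_kids:
            assert king_kinship(gm, sire, int(d)) > 0.176


class TestWrightFisher:
    def test_allele_frequencies_preserved_on_average(self):
        gm = simulate_wf_genotypes(generations=4, n_snps=500, seed=1)
        p = gm.allele_freq()
        assert 0.35 < np.nanmean(p) < 0.65  # founders uniform(0.1,0.9)

    def test_determinism(self):
        a = simulate_wf_genotypes(seed=2, n_snps=200, generations=3)
        b = simulate_wf_genotypes(seed=2, n_snps=200, generations=3)
        assert np.array_equal(a.calls, b.calls)


class TestExport:
    def test_paper_sized_groups_give_117_rows(self, neutral_sim, tmp_path):
        cfg, pop = neutral_sim
        groups = [
            {"name": "Wild2019", "birth_year": [2017, 2018], "genotype": "Wild", "n": 42},
            {"name": "Wild2022", "birth_year": [2020, 2021], "genotype": "Wild", "n": 49},
            {"name": "Mutant2019", "birth_year": [2017, 2018], "genotype": "Mutant", "n": 24},
            {"name": "Mutant2022", "birth_year": [2020, 2021], "genotype": "Mutant", "n": 2},
        ]
        paths = export_cohorts(pop, groups, tmp_path / "exp", seed=1)
        meta = read_metadata(paths["meta"])
        assert len(meta.df) == 117
        assert set(meta.df["group"]) == {"Wild2019", "Wild2022", "Mutant2019", "Mutant2022"}

    def test_truth_focal_frequency_matches_exported_genotypes(self, neutral_sim, tmp_path):
        cfg, pop = neutral_sim
        groups = [{"name": "all2021", "birth_year": 2021, "genotype": None, "n": 30}]
        paths = export_cohorts(pop, groups, tmp_path / "exp2", seed=2)
        truth = json.loads(paths["truth"].read_text())
        gm, _ = read_ped_map(paths["ped"], paths["map"])
        focal_id = truth["focal_snp"]
        j = list(gm.markers.ids).index(focal_id)
        q_exported = gm.calls[:, j].sum() / (2 * gm.n_samples)
        # exported dogs are a subsample; both must agree with the truth for
        # the full-year frequency within sampling error of n=30
        assert abs(q_exported - truth["focal_freq_by_year"]["2021"]) < 0.2
        # and genotype labels in metadata match the exported calls
        meta = read_metadata(paths["meta"]).df.set_index("id")
        for i, sid in enumerate(gm.samples):
            label = {0: "Wild", 1: "Hetero", 2: "Mutant"}[int(gm.calls[i, j])]
            assert meta.loc[sid, "focal_genotype"] == label

    def test_exported_files_pass_qc_smoke(self, neutral_sim, tmp_path):
        cfg, pop = neutral_sim
        groups = [{"name": "g", "birth_year": [2020, 2021], "genotype": None, "n": 40}]
        paths = export_cohorts(pop, groups, tmp_path / "exp3", seed=3)
        gm, _ = read_ped_map(paths["ped"], paths["map"])
        out = qc_filter(gm)
        assert out.n_samples == 40
        assert out.n_snps > 0

    def test_unavailable_group_lists_availability(self, neutral_sim, tmp_path):
        cfg, pop = neutral_sim
        groups = [{"name": "g", "birth_year": 2021, "genotype": "Mutant", "n": 10_000}]
        with pytest.raises(GroupUnavailableError, match="available"):
            export_cohorts(pop, groups, tmp_path / "exp4", seed=4)

    def test_truth_ibd_segments_are_autozygous_in_genotypes(self, neutral_sim, tmp_path):
        """Within a true IBD segment the two haplotypes are identical, so
        every call inside it must be homozygous."""
        cfg, pop = neutral_sim
        groups = [{"name": "g", "birth_year": 2021, "genotype": None, "n": 10}]
        paths = export_cohorts(pop, groups, tmp_path / "exp5", seed=5)
        truth = json.loads(paths["truth"].read_text())
        gm, _ = read_ped_map(paths["ped"], paths["map"])
        mdf = gm.markers.df
        for sid, segs in truth["ibd_segments"].items():
            i = gm.sample_index(sid)
            for seg in segs[:20]:
                in_seg = ((mdf["chrom"] == seg["chrom"])
                          & (mdf["pos_bp"] >= seg["start_bp"])
                          & (mdf["pos_bp"] <= seg["end_bp"])).to_numpy()
                calls = gm.calls[i, in_seg]
                assert np.all((calls == 0) | (calls == 2))
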