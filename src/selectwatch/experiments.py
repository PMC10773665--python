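"""Replicated validation experiments over the synthetic study conditions.

These functions bundle the package's headline self-checks so tests,
examples and the reproduction script all run the same procedures:

* drift-null calibration (martingale mean, one-generation variance);
* null F_ST behaviour and the selection-scan hit rate;
* LD-Ne parameter recovery at a known true Ne;
* the full end-to-end replicate: simulate a breed under genotype-informed
  selection, build paper-style genotype cohorts, test the focal-allele
  decline against the drift null, and scan for the selected region.
"""

from __future__ import annotations

import numpy as np

from .io import GenotypeMatrix
from .scan import rank_scan, wc_fst
from .simulate import breed_forward, simulate_founders, simulate_wf_genotypes, study_scenario
from .structure import ld_ne
from .trend import DriftModel, empirical_p, simulate_drift


def drift_calibration(ne: int = 540, male_fraction: float = 0.2, q0: float = 0.5,
                      replicates: int = 10_000, seed: int = 0) -> dict:
    """Martingale deviation (in SEs) and one-generation variance ratio
    against the closed-form q(1-q)/(2 Ne_eff)."""
    m = DriftModel(ne=ne, q_start=q0, male_fraction=male_fraction,
                   generations=6, replicates=replicates, seed=seed)
    res = simulate_drift(m)
    final = res.trajectories[:, -1]
    se = final.std(ddof=1) / np.sqrt(len(final))
    one_gen = simulate_drift(DriftModel(ne=ne, q_start=q0, male_fraction=male_fraction,
                                        generations=1, replicates=replicates, seed=seed + 1))
    v = one_gen.trajectories[:, 1].var()
    expected = q0 * (1 - q0) / (2 * m.ne_eff)
    return {
        "ne_eff": m.ne_eff,
        "martingale_dev_se": float(abs(final.mean() - q0) / se),
        "var_ratio": float(v / expected),
    }


def fst_null_mean(seed: int = 0, n_snps: int = 4000) -> dict:
    """Mean per-SNP F_ST (in SEs) for a random split of one panmictic
    population — should sit at zero."""
    gm = simulate_wf_genotypes(n_males=50, n_females=50, generations=2,
                               n_snps=n_snps, seed=seed)
    rng = np.random.default_rng(seed + 1)
    ids = np.array(gm.samples)
    rng.shuffle(ids)
    r = wc_fst(gm, list(ids[:50]), list(ids[50:]))
    vals = r.fst[np.isfinite(r.fst)]
    se = vals.std(ddof=1) / np.sqrt(len(vals))
    return {"mean_fst": float(vals.mean()), "mean_fst_se_units": float(abs(vals.mean()) / se)}


def ldne_recovery(n_reps: int = 20, true_half: int = 25, generations: int = 10,
                  n_snps: int = 2000, sample_size: int = 40, seed: int = 0) -> dict:
    """Median LD-Ne estimate across replicate populations held at
    Ne_eff = 2*true_half (equal sires and dams)."""
    ests = []
    for r in range(n_reps):
        gm = simulate_wf_genotypes(n_males=true_half, n_females=true_half,
                                   generations=generations, n_snps=n_snps,
                                   n_chroms=4, seed=seed + r)
        rng = np.random.default_rng(seed + 10_000 + r)
        samp = list(rng.choice(gm.samples, size=sample_size, replace=False))
        ests.append(ld_ne(gm, samp, maf_floor=0.01, seed=seed + r).ne_hat)
    finite = [e for e in ests if np.isfinite(e)]
    return {"estimates": ests, "median_ne": float(np.median(finite)), "true_ne": 2 * true_half}


def selection_replicate(seed: int, pre_years=(2016, 2017), post_years=(2021, 2022),
                        group_sizes=(30, 24, 49, 2), top_fraction: float = 0.001,
                        drift_replicates: int = 10_000) -> dict:
    """One end-to-end run under the reference selection scenario.

    Simulates the breed, samples paper-style genotype-stratified cohorts
    (pre-selection Wild and Mutant homozygotes vs post-selection ones,
    sizes capped by availability), then reports:

    * ``p_drift`` — lower-tail empirical p of the observed focal-allele
      frequency in the final year against the sex-structured drift null
      anchored at the last pre-selection year, with Ne equal to the true
      number of breeding dogs per year;
    * ``focal_hit`` — whether a SNP within 1 Mbp of the focal locus falls
      in the genome-wide top ``top_fraction`` of F_ST.
    """
    cfg = study_scenario(seed=seed)
    pop = breed_forward(simulate_founders(cfg), cfg)
    labels = np.array(pop.focal_labels())
    rng = np.random.default_rng(seed + 77)

    def pick(years, genotype, n):
        mask = np.isin(pop.birth_year, years) & (labels == genotype)
        avail = np.flatnonzero(mask)
        return rng.choice(avail, size=min(n, len(avail)), replace=False)

    n_wp, n_mp, n_wq, n_mq = group_sizes
    pre = np.concatenate([pick(pre_years, "Wild", n_wp), pick(pre_years, "Mutant", n_mp)])
    post = np.concatenate([pick(post_years, "Wild", n_wq), pick(post_years, "Mutant", n_mq)])
    both = np.concatenate([pre, post]).astype(int)
    gm = GenotypeMatrix(pop.markers, [pop.ids[i] for i in both], pop.genotypes(both))

    ranked = rank_scan(wc_fst(gm, [pop.ids[i] for i in pre], [pop.ids[i] for i in post]),
                       top_fraction=top_fraction)
    flagged = ranked[ranked["flagged"]]
    focal_pos = int(pop.markers.pos_bp[pop.focal_index])
    focal_hit = bool(((flagged["chrom"].astype(str) == cfg.focal_chrom)
                      & ((flagged["pos_bp"] - focal_pos).abs() <= 1_000_000)).any())

    fq = pop.focal_freq_by_year()
    anchor = cfg.selection_start_year - 1
    gens = cfg.years[1] - anchor
    n_sires = max(1, round(cfg.n_dams_per_year * cfg.male_fraction_breeding
                           / (1 - cfg.male_fraction_breeding)))
    model = DriftModel(ne=cfg.n_dams_per_year + n_sires, q_start=fq[anchor],
                       male_fraction=cfg.male_fraction_breeding, generations=gens,
                       replicates=drift_replicates, seed=seed + 99)
    res = simulate_drift(model)
    p_drift = empirical_p(res, fq[cfg.years[1]], gens)

    return {
        "p_drift": float(p_drift),
        "focal_hit": focal_hit,
        "q_anchor": float(fq[anchor]),
        "q_final": float(fq[cfg.years[1]]),
        "top_fst": float(ranked.iloc[0]["fst"]),
        "top_distance_bp": abs(int(ranked.iloc[0]["pos_bp"]) - focal_pos)
        if str(ranked.iloc[0]["chrom"]) == cfg.focal_chrom else None,
        "n_flagged": int(flagged.shape[0]),
    }


def selection_experiment(n_reps: int = 10, seed: int = 0, **kwargs) -> dict:
    """Replicate :func:`selection_replicate`; report joint hit rates."""
    reps = [selection_replicate(seed + 1000 * r, **kwargs) for r in range(n_reps)]
    both = [r["p_drift"] < 0.05 and r["focal_hit"] for r in reps]
    return {
        "replicates": reps,
        "drift_significant_rate": float(np.mean([r["p_drift"] < 0.05 for r in reps])),
        "focal_hit_rate": float(np.mean([r["focal_hit"] for r in reps])),
        "joint_rate": float(np.mean(both)),
    }
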