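"""Forward simulator for a closed breed under genotype-informed mate choice.

The generator emulates the statistical structure of a bottlenecked pedigree
dog population: founders drawn from a small pool of ancestral haplotype
templates (so background homozygosity and LD are high, as in a closed
breed), yearly overlapping-generation breeding with a female-biased breeder
sex ratio, and a focal biallelic disease locus starting at high mutant
frequency.  From a chosen year a selection policy can be switched on:

* ``avoid_mutant_matings`` — matings where both parents carry the mutant
  allele are rejected (the breeder response to genetic testing);
* ``cull_mutant_offspring`` — mutant homozygotes are removed at birth;
* ``none`` — neutral drift.

Alongside genotypes the simulator tracks, per haplotype, the founder
haplotype each SNP descends from.  That identity-by-descent record gives
oracle truths (true autozygous segments, pedigree kinship and inbreeding,
true focal allele frequency per year) against which the estimators in the
rest of the package are tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import CohortTable, GenotypeMatrix, MarkerMap, write_metadata, write_ped_map

GENO_LABELS = {0: "Wild", 1: "Hetero", 2: "Mutant"}


@dataclass
class SimConfig:
    """Scenario parameters for the closed-breed simulator.

    Defaults describe the study conditions the pipeline is aimed at: a
    moderately sized closed breed (~24 dams and ~6 sires active per year,
    i.e. 20% male / 80% female breeders), one breeding cycle per year, a
    focal locus at high initial mutant frequency, and marker density
    sufficient for ROH (41-SNP runs) and 1-Mbp EHH windows.
    """

    n_founders: int = 60
    n_snps: int = 5000
    n_chroms: int = 2
    chrom_len_bp: int = 10_000_000
    founder_maf_beta: tuple[float, float] = (1.2, 1.2)  # template allele-freq Beta
    ancestral_pool_size: int = 4       # haplotype templates per chromosome
    founder_mosaic_switch_rate: float = 1e-6  # per-bp template-switch rate in founder haplotypes
    # (0 = founders are exact template copies; >0 adds historic recombination)
    recomb_rate: float = 3e-8          # per-bp crossover probability
    focal_chrom: str = "1"
    focal_pos_bp: int = 5_000_000
    focal_q0: float = 0.6
    selection_start_year: int = 2018
    selection_policy: str = "none"     # none | avoid_mutant_matings | cull_mutant_offspring
    carrier_breeding_penalty: float = 0.0  # 0..1: carrier weight becomes (1 - penalty) once selection starts
    years: tuple[int, int] = (2013, 2022)
    litters_per_female_year: int = 1
    litter_size_mean: float = 5.0      # Poisson mean, clipped to >= 1
    male_fraction_breeding: float = 0.2  # male share of the breeding pool
    n_dams_per_year: int = 24
    n_dams_post: int | None = None     # widened breeding pool from selection_start_year
    breeding_age: tuple[int, int] = (1, 8)
    seed: int = 20231218

    def __post_init__(self) -> None:
        if not 0 < self.focal_q0 < 1:
            raise ValueError("focal_q0 must be in (0,1)")
        if not 0 < self.male_fraction_breeding < 1:
            raise ValueError("male_fraction_breeding must be in (0,1)")
        if self.focal_pos_bp > self.chrom_len_bp:
            raise ValueError("focal position beyond chromosome end")
        if self.selection_policy not in ("none", "avoid_mutant_matings", "cull_mutant_offspring"):
            raise ValueError(f"unknown selection_policy {self.selection_policy!r}")
        if not 0 <= self.carrier_breeding_penalty < 1:
            raise ValueError("carrier_breeding_penalty must be in [0,1)")


def study_scenario(seed: int = 20231218, **overrides) -> SimConfig:
    """The package's reference selection scenario: genetic testing starts
    mid-series, after which carrier-carrier matings are rejected and
    carriers are strongly disfavoured as breeding stock (penalty 0.8) —
    the combination of mate choice and stock selection that a breed club
    acting on test results applies."""
    base = dict(
        selection_policy="avoid_mutant_matings",
        carrier_breeding_penalty=0.8,
        n_dams_per_year=32,
        n_dams_post=64,
        seed=seed,
    )
    base.update(overrides)
    return SimConfig(**base)


class MatingRejectionError(RuntimeError):
    """Rejection-sampling cap hit; advise relaxing the selection policy."""


@dataclass
class SimPopulation:
    """Pedigreed diploid population with phased haplotypes and IBD ancestry.

    ``haps[d, k, :]`` is dog d's k-th haplotype over all SNPs (chromosomes
    concatenated in map order); ``anc`` holds the founder-haplotype id each
    site descends from.  ``sire``/``dam`` are indices (-1 for founders).
    """

    markers: MarkerMap
    chrom_bounds: list[tuple[int, int]]    # [start, end) SNP index per chromosome
    focal_index: int
    ids: list[str] = field(default_factory=list)
    sex: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int8))  # 0=F 1=M
    birth_year: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int32))
    sire: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int32))
    dam: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int32))
    haps: np.ndarray | None = None          # (n, 2, n_snps) int8
    anc: np.ndarray | None = None           # (n, 2, n_snps) int16 founder-hap ids

    @property
    def n_dogs(self) -> int:
        return len(self.ids)

    def focal_genotype(self) -> np.ndarray:
        return self.haps[:, :, self.focal_index].sum(axis=1).astype(np.int8)

    def focal_labels(self) -> list[str]:
        return [GENO_LABELS[int(g)] for g in self.focal_genotype()]

    def genotypes(self, idx=None) -> np.ndarray:
        """A2-count genotype matrix (dogs x SNPs)."""
        h = self.haps if idx is None else self.haps[idx]
        return h.sum(axis=1).astype(np.int8)

    def focal_freq_by_year(self) -> dict[int, float]:
        g = self.focal_genotype()
        out = {}
        for y in sorted(set(self.birth_year.tolist())):
            sel = self.birth_year == y
            out[int(y)] = float(g[sel].sum() / (2 * sel.sum()))
        return out

    def mendelian_ok(self) -> bool:
        """Every non-founder haplotype must be buildable from its parent."""
        for d in range(self.n_dogs):
            for k, par in enumerate((self.sire[d], self.dam[d])):
                if par < 0:
                    continue
                child = self.haps[d, k]
                ph = self.haps[par]
                if not np.all((child == ph[0]) | (child == ph[1])):
                    return False
        return True


def _make_marker_map(cfg: SimConfig, rng: np.random.Generator) -> tuple[MarkerMap, list[tuple[int, int]], int]:
    per = cfg.n_snps // cfg.n_chroms
    rows = []
    bounds = []
    focal_index = -1
    start = 0
    for c in range(cfg.n_chroms):
        chrom = str(c + 1)
        n = per + (cfg.n_snps - per * cfg.n_chroms if c == cfg.n_chroms - 1 else 0)
        pos = np.sort(rng.choice(np.arange(1, cfg.chrom_len_bp + 1), size=n, replace=False))
        if chrom == cfg.focal_chrom:
            # plant the focal SNP at its exact position
            j = int(np.searchsorted(pos, cfg.focal_pos_bp))
            pos = np.unique(np.insert(pos, min(j, n - 1), cfg.focal_pos_bp))[:n]
            focal_index = start + int(np.searchsorted(pos, cfg.focal_pos_bp))
        for k in range(n):
            rows.append((f"snp_{chrom}_{k:05d}", chrom, int(pos[k]), "A", "G"))
        bounds.append((start, start + n))
        start += n
    df = pd.DataFrame(rows, columns=["id", "chrom", "pos_bp", "a1", "a2"])
    return MarkerMap(df), bounds, focal_index


def _mosaic_templates(pos, anchor_rel: int, start_t: int, n_templates: int,
                      rate: float, rng) -> np.ndarray:
    """Template-id sequence along one chromosome for one founder haplotype.

    A Markov switch process anchored at ``anchor_rel``: between adjacent
    SNPs a switch occurs with probability 1-exp(-rate*gap), after which a
    uniformly drawn template takes over.  Rate 0 reproduces an exact
    template copy.
    """
    m = len(pos)
    t = np.empty(m, dtype=np.int64)
    if m == 1:
        t[0] = start_t
        return t
    gaps = np.diff(np.asarray(pos, dtype=float))
    switch = rng.random(m - 1) < -np.expm1(-rate * gaps)
    seg_r = np.concatenate([[0], np.cumsum(switch[anchor_rel:])])
    draws_r = rng.integers(n_templates, size=int(seg_r[-1]) + 1)
    draws_r[0] = start_t
    t[anchor_rel:] = draws_r[seg_r]
    if anchor_rel > 0:
        seg_l = np.cumsum(switch[:anchor_rel][::-1])
        draws_l = rng.integers(n_templates, size=int(seg_l[-1]) + 1)
        draws_l[0] = start_t
        t[:anchor_rel] = draws_l[seg_l][::-1]
    return t


def simulate_founders(cfg: SimConfig) -> SimPopulation:
    """Found the population from a small ancestral haplotype pool.

    Each founder haplotype is a copy of one of ``ancestral_pool_size``
    templates per chromosome (the breed-bottleneck model of background LD
    and homozygosity).  The mutant focal allele lives on exactly one
    ancestral template — the single risk haplotype spread through popular
    lineages — and on the focal chromosome each founder haplotype copies
    that template with probability q0 (so the realized focal frequency
    carries binomial sampling error) and one of the remaining templates
    otherwise.
    """
    if cfg.n_founders < 4:
        raise ValueError("need at least 4 founders")
    if cfg.ancestral_pool_size < 2:
        raise ValueError("need at least 2 ancestral templates")
    rng = np.random.default_rng(cfg.seed)
    markers, bounds, focal_index = _make_marker_map(cfg, rng)
    n_snps = markers.n_snps

    a, b = cfg.founder_maf_beta
    pool = np.zeros((cfg.ancestral_pool_size, n_snps), dtype=np.int8)
    for (s, e) in bounds:
        freqs = rng.beta(a, b, size=e - s)
        pool[:, s:e] = (rng.random((cfg.ancestral_pool_size, e - s)) < freqs).astype(np.int8)

    # template 0 carries the mutant focal allele; all others are wild there
    pool[:, focal_index] = 0
    pool[0, focal_index] = 1
    focal_ci = next(ci for ci, (s, e) in enumerate(bounds) if s <= focal_index < e)

    n = cfg.n_founders
    K = cfg.ancestral_pool_size
    haps = np.zeros((n, 2, n_snps), dtype=np.int8)
    anc = np.zeros((n, 2, n_snps), dtype=np.int16)
    hap_id = 0
    for d in range(n):
        for k in range(2):
            for ci, (s, e) in enumerate(bounds):
                pos_c = markers.pos_bp[s:e]
                if ci == focal_ci:
                    anchor = focal_index - s
                    start_t = 0 if rng.random() < cfg.focal_q0 else int(rng.integers(1, K))
                else:
                    anchor = 0
                    start_t = int(rng.integers(K))
                tseq = _mosaic_templates(pos_c, anchor, start_t, K,
                                         cfg.founder_mosaic_switch_rate, rng)
                haps[d, k, s:e] = pool[tseq, np.arange(s, e)]
            anc[d, k, :] = hap_id
            hap_id += 1

    start_year = cfg.years[0]
    sexes = np.array([1] * (n // 2) + [0] * (n - n // 2), dtype=np.int8)
    rng.shuffle(sexes)
    lo, hi = cfg.breeding_age
    birth = start_year - rng.integers(lo, hi + 1, size=n).astype(np.int32)
    return SimPopulation(
        markers=markers,
        chrom_bounds=bounds,
        focal_index=focal_index,
        ids=[f"F{d:04d}" for d in range(n)],
        sex=sexes,
        birth_year=birth,
        sire=np.full(n, -1, dtype=np.int32),
        dam=np.full(n, -1, dtype=np.int32),
        haps=haps,
        anc=anc,
    )


def _meiosis(haps2, anc2, pos_by_chrom, bounds, rate, rng):
    """One gamete: per chromosome, Poisson crossovers at uniform positions."""
    n_snps = haps2.shape[1]
    gam = np.empty(n_snps, dtype=np.int8)
    gam_anc = np.empty(n_snps, dtype=np.int16)
    for ci, (s, e) in enumerate(bounds):
        pos = pos_by_chrom[ci]
        length = int(pos[-1]) if len(pos) else 0
        k = rng.poisson(rate * length)
        phase = rng.integers(2)
        if k == 0:
            gam[s:e] = haps2[phase, s:e]
            gam_anc[s:e] = anc2[phase, s:e]
            continue
        cuts = np.sort(rng.integers(1, length + 1, size=k))
        seg = np.searchsorted(cuts, pos, side="left")
        choice = (phase + seg) % 2
        m0 = choice == 0
        gam[s:e] = np.where(m0, haps2[0, s:e], haps2[1, s:e])
        gam_anc[s:e] = np.where(m0, anc2[0, s:e], anc2[1, s:e])
    return gam, gam_anc


def breed_forward(pop: SimPopulation, cfg: SimConfig) -> SimPopulation:
    """Advance the population year by year from years[0] to years[1].

    Each year: eligible dogs are those of breeding age; ``n_dams_per_year``
    dams are drawn, and a sire pool sized to give a
    ``male_fraction_breeding`` male share of the breeding pool.  Each dam
    whelps ``litters_per_female_year`` litters of Poisson size by a pool
    sire.  Under ``avoid_mutant_matings`` the sire is redrawn (cap 1000)
    whenever both prospective parents carry the mutant allele.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    pos_by_chrom = [pop.markers.pos_bp[s:e] for (s, e) in pop.chrom_bounds]
    lo, hi = cfg.breeding_age
    mf = cfg.male_fraction_breeding

    ids = list(pop.ids)
    sex = [int(x) for x in pop.sex]
    birth = [int(x) for x in pop.birth_year]
    sire_l = [int(x) for x in pop.sire]
    dam_l = [int(x) for x in pop.dam]
    haps_l = [pop.haps[d] for d in range(pop.n_dogs)]
    anc_l = [pop.anc[d] for d in range(pop.n_dogs)]

    def carrier(d: int) -> bool:
        return bool(haps_l[d][0, pop.focal_index] or haps_l[d][1, pop.focal_index])

    for year in range(cfg.years[0], cfg.years[1] + 1):
        age = year - np.array(birth)
        elig = (age >= lo) & (age <= hi)
        sx = np.array(sex)
        fem = np.flatnonzero(elig & (sx == 0))
        mal = np.flatnonzero(elig & (sx == 1))
        if len(fem) == 0 or len(mal) == 0:
            raise RuntimeError(f"year {year}: no eligible breeding pair")
        policy_on = cfg.selection_policy != "none" and year >= cfg.selection_start_year

        def weighted_pick(cands: np.ndarray, size: int) -> np.ndarray:
            if policy_on and cfg.carrier_breeding_penalty > 0:
                w = np.array([1.0 - cfg.carrier_breeding_penalty if carrier(int(c)) else 1.0
                              for c in cands])
                return rng.choice(cands, size=size, replace=False, p=w / w.sum())
            return rng.choice(cands, size=size, replace=False)

        n_dams = cfg.n_dams_per_year
        if cfg.n_dams_post is not None and year >= cfg.selection_start_year:
            n_dams = cfg.n_dams_post
        dams = weighted_pick(fem, min(n_dams, len(fem)))
        n_sires = max(1, round(len(dams) * mf / (1.0 - mf)))
        sires = weighted_pick(mal, min(n_sires, len(mal)))

        for dm in dams:
            for _ in range(cfg.litters_per_female_year):
                sr = int(rng.choice(sires))
                if policy_on and cfg.selection_policy == "avoid_mutant_matings" and carrier(int(dm)):
                    tries = 0
                    while carrier(sr) and tries < 1000:
                        tries += 1
                        sr = int(rng.choice(sires))
                    if carrier(sr):
                        # pool exhausted: recruit a tested-clear stud from the
                        # wider eligible males, as breeders do in practice
                        clear = [m for m in mal if not carrier(int(m))]
                        if not clear:
                            raise MatingRejectionError(
                                f"year {year}: no non-carrier sire available after 1000 "
                                "tries; relax the selection policy"
                            )
                        sr = int(rng.choice(np.array(clear)))
                size = max(1, int(rng.poisson(cfg.litter_size_mean)))
                for _ in range(size):
                    g_s, a_s = _meiosis(haps_l[sr], anc_l[sr], pos_by_chrom, pop.chrom_bounds, cfg.recomb_rate, rng)
                    g_d, a_d = _meiosis(haps_l[int(dm)], anc_l[int(dm)], pos_by_chrom, pop.chrom_bounds, cfg.recomb_rate, rng)
                    focal_g = int(g_s[pop.focal_index]) + int(g_d[pop.focal_index])
                    if policy_on and cfg.selection_policy == "cull_mutant_offspring" and focal_g == 2:
                        continue
                    ids.append(f"D{len(ids):05d}")
                    sex.append(int(rng.integers(2)))
                    birth.append(year)
                    sire_l.append(sr)
                    dam_l.append(int(dm))
                    haps_l.append(np.stack([g_s, g_d]))
                    anc_l.append(np.stack([a_s, a_d]))

    return SimPopulation(
        markers=pop.markers,
        chrom_bounds=pop.chrom_bounds,
        focal_index=pop.focal_index,
        ids=ids,
        sex=np.array(sex, dtype=np.int8),
        birth_year=np.array(birth, dtype=np.int32),
        sire=np.array(sire_l, dtype=np.int32),
        dam=np.array(dam_l, dtype=np.int32),
        haps=np.stack(haps_l),
        anc=np.stack(anc_l),
    )


def simulate(cfg: SimConfig) -> SimPopulation:
    """Found and breed forward in one call."""
    return breed_forward(simulate_founders(cfg), cfg)


def simulate_wf_genotypes(
    n_males: int = 25,
    n_females: int = 25,
    generations: int = 10,
    n_snps: int = 2000,
    n_chroms: int = 4,
    founder_freq: tuple[float, float] = (0.1, 0.9),
    seed: int = 0,
) -> GenotypeMatrix:
    """Discrete-generation Wright–Fisher diploid population for estimator
    calibration (notably LD-based Ne recovery).

    All loci recombine freely (inter-chromosomal LD is the quantity of
    interest; chromosome labels only partition loci into unlinked sets).
    Founder allele frequencies are uniform on ``founder_freq``.  Returns
    the final generation as a GenotypeMatrix with evenly spaced markers on
    ``n_chroms`` chromosomes.
    """
    rng = np.random.default_rng(seed)
    n = n_males + n_females
    freqs = rng.uniform(*founder_freq, size=n_snps)
    h = (rng.random((2, n, n_snps)) < freqs).astype(np.int8)
    sex = np.array([1] * n_males + [0] * n_females)
    for _ in range(generations):
        sires = np.flatnonzero(sex == 1)
        dams = np.flatnonzero(sex == 0)
        s = rng.choice(sires, size=n)
        d = rng.choice(dams, size=n)
        pick_s = rng.integers(2, size=(n, n_snps))
        pick_d = rng.integers(2, size=(n, n_snps))
        h = np.stack([
            np.where(pick_s == 0, h[0][s], h[1][s]),
            np.where(pick_d == 0, h[0][d], h[1][d]),
        ])
        sex = np.concatenate([np.ones(n_males, dtype=int), np.zeros(n_females, dtype=int)])
        rng.shuffle(sex)
    per = n_snps // n_chroms
    rows = []
    for j in range(n_snps):
        c = min(j // per, n_chroms - 1)
        rows.append((f"wf_{j:05d}", str(c + 1), (j - c * per) * 10_000 + 1, "A", "G"))
    markers = MarkerMap(pd.DataFrame(rows, columns=["id", "chrom", "pos_bp", "a1", "a2"]))
    calls = (h[0] + h[1]).astype(np.int8)
    return GenotypeMatrix(markers, [f"W{i:04d}" for i in range(n)], calls)


# ---------------------------------------------------------------------------
# Truth extraction (test oracles)

def pedigree_kinship(pop: SimPopulation) -> np.ndarray:
    """Full pedigree kinship matrix by the tabular method.

    phi(i,i) = 0.5(1 + F_i) with F_i = phi(sire_i, dam_i); founders are
    treated as unrelated and non-inbred.
    """
    n = pop.n_dogs
    A = np.zeros((n, n), dtype=np.float64)
    # dogs are appended in birth order, so parents always precede children
    for i in range(n):
        s, d = int(pop.sire[i]), int(pop.dam[i])
        if s < 0 and d < 0:
            A[i, i] = 0.5
        else:
            A[i, i] = 0.5 + 0.5 * A[s, d]
            row = 0.5 * (A[s, :i] + A[d, :i])
            A[i, :i] = row
            A[:i, i] = row
    return A


def pedigree_inbreeding(pop: SimPopulation) -> np.ndarray:
    A = pedigree_kinship(pop)
    F = np.zeros(pop.n_dogs)
    for i in range(pop.n_dogs):
        s, d = int(pop.sire[i]), int(pop.dam[i])
        if s >= 0 and d >= 0:
            F[i] = A[s, d]
    return F


def true_ibd_segments(pop: SimPopulation, dog: int) -> list[dict]:
    """Maximal autozygous (both haplotypes IBD from one founder haplotype)
    segments for one dog, per chromosome, as marker-bounded intervals."""
    segs = []
    pos = pop.markers.pos_bp
    chroms = pop.markers.chrom
    eq = pop.anc[dog, 0] == pop.anc[dog, 1]
    for (s, e) in pop.chrom_bounds:
        m = eq[s:e]
        if not m.any():
            continue
        d = np.diff(m.astype(np.int8))
        starts = list(np.flatnonzero(d == 1) + 1)
        ends = list(np.flatnonzero(d == -1) + 1)
        if m[0]:
            starts = [0] + starts
        if m[-1]:
            ends = ends + [len(m)]
        for st, en in zip(starts, ends):
            segs.append({
                "chrom": str(chroms[s + st]),
                "start_bp": int(pos[s + st]),
                "end_bp": int(pos[s + en - 1]),
                "n_snps": int(en - st),
            })
    return segs


# ---------------------------------------------------------------------------
# Export

class GroupUnavailableError(ValueError):
    """A requested cohort group exceeds what the simulation produced."""


def export_cohorts(
    pop: SimPopulation,
    groups: list[dict],
    out_dir,
    seed: int = 0,
    truth: bool = True,
):
    """Write PED/MAP + metadata TSV (+ truth JSON, phased haplotype text).

    ``groups`` entries: {"name", "birth_year", "genotype" (Wild/Hetero/
    Mutant or None for any), "n"}.  Returns the paths written.
    """
    import json
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    labels = np.array(pop.focal_labels())
    chosen: list[int] = []
    meta_rows = []
    for g in groups:
        by = g["birth_year"]
        years = [by] if isinstance(by, int) else list(by)
        mask = np.isin(pop.birth_year, years)
        if g.get("genotype"):
            mask &= labels == g["genotype"]
        mask &= ~np.isin(np.arange(pop.n_dogs), chosen)
        avail = np.flatnonzero(mask)
        if len(avail) < g["n"]:
            raise GroupUnavailableError(
                f"group {g['name']!r}: requested {g['n']}, only {len(avail)} available "
                f"(birth_year={g['birth_year']}, genotype={g.get('genotype')})"
            )
        take = np.sort(rng.choice(avail, size=g["n"], replace=False))
        chosen.extend(int(t) for t in take)
        for t in take:
            meta_rows.append((pop.ids[t], int(pop.birth_year[t]), labels[t], g["name"]))

    gm = GenotypeMatrix(pop.markers, [pop.ids[i] for i in chosen], pop.genotypes(chosen))
    ped = out / "cohorts.ped"
    mp = out / "cohorts.map"
    meta = out / "cohorts.tsv"
    write_ped_map(gm, ped, mp)
    table = CohortTable(pd.DataFrame(meta_rows, columns=["id", "birth_year", "focal_genotype", "group"]))
    write_metadata(table, meta)

    haps_path = out / "cohorts.haps"
    with open(haps_path, "w") as fh:
        for i in chosen:
            for k in range(2):
                fh.write(f"{pop.ids[i]}_h{k}\t" + "".join(map(str, pop.haps[i, k].tolist())) + "\n")

    paths = {"ped": ped, "map": mp, "meta": meta, "haps": haps_path}
    if truth:
        A = pedigree_kinship(pop)
        Fped = pedigree_inbreeding(pop)
        tj = {
            "focal_snp": str(pop.markers.ids[pop.focal_index]),
            "focal_freq_by_year": pop.focal_freq_by_year(),
            "pedigree_inbreeding": {pop.ids[i]: float(Fped[i]) for i in chosen},
            "kinship": [
                [pop.ids[i], pop.ids[j], float(A[i, j])]
                for a, i in enumerate(chosen) for j in chosen[a + 1:]
            ],
            "ibd_segments": {pop.ids[i]: true_ibd_segments(pop, i) for i in chosen},
        }
        truth_path = out / "truth.json"
        with open(truth_path, "w") as fh:
            json.dump(tj, fh, indent=1)
        paths["truth"] = truth_path
    return paths
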