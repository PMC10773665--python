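"""Allele-frequency trends by birth year and the drift null model.

The question this module answers: did the mutant-allele decline observed
after genetic testing began exceed what random genetic drift could produce
in a breeding population of the assumed size?  The null is a sex-structured
Wright–Fisher model: each generation, Nm sires and Nf dams are drawn
binomially from the previous generation's allele frequency and the next
frequency is the average of the two sex-specific frequencies — this
reproduces the classical unequal-sex-ratio effective size
Ne_eff = 4·Nm·Nf/(Nm+Nf).  Observed frequencies are compared against the
simulated distribution with a lower-tail empirical p-value, alongside
exact binomial (Clopper–Pearson) confidence intervals and Fisher's exact
test on genotype-count tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import CohortTable

DEFAULT_SEED = 20231218


# ---------------------------------------------------------------------------
# Trend table

def build_trend(cohort: CohortTable) -> pd.DataFrame:
    """Per-birth-year genotype counts, genotype frequencies and mutant
    allele frequency q = (2·n_Mutant + n_Hetero) / (2·n_total).

    Rows with focal_genotype == "unknown" are excluded (count reported in
    the ``n_unknown`` attribute); years with no genotyped dog are omitted.
    """
    df = cohort.df
    known = df[df["focal_genotype"] != "unknown"]
    rows = []
    for year, sub in known.groupby("birth_year"):
        n_w = int((sub["focal_genotype"] == "Wild").sum())
        n_h = int((sub["focal_genotype"] == "Hetero").sum())
        n_m = int((sub["focal_genotype"] == "Mutant").sum())
        n = n_w + n_h + n_m
        if n == 0:
            continue
        rows.append({
            "birth_year": int(year),
            "n_Wild": n_w, "n_Hetero": n_h, "n_Mutant": n_m, "n_total": n,
            "freq_Wild": n_w / n, "freq_Hetero": n_h / n, "freq_Mutant": n_m / n,
            "q_mutant": (2 * n_m + n_h) / (2 * n),
        })
    out = pd.DataFrame(rows).sort_values("birth_year").reset_index(drop=True)
    out.attrs["n_unknown"] = int(len(df) - len(known))
    return out


# ---------------------------------------------------------------------------
# Fisher's exact test (r x c, conditional on margins)

def _log_table_prob(table: np.ndarray, lfact) -> float:
    # P(T | margins) = prod(row!)·prod(col!) / (N!·prod(cell!))
    r = table.sum(axis=1)
    c = table.sum(axis=0)
    n = table.sum()
    return (lfact[r].sum() + lfact[c].sum() - lfact[n] - lfact[table].sum())


def fisher_exact(table, max_tables: int = 10_000_000, mc_reps: int = 200_000,
                 seed: int = DEFAULT_SEED) -> dict:
    """Two-sided Fisher's exact test for an r x c count table.

    p = sum of conditional (multivariate hypergeometric) probabilities of
    all tables with the observed margins whose probability does not exceed
    the observed table's.  Full enumeration when the table space is small
    enough; otherwise Monte-Carlo over margin-preserving permutations, with
    the MC standard error reported.

    Returns {"p": float, "method": "enumeration"|"monte-carlo", "mc_se": ...}.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.ndim != 2 or (t < 0).any():
        raise ValueError("table must be a 2-D array of non-negative counts")
    # all-zero rows/columns carry no information conditional on the margins
    t = t[t.sum(axis=1) > 0][:, t.sum(axis=0) > 0]
    if t.shape[0] < 2 or t.shape[1] < 2:
        return {"p": 1.0, "method": "degenerate-margin", "mc_se": 0.0}
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    n = int(t.sum())
    lfact = np.zeros(n + 1)
    lfact[1:] = np.cumsum(np.log(np.arange(1, n + 1)))
    logp_obs = _log_table_prob(t, lfact)
    eps = 1e-7

    # rough bound on the number of tables with these margins
    bound = 1.0
    for ri in rows[:-1]:
        for cj in cols[:-1]:
            bound *= min(ri, cj) + 1
            if bound > max_tables:
                break
        if bound > max_tables:
            break

    if bound <= max_tables:
        total = 0.0
        nr, nc = t.shape
        work = np.zeros((nr, nc), dtype=np.int64)

        def recurse(i: int, j: int, col_rem: np.ndarray, row_rem: int):
            nonlocal total
            if i == nr - 1:
                # last row forced by column remainders
                work[i, :] = col_rem
                lp = _log_table_prob(work, lfact)
                if lp <= logp_obs + eps:
                    total += math.exp(lp)
                return
            if j == nc - 1:
                if col_rem[j] < row_rem:
                    return
                work[i, j] = row_rem
                col_rem[j] -= row_rem
                recurse(i + 1, 0, col_rem, int(rows[i + 1]))
                col_rem[j] += row_rem
                return
            hi = min(int(col_rem[j]), row_rem)
            for v in range(hi + 1):
                work[i, j] = v
                col_rem[j] -= v
                recurse(i, j + 1, col_rem, row_rem - v)
                col_rem[j] += v

        recurse(0, 0, cols.copy(), int(rows[0]))
        return {"p": min(1.0, total), "method": "enumeration", "mc_se": 0.0}

    # Monte-Carlo: sample margin-fixed tables by random bipartite assignment
    rng = np.random.default_rng(seed)
    row_of = np.repeat(np.arange(len(rows)), rows)
    col_of = np.repeat(np.arange(len(cols)), cols)
    hits = 0
    for _ in range(mc_reps):
        perm = rng.permutation(col_of)
        sim = np.zeros_like(t)
        np.add.at(sim, (row_of, perm), 1)
        if _log_table_prob(sim, lfact) <= logp_obs + eps:
            hits += 1
    p = hits / mc_reps
    se = math.sqrt(max(p * (1 - p), 1e-12) / mc_reps)
    return {"p": p, "method": "monte-carlo", "mc_se": se}


# ---------------------------------------------------------------------------
# Clopper–Pearson exact binomial CI

def clopper_pearson(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Exact binomial confidence interval via Beta quantiles."""
    if not 0 <= k <= n or n < 1:
        raise ValueError("need 0 <= k <= n, n >= 1")
    alpha = 1 - conf
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


# ---------------------------------------------------------------------------
# Drift null

@dataclass
class DriftModel:
    """Sex-structured Wright–Fisher null for one starting frequency.

    ``ne`` is the number of breeding dogs; ``male_fraction`` their male
    share (Nm = round-half-up(mf·Ne), Nf = Ne − Nm).
    """

    ne: int
    q_start: float
    male_fraction: float = 0.2
    generations: int = 6
    replicates: int = 10_000
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.ne < 2:
            raise ValueError("ne must be >= 2")
        if not 0 < self.male_fraction < 1:
            raise ValueError("male_fraction must be in (0,1)")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not 0 <= self.q_start <= 1:
            raise ValueError("q_start must be in [0,1]")

    @property
    def n_males(self) -> int:
        return int(math.floor(self.male_fraction * self.ne + 0.5))  # round half up

    @property
    def n_females(self) -> int:
        return self.ne - self.n_males

    @property
    def ne_eff(self) -> float:
        nm, nf = self.n_males, self.n_females
        return 4.0 * nm * nf / (nm + nf)


@dataclass
class DriftSimResult:
    model: DriftModel
    trajectories: np.ndarray  # (replicates, generations+1)

    def quantiles(self, lo: float = 0.025, hi: float = 0.975) -> pd.DataFrame:
        qs = np.quantile(self.trajectories, [lo, hi], axis=0)
        return pd.DataFrame({
            "generation": np.arange(self.trajectories.shape[1]),
            "q_lo": qs[0], "q_hi": qs[1],
            "q_mean": self.trajectories.mean(axis=0),
        })


def simulate_drift(model: DriftModel) -> DriftSimResult:
    """Simulate replicate allele-frequency trajectories under the null.

    Per generation and replicate the sire allele count is
    Binomial(2·Nm, q) and the dam count Binomial(2·Nf, q); the next
    generation's frequency is the mean of the two sex-specific
    frequencies.  0 and 1 are absorbing.
    """
    nm, nf = model.n_males, model.n_females
    if nm == 0 or nf == 0:
        raise ValueError(f"degenerate sex split Nm={nm}, Nf={nf}")
    rng = np.random.default_rng(model.seed)
    traj = np.empty((model.replicates, model.generations + 1))
    q = np.full(model.replicates, model.q_start)
    traj[:, 0] = q
    for g in range(1, model.generations + 1):
        qm = rng.binomial(2 * nm, q) / (2 * nm)
        qf = rng.binomial(2 * nf, q) / (2 * nf)
        q = 0.5 * (qm + qf)
        traj[:, g] = q
    return DriftSimResult(model=model, trajectories=traj)


def empirical_p(result: DriftSimResult, observed_q: float, generation: int) -> float:
    """Lower-tail empirical p: share of simulated frequencies strictly
    below the observed one at the given generation.  A zero count is
    reported as 1/(2·replicates) so that "p < 1/R" stays representable."""
    if not 0 <= generation < result.trajectories.shape[1]:
        raise ValueError(f"generation {generation} outside simulated range")
    sims = result.trajectories[:, generation]
    r = len(sims)
    count = int((sims < observed_q).sum())
    if count == 0:
        return 0.5 / r
    return count / r
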