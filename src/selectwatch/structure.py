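"""Population structure and contemporary effective population size.

Covers four classical descriptive analyses of a SNP panel:

* PCA on the Patterson-scaled genotype matrix (mean-centred per SNP,
  standardized by sqrt(p(1-p)), missing calls mean-imputed);
* pairwise p-distance between samples (share of mismatching genotype
  states over shared non-missing SNPs) and a Saitou–Nei neighbor-joining
  tree in Newick form;
* Nei's (1972) standard genetic distance D between population allele
  frequency profiles;
* contemporary Ne from linkage disequilibrium between physically unlinked
  loci (different chromosomes): Burrows' composite r-squared from unphased
  genotypes, corrected for its sampling expectation and inverted through
  the random-mating drift relation (Waples 2006 bias-corrected formulas,
  as used by the LD method of NeEstimator).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import MISSING, GenotypeMatrix


# ---------------------------------------------------------------------------
# PCA

def pca(gm: GenotypeMatrix, group_ids=None, n_components: int = 10):
    """Principal components of the scaled genotype matrix.

    Returns (coords DataFrame with sample + PC columns, explained-variance
    fractions).  Zero-variance SNPs are skipped; missing calls are imputed
    at the SNP mean before scaling.
    """
    sub = gm if group_ids is None else gm.subset(sample_ids=group_ids)
    if sub.n_samples < 3:
        raise ValueError("PCA needs at least 3 samples")
    g = sub.calls.astype(np.float64)
    miss = sub.calls == MISSING
    g[miss] = np.nan
    mean = np.nanmean(g, axis=0)
    p = mean / 2.0
    keep = (p > 0) & (p < 1)
    g = np.where(np.isnan(g), mean[None, :], g)[:, keep]
    x = (g - mean[keep]) / np.sqrt(p[keep] * (1 - p[keep]))
    x /= math.sqrt(x.shape[1])
    grm = x @ x.T
    vals, vecs = np.linalg.eigh(grm)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    k = min(n_components, sub.n_samples - 1)
    coords = pd.DataFrame(vecs[:, :k], columns=[f"PC{i+1}" for i in range(k)])
    coords.insert(0, "sample", sub.samples)
    explained = np.clip(vals, 0, None)
    explained = explained[:k] / explained.sum() if explained.sum() > 0 else explained[:k]
    return coords, explained


# ---------------------------------------------------------------------------
# p-distance and NJ

def p_distance(gm: GenotypeMatrix, i, j) -> float:
    """Share of mismatching genotype states over shared non-missing SNPs."""
    if isinstance(i, str):
        i = gm.sample_index(i)
    if isinstance(j, str):
        j = gm.sample_index(j)
    gi, gj = gm.calls[i], gm.calls[j]
    shared = (gi != MISSING) & (gj != MISSING)
    n = int(shared.sum())
    if n == 0:
        raise ValueError("no shared non-missing SNPs")
    return float((gi[shared] != gj[shared]).sum() / n)


def p_distance_matrix(gm: GenotypeMatrix, sample_ids=None) -> pd.DataFrame:
    sub = gm if sample_ids is None else gm.subset(sample_ids=sample_ids)
    g = sub.calls
    ok = (g != MISSING)
    n = sub.n_samples
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = ok[i] & ok[j]
            ns = int(shared.sum())
            if ns == 0:
                raise ValueError(f"no shared SNPs for {sub.samples[i]},{sub.samples[j]}")
            d[i, j] = d[j, i] = (g[i, shared] != g[j, shared]).sum() / ns
    return pd.DataFrame(d, index=sub.samples, columns=sub.samples)


def nj_tree(dm: pd.DataFrame) -> str:
    """Saitou–Nei neighbor joining; returns an unrooted Newick string.

    Joins the pair minimizing Q = (n-2)d_ij - r_i - r_j (ties by label
    order); negative branch lengths are clamped to zero with the excess
    moved to the sister branch.
    """
    labels = list(dm.index)
    if list(dm.columns) != labels:
        raise ValueError("distance matrix must have matching row/column labels")
    d = dm.to_numpy(dtype=float)
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if len(labels) < 3:
        raise ValueError("NJ needs at least 3 taxa")
    newick = {lab: lab for lab in labels}
    active = list(labels)
    dist = {(a, b): d[i, j] for i, a in enumerate(labels) for j, b in enumerate(labels)}

    def D(a, b):
        return dist[(a, b)] if (a, b) in dist else dist[(b, a)]

    while len(active) > 3:
        n = len(active)
        r = {a: sum(D(a, b) for b in active if b != a) for a in active}
        best = None
        for ii in range(n):
            for jj in range(ii + 1, n):
                a, b = active[ii], active[jj]
                q = (n - 2) * D(a, b) - r[a] - r[b]
                key = (q, min(a, b), max(a, b))
                if best is None or key < best[0]:
                    best = (key, a, b)
        _, a, b = best
        dab = D(a, b)
        la = dab / 2 + (r[a] - r[b]) / (2 * (n - 2))
        lb = dab - la
        if la < 0:
            lb -= la
            la = 0.0
        if lb < 0:
            la -= lb
            lb = 0.0
        u = f"({newick[a]}:{la:.10g},{newick[b]}:{lb:.10g})"
        for c in active:
            if c in (a, b):
                continue
            dist[(u, c)] = 0.5 * (D(a, c) + D(b, c) - dab)
        active = [c for c in active if c not in (a, b)] + [u]
        newick[u] = u

    a, b, c = active
    la = 0.5 * (D(a, b) + D(a, c) - D(b, c))
    lb = 0.5 * (D(a, b) + D(b, c) - D(a, c))
    lc = 0.5 * (D(a, c) + D(b, c) - D(a, b))
    la, lb, lc = (max(x, 0.0) for x in (la, lb, lc))
    return f"({newick[a]}:{la:.10g},{newick[b]}:{lb:.10g},{newick[c]}:{lc:.10g});"


# ---------------------------------------------------------------------------
# Nei's standard genetic distance

def neis_d(freqs_x, freqs_y) -> float:
    """Nei's (1972) standard D between two populations' allele frequencies.

    Inputs are per-locus allele-frequency arrays (list of 1-D arrays, or a
    2-D array loci x alleles); each locus must sum to 1 in each population.
    D = -ln( Jxy / sqrt(Jx Jy) ) with J's the mean gene identities.
    """
    fx = [np.asarray(f, dtype=float) for f in freqs_x]
    fy = [np.asarray(f, dtype=float) for f in freqs_y]
    if len(fx) != len(fy):
        raise ValueError("populations must share the locus set")
    jxy = jx = jy = 0.0
    for x, y in zip(fx, fy):
        if x.shape != y.shape:
            raise ValueError("allele sets differ at a locus")
        if not (math.isclose(x.sum(), 1.0, abs_tol=1e-6) and math.isclose(y.sum(), 1.0, abs_tol=1e-6)):
            raise ValueError("allele frequencies must sum to 1 per locus")
        jxy += float(np.dot(x, y))
        jx += float(np.dot(x, x))
        jy += float(np.dot(y, y))
    L = len(fx)
    jxy, jx, jy = jxy / L, jx / L, jy / L
    if jx == 0 or jy == 0:
        raise ValueError("zero gene identity within a population")
    return float(-math.log(jxy / math.sqrt(jx * jy)))


def neis_d_from_genotypes(gm: GenotypeMatrix, ids_x, ids_y) -> float:
    """Nei's D from two sample groups of a biallelic genotype matrix."""
    px = gm.subset(sample_ids=ids_x).allele_freq()
    py = gm.subset(sample_ids=ids_y).allele_freq()
    ok = np.isfinite(px) & np.isfinite(py)
    fx = [np.array([1 - p, p]) for p in px[ok]]
    fy = [np.array([1 - p, p]) for p in py[ok]]
    return neis_d(fx, fy)


# ---------------------------------------------------------------------------
# LD-based contemporary Ne

@dataclass
class NeEstimate:
    group: str
    s: float                 # sample size (individuals)
    n_pairs: int
    mean_r2: float
    r2_drift: float          # mean r2 minus sampling expectation
    ne_hat: float            # may be math.inf
    ci: tuple[float, float]  # parametric (chi-square) CI on ne_hat


def _expected_sample_r2(s: float) -> float:
    # sampling component of r^2 for unlinked loci, random-mating model
    if s >= 30:
        return 1.0 / s + 3.19 / s ** 2
    return 0.0018 + 0.907 / s + 4.44 / s ** 2


def _ne_from_r2drift(r2d: float, s: float) -> float:
    if r2d <= 0:
        return math.inf
    if s >= 30:
        disc = max(1.0 / 9.0 - 2.76 * r2d, 0.0)
        return (1.0 / 3.0 + math.sqrt(disc)) / (2.0 * r2d)
    disc = max(0.308 ** 2 - 2.08 * r2d, 0.0)
    return (0.308 + math.sqrt(disc)) / (2.0 * r2d)


def burrows_r2_matrix(g: np.ndarray) -> np.ndarray:
    """All-pairs composite r^2 from a complete (samples x loci) dosage
    matrix: r^2 = Delta^2 / [(pq + D_A)(pq + D_B)] with Burrows' Delta
    = S/(S-1) · (mean(XY)/2 − 2 p_A p_B) and D_A the homozygote excess."""
    s = g.shape[0]
    p = g.mean(axis=0) / 2.0
    delta = (g.T @ g) / (2.0 * s) - 2.0 * np.outer(p, p)
    delta *= s / (s - 1.0)
    d_hw = (g == 2).mean(axis=0) - p ** 2
    denom_vec = p * (1 - p) + d_hw
    denom = np.outer(denom_vec, denom_vec)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = delta ** 2 / denom
    return r2


def ld_ne(
    gm: GenotypeMatrix,
    group_ids,
    maf_floor: float = 0.01,
    max_pairs: int = 500_000,
    seed: int = 0,
    group: str = "",
) -> NeEstimate:
    """LD-based contemporary Ne for one group.

    Uses locus pairs on *different* chromosomes with MAF >= maf_floor,
    Burrows' composite r-squared on complete cases, the random-mating
    sampling correction, and the Waples (2006) drift inversion.  Pairs are
    subsampled (seeded) beyond ``max_pairs``; the CI is the parametric
    chi-square interval on the mean r-squared with n_pairs degrees of
    freedom.
    """
    sub = gm.subset(sample_ids=group_ids)
    if sub.n_samples < 10:
        raise ValueError("need at least 10 samples for LD-Ne")
    chroms = sub.markers.chrom
    if len(set(map(str, chroms))) < 2:
        raise ValueError("need loci on at least 2 chromosomes (no unlinked pairs)")
    g = sub.calls.astype(np.float64)
    g[sub.calls == MISSING] = np.nan
    p = np.nanmean(g, axis=0) / 2.0
    maf = np.minimum(p, 1 - p)
    complete = ~np.isnan(g).any(axis=0)  # complete cases per locus
    keep = (maf >= maf_floor) & complete
    g = g[:, keep]
    chroms = chroms[keep]
    s = float(g.shape[0])

    r2 = burrows_r2_matrix(g)
    codes = pd.factorize(np.asarray([str(c) for c in chroms]))[0]
    same_chrom = codes[:, None] == codes[None, :]
    iu = np.triu_indices(len(chroms), k=1)
    use = ~same_chrom[iu] & np.isfinite(r2[iu])
    vals = r2[iu][use]
    rng = np.random.default_rng(seed)
    if len(vals) > max_pairs:
        vals = rng.choice(vals, size=max_pairs, replace=False)
    if len(vals) == 0:
        raise ValueError("no usable unlinked locus pairs")

    mean_r2 = float(vals.mean())
    exp_r2 = _expected_sample_r2(s)
    r2d = mean_r2 - exp_r2
    ne_hat = _ne_from_r2drift(r2d, s)
    df = len(vals)
    lo_r2 = mean_r2 * df / stats.chi2.ppf(0.975, df)
    hi_r2 = mean_r2 * df / stats.chi2.ppf(0.025, df)
    ci = (
        _ne_from_r2drift(hi_r2 - exp_r2, s),
        _ne_from_r2drift(lo_r2 - exp_r2, s),
    )
    ci = (min(ci), max(ci)) if all(math.isfinite(c) for c in ci) else ci
    return NeEstimate(group=group, s=s, n_pairs=df, mean_r2=mean_r2,
                      r2_drift=r2d, ne_hat=ne_hat, ci=ci)
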