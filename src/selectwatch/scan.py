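"""Genome-wide selection scan: per-SNP Weir–Cockerham F_ST and EHH.

F_ST follows the Weir & Cockerham (1984) variance-components estimator for
two populations of diploids: per SNP the among-population (a),
among-individual-within-population (b) and within-individual (c)
components are computed from sample sizes, allele frequencies and observed
heterozygote frequencies on complete cases, and F_ST = a/(a+b+c).  Small
negative estimates are an expected property of the estimator.

EHH (extended haplotype homozygosity) is the probability that two randomly
drawn haplotypes carrying the core allele are identical over the whole
interval from the core SNP out to a flanking SNP; it decays from 1 at the
core and long flat decay marks a recent sweep.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix, MarkerMap


# ---------------------------------------------------------------------------
# Weir–Cockerham F_ST

def wc_fst(gm: GenotypeMatrix, group_a_ids, group_b_ids) -> pd.DataFrame:
    """Per-SNP WC84 components and F_ST between two groups of samples.

    Returns a DataFrame (id, chrom, pos_bp, a, b, c, fst); SNPs where the
    total variance a+b+c is zero (monomorphic across both groups) have
    fst = NaN.
    """
    if len(group_a_ids) == 0 or len(group_b_ids) == 0:
        raise ValueError("both groups must be non-empty")
    ga = gm.subset(sample_ids=group_a_ids).calls
    gb = gm.subset(sample_ids=group_b_ids).calls

    comps = []
    for g in (ga, gb):
        ok = g != MISSING
        n_i = ok.sum(axis=0).astype(float)                    # individuals genotyped
        with np.errstate(invalid="ignore", divide="ignore"):
            p_i = np.where(ok, g, 0).sum(axis=0) / (2 * n_i)  # A2 frequency
            h_i = ((g == 1) & ok).sum(axis=0) / n_i           # observed het freq
        comps.append((n_i, p_i, h_i))
    (n1, p1, h1), (n2, p2, h2) = comps

    r = 2.0
    n_sum = n1 + n2
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = n_sum / r
        nc = (n_sum - (n1 ** 2 + n2 ** 2) / n_sum) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / n_sum
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / n_sum

        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar))
        c = hbar / 2
        denom = a + b + c
        fst = np.where(denom != 0, a / np.where(denom != 0, denom, 1.0), np.nan)

    bad = (n1 < 2) | (n2 < 2)
    if bad.any():
        fst = np.where(bad, np.nan, fst)
    mdf = gm.markers.df
    return pd.DataFrame({
        "id": mdf["id"], "chrom": mdf["chrom"], "pos_bp": mdf["pos_bp"],
        "a": a, "b": b, "c": c, "fst": fst,
    })


def rank_scan(fst: pd.DataFrame, top_fraction: float = 0.001) -> pd.DataFrame:
    """Flag the upper ``top_fraction`` of defined F_ST values.

    The threshold is the k-th largest defined value with
    k = ceil(top_fraction × n_defined); all SNPs tied at the threshold are
    kept.  Adds a boolean ``flagged`` column; the result is sorted by
    descending fst with the top SNP first.
    """
    defined = fst[np.isfinite(fst["fst"])].copy()
    n = len(defined)
    if n == 0:
        raise ValueError("no defined F_ST values")
    k = max(1, math.ceil(top_fraction * n))
    thresh = np.sort(defined["fst"].to_numpy())[::-1][k - 1]
    defined["flagged"] = defined["fst"] >= thresh
    return defined.sort_values(["fst", "id"], ascending=[False, True]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# EHH

@dataclass
class HaplotypeSet:
    """Phased binary haplotypes (rows) over the SNPs of a marker map."""

    markers: MarkerMap
    haps: np.ndarray          # (n_haplotypes, n_snps) of 0/1
    labels: list[str]

    def __post_init__(self) -> None:
        self.haps = np.asarray(self.haps, dtype=np.int8)
        if self.haps.shape != (len(self.labels), self.markers.n_snps):
            raise ValueError("haplotype matrix shape inconsistent with labels/map")


def read_haps(haps_path, markers: MarkerMap) -> HaplotypeSet:
    """Read transposed-haplotype text: one row per haplotype,
    `label<TAB>010011...` over the SNPs of ``markers`` in map order."""
    labels, rows = [], []
    with open(haps_path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip():
                continue
            label, alleles = line.split()
            if len(alleles) != markers.n_snps:
                raise ValueError(
                    f"{haps_path}:{ln}: {len(alleles)} alleles, map has {markers.n_snps} SNPs"
                )
            labels.append(label)
            rows.append(np.frombuffer(alleles.encode(), dtype=np.uint8) - ord("0"))
    return HaplotypeSet(markers, np.array(rows, dtype=np.int8), labels)


def ehh(haps: HaplotypeSet, core_snp: str, core_allele: int,
        window_bp: int = 1_000_000) -> pd.DataFrame:
    """EHH decay curve around a core SNP for the haplotypes carrying
    ``core_allele`` there.

    For each flanking SNP x within the window (same chromosome), carrier
    haplotypes are grouped by identity over the whole interval [core, x];
    ehh(x) = Σ_h C(n_h,2) / C(n,2).  Returns rows (snp_id, pos_bp,
    distance_bp, ehh), including the core itself (ehh = 1), ordered by
    position.  Identity is evaluated at marker positions only.
    """
    mdf = haps.markers.df
    hits = np.flatnonzero(mdf["id"].to_numpy() == core_snp)
    if len(hits) != 1:
        raise KeyError(f"core SNP {core_snp!r} not found in map")
    core = int(hits[0])
    chrom = mdf["chrom"].iloc[core]
    pos = mdf["pos_bp"].to_numpy()
    core_pos = int(pos[core])
    on_chrom = (mdf["chrom"] == chrom).to_numpy()
    in_window = on_chrom & (np.abs(pos - core_pos) <= window_bp)

    carriers = haps.haps[:, core] == core_allele
    n = int(carriers.sum())
    if n < 2:
        raise ValueError(f"only {n} haplotype(s) carry allele {core_allele} at {core_snp}")
    sub = haps.haps[carriers]
    pair_total = n * (n - 1) / 2

    def homozygosity_sweep(indices):
        """EHH at successive SNPs walking away from the core."""
        group = np.zeros(n, dtype=np.int64)   # all carriers in one group at core
        out = []
        for j in indices:
            alleles = sub[:, j].astype(np.int64)
            # refine grouping by the new site
            key = group * 2 + alleles
            _, group = np.unique(key, return_inverse=True)
            counts = np.bincount(group)
            out.append(float((counts * (counts - 1) / 2).sum() / pair_total))
        return out

    left = [j for j in range(core - 1, -1, -1) if in_window[j]]
    right = [j for j in range(core + 1, len(pos)) if in_window[j]]
    rows = [(mdf["id"].iloc[core], core_pos, 0, 1.0)]
    for idx_list in (left, right):
        for j, e in zip(idx_list, homozygosity_sweep(idx_list)):
            rows.append((mdf["id"].iloc[j], int(pos[j]), int(pos[j] - core_pos), e))
    out = pd.DataFrame(rows, columns=["snp_id", "pos_bp", "distance_bp", "ehh"])
    return out.sort_values("pos_bp").reset_index(drop=True)
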