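"""Observed heterozygosity, runs of homozygosity and F_ROH.

ROH are called with the deterministic consecutive-runs method: per sample
and chromosome, maximal stretches of consecutive homozygous SNP calls
(allowing up to ``max_het`` heterozygous and ``max_miss`` missing calls,
both 0 by default) are candidate runs, broken wherever the gap between
adjacent SNPs exceeds ``max_gap_bp``; a candidate is reported when it
passes all of: n_snps >= min_snp, bp length >= min_length_bp, and SNP
density >= min_density (SNPs per bp).

F_ROH for a sample is the summed ROH length divided by the genotyped
genome span (per-autosome last-minus-first marker position), a genomic
inbreeding coefficient comparable across samples genotyped on the same
panel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import MISSING, GenotypeMatrix


@dataclass
class RohParams:
    """Consecutive-run ROH thresholds (defaults: 41 SNPs, 1 Mbp max gap,
    50 kb min length, 1 SNP / 5 kb min density, no het/missing allowed)."""

    min_snp: int = 41
    max_gap_bp: int = 1_000_000
    min_length_bp: int = 50_000
    min_density: float = 1.0 / 5000.0
    max_het: int = 0
    max_miss: int = 0


def observed_het(gm: GenotypeMatrix, group_ids) -> float:
    """Group Ho: mean over SNPs of (het calls / non-missing calls).

    SNPs with no non-missing call in the group are skipped.
    """
    if len(group_ids) == 0:
        raise ValueError("group is empty")
    g = gm.subset(sample_ids=group_ids).calls
    ok = g != MISSING
    n = ok.sum(axis=0)
    het = ((g == 1) & ok).sum(axis=0)
    use = n > 0
    return float((het[use] / n[use]).mean())


def _runs_no_tolerance(hom_ok: np.ndarray, gap_break: np.ndarray):
    """Maximal runs of True in hom_ok, additionally split at gap breaks.
    Yields (start, end) index pairs, end exclusive."""
    n = len(hom_ok)
    runs = []
    i = 0
    while i < n:
        if not hom_ok[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and hom_ok[j + 1] and not gap_break[j]:
            j += 1
        runs.append((i, j + 1))
        i = j + 1
    return runs


def detect_roh(gm: GenotypeMatrix, sample_id: str, params: RohParams | None = None) -> pd.DataFrame:
    """Call ROH for one sample; returns (sample, chrom, start_bp, end_bp,
    n_snps, length_bp) in coordinate order.  Requires a sorted marker map.
    """
    params = params or RohParams()
    if not gm.markers.is_sorted():
        raise ValueError("marker map must be sorted by (chrom, pos)")
    si = gm.sample_index(sample_id)
    calls = gm.calls[si]
    mdf = gm.markers.df
    out = []
    for chrom, sub in mdf.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        c = calls[idx]
        pos = sub["pos_bp"].to_numpy()
        gap_break = np.empty(len(pos), dtype=bool)
        gap_break[:-1] = np.diff(pos) > params.max_gap_bp
        gap_break[-1] = True

        if params.max_het == 0 and params.max_miss == 0:
            hom = (c == 0) | (c == 2)
            cands = _runs_no_tolerance(hom, gap_break)
        else:
            cands = _runs_with_tolerance(c, gap_break, params)

        for s, e in cands:
            n_snps = e - s
            length = int(pos[e - 1] - pos[s] + 1)
            if n_snps < params.min_snp or length < params.min_length_bp:
                continue
            if n_snps / length < params.min_density:
                continue
            out.append((sample_id, str(chrom), int(pos[s]), int(pos[e - 1]), n_snps, length))
    return pd.DataFrame(out, columns=["sample", "chrom", "start_bp", "end_bp", "n_snps", "length_bp"])


def _runs_with_tolerance(c: np.ndarray, gap_break: np.ndarray, params: RohParams):
    """Greedy scan allowing a bounded number of het/missing calls per run."""
    n = len(c)
    runs = []
    i = 0
    while i < n:
        if c[i] != 0 and c[i] != 2:
            i += 1
            continue
        het = miss = 0
        j = i
        last_hom = i
        while j + 1 < n and not gap_break[j]:
            nxt = c[j + 1]
            if nxt == MISSING:
                if miss + 1 > params.max_miss:
                    break
                miss += 1
            elif nxt == 1:
                if het + 1 > params.max_het:
                    break
                het += 1
            else:
                last_hom = j + 1
            j += 1
        runs.append((i, last_hom + 1))  # trim trailing het/missing
        i = j + 1
    return runs


def detect_roh_all(gm: GenotypeMatrix, params: RohParams | None = None) -> pd.DataFrame:
    frames = [detect_roh(gm, s, params) for s in gm.samples]
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["sample", "chrom", "start_bp", "end_bp", "n_snps", "length_bp"])


def genome_span(gm: GenotypeMatrix) -> int:
    """Genotyped genome span: sum over autosomes of (last − first + 1)."""
    total = 0
    for _, sub in gm.markers.df.groupby("chrom", sort=False):
        p = sub["pos_bp"].to_numpy()
        total += int(p.max() - p.min() + 1)
    return total


def f_roh(runs: pd.DataFrame, genome_span_bp: int, sample_ids) -> pd.Series:
    """Per-sample F_ROH = Σ ROH length / genome span (0 when no run)."""
    if genome_span_bp <= 0:
        raise ValueError("genome span must be positive")
    sums = runs.groupby("sample")["length_bp"].sum() if len(runs) else pd.Series(dtype=float)
    return pd.Series({s: float(sums.get(s, 0)) / genome_span_bp for s in sample_ids}, name="f_roh")


def group_summary(froh: pd.Series, cohort_df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Group mean ± SD of F_ROH plus Welch's t-test for every group pair."""
    merged = cohort_df.set_index("id").join(froh)
    rows = []
    groups = {}
    for g, sub in merged.groupby("group"):
        v = sub["f_roh"].dropna().to_numpy()
        groups[g] = v
        rows.append({"group": g, "n": len(v), "mean_f_roh": float(v.mean()),
                     "sd_f_roh": float(v.std(ddof=1)) if len(v) > 1 else float("nan")})
    summary = pd.DataFrame(rows)
    pairs = []
    names = sorted(groups)
    for i, gi in enumerate(names):
        for gj in names[i + 1:]:
            if len(groups[gi]) > 1 and len(groups[gj]) > 1:
                t, p = stats.ttest_ind(groups[gi], groups[gj], equal_var=False)
            else:
                t, p = float("nan"), float("nan")
            pairs.append({"group_a": gi, "group_b": gj, "welch_t": float(t), "p": float(p)})
    return summary, pd.DataFrame(pairs)
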