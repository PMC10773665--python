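"""Genotype I/O, quality control and relative pruning.

PLINK text PED/MAP is the interchange format: a MAP row per SNP
(chrom, id, cM, bp) and a PED row per sample (FID IID PAT MAT SEX PHENO
followed by two allele characters per SNP).  Genotypes are held as counts
of the A2 allele (0/1/2, ``-1`` for missing), where A2 is fixed as the
alphabetically-second allele observed for the SNP when the file is first
read, so downstream allele frequencies are orientation-stable.

Coordinates are 1-based inclusive throughout, autosomes only after QC.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1
VALID_ALLELES = frozenset("ACGT0")


class PedParseError(ValueError):
    """Malformed PED/MAP input; message names the offending line."""


class EmptyAfterQCError(ValueError):
    """Every SNP (or sample) was removed by the QC chain."""


@dataclass
class MarkerMap:
    """Per-SNP map: id, autosome label, 1-based bp position, (A1, A2) alleles.

    A2 is the counted allele.  ``df`` columns: id, chrom, pos_bp, a1, a2.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["id", "chrom", "pos_bp", "a1", "a2"]
        missing = [c for c in required if c not in self.df.columns]
        if missing:
            raise ValueError(f"MarkerMap missing columns: {missing}")
        if self.df["id"].duplicated().any():
            dup = self.df["id"][self.df["id"].duplicated()].iloc[0]
            raise ValueError(f"duplicate SNP id {dup!r}")

    @property
    def n_snps(self) -> int:
        return len(self.df)

    @property
    def ids(self) -> np.ndarray:
        return self.df["id"].to_numpy()

    @property
    def chrom(self) -> np.ndarray:
        return self.df["chrom"].to_numpy()

    @property
    def pos_bp(self) -> np.ndarray:
        return self.df["pos_bp"].to_numpy()

    def is_sorted(self) -> bool:
        for _, sub in self.df.groupby("chrom", sort=False):
            p = sub["pos_bp"].to_numpy()
            if np.any(np.diff(p) <= 0):
                return False
        return True


@dataclass
class GenotypeMatrix:
    """Samples x SNPs diploid calls as A2-allele counts; -1 = missing."""

    markers: MarkerMap
    samples: list[str]
    calls: np.ndarray  # (n_samples, n_snps) int8

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), self.markers.n_snps):
            raise ValueError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{len(self.samples)} samples x {self.markers.n_snps} SNPs"
            )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return self.markers.n_snps

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.samples.index(sample_id)
        except ValueError:
            raise KeyError(f"sample {sample_id!r} not in matrix") from None

    def subset(self, sample_ids=None, snp_mask=None) -> "GenotypeMatrix":
        """Return a copy restricted to the given samples and/or SNP mask."""
        calls = self.calls
        samples = list(self.samples)
        markers = self.markers
        if sample_ids is not None:
            idx = [self.sample_index(s) for s in sample_ids]
            calls = calls[idx, :]
            samples = [self.samples[i] for i in idx]
        if snp_mask is not None:
            snp_mask = np.asarray(snp_mask)
            calls = calls[:, snp_mask]
            markers = MarkerMap(markers.df.loc[snp_mask].reset_index(drop=True)
                                if snp_mask.dtype == bool
                                else markers.df.iloc[snp_mask].reset_index(drop=True))
        return GenotypeMatrix(markers, samples, calls.copy())

    def allele_freq(self) -> np.ndarray:
        """Per-SNP A2 frequency over non-missing calls (NaN if all missing)."""
        ok = self.calls != MISSING
        n = ok.sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(ok, self.calls, 0).sum(axis=0) / np.maximum(2 * n, 1) * np.where(n > 0, 1.0, np.nan)


@dataclass
class CohortTable:
    """Per-sample metadata: id, birth_year, focal genotype label, group."""

    df: pd.DataFrame

    GENOTYPES = ("Wild", "Hetero", "Mutant", "unknown")

    def __post_init__(self) -> None:
        required = ["id", "birth_year", "focal_genotype", "group"]
        missing = [c for c in required if c not in self.df.columns]
        if missing:
            raise ValueError(f"CohortTable missing columns: {missing}")
        bad = set(self.df["focal_genotype"]) - set(self.GENOTYPES)
        if bad:
            raise ValueError(f"unknown focal_genotype labels: {sorted(bad)}")

    def group_ids(self, group: str) -> list[str]:
        return self.df.loc[self.df["group"] == group, "id"].tolist()


@dataclass
class KinshipResult:
    """KING-robust kinship for all pairs plus the retained sample set."""

    pairs: pd.DataFrame  # columns id_i, id_j, phi
    kept: list[str]
    cutoff: float


# ---------------------------------------------------------------------------
# PED/MAP

def read_map(map_path) -> pd.DataFrame:
    rows = []
    with open(map_path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 4:
                raise PedParseError(f"{map_path}:{ln}: expected 4 fields, got {len(parts)}")
            chrom, snp_id, _cm, pos = parts
            rows.append((snp_id, chrom, int(pos)))
    return pd.DataFrame(rows, columns=["id", "chrom", "pos_bp"])


def read_ped_map(ped_path, map_path) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Read PLINK text PED+MAP into a GenotypeMatrix.

    Returns (gm, fam) where ``fam`` holds the six leading PED columns.
    A2 (the counted allele) is the alphabetically-second allele observed
    per SNP; "0 0" becomes missing.
    """
    mp = read_map(map_path)
    n_snps = len(mp)
    samples: list[str] = []
    fam_rows = []
    a_rows = []
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 6 + 2 * n_snps:
                raise PedParseError(
                    f"{ped_path}:{ln}: expected {6 + 2 * n_snps} fields, got {len(parts)}"
                )
            fam_rows.append(parts[:6])
            samples.append(parts[1])
            alleles = parts[6:]
            bad = set(alleles) - VALID_ALLELES
            if bad:
                raise PedParseError(
                    f"{ped_path}:{ln}: allele symbol(s) {sorted(bad)} outside A/C/G/T/0"
                )
            a_rows.append(alleles)
    if not samples:
        raise PedParseError(f"{ped_path}: no samples")
    al = np.array(a_rows, dtype="U1").reshape(len(samples), n_snps, 2)

    a1 = np.full(n_snps, "0", dtype="U1")
    a2 = np.full(n_snps, "0", dtype="U1")
    calls = np.full((len(samples), n_snps), MISSING, dtype=np.int8)
    for j in range(n_snps):
        col = al[:, j, :]
        obs = sorted(set(col.ravel()) - {"0"})
        if len(obs) > 2:
            raise PedParseError(f"SNP {mp['id'][j]!r}: >2 alleles observed {obs}")
        if len(obs) == 0:
            continue
        if len(obs) == 1:
            a1[j] = obs[0]          # monomorphic: count the observed allele as A2
            a2[j] = obs[0]
        else:
            a1[j], a2[j] = obs[0], obs[1]
        nonmiss = (col != "0").all(axis=1)
        calls[nonmiss, j] = (col[nonmiss] == a2[j]).sum(axis=1)

    mdf = mp.copy()
    mdf["a1"] = a1
    mdf["a2"] = a2
    gm = GenotypeMatrix(MarkerMap(mdf), samples, calls)
    fam = pd.DataFrame(fam_rows, columns=["fid", "iid", "pat", "mat", "sex", "pheno"])
    return gm, fam


def write_ped_map(gm: GenotypeMatrix, ped_path, map_path, fam: pd.DataFrame | None = None) -> None:
    """Write PLINK text PED+MAP (inverse of :func:`read_ped_map`)."""
    mdf = gm.markers.df
    with open(map_path, "w") as fh:
        for _, r in mdf.iterrows():
            fh.write(f"{r['chrom']}\t{r['id']}\t0\t{r['pos_bp']}\n")
    a1 = mdf["a1"].to_numpy()
    a2 = mdf["a2"].to_numpy()
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(gm.samples):
            if fam is not None:
                lead = fam.iloc[i].tolist()
            else:
                lead = [sid, sid, "0", "0", "0", "-9"]
            toks = list(map(str, lead))
            row = gm.calls[i]
            for j in range(gm.n_snps):
                c = row[j]
                if c == MISSING:
                    toks += ["0", "0"]
                elif c == 0:
                    toks += [a1[j], a1[j]]
                elif c == 1:
                    toks += [a1[j], a2[j]]
                else:
                    toks += [a2[j], a2[j]]
            fh.write(" ".join(toks) + "\n")


def read_metadata(path) -> CohortTable:
    """Read the headered TSV (id, birth_year, focal_genotype, group)."""
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    df["birth_year"] = df["birth_year"].astype(int)
    return CohortTable(df)


def write_metadata(table: CohortTable, path) -> None:
    table.df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# QC

AUTOSOME_MAX = 38  # CanFam autosomes 1..38; anything else is dropped


def _is_autosome(chrom_labels: np.ndarray) -> np.ndarray:
    out = np.zeros(len(chrom_labels), dtype=bool)
    for i, c in enumerate(chrom_labels):
        s = str(c)
        out[i] = s.isdigit() and 1 <= int(s) <= AUTOSOME_MAX
    return out


@dataclass
class QCReport:
    """SNP/sample counts through each QC stage (in - removed = out)."""

    stages: list[dict] = field(default_factory=list)

    def log(self, stage: str, kind: str, n_in: int, n_removed: int) -> None:
        self.stages.append(
            {"stage": stage, "kind": kind, "in": n_in, "removed": n_removed, "out": n_in - n_removed}
        )


def qc_filter(
    gm: GenotypeMatrix,
    geno_max: float = 0.01,
    mind_max: float = 0.01,
    maf_min: float = 0.01,
    report: QCReport | None = None,
) -> GenotypeMatrix:
    """Apply the QC chain: autosomes/SNPs only, then per-SNP missingness
    (< geno_max), per-sample missingness (< mind_max), and MAF >= maf_min.

    Filter order is fixed to mirror the conventional PLINK order.  Raises
    :class:`EmptyAfterQCError` if no SNP or no sample survives.
    """
    if gm.n_snps == 0 or gm.n_samples == 0:
        raise EmptyAfterQCError("input matrix is empty")
    rep = report if report is not None else QCReport()

    auto = _is_autosome(gm.markers.chrom)
    snp_like = np.array([len(a) == 1 for a in gm.markers.df["a2"]])  # indels never enter U1 arrays but keep the guard
    keep = auto & snp_like
    rep.log("autosome_snp", "snp", gm.n_snps, int((~keep).sum()))
    gm = gm.subset(snp_mask=keep)

    miss = gm.calls == MISSING
    snp_miss_rate = miss.mean(axis=0)
    keep_snp = snp_miss_rate < geno_max
    rep.log("geno", "snp", gm.n_snps, int((~keep_snp).sum()))
    gm = gm.subset(snp_mask=keep_snp)
    if gm.n_snps == 0:
        raise EmptyAfterQCError("no SNPs remain after missingness filter")

    miss = gm.calls == MISSING
    sample_miss_rate = miss.mean(axis=1)
    keep_sample = sample_miss_rate < mind_max
    rep.log("mind", "sample", gm.n_samples, int((~keep_sample).sum()))
    if not keep_sample.any():
        raise EmptyAfterQCError("no samples remain after missingness filter")
    gm = gm.subset(sample_ids=[s for s, k in zip(gm.samples, keep_sample) if k])

    p = gm.allele_freq()
    maf = np.minimum(p, 1 - p)
    keep_maf = maf >= maf_min
    rep.log("maf", "snp", gm.n_snps, int((~keep_maf).sum()))
    gm = gm.subset(snp_mask=keep_maf)
    if gm.n_snps == 0:
        raise EmptyAfterQCError("no SNPs remain after MAF filter")
    return gm


# ---------------------------------------------------------------------------
# KING-robust kinship

def king_kinship(gm: GenotypeMatrix, i, j, min_shared: int = 100) -> float:
    """KING-robust between-family kinship estimate for samples i and j.

    phi = (N_Aa,Aa - 2 N_AA,aa) / (N_Aa(i) + N_Aa(j)) over SNPs genotyped
    in both samples.  0.5 for duplicates, ~0.25 for first-degree pairs,
    ~0 for unrelated; structure-robust.  NaN if no heterozygous sites.
    """
    if isinstance(i, str):
        i = gm.sample_index(i)
    if isinstance(j, str):
        j = gm.sample_index(j)
    gi, gj = gm.calls[i], gm.calls[j]
    shared = (gi != MISSING) & (gj != MISSING)
    if int(shared.sum()) < min_shared:
        raise ValueError(
            f"only {int(shared.sum())} shared genotyped SNPs (< {min_shared})"
        )
    gi, gj = gi[shared], gj[shared]
    het_i = gi == 1
    het_j = gj == 1
    n_het_het = int((het_i & het_j).sum())
    n_opp_hom = int((((gi == 0) & (gj == 2)) | ((gi == 2) & (gj == 0))).sum())
    denom = int(het_i.sum()) + int(het_j.sum())
    if denom == 0:
        return float("nan")
    return (n_het_het - 2 * n_opp_hom) / denom


def king_kinship_matrix(gm: GenotypeMatrix, min_shared: int = 100) -> pd.DataFrame:
    """All-pairs KING-robust kinship (vectorized). Columns id_i, id_j, phi."""
    g = gm.calls
    ok = (g != MISSING)
    het = (g == 1) & ok
    hom0 = (g == 0) & ok
    hom2 = (g == 2) & ok
    het_f = het.astype(np.float32)
    n_hh = het_f @ het_f.T
    n_opp = hom0.astype(np.float32) @ hom2.astype(np.float32).T
    n_opp = n_opp + n_opp.T
    okf = ok.astype(np.float32)
    shared = okf @ okf.T
    # heterozygote counts restricted to the shared-callable SNPs of each pair
    het_on_ok = het_f @ okf.T  # n_het(i over sites callable in j)
    denom = het_on_ok + het_on_ok.T
    rows = []
    n = gm.n_samples
    for i in range(n):
        for j in range(i + 1, n):
            if shared[i, j] < min_shared:
                raise ValueError(
                    f"pair ({gm.samples[i]},{gm.samples[j]}): only "
                    f"{int(shared[i, j])} shared SNPs (< {min_shared})"
                )
            d = denom[i, j]
            phi = float("nan") if d == 0 else float((n_hh[i, j] - 2 * n_opp[i, j]) / d)
            rows.append((gm.samples[i], gm.samples[j], phi))
    return pd.DataFrame(rows, columns=["id_i", "id_j", "phi"])


def prune_relatives(gm: GenotypeMatrix, cutoff: float = 0.176, min_shared: int = 100) -> KinshipResult:
    """Greedy relative pruning at the first-degree cutoff (default 0.176).

    Iteratively drops the sample involved in the most above-cutoff pairs
    (ties: the higher sample index) until no pair exceeds the cutoff.
    """
    pairs = king_kinship_matrix(gm, min_shared=min_shared)
    idx = {s: k for k, s in enumerate(gm.samples)}
    active = set(gm.samples)
    over = pairs[pairs["phi"] > cutoff]
    edges = {(r.id_i, r.id_j) for r in over.itertuples()}
    while edges:
        deg: dict[str, int] = {}
        for a, b in edges:
            deg[a] = deg.get(a, 0) + 1
            deg[b] = deg.get(b, 0) + 1
        drop = max(deg, key=lambda s: (deg[s], idx[s]))
        active.discard(drop)
        edges = {(a, b) for a, b in edges if a != drop and b != drop}
    kept = [s for s in gm.samples if s in active]
    return KinshipResult(pairs=pairs, kept=kept, cutoff=cutoff)
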