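"""End-to-end orchestration: QC -> prune -> trend/drift -> scan ->
inbreeding -> structure/Ne, from one YAML/dict config to a report bundle.

The report is a single JSON document (plus TSV side files) containing the
trend table, drift-null p-values per model, the F_ST scan summary with the
top SNP's distance to the focal locus, EHH curves when phased haplotypes
are supplied, Ho and F_ROH group summaries with Welch tests, PCA
coordinates, the NJ tree in Newick, Nei's D between groups, and LD-based
Ne per group.  All randomness is funnelled through one root seed expanded
with fixed per-stage offsets, so the same config always yields a
byte-identical report.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io, roh, scan, structure, trend

log = logging.getLogger("selectwatch")

REPORT_SCHEMA_VERSION = 1

STAGE_SEED_OFFSETS = {"drift": 101, "ld_ne": 202, "fisher": 303}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def validate_config(cfg: dict) -> None:
    for key in ("ped", "map", "meta", "out_dir"):
        if key not in cfg:
            raise ValueError(f"config missing required key {key!r}")
    for key in ("ped", "map", "meta"):
        if not Path(cfg[key]).exists():
            raise ValueError(f"config file path {key}={cfg[key]!r} does not exist")
    fst_cfg = cfg.get("fst", {})
    ga, gb = fst_cfg.get("group_a", []), fst_cfg.get("group_b", [])
    if fst_cfg and (not ga or not gb):
        raise ValueError("fst config needs non-empty group_a and group_b")
    if set(ga) & set(gb):
        raise ValueError("fst group_a and group_b overlap")


def _round_floats(obj, nd=10):
    if isinstance(obj, float):
        return round(obj, nd)
    if isinstance(obj, dict):
        return {k: _round_floats(v, nd) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, nd) for v in obj]
    if isinstance(obj, (np.floating,)):
        return round(float(obj), nd)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def run_pipeline(cfg: dict) -> dict:
    """Run every configured stage in fixed order; return the report dict.

    A stage failure raises :class:`PipelineError` naming the stage;
    partial outputs already written to ``out_dir`` are left in place.
    """
    validate_config(cfg)
    out_dir = Path(cfg["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", trend.DEFAULT_SEED))
    qc_cfg = cfg.get("qc", {})
    report: dict = {"schema_version": REPORT_SCHEMA_VERSION, "stages": []}

    def stage(name):
        log.info("stage: %s", name)
        report["stages"].append(name)

    # ---- load + QC + prune
    try:
        stage("load")
        gm, _fam = io.read_ped_map(cfg["ped"], cfg["map"])
        cohort = io.read_metadata(cfg["meta"])
        report["counts"] = {"samples_in": gm.n_samples, "snps_in": gm.n_snps}

        stage("qc")
        qrep = io.QCReport()
        gm = io.qc_filter(
            gm,
            geno_max=float(qc_cfg.get("geno", 0.01)),
            mind_max=float(qc_cfg.get("mind", 0.01)),
            maf_min=float(qc_cfg.get("maf", 0.01)),
            report=qrep,
        )
        report["qc_stages"] = qrep.stages

        stage("prune_relatives")
        kin = io.prune_relatives(gm, cutoff=float(qc_cfg.get("king_cutoff", 0.176)),
                                 min_shared=int(qc_cfg.get("king_min_shared", 100)))
        gm = gm.subset(sample_ids=kin.kept)
        report["counts"]["samples_kept"] = gm.n_samples
        report["counts"]["snps_kept"] = gm.n_snps
        cohort_df = cohort.df[cohort.df["id"].isin(gm.samples)].reset_index(drop=True)
    except PipelineError:
        raise
    except Exception as e:  # noqa: BLE001 - report the failing stage
        raise PipelineError(report["stages"][-1], e) from e

    # ---- trend + drift
    try:
        stage("trend")
        tt = trend.build_trend(io.CohortTable(cohort_df))
        tt.to_csv(out_dir / "trend.tsv", sep="\t", index=False)
        report["trend"] = _round_floats(tt.to_dict(orient="records"))

        stage("drift")
        drift_out = []
        for mi, m in enumerate(cfg.get("drift_models", [])):
            q0 = float(m["q_start"])
            model = trend.DriftModel(
                ne=int(m["ne"]), q_start=q0,
                male_fraction=float(m.get("male_fraction", 0.2)),
                generations=int(m.get("generations", 6)),
                replicates=int(m.get("replicates", 10_000)),
                seed=seed + STAGE_SEED_OFFSETS["drift"] + mi,
            )
            res = trend.simulate_drift(model)
            obs = m.get("observed", {})  # {generation: observed_q}
            pvals = {str(g): trend.empirical_p(res, float(q), int(g)) for g, q in obs.items()}
            drift_out.append({
                "ne": model.ne, "ne_eff": model.ne_eff, "q_start": q0,
                "male_fraction": model.male_fraction,
                "p_lower_tail": pvals,
                "quantiles": _round_floats(res.quantiles().to_dict(orient="records")),
            })
        report["drift"] = drift_out
    except Exception as e:  # noqa: BLE001
        raise PipelineError(report["stages"][-1], e) from e

    # ---- selection scan
    fst_cfg = cfg.get("fst")
    if fst_cfg:
        try:
            stage("fst")
            ga = cohort_df[cohort_df["group"].isin(fst_cfg["group_a"])]["id"].tolist()
            gb = cohort_df[cohort_df["group"].isin(fst_cfg["group_b"])]["id"].tolist()
            if not ga or not gb:
                raise ValueError("empty F_ST group after QC/pruning")
            fst = scan.wc_fst(gm, ga, gb)
            ranked = scan.rank_scan(fst, top_fraction=float(fst_cfg.get("top_fraction", 0.001)))
            ranked.to_csv(out_dir / "fst.tsv", sep="\t", index=False)
            top = ranked.iloc[0]
            entry = {
                "n_snps": int(np.isfinite(fst["fst"]).sum()),
                "n_flagged": int(ranked["flagged"].sum()),
                "top_snp": {"id": str(top["id"]), "chrom": str(top["chrom"]),
                            "pos_bp": int(top["pos_bp"]), "fst": round(float(top["fst"]), 10)},
            }
            focal = cfg.get("focal")
            if focal:
                if str(top["chrom"]) == str(focal["chrom"]):
                    entry["top_snp"]["distance_to_focal_bp"] = abs(int(top["pos_bp"]) - int(focal["pos_bp"]))
                else:
                    entry["top_snp"]["distance_to_focal_bp"] = None
            report["fst"] = entry
        except Exception as e:  # noqa: BLE001
            raise PipelineError("fst", e) from e

    # ---- EHH (needs phased haplotypes)
    if cfg.get("haps") and cfg.get("ehh"):
        try:
            stage("ehh")
            haps = scan.read_haps(cfg["haps"], gm.markers) if Path(cfg["haps"]).exists() else None
            ecfg = cfg["ehh"]
            curves = {}
            for grp in ecfg["groups"]:
                ids = set(cohort_df[cohort_df["group"] == grp]["id"])
                keep = [k for k, lab in enumerate(haps.labels) if lab.rsplit("_h", 1)[0] in ids]
                sub = scan.HaplotypeSet(haps.markers, haps.haps[keep], [haps.labels[k] for k in keep])
                curve = scan.ehh(sub, ecfg["core_snp"], int(ecfg["core_allele"]),
                                 window_bp=int(ecfg.get("window_bp", 1_000_000)))
                curve.to_csv(out_dir / f"ehh_{grp}.tsv", sep="\t", index=False)
                curves[grp] = _round_floats(curve.to_dict(orient="records"))
            report["ehh"] = curves
        except Exception as e:  # noqa: BLE001
            raise PipelineError("ehh", e) from e

    # ---- inbreeding
    try:
        stage("inbreeding")
        params = roh.RohParams(**cfg.get("roh", {}))
        runs = roh.detect_roh_all(gm, params)
        runs.to_csv(out_dir / "roh.tsv", sep="\t", index=False)
        span = roh.genome_span(gm)
        froh = roh.f_roh(runs, span, gm.samples)
        summary, welch = roh.group_summary(froh, cohort_df)
        ho = {g: roh.observed_het(gm, cohort_df[cohort_df["group"] == g]["id"].tolist())
              for g in sorted(cohort_df["group"].unique())}
        report["inbreeding"] = {
            "genome_span_bp": span,
            "ho_by_group": _round_floats(ho),
            "f_roh_summary": _round_floats(summary.to_dict(orient="records")),
            "welch_tests": _round_floats(welch.to_dict(orient="records")),
        }
    except Exception as e:  # noqa: BLE001
        raise PipelineError("inbreeding", e) from e

    # ---- structure + Ne
    try:
        stage("structure")
        coords, explained = structure.pca(gm)
        coords.to_csv(out_dir / "pca.tsv", sep="\t", index=False)
        dm = structure.p_distance_matrix(gm)
        tree = structure.nj_tree(dm)
        (out_dir / "tree.nwk").write_text(tree + "\n")
        groups = sorted(cohort_df["group"].unique())
        nd = {}
        for i, gi in enumerate(groups):
            for gj in groups[i + 1:]:
                nd[f"{gi}|{gj}"] = structure.neis_d_from_genotypes(
                    gm,
                    cohort_df[cohort_df["group"] == gi]["id"].tolist(),
                    cohort_df[cohort_df["group"] == gj]["id"].tolist(),
                )
        ne_out = {}
        for g in groups:
            ids = cohort_df[cohort_df["group"] == g]["id"].tolist()
            if len(ids) >= 10:
                est = structure.ld_ne(gm, ids, maf_floor=float(cfg.get("ne_maf_floor", 0.01)),
                                      seed=seed + STAGE_SEED_OFFSETS["ld_ne"], group=g)
                ne_out[g] = {
                    "s": est.s, "n_pairs": est.n_pairs,
                    "mean_r2": est.mean_r2, "r2_drift": est.r2_drift,
                    "ne_hat": est.ne_hat if np.isfinite(est.ne_hat) else "inf",
                    "ci": [c if np.isfinite(c) else "inf" for c in est.ci],
                }
        report["structure"] = {
            "pca_explained": _round_floats(list(explained)),
            "nj_newick": tree,
            "neis_d": _round_floats(nd),
            "ld_ne": _round_floats(ne_out),
        }
    except Exception as e:  # noqa: BLE001
        raise PipelineError("structure", e) from e

    report = _round_floats(report)
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report


def run_pipeline_file(config_path) -> dict:
    return run_pipeline(load_config(config_path))
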