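"""End-to-end pipeline orchestration driven by a single config mapping.

Stages: simulate (or load inputs) -> qc -> gwas (base cohort) -> harmonize ->
clump -> threshold scan -> best-threshold association -> pathway enrichment.
Every numeric output file starts with comment lines recording the package
version, a config hash and the master seed; the run report collects
per-stage record counts, parameters, seeds and wall-clock. One master seed;
per-stage streams are derived deterministically, so toggling a stage never
shifts another stage's draws.
"""

from __future__ import annotations

import hashlib
import json
import time
import zlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, assoc, dataio, pathway, prscore, qc, synthdata

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "outdir": "prsoverlap_out",
    "simulate": {"enabled": True},  # extra keys: SimulationConfig fields
    "qc": {"enabled": True, "snp_call_rate": 0.95, "sample_call_rate": 0.95,
           "hwe": 1e-6, "maf": 0.01, "het_sd": 3.0},
    "gwas": {"enabled": True, "covariates": []},
    "prs": {"r2": 0.1, "window_kb": 250, "start": 1e-4, "step": 5e-5, "stop": 0.5,
            "mode": "clump_by_p", "strict_palindromic": False},
    "pathway": {"enabled": True, "n_perm": 2000, "flank_bp": 2000,
                "n_genes": 100, "n_sets": 20, "set_size": 10,
                "snp_scope": "best_threshold"},
    "inputs": {},  # sumstats/vcf/pheno/genes/sets paths when not simulating
}


class StageError(RuntimeError):
    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}/{code}] {message}")
        self.stage = stage
        self.code = code


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path) -> dict:
    with open(path) as fh:
        return _merge(DEFAULT_CONFIG, yaml.safe_load(fh) or {})


def config_hash(config: dict) -> str:
    """Fingerprint of the analysis parameters (output location excluded, so
    the same analysis written elsewhere hashes identically)."""
    cfg = {k: v for k, v in config.items() if k != "outdir"}
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def stage_seed(master: int, stage: str) -> int:
    return int(
        np.random.SeedSequence([int(master), zlib.crc32(stage.encode())])
        .generate_state(1)[0] % (2**31)
    )


def run_pipeline(config: dict) -> dict:
    """Execute the configured stages and return the run report (also written
    to ``outdir/report.json``)."""
    cfg = _merge(DEFAULT_CONFIG, config)
    t0 = time.time()
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    chash = config_hash(cfg)
    header = [f"prsoverlap_version={__version__}", f"config_hash={chash}", f"seed={seed}"]
    report: dict = {"version": __version__, "config_hash": chash, "seed": seed,
                    "stages": {}, "parameters": cfg}

    # ---- inputs: simulate or load -------------------------------------
    truth = None
    if cfg["simulate"]["enabled"]:
        sim_kwargs = {k: v for k, v in cfg["simulate"].items() if k != "enabled"}
        if isinstance(sim_kwargs.get("maf_range"), list):
            sim_kwargs["maf_range"] = tuple(sim_kwargs["maf_range"])
        sim_cfg = synthdata.SimulationConfig(seed=stage_seed(seed, "simulate"), **sim_kwargs)
        cohorts = synthdata.simulate_cohorts(sim_cfg)
        base_g, target_g = cohorts.base, cohorts.target
        pheno_base, pheno_target = cohorts.pheno_base, cohorts.pheno_target
        truth = cohorts.effects
        dataio.write_vcf_genotypes(base_g, outdir / "base.vcf", extra_header=header)
        dataio.write_vcf_genotypes(target_g, outdir / "target.vcf", extra_header=header)
        dataio.write_phenotypes(pheno_base, outdir / "pheno_base.tsv", header)
        dataio.write_phenotypes(pheno_target, outdir / "pheno_target.tsv", header)
        truth_df = pd.DataFrame({
            "snp_id": base_g.snps["id"],
            "beta_base": truth.beta_base,
            "beta_target": truth.beta_target,
        })
        dataio.write_phenotypes(truth_df, outdir / "truth.tsv", header)
        report["stages"]["simulate"] = {
            "n_snps": base_g.n_snps, "n_base": base_g.n_samples,
            "n_target": target_g.n_samples,
            "n_causal_base": len(truth.causal_base),
            "n_causal_target": len(truth.causal_target),
            "n_shared_causal": truth.n_shared,
            "seed": sim_cfg.seed,
        }
        sumstats = None
    else:
        inputs = cfg["inputs"]
        try:
            target_g = dataio.read_vcf_genotypes(inputs["vcf"])
            pheno_target = dataio.read_phenotypes(inputs["pheno"])
            sumstats = dataio.read_summary_stats(inputs["sumstats"])
            base_g = pheno_base = None
        except KeyError as exc:
            raise StageError("inputs", "E_INPUT", f"missing input path {exc}") from exc
        except (OSError, ValueError) as exc:
            raise StageError("inputs", "E_INPUT", str(exc)) from exc
        if "status" not in pheno_target.columns and "nrs" in pheno_target.columns:
            pheno_target = pheno_target.copy()
            pheno_target["status"] = [
                assoc.dichotomize_phenotype(v) for v in pheno_target["nrs"]
            ]

    # ---- qc -----------------------------------------------------------
    if cfg["qc"]["enabled"]:
        params = qc.QcParams(
            snp_call_rate=cfg["qc"]["snp_call_rate"],
            sample_call_rate=cfg["qc"]["sample_call_rate"],
            hwe_alpha=cfg["qc"]["hwe"], maf=cfg["qc"]["maf"],
            het_sd=cfg["qc"]["het_sd"],
        )
        stage_rep = {}
        if base_g is not None:
            n0s, n0n = base_g.n_snps, base_g.n_samples
            base_g, rep_b = qc.run_qc(base_g, params)
            stage_rep["base"] = {
                "snps_removed": rep_b.n_removed_snps,
                "samples_removed": rep_b.n_removed_samples,
                "snps_in": n0s, "samples_in": n0n,
            }
        n0s, n0n = target_g.n_snps, target_g.n_samples
        target_g, rep_t = qc.run_qc(target_g, params)
        stage_rep["target"] = {
            "snps_removed": rep_t.n_removed_snps,
            "samples_removed": rep_t.n_removed_samples,
            "snps_in": n0s, "samples_in": n0n,
            "by_rule_snps": {k: len(v) for k, v in rep_t.removed_snps_by_rule.items()},
            "by_rule_samples": {k: len(v) for k, v in rep_t.removed_samples_by_rule.items()},
        }
        rows = [(r, "snp", i) for r, ids in rep_t.removed_snps_by_rule.items() for i in ids]
        rows += [(r, "sample", i) for r, ids in rep_t.removed_samples_by_rule.items() for i in ids]
        dataio.write_phenotypes(
            pd.DataFrame(rows, columns=["rule", "kind", "id"]),
            outdir / "qc_report.tsv", header,
        )
        report["stages"]["qc"] = stage_rep

    # ---- base GWAS ----------------------------------------------------
    if cfg["gwas"]["enabled"] and base_g is not None:
        try:
            sumstats = assoc.gwas(base_g, pheno_base,
                                  covariates=cfg["gwas"]["covariates"] or None)
        except ValueError as exc:
            raise StageError("gwas", "E_STAGE", str(exc)) from exc
        dataio.write_summary_stats(sumstats, outdir / "sumstats.tsv", header)
        report["stages"]["gwas"] = {
            "n_tested": sumstats.attrs["n_tested"],
            "n_monomorphic": sumstats.attrs["n_monomorphic"],
        }
    if sumstats is None:
        raise StageError("gwas", "E_INPUT", "no summary statistics available")

    # ---- C+T scan -----------------------------------------------------
    p = cfg["prs"]
    prune = prscore.PruneConfig(r2_threshold=p["r2"], window_bp=int(p["window_kb"] * 1000),
                                mode=p["mode"])
    grid = prscore.threshold_grid(p["start"], p["step"], p["stop"])
    try:
        harm = prscore.harmonize(sumstats, target_g,
                                 strict_palindromic=p["strict_palindromic"])
        clumped = prscore.clump(harm, target_g, prune)
        scan = prscore.scan_clumped(harm, clumped, target_g, pheno_target, grid=grid)
    except ValueError as exc:
        raise StageError("prs", "E_STAGE", str(exc)) from exc
    scan_df = scan.to_frame()
    dataio.write_phenotypes(scan_df, outdir / "scan.tsv", header)
    best_ids = scan.best_snp_ids()
    best_rows = harm.set_index("snp_id").loc[best_ids]
    prs_best = prscore.compute_prs(
        target_g, harm,
        np.flatnonzero(harm["snp_id"].isin(best_ids).to_numpy()),
        threshold=scan.best_threshold,
    )
    dataio.write_phenotypes(
        pd.DataFrame({"sample_id": prs_best.sample_ids, "prs": prs_best.score,
                      "m_alleles": prs_best.m_alleles}),
        outdir / "prs_best.tsv", header,
    )
    report["stages"]["prs"] = {
        "n_harmonized": len(harm), "n_clumped": int(len(clumped)),
        "harmonize_drops": harm.attrs.get("drops", {}),
        "best_threshold": scan.best_threshold, "best_r2": scan.best_r2,
        "best_p": scan.best_p, "n_snps_best": scan.best_n_snps,
    }

    # ---- pathway ------------------------------------------------------
    if cfg["pathway"]["enabled"]:
        pw = cfg["pathway"]
        scope_ids = best_ids if pw["snp_scope"] == "best_threshold" \
            else [harm["snp_id"].iloc[i] for i in clumped]
        scope = sumstats[sumstats["snp_id"].isin(scope_ids)]
        if "genes" in cfg["inputs"]:
            genes = dataio.read_bed_genes(cfg["inputs"]["genes"])
            sets = dataio.read_gmt(cfg["inputs"]["sets"])
        else:
            span = int(target_g.snps["pos"].max()) + 1000
            causal_pos = causal_w = None
            if truth is not None and len(truth.causal_target):
                causal_pos = target_g.snps["pos"].to_numpy()[truth.causal_target]
                causal_w = truth.beta_target[truth.causal_target]
            try:
                ann = synthdata.simulate_gene_annotation(
                    pw["n_genes"], span, seed=stage_seed(seed, "genes"),
                    n_sets=pw["n_sets"], set_size=pw["set_size"],
                    causal_positions=causal_pos, causal_weights=causal_w,
                    enriched=causal_pos is not None,
                )
            except ValueError:  # too few causal genes for an enriched set
                ann = synthdata.simulate_gene_annotation(
                    pw["n_genes"], span, seed=stage_seed(seed, "genes"),
                    n_sets=pw["n_sets"], set_size=pw["set_size"],
                    causal_positions=causal_pos, enriched=False,
                )
            genes, sets = ann.genes, ann.sets
            dataio.write_bed_genes(genes, outdir / "genes.bed")
            dataio.write_gmt(sets, outdir / "sets.gmt")
        try:
            scores = pathway.score_genes(scope, genes, flank_bp=pw["flank_bp"])
            enr = pathway.pathway_analysis(
                scores, sets, n_perm=pw["n_perm"], seed=stage_seed(seed, "pathway"),
            )
        except ValueError as exc:
            raise StageError("pathway", "E_STAGE", str(exc)) from exc
        dataio.write_phenotypes(enr, outdir / "enrichment.tsv", header)
        report["stages"]["pathway"] = {
            "n_scope_snps": len(scope), "n_scored_genes": len(scores),
            "n_sets": len(enr),
            "top_set": enr.sort_values(["p", "set"]).iloc[0]["set"] if len(enr) else None,
        }

    report["wall_clock_s"] = round(time.time() - t0, 3)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report
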