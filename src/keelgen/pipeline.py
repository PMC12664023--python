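"""End-to-end orchestration: genotypes + scores in, annotated blocks out.

``run_full`` chains the whole analysis: sample filtering, shifted-log
transform, SNP QC, GRM + PCA diagnostics, single-GRM REML on both trait
scales, additive+dominance GWAS with empirical inflation correction, LD
pruning and Bonferroni/suggestive thresholds, hit selection on the
CORRECTED -log10(p), haplotype blocks, the two-GRM variance partition,
and (given an interval table) block-to-gene annotation.  Every stage
writes its output under ``out_dir`` and the run ends with a manifest of
SHA-256 checksums plus the echoed config, so identical configs and
seeds produce identical manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from keelgen import annotate as annotate_mod
from keelgen import dataio, gwas as gwas_mod, ldblocks, pheno, qc as qc_mod
from keelgen.grm import compute_grm, pca
from keelgen.simulate import SimConfig, simulate_genotypes, simulate_phenotypes
from keelgen.varcomp import fit_reml_single, fit_reml_two_grm

__all__ = ["PipelineConfig", "run_full"]

logger = logging.getLogger("keelgen")


@dataclasses.dataclass
class PipelineConfig:
    """All knobs of the full analysis; defaults are the standard settings.

    Either point ``ped_path``/``map_path``/``sample_path`` at input files
    or leave them None to analyze a synthetic cohort drawn from
    ``sim`` (a :class:`SimConfig`).
    """

    out_dir: str = "keelgen_run"
    ped_path: str | None = None
    map_path: str | None = None
    sample_path: str | None = None
    intervals_path: str | None = None
    intervals_format: str = "BED"
    sim: SimConfig | None = None

    log_offset: float = pheno.LOG_OFFSET
    maf_min: float = 0.02
    call_rate_min: float = 0.90
    sex_labels: tuple[str, ...] = ("Z", "W")

    variance_keep: float = 0.99
    inflation_cutoff: float = 3.0
    inflation_intercept: bool = False

    prune_window_kb: float = 500.0
    prune_step_snps: int = 10
    prune_r2_max: float = 0.2

    block_max_kb: float = 5000.0
    block_ci_low: float = 0.60
    block_ci_high: float = 0.90
    block_strong_frac: float = 0.95

    alpha_genomewide: float = 0.05
    alpha_suggestive: float = 0.10
    flank_bp: int = 50_000
    n_pcs_report: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        for name, lo, hi in (
            ("maf_min", 0.0, 0.5),
            ("call_rate_min", 0.0, 1.0),
            ("variance_keep", 0.0, 1.0),
            ("prune_r2_max", 0.0, 1.0),
            ("block_ci_low", 0.0, 1.0),
            ("block_ci_high", 0.0, 1.0),
            ("block_strong_frac", 0.0, 1.0),
            ("alpha_genomewide", 0.0, 1.0),
            ("alpha_suggestive", 0.0, 1.0),
        ):
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        if self.flank_bp < 0 or self.log_offset <= 0:
            raise ValueError("flank_bp must be >= 0 and log_offset > 0")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=2, default=str)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text())
        if data.get("sim") is not None:
            sim = dict(data["sim"])
            if "founder_freq_model" in sim:
                sim["founder_freq_model"] = tuple(tuple(x) for x in sim["founder_freq_model"])
            data["sim"] = SimConfig(**sim)
        if "sex_labels" in data:
            data["sex_labels"] = tuple(data["sex_labels"])
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_full(config: PipelineConfig) -> dict:
    """Run every stage; returns a result bundle and writes a manifest.

    Any stage failure raises with the stage name; outputs of completed
    stages remain on disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    bundle: dict = {}
    stage = "setup"

    def emit(name: str, text: str) -> Path:
        p = out / name
        p.write_text(text)
        written.append(p)
        return p

    try:
        # ---- inputs -------------------------------------------------
        stage = "load_inputs"
        if config.ped_path and config.map_path and config.sample_path:
            geno = dataio.read_plink_text(config.ped_path, config.map_path)
            samples = dataio.read_sample_table(config.sample_path)
        else:
            sim = config.sim if config.sim is not None else SimConfig(seed=config.seed)
            geno, pedigree = simulate_genotypes(sim)
            samples, truth = simulate_phenotypes(geno, pedigree, sim)
            bundle["sim_truth"] = truth
            emit("sim_truth.json", truth.to_json())

        # ---- stage 1: sample filtering -------------------------------
        stage = "sample_filtering"
        samples = samples.copy()
        has_factors = samples["pen"].notna() & samples["rearing_pen"].notna()
        genotyped = samples["sample_id"].astype(str).isin(set(geno.sample_ids))
        kept = samples[has_factors & genotyped].reset_index(drop=True)
        id_order = {s: i for i, s in enumerate(kept["sample_id"].astype(str))}
        keep_idx = [i for i, s in enumerate(geno.sample_ids) if s in id_order]
        geno = geno.subset_individuals(np.array(keep_idx, dtype=int))
        kept = kept.set_index(kept["sample_id"].astype(str)).loc[list(geno.sample_ids)].reset_index(drop=True)
        logger.info("samples retained: %d of %d", len(kept), len(samples))
        emit("samples_filtered.tsv", kept.to_csv(sep="\t", index=False))

        # ---- stage 2: log transform ----------------------------------
        stage = "log_transform"
        kept = pheno.log_transform(kept, offset=config.log_offset)
        summary = {
            "kbf_score": dataclasses.asdict(pheno.describe(kept["kbf_score"])),
            "log_kbf": dataclasses.asdict(pheno.describe(kept["log_kbf"])),
        }
        emit("trait_summary.json", json.dumps(summary, indent=2))
        emit("samples_transformed.tsv", kept.to_csv(sep="\t", index=False))

        # ---- stage 3: SNP QC ------------------------------------------
        stage = "snp_qc"
        geno, qc_report = qc_mod.apply_qc(
            geno, maf_min=config.maf_min, call_rate_min=config.call_rate_min,
            sex_labels=set(config.sex_labels),
        )
        for line in qc_report.log_lines():
            logger.info("%s", line)
        emit("qc_report.json", qc_report.to_json())

        # ---- stage 4: GRM + PCA ----------------------------------------
        stage = "grm"
        grm = compute_grm(geno)
        pcs = pca(grm, k=min(config.n_pcs_report, grm.n))
        diag = np.diag(grm.matrix)
        off = grm.matrix[np.triu_indices(grm.n, k=1)]
        grm_diag = {
            "diag_min": float(diag.min()), "diag_max": float(diag.max()),
            "diag_mean": float(diag.mean()),
            "offdiag_min": float(off.min()), "offdiag_max": float(off.max()),
            "offdiag_mean": float(off.mean()),
            "frac_offdiag_ge_0.1": float((off >= 0.1).mean()),
            "frac_offdiag_ge_0.3": float((off >= 0.3).mean()),
            "pc_variance_fractions": pcs.variance_fraction.tolist(),
        }
        grm.save(out / "grm")
        written += [out / "grm.grm.npy", out / "grm.grm.json"]
        emit("grm_diagnostics.json", json.dumps(grm_diag, indent=2))
        bundle.update(grm=grm, grm_diagnostics=grm_diag)

        # ---- stage 5: single-GRM REML, both scales ---------------------
        stage = "reml"
        # pen and rearing pen enter as dummy factors; redundant columns are
        # dropped inside the REML fitter
        X = pd.get_dummies(kept[["pen", "rearing_pen"]].astype(str), drop_first=True, dtype=float).to_numpy()
        fit_raw = fit_reml_single(kept["kbf_score"].to_numpy(), X, grm)
        fit_log = fit_reml_single(kept["log_kbf"].to_numpy(), X, grm)
        emit("reml_raw.json", fit_raw.to_json())
        emit("reml_log.json", fit_log.to_json())
        bundle.update(reml_raw=fit_raw, reml_log=fit_log)

        # ---- stage 6: GWAS + inflation correction ----------------------
        stage = "gwas"
        covs = gwas_mod.build_covariates(kept, variance_keep=config.variance_keep)
        results = gwas_mod.run_gwas(geno, kept, covs, trait="log_kbf")
        results, infl_add = gwas_mod.correct_inflation(
            results, "additive", cutoff=config.inflation_cutoff, intercept=config.inflation_intercept
        )
        results, infl_dom = gwas_mod.correct_inflation(
            results, "dominance", cutoff=config.inflation_cutoff, intercept=config.inflation_intercept
        )
        emit("inflation.json", json.dumps({
            "additive": dataclasses.asdict(infl_add), "dominance": dataclasses.asdict(infl_dom)
        }, indent=2))
        emit("gwas.tsv", results.to_csv(sep="\t", index=False))
        bundle.update(gwas=results, inflation=(infl_add, infl_dom))

        # ---- stage 7: pruning + thresholds ------------------------------
        stage = "pruning"
        prune_in = ldblocks.ld_prune(
            geno, window_kb=config.prune_window_kb, step_snps=config.prune_step_snps,
            r2_max=config.prune_r2_max,
        )
        thr_gw, thr_sugg = gwas_mod.significance_thresholds(
            len(prune_in), config.alpha_genomewide, config.alpha_suggestive
        )
        emit("prune.in", "\n".join(prune_in) + "\n")
        emit("thresholds.json", json.dumps({
            "m_independent": len(prune_in),
            "genomewide": thr_gw, "suggestive": thr_sugg,
        }, indent=2))
        bundle.update(m_independent=len(prune_in), thresholds=(thr_gw, thr_sugg))

        # ---- stage 8: hit selection (corrected p) -----------------------
        stage = "hit_selection"
        pc = results["p_add_corr"]
        hits = results[(pc < thr_sugg) & results["flag"].eq("")].copy()
        hits["significant"] = pc[hits.index] < thr_gw
        emit("hits.tsv", hits.to_csv(sep="\t", index=False))
        bundle["hits"] = hits

        # ---- stage 9: haplotype blocks ----------------------------------
        stage = "blocks"
        hit_chroms = sorted(hits["chrom"].astype(str).unique())
        sub = geno.subset_snps(geno.snp_info["chrom"].astype(str).isin(hit_chroms).to_numpy()) if hit_chroms else None
        blocks = ldblocks.find_blocks(
            sub, max_kb=config.block_max_kb, ci_low_min=config.block_ci_low,
            ci_high_min=config.block_ci_high, strong_frac=config.block_strong_frac,
        ) if sub is not None and sub.n_snps >= 2 else []
        block_table, union_n = ldblocks.assign_hits_to_blocks(hits, blocks)
        emit("blocks.tsv", block_table.to_csv(sep="\t", index=False))
        bundle.update(blocks=blocks, block_table=block_table, block_union_snps=union_n)

        # ---- stage 10: two-GRM variance partition ------------------------
        stage = "partition"
        if len(block_table):
            in_block = set()
            for ids in block_table["snp_ids"]:
                in_block.update(str(ids).split(","))
            mask = geno.snp_info["snp_id"].isin(in_block).to_numpy()
            partition: dict = {"n_block_snps": int(mask.sum()), "n_rest_snps": int((~mask).sum())}
            if mask.sum() >= 1 and (~mask).sum() >= 2:
                g1 = compute_grm(geno.subset_snps(mask))
                g0 = compute_grm(geno.subset_snps(~mask))
                fit2 = fit_reml_two_grm(kept["log_kbf"].to_numpy(), X, g1, g0)
                partition.update(json.loads(fit2.to_json()))
                bundle["partition_fit"] = fit2
        else:
            partition = {"n_block_snps": 0, "note": "no suggestive hits; partition skipped"}
        emit("partition.json", json.dumps(partition, indent=2))

        # ---- stage 11: annotation ----------------------------------------
        stage = "annotation"
        if config.intervals_path:
            intervals = dataio.read_intervals(config.intervals_path, config.intervals_format)
            labeled = [
                ldblocks.HaplotypeBlock(chrom=r.chrom, start=int(r.start), stop=int(r.stop),
                                        snp_ids=str(r.snp_ids).split(","), label=r.block)
                for r in block_table.itertuples(index=False)
            ]
            overlaps = annotate_mod.genes_near_blocks(labeled, intervals, flank_bp=config.flank_bp)
            emit("annotation.tsv", annotate_mod.overlaps_to_frame(overlaps).to_csv(sep="\t", index=False))
            bundle["annotation"] = overlaps
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "config": json.loads(config.to_json()),
        "outputs": {p.name: _sha256(p) for p in sorted(written)},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    bundle["manifest"] = manifest
    bundle["out_dir"] = out
    return bundle
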