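"""End-to-end orchestration: configuration, genotype I/O, stage wiring.

The pipeline runs growth-curve fitting, the mixed-model association scan,
and then the four adaptation analyses (differentiation, polygenic scores /
Qx, Qst-vs-Fst, GO enrichment) in order, writing every stage table plus a
JSON report.  A single global seed is expanded into per-stage seeds with
``numpy.random.SeedSequence([seed, stage_index])`` so an individual stage
can be re-run reproducibly.  All coordinates are 1-based inclusive
(VCF/GFF3 convention), including the vcftools ``.pos`` companion file.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import goenrich, growthfit, mixedassoc, polyscore, popdiff, qstfst, synthio
from .containers import GenotypeMatrix

log = logging.getLogger(__name__)

STAGES = ("simulate", "growth", "assoc", "diff", "polyadapt", "qst", "enrich")


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage 31-bit seed derived from the global seed."""
    ss = np.random.SeedSequence([int(seed), STAGES.index(stage)])
    return int(ss.generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """All paths, thresholds and resampling counts of one run.

    Thresholds default to the study's values: 5% MAF and missingness
    filters, clump index/secondary p of 1e-4 / 0.01 with a 1 Mb window and
    r2 0.5, 250 kb candidate windows, 10 kb gene proximity, 1000/10000
    resamples.  When no phenotype/genotype paths are given the pipeline
    generates its own synthetic study from ``sim``.
    """

    out_dir: str = "polygrowth_out"
    seed: int = 0
    # inputs (all optional; synthetic generation fills the gaps)
    phenotype_csv: str | None = None
    genotype_path: str | None = None
    genotype_format: str = "012"
    gff3: str | None = None
    go_tsv: str | None = None
    lof_tsv: str | None = None
    regions_csv: str | None = None          # line_id,region
    # thresholds
    maf_min: float = 0.05
    max_missing: float = 0.05
    p_index: float = 1e-4
    p_secondary: float = 0.01
    r2: float = 0.5
    clump_window: float = 1_000_000
    candidate_window: float = 250_000
    gene_window: float = 10_000
    # resampling counts
    n_perm: int = 1000
    n_sims: int = 10_000
    n_random_sets: int = 1000
    n_fst_resamples: int = 10_000
    # synthetic study
    sim: synthio.SimConfig | None = None
    trait_parameter: str = "fs"

    def validate(self) -> None:
        for name, val, lo, hi in (
            ("maf_min", self.maf_min, 0.0, 0.5),
            ("max_missing", self.max_missing, 0.0, 1.0),
            ("p_index", self.p_index, 0.0, 1.0),
            ("p_secondary", self.p_secondary, 0.0, 1.0),
            ("r2", self.r2, 0.0, 1.0),
        ):
            if not lo <= val <= hi:
                raise ValueError(f"{name}={val} outside [{lo}, {hi}]")
        for name in ("n_perm", "n_sims", "n_random_sets", "n_fst_resamples"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for p in (self.phenotype_csv, self.genotype_path, self.gff3,
                  self.go_tsv, self.lof_tsv, self.regions_csv):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("sim", None)
        cfg = cls(**raw)
        if sim is not None:
            gt = sim.pop("growth_truth", None)
            if gt is not None:
                sim["growth_truth"] = synthio.GrowthTruth(**gt)
            for key in ("n_per_region", "region_names", "measurement_days"):
                if key in sim and sim[key] is not None:
                    sim[key] = tuple(sim[key])
            cfg.sim = synthio.SimConfig(**sim)
        return cfg


@dataclass
class RunReport:
    config: dict
    seed: int
    sections: dict = field(default_factory=dict)
    timings: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        def default(o):
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            if isinstance(o, np.ndarray):
                return o.tolist()
            return str(o)

        payload = {
            "seed": self.seed,
            "config": self.config,
            "sections": self.sections,
            "timings_s": self.timings,
        }
        Path(path).write_text(json.dumps(payload, indent=2, default=default))


# ---------------------------------------------------------------------------
# genotype readers
# ---------------------------------------------------------------------------

def read_genotypes(
    path: str, fmt: str = "012", regions: pd.Series | None = None
) -> GenotypeMatrix:
    """Load genotypes from a vcftools 012 trio or a (biallelic-SNP) VCF.

    ``fmt="012"``: ``path`` is the prefix of <prefix>.012 / .012.indv /
    .012.pos; -1 codes are missing.  ``fmt="vcf"``: records that are not
    biallelic SNPs are skipped (count logged).
    """
    if fmt == "012":
        mat = pd.read_csv(f"{path}.012", sep="\t", header=None)
        codes = mat.iloc[:, 1:].to_numpy(dtype=np.int8)
        indv = pd.read_csv(f"{path}.012.indv", header=None)[0].astype(str)
        pos = pd.read_csv(f"{path}.012.pos", sep="\t", header=None)
        if len(indv) != codes.shape[0]:
            raise ValueError(
                f"{path}: .indv lists {len(indv)} lines but matrix has "
                f"{codes.shape[0]} rows"
            )
        if len(pos) != codes.shape[1]:
            raise ValueError(f"{path}: .pos/.012 marker counts disagree")
        chrom = pos[0].to_numpy()
        bp = pos[1].to_numpy(dtype=np.int64)
    elif fmt == "vcf":
        from cyvcf2 import VCF

        vcf = VCF(path, gts012=True)
        indv = pd.Series(vcf.samples, dtype=str)
        rows, chroms, bps = [], [], []
        skipped = 0
        for v in vcf:
            if not v.is_snp or len(v.ALT) != 1:
                skipped += 1
                continue
            g = np.asarray(v.gt_types, dtype=np.int8)
            g[g == 3] = -1
            rows.append(g)
            chroms.append(v.CHROM)
            bps.append(v.POS)
        if skipped:
            log.info("read_genotypes: skipped %d non-biallelic-SNP records", skipped)
        codes = np.vstack(rows).T
        chrom = np.asarray(chroms)
        bp = np.asarray(bps, dtype=np.int64)
    else:
        raise ValueError(f"unknown genotype format {fmt!r}")
    reg = None
    if regions is not None:
        reg = regions.reindex(indv).to_numpy()
    return GenotypeMatrix(
        codes=codes, chrom=chrom, pos=bp, line_ids=indv.to_numpy(), regions=reg
    )


# ---------------------------------------------------------------------------
# the pipeline
# ---------------------------------------------------------------------------

def _synthetic_inputs(config: PipelineConfig):
    sim = config.sim or synthio.SimConfig(seed=stage_seed(config.seed, "simulate"))
    G = synthio.simulate_genotypes(sim)
    pheno, truth = synthio.simulate_trait(G, sim)
    if sim.selection_delta:
        G, truth = synthio.apply_divergent_selection(G, truth, sim)
    truth = synthio.growth_parameter_truth(G, sim, truth)
    series = synthio.simulate_growth_experiment(truth, sim)
    return sim, G, pheno, truth, series


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute every stage and write tables + a JSON report to out_dir."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config={k: str(v) for k, v in vars(config).items()},
                       seed=config.seed)
    t0 = time.time()

    # --- inputs ---------------------------------------------------------
    truth = None
    if config.phenotype_csv is None:
        sim, G, trait_reps, truth, series = _synthetic_inputs(config)
        report.sections["simulate"] = {
            "n_lines": G.n_lines, "n_snps": G.n_markers,
            "fst_target": sim.fst_target, "h2_target": sim.h2,
            "regional_shift": sim.regional_shift,
        }
    else:
        series = growthfit.read_phenotype_csv(config.phenotype_csv)
        regions = None
        if config.regions_csv:
            rtab = pd.read_csv(config.regions_csv)
            regions = rtab.set_index(rtab.columns[0])[rtab.columns[1]]
        G = read_genotypes(config.genotype_path, config.genotype_format, regions)
    report.timings["inputs"] = time.time() - t0

    # --- growth ---------------------------------------------------------
    t = time.time()
    fits = growthfit.fit_all(series, seed=stage_seed(config.seed, "growth"))
    fits.to_csv(out / "growth_fits.csv", index=False)
    param = config.trait_parameter
    means = growthfit.genotypic_means(fits, parameter=param)
    means.to_csv(out / "genotypic_means.csv", index=False)
    h2 = growthfit.broad_sense_h2(fits, parameter=param)
    report.sections["growth"] = {
        "n_plants": len(fits), "n_failed_fits": int((~fits["converged"]).sum()),
        "parameter": param, "broad_sense_h2": h2,
    }
    report.timings["growth"] = time.time() - t

    # --- association ----------------------------------------------------
    t = time.time()
    Gf = mixedassoc.filter_markers(G, config.maf_min, config.max_missing)
    K = mixedassoc.compute_kinship(Gf)
    y = means.set_index("genotype")["mean"].reindex(Gf.line_ids).to_numpy()
    assoc = mixedassoc.mixed_gwas(y, Gf, K)
    assoc.to_csv(out / "association.tsv", sep="\t", index=False)
    report.sections["assoc"] = {
        "n_markers": len(assoc),
        "pseudo_h2": assoc.attrs["pseudo_h2"],
        "bonferroni": assoc.attrs["bonferroni"],
        "min_p": float(assoc["p"].min()),
        "top_marker": str(assoc.loc[assoc["p"].idxmin(), "marker_id"]),
        "top_effect": float(assoc.loc[assoc["p"].idxmin(), "beta"]),
    }
    report.timings["assoc"] = time.time() - t

    # --- differentiation ------------------------------------------------
    t = time.time()
    regions_arr = Gf.regions
    if regions_arr is None:
        raise ValueError(
            "region labels are required for the differentiation and Qst "
            "stages; provide regions_csv (line_id,region)"
        )
    pops = tuple(pd.unique(regions_arr))[:2]
    fst = popdiff.per_snp_fst(Gf, pops)
    popdiff.write_fst_tsv(fst, out / "fst.tsv")
    fst95 = float(np.nanpercentile(fst["fst"], 95))
    hit_ids = assoc.loc[assoc["p"] < config.p_index, "marker_id"].to_numpy()
    set_test = None
    if hit_ids.size:
        set_test = popdiff.fst_set_test(
            fst, hit_ids, n_resamples=config.n_fst_resamples,
            seed=stage_seed(config.seed, "diff"),
        )
    mm = means.copy()
    mm["region"] = (
        pd.Series(regions_arr, index=Gf.line_ids)
        .reindex(mm["genotype"]).to_numpy()
    )
    comparison = popdiff.region_compare(mm.dropna(subset=["region"]))
    report.sections["diff"] = {
        "populations": list(map(str, pops)),
        "fst_mean": float(np.nanmean(fst["fst"])),
        "fst95": fst95,
        "n_hits": int(hit_ids.size),
        "set_test": set_test,
        "region_means": comparison.group_means.to_dict(),
        "letters": comparison.letters,
    }
    report.timings["diff"] = time.time() - t

    # --- polygenic scores and Qx ---------------------------------------
    t = time.time()
    seed_pa = stage_seed(config.seed, "polyadapt")
    clump = polyscore.ld_clump(
        assoc, Gf, p_index=config.p_index, window=config.clump_window,
        p_secondary=config.p_secondary, r2=config.r2,
    )
    qx_section: dict = {"n_index_snps": clump.n_index}
    if clump.n_index >= 1:
        markers = clump.index["marker_id"].to_numpy()
        effects = clump.index["beta"].to_numpy()
        freqs = polyscore.unit_frequencies(Gf, markers)
        scores = polyscore.polygenic_score(freqs, effects)
        scores.to_csv(out / "polygenic_scores.tsv", sep="\t")
        F = polyscore.drift_covariance(Gf)
        pool = polyscore.unit_frequencies(Gf, Gf.marker_ids)
        n_null = min(config.n_random_sets, 1000)
        qx = polyscore.qx_test(
            freqs, effects, F, null_freq_pool=pool, n_null=n_null,
            seed=seed_pa,
        )
        qx_section.update(
            qx=qx.qx, df=qx.df, p_chi2=qx.p_chi2, p_empirical=qx.p_empirical
        )
        if Gf.regions is not None and len(np.unique(Gf.regions)) >= 2:
            freqs_reg = polyscore.unit_frequencies(Gf, markers, by_region=True)
            F_reg = polyscore.drift_covariance(Gf, by_region=True)
            pool_reg = polyscore.unit_frequencies(
                Gf, Gf.marker_ids, by_region=True
            )
            qx_reg = polyscore.qx_test(
                freqs_reg, effects, F_reg, null_freq_pool=pool_reg,
                n_null=n_null, seed=seed_pa,
            )
            qx_section.update(
                qx_regions=qx_reg.qx, df_regions=qx_reg.df,
                p_chi2_regions=qx_reg.p_chi2,
                p_empirical_regions=qx_reg.p_empirical,
            )
    trait_reps_df = None
    if truth is not None:
        # replicate-level growth fits serve as phenotype replicates
        trait_reps_df = fits.loc[fits["converged"],
                                 ["genotype", "block", param]].rename(
            columns={"genotype": "line_id", "block": "replicate", param: "value"}
        )
        cv = polyscore.validate_scores(
            trait_reps_df, Gf, K, scheme="replicate_cv",
            p_index=config.p_index, seed=seed_pa,
        )
        qx_section["replicate_cv"] = cv
    report.sections["polyadapt"] = qx_section
    report.timings["polyadapt"] = time.time() - t

    # --- Qst ------------------------------------------------------------
    t = time.time()
    mm2 = mm.dropna(subset=["region"])
    qst = qstfst.estimate_qst(mm2, trait=param)
    qst.fst_percentile_attained = qstfst.qst_vs_fst(qst.qst, fst)["percentile"]
    qst.p_perm = qstfst.qst_permutation(
        mm2, fst95, n_perm=config.n_perm, seed=stage_seed(config.seed, "qst")
    )
    vg = float(mm2.groupby("region")["mean"].transform(lambda s: s - s.mean()).var())
    idx = [list(Gf.line_ids).index(g) for g in mm2["genotype"]]
    mvn = qstfst.qst_mvn_null(
        K[np.ix_(idx, idx)], mm2["region"].to_numpy(), vg,
        n_sims=config.n_sims, seed=stage_seed(config.seed, "qst"),
        observed_qst=qst.qst,
    )
    qst.p_mvn = mvn["p"]
    report.sections["qst"] = {
        "trait": param, "qst": qst.qst, "var_b": qst.var_b, "var_w": qst.var_w,
        "fst_percentile": qst.fst_percentile_attained,
        "p_perm": qst.p_perm, "p_mvn": qst.p_mvn,
        "mvn_percentiles": mvn["percentiles"],
    }
    report.timings["qst"] = time.time() - t

    # --- enrichment -----------------------------------------------------
    t = time.time()
    if config.gff3 and config.go_tsv:
        genes = goenrich.read_gff3_genes(config.gff3)
        ann = goenrich.read_go_annotation(config.go_tsv)
    else:
        genes, ann = _synthetic_annotation(Gf, stage_seed(config.seed, "enrich"))
    scores_tab = goenrich.assign_gene_scores(assoc, genes)
    scores_tab.to_csv(out / "gene_scores.tsv", sep="\t", index=False)
    near = scores_tab.loc[scores_tab["p"] < config.p_index, "gene_id"]
    enrich_section: dict = {"n_candidate_genes": int(len(near))}
    if len(near):
        fisher = goenrich.go_fisher(set(near), set(scores_tab["gene_id"]), ann)
        fisher.to_csv(out / "go_fisher.tsv", sep="\t", index=False)
        enrich_section["min_fisher_p"] = (
            float(fisher["p"].min()) if len(fisher) else None
        )
    report.sections["enrich"] = enrich_section
    report.timings["enrich"] = time.time() - t

    report.timings["total"] = time.time() - t0
    report.to_json(out / "report.json")
    return report


def _synthetic_annotation(G: GenotypeMatrix, seed: int,
                          genes_per_chrom: int = 40, n_terms: int = 12):
    """Random gene intervals and GO annotation over the simulated genome."""
    rng = np.random.default_rng(seed)
    rows = []
    for c in np.unique(G.chrom):
        span = int(G.pos[G.chrom == c].max())
        starts = np.sort(rng.choice(max(span - 5000, genes_per_chrom),
                                    size=genes_per_chrom, replace=False) + 1)
        for i, s in enumerate(starts):
            rows.append({"gene_id": f"G{c}_{i:03d}", "chrom": c,
                         "start": int(s), "end": int(s + rng.integers(1000, 5000))})
    genes = pd.DataFrame(rows)
    ann_rows = []
    for t in range(n_terms):
        members = rng.choice(genes["gene_id"], size=rng.integers(6, 25),
                             replace=False)
        ann_rows.extend({"gene_id": g, "term": f"GO:{t:07d}"} for g in members)
    return genes, pd.DataFrame(ann_rows)
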