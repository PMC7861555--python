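"""Synthetic genotypes, traits, growth experiments and loss-of-function data.

The generator emulates the statistical structure the downstream analysis
assumes: two or more regional populations of fully selfing (homozygous)
lines whose allele frequencies diverge under a Balding-Nichols model, a
polygenic trait with configurable broad-sense heritability and a regional
mean shift, plant-level three-parameter-logistic diameter trajectories
observed with noise under a randomized block/tray design, and a sparse
binary gene x genotype loss-of-function (LOF) matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import MISSING, DiameterSeries, GenotypeMatrix

#: Default measurement schedule (days after sowing) for the high-light
#: regime: roughly bi-weekly checks between day 11 and day 46.
DEFAULT_DAYS_HL = (11, 14, 18, 21, 25, 28, 32, 35, 39, 42, 46)


@dataclass
class GrowthTruth:
    """Population means and genotypic SDs of the logistic growth parameters.

    Defaults describe a high-light rosette: final size ~7.5 cm reached with
    an inflection around day 14-15 and a rate constant of ~0.25/day.
    """

    fs_mean: float = 7.5
    fs_sd: float = 1.0
    slope_mean: float = 0.25
    slope_sd: float = 0.04
    t50_mean: float = 14.5
    t50_sd: float = 2.0


@dataclass
class SimConfig:
    """Parameters of one synthetic study.

    ``n_per_region`` lines per region are simulated (defaults scaled down
    from the ~119 Spanish / ~84 Northern-European accessions of a typical
    regional panel), genotyped at ``n_snps`` biallelic SNPs whose regional
    frequencies diverge with expected Fst ``fst_target``.  ``n_causal``
    markers carry effects on the trait; ``h2`` is the target broad-sense
    heritability of single-replicate phenotypes and ``regional_shift`` an
    additive trait offset between consecutive regions (trait units).
    """

    n_per_region: tuple[int, ...] = (60, 60)
    region_names: tuple[str, ...] | None = None
    n_snps: int = 5000
    fst_target: float = 0.06
    n_causal: int = 50
    h2: float = 0.6
    regional_shift: float = 0.0
    growth_truth: GrowthTruth = field(default_factory=GrowthTruth)
    noise_sd: float = 0.2          # cm, residual diameter noise per photo
    block_sd: float = 0.2          # cm, additive block offsets
    tray_sd: float = 0.1           # cm, additive tray-within-block offsets
    n_blocks: int = 3
    measurement_days: tuple[float, ...] = DEFAULT_DAYS_HL
    n_chromosomes: int = 5
    chromosome_length: int = 30_000_000
    missing_rate: float = 0.0
    #: divergent-selection strength: per-causal-locus allele-frequency
    #: tilt between consecutive regions, signed by the locus effect
    #: (0 = neutral causal loci; the additive regional_shift is separate)
    selection_delta: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.n_per_region):
            raise ValueError("n_per_region entries must be positive")
        if self.n_snps <= 0 or self.n_causal <= 0 or self.n_blocks <= 0:
            raise ValueError("counts must be positive")
        if not 0.0 <= self.fst_target < 1.0:
            raise ValueError("fst_target must lie in [0, 1)")
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError("h2 must lie in [0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.region_names is None:
            self.region_names = tuple(
                f"region{i+1}" for i in range(len(self.n_per_region))
            )
        if len(self.region_names) != len(self.n_per_region):
            raise ValueError("region_names must match n_per_region")

    def rng(self, stream: int) -> np.random.Generator:
        """Deterministic per-stream generator derived from the config seed."""
        return np.random.default_rng(np.random.SeedSequence([self.seed, stream]))


@dataclass
class SimTruth:
    """Ground truth of one simulated trait for downstream validation."""

    causal_ids: np.ndarray
    true_effects: np.ndarray
    true_genotypic_values: pd.Series      # per line, trait units
    region_labels: pd.Series              # per line
    growth_params: pd.DataFrame | None = None  # per line: fs, slope, t50


def simulate_genotypes(config: SimConfig) -> GenotypeMatrix:
    """Draw fully homozygous regional genotypes under Balding-Nichols drift.

    Ancestral frequencies are Uniform(0.05, 0.95) (avoids near-fixed
    markers); each region's frequency is Beta(p(1-F)/F, (1-p)(1-F)/F).
    The Balding-Nichols parameter F is calibrated so that the *realized*
    multi-locus Nei Fst (ratio of summed Ht - Hs over summed Ht) across
    the k regions equals ``fst_target``: with k demes
    Gst = F(1-1/k)/(1-F/k), hence F = Gk/(k-1+G).  The mean of per-SNP
    ratios is slightly smaller (per-locus Ht noise).
    ``fst_target=0`` means all regions share the ancestral frequency.
    Lines are selfers: one allele is drawn per line and the dosage code
    is 0 or 2.
    """
    rng = config.rng(1)
    m = config.n_snps
    p_anc = rng.uniform(0.05, 0.95, size=m)
    k = len(config.n_per_region)
    G_target = config.fst_target
    F = G_target * k / (k - 1 + G_target) if k > 1 else 0.0
    codes = []
    regions = []
    for n_r, name in zip(config.n_per_region, config.region_names):
        if F > 0:
            a = p_anc * (1.0 - F) / F
            b = (1.0 - p_anc) * (1.0 - F) / F
            p_r = rng.beta(a, b)
        else:
            p_r = p_anc
        alleles = rng.random((n_r, m)) < p_r
        codes.append(alleles.astype(np.int8) * 2)
        regions.extend([name] * n_r)
    codes = np.vstack(codes)
    if config.missing_rate > 0:
        miss = rng.random(codes.shape) < config.missing_rate
        codes[miss] = MISSING

    # marker map: markers spread round-robin over chromosomes, positions
    # sorted within each chromosome
    chrom = np.repeat(
        np.arange(1, config.n_chromosomes + 1),
        -(-m // config.n_chromosomes),
    )[:m]
    pos = np.empty(m, dtype=np.int64)
    for c in np.unique(chrom):
        idx = np.where(chrom == c)[0]
        pos[idx] = np.sort(
            rng.choice(config.chromosome_length, size=len(idx), replace=False) + 1
        )
    line_ids = np.array([f"line{i:04d}" for i in range(codes.shape[0])])
    return GenotypeMatrix(
        codes=codes, chrom=chrom, pos=pos, line_ids=line_ids,
        regions=np.array(regions),
    )


def simulate_trait(
    G: GenotypeMatrix, config: SimConfig
) -> tuple[pd.DataFrame, SimTruth]:
    """Simulate a polygenic trait with replicate phenotypes.

    The genotypic value is a sum of allele-dose effects over ``n_causal``
    random markers plus a per-region mean shift.  Environmental noise is
    scaled so the expected broad-sense heritability of single replicates
    equals ``h2``.  Returns a long-format replicate table
    (line_id, region, replicate, value) and the :class:`SimTruth`.
    """
    if config.n_causal > G.n_markers:
        raise ValueError("n_causal exceeds the number of simulated markers")
    if config.h2 == 0.0:
        raise ValueError("h2 = 0 leaves the trait pure noise; not supported")
    rng = config.rng(2)
    causal = rng.choice(G.n_markers, size=config.n_causal, replace=False)
    effects = rng.normal(0.0, 1.0, size=config.n_causal)
    dosage = G.dosage_imputed()[:, causal]
    g = dosage @ effects
    # standardize the polygenic component to unit SD so regional_shift and
    # downstream growth parameters are in genotypic-SD units
    scale = float(np.std(g))
    if scale > 0:
        g = (g - g.mean()) / scale
        effects = effects / scale
    regions = pd.Series(G.regions, index=G.line_ids, name="region")
    if config.regional_shift != 0.0:
        for i, name in enumerate(config.region_names):
            g[G.regions == name] += i * config.regional_shift
    var_g = float(np.var(g))
    if config.h2 < 1.0:
        var_e = var_g * (1.0 - config.h2) / config.h2
        noise = rng.normal(0.0, np.sqrt(var_e), size=(len(g), config.n_blocks))
    else:
        noise = np.zeros((len(g), config.n_blocks))
    rows = []
    for rep in range(config.n_blocks):
        rows.append(
            pd.DataFrame(
                {
                    "line_id": G.line_ids,
                    "region": G.regions,
                    "replicate": rep + 1,
                    "value": g + noise[:, rep],
                }
            )
        )
    pheno = pd.concat(rows, ignore_index=True)
    truth = SimTruth(
        causal_ids=G.marker_ids[causal],
        true_effects=effects,
        true_genotypic_values=pd.Series(g, index=G.line_ids),
        region_labels=regions,
    )
    return pheno, truth


def apply_divergent_selection(
    G: GenotypeMatrix, truth: SimTruth, config: SimConfig
) -> tuple[GenotypeMatrix, SimTruth]:
    """Tilt causal allele frequencies between regions along effect signs.

    Models polygenic divergent selection: in region i, each causal
    locus's allele frequency is shifted by i * selection_delta in the
    direction that raises the trait, and the region's genotypes at those
    loci are redrawn.  Genotypic values and the returned truth are
    recomputed; the induced regional trait shift is genuinely mediated by
    the causal markers (unlike the additive ``regional_shift``).
    """
    if config.selection_delta == 0.0:
        return G, truth
    rng = config.rng(6)
    codes = G.codes.copy()
    idx = {m: j for j, m in enumerate(G.marker_ids)}
    causal_cols = np.array([idx[m] for m in truth.causal_ids])
    sign = np.sign(truth.true_effects)
    for i, name in enumerate(config.region_names):
        if i == 0:
            continue
        rows = np.where(G.regions == name)[0]
        sub = codes[np.ix_(rows, causal_cols)].astype(float)
        p_obs = np.where(sub == MISSING, np.nan, sub)
        p_obs = np.nanmean(p_obs, axis=0) / 2.0
        p_new = np.clip(p_obs + i * config.selection_delta * sign, 0.02, 0.98)
        redrawn = (rng.random((rows.size, causal_cols.size)) < p_new
                   ).astype(np.int8) * 2
        keep_missing = codes[np.ix_(rows, causal_cols)] == MISSING
        redrawn[keep_missing] = MISSING
        codes[np.ix_(rows, causal_cols)] = redrawn
    G2 = GenotypeMatrix(
        codes=codes, chrom=G.chrom, pos=G.pos, line_ids=G.line_ids,
        regions=G.regions, marker_ids=G.marker_ids,
    )
    dosage = G2.dosage_imputed()[:, causal_cols]
    g = dosage @ truth.true_effects
    g = g - g.mean()
    truth2 = SimTruth(
        causal_ids=truth.causal_ids,
        true_effects=truth.true_effects,
        true_genotypic_values=pd.Series(g, index=G.line_ids),
        region_labels=truth.region_labels,
    )
    return G2, truth2


def growth_parameter_truth(
    G: GenotypeMatrix, config: SimConfig, truth: SimTruth | None = None
) -> SimTruth:
    """Attach per-line logistic growth parameters to a :class:`SimTruth`.

    Final size carries the polygenic signal (the genotypic value, already
    in genotypic-SD units, is mapped onto the FS scale as
    fs_mean + fs_sd * value); slope and t50 vary between genotypes with
    the configured genotypic SDs but no marker effects.
    """
    if truth is None:
        _, truth = simulate_trait(G, config)
    rng = config.rng(3)
    gt = config.growth_truth
    g = truth.true_genotypic_values.to_numpy()
    fs = np.maximum(gt.fs_mean + gt.fs_sd * g, 0.5)
    slope = np.maximum(gt.slope_mean + rng.normal(0, gt.slope_sd, len(g)), 0.02)
    t50 = np.maximum(gt.t50_mean + rng.normal(0, gt.t50_sd, len(g)), 1.0)
    truth.growth_params = pd.DataFrame(
        {"fs": fs, "slope": slope, "t50": t50}, index=truth.true_genotypic_values.index
    )
    return truth


def simulate_growth_experiment(
    truth: SimTruth, config: SimConfig, regime: str = "HL"
) -> list[DiameterSeries]:
    """Generate plant-level diameter series under a randomized block design.

    Each genotype appears exactly once per block; pots are laid out on
    trays of 5 x 7 positions within each block, mirroring a split-plot
    growth-chamber experiment.  Each plant's growth parameters are its
    genotype's true values plus micro-environmental deviations scaled so
    the broad-sense heritability of the fitted parameters is ~``h2``
    (none when h2 = 1); observed diameters are that plant's logistic
    curve plus additive block and tray offsets and i.i.d. Gaussian
    measurement noise, floored at zero.
    """
    if truth.growth_params is None:
        raise ValueError("truth has no growth parameters; "
                         "call growth_parameter_truth first")
    days = np.asarray(config.measurement_days, dtype=float)
    if days.size == 0:
        raise ValueError("measurement_days must not be empty")
    rng = config.rng(4)
    lines = truth.growth_params.index.to_numpy()
    n_lines = len(lines)
    n_tray_pos = 35  # 5 rows x 7 columns
    n_trays = -(-n_lines // n_tray_pos)
    block_off = rng.normal(0.0, config.block_sd, size=config.n_blocks)
    tray_off = rng.normal(0.0, config.tray_sd, size=(config.n_blocks, n_trays))
    gt = config.growth_truth
    env_ratio = np.sqrt((1.0 - config.h2) / config.h2) if config.h2 < 1 else 0.0
    # scale plant-level deviations to the *realized* genotypic SDs so the
    # broad-sense heritability tracks h2 even when selection or regional
    # shifts inflate the genotypic variance
    sd = truth.growth_params.std(ddof=0)
    fs_env = float(sd["fs"]) * env_ratio if sd["fs"] > 0 else gt.fs_sd * env_ratio
    slope_env = (float(sd["slope"]) or gt.slope_sd) * env_ratio
    t50_env = (float(sd["t50"]) or gt.t50_sd) * env_ratio
    series: list[DiameterSeries] = []
    for b in range(config.n_blocks):
        order = rng.permutation(n_lines)
        for slot, li in enumerate(order):
            tray, pos = divmod(slot, n_tray_pos)
            row, col = divmod(pos, 7)
            p = truth.growth_params.iloc[li]
            fs_p = max(p.fs + rng.normal(0, fs_env), 0.5)
            slope_p = max(p.slope + rng.normal(0, slope_env), 0.02)
            t50_p = max(p.t50 + rng.normal(0, t50_env), 1.0)
            curve = logistic_curve(days, fs_p, slope_p, t50_p)
            noise = rng.normal(0.0, config.noise_sd, size=days.size)
            diam = np.maximum(curve + block_off[b] + tray_off[b, tray] + noise, 0.0)
            series.append(
                DiameterSeries(
                    plant_id=f"{lines[li]}_b{b+1}",
                    genotype_id=str(lines[li]),
                    regime=regime,
                    block=b + 1,
                    tray=tray + 1,
                    row=row + 1,
                    col=col + 1,
                    days=days,
                    diameters=diam,
                )
            )
    return series


def logistic_curve(t: np.ndarray, fs: float, slope: float, t50: float) -> np.ndarray:
    """Three-parameter logistic d(t) = fs / (1 + exp(-slope*(t - t50)))."""
    return fs / (1.0 + np.exp(-slope * (np.asarray(t, dtype=float) - t50)))


@dataclass
class LofSim:
    """A simulated LOF study: binary matrix, affected trait, planted gene."""

    lof: pd.DataFrame          # genes x genotypes, entries in {0, 1}
    trait: pd.Series           # per genotype
    causal_gene: str
    effect: float


def simulate_lof(
    G: GenotypeMatrix,
    n_genes: int,
    freq: float = 0.15,
    effect: float = -3.5,
    seed: int = 0,
    noise_sd: float = 1.0,
) -> LofSim:
    """Simulate a sparse gene x genotype LOF matrix and an affected trait.

    Every gene's LOF state is Bernoulli(``freq``) per line; the first gene
    is causal and shifts the trait by ``effect`` in carriers.  The trait is
    standard-normal noise otherwise (``noise_sd``).
    """
    if n_genes <= 0:
        raise ValueError("n_genes must be positive")
    if not 0.0 < freq < 1.0:
        raise ValueError("freq must lie in (0, 1)")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 5]))
    states = (rng.random((n_genes, G.n_lines)) < freq).astype(np.int8)
    genes = np.array([f"GENE{i:04d}" for i in range(n_genes)])
    lof = pd.DataFrame(states, index=genes, columns=G.line_ids)
    trait = rng.normal(0.0, noise_sd, size=G.n_lines) + effect * states[0]
    return LofSim(
        lof=lof,
        trait=pd.Series(trait, index=G.line_ids, name="trait"),
        causal_gene=str(genes[0]),
        effect=effect,
    )


# ---------------------------------------------------------------------------
# writers for on-disk dialects consumed by the pipeline readers
# ---------------------------------------------------------------------------

def write_012(G: GenotypeMatrix, prefix: str) -> None:
    """Write the vcftools ``--012`` trio: <prefix>.012, .012.indv, .012.pos.

    The matrix file is tab-separated with a leading row-index column;
    missing calls are coded -1.  Positions are 1-based.
    """
    mat = pd.DataFrame(G.codes)
    mat.insert(0, "idx", np.arange(G.n_lines))
    mat.to_csv(f"{prefix}.012", sep="\t", header=False, index=False)
    pd.Series(G.line_ids).to_csv(f"{prefix}.012.indv", header=False, index=False)
    pd.DataFrame({"chrom": G.chrom, "pos": G.pos}).to_csv(
        f"{prefix}.012.pos", sep="\t", header=False, index=False
    )


def write_vcf(G: GenotypeMatrix, path: str) -> None:
    """Write a minimal uncompressed VCF 4.2 with GT fields only."""
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in np.unique(G.chrom):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(map(str, G.line_ids))
            + "\n"
        )
        for j in range(G.n_markers):
            gts = "\t".join(gt_map[int(c)] for c in G.codes[:, j])
            fh.write(
                f"{G.chrom[j]}\t{G.pos[j]}\t{G.marker_ids[j]}\tA\tT\t.\tPASS\t.\tGT\t{gts}\n"
            )


def phenotype_table(series: list[DiameterSeries]) -> pd.DataFrame:
    """Wide per-plant table: genotype, design columns, then diam<day> columns."""
    days = sorted({d for s in series for d in s.days})
    rows = []
    for s in series:
        row = {
            "plant_id": s.plant_id,
            "genotype": s.genotype_id,
            "regime": s.regime,
            "block": s.block,
            "tray": s.tray,
            "row": s.row,
            "col": s.col,
        }
        lookup = dict(zip(s.days, s.diameters))
        for d in days:
            key = f"diam{d:g}"
            row[key] = lookup.get(d, np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def write_phenotype_csv(series: list[DiameterSeries], path: str) -> None:
    phenotype_table(series).to_csv(path, index=False)


def write_lof_tsv(lof: pd.DataFrame, path: str) -> None:
    """Gene x genotype 0/1 matrix, genes as rows."""
    lof.to_csv(path, sep="\t", index_label="gene")
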