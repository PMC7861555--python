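"""Gene-level scoring of association scans and GO enrichment tests.

Each gene in the annotation universe receives exactly one score: the
smallest association p-value among SNPs inside the gene body, or — when no
SNP falls inside — the p-value of the physically closest SNP (midpoint
distance, ties toward the smaller p).  Enrichment of a candidate gene set
in a GO term uses the one-sided Fisher exact test on the 2x2 table; a
rank-based alternative applies a one-sided Kolmogorov-Smirnov test to the
score distribution of term genes versus the rest, sensitive to enrichment
at top ranks.  Because random SNP sets near structured genomes produce
anti-conservative enrichment p-values, the significance threshold is
calibrated by rerunning the enrichment on random sets and taking an
extreme quantile of the pooled p-value distribution.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GenotypeMatrix
from .polyscore import ld_r2


# ---------------------------------------------------------------------------
# gene models and annotation I/O
# ---------------------------------------------------------------------------

def read_gff3_genes(path: str) -> pd.DataFrame:
    """Gene features of a GFF3 file: gene_id, chrom, start, end (1-based)."""
    import gffutils

    db = gffutils.create_db(
        path, dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    rows = [
        {
            "gene_id": f.attributes.get("ID", [f.id])[0],
            "chrom": f.seqid,
            "start": f.start,
            "end": f.end,
        }
        for f in db.features_of_type("gene")
    ]
    if not rows:
        raise ValueError(f"{path}: no gene features found")
    return pd.DataFrame(rows)


def read_go_annotation(path: str) -> pd.DataFrame:
    """Two-column gene -> GO term TSV (no header or 'gene\\tterm' header)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "term"],
                     comment="#", dtype=str)
    if df.iloc[0, 0] == "gene_id":
        df = df.iloc[1:].reset_index(drop=True)
    return df


# ---------------------------------------------------------------------------
# gene scores
# ---------------------------------------------------------------------------

def assign_gene_scores(assoc: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """One association p-value per gene (min-p inside, else nearest SNP).

    Genes on chromosomes with no genotyped SNP are skipped with a warning.
    Returns gene_id, p, source_marker, distance_bp (0 for internal SNPs).
    """
    assoc = assoc.dropna(subset=["p"])
    records = []
    snp_by_chrom = {
        str(c): sub.sort_values("pos").reset_index(drop=True)
        for c, sub in assoc.groupby("chrom")
    }
    for g in genes.itertuples():
        sub = snp_by_chrom.get(str(g.chrom))
        if sub is None:
            warnings.warn(f"gene {g.gene_id}: no SNPs on chromosome {g.chrom}; skipped")
            continue
        inside = sub[(sub["pos"] >= g.start) & (sub["pos"] <= g.end)]
        if len(inside):
            best = inside.loc[inside["p"].idxmin()]
            records.append((g.gene_id, float(best["p"]), best["marker_id"], 0))
        else:
            mid = (g.start + g.end) / 2.0
            d = np.abs(sub["pos"].to_numpy() - mid)
            dmin = d.min()
            cand = sub[d == dmin]
            best = cand.loc[cand["p"].idxmin()]
            records.append(
                (g.gene_id, float(best["p"]), best["marker_id"], int(dmin))
            )
    return pd.DataFrame(
        records, columns=["gene_id", "p", "source_marker", "distance_bp"]
    )


def prune_tandem_duplicates(
    gene_order: pd.DataFrame,
    similarity: pd.DataFrame,
    evalue_max: float = 1e-30,
    max_gene_distance: int = 10,
) -> pd.DataFrame:
    """Drop the downstream member of tandem-duplicated gene pairs.

    ``gene_order`` (gene_id, chrom, start, ...) defines the genomic order;
    ``similarity`` holds precomputed all-vs-all alignment pairs
    (gene1, gene2, evalue).  For every pair with e-value < ``evalue_max``
    lying on the same chromosome fewer than ``max_gene_distance`` gene
    ranks apart, the member further downstream is removed.  The result is
    order-independent and idempotent.
    """
    order = gene_order.sort_values(["chrom", "start"]).reset_index(drop=True)
    rank = {g: i for i, g in enumerate(order["gene_id"])}
    chrom = dict(zip(order["gene_id"], order["chrom"].astype(str)))
    drop: set[str] = set()
    for p in similarity.itertuples():
        g1, g2 = p.gene1, p.gene2
        if g1 == g2 or p.evalue >= evalue_max:
            continue
        if g1 not in rank or g2 not in rank or chrom[g1] != chrom[g2]:
            continue
        if abs(rank[g1] - rank[g2]) < max_gene_distance:
            drop.add(g1 if rank[g1] > rank[g2] else g2)
    return gene_order[~gene_order["gene_id"].isin(drop)].reset_index(drop=True)


# ---------------------------------------------------------------------------
# enrichment tests
# ---------------------------------------------------------------------------

def _term_sets(annotation: pd.DataFrame, universe: set[str],
               min_genes: int = 5) -> dict[str, set[str]]:
    ann = annotation[annotation["gene_id"].isin(universe)]
    sets = {t: set(s["gene_id"]) for t, s in ann.groupby("term")}
    return {t: s for t, s in sets.items() if len(s) > min_genes}


def go_fisher(
    candidates: set[str] | list[str],
    universe: set[str] | list[str],
    annotation: pd.DataFrame,
    min_genes: int = 5,
) -> pd.DataFrame:
    """One-sided Fisher exact enrichment of candidates per GO term.

    Terms annotated to ``min_genes`` or fewer universe genes are
    suppressed.  n_expected is the hypergeometric expectation
    n_candidate_total * n_annotated / n_universe.
    """
    universe = set(universe)
    candidates = set(candidates) & universe
    if not candidates:
        raise ValueError("empty candidate set")
    n_u, n_c = len(universe), len(candidates)
    rows = []
    for term, genes in _term_sets(annotation, universe, min_genes).items():
        k = len(genes & candidates)
        K = len(genes)
        p = stats.hypergeom.sf(k - 1, n_u, K, n_c)
        rows.append(
            {
                "term": term, "n_annotated": K, "n_candidate": k,
                "n_expected": n_c * K / n_u, "p": float(p), "test": "fisher",
            }
        )
    return pd.DataFrame(rows).sort_values("p").reset_index(drop=True)


def go_ks(
    scores: pd.DataFrame,
    annotation: pd.DataFrame,
    min_genes: int = 5,
) -> pd.DataFrame:
    """One-sided KS enrichment on gene scores (small p-values = top ranks).

    Per term, tests whether term genes' scores are stochastically smaller
    than those of non-term genes; skips terms without scored genes.
    """
    scored = scores.dropna(subset=["p"]).drop_duplicates("gene_id")
    universe = set(scored["gene_id"])
    vals = scored.set_index("gene_id")["p"]
    rows = []
    for term, genes in _term_sets(annotation, universe, min_genes).items():
        inside = vals[list(genes)]
        outside = vals[~vals.index.isin(genes)]
        if inside.empty or outside.empty:
            continue
        res = stats.ks_2samp(inside, outside, alternative="greater")
        rows.append(
            {
                "term": term, "n_annotated": len(genes),
                "ks_stat": float(res.statistic), "p": float(res.pvalue),
                "test": "ks",
            }
        )
    return pd.DataFrame(rows).sort_values("p").reset_index(drop=True)


def permutation_threshold(
    universe: list[str],
    annotation: pd.DataFrame,
    set_size: int,
    n_sets: int = 1000,
    seed: int = 0,
    quantile: float = 1e-4,
    min_genes: int = 5,
) -> float:
    """Permutation-calibrated enrichment significance threshold.

    Runs the Fisher enrichment on ``n_sets`` random candidate sets of
    ``set_size`` genes and returns the ``quantile`` (default 0.01%)
    quantile of the pooled p-value distribution — the level below which an
    observed enrichment is more extreme than essentially anything random
    sets produce.
    """
    if n_sets <= 0:
        raise ValueError("n_sets must be positive")
    if set_size <= 0:
        raise ValueError("set_size must be positive")
    universe = list(universe)
    rng = np.random.default_rng(seed)
    pooled: list[np.ndarray] = []
    for _ in range(n_sets):
        pick = rng.choice(universe, size=min(set_size, len(universe)),
                          replace=False)
        res = go_fisher(set(pick), universe, annotation, min_genes=min_genes)
        if len(res):
            pooled.append(res["p"].to_numpy())
    if not pooled:
        raise ValueError("no reportable term in any random set")
    return float(np.quantile(np.concatenate(pooled), quantile))


# ---------------------------------------------------------------------------
# LD-defined candidate windows
# ---------------------------------------------------------------------------

def candidate_gene_window(
    focal_marker: str,
    G: GenotypeMatrix,
    genes: pd.DataFrame,
    max_window: float = 250_000,
    r2_min: float = 0.5,
) -> pd.DataFrame:
    """Genes overlapping the LD block around a focal SNP.

    The block is the contiguous run of markers around the focal one whose
    r2 with it stays >= ``r2_min``, truncated at +/- ``max_window``/2; any
    gene whose interval overlaps the block span (1-based inclusive) is
    returned.
    """
    hits = np.where(G.marker_ids == focal_marker)[0]
    if hits.size == 0:
        raise ValueError(f"focal marker {focal_marker!r} not genotyped")
    j = int(hits[0])
    chrom = G.chrom[j]
    pos = G.pos[j]
    half = max_window / 2.0
    on_chrom = np.where(G.chrom == chrom)[0]
    order = on_chrom[np.argsort(G.pos[on_chrom])]
    k = int(np.where(order == j)[0][0])
    lo = hi = pos
    for idx in order[k + 1:]:                      # extend right
        if G.pos[idx] - pos > half:
            break
        if ld_r2(G, j, np.array([idx]))[0] < r2_min:
            break
        hi = G.pos[idx]
    for idx in order[:k][::-1]:                    # extend left
        if pos - G.pos[idx] > half:
            break
        if ld_r2(G, j, np.array([idx]))[0] < r2_min:
            break
        lo = G.pos[idx]
    sel = genes[
        (genes["chrom"].astype(str) == str(chrom))
        & (genes["end"] >= lo)
        & (genes["start"] <= hi)
    ]
    out = sel.reset_index(drop=True).copy()
    out.attrs["span"] = (int(lo), int(hi))
    return out
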