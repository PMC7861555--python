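"""Gene scoring against exhaustive nearest-SNP scans, tandem-duplicate
pruning against a brute-force pair scan, Fisher enrichment against direct
hypergeometric summation, rank-based KS enrichment against the ECDF
sup-difference, the permutation-calibrated threshold, and LD candidate
windows."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from polygrowth import goenrich
from polygrowth.containers import GenotypeMatrix


def assoc_frame(chrom, pos, p):
    return pd.DataFrame(
        {"marker_id": [f"m{i}" for i in range(len(pos))],
         "chrom": chrom, "pos": pos, "p": p}
    )


def gene_frame(rows):
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])


class TestAssignGeneScores:
    def test_min_p_inside_gene(self):
        assoc = assoc_frame([1, 1], [100, 200], [0.1, 0.001])
        genes = gene_frame([("g", 1, 50, 250)])
        out = goenrich.assign_gene_scores(assoc, genes)
        assert out["p"].iloc[0] == 0.001
        assert out["distance_bp"].iloc[0] == 0

    def test_nearest_snp_when_none_inside(self):
        assoc = assoc_frame([1, 1], [1000, 9000], [0.02, 0.5])
        genes = gene_frame([("g", 1, 3000, 5000)])   # midpoint 4000
        out = goenrich.assign_gene_scores(assoc, genes)
        assert out["p"].iloc[0] == 0.02
        assert out["source_marker"].iloc[0] == "m0"

    def test_full_assignment_matches_brute_force(self):
        """5-gene / 8-SNP toy layout vs an exhaustive scan."""
        rng = np.random.default_rng(0)
        pos = np.sort(rng.choice(10_000, 8, replace=False))
        ps = rng.random(8)
        assoc = assoc_frame([1] * 8, pos, ps)
        genes = gene_frame(
            [(f"g{i}", 1, s, s + 800) for i, s in
             enumerate([200, 2500, 4800, 7000, 9000])]
        )
        out = goenrich.assign_gene_scores(assoc, genes).set_index("gene_id")
        for g in genes.itertuples():
            inside = [(p, i) for i, (x, p) in enumerate(zip(pos, ps))
                      if g.start <= x <= g.end]
            if inside:
                want = min(inside)[0]
            else:
                mid = (g.start + g.end) / 2
                dmin = min(abs(x - mid) for x in pos)
                want = min(p for x, p in zip(pos, ps) if abs(x - mid) == dmin)
            assert out.loc[g.gene_id, "p"] == want

    def test_every_gene_scored_once(self):
        assoc = assoc_frame([1] * 5, [10, 20, 30, 40, 50], [0.5] * 5)
        genes = gene_frame([(f"g{i}", 1, 5 + i * 10, 9 + i * 10)
                            for i in range(4)])
        out = goenrich.assign_gene_scores(assoc, genes)
        assert out["gene_id"].is_unique and len(out) == 4

    def test_unknown_chromosome_skipped_with_warning(self):
        assoc = assoc_frame([1], [100], [0.1])
        genes = gene_frame([("g1", 1, 50, 150), ("g2", 7, 50, 150)])
        with pytest.warns(UserWarning, match="chromosome"):
            out = goenrich.assign_gene_scores(assoc, genes)
        assert list(out["gene_id"]) == ["g1"]


class TestPruneTandemDuplicates:
    def order(self, n, chrom=1):
        return gene_frame([(f"g{i}", chrom, 1000 * i + 1, 1000 * i + 500)
                           for i in range(n)])

    def pairs(self, rows):
        return pd.DataFrame(rows, columns=["gene1", "gene2", "evalue"])

    def test_no_pair_under_threshold_unchanged(self):
        genes = self.order(6)
        out = goenrich.prune_tandem_duplicates(
            genes, self.pairs([("g0", "g2", 1e-10)])
        )
        assert list(out["gene_id"]) == list(genes["gene_id"])

    def test_close_duplicate_downstream_removed(self):
        genes = self.order(12)
        sim = self.pairs([("g2", "g5", 1e-40)])       # 3 apart
        out = goenrich.prune_tandem_duplicates(genes, sim)
        assert "g5" not in set(out["gene_id"])
        assert "g2" in set(out["gene_id"])

    def test_distant_duplicates_both_retained(self):
        genes = self.order(20)
        out = goenrich.prune_tandem_duplicates(
            genes, self.pairs([("g1", "g16", 1e-40)])  # 15 apart
        )
        assert {"g1", "g16"} <= set(out["gene_id"])

    def test_matches_brute_force_on_12_gene_toy(self):
        genes = self.order(12)
        rng = np.random.default_rng(1)
        rows = []
        ids = list(genes["gene_id"])
        for i in range(12):
            for j in range(i + 1, 12):
                rows.append((ids[i], ids[j],
                             10.0 ** rng.uniform(-60, -10)))
        sim = self.pairs(rows)
        out = set(goenrich.prune_tandem_duplicates(genes, sim)["gene_id"])
        drop = set()
        for r in sim.itertuples():
            i, j = ids.index(r.gene1), ids.index(r.gene2)
            if r.evalue < 1e-30 and abs(i - j) < 10:
                drop.add(ids[max(i, j)])
        assert out == set(ids) - drop

    def test_idempotent(self):
        genes = self.order(12)
        sim = self.pairs([("g2", "g5", 1e-40), ("g5", "g7", 1e-35)])
        once = goenrich.prune_tandem_duplicates(genes, sim)
        twice = goenrich.prune_tandem_duplicates(once, sim)
        assert list(once["gene_id"]) == list(twice["gene_id"])


class TestReaders:
    def test_gff3_gene_features(self, tmp_path):
        gff = tmp_path / "genes.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "1\tsrc\tgene\t100\t900\t.\t+\t.\tID=AT1G01010\n"
            "1\tsrc\tmRNA\t100\t900\t.\t+\t.\tID=m1;Parent=AT1G01010\n"
            "2\tsrc\tgene\t500\t1500\t.\t-\t.\tID=AT2G00500\n"
        )
        genes = goenrich.read_gff3_genes(str(gff))
        assert len(genes) == 2
        row = genes.set_index("gene_id").loc["AT1G01010"]
        assert (row["chrom"], row["start"], row["end"]) == ("1", 100, 900)

    def test_go_annotation_tsv(self, tmp_path):
        tsv = tmp_path / "go.tsv"
        tsv.write_text("AT1G01010\tGO:0009507\nAT2G00500\tGO:0009507\n")
        ann = goenrich.read_go_annotation(str(tsv))
        assert len(ann) == 2
        assert set(ann["term"]) == {"GO:0009507"}


def annotation(term_members):
    rows = [(g, t) for t, genes in term_members.items() for g in genes]
    return pd.DataFrame(rows, columns=["gene_id", "term"])


class TestGoFisher:
    def test_hypergeometric_oracle(self):
        """4 of 5 candidates in a 10-gene term, universe 100: p equals the
        direct hypergeometric tail sum."""
        universe = [f"g{i}" for i in range(100)]
        term = universe[:10]
        cands = universe[:4] + [universe[50]]
        res = goenrich.go_fisher(cands, universe, annotation({"T": term}))
        want = sum(
            stats.hypergeom.pmf(k, 100, 10, 5) for k in range(4, 6)
        )
        assert res["p"].iloc[0] == pytest.approx(want, rel=1e-10)

    def test_candidates_equal_universe_no_enrichment(self):
        universe = [f"g{i}" for i in range(40)]
        res = goenrich.go_fisher(universe, universe,
                                 annotation({"T": universe[:12]}))
        assert np.allclose(res["p"], 1.0)

    def test_small_terms_suppressed(self):
        universe = [f"g{i}" for i in range(50)]
        ann = annotation({"small": universe[:5], "big": universe[:12]})
        res = goenrich.go_fisher(universe[:8], universe, ann)
        assert set(res["term"]) == {"big"}

    def test_order_invariance_and_empty_guard(self):
        universe = [f"g{i}" for i in range(30)]
        ann = annotation({"T": universe[:10]})
        a = goenrich.go_fisher(universe[:6], universe, ann)
        b = goenrich.go_fisher(universe[:6][::-1], universe, ann)
        assert a["p"].iloc[0] == b["p"].iloc[0]
        with pytest.raises(ValueError):
            goenrich.go_fisher([], universe, ann)


class TestGoKs:
    def scores(self, ps):
        return pd.DataFrame(
            {"gene_id": [f"g{i}" for i in range(len(ps))], "p": ps}
        )

    def test_top_ranked_term_is_extreme(self):
        ps = np.linspace(0.001, 1, 40)
        ann = annotation({"T": [f"g{i}" for i in range(10)]})
        res = goenrich.go_ks(self.scores(ps), ann)
        # term genes occupy the top 10 ranks: minimal possible KS p
        other = annotation({"T": [f"g{i}" for i in range(5, 15)]})
        res2 = goenrich.go_ks(self.scores(ps), other)
        assert res["p"].iloc[0] < res2["p"].iloc[0]
        assert res["ks_stat"].iloc[0] == pytest.approx(1.0)

    def test_random_ranks_uniform_p(self):
        ps = []
        for seed in range(60):
            rng = np.random.default_rng(seed)
            sc = self.scores(rng.random(60))
            ann = annotation({"T": rng.choice(sc["gene_id"], 15,
                                              replace=False)})
            ps.append(goenrich.go_ks(sc, ann)["p"].iloc[0])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_statistic_matches_direct_ecdf_formula(self):
        rng = np.random.default_rng(2)
        sc = self.scores(rng.random(20))
        term = list(sc["gene_id"][::3])
        res = goenrich.go_ks(sc, annotation({"T": term}), min_genes=5)
        inside = sc[sc["gene_id"].isin(term)]["p"].to_numpy()
        outside = sc[~sc["gene_id"].isin(term)]["p"].to_numpy()
        grid = np.sort(sc["p"].to_numpy())
        d_plus = max(
            np.mean(inside <= x) - np.mean(outside <= x) for x in grid
        )
        assert res["ks_stat"].iloc[0] == pytest.approx(d_plus, abs=1e-12)


class TestPermutationThreshold:
    def test_quantile_matches_order_statistics_oracle(self):
        rng = np.random.default_rng(3)
        universe = [f"g{i}" for i in range(200)]
        ann = annotation({
            f"T{t}": rng.choice(universe, 20, replace=False)
            for t in range(8)
        })
        thr = goenrich.permutation_threshold(universe, ann, set_size=15,
                                             n_sets=200, seed=4,
                                             quantile=0.001)
        # recompute the pooled distribution independently
        pooled = []
        rng2 = np.random.default_rng(4)
        for _ in range(200):
            pick = rng2.choice(universe, 15, replace=False)
            pooled.extend(goenrich.go_fisher(set(pick), universe, ann)["p"])
        assert thr == pytest.approx(float(np.quantile(pooled, 0.001)),
                                    rel=1e-9)

    def test_deterministic_and_guarded(self):
        universe = [f"g{i}" for i in range(60)]
        ann = annotation({"T": universe[:15]})
        a = goenrich.permutation_threshold(universe, ann, 10, n_sets=50,
                                           seed=7)
        b = goenrich.permutation_threshold(universe, ann, 10, n_sets=50,
                                           seed=7)
        assert a == b
        with pytest.raises(ValueError):
            goenrich.permutation_threshold(universe, ann, 10, n_sets=0)
        with pytest.raises(ValueError):
            goenrich.permutation_threshold(universe, ann, 0, n_sets=10)


class TestCandidateGeneWindow:
    def matrix_with_blocks(self):
        """Markers every 10 kb; a 50 kb block (positions 100-150 kb) in
        perfect LD; elsewhere independent."""
        rng = np.random.default_rng(5)
        n = 60
        positions = np.arange(10_000, 400_000, 10_000)
        base = (rng.random(n) < 0.5).astype(np.int8) * 2
        cols = []
        for p in positions:
            if 100_000 <= p <= 150_000:
                cols.append(base.copy())
            else:
                cols.append((rng.random(n) < 0.5).astype(np.int8) * 2)
        return GenotypeMatrix(
            codes=np.column_stack(cols),
            chrom=np.ones(len(positions), dtype=int), pos=positions,
            line_ids=np.array([f"l{i}" for i in range(n)]),
        )

    def genes(self):
        rows = [(f"g{i}", 1, s, s + 4000)
                for i, s in enumerate(range(5_000, 400_000, 20_000))]
        return gene_frame(rows)

    def test_ld_block_genes_match_overlap_oracle(self):
        G = self.matrix_with_blocks()
        focal = G.marker_ids[list(G.pos).index(120_000)]
        out = goenrich.candidate_gene_window(focal, G, self.genes())
        lo, hi = out.attrs["span"]
        assert (lo, hi) == (100_000, 150_000)
        oracle = self.genes()
        oracle = oracle[(oracle["end"] >= lo) & (oracle["start"] <= hi)]
        assert list(out["gene_id"]) == list(oracle["gene_id"])

    def test_no_linked_neighbours_singleton_span(self):
        G = self.matrix_with_blocks()
        focal = G.marker_ids[list(G.pos).index(300_000)]
        out = goenrich.candidate_gene_window(focal, G, self.genes())
        assert out.attrs["span"] == (300_000, 300_000)

    def test_window_cap_truncates_linked_markers(self):
        """Even perfect LD cannot extend the span past +/-125 kb."""
        rng = np.random.default_rng(6)
        n = 50
        positions = np.arange(10_000, 500_000, 10_000)
        base = (rng.random(n) < 0.5).astype(np.int8) * 2
        G = GenotypeMatrix(
            codes=np.column_stack([base.copy() for _ in positions]),
            chrom=np.ones(len(positions), dtype=int), pos=positions,
            line_ids=np.array([f"l{i}" for i in range(n)]),
        )
        focal = G.marker_ids[list(G.pos).index(250_000)]
        out = goenrich.candidate_gene_window(focal, G, self.genes())
        lo, hi = out.attrs["span"]
        assert lo >= 125_000 and hi <= 375_000

    def test_missing_focal_marker_rejected(self):
        G = self.matrix_with_blocks()
        with pytest.raises(ValueError):
            goenrich.candidate_gene_window("nope", G, self.genes())
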