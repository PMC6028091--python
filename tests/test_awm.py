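"""AWM construction: z-scoring, selection steps, annotation, dedupe, overlap."""

import numpy as np
import pandas as pd
import pytest

from awmpcit import (
    AWMConfig,
    TRAIT_NAMES,
    annotate_snps,
    awm_trait_correlations,
    build_awm,
    combine_breeds,
    count_dependencies,
    dedupe_per_gene,
    select_primary,
    select_secondary,
    simulate_gene_map,
    zscore_effects,
)
from awmpcit.simdata import GeneMap

from .conftest import CHROM_LENGTHS, toy_assoc_set, uniform_pvals


def make_gene_map(rows):
    """rows: list of (gene_id, chrom, start, end)."""
    rows = sorted(rows, key=lambda r: (r[1], r[2]))
    return GeneMap(
        gene_ids=np.array([r[0] for r in rows]),
        chrom=np.array([r[1] for r in rows], dtype=np.int64),
        start=np.array([r[2] for r in rows], dtype=np.int64),
        end=np.array([r[3] for r in rows], dtype=np.int64),
        strand=np.array(["+"] * len(rows)),
    )


class TestZscore:
    def test_columns_standardized(self):
        rng = np.random.default_rng(1)
        e = pd.DataFrame(rng.standard_normal((50, 4)) * 3 + 1)
        z = zscore_effects(e)
        assert np.abs(z.mean()).max() < 1e-12
        assert np.abs(z.std(ddof=0) - 1).max() < 1e-12

    def test_population_sd_convention(self):
        z = zscore_effects(pd.DataFrame({"t": [1.0, 2.0, 3.0]}))
        np.testing.assert_allclose(z["t"], [-1.224744871391589, 0.0,
                                            1.224744871391589], atol=1e-12)

    def test_constant_column_raises(self):
        with pytest.raises(ValueError, match="constant"):
            zscore_effects(pd.DataFrame({"t": [1.0, 1.0, 1.0]}))


class TestSelection:
    def test_threshold_examples(self):
        p = pd.DataFrame({"UDD": [0.01, 0.04, 0.06, 0.5, 0.049]},
                         index=[f"s{i}" for i in range(5)])
        assert list(select_primary(p, "UDD")) == ["s0", "s1", "s4"]
        p_all1 = pd.DataFrame({"UDD": [1.0] * 4})
        assert len(select_primary(p_all1, "UDD")) == 0
        with pytest.raises(ValueError):
            select_primary(p, "nope")

    def test_null_selection_is_binomial(self):
        p = uniform_pvals(10_000, seed=2)
        sel = select_primary(p, "UDD", 0.05)
        sigma = np.sqrt(10_000 * 0.05 * 0.95)
        assert abs(len(sel) - 500) < 3 * sigma

    def test_count_dependencies_extremes(self):
        idx = ["a", "b"]
        none_sig = pd.DataFrame(1.0, index=idx, columns=list(TRAIT_NAMES))
        none_sig["UDD"] = 0.01
        assert count_dependencies(pd.Index(idx), none_sig) == 0.0
        all_sig = pd.DataFrame(0.01, index=idx, columns=list(TRAIT_NAMES))
        assert count_dependencies(pd.Index(idx), all_sig) == 11.0

    def test_count_dependencies_hand_enumeration(self):
        p = pd.DataFrame(0.5, index=["a", "b", "c", "d"], columns=list(TRAIT_NAMES))
        p["UDD"] = 0.01
        p.loc["a", ["MY", "FAT"]] = 0.01          # 2 non-key
        p.loc["b", ["FUA", "UC", "UB"]] = 0.02    # 3
        p.loc["c", "SCS"] = 0.04                  # 1
        # d: 0
        assert count_dependencies(p.index, p) == pytest.approx((2 + 3 + 1 + 0) / 4)

    def test_secondary_udder_requirement_binds(self):
        p = pd.DataFrame(0.5, index=["prod_only", "mixed"], columns=list(TRAIT_NAMES))
        p["UDD"] = 0.01
        # significant for 5 production traits but no udder trait: excluded
        p.loc["prod_only", ["MY", "FAT", "PROT", "FAT%", "PROT%"]] = 0.01
        # FUA+UC udder plus MY+FAT+PROT: 5 other incl 2 udder: included
        p.loc["mixed", ["FUA", "UC", "MY", "FAT", "PROT"]] = 0.01
        sel = select_secondary(p, min_other=5, min_udder=2)
        assert list(sel) == ["mixed"]

    def test_secondary_subset_of_primary_and_matches_brute_force(self):
        p = uniform_pvals(400, seed=3)
        primary = select_primary(p)
        sel = select_secondary(p, min_other=2, min_udder=1)
        assert set(sel) <= set(primary)
        udder_other = ["FUA", "UC", "UB", "FTP"]
        other = [t for t in TRAIT_NAMES if t != "UDD"]
        expected = {
            s for s in primary
            if (p.loc[s, other] < 0.05).sum() >= 2
            and (p.loc[s, udder_other] < 0.05).sum() >= 1
        }
        assert set(sel) == expected


class TestAnnotate:
    def test_boundary_cases(self):
        genes = make_gene_map([("gA", 1, 5_000, 8_000)])
        snps = pd.DataFrame(
            {"chrom": [1, 1, 1, 2], "pos": [6_000, 18_000, 18_001, 500]},
            index=pd.Index(["in", "edge", "out", "nogenes"], name="snp_id"),
        )
        ann = annotate_snps(snps, genes).table
        assert ann.loc["in", "category"] == "in_gene"
        assert ann.loc["in", "distance_bp"] == 0
        # exactly 10,000 bp from the gene end: inclusive boundary
        assert ann.loc["edge", "category"] == "within_10kb"
        assert ann.loc["edge", "distance_bp"] == 10_000
        assert ann.loc["out", "category"] == "beyond_10kb"
        assert ann.loc["nogenes", "category"] == "beyond_10kb"
        assert ann.loc["nogenes", "nearest_gene_id"] == ""

    def test_tie_broken_toward_lower_start(self):
        genes = make_gene_map([("gLow", 1, 1_000, 2_000), ("gHigh", 1, 4_000, 5_000)])
        snps = pd.DataFrame({"chrom": [1], "pos": [3_000]},
                            index=pd.Index(["mid"], name="snp_id"))
        ann = annotate_snps(snps, genes).table
        assert ann.loc["mid", "nearest_gene_id"] == "gLow"
        assert ann.loc["mid", "distance_bp"] == 1_000

    def test_matches_brute_force_scan(self):
        genes = simulate_gene_map(50, CHROM_LENGTHS, mean_gene_length=30_000, seed=4)
        rng = np.random.default_rng(5)
        snps = pd.DataFrame(
            {"chrom": rng.integers(1, 6, 1000),
             "pos": rng.integers(1, 10_000_000, 1000)},
            index=pd.Index([f"s{i}" for i in range(1000)], name="snp_id"),
        )
        ann = annotate_snps(snps, genes).table
        for sid, row in snps.iterrows():
            best_d, best_g = np.inf, ""
            for gi in range(genes.n_genes):
                if genes.chrom[gi] != row["chrom"]:
                    continue
                if genes.start[gi] <= row["pos"] <= genes.end[gi]:
                    d = 0
                elif row["pos"] < genes.start[gi]:
                    d = genes.start[gi] - row["pos"]
                else:
                    d = row["pos"] - genes.end[gi]
                if d < best_d:  # first hit at equal distance has lower start
                    best_d, best_g = d, genes.gene_ids[gi]
            if np.isinf(best_d):
                assert ann.loc[sid, "category"] == "beyond_10kb"
                continue
            assert ann.loc[sid, "distance_bp"] == best_d
            assert ann.loc[sid, "nearest_gene_id"] == best_g


class TestDedupe:
    def make(self, rows):
        df = pd.DataFrame(
            rows, columns=["snp_id", "nearest_gene_id", "n_traits_associated",
                           "mean_p", "pos"]
        )
        return df.set_index("snp_id")

    def test_single_snp_kept(self):
        kept = dedupe_per_gene(self.make([("s1", "g1", 3, 0.1, 100)]))
        assert list(kept) == ["s1"]

    def test_trait_count_dominates_mean_p(self):
        kept = dedupe_per_gene(self.make([
            ("sA", "g1", 6, 0.2, 100),
            ("sB", "g1", 4, 0.01, 200),
        ]))
        assert list(kept) == ["sA"]

    def test_ties_by_mean_p_then_position(self):
        kept = dedupe_per_gene(self.make([
            ("s1", "g1", 4, 0.2, 300),
            ("s2", "g1", 4, 0.1, 200),
            ("s3", "g2", 2, 0.5, 500),
            ("s4", "g2", 2, 0.5, 100),
        ]))
        assert set(kept) == {"s2", "s4"}

    def test_matches_exhaustive_comparator(self):
        rng = np.random.default_rng(6)
        rows = [(f"s{i}", f"g{rng.integers(0, 5)}", int(rng.integers(1, 13)),
                 float(rng.uniform(0, 1)), int(rng.integers(1, 10_000)))
                for i in range(40)]
        df = self.make(rows)
        kept = set(dedupe_per_gene(df))
        expected = set()
        for g, grp in df.groupby("nearest_gene_id"):
            best = min(grp.itertuples(),
                       key=lambda r: (-r.n_traits_associated, r.mean_p, r.pos))
            expected.add(best.Index)
        assert kept == expected


class TestBuildAwm:
    """Hand-built 10-SNP x 12-trait audit of the five construction steps."""

    def toy(self):
        snps = [f"s{i}" for i in range(1, 11)]
        meta = pd.DataFrame(
            {"chrom": [1] * 9 + [2],
             "pos": [i * 100_000 for i in range(1, 10)] + [500_000]},
            index=pd.Index(snps, name="snp_id"),
        )
        p = pd.DataFrame(0.5, index=meta.index, columns=list(TRAIT_NAMES))
        p["UDD"] = [0.01, 0.04, 0.049, 0.02, 0.06, 0.99, 0.03, 0.001, 0.04, 0.5]
        sig = {
            "s1": ["FUA", "UC", "MY"],                     # 3 other, 2 udder
            "s2": ["FUA", "UC", "UB", "MY", "FAT"],        # 5 other, 3 udder
            "s3": ["MY", "FAT", "PROT", "FAT%", "PROT%"],  # 5 other, 0 udder
            "s4": ["FUA", "UB", "MY"],                     # 3 other, 2 udder
            "s7": ["FUA", "UC", "MY", "FAT"],              # 4 other, 2 udder
            "s8": ["FUA", "UC", "UB"],                     # 3 other, 3 udder
            "s9": ["CM"],                                  # 1 other, 0 udder
        }
        for s, ts in sig.items():
            p.loc[s, ts] = 0.01
        effects = pd.DataFrame(
            np.arange(1.0, 121.0).reshape(10, 12, order="F"),
            index=meta.index, columns=list(TRAIT_NAMES),
        )
        genes = make_gene_map([
            ("geneX", 1, 95_000, 105_000),    # contains s1
            ("geneY", 1, 195_000, 198_000),   # 2 kb from s2
            ("geneZ", 1, 310_000, 320_000),   # 10 kb from s3 (not selected)
            ("geneW", 1, 690_000, 805_000),   # contains s7 and s8
        ])
        return toy_assoc_set(p, effects, meta), genes, p

    def test_hand_enumerated_steps(self):
        assoc, genes, p = self.toy()
        # step 1: key-trait p < 0.05
        primary = select_primary(assoc.pvals())
        assert set(primary) == {"s1", "s2", "s3", "s4", "s7", "s8", "s9"}
        # step 2: mean non-key dependencies = (3+5+5+3+4+3+1)/7, rounds to 3
        mean_dep = count_dependencies(primary, assoc.pvals())
        assert mean_dep == pytest.approx(24 / 7)
        assert round(mean_dep) == 3
        # step 3: >=3 other traits incl >=2 udder
        secondary = select_secondary(assoc.pvals(), min_other=3, min_udder=2)
        assert set(secondary) == {"s1", "s2", "s4", "s7", "s8"}

        awm = build_awm(assoc, genes)
        prov = awm.provenance
        # step 4: annotation classes and 1SNP:1gene (s7 beats s8 in geneW on
        # trait count 5 vs 4)
        assert set(prov.index[prov["set"] == "set1"]) == {"s1", "s2", "s7"}
        assert set(prov.index[prov["set"] == "set2"]) == {"s4"}
        assert prov.loc["s7", "nearest_gene_id"] == "geneW"
        assert prov.loc["s2", "category"] == "within_10kb"
        # step 5: rows = set1 + set2, z-scored cells for all 12 traits
        assert awm.counts["rows"] == awm.counts["set1"] + awm.counts["set2"] == 4
        assert list(awm.matrix.index) == ["s1", "s2", "s4", "s7"]
        assert list(awm.matrix.columns) == list(TRAIT_NAMES)
        # one cell checked by hand: FUA effects are 1..10, population SD
        z11 = (1.0 - 5.5) / np.std(np.arange(1.0, 11.0))
        assert awm.matrix.loc["s1", "FUA"] == pytest.approx(z11, abs=1e-12)
        # row labels: gene for set1, snp for set2
        assert list(prov.loc[["s1", "s2", "s4", "s7"], "row_label"]) == [
            "geneX", "geneY", "s4", "geneW"]

    def test_alpha_one_selects_everything(self):
        assoc, genes, _ = self.toy()
        cfg = AWMConfig(alpha=1.0, min_other=0, min_udder=0)
        awm = build_awm(assoc, genes, cfg)
        assert awm.counts["primary"] == 10
        assert awm.counts["rows"] == awm.counts["set1"] + awm.counts["set2"]

    def test_empty_selection_raises_with_counts(self):
        assoc, genes, p = self.toy()
        cfg = AWMConfig(alpha=1e-6)
        with pytest.raises(ValueError, match="stage counts"):
            build_awm(assoc, genes, cfg)

    def test_keep_all_primary_mode(self):
        assoc, genes, _ = self.toy()
        awm = build_awm(assoc, genes, AWMConfig(keep_all_primary=True))
        # all 7 primary SNP enter; s3 maps geneZ (10 kb boundary), s8 loses
        # the geneW dedupe, s9 on chrom 1 at 900 kb is 95 kb from geneW
        assert awm.counts["rows"] == 6
        assert set(awm.provenance.index) == {"s1", "s2", "s3", "s4", "s7", "s9"}


class TestTraitCorrelations:
    def test_duplicated_column_is_unit(self):
        rng = np.random.default_rng(7)
        m = pd.DataFrame(rng.standard_normal((20, 3)), columns=["a", "b", "c"])
        m["d"] = m["a"]
        c = awm_trait_correlations(m)
        assert c.loc["a", "d"] == pytest.approx(1.0)

    def test_matches_textbook_pearson(self):
        m = pd.DataFrame(
            [[1.0, 2.0, 0.5], [2.0, 1.0, 1.5], [3.0, 5.0, 2.0],
             [4.0, 3.0, 4.0], [5.0, 6.0, 3.5]],
            columns=["x", "y", "z"],
        )
        c = awm_trait_correlations(m)
        for a in m.columns:
            for b in m.columns:
                xa, xb = m[a] - m[a].mean(), m[b] - m[b].mean()
                r = (xa * xb).sum() / np.sqrt((xa**2).sum() * (xb**2).sum())
                assert c.loc[a, b] == pytest.approx(r, abs=1e-12)

    def test_too_few_rows_raises(self):
        with pytest.raises(ValueError):
            awm_trait_correlations(pd.DataFrame([[1.0, 2.0]], columns=["a", "b"]))


class TestCombineBreeds:
    def awm_with(self, snps, breed):
        prov = pd.DataFrame(
            {"set": "set2", "category": "beyond_10kb", "nearest_gene_id": "",
             "row_label": list(snps)},
            index=pd.Index(snps, name="snp_id"),
        )
        from awmpcit.awm import AWMatrix
        mat = pd.DataFrame(0.0, index=prov.index, columns=list(TRAIT_NAMES))
        return AWMatrix(matrix=mat, provenance=prov, breed=breed)

    def test_identical_and_disjoint(self):
        a = self.awm_with(["s1", "s2", "s3"], "A")
        b = self.awm_with(["s1", "s2", "s3"], "B")
        c = self.awm_with(["s1", "s2", "s3"], "C")
        out = combine_breeds(a, b, c)
        assert out["regions"]["all_three"] == 3
        assert out["n_common_snps"] == 3
        d = self.awm_with(["x1"], "B")
        e = self.awm_with(["y1"], "C")
        out = combine_breeds(a, d, e)
        assert out["n_common_snps"] == 0
        assert sum(out["regions"].values()) == 5

    def test_counts_match_set_algebra_oracle(self):
        rng = np.random.default_rng(8)
        universe = [f"s{i}" for i in range(40)]
        sets = [set(rng.choice(universe, size=rng.integers(5, 30), replace=False))
                for _ in range(3)]
        awms = [self.awm_with(sorted(s), b) for s, b in zip(sets, "ABC")]
        out = combine_breeds(*awms)
        a, b, c = sets
        assert out["regions"]["only_A"] == len(a - b - c)
        assert out["regions"]["A_B"] == len((a & b) - c)
        assert out["regions"]["all_three"] == len(a & b & c)
        assert sum(out["regions"].values()) == len(a | b | c)
        assert set(out["common_snp_ids"]) == a & b & c
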