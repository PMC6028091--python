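"""Association Weight Matrix construction from per-trait GWAS results.

The AWM is a SNP x trait matrix of z-score standardized allele-substitution
effects for SNP passing a multi-trait pleiotropy screen anchored on a key
trait (udder depth/development here).  The five construction steps:

1. primary selection: SNP with key-trait p below a nominal threshold;
2. trait dependency: the average number of non-key traits each primary SNP
   is associated with at the same threshold;
3. secondary selection: primary SNP associated with at least that many
   other traits, of which at least two are udder conformation traits;
4. genome map: each candidate SNP is classified as in a gene, within 10 kb
   of a gene, or beyond 10 kb; genes represented by several SNP keep the
   one associated with the most traits (ties: lowest mean p, then lowest
   position) -- the 1SNP:1gene rule;
5. the matrix rows are the deduplicated gene-assigned SNP (set1) plus the
   beyond-10 kb SNP (set2); cells are z-scored effects for all 12 traits
   regardless of per-trait significance.

Column-wise correlations of the AWM are the "SNP-based" trait correlations
compared against pedigree/true genetic correlations; rows feed PCIT.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gwas import AssocResult
from .simdata import GeneMap, KEY_TRAIT, TRAIT_NAMES, UDDER_TRAITS


@dataclass
class AWMConfig:
    alpha: float = 0.05
    key_trait: str = KEY_TRAIT
    min_udder: int = 2
    min_other: int | None = None          # None: data-driven from step 2
    window_bp: int = 10_000
    use_bonferroni: bool = False          # step-1 threshold on adjusted p
    keep_all_primary: bool = False        # rows = primary set, not just secondary
    udder_traits: tuple[str, ...] = UDDER_TRAITS


class AssocSet:
    """Per-breed bundle of AssocResult across traits with aligned SNP."""

    def __init__(self, results: dict[str, AssocResult]):
        if not results:
            raise ValueError("no association results")
        self.results = results
        first = next(iter(results.values()))
        self.breed = first.breed
        idx = first.table.index
        for r in results.values():
            if not r.table.index.equals(idx):
                raise ValueError("association results are not SNP-aligned")
        self.snp_ids = idx

    @property
    def traits(self) -> list[str]:
        return list(self.results)

    def effects(self) -> pd.DataFrame:
        return pd.DataFrame({t: r.table["effect"] for t, r in self.results.items()})

    def pvals(self, bonferroni: bool = False) -> pd.DataFrame:
        col = "p_bonferroni" if bonferroni else "p_raw"
        return pd.DataFrame({t: r.table[col] for t, r in self.results.items()})

    def meta(self) -> pd.DataFrame:
        return next(iter(self.results.values())).table[["chrom", "pos"]].copy()


@dataclass
class SnpGeneAssignment:
    """Per-SNP gene proximity classes within a 10-kb window."""

    table: pd.DataFrame  # index snp_id; category, nearest_gene_id, distance_bp

    def validate(self) -> None:
        t = self.table
        d = t["distance_bp"]
        bad = (
            ((t["category"] == "in_gene") & (d != 0))
            | ((t["category"] == "within_10kb") & ~d.between(1, 10_000))
            | ((t["category"] == "beyond_10kb") & (d <= 10_000) & np.isfinite(d))
        )
        if bad.any():
            raise ValueError("category inconsistent with distance")


@dataclass
class AWMatrix:
    """Selected SNP x traits matrix of z-scored effects with provenance."""

    matrix: pd.DataFrame       # index snp_id, columns traits
    provenance: pd.DataFrame   # index snp_id; row_label, set, category,
                               # nearest_gene_id, n_traits_associated, mean_p
    breed: str
    counts: dict[str, float] = field(default_factory=dict)

    @property
    def n_rows(self) -> int:
        return len(self.matrix)

    def row_labels(self) -> pd.Series:
        return self.provenance["row_label"]

    def snp_set(self) -> set[str]:
        return set(self.matrix.index)

    def gene_set(self) -> set[str]:
        prov = self.provenance
        return set(prov.loc[prov["set"] == "set1", "nearest_gene_id"])


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def zscore_effects(effects: pd.DataFrame) -> pd.DataFrame:
    """Standardize each trait column to mean 0, population SD 1."""
    if len(effects) < 2:
        raise ValueError("need at least 2 SNP per trait to z-score")
    mu = effects.mean(axis=0)
    sd = effects.std(axis=0, ddof=0)
    if (sd == 0).any():
        bad = sd.index[sd == 0].tolist()
        raise ValueError(f"constant effect column(s): {bad}")
    return (effects - mu) / sd


def select_primary(pvals: pd.DataFrame, key_trait: str = KEY_TRAIT,
                   alpha: float = 0.05) -> pd.Index:
    """SNP associated with the key trait at p < alpha (strict)."""
    if key_trait not in pvals.columns:
        raise ValueError(f"unknown key trait {key_trait!r}")
    mask = pvals[key_trait] < alpha
    return pvals.index[mask.fillna(False)]


def count_dependencies(selected: pd.Index, pvals: pd.DataFrame,
                       alpha: float = 0.05, key_trait: str = KEY_TRAIT) -> float:
    """Average number of non-key traits each selected SNP is associated with."""
    if len(selected) == 0:
        raise ValueError("empty primary selection")
    other = [t for t in pvals.columns if t != key_trait]
    counts = (pvals.loc[selected, other] < alpha).sum(axis=1)
    return float(counts.mean())


def select_secondary(
    pvals: pd.DataFrame,
    alpha: float = 0.05,
    min_other: int = 5,
    min_udder: int = 2,
    key_trait: str = KEY_TRAIT,
    udder_traits: tuple[str, ...] = UDDER_TRAITS,
    universe: pd.Index | None = None,
) -> pd.Index:
    """SNP from the primary set associated with >= min_other non-key traits,
    of which >= min_udder are (non-key) udder conformation traits."""
    if universe is None:
        universe = select_primary(pvals, key_trait, alpha)
    other = [t for t in pvals.columns if t != key_trait]
    udder_other = [t for t in other if t in udder_traits]
    sig = pvals.loc[universe, other] < alpha
    n_other = sig.sum(axis=1)
    n_udder = sig[udder_other].sum(axis=1)
    keep = (n_other >= min_other) & (n_udder >= min_udder)
    return universe[keep.to_numpy()]


def annotate_snps(snps: pd.DataFrame, genes: GeneMap,
                  window: int = 10_000) -> SnpGeneAssignment:
    """Assign each SNP its nearest gene and proximity class.

    ``snps`` has columns chrom, pos (1-based), indexed by snp_id.  Distance
    is the bp gap between the SNP position and the nearest interval edge
    (0 inside a gene); the window boundary is inclusive.  Ties are broken
    toward the gene with the lower start.  SNP on chromosomes without
    genes are beyond_10kb with an empty nearest gene.
    """
    category = np.full(len(snps), "beyond_10kb", dtype=object)
    nearest = np.full(len(snps), "", dtype=object)
    dist = np.full(len(snps), np.inf)

    for c in np.unique(snps["chrom"].to_numpy()):
        snp_m = (snps["chrom"] == c).to_numpy()
        gene_m = genes.chrom == c
        if not gene_m.any():
            continue
        g_start = genes.start[gene_m]
        g_end = genes.end[gene_m]
        g_ids = genes.gene_ids[gene_m]
        pos = snps.loc[snp_m, "pos"].to_numpy()
        # genes are sorted and non-overlapping; candidate neighbours are the
        # last gene starting at/before pos and the first starting after.
        right = np.searchsorted(g_start, pos, side="right")
        left = right - 1
        n_g = len(g_start)
        d_left = np.where(
            left >= 0,
            np.where(pos <= g_end[np.clip(left, 0, n_g - 1)], 0,
                     pos - g_end[np.clip(left, 0, n_g - 1)]),
            np.inf,
        )
        d_right = np.where(right < n_g,
                           g_start[np.clip(right, 0, n_g - 1)] - pos, np.inf)
        # tie toward the lower-start gene => prefer left on equality
        use_left = d_left <= d_right
        best_d = np.where(use_left, d_left, d_right)
        best_i = np.where(use_left, np.clip(left, 0, n_g - 1),
                          np.clip(right, 0, n_g - 1))
        dist[snp_m] = best_d
        nearest[snp_m] = g_ids[best_i]
        category[snp_m] = np.where(
            best_d == 0, "in_gene",
            np.where(best_d <= window, "within_10kb", "beyond_10kb"),
        )
    category[np.isinf(dist)] = "beyond_10kb"
    out = SnpGeneAssignment(
        pd.DataFrame(
            {"category": category, "nearest_gene_id": nearest,
             "distance_bp": dist},
            index=snps.index,
        )
    )
    out.validate()
    return out


def dedupe_per_gene(candidates: pd.DataFrame) -> pd.Index:
    """Apply the 1SNP:1gene rule to gene-assigned candidate SNP.

    ``candidates`` is indexed by snp_id with columns nearest_gene_id,
    n_traits_associated, mean_p, pos.  Per gene, keep the SNP with the
    most associated traits; ties go to the lowest mean raw p across all
    traits, then to the smallest position.
    """
    if candidates.empty:
        return candidates.index
    df = candidates.reset_index()
    df = df.sort_values(
        ["nearest_gene_id", "n_traits_associated", "mean_p", "pos"],
        ascending=[True, False, True, True],
        kind="mergesort",
    )
    keep = df.groupby("nearest_gene_id", sort=False).head(1)
    kept = candidates.index[candidates.index.isin(keep[candidates.index.name or "index"])]
    return kept


def build_awm(
    assoc: AssocSet | dict[str, AssocResult],
    genes: GeneMap,
    config: AWMConfig | None = None,
    allow_empty: bool = False,
) -> AWMatrix:
    """Run the five AWM construction steps for one breed."""
    if isinstance(assoc, dict):
        assoc = AssocSet(assoc)
    cfg = config or AWMConfig()

    pvals = assoc.pvals(bonferroni=cfg.use_bonferroni)
    effects = assoc.effects()
    meta = assoc.meta()
    zs = zscore_effects(effects)

    primary = select_primary(pvals, cfg.key_trait, cfg.alpha)
    counts: dict[str, float] = {"tested": len(pvals), "primary": len(primary)}
    if len(primary) == 0:
        if allow_empty:
            return _empty_awm(assoc, counts)
        raise ValueError(f"empty AWM selection; stage counts: {counts}")

    mean_dep = count_dependencies(primary, pvals, cfg.alpha, cfg.key_trait)
    min_other = cfg.min_other if cfg.min_other is not None else int(round(mean_dep))
    counts["mean_dependencies"] = mean_dep
    counts["min_other"] = min_other

    secondary = select_secondary(
        pvals, cfg.alpha, min_other, cfg.min_udder,
        cfg.key_trait, cfg.udder_traits, universe=primary,
    )
    counts["secondary"] = len(secondary)
    candidates = primary if cfg.keep_all_primary else secondary
    if len(candidates) == 0:
        if allow_empty:
            return _empty_awm(assoc, counts)
        raise ValueError(f"empty AWM selection; stage counts: {counts}")

    ann = annotate_snps(meta.loc[candidates], genes, cfg.window_bp)
    sig_any = pvals < cfg.alpha
    n_traits = sig_any.sum(axis=1)
    mean_p = pvals.mean(axis=1)

    cand = ann.table.copy()
    cand["n_traits_associated"] = n_traits.loc[candidates]
    cand["mean_p"] = mean_p.loc[candidates]
    cand["pos"] = meta.loc[candidates, "pos"]

    gene_assigned = cand[cand["category"] != "beyond_10kb"]
    set2_idx = cand.index[cand["category"] == "beyond_10kb"]
    counts["gene_assigned_before_dedupe"] = len(gene_assigned)
    set1_idx = dedupe_per_gene(gene_assigned)
    counts["set1"] = len(set1_idx)
    counts["set2"] = len(set2_idx)

    rows = meta.loc[set1_idx.union(set2_idx)].sort_values(["chrom", "pos"]).index
    prov = pd.DataFrame(index=rows)
    prov["set"] = np.where(cand.loc[rows, "category"] == "beyond_10kb", "set2", "set1")
    prov["category"] = cand.loc[rows, "category"]
    prov["nearest_gene_id"] = cand.loc[rows, "nearest_gene_id"]
    prov["distance_bp"] = cand.loc[rows, "distance_bp"]
    prov["row_label"] = np.where(prov["set"] == "set1",
                                 prov["nearest_gene_id"], rows)
    prov["selection_step"] = np.where(rows.isin(secondary), "secondary", "primary")
    prov["n_traits_associated"] = n_traits.loc[rows]
    prov["mean_p"] = mean_p.loc[rows]
    counts["rows"] = len(rows)

    return AWMatrix(matrix=zs.loc[rows], provenance=prov,
                    breed=assoc.breed, counts=counts)


def _empty_awm(assoc: AssocSet, counts: dict) -> AWMatrix:
    counts = dict(counts, set1=0, set2=0, rows=0)
    prov = pd.DataFrame(
        columns=["set", "category", "nearest_gene_id", "distance_bp",
                 "row_label", "selection_step", "n_traits_associated", "mean_p"]
    )
    return AWMatrix(
        matrix=pd.DataFrame(columns=assoc.traits), provenance=prov,
        breed=assoc.breed, counts=counts,
    )


def awm_trait_correlations(awm: AWMatrix | pd.DataFrame) -> pd.DataFrame:
    """Pearson correlations between trait columns over AWM rows."""
    mat = awm.matrix if isinstance(awm, AWMatrix) else awm
    if len(mat) < 3:
        raise ValueError("need at least 3 AWM rows for trait correlations")
    arr = mat.to_numpy(dtype=float)
    if (arr.std(axis=0) == 0).any():
        raise ValueError("constant trait column in AWM")
    c = np.corrcoef(arr, rowvar=False)
    return pd.DataFrame(c, index=mat.columns, columns=mat.columns)


def combine_breeds(*awms: AWMatrix) -> dict:
    """Venn-region counts of AWM SNP across breeds plus the common sets."""
    sets = {a.breed: a.snp_set() for a in awms}
    names = list(sets)
    out: dict = {"breeds": names}
    if len(names) == 3:
        a, b, c = (sets[n] for n in names)
        abc = a & b & c
        out["regions"] = {
            f"only_{names[0]}": len(a - b - c),
            f"only_{names[1]}": len(b - a - c),
            f"only_{names[2]}": len(c - a - b),
            f"{names[0]}_{names[1]}": len((a & b) - c),
            f"{names[0]}_{names[2]}": len((a & c) - b),
            f"{names[1]}_{names[2]}": len((b & c) - a),
            "all_three": len(abc),
        }
        common = abc
    else:
        common = set.intersection(*sets.values()) if sets else set()
        regions = {}
        for n, s in sets.items():
            others = [v for m, v in sets.items() if m != n]
            regions[f"only_{n}"] = len(s - set.union(*others)) if others else len(s)
        regions["common"] = len(common)
        out["regions"] = regions
    out["common_snp_ids"] = sorted(common)
    gene_sets = [a.gene_set() for a in awms]
    common_genes = set.intersection(*gene_sets) if gene_sets else set()
    out["common_gene_ids"] = sorted(common_genes)
    out["n_common_snps"] = len(common)
    out["n_common_genes"] = len(common_genes)
    return out
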