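"""Synthetic multi-breed genotype, gene-map and phenotype simulation.

The generator emulates the statistical structure that the downstream
mixed-model GWAS / association-weight-matrix / PCIT pipeline assumes for
dairy-cattle yield-deviation data:

* up to three breed cohorts of unequal size, genotyped at biallelic
  autosomal SNP with a near-uniform minor-allele-frequency spectrum;
* between-breed divergence modeled as Beta-perturbed allele frequencies
  around a shared ancestral frequency (one F-like parameter);
* 12 correlated traits (five udder conformation traits, five production
  traits, clinical mastitis and somatic cell score) with configurable
  heritabilities and genetic correlations and a sparse pleiotropic causal
  architecture (every causal SNP carries a dense effect vector drawn from a
  multivariate normal whose correlation is the target genetic correlation);
* a gene map dense enough that SNP both within 10 kb of a gene and beyond
  10 kb of every gene arise.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import is_psd, nearest_correlation

# The 12 analysis traits: five udder conformation traits, five milk
# production traits, clinical mastitis and somatic cell score.
TRAIT_NAMES: tuple[str, ...] = (
    "FUA", "UDD", "UC", "UB", "FTP",
    "MY", "FAT", "PROT", "FAT%", "PROT%",
    "CM", "SCS",
)
#: Udder conformation traits (five type traits, including the key trait).
UDDER_TRAITS: tuple[str, ...] = ("FUA", "UDD", "UC", "UB", "FTP")
#: Key trait anchoring primary SNP selection: udder depth / development.
KEY_TRAIT = "UDD"

TRAIT_ROLES: dict[str, str] = {
    "UDD": "key",
    "FUA": "udder", "UC": "udder", "UB": "udder", "FTP": "udder",
    "MY": "production", "FAT": "production", "PROT": "production",
    "FAT%": "production", "PROT%": "production",
    "CM": "health", "SCS": "health",
}

# Default genetic parameters: published pedigree-REML estimates for a
# Montbeliarde-like dairy population (heritability on the yield-deviation
# scale; CM is a low-heritability 0/1 liability trait).  Order matches
# _T4_ORDER; reindexed to TRAIT_NAMES below.
_T4_ORDER = ("FUA", "UDD", "FTP", "UB", "UC",
             "MY", "FAT", "PROT", "FAT%", "PROT%", "CM", "SCS")
_T4_H2 = (0.34, 0.37, 0.43, 0.36, 0.30, 0.50, 0.44, 0.44, 0.68, 0.66, 0.03, 0.39)
_T4_UPPER = [
    # FUA vs UDD..SCS
    [-0.11, -0.28, 0.40, 0.37, 0.42, 0.43, 0.39, 0.03, -0.05, 0.19, -0.05],
    [-0.39, -0.38, 0.37, 0.33, 0.32, 0.31, -0.02, -0.08, 0.09, 0.03],   # UDD
    [-0.24, -0.15, 0.20, 0.22, 0.21, 0.06, 0.04, 0.06, 0.02],           # FTP
    [-0.03, 0.02, 0.01, 0.00, 0.00, -0.03, -0.09, -0.02],               # UB
    [-0.01, -0.01, -0.01, -0.05, -0.06, 0.00, -0.05],                   # UC
    [0.88, 0.94, -0.22, -0.13, 0.02, 0.02],                             # MY
    [0.90, 0.26, 0.09, -0.01, 0.02],                                    # FAT
    [-0.06, 0.20, 0.01, 0.05],                                          # PROT
    [0.46, -0.03, -0.02],                                               # FAT%
    [-0.03, 0.00],                                                      # PROT%
    [0.20],                                                             # CM
]


def _default_params() -> tuple[pd.Series, pd.DataFrame]:
    t = len(_T4_ORDER)
    c = np.eye(t)
    for i, row in enumerate(_T4_UPPER):
        for k, v in enumerate(row):
            j = i + 1 + k
            c[i, j] = c[j, i] = v
    corr = pd.DataFrame(c, index=_T4_ORDER, columns=_T4_ORDER)
    corr = corr.loc[list(TRAIT_NAMES), list(TRAIT_NAMES)]
    corr.loc[:, :] = nearest_correlation(corr.to_numpy())
    h2 = pd.Series(_T4_H2, index=_T4_ORDER).loc[list(TRAIT_NAMES)]
    return h2, corr


DEFAULT_H2, DEFAULT_GENETIC_CORR = _default_params()


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class GenotypePanel:
    """Samples x SNP dosage matrix with SNP metadata and breed labels.

    ``dosage`` holds counted-allele dosages in {0,1,2}; -1 encodes a missing
    call (never produced by the simulator, accepted for user input).
    ``allele_freq`` is the per-breed observed frequency of the counted
    allele, shape (n_breeds, n_snps).
    """

    sample_ids: np.ndarray
    breed: np.ndarray
    snp_ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    dosage: np.ndarray
    breeds: tuple[str, ...]
    allele_freq: np.ndarray
    chrom_lengths: dict[int, int] | None = None
    ref_allele: str = "A"
    alt_allele: str = "C"

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def breed_mask(self, breed: str) -> np.ndarray:
        return self.breed == breed

    def observed_freq(self) -> np.ndarray:
        """Recompute per-breed counted-allele frequencies from dosage."""
        out = np.full((len(self.breeds), self.n_snps), np.nan)
        for b, name in enumerate(self.breeds):
            d = self.dosage[self.breed_mask(name)]
            obs = d >= 0
            with np.errstate(invalid="ignore"):
                out[b] = np.where(d >= 0, d, 0).sum(axis=0) / (2.0 * obs.sum(axis=0))
        return out

    def pooled_freq(self) -> np.ndarray:
        d = self.dosage
        obs = d >= 0
        return np.where(obs, d, 0).sum(axis=0) / (2.0 * obs.sum(axis=0))

    def maf_per_breed(self) -> np.ndarray:
        f = self.allele_freq
        return np.minimum(f, 1.0 - f)

    def subset_snps(self, mask: np.ndarray) -> "GenotypePanel":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return GenotypePanel(
            sample_ids=self.sample_ids,
            breed=self.breed,
            snp_ids=self.snp_ids[idx],
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            dosage=self.dosage[:, idx],
            breeds=self.breeds,
            allele_freq=self.allele_freq[:, idx],
            chrom_lengths=self.chrom_lengths,
            ref_allele=self.ref_allele,
            alt_allele=self.alt_allele,
        )

    def subset_breed(self, breed: str) -> "GenotypePanel":
        if breed not in self.breeds:
            raise ValueError(f"unknown breed {breed!r}")
        m = self.breed_mask(breed)
        sub = GenotypePanel(
            sample_ids=self.sample_ids[m],
            breed=self.breed[m],
            snp_ids=self.snp_ids,
            chrom=self.chrom,
            pos=self.pos,
            dosage=self.dosage[m],
            breeds=(breed,),
            allele_freq=np.empty((1, self.n_snps)),
            chrom_lengths=self.chrom_lengths,
            ref_allele=self.ref_allele,
            alt_allele=self.alt_allele,
        )
        sub.allele_freq = sub.observed_freq()
        return sub

    def validate(self) -> None:
        d = self.dosage
        if not np.isin(d[d >= 0], (0, 1, 2)).all():
            raise ValueError("dosage entries must be 0, 1 or 2 (or -1 missing)")
        if np.any(d < -1):
            raise ValueError("invalid dosage code below -1")
        if not np.allclose(self.observed_freq(), self.allele_freq,
                           atol=1e-12, equal_nan=True):
            raise ValueError("stored allele_freq inconsistent with dosage")
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if not np.all(np.diff(p) > 0):
                raise ValueError(f"positions not strictly increasing on chrom {c}")

    def snp_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"chrom": self.chrom, "pos": self.pos}, index=pd.Index(self.snp_ids, name="snp_id")
        )


@dataclass
class GeneMap:
    """Non-overlapping gene intervals, 1-based inclusive, sorted by (chrom, start)."""

    gene_ids: np.ndarray
    chrom: np.ndarray
    start: np.ndarray
    end: np.ndarray
    strand: np.ndarray
    chrom_lengths: dict[int, int] | None = None

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def validate(self) -> None:
        if self.n_genes == 0:
            return
        if np.any(self.start > self.end):
            raise ValueError("gene start > end")
        if len(np.unique(self.gene_ids)) != self.n_genes:
            raise ValueError("gene identifiers not unique")
        order = np.lexsort((self.start, self.chrom))
        if not np.array_equal(order, np.arange(self.n_genes)):
            raise ValueError("genes not sorted by (chrom, start)")
        for c in np.unique(self.chrom):
            m = self.chrom == c
            s, e = self.start[m], self.end[m]
            if np.any(s[1:] <= e[:-1]):
                raise ValueError(f"overlapping genes on chrom {c}")

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "gene_id": self.gene_ids, "chrom": self.chrom,
            "start": self.start, "end": self.end, "strand": self.strand,
        })

    def padded_coverage(self, window: int, chrom_lengths: dict[int, int]) -> float:
        """Exact fraction of the genome within ``window`` bp of a gene.

        Closed-form union of the padded intervals, clipped to chromosome
        bounds; positions are 1-based inclusive.
        """
        total = sum(chrom_lengths.values())
        covered = 0
        for c, length in chrom_lengths.items():
            m = self.chrom == c
            if not m.any():
                continue
            s = np.maximum(self.start[m] - window, 1)
            e = np.minimum(self.end[m] + window, length)
            cur_s, cur_e = None, None
            for a, b in zip(s, e):
                if cur_s is None:
                    cur_s, cur_e = a, b
                elif a <= cur_e + 1:
                    cur_e = max(cur_e, b)
                else:
                    covered += cur_e - cur_s + 1
                    cur_s, cur_e = a, b
            if cur_s is not None:
                covered += cur_e - cur_s + 1
        return covered / total


@dataclass
class TraitTable:
    """Per-cow yield deviations for the 12 traits."""

    sample_ids: np.ndarray
    breed: np.ndarray
    values: pd.DataFrame  # index sample_id, columns TRAIT_NAMES
    trait_role: dict[str, str] = field(default_factory=lambda: dict(TRAIT_ROLES))

    @property
    def trait_names(self) -> tuple[str, ...]:
        return tuple(self.values.columns)

    def udder_traits(self) -> tuple[str, ...]:
        return UDDER_TRAITS

    def validate(self) -> None:
        if self.trait_role.get(KEY_TRAIT) != "key":
            raise ValueError("UDD must be tagged key")
        udder = {t for t in self.trait_names if t in UDDER_TRAITS}
        if len(udder) != 5:
            raise ValueError("expected the 5 udder conformation traits")
        if self.values.index.has_duplicates:
            raise ValueError("one row per cow per trait expected")


@dataclass
class TruthSet:
    """Ground truth for parameter-recovery tests."""

    causal_snp_ids: np.ndarray
    true_effects: pd.DataFrame          # causal SNP x trait
    true_genetic_corr: pd.DataFrame     # trait x trait target
    true_h2: pd.Series
    seed: int
    genetic_values: pd.DataFrame | None = None   # sample x trait (breed-centered)
    realized_genetic_corr: pd.DataFrame | None = None
    realized_h2: pd.Series | None = None

    def validate(self) -> None:
        c = self.true_genetic_corr.to_numpy()
        if not np.allclose(c, c.T, atol=1e-10):
            raise ValueError("true_genetic_corr not symmetric")
        if not np.allclose(np.diag(c), 1.0, atol=1e-10):
            raise ValueError("true_genetic_corr diagonal must be 1")
        if not is_psd(c, tol=1e-6):
            raise ValueError("true_genetic_corr not positive semi-definite")
        h2 = self.true_h2.to_numpy()
        if np.any((h2 <= 0) | (h2 >= 1)):
            raise ValueError("true_h2 must lie in (0,1)")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def simulate_genotypes(
    n_per_breed: tuple[int, ...],
    n_snps: int,
    n_chrom: int = 5,
    maf_range: tuple[float, float] = (0.02, 0.5),
    seed: int = 0,
    divergence: float = 0.05,
    chrom_lengths: dict[int, int] | None = None,
    breeds: tuple[str, ...] = ("A", "B", "C"),
    ld_block_size: int = 1,
    ld_mismatch: float = 0.1,
) -> GenotypePanel:
    """Simulate dosage genotypes for up to three diverged breed cohorts.

    A shared ancestral counted-allele frequency is drawn uniformly on
    ``maf_range`` per SNP; each breed's frequency is a Beta perturbation
    around it with variance ``divergence * p * (1-p)`` (an F_ST-like
    parameter, default 0.05 -- of the order reported between European
    dairy breeds).  Dosages are binomial(2, p_breed) per sample; loci are
    independent unless ``ld_block_size > 1``, in which case SNP within a
    block copy a core SNP and disagree with probability ``ld_mismatch``
    (a crude block-LD mode).
    """
    lo, hi = float(maf_range[0]), float(maf_range[1])
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must be a sub-interval of (0, 0.5]")
    if any(int(n) <= 0 for n in n_per_breed):
        raise ValueError("cohort sizes must be positive")
    if len(n_per_breed) > len(breeds):
        raise ValueError("more cohorts than breed labels")
    if n_snps < n_chrom:
        raise ValueError("need n_snps >= n_chrom")
    if not (0.0 <= divergence < 1.0):
        raise ValueError("divergence must be in [0, 1)")

    rng = np.random.default_rng(seed)
    breeds = tuple(breeds[: len(n_per_breed)])
    n_total = int(sum(n_per_breed))

    p_anc = rng.uniform(lo, hi, n_snps) if lo < hi else np.full(n_snps, lo)

    dosage = np.empty((n_total, n_snps), dtype=np.int8)
    breed_labels = np.repeat(breeds, n_per_breed)
    row = 0
    for nb in n_per_breed:
        if divergence > 0:
            k = (1.0 - divergence) / divergence
            p_b = rng.beta(p_anc * k, (1.0 - p_anc) * k)
            p_b = np.clip(p_b, 5e-4, 1 - 5e-4)
        else:
            p_b = p_anc
        dosage[row : row + nb] = rng.binomial(2, p_b, size=(nb, n_snps)).astype(np.int8)
        row += nb

    if ld_block_size > 1:
        for b0 in range(0, n_snps, ld_block_size):
            core = dosage[:, b0]
            for j in range(b0 + 1, min(b0 + ld_block_size, n_snps)):
                keep = rng.random(n_total) < ld_mismatch
                dosage[:, j] = np.where(keep, dosage[:, j], core)

    if chrom_lengths is None:
        chrom_lengths = {c: 10_000_000 for c in range(1, n_chrom + 1)}
    chroms = sorted(chrom_lengths)
    counts = np.full(n_chrom, n_snps // n_chrom)
    counts[: n_snps % n_chrom] += 1
    chrom_arr = np.repeat(chroms, counts)
    pos = np.empty(n_snps, dtype=np.int64)
    i = 0
    for c, k in zip(chroms, counts):
        raw = np.sort(rng.integers(1, chrom_lengths[c] - k, size=k))
        pos[i : i + k] = raw + np.arange(k)  # strictly increasing
        i += k

    sample_ids = np.array(
        [f"{b}{j:05d}" for b, nb in zip(breeds, n_per_breed) for j in range(1, nb + 1)]
    )
    snp_ids = np.array([f"snp{c}_{p}" for c, p in zip(chrom_arr, pos)])

    panel = GenotypePanel(
        sample_ids=sample_ids,
        breed=breed_labels,
        snp_ids=snp_ids,
        chrom=chrom_arr.astype(np.int64),
        pos=pos,
        dosage=dosage,
        breeds=breeds,
        allele_freq=np.empty((len(breeds), n_snps)),
        chrom_lengths=dict(chrom_lengths),
    )
    panel.allele_freq = panel.observed_freq()
    return panel


def simulate_gene_map(
    n_genes: int,
    chrom_lengths: dict[int, int] | list[int],
    mean_gene_length: int = 15_000,
    seed: int = 0,
    min_gene_length: int = 200,
) -> GeneMap:
    """Place non-overlapping gene intervals with exponential lengths.

    Genes are allocated to chromosomes proportionally to length; within a
    chromosome the free space left after drawing gene lengths is split into
    random gaps (Dirichlet), which guarantees non-overlap by construction.
    """
    if isinstance(chrom_lengths, (list, tuple)):
        chrom_lengths = {i + 1: int(l) for i, l in enumerate(chrom_lengths)}
    total = sum(chrom_lengths.values())
    if n_genes == 0:
        empty = np.array([], dtype=np.int64)
        return GeneMap(np.array([], dtype=str), empty, empty, empty,
                       np.array([], dtype=str), dict(chrom_lengths))
    if total < n_genes * mean_gene_length:
        raise ValueError("infeasible packing: genome shorter than total gene length")

    rng = np.random.default_rng(seed)
    chroms = sorted(chrom_lengths)
    shares = np.array([chrom_lengths[c] for c in chroms], dtype=float) / total
    alloc = np.floor(shares * n_genes).astype(int)
    remainder = n_genes - alloc.sum()
    if remainder:
        frac = shares * n_genes - alloc
        for idx in np.argsort(-frac)[:remainder]:
            alloc[idx] += 1

    ids, chs, starts, ends, strands = [], [], [], [], []
    gid = 0
    for c, k in zip(chroms, alloc):
        if k == 0:
            continue
        length = chrom_lengths[c]
        glen = np.maximum(
            rng.exponential(mean_gene_length, size=k), min_gene_length
        ).astype(np.int64)
        free = length - int(glen.sum())
        if free < k:  # need at least 1 bp between/around genes
            raise ValueError(f"infeasible packing on chrom {c}")
        gaps = np.floor(rng.dirichlet(np.ones(k + 1)) * free).astype(np.int64)
        cursor = 0
        for j in range(k):
            start = cursor + gaps[j] + 1
            end = start + glen[j] - 1
            cursor = end
            gid += 1
            ids.append(f"G{gid:05d}")
            chs.append(c)
            starts.append(start)
            ends.append(end)
            strands.append("+" if rng.random() < 0.5 else "-")

    gm = GeneMap(
        gene_ids=np.array(ids),
        chrom=np.array(chs, dtype=np.int64),
        start=np.array(starts, dtype=np.int64),
        end=np.array(ends, dtype=np.int64),
        strand=np.array(strands),
        chrom_lengths=dict(chrom_lengths),
    )
    gm.validate()
    return gm


def n_genes_for_coverage(
    target_within: float,
    chrom_lengths: dict[int, int] | list[int],
    mean_gene_length: int = 15_000,
    window: int = 10_000,
) -> int:
    """Approximate gene count so ~``target_within`` of uniform SNP fall
    within ``window`` bp of a gene (ignores overlap of padded intervals)."""
    if isinstance(chrom_lengths, (list, tuple)):
        total = int(sum(chrom_lengths))
    else:
        total = int(sum(chrom_lengths.values()))
    return max(1, round(target_within * total / (mean_gene_length + 2 * window)))


def simulate_phenotypes(
    panel: GenotypePanel,
    n_causal: int,
    target_corr: pd.DataFrame | np.ndarray | None = None,
    target_h2: pd.Series | np.ndarray | None = None,
    seed: int = 0,
    cm_incidence: float = 0.25,
    trait_names: tuple[str, ...] = TRAIT_NAMES,
) -> tuple[TraitTable, TruthSet]:
    """Simulate correlated multi-trait phenotypes with known truth.

    Causal SNP are drawn without replacement; each carries a dense effect
    vector from a multivariate normal with correlation ``target_corr``
    (universal pleiotropy across traits, sparsity across SNP).  Residuals
    are scaled so the realized within-breed heritability matches
    ``target_h2``.  Clinical mastitis (CM) is produced by thresholding its
    latent liability at the (1 - ``cm_incidence``) quantile.
    """
    t = len(trait_names)
    if target_corr is None:
        target_corr = DEFAULT_GENETIC_CORR.loc[list(trait_names), list(trait_names)]
    corr = pd.DataFrame(np.asarray(target_corr, dtype=float),
                        index=trait_names, columns=trait_names)
    if target_h2 is None:
        target_h2 = DEFAULT_H2.loc[list(trait_names)]
    h2 = pd.Series(np.broadcast_to(np.asarray(target_h2, dtype=float), (t,)).copy(),
                   index=trait_names)

    if n_causal < 1 or n_causal > panel.n_snps:
        raise ValueError("n_causal must be in [1, n_snps]")
    c = corr.to_numpy()
    if not np.allclose(c, c.T, atol=1e-10) or not np.allclose(np.diag(c), 1.0):
        raise ValueError("target_corr must be a correlation matrix")
    if not is_psd(c):
        raise ValueError("target_corr is not positive semi-definite")
    if np.any((h2 <= 0) | (h2 >= 1)):
        raise ValueError("target_h2 must lie in (0,1)")
    if not (0.0 < cm_incidence < 1.0):
        raise ValueError("cm_incidence must lie in (0,1)")

    rng = np.random.default_rng(seed)
    causal_idx = np.sort(rng.choice(panel.n_snps, size=n_causal, replace=False))
    chol = np.linalg.cholesky(c + 1e-10 * np.eye(t))
    effects = rng.standard_normal((n_causal, t)) @ chol.T

    x = panel.dosage[:, causal_idx].astype(float)
    g = x @ effects

    # center genetic values within breed: GWAS is within breed and yield
    # deviations are pre-adjusted, so heritability targets the within-breed
    # variance ratio.
    gc = g.copy()
    for b in panel.breeds:
        m = panel.breed_mask(b)
        gc[m] -= gc[m].mean(axis=0)
    var_g = gc.var(axis=0)
    if np.any(var_g <= 0):
        raise ValueError("degenerate genetic variance; increase n_causal")
    sd_e = np.sqrt(var_g * (1.0 - h2.to_numpy()) / h2.to_numpy())
    y = g + rng.standard_normal(g.shape) * sd_e

    values = pd.DataFrame(y, index=pd.Index(panel.sample_ids, name="sample_id"),
                          columns=list(trait_names))
    realized_h2 = pd.Series(
        var_g / (var_g + sd_e**2), index=trait_names
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant columns impossible here
        realized_corr = pd.DataFrame(np.corrcoef(gc, rowvar=False),
                                     index=trait_names, columns=trait_names)

    if "CM" in values.columns:
        lia = values["CM"].to_numpy()
        thr = np.quantile(lia, 1.0 - cm_incidence)
        values["CM"] = (lia > thr).astype(float)

    traits = TraitTable(
        sample_ids=panel.sample_ids, breed=panel.breed, values=values
    )
    truth = TruthSet(
        causal_snp_ids=panel.snp_ids[causal_idx],
        true_effects=pd.DataFrame(effects, index=panel.snp_ids[causal_idx],
                                  columns=list(trait_names)),
        true_genetic_corr=corr,
        true_h2=h2,
        seed=int(seed),
        genetic_values=pd.DataFrame(gc, index=values.index, columns=list(trait_names)),
        realized_genetic_corr=realized_corr,
        realized_h2=realized_h2,
    )
    truth.validate()
    return traits, truth


def scs_from_scc(scc):
    """Somatic cell score from somatic cell count: SCS = 3 + log2(SCC/100000)."""
    scc = np.asarray(scc, dtype=float)
    if np.any(scc <= 0):
        raise ValueError("SCC must be positive")
    out = 3.0 + np.log2(scc / 100_000.0)
    return float(out) if out.ndim == 0 else out


def scc_from_scs(scs):
    """Inverse transform: SCC = 100000 * 2**(SCS - 3)."""
    scs = np.asarray(scs, dtype=float)
    out = 100_000.0 * np.exp2(scs - 3.0)
    return float(out) if out.ndim == 0 else out


def yd_heritability(var_additive: float, var_residual: float, n_records: float) -> float:
    """Heritability of a yield deviation averaged over ``n_records`` records.

    The permanent-environment variance is excluded because a yield deviation
    is already adjusted for it; averaging divides the residual variance by
    the number of records, e.g. 0.3 / (0.3 + 0.5/2.5) = 0.6.
    """
    if var_additive <= 0 or var_residual <= 0:
        raise ValueError("variances must be positive")
    if n_records < 1:
        raise ValueError("need at least one record")
    return var_additive / (var_additive + var_residual / n_records)
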