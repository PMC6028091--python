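import numpy as np
import pandas as pd
import pytest

from awmpcit import AssocSet, simulate_gene_map, simulate_genotypes
from awmpcit.gwas import AssocResult
from awmpcit.simdata import TRAIT_NAMES

CHROM_LENGTHS = {c: 10_000_000 for c in range(1, 6)}


@pytest.fixture(scope="session")
def small_panel():
    return simulate_genotypes((60, 50, 40), 300, n_chrom=5, seed=11,
                              chrom_lengths=CHROM_LENGTHS)


@pytest.fixture(scope="session")
def gene_map():
    return simulate_gene_map(60, CHROM_LENGTHS, mean_gene_length=20_000, seed=12)


def toy_assoc_set(pvals: pd.DataFrame, effects: pd.DataFrame | None = None,
                  meta: pd.DataFrame | None = None, breed: str = "A") -> AssocSet:
    """Assemble an AssocSet from a SNP x trait p-value table (plus optional
    effects and chrom/pos metadata) for hand-built selection tests."""
    n = len(pvals)
    if effects is None:
        rng = np.random.default_rng(0)
        effects = pd.DataFrame(rng.standard_normal(pvals.shape),
                               index=pvals.index, columns=pvals.columns)
    if meta is None:
        meta = pd.DataFrame(
            {"chrom": 1, "pos": np.arange(1, n + 1) * 1000}, index=pvals.index
        )
    results = {}
    for t in pvals.columns:
        tab = pd.DataFrame(
            {
                "chrom": meta["chrom"],
                "pos": meta["pos"],
                "effect_allele": "C",
                "maf": 0.3,
                "effect": effects[t],
                "se": 1.0,
                "p_raw": pvals[t],
                "p_bonferroni": np.minimum(1.0, pvals[t] * n),
                "n": 100,
                "reason": "",
            },
            index=pvals.index,
        )
        results[t] = AssocResult(breed=breed, trait=t, table=tab, m_tests=n)
    return AssocSet(results)


def uniform_pvals(n_snps: int, seed: int) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    idx = pd.Index([f"s{i}" for i in range(n_snps)], name="snp_id")
    return pd.DataFrame(rng.uniform(size=(n_snps, len(TRAIT_NAMES))),
                        index=idx, columns=list(TRAIT_NAMES))
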