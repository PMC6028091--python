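"""Quality control, genomic relationships and mixed-linear-model association.

The association model per breed, trait and SNP i is

    y = 1*mu + w_i * s_i + u + e,   u ~ N(0, G * var_u),  e ~ N(0, I * var_e)

where G is the genomic relationship matrix

    g_jk = (1/W) * sum_i (x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i (1 - p_i))

with observed cohort allele frequencies p_i and W markers.  Variance
components are estimated once per trait by REML on the null model (no SNP)
through a single eigendecomposition of G, then held fixed for the per-SNP
generalized-least-squares scan (the EMMA / GCTA-MLMA convention; a per-SNP
refit is available as a slow option).  The per-SNP test re-estimates the
residual scale from the GLS residuals and refers s_i / se to t(n-2), which
reduces exactly to the ordinary least-squares t-test when G = I.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .simdata import GenotypePanel


@dataclass
class QCThresholds:
    call_rate: float = 0.99
    maf: float = 0.02
    hwe_p: float = 1e-4


@dataclass
class QCReport:
    """Per-SNP QC metrics. pass_flag is True iff call_rate > threshold,
    max-over-breeds MAF > threshold and min-over-breeds HWE p >= threshold."""

    table: pd.DataFrame  # index snp_id; call_rate, maf_*, hwe_p, pass_flag, fail_reason
    thresholds: QCThresholds

    @property
    def n_pass(self) -> int:
        return int(self.table["pass_flag"].sum())


@dataclass
class GRM:
    """Genomic relationship matrix for one cohort."""

    sample_ids: np.ndarray
    matrix: np.ndarray
    _eig: tuple[np.ndarray, np.ndarray] | None = field(default=None, repr=False)

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def validate(self) -> None:
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise ValueError("GRM not symmetric")

    def eigen(self) -> tuple[np.ndarray, np.ndarray]:
        """Cached eigendecomposition; eigenvalues below -1e-8 are rejected,
        tiny negatives clipped to zero."""
        if self._eig is None:
            vals, vecs = np.linalg.eigh(self.matrix)
            if vals.min() < -1e-8 * max(1.0, vals.max()):
                raise ValueError("GRM is not positive semi-definite")
            self._eig = (np.clip(vals, 0.0, None), vecs)
        return self._eig


@dataclass
class MixedModelFit:
    """Null-model REML fit for one breed x trait."""

    trait: str
    breed: str
    mu: float
    var_u: float
    var_e: float
    loglik: float
    grm: GRM
    log_ratio: float  # log(var_u / var_e)

    @property
    def h2(self) -> float:
        return self.var_u / (self.var_u + self.var_e)


@dataclass
class AssocResult:
    """Per-SNP allele-substitution effects for one breed x trait."""

    breed: str
    trait: str
    table: pd.DataFrame  # index snp_id; chrom,pos,effect_allele,maf,effect,se,p_raw,p_bonferroni,n,reason
    m_tests: int

    def validate(self) -> None:
        t = self.table
        ok = t["p_raw"].dropna()
        if ((ok <= 0) | (ok > 1)).any():
            raise ValueError("p_raw outside (0,1]")
        exp = np.minimum(1.0, t["p_raw"] * self.m_tests)
        if not np.allclose(t["p_bonferroni"].dropna(), exp.dropna()):
            raise ValueError("p_bonferroni != min(1, p_raw * m)")


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def hwe_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """1-df chi-square goodness-of-fit p-value against Hardy-Weinberg
    proportions at the observed allele frequency."""
    counts = np.array([n_AA, n_Aa, n_aa], dtype=float)
    if np.any(counts < 0):
        raise ValueError("negative genotype count")
    n = counts.sum()
    if n == 0:
        raise ValueError("zero total genotype count")
    p = (2 * counts[0] + counts[1]) / (2 * n)
    expected = n * np.array([p * p, 2 * p * (1 - p), (1 - p) * (1 - p)])
    mask = expected > 0
    chi2 = float((((counts - expected) ** 2)[mask] / expected[mask]).sum())
    return float(stats.chi2.sf(chi2, df=1)) if chi2 > 0 else 1.0


def _hwe_many(n_AA: np.ndarray, n_Aa: np.ndarray, n_aa: np.ndarray) -> np.ndarray:
    n = (n_AA + n_Aa + n_aa).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = (2 * n_AA + n_Aa) / (2 * n)
        exp = np.stack([n * p * p, 2 * n * p * (1 - p), n * (1 - p) ** 2])
        obs = np.stack([n_AA, n_Aa, n_aa]).astype(float)
        terms = np.where(exp > 0, (obs - exp) ** 2 / np.where(exp > 0, exp, 1.0), 0.0)
        chi2 = terms.sum(axis=0)
    out = stats.chi2.sf(chi2, df=1)
    out[chi2 <= 0] = 1.0
    out[n == 0] = np.nan
    return out


def apply_qc(
    panel: GenotypePanel, thresholds: QCThresholds | None = None
) -> tuple[GenotypePanel, QCReport]:
    """Filter SNP on call rate, per-breed MAF and within-breed HWE.

    A SNP passes when its call rate exceeds the threshold, its MAF exceeds
    the threshold in at least one breed, and no breed shows a HWE
    departure below the p-value threshold.  ``fail_reason`` records the
    first failing rule in the order call_rate, maf, hwe.
    """
    if panel.n_snps == 0:
        raise ValueError("empty panel")
    thr = thresholds or QCThresholds()
    d = panel.dosage
    obs = d >= 0
    call_rate = obs.mean(axis=0)

    freq = panel.observed_freq()
    maf = np.minimum(freq, 1.0 - freq)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        maf_max = np.nanmax(maf, axis=0)

    hwe_p = np.full(panel.n_snps, np.nan)
    for b in panel.breeds:
        db = d[panel.breed_mask(b)]
        p_b = _hwe_many((db == 0).sum(axis=0), (db == 1).sum(axis=0),
                        (db == 2).sum(axis=0))
        hwe_p = np.fmin(hwe_p, p_b)

    pass_flag = (call_rate > thr.call_rate) & (maf_max > thr.maf) & (hwe_p >= thr.hwe_p)
    reason = np.where(call_rate <= thr.call_rate, "call_rate",
                      np.where(maf_max <= thr.maf, "maf",
                               np.where(hwe_p < thr.hwe_p, "hwe", "")))

    cols = {"call_rate": call_rate}
    for b_i, b in enumerate(panel.breeds):
        cols[f"maf_{b}"] = maf[b_i]
    cols.update(hwe_p=hwe_p, pass_flag=pass_flag, fail_reason=reason)
    report = QCReport(
        pd.DataFrame(cols, index=pd.Index(panel.snp_ids, name="snp_id")), thr
    )
    if not pass_flag.any():
        raise ValueError("QC removed every SNP")
    return panel.subset_snps(pass_flag), report


# ---------------------------------------------------------------------------
# GRM
# ---------------------------------------------------------------------------

def compute_grm(
    panel: GenotypePanel,
    freqs: np.ndarray | None = None,
    on_degenerate: str = "error",
) -> GRM:
    """Evaluate g_jk = (1/W) sum_i (x_ij-2p_i)(x_ik-2p_i) / (2 p_i (1-p_i)).

    ``freqs`` defaults to the observed counted-allele frequency of the
    cohort in ``panel`` (the within-breed convention: pass the breed
    subset).  SNP with 2p(1-p) < 1e-6 raise a division-by-zero error naming
    the SNP, or are dropped with a warning when ``on_degenerate='drop'``.
    Missing dosages are mean-imputed per SNP with a warning.
    """
    d = panel.dosage.astype(float)
    if (panel.dosage < 0).any():
        warnings.warn("missing dosages mean-imputed per SNP for GRM")
        col_mean = np.where(panel.dosage >= 0, d, np.nan)
        col_mean = np.nanmean(col_mean, axis=0)
        d = np.where(panel.dosage >= 0, d, col_mean[None, :])
    p = d.mean(axis=0) / 2.0 if freqs is None else np.asarray(freqs, dtype=float)
    het = 2.0 * p * (1.0 - p)
    degenerate = het < 1e-6
    if degenerate.any():
        bad = panel.snp_ids[degenerate]
        if on_degenerate == "drop":
            warnings.warn(f"dropping {len(bad)} near-monomorphic SNP from GRM")
            keep = ~degenerate
            d, p, het = d[:, keep], p[keep], het[keep]
        else:
            raise ZeroDivisionError(
                f"monomorphic SNP would divide by zero in GRM: {bad[0]}"
            )
    w = d.shape[1]
    if w == 0:
        raise ValueError("no usable SNP for GRM")
    m = (d - 2.0 * p) / np.sqrt(het)
    g = (m @ m.T) / w
    return GRM(sample_ids=panel.sample_ids, matrix=g)


# ---------------------------------------------------------------------------
# REML null model
# ---------------------------------------------------------------------------

def _reml_neg_ll(log_ratio: float, d_eig: np.ndarray, xt: np.ndarray,
                 yt: np.ndarray) -> float:
    """Negative REML log-likelihood profiled over var_e, for fixed
    ratio = var_u/var_e; data are rotated by the GRM eigenvectors."""
    n, p = xt.shape
    h = np.exp(log_ratio) * d_eig + 1.0
    w = 1.0 / h
    xtwx = xt.T @ (xt * w[:, None])
    xtwy = xt.T @ (yt * w)
    beta = np.linalg.solve(xtwx, xtwy)
    r = yt - xt @ beta
    rss = float(w @ (r * r))
    sigma2 = rss / (n - p)
    sign, logdet_xtwx = np.linalg.slogdet(xtwx)
    ll = -0.5 * ((n - p) * np.log(sigma2) + np.log(h).sum() + logdet_xtwx + (n - p))
    return -ll


def _reml_fit(d_eig, xt, yt, bounds=(-10.0, 10.0), tol=1e-8):
    res = optimize.minimize_scalar(
        _reml_neg_ll, args=(d_eig, xt, yt), bounds=bounds,
        method="bounded", options={"xatol": tol},
    )
    log_ratio = float(res.x)
    n, p = xt.shape
    h = np.exp(log_ratio) * d_eig + 1.0
    w = 1.0 / h
    xtwx = xt.T @ (xt * w[:, None])
    beta = np.linalg.solve(xtwx, xt.T @ (yt * w))
    r = yt - xt @ beta
    var_e = float(w @ (r * r)) / (n - p)
    var_u = np.exp(log_ratio) * var_e
    return log_ratio, beta, var_u, var_e, -float(res.fun)


def fit_null_model(grm: GRM, y: np.ndarray, trait: str = "", breed: str = "",
                   bounds: tuple[float, float] = (-10.0, 10.0)) -> MixedModelFit:
    """REML estimates of (var_u, var_e) for y = 1*mu + u + e.

    One-time eigendecomposition of G, then a bounded scalar search on
    log(var_u/var_e) with tolerance 1e-8.
    """
    y = np.asarray(y, dtype=float)
    if len(y) != grm.n:
        raise ValueError("phenotype length does not match GRM dimension")
    d_eig, u = grm.eigen()
    yt = u.T @ y
    xt = (u.T @ np.ones(grm.n)).reshape(-1, 1)
    log_ratio, beta, var_u, var_e, ll = _reml_fit(d_eig, xt, yt, bounds=bounds)
    return MixedModelFit(trait=trait, breed=breed, mu=float(beta[0]),
                         var_u=var_u, var_e=var_e, loglik=ll, grm=grm,
                         log_ratio=log_ratio)


# ---------------------------------------------------------------------------
# single-SNP scan
# ---------------------------------------------------------------------------

def mlma_scan(
    panel: GenotypePanel,
    y: np.ndarray,
    fit: MixedModelFit,
    m_tests: int | None = None,
    refit: bool = False,
) -> AssocResult:
    """Generalized-least-squares scan of every SNP against one trait.

    Variance components are fixed at the null REML fit (``refit=True``
    re-estimates them per SNP; slow).  The candidate SNP stays in G (no
    leave-one-chromosome-out).  Constant SNP are reported as missing with
    a reason.  Bonferroni correction uses ``m_tests`` (default: the panel
    SNP count).
    """
    y = np.asarray(y, dtype=float)
    n = panel.n_samples
    if len(y) != n or fit.grm.n != n:
        raise ValueError("cohort mismatch between panel, trait and fit")
    d_eig, u = fit.grm.eigen()
    m = m_tests if m_tests is not None else panel.n_snps

    dos = panel.dosage.astype(float)
    if (panel.dosage < 0).any():
        warnings.warn("missing dosages mean-imputed per SNP for association scan")
        col_mean = np.nanmean(np.where(panel.dosage >= 0, dos, np.nan), axis=0)
        dos = np.where(panel.dosage >= 0, dos, col_mean[None, :])
    constant = dos.std(axis=0) == 0

    yt = u.T @ y
    ot = u.T @ np.ones(n)
    wt = u.T @ dos  # rotated genotypes, n x n_snps

    if refit:
        effect = np.full(panel.n_snps, np.nan)
        se = np.full(panel.n_snps, np.nan)
        p_raw = np.full(panel.n_snps, np.nan)
        for j in range(panel.n_snps):
            if constant[j]:
                continue
            xt = np.column_stack([ot, wt[:, j]])
            log_ratio, beta, var_u, var_e, _ = _reml_fit(d_eig, xt, yt)
            h = np.exp(log_ratio) * d_eig + 1.0
            v = 1.0 / h
            xtwx = xt.T @ (xt * v[:, None])
            cov = np.linalg.inv(xtwx) * var_e
            effect[j] = beta[1]
            se[j] = np.sqrt(cov[1, 1])
            p_raw[j] = 2.0 * stats.t.sf(abs(effect[j] / se[j]), df=n - 2)
    else:
        ratio = np.exp(fit.log_ratio)
        v = 1.0 / (ratio * d_eig + 1.0)
        sxx = float(v @ (ot * ot))
        sxy = float(v @ (ot * yt))
        syy = float(v @ (yt * yt))
        sxw = (v * ot) @ wt
        sww = v @ (wt * wt)
        swy = (v * yt) @ wt
        det = sxx * sww - sxw**2
        with np.errstate(divide="ignore", invalid="ignore"):
            effect = (sxx * swy - sxw * sxy) / det
            mu_j = (sww * sxy - sxw * swy) / det
            rss = syy - mu_j * sxy - effect * swy
            sigma2 = np.clip(rss, 0.0, None) / (n - 2)
            se = np.sqrt(sigma2 * sxx / det)
            tstat = effect / se
        p_raw = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)
        effect[constant] = np.nan
        se[constant] = np.nan
        p_raw = np.where(constant, np.nan, p_raw)

    p_raw = np.clip(p_raw, np.finfo(float).tiny, 1.0)
    p_raw = np.where(constant, np.nan, p_raw)
    freq = dos.mean(axis=0) / 2.0
    table = pd.DataFrame(
        {
            "chrom": panel.chrom,
            "pos": panel.pos,
            "effect_allele": panel.alt_allele,
            "maf": np.minimum(freq, 1.0 - freq),
            "effect": effect,
            "se": se,
            "p_raw": p_raw,
            "p_bonferroni": np.minimum(1.0, p_raw * m),
            "n": n,
            "reason": np.where(constant, "constant", ""),
        },
        index=pd.Index(panel.snp_ids, name="snp_id"),
    )
    return AssocResult(breed=fit.breed, trait=fit.trait, table=table, m_tests=m)


def gwas_breed(
    panel: GenotypePanel,
    trait_values: pd.DataFrame,
    breed: str,
    m_tests: int | None = None,
    grm: GRM | None = None,
) -> dict[str, AssocResult]:
    """Run the per-trait mixed-model scan for one breed cohort.

    ``trait_values`` is indexed by sample id over at least the cohort's
    samples.  The GRM (and its eigendecomposition) is shared across traits.
    """
    cohort = panel.subset_breed(breed) if breed in panel.breeds and len(panel.breeds) > 1 else panel
    if grm is None:
        grm = compute_grm(cohort, on_degenerate="drop")
    out: dict[str, AssocResult] = {}
    values = trait_values.loc[cohort.sample_ids]
    for trait in values.columns:
        y = values[trait].to_numpy(dtype=float)
        fit = fit_null_model(grm, y, trait=trait, breed=breed)
        out[trait] = mlma_scan(cohort, y, fit, m_tests=m_tests)
    return out
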