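"""Per-SNP additive + dominance association and empirical inflation control.

Each SNP is tested with the genotypic OLS model

    y = mu + X_PC b_PC + z a + w d + e

where z is the centered allele count (0/1/2), w the heterozygosity
indicator, and X_PC the leading principal components of the dummy-coded
pen / rearing-pen design (enough to explain >99% of the fixed-effect
variation).  a and d get marginal two-sided Wald t-tests.  Individuals
with a missing call at the SNP are dropped casewise.

Residual stratification shows up as genomic inflation; the empirical
correction regresses observed -log10(p) below a cutoff on their
expected quantiles -log10((i-0.5)/m) (through the origin by default)
and divides ALL observed -log10(p) by the fitted slope, separately for
the additive and dominance channels.  Division by a positive constant
preserves ranking.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from keelgen.dataio import GenotypeMatrix

__all__ = [
    "GwasRecord",
    "InflationFit",
    "build_covariates",
    "fit_snp",
    "run_gwas",
    "correct_inflation",
    "significance_thresholds",
]


@dataclasses.dataclass
class GwasRecord:
    """Association result for one SNP."""

    snp_id: str
    chrom: str
    pos: int
    beta_add: float
    beta_dom: float
    p_add: float
    p_dom: float
    n0: int
    n1: int
    n2: int
    n_missing: int
    maf: float
    flag: str = ""  # "" = scored; otherwise reason the SNP was not scored

    @property
    def neglog10_p_add(self) -> float:
        return -np.log10(self.p_add) if self.p_add == self.p_add else float("nan")

    @property
    def neglog10_p_dom(self) -> float:
        return -np.log10(self.p_dom) if self.p_dom == self.p_dom else float("nan")


@dataclasses.dataclass
class InflationFit:
    """Slope of observed on expected -log10(p) among sub-cutoff points."""

    beta: float
    n_points_used: int
    applied_to: str  # "additive" or "dominance"
    intercept: float = 0.0

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError("inflation slope must be positive")


def build_covariates(samples: pd.DataFrame, variance_keep: float = 0.99) -> np.ndarray:
    """PCs of the dummy-coded pen x rearing-pen design.

    Dummy-codes both factors (all levels), centers the columns, and
    returns the smallest leading set of principal-component scores whose
    cumulative variance fraction exceeds ``variance_keep``.  With a
    single level in both factors the centered design is zero and an
    empty (n x 0) matrix is returned.
    """
    for col in ("pen", "rearing_pen"):
        if col not in samples.columns:
            raise ValueError(f"sample table lacks {col!r}")
    D = pd.get_dummies(samples[["pen", "rearing_pen"]].astype(str), dtype=float).to_numpy()
    Dc = D - D.mean(axis=0)
    U, s, _ = np.linalg.svd(Dc, full_matrices=False)
    var = s**2
    keep = var > 1e-10 * max(var.max(), 1.0) if var.size else np.array([], dtype=bool)
    var = var[keep]
    if var.size == 0:
        return np.empty((len(samples), 0))
    frac = np.cumsum(var) / var.sum()
    k = int(np.searchsorted(frac, variance_keep) + 1)
    k = min(k, var.size)
    return U[:, :k] * s[:k]


def fit_snp(y, covariates, dosages) -> GwasRecord:
    """Genotypic-model OLS for one SNP with casewise deletion.

    Requires >= 10 individuals with a non-missing call and >= 2 genotype
    classes among them.  When only two classes are present the
    heterozygosity column is collinear with the dosage and is dropped
    (its p-value is reported missing).
    """
    y = np.asarray(y, dtype=float).ravel()
    g = np.asarray(dosages, dtype=float).ravel()
    C = np.empty((y.size, 0)) if covariates is None else np.asarray(covariates, dtype=float)
    if C.ndim == 1:
        C = C[:, None]

    obs = ~np.isnan(g) & ~np.isnan(y)
    n_missing = int(np.isnan(g).sum())
    gg = g[obs]
    n0, n1, n2 = int((gg == 0).sum()), int((gg == 1).sum()), int((gg == 2).sum())
    freq = gg.mean() / 2.0 if gg.size else float("nan")
    maf = min(freq, 1.0 - freq) if gg.size else float("nan")
    base = dict(n0=n0, n1=n1, n2=n2, n_missing=n_missing, maf=maf,
                snp_id="", chrom="", pos=0)

    classes = np.unique(gg)
    if gg.size < 10:
        return GwasRecord(beta_add=np.nan, beta_dom=np.nan, p_add=np.nan, p_dom=np.nan,
                          flag="too_few_calls", **base)
    if classes.size < 2:
        return GwasRecord(beta_add=np.nan, beta_dom=np.nan, p_add=np.nan, p_dom=np.nan,
                          flag="monomorphic", **base)

    yy = y[obs]
    z = gg - gg.mean()
    w = (gg == 1).astype(float)
    with_dom = classes.size == 3
    cols = [np.ones(gg.size), *([C[obs][:, j] for j in range(C.shape[1])]), z]
    if with_dom:
        cols.append(w)
    X = np.column_stack(cols)

    XtX = X.T @ X
    rank = np.linalg.matrix_rank(XtX)
    if rank < X.shape[1]:
        return GwasRecord(beta_add=np.nan, beta_dom=np.nan, p_add=np.nan, p_dom=np.nan,
                          flag="collinear", **base)
    beta, res_ss, _, _ = np.linalg.lstsq(X, yy, rcond=None)
    resid = yy - X @ beta
    df = gg.size - X.shape[1]
    if df <= 0:
        return GwasRecord(beta_add=np.nan, beta_dom=np.nan, p_add=np.nan, p_dom=np.nan,
                          flag="no_residual_df", **base)
    s2 = float(resid @ resid) / df
    cov = s2 * np.linalg.inv(XtX)
    idx_add = 1 + C.shape[1]
    t_add = beta[idx_add] / np.sqrt(cov[idx_add, idx_add])
    p_add = 2.0 * stats.t.sf(abs(t_add), df)
    if with_dom:
        idx_dom = idx_add + 1
        t_dom = beta[idx_dom] / np.sqrt(cov[idx_dom, idx_dom])
        p_dom = 2.0 * stats.t.sf(abs(t_dom), df)
        beta_dom = float(beta[idx_dom])
    else:
        p_dom, beta_dom = np.nan, np.nan
    # a p-value of exactly 0 only arises from floating underflow on an exact fit
    p_add = max(float(p_add), np.nextafter(0, 1))
    return GwasRecord(beta_add=float(beta[idx_add]), beta_dom=beta_dom,
                      p_add=p_add, p_dom=float(p_dom) if p_dom == p_dom else np.nan,
                      **base)


def run_gwas(geno: GenotypeMatrix, samples: pd.DataFrame, covariates: np.ndarray | None = None,
             trait: str = "log_kbf") -> pd.DataFrame:
    """Apply :func:`fit_snp` to every SNP; returns a Table-2-shaped frame.

    The sample table must be aligned to ``geno.sample_ids`` and carry the
    (log-transformed) trait column.  Per-SNP failures are flagged, never
    raised.
    """
    if trait not in samples.columns:
        raise ValueError(f"trait column {trait!r} missing; run the log transform first")
    ids = list(samples["sample_id"].astype(str)) if "sample_id" in samples.columns else None
    if ids is not None and ids != list(geno.sample_ids):
        raise ValueError("sample table is not aligned with the genotype matrix")
    y = samples[trait].to_numpy(dtype=float)
    rows = []
    info = geno.snp_info
    for j in range(geno.n_snps):
        rec = fit_snp(y, covariates, geno.dosages[:, j])
        rec.snp_id = info["snp_id"].iloc[j]
        rec.chrom = info["chrom"].iloc[j]
        rec.pos = int(info["pos"].iloc[j])
        rows.append(rec)
    df = pd.DataFrame([dataclasses.asdict(r) for r in rows])
    with np.errstate(divide="ignore"):
        df["neglog10_p_add"] = -np.log10(df["p_add"])
        df["neglog10_p_dom"] = -np.log10(df["p_dom"])
    return df


def correct_inflation(records: pd.DataFrame, channel: str = "additive", cutoff: float = 3.0,
                      intercept: bool = False) -> tuple[pd.DataFrame, InflationFit]:
    """Divide a channel's -log10(p) by the empirical inflation slope.

    The slope regresses observed -log10(p) on expected quantiles
    -log10((i-0.5)/m) using only points with observed -log10(p) below
    ``cutoff``; ALL observed values are then divided by it.  Channels are
    corrected independently.
    """
    if channel not in ("additive", "dominance"):
        raise ValueError("channel must be 'additive' or 'dominance'")
    col = "neglog10_p_add" if channel == "additive" else "neglog10_p_dom"
    df = records.copy()
    obs_all = df[col].to_numpy(dtype=float)
    scored = np.flatnonzero(np.isfinite(obs_all))
    if scored.size < 100:
        raise ValueError(f"need >= 100 scored SNPs, have {scored.size}")
    obs = obs_all[scored]
    m = obs.size
    order = np.argsort(-obs)  # descending observed = ascending p
    expected = np.empty(m)
    expected[order] = -np.log10((np.arange(1, m + 1) - 0.5) / m)

    use = obs < cutoff
    x, yv = expected[use], obs[use]
    if intercept:
        A = np.column_stack([x, np.ones(x.size)])
        slope, icpt = np.linalg.lstsq(A, yv, rcond=None)[0]
    else:
        slope, icpt = float(x @ yv) / float(x @ x), 0.0
    if slope <= 0:
        raise ValueError(f"degenerate inflation slope {slope:.4g}")

    corrected = np.full_like(obs_all, np.nan)
    corrected[scored] = obs / slope
    df[col + "_corr"] = corrected
    df["p_" + ("add" if channel == "additive" else "dom") + "_corr"] = 10.0 ** (-corrected)
    fit = InflationFit(beta=float(slope), n_points_used=int(use.sum()),
                       applied_to=channel, intercept=float(icpt))
    return df, fit


def significance_thresholds(m_independent: int, alpha_genomewide: float = 0.05,
                            alpha_suggestive: float = 0.10) -> tuple[float, float]:
    """Bonferroni thresholds alpha/m at the genome-wide and suggestive levels."""
    if m_independent < 1:
        raise ValueError("m_independent must be >= 1")
    return alpha_genomewide / m_independent, alpha_suggestive / m_independent
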