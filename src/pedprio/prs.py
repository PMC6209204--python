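"""Polygenic risk scoring and kinship-aware association in families.

Workflow: greedy p-value clumping of GWAS summary statistics against the
sample LD; scoring of effect-allele dosages with all effects oriented
positive, scaled to a relative risk load in [0, 1] (0 = no risk allele
carried, 1 = homozygous for every risk allele); a polygenic linear mixed
model ``phenotype ~ covariates`` with the genetic relationship matrix as a
random effect, fitted by REML, whose environmental residuals are then tested
in a second linear model ``residuals ~ PRS``.  Inference on the slope uses
ordinary nonparametric bootstrap percentile intervals and a one-sided
permutation test, at each of ten GWAS p-value inclusion thresholds with a
Bonferroni flag for the ten tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .pedigree import Pedigree

__all__ = [
    "DEFAULT_THRESHOLDS",
    "DosageMatrix",
    "KinshipMatrix",
    "PrsResult",
    "AssocResult",
    "clump",
    "score",
    "grm",
    "expected_kinship",
    "polygenic_residuals",
    "PolygenicFit",
    "PrsAssociation",
    "prs_association",
    "threshold_sweep",
    "read_summary_stats",
]

#: The ten GWAS p-value inclusion thresholds.
DEFAULT_THRESHOLDS = (5e-8, 1e-7, 1e-6, 1e-5, 1e-4, 1e-3, 0.01, 0.05, 0.1, 0.2)


@dataclass
class DosageMatrix:
    """Effect-allele dosages, individuals x SNPs, with SNP metadata
    (columns chrom, pos, and optionally effect_allele/other_allele)."""

    dosages: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        d = self.dosages.to_numpy(float)
        if np.nanmin(d) < -1e-9 or np.nanmax(d) > 2 + 1e-9:
            raise ValueError("dosages must lie in [0, 2]")
        if self.dosages.columns.duplicated().any():
            raise ValueError("duplicate SNP ids")
        if not self.meta.index.equals(self.dosages.columns):
            self.meta = self.meta.loc[self.dosages.columns]

    @property
    def snps(self) -> list[str]:
        return list(self.dosages.columns)

    @property
    def individuals(self) -> list[str]:
        return list(self.dosages.index)


@dataclass
class KinshipMatrix:
    """Symmetric relationship matrix.  ``source='genomic'`` is on the
    relationship scale (diagonal ~ 1 + inbreeding); ``'pedigree_expected'``
    is on the kinship scale (diagonal 0.5 for non-inbred individuals) and is
    doubled internally when used as a random-effect covariance."""

    values: np.ndarray
    ids: list[str]
    source: str = "genomic"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or not np.allclose(v, v.T, atol=1e-8):
            raise ValueError("kinship matrix must be square and symmetric")
        self.values = v

    def relationship(self) -> np.ndarray:
        """Covariance-scale matrix (diagonal ~ 1)."""
        return 2 * self.values if self.source == "pedigree_expected" else self.values


def read_summary_stats(path) -> pd.DataFrame:
    """Read GWAS summary statistics: whitespace/TSV with columns
    SNP, CHR, BP, A1, A2, BETA (or OR, converted to log-odds), P."""
    df = pd.read_csv(path, sep=None, engine="python")
    df = df.rename(
        columns={"SNP": "snp", "CHR": "chrom", "BP": "pos", "A1": "effect_allele",
                 "A2": "other_allele", "BETA": "beta", "P": "p", "OR": "OR"}
    )
    if "beta" not in df and "OR" in df:
        df["beta"] = np.log(df["OR"].astype(float))
    need = {"snp", "chrom", "pos", "effect_allele", "beta", "p"}
    if not need <= set(df.columns):
        raise ValueError(f"summary statistics missing columns {need - set(df.columns)}")
    if ((df["p"] <= 0) | (df["p"] > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    return df


def clump(
    stats_df: pd.DataFrame,
    geno: DosageMatrix,
    r2_max: float = 0.1,
    window_kb: float = 500.0,
) -> list[str]:
    """Greedy p-value clumping.

    SNPs are visited by ascending p (ties broken by SNP id); each index SNP
    is retained and any unvisited SNP on the same chromosome within
    *window_kb* whose squared dosage correlation with it exceeds *r2_max* is
    discarded.  Windows never span chromosomes.
    """
    shared = [s for s in stats_df["snp"] if s in set(geno.snps)]
    if not shared:
        raise ValueError("no SNPs shared between summary statistics and genotypes")
    sub = stats_df.set_index("snp").loc[shared]
    order = sub.sort_values(["p", "chrom", "pos"]).index
    order = sorted(order, key=lambda s: (sub.loc[s, "p"], s))
    X = geno.dosages
    removed: set[str] = set()
    kept: list[str] = []
    for s in order:
        if s in removed:
            continue
        kept.append(s)
        chrom, pos = sub.loc[s, "chrom"], sub.loc[s, "pos"]
        near = sub[(sub["chrom"] == chrom) & (abs(sub["pos"] - pos) <= window_kb * 1000)]
        x = X[s].to_numpy(float)
        if x.std() == 0:
            continue
        for t in near.index:
            if t == s or t in removed or t in kept:
                continue
            y = X[t].to_numpy(float)
            if y.std() == 0:
                continue
            if np.corrcoef(x, y)[0, 1] ** 2 > r2_max:
                removed.add(t)
    return kept


@dataclass
class PrsResult:
    """Scaled per-individual risk load at one inclusion threshold."""

    threshold: float
    scores: pd.Series
    n_snps: int
    undefined: bool = False

    def __post_init__(self) -> None:
        if not self.undefined:
            s = self.scores.to_numpy(float)
            if np.nanmin(s) < -1e-9 or np.nanmax(s) > 1 + 1e-9:
                raise ValueError("scaled scores must lie in [0, 1]")


def score(
    geno: DosageMatrix,
    stats_df: pd.DataFrame,
    threshold: float,
    snps: Sequence[str] | None = None,
) -> PrsResult:
    """Scaled polygenic score at one p-value threshold.

    SNPs with p < threshold (restricted to *snps*, e.g. a clumped set) are
    oriented so every effect is positive (a negative beta flips the effect
    allele: beta -> -beta, dosage d -> 2 - d), summed as ``raw = sum b_i d_i``
    and scaled to ``raw / (2 sum b_i)`` in [0, 1].  Zero qualifying SNPs
    yield an undefined-flagged result, not an exception.
    """
    sub = stats_df[stats_df["p"] < threshold]
    use = [s for s in sub["snp"] if s in set(geno.snps)]
    if snps is not None:
        use = [s for s in use if s in set(snps)]
    if not use:
        return PrsResult(threshold, pd.Series(np.nan, index=geno.dosages.index),
                         n_snps=0, undefined=True)
    beta = sub.set_index("snp").loc[use, "beta"].to_numpy(float)
    D = geno.dosages[use].to_numpy(float)
    flip = beta < 0
    beta = np.abs(beta)
    D = np.where(flip[None, :], 2.0 - D, D)
    raw = D @ beta
    scaled = raw / (2.0 * beta.sum())
    return PrsResult(threshold, pd.Series(scaled, index=geno.dosages.index), len(use))


def grm(geno: DosageMatrix) -> KinshipMatrix:
    """Standardized (VanRaden-type) genomic relationship matrix:
    columns centred at 2p and scaled by sqrt(2p(1-p)), cross-product
    averaged over SNPs."""
    X = geno.dosages.to_numpy(float)
    p = X.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("need at least one polymorphic SNP")
    Xp = X[:, poly]
    pp = p[poly]
    Z = (Xp - 2 * pp) / np.sqrt(2 * pp * (1 - pp))
    G = Z @ Z.T / Z.shape[1]
    return KinshipMatrix(G, list(geno.dosages.index), source="genomic")


def expected_kinship(ped: Pedigree) -> KinshipMatrix:
    """Pedigree-expected kinship coefficients (recursive tabular method)."""
    order = [i for i in ped.members() if ped[i].is_founder]
    order += ped.topological_nonfounders()
    n = len(order)
    pos = {iid: k for k, iid in enumerate(order)}
    K = np.zeros((n, n))
    for i, iid in enumerate(order):
        ind = ped[iid]
        if ind.is_founder:
            K[i, i] = 0.5
        else:
            f, m = pos[ind.father], pos[ind.mother]
            K[i, i] = 0.5 * (1 + K[f, m])
            for j in range(i):
                K[i, j] = K[j, i] = 0.5 * (K[f, j] + K[m, j])
    # reorder to the pedigree's member order
    member_order = ped.members()
    idx = [pos[i] for i in member_order]
    return KinshipMatrix(K[np.ix_(idx, idx)], member_order, source="pedigree_expected")


@dataclass
class PolygenicFit:
    """REML fit of the polygenic mixed model."""

    residuals: pd.Series  # environmental residuals (default) or full
    beta: np.ndarray
    sigma_g2: float
    sigma_e2: float
    h2: float
    loglik: float
    residual_type: str = "environmental"


def polygenic_residuals(
    phenotype: Sequence[float] | pd.Series,
    covariates: pd.DataFrame | np.ndarray | None,
    K: KinshipMatrix,
    residual_type: str = "environmental",
) -> PolygenicFit:
    """Fit ``phenotype ~ covariates`` with a polygenic random effect.

    The covariance model is ``V = sigma_g^2 * A + sigma_e^2 * I`` where
    ``A`` is the relationship-scale matrix (2x kinship for pedigree-expected
    input).  Variance components maximize the restricted likelihood via a
    1-D profile over the ratio ``lambda = sigma_g^2 / sigma_e^2`` after
    eigendecomposition of A.  ``residual_type='environmental'`` subtracts
    both the fixed effects and the BLUP of the random effect;
    ``'full'`` subtracts the fixed effects only.  Binary phenotypes are
    treated on the observed 0/1 scale.

    An intercept is always included.  A non-positive-definite A (after
    bending by a small ridge) or singular covariates raise ``ValueError``.
    """
    y = np.asarray(
        phenotype.to_numpy() if isinstance(phenotype, pd.Series) else phenotype, float
    )
    n = len(y)
    index = phenotype.index if isinstance(phenotype, pd.Series) else pd.RangeIndex(n)
    if covariates is None:
        X = np.ones((n, 1))
    else:
        C = covariates.to_numpy(float) if isinstance(covariates, pd.DataFrame) else np.asarray(covariates, float)
        if C.ndim == 1:
            C = C[:, None]
        X = np.column_stack([np.ones(n), C])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("covariate matrix is singular")

    A = K.relationship()
    if A.shape[0] != n:
        raise ValueError("kinship dimension does not match phenotype length")
    w, U = np.linalg.eigh(A)
    if w.min() < -1e-6 * max(1.0, abs(w.max())):
        # bend: shift all eigenvalues up by the deficit
        shift = -w.min() + 1e-8
        w = w + shift
    w = np.clip(w, 1e-12, None)
    if not np.isfinite(w).all():
        raise ValueError("relationship matrix is not positive definite after bending")

    yt, Xt = U.T @ y, U.T @ X
    p = X.shape[1]

    def reml_neg(log_lam: float) -> float:
        lam = math.exp(log_lam)
        d = lam * w + 1.0
        Wi = 1.0 / d
        XtWX = Xt.T @ (Wi[:, None] * Xt)
        XtWy = Xt.T @ (Wi * yt)
        beta = np.linalg.solve(XtWX, XtWy)
        r = yt - Xt @ beta
        rss = float(r @ (Wi * r))
        sig_e = rss / (n - p)
        _, ld_xwx = np.linalg.slogdet(XtWX)
        ll = -0.5 * ((n - p) * math.log(sig_e) + np.log(d).sum() + ld_xwx + (n - p))
        return -ll

    grid = np.linspace(-12, 12, 49)
    vals = [reml_neg(g) for g in grid]
    g0 = grid[int(np.argmin(vals))]
    from scipy.optimize import minimize_scalar

    res = minimize_scalar(reml_neg, bounds=(g0 - 1.5, g0 + 1.5), method="bounded")
    lam = math.exp(float(res.x))
    # boundary handling: effectively zero genetic variance
    if reml_neg(-12.0) <= res.fun + 1e-9:
        lam = 0.0

    d = lam * w + 1.0
    Wi = 1.0 / d
    XtWX = Xt.T @ (Wi[:, None] * Xt)
    beta = np.linalg.solve(XtWX, Xt.T @ (Wi * yt))
    r = yt - Xt @ beta
    sigma_e2 = float(r @ (Wi * r)) / (n - p)
    sigma_g2 = lam * sigma_e2
    # BLUP of the random effect, rotated back
    g_blup = U @ ((lam * w / d) * r)
    fixed = X @ beta
    if residual_type == "environmental":
        resid = y - fixed - g_blup
    elif residual_type == "full":
        resid = y - fixed
    else:
        raise ValueError("residual_type must be 'environmental' or 'full'")
    h2 = sigma_g2 / (sigma_g2 + sigma_e2) if sigma_g2 + sigma_e2 > 0 else 0.0
    return PolygenicFit(
        residuals=pd.Series(resid, index=index),
        beta=beta,
        sigma_g2=sigma_g2,
        sigma_e2=sigma_e2,
        h2=h2,
        loglik=-float(res.fun),
        residual_type=residual_type,
    )


@dataclass
class AssocResult:
    """Association of polygenic load with the phenotype residuals."""

    threshold: float | None
    slope: float
    se: float
    r2: float
    ci95: tuple[float, float]
    p_one_sided: float
    p_perm: float
    n_boot: int
    n_perm: int
    seed: int | None
    n_snps: int | None = None
    undefined: bool = False

    def summary(self) -> str:
        lines = [
            "PRS association (residuals ~ PRS)",
            "=" * 46,
            f"{'threshold':<18}{self.threshold}",
            f"{'slope':<18}{self.slope:.6g}",
            f"{'SE':<18}{self.se:.6g}",
            f"{'R2':<18}{self.r2:.4f}",
            f"{'95% CI (boot)':<18}[{self.ci95[0]:.6g}, {self.ci95[1]:.6g}]",
            f"{'p (one-sided)':<18}{self.p_one_sided:.4g}",
            f"{'p (permutation)':<18}{self.p_perm:.4g}",
            f"{'n_boot/n_perm':<18}{self.n_boot}/{self.n_perm}",
        ]
        return "\n".join(lines)


def _slopes(x: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Row-wise OLS slopes of Y rows on x."""
    xc = x - x.mean()
    return (Y - Y.mean(axis=1, keepdims=True)) @ xc / (xc @ xc)


class PrsAssociation:
    """Linear model of polygenic-model residuals on a scaled PRS.

    statsmodels-style: construct from data, call :meth:`fit` for an
    :class:`AssocResult`.  The slope's 95% CI is a percentile interval from
    ordinary nonparametric pair resampling; the permutation p-value permutes
    the residuals (equivalently the PRS) and is computed as
    ``(1 + #{permuted slope >= observed}) / (1 + n_perm)``; the analytic
    one-sided p is the upper normal tail of slope/SE (alternative: slope > 0,
    i.e. higher risk load in affected members).
    """

    def __init__(self, residuals: Sequence[float] | pd.Series, prs: PrsResult | Sequence[float]):
        if isinstance(prs, PrsResult):
            if prs.undefined:
                raise ValueError("PRS is undefined (no SNPs below threshold)")
            self.threshold: float | None = prs.threshold
            self.n_snps: int | None = prs.n_snps
            x = prs.scores.to_numpy(float)
        else:
            self.threshold, self.n_snps = None, None
            x = np.asarray(prs, float)
        y = np.asarray(
            residuals.to_numpy() if isinstance(residuals, pd.Series) else residuals, float
        )
        if len(x) != len(y):
            raise ValueError("residuals and PRS must have the same length")
        if np.std(x) == 0:
            raise ValueError("constant PRS: slope undefined")
        self.x, self.y = x, y

    def fit(self, n_boot: int = 2000, n_perm: int = 10000, seed: int | None = None) -> AssocResult:
        if n_boot < 1 or n_perm < 1:
            raise ValueError("n_boot and n_perm must be >= 1")
        x, y = self.x, self.y
        n = len(x)
        xc, yc = x - x.mean(), y - y.mean()
        sxx = float(xc @ xc)
        slope = float(xc @ yc) / sxx
        intercept = y.mean() - slope * x.mean()
        resid = y - intercept - slope * x
        dof = n - 2
        s2 = float(resid @ resid) / dof
        se = math.sqrt(s2 / sxx)
        sst = float(yc @ yc)
        r2 = 1.0 - float(resid @ resid) / sst if sst > 0 else 0.0

        rng = np.random.default_rng(seed)
        # vectorized bootstrap: per-replicate slope from resampled pairs
        idx = rng.integers(0, n, size=(n_boot, n))
        xb, yb = x[idx], y[idx]
        xbc = xb - xb.mean(axis=1, keepdims=True)
        ybc = yb - yb.mean(axis=1, keepdims=True)
        sxxb = (xbc * xbc).sum(axis=1)
        boot = (xbc * ybc).sum(axis=1) / sxxb
        ci = (float(np.percentile(boot, 2.5)), float(np.percentile(boot, 97.5)))

        # a perfect fit has zero residual variance; the one-sided tail is then 0/1
        p_one = float(stats.norm.sf(slope / se)) if se > 0 else (0.0 if slope > 0 else 1.0)

        perm = rng.permuted(np.tile(y, (n_perm, 1)), axis=1)
        perm_slopes = _slopes(x, perm)
        p_perm = (1.0 + int((perm_slopes >= slope - 1e-15).sum())) / (1.0 + n_perm)

        return AssocResult(
            threshold=self.threshold,
            slope=slope,
            se=se,
            r2=r2,
            ci95=ci,
            p_one_sided=p_one,
            p_perm=p_perm,
            n_boot=n_boot,
            n_perm=n_perm,
            seed=seed,
            n_snps=self.n_snps,
        )


def prs_association(
    residuals: Sequence[float] | pd.Series,
    prs: PrsResult | Sequence[float],
    n_boot: int = 2000,
    n_perm: int = 10000,
    seed: int | None = None,
) -> AssocResult:
    """Functional wrapper around :class:`PrsAssociation`."""
    return PrsAssociation(residuals, prs).fit(n_boot=n_boot, n_perm=n_perm, seed=seed)


@dataclass
class SweepResult:
    results: list[AssocResult]
    alpha: float = 0.05

    @property
    def bonferroni_significant(self) -> list[bool]:
        k = len(self.results)
        return [
            (not r.undefined) and r.p_one_sided < self.alpha / k for r in self.results
        ]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r, sig in zip(self.results, self.bonferroni_significant):
            rows.append(
                {
                    "threshold": r.threshold,
                    "n_snps": r.n_snps,
                    "slope": r.slope,
                    "SE": r.se,
                    "R2": r.r2,
                    "ci_low": r.ci95[0],
                    "ci_high": r.ci95[1],
                    "p_one_sided": r.p_one_sided,
                    "p_perm": r.p_perm,
                    "bonferroni_significant": sig,
                    "undefined": r.undefined,
                }
            )
        return pd.DataFrame(rows)


def threshold_sweep(
    geno: DosageMatrix,
    stats_df: pd.DataFrame,
    residuals: Sequence[float] | pd.Series,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    clumped: Sequence[str] | None = None,
    n_boot: int = 2000,
    n_perm: int = 10000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> SweepResult:
    """One association per inclusion threshold plus a Bonferroni flag at
    alpha / (number of thresholds).  Undefined thresholds (no qualifying
    SNPs) yield flagged placeholder results."""
    results = []
    for i, t in enumerate(thresholds):
        pr = score(geno, stats_df, t, snps=clumped)
        if pr.undefined:
            results.append(
                AssocResult(t, math.nan, math.nan, math.nan, (math.nan, math.nan),
                            math.nan, math.nan, n_boot, n_perm, seed, 0, undefined=True)
            )
            continue
        sub_seed = None if seed is None else seed + i
        results.append(
            PrsAssociation(residuals, pr).fit(n_boot=n_boot, n_perm=n_perm, seed=sub_seed)
        )
    return SweepResult(results, alpha=alpha)
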