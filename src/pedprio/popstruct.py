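"""Population-substructure pipeline: variant filters, region masks, LD
pruning, pairwise identity-by-state, classical MDS, and representative
selection for highly related clusters.

Defaults follow common array-QC practice for ancestry analysis: drop markers
with MAF < 0.05 or an exact Hardy-Weinberg p below 1e-3, mask the extended
MHC (chr6 25-35 Mb) and the common chromosome-8 inversion (7-13 Mb) whose
long-range LD distorts ancestry axes, then window-based pruning (200-SNP
window, 100-SNP step, r2 > 0.2 dropped).  MDS is Torgerson double-centering
eigendecomposition of the IBS *distance* matrix, with component columns
scaled to unit standard deviation for plotting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
import numpy as np
import pandas as pd
from scipy.special import gammaln

from .npl import MarkerPanel

__all__ = [
    "RegionMask",
    "DEFAULT_MASK",
    "hwe_exact",
    "substructure_filter",
    "ibs_matrix",
    "MdsResult",
    "mds",
    "cluster_representatives",
]


@dataclass
class RegionMask:
    """Genomic exclusion windows as (chrom, start_mb, end_mb)."""

    regions: list[tuple[str, float, float]]

    def __post_init__(self) -> None:
        for chrom, start, end in self.regions:
            if not start < end:
                raise ValueError(f"empty mask window on chr{chrom}: {start}-{end}")

    def contains(self, chrom: str, pos: int) -> bool:
        mb = pos / 1e6
        return any(c == str(chrom) and s <= mb <= e for c, s, e in self.regions)


#: Extended MHC and the common chromosome-8 inversion.
DEFAULT_MASK = RegionMask([("6", 25.0, 35.0), ("8", 7.0, 13.0)])


def hwe_exact(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional Hardy-Weinberg test.

    Conditional on the allele counts, the p-value sums the probabilities of
    all heterozygote counts whose conditional probability does not exceed the
    observed one.  Monomorphic tables have a single attainable configuration
    and return p = 1.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("empty genotype table")
    n_a = 2 * n_aa + n_Aa  # minor-allele count (orientation is irrelevant)
    rare = min(n_a, 2 * n - n_a)
    if rare == 0:
        return 1.0
    hets = np.arange(rare % 2, rare + 1, 2)
    homr = (rare - hets) // 2
    homc = n - hets - homr
    logp = (
        gammaln(n + 1)
        - gammaln(homr + 1)
        - gammaln(hets + 1)
        - gammaln(homc + 1)
        + hets * math.log(2.0)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    obs = int(np.where(hets == n_Aa)[0][0]) if n_Aa in hets else None
    if obs is None:
        raise ValueError("heterozygote count inconsistent with allele-count parity")
    return float(min(1.0, probs[probs <= probs[obs] * (1 + 1e-12)].sum()))


def _windowed_prune(panel: MarkerPanel, window: int, step: int, r2_max: float) -> list[str]:
    """PLINK-style indep-pairwise scan: within each sliding window, greedily
    drop the later marker of any pair with r2 > r2_max."""
    removed: set[str] = set()
    for chrom, sub in panel.meta.groupby("chrom", sort=False):
        markers = list(sub.sort_values("pos").index)
        start = 0
        while start < len(markers):
            win = [m for m in markers[start : start + window] if m not in removed]
            G = panel.genotypes[win].to_numpy(float)
            if G.shape[1] > 1:
                sd = G.std(axis=0)
                ok = sd > 0
                with np.errstate(invalid="ignore"):
                    C = np.corrcoef(G[:, ok], rowvar=False) ** 2
                names = [m for m, o in zip(win, ok) if o]
                for i in range(len(names)):
                    if names[i] in removed:
                        continue
                    for j in range(i + 1, len(names)):
                        if names[j] in removed:
                            continue
                        if C[i, j] > r2_max:
                            removed.add(names[j])
            if start + window >= len(markers):
                break
            start += step
    return [m for m in panel.markers if m not in removed]


def substructure_filter(
    panel: MarkerPanel,
    maf_min: float = 0.05,
    hwe_min_p: float = 1e-3,
    mask: RegionMask = DEFAULT_MASK,
    prune: tuple[int, int, float] = (200, 100, 0.2),
) -> MarkerPanel:
    """MAF + exact-HWE filters, region mask, then windowed LD pruning.

    Idempotent: applying it twice yields the same panel.  An empty result is
    an error.
    """
    g = panel.genotypes
    keep = []
    for m in panel.markers:
        col = g[m].dropna()
        p = col.mean() / 2.0
        if min(p, 1 - p) < maf_min:
            continue
        counts = col.value_counts()
        n_aa = int(counts.get(2.0, 0))
        n_het = int(counts.get(1.0, 0))
        n_AA = int(counts.get(0.0, 0))
        if hwe_exact(n_AA, n_het, n_aa) < hwe_min_p:
            continue
        if mask.contains(str(panel.meta.loc[m, "chrom"]), int(panel.meta.loc[m, "pos"])):
            continue
        keep.append(m)
    pruned = _windowed_prune(panel.subset(keep), *prune) if keep else []
    if not pruned:
        raise ValueError("no markers remain after substructure filtering")
    return panel.subset(pruned)


def ibs_matrix(panel: MarkerPanel) -> pd.DataFrame:
    """Pairwise identity-by-state *distance* matrix (1 - mean shared-allele
    fraction over pairwise-complete markers; per marker the fraction is 0,
    1/2 or 1).  Pairs with no overlapping typed markers are NaN."""
    G = panel.genotypes.to_numpy(float)
    n = G.shape[0]
    if n < 2:
        raise ValueError("need at least two individuals")
    D = np.zeros((n, n))
    typed = ~np.isnan(G)
    for i in range(n):
        for j in range(i + 1, n):
            both = typed[i] & typed[j]
            if not both.any():
                D[i, j] = D[j, i] = np.nan
                continue
            sim = 1.0 - np.abs(G[i, both] - G[j, both]) / 2.0
            D[i, j] = D[j, i] = 1.0 - sim.mean()
    return pd.DataFrame(D, index=panel.genotypes.index, columns=panel.genotypes.index)


@dataclass
class MdsResult:
    coordinates: pd.DataFrame  # SD-scaled component columns C1..Ck
    eigenvalues: np.ndarray
    raw_coordinates: pd.DataFrame = field(repr=False, default=None)


def mds(distance: pd.DataFrame, k: int = 2) -> MdsResult:
    """Classical (Torgerson) multidimensional scaling.

    Double-centers the squared distance matrix, eigendecomposes, and keeps
    the top-*k* positive-eigenvalue components (truncating with a warning
    when fewer exist).  Missing entries are imputed by the row/column mean.
    Returned coordinate columns are divided by their standard deviation.
    """
    D = distance.to_numpy(float).copy()
    if np.isnan(D).any():
        means = np.nanmean(D, axis=1)
        ii, jj = np.where(np.isnan(D))
        D[ii, jj] = (means[ii] + means[jj]) / 2.0
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    w, U = np.linalg.eigh(B)
    order = np.argsort(w)[::-1]
    w, U = w[order], U[:, order]
    pos = w > max(1e-12, 1e-9 * abs(w[0]))
    k_eff = min(k, int(pos.sum()))
    if k_eff < k:
        import warnings

        warnings.warn(f"only {k_eff} positive components available; truncated")
    coords = U[:, :k_eff] * np.sqrt(w[:k_eff])
    cols = [f"C{i + 1}" for i in range(k_eff)]
    raw = pd.DataFrame(coords, index=distance.index, columns=cols)
    sd = raw.std(ddof=0).replace(0.0, 1.0)
    return MdsResult(coordinates=raw / sd, eigenvalues=w[:k_eff], raw_coordinates=raw)


def cluster_representatives(
    similarity: pd.DataFrame, threshold: float
) -> list[str]:
    """Collapse single-linkage clusters of pairwise similarity above
    *threshold* to one representative each (lexicographically smallest id)."""
    ids = list(similarity.index)
    parent = {i: i for i in ids}

    def find(i: str) -> str:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    S = similarity.to_numpy(float)
    for a in range(len(ids)):
        for b in range(a + 1, len(ids)):
            if S[a, b] > threshold:
                ra, rb = find(ids[a]), find(ids[b])
                if ra != rb:
                    parent[rb] = ra
    clusters: dict[str, list[str]] = {}
    for i in ids:
        clusters.setdefault(find(i), []).append(i)
    return sorted(min(members) for members in clusters.values())
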