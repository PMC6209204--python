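"""Single-marker non-parametric linkage (NPL) for small pedigrees.

The machinery is exact enumeration over inheritance vectors.  A pedigree with
``m`` non-founders has ``2m`` meiosis bits (one per parental transmission);
each of the ``2**(2m)`` inheritance vectors maps every individual's two
alleles to founder-allele *slots* (two slots per founder).  Given observed
single-marker genotypes and population allele frequencies, the posterior over
vectors is

    P(v | G)  proportional to  sum over founder-allele assignments
              of  [assignment consistent with G under v] * prod freq(allele),

enumerated exactly (bounded at 14 meiosis bits; larger pedigrees must be
subdivided).

Allele sharing among affected members is scored per vector with the
Whittemore-Halpern statistics: ``S_pairs`` (alleles shared identical by
descent summed over affected pairs) and ``S_all`` (2^-a * sum over the 2^a
ways of picking one allele per affected of the product of factorials of
founder-allele multiplicities).  The null mean and variance of each statistic
come from exact enumeration over uniformly distributed vectors, giving
standardized scores ``Z = (E_posterior[S] - mu0) / sigma0``.

Per-family Z-scores are combined into a model-free LOD with the one-parameter
Kong-Cox likelihoods (delta >= 0, one-sided): the *linear* model
``P_delta(v) = P_0(v) (1 + delta gamma Z(v))`` and the *exponential* model
``P_delta(v) = P_0(v) exp(delta gamma Z(v)) / c(delta)``.  The p-value uses
the one-sided 1/2 chi2_0 + 1/2 chi2_1 boundary mixture.

Marker QC (call rate, MAF) and aggressive LD pruning (the defaults, 500 kb
window at r2 0.01, make the retained markers approximately independent,
which is what justifies the single-marker treatment) operate on dosage
panels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .pedigree import Pedigree, PhenotypeClass

__all__ = [
    "MarkerPanel",
    "marker_qc",
    "ld_prune",
    "InheritanceModel",
    "InheritanceDistribution",
    "MendelianError",
    "inheritance_posterior",
    "npl_scores",
    "FamilyScore",
    "NplResult",
    "kong_cox",
    "max_attainable_lod",
    "npl_scan",
]

MAX_MEIOSIS_BITS = 14


@dataclass
class MarkerPanel:
    """Biallelic marker panel: individuals x markers dosage matrix (0/1/2,
    NaN = missing) plus per-marker metadata (chrom, pos, optional freq of the
    alternate allele)."""

    genotypes: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.meta.index.equals(self.genotypes.columns):
            self.meta = self.meta.loc[self.genotypes.columns]

    @property
    def markers(self) -> list[str]:
        return list(self.genotypes.columns)

    def subset(self, markers: Sequence[str]) -> "MarkerPanel":
        return MarkerPanel(self.genotypes[list(markers)], self.meta.loc[list(markers)])


def marker_qc(
    panel: MarkerPanel, min_call: float = 0.95, min_maf: float = 0.05
) -> MarkerPanel:
    """Retain markers with call rate >= min_call and sample MAF >= min_maf
    (both non-strict)."""
    g = panel.genotypes
    call = g.notna().mean(axis=0)
    p = g.mean(axis=0) / 2.0
    maf = np.minimum(p, 1 - p)
    keep = g.columns[(call >= min_call) & (maf >= min_maf)]
    return panel.subset(list(keep))


def ld_prune(
    panel: MarkerPanel, window_kb: float = 500.0, r2_max: float = 0.01
) -> MarkerPanel:
    """Greedy left-to-right LD pruning.

    Scanning markers in position order within each chromosome, a marker is
    dropped when its squared genotype correlation with any already-retained
    marker within *window_kb* exceeds *r2_max*.
    """
    meta = panel.meta
    keep: list[str] = []
    for chrom, sub in meta.groupby("chrom", sort=False):
        sub = sub.sort_values("pos")
        retained: list[str] = []
        for m in sub.index:
            pos = sub.loc[m, "pos"]
            ok = True
            for r in reversed(retained):
                if pos - meta.loc[r, "pos"] > window_kb * 1000:
                    break
                if _r2(panel.genotypes[m], panel.genotypes[r]) > r2_max:
                    ok = False
                    break
            if ok:
                retained.append(m)
        keep.extend(retained)
    return panel.subset([m for m in panel.markers if m in set(keep)])


def _r2(a: pd.Series, b: pd.Series) -> float:
    mask = a.notna() & b.notna()
    if mask.sum() < 2:
        return 0.0
    x, y = a[mask].to_numpy(float), b[mask].to_numpy(float)
    if x.std() == 0 or y.std() == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1] ** 2)


class MendelianError(ValueError):
    """Genotypes inconsistent with Mendelian transmission in the pedigree."""


class InheritanceModel:
    """Exact inheritance-vector machinery for one pedigree.

    Precomputes, for every inheritance vector, the founder-allele slot pair
    of every individual.  Slots are numbered ``2f`` (paternal) and ``2f+1``
    (maternal) for founder index ``f``.  Reused across markers: only the
    posterior step depends on observed genotypes and allele frequencies.
    """

    def __init__(self, ped: Pedigree, max_bits: int = MAX_MEIOSIS_BITS) -> None:
        self.ped = ped
        self.ids = ped.members()
        self.founders = ped.founders
        self.nonfounders = ped.topological_nonfounders()
        nbits = 2 * len(self.nonfounders)
        if nbits > max_bits:
            raise ValueError(
                f"pedigree has {nbits} meiosis bits, exceeding the exact-enumeration "
                f"bound of {max_bits}; subdivide the pedigree"
            )
        self.n_vectors = 1 << nbits
        self.n_slots = 2 * len(self.founders)
        self._slot_idx = self._build_slots()
        self._id_pos = {iid: k for k, iid in enumerate(self.ids)}

    def _build_slots(self) -> np.ndarray:
        """(V, n_individuals, 2) founder-slot index per vector."""
        V = self.n_vectors
        founder_idx = {f: i for i, f in enumerate(self.founders)}
        slots: dict[str, np.ndarray] = {}
        for f, i in founder_idx.items():
            arr = np.empty((V, 2), dtype=np.int16)
            arr[:, 0] = 2 * i
            arr[:, 1] = 2 * i + 1
            slots[f] = arr
        vec = np.arange(V, dtype=np.int64)
        for k, iid in enumerate(self.nonfounders):
            ind = self.ped[iid]
            pat_bit = ((vec >> (2 * k)) & 1).astype(bool)
            mat_bit = ((vec >> (2 * k + 1)) & 1).astype(bool)
            fa, mo = slots[ind.father], slots[ind.mother]
            arr = np.empty((V, 2), dtype=np.int16)
            arr[:, 0] = np.where(pat_bit, fa[:, 1], fa[:, 0])
            arr[:, 1] = np.where(mat_bit, mo[:, 1], mo[:, 0])
            slots[iid] = arr
        return np.stack([slots[i] for i in self.ids], axis=1)

    def _assignment_grid(self, n_alleles: int) -> np.ndarray:
        """(A, n_slots) allele-index matrix over all founder-slot assignments
        for an alphabet of *n_alleles*; cached across markers."""
        cache = getattr(self, "_grid_cache", None)
        if cache is None:
            cache = self._grid_cache = {}
        if n_alleles not in cache:
            grids = np.meshgrid(
                *([np.arange(n_alleles)] * self.n_slots), indexing="ij"
            )
            cache[n_alleles] = np.stack(
                [g.ravel() for g in grids], axis=1
            ).astype(np.int16)
        return cache[n_alleles]

    # -- posterior ---------------------------------------------------------
    def posterior(
        self,
        genotypes: Mapping[str, tuple[str, str] | None],
        allele_freq: Mapping[str, float],
        _chunk: int = 1 << 22,
    ) -> np.ndarray:
        """Posterior probability of each inheritance vector given observed
        unordered genotypes (``None``/absent = untyped) and population allele
        frequencies."""
        alleles = sorted(set(allele_freq))
        for iid, g in genotypes.items():
            if g is not None:
                for a in g:
                    if a not in allele_freq:
                        raise ValueError(f"allele {a!r} of {iid} has no frequency")
        total = sum(allele_freq.values())
        if not math.isclose(total, 1.0, abs_tol=1e-6):
            raise ValueError("allele frequencies must sum to 1")
        self._check_trios(genotypes)

        typed = [i for i, g in genotypes.items() if g is not None and i in self._id_pos]
        if not typed:
            return np.full(self.n_vectors, 1.0 / self.n_vectors)

        # alleles never observed in a typed genotype can be collapsed into a
        # single pseudo-allele carrying their pooled frequency: the
        # likelihood only ever tests slot-allele equality against observed
        # alleles, so the collapse is exact and shrinks the enumeration.
        observed = sorted({a for i in typed for a in genotypes[i]})
        other_freq = sum(f for a, f in allele_freq.items() if a not in observed)
        freqs = np.array(
            [allele_freq[a] for a in observed]
            + ([other_freq] if other_freq > 1e-12 else [])
        )
        n_all = len(freqs)
        a_index = {a: i for i, a in enumerate(observed)}
        n_assign = n_all**self.n_slots
        if n_assign * self.n_vectors > 1 << 28:
            raise ValueError(
                "founder-assignment enumeration too large; reduce founders or alleles"
            )
        assign = self._assignment_grid(n_all)  # (A, n_slots)
        prior = freqs[assign].prod(axis=1)  # (A,)

        pos = [self._id_pos[i] for i in typed]
        obs = np.array(
            [[a_index[a] for a in genotypes[i]] for i in typed], dtype=np.int8
        )  # (T, 2)
        slot_idx = self._slot_idx[:, pos, :]  # (V, T, 2)

        lik = np.empty(self.n_vectors)
        step = max(1, _chunk // max(1, len(assign) * len(typed)))
        for start in range(0, self.n_vectors, step):
            sl = slot_idx[start : start + step]  # (v, T, 2)
            g = assign[:, sl]  # (A, v, T, 2)
            g0, g1 = g[..., 0], g[..., 1]
            o0, o1 = obs[:, 0], obs[:, 1]
            match = ((g0 == o0) & (g1 == o1)) | ((g0 == o1) & (g1 == o0))
            lik[start : start + step] = prior @ match.all(axis=2)
        total_lik = lik.sum()
        if total_lik <= 0:
            raise MendelianError(
                "observed genotypes are jointly inconsistent with the pedigree"
            )
        return lik / total_lik

    def _check_trios(self, genotypes: Mapping[str, tuple[str, str] | None]) -> None:
        for iid in self.nonfounders:
            ind = self.ped[iid]
            gc = genotypes.get(iid)
            gf = genotypes.get(ind.father)
            gm = genotypes.get(ind.mother)
            if gc is None or gf is None or gm is None:
                continue
            # unordered: the child's genotype must equal {pa, ma} as a multiset
            ok = any(sorted(gc) == sorted((pa, ma)) for pa in gf for ma in gm)
            if not ok:
                raise MendelianError(
                    f"Mendelian inconsistency in trio child={iid} "
                    f"father={ind.father} mother={ind.mother}"
                )

    # -- sharing statistics -------------------------------------------------
    def s_pairs(self, affected: Sequence[str]) -> np.ndarray:
        """S_pairs per inheritance vector: IBD alleles shared, summed over
        all affected pairs (max bipartite matching of the 2x2 slot sets)."""
        idx = [self._id_pos[i] for i in affected]
        s = np.zeros(self.n_vectors)
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                pi, mi = self._slot_idx[:, idx[a], 0], self._slot_idx[:, idx[a], 1]
                pj, mj = self._slot_idx[:, idx[b], 0], self._slot_idx[:, idx[b], 1]
                m1 = (pi == pj).astype(int) + (mi == mj)
                m2 = (pi == mj).astype(int) + (mi == pj)
                s += np.maximum(m1, m2)
        return s

    def s_all(self, affected: Sequence[str]) -> np.ndarray:
        """Whittemore-Halpern all-sharing statistic per inheritance vector."""
        idx = [self._id_pos[i] for i in affected]
        a = len(idx)
        V = self.n_vectors
        total = np.zeros(V)
        sub = self._slot_idx[:, idx, :]  # (V, a, 2)
        for choice in range(1 << a):
            bits = [(choice >> i) & 1 for i in range(a)]
            sel = sub[np.arange(V)[:, None], np.arange(a)[None, :], np.array(bits)[None, :]]
            # prod of multiplicity factorials: element i contributes
            # (number of j <= i with the same slot)
            eq = sel[:, :, None] == sel[:, None, :]  # (V, a, a)
            tri = np.tril(np.ones((a, a), dtype=bool))
            contrib = (eq & tri).sum(axis=2)  # (V, a)
            total += contrib.prod(axis=1)
        return total / (1 << a)

    def null_moments(self, s: np.ndarray) -> tuple[float, float]:
        """Mean and SD of a per-vector statistic under uniform vectors."""
        return float(s.mean()), float(s.std())

    def standardized_null(self, s: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Null distribution of the standardized score: (values, probs)."""
        mu, sd = self.null_moments(s)
        z = (s - mu) / sd if sd > 0 else np.zeros_like(s)
        vals, counts = np.unique(np.round(z, 12), return_counts=True)
        return vals, counts / counts.sum()


@dataclass
class InheritanceDistribution:
    """Posterior over inheritance vectors at one marker."""

    model: InheritanceModel
    probs: np.ndarray

    def __post_init__(self) -> None:
        if not math.isclose(float(self.probs.sum()), 1.0, abs_tol=1e-8):
            raise ValueError("posterior must sum to 1")


def inheritance_posterior(
    ped: Pedigree | InheritanceModel,
    genotypes: Mapping[str, tuple[str, str] | None],
    allele_freq: Mapping[str, float],
) -> InheritanceDistribution:
    """Exact single-marker posterior over inheritance vectors."""
    model = ped if isinstance(ped, InheritanceModel) else InheritanceModel(ped)
    return InheritanceDistribution(model, model.posterior(genotypes, allele_freq))


def npl_scores(
    dist: InheritanceDistribution, affected: Sequence[str]
) -> tuple[float, float]:
    """Standardized (Z_all, Z_pairs) allele-sharing scores for *affected*."""
    if len(affected) < 2:
        raise ValueError("need at least 2 affected individuals")
    out = []
    for stat in (dist.model.s_all(affected), dist.model.s_pairs(affected)):
        mu, sd = dist.model.null_moments(stat)
        obs = float(dist.probs @ stat)
        out.append((obs - mu) / sd if sd > 0 else 0.0)
    return out[0], out[1]


@dataclass
class FamilyScore:
    """One family's contribution to the Kong-Cox likelihood.

    ``null_z`` is the exact null distribution (values, probabilities) of the
    standardized score, needed by the exponential model's normalizing
    constant and by the linear model's delta bound.
    """

    z: float
    null_z: tuple[np.ndarray, np.ndarray] | None = None
    weight: float = 1.0


@dataclass
class NplResult:
    """Kong-Cox combination result for one marker/statistic."""

    delta_hat: float
    lod: float
    p: float
    model: str
    marker: str | None = None

    def __post_init__(self) -> None:
        if self.lod < -1e-9:
            raise ValueError("one-sided LOD cannot be negative")


_DELTA_CAP = 30.0


def _normalize_scores(z_per_family) -> list[FamilyScore]:
    out = []
    for f in z_per_family:
        out.append(f if isinstance(f, FamilyScore) else FamilyScore(float(f)))
    n = len(out)
    # default weights: equal, normalized so sum of squares = 1
    if all(f.weight == 1.0 for f in out) and n > 1:
        w = 1.0 / math.sqrt(n)
        out = [FamilyScore(f.z, f.null_z, w) for f in out]
    return out


def kong_cox(
    z_per_family: Iterable[FamilyScore | float], model: str = "exponential"
) -> NplResult:
    """One-parameter Kong-Cox combination of per-family NPL scores.

    Maximizes the likelihood over delta >= 0 (one-sided) and returns the LOD
    ``log10 L(delta_hat)/L(0)`` with a p-value from the 1/2:1/2 chi-square
    boundary mixture.  The exponential model requires each family's exact
    null score distribution; the linear model constrains delta so that
    ``1 + delta * gamma * z`` stays positive over each family's null support.
    """
    fams = _normalize_scores(list(z_per_family))
    if not fams:
        raise ValueError("need at least one family score")
    if model not in ("linear", "exponential"):
        raise ValueError("model must be 'linear' or 'exponential'")

    if model == "linear":
        delta_max = _DELTA_CAP
        for f in fams:
            zmin = (
                float(np.min(f.null_z[0])) if f.null_z is not None else min(f.z, 0.0)
            )
            if zmin * f.weight < 0:
                delta_max = min(delta_max, -1.0 / (f.weight * zmin) * (1 - 1e-9))

        def negll(d: float) -> float:
            terms = [1.0 + d * f.weight * f.z for f in fams]
            if min(terms) <= 0:
                return np.inf
            return -sum(math.log(t) for t in terms)

    else:
        for f in fams:
            if f.null_z is None:
                raise ValueError(
                    "exponential model needs each family's null score distribution"
                )
        delta_max = _DELTA_CAP

        def negll(d: float) -> float:
            ll = 0.0
            for f in fams:
                vals, probs = f.null_z
                x = d * f.weight * vals
                m = x.max()
                log_c = m + math.log(float(probs @ np.exp(x - m)))
                ll += d * f.weight * f.z - log_c
            return -ll

    res = optimize.minimize_scalar(
        negll, bounds=(0.0, delta_max), method="bounded",
        options={"xatol": 1e-8},
    )
    delta_hat = float(res.x)
    ll_hat = -negll(delta_hat)
    if ll_hat <= 1e-12:  # boundary null: no evidence for excess sharing
        delta_hat, ll_hat = 0.0, 0.0
    lod = max(0.0, ll_hat / math.log(10))
    p = 0.5 * stats.chi2.sf(2 * math.log(10) * lod, df=1) if lod > 0 else 0.5
    return NplResult(delta_hat=delta_hat, lod=lod, p=p, model=model)


SUGGESTIVE_LOD = 2.2


def max_attainable_lod(
    ped: Pedigree | InheritanceModel,
    affected: Sequence[str],
    model: str = "exponential",
    statistic: str = "all",
) -> float:
    """LOD ceiling for a pedigree: the score when a perfectly informative
    marker shows the maximal-sharing inheritance vector."""
    if len(affected) < 2:
        return 0.0
    m = ped if isinstance(ped, InheritanceModel) else InheritanceModel(ped)
    s = m.s_all(affected) if statistic == "all" else m.s_pairs(affected)
    mu, sd = m.null_moments(s)
    if sd == 0:
        return 0.0
    z_max = (float(s.max()) - mu) / sd
    null = m.standardized_null(s)
    return kong_cox([FamilyScore(z_max, null)], model=model).lod


def npl_scan(
    panel: MarkerPanel,
    ped: Pedigree,
    affected: Sequence[str] | None = None,
    model: str = "exponential",
) -> pd.DataFrame:
    """Per-marker NPL scan of a biallelic dosage panel over one pedigree.

    Affected default to the pedigree's BD class (strict phenotype scheme is
    the convention for linkage: apply it to the pedigree first).  Alternate
    allele frequency comes from the panel metadata column ``freq`` or, absent
    that, the sample frequency.  Returns a frame with columns marker, z_all,
    z_pairs, lod_linear, exLOD and p (p of the exponential-model LOD).
    """
    if affected is None:
        affected = ped.ids_with_class(PhenotypeClass.BD)
    m = InheritanceModel(ped)
    s_all = m.s_all(affected)
    s_pairs = m.s_pairs(affected)
    null_all = m.standardized_null(s_all)
    mu_a, sd_a = m.null_moments(s_all)
    mu_p, sd_p = m.null_moments(s_pairs)

    rows = []
    for marker in panel.markers:
        freq = panel.meta["freq"].get(marker) if "freq" in panel.meta else None
        if freq is None or np.isnan(freq):
            freq = float(panel.genotypes[marker].mean() / 2.0)
        freq = min(max(freq, 1e-6), 1 - 1e-6)
        genos: dict[str, tuple[str, str] | None] = {}
        for iid in ped.members():
            d = panel.genotypes[marker].get(iid)
            if d is None or (isinstance(d, float) and np.isnan(d)):
                genos[iid] = None
            else:
                genos[iid] = [("r", "r"), ("r", "a"), ("a", "a")][int(d)]
        probs = m.posterior(genos, {"a": freq, "r": 1 - freq})
        e_all = float(probs @ s_all)
        e_pairs = float(probs @ s_pairs)
        z_all = (e_all - mu_a) / sd_a if sd_a > 0 else 0.0
        z_pairs = (e_pairs - mu_p) / sd_p if sd_p > 0 else 0.0
        lin = kong_cox([FamilyScore(z_all, null_all)], model="linear")
        ex = kong_cox([FamilyScore(z_all, null_all)], model="exponential")
        rows.append(
            {
                "marker": marker,
                "z_all": z_all,
                "z_pairs": z_pairs,
                "lod_linear": lin.lod,
                "exLOD": ex.lod,
                "p": ex.p,
            }
        )
    return pd.DataFrame(rows)
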