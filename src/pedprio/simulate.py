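"""Synthetic-data generator with known ground truth for every pipeline stage.

Emulates the study design end to end: multigenerational multiplex pedigrees
(founding couple, new spouses marrying in each generation), a rare founder
variant gene-dropped with incomplete penetrance and a phenocopy rate,
exome-like variant/annotation tables with correlated prediction-tool calls,
LD-structured array genotypes (block-haplotype model, recombination-free
within blocks), and GWAS summary statistics whose true polygenic score
explains a configurable fraction of liability.

Everything is driven by ``numpy.random.default_rng(cfg.seed)``; emitted
files are byte-identical for identical ``(cfg, seed)``.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd

from .filtering import (
    AnnotationRecord,
    SampleCall,
    VariantRecord,
    write_annotation_tsv,
)
from .npl import MarkerPanel
from .pedigree import (
    BROAD,
    Individual,
    Pedigree,
    classify_phenotype,
    write_pedigree,
)
from .prs import DosageMatrix
from .segregation import CarrierMap, write_carrier_tsv

__all__ = [
    "SimConfig",
    "GroundTruth",
    "simulate_pedigree",
    "gene_drop",
    "simulate_exome_table",
    "simulate_array",
    "simulate_gwas",
    "simulate_prs_cohort",
    "simulate_study",
]


@dataclass
class SimConfig:
    """Study-condition parameters for the generator.

    Defaults emulate the source families' scale: five to six generations,
    mean sibship 2.5, a single rare founder variant with incomplete
    penetrance (0.7) and a 5% phenocopy rate, a 10% independent base rate of
    non-BD psychiatric phenotypes, block-LD array genotypes, and a polygenic
    score explaining 30% of liability variance.
    """

    seed: int
    n_generations: int = 5
    mean_sibship: float = 2.5
    p_reproduce: float = 0.5
    max_members: int = 80
    founder_carriers: int = 1
    penetrance: float = 0.7
    phenocopy: float = 0.05
    other_psych_rate: float = 0.10
    n_background_variants: int = 300
    n_array_snps: int = 1000
    ld_block_size: int = 20
    ld_block_r2: float = 0.4
    n_gwas_snps: int = 200
    causal_fraction: float = 0.25
    h2_prs: float = 0.3
    gwas_n: int = 50000
    tool_concordance: float = 0.85

    def __post_init__(self) -> None:
        for name in ("p_reproduce", "penetrance", "phenocopy", "other_psych_rate",
                     "causal_fraction", "h2_prs", "tool_concordance", "ld_block_r2"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.mean_sibship <= 0:
            raise ValueError("mean sibship must be positive")


@dataclass
class GroundTruth:
    """What the generator knows that the pipeline must recover."""

    causal_variant_id: str | None = None
    carriers: dict = field(default_factory=dict)  # id -> bool
    bd_carrier_cases: list = field(default_factory=list)
    true_beta: dict = field(default_factory=dict)  # snp -> causal effect
    causal_snps: list = field(default_factory=list)
    params: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)


def _rng(cfg_or_seed) -> np.random.Generator:
    if isinstance(cfg_or_seed, np.random.Generator):
        return cfg_or_seed
    seed = cfg_or_seed.seed if isinstance(cfg_or_seed, SimConfig) else cfg_or_seed
    return np.random.default_rng(seed)


def simulate_pedigree(cfg: SimConfig, rng: np.random.Generator | None = None) -> Pedigree:
    """Multigenerational pedigree: a founding couple, sibships of mean
    ``mean_sibship`` (zero-truncated Poisson), each child reproducing with
    probability ``p_reproduce`` with a married-in spouse.  Growth is capped
    at ``max_members``.  One generation yields founders only."""
    rng = rng or _rng(cfg)
    counter = [0]

    def new_id() -> str:
        counter[0] += 1
        return str(counter[0])

    inds: list[Individual] = []
    a, b = new_id(), new_id()
    inds.append(Individual(a, sex="male", diagnosis="HEALTHY"))
    inds.append(Individual(b, sex="female", diagnosis="HEALTHY", married_in=True))
    couples = [(a, b)]
    for g in range(1, cfg.n_generations):
        children: list[Individual] = []
        for fa, mo in couples:
            n_kids = max(1, int(round(rng.normal(cfg.mean_sibship, 0.7))))
            for _ in range(n_kids):
                if len(inds) + len(children) >= cfg.max_members - 1:
                    break
                kid = new_id()
                sex = "male" if rng.random() < 0.5 else "female"
                children.append(Individual(kid, father=fa, mother=mo, sex=sex))
        inds.extend(children)
        if g == cfg.n_generations - 1 or not children:
            break
        # a regulated fraction of each generation's children reproduce;
        # clamping the number of continuing couples keeps pedigree size
        # stable across seeds instead of letting the branching compound
        n_rep = min(3, max(1, round(cfg.p_reproduce * len(children))))
        rep_idx = rng.choice(len(children), size=min(n_rep, len(children)), replace=False)
        couples = []
        for ci in sorted(rep_idx):
            kid = children[ci]
            spouse = new_id()
            sp_sex = "female" if kid.sex == "male" else "male"
            inds.append(Individual(spouse, sex=sp_sex, married_in=True))
            pair = (kid.iid, spouse) if kid.sex == "male" else (spouse, kid.iid)
            couples.append(pair)
    return Pedigree(inds, subpedigree_id="sim")


def gene_drop(
    ped: Pedigree, cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[CarrierMap, dict[str, str], GroundTruth]:
    """Drop a rare founder variant and sample phenotypes.

    One (or ``founder_carriers``) non-married-in founders start heterozygous;
    each meiosis transmits with probability 1/2.  Phenotype per individual:
    BD with probability ``penetrance`` for carriers and ``phenocopy``
    otherwise; failing that, another psychiatric phenotype with probability
    ``other_psych_rate``; else healthy.  Diagnoses (and the matching broad
    phenotype classes) are written onto the pedigree in place.
    """
    rng = rng or _rng(cfg)
    lineage_founders = [f for f in ped.founders if not ped[f].married_in] or ped.founders
    k = min(cfg.founder_carriers, len(lineage_founders))
    if k < 1:
        raise ValueError("need at least one founder carrier")
    carrier_founders = list(rng.choice(lineage_founders, size=k, replace=False))

    copies: dict[str, int] = {f: 0 for f in ped.founders}
    for f in carrier_founders:
        copies[f] = 1
    for iid in ped.topological_nonfounders():
        ind = ped[iid]
        inherited = 0
        for pid in (ind.father, ind.mother):
            if copies[pid] >= 1 and rng.random() < 0.5 * copies[pid]:
                inherited += 1
        copies[iid] = inherited

    bd_subtypes = ["BD_I", "BD_II", "BD_NOS"]
    other_dx = ["MDD_RECURRENT", "MDD_SINGLE", "ALCOHOL_ABUSE"]
    phenotypes: dict[str, str] = {}
    for iid in ped.members():
        carrier = copies[iid] > 0
        p_bd = cfg.penetrance if carrier else cfg.phenocopy
        if rng.random() < p_bd:
            dx = bd_subtypes[rng.choice(3, p=[0.5, 0.3, 0.2])]
        elif rng.random() < cfg.other_psych_rate:
            dx = other_dx[rng.choice(3)]
        else:
            dx = "HEALTHY"
        phenotypes[iid] = dx
        ped[iid].diagnosis = dx
        ped[iid].phenotype_class = classify_phenotype(dx, BROAD)

    vid = "7:5000000:C:T"
    cm = CarrierMap(
        vid, {i: ("carrier" if copies[i] > 0 else "non_carrier") for i in ped.members()}
    )
    truth = GroundTruth(
        causal_variant_id=vid,
        carriers={i: copies[i] > 0 for i in ped.members()},
        bd_carrier_cases=[
            i for i in ped.members()
            if copies[i] > 0 and phenotypes[i] in bd_subtypes
        ],
        params={"penetrance": cfg.penetrance, "phenocopy": cfg.phenocopy},
    )
    return cm, phenotypes, truth


def _het_call(sample: str, rng: np.random.Generator) -> SampleCall:
    return SampleCall(
        sample,
        "het",
        depth=int(20 + rng.poisson(60)),
        alt_fraction=float(rng.uniform(0.35, 0.65)),
        quality=99.0,
    )


def _ref_call(sample: str, rng: np.random.Generator) -> SampleCall:
    return SampleCall(sample, "hom_ref", depth=int(20 + rng.poisson(60)),
                      alt_fraction=0.0, quality=99.0)


def simulate_exome_table(
    ped: Pedigree,
    carriers: CarrierMap,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[VariantRecord], dict[str, AnnotationRecord]]:
    """Exome-like variant and annotation tables.

    The causal variant (all ground-truth carriers heterozygous, reference
    MAF absent, four of five tools damaging) is embedded among
    ``n_background_variants`` background variants, each gene-dropped from a
    random founder so sharing patterns are family-realistic, with a
    log-uniform reference MAF spectrum and prediction-tool calls sampled
    with per-tool concordance ``tool_concordance`` given the variant's
    latent damaging status.
    """
    rng = rng or _rng(cfg)
    members = ped.members()
    variants: list[VariantRecord] = []
    annotations: dict[str, AnnotationRecord] = {}

    causal = VariantRecord(
        chrom="7", pos=5_000_000, ref="C", alt="T",
        gene="GENE_CAUSAL", variant_class="missense",
        calls={
            i: (_het_call(i, rng) if carriers.get(i) == "carrier" else _ref_call(i, rng))
            for i in members
        },
    )
    # four damaging calls guaranteed; fifth sampled
    fifth = "D" if rng.random() < cfg.tool_concordance else "T"
    annotations[causal.vid] = AnnotationRecord(
        chrom="7", pos=5_000_000, ref="C", alt="T", gene="GENE_CAUSAL",
        exac_maf=None, aa_change="p.A100V",
        snv_predictions=("D", "D", "D", "D", fifth),
    )
    variants.append(causal)

    classes = np.array(["missense", "synonymous", "frameshift_indel", "splice"])
    class_p = np.array([0.6, 0.2, 0.1, 0.1])
    founders = ped.founders
    topo = ped.topological_nonfounders()
    for b in range(cfg.n_background_variants):
        chrom = str(1 + b % 22)
        pos = 1_000_000 + 10_000 * b
        vclass = str(classes[rng.choice(len(classes), p=class_p)])
        is_indel = vclass == "frameshift_indel"
        ref, alt = ("A", "AG") if is_indel else ("G", "A")
        # drop one background allele from a random founder
        origin = founders[rng.choice(len(founders))]
        has = {i: False for i in members}
        has[origin] = True
        for iid in topo:
            ind = ped[iid]
            has[iid] = any(
                has[p] and rng.random() < 0.5 for p in (ind.father, ind.mother)
            )
        calls = {
            i: (_het_call(i, rng) if has[i] else _ref_call(i, rng)) for i in members
        }
        v = VariantRecord(chrom=chrom, pos=pos, ref=ref, alt=alt,
                          gene=f"GENE{b:04d}", variant_class=vclass, calls=calls)
        damaging = rng.random() < 0.3
        if is_indel:
            preds_i = tuple(
                "D" if rng.random() < (cfg.tool_concordance if damaging else 0.05) else "N"
                for _ in range(3)
            )
            snv_preds = None
        else:
            preds_i = None
            snv_preds = tuple(
                ("D" if rng.random() < (cfg.tool_concordance if damaging else 0.08)
                 else ("P" if rng.random() < 0.1 else "B"))
                for _ in range(5)
            )
        maf = float(10 ** rng.uniform(-6, -1.2))
        annotations[v.vid] = AnnotationRecord(
            chrom=chrom, pos=pos, ref=ref, alt=alt, gene=v.gene,
            exac_maf=None if rng.random() < 0.1 else maf,
            aa_change="p.X1Y",
            snv_predictions=snv_preds, indel_predictions=preds_i,
            rpkm_hippocampus=float(np.round(10 ** rng.uniform(-2, 1.5), 2)),
        )
        variants.append(v)
    return variants, annotations


def simulate_array(
    ped: Pedigree, cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[DosageMatrix, MarkerPanel]:
    """Block-LD array genotypes dropped through the pedigree.

    Founder haplotypes follow a latent-haplotype block model: within a block
    of ``ld_block_size`` SNPs each marker copies a latent Bernoulli(1/2)
    variable with a flip probability tuned so the expected pairwise r2
    equals ``ld_block_r2``; blocks are independent.  Offspring inherit one
    whole parental haplotype per block (no within-block recombination, free
    recombination between blocks), so trios are Mendelian-consistent by
    construction.
    """
    rng = rng or _rng(cfg)
    n_blocks = max(1, cfg.n_array_snps // cfg.ld_block_size)
    block = cfg.ld_block_size
    n_snps = n_blocks * block
    # per-marker corr with the latent variable: rho^2 = sqrt(r2_target)
    rho = cfg.ld_block_r2 ** 0.25
    eps = (1 - rho) / 2.0

    members = ped.members()
    hap: dict[str, np.ndarray] = {}  # id -> (2, n_snps) int8
    for f in ped.founders:
        h = np.empty((2, n_snps), dtype=np.int8)
        for hx in range(2):
            z = rng.integers(0, 2, size=n_blocks)
            alleles = np.repeat(z, block)
            flips = rng.random(n_snps) < eps
            h[hx] = np.where(flips, 1 - alleles, alleles)
        hap[f] = h
    for iid in ped.topological_nonfounders():
        ind = ped[iid]
        h = np.empty((2, n_snps), dtype=np.int8)
        for hx, pid in enumerate((ind.father, ind.mother)):
            choice = np.repeat(rng.integers(0, 2, size=n_blocks), block)
            h[hx] = hap[pid][choice, np.arange(n_snps)]
        hap[iid] = h
    G = np.stack([hap[i].sum(axis=0) for i in members]).astype(float)

    snp_ids = [f"snp{j:05d}" for j in range(n_snps)]
    chroms = [str(1 + (j // block) % 22) for j in range(n_snps)]
    pos = [
        10_000_000 * (1 + (j // block) // 22) + (j // block) * 100_000 + (j % block) * 1_000
        for j in range(n_snps)
    ]
    meta = pd.DataFrame(
        {"chrom": chroms, "pos": pos, "freq": 0.5}, index=pd.Index(snp_ids, name="snp")
    )
    dosages = pd.DataFrame(G, index=members, columns=snp_ids)
    return DosageMatrix(dosages, meta.copy()), MarkerPanel(dosages.copy(), meta.copy())


def simulate_gwas(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, GroundTruth]:
    """GWAS summary statistics with known causal architecture.

    A ``causal_fraction`` of independent SNPs receive true effects scaled so
    the true score's liability variance equals ``h2_prs``; estimated betas
    add sampling noise for a notional discovery sample of ``gwas_n``, and
    two-sided p-values derive from the resulting z-statistics, so p-value
    thresholding behaves like real summary statistics.
    """
    rng = rng or _rng(cfg)
    m = cfg.n_gwas_snps
    freqs = rng.uniform(0.1, 0.9, size=m)
    n_causal = max(1, round(cfg.causal_fraction * m))
    causal_idx = rng.choice(m, size=n_causal, replace=False)
    beta = np.zeros(m)
    raw = rng.normal(size=n_causal)
    var_unit = 2 * freqs[causal_idx] * (1 - freqs[causal_idx])
    scale = (
        np.sqrt(cfg.h2_prs / float((raw**2 * var_unit).sum())) if cfg.h2_prs > 0 else 0.0
    )
    beta[causal_idx] = raw * scale
    se = 1.0 / np.sqrt(2 * freqs * (1 - freqs) * cfg.gwas_n)
    beta_hat = beta + rng.normal(scale=se)
    from scipy.stats import norm

    z = beta_hat / se
    p = np.clip(2 * norm.sf(np.abs(z)), 1e-300, 1.0)
    snps = [f"gw{j:05d}" for j in range(m)]
    stats_df = pd.DataFrame(
        {
            "snp": snps,
            "chrom": [str(1 + j % 22) for j in range(m)],
            "pos": [1_000_000 + 500_000 * j for j in range(m)],
            "effect_allele": "A",
            "other_allele": "G",
            "beta": beta_hat,
            "p": p,
            "freq": freqs,
        }
    )
    truth = GroundTruth(
        true_beta={snps[j]: float(beta[j]) for j in range(m)},
        causal_snps=[snps[j] for j in sorted(causal_idx)],
        params={"h2_prs": cfg.h2_prs, "gwas_n": cfg.gwas_n},
    )
    return stats_df, truth


def simulate_prs_cohort(
    stats_df: pd.DataFrame,
    truth: GroundTruth,
    cfg: SimConfig,
    n: int,
    rng: np.random.Generator | None = None,
) -> tuple[DosageMatrix, pd.Series, pd.Series]:
    """Unrelated cohort genotyped at the GWAS SNPs with a liability built
    from the true polygenic effects: liability = true score + environmental
    noise with variance ``1 - h2_prs``.  Returns (dosages, liability,
    genetic component)."""
    rng = rng or _rng(cfg)
    freqs = stats_df["freq"].to_numpy(float)
    snps = list(stats_df["snp"])
    G = rng.binomial(2, freqs, size=(n, len(snps))).astype(float)
    beta_true = np.array([truth.true_beta.get(s, 0.0) for s in snps])
    centred = G - 2 * freqs
    g = centred @ beta_true
    e = rng.normal(scale=np.sqrt(max(1e-12, 1 - cfg.h2_prs)), size=n)
    liab = g + e
    ids = [f"s{i:04d}" for i in range(n)]
    meta = stats_df.set_index("snp")[["chrom", "pos"]].copy()
    dos = DosageMatrix(pd.DataFrame(G, index=ids, columns=snps), meta)
    return dos, pd.Series(liab, index=ids), pd.Series(g, index=ids)


def simulate_study(cfg: SimConfig, outdir: str | Path) -> GroundTruth:
    """Generate one complete synthetic study into *outdir*: pedigree file,
    exome annotation table, carrier map, array dosages, marker metadata,
    GWAS summary statistics and a ground-truth JSON."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    rng = _rng(cfg)
    ped = simulate_pedigree(cfg, rng)
    cm, phenotypes, truth = gene_drop(ped, cfg, rng)
    variants, annotations = simulate_exome_table(ped, cm, cfg, rng)
    dosages, panel = simulate_array(ped, cfg, rng)
    stats_df, gwas_truth = simulate_gwas(cfg, rng)

    write_pedigree(ped, out / "pedigree.ped")
    write_annotation_tsv(annotations.values(), out / "annotations.tsv")
    write_carrier_tsv([cm], out / "carriers.tsv")
    dosages.dosages.round(0).to_csv(out / "dosages.tsv", sep="\t")
    panel.meta.to_csv(out / "markers.tsv", sep="\t")
    stats_df.to_csv(out / "gwas_stats.tsv", sep="\t", index=False)
    truth.true_beta = gwas_truth.true_beta
    truth.causal_snps = gwas_truth.causal_snps
    (out / "ground_truth.json").write_text(truth.to_json() + "\n")
    return truth
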