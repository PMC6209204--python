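"""Exome rare-variant prioritization cascade.

The cascade mirrors a family-based exome workflow for dominant-acting
candidate alleles: per-sample heterozygous-call evidence filters (allele
balance 25-75%, depth >= 10x, quality >= 10), restriction to nonsynonymous or
strong splice consequences, the requirement that the variant is positively
observed in *every* affected case of the pedigree, a population-rarity filter
(reference-exome MAF < 0.1%, strict), and an in-silico deleteriousness
consensus: SNVs must be called damaging/possibly-damaging by at least 4 of 5
tools (SIFT, PolyPhen-2 HumDiv, PolyPhen-2 HumVar, LRT, MutationTaster);
indels by at least 1 of 3 (MutationTaster, SIFT-indel, Provean).

Every stage records a surviving-variant count into a
:class:`PrioritizationFunnel`; counts decrease weakly along the cascade and
the final set is order-independent (all predicates are conjunctive).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import pandas as pd

from .pedigree import Pedigree

__all__ = [
    "SampleCall",
    "VariantRecord",
    "AnnotationRecord",
    "FilterConfig",
    "PrioritizationFunnel",
    "genotype_pass",
    "is_nonsynonymous",
    "is_rare",
    "consensus_damaging",
    "damaging_count",
    "shared_by_affected",
    "prioritize",
    "read_annotation_tsv",
    "write_annotation_tsv",
    "read_vcf",
    "write_funnel_tsv",
]

Genotype = Literal["hom_ref", "het", "hom_alt", "missing"]

#: Tool order for SNV predictions.
SNV_TOOLS = ("SIFT", "PPh2_HumDiv", "PPh2_HumVar", "LRT", "MutationTaster")
#: Tool order for indel predictions.
INDEL_TOOLS = ("MutationTaster", "SIFT_indel", "Provean")

#: Calls counted as (potentially) damaging for the SNV consensus:
#: D = damaging / probably damaging / deleterious / disease-causing,
#: P = possibly damaging.  B/T/N and NA count as non-damaging.
DAMAGING_CALLS = frozenset({"D", "P"})

NONSYNONYMOUS_CLASSES = frozenset(
    {"missense", "frameshift_indel", "inframe_indel", "splice"}
)


@dataclass
class SampleCall:
    sample_id: str
    genotype: Genotype
    depth: int = 0
    alt_fraction: float | None = None
    quality: float = 0.0


@dataclass
class VariantRecord:
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str = ""
    variant_class: str = "other"
    calls: dict[str, SampleCall] = field(default_factory=dict)

    @property
    def vid(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)


@dataclass
class AnnotationRecord:
    """External annotations for one variant.

    ``snv_predictions`` holds the five SNV tool calls in :data:`SNV_TOOLS`
    order; ``indel_predictions`` the three indel tool calls in
    :data:`INDEL_TOOLS` order.  Exactly one of the two is populated.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str = ""
    exac_maf: float | None = None
    dbsnp_id: str | None = None
    aa_change: str = ""
    snv_predictions: tuple[str, ...] | None = None
    indel_predictions: tuple[str, ...] | None = None
    rpkm_hippocampus: float | None = None

    @property
    def vid(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


@dataclass
class FilterConfig:
    """Thresholds for the prioritization cascade (defaults = study settings)."""

    ab_min: float = 0.25
    ab_max: float = 0.75
    min_depth: int = 10
    min_quality: float = 10.0
    maf_rare: float = 0.001
    maf_relaxed: float = 0.05
    snv_consensus_min: int = 4
    indel_consensus_min: int = 1
    #: relaxed mode compares MAF with <= instead of strict <
    maf_inclusive: bool = False
    #: optional artifact blacklist of (chrom, pos, ref, alt) tuples
    blacklist: frozenset = frozenset()

    def __post_init__(self) -> None:
        if not (0 <= self.ab_min < self.ab_max <= 1):
            raise ValueError("require 0 <= ab_min < ab_max <= 1")
        if self.min_depth <= 0 or self.min_quality < 0:
            raise ValueError("depth/quality thresholds must be positive")


@dataclass
class PrioritizationFunnel:
    """Per-stage surviving-variant counts and the final prioritized set."""

    stages: list[tuple[str, int]]
    final_ids: list[str]
    warnings: list[str] = field(default_factory=list)

    def counts(self) -> dict[str, int]:
        return dict(self.stages)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages, columns=["stage", "count"])


def genotype_pass(call: SampleCall, cfg: FilterConfig | None = None) -> bool:
    """True iff *call* is a well-supported heterozygous observation.

    Requires het genotype, alt-read fraction within [ab_min, ab_max],
    depth >= min_depth and quality >= min_quality.  Missing genotypes fail.
    """
    cfg = cfg or FilterConfig()
    if call.genotype != "het" or call.alt_fraction is None:
        return False
    return (
        cfg.ab_min <= call.alt_fraction <= cfg.ab_max
        and call.depth >= cfg.min_depth
        and call.quality >= cfg.min_quality
    )


def is_nonsynonymous(v: VariantRecord) -> bool:
    """True for consequences altering primary protein structure or splicing."""
    return v.variant_class in NONSYNONYMOUS_CLASSES


def is_rare(a: AnnotationRecord, threshold: float, inclusive: bool = False) -> bool:
    """Rarity filter against the reference-exome MAF.

    An absent MAF counts as rare (the variant is unobserved in the reference
    panel).  The default comparison is strict ``<``; ``inclusive`` switches
    to ``<=`` for the relaxed candidate list.
    """
    if not (0 < threshold < 1):
        raise ValueError("threshold must be in (0, 1)")
    if a.exac_maf is None:
        return True
    return a.exac_maf <= threshold if inclusive else a.exac_maf < threshold


def damaging_count(a: AnnotationRecord) -> int:
    """Number of damaging tool calls under the rule for the variant's class."""
    if a.snv_predictions is not None:
        return sum(c in DAMAGING_CALLS for c in a.snv_predictions)
    if a.indel_predictions is not None:
        return sum(c == "D" for c in a.indel_predictions)
    raise ValueError(f"variant {a.vid} has no prediction calls")


def consensus_damaging(a: AnnotationRecord, cfg: FilterConfig | None = None) -> bool:
    """In-silico deleteriousness consensus.

    SNVs: >= ``snv_consensus_min`` of the five calls in {D, P} (NA and
    benign/tolerated/neutral count as non-damaging).  Indels: >=
    ``indel_consensus_min`` of the three calls equal to D.
    """
    cfg = cfg or FilterConfig()
    n = damaging_count(a)
    if a.snv_predictions is not None:
        return n >= cfg.snv_consensus_min
    return n >= cfg.indel_consensus_min


def shared_by_affected(
    variants: Iterable[VariantRecord],
    ped: Pedigree,
    cases: Sequence[str],
    cfg: FilterConfig | None = None,
) -> list[VariantRecord]:
    """Variants positively observed (passing :func:`genotype_pass`) in every
    case.  A case id with no call at any variant is a hard error."""
    cfg = cfg or FilterConfig()
    variants = list(variants)
    if not cases:
        raise ValueError("cases must be non-empty")
    seen = {c for v in variants for c in v.calls if c in set(cases)}
    missing = set(cases) - seen
    if variants and missing:
        raise ValueError(f"case ids absent from all sample calls: {sorted(missing)}")
    out = []
    for v in variants:
        if all(c in v.calls and genotype_pass(v.calls[c], cfg) for c in cases):
            out.append(v)
    return out


_STAGES = (
    "input",
    "genotype_pass",
    "nonsynonymous",
    "shared_by_affected",
    "rare",
    "consensus_damaging",
)


def prioritize(
    variants: Iterable[VariantRecord],
    annotations: Mapping[str, AnnotationRecord],
    ped: Pedigree,
    cases: Sequence[str],
    cfg: FilterConfig | None = None,
) -> PrioritizationFunnel:
    """Run the full cascade and record the per-stage funnel.

    Stage semantics: *genotype_pass* keeps variants with at least one case
    carrying a passing het call (evidence exists); *shared_by_affected* then
    requires every case to pass.  Variants lacking an annotation record are
    excluded with a warning.  The final set equals the simultaneous
    conjunction of all predicates regardless of stage order.
    """
    cfg = cfg or FilterConfig()
    current = [
        v for v in variants if (v.chrom, v.pos, v.ref, v.alt) not in cfg.blacklist
    ]
    warnings: list[str] = []
    stages: list[tuple[str, int]] = [("input", len(current))]

    current = [
        v
        for v in current
        if any(c in v.calls and genotype_pass(v.calls[c], cfg) for c in cases)
    ]
    stages.append(("genotype_pass", len(current)))

    current = [v for v in current if is_nonsynonymous(v)]
    stages.append(("nonsynonymous", len(current)))

    current = shared_by_affected(current, ped, cases, cfg) if current else []
    stages.append(("shared_by_affected", len(current)))

    joined = []
    for v in current:
        ann = annotations.get(v.vid)
        if ann is None:
            warnings.append(f"variant {v.vid} has no annotation record; excluded")
            continue
        joined.append((v, ann))
    current_ann = [
        (v, a) for v, a in joined if is_rare(a, cfg.maf_rare, cfg.maf_inclusive)
    ]
    stages.append(("rare", len(current_ann)))

    final = [(v, a) for v, a in current_ann if consensus_damaging(a, cfg)]
    stages.append(("consensus_damaging", len(final)))

    return PrioritizationFunnel(
        stages=stages, final_ids=[v.vid for v, _ in final], warnings=warnings
    )


# ---------------------------------------------------------------------------
# text IO
# ---------------------------------------------------------------------------

_ANN_COLUMNS = [
    "Gene",
    "Chr",
    "Position",
    "Ref",
    "Alt",
    "VariantClass",
    "ExAC_MAF",
    "dbSNP",
    "AA_change",
    *SNV_TOOLS,
    *(f"Indel_{t}" for t in INDEL_TOOLS),
    "RPKM_hippocampus",
]


def read_annotation_tsv(path: str | Path) -> dict[str, AnnotationRecord]:
    """Read a per-variant annotation table (columns as written by
    :func:`write_annotation_tsv`; missing values as ``NA`` or empty)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out: dict[str, AnnotationRecord] = {}
    for _, row in df.iterrows():
        rec = _annotation_from_row(row)
        out[rec.vid] = rec
    return out


def _opt_float(x: str) -> float | None:
    return None if x in ("", "NA", ".") else float(x)


def _annotation_from_row(row: Mapping[str, str]) -> AnnotationRecord:
    snv = tuple(row.get(t, "NA") or "NA" for t in SNV_TOOLS)
    indel = tuple(row.get(f"Indel_{t}", "NA") or "NA" for t in INDEL_TOOLS)
    is_indel = len(row["Ref"].replace("-", "")) != len(row["Alt"].replace("-", ""))
    return AnnotationRecord(
        chrom=row["Chr"],
        pos=int(row["Position"]),
        ref=row["Ref"],
        alt=row["Alt"],
        gene=row.get("Gene", ""),
        exac_maf=_opt_float(row.get("ExAC_MAF", "NA")),
        dbsnp_id=row.get("dbSNP") if row.get("dbSNP") not in ("", "NA") else None,
        aa_change=row.get("AA_change", ""),
        snv_predictions=None if is_indel else snv,
        indel_predictions=indel if is_indel else None,
        rpkm_hippocampus=_opt_float(row.get("RPKM_hippocampus", "NA")),
    )


def write_annotation_tsv(records: Iterable[AnnotationRecord], path: str | Path) -> None:
    rows = []
    for a in records:
        snv = a.snv_predictions or ("NA",) * 5
        indel = a.indel_predictions or ("NA",) * 3
        rows.append(
            [
                a.gene,
                a.chrom,
                a.pos,
                a.ref,
                a.alt,
                "indel" if a.indel_predictions is not None else "snv",
                "NA" if a.exac_maf is None else repr(a.exac_maf),
                a.dbsnp_id or "NA",
                a.aa_change,
                *snv,
                *indel,
                "NA" if a.rpkm_hippocampus is None else a.rpkm_hippocampus,
            ]
        )
    pd.DataFrame(rows, columns=_ANN_COLUMNS).to_csv(path, sep="\t", index=False)


def write_funnel_tsv(funnel: PrioritizationFunnel, path: str | Path) -> None:
    funnel.to_frame().to_csv(path, sep="\t", index=False)


def read_vcf(path: str | Path, gene_field: str = "GENE", class_field: str = "CLASS") -> list[VariantRecord]:
    """Read variants with per-sample evidence from a VCF 4.x file.

    Uses GT, DP, AD (alt fraction) and GQ.  Gene symbol and consequence class
    are taken from the INFO fields *gene_field* / *class_field* when present.
    Requires cyvcf2 (optional dependency).
    """
    from cyvcf2 import VCF  # lazy: optional extra

    vcf = VCF(str(path))
    samples = vcf.samples
    out: list[VariantRecord] = []
    for rec in vcf:
        calls: dict[str, SampleCall] = {}
        gts = rec.genotypes  # [allele1, allele2, phased]
        depths = rec.format("DP")
        ads = rec.format("AD")
        gqs = rec.format("GQ")
        for i, s in enumerate(samples):
            a, b = gts[i][0], gts[i][1]
            if a < 0 or b < 0:
                gt: Genotype = "missing"
            elif a == b == 0:
                gt = "hom_ref"
            elif a == b:
                gt = "hom_alt"
            else:
                gt = "het"
            depth = int(depths[i][0]) if depths is not None and depths[i][0] >= 0 else 0
            af = None
            if ads is not None and depth > 0 and ads[i][1] >= 0:
                af = float(ads[i][1]) / depth
            gq = float(gqs[i][0]) if gqs is not None and gqs[i][0] >= 0 else 0.0
            calls[s] = SampleCall(s, gt, depth=depth, alt_fraction=af, quality=gq)
        out.append(
            VariantRecord(
                chrom=rec.CHROM,
                pos=rec.POS,
                ref=rec.REF,
                alt=rec.ALT[0] if rec.ALT else ".",
                gene=rec.INFO.get(gene_field, "") or "",
                variant_class=rec.INFO.get(class_field, "other") or "other",
                calls=calls,
            )
        )
    return out
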