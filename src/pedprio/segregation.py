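"""Segregation analysis of candidate variants across genotyped relatives.

Carrier-by-phenotype-class summaries (excluding individuals related by
marriage only), transmission counts into a bilineal offspring branch,
cross-family presence checks, and the hippocampal-expression rule
(RPKM >= 0.1 classifies a gene as brain-expressed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd

from .filtering import FilterConfig, VariantRecord, genotype_pass
from .pedigree import Pedigree, PhenotypeClass

__all__ = [
    "CarrierStatus",
    "CarrierMap",
    "SegregationSummary",
    "PresenceReport",
    "ExpressionCall",
    "carrier_map_from_variant",
    "segregation_summary",
    "transmission_count",
    "fully_shared_in",
    "cross_family_presence",
    "brain_expressed",
    "read_carrier_tsv",
    "write_carrier_tsv",
]

CarrierStatus = Literal["carrier", "non_carrier", "untyped"]

_SUMMARY_CLASSES = (
    PhenotypeClass.BD,
    PhenotypeClass.OTHER_PSYCH,
    PhenotypeClass.UNAFFECTED,
)


@dataclass
class CarrierMap:
    """Carrier status of one variant across genotyped individuals."""

    variant_id: str
    status: dict[str, CarrierStatus] = field(default_factory=dict)

    @property
    def carriers(self) -> set[str]:
        return {i for i, s in self.status.items() if s == "carrier"}

    def typed(self) -> set[str]:
        return {i for i, s in self.status.items() if s != "untyped"}

    def get(self, iid: str) -> CarrierStatus:
        return self.status.get(iid, "untyped")


def carrier_map_from_variant(
    v: VariantRecord, cfg: FilterConfig | None = None
) -> CarrierMap:
    """Derive carrier status from per-sample calls.

    Carrier = at least one alternate allele supported by passing evidence:
    a het call passing :func:`~pedprio.filtering.genotype_pass`, or a hom-alt
    call meeting the depth/quality thresholds (the allele-balance band is a
    heterozygote criterion and does not apply).  Missing genotypes are
    untyped; anything else typed is a non-carrier.
    """
    cfg = cfg or FilterConfig()
    status: dict[str, CarrierStatus] = {}
    for iid, call in v.calls.items():
        if call.genotype == "missing":
            status[iid] = "untyped"
        elif genotype_pass(call, cfg) or (
            call.genotype == "hom_alt"
            and call.depth >= cfg.min_depth
            and call.quality >= cfg.min_quality
        ):
            status[iid] = "carrier"
        else:
            status[iid] = "non_carrier"
    return CarrierMap(v.vid, status)


@dataclass
class SegregationSummary:
    """Carrier counts per phenotype class among typed, non-married-in members."""

    variant_id: str
    carriers: dict[PhenotypeClass, int]
    denominators: dict[PhenotypeClass, int]
    excluded_married_in: int = 0

    def to_row(self) -> dict:
        row: dict = {"variant_id": self.variant_id}
        for cls in _SUMMARY_CLASSES:
            row[cls.value] = self.carriers[cls]
            row[f"{cls.value}_n"] = self.denominators[cls]
        row["excluded_married_in"] = self.excluded_married_in
        return row


def segregation_summary(cm: CarrierMap, ped: Pedigree) -> SegregationSummary:
    """Tabulate carriers of *cm* per phenotype class.

    Only typed members count; individuals related by marriage only are
    excluded (their count is reported separately).  Typed ids absent from
    the pedigree are a hard error.
    """
    missing = cm.typed() - set(ped.members())
    if missing:
        raise ValueError(f"carrier status for ids not in pedigree: {sorted(missing)}")
    carriers = {cls: 0 for cls in _SUMMARY_CLASSES}
    denoms = {cls: 0 for cls in _SUMMARY_CLASSES}
    excluded = 0
    for iid in cm.typed():
        ind = ped[iid]
        if ind.married_in:
            excluded += 1
            continue
        cls = ind.phenotype_class
        if cls not in carriers:
            continue  # UNKNOWN-class members are not tabulated
        denoms[cls] += 1
        if cm.get(iid) == "carrier":
            carriers[cls] += 1
    return SegregationSummary(cm.variant_id, carriers, denoms, excluded)


def transmission_count(cm: CarrierMap, offspring: Iterable[str]) -> int:
    """Number of carriers among an offspring id set (e.g. a bilineal branch)."""
    return sum(cm.get(i) == "carrier" for i in set(offspring))


def fully_shared_in(cms: Iterable[CarrierMap], group: Iterable[str]) -> set[str]:
    """Variants carried by *every* member of *group*."""
    group = set(group)
    if not group:
        raise ValueError("group must be non-empty")
    return {
        cm.variant_id
        for cm in cms
        if sum(cm.get(i) == "carrier" for i in group) == len(group)
    }


@dataclass
class PresenceReport:
    variant_id: str
    status: dict[str, CarrierStatus]

    @property
    def any_present(self) -> bool:
        return any(s == "carrier" for s in self.status.values())

    @property
    def carriers(self) -> list[str]:
        return sorted(i for i, s in self.status.items() if s == "carrier")


def cross_family_presence(
    cm: CarrierMap,
    other: Pedigree | Iterable[str],
    married_in: Iterable[str] = (),
) -> PresenceReport:
    """Check a candidate variant in the other family and in married-in
    individuals; used to confirm that pedigree-private candidates are absent
    elsewhere."""
    ids = list(other.members() if isinstance(other, Pedigree) else other)
    ids += [i for i in married_in if i not in ids]
    return PresenceReport(cm.variant_id, {i: cm.get(i) for i in ids})


@dataclass
class ExpressionCall:
    gene: str
    rpkm_hippocampus: float | None
    brain_expressed: bool | None


def brain_expressed(rpkm: float | None, threshold: float = 0.1) -> bool | None:
    """Hippocampal-expression rule: RPKM >= threshold (non-strict).

    Returns ``None`` (unknown) for an absent RPKM; negative RPKM is an error.
    """
    if rpkm is None:
        return None
    if rpkm < 0:
        raise ValueError("RPKM must be non-negative")
    return rpkm >= threshold


# ---------------------------------------------------------------------------
# text IO
# ---------------------------------------------------------------------------

def read_carrier_tsv(path: str | Path) -> list[CarrierMap]:
    """Read carrier maps from TSV columns variant_id, individual_id, status."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    out: dict[str, CarrierMap] = {}
    for _, row in df.iterrows():
        cm = out.setdefault(row["variant_id"], CarrierMap(row["variant_id"]))
        status = row["status"]
        if status not in ("carrier", "non_carrier", "untyped"):
            raise ValueError(f"bad carrier status {status!r}")
        cm.status[row["individual_id"]] = status
    return list(out.values())


def write_carrier_tsv(cms: Sequence[CarrierMap], path: str | Path) -> None:
    rows = [
        {"variant_id": cm.variant_id, "individual_id": i, "status": s}
        for cm in cms
        for i, s in cm.status.items()
    ]
    pd.DataFrame(rows, columns=["variant_id", "individual_id", "status"]).to_csv(
        path, sep="\t", index=False
    )
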