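"""Pedigree and phenotype data model.

Individuals carry a free-text psychiatric diagnosis drawn from a controlled
vocabulary; downstream analyses never look at the diagnosis directly but at a
*phenotype class* (``BD``, ``OTHER_PSYCH``, ``UNAFFECTED``, ``UNKNOWN``)
assigned through a :class:`PhenotypeScheme`.  Two schemes are built in:

``broad``
    Bipolar subtypes (I, II, NOS) map to ``BD``; any other psychiatric
    diagnosis (recurrent or single-episode major depression, alcohol abuse)
    maps to ``OTHER_PSYCH``; healthy maps to ``UNAFFECTED``.  Used for
    segregation tables.

``strict_linkage``
    As above, except non-BD psychiatric diagnoses map to ``UNKNOWN`` so that
    linkage statistics neither count them as affected nor as unaffected.
    Default for the non-parametric linkage module.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import networkx as nx

__all__ = [
    "PhenotypeClass",
    "PhenotypeScheme",
    "BROAD",
    "STRICT_LINKAGE",
    "SCHEMES",
    "DIAGNOSIS_VOCABULARY",
    "classify_phenotype",
    "Individual",
    "Pedigree",
    "PedigreeError",
    "ValidationReport",
    "validate_pedigree",
    "read_pedigree",
    "write_pedigree",
]


class PhenotypeClass(str, Enum):
    BD = "BD"
    OTHER_PSYCH = "OTHER_PSYCH"
    UNAFFECTED = "UNAFFECTED"
    UNKNOWN = "UNKNOWN"


#: Controlled diagnosis vocabulary.  User-supplied mapping files may extend it.
DIAGNOSIS_VOCABULARY = (
    "BD_I",
    "BD_II",
    "BD_NOS",
    "MDD_RECURRENT",
    "MDD_SINGLE",
    "ALCOHOL_ABUSE",
    "HEALTHY",
)


@dataclass(frozen=True)
class PhenotypeScheme:
    """Mapping from diagnosis labels to phenotype classes."""

    name: str
    mapping: Mapping[str, PhenotypeClass]

    def classify(self, diagnosis: str) -> PhenotypeClass:
        return classify_phenotype(diagnosis, self)


_BD = {d: PhenotypeClass.BD for d in ("BD_I", "BD_II", "BD_NOS")}
_OTHER = ("MDD_RECURRENT", "MDD_SINGLE", "ALCOHOL_ABUSE")

BROAD = PhenotypeScheme(
    "broad",
    {**_BD, **{d: PhenotypeClass.OTHER_PSYCH for d in _OTHER}, "HEALTHY": PhenotypeClass.UNAFFECTED},
)
STRICT_LINKAGE = PhenotypeScheme(
    "strict_linkage",
    {**_BD, **{d: PhenotypeClass.UNKNOWN for d in _OTHER}, "HEALTHY": PhenotypeClass.UNAFFECTED},
)
SCHEMES = {"broad": BROAD, "strict_linkage": STRICT_LINKAGE}


def classify_phenotype(diagnosis: str, scheme: PhenotypeScheme | str) -> PhenotypeClass:
    """Map a diagnosis label to a phenotype class under *scheme*.

    Raises ``ValueError`` listing the vocabulary for unknown labels.
    """
    if isinstance(scheme, str):
        scheme = SCHEMES[scheme]
    try:
        return scheme.mapping[diagnosis]
    except KeyError:
        raise ValueError(
            f"unknown diagnosis {diagnosis!r}; expected one of {sorted(scheme.mapping)}"
        ) from None


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (duplicate or dangling ids)."""


@dataclass
class Individual:
    """One pedigree member.

    ``father``/``mother`` are ``None`` for founders.  ``married_in`` flags
    members related to the family by marriage only; segregation tables
    exclude them.
    """

    iid: str
    father: str | None = None
    mother: str | None = None
    sex: str = "unknown"  # {male, female, unknown}
    diagnosis: str = "HEALTHY"
    phenotype_class: PhenotypeClass = PhenotypeClass.UNKNOWN
    married_in: bool = False

    @property
    def is_founder(self) -> bool:
        return self.father is None and self.mother is None

    def __post_init__(self) -> None:
        if (self.father is None) != (self.mother is None):
            raise PedigreeError(
                f"individual {self.iid!r}: both parents must be present or both absent"
            )


class Pedigree:
    """A pedigree: a collection of individuals with resolvable parent links.

    Construction with ``strict=True`` (default) raises :class:`PedigreeError`
    on duplicate ids or parent references that do not resolve within the
    pedigree.  ``strict=False`` defers such problems to
    :func:`validate_pedigree`, which reports them instead.
    """

    def __init__(
        self,
        individuals: Iterable[Individual],
        subpedigree_id: str = "1",
        strict: bool = True,
    ) -> None:
        self.subpedigree_id = subpedigree_id
        self._members: dict[str, Individual] = {}
        for ind in individuals:
            if ind.iid in self._members:
                raise PedigreeError(f"duplicate individual id {ind.iid!r}")
            self._members[ind.iid] = ind
        if strict:
            for ind in self._members.values():
                for role, pid in (("father", ind.father), ("mother", ind.mother)):
                    if pid is not None and pid not in self._members:
                        raise PedigreeError(
                            f"{role} {pid!r} of individual {ind.iid!r} not present in pedigree"
                        )
            report = validate_pedigree(self)
            if not report.ok:
                raise PedigreeError("; ".join(report.issues))

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._members)

    def __iter__(self) -> Iterator[Individual]:
        return iter(self._members.values())

    def __contains__(self, iid: str) -> bool:
        return iid in self._members

    def __getitem__(self, iid: str) -> Individual:
        return self._members[iid]

    def members(self) -> list[str]:
        return list(self._members)

    # -- structure ----------------------------------------------------------
    @property
    def founders(self) -> list[str]:
        return [i.iid for i in self if i.is_founder]

    @property
    def nonfounders(self) -> list[str]:
        return [i.iid for i in self if not i.is_founder]

    def graph(self) -> nx.DiGraph:
        """Parent -> child digraph over the pedigree."""
        g = nx.DiGraph()
        g.add_nodes_from(self._members)
        for ind in self:
            for pid in (ind.father, ind.mother):
                if pid is not None and pid in self._members:
                    g.add_edge(pid, ind.iid)
        return g

    def topological_nonfounders(self) -> list[str]:
        """Non-founders ordered so every parent precedes its children."""
        order = list(nx.topological_sort(self.graph()))
        return [i for i in order if not self._members[i].is_founder]

    def children(self, iid: str) -> list[str]:
        return [i.iid for i in self if iid in (i.father, i.mother)]

    # -- phenotype ----------------------------------------------------------
    def apply_scheme(self, scheme: PhenotypeScheme | str) -> "Pedigree":
        """Return a copy with phenotype classes re-derived from diagnoses."""
        if isinstance(scheme, str):
            scheme = SCHEMES[scheme]
        new = [
            replace(ind, phenotype_class=classify_phenotype(ind.diagnosis, scheme))
            for ind in self
        ]
        return Pedigree(new, subpedigree_id=self.subpedigree_id)

    def ids_with_class(self, cls: PhenotypeClass) -> list[str]:
        return [i.iid for i in self if i.phenotype_class is cls]

    @property
    def affected(self) -> list[str]:
        return self.ids_with_class(PhenotypeClass.BD)


@dataclass
class ValidationReport:
    issues: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.issues


def validate_pedigree(ped: Pedigree) -> ValidationReport:
    """Report structural problems: dangling parents, cycles, sex-inconsistent
    parent roles.  An empty report means all pedigree invariants hold."""
    issues: list[str] = []
    for ind in ped:
        for role, pid, want_sex in (
            ("father", ind.father, "male"),
            ("mother", ind.mother, "female"),
        ):
            if pid is None:
                continue
            if pid not in ped:
                issues.append(f"{role} {pid!r} of {ind.iid!r} not in pedigree")
                continue
            parent = ped[pid]
            if parent.sex not in ("unknown", want_sex):
                issues.append(
                    f"{role} {pid!r} of {ind.iid!r} is coded {parent.sex}, expected {want_sex}"
                )
    g = ped.graph()
    if not nx.is_directed_acyclic_graph(g):
        cyc = nx.find_cycle(g)
        path = " -> ".join(e[0] for e in cyc) + f" -> {cyc[-1][1]}"
        issues.append(f"cycle in parent-child graph: {path}")
    return ValidationReport(issues)


_SEX_CODE = {"1": "male", "2": "female", "0": "unknown"}
_SEX_OUT = {v: k for k, v in _SEX_CODE.items()}
_MISSING_PARENT = {"0", ".", ""}


def read_pedigree(
    path: str | Path,
    scheme: PhenotypeScheme | str = BROAD,
    family: str | None = None,
    strict: bool = True,
) -> Pedigree:
    """Read a whitespace-delimited PED-like file.

    Columns: FID IID FATHER MOTHER SEX DIAGNOSIS [MARRIED_IN].  SEX is coded
    1/2/0; missing parents are "0" or ".".  Lines beginning with ``#`` are
    ignored.  When the file contains several family ids, *family* selects one.
    """
    rows: list[list[str]] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields_ = line.split()
        if len(fields_) < 6:
            raise PedigreeError(f"expected >= 6 columns, got {len(fields_)}: {line!r}")
        rows.append(fields_)

    fids = sorted({r[0] for r in rows})
    if family is None:
        if len(fids) > 1:
            raise PedigreeError(
                f"file contains families {fids}; pass family=... to select one"
            )
        family = fids[0]
    rows = [r for r in rows if r[0] == family]
    if not rows:
        raise PedigreeError(f"family {family!r} not found in {path}")

    if isinstance(scheme, str):
        scheme = SCHEMES[scheme]
    individuals = []
    for r in rows:
        _, iid, fa, mo, sex, dx = r[:6]
        married = len(r) > 6 and r[6] not in ("0", "false", "False")
        individuals.append(
            Individual(
                iid=iid,
                father=None if fa in _MISSING_PARENT else fa,
                mother=None if mo in _MISSING_PARENT else mo,
                sex=_SEX_CODE.get(sex, "unknown"),
                diagnosis=dx,
                phenotype_class=classify_phenotype(dx, scheme),
                married_in=married,
            )
        )
    return Pedigree(individuals, subpedigree_id=family, strict=strict)


def write_pedigree(ped: Pedigree, path: str | Path) -> None:
    """Write the PED-like text format read by :func:`read_pedigree`."""
    lines = ["#FID\tIID\tFATHER\tMOTHER\tSEX\tDIAGNOSIS\tMARRIED_IN"]
    for ind in ped:
        lines.append(
            "\t".join(
                [
                    ped.subpedigree_id,
                    ind.iid,
                    ind.father or "0",
                    ind.mother or "0",
                    _SEX_OUT[ind.sex],
                    ind.diagnosis,
                    "1" if ind.married_in else "0",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")
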