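"""Bundled worked-example data from a two-pedigree bipolar-disorder exome study.

Seventeen rare candidate variants (14 missense SNVs, 3 frameshift indels)
were published for a six-generation pedigree (pedigree 1) and a bilineal
four-generation family split into subpedigrees 2, 3 and 4.  The tables
reproduced here carry, per variant: the five SNV prediction-tool calls
(SIFT, PolyPhen-2 HumDiv/HumVar, LRT, MutationTaster) or the indel
MutationTaster call, the reference-exome MAF, the hippocampal RPKM of the
host gene, and carrier counts per phenotype class in each subpedigree.

The published pedigree drawings are anonymized, so :func:`family1_pedigree`
reconstructs a *synthetic* 11-member, four-generation structure that is
consistent with every printed count (five BD members including the
fifth-generation case, one alcohol-abuse member with carrier status, two
healthy carriers, class denominators 5/1/3 after excluding two married-in
healthy members).  Likewise :func:`pedigree4_carrier_maps` assigns
per-individual carrier status among the five BD members of bilineal
pedigree 4 synthetically, matching the printed per-variant counts.
"""

from __future__ import annotations

import io

import pandas as pd

from .filtering import AnnotationRecord, _annotation_from_row
from .pedigree import BROAD, Individual, Pedigree, PhenotypeScheme, classify_phenotype
from .segregation import CarrierMap

__all__ = [
    "candidate_variant_annotations",
    "candidate_variant_table",
    "rpkm_table",
    "family1_pedigree",
    "family1_carrier_maps",
    "pedigree4_carrier_maps",
    "PEDIGREE4_BD_MEMBERS",
]

# Published candidate-variant table: 17 variants.  VariantClass distinguishes
# the 14 missense SNVs from the 3 frameshift indels.  Indel rows carry the
# MutationTaster call in the Indel_MutationTaster column (SIFT-indel and
# Provean calls were not available, encoded NA).
_CANDIDATES_TSV = """\
Gene	Pedigree	Chr	Position	Ref	Alt	VariantClass	ExAC_MAF	dbSNP	AA_change	SIFT	PPh2_HumDiv	PPh2_HumVar	LRT	MutationTaster	Indel_MutationTaster	Indel_SIFT_indel	Indel_Provean	RPKM_hippocampus
SERPING1	1	11	57379205	C	T	missense	4.9E-05	rs141075266	p.L349F	D	P	B	D	D	NA	NA	NA	8.11
TMEM220	1	17	10633149	C	A	missense	NA	NA	p.R7L	D	D	P	N	D	NA	NA	NA	0.98
ABCA4	2	1	94544977	A	T	missense	4.9E-04	rs61748549	p.N380K	D	P	P	D	D	NA	NA	NA	0.06
DNAH7	2	2	196726484	C	T	missense	4.2E-04	rs201185180	p.E2565K	D	D	P	D	D	NA	NA	NA	0.42
RCCD1	2	15	91500673	G	C	missense	NA	NA	p.G166A	D	D	P	N	D	NA	NA	NA	3.17
EPS8L3	3	1	110293386	C	T	missense	3.1E-04	rs148185176	p.G526R	D	D	D	D	D	NA	NA	NA	0.01
OLFML2B	3	1	161953665	C	A	missense	3.0E-04	rs142349285	p.A685S	D	D	D	NA	D	NA	NA	NA	0.71
CAPN2	3	1	223934845	C	T	missense	6.0E-04	rs140704789	p.S236F	D	D	D	D	D	NA	NA	NA	9.26
COL3A1	3	2	189875383	G	A	missense	2.0E-04	rs140646380	p.G1341S	T	D	D	D	D	NA	NA	NA	0.52
ATR	3	3	142281560	T	TT	frameshift_indel	NA	NA	p.L229Tfs*13	NA	NA	NA	NA	NA	D	NA	NA	1.49
CSNK1G3	3	5	122926124	C	T	missense	NA	NA	p.R288C	D	P	P	D	D	NA	NA	NA	3.56
THYN1	3	11	134119132	G	A	missense	9.9E-05	rs143669769	p.H137Y	T	P	P	D	D	NA	NA	NA	20.93
MYH7	3	14	23898481	A	ATG	frameshift_indel	NA	NA	p.K405Nfs*17	NA	NA	NA	NA	NA	D	NA	NA	0.92
FAM169B	3	15	98995065	A	G	missense	4.6E-04	rs183490372	p.M120T	D	D	D	D	D	NA	NA	NA	0.01
ZNF433	3	19	12127214	CAGAGG	C	frameshift_indel	NA	NA	p.S155Cfs*5	NA	NA	NA	NA	NA	D	NA	NA	0.82
CRX	3	19	48337728	C	G	missense	4.1E-04	rs139340178	p.H10D	T	D	P	D	D	NA	NA	NA	0
SELENOO	3	22	50648648	G	T	missense	2.5E-05	NA	p.Q326H	D	D	D	D	D	NA	NA	NA	8.47
"""


def candidate_variant_table() -> pd.DataFrame:
    """The 17-variant candidate table as a DataFrame (one row per variant)."""
    return pd.read_csv(io.StringIO(_CANDIDATES_TSV), sep="\t", dtype=str, keep_default_na=False)


def candidate_variant_annotations() -> dict[str, AnnotationRecord]:
    """The candidate table as :class:`AnnotationRecord` objects keyed by variant id."""
    df = candidate_variant_table()
    out: dict[str, AnnotationRecord] = {}
    for _, row in df.iterrows():
        is_indel = row["VariantClass"] == "frameshift_indel"
        rec = _annotation_from_row(row)
        # indel coordinates here are already VCF-style left-anchored
        if is_indel and rec.indel_predictions is None:
            raise AssertionError("indel rows must carry indel predictions")
        out[rec.vid] = rec
    return out


def rpkm_table() -> pd.DataFrame:
    """Gene -> hippocampal RPKM for the 17 candidate genes."""
    df = candidate_variant_table()
    return df[["Gene", "RPKM_hippocampus"]].assign(
        RPKM_hippocampus=lambda d: d["RPKM_hippocampus"].astype(float)
    )


# ---------------------------------------------------------------------------
# family 1 fixture (synthetic structure, published counts)
# ---------------------------------------------------------------------------

# iid, father, mother, diagnosis, married_in.  "uX" members are untyped
# married-in connectors needed only so that non-founders have two parents.
_FAMILY1_ROWS = [
    ("1", None, None, "HEALTHY", False),
    ("2", None, None, "HEALTHY", True),
    ("3", "1", "2", "HEALTHY", False),
    ("10", "1", "2", "ALCOHOL_ABUSE", False),
    ("6", None, None, "HEALTHY", True),
    ("4", "3", "6", "BD_I", False),
    ("8", "3", "6", "HEALTHY", False),
    ("u4", None, None, "HEALTHY", True),
    ("5", "4", "u4", "BD_I", False),
    ("7", "4", "u4", "BD_I", False),
    ("9", "4", "u4", "BD_NOS", False),
    ("u6", None, None, "HEALTHY", True),
    ("11", "5", "u6", "BD_II", False),
]

#: ids of family-1 members with DNA (typed in the carrier maps)
FAMILY1_TYPED = [str(i) for i in range(1, 12)]

#: the five BD members of bilineal pedigree 4 (four siblings + one offspring)
PEDIGREE4_BD_MEMBERS = ["11", "12", "14", "15", "19"]


def family1_pedigree(scheme: PhenotypeScheme = BROAD) -> Pedigree:
    """Synthetic 4-generation reconstruction of the 11 DNA-available members
    of family 1 (plus two untyped married-in connectors)."""
    inds = [
        Individual(
            iid=iid,
            father=fa,
            mother=mo,
            sex="unknown",
            diagnosis=dx,
            phenotype_class=classify_phenotype(dx, scheme),
            married_in=married,
        )
        for iid, fa, mo, dx, married in _FAMILY1_ROWS
    ]
    return Pedigree(inds, subpedigree_id="1")


def family1_carrier_maps() -> dict[str, CarrierMap]:
    """Carrier maps for the two pedigree-1 candidates, per the published
    segregation account: the TMEM220 variant in all five BD members, two
    healthy relatives and the alcohol-abuse member; the SERPING1 variant in
    the four exome-sequenced BD cases plus the healthy obligate carrier."""
    tmem_carriers = {"1", "3", "4", "5", "7", "9", "10", "11"}
    serping_carriers = {"3", "4", "5", "7", "9"}
    maps = {}
    for name, carriers in (("TMEM220", tmem_carriers), ("SERPING1", serping_carriers)):
        status = {
            i: ("carrier" if i in carriers else "non_carrier") for i in FAMILY1_TYPED
        }
        maps[name] = CarrierMap(name, status)
    return maps


# Published carrier counts among the five BD members of pedigree 4 (four
# affected siblings 11/12/14/15 and BD II offspring 19).  The per-individual
# assignment is synthetic but matches the published counts and prose
# (COL3A1 in siblings 11, 12, 14 and transmitted to 19; THYN1 in three
# siblings; SELENOO transmitted to none).
_PEDIGREE4_CARRIERS: dict[str, list[str]] = {
    "COL3A1": ["11", "12", "14", "19"],
    "THYN1": ["11", "12", "14"],
    "EPS8L3": ["11", "12", "15"],
    "RCCD1": ["11", "12"],
    "DNAH7": ["12", "14"],
    "ABCA4": ["14", "15"],
    "CAPN2": ["11", "15"],
    "ATR": ["12", "15"],
    "MYH7": ["11", "14"],
    "ZNF433": ["14", "15"],
    "OLFML2B": ["11", "12"],
    "FAM169B": ["12", "19"],
    "CSNK1G3": ["15"],
    "CRX": ["11"],
    "SELENOO": [],
}


def pedigree4_carrier_maps() -> list[CarrierMap]:
    """Carrier maps for the 15 family-2 candidates over the five BD members
    of bilineal pedigree 4."""
    out = []
    for gene, carriers in _PEDIGREE4_CARRIERS.items():
        status = {
            i: ("carrier" if i in carriers else "non_carrier")
            for i in PEDIGREE4_BD_MEMBERS
        }
        out.append(CarrierMap(gene, status))
    return out
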