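"""Example datasets: the published cohort counts for rare damaging SMAD6
variants in craniosynostosis.

These are the printed summary counts of a 795-proband resequencing cohort
(prevalence by suture class and syndromic status), the gnomAD reference
loss-of-function counts, the family transmission/recurrence aggregates, and
the two-locus carrier tables for the BMP2 modifier SNP (rs1884302, risk
allele C), here and in the earlier Timberlake et al. cohort.  Pedigree
fixtures are reconstructed from the aggregates: individual-level detail is
synthetic, marginal totals are as published.
"""

from __future__ import annotations

from .burden import ContingencyTable2x2, ProbandRecord, SutureClass
from .families import (
    AffectionStatus,
    CarrierStatus,
    IndividualRecord,
    ModifierGenotype,
    PedigreeFamily,
    Role,
)

__all__ = [
    "TABLE1_COUNTS",
    "COHORT_LOF",
    "REFERENCE_LOF",
    "cohort_probands",
    "two_locus_this_study",
    "two_locus_timberlake",
    "two_locus_carriers_this_study",
    "transmission_families",
    "tdt_trios",
]

#: (nonsyndromic total, nonsyndromic positive, syndromic total, syndromic
#: positive) per suture class.
TABLE1_COUNTS: dict[SutureClass, tuple[int, int, int, int]] = {
    SutureClass.METOPIC: (167, 9, 40, 3),
    SutureClass.SAGITTAL: (279, 2, 37, 1),
    SutureClass.UNICORONAL: (150, 1, 16, 0),
    SutureClass.BICORONAL: (11, 0, 11, 0),
    SutureClass.LAMBDOID: (7, 0, 3, 0),
    SutureClass.MULTISUTURE: (35, 1, 29, 1),
    SutureClass.UNSPECIFIED: (0, 0, 10, 0),
}

#: LoF-positive probands and allele denominator (2 x 795) in the cohort.
COHORT_LOF = (9, 1590)

#: LoF alleles and minimum allele number in the gnomAD genome reference.
REFERENCE_LOF = (9, 29066)


def cohort_probands() -> list[ProbandRecord]:
    """Proband-level reconstruction of the published prevalence table.

    One synthetic ProbandRecord per proband, with suture class, syndromic
    status and gene-positivity assigned so every cell of the published
    table is reproduced exactly (795 probands, 18 gene-positive).
    """
    probands: list[ProbandRecord] = []
    serial = 0
    for suture, (ns_total, ns_pos, syn_total, syn_pos) in TABLE1_COUNTS.items():
        for syndromic, total, positive in (
            (False, ns_total, ns_pos),
            (True, syn_total, syn_pos),
        ):
            for i in range(total):
                serial += 1
                probands.append(
                    ProbandRecord(
                        proband_id=f"P{serial:04d}",
                        suture=suture,
                        syndromic=syndromic,
                        gene_positive=i < positive,
                    )
                )
    return probands


def two_locus_this_study() -> ContingencyTable2x2:
    """Carrier x affection table for the modifier risk allele, this cohort:
    rows risk-allele present/absent, columns affected/unaffected."""
    return ContingencyTable2x2(17, 12, 11, 8)


def two_locus_timberlake() -> ContingencyTable2x2:
    """The corresponding table from Timberlake et al."""
    return ContingencyTable2x2(15, 1, 6, 19)


def two_locus_carriers_this_study() -> list[IndividualRecord]:
    """Individual-level reconstruction of this cohort's two-locus table:
    48 major-gene carriers with modifier genotype and affection set so the
    cross-tabulation reproduces the published counts."""
    spec = [
        (ModifierGenotype.CT, AffectionStatus.AFFECTED, 17),
        (ModifierGenotype.CT, AffectionStatus.UNAFFECTED, 12),
        (ModifierGenotype.TT, AffectionStatus.AFFECTED, 11),
        (ModifierGenotype.TT, AffectionStatus.UNAFFECTED, 8),
    ]
    carriers: list[IndividualRecord] = []
    serial = 0
    for genotype, affection, count in spec:
        for _ in range(count):
            serial += 1
            carriers.append(
                IndividualRecord(
                    individual_id=f"C{serial:03d}",
                    family_id=f"CF{serial:03d}",
                    role=Role.OFFSPRING,
                    carrier=CarrierStatus.CARRIER,
                    affected=affection,
                    modifier_genotype=genotype,
                )
            )
    return carriers


def _family(
    fid: str,
    father_carrier: CarrierStatus,
    mother_carrier: CarrierStatus,
    n_unaffected_sibs: int = 0,
    n_affected_sibs: int = 0,
    father_present: bool = True,
    mother_present: bool = True,
) -> PedigreeFamily:
    members: list[IndividualRecord] = []
    if father_present:
        members.append(
            IndividualRecord(
                f"{fid}_fa", fid, Role.FATHER,
                carrier=father_carrier, affected=AffectionStatus.UNAFFECTED,
            )
        )
    if mother_present:
        members.append(
            IndividualRecord(
                f"{fid}_mo", fid, Role.MOTHER,
                carrier=mother_carrier, affected=AffectionStatus.UNAFFECTED,
            )
        )
    members.append(
        IndividualRecord(
            f"{fid}_pro", fid, Role.OFFSPRING,
            carrier=CarrierStatus.CARRIER, affected=AffectionStatus.AFFECTED,
        )
    )
    for i in range(n_affected_sibs):
        members.append(
            IndividualRecord(
                f"{fid}_as{i}", fid, Role.OFFSPRING,
                carrier=CarrierStatus.CARRIER,
                affected=AffectionStatus.AFFECTED,
            )
        )
    for i in range(n_unaffected_sibs):
        members.append(
            IndividualRecord(
                f"{fid}_us{i}", fid, Role.OFFSPRING,
                carrier=CarrierStatus.UNKNOWN,
                affected=AffectionStatus.UNAFFECTED,
            )
        )
    return PedigreeFamily(family_id=fid, members=members)


def transmission_families() -> list[PedigreeFamily]:
    """Pedigree reconstruction of the published family aggregates.

    26 proband families: 3 de novo, 11 maternal, 9 paternal, 3 of unknown
    origin.  The 20 transmitting families carry 25 additional offspring
    (2 affected sibs, 23 unaffected), so the sib recurrence computed from
    this fixture is 2/25 = 8%.  De novo and unknown-origin families are
    trios, contributing no sibs.
    """
    families: list[PedigreeFamily] = []
    for i in range(3):
        families.append(
            _family(
                f"DN{i+1:02d}",
                CarrierStatus.NONCARRIER,
                CarrierStatus.NONCARRIER,
            )
        )
    # 20 transmitting families: 2 with an affected sib, the rest sharing
    # 23 unaffected sibs (arbitrary within-fixture distribution; only the
    # marginal totals are published)
    sib_plan = [2] * 9 + [1] * 5 + [0] * 4
    assert sum(sib_plan) == 23
    transmitting = []
    for i in range(11):
        transmitting.append(("MA", CarrierStatus.NONCARRIER, CarrierStatus.CARRIER))
    for i in range(9):
        transmitting.append(("PA", CarrierStatus.CARRIER, CarrierStatus.NONCARRIER))
    affected_sib_flags = [1, 1] + [0] * 18
    unaffected_plan = [0, 0] + sib_plan
    for i, (tag, fa, mo) in enumerate(transmitting):
        families.append(
            _family(
                f"{tag}{i+1:02d}",
                fa,
                mo,
                n_unaffected_sibs=unaffected_plan[i],
                n_affected_sibs=affected_sib_flags[i],
            )
        )
    for i in range(3):
        families.append(
            _family(
                f"UN{i+1:02d}",
                CarrierStatus.UNKNOWN,
                CarrierStatus.NONCARRIER,
                father_present=False,
            )
        )
    return families


def tdt_trios() -> list[PedigreeFamily]:
    """Trios reconstructing the published modifier-SNP transmissions:
    heterozygous parents transmitted 12 C and 7 T alleles to affected
    offspring (each trio one CT x TT parental pair, so the transmitted
    allele is Mendelian-resolvable)."""
    trios: list[PedigreeFamily] = []
    for i in range(19):
        child_gt = ModifierGenotype.CT if i < 12 else ModifierGenotype.TT
        fid = f"T{i+1:02d}"
        trios.append(
            PedigreeFamily(
                family_id=fid,
                members=[
                    IndividualRecord(
                        f"{fid}_fa", fid, Role.FATHER,
                        carrier=CarrierStatus.CARRIER,
                        affected=AffectionStatus.UNAFFECTED,
                        modifier_genotype=ModifierGenotype.CT,
                    ),
                    IndividualRecord(
                        f"{fid}_mo", fid, Role.MOTHER,
                        carrier=CarrierStatus.NONCARRIER,
                        affected=AffectionStatus.UNAFFECTED,
                        modifier_genotype=ModifierGenotype.TT,
                    ),
                    IndividualRecord(
                        f"{fid}_pro", fid, Role.OFFSPRING,
                        carrier=CarrierStatus.CARRIER,
                        affected=AffectionStatus.AFFECTED,
                        modifier_genotype=child_gt,
                    ),
                ],
            )
        )
    return trios
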