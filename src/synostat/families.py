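"""Pedigree-level analyses for a dominant, incompletely penetrant variant.

Covers classification of each proband's variant origin (de novo versus
maternal/paternal transmission), sib recurrence risk and the penetrance it
implies under 50% transmission, a transmission disequilibrium test (TDT)
on a common modifier SNP, and the two-locus carrier association contrasting
affection in major-gene carriers with versus without the modifier risk
allele (dominant coding), including merging of 2x2 tables across studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional

from scipy import stats

from ._errors import DataError, DomainError
from .burden import ContingencyTable2x2, SutureClass, fisher_exact

__all__ = [
    "CarrierStatus",
    "AffectionStatus",
    "ModifierGenotype",
    "IndividualRecord",
    "PedigreeFamily",
    "TransmissionSummary",
    "PenetranceEstimate",
    "TdtCounts",
    "summarize_transmission",
    "sib_recurrence",
    "estimate_penetrance",
    "tdt",
    "count_tdt_alleles",
    "two_locus_table",
    "two_locus_p",
    "merge_two_locus",
    "Role",
]


class CarrierStatus(str, Enum):
    CARRIER = "carrier"
    NONCARRIER = "noncarrier"
    UNKNOWN = "unknown"


class AffectionStatus(str, Enum):
    AFFECTED = "affected"
    UNAFFECTED = "unaffected"
    UNKNOWN = "unknown"


class ModifierGenotype(str, Enum):
    """Genotype at the biallelic modifier SNP; C is the risk allele."""

    CC = "CC"
    CT = "CT"
    TT = "TT"
    UNKNOWN = "unknown"

    @property
    def n_risk_alleles(self) -> Optional[int]:
        return {"CC": 2, "CT": 1, "TT": 0}.get(self.value)

    @property
    def risk_allele_present(self) -> Optional[bool]:
        n = self.n_risk_alleles
        return None if n is None else n > 0


class Role(str, Enum):
    FATHER = "father"
    MOTHER = "mother"
    OFFSPRING = "offspring"


@dataclass(frozen=True)
class IndividualRecord:
    individual_id: str
    family_id: str
    role: Role
    carrier: CarrierStatus = CarrierStatus.UNKNOWN
    affected: AffectionStatus = AffectionStatus.UNKNOWN
    suture: Optional[SutureClass] = None
    modifier_genotype: ModifierGenotype = ModifierGenotype.UNKNOWN


@dataclass
class PedigreeFamily:
    """A nuclear family: at most one father, one mother, any offspring."""

    family_id: str
    members: list[IndividualRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [m.individual_id for m in self.members]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise DataError(
                f"family {self.family_id}: duplicate individual ids {dupes}"
            )
        for role in (Role.FATHER, Role.MOTHER):
            if sum(1 for m in self.members if m.role is role) > 1:
                raise DataError(
                    f"family {self.family_id}: more than one {role.value}"
                )

    def _one(self, role: Role) -> Optional[IndividualRecord]:
        for m in self.members:
            if m.role is role:
                return m
        return None

    @property
    def father(self) -> Optional[IndividualRecord]:
        return self._one(Role.FATHER)

    @property
    def mother(self) -> Optional[IndividualRecord]:
        return self._one(Role.MOTHER)

    @property
    def offspring(self) -> list[IndividualRecord]:
        return [m for m in self.members if m.role is Role.OFFSPRING]

    @property
    def proband(self) -> Optional[IndividualRecord]:
        """First affected carrier offspring, by member order."""
        for m in self.offspring:
            if (
                m.affected is AffectionStatus.AFFECTED
                and m.carrier is CarrierStatus.CARRIER
            ):
                return m
        return None


@dataclass(frozen=True)
class TransmissionSummary:
    """Partition of proband families by origin of the major-gene variant."""

    de_novo: int = 0
    maternal: int = 0
    paternal: int = 0
    unknown_origin: int = 0
    anomalous: int = 0  # both parents carriers; surfaced, never dropped

    @property
    def total(self) -> int:
        return (
            self.de_novo
            + self.maternal
            + self.paternal
            + self.unknown_origin
            + self.anomalous
        )

    @property
    def transmitted(self) -> int:
        return self.maternal + self.paternal


def summarize_transmission(
    families: Iterable[PedigreeFamily],
) -> TransmissionSummary:
    """Classify each proband family by the variant's parental origin.

    Both parents noncarrier -> de novo; exactly one carrier parent ->
    maternal or paternal; a missing/unknown parent with no known carrier
    parent -> unknown origin; both parents carriers -> anomalous (counted
    separately).  The five counts partition the families.
    """
    de_novo = maternal = paternal = unknown = anomalous = 0
    for fam in families:
        if fam.proband is None:
            raise DataError(
                f"family {fam.family_id}: no affected carrier offspring "
                "(proband) found"
            )
        father, mother = fam.father, fam.mother
        f_status = father.carrier if father else CarrierStatus.UNKNOWN
        m_status = mother.carrier if mother else CarrierStatus.UNKNOWN
        f_carrier = f_status is CarrierStatus.CARRIER
        m_carrier = m_status is CarrierStatus.CARRIER
        if f_carrier and m_carrier:
            anomalous += 1
        elif m_carrier:
            maternal += 1
        elif f_carrier:
            paternal += 1
        elif (
            f_status is CarrierStatus.NONCARRIER
            and m_status is CarrierStatus.NONCARRIER
        ):
            de_novo += 1
        else:
            unknown += 1
    return TransmissionSummary(
        de_novo=de_novo,
        maternal=maternal,
        paternal=paternal,
        unknown_origin=unknown,
        anomalous=anomalous,
    )


def sib_recurrence(affected_additional: int, total_offspring: int) -> float:
    """Recurrence risk among the non-proband offspring of carrier parents:
    additional affected / total additional offspring."""
    if total_offspring <= 0:
        raise DomainError(
            f"total_offspring must be positive, got {total_offspring}"
        )
    if not 0 <= affected_additional <= total_offspring:
        raise DomainError(
            f"affected_additional {affected_additional} outside "
            f"[0, {total_offspring}]"
        )
    return affected_additional / total_offspring


@dataclass(frozen=True)
class PenetranceEstimate:
    recurrence: float
    transmission_prob: float
    penetrance: float
    capped: bool = False
    counts: Optional[tuple[int, int]] = None  # (affected_additional, total)


def estimate_penetrance(
    recurrence: float, transmission_prob: float = 0.5
) -> PenetranceEstimate:
    """Penetrance implied by a sib recurrence risk: recurrence divided by
    the transmission probability (0.5 for a heterozygous carrier parent),
    capped at 1."""
    if not 0 <= recurrence <= 1:
        raise DomainError(f"recurrence must be in [0, 1], got {recurrence}")
    if not 0 < transmission_prob <= 1:
        raise DomainError(
            f"transmission_prob must be in (0, 1], got {transmission_prob}"
        )
    raw = recurrence / transmission_prob
    capped = raw > 1
    return PenetranceEstimate(
        recurrence=recurrence,
        transmission_prob=transmission_prob,
        penetrance=min(raw, 1.0),
        capped=capped,
    )


def tdt(transmitted: int, untransmitted: int) -> tuple[float, float]:
    """Transmission disequilibrium test on allele counts from heterozygous
    parents to affected offspring.

    chi-square = (b - c)^2 / (b + c) with no continuity correction; the P
    value is the upper tail of the 1-df chi-square distribution.  Symmetric
    in its arguments.
    """
    if transmitted < 0 or untransmitted < 0:
        raise DomainError("allele counts must be non-negative")
    total = transmitted + untransmitted
    if total == 0:
        raise DomainError("no informative transmissions (b + c = 0)")
    chi_square = (transmitted - untransmitted) ** 2 / total
    p = float(stats.chi2.sf(chi_square, df=1))
    return chi_square, p


@dataclass(frozen=True)
class TdtCounts:
    """Resolved risk-allele transmissions from heterozygous parents."""

    transmitted: int = 0
    untransmitted: int = 0
    unresolved: int = 0
    mendelian_errors: tuple[str, ...] = ()


def _transmitted_allele(
    het_parent: ModifierGenotype,
    other_parent: ModifierGenotype,
    child: ModifierGenotype,
) -> Optional[str]:
    """Allele ('C' or 'T') transmitted by a heterozygous parent, when the
    child genotype and the other parent's possible contributions determine
    it uniquely; None if ambiguous.  Raises DataError on Mendelian
    inconsistency."""
    other_alleles = {
        ModifierGenotype.CC: {"C"},
        ModifierGenotype.CT: {"C", "T"},
        ModifierGenotype.TT: {"T"},
    }[other_parent]
    child_pairs = {
        ModifierGenotype.CC: [("C", "C")],
        ModifierGenotype.CT: [("C", "T"), ("T", "C")],
        ModifierGenotype.TT: [("T", "T")],
    }[child]
    # (from het parent, from other parent) consistent combinations
    feasible = {
        het for het, oth in child_pairs if het in {"C", "T"} and oth in other_alleles
    }
    if not feasible:
        raise DataError("Mendelian inconsistency")
    if len(feasible) == 1:
        return next(iter(feasible))
    return None


def count_tdt_alleles(families: Iterable[PedigreeFamily]) -> TdtCounts:
    """Count modifier risk-allele transmissions from heterozygous parents
    to affected offspring with known genotype.

    C transmitted counts toward ``transmitted``, T toward ``untransmitted``.
    Pairs where the transmitted allele is not Mendelian-resolvable (both
    parents CT, child CT) are counted as unresolved, never guessed;
    Mendelian inconsistencies are flagged per parent-offspring pair.
    """
    b = c = unresolved = 0
    errors: list[str] = []
    for fam in families:
        parents = [p for p in (fam.father, fam.mother) if p is not None]
        for child in fam.offspring:
            if child.affected is not AffectionStatus.AFFECTED:
                continue
            if child.modifier_genotype is ModifierGenotype.UNKNOWN:
                continue
            for parent in parents:
                if parent.modifier_genotype is not ModifierGenotype.CT:
                    continue
                other = next((p for p in parents if p is not parent), None)
                other_gt = (
                    other.modifier_genotype
                    if other is not None
                    else ModifierGenotype.UNKNOWN
                )
                if other_gt is ModifierGenotype.UNKNOWN:
                    # treat as unconstrained: resolvable only if child is
                    # homozygous
                    if child.modifier_genotype is ModifierGenotype.CC:
                        allele: Optional[str] = "C"
                    elif child.modifier_genotype is ModifierGenotype.TT:
                        allele = "T"
                    else:
                        allele = None
                else:
                    try:
                        allele = _transmitted_allele(
                            parent.modifier_genotype, other_gt,
                            child.modifier_genotype,
                        )
                    except DataError:
                        errors.append(
                            f"{fam.family_id}:{parent.individual_id}->"
                            f"{child.individual_id}"
                        )
                        continue
                if allele == "C":
                    b += 1
                elif allele == "T":
                    c += 1
                else:
                    unresolved += 1
    return TdtCounts(
        transmitted=b,
        untransmitted=c,
        unresolved=unresolved,
        mendelian_errors=tuple(errors),
    )


def two_locus_table(
    carriers: Iterable[IndividualRecord],
) -> tuple[ContingencyTable2x2, int]:
    """Cross-tabulate major-gene carriers by modifier risk-allele presence
    (dominant coding: CC or CT versus TT) against affection.

    Returns ``(table, n_excluded)`` where the table rows are risk-allele
    present / absent and columns affected / unaffected; individuals with
    unknown genotype or affection are excluded and counted.
    """
    a = b = c = d = 0
    excluded = 0
    for ind in carriers:
        if ind.carrier is not CarrierStatus.CARRIER:
            raise DataError(
                f"{ind.individual_id}: two-locus table expects major-gene "
                "carriers only"
            )
        present = ind.modifier_genotype.risk_allele_present
        if present is None or ind.affected is AffectionStatus.UNKNOWN:
            excluded += 1
            continue
        affected = ind.affected is AffectionStatus.AFFECTED
        if present and affected:
            a += 1
        elif present:
            b += 1
        elif affected:
            c += 1
        else:
            d += 1
    return ContingencyTable2x2(a, b, c, d), excluded


def two_locus_p(table: ContingencyTable2x2) -> float:
    """One-tailed exact P for the two-locus table, with the direction fixed
    a priori as 'risk allele increases the probability of manifestation'."""
    return fisher_exact(table, sided="one_tailed", direction="greater")


def merge_two_locus(
    t1: ContingencyTable2x2, t2: ContingencyTable2x2
) -> ContingencyTable2x2:
    """Elementwise sum of two 2x2 tables with the same row/column
    semantics (pooling association data across studies)."""
    return t1 + t2
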