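"""Frequency- and deleteriousness-based stratification of candidate variants.

Implements the rare+damaging triage used for dominant, incompletely
penetrant disease genes: a variant is *rare* if its AF_max (the greater of
the maximum per-population allele frequency, restricted to populations with
at least two observed alleles and excluding catch-all populations, and the
overall allele frequency) falls below a maximum credible population allele
frequency derived from a disease model; it is *damaging* if it is a
predicted loss-of-function allele or if at least ``ds_threshold`` of up to
six in-silico missense predictors call it deleterious (the DS ensemble).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Optional, Sequence

from ._errors import ConfigError, DataError, DomainError

__all__ = [
    "ConsequenceClass",
    "PopulationFrequency",
    "FrequencyRecord",
    "PredictorCall",
    "PredictorPanel",
    "VariantRecord",
    "DiseaseModel",
    "StratificationConfig",
    "StratificationDecision",
    "max_credible_af",
    "assign_af_max",
    "classify_rare",
    "compute_ds",
    "classify_lof",
    "classify_damaging",
    "stratify_cohort",
    "detect_upstream_atg",
    "DEFAULT_PREDICTORS",
]


class ConsequenceClass(str, Enum):
    """Functional consequence of a coding/near-coding variant."""

    FRAMESHIFT = "frameshift"
    STOP_GAIN = "stop_gain"
    SPLICE_DONOR = "splice_donor"
    SPLICE_ACCEPTOR = "splice_acceptor"
    MISSENSE = "missense"
    INFRAME_INDEL = "inframe_indel"
    UTR5 = "utr5"
    SYNONYMOUS = "synonymous"
    OTHER = "other"

    @classmethod
    def parse(cls, value: str) -> "ConsequenceClass":
        try:
            return cls(value.strip().lower())
        except ValueError:
            accepted = ", ".join(m.value for m in cls)
            raise DataError(
                f"unknown consequence {value!r}; accepted values: {accepted}"
            ) from None


#: Consequence classes treated as predicted loss-of-function.  Canonical
#: splice donor/acceptor (+/-1,2) only; splice-region variants are not
#: auto-LoF.
LOF_CLASSES = frozenset(
    {
        ConsequenceClass.FRAMESHIFT,
        ConsequenceClass.STOP_GAIN,
        ConsequenceClass.SPLICE_DONOR,
        ConsequenceClass.SPLICE_ACCEPTOR,
    }
)


@dataclass(frozen=True)
class PopulationFrequency:
    """Allele count / allele number for one reference population."""

    population_code: str
    allele_count: int
    allele_number: int

    def __post_init__(self) -> None:
        if self.allele_number <= 0:
            raise DataError(
                f"population {self.population_code}: allele_number must be "
                f"positive, got {self.allele_number}"
            )
        if not 0 <= self.allele_count <= self.allele_number:
            raise DataError(
                f"population {self.population_code}: allele_count "
                f"{self.allele_count} outside [0, {self.allele_number}]"
            )

    @property
    def af(self) -> float:
        return self.allele_count / self.allele_number


@dataclass(frozen=True)
class FrequencyRecord:
    """Overall and per-population allele counts, gnomAD-style."""

    overall_allele_count: int
    overall_allele_number: int
    populations: tuple[PopulationFrequency, ...] = ()
    populations_partition: bool = False

    def __post_init__(self) -> None:
        if self.overall_allele_number <= 0:
            raise DataError(
                f"overall allele_number must be positive, got "
                f"{self.overall_allele_number}"
            )
        if not 0 <= self.overall_allele_count <= self.overall_allele_number:
            raise DataError(
                f"overall allele_count {self.overall_allele_count} outside "
                f"[0, {self.overall_allele_number}]"
            )
        object.__setattr__(self, "populations", tuple(self.populations))
        if self.populations_partition:
            for pop in self.populations:
                if pop.allele_count > self.overall_allele_count:
                    raise DataError(
                        f"population {pop.population_code} allele_count "
                        f"{pop.allele_count} exceeds overall "
                        f"{self.overall_allele_count}"
                    )

    @property
    def overall_af(self) -> float:
        return self.overall_allele_count / self.overall_allele_number


@dataclass(frozen=True)
class PredictorCall:
    """One in-silico predictor's verdict material for a variant.

    ``raw_score`` exceeds ``threshold`` "in the deleterious direction":
    strictly greater when ``higher_is_deleterious`` else strictly smaller.
    """

    predictor_name: str
    raw_score: Optional[float] = None
    threshold: float = 0.0
    higher_is_deleterious: bool = True
    available: bool = True

    def exceeds(self) -> bool:
        if not self.available or self.raw_score is None:
            return False
        if self.higher_is_deleterious:
            return self.raw_score > self.threshold
        return self.raw_score < self.threshold


@dataclass(frozen=True)
class PredictorPanel:
    """Up to six predictor calls plus an optional CADD score."""

    calls: tuple[PredictorCall, ...] = ()
    cadd: Optional[float] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "calls", tuple(self.calls))
        names = [c.predictor_name for c in self.calls]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ConfigError(f"duplicated predictor names: {dupes}")
        if len(self.calls) > 6:
            raise ConfigError(
                f"at most 6 predictor calls count toward DS, got "
                f"{len(self.calls)}"
            )
        if self.cadd is not None and not math.isfinite(self.cadd):
            raise DataError(f"CADD score must be finite, got {self.cadd}")

    @property
    def n_available(self) -> int:
        return sum(1 for c in self.calls if c.available and c.raw_score is not None)


@dataclass
class VariantRecord:
    """One candidate variant call in one proband."""

    variant_id: str
    gene: str
    consequence: ConsequenceClass
    frequency: FrequencyRecord
    predictors: PredictorPanel = field(default_factory=PredictorPanel)
    hgvs_c: Optional[str] = None
    hgvs_p: Optional[str] = None
    proband_id: Optional[str] = None
    af_max: Optional[float] = None
    ds: Optional[int] = None


@dataclass(frozen=True)
class DiseaseModel:
    """Disease architecture behind the maximum credible allele frequency.

    prevalence
        Population prevalence of the disease (e.g. 1/2000).
    penetrance
        Probability a variant carrier manifests the phenotype.
    genetic_contribution
        Share of disease cases attributable to the gene.
    allelic_contribution
        Share of the gene's cases attributable to the single most
        frequent causative allele.
    inheritance_factor
        0.5 for a heterozygous monoallelic (dominant) model, converting a
        case frequency into an allele frequency.
    """

    prevalence: float = 1 / 2000
    penetrance: float = 0.2
    genetic_contribution: float = 0.06
    allelic_contribution: float = 0.6
    inheritance_factor: float = 0.5

    def __post_init__(self) -> None:
        for name in (
            "prevalence",
            "penetrance",
            "genetic_contribution",
            "allelic_contribution",
            "inheritance_factor",
        ):
            value = getattr(self, name)
            if not (0 < value <= 1):
                raise DomainError(f"{name} must be in (0, 1], got {value}")


def _default_predictors() -> tuple[PredictorCall, ...]:
    # Shipped default ensemble of six commonly used missense predictors;
    # names, directions and thresholds are configuration, not doctrine.
    return (
        PredictorCall("sift", threshold=0.05, higher_is_deleterious=False),
        PredictorCall("polyphen2_hdiv", threshold=0.452, higher_is_deleterious=True),
        PredictorCall("lrt", threshold=0.001, higher_is_deleterious=False),
        PredictorCall("mutationtaster", threshold=0.5, higher_is_deleterious=True),
        PredictorCall("fathmm", threshold=-1.5, higher_is_deleterious=False),
        PredictorCall("provean", threshold=-2.5, higher_is_deleterious=False),
    )


DEFAULT_PREDICTORS: tuple[PredictorCall, ...] = _default_predictors()


@dataclass(frozen=True)
class StratificationConfig:
    """Thresholds and options for the rare+damaging joint filter."""

    af_threshold: float = 0.000045
    ds_threshold: int = 4
    min_population_allele_count: int = 2
    excluded_populations: frozenset[str] = frozenset({"OTH", "Other", "oth"})
    predictors: tuple[PredictorCall, ...] = DEFAULT_PREDICTORS

    def __post_init__(self) -> None:
        if not (0 < self.af_threshold < 1):
            raise ConfigError(
                f"af_threshold must be in (0, 1), got {self.af_threshold}"
            )
        if not (0 <= self.ds_threshold <= 6):
            raise ConfigError(
                f"ds_threshold must be in [0, 6], got {self.ds_threshold}"
            )
        object.__setattr__(
            self, "excluded_populations", frozenset(self.excluded_populations)
        )
        object.__setattr__(self, "predictors", tuple(self.predictors))

    @classmethod
    def from_disease_model(cls, model: DiseaseModel, **kwargs) -> "StratificationConfig":
        return cls(af_threshold=max_credible_af(model), **kwargs)


def max_credible_af(model: DiseaseModel) -> float:
    """Maximum credible population allele frequency for a causative variant.

    prevalence x genetic_contribution x allelic_contribution x
    inheritance_factor / penetrance.  Strictly decreasing in penetrance and
    strictly increasing in every other factor.
    """
    return (
        model.prevalence
        * model.genetic_contribution
        * model.allelic_contribution
        * model.inheritance_factor
        / model.penetrance
    )


def assign_af_max(freq: FrequencyRecord, config: StratificationConfig) -> float:
    """AF_max: the greater of the max qualifying per-population AF and the
    overall AF.

    A population qualifies if it is not excluded and carries at least
    ``min_population_allele_count`` alleles.  The minimum-count condition
    applies to per-population counts only, never to the overall fallback.
    """
    candidates = [freq.overall_af]
    for pop in freq.populations:
        if pop.population_code in config.excluded_populations:
            continue
        if pop.allele_count >= config.min_population_allele_count:
            candidates.append(pop.af)
    return max(candidates)


def classify_rare(af_max: float, config: StratificationConfig) -> bool:
    """True iff ``af_max`` is strictly below the rarity threshold."""
    if not 0 <= af_max <= 1:
        raise DomainError(f"af_max must be in [0, 1], got {af_max}")
    return af_max < config.af_threshold


def compute_ds(panel: PredictorPanel) -> tuple[int, int]:
    """Deleterious score: count of available predictor calls exceeding
    their threshold in the deleterious direction.

    Returns ``(ds, n_available)``; a DS of 4 with 4 available calls is thus
    distinguishable from 4/6.  Unavailable calls never contribute.
    """
    ds = sum(1 for call in panel.calls if call.exceeds())
    return ds, panel.n_available


def classify_lof(consequence: ConsequenceClass) -> bool:
    """True for frameshift, stop-gain and canonical splice-site classes."""
    return consequence in LOF_CLASSES


def classify_damaging(
    variant: VariantRecord, config: StratificationConfig
) -> bool:
    """Predicted LoF, or DS at/above the ensemble threshold."""
    if classify_lof(variant.consequence):
        return True
    ds = variant.ds
    if ds is None:
        ds, _ = compute_ds(variant.predictors)
    return ds >= config.ds_threshold


@dataclass(frozen=True)
class StratificationDecision:
    """Per-variant trace of the joint rare+damaging filter."""

    variant_id: str
    af_max: float
    ds: int
    n_predictors_available: int
    is_lof: bool
    rare: bool
    damaging: bool
    kept: bool
    unevaluable: bool
    failed_rules: tuple[str, ...]


def stratify_cohort(
    variants: Iterable[VariantRecord], config: Optional[StratificationConfig] = None
) -> tuple[list[VariantRecord], list[StratificationDecision]]:
    """Apply the joint rare AND damaging filter to a cohort of variants.

    Returns the kept records (with ``af_max`` and ``ds`` filled in) and a
    per-variant decision trace recording each rule's verdict and the
    failing rule(s).  Order-preserving; membership is order-invariant.
    """
    config = config or StratificationConfig()
    kept: list[VariantRecord] = []
    report: list[StratificationDecision] = []
    for variant in variants:
        af_max = assign_af_max(variant.frequency, config)
        ds, n_avail = compute_ds(variant.predictors)
        is_lof = classify_lof(variant.consequence)
        unevaluable = (
            not is_lof
            and variant.consequence is ConsequenceClass.MISSENSE
            and n_avail == 0
        )
        rare = classify_rare(af_max, config)
        damaging = is_lof or ds >= config.ds_threshold
        failed = []
        if not rare:
            failed.append("frequency")
        if not damaging:
            failed.append("deleteriousness")
        keep = rare and damaging
        annotated = replace(variant, af_max=af_max, ds=ds)
        report.append(
            StratificationDecision(
                variant_id=variant.variant_id,
                af_max=af_max,
                ds=ds,
                n_predictors_available=n_avail,
                is_lof=is_lof,
                rare=rare,
                damaging=damaging,
                kept=keep,
                unevaluable=unevaluable,
                failed_rules=tuple(failed),
            )
        )
        if keep:
            kept.append(annotated)
    return kept, report


def _find_atg_positions(sequence: str) -> set[int]:
    return {i for i in range(len(sequence) - 2) if sequence[i : i + 3] == "ATG"}


def detect_upstream_atg(
    utr_sequence: str,
    edit: tuple[int, str, str],
    cds_offset: int,
) -> tuple[bool, Optional[bool]]:
    """Does a single-base 5'UTR edit create a new upstream ATG, and is it
    in frame with the main ORF?

    Parameters
    ----------
    utr_sequence
        Uppercase ACGT string of the 5'UTR region (0-based offsets).
    edit
        ``(position, ref_base, alt_base)`` within ``utr_sequence``.
    cds_offset
        0-based offset of the main-ORF start codon's A within a frame that
        also contains the UTR: the distance (in bases) from ``utr_sequence``
        position 0 to the main ATG's A.  Any new upstream ATG at position
        ``p`` is in frame iff ``(cds_offset - p) % 3 == 0``.

    Returns
    -------
    (creates_uatg, in_frame_with_main_orf)
        ``in_frame_with_main_orf`` is ``None`` when no uATG is created.
    """
    position, ref_base, alt_base = edit
    for base, label in ((ref_base, "ref"), (alt_base, "alt")):
        if base not in "ACGT" or len(base) != 1:
            raise DataError(f"{label} base must be one of A/C/G/T, got {base!r}")
    if any(b not in "ACGT" for b in utr_sequence):
        raise DataError("utr_sequence must contain only A/C/G/T")
    if not 0 <= position < len(utr_sequence):
        raise DataError(
            f"edit position {position} outside sequence of length "
            f"{len(utr_sequence)}"
        )
    if position >= cds_offset:
        raise DataError(
            f"edit position {position} is not 5' of the main ORF start "
            f"({cds_offset})"
        )
    if utr_sequence[position] != ref_base:
        raise DataError(
            f"ref base mismatch at position {position}: sequence has "
            f"{utr_sequence[position]!r}, edit says {ref_base!r}"
        )
    edited = utr_sequence[:position] + alt_base + utr_sequence[position + 1 :]
    before = _find_atg_positions(utr_sequence)
    after = _find_atg_positions(edited)
    # only ATGs overlapping the edited base can be newly created
    new = {p for p in after - before if p <= position <= p + 2}
    if not new:
        return False, None
    in_frame = any((cds_offset - p) % 3 == 0 for p in new)
    return True, in_frame
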