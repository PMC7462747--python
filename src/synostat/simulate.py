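"""Synthetic cohorts with known ground truth.

Two generators feed the analysis modules end-to-end with no external data:

* a variant-table simulator producing gnomAD-style frequency records and
  six-predictor panels whose distributions differ between simulated
  pathogenic and benign variants, with truth labels returned alongside;
* a nuclear-family simulator implementing the dominant inheritance model —
  one unaffected carrier parent, 50% transmission to each offspring,
  affection sampled at a configurable penetrance, optionally modified by
  the genotype at a common biallelic modifier SNP drawn at Hardy-Weinberg
  proportions.

A Monte-Carlo harness quantifies the operating characteristics (type-I
error or power of the one-tailed two-locus exact test; bias and RMSE of
the penetrance estimator) under these models.

All randomness flows through a single ``numpy.random.Generator`` seeded
per call; identical seeds give identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace
from typing import Optional

import numpy as np

from ._errors import ConfigError
from .burden import SutureClass
from .families import (
    AffectionStatus,
    CarrierStatus,
    IndividualRecord,
    ModifierGenotype,
    PedigreeFamily,
    Role,
    estimate_penetrance,
    sib_recurrence,
    two_locus_p,
    two_locus_table,
)
from .stratify import (
    ConsequenceClass,
    FrequencyRecord,
    PopulationFrequency,
    PredictorCall,
    PredictorPanel,
    VariantRecord,
    DEFAULT_PREDICTORS,
)

__all__ = [
    "VariantSimParams",
    "FamilySimParams",
    "OperatingCharacteristics",
    "simulate_variant_table",
    "simulate_families",
    "penetrance_from_families",
    "evaluate_operating_characteristics",
]

#: Default per-population allele numbers, roughly mirroring the relative
#: ancestry composition of a large population reference.
DEFAULT_POPULATION_AN = {
    "NFE": 128000,
    "AFR": 24000,
    "EAS": 18000,
    "SAS": 30000,
    "AMR": 34000,
    "OTH": 6000,
}


def _check_prob(name: str, value: float) -> None:
    if not 0 <= value <= 1:
        raise ConfigError(f"{name} must be in [0, 1], got {value}")


@dataclass(frozen=True)
class VariantSimParams:
    """Parameters of the synthetic variant table.

    Pathogenic variants are effectively absent from the reference (at most
    one observed allele overall, so AF_max stays below ``pathogenic_af_cap``
    by construction) and are loss-of-function with probability
    ``lof_fraction_among_pathogenic``, otherwise missense with predictor
    panels exceeding each threshold independently at the pathogenic rate.
    Benign variants draw a true AF log-uniformly between the configured
    bounds (straddling any realistic rarity threshold) and benign-rate
    panels.
    """

    n_variants: int = 200
    fraction_pathogenic: float = 0.1
    benign_af_bounds: tuple[float, float] = (1e-6, 1e-2)
    pathogenic_af_cap: float = 0.000045
    predictor_exceed_prob_pathogenic: float = 0.9
    predictor_exceed_prob_benign: float = 0.15
    lof_fraction_among_pathogenic: float = 0.5
    population_an: dict = field(
        default_factory=lambda: dict(DEFAULT_POPULATION_AN)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_variants <= 0:
            raise ConfigError(f"n_variants must be positive, got {self.n_variants}")
        for name in (
            "fraction_pathogenic",
            "pathogenic_af_cap",
            "predictor_exceed_prob_pathogenic",
            "predictor_exceed_prob_benign",
            "lof_fraction_among_pathogenic",
        ):
            _check_prob(name, getattr(self, name))
        lo, hi = self.benign_af_bounds
        if not (0 < lo <= hi <= 1):
            raise ConfigError(
                f"benign_af_bounds must satisfy 0 < lo <= hi <= 1, got "
                f"{self.benign_af_bounds}"
            )


def _panel(rng: np.random.Generator, exceed_prob: float) -> PredictorPanel:
    calls = []
    for template in DEFAULT_PREDICTORS:
        exceeds = rng.random() < exceed_prob
        # place the raw score on the deleterious or tolerated side of the
        # template threshold accordingly
        offset = abs(template.threshold) * 0.5 + 0.5
        sign = 1 if template.higher_is_deleterious else -1
        score = template.threshold + (offset if exceeds else -offset) * sign
        calls.append(
            PredictorCall(
                template.predictor_name,
                raw_score=score,
                threshold=template.threshold,
                higher_is_deleterious=template.higher_is_deleterious,
            )
        )
    return PredictorPanel(calls=tuple(calls))


def simulate_variant_table(
    params: VariantSimParams,
) -> tuple[list[VariantRecord], list[bool]]:
    """Generate synthetic variants with per-variant pathogenicity truth.

    Returns ``(variants, truth)`` where ``truth[i]`` is True for simulated
    pathogenic variants.  Deterministic given ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    overall_an = sum(params.population_an.values())
    variants: list[VariantRecord] = []
    truth: list[bool] = []
    pops = sorted(params.population_an)
    for i in range(params.n_variants):
        pathogenic = bool(rng.random() < params.fraction_pathogenic)
        if pathogenic:
            # at most one allele in the reference, placed in a random
            # population: AF_max = overall AF <= 1/overall_an, far below
            # any credible rarity cap
            overall_ac = int(rng.integers(0, 2))
            pop_ac = {p: 0 for p in pops}
            if overall_ac:
                pop_ac[pops[int(rng.integers(len(pops)))]] = 1
            is_lof = rng.random() < params.lof_fraction_among_pathogenic
            consequence = (
                ConsequenceClass(
                    rng.choice(
                        ["frameshift", "stop_gain", "splice_donor", "splice_acceptor"]
                    )
                )
                if is_lof
                else ConsequenceClass.MISSENSE
            )
            panel = _panel(
                rng,
                params.predictor_exceed_prob_pathogenic
                if consequence is ConsequenceClass.MISSENSE
                else params.predictor_exceed_prob_benign,
            )
        else:
            lo, hi = params.benign_af_bounds
            af = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            pop_ac = {
                p: int(rng.binomial(an, af))
                for p, an in params.population_an.items()
            }
            overall_ac = sum(pop_ac.values())
            consequence = ConsequenceClass(
                rng.choice(["missense", "synonymous", "inframe_indel"],
                           p=[0.6, 0.3, 0.1])
            )
            panel = _panel(rng, params.predictor_exceed_prob_benign)
        freq = FrequencyRecord(
            overall_allele_count=overall_ac,
            overall_allele_number=overall_an,
            populations=tuple(
                PopulationFrequency(p, pop_ac[p], params.population_an[p])
                for p in pops
            ),
        )
        variants.append(
            VariantRecord(
                variant_id=f"var{i:05d}",
                gene="GENE1",
                consequence=consequence,
                frequency=freq,
                predictors=panel,
                proband_id=f"sim{i:05d}",
            )
        )
        truth.append(pathogenic)
    return variants, truth


@dataclass(frozen=True)
class FamilySimParams:
    """Parameters of the synthetic nuclear families.

    ``modifier_risk_allele_freq`` defaults to 0.327, the non-Finnish
    European frequency of the modifier SNP's risk allele; genotypes are
    drawn at Hardy-Weinberg proportions.  ``modifier_effect``, when given,
    is a penetrance pair ``(with_risk_allele, without_risk_allele)``
    applied under dominant coding of the risk allele.  With
    ``ascertained`` set, each family enters through a proband — its first
    offspring is an affected carrier by construction, with modifier
    genotype drawn proportional to genotype-specific penetrance — and the
    remaining offspring are sampled unconditionally, the proband-indexed
    ascertainment under which sib recurrence is an unbiased estimate of
    transmission_prob x penetrance.  With it unset, all offspring are
    sampled unconditionally.
    """

    n_families: int = 100
    penetrance: float = 0.16
    transmission_prob: float = 0.5
    offspring_range: tuple[int, int] = (1, 4)
    modifier_risk_allele_freq: float = 0.327
    modifier_effect: Optional[tuple[float, float]] = None
    de_novo_rate: float = 0.0
    ascertained: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_families <= 0:
            raise ConfigError(
                f"n_families must be positive, got {self.n_families}"
            )
        _check_prob("penetrance", self.penetrance)
        _check_prob("modifier_risk_allele_freq", self.modifier_risk_allele_freq)
        _check_prob("de_novo_rate", self.de_novo_rate)
        if not 0 < self.transmission_prob <= 1:
            raise ConfigError(
                f"transmission_prob must be in (0, 1], got "
                f"{self.transmission_prob}"
            )
        lo, hi = self.offspring_range
        if not (1 <= lo <= hi):
            raise ConfigError(
                f"offspring_range must satisfy 1 <= lo <= hi, got "
                f"{self.offspring_range}"
            )
        if self.modifier_effect is not None:
            _check_prob("modifier_effect[0]", self.modifier_effect[0])
            _check_prob("modifier_effect[1]", self.modifier_effect[1])


def _draw_genotype(rng: np.random.Generator, q: float) -> ModifierGenotype:
    u = rng.random()
    if u < q * q:
        return ModifierGenotype.CC
    if u < q * q + 2 * q * (1 - q):
        return ModifierGenotype.CT
    return ModifierGenotype.TT


def _child_genotype(
    rng: np.random.Generator, father: ModifierGenotype, mother: ModifierGenotype
) -> ModifierGenotype:
    alleles = []
    for parent in (father, mother):
        pair = {"CC": "CC", "CT": "CT", "TT": "TT"}[parent.value]
        alleles.append(pair[int(rng.integers(2))])
    n_c = alleles.count("C")
    return (ModifierGenotype.CC, ModifierGenotype.CT, ModifierGenotype.TT)[2 - n_c]


def _penetrance_for(
    genotype: ModifierGenotype, params: FamilySimParams
) -> float:
    if params.modifier_effect is None:
        return params.penetrance
    with_risk, without_risk = params.modifier_effect
    return with_risk if genotype.risk_allele_present else without_risk


def simulate_families(params: FamilySimParams) -> list[PedigreeFamily]:
    """Generate nuclear families under the dominant inheritance model.

    Each family has one carrier parent (or, at ``de_novo_rate``, noncarrier
    parents with a de novo proband); offspring inherit the variant with
    ``transmission_prob`` and, if carriers, are affected with the penetrance
    implied by their modifier genotype.  Carrier parents are clinically
    unaffected, mirroring transmission from unaffected carriers.
    Deterministic given ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    q = params.modifier_risk_allele_freq
    if params.ascertained and params.penetrance == 0 and (
        params.modifier_effect is None or max(params.modifier_effect) == 0
    ):
        raise ConfigError(
            "ascertained families require a nonzero penetrance: no affected "
            "proband can ever be generated"
        )
    families: list[PedigreeFamily] = []
    for index in range(params.n_families):
        fid = f"F{index + 1:06d}"
        de_novo = rng.random() < params.de_novo_rate
        carrier_is_father = bool(rng.integers(2))
        father_gt = _draw_genotype(rng, q)
        mother_gt = _draw_genotype(rng, q)
        if (
            not de_novo
            and params.modifier_effect is not None
            and params.modifier_effect[0] != params.modifier_effect[1]
        ):
            # the carrier parent is observed unaffected: its modifier
            # genotype is distributed as HWE x (1 - penetrance(genotype))
            max_escape = 1 - min(params.modifier_effect)
            if max_escape > 0:
                for _ in range(1000):
                    gt = _draw_genotype(rng, q)
                    escape = 1 - _penetrance_for(gt, params)
                    if rng.random() < escape / max_escape:
                        break
                if carrier_is_father:
                    father_gt = gt
                else:
                    mother_gt = gt
        father = IndividualRecord(
            f"{fid}_fa", fid, Role.FATHER,
            carrier=(
                CarrierStatus.CARRIER
                if (not de_novo and carrier_is_father)
                else CarrierStatus.NONCARRIER
            ),
            affected=AffectionStatus.UNAFFECTED,
            modifier_genotype=father_gt,
        )
        mother = IndividualRecord(
            f"{fid}_mo", fid, Role.MOTHER,
            carrier=(
                CarrierStatus.CARRIER
                if (not de_novo and not carrier_is_father)
                else CarrierStatus.NONCARRIER
            ),
            affected=AffectionStatus.UNAFFECTED,
            modifier_genotype=mother_gt,
        )
        n_off = int(rng.integers(params.offspring_range[0],
                                 params.offspring_range[1] + 1))
        members = [father, mother]
        for j in range(n_off):
            if params.ascertained and j == 0:
                # the proband: affected carrier by construction, genotype
                # drawn proportional to HWE x genotype-specific penetrance
                carrier = True
                # bounded rejection sampling; if the parental genotypes
                # cannot yield a penetrant child genotype (degenerate
                # modifier config), accept the last draw
                for _ in range(1000):
                    gt = _child_genotype(rng, father_gt, mother_gt)
                    pi = _penetrance_for(gt, params)
                    if pi > 0 and rng.random() < pi / _max_penetrance(params):
                        break
                affected = True
            else:
                if de_novo:
                    # the de novo event belongs to the first child only
                    carrier = j == 0 and not params.ascertained
                else:
                    carrier = rng.random() < params.transmission_prob
                gt = _child_genotype(rng, father_gt, mother_gt)
                affected = carrier and (
                    rng.random() < _penetrance_for(gt, params)
                )
            members.append(
                IndividualRecord(
                    f"{fid}_c{j}", fid, Role.OFFSPRING,
                    carrier=(
                        CarrierStatus.CARRIER if carrier
                        else CarrierStatus.NONCARRIER
                    ),
                    affected=(
                        AffectionStatus.AFFECTED if affected
                        else AffectionStatus.UNAFFECTED
                    ),
                    suture=SutureClass.METOPIC if affected else None,
                    modifier_genotype=gt,
                )
            )
        families.append(PedigreeFamily(family_id=fid, members=members))
    return families


def _max_penetrance(params: FamilySimParams) -> float:
    if params.modifier_effect is None:
        return params.penetrance
    return max(params.modifier_effect)


def penetrance_from_families(
    families: list[PedigreeFamily], transmission_prob: float = 0.5
):
    """Chain sib recurrence into a penetrance estimate.

    Counts, across families, the non-proband offspring and how many of
    them are affected, then divides the recurrence by the transmission
    probability.  Returns a PenetranceEstimate carrying the counts, or
    None when there are no non-proband offspring.
    """
    affected = total = 0
    for fam in families:
        proband = fam.proband
        if proband is None:
            continue
        sibs = [o for o in fam.offspring if o is not proband]
        total += len(sibs)
        affected += sum(
            1 for s in sibs if s.affected is AffectionStatus.AFFECTED
        )
    if total == 0:
        return None
    recurrence = sib_recurrence(affected, total)
    estimate = estimate_penetrance(recurrence, transmission_prob)
    return dc_replace(estimate, counts=(affected, total))


@dataclass(frozen=True)
class OperatingCharacteristics:
    """Monte-Carlo summary of the two-locus test and penetrance estimator."""

    rejection_fraction: float
    mean_penetrance_bias: float
    penetrance_rmse: float
    n_reps: int
    alpha: float
    true_penetrance: float


def evaluate_operating_characteristics(
    n_reps: int,
    fam_params: FamilySimParams,
    alpha: float = 0.05,
    seed: int = 0,
) -> OperatingCharacteristics:
    """Monte-Carlo operating characteristics under the family model.

    Per replicate: simulate families, build the two-locus table over all
    major-gene carriers (unaffected carrier parents and carrier offspring)
    and record whether the one-tailed exact P falls below ``alpha``; also
    record the penetrance estimate.  With ``modifier_effect`` unset the
    rejection fraction estimates the type-I error (at or below alpha, the
    exact test being conservative); with an effect set it estimates power.
    Bias is measured against ``fam_params.penetrance`` (the shared
    penetrance when no modifier effect is configured).
    """
    if n_reps < 1:
        raise ConfigError(f"n_reps must be >= 1, got {n_reps}")
    root = np.random.default_rng(seed)
    rejections = 0
    biases: list[float] = []
    true_pi = fam_params.penetrance
    for rep in range(n_reps):
        rep_seed = int(root.integers(0, 2**31 - 1))
        families = simulate_families(dc_replace(fam_params, seed=rep_seed))
        carriers = [
            m
            for fam in families
            for m in fam.members
            if m.carrier is CarrierStatus.CARRIER
        ]
        table, _ = two_locus_table(carriers)
        if two_locus_p(table) < alpha:
            rejections += 1
        est = penetrance_from_families(families, fam_params.transmission_prob)
        if est is not None:
            biases.append(est.penetrance - true_pi)
    bias_arr = np.array(biases) if biases else np.array([np.nan])
    return OperatingCharacteristics(
        rejection_fraction=rejections / n_reps,
        mean_penetrance_bias=float(np.mean(bias_arr)),
        penetrance_rmse=float(np.sqrt(np.mean(bias_arr**2))),
        n_reps=n_reps,
        alpha=alpha,
        true_penetrance=true_pi,
    )
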