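"""Readers and writers for the pipeline's file formats.

Tabular formats are TSV (UTF-8, no quoting, ``NA`` for missing); pedigrees
use the standard 6-column PED layout (family, individual, father, mother,
sex, affection; ``0`` for a missing parent) with a sidecar TSV keyed by
individual id carrying carrier status, suture class and modifier genotype.
Readers reject malformed input with line-numbered messages; writer/reader
round-trips are the identity on every record type.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd
import yaml

from ._errors import ConfigError, DataError, SchemaError
from .burden import ProbandRecord, SutureClass
from .families import (
    AffectionStatus,
    CarrierStatus,
    IndividualRecord,
    ModifierGenotype,
    PedigreeFamily,
    Role,
)
from .stratify import (
    ConsequenceClass,
    DiseaseModel,
    FrequencyRecord,
    PopulationFrequency,
    PredictorCall,
    PredictorPanel,
    StratificationConfig,
    VariantRecord,
    DEFAULT_PREDICTORS,
)

__all__ = [
    "read_variant_table",
    "read_variant_vcf",
    "write_variant_table",
    "read_probands",
    "read_pedigree",
    "write_pedigree",
    "load_config",
    "write_report",
    "format_percent",
    "format_p",
    "format_fold",
]

_REQUIRED_VARIANT_COLUMNS = ("variant_id", "gene", "consequence",
                             "overall_ac", "overall_an")
_NA = "NA"


def _read_tsv(path: Union[str, Path]) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False,
                       na_values=[_NA], quoting=3)


def _int_cell(value, column: str, line: int) -> int:
    try:
        return int(value)
    except (TypeError, ValueError):
        raise DataError(
            f"line {line}: column {column!r} must be an integer, got {value!r}"
        ) from None


def read_variant_table(
    path: Union[str, Path],
    config: Optional[StratificationConfig] = None,
) -> list[VariantRecord]:
    """Read a TSV variant table into VariantRecords.

    Population columns are auto-discovered from ``<POP>_ac``/``<POP>_an``
    pairs; predictor raw-score columns are matched to the config's
    predictor names (thresholds and directions come from the config, raw
    scores from the file; ``NA`` marks an unavailable call).
    """
    config = config or StratificationConfig()
    df = _read_tsv(path)
    missing = [c for c in _REQUIRED_VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s) {missing}; required columns "
            f"are {list(_REQUIRED_VARIANT_COLUMNS)}"
        )
    pop_codes = sorted(
        c[:-3]
        for c in df.columns
        if c.endswith("_ac") and c != "overall_ac" and f"{c[:-3]}_an" in df.columns
    )
    records: list[VariantRecord] = []
    for idx, row in df.iterrows():
        line = int(idx) + 2  # header is line 1
        overall_ac = _int_cell(row["overall_ac"], "overall_ac", line)
        overall_an = _int_cell(row["overall_an"], "overall_an", line)
        if overall_ac > overall_an:
            raise DataError(
                f"line {line}: overall_ac {overall_ac} exceeds overall_an "
                f"{overall_an}"
            )
        populations = []
        for pop in pop_codes:
            ac_raw, an_raw = row[f"{pop}_ac"], row[f"{pop}_an"]
            if pd.isna(ac_raw) or pd.isna(an_raw):
                continue
            ac = _int_cell(ac_raw, f"{pop}_ac", line)
            an = _int_cell(an_raw, f"{pop}_an", line)
            if ac > an:
                raise DataError(
                    f"line {line}: {pop}_ac {ac} exceeds {pop}_an {an}"
                )
            populations.append(PopulationFrequency(pop, ac, an))
        try:
            frequency = FrequencyRecord(
                overall_allele_count=overall_ac,
                overall_allele_number=overall_an,
                populations=tuple(populations),
            )
            consequence = ConsequenceClass.parse(row["consequence"])
        except DataError as exc:
            raise DataError(f"line {line}: {exc}") from None
        calls = []
        for template in config.predictors:
            name = template.predictor_name
            raw = row.get(name)
            available = name in df.columns and not pd.isna(raw)
            score = float(raw) if available else None
            calls.append(
                PredictorCall(
                    name,
                    raw_score=score,
                    threshold=template.threshold,
                    higher_is_deleterious=template.higher_is_deleterious,
                    available=available,
                )
            )
        cadd_raw = row.get("cadd")
        cadd = float(cadd_raw) if ("cadd" in df.columns and not pd.isna(cadd_raw)) else None

        def _opt(col: str) -> Optional[str]:
            value = row.get(col)
            return None if (col not in df.columns or pd.isna(value)) else str(value)

        records.append(
            VariantRecord(
                variant_id=str(row["variant_id"]),
                gene=str(row["gene"]),
                consequence=consequence,
                frequency=frequency,
                predictors=PredictorPanel(calls=tuple(calls), cadd=cadd),
                hgvs_c=_opt("hgvs_c"),
                hgvs_p=_opt("hgvs_p"),
                proband_id=_opt("proband_id"),
            )
        )
    return records


def read_variant_vcf(
    path: Union[str, Path],
    config: Optional[StratificationConfig] = None,
    gene_key: str = "GENE",
    consequence_key: str = "CSQ_CLASS",
    population_codes: Sequence[str] = ("NFE", "AFR", "EAS", "SAS", "AMR", "OTH"),
) -> list[VariantRecord]:
    """Read candidate variants from a VCF 4.x file (read-only ingestion).

    Maps only the fields the pipeline needs: overall AC/AN from the
    standard INFO keys, per-population counts from ``AC_<POP>``/``AN_<POP>``,
    gene and consequence class from the named INFO keys, and predictor raw
    scores from INFO keys matching the config's predictor names.
    """
    from cyvcf2 import VCF  # optional dependency, imported lazily

    config = config or StratificationConfig()
    records: list[VariantRecord] = []
    for n, v in enumerate(VCF(str(path))):
        info = dict(v.INFO)
        if "AC" not in info or "AN" not in info:
            raise SchemaError(
                f"{path}: record {n + 1} ({v.CHROM}:{v.POS}) lacks AC/AN "
                "INFO fields"
            )
        populations = []
        for pop in population_codes:
            ac, an = info.get(f"AC_{pop}"), info.get(f"AN_{pop}")
            if ac is None or an is None:
                continue
            populations.append(PopulationFrequency(pop, int(ac), int(an)))
        calls = []
        for template in config.predictors:
            raw = info.get(template.predictor_name)
            calls.append(
                PredictorCall(
                    template.predictor_name,
                    raw_score=float(raw) if raw is not None else None,
                    threshold=template.threshold,
                    higher_is_deleterious=template.higher_is_deleterious,
                    available=raw is not None,
                )
            )
        cadd = info.get("CADD")
        records.append(
            VariantRecord(
                variant_id=v.ID or f"{v.CHROM}-{v.POS}-{v.REF}-{v.ALT[0]}",
                gene=str(info.get(gene_key, "")),
                consequence=ConsequenceClass.parse(
                    str(info.get(consequence_key, "other"))
                ),
                frequency=FrequencyRecord(
                    overall_allele_count=int(info["AC"]),
                    overall_allele_number=int(info["AN"]),
                    populations=tuple(populations),
                ),
                predictors=PredictorPanel(calls=tuple(calls), cadd=(
                    float(cadd) if cadd is not None else None
                )),
            )
        )
    return records


def write_variant_table(
    variants: Iterable[VariantRecord], path: Union[str, Path]
) -> None:
    """Write VariantRecords to TSV in the layout read_variant_table reads."""
    variants = list(variants)
    pop_codes = sorted(
        {
            p.population_code
            for v in variants
            for p in v.frequency.populations
        }
    )
    predictor_names: list[str] = []
    for v in variants:
        for call in v.predictors.calls:
            if call.predictor_name not in predictor_names:
                predictor_names.append(call.predictor_name)
    rows = []
    for v in variants:
        row: dict = {
            "variant_id": v.variant_id,
            "gene": v.gene,
            "consequence": v.consequence.value,
            "overall_ac": v.frequency.overall_allele_count,
            "overall_an": v.frequency.overall_allele_number,
        }
        by_code = {p.population_code: p for p in v.frequency.populations}
        for pop in pop_codes:
            present = pop in by_code
            row[f"{pop}_ac"] = by_code[pop].allele_count if present else _NA
            row[f"{pop}_an"] = by_code[pop].allele_number if present else _NA
        by_name = {c.predictor_name: c for c in v.predictors.calls}
        for name in predictor_names:
            call = by_name.get(name)
            row[name] = (
                call.raw_score
                if call is not None and call.available and call.raw_score is not None
                else _NA
            )
        row["cadd"] = v.predictors.cadd if v.predictors.cadd is not None else _NA
        row["hgvs_c"] = v.hgvs_c if v.hgvs_c is not None else _NA
        row["hgvs_p"] = v.hgvs_p if v.hgvs_p is not None else _NA
        row["proband_id"] = v.proband_id if v.proband_id is not None else _NA
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_probands(path: Union[str, Path]) -> list[ProbandRecord]:
    """Read a proband table TSV (proband_id, suture, syndromic,
    gene_positive, lof_positive, family_id)."""
    df = _read_tsv(path)
    required = ("proband_id", "suture", "syndromic")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")

    def _bool(value, column: str, line: int) -> bool:
        text = str(value).strip().lower()
        if text in {"1", "true", "yes"}:
            return True
        if text in {"0", "false", "no"}:
            return False
        raise DataError(
            f"line {line}: column {column!r} must be boolean, got {value!r}"
        )

    records = []
    for idx, row in df.iterrows():
        line = int(idx) + 2
        records.append(
            ProbandRecord(
                proband_id=str(row["proband_id"]),
                suture=SutureClass.parse(row["suture"]),
                syndromic=_bool(row["syndromic"], "syndromic", line),
                gene_positive=(
                    _bool(row["gene_positive"], "gene_positive", line)
                    if "gene_positive" in df.columns and not pd.isna(row["gene_positive"])
                    else False
                ),
                lof_positive=(
                    _bool(row["lof_positive"], "lof_positive", line)
                    if "lof_positive" in df.columns and not pd.isna(row["lof_positive"])
                    else False
                ),
                family_id=(
                    str(row["family_id"])
                    if "family_id" in df.columns and not pd.isna(row["family_id"])
                    else None
                ),
            )
        )
    return records


_SEX_BY_ROLE = {Role.FATHER: "1", Role.MOTHER: "2", Role.OFFSPRING: "0"}
_AFFECTION_TO_PED = {
    AffectionStatus.UNAFFECTED: "1",
    AffectionStatus.AFFECTED: "2",
    AffectionStatus.UNKNOWN: "0",
}
_PED_TO_AFFECTION = {
    "1": AffectionStatus.UNAFFECTED,
    "2": AffectionStatus.AFFECTED,
    "0": AffectionStatus.UNKNOWN,
    "-9": AffectionStatus.UNKNOWN,
}


def read_pedigree(
    ped_path: Union[str, Path], meta_path: Optional[Union[str, Path]] = None
) -> list[PedigreeFamily]:
    """Assemble nuclear families from a 6-column PED file plus an optional
    sidecar TSV (individual_id, carrier, suture, modifier_genotype).

    ``0`` parent ids are missing per PED convention.  Individuals named as
    a father or mother of another member take that role; all others are
    offspring.
    """
    meta: dict[str, dict] = {}
    if meta_path is not None:
        mdf = _read_tsv(meta_path)
        if "individual_id" not in mdf.columns:
            raise SchemaError(f"{meta_path}: missing column 'individual_id'")
        for _, row in mdf.iterrows():
            meta[str(row["individual_id"])] = row.to_dict()

    rows = []
    seen: set[str] = set()
    with open(ped_path, encoding="utf-8") as handle:
        for line_no, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise SchemaError(
                    f"{ped_path} line {line_no}: expected 6 PED columns, got "
                    f"{len(fields)}"
                )
            fid, iid, father_id, mother_id, sex, affection = fields[:6]
            if iid in {father_id, mother_id}:
                raise DataError(
                    f"{ped_path} line {line_no}: individual {iid} listed as "
                    "its own parent"
                )
            if iid in seen:
                raise DataError(
                    f"{ped_path} line {line_no}: duplicate individual id {iid}"
                )
            seen.add(iid)
            rows.append((line_no, fid, iid, father_id, mother_id, sex, affection))

    families: dict[str, list] = {}
    for row in rows:
        families.setdefault(row[1], []).append(row)

    used_meta: set[str] = set()
    result: list[PedigreeFamily] = []
    for fid, fam_rows in families.items():
        fathers = {r[3] for r in fam_rows if r[3] != "0"}
        mothers = {r[4] for r in fam_rows if r[4] != "0"}
        members: list[IndividualRecord] = []
        for line_no, _, iid, father_id, mother_id, sex, affection in fam_rows:
            for pid, label in ((father_id, "father"), (mother_id, "mother")):
                if pid != "0" and pid not in {r[2] for r in fam_rows}:
                    raise DataError(
                        f"{ped_path} line {line_no}: {label} {pid} of {iid} "
                        f"not a member of family {fid}"
                    )
            if iid in fathers:
                role = Role.FATHER
            elif iid in mothers:
                role = Role.MOTHER
            else:
                role = Role.OFFSPRING
            if affection not in _PED_TO_AFFECTION:
                raise DataError(
                    f"{ped_path} line {line_no}: affection must be one of "
                    f"0/1/2/-9, got {affection!r}"
                )
            info = meta.get(iid, {})
            if iid in meta:
                used_meta.add(iid)

            def _enum(key, enum, default):
                value = info.get(key)
                if value is None or (isinstance(value, float) and math.isnan(value)):
                    return default
                return enum(str(value))

            members.append(
                IndividualRecord(
                    individual_id=iid,
                    family_id=fid,
                    role=role,
                    carrier=_enum("carrier", CarrierStatus, CarrierStatus.UNKNOWN),
                    affected=_PED_TO_AFFECTION[affection],
                    suture=(
                        SutureClass.parse(str(info["suture"]))
                        if info.get("suture") not in (None, "")
                        and not (isinstance(info.get("suture"), float)
                                 and math.isnan(info["suture"]))
                        else None
                    ),
                    modifier_genotype=_enum(
                        "modifier_genotype", ModifierGenotype,
                        ModifierGenotype.UNKNOWN,
                    ),
                )
            )
        result.append(PedigreeFamily(family_id=fid, members=members))
    unused = set(meta) - used_meta
    if unused:
        import sys

        print(
            f"warning: {len(unused)} individual(s) in metadata but not in "
            f"PED: {sorted(unused)[:5]}...",
            file=sys.stderr,
        )
    return result


def write_pedigree(
    families: Iterable[PedigreeFamily],
    ped_path: Union[str, Path],
    meta_path: Union[str, Path],
) -> None:
    """Write families as a PED file plus metadata sidecar TSV."""
    ped_lines = []
    meta_rows = []
    for fam in families:
        father = fam.father
        mother = fam.mother
        for m in fam.members:
            father_id = father.individual_id if (father and m.role is Role.OFFSPRING) else "0"
            mother_id = mother.individual_id if (mother and m.role is Role.OFFSPRING) else "0"
            ped_lines.append(
                "\t".join(
                    (
                        fam.family_id,
                        m.individual_id,
                        father_id,
                        mother_id,
                        _SEX_BY_ROLE[m.role],
                        _AFFECTION_TO_PED[m.affected],
                    )
                )
            )
            meta_rows.append(
                {
                    "individual_id": m.individual_id,
                    "carrier": m.carrier.value,
                    "suture": m.suture.value if m.suture else _NA,
                    "modifier_genotype": m.modifier_genotype.value,
                }
            )
    Path(ped_path).write_text("\n".join(ped_lines) + "\n", encoding="utf-8")
    pd.DataFrame(meta_rows).to_csv(meta_path, sep="\t", index=False)


def load_config(path: Union[str, Path]) -> tuple[StratificationConfig, DiseaseModel]:
    """Load a YAML/JSON config into a StratificationConfig and DiseaseModel.

    Recognised sections: ``stratification`` (af_threshold, ds_threshold,
    min_population_allele_count, excluded_populations,
    derive_af_threshold_from_model), ``predictors`` (list of name /
    threshold / higher_is_deleterious mappings) and ``disease_model``.
    Omitted sections fall back to package defaults.
    """
    text = Path(path).read_text(encoding="utf-8")
    try:
        data = yaml.safe_load(text) or {}
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: cannot parse config: {exc}") from None
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: config root must be a mapping")

    model_kwargs = data.get("disease_model", {})
    if not isinstance(model_kwargs, dict):
        raise ConfigError(f"{path}: disease_model must be a mapping")
    model = DiseaseModel(**model_kwargs)

    predictors = tuple(
        PredictorCall(
            predictor_name=entry["name"],
            threshold=float(entry["threshold"]),
            higher_is_deleterious=bool(entry.get("higher_is_deleterious", True)),
        )
        for entry in data.get("predictors", [])
    ) or DEFAULT_PREDICTORS

    strat = dict(data.get("stratification", {}))
    derive = strat.pop("derive_af_threshold_from_model", False)
    if "excluded_populations" in strat:
        strat["excluded_populations"] = frozenset(strat["excluded_populations"])
    if derive:
        strat.pop("af_threshold", None)
        config = StratificationConfig.from_disease_model(
            model, predictors=predictors, **strat
        )
    else:
        config = StratificationConfig(predictors=predictors, **strat)
    return config, model


def format_percent(value: float, decimals: int = 2) -> str:
    """Percentage formatting: 2 d.p. in tables, 1 d.p. in prose."""
    return f"{value:.{decimals}f}%"


def format_p(p: float) -> str:
    """P values to two significant figures; scientific below 1e-4."""
    if p >= 1:
        return "1"
    if p < 1e-4:
        return f"{p:.1e}"
    formatted = f"{p:.2g}"
    return formatted


def format_fold(fold: float) -> str:
    if math.isinf(fold):
        return "inf"
    return f"{fold:.1f}"


def write_report(results: dict, path: Union[str, Path]) -> None:
    """Render a results mapping as a JSON file plus a markdown sibling.

    Every table is emitted with its raw counts so each formatted statistic
    is recomputable from the report alone.  Formatting follows the field's
    reporting conventions: percentages at 1-2 d.p., P values at 2
    significant figures, fold changes at 1 d.p.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def _default(obj):
        if hasattr(obj, "__dict__"):
            return obj.__dict__
        if hasattr(obj, "_asdict"):
            return obj._asdict()
        if isinstance(obj, (set, frozenset, tuple)):
            return list(obj)
        return str(obj)

    path.write_text(
        json.dumps(results, indent=2, default=_default) + "\n", encoding="utf-8"
    )

    lines = ["# Analysis report", ""]
    for key, value in results.items():
        lines.append(f"## {key}")
        lines.append("")
        if isinstance(value, dict):
            for k, v in value.items():
                if k == "fold" and isinstance(v, (int, float)):
                    v = format_fold(float(v))
                elif k in {"p", "p_value", "p_one_tailed", "p_two_tailed"} and isinstance(v, (int, float)):
                    v = format_p(float(v))
                elif k.endswith("pct") and isinstance(v, (int, float)):
                    v = format_percent(float(v))
                lines.append(f"- {k}: {v}")
        else:
            lines.append(f"- value: {value}")
        lines.append("")
    path.with_suffix(".md").write_text("\n".join(lines), encoding="utf-8")
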