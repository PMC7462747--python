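import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from synostat.stratify import (
    ConsequenceClass,
    FrequencyRecord,
    PopulationFrequency,
    PredictorCall,
    PredictorPanel,
    StratificationConfig,
    VariantRecord,
)


@pytest.fixture
def default_config() -> StratificationConfig:
    return StratificationConfig()


def make_panel(n_exceed: int, n_total: int = 6) -> PredictorPanel:
    """Panel with exactly n_exceed of n_total calls past their threshold."""
    calls = []
    for i in range(n_total):
        exceeds = i < n_exceed
        calls.append(
            PredictorCall(
                f"pred{i}",
                raw_score=1.0 if exceeds else -1.0,
                threshold=0.0,
                higher_is_deleterious=True,
            )
        )
    return PredictorPanel(calls=tuple(calls))


def make_variant(
    variant_id: str = "v1",
    consequence: ConsequenceClass = ConsequenceClass.MISSENSE,
    overall_ac: int = 0,
    overall_an: int = 250000,
    populations: tuple = (),
    n_exceed: int = 0,
) -> VariantRecord:
    return VariantRecord(
        variant_id=variant_id,
        gene="GENE1",
        consequence=consequence,
        frequency=FrequencyRecord(
            overall_allele_count=overall_ac,
            overall_allele_number=overall_an,
            populations=tuple(
                PopulationFrequency(code, ac, an) for code, ac, an in populations
            ),
        ),
        predictors=make_panel(n_exceed),
    )
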