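import numpy as np
import pandas as pd
import pytest

from corticompare import ExpressionTable
from corticompare.synthetic import ConfoundedGene, MarkerConfig, Spike, SyntheticConfig

SPECIES_6 = ["seal", "ferret", "minke_whale", "bowhead_whale", "cow", "mouse"]

#: glia/neuron marker ratios spanning a 200-fold range (0.1 .. 20), the
#: composition-confound regime the correction must undo
COMPOSITION_RATIOS = np.geomspace(0.1, 20.0, 6)
GLIA_FRACTIONS = {s: r / (1 + r) for s, r in zip(SPECIES_6, COMPOSITION_RATIOS)}
DIVING_GROUPS = {
    "diving": ["seal", "minke_whale", "bowhead_whale"],
    "non_diving": ["ferret", "cow", "mouse"],
}


def composition_config(seed: int, spike_fold: float | None = None) -> SyntheticConfig:
    """Study conditions for the composition-correction checks: a glial
    target with constant per-glial-unit expression (100 RPKM/unit) across
    species whose marker ratios span 200-fold, optionally spiked in the
    diving group."""
    spikes = () if spike_fold is None else (Spike("S100B", "diving", spike_fold),)
    return SyntheticConfig(
        n_genes=200,
        seed=seed,
        markers=MarkerConfig(glia_fraction=GLIA_FRACTIONS),
        confounded=(ConfoundedGene("S100B", 100.0),),
        groups=DIVING_GROUPS,
        spikes=spikes,
    )


@pytest.fixture
def seal_like_table() -> ExpressionTable:
    return ExpressionTable(
        species_id="seal",
        data=pd.DataFrame(
            {
                "count": [1000, 400, 50],
                "length_bp": [1500, 2000, 800],
            },
            index=pd.Index(["CLU", "GFAP", "RBFOX3"], name="gene"),
        ),
        library_size=5_000_000,
    )


def rpkm_table(species_id: str, values: dict[str, float]) -> ExpressionTable:
    return ExpressionTable.from_rpkm(species_id, values, library_size=1_000_000)
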