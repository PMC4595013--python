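import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from triomic.containers import LayerMatrix, MultiOmicDataset, make_samples
from triomic.cycle_stats import fold_changes, zscore_columns
from triomic.synthetic_data import SimulationConfig, as_multiomic, simulate

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow], deadline=None
)
settings.load_profile("ci")

NO_DETECTION = {"mRNA": 0.0, "translation": 0.0, "protein": 0.0}


@pytest.fixture(scope="session")
def sim():
    """Default-condition simulation shared across tests (read-only)."""
    cfg = SimulationConfig(n_genes=400, seed=11)
    sd, truth = simulate(cfg)
    return sd, truth


@pytest.fixture(scope="session")
def merged(sim):
    sd, truth = sim
    return as_multiomic(sd), truth


@pytest.fixture(scope="session")
def fcm(merged):
    ds, _ = merged
    return zscore_columns(fold_changes(ds))


def toy_dataset(values_by_layer: dict[str, np.ndarray], genes: list[str], replicates=(1, 2, 3)):
    """Build a small MultiOmicDataset from per-layer genes x (phase*rep) arrays."""
    layers = {}
    idx = pd.Index(genes, name="gene")
    for layer, arr in values_by_layer.items():
        samples = make_samples(layer, replicates=replicates)
        layers[layer] = LayerMatrix(
            values=pd.DataFrame(np.asarray(arr, dtype=float), index=idx,
                                columns=[s.label for s in samples]),
            samples=samples,
        )
    prov = pd.DataFrame(
        {
            "in_transcriptome": layers["mRNA"].values.notna().any(axis=1)
            if "mRNA" in layers
            else False,
            "in_translatome": layers["translation"].values.notna().any(axis=1)
            if "translation" in layers
            else False,
            "in_proteome": layers["protein"].values.notna().any(axis=1)
            if "protein" in layers
            else False,
        },
        index=idx,
    )
    return MultiOmicDataset(gene_index=idx, layers=layers, provenance=prov)
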