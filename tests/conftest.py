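import numpy as np
import pandas as pd
import pytest

from nilqtl import simulate
from nilqtl.core_io import GenomePosition, GenotypeMatrix, Marker, MarkerPanel, PhenotypeTable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def independent_panel():
    """One marker per chromosome: effectively unlinked loci."""
    markers = [
        Marker(
            id=f"{chrom}_{(length // 2) // 1000}",
            position=GenomePosition(chrom, length // 2),
            allele_b="A",
            allele_g="C",
        )
        for chrom, length in simulate.DEFAULT_CHROMOSOMES.items()
    ]
    return MarkerPanel(markers).sorted()


@pytest.fixture(scope="session")
def h4_config():
    """H4-like design: 77 segregants, 4 backcrosses, two major QTLs."""
    return simulate.SimulationConfig(
        seed=2024,
        n_segregants=77,
        qtls=[
            simulate.QtlSpec("IV_766", -10.0, "B"),
            simulate.QtlSpec("VIII_281", -8.0, "B"),
        ],
        trait_mean=30.0,
        residual_sd=5.0,
    )


@pytest.fixture(scope="session")
def h4_population(h4_config):
    return simulate.simulate_population(h4_config)


def make_phenotype_table(values: dict, trait: str = "RS", n_replicates: int = 1):
    """Build a PhenotypeTable from {segregant: value-or-list}."""
    rows = []
    for seg, v in values.items():
        vals = v if isinstance(v, (list, tuple)) else [v] * n_replicates
        for rep, x in enumerate(vals, start=1):
            rows.append({"segregant": seg, "trait": trait, "replicate": rep, "value": x})
    return PhenotypeTable(pd.DataFrame(rows))


def make_matrix(calls: dict):
    """Build a GenotypeMatrix from {segregant: {marker: call}}."""
    return GenotypeMatrix(pd.DataFrame.from_dict(calls, orient="index"))
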