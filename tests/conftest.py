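import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from hapscreen.annotation import GeneModel, build_region_index
from hapscreen.insertions import GeneCountTable

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def toy_genes():
    """Three well-separated genes on two chromosomes."""
    return [
        GeneModel("GENEA", "chr1", "+", ((100, 500),)),
        GeneModel("GENEB", "chr1", "-", ((800, 1200),)),
        GeneModel("GENEC", "chr2", "+", ((0, 300),)),
    ]


@pytest.fixture
def toy_index(toy_genes):
    return build_region_index(toy_genes)


def make_count_table(rows, totals=None):
    """rows: (gene_id, sample, sense, antisense); totals derived if omitted."""
    counts = pd.DataFrame(rows, columns=["gene_id", "sample", "sense", "antisense"])
    if totals is None:
        tot = counts.groupby("sample")[["sense", "antisense"]].sum()
        tot = tot.rename(
            columns={"sense": "total_sense", "antisense": "total_antisense"}
        )
        tot["total_unassigned"] = 0
    else:
        tot = pd.DataFrame.from_dict(totals, orient="index")
        tot.index.name = "sample"
    return GeneCountTable(counts, tot)
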