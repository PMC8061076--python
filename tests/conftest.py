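import numpy as np
import pandas as pd
import pytest

from methregions import (
    MethylationDataset,
    SampleTable,
    SimulationConfig,
    SmoothedDataset,
    simulate,
)


def make_samples(groups: dict[str, int], tissue_class: str = "brain") -> SampleTable:
    """Sample table with ``groups`` mapping group/tissue name -> n samples."""
    rows = []
    for g, n in groups.items():
        for i in range(n):
            rows.append([f"{g}_{i}", f"d{i}", g, g, tissue_class])
    return SampleTable(
        pd.DataFrame(rows, columns=["sample_id", "donor_id", "tissue", "group", "tissue_class"])
    )


def make_dataset(
    pos, M, Cov, samples: SampleTable, chrom="chr1", strand="both", context="CG"
) -> MethylationDataset:
    loci = pd.DataFrame(
        {"chrom": chrom, "pos": np.asarray(pos, dtype=np.int64), "strand": strand, "context": context}
    )
    return MethylationDataset(loci, np.asarray(M), np.asarray(Cov), samples)


def make_smoothed(pos, beta, samples: SampleTable, chrom="chr1") -> SmoothedDataset:
    loci = pd.DataFrame(
        {"chrom": chrom, "pos": np.asarray(pos, dtype=np.int64), "strand": "both", "context": "CG"}
    )
    return SmoothedDataset(loci, np.asarray(beta, dtype=float), samples)


SMALL_CONFIG = dict(
    chrom_lengths={"chr1": 400_000},
    n_dmrs=4,
    dmr_n_loci=(12, 20),
    n_blocks=0,
    n_vmrs=4,
    n_snp_vmrs=1,
    n_outlier_vmrs=0,
    ch_contexts=(),
)


@pytest.fixture(scope="session")
def small_sim():
    """A small planted simulation shared by read-only tests."""
    return simulate(SimulationConfig(seed=42, **SMALL_CONFIG))
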