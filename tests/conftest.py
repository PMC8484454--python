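import numpy as np
import pytest

from germflow.io_core import PopulationMap, VariantMatrix


@pytest.fixture
def make_vm():
    """Builder for small genotype matrices from nested dosage lists."""

    def build(positions, genotypes, chrom="chr1", sample_ids=None):
        genotypes = np.asarray(genotypes, dtype=np.int8)
        n_sites, n_samples = genotypes.shape
        if sample_ids is None:
            sample_ids = [f"s{i}" for i in range(n_samples)]
        return VariantMatrix(
            chrom=chrom,
            positions=np.asarray(positions, dtype=np.int64),
            genotypes=genotypes,
            sample_ids=sample_ids,
            ref=np.array(["A"] * n_sites),
            alt=np.array(["G"] * n_sites),
        )

    return build


@pytest.fixture
def popmap_two_groups():
    """Two diploid samples per group plus a diploid outgroup sample pair."""
    return PopulationMap(
        {
            "a0": "A", "a1": "A",
            "b0": "B", "b1": "B",
            "c0": "C", "c1": "C",
            "o0": "OUT", "o1": "OUT",
        }
    )


@pytest.fixture(scope="session")
def desk_cohort():
    """One seeded desk-scale cohort without introgression, shared read-only."""
    from germflow import synth

    model = synth.desk_scale_model(11)
    return synth.simulate_cohort(model)
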