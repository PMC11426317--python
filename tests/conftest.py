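import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from ampliquant import (
    ExperimentBundle,
    GenotypeCountTable,
    SampleMetadata,
    SimulationConfig,
    TaxonomyTable,
    simulate_experiment,
)

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


def make_tiny_bundle() -> ExperimentBundle:
    """Hand-built 5-genotype, 4-sample bundle exercising every genotype class.

    g_spike is the quantification plasmid, g_chloro is chloroplast-flagged,
    g_cont dominates the blanks, g_dom/g_rare are genuine symbionts.
    """
    counts = pd.DataFrame(
        {
            "s1": [800, 50, 10, 40, 100],
            "s2": [600, 20, 30, 50, 300],
            "blank_e1": [0, 0, 90, 0, 110],
            "blank_p1": [0, 0, 100, 0, 0],
        },
        index=["g_dom", "g_rare", "g_cont", "g_chloro", "g_spike"],
    )
    taxonomy = TaxonomyTable(pd.DataFrame.from_dict({
        "g_dom": {"domain": "Bacteria", "genus": "Wolbachia", "flags": ""},
        "g_rare": {"domain": "Bacteria", "genus": "Serratia", "flags": ""},
        "g_cont": {"domain": "Bacteria", "genus": "Ralstonia", "flags": ""},
        "g_chloro": {"domain": "Eukaryota", "genus": "", "flags": "chloroplast"},
        "g_spike": {"domain": "Bacteria", "genus": "ArtificialTarget",
                    "flags": ""},
    }, orient="index"))
    metadata = [
        SampleMetadata("s1", species="speciesA", line="lineA1",
                       treatment="control", size_class=2,
                       spike_copies_added=10_000, homogenate_proportion=0.2),
        SampleMetadata("s2", species="speciesA", line="lineA1",
                       treatment="hotshot", size_class=2,
                       spike_copies_added=10_000, homogenate_proportion=0.2),
        SampleMetadata("blank_e1", role="blank_extraction", batch="ext1"),
        SampleMetadata("blank_p1", role="blank_pcr1", batch="pcr1"),
    ]
    return ExperimentBundle(
        counts=GenotypeCountTable(counts), taxonomy=taxonomy,
        metadata=metadata, spike_genotype_ids=frozenset({"g_spike"}))


@pytest.fixture
def tiny_bundle() -> ExperimentBundle:
    return make_tiny_bundle()


@pytest.fixture(scope="session")
def small_sim():
    """A small but complete simulated experiment shared across tests."""
    cfg = SimulationConfig(
        n_lines=4, samples_per_arm=(6, 8), depth_log_mean=8.0,
        depth_log_sd=0.8, blanks=(2, 2, 1), seed=123)
    bundle, truth = simulate_experiment(cfg)
    return cfg, bundle, truth


def random_count_table(rng, n_genotypes=8, n_samples=5, max_count=200):
    counts = rng.integers(0, max_count, size=(n_genotypes, n_samples))
    counts[0] += 1  # keep every sample non-empty
    return GenotypeCountTable(pd.DataFrame(
        counts,
        index=[f"g{i}" for i in range(n_genotypes)],
        columns=[f"s{j}" for j in range(n_samples)]))
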