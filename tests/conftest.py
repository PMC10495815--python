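import numpy as np
import pandas as pd
import pytest

import syncomics as sc
from syncomics.community import GeneSpec, SpeciesSpec


@pytest.fixture(scope="session")
def small_community() -> sc.CommunitySpec:
    """8 species, 20-30 genes each; fast enough for every downstream stage."""
    return sc.build_community(n_species=8, genes_per_species=(20, 30), seed=11)


@pytest.fixture(scope="session")
def design() -> pd.DataFrame:
    return sc.build_design()


@pytest.fixture(scope="session")
def truth(small_community, design) -> sc.GroundTruth:
    return sc.simulate_timecourse(small_community, design, seed=11)


@pytest.fixture(scope="session")
def noise_free() -> sc.NoiseParams:
    return sc.NoiseParams().noise_free()


def two_species_community(
    genome_lengths=(3_000_000, 1_000_000), n_genes=3, gene_length=1000
) -> sc.CommunitySpec:
    """Hand-built two-species community for arithmetic checks."""
    species = []
    for i, glen in enumerate(genome_lengths):
        sid = f"sp{i + 1:02d}"
        genes = [
            GeneSpec(f"{sid}_g{j + 1:04d}", gene_length, ko_id=f"K{j + 1:05d}")
            for j in range(n_genes)
        ]
        genes.append(GeneSpec(f"{sid}_rrna", 1500, is_rrna=True))
        species.append(SpeciesSpec(sid, "Bacillota" if i else "Bacteroidota", glen, tuple(genes)))
    peptides = pd.DataFrame(columns=["peptide_seq", "protein_id", "species_id"])
    return sc.CommunitySpec(tuple(species), {"path001": frozenset({"K00001"})}, peptides)


@pytest.fixture()
def two_species() -> sc.CommunitySpec:
    return two_species_community()


def make_counts(community, layer, data: dict[str, list[float]], genes=None):
    """LayerCounts from a {sample: values} dict over the community's genes."""
    idx = community.genes.index if genes is None else pd.Index(genes)
    values = pd.DataFrame(data, index=idx)
    return sc.LayerCounts(layer, values, community.feature_map().loc[idx])
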