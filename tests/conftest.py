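"""Shared fixtures: hand-built toy atlases and small simulated cohorts."""

import numpy as np
import pytest

from ribovar.atlas import (
    Atlas,
    AtlasAllele,
    NucleotideVariant,
    RegionAnnotation,
    SubunitReference,
    apply_variants,
    normalize_variant,
)
from ribovar.simulate import SimulationConfig, simulate_atlas, simulate_cohort


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture(scope="session")
def toy_subunit() -> SubunitReference:
    rng = np.random.default_rng(12345)
    return SubunitReference("28S", _random_seq(rng, 600))


@pytest.fixture(scope="session")
def toy_regions() -> list[RegionAnnotation]:
    return [
        RegionAnnotation("reg1", "28S", "ES", 1, 200),
        RegionAnnotation("reg2", "28S", "non-ES", 201, 400),
        RegionAnnotation("reg3", "28S", "ES", 401, 600),
    ]


@pytest.fixture(scope="session")
def toy_atlas(toy_subunit, toy_regions) -> Atlas:
    """Three regions; reg2 has three alleles ({v1}, {v1,v2}, reference)."""
    alleles = []
    for region in toy_regions:
        ref_seq = toy_subunit.slice(region.start, region.end)
        variant_sets = [()]
        if region.region_id == "reg2":
            base250 = toy_subunit.sequence[249]
            base320 = toy_subunit.sequence[319]
            v1 = NucleotideVariant(
                "28S", 250, base250, [b for b in "ACGT" if b != base250][0]
            )
            v2 = NucleotideVariant(
                "28S",
                *normalize_variant(320, base320, base320 + "TT",
                                   toy_subunit.sequence),
            )
            variant_sets += [(v1,), (v1, v2)]
        for i, vs in enumerate(variant_sets):
            alleles.append(
                AtlasAllele(
                    region_id=region.region_id,
                    allele_id="ref" if i == 0 else f"alt{i}",
                    core_sequence=apply_variants(ref_seq, vs, region.start),
                    variants=vs,
                    atlas_abundance=[0.6, 0.3, 0.1][i],
                )
            )
    atlas = Atlas(
        subunits={"28S": toy_subunit}, regions=list(toy_regions), alleles=alleles
    )
    return atlas.extend_all(150)


@pytest.fixture(scope="session")
def sim_config() -> SimulationConfig:
    return SimulationConfig(
        seed=7, n_participants=6, n_twin_pairs=2, n_regions=3, depth=400
    )


@pytest.fixture(scope="session")
def sim_atlas(sim_config) -> Atlas:
    return simulate_atlas(sim_config)


@pytest.fixture(scope="session")
def sim_truths(sim_atlas, sim_config):
    return simulate_cohort(sim_atlas, sim_config)
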