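import numpy as np
import pytest

from variantscape.anchors_profiles import AnchorSet, filter_distal, stack_profiles
from variantscape.clustering import (asymmetry_report, classify_and_orient,
                                     kmeans_profiles, mirror_pair)
from variantscape.genomic_io import rpkm_normalize
from variantscape.synthetic_data import (GenomeFixtureConfig,
                                         generate_genome_fixture)

VARIANTS = ("H3.1", "H3.3", "H2A.Z", "macroH2A")


@pytest.fixture(scope="session")
def fixture_default():
    """The default synthetic chromosome (16 planted groups, Poisson noise)."""
    return generate_genome_fixture(GenomeFixtureConfig(seed=0))


@pytest.fixture(scope="session")
def fixture_noise_free():
    return generate_genome_fixture(GenomeFixtureConfig(seed=0, noise="none"))


def cluster_fixture(fx, kmeans_seed=0):
    """Run the genomics arm (filter -> profiles -> cluster -> orient) on a
    generated fixture; returns (anchors, matrix, oriented result)."""
    anchors = filter_distal(fx.anchors, fx.genes)
    tracks = {t: rpkm_normalize(fx.tracks[t]) for t in VARIANTS}
    matrix = stack_profiles(tracks, anchors)
    res = kmeans_profiles(matrix, K=len(fx.config.archetypes), seed=kmeans_seed)
    res = mirror_pair(res)
    res = classify_and_orient(res, asymmetry_report(res, matrix))
    return anchors, matrix, res


@pytest.fixture(scope="session")
def clustered_default(fixture_default):
    return cluster_fixture(fixture_default)


@pytest.fixture(scope="session")
def clustered_noise_free(fixture_noise_free):
    return cluster_fixture(fixture_noise_free)


def truth_orientation(fx):
    return fx.truth["orientation"].to_numpy()


def normalized_erna(fx, scale=1.0):
    plus, minus = fx.erna_plus, fx.erna_minus
    library = plus.total() + minus.total()
    plus.library_size = minus.library_size = library
    return (rpkm_normalize(plus, scale=scale),
            rpkm_normalize(minus, scale=scale))
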