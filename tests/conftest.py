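import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")

from enhancercnv import FeatureSet, GenomeAssembly, Interval
from enhancercnv.datasets import hg19_assembly


@pytest.fixture(scope="session")
def hg19():
    return hg19_assembly()


@pytest.fixture
def toy_assembly():
    return GenomeAssembly("toy", (("chr1", 1000), ("chr2", 500)))


def random_feature_set(rng, assembly, n, max_len=50, kind="generic"):
    """Uniform random intervals on an assembly (may overlap)."""
    chroms = [c for c, _ in assembly.chromosomes]
    sizes = assembly.sizes
    features = []
    for i in range(n):
        chrom = chroms[rng.integers(0, len(chroms))]
        length = int(rng.integers(1, max_len + 1))
        if length > sizes[chrom]:
            length = sizes[chrom]
        start = int(rng.integers(0, sizes[chrom] - length + 1))
        features.append(Interval(chrom, start, start + length, id=f"f{i}"))
    return FeatureSet(features, assembly=assembly, kind=kind)


def brute_force_masks(feature_set, assembly):
    """Per-chromosome boolean base masks of a feature set (the oracle)."""
    masks = {c: np.zeros(l, dtype=bool) for c, l in assembly.chromosomes}
    for f in feature_set:
        masks[f.chrom][f.start:f.end] = True
    return masks
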