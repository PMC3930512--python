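import numpy as np
import pandas as pd
import pytest

from hybridqtl.cross import Chromosome, CrossData, GeneticMap, Marker
from hybridqtl.genoprob import calc_genoprob
from hybridqtl.simulate import simulate_f2, simulate_map


def make_map(spec: dict[str, tuple[float, ...]], x_name: str = "X") -> GeneticMap:
    """Build a map from {chrom: (cM positions...)}; Mb = 2 x cM."""
    chroms = []
    for name, positions in spec.items():
        kind = "X" if name == x_name else "autosome"
        markers = [Marker(f"M{name}_{i}", float(p), 2.0 * p) for i, p in enumerate(positions)]
        chroms.append(Chromosome(name, kind, markers))
    return GeneticMap(chroms)


def make_cross(gmap: GeneticMap, genotypes: dict[str, list[str]]) -> CrossData:
    """Cross from {individual: [codes in map order]}."""
    ids = list(genotypes)
    geno = pd.DataFrame(
        {i: genotypes[i] for i in ids}, index=gmap.marker_names
    )
    individuals = pd.DataFrame({"id": ids, "sex": "male", "cross_direction": "DxM"})
    return CrossData(gmap, individuals, geno)


@pytest.fixture(scope="session")
def mini_map():
    """3 autosomes of 60 cM plus a 40 cM X, markers every 10 cM."""
    return simulate_map(3, (60.0, 60.0, 60.0), 10.0, 40.0)


@pytest.fixture(scope="session")
def mini_cross(mini_map):
    cross, _ = simulate_f2(mini_map, n=300, seed=11, map_function="haldane")
    return cross


@pytest.fixture(scope="session")
def mini_probs(mini_cross):
    return calc_genoprob(mini_cross, 2.0, 0.001, "haldane")
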