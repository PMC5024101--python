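import json
from pathlib import Path

import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")

from linctools.synthetic_data import SimulationConfig, generate_all

FIXTURE_SEED = 20240917 % (2**31)


@pytest.fixture(scope="session")
def sim_config() -> SimulationConfig:
    return SimulationConfig(seed=FIXTURE_SEED)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory, sim_config) -> Path:
    """One full synthetic fixture set shared by the whole session."""
    out = tmp_path_factory.mktemp("fixtures")
    generate_all(sim_config, out)
    return out


@pytest.fixture(scope="session")
def manifest(fixture_dir) -> dict:
    with open(fixture_dir / "full_manifest.json") as fh:
        return json.load(fh)


@pytest.fixture(scope="session")
def fixture_net(fixture_dir, manifest):
    """Bicolor network built from the synthetic expression + PPI fixture.

    The co-expression percentile cut is the fixture-scale analogue (5%) of
    the production 0.5% threshold; see docs/methods.md.
    """
    from linctools.expression_analysis import read_fpkm, spearman_coexpression
    from linctools.function_annotation import (
        build_coexpression_edges,
        combine_network,
        load_go_annotations,
        load_ppi_edges,
    )

    df = read_fpkm(fixture_dir / "fpkm.tsv")
    expr = manifest["expression"]
    lincs, mrnas = expr["linc_ids"], expr["mrna_ids"]
    rho = spearman_coexpression(df, df).rho
    pair_rho = {}
    for i, a in enumerate(mrnas):
        for b in mrnas[i + 1:]:
            pair_rho[(a, b)] = float(rho.loc[a, b])
    for a in lincs:
        for b in mrnas:
            pair_rho[(a, b)] = float(rho.loc[a, b])
    edges = build_coexpression_edges(pair_rho, percentile=5.0)
    colors = {n: "lincRNA" for n in lincs} | {n: "mRNA" for n in mrnas}
    net = combine_network(edges, load_ppi_edges(fixture_dir / "ppi.tsv"), colors)
    go = load_go_annotations(fixture_dir / "go_annotations.tsv")
    net.attach_go(go)
    return net, go
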