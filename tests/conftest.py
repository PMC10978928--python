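"""Shared fixtures: worked trees, random-tree generators, demo world."""
from __future__ import annotations

import numpy as np
import pytest

import biogeodiv as bg

FOUR_TIP = "((A:1,B:1):1,(C:1,D:1):1);"


@pytest.fixture(scope="session")
def four_tip_tree() -> bg.Phylogeny:
    return bg.read_newick(FOUR_TIP)


def random_binary_newick(rng: np.random.Generator, n_tips: int) -> str:
    """Random binary tree with random positive branch lengths (newick)."""
    nodes = [f"t{i}" for i in range(n_tips)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        la, lb = rng.uniform(0.1, 2.0, size=2)
        nodes.append(f"({a}:{la:.6f},{b}:{lb:.6f})")
    return nodes[0] + ";"


@pytest.fixture(scope="session")
def demo_world() -> bg.World:
    return bg.build_world(bg.demo_config(0))


@pytest.fixture(scope="session")
def demo_run(demo_world, tmp_path_factory):
    """Demo world written to disk plus a pipeline run over it."""
    d = tmp_path_factory.mktemp("demo_world")
    demo_world.write(d)
    cfg = bg.RunConfig(
        tree=str(d / "tree.nwk"), occurrences=str(d / "occurrences.csv"),
        traits=str(d / "traits.csv"), traits_schema=str(d / "traits_schema.json"),
        environment=str(d / "environment.csv"), realms=str(d / "realms.csv"),
        outdir=str(d / "out"), taxon="demo", seed=0)
    report = bg.run_pipeline(cfg)
    return d, cfg, report


@pytest.fixture(scope="session")
def tree64() -> bg.Phylogeny:
    """64-tip ultrametric tree used by the signal calibrations."""
    cfg = bg.WorldConfig(n_rows=2, n_cols=2, n_realms=2, species_per_realm=32,
                         mixing=0.0, seed=7)
    tree, _ = bg.simulate_tree(cfg)
    assert tree.n_tips == 64
    return tree
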