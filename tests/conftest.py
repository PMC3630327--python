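"""Shared fixtures: the default benchmark simulation, run once per session."""

from types import SimpleNamespace

import pytest

from gsca import (
    build_compendium,
    build_peak_gene_map,
    simulate_annotation,
    simulate_compendium,
)
from gsca.simulate import default_config


def run_pipeline(cfg):
    """Simulate -> build -> map for a config; returns all intermediates."""
    annotation = simulate_annotation(cfg)
    datasets, truth = simulate_compendium(cfg, annotation)
    comp = build_compendium(datasets)
    pgmap = build_peak_gene_map(comp.regions, annotation)
    return SimpleNamespace(
        cfg=cfg, annotation=annotation, datasets=datasets,
        truth=truth, comp=comp, pgmap=pgmap,
    )


@pytest.fixture(scope="session")
def demo():
    """The default benchmark condition (seed 1): 20 datasets, 5 planted at
    3x density in the loci of a 200-gene target set, two co-occupancy
    groups."""
    return run_pipeline(default_config(seed=1))
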