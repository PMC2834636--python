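"""Shared fixtures: small simulated genome pairs and marker panels."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from salicoid.params import EvolutionParams

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")
from salicoid.simulate import build_linkage_map, sample_markers, simulate_pair


def small_params(**overrides) -> EvolutionParams:
    """A fast study-regime parameterization: short introns, few genes."""
    base = dict(
        t_wgd=150.0, t_spec=45.0, r=1.3e-9,
        event_rate=0.0,
        n_chromosomes=3, genes_per_chromosome=8,
        intron_length_range=(80, 120),
        seed=7,
    )
    base.update(overrides)
    return EvolutionParams(**base)


@pytest.fixture(scope="session")
def quiet_pair():
    """Genome pair with substitutions but no rearrangements."""
    params = small_params()
    focal, reference, truth = simulate_pair(params)
    return params, focal, reference, truth


@pytest.fixture(scope="session")
def quiet_markers(quiet_pair):
    params, focal, reference, truth = quiet_pair
    markers = sample_markers(focal, params)
    lmap = build_linkage_map(focal, markers, params)
    return params, focal, reference, truth, markers, lmap


def truth_correspondence(focal, reference, markers, lmap):
    """Correspondence table built from simulator ground truth.

    Physical position = the reference-genome locus of the marker's gene
    (same ancestral id and WGD copy); genetic position from the map.
    """
    from salicoid.synteny import make_correspondence

    positions = lmap.positions()
    ref_index = reference.gene_index()
    rows = []
    for row in markers.itertuples():
        lg, cm = positions[row.marker]
        chrom, gene = ref_index[(row.ancestral_id, row.wgd_copy)]
        rows.append((row.marker, lg, cm, chrom, (gene.start + gene.end) / 2))
    return make_correspondence(rows)


def rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)
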