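from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from sweepscan.core_data import HaplotypePanel, _site_frame
from sweepscan.synthetic_data import SimParams, simulate_neutral_panel


def make_panel(
    matrix,
    positions=None,
    chrom: str = "1",
    polarized: bool = True,
    sample_ids=None,
) -> HaplotypePanel:
    """Build a HaplotypePanel from a 0/1 matrix for hand-crafted cases."""
    H = np.asarray(matrix, dtype=np.int8)
    n_hap, n_sites = H.shape
    if positions is None:
        positions = np.arange(n_sites) * 1000
    sites = _site_frame([chrom] * n_sites, positions, ["A"] * n_sites, ["G"] * n_sites)
    panel = HaplotypePanel(H, sites, sample_ids or [])
    if polarized:
        ones = (H == 1).sum(axis=0)
        total = (H != -1).sum(axis=0)
        freq = ones / np.maximum(total, 1)
        panel.sites["ancestral_known"] = True
        panel.sites["derived_count"] = ones
        panel.sites["daf"] = freq
        panel.sites["maf"] = np.minimum(freq, 1 - freq)
    return panel


@pytest.fixture(scope="session")
def neutral_panel() -> HaplotypePanel:
    """One medium neutral panel shared across test modules (N=100, 100 kb)."""
    params = SimParams(
        n_diploids=100,
        sample_hap=60,
        seq_len=100_000,
        mu=7.5e-7,
        rho=2.5e-7,
        seed=20_240_901,
    )
    return simulate_neutral_panel(params)


@pytest.fixture(scope="session")
def neutral_replicates() -> list[HaplotypePanel]:
    """Twelve independent neutral replicates for calibration tests."""
    panels = []
    for seed in range(12):
        params = SimParams(
            n_diploids=100,
            sample_hap=60,
            seq_len=100_000,
            mu=1e-6,
            rho=2.5e-7,
            seed=1_000 + seed,
        )
        panels.append(simulate_neutral_panel(params))
    return panels


@pytest.fixture
def tiny_panel() -> HaplotypePanel:
    rng = np.random.default_rng(11)
    H = rng.integers(0, 2, size=(12, 30), dtype=np.int8)
    return make_panel(H, positions=np.sort(rng.choice(50_000, 30, replace=False)))
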