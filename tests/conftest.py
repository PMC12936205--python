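"""Shared fixtures: synthetic cells generated once per session.

The heavyweight fixtures run the full pipeline over ten simulated cells per
profile (the study conditions used throughout); image stacks are dropped
after analysis to keep memory bounded, while tracks, flow fields, wavefront
sets and ground truth are retained for the tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from synaptrack.pipeline import RunConfig, analyze_cell

N_CELLS = 10


def _run_batch(profile_name: str, n_cells: int = N_CELLS, keep_stacks: bool = False):
    cfg = RunConfig(profile=profile_name, n_cells=n_cells)
    cells = []
    for i in range(n_cells):
        res = analyze_cell(cfg.cell_profile(i), cfg)
        inter = res["intermediates"]
        cell = {
            "metrics": res["metrics"],
            "ground_truth": inter["ground_truth"],
            "geometry": inter["geometry"],
            "tracks": inter["tracks"],
            "motile_tracks": inter["motile_tracks"],
            "flow_fields": inter["flow_fields"],
            "wavefronts": inter["wavefronts"],
        }
        if keep_stacks and i == 0:
            cell["tcr_stack"] = inter["tcr_stack"]
            cell["actin_stack"] = inter["actin_stack"]
        cells.append(cell)
    return cells


@pytest.fixture(scope="session")
def primary_batch():
    """Ten primary-profile cells through the full pipeline (seeds 0-9)."""
    return _run_batch("primary", keep_stacks=True)


@pytest.fixture(scope="session")
def jurkat_batch():
    """Ten jurkat-profile cells through the full pipeline (seeds 0-9)."""
    return _run_batch("jurkat", keep_stacks=True)


@pytest.fixture(scope="session")
def waspko_batch():
    """Ten wasp_ko-profile cells through the full pipeline (seeds 0-9)."""
    return _run_batch("wasp_ko")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
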