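"""Shared fixtures: synthetic chase runs generated once per session."""

from __future__ import annotations

import numpy as np
import pytest

from tailchase import synth
from tailchase import workflows as wf


@pytest.fixture(scope="session")
def mex67_run(tmp_path_factory):
    """Default export-block chase (global k = 10.9 A/min), fixed seed."""
    out = tmp_path_factory.mktemp("mex67") / "run"
    spec = synth.preset("mex67_chase", seed=1)
    synth.write_chase(synth.gen_chase(spec), out)
    return wf.load_run(out)


@pytest.fixture(scope="session")
def mex67_kinetics(mex67_run):
    return wf.kinetics_workflow(mex67_run)


@pytest.fixture(scope="session")
def panel_run(tmp_path_factory):
    """200-transcript panel with k-lambda rank correlation 0.7, fixed seed."""
    out = tmp_path_factory.mktemp("panel") / "run"
    spec = synth.preset("transcript_panel", seed=11)
    synth.write_chase(synth.gen_chase(spec), out)
    return wf.load_run(out)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
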