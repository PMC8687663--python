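"""Shared fixtures: cached synthetic experiments and their analyses.

Experiments and full pipeline runs are cached per session because many
tests probe different facets of the same noise-free preset.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import pytest

import perwave as pw


@lru_cache(maxsize=None)
def _experiment(name: str):
    return pw.make_experiment(name)


@lru_cache(maxsize=None)
def _pulse_analysis(name: str, with_reference: bool = False):
    exp = _experiment(name)
    ref = exp.reference if with_reference else None
    return pw.analyze_pulse(exp.stimulated, exp.truth.stim_time_hr, reference=ref)


@lru_cache(maxsize=None)
def _entrainment_analysis(name: str):
    exp = _experiment(name)
    return pw.analyze_entrainment(exp.stimulated, exp.schedule)


@pytest.fixture(scope="session")
def experiment():
    return _experiment


@pytest.fixture(scope="session")
def pulse_analysis():
    return _pulse_analysis


@pytest.fixture(scope="session")
def entrainment_analysis():
    return _entrainment_analysis


@pytest.fixture()
def cosine_trace():
    """Undamped pure cosine, peak at t=12, 6 cycles, 0.1 h sampling."""
    cfg = pw.GeneratorConfig(damping_per_cycle=1.0, duration_hr=150.0)
    return pw.make_trace(cfg), cfg


@pytest.fixture()
def damped_trace():
    cfg = pw.GeneratorConfig(damping_per_cycle=0.95, duration_hr=240.0)
    return pw.make_trace(cfg), cfg
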