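import math
from collections import defaultdict

import numpy as np
import pytest

import cargoquant as cq


@pytest.fixture(scope="session")
def conditions():
    return cq.default_conditions()


def make_piecewise_trace(points_t, points_x, sampling_rate=2000.0, k=0.04, **meta):
    """Sample a piecewise-linear position skeleton on a uniform grid."""
    time = np.arange(0.0, points_t[-1], 1.0 / sampling_rate)
    position = np.interp(time, points_t, points_x)
    return cq.ForceTrace(time, position, k, sampling_rate, **meta)


def parse_cohort(traces, params=None):
    """detect_attempts over a cohort, grouped by experiment."""
    by_experiment = defaultdict(list)
    attempts = []
    for trace in traces:
        found = cq.detect_attempts(trace, params)
        attempts.extend(found)
        by_experiment[trace.experiment_id].extend(found)
    return attempts, by_experiment


def render_single_ellipse(eccentricity, semi_major, seed=0, **kwargs):
    """One noiseless crisp ellipse of the requested shape; returns (frame, truth)."""
    area = math.pi * semi_major**2 * math.sqrt(1.0 - eccentricity**2)
    stack, truth = cq.gen_organelle_stack(
        n_frames=1,
        n_objects=1,
        ecc_model=cq.EccentricityMixture(base_range=(eccentricity, eccentricity)),
        seed=seed,
        noise=False,
        blur_sigma=0.0,
        area_range=(area, area),
        background=0.0,
        **kwargs,
    )
    return stack[0], truth
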