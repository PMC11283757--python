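"""Shared helpers for the test suite."""

import numpy as np

from capitax import ConcentrationProfile


def profile_from_xy(x, y, region="inside"):
    """Wrap plain (x, y) arrays as a ConcentrationProfile for fitting."""
    x = np.asarray(x, float)
    dx = x[1] - x[0]
    edges = np.concatenate([x - dx / 2, [x[-1] + dx / 2]])
    return ConcentrationProfile(region, edges, np.asarray(y, float), np.zeros_like(x))
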