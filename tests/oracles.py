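"""Independent quadrature oracles for posterior means and evidences.

These integrate the observer's posterior numerically on a fine grid and
are kept deliberately separate from the closed-form implementation they
check.
"""

import numpy as np
from scipy.stats import norm

GRID_STEP = 0.001


def _grid(halfrange: float) -> np.ndarray:
    # endpoints chosen so +-45 (the flat-prior support edge) lies on a node
    n = int(round(halfrange / GRID_STEP))
    return np.linspace(-halfrange, halfrange, 2 * n + 1)


def single_cue_quadrature(x: float, sigma: float, prior, halfrange: float = 150.0):
    """(posterior mean, evidence) for one cue by trapezoid quadrature."""
    s = _grid(halfrange)
    f = norm.pdf(x, loc=s, scale=sigma) * prior.density(s)
    ev = np.trapezoid(f, s)
    mean = np.trapezoid(s * f, s) / ev
    return float(mean), float(ev)


def fused_quadrature(x_A, x_V, sigma_A, sigma_V, prior, halfrange: float = 150.0):
    """(posterior mean, evidence) for the common-cause structure."""
    s = _grid(halfrange)
    f = norm.pdf(x_A, loc=s, scale=sigma_A) * norm.pdf(x_V, loc=s, scale=sigma_V) * prior.density(s)
    ev = np.trapezoid(f, s)
    mean = np.trapezoid(s * f, s) / ev
    return float(mean), float(ev)
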