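"""Independent numerical oracles used by the test suite.

These deliberately avoid the package's life-table code path: survival is
integrated on a fine grid under a piecewise-constant hazard, with an exact
exponential closure for the open-ended age interval.
"""
import numpy as np


def piecewise_hazard(rates, scheme):
    """Return h(x) evaluator for a piecewise-constant hazard."""
    bounds = np.asarray(scheme.lower_bounds, dtype=float)

    def h(x):
        idx = np.clip(np.searchsorted(bounds, x, side="right") - 1, 0, len(bounds) - 1)
        return np.asarray(rates, dtype=float)[idx]

    return h


def e_at_integration(rates, scheme, at_age=0.0, step=0.01):
    """Remaining life expectancy at ``at_age`` by fine-grid integration.

    Integrates survival under the piecewise-constant hazard from 0 to the
    open-interval start; the open tail is exponential with rate m_open, so
    its person-years are S(open_start) / m_open exactly.
    """
    rates = np.asarray(rates, dtype=float)
    open_start = float(scheme.lower_bounds[-1])
    grid = np.arange(0.0, open_start + step / 2, step)
    h = piecewise_hazard(rates, scheme)
    # hazard on each sub-interval [x, x+step)
    hz = h(grid[:-1])
    cumhaz = np.concatenate([[0.0], np.cumsum(hz * step)])
    S = np.exp(-cumhaz)                      # survival at grid points
    if at_age >= open_start:
        raise ValueError("oracle supports ages below the open interval")
    i0 = int(round(at_age / step))
    # trapezoid integral of S from at_age to open_start, plus exponential tail
    years_closed = np.trapezoid(S[i0:], dx=step)
    tail = S[-1] / rates[-1]
    return (years_closed + tail) / S[i0]


def prob_death_before_integration(rates, scheme, age=70.0, step=0.01):
    """P(die before ``age``) under the piecewise-constant hazard."""
    h = piecewise_hazard(rates, scheme)
    grid = np.arange(0.0, age, step)
    return 1.0 - np.exp(-np.sum(h(grid) * step))
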