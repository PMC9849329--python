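"""Shared independent oracles for the test suite."""

import numpy as np
from scipy.linalg import expm

from cosplice.exondef import _phase_matrices, compute_delay_schedule


def exondef_expm_oracle(params, arch, profile, t_end):
    """Exact piecewise matrix-exponential propagation of the 19-state
    exon-definition system (independent of the solve_ivp path)."""
    schedule = compute_delay_schedule(arch, params.vpol)
    boundaries, mats = _phase_matrices(params, arch, profile, schedule)
    x = np.zeros(19)
    x[0] = 1.0
    spans = list(zip(boundaries, boundaries[1:] + [t_end]))
    for (t0, t1), A in zip(spans, mats):
        if t1 > t0:
            x = expm(A * (t1 - t0)) @ x
    return x
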