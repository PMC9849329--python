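"""Bimodal and trimodal single-cell PSI from bursting and feedback.

Simulates the extended stochastic model in its three multimodal regimes and
prints the KDE-detected PSI modes.  Bursting with differential isoform
degradation parks cells at PSI = 0 between bursts; positive feedback on the
skipping isoform creates alternating high/low-PSI plateaus; the combination
adds an intermediate feedback-on burst state, giving three modes.
"""

import numpy as np

from cosplice import detect_modes, get_fixture, simulate_bursting

for name in ("fig7_bursting", "fig7_feedback", "fig7_combined"):
    fx = get_fixture(name)
    traj = simulate_bursting(
        fx["params"], bursting=fx["bursting"], feedback=fx["feedback"],
        seed=101, t_end=fx["t_end"],
    )
    report = detect_modes(traj.psi_post_transient())
    print(f"{name:14s} {report.mode_count} mode(s) at PSI = "
          f"{np.round(report.modes, 2)}  (KDE bandwidth {report.bandwidth:.3f})")

print("\nmode counts 2 / 2 / 3: each regulatory mechanism contributes one "
      "discrete splicing state on top of the burst-driven baseline.")
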