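"""Transcriptional bursting and positive feedback on the skipping isoform.

Extends the multistep commitment model with continuous transcription: a
random-telegraph promoter (rates ``kon``/``koff``) initiates transcripts at
``Vsyn`` while active; transcripts elongate through an 8-step chain
(P1..P8), commit to inclusion at ``ki`` from every step (the committed
I1..I8 chain keeps elongating and matures into the Incl pool), and commit to
skipping from the terminal step P8 either basally (``ks``) or through a
positive-feedback channel whose propensity rises with the skipping-isoform
copy number (the skipping product acts as an RBP on its own precursor).
Isoform-specific degradation (``d_i``, ``d_s``) closes the system.

Bursting plus differential degradation, or the feedback alone, produce
bimodal single-cell PSI distributions; combined they produce tri-modality.
Modes are detected with a Gaussian kernel density estimate (Scott's rule).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.stats import gaussian_kde

from ._ssa_core import ssa_bursting

__all__ = [
    "BurstingParams",
    "ModalityReport",
    "feedback_propensity",
    "simulate_bursting",
    "ode_counterpart",
    "stationary_psi_no_feedback",
    "detect_modes",
    "scan_for_bimodality",
]

N_STEPS = 8
SPECIES = tuple(
    ["Prom"]
    + [f"P{i}" for i in range(1, 9)]
    + [f"I{i}" for i in range(1, 9)]
    + ["Incl", "Skip"]
)


@dataclass(frozen=True)
class BurstingParams:
    """Rates of the bursting/feedback model (1/s except K, N).

    ``Fb_s`` is the feedback magnitude (saturating per-P8 rate), ``K`` the
    skipping-copy-number threshold and ``N`` the Hill sensitivity.
    """

    kon: float = 0.002
    koff: float = 0.01
    vsyn: float = 1.0
    kelong: float = 1.0
    ki: float = 0.1
    ks: float = 0.1
    d_i: float = 0.01
    d_s: float = 0.01
    fb_s: float = 0.0
    K: float = 25.0
    N: float = 6.0

    def __post_init__(self) -> None:
        for name in ("kon", "koff", "vsyn", "kelong", "ki", "ks", "d_i", "d_s", "fb_s", "K"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.N <= 0:
            raise ValueError("N must be > 0")


def feedback_propensity(skip_count: int, params: BurstingParams) -> float:
    """Per-P8 feedback rate Fb_s / (1 + (K/Skip)^N); zero without Skip."""
    if skip_count < 0:
        raise ValueError("skip_count must be >= 0")
    if skip_count == 0:
        return 0.0
    return params.fb_s / (1.0 + (params.K / skip_count) ** params.N)


@dataclass
class BurstingTrajectory:
    """Uniformly sampled single-cell trajectory."""

    t: np.ndarray
    counts: np.ndarray  # (n_timepoints, 19) in SPECIES order
    params: BurstingParams
    seed: int

    @property
    def incl(self) -> np.ndarray:
        return self.counts[:, SPECIES.index("Incl")].astype(float)

    @property
    def skip(self) -> np.ndarray:
        return self.counts[:, SPECIES.index("Skip")].astype(float)

    def psi(self) -> np.ndarray:
        """PSI(t); NaN where both isoform pools are empty."""
        denom = self.incl + self.skip
        with np.errstate(invalid="ignore"):
            return np.where(denom > 0, self.incl / np.maximum(denom, 1.0), np.nan)

    def psi_post_transient(self, discard_fraction: float = 0.1) -> np.ndarray:
        """Defined PSI values after discarding the initial transient."""
        values = self.psi()[int(self.t.size * discard_fraction):]
        return values[~np.isnan(values)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=SPECIES)
        df.insert(0, "t", self.t)
        df["psi"] = self.psi()
        return df


def simulate_bursting(
    params: BurstingParams,
    bursting: bool = True,
    feedback: bool = True,
    seed: int = 0,
    t_end: float = 1e5,
    n_timepoints: int = 10_000,
) -> BurstingTrajectory:
    """SSA realization sampled on a uniform grid of ``n_timepoints``.

    Starts from an active promoter with zero pre-existing transcripts.  With
    ``bursting=False`` the promoter stays on; with ``feedback=False`` the
    feedback channel is silent.
    """
    grid = np.linspace(0.0, t_end, n_timepoints)
    counts = ssa_bursting(
        params.kon, params.koff, params.vsyn, params.kelong,
        params.ki, params.ks, params.d_i, params.d_s,
        params.fb_s, params.K, params.N,
        1 if bursting else 0, 1 if feedback else 0,
        grid, int(seed) % (2**31 - 1),
    )
    return BurstingTrajectory(t=grid, counts=counts, params=params, seed=seed)


def ode_counterpart(
    params: BurstingParams,
    bursting: bool = True,
    feedback: bool = True,
    t_end: float = 1e5,
    n_timepoints: int = 1000,
):
    """Deterministic mean-field trajectories of the same reaction set.

    The promoter is a continuous two-state occupancy; the feedback rate is
    evaluated on continuous Skip.  Returns (t, states) with states ordered
    as :data:`SPECIES`.
    """
    kon, koff = params.kon, params.koff
    ke, ki, ks = params.kelong, params.ki, params.ks

    def rhs(t, y):
        prom = y[0]
        p = y[1:9]
        ic = y[9:17]
        incl, skip = y[17], y[18]
        dy = np.zeros_like(y)
        dy[0] = kon * (1 - prom) - koff * prom if bursting else 0.0
        fb = 0.0
        if feedback and skip > 0:
            fb = params.fb_s / (1.0 + (params.K / skip) ** params.N)
        dy[1] = params.vsyn * prom - (ke + ki) * p[0]
        for i in range(1, 7):
            dy[1 + i] = ke * p[i - 1] - (ke + ki) * p[i]
        dy[8] = ke * p[6] - (ki + ks + fb) * p[7]
        dy[9] = ki * p[0] - ke * ic[0]
        for i in range(1, 8):
            dy[9 + i] = ki * p[i] + ke * ic[i - 1] - ke * ic[i]
        dy[17] = ke * ic[7] - params.d_i * incl
        dy[18] = (ks + fb) * p[7] - params.d_s * skip
        return dy

    y0 = np.zeros(19)
    y0[0] = 1.0
    grid = np.linspace(0.0, t_end, n_timepoints)
    sol = solve_ivp(rhs, (0.0, t_end), y0, t_eval=grid, method="LSODA",
                    rtol=1e-8, atol=1e-10)
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    return sol.t, sol.y.T


def stationary_psi_no_feedback(params: BurstingParams) -> tuple:
    """Closed-form stationary (Incl, Skip) means with the feedback off.

    Flux balance of the linear network: a transcript reaches P8 unspliced
    with probability q^7, q = kelong/(kelong+ki); at P8 inclusion and
    skipping compete directly.  The stationary pools scale the committed
    fluxes by the degradation rates and the promoter occupancy
    kon/(kon+koff).
    """
    q = params.kelong / (params.kelong + params.ki)
    f_skip = q ** 7 * params.ks / (params.ki + params.ks)
    f_incl = (1 - q ** 7) + q ** 7 * params.ki / (params.ki + params.ks)
    occ = params.kon / (params.kon + params.koff)
    influx = params.vsyn * occ
    return influx * f_incl / params.d_i, influx * f_skip / params.d_s


@dataclass
class ModalityReport:
    """Modes/antimodes of a PSI sample detected on the KDE in [0, 1]."""

    modes: np.ndarray
    antimodes: np.ndarray
    mode_count: int
    bandwidth: float
    degenerate: bool = False


def detect_modes(
    psi_series,
    grid_points: int = 512,
    rel_height: float = 0.05,
    merge_ratio: float = 0.9,
) -> ModalityReport:
    """Gaussian-KDE mode detection with Scott's bandwidth rule.

    Local maxima of the density on [0, 1] (boundaries included) are modes;
    the minima between consecutive modes are antimodes.  Maxima below
    ``rel_height`` times the global density maximum are ignored as noise,
    and neighboring maxima whose separating valley is shallower than
    ``merge_ratio`` times the lower of the two peaks are merged (KDE
    roughness, not genuine multimodality).
    """
    values = np.asarray(psi_series, dtype=float)
    values = values[~np.isnan(values)]
    if values.size < 100:
        raise ValueError("need at least 100 valid PSI points")
    if np.ptp(values) == 0.0:
        return ModalityReport(
            modes=np.array([values[0]]), antimodes=np.array([]),
            mode_count=1, bandwidth=0.0, degenerate=True,
        )
    kde = gaussian_kde(values, bw_method="scott")
    x = np.linspace(0.0, 1.0, grid_points)
    density = kde(x)
    interior = (density[1:-1] > density[:-2]) & (density[1:-1] >= density[2:])
    candidates = list(np.where(interior)[0] + 1)
    if density[0] > density[1]:
        candidates.insert(0, 0)
    if density[-1] > density[-2]:
        candidates.append(grid_points - 1)
    threshold = rel_height * density.max()
    mode_idx = [i for i in candidates if density[i] >= threshold]
    # merge peaks separated by a shallow valley, shallowest pair first
    while len(mode_idx) > 1:
        ratios = []
        for a, b in zip(mode_idx, mode_idx[1:]):
            valley = density[a:b + 1].min()
            ratios.append(valley / min(density[a], density[b]))
        worst = int(np.argmax(ratios))
        if ratios[worst] <= merge_ratio:
            break
        a, b = mode_idx[worst], mode_idx[worst + 1]
        mode_idx.remove(a if density[a] < density[b] else b)
    antimode_idx = []
    for a, b in zip(mode_idx, mode_idx[1:]):
        antimode_idx.append(a + int(np.argmin(density[a:b + 1])))
    bandwidth = float(kde.factor * values.std(ddof=1))
    return ModalityReport(
        modes=x[mode_idx], antimodes=x[antimode_idx],
        mode_count=len(mode_idx), bandwidth=bandwidth,
    )


def scan_for_bimodality(
    base: BurstingParams,
    grid: dict,
    seed: int = 0,
    bursting: bool = True,
    feedback: bool = True,
    t_end: float = 1e5,
    n_timepoints: int = 10_000,
) -> pd.DataFrame:
    """Mode count over a parameter grid, with fixed per-point seeds.

    ``grid`` maps parameter names to value lists; the scan is the cartesian
    product.  Returns a tidy table of parameter values and detected mode
    counts.
    """
    from itertools import product

    names = list(grid)
    rows = []
    for ic, combo in enumerate(product(*(grid[n] for n in names))):
        params = replace(base, **dict(zip(names, combo)))
        run_seed = int(
            np.random.SeedSequence([seed, ic]).generate_state(1)[0] % (2**31 - 1)
        )
        traj = simulate_bursting(
            params, bursting=bursting, feedback=feedback, seed=run_seed,
            t_end=t_end, n_timepoints=n_timepoints,
        )
        psi = traj.psi_post_transient()
        if psi.size < 100:
            count = 0
        else:
            count = detect_modes(psi).mode_count
        rows.append({**dict(zip(names, combo)), "mode_count": count, "seed": run_seed})
    return pd.DataFrame(rows)
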