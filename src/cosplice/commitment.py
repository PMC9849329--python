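"""Time-delay model of splicing commitment in a three-exon gene.

The model tracks a synchronized cohort of nascent transcripts from the moment
exon 2 synthesis is complete.  Each transcript commits irreversibly to the
inclusion isoform (rate ``ki``), to the skipping isoform (rate ``ks``), or is
first shifted into an RBP-inhibited state (escape rate ``kesc``) from which
only skipping remains possible.  Co-transcriptional kinetics enter through
three hard time delays derived from the polymerase velocity ``vpol``:

* ``tau_inh1``/``tau_inh2`` delimit the window of opportunity in which the
  elongating polymerase can deposit the inhibitory RBP (escape active);
* ``tau`` is the time at which exon 3 synthesis completes and direct
  commitment to skipping becomes possible.

Between delays the system is a linear ODE with piecewise-constant rates, so it
is solved either by phased numerical integration (:func:`simulate_delay_ode`)
or by an exact phase-wise probability recursion (:func:`analytic_psi`).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "CommitmentParams",
    "CommitmentTopology",
    "DelaySet",
    "SplicingOutcome",
    "PhaseTable",
    "compute_delays",
    "simulate_delay_ode",
    "analytic_psi",
    "psi",
    "psi_vpol_profile",
    "FEW_STEPS",
    "MANY_STEPS",
]


@dataclass(frozen=True)
class CommitmentParams:
    """First-order commitment rates, all in 1/s.

    ki   -- commitment to inclusion (active from t = 0)
    ks   -- commitment to skipping (active only after ``tau``)
    kesc -- RBP-mediated escape into the inhibited state (active only in the
            RBP deposition window [tau_inh1, tau_inh2])
    """

    ki: float
    ks: float
    kesc: float = 0.0

    def __post_init__(self) -> None:
        for name in ("ki", "ks", "kesc"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")


@dataclass(frozen=True)
class CommitmentTopology:
    """Relative lengths of the four sequence stretches downstream of exon 2.

    ``k`` nucleotide-stretch units precede the RBP motif, ``e`` span the RBP
    deposition window, ``m`` run to the end of exon 3 and ``n`` to the
    transcript end.  ``tr_len`` is the physical length (nt) they jointly
    cover; the per-unit length is ``tr_len / l`` with ``l = k + e + m + n``.
    """

    tr_len: float = 300.0
    k: int = 2
    e: int = 3
    m: int = 1
    n: int = 2

    def __post_init__(self) -> None:
        if self.tr_len <= 0:
            raise ValueError("tr_len must be > 0")
        for name in ("k", "e", "m", "n"):
            v = getattr(self, name)
            if not float(v).is_integer() or v < 0:
                raise ValueError(f"{name} must be a non-negative integer")
        if self.l <= 0:
            raise ValueError("total step count l = k+e+m+n must be > 0")

    @property
    def l(self) -> int:
        return self.k + self.e + self.m + self.n

    def scaled(self, factor: int) -> "CommitmentTopology":
        """Same geometry with every segment refined ``factor``-fold."""
        return CommitmentTopology(
            self.tr_len, self.k * factor, self.e * factor,
            self.m * factor, self.n * factor,
        )


#: Printed few-steps topology (8 elongation steps, segments 2/3/1/2).
FEW_STEPS = CommitmentTopology(300.0, 2, 3, 1, 2)
#: Printed many-steps topology (80 elongation steps, segments 20/30/10/20).
MANY_STEPS = CommitmentTopology(300.0, 20, 30, 10, 20)


@dataclass(frozen=True)
class DelaySet:
    """Delays (s) of escape-window opening/closing and skipping onset."""

    tau_inh1: float
    tau_inh2: float
    tau: float

    def __post_init__(self) -> None:
        if not (0 <= self.tau_inh1 <= self.tau_inh2 <= self.tau):
            raise ValueError(
                "delays must satisfy 0 <= tau_inh1 <= tau_inh2 <= tau, got "
                f"{self.tau_inh1}, {self.tau_inh2}, {self.tau}"
            )


@dataclass(frozen=True)
class SplicingOutcome:
    """Final-fate probabilities of one transcript.

    ``unspliced_residual`` is the probability mass still uncommitted at the
    end of the integration; ``residual_warning`` is set when it exceeds the
    completeness tolerance.
    """

    incl: float
    skip: float
    ret: float = 0.0
    unspliced_residual: float = 0.0
    residual_warning: bool = False

    def __post_init__(self) -> None:
        total = self.incl + self.skip + self.ret + self.unspliced_residual
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"outcome components sum to {total}, expected 1")


def psi(outcome: SplicingOutcome) -> float:
    """Percent spliced-in, PSI = incl / (incl + skip).

    Retention is excluded from the denominator.  When neither isoform was
    produced the PSI is undefined and NaN is returned.
    """
    denom = outcome.incl + outcome.skip
    if denom <= 0.0:
        return math.nan
    return outcome.incl / denom


def compute_delays(topology: CommitmentTopology, vpol: float) -> DelaySet:
    """Delays from polymerase velocity: each is inversely proportional to vpol.

    tau_inh1 = tr_len/(l*vpol) * k
    tau_inh2 = tr_len/(l*vpol) * (k+e)
    tau      = tr_len/(l*vpol) * (k+e+m)
    """
    if vpol <= 0:
        raise ValueError(f"vpol must be > 0, got {vpol}")
    unit = topology.tr_len / (topology.l * vpol)
    return DelaySet(
        tau_inh1=unit * topology.k,
        tau_inh2=unit * (topology.k + topology.e),
        tau=unit * (topology.k + topology.e + topology.m),
    )


@dataclass(frozen=True)
class PhaseTable:
    """Which rates act in each of the four integration phases.

    Defaults encode the standard escape-window model: inclusion always
    possible, escape only inside [tau_inh1, tau_inh2], skipping (from both the
    free and the inhibited transcript) only after tau.  Kept configurable so
    model variants with different switching schedules can reuse the solver.
    """

    ki_phases: tuple = (True, True, True, True)
    kesc_phases: tuple = (False, True, False, False)
    ks_phases: tuple = (False, False, False, True)


_DEFAULT_PHASES = PhaseTable()


def _rhs(ki: float, ks: float, kesc: float):
    def rhs(t, y):
        mrna, mrna_inh, incl, skip = y
        return [
            -(ki + ks + kesc) * mrna,
            kesc * mrna - ks * mrna_inh,
            ki * mrna,
            ks * (mrna + mrna_inh),
        ]

    return rhs


def simulate_delay_ode(
    params: CommitmentParams,
    delays: DelaySet,
    t_end: float = 1e4,
    phases: PhaseTable = _DEFAULT_PHASES,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    residual_tol: float = 1e-6,
) -> SplicingOutcome:
    """Phased numerical integration of the delay model.

    The four phases [0, tau_inh1], [tau_inh1, tau_inh2], [tau_inh2, tau] and
    [tau, t_end] are integrated consecutively with the phase-appropriate
    active rates; the final state of one phase seeds the next.
    """
    boundaries = [0.0, delays.tau_inh1, delays.tau_inh2, delays.tau, t_end]
    if t_end < delays.tau:
        raise ValueError("t_end must exceed the skipping delay tau")
    y = np.array([1.0, 0.0, 0.0, 0.0])
    for i in range(4):
        t0, t1 = boundaries[i], boundaries[i + 1]
        if t1 <= t0:
            continue
        rhs = _rhs(
            params.ki if phases.ki_phases[i] else 0.0,
            params.ks if phases.ks_phases[i] else 0.0,
            params.kesc if phases.kesc_phases[i] else 0.0,
        )
        sol = solve_ivp(rhs, (t0, t1), y, method="LSODA", rtol=rtol, atol=atol)
        if not sol.success:
            raise RuntimeError(f"ODE integration failed in phase {i + 1}: {sol.message}")
        y = sol.y[:, -1]
    residual = float(y[0] + y[1])
    warn = residual > residual_tol
    if warn:
        warnings.warn(
            f"unspliced residual {residual:.3e} above tolerance {residual_tol:.1e}; "
            "increase t_end",
            stacklevel=2,
        )
    # clip tiny negative integrator wiggle
    incl, skip = max(float(y[2]), 0.0), max(float(y[3]), 0.0)
    residual = max(0.0, 1.0 - incl - skip)
    return SplicingOutcome(
        incl=incl, skip=skip, ret=0.0,
        unspliced_residual=residual, residual_warning=warn,
    )


def analytic_psi(
    params: CommitmentParams,
    delays: DelaySet,
    phases: PhaseTable = _DEFAULT_PHASES,
) -> float:
    """Exact PSI of the delay model via the phase-wise probability recursion.

    In each phase i the probability that a still-uncommitted transcript
    reacts is ``p_react_i = p_rest_{i-1} * (1 - exp(-E_i))`` with
    ``E_i = (sum of active rates) * dt_i``; of the reacting mass a fraction
    ``ki / (active-rate sum)`` goes to inclusion.  The fourth phase is
    infinite, so its reaction probability is the whole remaining mass.
    Escaped transcripts commit to skipping eventually, hence PSI equals the
    accumulated inclusion probability directly.
    """
    ki, ks, kesc = params.ki, params.ks, params.kesc
    final_rates = (ki if phases.ki_phases[3] else 0.0) + (
        ks if phases.ks_phases[3] else 0.0
    ) + (kesc if phases.kesc_phases[3] else 0.0)
    if final_rates <= 0.0:
        raise ValueError(
            "no commitment rate active in the final phase: PSI undefined"
        )
    dts = [
        delays.tau_inh1,
        delays.tau_inh2 - delays.tau_inh1,
        delays.tau - delays.tau_inh2,
        math.inf,
    ]
    p_rest = 1.0
    p_incl = 0.0
    p_esc = 0.0
    p_skip = 0.0
    for i, dt in enumerate(dts):
        a_i = ki if phases.ki_phases[i] else 0.0
        a_esc = kesc if phases.kesc_phases[i] else 0.0
        a_s = ks if phases.ks_phases[i] else 0.0
        total = a_i + a_esc + a_s
        if total == 0.0 or dt == 0.0:
            continue
        if math.isinf(dt):
            p_react = p_rest
        else:
            p_react = p_rest * -math.expm1(-total * dt)
        p_incl += p_react * (a_i / total)
        p_esc += p_react * (a_esc / total)
        p_skip += p_react * (a_s / total)
        p_rest -= p_react
    # escaped transcripts commit to skipping once ks switches on; with
    # ks = 0 they are stuck and drop out of the PSI denominator
    if ks > 0:
        p_skip += p_esc
    denom = p_incl + p_skip
    if denom <= 0.0:
        raise ValueError("no spliced mass produced: PSI undefined")
    return p_incl / denom


@dataclass
class PSIProfile:
    """PSI as a function of polymerase velocity.

    ``shape`` is filled by :func:`cosplice.profiles.classify_profile`;
    ``inflection_vpol`` is the grid point of steepest PSI change against
    log10(vpol) (central differences).
    """

    vpol: np.ndarray
    psi: np.ndarray
    backend: str = "analytic"
    shape: str | None = None
    inflection_vpol: float | None = None
    extra: dict = field(default_factory=dict)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"vpol": self.vpol, "psi": self.psi, "backend": self.backend}
        )


def _inflection(vpol: np.ndarray, psi_values: np.ndarray) -> float | None:
    if len(vpol) < 3:
        return None
    x = np.log10(vpol)
    slope = np.gradient(psi_values, x)
    idx = int(np.argmax(np.abs(slope)))
    if abs(slope[idx]) < 1e-12:
        return None
    return float(vpol[idx])


def psi_vpol_profile(
    params: CommitmentParams,
    topology: CommitmentTopology,
    vpol_grid,
    backend: str = "analytic",
    phases: PhaseTable = _DEFAULT_PHASES,
    classify: bool = True,
) -> PSIProfile:
    """PSI across a velocity grid, with inflection point and shape class."""
    grid = np.asarray(vpol_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("vpol grid must not be empty")
    if np.any(grid <= 0) or np.any(np.diff(grid) <= 0):
        raise ValueError("vpol grid must be strictly positive and sorted")
    values = np.empty_like(grid)
    extra: dict = {}
    if backend == "analytic":
        for j, v in enumerate(grid):
            values[j] = analytic_psi(params, compute_delays(topology, v), phases)
    elif backend == "ode":
        incl = np.empty_like(grid)
        skip = np.empty_like(grid)
        for j, v in enumerate(grid):
            out = simulate_delay_ode(params, compute_delays(topology, v), phases=phases)
            values[j] = psi(out)
            incl[j], skip[j] = out.incl, out.skip
        extra = {"incl": incl, "skip": skip}
    else:
        raise ValueError(f"unknown backend {backend!r}")
    profile = PSIProfile(
        vpol=grid, psi=values, backend=backend,
        inflection_vpol=_inflection(grid, values), extra=extra,
    )
    if classify:
        from .profiles import classify_profile

        profile.shape = classify_profile(profile)
    return profile
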