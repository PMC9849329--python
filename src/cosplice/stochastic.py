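"""Exact stochastic simulation of the splicing models.

Every deterministic model in the package is a zero-/first-order reaction
network with piecewise-constant rates, so its kinetic parameters can be used
directly as reaction propensities in the Gillespie algorithm.  Delay switches
are handled with the boundary-redraw rule: when a sampled waiting time
crosses the next switch time the clock moves to the boundary and the waiting
time is redrawn, which is exact because exponential waiting times are
memoryless.

Per-run seeds are derived from a root seed with ``numpy.random.SeedSequence``
so ensembles are reproducible and order-independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _ssa_core
from .commitment import CommitmentParams, DelaySet
from .exondef import (
    SPECIES as EXONDEF_SPECIES,
    DelaySchedule,
    ExonDefinitionParams,
    GeneArchitecture,
    InhibitionProfile,
    compute_delay_schedule,
    effective_rates,
)

__all__ = [
    "Reaction",
    "StochasticModelSpec",
    "EnsembleStats",
    "delay_model_spec",
    "exon_definition_spec",
    "gillespie_run",
    "ensemble_psi",
    "binomial_reference",
    "noise_mean_curve",
]


@dataclass(frozen=True)
class Reaction:
    """Zero- or first-order reaction with an activity window [t_on, t_off).

    ``reactant`` is a species name or None (zero-order); ``products`` maps
    species names to integer stoichiometries.
    """

    name: str
    rate: float
    reactant: str | None
    products: dict
    t_on: float = 0.0
    t_off: float = math.inf

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError("rate must be >= 0")
        if self.t_on > self.t_off:
            raise ValueError("window must satisfy t_on <= t_off")


@dataclass(frozen=True)
class StochasticModelSpec:
    """Species list plus reactions, compiled to arrays for the SSA kernel."""

    species: tuple
    reactions: tuple

    def compile(self):
        idx = {s: i for i, s in enumerate(self.species)}
        n_r = len(self.reactions)
        reactant_idx = np.full(n_r, -1, dtype=np.int64)
        rates = np.zeros(n_r)
        stoich = np.zeros((n_r, len(self.species)), dtype=np.int64)
        t_on = np.zeros(n_r)
        t_off = np.full(n_r, np.inf)
        for j, r in enumerate(self.reactions):
            if r.reactant is not None:
                reactant_idx[j] = idx[r.reactant]
                stoich[j, idx[r.reactant]] -= 1
            rates[j] = r.rate
            for sp, k in r.products.items():
                stoich[j, idx[sp]] += k
            t_on[j], t_off[j] = r.t_on, r.t_off
        switches = np.unique(
            np.array(
                [t for t in np.concatenate([t_on, t_off]) if np.isfinite(t) and t > 0]
            )
        )
        return reactant_idx, rates, stoich, t_on, t_off, switches


def delay_model_spec(params: CommitmentParams, delays: DelaySet) -> StochasticModelSpec:
    """Stochastic version of the time-delay commitment model."""
    reactions = (
        Reaction("inclusion", params.ki, "mRNA", {"Incl": 1}),
        Reaction(
            "escape", params.kesc, "mRNA", {"mRNAinh": 1},
            t_on=delays.tau_inh1, t_off=delays.tau_inh2,
        ),
        Reaction("skipping", params.ks, "mRNA", {"Skip": 1}, t_on=delays.tau),
        Reaction("skipping_inh", params.ks, "mRNAinh", {"Skip": 1}, t_on=delays.tau),
    )
    return StochasticModelSpec(("mRNA", "mRNAinh", "Incl", "Skip"), reactions)


def exon_definition_spec(
    params: ExonDefinitionParams,
    arch: GeneArchitecture,
    profile: InhibitionProfile,
) -> StochasticModelSpec:
    """Stochastic version of the 19-species exon-definition model."""
    schedule: DelaySchedule = compute_delay_schedule(arch, params.vpol)
    k_base = (params.k1, params.k2, params.k3)
    k_mod = effective_rates(k_base, arch, profile)
    taus = (schedule.tau1, schedule.tau2, schedule.tau3)
    patterns = ("000", "100", "010", "001", "110", "101", "011", "111")
    reactions = []
    for suffix, rates in (("", k_base), ("inh", k_mod)):
        for pat in patterns:
            src = f"P{pat}{suffix}"
            for exon in range(3):
                if pat[exon] == "0":
                    dst = pat[:exon] + "1" + pat[exon + 1:]
                    reactions.append(
                        Reaction(
                            f"def{exon + 1}_{src}", rates[exon], src,
                            {f"P{dst}{suffix}": 1}, t_on=taus[exon],
                        )
                    )
            reactions.append(
                Reaction(
                    f"ret_{src}", params.kret, src, {"ret": 1},
                    t_on=schedule.tau6,
                )
            )
        reactions.append(
            Reaction(f"incl_{suffix or 'free'}", params.kspli, f"P111{suffix}", {"Incl": 1})
        )
        reactions.append(
            Reaction(f"skip_{suffix or 'free'}", params.kspls, f"P101{suffix}", {"Skip": 1})
        )
    for pat in patterns:
        reactions.append(
            Reaction(
                f"rbp_P{pat}", params.rbp_br, f"P{pat}", {f"P{pat}inh": 1},
                t_on=schedule.tau4, t_off=schedule.tau5,
            )
        )
    return StochasticModelSpec(EXONDEF_SPECIES, tuple(reactions))


@dataclass
class Trajectory:
    """Event log of a single SSA realization."""

    species: tuple
    times: np.ndarray
    reactions: np.ndarray
    final_counts: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "reaction": self.reactions})


def gillespie_run(
    spec: StochasticModelSpec,
    initial_counts: dict,
    seed: int,
    t_end: float = 1000.0,
    max_events: int = 1_000_000,
) -> Trajectory:
    """One exact SSA realization with a full event log."""
    x0 = np.zeros(len(spec.species), dtype=np.int64)
    for sp, n in initial_counts.items():
        if n < 0 or int(n) != n:
            raise ValueError("initial counts must be non-negative integers")
        x0[spec.species.index(sp)] = int(n)
    reactant_idx, rates, stoich, t_on, t_off, switches = spec.compile()
    times, rids, n, final = _ssa_core.ssa_events(
        x0, reactant_idx, rates, stoich, t_on, t_off, switches,
        float(t_end), int(seed), int(max_events),
    )
    if n < 0:
        raise RuntimeError(f"event log exceeded max_events={max_events}")
    assert np.all(final >= 0), "negative molecule count (engine invariant)"
    return Trajectory(spec.species, times[:n].copy(), rids[:n].copy(), final)


def sample_runs(
    spec: StochasticModelSpec,
    initial_counts: dict,
    n_runs: int,
    t_grid,
    seed: int,
) -> np.ndarray:
    """Counts of every species on ``t_grid`` for ``n_runs`` realizations.

    Returns an array of shape (n_runs, len(t_grid), n_species).
    """
    x0 = np.zeros(len(spec.species), dtype=np.int64)
    for sp, n in initial_counts.items():
        x0[spec.species.index(sp)] = int(n)
    reactant_idx, rates, stoich, t_on, t_off, switches = spec.compile()
    grid = np.asarray(t_grid, dtype=float)
    seeds = np.random.SeedSequence(seed).generate_state(n_runs) % (2**31 - 1)
    out = np.empty((n_runs, grid.size, len(spec.species)), dtype=np.int64)
    for r in range(n_runs):
        out[r] = _ssa_core.ssa_sample(
            x0, reactant_idx, rates, stoich, t_on, t_off, switches,
            grid, int(seeds[r]),
        )
    return out


@dataclass
class EnsembleStats:
    """PSI statistics across an ensemble of single-cell realizations."""

    n_runs: int
    incl: np.ndarray
    skip: np.ndarray
    ret: np.ndarray
    mean_psi: float
    std_psi: float
    n_undefined: int
    seed: int = 0

    @property
    def psi_values(self) -> np.ndarray:
        denom = self.incl + self.skip
        with np.errstate(invalid="ignore"):
            return np.where(denom > 0, self.incl / np.maximum(denom, 1), np.nan)

    @property
    def mean_molecule_count(self) -> float:
        """Mean spliced-molecule count (Incl+Skip) per run."""
        return float((self.incl + self.skip).mean())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "run": np.arange(self.n_runs),
                "incl": self.incl,
                "skip": self.skip,
                "ret": self.ret,
                "psi": self.psi_values,
            }
        )


def ensemble_psi(
    spec: StochasticModelSpec,
    initial_count: int,
    n_runs: int,
    seed: int,
    t_end: float = 1000.0,
    initial_species: str | None = None,
) -> EnsembleStats:
    """Per-realization PSI at ``t_end`` across ``n_runs`` cells.

    Each realization starts with ``initial_count`` precursor molecules.
    Realizations in which no spliced molecule was produced have undefined PSI
    and are excluded from the mean/std but counted.
    """
    if n_runs < 2:
        raise ValueError("need n_runs >= 2")
    if initial_species is None:
        initial_species = spec.species[0]
    counts = sample_runs(
        spec, {initial_species: initial_count}, n_runs, [t_end], seed
    )[:, 0, :]
    i_incl = spec.species.index("Incl")
    i_skip = spec.species.index("Skip")
    incl = counts[:, i_incl].astype(float)
    skip = counts[:, i_skip].astype(float)
    ret = (
        counts[:, spec.species.index("ret")].astype(float)
        if "ret" in spec.species
        else np.zeros(n_runs)
    )
    denom = incl + skip
    defined = denom > 0
    if not defined.any():
        raise RuntimeError("every realization ended with undefined PSI")
    psi = incl[defined] / denom[defined]
    return EnsembleStats(
        n_runs=n_runs, incl=incl, skip=skip, ret=ret,
        mean_psi=float(psi.mean()), std_psi=float(psi.std(ddof=0)),
        n_undefined=int((~defined).sum()), seed=seed,
    )


def binomial_reference(n: float, p: float) -> float:
    """Std of a binomial proportion: sqrt(p (1-p) / n)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    return math.sqrt(p * (1.0 - p) / n)


def noise_mean_curve(
    spec_factory,
    sweep_values,
    molecule_counts,
    n_runs: int,
    seed: int,
    t_end: float = 1000.0,
) -> pd.DataFrame:
    """Noise-mean relationship of PSI against the binomial reference.

    ``spec_factory(value)`` must return a :class:`StochasticModelSpec` for
    each sweep value (e.g. a polymerase velocity or an RBP position); the
    sweep generates a spread of mean PSI.  For each (sweep value, molecule
    count) pair the empirical mean/std of PSI over ``n_runs`` realizations is
    paired with the binomial std at matched mean and matched spliced-molecule
    count (Incl+Skip per run, which corrects for retention).
    """
    rows = []
    for iv, value in enumerate(sweep_values):
        spec = spec_factory(value)
        for ic, mc in enumerate(molecule_counts):
            sub_seed = int(
                np.random.SeedSequence([seed, iv, ic]).generate_state(1)[0]
                % (2**31 - 1)
            )
            stats = ensemble_psi(spec, mc, n_runs, sub_seed, t_end=t_end)
            eff_n = stats.mean_molecule_count
            rows.append(
                {
                    "sweep_value": value,
                    "initial_count": mc,
                    "mean_psi": stats.mean_psi,
                    "std_psi": stats.std_psi,
                    "mean_spliced_count": eff_n,
                    "binomial_std": binomial_reference(
                        max(eff_n, 1.0), stats.mean_psi
                    ),
                    "n_undefined": stats.n_undefined,
                }
            )
    return pd.DataFrame(rows)
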