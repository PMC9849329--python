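"""Named parameter bundles for the simulation regimes studied in the package.

Geometry values carry ``provenance="printed"`` where the source literature
states them explicitly (transcript length 300 nt, few/many-step topologies
2/3/1/2 and 20/30/10/20, exon ends 210/443/690 nt, gene length 700 nt);
every kinetic rate constant is a ``provenance="reconstructed"`` default,
chosen once to land in the physiological regime (splicing commitment on the
seconds-to-minutes scale, polymerase velocities 1-1000 nt/s) and to realize
the qualitative behavior of its regime.  All fixtures are plain dataclass
bundles: build your own variants with :func:`dataclasses.replace`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

from .bursting import BurstingParams
from .commitment import FEW_STEPS, MANY_STEPS, CommitmentParams, CommitmentTopology
from .exondef import (
    RON_MINIGENE,
    ExonDefinitionParams,
    GeneArchitecture,
    InhibitionProfile,
)

__all__ = ["Fixture", "FIXTURES", "get_fixture"]


@dataclass(frozen=True)
class Fixture:
    """A named, provenance-flagged parameter bundle."""

    name: str
    description: str
    provenance: str  # "printed" | "reconstructed" | "mixed"
    payload: dict = field(default_factory=dict)

    def __getitem__(self, key: str) -> Any:
        return self.payload[key]


FIXTURES: dict = {}


def _register(fx: Fixture) -> Fixture:
    FIXTURES[fx.name] = fx
    return fx


_register(
    Fixture(
        "fig1_basic",
        "Basic delay model without RBP escape: PSI decreases with vpol.",
        "mixed",  # topology printed, rates reconstructed
        {
            "params": CommitmentParams(ki=0.1, ks=0.1, kesc=0.0),
            "topology": FEW_STEPS,
        },
    )
)

_register(
    Fixture(
        "fig1_many_steps",
        "Many-steps multistep topology matching the delay model.",
        "mixed",
        {
            "params": CommitmentParams(ki=0.1, ks=0.1, kesc=0.0),
            "topology": MANY_STEPS,
        },
    )
)

_register(
    Fixture(
        "fig2_early_inh",
        "Early RBP inhibition (window opens at initiation, k=0): "
        "monotonically increasing PSI-vpol profile.",
        "reconstructed",
        {
            "params": CommitmentParams(ki=0.1, ks=0.05, kesc=1.0),
            "topology": CommitmentTopology(300.0, 0, 3, 3, 2),
        },
    )
)

_register(
    Fixture(
        "fig2_bell",
        "Early inhibition with a short window followed by a long "
        "inclusion-only stretch: bell-shaped PSI-vpol profile.",
        "reconstructed",
        {
            "params": CommitmentParams(ki=0.1, ks=0.4, kesc=0.2),
            "topology": CommitmentTopology(300.0, 0, 1, 6, 1),
        },
    )
)

_register(
    Fixture(
        "fig2_late_inh",
        "Late RBP inhibition (window opens after exon 2, k>0): "
        "U-shaped PSI-vpol profile.",
        "reconstructed",
        {
            "params": CommitmentParams(ki=0.1, ks=0.1, kesc=1.0),
            "topology": FEW_STEPS,
        },
    )
)

_register(
    Fixture(
        "fig3_mechanistic",
        "Mechanistic exon-definition model on the RON exon 10-12 minigene "
        "geometry with a bell-shaped +/-50 nt inhibition profile.",
        "mixed",  # exon ends/gene length printed; starts and rates reconstructed
        {
            "params": ExonDefinitionParams(),
            "arch": RON_MINIGENE,
            "profile": InhibitionProfile(l_up=50.0, r_down=50.0, p=8.0),
        },
    )
)

_register(
    Fixture(
        "fig4_scan",
        "RBP position x vpol heatmap scan on the RON geometry.",
        "mixed",
        {
            "params": ExonDefinitionParams(),
            "arch": RON_MINIGENE,
            "profile": InhibitionProfile(l_up=50.0, r_down=50.0, p=8.0),
            "positions": (60.0, 640.0, 60),  # (start, stop, n)
            "vpol_grid": (5.0, 50.0, 1000.0),
        },
    )
)

_register(
    Fixture(
        "fig5_asymmetry",
        "Quasi-binary inhibition profile (p=32, +/-25 nt) at slow elongation "
        "(vpol=5 nt/s) for splice-site asymmetry analyses.",
        "reconstructed",
        {
            "params": ExonDefinitionParams(vpol=5.0),
            "arch": RON_MINIGENE,
            "profile": InhibitionProfile(l_up=25.0, r_down=25.0, p=32.0),
            "activator_profile": InhibitionProfile(
                l_up=25.0, r_down=25.0, p=32.0, mode="activator"
            ),
        },
    )
)

_register(
    Fixture(
        "fig6_noise",
        "Stochastic ensembles of the delay model: vpol sweep generating a "
        "spread of mean PSI for the noise-mean analysis.",
        "reconstructed",
        {
            "params": CommitmentParams(ki=0.1, ks=0.1, kesc=1.0),
            "topology": FEW_STEPS,
            "vpol_sweep": (2.0, 5.0, 10.0, 20.0, 50.0, 150.0, 500.0),
            "molecule_counts": (10, 100, 1000),
            "n_runs": 5000,
        },
    )
)

_register(
    Fixture(
        "fig7_bursting",
        "Random-telegraph promoter with differential isoform degradation "
        "(feedback off): bimodal PSI with one mode at 0.",
        "reconstructed",
        {
            "params": BurstingParams(
                kon=0.002, koff=0.01, vsyn=1.0, kelong=1.0,
                ki=0.2, ks=0.05, d_i=0.05, d_s=0.002,
            ),
            "bursting": True,
            "feedback": False,
            "t_end": 1e5,
        },
    )
)

_register(
    Fixture(
        "fig7_feedback",
        "Positive feedback on skipping without bursting: bimodal PSI "
        "(plateaus of feedback-on skipping dominance).",
        "reconstructed",
        {
            "params": BurstingParams(
                kon=0.0, koff=0.0, vsyn=0.3, kelong=1.0,
                ki=0.1, ks=0.02, d_i=0.01, d_s=0.01,
                fb_s=0.3, K=8.0, N=6.0,
            ),
            "bursting": False,
            "feedback": True,
            "t_end": 1e5,
        },
    )
)

_register(
    Fixture(
        "fig7_combined",
        "Bursting plus differential degradation plus positive feedback: "
        "tri-modal PSI.",
        "reconstructed",
        {
            "params": BurstingParams(
                kon=0.004, koff=0.01, vsyn=1.0, kelong=1.0,
                ki=0.2, ks=0.05, d_i=0.05, d_s=0.008,
                fb_s=2.0, K=10.0, N=6.0,
            ),
            "bursting": True,
            "feedback": True,
            "t_end": 4e5,
        },
    )
)

_register(
    Fixture(
        "release_demo",
        "SYNTHETIC single-intron release-competition observables in the "
        "style of single-molecule imaging conditions; NOT measured values.",
        "reconstructed",
        {
            "conditions": {
                "WT": {
                    "pol_speed": 25.0, "dwell_time": 60.0,
                    "prerelease_fraction": 0.55,
                    "transcript_length": 4000.0, "L": 2353.0,
                },
                "slow_elongation": {
                    "pol_speed": 8.0, "dwell_time": 60.0,
                    "prerelease_fraction": 0.75,
                    "transcript_length": 4000.0, "L": 2353.0,
                },
                "splicing_inhibited": {
                    "pol_speed": 25.0, "dwell_time": 60.0,
                    "prerelease_fraction": 0.10,
                    "transcript_length": 4000.0, "L": 2353.0,
                },
            },
            "no_steps": 8,
        },
    )
)


def get_fixture(name: str) -> Fixture:
    try:
        return FIXTURES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(FIXTURES)}"
        ) from None
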