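"""SBML Level 3 export of the deterministic models.

The delay switches of the co-transcriptional models are encoded as
time-triggered SBML Events that flip effective rate parameters, and derived
parameters (the per-step elongation rate, the RBP-modulated exon definition
rates) are written as InitialAssignments, so the documents carry the full
model semantics for SBML-aware tools.  Documents are generated as plain
SBML L3v2 core XML; stochastic-only constructs (the feedback propensity)
are not exportable.
"""

from __future__ import annotations

from lxml import etree

from .commitment import CommitmentParams, CommitmentTopology, DelaySet, compute_delays
from .exondef import (
    SPECIES as EXONDEF_SPECIES,
    ExonDefinitionParams,
    GeneArchitecture,
    InhibitionProfile,
    compute_delay_schedule,
    effective_rates,
    inhibition_function,
)
from .multistep import MultistepSpec, build_multistep_system, kelong_from_vpol

__all__ = ["export_sbml", "UnsupportedModelError"]

SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"


class UnsupportedModelError(ValueError):
    """Raised for model specs that have no SBML representation here."""


class _Builder:
    def __init__(self, model_id: str):
        self.root = etree.Element(
            f"{{{SBML_NS}}}sbml", nsmap={None: SBML_NS}, level="3", version="2"
        )
        self.model = etree.SubElement(self.root, f"{{{SBML_NS}}}model", id=model_id)
        comps = etree.SubElement(self.model, f"{{{SBML_NS}}}listOfCompartments")
        etree.SubElement(
            comps, f"{{{SBML_NS}}}compartment",
            id="cell", size="1", constant="true", spatialDimensions="3",
        )
        self.species_list = etree.SubElement(self.model, f"{{{SBML_NS}}}listOfSpecies")
        self.param_list = etree.SubElement(self.model, f"{{{SBML_NS}}}listOfParameters")
        self.ia_list = None
        self.reaction_list = None
        self.event_list = None

    def species(self, sid: str, initial: float) -> None:
        etree.SubElement(
            self.species_list, f"{{{SBML_NS}}}species",
            id=sid, compartment="cell", initialAmount=str(initial),
            hasOnlySubstanceUnits="true", boundaryCondition="false",
            constant="false",
        )

    def parameter(self, pid: str, value: float, constant: bool = True) -> None:
        etree.SubElement(
            self.param_list, f"{{{SBML_NS}}}parameter",
            id=pid, value=repr(float(value)),
            constant="true" if constant else "false",
        )

    @staticmethod
    def _math(expr) -> etree._Element:
        """Tiny MathML builder: expr is a str (ci/cn) or ('times'|'minus', ...)."""
        math = etree.Element(f"{{{MATHML_NS}}}math", nsmap={None: MATHML_NS})

        def build(node, parent):
            if isinstance(node, str):
                el = etree.SubElement(parent, f"{{{MATHML_NS}}}ci")
                el.text = f" {node} "
            elif isinstance(node, (int, float)):
                el = etree.SubElement(parent, f"{{{MATHML_NS}}}cn")
                el.text = f" {node} "
            else:
                op, *args = node
                apply_el = etree.SubElement(parent, f"{{{MATHML_NS}}}apply")
                etree.SubElement(apply_el, f"{{{MATHML_NS}}}{op}")
                for a in args:
                    build(a, apply_el)

        build(expr, math)
        return math

    def initial_assignment(self, symbol: str, expr) -> None:
        if self.ia_list is None:
            self.ia_list = etree.SubElement(
                self.model, f"{{{SBML_NS}}}listOfInitialAssignments"
            )
        ia = etree.SubElement(
            self.ia_list, f"{{{SBML_NS}}}initialAssignment", symbol=symbol
        )
        ia.append(self._math(expr))

    def reaction(self, rid: str, reactant: str, products: dict, rate_param: str) -> None:
        if self.reaction_list is None:
            self.reaction_list = etree.SubElement(
                self.model, f"{{{SBML_NS}}}listOfReactions"
            )
        rxn = etree.SubElement(
            self.reaction_list, f"{{{SBML_NS}}}reaction", id=rid, reversible="false"
        )
        reactants = etree.SubElement(rxn, f"{{{SBML_NS}}}listOfReactants")
        etree.SubElement(
            reactants, f"{{{SBML_NS}}}speciesReference",
            species=reactant, stoichiometry="1", constant="true",
        )
        prods = etree.SubElement(rxn, f"{{{SBML_NS}}}listOfProducts")
        for sp, n in products.items():
            etree.SubElement(
                prods, f"{{{SBML_NS}}}speciesReference",
                species=sp, stoichiometry=str(n), constant="true",
            )
        kl = etree.SubElement(rxn, f"{{{SBML_NS}}}kineticLaw")
        kl.append(self._math(("times", rate_param, reactant)))

    def event(self, eid: str, trigger_time: float, assignments: dict) -> None:
        """Time-triggered event: at t >= trigger_time set parameters."""
        if self.event_list is None:
            self.event_list = etree.SubElement(
                self.model, f"{{{SBML_NS}}}listOfEvents"
            )
        ev = etree.SubElement(
            self.event_list, f"{{{SBML_NS}}}event", id=eid,
            useValuesFromTriggerTime="true",
        )
        trig = etree.SubElement(
            ev, f"{{{SBML_NS}}}trigger", initialValue="false", persistent="true"
        )
        trig.append(
            self._math(("geq", "time_sym", trigger_time))
        )
        # csymbol for time
        ci = trig.find(f".//{{{MATHML_NS}}}ci")
        csym = etree.Element(
            f"{{{MATHML_NS}}}csymbol", encoding="text",
            definitionURL="http://www.sbml.org/sbml/symbols/time",
        )
        csym.text = " t "
        ci.getparent().replace(ci, csym)
        eas = etree.SubElement(ev, f"{{{SBML_NS}}}listOfEventAssignments")
        for pid, value in assignments.items():
            ea = etree.SubElement(
                eas, f"{{{SBML_NS}}}eventAssignment", variable=pid
            )
            ea.append(self._math(value))

    def tostring(self) -> bytes:
        return etree.tostring(
            self.root, pretty_print=True, xml_declaration=True, encoding="UTF-8"
        )


def _delay_doc(params: CommitmentParams, delays: DelaySet) -> _Builder:
    b = _Builder("splicing_commitment_delay")
    for sid, x0 in (("mRNA", 1.0), ("mRNAinh", 0.0), ("Incl", 0.0), ("Skip", 0.0)):
        b.species(sid, x0)
    b.parameter("ki", params.ki)
    b.parameter("ks", params.ks)
    b.parameter("kesc", params.kesc)
    # effective, event-switched rates
    b.parameter("ks_eff", 0.0, constant=False)
    b.parameter("kesc_eff", 0.0, constant=False)
    b.reaction("inclusion", "mRNA", {"Incl": 1}, "ki")
    b.reaction("escape", "mRNA", {"mRNAinh": 1}, "kesc_eff")
    b.reaction("skipping", "mRNA", {"Skip": 1}, "ks_eff")
    b.reaction("skipping_inh", "mRNAinh", {"Skip": 1}, "ks_eff")
    b.event("escape_on", delays.tau_inh1, {"kesc_eff": "kesc"})
    b.event("escape_off", delays.tau_inh2, {"kesc_eff": 0.0})
    b.event("skipping_on", delays.tau, {"ks_eff": "ks"})
    return b


def _multistep_doc(spec: MultistepSpec, vpol: float) -> _Builder:
    topo = spec.topology
    b = _Builder("splicing_commitment_multistep")
    for sid in spec.species:
        b.species(sid, 1.0 if sid == "P1" else 0.0)
    b.parameter("vpol", vpol)
    b.parameter("l", topo.l)
    b.parameter("tr_len", topo.tr_len)
    b.parameter("ki", spec.params.ki)
    b.parameter("ks", spec.params.ks)
    b.parameter("kesc", spec.params.kesc)
    b.parameter("kelong", spec.kelong, constant=False)
    b.initial_assignment(
        "kelong", ("divide", ("times", "vpol", "l"), "tr_len")
    )
    n = len(spec.species)
    A = spec.matrix
    rate_of = {}
    for j, src in enumerate(spec.species[:-2]):
        for i in range(n):
            if i == j or A[i, j] == 0:
                continue
            dst = spec.species[i]
            rate = A[i, j]
            if abs(rate - spec.kelong) < 1e-12:
                pname = "kelong"
            elif abs(rate - spec.params.ki) < 1e-12:
                pname = "ki"
            elif abs(rate - spec.params.ks) < 1e-12:
                pname = "ks"
            else:
                pname = "kesc"
            b.reaction(f"r_{src}_{dst}", src, {dst: 1}, pname)
    return b


def _exondef_doc(
    params: ExonDefinitionParams,
    arch: GeneArchitecture,
    profile: InhibitionProfile,
) -> _Builder:
    b = _Builder("exon_definition_mechanistic")
    for sid in EXONDEF_SPECIES:
        b.species(sid, 1.0 if sid == "P000" else 0.0)
    schedule = compute_delay_schedule(arch, params.vpol)
    k_base = (params.k1, params.k2, params.k3)
    k_mod = effective_rates(k_base, arch, profile)
    sign = -1.0 if profile.mode == "inhibitor" else 1.0
    for x, (kx, kx_mod) in enumerate(zip(k_base, k_mod), start=1):
        b.parameter(f"k{x}", kx)
        ss3, ss5 = arch.splice_sites(x)
        f5 = inhibition_function(ss5 - arch.rbp_pos, profile)
        f3 = inhibition_function(ss3 - arch.rbp_pos, profile)
        b.parameter(f"inh_5ss_ex{x}", f5)
        b.parameter(f"inh_3ss_ex{x}", f3)
        b.parameter(f"k{x}_inh", kx_mod, constant=False)
        b.initial_assignment(
            f"k{x}_inh",
            (
                "times",
                f"k{x}",
                ("plus", 1.0, ("times", sign, f"inh_5ss_ex{x}")),
                ("plus", 1.0, ("times", sign, f"inh_3ss_ex{x}")),
            ),
        )
    b.parameter("rbp_br", params.rbp_br)
    b.parameter("kspli", params.kspli)
    b.parameter("kspls", params.kspls)
    b.parameter("kret", params.kret)
    for x in (1, 2, 3):
        b.parameter(f"k{x}_eff", 0.0, constant=False)
        b.parameter(f"k{x}_inh_eff", 0.0, constant=False)
    b.parameter("rbp_br_eff", 0.0, constant=False)
    b.parameter("kret_eff", 0.0, constant=False)
    patterns = ("000", "100", "010", "001", "110", "101", "011", "111")
    for suffix in ("", "inh"):
        eff = "_eff" if not suffix else "_inh_eff"
        for pat in patterns:
            src = f"P{pat}{suffix}"
            for exon in range(3):
                if pat[exon] == "0":
                    dst = pat[:exon] + "1" + pat[exon + 1:]
                    b.reaction(
                        f"def{exon + 1}_{src}", src, {f"P{dst}{suffix}": 1},
                        f"k{exon + 1}{eff}",
                    )
            b.reaction(f"ret_{src}", src, {"ret": 1}, "kret_eff")
        b.reaction(f"incl_{suffix or 'free'}", f"P111{suffix}", {"Incl": 1}, "kspli")
        b.reaction(f"skip_{suffix or 'free'}", f"P101{suffix}", {"Skip": 1}, "kspls")
    for pat in patterns:
        b.reaction(f"rbp_P{pat}", f"P{pat}", {f"P{pat}inh": 1}, "rbp_br_eff")
    taus = (schedule.tau1, schedule.tau2, schedule.tau3)
    for x, tau in enumerate(taus, start=1):
        b.event(
            f"exon{x}_definable", tau,
            {f"k{x}_eff": f"k{x}", f"k{x}_inh_eff": f"k{x}_inh"},
        )
    b.event("rbp_window_open", schedule.tau4, {"rbp_br_eff": "rbp_br"})
    b.event("rbp_window_close", schedule.tau5, {"rbp_br_eff": 0.0})
    b.event("transcription_end", schedule.tau6, {"kret_eff": "kret"})
    return b


def export_sbml(model_config: dict) -> bytes:
    """SBML L3 document (bytes) for a model bundle from :mod:`cosplice.config`.

    Supported kinds: ``delay`` (needs ``params``, ``topology``, ``vpol``),
    ``multistep`` (same) and ``exon_definition`` (``params``, ``arch``,
    ``profile``).  Stochastic-only models raise
    :class:`UnsupportedModelError`.
    """
    kind = model_config.get("model")
    if kind == "delay":
        delays = compute_delays(model_config["topology"], model_config["vpol"])
        doc = _delay_doc(model_config["params"], delays)
    elif kind == "multistep":
        topo = model_config["topology"]
        kelong = kelong_from_vpol(model_config["vpol"], topo.l, topo.tr_len)
        spec = build_multistep_system(topo, model_config["params"], kelong)
        doc = _multistep_doc(spec, model_config["vpol"])
    elif kind == "exon_definition":
        doc = _exondef_doc(
            model_config["params"], model_config["arch"], model_config["profile"]
        )
    else:
        raise UnsupportedModelError(
            f"model {kind!r} has no SBML representation (stochastic-only "
            "constructs are not exportable)"
        )
    return doc.tostring()
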