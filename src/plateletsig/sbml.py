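"""SBML (Level 2 Version 4) export of the kinetic model, plus re-import
and simulation of the package's own exports.

The basal model exports the ten species and thirteen reactions of the
resting-platelet network with their exact kinetic laws (Hill kinetics
for PDE2 on cAMP, Michaelis-Menten elsewhere, mass-action pool
interconversion).  The overall model additionally serializes the drug
and feedback modifications inside the affected kinetic laws: competitive
inhibition and the kf1 term in the PDE3 law, per-dose AC influx with the
kf2 feedback (as an explicit piecewise floor at zero) and the synergy
factor in the cAMP influx law.

Only step protocols with onset 0 are exportable (SBML kinetic laws here
are time-invariant).  Import is supported for documents produced by
this module: kinetic-law MathML is restricted to the operator subset the
exporter emits (times, divide, plus, minus, power, piecewise/gt).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from lxml import etree

from .model import (
    AC_INHIBITOR,
    AC_STIMULATORS,
    EMPTY_PROTOCOL,
    H0,
    PDE3_INHIBITORS,
    BasalConstants,
    ConfigurationError,
    DrugParameters,
    ModelVariant,
    PlateletState,
    StimulusProtocol,
)

__all__ = ["export_sbml", "parse_sbml", "simulate_sbml", "SbmlModel"]

SBML_NS = "http://www.sbml.org/sbml/level2/version4"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"

SPECIES_IDS = (
    "cAMP", "cGMP",
    "PDE2_active", "PDE3_active", "PDE5_active",
    "PDE2_inactive", "PDE3_inactive", "PDE5_inactive",
    "AMP", "GMP",
)

_K_NAMES = ("k1", "k2", "k3", "k4", "k5", "k6", "k7", "k8", "k9", "k10",
            "k11", "k12", "k13", "k14", "k15", "k16", "k17", "k18", "k19")

_CONST_ORDER = (
    "vmax_pde2_camp", "km_pde2_camp", "vmax_pde3_camp", "km_pde3_camp",
    "vmax_pde2_cgmp", "km_pde2_cgmp", "vmax_pde3_cgmp", "km_pde3_cgmp",
    "vmax_pde5_cgmp", "km_pde5_cgmp", "camp_influx", "cgmp_influx",
    "pde2_deactivation", "pde2_activation", "pde3_deactivation",
    "pde3_activation", "pde5_deactivation", "pde5_activation", "hill_pde2",
)


# -- expression mini-AST -> MathML ------------------------------------------

def _math_element(expr, parent) -> None:
    m = "{%s}" % MATHML_NS
    if isinstance(expr, str):
        ci = etree.SubElement(parent, m + "ci")
        ci.text = f" {expr} "
    elif isinstance(expr, (int, float)):
        cn = etree.SubElement(parent, m + "cn")
        cn.text = f" {expr:g} "
    elif isinstance(expr, tuple):
        op = expr[0]
        if op == "piecewise":
            pw = etree.SubElement(parent, m + "piecewise")
            piece = etree.SubElement(pw, m + "piece")
            _math_element(expr[1], piece)
            _math_element(expr[2], piece)
            other = etree.SubElement(pw, m + "otherwise")
            _math_element(expr[3], other)
        else:
            apply_el = etree.SubElement(parent, m + "apply")
            etree.SubElement(apply_el, m + op)
            for arg in expr[1:]:
                _math_element(arg, apply_el)
    else:
        raise ConfigurationError(f"cannot serialize expression node {expr!r}")


def _math_root(expr) -> etree._Element:
    root = etree.Element("{%s}math" % MATHML_NS)
    _math_element(expr, root)
    return root


# -- MathML -> evaluator -----------------------------------------------------

def _parse_math(node):
    """Compile a MathML node (the exporter's subset) into a closure
    ``f(env) -> float`` over a name -> value environment."""
    tag = etree.QName(node).localname
    if tag == "math":
        children = [c for c in node if isinstance(c.tag, str)]
        return _parse_math(children[0])
    if tag == "ci":
        name = node.text.strip()
        return lambda env: env[name]
    if tag == "cn":
        value = float(node.text.strip())
        return lambda env: value
    if tag == "piecewise":
        piece = node.find("{%s}piece" % MATHML_NS)
        parts = [c for c in piece if isinstance(c.tag, str)]
        value_f = _parse_math(parts[0])
        cond_f = _parse_math(parts[1])
        other = node.find("{%s}otherwise" % MATHML_NS)
        other_f = _parse_math([c for c in other if isinstance(c.tag, str)][0])
        return lambda env: value_f(env) if cond_f(env) else other_f(env)
    if tag == "apply":
        children = [c for c in node if isinstance(c.tag, str)]
        op = etree.QName(children[0]).localname
        args = [_parse_math(c) for c in children[1:]]
        if op == "plus":
            return lambda env: sum(f(env) for f in args)
        if op == "times":
            def times(env):
                out = 1.0
                for f in args:
                    out *= f(env)
                return out
            return times
        if op == "divide":
            a, b = args
            return lambda env: a(env) / b(env)
        if op == "minus":
            if len(args) == 1:
                a, = args
                return lambda env: -a(env)
            a, b = args
            return lambda env: a(env) - b(env)
        if op == "power":
            a, b = args
            return lambda env: a(env) ** b(env)
        if op == "gt":
            a, b = args
            return lambda env: a(env) > b(env)
        raise ConfigurationError(f"unsupported MathML operator {op!r}")
    raise ConfigurationError(f"unsupported MathML element {tag!r}")


# -- export ------------------------------------------------------------------

def _basal_reactions(hill: str = "k19"):
    """(id, reactants, products, modifiers, law) for r1..r13."""
    camp_h = ("power", "cAMP", hill)
    return [
        ("r1", [], ["cAMP"], [], "k11"),
        ("r2", [], ["cGMP"], [], "k12"),
        ("r3", ["cAMP"], ["AMP"], ["PDE2_active"],
         ("divide", ("times", "k1", camp_h, "PDE2_active"),
          ("plus", "k2", camp_h))),
        ("r4", ["cAMP"], ["AMP"], ["PDE3_active"],
         ("divide", ("times", "k3", "PDE3_active", "cAMP"),
          ("plus", "k4", "cAMP"))),
        ("r5", ["cGMP"], ["GMP"], ["PDE2_active"],
         ("divide", ("times", "k5", "PDE2_active", "cGMP"),
          ("plus", "k6", "cGMP"))),
        ("r6", ["cGMP"], ["GMP"], ["PDE3_active"],
         ("divide", ("times", "k7", "PDE3_active", "cGMP"),
          ("plus", "k8", "cGMP"))),
        ("r7", ["cGMP"], ["GMP"], ["PDE5_active"],
         ("divide", ("times", "k9", "PDE5_active", "cGMP"),
          ("plus", "k10", "cGMP"))),
        ("r8", ["PDE2_inactive"], ["PDE2_active"], [],
         ("times", "k14", "PDE2_inactive")),
        ("r9", ["PDE2_active"], ["PDE2_inactive"], [],
         ("times", "k13", "PDE2_active")),
        ("r10", ["PDE3_inactive"], ["PDE3_active"], [],
         ("times", "k16", "PDE3_inactive")),
        ("r11", ["PDE3_active"], ["PDE3_inactive"], [],
         ("times", "k15", "PDE3_active")),
        ("r12", ["PDE5_inactive"], ["PDE5_active"], [],
         ("times", "k18", "PDE5_inactive")),
        ("r13", ["PDE5_active"], ["PDE5_inactive"], [],
         ("times", "k17", "PDE5_active")),
    ]


def _safe(text: str) -> str:
    return "".join(ch if ch.isalnum() else "_" for ch in text)


def export_sbml(
    constants: BasalConstants,
    initial: PlateletState | None = None,
    drugs: DrugParameters | None = None,
    variant: ModelVariant = H0,
    protocol: StimulusProtocol = EMPTY_PROTOCOL,
    path=None,
    model_id: str | None = None,
) -> str:
    """Serialize the (basal or drug-extended) model as SBML L2V4.

    Returns the XML text; optionally writes it to ``path``.  Raises a
    configuration error for protocols that cannot be expressed as
    time-invariant kinetic laws (transient profiles, delayed onsets) or
    for unparameterized drug entries.
    """
    if initial is None:
        initial = PlateletState()
    drugs = drugs or DrugParameters()
    for entry in protocol.entries:
        if entry.profile != "step" or entry.onset != 0.0:
            raise ConfigurationError(
                "SBML export supports step protocols with onset 0 only")

    parameters: dict[str, float] = {
        name: getattr(constants, attr)
        for name, attr in zip(_K_NAMES, _CONST_ORDER)
    }

    inhibition_terms = []
    ac_terms = []
    basal_factor_expr = None
    has_pde_inh = protocol.has_pde_inhibitor
    missing = []
    for entry in protocol.entries:
        if entry.drug in PDE3_INHIBITORS:
            tag = _safe(entry.drug)
            if entry.drug not in drugs.ki:
                missing.append(f"ki:{entry.drug}")
                continue
            parameters[f"u_{tag}"] = entry.dose
            parameters[f"ki_{tag}"] = drugs.ki[entry.drug]
            inhibition_terms.append(("divide", f"u_{tag}", f"ki_{tag}"))
        elif entry.drug in AC_STIMULATORS:
            tag = f"x_{_safe(entry.drug)}_{_safe(f'{entry.dose:g}')}"
            if (entry.drug, float(entry.dose)) not in drugs.ac_influx:
                missing.append(f"influx:{entry.drug}:{entry.dose:g}")
                continue
            parameters[tag] = drugs.ac_influx[(entry.drug, float(entry.dose))]
            stim = ("times", "k_syn", tag) if has_pde_inh else tag
            if variant.ac_feedback:
                net = ("minus", stim, ("times", "kf2", "cAMP"))
                ac_terms.append(("piecewise", net, ("gt", net, 0), 0))
            else:
                ac_terms.append(stim)
        elif entry.drug == AC_INHIBITOR:
            parameters["u_ac_inhibitor"] = entry.dose
            parameters["khalf_ac_inhibitor"] = drugs.ac_inhibitor_khalf
            basal_factor_expr = ("divide", "khalf_ac_inhibitor",
                                 ("plus", "khalf_ac_inhibitor",
                                  "u_ac_inhibitor"))
    if missing:
        raise ConfigurationError(
            "model not fully parameterized; missing " + ", ".join(missing))
    if variant.pde3_feedback:
        parameters["kf1"] = drugs.kf1
    if variant.ac_feedback:
        parameters["kf2"] = drugs.kf2
    if has_pde_inh and any(e.drug in AC_STIMULATORS for e in protocol.entries):
        parameters["k_syn"] = drugs.k_syn

    reactions = _basal_reactions()
    # overall-model modifications live inside the affected kinetic laws
    r1_law = "k11" if basal_factor_expr is None else \
        ("times", basal_factor_expr, "k11")
    if ac_terms:
        r1_law = ("plus", r1_law, *ac_terms)
    vmax3 = ("plus", "k3", ("times", "kf1", "cAMP")) \
        if variant.pde3_feedback else "k3"
    km3 = ("times", ("plus", 1, *inhibition_terms), "k4") \
        if inhibition_terms else "k4"
    r4_law = ("divide", ("times", vmax3, "PDE3_active", "cAMP"),
              ("plus", km3, "cAMP"))
    reactions[0] = ("r1", [], ["cAMP"], [], r1_law)
    reactions[3] = ("r4", ["cAMP"], ["AMP"], ["PDE3_active"], r4_law)

    s = "{%s}" % SBML_NS
    root = etree.Element(s + "sbml", nsmap={None: SBML_NS}, level="2",
                         version="4")
    if model_id is None:
        model_id = ("platelet_cyclic_nucleotide_basal"
                    if not protocol.entries and variant.name == "H0"
                    else "platelet_cyclic_nucleotide_overall")
    model = etree.SubElement(root, s + "model", id=model_id)

    compartments = etree.SubElement(model, s + "listOfCompartments")
    etree.SubElement(compartments, s + "compartment", id="platelet",
                     size="1")

    species_list = etree.SubElement(model, s + "listOfSpecies")
    initial_values = initial.to_array()
    for sid, value in zip(SPECIES_IDS, initial_values):
        etree.SubElement(species_list, s + "species", id=sid,
                         compartment="platelet",
                         initialConcentration=f"{value:.12g}")

    params_list = etree.SubElement(model, s + "listOfParameters")
    for name, value in parameters.items():
        etree.SubElement(params_list, s + "parameter", id=name,
                         value=f"{value:.12g}", constant="true")

    reactions_list = etree.SubElement(model, s + "listOfReactions")
    for rid, reactants, products, modifiers, law in reactions:
        rx = etree.SubElement(reactions_list, s + "reaction", id=rid,
                              reversible="false")
        if reactants:
            lo = etree.SubElement(rx, s + "listOfReactants")
            for sp in reactants:
                etree.SubElement(lo, s + "speciesReference", species=sp)
        if products:
            lo = etree.SubElement(rx, s + "listOfProducts")
            for sp in products:
                etree.SubElement(lo, s + "speciesReference", species=sp)
        if modifiers:
            lo = etree.SubElement(rx, s + "listOfModifiers")
            for sp in modifiers:
                etree.SubElement(lo, s + "modifierSpeciesReference", species=sp)
        kl = etree.SubElement(rx, s + "kineticLaw")
        kl.append(_math_root(law))

    text = etree.tostring(root, pretty_print=True, xml_declaration=True,
                          encoding="UTF-8").decode()
    if path is not None:
        Path(path).write_text(text)
    return text


# -- import ------------------------------------------------------------------

@dataclass
class SbmlModel:
    """Parsed subset of an SBML document produced by this package."""

    model_id: str
    species: list
    initial: np.ndarray
    parameters: dict
    reactions: list  # (id, {species: stoich}, law closure)

    def rhs(self, _t, y) -> np.ndarray:
        env = dict(self.parameters)
        env.update(zip(self.species, y))
        dy = np.zeros(len(self.species))
        index = {sp: i for i, sp in enumerate(self.species)}
        for _rid, stoich, law in self.reactions:
            v = law(env)
            for sp, coeff in stoich.items():
                dy[index[sp]] += coeff * v
        return dy


def parse_sbml(source) -> SbmlModel:
    """Parse an SBML document written by :func:`export_sbml`."""
    if isinstance(source, Path) or (isinstance(source, str)
                                    and "<" not in source):
        root = etree.parse(str(source)).getroot()
    else:
        root = etree.fromstring(source.encode()
                                if isinstance(source, str) else source)
    s = "{%s}" % SBML_NS
    model = root.find(s + "model")
    if model is None:
        raise ConfigurationError("document has no SBML model element")

    species = []
    initial = []
    for sp in model.findall(f"{s}listOfSpecies/{s}species"):
        species.append(sp.get("id"))
        initial.append(float(sp.get("initialConcentration", "0")))

    parameters = {
        p.get("id"): float(p.get("value"))
        for p in model.findall(f"{s}listOfParameters/{s}parameter")
    }

    reactions = []
    for rx in model.findall(f"{s}listOfReactions/{s}reaction"):
        stoich: dict = {}
        for ref in rx.findall(f"{s}listOfReactants/{s}speciesReference"):
            sp = ref.get("species")
            stoich[sp] = stoich.get(sp, 0.0) - float(ref.get("stoichiometry", "1"))
        for ref in rx.findall(f"{s}listOfProducts/{s}speciesReference"):
            sp = ref.get("species")
            stoich[sp] = stoich.get(sp, 0.0) + float(ref.get("stoichiometry", "1"))
        math = rx.find(f"{s}kineticLaw/{{{MATHML_NS}}}math")
        if math is None:
            raise ConfigurationError(f"reaction {rx.get('id')} has no kinetic law")
        reactions.append((rx.get("id"), stoich, _parse_math(math)))

    return SbmlModel(model.get("id", ""), species, np.asarray(initial, float),
                     parameters, reactions)


def simulate_sbml(source, t_end: float = 10.0, grid=None,
                  rtol: float = 1e-10, atol: float = 1e-12):
    """Integrate a re-imported document; returns (times, state matrix,
    species ids) with one column per species."""
    from scipy.integrate import solve_ivp

    sbml_model = source if isinstance(source, SbmlModel) else parse_sbml(source)
    if grid is None:
        grid = np.linspace(0.0, t_end, 201)
    grid = np.asarray(grid, float)
    sol = solve_ivp(sbml_model.rhs, (float(grid[0]), float(grid[-1])),
                    sbml_model.initial, method="LSODA", t_eval=grid,
                    rtol=rtol, atol=atol)
    if not sol.success:
        raise ConfigurationError(f"SBML simulation failed: {sol.message}")
    return sol.t, sol.y.T, sbml_model.species
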