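"""Reading and writing metabolic network models.

Two formats are supported:

* **SBML Level 3 + FBC** (also legacy Level 2 with kinetic-law bound
  parameters and notes-field ``GENE_ASSOCIATION`` strings), read through
  python-libsbml.  By default the loader applies *cone semantics*: finite
  flux bounds are used only for orientation.  A reaction with lower bound
  >= 0 is irreversible; a reaction with upper bound <= 0 is flipped
  (column negated, marked irreversible) so that "irreversible backward"
  reactions are representable; bound magnitudes are otherwise discarded,
  because the steady-state flux cone carries no finite bounds.  The
  original (orientation-adjusted) bounds are kept on the network for the
  optional bound-honoring LP mode.
* **A JSON dialect** (schema below) used for fixtures and round-tripping::

      {
        "metabolites": ["A", ...],
        "reactions": [
          {"id": "r1", "stoich": {"A": -1.0, ...},
           "reversible": true, "gpr": "g1 or g2",        # gpr optional
           "lower_bound": -10.0, "upper_bound": 10.0}    # bounds optional
        ],
        "genes": ["g1", ...]
      }
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

from .network import GeneRule, MetabolicNetwork, parse_gene_rule

__all__ = ["load_network", "load_json", "load_sbml", "save_json"]

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """The file could not be parsed in the requested format."""


def load_network(path, format: str = "auto") -> MetabolicNetwork:
    """Load a network from SBML or the JSON dialect.

    ``format="auto"`` dispatches on the file extension (``.json`` vs
    anything else, which is treated as SBML; ``.gz``-compressed SBML is
    handled by libsbml).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "auto":
        format = "json" if path.suffix.lower() == ".json" else "sbml"
    if format == "json":
        return load_json(path)
    if format == "sbml":
        return load_sbml(path)
    raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# JSON dialect
# ---------------------------------------------------------------------------


def load_json(path) -> MetabolicNetwork:
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise FormatError(f"invalid JSON in {path}: {exc}") from exc
    try:
        metabolites = tuple(doc["metabolites"])
        reactions_doc = doc["reactions"]
    except (KeyError, TypeError) as exc:
        raise FormatError(f"missing required key in {path}: {exc}") from exc
    genes = set(doc.get("genes", []))
    reactions, stoich, irreversible, gpr, bounds = [], {}, set(), {}, {}
    for rx in reactions_doc:
        rid = rx["id"]
        reactions.append(rid)
        for m, c in rx.get("stoich", {}).items():
            stoich[(m, rid)] = float(c)
        if not rx.get("reversible", False):
            irreversible.add(rid)
        rule_text = rx.get("gpr")
        if rule_text:
            rule = parse_gene_rule(rule_text)
            undeclared = rule.genes() - genes
            if undeclared:
                warnings.warn(
                    f"GPR of {rid!r} references undeclared genes "
                    f"{sorted(undeclared)}; declaring them",
                    stacklevel=2,
                )
                genes |= undeclared
            gpr[rid] = rule
        if "lower_bound" in rx or "upper_bound" in rx:
            bounds[rid] = (
                float(rx.get("lower_bound", float("-inf"))),
                float(rx.get("upper_bound", float("inf"))),
            )
    return MetabolicNetwork(
        metabolites=metabolites,
        reactions=tuple(reactions),
        stoich=stoich,
        irreversible=frozenset(irreversible),
        genes=frozenset(genes),
        gpr=gpr,
        bounds=bounds or None,
    )


def save_json(net: MetabolicNetwork, path) -> None:
    """Serialize to the JSON dialect (inverse of :func:`load_json`)."""
    reactions = []
    for r in net.reactions:
        rx: dict = {
            "id": r,
            "stoich": {
                m: c for (m, rr), c in sorted(net.stoich.items()) if rr == r and c != 0.0
            },
            "reversible": r not in net.irreversible,
        }
        if r in net.gpr:
            rx["gpr"] = str(net.gpr[r])
        if net.bounds and r in net.bounds:
            rx["lower_bound"], rx["upper_bound"] = net.bounds[r]
        reactions.append(rx)
    doc = {
        "metabolites": list(net.metabolites),
        "reactions": reactions,
        "genes": sorted(net.genes),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


# ---------------------------------------------------------------------------
# SBML
# ---------------------------------------------------------------------------


def load_sbml(path) -> MetabolicNetwork:
    import libsbml

    doc = libsbml.readSBML(str(path))
    if doc.getModel() is None or doc.getNumErrors() > 0 and any(
        doc.getError(i).getSeverity() >= libsbml.LIBSBML_SEV_ERROR
        for i in range(doc.getNumErrors())
    ):
        raise FormatError(f"libsbml could not parse {path}")
    model = doc.getModel()
    fbc = model.getPlugin("fbc")

    metabolites = tuple(
        model.getSpecies(i).getId() for i in range(model.getNumSpecies())
    )

    gene_names: dict[str, str] = {}
    if fbc is not None:
        for i in range(fbc.getNumGeneProducts()):
            gp = fbc.getGeneProduct(i)
            gene_names[gp.getId()] = gp.getLabel() or gp.getId()

    reactions, stoich, irreversible, gpr, bounds = [], {}, set(), {}, {}
    genes: set[str] = set()
    flipped: list[str] = []
    for i in range(model.getNumReactions()):
        rx = model.getReaction(i)
        rid = rx.getId()
        reactions.append(rid)
        col: dict[str, float] = {}
        for j in range(rx.getNumReactants()):
            sr = rx.getReactant(j)
            col[sr.getSpecies()] = col.get(sr.getSpecies(), 0.0) - sr.getStoichiometry()
        for j in range(rx.getNumProducts()):
            sr = rx.getProduct(j)
            col[sr.getSpecies()] = col.get(sr.getSpecies(), 0.0) + sr.getStoichiometry()

        lb, ub = _reaction_bounds(model, rx)
        if ub <= 0.0:
            # irreversible backward: re-orient the column
            col = {m: -c for m, c in col.items()}
            lb, ub = -ub, -lb
            irreversible.add(rid)
            flipped.append(rid)
        elif lb >= 0.0:
            irreversible.add(rid)
        bounds[rid] = (lb, ub)
        for m, c in col.items():
            if c != 0.0:
                stoich[(m, rid)] = c

        rule = _gene_rule(rx, gene_names)
        if rule is not None:
            genes |= rule.genes()
            gpr[rid] = rule
    if flipped:
        logger.info("re-oriented %d backward-only reactions: %s", len(flipped), flipped)

    return MetabolicNetwork(
        metabolites=metabolites,
        reactions=tuple(reactions),
        stoich=stoich,
        irreversible=frozenset(irreversible),
        genes=frozenset(genes),
        gpr=gpr,
        bounds=bounds,
    )


def _reaction_bounds(model, rx) -> tuple[float, float]:
    import libsbml  # noqa: F401

    rfbc = rx.getPlugin("fbc")
    lb = ub = None
    if rfbc is not None:
        lb_id, ub_id = rfbc.getLowerFluxBound(), rfbc.getUpperFluxBound()
        if lb_id:
            p = model.getParameter(lb_id)
            lb = p.getValue() if p is not None else None
        if ub_id:
            p = model.getParameter(ub_id)
            ub = p.getValue() if p is not None else None
    if lb is None or ub is None:
        kl = rx.getKineticLaw()
        if kl is not None:
            for name, setter in (("LOWER_BOUND", "lb"), ("UPPER_BOUND", "ub")):
                p = kl.getParameter(name)
                if p is not None:
                    if setter == "lb" and lb is None:
                        lb = p.getValue()
                    elif setter == "ub" and ub is None:
                        ub = p.getValue()
    if lb is None:
        lb = float("-inf") if rx.getReversible() else 0.0
    if ub is None:
        ub = float("inf")
    return float(lb), float(ub)


def _gene_rule(rx, gene_names: dict[str, str]) -> GeneRule | None:
    from .network import And, Gene, Or

    rfbc = rx.getPlugin("fbc")
    if rfbc is not None and rfbc.isSetGeneProductAssociation():
        assoc = rfbc.getGeneProductAssociation().getAssociation()
        return _convert_association(assoc, gene_names)
    # legacy: notes field GENE_ASSOCIATION
    notes = rx.getNotesString() if rx.isSetNotes() else ""
    for line in notes.splitlines():
        if "GENE_ASSOCIATION" in line:
            text = line.split(":", 1)[-1]
            for tag in ("</p>", "</body>", "</html>", "</notes>"):
                text = text.replace(tag, " ")
            text = text.strip()
            if text:
                return parse_gene_rule(text)
    return None


def _convert_association(assoc, gene_names: dict[str, str]) -> GeneRule:
    import libsbml

    from .network import And, Gene, Or

    if isinstance(assoc, libsbml.GeneProductRef):
        gp = assoc.getGeneProduct()
        return Gene(gene_names.get(gp, gp))
    if isinstance(assoc, libsbml.FbcAnd):
        return And(
            tuple(
                _convert_association(assoc.getAssociation(i), gene_names)
                for i in range(assoc.getNumAssociations())
            )
        )
    if isinstance(assoc, libsbml.FbcOr):
        return Or(
            tuple(
                _convert_association(assoc.getAssociation(i), gene_names)
                for i in range(assoc.getNumAssociations())
            )
        )
    raise FormatError(f"unsupported gene association node {type(assoc).__name__}")
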