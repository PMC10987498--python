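"""Gene regulatory mechanism (GRM) data model.

A GRM is a directed regulatory network: input morphogen genes whose
concentration fields are fixed exponential gradients, intermediate genes,
and one or more reporter genes whose spatial expression is the output
pattern.  Every gene carries kinetic constants (production, decay,
diffusion); every regulation carries a sign (positive / negative), a
grouping (necessary / sufficient, meaningful for positive regulations
only), a Hill coefficient and a binding constant.

This module defines the immutable-ish dataclasses, structural validation,
the network complexity measure (links + 3 * genes), JSON serialization
with a versioned schema, and Graphviz DOT export.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "GeneSpec",
    "RegulationSpec",
    "GRM",
    "GRMValidationError",
    "GRMParseError",
    "validate",
    "basal_level",
    "complexity",
    "serialize",
    "deserialize",
    "to_json",
    "from_json",
    "to_dot",
    "HILL_RANGE",
    "BIND_RANGE",
    "DECAY_RANGE",
    "PRODUCTION_RANGE",
]

SCHEMA_VERSION = 1

#: Parameter ranges used both by validation and by the mutation operator.
HILL_RANGE = (1.0, 10.0)
BIND_RANGE = (1.0, 100.0)
DECAY_RANGE = (0.1, 1.0)
PRODUCTION_RANGE = (0.0, 0.1)

ROLES = ("input", "intermediate", "reporter")
SIGNS = ("positive", "negative")
GROUPINGS = ("necessary", "sufficient")
ORIENTATIONS = ("from_left", "from_top", "from_right", "from_bottom")


class GRMValidationError(ValueError):
    """Raised when a GRM violates its structural invariants.

    Carries the full list of violation messages in ``violations``.
    """

    def __init__(self, violations: list[str]):
        self.violations = list(violations)
        super().__init__("; ".join(self.violations))


class GRMParseError(ValueError):
    """Raised for malformed GRM files (missing/ill-typed fields)."""


@dataclass
class GeneSpec:
    """A single gene and its kinetic constants.

    Parameters
    ----------
    name : str
        Unique identifier within the GRM.
    role : {"input", "intermediate", "reporter"}
    production : float
        Maximum production rate rho >= 0 (concentration / time).  Fixed
        to 0 for input genes, whose fields are analytic gradients.
    decay : float
        First-order decay constant lambda >= 0 (1 / time).
    diffusion : float
        Diffusion constant D >= 0 (area / time); zero throughout this
        work (products are confined intracellularly).
    orientation : str, optional
        For input genes only: which domain edge sources the gradient
        ("from_left", "from_top", "from_right", "from_bottom").
    gradient_decay : float
        For input genes only: per-cell exponential decay base d of the
        gradient (default 0.93).
    """

    name: str
    role: str
    production: float = 0.0
    decay: float = 0.0
    diffusion: float = 0.0
    orientation: str | None = None
    gradient_decay: float = 0.93


@dataclass
class RegulationSpec:
    """One regulatory interaction source -> target.

    ``grouping`` distinguishes necessary (AND) from sufficient (OR)
    combination of positive regulations; negative regulations always
    combine multiplicatively, so their grouping is fixed to "necessary".
    ``hill_coeff`` (eta) sets the sharpness of the Hill response and
    ``bind_const`` (K) its concentration threshold (term (K*c)**eta).
    """

    source: str
    target: str
    sign: str
    grouping: str = "necessary"
    hill_coeff: float = 1.0
    bind_const: float = 1.0


@dataclass
class GRM:
    """A complete gene regulatory mechanism.

    ``reporter_bindings`` maps each reporter gene name to the index of
    the target-pattern channel it is scored against.
    """

    genes: list[GeneSpec] = field(default_factory=list)
    regulations: list[RegulationSpec] = field(default_factory=list)
    reporter_bindings: dict[str, int] = field(default_factory=dict)

    # -- convenience accessors -------------------------------------------
    def gene(self, name: str) -> GeneSpec:
        for g in self.genes:
            if g.name == name:
                return g
        raise KeyError(name)

    def gene_names(self) -> list[str]:
        return [g.name for g in self.genes]

    @property
    def inputs(self) -> list[GeneSpec]:
        return [g for g in self.genes if g.role == "input"]

    @property
    def intermediates(self) -> list[GeneSpec]:
        return [g for g in self.genes if g.role == "intermediate"]

    @property
    def reporters(self) -> list[GeneSpec]:
        return [g for g in self.genes if g.role == "reporter"]

    def incoming(self, name: str) -> list[RegulationSpec]:
        return [r for r in self.regulations if r.target == name]

    def outgoing(self, name: str) -> list[RegulationSpec]:
        return [r for r in self.regulations if r.source == name]

    def copy(self) -> "GRM":
        # field-wise reconstruction: ~10x faster than deepcopy and all
        # fields are immutable scalars/strings
        return GRM(
            genes=[
                GeneSpec(g.name, g.role, g.production, g.decay, g.diffusion,
                         g.orientation, g.gradient_decay)
                for g in self.genes
            ],
            regulations=[
                RegulationSpec(r.source, r.target, r.sign, r.grouping,
                               r.hill_coeff, r.bind_const)
                for r in self.regulations
            ],
            reporter_bindings=dict(self.reporter_bindings),
        )


def basal_level(gene: GeneSpec, regulations: Iterable[RegulationSpec]) -> int:
    """Derived basal expression level of a non-input gene.

    0 if the gene receives at least one positive regulation, otherwise 1
    (a constitutive promoter that can only be inhibited).
    """
    if gene.role == "input":
        raise ValueError(
            f"input gene {gene.name!r} has no rate law, hence no basal level"
        )
    for r in regulations:
        if r.target == gene.name and r.sign == "positive":
            return 0
    return 1


def validate(grm: GRM) -> list[str]:
    """Check all structural invariants; return a list of violations.

    An empty list means the GRM is valid.  Each message names the
    offending gene or regulation.
    """
    v: list[str] = []
    names = grm.gene_names()
    seen: set[str] = set()
    for n in names:
        if n in seen:
            v.append(f"duplicate gene name {n!r}")
        seen.add(n)

    roles = {g.name: g.role for g in grm.genes}
    for g in grm.genes:
        if g.role not in ROLES:
            v.append(f"gene {g.name!r}: unknown role {g.role!r}")
        if g.production < 0:
            v.append(f"gene {g.name!r}: production {g.production} < 0")
        if g.decay < 0:
            v.append(f"gene {g.name!r}: decay {g.decay} < 0")
        if g.diffusion < 0:
            v.append(f"gene {g.name!r}: diffusion {g.diffusion} < 0")
        if g.role == "input":
            if g.production != 0:
                v.append(f"input gene {g.name!r}: production must be 0")
            if g.orientation not in ORIENTATIONS:
                v.append(
                    f"input gene {g.name!r}: orientation {g.orientation!r} "
                    f"not one of {ORIENTATIONS}"
                )
            if not 0.0 < g.gradient_decay < 1.0:
                v.append(
                    f"input gene {g.name!r}: gradient_decay "
                    f"{g.gradient_decay} outside (0, 1)"
                )

    if not grm.inputs:
        v.append("GRM has no input gene")
    if not grm.reporters:
        v.append("GRM has no reporter gene")

    pairs: set[tuple[str, str]] = set()
    for r in grm.regulations:
        edge = f"regulation {r.source!r}->{r.target!r}"
        if r.source not in roles:
            v.append(f"{edge}: unknown source gene")
            continue
        if r.target not in roles:
            v.append(f"{edge}: unknown target gene")
            continue
        if (r.source, r.target) in pairs:
            v.append(f"{edge}: duplicate regulation for this gene pair")
        pairs.add((r.source, r.target))
        if roles[r.source] == "reporter":
            v.append(f"{edge}: reporter gene cannot regulate other genes")
        if roles[r.target] == "input":
            v.append(f"{edge}: input gene cannot be regulated")
        if r.sign not in SIGNS:
            v.append(f"{edge}: unknown sign {r.sign!r}")
        if r.grouping not in GROUPINGS:
            v.append(f"{edge}: unknown grouping {r.grouping!r}")
        if r.sign == "negative" and r.grouping != "necessary":
            v.append(f"{edge}: negative regulations are always 'necessary'")
        if not HILL_RANGE[0] <= r.hill_coeff <= HILL_RANGE[1]:
            v.append(f"{edge}: hill_coeff {r.hill_coeff} outside {HILL_RANGE}")
        if not BIND_RANGE[0] <= r.bind_const <= BIND_RANGE[1]:
            v.append(f"{edge}: bind_const {r.bind_const} outside {BIND_RANGE}")

    for rep in grm.reporter_bindings:
        if rep not in roles:
            v.append(f"reporter binding for unknown gene {rep!r}")
        elif roles[rep] != "reporter":
            v.append(f"reporter binding for non-reporter gene {rep!r}")
    return v


def complexity(grm: GRM) -> int:
    """Network complexity: number of links plus three times the number of
    genes (all nodes counted, inputs and reporters included)."""
    return len(grm.regulations) + 3 * len(grm.genes)


# -- serialization -------------------------------------------------------

_GENE_FIELDS = {
    "name": str,
    "role": str,
    "production": (int, float),
    "decay": (int, float),
    "diffusion": (int, float),
}


def serialize(grm: GRM) -> dict:
    """GRM -> plain-JSON dict (schema version tag included)."""
    genes = []
    for g in grm.genes:
        d = {
            "name": g.name,
            "role": g.role,
            "production": g.production,
            "decay": g.decay,
            "diffusion": g.diffusion,
        }
        if g.role == "input":
            d["orientation"] = g.orientation
            d["gradient_decay"] = g.gradient_decay
        genes.append(d)
    regs = [
        {
            "source": r.source,
            "target": r.target,
            "sign": r.sign,
            "grouping": r.grouping,
            "hill_coeff": r.hill_coeff,
            "bind_const": r.bind_const,
        }
        for r in grm.regulations
    ]
    return {
        "version": SCHEMA_VERSION,
        "genes": genes,
        "regulations": regs,
        "reporter_bindings": dict(grm.reporter_bindings),
    }


def deserialize(data: Mapping) -> GRM:
    """Plain dict -> GRM, with field-level parse errors and full
    structural validation (raises GRMValidationError on violations)."""
    if not isinstance(data, Mapping):
        raise GRMParseError("GRM document must be a JSON object")
    if data.get("version") != SCHEMA_VERSION:
        raise GRMParseError(
            f"unsupported or missing schema version {data.get('version')!r}"
        )
    genes = []
    for i, gd in enumerate(data.get("genes", [])):
        for f, typ in _GENE_FIELDS.items():
            if f not in gd:
                raise GRMParseError(f"genes[{i}]: missing field {f!r}")
            if not isinstance(gd[f], typ) or isinstance(gd[f], bool):
                raise GRMParseError(f"genes[{i}].{f}: wrong type")
        kwargs = {f: gd[f] for f in _GENE_FIELDS}
        if gd["role"] == "input":
            kwargs["orientation"] = gd.get("orientation")
            kwargs["gradient_decay"] = gd.get("gradient_decay", 0.93)
        genes.append(GeneSpec(**kwargs))
    regs = []
    for i, rd in enumerate(data.get("regulations", [])):
        for f in ("source", "target", "sign", "grouping", "hill_coeff", "bind_const"):
            if f not in rd:
                raise GRMParseError(f"regulations[{i}]: missing field {f!r}")
        regs.append(
            RegulationSpec(
                source=rd["source"],
                target=rd["target"],
                sign=rd["sign"],
                grouping=rd["grouping"],
                hill_coeff=float(rd["hill_coeff"]),
                bind_const=float(rd["bind_const"]),
            )
        )
    bindings = data.get("reporter_bindings", {})
    if not isinstance(bindings, Mapping):
        raise GRMParseError("reporter_bindings: must be an object")
    grm = GRM(genes=genes, regulations=regs,
              reporter_bindings={str(k): int(x) for k, x in bindings.items()})
    violations = validate(grm)
    if violations:
        raise GRMValidationError(violations)
    return grm


def to_json(grm: GRM, path=None) -> str:
    """Serialize to a JSON string (and optionally write it to ``path``).

    Floats round-trip bit-exactly through Python's repr-based JSON
    encoding.
    """
    text = json.dumps(serialize(grm), indent=2)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text + "\n")
    return text


def from_json(source) -> GRM:
    """Load a GRM from a JSON string or a file path."""
    text = source
    if hasattr(source, "read"):
        text = source.read()
    elif isinstance(source, str) and "{" not in source:
        with open(source) as fh:
            text = fh.read()
    elif not isinstance(source, str):
        with open(source) as fh:
            text = fh.read()
    try:
        data = json.loads(text)
    except json.JSONDecodeError as exc:
        raise GRMParseError(f"invalid JSON: {exc}") from exc
    return deserialize(data)


def to_dot(grm: GRM) -> str:
    """Graphviz DOT export.

    Point arrowheads mark positive regulations, tee arrowheads negative
    ones; dashed edges are sufficient, solid edges necessary.
    """
    colors = {"input": "lightcoral", "intermediate": "lightgray",
              "reporter": "lightblue"}
    lines = ["digraph GRM {", "  rankdir=LR;"]
    for g in grm.genes:
        lines.append(
            f'  "{g.name}" [shape=circle style=filled '
            f'fillcolor={colors.get(g.role, "white")}];'
        )
    for r in grm.regulations:
        head = "normal" if r.sign == "positive" else "tee"
        style = "dashed" if r.grouping == "sufficient" else "solid"
        lines.append(
            f'  "{r.source}" -> "{r.target}" '
            f"[arrowhead={head} style={style}];"
        )
    lines.append("}")
    return "\n".join(lines) + "\n"
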