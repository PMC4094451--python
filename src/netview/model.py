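"""Domain types and a versioned JSON document format for rule-based reaction models.

The modelling language follows the contact-map tradition of rule-based
frameworks: *molecules* are built from *components* (sub-domains) that carry
binding sites and tri-state state variables; a *complex species* is a
structural prototype (a fixed multiset of molecule instances connected by
bonds); a *complex* is an instance of its species with a concrete tri-state
assignment for every declared state variable; *reaction rules* rewrite
complexes and fall into exactly three categories — association (2 reactants,
1 product, forms a bond), dissociation (1 reactant, 2 products, dissolves a
bond) and transformation (1 reactant, 1 product, state change only, no
binding sites involved).

The on-disk format is versioned JSON (YAML is accepted as a reading dialect);
a draft-07 style schema describing it ships under ``netview/schema``.
Validation is complete rather than fail-fast: :func:`validate_model` returns
*every* violation as data, each with a machine-readable code and the path of
the offending entity.
"""

from __future__ import annotations

import io
import json
import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Any, Iterable, Mapping, Optional, Sequence, Union

import yaml

logger = logging.getLogger(__name__)

FORMAT_VERSION = "1.0"

StateKey = tuple[str, str, str]  # (instance_id, component_name, state_variable)


# ---------------------------------------------------------------------------
# errors


class NetviewError(Exception):
    """Base class for all errors raised by this package."""


class ModelFormatError(NetviewError):
    """Raised when a model document is not well-formed JSON/YAML.

    Carries ``line`` and ``column`` (1-based) when the underlying parser
    reports a position.
    """

    def __init__(self, message: str, line: int | None = None, column: int | None = None):
        self.line = line
        self.column = column
        if line is not None:
            message = f"{message} (line {line}, column {column})"
        super().__init__(message)


class ModelSchemaError(NetviewError):
    """Structural schema violation; ``paths`` holds JSON-pointer locations."""

    def __init__(self, errors: Sequence[tuple[str, str]]):
        self.paths = [p for p, _ in errors]
        self.errors = list(errors)
        detail = "; ".join(f"{p}: {m}" for p, m in errors)
        super().__init__(f"model document violates schema: {detail}")


class ModelReferenceError(NetviewError):
    """A cross-reference names an entity that does not exist."""

    def __init__(self, violations: Sequence["Violation"]):
        self.violations = list(violations)
        detail = "; ".join(str(v) for v in violations)
        super().__init__(f"dangling reference(s): {detail}")


class InvalidModelError(NetviewError):
    """Operation refused because the model fails validation."""

    def __init__(self, violations: Sequence["Violation"]):
        self.violations = list(violations)
        detail = "; ".join(str(v) for v in violations)
        super().__init__(f"invalid model: {detail}")


class NotFoundError(NetviewError, LookupError):
    """Lookup of a named entity (species, complex, rule, site) failed."""


# ---------------------------------------------------------------------------
# enums


class TriState(Enum):
    """Three-valued state of a component state variable.

    ON/OFF are concrete biochemical states (e.g. phosphorylated or not);
    DONT_CARE is the wildcard used by rule patterns and searches.
    """

    ON = "on"
    OFF = "off"
    DONT_CARE = "dont_care"

    @classmethod
    def from_string(cls, text: str) -> "TriState":
        try:
            return cls(text)
        except ValueError:
            raise ValueError(
                f"invalid tri-state value {text!r}; expected 'on', 'off' or 'dont_care'"
            ) from None


class RuleCategory(Enum):
    ASSOCIATION = "association"
    DISSOCIATION = "dissociation"
    TRANSFORMATION = "transformation"


#: (number of reactants, number of products) required per category.
CATEGORY_ARITY: dict[RuleCategory, tuple[int, int]] = {
    RuleCategory.ASSOCIATION: (2, 1),
    RuleCategory.DISSOCIATION: (1, 2),
    RuleCategory.TRANSFORMATION: (1, 1),
}


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class Component:
    """A molecule sub-domain carrying state variables and binding sites."""

    name: str
    state_variables: tuple[str, ...] = ()
    binding_sites: tuple[str, ...] = ()


@dataclass(frozen=True)
class Molecule:
    name: str
    components: tuple[Component, ...] = ()


@dataclass(frozen=True)
class BindingSiteRef:
    """A binding site addressed by species name and 1-based site index.

    Site indices are assigned per species in declaration order across its
    molecule instances and their components.
    """

    species_name: str
    site_index: int


@dataclass(frozen=True)
class SiteInfo:
    """Resolved description of one binding site of a complex species."""

    index: int  # 1-based, species-wide
    instance_id: str
    molecule_name: str
    component_name: str
    site_name: str


@dataclass
class Complex:
    """An instance of a complex species: a total tri-state assignment.

    ``state_map`` maps ``(instance_id, component, state_variable)`` to a
    :class:`TriState` and must cover exactly the variables declared by the
    species' molecules. Rule-side complexes are patterns and may use
    DONT_CARE.
    """

    name: str
    species_name: str
    state_map: dict[StateKey, TriState] = field(default_factory=dict)


@dataclass
class ComplexSpecies:
    """Structural prototype for a set of structurally identical complexes."""

    name: str
    molecule_instances: tuple[tuple[str, str], ...] = ()  # (instance_id, molecule_name)
    structural_bonds: tuple[tuple[int, int], ...] = ()  # unordered site-index pairs
    complexes: tuple[Complex, ...] = ()


@dataclass
class ReactionRule:
    """A categorized rewrite of declared complexes.

    ``bond_sites`` holds the two binding sites whose bond is formed
    (association: one site per reactant species) or dissolved (dissociation:
    both sites in the reactant species); transformations never carry bond
    sites. ``rate_constant`` is stored but never integrated.
    """

    name: str
    category: RuleCategory
    reactants: tuple[tuple[str, str], ...] = ()  # (species_name, complex_name)
    products: tuple[tuple[str, str], ...] = ()
    bond_sites: Optional[tuple[BindingSiteRef, BindingSiteRef]] = None
    rate_constant: float = 1.0


@dataclass
class Model:
    """Container for molecules, complex species and reaction rules."""

    format_version: str = FORMAT_VERSION
    molecules: tuple[Molecule, ...] = ()
    species: tuple[ComplexSpecies, ...] = ()
    rules: tuple[ReactionRule, ...] = ()
    metadata: dict[str, Any] = field(default_factory=dict)

    # -- lookups ---------------------------------------------------------

    def molecule(self, name: str) -> Molecule:
        for m in self.molecules:
            if m.name == name:
                return m
        raise NotFoundError(f"no molecule named {name!r}")

    def species_by_name(self, name: str) -> ComplexSpecies:
        for s in self.species:
            if s.name == name:
                return s
        raise NotFoundError(f"no complex species named {name!r}")

    def rule(self, name: str) -> ReactionRule:
        for r in self.rules:
            if r.name == name:
                return r
        raise NotFoundError(f"no reaction rule named {name!r}")

    def complex(self, species_name: str, complex_name: str) -> Complex:
        sp = self.species_by_name(species_name)
        for c in sp.complexes:
            if c.name == complex_name:
                return c
        raise NotFoundError(
            f"species {species_name!r} has no complex named {complex_name!r}"
        )

    def site_table(self, species_name: str) -> tuple[SiteInfo, ...]:
        """All binding sites of a species, indexed 1..N in declaration order."""
        sp = self.species_by_name(species_name)
        table: list[SiteInfo] = []
        idx = 0
        for instance_id, mol_name in sp.molecule_instances:
            mol = self.molecule(mol_name)
            for comp in mol.components:
                for site_name in comp.binding_sites:
                    idx += 1
                    table.append(
                        SiteInfo(idx, instance_id, mol_name, comp.name, site_name)
                    )
        return tuple(table)

    def site_count(self, species_name: str) -> int:
        return len(self.site_table(species_name))

    def state_keys(self, species_name: str) -> tuple[StateKey, ...]:
        """All state-variable keys a complex of this species must assign."""
        sp = self.species_by_name(species_name)
        keys: list[StateKey] = []
        for instance_id, mol_name in sp.molecule_instances:
            mol = self.molecule(mol_name)
            for comp in mol.components:
                for var in comp.state_variables:
                    keys.append((instance_id, comp.name, var))
        return tuple(keys)

    # -- equality via canonical form -------------------------------------

    def canonical_dict(self) -> dict[str, Any]:
        """Order-insensitive canonical representation (entities sorted by name)."""
        return _to_document(self, canonical=True)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Model):
            return NotImplemented
        return self.canonical_dict() == other.canonical_dict()


def species_contains_molecule(species: ComplexSpecies, molecule_name: str) -> bool:
    """True iff the species' structure includes the named molecule.

    Complexes inherit this answer from their species: a complex contains a
    molecule exactly when its species does, because all complexes of a
    species are structurally identical. Unknown names simply yield False.
    """
    return any(mol == molecule_name for _, mol in species.molecule_instances)


# ---------------------------------------------------------------------------
# validation


@dataclass(frozen=True)
class Violation:
    """One invariant violation; ``severity`` is 'error' or 'warning'."""

    code: str
    path: str
    message: str
    severity: str = "error"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.code}] {self.path}: {self.message}"


def validate_model(model: Model) -> list[Violation]:
    """Check every model invariant; returns all violations, not just the first.

    A model is valid when no returned violation has severity 'error';
    warnings (e.g. duplicate state maps within a species) do not invalidate.
    """
    out: list[Violation] = []

    def err(code: str, path: str, message: str, severity: str = "error") -> None:
        out.append(Violation(code, path, message, severity))

    # molecule-level uniqueness
    seen_mol: set[str] = set()
    for i, mol in enumerate(model.molecules):
        path = f"/molecules/{i}"
        if mol.name in seen_mol:
            err("DUP_NAME", path, f"duplicate molecule name {mol.name!r}")
        seen_mol.add(mol.name)
        seen_comp: set[str] = set()
        for j, comp in enumerate(mol.components):
            cpath = f"{path}/components/{j}"
            if comp.name in seen_comp:
                err("DUP_NAME", cpath, f"duplicate component name {comp.name!r}")
            seen_comp.add(comp.name)
            if len(set(comp.state_variables)) != len(comp.state_variables):
                err("DUP_NAME", cpath, "duplicate state-variable names")
            if len(set(comp.binding_sites)) != len(comp.binding_sites):
                err("DUP_NAME", cpath, "duplicate binding-site names")

    # species level
    seen_sp: set[str] = set()
    for i, sp in enumerate(model.species):
        path = f"/species/{i}"
        if sp.name in seen_sp:
            err("DUP_NAME", path, f"duplicate species name {sp.name!r}")
        seen_sp.add(sp.name)

        seen_inst: set[str] = set()
        resolvable = True
        for j, (inst, mol_name) in enumerate(sp.molecule_instances):
            if inst in seen_inst:
                err("DUP_NAME", f"{path}/molecule_instances/{j}",
                    f"duplicate instance id {inst!r}")
            seen_inst.add(inst)
            if mol_name not in seen_mol:
                err("DANGLING_REF", f"{path}/molecule_instances/{j}",
                    f"unknown molecule {mol_name!r}")
                resolvable = False
        if not resolvable:
            continue  # site table / state keys undefined for this species

        n_sites = model.site_count(sp.name)
        used_sites: set[int] = set()
        for j, bond in enumerate(sp.structural_bonds):
            bpath = f"{path}/bonds/{j}"
            for s in bond:
                if not (1 <= s <= n_sites):
                    err("SITE_INDEX", bpath,
                        f"site index {s} out of range 1..{n_sites}")
                elif s in used_sites:
                    err("BOND_SITE_REUSE", bpath,
                        f"site {s} appears in more than one bond")
                else:
                    used_sites.add(s)
            if bond[0] == bond[1]:
                err("SITE_INDEX", bpath, "bond joins a site with itself")

        declared = set(model.state_keys(sp.name))
        seen_cx: set[str] = set()
        state_fingerprints: dict[tuple, str] = {}
        for j, cx in enumerate(sp.complexes):
            cpath = f"{path}/complexes/{j}"
            if cx.name in seen_cx:
                err("DUP_NAME", cpath, f"duplicate complex name {cx.name!r}")
            seen_cx.add(cx.name)
            if cx.species_name != sp.name:
                err("DANGLING_REF", cpath,
                    f"complex {cx.name!r} claims species {cx.species_name!r}")
            got = set(cx.state_map)
            missing = declared - got
            extra = got - declared
            if missing or extra:
                parts = []
                if missing:
                    parts.append(f"missing {sorted(missing)}")
                if extra:
                    parts.append(f"undeclared {sorted(extra)}")
                err("STATE_COVERAGE", cpath,
                    f"state map must cover declared variables exactly: {'; '.join(parts)}")
            fp = tuple(sorted((k, v.value) for k, v in cx.state_map.items()))
            if fp in state_fingerprints:
                err("DUP_STATE_MAP", cpath,
                    f"complex {cx.name!r} has the same state map as "
                    f"{state_fingerprints[fp]!r}", severity="warning")
            else:
                state_fingerprints[fp] = cx.name

    # rule level
    complexes_by_species: dict[str, set[str]] = {
        sp.name: {c.name for c in sp.complexes} for sp in model.species
    }
    seen_rule: set[str] = set()
    for i, rule in enumerate(model.rules):
        path = f"/rules/{i}"
        if rule.name in seen_rule:
            err("DUP_NAME", path, f"duplicate rule name {rule.name!r}")
        seen_rule.add(rule.name)

        want = CATEGORY_ARITY[rule.category]
        have = (len(rule.reactants), len(rule.products))
        if want != have:
            err("ARITY", path,
                f"{rule.category.value} requires {want[0]} reactant(s) and "
                f"{want[1]} product(s), got {have[0]}/{have[1]}")

        for side, refs in (("reactants", rule.reactants), ("products", rule.products)):
            for j, (sp_name, cx_name) in enumerate(refs):
                rpath = f"{path}/{side}/{j}"
                if sp_name not in complexes_by_species:
                    err("DANGLING_REF", rpath, f"unknown species {sp_name!r}")
                elif cx_name not in complexes_by_species[sp_name]:
                    err("DANGLING_REF", rpath,
                        f"species {sp_name!r} has no complex {cx_name!r}")

        if rule.category is RuleCategory.TRANSFORMATION:
            if rule.bond_sites is not None:
                err("BOND_ON_TRANSFORM", path,
                    "complex transformations do not involve any binding sites")
        elif rule.bond_sites is not None:
            reactant_species = [sp for sp, _ in rule.reactants]
            for j, ref in enumerate(rule.bond_sites):
                bpath = f"{path}/bond_sites/{j}"
                if ref.species_name not in complexes_by_species:
                    err("DANGLING_REF", bpath,
                        f"unknown species {ref.species_name!r}")
                    continue
                n_sites = model.site_count(ref.species_name)
                if not (1 <= ref.site_index <= n_sites):
                    err("SITE_INDEX", bpath,
                        f"site index {ref.site_index} out of range 1..{n_sites} "
                        f"for species {ref.species_name!r}")
                if ref.species_name not in reactant_species:
                    err("BOND_SITE_SPECIES", bpath,
                        f"bond site names species {ref.species_name!r} which is "
                        f"not a reactant of rule {rule.name!r}")

        if rule.rate_constant < 0:
            err("NEGATIVE_RATE", path,
                f"rate constant must be non-negative, got {rule.rate_constant}")

    return out


def is_valid(model: Model) -> bool:
    return not any(v.severity == "error" for v in validate_model(model))


# ---------------------------------------------------------------------------
# document <-> Model


_TOP_KEYS = {"format_version", "molecules", "species", "rules", "metadata"}
_MOL_KEYS = {"name", "components"}
_COMP_KEYS = {"name", "state_variables", "binding_sites"}
_SP_KEYS = {"name", "molecule_instances", "bonds", "complexes"}
_INST_KEYS = {"id", "molecule"}
_CX_KEYS = {"name", "states"}
_STATE_KEYS = {"instance", "component", "variable", "value"}
_RULE_KEYS = {"name", "category", "reactants", "products", "bond_sites", "rate_constant"}
_REF_KEYS = {"species", "complex"}
_SITE_KEYS = {"species", "site"}


def _schema_check(doc: Any) -> list[tuple[str, str]]:
    """Structural check of the raw document; returns (json-pointer, message) pairs."""
    errs: list[tuple[str, str]] = []

    def need(cond: bool, path: str, msg: str) -> bool:
        if not cond:
            errs.append((path, msg))
        return cond

    def warn_unknown(obj: Mapping, known: set[str], path: str) -> None:
        for key in obj:
            if key not in known:
                logger.warning("ignoring unknown key %s at %s", key, path or "/")

    if not need(isinstance(doc, dict), "", "document must be a JSON object"):
        return errs
    warn_unknown(doc, _TOP_KEYS, "")
    need(isinstance(doc.get("format_version"), str), "/format_version",
         "required string")
    for key in ("molecules", "species", "rules"):
        need(isinstance(doc.get(key, []), list), f"/{key}", "must be an array")
    need(isinstance(doc.get("metadata", {}), dict), "/metadata", "must be an object")

    def check_str(obj: Mapping, key: str, path: str, required: bool = True) -> None:
        if key not in obj:
            if required:
                errs.append((f"{path}/{key}", "required string"))
            return
        need(isinstance(obj[key], str) and obj[key] != "", f"{path}/{key}",
             "must be a non-empty string")

    def check_strlist(obj: Mapping, key: str, path: str) -> None:
        val = obj.get(key, [])
        if not need(isinstance(val, list), f"{path}/{key}", "must be an array"):
            return
        for i, v in enumerate(val):
            need(isinstance(v, str), f"{path}/{key}/{i}", "must be a string")

    for i, mol in enumerate(doc.get("molecules") or []):
        path = f"/molecules/{i}"
        if not need(isinstance(mol, dict), path, "must be an object"):
            continue
        warn_unknown(mol, _MOL_KEYS, path)
        check_str(mol, "name", path)
        for j, comp in enumerate(mol.get("components") or []):
            cpath = f"{path}/components/{j}"
            if not need(isinstance(comp, dict), cpath, "must be an object"):
                continue
            warn_unknown(comp, _COMP_KEYS, cpath)
            check_str(comp, "name", cpath)
            check_strlist(comp, "state_variables", cpath)
            check_strlist(comp, "binding_sites", cpath)

    for i, sp in enumerate(doc.get("species") or []):
        path = f"/species/{i}"
        if not need(isinstance(sp, dict), path, "must be an object"):
            continue
        warn_unknown(sp, _SP_KEYS, path)
        check_str(sp, "name", path)
        for j, inst in enumerate(sp.get("molecule_instances") or []):
            ipath = f"{path}/molecule_instances/{j}"
            if not need(isinstance(inst, dict), ipath, "must be an object"):
                continue
            warn_unknown(inst, _INST_KEYS, ipath)
            check_str(inst, "id", ipath)
            check_str(inst, "molecule", ipath)
        for j, bond in enumerate(sp.get("bonds") or []):
            bpath = f"{path}/bonds/{j}"
            ok = isinstance(bond, list) and len(bond) == 2 and all(
                isinstance(s, int) and s >= 1 for s in bond)
            need(ok, bpath, "must be a pair of positive site indices")
        for j, cx in enumerate(sp.get("complexes") or []):
            cpath = f"{path}/complexes/{j}"
            if not need(isinstance(cx, dict), cpath, "must be an object"):
                continue
            warn_unknown(cx, _CX_KEYS, cpath)
            check_str(cx, "name", cpath)
            for k, st in enumerate(cx.get("states") or []):
                spath = f"{cpath}/states/{k}"
                if not need(isinstance(st, dict), spath, "must be an object"):
                    continue
                warn_unknown(st, _STATE_KEYS, spath)
                check_str(st, "instance", spath)
                check_str(st, "component", spath)
                check_str(st, "variable", spath)
                need(st.get("value") in ("on", "off", "dont_care"),
                     f"{spath}/value", "must be 'on', 'off' or 'dont_care'")

    for i, rule in enumerate(doc.get("rules") or []):
        path = f"/rules/{i}"
        if not need(isinstance(rule, dict), path, "must be an object"):
            continue
        warn_unknown(rule, _RULE_KEYS, path)
        check_str(rule, "name", path)
        need(rule.get("category") in ("association", "dissociation", "transformation"),
             f"{path}/category",
             "must be 'association', 'dissociation' or 'transformation'")
        for side in ("reactants", "products"):
            refs = rule.get(side) or []
            if not need(isinstance(refs, list), f"{path}/{side}", "must be an array"):
                continue
            for j, ref in enumerate(refs):
                rpath = f"{path}/{side}/{j}"
                if not need(isinstance(ref, dict), rpath, "must be an object"):
                    continue
                warn_unknown(ref, _REF_KEYS, rpath)
                check_str(ref, "species", rpath)
                check_str(ref, "complex", rpath)
        bs = rule.get("bond_sites")
        if bs is not None:
            if need(isinstance(bs, list) and len(bs) == 2, f"{path}/bond_sites",
                    "must be a pair of site references"):
                for j, ref in enumerate(bs):
                    rpath = f"{path}/bond_sites/{j}"
                    if not need(isinstance(ref, dict), rpath, "must be an object"):
                        continue
                    warn_unknown(ref, _SITE_KEYS, rpath)
                    check_str(ref, "species", rpath)
                    need(isinstance(ref.get("site"), int) and ref.get("site", 0) >= 1,
                         f"{rpath}/site", "must be a positive integer")
        rate = rule.get("rate_constant", 1.0)
        need(isinstance(rate, (int, float)) and not isinstance(rate, bool),
             f"{path}/rate_constant", "must be a number")

    return errs


def _from_document(doc: Mapping[str, Any]) -> Model:
    molecules = tuple(
        Molecule(
            name=m["name"],
            components=tuple(
                Component(
                    name=c["name"],
                    state_variables=tuple(c.get("state_variables") or ()),
                    binding_sites=tuple(c.get("binding_sites") or ()),
                )
                for c in (m.get("components") or ())
            ),
        )
        for m in (doc.get("molecules") or ())
    )
    species = tuple(
        ComplexSpecies(
            name=s["name"],
            molecule_instances=tuple(
                (inst["id"], inst["molecule"])
                for inst in (s.get("molecule_instances") or ())
            ),
            structural_bonds=tuple(
                (min(b), max(b)) for b in (s.get("bonds") or ())
            ),
            complexes=tuple(
                Complex(
                    name=c["name"],
                    species_name=s["name"],
                    state_map={
                        (st["instance"], st["component"], st["variable"]):
                            TriState(st["value"])
                        for st in (c.get("states") or ())
                    },
                )
                for c in (s.get("complexes") or ())
            ),
        )
        for s in (doc.get("species") or ())
    )
    rules = tuple(
        ReactionRule(
            name=r["name"],
            category=RuleCategory(r["category"]),
            reactants=tuple(
                (ref["species"], ref["complex"]) for ref in (r.get("reactants") or ())
            ),
            products=tuple(
                (ref["species"], ref["complex"]) for ref in (r.get("products") or ())
            ),
            bond_sites=(
                tuple(BindingSiteRef(ref["species"], ref["site"])
                      for ref in r["bond_sites"])  # type: ignore[assignment]
                if r.get("bond_sites") is not None
                else None
            ),
            rate_constant=float(r.get("rate_constant", 1.0)),
        )
        for r in (doc.get("rules") or ())
    )
    return Model(
        format_version=doc.get("format_version", FORMAT_VERSION),
        molecules=molecules,
        species=species,
        rules=rules,
        metadata=dict(doc.get("metadata") or {}),
    )


def _to_document(model: Model, canonical: bool = False) -> dict[str, Any]:
    def maybe_sorted(items: Iterable, key) -> list:
        items = list(items)
        return sorted(items, key=key) if canonical else items

    doc: dict[str, Any] = {
        "format_version": model.format_version,
        "metadata": model.metadata,
        "molecules": [
            {
                "name": m.name,
                "components": [
                    {
                        "name": c.name,
                        "state_variables": list(c.state_variables),
                        "binding_sites": list(c.binding_sites),
                    }
                    for c in m.components
                ],
            }
            for m in maybe_sorted(model.molecules, key=lambda m: m.name)
        ],
        "species": [
            {
                "name": s.name,
                "molecule_instances": [
                    {"id": inst, "molecule": mol} for inst, mol in s.molecule_instances
                ],
                "bonds": maybe_sorted(
                    ([min(b), max(b)] for b in s.structural_bonds), key=tuple
                ),
                "complexes": [
                    {
                        "name": c.name,
                        "states": [
                            {
                                "instance": k[0],
                                "component": k[1],
                                "variable": k[2],
                                "value": v.value,
                            }
                            for k, v in sorted(
                                c.state_map.items(), key=lambda kv: kv[0]
                            )
                        ],
                    }
                    for c in maybe_sorted(s.complexes, key=lambda c: c.name)
                ],
            }
            for s in maybe_sorted(model.species, key=lambda s: s.name)
        ],
        "rules": [
            {
                "name": r.name,
                "category": r.category.value,
                "reactants": [
                    {"species": sp, "complex": cx} for sp, cx in r.reactants
                ],
                "products": [
                    {"species": sp, "complex": cx} for sp, cx in r.products
                ],
                "bond_sites": (
                    [
                        {"species": ref.species_name, "site": ref.site_index}
                        for ref in r.bond_sites
                    ]
                    if r.bond_sites is not None
                    else None
                ),
                "rate_constant": r.rate_constant,
            }
            for r in maybe_sorted(model.rules, key=lambda r: r.name)
        ],
    }
    return doc


def parse_model(document: Union[str, io.TextIOBase]) -> Model:
    """Read a model document (JSON, or YAML as a convenience dialect).

    Raises :class:`ModelFormatError` on malformed text (with line/column),
    :class:`ModelSchemaError` on structural violations (with JSON-pointer
    paths), :class:`ModelReferenceError` on dangling cross-references and
    :class:`InvalidModelError` on any other invariant violation. Unknown keys
    are ignored with a logged warning.
    """
    text = document.read() if hasattr(document, "read") else document
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as je:
        # fall back to the YAML reading dialect
        try:
            doc = yaml.safe_load(text)
        except yaml.YAMLError:
            raise ModelFormatError(
                f"malformed model document: {je.msg}", je.lineno, je.colno
            ) from None
        if not isinstance(doc, dict):
            raise ModelFormatError(
                f"malformed model document: {je.msg}", je.lineno, je.colno
            ) from None

    schema_errors = _schema_check(doc)
    if schema_errors:
        raise ModelSchemaError(schema_errors)

    model = _from_document(doc)
    violations = [v for v in validate_model(model) if v.severity == "error"]
    dangling = [v for v in violations if v.code == "DANGLING_REF"]
    if dangling:
        raise ModelReferenceError(dangling)
    if violations:
        raise InvalidModelError(violations)
    return model


def serialize_model(model: Model) -> str:
    """Serialize a valid model to canonical JSON text.

    Entity lists are sorted by name and object keys alphabetically, so two
    models with equal content — however constructed — produce byte-identical
    output. Refuses invalid models with the aggregated validation report.
    """
    violations = [v for v in validate_model(model) if v.severity == "error"]
    if violations:
        raise InvalidModelError(violations)
    doc = _to_document(model, canonical=True)
    return json.dumps(doc, indent=2, sort_keys=True, ensure_ascii=False) + "\n"
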