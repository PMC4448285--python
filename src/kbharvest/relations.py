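"""Default relation inventory: type signatures, seed counts, and exclusions.

The pipeline targets 13 binary relations between biomedical entities
(diseases, organs, drugs, symptoms, devices, behaviors and environmental
"ecofactors").  Every relation carries a type signature constraining the
semantic types of its left (domain) and right (range) argument; the
signatures double as hard consistency constraints during reasoning.

Type codes here are coarse top-level codes; real deployments refine them
through a semantic-type hierarchy file, and the reasoner accepts any
descendant of a signature type.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import yaml

BEHAVIOR = "behavior"
DEVICE = "device"
DISEASE = "disease"
DRUG = "drug"
ECOFACTOR = "ecofactor"
ORGAN = "organ"
SYMPTOM = "symptom"

CORE_TYPES = (BEHAVIOR, DEVICE, DISEASE, DRUG, ECOFACTOR, ORGAN, SYMPTOM)


@dataclass(frozen=True)
class TypeSignature:
    """Permitted semantic types for a relation's two arguments."""

    relation: str
    domain_types: frozenset[str]
    range_types: frozenset[str]

    def __post_init__(self) -> None:
        if not self.domain_types or not self.range_types:
            raise ValueError(
                f"type signature for {self.relation!r} needs non-empty domain and range"
            )


@dataclass(frozen=True)
class ExclusionConstraint:
    """Mutual exclusion between two instantiated relations.

    ``argument_map`` is ``"same"`` when a(x, y) excludes b(x, y) and
    ``"swapped"`` when a(x, y) excludes b(y, x), e.g. a drug with a
    side effect cannot treat that same symptom.
    """

    relation_a: str
    relation_b: str
    argument_map: str = "same"

    def __post_init__(self) -> None:
        if self.argument_map not in ("same", "swapped"):
            raise ValueError(f"argument_map must be 'same' or 'swapped', got {self.argument_map!r}")
        if self.relation_a == self.relation_b and self.argument_map == "same":
            raise ValueError("self-exclusion with same argument order is vacuous")


def _sig(relation: str, domain: set[str], range_: set[str]) -> TypeSignature:
    return TypeSignature(relation, frozenset(domain), frozenset(range_))


DEFAULT_SIGNATURES: dict[str, TypeSignature] = {
    s.relation: s
    for s in (
        _sig("affects", {DISEASE}, {ORGAN}),
        _sig("aggravates", {ECOFACTOR}, {DISEASE}),
        _sig("alleviates", {DRUG}, {DISEASE}),
        _sig("causes", {DISEASE}, {DISEASE}),
        _sig("complicationOf", {DISEASE}, {DISEASE}),
        _sig("contraindicates", {DRUG}, {DISEASE}),
        _sig("createsRisk", {ECOFACTOR}, {DISEASE}),
        _sig("diagnoses", {DEVICE}, {DISEASE}),
        _sig("interacts", {DRUG}, {DRUG}),
        _sig("isSymptom", {SYMPTOM, DISEASE}, {DISEASE}),
        _sig("reducesRisk", {DRUG, BEHAVIOR}, {DISEASE}),
        _sig("sideEffect", {SYMPTOM, DISEASE}, {DRUG}),
        _sig("treats", {DRUG}, {DISEASE}),
    )
}

DEFAULT_RELATIONS: tuple[str, ...] = tuple(sorted(DEFAULT_SIGNATURES))

# Per-relation seed-fact counts of the reference seed set (sums to 467).
DEFAULT_SEED_COUNTS: dict[str, int] = {
    "affects": 23,
    "aggravates": 21,
    "alleviates": 18,
    "causes": 70,
    "complicationOf": 5,
    "contraindicates": 26,
    "createsRisk": 103,
    "diagnoses": 29,
    "interacts": 9,
    "isSymptom": 69,
    "reducesRisk": 24,
    "sideEffect": 12,
    "treats": 58,
}

# The one exclusion shipped by default: sideEffect(x, y) is incompatible
# with treats(y, x).  Additional constraints go in a user YAML file.
DEFAULT_EXCLUSIONS: tuple[ExclusionConstraint, ...] = (
    ExclusionConstraint("sideEffect", "treats", "swapped"),
)


def load_signatures(path: str | Path) -> dict[str, TypeSignature]:
    """Read relation type signatures from YAML: ``rel: {domain: [...], range: [...]}``."""
    data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    out = {}
    for rel, entry in data.items():
        out[rel] = _sig(rel, set(entry["domain"]), set(entry["range"]))
    return out


def load_exclusions(path: str | Path) -> tuple[ExclusionConstraint, ...]:
    """Read exclusion constraints from YAML: list of ``[rel_a, rel_b, same|swapped]``."""
    data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or []
    return tuple(ExclusionConstraint(a, b, m) for a, b, m in data)


def dump_signatures(signatures: dict[str, TypeSignature], path: str | Path) -> None:
    data = {
        rel: {"domain": sorted(sig.domain_types), "range": sorted(sig.range_types)}
        for rel, sig in sorted(signatures.items())
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True), encoding="utf-8")


def dump_exclusions(exclusions: tuple[ExclusionConstraint, ...], path: str | Path) -> None:
    data = [[e.relation_a, e.relation_b, e.argument_map] for e in exclusions]
    Path(path).write_text(yaml.safe_dump(data), encoding="utf-8")
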