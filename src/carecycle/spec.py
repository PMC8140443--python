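"""Declarative cyclical continuum-of-care models.

A continuum spec arranges clinical *phases* on a closed cycle, each phase
holding ordered *elements of care* (risk factors, outcomes, interventions).
Every element carries a classification rule that decides, from a patient's
coded record, whether the element is present.  The ordering of phases and
elements defines the clockwise axis order of the cyclical visualization and
the row order of the estimates table.

The shipped default models a musculoskeletal-infection care cycle with four
phases of two elements each: primary risk factors for limb loss (diabetes
mellitus, peripheral vascular disease), secondary risk factors
(osteomyelitis, multiple infection types), infection-related outcomes
(sepsis, antibiotic use), and surgical interventions (any surgical
procedure, amputation).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Any, Iterator, Optional

import yaml

__all__ = [
    "CodeCriterion",
    "LabCriterion",
    "MedCriterion",
    "ProcedureCriterion",
    "CompositeCriterion",
    "TimeWindow",
    "ElementRule",
    "Phase",
    "ContinuumSpec",
    "ValidationFinding",
    "ValidationReport",
    "SpecError",
    "load_continuum_spec",
    "loads_continuum_spec",
    "default_msk_spec",
    "validate_spec",
]

SPEC_VERSION = 1

CODE_SYSTEMS = ("ICD9", "ICD10", "procedure")


class SpecError(ValueError):
    """Raised when a continuum spec file cannot be parsed or fails validation."""


def normalize_code(code: str) -> str:
    """Canonical form of a diagnosis/procedure code: dots stripped, upper-case."""
    return str(code).replace(".", "").strip().upper()


@dataclass(frozen=True)
class CodeCriterion:
    """Match if any diagnosis code in the given system starts with a listed prefix."""

    code_system: str
    prefixes: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "prefixes", tuple(normalize_code(p) for p in self.prefixes)
        )

    def to_dict(self) -> dict[str, Any]:
        return {"system": self.code_system, "prefixes": list(self.prefixes)}


@dataclass(frozen=True)
class LabCriterion:
    """Aggregate a patient's results for one analyte, then compare to a threshold.

    E.g. diabetes via a maximum hemoglobin A1c >= 6.5 % is
    ``LabCriterion("hba1c", "max", "ge", 6.5, "%")``.
    """

    analyte: str
    aggregation: str  # max | min | any
    comparator: str  # ge | le
    threshold: float
    units: str = ""

    def to_dict(self) -> dict[str, Any]:
        return {
            "analyte": self.analyte,
            "aggregation": self.aggregation,
            "comparator": self.comparator,
            "threshold": self.threshold,
            "units": self.units,
        }


@dataclass(frozen=True)
class MedCriterion:
    """Match if any medication's drug class starts with a listed prefix.

    Topical-route rows are excluded when ``systemic_only`` and the record
    carries a route field.
    """

    drug_class_prefixes: tuple[str, ...]
    systemic_only: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "drug_class_prefixes",
            tuple(str(p).strip().lower() for p in self.drug_class_prefixes),
        )

    def to_dict(self) -> dict[str, Any]:
        return {
            "drug_class_prefixes": list(self.drug_class_prefixes),
            "systemic_only": self.systemic_only,
        }


@dataclass(frozen=True)
class ProcedureCriterion:
    """Match procedure events, optionally restricted by code prefix or amputation flag.

    Empty ``prefixes`` matches any procedure ("any surgical procedure").
    ``amputation_only`` requires the procedure's explicit amputation flag.
    """

    prefixes: tuple[str, ...] = ()
    amputation_only: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "prefixes", tuple(normalize_code(p) for p in self.prefixes)
        )

    def to_dict(self) -> dict[str, Any]:
        return {"prefixes": list(self.prefixes), "amputation_only": self.amputation_only}


@dataclass(frozen=True)
class CompositeCriterion:
    """True when at least ``min_count`` member elements are true.

    Members must be atomic (non-composite) elements of the same spec; the
    "two or more musculoskeletal infection types" element is the canonical
    use.
    """

    member_elements: tuple[str, ...]
    min_count: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "member_elements", tuple(self.member_elements))

    def to_dict(self) -> dict[str, Any]:
        return {"members": list(self.member_elements), "min_count": self.min_count}


@dataclass(frozen=True)
class TimeWindow:
    """Inclusive day-offset window around an anchor date.

    The only supported anchor is the index infection date (earliest
    musculoskeletal-infection diagnosis).  "Within the first 3 months" is
    fixed as offsets (0, 90): calendar-month arithmetic is locale-ambiguous,
    90 days is deterministic.
    """

    anchor: str = "index_infection_date"
    start_offset_days: int = 0
    end_offset_days: int = 90

    def to_dict(self) -> dict[str, Any]:
        return {
            "anchor": self.anchor,
            "start_offset_days": self.start_offset_days,
            "end_offset_days": self.end_offset_days,
        }


@dataclass(frozen=True)
class ElementRule:
    """Classification rule for one element of care.

    Atomic elements are a disjunction: the element is true iff at least one
    code, lab, medication, or procedure criterion is satisfied.  Composite
    elements use ``composite`` alone.  ``window``, when present, constrains
    which dated code/procedure events may satisfy their criteria.
    """

    element_id: str
    code_criteria: tuple[CodeCriterion, ...] = ()
    lab_criteria: tuple[LabCriterion, ...] = ()
    med_criteria: tuple[MedCriterion, ...] = ()
    procedure_criteria: tuple[ProcedureCriterion, ...] = ()
    composite: Optional[CompositeCriterion] = None
    window: Optional[TimeWindow] = None
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "code_criteria", tuple(self.code_criteria))
        object.__setattr__(self, "lab_criteria", tuple(self.lab_criteria))
        object.__setattr__(self, "med_criteria", tuple(self.med_criteria))
        object.__setattr__(self, "procedure_criteria", tuple(self.procedure_criteria))
        if not self.label:
            object.__setattr__(
                self, "label", self.element_id.replace("_", " ").capitalize()
            )

    @property
    def is_composite(self) -> bool:
        return self.composite is not None

    def to_dict(self) -> dict[str, Any]:
        d: dict[str, Any] = {"id": self.element_id, "label": self.label}
        if self.code_criteria:
            d["codes"] = [c.to_dict() for c in self.code_criteria]
        if self.lab_criteria:
            d["labs"] = [c.to_dict() for c in self.lab_criteria]
        if self.med_criteria:
            d["medications"] = [c.to_dict() for c in self.med_criteria]
        if self.procedure_criteria:
            d["procedures"] = [c.to_dict() for c in self.procedure_criteria]
        if self.composite is not None:
            d["composite"] = self.composite.to_dict()
        if self.window is not None:
            d["window"] = self.window.to_dict()
        return d


@dataclass(frozen=True)
class Phase:
    """One clinical phase of the cycle, holding its ordered elements."""

    label: str
    elements: tuple[ElementRule, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "elements", tuple(self.elements))

    def to_dict(self) -> dict[str, Any]:
        return {"label": self.label, "elements": [e.to_dict() for e in self.elements]}


@dataclass(frozen=True)
class ContinuumSpec:
    """A cyclical continuum model.

    Parameters
    ----------
    name : str
        Model name.
    phases : tuple of Phase
        Ordered phases; phase order and element order within phases define
        the cycle's clockwise axis order.
    index_element : str
        Element whose crude odds select the reference stratum.
    infection_elements : tuple of str
        Elements whose code criteria define cohort inclusion and anchor the
        index infection date (earliest matching diagnosis).
    auxiliary_elements : tuple of ElementRule
        Helper elements (e.g. septic arthritis) that are evaluated so that
        composites and the infection anchor can reference them, but that are
        not axes of the cycle.
    """

    name: str
    phases: tuple[Phase, ...]
    index_element: str
    infection_elements: tuple[str, ...] = ()
    auxiliary_elements: tuple[ElementRule, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "phases", tuple(self.phases))
        object.__setattr__(self, "infection_elements", tuple(self.infection_elements))
        object.__setattr__(self, "auxiliary_elements", tuple(self.auxiliary_elements))

    # -- accessors ---------------------------------------------------------
    @property
    def element_ids(self) -> list[str]:
        """Cycle-order identifiers of the elements (the matrix/table columns)."""
        return [e.element_id for p in self.phases for e in p.elements]

    def iter_elements(self) -> Iterator[ElementRule]:
        """Cycle elements in order, then auxiliary elements."""
        for p in self.phases:
            yield from p.elements
        yield from self.auxiliary_elements

    def element(self, element_id: str) -> ElementRule:
        for e in self.iter_elements():
            if e.element_id == element_id:
                return e
        raise KeyError(element_id)

    def phase_of(self, element_id: str) -> str:
        for p in self.phases:
            if any(e.element_id == element_id for e in p.elements):
                return p.label
        raise KeyError(element_id)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        return {
            "spec_version": SPEC_VERSION,
            "name": self.name,
            "index_element": self.index_element,
            "infection_elements": list(self.infection_elements),
            "phases": [p.to_dict() for p in self.phases],
            "auxiliary_elements": [e.to_dict() for e in self.auxiliary_elements],
        }

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False, allow_unicode=True)

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(self.to_yaml())


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ValidationFinding:
    code: str  # machine-readable, e.g. "duplicate-element-id"
    path: str  # phase/element location
    message: str


@dataclass
class ValidationReport:
    findings: list[ValidationFinding] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.findings

    def add(self, code: str, path: str, message: str) -> None:
        self.findings.append(ValidationFinding(code, path, message))

    def codes(self) -> set[str]:
        return {f.code for f in self.findings}

    def __str__(self) -> str:
        if self.ok:
            return "spec valid"
        return "\n".join(f"{f.code} at {f.path}: {f.message}" for f in self.findings)


def validate_spec(spec: ContinuumSpec) -> ValidationReport:
    """Check every spec invariant; reports findings, never raises."""
    rep = ValidationReport()
    if not spec.phases:
        rep.add("empty-spec", spec.name or "<spec>", "spec has no phases")
        return rep

    seen: set[str] = set()
    all_ids: list[str] = []
    for pi, phase in enumerate(spec.phases):
        if not phase.elements:
            rep.add("empty-phase", f"phases[{pi}]", f"phase {phase.label!r} has no elements")
        for e in phase.elements:
            all_ids.append(e.element_id)
    for e in spec.auxiliary_elements:
        all_ids.append(e.element_id)
    for eid in all_ids:
        if eid in seen:
            rep.add("duplicate-element-id", eid, f"element id {eid!r} appears more than once")
        seen.add(eid)

    atomic = {e.element_id for e in spec.iter_elements() if not e.is_composite}
    for e in spec.iter_elements():
        path = e.element_id
        if e.is_composite:
            comp = e.composite
            assert comp is not None
            if e.code_criteria or e.lab_criteria or e.med_criteria or e.procedure_criteria:
                rep.add("composite-with-atomic-criteria", path,
                        "composite elements must not also carry atomic criteria")
            for m in comp.member_elements:
                if m not in seen:
                    rep.add("unresolved-reference", path,
                            f"composite member {m!r} is not an element of the spec")
                elif m not in atomic:
                    rep.add("composite-of-composite", path,
                            f"composite member {m!r} is itself composite")
            if comp.min_count < 1:
                rep.add("nonpositive-min-count", path, "min_count must be >= 1")
            elif comp.min_count > len(comp.member_elements):
                rep.add("min-count-exceeds-members", path,
                        f"min_count {comp.min_count} > {len(comp.member_elements)} members")
        else:
            if not (e.code_criteria or e.lab_criteria or e.med_criteria
                    or e.procedure_criteria):
                rep.add("no-criteria", path, "atomic element has no criteria")
        for c in e.code_criteria:
            if c.code_system not in CODE_SYSTEMS:
                rep.add("unknown-code-system", path, f"code system {c.code_system!r}")
            if not c.prefixes or any(not p for p in c.prefixes):
                rep.add("empty-code-prefix", path, "code prefixes must be non-empty")
        for c in e.lab_criteria:
            if c.aggregation not in ("max", "min", "any"):
                rep.add("unknown-aggregation", path, f"aggregation {c.aggregation!r}")
            if c.comparator not in ("ge", "le"):
                rep.add("unknown-comparator", path, f"comparator {c.comparator!r}")
            try:
                finite = float(c.threshold) == float(c.threshold) and abs(float(c.threshold)) != float("inf")
            except (TypeError, ValueError):
                finite = False
            if not finite:
                rep.add("nonfinite-threshold", path, f"threshold {c.threshold!r}")
        if e.window is not None:
            w = e.window
            if w.anchor != "index_infection_date":
                rep.add("unknown-anchor", path, f"anchor {w.anchor!r}")
            if w.start_offset_days > w.end_offset_days:
                rep.add("inverted-window", path,
                        f"window start {w.start_offset_days} > end {w.end_offset_days}")

    if spec.index_element not in seen:
        rep.add("unknown-index-element", spec.index_element,
                "index_element does not name an element of the spec")
    for eid in spec.infection_elements:
        if eid not in seen:
            rep.add("unknown-infection-element", eid,
                    "infection_elements entry does not name an element")
    return rep


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------

def _parse_criteria(node: dict[str, Any], path: str) -> dict[str, Any]:
    kw: dict[str, Any] = {}
    try:
        kw["code_criteria"] = tuple(
            CodeCriterion(c["system"], tuple(c["prefixes"])) for c in node.get("codes", [])
        )
        kw["lab_criteria"] = tuple(
            LabCriterion(c["analyte"], c.get("aggregation", "max"),
                         c.get("comparator", "ge"), float(c["threshold"]),
                         c.get("units", ""))
            for c in node.get("labs", [])
        )
        kw["med_criteria"] = tuple(
            MedCriterion(tuple(c["drug_class_prefixes"]), c.get("systemic_only", True))
            for c in node.get("medications", [])
        )
        kw["procedure_criteria"] = tuple(
            ProcedureCriterion(tuple(c.get("prefixes", [])), c.get("amputation_only", False))
            for c in node.get("procedures", [])
        )
        if "composite" in node:
            c = node["composite"]
            kw["composite"] = CompositeCriterion(tuple(c["members"]), int(c["min_count"]))
        if "window" in node:
            w = node["window"]
            kw["window"] = TimeWindow(
                w.get("anchor", "index_infection_date"),
                int(w.get("start_offset_days", 0)),
                int(w.get("end_offset_days", 90)),
            )
    except (KeyError, TypeError, ValueError) as exc:
        raise SpecError(f"malformed criterion at {path}: {exc}") from exc
    return kw


def _spec_from_dict(doc: dict[str, Any]) -> ContinuumSpec:
    if not isinstance(doc, dict):
        raise SpecError("spec file must be a mapping at top level")
    try:
        phases = []
        for pi, pnode in enumerate(doc.get("phases", []) or []):
            elements = tuple(
                ElementRule(element_id=e["id"], label=e.get("label", ""),
                            **_parse_criteria(e, f"phases[{pi}]/{e.get('id', '?')}"))
                for e in pnode.get("elements", [])
            )
            phases.append(Phase(pnode.get("label", f"phase {pi + 1}"), elements))
        aux = tuple(
            ElementRule(element_id=e["id"], label=e.get("label", ""),
                        **_parse_criteria(e, f"auxiliary/{e.get('id', '?')}"))
            for e in doc.get("auxiliary_elements", []) or []
        )
        spec = ContinuumSpec(
            name=doc.get("name", "unnamed"),
            phases=tuple(phases),
            index_element=doc.get("index_element", ""),
            infection_elements=tuple(doc.get("infection_elements", []) or []),
            auxiliary_elements=aux,
        )
    except (KeyError, TypeError) as exc:
        raise SpecError(f"malformed spec document: {exc}") from exc
    report = validate_spec(spec)
    if not report.ok:
        raise SpecError(f"invalid continuum spec:\n{report}")
    return spec


def loads_continuum_spec(text: str) -> ContinuumSpec:
    """Parse and validate a continuum spec from YAML text."""
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise SpecError(f"cannot parse spec file: {exc}") from exc
    return _spec_from_dict(doc)


def load_continuum_spec(path) -> ContinuumSpec:
    """Load and validate a continuum spec from a YAML file."""
    with open(path, "r", encoding="utf-8") as fh:
        return loads_continuum_spec(fh.read())


# ---------------------------------------------------------------------------
# Default musculoskeletal-infection model
# ---------------------------------------------------------------------------
# Code lists below are ILLUSTRATIVE prefix sets for the standard ICD-9/10
# chapters of each condition; they are a usable starting point, not a
# validated extraction code set, and are meant to be replaced per site.

_MSK_SURGICAL_WINDOW = TimeWindow("index_infection_date", 0, 90)

_DEFAULT_SPEC_CACHE: Optional[ContinuumSpec] = None


def default_msk_spec() -> ContinuumSpec:
    """The default musculoskeletal-infection cyclical continuum model.

    Four phases, two elements each, in cycle order: diabetes_mellitus,
    peripheral_vascular_disease, osteomyelitis, multiple_infections, sepsis,
    antibiotics, surgical_procedure, amputation.  Diabetes is a disjunction
    of diagnosis codes, max HbA1c >= 6.5 %, or an antidiabetic prescription;
    multiple_infections is "two or more of osteomyelitis, septic arthritis,
    infectious myositis"; the two surgical elements are restricted to 0-90
    days (inclusive) after the index infection date.
    """
    global _DEFAULT_SPEC_CACHE
    if _DEFAULT_SPEC_CACHE is None:
        _DEFAULT_SPEC_CACHE = _build_default_msk_spec()
    return copy.deepcopy(_DEFAULT_SPEC_CACHE)


def _build_default_msk_spec() -> ContinuumSpec:
    diabetes = ElementRule(
        "diabetes_mellitus",
        label="Diabetes mellitus",
        code_criteria=(
            CodeCriterion("ICD9", ("250",)),
            CodeCriterion("ICD10", ("E08", "E09", "E10", "E11", "E13")),
        ),
        lab_criteria=(LabCriterion("hba1c", "max", "ge", 6.5, "%"),),
        med_criteria=(MedCriterion(("antidiabetic",)),),
    )
    pvd = ElementRule(
        "peripheral_vascular_disease",
        label="Peripheral vascular disease",
        code_criteria=(
            CodeCriterion("ICD9", ("443", "4402")),
            CodeCriterion("ICD10", ("I73", "I702")),
        ),
    )
    osteo = ElementRule(
        "osteomyelitis",
        label="Osteomyelitis",
        code_criteria=(
            CodeCriterion("ICD9", ("730",)),
            CodeCriterion("ICD10", ("M86",)),
        ),
    )
    multiple = ElementRule(
        "multiple_infections",
        label="Multiple infections",
        composite=CompositeCriterion(
            ("osteomyelitis", "septic_arthritis", "infectious_myositis"), 2
        ),
    )
    sepsis = ElementRule(
        "sepsis",
        label="Sepsis",
        code_criteria=(
            CodeCriterion("ICD9", ("038", "99591", "99592")),
            CodeCriterion("ICD10", ("A40", "A41", "R652")),
        ),
    )
    antibiotics = ElementRule(
        "antibiotics",
        label="Antibiotics",
        med_criteria=(MedCriterion(("antimicrobial",)),),
    )
    surgical = ElementRule(
        "surgical_procedure",
        label="Surgical procedure",
        procedure_criteria=(ProcedureCriterion(),),
        window=_MSK_SURGICAL_WINDOW,
    )
    amputation = ElementRule(
        "amputation",
        label="Amputation",
        procedure_criteria=(ProcedureCriterion(amputation_only=True),),
        window=_MSK_SURGICAL_WINDOW,
    )
    septic_arthritis = ElementRule(
        "septic_arthritis",
        label="Septic arthritis",
        code_criteria=(
            CodeCriterion("ICD9", ("7110",)),
            CodeCriterion("ICD10", ("M00",)),
        ),
    )
    myositis = ElementRule(
        "infectious_myositis",
        label="Infectious myositis",
        code_criteria=(
            CodeCriterion("ICD9", ("7280",)),
            CodeCriterion("ICD10", ("M600",)),
        ),
    )
    return ContinuumSpec(
        name="msk_infection_default",
        phases=(
            Phase("primary risk factors", (diabetes, pvd)),
            Phase("secondary risk factors", (osteo, multiple)),
            Phase("infection-related outcomes", (sepsis, antibiotics)),
            Phase("surgical interventions", (surgical, amputation)),
        ),
        index_element="diabetes_mellitus",
        infection_elements=("osteomyelitis", "septic_arthritis", "infectious_myositis"),
        auxiliary_elements=(septic_arthritis, myositis),
    )
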