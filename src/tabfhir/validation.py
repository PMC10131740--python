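"""Syntactic validation of FHIR R4 resources against shipped profiles.

Checks exactly what syntactic conformance means for this pipeline: data
types of primitive elements, presence of required elements, nesting
hierarchy (no unknown elements in strict mode), cardinality (single vs
repeating), choice-element rules (``value[x]``, ``effective[x]``,
``medication[x]``) and the lexical form of dates and dateTimes —
including calendar validity, since type conversion of date features is a
canonical source of silent corruption upstream.

Failures are data, not exceptions: each resource gets a ValidationReport
enumerating *all* issues, and a failed resource is rejected (never
stored) while the run continues, feeding the logging-and-improvement
loop.  Profiles cover the seven resource types the default registry
emits; they are derived from the R4 core definitions.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from datetime import date
from typing import Any, Iterable, Optional, Sequence

from .errors import ConfigurationError
from .mapping import FhirResource

logger = logging.getLogger("tabfhir.validation")

# R4 lexical forms.  The dateTime form requires a zone offset whenever a
# time component is present.
_DATETIME_RE = re.compile(
    r"^([0-9]([0-9]([0-9][1-9]|[1-9]0)|[1-9]00)|[1-9]000)"
    r"(-(0[1-9]|1[0-2])"
    r"(-(0[1-9]|[1-2][0-9]|3[0-1])"
    r"(T([01][0-9]|2[0-3]):[0-5][0-9]:([0-5][0-9]|60)(\.[0-9]+)?"
    r"(Z|(\+|-)((0[0-9]|1[0-3]):[0-5][0-9]|14:00)))?)?)?$"
)
_DATE_RE = re.compile(
    r"^([0-9]([0-9]([0-9][1-9]|[1-9]0)|[1-9]00)|[1-9]000)"
    r"(-(0[1-9]|1[0-2])(-(0[1-9]|[1-2][0-9]|3[0-1]))?)?$"
)
_CODE_RE = re.compile(r"^[^\s]+( [^\s]+)*$")
_ID_RE = re.compile(r"^[A-Za-z0-9\-.]{1,64}$")


def _calendar_ok(text: str) -> bool:
    m = re.match(r"^(\d{4})-(\d{2})-(\d{2})", text)
    if not m:
        return True  # year or year-month precision
    try:
        date(int(m.group(1)), int(m.group(2)), int(m.group(3)))
        return True
    except ValueError:
        return False


@dataclass(frozen=True)
class ElementDef:
    kind: str  # string|code|id|uri|integer|decimal|boolean|dateTime|date|complex
    required: bool = False
    many: bool = False
    children: Optional[dict[str, "ElementDef"]] = None
    binding: Optional[frozenset[str]] = None


@dataclass(frozen=True)
class ChoiceGroup:
    name: str  # e.g. "value[x]" — for reporting
    options: tuple[str, ...]
    required: bool = False


@dataclass(frozen=True)
class ResourceProfile:
    resource_type: str
    elements: dict[str, ElementDef]
    choices: tuple[ChoiceGroup, ...] = ()


@dataclass(frozen=True)
class ValidationIssue:
    path: str
    kind: str  # missing_required|wrong_type|bad_cardinality|unknown_element|bad_value_format
    message: str


@dataclass
class ValidationReport:
    resource_id: str
    issues: list[ValidationIssue]

    @property
    def passed(self) -> bool:
        return not self.issues

    def to_dict(self) -> dict:
        return {
            "resource_id": self.resource_id,
            "passed": self.passed,
            "issues": [
                {"path": i.path, "kind": i.kind, "message": i.message} for i in self.issues
            ],
        }


# ---------------------------------------------------------------------------
# Profile construction helpers (R4 core complex datatypes, minimal subset)
# ---------------------------------------------------------------------------

def _el(kind: str, required: bool = False, many: bool = False,
        children: Optional[dict] = None, binding: Optional[Iterable[str]] = None) -> ElementDef:
    return ElementDef(
        kind=kind, required=required, many=many, children=children,
        binding=frozenset(binding) if binding else None,
    )


def _coding() -> dict[str, ElementDef]:
    return {
        "system": _el("uri"),
        "version": _el("string"),
        "code": _el("code"),
        "display": _el("string"),
    }


def _codeable(required: bool = False) -> ElementDef:
    return _el("complex", required=required, children={
        "coding": _el("complex", many=True, children=_coding()),
        "text": _el("string"),
    })


def _quantity() -> ElementDef:
    return _el("complex", children={
        "value": _el("decimal"),
        "unit": _el("string"),
        "system": _el("uri"),
        "code": _el("code"),
    })


def _period() -> ElementDef:
    return _el("complex", children={"start": _el("dateTime"), "end": _el("dateTime")})


def _reference(required: bool = False) -> ElementDef:
    return _el("complex", required=required, children={
        "reference": _el("string"),
        "type": _el("uri"),
        "display": _el("string"),
    })


def _identifier() -> ElementDef:
    return _el("complex", many=True, children={"system": _el("uri"), "value": _el("string")})


def _root(extra: dict[str, ElementDef]) -> dict[str, ElementDef]:
    base = {"resourceType": _el("code", required=True), "id": _el("id", required=True)}
    base.update(extra)
    return base


_OBS_STATUS = ("registered", "preliminary", "final", "amended", "corrected",
               "cancelled", "entered-in-error", "unknown")
_ENC_STATUS = ("planned", "arrived", "triaged", "in-progress", "onleave",
               "finished", "cancelled", "entered-in-error", "unknown")


def default_profiles() -> dict[str, ResourceProfile]:
    """Profiles for the seven resource types the default registry emits."""
    profiles = [
        ResourceProfile("Patient", _root({
            "identifier": _identifier(),
            "gender": _el("code", binding=("male", "female", "other", "unknown")),
            "birthDate": _el("date"),
            "deceasedDateTime": _el("dateTime"),
            "deceasedBoolean": _el("boolean"),
        }), choices=(ChoiceGroup("deceased[x]", ("deceasedDateTime", "deceasedBoolean")),)),
        ResourceProfile("Encounter", _root({
            "identifier": _identifier(),
            "status": _el("code", required=True, binding=_ENC_STATUS),
            "class": _el("complex", required=True, children=_coding()),
            "type": _el("complex", many=True, children={
                "coding": _el("complex", many=True, children=_coding()),
                "text": _el("string"),
            }),
            "serviceType": _codeable(),
            "subject": _reference(),
            "period": _period(),
            "partOf": _reference(),
            "hospitalization": _el("complex", children={
                "dischargeDisposition": _codeable(),
            }),
        })),
        ResourceProfile("Observation", _root({
            "identifier": _identifier(),
            "status": _el("code", required=True, binding=_OBS_STATUS),
            "category": _el("complex", many=True, children={
                "coding": _el("complex", many=True, children=_coding()),
                "text": _el("string"),
            }),
            "code": _codeable(required=True),
            "subject": _reference(),
            "encounter": _reference(),
            "effectiveDateTime": _el("dateTime"),
            "effectivePeriod": _period(),
            "valueQuantity": _quantity(),
            "valueString": _el("string"),
            "interpretation": _el("complex", many=True, children={
                "coding": _el("complex", many=True, children=_coding()),
                "text": _el("string"),
            }),
            "component": _el("complex", many=True, children={
                "code": _codeable(required=True),
                "valueQuantity": _quantity(),
                "valueString": _el("string"),
            }),
        }), choices=(
            ChoiceGroup("effective[x]", ("effectiveDateTime", "effectivePeriod")),
            ChoiceGroup("value[x]", ("valueQuantity", "valueString")),
        )),
        ResourceProfile("Condition", _root({
            "identifier": _identifier(),
            "code": _codeable(),
            "subject": _reference(required=True),
            "encounter": _reference(),
        })),
        ResourceProfile("Procedure", _root({
            "identifier": _identifier(),
            "status": _el("code", required=True, binding=(
                "preparation", "in-progress", "not-done", "on-hold", "stopped",
                "completed", "entered-in-error", "unknown")),
            "code": _codeable(),
            "subject": _reference(required=True),
            "encounter": _reference(),
            "performedDateTime": _el("dateTime"),
            "performedPeriod": _period(),
        }), choices=(ChoiceGroup("performed[x]", ("performedDateTime", "performedPeriod")),)),
        ResourceProfile("MedicationRequest", _root({
            "identifier": _identifier(),
            "status": _el("code", required=True, binding=(
                "active", "on-hold", "cancelled", "completed", "entered-in-error",
                "stopped", "draft", "unknown")),
            "intent": _el("code", required=True, binding=(
                "proposal", "plan", "order", "original-order", "reflex-order",
                "filler-order", "instance-order", "option")),
            "medicationCodeableConcept": _codeable(),
            "medicationReference": _reference(),
            "subject": _reference(required=True),
            "encounter": _reference(),
            "authoredOn": _el("dateTime"),
            "dispenseRequest": _el("complex", children={"quantity": _quantity()}),
        }), choices=(
            ChoiceGroup("medication[x]", ("medicationCodeableConcept", "medicationReference"),
                        required=True),
        )),
        ResourceProfile("MedicationAdministration", _root({
            "identifier": _identifier(),
            "status": _el("code", required=True, binding=(
                "in-progress", "not-done", "on-hold", "completed",
                "entered-in-error", "stopped", "unknown")),
            "medicationCodeableConcept": _codeable(),
            "medicationReference": _reference(),
            "subject": _reference(required=True),
            "context": _reference(),
            "effectiveDateTime": _el("dateTime"),
            "effectivePeriod": _period(),
            "dosage": _el("complex", children={"text": _el("string"), "dose": _quantity()}),
        }), choices=(
            ChoiceGroup("medication[x]", ("medicationCodeableConcept", "medicationReference"),
                        required=True),
            ChoiceGroup("effective[x]", ("effectiveDateTime", "effectivePeriod"),
                        required=True),
        )),
    ]
    return {p.resource_type: p for p in profiles}


# ---------------------------------------------------------------------------
# Validation walk
# ---------------------------------------------------------------------------

def _check_primitive(value: Any, el: ElementDef, path: str, issues: list[ValidationIssue]) -> None:
    kind = el.kind
    if kind in ("string", "uri"):
        if not isinstance(value, str) or not value:
            issues.append(ValidationIssue(path, "wrong_type", f"expected non-empty {kind}"))
        return
    if kind == "id":
        if not isinstance(value, str) or not _ID_RE.match(value):
            issues.append(ValidationIssue(path, "bad_value_format", "invalid FHIR id"))
        return
    if kind == "code":
        if not isinstance(value, str) or not _CODE_RE.match(value):
            issues.append(ValidationIssue(path, "wrong_type", "expected a code token"))
            return
        if el.binding is not None and value not in el.binding:
            issues.append(ValidationIssue(path, "bad_value_format",
                                          f"code {value!r} outside required value set"))
        return
    if kind == "integer":
        if not isinstance(value, int) or isinstance(value, bool):
            issues.append(ValidationIssue(path, "wrong_type", "expected integer"))
        return
    if kind == "decimal":
        if isinstance(value, bool) or not isinstance(value, (int, float)):
            issues.append(ValidationIssue(path, "wrong_type", "expected decimal"))
        return
    if kind == "boolean":
        if not isinstance(value, bool):
            issues.append(ValidationIssue(path, "wrong_type", "expected boolean"))
        return
    if kind == "dateTime":
        if not isinstance(value, str):
            issues.append(ValidationIssue(path, "wrong_type", "expected dateTime string"))
        elif not _DATETIME_RE.match(value) or not _calendar_ok(value):
            issues.append(ValidationIssue(path, "bad_value_format",
                                          f"invalid dateTime {value!r}"))
        return
    if kind == "date":
        if not isinstance(value, str):
            issues.append(ValidationIssue(path, "wrong_type", "expected date string"))
        elif not _DATE_RE.match(value) or not _calendar_ok(value):
            issues.append(ValidationIssue(path, "bad_value_format", f"invalid date {value!r}"))
        return
    raise ConfigurationError(f"profile defines unknown kind {kind!r} at {path}")


def _validate_object(node: Any, elements: dict[str, ElementDef], prefix: str,
                     issues: list[ValidationIssue], strict: bool) -> None:
    if not isinstance(node, dict):
        issues.append(ValidationIssue(prefix or ".", "wrong_type", "expected an object"))
        return
    for key, value in node.items():
        path = f"{prefix}.{key}" if prefix else key
        el = elements.get(key)
        if el is None:
            if strict:
                issues.append(ValidationIssue(path, "unknown_element",
                                              f"element {key!r} not in R4 core profile"))
            else:
                logger.warning("lenient mode: ignoring unknown element %s", path)
            continue
        if el.many:
            if not isinstance(value, list):
                issues.append(ValidationIssue(path, "bad_cardinality",
                                              "repeating element must be an array"))
                continue
            items = value
        else:
            if isinstance(value, list):
                issues.append(ValidationIssue(path, "bad_cardinality",
                                              "singular element must not be an array"))
                continue
            items = [value]
        for item in items:
            if el.kind == "complex":
                if not isinstance(item, dict):
                    issues.append(ValidationIssue(path, "wrong_type", "expected an object"))
                    continue
                _validate_object(item, el.children or {}, path, issues, strict)
            else:
                _check_primitive(item, el, path, issues)
    for key, el in elements.items():
        if el.required and key not in node:
            path = f"{prefix}.{key}" if prefix else key
            issues.append(ValidationIssue(path, "missing_required",
                                          f"required element {key!r} absent"))


def validate_resource(
    resource: FhirResource,
    profiles: Optional[dict[str, ResourceProfile]] = None,
    mode: str = "strict",
) -> ValidationReport:
    """Validate one resource; the report enumerates every issue found."""
    profiles = profiles if profiles is not None else default_profiles()
    profile = profiles.get(resource.resource_type)
    if profile is None:
        raise ConfigurationError(f"no profile for resource type {resource.resource_type!r}")
    issues: list[ValidationIssue] = []
    body = resource.body
    declared = body.get("resourceType")
    if declared is not None and declared != profile.resource_type:
        issues.append(ValidationIssue("resourceType", "wrong_type",
                                      f"resourceType {declared!r} does not match profile"))
    _validate_object(body, profile.elements, "", issues, strict=(mode == "strict"))
    for choice in profile.choices:
        present = [o for o in choice.options if o in body]
        if len(present) > 1:
            issues.append(ValidationIssue(choice.name, "bad_cardinality",
                                          f"multiple {choice.name} alternatives present: {present}"))
        elif choice.required and not present:
            issues.append(ValidationIssue(choice.name, "missing_required",
                                          f"one of {choice.options} is required"))
    return ValidationReport(resource_id=resource.id or body.get("id", ""), issues=issues)


def validate_batch(
    resources: Sequence[FhirResource],
    profiles: Optional[dict[str, ResourceProfile]] = None,
    mode: str = "strict",
) -> tuple[list[FhirResource], list[ValidationReport]]:
    """Partition a batch into accepted resources and per-resource reports.

    Every input yields exactly one report; accepted contains exactly the
    resources whose report passed.  Each failure is logged.
    """
    profiles = profiles if profiles is not None else default_profiles()
    accepted: list[FhirResource] = []
    reports: list[ValidationReport] = []
    for resource in resources:
        report = validate_resource(resource, profiles, mode=mode)
        reports.append(report)
        if report.passed:
            accepted.append(resource)
        else:
            logger.warning(
                "validation rejected %s/%s: %s",
                resource.resource_type, resource.id,
                "; ".join(f"{i.kind}@{i.path}" for i in report.issues),
            )
    return accepted, reports
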