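"""Independent minimal R4 structural checker used as a validation oracle.

Deliberately written as a *different* program from the package's
validator: a flat table of required element paths per resource type plus
datetime parsing via the standard library, with no shared code.  It only
answers pass/fail; agreement of the two independent routes on generated
and mutated corpora is what the tests assert.
"""

from __future__ import annotations

from datetime import datetime

# required element paths per R4 core resource type (dotted; arrays implicit)
REQUIRED = {
    "Patient": ["id"],
    "Encounter": ["id", "status", "class"],
    "Observation": ["id", "status", "code"],
    "Condition": ["id", "subject"],
    "Procedure": ["id", "status", "subject"],
    "MedicationRequest": ["id", "status", "intent", "subject", "medication[x]"],
    "MedicationAdministration": ["id", "status", "subject", "medication[x]", "effective[x]"],
}

CHOICES = {
    "medication[x]": ("medicationCodeableConcept", "medicationReference"),
    "effective[x]": ("effectiveDateTime", "effectivePeriod"),
}

# elements holding dateTime strings, searched recursively by key name
DATETIME_KEYS = {
    "effectiveDateTime", "performedDateTime", "authoredOn", "deceasedDateTime",
    "start", "end",
}

CODE_VALUES = {
    "status", "intent", "gender",
}


def _iter_items(node, key=None):
    if isinstance(node, dict):
        for k, v in node.items():
            yield from _iter_items(v, k)
    elif isinstance(node, list):
        for v in node:
            yield from _iter_items(v, key)
    else:
        yield key, node


def _dt_ok(text) -> bool:
    if not isinstance(text, str):
        return False
    try:
        datetime.fromisoformat(text)
    except ValueError:
        return False
    # FHIR wants 'T'-separated form with an explicit offset when a time is given
    if "T" in text:
        return text.endswith("Z") or ("+" in text[10:] or "-" in text[10:])
    return len(text) in (4, 7, 10)


def check(body: dict) -> bool:
    """True when the document looks like a valid instance of its type."""
    rtype = body.get("resourceType")
    if rtype not in REQUIRED:
        return False
    for req in REQUIRED[rtype]:
        if req in CHOICES:
            if not any(opt in body for opt in CHOICES[req]):
                return False
        elif body.get(req) in (None, "", [], {}):
            return False
    for key, value in _iter_items(body):
        if key in DATETIME_KEYS and not _dt_ok(value):
            return False
        if key in CODE_VALUES and (not isinstance(value, str) or not value):
            return False
    return True
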