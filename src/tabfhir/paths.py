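"""Dotted-path access into FHIR-style nested JSON documents.

FHIR JSON nests complex datatypes (CodeableConcept, Quantity, Period) and
repeats some elements as arrays.  Mapping and extraction rules address
elements with plain dotted paths such as ``code.coding.display``; path
segments that are repeating elements in R4 core are transparently wrapped
in (and unwrapped from) single-element arrays, so rule authors never
write array indices.  This deliberately avoids exposing FHIRPath: the
rule language stays a flat dotted string.
"""

from __future__ import annotations

from typing import Any, Iterable, Optional

# R4 core elements that repeat (0..*) among the elements the default
# registry and extraction rules can touch.  A segment listed here is
# materialized as a one-element array on write and unwrapped to its first
# repetition on read.
ARRAY_SEGMENTS = frozenset(
    {
        "identifier",
        "coding",
        "category",
        "type",
        "interpretation",
        "note",
        "component",
        "dosageInstruction",
        "doseAndRate",
        "performer",
    }
)


def set_path(doc: dict, path: str, value: Any) -> None:
    """Set ``value`` at dotted ``path``, creating intermediate objects.

    Array-typed segments are created as single-element arrays and the
    write descends into their first repetition.
    """
    parts = path.split(".")
    node = doc
    for seg in parts[:-1]:
        child = node.get(seg)
        if seg in ARRAY_SEGMENTS:
            if child is None:
                child = [{}]
                node[seg] = child
            node = child[0]
        else:
            if child is None:
                child = {}
                node[seg] = child
            node = child
    leaf = parts[-1]
    if leaf in ARRAY_SEGMENTS:
        node[leaf] = [value]
    else:
        node[leaf] = value


def get_path(doc: Any, path: str) -> Any:
    """Resolve dotted ``path`` against a document; None when any hop misses.

    Lists are traversed through their first element (scalar-slot reads);
    use :func:`get_path_all` to fan out over repetitions.
    """
    node = doc
    for seg in path.split("."):
        if isinstance(node, list):
            if not node:
                return None
            node = node[0]
        if not isinstance(node, dict):
            return None
        node = node.get(seg)
        if node is None:
            return None
    if isinstance(node, list):
        return node[0] if node else None
    return node


def get_path_all(doc: Any, path: str) -> list:
    """Resolve a dotted path fanning out across every array repetition."""
    nodes = [doc]
    for seg in path.split("."):
        nxt: list = []
        for node in nodes:
            if isinstance(node, list):
                candidates = node
            else:
                candidates = [node]
            for cand in candidates:
                if isinstance(cand, dict) and cand.get(seg) is not None:
                    nxt.append(cand[seg])
        nodes = nxt
    out: list = []
    for node in nodes:
        if isinstance(node, list):
            out.extend(node)
        else:
            out.append(node)
    return out


def resolve_first(doc: Any, paths: Iterable[str]) -> Optional[Any]:
    """First non-null resolution among a prioritized list of paths."""
    for p in paths:
        v = get_path(doc, p)
        if v is not None:
            return v
    return None
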