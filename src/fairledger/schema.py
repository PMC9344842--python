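"""Metadata templates and record validation.

This is the computation the endorser-validator-committer (EVC) nodes run
during endorsement: a metadata record, a flat map of field name to text
value, is checked against a named, versioned template.  The shipped base
template is the 15-element Dublin Core standard (Creator, Contributor,
Publisher, Title, Date, Language, Format, Subject, Description,
Identifier, Relation, Source, Type, Coverage, Rights); experiment
templates extend it with domain fields.

Validation rules
----------------
* every required field present and non-empty (an empty string counts as
  missing),
* no field outside the template,
* language-code fields are exactly two ASCII letters (ISO 639-1 syntax;
  comparison is case-insensitive, and an optional allowlist of assigned
  codes can be switched on),
* controlled-vocabulary membership,
* dates are ISO 8601 calendar dates (YYYY-MM-DD),
* integer / decimal fields parse as numbers.

Records are hashed through :func:`canonical_bytes`, a canonical UTF-8
JSON form with sorted keys, so every node derives the same digest from
the same record regardless of insertion order.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from datetime import date
from importlib import resources
from typing import Iterable, Mapping, NamedTuple

from ._canon import canonical_json, sha256_hex
from .errors import SchemaError, SerializationError, TemplateResolutionError

#: The 15 Dublin Core element names, in standard order.
DUBLIN_CORE_ELEMENTS: tuple[str, ...] = (
    "Creator",
    "Contributor",
    "Publisher",
    "Title",
    "Date",
    "Language",
    "Format",
    "Subject",
    "Description",
    "Identifier",
    "Relation",
    "Source",
    "Type",
    "Coverage",
    "Rights",
)

FIELD_KINDS = frozenset(
    {
        "free-text",
        "controlled-vocabulary",
        "language-code",
        "date",
        "integer",
        "decimal",
        "identifier",
    }
)

# ISO 639-1 alpha-2 codes (assigned set), used only when allowlist
# checking is requested; the default check is purely syntactic.
ISO_639_1_CODES = frozenset(
    """
    aa ab ae af ak am an ar as av ay az ba be bg bh bi bm bn bo br bs ca
    ce ch co cr cs cu cv cy da de dv dz ee el en eo es et eu fa ff fi fj
    fo fr fy ga gd gl gn gu gv ha he hi ho hr ht hu hy hz ia id ie ig ii
    ik io is it iu ja jv ka kg ki kj kk kl km kn ko kr ks ku kv kw ky la
    lb lg li ln lo lt lu lv mg mh mi mk ml mn mr ms mt my na nb nd ne ng
    nl nn no nr nv ny oc oj om or os pa pi pl ps pt qu rm rn ro ru rw sa
    sc sd se sg si sk sl sm sn so sq sr ss st su sv sw ta te tg th ti tk
    tl tn to tr ts tt tw ty ug uk ur uz ve vi vo wa wo xh yi yo za zh zu
    """.split()
)

_LANGUAGE_RE = re.compile(r"^[A-Za-z]{2}$")
_DATE_RE = re.compile(r"^\d{4}-\d{2}-\d{2}$")
_INTEGER_RE = re.compile(r"^[+-]?\d+$")
_DECIMAL_RE = re.compile(r"^[+-]?(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?$")


@dataclass(frozen=True)
class FieldSpec:
    """Specification of one metadata element within a template."""

    name: str
    required: bool = True
    kind: str = "free-text"
    vocabulary: tuple[str, ...] | None = None
    units: str | None = None  # documentation only, never validated

    def __post_init__(self) -> None:
        if not self.name:
            raise SchemaError("field name must be nonempty")
        if self.kind not in FIELD_KINDS:
            raise SchemaError(f"unknown field kind {self.kind!r} for {self.name!r}")
        if self.kind == "controlled-vocabulary" and not self.vocabulary:
            raise SchemaError(
                f"controlled-vocabulary field {self.name!r} needs a nonempty vocabulary"
            )
        if self.vocabulary is not None:
            object.__setattr__(self, "vocabulary", tuple(self.vocabulary))


@dataclass(frozen=True)
class MetadataTemplate:
    """A named, versioned, ordered set of field specifications.

    ``base`` names the template this one extends; after resolution the
    field list always starts with the full base field list.
    """

    template_id: str
    version: int
    fields: tuple[FieldSpec, ...]
    base: str | None = None

    def __post_init__(self) -> None:
        if not self.template_id:
            raise SchemaError("template_id must be nonempty")
        if self.version < 1:
            raise SchemaError("template version must be >= 1")
        object.__setattr__(self, "fields", tuple(self.fields))
        names = [f.name for f in self.fields]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise SchemaError(f"duplicate field names in template: {sorted(dupes)}")

    @property
    def field_names(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.fields)

    def field(self, name: str) -> FieldSpec:
        for f in self.fields:
            if f.name == name:
                return f
        raise KeyError(name)


@dataclass(frozen=True)
class MetadataRecord:
    """One metadata document: a template reference plus field values.

    Values are always text; numeric fields hold the textual form the
    submitter entered and are parsed during validation.
    """

    template_id: str
    values: Mapping[str, str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", dict(self.values))

    def to_dict(self) -> dict:
        return {"template_id": self.template_id, "values": dict(self.values)}


class Violation(NamedTuple):
    field: str
    kind: str
    message: str


@dataclass(frozen=True)
class ValidationReport:
    """Outcome of checking a record against a template."""

    violations: tuple[Violation, ...] = ()

    @property
    def valid(self) -> bool:
        return not self.violations

    def kinds(self) -> tuple[str, ...]:
        return tuple(v.kind for v in self.violations)


# ---------------------------------------------------------------------------
# canonical serialization


def canonical_bytes(record: MetadataRecord) -> bytes:
    """Deterministic byte form of a record.

    Equal records (same key-to-value map, any insertion order) map to
    identical bytes; the round trip through :func:`record_from_bytes`
    is lossless.
    """
    if not isinstance(record.template_id, str):
        raise SerializationError("template_id must be text")
    for k, v in record.values.items():
        if not isinstance(k, str) or not isinstance(v, str):
            raise SerializationError(f"non-text entry {k!r}: values must be strings")
    return canonical_json(record.to_dict())


def record_from_bytes(data: bytes) -> MetadataRecord:
    obj = json.loads(data.decode("utf-8"))
    return MetadataRecord(template_id=obj["template_id"], values=obj["values"])


def record_digest(record: MetadataRecord) -> str:
    """SHA-256 hex digest of the canonical byte form."""
    return sha256_hex(canonical_bytes(record))


# ---------------------------------------------------------------------------
# template loading


def _parse_field(obj: dict) -> FieldSpec:
    try:
        name = obj["name"]
    except (KeyError, TypeError) as exc:
        raise SchemaError(f"field object missing 'name': {obj!r}") from exc
    vocab = obj.get("vocabulary")
    return FieldSpec(
        name=name,
        required=bool(obj.get("required", True)),
        kind=obj.get("kind", "free-text"),
        vocabulary=tuple(vocab) if vocab is not None else None,
        units=obj.get("units"),
    )


def load_template(source, registry: "TemplateRegistry | None" = None) -> MetadataTemplate:
    """Load a template document and resolve its base, if any.

    ``source`` may be a dict, JSON text/bytes, an open file, or a path.
    Extensions are resolved against ``registry`` (falling back to the
    packaged built-in templates) and yield the full base field list
    followed by the extension's additions.
    """
    if isinstance(source, Mapping):
        doc = dict(source)
    else:
        if hasattr(source, "read"):
            text = source.read()
        elif isinstance(source, (bytes, str)) and _looks_like_json(source):
            text = source
        else:
            with open(source, "r", encoding="utf-8") as fh:
                text = fh.read()
        try:
            doc = json.loads(text)
        except json.JSONDecodeError as exc:
            raise SchemaError(f"malformed template document: {exc}") from exc
    if not isinstance(doc, dict):
        raise SchemaError("template document must be a JSON object")

    template_id = doc.get("template_id")
    if not template_id:
        raise SchemaError("template document lacks template_id")
    own_fields = [_parse_field(f) for f in doc.get("fields", [])]
    base_id = doc.get("base")
    if base_id:
        reg = registry if registry is not None else builtin_registry()
        base = reg.get(base_id)
        if base is None:
            raise TemplateResolutionError(
                f"template {template_id!r} extends unknown base {base_id!r}"
            )
        fields = list(base.fields) + own_fields
    else:
        fields = own_fields
    return MetadataTemplate(
        template_id=template_id,
        version=int(doc.get("version", 1)),
        fields=tuple(fields),
        base=base_id,
    )


def _looks_like_json(text) -> bool:
    s = text.decode("utf-8", "replace") if isinstance(text, bytes) else text
    return s.lstrip()[:1] in ("{", "[")


class TemplateRegistry:
    """Lookup table of registered templates, keyed by template_id.

    This is the 'predefined standard' an endorsing node consults; a
    record naming an unregistered template fails endorsement with an
    unknown-template violation.
    """

    def __init__(self, templates: Iterable[MetadataTemplate] = ()):
        self._templates: dict[str, MetadataTemplate] = {}
        for t in templates:
            self.register(t)

    def register(self, template: MetadataTemplate) -> None:
        self._templates[template.template_id] = template

    def get(self, template_id: str) -> MetadataTemplate | None:
        return self._templates.get(template_id)

    def __contains__(self, template_id: str) -> bool:
        return template_id in self._templates

    def ids(self) -> tuple[str, ...]:
        return tuple(sorted(self._templates))


_BUILTIN: TemplateRegistry | None = None


def builtin_registry() -> TemplateRegistry:
    """Registry of the packaged templates: the Dublin Core base plus the
    fiber manufacture and measurement extensions."""
    global _BUILTIN
    if _BUILTIN is None:
        reg = TemplateRegistry()
        pkg = resources.files("fairledger") / "templates"
        for name in ("dublin_core.json", "manufacture.json", "measurement.json"):
            doc = json.loads((pkg / name).read_text(encoding="utf-8"))
            reg.register(load_template(doc, registry=reg))
        _BUILTIN = reg
    return _BUILTIN


# ---------------------------------------------------------------------------
# validation


def _check_kind(spec: FieldSpec, value: str, enforce_iso639: bool) -> Violation | None:
    if spec.kind == "language-code":
        if not _LANGUAGE_RE.match(value):
            return Violation(
                spec.name,
                "bad-language-code",
                f"{value!r} is not a two-letter ISO 639-1 code",
            )
        if enforce_iso639 and value.lower() not in ISO_639_1_CODES:
            return Violation(
                spec.name,
                "bad-language-code",
                f"{value!r} is not an assigned ISO 639-1 code",
            )
    elif spec.kind == "controlled-vocabulary":
        assert spec.vocabulary is not None
        if value not in spec.vocabulary:
            return Violation(
                spec.name,
                "not-in-vocabulary",
                f"{value!r} not in vocabulary {sorted(spec.vocabulary)}",
            )
    elif spec.kind == "date":
        ok = bool(_DATE_RE.match(value))
        if ok:
            try:
                date.fromisoformat(value)
            except ValueError:
                ok = False
        if not ok:
            return Violation(
                spec.name, "bad-date", f"{value!r} is not an ISO 8601 date (YYYY-MM-DD)"
            )
    elif spec.kind == "integer":
        if not _INTEGER_RE.match(value):
            return Violation(spec.name, "bad-number", f"{value!r} is not an integer")
    elif spec.kind == "decimal":
        if not _DECIMAL_RE.match(value):
            return Violation(spec.name, "bad-number", f"{value!r} is not a number")
    # free-text and identifier carry no syntactic constraint
    return None


def validate_record(
    record: MetadataRecord,
    template: MetadataTemplate,
    *,
    enforce_iso639_codes: bool = False,
) -> ValidationReport:
    """Check a record against a template; all problems are reported, never raised.

    One violation entry is produced per failed check, in deterministic
    order: template mismatch, missing required fields (template order),
    unknown fields (sorted), then per-field kind violations (template
    order).  Validation is a pure function of its inputs.
    """
    violations: list[Violation] = []
    if record.template_id != template.template_id:
        violations.append(
            Violation(
                "template_id",
                "unknown-template",
                f"record names template {record.template_id!r}, "
                f"validated against {template.template_id!r}",
            )
        )

    known = set(template.field_names)
    for spec in template.fields:
        value = record.values.get(spec.name)
        if spec.required and not value:
            violations.append(
                Violation(spec.name, "missing-required", "required field absent or empty")
            )
    for name in sorted(record.values):
        if name not in known:
            violations.append(
                Violation(name, "unknown-field", "field not defined by the template")
            )
    for spec in template.fields:
        value = record.values.get(spec.name)
        if not value:
            continue
        v = _check_kind(spec, value, enforce_iso639_codes)
        if v is not None:
            violations.append(v)
    return ValidationReport(violations=tuple(violations))
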