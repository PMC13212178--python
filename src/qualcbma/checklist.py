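"""The 15-criterion CBMA methodological-quality checklist, machine-readable.

The checklist operationalizes the "ten simple rules" of coordinate-based
meta-analysis into 15 binary criteria (preregistration, systematic search,
homogeneous modalities/paradigms/conditions, contrast adjustment, space-uniform
thresholds, coverage and reference space, double extraction, dataset count,
diagnostics, transparent reporting). Authors answer yes/no (not-applicable is
allowed only for the paradigm and condition items, 5 and 6), comment on every
item, and declare that unmet items are also commented in the manuscript.

The engine deliberately produces no aggregate quality score: an unmet criterion
is surfaced as a *note*, never summed — a CBMA is judged by the transparency of
its comments, not by a tally of boxes. ``tally`` counts responses across
documents only for meta-research on reporting practices.

Documents are YAML (one or more analyses per file; in multi-CBMA manuscripts
each individual CBMA gets its own checklist, never the multimodal conjunction).
``render_markdown`` emits a human-readable form that ``load_checklist`` parses
back losslessly.
"""

from __future__ import annotations

import json
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import yaml

from .power import (
    MODALITIES,
    Criterion12Config,
    PowerSpec,
    StudyRecord,
    evaluate_criterion12,
)

__all__ = [
    "CriterionSpec",
    "CriterionEntry",
    "ChecklistDoc",
    "ValidationIssue",
    "Tally",
    "ChecklistParseError",
    "CRITERIA",
    "RESPONSES",
    "NA_ALLOWED_IDS",
    "load_checklist",
    "load_checklists",
    "validate",
    "render_markdown",
    "tally",
    "checklist_json_schema",
]

YES = "yes"
NO = "no"
NOT_APPLICABLE = "not_applicable"
RESPONSES = (YES, NO, NOT_APPLICABLE)

#: Criteria that may be answered "not applicable" (paradigm / condition items).
NA_ALLOWED_IDS = frozenset({5, 6})


class ChecklistParseError(ValueError):
    """A checklist document could not be parsed; the message names the location."""


@dataclass(frozen=True)
class CriterionSpec:
    """One checklist item: its id, short label, originating simple rule, and
    the full prompt shown to authors."""

    id: int
    label: str
    rule_ref: int
    allows_na: bool
    prompt: str


CRITERIA: tuple[CriterionSpec, ...] = (
    CriterionSpec(
        1, "preregistration", 7, False,
        "The protocol of the CBMA is preregistered in a publicly available "
        "database.",
    ),
    CriterionSpec(
        2, "systematic_search", 3, False,
        "Studies are searched using search keywords in multiple scientific "
        "databases.",
    ),
    CriterionSpec(
        3, "inclusion_exclusion_criteria", 3, False,
        "The CBMA specifies clear inclusion/exclusion criteria.",
    ),
    CriterionSpec(
        4, "same_modality_measure", 1, False,
        "Studies use the same imaging modality (e.g., structural MRI) and "
        "measure (e.g., gray matter VBM).",
    ),
    CriterionSpec(
        5, "same_paradigm", 1, True,
        "If applicable, same functional paradigm (e.g., n-back). Not "
        "applicable to modalities with no functional paradigms.",
    ),
    CriterionSpec(
        6, "same_condition_disorder", 1, True,
        "If applicable, same condition (e.g., psychological distress) or "
        "disorder (e.g., only schizophrenia). Not applicable to studies not "
        "investigating conditions or disorders.",
    ),
    CriterionSpec(
        7, "contrast_adjustment", 5, False,
        "Only one GLM contrast per dataset, or multiple contrasts are "
        "adequately adjusted and the approach is fully justified or "
        "referenced.",
    ),
    CriterionSpec(
        8, "space_uniform_thresholds", 4, False,
        "Only results in which the statistical threshold does not depend on "
        "the brain region (excluding results obtained with region-liberal "
        "thresholds such as small-volume corrections or other hidden ROIs, "
        "unless they meet the whole-brain threshold).",
    ),
    CriterionSpec(
        9, "same_coverage", 4, False,
        "The brain or tissue coverages of the included datasets and the CBMA "
        "agree (e.g., all studies and the CBMA cover the gray but not the "
        "white matter).",
    ),
    CriterionSpec(
        10, "common_space", 4, False,
        "Data are transformed into a common space (e.g., MNI) before "
        "conducting the analyses.",
    ),
    CriterionSpec(
        11, "double_extraction", 6, False,
        "Data are collected independently by at least two investigators and "
        "then checked.",
    ),
    CriterionSpec(
        12, "dataset_count", 2, False,
        "Total number of independent datasets is at least 17. As an optional "
        "contextualization, authors may weight studies according to sample "
        "size and count studies providing statistical maps as two datasets "
        "of that sample size.",
    ),
    CriterionSpec(
        13, "diagnostics", 9, False,
        "Assessment of potential publication bias, robustness, and/or "
        "experiment contribution with an appropriate method (e.g., Egger "
        "tests, Galbraith plots, number of additional noise studies, number "
        "of contributing experiments).",
    ),
    CriterionSpec(
        14, "dataset_description", 10, False,
        "Description of datasets, contrasts, and samples (e.g., specific "
        "contrast, mean age, and percentage of females in the samples).",
    ),
    CriterionSpec(
        15, "reproducible_reporting", 10, False,
        "Data and code required to reproduce the CBMA are publicly available, "
        "or sufficient information is reported to allow replication.",
    ),
)

CRITERIA_BY_ID = {c.id: c for c in CRITERIA}
_TITLES = {c.id: c.label.replace("_", " ").capitalize() for c in CRITERIA}


def _normalize_response(value: object, where: str) -> str:
    """Map tokens (incl. YAML booleans) to the closed response vocabulary."""
    if value is True:
        return YES
    if value is False:
        return NO
    if isinstance(value, str):
        token = value.strip().lower().replace(" ", "_").replace("-", "_")
        if token in RESPONSES:
            return token
        if token in {"na", "n/a", "notapplicable"}:
            return NOT_APPLICABLE
    raise ChecklistParseError(
        f"{where}: unknown response token {value!r} "
        f"(expected yes, no or not_applicable)"
    )


# everything str.splitlines() treats as a line break, incl. \x1c-\x1e
_LINE_BREAKS = re.compile("[\\n\\r\\x0b\\x0c\\x1c\\x1d\\x1e\\x85\\u2028\\u2029]")


def _normalize_text(text: object) -> str:
    """Collapse line breaks and runs of whitespace to single spaces so labels
    and comments survive the Markdown round-trip byte-for-byte; both are
    single-paragraph free text."""
    if text is None:
        return ""
    return re.sub(r"\s+", " ", _LINE_BREAKS.sub(" ", str(text))).strip()


@dataclass(frozen=True)
class CriterionEntry:
    """An author's answer to one criterion.

    ``manuscript_commented`` declares that an unmet criterion is also
    commented in the manuscript; it is self-declared (the tool cannot read the
    manuscript) and may be left undeclared (None), which ``validate`` flags
    for "no" responses.
    """

    id: int
    response: str
    comment: str = ""
    manuscript_commented: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.id not in CRITERIA_BY_ID:
            raise ChecklistParseError(f"unknown criterion id {self.id}")
        if self.response not in RESPONSES:
            raise ChecklistParseError(
                f"criterion {self.id}: unknown response {self.response!r}"
            )
        object.__setattr__(self, "comment", _normalize_text(self.comment))


@dataclass(frozen=True)
class ChecklistDoc:
    """One filled checklist — exactly one entry per criterion — for one CBMA
    within a manuscript, optionally carrying its study table."""

    analysis_label: str
    modality: str
    entries: tuple[CriterionEntry, ...]
    studies: Optional[tuple[StudyRecord, ...]] = None

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "analysis_label", _normalize_text(self.analysis_label)
        )
        if self.modality not in MODALITIES:
            raise ChecklistParseError(
                f"analysis {self.analysis_label!r}: unknown modality "
                f"{self.modality!r} (expected one of {MODALITIES})"
            )
        ids = [e.id for e in self.entries]
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        if dupes:
            raise ChecklistParseError(
                f"analysis {self.analysis_label!r}: duplicate criterion ids {dupes}"
            )
        missing = sorted(set(CRITERIA_BY_ID) - set(ids))
        if missing:
            raise ChecklistParseError(
                f"analysis {self.analysis_label!r}: missing criterion ids {missing}"
            )
        object.__setattr__(
            self, "entries", tuple(sorted(self.entries, key=lambda e: e.id))
        )
        if self.studies is not None:
            object.__setattr__(self, "studies", tuple(self.studies))

    def entry(self, criterion_id: int) -> CriterionEntry:
        return self.entries[criterion_id - 1]

    @property
    def responses(self) -> dict[int, str]:
        return {e.id: e.response for e in self.entries}


@dataclass(frozen=True)
class ValidationIssue:
    """One finding of ``validate``: errors break the document's invariants,
    warnings deserve author attention, notes flag unmet criteria."""

    criterion_id: Optional[int]
    severity: str  # "error" | "warning" | "note"
    message: str


@dataclass(frozen=True)
class Tally:
    """Per-criterion response counts over a collection of documents."""

    n_docs: int
    counts: dict[int, dict[str, int]]

    def to_frame(self):
        import pandas as pd

        rows = [
            {
                "criterion": cid,
                "label": CRITERIA_BY_ID[cid].label,
                **{r: self.counts[cid][r] for r in RESPONSES},
            }
            for cid in sorted(self.counts)
        ]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# loading

def _entry_from_mapping(cid_raw: object, raw: object, where: str) -> CriterionEntry:
    try:
        cid = int(cid_raw)  # type: ignore[arg-type]
    except (TypeError, ValueError):
        raise ChecklistParseError(f"{where}: criterion id {cid_raw!r} is not an integer")
    if cid not in CRITERIA_BY_ID:
        raise ChecklistParseError(f"{where}: unknown criterion id {cid}")
    if not isinstance(raw, dict):
        raise ChecklistParseError(f"{where}, criterion {cid}: entry must be a mapping")
    unknown = set(raw) - {"response", "comment", "manuscript_commented"}
    if unknown:
        raise ChecklistParseError(
            f"{where}, criterion {cid}: unknown fields {sorted(unknown)}"
        )
    if "response" not in raw:
        raise ChecklistParseError(f"{where}, criterion {cid}: missing response")
    mc = raw.get("manuscript_commented")
    if mc is not None and not isinstance(mc, bool):
        raise ChecklistParseError(
            f"{where}, criterion {cid}: manuscript_commented must be a boolean"
        )
    return CriterionEntry(
        id=cid,
        response=_normalize_response(raw["response"], f"{where}, criterion {cid}"),
        comment=raw.get("comment", ""),
        manuscript_commented=mc,
    )


def _study_from_mapping(raw: object, where: str) -> StudyRecord:
    if not isinstance(raw, dict):
        raise ChecklistParseError(f"{where}: study rows must be mappings")
    try:
        n2 = raw.get("n2")
        return StudyRecord(
            id=str(raw.get("id", "?")),
            design=str(raw.get("design", "")).replace("-", "_"),
            n1=int(raw["n1"]),
            n2=None if n2 in (None, "") else int(n2),
            has_map=bool(raw.get("has_map", False)),
        )
    except KeyError as exc:
        raise ChecklistParseError(f"{where}: study row missing field {exc}") from exc
    except ValueError as exc:
        raise ChecklistParseError(f"{where}: {exc}") from exc


def _doc_from_mapping(raw: object, where: str) -> ChecklistDoc:
    if not isinstance(raw, dict):
        raise ChecklistParseError(f"{where}: analysis must be a mapping")
    label = str(raw.get("analysis_label", raw.get("label", "unnamed")))
    modality = str(raw.get("modality", "other"))
    entries_raw = raw.get("entries")
    if not isinstance(entries_raw, dict) or not entries_raw:
        raise ChecklistParseError(
            f"{where} ({label!r}): 'entries' must be a mapping of criterion id "
            f"to response/comment"
        )
    entries = tuple(
        _entry_from_mapping(cid, entry, f"{where} ({label!r})")
        for cid, entry in entries_raw.items()
    )
    studies_raw = raw.get("studies")
    studies = None
    if studies_raw is not None:
        if not isinstance(studies_raw, list):
            raise ChecklistParseError(f"{where} ({label!r}): 'studies' must be a list")
        studies = tuple(
            _study_from_mapping(s, f"{where} ({label!r}), study row {i + 1}")
            for i, s in enumerate(studies_raw)
        )
    return ChecklistDoc(
        analysis_label=label, modality=modality, entries=entries, studies=studies
    )


def load_checklists(text: str) -> list[ChecklistDoc]:
    """Parse a checklist file (YAML, or the rendered Markdown) into documents.

    YAML files carry either a single analysis mapping or a top-level
    ``analyses:`` list — one document per individual CBMA. Parsing is atomic:
    any structural defect raises :class:`ChecklistParseError` naming the
    location.
    """
    if text.lstrip().startswith("# CBMA methodological-quality checklist:"):
        return [_parse_markdown(text)]
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ChecklistParseError(f"not valid YAML: {exc}") from exc
    if raw is None:
        raise ChecklistParseError("empty document")
    if isinstance(raw, dict) and "analyses" in raw:
        analyses = raw["analyses"]
        if not isinstance(analyses, list) or not analyses:
            raise ChecklistParseError("'analyses' must be a nonempty list")
        return [
            _doc_from_mapping(a, f"analysis {i + 1}") for i, a in enumerate(analyses)
        ]
    return [_doc_from_mapping(raw, "analysis 1")]


def load_checklist(text: str) -> ChecklistDoc:
    """Parse a file expected to contain exactly one checklist document."""
    docs = load_checklists(text)
    if len(docs) != 1:
        raise ChecklistParseError(
            f"expected exactly one analysis, found {len(docs)}"
        )
    return docs[0]


# ---------------------------------------------------------------------------
# validation

def validate(
    doc: ChecklistDoc,
    c12_config: Criterion12Config | None = None,
    power_spec: PowerSpec | None = None,
) -> list[ValidationIssue]:
    """Check a structurally valid document against the checklist's rules.

    Errors: empty comment; not-applicable outside criteria 5-6; a "no"
    response with no declaration about manuscript commenting. Warnings: a "no"
    explicitly declared *not* commented in the manuscript; a criterion-12
    response contradicting the attached study table (a warning, never an
    error — authors may justify contextually). Notes: every unmet criterion.
    """
    issues: list[ValidationIssue] = []
    for e in doc.entries:
        spec = CRITERIA_BY_ID[e.id]
        if not e.comment:
            issues.append(
                ValidationIssue(
                    e.id, "error",
                    f"criterion {e.id} ({spec.label}): comment is required",
                )
            )
        if e.response == NOT_APPLICABLE and not spec.allows_na:
            issues.append(
                ValidationIssue(
                    e.id, "error",
                    f"criterion {e.id} ({spec.label}): 'not applicable' is only "
                    f"allowed for criteria {sorted(NA_ALLOWED_IDS)}",
                )
            )
        if e.response == NO:
            issues.append(
                ValidationIssue(
                    e.id, "note",
                    f"criterion {e.id} ({spec.label}) is unmet; comment in the "
                    f"checklist and in the manuscript",
                )
            )
            if e.manuscript_commented is None:
                issues.append(
                    ValidationIssue(
                        e.id, "error",
                        f"criterion {e.id} ({spec.label}): unmet criteria must "
                        f"declare whether they are commented in the manuscript",
                    )
                )
            elif e.manuscript_commented is False:
                issues.append(
                    ValidationIssue(
                        e.id, "warning",
                        f"criterion {e.id} ({spec.label}) is unmet and declared "
                        f"not commented in the manuscript",
                    )
                )
    if doc.studies is not None:
        r12 = evaluate_criterion12(
            doc.studies, doc.modality, c12_config, power_spec
        )
        answered_yes = doc.entry(12).response == YES
        if answered_yes and not r12.passed:
            issues.append(
                ValidationIssue(
                    12, "warning",
                    f"criterion 12 answered 'yes' but the attached study table "
                    f"has {r12.raw} datasets (adjusted {r12.adjusted:.2f}), below "
                    f"the threshold of {r12.threshold}",
                )
            )
        elif doc.entry(12).response == NO and r12.passed:
            issues.append(
                ValidationIssue(
                    12, "warning",
                    f"criterion 12 answered 'no' but the attached study table "
                    f"has {r12.raw} datasets (adjusted {r12.adjusted:.2f}), "
                    f"meeting the threshold of {r12.threshold}",
                )
            )
    return issues


def issues_to_json(issues: Sequence[ValidationIssue]) -> str:
    """Machine-readable validation report."""
    payload = {
        "n_errors": sum(i.severity == "error" for i in issues),
        "n_warnings": sum(i.severity == "warning" for i in issues),
        "n_notes": sum(i.severity == "note" for i in issues),
        "issues": [
            {
                "criterion_id": i.criterion_id,
                "severity": i.severity,
                "message": i.message,
            }
            for i in issues
        ],
    }
    return json.dumps(payload, indent=2)


# ---------------------------------------------------------------------------
# rendering (Markdown) and its inverse

_RESPONSE_BOX = {YES: "☑ Yes", NO: "☑ No", NOT_APPLICABLE: "☑ Not applicable"}
_BOX_RESPONSE = {v: k for k, v in _RESPONSE_BOX.items()}


def render_markdown(doc: ChecklistDoc) -> str:
    """Render a document as a checklist table readers can review.

    The output is deterministic and lossless: ``load_checklist`` parses it
    back to an identical document (responses, comments, declarations, study
    table), so render -> load -> render is byte-identical.
    """
    lines = [
        f"# CBMA methodological-quality checklist: {doc.analysis_label}",
        "",
        f"- Modality: {doc.modality}",
        "",
    ]
    for e in doc.entries:
        spec = CRITERIA_BY_ID[e.id]
        lines.append(f"## {e.id}. {_TITLES[e.id]}")
        lines.append("")
        lines.append(f"> {spec.prompt}")
        lines.append("")
        lines.append(f"- Response: {_RESPONSE_BOX[e.response]}")
        if e.manuscript_commented is not None:
            lines.append(
                "- Commented in manuscript: "
                + ("yes" if e.manuscript_commented else "no")
            )
        lines.append(f"- Comment: {e.comment}")
        lines.append("")
    if doc.studies is not None:
        lines.append("## Attached study table")
        lines.append("")
        lines.append("| id | design | n1 | n2 | has_map |")
        lines.append("|---|---|---|---|---|")
        for s in doc.studies:
            n2 = "" if s.n2 is None else str(s.n2)
            lines.append(
                f"| {s.id} | {s.design} | {s.n1} | {n2} | "
                f"{'yes' if s.has_map else 'no'} |"
            )
        lines.append("")
    return "\n".join(lines)


_MD_HEADER = re.compile(r"^# CBMA methodological-quality checklist: (?P<label>.*)$")
_MD_CRIT = re.compile(r"^## (?P<id>\d+)\. ")


def _parse_markdown(text: str) -> ChecklistDoc:
    lines = text.splitlines()
    label = None
    modality = "other"
    entries: list[CriterionEntry] = []
    studies: Optional[list[StudyRecord]] = None
    current: Optional[dict] = None
    in_studies = False

    def flush() -> None:
        nonlocal current
        if current is None:
            return
        if "response" not in current:
            raise ChecklistParseError(
                f"criterion {current['id']}: missing Response line"
            )
        entries.append(
            CriterionEntry(
                id=current["id"],
                response=current["response"],
                comment=current.get("comment", ""),
                manuscript_commented=current.get("manuscript_commented"),
            )
        )
        current = None

    for lineno, line in enumerate(lines, start=1):
        where = f"line {lineno}"
        m = _MD_HEADER.match(line)
        if m:
            label = m.group("label")
            continue
        m = _MD_CRIT.match(line)
        if m:
            flush()
            in_studies = False
            current = {"id": int(m.group("id"))}
            continue
        if line.startswith("## Attached study table"):
            flush()
            in_studies = True
            studies = []
            continue
        if line.startswith("- Modality: "):
            modality = line.removeprefix("- Modality: ").strip()
            continue
        if current is not None:
            if line.startswith("- Response: "):
                box = line.removeprefix("- Response: ").strip()
                if box not in _BOX_RESPONSE:
                    raise ChecklistParseError(
                        f"{where}: unknown response token {box!r}"
                    )
                current["response"] = _BOX_RESPONSE[box]
            elif line.startswith("- Commented in manuscript: "):
                token = line.removeprefix("- Commented in manuscript: ").strip()
                if token not in {"yes", "no"}:
                    raise ChecklistParseError(
                        f"{where}: manuscript declaration must be yes or no"
                    )
                current["manuscript_commented"] = token == "yes"
            elif line.startswith("- Comment: "):
                current["comment"] = line.removeprefix("- Comment: ")
        elif in_studies and line.startswith("|") and not set(line) <= {"|", "-", " "}:
            cells = [c.strip() for c in line.strip().strip("|").split("|")]
            if cells[0] == "id":  # table header
                continue
            if len(cells) != 5:
                raise ChecklistParseError(f"{where}: malformed study row")
            try:
                studies.append(  # type: ignore[union-attr]
                    StudyRecord(
                        id=cells[0],
                        design=cells[1],
                        n1=int(cells[2]),
                        n2=int(cells[3]) if cells[3] else None,
                        has_map=cells[4] == "yes",
                    )
                )
            except ValueError as exc:
                raise ChecklistParseError(f"{where}: {exc}") from exc
    flush()
    if label is None:
        raise ChecklistParseError("missing checklist title line")
    return ChecklistDoc(
        analysis_label=label,
        modality=modality,
        entries=tuple(entries),
        studies=tuple(studies) if studies is not None else None,
    )


# ---------------------------------------------------------------------------
# aggregation

def tally(docs: Iterable[ChecklistDoc]) -> Tally:
    """Count responses per criterion across documents (order-invariant).

    Member documents must be free of validation *errors*; an invalid member
    raises a ValueError naming it. Counts are for meta-research on reporting
    practices, never a quality score.
    """
    docs = list(docs)
    counters = {cid: Counter() for cid in CRITERIA_BY_ID}
    for doc in docs:
        errors = [i for i in validate(doc) if i.severity == "error"]
        if errors:
            raise ValueError(
                f"document {doc.analysis_label!r} has validation errors: "
                f"{errors[0].message}"
            )
        for e in doc.entries:
            counters[e.id][e.response] += 1
    return Tally(
        n_docs=len(docs),
        counts={
            cid: {r: counters[cid].get(r, 0) for r in RESPONSES}
            for cid in CRITERIA_BY_ID
        },
    )


def checklist_json_schema() -> dict:
    """JSON schema of the YAML document format (published alongside)."""
    entry_schema = {
        "type": "object",
        "required": ["response"],
        "additionalProperties": False,
        "properties": {
            "response": {"enum": list(RESPONSES)},
            "comment": {"type": "string"},
            "manuscript_commented": {"type": "boolean"},
        },
    }
    analysis_schema = {
        "type": "object",
        "required": ["entries"],
        "properties": {
            "analysis_label": {"type": "string"},
            "modality": {"enum": list(MODALITIES)},
            "entries": {
                "type": "object",
                "minProperties": 15,
                "maxProperties": 15,
                "propertyNames": {"pattern": r"^([1-9]|1[0-5])$"},
                "additionalProperties": entry_schema,
            },
            "studies": {
                "type": "array",
                "items": {
                    "type": "object",
                    "required": ["id", "design", "n1"],
                    "properties": {
                        "id": {"type": "string"},
                        "design": {"enum": ["one_sample", "two_sample"]},
                        "n1": {"type": "integer", "minimum": 2},
                        "n2": {"type": ["integer", "null"], "minimum": 2},
                        "has_map": {"type": "boolean"},
                    },
                },
            },
        },
    }
    return {
        "$schema": "https://json-schema.org/draft/2020-12/schema",
        "title": "CBMA methodological-quality checklist",
        "oneOf": [
            analysis_schema,
            {
                "type": "object",
                "required": ["analyses"],
                "properties": {
                    "analyses": {"type": "array", "items": analysis_schema}
                },
            },
        ],
    }
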