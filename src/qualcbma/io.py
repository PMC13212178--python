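"""File plumbing: study-table CSV readers/writers and fixture generation.

Study tables are plain CSV with columns ``id, design, n1, n2, has_map``
(header required; ``n2`` empty on one-sample rows). Parse errors carry the
offending row number. Fixture generation is deterministic given its seed and
exists so tests and demos never need binary data files.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .power import ONE_SAMPLE, TWO_SAMPLE, StudyRecord

__all__ = [
    "FixtureSpec",
    "read_study_table",
    "write_study_table",
    "example_checklist_text",
    "generate_fixture",
    "STUDY_TABLE_COLUMNS",
]

STUDY_TABLE_COLUMNS = ("id", "design", "n1", "n2", "has_map")

_TRUE_TOKENS = {"true", "yes", "1", "y"}
_FALSE_TOKENS = {"false", "no", "0", "n", ""}


def _parse_bool(token: str, where: str) -> bool:
    t = token.strip().lower()
    if t in _TRUE_TOKENS:
        return True
    if t in _FALSE_TOKENS:
        return False
    raise ValueError(f"{where}: has_map must be a boolean token, got {token!r}")


def _parse_int(token: str, where: str, fieldname: str) -> int:
    t = token.strip()
    try:
        return int(t)
    except ValueError:
        raise ValueError(
            f"{where}: {fieldname} must be an integer, got {token!r}"
        ) from None


def read_study_table(source: Union[str, Path, _io.TextIOBase]) -> list[StudyRecord]:
    """Read a study-table CSV into validated records.

    Row numbers in error messages count the header as line 1, so the first
    data row is row 2 — matching what a spreadsheet shows.
    """
    df = pd.read_csv(source, dtype=str, keep_default_na=False, comment="#")
    missing = [c for c in STUDY_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"study table is missing columns {missing}")
    records = []
    for i, row in df.iterrows():
        where = f"row {i + 2}"
        design = row["design"].strip().replace("-", "_")
        n2_raw = row["n2"].strip()
        if design == ONE_SAMPLE and n2_raw:
            raise ValueError(
                f"{where} (id {row['id']!r}): one-sample rows must leave n2 empty"
            )
        if design == TWO_SAMPLE and not n2_raw:
            raise ValueError(
                f"{where} (id {row['id']!r}): two-sample rows require n2"
            )
        try:
            records.append(
                StudyRecord(
                    id=row["id"].strip(),
                    design=design,
                    n1=_parse_int(row["n1"], where, "n1"),
                    n2=_parse_int(n2_raw, where, "n2") if n2_raw else None,
                    has_map=_parse_bool(row["has_map"], where),
                )
            )
        except ValueError as exc:
            raise ValueError(f"{where}: {exc}") from None
    return records


def write_study_table(
    records: Sequence[StudyRecord],
    path: Union[str, Path, None] = None,
) -> str:
    """Serialize records to study-table CSV; returns the text, and writes it
    to ``path`` when given."""
    lines = [",".join(STUDY_TABLE_COLUMNS)]
    for r in records:
        n2 = "" if r.n2 is None else str(r.n2)
        lines.append(
            f"{r.id},{r.design},{r.n1},{n2},{'true' if r.has_map else 'false'}"
        )
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def example_checklist_text() -> str:
    """The packaged worked-example checklist document (YAML)."""
    return (
        resources.files("qualcbma") / "data" / "example_checklist.yaml"
    ).read_text()


@dataclass(frozen=True)
class FixtureSpec:
    """What to generate: a checklist document, a study table, or a small grid
    of simulation cells. Deterministic given ``seed``."""

    kind: str  # "checklist_doc" | "study_table" | "sim_cells"
    seed: int = 0
    # checklist_doc
    pattern: str = "example"  # "example" | "random"
    # study_table
    n_studies: int = 17
    design: str = ONE_SAMPLE  # or "two_sample" or "mixed"
    n_fixed: Optional[int] = 20
    n_range: tuple[int, int] = (10, 40)
    map_fraction: float = 0.0


def _random_checklist(rng: np.random.Generator) -> str:
    from . import checklist as cl

    lines = ["analyses:", "- analysis_label: synthetic", "  modality: other",
             "  entries:"]
    for spec in cl.CRITERIA:
        opts = ["yes", "no"] + (["not_applicable"] if spec.allows_na else [])
        response = opts[rng.integers(len(opts))]
        lines.append(f"    {spec.id}:")
        lines.append(f'      response: "{response}"')
        lines.append(f'      comment: "Synthetic response for {spec.label}."')
        if response == "no":
            lines.append("      manuscript_commented: true")
    return "\n".join(lines) + "\n"


def _random_study_table(spec: FixtureSpec, rng: np.random.Generator) -> str:
    records = []
    for i in range(spec.n_studies):
        if spec.design == "mixed":
            design = ONE_SAMPLE if rng.random() < 0.5 else TWO_SAMPLE
        else:
            design = spec.design
        if spec.n_fixed is not None:
            n1 = spec.n_fixed
        else:
            n1 = int(rng.integers(spec.n_range[0], spec.n_range[1] + 1))
        n2 = None
        if design == TWO_SAMPLE:
            n2 = n1 if spec.n_fixed is not None else int(
                rng.integers(spec.n_range[0], spec.n_range[1] + 1)
            )
        records.append(
            StudyRecord(
                id=f"study{i + 1:02d}",
                design=design,
                n1=n1,
                n2=n2,
                has_map=bool(rng.random() < spec.map_fraction),
            )
        )
    return write_study_table(records)


def generate_fixture(spec: FixtureSpec) -> dict[str, str]:
    """Generate fixture file(s) as {filename: text}; deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    if spec.kind == "checklist_doc":
        if spec.pattern == "example":
            return {"example_checklist.yaml": example_checklist_text()}
        if spec.pattern == "random":
            return {"random_checklist.yaml": _random_checklist(rng)}
        raise ValueError(f"unknown checklist pattern {spec.pattern!r}")
    if spec.kind == "study_table":
        return {"study_table.csv": _random_study_table(spec, rng)}
    if spec.kind == "sim_cells":
        from .infosim import SimConfig, cells_to_frame, run_information_grid

        config = SimConfig(
            k_values=(5, 8), d_values=(0.8,), reps=5, seed=spec.seed
        )
        df = cells_to_frame(run_information_grid(config))
        buf = _io.StringIO()
        buf.write(f"# seed={spec.seed}\n")
        df.to_csv(buf, index=False)
        return {"sim_cells.csv": buf.getvalue()}
    raise ValueError(f"unknown fixture kind {spec.kind!r}")
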