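"""Compound annotation table: identities, C-max exposure anchors, and DILI labels.

The screen's compound set is shipped as a packaged CSV with one row per
compound: name, abbreviation, peak plasma concentration (C-max, µM), the FDA
DILI-concern label (no / ambiguous / less / most), the derived two-class
severity label (severe / non-severe), and an eight-level hepatotoxicity class.
Vehicle and pathway-positive controls (DMSO, TNFα, DEM, thapsigargin,
etoposide) carry the ``control`` label and no C-max.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd

DILI_CONCERN_LEVELS = ("no", "ambiguous", "less", "most", "control")
SEVERITY_LEVELS = ("severe", "non_severe", "control")

#: severity grouping: most-concern drugs are the 'severe' class, every other
#: labelled drug is 'non-severe'; controls stay out of both classes.
_SEVERITY_FROM_CONCERN = {
    "most": "severe",
    "no": "non_severe",
    "less": "non_severe",
    "ambiguous": "non_severe",
    "control": "control",
}

_COLUMNS = [
    "name",
    "abbreviation",
    "cmax_uM",
    "dili_concern",
    "severity",
    "hepatotox_class",
    "is_control",
]


class AnnotationError(ValueError):
    """Raised when an annotation table violates the schema or its invariants."""


@dataclass(frozen=True)
class CompoundAnnotation:
    """One compound of the screen with its exposure anchor and DILI labels."""

    name: str
    abbreviation: str
    cmax_uM: float | None
    dili_concern: str
    severity: str
    hepatotox_class: int | None
    is_control: bool

    def __post_init__(self) -> None:
        if self.dili_concern not in DILI_CONCERN_LEVELS:
            raise AnnotationError(
                f"{self.abbreviation}: unknown dili_concern {self.dili_concern!r}"
            )
        if self.severity != assign_severity(self.dili_concern):
            raise AnnotationError(
                f"{self.abbreviation}: severity {self.severity!r} inconsistent "
                f"with dili_concern {self.dili_concern!r}"
            )
        if self.is_control != (self.dili_concern == "control"):
            raise AnnotationError(
                f"{self.abbreviation}: is_control flag inconsistent with label"
            )
        if self.cmax_uM is not None and not self.cmax_uM > 0:
            raise AnnotationError(f"{self.abbreviation}: cmax_uM must be positive")
        if not self.is_control and self.cmax_uM is None:
            raise AnnotationError(f"{self.abbreviation}: non-control lacks cmax_uM")
        if self.hepatotox_class is not None and not 1 <= self.hepatotox_class <= 8:
            raise AnnotationError(
                f"{self.abbreviation}: hepatotox_class outside 1-8"
            )


def assign_severity(dili_concern: str) -> str:
    """Map a DILI-concern label onto the two-class severity label.

    ``most`` becomes ``severe``; ``no``/``less``/``ambiguous`` are grouped as
    ``non_severe``; ``control`` stays ``control``.
    """
    try:
        return _SEVERITY_FROM_CONCERN[dili_concern]
    except KeyError:
        raise AnnotationError(f"unknown dili_concern token {dili_concern!r}") from None


def _parse_row(row: pd.Series, idx: int) -> CompoundAnnotation:
    def _missing(v) -> bool:
        return v is None or (isinstance(v, float) and math.isnan(v)) or v == ""

    try:
        cmax = None if _missing(row["cmax_uM"]) else float(row["cmax_uM"])
        hep = None if _missing(row["hepatotox_class"]) else int(float(row["hepatotox_class"]))
        is_control = str(row["is_control"]).strip().lower() in ("true", "1", "yes")
        return CompoundAnnotation(
            name=str(row["name"]),
            abbreviation=str(row["abbreviation"]),
            cmax_uM=cmax,
            dili_concern=str(row["dili_concern"]),
            severity=str(row["severity"]),
            hepatotox_class=hep,
            is_control=is_control,
        )
    except AnnotationError as exc:
        raise AnnotationError(f"row {idx}: {exc}") from None


def read_compound_table(path: str | Path) -> list[CompoundAnnotation]:
    """Read and validate a compound annotation CSV.

    Rows are returned in file order. Duplicate abbreviations, unknown label
    tokens, and label inconsistencies raise :class:`AnnotationError` naming the
    offending row.
    """
    df = pd.read_csv(path, dtype={"name": str, "abbreviation": str})
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise AnnotationError(f"missing columns: {missing}")
    annotations = [_parse_row(row, i + 2) for i, (_, row) in enumerate(df.iterrows())]
    counts = Counter(a.abbreviation for a in annotations)
    dupes = sorted(a for a, n in counts.items() if n > 1)
    if dupes:
        raise AnnotationError(f"duplicate abbreviations: {dupes}")
    return annotations


def write_compound_table(annotations: Iterable[CompoundAnnotation], path: str | Path) -> None:
    """Write annotations back to CSV in the packaged schema (round-trip safe)."""
    df = to_frame(list(annotations))
    out = df.copy()
    out["cmax_uM"] = out["cmax_uM"].map(
        lambda v: "" if pd.isna(v) else f"{v:g}"
    )
    out["hepatotox_class"] = out["hepatotox_class"].map(
        lambda v: "" if pd.isna(v) else str(int(v))
    )
    out["is_control"] = out["is_control"].map(lambda v: "true" if v else "false")
    out.to_csv(path, index=False)


def to_frame(annotations: list[CompoundAnnotation]) -> pd.DataFrame:
    """Annotation list as a DataFrame with one row per compound."""
    return pd.DataFrame(
        [
            {
                "name": a.name,
                "abbreviation": a.abbreviation,
                "cmax_uM": a.cmax_uM,
                "dili_concern": a.dili_concern,
                "severity": a.severity,
                "hepatotox_class": a.hepatotox_class,
                "is_control": a.is_control,
            }
            for a in annotations
        ],
        columns=_COLUMNS,
    )


def class_counts(annotations: list[CompoundAnnotation]) -> dict[str, dict[str, int]]:
    """Counts per DILI-concern label and per derived severity label."""
    concern = Counter(a.dili_concern for a in annotations)
    severity = Counter(a.severity for a in annotations)
    return {
        "dili_concern": {k: concern.get(k, 0) for k in DILI_CONCERN_LEVELS},
        "severity": {k: severity.get(k, 0) for k in SEVERITY_LEVELS},
    }


def packaged_annotation_path() -> Path:
    """Filesystem path of the packaged compound table."""
    return Path(resources.files("stressdyn").joinpath("data/compound_annotations.csv"))


def load_packaged_annotations() -> list[CompoundAnnotation]:
    """Load the packaged screen compound set (123 rows, 118 labelled drugs)."""
    return read_compound_table(packaged_annotation_path())
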