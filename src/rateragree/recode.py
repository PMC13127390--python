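"""Category merges, dichotomizations, and anchor-score case subsets.

Two families of derived analyses are supported:

* **Recoding** — mapping the ordered categories onto a coarser schema, such
  as merging 1+ and 2+ into a single "low" category, or any of the six
  clinically motivated binary splits (0 vs. not 0, <2+ vs. >=2+, ...).
* **Subsetting** — restricting to the cases that received a given anchor
  score from at least one observer ("X only" subsets).  Subset statistics
  are computed on the original category codes, since all categories remain
  present within every such subset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import CategorySchema, HER2_SCHEMA, ScoreMatrix, to_count_table

__all__ = [
    "RecodeMap",
    "SubsetSpec",
    "EmptySubsetError",
    "BUILTIN_RECODES",
    "builtin_recode",
    "recode",
    "recode_map_from_json",
    "select_subset",
    "subset_mask",
    "subset_rating_counts",
    "subset_case_cooccurrence",
]


class EmptySubsetError(ValueError):
    """No case received the anchor score from any observer."""


@dataclass(frozen=True)
class RecodeMap:
    """A total mapping from one category schema onto a coarser one.

    ``mapping`` sends every input code to an output code of ``out_schema``.
    """

    name: str
    mapping: dict[int, int]
    out_schema: CategorySchema

    def __post_init__(self) -> None:
        out_codes = set(self.out_schema.codes)
        for src, dst in self.mapping.items():
            if dst not in out_codes:
                raise ValueError(
                    f"recode map {self.name!r}: output code {dst} (from {src}) "
                    f"not in output schema {self.out_schema.codes}"
                )


@dataclass(frozen=True)
class SubsetSpec:
    """Cases that received ``anchor_code`` from at least one observer."""

    anchor_code: int

    def name(self, schema: CategorySchema) -> str:
        return f"{schema.label_of(self.anchor_code)} only"


def _binary(name: str, positive_label: str, positive_codes: set[int]) -> RecodeMap:
    out = CategorySchema(labels=(positive_label, f"not {positive_label}"))
    mapping = {c: (0 if c in positive_codes else 1) for c in HER2_SCHEMA.codes}
    return RecodeMap(name=name, mapping=mapping, out_schema=out)


#: Built-in recodings of the 4-category HER2 schema, addressable by name.
BUILTIN_RECODES: dict[str, RecodeMap] = {
    "three_cat": RecodeMap(
        name="three_cat",
        mapping={0: 0, 1: 1, 2: 1, 3: 2},
        out_schema=CategorySchema(labels=("0", "low", "3+")),
    ),
    "0_vs_not0": _binary("0_vs_not0", "0", {0}),
    "1_vs_not1": _binary("1_vs_not1", "1+", {1}),
    "2_vs_not2": _binary("2_vs_not2", "2+", {2}),
    "low_vs_notlow": _binary("low_vs_notlow", "low", {1, 2}),
    "3_vs_not3": _binary("3_vs_not3", "3+", {3}),
    "lt2_vs_ge2": RecodeMap(
        name="lt2_vs_ge2",
        mapping={0: 0, 1: 0, 2: 1, 3: 1},
        out_schema=CategorySchema(labels=("<2+", ">=2+")),
    ),
    "identity": RecodeMap(
        name="identity",
        mapping={c: c for c in HER2_SCHEMA.codes},
        out_schema=HER2_SCHEMA,
    ),
}


def builtin_recode(name: str) -> RecodeMap:
    try:
        return BUILTIN_RECODES[name]
    except KeyError:
        raise KeyError(
            f"unknown recode map {name!r}; available: {sorted(BUILTIN_RECODES)}"
        ) from None


def recode_map_from_json(obj: str | Path | dict, schema: CategorySchema = HER2_SCHEMA) -> RecodeMap:
    """Build a RecodeMap from ``{"name": ..., "mapping": {label: label}}``.

    Output categories are ordered by first appearance over the input codes
    in schema order.
    """
    if not isinstance(obj, dict):
        obj = json.loads(Path(obj).read_text())
    raw = obj["mapping"]
    out_labels: list[str] = []
    mapping: dict[int, int] = {}
    for code, label in zip(schema.codes, schema.labels):
        key = label if label in raw else str(code)
        if key not in raw:
            raise ValueError(f"recode map {obj.get('name')!r} does not map category {label!r}")
        dst = str(raw[key])
        if dst not in out_labels:
            out_labels.append(dst)
        mapping[code] = out_labels.index(dst)
    return RecodeMap(
        name=str(obj.get("name", "custom")),
        mapping=mapping,
        out_schema=CategorySchema(labels=tuple(out_labels)),
    )


def recode(m: ScoreMatrix, rmap: RecodeMap) -> ScoreMatrix:
    """Apply a recode map cell-wise; identifiers and metadata are preserved."""
    present = set(np.unique(m.scores).tolist())
    unmapped = present - set(rmap.mapping)
    if unmapped:
        raise ValueError(
            f"recode map {rmap.name!r} does not cover categories {sorted(unmapped)} "
            "present in the matrix"
        )
    lut = np.full(max(rmap.mapping) + 1, -1, dtype=int)
    for src, dst in rmap.mapping.items():
        lut[src] = dst
    return ScoreMatrix(
        case_ids=list(m.case_ids),
        observer_ids=list(m.observer_ids),
        scores=lut[m.scores],
        schema=rmap.out_schema,
        case_meta=m.case_meta,
        observer_meta=m.observer_meta,
    )


def subset_mask(m: ScoreMatrix, spec: SubsetSpec) -> np.ndarray:
    """Boolean case mask: at least one observer assigned the anchor score."""
    m.schema.index_of(spec.anchor_code)  # validates the anchor
    return (m.scores == spec.anchor_code).any(axis=1)


def select_subset(m: ScoreMatrix, spec: SubsetSpec) -> ScoreMatrix:
    """Restrict to the anchor's cases; original category codes are kept."""
    mask = subset_mask(m, spec)
    if not mask.any():
        raise EmptySubsetError(
            f"no case received score {m.schema.label_of(spec.anchor_code)!r} "
            "from any observer"
        )
    return m.select_cases(mask)


def subset_rating_counts(m: ScoreMatrix, anchors: list[SubsetSpec]) -> pd.DataFrame:
    """Per-subset tally of all ratings, one row per anchor.

    Each row counts, within the anchor's case subset, how many of the
    R x |subset| individual ratings fell in each category; the trailing
    column holds that total.  Empty subsets yield a zero row.
    """
    rows = []
    index = []
    for spec in anchors:
        index.append(spec.name(m.schema))
        mask = subset_mask(m, spec)
        if not mask.any():
            rows.append([0] * (m.schema.n_categories + 1))
            continue
        counts = to_count_table(m.select_cases(mask)).counts.sum(axis=0)
        rows.append(list(counts) + [int(counts.sum())])
    columns = [f"{label} counts" for label in m.schema.labels] + ["Total Ratings"]
    return pd.DataFrame(rows, index=index, columns=columns)


def subset_case_cooccurrence(m: ScoreMatrix, anchors: list[SubsetSpec]) -> pd.DataFrame:
    """Case co-occurrence between anchor subsets.

    Entry (a, b) counts the cases that received both anchor a and anchor b
    from at least one observer each; the diagonal holds subset sizes and the
    table is symmetric.  A trailing column repeats the subset size.
    """
    masks = [subset_mask(m, spec) for spec in anchors]
    index = [spec.name(m.schema) for spec in anchors]
    grid = np.array([[int((ma & mb).sum()) for mb in masks] for ma in masks])
    out = pd.DataFrame(grid, index=index, columns=[f"{m.schema.label_of(s.anchor_code)} counts" for s in anchors])
    out["Total Cases"] = [int(ma.sum()) for ma in masks]
    return out
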