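"""Core containers for case x observer panels of ordinal categorical scores.

The central object is the :class:`ScoreMatrix`: a complete N x R grid in
which every one of R observers has assigned one of C ordered categories to
every one of N cases.  HER2 immunohistochemistry panels (categories
``0 < 1+ < 2+ < 3+``) are the motivating application, but nothing here is
specific to that assay.

All downstream agreement statistics (overall percent agreement, Fleiss'
kappa, intraclass correlation) are functions of either the raw grid or of
its sufficient statistic, the :class:`CategoryCountTable` of per-case
category counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CategorySchema",
    "ScoreMatrix",
    "CategoryCountTable",
    "HER2_SCHEMA",
    "to_count_table",
    "rater_marginals",
    "case_vote_profile",
]


class SchemaError(ValueError):
    """Raised when a category schema or a score violates it."""


@dataclass(frozen=True)
class CategorySchema:
    """An ordered set of score categories with integer codes.

    Parameters
    ----------
    labels:
        Category names in rank order, e.g. ``("0", "1+", "2+", "3+")``.
    codes:
        Strictly increasing integer code per label.  When omitted, labels
        are coded ``0 .. C-1``.  The codes double as the numeric values the
        categories take in the ICC ANOVA.
    """

    labels: tuple[str, ...]
    codes: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        labels = tuple(str(x) for x in self.labels)
        codes = tuple(int(c) for c in (self.codes or range(len(labels))))
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "codes", codes)
        if len(labels) < 2:
            raise SchemaError("a schema needs at least 2 categories")
        if len(set(labels)) != len(labels):
            raise SchemaError(f"duplicate category labels: {labels}")
        if len(codes) != len(labels):
            raise SchemaError("labels and codes must have equal length")
        if any(b <= a for a, b in zip(codes, codes[1:])):
            raise SchemaError(f"codes must be strictly increasing: {codes}")

    @property
    def n_categories(self) -> int:
        return len(self.labels)

    def code_of(self, token: str) -> int:
        """Map a cell token (label or numeric-code string) to its code."""
        token = str(token).strip()
        if token in self.labels:
            return self.codes[self.labels.index(token)]
        try:
            value = int(token)
        except ValueError:
            raise SchemaError(f"unknown category token {token!r}") from None
        if value in self.codes:
            return value
        raise SchemaError(f"unknown category token {token!r}")

    def label_of(self, code: int) -> str:
        try:
            return self.labels[self.codes.index(int(code))]
        except ValueError:
            raise SchemaError(f"code {code} not in schema {self.codes}") from None

    def index_of(self, code: int) -> int:
        """Position of a code in the ordered category list."""
        try:
            return self.codes.index(int(code))
        except ValueError:
            raise SchemaError(f"code {code} not in schema {self.codes}") from None


#: The HER2 immunohistochemistry scoring schema: 0 < 1+ < 2+ < 3+.
HER2_SCHEMA = CategorySchema(labels=("0", "1+", "2+", "3+"))


@dataclass
class ScoreMatrix:
    """A complete case x observer grid of category codes.

    ``scores[i, r]`` is the code observer ``observer_ids[r]`` assigned to
    case ``case_ids[i]``.  Missing cells are not representable: the study
    designs this package targets are balanced (every observer scores every
    case), and every formula downstream assumes it.

    ``case_meta`` / ``observer_meta`` are optional one-column annotations:
    specimen type per case (e.g. ``"biopsy"`` / ``"surgical"``) and
    experience stratum per observer (e.g. ``"senior"`` / ``"junior"``).
    """

    case_ids: list[str]
    observer_ids: list[str]
    scores: np.ndarray
    schema: CategorySchema = HER2_SCHEMA
    case_meta: dict[str, str] | None = None
    observer_meta: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.case_ids = [str(c) for c in self.case_ids]
        self.observer_ids = [str(o) for o in self.observer_ids]
        self.scores = np.asarray(self.scores, dtype=int)
        n, r = self.scores.shape
        if n != len(self.case_ids):
            raise ValueError("scores row count does not match case_ids")
        if r != len(self.observer_ids):
            raise ValueError("scores column count does not match observer_ids")
        if n < 1:
            raise ValueError("need at least one case")
        if r < 2:
            raise ValueError("need at least two observers")
        if len(set(self.case_ids)) != n:
            raise ValueError("duplicate case identifiers")
        if len(set(self.observer_ids)) != r:
            raise ValueError("duplicate observer identifiers")
        valid = np.isin(self.scores, self.schema.codes)
        if not valid.all():
            i, j = np.argwhere(~valid)[0]
            raise SchemaError(
                f"invalid score {self.scores[i, j]} for case "
                f"{self.case_ids[i]!r}, observer {self.observer_ids[j]!r}"
            )

    @property
    def n_cases(self) -> int:
        return self.scores.shape[0]

    @property
    def n_observers(self) -> int:
        return self.scores.shape[1]

    def to_frame(self, labels: bool = True) -> pd.DataFrame:
        """Return the grid as a DataFrame (cases x observers)."""
        if labels:
            lut = {c: l for c, l in zip(self.schema.codes, self.schema.labels)}
            data = np.vectorize(lut.get)(self.scores)
        else:
            data = self.scores
        return pd.DataFrame(data, index=self.case_ids, columns=self.observer_ids)

    def select_cases(self, mask: np.ndarray) -> "ScoreMatrix":
        """Restrict to the cases where ``mask`` is True, preserving order."""
        mask = np.asarray(mask, dtype=bool)
        kept = [c for c, m in zip(self.case_ids, mask) if m]
        meta = None
        if self.case_meta is not None:
            meta = {c: self.case_meta[c] for c in kept if c in self.case_meta}
        return ScoreMatrix(
            case_ids=kept,
            observer_ids=list(self.observer_ids),
            scores=self.scores[mask],
            schema=self.schema,
            case_meta=meta,
            observer_meta=self.observer_meta,
        )

    def select_observers(self, keep: Sequence[str]) -> "ScoreMatrix":
        """Restrict to the named observers, in the given order."""
        idx = [self.observer_ids.index(str(o)) for o in keep]
        meta = None
        if self.observer_meta is not None:
            meta = {o: self.observer_meta[o] for o in keep if o in self.observer_meta}
        return ScoreMatrix(
            case_ids=list(self.case_ids),
            observer_ids=[self.observer_ids[i] for i in idx],
            scores=self.scores[:, idx],
            schema=self.schema,
            case_meta=self.case_meta,
            observer_meta=meta,
        )


@dataclass
class CategoryCountTable:
    """Per-case category counts ``n_ij`` (cases x categories).

    ``counts[i, j]`` is the number of observers assigning case ``i`` the
    j-th category of the schema.  Every row sums to the panel size R; this
    table is the sufficient statistic for OPA and Fleiss' kappa.
    """

    counts: np.ndarray
    schema: CategorySchema
    case_ids: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-dimensional")
        if self.counts.shape[1] != self.schema.n_categories:
            raise ValueError("counts column count does not match schema")
        if (self.counts < 0).any():
            raise ValueError("negative counts")
        sums = self.counts.sum(axis=1)
        if len(set(sums.tolist())) > 1:
            raise ValueError("unbalanced rows: all cases must have equal ratings")

    @property
    def n_raters(self) -> int:
        return int(self.counts[0].sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.case_ids, columns=self.schema.labels)


def to_count_table(m: ScoreMatrix) -> CategoryCountTable:
    """Tally, per case, how many observers assigned each category."""
    positions = np.searchsorted(m.schema.codes, m.scores)
    counts = np.zeros((m.n_cases, m.schema.n_categories), dtype=int)
    for j in range(m.schema.n_categories):
        counts[:, j] = (positions == j).sum(axis=1)
    return CategoryCountTable(counts=counts, schema=m.schema, case_ids=list(m.case_ids))


def rater_marginals(m: ScoreMatrix) -> pd.DataFrame:
    """Per-observer category proportions (observers x categories).

    Each row sums to 1; row order follows ``observer_ids``.  This is the
    data behind per-rater score-distribution stacked bars.
    """
    positions = np.searchsorted(m.schema.codes, m.scores)
    props = np.stack(
        [(positions == j).mean(axis=0) for j in range(m.schema.n_categories)], axis=1
    )
    return pd.DataFrame(props, index=m.observer_ids, columns=m.schema.labels)


def case_vote_profile(m: ScoreMatrix) -> pd.DataFrame:
    """Per-case category proportions plus a unanimity flag.

    Returns an N x (C+1) frame: one proportion column per category (rows sum
    to 1) and a boolean ``concordant`` column, true iff all observers agreed
    on the case.  The number of concordant cases divided by N is the overall
    percent agreement.
    """
    table = to_count_table(m)
    props = table.counts / m.n_observers
    out = pd.DataFrame(props, index=m.case_ids, columns=m.schema.labels)
    out["concordant"] = (table.counts == m.n_observers).any(axis=1)
    return out
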