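"""Reading and writing score matrices and their metadata sidecars.

Formats
-------
Score matrix: UTF-8 CSV, header ``case_id,<observer_1>,...,<observer_R>``,
one row per case.  Cells may hold category labels (``"1+"``) or their
numeric codes (``1``); both dialects are accepted on read, labels are
always written.  A transposed (observer x case) layout is read with
``transposed=True``.

Metadata: optional CSV sidecars ``observer_id,experience`` and
``case_id,specimen_type``.

Exports: TSV for per-rater marginals and per-case vote profiles.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .core import (
    CategorySchema,
    HER2_SCHEMA,
    ScoreMatrix,
    SchemaError,
    case_vote_profile,
    rater_marginals,
)

__all__ = [
    "read_score_matrix",
    "write_score_matrix",
    "read_observer_meta",
    "read_case_meta",
    "write_observer_meta",
    "write_case_meta",
    "export_rater_marginals",
    "export_case_vote_profile",
]


def read_score_matrix(
    path: str | Path,
    schema: CategorySchema = HER2_SCHEMA,
    transposed: bool = False,
) -> ScoreMatrix:
    """Read a case x observer score matrix from CSV.

    Parameters
    ----------
    path:
        CSV file with a leading case-identifier column and one column per
        observer.
    schema:
        Category schema the cells must conform to.
    transposed:
        If true, the file is observer x case (leading column holds observer
        identifiers) and is transposed after reading.

    Raises
    ------
    SchemaError
        On an unknown category token (the message names the case, the
        observer and the token) or an empty cell.
    ValueError
        On duplicate identifiers or fewer than two observer columns.
    """
    frame = pd.read_csv(path, dtype=str, index_col=0, keep_default_na=False)
    if transposed:
        frame = frame.T
    case_ids = [str(c) for c in frame.index]
    observer_ids = [str(o) for o in frame.columns]
    if len(observer_ids) < 2:
        raise ValueError(f"{path}: need at least 2 observer columns, found {len(observer_ids)}")
    if len(set(case_ids)) != len(case_ids):
        dup = sorted({c for c in case_ids if case_ids.count(c) > 1})
        raise ValueError(f"{path}: duplicate case identifiers {dup}")
    if len(set(observer_ids)) != len(observer_ids):
        dup = sorted({o for o in observer_ids if observer_ids.count(o) > 1})
        raise ValueError(f"{path}: duplicate observer identifiers {dup}")

    scores = frame.to_numpy(dtype=object)
    coded = [[0] * len(observer_ids) for _ in case_ids]
    for i, case in enumerate(case_ids):
        for j, obs in enumerate(observer_ids):
            token = str(scores[i][j]).strip()
            if token == "" or token.lower() == "nan":
                raise SchemaError(
                    f"{path}: empty cell for case {case!r}, observer {obs!r} "
                    "(missing data is not supported)"
                )
            try:
                coded[i][j] = schema.code_of(token)
            except SchemaError:
                raise SchemaError(
                    f"{path}: unknown category token {token!r} for case {case!r}, "
                    f"observer {obs!r}; expected one of {schema.labels}"
                ) from None
    return ScoreMatrix(case_ids=case_ids, observer_ids=observer_ids, scores=coded, schema=schema)


def write_score_matrix(m: ScoreMatrix, path: str | Path) -> None:
    """Write the matrix as CSV with category labels in the cells."""
    frame = m.to_frame(labels=True)
    frame.index.name = "case_id"
    frame.to_csv(path)


def _read_two_column(path: str | Path, key: str, value: str) -> dict[str, str]:
    frame = pd.read_csv(path, dtype=str)
    for col in (key, value):
        if col not in frame.columns:
            raise ValueError(f"{path}: expected columns {key!r},{value!r}, got {list(frame.columns)}")
    if frame[key].duplicated().any():
        dup = sorted(frame.loc[frame[key].duplicated(), key].unique())
        raise ValueError(f"{path}: duplicate {key} entries {dup}")
    return dict(zip(frame[key].astype(str), frame[value].astype(str)))


def read_observer_meta(path: str | Path) -> dict[str, str]:
    """Read the ``observer_id,experience`` sidecar into a mapping."""
    return _read_two_column(path, "observer_id", "experience")


def read_case_meta(path: str | Path) -> dict[str, str]:
    """Read the ``case_id,specimen_type`` sidecar into a mapping."""
    return _read_two_column(path, "case_id", "specimen_type")


def write_observer_meta(meta: dict[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"observer_id": list(meta), "experience": list(meta.values())}
    ).to_csv(path, index=False)


def write_case_meta(meta: dict[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"case_id": list(meta), "specimen_type": list(meta.values())}
    ).to_csv(path, index=False)


def export_rater_marginals(m: ScoreMatrix, path: str | Path) -> None:
    """Write per-observer category proportions as TSV."""
    frame = rater_marginals(m)
    frame.index.name = "observer_id"
    frame.to_csv(path, sep="\t")


def export_case_vote_profile(m: ScoreMatrix, path: str | Path) -> None:
    """Write per-case category proportions and unanimity flags as TSV."""
    frame = case_vote_profile(m)
    frame.index.name = "case_id"
    frame.to_csv(path, sep="\t")
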