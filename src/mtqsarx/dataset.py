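"""Dataset schema, CSV I/O and synthetic fixture generation.

A dataset is one row per (compound, experimental-condition) data point:
a unique case id, a binary response in {+1, -1}, one or more categorical
condition columns, a block of numeric input descriptors, and optionally a
pre-defined set tag ("Train"/"Test") and a per-row positive probability
factor used by the user-specific deviation operator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "DatasetSchema",
    "MTQSARDataset",
    "SyntheticSpec",
    "read_dataset",
    "write_dataset",
    "read_schema",
    "write_schema",
    "write_report",
    "generate_synthetic",
]

VALID_SET_TAGS = ("Train", "Test")


@dataclass(frozen=True)
class DatasetSchema:
    """Column-role declaration for a delimited dataset file."""

    id_col: str
    response_col: str
    condition_cols: tuple[str, ...]
    descriptor_cols: tuple[str, ...]
    set_tag_col: Optional[str] = None
    p_user_col: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.condition_cols:
            raise ValueError("schema must declare at least one condition column")
        if not self.descriptor_cols:
            raise ValueError("schema must declare at least one descriptor column")
        declared = [self.id_col, self.response_col, *self.condition_cols,
                    *self.descriptor_cols]
        if self.set_tag_col:
            declared.append(self.set_tag_col)
        if self.p_user_col:
            declared.append(self.p_user_col)
        dupes = {c for c in declared if declared.count(c) > 1}
        if dupes:
            raise ValueError(f"columns declared in more than one role: {sorted(dupes)}")


@dataclass
class MTQSARDataset:
    """Validated in-memory dataset.

    ``conditions`` and ``descriptors`` are indexed by case id; descriptor
    column order is preserved from the source file (downstream tie-breaking
    relies on it).
    """

    ids: list
    response: pd.Series          # values in {+1, -1}, index = ids
    conditions: pd.DataFrame     # categorical, index = ids
    descriptors: pd.DataFrame    # float, index = ids
    set_tag: Optional[pd.Series] = None
    p_user: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        if len(self.ids) != len(set(self.ids)):
            seen: set = set()
            dupes = sorted({i for i in self.ids if i in seen or seen.add(i)})
            raise ValueError(f"duplicate case ids: {dupes!r}")
        bad = set(np.unique(self.response)) - {1, -1}
        if bad:
            raise ValueError(f"response values outside {{+1,-1}}: {sorted(bad)}")
        if not np.all(np.isfinite(self.descriptors.to_numpy(dtype=float))):
            bad_cols = [c for c in self.descriptors.columns
                        if not np.all(np.isfinite(self.descriptors[c].to_numpy(dtype=float)))]
            raise ValueError(f"non-finite descriptor values in columns {bad_cols}")
        for col in self.conditions.columns:
            vals = self.conditions[col].astype(str)
            if (vals.str.len() == 0).any() or vals.isin(["nan", "None"]).any():
                raise ValueError(f"empty condition element in column {col!r}")
        if self.set_tag is not None:
            bad = set(self.set_tag.unique()) - set(VALID_SET_TAGS)
            if bad:
                raise ValueError(f"set tags outside {VALID_SET_TAGS}: {sorted(bad)}")
        if self.p_user is not None and not (self.p_user > 0).all():
            raise ValueError("p_user must be strictly positive for every row")

    @property
    def n_rows(self) -> int:
        return len(self.ids)

    @property
    def n_descriptors(self) -> int:
        return self.descriptors.shape[1]

    @property
    def n_condition_cols(self) -> int:
        return self.conditions.shape[1]

    def subset(self, ids: Sequence) -> "MTQSARDataset":
        """Row subset by case id, preserving the given order."""
        ids = list(ids)
        missing = set(ids) - set(self.ids)
        if missing:
            raise KeyError(f"unknown ids: {sorted(missing)!r}")
        return MTQSARDataset(
            ids=ids,
            response=self.response.loc[ids],
            conditions=self.conditions.loc[ids],
            descriptors=self.descriptors.loc[ids],
            set_tag=None if self.set_tag is None else self.set_tag.loc[ids],
            p_user=None if self.p_user is None else self.p_user.loc[ids],
        )

    def to_frame(self, schema: DatasetSchema) -> pd.DataFrame:
        """Reassemble the flat table described by ``schema``."""
        parts = {schema.id_col: self.ids,
                 schema.response_col: self.response.to_numpy()}
        for c in schema.condition_cols:
            parts[c] = self.conditions[c].to_numpy()
        for c in schema.descriptor_cols:
            parts[c] = self.descriptors[c].to_numpy()
        if schema.set_tag_col and self.set_tag is not None:
            parts[schema.set_tag_col] = self.set_tag.to_numpy()
        if schema.p_user_col and self.p_user is not None:
            parts[schema.p_user_col] = self.p_user.to_numpy()
        return pd.DataFrame(parts)


def read_schema(path) -> DatasetSchema:
    """Load a column-role declaration from YAML."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return DatasetSchema(
        id_col=raw["id"],
        response_col=raw["response"],
        condition_cols=tuple(raw["conditions"]),
        descriptor_cols=tuple(raw["descriptors"]),
        set_tag_col=raw.get("set_tag"),
        p_user_col=raw.get("p_user"),
    )


def write_schema(schema: DatasetSchema, path) -> None:
    raw = {
        "id": schema.id_col,
        "response": schema.response_col,
        "conditions": list(schema.condition_cols),
        "descriptors": list(schema.descriptor_cols),
    }
    if schema.set_tag_col:
        raw["set_tag"] = schema.set_tag_col
    if schema.p_user_col:
        raw["p_user"] = schema.p_user_col
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)


def read_dataset(path, schema: DatasetSchema) -> MTQSARDataset:
    """Read and validate a delimited dataset file against ``schema``.

    Raises ``ValueError`` naming the offending row/column on any schema
    violation (missing column, non-numeric descriptor cell, response outside
    {+1, -1}, duplicate id, unknown set tag).
    """
    df = pd.read_csv(path)
    declared = [schema.id_col, schema.response_col,
                *schema.condition_cols, *schema.descriptor_cols]
    if schema.set_tag_col:
        declared.append(schema.set_tag_col)
    if schema.p_user_col:
        declared.append(schema.p_user_col)
    missing = [c for c in declared if c not in df.columns]
    if missing:
        raise ValueError(f"declared columns missing from {path}: {missing}")

    ids = df[schema.id_col].tolist()
    dupes = df[schema.id_col][df[schema.id_col].duplicated()].tolist()
    if dupes:
        raise ValueError(f"duplicate case ids in {path}: {sorted(set(dupes))!r}")

    resp_raw = df[schema.response_col]
    resp = pd.to_numeric(resp_raw, errors="coerce")
    bad = resp.isna() | ~resp.isin([1, -1])
    if bad.any():
        r = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(
            f"response value {resp_raw.iloc[r]!r} outside {{+1,-1}} "
            f"(row {r}, column {schema.response_col!r})")

    desc = pd.DataFrame(index=ids)
    for c in schema.descriptor_cols:
        num = pd.to_numeric(df[c], errors="coerce")
        if num.isna().any():
            r = int(np.flatnonzero(num.isna().to_numpy())[0])
            raise ValueError(
                f"non-numeric or missing descriptor cell {df[c].iloc[r]!r} "
                f"(row {r}, column {c!r})")
        desc[c] = num.to_numpy(dtype=float)

    cond = df[list(schema.condition_cols)].astype(str)
    cond.index = ids

    set_tag = None
    if schema.set_tag_col:
        set_tag = df[schema.set_tag_col].astype(str)
        set_tag.index = ids
    p_user = None
    if schema.p_user_col:
        p_user = pd.to_numeric(df[schema.p_user_col], errors="coerce")
        if p_user.isna().any():
            raise ValueError(f"non-numeric value in column {schema.p_user_col!r}")
        p_user.index = ids

    return MTQSARDataset(
        ids=ids,
        response=pd.Series(resp.astype(int).to_numpy(), index=ids),
        conditions=cond,
        descriptors=desc,
        set_tag=set_tag,
        p_user=p_user,
    )


def write_dataset(ds: MTQSARDataset, schema: DatasetSchema, path) -> None:
    """Write the dataset back to CSV (lossless round trip with read_dataset)."""
    ds.to_frame(schema).to_csv(path, index=False)


def write_report(report, path) -> None:
    """Write any tabular report (DataFrame or dict of rows) as CSV."""
    if isinstance(report, pd.DataFrame):
        df = report
    elif isinstance(report, pd.Series):
        df = report.to_frame()
    else:
        df = pd.DataFrame(report)
    if df.empty:
        raise ValueError("refusing to write an empty report")
    df.to_csv(path, index=isinstance(df.index, pd.MultiIndex) or df.index.name is not None)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic mt-QSAR dataset generator.

    Each (condition column, element, descriptor) triple gets its own mean
    shift, and active rows are displaced by ``effect_size`` on every
    descriptor, so deviation descriptors computed downstream carry class
    signal iff ``effect_size > 0``.
    """

    n_rows: int
    n_descriptors: int
    condition_cardinalities: tuple[int, ...]
    active_fraction: float = 0.5
    effect_size: float = 1.0
    noise_sd: float = 1.0
    seed: int = 0
    train_fraction: Optional[float] = None   # if set, emit a Train/Test tag

    def __post_init__(self) -> None:
        if self.n_rows < 2:
            raise ValueError("n_rows must be >= 2")
        if self.n_descriptors < 1:
            raise ValueError("n_descriptors must be >= 1")
        if not self.condition_cardinalities or any(k < 1 for k in self.condition_cardinalities):
            raise ValueError("condition cardinalities must all be >= 1")
        if not 0.0 < self.active_fraction < 1.0:
            raise ValueError("active_fraction must lie in (0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def generate_synthetic(spec: SyntheticSpec) -> MTQSARDataset:
    """Generate a reproducible dataset with planted condition structure.

    The realised number of actives is exactly round(n_rows * active_fraction)
    (well inside three standard errors of the target fraction); identical
    specs yield byte-identical datasets.
    """
    rng = np.random.default_rng(spec.seed)
    n, d = spec.n_rows, spec.n_descriptors
    ids = [f"cmp{i:05d}" for i in range(n)]
    desc_names = [f"D{i + 1}" for i in range(d)]
    cond_names = [f"c{j + 1}" for j in range(len(spec.condition_cardinalities))]

    n_active = int(round(n * spec.active_fraction))
    n_active = min(max(n_active, 1), n - 1)
    resp = np.full(n, -1, dtype=int)
    resp[rng.choice(n, size=n_active, replace=False)] = 1

    cond = {}
    elem_idx = {}
    for col, k in zip(cond_names, spec.condition_cardinalities):
        idx = rng.integers(0, k, size=n)
        elem_idx[col] = idx
        cond[col] = np.array([f"{col}e{e + 1}" for e in idx])

    # per-(column, element, descriptor) baseline shifts + class displacement
    X = rng.normal(0.0, spec.noise_sd, size=(n, d))
    for col, k in zip(cond_names, spec.condition_cardinalities):
        shifts = rng.normal(0.0, spec.effect_size, size=(k, d))
        X += shifts[elem_idx[col]]
    X += (resp == 1)[:, None] * spec.effect_size

    set_tag = None
    if spec.train_fraction is not None:
        n_train = int(np.floor(spec.train_fraction * n + 0.5))
        tags = np.array(["Test"] * n, dtype=object)
        tags[rng.choice(n, size=n_train, replace=False)] = "Train"
        set_tag = pd.Series(tags, index=ids)

    return MTQSARDataset(
        ids=ids,
        response=pd.Series(resp, index=ids),
        conditions=pd.DataFrame(cond, index=ids),
        descriptors=pd.DataFrame(X, index=ids, columns=desc_names),
        set_tag=set_tag,
    )


def default_schema(ds: MTQSARDataset) -> DatasetSchema:
    """Schema matching the column names produced by generate_synthetic."""
    return DatasetSchema(
        id_col="id",
        response_col="class",
        condition_cols=tuple(ds.conditions.columns),
        descriptor_cols=tuple(ds.descriptors.columns),
        set_tag_col="set" if ds.set_tag is not None else None,
        p_user_col="p_user" if ds.p_user is not None else None,
    )
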