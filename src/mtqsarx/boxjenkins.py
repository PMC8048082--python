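"""Moving-average deviation descriptors conditioned on experimental elements.

Four operators turn an input descriptor D_i into a condition-dependent
deviation feature, one block per condition column:

* Method1: D_i - avg(D_i | element)
* Method2: (D_i - avg) / (D_max - D_min)
* Method3: (D_i - avg) / ((D_max - D_min) * p_c(element))
* Method4: (D_i - avg) / p_u(row)

avg is the arithmetic mean over ACTIVE training rows sharing the element
(optionally over all rows); D_max/D_min are training-set ranges; p_c is the
element's active count over the training size; p_u is a user-supplied or
computed per-row probability factor. All statistics come strictly from the
training set — transforming other rows never updates them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .dataset import MTQSARDataset

__all__ = [
    "BoxJenkinsModel",
    "DeviationFeatures",
    "ProbabilityFactorModel",
    "fit_boxjenkins",
    "transform",
    "compute_probability_factors",
    "feature_name",
    "parse_feature_name",
]

METHODS = (1, 2, 3, 4)
_SEP = "::"


def feature_name(descriptor: str, condition_col: str) -> str:
    """Deviation-feature name for a (descriptor, condition column) pair."""
    return f"d({descriptor}){_SEP}{condition_col}"


def parse_feature_name(name: str) -> tuple[str, str]:
    head, col = name.rsplit(_SEP, 1)
    if not (head.startswith("d(") and head.endswith(")")):
        raise ValueError(f"not a deviation-feature name: {name!r}")
    return head[2:-1], col


@dataclass
class ProbabilityFactorModel:
    """Per-row composite probability factors from training-set element counts.

    For a condition column linked to a secondary column the factor of a row
    is  n_T(primary element) / N_T(secondary element); for an unlinked column
    it is  n_T(element) / N_T.  Counts include ALL training rows (actives and
    inactives). The per-row composite is the product over condition columns.
    """

    links: dict                              # primary column -> secondary column
    counts: dict = field(default_factory=dict)   # (column, element) -> count
    n_train: int = 0
    columns: tuple = ()

    def fit(self, train: MTQSARDataset) -> "ProbabilityFactorModel":
        for primary, secondary in self.links.items():
            for col in (primary, secondary):
                if col not in train.conditions.columns:
                    raise ValueError(f"linked condition column {col!r} not in dataset")
        self.columns = tuple(c for c in train.conditions.columns
                             if c not in set(self.links.values()))
        self.n_train = train.n_rows
        self.counts = {}
        for col in train.conditions.columns:
            vc = train.conditions[col].value_counts()
            for elem, cnt in vc.items():
                self.counts[(col, elem)] = int(cnt)
        return self

    def factor(self, conditions: pd.DataFrame) -> pd.Series:
        """Composite p_u per row of ``conditions`` (training counts applied)."""
        out = np.ones(len(conditions), dtype=float)
        for col in self.columns:
            elems = conditions[col].to_numpy()
            num = np.array([self.counts.get((col, e), 0) for e in elems], dtype=float)
            if col in self.links:
                sec = self.links[col]
                sec_elems = conditions[sec].to_numpy()
                den = np.array([self.counts.get((sec, e), 0) for e in sec_elems],
                               dtype=float)
            else:
                den = np.full(len(conditions), float(self.n_train))
            if (den == 0).any():
                if col in self.links:
                    sec = self.links[col]
                    bad = sorted({str(e) for e, d in zip(sec_elems, den) if d == 0})
                else:
                    sec, bad = col, []
                raise ValueError(
                    f"zero training count for secondary element(s) {bad} "
                    f"of column {sec!r}")
            if (num == 0).any():
                bad = sorted({str(e) for e, v in zip(elems, num) if v == 0})
                raise ValueError(
                    f"element(s) {bad} of column {col!r} never seen in training")
            out *= num / den
        return pd.Series(out, index=conditions.index)


def compute_probability_factors(train: MTQSARDataset,
                                links: dict | None = None) -> pd.Series:
    """Composite per-row probability factors for the training rows."""
    model = ProbabilityFactorModel(links=dict(links or {})).fit(train)
    return model.factor(train.conditions)


@dataclass
class BoxJenkinsModel:
    method: int
    avg: pd.DataFrame            # index: MultiIndex (column, element); cols: descriptors
    dmax: pd.Series              # per retained descriptor, over ALL training rows
    dmin: pd.Series
    p_c: dict                    # (column, element) -> active fraction (Method3)
    n_train: int
    descriptors: tuple           # retained descriptor names, input order
    condition_cols: tuple
    avg_over: str = "actives"
    grand_avg: Optional[pd.Series] = None    # fallback for unseen elements
    p_factors: Optional[ProbabilityFactorModel] = None   # Method4, computed mode

    @property
    def feature_names(self) -> list:
        return [feature_name(d, c) for c in self.condition_cols
                for d in self.descriptors]


@dataclass
class DeviationFeatures:
    X: pd.DataFrame              # index = row ids, columns = deviation features
    method: int

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.X.to_numpy(dtype=float))):
            raise ValueError("non-finite deviation features")


def fit_boxjenkins(train: MTQSARDataset, method: int, *,
                   avg_over: str = "actives",
                   links: dict | None = None,
                   allow_empty_elements: bool = False) -> BoxJenkinsModel:
    """Fit the deviation-descriptor statistics on the training set only.

    Parameters
    ----------
    method : 1-4, selecting the operator.
    avg_over : "actives" (default) averages descriptor values over rows with
        response +1 only; "all" averages over every training row.
    links : primary->secondary condition-column links for Method4 computed
        probability factors (used when the dataset has no p_user column).
    allow_empty_elements : substitute the grand mean for elements with no
        active training row instead of raising (used by randomisation runs,
        where scrambling can empty a group).
    """
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}")
    if avg_over not in ("actives", "all"):
        raise ValueError("avg_over must be 'actives' or 'all'")

    desc = train.descriptors
    dmax = desc.max(axis=0)
    dmin = desc.min(axis=0)
    retained = tuple(desc.columns)
    if method in (2, 3):
        retained = tuple(c for c in desc.columns if dmax[c] > dmin[c])
        if not retained:
            raise ValueError("all descriptors are invariant on the training set")

    mask = (train.response == 1) if avg_over == "actives" else pd.Series(True, index=desc.index)
    base = desc.loc[mask.to_numpy(), list(retained)]
    grand_avg = base.mean(axis=0)

    rows, index = [], []
    empty: list = []
    for col in train.conditions.columns:
        groups = train.conditions[col]
        for elem in pd.unique(groups):
            sel = (groups == elem) & mask
            if not sel.any():
                if allow_empty_elements:
                    rows.append(grand_avg)
                    index.append((col, elem))
                    continue
                empty.append((col, elem))
                continue
            rows.append(desc.loc[sel.to_numpy(), list(retained)].mean(axis=0))
            index.append((col, elem))
    if empty:
        raise ValueError(
            "condition element(s) with no active training row: "
            + ", ".join(f"{c}={e}" for c, e in empty))
    avg = pd.DataFrame(rows, index=pd.MultiIndex.from_tuples(index, names=["column", "element"]))

    p_c: dict = {}
    if method == 3:
        active = train.response == 1
        for col in train.conditions.columns:
            groups = train.conditions[col]
            for elem in pd.unique(groups):
                p_c[(col, elem)] = float(((groups == elem) & active).sum()) / train.n_rows

    p_factors = None
    if method == 4:
        if train.p_user is None and links is None:
            raise ValueError("Method4 requires a p_user column or condition links")
        if train.p_user is None:
            p_factors = ProbabilityFactorModel(links=dict(links)).fit(train)

    return BoxJenkinsModel(
        method=method,
        avg=avg,
        dmax=dmax[list(retained)],
        dmin=dmin[list(retained)],
        p_c=p_c,
        n_train=train.n_rows,
        descriptors=retained,
        condition_cols=tuple(train.conditions.columns),
        avg_over=avg_over,
        grand_avg=grand_avg,
        p_factors=p_factors,
    )


def transform(ds: MTQSARDataset, model: BoxJenkinsModel, *,
              unseen_policy: str = "error") -> DeviationFeatures:
    """Apply the fitted operator; one deviation block per condition column.

    ``unseen_policy`` controls rows whose condition element was absent from
    the training fit: "error" raises; "global-active-mean" substitutes the
    grand training mean (and, for Method3, the overall active fraction).
    """
    if unseen_policy not in ("error", "global-active-mean"):
        raise ValueError("unseen_policy must be 'error' or 'global-active-mean'")
    missing_cols = set(model.condition_cols) - set(ds.conditions.columns)
    if missing_cols:
        raise ValueError(f"rows lack condition columns {sorted(missing_cols)}")

    desc = ds.descriptors[list(model.descriptors)]
    rng = (model.dmax - model.dmin)

    p_u = None
    if model.method == 4:
        if ds.p_user is not None:
            p_u = ds.p_user.to_numpy(dtype=float)
        elif model.p_factors is not None:
            p_u = model.p_factors.factor(ds.conditions).to_numpy()
        else:
            raise ValueError("Method4 transform needs p_user values on the rows")
        if (p_u <= 0).any():
            raise ValueError("p_user must be strictly positive")

    blocks = {}
    for col in model.condition_cols:
        elems = ds.conditions[col]
        avg_block = np.empty((ds.n_rows, len(model.descriptors)))
        p_block = np.empty(ds.n_rows) if model.method == 3 else None
        known = {e: model.avg.loc[(col, e)].to_numpy()
                 for e in model.avg.loc[col].index}
        for r, elem in enumerate(elems.to_numpy()):
            if elem in known:
                avg_block[r] = known[elem]
                if p_block is not None:
                    p_block[r] = model.p_c[(col, elem)]
            elif unseen_policy == "global-active-mean":
                avg_block[r] = model.grand_avg.to_numpy()
                if p_block is not None:
                    # fall back to the column's total active fraction
                    p_block[r] = sum(v for (c, _), v in model.p_c.items() if c == col)
            else:
                raise ValueError(
                    f"element {elem!r} of condition column {col!r} was never "
                    f"seen in training (unseen_policy='error')")
        delta = desc.to_numpy(dtype=float) - avg_block
        if model.method == 2:
            delta = delta / rng.to_numpy()
        elif model.method == 3:
            delta = delta / (rng.to_numpy()[None, :] * p_block[:, None])
        elif model.method == 4:
            delta = delta / p_u[:, None]
        blocks[col] = delta

    data = {}
    for col in model.condition_cols:
        for k, d in enumerate(model.descriptors):
            data[feature_name(d, col)] = blocks[col][:, k]
    X = pd.DataFrame(data, index=desc.index)
    return DeviationFeatures(X=X, method=model.method)
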