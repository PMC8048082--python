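"""Training/validation division schemes and the sub-training/test sub-division.

Three division schemes are provided: pre-defined set tags, seeded random
division, and k-means cluster analysis (kMCA) division in which validation
rows are drawn per cluster. The training set is subsequently sub-divided
into sub-training and test (calibration) sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .dataset import MTQSARDataset

__all__ = [
    "TrainValidSplit",
    "SplitAssignment",
    "split_predefined",
    "split_random",
    "split_kmca",
    "split_subtrain_test",
]

SUBTRAIN, TEST, VALIDATION = "sub-training", "test", "validation"


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


@dataclass
class TrainValidSplit:
    train_ids: list
    valid_ids: list
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        overlap = set(self.train_ids) & set(self.valid_ids)
        if overlap:
            raise ValueError(f"ids in both sets: {sorted(overlap)!r}")


@dataclass
class SplitAssignment:
    """Final three-set partition: id -> {sub-training, test, validation}."""

    labels: pd.Series            # index = ids, values in the three set names
    provenance: dict = field(default_factory=dict)

    def ids_in(self, set_name: str) -> list:
        return list(self.labels.index[self.labels == set_name])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"id": self.labels.index, "set": self.labels.to_numpy()})

    def validate_against(self, ds: MTQSARDataset) -> None:
        if sorted(self.labels.index) != sorted(ds.ids):
            raise ValueError("assignment does not partition the dataset ids exactly")


def split_predefined(ds: MTQSARDataset) -> TrainValidSplit:
    """Partition by the dataset's own 'Train'/'Test' tags."""
    if ds.set_tag is None:
        raise ValueError("dataset has no set-tag column; cannot use the pre-defined scheme")
    train_ids = [i for i in ds.ids if ds.set_tag.loc[i] == "Train"]
    valid_ids = [i for i in ds.ids if ds.set_tag.loc[i] == "Test"]
    if len(train_ids) + len(valid_ids) != ds.n_rows:
        untagged = set(ds.ids) - set(train_ids) - set(valid_ids)
        raise ValueError(f"rows without a 'Train'/'Test' tag: {sorted(untagged)!r}")
    if not valid_ids:
        warnings.warn("pre-defined division produced an empty validation set")
    if not train_ids:
        warnings.warn("pre-defined division produced an empty training set")
    return TrainValidSplit(train_ids, valid_ids,
                           {"scheme": "predefined", "n_train": len(train_ids),
                            "n_valid": len(valid_ids)})


def split_random(ds: MTQSARDataset, validation_fraction: float, seed: int) -> TrainValidSplit:
    """Seeded uniform random division; validation size rounds half up."""
    if not 0.0 < validation_fraction < 1.0:
        raise ValueError("validation_fraction must lie in (0, 1)")
    n_valid = _round_half_up(validation_fraction * ds.n_rows)
    if n_valid == 0 or n_valid == ds.n_rows:
        raise ValueError(
            f"validation_fraction {validation_fraction} yields a degenerate split "
            f"({n_valid}/{ds.n_rows} validation rows)")
    rng = np.random.default_rng(seed)
    order = rng.permutation(ds.n_rows)
    valid_pos = set(order[:n_valid].tolist())
    train_ids = [i for k, i in enumerate(ds.ids) if k not in valid_pos]
    valid_ids = [i for k, i in enumerate(ds.ids) if k in valid_pos]
    return TrainValidSplit(train_ids, valid_ids,
                           {"scheme": "random", "validation_fraction": validation_fraction,
                            "seed": seed, "n_valid": n_valid})


def split_kmca(ds: MTQSARDataset, n_clusters: int, validation_fraction: float,
               seed: int) -> TrainValidSplit:
    """k-means cluster analysis division.

    Rows are clustered on z-scored input descriptors, then round-half-up
    ``validation_fraction`` of each cluster is drawn uniformly into the
    validation set.
    """
    if not 1 <= n_clusters <= ds.n_rows:
        raise ValueError("n_clusters must lie in [1, n_rows]")
    if not 0.0 < validation_fraction < 1.0:
        raise ValueError("validation_fraction must lie in (0, 1)")
    X = ds.descriptors.to_numpy(dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0                      # constant descriptors contribute nothing
    Z = (X - mu) / sd
    km = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed)
    labels = km.fit_predict(Z)

    rng = np.random.default_rng(seed)
    ids = np.asarray(ds.ids, dtype=object)
    valid_ids: list = []
    cluster_sizes = {}
    for c in range(n_clusters):
        members = ids[labels == c]
        cluster_sizes[c] = len(members)
        if len(members) == 0:
            continue
        k = _round_half_up(validation_fraction * len(members))
        k = min(k, len(members))
        if k:
            valid_ids.extend(rng.choice(members, size=k, replace=False).tolist())
    valid_set = set(valid_ids)
    train_ids = [i for i in ds.ids if i not in valid_set]
    valid_ids = [i for i in ds.ids if i in valid_set]
    return TrainValidSplit(train_ids, valid_ids,
                           {"scheme": "kmca", "n_clusters": n_clusters,
                            "validation_fraction": validation_fraction, "seed": seed,
                            "cluster_sizes": cluster_sizes,
                            "stratified_by_class": False})


def split_subtrain_test(train_ids, test_fraction: float, seed: int,
                        provenance: dict | None = None) -> SplitAssignment:
    """Randomly sub-divide the training rows into sub-training and test sets."""
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must lie in (0, 1)")
    train_ids = list(train_ids)
    n_test = _round_half_up(test_fraction * len(train_ids))
    if n_test == 0 or n_test == len(train_ids):
        raise ValueError(
            f"test_fraction {test_fraction} yields a degenerate sub-division "
            f"({n_test}/{len(train_ids)} test rows)")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(train_ids))
    test_pos = set(order[:n_test].tolist())
    labels = pd.Series(
        [TEST if k in test_pos else SUBTRAIN for k in range(len(train_ids))],
        index=train_ids,
    )
    prov = dict(provenance or {})
    prov.update({"test_fraction": test_fraction, "subdivision_seed": seed})
    return SplitAssignment(labels, prov)


def assemble_assignment(split: TrainValidSplit, test_fraction: float,
                        seed: int) -> SplitAssignment:
    """Full three-set assignment from a train/valid division."""
    sub = split_subtrain_test(split.train_ids, test_fraction, seed,
                              provenance=split.provenance)
    labels = pd.concat([sub.labels,
                        pd.Series(VALIDATION, index=split.valid_ids)])
    return SplitAssignment(labels, sub.provenance)
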