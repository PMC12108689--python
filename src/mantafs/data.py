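"""Datasets: tabular I/O, stratified splitting, and synthetic expression-like data.

The synthetic generator emulates the regime the optimizer targets: far more
features than samples, a handful of truly class-separating features, a block
of redundant (noisy-copy) features, and a large majority of pure-noise
features.  The ground-truth informative block is carried alongside the data so
selection quality (recall of true features) can be measured.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "LabeledDataset",
    "SyntheticSpec",
    "synthesize_dataset",
    "read_tabular",
    "write_tabular",
    "stratified_holdout",
    "stratified_split_indices",
    "stratified_kfold",
    "min_max_scale",
]


@dataclass
class LabeledDataset:
    """A sample-by-feature matrix with integer class labels.

    Attributes
    ----------
    X : (n_samples, n_features) float array
    y : (n_samples,) int array of consecutive class codes
    feature_names : optional list of feature names
    truth_mask : optional 0/1 array marking the truly informative features
        (synthetic data only)
    label_names : optional original label values, indexed by class code
    """

    X: np.ndarray
    y: np.ndarray
    feature_names: list[str] | None = None
    truth_mask: np.ndarray | None = None
    label_names: list | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-dimensional (samples x features)")
        if self.y.shape[0] != self.X.shape[0]:
            raise ValueError("y length must match the number of rows of X")
        if np.isnan(self.X).any():
            raise ValueError("X contains missing values")
        if np.unique(self.y).size < 2:
            raise ValueError("dataset must contain at least 2 distinct classes")
        if self.feature_names is not None and len(self.feature_names) != self.X.shape[1]:
            raise ValueError("feature_names length must match the number of columns")
        if self.truth_mask is not None:
            self.truth_mask = np.asarray(self.truth_mask, dtype=np.int8)
            if self.truth_mask.shape[0] != self.X.shape[1]:
                raise ValueError("truth_mask length must match the number of columns")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def n_classes(self) -> int:
        return int(np.unique(self.y).size)

    def subset(self, idx: np.ndarray) -> "LabeledDataset":
        """Row subset sharing feature metadata."""
        return LabeledDataset(
            self.X[idx], self.y[idx],
            feature_names=self.feature_names,
            truth_mask=self.truth_mask,
            label_names=self.label_names,
        )


@dataclass
class SyntheticSpec:
    """Recipe for a synthetic high-dimensional small-sample classification set.

    ``effect_size`` is the class-mean separation in noise-standard-deviation
    units: informative feature ``j`` of a class-``c`` sample is drawn from
    ``Normal(effect_size * m[c, j], 1)`` where ``m`` is a fixed class-signature
    matrix with entries in {-1, 0, +1} and distinct rows per class.  Redundant
    features are noisy copies of randomly chosen informative features
    (parent + ``Normal(0, redundancy_noise)``); noise features are standard
    normal and carry no class signal.

    Defaults describe a 60-sample, 3-class, 500-feature problem with a
    10-feature informative block — the small-n, large-D shape typical of
    gene-expression tumor panels, scaled to desk size.
    """

    n_samples: int = 60
    n_classes: int = 3
    n_informative: int = 10
    n_redundant: int = 20
    n_noise: int = 470
    effect_size: float = 3.0
    redundancy_noise: float = 0.5
    label_balance: tuple[float, ...] | None = None
    seed: int | None = None

    @property
    def n_features(self) -> int:
        return self.n_informative + self.n_redundant + self.n_noise

    def validate(self) -> None:
        if self.n_informative < 1:
            raise ValueError("need at least one informative feature")
        if self.n_classes < 2:
            raise ValueError("need at least two classes")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if 3**self.n_informative < self.n_classes:
            raise ValueError(
                "n_informative too small to give every class a distinct signature"
            )
        if self.label_balance is not None and len(self.label_balance) != self.n_classes:
            raise ValueError("label_balance must have one proportion per class")


def _class_signatures(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """Distinct {-1, 0, +1} signature rows, one per class, by rejection sampling."""
    for _ in range(1000):
        m = rng.integers(-1, 2, size=(spec.n_classes, spec.n_informative))
        if len({tuple(row) for row in m}) == spec.n_classes:
            return m
    raise RuntimeError("could not sample distinct class signatures")  # pragma: no cover


def synthesize_dataset(spec: SyntheticSpec, rng: np.random.Generator | None = None) -> LabeledDataset:
    """Generate a dataset from ``spec``; deterministic given the seed/rng."""
    spec.validate()
    if rng is None:
        rng = np.random.default_rng(spec.seed)

    counts = _class_counts(spec)
    y = np.repeat(np.arange(spec.n_classes), counts)
    m = _class_signatures(spec, rng)

    X_inf = spec.effect_size * m[y].astype(float) + rng.standard_normal((spec.n_samples, spec.n_informative))
    parents = rng.integers(0, spec.n_informative, size=spec.n_redundant)
    X_red = X_inf[:, parents] + spec.redundancy_noise * rng.standard_normal((spec.n_samples, spec.n_redundant))
    X_noise = rng.standard_normal((spec.n_samples, spec.n_noise))

    X = np.hstack([X_inf, X_red, X_noise])
    names = (
        [f"inf_{j}" for j in range(spec.n_informative)]
        + [f"red_{j}_of_inf_{p}" for j, p in enumerate(parents)]
        + [f"noise_{j}" for j in range(spec.n_noise)]
    )
    truth = np.zeros(spec.n_features, dtype=np.int8)
    truth[: spec.n_informative] = 1
    return LabeledDataset(X, y, feature_names=names, truth_mask=truth)


def _class_counts(spec: SyntheticSpec) -> np.ndarray:
    if spec.label_balance is None:
        props = np.full(spec.n_classes, 1.0 / spec.n_classes)
    else:
        props = np.asarray(spec.label_balance, dtype=float)
        props = props / props.sum()
    counts = np.floor(props * spec.n_samples).astype(int)
    # distribute the rounding remainder to the earliest classes
    for c in range(spec.n_samples - counts.sum()):
        counts[c % spec.n_classes] += 1
    if (counts < 2).any():
        raise ValueError("every class needs at least 2 samples")
    return counts


# ---------------------------------------------------------------------------
# tabular I/O


def _detect_delimiter(path: Path) -> str:
    first = path.open().readline()
    return "\t" if first.count("\t") >= first.count(",") and "\t" in first else ","


def _looks_numeric(token: str) -> bool:
    try:
        float(token)
        return True
    except (TypeError, ValueError):
        return False


def read_tabular(
    path: str | Path,
    label_column: str | int = -1,
    delimiter: str | None = None,
) -> LabeledDataset:
    """Read a samples-by-features CSV/TSV with one label column.

    The delimiter (comma vs tab) and the presence of a header row are
    auto-detected unless given.  Labels are encoded as consecutive integers in
    order of first appearance.  Any non-numeric feature cell raises a parse
    error naming the offending row and column.
    """
    path = Path(path)
    if delimiter is None:
        delimiter = _detect_delimiter(path)
    first_tokens = path.open().readline().rstrip("\n").split(delimiter)
    # header iff any token besides a possible label column is non-numeric
    has_header = sum(not _looks_numeric(t) for t in first_tokens) > 1 or (
        isinstance(label_column, str)
    )
    # keep tokens like "NA" as strings so parse errors can name the cell
    df = pd.read_csv(
        path, sep=delimiter, header=0 if has_header else None,
        keep_default_na=False, na_values=[""],
    )

    if isinstance(label_column, str):
        if label_column not in df.columns:
            raise ValueError(f"label column {label_column!r} not found in header")
        label_name = label_column
    else:
        label_name = df.columns[label_column]
    labels = df[label_name]
    if labels.isna().any():
        raise ValueError("missing labels")
    feats = df.drop(columns=[label_name])

    numeric = feats.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~feats.isna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric feature value {feats.iloc[r, c]!r} at row {r}, column {feats.columns[c]!r}"
        )
    if numeric.isna().to_numpy().any():
        raise ValueError("feature matrix contains missing values")

    uniq = list(pd.unique(labels))
    code = {v: i for i, v in enumerate(uniq)}
    y = labels.map(code).to_numpy()
    names = [str(c) for c in feats.columns] if has_header else None
    return LabeledDataset(numeric.to_numpy(dtype=float), y, feature_names=names, label_names=uniq)


def write_tabular(
    dataset: LabeledDataset,
    path: str | Path,
    delimiter: str = ",",
    truth_sidecar: str | Path | None = None,
) -> None:
    """Write a dataset as CSV/TSV (label column last); optionally write a
    sidecar text file listing the 0-based truth-mask feature indices."""
    path = Path(path)
    names = dataset.feature_names or [f"f{j}" for j in range(dataset.n_features)]
    df = pd.DataFrame(dataset.X, columns=names)
    if dataset.label_names is not None:
        df["label"] = [dataset.label_names[c] for c in dataset.y]
    else:
        df["label"] = dataset.y
    df.to_csv(path, sep=delimiter, index=False)
    if truth_sidecar is not None and dataset.truth_mask is not None:
        idx = np.flatnonzero(dataset.truth_mask)
        Path(truth_sidecar).write_text("\n".join(str(i) for i in idx) + "\n")


# ---------------------------------------------------------------------------
# splitting


def stratified_split_indices(
    y: np.ndarray,
    test_fraction: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-class proportional train/test indices.

    Each class contributes ``round(test_fraction * n_c)`` test samples, with
    the rounding adjusted so both sides keep at least one sample of every
    class whenever the class has two or more.  Classes with a single sample
    cannot be stratified and raise.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    y = np.asarray(y)
    train_idx, test_idx = [], []
    for c in np.unique(y):
        members = np.flatnonzero(y == c)
        if members.size < 2:
            raise ValueError(
                f"class {c!r} has a single sample and cannot be split with stratification"
            )
        n_test = int(round(test_fraction * members.size))
        n_test = min(max(n_test, 1), members.size - 1)
        perm = rng.permutation(members)
        test_idx.append(perm[:n_test])
        train_idx.append(perm[n_test:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(test_idx))


def stratified_holdout(
    dataset: LabeledDataset,
    test_fraction: float,
    rng: np.random.Generator,
) -> tuple[LabeledDataset, LabeledDataset]:
    """Stratified train/test split of a dataset (see
    :func:`stratified_split_indices` for the rounding rules)."""
    tr, te = stratified_split_indices(dataset.y, test_fraction, rng)
    return dataset.subset(tr), dataset.subset(te)


def stratified_kfold(
    dataset: LabeledDataset,
    n_folds: int,
    rng: np.random.Generator,
) -> list[tuple[LabeledDataset, LabeledDataset]]:
    """Stratified k-fold partition; folds shrink with a warning if the
    smallest class has fewer members than ``n_folds``."""
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    min_class = int(np.bincount(dataset.y).min())
    if min_class < n_folds:
        warnings.warn(
            f"reducing n_folds from {n_folds} to {min_class}: smallest class has "
            f"{min_class} samples",
            stacklevel=2,
        )
        n_folds = min_class
    seed = int(rng.integers(0, 2**31 - 1))
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return [
        (dataset.subset(tr), dataset.subset(te))
        for tr, te in skf.split(dataset.X, dataset.y)
    ]


def min_max_scale(
    train_X: np.ndarray,
    apply_X: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Column-wise min-max scaling with statistics from ``train_X`` only.

    Constant training columns map to zero everywhere; applied values outside
    the training range are not clipped.
    """
    train_X = np.asarray(train_X, dtype=float)
    lo = train_X.min(axis=0)
    span = train_X.max(axis=0) - lo
    span = np.where(span == 0, 1.0, span)
    scaled_train = (train_X - lo) / span
    scaled_apply = None if apply_X is None else (np.asarray(apply_X, dtype=float) - lo) / span
    return scaled_train, scaled_apply
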