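"""Loading, cleaning, normalizing and splitting numeric tabular datasets.

Supports the two UCI breast-cancer dialects (the Original/WBC layout with
an ID column, nine integer features, ``?`` missing markers and a 2/4 class
code; the Diagnostic/WDBC layout with an ID column, an M/B diagnosis and
thirty real features) plus a generic headered CSV.

Label convention throughout the package: 0 = malignant (the negative
class), 1 = benign (the positive class).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.model_selection import train_test_split

__all__ = [
    "TabularDataset",
    "SplitSpec",
    "ParseError",
    "load_uci_table",
    "handle_missing",
    "minmax_normalize",
    "split",
    "write_csv",
]


class ParseError(ValueError):
    """A delimited-text row could not be interpreted under the dialect."""


@dataclass
class TabularDataset:
    """An N x d numeric feature table with binary labels.

    Missing cells are stored as NaN in ``features`` and flagged in
    ``missing_mask``. ``normalized`` records whether every non-missing
    value has been mapped into [0, 1].
    """

    features: np.ndarray
    labels: np.ndarray
    field_names: list[str]
    missing_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    normalized: bool = False

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 2:
            raise ValueError("features must be a 2-D array")
        self.labels = np.asarray(self.labels, dtype=int)
        n, d = self.features.shape
        if n < 1 or d < 1:
            raise ValueError("need at least one row and one feature")
        if self.labels.shape != (n,):
            raise ValueError("labels must have one entry per row")
        if np.unique(self.labels).size > 2:
            raise ValueError("labels must contain at most two distinct values")
        if self.missing_mask is None:
            self.missing_mask = np.isnan(self.features)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.missing_mask.shape != (n, d):
            raise ValueError("missing_mask must match the feature shape")
        if len(self.field_names) != d:
            raise ValueError("need one field name per feature")
        if self.normalized:
            vals = self.features[~self.missing_mask]
            if vals.size and (vals.min() < 0 or vals.max() > 1):
                raise ValueError("normalized dataset holds values outside [0, 1]")

    @property
    def n_rows(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def take(self, idx: np.ndarray) -> "TabularDataset":
        """Row subset preserving field names and flags."""
        return TabularDataset(
            self.features[idx],
            self.labels[idx],
            list(self.field_names),
            self.missing_mask[idx],
            self.normalized,
        )


@dataclass(frozen=True)
class SplitSpec:
    """Train/validation/test partition sizes and determinism.

    The test partition takes ``floor(test_fraction * N)`` rows; the
    validation partition then takes ``floor(validation_fraction_of_train *
    remaining)`` rows from what is left.
    """

    test_fraction: float = 0.20
    validation_fraction_of_train: float = 0.20
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        for f in (self.test_fraction, self.validation_fraction_of_train):
            if not 0.0 < f < 1.0:
                raise ValueError("split fractions must lie in (0, 1)")


_WBC_FIELDS = [
    "clump_thickness",
    "cell_size_uniformity",
    "cell_shape_uniformity",
    "marginal_adhesion",
    "single_epithelial_cell_size",
    "bare_nuclei",
    "bland_chromatin",
    "normal_nucleoli",
    "mitoses",
]

_WDBC_STATS = ["mean", "se", "worst"]
_WDBC_BASE = [
    "radius",
    "texture",
    "perimeter",
    "area",
    "smoothness",
    "compactness",
    "concavity",
    "concave_points",
    "symmetry",
    "fractal_dimension",
]
_WDBC_FIELDS = [f"{b}_{s}" for s in _WDBC_STATS for b in _WDBC_BASE]


def _parse_cell(token: str, path: str, lineno: int) -> float:
    token = token.strip()
    if token == "?":
        return np.nan
    try:
        return float(token)
    except ValueError:
        raise ParseError(
            f"{path}:{lineno}: cannot parse numeric value {token!r}"
        ) from None


def load_uci_table(
    path: str | Path,
    dialect: str = "generic",
    label_column: str = "label",
) -> TabularDataset:
    """Read a delimited-text table in one of three dialects.

    ``wbc``  — no header; ID, 9 integer features, class coded 2 (benign)
    or 4 (malignant); ``?`` marks a missing cell.
    ``wdbc`` — no header; ID, diagnosis M/B, 30 real features.
    ``generic`` — header row; the label column is named by
    ``label_column`` and must be binary; ``?`` marks a missing cell.

    The ID column is dropped and the class is recoded to 0 = malignant,
    1 = benign.
    """
    path = Path(path)
    if dialect == "wbc":
        return _load_coded(path, n_features=10, class_last=True,
                           codes={"2": 1, "4": 0}, names=_WBC_FIELDS)
    if dialect == "wdbc":
        return _load_coded(path, n_features=31, class_last=False,
                           codes={"B": 1, "M": 0}, names=_WDBC_FIELDS)
    if dialect == "generic":
        return _load_generic(path, label_column)
    raise ValueError(f"unknown dialect {dialect!r}")


def _load_coded(path: Path, n_features: int, class_last: bool,
                codes: dict[str, int], names: list[str]) -> TabularDataset:
    # n_features counts the columns after the ID, class included.
    rows: list[list[float]] = []
    labels: list[int] = []
    with open(path, newline="") as fh:
        for lineno, rec in enumerate(csv.reader(fh), start=1):
            if not rec or (len(rec) == 1 and not rec[0].strip()):
                continue  # blank line
            if len(rec) != n_features + 1:
                raise ParseError(
                    f"{path}:{lineno}: expected {n_features + 1} columns, "
                    f"found {len(rec)}"
                )
            body = rec[1:]  # drop ID
            cls = (body[-1] if class_last else body[0]).strip()
            if cls not in codes:
                raise ValueError(
                    f"{path}:{lineno}: unknown class code {cls!r}"
                )
            labels.append(codes[cls])
            feats = body[:-1] if class_last else body[1:]
            rows.append([_parse_cell(t, str(path), lineno) for t in feats])
    feats_arr = np.asarray(rows, dtype=float)
    return TabularDataset(feats_arr, np.asarray(labels), list(names))


def _load_generic(path: Path, label_column: str) -> TabularDataset:
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}:1: empty file") from None
        header = [h.strip() for h in header]
        if label_column not in header:
            raise ValueError(f"label column {label_column!r} not in header")
        label_idx = header.index(label_column)
        names = [h for i, h in enumerate(header) if i != label_idx]
        rows, labels = [], []
        for lineno, rec in enumerate(reader, start=2):
            if not rec or (len(rec) == 1 and not rec[0].strip()):
                continue
            if len(rec) != len(header):
                raise ParseError(
                    f"{path}:{lineno}: expected {len(header)} columns, "
                    f"found {len(rec)}"
                )
            lab = rec[label_idx].strip()
            try:
                labels.append(int(float(lab)))
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: unknown class code {lab!r}"
                ) from None
            rows.append([
                _parse_cell(t, str(path), lineno)
                for i, t in enumerate(rec) if i != label_idx
            ])
    if not rows:
        raise ParseError(f"{path}: no data rows")
    return TabularDataset(np.asarray(rows, dtype=float),
                          np.asarray(labels), names)


def handle_missing(ds: TabularDataset, policy: str = "drop_rows") -> TabularDataset:
    """Resolve missing cells by dropping affected rows or mean imputation."""
    if ds.normalized:
        raise ValueError("handle missing values before normalization")
    if not ds.missing_mask.any():
        return ds
    if policy == "drop_rows":
        keep = ~ds.missing_mask.any(axis=1)
        if not keep.any():
            raise ValueError("every row has a missing cell")
        return ds.take(np.flatnonzero(keep))
    if policy == "impute_mean":
        fully_missing = ds.missing_mask.all(axis=0)
        if fully_missing.any():
            bad = [ds.field_names[j] for j in np.flatnonzero(fully_missing)]
            raise ValueError(f"feature(s) entirely missing: {bad}")
        feats = ds.features.copy()
        col_means = np.nanmean(np.where(ds.missing_mask, np.nan, feats), axis=0)
        rr, cc = np.nonzero(ds.missing_mask)
        feats[rr, cc] = col_means[cc]
        return TabularDataset(feats, ds.labels, list(ds.field_names),
                              np.zeros_like(ds.missing_mask), ds.normalized)
    raise ValueError(f"unknown policy {policy!r}")


def minmax_normalize(
    ds: TabularDataset,
    stats: tuple[np.ndarray, np.ndarray] | None = None,
) -> TabularDataset:
    """Map each feature column into [0, 1] by (x - min) / (max - min).

    Statistics come from the dataset itself unless ``stats`` (per-column
    minima and maxima, e.g. from a training partition for leakage-free
    use) is supplied. Constant columns map to 0.
    """
    if ds.missing_mask.any():
        raise ValueError("resolve missing values before normalizing")
    if stats is None:
        lo, hi = ds.features.min(axis=0), ds.features.max(axis=0)
    else:
        lo, hi = (np.asarray(a, dtype=float) for a in stats)
    span = hi - lo
    out = np.zeros_like(ds.features)
    nz = span > 0
    out[:, nz] = (ds.features[:, nz] - lo[nz]) / span[nz]
    out = np.clip(out, 0.0, 1.0)
    return TabularDataset(out, ds.labels, list(ds.field_names),
                          ds.missing_mask, normalized=True)


def split(
    ds: TabularDataset, spec: SplitSpec
) -> tuple[TabularDataset, TabularDataset, TabularDataset]:
    """Partition into (train, validation, test) per the spec's fractions."""
    n = ds.n_rows
    if n < 5:
        raise ValueError("need at least 5 rows to split")
    n_test = int(np.floor(spec.test_fraction * n))
    n_val = int(np.floor(spec.validation_fraction_of_train * (n - n_test)))
    n_train = n - n_test - n_val
    if min(n_test, n_val, n_train) < 1:
        raise ValueError("split produces an empty partition")
    idx = np.arange(n)
    strat = ds.labels if spec.stratified else None
    rest, test_idx = train_test_split(
        idx, test_size=n_test, random_state=spec.seed, stratify=strat)
    strat_rest = ds.labels[rest] if spec.stratified else None
    train_idx, val_idx = train_test_split(
        rest, test_size=n_val, random_state=spec.seed + 1, stratify=strat_rest)
    return ds.take(train_idx), ds.take(val_idx), ds.take(test_idx)


def write_csv(ds: TabularDataset, path: str | Path,
              label_column: str = "label") -> None:
    """Write in the generic dialect; missing cells become ``?``."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(list(ds.field_names) + [label_column])
        for i in range(ds.n_rows):
            row: list[str] = []
            for j in range(ds.n_features):
                if ds.missing_mask[i, j]:
                    row.append("?")
                else:
                    row.append(repr(float(ds.features[i, j])))
            row.append(str(int(ds.labels[i])))
            writer.writerow(row)
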