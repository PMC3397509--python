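"""Core data containers and CSV I/O for descriptor-based QSAR modelling.

The package works on three in-memory objects: a :class:`DescriptorMatrix`
(compounds x named molecular descriptors), an :class:`ActivityVector`
(compound id -> pIC50), and their inner join, a :class:`QSARDataset`, which
additionally carries a train/test split label per compound.

A transcription of the 190-compound fructose 1,6-bisphosphatase (FBPase)
inhibitor benchmark -- observed pIC50, GA-RF and RF predictions, and
train/test membership -- ships with the package and is available through
:func:`load_table3_fixture`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DescriptorMatrix",
    "ActivityVector",
    "QSARDataset",
    "Table3Record",
    "read_descriptor_csv",
    "read_activity_csv",
    "write_descriptor_csv",
    "assemble_dataset",
    "load_table3_fixture",
    "fixture_dataset",
]

TRAIN, TEST, UNASSIGNED = "train", "test", "unassigned"


def _check_unique(names: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for n in names:
        if n in seen:
            raise ValueError(f"duplicate {what}: {n!r}")
        seen.add(n)


@dataclass
class DescriptorMatrix:
    """A compounds x descriptors numeric matrix with stable row/column names.

    Parameters
    ----------
    compound_ids
        Ordered, unique compound identifiers (opaque strings).
    descriptor_names
        Ordered, unique descriptor names (e.g. Mold2 ``D###`` codes).
    values
        Real matrix of shape ``(len(compound_ids), len(descriptor_names))``;
        all entries must be finite (no NA handling -- descriptor generators
        such as Mold2 emit complete matrices).
    """

    compound_ids: list[str]
    descriptor_names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.compound_ids = [str(c) for c in self.compound_ids]
        self.descriptor_names = [str(d) for d in self.descriptor_names]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        n, p = self.values.shape
        if n != len(self.compound_ids):
            raise ValueError(
                f"row count {n} != number of compound ids {len(self.compound_ids)}"
            )
        if p != len(self.descriptor_names):
            raise ValueError(
                f"column count {p} != number of descriptor names "
                f"{len(self.descriptor_names)}"
            )
        _check_unique(self.compound_ids, "compound id")
        _check_unique(self.descriptor_names, "descriptor name")
        if not np.all(np.isfinite(self.values)):
            i, j = map(int, np.argwhere(~np.isfinite(self.values))[0])
            raise ValueError(
                f"non-finite value at compound {self.compound_ids[i]!r}, "
                f"descriptor {self.descriptor_names[j]!r}"
            )

    @property
    def n_compounds(self) -> int:
        return self.values.shape[0]

    @property
    def n_descriptors(self) -> int:
        return self.values.shape[1]

    def select_descriptors(self, names: Sequence[str]) -> "DescriptorMatrix":
        """Return a copy restricted to ``names`` (kept in the given order)."""
        idx = [self.descriptor_names.index(n) for n in names]
        return DescriptorMatrix(
            list(self.compound_ids), [self.descriptor_names[i] for i in idx],
            self.values[:, idx].copy(),
        )

    def select_compounds(self, ids: Sequence[str]) -> "DescriptorMatrix":
        idx = [self.compound_ids.index(c) for c in ids]
        return DescriptorMatrix(
            [self.compound_ids[i] for i in idx], list(self.descriptor_names),
            self.values[idx, :].copy(),
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.compound_ids, name="compound_id"),
            columns=self.descriptor_names,
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "DescriptorMatrix":
        return cls(list(map(str, df.index)), list(map(str, df.columns)),
                   df.to_numpy(dtype=float))


@dataclass
class ActivityVector:
    """Observed activities as molar pIC50 = -log10(IC50)."""

    compound_ids: list[str]
    pic50: np.ndarray

    def __post_init__(self) -> None:
        self.compound_ids = [str(c) for c in self.compound_ids]
        self.pic50 = np.asarray(self.pic50, dtype=float)
        if self.pic50.ndim != 1 or len(self.pic50) != len(self.compound_ids):
            raise ValueError("pic50 must be 1-D with one value per compound id")
        _check_unique(self.compound_ids, "compound id")
        if not np.all(np.isfinite(self.pic50)):
            raise ValueError("pIC50 values must be finite")


@dataclass
class QSARDataset:
    """A descriptor matrix and activity vector over identical compounds.

    ``split`` labels each compound ``train``/``test``/``unassigned`` and is
    produced by :mod:`qsar_garf.som` (rational SOM-based splitting) or read
    from a file.
    """

    matrix: DescriptorMatrix
    activity: ActivityVector
    split: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.matrix.compound_ids != self.activity.compound_ids:
            raise ValueError("matrix and activity must cover identical compound "
                             "ids in identical order")
        if not self.split:
            self.split = [UNASSIGNED] * self.matrix.n_compounds
        if len(self.split) != self.matrix.n_compounds:
            raise ValueError("split must have one label per compound")
        bad = set(self.split) - {TRAIN, TEST, UNASSIGNED}
        if bad:
            raise ValueError(f"invalid split labels: {sorted(bad)}")

    @property
    def compound_ids(self) -> list[str]:
        return self.matrix.compound_ids

    def _mask(self, label: str) -> np.ndarray:
        return np.array([s == label for s in self.split])

    @property
    def train_mask(self) -> np.ndarray:
        return self._mask(TRAIN)

    @property
    def test_mask(self) -> np.ndarray:
        return self._mask(TEST)

    def with_split(self, split: Sequence[str]) -> "QSARDataset":
        return QSARDataset(self.matrix, self.activity, list(split))

    def training_xy(self) -> tuple[np.ndarray, np.ndarray]:
        m = self.train_mask
        if not m.any():
            raise ValueError("dataset has no training compounds assigned")
        return self.matrix.values[m], self.activity.pic50[m]

    def test_xy(self) -> tuple[np.ndarray, np.ndarray]:
        m = self.test_mask
        if not m.any():
            raise ValueError("dataset has no test compounds assigned")
        return self.matrix.values[m], self.activity.pic50[m]


@dataclass(frozen=True)
class Table3Record:
    """One row of the packaged FBPase benchmark table."""

    compound_no: int
    observed_pic50: float
    garf_pred: float
    rf_pred: float
    is_test: bool
    source_ref: str


def read_descriptor_csv(path: str | Path) -> DescriptorMatrix:
    """Read a descriptor matrix from CSV.

    Layout: header row with descriptor names, first column ``compound_id``.
    Duplicate compound ids and non-numeric cells are rejected with the
    offending row/column named.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"descriptor file not found: {path}")
    df = pd.read_csv(path, dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected compound id column plus at least "
                         "one descriptor column")
    ids = df.iloc[:, 0].astype(str).tolist()
    dup = pd.Series(ids)[pd.Series(ids).duplicated()]
    if not dup.empty:
        raise ValueError(f"{path}: duplicate compound ID {dup.iloc[0]!r}")
    names = list(map(str, df.columns[1:]))
    raw = df.iloc[:, 1:]
    values = raw.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    if np.isnan(values).any():
        i, j = map(int, np.argwhere(np.isnan(values))[0])
        raise ValueError(
            f"{path}: unparseable cell {raw.iat[i, j]!r} at compound "
            f"{ids[i]!r}, descriptor {names[j]!r}"
        )
    return DescriptorMatrix(ids, names, values)


def read_activity_csv(path: str | Path) -> ActivityVector:
    """Read a ``compound_id,pic50`` CSV."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"activity file not found: {path}")
    df = pd.read_csv(path)
    if "compound_id" not in df.columns or "pic50" not in df.columns:
        raise ValueError(f"{path}: expected columns 'compound_id,pic50'")
    return ActivityVector(df["compound_id"].astype(str).tolist(),
                          df["pic50"].to_numpy(dtype=float))


def write_descriptor_csv(matrix: DescriptorMatrix, path: str | Path) -> None:
    """Write a matrix in the layout :func:`read_descriptor_csv` expects.

    Values are serialized with 12 significant digits, which round-trips any
    decimal text of up to 12 significant digits bit-identically.
    """
    df = matrix.to_dataframe()
    df.to_csv(Path(path), float_format="%.12g")


def write_activity_csv(activity: ActivityVector, path: str | Path) -> None:
    pd.DataFrame({"compound_id": activity.compound_ids,
                  "pic50": activity.pic50}).to_csv(Path(path), index=False,
                                                   float_format="%.12g")


def assemble_dataset(matrix: DescriptorMatrix,
                     activity: ActivityVector) -> QSARDataset:
    """Inner-join a descriptor matrix and activity table by compound id.

    Compounds present in only one input are dropped with a warning naming
    them; an empty intersection is an error.
    """
    common = [c for c in matrix.compound_ids if c in set(activity.compound_ids)]
    if not common:
        raise ValueError("no compound ids shared between descriptor matrix "
                         "and activity table")
    dropped = (set(matrix.compound_ids) | set(activity.compound_ids)) - set(common)
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} compound(s) lacking descriptors or "
            f"activity: {sorted(dropped)}", stacklevel=2)
    sub_matrix = matrix.select_compounds(common)
    order = {c: i for i, c in enumerate(activity.compound_ids)}
    pic50 = activity.pic50[[order[c] for c in common]]
    return QSARDataset(sub_matrix, ActivityVector(common, pic50))


_FIXTURE_NAME = "table3_fbpase.csv"
_N_COMPOUNDS, _N_TEST = 190, 64
_PIC50_RANGE = (3.60, 8.00)


def load_table3_fixture() -> list[Table3Record]:
    """Load the packaged FBPase benchmark (190 compounds, 126 train / 64 test).

    The loader re-validates the transcription on every call: compound numbers
    must be exactly 1..190, exactly 64 rows flagged as test, and observed
    pIC50 within [3.60, 8.00]. Any violation signals a transcription error
    and raises.
    """
    with resources.files("qsar_garf.data").joinpath(_FIXTURE_NAME).open() as fh:
        df = pd.read_csv(fh)
    records = [
        Table3Record(int(r.compound_no), float(r.observed), float(r.garf_pred),
                     float(r.rf_pred), bool(int(r.is_test)), str(r.source))
        for r in df.itertuples()
    ]
    nos = sorted(r.compound_no for r in records)
    if nos != list(range(1, _N_COMPOUNDS + 1)):
        raise RuntimeError("fixture corrupt: compound numbers are not 1..190")
    n_test = sum(r.is_test for r in records)
    if n_test != _N_TEST:
        raise RuntimeError(f"fixture corrupt: {n_test} test records, expected 64")
    lo, hi = _PIC50_RANGE
    for r in records:
        if not lo <= r.observed_pic50 <= hi:
            raise RuntimeError(
                f"fixture corrupt: compound {r.compound_no} observed pIC50 "
                f"{r.observed_pic50} outside [{lo}, {hi}]")
    return records


def fixture_dataset(model: str = "garf") -> "tuple[np.ndarray, np.ndarray, np.ndarray]":
    """Return (observed, predicted, is_test) arrays for one fixture model.

    ``model`` selects the prediction column: ``"garf"`` or ``"rf"``.
    """
    records = load_table3_fixture()
    records.sort(key=lambda r: r.compound_no)
    y = np.array([r.observed_pic50 for r in records])
    if model == "garf":
        yhat = np.array([r.garf_pred for r in records])
    elif model == "rf":
        yhat = np.array([r.rf_pred for r in records])
    else:
        raise ValueError(f"unknown model {model!r}; use 'garf' or 'rf'")
    is_test = np.array([r.is_test for r in records])
    return y, yhat, is_test
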