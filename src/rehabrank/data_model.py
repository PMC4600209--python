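"""Domain types for home-care assessment cohorts.

An assessment instrument is a battery of coded items (``K5`` = falls
frequency, ``H2A``..``H2J`` = activities of daily living, ...).  Most items
are categorical or ordinal with a small declared level set; a handful (age,
falls count) are continuous.  A cohort is one row per client with a binary
outcome: whether the client received physiotherapy or occupational therapy
within six months of assessment.

The ranking machinery works on a dummy-coded design matrix in which every
multi-level item contributes one *group* of columns, so that grouped
penalties can force an item's dummies to enter or leave a model together.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

OUTCOME_COL = "rehab6m"

KIND_CATEGORICAL = "categorical"
KIND_ORDINAL = "ordinal"  # ordinal treated as categorical for coding purposes
KIND_CONTINUOUS = "continuous"
_KINDS = (KIND_CATEGORICAL, KIND_ORDINAL, KIND_CONTINUOUS)


class ValidationError(ValueError):
    """A cohort, dictionary or configuration violated its contract."""


# ---------------------------------------------------------------------------
# Item dictionary
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Item:
    """Metadata for one assessment item.

    Parameters
    ----------
    code:
        Short item code, e.g. ``"K5"``.
    kind:
        ``"categorical"``, ``"ordinal"`` (coded like categorical) or
        ``"continuous"``.
    levels:
        Ordered level set for non-continuous items; the first level is the
        reference level dropped during dummy coding.
    include:
        Whether the item is a ranked predictor.  The included items define
        ``d``, the number of variables every ranker must place.
    """

    code: str
    kind: str
    levels: tuple | None = None
    include: bool = True

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValidationError(f"item {self.code!r}: unknown kind {self.kind!r}")
        if self.kind == KIND_CONTINUOUS:
            if self.levels is not None:
                raise ValidationError(f"item {self.code!r}: continuous items have no levels")
        else:
            if self.levels is None or len(self.levels) < 2:
                raise ValidationError(
                    f"item {self.code!r}: non-continuous items need >= 2 levels"
                )
            if len(set(self.levels)) != len(self.levels):
                raise ValidationError(f"item {self.code!r}: duplicate levels")
            object.__setattr__(self, "levels", tuple(self.levels))

    @property
    def is_continuous(self) -> bool:
        return self.kind == KIND_CONTINUOUS


class ItemDictionary:
    """Ordered collection of :class:`Item` with unique codes."""

    def __init__(self, items: Iterable[Item]):
        self.items: list[Item] = list(items)
        codes = [it.code for it in self.items]
        if len(set(codes)) != len(codes):
            dupes = sorted({c for c in codes if codes.count(c) > 1})
            raise ValidationError(f"duplicate item codes: {dupes}")
        self._by_code = {it.code: it for it in self.items}

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self) -> Iterator[Item]:
        return iter(self.items)

    def __contains__(self, code: str) -> bool:
        return code in self._by_code

    def __getitem__(self, code: str) -> Item:
        try:
            return self._by_code[code]
        except KeyError:
            raise KeyError(f"unknown item code {code!r}") from None

    @property
    def codes(self) -> list[str]:
        return [it.code for it in self.items]

    @property
    def included(self) -> list[Item]:
        return [it for it in self.items if it.include]

    @property
    def d(self) -> int:
        """Number of ranked predictors."""
        return len(self.included)

    # -- serialisation ------------------------------------------------------

    def to_yaml(self, path) -> None:
        payload = [
            {
                "code": it.code,
                "kind": it.kind,
                "levels": list(it.levels) if it.levels is not None else None,
                "include": it.include,
            }
            for it in self.items
        ]
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ItemDictionary":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls(
            Item(
                code=entry["code"],
                kind=entry["kind"],
                levels=tuple(entry["levels"]) if entry.get("levels") is not None else None,
                include=bool(entry.get("include", True)),
            )
            for entry in payload
        )


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------


@dataclass
class ClientRecord:
    """One client: an item-value mapping plus the binary outcome."""

    client_id: str
    item_values: dict
    outcome: int


class Cohort:
    """Client-by-item table with a binary rehabilitation outcome.

    Internally a :class:`pandas.DataFrame` indexed by ``client_id`` whose
    columns are the dictionary's item codes plus :data:`OUTCOME_COL`.
    Construction validates every value against the dictionary.
    """

    def __init__(self, df: pd.DataFrame, dictionary: ItemDictionary, validate: bool = True):
        self.df = df
        self.dictionary = dictionary
        if validate:
            self.validate()

    # -- contract -----------------------------------------------------------

    def validate(self) -> None:
        df, dic = self.df, self.dictionary
        if len(df) == 0:
            raise ValidationError("cohort is empty")
        if OUTCOME_COL not in df.columns:
            raise ValidationError(f"missing outcome column {OUTCOME_COL!r}")
        if df.index.duplicated().any():
            dupes = df.index[df.index.duplicated()].unique().tolist()[:5]
            raise ValidationError(f"duplicate client_id values: {dupes}")
        y = df[OUTCOME_COL]
        if y.isna().any() or not y.isin([0, 1]).all():
            raise ValidationError("outcome values must all be 0 or 1")
        for item in dic:
            if item.code not in df.columns:
                raise ValidationError(f"cohort missing item column {item.code!r}")
            col = df[item.code]
            if col.isna().any():
                row = df.index[col.isna()][0]
                raise ValidationError(
                    f"item {item.code!r}: missing value at client {row!r}"
                )
            if not item.is_continuous:
                ok = col.isin(item.levels)
                if not ok.all():
                    row = df.index[~ok][0]
                    raise ValidationError(
                        f"item {item.code!r}: value {df.loc[row, item.code]!r} at "
                        f"client {row!r} outside declared levels {item.levels}"
                    )

    # -- views --------------------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def outcome(self) -> np.ndarray:
        return self.df[OUTCOME_COL].to_numpy(dtype=np.int64)

    def records(self) -> Iterator[ClientRecord]:
        item_cols = self.dictionary.codes
        for cid, row in self.df.iterrows():
            yield ClientRecord(
                client_id=str(cid),
                item_values={c: row[c] for c in item_cols},
                outcome=int(row[OUTCOME_COL]),
            )

    def subset(self, index) -> "Cohort":
        return Cohort(self.df.loc[index], self.dictionary, validate=False)

    def __len__(self) -> int:
        return self.n

    def __repr__(self) -> str:
        return f"Cohort(n={self.n}, items={len(self.dictionary)}, d={self.dictionary.d})"


def read_cohort(path, dictionary: ItemDictionary, outcome_col: str = OUTCOME_COL) -> Cohort:
    """Read a cohort CSV (header row of item codes plus the outcome column)."""
    df = pd.read_csv(path, comment="#")
    if "client_id" not in df.columns:
        raise ValidationError("cohort CSV must have a 'client_id' column")
    df["client_id"] = df["client_id"].astype(str)
    df = df.set_index("client_id")
    if outcome_col not in df.columns:
        raise ValidationError(f"missing outcome column {outcome_col!r}")
    if outcome_col != OUTCOME_COL:
        df = df.rename(columns={outcome_col: OUTCOME_COL})
    return Cohort(df, dictionary)


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort to CSV; ``read_cohort`` inverts this exactly."""
    cohort.df.to_csv(path, index_label="client_id")


# ---------------------------------------------------------------------------
# Design matrix
# ---------------------------------------------------------------------------


@dataclass
class DesignMatrix:
    """Dummy-coded numeric design with per-item column groups.

    Reference-cell coding: an item with ``L`` levels contributes ``L - 1``
    indicator columns (the first level is the dropped reference), all sharing
    one group id; a continuous item contributes a single column in its own
    group.  Group ids partition the columns and biject onto included items.
    """

    X: np.ndarray
    groups: np.ndarray                  # group id per column
    group_codes: list[str]              # item code per group id
    column_labels: list[str]
    constant_mask: np.ndarray           # columns with zero variance (flagged, unscaled)
    standardized: bool
    center: np.ndarray
    scale: np.ndarray

    @property
    def n_groups(self) -> int:
        return len(self.group_codes)

    def group_columns(self, g: int) -> np.ndarray:
        return np.flatnonzero(self.groups == g)

    def columns_for(self, code: str) -> np.ndarray:
        return self.group_columns(self.group_codes.index(code))


def build_design(cohort: Cohort, standardize: bool = True) -> DesignMatrix:
    """Dummy-code the included items of a cohort.

    With ``standardize`` every non-constant column is centred and scaled to
    unit sample standard deviation (ddof=1); constant columns are centred
    (hence identically zero) but left unscaled and flagged, so their groups
    can never enter a penalized path.
    """
    if cohort.n == 0:
        raise ValidationError("cannot build a design from an empty cohort")
    cols: list[np.ndarray] = []
    labels: list[str] = []
    groups: list[int] = []
    group_codes: list[str] = []
    df = cohort.df
    for item in cohort.dictionary.included:
        g = len(group_codes)
        group_codes.append(item.code)
        if item.is_continuous:
            cols.append(df[item.code].to_numpy(dtype=float))
            labels.append(item.code)
            groups.append(g)
        else:
            values = df[item.code].to_numpy()
            for level in item.levels[1:]:
                cols.append((values == level).astype(float))
                labels.append(f"{item.code}={level}")
                groups.append(g)
    X = np.column_stack(cols) if cols else np.empty((cohort.n, 0))
    n, p = X.shape
    center = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1) if n > 1 else np.zeros(p)
    constant_mask = sd == 0.0
    scale = np.where(constant_mask, 1.0, sd)
    if standardize:
        X = (X - center) / scale
    return DesignMatrix(
        X=X,
        groups=np.asarray(groups, dtype=np.int64),
        group_codes=group_codes,
        column_labels=labels,
        constant_mask=constant_mask,
        standardized=standardize,
        center=center,
        scale=scale,
    )
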