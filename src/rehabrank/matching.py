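"""Frequency-matched stratified sampling.

Long-stay home-care clients (who receive the full assessment) differ
systematically from the broader screening population, so items ranked on the
raw caseload may not transfer.  The remedy is frequency matching: draw
samples from the source database so that the joint distribution of five key
variables — age bin, gender, any ADL impairment, any cognitive impairment,
any falls — equals the screening population's published joint distribution
over its 80 strata (16 binary patterns x 5 age bins).

Stratum definitions: Gender = 1 if male; ADL = 1 if any of the ten ADL items
(H2A-H2J) >= 1; Cognition = 1 if cognitive skills for daily decision making
(B2A) >= 1; Falls = 1 if falls frequency (K5) >= 1; age binned as
<50, 50-64, 65-74, 75-84, >84.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd

from .data_model import Cohort, ValidationError

logger = logging.getLogger(__name__)

AGE_BINS = ("<50", "50-64", "65-74", "75-84", ">84")
_AGE_EDGES = (50, 65, 75, 85)  # left-closed bins: [0,50), [50,65), [65,75), [75,85), [85,inf)


class StratumKey(NamedTuple):
    """One of the 80 matching strata."""

    age_bin: str
    gender: int
    adl: int
    cognition: int
    falls: int


class MatchingError(ValueError):
    """A matched draw could not satisfy its per-stratum counts."""


# ---------------------------------------------------------------------------
# Target joint distribution of the screening (Contact Assessment) population
# over the five matching variables, in percent.  Rows are (gender, adl,
# cognition, falls) patterns; columns the five age bins.  Grand total 100.00.
# ---------------------------------------------------------------------------
CA_POPULATION_PERCENT: dict[tuple[int, int, int, int], tuple[float, ...]] = {
    (1, 1, 1, 1): (0.06, 0.16, 0.15, 0.20, 0.09),
    (1, 1, 1, 0): (0.39, 0.41, 0.73, 2.12, 1.68),
    (1, 1, 0, 1): (0.39, 0.60, 0.38, 0.36, 0.10),
    (1, 1, 0, 0): (0.72, 1.57, 2.00, 3.57, 2.12),
    (1, 0, 1, 1): (0.09, 0.11, 0.05, 0.08, 0.01),
    (1, 0, 1, 0): (0.14, 0.18, 0.23, 0.62, 0.44),
    (1, 0, 0, 1): (2.09, 1.79, 0.72, 0.44, 0.09),
    (1, 0, 0, 0): (3.32, 4.41, 3.76, 4.37, 1.84),
    (0, 1, 1, 1): (0.05, 0.13, 0.11, 0.24, 0.11),
    (0, 1, 1, 0): (0.41, 0.46, 0.69, 2.82, 3.56),
    (0, 1, 0, 1): (0.46, 0.70, 0.48, 0.56, 0.16),
    (0, 1, 0, 0): (1.23, 2.44, 2.99, 6.36, 5.02),
    (0, 0, 1, 1): (0.07, 0.08, 0.05, 0.09, 0.03),
    (0, 0, 1, 0): (0.16, 0.15, 0.23, 0.89, 0.70),
    (0, 0, 0, 1): (1.96, 1.43, 0.56, 0.47, 0.10),
    (0, 0, 0, 0): (4.62, 4.84, 3.81, 5.39, 2.81),
}


@dataclass(frozen=True)
class MatchingItems:
    """Raw item codes from which the five matching variables are derived."""

    age: str = "AGE"
    gender: str = "GENDER"
    adl_items: tuple[str, ...] = tuple(f"H2{c}" for c in "ABCDEFGHIJ")
    cognition: str = "B2A"
    falls: str = "K5"


DEFAULT_MATCHING_ITEMS = MatchingItems()


class StratumTable:
    """Target percentage per stratum; totals must be 100 within +/-0.05
    (two-decimal rounding of printed cells)."""

    TOTAL_TOL = 0.05

    def __init__(self, cells: Mapping[StratumKey, float]):
        self.cells: dict[StratumKey, float] = {StratumKey(*k): float(v) for k, v in cells.items()}
        for key, pct in self.cells.items():
            if pct < 0:
                raise ValidationError(f"stratum {key}: negative percentage {pct}")
            if key.age_bin not in AGE_BINS:
                raise ValidationError(f"stratum {key}: unknown age bin")
        total = sum(self.cells.values())
        if abs(total - 100.0) > self.TOTAL_TOL:
            raise ValidationError(f"stratum percentages total {total:.4f}, not 100")

    def __getitem__(self, key: StratumKey) -> float:
        return self.cells.get(StratumKey(*key), 0.0)

    def __len__(self) -> int:
        return len(self.cells)

    @property
    def total(self) -> float:
        return sum(self.cells.values())

    def keys_in_order(self) -> list[StratumKey]:
        """Deterministic cell order: pattern rows as published, age bins left to right."""
        return sorted(
            self.cells,
            key=lambda k: (-k.gender, -k.adl, -k.cognition, -k.falls, AGE_BINS.index(k.age_bin)),
        )

    @classmethod
    def ca_population(cls) -> "StratumTable":
        """The packaged screening-population target distribution."""
        cells = {
            StratumKey(age_bin, *pattern): pct
            for pattern, row in CA_POPULATION_PERCENT.items()
            for age_bin, pct in zip(AGE_BINS, row)
        }
        return cls(cells)

    # -- serialisation ------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"age_bin": k.age_bin, "gender": k.gender, "adl": k.adl,
             "cognition": k.cognition, "falls": k.falls, "percent": v}
            for k, v in sorted(self.cells.items())
        ]
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "StratumTable":
        df = pd.read_csv(path)
        cells = {
            StratumKey(r.age_bin, int(r.gender), int(r.adl), int(r.cognition), int(r.falls)): float(r.percent)
            for r in df.itertuples()
        }
        return cls(cells)


# ---------------------------------------------------------------------------
# Stratum keys
# ---------------------------------------------------------------------------


def age_bin_of(age: float) -> str:
    """Bin an age in years; bins are closed on the left."""
    if age is None or (isinstance(age, float) and np.isnan(age)):
        raise ValidationError("age is missing")
    if age < 0:
        raise ValidationError(f"negative age {age}")
    for label, edge in zip(AGE_BINS, _AGE_EDGES):
        if age < edge:
            return label
    return AGE_BINS[-1]


def stratum_key(values: Mapping, age: float | None = None,
                items: MatchingItems = DEFAULT_MATCHING_ITEMS) -> StratumKey:
    """Derive the matching stratum of one record from its raw items.

    ``values`` must carry the gender item, the ten ADL items, the cognition
    item and the falls item; ``age`` defaults to the record's age item.
    """
    if age is None:
        if items.age not in values:
            raise ValidationError(f"record carries no age item {items.age!r}")
        age = float(values[items.age])
    adl = int(any(float(values[c]) >= 1 for c in items.adl_items))
    return StratumKey(
        age_bin=age_bin_of(age),
        gender=int(values[items.gender]),
        adl=adl,
        cognition=int(float(values[items.cognition]) >= 1),
        falls=int(float(values[items.falls]) >= 1),
    )


def assign_strata(cohort: Cohort, items: MatchingItems = DEFAULT_MATCHING_ITEMS) -> pd.Series:
    """Vectorised stratum keys for every record of a cohort."""
    df = cohort.df
    for code in (items.age, items.gender, items.cognition, items.falls, *items.adl_items):
        if code not in df.columns:
            raise ValidationError(f"cohort carries no raw matching item {code!r}")
    age = df[items.age].to_numpy(dtype=float)
    if (age < 0).any():
        raise ValidationError("negative age in cohort")
    bins = np.asarray(AGE_BINS, dtype=object)[np.searchsorted(_AGE_EDGES, age, side="right")]
    adl = (df[list(items.adl_items)].to_numpy(dtype=float) >= 1).any(axis=1).astype(int)
    cog = (df[items.cognition].to_numpy(dtype=float) >= 1).astype(int)
    falls = (df[items.falls].to_numpy(dtype=float) >= 1).astype(int)
    gender = df[items.gender].to_numpy(dtype=int)
    keys = [StratumKey(b, g, a, c, f) for b, g, a, c, f in zip(bins, gender, adl, cog, falls)]
    return pd.Series(keys, index=df.index, name="stratum")


# ---------------------------------------------------------------------------
# Count allocation and matched draws
# ---------------------------------------------------------------------------


def allocate_counts(table: StratumTable, n: int) -> dict[StratumKey, int]:
    """Integer per-stratum counts summing exactly to ``n``.

    Largest-remainder (Hamilton) apportionment: floor every quota
    ``n * pct / 100`` and hand the remaining units to the cells with the
    largest fractional remainders.  Integer-exact quotas (e.g. 10,000 x
    0.06 % = 6) are honoured exactly.
    """
    if n <= 0:
        raise ValidationError(f"target sample size must be positive, got {n}")
    keys = table.keys_in_order()
    quotas = np.array([n * table[k] / 100.0 for k in keys])
    base = np.floor(quotas + 1e-9).astype(int)  # guard float dust on exact quotas
    shortfall = n - int(base.sum())
    counts = dict(zip(keys, base))
    remainders = quotas - base
    if shortfall > 0:
        order = sorted(range(len(keys)), key=lambda i: (-remainders[i], i))
        for i in order[:shortfall]:
            counts[keys[i]] += 1
    elif shortfall < 0:
        # table totals slightly above 100: retract units from the smallest remainders
        order = sorted(range(len(keys)), key=lambda i: (remainders[i], i))
        removed = 0
        for i in order:
            if removed == -shortfall:
                break
            if counts[keys[i]] > 0:
                counts[keys[i]] -= 1
                removed += 1
    return counts


def draw_matched_sample(source: Cohort, table: StratumTable, n: int, seed: int,
                        allow_replacement: bool = False,
                        items: MatchingItems = DEFAULT_MATCHING_ITEMS) -> Cohort:
    """Draw a frequency-matched sample of size ``n`` from ``source``.

    Per-stratum counts come from :func:`allocate_counts`; within each stratum
    records are drawn uniformly without replacement.  A stratum holding fewer
    source records than its allocation raises :class:`MatchingError` unless
    ``allow_replacement`` permits topping up with replacement (logged).
    """
    counts = allocate_counts(table, n)
    strata = assign_strata(source, items)
    rng = np.random.default_rng(seed)
    by_key: dict[StratumKey, np.ndarray] = {
        key: np.asarray(grp.index) for key, grp in strata.groupby(strata.values)
    }
    chosen: list[np.ndarray] = []
    replaced = False
    for key in sorted(counts):
        need = counts[key]
        if need == 0:
            continue
        pool = by_key.get(key)
        avail = 0 if pool is None else len(pool)
        if avail < need:
            if not allow_replacement or avail == 0:
                raise MatchingError(
                    f"stratum {tuple(key)}: need {need} records, source has {avail} "
                    f"(deficit {need - avail})"
                )
            logger.warning("stratum %s short by %d; drawing with replacement",
                           tuple(key), need - avail)
            replaced = True
            take = np.concatenate([
                rng.permutation(pool),
                rng.choice(pool, size=need - avail, replace=True),
            ])
        else:
            take = rng.choice(pool, size=need, replace=False)
        chosen.append(take)
    idx = np.concatenate(chosen)
    df = source.df.loc[idx]
    if replaced:
        # disambiguate repeated clients so the sample is still a valid cohort
        dup = df.index.duplicated(keep=False)
        if dup.any():
            new_index = df.index.to_numpy(dtype=object).copy()
            seen: dict[str, int] = {}
            for i, cid in enumerate(new_index):
                k = seen.get(cid, 0)
                if k:
                    new_index[i] = f"{cid}#r{k}"
                seen[cid] = k + 1
            df = df.set_axis(pd.Index(new_index, name=df.index.name))
    return Cohort(df, source.dictionary, validate=False)


def empirical_table(cohort: Cohort, items: MatchingItems = DEFAULT_MATCHING_ITEMS) -> StratumTable:
    """Observed joint distribution of a cohort over the matching strata."""
    strata = assign_strata(cohort, items)
    pct = strata.value_counts(normalize=True) * 100.0
    return StratumTable({k: v for k, v in pct.items()})
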