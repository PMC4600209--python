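"""Synthetic cohort generator.

The real assessment/service-use data are confidential, so every downstream
stage is exercised on generated cohorts that reproduce the statistical
structure the analysis assumes:

* the five matching variables follow the published screening-population
  joint distribution over 80 strata;
* the raw items behind the derived flags (ADL items H2A-H2J, cognition item
  B2A, falls count K5) are back-filled consistently with those flags;
* an extra battery of mostly-categorical items stands in for the ~239-item
  instrument;
* the binary outcome is Bernoulli with a logistic link over planted main
  effects and optional pairwise (product) interactions.

One global seed expands into fixed per-stage substreams, so a generated
cohort is a pure function of its :class:`GeneratorSpec`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data_model import (
    Cohort,
    Item,
    ItemDictionary,
    KIND_CATEGORICAL,
    KIND_CONTINUOUS,
    OUTCOME_COL,
    ValidationError,
)
from .matching import (
    AGE_BINS,
    DEFAULT_MATCHING_ITEMS,
    StratumKey,
    StratumTable,
    allocate_counts,
)

# integer age ranges per bin (closed)
_AGE_RANGES = {"<50": (18, 49), "50-64": (50, 64), "65-74": (65, 74),
               "75-84": (75, 84), ">84": (85, 99)}

# fixed substream labels expanded from the global seed
_STAGE = {"block": 1, "backfill": 2, "extras": 3, "outcome": 4}


def _rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STAGE[stage]]))


@dataclass(frozen=True)
class ExtraItem:
    """One battery item beyond the raw matching items.

    Discrete items carry an ordered level set and matching marginal
    probabilities (must sum to 1 within 1e-9); continuous items carry a
    normal ``(mean, sd)`` instead.
    """

    code: str
    kind: str = KIND_CATEGORICAL
    levels: tuple | None = (0, 1)
    probs: tuple | None = (0.5, 0.5)
    normal: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        if self.kind != KIND_CONTINUOUS:
            if self.levels is None or self.probs is None or len(self.levels) != len(self.probs):
                raise ValidationError(f"item {self.code!r}: levels and probs must align")
            if abs(sum(self.probs) - 1.0) > 1e-9:
                raise ValidationError(
                    f"item {self.code!r}: marginal probabilities sum to {sum(self.probs)}, not 1"
                )


@dataclass(frozen=True)
class GeneratorSpec:
    """Full recipe for one synthetic cohort.

    ``planted_effects`` maps an item code to either a scalar log-odds slope
    (applied to the item's numeric value) or a ``{level: offset}`` mapping
    for categorical items (missing levels contribute 0).
    ``planted_interactions`` is a list of ``(code_a, code_b, coefficient)``
    product terms on the log-odds scale.
    """

    n: int
    extra_items: tuple[ExtraItem, ...] = ()
    planted_effects: dict = field(default_factory=dict)
    planted_interactions: tuple = ()
    intercept: float = -1.5
    seed: int = 0
    include_matching_items: bool = False
    exact_strata: bool = False   # allocate stratum counts exactly instead of multinomially

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValidationError(f"cohort size must be positive, got {self.n}")
        object.__setattr__(self, "extra_items", tuple(self.extra_items))
        object.__setattr__(self, "planted_interactions",
                           tuple(tuple(t) for t in self.planted_interactions))


def default_battery() -> tuple[ExtraItem, ...]:
    """Desk-scale stand-in battery: 30 binary, 10 three-level, 2 continuous.

    Binary prevalences cycle through 0.1..0.5 so the battery spans the
    sparse-to-common range seen in assessment items.
    """
    binary = tuple(
        ExtraItem(code=f"B{i:02d}", levels=(0, 1),
                  probs=(1 - p, p))
        for i, p in ((i, (0.1, 0.2, 0.3, 0.4, 0.5)[(i - 1) % 5]) for i in range(1, 31))
    )
    trilevel = tuple(
        ExtraItem(code=f"T{i:02d}", levels=(0, 1, 2), probs=(0.6, 0.3, 0.1))
        for i in range(1, 11)
    )
    continuous = tuple(
        ExtraItem(code=f"Z{i:02d}", kind=KIND_CONTINUOUS, levels=None, probs=None)
        for i in (1, 2)
    )
    return binary + trilevel + continuous


def recovery_spec(seed: int = 0, n: int = 50_000) -> GeneratorSpec:
    """Planted-signal recovery conditions for the scaled-down study profile.

    Three strong main effects (|beta| >= 1.5) on battery items of moderate
    prevalence plus one interaction-only pair: two p = 0.5 binary items with
    zero main effects and a product coefficient of 2.0 on the log-odds
    scale.  The pair's marginal association (~1.1 log-odds) is weaker than
    any planted main, so a main-effects-only ranker places it behind the
    mains while an interaction-aware ranker can move it up.
    """
    return GeneratorSpec(
        n=n,
        extra_items=default_battery(),
        planted_effects={"B03": 1.5, "B04": 1.6, "B13": -1.7},
        planted_interactions=(("B05", "B10", 2.0),),
        intercept=-1.6,
        seed=seed,
    )


def demo_spec(n: int = 2000, seed: int = 0) -> GeneratorSpec:
    """Default demonstration cohort: the standard battery with a few sparse
    planted effects and ~20 % outcome prevalence."""
    return GeneratorSpec(
        n=n,
        extra_items=default_battery(),
        planted_effects={"B01": 1.5, "B02": -1.2, "T01": {1: 0.7, 2: 1.4}, "Z01": 0.6},
        intercept=-1.6,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Matching block
# ---------------------------------------------------------------------------


def sample_matching_block(n: int, stratum_table: StratumTable, seed: int,
                          exact: bool = False) -> pd.DataFrame:
    """Draw ``n`` rows of the five matching variables from a stratum table.

    Each row is assigned one of the 80 cells — multinomially with the
    table's probabilities by default, or with exact largest-remainder counts
    when ``exact`` (useful for building sources guaranteed to cover every
    stratum).  Ages are uniform integers within the cell's bin.
    """
    if n <= 0:
        raise ValidationError(f"n must be positive, got {n}")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), _STAGE["block"]]))
    keys = stratum_table.keys_in_order()
    if exact:
        counts_map = allocate_counts(stratum_table, n)
        counts = np.array([counts_map[k] for k in keys])
    else:
        probs = np.array([stratum_table[k] for k in keys], dtype=float)
        probs = probs / probs.sum()
        counts = rng.multinomial(n, probs)
    cells = np.repeat(np.arange(len(keys)), counts)
    rng.shuffle(cells)
    age_lo = np.array([_AGE_RANGES[k.age_bin][0] for k in keys])
    age_hi = np.array([_AGE_RANGES[k.age_bin][1] for k in keys])
    age = rng.integers(age_lo[cells], age_hi[cells] + 1)
    df = pd.DataFrame({
        "AGE_BIN": [keys[c].age_bin for c in cells],
        "GENDER": np.array([k.gender for k in keys])[cells],
        "ADL": np.array([k.adl for k in keys])[cells],
        "COGNITION": np.array([k.cognition for k in keys])[cells],
        "FALLS": np.array([k.falls for k in keys])[cells],
        "AGE": age.astype(float),
    })
    return df


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------


def _backfill_raw_items(block: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Raw items consistent with the derived flags.

    ADL = 1: a uniform 1..10 subset of H2A-H2J is elevated to levels 1..3;
    ADL = 0: all ten are 0.  Cognition maps to B2A in 1..3 or 0; Falls maps
    to K5 = 1 + Binomial(4, 0.25) or 0.
    """
    rng = _rng(seed, "backfill")
    n = len(block)
    adl_codes = list(DEFAULT_MATCHING_ITEMS.adl_items)
    out = {}
    adl_flag = block["ADL"].to_numpy()
    m = np.where(adl_flag == 1, rng.integers(1, len(adl_codes) + 1, size=n), 0)
    # rank-based random subset selection per row
    u = rng.random((n, len(adl_codes)))
    ranks = np.argsort(np.argsort(u, axis=1), axis=1)
    elevated = ranks < m[:, None]
    values = rng.integers(1, 4, size=(n, len(adl_codes)))
    for j, code in enumerate(adl_codes):
        out[code] = np.where(elevated[:, j], values[:, j], 0)
    cog = block["COGNITION"].to_numpy()
    out["B2A"] = np.where(cog == 1, rng.integers(1, 4, size=n), 0)
    falls = block["FALLS"].to_numpy()
    out["K5"] = np.where(falls == 1, 1 + rng.binomial(4, 0.25, size=n), 0).astype(float)
    return pd.DataFrame(out, index=block.index)


def _linear_predictor(spec: GeneratorSpec, df: pd.DataFrame) -> np.ndarray:
    eta = np.full(len(df), float(spec.intercept))
    for code, eff in spec.planted_effects.items():
        if code not in df.columns:
            raise ValidationError(f"planted effect on unknown item {code!r}")
        x = df[code].to_numpy(dtype=float)
        if isinstance(eff, dict):
            term = np.zeros(len(df))
            for level, offset in eff.items():
                term += float(offset) * (df[code].to_numpy() == level)
            eta += term
        else:
            eta += float(eff) * x
    for code_a, code_b, coef in spec.planted_interactions:
        for code in (code_a, code_b):
            if code not in df.columns:
                raise ValidationError(f"planted interaction on unknown item {code!r}")
        eta += float(coef) * df[code_a].to_numpy(dtype=float) * df[code_b].to_numpy(dtype=float)
    return eta


def _battery_dictionary(spec: GeneratorSpec) -> ItemDictionary:
    inc = spec.include_matching_items
    items = [
        Item("AGE", KIND_CONTINUOUS, include=inc),
        Item("GENDER", KIND_CATEGORICAL, (0, 1), include=inc),
    ]
    items += [Item(c, KIND_CATEGORICAL, (0, 1, 2, 3), include=inc)
              for c in DEFAULT_MATCHING_ITEMS.adl_items]
    items += [
        Item("B2A", KIND_CATEGORICAL, (0, 1, 2, 3), include=inc),
        Item("K5", KIND_CONTINUOUS, include=inc),
    ]
    for extra in spec.extra_items:
        if extra.kind == KIND_CONTINUOUS:
            items.append(Item(extra.code, KIND_CONTINUOUS))
        else:
            items.append(Item(extra.code, KIND_CATEGORICAL, tuple(extra.levels)))
    return ItemDictionary(items)


def generate_cohort(spec: GeneratorSpec, stratum_table: StratumTable | None = None) -> Cohort:
    """Generate a full synthetic cohort from a :class:`GeneratorSpec`."""
    table = stratum_table if stratum_table is not None else StratumTable.ca_population()
    block = sample_matching_block(spec.n, table, spec.seed, exact=spec.exact_strata)
    raw = _backfill_raw_items(block, spec.seed)
    df = pd.concat([block[["AGE", "GENDER"]], raw], axis=1)

    rng_x = _rng(spec.seed, "extras")
    for extra in spec.extra_items:
        if extra.code in df.columns:
            raise ValidationError(f"duplicate item code {extra.code!r}")
        if extra.kind == KIND_CONTINUOUS:
            mu, sd = extra.normal
            df[extra.code] = rng_x.normal(mu, sd, size=spec.n)
        else:
            df[extra.code] = rng_x.choice(np.asarray(extra.levels),
                                          p=np.asarray(extra.probs), size=spec.n)

    eta = _linear_predictor(spec, df)
    rng_y = _rng(spec.seed, "outcome")
    p = 1.0 / (1.0 + np.exp(-eta))
    df[OUTCOME_COL] = rng_y.binomial(1, p)

    df.index = pd.Index([f"C{i:06d}" for i in range(spec.n)], name="client_id")
    return Cohort(df, _battery_dictionary(spec))
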