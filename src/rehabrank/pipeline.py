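"""Run configuration and the end-to-end pipeline.

A :class:`RunConfig` fully determines a run (generate/load source -> matched
resampling -> both rankers -> aggregation -> comparison -> RA overlap); all
artifacts are computed first and written only on success, each tagged with
the configuration hash in a provenance record so a run is reproducible from
its config alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .data_model import ItemDictionary, ValidationError, read_cohort
from .ensemble import compare_rankings, effect_direction, ensemble_ranks
from .matching import StratumTable
from .ra_scorer import HC_CA_CROSSWALK, RA_CA_ITEMS, items_overlap
from .synthetic import GeneratorSpec, default_battery, demo_spec, generate_cohort

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Serializable recipe for one full pipeline run."""

    out_dir: str = "rehabrank_out"
    # source: either a generator recipe or paths to an existing cohort
    source_n: int = 50_000
    cohort_csv: str | None = None
    dictionary_yaml: str | None = None
    stratum_csv: str | None = None      # default: packaged CA population table
    # ensemble settings
    K: int = 10
    n: int = 2_000
    rankers: tuple[str, ...] = ("path", "forest")
    top_threshold: float = 20.0
    # scaled-down ranker profile (full-scale study: K=100, n=10,000, 500 trees)
    path_n_lambda: int = 100
    forest_n_trees: int = 100
    master_seed: int = 0
    make_plots: bool = False
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.K < 1:
            raise ValidationError(f"K must be >= 1, got {self.K}")
        if self.n < 1:
            raise ValidationError(f"n must be >= 1, got {self.n}")
        if self.source_n < self.n:
            raise ValidationError("source_n must be at least the matched-sample size n")
        for r in self.rankers:
            if r not in ("path", "forest"):
                raise ValidationError(f"unknown ranker {r!r}")
        if (self.cohort_csv is None) != (self.dictionary_yaml is None):
            raise ValidationError("cohort_csv and dictionary_yaml must be given together")

    # -- identity -----------------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["rankers"] = list(self.rankers)
        return d

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        if "rankers" in payload:
            payload["rankers"] = tuple(payload["rankers"])
        return cls(**payload)


def _load_source(config: RunConfig):
    if config.cohort_csv is not None:
        dictionary = ItemDictionary.from_yaml(config.dictionary_yaml)
        return read_cohort(config.cohort_csv, dictionary)
    spec = demo_spec(n=config.source_n, seed=config.master_seed)
    return generate_cohort(spec)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline; returns {artifact name: path}.

    Stages: load or generate the source cohort, run each configured ranker
    through the K-sample matched ensemble, compare rankings, determine
    effect directions for the jointly-top items, and report the overlap with
    the RA's expert item list.  Any stage error aborts before any artifact
    is written.
    """
    config.validate()
    logging.basicConfig(level=config.log_level)
    table = (StratumTable.from_csv(config.stratum_csv) if config.stratum_csv
             else StratumTable.ca_population())

    logger.info("stage 1/5: source cohort")
    source = _load_source(config)

    summaries = {}
    matrices = {}
    for ranker in config.rankers:
        logger.info("stage 2/5: ensemble ranking (%s, K=%d, n=%d)", ranker, config.K, config.n)
        kwargs = ({"n_lambda": config.path_n_lambda} if ranker == "path"
                  else {"n_trees": config.forest_n_trees})
        matrices[ranker], summaries[ranker] = ensemble_ranks(
            source, table, ranker, K=config.K, n=config.n,
            master_seed=config.master_seed, **kwargs)

    report = None
    directions = {}
    if len(summaries) == 2:
        logger.info("stage 3/5: ranker comparison")
        report = compare_rankings(summaries["path"], summaries["forest"],
                                  top_threshold=config.top_threshold)
        if report.both_top:
            logger.info("stage 4/5: effect directions for %d jointly-top items",
                        len(report.both_top))
            directions = effect_direction(source, sorted(report.both_top))

    logger.info("stage 5/5: RA overlap")
    any_summary = next(iter(summaries.values()))
    overlap = items_overlap(any_summary, RA_CA_ITEMS, HC_CA_CROSSWALK,
                            top_threshold=config.top_threshold)

    # ---- everything computed; emit artifacts ------------------------------
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    h = config.config_hash
    artifacts: dict[str, str] = {}

    def _emit(name: str, writer) -> None:
        path = out / name
        writer(path)
        artifacts[name] = str(path)

    for ranker in config.rankers:
        _emit(f"rank_matrix_{ranker}.csv", matrices[ranker].to_frame().to_csv)
        _emit(f"rank_summary_{ranker}.csv",
              lambda p, r=ranker: summaries[r].to_frame().to_csv(p, index=False))
    if report is not None:
        _emit("comparison_paired.csv", lambda p: report.paired.to_csv(p, index=False))
        _emit("comparison.json", lambda p: Path(p).write_text(json.dumps({
            "config_hash": h,
            "spearman": report.spearman,
            "top_threshold": report.top_threshold,
            "both_top": sorted(report.both_top),
            "only_path": sorted(report.only_a),
            "only_forest": sorted(report.only_b),
            "effect_direction": {k: v.sign for k, v in directions.items()},
        }, indent=2)))
        if config.make_plots:
            _emit("comparison_scatter.png", lambda p: _scatter(report, p))
    _emit("ra_overlap.json", lambda p: Path(p).write_text(json.dumps({
        "config_hash": h,
        "overlap": overlap.overlap,
        "overlap_labels": sorted(overlap.overlap_labels),
        "hc_only": overlap.hc_only,
        "ca_only": overlap.ca_only,
    }, indent=2)))
    _emit("provenance.json", lambda p: Path(p).write_text(json.dumps({
        "config_hash": h,
        "config": config.to_dict(),
        "sample_seeds": {r: matrices[r].sample_seeds for r in config.rankers},
        "package_version": __version__,
        "artifacts": sorted(artifacts),
    }, indent=2)))
    _emit("config.yaml", config.to_yaml)
    return artifacts


def _scatter(report, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(report.paired["mean_rank_a"], report.paired["mean_rank_b"], s=12)
    lim = max(report.paired["mean_rank_a"].max(), report.paired["mean_rank_b"].max())
    ax.plot([0, lim], [0, lim], lw=0.5, color="grey")
    ax.axvline(report.top_threshold, lw=0.5, ls="--", color="red")
    ax.axhline(report.top_threshold, lw=0.5, ls="--", color="red")
    ax.set_xlabel("mean rank (path)")
    ax.set_ylabel("mean rank (forest)")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
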