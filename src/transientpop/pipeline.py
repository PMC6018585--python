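"""End-to-end orchestration: generate -> ingest -> matrices -> metrics ->
pseudospectra -> comparative statistics.

A run is fully described by a RunConfig (serialisable to YAML); the
resolved configuration is echoed next to the outputs, and all randomness
flows from the single top-level seed via named substreams per stage, so
identical configs produce identical output files.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import ingest, matrix, nonnormality, pseudospectra, stats, synthetic
from .errors import ConfigurationError, DegenerateBinError, TransientPopError
from .transient import DEFAULT_HORIZON, TransientRecord, transient_record

logger = logging.getLogger(__name__)

_STAGE_SEED_SALT = {"generate": 1, "parallel_analysis": 2}


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed derived from the run seed."""
    ss = np.random.SeedSequence([seed, _STAGE_SEED_SALT.get(stage, 0)])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    output_dir: str = "out"
    seed: int = 0
    input_table: str | None = None  # user table; None -> synthetic
    synthetic: synthetic.SyntheticConfig = field(
        default_factory=synthetic.SyntheticConfig
    )
    sex_ratio_at_birth: float = ingest.DEFAULT_SRB
    zero_run_length: int = ingest.DEFAULT_ZERO_RUN
    inertia_horizon: int = DEFAULT_HORIZON
    pseudospectra_for: tuple[tuple[str, int], ...] = ()
    pseudospectra_resolution: int = pseudospectra.DEFAULT_RESOLUTION
    parallel_analysis_iterations: int = 1000
    parallel_analysis_quantile: float = 0.95

    def resolved(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["synthetic"]["anomaly_spec"] = [
            dataclasses.asdict(a) for a in self.synthetic.anomaly_spec
        ]
        d["pseudospectra_for"] = [list(k) for k in self.pseudospectra_for]
        return d

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "RunConfig":
        raw = dict(raw)
        syn = raw.pop("synthetic", {})
        if isinstance(syn, dict):
            syn = dict(syn)
            anomalies = tuple(
                synthetic.Anomaly(**a) for a in syn.pop("anomaly_spec", [])
            )
            for key in ("years", "boom_ages", "reproductive_window"):
                if key in syn:
                    syn[key] = tuple(syn[key])
            syn = synthetic.SyntheticConfig(anomaly_spec=anomalies, **syn)
        raw["synthetic"] = syn
        raw["pseudospectra_for"] = tuple(
            (str(c), int(y)) for c, y in raw.get("pseudospectra_for", ())
        )
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigurationError(f"config file not found: {path}")
        return cls.from_dict(yaml.safe_load(path.read_text()) or {})


@dataclass
class RunOutputs:
    """Handles to everything one run produced."""

    config: RunConfig
    series: list[ingest.AgeSeries]
    retained: list[ingest.AgeSeries]
    audit: list[ingest.CleaningRecord]
    matrices: list[matrix.ProjectionMatrix]
    records: list[TransientRecord]
    metrics: "Any"  # pandas DataFrame
    output_dir: Path


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                result = fn(*args, **kwargs)
            except TransientPopError as exc:
                raise TransientPopError(f"stage {name!r}: {exc}") from exc
            logger.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
            return result

        return inner

    return wrap


@_stage("generate")
def _load_series(config: RunConfig) -> list[ingest.AgeSeries]:
    if config.input_table is not None:
        return ingest.read_demography_table(config.input_table)
    syn = dataclasses.replace(
        config.synthetic, seed=stage_seed(config.seed, "generate")
    )
    return synthetic.simulate_country_series(syn)


def run_pipeline(config: RunConfig) -> RunOutputs:
    """Execute the full pipeline and write the output bundle.

    Outputs under ``config.output_dir``: the resolved config echo, the
    synthetic input table (when generated), the exclusion audit, per-run
    matrix bundle, the metrics CSV (one row per retained country-year),
    Spearman correlation matrices, PCA loadings/scores, trend summaries,
    and sigma_min grids for any requested country-years.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config_resolved.yaml").write_text(
        yaml.safe_dump(config.resolved(), sort_keys=True)
    )

    series = _load_series(config)
    if config.input_table is None:
        synthetic.write_demography_table(series, out / "input_table.csv")

    retained, audit = ingest.apply_filters(series, config.zero_run_length)
    ingest.write_cleaning_log(audit, out / "exclusions.csv")
    logger.info(
        "retained %d of %d country-years (%d excluded)",
        len(retained), len(series), len(audit),
    )

    matrices: list[matrix.ProjectionMatrix] = []
    records: list[TransientRecord] = []
    for s in retained:
        try:
            binned = ingest.bin_to_five_year(s, config.sex_ratio_at_birth)
            ppm = matrix.build_ppm(binned)
        except DegenerateBinError as exc:
            audit.append(
                ingest.CleaningRecord(s.country, s.year, "degenerate_bin", str(exc))
            )
            continue
        matrices.append(ppm)
        n0 = binned.population  # observed structure, normalised downstream
        rec = transient_record(ppm, n0, horizon=config.inertia_horizon)
        nonnormality.fill_record(rec, ppm)
        records.append(rec)
    if audit:
        ingest.write_cleaning_log(audit, out / "exclusions.csv")

    matrix.write_matrix_bundle(matrices, out / "matrices.csv")
    metrics = stats.records_to_frame(records)
    metrics.to_csv(out / "metrics.csv", index=False)

    if len(metrics) >= 4:
        _comparative_outputs(config, metrics, out)

    index = {m.key: m for m in matrices}
    for key in config.pseudospectra_for:
        if key not in index:
            raise TransientPopError(
                f"stage 'pseudospectra': no matrix for country-year {key}"
            )
        grid = pseudospectra.sigma_min_grid(
            index[key], resolution=config.pseudospectra_resolution
        )
        pseudospectra.write_grid_csv(
            grid, out / f"pseudospectrum_{key[0]}_{key[1]}.csv"
        )

    return RunOutputs(
        config=config,
        series=series,
        retained=retained,
        audit=audit,
        matrices=matrices,
        records=records,
        metrics=metrics,
        output_dir=out,
    )


@_stage("stats")
def _comparative_outputs(config: RunConfig, metrics, out: Path) -> None:
    for tag, columns in (("raw", stats.RAW_VARIABLES), ("scaled", stats.SCALED_VARIABLES)):
        clean, dropped = stats.drop_nonfinite(metrics, columns)
        if dropped:
            logger.info("%s analysis: %d non-finite rows excluded", tag, dropped)
        if len(clean) <= len(columns):
            logger.warning("%s analysis skipped: too few rows", tag)
            continue
        corr = stats.correlation_matrix(clean, columns)
        corr.to_csv(out / f"spearman_{tag}.csv")
        pa = stats.parallel_analysis(
            clean[list(columns)].to_numpy(float),
            n_iter=config.parallel_analysis_iterations,
            quantile=config.parallel_analysis_quantile,
            seed=stage_seed(config.seed, "parallel_analysis"),
        )
        n_keep = max(pa.n_retained, 1)
        result = stats.pca(clean, columns, n_retained=n_keep)
        loadings = pd.DataFrame(
            result.loadings, index=list(columns),
            columns=[f"PC{k+1}" for k in range(len(columns))],
        )
        loadings.to_csv(out / f"pca_loadings_{tag}.csv")
        scores = pd.DataFrame(
            result.scores, columns=[f"PC{k+1}" for k in range(n_keep)]
        )
        scores.insert(0, "country", clean["country"].to_numpy())
        scores.insert(1, "year", clean["year"].to_numpy())
        scores.to_csv(out / f"pca_scores_{tag}.csv", index=False)
    trends = stats.summarise_trends(metrics)
    trends.to_csv(out / "trends.csv", index=False)
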