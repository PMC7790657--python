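"""Pooled summary statistics and reproducible run manifests."""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .population import ExperimentResult, PopulationConfig

__all__ = ["summarize", "RunManifest", "write_experiment"]


def summarize(endpoints: pd.DataFrame,
              by: Sequence[str] = ("group",),
              columns: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Mean +- SD per group (and level, if present) over the pooled records.

    The SD is the sample (n-1) standard deviation of the pooled individual
    records (n = replicates x individuals), not of replicate means; ``n`` in
    the output states the pooled count.
    """
    if endpoints.empty:
        raise ValueError("cannot summarize an empty endpoint table")
    if columns is None:
        columns = [c for c in endpoints.columns
                   if c not in (*by, "replicate", "individual")
                   and pd.api.types.is_numeric_dtype(endpoints[c])]
    grouped = endpoints.groupby(list(by))
    out = grouped[list(columns)].agg(["mean", "std"])
    # A single record has no dispersion, not an undefined one.
    out.loc[:, (slice(None), "std")] = \
        out.loc[:, (slice(None), "std")].fillna(0.0)
    out[("n", "")] = grouped.size()
    return out


@dataclass
class RunManifest:
    """Everything needed to reproduce a run bit-exactly."""

    config: dict[str, Any]
    master_seed: int
    replicate_seeds: list[int]
    package_version: str = __version__
    created: str = field(
        default_factory=lambda: _dt.datetime.now(_dt.timezone.utc).isoformat())

    @classmethod
    def for_config(cls, config: PopulationConfig,
                   extra: Optional[dict[str, Any]] = None) -> "RunManifest":
        seeds = [int(s.generate_state(1)[0]) for s in
                 np.random.SeedSequence(config.seed).spawn(config.n_replicates)]
        snapshot = dataclasses.asdict(config)
        if extra:
            snapshot.update(extra)
        return cls(config=snapshot, master_seed=config.seed,
                   replicate_seeds=seeds)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            json.dump(dataclasses.asdict(self), handle, indent=2, default=str)

    @classmethod
    def read(cls, path: str | Path) -> "RunManifest":
        with open(path) as handle:
            return cls(**json.load(handle))


def write_experiment(result: ExperimentResult, outdir: str | Path,
                     manifest_extra: Optional[dict[str, Any]] = None) -> Path:
    """Write endpoint and daily-trajectory tables plus the run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.endpoints.to_csv(outdir / "endpoints.csv", index=False)
    result.daily.to_csv(outdir / "daily.csv", index=False)
    summarize(result.endpoints).to_csv(outdir / "summary.csv")
    RunManifest.for_config(result.config, manifest_extra).write(
        outdir / "manifest.json")
    return outdir
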