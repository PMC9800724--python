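"""End-to-end orchestration: simulate -> filter -> annotate -> analyze.

A single structured :class:`RunConfig` (loadable from YAML) drives the
whole run; every filter threshold the analysis relies on is surfaced as
a named default, and a provenance manifest (package version, config
hash, seed) is written next to the report so any run can be reproduced
from the manifest alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .annotate import annotate_catalog
from .genome import MitoGenomeModel
from .simulate import SyntheticConfig, generate_cohort, write_calls_tsv, write_truth_tsv
from .stats import build_selection_report
from .variants import classify_somatic, read_site_calls, write_catalog

log = logging.getLogger("mtselect")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Configuration of one pipeline run (defaults = study thresholds)."""

    outdir: str = "mtselect_run"
    seed: int = 0
    # input: either a calls file or a synthetic cohort
    calls: str | None = None
    format: str = "tsv"
    n_samples: int | None = None
    simulate: dict | None = None  # SyntheticConfig fields
    # analysis options
    vaf_bins: tuple[float, ...] = (0.01, 0.05, 0.5, 1.0)
    correlation: str = "pearson"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            log.info("stage %s: start", name)
            try:
                result = fn(*args, **kwargs)
            except Exception as exc:
                raise StageError(f"stage {name} failed: {exc}") from exc
            log.info("stage %s: done in %.2fs", name, time.perf_counter() - t0)
            return result

        return wrapped

    return deco


def run_pipeline(config: RunConfig, model: MitoGenomeModel | None = None) -> Path:
    """Execute all stages in order; returns the report directory."""
    model = model or MitoGenomeModel.bundled()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.simulate is not None:
        sim = SyntheticConfig(**{**config.simulate, "seed": config.seed})
        calls, truth = _stage("simulate")(generate_cohort)(sim, model)
        write_calls_tsv(calls, outdir / "sim_calls.tsv")
        write_truth_tsv(truth, outdir / "sim_truth.tsv", sim)
        calls_path = outdir / "sim_calls.tsv"
        n_samples = sim.n_samples
        fmt = "tsv"
    elif config.calls is not None:
        calls_path = Path(config.calls)
        n_samples = config.n_samples
        fmt = config.format
        if n_samples is None:
            raise StageError("stage filter failed: n_samples required for external calls")
    else:
        raise StageError("stage input failed: neither calls nor simulate configured")

    calls = _stage("read")(read_site_calls)(calls_path, format=fmt)
    catalog, qc = _stage("filter")(classify_somatic)(calls, n_samples, model)
    catalog = _stage("annotate")(annotate_catalog)(catalog, model)
    write_catalog(catalog, outdir / "catalog.tsv", qc=qc)

    report = _stage("analyze")(build_selection_report)(catalog, model)
    report.write(outdir)

    manifest = {
        "mtselect_version": __version__,
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_mutations": len(catalog),
        "n_samples": catalog.n_samples,
    }
    (outdir / "provenance.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n"
    )
    return outdir
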