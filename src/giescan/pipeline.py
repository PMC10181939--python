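"""Seeded end-to-end orchestration of the GIE analyses with tabular reporting.

A single master seed fans out to per-stage seeds through a documented SHA-256
hash, so stages are reproducible independently and the whole run is
byte-identical for a fixed configuration. Every stage writes fixed-column TSV
output plus a machine-readable run report.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .allele_loss_bias import bootstrap_bias, collect_records, ks_bias_test
from .cna_selection import selection_scan
from .genome_model import hg19_genome, load_gene_registry, make_bins, toy_genome
from .gie_annotation import (
    annotate_cohort, compare_cohorts, mutual_exclusivity, prevalence, qc_filter,
)
from .gie_simulation import run_simulations
from .synthetic_cohort import CohortConfig, generate_cohort, read_cohort, write_cohort
from .tmb_association import bucket_gie_frequency, overlay_simulated

log = logging.getLogger(__name__)

STAGES = (
    "simulate-cohort", "annotate", "prevalence", "compare", "exclusivity",
    "selection", "allele-bias", "tmb", "simulate-gie",
)

DEFAULT_PARAMS = {
    "selection": {"event_type": "loh", "scale": "focal", "n_rand": 10,
                  "bin_size": 100_000},
    "allele-bias": {"focality": "all", "n_boot": 100, "subsample": 0.75},
    "tmb": {"baseline": "tmb", "exclude_nonfocal_loh": False, "n_buckets": 20,
            "n_boot": 1000, "frac": 0.5},
    "simulate-gie": {"n_iter": 100},
    "exclusivity": {"n_rand": 10_000},
    "qc": {"purity_min": 0.2, "tmb_min": 50},
}


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).hexdigest()
    return int(digest[:8], 16) % (2**31)


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    out_dir: str = "gie_run"
    seed: int = 0
    stages: list = field(default_factory=lambda: list(STAGES))
    input_dir: str | None = None  # read an existing cohort instead of generating
    cohort: dict = field(default_factory=dict)  # CohortConfig overrides
    genome: str = "hg19"  # "hg19" or "toy"
    params: dict = field(default_factory=dict)  # per-stage overrides

    def validate(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stage name(s): {sorted(unknown)}")
        unknown_params = set(self.params) - set(DEFAULT_PARAMS)
        if unknown_params:
            raise ValueError(f"unknown parameter group(s): {sorted(unknown_params)}")
        if self.genome not in ("hg19", "toy"):
            raise ValueError(f"unknown genome {self.genome!r}")

    def stage_params(self, stage: str) -> dict:
        merged = dict(DEFAULT_PARAMS.get(stage, {}))
        merged.update(self.params.get(stage, {}))
        return merged

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown RunConfig field(s): {sorted(unknown)}")
        return cls(**raw)


def _write(df: pd.DataFrame, path: Path) -> str:
    df.to_csv(path, sep="\t", index=False)
    return path.name


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages in dependency order; returns the run report."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    genome = hg19_genome() if config.genome == "hg19" else toy_genome()
    registry = load_gene_registry()
    report: dict = {
        "package": "gie-scan",
        "version": __version__,
        "seed": config.seed,
        "stages": list(config.stages),
        "params": {s: config.stage_params(s) for s in STAGES if s in DEFAULT_PARAMS},
        "outputs": {},
        "warnings": [],
    }
    stage = "setup"
    try:
        # --- cohort ---
        if config.input_dir:
            bundle = read_cohort(config.input_dir)
        else:
            stage = "simulate-cohort"
            cohort_cfg = CohortConfig(**config.cohort)
            if "seed" not in config.cohort:
                cohort_cfg.seed = stage_seed(config.seed, "simulate-cohort")
            bundle = generate_cohort(cohort_cfg, genome=genome)
            if stage in config.stages:
                write_cohort(bundle, out_dir / "cohort")
                report["outputs"]["simulate-cohort"] = "cohort"

        qc = config.stage_params("qc")
        kept, excluded = qc_filter(bundle.samples, **qc)
        samples = bundle.samples[bundle.samples["sample_id"].isin(kept)]
        if not excluded.empty:
            _write(excluded, out_dir / "qc_exclusions.tsv")
            report["warnings"].append(f"{len(excluded)} sample(s) failed QC")

        events = None
        if {"annotate", "prevalence", "compare", "exclusivity",
            "allele-bias", "tmb"} & set(config.stages):
            stage = "annotate"
            events = annotate_cohort(
                samples, bundle.segments, bundle.mutations, bundle.hla,
                registry, genome,
            )
            report["outputs"]["annotate"] = _write(events, out_dir / "events.tsv")

        if "prevalence" in config.stages:
            stage = "prevalence"
            prev = prevalence(events, samples)
            report["outputs"]["prevalence"] = _write(prev, out_dir / "prevalence.tsv")

        if "compare" in config.stages:
            stage = "compare"
            cohorts = sorted(samples["cohort"].unique())
            if len(cohorts) >= 2:
                comp, skipped = compare_cohorts(events, samples, cohorts[0], cohorts[1])
                report["outputs"]["compare"] = _write(comp, out_dir / "comparison.tsv")
                report["warnings"] += [f"compare: skipped cancer type {c}" for c in skipped]
            else:
                report["warnings"].append("compare: fewer than two cohorts, skipped")

        if "exclusivity" in config.stages:
            stage = "exclusivity"
            p = config.stage_params("exclusivity")
            rows = [
                mutual_exclusivity(events, samples, ct, n_rand=p["n_rand"],
                                   seed=stage_seed(config.seed, f"exclusivity:{ct}"))
                for ct in sorted(samples["cancer_type"].unique())
            ]
            report["outputs"]["exclusivity"] = _write(
                pd.DataFrame(rows), out_dir / "exclusivity.tsv"
            )

        if "selection" in config.stages:
            stage = "selection"
            p = config.stage_params("selection")
            bins = make_bins(genome, p["bin_size"])
            result = selection_scan(
                bundle.segments, samples, p["event_type"], p["scale"],
                genome, bins, registry, n_rand=p["n_rand"],
                seed=stage_seed(config.seed, "selection"),
            )
            report["outputs"]["selection"] = [
                _write(result.bins, out_dir / "selection_bins.tsv"),
                _write(result.genes, out_dir / "selection_genes.tsv"),
            ]
            report["warnings"] += [
                f"selection: shuffle fallback for sample {s}"
                for s in result.fallback_samples
            ]

        if "allele-bias" in config.stages:
            stage = "allele-bias"
            p = config.stage_params("allele-bias")
            seed = stage_seed(config.seed, "allele-bias")
            records = collect_records(bundle.hla, events, focality=p["focality"],
                                      seed=seed)
            if records.empty:
                report["warnings"].append("allele-bias: no LOH records, skipped")
            else:
                result = bootstrap_bias(records, n_boot=p["n_boot"],
                                        subsample=p["subsample"], seed=seed)
                outputs = [_write(result.buckets, out_dir / "allele_bias_buckets.tsv")]
                try:
                    test = ks_bias_test(result)
                    outputs.append(_write(pd.DataFrame([dataclasses.asdict(test)]),
                                          out_dir / "allele_bias_test.tsv"))
                except ValueError as exc:
                    report["warnings"].append(f"allele-bias: KS test skipped ({exc})")
                report["outputs"]["allele-bias"] = outputs

        if "simulate-gie" in config.stages or "tmb" in config.stages:
            simulated = None
            if "simulate-gie" in config.stages:
                stage = "simulate-gie"
                p = config.stage_params("simulate-gie")
                simulated = run_simulations(
                    samples, bundle.segments, bundle.mutations, registry, genome,
                    n_iter=p["n_iter"], seed=stage_seed(config.seed, "simulate-gie"),
                )
                report["outputs"]["simulate-gie"] = _write(
                    simulated, out_dir / "simulated_status.tsv"
                )
            if "tmb" in config.stages:
                stage = "tmb"
                p = config.stage_params("tmb")
                series = bucket_gie_frequency(
                    samples, events, baseline=p["baseline"],
                    exclude_nonfocal_loh=p["exclude_nonfocal_loh"],
                    n_buckets=p["n_buckets"], n_boot=p["n_boot"], frac=p["frac"],
                    seed=stage_seed(config.seed, "tmb"),
                )
                if simulated is not None and simulated["iteration"].nunique() >= 2:
                    series = overlay_simulated(series, simulated)
                report["outputs"]["tmb"] = _write(series.table, out_dir / "tmb_buckets.tsv")
    except Exception as exc:
        (out_dir / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise
    with open(out_dir / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
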