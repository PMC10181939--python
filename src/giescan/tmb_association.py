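"""GIE frequency as a function of mutation or neoepitope burden.

Samples are allocated to evenly spaced buckets on the log10 burden scale
between the 1st and 99th percentile (20 buckets pan-cancer, 10 for cancer-type
analyses); per bucket, the escape frequency and its bootstrap uncertainty
(1,000 subsamples of 50% of the bucket) are reported, optionally against a
simulated-GIE background (mean and s.d. across simulation iterations). Burdens
are displayed per megabase by dividing mutation counts by 3,000 (approximate
human genome megabases). On the neoepitope axis, putative neoantigen counts are
estimated as 1% and 5% of each bucket's summed predicted neoepitopes.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

GENOME_MEGABASES = 3000.0


def per_mb(mutation_count: float) -> float:
    """Mutations per megabase: total count / 3,000."""
    if mutation_count < 0:
        raise ValueError("mutation count must be non-negative")
    return mutation_count / GENOME_MEGABASES


def bucket_thresholds(
    values: np.ndarray,
    n_buckets: int = 20,
    lo_pct: float = 1.0,
    hi_pct: float = 99.0,
) -> np.ndarray:
    """n_buckets + 1 evenly spaced edges on the log10 scale between two percentiles."""
    values = np.asarray(values, dtype=float)
    if (values <= 0).any():
        raise ValueError("burden values must be positive (log10 scale)")
    if len(np.unique(values)) < n_buckets:
        raise ValueError(f"need at least {n_buckets} distinct burden values")
    logv = np.log10(values)
    lo, hi = np.percentile(logv, [lo_pct, hi_pct])
    if lo == hi:
        raise ValueError("degenerate burden range: percentiles coincide")
    return np.linspace(lo, hi, n_buckets + 1)


def assign_bucket(log10_burden, thresholds: np.ndarray) -> np.ndarray:
    """Left-open/right-closed bucket assignment: thr[i-1] < s <= thr[i].

    Values above the top edge go to the last bucket; values at or below the
    bottom edge go to the first.
    """
    s = np.asarray(log10_burden, dtype=float)
    idx = np.searchsorted(thresholds, s, side="left") - 1
    return np.clip(idx, 0, len(thresholds) - 2)


@dataclass
class BucketSeries:
    """Per-bucket escape frequencies with bootstrap and simulation uncertainty."""

    thresholds: np.ndarray
    table: pd.DataFrame  # bucket, lo, hi, n, n_gie, freq, boot_mean, boot_sd, ...
    sample_buckets: pd.DataFrame  # sample_id, bucket (the assignment used)
    baseline: str = "tmb"
    exclude: str = "none"


def _gie_status(
    samples: pd.DataFrame, events: pd.DataFrame, exclude_nonfocal_loh: bool
) -> pd.Series:
    ev = events
    if exclude_nonfocal_loh:
        ev = ev[~((ev["event_class"] == "LOH_HLA") & (ev["focality"] == "nonfocal"))]
    escaped = set(ev["sample_id"])
    return samples["sample_id"].isin(escaped)


def bucket_gie_frequency(
    samples: pd.DataFrame,
    events: pd.DataFrame,
    baseline: str = "tmb",
    exclude_nonfocal_loh: bool = False,
    n_buckets: int = 20,
    n_boot: int = 1000,
    frac: float = 0.5,
    seed: int = 0,
    thresholds: np.ndarray | None = None,
) -> BucketSeries:
    """Escape frequency per burden bucket with bootstrap mean and s.d.

    ``baseline`` is ``tmb`` (somatic SNV+indel count) or ``neoepitopes`` (the
    per-sample predicted-neoepitope total); the neoepitope baseline additionally
    reports 1% and 5% neoantigen estimates of each bucket's summed neoepitopes.
    Bootstraps draw floor(frac * n) samples per bucket without replacement.
    """
    if baseline == "tmb":
        burden = samples["tmb"].to_numpy(dtype=float)
    elif baseline == "neoepitopes":
        burden = samples["n_neoepitopes"].to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown baseline {baseline!r}")
    if np.isnan(burden).any():
        raise ValueError("missing burden value(s)")
    if thresholds is None:
        thresholds = bucket_thresholds(burden, n_buckets=n_buckets)
    log_burden = np.log10(burden)
    bucket = assign_bucket(log_burden, thresholds)
    gie = _gie_status(samples, events, exclude_nonfocal_loh).to_numpy()
    rng = np.random.default_rng(seed)
    rows = []
    for b in range(len(thresholds) - 1):
        in_b = bucket == b
        n = int(in_b.sum())
        n_gie = int(gie[in_b].sum())
        row = {
            "bucket": b, "lo": thresholds[b], "hi": thresholds[b + 1],
            "n": n, "n_gie": n_gie,
            "freq": n_gie / n if n else np.nan,
            "boot_mean": np.nan, "boot_sd": np.nan,
            "mutations_per_mb": per_mb(
                float(np.sum(burden[in_b]))) if baseline == "tmb" and n else np.nan,
        }
        m = int(np.floor(frac * n))
        if m >= 1:
            # subsampling without replacement == hypergeometric draw of escapees
            hits = rng.hypergeometric(n_gie, n - n_gie, m, size=n_boot)
            f = hits / m
            row.update(boot_mean=float(f.mean()), boot_sd=float(f.std(ddof=0)))
        if baseline == "neoepitopes":
            total_neo = float(np.sum(burden[in_b])) if n else 0.0
            row.update(neo_total=total_neo,
                       neoantigen_1pct=0.01 * total_neo,
                       neoantigen_5pct=0.05 * total_neo)
        rows.append(row)
    table = pd.DataFrame(rows)
    return BucketSeries(
        thresholds=thresholds, table=table,
        sample_buckets=pd.DataFrame(
            {"sample_id": samples["sample_id"].to_numpy(), "bucket": bucket}
        ),
        baseline=baseline,
        exclude="nonfocal_loh" if exclude_nonfocal_loh else "none",
    )


def overlay_simulated(series: BucketSeries, simulated: pd.DataFrame) -> BucketSeries:
    """Fill the simulated-GIE background columns of a bucket series.

    ``simulated`` holds one row per (iteration, sample) with a boolean ``gie``
    column; the per-bucket mean and s.d. across iterations use the same bucket
    assignment as the observed series.
    """
    if simulated["iteration"].nunique() < 2:
        raise ValueError("need at least two simulation iterations")
    sim_samples = set(simulated["sample_id"])
    obs_samples = set(series.sample_buckets["sample_id"])
    if sim_samples != obs_samples:
        raise ValueError(
            "simulated statuses do not cover the same samples as the observed series"
        )
    sim = simulated.merge(series.sample_buckets, on="sample_id")
    freq = (
        sim.groupby(["iteration", "bucket"])["gie"].mean().unstack(fill_value=np.nan)
    )
    table = series.table.copy()
    table["sim_mean"] = table["bucket"].map(freq.mean(axis=0))
    table["sim_sd"] = table["bucket"].map(freq.std(axis=0, ddof=0))
    return BucketSeries(
        thresholds=series.thresholds, table=table,
        sample_buckets=series.sample_buckets,
        baseline=series.baseline, exclude=series.exclude,
    )
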