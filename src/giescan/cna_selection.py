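"""Randomization-based positive-selection scan for copy-number events.

Qualifying events (LOH, homozygous deletion or amplification, at a requested
focality scale) are gathered per sample, shuffled along the autosomes in 10
independent randomizations per sample, and counted in 100-kb bins. Each bin's
observed total is tested against the global simulated mean (the expected count
under random placement, robust to chromosome-start depletion) with a two-category
G-test of goodness of fit; p-values are BH-adjusted across all bins and projected
to genes as the minimum q over the bins overlapping each gene's coding span.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import xlogy
from statsmodels.stats.multitest import multipletests

from .genome_model import (
    BinIndex, GeneDef, GenomeBuild, bins_for_gene, scale_matches, segment_scale,
)
from .gie_annotation import (
    AMP_PLOIDY_FACTOR, HD_CN_MAX, LOH_MAJOR_MIN, LOH_MINOR_MAX,
)

log = logging.getLogger(__name__)

EVENT_TYPES = ("loh", "hd", "amp")
NO_OVERLAP_MAX_EVENTS = 10_000  # above this, fall back to overlapping placement


@dataclass
class EventSet:
    """Per-sample interval lists of one event type at one focality scale."""

    event_type: str
    scale: str | None
    per_sample: dict[str, pd.DataFrame]

    @property
    def n_samples(self) -> int:
        return len(self.per_sample)

    @property
    def total_events(self) -> int:
        return sum(len(df) for df in self.per_sample.values())


def extract_events(
    segments: pd.DataFrame,
    samples: pd.DataFrame,
    event_type: str,
    scale: str | None,
    genome: GenomeBuild,
) -> EventSet:
    """Filter copy-number segments to qualifying events on the autosomes.

    Samples without any qualifying event are omitted. ``scale=None`` keeps all
    focality scales (used by the simulated-GIE control).
    """
    if event_type not in EVENT_TYPES:
        raise ValueError(f"unknown event type {event_type!r}; expected one of {EVENT_TYPES}")
    seg = segments[segments["chrom"].isin(genome.autosomes)].copy()
    total = seg["major_cn"] + seg["minor_cn"]
    if event_type == "loh":
        mask = (seg["minor_cn"] < LOH_MINOR_MAX) & (seg["major_cn"] > LOH_MAJOR_MIN)
    elif event_type == "hd":
        mask = total < HD_CN_MAX
    else:
        ploidy = samples.set_index("sample_id")["ploidy"]
        mask = total > AMP_PLOIDY_FACTOR * seg["sample_id"].map(ploidy)
    seg = seg[mask]
    if scale is not None and not seg.empty:
        classes = [
            segment_scale(r.chrom, r.start, r.end, genome) for r in seg.itertuples()
        ]
        seg = seg[[scale_matches(c, scale) for c in classes]]
    per_sample = {
        sid: grp[["chrom", "start", "end"]].reset_index(drop=True)
        for sid, grp in seg.groupby("sample_id")
    }
    return EventSet(event_type=event_type, scale=scale, per_sample=per_sample)


def shuffle_events(
    intervals: pd.DataFrame,
    genome: GenomeBuild,
    rng: np.random.Generator,
    no_overlap: bool = True,
) -> tuple[pd.DataFrame, bool]:
    """Randomly re-place one sample's intervals along the autosomes.

    Placement is uniform over all valid start positions (chromosome chosen with
    probability proportional to its number of valid starts); interval lengths
    are conserved and placements never extend beyond a chromosome end. With
    ``no_overlap``, intervals are placed sequentially into the remaining free
    gaps (longest first), which handles even exact genome tilings; when no gap
    can host an interval the whole placement falls back to overlapping mode
    (flagged in the return value and logged).
    """
    lengths = (intervals["end"] - intervals["start"]).to_numpy(dtype=np.int64)
    if (lengths <= 0).any():
        raise ValueError("zero-length interval in shuffle input")
    chroms = genome.autosomes
    chrom_len = np.array([genome.lengths[c] for c in chroms], dtype=np.int64)
    if lengths.max(initial=0) > chrom_len.max(initial=0):
        raise ValueError("interval longer than every autosome")

    out = np.empty((len(lengths), 2), dtype=np.int64)
    out_chrom = np.empty(len(lengths), dtype=object)
    if no_overlap:
        # gap-based sequential placement: uniform over the start positions that
        # keep the interval inside a free gap; exact tilings place without retries
        order = np.argsort(-lengths)  # long intervals first
        gaps: list[tuple[int, int, int]] = [  # (chrom index, gap start, gap end)
            (ci, 0, int(length)) for ci, length in enumerate(chrom_len)
        ]
        ok = True
        for idx in order:
            L = int(lengths[idx])
            weights = np.array([max(ge - gs - L + 1, 0) for _, gs, ge in gaps],
                               dtype=float)
            total = weights.sum()
            if total <= 0:
                ok = False
                break
            gi = int(rng.choice(len(gaps), p=weights / total))
            ci, gs, ge = gaps[gi]
            start = gs + int(rng.integers(0, ge - gs - L + 1))
            end = start + L
            out[idx] = (start, end)
            out_chrom[idx] = chroms[ci]
            new_gaps = [(ci, gs, start), (ci, end, ge)]
            gaps[gi: gi + 1] = [g for g in new_gaps if g[2] > g[1]]
        if ok:
            return (
                pd.DataFrame({"chrom": out_chrom, "start": out[:, 0],
                              "end": out[:, 1]}),
                False,
            )
        log.warning("shuffle: no free gap can host every interval; "
                    "fell back to overlapping placement")
    # overlapping placement: intervals independent, uniform over valid starts
    for idx, L in enumerate(lengths):
        valid = np.maximum(chrom_len - int(L) + 1, 0)
        ci = int(rng.choice(len(chroms), p=valid / valid.sum()))
        start = int(rng.integers(0, valid[ci]))
        out[idx] = (start, start + int(L))
        out_chrom[idx] = chroms[ci]
    return (
        pd.DataFrame({"chrom": out_chrom, "start": out[:, 0], "end": out[:, 1]}),
        no_overlap,
    )


def g_test(observed: float, expected: float, total: float) -> tuple[float, float]:
    """Two-category G-test of goodness of fit (in-bin vs not-in-bin, df = 1).

    G = 2 [O ln(O/E) + (N-O) ln((N-O)/(N-E))], with the 0 ln 0 convention;
    p from the chi-square survival function with one degree of freedom.
    """
    if expected <= 0:
        raise ValueError("expected count must be positive")
    if not (0 <= observed <= total) or expected >= total:
        raise ValueError("need 0 <= O <= N and 0 < E < N")
    g = 2.0 * (
        xlogy(observed, observed / expected)
        + xlogy(total - observed, (total - observed) / (total - expected))
    )
    return float(g), float(stats.chi2.sf(g, df=1))


def bin_overlap_counts(intervals: pd.DataFrame, bins: BinIndex) -> np.ndarray:
    """Number of intervals overlapping each bin (an interval counts in every bin it touches)."""
    counts = np.zeros(bins.n_bins)
    if intervals.empty:
        return counts
    off = intervals["chrom"].map(bins.offsets)
    if off.isna().any():
        bad = intervals.loc[off.isna(), "chrom"].iloc[0]
        raise KeyError(f"chromosome {bad!r} is not binned")
    lo = (off + intervals["start"] // bins.bin_size).to_numpy(dtype=np.int64)
    hi = (off + (intervals["end"] - 1) // bins.bin_size + 1).to_numpy(dtype=np.int64)
    diff = np.zeros(bins.n_bins + 1)
    np.add.at(diff, lo, 1.0)
    np.add.at(diff, hi, -1.0)
    return np.cumsum(diff)[:-1]


@dataclass
class SelectionResult:
    """Per-bin and per-gene output of one selection scan."""

    event_type: str
    scale: str | None
    n_samples: int
    total_events: int
    expected: float
    bins: pd.DataFrame
    genes: pd.DataFrame
    fallback_samples: list[str] = field(default_factory=list)
    empty: bool = False


def _empty_result(event_type: str, scale: str | None) -> SelectionResult:
    return SelectionResult(
        event_type=event_type, scale=scale, n_samples=0, total_events=0,
        expected=np.nan,
        bins=pd.DataFrame(columns=["chrom", "start", "end", "observed", "sim_mean",
                                   "expected", "G", "p", "q", "enriched", "p_smooth"]),
        genes=pd.DataFrame(columns=["gene", "chrom", "observed", "q"]),
        empty=True,
    )


def selection_scan(
    segments: pd.DataFrame,
    samples: pd.DataFrame,
    event_type: str,
    scale: str | None,
    genome: GenomeBuild,
    bins: BinIndex,
    registry: list[GeneDef],
    n_rand: int = 10,
    seed: int = 0,
    no_overlap: bool = True,
) -> SelectionResult:
    """Full positive-selection scan for one event type at one focality scale."""
    events = extract_events(segments, samples, event_type, scale, genome)
    if events.n_samples == 0:
        return _empty_result(event_type, scale)

    observed = np.zeros(bins.n_bins)
    sim = np.zeros((n_rand, bins.n_bins))
    fallback_samples: list[str] = []
    for s_idx, (sid, intervals) in enumerate(sorted(events.per_sample.items())):
        observed += bin_overlap_counts(intervals, bins)
        sample_no_overlap = no_overlap and len(intervals) <= NO_OVERLAP_MAX_EVENTS
        for r in range(n_rand):
            rng = np.random.default_rng(np.random.SeedSequence([seed, s_idx, r]))
            shuffled, fell_back = shuffle_events(
                intervals, genome, rng, no_overlap=sample_no_overlap
            )
            if fell_back and sid not in fallback_samples:
                fallback_samples.append(sid)
            sim[r] += bin_overlap_counts(shuffled, bins)

    expected = sim.sum() / (n_rand * bins.n_bins)
    total = observed.sum()
    g = 2.0 * (
        xlogy(observed, observed / expected)
        + xlogy(total - observed, (total - observed) / (total - expected))
    )
    p = stats.chi2.sf(g, df=1)
    q = multipletests(p, method="fdr_bh")[1]
    rng_diag = np.random.default_rng(np.random.SeedSequence([seed, 2**20]))
    u = rng_diag.random(bins.n_bins)
    p_smooth = stats.poisson.sf(observed, expected) + u * stats.poisson.pmf(
        observed, expected
    )
    bins_df = bins.to_frame()
    bins_df["observed"] = observed
    bins_df["sim_mean"] = sim.mean(axis=0)
    bins_df["expected"] = expected
    bins_df["G"] = g
    bins_df["p"] = p
    bins_df["q"] = q
    bins_df["enriched"] = observed > expected
    bins_df["p_smooth"] = p_smooth

    gene_rows = []
    for gene in registry:
        if gene.chrom not in bins.offsets or gene.end > genome.lengths[gene.chrom]:
            continue
        ids = bins_for_gene(bins, gene)
        gene_rows.append({
            "gene": gene.symbol, "chrom": gene.chrom,
            "observed": float(observed[ids].sum()),
            "q": float(q[ids].min()),
        })
    return SelectionResult(
        event_type=event_type, scale=scale,
        n_samples=events.n_samples, total_events=events.total_events,
        expected=float(expected), bins=bins_df,
        genes=pd.DataFrame(gene_rows, columns=["gene", "chrom", "observed", "q"]),
        fallback_samples=fallback_samples,
    )
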