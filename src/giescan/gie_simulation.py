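"""Simulated-GIE background control: escape frequency expected from burden alone.

Each iteration redistributes every sample's observed alteration burden at
random and re-annotates escape status: the sample's coding-mutation count is
re-placed over a genome-wide coding footprint with per-gene hit probability
proportional to coding length (consequence, clonality and biallelic flags
resampled from the sample's own observed mutations), and its qualifying
copy-number events (LOH / homozygous deletion / amplification) are re-placed
along the autosomes with the same interval shuffle the selection scan uses.
Comparing observed escape frequencies with the mean and s.d. across iterations
separates locus-targeted escape from what random placement of the same burden
would produce.

The exact placement policy is pluggable by construction (the mutation model is
length-proportional and signature-agnostic; see docs/methods.md for the
assumptions and their limits).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cna_selection import extract_events, shuffle_events
from .genome_model import GeneDef, GenomeBuild, registry_for_genome
from .gie_annotation import LOF_CONSEQUENCES, NONSYN_NON_LOF
from .synthetic_cohort import DEFAULT_CONSEQUENCE_MIX, coding_mutation_count

log = logging.getLogger(__name__)

STATUS_COLUMNS = ["iteration", "sample_id", "gie", "classes"]


@dataclass
class _SimInputs:
    """Precomputed per-sample inputs shared across iterations."""

    sample_ids: list[str]
    n_coding: dict[str, int]
    mutation_pool: dict[str, np.ndarray]  # (consequence, clonal, biallelic) records
    cohort_pool: np.ndarray
    cnv: dict[str, pd.DataFrame]  # qualifying intervals with a "kind" column
    p_gene: np.ndarray
    genes: list[GeneDef]


def _prepare(
    samples: pd.DataFrame,
    segments: pd.DataFrame,
    mutations: pd.DataFrame,
    registry: list[GeneDef],
    genome: GenomeBuild,
    coding_footprint_mb: float,
) -> _SimInputs:
    genes = registry_for_genome(registry, genome)
    footprint_bp = coding_footprint_mb * 1e6
    p_gene = np.array([g.coding_len for g in genes], dtype=float) / footprint_bp
    if "tmb" not in samples or samples["tmb"].isna().any():
        raise ValueError("every sample needs an observed mutation burden (tmb)")
    pool_dtype = [("consequence", "U40"), ("clonal", "?"), ("biallelic", "?")]
    mutation_pool = {}
    if not mutations.empty:
        for sid, grp in mutations.groupby("sample_id"):
            mutation_pool[sid] = np.array(
                list(zip(grp["consequence"], grp["clonal"], grp["biallelic"])),
                dtype=pool_dtype,
            )
        cohort_pool = np.concatenate(list(mutation_pool.values()))
    else:
        cohort_pool = np.array(
            [(c, True, False) for c in DEFAULT_CONSEQUENCE_MIX], dtype=pool_dtype
        )
    cnv: dict[str, pd.DataFrame] = {}
    for kind in ("loh", "hd", "amp"):
        es = extract_events(segments, samples, kind, scale=None, genome=genome)
        for sid, df in es.per_sample.items():
            df = df.copy()
            df["kind"] = kind
            cnv[sid] = pd.concat([cnv[sid], df], ignore_index=True) if sid in cnv else df
    return _SimInputs(
        sample_ids=list(samples["sample_id"]),
        n_coding={
            r.sample_id: coding_mutation_count(int(r.tmb), coding_footprint_mb)
            for r in samples.itertuples()
        },
        mutation_pool=mutation_pool,
        cohort_pool=cohort_pool,
        cnv=cnv,
        p_gene=p_gene,
        genes=genes,
    )


def _classes_from_mutations(
    hits: np.ndarray, pool: np.ndarray, genes: list[GeneDef], rng: np.random.Generator
) -> set[str]:
    classes: set[str] = set()
    for gene, n_hit in zip(genes, hits):
        for _ in range(int(n_hit)):
            mut = pool[rng.integers(0, len(pool))]
            cons, clonal, biallelic = str(mut[0]), bool(mut[1]), bool(mut[2])
            nonsyn = cons in LOF_CONSEQUENCES or cons in NONSYN_NON_LOF
            if gene.is_hla:
                if nonsyn:
                    classes.add("HLA_nonsyn_mutation")
            elif gene.mechanism == "loss":
                if clonal and (cons in LOF_CONSEQUENCES
                               or (cons in NONSYN_NON_LOF and biallelic)):
                    classes.add("inactivating_mutation")
    return classes


def _classes_from_cnv(
    intervals: pd.DataFrame, genes: list[GeneDef], genome: GenomeBuild,
    rng: np.random.Generator,
) -> set[str]:
    classes: set[str] = set()
    shuffled, _ = shuffle_events(intervals, genome, rng, no_overlap=True)
    shuffled = shuffled.assign(kind=intervals["kind"].to_numpy())
    for row in shuffled.itertuples():
        for gene in genes:
            if gene.chrom != row.chrom or row.start >= gene.end or row.end <= gene.start:
                continue
            if row.kind == "loh" and gene.is_hla:
                classes.add("LOH_HLA")
            elif row.kind == "hd" and gene.mechanism == "loss":
                classes.add("LOH_HLA" if gene.is_hla else "HD")
            elif row.kind == "amp" and gene.mechanism == "gain":
                classes.add("amplification")
    return classes


def simulate_iteration(
    samples: pd.DataFrame,
    segments: pd.DataFrame,
    mutations: pd.DataFrame,
    registry: list[GeneDef],
    genome: GenomeBuild,
    seed: int = 0,
    coding_footprint_mb: float = 30.0,
    _inputs: _SimInputs | None = None,
    _iteration: int = 0,
) -> pd.DataFrame:
    """One background iteration: per-sample simulated escape status and event classes."""
    inp = _inputs or _prepare(
        samples, segments, mutations, registry, genome, coding_footprint_mb
    )
    rng = np.random.default_rng(np.random.SeedSequence([seed, _iteration]))
    n = len(inp.sample_ids)
    n_coding = np.array([inp.n_coding[s] for s in inp.sample_ids])
    pvec = np.append(inp.p_gene, 1.0 - inp.p_gene.sum())
    hit_matrix = rng.multinomial(n_coding, pvec) if n else \
        np.zeros((0, len(pvec)), dtype=int)
    rows = []
    for i, sid in enumerate(inp.sample_ids):
        classes: set[str] = set()
        hits = hit_matrix[i, :-1]
        if hits.any():
            pool = inp.mutation_pool.get(sid, inp.cohort_pool)
            classes |= _classes_from_mutations(hits, pool, inp.genes, rng)
        if sid in inp.cnv:
            classes |= _classes_from_cnv(inp.cnv[sid], inp.genes, genome, rng)
        rows.append(
            {"iteration": _iteration, "sample_id": sid,
             "gie": bool(classes), "classes": ";".join(sorted(classes))}
        )
    return pd.DataFrame(rows, columns=STATUS_COLUMNS)


def run_simulations(
    samples: pd.DataFrame,
    segments: pd.DataFrame,
    mutations: pd.DataFrame,
    registry: list[GeneDef],
    genome: GenomeBuild,
    n_iter: int = 100,
    seed: int = 0,
    coding_footprint_mb: float = 30.0,
) -> pd.DataFrame:
    """n_iter independent background iterations; deterministic per (seed, iteration)."""
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    inputs = _prepare(samples, segments, mutations, registry, genome, coding_footprint_mb)
    frames = [
        simulate_iteration(
            samples, segments, mutations, registry, genome,
            seed=seed, coding_footprint_mb=coding_footprint_mb,
            _inputs=inputs, _iteration=it,
        )
        for it in range(n_iter)
    ]
    return pd.concat(frames, ignore_index=True)
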