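"""Per-sample genetic immune escape (GIE) calling and cohort-level statistics.

Six escape pathways are annotated over a 21-gene registry: HLA-I loss
(LOH / homozygous deletion / nonsynonymous mutation of HLA-A/B/C), antigen
presentation, IFN-gamma signalling, PD-L1 amplification, CD58 inactivation and
SETDB1 amplification. Calling thresholds follow allele-specific copy-number
conventions: LOH when minor allele ploidy < 0.3 and major > 0.7, homozygous
deletion when minimum tumor CN < 0.5, amplification when minimum tumor CN
exceeds 3x the mean sample ploidy.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genome_model import (
    GeneDef, GenomeBuild, gene_min_cn, registry_for_genome, segment_scale,
)

log = logging.getLogger(__name__)

LOH_MINOR_MAX = 0.3
LOH_MAJOR_MIN = 0.7
HD_CN_MAX = 0.5
AMP_PLOIDY_FACTOR = 3.0

LOF_CONSEQUENCES = frozenset(
    {
        "frameshift_variant",
        "stop_gained",
        "stop_lost",
        "splice_acceptor_variant",
        "splice_donor_variant",
        "splice_region_variant",
        "start_lost",
    }
)
NONSYN_NON_LOF = frozenset(
    {"missense_variant", "inframe_deletion", "inframe_insertion", "protein_altering_variant"}
)
NEUTRAL_CONSEQUENCES = frozenset(
    {"synonymous_variant", "intron_variant", "upstream_gene_variant",
     "downstream_gene_variant", "5_prime_UTR_variant", "3_prime_UTR_variant"}
)
CONSEQUENCE_VOCAB = LOF_CONSEQUENCES | NONSYN_NON_LOF | NEUTRAL_CONSEQUENCES

PATHWAY_NAMES = {
    1: "HLA-I",
    2: "antigen_presentation",
    3: "ifn_gamma",
    4: "pd_l1",
    5: "cd58",
    6: "setdb1",
}

EVENT_COLUMNS = [
    "sample_id", "pathway", "gene", "event_class", "focality", "biallelic", "subclass",
]


@dataclass(frozen=True)
class HLAGeneState:
    """One HLA-I gene in one sample, as reported by allele-level typing."""

    sample_id: str
    gene: str
    allele1: str
    allele2: str
    cn1: float
    cn2: float
    neo1: int
    neo2: int
    minor_ploidy: float
    major_ploidy: float

    @property
    def homozygous(self) -> bool:
        return self.allele1 == self.allele2


@dataclass(frozen=True)
class GIEEvent:
    """One called immune-escape alteration."""

    sample_id: str
    pathway: int
    gene: str
    event_class: str  # LOH_HLA | HD | HLA_nonsyn_mutation | inactivating_mutation | amplification
    focality: str = "not_applicable"
    biallelic: bool = False
    subclass: str = ""


def qc_filter(
    samples: pd.DataFrame, purity_min: float = 0.2, tmb_min: float = 50
) -> tuple[list[str], pd.DataFrame]:
    """Retain samples with purity >= purity_min and TMB >= tmb_min (inclusive).

    Returns the retained sample ids and an exclusion log with one reason string
    per dropped sample.
    """
    for col in ("purity", "tmb"):
        missing = samples[samples[col].isna()]
        if not missing.empty:
            raise ValueError(
                f"sample {missing['sample_id'].iloc[0]!r} is missing {col}"
            )
    kept, dropped = [], []
    for row in samples.itertuples():
        reasons = []
        if row.purity < purity_min:
            reasons.append("purity")
        if row.tmb < tmb_min:
            reasons.append("TMB")
        if reasons:
            dropped.append({"sample_id": row.sample_id, "reason": ",".join(reasons)})
        else:
            kept.append(row.sample_id)
    return kept, pd.DataFrame(dropped, columns=["sample_id", "reason"])


def call_loh_hla(
    state: HLAGeneState, hd_threshold: float = HD_CN_MAX, focality: str = "not_applicable"
) -> GIEEvent | None:
    """LOH call on one HLA-I gene; homozygous deletions are folded in with a sub-flag."""
    if min(state.cn1, state.cn2, state.minor_ploidy, state.major_ploidy) < 0:
        raise ValueError(f"negative ploidy for {state.sample_id}/{state.gene}")
    if state.cn1 < hd_threshold and state.cn2 < hd_threshold:
        return GIEEvent(state.sample_id, 1, state.gene, "LOH_HLA",
                        focality=focality, subclass="homozygous_deletion")
    if state.minor_ploidy < LOH_MINOR_MAX and state.major_ploidy > LOH_MAJOR_MIN:
        return GIEEvent(state.sample_id, 1, state.gene, "LOH_HLA", focality=focality)
    return None


def _check_vocab(consequences) -> None:
    unknown = set(consequences) - CONSEQUENCE_VOCAB
    if unknown:
        raise ValueError(
            f"unknown consequence(s) {sorted(unknown)}; accepted vocabulary: "
            f"{sorted(CONSEQUENCE_VOCAB)}"
        )


def call_inactivation(
    gene: GeneDef, mutations: pd.DataFrame, min_cn: float
) -> GIEEvent | None:
    """Inactivation of a non-HLA loss-type gene.

    An event is called for (a) any clonal loss-of-function mutation (mono- or
    biallelic), (b) a biallelic clonal nonsynonymous non-LoF mutation, or
    (c) homozygous deletion (minimum tumor CN < 0.5).
    """
    if gene.mechanism != "loss" or gene.is_hla:
        raise ValueError(f"{gene.symbol} is not a non-HLA loss-type gene")
    if not mutations.empty:
        _check_vocab(mutations["consequence"])
        clonal = mutations[mutations["clonal"]]
        lof = clonal[clonal["consequence"].isin(LOF_CONSEQUENCES)]
        if not lof.empty:
            sample_id = str(mutations["sample_id"].iloc[0])
            return GIEEvent(sample_id, gene.pathway, gene.symbol,
                            "inactivating_mutation", biallelic=bool(lof["biallelic"].any()))
        nonsyn = clonal[clonal["consequence"].isin(NONSYN_NON_LOF) & clonal["biallelic"]]
        if not nonsyn.empty:
            sample_id = str(mutations["sample_id"].iloc[0])
            return GIEEvent(sample_id, gene.pathway, gene.symbol,
                            "inactivating_mutation", biallelic=True)
    if min_cn < HD_CN_MAX:
        sample_id = str(mutations["sample_id"].iloc[0]) if not mutations.empty else ""
        return GIEEvent(sample_id, gene.pathway, gene.symbol, "HD")
    return None


def call_amplification(
    gene: GeneDef, min_cn: float, sample_ploidy: float
) -> GIEEvent | None:
    """Amplification of a gain-type gene: minimum tumor CN > 3x mean sample ploidy."""
    if gene.mechanism != "gain":
        raise ValueError(f"{gene.symbol} is not a gain-type gene")
    if sample_ploidy <= 0:
        raise ValueError(f"non-positive sample ploidy {sample_ploidy}")
    if min_cn > AMP_PLOIDY_FACTOR * sample_ploidy:
        return GIEEvent("", gene.pathway, gene.symbol, "amplification")
    return None


def _hla_states_from_frame(hla: pd.DataFrame) -> list[HLAGeneState]:
    states = []
    for r in hla.itertuples():
        cn1, cn2 = float(r.cn1), float(r.cn2)
        states.append(
            HLAGeneState(
                sample_id=str(r.sample_id), gene=str(r.gene),
                allele1=str(r.allele1), allele2=str(r.allele2),
                cn1=cn1, cn2=cn2, neo1=int(r.neo1), neo2=int(r.neo2),
                minor_ploidy=min(cn1, cn2), major_ploidy=max(cn1, cn2),
            )
        )
    return states


def _loh_segment_focality(
    segments: pd.DataFrame, gene: GeneDef, genome: GenomeBuild, hd: bool
) -> str:
    """Scale class of the copy-number segment underlying an HLA loss call."""
    seg = segments[
        (segments["chrom"] == gene.chrom)
        & (segments["start"] < gene.end)
        & (segments["end"] > gene.start)
    ]
    if hd:
        seg = seg[seg["major_cn"] + seg["minor_cn"] < HD_CN_MAX]
    else:
        seg = seg[(seg["minor_cn"] < LOH_MINOR_MAX) & (seg["major_cn"] > LOH_MAJOR_MIN)]
    if seg.empty:
        return "not_applicable"
    # if several qualify, take the most deleted segment
    idx = (seg["major_cn"] + seg["minor_cn"]).idxmin()
    row = seg.loc[idx]
    return segment_scale(row["chrom"], int(row["start"]), int(row["end"]), genome)


def annotate_sample(
    sample: pd.Series,
    segments: pd.DataFrame,
    mutations: pd.DataFrame,
    hla: pd.DataFrame,
    registry: list[GeneDef],
    genome: GenomeBuild,
) -> list[GIEEvent]:
    """All GIE events of one sample: the union of calls over the 21 registry genes."""
    sample_id = str(sample["sample_id"])
    events: list[GIEEvent] = []
    states = {s.gene: s for s in _hla_states_from_frame(hla)}
    if not mutations.empty:
        _check_vocab(mutations["consequence"])

    for gene in registry:
        gene_muts = mutations[mutations["gene"] == gene.symbol] if not mutations.empty \
            else mutations
        if gene.is_hla:
            state = states.get(gene.symbol)
            if state is not None:
                ev = call_loh_hla(state)
                if ev is not None:
                    foc = _loh_segment_focality(
                        segments, gene, genome, hd=ev.subclass == "homozygous_deletion"
                    )
                    events.append(GIEEvent(sample_id, 1, gene.symbol, "LOH_HLA",
                                           focality=foc, subclass=ev.subclass))
            nonsyn = gene_muts[
                gene_muts["consequence"].isin(LOF_CONSEQUENCES | NONSYN_NON_LOF)
            ] if not gene_muts.empty else gene_muts
            if not nonsyn.empty:
                events.append(
                    GIEEvent(sample_id, 1, gene.symbol, "HLA_nonsyn_mutation",
                             biallelic=bool(nonsyn["biallelic"].any()))
                )
        elif gene.mechanism == "loss":
            ev = call_inactivation(gene, gene_muts, gene_min_cn(segments, gene))
            if ev is not None:
                events.append(GIEEvent(sample_id, ev.pathway, ev.gene, ev.event_class,
                                       biallelic=ev.biallelic))
        else:  # gain
            ev = call_amplification(
                gene, gene_min_cn(segments, gene), float(sample["ploidy"])
            )
            if ev is not None:
                events.append(GIEEvent(sample_id, ev.pathway, ev.gene, "amplification"))
    return events


def events_to_frame(events: list[GIEEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": e.sample_id, "pathway": e.pathway, "gene": e.gene,
                "event_class": e.event_class, "focality": e.focality,
                "biallelic": e.biallelic, "subclass": e.subclass,
            }
            for e in events
        ],
        columns=EVENT_COLUMNS,
    )


def annotate_cohort(
    samples: pd.DataFrame,
    segments: pd.DataFrame,
    mutations: pd.DataFrame,
    hla: pd.DataFrame,
    registry: list[GeneDef],
    genome: GenomeBuild,
) -> pd.DataFrame:
    """annotate_sample applied to every sample; returns the cohort event table."""
    registry = registry_for_genome(registry, genome)
    events: list[GIEEvent] = []
    seg_g = dict(iter(segments.groupby("sample_id"))) if not segments.empty else {}
    mut_g = dict(iter(mutations.groupby("sample_id"))) if not mutations.empty else {}
    hla_g = dict(iter(hla.groupby("sample_id"))) if not hla.empty else {}
    empty_seg = segments.iloc[0:0]
    empty_mut = mutations.iloc[0:0]
    empty_hla = hla.iloc[0:0]
    for _, sample in samples.iterrows():
        sid = sample["sample_id"]
        events.extend(
            annotate_sample(
                sample,
                seg_g.get(sid, empty_seg),
                mut_g.get(sid, empty_mut),
                hla_g.get(sid, empty_hla),
                registry,
                genome,
            )
        )
    return events_to_frame(events)


def prevalence(
    events: pd.DataFrame,
    samples: pd.DataFrame,
    by: list[str] = ("cohort", "cancer_type"),
) -> pd.DataFrame:
    """Per-pathway escape prevalence: samples with >=1 pathway event / cohort size.

    A combined ``any`` row counts samples with at least one event in any pathway.
    """
    by = list(by)
    orphan = set(events["sample_id"]) - set(samples["sample_id"])
    if orphan:
        raise ValueError(f"events reference unknown sample(s): {sorted(orphan)[:5]}")
    ev = events.merge(samples[["sample_id", *by]], on="sample_id")
    rows = []
    for keys, group in samples.groupby(by):
        keys = keys if isinstance(keys, tuple) else (keys,)
        denom = len(group)
        sub = ev[np.logical_and.reduce([ev[c] == k for c, k in zip(by, keys)])] \
            if len(ev) else ev
        for pathway in sorted(PATHWAY_NAMES):
            num = sub.loc[sub["pathway"] == pathway, "sample_id"].nunique()
            rows.append(dict(zip(by, keys)) | {
                "pathway": str(pathway), "numerator": num, "denominator": denom,
                "proportion": num / denom if denom else np.nan,
            })
        num_any = sub["sample_id"].nunique()
        rows.append(dict(zip(by, keys)) | {
            "pathway": "any", "numerator": num_any, "denominator": denom,
            "proportion": num_any / denom if denom else np.nan,
        })
    return pd.DataFrame(rows)


def compare_cohorts(
    events: pd.DataFrame,
    samples: pd.DataFrame,
    cohort_a: str,
    cohort_b: str,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, list[str]]:
    """Cancer-type-specific Fisher comparison of escape prevalence between cohorts.

    Two-sided Fisher exact test on the 2x2 escaped/not x cohort table for every
    cancer type and pathway (plus the combined ``any`` status), BH-adjusted in
    one family across all tests of the run. log2 odds ratios use Haldane's 0.5
    continuity correction when any cell is zero.
    """
    skipped: list[str] = []
    rows = []
    cancer_types = sorted(samples["cancer_type"].unique())
    pathway_keys = [str(p) for p in sorted(PATHWAY_NAMES)] + ["any"]
    ev = events.merge(samples[["sample_id", "cohort", "cancer_type"]], on="sample_id")
    for ct in cancer_types:
        s_ct = samples[samples["cancer_type"] == ct]
        n_a = (s_ct["cohort"] == cohort_a).sum()
        n_b = (s_ct["cohort"] == cohort_b).sum()
        if n_a == 0 or n_b == 0:
            skipped.append(ct)
            log.warning("compare_cohorts: cancer type %s absent from one cohort", ct)
            continue
        e_ct = ev[ev["cancer_type"] == ct]
        for pw in pathway_keys:
            sub = e_ct if pw == "any" else e_ct[e_ct["pathway"] == int(pw)]
            esc_a = sub.loc[sub["cohort"] == cohort_a, "sample_id"].nunique()
            esc_b = sub.loc[sub["cohort"] == cohort_b, "sample_id"].nunique()
            a, b = esc_a, n_a - esc_a
            c, d = esc_b, n_b - esc_b
            odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
            if min(a, b, c, d) == 0:
                log2_or = np.log2(((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5)))
            else:
                log2_or = np.log2((a * d) / (b * c))
            rows.append({
                "cancer_type": ct, "pathway": pw,
                "escaped_a": a, "n_a": n_a, "escaped_b": c, "n_b": n_b,
                "odds_ratio": odds, "log2_or": log2_or, "p": p,
            })
    out = pd.DataFrame(rows)
    if not out.empty:
        out["q"] = multipletests(out["p"], alpha=alpha, method="fdr_bh")[1]
    return out, skipped


def mutual_exclusivity(
    events: pd.DataFrame,
    samples: pd.DataFrame,
    cancer_type: str,
    n_rand: int = 10_000,
    seed: int = 0,
) -> dict:
    """Mutual exclusivity of HLA-I LOH versus other GIE events in one cancer type.

    Left-sided Fisher exact test on the 2x2 of group memberships, plus an
    empirical p from per-sample independent Bernoulli randomizations at the
    observed group frequencies with the (1 + x) / (1 + N) pseudocount. The
    default ``empirical_p`` uses the <= direction (low co-occurrence means
    exclusivity); the >= direction is also reported.
    """
    s_ct = samples[samples["cancer_type"] == cancer_type]
    if s_ct.empty:
        raise ValueError(f"cancer type {cancer_type!r} absent from sample table")
    ids = s_ct["sample_id"]
    ev = events[events["sample_id"].isin(ids)]
    loh_set = set(ev.loc[ev["event_class"] == "LOH_HLA", "sample_id"])
    other_set = set(ev.loc[ev["event_class"] != "LOH_HLA", "sample_id"])
    n = len(ids)
    both = len(loh_set & other_set)
    a, b = both, len(loh_set - other_set)
    c, d = len(other_set - loh_set), n - len(loh_set | other_set)
    _, fisher_left_p = stats.fisher_exact([[a, b], [c, d]], alternative="less")
    f_loh, f_other = len(loh_set) / n, len(other_set) / n
    rng = np.random.default_rng(seed)
    sim_loh = rng.random((n_rand, n)) < f_loh
    sim_other = rng.random((n_rand, n)) < f_other
    co = (sim_loh & sim_other).sum(axis=1)
    p_le = (1 + int((co <= both).sum())) / (1 + n_rand)
    p_ge = (1 + int((co >= both).sum())) / (1 + n_rand)
    return {
        "cancer_type": cancer_type,
        "n_samples": n,
        "observed_cooccurrence": both,
        "freq_loh_hla": f_loh,
        "freq_other_gie": f_other,
        "fisher_left_p": float(fisher_left_p),
        "empirical_p": p_le,
        "empirical_p_ge": p_ge,
        "n_rand": n_rand,
    }
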