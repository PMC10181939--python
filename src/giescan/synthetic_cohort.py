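"""Seeded generator of synthetic tumor cohorts with the structure the GIE analyses assume.

The generator stands in for controlled-access WGS cohorts. Per sample it draws
purity, mean ploidy and mutation burden; builds an allele-specific copy-number
profile that tiles every autosome (arm-level and focal events over a diploid
baseline, with optional per-locus enrichment); materializes somatic mutations in
the 21 registry genes from a genome-wide coding background; and emits HLA-I
allele states with per-allele neoepitope counts. Immune-escape events can be
injected with a logistic link to log10 burden, and HLA allele loss can be biased
toward the allele with the larger neoepitope repertoire:
P(lose allele 1) = logistic(beta * (nr - 0.5)).

Every injected event is recorded in a truth table so downstream analyses can be
checked against known ground truth.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit, logit

from .genome_model import (
    GenomeBuild, GeneDef, hg19_genome, load_gene_registry, registry_for_genome,
)

DEFAULT_CONSEQUENCE_MIX = {
    "missense_variant": 0.55,
    "frameshift_variant": 0.12,
    "stop_gained": 0.10,
    "splice_region_variant": 0.07,
    "splice_acceptor_variant": 0.02,
    "splice_donor_variant": 0.02,
    "inframe_deletion": 0.02,
    "synonymous_variant": 0.10,
}

SAMPLE_COLUMNS = [
    "sample_id", "cohort", "cancer_type", "purity", "ploidy",
    "tmb", "tmb_clonal", "tmb_subclonal", "n_neoepitopes",
]
SEGMENT_COLUMNS = ["sample_id", "chrom", "start", "end", "major_cn", "minor_cn"]
MUTATION_COLUMNS = ["sample_id", "gene", "consequence", "clonal", "biallelic"]
HLA_COLUMNS = [
    "sample_id", "gene", "allele1", "allele2", "cn1", "cn2", "neo1", "neo2",
]
TRUTH_COLUMNS = ["sample_id", "pathway", "gene", "kind", "lost_allele", "nr"]


@dataclass
class CohortConfig:
    """All tunable parameters of the cohort generator (defaults: metastatic-like)."""

    n_samples: int = 200
    cohort_label: str = "metastatic"
    cancer_types: dict = field(default_factory=lambda: {"PANCANCER": 1.0})
    seed: int = 0
    # sample-level distributions
    purity_alpha: float = 6.0
    purity_beta: float = 2.0
    allow_qc_failures: bool = False
    ploidy_mean: float = 2.0
    ploidy_sd: float = 0.35
    tmb_log10_mean: dict = field(default_factory=lambda: {"PANCANCER": 3.9})
    tmb_log10_sd: dict = field(default_factory=lambda: {"PANCANCER": 0.45})
    clonal_fraction: float = 0.8
    biallelic_fraction: float = 0.1
    # copy-number segment process
    arm_event_rate: float = 0.05
    arm_loh_fraction: float = 0.6
    focal_loh_rate: float = 3.5
    focal_hd_rate: float = 0.3
    focal_amp_rate: float = 0.5
    focal_length_mean: float = 500_000.0
    focal_length_min: float = 100_000.0
    focal_length_max: float = 2_900_000.0
    locus_enrichment: dict = field(default_factory=dict)  # gene symbol -> multiplier
    # mutation model
    coding_footprint_mb: float = 30.0
    consequence_mix: dict = field(default_factory=lambda: dict(DEFAULT_CONSEQUENCE_MIX))
    # GIE injection (per-pathway base rate; logistic link to log10 TMB)
    gie_base_rate: dict = field(default_factory=dict)  # pathway id -> probability
    gie_tmb_slope: float = 0.0
    gie_tmb_center: float = 4.0
    # HLA model
    allele_pool: int = 30
    homozygosity_rate: float = 0.1
    neo_mean: float = 150.0
    neo_dispersion: float = 4.0
    allele_loss_beta: float = 0.0

    def validate(self) -> None:
        bad = []
        probs = {
            "arm_event_rate": self.arm_event_rate,
            "arm_loh_fraction": self.arm_loh_fraction,
            "clonal_fraction": self.clonal_fraction,
            "biallelic_fraction": self.biallelic_fraction,
            "homozygosity_rate": self.homozygosity_rate,
            **{f"gie_base_rate[{k}]": v for k, v in self.gie_base_rate.items()},
        }
        for name, v in probs.items():
            if not 0 <= v <= 1:
                bad.append(name)
        for name in ("focal_loh_rate", "focal_hd_rate", "focal_amp_rate",
                     "focal_length_mean", "neo_mean", "neo_dispersion"):
            if getattr(self, name) < 0:
                bad.append(name)
        if self.n_samples < 0:
            bad.append("n_samples")
        if abs(sum(self.cancer_types.values()) - 1) > 1e-9:
            bad.append("cancer_types")
        for ct in self.cancer_types:
            if ct not in self.tmb_log10_mean or ct not in self.tmb_log10_sd:
                bad.append(f"tmb_log10_mean/sd[{ct}]")
        if any(m <= 0 for m in self.locus_enrichment.values()):
            bad.append("locus_enrichment")
        if bad:
            raise ValueError(f"invalid CohortConfig field(s): {', '.join(sorted(set(bad)))}")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown CohortConfig field(s): {sorted(unknown)}")
        cfg = cls(**raw)
        # YAML round-trips dict keys as written; pathway ids must be ints
        cfg.gie_base_rate = {int(k): float(v) for k, v in cfg.gie_base_rate.items()}
        return cfg


@dataclass
class CohortBundle:
    """All generated tables of one cohort."""

    samples: pd.DataFrame
    segments: pd.DataFrame
    mutations: pd.DataFrame
    hla: pd.DataFrame
    truth: pd.DataFrame
    config: CohortConfig | None = None

    def equals(self, other: "CohortBundle") -> bool:
        return all(
            getattr(self, t).reset_index(drop=True).equals(
                getattr(other, t).reset_index(drop=True)
            )
            for t in ("samples", "segments", "mutations", "hla", "truth")
        )


def coding_mutation_count(tmb: int, coding_footprint_mb: float) -> int:
    """Coding mutations implied by a genome-wide burden (genome approx. 3,000 Mb)."""
    return int(round(tmb * coding_footprint_mb / 3000.0))


def _draw_lengths(cfg: CohortConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    raw = rng.exponential(cfg.focal_length_mean, n)
    return np.clip(raw, cfg.focal_length_min, cfg.focal_length_max).astype(np.int64)


def _place_uniform(
    lengths: np.ndarray, genome: GenomeBuild, rng: np.random.Generator
) -> list[tuple[str, int, int]]:
    """Place intervals uniformly over valid start positions across the autosomes."""
    chroms = genome.autosomes
    chrom_len = np.array([genome.lengths[c] for c in chroms], dtype=np.int64)
    out = []
    for L in lengths:
        valid = np.maximum(chrom_len - L + 1, 0)
        total = valid.sum()
        if total <= 0:
            raise ValueError(f"interval of length {L} exceeds every autosome")
        ci = rng.choice(len(chroms), p=valid / total)
        start = int(rng.integers(0, valid[ci]))
        out.append((chroms[ci], start, start + int(L)))
    return out


def _place_overlapping_gene(
    gene: GeneDef, length: int, genome: GenomeBuild, rng: np.random.Generator
) -> tuple[str, int, int]:
    chrom_len = genome.lengths[gene.chrom]
    lo = max(0, gene.start - length + 1)
    hi = min(chrom_len - length, gene.end - 1)
    start = int(rng.integers(lo, max(lo, hi) + 1))
    return (gene.chrom, start, start + length)


def _place_containing_gene(
    gene: GeneDef, length: int, genome: GenomeBuild, rng: np.random.Generator
) -> tuple[str, int, int]:
    length = max(length, gene.end - gene.start + 2)
    chrom_len = genome.lengths[gene.chrom]
    lo = max(0, gene.end - length)
    hi = max(lo, min(gene.start, chrom_len - length))
    start = int(rng.integers(lo, hi + 1))
    return (gene.chrom, start, start + length)


def _build_profile(
    events: list[tuple[str, int, int, str]],
    genome: GenomeBuild,
    ploidy: float,
) -> list[tuple[str, int, int, float, float]]:
    """Tile every autosome with (major, minor) states: baseline (1, 1), events applied in order."""
    amp_major = float(np.ceil(3.0 * ploidy) + 2.0)
    rows = []
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for chrom, start, end, kind in events:
        by_chrom.setdefault(chrom, []).append((start, end, kind))
    for chrom in genome.autosomes:
        length = genome.lengths[chrom]
        evs = by_chrom.get(chrom, [])
        points = sorted({0, length, *(s for s, _, _ in evs), *(e for _, e, _ in evs)})
        points = [p for p in points if 0 <= p <= length]
        prev_state = None
        seg_start = 0
        for lo, hi in zip(points[:-1], points[1:]):
            major, minor = 1.0, 1.0
            for s, e, kind in evs:
                if s <= lo and hi <= e:
                    if kind in ("arm_loh", "loh"):
                        minor = 0.0
                    elif kind == "arm_gain":
                        major += 1.0
                    elif kind == "hd":
                        major, minor = 0.0, 0.0
                    elif kind == "amp":
                        major = amp_major
            state = (major, minor)
            if state != prev_state:
                if prev_state is not None:
                    rows.append((chrom, seg_start, lo, *prev_state))
                seg_start = lo
                prev_state = state
        rows.append((chrom, seg_start, length, *prev_state))
    return rows


def _profile_at_gene(
    profile_rows: list[tuple[str, int, int, float, float]], gene: GeneDef
) -> tuple[float, float]:
    """(major, minor) of the most deleted profile segment overlapping the gene."""
    best = None
    for chrom, start, end, major, minor in profile_rows:
        if chrom == gene.chrom and start < gene.end and end > gene.start:
            if best is None or major + minor < best[0] + best[1]:
                best = (major, minor)
    if best is None:
        raise ValueError(f"profile does not cover gene {gene.symbol}")
    return best


def generate_cohort(
    config: CohortConfig,
    genome: GenomeBuild | None = None,
    registry: list[GeneDef] | None = None,
) -> CohortBundle:
    """Generate a cohort; deterministic for a fixed config (including its seed)."""
    config.validate()
    genome = genome or hg19_genome()
    registry = registry or load_gene_registry()
    registry = registry_for_genome(registry, genome)
    hla_genes = [g for g in registry if g.is_hla]
    by_pathway: dict[int, list[GeneDef]] = {}
    for g in registry:
        by_pathway.setdefault(g.pathway, []).append(g)

    rng = np.random.default_rng(config.seed)
    ct_names = list(config.cancer_types)
    ct_probs = np.array([config.cancer_types[c] for c in ct_names])
    cons_names = list(config.consequence_mix)
    cons_probs = np.array(list(config.consequence_mix.values()), dtype=float)
    cons_probs = cons_probs / cons_probs.sum()
    autosome_len = genome.autosome_length()

    sample_rows, seg_rows, mut_rows, hla_rows, truth_rows = [], [], [], [], []
    prefix = config.cohort_label[:3].upper() or "SAM"
    for i in range(config.n_samples):
        sid = f"{prefix}{i:04d}"
        cancer_type = ct_names[rng.choice(len(ct_names), p=ct_probs)]
        purity = float(rng.beta(config.purity_alpha, config.purity_beta))
        if not config.allow_qc_failures:
            for _ in range(1000):
                if purity >= 0.2:
                    break
                purity = float(rng.beta(config.purity_alpha, config.purity_beta))
        ploidy = float(max(1.0, rng.normal(config.ploidy_mean, config.ploidy_sd)))
        mu = config.tmb_log10_mean[cancer_type]
        sd = config.tmb_log10_sd[cancer_type]
        tmb = int(max(1, round(10 ** rng.normal(mu, sd))))
        tmb_clonal = int(rng.binomial(tmb, config.clonal_fraction))
        log10_tmb = float(np.log10(tmb))

        events: list[tuple[str, int, int, str]] = []
        # arm-level events
        for chrom in genome.autosomes:
            for arm_start, arm_end in genome.arms(chrom):
                if rng.random() < config.arm_event_rate:
                    kind = "arm_loh" if rng.random() < config.arm_loh_fraction else "arm_gain"
                    events.append((chrom, arm_start, arm_end, kind))
        # focal background events
        for kind, rate in (("loh", config.focal_loh_rate),
                           ("hd", config.focal_hd_rate),
                           ("amp", config.focal_amp_rate)):
            n = int(rng.poisson(rate))
            if n:
                for chrom, start, end in _place_uniform(_draw_lengths(config, rng, n),
                                                        genome, rng):
                    events.append((chrom, start, end, kind))
        # per-locus enrichment of focal LOH
        for symbol, mult in sorted(config.locus_enrichment.items()):
            gene = next((g for g in registry if g.symbol == symbol), None)
            if gene is None or mult <= 1:
                continue
            p_gene = (config.focal_length_mean + (gene.end - gene.start)) / autosome_len
            n_extra = int(rng.poisson((mult - 1) * config.focal_loh_rate * p_gene))
            for L in _draw_lengths(config, rng, n_extra):
                events.append((*_place_overlapping_gene(gene, int(L), genome, rng), "loh"))

        # burden-linked GIE injection
        injected_mutations: list[dict] = []
        for pathway in sorted(config.gie_base_rate):
            base = config.gie_base_rate[pathway]
            genes = by_pathway.get(pathway, [])
            if not genes or base <= 0:
                continue
            if 0 < base < 1:
                p = float(expit(logit(base) + config.gie_tmb_slope
                                * (log10_tmb - config.gie_tmb_center)))
            else:
                p = base
            if rng.random() >= p:
                continue
            gene = genes[rng.integers(0, len(genes))]
            if gene.mechanism == "gain":
                L = int(_draw_lengths(config, rng, 1)[0])
                events.append((*_place_containing_gene(gene, L, genome, rng), "amp"))
                truth_rows.append((sid, pathway, gene.symbol, "injected_amp", 0, np.nan))
            elif gene.is_hla:
                L = int(_draw_lengths(config, rng, 1)[0])
                events.append((*_place_containing_gene(gene, L, genome, rng), "loh"))
                truth_rows.append((sid, pathway, gene.symbol, "injected_loh", 0, np.nan))
            else:
                if rng.random() < 0.25:
                    L = int(min(_draw_lengths(config, rng, 1)[0], 1_000_000))
                    events.append((*_place_containing_gene(gene, L, genome, rng), "hd"))
                    truth_rows.append((sid, pathway, gene.symbol, "injected_hd", 0, np.nan))
                else:
                    if rng.random() < 0.7:
                        cons, biallelic = "stop_gained", bool(rng.random()
                                                             < config.biallelic_fraction)
                    else:
                        cons, biallelic = "missense_variant", True
                    injected_mutations.append(
                        {"sample_id": sid, "gene": gene.symbol, "consequence": cons,
                         "clonal": True, "biallelic": biallelic}
                    )
                    truth_rows.append((sid, pathway, gene.symbol, "injected_mutation",
                                       0, np.nan))

        profile = _build_profile(events, genome, ploidy)
        seg_rows.extend((sid, *row) for row in profile)

        # background coding mutations: multinomial over registry genes + the rest
        # of the coding footprint, so the coding burden is conserved exactly
        n_coding = coding_mutation_count(tmb, config.coding_footprint_mb)
        footprint_bp = config.coding_footprint_mb * 1e6
        pvec = np.array([g.coding_len for g in registry], dtype=float) / footprint_bp
        gene_hits = (
            rng.multinomial(n_coding, np.append(pvec, 1.0 - pvec.sum()))[:-1]
            if n_coding > 0 else np.zeros(len(registry), dtype=int)
        )
        for gene, hits in zip(registry, gene_hits):
            for _ in range(int(hits)):
                cons = cons_names[rng.choice(len(cons_names), p=cons_probs)]
                mut_rows.append(
                    {"sample_id": sid, "gene": gene.symbol, "consequence": cons,
                     "clonal": bool(rng.random() < config.clonal_fraction),
                     "biallelic": bool(rng.random() < config.biallelic_fraction)}
                )
        mut_rows.extend(injected_mutations)

        # HLA-I allele states, with optional allele-loss bias
        neo_total = 0
        p_nb = config.neo_dispersion / (config.neo_dispersion + config.neo_mean)
        for gene in hla_genes:
            major, minor = _profile_at_gene(profile, gene)
            locus = gene.symbol.split("-")[-1]
            a1 = f"{locus}*{int(rng.integers(1, config.allele_pool + 1)):02d}:01"
            if rng.random() < config.homozygosity_rate:
                a2 = a1
            else:
                a2 = f"{locus}*{int(rng.integers(1, config.allele_pool + 1)):02d}:01"
            neo1 = int(rng.negative_binomial(config.neo_dispersion, p_nb)) + 1
            neo2 = int(rng.negative_binomial(config.neo_dispersion, p_nb)) + 1
            neo_total += neo1 + neo2
            total = major + minor
            if minor < 0.3 and major > 0.7:  # LOH state at this gene
                nr = neo1 / (neo1 + neo2)
                p_lose_1 = float(expit(config.allele_loss_beta * (nr - 0.5)))
                lost = 1 if rng.random() < p_lose_1 else 2
                cn1, cn2 = (minor, major) if lost == 1 else (major, minor)
                truth_rows.append((sid, 1, gene.symbol, "hla_allele_loss", lost, nr))
            else:
                cn1 = cn2 = total / 2.0
            hla_rows.append((sid, gene.symbol, a1, a2, cn1, cn2, neo1, neo2))

        sample_rows.append(
            (sid, config.cohort_label, cancer_type, purity, ploidy,
             tmb, tmb_clonal, tmb - tmb_clonal, neo_total)
        )

    bundle = CohortBundle(
        samples=pd.DataFrame(sample_rows, columns=SAMPLE_COLUMNS),
        segments=pd.DataFrame(seg_rows, columns=SEGMENT_COLUMNS),
        mutations=pd.DataFrame(mut_rows, columns=MUTATION_COLUMNS),
        hla=pd.DataFrame(hla_rows, columns=HLA_COLUMNS),
        truth=pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS),
        config=config,
    )
    _enforce_schemas(bundle)
    return bundle


def _enforce_schemas(bundle: CohortBundle) -> None:
    b = bundle
    b.samples = b.samples.astype(
        {"sample_id": str, "cohort": str, "cancer_type": str, "purity": float,
         "ploidy": float, "tmb": np.int64, "tmb_clonal": np.int64,
         "tmb_subclonal": np.int64, "n_neoepitopes": np.int64}
    )
    b.segments = b.segments.astype(
        {"sample_id": str, "chrom": str, "start": np.int64, "end": np.int64,
         "major_cn": float, "minor_cn": float}
    )
    b.mutations = b.mutations.astype(
        {"sample_id": str, "gene": str, "consequence": str,
         "clonal": bool, "biallelic": bool}
    )
    b.hla = b.hla.astype(
        {"sample_id": str, "gene": str, "allele1": str, "allele2": str,
         "cn1": float, "cn2": float, "neo1": np.int64, "neo2": np.int64}
    )
    b.truth = b.truth.astype(
        {"sample_id": str, "pathway": np.int64, "gene": str, "kind": str,
         "lost_allele": np.int64, "nr": float}
    )


_TABLES = ("samples", "segments", "mutations", "hla", "truth")


def write_cohort(bundle: CohortBundle, out_dir: str | Path) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name in _TABLES:
        getattr(bundle, name).to_csv(out_dir / f"{name}.tsv", sep="\t", index=False)
    if bundle.config is not None:
        bundle.config.to_yaml(out_dir / "config.yaml")
    return out_dir


def read_cohort(in_dir: str | Path) -> CohortBundle:
    in_dir = Path(in_dir)
    frames = {}
    expected = {
        "samples": SAMPLE_COLUMNS, "segments": SEGMENT_COLUMNS,
        "mutations": MUTATION_COLUMNS, "hla": HLA_COLUMNS, "truth": TRUTH_COLUMNS,
    }
    for name in _TABLES:
        path = in_dir / f"{name}.tsv"
        try:
            df = pd.read_csv(path, sep="\t", dtype={"sample_id": str},
                             float_precision="round_trip")
        except pd.errors.ParserError as exc:
            raise ValueError(f"malformed table {path}: {exc}") from exc
        missing = set(expected[name]) - set(df.columns)
        if missing:
            raise ValueError(f"table {path} is missing column(s) {sorted(missing)}")
        frames[name] = df
    config = None
    cfg_path = in_dir / "config.yaml"
    if cfg_path.exists():
        config = CohortConfig.from_yaml(cfg_path)
    bundle = CohortBundle(config=config, **frames)
    _enforce_schemas(bundle)
    return bundle
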