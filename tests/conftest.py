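"""Shared fixtures: genomes, the gene registry, and a hand-constructed 12-sample cohort.

The fixture cohort exercises all six escape pathways; its expected event table
was enumerated by hand from the calling rules (thresholds 0.3/0.7 for LOH,
0.5 for homozygous deletion, 3x ploidy for amplification, clonal LoF /
biallelic clonal nonsynonymous mutations for inactivation) before being frozen
here.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from giescan import hg19_genome, load_gene_registry, make_bins, toy_genome

HLA_DEFAULT = {"cn1": 1.0, "cn2": 1.0, "neo1": 100, "neo2": 120}


@pytest.fixture(scope="session")
def hg19():
    return hg19_genome()


@pytest.fixture(scope="session")
def registry():
    return load_gene_registry()


@pytest.fixture(scope="session")
def hg19_bins(hg19):
    return make_bins(hg19)


@pytest.fixture(scope="session")
def toy():
    return toy_genome()


@pytest.fixture(scope="session")
def toy_bins(toy):
    return make_bins(toy)


# chromosomes hosting registry genes: baseline diploid coverage is needed on all
_FIXTURE_CHROMS = ("chr1", "chr2", "chr4", "chr6", "chr9", "chr11",
                   "chr15", "chr16", "chr19", "chr21")


def _tiled_segments(sample_id, genome, overrides):
    """Tile the fixture chromosomes with (1, 1) baseline, carving in overrides."""
    by_chrom = {}
    for chrom, start, end, major, minor in overrides:
        by_chrom.setdefault(chrom, []).append((start, end, major, minor))
    rows = []
    for chrom in _FIXTURE_CHROMS:
        length = genome.lengths[chrom]
        cursor = 0
        for start, end, major, minor in sorted(by_chrom.get(chrom, [])):
            if start > cursor:
                rows.append((sample_id, chrom, cursor, start, 1.0, 1.0))
            rows.append((sample_id, chrom, start, end, major, minor))
            cursor = end
        if cursor < length:
            rows.append((sample_id, chrom, cursor, length, 1.0, 1.0))
    return rows


@pytest.fixture(scope="session")
def fixture_cohort(hg19):
    """12 hand-built samples (tables) plus the hand-enumerated expected event table."""
    ids = [f"S{i:02d}" for i in range(1, 13)]
    samples = pd.DataFrame(
        {"sample_id": ids, "cohort": "metastatic", "cancer_type": "PANCANCER",
         "purity": 0.8, "ploidy": 2.0, "tmb": 5000, "tmb_clonal": 4000,
         "tmb_subclonal": 1000, "n_neoepitopes": 660}
    )

    seg_overrides = {
        "S01": [("chr6", 29_000_000, 31_000_000, 1.2, 0.0)],   # 2 Mb HLA-A LOH
        "S02": [("chr15", 44_950_000, 45_050_000, 0.0, 0.0)],  # B2M homozygous deletion
        "S04": [("chr9", 5_450_503, 5_470_567, 6.5, 0.8)],     # CD274 amplification
        "S06": [("chr1", 150_898_814, 150_937_220, 7.0, 1.0)], # SETDB1 amplification
        "S09": [("chr1", 150_898_814, 150_937_220, 5.0, 1.0)], # SETDB1 at exactly 3x ploidy
        "S10": [("chr6", 9_000_000, 55_000_000, 1.0, 0.0)],    # 46 Mb LOH (>75% of 61 Mb p-arm)
        "S11": [("chr6", 29_800_000, 30_000_000, 0.1, 0.1)],   # HLA-A homozygous deletion
        "S12": [("chr19", 13_000_000, 13_100_000, 0.25, 0.15)],  # CALR min CN 0.4
    }
    seg_rows = []
    for sid in ids:
        seg_rows.extend(_tiled_segments(sid, hg19, seg_overrides.get(sid, [])))
    segments = pd.DataFrame(
        seg_rows, columns=["sample_id", "chrom", "start", "end", "major_cn", "minor_cn"]
    )

    mutations = pd.DataFrame(
        [
            ("S03", "JAK1", "stop_gained", True, False),
            ("S05", "CD58", "frameshift_variant", True, False),
            ("S07", "HLA-B", "missense_variant", False, False),
            ("S08", "JAK2", "missense_variant", True, True),
            ("S09", "TAP1", "missense_variant", True, False),   # monoallelic: no event
            ("S10", "B2M", "stop_gained", True, False),
            ("S12", "TAP2", "stop_gained", False, False),       # subclonal: no event
        ],
        columns=["sample_id", "gene", "consequence", "clonal", "biallelic"],
    )

    hla_overrides = {
        ("S01", "HLA-A"): {"cn1": 0.1, "cn2": 1.2},
        ("S09", "HLA-C"): {"cn1": 0.3, "cn2": 0.8},   # minor exactly 0.3: no event
        ("S10", "HLA-A"): {"cn1": 0.15, "cn2": 1.05},
        ("S10", "HLA-B"): {"cn1": 1.0, "cn2": 0.1},
        ("S10", "HLA-C"): {"cn1": 0.95, "cn2": 0.05},
        ("S11", "HLA-A"): {"cn1": 0.2, "cn2": 0.3},   # both < 0.5: HD sub-flag
    }
    hla_rows = []
    for sid in ids:
        for gene in ("HLA-A", "HLA-B", "HLA-C"):
            locus = gene[-1]
            row = {"sample_id": sid, "gene": gene,
                   "allele1": f"{locus}*01:01", "allele2": f"{locus}*02:01",
                   **HLA_DEFAULT}
            row.update(hla_overrides.get((sid, gene), {}))
            hla_rows.append(row)
    hla = pd.DataFrame(hla_rows)

    expected_events = pd.DataFrame(
        [
            ("S01", 1, "HLA-A", "LOH_HLA", "highly_focal", False, ""),
            ("S02", 2, "B2M", "HD", "not_applicable", False, ""),
            ("S03", 3, "JAK1", "inactivating_mutation", "not_applicable", False, ""),
            ("S04", 4, "CD274", "amplification", "not_applicable", False, ""),
            ("S05", 5, "CD58", "inactivating_mutation", "not_applicable", False, ""),
            ("S06", 6, "SETDB1", "amplification", "not_applicable", False, ""),
            ("S07", 1, "HLA-B", "HLA_nonsyn_mutation", "not_applicable", False, ""),
            ("S08", 3, "JAK2", "inactivating_mutation", "not_applicable", True, ""),
            ("S10", 1, "HLA-A", "LOH_HLA", "nonfocal", False, ""),
            ("S10", 1, "HLA-B", "LOH_HLA", "nonfocal", False, ""),
            ("S10", 1, "HLA-C", "LOH_HLA", "nonfocal", False, ""),
            ("S10", 2, "B2M", "inactivating_mutation", "not_applicable", False, ""),
            ("S11", 1, "HLA-A", "LOH_HLA", "highly_focal", False, "homozygous_deletion"),
            ("S12", 2, "CALR", "HD", "not_applicable", False, ""),
        ],
        columns=["sample_id", "pathway", "gene", "event_class", "focality",
                 "biallelic", "subclass"],
    )
    return {"samples": samples, "segments": segments, "mutations": mutations,
            "hla": hla, "expected_events": expected_events}
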