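"""Site hard-filter cascade, SNP-cluster flagging and region masking.

Candidate SNPs pass through three layers of composable per-site predicates:

1. hard filters on site QC annotations (QUAL, QD, FS, MQ, MQRankSum,
   ReadPosRankSum, HaplotypeScore), each a strict threshold comparison;
2. the SNP-cluster filter (>= 3 SNPs within a 10 bp window);
3. region filters: repeat/low-complexity masks, CNV masks (heterozygous
   deletions masquerade as homozygous genotypes and inflate Mendelian
   errors), proximity to indels (false-positive hotspots), proximity to
   assembly gaps, and the read-depth window 4..50.

Each site gets a :class:`FilterVerdict` naming exactly the filters it trips;
a site passes iff the set is empty.  Filters are pure predicates and
order-independent.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import yaml

from .trio_io import GenomeMaskSet, TrioSiteRecord

logger = logging.getLogger(__name__)

FILTER_NAMES = (
    "LowQual",
    "FilterQD",
    "FilterFS",
    "FilterMQ",
    "FilterMQRankSum",
    "FilterReadPosRankSum",
    "HaplotypeScore",
    "SnpCluster",
    "RepeatMask",
    "CNVMask",
    "DepthWindow",
    "NearIndel",
    "NearGap",
)


@dataclass(frozen=True)
class FilterVerdict:
    chrom: str
    pos: int
    tripped: frozenset[str]

    @property
    def passed(self) -> bool:
        return not self.tripped


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the filter cascade.

    Hard-filter comparisons are strict, exactly as written in the GATK
    filter expressions they mirror (e.g. a site with QD == 2.0 passes).
    ``depth_mode`` selects whose depth the 4..50 window inspects:
    "all" requires every trio member in-window (the default for trio
    classification), "offspring" only the offspring (per-genome summaries
    use per-sample depth directly).
    """

    qual_min: float = 30.0
    qd_min: float = 2.0
    fs_max: float = 20.0
    mq_min: float = 20.0
    mqranksum_min: float = -3.0
    readposranksum_min: float = -3.0
    haplotypescore_max: float = 13.0
    cluster_size: int = 3
    cluster_window: int = 10
    depth_min: int = 4
    depth_max: int = 50
    depth_mode: str = "all"
    indel_flank: int = 50
    gap_core: int = 3
    gap_flank: int = 10

    def __post_init__(self) -> None:
        if self.cluster_size < 2:
            raise ValueError("cluster_size must be >= 2")
        if self.depth_min > self.depth_max:
            raise ValueError("depth_min must be <= depth_max")
        if self.depth_mode not in ("all", "offspring"):
            raise ValueError("depth_mode must be 'all' or 'offspring'")

    @property
    def gap_margin(self) -> int:
        """Conservative exclusion margin around gap edges."""
        return self.gap_core + self.gap_flank

    @classmethod
    def from_yaml(cls, path: str) -> "FilterConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def apply_hard_filters(record: TrioSiteRecord, cfg: FilterConfig) -> set[str]:
    """Evaluate the QC-annotation hard filters for one site.

    An absent annotation never trips its filter: rank-sum statistics are
    undefined at sites without reference-supporting reads, and dropping such
    sites for missing metadata would be over-aggressive.
    """
    tripped: set[str] = set()
    info = record.info
    if record.qual is not None and record.qual < cfg.qual_min:
        tripped.add("LowQual")
    checks = (
        ("FilterQD", "QD", lambda v: v < cfg.qd_min),
        ("FilterFS", "FS", lambda v: v > cfg.fs_max),
        ("FilterMQ", "MQ", lambda v: v < cfg.mq_min),
        ("FilterMQRankSum", "MQRankSum", lambda v: v < cfg.mqranksum_min),
        ("FilterReadPosRankSum", "ReadPosRankSum", lambda v: v < cfg.readposranksum_min),
        ("HaplotypeScore", "HaplotypeScore", lambda v: v > cfg.haplotypescore_max),
    )
    for name, key, fails in checks:
        val = info.get(key)
        if val is not None and fails(val):
            tripped.add(name)
    return tripped


def flag_snp_clusters(
    positions: Sequence[int], cfg: FilterConfig
) -> set[int]:
    """Positions belonging to any window of ``cluster_size`` consecutive
    SNPs spanning at most ``cluster_window`` bp.

    Any ``cluster_size`` consecutive SNPs whose span (last - first) is
    <= ``cluster_window - 1`` flag *all* of their members, mirroring the
    GATK SnpCluster behaviour the parameters come from.  Positions must be
    sorted ascending.
    """
    if any(b < a for a, b in zip(positions, positions[1:])):
        raise ValueError("positions must be sorted ascending")
    k, w = cfg.cluster_size, cfg.cluster_window
    flagged: set[int] = set()
    for i in range(len(positions) - k + 1):
        if positions[i + k - 1] - positions[i] <= w - 1:
            flagged.update(positions[i : i + k])
    return flagged


def apply_region_filters(
    record: TrioSiteRecord, masks: GenomeMaskSet, cfg: FilterConfig
) -> set[str]:
    """Mask-track and depth-window predicates for one site."""
    tripped: set[str] = set()
    chrom, p0 = record.chrom, record.pos0
    if masks.in_repeat(chrom, p0):
        tripped.add("RepeatMask")
    if masks.in_cnv(chrom, p0):
        tripped.add("CNVMask")
    if masks.near_indel(chrom, p0, cfg.indel_flank):
        tripped.add("NearIndel")
    if masks.near_gap(chrom, p0, cfg.gap_margin):
        tripped.add("NearGap")
    if _depth_out_of_window(record, cfg):
        tripped.add("DepthWindow")
    return tripped


def _depth_out_of_window(record: TrioSiteRecord, cfg: FilterConfig) -> bool:
    samples = record.samples if cfg.depth_mode == "all" else (record.offspring,)
    for s in samples:
        if s.total_depth is None:
            continue  # unknown depth cannot trip the window
        if s.total_depth < cfg.depth_min or s.total_depth > cfg.depth_max:
            return True
    return False


def filter_pipeline(
    records: Iterable[TrioSiteRecord],
    masks: GenomeMaskSet,
    cfg: FilterConfig,
) -> list[tuple[TrioSiteRecord, FilterVerdict]]:
    """Run the full cascade over a sorted record stream.

    The verdict is the union of hard, cluster and region trips; input order
    is preserved and per-filter trip counts are logged.
    """
    records = list(records)
    last: dict[str, int] = {}
    seen_chroms: set[str] = set()
    prev_chrom: str | None = None
    by_chrom: dict[str, list[int]] = {}
    for r in records:
        if r.chrom != prev_chrom:
            if r.chrom in seen_chroms:
                raise ValueError("records must be sorted by (chrom, pos)")
            seen_chroms.add(r.chrom)
            prev_chrom = r.chrom
        elif r.pos < last[r.chrom]:
            raise ValueError("records must be sorted by (chrom, pos)")
        last[r.chrom] = r.pos
        if r.is_snp:
            by_chrom.setdefault(r.chrom, []).append(r.pos)

    clustered: dict[str, set[int]] = {
        chrom: flag_snp_clusters(pos, cfg) for chrom, pos in by_chrom.items()
    }

    out: list[tuple[TrioSiteRecord, FilterVerdict]] = []
    counts: Counter[str] = Counter()
    for r in records:
        tripped = apply_hard_filters(r, cfg)
        tripped |= apply_region_filters(r, masks, cfg)
        if r.is_snp and r.pos in clustered.get(r.chrom, ()):
            tripped.add("SnpCluster")
        counts.update(tripped)
        out.append((r, FilterVerdict(r.chrom, r.pos, frozenset(tripped))))
    n_pass = sum(1 for _, v in out if v.passed)
    logger.info(
        "filter cascade: %d sites in, %d pass; trips per filter: %s",
        len(out),
        n_pass,
        dict(counts),
    )
    return out
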