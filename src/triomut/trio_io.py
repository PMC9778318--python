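"""Data model and I/O for trio variant analysis.

A *trio site* is one variant position genotyped in a mother, father and
offspring (here: mare, jack donkey, mule).  This module defines the in-memory
record types used throughout the pipeline and readers/writers for the
standard formats it touches: multi-sample VCF, BED3 mask tracks, GFF3 gene
models and the TSV call table.

Coordinate convention: everything internal is 0-based half-open.  VCF and
GFF3 are 1-based inclusive on disk; conversion happens only at the format
boundary (``pos`` on :class:`TrioSiteRecord` keeps the 1-based VCF position
for reporting, ``pos0`` gives the internal coordinate).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd
from cyvcf2 import VCF
from intervaltree import Interval, IntervalTree

logger = logging.getLogger(__name__)

ROLES = ("mother", "father", "offspring")
BASES = frozenset("ACGT")

# Site-level QC annotations the hard-filter cascade inspects.
INFO_KEYS = ("QD", "FS", "MQ", "MQRankSum", "ReadPosRankSum", "HaplotypeScore")


class TrioConfigError(ValueError):
    """Bad configuration (e.g. a sample role not present in the VCF)."""


class TrioParseError(ValueError):
    """Malformed input file."""


Genotype = tuple[int, int]  # allele indices into (ref,) + alts


@dataclass(frozen=True)
class SampleCall:
    """Per-sample genotype and read support at one site.

    ``genotype`` is ``None`` when the VCF call is missing (``./.``) or
    half-missing; allele depths may be absent independently of the genotype.
    """

    genotype: Genotype | None
    allele_depths: tuple[int, ...] | None
    total_depth: int | None

    def is_missing(self) -> bool:
        return self.genotype is None


@dataclass(frozen=True)
class TrioSiteRecord:
    """One variant site with mother/father/offspring calls.

    ``samples`` is ordered (mother, father, offspring).  ``info`` holds the
    site QC annotations (QD, FS, MQ, MQRankSum, ReadPosRankSum,
    HaplotypeScore); any key may be absent.
    """

    chrom: str
    pos: int  # 1-based, as printed in the VCF
    ref_allele: str
    alt_alleles: tuple[str, ...]
    qual: float | None
    info: Mapping[str, float]
    samples: tuple[SampleCall, SampleCall, SampleCall]

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        n_alleles = 1 + len(self.alt_alleles)
        for role, s in zip(ROLES, self.samples):
            if s.allele_depths is not None and len(s.allele_depths) != n_alleles:
                raise ValueError(
                    f"{role} allele_depths length {len(s.allele_depths)} != "
                    f"{n_alleles} alleles at {self.chrom}:{self.pos}"
                )
            if (
                s.allele_depths is not None
                and s.total_depth is not None
                and s.total_depth < max(s.allele_depths)
            ):
                raise ValueError(
                    f"total_depth < max allele depth for {role} at "
                    f"{self.chrom}:{self.pos}"
                )

    @property
    def pos0(self) -> int:
        """0-based position."""
        return self.pos - 1

    @property
    def alleles(self) -> tuple[str, ...]:
        return (self.ref_allele,) + self.alt_alleles

    @property
    def is_snp(self) -> bool:
        return all(len(a) == 1 and a in BASES for a in self.alleles)

    @property
    def mother(self) -> SampleCall:
        return self.samples[0]

    @property
    def father(self) -> SampleCall:
        return self.samples[1]

    @property
    def offspring(self) -> SampleCall:
        return self.samples[2]

    @property
    def key(self) -> tuple[str, int]:
        return (self.chrom, self.pos)

    def is_variant(self) -> bool:
        """True if any sample carries a non-reference allele."""
        return any(
            s.genotype is not None and any(a != 0 for a in s.genotype)
            for s in self.samples
        )


# ---------------------------------------------------------------------------
# Coordinate conversion (1-based inclusive <-> 0-based half-open)
# ---------------------------------------------------------------------------

def to_zero_based(start1: int, end1: int) -> tuple[int, int]:
    """Convert a 1-based inclusive interval to 0-based half-open."""
    return start1 - 1, end1


def to_one_based(start0: int, end0: int) -> tuple[int, int]:
    """Convert a 0-based half-open interval to 1-based inclusive."""
    return start0 + 1, end0


# ---------------------------------------------------------------------------
# Mask tracks
# ---------------------------------------------------------------------------

MaskTrack = dict[str, IntervalTree]


def _merge_intervals(ivs: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of intervals; overlapping or book-ended runs are merged."""
    out: list[tuple[int, int]] = []
    for s, e in sorted(ivs):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


@dataclass
class GenomeMaskSet:
    """The four mask tracks used by the region filters.

    All tracks are 0-based half-open interval sets keyed by chromosome,
    stored merged and sorted.  ``indel_positions`` holds single-base anchor
    intervals for indel sites.
    """

    repeat_regions: MaskTrack = field(default_factory=dict)
    cnv_regions: MaskTrack = field(default_factory=dict)
    gap_regions: MaskTrack = field(default_factory=dict)
    indel_positions: MaskTrack = field(default_factory=dict)

    @classmethod
    def from_beds(
        cls,
        repeats: str | None = None,
        cnv: str | None = None,
        gaps: str | None = None,
        indels: str | None = None,
    ) -> "GenomeMaskSet":
        def load(p):
            return read_mask_bed(p) if p else {}

        return cls(load(repeats), load(cnv), load(gaps), load(indels))

    @staticmethod
    def _contains(track: MaskTrack, chrom: str, pos0: int) -> bool:
        tree = track.get(chrom)
        return bool(tree is not None and tree.overlap(pos0, pos0 + 1))

    def in_repeat(self, chrom: str, pos0: int) -> bool:
        return self._contains(self.repeat_regions, chrom, pos0)

    def in_cnv(self, chrom: str, pos0: int) -> bool:
        return self._contains(self.cnv_regions, chrom, pos0)

    def near_indel(self, chrom: str, pos0: int, flank: int) -> bool:
        """Within ``flank`` bp of any indel anchor (distance measured
        between single positions, inclusive)."""
        tree = self.indel_positions.get(chrom)
        if tree is None:
            return False
        return bool(tree.overlap(pos0 - flank, pos0 + flank + 1))

    def near_gap(self, chrom: str, pos0: int, margin: int) -> bool:
        """Inside a gap or within ``margin`` bp of a gap edge."""
        tree = self.gap_regions.get(chrom)
        if tree is None:
            return False
        return bool(tree.overlap(pos0 - margin, pos0 + margin + 1))


def read_mask_bed(path: str) -> MaskTrack:
    """Read a BED3 file into merged per-chromosome interval trees.

    BED is 0-based half-open already; intervals are unioned per chromosome.
    """
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            comment="#",
            usecols=[0, 1, 2],
            names=["chrom", "start", "end"],
            dtype={"chrom": str, "start": int, "end": int},
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise TrioParseError(f"malformed BED file {path}: {exc}") from exc
    bad = df[df.start >= df.end]
    if len(bad):
        row = bad.iloc[0]
        raise TrioParseError(
            f"BED interval start >= end at {row.chrom}:{row.start}-{row.end} in {path}"
        )
    track: MaskTrack = {}
    for chrom, grp in df.groupby("chrom", sort=False):
        merged = _merge_intervals(zip(grp.start, grp.end))
        track[str(chrom)] = IntervalTree(Interval(s, e) for s, e in merged)
    return track


def write_mask_bed(track: MaskTrack, path: str) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(track):
            for iv in sorted(track[chrom]):
                fh.write(f"{chrom}\t{iv.begin}\t{iv.end}\n")


# ---------------------------------------------------------------------------
# Gene models (GFF3)
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    """A gene with its transcript structure, internally 0-based half-open.

    ``exons``/``cds``/``utr5``/``utr3`` are unions over all transcripts of
    the gene; precedence-based region annotation resolves transcript
    disagreement downstream.  ``biotype`` is "coding" or "noncoding".
    """

    gene_id: str
    chrom: str
    strand: str
    span: tuple[int, int]
    transcript_spans: list[tuple[int, int]] = field(default_factory=list)
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds: list[tuple[int, int]] = field(default_factory=list)
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)
    biotype: str = "coding"

    @property
    def start(self) -> int:
        return self.span[0]

    @property
    def end(self) -> int:
        return self.span[1]


def _covered(inner: Sequence[tuple[int, int]], outer: Sequence[tuple[int, int]]) -> bool:
    """True if every inner interval is contained in the union of outer."""
    merged = _merge_intervals(outer)
    for s, e in inner:
        if not any(ms <= s and e <= me for ms, me in merged):
            return False
    return True


def read_gff3(path: str) -> list[GeneModel]:
    """Parse gene/mRNA/exon/CDS/UTR features into :class:`GeneModel` objects.

    Validates the structural invariants: exons within a transcript must not
    overlap one another and CDS must lie within exons.  An exon whose Parent
    is absent from the file is an error.
    """
    import gffutils

    db = gffutils.create_db(
        path, ":memory:", merge_strategy="create_unique", keep_order=True
    )
    # Validate parentage of exon-level features.
    known_ids = {f.id for f in db.all_features()}
    for feat in db.all_features():
        if feat.featuretype in ("exon", "CDS", "five_prime_UTR", "three_prime_UTR"):
            parents = feat.attributes.get("Parent", [])
            if not parents or any(p not in known_ids for p in parents):
                raise TrioParseError(
                    f"orphan {feat.featuretype} at {feat.seqid}:{feat.start} "
                    f"without a known Parent in {path}"
                )

    genes: list[GeneModel] = []
    for g in db.features_of_type("gene"):
        biotype = (g.attributes.get("biotype") or ["coding"])[0]
        if biotype in ("protein_coding", "coding"):
            biotype = "coding"
        else:
            biotype = "noncoding"
        model = GeneModel(
            gene_id=g.id,
            chrom=g.seqid,
            strand=g.strand,
            span=to_zero_based(g.start, g.end),
            biotype=biotype,
        )
        for t in db.children(g, level=1):
            if t.featuretype not in ("mRNA", "transcript", "ncRNA"):
                continue
            t_exons: list[tuple[int, int]] = []
            t_cds: list[tuple[int, int]] = []
            for child in db.children(t, level=1):
                iv = to_zero_based(child.start, child.end)
                if child.featuretype == "exon":
                    t_exons.append(iv)
                elif child.featuretype == "CDS":
                    t_cds.append(iv)
                elif child.featuretype == "five_prime_UTR":
                    model.utr5.append(iv)
                elif child.featuretype == "three_prime_UTR":
                    model.utr3.append(iv)
            t_exons.sort()
            for (s1, e1), (s2, e2) in zip(t_exons, t_exons[1:]):
                if s2 < e1:
                    raise TrioParseError(
                        f"overlapping exons in transcript {t.id} of {g.id}"
                    )
            if t_cds and not _covered(t_cds, t_exons):
                raise TrioParseError(
                    f"CDS extends beyond exons in transcript {t.id} of {g.id}"
                )
            model.transcript_spans.append(to_zero_based(t.start, t.end))
            model.exons.extend(t_exons)
            model.cds.extend(t_cds)
        model.exons = _merge_intervals(model.exons)
        model.cds = _merge_intervals(model.cds)
        model.utr5 = _merge_intervals(model.utr5)
        model.utr3 = _merge_intervals(model.utr3)
        genes.append(model)
    return genes


# ---------------------------------------------------------------------------
# VCF reading / writing
# ---------------------------------------------------------------------------

def read_trio_vcf(
    path: str,
    sample_roles: Mapping[str, str],
    chromosomes: Sequence[str] | None = None,
) -> Iterator[TrioSiteRecord]:
    """Stream trio site records from a multi-sample VCF.

    ``sample_roles`` maps the roles "mother", "father", "offspring" to VCF
    sample names.  Missing or half-missing genotypes become ``None``; missing
    AD/DP stay ``None`` — no values are fabricated.  Non-SNP records are
    yielded as-is (``is_snp`` is False).  When ``chromosomes`` is given,
    records on other sequences are dropped and the drop count logged
    (autosome-only analysis).
    """
    for role in ROLES:
        if role not in sample_roles:
            raise TrioConfigError(f"sample_roles is missing the role {role!r}")
    vcf = VCF(path)
    try:
        idx = [vcf.samples.index(sample_roles[r]) for r in ROLES]
    except ValueError as exc:
        raise TrioConfigError(
            f"sample {exc} not found in VCF samples {vcf.samples}"
        ) from None
    allowed = set(chromosomes) if chromosomes is not None else None
    n_dropped = 0
    for rec_no, v in enumerate(vcf, start=1):
        if allowed is not None and v.CHROM not in allowed:
            n_dropped += 1
            continue
        try:
            yield _convert_record(v, idx)
        except Exception as exc:
            raise TrioParseError(
                f"malformed VCF record #{rec_no} at {v.CHROM}:{v.POS}: {exc}"
            ) from exc
    if n_dropped:
        logger.info("dropped %d records on non-analysis chromosomes", n_dropped)


def _convert_record(v, idx: list[int]) -> TrioSiteRecord:
    ad = v.format("AD")
    dp = v.format("DP")
    gts = v.genotypes
    n_alleles = 1 + len(v.ALT)
    calls = []
    for i in idx:
        g = gts[i]
        alleles = tuple(int(a) for a in g[:-1])
        gt: Genotype | None
        if len(alleles) != 2 or any(a < 0 for a in alleles):
            gt = None  # missing or half-missing
        else:
            gt = (alleles[0], alleles[1])
        depths: tuple[int, ...] | None = None
        if ad is not None:
            row = [int(x) for x in ad[i][:n_alleles]]
            if all(x >= 0 for x in row):
                depths = tuple(row)
        total: int | None = None
        if dp is not None:
            val = int(dp[i].item() if hasattr(dp[i], "item") else dp[i])
            if val >= 0:
                total = val
        if total is None and depths is not None:
            total = sum(depths)
        calls.append(SampleCall(gt, depths, total))
    info = {}
    for k in INFO_KEYS:
        val = v.INFO.get(k)
        if val is not None:
            info[k] = float(val)
    return TrioSiteRecord(
        chrom=v.CHROM,
        pos=v.POS,
        ref_allele=v.REF,
        alt_alleles=tuple(v.ALT),
        qual=None if v.QUAL is None else float(v.QUAL),
        info=info,
        samples=tuple(calls),
    )


def write_trio_vcf(
    records: Iterable[TrioSiteRecord],
    path: str,
    sample_names: Mapping[str, str] | None = None,
    contig_lengths: Mapping[str, int] | None = None,
) -> None:
    """Write records as a VCF v4.2 file with GT:AD:DP sample fields.

    ``sample_names`` maps roles to column names (defaults to the role names
    themselves).  Output is deterministic for identical input.
    """
    names = [
        (sample_names or {}).get(r, r) for r in ROLES
    ]
    records = list(records)
    if contig_lengths is None:
        contig_lengths = {}
        for r in records:
            contig_lengths[r.chrom] = max(contig_lengths.get(r.chrom, 0), r.pos + 1000)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, length in contig_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        for k in INFO_KEYS:
            fh.write(
                f'##INFO=<ID={k},Number=1,Type=Float,Description="{k}">\n'
            )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n'
        )
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(names)
            + "\n"
        )
        for r in records:
            info = ";".join(f"{k}={r.info[k]:g}" for k in INFO_KEYS if k in r.info)
            cols = [
                r.chrom,
                str(r.pos),
                ".",
                r.ref_allele,
                ",".join(r.alt_alleles) if r.alt_alleles else ".",
                "." if r.qual is None else f"{r.qual:g}",
                ".",
                info or ".",
                "GT:AD:DP",
            ]
            for s in r.samples:
                gt = "./." if s.genotype is None else f"{s.genotype[0]}/{s.genotype[1]}"
                ad = "." if s.allele_depths is None else ",".join(
                    map(str, s.allele_depths)
                )
                dp = "." if s.total_depth is None else str(s.total_depth)
                cols.append(f"{gt}:{ad}:{dp}")
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# Call table (TSV)
# ---------------------------------------------------------------------------

CALL_TABLE_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "state",
    "origin",
    "method_agreement",
    "retained",
    "reason",
    "tripped_filters",
    "offspring_ad",
    "mother_dp",
    "father_dp",
    "offspring_dp",
]


def write_call_table(calls: Iterable[Mapping[str, object]], path: str) -> None:
    """Write classified calls to TSV with a stable column order.

    Each call is a mapping carrying the :data:`CALL_TABLE_COLUMNS` keys
    (missing keys are written as empty strings).  Byte output is
    deterministic for identical input.
    """
    with open(path, "w", newline="") as fh:
        w = csv.DictWriter(
            fh, fieldnames=CALL_TABLE_COLUMNS, delimiter="\t", extrasaction="ignore"
        )
        w.writeheader()
        for c in calls:
            w.writerow({k: c.get(k, "") for k in CALL_TABLE_COLUMNS})


def read_call_table(path: str) -> list[dict[str, str]]:
    with open(path, newline="") as fh:
        return list(csv.DictReader(fh, delimiter="\t"))
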