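"""Precedence-based genomic region annotation of SNPs against gene models.

Each site receives exactly one region label with the precedence

    exonic > UTR5 > UTR3 > intronic > ncRNA_exonic > ncRNA_intronic
           > upstream > downstream > intergenic

mirroring precedence-based annotators: when transcripts disagree (exonic in
one isoform, intronic in another) the highest-precedence label wins.
Upstream/downstream means within 1 kb of the gene's 5'/3' end respecting
strand.  Intergenic sites are assigned their nearest gene(s) only when
within 5 kb; farther sites carry no gene.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from decimal import ROUND_HALF_EVEN, Decimal
from typing import Iterable, Mapping, Sequence

from intervaltree import Interval, IntervalTree

from .inheritance import InheritanceCall, Origin, State
from .trio_io import GeneModel

REGION_PRECEDENCE = (
    "exonic",
    "UTR5",
    "UTR3",
    "intronic",
    "ncRNA_exonic",
    "ncRNA_intronic",
    "upstream",
    "downstream",
    "intergenic",
)
_RANK = {r: i for i, r in enumerate(REGION_PRECEDENCE)}


@dataclass(frozen=True)
class RegionAnnotation:
    chrom: str
    pos: int  # 1-based, matching the call table
    region: str
    assigned_genes: tuple[str, ...]
    distance_to_nearest_gene: int | None = None  # intergenic only

    def __post_init__(self) -> None:
        if self.region not in _RANK:
            raise ValueError(f"unknown region label {self.region!r}")


def _in_any(pos: int, intervals: Sequence[tuple[int, int]]) -> bool:
    return any(s <= pos < e for s, e in intervals)


def _gene_label(gene: GeneModel, pos0: int, upstream_window: int) -> str | None:
    """Region label this single gene gives a position, or None."""
    s, e = gene.span
    if s <= pos0 < e:
        if gene.biotype == "coding":
            if _in_any(pos0, gene.cds):
                return "exonic"
            if _in_any(pos0, gene.utr5):
                return "UTR5"
            if _in_any(pos0, gene.utr3):
                return "UTR3"
            if _in_any(pos0, gene.exons):
                # exon outside annotated CDS/UTR: treat as exonic
                return "exonic"
            return "intronic"
        if _in_any(pos0, gene.exons):
            return "ncRNA_exonic"
        return "ncRNA_intronic"
    # flanks, strand-aware
    if gene.strand == "+":
        five, three = s, e
        if five - upstream_window <= pos0 < five:
            return "upstream"
        if three <= pos0 < three + upstream_window:
            return "downstream"
    else:
        five, three = e, s
        if five <= pos0 < five + upstream_window:
            return "upstream"
        if three - upstream_window <= pos0 < three:
            return "downstream"
    return None


class GeneIndex:
    """Interval index over gene models for fast per-site region lookup."""

    def __init__(
        self,
        genes: Iterable[GeneModel],
        upstream_window: int = 1000,
        intergenic_window: int = 5000,
    ) -> None:
        self.upstream_window = upstream_window
        self.intergenic_window = intergenic_window
        self._trees: dict[str, IntervalTree] = {}
        self._spans: dict[str, list[tuple[int, int, GeneModel]]] = {}
        for g in genes:
            tree = self._trees.setdefault(g.chrom, IntervalTree())
            s, e = g.span
            tree.add(Interval(s - upstream_window, e + upstream_window, g))
            self._spans.setdefault(g.chrom, []).append((s, e, g))
        for chrom in self._spans:
            self._spans[chrom].sort(key=lambda t: (t[0], t[1]))
        self._starts = {
            chrom: [s for s, _, _ in spans] for chrom, spans in self._spans.items()
        }

    def nearest_genes(self, chrom: str, pos0: int) -> tuple[int, list[GeneModel]]:
        """Distance to the nearest gene span and all genes at that distance.

        Distance is 0 inside a span; returns (-1, []) on a chromosome with
        no genes.
        """
        spans = self._spans.get(chrom)
        if not spans:
            return -1, []
        # scan a neighbourhood around the insertion point; spans may overlap
        # so widen generously (gene lists per chromosome are small here).
        i = bisect.bisect_right(self._starts[chrom], pos0)
        best = None
        best_genes: list[GeneModel] = []
        lo = max(0, i - 50)
        hi = min(len(spans), i + 50)
        for s, e, g in spans[lo:hi]:
            if s <= pos0 < e:
                d = 0
            elif pos0 < s:
                d = s - pos0
            else:
                d = pos0 - (e - 1)
            if best is None or d < best:
                best, best_genes = d, [g]
            elif d == best:
                best_genes.append(g)
        return best, best_genes

    def classify(self, chrom: str, pos0: int) -> RegionAnnotation:
        return classify_region(chrom, pos0, self)


def classify_region(chrom: str, pos0: int, index: GeneIndex) -> RegionAnnotation:
    """Assign the single region label and owning genes for one position.

    ``pos0`` is 0-based.  A position on an unannotated chromosome is
    intergenic with no assigned gene.
    """
    tree = index._trees.get(chrom)
    hits: list[tuple[str, GeneModel]] = []
    if tree is not None:
        for iv in tree.overlap(pos0, pos0 + 1):
            label = _gene_label(iv.data, pos0, index.upstream_window)
            if label is not None:
                hits.append((label, iv.data))
    if hits:
        best_rank = min(_RANK[lbl] for lbl, _ in hits)
        label = REGION_PRECEDENCE[best_rank]
        genes = sorted({g.gene_id for lbl, g in hits if _RANK[lbl] == best_rank})
        return RegionAnnotation(chrom, pos0 + 1, label, tuple(genes))
    dist, near = index.nearest_genes(chrom, pos0)
    if dist < 0:
        return RegionAnnotation(chrom, pos0 + 1, "intergenic", (), None)
    genes = (
        tuple(sorted(g.gene_id for g in near))
        if dist <= index.intergenic_window
        else ()
    )
    return RegionAnnotation(chrom, pos0 + 1, "intergenic", genes, dist)


def annotate_sites(
    sites: Iterable[tuple[str, int]], index: GeneIndex
) -> list[RegionAnnotation]:
    """Annotate (chrom, 1-based pos) site keys."""
    return [classify_region(chrom, pos - 1, index) for chrom, pos in sites]


def distribution_report(
    annotations: Iterable[RegionAnnotation],
    total: int | None = None,
) -> dict[str, dict[str, object]]:
    """Counts and percentages per region label.

    Percentages are count/total*100 rounded half-even to 2 decimals on the
    exact fraction.  ``total`` defaults to the number of annotations; it can
    be supplied explicitly when percentages must be taken against a larger
    reported SNP total than the labelled subset at hand.
    """
    counts: dict[str, int] = {}
    for a in annotations:
        counts[a.region] = counts.get(a.region, 0) + 1
    if total is None:
        total = sum(counts.values())
    report: dict[str, dict[str, object]] = {}
    for region in REGION_PRECEDENCE:
        if region not in counts:
            continue
        n = counts[region]
        pct = Decimal(n * 100) / Decimal(total)
        report[region] = {
            "count": n,
            "pct": float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_EVEN)),
        }
    return report


def genes_per_class(
    calls: Iterable[InheritanceCall],
    annotations: Mapping[tuple[str, int], RegionAnnotation],
) -> dict[str, set[str]]:
    """Union of assigned genes per mutation class.

    Classes: ``mie_from_mother``, ``mie_from_father``, ``denovo``.  A gene
    near several SNPs is counted once per class; a SNP assigned several
    genes contributes all of them, so gene totals can exceed SNP totals.
    """
    out: dict[str, set[str]] = {
        "mie_from_mother": set(),
        "mie_from_father": set(),
        "denovo": set(),
    }
    for c in calls:
        if not c.retained:
            continue
        if c.state == State.DENOVO:
            key = "denovo"
        elif c.state == State.MIE and c.origin == Origin.MOTHER:
            key = "mie_from_mother"
        elif c.state == State.MIE and c.origin == Origin.FATHER:
            key = "mie_from_father"
        else:
            continue
        ann = annotations.get((c.chrom, c.pos))
        if ann is not None:
            out[key].update(ann.assigned_genes)
    return out
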