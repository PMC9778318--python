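"""Synthetic hybrid-trio generator with ground truth.

Emulates the data a horse x donkey -> mule trio analysis consumes: a
multi-sample VCF over a set of scanned callable positions, mask tracks
(repeats, CNVs, assembly gaps, indel anchors), GFF3 gene models, a
gene->pathway map, and a per-site truth table.

The statistical structure mirrors the study system:

* the two parents have very different SNP densities against the (horse)
  reference — the mother/horse ~0.20% of sites, the father/donkey ~0.95% —
  and very different heterozygous fractions (~0.67 vs ~0.08);
* the offspring receives one uniformly chosen allele from each parent;
* MIE events override transmission: the offspring is made homozygous for an
  allele carried by exactly one parent (both alleles from one parent);
* de novo events substitute one transmitted offspring allele with a base
  absent from both parental genotypes;
* per-sample site depth is Poisson(mean_depth); allele depths follow the
  allele dosage with a per-read error rate that redirects reads uniformly
  to the other three bases;
* site QC annotations are drawn from passing ranges, with a configured
  fraction of sites given one planted hard-filter violation;
* SNP-cluster test cases are planted explicitly (sites are otherwise spaced
  far apart and simulated independently — the site-wise analysis needs no
  linkage).

Everything is driven by one numpy Generator; a fixed seed gives
byte-identical output files.
"""

from __future__ import annotations


import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from intervaltree import Interval, IntervalTree

from .trio_io import (
    GeneModel,
    GenomeMaskSet,
    SampleCall,
    TrioSiteRecord,
    write_mask_bed,
    write_trio_vcf,
)

BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of the synthetic trio.

    Default SNP rates and heterozygous fractions follow the per-genome SNP
    summaries of the real trio (donkey ~0.95% of sites variant, ~8% of
    those heterozygous; horse ~0.20% variant, ~68% heterozygous); default
    event rates follow the per-callable-site MIE and de novo rates the
    analysis reports (~1e-5 and ~2.2e-7).  ``n_sites`` is the number of
    scanned callable positions and is the denominator of simulated rates.
    """

    seed: int = 0
    n_sites: int = 100_000
    n_chroms: int = 2
    site_spacing: int = 100  # bp between scanned sites
    mother_snp_rate: float = 0.0020
    father_snp_rate: float = 0.0095
    mother_het_fraction: float = 0.67
    father_het_fraction: float = 0.08
    mean_depth: float = 30.0
    base_error_rate: float = 0.01
    mie_injection_rate: float = 1.0e-5
    denovo_injection_rate: float = 2.21e-7
    qc_violation_rate: float = 0.02
    repeat_density: float = 0.05
    cnv_density: float = 0.02
    gap_density: float = 0.005
    indel_density: float = 5.0e-5  # anchors per bp
    n_cluster_groups: int = 5
    n_genes: int = 200
    n_pathways: int = 20
    noncoding_fraction: float = 0.2
    mother_name: str = "horse"
    father_name: str = "donkey"
    offspring_name: str = "mule"

    def __post_init__(self) -> None:
        rates = (
            self.mother_snp_rate,
            self.father_snp_rate,
            self.mother_het_fraction,
            self.father_het_fraction,
            self.mie_injection_rate,
            self.denovo_injection_rate,
            self.qc_violation_rate,
        )
        if any(not 0 <= r <= 1 for r in rates):
            raise ValueError("rates and fractions must lie in [0, 1]")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if self.n_sites < 1 or self.n_chroms < 1:
            raise ValueError("n_sites and n_chroms must be positive")


@dataclass(frozen=True)
class TruthRow:
    """Ground truth for one emitted site."""

    chrom: str
    pos: int  # 1-based
    alleles: tuple[str, ...]
    mother_gt: tuple[int, int]
    father_gt: tuple[int, int]
    offspring_gt: tuple[int, int]
    transmitted: tuple[int, int]  # (from mother, from father) pre-override
    event: str  # none | MIE | DENOVO
    event_origin: str  # MOTHER | FATHER | NA
    mechanism: str  # transmission | injected | cluster_plant | none
    planted_violation: str  # hard-filter name or ""


@dataclass
class TrioSimulation:
    """Bundle of everything :func:`simulate_trio` produces."""

    config: SimConfig
    records: list[TrioSiteRecord]
    masks: GenomeMaskSet
    genes: list[GeneModel]
    pathway_map: dict[str, set[str]]
    truth: list[TruthRow]
    chrom_lengths: dict[str, int]

    @property
    def n_scanned(self) -> int:
        """Scanned callable positions — the rate denominator."""
        return self.config.n_sites

    def truth_by_key(self) -> dict[tuple[str, int], TruthRow]:
        return {(t.chrom, t.pos): t for t in self.truth}

    def sample_roles(self) -> dict[str, str]:
        c = self.config
        return {
            "mother": c.mother_name,
            "father": c.father_name,
            "offspring": c.offspring_name,
        }

    def write(self, outdir: str) -> dict[str, str]:
        """Write VCF, BED masks, GFF3, pathway TSV and truth TSV."""
        os.makedirs(outdir, exist_ok=True)
        paths = {
            "vcf": os.path.join(outdir, "trio.vcf"),
            "repeats": os.path.join(outdir, "repeats.bed"),
            "cnv": os.path.join(outdir, "cnv.bed"),
            "gaps": os.path.join(outdir, "gaps.bed"),
            "indels": os.path.join(outdir, "indels.bed"),
            "gff3": os.path.join(outdir, "genes.gff3"),
            "pathways": os.path.join(outdir, "pathways.tsv"),
            "truth": os.path.join(outdir, "truth.tsv"),
        }
        write_trio_vcf(
            self.records,
            paths["vcf"],
            sample_names=self.sample_roles(),
            contig_lengths=self.chrom_lengths,
        )
        write_mask_bed(self.masks.repeat_regions, paths["repeats"])
        write_mask_bed(self.masks.cnv_regions, paths["cnv"])
        write_mask_bed(self.masks.gap_regions, paths["gaps"])
        write_mask_bed(self.masks.indel_positions, paths["indels"])
        write_gff3(self.genes, self.chrom_lengths, paths["gff3"])
        with open(paths["pathways"], "w") as fh:
            for gene in sorted(self.pathway_map):
                for pw in sorted(self.pathway_map[gene]):
                    fh.write(f"{gene}\t{pw}\n")
        with open(paths["truth"], "w") as fh:
            fh.write(
                "chrom\tpos\talleles\tmother_gt\tfather_gt\toffspring_gt\t"
                "transmitted\tevent\tevent_origin\tmechanism\tplanted_violation\n"
            )
            for t in self.truth:
                fh.write(
                    f"{t.chrom}\t{t.pos}\t{','.join(t.alleles)}\t"
                    f"{t.mother_gt[0]}/{t.mother_gt[1]}\t"
                    f"{t.father_gt[0]}/{t.father_gt[1]}\t"
                    f"{t.offspring_gt[0]}/{t.offspring_gt[1]}\t"
                    f"{t.transmitted[0]}|{t.transmitted[1]}\t"
                    f"{t.event}\t{t.event_origin}\t{t.mechanism}\t"
                    f"{t.planted_violation}\n"
                )
        return paths


# QC annotation ranges: (passing low, high) and (failing low, high).
_QC_PASS = {
    "QUAL": (100.0, 1000.0),
    "QD": (15.0, 35.0),
    "FS": (0.0, 5.0),
    "MQ": (50.0, 60.0),
    "MQRankSum": (-1.5, 1.5),
    "ReadPosRankSum": (-1.5, 1.5),
    "HaplotypeScore": (0.0, 5.0),
}
_QC_FAIL = {
    "LowQual": ("QUAL", (0.0, 29.9)),
    "FilterQD": ("QD", (0.0, 1.9)),
    "FilterFS": ("FS", (20.1, 60.0)),
    "FilterMQ": ("MQ", (0.0, 19.9)),
    "FilterMQRankSum": ("MQRankSum", (-8.0, -3.1)),
    "FilterReadPosRankSum": ("ReadPosRankSum", (-8.0, -3.1)),
    "HaplotypeScore": ("HaplotypeScore", (13.1, 30.0)),
}
_FAIL_NAMES = tuple(_QC_FAIL)


def _draw_qc(rng: np.random.Generator, violation: str | None) -> tuple[float, dict]:
    # 2-decimal quantisation keeps values faithful through VCF text round trips
    vals = {
        k: round(float(rng.uniform(*rng_range)), 2) for k, rng_range in _QC_PASS.items()
    }
    if violation is not None:
        key, (lo, hi) = _QC_FAIL[violation]
        vals[key] = round(float(rng.uniform(lo, hi)), 2)
    qual = vals.pop("QUAL")
    return qual, vals


def _sample_reads(
    rng: np.random.Generator,
    alleles: Sequence[str],
    genotype: tuple[int, int],
    mean_depth: float,
    error_rate: float,
) -> SampleCall:
    """Poisson depth, dosage-proportional allele draws, per-read error."""
    dp = int(rng.poisson(mean_depth))
    n_alleles = len(alleles)
    ad = np.zeros(n_alleles, dtype=int)
    if dp > 0:
        dosage = np.zeros(n_alleles)
        dosage[genotype[0]] += 0.5
        dosage[genotype[1]] += 0.5
        true_counts = rng.multinomial(dp, dosage)
        base_index = {b: i for i, b in enumerate(alleles)}
        for j in range(n_alleles):
            errs = rng.binomial(true_counts[j], error_rate)
            ad[j] += true_counts[j] - errs
            if errs:
                others = [b for b in BASES if b != alleles[j]]
                landed = rng.multinomial(errs, [1 / 3] * 3)
                for b, cnt in zip(others, landed):
                    tgt = base_index.get(b)
                    if tgt is not None:
                        ad[tgt] += cnt
                    # error reads to non-site bases are dropped from AD
    return SampleCall(genotype, tuple(int(x) for x in ad), dp)


def _parent_genotype(rng: np.random.Generator, het_fraction: float) -> tuple[int, int]:
    return (0, 1) if rng.random() < het_fraction else (1, 1)


def _random_intervals(
    rng: np.random.Generator, length: int, density: float, mean_len: int
) -> IntervalTree:
    n = int(round(density * length / mean_len))
    ivs: list[tuple[int, int]] = []
    for _ in range(n):
        ln = max(1, int(rng.exponential(mean_len)))
        s = int(rng.integers(0, max(1, length - ln)))
        ivs.append((s, s + ln))
    merged: list[tuple[int, int]] = []
    for s, e in sorted(ivs):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return IntervalTree(Interval(s, e) for s, e in merged)


def _point_track(rng: np.random.Generator, length: int, density: float) -> IntervalTree:
    n = int(round(density * length))
    pos = sorted(set(int(p) for p in rng.integers(0, length, n)))
    return IntervalTree(Interval(p, p + 1) for p in pos)


def simulate_masks(
    rng: np.random.Generator, cfg: SimConfig, chrom_lengths: dict[str, int]
) -> GenomeMaskSet:
    masks = GenomeMaskSet()
    for chrom, L in chrom_lengths.items():
        masks.repeat_regions[chrom] = _random_intervals(rng, L, cfg.repeat_density, 500)
        masks.cnv_regions[chrom] = _random_intervals(rng, L, cfg.cnv_density, 5000)
        masks.gap_regions[chrom] = _random_intervals(rng, L, cfg.gap_density, 1000)
        masks.indel_positions[chrom] = _point_track(rng, L, cfg.indel_density)
    return masks


def simulate_genes(
    rng: np.random.Generator, cfg: SimConfig, chrom_lengths: dict[str, int]
) -> list[GeneModel]:
    """Place non-overlapping gene models with exon/intron/UTR structure."""
    genes: list[GeneModel] = []
    per_chrom = max(1, cfg.n_genes // cfg.n_chroms)
    gid = 0
    for chrom, L in chrom_lengths.items():
        cursor = 1000
        for _ in range(per_chrom):
            gl = int(rng.integers(2000, 10001))
            if cursor + gl + 1000 >= L:
                break
            start = cursor
            end = start + gl
            cursor = end + int(rng.integers(2000, 8001))
            gid += 1
            strand = "+" if rng.random() < 0.5 else "-"
            biotype = (
                "noncoding" if rng.random() < cfg.noncoding_fraction else "coding"
            )
            ne = int(rng.integers(2, 5))
            exon_lens = rng.integers(100, 401, ne)
            slack = gl - int(exon_lens.sum())
            cuts = np.sort(rng.integers(1, max(2, slack), ne - 1)) if ne > 1 else []
            intron_lens = np.diff(np.concatenate(([0], cuts, [slack])))
            exons = []
            p = start
            for j in range(ne):
                if j > 0:
                    p += int(intron_lens[j])
                exons.append((p, p + int(exon_lens[j])))
                p = exons[-1][1]
            end = max(end, exons[-1][1])
            model = GeneModel(
                gene_id=f"G{gid:05d}",
                chrom=chrom,
                strand=strand,
                span=(start, end),
                transcript_spans=[(start, end)],
                exons=exons,
                biotype=biotype,
            )
            if biotype == "coding":
                first, last = exons[0], exons[-1]
                u5 = min(50, (first[1] - first[0]) - 1)
                u3 = min(100, (last[1] - last[0]) - 1)
                if strand == "+":
                    model.utr5 = [(first[0], first[0] + u5)]
                    model.utr3 = [(last[1] - u3, last[1])]
                else:
                    model.utr5 = [(last[1] - u5, last[1])]
                    model.utr3 = [(first[0], first[0] + u3)]
                blocked = model.utr5 + model.utr3
                cds = []
                for s, e in exons:
                    cs, ce = s, e
                    for bs, be in blocked:
                        if bs <= cs < be:
                            cs = be
                        if bs < ce <= be:
                            ce = bs
                    if cs < ce:
                        cds.append((cs, ce))
                model.cds = cds
            genes.append(model)
    return genes


def simulate_pathways(
    rng: np.random.Generator, cfg: SimConfig, genes: Sequence[GeneModel]
) -> dict[str, set[str]]:
    pathways = [f"pw{j:03d}" for j in range(cfg.n_pathways)]
    out: dict[str, set[str]] = {}
    for g in genes:
        if rng.random() < 0.7 and pathways:
            k = int(rng.integers(1, min(4, len(pathways) + 1)))
            chosen = rng.choice(len(pathways), size=k, replace=False)
            out[g.gene_id] = {pathways[int(c)] for c in chosen}
    return out


def write_gff3(
    genes: Sequence[GeneModel], chrom_lengths: dict[str, int], path: str
) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, L in chrom_lengths.items():
            fh.write(f"##sequence-region {chrom} 1 {L}\n")
        for g in genes:
            s1, e1 = g.span[0] + 1, g.span[1]
            bt = "protein_coding" if g.biotype == "coding" else "noncoding"
            fh.write(
                f"{g.chrom}\tsim\tgene\t{s1}\t{e1}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id};biotype={bt}\n"
            )
            tid = f"{g.gene_id}.t1"
            ttype = "mRNA" if g.biotype == "coding" else "transcript"
            fh.write(
                f"{g.chrom}\tsim\t{ttype}\t{s1}\t{e1}\t.\t{g.strand}\t.\t"
                f"ID={tid};Parent={g.gene_id}\n"
            )
            def emit(ftype: str, ivs: Sequence[tuple[int, int]]) -> None:
                for s, e in ivs:
                    fh.write(
                        f"{g.chrom}\tsim\t{ftype}\t{s + 1}\t{e}\t.\t{g.strand}\t"
                        f"{'0' if ftype == 'CDS' else '.'}\tParent={tid}\n"
                    )
            emit("exon", g.exons)
            emit("CDS", g.cds)
            emit("five_prime_UTR", g.utr5)
            emit("three_prime_UTR", g.utr3)


def simulate_trio(cfg: SimConfig) -> TrioSimulation:
    """Generate the full synthetic dataset under one seeded Generator."""
    rng = np.random.default_rng(cfg.seed)
    per_chrom = -(-cfg.n_sites // cfg.n_chroms)  # ceil
    chrom_lengths = {
        f"chr{c + 1}": per_chrom * cfg.site_spacing + 2000
        for c in range(cfg.n_chroms)
    }
    chrom_names = list(chrom_lengths)

    # Site-level event designation over all scanned positions.
    u = rng.random(cfg.n_sites)
    mie_mask = u < cfg.mie_injection_rate
    dnv_mask = (~mie_mask) & (u < cfg.mie_injection_rate + cfg.denovo_injection_rate)
    m_var = rng.random(cfg.n_sites) < cfg.mother_snp_rate
    f_var = rng.random(cfg.n_sites) < cfg.father_snp_rate
    emit = m_var | f_var | mie_mask | dnv_mask
    emit_idx = np.flatnonzero(emit)

    # Planted SNP-cluster groups at otherwise-invariant scanned sites.
    cluster_anchor = set()
    non_emit = np.flatnonzero(~emit)
    if cfg.n_cluster_groups > 0 and len(non_emit):
        chosen = rng.choice(
            len(non_emit), size=min(cfg.n_cluster_groups, len(non_emit)), replace=False
        )
        cluster_anchor = {int(non_emit[int(c)]) for c in chosen}

    records: list[TrioSiteRecord] = []
    truth: list[TruthRow] = []

    def site_coords(i: int) -> tuple[str, int]:
        chrom = chrom_names[i // per_chrom]
        pos0 = (i % per_chrom) * cfg.site_spacing + 500
        return chrom, pos0

    def build_site(
        chrom: str,
        pos0: int,
        mother_gt: tuple[int, int],
        father_gt: tuple[int, int],
        offspring_gt: tuple[int, int],
        alleles: tuple[str, ...],
        transmitted: tuple[int, int],
        event: str,
        origin: str,
        mechanism: str,
    ) -> None:
        violation = (
            _FAIL_NAMES[int(rng.integers(len(_FAIL_NAMES)))]
            if rng.random() < cfg.qc_violation_rate
            else None
        )
        qual, info = _draw_qc(rng, violation)
        samples = tuple(
            _sample_reads(rng, alleles, gt, cfg.mean_depth, cfg.base_error_rate)
            for gt in (mother_gt, father_gt, offspring_gt)
        )
        records.append(
            TrioSiteRecord(
                chrom=chrom,
                pos=pos0 + 1,
                ref_allele=alleles[0],
                alt_alleles=alleles[1:],
                qual=qual,
                info=info,
                samples=samples,
            )
        )
        truth.append(
            TruthRow(
                chrom=chrom,
                pos=pos0 + 1,
                alleles=alleles,
                mother_gt=mother_gt,
                father_gt=father_gt,
                offspring_gt=offspring_gt,
                transmitted=transmitted,
                event=event,
                event_origin=origin,
                mechanism=mechanism,
                planted_violation=violation or "",
            )
        )

    def draw_site_alleles() -> tuple[str, str]:
        ref = BASES[int(rng.integers(4))]
        alt = [b for b in BASES if b != ref][int(rng.integers(3))]
        return ref, alt

    ordered = sorted(set(emit_idx.tolist()) | cluster_anchor)
    for i in ordered:
        chrom, pos0 = site_coords(i)
        if i in cluster_anchor:
            # Three Mendelian het-transmission SNPs within 7 bp.
            for off in (0, 3, 6):
                ref, alt = draw_site_alleles()
                gm = (0, 1)
                gf = (0, 0)
                a = int(rng.integers(2))  # allele from mother
                gc = tuple(sorted((gm[a], 0)))
                build_site(
                    chrom, pos0 + off, gm, gf, gc, (ref, alt), (gm[a], 0),
                    "none", "NA", "cluster_plant",
                )
            continue
        ref, alt = draw_site_alleles()
        alleles: tuple[str, ...] = (ref, alt)
        if mie_mask[i]:
            # Both offspring alleles from one parent; other parent hom-ref.
            origin_is_mother = rng.random() < 0.5
            if origin_is_mother:
                gm = _parent_genotype(rng, cfg.mother_het_fraction)
                gf = (0, 0)
                origin = "MOTHER"
            else:
                gf = _parent_genotype(rng, cfg.father_het_fraction)
                gm = (0, 0)
                origin = "FATHER"
            gc = (1, 1)
            build_site(
                chrom, pos0, gm, gf, gc, alleles, (1, 1), "MIE", origin, "injected"
            )
            continue
        gm = _parent_genotype(rng, cfg.mother_het_fraction) if m_var[i] else (0, 0)
        gf = _parent_genotype(rng, cfg.father_het_fraction) if f_var[i] else (0, 0)
        a = gm[int(rng.integers(2))]
        b = gf[int(rng.integers(2))]
        transmitted = (a, b)
        gc = tuple(sorted((a, b)))
        if dnv_mask[i]:
            parental_bases = {alleles[x] for x in gm} | {alleles[x] for x in gf}
            novel_candidates = [bb for bb in BASES if bb not in parental_bases]
            novel = novel_candidates[int(rng.integers(len(novel_candidates)))]
            if novel not in alleles:
                alleles = alleles + (novel,)
            novel_idx = alleles.index(novel)
            replace_first = rng.random() < 0.5
            gc = tuple(
                sorted((novel_idx, gc[1]) if replace_first else (gc[0], novel_idx))
            )
            build_site(
                chrom, pos0, gm, gf, gc, alleles, transmitted, "DENOVO", "NA",
                "injected",
            )
            continue
        build_site(chrom, pos0, gm, gf, gc, alleles, transmitted, "none", "NA",
                   "transmission" if (m_var[i] or f_var[i]) else "none")

    masks = simulate_masks(rng, cfg, chrom_lengths)
    genes = simulate_genes(rng, cfg, chrom_lengths)
    pathway_map = simulate_pathways(rng, cfg, genes)
    return TrioSimulation(
        config=cfg,
        records=records,
        masks=masks,
        genes=genes,
        pathway_map=pathway_map,
        truth=truth,
        chrom_lengths=chrom_lengths,
    )


def expected_counts(cfg: SimConfig) -> dict[str, float]:
    """First-order analytic expectations for the simulator's tallies.

    Event-injection overlap terms (O(rate^2)) are ignored; with the default
    rates they are negligible relative to binomial noise.
    """
    n = cfg.n_sites
    pm, pf = cfg.mother_snp_rate, cfg.father_snp_rate
    hm, hf = cfg.mother_het_fraction, cfg.father_het_fraction
    p_variant = pm + pf - pm * pf
    exp_emitted = n * (
        p_variant + (cfg.mie_injection_rate + cfg.denovo_injection_rate)
        * (1 - p_variant)
    ) + 3 * cfg.n_cluster_groups
    return {
        "mother_variant_sites": n * pm,
        "father_variant_sites": n * pf,
        "mother_het_sites": n * pm * hm,
        "mother_hom_sites": n * pm * (1 - hm),
        "father_het_sites": n * pf * hf,
        "father_hom_sites": n * pf * (1 - hf),
        "mie_events": n * cfg.mie_injection_rate,
        "denovo_events": n * cfg.denovo_injection_rate,
        "variant_positions": exp_emitted,
        "qc_violations": exp_emitted * cfg.qc_violation_rate,
    }
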