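"""End-to-end pipeline: filter -> classify -> annotate -> stats -> enrich.

Driven by a YAML/dict config:

.. code-block:: yaml

    vcf: trio.vcf
    sample_roles: {mother: horse, father: donkey, offspring: mule}
    masks: {repeats: repeats.bed, cnv: cnv.bed, gaps: gaps.bed, indels: indels.bed}
    gff3: genes.gff3
    pathways: pathways.tsv
    chromosomes: [chr1, chr2]      # optional autosome restriction
    callable_sites: 100000         # denominator for rates/percentages
    filter: {qual_min: 30.0, ...}  # FilterConfig overrides
    read_genotype: {min_coverage: 10, ...}
    annotate: {upstream_window: 1000, intergenic_window: 5000}
    reference_counts:              # optional fold comparisons
      mie_vs_chimp: [n_mie, 794]
      denovo_vs_chimp: [n_denovo, 45]

Outputs in the target directory: ``calls.tsv``, ``annotations.tsv``,
``summary.json``, ``enrichment.tsv`` and ``manifest.json``.  The summary is
byte-identical across runs with identical inputs and config; run metadata
with timestamps lives only in the manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from datetime import datetime, timezone
from typing import Mapping

import yaml

from . import __version__
from .annotate import GeneIndex, annotate_sites, distribution_report, genes_per_class
from .enrich import hypergeom_enrich, read_pathway_map, write_enrichment_table
from .inheritance import ReadGenotypeConfig, State, run_trio_classification
from .site_filter import FilterConfig, filter_pipeline
from .stats import TrioMutationSummary, summarize_genome
from .trio_io import (
    ROLES,
    GenomeMaskSet,
    read_gff3,
    read_trio_vcf,
    write_call_table,
)

logger = logging.getLogger(__name__)


class PipelineConfigError(ValueError):
    pass


def load_config(path_or_dict: str | Mapping) -> dict:
    if isinstance(path_or_dict, Mapping):
        cfg = dict(path_or_dict)
    else:
        with open(path_or_dict) as fh:
            cfg = yaml.safe_load(fh) or {}
    for key in ("vcf", "sample_roles", "callable_sites"):
        if key not in cfg:
            raise PipelineConfigError(f"config is missing required key {key!r}")
    if not os.path.exists(cfg["vcf"]):
        raise PipelineConfigError(f"VCF not found: {cfg['vcf']}")
    for _, p in (cfg.get("masks") or {}).items():
        if p and not os.path.exists(p):
            raise PipelineConfigError(f"mask file not found: {p}")
    for key in ("gff3", "pathways"):
        if cfg.get(key) and not os.path.exists(cfg[key]):
            raise PipelineConfigError(f"{key} file not found: {cfg[key]}")
    return cfg


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: str | Mapping, outdir: str) -> dict:
    """Execute all stages and write the output bundle; returns the summary."""
    cfg = load_config(config)
    os.makedirs(outdir, exist_ok=True)
    fcfg = FilterConfig(**(cfg.get("filter") or {}))
    rcfg = ReadGenotypeConfig(**(cfg.get("read_genotype") or {}))
    stage_counts: dict[str, int] = {}

    masks_cfg = cfg.get("masks") or {}
    masks = GenomeMaskSet.from_beds(
        repeats=masks_cfg.get("repeats"),
        cnv=masks_cfg.get("cnv"),
        gaps=masks_cfg.get("gaps"),
        indels=masks_cfg.get("indels"),
    )
    records = list(
        read_trio_vcf(
            cfg["vcf"], cfg["sample_roles"], chromosomes=cfg.get("chromosomes")
        )
    )
    stage_counts["input_records"] = len(records)

    filtered = filter_pipeline(records, masks, fcfg)
    passing = [r for r, v in filtered if v.passed]
    stage_counts["filter_pass"] = len(passing)
    stage_counts["filter_fail"] = len(records) - len(passing)

    calls, tallies = run_trio_classification(passing, rcfg)
    stage_counts["classified"] = len(calls)

    verdict_by_key = {(r.chrom, r.pos): v for r, v in filtered}
    call_rows = []
    rec_by_key = {r.key: r for r in records}
    for c in calls:
        r = rec_by_key[(c.chrom, c.pos)]
        call_rows.append(
            {
                "chrom": c.chrom,
                "pos": c.pos,
                "ref": r.ref_allele,
                "alt": ",".join(r.alt_alleles),
                "state": c.state.value,
                "origin": c.origin.value,
                "method_agreement": c.method_agreement,
                "retained": int(c.retained),
                "reason": c.reason,
                "tripped_filters": ";".join(
                    sorted(verdict_by_key[(c.chrom, c.pos)].tripped)
                ),
                "offspring_ad": ",".join(map(str, c.offspring_allele_depths or ())),
                "mother_dp": c.mother_depth,
                "father_dp": c.father_depth,
                "offspring_dp": c.offspring_depth,
            }
        )
    write_call_table(call_rows, os.path.join(outdir, "calls.tsv"))

    callable_sites = int(cfg["callable_sites"])
    summary: dict = {"tallies": tallies, "callable_sites": callable_sites}

    # Per-genome summaries over passing biallelic SNPs.
    snp_records = [r for r in passing if r.is_snp and len(r.alt_alleles) == 1]
    summary["per_genome"] = {
        role: summarize_genome(snp_records, role, callable_sites).as_dict()
        for role in ROLES
    }

    ref_counts = {
        name: (str(pair[0]), int(pair[1]))
        for name, pair in (cfg.get("reference_counts") or {}).items()
    }
    trio_summary = TrioMutationSummary.from_tallies(
        tallies, callable_sites, reference_counts=ref_counts
    )
    summary["trio"] = trio_summary.as_dict()

    # Annotate retained non-Mendelian calls.
    nm_calls = [
        c for c in calls if c.retained and c.state in (State.MIE, State.DENOVO)
    ]
    stage_counts["non_mendelian_retained"] = len(nm_calls)
    annotations = []
    gene_sets: dict[str, list[str]] = {}
    if cfg.get("gff3"):
        genes = read_gff3(cfg["gff3"])
        acfg = cfg.get("annotate") or {}
        index = GeneIndex(
            genes,
            upstream_window=int(acfg.get("upstream_window", 1000)),
            intergenic_window=int(acfg.get("intergenic_window", 5000)),
        )
        annotations = annotate_sites([(c.chrom, c.pos) for c in nm_calls], index)
        summary["region_distribution"] = distribution_report(annotations)
        ann_by_key = {(a.chrom, a.pos): a for a in annotations}
        gene_sets = {
            k: sorted(v) for k, v in genes_per_class(nm_calls, ann_by_key).items()
        }
        summary["genes_per_class"] = {k: len(v) for k, v in gene_sets.items()}
        with open(os.path.join(outdir, "annotations.tsv"), "w") as fh:
            fh.write("chrom\tpos\tregion\tassigned_genes\tdistance\n")
            for a in annotations:
                dist = "" if a.distance_to_nearest_gene is None else str(
                    a.distance_to_nearest_gene
                )
                fh.write(
                    f"{a.chrom}\t{a.pos}\t{a.region}\t"
                    f"{','.join(a.assigned_genes)}\t{dist}\n"
                )
        stage_counts["annotated"] = len(annotations)

        if cfg.get("pathways"):
            pathway_map = read_pathway_map(cfg["pathways"])
            if cfg.get("universe") == "pathway_map":
                universe = set(pathway_map)
            else:
                universe = {g.gene_id for g in genes}
            gene_set = set().union(*map(set, gene_sets.values())) if gene_sets else set()
            gene_set &= universe
            results = hypergeom_enrich(gene_set, pathway_map, universe)
            write_enrichment_table(results, os.path.join(outdir, "enrichment.tsv"))
            stage_counts["pathways_tested"] = len(results)
            summary["enrichment_top"] = [
                {"pathway_id": r.pathway_id, "p_value": r.p_value, "q_value": r.q_value}
                for r in results[:10]
            ]

    with open(os.path.join(outdir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")

    manifest = {
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "config": {k: v for k, v in cfg.items()},
        "inputs": {
            name: _sha256(p)
            for name, p in {
                "vcf": cfg["vcf"],
                **{f"mask_{k}": v for k, v in masks_cfg.items() if v},
                **({"gff3": cfg["gff3"]} if cfg.get("gff3") else {}),
                **({"pathways": cfg["pathways"]} if cfg.get("pathways") else {}),
            }.items()
        },
        "stage_counts": stage_counts,
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("pipeline complete: %s", stage_counts)
    return summary
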