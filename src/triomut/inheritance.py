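"""Trio inheritance-state classification and de novo / MIE calling.

Each passing trio site is assigned one of three transmission states:

* **Mendelian** — the offspring genotype is explainable as one allele drawn
  from each parent;
* **MIE** (Mendelian inheritance error) — both offspring alleles are
  attributable to a single parent, which identifies the parental origin;
* **de novo** — the offspring carries at least one allele absent from both
  parental genotypes (takes precedence over MIE).

Two independent classifiers are run per site and only their intersection is
trusted for non-Mendelian calls: one uses the genotypes as called in the
VCF, the other re-genotypes every sample directly from allele read depths
(minimum coverage 10, variant-allele frequency >= 0.20, one-sided binomial
test of the read count against a per-read error rate at p <= 0.05).  When
the genotype-based classifier is non-Mendelian but the read-based one
disagrees, discordant samples are re-called once under relaxed thresholds
(frequency >= 0.05, p <= 0.15) before final adjudication — this rescues
low-frequency parental alleles that would otherwise masquerade as de novo
events in the offspring.

Retained non-Mendelian calls additionally satisfy the read-support rules:
the offspring site is covered by >= 10 reads, each of a heterozygous
offspring's two alleles by >= 5 reads (>= 10 for a homozygote), and each
parent by at least the minimum coverage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

from scipy.stats import binom

from .trio_io import Genotype, TrioSiteRecord

logger = logging.getLogger(__name__)


class State(str, Enum):
    MENDELIAN = "MENDELIAN"
    MIE = "MIE"
    DENOVO = "DENOVO"
    UNCLASSIFIED = "UNCLASSIFIED"


class Origin(str, Enum):
    MOTHER = "MOTHER"
    FATHER = "FATHER"
    UNDETERMINED = "UNDETERMINED"
    NA = "NA"


@dataclass(frozen=True)
class ReadGenotypeConfig:
    """Thresholds of the read-count re-genotyper and the retention rules."""

    min_coverage: int = 10
    min_var_freq: float = 0.20
    p_value: float = 0.05
    adj_var_freq: float = 0.05
    adj_p_value: float = 0.15
    base_error_rate: float = 0.01
    min_offspring_reads: int = 10
    min_allele_reads: int = 5

    def __post_init__(self) -> None:
        for f in (self.min_var_freq, self.adj_var_freq):
            if not 0 < f < 1:
                raise ValueError("allele frequencies must be in (0, 1)")
        for p in (self.p_value, self.adj_p_value):
            if not 0 < p < 1:
                raise ValueError("p-values must be in (0, 1)")


@dataclass(frozen=True)
class InheritanceCall:
    """Classification outcome for one site, with its read-support evidence."""

    chrom: str
    pos: int
    state: State
    origin: Origin
    method_agreement: str  # "both" | "genotype_vcf" | "reads" | "relaxed" | "none"
    offspring_allele_depths: tuple[int, ...] | None
    mother_depth: int | None
    father_depth: int | None
    offspring_depth: int | None
    retained: bool = True
    reason: str = ""

    def __post_init__(self) -> None:
        if (self.origin != Origin.NA) != (self.state == State.MIE):
            raise ValueError("origin must be NA exactly when state is not MIE")


def classify_by_genotype(
    gm: Genotype | None, gf: Genotype | None, gc: Genotype | None
) -> tuple[State, Origin]:
    """Classify a genotype trio into Mendelian / MIE / de novo.

    De novo takes precedence: any offspring allele absent from the pooled
    parental alleles makes the site de novo regardless of the rest.
    Otherwise the site is Mendelian iff some assignment of one allele from
    each parent reproduces the offspring genotype as a multiset; otherwise
    it is an MIE whose origin is the unique parent whose genotype contains
    every offspring allele (UNDETERMINED only possible at multiallelic
    sites).
    """
    if gm is None or gf is None or gc is None:
        return State.UNCLASSIFIED, Origin.NA
    mother_alleles = set(gm)
    father_alleles = set(gf)
    pooled = mother_alleles | father_alleles
    if any(a not in pooled for a in gc):
        return State.DENOVO, Origin.NA
    child = tuple(sorted(gc))
    for a in gm:
        for b in gf:
            if tuple(sorted((a, b))) == child:
                return State.MENDELIAN, Origin.NA
    child_set = set(gc)
    from_mother = child_set <= mother_alleles
    from_father = child_set <= father_alleles
    if from_mother and not from_father:
        return State.MIE, Origin.MOTHER
    if from_father and not from_mother:
        return State.MIE, Origin.FATHER
    return State.MIE, Origin.UNDETERMINED


def genotype_from_reads(
    allele_depths: Sequence[int] | None,
    cfg: ReadGenotypeConfig,
    alleles: Sequence[str] | None = None,
    relaxed: bool = False,
) -> Genotype | None:
    """Call a diploid genotype from per-allele read counts.

    An allele is present iff its read fraction reaches the frequency
    threshold AND its count is inconsistent with sequencing error alone
    (one-sided binomial tail P(X >= k | n, base_error_rate) at the p-value
    threshold).  The genotype is the two highest-frequency present alleles
    (duplicated when only one is present).  Frequency ties break toward the
    reference allele, then lexicographically by allele string (by index if
    allele strings are not supplied).  Returns ``None`` below minimum
    coverage or when no allele qualifies.
    """
    if allele_depths is None:
        return None
    total = int(sum(allele_depths))
    if total < cfg.min_coverage:
        return None
    min_freq = cfg.adj_var_freq if relaxed else cfg.min_var_freq
    max_p = cfg.adj_p_value if relaxed else cfg.p_value
    present: list[tuple[float, int, str, int]] = []
    for i, k in enumerate(allele_depths):
        if k <= 0:
            continue
        freq = k / total
        if freq < min_freq:
            continue
        p = float(binom.sf(k - 1, total, cfg.base_error_rate))
        if p > max_p:
            continue
        label = alleles[i] if alleles is not None else str(i)
        present.append((freq, i, label, k))
    if not present:
        return None
    # sort: frequency desc, reference first, then lexicographic allele
    present.sort(key=lambda t: (-t[0], t[1] != 0, t[2]))
    if len(present) == 1:
        i = present[0][1]
        return (i, i)
    a, b = present[0][1], present[1][1]
    return (min(a, b), max(a, b))


def _trio_read_genotypes(
    site: TrioSiteRecord,
    cfg: ReadGenotypeConfig,
    relax: Sequence[bool] = (False, False, False),
) -> list[Genotype | None]:
    return [
        genotype_from_reads(s.allele_depths, cfg, site.alleles, relaxed=rx)
        for s, rx in zip(site.samples, relax)
    ]


def reconcile_trio(site: TrioSiteRecord, cfg: ReadGenotypeConfig) -> InheritanceCall:
    """Run both classifiers on one site and report their intersection.

    A non-Mendelian state (MIE or de novo) is reported only when the
    VCF-genotype classifier and the read-count classifier agree on it.
    Discordant samples get one relaxed re-call before adjudication; a
    conflict that survives relaxation demotes the call to Mendelian or
    unclassified according to the re-called classification.
    """
    common = dict(
        chrom=site.chrom,
        pos=site.pos,
        offspring_allele_depths=site.offspring.allele_depths,
        mother_depth=site.mother.total_depth,
        father_depth=site.father.total_depth,
        offspring_depth=site.offspring.total_depth,
    )
    gts = [s.genotype for s in site.samples]
    if any(g is None for g in gts):
        return InheritanceCall(
            state=State.UNCLASSIFIED,
            origin=Origin.NA,
            method_agreement="none",
            reason="missing_genotype",
            **common,
        )
    if any(s.allele_depths is None for s in site.samples):
        return InheritanceCall(
            state=State.UNCLASSIFIED,
            origin=Origin.NA,
            method_agreement="none",
            reason="missing_allele_depths",
            **common,
        )

    state_a, origin_a = classify_by_genotype(*gts)
    read_gts = _trio_read_genotypes(site, cfg)
    state_b, origin_b = classify_by_genotype(*read_gts)

    if state_a in (State.MIE, State.DENOVO):
        if state_b == state_a:
            return InheritanceCall(
                state=state_a, origin=origin_a, method_agreement="both", **common
            )
        # Re-call discordant samples once with relaxed thresholds.
        relax = [rg != g for rg, g in zip(read_gts, gts)]
        relaxed_gts = [
            genotype_from_reads(s.allele_depths, cfg, site.alleles, relaxed=True)
            if rx
            else rg
            for s, rg, rx in zip(site.samples, read_gts, relax)
        ]
        state_c, origin_c = classify_by_genotype(*relaxed_gts)
        if state_c == state_a:
            return InheritanceCall(
                state=state_a, origin=origin_a, method_agreement="relaxed", **common
            )
        if state_c == State.MENDELIAN:
            return InheritanceCall(
                state=State.MENDELIAN,
                origin=Origin.NA,
                method_agreement="genotype_vcf",
                reason="read_recall_mendelian",
                **common,
            )
        return InheritanceCall(
            state=State.UNCLASSIFIED,
            origin=Origin.NA,
            method_agreement="none",
            reason="method_disagreement",
            **common,
        )
    if state_a == State.MENDELIAN:
        return InheritanceCall(
            state=State.MENDELIAN,
            origin=Origin.NA,
            method_agreement="both" if state_b == State.MENDELIAN else "genotype_vcf",
            **common,
        )
    return InheritanceCall(
        state=State.UNCLASSIFIED,
        origin=Origin.NA,
        method_agreement="none",
        reason="unclassifiable_genotypes",
        **common,
    )


def apply_support_filters(
    call: InheritanceCall, site: TrioSiteRecord, cfg: ReadGenotypeConfig
) -> bool:
    """Read-support retention decision for a non-Mendelian call.

    Retained iff the offspring's genotype alleles are supported by >= 10
    reads in total, a heterozygous offspring has >= 5 reads per allele (a
    homozygote >= 10 on its single allele), and each parent's site depth is
    at least the minimum coverage.
    """
    if call.state not in (State.MIE, State.DENOVO):
        raise ValueError("support filters apply only to MIE/DENOVO calls")
    off = site.offspring
    if off.genotype is None or off.allele_depths is None:
        return False
    a, b = off.genotype
    ad = off.allele_depths
    if a == b:
        if ad[a] < cfg.min_offspring_reads:
            return False
    else:
        if ad[a] + ad[b] < cfg.min_offspring_reads:
            return False
        if ad[a] < cfg.min_allele_reads or ad[b] < cfg.min_allele_reads:
            return False
    for parent in (site.mother, site.father):
        if parent.total_depth is None or parent.total_depth < cfg.min_coverage:
            return False
    return True


TALLY_KEYS = (
    "n_input",
    "n_sites_variant_vs_reference",
    "n_mendelian",
    "n_mie",
    "n_mie_from_mother",
    "n_mie_from_father",
    "n_mie_undetermined",
    "n_denovo",
    "n_unclassified",
)


def run_trio_classification(
    sites: Iterable[TrioSiteRecord], cfg: ReadGenotypeConfig
) -> tuple[list[InheritanceCall], dict[str, int]]:
    """Classify every (already filter-passing) site and tally the outcome.

    Non-Mendelian calls failing the read-support retention rules are kept in
    the output with ``retained=False`` but tallied as unclassified, so the
    tallies partition the input:
    ``n_mendelian + n_mie + n_denovo + n_unclassified == n_input``.
    """
    calls: list[InheritanceCall] = []
    tallies = {k: 0 for k in TALLY_KEYS}
    for site in sites:
        tallies["n_input"] += 1
        if site.is_variant():
            tallies["n_sites_variant_vs_reference"] += 1
        call = reconcile_trio(site, cfg)
        if call.state in (State.MIE, State.DENOVO):
            if not apply_support_filters(call, site, cfg):
                call = InheritanceCall(
                    chrom=call.chrom,
                    pos=call.pos,
                    state=call.state,
                    origin=call.origin,
                    method_agreement=call.method_agreement,
                    offspring_allele_depths=call.offspring_allele_depths,
                    mother_depth=call.mother_depth,
                    father_depth=call.father_depth,
                    offspring_depth=call.offspring_depth,
                    retained=False,
                    reason="support_filter",
                )
        calls.append(call)
        if call.state == State.MENDELIAN:
            tallies["n_mendelian"] += 1
        elif call.state == State.MIE and call.retained:
            tallies["n_mie"] += 1
            if call.origin == Origin.MOTHER:
                tallies["n_mie_from_mother"] += 1
            elif call.origin == Origin.FATHER:
                tallies["n_mie_from_father"] += 1
            else:
                tallies["n_mie_undetermined"] += 1
        elif call.state == State.DENOVO and call.retained:
            tallies["n_denovo"] += 1
        else:
            tallies["n_unclassified"] += 1
    logger.info("trio classification tallies: %s", tallies)
    return calls, tallies
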