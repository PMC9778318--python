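"""Per-genome and per-trio summary statistics.

Covers the standard SNP summary for one genome against the reference
(heterozygous/homozygous counts, %SNP and %heterozygosity against a callable
denominator, transition/transversion counts and their ratio) and the
trio-level mutation summary (inheritance-state tallies, the de novo rate per
callable site per generation, and floor-fold comparisons against external
reference counts such as a chimpanzee trio's MIE and de novo totals).

Reported ratios and percentages round half-even to 2 decimals.  The de novo
rate convention is per *haploid* site per generation: count divided by
callable sites, with no factor of 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_EVEN, Decimal
from fractions import Fraction
from typing import Iterable, Mapping

# round_half_even serves reports across modules
from .trio_io import ROLES, TrioSiteRecord

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")


def round_half_even(value: float | Fraction, ndigits: int = 2) -> float:
    """Banker's rounding on the exact ratio (Decimal-based, no float drift)."""
    if isinstance(value, Fraction):
        d = Decimal(value.numerator) / Decimal(value.denominator)
    else:
        d = Decimal(repr(value))
    q = Decimal(1).scaleb(-ndigits)
    return float(d.quantize(q, rounding=ROUND_HALF_EVEN))


def is_transition(ref: str, alt: str) -> bool:
    """True for A<->G and C<->T substitutions, False for transversions."""
    if ref == alt:
        raise ValueError("ref and alt must differ")
    if ref not in "ACGT" or alt not in "ACGT":
        raise ValueError(f"non-ACGT bases: {ref}>{alt}")
    pair = {ref, alt}
    return pair <= PURINES or pair <= PYRIMIDINES


@dataclass(frozen=True)
class GenomeSnpSummary:
    """Table-1-style SNP summary for one sample."""

    sample: str
    n_het: int
    n_hom: int
    n_transitions: int
    n_transversions: int
    callable_sites: int

    @property
    def n_total(self) -> int:
        return self.n_het + self.n_hom

    @property
    def pct_snp(self) -> float:
        return self.n_total / self.callable_sites * 100

    @property
    def pct_heterozygosity(self) -> float:
        return self.n_het / self.callable_sites * 100

    @property
    def titv(self) -> float | None:
        """Ti/Tv to 2 decimals (round-half-even); absent if Tv is zero."""
        if self.n_transversions == 0:
            return None
        return round_half_even(
            Fraction(self.n_transitions, self.n_transversions)
        )

    def as_dict(self) -> dict[str, object]:
        return {
            "sample": self.sample,
            "n_het": self.n_het,
            "n_hom": self.n_hom,
            "n_total": self.n_total,
            "pct_snp": self.pct_snp,
            "pct_heterozygosity": self.pct_heterozygosity,
            "n_transitions": self.n_transitions,
            "n_transversions": self.n_transversions,
            "titv": self.titv,
        }


def summarize_genome(
    records: Iterable[TrioSiteRecord],
    sample: str,
    callable_sites: int,
) -> GenomeSnpSummary:
    """Summarise one sample's SNPs over (passing, biallelic) records.

    A site counts when the sample's genotype carries a non-reference allele:
    heterozygous if the two alleles differ, homozygous otherwise.
    Transition/transversion classification uses the sample's non-reference
    allele against the reference base; het sites with two non-reference
    alleles contribute one substitution per distinct alt allele.
    """
    if callable_sites <= 0:
        raise ValueError("callable_sites must be positive")
    if sample not in ROLES:
        raise ValueError(f"sample must be one of {ROLES}")
    idx = ROLES.index(sample)
    n_het = n_hom = n_ti = n_tv = 0
    for r in records:
        g = r.samples[idx].genotype
        if g is None or not any(a != 0 for a in g):
            continue
        if g[0] != g[1]:
            n_het += 1
        else:
            n_hom += 1
        if not r.is_snp:
            continue
        for a in set(g) - {0}:
            if is_transition(r.ref_allele, r.alleles[a]):
                n_ti += 1
            else:
                n_tv += 1
    return GenomeSnpSummary(sample, n_het, n_hom, n_ti, n_tv, callable_sites)


def denovo_rate(n_denovo: int, callable_sites: int) -> float:
    """De novo SNP rate per site per generation (count / callable sites)."""
    if callable_sites <= 0:
        raise ValueError("callable_sites must be positive")
    if n_denovo < 0:
        raise ValueError("n_denovo must be non-negative")
    return n_denovo / callable_sites


def format_rate(rate: float) -> str:
    """Scientific notation with 3 significant digits, e.g. '2.21e-07'."""
    return f"{rate:.2e}"


def fold_vs_reference(n: int, reference: int) -> tuple[int, float]:
    """Floor-fold of a count over an external reference count.

    Returns ``(floor(n / reference), exact quotient)``; the floor matches
    the "almost k times" phrasing used when comparing trio mutation counts
    across species.
    """
    if reference <= 0:
        raise ValueError("reference count must be positive")
    return n // reference, n / reference


@dataclass(frozen=True)
class TrioMutationSummary:
    """Trio-level mutation statistics assembled from classification tallies."""

    n_variant_positions: int
    n_mendelian: int
    n_mie: int
    n_mie_from_mother: int
    n_mie_from_father: int
    n_mie_undetermined: int
    n_denovo: int
    callable_sites: int
    fold_vs_reference: Mapping[str, tuple[int, int, int]] = field(
        default_factory=dict
    )  # name -> (numerator, reference, floor fold)

    @property
    def denovo_rate(self) -> float:
        return denovo_rate(self.n_denovo, self.callable_sites)

    @classmethod
    def from_tallies(
        cls,
        tallies: Mapping[str, int],
        callable_sites: int,
        reference_counts: Mapping[str, tuple[str, int]] | None = None,
    ) -> "TrioMutationSummary":
        """Build from :func:`run_trio_classification` tallies.

        ``reference_counts`` maps a comparison name to
        ``(tally_key, reference_count)``, e.g.
        ``{"mie_vs_chimp": ("n_mie", 794)}``.
        """
        folds = {}
        for name, (key, ref) in (reference_counts or {}).items():
            num = int(tallies[key])
            folds[name] = (num, ref, fold_vs_reference(num, ref)[0])
        return cls(
            n_variant_positions=tallies["n_sites_variant_vs_reference"],
            n_mendelian=tallies["n_mendelian"],
            n_mie=tallies["n_mie"],
            n_mie_from_mother=tallies["n_mie_from_mother"],
            n_mie_from_father=tallies["n_mie_from_father"],
            n_mie_undetermined=tallies["n_mie_undetermined"],
            n_denovo=tallies["n_denovo"],
            callable_sites=callable_sites,
            fold_vs_reference=folds,
        )

    def as_dict(self) -> dict[str, object]:
        return {
            "n_variant_positions": self.n_variant_positions,
            "n_mendelian": self.n_mendelian,
            "n_mie": self.n_mie,
            "n_mie_from_mother": self.n_mie_from_mother,
            "n_mie_from_father": self.n_mie_from_father,
            "n_mie_undetermined": self.n_mie_undetermined,
            "n_denovo": self.n_denovo,
            "callable_sites": self.callable_sites,
            "denovo_rate": self.denovo_rate,
            "denovo_rate_str": format_rate(self.denovo_rate),
            "fold_vs_reference": {
                k: list(v) for k, v in self.fold_vs_reference.items()
            },
        }
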