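import math

import pytest

from triomut.trio_io import SampleCall, TrioSiteRecord

NOMINAL_INFO = {
    "QD": 20.0,
    "FS": 1.0,
    "MQ": 55.0,
    "MQRankSum": 0.0,
    "ReadPosRankSum": 0.0,
    "HaplotypeScore": 2.0,
}


def make_record(
    chrom="chr1",
    pos=1000,
    ref="A",
    alts=("G",),
    qual=100.0,
    info=None,
    gts=((0, 0), (0, 1), (0, 1)),
    ads=None,
    dps=None,
):
    """Build a trio site with nominal QC values unless overridden."""
    n_alleles = 1 + len(alts)
    if ads is None:
        ads = []
        for g in gts:
            ad = [0] * n_alleles
            if g is None:
                ads.append(tuple(ad))
                continue
            for a in g:
                ad[a] += 15
            ads.append(tuple(ad))
    ads = [None if ad is None else tuple(ad) for ad in ads]
    if dps is None:
        dps = [None if ad is None else sum(ad) for ad in ads]
    merged_info = dict(NOMINAL_INFO)
    if info is not None:
        for k, v in info.items():
            if v is None:
                merged_info.pop(k, None)
            else:
                merged_info[k] = v
    return TrioSiteRecord(
        chrom=chrom,
        pos=pos,
        ref_allele=ref,
        alt_alleles=tuple(alts),
        qual=qual,
        info=merged_info,
        samples=tuple(
            SampleCall(g, ad, dp) for g, ad, dp in zip(gts, ads, dps)
        ),
    )


def records_close(a: TrioSiteRecord, b: TrioSiteRecord, rel=1e-4) -> bool:
    """Field-by-field equality with float tolerance for QUAL/INFO (VCF text
    stores limited precision and readers return 32-bit floats)."""
    if (a.chrom, a.pos, a.ref_allele, a.alt_alleles) != (
        b.chrom,
        b.pos,
        b.ref_allele,
        b.alt_alleles,
    ):
        return False
    if a.samples != b.samples:
        return False
    if (a.qual is None) != (b.qual is None):
        return False
    if a.qual is not None and not math.isclose(a.qual, b.qual, rel_tol=rel):
        return False
    if set(a.info) != set(b.info):
        return False
    return all(math.isclose(a.info[k], b.info[k], rel_tol=rel) for k in a.info)


@pytest.fixture(scope="session")
def small_sim():
    """A modest simulated trio with elevated event rates, shared per session."""
    from triomut.simtrio import SimConfig, simulate_trio

    return simulate_trio(
        SimConfig(
            seed=7,
            n_sites=20_000,
            mie_injection_rate=2e-3,
            denovo_injection_rate=5e-4,
        )
    )


@pytest.fixture(scope="session")
def small_sim_dir(small_sim, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("simdata")
    paths = small_sim.write(str(outdir))
    return paths
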