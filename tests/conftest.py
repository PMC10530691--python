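import pytest

from hrdscar import ChromAnnotation, CNVSegment, GenomeBuild, SVCall, load_genome


@pytest.fixture(scope="session")
def grch38():
    return load_genome("GRCh38")


@pytest.fixture(scope="session")
def toy_genome():
    """Two mask-free chromosomes: T (200 Mb, cen 95-100 Mb), U (150 Mb, cen 40-45 Mb)."""
    return GenomeBuild("toy", (
        ChromAnnotation("T", 200_000_000, (95_000_000, 100_000_000)),
        ChromAnnotation("U", 150_000_000, (40_000_000, 45_000_000)),
    ))


@pytest.fixture(scope="session")
def masked_genome():
    """One chromosome with telomeric and centromere-flanking masks."""
    return GenomeBuild("toy-masked", (
        ChromAnnotation(
            "M", 200_000_000, (95_000_000, 100_000_000),
            masked_regions=(
                (1, 2_000_000),                    # p-telomeric
                (10_000_000, 12_000_000),          # interior, not telomere-contiguous
                (94_500_000, 94_900_000),          # abuts centromere (left)
                (100_050_000, 101_000_000),        # near centromere (right, 49 999 bp gap)
                (198_000_000, 200_000_000),        # q-telomeric
            ),
        ),
    ))


def make_sv(id="sv1", chrom_a="T", pos_a=110_000_000, chrom_b="U", pos_b=60_000_000,
            sv_type="translocation", size=0, confidence=0.5, molecule_support=10,
            control_frequency=0.0):
    return SVCall(id=id, chrom_a=chrom_a, pos_a=pos_a, chrom_b=chrom_b, pos_b=pos_b,
                  sv_type=sv_type, size=size, confidence=confidence,
                  molecule_support=molecule_support, control_frequency=control_frequency)


def make_cnv(chrom="T", start=110_000_000, length=16_000_000, state="loss",
             confidence=0.995, id="cnv1"):
    return CNVSegment(chrom=chrom, start=start, end=start + length - 1, state=state,
                      confidence=confidence, id=id)
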