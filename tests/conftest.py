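import pytest

from dmgraph.records import Amplicon, Breakend, SVCall


@pytest.fixture
def triangle_amplicons():
    """Three well-separated amplicons on one chromosome, uniform coverage."""
    return [
        Amplicon(0, "chr1", 100_000, 150_000, 30.0),
        Amplicon(1, "chr1", 300_000, 360_000, 31.0),
        Amplicon(2, "chr1", 500_000, 540_000, 29.0),
    ]


def link(a: Amplicon, b: Amplicon, svtype: str = "DEL") -> SVCall:
    """An SV call joining the end of ``a`` to the start of ``b`` exactly."""
    return SVCall.make(
        Breakend(a.chrom, a.end - 1), Breakend(b.chrom, b.start), svtype
    )


@pytest.fixture
def triangle_svcalls(triangle_amplicons):
    a, b, c = triangle_amplicons
    return [link(a, b), link(b, c), link(a, c, "ITX")]
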