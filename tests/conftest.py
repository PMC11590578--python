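import pytest

from lncscape.annotation import GenomicInterval, TranscriptModel, TranscriptomeAnnotation
from lncscape.simulate import SimulationConfig, generate


def make_transcript(
    tid,
    exons,
    strand="+",
    chrom="Chr1",
    biotype="other",
    cds=None,
    gene=None,
):
    """Build a TranscriptModel from (start, end) exon pairs."""
    return TranscriptModel(
        transcript_id=tid,
        gene_id=gene or tid.rsplit(".", 1)[0],
        chrom=chrom,
        strand=strand,
        exons=tuple(GenomicInterval(chrom, s, e, strand) for s, e in exons),
        biotype=biotype,
        cds=GenomicInterval(chrom, cds[0], cds[1], strand) if cds else None,
    )


def make_annotation(transcripts, source="reference"):
    return TranscriptomeAnnotation.from_transcripts(transcripts, source=source)


@pytest.fixture(scope="session")
def default_bundle(tmp_path_factory):
    """One default synthetic bundle shared across test modules."""
    out = tmp_path_factory.mktemp("bundle")
    return generate(SimulationConfig(seed=11), out)
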