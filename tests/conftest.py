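import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from asflow.genome import Exon, GeneModel, GenomeAnnotation, Transcript


def make_transcript(tid, gene_id, intervals, chrom="chr1", strand="+"):
    return Transcript(tid, gene_id, [Exon(chrom, s, e, strand) for s, e in intervals])


def make_gene(gene_id, transcript_intervals, chrom="chr1", strand="+"):
    transcripts = [
        make_transcript(f"{gene_id}.t{i + 1}", gene_id, ivs, chrom, strand)
        for i, ivs in enumerate(transcript_intervals)
    ]
    return GeneModel(gene_id, chrom, strand, transcripts)


@pytest.fixture
def cassette_gene():
    """Two transcripts differing by one cassette exon."""
    return make_gene(
        "gSE", [[(100, 300), (400, 600), (700, 900)], [(100, 300), (700, 900)]]
    )


@pytest.fixture
def single_transcript_annotation():
    gene = make_gene("gPlain", [[(100, 250), (400, 550)]])
    return GenomeAnnotation({"gPlain": gene})
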