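import pytest

from tascreen import reference_db as rdb
from tascreen.pairing import GeneFeature


@pytest.fixture(scope="session")
def demo_records():
    return rdb.load_reference_fasta(rdb.bundled_reference_path())


@pytest.fixture(scope="session")
def demo_clusters(demo_records):
    return rdb.cluster_references(demo_records)


@pytest.fixture
def make_gene():
    def _make(gene_id, start, end, strand="+", contig="chr", protein=""):
        return GeneFeature(gene_id=gene_id, contig=contig, start=start, end=end,
                           strand=strand, protein=protein)

    return _make


def write_fasta(path, entries, eol="\n", width=None):
    """Minimal FASTA writer for fixture files."""
    chunks = []
    for header, seq in entries:
        chunks.append(f">{header}{eol}")
        if width:
            for i in range(0, len(seq), width):
                chunks.append(seq[i:i + width] + eol)
        else:
            chunks.append(seq + eol)
    path.write_text("".join(chunks), newline="")
    return path
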