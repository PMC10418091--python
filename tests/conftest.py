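import numpy as np
import pytest

from mgcscan.genome import Contig, GeneFeature, GenomeAnnotation


def F(fid, start, end, strand="+", contig="c1", protein=None, ftype="CDS",
      product=""):
    """Shorthand GeneFeature constructor for hand-built genomes."""
    return GeneFeature(
        feature_id=fid, contig_id=contig, start=start, end=end, strand=strand,
        protein_seq=protein, feature_type=ftype, product=product,
    )


def make_genome(features, genome_id="test", contig="c1", length=None):
    feats = sorted(features, key=lambda f: (f.start, f.end, f.feature_id))
    if length is None:
        length = max((f.end for f in feats), default=0) + 1000
    g = GenomeAnnotation(
        genome_id=genome_id,
        contigs={contig: Contig(contig_id=contig, length=length, features=feats)},
    )
    g.validate()
    return g


@pytest.fixture(scope="session")
def seed_sets():
    from mgcscan.synthetic import seed_sets

    return seed_sets()


@pytest.fixture(scope="session")
def seeds():
    from mgcscan.synthetic import seed_proteins

    return seed_proteins()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
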