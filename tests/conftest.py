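import numpy as np
import pytest

from crypticscan import GeneModel, GeneSet, RatioTrack, StrandSignal


@pytest.fixture
def chrom_sizes():
    return {"chrI": 10_000, "chrII": 8_000}


@pytest.fixture
def small_genes(chrom_sizes):
    genes = [
        GeneModel("geneA", "chrI", 1000, 2000, "+", biotype="coding", promoter_class="TATA"),
        GeneModel("geneB", "chrI", 3000, 4500, "-", biotype="coding", promoter_class="TATA-like"),
        GeneModel("sut1", "chrI", 5000, 5400, "+", biotype="SUT"),
        GeneModel("cut1", "chrII", 1000, 1300, "-", biotype="CUT"),
        GeneModel("dub1", "chrI", 2010, 2200, "+", biotype="dubious_orf"),
    ]
    return GeneSet(genes=genes, chrom_sizes=chrom_sizes)


def constant_signal(chrom_sizes, value, sample_id="s", replicate=1):
    return StrandSignal(
        data={c: {"+": np.full(n, float(value)), "-": np.full(n, float(value))} for c, n in chrom_sizes.items()},
        sample_id=sample_id,
        replicate=replicate,
    )


def constant_ratio(chrom_sizes, value=1.0, pseudocount=0.01):
    return RatioTrack(
        data={c: {"+": np.full(n, float(value)), "-": np.full(n, float(value))} for c, n in chrom_sizes.items()},
        pseudocount=pseudocount,
    )
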