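import numpy as np
import pytest

from lactotrail.io import HaplotypeMatrix, PopMap


TOY_VCF = """\
##fileformat=VCFv4.2
##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##contig=<ID=chr1>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2
chr1\t100\t.\tA\tG\t.\tPASS\tAA=A\tGT\t0|1\t0|0
chr1\t200\t.\tC\tT\t.\tPASS\tAA=T\tGT\t1|1\t0|1
chr1\t300\t.\tG\tA,T\t.\tPASS\t.\tGT\t1|2\t0|0
chr1\t400\t.\tT\tC\t.\tPASS\tAA=T\tGT\t0|0\t1|0
chr1\t500\t.\tG\tC\t.\tPASS\tAA=G\tGT\t1|0\t0|1
"""


@pytest.fixture
def toy_vcf(tmp_path):
    path = tmp_path / "toy.vcf"
    path.write_text(TOY_VCF)
    return str(path)


@pytest.fixture
def toy_popmap():
    return PopMap({"S1": "POPA", "S2": "POPB"})


def make_hm(H, positions=None, pops=None, chrom="chr1", polarized=True):
    """Small HaplotypeMatrix from a list-of-lists; pops maps sample->pop."""
    H = np.asarray(H, dtype=np.int8)
    n_samples = H.shape[0] // 2
    if positions is None:
        positions = np.arange(1, H.shape[1] + 1) * 100
    ids = [f"S{i}" for i in range(n_samples)]
    if pops is None:
        pop_of = {s: "POP" for s in ids}
    elif isinstance(pops, dict):
        pop_of = pops
        if set(ids) != set(pops):
            if len(pops) != n_samples:
                raise ValueError("pops dict must have one entry per sample")
            ids = list(pops)
    else:
        pop_of = {s: p for s, p in zip(ids, pops)}
    return HaplotypeMatrix(chrom=chrom, positions=np.asarray(positions),
                           H=H, sample_ids=ids, pop_of=pop_of,
                           polarized=polarized)


@pytest.fixture
def make_matrix():
    return make_hm
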