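import numpy as np
import pytest

from introscan.genotype_io import (GenotypeTable, PopulationMap,
                                   polarize_by_outgroup)


def make_table(genotypes, samples=None, chrom="chr1", positions=None,
               **kw):
    """GenotypeTable from a (sites x samples) list/array of codes."""
    g = np.asarray(genotypes, dtype=np.int8)
    n_sites, n_samples = g.shape
    if samples is None:
        samples = [f"s{j}" for j in range(n_samples)]
    pos = np.asarray(positions if positions is not None
                     else np.arange(n_sites) * 10, dtype=np.int64)
    return GenotypeTable(np.full(n_sites, chrom, object), pos,
                         np.full(n_sites, "A", object),
                         np.full(n_sites, "C", object), g, list(samples))


def freqs_from_matrix(pop_sizes, genotypes, positions=None, chrom="chr1",
                      outgroup="OUT"):
    """FrequencyTable from genotype codes with an appended fixed-ancestral
    outgroup sample; pop_sizes maps label -> n diploids, in column order."""
    g = np.asarray(genotypes, dtype=np.int8)
    og = np.zeros((g.shape[0], 1), dtype=np.int8)
    g = np.hstack([g, og])
    samples, assign = [], {}
    j = 0
    for label, n in pop_sizes.items():
        for _ in range(n):
            name = f"{label}_{j}"
            samples.append(name)
            assign[name] = label
            j += 1
    samples.append("og_1")
    assign["og_1"] = outgroup
    gt = make_table(g, samples=samples, positions=positions, chrom=chrom)
    return polarize_by_outgroup(gt, PopulationMap(assign, outgroup))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_vcf(tmp_path):
    """3-record VCF: one multiallelic site, one ./. genotype."""
    text = """##fileformat=VCFv4.2
##contig=<ID=chr1,length=1000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ta\tb\tc
chr1\t100\t.\tA\tC\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1
chr1\t200\t.\tG\tA,T\t.\tPASS\t.\tGT\t0/0\t0/1\t2/2
chr1\t300\t.\tT\tG\t.\tPASS\t.\tGT\t./.\t0/0\t0/1
"""
    p = tmp_path / "toy.vcf"
    p.write_text(text)
    return p
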