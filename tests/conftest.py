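import numpy as np
import pytest

import transgwas as tg


@pytest.fixture(scope="session")
def table2():
    return tg.load_table2()


@pytest.fixture(scope="session")
def index_snps():
    return tg.table2_index_snps()


@pytest.fixture(scope="session")
def cohort_records():
    return tg.table2_cohort_records()


@pytest.fixture(scope="session")
def meta_results():
    return tg.table2_meta_results()


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def write_vcf(path, positions, alleles, genotypes):
    """Write a minimal phased VCF: genotypes is sites x samples list of 'a|b'."""
    lines = [
        "##fileformat=VCFv4.2",
        "##contig=<ID=1>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    n_samples = len(genotypes[0])
    header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
    header += [f"S{i + 1}" for i in range(n_samples)]
    lines.append("\t".join(header))
    for pos, (ref, alt), gts in zip(positions, alleles, genotypes):
        row = ["1", str(pos), f"var{pos}", ref, alt, ".", ".", ".", "GT"] + list(gts)
        lines.append("\t".join(row))
    path.write_text("\n".join(lines) + "\n")
    return path
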