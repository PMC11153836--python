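from __future__ import annotations

import pytest

from ismkit.predictor import ToyCGPredictor
from ismkit.reference_genome import ArmTable, load_fasta, make_toy_genome

try:  # derandomize hypothesis when available
    from hypothesis import settings

    settings.register_profile("ci", derandomize=True, max_examples=50)
    settings.load_profile("ci")
except ImportError:
    pass


VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=END,Number=1,Type=Integer,Description="End position">
##INFO=<ID=SVLEN,Number=.,Type=Integer,Description="SV length">
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">
##INFO=<ID=MATEID,Number=.,Type=String,Description="Mate breakend id">
##contig=<ID=chrA,length=10000>
##contig=<ID=chrB,length=6000>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


@pytest.fixture(scope="session")
def toy_genome_path(tmp_path_factory):
    out = tmp_path_factory.mktemp("genome") / "toy.fa"
    return make_toy_genome({"chrA": 10000, "chrB": 6000}, seed=11, out_path=out)


@pytest.fixture(scope="session")
def genome(toy_genome_path):
    return load_fasta(toy_genome_path)


@pytest.fixture(scope="session")
def arms(genome):
    return ArmTable.whole_chromosomes(genome)


@pytest.fixture(scope="session")
def predictor():
    # 384 bp windows, 32 bp bins, 1 bin cropped per edge -> 10x10 maps
    return ToyCGPredictor(384, 32, 1)


def write_six_variant_vcf(genome, out_path):
    """One variant of each supported kind, all under the default limit for
    seq_len=384: SNP, 2-bp deletion indel, 100 bp DEL, 80 bp DUP, 100 bp
    INV, and one breakend mate pair."""
    b = lambda c, p: genome.fetch(c, p, p + 1)
    alt_of = lambda r: "A" if r != "A" else "G"
    rows = [
        f"chrA\t501\tsnp1\t{b('chrA', 500)}\t{alt_of(b('chrA', 500))}\t.\tPASS\t.",
        f"chrA\t601\tind1\t{genome.fetch('chrA', 600, 603)}\t{b('chrA', 600)}\t.\tPASS\t.",
        f"chrA\t1001\tdel1\t{b('chrA', 1000)}\t<DEL>\t.\tPASS\tSVTYPE=DEL;END=1100",
        f"chrA\t2001\tdup1\t{b('chrA', 2000)}\t<DUP:TANDEM>\t.\tPASS\tSVTYPE=DUP;END=2080",
        f"chrA\t3001\tinv1\t{b('chrA', 3000)}\t<INV>\t.\tPASS\tSVTYPE=INV;END=3100",
        f"chrA\t4001\tbndU\t{b('chrA', 4000)}\t{b('chrA', 4000)}[chrB:2001[\t.\tPASS\tSVTYPE=BND;MATEID=bndV",
        f"chrB\t2001\tbndV\t{b('chrB', 2000)}\t]chrA:4001]{b('chrB', 2000)}\t.\tPASS\tSVTYPE=BND;MATEID=bndU",
    ]
    out_path.write_text(VCF_HEADER + "\n".join(rows) + "\n")
    return out_path


@pytest.fixture(scope="session")
def six_variant_vcf(genome, tmp_path_factory):
    out = tmp_path_factory.mktemp("vcf") / "six.vcf"
    return write_six_variant_vcf(genome, out)
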