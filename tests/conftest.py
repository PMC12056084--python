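import numpy as np
import pandas as pd
import pytest

from trihybrid import MISSING, GenotypeMatrix, PopMap

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    "##contig=<ID=chr1>\n"
)


def write_vcf_text(path, sample_names, records):
    """Write a VCF from (chrom, pos, ref, alt, [gt strings]) tuples."""
    with open(path, "w") as fh:
        fh.write(VCF_HEADER)
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_names) + "\n"
        )
        for chrom, pos, ref, alt, gts in records:
            fh.write(
                f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts) + "\n"
            )


@pytest.fixture
def toy_vcf(tmp_path):
    """4 records: one triallelic, one with mixed phasing, one half-missing."""
    path = tmp_path / "toy.vcf"
    write_vcf_text(
        path,
        ["s1", "s2", "s3"],
        [
            ("chr1", 100, "A", "T", ["0/0", "0|1", "1/1"]),
            ("chr1", 200, "G", "C,T", ["0/0", "0/1", "0/2"]),  # triallelic: dropped
            ("chr1", 300, "C", "G", ["0|1", "1/0", "./1"]),    # half-missing -> MISSING
            ("chr1", 400, "T", "A", ["./.", ".|.", "1/1"]),
        ],
    )
    return str(path)


@pytest.fixture
def toy_popmap(tmp_path):
    path = tmp_path / "pops.txt"
    path.write_text("s1\tA\ns2\tB\ns3\tC\n")
    return str(path)


def matrix_from_rows(rows, individual_ids=None):
    """GenotypeMatrix from a list of per-individual genotype rows."""
    geno = np.array(rows, dtype=np.int8)
    n_ind, n_sites = geno.shape
    ids = individual_ids or [f"i{k}" for k in range(n_ind)]
    sites = pd.DataFrame(
        {
            "chrom": "chr1",
            "pos": np.arange(1, n_sites + 1),
            "ref": "A",
            "alt": "T",
        }
    )
    return GenotypeMatrix(individual_ids=ids, sites=sites, genotypes=geno)


@pytest.fixture
def delta_matrix():
    """3 parental individuals per pool; sites with delta = 1, 0.8, 0.5, 0.1, 0.

    Alt-allele counts are chosen so pooled frequencies are exact:
      site0: P1 freq 0/6, P2 freq 6/6      -> delta 1.0 (fixed difference)
      site1: P1 freq 0.1? not representable with 6 copies; use 5 individuals.
    """
    # 5 individuals per pool -> 10 allele copies, frequencies in tenths
    p1_geno = np.array(
        [
            # sites:  d=1.0 d=0.8 d=0.5 d=0.1 d=0.0
            [0, 0, 0, 0, 1],
            [0, 0, 0, 0, 1],
            [0, 0, 1, 1, 1],
            [0, 1, 2, 1, 0],
            [0, 0, 2, 1, 0],
        ]
    )  # P1 alt freqs: 0.0, 0.1, 0.5, 0.3, 0.3
    p2_geno = np.array(
        [
            [2, 2, 2, 1, 1],
            [2, 2, 2, 1, 1],
            [2, 2, 2, 1, 1],
            [2, 2, 2, 1, 0],
            [2, 1, 2, 0, 0],
        ]
    )  # P2 alt freqs: 1.0, 0.9, 1.0, 0.4, 0.3
    G = matrix_from_rows(
        np.vstack([p1_geno, p2_geno]),
        [f"a{k}" for k in range(5)] + [f"b{k}" for k in range(5)],
    )
    pm = PopMap(
        assignments={f"a{k}": "A" for k in range(5)}
        | {f"b{k}": "B" for k in range(5)},
        p1_label="A",
        p2_label="B",
    )
    return G, pm
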