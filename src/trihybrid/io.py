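"""Input/output: VCF genotypes, population maps, and results tables.

The central container is :class:`GenotypeMatrix`, an individuals x sites
array of alt-allele copy counts (0, 1, 2) with an explicit missing state
(:data:`MISSING`).  Only diploid biallelic SNPs are represented; everything
else is filtered out on read.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .errors import EmptyResultError, InputError, PopmapError

#: Sentinel for a missing diploid genotype (includes half-missing calls).
MISSING: int = -1

_NUCLEOTIDES = frozenset("ACGT")

SITE_COLUMNS = ("chrom", "pos", "ref", "alt")


@dataclass
class GenotypeMatrix:
    """Biallelic SNP genotypes for a set of individuals.

    Parameters
    ----------
    individual_ids
        Ordered, unique sample identifiers (rows of ``genotypes``).
    sites
        DataFrame with columns ``chrom, pos, ref, alt`` (one row per site,
        1-based VCF positions), unique by ``(chrom, pos)``.
    genotypes
        ``(n_individuals, n_sites)`` int8 array of alt-allele copy counts in
        ``{0, 1, 2}`` or :data:`MISSING`.
    """

    individual_ids: list[str]
    sites: pd.DataFrame
    genotypes: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.individual_ids = list(self.individual_ids)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if len(set(self.individual_ids)) != len(self.individual_ids):
            raise InputError("duplicate individual ids in genotype matrix")
        if list(self.sites.columns[:4]) != list(SITE_COLUMNS):
            raise InputError(f"site table must have columns {SITE_COLUMNS}")
        if self.sites.duplicated(subset=["chrom", "pos"]).any():
            raise InputError("duplicate (chrom, pos) in site table")
        if self.genotypes.shape != (len(self.individual_ids), len(self.sites)):
            raise InputError("genotype array shape does not match ids/sites")
        bad = ~np.isin(self.genotypes, (MISSING, 0, 1, 2))
        if bad.any():
            raise InputError("genotype values must be in {0, 1, 2, MISSING}")

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def individual_index(self, individual: str) -> int:
        try:
            return self.individual_ids.index(individual)
        except ValueError:
            raise KeyError(f"unknown individual {individual!r}") from None

    def take_sites(self, index: np.ndarray) -> "GenotypeMatrix":
        """Return a copy restricted to the given site positions (by index)."""
        return GenotypeMatrix(
            individual_ids=list(self.individual_ids),
            sites=self.sites.iloc[index].reset_index(drop=True),
            genotypes=self.genotypes[:, index].copy(),
        )


@dataclass
class PopMap:
    """Individual -> population assignment with two designated parental labels."""

    assignments: dict[str, str]
    p1_label: str
    p2_label: str

    def __post_init__(self) -> None:
        if self.p1_label == self.p2_label:
            raise PopmapError("p1 and p2 labels must differ")
        labels = set(self.assignments.values())
        for lab in (self.p1_label, self.p2_label):
            if lab not in labels:
                raise PopmapError(
                    f"parental label {lab!r} not found; available labels: "
                    f"{sorted(labels)}"
                )

    def population(self, individual: str) -> str:
        return self.assignments[individual]

    def individuals(self, label: str) -> list[str]:
        """Individuals carrying ``label``, in insertion order."""
        return [i for i, lab in self.assignments.items() if lab == label]

    @property
    def p1_individuals(self) -> list[str]:
        return self.individuals(self.p1_label)

    @property
    def p2_individuals(self) -> list[str]:
        return self.individuals(self.p2_label)

    def validate_against(self, G: GenotypeMatrix) -> None:
        """Check consistency with a genotype matrix.

        Individuals present in the popmap but absent from the matrix are
        tolerated with a warning (they may simply not have been genotyped);
        a genotyped individual missing from the popmap is an error because
        every individual needs a population for reporting.
        """
        geno_ids = set(G.individual_ids)
        extra = [i for i in self.assignments if i not in geno_ids]
        if extra:
            warnings.warn(
                f"{len(extra)} popmap individuals absent from genotypes "
                f"(e.g. {extra[:3]}); retained for reporting only",
                stacklevel=2,
            )
        unassigned = [i for i in G.individual_ids if i not in self.assignments]
        if unassigned:
            raise PopmapError(
                f"{len(unassigned)} genotyped individuals missing from popmap "
                f"(e.g. {unassigned[:3]})"
            )


def _decode_genotype(call) -> int:
    """Decode one cyvcf2 genotype (allele indices + phase flag) to a count.

    Any missing allele (half-missing included) yields MISSING; phasing is
    ignored, so 0|1 and 1/0 both decode to 1.
    """
    alleles = call[:-1]
    if len(alleles) != 2 or any(a < 0 for a in alleles):
        return MISSING
    return int(alleles[0] + alleles[1])


def read_vcf(path: str, completeness_min: float = 0.0) -> GenotypeMatrix:
    """Read biallelic SNP genotypes from a VCF file.

    Sites that are not biallelic SNPs (multiallelic, indels, spanning
    deletions) are dropped.  GT values are decoded to alt-allele counts
    regardless of phasing; any fully or half missing call becomes
    :data:`MISSING`.  Sites whose fraction of non-missing genotypes is below
    ``completeness_min`` are dropped.

    Raises
    ------
    InputError
        If the file cannot be read.
    EmptyResultError
        If no site survives the filters.
    """
    if not 0.0 <= completeness_min <= 1.0:
        raise InputError("completeness_min must be in [0, 1]")
    try:
        vcf = VCF(path)
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception
        raise InputError(f"cannot read VCF {path!r}: {exc}") from exc

    individual_ids = list(vcf.samples)
    rows: list[tuple] = []
    geno_rows: list[list[int]] = []
    n_total = 0
    for variant in vcf:
        n_total += 1
        if len(variant.ALT) != 1:
            continue
        ref, alt = variant.REF, variant.ALT[0]
        if ref not in _NUCLEOTIDES or alt not in _NUCLEOTIDES:
            continue
        rows.append((variant.CHROM, variant.POS, ref, alt))
        geno_rows.append([_decode_genotype(c) for c in variant.genotypes])
    vcf.close()

    if not rows:
        raise EmptyResultError(
            f"no biallelic SNPs in {path!r} ({n_total} records read); "
            "filter responsible: biallelic-SNP"
        )
    sites = pd.DataFrame(rows, columns=list(SITE_COLUMNS))
    genotypes = np.array(geno_rows, dtype=np.int8).T  # individuals x sites

    called = (genotypes != MISSING).mean(axis=0)
    keep = called >= completeness_min
    if not keep.any():
        raise EmptyResultError(
            f"all {len(sites)} biallelic SNPs dropped; filter responsible: "
            f"completeness >= {completeness_min}"
        )
    return GenotypeMatrix(
        individual_ids=individual_ids,
        sites=sites.loc[keep].reset_index(drop=True),
        genotypes=genotypes[:, keep],
    )


_GT_STRING = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(G: GenotypeMatrix, path: str) -> None:
    """Serialize a GenotypeMatrix as a minimal VCF 4.2 file (GT field only)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(G.sites["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(G.individual_ids)
            + "\n"
        )
        for j, site in enumerate(G.sites.itertuples(index=False)):
            gts = "\t".join(_GT_STRING[int(g)] for g in G.genotypes[:, j])
            fh.write(
                f"{site.chrom}\t{site.pos}\t.\t{site.ref}\t{site.alt}"
                f"\t.\t.\t.\tGT\t{gts}\n"
            )


def read_popmap(
    path: str,
    p1_label: str,
    p2_label: str,
    individuals: list[str] | None = None,
) -> PopMap:
    """Read a two-column (id, population) whitespace-delimited popmap.

    ``individuals``, when given (usually the VCF sample list), is
    cross-checked: genotyped individuals absent from the popmap are an error,
    popmap-only individuals a warning.
    """
    assignments: dict[str, str] = {}
    try:
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                if not line.strip() or line.lstrip().startswith("#"):
                    continue
                fields = line.split()
                if len(fields) != 2:
                    raise PopmapError(
                        f"{path}:{lineno}: expected 2 columns, got {len(fields)}"
                    )
                ind, pop = fields
                if ind in assignments:
                    raise PopmapError(f"{path}:{lineno}: duplicate individual {ind!r}")
                assignments[ind] = pop
    except OSError as exc:
        raise InputError(f"cannot read popmap {path!r}: {exc}") from exc
    if not assignments:
        raise PopmapError(f"popmap {path!r} is empty")
    pm = PopMap(assignments=assignments, p1_label=p1_label, p2_label=p2_label)
    if individuals is not None:
        pm.validate_against(
            GenotypeMatrix(
                individual_ids=list(individuals),
                sites=pd.DataFrame(columns=list(SITE_COLUMNS)),
                genotypes=np.empty((len(individuals), 0), dtype=np.int8),
            )
        )
    return pm


def write_popmap(pm: PopMap, path: str) -> None:
    with open(path, "w") as fh:
        for ind, pop in pm.assignments.items():
            fh.write(f"{ind}\t{pop}\n")


TRIANGLE_COLUMNS = ("id", "pop", "hybrid_index", "heterozygosity", "perc_missing")


def write_triangle_table(table: pd.DataFrame, path: str) -> None:
    """Write a triangle table as TSV with a fixed header; NaN serialized as NA."""
    if table.empty:
        raise InputError("refusing to write an empty triangle table")
    table.loc[:, list(TRIANGLE_COLUMNS)].to_csv(
        path, sep="\t", index=False, na_rep="NA", float_format="%.17g"
    )


def read_triangle_table(path: str) -> pd.DataFrame:
    table = pd.read_csv(
        path,
        sep="\t",
        na_values=["NA"],
        dtype={"id": str, "pop": str,
               "hybrid_index": float, "heterozygosity": float,
               "perc_missing": float},
        float_precision="round_trip",
    )
    missing = set(TRIANGLE_COLUMNS) - set(table.columns)
    if missing:
        raise InputError(f"triangle table {path!r} lacks columns {sorted(missing)}")
    return table
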