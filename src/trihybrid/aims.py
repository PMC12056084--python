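"""Ancestry-informative marker (AIM) selection.

An AIM is a biallelic SNP whose allele-frequency difference (delta) between
the two designated parental populations reaches a threshold; delta = 1 is a
fixed difference.  Selected sites are polarized so that allele counts can be
read as dosage of the P2-associated allele.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EmptyResultError, ParameterError, PopmapError
from .io import MISSING, GenotypeMatrix, PopMap

#: Tolerance for threshold comparison, so fixed differences survive rounding.
DELTA_TOL = 1e-12


@dataclass
class SiteFrequencies:
    """Per-site alt-allele frequency in one population.

    ``freq`` is NaN wherever fewer than ``min_alleles`` non-missing allele
    copies were available; ``n_alleles`` counts the copies used.
    """

    freq: np.ndarray
    n_alleles: np.ndarray


def allele_frequencies(
    G: GenotypeMatrix, pop_individuals: list[str], min_alleles: int = 2
) -> SiteFrequencies:
    """Alt-allele frequencies over the non-missing genotypes of a population.

    frequency = (sum of alt copies) / (2 x number of non-missing genotypes).
    """
    if not pop_individuals:
        raise PopmapError("population has no individuals")
    if min_alleles < 1:
        raise ParameterError("min_alleles must be >= 1")
    rows = [G.individual_index(i) for i in pop_individuals]
    geno = G.genotypes[rows, :]
    called = geno != MISSING
    n_alleles = 2 * called.sum(axis=0)
    alt_copies = np.where(called, geno, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n_alleles >= min_alleles, alt_copies / n_alleles, np.nan)
    return SiteFrequencies(freq=freq, n_alleles=n_alleles)


def allele_freq_diff(f1: SiteFrequencies, f2: SiteFrequencies) -> np.ndarray:
    """Per-site delta = |freq_P1 - freq_P2|; NaN where either is undefined."""
    if f1.freq.shape != f2.freq.shape:
        raise ParameterError(
            f"site-set mismatch: {f1.freq.shape} vs {f2.freq.shape}"
        )
    return np.abs(f1.freq - f2.freq)


@dataclass
class AimSet:
    """The AIM subset of a genotype matrix.

    ``sites`` carries per-site ``freq_p1``, ``freq_p2``, ``delta`` and
    ``p2_allele`` ("ref" or "alt": the allele with the strictly higher P2
    frequency) next to the usual coordinates.  ``genotypes`` keeps the
    original alt-allele dosage for every individual at the retained sites;
    :attr:`p2_dosage` recodes it as copies of the P2 allele.
    """

    individual_ids: list[str]
    sites: pd.DataFrame
    genotypes: np.ndarray = field(repr=False)
    threshold: float = 1.0

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def p2_dosage(self) -> np.ndarray:
        """Genotypes recoded as P2-allele copy counts (MISSING preserved)."""
        alt_is_p2 = (self.sites["p2_allele"] == "alt").to_numpy()
        dosage = np.where(alt_is_p2[None, :], self.genotypes, 2 - self.genotypes)
        return np.where(self.genotypes == MISSING, MISSING, dosage).astype(np.int8)

    def individual_index(self, individual: str) -> int:
        try:
            return self.individual_ids.index(individual)
        except ValueError:
            raise KeyError(f"unknown individual {individual!r}") from None

    def with_genotypes(self, G: GenotypeMatrix) -> "AimSet":
        """Same AIM sites and polarization, genotypes taken from ``G``.

        Used to score individuals at reduced depth while keeping the AIM set
        identified from the full-depth parental sample.  ``G`` must contain
        the AIM sites (matched by chrom/pos).
        """
        key = pd.MultiIndex.from_frame(G.sites[["chrom", "pos"]])
        want = pd.MultiIndex.from_frame(self.sites[["chrom", "pos"]])
        idx = key.get_indexer(want)
        if (idx < 0).any():
            raise ParameterError("genotype matrix lacks some AIM sites")
        return AimSet(
            individual_ids=list(G.individual_ids),
            sites=self.sites.reset_index(drop=True),
            genotypes=G.genotypes[:, idx].copy(),
            threshold=self.threshold,
        )


def select_aims(
    G: GenotypeMatrix,
    pm: PopMap,
    threshold: float = 1.0,
    min_alleles: int = 2,
) -> AimSet:
    """Select sites with delta >= threshold and polarize them by P2.

    The comparison is inclusive (with a 1e-12 tolerance) so that
    ``threshold=1`` retains exactly the fixed differences.  AIM sets are
    nested across thresholds: a site kept at a high threshold is kept at any
    lower one.

    Raises
    ------
    ParameterError
        threshold outside (0, 1].
    EmptyResultError
        no site reaches the threshold (try lowering it).
    """
    if not 0.0 < threshold <= 1.0:
        raise ParameterError("threshold must be in (0, 1]")
    f1 = allele_frequencies(G, pm.p1_individuals, min_alleles=min_alleles)
    f2 = allele_frequencies(G, pm.p2_individuals, min_alleles=min_alleles)
    delta = allele_freq_diff(f1, f2)
    keep = np.flatnonzero(~np.isnan(delta) & (delta >= threshold - DELTA_TOL))
    if keep.size == 0:
        raise EmptyResultError(
            f"no AIMs at delta >= {threshold}; maximum defined delta is "
            f"{np.nanmax(delta) if np.isfinite(delta).any() else float('nan'):.4g}; "
            "consider a lower threshold"
        )
    sites = G.sites.iloc[keep].reset_index(drop=True)
    sites["freq_p1"] = f1.freq[keep]
    sites["freq_p2"] = f2.freq[keep]
    sites["delta"] = delta[keep]
    # delta >= threshold > 0 makes the P2-majority allele strictly defined.
    sites["p2_allele"] = np.where(
        f2.freq[keep] > f1.freq[keep], "alt", "ref"
    )
    return AimSet(
        individual_ids=list(G.individual_ids),
        sites=sites,
        genotypes=G.genotypes[:, keep].copy(),
        threshold=threshold,
    )


def write_aim_sites(aims: AimSet, path: str) -> None:
    """Per-site TSV: chrom, pos, freq_p1, freq_p2, delta, p2_allele."""
    cols = ["chrom", "pos", "freq_p1", "freq_p2", "delta", "p2_allele"]
    aims.sites.loc[:, cols].to_csv(path, sep="\t", index=False, float_format="%.17g")
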