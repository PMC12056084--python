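"""Hardy-Weinberg theory for triangle plots.

On AIMs that are fixed differences, an individual's hybrid index equals the
genome-wide frequency of the P1-associated allele in its genome, and its
interclass heterozygosity equals the genome-wide frequency of the
heterozygous genotype.  Crossing two individuals whose genome-wide allele
frequencies differ inflates offspring heterozygosity above the
random-mating expectation — the inverse of the Wahlund effect.  With parental
allele frequencies ``hA`` and ``hB``, mean ``m`` and between-parent variance

    sigma2 = ((hA - m)^2 + (hB - m)^2) / 2,

the expected offspring genotype frequencies are

    p11 = m^2         - sigma2
    p12 = 2 m (1 - m) + 2 sigma2
    p22 = (1 - m)^2   - sigma2

(the variance enters with signs opposite to the classical Wahlund
decomposition because these are the offspring expectations, not deviations
from HWE).  Offspring hybrid index is ``m``; offspring heterozygosity is
``p12``.  Since ``p12 - 2m(1-m) = 2 sigma2 >= 0``, no cross can produce
offspring below the curve ``het = 2h(1-h)``, which with the lines
``het = 2h`` and ``het = 2 - 2h`` bounds the reachable space of the
triangle plot.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .errors import ParameterError

#: Geometric tolerance for boundary classification and point deduplication.
TOL = 1e-12


@dataclass(frozen=True)
class GenotypeFreqs:
    """Genome-wide genotype frequencies (p11: P1 homozygote, p12: het, p22)."""

    p11: float
    p12: float
    p22: float

    def __post_init__(self) -> None:
        if min(self.p11, self.p12, self.p22) < -TOL:
            raise ParameterError("negative genotype frequency")
        if abs(self.p11 + self.p12 + self.p22 - 1.0) > 1e-9:
            raise ParameterError("genotype frequencies must sum to 1")

    @property
    def hybrid_index(self) -> float:
        """Implied genome-wide P1-allele frequency, p11 + p12/2."""
        return self.p11 + self.p12 / 2.0


@dataclass(frozen=True)
class ClassExpectation:
    """Expected (hybrid index, heterozygosity) of a canonical hybrid class."""

    label: str
    hybrid_index: float
    heterozygosity: float


def cross_variance(hA: float, hB: float) -> float:
    """Between-parent variance of genome-wide allele frequency (N = 2 parents)."""
    m = (hA + hB) / 2.0
    return ((hA - m) ** 2 + (hB - m) ** 2) / 2.0


def offspring_genotype_freqs(hA: float, hB: float) -> GenotypeFreqs:
    """Expected offspring genotype frequencies for parents at hA, hB."""
    for h in (hA, hB):
        if not 0.0 <= h <= 1.0:
            raise ParameterError("parental allele frequencies must lie in [0, 1]")
    m = (hA + hB) / 2.0
    s2 = cross_variance(hA, hB)
    # s2 = ((hA-hB)/2)^2 <= m(1-m) on [0,1]^2, so p11 and p22 stay nonnegative
    p11 = m * m - s2
    p12 = 2.0 * m * (1.0 - m) + 2.0 * s2
    p22 = (1.0 - m) ** 2 - s2
    return GenotypeFreqs(p11=max(p11, 0.0), p12=p12, p22=max(p22, 0.0))


def class_expectations(max_backcross: int = 4) -> list[ClassExpectation]:
    """Expected triangle-plot positions of the canonical hybrid classes.

    BCn toward a parent sits at hybrid-index offset ``2**-(n+1)`` from that
    parent with heterozygosity ``2**-n``; the mirror-image classes toward
    each parent are both reported (orientation: P2 at hybrid index 1).
    """
    if max_backcross < 1:
        raise ParameterError("max_backcross must be >= 1")
    out = [
        ClassExpectation("P1", 0.0, 0.0),
        ClassExpectation("P2", 1.0, 0.0),
        ClassExpectation("F1", 0.5, 1.0),
        ClassExpectation("F2", 0.5, 0.5),
    ]
    for n in range(1, max_backcross + 1):
        offset = 2.0 ** -(n + 1)
        het = 2.0**-n
        out.append(ClassExpectation(f"BC{n}_P1", offset, het))
        out.append(ClassExpectation(f"BC{n}_P2", 1.0 - offset, het))
    return out


def triangle_boundary(h: float) -> tuple[float, float]:
    """(min, max) heterozygosity reachable under HWE at hybrid index ``h``."""
    if not 0.0 <= h <= 1.0:
        raise ParameterError("hybrid index must lie in [0, 1]")
    return 2.0 * h * (1.0 - h), min(2.0 * h, 2.0 - 2.0 * h)


PointClass = Literal["inside", "on_curve", "below_curve", "outside_lines"]


def classify_point(h: float, het: float, tol: float = 1e-9) -> PointClass:
    """Locate (h, het) relative to the HWE-permissible triangle region.

    A point below the curve ``2h(1-h)`` is impossible under HWE and flags a
    violation (e.g. assortative mating or selection against heterozygotes).
    """
    if not (0.0 <= h <= 1.0 and 0.0 <= het <= 1.0):
        raise ParameterError("point must lie in the unit square")
    lo, hi = triangle_boundary(h)
    if het < lo - tol:
        return "below_curve"
    if het > hi + tol:
        return "outside_lines"
    if het <= lo + tol:
        return "on_curve"
    return "inside"


def enumerate_space(
    generations: int, max_generations: int = 8
) -> list[tuple[float, float]]:
    """All (hybrid index, heterozygosity) points reachable in G generations.

    Generation 0 holds only the two parental states (0, 0) and (1, 0).  At
    each later generation every unordered pair of previously available
    genome-wide allele frequencies (parentals included, so backcrosses
    arise) is crossed; offspring heterozygosity depends only on the parents'
    allele frequencies, never on their own heterozygosity.  Distinct points
    are accumulated; all of them lie inside the closed triangle region.
    """
    if generations < 0:
        raise ParameterError("generations must be >= 0")
    if generations > max_generations:
        raise ParameterError(
            f"generations = {generations} exceeds cap {max_generations} "
            "(point count grows combinatorially)"
        )
    points = {(0.0, 0.0), (1.0, 0.0)}
    freqs = {0.0, 1.0}  # genome-wide allele frequencies available as mates
    for _ in range(generations):
        parents = sorted(freqs)
        new_points = set()
        for i, hA in enumerate(parents):
            for hB in parents[i:]:
                g = offspring_genotype_freqs(hA, hB)
                new_points.add((round(g.hybrid_index, 12), round(g.p12, 12)))
        points |= new_points
        freqs |= {h for h, _ in new_points}
    return sorted(points)
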