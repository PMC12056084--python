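"""Synthetic hybrid-zone data: divergent parental pools, Mendelian crosses,
sequencing-depth downsampling, and parental subsampling replicates.

Sites are simulated unlinked (independent across sites), which makes the
class expectations exactly computable; real reduced-representation data has
linkage, so real-data uncertainty is larger than these fixtures suggest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError, PopmapError
from .io import MISSING, GenotypeMatrix, PopMap


@dataclass
class SimConfig:
    """Parameters of the two-population parental-pool generator.

    ``n_fixed_diff`` sites carry a true fixed difference (alt frequency 0 in
    P1, 1 in P2); the remaining sites draw per-population alt frequencies
    from ``spectrum``: ``("uniform",)`` or ``("beta", a, b)``.  The default
    Beta(0.5, 0.5) gives the U-shaped site-frequency spectrum typical of
    SNP panels.  Genotypes are two binomial allele copies at the population
    frequency.
    """

    n_sites: int = 1000
    n_fixed_diff: int = 100
    n_per_parental: int = 20
    spectrum: tuple = ("beta", 0.5, 0.5)
    p1_label: str = "P1"
    p2_label: str = "P2"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_sites < 1 or self.n_per_parental < 1:
            raise ParameterError("all counts must be positive")
        if not 0 <= self.n_fixed_diff <= self.n_sites:
            raise ParameterError("n_fixed_diff must be in [0, n_sites]")
        kind = self.spectrum[0]
        if kind == "beta":
            if len(self.spectrum) != 3 or min(self.spectrum[1:]) <= 0:
                raise ParameterError("beta spectrum needs two positive parameters")
        elif kind != "uniform":
            raise ParameterError(f"unknown spectrum {kind!r}")


def _draw_frequencies(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """(2, n_sites) true alt-allele frequencies; fixed differences first."""
    n_free = cfg.n_sites - cfg.n_fixed_diff
    if cfg.spectrum[0] == "uniform":
        free = rng.uniform(0.0, 1.0, size=(2, n_free))
    else:
        _, a, b = cfg.spectrum
        free = rng.beta(a, b, size=(2, n_free))
    fixed = np.tile([[0.0], [1.0]], (1, cfg.n_fixed_diff))
    return np.concatenate([fixed, free], axis=1)


def simulate_parental_pools(cfg: SimConfig) -> tuple[GenotypeMatrix, PopMap]:
    """Two parental populations with known true allele frequencies.

    The site table carries extra columns ``true_freq_p1``/``true_freq_p2``
    and ``true_delta`` so downstream validation can compare sample estimates
    with truth.  Deterministic for a given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    freqs = _draw_frequencies(cfg, rng)
    n = cfg.n_per_parental
    genos = []
    ids: list[str] = []
    assignments: dict[str, str] = {}
    for p, label in enumerate((cfg.p1_label, cfg.p2_label)):
        genos.append(rng.binomial(2, freqs[p], size=(n, cfg.n_sites)))
        for k in range(n):
            ind = f"{label}_{k:03d}"
            ids.append(ind)
            assignments[ind] = label
    sites = pd.DataFrame(
        {
            "chrom": "sim1",
            "pos": np.arange(1, cfg.n_sites + 1),
            "ref": "A",
            "alt": "T",
            "true_freq_p1": freqs[0],
            "true_freq_p2": freqs[1],
            "true_delta": np.abs(freqs[0] - freqs[1]),
        }
    )
    G = GenotypeMatrix(
        individual_ids=ids,
        sites=sites,
        genotypes=np.concatenate(genos, axis=0).astype(np.int8),
    )
    pm = PopMap(assignments=assignments, p1_label=cfg.p1_label, p2_label=cfg.p2_label)
    return G, pm


def cross(
    parentA: np.ndarray, parentB: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Mendelian offspring: one allele drawn from each parent per site.

    A parent with dosage d transmits the alt allele with probability d/2,
    independently across sites.  A site missing in either parent is missing
    in the offspring.
    """
    parentA = np.asarray(parentA)
    parentB = np.asarray(parentB)
    if parentA.shape != parentB.shape:
        raise ParameterError("parents must cover the same sites")
    miss = (parentA == MISSING) | (parentB == MISSING)
    a = rng.random(parentA.shape) < parentA / 2.0
    b = rng.random(parentB.shape) < parentB / 2.0
    child = (a.astype(np.int8) + b.astype(np.int8)).astype(np.int8)
    child[miss] = MISSING
    return child


#: Class labels emitted by :func:`make_hybrid_classes`.
HYBRID_CLASSES = ("F1", "F2", "BC1_P1", "BC1_P2")


def make_hybrid_classes(
    parents: GenotypeMatrix,
    pm: PopMap,
    n_per_class: int = 20,
    rng: np.random.Generator | int | None = None,
) -> tuple[GenotypeMatrix, PopMap]:
    """Append known hybrid classes to a parental matrix.

    F1s pair one individual from each parental population (without
    replacement while the pools last); each F2 pairs an F1 with another F1;
    first-generation backcrosses pair each F1 with a randomly chosen
    parental individual from the respective population.  Labels follow
    :data:`HYBRID_CLASSES`.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    p1 = [parents.individual_index(i) for i in pm.p1_individuals]
    p2 = [parents.individual_index(i) for i in pm.p2_individuals]
    if not p1 or not p2:
        raise PopmapError("both parental populations must be non-empty")
    if n_per_class < 1:
        raise ParameterError("n_per_class must be >= 1")

    def pick(pool: list[int], k: int) -> np.ndarray:
        if k <= len(pool):
            return rng.choice(pool, size=k, replace=False)
        return rng.choice(pool, size=k, replace=True)

    geno = parents.genotypes
    f1 = np.stack(
        [
            cross(geno[i], geno[j], rng)
            for i, j in zip(pick(p1, n_per_class), pick(p2, n_per_class))
        ]
    )
    # each F1 with another (distinct, when possible) F1
    mates = np.roll(np.arange(n_per_class), 1) if n_per_class >= 2 else [0]
    f2 = np.stack([cross(f1[k], f1[m], rng) for k, m in zip(range(n_per_class), mates)])
    bc1 = np.stack(
        [cross(f1[k], geno[j], rng) for k, j in enumerate(pick(p1, n_per_class))]
    )
    bc2 = np.stack(
        [cross(f1[k], geno[j], rng) for k, j in enumerate(pick(p2, n_per_class))]
    )

    new_geno = np.concatenate([parents.genotypes, f1, f2, bc1, bc2], axis=0)
    ids = list(parents.individual_ids)
    assignments = dict(pm.assignments)
    for label, block in zip(HYBRID_CLASSES, (f1, f2, bc1, bc2)):
        for k in range(n_per_class):
            ind = f"{label}_{k:03d}"
            ids.append(ind)
            assignments[ind] = label
    G = GenotypeMatrix(
        individual_ids=ids,
        sites=parents.sites.copy(),
        genotypes=new_geno.astype(np.int8),
    )
    return G, PopMap(assignments=assignments, p1_label=pm.p1_label, p2_label=pm.p2_label)


def downsample_depth(
    G: GenotypeMatrix,
    depth: int,
    rng: np.random.Generator | int | None = None,
    individuals: list[str] | None = None,
) -> GenotypeMatrix:
    """Recode genotypes as if called from ``depth`` reads without error.

    Per non-missing genotype, ``depth`` alleles are drawn with replacement
    from the individual's two allele copies; the site is recoded
    heterozygous only if both alleles were observed, else homozygous for
    the observed allele.  Homozygous genotypes are unchanged; a true
    heterozygote survives with probability ``1 - 2**(1 - depth)``.
    ``individuals`` restricts downsampling to a subset (e.g. hybrids only,
    keeping the parental sample at full depth).
    """
    if depth < 1:
        raise ParameterError("depth must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    geno = G.genotypes.copy()
    rows = (
        np.arange(G.n_individuals)
        if individuals is None
        else np.array([G.individual_index(i) for i in individuals])
    )
    sub = geno[rows, :]
    het = sub == 1
    # a het stays het iff the depth draws are not all-ref or all-alt
    n_alt = rng.binomial(depth, 0.5, size=sub.shape)
    recoded = np.where(n_alt == 0, 0, np.where(n_alt == depth, 2, 1)).astype(np.int8)
    sub = np.where(het, recoded, sub)
    geno[rows, :] = sub
    return GenotypeMatrix(
        individual_ids=list(G.individual_ids),
        sites=G.sites.copy(),
        genotypes=geno,
    )


def subsample_parentals(
    pm: PopMap,
    n: int,
    replicates: int,
    rng: np.random.Generator | int | None = None,
) -> list[PopMap]:
    """Replicate popmaps keeping ``n`` random individuals per parental label.

    Non-chosen parentals lose parental status (their label gains an
    ``_excluded`` suffix) but remain in the map so they are still reported
    downstream; non-parental individuals are untouched.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    pools = {lab: pm.individuals(lab) for lab in (pm.p1_label, pm.p2_label)}
    for lab, pool in pools.items():
        if n > len(pool):
            raise ParameterError(
                f"cannot keep {n} of {len(pool)} individuals in {lab!r}"
            )
    out = []
    for _ in range(replicates):
        assignments = dict(pm.assignments)
        for lab, pool in pools.items():
            kept = set(rng.choice(pool, size=n, replace=False))
            for ind in pool:
                if ind not in kept:
                    assignments[ind] = f"{lab}_excluded"
        out.append(
            PopMap(assignments=assignments, p1_label=pm.p1_label, p2_label=pm.p2_label)
        )
    return out
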