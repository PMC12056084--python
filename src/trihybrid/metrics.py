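"""Per-individual hybrid index and interclass heterozygosity over an AIM set.

Hybrid index (HI) is the fraction of an individual's allele copies at AIMs
that belong to the P2-associated allele: P1 parentals sit at 0, P2 at 1.
Interclass heterozygosity is the fraction of non-missing AIM sites at which
the individual carries one allele from each parental group.  Both are
undefined (NaN) when every AIM genotype is missing.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .aims import AimSet
from .errors import ParameterError
from .io import MISSING, PopMap


def _row_stats(dosage_row: np.ndarray) -> tuple[float, float, float]:
    """(hybrid index, heterozygosity, percent missing) from one dosage row."""
    called = dosage_row != MISSING
    n = int(called.sum())
    perc_missing = 100.0 * (dosage_row.size - n) / dosage_row.size
    if n == 0:
        return (np.nan, np.nan, perc_missing)
    hi = float(dosage_row[called].sum()) / (2.0 * n)
    het = float((dosage_row[called] == 1).sum()) / n
    return (hi, het, perc_missing)


def hybrid_index(aims: AimSet, individual: str) -> float:
    """P2-allele dosage summed over non-missing AIMs, divided by 2 x their count."""
    row = aims.p2_dosage[aims.individual_index(individual)]
    return _row_stats(row)[0]


def interclass_heterozygosity(aims: AimSet, individual: str) -> float:
    """Heterozygous AIM sites divided by non-missing AIM sites."""
    row = aims.p2_dosage[aims.individual_index(individual)]
    return _row_stats(row)[1]


def build_triangle_table(
    aims: AimSet, pm: PopMap, min_sites: int = 0
) -> pd.DataFrame:
    """One row per individual: id, pop, hybrid_index, heterozygosity, perc_missing.

    ``min_sites`` optionally blanks (sets to NaN) estimates based on fewer
    non-missing AIMs than requested; rows are never dropped, so the percent
    missing of every sequenced individual is always reported.
    """
    if aims.n_sites == 0:
        raise ParameterError("AIM set is empty")
    dosage = aims.p2_dosage
    rows = []
    for i, ind in enumerate(aims.individual_ids):
        hi, het, miss = _row_stats(dosage[i])
        n_called = int((dosage[i] != MISSING).sum())
        if n_called < min_sites:
            hi = het = np.nan
        rows.append(
            {
                "id": ind,
                "pop": pm.assignments.get(ind, "NA"),
                "hybrid_index": hi,
                "heterozygosity": het,
                "perc_missing": miss,
            }
        )
    return pd.DataFrame(rows)
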