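"""Within- and between-population diversity and SNP-sharing statistics.

A site is *polymorphic within a population* when both alleles are observed
among that population's genotypes (sites fixed for the alternate allele are
differences from the reference, not polymorphism). SNP-sharing partitions
assign every site that is polymorphic in at least one population to the
exact subset of populations in which it is polymorphic, the quantity behind
multi-set Venn diagrams of shared variation.

Mitochondrial divergence is summarised with uncorrected p-distances
(proportion of differing positions among pairwise-comparable positions,
reported as percent), with pairwise deletion of ambiguous bases and gaps.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd

from .genio import MISSING, GenotypeMatrix, PopulationMap, SeqAlignment


def _require_complete(gm: GenotypeMatrix) -> None:
    if (gm.genotypes == MISSING).any():
        raise ValueError("statistic requires a matrix without missing genotypes")


def _polymorphic_mask(genotypes: np.ndarray, rows: np.ndarray) -> np.ndarray:
    """Boolean site mask: both alleles seen within the given individuals."""
    sub = genotypes[rows]
    has_ref = ((sub == 0) | (sub == 1)).any(axis=0)
    has_alt = ((sub == 2) | (sub == 1)).any(axis=0)
    return has_ref & has_alt


def polymorphic_counts(gm: GenotypeMatrix, popmap: PopulationMap) -> dict[str, int]:
    """Number of sites polymorphic within each population."""
    _require_complete(gm)
    return {
        pop: int(_polymorphic_mask(gm.genotypes, popmap.indices(gm, pop)).sum())
        for pop in popmap.populations
    }


def sharing_partition(gm: GenotypeMatrix, popmap: PopulationMap) -> dict[frozenset, int]:
    """Counts of sites per exact subset of populations in which they are polymorphic.

    Every site polymorphic in at least one population lands in exactly one of
    the 2^k - 1 nonempty subsets, so the counts sum to the number of such
    sites.
    """
    _require_complete(gm)
    pops = popmap.populations
    masks = np.stack([_polymorphic_mask(gm.genotypes, popmap.indices(gm, p)) for p in pops])
    out: dict[frozenset, int] = {}
    any_poly = masks.any(axis=0)
    codes = np.zeros(gm.n_sites, dtype=np.int64)
    for i in range(len(pops)):
        codes |= masks[i].astype(np.int64) << i
    values, counts = np.unique(codes[any_poly], return_counts=True)
    for code, count in zip(values, counts):
        subset = frozenset(pops[i] for i in range(len(pops)) if code >> i & 1)
        out[subset] = int(count)
    return out


def sharing_table(gm: GenotypeMatrix, popmap: PopulationMap) -> pd.DataFrame:
    """The sharing partition as a tidy table (one row per nonempty subset)."""
    part = sharing_partition(gm, popmap)
    rows = []
    for r in range(1, len(popmap.populations) + 1):
        for combo in combinations(popmap.populations, r):
            key = frozenset(combo)
            rows.append({"populations": "+".join(combo), "n_sites": part.get(key, 0)})
    return pd.DataFrame(rows)


def fixed_differences(gm: GenotypeMatrix, group_a, group_b) -> int:
    """Sites where group A is fixed for one allele and group B for the other."""
    _require_complete(gm)
    ia = np.array([gm.individuals.index(i) for i in group_a])
    ib = np.array([gm.individuals.index(i) for i in group_b])
    a = gm.genotypes[ia]
    b = gm.genotypes[ib]
    a_ref = (a == 0).all(axis=0)
    a_alt = (a == 2).all(axis=0)
    b_ref = (b == 0).all(axis=0)
    b_alt = (b == 2).all(axis=0)
    return int(((a_ref & b_alt) | (a_alt & b_ref)).sum())


def downsampled_polymorphic(
    gm: GenotypeMatrix, popmap: PopulationMap, pop: str, k: int = 3
) -> tuple[float, list[int]]:
    """Mean polymorphic-site count over all C(n, k) subsets of ``k`` individuals.

    Exact enumeration; intended for the small per-population cohorts of this
    kind of study (n <= 5 or so).
    """
    rows = popmap.indices(gm, pop)
    if len(rows) < k:
        raise ValueError(f"population {pop!r} has {len(rows)} < k={k} individuals")
    _require_complete(gm)
    per_subset = [
        int(_polymorphic_mask(gm.genotypes, np.array(sub)).sum())
        for sub in combinations(rows, k)
    ]
    return float(np.mean(per_subset)), per_subset


def individual_heterozygosity(
    gm: GenotypeMatrix,
    denominator: str = "variant-only",
    callable_total: int | None = None,
) -> dict[str, float]:
    """Observed heterozygosity per individual.

    ``variant-only`` divides heterozygous genotype counts by the number of
    sites in the matrix; ``all-callable`` divides by ``callable_total``, a
    genome-wide count of callable positions that includes invariant sites.
    """
    _require_complete(gm)
    het = (gm.genotypes == 1).sum(axis=1)
    if denominator == "variant-only":
        denom = gm.n_sites
    elif denominator == "all-callable":
        if callable_total is None:
            raise ValueError("all-callable denominator requires callable_total")
        if callable_total < gm.n_sites:
            raise ValueError("callable_total smaller than the number of variant sites")
        denom = callable_total
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    if denom == 0:
        raise ValueError("empty matrix: heterozygosity undefined")
    return {ind: float(h) / denom for ind, h in zip(gm.individuals, het)}


_UNAMBIGUOUS = set("ACGT")


def p_distance(aln: SeqAlignment) -> pd.DataFrame:
    """Pairwise uncorrected p-distances in percent, pairwise-deleting N/-.

    Raises when a pair shares no unambiguous positions.
    """
    arr = aln.as_array()
    ok = np.isin(arr, list(_UNAMBIGUOUS))
    n = len(aln.labels)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            comparable = ok[i] & ok[j]
            total = int(comparable.sum())
            if total == 0:
                raise ValueError(
                    f"no comparable positions between {aln.labels[i]!r} and {aln.labels[j]!r}"
                )
            diff = int((arr[i][comparable] != arr[j][comparable]).sum())
            out[i, j] = out[j, i] = 100.0 * diff / total
    return pd.DataFrame(out, index=aln.labels, columns=aln.labels)


def group_summary(matrix: pd.DataFrame, groups: dict[str, str]) -> pd.DataFrame:
    """Within/between-group min, mean and max of a pairwise distance matrix.

    ``groups`` maps sequence label -> group label.
    """
    labels = list(matrix.index)
    members = {}
    for lab in labels:
        members.setdefault(groups[lab], []).append(lab)
    group_names = sorted(members)
    rows = []
    for i, ga in enumerate(group_names):
        for gb in group_names[i:]:
            if ga == gb:
                vals = [matrix.loc[a, b] for a, b in combinations(members[ga], 2)]
            else:
                vals = [matrix.loc[a, b] for a in members[ga] for b in members[gb]]
            if not vals:
                continue
            rows.append(
                {
                    "group_a": ga,
                    "group_b": gb,
                    "min": float(np.min(vals)),
                    "mean": float(np.mean(vals)),
                    "max": float(np.max(vals)),
                    "n_pairs": len(vals),
                }
            )
    return pd.DataFrame(rows)
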