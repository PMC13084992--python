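"""ABBA-BABA introgression tests.

Sites are polarized with an outgroup (retained only where every outgroup
individual is homozygous for the same allele, which is taken as ancestral).
For a quartet (P1, P2, P3, outgroup) the frequency-based site patterns are

    ABBA = (1 - p1) * p2 * p3        BABA = p1 * (1 - p2) * p3

with p_i the derived-allele frequency in population i (the outgroup's
derived frequency is 0 by construction). The D statistic is
(sum ABBA - sum BABA) / (sum ABBA + sum BABA); the admixture fraction f
compares the observed ABBA-BABA excess with the excess expected under
complete admixture, approximated by splitting the donor population P3 into
two halves (P3a in the P2 slot, P3b in the P3 slot). Standard errors come
from a delete-one block jackknife over contiguous genomic blocks (1 Mb by
default; with scaffolds shorter than the span, blocks coincide with
scaffolds).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genio import MISSING, GenotypeMatrix, PopulationMap

__all__ = [
    "PolarizedFreqs",
    "DStatResult",
    "polarize",
    "d_statistic",
    "f_fraction",
    "block_jackknife",
    "dstat_test",
    "test_battery",
]


@dataclass
class PolarizedFreqs:
    """Derived-allele frequencies per population at outgroup-polarized sites."""

    sites: pd.DataFrame  # scaffold, pos for retained sites
    freqs: dict[str, np.ndarray]  # population -> derived frequency per site
    half_freqs: dict[str, tuple[np.ndarray, np.ndarray]]  # population -> (P3a, P3b)
    excluded: int  # sites dropped by the outgroup-homozygosity rule

    @property
    def n_sites(self) -> int:
        return len(self.sites)


def polarize(gm: GenotypeMatrix, popmap: PopulationMap, outgroup: str) -> PolarizedFreqs:
    """Polarize sites with the outgroup population.

    Retains sites where every outgroup individual is homozygous for the same
    allele; that allele is ancestral. Ingroup derived-allele frequencies are
    dosage fractions; each ingroup population is additionally split into two
    deterministic halves (alternating individuals in population-map order,
    even indices -> a, odd -> b) for the f denominator.
    """
    out_rows = popmap.indices(gm, outgroup)
    if len(out_rows) == 0:
        raise ValueError("empty outgroup")
    og = gm.genotypes[out_rows]
    # sites with missing outgroup genotypes fail the homozygosity rule below
    all_ref = (og == 0).all(axis=0)
    all_alt = (og == 2).all(axis=0)
    retained = all_ref | all_alt
    excluded = int((~retained).sum())
    # derived allele: alt where outgroup fixed ref, ref where outgroup fixed alt
    flip = all_alt[retained]
    freqs: dict[str, np.ndarray] = {}
    half_freqs: dict[str, tuple[np.ndarray, np.ndarray]] = {}

    def derived_freq(rows: np.ndarray) -> np.ndarray:
        sub = gm.genotypes[rows][:, retained].astype(float)
        if (sub == MISSING).any():
            raise ValueError("missing ingroup genotypes at polarized sites")
        p = sub.sum(axis=0) / (2.0 * len(rows))
        p[flip] = 1.0 - p[flip]
        return p

    for pop in popmap.populations:
        if pop == outgroup:
            continue
        rows = popmap.indices(gm, pop)
        freqs[pop] = derived_freq(rows)
        if len(rows) >= 2:
            half_freqs[pop] = (derived_freq(rows[0::2]), derived_freq(rows[1::2]))
    sites = gm.sites.loc[retained, ["scaffold", "pos"]].reset_index(drop=True)
    return PolarizedFreqs(sites, freqs, half_freqs, excluded)


def _abba_baba(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    abba = (1.0 - p1) * p2 * p3
    baba = p1 * (1.0 - p2) * p3
    return abba, baba


def d_statistic(freqs: PolarizedFreqs, p1: str, p2: str, p3: str) -> tuple[float, float, float]:
    """Genome-wide D with its ABBA and BABA sums."""
    if len({p1, p2, p3}) != 3:
        raise ValueError("P1, P2, P3 must be distinct populations")
    abba, baba = _abba_baba(freqs.freqs[p1], freqs.freqs[p2], freqs.freqs[p3])
    s_abba, s_baba = float(abba.sum()), float(baba.sum())
    if s_abba + s_baba == 0:
        raise ValueError("D undefined: no ABBA or BABA signal")
    return (s_abba - s_baba) / (s_abba + s_baba), s_abba, s_baba


def f_fraction(freqs: PolarizedFreqs, p1: str, p2: str, p3: str) -> float:
    """Admixture fraction f = S(P1,P2,P3) / S(P1,P3a,P3b)."""
    if p3 not in freqs.half_freqs:
        raise ValueError(f"P3 population {p3!r} needs at least two individuals")
    abba, baba = _abba_baba(freqs.freqs[p1], freqs.freqs[p2], freqs.freqs[p3])
    p3a, p3b = freqs.half_freqs[p3]
    abba_d, baba_d = _abba_baba(freqs.freqs[p1], p3a, p3b)
    denom = float((abba_d - baba_d).sum())
    if denom == 0:
        raise ValueError("f undefined: zero expected excess under complete admixture")
    return float((abba - baba).sum()) / denom


def block_ids(sites: pd.DataFrame, block_span: int = 1_000_000) -> np.ndarray:
    """Integer block index per site: contiguous windows within scaffolds."""
    key = sites["scaffold"].astype(str) + ":" + ((sites["pos"] - 1) // block_span).astype(str)
    _, ids = np.unique(key.to_numpy(), return_inverse=True)
    return ids


def block_jackknife(
    numerator: np.ndarray,
    denominator: np.ndarray,
    blocks: np.ndarray,
) -> tuple[float, float, float, int]:
    """Delete-one-block jackknife for a ratio statistic sum(num)/sum(den).

    Returns (estimate, SE, Z, number of nonempty blocks) with
    SE = sqrt[(B-1)/B * sum_j (theta_(-j) - mean theta_(-j))^2].
    """
    uniq = np.unique(blocks)
    num_b = np.zeros(len(uniq))
    den_b = np.zeros(len(uniq))
    inv = np.searchsorted(uniq, blocks)
    np.add.at(num_b, inv, numerator)
    np.add.at(den_b, inv, denominator)
    n_total, d_total = num_b.sum(), den_b.sum()
    if d_total == 0:
        raise ValueError("jackknife statistic undefined: zero denominator")
    estimate = n_total / d_total
    b = len(uniq)
    if b < 2:
        raise ValueError("block jackknife requires at least two nonempty blocks")
    loo = (n_total - num_b) / (d_total - den_b)
    se = float(np.sqrt((b - 1) / b * ((loo - loo.mean()) ** 2).sum()))
    z = float(estimate / se) if se > 0 else float("inf") if estimate != 0 else 0.0
    return float(estimate), se, z, b


@dataclass
class DStatResult:
    """One quartet's introgression test."""

    p1: str
    p2: str
    p3: str
    outgroup: str
    d: float
    d_se: float
    d_z: float
    f: float
    f_se: float
    f_z: float
    n_blocks: int
    abba: float
    baba: float
    n_sites: int

    def as_row(self) -> dict:
        return {
            "P1": self.p1, "P2": self.p2, "P3": self.p3, "outgroup": self.outgroup,
            "D": self.d, "D_se": self.d_se, "D_Z": self.d_z,
            "f": self.f, "f_se": self.f_se, "f_Z": self.f_z,
            "n_blocks": self.n_blocks, "ABBA": self.abba, "BABA": self.baba,
            "n_sites": self.n_sites,
        }


def dstat_test(
    freqs: PolarizedFreqs,
    p1: str,
    p2: str,
    p3: str,
    outgroup: str = "outgroup",
    block_span: int = 1_000_000,
) -> DStatResult:
    """D and f with block-jackknife standard errors for one quartet."""
    d, s_abba, s_baba = d_statistic(freqs, p1, p2, p3)
    abba, baba = _abba_baba(freqs.freqs[p1], freqs.freqs[p2], freqs.freqs[p3])
    blocks = block_ids(freqs.sites, block_span)
    d_est, d_se, d_z, n_blocks = block_jackknife(abba - baba, abba + baba, blocks)
    p3a, p3b = freqs.half_freqs[p3]
    abba_d, baba_d = _abba_baba(freqs.freqs[p1], p3a, p3b)
    f_est, f_se, f_z, _ = block_jackknife(abba - baba, abba_d - baba_d, blocks)
    return DStatResult(
        p1, p2, p3, outgroup,
        d=d_est, d_se=d_se, d_z=d_z,
        f=f_est, f_se=f_se, f_z=f_z,
        n_blocks=n_blocks, abba=s_abba, baba=s_baba, n_sites=freqs.n_sites,
    )


def test_battery(
    gm: GenotypeMatrix,
    popmap: PopulationMap,
    quartets: list[tuple[str, str, str, str]],
    block_span: int = 1_000_000,
) -> pd.DataFrame:
    """Run a set of (P1, P2, P3, outgroup) quartets on a shared polarization.

    All quartets must share one outgroup (polarization is computed once).
    """
    outgroups = {q[3] for q in quartets}
    if len(outgroups) != 1:
        raise ValueError("all quartets in a battery must share the outgroup")
    outgroup = outgroups.pop()
    freqs = polarize(gm, popmap, outgroup)
    rows = [
        dstat_test(freqs, p1, p2, p3, outgroup, block_span).as_row()
        for p1, p2, p3, _og in quartets
    ]
    return pd.DataFrame(rows)


#: The study-design battery: the gray-seal louse population as candidate
#: donor (P3), the Baltic/Ladoga/Saimaa ringed-seal louse populations as
#: recipients (P2), and successively deeper-diverged populations as P1.
STUDY_QUARTETS = [
    ("ladoga", "baltic", "gray", "baikal"),
    ("saimaa", "baltic", "gray", "baikal"),
    ("arctic", "baltic", "gray", "baikal"),
    ("saimaa", "ladoga", "gray", "baikal"),
    ("arctic", "ladoga", "gray", "baikal"),
    ("arctic", "saimaa", "gray", "baikal"),
]
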