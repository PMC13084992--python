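"""SNP filtering cascade and LD pruning.

The site/genotype filters mirror a conventional short-read population-VCF
cleanup: site quality, excess total depth (a collapsed-repeat signal),
genotype-level depth/quality masking, removal of sites heterozygous in an
implausible number of individuals, and finally removal of any site with
missing genotypes. Rule order is fixed and each removed site is attributed
to the first rule it fails, which makes reports reproducible and auditable.

LD pruning follows the sliding-window r^2 heuristic (windows of 50 SNPs
advanced by 10 within each scaffold, pruning one site of any retained pair
with squared Pearson dosage correlation above the threshold).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .genio import MISSING, GenotypeMatrix


@dataclass
class FilterConfig:
    """Thresholds for the site/genotype filter cascade.

    qual_min : retain sites with QUAL strictly greater than this.
    site_depth_max_mult : remove sites whose summed depth exceeds this
        multiple of the mean site depth (mean computed on the input matrix).
    gt_depth_min : genotypes with DP below this are masked to missing.
    gq_min : genotypes with GQ not above this are masked to missing.
    max_het_individuals : remove sites heterozygous in more than this many
        individuals; ``max_het_fraction`` is the cohort-size-portable
        alternative (use whichever is set; absolute count wins if both).
    drop_any_missing : remove sites with any missing genotype after masking.
    """

    qual_min: float | None = 30.0
    site_depth_max_mult: float | None = 2.0
    gt_depth_min: int | None = 10
    gq_min: int | None = 30
    max_het_individuals: int | None = 14
    max_het_fraction: float | None = None
    drop_any_missing: bool = True

    def __post_init__(self) -> None:
        for name in ("qual_min", "site_depth_max_mult", "gt_depth_min", "gq_min",
                     "max_het_individuals", "max_het_fraction"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0")

    def het_threshold(self, n_individuals: int) -> int | None:
        if self.max_het_individuals is not None:
            return int(self.max_het_individuals)
        if self.max_het_fraction is not None:
            return int(np.floor(self.max_het_fraction * n_individuals))
        return None


@dataclass
class FilterReport:
    """Per-rule removal counts; input = output + sum of removals."""

    input_sites: int = 0
    output_sites: int = 0
    mean_site_depth: float = float("nan")
    removed: dict[str, int] = field(default_factory=dict)
    masked_genotypes: int = 0

    def to_json(self) -> str:
        return json.dumps(
            {
                "input_sites": self.input_sites,
                "output_sites": self.output_sites,
                "mean_site_depth": self.mean_site_depth,
                "removed": self.removed,
                "masked_genotypes": self.masked_genotypes,
            },
            indent=2,
        )

    def __str__(self) -> str:
        lines = [f"input sites:  {self.input_sites}"]
        for rule, n in self.removed.items():
            lines.append(f"  removed by {rule}: {n}")
        lines.append(f"masked genotypes: {self.masked_genotypes}")
        lines.append(f"output sites: {self.output_sites}")
        return "\n".join(lines)


RULE_ORDER = ("qual", "site_depth", "het_excess", "missing")


def filter_sites(gm: GenotypeMatrix, cfg: FilterConfig | None = None) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the filter cascade; returns the filtered matrix and a report.

    Order: (1) site QUAL; (2) total site depth vs. a multiple of the input
    mean site depth; (3) genotype-level DP/GQ masking (genotypes set to
    missing, not sites removed); (4) heterozygote-excess site removal;
    (5) removal of sites with any missing genotype. A removed site is
    attributed to the first rule it fails.
    """
    if cfg is None:
        cfg = FilterConfig()
    n, s = gm.genotypes.shape
    report = FilterReport(input_sites=s, removed={r: 0 for r in RULE_ORDER})
    if s == 0:
        return gm.copy(), report
    keep = np.ones(s, dtype=bool)
    fail_rule = np.full(s, "", dtype=object)

    def mark(mask: np.ndarray, rule: str) -> None:
        new = mask & keep
        fail_rule[new] = rule
        keep[new] = False

    if cfg.qual_min is not None:
        qual = gm.sites["qual"].to_numpy(dtype=float)
        if np.isnan(qual).all():
            raise ValueError("QUAL filter enabled but site QUAL is absent")
        mark(~(qual > cfg.qual_min), "qual")

    if cfg.site_depth_max_mult is not None:
        if gm.dp is None:
            raise ValueError("site-depth filter enabled but DP layer is absent")
        site_depth = gm.dp.sum(axis=0)
        report.mean_site_depth = float(site_depth.mean())
        mark(site_depth > cfg.site_depth_max_mult * report.mean_site_depth, "site_depth")

    genotypes = gm.genotypes.copy()
    if cfg.gt_depth_min is not None or cfg.gq_min is not None:
        bad = np.zeros((n, s), dtype=bool)
        if cfg.gt_depth_min is not None:
            if gm.dp is None:
                raise ValueError("genotype-depth filter enabled but DP layer is absent")
            bad |= gm.dp < cfg.gt_depth_min
        if cfg.gq_min is not None:
            if gm.gq is None:
                raise ValueError("GQ filter enabled but GQ layer is absent")
            bad |= ~(gm.gq > cfg.gq_min)
        bad &= genotypes != MISSING
        report.masked_genotypes = int(bad.sum())
        genotypes[bad] = MISSING

    het_max = cfg.het_threshold(n)
    if het_max is not None:
        mark((genotypes == 1).sum(axis=0) > het_max, "het_excess")

    if cfg.drop_any_missing:
        mark((genotypes == MISSING).any(axis=0), "missing")

    for rule in RULE_ORDER:
        report.removed[rule] = int((fail_rule == rule).sum())
    report.output_sites = int(keep.sum())
    out = GenotypeMatrix(
        list(gm.individuals),
        gm.sites[keep].reset_index(drop=True),
        genotypes[:, keep],
        None if gm.dp is None else gm.dp[:, keep],
        None if gm.gq is None else gm.gq[:, keep],
    )
    return out, report


def ld_prune(
    gm: GenotypeMatrix,
    r2_max: float = 0.1,
    window: int = 50,
    step: int = 10,
) -> np.ndarray:
    """Greedy sliding-window LD pruning; returns the retained site indices.

    Within each scaffold, windows of ``window`` sites advance by ``step``
    sites; within a window, for every retained pair whose squared Pearson
    correlation of alt-allele dosages exceeds ``r2_max`` the site with the
    larger index (the later position) is removed. Monomorphic sites have no
    defined correlation and are always retained. Requires a matrix without
    missing genotypes.
    """
    if (gm.genotypes == MISSING).any():
        raise ValueError("LD pruning requires a matrix without missing genotypes")
    if window < 2 or step < 1:
        raise ValueError("window must be >= 2 and step >= 1")
    dosage = gm.genotypes.astype(float)
    variances = dosage.var(axis=0)
    keep = np.ones(gm.n_sites, dtype=bool)
    scaffolds = gm.sites["scaffold"].to_numpy()
    for scaffold in np.unique(scaffolds):
        idx = np.flatnonzero(scaffolds == scaffold)
        start = 0
        while True:
            win = idx[start : start + window]
            if len(win) >= 2:
                _prune_window(dosage, variances, keep, win, r2_max)
            if start + window >= len(idx):
                break
            start += step
    return np.flatnonzero(keep)


def _prune_window(dosage, variances, keep, win, r2_max) -> None:
    active = [i for i in win if keep[i] and variances[i] > 0]
    if len(active) < 2:
        return
    sub = dosage[:, active]
    r = np.corrcoef(sub, rowvar=False)
    r2 = r * r
    alive = np.ones(len(active), dtype=bool)
    for a in range(len(active)):
        if not alive[a]:
            continue
        for b in range(a + 1, len(active)):
            if alive[b] and r2[a, b] > r2_max:
                alive[b] = False
    for j, site in enumerate(active):
        if not alive[j]:
            keep[site] = False
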