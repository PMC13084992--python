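"""Folded multidimensional SFS construction and coalescent demographic inference.

The observed data are a k-dimensional folded site frequency spectrum (SFS)
over the sampled populations. For a candidate demography the probability
that a segregating site falls in each SFS cell is estimated by Monte Carlo
over coalescent genealogies: for every simulated locus, tskit's branch-mode
allele-frequency spectrum gives the expected branch length subtending each
joint frequency class, and under the infinite-sites model cell
probabilities are proportional to those expected lengths. The fit criterion
is the SNP-only composite likelihood

    L10 = sum over unmasked cells of  m_cell * log10(p_cell)

(composite because SNPs are treated as independent; reported in log10
units). Model selection uses AIC = 2k - 2*ln(10)*L10, the convention under
which printed log10 composite likelihoods translate directly; confidence
intervals come from a block bootstrap over 1-kb blocks of sites.

The fitting interface follows the model/results idiom:
:class:`SFSDemographicModel` holds the observed SFS and a demography
builder; its :meth:`~SFSDemographicModel.fit` runs a seeded multi-start
derivative-free search (Nelder-Mead on log-transformed sizes/times, with
common random numbers across proposals so the Monte-Carlo likelihood
surface is smooth) and returns :class:`DemographicFitResults`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import msprime
import numpy as np
import pandas as pd
from scipy import optimize

from .genio import MISSING, GenotypeMatrix, PopulationMap
from .simdata import DemographyModel, SampleConfig, model_registry

__all__ = [
    "SFSArray",
    "build_sfs",
    "thin_one_per_block",
    "expected_sfs",
    "composite_loglik",
    "SFSDemographicModel",
    "DemographicFitResults",
    "fit_model",
    "model_selection",
    "likelihood_surface",
    "bootstrap_ci",
    "to_natural_units",
    "LN10",
]

LN10 = math.log(10.0)


# --------------------------------------------------------------------------
# the SFS container and folding
# --------------------------------------------------------------------------


def _folding_maps(shape: tuple[int, ...]):
    """Flat canonical-cell index map and canonical mask for folding.

    A cell is canonical when its total derived count is below half the total
    allele count; at exact ties the lexicographically smaller of the cell and
    its complement is canonical and receives the full count.
    """
    grids = np.indices(shape).reshape(len(shape), -1)
    caps = (np.array(shape) - 1)[:, None]
    comp = caps - grids
    total = grids.sum(axis=0)
    half = caps.sum() / 2.0
    canonical = total < half
    ties = total == half
    if ties.any():
        # lexicographic comparison cell vs complement
        smaller = np.zeros(ties.sum(), dtype=bool)
        undecided = np.ones(ties.sum(), dtype=bool)
        g = grids[:, ties]
        c = comp[:, ties]
        for dim in range(len(shape)):
            lt = undecided & (g[dim] < c[dim])
            gt = undecided & (g[dim] > c[dim])
            smaller |= lt
            undecided &= ~(lt | gt)
        canonical[ties] = smaller | undecided  # self-complement cells are canonical
    comp_flat = np.ravel_multi_index(comp, shape)
    return comp_flat, canonical


@dataclass
class SFSArray:
    """A k-dimensional (optionally folded) site frequency spectrum.

    ``counts`` has shape ``(2*n_1+1, ..., 2*n_k+1)`` for diploid sample
    sizes ``n_i``. ``mask`` flags cells excluded from likelihoods: the
    monomorphic corners and, in a folded spectrum, every non-canonical cell
    (whose mass has been moved onto its complement).
    """

    counts: np.ndarray
    populations: list[str]
    sample_sizes: dict[str, int]
    folded: bool = True
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        expected = tuple(2 * self.sample_sizes[p] + 1 for p in self.populations)
        if self.counts.shape != expected:
            raise ValueError(f"counts shape {self.counts.shape} != {expected} from sample sizes")
        if self.mask is None:
            self.mask = self.default_mask(self.counts.shape, self.folded)

    @staticmethod
    def default_mask(shape: tuple[int, ...], folded: bool) -> np.ndarray:
        mask = np.zeros(shape, dtype=bool)
        zero = tuple(0 for _ in shape)
        top = tuple(s - 1 for s in shape)
        mask[zero] = True
        mask[top] = True
        if folded:
            _comp, canonical = _folding_maps(shape)
            mask |= ~canonical.reshape(shape)
        return mask

    @property
    def total_snps(self) -> float:
        return float(self.counts[~self.mask].sum())

    def fold(self) -> "SFSArray":
        if self.folded:
            return self
        folded_counts = fold_array(self.counts)
        return SFSArray(folded_counts, list(self.populations), dict(self.sample_sizes), folded=True)


def fold_array(arr: np.ndarray) -> np.ndarray:
    """Fold an unfolded spectrum onto canonical minor-allele cells."""
    shape = arr.shape
    comp_flat, canonical = _folding_maps(shape)
    flat = arr.reshape(-1).astype(float)
    out = np.zeros_like(flat)
    self_comp = comp_flat == np.arange(flat.size)
    out[canonical] = flat[canonical]
    add = canonical & ~self_comp
    out[np.flatnonzero(add)] += flat[comp_flat[add]]
    return out.reshape(shape)


def build_sfs(
    gm: GenotypeMatrix,
    popmap: PopulationMap,
    populations: list[str] | None = None,
    fold: bool = True,
) -> SFSArray:
    """Build the joint SFS from alt-allele dosages (one cell increment per site)."""
    if (gm.genotypes == MISSING).any():
        raise ValueError("SFS construction requires a matrix without missing genotypes")
    pops = populations if populations is not None else popmap.populations
    rows = [popmap.indices(gm, p) for p in pops]
    sizes = {p: len(r) for p, r in zip(pops, rows)}
    shape = tuple(2 * sizes[p] + 1 for p in pops)
    dosage = np.stack([gm.genotypes[r].sum(axis=0) for r in rows])  # (k, S)
    flat_idx = np.ravel_multi_index(dosage, shape)
    counts = np.bincount(flat_idx, minlength=int(np.prod(shape))).astype(float).reshape(shape)
    if fold:
        counts = fold_array(counts)
    return SFSArray(counts, list(pops), sizes, folded=fold)


def site_cell_indices(
    gm: GenotypeMatrix, popmap: PopulationMap, populations: list[str] | None = None
) -> tuple[np.ndarray, tuple[int, ...], list[str], dict[str, int]]:
    """Flat (unfolded) SFS cell index of every site; used by the block bootstrap."""
    pops = populations if populations is not None else popmap.populations
    rows = [popmap.indices(gm, p) for p in pops]
    sizes = {p: len(r) for p, r in zip(pops, rows)}
    shape = tuple(2 * sizes[p] + 1 for p in pops)
    dosage = np.stack([gm.genotypes[r].sum(axis=0) for r in rows])
    return np.ravel_multi_index(dosage, shape), shape, pops, sizes


def thin_one_per_block(gm: GenotypeMatrix, block_span: int = 1000, seed: int = 0) -> GenotypeMatrix:
    """Retain one uniformly chosen site per (scaffold, block_span) window."""
    rng = np.random.default_rng(seed)
    scaff = gm.sites["scaffold"].to_numpy()
    block = (gm.sites["pos"].to_numpy() - 1) // block_span
    keys = pd.DataFrame({"scaffold": scaff, "block": block})
    keep = np.zeros(gm.n_sites, dtype=bool)
    for _key, idx in keys.groupby(["scaffold", "block"], sort=False).groups.items():
        keep[rng.choice(np.asarray(idx))] = True
    return gm.subset(site_mask=keep)


# --------------------------------------------------------------------------
# expected SFS and the composite likelihood
# --------------------------------------------------------------------------


def expected_sfs(
    model: DemographyModel,
    cfg: SampleConfig,
    n_rep: int = 1000,
    seed: int = 1,
    fold: bool = True,
    populations: list[str] | None = None,
) -> np.ndarray:
    """Monte-Carlo cell probabilities for a segregating site under ``model``.

    Averages tskit branch-mode allele-frequency spectra over ``n_rep``
    independent locus genealogies: the expected branch length subtending
    each joint derived-allele count is proportional, under infinite sites,
    to the probability that a SNP falls in that cell. Probabilities are
    normalized over unmasked (segregating, canonical) cells. Deterministic
    given ``seed``; reusing the seed across parameter proposals gives
    common random numbers.
    """
    pops = populations if populations is not None else [p for p, n in cfg.n_per_pop.items() if n > 0]
    for p in pops:
        if cfg.n_per_pop.get(p, 0) <= 0:
            raise ValueError(f"population {p!r} not sampled")
    sizes = {p: cfg.n_per_pop[p] for p in pops}
    for label, size in sizes.items():
        for _t, n in model.size_epochs(label):
            if n <= 0:
                raise ValueError(f"population {label!r} has non-positive size")
    reps = msprime.sim_ancestry(
        samples={p: sizes[p] for p in pops},
        demography=model.to_msprime(),
        ploidy=2,
        num_replicates=n_rep,
        random_seed=seed,
    )
    total = None
    sample_sets = None
    for ts in reps:
        if sample_sets is None:
            name_to_id = {pop.metadata.get("name", str(pop.id)): pop.id for pop in ts.populations()}
            sample_sets = [ts.samples(population=name_to_id[p]) for p in pops]
        afs = ts.allele_frequency_spectrum(
            sample_sets=sample_sets, mode="branch", polarised=True, span_normalise=True
        )
        total = afs if total is None else total + afs
    if fold:
        total = fold_array(total)
    mask = SFSArray.default_mask(total.shape, fold)
    probs = np.zeros_like(total)
    seg = total[~mask].sum()
    if seg <= 0:
        raise ValueError("degenerate model: no expected segregating branch length")
    probs[~mask] = total[~mask] / seg
    return probs


def composite_loglik(obs: SFSArray, probs: np.ndarray, p_floor: float = 0.0) -> float:
    """SNP-only composite log-likelihood in log10 units.

    Sum over unmasked cells of m_cell * log10(max(p_cell, p_floor)). Returns
    -inf when an observed cell has zero probability and no floor is given.
    """
    if probs.shape != obs.counts.shape:
        raise ValueError(f"probability array shape {probs.shape} != SFS shape {obs.counts.shape}")
    m = obs.counts[~obs.mask]
    p = np.maximum(probs[~obs.mask], p_floor)
    nonzero = m > 0
    if (p[nonzero] == 0).any():
        return float("-inf")
    return float((m[nonzero] * np.log10(p[nonzero])).sum())


# --------------------------------------------------------------------------
# model / results
# --------------------------------------------------------------------------


class SFSDemographicModel:
    """Composite-likelihood demographic model for an observed folded SFS.

    Parameters
    ----------
    sfs : SFSArray
        Observed spectrum (folded, by convention).
    builder : callable or int
        Either a registry model id (1..8) or a callable mapping a full
        parameter dict to a :class:`DemographyModel`.
    free_params : dict of name -> (lower, upper)
        Search bounds for the free parameters; sizes and times are searched
        on a log10 scale, parameters bounded in [0, 1] (admixture fractions)
        on a linear scale.
    fixed_params : dict
        Values for every other parameter the builder needs.
    sample_config : SampleConfig
        Sample sizes per population (must match the SFS dimensions).
    n_rep : int
        Genealogy replicates per likelihood evaluation.
    """

    def __init__(
        self,
        sfs: SFSArray,
        builder,
        free_params: dict[str, tuple[float, float]],
        fixed_params: dict | None = None,
        sample_config: SampleConfig | None = None,
        n_rep: int = 1000,
        p_floor: float | None = None,
    ) -> None:
        self.sfs = sfs
        if isinstance(builder, int):
            model_id = builder
            self.builder = lambda params: model_registry(model_id, params=params)
            self.model_id: int | None = model_id
        else:
            self.builder = builder
            self.model_id = None
        self.free_names = list(free_params)
        self.bounds = dict(free_params)
        for name, (lo, hi) in self.bounds.items():
            if not lo < hi:
                raise ValueError(f"empty search range for {name!r}")
        self.fixed_params = dict(fixed_params or {})
        if sample_config is None:
            sample_config = SampleConfig(dict(sfs.sample_sizes), num_loci=1, locus_length=1)
        self.sample_config = sample_config
        self.n_rep = int(n_rep)
        self.p_floor = 1.0 / (10.0 * self.n_rep) if p_floor is None else p_floor
        self._log_scale = {
            name: not (0.0 <= lo and hi <= 1.0) for name, (lo, hi) in self.bounds.items()
        }

    # -- parameter transforms ------------------------------------------------

    def _to_internal(self, values: np.ndarray) -> np.ndarray:
        out = np.empty(len(values))
        for i, name in enumerate(self.free_names):
            out[i] = math.log10(values[i]) if self._log_scale[name] else values[i]
        return out

    def _from_internal(self, x: np.ndarray) -> np.ndarray:
        out = np.empty(len(x))
        for i, name in enumerate(self.free_names):
            out[i] = 10.0 ** x[i] if self._log_scale[name] else x[i]
        return out

    def params_dict(self, values) -> dict:
        params = dict(self.fixed_params)
        params.update(dict(zip(self.free_names, np.asarray(values, dtype=float))))
        return params

    def expected_probs(self, params: dict, seed: int) -> np.ndarray:
        model = self.builder(params)
        return expected_sfs(
            model,
            self.sample_config,
            n_rep=self.n_rep,
            seed=seed,
            fold=self.sfs.folded,
            populations=self.sfs.populations,
        )

    def loglike(self, values, seed: int = 1) -> float:
        """log10 composite likelihood at the given free-parameter values."""
        try:
            probs = self.expected_probs(self.params_dict(values), seed)
        except ValueError:
            return float("-inf")
        return composite_loglik(self.sfs, probs, p_floor=self.p_floor)

    # -- fitting -------------------------------------------------------------

    def fit(
        self,
        n_restarts: int = 3,
        seed: int = 1,
        start: dict | None = None,
        maxiter: int | None = None,
        xatol: float = 1e-3,
        fatol: float = 0.5,
        sim_seed: int | None = None,
    ) -> "DemographicFitResults":
        """Maximize the composite likelihood by seeded multi-start Nelder-Mead.

        Each restart draws its starting point from the (log-transformed)
        search box; every likelihood evaluation within the fit reuses one
        genealogy seed (common random numbers, derived from ``seed`` unless
        ``sim_seed`` pins it explicitly). Deterministic given ``seed``.
        """
        rng = np.random.default_rng(seed)
        drawn = int(rng.integers(1, 2**31 - 1))
        sim_seed = drawn if sim_seed is None else int(sim_seed)
        lo = np.array([self.bounds[n][0] for n in self.free_names])
        hi = np.array([self.bounds[n][1] for n in self.free_names])
        ilo, ihi = self._to_internal(lo), self._to_internal(hi)

        def objective(x: np.ndarray) -> float:
            if (x < ilo).any() or (x > ihi).any():
                return float("inf")
            return -self.loglike(self._from_internal(x), seed=sim_seed)

        if not self.free_names:
            ll = self.loglike(np.empty(0), seed=sim_seed)
            return DemographicFitResults(self, np.empty(0), ll, sim_seed, [(np.empty(0), ll)])

        starts: list[tuple[np.ndarray, bool]] = []
        if start is not None:
            starts.append((self._to_internal(np.array([start[n] for n in self.free_names])), True))
        else:
            starts.append(((ilo + ihi) / 2.0, False))
        while len(starts) < n_restarts:
            starts.append((ilo + rng.random(len(ilo)) * (ihi - ilo), False))

        runs = []
        for x0, warm in starts:
            # initial simplex scaled to the search: a warm start probes ~5%
            # parameter steps (+/-0.02 of a log10 coordinate; the scipy
            # default of 5% of the coordinate would jump ~50%), a cold start
            # spans a fifth of the box
            simplex = [np.array(x0, dtype=float)]
            for i in range(len(x0)):
                step = min(0.02, 0.1 * (ihi[i] - ilo[i])) if warm else 0.2 * (ihi[i] - ilo[i])
                vertex = np.array(x0, dtype=float)
                vertex[i] += step if vertex[i] + step <= ihi[i] else -step
                simplex.append(vertex)
            res = optimize.minimize(
                objective,
                x0,
                method="Nelder-Mead",
                options={
                    "xatol": xatol,
                    "fatol": fatol,
                    "initial_simplex": np.array(simplex),
                    "maxiter": maxiter if maxiter is not None else 120 * len(x0),
                },
            )
            runs.append((self._from_internal(res.x), -res.fun))
        best_values, best_ll = max(runs, key=lambda r: r[1])
        return DemographicFitResults(self, np.asarray(best_values), best_ll, sim_seed, runs)


@dataclass
class DemographicFitResults:
    """Point estimates, composite likelihood and AIC of a demographic fit."""

    model: SFSDemographicModel
    estimates: np.ndarray
    loglik10: float
    sim_seed: int
    restarts: list
    conf_int_: pd.DataFrame | None = None
    boot_replicates: pd.DataFrame | None = None

    @property
    def k(self) -> int:
        """Number of free parameters in this fit."""
        return len(self.model.free_names)

    @property
    def params(self) -> dict:
        return self.model.params_dict(self.estimates)

    @property
    def aic(self) -> float:
        return 2.0 * self.k - 2.0 * LN10 * self.loglik10

    def conf_int(self) -> pd.DataFrame:
        if self.conf_int_ is None:
            raise ValueError("no bootstrap confidence intervals: run bootstrap_ci first")
        return self.conf_int_

    def demography(self) -> DemographyModel:
        return self.model.builder(self.params)

    def summary(self) -> str:
        lines = [
            "Composite-likelihood demographic fit",
            "=" * 44,
            f"free parameters : {self.k}",
            f"log10 likelihood: {self.loglik10:.2f}",
            f"AIC             : {self.aic:.2f}",
            f"MC replicates   : {self.model.n_rep} (seed {self.sim_seed})",
            "-" * 44,
            f"{'parameter':<18}{'estimate':>14}{'95% CI':>22}",
        ]
        for i, name in enumerate(self.model.free_names):
            ci = ""
            if self.conf_int_ is not None:
                row = self.conf_int_.loc[name]
                ci = f"[{row['2.5%']:.4g}, {row['97.5%']:.4g}]"
            lines.append(f"{name:<18}{self.estimates[i]:>14.6g}{ci:>22}")
        for name, value in self.model.fixed_params.items():
            lines.append(f"{name:<18}{value:>14.6g}{'(fixed)':>22}")
        return "\n".join(lines)


def fit_model(
    obs: SFSArray,
    model_id,
    search_ranges: dict[str, tuple[float, float]],
    fixed_params: dict | None = None,
    n_restarts: int = 3,
    n_rep: int = 1000,
    seed: int = 1,
    sample_config: SampleConfig | None = None,
    **fit_kwargs,
) -> DemographicFitResults:
    """Functional wrapper around :class:`SFSDemographicModel` + ``fit``."""
    model = SFSDemographicModel(
        obs, model_id, search_ranges, fixed_params, sample_config, n_rep=n_rep
    )
    return model.fit(n_restarts=n_restarts, seed=seed, **fit_kwargs)


def model_selection(fits) -> pd.DataFrame:
    """Rank models by AIC; ΔAIC is relative to the best model.

    ``fits`` is a list of :class:`DemographicFitResults` or of mappings with
    keys ``model``, ``k`` and ``loglik10``. AIC = 2k - 2*ln(10)*L10 and the
    relative likelihood is exp(-ΔAIC/2).
    """
    if len(fits) == 0:
        raise ValueError("empty model list")
    rows = []
    for i, f in enumerate(fits):
        if isinstance(f, DemographicFitResults):
            label = f.model.model_id if f.model.model_id is not None else f"fit{i + 1}"
            rows.append({"model": label, "k": f.k, "loglik10": f.loglik10})
        else:
            rows.append({"model": f["model"], "k": int(f["k"]), "loglik10": float(f["loglik10"])})
    table = pd.DataFrame(rows)
    table["AIC"] = 2.0 * table["k"] - 2.0 * LN10 * table["loglik10"]
    table["dAIC"] = table["AIC"] - table["AIC"].min()
    table["rel_likelihood"] = np.exp(-table["dAIC"] / 2.0)
    return table.sort_values("AIC", kind="stable").reset_index(drop=True)


def likelihood_surface(
    model: SFSDemographicModel,
    axes: list[np.ndarray],
    seed: int,
    n_rep: int | None = None,
) -> tuple[np.ndarray, list]:
    """Cache expected-SFS cell probabilities on a free-parameter grid.

    ``axes`` gives, per free parameter, grid coordinates in the model's
    internal scale (log10 for sizes/times). The cache depends only on the
    parameters and the genealogy seed, never on the data, so one surface can
    score the composite likelihood of arbitrarily many (resampled or
    simulated) spectra; :func:`bootstrap_ci` accepts it via ``surface=``.
    Pass ``n_rep`` to evaluate the surface with more replicates than the
    fitting model uses (a smoother surface at a one-off cost).
    """
    surface_model = model
    if n_rep is not None and n_rep != model.n_rep:
        surface_model = SFSDemographicModel(
            model.sfs, model.model_id if model.model_id is not None else model.builder,
            model.bounds, model.fixed_params, model.sample_config, n_rep=n_rep,
        )
    mesh = np.meshgrid(*axes, indexing="ij")
    grid = np.stack([m.ravel() for m in mesh], axis=1)
    probs = [
        surface_model.expected_probs(model.params_dict(model._from_internal(x)), seed=seed)
        for x in grid
    ]
    return grid, probs


def bootstrap_ci(
    gm: GenotypeMatrix,
    popmap: PopulationMap,
    results: DemographicFitResults,
    block_span: int = 1000,
    n_boot: int = 100,
    seed: int = 1,
    grid_halfwidth: float = 0.15,
    grid_points: int = 25,
    n_rep: int | None = None,
    surface: tuple[np.ndarray, list] | None = None,
) -> pd.DataFrame:
    """95% block-bootstrap confidence intervals for the fitted parameters.

    1-kb (by default) blocks of sites are resampled with replacement to the
    original block count and each replicate SFS is refitted. Because the
    Monte-Carlo expected spectrum depends on the parameters but not on the
    data, the refits share one cached likelihood surface: cell probabilities
    are precomputed (with the point fit's genealogy seed, i.e. common random
    numbers) on a parameter grid spanning ``grid_halfwidth`` around the
    point estimates (log10 units for sizes/times), and every replicate takes
    the argmax over that grid. Replicate scatter therefore reflects data
    resampling, not Monte-Carlo noise, and resampling degenerate data
    reproduces the point estimate exactly. Percentile 2.5/97.5 intervals are
    attached to ``results`` and returned.
    """
    model = results.model
    if not model.free_names:
        raise ValueError("no free parameters to bootstrap")
    cell_idx, shape, pops, sizes = site_cell_indices(gm, popmap, model.sfs.populations)
    scaff = gm.sites["scaffold"].to_numpy()
    block = (gm.sites["pos"].to_numpy() - 1) // block_span
    keys = pd.Series([f"{s}:{b}" for s, b in zip(scaff, block)])
    groups = keys.groupby(keys, sort=False).groups
    block_cells = [cell_idx[np.asarray(idx)] for idx in groups.values()]
    n_blocks = len(block_cells)
    if n_blocks < 2:
        raise ValueError("block bootstrap requires at least two blocks")

    if surface is not None:
        grid, prob_cache = surface
        grid = np.asarray(grid, dtype=float)
    else:
        # axis-aligned grid (in internal coordinates) around the point estimate
        center = model._to_internal(np.asarray(results.estimates, dtype=float))
        ilo = model._to_internal(np.array([model.bounds[n][0] for n in model.free_names]))
        ihi = model._to_internal(np.array([model.bounds[n][1] for n in model.free_names]))
        axes = [
            np.unique(np.clip(np.linspace(c - grid_halfwidth, c + grid_halfwidth, grid_points), lo, hi))
            for c, lo, hi in zip(center, ilo, ihi)
        ]
        grid, prob_cache = likelihood_surface(model, axes, seed=results.sim_seed, n_rep=n_rep)

    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n_boot):
        chosen = rng.integers(0, n_blocks, size=n_blocks)
        flat = np.concatenate([block_cells[j] for j in chosen])
        counts = np.bincount(flat, minlength=int(np.prod(shape))).astype(float).reshape(shape)
        if model.sfs.folded:
            counts = fold_array(counts)
        boot_sfs = SFSArray(counts, pops, sizes, folded=model.sfs.folded)
        lls = [composite_loglik(boot_sfs, p, p_floor=model.p_floor) for p in prob_cache]
        best = model._from_internal(grid[int(np.argmax(lls))])
        rows.append(dict(zip(model.free_names, best)))
    reps = pd.DataFrame(rows)
    # two interval flavours: raw 2.5/97.5 percentiles, and a normal-method
    # interval (point estimate +/- 1.96 SE on the internal/log scale). With
    # few replicates the extreme percentiles are order-statistic-limited
    # (max attainable coverage ~ (B-1)/(B+1)), so the SE-based interval is
    # the better-calibrated 95% CI at small n_boot.
    internal_reps = np.stack([model._to_internal(r.to_numpy()) for _, r in reps.iterrows()])
    se = internal_reps.std(axis=0, ddof=1) if len(reps) > 1 else np.zeros(len(model.free_names))
    center = model._to_internal(np.asarray(results.estimates, dtype=float))
    ci = pd.DataFrame(
        {
            "2.5%": reps.quantile(0.025),
            "97.5%": reps.quantile(0.975),
            "norm_2.5%": model._from_internal(center - 1.96 * se),
            "norm_97.5%": model._from_internal(center + 1.96 * se),
            "estimate": results.estimates,
        }
    )
    results.conf_int_ = ci
    results.boot_replicates = reps
    return ci


def to_natural_units(
    params: dict, mu: float = 3.5e-9, generations_per_year: float = 2.0
) -> dict:
    """Convert generation-scaled parameters to years / individuals / migrants.

    Times (``T_*``, generations) become years (rounded to integer); sizes
    (``N_*``) are already diploid individuals; forward migration rates named
    ``M_<SOURCE>_<DEST>`` become numbers of migrants per generation,
    N_m = N_recipient * m.
    """
    out: dict = {"mu": mu, "generations_per_year": generations_per_year}
    for name, value in params.items():
        if name.startswith("T_"):
            out[name.replace("T_", "T_years_", 1)] = int(round(value / generations_per_year))
        elif name.startswith("N_"):
            out[name] = value
        elif name.startswith("M_"):
            recipient = name.split("_")[-1]
            n_key = f"N_{recipient}"
            if n_key in params:
                out[name.replace("M_", "Nm_", 1)] = params[n_key] * value
            else:
                out[name] = value
        elif name.startswith("F_"):
            out[name] = value
    return out
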