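"""Coalescent synthetic-data generator.

Produces genotype matrices (and VCFs, via :mod:`lousepop.genio`) and
mitochondrial alignments under parameterised multi-population demographies
with nested splits, admixture pulses and bounded migration epochs, plus
genealogy-level utilities such as the reciprocal-monophyly experiment.

Times are expressed in generations before present throughout, population
sizes as diploid effective sizes (pairwise coalescence rate 1/(2N) per
generation), and mutation rates per site per generation. Genealogies are
drawn from the structured coalescent with msprime; loci are independent and
non-recombining.

The module ships a named default configuration, :func:`study_demography`,
that emulates the sampling structure of a seal-louse population survey:
five focal populations (lice of Arctic, Baltic, Ladoga and Saimaa ringed
seals plus Baltic gray seal) whose effective sizes span three orders of
magnitude, an outgroup (Baikal seal lice), postglacial nested splits, and
optional gene flow between the gray-seal and Baltic ringed-seal louse
populations.

Randomness: every public operation takes one master seed; per-component
child seeds are derived with ``numpy.random.SeedSequence(master).spawn()``
in a fixed order, so each stage is individually reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import msprime
import numpy as np
import pandas as pd

from .genio import MISSING, GenotypeMatrix, PopulationMap

__all__ = [
    "DemographyModel",
    "SampleConfig",
    "GenealogyForest",
    "SimulatedDataset",
    "model_registry",
    "MODEL_PARAMETER_COUNTS",
    "DEFAULT_STUDY_PARAMS",
    "study_demography",
    "study_sample_config",
    "study_population_map",
    "simulate_genealogies",
    "drop_mutations",
    "simulate_dataset",
    "synthesize_vcf_annotations",
    "simulate_mtdna",
    "reciprocal_monophyly_fraction",
]


def child_seeds(master_seed: int, n: int) -> list[int]:
    """Derive ``n`` deterministic msprime-safe child seeds (< 2**31)."""
    states = [ss.generate_state(1)[0] for ss in np.random.SeedSequence(master_seed).spawn(n)]
    return [int(s % (2**31 - 2)) + 1 for s in states]


class MutationOverflowError(ValueError):
    """Raised when the realised mutation count exceeds the locus length."""


# --------------------------------------------------------------------------
# demography specification
# --------------------------------------------------------------------------


@dataclass
class DemographyModel:
    """A multi-population demography.

    Attributes
    ----------
    populations : list of (label, size_spec)
        ``size_spec`` is either a single diploid effective size or a list of
        ``(start_time, size)`` piecewise-constant epochs (first entry at
        time 0).
    splits : list of (time, derived_labels, ancestral_label)
        Backwards in time, the derived populations merge into the ancestral
        one at ``time`` (generations before present).
    pulses : list of (time, source, destination, fraction)
        Forward-time admixture pulse: at ``time`` generations ago a
        ``fraction`` of the destination population's ancestry is replaced by
        migrants from the source population.
    migration_epochs : list of (t_start, t_end, rates)
        Continuous migration over the window ``[t_end, t_start)`` generations
        before present (``t_start`` is the forward-time start, hence the
        older bound; ``t_end >= 0``). ``rates`` is a list of
        ``(source, destination, m)`` entries, forward-time: each generation
        a fraction ``m`` of the destination population is replaced by
        migrants from the source.
    mutation_rate : float, per site per generation.
    generation_time : float, years per generation.
    """

    populations: list[tuple]
    splits: list[tuple] = field(default_factory=list)
    pulses: list[tuple] = field(default_factory=list)
    migration_epochs: list[tuple] = field(default_factory=list)
    mutation_rate: float = 3.5e-9
    generation_time: float = 0.5

    def __post_init__(self) -> None:
        labels = [p[0] for p in self.populations]
        if len(set(labels)) != len(labels):
            raise ValueError("population labels must be unique")
        self._labels = labels
        merge_time = self.merge_times()
        for t, derived, anc in self._normalised_splits():
            if t <= 0:
                raise ValueError(f"split time must be strictly positive, got {t}")
            if anc not in labels:
                raise ValueError(f"unknown ancestral population {anc!r}")
            for d in derived:
                if d not in labels:
                    raise ValueError(f"unknown derived population {d!r}")
            # ancestral must not itself have merged before this split
            if merge_time.get(anc) is not None and merge_time[anc] <= t:
                raise ValueError(
                    f"population {anc!r} receives a split at {t} after merging at {merge_time[anc]}"
                )
        for t, src, dst, frac in self.pulses:
            if not (0.0 <= frac <= 1.0):
                raise ValueError(f"pulse fraction {frac} outside [0, 1]")
            for label in (src, dst):
                self._check_active(label, t, merge_time)
        for t_start, t_end, rates in self.migration_epochs:
            if not (t_start > t_end >= 0):
                raise ValueError(
                    f"migration epoch must have forward-time start older than end: ({t_start}, {t_end})"
                )
            for src, dst, m in rates:
                if m < 0:
                    raise ValueError("negative migration rate")
                for label in (src, dst):
                    self._check_active(label, t_end, merge_time)

    def _normalised_splits(self):
        out = []
        for t, derived, anc in self.splits:
            if isinstance(derived, str):
                derived = [derived]
            out.append((float(t), list(derived), anc))
        return out

    def merge_times(self) -> dict:
        """Time at which each population merges into its ancestor (or None)."""
        merge = {p[0]: None for p in self.populations}
        for t, derived, _anc in self._normalised_splits():
            for d in derived:
                if merge[d] is not None:
                    raise ValueError(f"population {d!r} is derived in two splits")
                merge[d] = float(t)
        return merge

    def _check_active(self, label: str, time: float, merge_time: dict) -> None:
        if label not in merge_time:
            raise ValueError(f"unknown population {label!r}")
        if merge_time[label] is not None and time >= merge_time[label]:
            raise ValueError(
                f"population {label!r} receives an event at {time} after merging "
                f"at {merge_time[label]}"
            )

    @property
    def labels(self) -> list[str]:
        return list(self._labels)

    def sampled_labels(self) -> list[str]:
        """Populations extant at time 0 (never ancestral-only)."""
        ancestral = {anc for _t, _d, anc in self._normalised_splits()}
        return [lab for lab in self._labels if lab not in ancestral]

    def size_epochs(self, label: str) -> list[tuple[float, float]]:
        spec = dict((p[0], p[1]) for p in self.populations)[label]
        if np.isscalar(spec):
            return [(0.0, float(spec))]
        return [(float(t), float(s)) for t, s in spec]

    def to_msprime(self) -> msprime.Demography:
        dem = msprime.Demography()
        ancestral = {anc for _t, _d, anc in self._normalised_splits()}
        for label in self._labels:
            epochs = self.size_epochs(label)
            dem.add_population(
                name=label,
                initial_size=epochs[0][1],
                initially_active=label not in ancestral,
            )
            for t, size in epochs[1:]:
                dem.add_population_parameters_change(time=t, population=label, initial_size=size)
        for t, derived, anc in self._normalised_splits():
            dem.add_population_split(time=t, derived=derived, ancestral=anc)
        for t, src, dst, frac in self.pulses:
            # backwards in time, lineages now in the destination moved from the source
            dem.add_mass_migration(time=t, source=dst, dest=src, proportion=frac)
        for t_start, t_end, rates in self.migration_epochs:
            for src, dst, m in rates:
                # msprime matrix entry (j, k) is the backwards lineage-movement
                # rate j -> k, i.e. forward migration k -> j
                dem.add_migration_rate_change(time=t_end, rate=m, source=dst, dest=src)
                dem.add_migration_rate_change(time=t_start, rate=0, source=dst, dest=src)
        dem.sort_events()
        return dem

    def with_updates(self, **kwargs) -> "DemographyModel":
        return dataclasses.replace(self, **kwargs)


@dataclass
class SampleConfig:
    """How many diploid individuals to sample per population, and the loci."""

    n_per_pop: dict[str, int]
    num_loci: int = 100
    locus_length: int = 1000
    scaffold_labels: list[str] | None = None

    def __post_init__(self) -> None:
        for pop, n in self.n_per_pop.items():
            if n < 0:
                raise ValueError(f"negative sample count for {pop!r}")
        if self.num_loci < 1 or self.locus_length < 1:
            raise ValueError("num_loci and locus_length must be positive")
        if self.scaffold_labels is not None and len(self.scaffold_labels) != self.num_loci:
            raise ValueError("need one scaffold label per locus")

    def scaffold(self, locus: int) -> str:
        if self.scaffold_labels is not None:
            return self.scaffold_labels[locus]
        width = len(str(self.num_loci))
        return f"scaffold_{locus:0{width}d}"

    def individual_labels(self) -> list[str]:
        out = []
        for pop, n in self.n_per_pop.items():
            out.extend(f"{pop}_{i + 1}" for i in range(n))
        return out

    def population_map(self) -> PopulationMap:
        mapping = {}
        for pop, n in self.n_per_pop.items():
            for i in range(n):
                mapping[f"{pop}_{i + 1}"] = pop
        return PopulationMap(mapping, [p for p, n in self.n_per_pop.items() if n > 0])


@dataclass
class GenealogyForest:
    """One non-recombining genealogy per locus (tskit tree sequences)."""

    tree_sequences: list
    model: DemographyModel
    config: SampleConfig
    seed: int

    @property
    def num_loci(self) -> int:
        return len(self.tree_sequences)

    def __iter__(self):
        return iter(self.tree_sequences)

    def sample_populations(self) -> list[str]:
        """Population label of each haploid sample, in sample order."""
        ts = self.tree_sequences[0]
        pops = {p.id: p.metadata.get("name", str(p.id)) for p in ts.populations()}
        return [pops[ts.node(u).population] for u in ts.samples()]


@dataclass
class SimulatedDataset:
    """A genotype matrix plus the truth record that generated it."""

    gm: GenotypeMatrix
    model: DemographyModel
    config: SampleConfig
    seed: int
    ancestral_is_ref: bool = True
    haplotypes: np.ndarray | None = None  # (n_haploids, n_sites) derived indicators

    def population_map(self) -> PopulationMap:
        return self.config.population_map()


# --------------------------------------------------------------------------
# the model registry (eight demographic hypotheses)
# --------------------------------------------------------------------------

#: Free-parameter counts of the eight study models, used for AIC arithmetic
#: on fits that estimate every parameter.
MODEL_PARAMETER_COUNTS = {1: 12, 2: 12, 3: 12, 4: 11, 5: 13, 6: 14, 7: 15, 8: 16}

#: Default parameter values for the named study-mimic configuration.
#: Sizes are diploid effective sizes; times are generations before present
#: (two louse generations per year).
DEFAULT_STUDY_PARAMS = {
    "N_SAIMAA": 4600.0,
    "N_LADOGA": 43_000.0,
    "N_BALTIC": 90_000.0,
    "N_ARCTIC": 4.9e6,
    "N_GRAY": 1.2e6,
    "N_ANC_BALTIC": 1e5,
    "N_ANC_RINGED": 2e6,
    "N_ROOT": 2e6,
    "T_SAIMAA": 16_720.0,
    "T_LADOGA": 15_090.0,
    "T_ARCTIC": 192_179.0,
    "T_GRAY": 4.8e6,
    # outgroup branch
    "N_BAIKAL": 5e5,
    "N_ROOT_ALL": 1e6,
    "T_BAIKAL": 9.6e6,
    # models 2-5 alternative split times
    "T_BALTIC": 16_720.0,
    "T_SAIMAA_LADOGA": 15_090.0,
    "T_LADOGA_FIRST": 16_720.0,
    "T_SAIMAA_BALTIC": 15_090.0,
    "T_SAIMAA_OLD": 250_000.0,
    "T_GHOST": 100_000.0,
    # gene flow (models 6-8)
    "T_PULSE": 10_500.0,
    "F_PULSE": 0.04,
    "M_BALTIC_GRAY": 4.2e-5,
    "M_GRAY_BALTIC": 8.0e-6,
    "T_MIG_START": 11_000.0,
    "T_MIG_END": 10_200.0,
    "MU": 3.5e-9,
    "GENERATION_TIME": 0.5,
}

INGROUP_POPULATIONS = ["arctic", "baltic", "ladoga", "saimaa", "gray"]
OUTGROUP_POPULATION = "baikal"


def _require(params: dict, names: list[str], model_id: int) -> None:
    missing = [n for n in names if n not in params]
    if missing:
        raise ValueError(f"model {model_id} missing parameters: {missing}")


def model_registry(
    model_id: int,
    params: dict | None = None,
    include_outgroup: bool = False,
) -> DemographyModel:
    """Build one of the eight competing demographies for the five-population system.

    Models 1-3 are the three possible split orders of the Saimaa, Ladoga and
    Baltic ringed-seal louse populations within their clade; model 4 places
    the Saimaa split before the Arctic split; model 5 derives the Saimaa and
    Ladoga populations from an unsampled ghost lineage; model 6 adds a single
    admixture pulse from the gray-seal louse population into the Baltic
    ringed-seal louse population; model 7 adds continuous migration between
    those two populations up to the present; model 8 bounds that migration
    within an ancient window with estimated start and end times.

    ``params`` overrides entries of :data:`DEFAULT_STUDY_PARAMS`.
    """
    if model_id not in MODEL_PARAMETER_COUNTS:
        raise ValueError(f"unknown model_id {model_id!r}; expected 1..8")
    p = dict(DEFAULT_STUDY_PARAMS)
    if params:
        unknown = set(params) - set(p)
        if unknown:
            raise ValueError(f"unknown parameters: {sorted(unknown)}")
        p.update(params)

    pops = [
        ("saimaa", p["N_SAIMAA"]),
        ("ladoga", p["N_LADOGA"]),
        ("baltic", p["N_BALTIC"]),
        ("arctic", p["N_ARCTIC"]),
        ("gray", p["N_GRAY"]),
    ]
    splits: list[tuple] = []
    pulses: list[tuple] = []
    epochs: list[tuple] = []

    def clade_splits(first: str, pair: tuple[str, str], t_first: float, t_second: float):
        """First population leaves the Baltic clade at t_first (older); the
        remaining pair split at t_second."""
        if not t_first > t_second:
            raise ValueError(
                f"model {model_id} requires the first clade split ({t_first}) to be "
                f"older than the second ({t_second})"
            )
        pops.append(("anc_pair", p["N_ANC_BALTIC"]))
        pops.append(("anc_baltic", p["N_ANC_BALTIC"]))
        splits.append((t_second, list(pair), "anc_pair"))
        splits.append((t_first, [first, "anc_pair"], "anc_baltic"))
        return "anc_baltic"

    if model_id in (1, 6, 7, 8):
        _require(p, ["T_SAIMAA", "T_LADOGA"], model_id)
        clade_root = clade_splits("saimaa", ("ladoga", "baltic"), p["T_SAIMAA"], p["T_LADOGA"])
    elif model_id == 2:
        clade_root = clade_splits("baltic", ("saimaa", "ladoga"), p["T_BALTIC"], p["T_SAIMAA_LADOGA"])
    elif model_id == 3:
        clade_root = clade_splits("ladoga", ("saimaa", "baltic"), p["T_LADOGA_FIRST"], p["T_SAIMAA_BALTIC"])
    elif model_id == 4:
        # Saimaa diverges from the ringed lineage before the Arctic split;
        # the Baltic+Ladoga ancestor shares the ringed-ancestor size (11 free
        # parameters, matching the study's model-4 count)
        if not p["T_SAIMAA_OLD"] > p["T_ARCTIC"]:
            raise ValueError("model 4 requires the Saimaa split older than the Arctic split")
        pops.append(("anc_pair", p["N_ANC_RINGED"]))
        splits.append((p["T_LADOGA"], ["ladoga", "baltic"], "anc_pair"))
        clade_root = "anc_pair"
    elif model_id == 5:
        # Saimaa and Ladoga descend from an unsampled ghost lineage (its size
        # shares the clade-ancestor parameter: 13 free parameters)
        if not (p["T_GHOST"] > p["T_SAIMAA"] > p["T_LADOGA"]):
            raise ValueError("model 5 requires T_GHOST > T_SAIMAA > T_LADOGA")
        pops.append(("ghost", p["N_ANC_BALTIC"]))
        pops.append(("anc_ghost", p["N_ANC_BALTIC"]))
        pops.append(("anc_baltic", p["N_ANC_BALTIC"]))
        splits.append((p["T_LADOGA"], ["ladoga"], "ghost"))
        splits.append((p["T_SAIMAA"], ["saimaa", "ghost"], "anc_ghost"))
        splits.append((p["T_GHOST"], ["baltic", "anc_ghost"], "anc_baltic"))
        clade_root = "anc_baltic"

    pops.append(("anc_ringed", p["N_ANC_RINGED"]))
    pops.append(("root", p["N_ROOT"]))
    if model_id == 4:
        pops.append(("anc_saimaa", p["N_ANC_RINGED"]))
        splits.append((p["T_ARCTIC"], [clade_root, "arctic"], "anc_ringed"))
        splits.append((p["T_SAIMAA_OLD"], ["saimaa", "anc_ringed"], "anc_saimaa"))
        splits.append((p["T_GRAY"], ["anc_saimaa", "gray"], "root"))
    else:
        splits.append((p["T_ARCTIC"], [clade_root, "arctic"], "anc_ringed"))
        splits.append((p["T_GRAY"], ["anc_ringed", "gray"], "root"))

    if model_id == 6:
        if not p["T_PULSE"] < p["T_LADOGA"]:
            raise ValueError("model 6 pulse must postdate the Baltic/Ladoga split")
        pulses.append((p["T_PULSE"], "gray", "baltic", p["F_PULSE"]))
    elif model_id in (7, 8):
        t_end = 0.0 if model_id == 7 else p["T_MIG_END"]
        t_start = p["T_MIG_START"]
        if not t_start > t_end:
            raise ValueError("migration window start must be older than its end")
        if t_start >= p["T_LADOGA"]:
            raise ValueError(
                "migration window must lie within the Baltic population's existence "
                f"(start {t_start} >= Baltic/Ladoga split {p['T_LADOGA']})"
            )
        epochs.append(
            (
                t_start,
                t_end,
                [
                    ("baltic", "gray", p["M_BALTIC_GRAY"]),
                    ("gray", "baltic", p["M_GRAY_BALTIC"]),
                ],
            )
        )

    if include_outgroup:
        pops.append(("baikal", p["N_BAIKAL"]))
        pops.append(("root_all", p["N_ROOT_ALL"]))
        splits.append((p["T_BAIKAL"], ["root", "baikal"], "root_all"))

    return DemographyModel(
        populations=pops,
        splits=splits,
        pulses=pulses,
        migration_epochs=epochs,
        mutation_rate=p["MU"],
        generation_time=p["GENERATION_TIME"],
    )


def study_demography(model_id: int = 1, include_outgroup: bool = True, **overrides) -> DemographyModel:
    """The named default study-mimic demography (see module docstring)."""
    return model_registry(model_id, params=overrides or None, include_outgroup=include_outgroup)


def study_sample_config(num_loci: int = 1000, locus_length: int = 1000,
                        include_outgroup: bool = True) -> SampleConfig:
    """Default sampling design: 3/5/4/4/3 focal lice + 3 outgroup lice."""
    counts = {"arctic": 3, "baltic": 5, "ladoga": 4, "saimaa": 4, "gray": 3}
    if include_outgroup:
        counts["baikal"] = 3
    return SampleConfig(counts, num_loci=num_loci, locus_length=locus_length)


def study_population_map(include_outgroup: bool = True) -> PopulationMap:
    return study_sample_config(include_outgroup=include_outgroup).population_map()


# --------------------------------------------------------------------------
# simulation operations
# --------------------------------------------------------------------------


def _sim_replicates(model: DemographyModel, cfg: SampleConfig, seed: int):
    sampled = set(model.sampled_labels())
    bad = [pop for pop, n in cfg.n_per_pop.items() if n > 0 and pop not in sampled]
    if bad:
        raise ValueError(f"cannot sample from non-extant population(s) {bad}")
    samples = {pop: n for pop, n in cfg.n_per_pop.items() if n > 0}
    return msprime.sim_ancestry(
        samples=samples,
        demography=model.to_msprime(),
        ploidy=2,
        sequence_length=cfg.locus_length,
        num_replicates=cfg.num_loci,
        random_seed=seed,
    )


def simulate_genealogies(model: DemographyModel, cfg: SampleConfig, seed: int) -> GenealogyForest:
    """Draw one structured-coalescent genealogy per locus (no recombination)."""
    ts_list = list(_sim_replicates(model, cfg, seed))
    return GenealogyForest(ts_list, model, cfg, seed)


def _descendant_matrix(tree, num_nodes: int, sample_ids: np.ndarray) -> np.ndarray:
    """Boolean (num_nodes x n_samples) matrix of sample descent."""
    n = len(sample_ids)
    desc = np.zeros((num_nodes, n), dtype=bool)
    col = {int(s): j for j, s in enumerate(sample_ids)}
    for u in tree.nodes(order="postorder"):
        if u in col:
            desc[u, col[u]] = True
        parent = tree.parent(u)
        if parent != -1:
            desc[parent] |= desc[u]
    return desc


def _mutate_tree(ts, mu: float, locus_length: int, rng: np.random.Generator):
    """Place infinite-sites mutations on a single-tree genealogy.

    Returns (positions, dosage-per-haploid matrix) with positions 1-based and
    unique within the locus; raises MutationOverflowError when the realised
    mutation count exceeds the locus length.
    """
    tree = ts.first()
    total = tree.total_branch_length
    n_mut = rng.poisson(mu * locus_length * total)
    if n_mut == 0:
        return np.empty(0, dtype=int), np.empty((0, ts.num_samples), dtype=bool)
    if n_mut > locus_length:
        raise MutationOverflowError(
            f"{n_mut} mutations realised on a {locus_length} bp locus; "
            "increase locus length or lower the mutation rate"
        )
    nodes = [u for u in tree.nodes() if tree.parent(u) != -1]
    lengths = np.array([tree.branch_length(u) for u in nodes])
    picks = rng.choice(len(nodes), size=n_mut, p=lengths / lengths.sum())
    positions = np.sort(rng.choice(locus_length, size=n_mut, replace=False)) + 1
    desc = _descendant_matrix(tree, ts.num_nodes, ts.samples())
    carriers = desc[np.array(nodes)[picks]]
    return positions, carriers


_BASES = np.array(list("ACGT"))


def drop_mutations(
    forest: GenealogyForest,
    mu: float | None = None,
    locus_length: int | None = None,
    seed: int = 0,
    keep_haplotypes: bool = False,
) -> SimulatedDataset:
    """Drop infinite-sites mutations on every locus genealogy.

    Haploid genomes are paired into diploid individuals in sampling order;
    the ancestral allele is recorded as the REF allele, so polarity against
    the simulated truth is preserved. Only biallelic sites arise (each site
    hosts exactly one mutation).
    """
    if mu is None:
        mu = forest.model.mutation_rate
    if locus_length is None:
        locus_length = forest.config.locus_length
    rng = np.random.default_rng(seed)
    labels = forest.config.individual_labels()
    n_ind = len(labels)

    scaffs, poss, refs, alts = [], [], [], []
    dosage_chunks = []
    hap_chunks = [] if keep_haplotypes else None
    for k, ts in enumerate(forest.tree_sequences):
        positions, carriers = _mutate_tree(ts, mu, locus_length, rng)
        if len(positions) == 0:
            continue
        ref_idx = rng.integers(0, 4, size=len(positions))
        alt_off = rng.integers(1, 4, size=len(positions))
        scaffs.extend([forest.config.scaffold(k)] * len(positions))
        poss.extend(positions.tolist())
        refs.extend(_BASES[ref_idx].tolist())
        alts.extend(_BASES[(ref_idx + alt_off) % 4].tolist())
        dosage_chunks.append(carriers.reshape(len(positions), n_ind, 2).sum(axis=2))
        if keep_haplotypes:
            hap_chunks.append(carriers)

    if dosage_chunks:
        genotypes = np.concatenate(dosage_chunks, axis=0).T.astype(np.int8)
        haplotypes = np.concatenate(hap_chunks, axis=0).T if keep_haplotypes else None
    else:
        genotypes = np.zeros((n_ind, 0), dtype=np.int8)
        haplotypes = np.zeros((2 * n_ind, 0), dtype=bool) if keep_haplotypes else None
    sites = pd.DataFrame(
        {"scaffold": scaffs, "pos": poss, "ref": refs, "alt": alts,
         "qual": np.full(len(poss), np.nan)},
    )
    gm = GenotypeMatrix(labels, sites, genotypes)
    return SimulatedDataset(gm, forest.model, forest.config, forest.seed, haplotypes=haplotypes)


def simulate_dataset(
    model: DemographyModel, cfg: SampleConfig, seed: int, keep_haplotypes: bool = False
) -> SimulatedDataset:
    """Genealogies plus mutations in one streaming pass (master seed -> stages)."""
    anc_seed, mut_seed = child_seeds(seed, 2)
    forest = GenealogyForest(list(_sim_replicates(model, cfg, anc_seed)), model, cfg, seed)
    return drop_mutations(forest, seed=mut_seed, keep_haplotypes=keep_haplotypes)


def synthesize_vcf_annotations(
    ds: SimulatedDataset,
    depth_mean: float = 80.0,
    gq_model: tuple[float, float] = (75.0, 15.0),
    missing_rate: float = 0.0,
    error_sites_rate: float = 0.0,
    seed: int = 0,
    qual_model: tuple[float, float] = (500.0, 150.0),
) -> SimulatedDataset:
    """Attach stochastic DP/GQ/QUAL layers and artefacts to a simulated dataset.

    DP is Poisson around ``depth_mean`` (genotypes with DP=0 become missing);
    GQ is normal with the given (mean, sd), rounded and clamped to [0, 99];
    a fraction ``error_sites_rate`` of sites is converted into
    all-heterozygous artefacts mimicking collapsed repeats; ``missing_rate``
    knocks out random genotypes.
    """
    for name, rate in (("missing_rate", missing_rate), ("error_sites_rate", error_sites_rate)):
        if not (0.0 <= rate <= 1.0):
            raise ValueError(f"{name} must be in [0, 1], got {rate}")
    if depth_mean < 0:
        raise ValueError("depth_mean must be non-negative")
    rng = np.random.default_rng(seed)
    gm = ds.gm.copy()
    n, s = gm.genotypes.shape
    dp = rng.poisson(depth_mean, size=(n, s)).astype(np.int32)
    gq = np.clip(np.round(rng.normal(gq_model[0], gq_model[1], size=(n, s))), 0, 99).astype(np.int32)
    qual = np.clip(rng.normal(qual_model[0], qual_model[1], size=s), 0.0, None)
    artefact = rng.random(s) < error_sites_rate
    gm.genotypes[:, artefact] = 1
    gm.genotypes[rng.random((n, s)) < missing_rate] = MISSING
    gm.genotypes[dp == 0] = MISSING
    gm.dp = dp
    gm.gq = gq
    gm.sites = gm.sites.assign(qual=np.round(qual, 2))
    return SimulatedDataset(gm, ds.model, ds.config, ds.seed, ds.ancestral_is_ref, ds.haplotypes)


def simulate_mtdna(tree, length: int, subst_rate: float, seed: int = 0):
    """Evolve a nucleotide alignment along a single (maternal, haploid) genealogy.

    Jukes-Cantor substitution: on a branch of ``t`` generations each site
    changes with probability (3/4)(1 - exp(-4*r*t/3)), drawing the new base
    uniformly from the three alternatives.
    """
    from .genio import SeqAlignment

    if length <= 0:
        raise ValueError("alignment length must be positive")
    if hasattr(tree, "first"):
        ts = tree
        tree = ts.first()
    else:
        ts = tree.tree_sequence
    rng = np.random.default_rng(seed)
    seqs = {}
    root_seq = rng.integers(0, 4, size=length).astype(np.int8)
    for root in tree.roots:
        seqs[root] = root_seq
        for u in tree.nodes(root, order="preorder"):
            if u == root:
                continue
            t = tree.branch_length(u)
            p_change = 0.75 * (1.0 - np.exp(-4.0 * subst_rate * t / 3.0))
            parent_seq = seqs[tree.parent(u)]
            child = parent_seq.copy()
            hit = rng.random(length) < p_change
            if hit.any():
                child[hit] = (child[hit] + rng.integers(1, 4, size=int(hit.sum()))) % 4
            seqs[u] = child
    labels = [f"hap_{int(u)}" for u in ts.samples()]
    sequences = ["".join(_BASES[seqs[int(u)]]) for u in ts.samples()]
    return SeqAlignment(labels, sequences)


def two_population_model(Ne: float, T: float, mu: float = 3.5e-9) -> DemographyModel:
    """Clean two-population split at T generations, constant diploid size Ne."""
    return DemographyModel(
        populations=[("pop1", Ne), ("pop2", Ne), ("anc", Ne)],
        splits=[(T, ["pop1", "pop2"], "anc")] if T != 0 else [],
        mutation_rate=mu,
    )


def reciprocal_monophyly_fraction(
    Ne: float, T: float, n_per_pop: int, n_loci: int, seed: int
) -> float:
    """Fraction of independent loci at which two isolated population samples
    are reciprocally monophyletic.

    Two populations of constant diploid size ``Ne`` split ``T`` generations
    ago with no migration; ``n_per_pop`` haploid genomes are sampled from
    each. A locus counts when each population's sample forms an exclusive
    clade in the locus genealogy.
    """
    if n_per_pop < 2:
        raise ValueError("need at least two haploid samples per population")
    if n_loci < 1:
        raise ValueError("need at least one locus")
    if T > 0:
        model = two_population_model(Ne, T)
        samples = [
            msprime.SampleSet(n_per_pop, population="pop1", ploidy=1),
            msprime.SampleSet(n_per_pop, population="pop2", ploidy=1),
        ]
    else:
        model = DemographyModel(populations=[("pop1", Ne)])
        samples = [msprime.SampleSet(2 * n_per_pop, population="pop1", ploidy=1)]
    reps = msprime.sim_ancestry(
        samples=samples,
        demography=model.to_msprime(),
        ploidy=2,
        num_replicates=n_loci,
        random_seed=seed,
    )
    hits = 0
    for ts in reps:
        tree = ts.first()
        ids = ts.samples()
        set_a, set_b = ids[:n_per_pop], ids[n_per_pop:]
        mono_a = tree.num_samples(tree.mrca(*set_a)) == n_per_pop
        mono_b = tree.num_samples(tree.mrca(*set_b)) == n_per_pop
        hits += mono_a and mono_b
    return hits / n_loci
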