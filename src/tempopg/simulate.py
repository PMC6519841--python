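"""Simulation of serially sampled island metapopulations.

Two independent engines are provided:

* :func:`simulate_snp_table` — coalescent simulation (msprime) of an island
  model with deme-size and migration-rate changes, sampling lineages at the
  present and again ``t_hist_sample`` generations in the past, mirroring a
  museum (historic) versus resurvey (modern) contrast;
* :func:`wf_forward_oracle` — a discrete-generation Wright-Fisher forward
  simulator with binomial drift, island migration and mutation influx, used
  in tests as an independent cross-check of the coalescent path.

:class:`SummaryPipeline` fixes the *entire* processing chain (simulate ->
matched SNP filtering -> pool periods -> joint SFS -> projection -> folding
-> binning) so that simulated reference tables and observed data are
guaranteed to receive identical treatment — the property ABC validity
rests on.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import msprime
import numpy as np
import pandas as pd

from .demography import HistoryParams, ModelSpec, draw_history
from .sfs import Spectrum2D, bin_joint_sfs, build_joint_sfs, fold_joint_sfs, project_joint_sfs
from .snptable import DEAMINATION_CLASSES, SNPTable, UNPOLARIZED, filter_snp_classes, group_label

__all__ = [
    "SamplingConfig",
    "GenomeConfig",
    "SummaryPipeline",
    "ReferenceTable",
    "simulate_snp_table",
    "matched_filter",
    "observed_excluded_fraction",
    "build_reference_table",
    "wf_forward_oracle",
    "wf_drift_frequencies",
    "to_msprime_demography",
]

SIZE_FLOOR = 10.0  # smallest deme size (individuals) an expansion may reach


@dataclass(frozen=True)
class SamplingConfig:
    """Diploid sample sizes per deme for the modern and historic periods."""

    modern: tuple
    historic: tuple

    def __post_init__(self) -> None:
        object.__setattr__(self, "modern", tuple(int(k) for k in self.modern))
        object.__setattr__(self, "historic", tuple(int(k) for k in self.historic))
        if len(self.modern) != len(self.historic):
            raise ValueError("modern and historic must list the same demes")
        if any(k < 0 for k in self.modern + self.historic):
            raise ValueError("sample sizes must be >= 0")
        if sum(self.modern) == 0 or sum(self.historic) == 0:
            raise ValueError("each period needs at least one sampled diploid")

    @property
    def n_demes(self) -> int:
        return len(self.modern)

    def groups(self) -> list[str]:
        out = [group_label("hist", d) for d, k in enumerate(self.historic) if k > 0]
        out += [group_label("mod", d) for d, k in enumerate(self.modern) if k > 0]
        return out

    def chromosomes(self, period: str) -> int:
        sizes = self.historic if period == "hist" else self.modern
        return 2 * sum(sizes)


@dataclass(frozen=True)
class GenomeConfig:
    """Independent-locus genome: ``n_loci`` stretches of ``locus_length`` bp."""

    n_loci: int = 1000
    locus_length: float = 1000.0
    mu: float = 1e-8
    recombination: float = 0.0

    def __post_init__(self) -> None:
        if self.n_loci < 1 or self.locus_length <= 0 or self.mu < 0 or self.recombination < 0:
            raise ValueError("invalid genome configuration")

    @property
    def total_length(self) -> float:
        return self.n_loci * self.locus_length


# ---------------------------------------------------------------------------
# history -> msprime


def _scalar_or_pairs(rate, n_demes: int) -> np.ndarray:
    """Symmetric per-pair migration matrix from a scalar or pair dict."""
    m = np.zeros((n_demes, n_demes))
    if rate is None:
        return m
    if isinstance(rate, dict):
        for pair, r in rate.items():
            i, j = (int(v) for v in pair.split("-"))
            m[i, j] = m[j, i] = r
    else:
        m[:] = rate
        np.fill_diagonal(m, 0.0)
    return m


def to_msprime_demography(h: HistoryParams, n_demes: int) -> msprime.Demography:
    """Translate a history into an msprime demography (time backwards).

    The modern epoch starts at the present with per-deme size ``Ne_mod`` and
    (for bottleneck histories) backward growth ``-r_shrink``, so that the
    deme declines into the present. Expansion histories decay exponentially
    backwards from ``t_grow_stop`` and are floored at ``SIZE_FLOOR``
    individuals by a final constant epoch.
    """
    if n_demes > 1:
        hist_m = _scalar_or_pairs(h.m_hist, n_demes)
        if not hist_m.any():
            raise ValueError(
                "zero historic migration with multiple demes: lineages in different "
                "demes could never find common ancestry"
            )
    dem = msprime.Demography()
    g0 = -(h.r_shrink or 0.0) if h.r_shrink is not None else 0.0
    for d in range(n_demes):
        dem.add_population(name=f"deme{d}", initial_size=h.Ne_mod, growth_rate=g0)
    if n_demes > 1:
        mod_m = _scalar_or_pairs(h.m_mod if h.m_mod is not None else h.m_hist, n_demes)
        dem.migration_matrix[:] = mod_m
    size_now = h.Ne_mod
    if h.r_shrink is not None:
        t_shrink = h.t_shrink if h.t_shrink is not None else h.t_hist_sample
        size_now = h.Ne_mod * math.exp(h.r_shrink * t_shrink)
        dem.add_population_parameters_change(
            time=t_shrink, initial_size=size_now, growth_rate=0.0
        )
    if h.r_grow is not None:
        t_stop = float(h.t_grow_stop)
        dem.add_population_parameters_change(time=t_stop, growth_rate=h.r_grow)
        if size_now > SIZE_FLOOR:
            t_floor = t_stop + math.log(size_now / SIZE_FLOOR) / h.r_grow
            dem.add_population_parameters_change(
                time=t_floor, initial_size=SIZE_FLOOR, growth_rate=0.0
            )
    if n_demes > 1 and h.t_mig_change is not None:
        hist_m = _scalar_or_pairs(h.m_hist, n_demes)
        if isinstance(h.m_hist, dict):
            for pair, r in h.m_hist.items():
                i, j = (int(v) for v in pair.split("-"))
                dem.add_migration_rate_change(time=h.t_mig_change, rate=r,
                                              source=f"deme{i}", dest=f"deme{j}")
                dem.add_migration_rate_change(time=h.t_mig_change, rate=r,
                                              source=f"deme{j}", dest=f"deme{i}")
        else:
            dem.add_migration_rate_change(time=h.t_mig_change, rate=float(h.m_hist))
    dem.sort_events()
    return dem


# ---------------------------------------------------------------------------
# coalescent SNP tables


def _sample_sets(h: HistoryParams, sampling: SamplingConfig) -> list[msprime.SampleSet]:
    sets = []
    for d, k in enumerate(sampling.modern):
        if k > 0:
            sets.append(msprime.SampleSet(k, population=f"deme{d}", time=0))
    for d, k in enumerate(sampling.historic):
        if k > 0:
            sets.append(msprime.SampleSet(k, population=f"deme{d}", time=h.t_hist_sample))
    return sets


def simulate_snp_table(
    h: HistoryParams,
    spec: ModelSpec | int,
    sampling: SamplingConfig,
    genome: GenomeConfig,
    seed: int,
) -> SNPTable:
    """Coalescent simulation of biallelic SNPs under a temporal island model.

    Loci are simulated as independent msprime replicates; mutations follow
    an infinite-sites binary model, so every site is biallelic with known
    ancestral state. The returned table has one group per sampled
    (period, deme) with chromosome totals equal to twice the diploid sample
    sizes, and keeps only sites segregating in the union of all samples.
    """
    n_demes = spec.n_demes if isinstance(spec, ModelSpec) else int(spec)
    if sampling.n_demes != n_demes:
        raise ValueError(f"sampling lists {sampling.n_demes} demes, history has {n_demes}")
    dem = to_msprime_demography(h, n_demes)
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 0xC0A1)))
    anc_seed, mut_seed = (int(s) for s in rng.integers(1, 2**31 - 1, size=2))
    reps = msprime.sim_ancestry(
        samples=_sample_sets(h, sampling),
        demography=dem,
        sequence_length=genome.locus_length,
        recombination_rate=genome.recombination,
        num_replicates=genome.n_loci,
        random_seed=anc_seed,
        ploidy=2,
    )
    mut_seeds = np.random.default_rng(mut_seed).integers(1, 2**31 - 1, size=genome.n_loci)
    groups = sampling.groups()
    masks = None
    site_id, contig, position, xs = [], [], [], []
    for locus, ts in enumerate(reps):
        mts = msprime.sim_mutations(
            ts,
            rate=genome.mu,
            random_seed=int(mut_seeds[locus]),
            model=msprime.BinaryMutationModel(),
            discrete_genome=False,
        )
        if masks is None:
            samples = mts.samples()
            pops = np.array([mts.node(u).population for u in samples])
            times = np.array([mts.node(u).time for u in samples])
            masks = {}
            for g in groups:
                period, deme = g.split(":")
                d = int(deme[1:])  # populations are added in deme order
                t = 0.0 if period == "mod" else float(h.t_hist_sample)
                masks[g] = (pops == d) & np.isclose(times, t)
        if mts.num_sites == 0:
            continue
        gm = mts.genotype_matrix()  # (sites, sample chromosomes), entries 0/1
        pos = mts.tables.sites.position
        counts = np.column_stack([gm[:, masks[g]].sum(axis=1) for g in groups])
        for k in range(mts.num_sites):
            site_id.append(f"L{locus}_S{k}")
            contig.append(f"locus{locus}")
            position.append(int(pos[k]) + 1)
        xs.append(counts)
    if xs:
        x = np.vstack(xs)
    else:
        x = np.zeros((0, len(groups)), dtype=np.int64)
    n = np.tile(
        np.array([2 * (sampling.historic if g.startswith("hist") else sampling.modern)[int(g.split(":d")[1])]
                  for g in groups], dtype=np.int64),
        (len(site_id), 1),
    )
    table = SNPTable(
        site_id=np.array(site_id, dtype=object),
        contig=np.array(contig, dtype=object),
        position=np.array(position, dtype=np.int64),
        anc=np.array(["A"] * len(site_id), dtype=object),
        der=np.array(["G"] * len(site_id), dtype=object),
        x=x,
        n=n,
        groups=groups,
    )
    return table.drop_nonsegregating()


# ---------------------------------------------------------------------------
# matched filtering

#: The twelve ordered substitution types.
SUBSTITUTION_TYPES = [(a, b) for a in "ACGT" for b in "ACGT" if a != b]


def matched_filter(
    table: SNPTable,
    excluded_probability: float | None = None,
    class_probs: dict | None = None,
    classes: Sequence[frozenset] = DEAMINATION_CLASSES,
    seed: int = 0,
) -> tuple[SNPTable, int]:
    """Apply the observed-data SNP-class exclusion to simulated SNPs.

    Coalescent SNPs carry no nucleotide identity, so the ascertainment
    effect of removing deamination-prone classes is reproduced either by

    * the default fast path: independent Bernoulli thinning with the
      excluded-class probability observed in the real data
      (:func:`observed_excluded_fraction`), or
    * assigning each site an (ancestral, derived) pair drawn from
      ``class_probs`` (keys from :data:`SUBSTITUTION_TYPES`) and removing
      excluded classes exactly as :func:`filter_snp_classes` does for
      observed data.

    Returns the filtered table and the number of sites removed.
    """
    rng = np.random.default_rng(seed)
    if class_probs is not None:
        types = list(class_probs.keys())
        probs = np.array([class_probs[t] for t in types], dtype=float)
        if np.any(probs < 0) or not math.isclose(probs.sum(), 1.0, rel_tol=1e-9):
            raise ValueError("class_probs must be a probability distribution")
        draw = rng.choice(len(types), size=table.n_sites, p=probs)
        out = table.take(np.arange(table.n_sites))
        out.anc = np.array([types[i][0] for i in draw], dtype=object)
        out.der = np.array([types[i][1] for i in draw], dtype=object)
        return filter_snp_classes(out, classes)
    p = 0.0 if excluded_probability is None else float(excluded_probability)
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"excluded-class probability {p} outside [0, 1]")
    if p == 0.0:
        return table, 0
    keep = rng.random(table.n_sites) >= p
    return table.take(np.nonzero(keep)[0]), int((~keep).sum())


def observed_excluded_fraction(
    table: SNPTable, classes: Sequence[frozenset] = DEAMINATION_CLASSES
) -> float:
    """Fraction of sites in the excluded classes, before filtering."""
    if table.n_sites == 0:
        return 0.0
    classes = [frozenset(c) for c in classes]
    pairs = [frozenset((a, d)) for a, d in zip(table.anc, table.der)]
    return sum(p in classes for p in pairs) / table.n_sites


# ---------------------------------------------------------------------------
# the observed == simulated processing pipeline


@dataclass(frozen=True)
class SummaryPipeline:
    """The fixed chain from SNP table to ABC summary vector.

    Order of operations: pool periods -> joint SFS (unfolded counts) ->
    hypergeometric projection to the common square grid -> optional folding
    -> diagonal/anti-diagonal binning with half-width ``bin_width``. The
    same object must be used for observed data and every simulation in a
    reference table; :meth:`config` is stored with results so mismatches
    are detectable.
    """

    sampling: SamplingConfig
    genome: GenomeConfig
    fold: bool = True
    bin_width: int = 2
    family: str = "both"
    excluded_probability: float = 0.0
    binner: Callable = bin_joint_sfs

    @property
    def square_n(self) -> int:
        return min(self.sampling.chromosomes("hist"), self.sampling.chromosomes("mod"))

    def config(self) -> dict:
        d = dataclasses.asdict(self)
        d["binner"] = getattr(self.binner, "__name__", str(self.binner))
        return d

    def summary_length(self) -> int:
        z = Spectrum2D(np.zeros((self.square_n + 1, self.square_n + 1)))
        return len(self.binner(z, self.bin_width, self.family).vector())

    def summarize_table(self, table: SNPTable) -> np.ndarray:
        """Bin vector of a SNP table's historic-vs-modern joint SFS."""
        n1 = self.sampling.chromosomes("hist")
        n2 = self.sampling.chromosomes("mod")
        if table.n_sites == 0:
            s = Spectrum2D(np.zeros((n1 + 1, n2 + 1)))
        else:
            s = build_joint_sfs(table, "hist", "mod", polarized=False)
            if (s.n1, s.n2) != (n1, n2):
                raise ValueError(
                    f"table chromosome totals {(s.n1, s.n2)} do not match the "
                    f"pipeline sampling configuration {(n1, n2)}"
                )
        return self.summarize_spectrum(s)

    def summarize_spectrum(self, s: Spectrum2D) -> np.ndarray:
        m = self.square_n
        s = project_joint_sfs(s, m, m)
        if self.fold and not s.folded:
            s = fold_joint_sfs(s)
        return self.binner(s, self.bin_width, self.family).vector()

    def simulate_summary(
        self, h: HistoryParams, spec: ModelSpec | int, seed: int
    ) -> np.ndarray:
        table = self.simulate_table(h, spec, seed)
        return self.summarize_table(table)

    def simulate_table(self, h: HistoryParams, spec: ModelSpec | int, seed: int) -> SNPTable:
        """Simulate and matched-filter one SNP table under this pipeline."""
        ss = np.random.SeedSequence((int(seed), 0x51))
        sim_seed, filt_seed = (int(s) for s in
                               np.random.default_rng(ss).integers(1, 2**31 - 1, size=2))
        table = simulate_snp_table(h, spec, self.sampling, self.genome, sim_seed)
        table, _ = matched_filter(
            table, excluded_probability=self.excluded_probability, seed=filt_seed
        )
        return table


# ---------------------------------------------------------------------------
# reference tables


@dataclass
class ReferenceTable:
    """Bank of simulated (model, parameters, summaries) rows for ABC.

    ``df`` has a ``model`` column, flattened parameter columns (NaN where a
    parameter does not exist under a model) and summary columns ``s0..sK``.
    Standardization constants (per-summary median and MAD over *all* rows
    jointly) are computed once and cached in ``meta``.
    """

    df: pd.DataFrame
    meta: dict = field(default_factory=dict)

    @property
    def summary_cols(self) -> list[str]:
        return [c for c in self.df.columns if c.startswith("s") and c[1:].isdigit()]

    @property
    def param_cols(self) -> list[str]:
        return [c for c in self.df.columns if not (c == "model" or c in self.summary_cols)]

    def summaries(self) -> np.ndarray:
        return self.df[self.summary_cols].to_numpy(dtype=float)

    def standardization(self) -> tuple[np.ndarray, np.ndarray]:
        if "std_median" not in self.meta:
            s = self.summaries()
            med = np.median(s, axis=0)
            mad = np.median(np.abs(s - med), axis=0)
            mad = np.where(mad == 0, 1.0, mad)
            self.meta["std_median"] = med.tolist()
            self.meta["std_mad"] = mad.tolist()
        return (np.asarray(self.meta["std_median"], dtype=float),
                np.asarray(self.meta["std_mad"], dtype=float))

    def subset(self, model_id: str) -> "ReferenceTable":
        """Rows of one model, retaining the *joint* standardization constants."""
        med, mad = self.standardization()
        sub = ReferenceTable(self.df[self.df["model"] == model_id].reset_index(drop=True),
                             meta=dict(self.meta))
        sub.meta["std_median"] = med.tolist()
        sub.meta["std_mad"] = mad.tolist()
        return sub

    def save(self, tsv_path) -> None:
        self.standardization()
        self.df.to_csv(tsv_path, sep="\t", index=False)
        with open(str(tsv_path) + ".json", "w") as fh:
            json.dump(self.meta, fh, indent=1, sort_keys=True)

    @staticmethod
    def load(tsv_path) -> "ReferenceTable":
        df = pd.read_csv(tsv_path, sep="\t")
        try:
            with open(str(tsv_path) + ".json") as fh:
                meta = json.load(fh)
        except FileNotFoundError:
            meta = {}
        return ReferenceTable(df, meta)


def build_reference_table(
    specs: Sequence[ModelSpec],
    n_sims_per_model: int,
    pipeline: SummaryPipeline,
    seed: int,
    out_path=None,
) -> ReferenceTable:
    """Simulate the ABC reference table: draw histories from each model's
    priors, run the full matched pipeline, and record (params, summaries).

    Per-row seeds are derived deterministically from ``(seed, model index,
    replicate index)``, so tables are bit-reproducible and individual rows
    can be recomputed in isolation. When ``out_path`` is given rows are
    appended to the TSV as they are produced.
    """
    if n_sims_per_model < 1:
        raise ValueError("n_sims_per_model must be >= 1")
    rows = []
    k = pipeline.summary_length()
    scols = [f"s{i}" for i in range(k)]
    fh = None
    all_cols: list[str] | None = None
    param_cols: list[str] = []
    for spec in specs:
        probe = draw_history(spec, np.random.default_rng(0))
        for c in probe.to_flat():
            if c not in param_cols:
                param_cols.append(c)
    all_cols = ["model"] + param_cols + scols
    if out_path is not None:
        fh = open(out_path, "w")
        fh.write("\t".join(all_cols) + "\n")
    try:
        for mi, spec in enumerate(specs):
            for ri in range(n_sims_per_model):
                prior_rng = np.random.default_rng(np.random.SeedSequence((int(seed), mi, ri, 0)))
                h = draw_history(spec, prior_rng)
                sim_seed = int(np.random.default_rng(
                    np.random.SeedSequence((int(seed), mi, ri, 1))
                ).integers(1, 2**31 - 1))
                summary = pipeline.simulate_summary(h, spec, sim_seed)
                row = {"model": spec.model_id, **h.to_flat(),
                       **{c: v for c, v in zip(scols, summary)}}
                rows.append(row)
                if fh is not None:
                    fh.write("\t".join(_fmt(row.get(c)) for c in all_cols) + "\n")
                    fh.flush()
    finally:
        if fh is not None:
            fh.close()
    df = pd.DataFrame(rows, columns=all_cols)
    ref = ReferenceTable(df, meta={
        "seed": int(seed),
        "n_sims_per_model": int(n_sims_per_model),
        "models": [s.model_id for s in specs],
        "pipeline": _jsonable(pipeline.config()),
    })
    ref.standardization()
    if out_path is not None:
        with open(str(out_path) + ".json", "w") as fhj:
            json.dump(ref.meta, fhj, indent=1, sort_keys=True)
    return ref


def _fmt(v) -> str:
    if v is None:
        return "nan"
    if isinstance(v, str):
        return v
    return repr(float(v))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


# ---------------------------------------------------------------------------
# Wright-Fisher forward oracle


def wf_drift_frequencies(
    p0: float, Ne: float, t: int, n_rep: int, seed: int = 0
) -> np.ndarray:
    """Allele frequencies after ``t`` generations of pure binomial drift in a
    diploid population of ``2 Ne`` chromosomes, for ``n_rep`` replicate loci."""
    rng = np.random.default_rng(seed)
    n_chrom = int(round(2 * Ne))
    p = np.full(n_rep, p0, dtype=float)
    for _ in range(int(t)):
        p = rng.binomial(n_chrom, p) / n_chrom
    return p


def _deme_size_at(h: HistoryParams, t_before_present: float) -> float:
    """Forward-model deme size at a time before present (individuals)."""
    size = h.Ne_mod
    if h.r_shrink is not None:
        t_shr = h.t_shrink if h.t_shrink is not None else h.t_hist_sample
        size = h.Ne_mod * math.exp(h.r_shrink * min(t_before_present, t_shr))
    if h.r_grow is not None and t_before_present > h.t_grow_stop:
        size *= math.exp(-h.r_grow * (t_before_present - h.t_grow_stop))
        size = max(size, SIZE_FLOOR)
    return max(size, 1.0)


def wf_forward_oracle(
    h: HistoryParams,
    sampling: SamplingConfig,
    n_sites: int | None = None,
    genome: GenomeConfig | None = None,
    seed: int = 0,
    burn_in: int | None = None,
) -> SNPTable:
    """Forward Wright-Fisher simulation of the temporal sampling design.

    Each generation, deme allele frequencies are mixed by island migration,
    then resampled binomially at the deme's current size. The historic
    sample is taken (hypergeometrically, i.e. without replacement) at
    ``t_hist_sample`` generations before present and the modern sample at
    the present; only sites segregating in the union of both samples are
    returned. Intended for desk-scale validation (``Ne_mod <= 5000``).

    Standing variation is either seeded by ``n_sites`` variants with counts
    drawn from the neutral equilibrium law ``P(x) ~ 1/x`` (no new mutation),
    or, when ``genome`` is given, built up from scratch by Poisson mutation
    influx over ``burn_in`` generations (default ``8 Ne``) and maintained
    through the sampling window.
    """
    if h.Ne_mod > 5000:
        raise ValueError("forward oracle is restricted to Ne_mod <= 5000")
    if (n_sites is None) == (genome is None):
        raise ValueError("provide exactly one of n_sites or genome")
    rng = np.random.default_rng(seed)
    d = sampling.n_demes
    t_window = int(round(h.t_hist_sample))

    def mig_matrix(t_before: float) -> np.ndarray:
        use_hist = h.t_mig_change is not None and t_before >= h.t_mig_change
        rate = h.m_hist if (use_hist or h.m_mod is None) else h.m_mod
        m = _scalar_or_pairs(rate, d)
        np.fill_diagonal(m, 1.0 - m.sum(axis=1))
        if np.any(np.diag(m) < 0):
            raise ValueError("total emigration rate exceeds 1")
        return m

    def sizes_at(t_before: float) -> np.ndarray:
        n_chrom = max(int(round(2 * _deme_size_at(h, t_before))), 2)
        return np.full(d, n_chrom, dtype=np.int64)  # island model: equal deme sizes

    # counts[deme, site]: derived chromosomes per deme
    if n_sites is not None:
        # seed every deme independently from the single-population
        # equilibrium law P(x) ~ 1/x (an initial condition, not the joint
        # multi-deme equilibrium; use the genome/burn-in path for that)
        n_hist_chrom = sizes_at(t_window)
        x = np.arange(1, int(n_hist_chrom.min()))
        w = 1.0 / x
        counts = rng.choice(x, size=(d, n_sites), p=w / w.sum()).astype(np.int64)
    else:
        counts = np.zeros((d, 0), dtype=np.int64)
        hist_size = sizes_at(t_window)
        influx = genome.mu * genome.total_length * hist_size  # per deme per gen
        nb = int(burn_in if burn_in is not None else round(8 * h.Ne_mod))
        m = mig_matrix(t_window + 1)
        for _ in range(nb):
            counts = _wf_step(counts, hist_size, hist_size, m, rng)
            new = rng.poisson(influx)
            if new.sum():
                add = np.zeros((d, int(new.sum())), dtype=np.int64)
                col = 0
                for dd in range(d):
                    for _k in range(int(new[dd])):
                        add[dd, col] = 1
                        col += 1
                counts = np.concatenate([counts, add], axis=1)
            seg = (counts.sum(axis=0) > 0) & (counts.sum(axis=0) < hist_size.sum())
            counts = counts[:, seg]

    # historic sample (without replacement within each deme)
    pop_n = sizes_at(t_window)
    x_hist = np.vstack([
        rng.hypergeometric(counts[dd], pop_n[dd] - counts[dd], 2 * sampling.historic[dd])
        if sampling.historic[dd] > 0 and counts.shape[1] else
        np.zeros(counts.shape[1], dtype=np.int64)
        for dd in range(d)
    ])

    # evolve the window 90 -> 0 generations before present
    for step in range(t_window):
        t_before = t_window - step           # parents live at t_before
        n_par = sizes_at(t_before)
        n_off = sizes_at(t_before - 1)
        counts = _wf_step(counts, n_par, n_off, mig_matrix(t_before - 1e-9), rng)
        if genome is not None:
            influx = genome.mu * genome.total_length * n_off
            new = rng.poisson(influx)
            if new.sum():
                add = np.zeros((d, int(new.sum())), dtype=np.int64)
                add_hist = np.zeros((d, int(new.sum())), dtype=np.int64)
                col = 0
                for dd in range(d):
                    for _k in range(int(new[dd])):
                        add[dd, col] = 1
                        col += 1
                counts = np.concatenate([counts, add], axis=1)
                x_hist = np.concatenate([x_hist, add_hist], axis=1)

    pop_n = sizes_at(0)
    x_mod = np.vstack([
        rng.hypergeometric(counts[dd], pop_n[dd] - counts[dd], 2 * sampling.modern[dd])
        if sampling.modern[dd] > 0 and counts.shape[1] else
        np.zeros(counts.shape[1], dtype=np.int64)
        for dd in range(d)
    ])

    groups = sampling.groups()
    cols = []
    ns = []
    for g in groups:
        period, deme = g.split(":d")
        dd = int(deme)
        cols.append(x_hist[dd] if period == "hist" else x_mod[dd])
        ns.append(2 * (sampling.historic[dd] if period == "hist" else sampling.modern[dd]))
    x = np.column_stack(cols) if cols else np.zeros((0, 0), dtype=np.int64)
    n_sites_out = x.shape[0]
    table = SNPTable(
        site_id=np.array([f"wf_{i}" for i in range(n_sites_out)], dtype=object),
        contig=np.array(["wf"] * n_sites_out, dtype=object),
        position=np.arange(1, n_sites_out + 1, dtype=np.int64),
        anc=np.array([UNPOLARIZED] * n_sites_out, dtype=object),
        der=np.array([UNPOLARIZED] * n_sites_out, dtype=object),
        x=x,
        n=np.tile(np.array(ns, dtype=np.int64), (n_sites_out, 1)),
        groups=groups,
    )
    return table.drop_nonsegregating()


def _wf_step(
    counts: np.ndarray,
    n_parent: np.ndarray,
    n_offspring: np.ndarray,
    mig: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """One Wright-Fisher generation: migrant-mixed expected frequencies, then
    binomial resampling at each deme's offspring size (chromosome counts)."""
    if counts.shape[1] == 0:
        return counts
    freq = counts / n_parent[:, None]
    p = mig @ freq
    p = np.clip(p, 0.0, 1.0)
    return rng.binomial(n_offspring[:, None], p)
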