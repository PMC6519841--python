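"""Packaged synthetic scenarios emulating the temporal study design.

Each scenario writes a SNP table TSV plus a ``truth.json`` describing the
generating history and any injected selected sites, so downstream tools
can be validated end-to-end. The default design mirrors a century-scale
museum contrast: an island metapopulation sampled twice, 90 generations
apart, with roughly 50 diploids per period, and a transition-biased
substitution-type distribution so that deamination-class filtering
(C/T and G/A removal) is exercised exactly as on real historic DNA.
"""

from __future__ import annotations

import json
import zlib
from pathlib import Path

import numpy as np

from .demography import HistoryParams, ModelSpec, Prior
from .io import write_snp_table
from .simulate import (
    GenomeConfig,
    SamplingConfig,
    matched_filter,
    simulate_snp_table,
)
from .snptable import SNPTable

__all__ = ["generate_fixtures", "SCENARIOS", "DEFAULT_SUBSTITUTION_PROBS", "scenario_components"]

#: Transition-biased substitution-type distribution (Ts:Tv = 2:1) used to
#: give simulated SNPs nucleotide identities.
DEFAULT_SUBSTITUTION_PROBS = {
    **{pair: 0.125 for pair in [("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")]},
    **{pair: 0.0625 for pair in [
        ("A", "C"), ("C", "A"), ("A", "T"), ("T", "A"),
        ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G"),
    ]},
}


def _base_design():
    """The shared study design: 4-deme island metapopulation, deme size
    1,500, threefold migration decline at the historic sampling time."""
    history = HistoryParams(
        Ne_mod=1500.0,
        m_hist=0.01,
        m_mod=0.01 / 3.0,
        t_mig_change=90.0,
        t_hist_sample=90.0,
        model_id="F",
    )
    spec = ModelSpec(
        model_id="F", n_demes=4, migration_mode="symmetric",
        size_change="none", migration_change=True,
        priors={"Ne_mod": Prior("log-uniform", 1e2, 5e4),
                "m_hist": Prior("log-uniform", 1e-5, 1e-1),
                "m_mod": Prior("log-uniform", 1e-5, 1e-1)},
    )
    sampling = SamplingConfig(modern=(12, 12, 12, 12), historic=(13, 13, 13, 13))
    genome = GenomeConfig(n_loci=400, locus_length=2500.0, mu=1e-8, recombination=0.0)
    elevations = {f"{p}:d{d}": 2600.0 + 200.0 * d
                  for p in ("hist", "mod") for d in range(4)}
    return history, spec, sampling, genome, elevations


def _spread_counts(total: int, sizes: np.ndarray) -> np.ndarray:
    """Largest-remainder split of a pooled derived count across demes."""
    quota = total * sizes / sizes.sum()
    base = np.floor(quota).astype(np.int64)
    rem = total - base.sum()
    order = np.argsort(-(quota - base))
    base[order[:rem]] += 1
    return base


def _inject_outlier(table: SNPTable, sampling: SamplingConfig, rng=None) -> tuple[SNPTable, str]:
    """Append one site forced to sample frequencies 0.2 (historic) and 0.65
    (modern) — the magnitude of shift a strongly selected standing variant
    can reach over ~90 generations. Counts are deterministic: the pooled
    frequency is hit exactly and spread across demes by largest remainder."""
    x_row = np.empty(len(table.groups), dtype=np.int64)
    n_row = np.empty(len(table.groups), dtype=np.int64)
    for period, p in (("hist", 0.2), ("mod", 0.65)):
        sizes = np.array(sampling.historic if period == "hist" else sampling.modern)
        cols = [i for i, g in enumerate(table.groups) if g.startswith(period)]
        demes = [int(table.groups[i].split(":d")[1]) for i in cols]
        chrom = 2 * sizes[demes]
        alloc = _spread_counts(int(round(p * chrom.sum())), chrom)
        for c, k, a in zip(cols, chrom, alloc):
            n_row[c] = k
            x_row[c] = a
    sid = "outlier_0"
    out = SNPTable(
        site_id=np.concatenate([table.site_id, [sid]]),
        contig=np.concatenate([table.contig, ["outlier"]]),
        position=np.concatenate([table.position, [1]]),
        anc=np.concatenate([table.anc, ["A"]]),
        der=np.concatenate([table.der, ["C"]]),
        x=np.vstack([table.x, x_row]),
        n=np.vstack([table.n, n_row]),
        groups=table.groups,
    )
    return out, sid


def scenario_components(scenario: str, seed: int):
    """Build a scenario in memory: (table, truth dict)."""
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {sorted(SCENARIOS)}")
    history, spec, sampling, genome, elevations = _base_design()
    ss = np.random.SeedSequence((int(seed), zlib.crc32(scenario.encode()) & 0x7FFFFFFF))
    sim_seed, class_seed, out_seed = (
        int(v) for v in np.random.default_rng(ss).integers(1, 2**31 - 1, size=3)
    )
    table = simulate_snp_table(history, spec, sampling, genome, sim_seed)
    # assign nucleotide identities (no class excluded yet: filtering is the
    # consumer's job, exactly as for observed data)
    table, _ = matched_filter(
        table, class_probs=DEFAULT_SUBSTITUTION_PROBS, classes=[], seed=class_seed
    )
    selected: list[str] = []
    if scenario == "one_outlier":
        table, sid = _inject_outlier(table, sampling, np.random.default_rng(out_seed))
        selected = [sid]
    truth = {
        "scenario": scenario,
        "seed": int(seed),
        "history": history.to_flat(),
        "model_id": history.model_id,
        "n_demes": spec.n_demes,
        "sampling": {"modern": list(sampling.modern), "historic": list(sampling.historic)},
        "genome": {"n_loci": genome.n_loci, "locus_length": genome.locus_length,
                   "mu": genome.mu, "recombination": genome.recombination},
        "elevations_m": elevations,
        "selected_sites": selected,
    }
    return table, truth


SCENARIOS = {
    "null_4deme": "neutral 4-deme island metapopulation with a threefold "
                  "migration decline 90 generations before present",
    "one_outlier": "the null_4deme design plus one injected site shifting "
                   "from frequency 0.2 (historic) to 0.65 (modern)",
}


def generate_fixtures(scenario: str, seed: int, out_dir) -> dict:
    """Write a scenario's SNP table and truth record; deterministic in ``seed``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table, truth = scenario_components(scenario, seed)
    table_path = out_dir / f"{scenario}.snps.tsv"
    truth_path = out_dir / f"{scenario}.truth.json"
    write_snp_table(table, table_path)
    with open(truth_path, "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return {"table": table_path, "truth": truth_path}
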