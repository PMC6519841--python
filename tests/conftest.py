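"""Shared fixtures: small random SNP tables and toy ABC reference tables."""

import numpy as np
import pandas as pd
import pytest

from tempopg import SNPTable
from tempopg.simulate import ReferenceTable

BASES = np.array(list("ACGT"), dtype=object)


def random_snp_table(n_sites: int, groups, n_chrom, seed: int = 0,
                     polarized: bool = True) -> SNPTable:
    """A random biallelic table, polymorphic in the union of all groups."""
    rng = np.random.default_rng(seed)
    n_chrom = np.asarray(n_chrom, dtype=np.int64)
    n = np.tile(n_chrom, (n_sites, 1))
    x = rng.integers(0, n + 1)
    tot = x.sum(axis=1)
    # force union polymorphism without changing marginal randomness much
    fix_lo = tot == 0
    x[fix_lo, 0] = 1
    fix_hi = x.sum(axis=1) == n.sum(axis=1)
    x[fix_hi, 0] -= 1
    anc = rng.choice(BASES, size=n_sites)
    der = np.array([rng.choice([b for b in BASES if b != a]) for a in anc], dtype=object)
    if not polarized:
        anc = np.array(["."] * n_sites, dtype=object)
        der = anc.copy()
    return SNPTable(
        site_id=np.array([f"s{i}" for i in range(n_sites)], dtype=object),
        contig=np.array(["c1"] * n_sites, dtype=object),
        position=np.arange(1, n_sites + 1, dtype=np.int64),
        anc=anc,
        der=der,
        x=x,
        n=n,
        groups=list(groups),
    )


def toy_reference(summaries_by_model: dict, params_by_model: dict | None = None) -> ReferenceTable:
    """Reference table from explicit summary arrays per model."""
    frames = []
    for model, s in summaries_by_model.items():
        s = np.atleast_2d(np.asarray(s, dtype=float))
        df = pd.DataFrame(s, columns=[f"s{i}" for i in range(s.shape[1])])
        df.insert(0, "model", model)
        if params_by_model and model in params_by_model:
            for name, vals in params_by_model[model].items():
                df[name] = np.asarray(vals, dtype=float)
        frames.append(df)
    big = pd.concat(frames, ignore_index=True)
    cols = ["model"] + [c for c in big.columns if c not in ("model",) and not c.startswith("s")]
    cols += [c for c in big.columns if c.startswith("s")]
    return ReferenceTable(big[cols])


@pytest.fixture
def two_group_table() -> SNPTable:
    return random_snp_table(50, ["hist:d0", "mod:d0"], [10, 12], seed=42)
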