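"""Readers and writers for on-disk formats.

Canonical interchange format for allele-count data is a tab-separated
SNP table (one row per site, ``x_<group>``/``n_<group>`` count columns);
VCF is supported read-only. Joint spectra use the dadi-style text format:
a shape line ``"<n1+1> <n2+1> folded|unfolded"`` followed by the row-major
entries.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import yaml

from .sfs import Spectrum2D
from .snptable import SNPTable, group_label

log = logging.getLogger("tempopg")

__all__ = [
    "write_snp_table",
    "read_snp_table",
    "read_snp_table_vcf",
    "write_spectrum",
    "read_spectrum",
    "load_config",
    "write_provenance",
]


# ---------------------------------------------------------------------------
# SNP table TSV


def write_snp_table(table: SNPTable, path) -> None:
    header = ["site_id", "contig", "pos", "anc", "der"]
    header += [f"x_{g}" for g in table.groups] + [f"n_{g}" for g in table.groups]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(header) + "\n")
        for i in range(table.n_sites):
            row = [str(table.site_id[i]), str(table.contig[i]), str(table.position[i]),
                   str(table.anc[i]), str(table.der[i])]
            row += [str(v) for v in table.x[i]] + [str(v) for v in table.n[i]]
            fh.write("\t".join(row) + "\n")


def read_snp_table(path) -> SNPTable:
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected_fixed = ["site_id", "contig", "pos", "anc", "der"]
        if header[:5] != expected_fixed:
            raise ValueError(f"{path}: header must start with {expected_fixed}")
        groups = [c[2:] for c in header[5:] if c.startswith("x_")]
        n_cols = [c[2:] for c in header[5:] if c.startswith("n_")]
        if groups != n_cols:
            raise ValueError(f"{path}: x_/n_ column groups mismatch: {groups} vs {n_cols}")
        cols = {c: i for i, c in enumerate(header)}
        recs = []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise ValueError(f"{path}:{lineno}: expected {len(header)} fields, got {len(parts)}")
            try:
                recs.append((
                    parts[0], parts[1], int(parts[2]), parts[3], parts[4],
                    [int(parts[cols[f"x_{g}"]]) for g in groups],
                    [int(parts[cols[f"n_{g}"]]) for g in groups],
                ))
            except ValueError as e:
                raise ValueError(f"{path}:{lineno}: malformed row ({e})") from None
    if not recs:
        return SNPTable.empty(groups)
    return SNPTable(
        site_id=np.array([r[0] for r in recs], dtype=object),
        contig=np.array([r[1] for r in recs], dtype=object),
        position=np.array([r[2] for r in recs], dtype=np.int64),
        anc=np.array([r[3] for r in recs], dtype=object),
        der=np.array([r[4] for r in recs], dtype=object),
        x=np.array([r[5] for r in recs], dtype=np.int64),
        n=np.array([r[6] for r in recs], dtype=np.int64),
        groups=groups,
    )


# ---------------------------------------------------------------------------
# VCF


def read_snp_table_vcf(path, sample_map: dict, min_call_fraction: float = 0.5) -> SNPTable:
    """Aggregate a VCF of diploid genotypes into per-group allele counts.

    ``sample_map`` maps VCF sample names to ``(period, deme)`` (an optional
    third element, elevation, is ignored here). Only biallelic SNPs are
    kept; missing genotypes reduce the per-group chromosome total, and
    sites called in fewer than ``min_call_fraction`` of mapped samples are
    dropped. Skip counts are logged. The ALT allele is treated as derived
    and REF as ancestral.
    """
    from cyvcf2 import VCF  # optional dependency, imported lazily

    vcf = VCF(str(path))
    unknown = [s for s in vcf.samples if s not in sample_map]
    if unknown:
        raise ValueError(f"samples missing from sample_map: {unknown}")
    groups = sorted({group_label(*sample_map[s][:2]) for s in vcf.samples})
    gidx = {g: i for i, g in enumerate(groups)}
    sample_group = np.array([gidx[group_label(*sample_map[s][:2])] for s in vcf.samples])
    n_samples = len(vcf.samples)
    recs = []
    skipped = {"non_snp_or_multiallelic": 0, "low_call_rate": 0, "monomorphic": 0}
    for var in vcf:
        if not var.is_snp or len(var.ALT) != 1:
            skipped["non_snp_or_multiallelic"] += 1
            continue
        gt = np.asarray(var.genotype.array())[:, :2]
        called = np.all(gt >= 0, axis=1)
        if called.sum() < min_call_fraction * n_samples:
            skipped["low_call_rate"] += 1
            continue
        x = np.zeros(len(groups), dtype=np.int64)
        n = np.zeros(len(groups), dtype=np.int64)
        alt = gt.sum(axis=1)
        for g in range(len(groups)):
            mask = called & (sample_group == g)
            x[g] = alt[mask].sum()
            n[g] = 2 * mask.sum()
        if not (0 < x.sum() < n.sum()):
            skipped["monomorphic"] += 1
            continue
        recs.append((f"{var.CHROM}:{var.POS}", var.CHROM, var.POS, var.REF, var.ALT[0], x, n))
    log.info("VCF %s: kept %d sites, skipped %s", path, len(recs), skipped)
    if not recs:
        return SNPTable.empty(groups)
    return SNPTable(
        site_id=np.array([r[0] for r in recs], dtype=object),
        contig=np.array([r[1] for r in recs], dtype=object),
        position=np.array([r[2] for r in recs], dtype=np.int64),
        anc=np.array([r[3] for r in recs], dtype=object),
        der=np.array([r[4] for r in recs], dtype=object),
        x=np.array([r[5] for r in recs], dtype=np.int64),
        n=np.array([r[6] for r in recs], dtype=np.int64),
        groups=groups,
    )


# ---------------------------------------------------------------------------
# dadi-style spectrum text


def write_spectrum(s: Spectrum2D, path) -> None:
    """Write a joint SFS in dadi-style text; entries use ``repr`` so the
    round-trip is bit-exact."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{s.n1 + 1} {s.n2 + 1} {'folded' if s.folded else 'unfolded'}\n")
        fh.write(" ".join(repr(float(v)) for v in s.counts.ravel()) + "\n")


def read_spectrum(path) -> Spectrum2D:
    with open(path, encoding="utf-8") as fh:
        shape_line = fh.readline().split()
        if len(shape_line) < 2:
            raise ValueError(f"{path}: malformed shape line")
        d1, d2 = int(shape_line[0]), int(shape_line[1])
        folded = len(shape_line) > 2 and shape_line[2] == "folded"
        values = []
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            values.extend(float(v) for v in line.split())
            if len(values) >= d1 * d2:
                break
    if len(values) < d1 * d2:
        raise ValueError(f"{path}: expected {d1 * d2} entries, found {len(values)}")
    counts = np.array(values[: d1 * d2]).reshape(d1, d2)
    return Spectrum2D(counts, folded=folded)


# ---------------------------------------------------------------------------
# configuration / provenance


def load_config(path) -> dict:
    """Load a YAML or JSON run configuration with light validation."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    return cfg


def write_provenance(out_dir, command: str, config: dict, seed: int | None) -> Path:
    """Record everything needed to re-run a command in the output directory."""
    import tempopg

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    record = {
        "command": command,
        "config": _plain(config),
        "seed": seed,
        "tempopg_version": tempopg.__version__,
        "numpy_version": np.__version__,
    }
    path = out_dir / "provenance.json"
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(record, fh, indent=1, sort_keys=True)
    return path


def _plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _plain(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if callable(obj):
        return getattr(obj, "__name__", str(obj))
    return obj
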