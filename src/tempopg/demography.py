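"""Island-model demographic histories for serially sampled metapopulations.

The catalog crosses four deme-size trajectories (constant, bottleneck into
the present, historic expansion, expansion followed by a bottleneck) with
whether the migration rate changed recently, giving eight model topologies.
Bottleneck onset and migration-rate change are pinned at the historic
sampling time (90 generations before present by default), the natural
changepoint for a century-scale temporal contrast. Time is measured in
generations before present; sizes are effective diploid individuals per
deme; migration rates are per-generation probabilities that a lineage in
one deme originates from one specific other deme.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Literal

import numpy as np

__all__ = [
    "Prior",
    "ModelSpec",
    "HistoryParams",
    "model_catalog",
    "draw_history",
    "validate_history",
    "DEFAULT_PRIORS",
]

SizeChange = Literal["none", "bottleneck", "expansion", "expansion_then_bottleneck"]
MigrationMode = Literal["symmetric", "pairwise"]

#: Lower/upper bounds on deme size (individuals) any drawn history may reach.
SIZE_ENVELOPE = (10.0, 1e6)


@dataclass(frozen=True)
class Prior:
    """Uniform or log-uniform prior over a scalar parameter."""

    shape: Literal["uniform", "log-uniform"]
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            if self.lower == self.upper:  # degenerate point mass is allowed
                return
            raise ValueError(f"prior lower {self.lower} >= upper {self.upper}")
        if self.shape == "log-uniform" and self.lower <= 0:
            raise ValueError("log-uniform prior requires lower > 0")
        if self.shape not in ("uniform", "log-uniform"):
            raise ValueError(f"unknown prior shape {self.shape!r}")

    def draw(self, rng: np.random.Generator) -> float:
        if self.lower == self.upper:
            return float(self.lower)
        if self.shape == "uniform":
            return float(rng.uniform(self.lower, self.upper))
        return float(math.exp(rng.uniform(math.log(self.lower), math.log(self.upper))))


#: Default prior ranges; deliberately wide, overridable in every catalog call.
DEFAULT_PRIORS: dict[str, Prior] = {
    "Ne_mod": Prior("log-uniform", 1e2, 5e4),
    "m": Prior("log-uniform", 1e-5, 1e-1),
    "m_hist": Prior("log-uniform", 1e-5, 1e-1),
    "m_mod": Prior("log-uniform", 1e-5, 1e-1),
    "r_shrink": Prior("uniform", 1e-4, 0.03),
    "r_grow": Prior("uniform", 1e-4, 0.02),
    "t_grow_stop": Prior("uniform", 90.0, 5000.0),
}


def _free_parameters(n_demes: int, size_change: str, migration_change: bool) -> list[str]:
    params = ["Ne_mod"]
    if n_demes > 1:
        params += ["m_hist", "m_mod"] if migration_change else ["m"]
    if size_change in ("expansion", "expansion_then_bottleneck"):
        params += ["r_grow", "t_grow_stop"]
    if size_change in ("bottleneck", "expansion_then_bottleneck"):
        params += ["r_shrink"]
    return params


@dataclass(frozen=True)
class ModelSpec:
    """One demographic model topology plus its free-parameter priors."""

    model_id: str
    n_demes: int
    migration_mode: MigrationMode
    size_change: SizeChange
    migration_change: bool
    fixed_event_time: float | None = 90.0
    priors: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_demes < 1:
            raise ValueError("n_demes must be >= 1")
        if self.migration_mode == "pairwise" and self.n_demes < 2:
            raise ValueError("pairwise migration requires >= 2 demes")
        missing = [p for p in self.free_parameters() if p not in self.priors]
        if missing:
            raise ValueError(f"model {self.model_id}: no prior for {missing}")

    def free_parameters(self) -> list[str]:
        """Names of the parameters drawn from priors, in stable order."""
        return _free_parameters(self.n_demes, self.size_change, self.migration_change)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["priors"] = {k: asdict(v) for k, v in self.priors.items()}
        return d

    @staticmethod
    def from_dict(d: dict) -> "ModelSpec":
        priors = {k: Prior(**v) for k, v in d["priors"].items()}
        return ModelSpec(**{**d, "priors": priors})

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)


@dataclass
class HistoryParams:
    """A concrete parameter realization of a :class:`ModelSpec`.

    Migration rates are scalars under symmetric migration or dicts keyed by
    ``"i-j"`` unordered deme pairs under pairwise migration. Parameters not
    present in the generating model are ``None``.
    """

    Ne_mod: float
    m_hist: float | dict | None = None
    m_mod: float | dict | None = None
    t_mig_change: float | None = None
    r_grow: float | None = None
    t_grow_stop: float | None = None
    r_shrink: float | None = None
    t_shrink: float | None = None
    t_hist_sample: float = 90.0
    generation_time: float = 1.0
    model_id: str | None = None
    extras: dict = field(default_factory=dict)

    def to_flat(self) -> dict[str, float]:
        """Flatten to scalar columns (pairwise rates become ``m_hist_i_j``)."""
        out: dict[str, float] = {}
        for name in ("Ne_mod", "t_mig_change", "r_grow", "t_grow_stop",
                     "r_shrink", "t_shrink", "t_hist_sample", "generation_time"):
            v = getattr(self, name)
            if v is not None:
                out[name] = float(v)
        for name in ("m_hist", "m_mod"):
            v = getattr(self, name)
            if v is None:
                continue
            if isinstance(v, dict):
                for pair, rate in sorted(v.items()):
                    out[f"{name}_{pair.replace('-', '_')}"] = float(rate)
            else:
                out[name] = float(v)
        out.update({k: float(v) for k, v in self.extras.items()})
        return out

    @staticmethod
    def from_flat(row: dict, model_id: str | None = None) -> "HistoryParams":
        scalars = {}
        pair_rates: dict[str, dict] = {}
        for k, v in row.items():
            if v is None or (isinstance(v, float) and math.isnan(v)):
                continue
            for name in ("m_hist", "m_mod"):
                if k.startswith(name + "_"):
                    i, j = k[len(name) + 1:].split("_")
                    pair_rates.setdefault(name, {})[f"{i}-{j}"] = float(v)
                    break
            else:
                scalars[k] = float(v)
        known = {k: v for k, v in scalars.items()
                 if k in HistoryParams.__dataclass_fields__ and k != "extras"}
        extras = {k: v for k, v in scalars.items() if k not in known}
        known.setdefault("Ne_mod", float("nan"))  # rows from toy tables may lack it
        h = HistoryParams(model_id=model_id, extras=extras, **known)
        for name, d in pair_rates.items():
            setattr(h, name, d)
        return h


_LETTERS = {
    ("none", False): "E",
    ("none", True): "F",
    ("bottleneck", False): "A",
    ("bottleneck", True): "B",
    ("expansion", False): "C",
    ("expansion", True): "D",
    ("expansion_then_bottleneck", False): "H",
    ("expansion_then_bottleneck", True): "G",
}


def model_catalog(
    n_demes: int,
    migration_mode: MigrationMode = "symmetric",
    fixed_event_time: float = 90.0,
    priors: dict[str, Prior] | None = None,
) -> list[ModelSpec]:
    """Full factorial catalog of island-model histories.

    Crosses the four size-change options with migration-rate change yes/no,
    yielding eight models with stable single-letter ids (the second letter
    of each pair carries the recent migration change). With a single deme
    migration parameters are absent and pairwise mode is rejected.
    """
    if n_demes < 1:
        raise ValueError("n_demes must be >= 1")
    if migration_mode == "pairwise" and n_demes < 2:
        raise ValueError("pairwise migration mode requires >= 2 demes")
    prior_table = dict(DEFAULT_PRIORS)
    if priors:
        prior_table.update(priors)
    catalog = []
    for size_change in ("none", "bottleneck", "expansion", "expansion_then_bottleneck"):
        for migration_change in (False, True):
            mid = _LETTERS[(size_change, migration_change)]
            needed = _free_parameters(n_demes, size_change, migration_change)
            catalog.append(ModelSpec(
                model_id=mid,
                n_demes=n_demes,
                migration_mode=migration_mode,
                size_change=size_change,  # type: ignore[arg-type]
                migration_change=migration_change,
                fixed_event_time=fixed_event_time,
                priors={p: prior_table[p] for p in needed},
            ))
    return catalog


def _deme_pairs(n_demes: int) -> list[str]:
    return [f"{i}-{j}" for i in range(n_demes) for j in range(i + 1, n_demes)]


def draw_history(spec: ModelSpec, seed: int | np.random.Generator) -> HistoryParams:
    """Draw one history from the model's priors; reproducible from ``seed``."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    def draw_rate(prior: Prior):
        if spec.migration_mode == "pairwise":
            return {pair: prior.draw(rng) for pair in _deme_pairs(spec.n_demes)}
        return prior.draw(rng)

    h = HistoryParams(Ne_mod=spec.priors["Ne_mod"].draw(rng), model_id=spec.model_id,
                      t_hist_sample=spec.fixed_event_time or 90.0)
    if spec.n_demes > 1:
        if spec.migration_change:
            h.m_hist = draw_rate(spec.priors["m_hist"])
            h.m_mod = draw_rate(spec.priors["m_mod"])
            h.t_mig_change = spec.fixed_event_time
        else:
            m = draw_rate(spec.priors["m"])
            h.m_hist = m
            h.m_mod = m
    if spec.size_change in ("expansion", "expansion_then_bottleneck"):
        h.r_grow = spec.priors["r_grow"].draw(rng)
        h.t_grow_stop = spec.priors["t_grow_stop"].draw(rng)
    if spec.size_change in ("bottleneck", "expansion_then_bottleneck"):
        h.r_shrink = spec.priors["r_shrink"].draw(rng)
        h.t_shrink = spec.fixed_event_time
    return h


def validate_history(h: HistoryParams, spec: ModelSpec | None = None) -> list[str]:
    """Return all invariant violations (empty list means the history is valid)."""
    v: list[str] = []
    if not h.Ne_mod > 0:
        v.append(f"Ne_mod must be positive, got {h.Ne_mod}")

    def rates(x):
        if x is None:
            return []
        return list(x.values()) if isinstance(x, dict) else [x]

    for name in ("m_hist", "m_mod"):
        for r in rates(getattr(h, name)):
            if not (0 <= r < 1):
                v.append(f"{name} rate {r} outside [0, 1)")
    for name in ("t_mig_change", "t_grow_stop", "t_shrink", "t_hist_sample"):
        t = getattr(h, name)
        if t is not None and t < 0:
            v.append(f"{name} must be >= 0, got {t}")
    if h.t_grow_stop is not None and h.t_shrink is not None and h.t_grow_stop < h.t_shrink:
        v.append(f"t_grow_stop {h.t_grow_stop} earlier than bottleneck onset t_shrink {h.t_shrink}")
    if spec is not None:
        for p in spec.free_parameters():
            key = "m_hist" if p == "m" else p
            if getattr(h, key, None) is None:
                v.append(f"parameter {p} required by model {spec.model_id} is absent")
        if spec.size_change == "none" and (h.r_grow is not None or h.r_shrink is not None):
            v.append("size-change parameters set on a constant-size model")
    return v
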