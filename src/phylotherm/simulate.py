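"""Synthetic trees, traits and mortality tables with the structure the
analysis assumes.

Every stage of the comparative pipeline can be exercised without external
data: trees from a pure-birth (Yule) process or deterministic shapes, traits
from Brownian-motion or Ornstein-Uhlenbeck evolution around per-province
optima, and temperature-mortality tables from the binomial probit
dose-response model the estimation stage inverts. One seed fixes everything:
each top-level call derives named substreams (tree / trait / mortality) from
the master seed, so adding a stage never perturbs the draws of another.

Default province optima follow the adaptive-peak reading of the study
system: lower critical limits near 13.5 / 8.5 / -0.2 deg C and upper limits
near 37.4 / 37.4 / 26.0 deg C for the Brazilian / Argentinian / Magellanic
provinces, with microhabitat temperature optima 27 / 27 / 1.5 deg C.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import linalg, stats

from .errors import ValidationError
from .probit import MortalityTable
from .tree import Phylogeny, covariance, patristic_distances, read_newick

__all__ = [
    "SimulationConfig",
    "substreams",
    "simulate_tree",
    "simulate_trait",
    "simulate_mortality",
    "simulate_dataset",
]

PROVINCES = ("Brazilian", "Argentinian", "Magellanic")

DEFAULT_OPTIMA = {
    "LL50": {"Brazilian": 13.5, "Argentinian": 8.5, "Magellanic": -0.2},
    "UL50": {"Brazilian": 37.4, "Argentinian": 37.4, "Magellanic": 26.0},
    "MHT": {"Brazilian": 27.0, "Argentinian": 27.0, "Magellanic": 1.5},
}


def substreams(seed: int, names: Sequence[str]) -> dict[str, np.random.Generator]:
    """Independent, reproducible child generators derived from one seed."""
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {name: np.random.default_rng(ss) for name, ss in zip(names, children)}


@dataclass
class SimulationConfig:
    """Study-condition bundle for an end-to-end synthetic dataset.

    The defaults mirror the experimental design the analysis expects:
    12 species in three provinces (7 / 3 / 2), OU trait evolution around the
    province optima above, and per-species acute-exposure mortality assays
    with 4 consecutive temperatures and 10 animals per temperature chosen to
    bracket 50% mortality.
    """

    n_species: int = 12
    tree_model: Literal["pure_birth", "balanced", "star"] = "pure_birth"
    trait_model: Literal["BM", "OU"] = "OU"
    sigma2: float = 2.0
    alpha: float = 2.0
    province_fractions: tuple[float, ...] = (7 / 12, 3 / 12, 2 / 12)
    province_optima: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_OPTIMA.items()}
    )
    mortality_temps_offsets: tuple[float, ...] = (-3.0, -1.0, 1.0, 3.0)
    n_per_temp: int = 10
    probit_slope: float = 0.8
    seed: int = 0

    def __post_init__(self):
        if self.sigma2 <= 0:
            raise ValidationError("sigma2 must be > 0")
        if self.trait_model == "OU" and self.alpha <= 0:
            raise ValidationError("OU requires alpha > 0")

    @classmethod
    def from_yaml(cls, path: str) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {', '.join(sorted(unknown))}")
        for key in ("province_fractions", "mortality_temps_offsets"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

def _pure_birth_newick(n: int, rng: np.random.Generator) -> str:
    """Yule tree: exponential waiting times, random lineage splits, then the
    whole tree rescaled to unit root-to-tip depth (ultrametric)."""
    birth = {0: 0.0, 1: 0.0}  # lineage id -> birth time
    children: dict[int, tuple[int, int]] = {}
    split_time: dict[int, float] = {}
    active = [0, 1]
    next_id = 2
    t = 0.0
    while len(active) < n:
        t += rng.exponential(1.0 / len(active))
        idx = int(rng.integers(len(active)))
        lin = active.pop(idx)
        split_time[lin] = t
        a, b = next_id, next_id + 1
        next_id += 2
        birth[a] = birth[b] = t
        children[lin] = (a, b)
        active += [a, b]
    t_end = t + rng.exponential(1.0 / n)
    tip_names = iter(f"t{i}" for i in range(1, n + 1))

    def render(lin: int) -> str:
        if lin in children:
            a, b = children[lin]
            length = split_time[lin] - birth[lin]
            return f"({render(a)},{render(b)}):{length / t_end:.12f}"
        return f"{next(tip_names)}:{(t_end - birth[lin]) / t_end:.12f}"

    left = render(0)
    right = render(1)
    return f"({left},{right});"


def _balanced_newick(n: int) -> str:
    counter = iter(f"t{i}" for i in range(1, n + 1))

    def build(k: int) -> str:
        if k == 1:
            return f"{next(counter)}:1"
        left = build((k + 1) // 2)
        right = build(k // 2)
        return f"({left},{right}):1"

    inner = build(n)
    return inner.rsplit(":", 1)[0] + ";"


def simulate_tree(config: SimulationConfig, rng: np.random.Generator | None = None) -> Phylogeny:
    """Generate a tree under the configured model; tips are t1..tn."""
    n = config.n_species
    if n < 2:
        raise ValidationError("need at least 2 species")
    if config.tree_model == "star":
        text = "(" + ",".join(f"t{i}:1" for i in range(1, n + 1)) + ");"
    elif config.tree_model == "balanced":
        text = _balanced_newick(n)
    elif config.tree_model == "pure_birth":
        if rng is None:
            rng = substreams(config.seed, ["tree"])["tree"]
        text = _pure_birth_newick(n, rng)
    else:
        raise ValidationError(f"unknown tree model {config.tree_model!r}")
    return read_newick(text)


# ---------------------------------------------------------------------------
# traits
# ---------------------------------------------------------------------------

def simulate_trait(
    tree: Phylogeny,
    trait_model: Literal["BM", "OU"],
    sigma2: float,
    alpha: float | None = None,
    group_map: Mapping[str, str] | None = None,
    optima: Mapping[str, float] | float = 0.0,
    rng: np.random.Generator | int = 0,
) -> pd.Series:
    """One multivariate-normal draw of a trait evolving on the tree.

    BM: covariance sigma2 * C_BM (shared-path form). OU: the stationary
    process, covariance (sigma2 / 2 alpha) * exp(-alpha d). Species means
    come from ``optima`` — a constant or a per-group optimum routed through
    ``group_map`` (species -> group). sigma2 = 0 is allowed and returns the
    optima exactly.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    species = tree.tips
    if group_map is not None and not isinstance(optima, Mapping):
        raise ValidationError("group_map requires per-group optima")
    if isinstance(optima, Mapping):
        if group_map is None:
            raise ValidationError("per-group optima require group_map")
        try:
            mean = np.array([float(optima[group_map[s]]) for s in species])
        except KeyError as exc:
            raise ValidationError(f"missing group or optimum for {exc}") from exc
    else:
        mean = np.full(len(species), float(optima))
    if sigma2 < 0:
        raise ValidationError("sigma2 must be >= 0")
    if sigma2 == 0:
        return pd.Series(mean, index=species)
    if trait_model == "BM":
        cov = sigma2 * covariance(tree, "BM").C
    elif trait_model == "OU":
        if alpha is None or alpha <= 0:
            raise ValidationError("OU requires alpha > 0")
        d = patristic_distances(tree).values
        cov = (sigma2 / (2 * alpha)) * np.exp(-alpha * d)
    else:
        raise ValidationError(f"unknown trait model {trait_model!r}")
    L = linalg.cholesky(cov, lower=True)
    values = mean + L @ rng.standard_normal(len(species))
    return pd.Series(values, index=species)


# ---------------------------------------------------------------------------
# mortality assays
# ---------------------------------------------------------------------------

def simulate_mortality(
    true_limit: float,
    slope: float,
    temps: Sequence[float],
    n_per_temp: int | Sequence[int],
    direction: Literal["upper", "lower"] = "upper",
    rng: np.random.Generator | int = 0,
) -> MortalityTable:
    """Binomial deaths around a true 50% limit on the probit dose-response.

    deaths_i ~ Binomial(n_i, Phi(slope * (T_i - true_limit))), with the sign
    of the argument flipped for the lower (cold-death) direction.
    """
    if slope == 0:
        raise ValidationError("slope must be nonzero")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    temps = np.asarray(temps, dtype=float)
    n = np.broadcast_to(np.asarray(n_per_temp, dtype=int), temps.shape).copy()
    if np.any(n < 1):
        raise ValidationError("n_per_temp must be >= 1")
    sign = 1.0 if direction == "upper" else -1.0
    p = stats.norm.cdf(sign * slope * (temps - true_limit))
    deaths = rng.binomial(n, p)
    return MortalityTable(temps, n, deaths, direction)


# ---------------------------------------------------------------------------
# full datasets
# ---------------------------------------------------------------------------

def _assign_provinces(species: Sequence[str], fractions: Sequence[float]) -> dict[str, str]:
    n = len(species)
    counts = np.floor(np.asarray(fractions) / np.sum(fractions) * n).astype(int)
    while counts.sum() < n:
        counts[int(np.argmax(np.asarray(fractions) - counts / n))] += 1
    out = {}
    i = 0
    for prov, c in zip(PROVINCES, counts):
        for s in species[i : i + c]:
            out[s] = prov
        i += c
    return out


def simulate_dataset(config: SimulationConfig) -> dict:
    """Tree + trait table + per-species mortality tables under one seed.

    Returns a dict with keys ``tree`` (Phylogeny), ``traits`` (DataFrame:
    species, province, MHT, LL50, UL50) and ``mortality`` (nested dict
    species -> {"upper": MortalityTable, "lower": MortalityTable} whose true
    limits are the species' simulated UL50/LL50 values).
    """
    rngs = substreams(config.seed, ["tree", "trait", "mortality"])
    tree = simulate_tree(config, rngs["tree"])
    groups = _assign_provinces(tree.tips, config.province_fractions)
    traits = {"species": list(tree.tips), "province": [groups[s] for s in tree.tips]}
    for name in ("MHT", "LL50", "UL50"):
        series = simulate_trait(
            tree,
            config.trait_model,
            config.sigma2,
            alpha=config.alpha,
            group_map=groups,
            optima=config.province_optima[name],
            rng=rngs["trait"],
        )
        traits[name] = series.to_numpy()
    frame = pd.DataFrame(traits)
    offsets = np.asarray(config.mortality_temps_offsets)
    mortality: dict[str, dict[str, MortalityTable]] = {}
    for _, row in frame.iterrows():
        mortality[row["species"]] = {
            "upper": simulate_mortality(
                row["UL50"], config.probit_slope, row["UL50"] + offsets,
                config.n_per_temp, "upper", rngs["mortality"],
            ),
            "lower": simulate_mortality(
                row["LL50"], config.probit_slope, row["LL50"] + offsets,
                config.n_per_temp, "lower", rngs["mortality"],
            ),
        }
    return {"tree": tree, "traits": frame, "mortality": mortality, "config": config}
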