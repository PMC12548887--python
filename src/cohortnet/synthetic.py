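"""Synthetic layered-cohort generator with known ground truth.

Emulates the statistical structure of a multimodal dementia cohort: a few
thousand subjects in three diagnostic groups (control / MCI / AD), six layers
of mixed-type variables (genetic, molecular, PET, MRI, risk-factor,
phenotype), per-layer missingness (a subject may lack a whole modality),
within-layer correlated blocks, and planted cross-layer dependency chains
terminating in the phenotype layer.

The generative model is a latent-Gaussian factor model: every variable is a
unit-variance Gaussian that may load on a shared latent factor (a within-layer
block factor, or a cross-layer chain factor), and discrete variables are
deterministic monotone transforms (threshold / equiprobable quantile bins) of
their latent value. Two variables sharing a factor with loadings a and b have
population correlation a*b / sqrt((a^2 + s^2(1-a^2))(b^2 + s^2(1-b^2))) where
s is the residual noise scale; with s = 1 this reduces to a*b.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "LayerSpec",
    "PlantedChain",
    "CohortSpec",
    "CohortTable",
    "GroundTruth",
    "generate_cohort",
    "ground_truth",
    "default_cohort_spec",
    "CohortSpecError",
]

GROUP_NAMES = ("control", "MCI", "AD")

_KINDS = ("continuous", "binary", "categorical", "ordinal")


class CohortSpecError(ValueError):
    """Raised when a cohort specification is internally inconsistent."""


@dataclass(frozen=True)
class LayerSpec:
    """One layer of the cohort: how many variables of each kind it holds.

    Variables are named ``{name}_{i:03d}`` in kind order (continuous, binary,
    categorical, ordinal). The first ``n_blocks * block_size`` variables are
    partitioned into consecutive correlated blocks sharing a latent factor
    with loading ``block_loading``; chain membership overrides block
    membership for a variable.
    """

    name: str
    n_continuous: int = 0
    n_binary: int = 0
    n_categorical: int = 0
    n_ordinal: int = 0
    n_levels: int = 3
    missing_prob: float = 0.0
    block_size: int = 0
    n_blocks: int = 0
    block_loading: float = 0.0

    @property
    def n_variables(self) -> int:
        return self.n_continuous + self.n_binary + self.n_categorical + self.n_ordinal

    def variable_names(self) -> list[str]:
        return [f"{self.name}_{i:03d}" for i in range(self.n_variables)]

    def variable_kinds(self) -> list[str]:
        return (
            ["continuous"] * self.n_continuous
            + ["binary"] * self.n_binary
            + ["categorical"] * self.n_categorical
            + ["ordinal"] * self.n_ordinal
        )


@dataclass(frozen=True)
class PlantedChain:
    """A planted cross-layer dependency chain ending in the phenotype layer.

    All chain members load on one shared latent factor with loading
    ``strength``; consecutive members are the chain's "edges" for recovery
    purposes. If ``group`` is set, the dependence holds only within that
    diagnostic group (elsewhere the members are independent noise).
    """

    variables: tuple[str, ...]
    strength: float
    group: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "variables", tuple(self.variables))


@dataclass(frozen=True)
class CohortSpec:
    """Full description of a synthetic cohort."""

    n_subjects: int
    layers: tuple[LayerSpec, ...]
    group_fractions: tuple[float, float, float] = (0.4, 0.4, 0.2)
    chains: tuple[PlantedChain, ...] = ()
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "layers", tuple(self.layers))
        object.__setattr__(self, "chains", tuple(self.chains))
        object.__setattr__(self, "group_fractions", tuple(self.group_fractions))

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise CohortSpecError("n_subjects: must be >= 1")
        if abs(sum(self.group_fractions) - 1.0) > 1e-9:
            raise CohortSpecError("group_fractions: must sum to 1")
        if any(f < 0 for f in self.group_fractions):
            raise CohortSpecError("group_fractions: must be non-negative")
        if self.noise_sd < 0:
            raise CohortSpecError("noise_sd: must be non-negative")
        names = set()
        var_layer: dict[str, str] = {}
        for lay in self.layers:
            if lay.name in names:
                raise CohortSpecError(f"layers: duplicate layer name {lay.name!r}")
            names.add(lay.name)
            if lay.n_variables < 1:
                raise CohortSpecError(f"layers[{lay.name}]: empty layer")
            if not (0.0 <= lay.missing_prob <= 1.0):
                raise CohortSpecError(f"layers[{lay.name}].missing_prob: not in [0, 1]")
            if lay.n_levels < 2 and (lay.n_categorical or lay.n_ordinal):
                raise CohortSpecError(f"layers[{lay.name}].n_levels: must be >= 2")
            if lay.block_size * lay.n_blocks > lay.n_variables:
                raise CohortSpecError(
                    f"layers[{lay.name}].block_size: blocks exceed layer size"
                )
            if not (0.0 <= lay.block_loading <= 1.0):
                raise CohortSpecError(f"layers[{lay.name}].block_loading: not in [0, 1]")
            for v in lay.variable_names():
                var_layer[v] = lay.name
        seen_in_chain: set[str] = set()
        for ci, chain in enumerate(self.chains):
            if not (0.0 <= chain.strength <= 1.0):
                raise CohortSpecError(f"chains[{ci}].strength: not in (0, 1]")
            if len(set(chain.variables)) != len(chain.variables):
                raise CohortSpecError(f"chains[{ci}].variables: not distinct")
            if chain.group is not None and chain.group not in GROUP_NAMES:
                raise CohortSpecError(f"chains[{ci}].group: unknown group {chain.group!r}")
            for v in chain.variables:
                if v not in var_layer:
                    raise CohortSpecError(f"chains[{ci}].variables: unknown variable {v!r}")
                if v in seen_in_chain:
                    raise CohortSpecError(
                        f"chains[{ci}].variables: {v!r} appears in more than one chain"
                    )
                seen_in_chain.add(v)


@dataclass
class CohortTable:
    """Subjects x variables table with missingness, metadata and group labels.

    ``data`` holds numeric values with NaN for missing; ``meta`` is indexed by
    variable name with columns ``layer``, ``kind``, ``levels``; ``groups`` is
    a per-subject diagnostic label.
    """

    data: pd.DataFrame
    meta: pd.DataFrame
    groups: pd.Series

    @property
    def n_subjects(self) -> int:
        return len(self.data)

    @property
    def layer_names(self) -> list[str]:
        seen: list[str] = []
        for lay in self.meta["layer"]:
            if lay not in seen:
                seen.append(lay)
        return seen

    def variables(self, layer: str | None = None) -> list[str]:
        if layer is None:
            return list(self.meta.index)
        if layer not in set(self.meta["layer"]):
            raise KeyError(f"unknown layer {layer!r}")
        return list(self.meta.index[self.meta["layer"] == layer])

    def layer_of(self, variable: str) -> str:
        return str(self.meta.loc[variable, "layer"])

    def kind_of(self, variable: str) -> str:
        return str(self.meta.loc[variable, "kind"])

    def is_discrete(self, variable: str) -> bool:
        return self.kind_of(variable) != "continuous"

    def subset(self, group: str) -> "CohortTable":
        """Rows belonging to one diagnostic group."""
        mask = (self.groups == group).to_numpy()
        return CohortTable(
            data=self.data.loc[mask].reset_index(drop=True),
            meta=self.meta.copy(),
            groups=self.groups.loc[mask].reset_index(drop=True),
        )


@dataclass(frozen=True)
class GroundTruth:
    """Planted structure of a cohort spec, for recovery oracles.

    ``edges`` are the planted pairs a network builder is expected to recover:
    within-block pairs plus consecutive chain pairs. ``dependent_pairs`` is
    the superset of all pairs with nonzero population dependence (it adds
    non-consecutive chain pairs, which share the chain latent too); null-pair
    false-positive checks must use its complement.
    """

    edges: frozenset[frozenset]
    dependent_pairs: frozenset[frozenset]
    chains: tuple[tuple[str, ...], ...]


def ground_truth(spec: CohortSpec) -> GroundTruth:
    """Planted edge set and chains of ``spec`` (see :class:`GroundTruth`)."""
    spec.validate()
    edges: set[frozenset] = set()
    dependent: set[frozenset] = set()
    chain_vars = {v for c in spec.chains for v in c.variables}
    for lay in spec.layers:
        if lay.block_loading > 0 and lay.block_size >= 2:
            names = lay.variable_names()
            for b in range(lay.n_blocks):
                block = [
                    v
                    for v in names[b * lay.block_size : (b + 1) * lay.block_size]
                    if v not in chain_vars  # chain membership overrides block
                ]
                for u, v in itertools.combinations(block, 2):
                    edges.add(frozenset((u, v)))
                    dependent.add(frozenset((u, v)))
    for chain in spec.chains:
        if chain.strength <= 0:
            continue
        for u, v in zip(chain.variables[:-1], chain.variables[1:]):
            edges.add(frozenset((u, v)))
        for u, v in itertools.combinations(chain.variables, 2):
            dependent.add(frozenset((u, v)))
    return GroundTruth(
        edges=frozenset(edges),
        dependent_pairs=frozenset(dependent),
        chains=tuple(c.variables for c in spec.chains if c.strength > 0),
    )


def _discretize(raw: np.ndarray, kind: str, n_levels: int) -> np.ndarray:
    """Monotone transform of a standard-normal latent into the target kind."""
    if kind == "continuous":
        return raw
    if kind == "binary":
        return (raw > 0.0).astype(float)
    # categorical and ordinal: equiprobable bins at population normal quantiles
    edges = norm.ppf(np.arange(1, n_levels) / n_levels)
    return np.searchsorted(edges, raw).astype(float)


def generate_cohort(spec: CohortSpec) -> CohortTable:
    """Draw one cohort table from ``spec``. Deterministic given ``spec.seed``."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects

    groups = pd.Series(
        rng.choice(GROUP_NAMES, size=n, p=np.asarray(spec.group_fractions)),
        name="group",
    )

    # latent factors: chains first (they span layers), then per-layer blocks
    chain_latent = {ci: rng.standard_normal(n) for ci in range(len(spec.chains))}
    var_chain: dict[str, int] = {
        v: ci for ci, c in enumerate(spec.chains) for v in c.variables
    }

    s2 = spec.noise_sd**2
    columns: dict[str, np.ndarray] = {}
    meta_rows: list[tuple[str, str, str, int]] = []
    for lay in spec.layers:
        block_latent = [rng.standard_normal(n) for _ in range(lay.n_blocks)]
        names = lay.variable_names()
        kinds = lay.variable_kinds()
        for idx, (vname, kind) in enumerate(zip(names, kinds)):
            eps = rng.standard_normal(n)
            lam, z = 0.0, None
            if vname in var_chain:
                ci = var_chain[vname]
                lam = spec.chains[ci].strength
                z = chain_latent[ci]
            elif lay.n_blocks and idx < lay.n_blocks * lay.block_size:
                lam = lay.block_loading
                z = block_latent[idx // lay.block_size]
            if lam > 0 and z is not None:
                raw = lam * z + spec.noise_sd * np.sqrt(1.0 - lam * lam) * eps
                raw = raw / np.sqrt(lam * lam + s2 * (1.0 - lam * lam))
            else:
                raw = eps
            if vname in var_chain and spec.chains[var_chain[vname]].group is not None:
                # group-restricted chain: outside the group, plain noise
                in_group = (groups == spec.chains[var_chain[vname]].group).to_numpy()
                raw = np.where(in_group, raw, rng.standard_normal(n))
            levels = 2 if kind == "binary" else (lay.n_levels if kind != "continuous" else 0)
            columns[vname] = _discretize(raw, kind, lay.n_levels)
            meta_rows.append((vname, lay.name, kind, levels))

    data = pd.DataFrame(columns, index=pd.RangeIndex(n, name="subject"))

    # missingness: a subject is missing a whole layer (modality) at random
    for lay in spec.layers:
        if lay.missing_prob > 0:
            missing = rng.random(n) < lay.missing_prob
            data.loc[missing, lay.variable_names()] = np.nan

    meta = pd.DataFrame(
        meta_rows, columns=["variable", "layer", "kind", "levels"]
    ).set_index("variable")
    return CohortTable(data=data, meta=meta, groups=groups)


def default_cohort_spec(
    n_subjects: int = 2000,
    seed: int = 0,
    chain_strength: float = 0.7,
    with_chain: bool = True,
) -> CohortSpec:
    """The default study conditions: six layers, ~60 mixed-type variables.

    Layer sizes, kinds and missingness emulate a multimodal dementia cohort:
    imaging layers (PET, MRI) are strongly internally correlated and more
    often missing; the risk-factor layer mixes binary history/symptom items
    with weak internal structure; the phenotype layer holds cognitive scores.
    One planted chain genetic -> PET -> risk -> phenotype provides ground
    truth for path recovery.
    """
    layers = (
        LayerSpec("genetic", n_continuous=6, n_categorical=4, n_levels=3,
                  missing_prob=0.05, block_size=3, n_blocks=1, block_loading=0.6),
        LayerSpec("molecular", n_continuous=10, missing_prob=0.15,
                  block_size=3, n_blocks=2, block_loading=0.6),
        LayerSpec("PET", n_continuous=10, missing_prob=0.20,
                  block_size=4, n_blocks=2, block_loading=0.8),
        LayerSpec("MRI", n_continuous=10, missing_prob=0.15,
                  block_size=5, n_blocks=2, block_loading=0.8),
        LayerSpec("risk", n_continuous=4, n_binary=6, missing_prob=0.10,
                  block_size=2, n_blocks=1, block_loading=0.5),
        LayerSpec("phenotype", n_continuous=6, n_ordinal=2, n_levels=4,
                  missing_prob=0.05, block_size=3, n_blocks=1, block_loading=0.6),
    )
    chains = (
        (PlantedChain(("genetic_004", "PET_008", "risk_002", "phenotype_004"),
                      strength=chain_strength),)
        if with_chain
        else ()
    )
    return CohortSpec(
        n_subjects=n_subjects,
        layers=layers,
        group_fractions=(0.4, 0.4, 0.2),
        chains=chains,
        seed=seed,
    )
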