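"""Generators for the network-of-networks cortical architecture.

The cortex is modelled as a two-level structure: dense directed *inner*
networks of excitable neurons (one per neural column), coupled through a
sparser, *range-dependent* directed *outer* network laid out on a 2-D grid.
Every edge carries a real-valued transmission delay; the fact that delays
are generic reals (no two alike, not on a lattice) is a load-bearing
property of the model, not an implementation detail.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ColumnNetwork",
    "OuterNetwork",
    "NetworkOfNetworks",
    "generate_column_network",
    "generate_range_dependent_grid",
    "assemble_network_of_networks",
]


@dataclass
class ColumnNetwork:
    """Dense directed graph of one neural column.

    Edges are stored as parallel arrays; ``edges`` yields the
    (source, target, weight, delay) view used by serialisation.
    """

    n: int
    sources: np.ndarray
    targets: np.ndarray
    weights: np.ndarray
    delays: np.ndarray
    seed: int
    density: float

    def __post_init__(self) -> None:
        self.sources = np.asarray(self.sources, dtype=np.int64)
        self.targets = np.asarray(self.targets, dtype=np.int64)
        self.weights = np.asarray(self.weights, dtype=np.float64)
        self.delays = np.asarray(self.delays, dtype=np.float64)
        if self.sources.size:
            if self.sources.min() < 0 or self.sources.max() >= self.n:
                raise ValueError("edge source id outside [0, n)")
            if self.targets.min() < 0 or self.targets.max() >= self.n:
                raise ValueError("edge target id outside [0, n)")
            if np.any(self.sources == self.targets):
                raise ValueError("self-edges are not allowed")
            if np.any(self.delays <= 0):
                raise ValueError("all delays must be strictly positive")

    @property
    def n_edges(self) -> int:
        return int(self.sources.size)

    @property
    def edges(self) -> list[tuple[int, int, float, float]]:
        return list(
            zip(
                self.sources.tolist(),
                self.targets.tolist(),
                self.weights.tolist(),
                self.delays.tolist(),
            )
        )

    def with_unit_delays(self) -> "ColumnNetwork":
        """Copy of the network with every delay forced to 1.0 (delay quench)."""
        return ColumnNetwork(
            n=self.n,
            sources=self.sources.copy(),
            targets=self.targets.copy(),
            weights=self.weights.copy(),
            delays=np.ones_like(self.delays),
            seed=self.seed,
            density=self.density,
        )


@dataclass
class OuterNetwork:
    """Range-dependent directed column-to-column graph on a 2-D grid."""

    rows: int
    cols: int
    positions: np.ndarray  # (N, 2) integer grid coordinates per column id
    sources: np.ndarray
    targets: np.ndarray
    beta: float
    lam: float
    seed: int

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.sources = np.asarray(self.sources, dtype=np.int64)
        self.targets = np.asarray(self.targets, dtype=np.int64)
        uniq = {tuple(p) for p in self.positions.tolist()}
        if len(uniq) != len(self.positions):
            raise ValueError("column positions must be unique")

    @property
    def n_columns(self) -> int:
        return int(len(self.positions))

    @property
    def edges(self) -> list[tuple[int, int]]:
        return list(zip(self.sources.tolist(), self.targets.tolist()))


@dataclass
class NetworkOfNetworks:
    """Columns coupled by neuron-level bridges restricted to outer edges.

    ``inter_edges`` columns: (source column, source neuron, target column,
    target neuron, weight, delay).
    """

    outer: OuterNetwork
    columns: list[ColumnNetwork]
    inter_sources_col: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    inter_sources_neu: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    inter_targets_col: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    inter_targets_neu: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    inter_weights: np.ndarray = field(default_factory=lambda: np.empty(0, np.float64))
    inter_delays: np.ndarray = field(default_factory=lambda: np.empty(0, np.float64))

    def __post_init__(self) -> None:
        outer_pairs = set(zip(self.outer.sources.tolist(), self.outer.targets.tolist()))
        for sc, tc in zip(self.inter_sources_col.tolist(), self.inter_targets_col.tolist()):
            if (sc, tc) not in outer_pairs:
                raise ValueError(f"bridge ({sc}->{tc}) has no matching outer edge")
        if self.inter_delays.size and np.any(self.inter_delays <= 0):
            raise ValueError("bridge delays must be strictly positive")

    @property
    def n_neurons(self) -> int:
        return int(sum(c.n for c in self.columns))

    @property
    def inter_edges(self) -> list[tuple[int, int, int, int, float, float]]:
        return list(
            zip(
                self.inter_sources_col.tolist(),
                self.inter_sources_neu.tolist(),
                self.inter_targets_col.tolist(),
                self.inter_targets_neu.tolist(),
                self.inter_weights.tolist(),
                self.inter_delays.tolist(),
            )
        )


def generate_column_network(
    n: int,
    density: float,
    delay_range: tuple[float, float],
    weight: float = 1.0,
    seed: int = 0,
    inhibitory_fraction: float = 0.0,
) -> ColumnNetwork:
    """Sample a dense directed column with real-valued delays.

    Every ordered pair (i, j), i != j, is included independently with
    probability ``density``; each included edge gets a delay drawn uniformly
    on ``delay_range`` and weight ``weight`` (negated for a randomly chosen
    ``inhibitory_fraction`` of edges).

    Parameters
    ----------
    n : neuron count.
    density : edge-inclusion probability in [0, 1].
    delay_range : (tau_min, tau_max) with 0 < tau_min <= tau_max, model
        time units.
    weight : membrane-kick amplitude per edge.
    seed : RNG seed; the network is a pure function of its arguments.
    inhibitory_fraction : probability that an edge's weight is negated.
    """
    tau_min, tau_max = float(delay_range[0]), float(delay_range[1])
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0.0 <= density <= 1.0):
        raise ValueError(f"density must lie in [0, 1], got {density}")
    if tau_min <= 0:
        raise ValueError(f"tau_min must be > 0, got {tau_min}")
    if tau_max < tau_min:
        raise ValueError("delay_range must satisfy tau_min <= tau_max")
    if not (0.0 <= inhibitory_fraction <= 1.0):
        raise ValueError("inhibitory_fraction must lie in [0, 1]")

    rng = np.random.default_rng(seed)
    # all ordered pairs i != j, row-major
    src = np.repeat(np.arange(n), n - 1) if n > 1 else np.empty(0, np.int64)
    tgt = np.concatenate([np.delete(np.arange(n), i) for i in range(n)]) if n > 1 else np.empty(0, np.int64)
    keep = rng.random(src.size) < density
    src, tgt = src[keep], tgt[keep]
    m = src.size
    delays = rng.uniform(tau_min, tau_max, m)
    weights = np.full(m, float(weight))
    if inhibitory_fraction > 0 and m:
        weights[rng.random(m) < inhibitory_fraction] *= -1.0
    return ColumnNetwork(
        n=n, sources=src, targets=tgt, weights=weights, delays=delays,
        seed=seed, density=density,
    )


def generate_range_dependent_grid(
    rows: int,
    cols: int,
    beta: float,
    lam: float,
    seed: int = 0,
    cutoff: float | None = None,
) -> OuterNetwork:
    """Sample a range-dependent directed graph over an (rows x cols) grid.

    An ordered pair of distinct columns at Euclidean grid distance d is
    connected with probability ``min(1, beta * exp(-d / lam))``; with a
    ``cutoff`` radius the probability is zero beyond it. The grid is flat
    (no wraparound).
    """
    if rows * cols < 1:
        raise ValueError("grid must contain at least one column")
    if beta < 0:
        raise ValueError(f"beta must be >= 0, got {beta}")
    if lam <= 0:
        raise ValueError(f"lam must be > 0, got {lam}")

    rng = np.random.default_rng(seed)
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    positions = np.column_stack([rr.ravel(), cc.ravel()])
    n = positions.shape[0]
    diff = positions[:, None, :] - positions[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=2))
    p = np.minimum(1.0, beta * np.exp(-dist / lam))
    if cutoff is not None:
        p = np.where(dist > cutoff, 0.0, p)
    np.fill_diagonal(p, 0.0)
    adj = rng.random((n, n)) < p
    src, tgt = np.nonzero(adj)
    return OuterNetwork(
        rows=rows, cols=cols, positions=positions,
        sources=src.astype(np.int64), targets=tgt.astype(np.int64),
        beta=beta, lam=lam, seed=seed,
    )


def assemble_network_of_networks(
    outer: OuterNetwork,
    column_params: dict,
    bridge_density: float,
    seed: int = 0,
    bridge_delay_scale: float = 2.0,
) -> NetworkOfNetworks:
    """Attach a ColumnNetwork to every grid column and sample neuron bridges.

    For each outer edge (A -> B), every (neuron in A, neuron in B) pair is
    bridged independently with probability ``bridge_density``. Bridge delays
    are drawn uniformly from the intra-column delay range scaled by
    ``bridge_delay_scale`` (> 1 by default: inter-column axonal paths are
    longer than intra-column ones).

    ``column_params`` holds keyword arguments for
    :func:`generate_column_network` (n, density, delay_range, weight, ...).
    """
    if not (0.0 <= bridge_density <= 1.0):
        raise ValueError("bridge_density must lie in [0, 1]")
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(outer.n_columns + 1)]
    columns = [
        generate_column_network(seed=child_seeds[i], **column_params)
        for i in range(outer.n_columns)
    ]
    rng = np.random.default_rng(child_seeds[-1])
    tau_min, tau_max = column_params["delay_range"]
    b_lo, b_hi = bridge_delay_scale * tau_min, bridge_delay_scale * tau_max
    weight = float(column_params.get("weight", 1.0))

    sc, sn, tc, tn = [], [], [], []
    for a, b in zip(outer.sources.tolist(), outer.targets.tolist()):
        na, nb = columns[a].n, columns[b].n
        keep = rng.random(na * nb) < bridge_density
        if not keep.any():
            continue
        idx = np.nonzero(keep)[0]
        sc.append(np.full(idx.size, a))
        sn.append(idx // nb)
        tc.append(np.full(idx.size, b))
        tn.append(idx % nb)
    if sc:
        sc = np.concatenate(sc).astype(np.int64)
        sn = np.concatenate(sn).astype(np.int64)
        tc = np.concatenate(tc).astype(np.int64)
        tn = np.concatenate(tn).astype(np.int64)
    else:
        sc = sn = tc = tn = np.empty(0, np.int64)
    m = sc.size
    return NetworkOfNetworks(
        outer=outer,
        columns=columns,
        inter_sources_col=sc,
        inter_sources_neu=sn,
        inter_targets_col=tc,
        inter_targets_neu=tn,
        inter_weights=np.full(m, weight),
        inter_delays=rng.uniform(b_lo, b_hi, m),
    )
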