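"""Serialisation, run configuration and the reference fixture suite.

Canonical on-disk formats: networks as JSON (full double precision) with
GraphML and edge-list CSV for interoperability; spike trains as CSV;
phase records as HDF5 plus a CSV trigger-event log; configs as YAML (JSON
is a subset and equally accepted).  Delays are serialised with enough
digits that a round trip is exact — real-valued delays are the point of
the model, so truncating them would change the dynamics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import h5py
import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .netgen import ColumnNetwork, OuterNetwork, generate_column_network, \
    generate_range_dependent_grid
from .column_sim import NeuronDynamicsParams, SpikeTrain, StimulusRegime
from .clockdyn import ClockNetwork, KClock, ClockEdge, PhaseRecord, build_clock_network

__all__ = [
    "RunConfig",
    "FixtureSuite",
    "make_fixture_suite",
    "save_network_json",
    "load_network_json",
    "save_network_graphml",
    "load_network_graphml",
    "edges_to_csv",
    "save_spike_train_csv",
    "load_spike_train_csv",
    "save_phase_record_h5",
    "load_phase_record_h5",
    "save_stimulus_json",
    "load_stimulus_json",
    "save_clock_network_json",
    "load_clock_network_json",
]


class DataFormatError(ValueError):
    """Malformed input file; the message names the file and offending field."""


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------

def save_network_json(net: ColumnNetwork, path) -> None:
    obj = {
        "type": "ColumnNetwork",
        "n": net.n,
        "seed": net.seed,
        "density": net.density,
        "edges": [
            [int(s), int(t), float(w), float(d)]
            for s, t, w, d in net.edges
        ],
    }
    Path(path).write_text(json.dumps(obj))


def load_network_json(path) -> ColumnNetwork:
    path = Path(path)
    try:
        obj = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise DataFormatError(f"{path}: not valid JSON ({exc})") from exc
    if obj.get("type") != "ColumnNetwork":
        raise DataFormatError(f"{path}: expected a ColumnNetwork object")
    edges = obj["edges"]
    arr = np.array(edges, dtype=np.float64).reshape(-1, 4)
    return ColumnNetwork(
        n=int(obj["n"]),
        sources=arr[:, 0].astype(np.int64),
        targets=arr[:, 1].astype(np.int64),
        weights=arr[:, 2],
        delays=arr[:, 3],
        seed=int(obj["seed"]),
        density=float(obj["density"]),
    )


def save_network_graphml(net: ColumnNetwork, path) -> None:
    g = nx.MultiDiGraph(n=net.n, seed=net.seed, density=net.density)
    g.add_nodes_from(range(net.n))
    for s, t, w, d in net.edges:
        g.add_edge(s, t, weight=w, delay=d)
    nx.write_graphml(g, path)


def load_network_graphml(path) -> ColumnNetwork:
    g = nx.read_graphml(path, node_type=int)
    src, tgt, w, d = [], [], [], []
    for u, v, attrs in g.edges(data=True):
        src.append(u)
        tgt.append(v)
        w.append(attrs["weight"])
        d.append(attrs["delay"])
    return ColumnNetwork(
        n=int(g.graph["n"]), sources=np.array(src, np.int64),
        targets=np.array(tgt, np.int64), weights=np.array(w),
        delays=np.array(d), seed=int(g.graph["seed"]),
        density=float(g.graph["density"]),
    )


def edges_to_csv(net: ColumnNetwork, path) -> None:
    pd.DataFrame(
        {"source": net.sources, "target": net.targets,
         "weight": net.weights, "delay": net.delays}
    ).to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# spike trains & stimuli
# ---------------------------------------------------------------------------

def save_spike_train_csv(train: SpikeTrain, path) -> None:
    pd.DataFrame({"unit": train.units, "time": train.times}).to_csv(
        path, index=False, float_format="%.17g"
    )


def load_spike_train_csv(path, t_end: float | None = None,
                         refractory: float = 0.0) -> SpikeTrain:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if list(df.columns) != ["unit", "time"]:
        raise DataFormatError(f"{path}: expected header 'unit,time', got {list(df.columns)}")
    times = pd.to_numeric(df["time"], errors="coerce")
    if times.isna().any():
        line = int(times.isna().idxmax()) + 2  # header is line 1
        raise DataFormatError(f"{path}: line {line}: non-numeric time field")
    units = pd.to_numeric(df["unit"], errors="coerce")
    if units.isna().any():
        line = int(units.isna().idxmax()) + 2
        raise DataFormatError(f"{path}: line {line}: non-numeric unit field")
    times = times.to_numpy(dtype=np.float64)
    units = units.to_numpy(dtype=np.int64)
    if t_end is None:
        t_end = float(times.max()) if times.size else 0.0
    return SpikeTrain(units=units, times=times, t_end=t_end,
                      observed=frozenset(np.unique(units).tolist()),
                      refractory=refractory)


def save_stimulus_json(stim: StimulusRegime, path) -> None:
    Path(path).write_text(json.dumps({
        "label": stim.label,
        "spikes": [[int(u), float(t)] for u, t in stim.spikes],
        "poisson": [[int(u), float(r), [float(a), float(b)]] for u, r, (a, b) in stim.poisson],
        "amplitude": stim.amplitude,
        "seed": stim.seed,
    }))


def load_stimulus_json(path) -> StimulusRegime:
    path = Path(path)
    try:
        obj = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise DataFormatError(f"{path}: not valid JSON ({exc})") from exc
    return StimulusRegime(
        label=obj.get("label", "stimulus"),
        spikes=[(int(u), float(t)) for u, t in obj.get("spikes", [])],
        poisson=[(int(u), float(r), (float(w[0]), float(w[1])))
                 for u, r, w in obj.get("poisson", [])],
        amplitude=obj.get("amplitude"),
        seed=int(obj.get("seed", 0)),
    )


# ---------------------------------------------------------------------------
# clock networks & phase records
# ---------------------------------------------------------------------------

def save_clock_network_json(net: ClockNetwork, path) -> None:
    Path(path).write_text(json.dumps({
        "type": "ClockNetwork",
        "seed": net.seed,
        "positions": net.positions.tolist() if net.positions is not None else None,
        "clocks": [
            {"phases": c.phases.tolist(), "rates": c.rates.tolist()}
            for c in net.clocks
        ],
        "edges": [
            {"sender": e.sender, "receiver": e.receiver,
             "trigger_phase": e.trigger_phase, "trigger_value": e.trigger_value,
             "delay": e.delay, "prm": e.prm.tolist()}
            for e in net.edges
        ],
    }))


def load_clock_network_json(path) -> ClockNetwork:
    path = Path(path)
    try:
        obj = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise DataFormatError(f"{path}: not valid JSON ({exc})") from exc
    if obj.get("type") != "ClockNetwork":
        raise DataFormatError(f"{path}: expected a ClockNetwork object")
    return ClockNetwork(
        clocks=[KClock(phases=np.array(c["phases"]), rates=np.array(c["rates"]))
                for c in obj["clocks"]],
        edges=[ClockEdge(sender=e["sender"], receiver=e["receiver"],
                         trigger_phase=e["trigger_phase"],
                         trigger_value=e["trigger_value"], delay=e["delay"],
                         prm=np.array(e["prm"]))
               for e in obj["edges"]],
        seed=int(obj.get("seed", 0)),
        positions=np.array(obj["positions"]) if obj.get("positions") is not None else None,
    )


def save_phase_record_h5(rec: PhaseRecord, path, event_csv=None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("sample_times", data=rec.sample_times)
        f.create_dataset("phases", data=rec.phases)
        f.create_dataset("observed", data=np.asarray(rec.observed, np.int64))
        ev = np.array([(e, t0, t1) for e, t0, t1 in rec.events], dtype=np.float64)
        f.create_dataset("events", data=ev.reshape(-1, 3))
    if event_csv is not None:
        pd.DataFrame(
            rec.events, columns=["edge", "emit_time", "arrival_time"]
        ).to_csv(event_csv, index=False, float_format="%.17g")


def load_phase_record_h5(path) -> PhaseRecord:
    with h5py.File(path, "r") as f:
        ev = f["events"][()]
        return PhaseRecord(
            sample_times=f["sample_times"][()],
            phases=f["phases"][()],
            observed=[int(c) for c in f["observed"][()]],
            events=[(int(e), float(t0), float(t1)) for e, t0, t1 in ev],
        )


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Resolved parameters of one run; round-trips losslessly through YAML.

    Every CLI entry point resolves its arguments into a RunConfig and
    writes it next to the outputs, so a run can be replayed exactly.
    """

    seed: int = 0
    netgen: dict = field(default_factory=dict)
    dynamics: dict = field(default_factory=dict)
    stimulus: dict = field(default_factory=dict)
    estimation: dict = field(default_factory=dict)
    clustering: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        path = Path(path)
        try:
            obj = yaml.safe_load(path.read_text()) or {}
        except yaml.YAMLError as exc:
            raise DataFormatError(f"{path}: not valid YAML ({exc})") from exc
        if "seed" not in obj:
            raise DataFormatError(f"{path}: config must state an explicit seed")
        known = {f_.name for f_ in cls.__dataclass_fields__.values()}
        unknown = set(obj) - known
        if unknown:
            raise DataFormatError(f"{path}: unknown config sections {sorted(unknown)}")
        return cls(**obj)


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@dataclass
class FixtureSuite:
    """Small named systems exercising every part of the pipeline.

    * ``dead_heat``: two parallel 2-hop walks A->B->D and A->C->D with
      generic real delays; under unit delays the two arrivals at D
      coincide exactly.
    * ``ring3``: a 3-neuron directed ring with delays summing to 4.0 that
      sustains a spike indefinitely once kicked.
    * ``clock_grid`` + ``clock_regimes``: a 3x3 range-dependent clock
      network (shared winding rates, weak coupling) with three stimulation
      regimes forcing disjoint clock subsets periodically over [0, 98);
      the battery protocol records the steady-state window [48, 98].
    * ``torus_signals``: sin-sum signals with 1, 2 and 3 incommensurate
      frequencies (known correlation dimension equal to the count).
    """

    seed: int
    dead_heat: ColumnNetwork
    ring3: ColumnNetwork
    clock_grid: ClockNetwork
    clock_regimes: list[StimulusRegime]
    torus_signals: dict[int, np.ndarray]

    #: battery protocol constants matching the regimes above
    battery_t_end: float = 98.0
    battery_t_start: float = 48.0


def make_fixture_suite(seed: int = 0) -> FixtureSuite:
    from .kestim import torus_signal

    rng = np.random.default_rng(seed)
    dead_heat = ColumnNetwork(
        n=4,
        sources=np.array([0, 1, 0, 2]),
        targets=np.array([1, 3, 2, 3]),
        weights=np.full(4, 1.2),
        delays=np.array([1.1, 1.3, 1.2, 1.6]),
        seed=seed, density=1.0,
    )
    ring3 = ColumnNetwork(
        n=3,
        sources=np.array([0, 1, 2]),
        targets=np.array([1, 2, 0]),
        weights=np.full(3, 1.2),
        delays=np.array([1.1, 1.3, 1.6]),
        seed=seed, density=1.0,
    )
    grid = generate_range_dependent_grid(3, 3, beta=0.9, lam=1.5, seed=seed)
    clock_grid = build_clock_network(grid, k=3, seed=seed + 1,
                                     shared_rates=True, kick_scale=0.1)
    n_clocks = clock_grid.n_clocks
    groups = np.array_split(rng.permutation(n_clocks), 3)
    regimes = []
    for gi, grp in enumerate(groups):
        spikes = []
        for c in grp.tolist():
            spikes.extend((int(c), float(t)) for t in np.arange(1.0 + 0.37 * gi, 98.0, 4.0))
        regimes.append(StimulusRegime(label=f"regime-{gi}", spikes=spikes, seed=seed + gi))
    torus = {
        j: torus_signal(j, t_len=t_len, dt=0.05, seed=seed + 10 * j).rates[0]
        for j, t_len in ((1, 400.0), (2, 400.0), (3, 1200.0))
    }
    return FixtureSuite(
        seed=seed, dead_heat=dead_heat, ring3=ring3,
        clock_grid=clock_grid, clock_regimes=regimes, torus_signals=torus,
    )
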