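"""Event-driven simulation of excitable-refractory spiking networks.

Neurons are leaky integrate-and-fire units with an absolute refractory
period — the simplest dynamics that are *excitable* (fire only when driven
past threshold) and *refractory* (silent for a fixed time after firing).
No neuron is intrinsically oscillatory; all rhythm comes from directed
cycles in the network and their transmission delays.

Time is continuous and the simulation is exactly event-driven: membrane
potentials are updated lazily in closed form (exponential decay between
events), and every spike schedules deliveries at emission time + the
edge's real-valued delay, with no time-step quantisation.  Exactness
matters because the central comparison of the package is between generic
real-valued delays and unit (lattice) delays, where equal-hop parallel
walks produce coincident arrivals ("dead heats").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .netgen import ColumnNetwork, NetworkOfNetworks

__all__ = [
    "NeuronDynamicsParams",
    "StimulusRegime",
    "SpikeTrain",
    "simulate_spiking",
    "count_distinct_arrival_times",
]


@dataclass
class NeuronDynamicsParams:
    """Leaky integrate-and-fire parameters (model units).

    The potential decays toward ``rest`` with time constant ``leak_tau``;
    an arriving kick adds the edge weight instantaneously; crossing
    ``threshold`` emits a spike, resets the potential to ``reset`` and
    silences the neuron for ``refractory`` time units.  Kicks delivered
    during the refractory period are discarded.
    """

    threshold: float = 1.0
    reset: float = 0.0
    rest: float = 0.0
    leak_tau: float = 5.0
    refractory: float = 1.0

    def __post_init__(self) -> None:
        if self.threshold <= self.rest:
            raise ValueError("threshold must exceed rest")
        if self.refractory <= 0:
            raise ValueError("refractory period must be > 0")
        if self.leak_tau <= 0:
            raise ValueError("leak_tau must be > 0")


@dataclass
class StimulusRegime:
    """External forcing: explicit spike times and/or Poisson spike trains.

    ``spikes`` is a list of (target unit, time) pairs; ``poisson`` a list of
    (target unit, rate, (t_start, t_stop)) descriptors expanded with
    ``seed``.  ``amplitude`` is the membrane kick per forced spike; None
    means suprathreshold forcing (1.1x the threshold-rest gap), so a forced
    spike directly elicits a spike in a resting target.
    """

    label: str = "stimulus"
    spikes: list[tuple[int, float]] = field(default_factory=list)
    poisson: list[tuple[int, float, tuple[float, float]]] = field(default_factory=list)
    amplitude: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for unit, t in self.spikes:
            if t < 0:
                raise ValueError(f"stimulus spike time {t} for unit {unit} is negative")
        for unit, rate, _win in self.poisson:
            if rate < 0:
                raise ValueError(f"Poisson rate {rate} for unit {unit} is negative")

    def expand(self, t_end: float, amplitude: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Materialise all forced kicks as (times, targets, amps), time-sorted."""
        times = [t for _, t in self.spikes]
        units = [u for u, _ in self.spikes]
        rng = np.random.default_rng(self.seed)
        for unit, rate, (t0, t1) in self.poisson:
            t1 = min(t1, t_end)
            if rate <= 0 or t1 <= t0:
                continue
            # expected count with safety margin; exact thinning not needed
            n_exp = rng.poisson(rate * (t1 - t0))
            ts = np.sort(rng.uniform(t0, t1, n_exp))
            times.extend(ts.tolist())
            units.extend([unit] * len(ts))
        times = np.asarray(times, dtype=np.float64)
        units = np.asarray(units, dtype=np.int64)
        order = np.lexsort((units, times))
        amps = np.full(times.size, amplitude)
        return times[order], units[order], amps[order]


@dataclass
class SpikeTrain:
    """Recorded spikes of the observed units, time-sorted.

    ``deliveries`` (optional) is the full delivery log (unit, arrival time)
    used by the dead-heat accounting; populated only when the simulation is
    run with ``record_deliveries=True``.
    """

    units: np.ndarray
    times: np.ndarray
    t_end: float
    observed: frozenset
    refractory: float
    deliveries: tuple[np.ndarray, np.ndarray] | None = None

    @property
    def events(self) -> list[tuple[int, float]]:
        return list(zip(self.units.tolist(), self.times.tolist()))

    @property
    def n_spikes(self) -> int:
        return int(self.units.size)

    def spikes_of(self, unit: int) -> np.ndarray:
        return self.times[self.units == unit]


# ---------------------------------------------------------------------------
# numba kernel: binary heap keyed on (time, edge id); external forcing is a
# pre-sorted array merged in (external events win ties, i.e. edge id -1).
# ---------------------------------------------------------------------------

@njit(cache=False)
def _heap_push(ht, he, size, t, e):
    i = size
    ht[i] = t
    he[i] = e
    while i > 0:
        parent = (i - 1) >> 1
        if (ht[parent] > ht[i]) or (ht[parent] == ht[i] and he[parent] > he[i]):
            ht[parent], ht[i] = ht[i], ht[parent]
            he[parent], he[i] = he[i], he[parent]
            i = parent
        else:
            break
    return size + 1


@njit(cache=False)
def _heap_pop(ht, he, size):
    t, e = ht[0], he[0]
    size -= 1
    ht[0] = ht[size]
    he[0] = he[size]
    i = 0
    while True:
        l = 2 * i + 1
        r = l + 1
        smallest = i
        if l < size and ((ht[l] < ht[smallest]) or (ht[l] == ht[smallest] and he[l] < he[smallest])):
            smallest = l
        if r < size and ((ht[r] < ht[smallest]) or (ht[r] == ht[smallest] and he[r] < he[smallest])):
            smallest = r
        if smallest == i:
            break
        ht[smallest], ht[i] = ht[i], ht[smallest]
        he[smallest], he[i] = he[i], he[smallest]
        i = smallest
    return t, e, size


@njit(cache=False)
def _run_events(
    indptr, targets, weights, delays,
    ext_t, ext_u, ext_a,
    threshold, reset, rest, leak_tau, rho,
    t_end, record_mask, record_deliv,
):
    n = indptr.size - 1
    v = np.full(n, rest)
    t_last = np.zeros(n)
    refr_until = np.full(n, -1.0)

    cap = 4096
    ht = np.empty(cap)
    he = np.empty(cap, np.int64)
    size = 0

    sp_cap = 4096
    sp_u = np.empty(sp_cap, np.int64)
    sp_t = np.empty(sp_cap)
    n_sp = 0

    dl_cap = 4096 if record_deliv else 1
    dl_u = np.empty(dl_cap, np.int64)
    dl_t = np.empty(dl_cap)
    n_dl = 0

    p_ext = 0
    n_ext = ext_t.size

    while True:
        # next event: min over heap top and external pointer; external (edge
        # id -1) wins ties at equal times
        if size == 0 and p_ext >= n_ext:
            break
        use_ext = False
        if size == 0:
            use_ext = True
        elif p_ext < n_ext and (ext_t[p_ext] < ht[0] or (ext_t[p_ext] == ht[0])):
            use_ext = True

        if use_ext:
            t = ext_t[p_ext]
            u = ext_u[p_ext]
            w = ext_a[p_ext]
            p_ext += 1
        else:
            t, e, size = _heap_pop(ht, he, size)
            u = targets[e]
            w = weights[e]
        if t > t_end:
            break

        if record_deliv:
            if n_dl >= dl_cap:
                dl_cap *= 2
                tmp_u = np.empty(dl_cap, np.int64)
                tmp_t = np.empty(dl_cap)
                tmp_u[:n_dl] = dl_u[:n_dl]
                tmp_t[:n_dl] = dl_t[:n_dl]
                dl_u, dl_t = tmp_u, tmp_t
            dl_u[n_dl] = u
            dl_t[n_dl] = t
            n_dl += 1

        if t < refr_until[u]:
            continue  # absolute refractory: kick discarded

        # lazy exponential decay toward rest
        v[u] = rest + (v[u] - rest) * np.exp(-(t - t_last[u]) / leak_tau)
        t_last[u] = t
        v[u] += w
        if v[u] >= threshold:
            # spike
            if record_mask[u]:
                if n_sp >= sp_cap:
                    sp_cap *= 2
                    tmp_u = np.empty(sp_cap, np.int64)
                    tmp_t = np.empty(sp_cap)
                    tmp_u[:n_sp] = sp_u[:n_sp]
                    tmp_t[:n_sp] = sp_t[:n_sp]
                    sp_u, sp_t = tmp_u, tmp_t
                sp_u[n_sp] = u
                sp_t[n_sp] = t
                n_sp += 1
            v[u] = reset
            refr_until[u] = t + rho
            for e2 in range(indptr[u], indptr[u + 1]):
                ta = t + delays[e2]
                if ta <= t_end:
                    if size >= cap:
                        cap *= 2
                        tmp_ht = np.empty(cap)
                        tmp_he = np.empty(cap, np.int64)
                        tmp_ht[:size] = ht[:size]
                        tmp_he[:size] = he[:size]
                        ht, he = tmp_ht, tmp_he
                    size = _heap_push(ht, he, size, ta, e2)

    return sp_u[:n_sp], sp_t[:n_sp], dl_u[:n_dl], dl_t[:n_dl]


def _flatten(network: ColumnNetwork | NetworkOfNetworks):
    """CSR adjacency over global neuron ids for either network type."""
    if isinstance(network, ColumnNetwork):
        n = network.n
        src, tgt = network.sources, network.targets
        w, d = network.weights, network.delays
    else:
        offsets = np.cumsum([0] + [c.n for c in network.columns])
        n = int(offsets[-1])
        parts_s, parts_t, parts_w, parts_d = [], [], [], []
        for i, c in enumerate(network.columns):
            parts_s.append(c.sources + offsets[i])
            parts_t.append(c.targets + offsets[i])
            parts_w.append(c.weights)
            parts_d.append(c.delays)
        parts_s.append(offsets[network.inter_sources_col] + network.inter_sources_neu)
        parts_t.append(offsets[network.inter_targets_col] + network.inter_targets_neu)
        parts_w.append(network.inter_weights)
        parts_d.append(network.inter_delays)
        src = np.concatenate(parts_s).astype(np.int64)
        tgt = np.concatenate(parts_t).astype(np.int64)
        w = np.concatenate(parts_w)
        d = np.concatenate(parts_d)
    # sort edges by (source, target) for a stable global edge-id order
    order = np.lexsort((tgt, src))
    src, tgt, w, d = src[order], tgt[order], w[order], d[order]
    indptr = np.zeros(n + 1, dtype=np.int64)
    np.add.at(indptr, src + 1, 1)
    indptr = np.cumsum(indptr)
    return n, indptr, tgt, w, d


def simulate_spiking(
    network: ColumnNetwork | NetworkOfNetworks,
    params: NeuronDynamicsParams,
    stimulus: StimulusRegime,
    t_end: float,
    observed=None,
    seed: int = 0,
    record_deliveries: bool = False,
) -> SpikeTrain:
    """Run the exact event-driven simulation and return observed spikes.

    ``observed`` is a set of unit ids (global ids for a
    NetworkOfNetworks); None records every unit.  ``seed`` re-seeds the
    stimulus's Poisson expansion so batteries can derive fresh realisations
    of a regime; explicit spike lists are unaffected by it.
    """
    if t_end <= 0:
        raise ValueError(f"t_end must be > 0, got {t_end}")
    n, indptr, tgt, w, d = _flatten(network)
    if observed is None:
        observed = frozenset(range(n))
    else:
        observed = frozenset(int(u) for u in observed)
        bad = [u for u in observed if not (0 <= u < n)]
        if bad:
            raise ValueError(f"observed units {sorted(bad)} not in network (n={n})")

    amp = stimulus.amplitude
    if amp is None:
        amp = 1.1 * (params.threshold - params.rest)
    stim = StimulusRegime(
        label=stimulus.label,
        spikes=stimulus.spikes,
        poisson=stimulus.poisson,
        amplitude=stimulus.amplitude,
        seed=(stimulus.seed + seed) % (2**31),
    )
    ext_t, ext_u, ext_a = stim.expand(t_end, amp)
    bad = [u for u in np.unique(ext_u).tolist() if not (0 <= u < n)]
    if bad:
        raise ValueError(f"stimulus targets unknown units {bad} (n={n})")

    mask = np.zeros(n, dtype=np.bool_)
    mask[list(observed)] = True
    sp_u, sp_t, dl_u, dl_t = _run_events(
        indptr, tgt, w, d,
        ext_t, ext_u, ext_a,
        params.threshold, params.reset, params.rest, params.leak_tau,
        params.refractory,
        float(t_end), mask, record_deliveries,
    )
    order = np.lexsort((sp_u, sp_t))
    return SpikeTrain(
        units=sp_u[order],
        times=sp_t[order],
        t_end=float(t_end),
        observed=observed,
        refractory=params.refractory,
        deliveries=(dl_u, dl_t) if record_deliveries else None,
    )


def count_distinct_arrival_times(
    train_or_log,
    window: tuple[float, float] | None = None,
    tol: float = 1e-9,
) -> int:
    """Count distinct delivery timestamps per neuron, summed over neurons.

    Under generic real-valued delays, parallel directed walks of equal hop
    count arrive at distinct times; forcing every delay to 1 collapses them
    into coincident arrivals ("dead heats"), which this count quantifies.
    Timestamps are compared after rounding to ``tol``.
    """
    if isinstance(train_or_log, SpikeTrain):
        if train_or_log.deliveries is None:
            raise ValueError(
                "SpikeTrain has no delivery log; simulate with record_deliveries=True"
            )
        units, times = train_or_log.deliveries
    else:
        units, times = train_or_log
        units = np.asarray(units, dtype=np.int64)
        times = np.asarray(times, dtype=np.float64)
    if times.size == 0:
        return 0
    if window is not None:
        keep = (times >= window[0]) & (times <= window[1])
        units, times = units[keep], times[keep]
    if times.size == 0:
        return 0
    keys = np.round(times / tol).astype(np.int64)
    pairs = np.unique(np.stack([units, keys]), axis=1)
    return int(pairs.shape[1])
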