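"""Reverse-engineering pipeline: discover hierarchical dynamical modes
from batteries of stimulation experiments.

A battery applies many stimulus regimes (each forcing different units) to
the same system and records the multichannel response of the observed
units.  Responses are compared with an offset-tolerant correlation
dissimilarity — relative firing patterns matter, not absolute time — and
hierarchically clustered.  Each cluster is a dynamical "mode": a class of
similar internal responses.  Because clustering always "finds" structure,
mode significance is assessed against circular-shift surrogates, and mode
competition/preconditioning are quantified on top of the hierarchy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import squareform

from .column_sim import NeuronDynamicsParams, StimulusRegime, simulate_spiking
from .clockdyn import ClockNetwork, KClock, simulate_clock_network
from .kestim import bin_and_smooth

__all__ = [
    "ResponseRecord",
    "DissimilarityMatrix",
    "ModeHierarchy",
    "SignificanceReport",
    "PreconditioningReport",
    "run_experiment_battery",
    "response_dissimilarity",
    "dissimilarity_matrix",
    "hierarchical_modes",
    "clustering_significance",
    "mode_exclusivity",
    "preconditioning_index",
]


@dataclass
class ResponseRecord:
    """One experiment's response: observed units x time bins."""

    experiment_id: int
    regime_label: str
    matrix: np.ndarray
    bin_width: float

    def __post_init__(self) -> None:
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=np.float64))
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("response matrix contains non-finite entries")


@dataclass
class DissimilarityMatrix:
    values: np.ndarray
    max_lag: int
    metric: str = "1 - max-lag correlation"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("dissimilarity matrix must be square")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class ModeHierarchy:
    """Dendrogram over experiments with requested level cuts.

    ``assignments[L]`` maps each experiment to a cluster id in 1..L;
    ``medoids[L]`` gives, per cluster, the member experiment minimising its
    summed within-cluster dissimilarity.
    """

    merge: np.ndarray  # scipy linkage matrix
    assignments: dict[int, np.ndarray]
    medoids: dict[int, dict[int, int]]
    linkage_method: str


@dataclass
class SignificanceReport:
    observed: float
    null_values: np.ndarray
    p_value: float
    n_perm: int
    seed: int


@dataclass
class PreconditioningReport:
    unprimed_distribution: np.ndarray
    primed_distributions: dict[int, np.ndarray]
    exclusivity_index: float
    entropy_reduction_bits: float
    match_rate_primed: float
    match_rate_unprimed: float


# ---------------------------------------------------------------------------
# batteries
# ---------------------------------------------------------------------------

def _derive_seed(master: int, *keys) -> int:
    ints = tuple(
        int.from_bytes(k.encode(), "little") % (2**32) if isinstance(k, str) else int(k)
        for k in keys
    )
    return int(np.random.SeedSequence((master,) + ints).generate_state(1)[0] % (2**31))


def _jitter_clock_network(net: ClockNetwork, scale: float, seed: int) -> ClockNetwork:
    """Per-run copy with phase perturbations (trial-to-trial variability)."""
    rng = np.random.default_rng(seed)
    clocks = [
        KClock(phases=c.phases + rng.normal(0, scale, c.k), rates=c.rates.copy())
        for c in net.clocks
    ]
    return ClockNetwork(clocks=clocks, edges=net.edges, seed=net.seed,
                        positions=net.positions)


def simulate_response(
    system,
    regime: StimulusRegime,
    t_end: float,
    observed,
    run_seed: int,
    bin_width: float = 0.5,
    kernel_width: float = 0.75,
    sample_dt: float | None = None,
    init_jitter: float = 0.25,
    t_start: float = 0.0,
    ext_kick=1.0,
    initial_phases: list[np.ndarray] | None = None,
) -> np.ndarray:
    """Simulate one run and return the response matrix (units x bins).

    ``system`` is either a ClockNetwork or (network, NeuronDynamicsParams).
    Clock responses are sin-of-phase channels; spiking responses smoothed
    rates.  ``init_jitter`` perturbs clock initial phases per run;
    ``initial_phases`` overrides the network's initial state outright
    (used to continue from a pre-driven state).
    """
    if isinstance(system, ClockNetwork):
        net = system
        if initial_phases is not None:
            net = ClockNetwork(
                clocks=[KClock(phases=p, rates=c.rates.copy())
                        for p, c in zip(initial_phases, net.clocks)],
                edges=net.edges, seed=net.seed, positions=net.positions,
            )
        if init_jitter:
            net = _jitter_clock_network(net, init_jitter, run_seed)
        rec = simulate_clock_network(
            net, regime, t_end=t_end, observed=observed,
            sample_dt=sample_dt or bin_width, seed=run_seed, ext_kick=ext_kick,
        )
        mat = rec.sin_channels()
        if t_start > 0:
            mat = mat[:, rec.sample_times >= t_start]
        return mat
    network, params = system
    train = simulate_spiking(network, params, regime, t_end=t_end,
                             observed=observed, seed=run_seed)
    sig = bin_and_smooth(train, bin_width, kernel_width, channels=sorted(observed))
    mat = sig.rates
    if t_start > 0:
        mat = mat[:, int(t_start / bin_width):]
    return mat


def run_experiment_battery(
    system,
    regimes: list[StimulusRegime],
    reps: int,
    t_end: float,
    observed,
    seed: int = 0,
    **response_kwargs,
) -> list[ResponseRecord]:
    """Simulate ``reps`` independent runs of every regime.

    Each run gets a sub-seed derived from the master seed, the regime index
    and the rep index, so the battery is reproducible as a whole and every
    record is reproducible individually.
    """
    if not regimes:
        raise ValueError("battery needs at least one regime")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    bw = response_kwargs.get("bin_width", 0.5)
    records = []
    eid = 0
    for ri, regime in enumerate(regimes):
        for rep in range(reps):
            sub = _derive_seed(seed, ri, rep)
            mat = simulate_response(system, regime, t_end, observed, sub,
                                    **response_kwargs)
            records.append(
                ResponseRecord(experiment_id=eid, regime_label=regime.label,
                               matrix=mat, bin_width=bw)
            )
            eid += 1
    return records


# ---------------------------------------------------------------------------
# dissimilarity
# ---------------------------------------------------------------------------

def _lagged_correlation(a: np.ndarray, b: np.ndarray, lag: int) -> float:
    """Pearson correlation of flattened unit x time matrices at shift
    ``lag`` (b shifted right by lag), over the overlapping window."""
    t = a.shape[1]
    if lag >= 0:
        aw, bw = a[:, lag:], b[:, : t - lag]
    else:
        aw, bw = a[:, : t + lag], b[:, -lag:]
    x = aw.ravel()
    y = bw.ravel()
    x = x - x.mean()
    y = y - y.mean()
    nx = float(np.dot(x, x))
    ny = float(np.dot(y, y))
    if nx == 0.0 or ny == 0.0:
        # zero-variance window: correlation undefined; count as uncorrelated
        # unless the windows are literally identical
        return 1.0 if np.array_equal(aw, bw) else 0.0
    return float(np.dot(x, y) / np.sqrt(nx * ny))


def response_dissimilarity(r1: ResponseRecord, r2: ResponseRecord, max_lag: int = 8) -> float:
    """Offset-tolerant dissimilarity: 1 - max correlation over integer lags.

    The maximum is over |lag| <= max_lag bins, so two responses identical up
    to an absolute time shift within the window are at distance 0; values
    lie in [0, 2] (2 = perfectly anti-correlated at every lag).
    """
    if r1.matrix.shape[0] != r2.matrix.shape[0]:
        raise ValueError("records have different unit sets")
    if r1.bin_width != r2.bin_width:
        raise ValueError("records have different bin widths")
    t = min(r1.matrix.shape[1], r2.matrix.shape[1])
    if r1.matrix.shape[1] != r2.matrix.shape[1]:
        raise ValueError("records have different lengths")
    if max_lag >= t:
        raise ValueError("max_lag must be smaller than the record length")
    best = max(
        _lagged_correlation(r1.matrix, r2.matrix, lag)
        for lag in range(-max_lag, max_lag + 1)
    )
    return float(np.clip(1.0 - best, 0.0, 2.0))


def _stack(records: list[ResponseRecord]) -> np.ndarray:
    shapes = {r.matrix.shape for r in records}
    if len(shapes) > 1:
        raise ValueError(f"records have inconsistent shapes: {shapes}")
    return np.stack([r.matrix for r in records])


def dissimilarity_matrix(records: list[ResponseRecord], max_lag: int = 8) -> DissimilarityMatrix:
    """All pairwise dissimilarities, computed lag-by-lag over the stack.

    Equivalent to calling :func:`response_dissimilarity` on every pair, but
    standardises all records' overlap windows at each lag and takes one
    matrix product, which keeps permutation-test null ensembles cheap.
    """
    if len(records) < 2:
        raise ValueError("need at least 2 records")
    x = _stack(records)  # (E, C, T)
    e, c, t = x.shape
    max_lag = int(max_lag)
    if max_lag >= t:
        raise ValueError("max_lag must be smaller than the record length")
    best = np.full((e, e), -np.inf)
    exact_equal = None
    for lag in range(0, max_lag + 1):
        a = x[:, :, lag:].reshape(e, -1)  # shifted
        b = x[:, :, : t - lag].reshape(e, -1)
        am = a - a.mean(axis=1, keepdims=True)
        bm = b - b.mean(axis=1, keepdims=True)
        na = np.linalg.norm(am, axis=1)
        nb = np.linalg.norm(bm, axis=1)
        corr = am @ bm.T  # corr[i, j] = <a_i, b_j>
        denom = np.outer(na, nb)
        zero = denom == 0
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.where(zero, 0.0, corr / np.where(zero, 1.0, denom))
        if zero.any():
            # degenerate windows: identical raw windows still count as match
            ii, jj = np.nonzero(zero)
            for i, j in zip(ii, jj):
                corr[i, j] = 1.0 if np.array_equal(x[i, :, lag:], x[j, :, : t - lag]) else 0.0
        # record i vs record j at +lag, and the transpose for -lag
        best = np.maximum(best, corr)
        best = np.maximum(best, corr.T)
    d = np.clip(1.0 - best, 0.0, 2.0)
    np.fill_diagonal(d, 0.0)
    d = 0.5 * (d + d.T)
    return DissimilarityMatrix(values=d, max_lag=max_lag)


# ---------------------------------------------------------------------------
# hierarchy, significance, competition
# ---------------------------------------------------------------------------

def hierarchical_modes(
    D: DissimilarityMatrix,
    linkage: str = "average",
    levels: list[int] | None = None,
) -> ModeHierarchy:
    """Agglomerative clustering of experiment responses.

    ``levels`` lists requested cluster counts; cutting the dendrogram at a
    coarser level always yields unions of finer-level clusters.  The medoid
    of a cluster is its member with minimal summed dissimilarity to the
    rest of the cluster.
    """
    e = D.n
    levels = sorted(levels or [2])
    if any(l > e for l in levels):
        raise ValueError(f"requested level exceeds the number of experiments ({e})")
    z = scipy_linkage(squareform(D.values, checks=False), method=linkage)
    assignments = {}
    medoids = {}
    for lv in levels:
        lab = fcluster(z, t=lv, criterion="maxclust")
        assignments[lv] = lab
        med = {}
        for cl in np.unique(lab):
            members = np.nonzero(lab == cl)[0]
            sums = D.values[np.ix_(members, members)].sum(axis=1)
            med[int(cl)] = int(members[np.argmin(sums)])
        medoids[lv] = med
    return ModeHierarchy(merge=z, assignments=assignments, medoids=medoids,
                         linkage_method=linkage)


def _cluster_contrast(D: np.ndarray, labels: np.ndarray) -> float:
    """Mean between-cluster minus mean within-cluster dissimilarity."""
    same = labels[:, None] == labels[None, :]
    off = ~np.eye(len(labels), dtype=bool)
    within = D[same & off]
    between = D[~same]
    if within.size == 0 or between.size == 0:
        return 0.0
    return float(between.mean() - within.mean())


def clustering_significance(
    records: list[ResponseRecord],
    n_perm: int = 99,
    seed: int = 0,
    n_clusters: int = 3,
    max_lag: int = 8,
    linkage: str = "average",
) -> SignificanceReport:
    """Permutation test of mode structure against circular-shift surrogates.

    The observed statistic is the between-minus-within cluster contrast at
    an ``n_clusters`` cut.  The null recomputes it on surrogate batteries
    in which each record's time axis is independently circularly shifted by
    a random offset — destroying regime-specific relative timing while
    preserving every record's marginal and autocorrelation structure.
    p = (1 + #{null >= observed}) / (1 + n_perm), so p is never zero:
    whenever you look for clustering you will find some, and the test
    quantifies how much is expected by chance.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)

    def statistic(recs):
        d = dissimilarity_matrix(recs, max_lag=max_lag)
        h = hierarchical_modes(d, linkage=linkage, levels=[n_clusters])
        return _cluster_contrast(d.values, h.assignments[n_clusters])

    observed = statistic(records)
    t = records[0].matrix.shape[1]
    null = np.empty(n_perm)
    for p in range(n_perm):
        surr = []
        for r in records:
            shift = int(rng.integers(t))
            surr.append(
                ResponseRecord(r.experiment_id, r.regime_label,
                               np.roll(r.matrix, shift, axis=1), r.bin_width)
            )
        null[p] = statistic(surr)
    p_value = (1.0 + np.sum(null >= observed)) / (1.0 + n_perm)
    return SignificanceReport(observed=observed, null_values=null,
                              p_value=float(p_value), n_perm=n_perm, seed=seed)


def mode_exclusivity(activations: np.ndarray) -> float:
    """Competition index: 1 - mean normalised entropy of per-window mode
    distributions.

    ``activations`` is windows x modes, each row a distribution.  1 means
    exactly one mode active per window (fully competitive); 0 means uniform
    co-activation.
    """
    a = np.atleast_2d(np.asarray(activations, dtype=np.float64))
    m = a.shape[1]
    if m < 2:
        raise ValueError("need at least 2 modes")
    if np.any(a < 0) or not np.allclose(a.sum(axis=1), 1.0):
        raise ValueError("each window's activation must be a distribution")
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -np.where(a > 0, a * np.log(a), 0.0).sum(axis=1)
    return float(1.0 - np.mean(h) / np.log(m))


def _entropy_bits(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def assign_to_modes(
    responses: list[np.ndarray],
    battery: list[ResponseRecord],
    hierarchy: ModeHierarchy,
    level: int,
    max_lag: int = 8,
    bin_width: float = 0.5,
) -> np.ndarray:
    """Nearest-medoid mode assignment for new responses."""
    med = hierarchy.medoids[level]
    mode_ids = sorted(med)
    out = np.empty(len(responses), dtype=np.int64)
    for i, mat in enumerate(responses):
        rec = ResponseRecord(-1, "query", mat, bin_width)
        dists = [
            response_dissimilarity(rec, battery[med[m]], max_lag=max_lag)
            for m in mode_ids
        ]
        out[i] = mode_ids[int(np.argmin(dists))]
    return out


def preconditioning_index(
    system,
    battery: list[ResponseRecord],
    hierarchy: ModeHierarchy,
    level: int,
    priming_regimes: dict[int, StimulusRegime],
    ambiguous_regime: StimulusRegime,
    reps: int,
    t_end: float,
    observed,
    seed: int = 0,
    t_prime: float | None = None,
    max_lag: int = 8,
    **response_kwargs,
) -> PreconditioningReport:
    """Measure how priming with a mode's regime biases the response to an
    ambiguous stimulus.

    The ambiguous stimulus is run ``reps`` times from rest (unprimed) and
    ``reps`` times after each priming regime has been applied during
    [0, t_prime); the response window is identical in both arms, and each
    response is assigned to its nearest mode medoid.  The exclusivity index
    is the mean over priming modes of P(assigned = primed mode | primed);
    entropy reduction is H(unprimed) - mean H(primed), in bits (negative
    values are reported as-is).
    """
    if len(priming_regimes) < 1:
        raise ValueError("need at least one priming regime")
    if not isinstance(system, ClockNetwork):
        raise ValueError("preconditioning is defined for clock networks")
    mode_ids = sorted(hierarchy.medoids[level])
    m = len(mode_ids)
    if m < 2:
        raise ValueError("hierarchy cut must contain at least 2 modes")
    bw = response_kwargs.get("bin_width", 0.5)
    if t_prime is None:
        t_prime = t_end

    def dist_of(mats) -> np.ndarray:
        lab = assign_to_modes(mats, battery, hierarchy, level,
                              max_lag=max_lag, bin_width=bw)
        return np.array([(lab == mid).mean() for mid in mode_ids])

    def shifted(regime: StimulusRegime, offset: float) -> StimulusRegime:
        return StimulusRegime(
            label=regime.label,
            spikes=[(u, t + offset) for u, t in regime.spikes],
            poisson=[(u, r, (w0 + offset, w1 + offset))
                     for u, r, (w0, w1) in regime.poisson],
            amplitude=regime.amplitude, seed=regime.seed,
        )

    def merged(a: StimulusRegime | None, b: StimulusRegime, label: str) -> StimulusRegime:
        if a is None:
            return StimulusRegime(label=label, spikes=b.spikes,
                                  poisson=b.poisson, seed=b.seed)
        return StimulusRegime(label=label, spikes=a.spikes + b.spikes,
                              poisson=a.poisson + b.poisson, seed=a.seed)

    # both arms are one continuous simulation: [0, t_prime) carries the
    # priming forcing (or silence), then the ambiguous forcing; only the
    # response window [t_prime, t_prime + t_end] is scored.  A continuous
    # run — rather than restarting from a transplanted phase state — keeps
    # priming-era signals that are still in flight on long-delay edges, so
    # the network reverberates with the primed pattern into the window.
    amb_late = shifted(ambiguous_regime, t_prime)
    total_t = t_prime + t_end

    def arm(prime_regime: StimulusRegime | None, tag, r: int) -> np.ndarray:
        stim = merged(prime_regime, amb_late,
                      f"{tag}+{ambiguous_regime.label}")
        return simulate_response(system, stim, total_t, observed,
                                 _derive_seed(seed, "run", tag, r),
                                 t_start=t_prime, **response_kwargs)

    unprimed = dist_of([arm(None, "rest", r) for r in range(reps)])

    primed = {}
    match_rates = []
    unprimed_match = []
    for mid, regime in priming_regimes.items():
        dist = dist_of([arm(regime, mid, r) for r in range(reps)])
        primed[mid] = dist
        pos = mode_ids.index(mid)
        match_rates.append(dist[pos])
        unprimed_match.append(unprimed[pos])

    entropy_red = _entropy_bits(unprimed) - float(
        np.mean([_entropy_bits(p) for p in primed.values()])
    )
    return PreconditioningReport(
        unprimed_distribution=unprimed,
        primed_distributions=primed,
        exclusivity_index=float(np.mean(match_rates)),
        entropy_reduction_bits=entropy_red,
        match_rate_primed=float(np.mean(match_rates)),
        match_rate_unprimed=float(np.mean(unprimed_match)),
    )
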