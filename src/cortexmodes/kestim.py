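"""Degrees-of-freedom estimation from recordings, and the two studies
built on it: the k ~ log n scaling study and the unit-delay quench
experiment.

A neural column driven into sustained activity behaves collectively like a
k-dimensional clock: k independent phases winding on a torus.  k is
estimated here from observed firing rates via delay embedding and the
Grassberger-Procaccia correlation dimension: embed a scalar observable,
compute the correlation sum C(r), fit the slope of log C against log r
over an automatically selected scaling range, and round to an integer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.stats import spearmanr

from .netgen import ColumnNetwork, generate_column_network
from .column_sim import (
    NeuronDynamicsParams,
    StimulusRegime,
    SpikeTrain,
    simulate_spiking,
    count_distinct_arrival_times,
)

__all__ = [
    "RateSignal",
    "KEstimate",
    "bin_and_smooth",
    "estimate_k",
    "k_scaling_study",
    "delay_quench_experiment",
]


@dataclass
class RateSignal:
    """Smoothed firing rates: channels x time-bins, events per time unit."""

    rates: np.ndarray
    bin_width: float
    kernel_width: float
    channels: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.rates = np.atleast_2d(np.asarray(self.rates, dtype=np.float64))

    @property
    def n_channels(self) -> int:
        return self.rates.shape[0]

    @property
    def n_bins(self) -> int:
        return self.rates.shape[1]


@dataclass
class KEstimate:
    """Correlation-dimension estimate with diagnostics.

    ``k_hat`` is ``dim_raw`` rounded and clipped at zero; diagnostics carry
    the r-grid, correlation sums, local slopes and embedding settings so a
    bad scaling-range fit can be spotted.
    """

    k_hat: int
    dim_raw: float
    method: str = "grassberger-procaccia"
    diagnostics: dict = field(default_factory=dict)


def bin_and_smooth(
    train: SpikeTrain,
    bin_width: float,
    kernel_width: float = 0.0,
    channels=None,
) -> RateSignal:
    """Histogram spikes per channel, convert to rates, Gaussian-smooth.

    Total spike count is conserved exactly before smoothing (and, up to
    boundary truncation, after).  ``kernel_width`` is the Gaussian sigma in
    time units; 0 disables smoothing.
    """
    if bin_width <= 0:
        raise ValueError(f"bin_width must be > 0, got {bin_width}")
    if channels is None:
        channels = sorted(train.observed)
    n_bins = int(np.floor(train.t_end / bin_width))
    if n_bins < 1:
        raise ValueError("t_end shorter than one bin")
    edges = np.arange(n_bins + 1) * bin_width
    rates = np.zeros((len(channels), n_bins))
    for i, ch in enumerate(channels):
        ts = train.spikes_of(ch)
        ts = ts[ts < edges[-1]]
        rates[i], _ = np.histogram(ts, bins=edges)
    rates /= bin_width
    if kernel_width > 0:
        rates = gaussian_filter1d(rates, sigma=kernel_width / bin_width, axis=1, mode="nearest")
    return RateSignal(rates=rates, bin_width=bin_width, kernel_width=kernel_width,
                      channels=list(channels))


# ---------------------------------------------------------------------------
# Grassberger-Procaccia machinery
# ---------------------------------------------------------------------------

def _principal_observable(rates: np.ndarray) -> np.ndarray:
    """First principal component of the channel x bins matrix.

    A single generic scalar observable suffices for delay-embedding; the
    leading PC is used so no one channel is privileged.
    """
    if rates.shape[0] == 1:
        return rates[0].copy()
    x = rates - rates.mean(axis=1, keepdims=True)
    # leading left-singular direction projected out
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    return vt[0] * s[0]


def _auto_lag(x: np.ndarray, max_lag: int) -> int:
    """First lag where autocorrelation drops below 1/e (bounded)."""
    x = x - x.mean()
    denom = float(np.dot(x, x))
    if denom == 0:
        return 1
    for lag in range(1, max_lag + 1):
        r = float(np.dot(x[:-lag], x[lag:])) / denom
        if r < 1.0 / np.e:
            return lag
    return max_lag


def _delay_embed(x: np.ndarray, m: int, lag: int) -> np.ndarray:
    n = x.size - (m - 1) * lag
    if n < 2:
        raise ValueError("signal too short for requested embedding")
    out = np.empty((n, m))
    for j in range(m):
        out[:, j] = x[j * lag: j * lag + n]
    return out


def _pairwise_admissible(pts: np.ndarray, orig_idx: np.ndarray, theiler: int) -> np.ndarray:
    """Euclidean distances of all Theiler-admissible unordered pairs."""
    n = pts.shape[0]
    out = []
    chunk = max(1, int(4e6 // max(n, 1)))
    for a in range(0, n, chunk):
        b = min(a + chunk, n)
        d = np.sqrt(((pts[a:b, None, :] - pts[None, :, :]) ** 2).sum(axis=2))
        sep = orig_idx[None, :] - orig_idx[a:b, None]
        out.append(d[sep > theiler])  # upper triangle + Theiler exclusion
    return np.concatenate(out) if out else np.empty(0)


def estimate_k(
    signal: RateSignal,
    embed_dim: int = 7,
    embed_lag: int | None = None,
    theiler: int | None = None,
    max_points: int = 3000,
    c_cut: float = 0.01,
    n_r: int = 40,
) -> KEstimate:
    """Grassberger-Procaccia correlation-dimension estimate of k.

    The signal's leading principal component is z-scored and delay-embedded
    into ``embed_dim`` dimensions (lag chosen from the autocorrelation time
    when not given).  The correlation-sum slope is extracted by the Takens
    maximum-likelihood form over the automatically selected scaling range
    r <= r0, where r0 is the radius at which the correlation sum reaches
    ``c_cut`` — i.e. the fit is weighted over the small-distance regime
    where the power law holds.  Pairs closer than ``theiler`` bins in time
    (default: 10x the embedding lag) are excluded so that trajectory
    segments do not masquerade as low-dimensional structure.  ``k_hat`` is
    the rounded slope, clipped at zero.  Dimension is scale-free: the
    estimate is invariant to affine rescaling of the signal.
    """
    if embed_dim < 1:
        raise ValueError("embed_dim must be >= 1")
    x = _principal_observable(signal.rates)
    min_len = (embed_dim - 1) * max(embed_lag or 1, 1) + 20
    if x.size < min_len:
        raise ValueError(
            f"signal too short for embedding: need >= {min_len} bins, got {x.size}"
        )
    sd = x.std()
    if sd < 1e-12 * (1.0 + np.abs(x).max()):
        # constant signal: a point attractor
        return KEstimate(k_hat=0, dim_raw=0.0, diagnostics={"reason": "constant signal"})
    x = (x - x.mean()) / sd
    if embed_lag is None:
        embed_lag = _auto_lag(x, max(1, x.size // (embed_dim * 4)))
    if theiler is None:
        theiler = 10 * embed_lag
    pts = _delay_embed(x, embed_dim, embed_lag)
    idx = np.arange(pts.shape[0])
    if pts.shape[0] > max_points:
        # random (seeded) subsample: a uniform stride aliases against the
        # winding frequencies and distorts small-distance pair statistics
        sub_rng = np.random.default_rng(12345)
        sel = np.sort(sub_rng.choice(pts.shape[0], size=max_points, replace=False))
        pts = pts[sel]
        idx = idx[sel]

    dists = _pairwise_admissible(pts, idx, theiler)
    if dists.size < 100:
        raise ValueError(
            "too few Theiler-admissible pairs for a dimension estimate; "
            "need a longer signal or a smaller theiler window"
        )
    dists = np.sort(dists)
    if dists[-1] == 0:
        return KEstimate(k_hat=0, dim_raw=0.0, diagnostics={"reason": "degenerate embedding"})

    # scaling range: all pairs below the radius where C(r) = c_cut
    m_cut = max(50, int(c_cut * dists.size))
    m_cut = min(m_cut, dists.size)
    r0 = dists[m_cut - 1]
    dd = dists[:m_cut]
    dd = dd[dd > 0]
    if dd.size < 10 or r0 <= 0:
        return KEstimate(k_hat=0, dim_raw=0.0,
                         diagnostics={"reason": "no scaling range"})
    logs = np.log(dd / r0)
    slope = float(-dd.size / logs.sum())

    # diagnostics: correlation sum on a log-spaced grid with local slopes
    r_grid = np.geomspace(max(dists[0], r0 * 1e-3), dists[-1], n_r)
    c = np.searchsorted(dists, r_grid, side="right") / dists.size
    pos = c > 0
    local = np.full(n_r - 1, np.nan)
    lv = np.diff(np.log(c[pos])) / np.diff(np.log(r_grid[pos]))
    local[np.nonzero(pos)[0][1:] - 1] = lv

    k_hat = max(0, int(round(slope)))
    return KEstimate(
        k_hat=k_hat,
        dim_raw=slope,
        diagnostics={
            "r": r_grid,
            "C": c,
            "local_slopes": local,
            "r0": float(r0),
            "c_cut": c_cut,
            "embed_dim": embed_dim,
            "embed_lag": int(embed_lag),
            "theiler": int(theiler),
            "n_points": int(pts.shape[0]),
            "n_pairs": int(dists.size),
        },
    )


# ---------------------------------------------------------------------------
# Synthetic reference signals
# ---------------------------------------------------------------------------

_TORUS_FREQS = (1.0, np.sqrt(2.0), np.sqrt(5.0))


def torus_signal(j: int, t_len: float = 400.0, dt: float = 0.05,
                 seed: int = 0) -> RateSignal:
    """Quasi-periodic test signal with exactly j degrees of freedom.

    A sum of j unit-amplitude sines at pairwise incommensurate frequencies
    (1, sqrt(2), sqrt(5)) with random initial phases: the trajectory fills a
    j-torus, so its correlation dimension is j.  Ground truth for the
    estimator; higher j needs a longer record (torus filling is slow).
    """
    if not 1 <= j <= len(_TORUS_FREQS):
        raise ValueError(f"j must be in 1..{len(_TORUS_FREQS)}")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, t_len, dt)
    phases = rng.uniform(0, 2 * np.pi, j)
    x = sum(np.sin(f * t + p) for f, p in zip(_TORUS_FREQS[:j], phases))
    return RateSignal(rates=x[None, :], bin_width=dt, kernel_width=0.0)


# ---------------------------------------------------------------------------
# Studies
# ---------------------------------------------------------------------------

#: Desk-scale operating point for the column studies: a near-critical
#: sparse transmission regime (mean out-degree ~1.2, single-kick
#: suprathreshold weight) in which sustained activity consists of spike
#: packets circulating on directed loops.  Distinct loops have
#: incommensurate real-valued delay-sum periods, so the collective dynamics
#: is a winding on a torus whose dimension counts the active independent
#: loops — the regime in which k is both well-defined and resolvable at
#: desk scale.
DEFAULT_COLUMN_PARAMS = {
    "mean_degree": 1.2,
    "delay_range": (0.5, 2.0),
    "weight": 1.1,
}

DEFAULT_DYNAMICS = dict(threshold=1.0, reset=0.0, rest=0.0, leak_tau=0.5,
                        refractory=2.0)

#: recording/estimation defaults for the studies
STUDY_BIN_WIDTH = 0.5
STUDY_KERNEL_WIDTH = 0.75
STUDY_TRANSIENT = 300.0
STUDY_EMBED_DIM = 10


def _column_for_study(n: int, column_params: dict, seed: int) -> ColumnNetwork:
    cp = dict(DEFAULT_COLUMN_PARAMS)
    cp.update(column_params or {})
    if "density" not in cp:
        k = cp.pop("mean_degree")
        cp["density"] = min(1.0, k / max(n - 1, 1))
    else:
        cp.pop("mean_degree", None)
    return generate_column_network(n=n, seed=seed, **cp)


def _default_stimulus(n: int, t_end: float, seed: int) -> StimulusRegime:
    """Sustained stimulation: a broad ignition volley plus sparse periodic
    re-ignition kicks, all at deterministic (seeded) times.

    Half the neurons are kicked during [0, 3); thereafter 5% of the
    neurons (at least 3) are kicked every 250 time units, so activity that
    has collapsed is re-seeded and dormant loops get repopulated.  The
    re-ignition count scales with n so the per-capita drive is
    size-invariant.
    """
    rng = np.random.default_rng(seed)
    spikes = []
    nk = max(10, n // 2)
    spikes += [(int(i), float(t)) for i, t in
               zip(rng.choice(n, nk, replace=False), rng.uniform(0, 3, nk))]
    m = max(3, n // 20)
    for t0 in np.arange(250.0, t_end, 250.0):
        spikes += [(int(i), float(t0 + t)) for i, t in
                   zip(rng.choice(n, m, replace=False), rng.uniform(0, 3, m))]
    return StimulusRegime(label="sustained", spikes=spikes, seed=seed)


def _windowed_k(train: SpikeTrain, estimator_kwargs: dict | None,
                n_windows: int = 3) -> int:
    """Median k_hat over disjoint post-transient windows of one recording.

    The windowed median suppresses single-window estimator noise while the
    underlying attractor is unchanged.
    """
    kwargs = {"embed_dim": STUDY_EMBED_DIM}
    kwargs.update(estimator_kwargs or {})
    sig = bin_and_smooth(train, STUDY_BIN_WIDTH, STUDY_KERNEL_WIDTH)
    transient = min(STUDY_TRANSIENT, 0.2 * train.t_end)
    w0 = int(transient / STUDY_BIN_WIDTH)
    nb = sig.n_bins
    ks = []
    for i in range(n_windows):
        a = w0 + i * (nb - w0) // n_windows
        b = w0 + (i + 1) * (nb - w0) // n_windows
        window = RateSignal(sig.rates[:, a:b], STUDY_BIN_WIDTH, STUDY_KERNEL_WIDTH)
        ks.append(estimate_k(window, **kwargs).k_hat)
    return int(np.median(ks))


def k_scaling_study(
    n_list,
    reps: int,
    column_params: dict | None = None,
    stimulus_template=None,
    seed: int = 0,
    t_end: float = 4200.0,
    dynamics: NeuronDynamicsParams | None = None,
    estimator_kwargs: dict | None = None,
):
    """Estimate mean k_hat across column sizes and test the log-n trend.

    For each n, ``reps`` columns are generated (fresh sub-seeds), simulated
    under sustained stimulation, and their k estimated (median over three
    post-transient windows).  Returns a dict with a per-n summary table
    (lists ``n``, ``reps``, ``k_mean``, ``k_sd``), the Spearman correlation
    of mean k_hat with log n, and the sign of the regression slope of mean
    k_hat on log n.  Per-cell failures are recorded in ``failures`` without
    aborting the study.
    """
    n_list = [int(n) for n in n_list]
    if any(n < 10 for n in n_list):
        raise ValueError("column sizes must be >= 10")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    dynamics = dynamics or NeuronDynamicsParams(**DEFAULT_DYNAMICS)
    rows = {"n": [], "reps": [], "k_mean": [], "k_sd": []}
    failures = []
    per_cell = {}
    for n in n_list:
        ks = []
        for rep in range(reps):
            sub = int(np.random.SeedSequence((seed, n, rep)).generate_state(1)[0] % (2**31))
            try:
                net = _column_for_study(n, column_params or {}, sub)
                if stimulus_template is not None:
                    stim = stimulus_template(n=n, t_end=t_end, seed=sub)
                else:
                    stim = _default_stimulus(n, t_end, sub + 77)
                train = simulate_spiking(net, dynamics, stim, t_end=t_end, seed=0)
                ks.append(_windowed_k(train, estimator_kwargs))
            except Exception as exc:  # record, keep going
                failures.append({"n": n, "rep": rep, "error": repr(exc)})
        per_cell[n] = ks
        rows["n"].append(n)
        rows["reps"].append(len(ks))
        rows["k_mean"].append(float(np.mean(ks)) if ks else float("nan"))
        rows["k_sd"].append(float(np.std(ks, ddof=1)) if len(ks) > 1 else 0.0)
    out = {"table": rows, "per_cell": per_cell, "failures": failures, "seed": seed}
    if len(n_list) > 1:
        means = np.asarray(rows["k_mean"])
        logn = np.log(np.asarray(rows["n"], dtype=float))
        rho = spearmanr(means, logn).statistic
        slope = float(np.polyfit(logn, means, 1)[0])
        out["spearman_logn"] = float(rho)
        out["slope_sign"] = int(np.sign(slope))
        out["slope"] = slope
    return out


def delay_quench_experiment(
    network: ColumnNetwork,
    params: NeuronDynamicsParams | None = None,
    stimulus: StimulusRegime | None = None,
    seeds=(0,),
    t_end: float = 1500.0,
    estimator_kwargs: dict | None = None,
    arrival_window: tuple[float, float] | None = None,
):
    """Compare k under the network's real delays vs all delays forced to 1.

    For each seed the same column is simulated twice — once as given, once
    with every delay replaced by 1.0 — and k estimated for both arms.
    Under unit delays all loop periods are integers, so every frequency
    ratio is rational and equal-hop parallel walks arrive coincidentally
    ("dead heats"): the winding collapses toward a periodic orbit and the
    achieved k quenches.  Returns per-seed (k_real, k_unit),
    distinct-arrival-time counts, and the fraction of seeds with
    k_unit <= k_real.
    """
    if len(seeds) < 1:
        raise ValueError("need at least one seed")
    params = params or NeuronDynamicsParams(**DEFAULT_DYNAMICS)
    unit_net = network.with_unit_delays()
    if arrival_window is None:
        arrival_window = (t_end * 0.5, t_end)
    recs = {"seed": [], "k_real": [], "k_unit": [], "arrivals_real": [], "arrivals_unit": []}
    for s in seeds:
        if stimulus is None:
            stim = _default_stimulus(network.n, t_end, int(s) + 77)
        else:
            stim = StimulusRegime(
                label=stimulus.label, spikes=stimulus.spikes,
                poisson=stimulus.poisson, amplitude=stimulus.amplitude,
                seed=(stimulus.seed + int(s)) % (2**31),
            )
        out = {}
        for arm, net in (("real", network), ("unit", unit_net)):
            train = simulate_spiking(net, params, stim, t_end=t_end, seed=0,
                                     record_deliveries=True)
            k = _windowed_k(train, estimator_kwargs)
            arr = count_distinct_arrival_times(train, window=arrival_window)
            out[arm] = (k, arr)
        recs["seed"].append(int(s))
        recs["k_real"].append(out["real"][0])
        recs["k_unit"].append(out["unit"][0])
        recs["arrivals_real"].append(out["real"][1])
        recs["arrivals_unit"].append(out["unit"][1])
    kr = np.asarray(recs["k_real"])
    ku = np.asarray(recs["k_unit"])
    recs["fraction_quenched"] = float(np.mean(ku <= kr))
    recs["mean_k_real"] = float(kr.mean())
    recs["mean_k_unit"] = float(ku.mean())
    return recs
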