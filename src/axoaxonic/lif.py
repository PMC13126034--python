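"""Conductance-based leaky integrate-and-fire network built from a connectome.

Each neuron follows

    C_m dv/dt = -g_L (v - V_rest) - g_ach (v - E_ach)
                - g_gaba (v - E_gaba) - g_glut (v - E_glut)

with exponentially decaying synaptic conductances (dg_x/dt = -g_x / tau_x) that
jump by J_x × synapse count on a presynaptic spike.  Channels are assigned from
the presynaptic transmitter: acetylcholine drives the ach channel (E = 0 mV,
excitatory), GABA and glutamate their chloride channels (E = -60 mV,
inhibitory).  The giant-fiber analog gets a lower membrane resistance (25 MΩ,
membrane time constant 1.8 ms at 72 pF) than the rest of the population
(300 MΩ).

Numerics: exponential-Euler stepping at dt = 0.1 ms.  Conductance decay is
integrated exactly; the membrane equation is advanced with the channel
conductances evaluated at the step midpoint of their analytic decay, which
keeps single-EPSP transients within 0.01 mV of a dense adaptive reference
integration.  Spikes (v ≥ V_th) reset v to V_reset with a 2 ms refractory
clamp and are delivered to targets with a one-step (0.1 ms) delay.

Units: mV, ms, nS, pF (consistent: nS·mV/pF = mV/ms).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import sparse, stats

from .connectome import ConnectomeTable, Transmitter

__all__ = [
    "LIFParams",
    "SynapseKinetics",
    "NetworkModel",
    "SimConfig",
    "SimResult",
    "PoissonDrive",
    "PulseTrain",
    "ConductanceEvents",
    "build_network",
    "run",
    "delete_neurons",
    "silence_synapses",
    "calibrate_subthreshold_pulse",
    "experiment_fig6",
    "experiment_fig7",
    "subthreshold_samples",
    "compare_subthreshold",
]

CHANNELS = ("ach", "gaba", "glut")

_CHANNEL_OF = {
    Transmitter.ACETYLCHOLINE: "ach",
    Transmitter.GABA: "gaba",
    Transmitter.GLUTAMATE: "glut",
}


@dataclass(frozen=True)
class LIFParams:
    """Membrane parameters; the GF analog gets the low-resistance variant."""

    c_m: float = 72.0            # pF
    r_m_gf: float = 25.0         # MΩ
    r_m_other: float = 300.0     # MΩ
    v_rest: float = -55.0        # mV
    v_th: float = -40.0          # mV
    v_reset: float = -55.0       # mV
    tau_ref: float = 2.0         # ms

    def __post_init__(self) -> None:
        if self.v_reset > self.v_th:
            raise ValueError("V_reset must not exceed V_th")
        if min(self.c_m, self.r_m_gf, self.r_m_other) <= 0:
            raise ValueError("capacitance and resistances must be positive")

    @property
    def g_l_gf(self) -> float:      # nS; 1/(25 MΩ) = 40 nS
        return 1e3 / self.r_m_gf

    @property
    def g_l_other(self) -> float:   # nS; 1/(300 MΩ)
        return 1e3 / self.r_m_other


@dataclass(frozen=True)
class SynapseKinetics:
    """Per-channel conductance increment J_x (nS), decay tau_x (ms), reversal E_x (mV)."""

    j: dict = field(default_factory=lambda: {"ach": 0.27, "gaba": 0.8, "glut": 0.8})
    tau: dict = field(default_factory=lambda: {"ach": 1.1, "gaba": 5.4, "glut": 5.0})
    e_rev: dict = field(default_factory=lambda: {"ach": 0.0, "gaba": -60.0, "glut": -60.0})

    def __post_init__(self) -> None:
        if any(self.tau[c] <= 0 for c in CHANNELS):
            raise ValueError("decay time constants must be positive")


@dataclass
class NetworkModel:
    """Connectome instantiated as a LIF network.

    ``weights[ch]`` is a CSR matrix indexed [pre, post] holding the conductance
    increment J_ch × synapse count for each connection on channel ``ch``.
    """

    ids: np.ndarray                      # (n,) neuron ids
    index: dict[int, int]                # id -> row
    g_l: np.ndarray                      # (n,) leak conductance, nS
    weights: dict[str, sparse.csr_matrix]
    params: LIFParams
    kinetics: SynapseKinetics
    deleted: np.ndarray                  # (n,) bool
    gf_ids: list[int] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.ids)

    def presynaptic_of(self, neuron_id: int) -> list[int]:
        """Ids with a surviving synapse onto ``neuron_id`` on any channel."""
        col = self.index[neuron_id]
        pres: set[int] = set()
        for ch in CHANNELS:
            rows = self.weights[ch].getcol(col).tocoo().row
            pres.update(int(self.ids[r]) for r in rows)
        pres.discard(neuron_id)
        return sorted(pres)


# ---------------------------------------------------------------------------
# stimuli
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PoissonDrive:
    """Independent Poisson conductance kicks onto each target neuron."""

    targets: tuple
    rate_hz: float
    conductance_ns: float
    window: tuple = (0.0, math.inf)  # ms
    channel: str = "ach"


@dataclass(frozen=True)
class PulseTrain:
    """Periodic conductance pulses ('electrical' stimulation analog)."""

    targets: tuple
    rate_hz: float
    amplitude_ns: float
    window: tuple = (0.0, math.inf)  # ms
    channel: str = "ach"

    def pulse_times(self, duration: float) -> np.ndarray:
        lo = max(0.0, self.window[0])
        hi = min(duration, self.window[1])
        period = 1e3 / self.rate_hz
        return np.arange(lo, hi, period)


@dataclass(frozen=True)
class ConductanceEvents:
    """Explicit conductance increments at given times (ms)."""

    targets: tuple
    times: tuple
    amplitude_ns: float
    channel: str = "ach"


@dataclass
class SimConfig:
    dt: float = 0.1                      # ms
    duration: float = 2000.0             # ms
    background_rate_hz: float = 30.0
    background_conductance_ns: float = 5.0
    stimuli: list = field(default_factory=list)
    record: list = field(default_factory=list)  # neuron ids to record voltage for
    record_conductance: list = field(default_factory=list)  # ids to record g_ach for
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.background_rate_hz < 0:
            raise ValueError("rates must be non-negative")


@dataclass
class SimResult:
    times: np.ndarray                    # (n_steps,) ms, sample times
    spikes: dict[int, np.ndarray]        # id -> spike times (ms)
    traces: dict[int, np.ndarray]        # id -> voltage samples (mV)
    conductances: dict[int, np.ndarray]  # id -> g_ach samples (nS), if requested
    dt: float
    tau_ref: float
    meta: dict = field(default_factory=dict)

    def spike_count(self, neuron_id: int) -> int:
        return len(self.spikes.get(neuron_id, ()))


# ---------------------------------------------------------------------------
# construction and surgery
# ---------------------------------------------------------------------------

def build_network(
    table: ConnectomeTable,
    params: LIFParams | None = None,
    kinetics: SynapseKinetics | None = None,
    gf_type_label: str = "DNp01",
    gf_ids: Iterable[int] | None = None,
) -> NetworkModel:
    """Instantiate a scrubbed connectome table as a LIF network.

    GF-tagged neurons (by type label, or an explicit id list) get the 25 MΩ
    membrane; everyone else 300 MΩ.  Raises if a connected neuron still has an
    unknown transmitter — scrub first.
    """
    params = params or LIFParams()
    kinetics = kinetics or SynapseKinetics()
    ids = np.array(sorted(n.neuron_id for n in table.neurons), dtype=np.int64)
    index = {int(i): k for k, i in enumerate(ids)}
    by_id = table.neuron_by_id()

    if gf_ids is None:
        gf = [n.neuron_id for n in table.neurons if n.type_label == gf_type_label]
    else:
        gf = list(gf_ids)
    g_l = np.full(len(ids), params.g_l_other)
    for i in gf:
        g_l[index[i]] = params.g_l_gf

    rows: dict[str, list[int]] = {c: [] for c in CHANNELS}
    cols: dict[str, list[int]] = {c: [] for c in CHANNELS}
    vals: dict[str, list[float]] = {c: [] for c in CHANNELS}
    for c in table.connections:
        trans = by_id[c.pre_id].transmitter
        if trans is Transmitter.UNKNOWN:
            raise ValueError(
                f"neuron {c.pre_id} has unknown transmitter but bears connections; scrub first"
            )
        ch = _CHANNEL_OF[trans]
        rows[ch].append(index[c.pre_id])
        cols[ch].append(index[c.post_id])
        vals[ch].append(kinetics.j[ch] * c.weight)
    n = len(ids)
    weights = {
        ch: sparse.csr_matrix(
            (vals[ch], (rows[ch], cols[ch])), shape=(n, n)
        )
        for ch in CHANNELS
    }
    return NetworkModel(
        ids=ids, index=index, g_l=g_l, weights=weights,
        params=params, kinetics=kinetics,
        deleted=np.zeros(n, dtype=bool), gf_ids=[int(i) for i in gf],
    )


def delete_neurons(model: NetworkModel, ids: Iterable[int]) -> NetworkModel:
    """Remove neurons from the dynamics: no spikes, no synapses either way."""
    idx = [model.index[i] for i in ids]  # KeyError on unknown id
    deleted = model.deleted.copy()
    deleted[idx] = True
    weights = {}
    for ch, w in model.weights.items():
        w = w.tolil(copy=True)
        w[idx, :] = 0
        w[:, idx] = 0
        weights[ch] = w.tocsr()
    return replace(model, deleted=deleted, weights=weights)


def silence_synapses(
    model: NetworkModel, pre_ids: Iterable[int], post_ids: Iterable[int]
) -> NetworkModel:
    """Remove only the directed pre→post synapse set; neurons keep spiking."""
    pre_idx = [model.index[i] for i in pre_ids]
    post_idx = [model.index[i] for i in post_ids]
    weights = {}
    for ch, w in model.weights.items():
        w = w.tolil(copy=True)
        for p in pre_idx:
            for q in post_idx:
                w[p, q] = 0
        weights[ch] = w.tocsr()
    return replace(model, weights=weights)


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------

def run(model: NetworkModel, config: SimConfig) -> SimResult:
    """Integrate the network; deterministic given ``config.seed``.

    Sample i of a recorded trace is the voltage at time (i+1)·dt.  Spike times
    are reported on the same grid.
    """
    p, kin = model.params, model.kinetics
    dt = config.dt
    n_steps = int(round(config.duration / dt))
    n = model.n
    rng = np.random.default_rng(config.seed)

    active = ~model.deleted
    v = np.full(n, p.v_rest)
    g = {ch: np.zeros(n) for ch in CHANNELS}
    ref = np.zeros(n)  # remaining refractory time, ms
    pending = {ch: np.zeros(n) for ch in CHANNELS}

    decay = {ch: math.exp(-dt / kin.tau[ch]) for ch in CHANNELS}
    half = {ch: math.exp(-dt / (2.0 * kin.tau[ch])) for ch in CHANNELS}
    wT = {ch: model.weights[ch].tocsr() for ch in CHANNELS}

    # pre-expand deterministic event stimuli into per-step buckets
    pulse_events: dict[int, list[tuple[np.ndarray, float, str]]] = {}
    poisson_drives = []
    for stim in config.stimuli:
        if isinstance(stim, PoissonDrive):
            t_idx = np.array([model.index[i] for i in stim.targets], dtype=int)
            lo = int(np.ceil(max(0.0, stim.window[0]) / dt))
            hi = int(np.ceil(min(config.duration, stim.window[1]) / dt))
            poisson_drives.append((t_idx, stim.rate_hz * 1e-3 * dt, stim.conductance_ns, lo, hi, stim.channel))
        elif isinstance(stim, PulseTrain):
            t_idx = np.array([model.index[i] for i in stim.targets], dtype=int)
            for t in stim.pulse_times(config.duration):
                step = int(t / dt)
                if step < n_steps:
                    pulse_events.setdefault(step, []).append((t_idx, stim.amplitude_ns, stim.channel))
        elif isinstance(stim, ConductanceEvents):
            t_idx = np.array([model.index[i] for i in stim.targets], dtype=int)
            for t in stim.times:
                step = int(t / dt)
                if step < n_steps:
                    pulse_events.setdefault(step, []).append((t_idx, stim.amplitude_ns, stim.channel))
        else:
            raise TypeError(f"unknown stimulus type {type(stim)!r}")

    record_idx = {int(i): model.index[int(i)] for i in config.record}
    traces = {i: np.empty(n_steps) for i in record_idx}
    g_record_idx = {int(i): model.index[int(i)] for i in config.record_conductance}
    g_traces = {i: np.empty(n_steps) for i in g_record_idx}
    spike_steps: list[tuple[int, np.ndarray]] = []
    bg_j = config.background_conductance_ns
    bg_lam = config.background_rate_hz * 1e-3 * dt
    active_idx = np.flatnonzero(active)

    for step in range(n_steps):
        # 1. deliver last step's spikes (one-step synaptic delay)
        for ch in CHANNELS:
            if pending[ch].any():
                g[ch] += pending[ch]
                pending[ch][:] = 0.0

        # 2. external drive
        if bg_lam > 0 and bg_j > 0 and len(active_idx):
            counts = rng.poisson(bg_lam, size=len(active_idx))
            if counts.any():
                g["ach"][active_idx] += bg_j * counts
        for t_idx, lam, j, lo, hi, ch in poisson_drives:
            if lo <= step < hi and len(t_idx):
                counts = rng.poisson(lam, size=len(t_idx))
                if counts.any():
                    g[ch][t_idx] += j * counts
        for t_idx, amp, ch in pulse_events.get(step, ()):
            g[ch][t_idx] += amp

        # 3. membrane update (exponential Euler, midpoint conductances)
        g_mid = {ch: g[ch] * half[ch] for ch in CHANNELS}
        for nid, k in g_record_idx.items():
            g_traces[nid][step] = g_mid["ach"][k]  # mid-step sample (unbiased in time-average)
        g_tot = model.g_l + g_mid["ach"] + g_mid["gaba"] + g_mid["glut"]
        num = model.g_l * p.v_rest
        for ch in CHANNELS:
            num = num + g_mid[ch] * kin.e_rev[ch]
        v_inf = num / g_tot
        v = v_inf + (v - v_inf) * np.exp(-dt * g_tot / p.c_m)

        # refractory clamp and deletions
        clamped = ref > 0
        v[clamped] = p.v_reset
        v[~active] = p.v_rest

        # 4. exact conductance decay
        for ch in CHANNELS:
            g[ch] *= decay[ch]

        # 5. spikes
        spiking = (v >= p.v_th) & ~clamped & active
        if spiking.any():
            idx = np.flatnonzero(spiking)
            spike_steps.append((step, idx))
            v[idx] = p.v_reset
            ref[idx] = p.tau_ref
            for ch in CHANNELS:
                w = wT[ch]
                if w.nnz:
                    inc = np.asarray(w[idx, :].sum(axis=0)).ravel()
                    if inc.any():
                        pending[ch] += inc

        ref = np.maximum(ref - dt, 0.0)

        if not np.all(np.isfinite(v)):
            raise FloatingPointError(f"non-finite membrane potential at step {step}")

        for nid, k in record_idx.items():
            traces[nid][step] = v[k]

    times = (np.arange(n_steps) + 1) * dt
    spikes: dict[int, list[float]] = {}
    for step, idx in spike_steps:
        t = (step + 1) * dt
        for k in idx:
            spikes.setdefault(int(model.ids[k]), []).append(t)
    spikes_arr = {i: np.array(ts) for i, ts in spikes.items()}
    return SimResult(
        times=times, spikes=spikes_arr, traces=traces, conductances=g_traces,
        dt=dt, tau_ref=p.tau_ref,
        meta={"seed": config.seed, "duration": config.duration},
    )


# ---------------------------------------------------------------------------
# protocols
# ---------------------------------------------------------------------------

def calibrate_subthreshold_pulse(
    model: NetworkModel,
    probe_id: int,
    rate_hz: float = 24.0,
    safety: float = 0.95,
    duration: float = 500.0,
    dt: float = 0.1,
) -> float:
    """Largest just-subthreshold pulse amplitude for the probe, scaled by safety.

    Calibration runs on a quiescent single-neuron copy of the probe (in a
    quiescent network no other neuron can ever spike, so the probe in isolation
    is exact).  Bisects the pulse amplitude between a non-spiking lower bound
    and a spiking upper bound until lower/upper > safety, then returns
    safety × upper: the returned amplitude alone produces no probe spike, while
    the un-scaled upper bound produces at least one.
    """
    iso = _isolated_probe(model, probe_id)

    def spikes_at(amp: float) -> bool:
        cfg = SimConfig(
            dt=dt, duration=duration,
            background_rate_hz=0.0, background_conductance_ns=0.0,
            stimuli=[PulseTrain((probe_id,), rate_hz, amp)],
            seed=0,
        )
        return run(iso, cfg).spike_count(probe_id) > 0

    lo, hi = 0.0, 1.0
    while not spikes_at(hi):
        hi *= 2.0
        if hi > 1e7:
            raise RuntimeError("pulse cannot reach threshold: calibration failure")
    for _ in range(200):
        if lo > 0 and lo / hi > safety:
            break
        mid = 0.5 * (lo + hi)
        if spikes_at(mid):
            hi = mid
        else:
            lo = mid
    else:
        raise RuntimeError("calibration bisection did not converge")
    return safety * hi


def _isolated_probe(model: NetworkModel, probe_id: int) -> NetworkModel:
    """Single-neuron model with the probe's membrane parameters."""
    k = model.index[probe_id]
    empty = {ch: sparse.csr_matrix((1, 1)) for ch in CHANNELS}
    return NetworkModel(
        ids=np.array([probe_id]), index={probe_id: 0},
        g_l=np.array([model.g_l[k]]), weights=empty,
        params=model.params, kinetics=model.kinetics,
        deleted=np.zeros(1, dtype=bool),
        gf_ids=[probe_id] if probe_id in model.gf_ids else [],
    )


@dataclass
class ExperimentReport:
    scenarios: dict[str, dict]           # name -> {"spike_counts": [...], ...}
    comparisons: dict[str, dict]         # "B_vs_A" -> {"u": ..., "p": ...}
    meta: dict = field(default_factory=dict)


_FIG6_SCENARIOS = ("A", "B", "C", "D", "E")


def experiment_fig6(
    model: NetworkModel,
    probe_id: int,
    octet_ids: Sequence[int],
    scenarios: Sequence[str] = _FIG6_SCENARIOS,
    n_trials: int = 5,
    base_seed: int = 0,
    duration: float = 2000.0,
    probe_drive: tuple[float, float] = (10.0, 40.0),   # Hz, nS
    octet_drive: tuple[float, float] = (10.0, 40.0),
) -> ExperimentReport:
    """Stimulation/ablation scenarios probing octet influence on the probe.

    A: probe drive only.  B: probe + octet drive.  C: probe + non-octet
    presynaptic (nAxc) drive with the octet deleted.  D: probe + octet drive
    with nAxc deleted.  E: probe drive with the octet deleted.  Each scenario
    runs ``n_trials`` seeds; probe spike counts and mean subthreshold voltage
    are collected, and spike-count distributions are compared pairwise with a
    two-sided Mann–Whitney U test.
    """
    if not octet_ids and any(s in scenarios for s in "BCDE"):
        raise ValueError("scenarios B-E require designated octet ids")
    octet = [i for i in octet_ids]
    naxc = [i for i in model.presynaptic_of(probe_id) if i not in octet]

    def _stims(extra_targets: list[int] | None, drive: tuple[float, float]) -> list:
        stims: list = [PoissonDrive((probe_id,), probe_drive[0], probe_drive[1])]
        if extra_targets:
            stims.append(PoissonDrive(tuple(extra_targets), drive[0], drive[1]))
        return stims

    plans: dict[str, tuple[NetworkModel, list]] = {}
    for name in scenarios:
        if name == "A":
            plans[name] = (model, _stims(None, octet_drive))
        elif name == "B":
            plans[name] = (model, _stims(octet, octet_drive))
        elif name == "C":
            plans[name] = (delete_neurons(model, octet), _stims(naxc, octet_drive))
        elif name == "D":
            plans[name] = (delete_neurons(model, naxc), _stims(octet, octet_drive))
        elif name == "E":
            plans[name] = (delete_neurons(model, octet), _stims(None, octet_drive))
        else:
            raise ValueError(f"unknown scenario {name!r}")

    results: dict[str, dict] = {}
    for name, (m, stims) in plans.items():
        counts, v_means = [], []
        for trial in range(n_trials):
            cfg = SimConfig(
                duration=duration, stimuli=stims, record=[probe_id],
                seed=base_seed + 1000 * trial,
            )
            res = run(m, cfg)
            counts.append(res.spike_count(probe_id))
            sub = subthreshold_samples(res, probe_id)
            v_means.append(float(sub.mean()) if len(sub) else float("nan"))
        results[name] = {"spike_counts": counts, "subthreshold_mean_mv": v_means}

    comparisons: dict[str, dict] = {}
    names = list(results)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            xa, xb = results[a]["spike_counts"], results[b]["spike_counts"]
            try:
                u = stats.mannwhitneyu(xa, xb, alternative="two-sided")
                comparisons[f"{a}_vs_{b}"] = {"u": float(u.statistic), "p": float(u.pvalue)}
            except ValueError:  # identical samples
                comparisons[f"{a}_vs_{b}"] = {"u": float("nan"), "p": 1.0}
    return ExperimentReport(
        scenarios=results, comparisons=comparisons,
        meta={"probe_id": probe_id, "octet_ids": octet, "n_naxc": len(naxc),
              "n_trials": n_trials, "duration_ms": duration},
    )


def experiment_fig7(
    model: NetworkModel,
    probe_id: int,
    octet_ids: Sequence[int],
    pulse_rate_hz: float = 24.0,
    octet_drive: tuple[float, float] = (40.0, 40.0),   # Hz, nS: strong activation
    duration: float = 3000.0,
    response_window_ms: float = 5.0,
    safety: float = 0.95,
    seed: int = 0,
    amplitude_ns: float | None = None,
) -> dict:
    """Just-subthreshold periodic probe stimulation with an octet-drive window.

    The pulse amplitude is calibrated so the probe alone never crosses
    threshold; the simulation then adds background drive throughout and octet
    activation during the middle third of the run.  A pulse counts as a
    response when the probe spikes within ``response_window_ms`` after it.
    Returns per-window (before/during/after) response probabilities.
    """
    amp = (
        amplitude_ns
        if amplitude_ns is not None
        else calibrate_subthreshold_pulse(model, probe_id, rate_hz=pulse_rate_hz, safety=safety)
    )
    w1, w2 = duration / 3.0, 2.0 * duration / 3.0
    pulses = PulseTrain((probe_id,), pulse_rate_hz, amp)
    stims: list = [pulses]
    if octet_ids:
        stims.append(PoissonDrive(tuple(octet_ids), octet_drive[0], octet_drive[1], window=(w1, w2)))
    cfg = SimConfig(duration=duration, stimuli=stims, record=[probe_id], seed=seed)
    res = run(model, cfg)

    pulse_times = pulses.pulse_times(duration)
    spike_times = res.spikes.get(probe_id, np.array([]))
    responded = np.array([
        bool(np.any((spike_times > t) & (spike_times <= t + response_window_ms)))
        for t in pulse_times
    ])
    windows = {
        "before": (0.0, w1),
        "during": (w1, w2),
        "after": (w2, duration),
    }
    probs = {}
    for name, (lo, hi) in windows.items():
        mask = (pulse_times >= lo) & (pulse_times < hi)
        probs[name] = float(responded[mask].mean()) if mask.any() else float("nan")
    return {
        "amplitude_ns": amp,
        "response_probability": probs,
        "pulse_times": pulse_times,
        "responded": responded,
        "probe_spikes": spike_times,
        "result": res,
    }


# ---------------------------------------------------------------------------
# subthreshold statistics
# ---------------------------------------------------------------------------

def subthreshold_samples(result: SimResult, probe_id: int) -> np.ndarray:
    """Probe voltage samples with spike-adjacent windows removed.

    Samples in [t_spike, t_spike + tau_ref] are excluded so reset/refractory
    values do not contaminate the subthreshold distribution.
    """
    if probe_id not in result.traces:
        raise KeyError(f"no recorded trace for neuron {probe_id}")
    v = result.traces[probe_id]
    t = result.times
    keep = np.ones(len(v), dtype=bool)
    for ts in result.spikes.get(probe_id, ()):
        keep &= ~((t >= ts) & (t <= ts + result.tau_ref))
    return v[keep]


def compare_subthreshold(
    result_a: SimResult, result_b: SimResult, probe_id: int, bins: int = 60
) -> dict:
    """Binned subthreshold-voltage distributions plus a two-sample test."""
    a = subthreshold_samples(result_a, probe_id)
    b = subthreshold_samples(result_b, probe_id)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty subthreshold sample")
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    edges = np.linspace(lo, hi, bins + 1)
    ha, _ = np.histogram(a, bins=edges)
    hb, _ = np.histogram(b, bins=edges)
    if np.array_equal(a, b):
        u, p = float("nan"), 1.0
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        u, p = float(res.statistic), float(res.pvalue)
    return {
        "bin_edges": edges, "hist_a": ha, "hist_b": hb,
        "mean_a": float(a.mean()), "mean_b": float(b.mean()),
        "u_statistic": u, "p_value": p,
    }
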