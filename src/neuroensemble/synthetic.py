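"""Synthetic calcium-fluorescence data from a leaky integrate-and-fire net.

The forward model mirrors a typical calcium-imaging benchmark: a network of
N = 100 neurons partitioned into 8 structural ensembles (sizes 20, 10, 10,
10, 20, 10, 10, 10) with probabilistic chemical synapses and gap junctions,
driven by one of three external-current scenarios; membrane potentials are
integrated by Euler–Maruyama; potentials are converted to fluorescence
through a first-order indicator ODE with a Hill-equation response; the
fluorescence is min–max rescaled per neuron to [0, 1] and, for the binary
baseline, binarized by strict local-maximum peak detection.

Cross-ensemble chemical connections exist only for E1→E2 (excitatory),
E1→E3 (inhibitory), E6→E5 (excitatory) and E7→E5 (inhibitory), each with
probability 0.5.  Within-ensemble excitatory synapses have probability 0.5
and symmetric gap junctions probability 0.8.  Neurons in E1–E4 have membrane
time constant 0.05, those in E5–E8 have 0.1; all other parameters are shared
(resistance 1, rest 0, threshold 0.2, spike value 1, reset 0, noise 0.2,
stimulus amplitude 0.3, synaptic weight ±0.08, gap weight 0.3).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LIFParams",
    "FluorescenceParams",
    "NetworkSpec",
    "InputSchedule",
    "SyntheticDataset",
    "DEFAULT_SIZES",
    "build_network",
    "make_input_schedule",
    "chem_current",
    "gap_current",
    "simulate_lif",
    "simulate_fluorescence",
    "rescale_fluorescence",
    "binarize_peaks",
    "generate_dataset",
]

DEFAULT_SIZES = (20, 10, 10, 10, 20, 10, 10, 10)

# cross-ensemble chemical connections: (source, target, sign), 0-based labels
CROSS_CONNECTIONS = ((0, 1, +1), (0, 2, -1), (5, 4, +1), (6, 4, -1))

# external-input pairing of structural ensembles: {E1,E5},{E2,E6},{E3,E7},{E4,E8}
PAIR_GROUPS = ((0, 4), (1, 5), (2, 6), (3, 7))


@dataclass
class LIFParams:
    """Leaky integrate-and-fire parameters (arbitrary consistent units).

    ``tau_m_fast`` applies to the first four structural ensembles,
    ``tau_m_slow`` to the last four.  A neuron whose potential reaches
    ``v_th`` is recorded at the spike value ``v_act`` for that step and
    restarts from ``v_init`` at the next step; there is no refractory period.
    """

    tau_m_fast: float = 0.05
    tau_m_slow: float = 0.1
    v_rest: float = 0.0
    sigma_noise: float = 0.2
    resistance: float = 1.0
    v_th: float = 0.2
    v_act: float = 1.0
    v_init: float = 0.0
    v_half: float = 0.3
    v_width: float = 0.1
    dt: float = 0.001

    def __post_init__(self):
        if min(self.tau_m_fast, self.tau_m_slow, self.dt, self.v_width) <= 0:
            raise ValueError("tau_m, dt and v_width must be positive")
        if self.v_th <= self.v_rest:
            raise ValueError("v_th must exceed v_rest for excitable dynamics")


@dataclass
class FluorescenceParams:
    """Indicator response: Hill equation f(c) = F_max c^h / (K_D^h + c^h)
    (zero for negative c) relaxed with time constant tau_f."""

    tau_f: float = 0.1
    f_max: float = 5.0
    k_d: float = 0.3
    hill: float = 3.0

    def __post_init__(self):
        if min(self.tau_f, self.f_max, self.k_d, self.hill) <= 0:
            raise ValueError("all fluorescence parameters must be positive")


@dataclass
class NetworkSpec:
    """Structural connectivity: signed chemical weights and symmetric
    nonnegative gap-junction weights, plus the ensemble partition."""

    sizes: tuple
    w_chem: np.ndarray
    w_gap: np.ndarray

    @property
    def n_neurons(self) -> int:
        return int(sum(self.sizes))

    @property
    def labels(self) -> np.ndarray:
        """Structural-ensemble label of each neuron (0-based)."""
        return np.repeat(np.arange(len(self.sizes)), self.sizes)

    def members(self, ensemble: int) -> np.ndarray:
        return np.flatnonzero(self.labels == ensemble)


@dataclass
class InputSchedule:
    """External stimulus current per neuron and integration step."""

    scenario: int
    i_stim: np.ndarray          # (N, n_steps)
    amplitude: float = 0.3


@dataclass
class SyntheticDataset:
    """All products of the forward model at the recording resolution."""

    potentials: np.ndarray      # (N, M) membrane potential V
    fluorescence: np.ndarray    # (N, M) raw fluorescence F
    normalized: np.ndarray      # (N, M) rescaled fluorescence in [0, 1]
    binary: np.ndarray          # (N, M) peak-binarized activity
    network: NetworkSpec = None
    schedule: InputSchedule = None
    labels: np.ndarray = None   # structural ensemble of each neuron


def build_network(sizes=DEFAULT_SIZES, *, p_within_chem=0.5, p_within_gap=0.8,
                  p_cross=0.5, w_exc=0.08, w_inh=-0.08, w_gap=0.3,
                  rng=None) -> NetworkSpec:
    """Draw the structural network.

    Within each ensemble, excitatory chemical synapses appear independently
    with probability ``p_within_chem`` and symmetric gap junctions with
    probability ``p_within_gap``; the four cross-ensemble blocks listed in
    ``CROSS_CONNECTIONS`` get directed synapses of the stated sign with
    probability ``p_cross``.  No self-connections.
    """
    rng = np.random.default_rng(rng)
    labels = np.repeat(np.arange(len(sizes)), sizes)
    n = labels.shape[0]
    same = labels[:, None] == labels[None, :]
    eye = np.eye(n, dtype=bool)

    w_chem = np.zeros((n, n))
    mask = (rng.random((n, n)) < p_within_chem) & same & ~eye
    w_chem[mask] = w_exc
    for src, dst, sign in CROSS_CONNECTIONS:
        block = (labels[:, None] == dst) & (labels[None, :] == src)
        hit = (rng.random((n, n)) < p_cross) & block
        w_chem[hit] = w_exc if sign > 0 else w_inh

    upper = np.triu((rng.random((n, n)) < p_within_gap) & same & ~eye, k=1)
    gap = np.zeros((n, n))
    gap[upper] = w_gap
    gap = gap + gap.T
    return NetworkSpec(sizes=tuple(sizes), w_chem=w_chem, w_gap=gap)


def make_input_schedule(scenario: int, sizes=DEFAULT_SIZES, n_steps: int = 20000,
                        amplitude: float = 0.3, n_epochs: int = 8) -> InputSchedule:
    """Build the external current for one of the three input scenarios.

    1. Identical stationary: constant ``amplitude`` to every neuron.
    2. Identical non-stationary: one shared on/off square wave
       (``n_epochs`` equal epochs, alternating on/off).
    3. Different non-stationary: four distinct staggered on/off schedules,
       one per ensemble-pair group {E1,E5}, {E2,E6}, {E3,E7}, {E4,E8}
       (group g is on during epochs g and g+4 of 8).
    """
    labels = np.repeat(np.arange(len(sizes)), sizes)
    n = labels.shape[0]
    if scenario == 1:
        return InputSchedule(1, np.full((n, n_steps), amplitude), amplitude)
    epoch = (np.arange(n_steps) * n_epochs) // n_steps
    if scenario == 2:
        on = (epoch % 2 == 0).astype(float)
        return InputSchedule(2, amplitude * np.tile(on, (n, 1)), amplitude)
    if scenario == 3:
        i_stim = np.zeros((n, n_steps))
        for g, pair in enumerate(PAIR_GROUPS):
            on = ((epoch % (n_epochs // 2)) == g).astype(float)
            rows = np.isin(labels, pair)
            i_stim[rows] = amplitude * on
        return InputSchedule(3, i_stim, amplitude)
    raise ValueError(f"unknown scenario {scenario!r}; expected 1, 2 or 3")


def chem_current(v, w_chem, v_half=0.3, v_width=0.1):
    """Chemical synaptic current: logistic gating of presynaptic potential."""
    gate = 1.0 / (1.0 + np.exp(-(v - v_half) / v_width))
    return w_chem @ gate


def gap_current(v, w_gap):
    """Gap-junction current: ohmic coupling to potential differences."""
    return w_gap @ v - w_gap.sum(axis=1) * v


def simulate_lif(network: NetworkSpec, schedule: InputSchedule,
                 params: LIFParams = None, rng=None,
                 record_every: int = 10) -> np.ndarray:
    """Euler–Maruyama integration of the network LIF dynamics.

    Potentials start at rest; every ``record_every`` substeps the
    instantaneous potential is recorded as one frame.  Returns the (N, M)
    recorded potential matrix where M = n_steps // record_every.
    """
    params = params or LIFParams()
    rng = np.random.default_rng(rng)
    n = network.n_neurons
    n_steps = schedule.i_stim.shape[1]
    if schedule.i_stim.shape[0] != n:
        raise ValueError("schedule and network disagree on neuron count")
    labels = network.labels
    tau_m = np.where(labels < len(network.sizes) // 2,
                     params.tau_m_fast, params.tau_m_slow)
    dt = params.dt
    sqrt_dt = np.sqrt(dt)

    v = np.full(n, params.v_rest, dtype=float)
    spiking = np.zeros(n, dtype=bool)
    frames = np.empty((n, n_steps // record_every))
    for step in range(n_steps):
        # reset one step after a spike was recorded
        v[spiking] = params.v_init
        spiking = np.zeros(n, dtype=bool)
        i_total = (chem_current(v, network.w_chem, params.v_half, params.v_width)
                   + gap_current(v, network.w_gap)
                   + schedule.i_stim[:, step])
        v = (v + (dt / tau_m) * (-(v - params.v_rest)
                                 + params.resistance * i_total)
             + params.sigma_noise * sqrt_dt * rng.standard_normal(n))
        fired = v >= params.v_th
        v[fired] = params.v_act
        spiking = fired
        if not np.all(np.isfinite(v)):
            raise FloatingPointError(
                f"non-finite membrane potential at step {step}")
        if (step + 1) % record_every == 0:
            frames[:, (step + 1) // record_every - 1] = v
    return frames


def simulate_fluorescence(v: np.ndarray, params: FluorescenceParams = None,
                          dt: float = 0.001) -> np.ndarray:
    """Euler integration of the indicator ODE dF/dt = (f(V) - F)/tau_f.

    Calcium concentration is taken proportional to the membrane potential
    with unit constant; the Hill response is zero for negative potentials.
    ``v`` is sampled at interval ``dt``.  F(0) = f(V(0)).
    """
    params = params or FluorescenceParams()

    def hill(c):
        c = np.maximum(c, 0.0)
        ch = c ** params.hill
        return params.f_max * ch / (params.k_d ** params.hill + ch)

    out = np.empty_like(v, dtype=float)
    f = hill(v[..., 0])
    out[..., 0] = f
    coef = dt / params.tau_f
    for k in range(1, v.shape[-1]):
        f = f + coef * (hill(v[..., k - 1]) - f)
        out[..., k] = f
    return out


def rescale_fluorescence(f: np.ndarray) -> np.ndarray:
    """Per-neuron min–max rescaling to [0, 1] (rows are neurons)."""
    f = np.asarray(f, dtype=float)
    squeeze = f.ndim == 1
    f = np.atleast_2d(f)
    lo = f.min(axis=1, keepdims=True)
    hi = f.max(axis=1, keepdims=True)
    rng_ = hi - lo
    if np.any(rng_ == 0):
        bad = int(np.flatnonzero(rng_.ravel() == 0)[0])
        raise ValueError(f"constant series (row {bad}) cannot be rescaled")
    out = (f - lo) / rng_
    return out[0] if squeeze else out


def binarize_peaks(series: np.ndarray, min_height: float = 0.3) -> np.ndarray:
    """Mark strict local maxima at least ``min_height`` high with 1.

    A sample is a peak when it strictly exceeds both neighbors; endpoints and
    plateau points are never peaks.  Works on a 1-D series or row-wise on a
    2-D matrix.
    """
    x = np.asarray(series, dtype=float)
    squeeze = x.ndim == 1
    x = np.atleast_2d(x)
    if x.shape[1] < 3:
        raise ValueError("peak detection needs at least 3 samples")
    out = np.zeros_like(x)
    mid = (x[:, 1:-1] > x[:, :-2]) & (x[:, 1:-1] > x[:, 2:]) \
        & (x[:, 1:-1] >= min_height)
    out[:, 1:-1][mid] = 1.0
    return out[0] if squeeze else out


def generate_planted_data(n_neurons: int = 30, n_timesteps: int = 200,
                          n_ensembles: int = 3, p_active: float = 0.9,
                          p_inactive: float = 0.1, rng=None):
    """Draw binary activity from the inference model itself.

    Neurons are split evenly into ``n_ensembles`` planted ensembles; each
    ensemble is active at each time step with probability 1/2; a neuron fires
    with probability ``p_active`` when its ensemble is active and
    ``p_inactive`` otherwise.  Returns ``(s, labels, omega)`` — the (N, M)
    activity, the planted labels and the (M, A) ensemble activity.  Used as
    ground truth in recovery benchmarks.
    """
    rng = np.random.default_rng(rng)
    labels = np.arange(n_neurons) % n_ensembles
    omega = (rng.random((n_timesteps, n_ensembles)) < 0.5).astype(float)
    p = np.where(omega[:, labels] == 1.0, p_active, p_inactive)  # (M, N)
    s = (rng.random((n_timesteps, n_neurons)) < p).T.astype(float)
    return s, labels, omega


def generate_dataset(scenario: int = 3, sizes=DEFAULT_SIZES, n_frames: int = 2000,
                     record_every: int = 10, lif: LIFParams = None,
                     fluor: FluorescenceParams = None, min_height: float = 0.3,
                     rng=None) -> SyntheticDataset:
    """Full forward pipeline at recording resolution ``n_frames``.

    Network construction, input schedule, LIF integration (with
    ``record_every`` substeps per recorded frame), fluorescence conversion at
    the integration resolution, subsampling, per-neuron rescaling and peak
    binarization.  Deterministic for a given ``rng`` seed.
    """
    rng = np.random.default_rng(rng)
    lif = lif or LIFParams()
    fluor = fluor or FluorescenceParams()
    network = build_network(sizes, rng=rng)
    n_steps = n_frames * record_every
    schedule = make_input_schedule(scenario, sizes, n_steps,
                                   amplitude=0.3)
    # integrate potential and fluorescence at full resolution, then keep the
    # last substep of each recording frame
    v_full = simulate_lif(network, schedule, lif, rng=rng, record_every=1)
    f_full = simulate_fluorescence(v_full, fluor, dt=lif.dt)
    keep = np.arange(record_every - 1, n_steps, record_every)
    v_frames = v_full[:, keep]
    f_frames = f_full[:, keep]
    normalized = rescale_fluorescence(f_frames)
    binary = binarize_peaks(normalized, min_height=min_height)
    return SyntheticDataset(
        potentials=v_frames, fluorescence=f_frames, normalized=normalized,
        binary=binary, network=network, schedule=schedule,
        labels=network.labels,
    )
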