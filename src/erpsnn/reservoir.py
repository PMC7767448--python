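"""3D spatially-mapped spiking reservoir: small-world wiring, LIF dynamics,
and STDP learning.

The reservoir is a set of neurons at fixed 3D coordinates (by default the
packaged 1471-site 1 cm lattice).  Each EEG channel is attached to its
nearest grid neuron (injectively); input spike trains are injected there as
+/-1 membrane-drive increments.  Directed connections are created with a
distance-dependent ("small-world") probability

    p(i -> j) = base_prob * exp(-d(i, j)^2 / radius_mm^2)   for d <= radius_mm

and never beyond the hard radius.  Initial weights are uniform on
(0, init_weight_scale]; a configurable fraction of presynaptic neurons is
inhibitory and projects negative weights.

Dynamics run in discrete 1 ms steps with a one-step axonal delay:

    u_i(t) = leak * u_i(t-1) + sum_j w_ji s_j(t-1) + injection_i(t)

A neuron fires when u exceeds ``fire_threshold``, resets to 0 and is
refractory for ``refractory_steps`` steps.  On every firing, nearest-spike
additive STDP runs: incoming connections whose presynaptic neuron fired
earlier are potentiated by ``a_plus * exp(-dt / tau_ms)``, outgoing
connections whose postsynaptic neuron fired earlier are depressed by
``a_minus * exp(-dt / tau_ms)``; simultaneous spikes are not paired.
Excitatory weights are clipped to [0, w_max]; inhibitory weights update on
their magnitude, mirrored into [-w_max, 0].
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from numba import njit

__all__ = [
    "NeuronGrid",
    "SWCConfig",
    "LIFConfig",
    "STDPConfig",
    "Reservoir",
    "FiringLog",
    "build_reservoir",
    "run_stdp",
    "snapshot_activity",
]


class ReservoirError(ValueError):
    pass


@dataclass(frozen=True)
class NeuronGrid:
    """Neuron coordinates (n x 3, mm) with optional anatomical labels."""

    coords: np.ndarray
    labels: tuple | None = None

    def __post_init__(self):
        c = np.asarray(self.coords, dtype=float)
        if c.ndim != 2 or c.shape[1] != 3:
            raise ReservoirError("coords must be an (n, 3) array")
        if len(np.unique(c, axis=0)) != len(c):
            raise ReservoirError("grid coordinates must be pairwise distinct")
        object.__setattr__(self, "coords", c)

    def __len__(self) -> int:
        return len(self.coords)

    @classmethod
    def from_fixture(cls) -> "NeuronGrid":
        from .fixtures import load_grid

        return cls(coords=load_grid())

    def subsample(self, n: int, seed: int = 0) -> "NeuronGrid":
        """A reduced grid of ``n`` sites drawn without replacement (seeded).

        Used to scale simulations down while keeping spatial coverage; sites
        are a uniform random subset, so the spatial extent is preserved.
        """
        if not 0 < n <= len(self):
            raise ReservoirError(f"cannot subsample {n} of {len(self)} sites")
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0x6121D]))
        idx = np.sort(rng.choice(len(self), size=n, replace=False))
        return NeuronGrid(coords=self.coords[idx])


@dataclass(frozen=True)
class SWCConfig:
    """Small-world connectivity parameters (distances in mm)."""

    radius_mm: float = 25.0
    base_prob: float = 0.15
    inhibitory_fraction: float = 0.2
    init_weight_scale: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.radius_mm < 0:
            raise ReservoirError("radius_mm must be >= 0")
        if not 0 < self.base_prob <= 1:
            raise ReservoirError("base_prob must lie in (0, 1]")
        if not 0 <= self.inhibitory_fraction <= 1:
            raise ReservoirError("inhibitory_fraction must lie in [0, 1]")
        if not self.init_weight_scale > 0:
            raise ReservoirError("init_weight_scale must be > 0")


@dataclass(frozen=True)
class LIFConfig:
    """Leaky integrate-and-fire parameters (per 1 ms step).

    The defaults (threshold 1.2, leak 0.5, refractory 1) keep input-neuron
    firing proportional to input spike density even inside short
    alternating-polarity ERP bursts: a long refractory period or a long
    membrane memory saturates or cancels exactly the burst-density
    differences the connectivity statistics are meant to pick up.
    """

    fire_threshold: float = 1.2
    leak: float = 0.5
    refractory_steps: int = 1

    def __post_init__(self):
        if not self.fire_threshold > 0:
            raise ReservoirError("fire_threshold must be > 0")
        if not 0 <= self.leak < 1:
            raise ReservoirError("leak must lie in [0, 1)")
        if self.refractory_steps < 0:
            raise ReservoirError("refractory_steps must be >= 0")


@dataclass(frozen=True)
class STDPConfig:
    """Nearest-spike additive STDP parameters.

    Potentiation outweighs depression by default (2:1) so sustained local
    drive produces a net weight increase, matching the convention that
    stronger spike transmission shows up as larger connection weights.
    """

    a_plus: float = 0.02
    a_minus: float = 0.01
    tau_ms: float = 10.0
    w_max: float = 2.0

    def __post_init__(self):
        if self.a_plus < 0 or self.a_minus < 0:
            raise ReservoirError("a_plus and a_minus must be >= 0")
        if not self.tau_ms > 0:
            raise ReservoirError("tau_ms must be > 0")
        if not self.w_max > 0:
            raise ReservoirError("w_max must be > 0")


@dataclass(frozen=True)
class Reservoir:
    """An initialised (or trained) reservoir.

    Edges are stored as parallel arrays ``pre``, ``post``, ``weights`` sorted
    by presynaptic index.  ``input_neurons[k]`` is the grid neuron receiving
    channel ``input_channels[k]``.
    """

    coords: np.ndarray
    input_channels: tuple
    input_neurons: np.ndarray
    pre: np.ndarray
    post: np.ndarray
    weights: np.ndarray
    inhibitory: np.ndarray  # bool per neuron
    swc: SWCConfig

    @property
    def n_neurons(self) -> int:
        return len(self.coords)

    @property
    def n_edges(self) -> int:
        return len(self.pre)

    def input_index(self, channel: str) -> int:
        return int(self.input_neurons[self.input_channels.index(channel)])

    def with_weights(self, w: np.ndarray) -> "Reservoir":
        return replace(self, weights=np.asarray(w, dtype=float))

    def edge_lengths(self) -> np.ndarray:
        return np.linalg.norm(self.coords[self.pre] - self.coords[self.post], axis=1)


@dataclass(frozen=True)
class FiringLog:
    """Firing events: parallel arrays of neuron index, time step, and the
    sign of the membrane drive at the firing step."""

    neuron: np.ndarray
    t: np.ndarray
    polarity: np.ndarray
    n_neurons: int
    n_steps: int

    def __len__(self) -> int:
        return len(self.neuron)

    def first_spike_times(self) -> np.ndarray:
        """Per-neuron time of first firing (-1 for neurons that never fire)."""
        first = np.full(self.n_neurons, -1, dtype=np.int64)
        for j, tt in zip(self.neuron[::-1], self.t[::-1]):
            first[j] = tt
        return first

    def spike_counts(self) -> np.ndarray:
        return np.bincount(self.neuron, minlength=self.n_neurons)


def _nearest_injective(grid_coords: np.ndarray, channel_coords: np.ndarray) -> np.ndarray:
    taken: set = set()
    out = np.empty(len(channel_coords), dtype=np.int64)
    for k, c in enumerate(channel_coords):
        d = np.linalg.norm(grid_coords - c, axis=1)
        for j in np.argsort(d, kind="stable"):
            if int(j) not in taken:
                taken.add(int(j))
                out[k] = j
                break
    return out


def build_reservoir(grid: NeuronGrid, montage, swc: SWCConfig = SWCConfig()) -> Reservoir:
    """Initialise a reservoir on ``grid`` with inputs mapped from ``montage``.

    ``montage`` provides ``channels`` and ``coords`` in the grid's frame.
    Each channel maps to its nearest unclaimed grid neuron (montage order
    breaks ties).  Wiring and weights are drawn deterministically from
    ``swc.seed``.
    """
    coords = grid.coords
    n = len(coords)
    channels = tuple(montage.channels)
    if n < len(channels):
        raise ReservoirError(
            f"grid has {n} neurons but montage needs {len(channels)} inputs"
        )
    input_neurons = _nearest_injective(coords, np.asarray(montage.coords, dtype=float))

    rng = np.random.default_rng(np.random.SeedSequence([swc.seed, 0x5C5C]))
    diff = coords[:, None, :] - coords[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    if swc.radius_mm > 0:
        p = swc.base_prob * np.exp(-d2 / swc.radius_mm**2)
        p[d2 > swc.radius_mm**2] = 0.0
    else:
        p = np.zeros_like(d2)
    np.fill_diagonal(p, 0.0)
    mask = rng.random((n, n)) < p
    w_full = (1.0 - rng.random((n, n))) * swc.init_weight_scale  # uniform (0, scale]
    n_inhib = int(round(swc.inhibitory_fraction * n))
    inhibitory = np.zeros(n, dtype=bool)
    if n_inhib:
        inhibitory[rng.choice(n, size=n_inhib, replace=False)] = True
    pre, post = np.nonzero(mask)
    weights = w_full[pre, post]
    weights[inhibitory[pre]] *= -1.0
    return Reservoir(
        coords=coords,
        input_channels=channels,
        input_neurons=input_neurons,
        pre=pre.astype(np.int64),
        post=post.astype(np.int64),
        weights=weights.astype(float),
        inhibitory=inhibitory,
        swc=swc,
    )


# --------------------------------------------------------------------------
# dynamics kernel
# --------------------------------------------------------------------------

@njit(cache=True)
def _simulate(out_indptr, out_idx, w, in_indptr, in_src, in_eid,
              inp_neurons, spikes, T, leak, thr, refr,
              a_plus, a_minus, tau, w_max, record):
    n = out_indptr.shape[0] - 1
    u = np.zeros(n)
    refr_left = np.zeros(n, dtype=np.int64)
    last = np.full(n, -1, dtype=np.int64)
    drive = np.zeros(n)
    fired_prev = np.empty(0, dtype=np.int64)
    cap = n * (T // (refr + 1) + 1) if record else 0
    log_n = np.empty(cap, dtype=np.int32)
    log_t = np.empty(cap, dtype=np.int32)
    log_p = np.empty(cap, dtype=np.int8)
    m = 0
    fired = np.empty(n, dtype=np.int64)
    for t in range(T):
        for i in range(n):
            drive[i] = 0.0
        for fi in range(fired_prev.shape[0]):
            j = fired_prev[fi]
            for e in range(out_indptr[j], out_indptr[j + 1]):
                drive[out_idx[e]] += w[e]
        for c in range(inp_neurons.shape[0]):
            s = spikes[c, t]
            if s != 0:
                drive[inp_neurons[c]] += s
        nf = 0
        for i in range(n):
            if refr_left[i] > 0:
                refr_left[i] -= 1
                u[i] = 0.0
                continue
            u[i] = u[i] * leak + drive[i]
            if u[i] > thr:
                fired[nf] = i
                nf += 1
        for fi in range(nf):
            j = fired[fi]
            # potentiate incoming edges whose pre fired strictly earlier
            for e in range(in_indptr[j], in_indptr[j + 1]):
                i = in_src[e]
                if last[i] >= 0 and last[i] < t:
                    dw = a_plus * np.exp(-(t - last[i]) / tau)
                    ei = in_eid[e]
                    if w[ei] >= 0.0:
                        w[ei] = min(w[ei] + dw, w_max)
                    else:
                        w[ei] = -min(-w[ei] + dw, w_max)
            # depress outgoing edges whose post fired strictly earlier
            for e in range(out_indptr[j], out_indptr[j + 1]):
                k = out_idx[e]
                if last[k] >= 0 and last[k] < t:
                    dw = a_minus * np.exp(-(t - last[k]) / tau)
                    if w[e] >= 0.0:
                        w[e] = max(w[e] - dw, 0.0)
                    else:
                        w[e] = -max(-w[e] - dw, 0.0)
            if record:
                log_n[m] = j
                log_t[m] = t
                log_p[m] = 1 if drive[j] >= 0.0 else -1
                m += 1
            u[j] = 0.0
            refr_left[j] = refr
        for fi in range(nf):
            last[fired[fi]] = t
        fired_prev = fired[:nf].copy()
    return log_n[:m], log_t[:m], log_p[:m]


def _csr(reservoir: Reservoir):
    n = reservoir.n_neurons
    order = np.argsort(reservoir.pre, kind="stable")
    pre = reservoir.pre[order]
    post = reservoir.post[order]
    out_indptr = np.zeros(n + 1, dtype=np.int64)
    np.add.at(out_indptr[1:], pre, 1)
    out_indptr = np.cumsum(out_indptr)
    in_indptr = np.zeros(n + 1, dtype=np.int64)
    np.add.at(in_indptr[1:], post, 1)
    in_indptr = np.cumsum(in_indptr)
    order_in = np.argsort(post, kind="stable")
    in_src = pre[order_in]
    in_eid = order_in.astype(np.int64)
    return order, out_indptr, post, in_indptr, in_src, in_eid


def run_stdp(reservoir: Reservoir, spike_set, lif: LIFConfig = LIFConfig(),
             stdp: STDPConfig = STDPConfig(), passes: int = 1,
             record: bool = True):
    """Drive the reservoir with a spike-train set and adapt weights by STDP.

    Neuron state (potentials, refractoriness, spike memory) resets between
    passes; weights persist.  Returns the trained reservoir and the firing
    log of the final pass.

    Raises
    ------
    ReservoirError
        If the spike set's channels do not match the reservoir's input map.
    """
    if tuple(spike_set.channels) != tuple(reservoir.input_channels):
        missing = set(spike_set.channels) - set(reservoir.input_channels)
        raise ReservoirError(
            f"spike-train channels do not match the input map "
            f"(unmapped: {sorted(missing) if missing else 'order mismatch'})"
        )
    order, out_indptr, out_idx, in_indptr, in_src, in_eid = _csr(reservoir)
    w = reservoir.weights[order].astype(float).copy()
    spikes = np.ascontiguousarray(spike_set.spikes, dtype=np.int8)
    T = spikes.shape[1]
    log_n = log_t = log_p = None
    for p in range(passes):
        rec = record and (p == passes - 1)
        log_n, log_t, log_p = _simulate(
            out_indptr, out_idx, w, in_indptr, in_src, in_eid,
            reservoir.input_neurons.astype(np.int64), spikes, T,
            float(lif.leak), float(lif.fire_threshold), int(lif.refractory_steps),
            float(stdp.a_plus), float(stdp.a_minus), float(stdp.tau_ms),
            float(stdp.w_max), rec,
        )
    # map weights back to the reservoir's original edge order
    w_out = np.empty_like(w)
    w_out[order] = w
    trained = replace(reservoir, weights=w_out)
    log = FiringLog(
        neuron=np.asarray(log_n, dtype=np.int64),
        t=np.asarray(log_t, dtype=np.int64),
        polarity=np.asarray(log_p, dtype=np.int8),
        n_neurons=reservoir.n_neurons,
        n_steps=T,
    )
    return trained, log


def snapshot_activity(log: FiringLog, t_ms: int, window_ms: int):
    """Positive/negative firing counts per neuron in a window around t_ms.

    The window is [t - window/2, t + window/2], inclusive, and must lie
    inside the epoch.
    """
    lo = t_ms - window_ms / 2
    hi = t_ms + window_ms / 2
    if lo < 0 or hi > log.n_steps - 1:
        raise ValueError(
            f"window [{lo}, {hi}] outside epoch [0, {log.n_steps - 1}]"
        )
    sel = (log.t >= lo) & (log.t <= hi)
    pos = np.bincount(log.neuron[sel & (log.polarity > 0)], minlength=log.n_neurons)
    neg = np.bincount(log.neuron[sel & (log.polarity < 0)], minlength=log.n_neurons)
    return pos, neg
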