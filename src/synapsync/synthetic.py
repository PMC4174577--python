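"""Synthetic paired-recording generator with known ground-truth synchrony.

The generator emulates the statistics that the synchrony inference assumes:

* Release opportunities are discretized into bins of width ``bin_width``.
  Each rod bipolar cell (RBC) carries a *master* drive stream — per bin a
  Bernoulli(``p_master``) event standing for an axon-wide excursion of
  release probability.
* Every output synapse of that RBC follows each master event independently
  with probability ``q_follow`` (the synchrony dial) and additionally
  releases on its own at rate ``r_async`` per bin (asynchronous release).
* Two A17-like cells are wired to the RBC population ring by ring: within a
  ring at mean radius ``r`` each of the ``n_r`` contacts of cell A is shared
  with cell B with probability ``p_shared(r)``; cell B receives private RBCs
  in place of the unshared ones so both cells see ``n_r`` contacts per ring.
  Each RBC contributes exactly one synapse per A17.
* Every release event is rendered as a quantal current kernel whose
  amplitude is attenuated by ``exp(-(r + r0)/gamma)``, so event *variance*
  carries the electrotonic weight ``exp(-2 (r + r0)/gamma)`` used by the
  inference.  Gaussian instrument noise is added last.

Because the two synapses of a shared RBC are thinned from one master stream,
their per-bin event correlation — the ground-truth cross-synaptic synchrony
— has the closed form ``q (1 - p) / (1 - p q)`` (extended below for
``r_async > 0``), and the expected trace-level correlation is that value
times the anatomical slope of the ring table.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, signal

from .connectivity import RingTable
from .trace import Trace

__all__ = [
    "KernelParams",
    "DriveParams",
    "PairScenario",
    "default_ring_table",
    "effective_css",
    "stream_correlation",
    "calibrate_q_follow",
    "quantal_kernel",
    "sample_synapse_pair",
    "generate_pair",
    "generate_convergent_trace",
    "substream",
]


@dataclass(frozen=True)
class KernelParams:
    """Shape of the quantal current: a difference of exponentials,
    normalized so the kernel extremum equals ``amplitude``.

    ``amplitude`` is the *local* quantal current at the synapse (pA, negative
    for inward); what appears at the soma is this amplitude times the
    electrotonic attenuation factor of the contact's ring.
    """

    amplitude: float = -45.0
    tau_rise: float = 0.25
    tau_decay: float = 2.0

    def __post_init__(self) -> None:
        if self.amplitude == 0:
            raise ValueError("kernel amplitude must be nonzero")
        if not 0 < self.tau_rise < self.tau_decay:
            raise ValueError("need 0 < tau_rise < tau_decay")


@dataclass(frozen=True)
class DriveParams:
    """Presynaptic release-drive parameters (probabilities are per bin).

    ``tau_drive`` / ``modulation_depth`` describe an optional slow AR(1)
    modulation of the master rate, emulating the broad temporal correlations
    of dark presynaptic voltage noise.  The modulation defaults to off: it
    adds shared rate drift whose contribution to measured correlations is
    not captured by the closed-form synchrony dial.
    """

    bin_width: float = 2.0
    p_master: float = 0.10
    q_follow: float = 0.85
    r_async: float = 0.005
    tau_drive: float = 50.0
    modulation_depth: float = 0.0

    def __post_init__(self) -> None:
        for name in ("p_master", "q_follow", "r_async", "modulation_depth"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not self.bin_width > 0:
            raise ValueError("bin_width must be positive")
        if not self.tau_drive > 0:
            raise ValueError("tau_drive must be positive")


def default_ring_table() -> RingTable:
    """A documented toy connectivity table of the canonical shape.

    Four 20-µm rings with mean radii 10-70 µm; contact counts grow with ring
    area while the shared fraction declines with distance.  r0 = 40 µm (the
    descending-dendrite length) and gamma = 32.3 µm (the A17 electrotonic
    length factor).  The implied CC-per-CSS slope is ~0.64.
    """
    return RingTable(
        r=np.array([10.0, 30.0, 50.0, 70.0]),
        n_r=np.array([6.0, 12.0, 18.0, 24.0]),
        p_shared=np.array([0.70, 0.62, 0.54, 0.46]),
        r0=40.0,
        gamma=32.3,
        delta_r=20.0,
        preparation="slice",
    )


@dataclass(frozen=True)
class PairScenario:
    """Everything needed to generate one synthetic A17 pair."""

    ring_table: RingTable = field(default_factory=default_ring_table)
    drive: DriveParams = field(default_factory=DriveParams)
    kernel: KernelParams = field(default_factory=KernelParams)
    noise_sd: float = 0.5
    duration: float = 30.0  # s
    dt: float = 0.1  # ms
    seed: int = 0
    target_css: float | None = None

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if int(round(self.duration * 1000.0 / self.dt)) < 1:
            raise ValueError("duration/dt must yield at least one sample")
        if self.target_css is not None and not 0.0 <= self.target_css <= 1.0:
            raise ValueError("target_css must lie in [0, 1]")


# ---------------------------------------------------------------------------
# closed-form synchrony of two thinned Bernoulli streams


def effective_css(p_master: float, q_follow: float) -> float:
    """Per-bin correlation of two synapse streams thinned from one master.

    With X = M·A, Y = M·B, M ~ Bernoulli(p), A, B ~ Bernoulli(q) independent:
    Cov(X, Y) = p q² (1 - p) and Var(X) = p q (1 - p q), giving
    ``q (1 - p) / (1 - p q)``.  Assumes no asynchronous release.
    """
    for name, v in (("p_master", p_master), ("q_follow", q_follow)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    denom = 1.0 - p_master * q_follow
    if denom == 0.0:  # p = q = 1: identical constant streams
        return 1.0
    return q_follow * (1.0 - p_master) / denom


def stream_correlation(p_master: float, q_follow: float, r_async: float) -> float:
    """Ground-truth synchrony including independent asynchronous release.

    Async events add per-synapse variance ``r (1 - r)`` but no covariance:
    ``corr = p q² (1 - p) / (p q (1 - p q) + r (1 - r))``.
    """
    cov = p_master * q_follow**2 * (1.0 - p_master)
    var = p_master * q_follow * (1.0 - p_master * q_follow) + r_async * (1.0 - r_async)
    if var == 0.0:
        return 1.0 if p_master * q_follow > 0 or (p_master == 1 and q_follow == 1) else 0.0
    return cov / var


def calibrate_q_follow(target_css: float, p_master: float, r_async: float = 0.0) -> float:
    """Solve for the per-synapse follow probability realizing a target synchrony.

    Raises if the target exceeds the synchrony attainable at ``q = 1`` given
    the asynchronous-release floor.
    """
    if not 0.0 <= target_css <= 1.0:
        raise ValueError("target_css must lie in [0, 1]")
    if target_css == 0.0:
        return 0.0
    attainable = stream_correlation(p_master, 1.0, r_async)
    if target_css > attainable + 1e-12:
        raise ValueError(
            f"target synchrony {target_css} unattainable: maximum with "
            f"p_master={p_master}, r_async={r_async} is {attainable:.4f}"
        )
    if abs(target_css - attainable) <= 1e-12:
        return 1.0
    f = lambda q: stream_correlation(p_master, q, r_async) - target_css
    return float(optimize.brentq(f, 0.0, 1.0, xtol=1e-12))


# ---------------------------------------------------------------------------
# random-stream plumbing


def substream(seed: int, *names) -> np.random.Generator:
    """Named, independent random substream derived from one top-level seed."""
    key = tuple(zlib.crc32(str(n).encode()) for n in names)
    return np.random.default_rng(np.random.SeedSequence((int(seed),) + key))


def quantal_kernel(params: KernelParams, dt: float) -> np.ndarray:
    """Difference-of-exponentials kernel sampled at ``dt``, extremum = amplitude."""
    t_end = params.tau_rise + 8.0 * params.tau_decay
    t = np.arange(0.0, t_end, dt)
    k = np.exp(-t / params.tau_decay) - np.exp(-t / params.tau_rise)
    peak = k.max()
    if peak <= 0:
        raise ValueError("degenerate kernel (dt too coarse for tau_rise)")
    return params.amplitude * k / peak


def _master_streams(k: int, n_bins: int, drive: DriveParams,
                    rng: np.random.Generator) -> np.ndarray:
    """k Boolean master streams, optionally with shared-per-RBC AR(1) rate drift."""
    if k == 0:
        return np.zeros((0, n_bins), dtype=bool)
    if drive.modulation_depth == 0.0:
        return rng.random((k, n_bins)) < drive.p_master
    a = np.exp(-drive.bin_width / drive.tau_drive)
    eps = rng.standard_normal((k, n_bins))
    z = signal.lfilter([np.sqrt(1.0 - a * a)], [1.0, -a], eps, axis=1)
    p_t = np.clip(drive.p_master * (1.0 + drive.modulation_depth * z), 0.0, 1.0)
    return rng.random((k, n_bins)) < p_t


def _thin(master: np.ndarray, drive: DriveParams,
          rng: np.random.Generator) -> np.ndarray:
    """Per-synapse event counts: thinned master events plus asynchronous release."""
    followed, asynchronous = _thin_split(master, drive, rng)
    return followed.astype(np.int8) + asynchronous.astype(np.int8)


def _thin_split(master: np.ndarray, drive: DriveParams, rng: np.random.Generator):
    """Thinned master events and asynchronous events as separate Boolean arrays."""
    q, r = drive.q_follow, drive.r_async
    if q >= 1.0:
        followed = master.copy()
    elif q <= 0.0:
        followed = np.zeros(master.shape, dtype=bool)
    else:
        followed = master & (rng.random(master.shape) < q)
    if r > 0.0:
        asynchronous = rng.random(master.shape) < r
    else:
        asynchronous = np.zeros(master.shape, dtype=bool)
    return followed, asynchronous


def sample_synapse_pair(drive: DriveParams, n_bins: int, seed: int = 0):
    """Event-count streams of two synapses of one RBC (for validating the dial)."""
    rng_m = substream(seed, "master")
    master = _master_streams(1, n_bins, drive, rng_m)
    x = _thin(master, drive, substream(seed, "events", "x"))[0]
    y = _thin(master, drive, substream(seed, "events", "y"))[0]
    return x, y


def _deposit(impulses: np.ndarray, events: np.ndarray, jitter: np.ndarray,
             amp: float, bin_width: float, dt: float) -> None:
    """Add amplitude-weighted impulses for Boolean per-bin events.

    Each event lands at ``(bin + jitter) * bin_width`` where ``jitter`` in
    [0, 1) is the event's sub-bin offset.  Aligning all events to bin
    centres instead would imprint a deterministic 2-ms comb on the mean
    current, identical in both cells of a pair, and spuriously inflate their
    cross-correlation; jitter keeps the point process time-homogeneous.
    Synapses following the same master event share that event's jitter, so
    synchronized events still coincide exactly across cells.
    """
    rows, cols = np.nonzero(events)
    if rows.size == 0:
        return
    idx = ((cols + jitter[rows, cols]) * bin_width / dt).astype(int)
    np.add.at(impulses, np.minimum(idx, impulses.size - 1), amp)


def _render(impulses: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Convolve the impulse train with the quantal kernel (causal, cropped)."""
    return signal.fftconvolve(impulses, kernel)[: impulses.size]


def _resolve_drive(scenario: PairScenario) -> DriveParams:
    d = scenario.drive
    if scenario.target_css is None:
        return d
    q = calibrate_q_follow(scenario.target_css, d.p_master, d.r_async)
    return DriveParams(
        bin_width=d.bin_width, p_master=d.p_master, q_follow=q,
        r_async=d.r_async, tau_drive=d.tau_drive,
        modulation_depth=d.modulation_depth,
    )


def _check_duration(drive: DriveParams, n_bins: int) -> None:
    rate = drive.p_master * drive.q_follow + drive.r_async
    if n_bins * rate < 10:
        raise ValueError(
            f"record too short: expected {n_bins * rate:.1f} events per synapse, "
            "need at least 10"
        )


def generate_pair(scenario: PairScenario):
    """Generate one synthetic A17 pair.

    Returns ``(trace_a, trace_b, ground_truth)`` where ``ground_truth`` is
    the per-bin synchrony of same-RBC synapse streams actually realized by
    the drive parameters (equal to ``scenario.target_css`` when one was
    requested).  Fixed seeds give bit-identical traces.
    """
    table = scenario.ring_table
    drive = _resolve_drive(scenario)
    n_bins = int(round(scenario.duration * 1000.0 / drive.bin_width))
    _check_duration(drive, n_bins)
    n_samples = int(round(scenario.duration * 1000.0 / scenario.dt))

    rng_wiring = substream(scenario.seed, "wiring")
    rng_master = substream(scenario.seed, "master")
    rng_jitter = substream(scenario.seed, "jitter")
    rng_ev_a = substream(scenario.seed, "events", "a")
    rng_ev_b = substream(scenario.seed, "events", "b")
    rng_jit_a = substream(scenario.seed, "jitter", "a")
    rng_jit_b = substream(scenario.seed, "jitter", "b")
    rng_noise = substream(scenario.seed, "noise")

    bw, dt = drive.bin_width, scenario.dt
    imp_a = np.zeros(n_samples)
    imp_b = np.zeros(n_samples)
    for r, n_r, p_sh in zip(table.r, table.n_r, table.p_shared):
        n_contacts = int(round(n_r))
        if n_contacts == 0:
            continue
        amp = np.exp(-(r + table.r0) / table.gamma)  # amplitude attenuation
        shared = rng_wiring.random(n_contacts) < p_sh
        masters_a = _master_streams(n_contacts, n_bins, drive, rng_master)
        jit_master = rng_jitter.random((n_contacts, n_bins))
        fol_a, asy_a = _thin_split(masters_a, drive, rng_ev_a)
        _deposit(imp_a, fol_a, jit_master, amp, bw, dt)
        _deposit(imp_a, asy_a, rng_jit_a.random(asy_a.shape), amp, bw, dt)
        # cell B: shared RBCs reuse cell A's masters (and their jitter);
        # unshared slots are replaced by private RBCs with fresh masters
        fol_b, asy_b = _thin_split(masters_a[shared], drive, rng_ev_b)
        _deposit(imp_b, fol_b, jit_master[shared], amp, bw, dt)
        _deposit(imp_b, asy_b, rng_jit_b.random(asy_b.shape), amp, bw, dt)
        n_priv = n_contacts - int(shared.sum())
        masters_priv = _master_streams(n_priv, n_bins, drive, rng_master)
        jit_priv = rng_jitter.random((n_priv, n_bins))
        fol_p, asy_p = _thin_split(masters_priv, drive, rng_ev_b)
        _deposit(imp_b, fol_p, jit_priv, amp, bw, dt)
        _deposit(imp_b, asy_p, rng_jit_b.random(asy_p.shape), amp, bw, dt)

    kernel = quantal_kernel(scenario.kernel, scenario.dt)
    a = _render(imp_a, kernel)
    b = _render(imp_b, kernel)
    if scenario.noise_sd > 0:
        a = a + rng_noise.normal(0.0, scenario.noise_sd, n_samples)
        b = b + rng_noise.normal(0.0, scenario.noise_sd, n_samples)
    gt = stream_correlation(drive.p_master, drive.q_follow, drive.r_async)
    return (
        Trace(a, scenario.dt, label="a17_a"),
        Trace(b, scenario.dt, label="a17_b"),
        float(gt),
    )


def generate_convergent_trace(scenario: PairScenario, synapses_per_rbc: int) -> Trace:
    """One AII-like cell receiving ``synapses_per_rbc`` synapses from every RBC.

    All synapses of an RBC are thinned from that RBC's single master stream,
    so with a high follow probability they release coherently and the trace
    variance grows quadratically in the synapse count — the convergent-wiring
    asymmetry between AII and A17 noise.
    """
    if synapses_per_rbc < 1:
        raise ValueError("synapses_per_rbc must be >= 1")
    table = scenario.ring_table
    drive = _resolve_drive(scenario)
    n_bins = int(round(scenario.duration * 1000.0 / drive.bin_width))
    _check_duration(drive, n_bins)
    n_samples = int(round(scenario.duration * 1000.0 / scenario.dt))

    rng_master = substream(scenario.seed, "master")
    rng_jitter = substream(scenario.seed, "jitter")
    rng_ev = substream(scenario.seed, "events", "a")
    rng_jit_a = substream(scenario.seed, "jitter", "a")
    rng_noise = substream(scenario.seed, "noise")

    bw, dt = drive.bin_width, scenario.dt
    impulses = np.zeros(n_samples)
    for r, n_r, _p in zip(table.r, table.n_r, table.p_shared):
        n_contacts = int(round(n_r))
        if n_contacts == 0:
            continue
        amp = np.exp(-(r + table.r0) / table.gamma)
        masters = _master_streams(n_contacts, n_bins, drive, rng_master)
        jit_master = rng_jitter.random((n_contacts, n_bins))
        for _ in range(synapses_per_rbc):
            fol, asy = _thin_split(masters, drive, rng_ev)
            _deposit(impulses, fol, jit_master, amp, bw, dt)
            _deposit(impulses, asy, rng_jit_a.random(asy.shape), amp, bw, dt)

    kernel = quantal_kernel(scenario.kernel, scenario.dt)
    out = _render(impulses, kernel)
    if scenario.noise_sd > 0:
        out = out + rng_noise.normal(0.0, scenario.noise_sd, n_samples)
    return Trace(out, scenario.dt, label="aii")
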