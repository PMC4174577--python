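"""Anatomy-weighted mapping between paired-recording correlation and synaptic synchrony.

A rod bipolar cell (RBC) releases from ~50 ribbon output synapses.  Two A17
amacrine cells with overlapping dendritic fields receive input from many of
the same RBCs, each typically at a *different* ribbon of that RBC, so the
zero-lag correlation between their excitatory input currents reports how
strongly release covaries across synapses of a single RBC — the
cross-synaptic synchrony (CSS), written ``beta`` here and constrained to
[0, 1].

The measured correlation is diluted by two anatomical factors: only a
fraction ``p_shared(r)`` of the RBC contacts within a radial ring are common
to both cells, and distal inputs are attenuated electrotonically before they
reach the somatic recording pipette.  With ``w(r) = exp(-2 (r + r0) / gamma)``
the variance weight of a contact at radial distance ``r`` (``r0`` accounts
for the initial descending dendrite, ``gamma`` is the electrotonic length
factor), the model is

    sigma_total^2           = sum_r n_r * w(r)
    sigma_shared^2          = beta * sum_r p_shared(r) * n_r * w(r)
    CC(0) = sigma_shared^2 / sigma_total^2 = slope * beta

so the zero-lag correlation is proportional to CSS with a purely anatomical
slope ``sum_r p_shared n_r w / sum_r n_r w``.  Inverting the relation yields
the CSS estimate ``beta = CC_peak / slope``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

#: Published proportionality between CC peak and CSS for slice recordings,
#: after correcting ring contact counts for dendrites lost to slicing.
SLICE_SLOPE = 0.64
#: Same proportionality for whole-mount (intact) retina.
WHOLEMOUNT_SLOPE = 0.67


@dataclass(frozen=True)
class RingTable:
    """Per-ring RBC connectivity of an A17 amacrine cell.

    Connectivity is tabulated in concentric rings of width ``delta_r``
    centred on the soma; ``r`` holds each ring's *mean* radial distance.

    Attributes
    ----------
    r : ndarray
        Mean radial distance of each ring from the soma (µm), strictly
        increasing.
    n_r : ndarray
        Number of RBC contacts within each ring (fractional values allowed;
        anatomical counts are per-cell means).
    p_shared : ndarray
        Fraction of each ring's contacts shared with an overlapping A17,
        in [0, 1].
    r0 : float
        Length of the initial descending dendrite (µm); added to ``r`` when
        converting radial to dendritic distance.
    gamma : float
        Electrotonic length factor of the dendrites (µm).
    delta_r : float
        Ring width (µm); metadata only.
    preparation : str
        ``"slice"`` or ``"wholemount"``; metadata only.
    """

    r: np.ndarray
    n_r: np.ndarray
    p_shared: np.ndarray
    r0: float = 40.0
    gamma: float = 32.3
    delta_r: float = 20.0
    preparation: str = "slice"

    def __post_init__(self) -> None:
        r = np.atleast_1d(np.asarray(self.r, dtype=float))
        n = np.atleast_1d(np.asarray(self.n_r, dtype=float))
        p = np.atleast_1d(np.asarray(self.p_shared, dtype=float))
        if r.size == 0:
            raise ValueError("ring table must contain at least one ring")
        if not (r.size == n.size == p.size):
            raise ValueError("r, n_r and p_shared must have equal length")
        if r.size > 1 and not np.all(np.diff(r) > 0):
            raise ValueError("ring radii must be strictly increasing")
        if np.any(n < 0):
            raise ValueError("contact counts must be non-negative")
        if np.any((p < 0) | (p > 1)):
            raise ValueError("p_shared values must lie in [0, 1]")
        if not (self.gamma > 0):
            raise ValueError("gamma must be positive")
        if self.r0 < 0:
            raise ValueError("r0 must be non-negative")
        object.__setattr__(self, "r", r)
        object.__setattr__(self, "n_r", n)
        object.__setattr__(self, "p_shared", p)

    def __len__(self) -> int:
        return self.r.size


@dataclass(frozen=True)
class CssEstimate:
    """An inferred cross-synaptic synchrony value.

    ``beta`` is ``cc_peak / slope``.  Values above 1 indicate that the
    measured correlation exceeds what the anatomical model can produce at
    perfect synchrony (the model's simplifying assumptions make it
    *underestimate* the synchrony required for a given correlation), so such
    estimates are flagged rather than clamped.
    """

    beta: float
    slope: float
    source: str  # "ring_table" | "fixed_slope"
    out_of_range: bool = False


def electrotonic_weight(r: float, r0: float, gamma: float) -> float:
    """Variance weight ``exp(-2 (r + r0) / gamma)`` of a synaptic contact.

    The factor 2 reflects that current *amplitude* attenuates as
    ``exp(-(r + r0)/gamma)`` and variance goes as amplitude squared.
    """
    if not gamma > 0:
        raise ValueError("gamma must be positive")
    return float(np.exp(-2.0 * (np.asarray(r, dtype=float) + r0) / gamma))


def _weights(table: RingTable) -> np.ndarray:
    return np.exp(-2.0 * (table.r + table.r0) / table.gamma)


def total_variance(table: RingTable) -> float:
    """Total input variance ``sum_r n_r exp(-2 (r + r0)/gamma)`` (arbitrary units)."""
    return float(np.sum(table.n_r * _weights(table)))


def shared_variance(table: RingTable, beta: float) -> float:
    """Variance shared by two overlapping cells,
    ``beta * sum_r p_shared n_r exp(-2 (r + r0)/gamma)``."""
    if not 0.0 <= beta <= 1.0:
        raise ValueError(f"beta must lie in [0, 1], got {beta}")
    return float(beta * np.sum(table.p_shared * table.n_r * _weights(table)))


def css_slope(table: RingTable) -> float:
    """Anatomical proportionality between CC peak and CSS.

    ``slope = sum_r p_shared n_r w / sum_r n_r w``; with all probabilities in
    [0, 1] the slope lies in [0, 1] and ``CC(0) = slope * beta``.
    """
    total = total_variance(table)
    if total <= 0:
        raise ValueError("ring table has zero total variance")
    return shared_variance(table, 1.0) / total


def cc_from_css(beta: float, table: RingTable) -> float:
    """Forward model: expected CC peak for a given synchrony ``beta``."""
    if not 0.0 <= beta <= 1.0:
        raise ValueError(f"beta must lie in [0, 1], got {beta}")
    return beta * css_slope(table)


def css_from_cc(cc_peak: float, slope: float, source: str = "fixed_slope") -> CssEstimate:
    """Invert the correlation-synchrony relation: ``beta = cc_peak / slope``.

    Emits a ``UserWarning`` (and sets ``out_of_range``) when the estimate
    exceeds 1 instead of silently clamping it.
    """
    if not 0.0 < slope <= 1.0:
        raise ValueError(f"slope must lie in (0, 1], got {slope}")
    if cc_peak < 0:
        raise ValueError(f"cc_peak must be non-negative, got {cc_peak}")
    beta = cc_peak / slope
    out_of_range = beta > 1.0
    if out_of_range:
        warnings.warn(
            f"inferred synchrony {beta:.3f} exceeds 1: measured correlation is larger "
            "than the anatomical model allows at perfect synchrony (model mismatch)",
            UserWarning,
            stacklevel=2,
        )
    return CssEstimate(beta=float(beta), slope=float(slope), source=source,
                       out_of_range=out_of_range)


def css_from_cc_table(cc_peak: float, table: RingTable) -> CssEstimate:
    """Convenience wrapper deriving the slope from a ring table."""
    est = css_from_cc(cc_peak, css_slope(table), source="ring_table")
    return est


def apply_slice_correction(table: RingTable) -> RingTable:
    """Halve contact counts in every ring after the first.

    Slicing the retina truncates distal A17 dendrites; contacts beyond the
    innermost ring are assumed to survive with probability one half.  Returns
    a new table; the input is unchanged.
    """
    n = table.n_r.copy()
    if n.size > 1:
        n[1:] = n[1:] / 2.0
    return replace(table, n_r=n)
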