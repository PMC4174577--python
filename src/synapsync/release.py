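"""Quantal release-variability model linking synchrony to single-synapse reliability.

Under a homogeneous-release-probability assumption, cross-synaptic synchrony
and the trial-to-trial coefficient of variation of transmission at a single
synapse are tied by

    beta_sync = 1 / (1 + CV_single²)

so a measured synchrony directly bounds how reliable each synapse must be
(beta = 0.8 implies CV <= 0.5).  With ``N`` independent release sites
(active zones) per ribbon, each releasing one vesicle with probability
``Pr``, the released count is Binomial(N, Pr) and

    CV_single = sqrt((1 - Pr) / (N Pr)).

Postsynaptic receptor saturation — responses to ``s`` or more vesicles being
indistinguishable — is modeled by clipping the count at ``s``; the package
provides both a Monte Carlo simulation of this process and its exact value
from the binomial pmf.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class ReleaseModel:
    """A single ribbon synapse with ``n_sites`` active zones.

    ``saturation`` is the vesicle count at or above which postsynaptic
    responses are equal (``None`` disables saturation).  Presets in the
    literature are 2 (receptor saturation by paired vesicles) and 5.
    """

    n_sites: int = 10
    pr: float = 0.5
    saturation: int | None = None
    n_trials: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if not 0.0 <= self.pr <= 1.0:
            raise ValueError("pr must lie in [0, 1]")
        if self.saturation is not None and self.saturation < 1:
            raise ValueError("saturation must be >= 1 or None")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")


def css_from_cv(cv: float) -> float:
    """Synchrony implied by a single-synapse CV: ``1 / (1 + cv²)``."""
    if cv < 0:
        raise ValueError("cv must be non-negative")
    return 1.0 / (1.0 + cv * cv)


def cv_required(beta: float) -> float:
    """Largest single-synapse CV compatible with synchrony ``beta``:
    ``sqrt(1/beta - 1)``.  Inverse of :func:`css_from_cv`."""
    if not 0.0 < beta <= 1.0:
        raise ValueError(f"beta must lie in (0, 1], got {beta}")
    return float(np.sqrt(1.0 / beta - 1.0))


def cv_single_analytic(n_sites: int, pr: float) -> float:
    """Binomial CV of the released vesicle count, ``sqrt((1 - pr)/(n pr))``."""
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    if not 0.0 < pr <= 1.0:
        raise ValueError(f"pr must lie in (0, 1], got {pr}")
    return float(np.sqrt((1.0 - pr) / (n_sites * pr)))


def simulate_release(model: ReleaseModel) -> np.ndarray:
    """Monte Carlo per-trial responses.

    Each trial draws ``n_sites`` independent uniform numbers; a site releases
    when its number falls below ``pr``.  The response is the released count,
    clipped at ``saturation`` when set.  Reproducible under a fixed seed.
    """
    rng = np.random.default_rng(model.seed)
    released = rng.random((model.n_trials, model.n_sites)) < model.pr
    counts = released.sum(axis=1).astype(float)
    if model.saturation is not None:
        counts = np.minimum(counts, float(model.saturation))
    return counts


def cv_empirical(responses: np.ndarray) -> float:
    """Across-trial coefficient of variation, sample SD (n-1 denominator) / mean."""
    responses = np.asarray(responses, dtype=float)
    if responses.size == 0:
        raise ValueError("responses must be nonempty")
    mean = responses.mean()
    if mean == 0:
        raise ValueError("mean response is zero: CV undefined")
    if responses.size == 1:
        return 0.0
    return float(responses.std(ddof=1) / mean)


def cv_saturated_exact(n_sites: int, pr: float, saturation: int) -> float:
    """Exact CV of ``min(Binomial(n, pr), saturation)`` from the binomial pmf."""
    if saturation < 1:
        raise ValueError("saturation must be >= 1")
    if not 0.0 < pr <= 1.0:
        raise ValueError(f"pr must lie in (0, 1], got {pr}")
    k = np.arange(n_sites + 1)
    pmf = stats.binom.pmf(k, n_sites, pr)
    resp = np.minimum(k, saturation)
    mean = float(np.sum(pmf * resp))
    var = float(np.sum(pmf * resp**2) - mean**2)
    if mean == 0:
        raise ValueError("mean response is zero: CV undefined")
    return float(np.sqrt(max(var, 0.0)) / mean)


def release_sweep(
    pr_values: np.ndarray,
    n_sites: int = 10,
    saturation: int | None = None,
    n_trials: int = 200,
    seed: int = 0,
):
    """Sweep release probability, returning per-pr analytic and empirical CV
    and the synchrony each empirical CV implies.  Rows are dicts suitable for
    a DataFrame."""
    rows = []
    for i, pr in enumerate(np.asarray(pr_values, dtype=float)):
        model = ReleaseModel(n_sites=n_sites, pr=float(pr), saturation=saturation,
                             n_trials=n_trials, seed=seed + i)
        resp = simulate_release(model)
        emp = cv_empirical(resp) if resp.mean() > 0 else np.nan
        rows.append(
            {
                "pr": float(pr),
                "cv_analytic": cv_single_analytic(n_sites, float(pr)) if pr > 0 else np.nan,
                "cv_empirical": emp,
                "beta_implied": css_from_cv(emp) if np.isfinite(emp) else np.nan,
            }
        )
    return rows
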