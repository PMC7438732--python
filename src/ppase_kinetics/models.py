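"""Rate laws for membrane pyrophosphatase kinetics.

Two parameterisations of the hydrolysis rate versus substrate concentration
S = [Mg2PPi] are provided:

* the empirical Hill equation  v = Vm * S^nH / (K0.5^nH + S^nH);
* a two-state concerted (MWC-type) allosteric saturation function for a
  homodimeric enzyme with two catalytic sites, in which the substrate binds
  exclusively to the active R state (dissociation constant K_R) and also
  stabilises R, so the allosteric constant L = [T]/[R] is divided by
  (1 + S/K_R)^2:

      v / Vm = Yhat = (S/K_R)(1 + S/K_R) / [ (1+S/K_R)^2 + L/(1+S/K_R)^2 ].

With u = 1 + S/K_R this is (u^4 - u^3) / (u^4 + L), the numerically stable
form used internally.  L = 0 collapses to Michaelis-Menten with Km = K_R.

Unit conventions: substrate concentrations are handled in mM throughout;
K_R is carried in uM on :class:`MWCParams` (the scale on which allosteric
fits are reported) and converted at the boundary.  Rates are in enzyme
units per mg protein (U/mg = umol PPi min^-1 mg^-1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.typing import ArrayLike
from scipy.optimize import brentq

__all__ = [
    "HillParams",
    "MWCParams",
    "mwc_saturation",
    "mwc_rate",
    "hill_rate",
    "mm_rate",
    "effective_hill",
]


@dataclass(frozen=True)
class HillParams:
    """Hill-equation parameters: Vm (U/mg), K0.5 (mM), Hill coefficient nH."""

    vm: float
    k_half: float
    n_h: float

    def __post_init__(self) -> None:
        if not (self.vm > 0):
            raise ValueError(f"vm must be > 0, got {self.vm!r}")
        if not (self.k_half > 0):
            raise ValueError(f"k_half must be > 0, got {self.k_half!r}")
        if not (self.n_h > 0):
            raise ValueError(f"n_h must be > 0, got {self.n_h!r}")


@dataclass(frozen=True)
class MWCParams:
    """Two-state allosteric parameters.

    Attributes
    ----------
    vm : float
        Maximal rate, U/mg.
    l : float
        Allosteric constant L = [T]/[R]; 0 means all-R (Michaelian limit),
        large L locks the enzyme in the inactive T state.
    k_r : float
        Substrate dissociation constant toward the R state, in uM.
    """

    vm: float
    l: float
    k_r: float

    def __post_init__(self) -> None:
        if not (self.vm > 0):
            raise ValueError(f"vm must be > 0, got {self.vm!r}")
        if not (self.l >= 0):
            raise ValueError(f"l must be >= 0, got {self.l!r}")
        if not (self.k_r > 0):
            raise ValueError(f"k_r must be > 0, got {self.k_r!r}")

    @property
    def k_r_mM(self) -> float:
        return self.k_r / 1000.0


def _check_s(s: ArrayLike) -> np.ndarray:
    arr = np.asarray(s, dtype=float)
    if np.any(arr < 0) or not np.all(np.isfinite(arr)):
        raise ValueError("substrate concentrations must be finite and >= 0")
    return arr


def mwc_saturation(s: ArrayLike, k_r: float, l: float) -> np.ndarray | float:
    """Saturation fraction Yhat in [0, 1) of the two-state allosteric model.

    ``s`` and ``k_r`` must share units (both mM or both uM).
    """
    if not (k_r > 0):
        raise ValueError(f"k_r must be > 0, got {k_r!r}")
    if not (l >= 0):
        raise ValueError(f"l must be >= 0, got {l!r}")
    arr = _check_s(s)
    r = arr / k_r
    u = 1.0 + r
    u3 = u * u * u
    # u^4 - u^3 = u^3 (u - 1) = u^3 r, written so tiny s does not cancel
    out = (u3 * r) / (u3 * u + l)
    return out if out.ndim else float(out)


def mwc_rate(s: ArrayLike, params: MWCParams) -> np.ndarray | float:
    """Hydrolysis rate Vm * Yhat(S); ``s`` in mM, result in U/mg."""
    return params.vm * mwc_saturation(s, params.k_r_mM, params.l)


def hill_rate(s: ArrayLike, params: HillParams) -> np.ndarray | float:
    """Hill-equation rate Vm * S^nH / (K0.5^nH + S^nH); ``s`` in mM."""
    arr = _check_s(s)
    # Work on the ratio scale so large nH does not overflow for large S.
    ratio = arr / params.k_half
    with np.errstate(divide="ignore"):
        r_n = np.where(ratio > 0, np.exp(params.n_h * np.log(np.maximum(ratio, 1e-300))), 0.0)
    out = params.vm * r_n / (1.0 + r_n)
    out = np.where(ratio == 0.0, 0.0, out)
    return out if out.ndim else float(out)


def mm_rate(s: ArrayLike, vm: float, km: float) -> np.ndarray | float:
    """Michaelis-Menten rate vm * s / (km + s); the L = 0 / nH = 1 limit law."""
    if not (vm > 0):
        raise ValueError(f"vm must be > 0, got {vm!r}")
    if not (km > 0):
        raise ValueError(f"km must be > 0, got {km!r}")
    arr = _check_s(s)
    out = vm * arr / (km + arr)
    return out if out.ndim else float(out)


def effective_hill(params: MWCParams) -> float:
    """Apparent cooperativity of the allosteric curve.

    Returns n_eff = log(81) / log(S90 / S10), where S10 and S90 are the
    substrate concentrations at 10% and 90% saturation, found by bracketed
    root-finding.  Equals 1 in the Michaelian limit (L = 0) and grows with L.
    """
    k_r_mM = params.k_r_mM
    l = params.l

    def find(level: float) -> float:
        f = lambda s: mwc_saturation(s, k_r_mM, l) - level
        hi = k_r_mM
        for _ in range(200):
            if f(hi) > 0:
                break
            hi *= 2.0
        else:  # pragma: no cover
            raise RuntimeError(f"could not bracket Yhat = {level}")
        return brentq(f, 0.0, hi, xtol=1e-15, rtol=1e-14, maxiter=200)

    s10 = find(0.1)
    s90 = find(0.9)
    return float(np.log(81.0) / np.log(s90 / s10))
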