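"""Synthetic replicate assay data with the designs used for membrane PPases.

Two experimental designs are emulated:

* ``matched_mg`` — total Mg is held at exactly twice total PPi at every
  point, so the dominant species tracks the substrate Mg2PPi (the design
  behind substrate-saturation curves plotted against [Mg2PPi]);
* ``fixed_mg`` — MgCl2 is fixed (typically 1 or 2.5 mM) while total PPi is
  titrated, leaving free Mg2+ in excess.

In both designs PPi is added as the tetrasodium salt, so a basal sodium
concentration of 4 x total PPi is always present on top of any added NaCl,
and KCl (default 100 mM) supplies the K+ both enzymes require.

Replicate noise is Gaussian on the rate with standard deviation
``cv * true_rate + sd_floor``; negative draws are redrawn, keeping the mean
unbiased at the cost of a slight variance shrinkage.  Each (point,
replicate) pair has its own deterministic substream derived from
(seed, point index, replicate index), so subsetting a design never changes
the draws at shared points.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .models import HillParams, MWCParams, hill_rate, mwc_rate
from .speciation import ComplexationConstants, IonicConditions, speciate

__all__ = [
    "AssayDesign",
    "DesignPoint",
    "SyntheticConfig",
    "make_design",
    "matched_design_for_substrate",
    "ppi_total_for_substrate",
    "simulate_assay",
    "DEFAULT_SUBSTRATE_GRID",
]

#: Default matched-Mg substrate grid (mM Mg2PPi): 8 points spanning the
#: rising limb through >=80% saturation for the parameter sets modelled.
DEFAULT_SUBSTRATE_GRID: tuple[float, ...] = (
    0.025, 0.05, 0.1, 0.15, 0.2, 0.3, 0.4, 0.5,
)

_MODES = ("matched_mg", "fixed_mg")


@dataclass(frozen=True)
class DesignPoint:
    """One fully expanded assay point."""

    index: int
    nacl: float
    ppi_total: float
    conditions: IonicConditions


@dataclass(frozen=True)
class AssayDesign:
    """An expanded assay design over PPi totals and added-NaCl levels.

    Invariants: grids non-empty and strictly increasing; in ``matched_mg``
    mode total Mg = 2 x total PPi per point; total Na always includes the
    basal 4 x PPi from the tetrasodium salt on top of the added NaCl.
    """

    mode: str
    ppi_totals: tuple[float, ...]
    nacl_levels: tuple[float, ...] = (0.0,)
    kcl: float = 100.0
    fixed_mgcl2: float | None = None
    ph: float = 7.2

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}, got {self.mode!r}")
        for name, grid in (("ppi_totals", self.ppi_totals), ("nacl_levels", self.nacl_levels)):
            arr = np.asarray(grid, dtype=float)
            if arr.size == 0:
                raise ValueError(f"{name} must be non-empty")
            if np.any(arr < 0):
                raise ValueError(f"{name} must be >= 0")
            if arr.size > 1 and np.any(np.diff(arr) <= 0):
                raise ValueError(f"{name} must be strictly increasing")
        if self.mode == "fixed_mg":
            if self.fixed_mgcl2 is None or not (self.fixed_mgcl2 > 0):
                raise ValueError("fixed_mg mode requires fixed_mgcl2 > 0")
        if self.kcl < 0:
            raise ValueError("kcl must be >= 0")

    def total_mg(self, ppi_total: float) -> float:
        if self.mode == "matched_mg":
            return 2.0 * ppi_total
        return float(self.fixed_mgcl2)

    def points(self) -> list[DesignPoint]:
        """Expand to points, ordered NaCl level first, then PPi total."""
        out: list[DesignPoint] = []
        index = 0
        for nacl in self.nacl_levels:
            for ppi in self.ppi_totals:
                cond = IonicConditions(
                    total_ppi=ppi,
                    total_mg=self.total_mg(ppi),
                    total_k=self.kcl,
                    total_na=nacl + 4.0 * ppi,  # tetrasodium salt rule
                    ph=self.ph,
                )
                out.append(DesignPoint(index, nacl, ppi, cond))
                index += 1
        return out

    def conditions(self) -> list[IonicConditions]:
        return [p.conditions for p in self.points()]


def make_design(
    mode: str,
    ppi_totals: Sequence[float],
    *,
    nacl_levels: Sequence[float] = (0.0,),
    kcl: float = 100.0,
    fixed_mgcl2: float | None = None,
    ph: float = 7.2,
) -> AssayDesign:
    """Build a validated assay design (see :class:`AssayDesign`)."""
    return AssayDesign(
        mode=mode,
        ppi_totals=tuple(float(x) for x in ppi_totals),
        nacl_levels=tuple(float(x) for x in nacl_levels),
        kcl=float(kcl),
        fixed_mgcl2=None if fixed_mgcl2 is None else float(fixed_mgcl2),
        ph=float(ph),
    )


def ppi_total_for_substrate(
    target_s: float,
    *,
    constants: ComplexationConstants,
    nacl: float = 0.0,
    kcl: float = 100.0,
    ph: float = 7.2,
    mode: str = "matched_mg",
    fixed_mgcl2: float | None = None,
    rtol: float = 1e-10,
) -> float:
    """Invert speciation: total PPi whose speciated [Mg2PPi] equals target_s.

    The map total PPi -> S is strictly increasing under both designs (more
    ligand and, in matched mode, more Mg), so bisection on a doubling bracket
    is exact.  Used to lay out matched-Mg designs on the substrate scale.
    """
    if not (target_s > 0):
        raise ValueError("target_s must be > 0")
    constants.require_substrate()

    def s_of(ppi_total: float) -> float:
        mg = 2.0 * ppi_total if mode == "matched_mg" else float(fixed_mgcl2)
        cond = IonicConditions(ppi_total, mg, kcl, nacl + 4.0 * ppi_total, ph)
        return speciate(cond, constants).substrate

    hi = max(target_s, 1e-6)
    for _ in range(80):
        if s_of(hi) >= target_s:
            break
        hi *= 2.0
    else:
        raise RuntimeError(f"could not bracket total PPi for S = {target_s} mM")
    return float(brentq(lambda p: s_of(p) - target_s, 0.0, hi, rtol=rtol, maxiter=200))


def matched_design_for_substrate(
    substrate_targets: Sequence[float] = DEFAULT_SUBSTRATE_GRID,
    *,
    constants: ComplexationConstants | None = None,
    nacl_levels: Sequence[float] = (0.0,),
    kcl: float = 100.0,
    ph: float = 7.2,
) -> AssayDesign:
    """Matched-Mg design whose speciated substrate grid hits the targets.

    The substrate-to-total map depends (weakly) on added NaCl through NaPPi
    pairing; the inversion uses the lowest NaCl level, so quoted targets are
    exact there and very slightly lower at higher salt, as in a real assay
    where one stock dilution series serves all salt conditions.
    """
    constants = constants or ComplexationConstants.default()
    nacl0 = float(min(nacl_levels))
    totals = [
        ppi_total_for_substrate(s, constants=constants, nacl=nacl0, kcl=kcl, ph=ph)
        for s in substrate_targets
    ]
    return make_design(
        "matched_mg", totals, nacl_levels=nacl_levels, kcl=kcl, ph=ph
    )


@dataclass(frozen=True)
class SyntheticConfig:
    """Generating truth and noise model for one simulated assay.

    ``truth`` maps each added-NaCl level (mM) to the generating rate-law
    parameters (:class:`HillParams` or :class:`MWCParams`) for that
    condition.  Noise: SD = cv * true_rate + sd_floor, redrawn while
    negative.  ``abscissa`` chooses the concentration the generating model
    is evaluated at: ``"speciated"`` (Mg2PPi), ``"total_ppi"``, or ``"auto"``
    (speciated for matched-Mg designs, total PPi for fixed-Mg).
    """

    truth: Mapping[float, HillParams | MWCParams]
    n_replicates: int = 4
    cv: float = 0.08
    sd_floor: float = 0.005
    seed: int = 0
    abscissa: str = "auto"
    override_replicate_range: bool = False

    def __post_init__(self) -> None:
        if not self.truth:
            raise ValueError("truth mapping must be non-empty")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not self.override_replicate_range and not (3 <= self.n_replicates <= 5):
            raise ValueError(
                "n_replicates outside [3, 5]; set override_replicate_range=True "
                "to simulate outside the replicate range of a real assay"
            )
        if self.cv < 0 or self.sd_floor < 0:
            raise ValueError("cv and sd_floor must be >= 0")
        if self.abscissa not in ("auto", "speciated", "total_ppi"):
            raise ValueError(f"invalid abscissa {self.abscissa!r}")


def _true_rate(x: float, params: HillParams | MWCParams) -> float:
    if isinstance(params, HillParams):
        return float(hill_rate(x, params))
    if isinstance(params, MWCParams):
        return float(mwc_rate(x, params))
    raise TypeError(f"unsupported generating model {type(params).__name__}")


def simulate_assay(
    design: AssayDesign,
    config: SyntheticConfig,
    *,
    enzyme: str = "ENZ",
    constants: ComplexationConstants | None = None,
) -> pd.DataFrame:
    """Simulate replicate assay records for a design.

    Returns a table in the pipeline input schema (one row per replicate
    measurement) carrying the full ionic metadata.  Identical seeds give
    bit-identical tables.
    """
    abscissa = config.abscissa
    if abscissa == "auto":
        abscissa = "speciated" if design.mode == "matched_mg" else "total_ppi"
    if abscissa == "speciated":
        constants = constants or ComplexationConstants.default()

    rows: list[dict] = []
    for point in design.points():
        try:
            params = config.truth[point.nacl]
        except KeyError:
            raise ValueError(
                f"no generating parameters for NaCl level {point.nacl} mM"
            ) from None
        if abscissa == "speciated":
            x = speciate(point.conditions, constants).substrate
        else:
            x = point.ppi_total
        mu = _true_rate(x, params)
        sd = config.cv * mu + config.sd_floor
        for rep in range(config.n_replicates):
            rng = np.random.default_rng((config.seed, point.index, rep))
            rate = rng.normal(mu, sd) if sd > 0 else mu
            tries = 0
            while rate < 0:
                rate = rng.normal(mu, sd)
                tries += 1
                if tries > 1000:
                    raise RuntimeError(
                        "noise model keeps producing negative rates; "
                        "check cv/sd_floor against the true rate"
                    )
            rows.append(
                {
                    "enzyme": enzyme,
                    "mode": design.mode,
                    "nacl_mM": point.nacl,
                    "kcl_mM": design.kcl,
                    "mgcl2_mM": (
                        design.fixed_mgcl2 if design.mode == "fixed_mg" else np.nan
                    ),
                    "ppi_total_mM": point.ppi_total,
                    "ph": design.ph,
                    "replicate_id": rep + 1,
                    "rate_U_per_mg": float(rate),
                }
            )
    return pd.DataFrame(rows)
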