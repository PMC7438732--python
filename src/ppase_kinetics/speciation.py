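"""Equilibrium speciation of pyrophosphate among H+, Mg2+, K+ and Na+ complexes.

Membrane-bound pyrophosphatases hydrolyse the magnesium-pyrophosphate complex
Mg2PPi, not free pyrophosphate.  Assay mixtures contain total PPi (added as the
tetrasodium salt), MgCl2, KCl and NaCl at a buffered pH, so the substrate
concentration S = [Mg2PPi] must be computed from the totals and the stepwise
dissociation constants of the individual PPi complexes.

The model solved here:

* free ligand reference species is fully deprotonated PPi(4-);
* protonation (HPPi, H2PPi), monovalent pairing (KPPi, NaPPi) and magnesium
  complexation (MgPPi, Mg2PPi, optionally MgHPPi) are stepwise equilibria,
  each defined by a dissociation constant Kd = [M][L]/[ML] in mM;
* pH is buffered, so [H+] is an input, never a solved variable;
* K+ and Na+ are in large excess over PPi (>= 100x in the assays modelled),
  so their free concentrations are taken equal to their totals;
* constants are conditional constants at assay ionic strength (no
  activity-coefficient correction).

Only two unknowns remain: free PPi and free Mg2+.  For a fixed free Mg2+
every PPi-containing species is linear in free PPi, so the PPi mass balance
has a closed-form solution and the Mg mass balance reduces to a monotone
one-dimensional root-find, solved with Brent's method.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "IonicConditions",
    "ComplexationConstants",
    "SpeciationState",
    "SpeciationError",
    "speciate",
    "substrate_grid",
    "pka_to_kd_mM",
]

#: Species names understood by the solver.
KNOWN_SPECIES = ("HPPi", "H2PPi", "MgPPi", "Mg2PPi", "KPPi", "NaPPi", "MgHPPi")

#: Stepwise species whose parent complex must also be present.
_PARENT = {"H2PPi": "HPPi", "Mg2PPi": "MgPPi", "MgHPPi": "HPPi"}


class SpeciationError(RuntimeError):
    """Raised when the equilibrium solver fails to converge."""


def pka_to_kd_mM(pka: float) -> float:
    """Convert a pKa (molar scale) to a dissociation constant in mM.

    Kd[M] = 10**(-pKa), hence Kd[mM] = 10**(3 - pKa).
    """
    return 10.0 ** (3.0 - float(pka))


@dataclass(frozen=True)
class IonicConditions:
    """Total (analytical) concentrations and pH for one assay point.

    All concentrations in mM.  ``total_na`` must already include the basal
    sodium contributed by the tetrasodium pyrophosphate salt (4 x total PPi);
    the design builders in :mod:`ppase_kinetics.synthetic` apply that rule.
    """

    total_ppi: float
    total_mg: float
    total_k: float
    total_na: float
    ph: float

    def __post_init__(self) -> None:
        for name in ("total_ppi", "total_mg", "total_k", "total_na"):
            value = getattr(self, name)
            if not np.isfinite(value) or value < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {value!r}")
        if not (2.0 <= self.ph <= 12.0):
            raise ValueError(f"ph must lie in [2, 12], got {self.ph!r}")

    @property
    def h_free(self) -> float:
        """Free proton concentration in mM (buffered)."""
        return 10.0 ** (3.0 - self.ph)


@dataclass(frozen=True)
class ComplexationConstants:
    """Stepwise dissociation constants (mM) for the PPi complexes.

    A species absent from the mapping is excluded from the model.  MgPPi and
    Mg2PPi are required whenever the substrate concentration is requested.
    """

    kd: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for species, value in self.kd.items():
            if species not in KNOWN_SPECIES:
                raise ValueError(
                    f"unknown species {species!r}; expected one of {KNOWN_SPECIES}"
                )
            if not np.isfinite(value) or value <= 0:
                raise ValueError(f"Kd for {species} must be > 0, got {value!r}")
        for species, parent in _PARENT.items():
            if species in self.kd and parent not in self.kd:
                raise ValueError(f"{species} requires its parent species {parent}")

    def __contains__(self, species: str) -> bool:
        return species in self.kd

    def __getitem__(self, species: str) -> float:
        return float(self.kd[species])

    def require_substrate(self) -> None:
        missing = [s for s in ("MgPPi", "Mg2PPi") if s not in self.kd]
        if missing:
            raise ValueError(
                "substrate computation requires MgPPi and Mg2PPi constants; "
                f"missing {missing}"
            )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ComplexationConstants":
        """Build from a table with columns ``species`` and ``kd_mM`` or ``pka``."""
        if "species" not in frame.columns:
            raise ValueError("constants table needs a 'species' column")
        kd: dict[str, float] = {}
        for _, row in frame.iterrows():
            species = str(row["species"]).strip()
            value = row.get("kd_mM")
            if value is None or (isinstance(value, float) and np.isnan(value)):
                pka = row.get("pka")
                if pka is None or (isinstance(pka, float) and np.isnan(pka)):
                    raise ValueError(f"species {species}: give kd_mM or pka")
                value = pka_to_kd_mM(float(pka))
            kd[species] = float(value)
        return cls(kd=kd)

    @classmethod
    def from_table(cls, path: str | Path) -> "ComplexationConstants":
        return cls.from_frame(pd.read_csv(path, sep="\t", comment="#"))

    @classmethod
    def default(cls) -> "ComplexationConstants":
        """Default constants shipped with the package (see data/ppi_constants.tsv).

        These are conditional constants at typical assay ionic strength taken
        from a standard PPi-complexation compilation; override them with
        :meth:`from_table` when assay-specific values are available.
        """
        ref = resources.files("ppase_kinetics.data").joinpath("ppi_constants.tsv")
        with resources.as_file(ref) as path:
            return cls.from_table(path)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"species": list(self.kd), "kd_mM": [self.kd[s] for s in self.kd]}
        )


@dataclass(frozen=True)
class SpeciationState:
    """Solved equilibrium state for one assay point (all concentrations mM)."""

    free_ppi: float
    free_mg: float
    complexes: Mapping[str, float]
    conditions: IonicConditions

    @property
    def substrate(self) -> float:
        """S = [Mg2PPi], the substrate of the membrane pyrophosphatases."""
        return float(self.complexes.get("Mg2PPi", 0.0))

    @property
    def total_ppi_recovered(self) -> float:
        bound = sum(v for k, v in self.complexes.items())
        return self.free_ppi + bound

    @property
    def total_mg_recovered(self) -> float:
        bound = (
            self.complexes.get("MgPPi", 0.0)
            + 2.0 * self.complexes.get("Mg2PPi", 0.0)
            + self.complexes.get("MgHPPi", 0.0)
        )
        return self.free_mg + bound


def _ppi_side_factors(
    cond: IonicConditions, constants: ComplexationConstants, free_mg: float
) -> dict[str, float]:
    """Concentration of each complex per unit free PPi(4-), at fixed free Mg."""
    h = cond.h_free
    f: dict[str, float] = {}
    if "HPPi" in constants:
        f["HPPi"] = h / constants["HPPi"]
        if "H2PPi" in constants:
            f["H2PPi"] = f["HPPi"] * h / constants["H2PPi"]
        if "MgHPPi" in constants:
            f["MgHPPi"] = f["HPPi"] * free_mg / constants["MgHPPi"]
    if "KPPi" in constants:
        f["KPPi"] = cond.total_k / constants["KPPi"]
    if "NaPPi" in constants:
        f["NaPPi"] = cond.total_na / constants["NaPPi"]
    if "MgPPi" in constants:
        f["MgPPi"] = free_mg / constants["MgPPi"]
        if "Mg2PPi" in constants:
            f["Mg2PPi"] = f["MgPPi"] * free_mg / constants["Mg2PPi"]
    return f


def _solve_at_mg(
    cond: IonicConditions, constants: ComplexationConstants, free_mg: float
) -> tuple[float, dict[str, float]]:
    """Closed-form free PPi and complex concentrations at fixed free Mg."""
    factors = _ppi_side_factors(cond, constants, free_mg)
    alpha = 1.0 + sum(factors.values())
    free_ppi = cond.total_ppi / alpha
    complexes = {name: fac * free_ppi for name, fac in factors.items()}
    return free_ppi, complexes


def _mg_bound(complexes: Mapping[str, float]) -> float:
    return (
        complexes.get("MgPPi", 0.0)
        + 2.0 * complexes.get("Mg2PPi", 0.0)
        + complexes.get("MgHPPi", 0.0)
    )


def speciate(
    cond: IonicConditions,
    constants: ComplexationConstants,
    tol: float = 1e-10,
    max_iter: int = 200,
) -> SpeciationState:
    """Solve the two-variable equilibrium system for one assay point.

    Parameters
    ----------
    cond
        Total concentrations and pH.
    constants
        Stepwise dissociation constants; absent species are excluded.
    tol
        Relative tolerance on both mass balances.
    max_iter
        Iteration budget for the bracketing root-find on free Mg.

    Returns
    -------
    SpeciationState
        Free PPi, free Mg and every included complex, satisfying both mass
        balances to ``tol``; the mass-action relations hold by construction.

    Notes
    -----
    The system is monotone in (free PPi, free Mg): for fixed free Mg the PPi
    balance is linear in free PPi and solved exactly; the residual of the Mg
    balance is then continuous on [0, total_mg] with a sign change, and its
    root is unique, so Brent's method converges unconditionally.
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")

    mg_complexed = any(s in constants for s in ("MgPPi", "MgHPPi"))
    if cond.total_mg == 0.0 or cond.total_ppi == 0.0 or not mg_complexed:
        free_mg = cond.total_mg
        free_ppi, complexes = _solve_at_mg(cond, constants, free_mg)
        return SpeciationState(free_ppi, free_mg, complexes, cond)

    def residual(free_mg: float) -> float:
        _, complexes = _solve_at_mg(cond, constants, free_mg)
        return free_mg + _mg_bound(complexes) - cond.total_mg

    lo, hi = 0.0, cond.total_mg
    # residual(0) = -total_mg < 0 and residual(total_mg) >= 0, so the root is
    # bracketed; xtol is absolute, rtol handles the scale of total_mg.
    try:
        free_mg = brentq(
            residual,
            lo,
            hi,
            xtol=tol * max(cond.total_mg, 1e-12),
            rtol=max(tol, 4.0 * np.finfo(float).eps),
            maxiter=max_iter,
        )
    except Exception as exc:  # pragma: no cover - brentq is robust on brackets
        raise SpeciationError(
            f"speciation did not converge within {max_iter} iterations for "
            f"conditions {cond!r}"
        ) from exc

    free_ppi, complexes = _solve_at_mg(cond, constants, free_mg)
    state = SpeciationState(free_ppi, free_mg, complexes, cond)

    scale_ppi = max(cond.total_ppi, 1e-12)
    scale_mg = max(cond.total_mg, 1e-12)
    if abs(state.total_ppi_recovered - cond.total_ppi) > 100 * tol * scale_ppi or abs(
        state.total_mg_recovered - cond.total_mg
    ) > 100 * tol * scale_mg:
        raise SpeciationError(
            f"mass balance violated beyond tolerance for conditions {cond!r}"
        )
    return state


def substrate_grid(
    design, constants: ComplexationConstants, tol: float = 1e-10
) -> list[tuple[IonicConditions, float]]:
    """Vectorise :func:`speciate` over a design, returning (condition, S) pairs.

    ``design`` may be an :class:`~ppase_kinetics.synthetic.AssayDesign` (its
    expanded conditions are used) or any iterable of :class:`IonicConditions`.
    Order is preserved; one substrate value is returned per design point.
    """
    conditions: Sequence[IonicConditions]
    if hasattr(design, "conditions"):
        conditions = list(design.conditions())
    else:
        conditions = list(design)
    if not conditions:
        raise ValueError("design is empty: no conditions to speciate")
    constants.require_substrate()
    out: list[tuple[IonicConditions, float]] = []
    for cond in conditions:
        state = speciate(cond, constants, tol=tol)
        out.append((cond, state.substrate))
    return out
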