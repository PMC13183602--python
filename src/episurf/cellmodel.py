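"""Reduced steady-state model of a renal epithelial cell.

Two variants are provided: a proximal convoluted tubule (PCT) cell with five
solutes (Na+, K+, Cl-, HCO3-, glucose) and osmotic water transport, and a
medullary thick ascending limb (mTAL) cell with three solutes (Na+, K+, Cl-)
and a water-impermeable membrane.  The cell sits between two compartments of
prescribed composition -- the tubular lumen and the interstitium -- and
exchanges solutes across its apical and basolateral membranes; a paracellular
shunt connects lumen and interstitium directly.  Protons are clamped (fixed
pH) in every compartment, which collapses the acid-base system onto a single
HCO3- balance.

Unknowns are the cytosolic concentrations, the cell volume (PCT only, the
mTAL cell has fixed volume), and the two electrical potentials V_cell and
V_lumen (interstitium grounded at 0 mV).  The governing system couples one
mass balance per solute, a water balance (PCT), cytosolic electroneutrality,
and an open-circuit condition (zero net transepithelial current).  It is
solved by a damped Newton iteration on log-transformed concentrations/volume;
an independent pseudo-transient relaxation integrator is provided as a
test-time oracle.

Units
-----
concentrations   mM
potentials       mV (relative to the interstitium)
permeabilities   cm/s
solute fluxes    mM*cm/s  (= 1e-3 mmol s^-1 cm^-2; positive reabsorptive:
                 lumen->cell, cell->interstitium, lumen->interstitium)
water fluxes     cm/s
volume           cm^3 per cm^2 of epithelium
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "PhysicalConstants",
    "CONSTANTS",
    "SoluteSpec",
    "CompartmentComposition",
    "MembraneSide",
    "MembraneProperties",
    "TransporterActivities",
    "CellGeometry",
    "ModelVariant",
    "SteadyState",
    "FluxRecord",
    "DomainError",
    "ConfigurationError",
    "ConvergenceError",
    "nernst_potential",
    "ghk_flux",
    "nak_pump_flux",
    "nhe3_flux",
    "cotransport_flux",
    "water_flux",
    "residuals",
    "solve_steady_state",
    "relax_to_steady_state",
    "transcellular_fluxes",
    "load_variant",
    "apply_parameter_fractions",
    "cold_start_state",
]


# --------------------------------------------------------------------------
# Errors
# --------------------------------------------------------------------------

class DomainError(ValueError):
    """Input outside the mathematical domain of a flux law."""


class ConfigurationError(ValueError):
    """Inconsistent or incomplete model configuration."""


class ConvergenceError(RuntimeError):
    """Newton or relaxation failed to converge.

    Carries the last iterate so callers can inspect or warm-start from it.
    """

    def __init__(self, message, last_state=None, residual_norm=None,
                 iterations=None):
        super().__init__(message)
        self.last_state = last_state
        self.residual_norm = residual_norm
        self.iterations = iterations


# --------------------------------------------------------------------------
# Constants and domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PhysicalConstants:
    """F in C/mmol, R in mJ/(mmol K), T in K, Vw in cm^3/mmol."""

    F: float = 96.485
    R: float = 8.314
    T: float = 310.0
    Vw: float = 0.018

    def __post_init__(self):
        if min(self.F, self.R, self.T, self.Vw) <= 0:
            raise ConfigurationError("physical constants must be positive")

    @property
    def RT(self) -> float:
        return self.R * self.T

    @property
    def RT_over_F(self) -> float:
        """Thermal voltage in mV (~26.7 mV at 310 K)."""
        return self.R * self.T / self.F


CONSTANTS = PhysicalConstants()


@dataclass(frozen=True)
class SoluteSpec:
    name: str
    z: int
    osmotic_coefficient: float = 1.0


@dataclass(frozen=True)
class CompartmentComposition:
    """Composition of one fluid compartment.

    ``impermeant_anions`` are fixed monovalent anions (mM) completing
    electroneutrality of a prescribed compartment; ``impermeant_osmolytes``
    is the osmolarity (mOsm) of additional uncharged, non-transported
    species.  Both contribute to osmolarity; only the anions carry charge.
    """

    concentrations: Mapping[str, float]
    H_concentration: float
    potential: float = 0.0
    impermeant_anions: float = 0.0
    impermeant_osmolytes: float = 0.0

    def __post_init__(self):
        for name, c in self.concentrations.items():
            if not c > 0:
                raise ConfigurationError(f"non-positive concentration for {name}")
        if not self.H_concentration > 0:
            raise ConfigurationError("H_concentration must be positive")

    def osmolarity(self, solutes: Sequence[SoluteSpec]) -> float:
        osm = sum(s.osmotic_coefficient * self.concentrations[s.name]
                  for s in solutes)
        return osm + self.impermeant_anions + self.impermeant_osmolytes

    def charge(self, solutes: Sequence[SoluteSpec]) -> float:
        q = sum(s.z * self.concentrations[s.name] for s in solutes)
        return q - self.impermeant_anions


@dataclass(frozen=True)
class MembraneSide:
    permeabilities: Mapping[str, float]
    Pf: float = 0.0

    def __post_init__(self):
        if any(p < 0 for p in self.permeabilities.values()) or self.Pf < 0:
            raise ConfigurationError("permeabilities must be non-negative")


@dataclass(frozen=True)
class MembraneProperties:
    apical: MembraneSide
    basolateral: MembraneSide
    paracellular: MembraneSide

    def __post_init__(self):
        if self.paracellular.Pf != 0.0:
            raise ConfigurationError("paracellular water permeability must be 0")


@dataclass(frozen=True)
class TransporterActivities:
    """Activity coefficients of the represented transporters.

    ``x_*`` are linear activities (flux per unit driving force, except NHE3
    whose mass-action form is dimensionless in the concentration ratios);
    pump parameters are the Na+/K+-ATPase maximal cycle rate and its
    half-saturation constants.  Activities that do not exist in a variant
    (e.g. NKCC2 in the PCT) are exactly zero.
    """

    x_NHE3: float = 0.0
    x_SGLT2: float = 0.0
    x_NBCe1: float = 0.0
    x_NKCC2: float = 0.0
    pump_Jmax: float = 0.0
    pump_K_Na: float = 15.0
    pump_K_K: float = 2.5

    def __post_init__(self):
        for f in ("x_NHE3", "x_SGLT2", "x_NBCe1", "x_NKCC2",
                  "pump_Jmax", "pump_K_Na", "pump_K_K"):
            if getattr(self, f) < 0:
                raise ConfigurationError(f"{f} must be non-negative")


@dataclass(frozen=True)
class CellGeometry:
    volume: float                 # cm^3 per cm^2 epithelium
    impermeant_amount: float      # mmol-scale amount per cm^2 (mM*cm units)
    impermeant_valence: int = -1

    def __post_init__(self):
        if not self.volume > 0 or not self.impermeant_amount > 0:
            raise ConfigurationError("volume and impermeant_amount must be positive")
        if self.impermeant_valence >= 0:
            raise ConfigurationError("impermeant_valence must be negative")


@dataclass(frozen=True)
class ModelVariant:
    """Full parameterization of one cell type x sex."""

    cell_type: str                      # "pct" | "mtal"
    sex: str                            # "male" | "female"
    solutes: tuple[SoluteSpec, ...]
    lumen: CompartmentComposition
    interstitium: CompartmentComposition
    membranes: MembraneProperties
    baseline_activities: TransporterActivities
    geometry: CellGeometry
    water_permeable: bool
    cytosol_H: float = 6.31e-5          # clamped cytosolic [H+] (mM), pH 7.2
    varied_parameters: tuple[str, ...] = ()
    sex_factors: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        names = [s.name for s in self.solutes]
        if len(set(names)) != len(names):
            raise ConfigurationError("solute names must be unique")
        expected = {"pct": {"Na", "K", "Cl", "HCO3", "glucose"},
                    "mtal": {"Na", "K", "Cl"}}
        if self.cell_type not in expected:
            raise ConfigurationError(f"unknown cell_type {self.cell_type!r}")
        if set(names) != expected[self.cell_type]:
            raise ConfigurationError(
                f"{self.cell_type} requires solutes {sorted(expected[self.cell_type])}")
        for comp, label in ((self.lumen, "lumen"),
                            (self.interstitium, "interstitium")):
            q = comp.charge(self.solutes)
            if abs(q) > 1e-9:
                raise ConfigurationError(
                    f"{label} composition not electroneutral (charge {q:.3e} mM)")

    @property
    def name(self) -> str:
        return f"{self.cell_type}_{self.sex}"


@dataclass(frozen=True)
class FluxRecord:
    """Per-solute membrane fluxes at a (converged) state.

    All solute fluxes in mM*cm/s, positive reabsorptive; water fluxes in
    cm/s.  ``sources`` holds intracellular production rates (the PCT HCO3-
    source from NHE3-coupled CO2 hydration).  At steady state the
    basolateral flux equals the transcellular flux.
    """

    apical: Mapping[str, float]
    basolateral: Mapping[str, float]
    paracellular: Mapping[str, float]
    sources: Mapping[str, float]
    Jv_apical: float
    Jv_basolateral: float

    def transcellular(self, solute: str) -> float:
        return self.basolateral[solute]


@dataclass(frozen=True)
class SteadyState:
    cytosol: CompartmentComposition
    volume: float
    V_cell: float
    V_lumen: float
    fluxes: FluxRecord | None = None
    converged: bool = False
    iterations: int = 0
    residual_norm: float = math.inf

    @property
    def Va(self) -> float:
        """Apical membrane potential, cell minus lumen (mV)."""
        return self.V_cell - self.V_lumen

    @property
    def Vb(self) -> float:
        """Basolateral membrane potential, cell minus interstitium (mV)."""
        return self.V_cell


# --------------------------------------------------------------------------
# Flux laws
# --------------------------------------------------------------------------

def nernst_potential(z: int, C_in: float, C_out: float,
                     constants: PhysicalConstants = CONSTANTS) -> float:
    """Equilibrium potential (RT/zF) ln(C_out/C_in), in mV."""
    if z == 0:
        raise DomainError("Nernst potential undefined for uncharged solute")
    if C_in <= 0 or C_out <= 0:
        raise DomainError("concentrations must be positive")
    return constants.RT_over_F / z * math.log(C_out / C_in)


def ghk_flux(P: float, z: int, V: float, C_i: float, C_e: float,
             constants: PhysicalConstants = CONSTANTS) -> float:
    """Goldman-Hodgkin-Katz constant-field flux, positive side i -> side e.

    ``V`` is the potential of side i minus side e (mV).  For z = 0 the law
    reduces to Fick diffusion; near zero field the regular series limit is
    used so the flux is continuous and smooth across V = 0.
    """
    if P < 0:
        raise DomainError("permeability must be non-negative")
    if C_i <= 0 or C_e <= 0:
        raise DomainError("concentrations must be positive")
    if z == 0:
        return P * (C_i - C_e)
    xi = z * V / constants.RT_over_F
    if abs(xi) < 1e-6:
        return P * (C_i - C_e) + P * xi * (C_i + C_e) / 2.0
    emx = math.exp(-xi)
    return P * xi * (C_i - C_e * emx) / (1.0 - emx)


def nak_pump_flux(act: TransporterActivities, C_Na_cell: float,
                  C_K_ext: float) -> tuple[float, float]:
    """Na+/K+-ATPase fluxes (J_Na_out, J_K_in) with 3:2 stoichiometry.

    Cycle rate follows cubic/squared Michaelis-Menten saturation in
    cytosolic Na+ and external (interstitial) K+.
    """
    if C_Na_cell < 0 or C_K_ext < 0:
        raise DomainError("concentrations must be non-negative")
    fna = C_Na_cell / (C_Na_cell + act.pump_K_Na)
    fk = C_K_ext / (C_K_ext + act.pump_K_K)
    r = act.pump_Jmax * fna ** 3 * fk ** 2
    return 3.0 * r, 2.0 * r


def nhe3_flux(x: float, C_Na_L: float, C_Na_C: float,
              C_H_L: float, C_H_C: float) -> float:
    """Electroneutral 1:1 Na+/H+ exchange (NHE3), symmetric mass-action.

    Positive flux moves Na+ lumen->cell and H+ cell->lumen; it vanishes at
    exchange equilibrium C_Na_L/C_Na_C = C_H_L/C_H_C.
    """
    if min(C_Na_L, C_Na_C, C_H_L, C_H_C) <= 0:
        raise DomainError("concentrations must be positive")
    num = C_Na_L * C_H_C - C_Na_C * C_H_L
    den = (C_Na_L + C_Na_C) * (C_H_L + C_H_C)
    return x * num / den


def cotransport_flux(x: float, stoichiometry: Mapping[str, int],
                     side_i: CompartmentComposition,
                     side_e: CompartmentComposition,
                     z_net: int, V: float,
                     constants: PhysicalConstants = CONSTANTS) -> float:
    """Linear nonequilibrium-thermodynamic cotransporter cycle flux.

    J = x * Delta_mu with Delta_mu = sum_k s_k RT ln(C_k,i/C_k,e)
    + z_net F (V_i - V_e); ``V`` is V_i - V_e in mV.  Returns the cycle
    flux, positive i -> e; per-solute fluxes are s_k * J.
    """
    dmu = 0.0
    for name, s in stoichiometry.items():
        try:
            ci = side_i.concentrations[name]
            ce = side_e.concentrations[name]
        except KeyError:
            raise ConfigurationError(
                f"cotransported solute {name!r} missing from a compartment")
        if ci <= 0 or ce <= 0:
            raise DomainError("concentrations must be positive")
        dmu += s * constants.RT * math.log(ci / ce)
    dmu += z_net * constants.F * V
    return x * dmu


def water_flux(Pf: float, osm_i: float, osm_e: float,
               constants: PhysicalConstants = CONSTANTS) -> float:
    """Osmotic volume flux Pf*Vw*(osm_e - osm_i), positive i -> e."""
    if Pf < 0:
        raise DomainError("water permeability must be non-negative")
    return Pf * constants.Vw * (osm_e - osm_i)


# --------------------------------------------------------------------------
# Compiled evaluation context (fast scalar inner loop)
# --------------------------------------------------------------------------

class _Context:
    """Plain-float view of a variant used by the inner numerical loops."""

    __slots__ = ("variant", "names", "z", "idx", "n_sol", "CL", "CI",
                 "osmL", "osmI", "PA", "PB", "PP", "PfA", "PfB",
                 "act", "N_imp", "z_imp", "vol0", "water", "HL", "HC",
                 "ref_flux", "constants", "has_sglt2", "has_nhe3",
                 "has_nbce1", "has_nkcc2")

    def __init__(self, variant: ModelVariant,
                 activities: TransporterActivities,
                 membranes: MembraneProperties,
                 constants: PhysicalConstants = CONSTANTS):
        self.variant = variant
        self.constants = constants
        sols = variant.solutes
        self.names = [s.name for s in sols]
        self.z = [s.z for s in sols]
        self.idx = {s.name: k for k, s in enumerate(sols)}
        self.n_sol = len(sols)
        self.CL = [variant.lumen.concentrations[n] for n in self.names]
        self.CI = [variant.interstitium.concentrations[n] for n in self.names]
        self.osmL = variant.lumen.osmolarity(sols)
        self.osmI = variant.interstitium.osmolarity(sols)

        def pvec(side: MembraneSide):
            return [side.permeabilities.get(n, 0.0) for n in self.names]

        self.PA = pvec(membranes.apical)
        self.PB = pvec(membranes.basolateral)
        self.PP = pvec(membranes.paracellular)
        self.PfA = membranes.apical.Pf
        self.PfB = membranes.basolateral.Pf
        self.act = activities
        self.N_imp = variant.geometry.impermeant_amount
        self.z_imp = variant.geometry.impermeant_valence
        self.vol0 = variant.geometry.volume
        self.water = variant.water_permeable
        self.HL = variant.lumen.H_concentration
        self.HC = variant.cytosol_H
        # reference flux for residual scaling: baseline pump throughput
        self.ref_flux = 3.0 * variant.baseline_activities.pump_Jmax
        if self.ref_flux <= 0:
            raise ConfigurationError("baseline pump_Jmax must be positive")
        self.has_nhe3 = activities.x_NHE3 > 0 or variant.cell_type == "pct"
        self.has_sglt2 = activities.x_SGLT2 > 0
        self.has_nbce1 = activities.x_NBCe1 > 0
        self.has_nkcc2 = activities.x_NKCC2 > 0

    @property
    def n_unknowns(self) -> int:
        return self.n_sol + (1 if self.water else 0) + 2


def _ghk_raw(P, z, V, C_i, C_e, rt_over_f):
    # inner-loop GHK without domain checks (caller guarantees positivity)
    if P == 0.0:
        return 0.0
    if z == 0:
        return P * (C_i - C_e)
    xi = z * V / rt_over_f
    if abs(xi) < 1e-6:
        return P * (C_i - C_e) + P * xi * (C_i + C_e) / 2.0
    emx = math.exp(-xi)
    return P * xi * (C_i - C_e * emx) / (1.0 - emx)


def _all_fluxes(ctx: _Context, C, vol, V_C, V_L):
    """Return (J_ap, J_bl, J_pc, src, Jv_a, Jv_b) lists aligned with solutes."""
    k = ctx.constants
    rtf = k.RT_over_F
    RT = k.RT
    F = k.F
    n = ctx.n_sol
    J_ap = [0.0] * n
    J_bl = [0.0] * n
    J_pc = [0.0] * n
    src = [0.0] * n
    Vac = V_L - V_C      # apical: side i = lumen, side e = cell
    for j in range(n):
        zj = ctx.z[j]
        J_ap[j] = _ghk_raw(ctx.PA[j], zj, Vac, ctx.CL[j], C[j], rtf)
        J_bl[j] = _ghk_raw(ctx.PB[j], zj, V_C, C[j], ctx.CI[j], rtf)
        J_pc[j] = _ghk_raw(ctx.PP[j], zj, V_L, ctx.CL[j], ctx.CI[j], rtf)

    act = ctx.act
    iNa = ctx.idx["Na"]
    iK = ctx.idx["K"]

    # Na+/K+-ATPase (basolateral; external K+ = interstitial K+)
    fna = C[iNa] / (C[iNa] + act.pump_K_Na)
    fk = ctx.CI[iK] / (ctx.CI[iK] + act.pump_K_K)
    r = act.pump_Jmax * fna ** 3 * fk ** 2
    J_bl[iNa] += 3.0 * r
    J_bl[iK] -= 2.0 * r

    if act.x_NHE3 > 0.0:
        jn = act.x_NHE3 * (ctx.CL[iNa] * ctx.HC - C[iNa] * ctx.HL) / (
            (ctx.CL[iNa] + C[iNa]) * (ctx.HL + ctx.HC))
        J_ap[iNa] += jn
        # clamped-pH closure: each secreted H+ leaves behind one HCO3-
        iB = ctx.idx["HCO3"]
        src[iB] += jn

    if act.x_SGLT2 > 0.0:
        iG = ctx.idx["glucose"]
        dmu = RT * (math.log(ctx.CL[iNa] / C[iNa])
                    + math.log(ctx.CL[iG] / C[iG])) + F * Vac
        js = act.x_SGLT2 * dmu
        J_ap[iNa] += js
        J_ap[iG] += js

    if act.x_NBCe1 > 0.0:
        iB = ctx.idx["HCO3"]
        dmu = RT * (math.log(C[iNa] / ctx.CI[iNa])
                    + 3.0 * math.log(C[iB] / ctx.CI[iB])) - 2.0 * F * V_C
        jb = act.x_NBCe1 * dmu
        J_bl[iNa] += jb
        J_bl[iB] += 3.0 * jb

    if act.x_NKCC2 > 0.0:
        iCl = ctx.idx["Cl"]
        dmu = RT * (math.log(ctx.CL[iNa] / C[iNa])
                    + math.log(ctx.CL[iK] / C[iK])
                    + 2.0 * math.log(ctx.CL[iCl] / C[iCl]))
        jk = act.x_NKCC2 * dmu
        J_ap[iNa] += jk
        J_ap[iK] += jk
        J_ap[iCl] += 2.0 * jk

    if ctx.water:
        osmC = sum(C) + ctx.N_imp / vol
        Jv_a = ctx.PfA * k.Vw * (osmC - ctx.osmL)
        Jv_b = ctx.PfB * k.Vw * (ctx.osmI - osmC)
    else:
        Jv_a = Jv_b = 0.0
    return J_ap, J_bl, J_pc, src, Jv_a, Jv_b


def _scaled_residual(ctx: _Context, C, vol, V_C, V_L):
    """Scaled residual vector: mass balances, [water], charge, current."""
    J_ap, J_bl, J_pc, src, Jv_a, Jv_b = _all_fluxes(ctx, C, vol, V_C, V_L)
    k = ctx.constants
    rf = ctx.ref_flux
    res = []
    for j in range(ctx.n_sol):
        res.append((J_ap[j] + src[j] - J_bl[j]) / rf)
    if ctx.water:
        res.append((Jv_a - Jv_b) / (k.Vw * rf))
    charge = sum(ctx.z[j] * C[j] for j in range(ctx.n_sol))
    charge += ctx.z_imp * ctx.N_imp / vol
    res.append(charge / 1.0)
    current = sum(ctx.z[j] * (J_bl[j] + J_pc[j]) for j in range(ctx.n_sol))
    res.append(current * k.F / (k.F * rf))
    return res


def _unpack(ctx: _Context, u):
    C = [math.exp(v) for v in u[:ctx.n_sol]]
    if ctx.water:
        vol = math.exp(u[ctx.n_sol])
        V_C, V_L = u[ctx.n_sol + 1], u[ctx.n_sol + 2]
    else:
        vol = ctx.vol0
        V_C, V_L = u[ctx.n_sol], u[ctx.n_sol + 1]
    return C, vol, V_C, V_L


def _pack(ctx: _Context, C, vol, V_C, V_L):
    u = [math.log(c) for c in C]
    if ctx.water:
        u.append(math.log(vol))
    u.extend([V_C, V_L])
    return np.asarray(u, dtype=float)


def _residual_u(ctx: _Context, u):
    C, vol, V_C, V_L = _unpack(ctx, u)
    return np.asarray(_scaled_residual(ctx, C, vol, V_C, V_L), dtype=float)


def _state_from_u(ctx: _Context, u, iterations, residual_norm, converged):
    C, vol, V_C, V_L = _unpack(ctx, u)
    J_ap, J_bl, J_pc, src, Jv_a, Jv_b = _all_fluxes(ctx, C, vol, V_C, V_L)
    names = ctx.names
    fluxes = FluxRecord(
        apical=dict(zip(names, J_ap)),
        basolateral=dict(zip(names, J_bl)),
        paracellular=dict(zip(names, J_pc)),
        sources=dict(zip(names, src)),
        Jv_apical=Jv_a,
        Jv_basolateral=Jv_b,
    )
    cytosol = CompartmentComposition(
        concentrations=dict(zip(names, C)),
        H_concentration=ctx.HC,
        potential=V_C,
        impermeant_anions=0.0,
        impermeant_osmolytes=ctx.N_imp / vol,
    )
    return SteadyState(cytosol=cytosol, volume=vol, V_cell=V_C, V_lumen=V_L,
                       fluxes=fluxes, converged=converged,
                       iterations=iterations, residual_norm=residual_norm)


# --------------------------------------------------------------------------
# Public residual / solver API
# --------------------------------------------------------------------------

def _make_context(variant, activities=None, membranes=None):
    act = activities if activities is not None else variant.baseline_activities
    mem = membranes if membranes is not None else variant.membranes
    return _Context(variant, act, mem)


def residuals(variant: ModelVariant,
              activities: TransporterActivities | None = None,
              membranes: MembraneProperties | None = None,
              state: SteadyState | None = None) -> np.ndarray:
    """Scaled residual vector of the governing system at ``state``.

    Order: one mass balance per solute (apical + source - basolateral,
    divided by the baseline pump throughput 3*Jmax), the water balance for
    water-permeable variants (divided by Vw*3*Jmax), cytosolic
    electroneutrality (mM), and the open-circuit condition (total
    transepithelial current over F*3*Jmax).
    """
    if state is None:
        raise ValueError("state is required")
    ctx = _make_context(variant, activities, membranes)
    C = [state.cytosol.concentrations[n] for n in ctx.names]
    res = _scaled_residual(ctx, C, state.volume, state.V_cell, state.V_lumen)
    arr = np.asarray(res, dtype=float)
    if not np.all(np.isfinite(arr)):
        bad = [k for k, v in enumerate(arr) if not math.isfinite(v)]
        raise ConvergenceError(f"non-finite residual components {bad}",
                               residual_norm=math.inf)
    return arr


def cold_start_state(variant: ModelVariant) -> SteadyState:
    """Shipped cold-start guess: interstitial composition with Na/K moved
    to typical cytosolic values, Cl- adjusted for electroneutrality,
    V_cell = -70 mV, V_lumen = -1 mV."""
    conc = dict(variant.interstitium.concentrations)
    conc["Na"] = 15.0
    conc["K"] = 130.0
    geo = variant.geometry
    c_imp = geo.impermeant_amount / geo.volume
    other = sum(s.z * conc[s.name] for s in variant.solutes if s.name != "Cl")
    conc["Cl"] = max(1.0, other + geo.impermeant_valence * c_imp)
    cytosol = CompartmentComposition(
        concentrations=conc, H_concentration=variant.cytosol_H,
        potential=-70.0, impermeant_osmolytes=c_imp)
    return SteadyState(cytosol=cytosol, volume=geo.volume,
                       V_cell=-70.0, V_lumen=-1.0)


def solve_steady_state(variant: ModelVariant,
                       activities: TransporterActivities | None = None,
                       membranes: MembraneProperties | None = None,
                       initial_guess: SteadyState | None = None,
                       tol: float = 1e-10,
                       max_iter: int = 50) -> SteadyState:
    """Damped Newton solve of the steady-state system.

    Unknowns are log-concentrations (and log-volume for water-permeable
    variants) plus the raw potentials; the Jacobian is assembled by forward
    finite differences and steps are backtracked (up to 20 halvings) when
    the scaled residual norm would increase.  Raises :class:`ConvergenceError`
    carrying the last iterate on failure.
    """
    ctx = _make_context(variant, activities, membranes)
    guess = initial_guess if initial_guess is not None else cold_start_state(variant)
    C = [guess.cytosol.concentrations[n] for n in ctx.names]
    u = _pack(ctx, C, guess.volume, guess.V_cell, guess.V_lumen)

    F = _residual_u(ctx, u)
    nrm = float(np.max(np.abs(F)))
    it = 0
    n = ctx.n_unknowns
    while nrm >= tol and it < max_iter:
        # forward-difference Jacobian, relative step 1e-7
        J = np.empty((n, n))
        for j in range(n):
            h = 1e-7 * max(abs(u[j]), 1.0)
            up = u.copy()
            up[j] += h
            J[:, j] = (_residual_u(ctx, up) - F) / h
        try:
            step = np.linalg.solve(J, -F)
        except np.linalg.LinAlgError:
            step = None
        if step is None:
            raise ConvergenceError(
                "singular Jacobian",
                last_state=_state_from_u(ctx, u, it, nrm, False),
                residual_norm=nrm, iterations=it)
        # trust-region-style cap: at most ~0.7 log-units on concentrations
        # and volume, ~20 mV on potentials, preserving the step direction
        full_norm = float(np.linalg.norm(step))
        n_log = ctx.n_sol + (1 if ctx.water else 0)
        cap = max(np.max(np.abs(step[:n_log])) / 0.7,
                  np.max(np.abs(step[n_log:])) / 20.0, 1.0)
        step /= cap
        lam = 1.0
        accepted = False
        for _ in range(21):
            u_new = u + lam * step
            try:
                F_new = _residual_u(ctx, u_new)
            except (OverflowError, ValueError):
                lam *= 0.5
                continue
            if np.all(np.isfinite(F_new)):
                nrm_new = float(np.max(np.abs(F_new)))
                if nrm_new < tol or nrm_new < 0.5 * nrm:
                    accepted = True
                    break
                # affine-invariant (natural) monotonicity test: accept when
                # the simplified Newton correction from the trial point
                # shrinks relative to the full (uncapped) correction.  This
                # is robust where the residual norm transiently grows, e.g.
                # the quadratic electroneutrality error of a log-variable
                # step.
                lam_eff = lam / cap
                d_new = np.linalg.solve(J, -F_new)
                if float(np.linalg.norm(d_new)) <= (1.0 - 0.5 * lam_eff) * full_norm:
                    accepted = True
                    break
                if lam < 1.0 / (1 << 20):
                    accepted = True
                    break
            lam *= 0.5
        if not accepted:
            raise ConvergenceError(
                "line search failed",
                last_state=_state_from_u(ctx, u, it, nrm, False),
                residual_norm=nrm, iterations=it)
        u, F, nrm = u_new, F_new, nrm_new
        it += 1

    if nrm >= tol:
        state = _state_from_u(ctx, u, it, nrm, False)
        logger.warning("Newton failed for %s: residual %.3e after %d iterations",
                       variant.name, nrm, it)
        raise ConvergenceError(
            f"no convergence after {it} iterations (residual {nrm:.3e})",
            last_state=state, residual_norm=nrm, iterations=it)
    state = _state_from_u(ctx, u, it, nrm, True)
    logger.debug("solved %s in %d iterations (residual %.3e)",
                 variant.name, it, nrm)
    return state


# --------------------------------------------------------------------------
# Pseudo-transient relaxation oracle (test-only path)
# --------------------------------------------------------------------------

def _resolve_potentials(ctx: _Context, C, vol, V_C, V_L, tol=1e-12,
                        max_iter=60):
    """Inner 2-variable Newton: zero net cell current and zero total
    transepithelial current, at fixed concentrations."""
    rf = ctx.ref_flux

    def g(vc, vl):
        J_ap, J_bl, _J_pc, src, _, _ = _all_fluxes(ctx, C, vol, vc, vl)
        cell = sum(ctx.z[j] * (J_ap[j] + src[j] - J_bl[j])
                   for j in range(ctx.n_sol)) / rf
        total = sum(ctx.z[j] * (J_bl[j] + _J_pc[j])
                    for j in range(ctx.n_sol)) / rf
        return cell, total

    for _ in range(max_iter):
        g1, g2 = g(V_C, V_L)
        if abs(g1) < tol and abs(g2) < tol:
            break
        h = 1e-6
        a11 = (g(V_C + h, V_L)[0] - g1) / h
        a21 = (g(V_C + h, V_L)[1] - g2) / h
        a12 = (g(V_C, V_L + h)[0] - g1) / h
        a22 = (g(V_C, V_L + h)[1] - g2) / h
        det = a11 * a22 - a12 * a21
        if det == 0 or not math.isfinite(det):
            raise ConvergenceError("singular potential subsystem")
        dvc = (-g1 * a22 + g2 * a12) / det
        dvl = (-g2 * a11 + g1 * a21) / det
        # limit potential steps to keep the inner iteration tame
        mag = max(abs(dvc), abs(dvl))
        if mag > 25.0:
            dvc *= 25.0 / mag
            dvl *= 25.0 / mag
        V_C += dvc
        V_L += dvl
    return V_C, V_L


def relax_to_steady_state(variant: ModelVariant,
                          activities: TransporterActivities | None = None,
                          membranes: MembraneProperties | None = None,
                          dt: float = 1.0,
                          t_end: float = 5e6,
                          rate_tol: float = 1e-12) -> SteadyState:
    """Pseudo-transient relaxation to steady state (independent oracle).

    Integrates the solute amounts (and cell volume for water-permeable
    variants) with explicit Euler steps while resolving the two potentials
    algebraically at every step (electroneutrality preservation + open
    circuit).  Steps that destabilize the iteration halve ``dt`` (up to 10
    consecutive times); successful steps grow it again.  Terminates when the
    relative state change per unit time drops below ``rate_tol``.
    """
    if dt <= 0:
        raise DomainError("dt must be positive")
    ctx = _make_context(variant, activities, membranes)
    guess = cold_start_state(variant)
    C = [guess.cytosol.concentrations[n] for n in ctx.names]
    vol = guess.volume
    N = [c * vol for c in C]
    V_C, V_L = guess.V_cell, guess.V_lumen

    def rates(N, vol, V_C, V_L):
        C = [x / vol for x in N]
        V_C, V_L = _resolve_potentials(ctx, C, vol, V_C, V_L)
        J_ap, J_bl, _, src, Jv_a, Jv_b = _all_fluxes(ctx, C, vol, V_C, V_L)
        dN = [J_ap[j] + src[j] - J_bl[j] for j in range(ctx.n_sol)]
        dvol = (Jv_a - Jv_b) if ctx.water else 0.0
        rel = max(max(abs(dN[j]) / max(N[j], 1e-12) for j in range(ctx.n_sol)),
                  abs(dvol) / vol)
        return dN, dvol, V_C, V_L, rel

    def stability_cap(N, vol, V_C, V_L, dN, dvol):
        # explicit-Euler cap from the diagonal of the amount-space rate
        # Jacobian (fastest local feedback mode), estimated by differencing
        lam = 0.0
        for j in range(ctx.n_sol):
            h = 1e-4 * N[j]
            Np = list(N)
            Np[j] += h
            out = rates(Np, vol, V_C, V_L)
            lam = max(lam, abs(out[0][j] - dN[j]) / h)
        if ctx.water:
            h = 1e-4 * vol
            out = rates(N, vol + h, V_C, V_L)
            lam = max(lam, abs(out[1] - dvol) / h)
        return 0.8 / lam if lam > 0 else math.inf

    t = 0.0
    dt0 = dt
    dN, dvol, V_C, V_L, rel = rates(N, vol, V_C, V_L)
    dt_max = min(1024.0 * dt0, stability_cap(N, vol, V_C, V_L, dN, dvol))
    dt = min(dt, dt_max)
    halvings = 0
    accepted_steps = 0
    while t < t_end:
        if rel < rate_tol:
            break
        N_new = [N[j] + dt * dN[j] for j in range(ctx.n_sol)]
        vol_new = vol + dt * dvol
        if min(N_new) <= 0 or vol_new <= 0:
            dt *= 0.5
            halvings += 1
            if halvings > 10:
                raise ConvergenceError("relaxation unstable (state left domain)")
            continue
        try:
            out = rates(N_new, vol_new, V_C, V_L)
        except (ConvergenceError, OverflowError, ValueError):
            dt *= 0.5
            halvings += 1
            if halvings > 10:
                raise ConvergenceError("relaxation unstable (rates diverged)")
            continue
        rel_new = out[4]
        if rel_new > rel * 1.5 and rel > 10 * rate_tol:
            dt *= 0.5
            halvings += 1
            if halvings > 10:
                raise ConvergenceError("relaxation unstable (residual growth)")
            continue
        halvings = 0
        t += dt
        N, vol = N_new, vol_new
        dN, dvol, V_C, V_L, rel = out[0], out[1], out[2], out[3], rel_new
        accepted_steps += 1
        if accepted_steps % 1000 == 0:
            dt_max = min(1024.0 * dt0,
                         stability_cap(N, vol, V_C, V_L, dN, dvol))
        dt = min(dt * 1.25, dt_max)
    if rel >= rate_tol:
        raise ConvergenceError(f"relaxation did not settle by t={t_end:g} s",
                               residual_norm=rel)
    C = [x / vol for x in N]
    u = _pack(ctx, C, vol, V_C, V_L)
    res = _residual_u(ctx, u)
    nrm = float(np.max(np.abs(res)))
    return _state_from_u(ctx, u, 0, nrm, True)


def transcellular_fluxes(state: SteadyState) -> FluxRecord:
    """Flux record of a converged steady state (basolateral = transcellular)."""
    if not state.converged or state.fluxes is None:
        raise ValueError("state is not a converged steady state")
    return state.fluxes


# --------------------------------------------------------------------------
# Variant configuration (YAML)
# --------------------------------------------------------------------------

_VARIED = {
    # name -> (kind, attribute/solute)
    "NHE3": ("activity", "x_NHE3"),
    "SGLT2": ("activity", "x_SGLT2"),
    "NBCe1": ("activity", "x_NBCe1"),
    "NKCC2": ("activity", "x_NKCC2"),
    "NaKATPase": ("activity", "pump_Jmax"),
    "P_K_api": ("permeability", ("apical", "K")),
    "P_K_baso": ("permeability", ("basolateral", "K")),
}


def apply_parameter_fractions(variant: ModelVariant,
                              fractions: Mapping[str, float]
                              ) -> tuple[TransporterActivities, MembraneProperties]:
    """Scale named transport parameters by multiplicative fractions.

    Returns (activities, membranes) with every named parameter multiplied by
    its fraction of the variant's baseline; unnamed parameters are left at
    baseline.  Unknown names raise :class:`ConfigurationError`.
    """
    act = variant.baseline_activities
    mem = variant.membranes
    act_updates: dict[str, float] = {}
    memb_updates: dict[str, dict[str, float]] = {}
    for name, frac in fractions.items():
        if name not in _VARIED:
            raise ConfigurationError(f"unknown transport parameter {name!r}")
        if frac <= 0:
            raise ConfigurationError(f"fraction for {name!r} must be positive")
        kind, target = _VARIED[name]
        if kind == "activity":
            act_updates[target] = getattr(act, target) * frac
        else:
            side, solute = target
            memb_updates.setdefault(side, {})[solute] = frac
    if act_updates:
        act = replace(act, **act_updates)
    if memb_updates:
        sides = {}
        for side_name in ("apical", "basolateral", "paracellular"):
            side = getattr(mem, side_name)
            if side_name in memb_updates:
                perms = dict(side.permeabilities)
                for solute, frac in memb_updates[side_name].items():
                    perms[solute] = perms.get(solute, 0.0) * frac
                side = MembraneSide(permeabilities=perms, Pf=side.Pf)
            sides[side_name] = side
        mem = MembraneProperties(**sides)
    return act, mem


def _composition_from_config(d: Mapping) -> CompartmentComposition:
    return CompartmentComposition(
        concentrations=dict(d["concentrations"]),
        H_concentration=float(d["H_concentration"]),
        potential=float(d.get("potential", 0.0)),
        impermeant_anions=float(d.get("impermeant_anions", 0.0)),
        impermeant_osmolytes=float(d.get("impermeant_osmolytes", 0.0)),
    )


def variant_from_dict(cfg: Mapping) -> ModelVariant:
    """Build a :class:`ModelVariant` from a parsed configuration mapping."""
    try:
        solutes = tuple(SoluteSpec(name=s["name"], z=int(s["z"]),
                                   osmotic_coefficient=float(
                                       s.get("osmotic_coefficient", 1.0)))
                        for s in cfg["solutes"])
        membranes = MembraneProperties(
            apical=MembraneSide(
                permeabilities=dict(cfg["membranes"]["apical"]["permeabilities"]),
                Pf=float(cfg["membranes"]["apical"].get("Pf", 0.0))),
            basolateral=MembraneSide(
                permeabilities=dict(cfg["membranes"]["basolateral"]["permeabilities"]),
                Pf=float(cfg["membranes"]["basolateral"].get("Pf", 0.0))),
            paracellular=MembraneSide(
                permeabilities=dict(cfg["membranes"]["paracellular"]["permeabilities"]),
                Pf=float(cfg["membranes"]["paracellular"].get("Pf", 0.0))),
        )
        act = cfg["activities"]
        activities = TransporterActivities(
            x_NHE3=float(act.get("NHE3", 0.0)),
            x_SGLT2=float(act.get("SGLT2", 0.0)),
            x_NBCe1=float(act.get("NBCe1", 0.0)),
            x_NKCC2=float(act.get("NKCC2", 0.0)),
            pump_Jmax=float(act["pump_Jmax"]),
            pump_K_Na=float(act.get("pump_K_Na", 15.0)),
            pump_K_K=float(act.get("pump_K_K", 2.5)),
        )
        geometry = CellGeometry(
            volume=float(cfg["geometry"]["volume"]),
            impermeant_amount=float(cfg["geometry"]["impermeant_amount"]),
            impermeant_valence=int(cfg["geometry"].get("impermeant_valence", -1)),
        )
        return ModelVariant(
            cell_type=str(cfg["cell_type"]),
            sex=str(cfg["sex"]),
            solutes=solutes,
            lumen=_composition_from_config(cfg["lumen"]),
            interstitium=_composition_from_config(cfg["interstitium"]),
            membranes=membranes,
            baseline_activities=activities,
            geometry=geometry,
            water_permeable=bool(cfg["water_permeable"]),
            cytosol_H=float(cfg.get("cytosol_H", 6.31e-5)),
            varied_parameters=tuple(cfg.get("varied_parameters", ())),
            sex_factors=dict(cfg.get("sex_factors", {})),
        )
    except KeyError as exc:
        raise ConfigurationError(f"missing configuration key: {exc}") from exc


def load_variant(name_or_path: str | Path) -> ModelVariant:
    """Load a shipped variant by name (e.g. ``"pct_male"``) or a YAML path."""
    p = Path(name_or_path)
    if p.suffix in (".yaml", ".yml") and p.exists():
        text = p.read_text()
    else:
        ref = resources.files("episurf.config").joinpath(f"{name_or_path}.yaml")
        if not ref.is_file():
            raise ConfigurationError(f"unknown variant {name_or_path!r}")
        text = ref.read_text()
    return variant_from_dict(yaml.safe_load(text))
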