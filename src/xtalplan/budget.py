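"""Sample-budget arithmetic: how much protein and solution a target crystal needs.

Neutron crystallography needs roughly cubic crystals of about 1 mm edge.
Before any experiment it is worth knowing how much protein such a crystal
contains and, given the working concentration and the solubility, the minimum
solution volume able to feed it.  The crystal is idealised as a cube of edge
``a``; the number of molecules follows from the Matthews coefficient V_M
(crystal volume per Dalton, Å³/Da) and the molecular weight, and converting
through Avogadro's number gives the protein mass.  A closed container can
only deposit the protein between the initial concentration C and the
solubility C_e, which fixes the required volume.

Also provided here is the one-dimensional diffusion migration time used to
judge when crystals in the same capillary stop influencing each other.
"""

from __future__ import annotations

from dataclasses import dataclass

from .constants import (
    A3_PER_MM3,
    AVOGADRO,
    M_PER_MM,
    MG_PER_G,
    MM3_PER_ML,
    S_PER_H,
    UL_PER_ML,
)
from .errors import InfeasibleBudgetError, InvalidSpecError

__all__ = [
    "ProteinSpec",
    "CrystalBudget",
    "molecules_in_crystal",
    "protein_mass_in_crystal",
    "crystal_protein_density",
    "required_solution_volume",
    "crystal_budget",
    "diffusion_time",
]


@dataclass(frozen=True)
class ProteinSpec:
    """Physical description of the protein and its crystal form.

    Parameters
    ----------
    matthews_vm : float
        Matthews coefficient in Å³ per Dalton.
    mol_weight : float
        Molecular weight in Daltons.
    diffusion_coeff : float, optional
        Translational diffusion coefficient in m² s⁻¹ for the working
        solution (it drops sharply in viscous precipitants such as PEG).
    """

    matthews_vm: float
    mol_weight: float
    diffusion_coeff: float | None = None

    def __post_init__(self) -> None:
        if not self.matthews_vm > 0:
            raise InvalidSpecError(f"matthews_vm must be > 0, got {self.matthews_vm}")
        if not self.mol_weight > 0:
            raise InvalidSpecError(f"mol_weight must be > 0, got {self.mol_weight}")
        if self.diffusion_coeff is not None and not self.diffusion_coeff > 0:
            raise InvalidSpecError(
                f"diffusion_coeff must be > 0 when given, got {self.diffusion_coeff}"
            )


@dataclass(frozen=True)
class CrystalBudget:
    """Complete budget for one target crystal (cube idealisation)."""

    cube_edge_mm: float
    n_molecules: float
    n_moles: float
    protein_mass_mg: float
    required_volume_ul: float


def molecules_in_crystal(edge_mm: float, spec: ProteinSpec) -> float:
    """Number of protein molecules in a cubic crystal of the given edge (mm).

    The crystal provides V_M ų of lattice volume per Dalton, so a cube of
    edge ``a`` mm holds a³·10²¹ / (V_M · M) molecules.
    """
    if edge_mm < 0:
        raise InvalidSpecError(f"edge_mm must be >= 0, got {edge_mm}")
    return edge_mm**3 * A3_PER_MM3 / (spec.matthews_vm * spec.mol_weight)


def protein_mass_in_crystal(edge_mm: float, spec: ProteinSpec) -> float:
    """Protein mass (mg) in a cubic crystal of the given edge (mm).

    The molecular weight cancels: mass = a³·10²¹ / (V_M · N_A) grams.
    """
    n = molecules_in_crystal(edge_mm, spec)
    return n * spec.mol_weight / AVOGADRO * MG_PER_G


def crystal_protein_density(spec: ProteinSpec) -> float:
    """Protein mass concentration inside the crystal lattice, C_s, in g/ml.

    This is the density the mass balance uses when growing crystals deplete
    the mother liquor.  For lysozyme with V_M = 1.84 Å³/Da it is ≈0.902 g/ml.
    """
    mass_mg_per_mm3 = protein_mass_in_crystal(1.0, spec)  # 1 mm cube
    return mass_mg_per_mm3 / MG_PER_G * MM3_PER_ML


def required_solution_volume(
    edge_mm: float, spec: ProteinSpec, conc_mg_ml: float, solubility_mg_ml: float
) -> float:
    """Minimum solution volume (µl) able to grow the target crystal.

    A sealed container can only transfer the protein between the initial
    concentration C and the solubility C_e into the crystal, so
    volume = mass / (C − C_e).
    """
    if solubility_mg_ml < 0:
        raise InvalidSpecError(f"solubility must be >= 0, got {solubility_mg_ml}")
    if conc_mg_ml <= solubility_mg_ml:
        raise InfeasibleBudgetError(
            f"concentration ({conc_mg_ml} mg/ml) must exceed solubility "
            f"({solubility_mg_ml} mg/ml): the crystal cannot consume protein "
            "below the solubility"
        )
    mass_mg = protein_mass_in_crystal(edge_mm, spec)
    return mass_mg / (conc_mg_ml - solubility_mg_ml) * UL_PER_ML


def crystal_budget(
    edge_mm: float, spec: ProteinSpec, conc_mg_ml: float, solubility_mg_ml: float
) -> CrystalBudget:
    """Assemble the full budget (molecules, moles, mass, volume) in one call."""
    n = molecules_in_crystal(edge_mm, spec)
    mass = protein_mass_in_crystal(edge_mm, spec)
    vol = required_solution_volume(edge_mm, spec, conc_mg_ml, solubility_mg_ml)
    return CrystalBudget(
        cube_edge_mm=edge_mm,
        n_molecules=n,
        n_moles=n / AVOGADRO,
        protein_mass_mg=mass,
        required_volume_ul=vol,
    )


def diffusion_time(distance_mm: float, diffusion_coeff: float) -> float:
    """Mean time (h) for a molecule to diffuse the given distance (mm).

    Uses the one-dimensional mean-square displacement x² = 2Dt, i.e.
    t = x² / (2D).  Crystals in the same capillary separated by more than the
    distance diffused since the first nucleation grow quasi-independently.
    """
    if distance_mm < 0:
        raise InvalidSpecError(f"distance_mm must be >= 0, got {distance_mm}")
    if not diffusion_coeff > 0:
        raise InvalidSpecError(f"diffusion_coeff must be > 0, got {diffusion_coeff}")
    x_m = distance_mm * M_PER_MM
    return x_m**2 / (2.0 * diffusion_coeff) / S_PER_H
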