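"""Photon energy/wavelength conversion, anomalous scattering coefficients,
Bijvoet-ratio estimation and detector-limited resolution.

The anomalous contribution f'' to an atom's scattering factor drives the
intensity difference between Bijvoet mates and therefore the feasibility of
native-SAD phasing.  Per-element (energy, f', f'') grids computed with the
Cromer-Liberman relativistic algorithm are bundled as plain-text package
data; lookups interpolate between grid points without ever crossing a
labelled absorption edge, where f'' is discontinuous.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

__all__ = [
    "HC_KEV_ANGSTROM",
    "SpectralPoint",
    "ScatteringTable",
    "BijvoetModel",
    "DetectorGeometry",
    "energy_to_wavelength",
    "wavelength_to_energy",
    "f_double_prime",
    "f_prime",
    "bijvoet_ratio",
    "detector_dmin",
]

#: Planck constant times speed of light, in keV * Angstrom.
HC_KEV_ANGSTROM = 12.3984


def energy_to_wavelength(energy: float) -> float:
    """Convert photon energy in keV to wavelength in Angstrom."""
    if energy <= 0:
        raise ValueError(f"photon energy must be positive, got {energy}")
    return HC_KEV_ANGSTROM / energy


def wavelength_to_energy(wavelength: float) -> float:
    """Convert wavelength in Angstrom to photon energy in keV."""
    if wavelength <= 0:
        raise ValueError(f"wavelength must be positive, got {wavelength}")
    return HC_KEV_ANGSTROM / wavelength


@dataclass(frozen=True)
class SpectralPoint:
    """A photon energy (keV) together with its wavelength (Angstrom).

    The two fields are redundant by construction (E * lambda = hc); use the
    ``from_energy`` / ``from_wavelength`` constructors.
    """

    energy: float
    wavelength: float

    def __post_init__(self) -> None:
        if self.energy <= 0 or self.wavelength <= 0:
            raise ValueError("energy and wavelength must be positive")
        if not math.isclose(
            self.energy * self.wavelength, HC_KEV_ANGSTROM, rel_tol=1e-9
        ):
            raise ValueError(
                f"inconsistent spectral point: E*lambda = "
                f"{self.energy * self.wavelength!r} != {HC_KEV_ANGSTROM}"
            )

    @classmethod
    def from_energy(cls, energy: float) -> "SpectralPoint":
        return cls(energy=energy, wavelength=energy_to_wavelength(energy))

    @classmethod
    def from_wavelength(cls, wavelength: float) -> "SpectralPoint":
        return cls(energy=wavelength_to_energy(wavelength), wavelength=wavelength)


def _as_point(point: "SpectralPoint | float") -> SpectralPoint:
    """Accept a SpectralPoint or a bare energy in keV."""
    if isinstance(point, SpectralPoint):
        return point
    return SpectralPoint.from_energy(float(point))


@dataclass(frozen=True)
class ScatteringTable:
    """Tabulated anomalous scattering coefficients for one element.

    ``grid`` rows are (energy keV, f' electrons, f'' electrons), strictly
    increasing in energy.  ``edges`` holds labelled absorption-edge energies
    (keV); interpolation is clamped so that a query never mixes grid rows
    from opposite sides of an edge.
    """

    element: str
    grid: tuple[tuple[float, float, float], ...]
    edges: tuple[tuple[str, float], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        energies = [row[0] for row in self.grid]
        if any(b <= a for a, b in zip(energies, energies[1:])):
            raise ValueError(f"{self.element}: grid energies must strictly increase")
        if any(row[2] < 0 for row in self.grid):
            raise ValueError(f"{self.element}: f'' must be non-negative")

    @property
    def energy_range(self) -> tuple[float, float]:
        return self.grid[0][0], self.grid[-1][0]

    @classmethod
    def from_text(cls, element: str, text: str) -> "ScatteringTable":
        """Parse the bundled whitespace-delimited format.

        Data lines are ``energy_eV f' f''``; comment lines start with '#';
        edges are declared as ``# edge: <label> <energy_eV>``.
        """
        rows = []
        edges = []
        for line in text.splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.lower().startswith("edge:"):
                    _, label, e_ev = body.split()
                    edges.append((label, float(e_ev) / 1000.0))
                continue
            e_ev, f1, f2 = line.split()
            rows.append((float(e_ev) / 1000.0, float(f1), float(f2)))
        return cls(element=element, grid=tuple(rows), edges=tuple(edges))

    @classmethod
    @lru_cache(maxsize=None)
    def for_element(cls, element: str) -> "ScatteringTable":
        """Load the bundled table for ``element`` (cached)."""
        ref = resources.files("natsad").joinpath("data", "scattering", f"{element}.dat")
        try:
            text = ref.read_text()
        except FileNotFoundError:
            raise LookupError(
                f"no bundled scattering table for element {element!r}"
            ) from None
        return cls.from_text(element, text)

    # -- interpolation ----------------------------------------------------

    def _bracket(self, energy: float) -> tuple[int, int]:
        lo, hi = self.energy_range
        if not (lo <= energy <= hi):
            raise LookupError(
                f"energy {energy:.4f} keV outside the tabulated range "
                f"[{lo:.4f}, {hi:.4f}] keV for element {self.element}"
            )
        energies = [row[0] for row in self.grid]
        # rightmost i with energies[i] <= energy
        import bisect

        i = bisect.bisect_right(energies, energy) - 1
        if i == len(energies) - 1:
            return i, i
        return i, i + 1

    def _clamped_indices(self, energy: float) -> tuple[int, int]:
        i, j = self._bracket(energy)
        if self.grid[i][0] == energy:  # exact grid hit: no interpolation
            return i, i
        if i != j:
            e_i, e_j = self.grid[i][0], self.grid[j][0]
            for _, e_edge in self.edges:
                if e_i < e_edge < e_j:
                    # do not interpolate across the discontinuity: use the
                    # grid row on the same side of the edge as the query
                    return (i, i) if energy < e_edge else (j, j)
        return i, j

    def f_double_prime(self, point: "SpectralPoint | float") -> float:
        """f'' in electrons, interpolated log(E)-log(f'') between grid rows."""
        energy = _as_point(point).energy
        i, j = self._clamped_indices(energy)
        if i == j:
            return self.grid[i][2]
        e_i, _, f_i = self.grid[i]
        e_j, _, f_j = self.grid[j]
        t = (math.log(energy) - math.log(e_i)) / (math.log(e_j) - math.log(e_i))
        if f_i <= 0 or f_j <= 0:
            return f_i + t * (f_j - f_i)
        return math.exp(math.log(f_i) + t * (math.log(f_j) - math.log(f_i)))

    def f_prime(self, point: "SpectralPoint | float") -> float:
        """f' in electrons (can be negative), interpolated linearly in log E."""
        energy = _as_point(point).energy
        i, j = self._clamped_indices(energy)
        if i == j:
            return self.grid[i][1]
        e_i, f_i, _ = self.grid[i]
        e_j, f_j, _ = self.grid[j]
        t = (math.log(energy) - math.log(e_i)) / (math.log(e_j) - math.log(e_i))
        return f_i + t * (f_j - f_i)

    def nearest_edge(self, point: "SpectralPoint | float") -> tuple[str, float] | None:
        """Label and energy (keV) of the labelled edge closest to the query."""
        if not self.edges:
            return None
        energy = _as_point(point).energy
        return min(self.edges, key=lambda le: abs(le[1] - energy))


def f_double_prime(element: str, point: "SpectralPoint | float") -> float:
    """f''(element) in electrons at the given spectral point."""
    return ScatteringTable.for_element(element).f_double_prime(point)


def f_prime(element: str, point: "SpectralPoint | float") -> float:
    """f'(element) in electrons at the given spectral point."""
    return ScatteringTable.for_element(element).f_prime(point)


# -- Bijvoet ratio --------------------------------------------------------

#: Effective normal scattering power per protein atom, electrons.
Z_EFF_PROTEIN = 6.7
#: Average non-hydrogen atoms per amino-acid residue.
NON_H_ATOMS_PER_RESIDUE = 7.7


@dataclass(frozen=True)
class BijvoetModel:
    """Inputs of the Bijvoet-ratio estimate <|dF|>/<|F|>.

    ``n_anom`` anomalous scatterers with imaginary scattering contribution
    ``f_double_prime`` against ``n_protein_nonH`` ordinary protein atoms of
    mean scattering power ``z_eff`` electrons.
    """

    n_anom: float
    n_protein_nonH: float
    f_double_prime: float
    z_eff: float = Z_EFF_PROTEIN

    def __post_init__(self) -> None:
        if self.n_anom < 0 or self.n_protein_nonH < 0:
            raise ValueError("atom counts must be non-negative")
        if self.z_eff <= 0:
            raise ValueError("z_eff must be positive")


def bijvoet_ratio(model: BijvoetModel) -> float:
    """Expected relative Bijvoet amplitude difference, as a fraction.

    ratio = sqrt(N_anom / (2 N_protein)) * 2 f'' / Z_eff
    """
    if model.n_protein_nonH <= 0:
        raise ValueError("Bijvoet ratio undefined without protein atoms")
    return (
        math.sqrt(model.n_anom / (2.0 * model.n_protein_nonH))
        * 2.0
        * model.f_double_prime
        / model.z_eff
    )


# -- detector geometry ----------------------------------------------------


@dataclass(frozen=True)
class DetectorGeometry:
    """Angular coverage of a (semi-)cylindrical detector.

    ``two_theta_max`` is the maximum scattering angle reached along the
    cylinder meridian, degrees.  ``axial_half_range`` records the coverage
    along the cylinder axis and is informational only.
    """

    two_theta_max: float = 100.0
    axial_half_range: float = 100.0

    def __post_init__(self) -> None:
        if not (0.0 < self.two_theta_max <= 180.0):
            raise ValueError("two_theta_max must be in (0, 180] degrees")


def detector_dmin(
    geometry: DetectorGeometry, point: "SpectralPoint | float | None" = None,
    *, wavelength: float | None = None,
) -> float:
    """Detector-limited resolution d_min = lambda / (2 sin(2theta_max / 2)).

    Bragg's law (n lambda = 2 d sin(theta)) with the highest scattering
    angle the detector subtends.
    """
    if wavelength is None:
        if point is None:
            raise ValueError("either a spectral point or a wavelength is required")
        wavelength = _as_point(point).wavelength
    if wavelength <= 0:
        raise ValueError("wavelength must be positive")
    theta = math.radians(geometry.two_theta_max / 2.0)
    return wavelength / (2.0 * math.sin(theta))
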