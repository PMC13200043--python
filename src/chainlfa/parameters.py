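"""Parameter sets for both simulation models.

Two parameter families are housed here:

* :class:`MicroModelParams` — the microscale model of antigen capture by
  rotating nanochains: a 15 µm square of buffer containing nine rigid
  rectangular nanochains whose rotating walls stir the fluid while
  antibody-functionalized chain surfaces take up antigen with Langmuir-type
  kinetics.
* :class:`MembraneModelParams` — the lateral-flow membrane model: a 7 mm
  nitrocellulose strip (3 mm inlet segment, 1 mm test line, 3 mm outlet
  segment) wetted by Lucas–Washburn capillary imbibition, carrying nanochains
  by Darcy flow toward immobilized test-line antibodies with an optional
  cooperative magnetic-recruitment capture term.

All quantities are SI internally.  Rate constants quoted per molar
(1/(M*s)) are converted through a single audited helper,
:func:`per_molar_rate_to_si`.  Derived quantities (``omega``, ``K_D``,
``P_cap``, ``kon``) are computed on access from the stored fields, so
mutating a field can never leave a stale derived value behind.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field, fields

log = logging.getLogger(__name__)

#: Litres per cubic metre: 1/(M*s) = 1 L/(mol*s) = 1e-3 m^3/(mol*s).
_L_PER_M3 = 1e-3


def per_molar_rate_to_si(rate_per_molar: float) -> float:
    """Convert a bimolecular rate constant from 1/(M*s) to m^3/(mol*s).

    1 M^-1 s^-1 = 1 L mol^-1 s^-1 = 1e-3 m^3 mol^-1 s^-1.
    """
    return rate_per_molar * _L_PER_M3


def angular_velocity(freq: float) -> float:
    """Angular velocity omega = 2*pi*freq (rad/s) for rotation frequency in Hz."""
    if freq < 0:
        raise ValueError(f"rotation frequency must be >= 0, got {freq}")
    return 2.0 * math.pi * freq


def capillary_pressure(gamma_surface: float, pore_size: float) -> float:
    """Capillary pressure P_cap = 2*gamma/pore (Pa) of a cylindrical pore."""
    if pore_size <= 0:
        raise ValueError(f"pore size must be > 0, got {pore_size}")
    return 2.0 * gamma_surface / pore_size


def si_association_rate(n_abs: float) -> float:
    """Test-line association rate kon in m^3/(mol*s) from the binding
    efficiency parameter N_Abs.

    The membrane model parameterizes kon as ``N_Abs * 1e4`` per molar per
    second; in SI this is ``N_Abs * 10`` m^3/(mol*s).
    """
    if n_abs < 0:
        raise ValueError(f"N_Abs must be >= 0, got {n_abs}")
    return per_molar_rate_to_si(n_abs * 1e4)


def _require_positive(name: str, value: float) -> None:
    if not value > 0:
        raise ValueError(f"{name} must be strictly positive, got {value}")


@dataclass
class MicroModelParams:
    """Global parameters of the microscale rotating-nanochain model.

    Defaults are the reference configuration of the method: a 1 ng/mL
    solution of a 15 kDa analyte (H-FABP) stirred by nine 1.05 µm x 0.15 µm
    nanochains in a 15 µm square domain.
    """

    L_chain: float = 1050e-9          # nanochain length (m)
    W_chain: float = 150e-9           # nanochain width (m)
    domain_size: float = 15e-6        # square domain side (m)
    C_bulk: float = 6.67e-8           # initial antigen concentration (mol/m^3)
    mu_fluid: float = 1.8e-3          # dynamic viscosity (Pa*s)
    rho_fluid: float = 1000.0         # density (kg/m^3)
    k_on: float = 1.0                 # association rate (m^3/(mol*s))
    k_off: float = 0.1                # dissociation rate (1/s)
    freq: float = 0.0                 # rotation frequency (Hz); sweep variable
    Gamma_max: float = 1e-8           # surface binding-site density (mol/m^2)
    t_end: float = 360.0              # simulated incubation time (s)
    spacing: float | None = None      # chain grid pitch (m); default domain_size/3
    D_analyte: float = 1.1e-10        # analyte diffusivity (m^2/s)
    M_analyte: float = 15000.0        # analyte molar mass (g/mol)

    def __post_init__(self) -> None:
        if self.spacing is None:
            self.spacing = self.domain_size / 3.0
        self.validate()

    def validate(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name in ("freq", "Gamma_max"):
                # freq = 0 is the static condition; Gamma_max = 0 switches
                # the wall uptake off (useful for no-sink oracles)
                if v < 0:
                    raise ValueError(f"{f.name} must be >= 0, got {v}")
            else:
                _require_positive(f.name, v)
        if self.L_chain >= self.domain_size or self.W_chain >= self.domain_size:
            raise ValueError("chain dimensions must be smaller than the domain")

    # ---- derived quantities (computed on access; never cached) ----

    @property
    def omega(self) -> float:
        """Angular velocity 2*pi*freq (rad/s)."""
        return angular_velocity(self.freq)

    @property
    def K_D(self) -> float:
        """Equilibrium dissociation constant k_off/k_on (mol/m^3)."""
        return self.k_off / self.k_on

    @property
    def chain_area(self) -> float:
        """Area of one nanochain rectangle (m^2)."""
        return self.L_chain * self.W_chain

    @property
    def fluid_area(self) -> float:
        """Fluid area: domain square minus the nine chain rectangles (m^2)."""
        return self.domain_size**2 - 9.0 * self.chain_area

    @property
    def chain_perimeter(self) -> float:
        """Perimeter of one nanochain rectangle (m)."""
        return 2.0 * (self.L_chain + self.W_chain)

    @property
    def uptake_velocity(self) -> float:
        """Reaction-limited uptake velocity k_on*Gamma_max (m/s)."""
        return self.k_on * self.Gamma_max

    def reynolds_number(self, freq: float | None = None) -> float:
        """Chain-scale Reynolds number rho*U*L/mu at tip speed U = omega*L/2.

        ~1e-5 at 3 Hz with defaults: inertia is negligible and the flow is
        well inside the creeping (Stokes) regime.
        """
        f = self.freq if freq is None else freq
        u_tip = angular_velocity(f) * self.L_chain / 2.0
        return self.rho_fluid * u_tip * self.L_chain / self.mu_fluid

    def replace(self, **changes) -> "MicroModelParams":
        return dataclasses.replace(self, **changes)


@dataclass
class MembraneModelParams:
    """Global parameters of the porous lateral-flow membrane model.

    The strip is 2*L_model + W_TL long (7 mm with defaults) and H_membrane
    wide in the 2D plane.  ``V_chain`` and ``c3_max`` are housed because the
    method tabulates them, but no printed rate law consumes them; supplying
    them in a config logs a warning to that effect.
    """

    L_model: float = 3e-3             # inlet/outlet segment length (m)
    H_membrane: float = 2.5e-3        # strip width in-plane (m)
    porosity: float = 0.75            # membrane porosity (-)
    k_perm: float = 1e-13             # permeability (m^2)
    pore_size: float = 20e-6          # mean pore size (m)
    rho_fluid: float = 1000.0         # fluid density (kg/m^3)
    eta_fluid: float = 1e-3           # fluid viscosity (Pa*s)
    gamma_surface: float = 0.072      # surface tension (N/m)
    C0_mol: float = 7e-8              # inflow nanochain concentration (mol/m^3)
    D0: float = 2e-13                 # nanochain diffusivity (m^2/s)
    delta_smooth: float = 100e-6      # wetting-front smoothing width (m)
    power_contrast: float = 2.0       # wetness exponent for k_eff (-)
    P_inlet: float = 25000.0          # inlet pressure (Pa)
    k_min: float = 0.01               # dry relative permeability floor (-)
    W_TL: float = 1e-3                # test-line width (m)
    H_TL: float | None = None         # test-line height (m); default H_membrane
    x_testline: float | None = None   # test-line start (m); default L_model
    w_testline: float | None = None   # test-line width (m); default W_TL
    C_Ab_init: float = 1e-5           # initial test-line antibody conc (mol/m^3)
    koff: float = 1e-9                # complex dissociation rate (1/s)
    N_Abs: float = 100.0              # binding efficiency parameter (sweep)
    k_recruit: float = 7e4            # cooperative recruitment rate (m^3/(mol*s))
    V_chain: float = 2e-20            # nanochain volume (m^3); housed, unused
    c3_max: float = 70e-6             # max complex density (mol/m^3); housed, unused
    d_z: float = 3e-6                 # out-of-plane thickness (m); housed

    def __post_init__(self) -> None:
        if self.H_TL is None:
            self.H_TL = self.H_membrane
        if self.x_testline is None:
            self.x_testline = self.L_model
        if self.w_testline is None:
            self.w_testline = self.W_TL
        self.validate()

    def validate(self) -> None:
        if not 0.0 < self.porosity < 1.0:
            raise ValueError(f"porosity must be in (0, 1), got {self.porosity}")
        if not 0.0 < self.k_min <= 1.0:
            raise ValueError(f"k_min must be in (0, 1], got {self.k_min}")
        if self.k_recruit < 0 or self.N_Abs < 0:
            raise ValueError("N_Abs and k_recruit must be >= 0")
        for name in ("L_model", "H_membrane", "k_perm", "pore_size", "rho_fluid",
                     "eta_fluid", "gamma_surface", "C0_mol", "D0", "delta_smooth",
                     "power_contrast", "P_inlet", "W_TL", "H_TL", "C_Ab_init",
                     "koff", "V_chain", "c3_max", "d_z"):
            _require_positive(name, getattr(self, name))

    # ---- derived quantities ----

    @property
    def P_cap(self) -> float:
        """Capillary pressure 2*gamma_surface/pore_size (Pa)."""
        return capillary_pressure(self.gamma_surface, self.pore_size)

    @property
    def kon(self) -> float:
        """Association rate N_Abs*1e4 1/(M*s), in SI m^3/(mol*s)."""
        return si_association_rate(self.N_Abs)

    @property
    def domain_length(self) -> float:
        """Total strip length 2*L_model + W_TL (m)."""
        return 2.0 * self.L_model + self.W_TL

    def replace(self, **changes) -> "MembraneModelParams":
        return dataclasses.replace(self, **changes)

    def warn_unused_fields(self) -> None:
        log.warning(
            "V_chain=%.3g m^3 and c3_max=%.3g mol/m^3 are stored but no "
            "printed rate law consumes them; they do not affect the simulation.",
            self.V_chain, self.c3_max,
        )
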