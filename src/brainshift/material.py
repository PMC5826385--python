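"""Ogden hyperelastic / Prony viscoelastic constitutive model for brain tissue.

The brain is homogeneous, isotropic and nearly incompressible, with strain
energy density (first-order Ogden, principal stretches lambda_i)

    W = 2 mu(t) / alpha^2 * (lambda_1^alpha + lambda_2^alpha + lambda_3^alpha - 3)

and a two-term Prony shear relaxation modulus

    mu(t) = mu_0 * (1 - sum_i C_i (1 - exp(-t / tau_i))).

Default constants are the neonatal (3- to 5-day-old) piglet brain values:
mu_0 = 553 Pa, alpha = 0.01, C_1 = 0.3322, C_2 = 0.3890, tau_1 = 2.9572 s,
tau_2 = 0.1813 s, rho = 1.04 g/cm^3.  Near-incompressibility is enforced by
a penalty bulk term derived from Poisson's ratio; the published
nu = 0.49999 is softened to 0.495 by default for explicit-dynamics
stability (the deviation is configurable).

The viscoelastic hereditary integral is evaluated with the standard
internal-variable (exponential) recurrence applied to the deviatoric
stress, which reproduces the Prony relaxation function exactly for a held
deformation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "OgdenPronyMaterial",
    "FALX_PROPERTIES",
    "relaxation_modulus",
    "ogden_energy",
    "ogden_principal_stress",
    "relaxed_principal_stress",
    "deviatoric_kirchhoff_2d",
    "PronyHistory",
]

#: Falx constants carried for completeness; the falx is treated as part of
#: the rigid boundary (its modulus is ~4 orders above brain), so these are
#: not assigned to deformable elements.
FALX_PROPERTIES = {"rho": 1130.0, "E": 15e6, "nu": 0.45}  # kg/m^3, Pa, -


@dataclass(frozen=True)
class OgdenPronyMaterial:
    """Constitutive constants; SI units (Pa, s, kg/m^3)."""

    mu0: float = 553.0
    alpha: float = 0.01
    C1: float = 0.3322
    C2: float = 0.3890
    tau1: float = 2.9572
    tau2: float = 0.1813
    rho: float = 1040.0
    nu: float = 0.495

    def __post_init__(self) -> None:
        if self.mu0 <= 0:
            raise ValueError("mu0 must be positive")
        if not 0.0 < self.C1 + self.C2 < 1.0:
            raise ValueError("relaxation moduli must satisfy 0 < C1 + C2 < 1")
        if self.tau1 <= 0 or self.tau2 <= 0:
            raise ValueError("time constants must be positive")
        if not 0.0 < self.nu < 0.5:
            raise ValueError("Poisson ratio must lie in (0, 0.5)")

    @property
    def long_term_mu(self) -> float:
        """mu(infinity) = mu0 (1 - C1 - C2)."""
        return self.mu0 * (1.0 - self.C1 - self.C2)

    @property
    def bulk_modulus(self) -> float:
        """Penalty bulk modulus K = 2 mu0 (1 + nu) / (3 (1 - 2 nu))."""
        return 2.0 * self.mu0 * (1.0 + self.nu) / (3.0 * (1.0 - 2.0 * self.nu))


def relaxation_modulus(t, material: OgdenPronyMaterial):
    """Shear relaxation modulus mu(t), Pa."""
    t = np.asarray(t, dtype=float)
    decay = (
        material.C1 * (1.0 - np.exp(-t / material.tau1))
        + material.C2 * (1.0 - np.exp(-t / material.tau2))
    )
    return material.mu0 * (1.0 - decay)


def ogden_energy(stretches, mu: float, alpha: float):
    """Strain energy density W for principal stretches (..., 3)."""
    lams = np.asarray(stretches, dtype=float)
    if np.any(lams <= 0):
        raise ValueError("principal stretches must be positive (element inversion)")
    return 2.0 * mu / alpha**2 * (np.sum(lams**alpha, axis=-1) - 3.0)


def ogden_principal_stress(stretches, mu: float, alpha: float):
    """Deviatoric principal Kirchhoff stresses for isochoric stretches.

    tau_i = 2 mu / alpha * (lam_i^alpha - mean_j lam_j^alpha); the mean
    subtraction makes the result deviatoric (incompressible response, with
    the pressure supplied separately).
    """
    lams = np.asarray(stretches, dtype=float)
    if np.any(lams <= 0):
        raise ValueError("principal stretches must be positive (element inversion)")
    la = lams**alpha
    return 2.0 * mu / alpha * (la - la.mean(axis=-1, keepdims=True))


def relaxed_principal_stress(stretches, material: OgdenPronyMaterial, t: float):
    """Principal deviatoric stress of a deformation held constant since t=0.

    For a step deformation the hereditary integral collapses to scaling the
    instantaneous stress by mu(t)/mu0.
    """
    inst = ogden_principal_stress(stretches, material.mu0, material.alpha)
    return inst * (relaxation_modulus(t, material) / material.mu0)


def deviatoric_kirchhoff_2d(F: np.ndarray, mu: float, alpha: float):
    """In-plane deviatoric Kirchhoff stress for plane-strain deformations.

    Parameters
    ----------
    F : ndarray, shape (n, 2, 2)
        In-plane deformation gradients; lambda_3 = 1 (plane strain).

    Returns
    -------
    tau : ndarray, shape (n, 2, 2)
        In-plane part of the deviatoric Kirchhoff stress.
    J : ndarray, shape (n,)
        Volume ratios det(F) (with lambda_3 = 1).
    """
    F = np.asarray(F, dtype=float)
    J = F[:, 0, 0] * F[:, 1, 1] - F[:, 0, 1] * F[:, 1, 0]
    if np.any(J <= 0):
        raise ValueError("element inversion: det(F) <= 0")
    B = np.einsum("nij,nkj->nik", F, F)  # left Cauchy-Green, symmetric
    # analytic eigendecomposition of symmetric 2x2
    tr = B[:, 0, 0] + B[:, 1, 1]
    det = B[:, 0, 0] * B[:, 1, 1] - B[:, 0, 1] ** 2
    disc = np.sqrt(np.maximum((tr / 2.0) ** 2 - det, 0.0))
    e1 = tr / 2.0 + disc
    e2 = tr / 2.0 - disc
    lam1 = np.sqrt(np.maximum(e1, 1e-300))
    lam2 = np.sqrt(np.maximum(e2, 1e-300))

    # principal direction for e1: rows of (B - e2 I) span it
    n1 = np.stack([B[:, 0, 1], e1 - B[:, 0, 0]], axis=-1)
    small = np.linalg.norm(n1, axis=-1) < 1e-12
    n1[small] = np.array([1.0, 0.0])  # isotropic in-plane state
    n1 /= np.linalg.norm(n1, axis=-1, keepdims=True)
    n2 = np.stack([-n1[:, 1], n1[:, 0]], axis=-1)

    Jm13 = J ** (-1.0 / 3.0)
    lams = np.stack([lam1 * Jm13, lam2 * Jm13, Jm13], axis=-1)
    tau_p = ogden_principal_stress(lams, mu, alpha)  # (n, 3)
    tau = (
        tau_p[:, 0, None, None] * np.einsum("ni,nj->nij", n1, n1)
        + tau_p[:, 1, None, None] * np.einsum("ni,nj->nij", n2, n2)
    )
    return tau, J


@dataclass
class PronyHistory:
    """Internal variables for the two-term Prony recurrence (per element).

    The relaxed deviatoric stress is ``tau_inst - h1 - h2`` where each
    internal tensor follows

        h_i <- exp(-dt/tau_i) h_i + C_i (1 - exp(-dt/tau_i)) tau_inst.
    """

    material: OgdenPronyMaterial
    n_elements: int
    h1: np.ndarray = field(init=False)
    h2: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.h1 = np.zeros((self.n_elements, 2, 2))
        self.h2 = np.zeros((self.n_elements, 2, 2))

    def relax(self, tau_inst: np.ndarray, dt: float) -> np.ndarray:
        m = self.material
        a1 = np.exp(-dt / m.tau1)
        a2 = np.exp(-dt / m.tau2)
        self.h1 = a1 * self.h1 + m.C1 * (1.0 - a1) * tau_inst
        self.h2 = a2 * self.h2 + m.C2 * (1.0 - a2) * tau_inst
        return tau_inst - self.h1 - self.h2
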