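"""Structured perturbations of the E-to-E connectivity.

Three kinds of multiplicative scaling break the per-mode excitation-inhibition
balance of the ring network:

* ``global`` — every entry scaled by 1-p (uniform loss of E-to-E strength,
  e.g. NMDA-receptor blockade across the network);
* ``postsynaptic`` — row-wise scaling by a bell-shaped profile centered on a
  group of postsynaptic neurons;
* ``presynaptic`` — column-wise scaling of the outgoing weights of a group of
  presynaptic neurons (e.g. reduced transmitter release).

The local profile is 1 - p*exp(-(d(theta, center)/sigma_p)^2) with d the
wrapped circular distance, so the multiplier is 1-p at the center and tends
to 1 far away.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PerturbationSpec", "perturbation_profile", "apply_perturbation", "KINDS"]

KINDS = ("global", "postsynaptic", "presynaptic")


@dataclass(frozen=True)
class PerturbationSpec:
    """Perturbation kind, strength p in [0, 1), profile width and center.

    ``strength`` is the fractional reduction at the perturbation center: the
    multiplier there is 1-p.  ``sigma_p`` (radians) is the width of the local
    Gaussian profile; it is unused by the global kind.
    """

    kind: str = "global"
    strength: float = 0.1
    sigma_p: float = 0.25 * np.pi
    center: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown perturbation kind {self.kind!r}; expected one of {KINDS}")
        if not (0.0 <= self.strength < 1.0):
            raise ValueError("perturbation strength p must be in [0, 1)")
        if self.kind != "global" and self.sigma_p <= 0:
            raise ValueError("sigma_p must be positive for local perturbations")


def perturbation_profile(spec: PerturbationSpec, N: int,
                         theta_grid: np.ndarray | None = None) -> np.ndarray:
    """Per-neuron multiplier vector of the perturbation.

    Global: the constant vector 1-p.  Local kinds: 1 - p*exp(-(d/sigma_p)^2)
    evaluated at the N preferred features theta_k = -pi + 2*pi*k/N, with d the
    wrapped distance from ``spec.center``.
    """
    if theta_grid is None:
        theta_grid = -np.pi + 2.0 * np.pi * np.arange(N) / N
    if spec.kind == "global":
        return np.full(N, 1.0 - spec.strength)
    delta = np.abs(theta_grid - spec.center) % (2.0 * np.pi)
    d = np.minimum(delta, 2.0 * np.pi - delta)
    return 1.0 - spec.strength * np.exp(-((d / spec.sigma_p) ** 2))


def apply_perturbation(W_EE: np.ndarray, spec: PerturbationSpec) -> np.ndarray:
    """Return the perturbed copy of W_EE; the input matrix is untouched.

    Global scales every entry by 1-p; postsynaptic multiplies row i by the
    profile at theta_i; presynaptic multiplies column j by the profile at
    theta_j.  Only the E-to-E matrix is ever perturbed.
    """
    W_EE = np.asarray(W_EE, dtype=float)
    if W_EE.ndim != 2 or W_EE.shape[0] != W_EE.shape[1]:
        raise ValueError("W_EE must be a square matrix")
    mult = perturbation_profile(spec, W_EE.shape[0])
    if spec.kind == "global":
        return W_EE * (1.0 - spec.strength)
    if spec.kind == "postsynaptic":
        return W_EE * mult[:, None]
    return W_EE * mult[None, :]
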