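"""Unsupervised plasticity rules for excitatory-to-excitatory weights.

Four rules repair the excitation-inhibition balance of a negative-derivative-
feedback memory circuit online:

``differential``
    dW_ij/dt = -alpha_d * (dr_i/dt) * r_j.  Potentiates synapses while the
    postsynaptic rate decays, driving the net drift of persistent activity
    toward zero.
``homeostatic``
    dW_ij/dt = -alpha_h * W_ij * (r_i - r0).  Multiplicative scaling of a
    neuron's incoming weights toward a target rate ``r0``.
``combined``
    W_ij = g_i * U_ij with g following the homeostatic rule and U the
    differential rule.
``saturating_differential``
    The differential rule with the sensed derivative clipped to [-K, K],
    allowing the rule to stay on during stimulation without unlearning.

All update functions accept either scalars (homogeneous population) or
vectors/matrices (ring network) and return the updated weights; matrix
updates never modify their inputs in place.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "PlasticityConfig",
    "CombinedWeightState",
    "differential_update",
    "homeostatic_update",
    "combined_update",
    "saturating_differential_update",
    "plasticity_gate",
    "RULES",
]

RULES = ("none", "differential", "homeostatic", "combined", "saturating_differential")


@dataclass(frozen=True)
class PlasticityConfig:
    """Settings for the plasticity rule applied to E-to-E weights.

    Parameters
    ----------
    rule : str
        One of :data:`RULES`.
    alpha_d : float
        Differential learning rate (used by ``differential``, ``combined``
        and ``saturating_differential``).
    alpha_h : float
        Homeostatic learning rate.
    r0 : float
        Target firing rate of the homeostatic term.
    K : float
        Saturation bound on the sensed rate derivative
        (``saturating_differential`` only), in activity units per time unit.
    always_on : bool
        Keep the rule active during the stimulus epoch as well (the
        saturating always-on mode); default gates plasticity to the delay.
    gate_with_stimulus : bool
        Multiply the gate by ``1 - I_temp(t)`` during the delay so residual
        stimulus drive does not feed the rule (ring network only).
    clip_weights : bool
        Clamp weights at zero after each update.  Off by default: the update
        equations are followed literally.
    """

    rule: str = "none"
    alpha_d: float = 0.0
    alpha_h: float = 0.0
    r0: float = 0.0
    K: float = 0.0
    always_on: bool = False
    gate_with_stimulus: bool = True
    clip_weights: bool = False

    def __post_init__(self) -> None:
        if self.rule not in RULES:
            raise ValueError(f"unknown plasticity rule {self.rule!r}; expected one of {RULES}")
        if self.alpha_d < 0 or self.alpha_h < 0:
            raise ValueError("learning rates must be nonnegative")
        uses_homeo = self.rule in ("homeostatic", "combined") and self.alpha_h > 0
        if uses_homeo and self.r0 <= 0:
            raise ValueError("r0 must be positive when the homeostatic term is active")
        if self.rule == "saturating_differential" and self.K <= 0:
            raise ValueError("K must be positive for the saturating rule")


@dataclass
class CombinedWeightState:
    """Factorized weights W_ij = g_i * U_ij for the combined rule.

    ``g`` is the per-postsynaptic-neuron homeostatic scaling and ``U`` the
    differentially plastic component.  Scalars are accepted for the
    homogeneous population.
    """

    g: np.ndarray | float
    U: np.ndarray | float

    @classmethod
    def from_weights(cls, W: np.ndarray | float) -> "CombinedWeightState":
        if np.ndim(W) == 0:
            return cls(g=1.0, U=float(W))
        W = np.asarray(W, dtype=float)
        return cls(g=np.ones(W.shape[0]), U=W.copy())

    def materialize(self) -> np.ndarray | float:
        """Return W = diag(g) @ U (or g*U in the scalar case)."""
        if np.ndim(self.U) == 0:
            return self.g * self.U
        return np.asarray(self.g)[:, None] * self.U


def differential_update(W, dr_post, r_pre, alpha_d, gate=1.0, dt=1.0):
    """One Euler step of the differential rule.

    W_ij <- W_ij - gate*dt*alpha_d * (dr_i/dt) * r_j; the outer-product
    structure makes the update rank one in the matrix case.
    """
    step = gate * dt * alpha_d
    if np.ndim(W) == 0:
        return W - step * dr_post * r_pre
    return W - step * np.multiply.outer(np.asarray(dr_post), np.asarray(r_pre))


def homeostatic_update(W, r_post, r0, alpha_h, gate=1.0, dt=1.0):
    """One Euler step of multiplicative homeostatic scaling.

    Row i (all incoming synapses of postsynaptic neuron i) is multiplied by
    ``1 - gate*dt*alpha_h*(r_i - r0)``; zero weights stay zero.
    """
    factor = 1.0 - gate * dt * alpha_h * (np.asarray(r_post) - r0)
    if np.ndim(W) == 0:
        return W * float(factor)
    if np.ndim(W) == 1:  # per-neuron scaling vector (combined rule's g)
        return W * factor
    return W * factor[:, None]


def saturating_differential_update(W, dr_post, r_pre, alpha_d, K, gate=1.0, dt=1.0):
    """Differential rule with the sensed derivative clipped to [-K, K].

    Below threshold this is exactly :func:`differential_update`; above it the
    drive saturates at magnitude alpha_d*K*r_j with the sign of dr_i/dt.
    """
    if K <= 0:
        raise ValueError("K must be positive")
    sensed = np.clip(dr_post, -K, K)
    return differential_update(W, sensed, r_pre, alpha_d, gate=gate, dt=dt)


def combined_update(state: CombinedWeightState, dr_post, r_pre, r_post,
                    cfg: PlasticityConfig, gate=1.0, dt=1.0) -> CombinedWeightState:
    """One Euler step of the combined rule on the factorized state.

    g_i <- g_i * (1 - gate*dt*alpha_h*(r_i - r0));
    U_ij <- U_ij - gate*dt*alpha_d*(dr_i/dt)*r_j.
    """
    g = homeostatic_update(state.g, r_post, cfg.r0, cfg.alpha_h, gate=gate, dt=dt)
    U = differential_update(state.U, dr_post, r_pre, cfg.alpha_d, gate=gate, dt=dt)
    return CombinedWeightState(g=g, U=U)


def plasticity_gate(t: float, protocol_or_params, cfg: PlasticityConfig,
                    i_temp: Optional[float] = None) -> float:
    """Gating factor in [0, 1] for the plasticity rule at trial time ``t``.

    For the homogeneous protocol (object with ``t_stim``/``t_delay``/``t_iti``)
    the gate is hard: 0 during stimulus and inter-trial interval, 1 during the
    delay.  For the ring (object with ``t_stim``/``t_total``) the delay-period
    gate is ``1 - I_temp(t)`` when ``cfg.gate_with_stimulus`` is set, damping
    the rule while residual stimulus drive decays.  ``always_on`` forces the
    gate to 1 at all in-trial times (the saturating mode handles the stimulus
    epoch through its derivative bound instead).

    ``i_temp`` supplies the temporal stimulus profile value for the ring; it
    is ignored for the homogeneous protocol.
    """
    if cfg.always_on:
        return 1.0
    t_stim = protocol_or_params.t_stim
    if t < t_stim:
        return 0.0
    if hasattr(protocol_or_params, "t_total"):  # ring parameters
        if t >= protocol_or_params.t_total:
            return 0.0
        if cfg.gate_with_stimulus:
            if i_temp is None:
                raise ValueError("i_temp is required for the ring gate with gate_with_stimulus")
            return 1.0 - i_temp
        return 1.0
    # homogeneous trial protocol
    if t < t_stim + protocol_or_params.t_delay:
        return 1.0
    return 0.0
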