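"""Intersecting Cortical Model (ICM) pulse network.

The ICM is a reduced pulse-coupled neural network: each pixel is a neuron
with three coupled state variables iterated in lockstep,

    F[n+1] = f * F[n] + S + (W * Y[n])        (feeding / internal activation)
    Y[n+1] = 1  if F[n+1] > E[n],  else 0     (pulse)
    E[n+1] = g * E[n] + h * Y[n+1]            (dynamic threshold)

where S is the stimulus image (here the rescaled LoG response), W the 3x3
synaptic link kernel and ``*`` a same-shape 2-D correlation of the previous
pulse image.  The threshold starts high (E = 5 everywhere) and decays
geometrically, so pixels with the strongest stimulus fire first; the
negative threshold amplitude h keeps a fired neuron firing, and the link
kernel lets a fired pixel nudge similar neighbours over threshold.  The
pulse image after n iterations is the segmentation.

Within one step the freshly updated F is compared against the previous
threshold E, following the model's signal flow (F feeds the comparator that
produces Y, which in turn drives the threshold update).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = ["DEFAULT_W", "ICMParams", "ICMState", "init_state", "step_icm", "run_icm"]

#: Default synaptic weight kernel: self-link 1, 4-neighbour links 0.01.
DEFAULT_W = np.array(
    [
        [0.0, 0.01, 0.0],
        [0.01, 1.0, 0.01],
        [0.0, 0.01, 0.0],
    ]
)


@dataclass(frozen=True)
class ICMParams:
    """The network's free constants.

    f, g
        Feeding and threshold decay factors; both in (0, 1) with g < f so
        every stimulated neuron eventually fires (F converges upward toward
        S / (1 - f) while E decays geometrically to 0).
    h
        Threshold amplitude, strictly negative: firing *lowers* the
        threshold so a fired neuron keeps firing.
    n_iterations
        Number of pulse iterations; the pulse image at the last one is the
        segmentation output.
    e_init
        Initial threshold, uniformly applied; set well above the stimulus
        range (default 5) so nothing fires on the first step.
    w
        3x3 link kernel (defaults to DEFAULT_W).
    """

    f: float
    g: float
    h: float
    n_iterations: int
    e_init: float = 5.0
    w: np.ndarray = field(default_factory=lambda: DEFAULT_W.copy())

    def __post_init__(self) -> None:
        for name in ("f", "g", "h", "e_init"):
            object.__setattr__(self, name, float(getattr(self, name)))
        if not (0.0 < self.g < self.f < 1.0):
            raise ValueError(
                f"decay factors must satisfy 0 < g < f < 1, got f={self.f}, g={self.g}"
            )
        if self.h >= 0:
            raise ValueError(f"threshold amplitude h must be negative, got {self.h}")
        if self.n_iterations < 1:
            raise ValueError(f"n_iterations must be >= 1, got {self.n_iterations}")
        if self.e_init <= 1.0:
            raise ValueError(f"e_init must exceed 1, got {self.e_init}")
        w = np.asarray(self.w, dtype=float)
        if w.shape != (3, 3):
            raise ValueError(f"link kernel must be 3x3, got {w.shape}")
        object.__setattr__(self, "w", w)


@dataclass
class ICMState:
    """Evolving per-pixel grids: activation F, threshold E, pulse Y."""

    F: np.ndarray
    E: np.ndarray
    Y: np.ndarray
    iteration: int = 0

    @property
    def shape(self) -> tuple[int, int]:
        return self.F.shape


def init_state(image: np.ndarray, params: ICMParams) -> ICMState:
    """Zero activation and pulses, uniform threshold at ``e_init``."""
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError(f"expected a 2-D stimulus image, got shape {image.shape}")
    return ICMState(
        F=np.zeros_like(image),
        E=np.full(image.shape, float(params.e_init)),
        Y=np.zeros(image.shape, dtype=np.uint8),
        iteration=0,
    )


def step_icm(state: ICMState, s: np.ndarray, params: ICMParams) -> ICMState:
    """Advance the network one iteration.

    Linking uses the *previous* pulse image; outside the frame the pulse is
    taken as 0 (border pixels simply receive less linking input).  Firing
    requires strict inequality F > E; exact ties do not fire.
    """
    s = np.asarray(s, dtype=float)
    if state.shape != s.shape:
        raise ValueError(f"state shape {state.shape} != stimulus shape {s.shape}")
    link = ndimage.correlate(state.Y.astype(float), params.w, mode="constant", cval=0.0)
    F = params.f * state.F + s + link
    Y = (F > state.E).astype(np.uint8)
    E = params.g * state.E + params.h * Y.astype(float)
    return ICMState(F=F, E=E, Y=Y, iteration=state.iteration + 1)


def run_icm(
    image: np.ndarray, params: ICMParams
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Iterate the network ``n_iterations`` times on stimulus ``image``.

    Returns the final pulse image as the segmentation mask plus the full
    per-iteration pulse history for diagnostics.
    """
    state = init_state(image, params)
    history: list[np.ndarray] = []
    for _ in range(params.n_iterations):
        state = step_icm(state, image, params)
        history.append(state.Y.copy())
    return state.Y, history
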