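"""Single-region neural mass generating an EEG/MEG-like alpha rhythm.

A cortical region is lumped into one excitatory (pyramidal) and one
inhibitory population.  Each population carries an average membrane
potential (``Ve``, ``Vi``) and a pulse density (``E``, ``I``).  Potentials
are mapped to pulse densities by sigmoid threshold functions and pulse
densities are mapped back to potentials by second-order synaptic impulse
responses ``h(t) = A * a * t * exp(-a*t)``.  The excitatory population is
driven by stochastic thalamic input and by the output of connected
regions; the inhibitory population is driven by the local excitatory
output and feeds back negatively.  With the default constants the closed
loop resonates in the alpha band (8-13 Hz), which is the regime of
interest for modeling the dominant posterior rhythm and its slowing in
Alzheimer's disease.

The excitatory threshold potential ``Vd1`` is the handle used to emulate
transcranial direct current stimulation: lowering it (7 -> 5) makes the
pyramidal population easier to excite (anodal), raising it (7 -> 9) makes
it harder (cathodal).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

__all__ = [
    "NeuralMassParameters",
    "NeuralMassState",
    "PSPFilterCoefficients",
    "pulse_density",
    "psp_filter_coefficients",
    "psp_filter_step",
    "mass_step",
    "simulate_mass",
    "resolve_thalamic_input",
    "load_parameter_profile",
]


def load_parameter_profile(name: str = "defaults") -> "NeuralMassParameters":
    """Load a named parameter profile shipped with the package.

    Profiles are YAML files under ``tdcsim/data``; the ``defaults``
    profile is the alpha-band parameterization used throughout.
    """
    import yaml
    from importlib import resources

    text = resources.files("tdcsim.data").joinpath(f"{name}.yaml").read_text()
    payload = yaml.safe_load(text)
    for key in ("he_params", "hi_params", "sigmoid_steepness", "thalamic_input"):
        if key in payload:
            payload[key] = tuple(payload[key])
    return NeuralMassParameters(**payload)


@dataclass
class NeuralMassParameters:
    """Constants of one neural mass.

    Parameters
    ----------
    Vd1, Vd2 : float
        Threshold potentials (model units, mV-like) of the excitatory and
        inhibitory populations.  ``Vd1`` defaults to 7 and takes the values
        5 (anodal) or 9 (cathodal) under stimulation.
    C1, C2 : float
        Intra-mass coupling strengths: ``C1`` scales the excitatory drive
        onto the inhibitory population, ``C2`` scales the inhibitory
        feedback onto the excitatory population.
    he_params, hi_params : (float, float)
        Amplitude ``A`` (model units) and rate constant ``a`` (1/s) of the
        excitatory and inhibitory postsynaptic impulse responses
        ``h(t) = A * a * t * exp(-a t)``.
    sigmoid_steepness : (float, float)
        Slope constants of the excitatory and inhibitory sigmoids
        (1 / model unit).
    thalamic_input : (float | None, float | None)
        Mean and standard deviation of the stochastic thalamic pulse
        density ``P(t)`` (pulses per second), drawn independently per mass
        and per step and clipped at zero.  ``None`` entries are resolved
        by :func:`resolve_thalamic_input`: the mean is calibrated so the
        healthy operating point sits at the excitatory sigmoid midpoint
        (given the mean network drive), and the standard deviation
        defaults to a tenth of the mean.
    dmax : float
        Saturation pulse density of both sigmoids (pulses per second).
    coupling_gain : float
        Synaptic gain applied to the summed pulse density arriving from
        connected masses (dimensionless synapse-count factor).
    input_gain : float
        Multiplier on all excitatory afferents of the mass (thalamic and
        inter-mass).  1 in the intact mass; reduced by the degeneration
        process.
    """

    Vd1: float = 7.0
    Vd2: float = 7.0
    C1: float = 86.154
    C2: float = 1.655
    he_params: tuple[float, float] = (3.25, 100.0)
    hi_params: tuple[float, float] = (22.0, 45.0)
    sigmoid_steepness: tuple[float, float] = (0.56, 2.24)
    thalamic_input: tuple[float | None, float | None] = (None, None)
    dmax: float = 5.0
    coupling_gain: float = 2.0
    input_gain: float = 1.0

    def __post_init__(self) -> None:
        if self.he_params[1] <= 0 or self.hi_params[1] <= 0:
            raise ValueError("PSP rate constants must be positive")
        if self.sigmoid_steepness[0] <= 0 or self.sigmoid_steepness[1] <= 0:
            raise ValueError("sigmoid steepness must be positive")
        if self.thalamic_input[1] is not None and self.thalamic_input[1] < 0:
            raise ValueError("thalamic input variance must be non-negative")
        if self.dmax <= 0:
            raise ValueError("saturation density must be positive")

    def copy(self, **changes) -> "NeuralMassParameters":
        return replace(self, **changes)


def resolve_thalamic_input(
    params: NeuralMassParameters,
    mean_network_input: float = 0.0,
    noise_fraction: float = 0.1,
) -> NeuralMassParameters:
    """Fill unset thalamic-input statistics of a parameter set.

    The mean pulse density is calibrated so that, with every population at
    its sigmoid midpoint and an average inter-mass drive of
    ``mean_network_input`` (summed neighbor pulse density before the
    coupling gain), the excitatory potential settles exactly at the
    threshold ``Vd1`` - the operating point at which the alpha resonance
    is strongest and from which degeneration-driven drift is monotone.
    An explicitly set mean (or standard deviation) is left untouched.
    """
    mean, sd = params.thalamic_input
    if mean is None:
        A, a = params.he_params
        B, b = params.hi_params
        half = params.dmax / 2.0
        mean = (
            params.Vd1 * a / A
            + params.C2 * (B / b) * half * a / A
            - params.coupling_gain * mean_network_input
        )
        if mean <= 0:
            raise ValueError("calibrated thalamic mean is non-positive; lower the network drive")
    if sd is None:
        sd = noise_fraction * mean
    return params.copy(thalamic_input=(float(mean), float(sd)))


@dataclass
class NeuralMassState:
    """Dynamic state of one mass.

    ``filter_state`` holds three second-order filter states, each a pair
    ``(y, dy)``: the excitatory PSP filter feeding ``Ve``, the inhibitory
    PSP filter feeding ``Ve`` (weighted by ``C2``), and the excitatory PSP
    filter feeding ``Vi`` (weighted by ``C1``).
    """

    Ve: float = 0.0
    Vi: float = 0.0
    E: float = 0.0
    I: float = 0.0
    filter_state: np.ndarray = field(default_factory=lambda: np.zeros((3, 2)))

    def validate(self) -> None:
        if not np.all(np.isfinite(self.filter_state)):
            raise FloatingPointError("non-finite neural mass filter state")


def pulse_density(V, threshold, steepness, dmax=5.0):
    """Sigmoid mapping membrane potential to pulse density.

    ``dmax / (1 + exp(-steepness * (V - threshold)))``: zero for strongly
    hyperpolarized potentials, ``dmax`` at saturation, ``dmax / 2`` at the
    threshold.  Vectorized over ``V``.
    """
    V = np.asarray(V, dtype=float)
    if np.ndim(steepness) == 0 and steepness <= 0:
        raise ValueError("steepness must be positive")
    if not np.all(np.isfinite(V)):
        raise FloatingPointError("non-finite membrane potential")
    x = np.asarray(steepness, dtype=float) * (V - np.asarray(threshold, dtype=float))
    # guard exp overflow for strongly negative drive
    out = dmax / (1.0 + np.exp(-np.clip(x, -700.0, 700.0)))
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class PSPFilterCoefficients:
    """Zero-order-hold discretization of ``H(s) = A a / (s + a)^2``.

    The continuous filter is advanced exactly over one step of length
    ``dt`` under the assumption that the input is constant within the
    step.  For the critically damped double pole the transition matrix has
    the closed form ``exp(-a dt) [[1 + a dt, dt], [-a^2 dt, 1 - a dt]]``.
    """

    a11: float
    a12: float
    a21: float
    a22: float
    b1: float
    b2: float


def psp_filter_coefficients(A: float, a: float, dt: float) -> PSPFilterCoefficients:
    if dt <= 0:
        raise ValueError("dt must be positive")
    if a <= 0:
        raise ValueError("rate constant must be positive")
    ead = math.exp(-a * dt)
    return PSPFilterCoefficients(
        a11=ead * (1.0 + a * dt),
        a12=ead * dt,
        a21=-ead * a * a * dt,
        a22=ead * (1.0 - a * dt),
        b1=A * (1.0 - ead * (1.0 + a * dt)) / a,
        b2=A * a * ead * dt,
    )


def psp_filter_step(filter_state, input_density, coeffs: PSPFilterCoefficients):
    """Advance one PSP filter by one step.

    Parameters
    ----------
    filter_state : array-like, shape (2,) or (2, n)
        ``(y, dy)`` where ``y`` is the output potential contribution.
    input_density : float or array
        Pulse density driving the filter, held constant over the step.

    Returns
    -------
    (new_state, y) with ``y`` the potential contribution after the step.
    """
    y, dy = np.asarray(filter_state, dtype=float)
    u = np.asarray(input_density, dtype=float)
    y_new = coeffs.a11 * y + coeffs.a12 * dy + coeffs.b1 * u
    dy_new = coeffs.a21 * y + coeffs.a22 * dy + coeffs.b2 * u
    state = np.stack([y_new, dy_new])
    return state, y_new


def mass_step(
    state: NeuralMassState,
    params: NeuralMassParameters,
    external_input: float,
    noise_draw: float,
    dt: float,
    *,
    _coeffs: tuple[PSPFilterCoefficients, PSPFilterCoefficients] | None = None,
) -> NeuralMassState:
    """One integration step of the excitatory-inhibitory loop.

    The current potentials are read from the filter states, converted to
    pulse densities through the sigmoids, and the three filters are then
    advanced with their inputs: thalamic plus network drive (scaled by the
    mass's ``input_gain``) for the excitatory PSP onto ``Ve``, the
    inhibitory density for the feedback PSP onto ``Ve`` and the excitatory
    density for the PSP onto ``Vi``.
    """
    if external_input < 0:
        raise ValueError("external input pulse density must be non-negative")
    if _coeffs is None:
        he = psp_filter_coefficients(*params.he_params, dt)
        hi = psp_filter_coefficients(*params.hi_params, dt)
    else:
        he, hi = _coeffs

    fs = state.filter_state
    Ve = fs[0, 0] - params.C2 * fs[1, 0]
    Vi = params.C1 * fs[2, 0]
    if not (np.isfinite(Ve) and np.isfinite(Vi)):
        raise FloatingPointError("neural mass produced a non-finite potential")
    E = pulse_density(Ve, params.Vd1, params.sigmoid_steepness[0], params.dmax)
    I = pulse_density(Vi, params.Vd2, params.sigmoid_steepness[1], params.dmax)

    # synaptic loss (input_gain < 1) attenuates the mean afferent drive and
    # the inter-mass coupling; the stochastic background fluctuation rides
    # on top unattenuated, so a deafferented mass is quiet but not noiseless
    p_mean = params.thalamic_input[0]
    if p_mean is None:
        raise ValueError("thalamic input unresolved; call resolve_thalamic_input first")
    drive = max(
        params.input_gain * (p_mean + params.coupling_gain * external_input)
        + max(noise_draw, 0.0)
        - p_mean,
        0.0,
    )
    s0, _ = psp_filter_step(fs[0], drive, he)
    s1, _ = psp_filter_step(fs[1], I, hi)
    s2, _ = psp_filter_step(fs[2], E, he)
    new = NeuralMassState(Ve=Ve, Vi=Vi, E=E, I=I, filter_state=np.stack([s0, s1, s2]))
    new.validate()
    return new


def simulate_mass(
    params: NeuralMassParameters,
    n_steps: int,
    dt: float = 1e-3,
    rng: np.random.Generator | int | None = None,
    external_input: float | Iterable[float] = 0.0,
) -> dict[str, np.ndarray]:
    """Simulate one isolated mass; returns ``Ve``, ``E`` time series.

    Thalamic input is drawn from the mass's configured Gaussian pulse
    density, clipped at zero.  Deterministic given the generator state.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    rng = np.random.default_rng(rng)
    params = resolve_thalamic_input(params)
    he = psp_filter_coefficients(*params.he_params, dt)
    hi = psp_filter_coefficients(*params.hi_params, dt)
    mean, sd = params.thalamic_input
    noise = np.clip(rng.normal(mean, sd, n_steps), 0.0, None) if sd > 0 else np.full(n_steps, float(mean))
    ext = np.broadcast_to(np.asarray(external_input, dtype=float), (n_steps,))
    state = NeuralMassState()
    Ve = np.empty(n_steps)
    E = np.empty(n_steps)
    for t in range(n_steps):
        state = mass_step(state, params, float(ext[t]), float(noise[t]), dt, _coeffs=(he, hi))
        Ve[t] = state.Ve
        E[t] = state.E
    return {"Ve": Ve, "E": E}
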