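"""Synthetic bilateral swimming traces from a two-unit half-center CPG.

The generator is a Matsuoka-style half-center: two rectified leaky units with
slow self-adaptation, coupled by crossed inhibition (glycinergic in the larva)
and optionally by weak crossed excitation.  Tonic excitatory drive (glutamate
in the reduced preparation) sets the tempo of the network: the unit dynamics
are integrated on a drive-scaled clock, so oscillation frequency grows
proportionally with effective drive, as larval swimming frequency does with
bath glutamate concentration.  Tonic GABAergic modulation divides the
effective drive, so removing it (picrotoxin) raises the frequency without
touching the crossed inhibition that enforces left/right alternation.

With crossed inhibition intact the two sides lock close to antiphase (a small
left/right drive asymmetry shifts the locked phase slightly past 0.5, matching
the measured 0.54).  With crossed inhibition removed (strychnine, antisense
morpholino) each unit is a damped oscillatory focus whose rhythm is sustained
by stochastic drive fluctuation: both sides stay rhythmic at an unchanged
frequency but their relative phase diffuses, so the strict L/R alternation
breaks down.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ParameterError, UnknownConditionError
from .trace import BilateralTrace, make_time_grid

__all__ = [
    "CPGParams",
    "ConditionPreset",
    "simulate_cpg",
    "simulate_cohort",
    "preset",
    "preset_names",
    "BASE_FREQ_HZ",
]

#: Integration oversampling factor (fixed-step Euler-Maruyama runs at
#: ``oversample * rate_hz`` and is then decimated).
OVERSAMPLE = 10

#: First-order output low-pass time constant (s), mimicking muscle/optical
#: smoothing of the motor rhythm.
OUTPUT_LP_S = 0.020

#: OU drive-noise correlation time (s).
NOISE_TAU_S = 0.050

#: Simulated-but-discarded lead-in (s): lets the network forget its fixed
#: initial state so traces start in the stationary regime (uncoupled sides
#: start with randomized relative phase, coupled sides start locked).
BURN_IN_S = 2.0

#: Network frequency (Hz) at unit effective drive for the default time
#: constants, adaptation gain and left/right asymmetry; measured once from
#: the simulator and used to convert target frequencies into preset drive
#: levels (frequency scales proportionally with effective drive).
BASE_FREQ_HZ = 12.17


@dataclass
class CPGParams:
    """Half-center CPG parameterization.

    drive : tonic excitatory input (dimensionless >= 0); effective drive
        ``drive / (1 + gaba_tone)`` sets the network tempo.
    w_inh : crossed inhibitory gain (>= 0); ~0 models strychnine / antisense
        morpholino block of glycinergic transmission.
    w_exc : weak crossed excitatory gain (>= 0); default 0 (its presence in
        the larva is uncertain).
    gaba_tone : tonic modulatory inhibition of drive (>= 0); ~0 models
        picrotoxin.
    tau_act, tau_adapt : activation and adaptation time constants (s),
        ``tau_adapt > tau_act > 0``.
    b_adapt : adaptation gain (>= 0).
    asym : left/right drive imbalance; ``drive_L = drive*(1+asym)``,
        ``drive_R = drive*(1-asym)``; produces a locked phase != 0.5.
    noise_sd : stationary SD of the OU drive fluctuation.
    episode_on : enable slow episode gating (swimming bouts); default off.
    duration_s, rate_hz, seed : simulation length, output sampling rate, RNG
        seed.
    """

    drive: float = 1.15
    w_inh: float = 2.0
    w_exc: float = 0.0
    gaba_tone: float = 0.15
    tau_act: float = 0.059
    tau_adapt: float = 0.074
    b_adapt: float = 30.0
    asym: float = -0.045
    noise_sd: float = 0.05
    episode_on: bool = False
    duration_s: float = 20.0
    rate_hz: float = 500.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("drive", "w_inh", "w_exc", "gaba_tone", "b_adapt",
                     "noise_sd"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v >= 0):
                raise ParameterError(f"{name}: must be finite and >= 0, got {v}")
        if not (np.isfinite(self.tau_act) and self.tau_act > 0):
            raise ParameterError(f"tau_act: must be > 0, got {self.tau_act}")
        if not (np.isfinite(self.tau_adapt) and self.tau_adapt > self.tau_act):
            raise ParameterError(
                f"tau_adapt: must exceed tau_act ({self.tau_act}), "
                f"got {self.tau_adapt}"
            )
        if not (np.isfinite(self.rate_hz) and self.rate_hz >= 100):
            raise ParameterError(f"rate_hz: must be >= 100, got {self.rate_hz}")
        if not (np.isfinite(self.duration_s) and self.duration_s > 0):
            raise ParameterError(
                f"duration_s: must be > 0, got {self.duration_s}")
        if not (np.isfinite(self.asym) and abs(self.asym) < 1):
            raise ParameterError(f"asym: must satisfy |asym| < 1, got {self.asym}")
        if not float(self.seed).is_integer():
            raise ParameterError(f"seed: must be an integer, got {self.seed}")

    def replace(self, **changes) -> "CPGParams":
        return replace(self, **changes)


@dataclass
class ConditionPreset:
    """A named experimental condition mapped onto CPG parameters.

    ``expected_freq_band`` is the calibration band (Hz) the left-side
    frequency of a simulated cohort should fall in; ``phase_expected`` is the
    expected contralateral phase, or the string ``"undefined"`` when crossed
    inhibition is absent and no stable phase exists.
    """

    name: str
    params: CPGParams
    expected_freq_band: tuple[float, float]
    phase_expected: float | str

    def __post_init__(self) -> None:
        lo, hi = self.expected_freq_band
        if not lo < hi:
            raise ParameterError(
                f"expected_freq_band: low must be < high, got ({lo}, {hi})")


# ---------------------------------------------------------------------------
# simulator
# ---------------------------------------------------------------------------
def simulate_cpg(params: CPGParams) -> BilateralTrace:
    """Integrate the half-center CPG and return a bilateral trace.

    Fixed-step Euler-Maruyama at ``OVERSAMPLE * rate_hz``, decimated to
    ``rate_hz``; the output per side is the rectified activation passed
    through a first-order 20 ms low-pass.  Deterministic for a fixed seed.
    """
    params.validate()
    p = params
    n_out = int(round(p.duration_s * p.rate_hz))
    if n_out < 2:
        raise ParameterError(
            f"duration_s: too short for rate_hz ({n_out} samples)")
    n_burn = int(round(BURN_IN_S * p.rate_hz))
    dt = 1.0 / (p.rate_hz * OVERSAMPLE)
    rng = np.random.default_rng(p.seed)

    d_eff = p.drive / (1.0 + p.gaba_tone)
    tempo = np.array([d_eff * (1.0 + p.asym), d_eff * (1.0 - p.asym)])
    if np.any(tempo < 0):
        raise ParameterError("asym: effective drive became negative")

    # state: activation u, adaptation v, OU noise xi, output low-pass z
    u = np.array([0.01, -0.01])
    v = np.zeros(2)
    xi = np.zeros(2)
    z = np.zeros(2)
    out = np.empty((n_burn + n_out, 2))

    noise_scale = p.noise_sd * math.sqrt(2.0 * dt / NOISE_TAU_S)
    lp_a = dt / OUTPUT_LP_S
    # episode gating: bouts of swimming separated by quiescent gaps; bout
    # length grows when tonic GABAergic modulation is removed.
    if p.episode_on:
        bout_on_s = 2.0 * (1.0 + max(0.0, 0.3 - p.gaba_tone) / 0.3)
        bout_off_s = 1.0
        bout_period = bout_on_s + bout_off_s
    n_steps = (n_burn + n_out) * OVERSAMPLE
    eta = rng.standard_normal((n_steps, 2))
    k_out = 0
    for step in range(n_steps):
        gate = 1.0
        if p.episode_on:
            gate = 1.0 if (step * dt) % bout_period < bout_on_s else 0.0
        y = np.maximum(u, 0.0)
        cross = (p.w_exc - p.w_inh) * y[::-1]
        du = (-u + 1.0 + cross - p.b_adapt * v + xi) / p.tau_act
        dv = (-v + y) / p.tau_adapt
        rate = tempo * gate
        u = u + dt * rate * du
        v = v + dt * rate * dv
        xi = xi + dt * (-xi / NOISE_TAU_S) + noise_scale * eta[step]
        z = z + lp_a * (np.maximum(u, 0.0) - z)
        if (step + 1) % OVERSAMPLE == 0:
            out[k_out] = z
            k_out += 1

    out = out[n_burn:]
    t = make_time_grid(n_out, p.rate_hz)
    return BilateralTrace(
        t=t, left=out[:, 0], right=out[:, 1], rate_hz=p.rate_hz,
        condition="", seed=p.seed,
    )


def simulate_cohort(
    cond: "ConditionPreset | str", n: int, base_seed: int = 0,
    **overrides,
) -> list[BilateralTrace]:
    """Simulate ``n`` animals from a preset with seeds ``base_seed..base_seed+n-1``.

    ``overrides`` patch any :class:`CPGParams` field (e.g. ``duration_s``).
    """
    if n < 1:
        raise ParameterError(f"n: must be >= 1, got {n}")
    if isinstance(cond, str):
        cond = preset(cond)
    traces = []
    for i in range(n):
        p = cond.params.replace(seed=base_seed + i, **overrides)
        tr = simulate_cpg(p)
        tr.condition = cond.name
        traces.append(tr)
    return traces


# ---------------------------------------------------------------------------
# condition registry
# ---------------------------------------------------------------------------
def _drive_for(freq_hz: float, gaba_tone: float) -> float:
    """Drive level whose effective drive maps to ``freq_hz`` at the default
    time constants (frequency scales proportionally with effective drive)."""
    return (1.0 + gaba_tone) * freq_hz / BASE_FREQ_HZ


def _build_registry() -> dict[str, ConditionPreset]:
    gaba = 0.15
    intact = CPGParams(drive=_drive_for(12.24, gaba), gaba_tone=gaba)
    reg = {}

    def add(name, params, band, phase):
        reg[name] = ConditionPreset(
            name=name, params=params, expected_freq_band=band,
            phase_expected=phase,
        )

    add("intact", intact, (11.2, 13.3), 0.54)
    add("headless_glut_100uM",
        intact.replace(drive=_drive_for(24.4, gaba)), (23.4, 25.4), 0.54)
    add("headless_glut_10uM",
        intact.replace(drive=_drive_for(11.68, gaba)), (10.4, 13.0), 0.54)
    # strychnine blocks glycinergic crossed inhibition; rhythm on each side
    # persists (noise-sustained) but phase locking is lost
    add("strychnine", intact.replace(w_inh=0.0), (11.2, 13.3), "undefined")
    # picrotoxin removes tonic GABAergic modulation: effective drive rises,
    # frequency climbs ~15%, alternation is untouched
    add("picrotoxin", intact.replace(gaba_tone=0.0), (12.5, 15.5), 0.53)
    add("mo_antisense", intact.replace(w_inh=0.0), (11.2, 13.3), "undefined")
    add("mo_mismatch", intact, (11.2, 13.3), 0.54)
    return reg


_REGISTRY = _build_registry()


def preset_names() -> list[str]:
    return sorted(_REGISTRY)


def preset(name: str) -> ConditionPreset:
    """Look up a calibrated condition preset by name."""
    try:
        return _REGISTRY[name]
    except KeyError:
        raise UnknownConditionError(
            f"unknown condition {name!r}; valid names: {', '.join(preset_names())}"
        ) from None
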