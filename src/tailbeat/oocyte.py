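"""Heterologous-expression analyses: Hill dose-response, reversal potential,
Nernst predictions and ion-substitution classification.

A glycine-gated channel expressed in *Xenopus* oocytes is characterized by
(i) the agonist concentration producing half-maximal current (EC50) from a
Hill fit of the normalized dose-response curve, and (ii) its permeant ion,
inferred by comparing measured reversal-potential shifts under ion
substitution with the Nernst predictions for each candidate ion.  A chloride
channel's reversal potential follows the Cl- Nernst potential: lowering bath
Cl- (methanesulphonate substitution) shifts it strongly positive, while
replacing Na+/K+ with NMDG+ leaves it unchanged.

The module also provides a synthetic current generator (ohmic leak + agonist
conductance with a Nernstian reversal) so every analysis can be validated by
generator/refit round trips.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import (
    IllConditionedFitError,
    OutOfRangeError,
    ParameterError,
    UnknownConditionError,
)

__all__ = [
    "BathSolution",
    "DoseResponseTable",
    "HillFit",
    "IVRamp",
    "ReceptorParams",
    "bath_solution",
    "bath_names",
    "nernst",
    "nernst_potential_mv",
    "fit_hill",
    "hill_curve",
    "reversal_potential",
    "simulate_dose_response",
    "simulate_iv_ramp",
    "substitution_shift",
    "INTERNAL_MM",
]

R_GAS = 8.314462618        # J / (mol K)
FARADAY = 96485.33212      # C / mol

#: Default intracellular concentrations (mM) for a *Xenopus* oocyte.
#: Internal Cl- of 40 mM is a typical oocyte value; configurable per call.
INTERNAL_MM = {"Na+": 10.0, "K+": 110.0, "Cl-": 40.0}

ION_VALENCE = {"Na+": +1, "K+": +1, "Cl-": -1}


@dataclass
class BathSolution:
    """Extracellular solution composition (mM) and recording temperature."""

    name: str
    na_mM: float = 0.0
    k_mM: float = 0.0
    ca_mM: float = 0.0
    mg_mM: float = 0.0
    cl_mM: float = 0.0
    nmdg_mM: float = 0.0       # N-methyl-D-glucamine (impermeant cation)
    mets_mM: float = 0.0       # methanesulphonate (impermeant anion)
    temperature_c: float = 20.0

    def __post_init__(self) -> None:
        for f in ("na_mM", "k_mM", "ca_mM", "mg_mM", "cl_mM",
                  "nmdg_mM", "mets_mM"):
            if getattr(self, f) < 0:
                raise ParameterError(f"{f}: concentration must be >= 0")

    def concentration(self, ion: str) -> float:
        return {"Na+": self.na_mM, "K+": self.k_mM, "Cl-": self.cl_mM}[ion]


def _build_baths() -> dict[str, BathSolution]:
    # ND96: 96 NaCl, 2 KCl, 2 CaCl2, 1.8 MgCl2 (5 Hepes buffer ignored);
    # total Cl- = 96 + 2 + 4 + 3.6 = 105.6 mM
    nd96 = BathSolution("nd96", na_mM=96, k_mM=2, ca_mM=2, mg_mM=1.8,
                        cl_mM=105.6)
    # Substitution recipes are plausible reconstructions (the exact low-Cl-
    # and low-Na+/K+ compositions are assumptions, not published values):
    # low Cl-: NaCl replaced by Na-methanesulphonate, divalent chlorides kept
    low_cl = BathSolution("low_cl_mets", na_mM=96, k_mM=2, ca_mM=2, mg_mM=1.8,
                          cl_mM=9.6, mets_mM=96)
    # low Na+/K+: NaCl and most KCl replaced by NMDG-Cl; small residual
    # Na+/K+ keeps Nernst predictions finite
    low_na_k = BathSolution("low_na_k_nmdg", na_mM=1.0, k_mM=0.5, ca_mM=2,
                            mg_mM=1.8, cl_mM=105.6, nmdg_mM=96.5)
    return {b.name: b for b in (nd96, low_cl, low_na_k)}


_BATHS = _build_baths()


def bath_names() -> list[str]:
    return sorted(_BATHS)


def bath_solution(name: str) -> BathSolution:
    try:
        return _BATHS[name]
    except KeyError:
        raise UnknownConditionError(
            f"unknown bath {name!r}; valid names: {', '.join(bath_names())}"
        ) from None


# ---------------------------------------------------------------------------
# Nernst potentials
# ---------------------------------------------------------------------------
def nernst_potential_mv(
    valence: int, out_mM: float, in_mM: float, temperature_c: float = 20.0
) -> float:
    """Nernst equilibrium potential ``E = (RT/zF) ln([out]/[in])`` in mV."""
    if valence == 0:
        raise ParameterError("valence: must be non-zero")
    if out_mM <= 0 or in_mM <= 0:
        raise ParameterError(
            f"concentrations must be > 0, got out={out_mM}, in={in_mM}")
    t_kelvin = temperature_c + 273.15
    return 1000.0 * R_GAS * t_kelvin / (valence * FARADAY) * math.log(out_mM / in_mM)


def nernst(ion: str, bath: BathSolution, internal_mM: float | None = None) -> float:
    """Nernst potential (mV) of ``ion`` ("Na+", "K+" or "Cl-") in a bath.

    Internal concentration defaults to the oocyte values in
    :data:`INTERNAL_MM`.
    """
    if ion not in ION_VALENCE:
        raise ParameterError(
            f"ion: must be one of {sorted(ION_VALENCE)}, got {ion!r}")
    if internal_mM is None:
        internal_mM = INTERNAL_MM[ion]
    return nernst_potential_mv(
        ION_VALENCE[ion], bath.concentration(ion), internal_mM,
        bath.temperature_c,
    )


# ---------------------------------------------------------------------------
# dose-response
# ---------------------------------------------------------------------------
@dataclass
class DoseResponseTable:
    """Rows of (concentration [M], normalized response, replicate id)."""

    concentration_M: np.ndarray
    response: np.ndarray
    replicate: np.ndarray

    def __post_init__(self) -> None:
        self.concentration_M = np.asarray(self.concentration_M, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        self.replicate = np.asarray(self.replicate)
        if not (len(self.concentration_M) == len(self.response) == len(self.replicate)):
            raise ParameterError("dose-response table: column length mismatch")
        if np.any(self.concentration_M <= 0):
            raise ParameterError("concentration_M: must be > 0")
        if not np.all(np.isfinite(self.response)):
            raise ParameterError("response: contains non-finite values")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "concentration_M": self.concentration_M,
            "response": self.response,
            "replicate": self.replicate,
        })

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DoseResponseTable":
        missing = {"concentration_M", "response"} - set(df.columns)
        if missing:
            raise ParameterError(
                f"dose-response table: missing columns {sorted(missing)}")
        rep = df["replicate"] if "replicate" in df.columns else np.zeros(len(df), int)
        return cls(df["concentration_M"].to_numpy(),
                   df["response"].to_numpy(), np.asarray(rep))


@dataclass
class HillFit:
    """Hill-equation fit ``r = r_max * c^n / (c^n + ec50^n)``."""

    ec50_M: float
    hill_n: float
    r_max: float
    residual_sse: float

    def __post_init__(self) -> None:
        if not (self.ec50_M > 0 and self.hill_n > 0 and self.r_max > 0):
            raise ParameterError("HillFit: ec50, hill_n and r_max must be > 0")


def hill_curve(conc_M, ec50_M: float, hill_n: float, r_max: float):
    conc_M = np.asarray(conc_M, dtype=float)
    cn = conc_M ** hill_n
    return r_max * cn / (cn + ec50_M ** hill_n)


def fit_hill(table: DoseResponseTable) -> HillFit:
    """Least-squares Hill fit of a dose-response table.

    Requires at least 4 distinct concentrations spanning >= 1.5 log10 units.
    Initialization: ``r_max`` = max response, ``ec50`` = dose nearest
    half-max, ``n`` = 1; the Hill coefficient is bounded to [0.3, 6].
    """
    doses = np.unique(table.concentration_M)
    if len(doses) < 4:
        raise IllConditionedFitError(
            f"need >= 4 distinct concentrations, got {len(doses)}")
    span = math.log10(doses.max() / doses.min())
    if span < 1.5:
        raise IllConditionedFitError(
            f"doses span {span:.2f} log10 units; need >= 1.5")
    c = table.concentration_M
    r = table.response
    r_max0 = float(np.max(r))
    if r_max0 <= 0:
        raise IllConditionedFitError("all responses <= 0; cannot fit")
    half = 0.5 * r_max0
    ec50_0 = float(c[np.argmin(np.abs(r - half))])
    p0 = [ec50_0, 1.0, r_max0]
    bounds = ([1e-12, 0.3, 1e-12], [np.inf, 6.0, np.inf])
    try:
        popt, _ = curve_fit(
            lambda cc, ec50, n, rmax: hill_curve(cc, ec50, n, rmax),
            c, r, p0=p0, bounds=bounds, maxfev=20000,
        )
    except RuntimeError as err:
        raise IllConditionedFitError(f"Hill fit failed to converge: {err}") from None
    resid = r - hill_curve(c, *popt)
    return HillFit(ec50_M=float(popt[0]), hill_n=float(popt[1]),
                   r_max=float(popt[2]), residual_sse=float(np.sum(resid ** 2)))


# ---------------------------------------------------------------------------
# synthetic currents
# ---------------------------------------------------------------------------
@dataclass
class ReceptorParams:
    """Agonist-gated channel: max conductance (uS), EC50 (M), Hill n, and the
    ion it conducts (sets the reversal potential from the bath)."""

    g_max_uS: float = 10.0
    ec50_M: float = 7.5e-4
    hill_n: float = 1.5
    permeant_ion: str = "Cl-"

    def __post_init__(self) -> None:
        if self.ec50_M <= 0:
            raise ParameterError("ec50_M: must be > 0")
        if self.hill_n <= 0:
            raise ParameterError("hill_n: must be > 0")
        if self.g_max_uS <= 0:
            raise ParameterError("g_max_uS: must be > 0")
        if self.permeant_ion not in ION_VALENCE:
            raise ParameterError(f"permeant_ion: unknown ion {self.permeant_ion!r}")

    def occupancy(self, conc_M) -> np.ndarray:
        return np.asarray(hill_curve(conc_M, self.ec50_M, self.hill_n, 1.0))


def simulate_dose_response(
    receptor: ReceptorParams | None = None,
    doses_M=None,
    noise_sd: float = 0.02,
    n_replicates: int = 3,
    seed: int | None = 0,
) -> DoseResponseTable:
    """Normalized dose-response data at a fixed holding potential.

    Default doses span the tested range 30 uM - 3 mM; responses are the Hill
    occupancy (current normalized to its asymptotic maximum) plus Gaussian
    noise of SD ``noise_sd``.
    """
    if receptor is None:
        receptor = ReceptorParams()
    if doses_M is None:
        doses_M = np.geomspace(30e-6, 3e-3, 7)
    doses_M = np.asarray(doses_M, dtype=float)
    rng = np.random.default_rng(seed)
    conc = np.repeat(doses_M, n_replicates)
    rep = np.tile(np.arange(n_replicates), len(doses_M))
    resp = receptor.occupancy(conc)
    if noise_sd > 0:
        resp = resp + rng.normal(0.0, noise_sd, resp.shape)
    return DoseResponseTable(conc, resp, rep)


@dataclass
class IVRamp:
    """Voltage-ramp record: command voltage (mV), total current (nA), and the
    matching pre-agonist leak ramp when available."""

    voltage_mV: np.ndarray
    current_nA: np.ndarray
    leak_nA: np.ndarray | None = None
    protocol: str = ""

    def __post_init__(self) -> None:
        self.voltage_mV = np.asarray(self.voltage_mV, dtype=float)
        self.current_nA = np.asarray(self.current_nA, dtype=float)
        if len(self.voltage_mV) != len(self.current_nA):
            raise ParameterError("IVRamp: voltage/current length mismatch")
        if len(self.voltage_mV) < 2:
            raise ParameterError("IVRamp: need >= 2 samples")
        dv = np.diff(self.voltage_mV)
        if not (np.all(dv > 0) or np.all(dv < 0)):
            raise ParameterError("IVRamp: voltage must be monotone")
        if self.leak_nA is not None:
            self.leak_nA = np.asarray(self.leak_nA, dtype=float)
            if len(self.leak_nA) != len(self.voltage_mV):
                raise ParameterError("IVRamp: leak length mismatch")


def simulate_iv_ramp(
    receptor: ReceptorParams | None = None,
    bath: BathSolution | None = None,
    agonist_M: float = 1e-3,
    v_start_mV: float = -80.0,
    v_end_mV: float = 40.0,
    n_points: int = 241,
    g_leak_uS: float = 1.0,
    e_leak_mV: float = -35.0,
    noise_sd_frac: float = 0.0,
    seed: int | None = 0,
) -> IVRamp:
    """Synthetic two-electrode voltage-clamp ramp.

    Total current = ohmic leak + agonist-gated current
    ``g_max * occ * (V - E_rev)`` with ``E_rev`` the Nernst potential of the
    receptor's permeant ion in the bath.  The pre-agonist leak ramp is
    generated alongside, with independent noise.  ``noise_sd_frac`` scales
    Gaussian current noise relative to the peak agonist current.
    """
    if receptor is None:
        receptor = ReceptorParams()
    if bath is None:
        bath = bath_solution("nd96")
    rng = np.random.default_rng(seed)
    v = np.linspace(v_start_mV, v_end_mV, n_points)
    e_rev = nernst(receptor.permeant_ion, bath)
    occ = float(receptor.occupancy(agonist_M))
    i_agonist = receptor.g_max_uS * occ * (v - e_rev)     # uS * mV = nA
    i_leak = g_leak_uS * (v - e_leak_mV)
    if noise_sd_frac > 0:
        sd = noise_sd_frac * np.max(np.abs(i_agonist))
        total = i_leak + i_agonist + rng.normal(0, sd, v.shape)
        leak = i_leak + rng.normal(0, sd, v.shape)
    else:
        total = i_leak + i_agonist
        leak = i_leak.copy()
    return IVRamp(voltage_mV=v, current_nA=total, leak_nA=leak,
                  protocol=f"ramp {v_start_mV}..{v_end_mV} mV, "
                           f"[agonist]={agonist_M:g} M, bath={bath.name}")


# ---------------------------------------------------------------------------
# reversal potential & ion substitution
# ---------------------------------------------------------------------------
def reversal_potential(
    ramp: IVRamp, expected_mV: float | None = None
) -> tuple[float, bool]:
    """Reversal potential (mV) of the agonist-evoked current.

    When a pre-agonist leak ramp is present, a straight line is fitted to it
    and subtracted first.  The zero crossing is linearly interpolated; with
    several crossings (noise), the one nearest ``expected_mV`` (default: the
    Cl- Nernst potential in ND96) is returned and flagged.

    Returns ``(e_rev_mV, ambiguous)``.  Raises :class:`OutOfRangeError` if
    the current never crosses zero inside the ramp.
    """
    v = ramp.voltage_mV
    i = ramp.current_nA.copy()
    if ramp.leak_nA is not None:
        slope, intercept = np.polyfit(v, ramp.leak_nA, 1)
        i = i - (slope * v + intercept)
    sign_change = np.nonzero(np.diff(np.signbit(i)))[0]
    exact_zero = np.nonzero(i == 0.0)[0]
    crossings = [
        v[k] - i[k] * (v[k + 1] - v[k]) / (i[k + 1] - i[k]) for k in sign_change
    ]
    crossings.extend(float(v[k]) for k in exact_zero)
    if not crossings:
        raise OutOfRangeError(
            "agonist-evoked current does not cross zero within the ramp")
    crossings = sorted(set(round(c, 12) for c in crossings))
    if len(crossings) == 1:
        return float(crossings[0]), False
    if expected_mV is None:
        expected_mV = nernst("Cl-", bath_solution("nd96"))
    best = min(crossings, key=lambda c: abs(c - expected_mV))
    return float(best), True


def substitution_shift(
    ramps: dict[str, IVRamp],
    reference: str = "nd96",
    baths: dict[str, BathSolution] | None = None,
    internal_mM: dict[str, float] | None = None,
) -> tuple[pd.DataFrame, str]:
    """Ion-substitution analysis: measured vs Nernst-predicted E_rev shifts.

    For each solution, the measured reversal-potential shift relative to the
    reference bath is compared with the shift predicted under the hypothesis
    that the channel is selectively permeant to Cl-, Na+ or K+.  The
    hypothesis minimizing the summed squared discrepancy wins.

    Returns ``(table, best_ion)`` where the table has one row per solution
    with measured and predicted shifts.
    """
    if reference not in ramps:
        raise ParameterError(
            f"substitution_shift: reference {reference!r} not among ramps")
    if baths is None:
        baths = {name: bath_solution(name) for name in ramps}
    internal = dict(INTERNAL_MM)
    if internal_mM:
        internal.update(internal_mM)

    e_ref = reversal_potential(ramps[reference])[0]
    rows = []
    discrepancy = {ion: 0.0 for ion in ION_VALENCE}
    for name, ramp in ramps.items():
        e_meas = reversal_potential(ramp)[0]
        shift = e_meas - e_ref
        row = {"solution": name, "e_rev_mV": e_meas, "shift_mV": shift}
        for ion in ION_VALENCE:
            pred = (nernst(ion, baths[name], internal[ion])
                    - nernst(ion, baths[reference], internal[ion]))
            row[f"predicted_shift_{ion}"] = pred
            discrepancy[ion] += (shift - pred) ** 2
        rows.append(row)
    best_ion = min(discrepancy, key=discrepancy.get)
    return pd.DataFrame(rows), best_ion
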