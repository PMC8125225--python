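"""First-order kinetic network of HO•-induced methionine peptide oxidation.

The reaction scheme, with the substrate in large (≥200-fold) excess over
the radicals so every bimolecular step is pseudo-first order:

    HO•  ──(k_HO·[1], branched)──►  HOS• / αS• / αC•     (paths 1–3)
    HOS• ──(k_d)──►  S•+                                  (HO⁻ elimination)
    S•+  ⇄  SS•+          (k_f·[1] forward / k_r reverse)
    S•+  ──► αS•          (fast deprotonation)
    S•+  ──► SN•          (cyclisation, observed growth constant)
    SN•  ──► αC•          (protonation-assisted ring opening)
    αC•  ──► sink         (β-fragmentation, counted as radical equivalents)

Radical–radical termination (dominant only after ~6 µs) is excluded, so
the network is linear and conserves total radical equivalents.  The
slow αS• formation channel is carried by the SS•+ reverse step followed
by deprotonation, which is why its observed rate matches the SS•+
decay; it is not an independent edge.

The system is linear with constant coefficients, so trajectories are
computed with the matrix exponential — exact up to floating point, with
no integrator tolerance to tune.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.linalg import expm
from scipy.optimize import curve_fit

__all__ = [
    "SPECIES",
    "OBSERVABLE_SPECIES",
    "RateConstantSet",
    "KineticScheme",
    "ConcentrationProfiles",
    "FormationDecayFit",
    "simulate_scheme",
    "fit_formation_decay",
    "formation_decay_model",
    "second_order_from_pseudo",
    "equilibrium_constant",
    "pseudo_first_order_from_pH",
    "load_scheme_config",
    "parse_time_grid",
]

#: Species of the network, in state-vector order.
SPECIES = ("HO", "HOS", "Scation", "SS", "SN", "alphaS", "alphaC", "sink")

#: Species with reference spectra in the default library (the sulfide
#: radical cation S•+ is a fleeting intermediate with no usable band and
#: the sink is non-absorbing).
OBSERVABLE_SPECIES = ("HOS", "alphaC", "alphaS", "SS", "SN")


@dataclass(frozen=True)
class RateConstantSet:
    """All rate constants of the scheme (M⁻¹ s⁻¹ for bimolecular, s⁻¹ else)."""

    k_HO_plus_1: float = 1.1e10    #: HO• + substrate
    k_d_HOS: float = 5.6e5         #: HOS• → S•+ decay
    k_f_SS: float = 2.2e9          #: S•+ + substrate → SS•+
    k_r_SS: float = 3.6e4          #: SS•+ → S•+ + substrate
    k_deprot_fast: float = 4.1e5   #: S•+ → αS• (fast channel)
    k_deprot_slow: float = 3.6e4   #: observed slow αS• formation (≡ SS•+ decay)
    k_aC_growth_obs: float = 1.5e6 #: observed αC• growth (pseudo-first order)
    k_aC_decay: float = 1.4e6      #: αC• → sink
    k_SN_growth_obs: float = 3.7e5 #: S•+ → SN• (observed growth constant)
    k_SN_decay: float = 8.2e3      #: SN• → αC•
    k_H_plus_S: float = 1.7e9      #: H• + sulfide
    k_SN_Hplus: float = 2.1e9      #: SN• + H⁺

    def __post_init__(self) -> None:
        for name, value in self.__dict__.items():
            if value < 0:
                raise ValueError(f"rate constant {name} must be >= 0, got {value}")


@dataclass(frozen=True)
class KineticScheme:
    """Network topology plus conditions: substrate excess, pH, branching.

    ``branching`` gives the fractions of the initial HO• attack routed to
    HOS• (path 1), directly to αS• (path 2) and directly to αC• (path 3);
    they must sum to one.
    """

    substrate_M: float = 2e-4
    pH: float = 7.0
    branching: tuple[float, float, float] = (0.85, 0.02, 0.13)

    def __post_init__(self) -> None:
        if self.substrate_M < 0:
            raise ValueError("substrate concentration must be >= 0")
        if any(f < 0 for f in self.branching):
            raise ValueError(f"branching fractions must be >= 0: {self.branching}")
        if abs(sum(self.branching) - 1.0) > 1e-9:
            raise ValueError(
                f"branching fractions must sum to 1, got {sum(self.branching)}"
            )

    def rate_matrix(self, rates: RateConstantSet) -> np.ndarray:
        """The 8×8 generator K of dy/dt = K·y over :data:`SPECIES`."""
        idx = {name: i for i, name in enumerate(SPECIES)}
        K = np.zeros((len(SPECIES), len(SPECIES)))

        def edge(src: str, dst: str, k: float) -> None:
            K[idx[src], idx[src]] -= k
            K[idx[dst], idx[src]] += k

        f1, f2, f3 = self.branching
        k_ho = rates.k_HO_plus_1 * self.substrate_M
        edge("HO", "HOS", f1 * k_ho)
        edge("HO", "alphaS", f2 * k_ho)
        edge("HO", "alphaC", f3 * k_ho)
        edge("HOS", "Scation", rates.k_d_HOS)
        edge("Scation", "SS", rates.k_f_SS * self.substrate_M)
        edge("SS", "Scation", rates.k_r_SS)
        edge("Scation", "alphaS", rates.k_deprot_fast)
        edge("Scation", "SN", rates.k_SN_growth_obs)
        edge("SN", "alphaC", rates.k_SN_decay)
        edge("alphaC", "sink", rates.k_aC_decay)
        return K


@dataclass
class ConcentrationProfiles:
    """Species trajectories in yield units (µmol J⁻¹ radical equivalents)."""

    times: np.ndarray
    profiles: dict[str, np.ndarray]

    def __getitem__(self, name: str) -> np.ndarray:
        return self.profiles[name]

    def total(self) -> np.ndarray:
        """Total radical equivalents including HO• and the sink (conserved)."""
        return np.sum([traj for traj in self.profiles.values()], axis=0)

    def downstream_total(self) -> np.ndarray:
        """Substrate-derived radical equivalents: everything except HO•."""
        return np.sum(
            [traj for name, traj in self.profiles.items() if name != "HO"], axis=0
        )

    def observable(self) -> dict[str, np.ndarray]:
        """Trajectories of the spectroscopically observable species only."""
        return {name: self.profiles[name] for name in OBSERVABLE_SPECIES}

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame({"time_s": self.times})
        for name in SPECIES:
            df[name] = self.profiles[name]
        return df


def simulate_scheme(
    scheme: KineticScheme,
    rates: RateConstantSet,
    initial_yield: float,
    times: np.ndarray,
) -> ConcentrationProfiles:
    """Propagate an initial HO• yield through the network.

    Primary radiolysis is treated as an instantaneous initial condition:
    HO• carries the full scavenged yield at t = 0 (its sub-100-ns
    production is not resolved on the observation window).  The linear
    system is solved exactly via the matrix exponential at each
    requested time.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be 1-D and strictly increasing")
    if initial_yield < 0:
        raise ValueError("initial HO• yield must be >= 0")
    K = scheme.rate_matrix(rates)
    y0 = np.zeros(len(SPECIES))
    y0[SPECIES.index("HO")] = initial_yield

    out = np.empty((len(times), len(SPECIES)))
    try:
        for i, t in enumerate(times):
            out[i] = expm(K * t) @ y0
    except Exception as exc:  # pragma: no cover - defensive
        raise RuntimeError(f"kinetic propagation failed at t={t:.3e} s") from exc
    # the exact solution is nonnegative; clip float roundoff
    out = np.maximum(out, 0.0)
    return ConcentrationProfiles(
        times=times,
        profiles={name: out[:, j] for j, name in enumerate(SPECIES)},
    )


# ---------------------------------------------------------------------------
# Formation/decay fitting

def formation_decay_model(
    t: np.ndarray, amplitude: float, k_form: float, k_decay: float
) -> np.ndarray:
    """Intermediate of a consecutive first-order scheme.

    c(t) = A·k_form/(k_decay − k_form)·(e^(−k_form·t) − e^(−k_decay·t)),
    continuously extended to A·k·t·e^(−kt) at k_form = k_decay.
    """
    t = np.asarray(t, dtype=float)
    kf, kd = k_form, k_decay
    scale = max(abs(kf), abs(kd), 1e-300)
    if abs(kf - kd) < 1e-9 * scale:
        return amplitude * kf * t * np.exp(-kf * t)
    return amplitude * kf / (kd - kf) * (np.exp(-kf * t) - np.exp(-kd * t))


@dataclass
class FormationDecayFit:
    """Result of a formation/decay fit.

    ``k_form`` is the constant of the rising phase (the faster of the
    two; an unconstrained biexponential cannot distinguish the labels
    otherwise), ``k_decay`` of the falling phase.
    """

    k_form: float
    k_decay: float
    amplitude: float
    stderr: dict[str, float]
    converged: bool
    formation_resolved: bool = True
    decay_resolved: bool = True


def _tail_rate(times: np.ndarray, values: np.ndarray) -> float:
    """Initial decay-rate guess from the log-slope of the positive tail."""
    n = len(times)
    tail = slice(max(n // 2, n - max(n // 3, 4)), n)
    t, v = times[tail], values[tail]
    mask = v > 0
    if mask.sum() < 2:
        return 1.0 / max(times[-1], 1e-300)
    slope = np.polyfit(t[mask], np.log(v[mask]), 1)[0]
    return max(-slope, 1e-6 / max(times[-1], 1e-300))


def fit_formation_decay(times: np.ndarray, values: np.ndarray) -> FormationDecayFit:
    """Fit a formation/decay trace, correcting the formation constant for
    the decay occurring during the rise.

    Initial guesses come from the peak position (decay ≈ 1/t_peak) and
    the tail log-slope.  Monotone traces leave one constant
    unidentifiable: a purely decaying input is fitted as a single
    exponential with ``k_form`` reported as +inf and flagged.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(times) < 6:
        raise ValueError("need at least 6 points spanning rise and fall")
    i_peak = int(np.argmax(values))

    if i_peak == 0:
        warnings.warn(
            "trace decays from the first point; formation constant is "
            "unidentifiable and reported as +inf"
        )
        k0 = _tail_rate(times, values)
        popt, pcov = curve_fit(
            lambda t, a, k: a * np.exp(-k * t), times, values,
            p0=[values[0], k0], maxfev=20000,
        )
        err = np.sqrt(np.diag(pcov))
        return FormationDecayFit(
            k_form=math.inf, k_decay=float(popt[1]), amplitude=float(popt[0]),
            stderr={"k_decay": float(err[1]), "amplitude": float(err[0])},
            converged=True, formation_resolved=False,
        )
    if i_peak == len(values) - 1:
        warnings.warn(
            "trace is still rising at the last point; the decay constant "
            "is poorly identified"
        )

    t_peak = times[i_peak]
    k_slow0 = max(_tail_rate(times, values), 0.1 / t_peak)
    k_fast0 = max(3.0 / t_peak, 2.0 * k_slow0)
    a0 = values[i_peak] * (1.0 + k_slow0 / k_fast0) * math.e / 2.0

    try:
        popt, pcov = curve_fit(
            formation_decay_model, times, values,
            p0=[a0, k_fast0, k_slow0],
            bounds=([0.0, 0.0, 0.0], [np.inf, np.inf, np.inf]),
            maxfev=40000,
        )
    except RuntimeError as exc:
        raise RuntimeError(
            f"formation/decay fit did not converge (peak at t={t_peak:.3e} s, "
            f"initial guesses k_form={k_fast0:.3g}, k_decay={k_slow0:.3g})"
        ) from exc
    err = np.sqrt(np.diag(pcov))
    a, k1, k2 = popt
    e_a, e_k1, e_k2 = err
    # label the faster constant as the rising phase
    if k1 < k2:
        k1, k2 = k2, k1
        e_k1, e_k2 = e_k2, e_k1
        a = a * k2 / k1  # amplitude of the equivalent relabelled form
    return FormationDecayFit(
        k_form=float(k1), k_decay=float(k2), amplitude=float(a),
        stderr={"k_form": float(e_k1), "k_decay": float(e_k2),
                "amplitude": float(e_a)},
        converged=True,
        decay_resolved=i_peak < len(values) - 1,
    )


# ---------------------------------------------------------------------------
# Rate-constant arithmetic

def second_order_from_pseudo(k_obs: float, conc: float) -> float:
    """Second-order constant from a pseudo-first-order observation: k_obs/[Q]."""
    if conc <= 0:
        raise ValueError(f"partner concentration must be > 0, got {conc}")
    return k_obs / conc


def equilibrium_constant(k_f: float, k_r: float) -> float:
    """Association equilibrium constant K = k_f/k_r (M⁻¹)."""
    if k_r <= 0:
        raise ValueError(f"reverse rate constant must be > 0, got {k_r}")
    return k_f / k_r


def pseudo_first_order_from_pH(k2: float, pH: float) -> float:
    """Pseudo-first-order constant for a proton-driven step: k₂·10^(−pH)."""
    exponent = -pH
    if exponent > 300:
        raise OverflowError(f"10^{exponent} overflows for pH={pH}")
    return k2 * 10.0 ** exponent


# ---------------------------------------------------------------------------
# Config / CLI helpers

def load_scheme_config(path: str | Path) -> tuple[KineticScheme, RateConstantSet]:
    """Load a JSON scheme config.

    Keys mirror :class:`RateConstantSet` field names, plus
    ``substrate_M``, ``pH`` and ``branching`` {path1, path2, path3}.
    """
    with open(path, "r", encoding="utf-8") as fh:
        cfg = json.load(fh)
    branching = cfg.get("branching", {})
    scheme = KineticScheme(
        substrate_M=cfg.get("substrate_M", 2e-4),
        pH=cfg.get("pH", 7.0),
        branching=(
            branching.get("path1", 0.85),
            branching.get("path2", 0.02),
            branching.get("path3", 0.13),
        ),
    )
    rate_fields = set(RateConstantSet.__dataclass_fields__)
    rates = RateConstantSet(**{k: v for k, v in cfg.items() if k in rate_fields})
    return scheme, rates


def parse_time_grid(spec: str) -> np.ndarray:
    """Parse ``start:stop:log|lin:n`` into a time grid (seconds)."""
    parts = spec.split(":")
    if len(parts) != 4 or parts[2] not in ("log", "lin"):
        raise ValueError(
            f"time grid spec must be 'start:stop:log|lin:n', got {spec!r}"
        )
    start, stop, scale, n = float(parts[0]), float(parts[1]), parts[2], int(parts[3])
    if scale == "log":
        return np.geomspace(start, stop, n)
    return np.linspace(start, stop, n)
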