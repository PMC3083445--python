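"""Inhibition kinetics: competitive, Morrison tight-binding, IC50,
slow-binding progress curves and exponential decay.

Units are carried explicitly in parameter names: substrate and KM in µM,
inhibitor and Ki in nM, enzyme in nM, rate constants in s⁻¹ (k_off, k_obs)
and M⁻¹s⁻¹ (k_on).  Mixed-scale expressions convert to molar internally —
silent unit mismatch is the dominant failure mode in this kind of analysis,
so every public signature names its unit.

Models
------
competitive       v = Vmax·S / (KM·(1 + I/Ki) + S)
Morrison          v_i/v_0 = 1 − [(E+I+Ki') − sqrt((E+I+Ki')² − 4·E·I)] / (2E),
                  Ki' = Ki·(1 + S/KM)  (tight binding: free ≠ total inhibitor)
slow binding      P(t) = vs·t + (v0 − vs)·(1 − exp(−k_obs·t)) / k_obs,
                  k_off = k_obs·vs/v0
4PL (IC50)        a = bottom + (top − bottom)/(1 + (I/IC50)^h)
exponential decay A(t) = A0·exp(−λt),  t½ = ln2/λ
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import lmfit
import numpy as np
import pandas as pd

__all__ = [
    "FitResult",
    "competitive_velocity",
    "fit_competitive",
    "morrison_fraction",
    "fit_morrison",
    "fit_ic50",
    "slow_binding_progress",
    "fit_slow_binding",
    "fit_koff",
    "second_order_kon",
    "fold_change",
    "fit_half_life",
    "nM_to_M",
    "uM_to_M",
]

NM_PER_M = 1e9
UM_PER_M = 1e6


def nM_to_M(value_nM: float) -> float:
    return value_nM / NM_PER_M


def uM_to_M(value_uM: float) -> float:
    return value_uM / UM_PER_M


@dataclass(frozen=True)
class FitResult:
    """Outcome of a nonlinear least-squares fit."""

    params: Mapping[str, float]
    stderr: Mapping[str, float | None]
    rss: float
    n_points: int
    converged: bool
    notes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        free = sum(1 for se in dict(self.stderr).values() if se is not None)
        if self.n_points < free:
            raise ValueError("fewer data points than free parameters")


def _minimize(residual, params: lmfit.Parameters, n_points: int) -> lmfit.minimizer.MinimizerResult:
    return lmfit.minimize(residual, params, method="leastsq", xtol=1e-12, ftol=1e-12)


def _collect(result, names: Sequence[str], notes: tuple[str, ...] = ()) -> FitResult:
    params = {n: float(result.params[n].value) for n in names}
    stderr = {
        n: (float(result.params[n].stderr) if result.params[n].stderr is not None else None)
        for n in names
    }
    return FitResult(
        params=params,
        stderr=stderr,
        rss=float(np.sum(np.asarray(result.residual) ** 2)),
        n_points=int(result.ndata),
        converged=bool(result.success),
        notes=notes,
    )


# ---------------------------------------------------------------------------
# Competitive inhibition
# ---------------------------------------------------------------------------

def competitive_velocity(substrate_uM, inhibitor_nM, vmax, km_uM, ki_nM):
    """Rate under the competitive-inhibition model (array-friendly)."""
    if km_uM <= 0 or ki_nM <= 0:
        raise ValueError("km_uM and ki_nM must be positive")
    S = np.asarray(substrate_uM, dtype=float)
    I = np.asarray(inhibitor_nM, dtype=float)
    return vmax * S / (km_uM * (1.0 + I / ki_nM) + S)


def _as_rate_table(data) -> pd.DataFrame:
    df = pd.DataFrame(data)
    missing = {"substrate_uM", "inhibitor_nM", "velocity"} - set(df.columns)
    if missing:
        raise ValueError(f"rate table is missing columns: {sorted(missing)}")
    return df


def fit_competitive(data, km_uM: float | None = None) -> FitResult:
    """Fit Vmax, KM and Ki to rate measurements at varied [S] and [I].

    ``data`` needs columns ``substrate_uM``, ``inhibitor_nM``, ``velocity``.
    Pass ``km_uM`` to fix the Michaelis constant instead of fitting it.
    """
    df = _as_rate_table(data)
    S = df["substrate_uM"].to_numpy(float)
    I = df["inhibitor_nM"].to_numpy(float)
    v = df["velocity"].to_numpy(float)
    if not np.any(v > 0):
        raise ValueError("no positive velocities in the data")
    if not np.any(I > 0):
        raise ValueError("Ki is unidentifiable: every measurement has [I] = 0")
    if len(df) < 4:
        raise ValueError("need at least 4 rate measurements")

    params = lmfit.Parameters()
    params.add("vmax", value=float(v.max()) * 1.2, min=0)
    if km_uM is None:
        params.add("km_uM", value=float(np.median(S[S > 0])), min=1e-12)
    else:
        params.add("km_uM", value=float(km_uM), vary=False)
    params.add("ki_nM", value=float(np.median(I[I > 0])), min=1e-12)

    def residual(p):
        return v - competitive_velocity(S, I, p["vmax"], p["km_uM"], p["ki_nM"])

    result = _minimize(residual, params, len(df))
    names = ["vmax", "km_uM", "ki_nM"] if km_uM is None else ["vmax", "ki_nM"]
    fit = _collect(result, names)
    if km_uM is not None:
        fit = FitResult(
            params={**fit.params, "km_uM": float(km_uM)},
            stderr={**fit.stderr, "km_uM": None},
            rss=fit.rss,
            n_points=fit.n_points,
            converged=fit.converged,
        )
    return fit


# ---------------------------------------------------------------------------
# Morrison tight binding
# ---------------------------------------------------------------------------

def morrison_fraction(enzyme_nM, inhibitor_nM, ki_app_nM):
    """Fractional velocity v_i/v_0 under tight-binding (Morrison) conditions."""
    E = float(enzyme_nM)
    if E <= 0:
        raise ValueError("enzyme_nM must be positive")
    I = np.asarray(inhibitor_nM, dtype=float)
    K = float(ki_app_nM)
    s = E + I + K
    disc = np.clip(s * s - 4.0 * E * I, 0.0, None)
    frac = 1.0 - (s - np.sqrt(disc)) / (2.0 * E)
    return np.clip(frac, 0.0, 1.0)


def fit_morrison(
    inhibitor_nM,
    fractional_velocity,
    enzyme_nM: float,
    substrate_uM: float,
    km_uM: float,
) -> FitResult:
    """Fit the tight-binding Ki from fractional velocities versus [I].

    The fit is on the apparent constant Ki_app; the substrate-corrected
    Ki = Ki_app / (1 + S/KM) is derived afterwards with KM held fixed at
    the supplied value (its uncertainty is not propagated).
    """
    I = np.asarray(inhibitor_nM, dtype=float)
    frac = np.asarray(fractional_velocity, dtype=float)
    if I.shape != frac.shape:
        raise ValueError("inhibitor and velocity arrays differ in length")
    if len(np.unique(I)) < 4:
        raise ValueError("need at least 4 distinct inhibitor concentrations")
    if frac.min() > 0.9:
        raise ValueError("Ki unidentifiable: no appreciable inhibition in the data")

    params = lmfit.Parameters()
    half = I[np.argmin(np.abs(frac - 0.5))]
    params.add("ki_app_nM", value=max(float(half) / 2.0, 1e-6), min=1e-12)

    def residual(p):
        return frac - morrison_fraction(enzyme_nM, I, p["ki_app_nM"])

    result = _minimize(residual, params, len(I))
    correction = 1.0 + substrate_uM / km_uM
    ki_app = float(result.params["ki_app_nM"].value)
    se_app = result.params["ki_app_nM"].stderr
    notes: tuple[str, ...] = ()
    if ki_app < enzyme_nM / 100.0:
        warnings.warn(
            "enzyme concentration far exceeds the fitted Ki_app: the assay is a "
            "stoichiometric titration and Ki is poorly conditioned",
            stacklevel=2,
        )
        notes = ("titration regime: Ki poorly conditioned",)
    return FitResult(
        params={"ki_app_nM": ki_app, "ki_nM": ki_app / correction},
        stderr={
            "ki_app_nM": float(se_app) if se_app is not None else None,
            "ki_nM": float(se_app) / correction if se_app is not None else None,
        },
        rss=float(np.sum(np.asarray(result.residual) ** 2)),
        n_points=len(I),
        converged=bool(result.success),
        notes=notes,
    )


# ---------------------------------------------------------------------------
# IC50 (four-parameter logistic)
# ---------------------------------------------------------------------------

def _logistic(I, ic50, hill, top, bottom):
    return bottom + (top - bottom) / (1.0 + (I / ic50) ** hill)


def fit_ic50(
    inhibitor_nM,
    activity,
    top: float | None = 1.0,
    bottom: float | None = 0.0,
    hill: float | None = None,
) -> FitResult:
    """Fit a four-parameter logistic on log-concentration.

    ``top``/``bottom``/``hill`` fix the corresponding parameter when given a
    number and leave it free when ``None``.  By default the asymptotes are
    fixed at 1 and 0 (fractional activity) with a free Hill slope.
    """
    I = np.asarray(inhibitor_nM, dtype=float)
    act = np.asarray(activity, dtype=float)
    if I.shape != act.shape:
        raise ValueError("inhibitor and activity arrays differ in length")
    if len(np.unique(I[I > 0])) < 4:
        raise ValueError("need at least 4 positive inhibitor concentrations")
    if act.max() - act.min() < 0.2:
        raise ValueError("IC50 unidentifiable: no transition within the data range")
    mask = I > 0
    I, act = I[mask], act[mask]

    params = lmfit.Parameters()
    mid = 0.5 * (act.max() + act.min())
    params.add("ic50_nM", value=float(I[np.argmin(np.abs(act - mid))]), min=1e-12)
    params.add("hill", value=1.0 if hill is None else float(hill), vary=hill is None, min=0.05)
    params.add("top", value=1.0 if top is None else float(top), vary=top is None)
    params.add("bottom", value=0.0 if bottom is None else float(bottom), vary=bottom is None)

    def residual(p):
        return act - _logistic(I, p["ic50_nM"], p["hill"], p["top"], p["bottom"])

    result = _minimize(residual, params, len(I))
    return _collect(result, ["ic50_nM", "hill", "top", "bottom"])


# ---------------------------------------------------------------------------
# Slow binding
# ---------------------------------------------------------------------------

def slow_binding_progress(time_s, v0, vs, k_obs):
    """Product signal of a slow-binding progress curve."""
    if k_obs <= 0:
        raise ValueError("k_obs must be positive")
    t = np.asarray(time_s, dtype=float)
    return vs * t + (v0 - vs) * (1.0 - np.exp(-k_obs * t)) / k_obs


def fit_slow_binding(time_s, signal) -> FitResult:
    """Fit v0, vs and k_obs to a single progress curve."""
    t = np.asarray(time_s, dtype=float)
    y = np.asarray(signal, dtype=float)
    if t.shape != y.shape or len(t) < 5:
        raise ValueError("need matched time/signal arrays with at least 5 points")
    order = np.argsort(t)
    t, y = t[order], y[order]

    n_head = max(3, len(t) // 10)
    v0_guess = float(np.polyfit(t[:n_head], y[:n_head], 1)[0])
    n_tail = max(3, len(t) // 4)
    vs_guess = float(np.polyfit(t[-n_tail:], y[-n_tail:], 1)[0])
    params = lmfit.Parameters()
    params.add("v0", value=max(v0_guess, 1e-9), min=0)
    params.add("vs", value=max(vs_guess, 1e-9), min=0)
    params.add("k_obs", value=3.0 / max(t.max(), 1e-9), min=1e-9)

    def residual(p):
        return y - slow_binding_progress(t, p["v0"], p["vs"], p["k_obs"])

    result = _minimize(residual, params, len(t))
    fit = _collect(result, ["v0", "vs", "k_obs"])
    if fit.params["k_obs"] * t.max() < 1.0:
        warnings.warn(
            "progress curve shows no resolved lag (k_obs·t_max < 1); "
            "slow-binding parameters carry wide uncertainty",
            stacklevel=2,
        )
    return fit


def fit_koff(time_s, uninhibited, coadd, preformed) -> FitResult:
    """Extract k_off from the three-curve slow-binding design.

    The three progress curves share a time base: the uninhibited reaction,
    simultaneous addition of substrate and inhibitor (relaxing v0 → vs) and
    a preformed enzyme–inhibitor complex (relaxing upward to the same vs).

    Primary estimator: k_off = k_obs·vs/v0 from the co-addition curve.
    Secondary ("intercept") estimator: 1/Δt, where Δt is the separation of
    the time-axis intercepts of the back-extrapolated steady-state lines of
    the co-addition and preformed-complex curves.  The two agree when the
    preformed complex starts fully bound.
    """
    t = np.asarray(time_s, dtype=float)
    slope_uninhibited = float(np.polyfit(t, np.asarray(uninhibited, float), 1)[0])

    fit_b = fit_slow_binding(t, coadd)
    fit_c = fit_slow_binding(t, preformed)
    v0_b, vs_b, kobs_b = (fit_b.params[k] for k in ("v0", "vs", "k_obs"))
    v0_c, vs_c, kobs_c = (fit_c.params[k] for k in ("v0", "vs", "k_obs"))

    if vs_b >= 0.95 * v0_b:
        raise ValueError("steady state equals the initial rate: no inhibition, k_off degenerate")

    k_off = kobs_b * vs_b / v0_b
    # First-order error propagation through k_off = k_obs·vs/v0.
    se = None
    if all(fit_b.stderr[k] is not None for k in ("v0", "vs", "k_obs")):
        rel = math.sqrt(
            (fit_b.stderr["k_obs"] / kobs_b) ** 2
            + (fit_b.stderr["vs"] / vs_b) ** 2
            + (fit_b.stderr["v0"] / v0_b) ** 2
        )
        se = k_off * rel

    # Steady-state lines y = vs·t + (v0 − vs)/k_obs, back-extrapolated to y = 0.
    t0_b = -((v0_b - vs_b) / kobs_b) / vs_b
    t0_c = -((v0_c - vs_c) / kobs_c) / vs_c
    delta = abs(t0_c - t0_b)
    k_off_intercept = 1.0 / delta if delta > 0 else math.inf

    return FitResult(
        params={
            "k_off": k_off,
            "k_off_intercept": k_off_intercept,
            "k_obs": kobs_b,
            "v0": v0_b,
            "vs": vs_b,
            "v0_uninhibited": slope_uninhibited,
        },
        stderr={
            "k_off": se,
            "k_off_intercept": None,
            "k_obs": fit_b.stderr["k_obs"],
            "v0": fit_b.stderr["v0"],
            "vs": fit_b.stderr["vs"],
            "v0_uninhibited": None,
        },
        rss=fit_b.rss + fit_c.rss,
        n_points=fit_b.n_points + fit_c.n_points + len(t),
        converged=fit_b.converged and fit_c.converged,
    )


def second_order_kon(k_off_per_s: float, ki_nM: float) -> float:
    """Association rate constant k_on = k_off / Ki, in M⁻¹ s⁻¹."""
    if ki_nM <= 0:
        raise ValueError("ki_nM must be positive")
    return k_off_per_s / nM_to_M(ki_nM)


def fold_change(reference_value: float, improved_value: float) -> float:
    """Potency improvement reference/improved, to 3 significant figures."""
    if improved_value <= 0:
        raise ValueError("improved_value must be positive")
    return float(f"{reference_value / improved_value:.3g}")


# ---------------------------------------------------------------------------
# Exponential decay / half-life
# ---------------------------------------------------------------------------

def fit_half_life(time, values) -> FitResult:
    """Fit A(t) = A0·exp(−λt) and report t½ = ln2/λ.

    Time units are whatever the input uses; t½ comes back in the same unit.
    A non-decaying series is reported with a warning and an infinite t½.
    """
    t = np.asarray(time, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.shape != y.shape or len(t) < 3:
        raise ValueError("need matched time/value arrays with at least 3 points")
    if np.any(y <= 0):
        raise ValueError("values must be positive for an exponential-decay fit")

    slope, log_a0 = np.polyfit(t, np.log(y), 1)
    params = lmfit.Parameters()
    params.add("a0", value=float(np.exp(log_a0)), min=1e-300)
    params.add("lam", value=float(-slope))

    def residual(p):
        return y - p["a0"] * np.exp(-p["lam"] * t)

    result = _minimize(residual, params, len(t))
    a0 = float(result.params["a0"].value)
    lam = float(result.params["lam"].value)
    se_lam = result.params["lam"].stderr
    se_a0 = result.params["a0"].stderr

    if lam <= 0:
        warnings.warn("series does not decay (fitted rate <= 0); t_half undefined", stacklevel=2)
        t_half, se_t = math.inf, None
    else:
        t_half = math.log(2) / lam
        se_t = math.log(2) / lam**2 * float(se_lam) if se_lam is not None else None

    return FitResult(
        params={"a0": a0, "decay_rate": lam, "t_half": t_half},
        stderr={
            "a0": float(se_a0) if se_a0 is not None else None,
            "decay_rate": float(se_lam) if se_lam is not None else None,
            "t_half": se_t,
        },
        rss=float(np.sum(np.asarray(result.residual) ** 2)),
        n_points=len(t),
        converged=bool(result.success),
    )
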