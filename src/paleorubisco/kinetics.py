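"""RuBisCO enzyme-kinetics calculus.

RuBisCO carboxylates RuBP with Michaelis–Menten kinetics in CO2 while O2
acts as a competitive substrate: the apparent Michaelis constant for CO2
rises linearly with dissolved O2,

    Kc(O2) = Kc(N2) * (1 + [O2] / Ko).

This module implements the parameter calculus built on that relation:
Michaelis–Menten fitting of assay curves, inference of Ko from the O2
dependence of apparent Kc, derivation of the oxygenation turnover Vo from
the specificity factor tau = (Vc/Kc) / (Vo/Ko), the air-referenced
quantities Kc^air and Vc/Kc^air used to compare carboxylation efficiency
at today's atmosphere, wheat-referenced normalization of measured
specificity factors (wheat = 100.0 at 25 C), and the power-law fit of the
inverse tradeoff between carboxylation rate Vc and specificity factor.

Units: concentrations in uM dissolved gas, turnover rates in 1/s, and
Vc/Kc^air in s^-1 mM^-1.  Dissolved O2 in air-equilibrated water at 25 C
defaults to 260 uM.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import linregress

#: Dissolved O2 (uM) in water equilibrated with air (21% O2) at 25 C.
O2_AIR_UM = 260.0


class KineticsError(ValueError):
    pass


@dataclass
class KineticParams:
    """Kinetic constants of one enzyme.

    Vc, Vo in 1/s per active site; Kc, Ko, Kc_air in uM; tau dimensionless
    (wheat-normalized when stated); Vc_over_Kc_air in s^-1 mM^-1.
    """

    enzyme: str
    Vc: float | None = None
    Vo: float | None = None
    Kc: float | None = None
    Ko: float | None = None
    tau: float | None = None
    Kc_air: float | None = None
    Vc_over_Kc_air: float | None = None


@dataclass
class AssayTable:
    """Observed carboxylation rates across CO2 and O2 levels.

    Columns: ``o2`` (uM dissolved), ``co2`` (uM dissolved), ``rate``
    (1/s per active site).
    """

    enzyme: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"o2", "co2", "rate"}
        missing = required - set(self.data.columns)
        if missing:
            raise KineticsError(f"assay table missing columns: {sorted(missing)}")
        if (self.data[["o2", "co2"]] < 0).any().any():
            raise KineticsError("concentrations must be non-negative")
        for o2, grp in self.data.groupby("o2"):
            if grp["co2"].nunique() < 2:
                raise KineticsError(
                    f"need >=2 distinct CO2 levels at O2={o2} for MM fitting"
                )


def fit_mm(substrate: Sequence[float], rate: Sequence[float]) -> tuple[float, float, float]:
    """Fit v = Vmax * S / (Km + S) by nonlinear least squares.

    Starting values come from the double-reciprocal (Lineweaver–Burk)
    linearization; the final estimates are untransformed least squares,
    which is unbiased under multiplicative noise in the rates.  Returns
    (Vmax, Km, residual sum of squares).
    """
    S = np.asarray(substrate, dtype=float)
    v = np.asarray(rate, dtype=float)
    if S.shape != v.shape or S.ndim != 1:
        raise KineticsError("substrate and rate must be 1-D and equal length")
    if np.unique(S).size < 2:
        raise KineticsError("need at least 2 distinct substrate levels")
    if np.all(v == 0):
        raise KineticsError("all rates are zero; nothing to fit")
    if np.any(v < 0):
        raise KineticsError("negative rates")
    pos = (v > 0) & (S > 0)
    if pos.sum() >= 2:
        # 1/v = (Km/Vmax) (1/S) + 1/Vmax
        slope, intercept, *_ = linregress(1.0 / S[pos], 1.0 / v[pos])
        if intercept > 0 and slope > 0:
            v0, k0 = 1.0 / intercept, slope / intercept
        else:
            v0, k0 = v.max(), np.median(S)
    else:
        v0, k0 = v.max(), np.median(S)
    try:
        popt, _ = curve_fit(
            lambda s, vmax, km: vmax * s / (km + s),
            S,
            v,
            p0=[v0, max(k0, 1e-6)],
            bounds=([0.0, 0.0], [np.inf, np.inf]),
            maxfev=10000,
        )
    except RuntimeError as exc:
        raise KineticsError(f"Michaelis–Menten fit did not converge: {exc}") from exc
    vmax, km = float(popt[0]), float(popt[1])
    ssq = float(np.sum((v - vmax * S / (km + S)) ** 2))
    return vmax, km, ssq


def kc_at_o2(Kc_N2: float, Ko: float, O2: float) -> float:
    """Apparent Kc (uM) at a given dissolved O2: Kc * (1 + O2/Ko)."""
    if Kc_N2 <= 0 or Ko <= 0:
        raise KineticsError("Kc and Ko must be positive")
    if O2 < 0:
        raise KineticsError("O2 must be non-negative")
    return Kc_N2 * (1.0 + O2 / Ko)


def infer_ko(series: Sequence[tuple[float, float]]) -> tuple[float, float, float]:
    """Infer (Kc in N2, Ko) from apparent Kc measured at several O2 levels.

    Ordinary least squares of apparent Kc on O2: the intercept is Kc(N2)
    and the slope is Kc(N2)/Ko, so Ko = intercept / slope.  Returns
    (Kc_N2, Ko, R^2).
    """
    pts = np.asarray(series, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise KineticsError("series must be (O2, apparent Kc) pairs")
    o2, kc = pts[:, 0], pts[:, 1]
    if np.unique(o2).size < 2:
        raise KineticsError("need >=2 distinct O2 levels")
    res = linregress(o2, kc)
    if res.slope <= 0:
        raise KineticsError("no O2 inhibition detected (slope <= 0)")
    if res.intercept <= 0:
        raise KineticsError("non-positive extrapolated Kc in N2")
    kc_n2 = float(res.intercept)
    ko = float(res.intercept / res.slope)
    r2 = float(res.rvalue**2)
    return kc_n2, ko, r2


def derive_vo(Vc: float, Kc: float, Ko: float, tau: float) -> float:
    """Oxygenation turnover from tau = (Vc/Kc)/(Vo/Ko): Vo = Vc*Ko/(Kc*tau)."""
    for name, val in (("Vc", Vc), ("Kc", Kc), ("Ko", Ko), ("tau", tau)):
        if val <= 0:
            raise KineticsError(f"{name} must be positive, got {val}")
    return Vc * Ko / (Kc * tau)


def efficiency_air(params: KineticParams, O2_air: float = O2_AIR_UM) -> KineticParams:
    """Fill Kc_air (uM) and Vc/Kc_air (s^-1 mM^-1) for one enzyme.

    Kc_air is the apparent Kc at air-equilibrated dissolved O2;
    Vc/Kc_air expresses the initial slope of the carboxylation response to
    CO2 under today's atmosphere, i.e. performance at low CO2.
    """
    missing = [n for n in ("Vc", "Kc", "Ko") if getattr(params, n) is None]
    if missing:
        raise KineticsError(f"cannot derive air efficiency; unset: {missing}")
    if O2_air <= 0:
        raise KineticsError("O2_air must be positive")
    kc_air = kc_at_o2(params.Kc, params.Ko, O2_air)
    return replace(
        params,
        Kc_air=kc_air,
        Vc_over_Kc_air=params.Vc / (kc_air / 1000.0),
    )


def normalize_tau(raw: Sequence[float], reference_raw: float) -> list[float]:
    """Scale measured specificity factors so the reference enzyme reads 100.0.

    The reference is wheat RuBisCO assayed alongside; its mean measured tau
    maps to exactly 100.0 (at 25 C).
    """
    if reference_raw <= 0:
        raise KineticsError("reference tau must be positive")
    return [float(x) * 100.0 / float(reference_raw) for x in raw]


def fit_tradeoff(
    points: Sequence[tuple[float, float]]
) -> tuple[float, float, np.ndarray]:
    """Fit the inverse Vc–tau tradeoff as a power law tau = a * Vc^b.

    Least squares on log tau against log Vc.  Returns (a, b, residuals)
    where residuals are per-point signed log-space deviations
    (log tau_obs - log tau_fit): positive means the enzyme sits above the
    fitted frontier, negative below/inside it.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise KineticsError("need >=3 (Vc, tau) points")
    if np.any(pts <= 0):
        raise KineticsError("Vc and tau must be positive")
    x, y = np.log(pts[:, 0]), np.log(pts[:, 1])
    if np.unique(x).size < 2:
        raise KineticsError("degenerate fit: all Vc values identical")
    res = linregress(x, y)
    a, b = float(np.exp(res.intercept)), float(res.slope)
    residuals = y - (res.intercept + res.slope * x)
    return a, b, residuals


def derive_table(
    measured: pd.DataFrame,
    O2_air: float = O2_AIR_UM,
    derive_vo_for: Sequence[str] = (),
) -> pd.DataFrame:
    """Complete a table of measured constants with the derived columns.

    `measured` needs columns ``enzyme``, ``Vc``, ``Kc``, ``Ko`` and
    optionally ``tau``.  Adds ``Kc_air`` and ``Vc_over_Kc_air`` for every
    row, and ``Vo`` (from tau) for enzymes named in `derive_vo_for`.
    """
    required = {"enzyme", "Vc", "Kc", "Ko"}
    missing = required - set(measured.columns)
    if missing:
        raise KineticsError(f"parameter table missing columns: {sorted(missing)}")
    if measured.empty:
        raise KineticsError("parameter table is empty")
    out = measured.copy()
    out["Kc_air"] = [
        kc_at_o2(r.Kc, r.Ko, O2_air) for r in out.itertuples()
    ]
    out["Vc_over_Kc_air"] = out["Vc"] / (out["Kc_air"] / 1000.0)
    if derive_vo_for:
        if "tau" not in out.columns:
            raise KineticsError("tau column required to derive Vo")
        vo = []
        for r in out.itertuples():
            if r.enzyme in derive_vo_for:
                vo.append(derive_vo(r.Vc, r.Kc, r.Ko, r.tau))
            else:
                vo.append(getattr(r, "Vo", np.nan))
        out["Vo"] = vo
    return out
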