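"""Viability normalization, 4PL dose-response fits, and Loewe isobolograms.

Raw absorbances are normalized to percent viability against blank and
untreated controls.  Cytotoxic dose-response is modeled with the
four-parameter logistic in log10 dose,

    Y = Bottom + (Top - Bottom) / (1 + 10^((LogLD50 - X) * Hillslope)),

fit by least squares from a deterministic start (Top = max Y, Bottom =
min Y, LogLD50 = mid-range X, Hillslope = -1); the 50% cytotoxic
concentration is CC50 = 10^LogLD50 (LD50 and CC50 name the same quantity
here).  Drug-pair interaction is read off a Loewe-additivity isobologram:
combination dose pairs (d1, d2) reaching 50% cytotoxicity are scored with
the interaction index d1/D1 + d2/D2 against the single-agent CC50s; the
additive isobole is index = 1, synergy below, antagonism above.
Combination CC50 points come from a ray design — drug 2 fixed per ray, a
1-D 4PL fit over drug 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares


class FitError(RuntimeError):
    pass


def normalize_viability(a_treated, a_blank, a_control) -> np.ndarray | float:
    """Percent viability (A_treated - A_blank) / (A_control - A_blank) * 100.

    Values above 100% or below 0% are returned as-is (flag downstream);
    a control absorbance at or below blank is an assay failure."""
    a_treated = np.asarray(a_treated, dtype=float)
    if np.any(np.asarray(a_control) <= np.asarray(a_blank)):
        raise ValueError("control absorbance <= blank: assay failure")
    out = (a_treated - a_blank) / (a_control - a_blank) * 100.0
    return float(out) if out.ndim == 0 else out


def four_param_logistic(x, bottom, top, log_ld50, hillslope):
    """Viability at log10 dose x."""
    return bottom + (top - bottom) / (1.0 + 10.0 ** ((log_ld50 - x) * hillslope))


@dataclass
class DoseResponseFit:
    bottom: float
    top: float
    log_ld50: float
    hillslope: float
    residuals: np.ndarray = field(repr=False, default=None)
    non_cytotoxic: bool = False  # positive hillslope: viability rises with dose

    @property
    def cc50(self) -> float:
        return 10.0 ** self.log_ld50

    def predict(self, doses) -> np.ndarray:
        return four_param_logistic(
            np.log10(np.asarray(doses, dtype=float)), self.bottom, self.top, self.log_ld50, self.hillslope
        )


def fit_4pl(doses, viabilities, tol: float = 1e-8) -> DoseResponseFit:
    """Least-squares 4PL fit on X = log10(dose).

    Requires at least four distinct positive dose levels.  Initialization is
    deterministic, so the fit is reproducible and exactly scale-equivariant:
    multiplying all doses by k multiplies CC50 by k.
    """
    d = np.asarray(doses, dtype=float)
    y = np.asarray(viabilities, dtype=float)
    if d.shape != y.shape or d.ndim != 1:
        raise ValueError("doses and viabilities must be matching 1-D arrays")
    if np.any(d <= 0):
        raise ValueError("doses must be positive (log scale)")
    if np.unique(d).size < 4:
        raise FitError("need at least four distinct dose levels")
    if np.ptp(y) < 1e-9:
        raise FitError("degenerate response span: viability does not vary with dose")
    x = np.log10(d)
    p0 = np.array([y.min(), y.max(), 0.5 * (x.min() + x.max()), -1.0])

    def resid(p):
        return four_param_logistic(x, *p) - y

    sol = least_squares(resid, p0, xtol=tol, ftol=tol, gtol=tol, method="lm")
    if not sol.success:
        raise FitError(f"4PL fit did not converge: {sol.message}")
    bottom, top, log_ld50, hill = sol.x
    if bottom > top:  # normalize orientation so bottom <= top
        bottom, top = top, bottom
        hill = -hill
    span = x.max() - x.min()
    if not (x.min() - span <= log_ld50 <= x.max() + span):
        raise FitError(
            f"fitted LogLD50 {log_ld50:.3g} far outside dosed range; transition not spanned"
        )
    return DoseResponseFit(
        bottom=float(bottom),
        top=float(top),
        log_ld50=float(log_ld50),
        hillslope=float(hill),
        residuals=sol.fun,
        non_cytotoxic=bool(hill > 0),
    )


@dataclass(frozen=True)
class IsobologramPoint:
    d1: float
    d2: float
    cc50_drug1: float
    cc50_drug2: float

    @property
    def interaction_index(self) -> float:
        return self.d1 / self.cc50_drug1 + self.d2 / self.cc50_drug2


def interaction_index(
    combo_cc50_points,
    cc50_drug1: float,
    cc50_drug2: float,
    tau: float = 0.2,
) -> tuple[list[IsobologramPoint], str]:
    """Loewe interaction indices for combination CC50 dose pairs.

    Returns the scored points and a qualitative call from the mean index:
    synergistic below 1 - tau, antagonistic above 1 + tau, additive within.
    """
    if not (math.isfinite(cc50_drug1) and cc50_drug1 > 0) or not (
        math.isfinite(cc50_drug2) and cc50_drug2 > 0
    ):
        raise ValueError("single-agent CC50s must be finite and positive")
    points = []
    for d1, d2 in combo_cc50_points:
        if d1 == 0 and d2 == 0:
            raise ValueError("combination point with both doses zero")
        points.append(IsobologramPoint(float(d1), float(d2), cc50_drug1, cc50_drug2))
    if not points:
        raise ValueError("no combination points")
    mean_idx = float(np.mean([p.interaction_index for p in points]))
    if mean_idx < 1.0 - tau:
        call = "synergistic"
    elif mean_idx > 1.0 + tau:
        call = "antagonistic"
    else:
        call = "additive"
    return points, call


def combination_cc50s(table: pd.DataFrame) -> list[tuple[float, float]]:
    """CC50 dose pairs from a ray-design combination table.

    Expects long-format columns drug1_dose, drug2_dose, viability; for each
    fixed drug2 dose a 1-D 4PL over drug1 yields the drug-1 CC50 on that
    ray.  Rays whose fit fails (e.g. no transition at that co-dose) are
    skipped.
    """
    pts = []
    for d2, sub in table.groupby("drug2_dose"):
        sub = sub[sub["drug1_dose"] > 0]
        try:
            fit = fit_4pl(sub["drug1_dose"].to_numpy(), sub["viability"].to_numpy())
        except (FitError, ValueError):
            continue
        if not fit.non_cytotoxic:
            pts.append((fit.cc50, float(d2)))
    return pts


def synergy_analysis(
    table: pd.DataFrame,
    tau: float = 0.2,
) -> dict:
    """End-to-end ray-design synergy analysis from a long-format table.

    Single-agent CC50s come from the rows where the partner dose is zero;
    combination CC50s from the remaining rays.
    """
    single1 = table[table["drug2_dose"] == 0]
    single2 = table[table["drug1_dose"] == 0]
    if single1.empty or single2.empty:
        raise ValueError("table must contain single-agent titrations (partner dose 0)")
    fit1 = fit_4pl(single1["drug1_dose"].to_numpy(), single1["viability"].to_numpy())
    fit2 = fit_4pl(single2["drug2_dose"].to_numpy(), single2["viability"].to_numpy())
    combo = table[(table["drug1_dose"] > 0) & (table["drug2_dose"] > 0)]
    pts = combination_cc50s(combo)
    points, call = interaction_index(pts, fit1.cc50, fit2.cc50, tau=tau)
    return {
        "cc50_drug1": fit1.cc50,
        "cc50_drug2": fit2.cc50,
        "points": points,
        "indices": [p.interaction_index for p in points],
        "call": call,
    }
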