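"""Binding-curve quantification and sequence utilities.

Microtubule co-sedimentation: pellet intensities are background-subtracted
by the 0 uM-microtubule pellet lane, fraction bound = [P]/([S]+[P]), and a
hyperbolic isotherm f = f_max [L] / (K_D + [L]) is fitted (the default
ignores protein depletion; a depletion-aware quadratic variant is exposed
behind a flag and the fit report names the model used).

Fluorescence anisotropy: r = r_free + (r_bound - r_free) b with the bound
probe fraction b from the exact 1:1 quadratic equilibrium, which accounts
for probe depletion (required when K_D is comparable to the probe
concentration); a hyperbolic variant covers the probe -> 0 limit.

Isoelectric point: Henderson-Hasselbalch net charge zeroed by bisection;
two named pKa tables ship (EMBOSS-style and Lehninger-style) and reports
always name the table since the result depends on the choice.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

logger = logging.getLogger("coilreg")


class NonIdentifiableError(Exception):
    """Data carry no curvature: the binding model cannot be identified."""


class UndefinedPIError(Exception):
    """Sequence has no ionizable groups."""


# ---------------------------------------------------------------- cosedimentation

@dataclass
class CosedExperiment:
    """Gel densitometry per microtubule concentration (uM polymerized tubulin)."""
    concentrations: np.ndarray
    intensity_s: np.ndarray
    intensity_p: np.ndarray

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.intensity_s = np.asarray(self.intensity_s, dtype=float)
        self.intensity_p = np.asarray(self.intensity_p, dtype=float)
        if np.any(self.concentrations < 0):
            raise ValueError("concentrations must be >= 0")
        if int(np.sum(self.concentrations == 0)) != 1:
            raise ValueError("exactly one 0 uM lane is required for "
                             "background subtraction")

    @property
    def background_p(self) -> float:
        return float(self.intensity_p[self.concentrations == 0][0])


def fraction_bound(exp: CosedExperiment) -> tuple[np.ndarray, np.ndarray]:
    """Background-subtracted fraction bound per concentration.

    P' = max(P - background, 0) (negative values are clamped with a logged
    count); fraction = P' / (S + P'). Points with S + P' = 0 are excluded
    with a warning. Returns (concentrations, fractions) over defined points.
    """
    p_sub = exp.intensity_p - exp.background_p
    n_clamped = int(np.sum(p_sub < 0))
    if n_clamped:
        logger.info("clamped %d negative background-subtracted pellet "
                    "intensities to 0", n_clamped)
    p_sub = np.clip(p_sub, 0.0, None)
    denom = exp.intensity_s + p_sub
    ok = denom > 0
    if not ok.all():
        logger.warning("excluded %d points with S + P' = 0", int((~ok).sum()))
    return exp.concentrations[ok], p_sub[ok] / denom[ok]


@dataclass
class BindingFit:
    kd: float
    kd_stderr: float
    params: dict[str, float]
    stderrs: dict[str, float]
    residuals: np.ndarray
    model: str
    warnings: list[str] = field(default_factory=list)

    def report(self) -> str:
        lines = [f"model\t{self.model}", f"kd\t{self.kd:.6g}",
                 f"kd_stderr\t{self.kd_stderr:.6g}"]
        for k, v in self.params.items():
            lines.append(f"{k}\t{v:.6g}\t+/-\t{self.stderrs.get(k, math.nan):.6g}")
        for w in self.warnings:
            lines.append(f"warning\t{w}")
        return "\n".join(lines) + "\n"


def _hyperbolic(conc, f_max, kd):
    return f_max * conc / (kd + conc)


def _quadratic_bound_fraction(titrant, probe, kd):
    """Exact bound fraction of the probe in a 1:1 equilibrium.

    Uses the cancellation-free conjugate form of the quadratic root so the
    probe -> 0 limit stays numerically smooth.
    """
    s = titrant + probe + kd
    disc = np.maximum(s * s - 4.0 * titrant * probe, 0.0)
    complex_conc = 2.0 * titrant * probe / (s + np.sqrt(disc))
    return complex_conc / probe


def fit_kd_hyperbolic(concentrations: np.ndarray, fractions: np.ndarray,
                      sigma: np.ndarray | None = None,
                      depletion_protein_conc: float | None = None) -> BindingFit:
    """Fit f = f_max [L] / (K_D + [L]) by least squares.

    With ``depletion_protein_conc`` set, the depletion-aware quadratic
    variant is fitted instead (f = f_max * exact bound fraction of the
    protein at that fixed total concentration). Standard errors come from
    the fit covariance.
    """
    conc = np.asarray(concentrations, dtype=float)
    frac = np.asarray(fractions, dtype=float)
    if len(conc) < 4:
        raise ValueError("need >= 4 concentrations spanning the transition")
    if np.ptp(frac) < 1e-12:
        raise NonIdentifiableError("all fractions equal: no curvature to fit")
    if depletion_protein_conc is None:
        model_name = "hyperbolic [L]/(Kd+[L])"
        fun = _hyperbolic
    else:
        model_name = (f"quadratic (protein depletion, total "
                      f"{depletion_protein_conc:g})")

        def fun(c, f_max, kd):
            return f_max * _quadratic_bound_fraction(c, depletion_protein_conc, kd)

    p0 = [max(frac.max(), 0.1), max(np.median(conc[conc > 0]), 1e-6)]
    popt, pcov = curve_fit(fun, conc, frac, p0=p0, sigma=sigma,
                           bounds=([0, 1e-12], [np.inf, np.inf]), maxfev=20000)
    perr = np.sqrt(np.diag(pcov))
    resid = frac - fun(conc, *popt)
    return BindingFit(kd=float(popt[1]), kd_stderr=float(perr[1]),
                      params={"f_max": float(popt[0]), "kd": float(popt[1])},
                      stderrs={"f_max": float(perr[0]), "kd": float(perr[1])},
                      residuals=resid, model=model_name)


def fit_kd_anisotropy(protein_conc: np.ndarray, anisotropy: np.ndarray,
                      probe_conc: float, model: str = "quadratic") -> BindingFit:
    """Fit r = r_free + (r_bound - r_free) * b(titration).

    model='quadratic' (default) uses the exact 1:1 equilibrium with probe
    depletion; model='hyperbolic' uses b = [L]/(K_D + [L]). The chosen
    functional form is recorded in the fit because it is a modelling
    decision, not a measurement.
    """
    conc = np.asarray(protein_conc, dtype=float)
    r = np.asarray(anisotropy, dtype=float)
    warnings: list[str] = []
    order = np.argsort(conc)
    dr = np.diff(r[order])
    noise = float(np.std(dr)) if len(dr) > 2 else 0.0
    if len(dr) > 3 and np.sum(dr < -3 * max(noise, 1e-12)) > 1:
        warnings.append("titration non-monotone beyond noise")

    if model == "quadratic":
        def fun(c, r_free, r_bound, kd):
            return r_free + (r_bound - r_free) * _quadratic_bound_fraction(
                c, probe_conc, kd)
    elif model == "hyperbolic":
        def fun(c, r_free, r_bound, kd):
            return r_free + (r_bound - r_free) * c / (kd + c)
    else:
        raise ValueError("model must be 'quadratic' or 'hyperbolic'")

    p0 = [float(r.min()), float(r.max()),
          float(max(np.median(conc[conc > 0]), probe_conc))]
    popt, pcov = curve_fit(fun, conc, r, p0=p0,
                           bounds=([-1, -1, 1e-15], [2, 2, np.inf]),
                           maxfev=40000)
    perr = np.sqrt(np.diag(pcov))
    resid = r - fun(conc, *popt)
    span = fun(conc.max(), *popt) - popt[0]
    if abs(span) < 0.8 * abs(popt[1] - popt[0]):
        warnings.append("saturation not reached: confidence interval is wide")
    return BindingFit(kd=float(popt[2]), kd_stderr=float(perr[2]),
                      params={"r_free": float(popt[0]), "r_bound": float(popt[1]),
                              "kd": float(popt[2])},
                      stderrs={"r_free": float(perr[0]), "r_bound": float(perr[1]),
                               "kd": float(perr[2])},
                      residuals=resid,
                      model=f"anisotropy {model} (probe {probe_conc:g})",
                      warnings=warnings)


def serial_dilution(top: float, ratio: float = 2.0 / 3.0, n: int = 12) -> np.ndarray:
    """Concentration series from serial dilution (default the 2:3 v/v scheme)."""
    return top * ratio ** np.arange(n)


# ---------------------------------------------------------------- sequence

PKA_TABLES: dict[str, dict[str, float]] = {
    # positive groups listed with the pH at which they are half-deprotonated
    "emboss": {"Nterm": 8.6, "K": 10.8, "R": 12.5, "H": 6.5,
               "Cterm": 3.6, "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1},
    "lehninger": {"Nterm": 9.69, "K": 10.53, "R": 12.48, "H": 6.0,
                  "Cterm": 2.34, "D": 3.65, "E": 4.25, "C": 8.18, "Y": 10.07},
}

POSITIVE_GROUPS = ("Nterm", "K", "R", "H")
NEGATIVE_GROUPS = ("Cterm", "D", "E", "C", "Y")


def net_charge(sequence: str, ph: float, pka_set: str = "emboss",
               include_termini: bool = True) -> float:
    """Henderson-Hasselbalch net charge at a pH."""
    table = PKA_TABLES[pka_set]
    seq = sequence.upper()
    counts = {aa: seq.count(aa) for aa in "KRHDECY"}
    charge = 0.0
    groups = []
    if include_termini:
        groups += [("Nterm", 1), ("Cterm", 1)]
    groups += [(aa, counts[aa]) for aa in "KRHDECY" if counts[aa]]
    for name, n in groups:
        pka = table[name]
        if name in POSITIVE_GROUPS:
            charge += n / (1.0 + 10.0 ** (ph - pka))
        else:
            charge -= n / (1.0 + 10.0 ** (pka - ph))
    return charge


def isoelectric_point(sequence: str, pka_set: str = "emboss",
                      include_termini: bool = True,
                      tolerance: float = 0.01) -> float:
    """pH at which the net charge crosses zero, by bisection.

    Raises UndefinedPIError when the sequence (with termini excluded)
    carries no ionizable group.
    """
    if pka_set not in PKA_TABLES:
        raise ValueError(f"unknown pKa table {pka_set!r}; "
                         f"available: {sorted(PKA_TABLES)}")
    seq = sequence.upper()
    has_group = include_termini or any(aa in seq for aa in "KRHDECY")
    if not has_group or (not seq and not include_termini):
        raise UndefinedPIError("no ionizable groups in sequence")
    lo, hi = 0.0, 14.0
    f_lo = net_charge(seq, lo, pka_set, include_termini)
    f_hi = net_charge(seq, hi, pka_set, include_termini)
    if f_lo <= 0:
        return lo
    if f_hi >= 0:
        return hi
    while hi - lo > tolerance / 4:
        mid = 0.5 * (lo + hi)
        if net_charge(seq, mid, pka_set, include_termini) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def basic_residue_positions(sequence: str, start_number: int = 1) -> list[int]:
    """Positions (1-based numbering from start_number) of Lys/Arg residues."""
    return [start_number + i for i, aa in enumerate(sequence.upper()) if aa in "KR"]
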