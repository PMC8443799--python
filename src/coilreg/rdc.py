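"""Residual dipolar coupling back-calculation and alignment-tensor fitting.

A coupling for amide bond vector v is D = v^T S v with S the symmetric
traceless Saupe (alignment) matrix, or equivalently

    D = Da [ (3 cos^2 theta - 1) + (3/2) R sin^2 theta cos 2 phi ]

with (theta, phi) the polar angles of v in the tensor principal frame,
Da = Azz / 2 the axial magnitude (in Hz: the dipolar prefactor is carried
implicitly because fits are Hz against Hz) and R = 2(Axx - Ayy) / (3 Azz)
the rhombicity. Principal components are ordered |Azz| >= |Ayy| >= |Axx|,
which puts R in [0, 2/3].

The primary fit is linear least squares over the five independent Saupe
elements (the exact global chi^2 minimum); a 5-parameter nonlinear
(Da, R, Euler) solver is provided as an independent cross-check. Euler
angles use the z-y-z convention, in degrees, reported in
[0,360) x [0,180) x [0,360).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .structure_io import AmideVector

logger = logging.getLogger("coilreg")


class UnderdeterminedError(Exception):
    """Fewer than five usable measurements."""


class ConditioningError(Exception):
    """Rank-deficient design (e.g. near-collinear bond vectors)."""


class UndefinedQError(Exception):
    """Q factor undefined: rms(d_obs) = 0 with nonzero residuals."""


@dataclass
class RDCMeasurement:
    residue_number: int
    d_obs: float    # Hz
    sigma: float    # Hz

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError(f"sigma must be > 0 (residue {self.residue_number})")


def read_rdc_table(path: str | Path) -> list[RDCMeasurement]:
    """Whitespace/TSV table: residue  d_obs_hz  sigma_hz."""
    df = pd.read_csv(path, sep=r"\s+", comment="#",
                     names=["residue", "d_obs_hz", "sigma_hz"], header=None,
                     skiprows=lambda i: False)
    # tolerate a header row
    if isinstance(df.iloc[0, 0], str):
        df = df.iloc[1:].reset_index(drop=True)
    return [RDCMeasurement(int(r), float(d), float(s))
            for r, d, s in df.itertuples(index=False)]


def write_rdc_table(measurements: Sequence[RDCMeasurement], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("residue\td_obs_hz\tsigma_hz\n")
        for m in measurements:
            fh.write(f"{m.residue_number}\t{m.d_obs:.6f}\t{m.sigma:.6f}\n")


def _rot_z(a):
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


def _rot_y(a):
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])


class AlignmentTensor:
    """Symmetric traceless alignment tensor with derived Da/R/Euler angles."""

    def __init__(self, saupe: np.ndarray):
        saupe = np.asarray(saupe, dtype=float)
        if saupe.shape != (3, 3):
            raise ValueError("Saupe matrix must be 3x3")
        if not np.allclose(saupe, saupe.T, atol=1e-9):
            raise ValueError("Saupe matrix must be symmetric")
        if abs(np.trace(saupe)) > 1e-9 * max(1.0, float(np.abs(saupe).max())):
            raise ValueError("Saupe matrix must be traceless")
        self.saupe = 0.5 * (saupe + saupe.T)
        vals, vecs = np.linalg.eigh(self.saupe)
        order = np.argsort(np.abs(vals))        # |Axx| <= |Ayy| <= |Azz|
        self._principal = vals[order]
        v = vecs[:, order]
        if np.linalg.det(v) < 0:
            v[:, 0] = -v[:, 0]
        self._axes = v                          # columns: x, y, z principal axes

    @classmethod
    def from_elements(cls, sxx: float, syy: float, sxy: float, sxz: float,
                      syz: float) -> "AlignmentTensor":
        szz = -sxx - syy
        return cls(np.array([[sxx, sxy, sxz], [sxy, syy, syz], [sxz, syz, szz]]))

    @classmethod
    def from_parameters(cls, da: float, rhombicity: float,
                        euler_deg: tuple[float, float, float] = (0.0, 0.0, 0.0),
                        ) -> "AlignmentTensor":
        """Build from magnitude Da (Hz), rhombicity R in [0, 2/3] and z-y-z
        Euler angles (deg) orienting the principal frame."""
        if not 0 <= rhombicity <= 2.0 / 3.0 + 1e-12:
            raise ValueError("rhombicity must lie in [0, 2/3]")
        azz = 2.0 * da
        delta = 1.5 * rhombicity * da
        diag = np.diag([-da + delta, -da - delta, azz])
        phi, theta, psi = (math.radians(a) for a in euler_deg)
        rot = _rot_z(phi) @ _rot_y(theta) @ _rot_z(psi)
        return cls(rot @ diag @ rot.T)

    @property
    def principal_components(self) -> tuple[float, float, float]:
        """(Axx, Ayy, Azz) with |Azz| >= |Ayy| >= |Axx|."""
        return tuple(self._principal)

    @property
    def da(self) -> float:
        return self._principal[2] / 2.0

    @property
    def rhombicity(self) -> float:
        axx, ayy, azz = self._principal
        if azz == 0:
            return 0.0
        return 2.0 * (axx - ayy) / (3.0 * azz)

    @property
    def euler_deg(self) -> tuple[float, float, float]:
        """z-y-z Euler angles of the principal frame, degrees, in
        [0,360) x [0,180) x [0,360)."""
        r = self._axes
        theta = math.acos(np.clip(r[2, 2], -1.0, 1.0))
        if abs(math.sin(theta)) < 1e-9:
            phi = math.atan2(r[1, 0], r[0, 0])
            psi = 0.0
        else:
            phi = math.atan2(r[1, 2], r[0, 2])
            psi = math.atan2(r[2, 1], -r[2, 0])
        return (math.degrees(phi) % 360.0, math.degrees(theta) % 180.0,
                math.degrees(psi) % 360.0)

    def is_zero(self, tol: float = 1e-12) -> bool:
        return bool(np.all(np.abs(self.saupe) < tol))


def _unit_vectors(vectors: Sequence[AmideVector] | np.ndarray) -> np.ndarray:
    if isinstance(vectors, np.ndarray):
        arr = np.atleast_2d(np.asarray(vectors, dtype=float))
    else:
        arr = np.array([v.vector for v in vectors], dtype=float)
    norms = np.linalg.norm(arr, axis=1)
    if np.any(np.abs(norms - 1.0) > 1e-9):
        logger.warning("non-unit amide vectors normalized before use")
        arr = arr / norms[:, None]
    return arr


def back_calculate(vectors: Sequence[AmideVector] | np.ndarray,
                   tensor: AlignmentTensor,
                   method: str = "saupe") -> np.ndarray:
    """Couplings (Hz) for each bond vector under the alignment tensor.

    method='saupe' evaluates v^T S v; method='angles' evaluates the polar
    form in the principal frame. The two agree to numerical precision and
    the 'angles' path exists as an internal consistency check.
    """
    arr = _unit_vectors(vectors)
    if method == "saupe":
        return np.einsum("ni,ij,nj->n", arr, tensor.saupe, arr)
    if method == "angles":
        local = arr @ tensor._axes       # coordinates in principal frame
        cos_t = local[:, 2]
        sin2_t = 1.0 - cos_t ** 2
        phi = np.arctan2(local[:, 1], local[:, 0])
        da, rr = tensor.da, tensor.rhombicity
        return da * ((3.0 * cos_t ** 2 - 1.0)
                     + 1.5 * rr * sin2_t * np.cos(2.0 * phi))
    raise ValueError(f"unknown method {method!r}")


def q_factor(d_obs: np.ndarray, d_calc: np.ndarray) -> float:
    """Normalized rms deviation Q = rms(d_obs - d_calc) / rms(d_obs)."""
    d_obs = np.asarray(d_obs, dtype=float)
    d_calc = np.asarray(d_calc, dtype=float)
    if d_obs.shape != d_calc.shape:
        raise ValueError("series length mismatch")
    rms_obs = math.sqrt(float(np.mean(d_obs ** 2)))
    rms_res = math.sqrt(float(np.mean((d_obs - d_calc) ** 2)))
    if rms_obs == 0.0:
        if rms_res == 0.0:
            return 0.0   # null data fitted by the null tensor, by convention
        raise UndefinedQError("rms(d_obs) = 0 with nonzero residuals")
    return rms_res / rms_obs


@dataclass
class FitResult:
    tensor: AlignmentTensor
    chi2: float
    q: float
    n_used: int
    residue_numbers: np.ndarray
    residuals: np.ndarray          # d_obs - d_calc, Hz
    d_calc: np.ndarray

    @property
    def q_factor(self) -> float:
        return self.q


def _design_matrix(arr: np.ndarray) -> np.ndarray:
    x, y, z = arr[:, 0], arr[:, 1], arr[:, 2]
    return np.column_stack([x * x - z * z, y * y - z * z,
                            2 * x * y, 2 * x * z, 2 * y * z])


def match_vectors(vectors: Sequence[AmideVector],
                  measurements: Sequence[RDCMeasurement],
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Pairwise-match vectors and measurements on residue number."""
    vmap = {v.residue_number: v.vector for v in vectors}
    nums, arr, dobs, sig = [], [], [], []
    dropped = 0
    for m in measurements:
        if m.residue_number in vmap:
            nums.append(m.residue_number)
            arr.append(vmap[m.residue_number])
            dobs.append(m.d_obs)
            sig.append(m.sigma)
        else:
            dropped += 1
    if dropped:
        logger.info("dropped %d measurements without a matching vector", dropped)
    return (np.array(nums, dtype=int), np.asarray(arr, dtype=float),
            np.array(dobs), np.array(sig))


def fit_tensor(vectors: Sequence[AmideVector],
               measurements: Sequence[RDCMeasurement],
               weighted: bool = True) -> FitResult:
    """Least-squares Saupe fit minimizing chi^2 = sum((d_obs-d_calc)/sigma)^2.

    With weighted=False unit weights are used instead of measurement sigmas
    (chi^2 is then in Hz^2).
    """
    nums, arr, d_obs, sigma = match_vectors(vectors, measurements)
    n = len(nums)
    if n < 5:
        raise UnderdeterminedError(f"{n} usable measurements (need >= 5)")
    arr = _unit_vectors(arr)
    a = _design_matrix(arr)
    w = 1.0 / sigma if weighted else np.ones(n)
    aw = a * w[:, None]
    sv = np.linalg.svd(aw, compute_uv=False)
    if sv[-1] < 1e-10 * sv[0]:
        raise ConditioningError(
            "rank-deficient design: bond vectors too nearly collinear/coplanar "
            f"(singular value ratio {sv[-1] / sv[0]:.2e})")
    coef, *_ = np.linalg.lstsq(aw, d_obs * w, rcond=None)
    tensor = AlignmentTensor.from_elements(*coef)
    d_calc = a @ coef
    resid = d_obs - d_calc
    chi2 = float(np.sum((resid * w) ** 2))
    return FitResult(tensor=tensor, chi2=chi2, q=q_factor(d_obs, d_calc),
                     n_used=n, residue_numbers=nums, residuals=resid,
                     d_calc=d_calc)


def fit_tensor_nonlinear(vectors: Sequence[AmideVector],
                         measurements: Sequence[RDCMeasurement],
                         x0: np.ndarray | None = None,
                         weighted: bool = True) -> FitResult:
    """Nonlinear (Da, R, phi, theta, psi) fit; cross-check of the linear solver."""
    nums, arr, d_obs, sigma = match_vectors(vectors, measurements)
    if len(nums) < 5:
        raise UnderdeterminedError(f"{len(nums)} usable measurements (need >= 5)")
    arr = _unit_vectors(arr)
    w = 1.0 / sigma if weighted else np.ones(len(nums))

    def resid(p):
        da, rr, phi, theta, psi = p
        t = AlignmentTensor.from_parameters(da, np.clip(rr, 0.0, 2.0 / 3.0),
                                            (phi, theta, psi))
        return (d_obs - back_calculate(arr, t)) * w

    if x0 is None:
        lin = fit_tensor(vectors, measurements, weighted=weighted)
        x0 = np.array([lin.tensor.da, lin.tensor.rhombicity,
                       *lin.tensor.euler_deg])
    sol = least_squares(resid, x0, method="lm", xtol=1e-14, ftol=1e-14)
    da, rr, phi, theta, psi = sol.x
    tensor = AlignmentTensor.from_parameters(da, float(np.clip(rr, 0, 2 / 3)),
                                             (phi, theta, psi))
    d_calc = back_calculate(arr, tensor)
    res = d_obs - d_calc
    return FitResult(tensor=tensor, chi2=float(np.sum((res * w) ** 2)),
                     q=q_factor(d_obs, d_calc), n_used=len(nums),
                     residue_numbers=nums, residuals=res, d_calc=d_calc)


def fit_report(fit: FitResult) -> str:
    """Key/value text report plus per-residue residual table."""
    t = fit.tensor
    axx, ayy, azz = t.principal_components
    lines = [
        f"n_used\t{fit.n_used}",
        f"chi2\t{fit.chi2:.6g}",
        f"q_factor\t{fit.q:.6g}",
        f"Da_hz\t{t.da:.6g}",
        f"rhombicity\t{t.rhombicity:.6g}",
        f"Axx_hz\t{axx:.6g}",
        f"Ayy_hz\t{ayy:.6g}",
        f"Azz_hz\t{azz:.6g}",
        "euler_convention\tz-y-z, degrees, [0,360)x[0,180)x[0,360)",
        "euler_deg\t{:.3f} {:.3f} {:.3f}".format(*t.euler_deg),
        "",
        "residue\td_calc_hz\tresidual_hz",
    ]
    for num, dc, r in zip(fit.residue_numbers, fit.d_calc, fit.residuals):
        lines.append(f"{num}\t{dc:.4f}\t{r:.4f}")
    return "\n".join(lines) + "\n"
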