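"""Local parameterization of two-stranded parallel coiled coils.

For each interior residue a local helix frame (axis point, radius, rise,
twist) is computed from three consecutive CA positions by the bisector
construction. Pairing the two chains' local axes gives the coiled-coil
axis, the local coiled-coil radius (the "inter-helical distance" reported
for dimers: helix axis to coiled-coil axis, i.e. half the axis-axis
separation), the local superhelical pitch, and the Crick phase from which
heptad letters a-g are assigned.

Conventions
-----------
Crick phase 0 points from the local helix axis directly away from the
coiled-coil axis; the most buried orientation is therefore 180 deg, and
letters a/d are anchored on the two ideal positions straddling it.
Positions where the superhelical phase advances by less than
``SUPERCOIL_PHASE_MIN`` deg/residue are flagged as not supercoiled and the
pitch is reported as +inf.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .structure_io import Residue

logger = logging.getLogger("coilreg")

CHAIN_BREAK_CA_CA = 4.5       # Angstrom: larger gaps split a chain into segments
SUPERCOIL_PHASE_MIN = 0.8     # deg/residue: below this the coil is not supercoiled
HEPTAD_DRIFT_TOL = 15.0       # deg cumulative Crick-phase drift per regular heptad
IDEAL_HEPTAD_STEP = 720.0 / 7.0   # deg/residue Crick-phase advance (3.5 res/turn)
HEPTAD_LETTERS = "abcdefg"


class InsufficientDataError(Exception):
    """Raised when too few residues/pairs are available for the analysis."""


def wrap_angle(deg):
    """Wrap angle(s) to (-180, 180]."""
    return (np.asarray(deg) + 180.0) % 360.0 - 180.0


@dataclass
class LocalHelixFrame:
    """Per-residue local helix geometry.

    ``local_twist`` is the rotation per residue about the local axis step in
    the fixed (laboratory) frame: for a supercoiled helix it equals the sum
    of the minor-helix twist and the superhelical twist (~98.9 deg/residue
    for a canonical dimer); the heptad-frame twist of ~102.9 deg/residue is
    the per-residue Crick-phase step reported in the coiled-coil profile.
    """
    residue: Residue
    axis_point: np.ndarray | None
    axis_direction: np.ndarray | None
    local_rise: float
    local_twist: float
    local_helix_radius: float
    defined: bool = True

    @property
    def residue_number(self) -> int:
        return self.residue.number


@dataclass
class CoiledCoilProfile:
    """Per matched residue position, indexed by chain-A residue number."""
    residue_numbers: np.ndarray
    cc_axis_points: np.ndarray     # (n, 3)
    cc_radius: np.ndarray
    cc_pitch: np.ndarray           # +inf where not supercoiled
    delta_phase: np.ndarray        # deg/residue superhelical phase advance
    crick_phase: np.ndarray        # deg in [0, 360)
    supercoiled: np.ndarray        # bool
    heptad_letters: list[str] = field(default_factory=list)
    residues: list[Residue] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.residue_numbers)

    def to_frame(self) -> pd.DataFrame:
        d = {
            "residue": self.residue_numbers,
            "cc_radius_A": self.cc_radius,
            "cc_pitch_A": self.cc_pitch,
            "delta_phase_deg": self.delta_phase,
            "crick_phase_deg": self.crick_phase,
            "supercoiled": self.supercoiled,
        }
        if self.heptad_letters:
            d["heptad"] = self.heptad_letters
        return pd.DataFrame(d)

    def window(self, first: int, last: int) -> np.ndarray:
        return (self.residue_numbers >= first) & (self.residue_numbers <= last)


@dataclass
class GeometrySummary:
    window: tuple[int, int]
    mean_radius: float
    sd_radius: float
    mean_pitch: float
    sd_pitch: float
    n_regular_heptads: int
    heptad_span: tuple[int, int] | None


def _segments(residues: list[Residue]) -> list[list[Residue]]:
    """Split at missing CA or CA-CA breaks > CHAIN_BREAK_CA_CA."""
    with_ca = [r for r in residues if r.coords("CA") is not None]
    segs: list[list[Residue]] = []
    cur: list[Residue] = []
    for r in with_ca:
        if cur and np.linalg.norm(r.coords("CA") - cur[-1].coords("CA")) > CHAIN_BREAK_CA_CA:
            segs.append(cur)
            cur = []
        cur.append(r)
    if cur:
        segs.append(cur)
    return segs


def _proj_angle(v1: np.ndarray, v2: np.ndarray, axis: np.ndarray) -> float:
    """Signed angle (deg) from v1 to v2 about unit vector axis."""
    p1 = v1 - np.dot(v1, axis) * axis
    p2 = v2 - np.dot(v2, axis) * axis
    n1, n2 = np.linalg.norm(p1), np.linalg.norm(p2)
    if n1 < 1e-9 or n2 < 1e-9:
        return math.nan
    p1, p2 = p1 / n1, p2 / n2
    s = np.dot(np.cross(p1, p2), axis)
    c = np.clip(np.dot(p1, p2), -1.0, 1.0)
    return math.degrees(math.atan2(s, c))


def local_helix_frames(residues: list[Residue]) -> list[LocalHelixFrame]:
    """TWISTER-style local helix frames from three-CA bisector geometry.

    For interior residue i the unit bisector of the angle at CA(i) points
    at the local helix axis; the radius is the least-squares solution that
    makes consecutive axis points advance parallel to the axis. Terminal
    residues carry no frame; collinear (straight) stretches are flagged as
    undefined rather than raising.
    """
    frames: list[LocalHelixFrame] = []
    for seg in _segments(residues):
        if len(seg) < 4:
            continue
        ca = np.array([r.coords("CA") for r in seg])
        m = len(seg)
        bis = np.full((m, 3), np.nan)
        ok = np.zeros(m, dtype=bool)
        for i in range(1, m - 1):
            u1 = ca[i - 1] - ca[i]
            u2 = ca[i + 1] - ca[i]
            u1 /= np.linalg.norm(u1)
            u2 /= np.linalg.norm(u2)
            b = u1 + u2
            nb = np.linalg.norm(b)
            if nb < 1e-6:
                continue  # collinear: undefined
            bis[i] = b / nb
            ok[i] = True
        # per-pair radius from consecutive bisectors
        pair_r = np.full(m, np.nan)     # value for pair (i, i+1)
        for i in range(1, m - 2):
            if not (ok[i] and ok[i + 1]):
                continue
            q = bis[i + 1] - bis[i]
            d = ca[i + 1] - ca[i]
            qq = float(np.dot(q, q))
            if qq < 1e-10:
                continue  # parallel bisectors: straight helix, radius undefined
            r = -float(np.dot(d, q)) / qq
            if r > 0:
                pair_r[i] = r
        radius = np.full(m, np.nan)
        for i in range(1, m - 1):
            vals = [pair_r[j] for j in (i - 1, i) if not math.isnan(pair_r[j])]
            if vals:
                radius[i] = float(np.mean(vals))
        axis_pt = np.full((m, 3), np.nan)
        for i in range(1, m - 1):
            if ok[i] and not math.isnan(radius[i]):
                axis_pt[i] = ca[i] + radius[i] * bis[i]
        # rise / twist from consecutive axis points
        pair_rise = np.full(m, np.nan)
        pair_twist = np.full(m, np.nan)
        for i in range(1, m - 2):
            if np.any(np.isnan(axis_pt[i])) or np.any(np.isnan(axis_pt[i + 1])):
                continue
            step = axis_pt[i + 1] - axis_pt[i]
            rise = float(np.linalg.norm(step))
            if rise < 1e-9:
                continue
            a = step / rise
            tw = _proj_angle(ca[i] - axis_pt[i], ca[i + 1] - axis_pt[i + 1], a)
            pair_rise[i] = rise
            pair_twist[i] = abs(tw)
        for i in range(1, m - 1):
            rises = [pair_rise[j] for j in (i - 1, i) if not math.isnan(pair_rise[j])]
            twists = [pair_twist[j] for j in (i - 1, i) if not math.isnan(pair_twist[j])]
            defined = ok[i] and not math.isnan(radius[i]) and bool(rises)
            adir = None
            if defined:
                lo = i - 1 if not np.any(np.isnan(axis_pt[i - 1])) else i
                hi = i + 1 if not np.any(np.isnan(axis_pt[i + 1])) else i
                if hi > lo:
                    step = axis_pt[hi] - axis_pt[lo]
                    nrm = np.linalg.norm(step)
                    adir = step / nrm if nrm > 1e-9 else None
                defined = adir is not None
            frames.append(LocalHelixFrame(
                residue=seg[i],
                axis_point=axis_pt[i] if defined else None,
                axis_direction=adir,
                local_rise=float(np.mean(rises)) if rises else math.nan,
                local_twist=float(np.mean(twists)) if twists else math.nan,
                local_helix_radius=radius[i] if defined else math.nan,
                defined=bool(defined)))
    return frames


def coiled_coil_profile(frames_a: list[LocalHelixFrame],
                        frames_b: list[LocalHelixFrame],
                        register_map: dict[int, int] | None = None,
                        ) -> CoiledCoilProfile:
    """Pair the two chains' local helix axes into a coiled-coil profile.

    The register map sends chain-A residue numbers to chain-B residue
    numbers and defaults to pairing equal numbers (parallel, in-register
    dimer). The coiled-coil radius at each position is the distance from a
    helix-axis point to the midpoint axis, i.e. half the axis-axis
    separation of the dimer.
    """
    fa = {f.residue_number: f for f in frames_a if f.defined}
    fb = {f.residue_number: f for f in frames_b if f.defined}
    if register_map is None:
        register_map = {n: n for n in fa}
    paired = sorted(n for n in fa if register_map.get(n) in fb)
    if len(paired) < 7:
        raise InsufficientDataError(
            f"only {len(paired)} paired positions with defined frames (need >= 7)")
    nums = np.array(paired)
    oa = np.array([fa[n].axis_point for n in paired])
    ob = np.array([fb[register_map[n]].axis_point for n in paired])
    center = 0.5 * (oa + ob)
    radius = np.linalg.norm(oa - center, axis=1)

    n = len(paired)
    pair_dphase = np.full(n, np.nan)
    pair_pitch = np.full(n, np.nan)
    for i in range(n - 1):
        if nums[i + 1] - nums[i] != 1:
            continue
        t = center[i + 1] - center[i]
        rise_cc = float(np.linalg.norm(t))
        if rise_cc < 1e-9:
            continue
        a = t / rise_cc
        dph = _proj_angle(oa[i] - center[i], oa[i + 1] - center[i + 1], a)
        if math.isnan(dph):
            continue
        pair_dphase[i] = dph
        pair_pitch[i] = (rise_cc * 360.0 / abs(dph)) if abs(dph) >= 1e-6 else math.inf

    dphase = np.full(n, np.nan)
    pitch = np.full(n, np.nan)
    for i in range(n):
        vals = [pair_dphase[j] for j in (i - 1, i)
                if 0 <= j < n and not math.isnan(pair_dphase[j])]
        if vals:
            dphase[i] = float(np.mean(vals))
            pv = [pair_pitch[j] for j in (i - 1, i)
                  if 0 <= j < n and not math.isnan(pair_pitch[j])]
            pitch[i] = float(np.mean(pv)) if all(map(math.isfinite, pv)) else math.inf
    supercoiled = np.abs(np.nan_to_num(dphase, nan=0.0)) >= SUPERCOIL_PHASE_MIN
    pitch = np.where(supercoiled, pitch, math.inf)

    # Crick phase of chain A about its local helix axis, zero pointing away
    # from the coiled-coil axis.
    crick = np.full(n, np.nan)
    for i in range(n):
        f = fa[paired[i]]
        h = f.axis_direction
        u_out = oa[i] - center[i]
        ca = f.residue.coords("CA")
        v = ca - oa[i]
        ang = _proj_angle(u_out, v, h)
        if not math.isnan(ang):
            crick[i] = ang % 360.0

    return CoiledCoilProfile(
        residue_numbers=nums,
        cc_axis_points=center,
        cc_radius=radius,
        cc_pitch=pitch,
        delta_phase=dphase,
        crick_phase=crick,
        supercoiled=supercoiled,
        residues=[fa[m].residue for m in paired])


def heptad_letter_from_phase(phase_deg: float, step_sign: int = 1) -> str:
    """Map a Crick phase to its heptad letter.

    Letters advance a,b,c,... with the per-residue ideal phase step of
    +/-720/7 deg; 'a' and 'd' are anchored on the two ideal positions that
    straddle the buried orientation (180 deg).
    """
    p_a = 180.0 + step_sign * IDEAL_HEPTAD_STEP / 4.0
    anchors = [(p_a + k * step_sign * IDEAL_HEPTAD_STEP) % 360.0 for k in range(7)]
    dists = [abs(wrap_angle(phase_deg - a)) for a in anchors]
    return HEPTAD_LETTERS[int(np.argmin(dists))]


def assign_heptads(profile: CoiledCoilProfile,
                   drift_tol: float = HEPTAD_DRIFT_TOL) -> GeometrySummary:
    """Assign heptad letters from Crick phase and count regular heptads.

    A heptad starting at position i is regular when all eight positions
    i..i+7 are consecutive, supercoiled, and the cumulative Crick-phase
    drift over the heptad (ideal advance is congruent to 0 mod 360) stays
    below ``drift_tol``. The longest run of consecutive regular starts
    defines the heptad span; whole heptads within it are counted.
    """
    n = len(profile)
    phases = profile.crick_phase
    steps = wrap_angle(np.diff(phases))
    finite = steps[~np.isnan(steps)]
    step_sign = 1 if (len(finite) == 0 or np.median(finite) >= 0) else -1
    profile.heptad_letters = [
        heptad_letter_from_phase(p, step_sign) if not math.isnan(p) else "-"
        for p in phases]

    nums = profile.residue_numbers
    regular_start = np.zeros(n, dtype=bool)
    for i in range(n - 7):
        if nums[i + 7] - nums[i] != 7:
            continue
        if not profile.supercoiled[i:i + 8].all():
            continue
        if math.isnan(phases[i]) or math.isnan(phases[i + 7]):
            continue
        if abs(wrap_angle(phases[i + 7] - phases[i])) < drift_tol:
            regular_start[i] = True

    best_run: tuple[int, int] | None = None
    i = 0
    while i < n:
        if regular_start[i]:
            j = i
            while j + 1 < n and regular_start[j + 1]:
                j += 1
            if best_run is None or (j - i) > (best_run[1] - best_run[0]):
                best_run = (i, j)
            i = j + 1
        else:
            i += 1

    if best_run is None:
        n_heptads = 0
        span = None
        mask = profile.supercoiled
    else:
        i0, j0 = best_run
        span_len = (j0 + 7) - i0 + 1
        n_heptads = span_len // 7
        span = (int(nums[i0]), int(nums[j0 + 7]))
        mask = profile.window(*span)

    radius = profile.cc_radius[mask]
    pitchv = profile.cc_pitch[mask]
    pitchv = pitchv[np.isfinite(pitchv)]
    window = ((int(nums[0]), int(nums[-1])) if span is None else span)
    return GeometrySummary(
        window=window,
        mean_radius=float(np.mean(radius)) if len(radius) else math.nan,
        sd_radius=float(np.std(radius, ddof=1)) if len(radius) > 1 else 0.0,
        mean_pitch=float(np.mean(pitchv)) if len(pitchv) else math.inf,
        sd_pitch=float(np.std(pitchv, ddof=1)) if len(pitchv) > 1 else 0.0,
        n_regular_heptads=int(n_heptads),
        heptad_span=span)


def summarize_window(profile: CoiledCoilProfile, first: int, last: int,
                     ) -> GeometrySummary:
    """Mean +/- sd radius and pitch over an explicit residue window."""
    mask = profile.window(first, last)
    if not mask.any():
        raise InsufficientDataError(f"no profile positions in [{first}, {last}]")
    radius = profile.cc_radius[mask]
    pitchv = profile.cc_pitch[mask]
    pitchv = pitchv[np.isfinite(pitchv)]
    return GeometrySummary(
        window=(first, last),
        mean_radius=float(np.mean(radius)),
        sd_radius=float(np.std(radius, ddof=1)) if len(radius) > 1 else 0.0,
        mean_pitch=float(np.mean(pitchv)) if len(pitchv) else math.inf,
        sd_pitch=float(np.std(pitchv, ddof=1)) if len(pitchv) > 1 else 0.0,
        n_regular_heptads=0,
        heptad_span=None)
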