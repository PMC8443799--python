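"""Synthetic fixtures: Crick-parameterized coiled coils, simulated RDC,
relaxation and binding data.

The coiled-coil generator realizes the Crick parameterization of a parallel
dimer: CA atoms follow a minor helix (radius r1, twist omega1, rise d)
wound around a superhelix (radius r0, pitch P; the pitch sign encodes
handedness, negative = left-handed), with the two chains 180 deg apart in
superhelical phase. Backbone N, C, O and the amide H are placed from local
CA-frame offsets calibrated once against an ideal straight alpha-helix.
Defaults reproduce the canonical dimer geometry: r0 = 4.9 A, r1 = 2.26 A,
omega1 = 720/7 deg/residue (3.5 residues per turn, the heptad periodicity),
rise 1.51 A/residue and the theoretical left-handed pitch of 135 A arising
from the mismatch between alpha-helical (~3.6 res/turn) and heptad
periodicity.

Crick phase convention: phase 0 points from the local helix axis directly
away from the coiled-coil axis, so the buried orientation is 180 deg;
heptad letter 'a' sits at the ideal position 180 + (720/7)/4 deg. Every
generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import assembly
from .binding_seq import CosedExperiment, _hyperbolic, _quadratic_bound_fraction
from .rdc import AlignmentTensor, RDCMeasurement, back_calculate
from .relaxation import PeakPair
from .structure_io import (Atom, Residue, Structure, amide_vectors,
                           reconstruct_amide_h, ONE_TO_THREE)

IDEAL_OMEGA1 = 720.0 / 7.0       # deg/residue, 3.5 residues per helical turn
DEFAULT_PITCH = -135.0           # A, negative = left-handed supercoil
DEFAULT_R0 = 4.9                 # A, superhelical radius of the dimer
DEFAULT_R1 = 2.26                # A, alpha-helix CA radius
DEFAULT_RISE = 1.51              # A/residue along the coiled-coil axis


class ParameterError(Exception):
    """Inconsistent Crick parameter combination."""


@dataclass
class CrickParameters:
    r0: float = DEFAULT_R0
    r1: float = DEFAULT_R1
    pitch: float = DEFAULT_PITCH     # signed; or give omega0 instead
    omega0: float | None = None      # deg/residue superhelical twist (signed)
    omega1: float = IDEAL_OMEGA1     # deg/residue local helical twist
    rise: float = DEFAULT_RISE       # A/residue along the coiled-coil axis
    phase1: float = 180.0 + IDEAL_OMEGA1 / 4.0   # Crick phase of residue 1 ('a')
    n_res: int = 70

    def __post_init__(self) -> None:
        if not (self.r0 > self.r1 > 0):
            raise ParameterError("need r0 > r1 > 0")
        if self.n_res < 2:
            raise ParameterError("n_res must be >= 2")
        if self.omega0 is None:
            if self.pitch == 0:
                raise ParameterError("pitch must be nonzero")
            self.omega0 = 360.0 * self.rise / self.pitch
        else:
            implied = (360.0 * self.rise / self.omega0
                       if self.omega0 != 0 else math.inf)
            if math.isfinite(implied) and self.pitch != DEFAULT_PITCH \
                    and abs(implied - self.pitch) > 1e-6 * abs(self.pitch):
                raise ParameterError(
                    f"(omega0, pitch, rise) inconsistent: omega0 {self.omega0} "
                    f"implies pitch {implied:.3f}, got {self.pitch}")
            self.pitch = implied


@dataclass
class DistortionSpec:
    supercoil_loss_after: int | None = None   # residue index; omega0 -> 0 after it
    fray_ranges: list[tuple[int, int]] = field(default_factory=list)
    linker_range: tuple[int, int] | None = None
    noise_sd: float = 0.0                     # A, per-atom Gaussian


def _local_ca_frames(ca: np.ndarray) -> np.ndarray:
    """Orthonormal frames (n, 3, 3) from a CA trace padded by one residue at
    each end; columns are (outward radial, transverse, chain direction)."""
    n = len(ca) - 2
    frames = np.zeros((n, 3, 3))
    for i in range(1, n + 1):
        u1 = ca[i - 1] - ca[i]
        u2 = ca[i + 1] - ca[i]
        u1 /= np.linalg.norm(u1)
        u2 /= np.linalg.norm(u2)
        b = u1 + u2
        e_x = -b / np.linalg.norm(b)                  # away from the helix axis
        t = ca[i + 1] - ca[i - 1]
        e_z = t - np.dot(t, e_x) * e_x
        e_z /= np.linalg.norm(e_z)
        e_y = np.cross(e_z, e_x)
        frames[i - 1] = np.column_stack([e_x, e_y, e_z])
    return frames


def _calibrate_backbone_offsets() -> dict[str, np.ndarray]:
    """Local-frame offsets of N, C, O, H relative to CA, averaged over the
    interior of an ideal straight alpha-helix built from (-57, -47) dihedrals."""
    n_res = 14
    coords = assembly.grow_backbone([(-57.0, -47.0)] * n_res)
    ca = coords[:, 1]
    frames = _local_ca_frames(ca)      # frame j belongs to residue j + 1
    offs = {name: [] for name in ("N", "C", "O", "H")}
    for i in range(4, n_res - 4):
        r = frames[i - 1]
        offs["N"].append(r.T @ (coords[i, 0] - ca[i]))
        offs["C"].append(r.T @ (coords[i, 2] - ca[i]))
        offs["O"].append(r.T @ (coords[i, 3] - ca[i]))
        h = reconstruct_amide_h(coords[i, 0], ca[i], coords[i - 1, 2])
        offs["H"].append(r.T @ (h - ca[i]))
    return {k: np.mean(v, axis=0) for k, v in offs.items()}


_BACKBONE_OFFSETS = _calibrate_backbone_offsets()


def _crick_ca_trace(params: CrickParameters, chain_phase_deg: float,
                    t_index: np.ndarray,
                    supercoil_loss_after: int | None = None) -> np.ndarray:
    """CA positions at (possibly fractional) residue indices t_index."""
    w0 = math.radians(params.omega0)
    w1 = math.radians(params.omega1)
    phi0 = math.radians(chain_phase_deg)
    nu0 = math.radians(params.phase1)
    d = params.rise
    if supercoil_loss_after is not None:
        t_eff = np.minimum(t_index, float(supercoil_loss_after - 1))
    else:
        t_eff = t_index
    mu = w0 * t_eff + phi0
    nu = w1 * t_index + nu0
    alpha = math.atan2(params.r0 * w0, d)
    x = (params.r0 * np.cos(mu) + params.r1 * np.cos(mu) * np.cos(nu)
         - params.r1 * math.cos(alpha) * np.sin(mu) * np.sin(nu))
    y = (params.r0 * np.sin(mu) + params.r1 * np.sin(mu) * np.cos(nu)
         + params.r1 * math.cos(alpha) * np.cos(mu) * np.sin(nu))
    z = d * t_index - params.r1 * math.sin(alpha) * np.sin(nu)
    return np.column_stack([x, y, z])


def generate_coiled_coil(params: CrickParameters | None = None,
                         distortion: DistortionSpec | None = None,
                         seed: int = 0,
                         sequence: str | None = None) -> Structure:
    """Parallel two-chain coiled coil with backbone N, CA, C, O, H atoms.

    Distortions (supercoil loss, frayed ranges, a random-coil linker,
    coordinate noise) are applied after the ideal construction and are
    deterministic for a fixed seed. Residues are numbered from 1; both
    chains carry the same sequence (poly-Ala when none is given).
    """
    params = params or CrickParameters()
    distortion = distortion or DistortionSpec()
    rng = np.random.default_rng(seed)
    n = params.n_res
    if sequence is not None and len(sequence) != n:
        raise ParameterError("sequence length must equal n_res")
    for lo, hi in distortion.fray_ranges:
        if not (1 <= lo <= hi <= n):
            raise ParameterError(f"fray range ({lo}, {hi}) outside [1, {n}]")
    if distortion.linker_range is not None:
        lo, hi = distortion.linker_range
        if not (1 < lo <= hi < n):
            raise ParameterError("linker range must be interior to the chain")

    chains: dict[str, list[Residue]] = {}
    for chain_id, phase in (("A", 0.0), ("B", 180.0)):
        t = np.arange(-1, n + 1, dtype=float)
        ca = _crick_ca_trace(params, phase, t,
                             distortion.supercoil_loss_after)
        frames = _local_ca_frames(ca)
        residues: list[Residue] = []
        for i in range(n):
            number = i + 1
            pos_ca = ca[i + 1]
            r = frames[i]
            aa = sequence[i].upper() if sequence else "A"
            name3 = ONE_TO_THREE.get(aa, "ALA")
            atoms = [Atom("N", "N", pos_ca + r @ _BACKBONE_OFFSETS["N"]),
                     Atom("CA", "C", pos_ca.copy()),
                     Atom("C", "C", pos_ca + r @ _BACKBONE_OFFSETS["C"]),
                     Atom("O", "O", pos_ca + r @ _BACKBONE_OFFSETS["O"]),
                     Atom("H", "H", pos_ca + r @ _BACKBONE_OFFSETS["H"])]
            residues.append(Residue(number=number, name=name3, atoms=atoms))

        if distortion.linker_range is not None:
            lo, hi = distortion.linker_range
            prev = residues[lo - 2]
            frame = tuple(prev.coords(x) for x in ("N", "CA", "C"))
            seq = "".join(res.one_letter for res in residues[lo - 1:hi])
            ens = assembly.sample_linker(
                seq, n=1, seed=int(rng.integers(2 ** 31)), start_frame=frame,
                start_number=lo, chain_id=chain_id)
            coil = ens.conformers[0].chain(chain_id)
            tail = residues[hi:]
            if tail:
                tail_struct = Structure(chains={chain_id: tail})
                docked = assembly.dock_onto_continuation(coil[-1], tail_struct)
                tail = docked.chain(chain_id)
            residues = residues[:lo - 1] + coil + tail

        keep = []
        for res in residues:
            frayed = any(lo <= res.number <= hi
                         for lo, hi in distortion.fray_ranges)
            if not frayed:
                keep.append(res)
        if distortion.noise_sd > 0:
            for res in keep:
                for a in res.atoms:
                    a.coords = a.coords + distortion.noise_sd * \
                        rng.standard_normal(3)
        chains[chain_id] = keep
    return Structure(chains=chains, source_id="synthetic-coiled-coil")


def generate_compact_domain(n_res: int, seed: int = 0, start_number: int = 1,
                            chain_id: str = "A") -> Structure:
    """Synthetic stand-in for a compact folded domain (backbone only).

    The CA trace winds along a spherical helix whose radius is chosen so
    consecutive CAs are ~3.8 A apart and adjacent windings stay clash-free,
    giving a globular footprint comparable to a real domain of this size.
    A small seeded jitter decorrelates repeated draws. This is a synthetic
    surrogate used where real folded-domain coordinates are not supplied;
    it reproduces a globular domain's compactness, not any fold.
    """
    rng = np.random.default_rng(seed)
    length = 3.8 * (n_res - 1)
    gap = 5.6                                  # A between adjacent windings
    radius = math.sqrt(gap * length / (2.0 * math.pi))
    turns = length / (2.0 * radius)
    # arc-length parameterization of theta in (0, pi)
    thetas = np.zeros(n_res)
    thetas[0] = 0.12
    nsub = 16   # sub-stepped arc-length integration keeps CA-CA near 3.8
    for i in range(1, n_res):
        th = thetas[i - 1]
        for _ in range(nsub):
            speed = radius * math.sqrt(1.0 + (turns * math.sin(th)) ** 2)
            th += (3.8 / nsub) / speed
        thetas[i] = th
    phis = turns * thetas + rng.uniform(0, 2 * math.pi)
    ca = np.column_stack([radius * np.sin(thetas) * np.cos(phis),
                          radius * np.sin(thetas) * np.sin(phis),
                          radius * np.cos(thetas)])
    ca = ca + 0.05 * rng.standard_normal(ca.shape)
    # random global orientation
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array([[1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
                    [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
                    [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)]])
    ca = ca @ rot.T
    pad = np.vstack([2 * ca[0] - ca[1] + 0.5, ca, 2 * ca[-1] - ca[-2] + 0.5])
    frames = _local_ca_frames(pad)
    residues = []
    for i in range(n_res):
        r = frames[i]
        atoms = [Atom("N", "N", ca[i] + r @ _BACKBONE_OFFSETS["N"]),
                 Atom("CA", "C", ca[i].copy()),
                 Atom("C", "C", ca[i] + r @ _BACKBONE_OFFSETS["C"]),
                 Atom("O", "O", ca[i] + r @ _BACKBONE_OFFSETS["O"])]
        residues.append(Residue(number=start_number + i, name="ALA", atoms=atoms))
    return Structure(chains={chain_id: residues},
                     source_id="synthetic-compact-domain")


def simulate_rdcs(structure: Structure, tensor: AlignmentTensor,
                  noise_sd: float = 0.0, seed: int = 0,
                  chain_ids: list[str] | None = None) -> list[RDCMeasurement]:
    """Back-calculated couplings plus Gaussian noise; sigma records the
    planted noise (unit sigma when noiseless, for unit-weight fits)."""
    rng = np.random.default_rng(seed)
    vecs = amide_vectors(structure, chain_ids=chain_ids)
    d = back_calculate(vecs, tensor)
    if noise_sd > 0:
        d = d + noise_sd * rng.standard_normal(len(d))
    sigma = noise_sd if noise_sd > 0 else 1.0
    return [RDCMeasurement(v.residue_number, float(x), sigma)
            for v, x in zip(vecs, d)]


def simulate_relaxation(rigid_ranges: list[tuple[int, int]],
                        flexible_ranges: list[tuple[int, int]],
                        noise: float = 0.05, seed: int = 0,
                        rigid_ratio: float = 0.8, flexible_ratio: float = 0.3,
                        base_height: float = 1000.0) -> list[PeakPair]:
    """Peak-height pairs for planted rigid/flexible residue ranges.

    True ratios are rigid_ratio / flexible_ratio; observed heights carry
    Gaussian noise of sd ``noise * base_height``, which is also recorded as
    the baseline noise.
    """
    spans = [(lo, hi, rigid_ratio) for lo, hi in rigid_ranges] + \
            [(lo, hi, flexible_ratio) for lo, hi in flexible_ranges]
    seen: set[int] = set()
    for lo, hi, _ in spans:
        rng_set = set(range(lo, hi + 1))
        if rng_set & seen:
            raise ValueError("rigid and flexible ranges must be disjoint")
        seen |= rng_set
    rng = np.random.default_rng(seed)
    baseline = max(noise, 1e-9) * base_height
    pairs = []
    for lo, hi, ratio in sorted(spans):
        for num in range(lo, hi + 1):
            unsat = base_height + (noise * base_height) * rng.standard_normal() \
                if noise > 0 else base_height
            sat = ratio * base_height + (noise * base_height) * \
                rng.standard_normal() if noise > 0 else ratio * base_height
            pairs.append(PeakPair(residue_number=num, height_sat=float(sat),
                                  height_unsat=float(unsat),
                                  baseline_noise=float(baseline)))
    pairs.sort(key=lambda p: p.residue_number)
    return pairs


def simulate_binding(model: str, kd: float, concentrations: np.ndarray,
                     noise: float = 0.0, seed: int = 0, f_max: float = 1.0,
                     probe_conc: float | None = None, r_free: float = 0.05,
                     r_bound: float = 0.25) -> pd.DataFrame:
    """Forward binding model plus Gaussian noise.

    model='hyperbolic' returns fraction-bound data; model='quadratic'
    returns anisotropy data for a probe of concentration ``probe_conc``
    (same units as the titration).
    """
    if kd <= 0:
        raise ValueError("kd must be > 0")
    conc = np.asarray(concentrations, dtype=float)
    rng = np.random.default_rng(seed)
    if model == "hyperbolic":
        y = f_max * _hyperbolic(conc, 1.0, kd)
        col = "fraction_bound"
    elif model == "quadratic":
        if probe_conc is None:
            raise ValueError("quadratic model needs probe_conc")
        b = _quadratic_bound_fraction(conc, probe_conc, kd)
        y = r_free + (r_bound - r_free) * b
        col = "anisotropy"
    else:
        raise ValueError("model must be 'hyperbolic' or 'quadratic'")
    if noise > 0:
        y = y + noise * np.ptp(y) * rng.standard_normal(len(conc))
    return pd.DataFrame({"concentration": conc, col: y})


def simulate_cosed_gel(kd: float, concentrations: np.ndarray,
                       noise: float = 0.05, seed: int = 0, f_max: float = 1.0,
                       total_intensity: float = 100.0,
                       background: float = 5.0) -> CosedExperiment:
    """Gel band intensities from a planted hyperbolic binding curve.

    The concentration series must include the 0 uM background lane. Pellet
    lanes carry the background plus the bound signal; supernatant lanes the
    unbound remainder; both with Gaussian noise of sd noise*total_intensity.
    """
    conc = np.asarray(concentrations, dtype=float)
    if not np.any(conc == 0):
        raise ValueError("include a 0 uM lane for background subtraction")
    rng = np.random.default_rng(seed)
    f = f_max * _hyperbolic(conc, 1.0, kd)
    sd = noise * total_intensity
    p = background + f * total_intensity + sd * rng.standard_normal(len(conc))
    s = (1.0 - f) * total_intensity + sd * rng.standard_normal(len(conc))
    return CosedExperiment(concentrations=conc, intensity_s=np.clip(s, 0, None),
                           intensity_p=np.clip(p, 0, None))
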