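"""Hybrid model assembly: threading, random linker sampling, merging,
crosslink compatibility.

Models are built from a segment plan covering a contiguous target range:
template-threaded coiled-coil segments, rigid folded domains and
random-extended segments for disordered stretches. Linkers are grown
residue by residue (NeRF) with backbone dihedrals from an extended /
polyproline-II-weighted coil library, with hard-sphere clash rejection.
Crosslink restraints are scored on CA-CA distances: <= 30 A for BS3
(amine-amine, spacer spans 26-30 A between surface lysines) and <= 16 A
for zero-length EDC pairs (lysine + acid side-chain reach plus backbone
tolerance; side chains are not modeled beyond CB, so all distances are
CA-based and documented as such).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .structure_io import Atom, Residue, Structure, ONE_TO_THREE
from .superpose import kabsch

logger = logging.getLogger("coilreg")

# ideal backbone geometry (A, deg)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8

CLASH_DISTANCE = 2.5        # A, heavy-atom hard-sphere cutoff
CLASH_EXEMPT_SEPARATION = 2  # bonded neighbours within 2 residues exempt
PEPTIDE_BOND_TOL = 0.2      # A around 1.33 at segment seams

CROSSLINK_CUTOFFS = {"BS3": 30.0, "EDC": 16.0}

PPII_PHI_PSI = (-75.0, 145.0)
PPII_WEIGHT = 0.2
COIL_PHI_RANGE = (-180.0, -50.0)
COIL_PSI_RANGE = (80.0, 180.0)


class SamplingFailure(Exception):
    """Linker sampling exhausted its retry budget."""


class MergeError(Exception):
    """Segment plan violation or discontinuous seam."""


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """NeRF: position of atom d given three predecessors and internal coords."""
    angle = math.radians(angle_deg)
    torsion = math.radians(torsion_deg)
    bcx, bcy, bcz = c[0] - b[0], c[1] - b[1], c[2] - b[2]
    inv = 1.0 / math.sqrt(bcx * bcx + bcy * bcy + bcz * bcz)
    bcx, bcy, bcz = bcx * inv, bcy * inv, bcz * inv
    abx, aby, abz = b[0] - a[0], b[1] - a[1], b[2] - a[2]
    nx = aby * bcz - abz * bcy
    ny = abz * bcx - abx * bcz
    nz = abx * bcy - aby * bcx
    inv = 1.0 / math.sqrt(nx * nx + ny * ny + nz * nz)
    nx, ny, nz = nx * inv, ny * inv, nz * inv
    mx = ny * bcz - nz * bcy
    my = nz * bcx - nx * bcz
    mz = nx * bcy - ny * bcx
    d0 = -bond * math.cos(angle)
    sa = bond * math.sin(angle)
    d1 = sa * math.cos(torsion)
    d2 = sa * math.sin(torsion)
    return np.array([c[0] + d0 * bcx + d1 * mx + d2 * nx,
                     c[1] + d0 * bcy + d1 * my + d2 * ny,
                     c[2] + d0 * bcz + d1 * mz + d2 * nz])


def _seed_backbone() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Canonical first-residue N, CA, C at the origin."""
    n = np.zeros(3)
    ca = np.array([BOND_N_CA, 0.0, 0.0])
    ang = math.radians(ANGLE_N_CA_C)
    c = ca + BOND_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])
    return n, ca, c


def grow_backbone(phi_psi: Sequence[tuple[float, float]],
                  start_frame: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
                  prev_psi: float = 140.0, with_oxygens: bool = True) -> np.ndarray:
    """Backbone coordinates (n_res, 4, 3) for atoms N, CA, C, O.

    With ``start_frame`` = (N, CA, C) of a preceding residue the first
    residue is grown as its peptide continuation (the preceding psi is
    taken as ``prev_psi``); otherwise the chain starts at the origin.
    """
    n_res = len(phi_psi)
    coords = np.zeros((n_res, 4, 3))
    if start_frame is None:
        n0, ca0, c0 = _seed_backbone()
        coords[0, 0], coords[0, 1], coords[0, 2] = n0, ca0, c0
        first = 1
        prev = (n0, ca0, c0)
        # rebuild C of residue 0 using its own phi? (phi of residue 0 is
        # undefined without a preceding C; the seed geometry stands in)
    else:
        pn, pca, pc = start_frame
        n = place_atom(pn, pca, pc, BOND_C_N, ANGLE_CA_C_N, prev_psi)
        ca = place_atom(pca, pc, n, BOND_N_CA, ANGLE_C_N_CA, 180.0)  # omega trans
        c = place_atom(pc, n, ca, BOND_CA_C, ANGLE_N_CA_C, phi_psi[0][0])
        coords[0, 0], coords[0, 1], coords[0, 2] = n, ca, c
        first = 1
        prev = (n, ca, c)
    for i in range(first, n_res):
        pn, pca, pc = prev
        psi_prev = phi_psi[i - 1][1]
        n = place_atom(pn, pca, pc, BOND_C_N, ANGLE_CA_C_N, psi_prev)
        ca = place_atom(pca, pc, n, BOND_N_CA, ANGLE_C_N_CA, 180.0)
        c = place_atom(pc, n, ca, BOND_CA_C, ANGLE_N_CA_C, phi_psi[i][0])
        coords[i, 0], coords[i, 1], coords[i, 2] = n, ca, c
        prev = (n, ca, c)
    if with_oxygens:
        add_oxygens(coords, [pp[1] for pp in phi_psi])
    return coords


def add_oxygens(coords: np.ndarray, psis: Sequence[float]) -> None:
    """Fill carbonyl oxygens (slot 3) in place: O at psi + 180 about N-CA-C."""
    n_res = len(coords)
    for i in range(n_res):
        n, ca, c = coords[i, 0], coords[i, 1], coords[i, 2]
        if i + 1 < n_res:
            psi = _dihedral(n, ca, c, coords[i + 1, 0])
        else:
            psi = psis[i]
        coords[i, 3] = place_atom(n, ca, c, BOND_C_O, ANGLE_CA_C_O, psi + 180.0)


def _dihedral(p0, p1, p2, p3) -> float:
    b0, b1, b2 = p1 - p0, p2 - p1, p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    return math.degrees(math.atan2(np.dot(np.cross(b1n, v), w), np.dot(v, w)))


def count_clashes(coords: np.ndarray) -> int:
    """Non-bonded heavy-atom pairs closer than CLASH_DISTANCE.

    coords is (n_res, n_atoms_per_res, 3); atoms of residues within
    CLASH_EXEMPT_SEPARATION of each other are exempt.
    """
    n_res, n_at, _ = coords.shape
    flat = coords.reshape(-1, 3)
    res_idx = np.repeat(np.arange(n_res), n_at)
    d = cdist(flat, flat)
    close = (d < CLASH_DISTANCE)
    sep = np.abs(res_idx[:, None] - res_idx[None, :])
    mask = close & (sep > CLASH_EXEMPT_SEPARATION)
    return int(np.triu(mask, k=1).sum())


def backbone_to_structure(coords: np.ndarray, sequence: str,
                          start_number: int, chain_id: str = "A") -> Structure:
    """Wrap an (n_res, 4, 3) N/CA/C/O array as a Structure."""
    residues = []
    for i, aa in enumerate(sequence):
        name3 = ONE_TO_THREE.get(aa.upper(), "GLY")
        atoms = [Atom("N", "N", coords[i, 0]), Atom("CA", "C", coords[i, 1]),
                 Atom("C", "C", coords[i, 2]), Atom("O", "O", coords[i, 3])]
        residues.append(Residue(number=start_number + i, name=name3, atoms=atoms))
    return Structure(chains={chain_id: residues}, source_id="model")


@dataclass
class ConformerEnsemble:
    conformers: list[Structure]
    end_to_end: np.ndarray
    clash_counts: np.ndarray
    seed: int
    acceptance_rate: float

    @property
    def n_conformers(self) -> int:
        return len(self.conformers)


def _draw_phi_psi(rng: np.random.Generator, n_res: int) -> np.ndarray:
    phi = rng.uniform(*COIL_PHI_RANGE, size=n_res)
    psi = rng.uniform(*COIL_PSI_RANGE, size=n_res)
    ppii = rng.random(n_res) < PPII_WEIGHT
    phi[ppii] = PPII_PHI_PSI[0]
    psi[ppii] = PPII_PHI_PSI[1]
    return np.column_stack([phi, psi])


def sample_linker(sequence: str, n: int, seed: int,
                  start_frame: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
                  end_anchor: np.ndarray | None = None,
                  end_tolerance: float = 10.0,
                  start_number: int = 1, chain_id: str = "A",
                  max_retries_per_conformer: int = 200) -> ConformerEnsemble:
    """Random extended conformers for a disordered segment.

    Dihedrals are drawn from the coil library (phi in [-180, -50], psi in
    [80, 180], 20% weight on ideal PPII); conformers with any non-bonded
    heavy-atom contact below 2.5 A are rejected and resampled. With an
    ``end_anchor``, only conformers whose final CA lies within
    ``end_tolerance`` of it are accepted. Bitwise reproducible for a seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    n_res = len(sequence)
    conformers: list[Structure] = []
    e2e = []
    attempts = 0
    while len(conformers) < n:
        if attempts >= max_retries_per_conformer * n:
            rate = len(conformers) / max(attempts, 1)
            raise SamplingFailure(
                f"accepted {len(conformers)}/{n} conformers after {attempts} "
                f"attempts (acceptance rate {rate:.3f}); relax the anchor "
                "tolerance or shorten the segment")
        attempts += 1
        phi_psi = _draw_phi_psi(rng, n_res)
        coords = grow_backbone(phi_psi, start_frame=start_frame,
                               with_oxygens=False)
        # anchor check first: it is cheap and dominates rejection when set
        if end_anchor is not None and \
                np.linalg.norm(coords[-1, 1] - end_anchor) > end_tolerance:
            continue
        add_oxygens(coords, phi_psi[:, 1])
        if n_res > 1 and count_clashes(coords) > 0:
            continue
        conformers.append(backbone_to_structure(coords, sequence, start_number,
                                                chain_id))
        e2e.append(float(np.linalg.norm(coords[-1, 1] - coords[0, 1])))
    return ConformerEnsemble(conformers=conformers, end_to_end=np.array(e2e),
                             clash_counts=np.zeros(n, dtype=int), seed=seed,
                             acceptance_rate=n / attempts)


BACKBONE_COPY = ("N", "CA", "C", "O", "CB")


def thread_backbone(template: Structure, chain_id: str, offset: int,
                    target_sequence: dict[int, str],
                    out_chain_id: str = "A") -> Structure:
    """Thread a target sequence onto template backbone coordinates.

    Target residue i inherits the backbone (through CB) of template residue
    i + offset and is renumbered/renamed to the target. A template gap
    inside the window raises, listing the missing residues.
    """
    tmap = {r.number: r for r in template.chain(chain_id)}
    missing = [i + offset for i in target_sequence if i + offset not in tmap]
    if missing:
        raise MergeError(f"template gap: missing residues {sorted(missing)}")
    residues = []
    for i in sorted(target_sequence):
        src = tmap[i + offset]
        aa = target_sequence[i]
        name3 = ONE_TO_THREE.get(aa.upper(), aa.upper() if len(aa) == 3 else "GLY")
        atoms = [Atom(a.name, a.element, a.coords.copy(), a.occupancy, a.b_factor)
                 for a in src.atoms if a.name in BACKBONE_COPY]
        if name3 == "GLY":
            atoms = [a for a in atoms if a.name != "CB"]
        residues.append(Residue(number=i, name=name3, atoms=atoms))
    return Structure(chains={out_chain_id: residues},
                     source_id=f"threaded(offset={offset:+d})")


@dataclass
class Segment:
    kind: str                     # template-threaded | random-extended | rigid-domain
    start: int
    end: int
    offset: int | None = None


@dataclass
class SegmentPlan:
    segments: list[Segment]

    def __post_init__(self) -> None:
        segs = sorted(self.segments, key=lambda s: s.start)
        for a, b in zip(segs, segs[1:]):
            if b.start != a.end + 1:
                raise MergeError(
                    f"segments not contiguous: [{a.start},{a.end}] then "
                    f"[{b.start},{b.end}]")
        self.segments = segs

    @property
    def span(self) -> tuple[int, int]:
        return (self.segments[0].start, self.segments[-1].end)


def read_segment_plan(path) -> SegmentPlan:
    """Plain-text plan: one segment per line, `kind start end [offset]`."""
    segs = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#")[0].strip()
            if not line:
                continue
            parts = line.split()
            segs.append(Segment(kind=parts[0], start=int(parts[1]),
                                end=int(parts[2]),
                                offset=int(parts[3]) if len(parts) > 3 else None))
    return SegmentPlan(segs)


def merge_models(plan: SegmentPlan, parts: dict[tuple[int, int], Structure],
                 chain_id: str = "A") -> tuple[Structure, dict[int, str]]:
    """Concatenate positioned segment parts into one renumbered chain.

    Every seam must already be geometrically continuous: the peptide C-N
    distance across each junction must be 1.33 +/- 0.2 A, otherwise a
    MergeError names the seam. Returns the merged structure and a
    residue -> segment-kind provenance map.
    """
    residues: list[Residue] = []
    provenance: dict[int, str] = {}
    for seg in plan.segments:
        key = (seg.start, seg.end)
        if key not in parts:
            raise MergeError(f"no part supplied for segment {key}")
        part = parts[key]
        cid = part.chain_ids()[0]
        seg_res = [r for r in part.chain(cid) if seg.start <= r.number <= seg.end]
        got = {r.number for r in seg_res}
        expect = set(range(seg.start, seg.end + 1))
        if got != expect:
            raise MergeError(f"segment {key}: part misses residues "
                             f"{sorted(expect - got)}")
        if residues:
            c_prev = residues[-1].coords("C")
            n_next = seg_res[0].coords("N")
            if c_prev is None or n_next is None:
                raise MergeError(f"seam at residue {seg.start}: missing C or N")
            d = float(np.linalg.norm(n_next - c_prev))
            if abs(d - 1.33) > PEPTIDE_BOND_TOL:
                raise MergeError(
                    f"seam at residue {seg.start}: C-N distance {d:.2f} A "
                    f"outside 1.33 +/- {PEPTIDE_BOND_TOL} A")
        residues.extend(seg_res)
        for r in seg_res:
            provenance[r.number] = seg.kind
    merged = Structure(chains={chain_id: residues}, source_id="merged-model")
    return merged, provenance


def dock_onto_continuation(prev_residue: Residue, part: Structure,
                           prev_psi: float = 140.0) -> Structure:
    """Rigidly place a part so its first residue continues the previous
    segment's backbone (ideal peptide geometry at the seam)."""
    pn, pca, pc = (prev_residue.coords(x) for x in ("N", "CA", "C"))
    n_pred = place_atom(pn, pca, pc, BOND_C_N, ANGLE_CA_C_N, prev_psi)
    ca_pred = place_atom(pca, pc, n_pred, BOND_N_CA, ANGLE_C_N_CA, 180.0)
    c_pred = place_atom(pc, n_pred, ca_pred, BOND_CA_C, ANGLE_N_CA_C, -120.0)
    cid = part.chain_ids()[0]
    first = part.chain(cid)[0]
    src = np.array([first.coords("N"), first.coords("CA"), first.coords("C")])
    dst = np.array([n_pred, ca_pred, c_pred])
    sup = kabsch(dst, src)
    out_chains = {}
    for ch, residues in part.chains.items():
        new_res = []
        for r in residues:
            atoms = [Atom(a.name, a.element, sup.transform(a.coords),
                          a.occupancy, a.b_factor) for a in r.atoms]
            new_res.append(Residue(number=r.number, name=r.name, atoms=atoms,
                                   insertion_code=r.insertion_code))
        out_chains[ch] = new_res
    return Structure(chains=out_chains, source_id=part.source_id)


def assemble_hybrid(plan: SegmentPlan, sources: dict[tuple[int, int], Structure],
                    sequences: dict[tuple[int, int], str],
                    n_conformers: int = 1, seed: int = 0,
                    chain_id: str = "A") -> list[tuple[Structure, dict[int, str]]]:
    """Build merged conformers for a plan whose random segments are sampled.

    Non-random segments come positioned-or-dockable from ``sources``; random
    segments are grown from the preceding segment's end frame; each
    following rigid part is docked onto the growing chain. Returns
    ``n_conformers`` (structure, provenance) tuples, seed-reproducible.
    """
    results = []
    for ic in range(n_conformers):
        parts: dict[tuple[int, int], Structure] = {}
        prev_last: Residue | None = None
        for seg in plan.segments:
            key = (seg.start, seg.end)
            if seg.kind == "random-extended":
                seq = sequences.get(key, "G" * (seg.end - seg.start + 1))
                frame = None
                if prev_last is not None:
                    frame = tuple(prev_last.coords(x) for x in ("N", "CA", "C"))
                ens = sample_linker(seq, n=1,
                                    seed=(seed * 10007 + ic * 101 +
                                          seg.start) % (2 ** 31),
                                    start_frame=frame, start_number=seg.start,
                                    chain_id=chain_id)
                part = ens.conformers[0]
            else:
                part = sources[key]
                if prev_last is not None:
                    part = dock_onto_continuation(prev_last, part)
            parts[key] = part
            cid = part.chain_ids()[0]
            prev_last = [r for r in part.chain(cid)
                         if seg.start <= r.number <= seg.end][-1]
        results.append(merge_models(plan, parts, chain_id=chain_id))
    return results


@dataclass
class CrosslinkResult:
    pairs: list[tuple[int, int]]
    distances: np.ndarray            # nan where unassessable
    compatible: np.ndarray           # bool, False where unassessable
    assessable: np.ndarray
    chemistry: str

    @property
    def fraction_compatible(self) -> float:
        if not self.assessable.any():
            return math.nan
        return float(self.compatible[self.assessable].mean())


def crosslink_check(model: Structure, pairs: Sequence[tuple[int, int]],
                    linker: str = "BS3", chain_id: str | None = None,
                    ) -> CrosslinkResult:
    """CA-CA distances for residue pairs and crosslinker compatibility.

    Compatible iff distance <= 30 A (BS3) or <= 16 A (zero-length EDC).
    Pairs with a residue absent from the model are reported unassessable.
    """
    if linker not in CROSSLINK_CUTOFFS:
        raise ValueError(f"unknown chemistry {linker!r}")
    cutoff = CROSSLINK_CUTOFFS[linker]
    cid = chain_id or model.chain_ids()[0]
    ca = {r.number: r.coords("CA") for r in model.chain(cid)
          if r.coords("CA") is not None}
    dist = np.full(len(pairs), np.nan)
    ok = np.zeros(len(pairs), dtype=bool)
    assessable = np.zeros(len(pairs), dtype=bool)
    for i, (r1, r2) in enumerate(pairs):
        if r1 in ca and r2 in ca:
            assessable[i] = True
            dist[i] = float(np.linalg.norm(ca[r1] - ca[r2]))
            ok[i] = dist[i] <= cutoff
        else:
            logger.warning("crosslink pair (%d, %d) unassessable: residue "
                           "without coordinates", r1, r2)
    return CrosslinkResult(pairs=list(pairs), distances=dist, compatible=ok,
                           assessable=assessable, chemistry=linker)


def domain_proximity(model: Structure, domain_range: tuple[int, int],
                     reference_range: tuple[int, int],
                     chain_id: str | None = None) -> float:
    """Distance between the CA centroids of two residue ranges (e.g. a
    folded domain and the coiled-coil region), used to pick illustrative
    proximal/distal conformers from an ensemble."""
    cid = chain_id or model.chain_ids()[0]
    def centroid(lo, hi):
        pts = [r.coords("CA") for r in model.chain(cid)
               if lo <= r.number <= hi and r.coords("CA") is not None]
        return np.mean(pts, axis=0)
    return float(np.linalg.norm(centroid(*domain_range) - centroid(*reference_range)))
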