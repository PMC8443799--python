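"""Rigid-body superposition (Kabsch) with iterative outlier rejection.

``kabsch`` solves the least-squares rotation/translation for a fixed
pairing; ``align_with_rejection`` emulates sequence-based structure
alignment: pair CA atoms through a global sequence alignment (BLOSUM62,
affine gaps), then alternate fitting with rejection of pairs deviating by
more than ``cutoff_sd`` standard deviations, for up to ``cycles`` cycles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .structure_io import Structure

logger = logging.getLogger("coilreg")

DEFAULT_CYCLES = 5
DEFAULT_CUTOFF_SD = 2.0


class DegenerateError(Exception):
    """Collinear or otherwise rank-deficient coordinate pairing."""


class RejectionCollapseError(Exception):
    """Outlier rejection removed (almost) all pairs."""


@dataclass
class Superposition:
    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_pairs_initial: int
    n_pairs_final: int
    rejected: list[tuple[int, int]] = field(default_factory=list)
    pairing: list[tuple[int, int]] = field(default_factory=list)

    def transform(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def kabsch(coords_a: np.ndarray, coords_b: np.ndarray) -> Superposition:
    """Proper rotation R and translation t minimizing sum |a - (R b + t)|^2.

    A reflection is never returned: the smallest singular direction is
    flipped when needed, so mirrored inputs superpose with rmsd > 0.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("coordinate arrays must both be (n, 3)")
    n = len(a)
    if n < 3:
        raise DegenerateError("need at least 3 pairs")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    h = (b - cb).T @ (a - ca)
    u, s, vt = np.linalg.svd(h)
    if s[1] < 1e-8 * max(s[0], 1e-30):
        raise DegenerateError("pairing is (near-)collinear; rotation ill-defined")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = ca - r @ cb
    diff = a - (b @ r.T + t)
    rmsd = float(np.sqrt(np.mean(np.sum(diff ** 2, axis=1))))
    return Superposition(rotation=r, translation=t, rmsd=rmsd,
                         n_pairs_initial=n, n_pairs_final=n)


def sequence_pairing(struct_a: Structure, chain_a: str,
                     struct_b: Structure, chain_b: str,
                     open_gap: float = -10.0, extend_gap: float = -0.5,
                     ) -> list[tuple[int, int]]:
    """Residue-number pairs from a global BLOSUM62 alignment of the two
    chains' sequences (CA-bearing residues only)."""
    res_a = [r for r in struct_a.chain(chain_a) if r.coords("CA") is not None]
    res_b = [r for r in struct_b.chain(chain_b) if r.coords("CA") is not None]
    seq_a = "".join(r.one_letter for r in res_a)
    seq_b = "".join(r.one_letter for r in res_b)
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = open_gap
    aligner.extend_gap_score = extend_gap
    aln = aligner.align(seq_a.replace("X", "A"), seq_b.replace("X", "A"))[0]
    pairs: list[tuple[int, int]] = []
    for (a0, a1), (b0, b1) in zip(aln.aligned[0], aln.aligned[1]):
        for i, j in zip(range(a0, a1), range(b0, b1)):
            pairs.append((res_a[i].number, res_b[j].number))
    return pairs


def align_with_rejection(struct_a: Structure, struct_b: Structure,
                         chain_a: str | None = None, chain_b: str | None = None,
                         pairing: list[tuple[int, int]] | None = None,
                         cycles: int = DEFAULT_CYCLES,
                         cutoff_sd: float = DEFAULT_CUTOFF_SD) -> Superposition:
    """Iterative CA superposition with outlier rejection.

    Pairs deviating by more than ``cutoff_sd`` times the sd of per-pair
    deviations are dropped after each fit; iteration stops when a cycle
    rejects nothing or the cycle budget is exhausted. Defaults (5 cycles,
    2.0 sd) emulate commonly used align tools; exact third-party pair
    subsets are not guaranteed, so both parameters are exposed.
    """
    chain_a = chain_a or struct_a.chain_ids()[0]
    chain_b = chain_b or struct_b.chain_ids()[0]
    if pairing is None:
        pairing = sequence_pairing(struct_a, chain_a, struct_b, chain_b)
    coords = []
    kept_pairs = []
    for na, nb in pairing:
        ra = struct_a.residue(chain_a, na)
        rb = struct_b.residue(chain_b, nb)
        if ra is None or rb is None:
            continue
        pa, pb = ra.coords("CA"), rb.coords("CA")
        if pa is None or pb is None:
            continue
        coords.append((pa, pb))
        kept_pairs.append((na, nb))
    if len(coords) < 3:
        raise DegenerateError("fewer than 3 CA pairs to superpose")
    a = np.array([c[0] for c in coords])
    b = np.array([c[1] for c in coords])
    n0 = len(a)
    active = np.ones(n0, dtype=bool)
    sup = kabsch(a, b)
    for _ in range(cycles):
        sup = kabsch(a[active], b[active])
        dev = np.linalg.norm(a - (b @ sup.rotation.T + sup.translation), axis=1)
        sd = float(np.std(dev[active]))
        if sd < 1e-12:
            break
        # threshold is mean + k*sd: a pure k*sd cutoff falls below the mean
        # deviation once outliers are gone and rejects everything
        thr = float(np.mean(dev[active])) + cutoff_sd * sd
        reject = active & (dev > thr)
        if not reject.any():
            break
        active &= ~reject
        if active.sum() < 3:
            raise RejectionCollapseError("outlier rejection left < 3 pairs")
    sup = kabsch(a[active], b[active])
    sup.n_pairs_initial = n0
    sup.n_pairs_final = int(active.sum())
    sup.rejected = [kept_pairs[i] for i in np.flatnonzero(~active)]
    sup.pairing = [kept_pairs[i] for i in np.flatnonzero(active)]
    return sup
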