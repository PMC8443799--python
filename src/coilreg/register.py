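"""Offset scan: slide measured RDCs along a template structure's positions.

Target residue i is mapped to template position i + k for every offset k
in the scan range; residues whose hetNOE ratio is below the flexibility
cutoff are excluded; an alignment tensor is fitted at each offset and the
offsets are ranked by Q factor. This reproduces the procedure that places
a helix with measured couplings into the heptad register of a homologous
coiled-coil structure.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import rdc as rdc_mod
from .rdc import RDCMeasurement, UnderdeterminedError, ConditioningError
from .relaxation import RelaxationTable
from .structure_io import Structure, amide_vectors
from .ccgeom import CoiledCoilProfile

logger = logging.getLogger("coilreg")

HYDROPHOBIC = set("AVLIMFWY")
Q_TIE_TOLERANCE = 0.01
DEFAULT_NOE_CUTOFF = 0.6


class ScanError(Exception):
    """No offset in the scanned range produced a usable fit."""


class _KeyedVector:
    """Template bond vector re-keyed to a target residue number."""

    def __init__(self, residue_number: int, vector: np.ndarray):
        self.residue_number = residue_number
        self.vector = vector


@dataclass
class OffsetScanResult:
    table: pd.DataFrame          # offset, n_used, chi2, q_factor, da_hz, rhombicity
    best_offset: int
    co_optimal: list[int]
    ambiguous: bool
    fits: dict[int, rdc_mod.FitResult] = field(default_factory=dict)

    def ranking(self) -> pd.DataFrame:
        usable = self.table.dropna(subset=["q_factor"])
        return usable.sort_values("q_factor").reset_index(drop=True)


def scan_offsets(template: Structure, chain_id: str,
                 window: tuple[int, int],
                 target_rdcs: Sequence[RDCMeasurement],
                 hetnoe_table: RelaxationTable | None = None,
                 offsets: Iterable[int] = range(-10, 11),
                 noe_cutoff: float = DEFAULT_NOE_CUTOFF,
                 weighted: bool = True) -> OffsetScanResult:
    """Fit a tensor per offset and rank offsets by Q.

    Offsets with fewer than five usable (vector, measurement) pairs are
    reported as unusable rows rather than dropped. Ties within
    ``Q_TIE_TOLERANCE`` are surfaced: best_offset is then the co-optimal
    offset with the smallest magnitude and the result is flagged ambiguous.
    """
    offsets = list(offsets)
    vecs = amide_vectors(template, chain_ids=[chain_id])
    lo, hi = window
    vmap = {v.residue_number: v for v in vecs if lo <= v.residue_number <= hi}
    if not vmap:
        raise ScanError(f"template window [{lo}, {hi}] yields no amide vectors")

    usable_rdcs = []
    n_excluded = 0
    for m in target_rdcs:
        if hetnoe_table is not None:
            ratio = hetnoe_table.ratio(m.residue_number)
            if ratio is not None and ratio < noe_cutoff:
                n_excluded += 1
                continue
        usable_rdcs.append(m)
    if n_excluded:
        logger.info("excluded %d residues with hetNOE < %.2f from the scan",
                    n_excluded, noe_cutoff)

    rows = []
    fits: dict[int, rdc_mod.FitResult] = {}
    for k in offsets:
        pairs = [(vmap[m.residue_number + k], m) for m in usable_rdcs
                 if m.residue_number + k in vmap]
        if len(pairs) < 5:
            rows.append((k, len(pairs), np.nan, np.nan, np.nan, np.nan))
            continue
        # re-key template vectors on the target residue numbering so the
        # tensor fit matches them to the measurements
        keyed_vecs = [_KeyedVector(m.residue_number, v.vector) for v, m in pairs]
        keyed_meas = [m for _, m in pairs]
        try:
            fit = rdc_mod.fit_tensor(keyed_vecs, keyed_meas, weighted=weighted)
        except (UnderdeterminedError, ConditioningError) as exc:
            logger.warning("offset %+d unusable: %s", k, exc)
            rows.append((k, len(pairs), np.nan, np.nan, np.nan, np.nan))
            continue
        fits[k] = fit
        rows.append((k, fit.n_used, fit.chi2, fit.q, fit.tensor.da,
                     fit.tensor.rhombicity))

    table = pd.DataFrame(rows, columns=["offset", "n_used", "chi2", "q_factor",
                                        "da_hz", "rhombicity"])
    usable = table.dropna(subset=["q_factor"])
    if usable.empty:
        raise ScanError("no offset in the scanned range produced >= 5 usable pairs")
    q_min = float(usable["q_factor"].min())
    co = sorted(int(o) for o, q in zip(usable["offset"], usable["q_factor"])
                if q - q_min < Q_TIE_TOLERANCE)
    best = min(co, key=lambda o: (abs(o), o))
    ambiguous = len(co) > 1
    if ambiguous:
        logger.warning("offset scan ambiguous: co-optimal offsets %s (dQ < %.3g)",
                       co, Q_TIE_TOLERANCE)
    return OffsetScanResult(table=table, best_offset=best, co_optimal=co,
                            ambiguous=ambiguous, fits=fits)


@dataclass
class ConsistencyReport:
    consistent: bool
    implied_offsets: dict[int, int]          # target position -> implied offset
    ad_positions: list[tuple[int, str, str]]  # (target pos, residue, letter)
    ad_hydrophobic_fraction: float
    warnings: list[str] = field(default_factory=list)


def offset_consistency(offset: int,
                       alignment: Sequence[tuple[int, int]],
                       target_sequence: dict[int, str] | None = None,
                       template_profile: CoiledCoilProfile | None = None,
                       window: tuple[int, int] | None = None,
                       ) -> tuple[bool, ConsistencyReport]:
    """Check an RDC-derived offset against a sequence alignment.

    ``alignment`` is a list of (target_position, template_position) pairs;
    the implied offset of a pair is template - target. The result is true
    iff every pair inside the window implies the scanned offset. When a
    one-letter target sequence and a template heptad profile are supplied,
    the report lists the target residues landing on template a/d positions
    and the fraction of them that are hydrophobic.
    """
    warnings: list[str] = []
    implied: dict[int, int] = {}
    for tgt, tpl in alignment:
        if window is not None and not (window[0] <= tgt <= window[1]):
            continue
        implied[tgt] = tpl - tgt
    if not implied:
        raise ValueError("alignment has no pairs inside the window")
    offsets_seen = sorted(set(implied.values()))
    if len(offsets_seen) > 1:
        warnings.append(f"gapped window: alignment implies offsets {offsets_seen}; "
                        "evaluating per segment")
    consistent = all(v == offset for v in implied.values())

    ad: list[tuple[int, str, str]] = []
    frac = math.nan
    if target_sequence is not None and template_profile is not None \
            and template_profile.heptad_letters:
        letter = dict(zip(template_profile.residue_numbers,
                          template_profile.heptad_letters))
        for tgt in sorted(target_sequence):
            tpl = tgt + offset
            lt = letter.get(tpl)
            if lt in ("a", "d"):
                ad.append((tgt, target_sequence[tgt], lt))
        if ad:
            frac = sum(1 for _, aa, _ in ad if aa in HYDROPHOBIC) / len(ad)
    report = ConsistencyReport(consistent=consistent, implied_offsets=implied,
                               ad_positions=ad, ad_hydrophobic_fraction=frac,
                               warnings=warnings)
    return consistent, report
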