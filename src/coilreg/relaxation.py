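"""Heteronuclear {1H}-15N NOE ratios, Monte Carlo errors, flexibility flags.

The hetNOE for a residue is the ratio of its peak height in the
proton-saturated spectrum to that in the unsaturated spectrum. Errors are
propagated by Monte Carlo: both heights are perturbed with Gaussian noise
of sd equal to the spectral baseline noise and the sd of the resulting
ratios is reported (default 500 trials). Ratios below the cutoff (default
0.6, strict inequality) flag a flexible backbone.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass
class PeakPair:
    residue_number: int
    height_sat: float
    height_unsat: float
    baseline_noise: float

    def __post_init__(self) -> None:
        if not self.baseline_noise > 0:
            raise ValueError(
                f"baseline_noise must be > 0 (residue {self.residue_number})")


@dataclass
class RelaxationTable:
    """Per-residue hetNOE ratio, MC error and flexibility flag."""
    data: pd.DataFrame   # columns: residue, noe_ratio, noe_error, defined[, flexible]
    cutoff: float | None = None
    segments: list[tuple[int, int]] | None = None

    def ratio(self, residue_number: int) -> float | None:
        rows = self.data.loc[self.data["residue"] == residue_number]
        if rows.empty or not bool(rows.iloc[0]["defined"]):
            return None
        return float(rows.iloc[0]["noe_ratio"])

    def flexible_residues(self) -> set[int]:
        if "flexible" not in self.data.columns:
            raise ValueError("call classify_flexible first")
        sub = self.data[self.data["flexible"]]
        return set(int(r) for r in sub["residue"])


def read_peak_table(path: str | Path) -> list[PeakPair]:
    """TSV: residue  height_sat  height_unsat  baseline_noise."""
    df = pd.read_csv(path, sep=r"\s+", comment="#")
    df.columns = ["residue", "height_sat", "height_unsat", "baseline_noise"]
    return [PeakPair(int(r.residue), float(r.height_sat),
                     float(r.height_unsat), float(r.baseline_noise))
            for r in df.itertuples(index=False)]


def noe_ratios(pairs: Sequence[PeakPair], n_mc: int = 500, seed: int = 0,
               perturb: str = "both") -> RelaxationTable:
    """hetNOE ratios with Monte Carlo errors.

    perturb='both' (default) adds independent noise to the saturated and
    unsaturated heights in every trial; perturb='sat' perturbs only the
    saturated spectrum. Deterministic for a fixed seed. Residues with a
    zero unsaturated height are flagged undefined.
    """
    if n_mc < 2:
        raise ValueError("n_mc must be >= 2")
    if perturb not in ("both", "sat"):
        raise ValueError("perturb must be 'both' or 'sat'")
    rng = np.random.default_rng(seed)
    rows = []
    for p in pairs:
        if p.height_unsat == 0:
            rows.append((p.residue_number, np.nan, np.nan, False))
            continue
        ratio = p.height_sat / p.height_unsat
        sat = p.height_sat + p.baseline_noise * rng.standard_normal(n_mc)
        if perturb == "both":
            unsat = p.height_unsat + p.baseline_noise * rng.standard_normal(n_mc)
        else:
            unsat = np.full(n_mc, p.height_unsat)
        ok = unsat != 0
        err = float(np.std(sat[ok] / unsat[ok], ddof=1))
        rows.append((p.residue_number, ratio, err, True))
    df = pd.DataFrame(rows, columns=["residue", "noe_ratio", "noe_error",
                                     "defined"])
    return RelaxationTable(data=df)


def classify_flexible(table: RelaxationTable,
                      cutoff: float = 0.6) -> RelaxationTable:
    """Flag residues with ratio strictly below the cutoff and report
    contiguous flexible segments as (first, last) residue numbers."""
    df = table.data.copy()
    df["flexible"] = df["defined"] & (df["noe_ratio"] < cutoff)
    flex = sorted(int(r) for r in df.loc[df["flexible"], "residue"])
    segments: list[tuple[int, int]] = []
    for num in flex:
        if segments and num == segments[-1][1] + 1:
            segments[-1] = (segments[-1][0], num)
        else:
            segments.append((num, num))
    return RelaxationTable(data=df, cutoff=cutoff, segments=segments)


def write_relaxation_table(table: RelaxationTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index=False, float_format="%.6g")
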