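"""Chemical-shift perturbation and steady-state heteronuclear NOE analysis.

Works from assigned per-residue peak lists (residue, 1H shift, 15N shift,
intensity) of 1H,15N correlation (HSQC) spectra.  CSP combines the proton
and nitrogen shift changes as sqrt(ddH^2 + (w*ddN)^2) with the conventional
nitrogen weight w = 0.154.  The steady-state {1H}-15N NOE is the per-residue
intensity ratio saturated/reference, averaged over replicate experiment
pairs; residues with mean NOE below 0.2 (strict) are flagged as undergoing
fast backbone motion.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Sequence

import pandas as pd

NITROGEN_WEIGHT = 0.154
FLEXIBLE_NOE_CUTOFF = 0.2


@dataclasses.dataclass
class PeakList:
    """Assigned peaks of one spectrum: residue -> (dH ppm, dN ppm, intensity)."""

    entries: dict[int, tuple[float, float, float]]
    spectrum_id: str = ""
    replicate_id: str | None = None

    def __post_init__(self) -> None:
        for res, (h, n, i) in self.entries.items():
            if not all(math.isfinite(v) for v in (h, n, i)):
                raise ValueError(f"non-finite entry for residue {res}")

    @classmethod
    def read_table(cls, path: str | Path, spectrum_id: str = "",
                   replicate_id: str | None = None) -> "PeakList":
        """Read a TSV/CSV with columns residue, dH, dN, intensity."""
        sep = "," if str(path).endswith(".csv") else "\t"
        df = pd.read_csv(path, sep=sep, comment="#")
        df.columns = [c.strip().lower() for c in df.columns]
        cols = list(df.columns)
        entries = {
            int(row[cols[0]]): (float(row[cols[1]]), float(row[cols[2]]),
                                float(row[cols[3]]) if len(cols) > 3 else 0.0)
            for _, row in df.iterrows()
        }
        return cls(entries=entries, spectrum_id=spectrum_id or str(path),
                   replicate_id=replicate_id)


@dataclasses.dataclass
class CspProfile:
    """Combined chemical shift perturbation per residue (ppm, >= 0)."""

    per_residue: dict[int, float]
    nitrogen_weight: float
    reference_spectrum: str
    query_spectrum: str
    missing: set[int]  # residues present in only one of the two lists


@dataclasses.dataclass
class NoeProfile:
    """Steady-state heteronuclear NOE per residue: (mean ratio, sd)."""

    per_residue: dict[int, tuple[float, float]]
    n_replicates: int
    excluded: dict[int, str]  # residue -> reason (e.g. zero reference intensity)
    flexible_cutoff: float = FLEXIBLE_NOE_CUTOFF


def csp(
    reference: PeakList,
    query: PeakList,
    nitrogen_weight: float = NITROGEN_WEIGHT,
) -> CspProfile:
    """Combined CSP sqrt(ddH^2 + (w*ddN)^2) for residues shared by both lists.

    Residues present in only one list are reported in ``missing``, never
    imputed.
    """
    shared = set(reference.entries) & set(query.entries)
    if not shared:
        raise ValueError("the two peak lists share no residues")
    per_residue = {}
    for res in sorted(shared):
        h_ref, n_ref, _ = reference.entries[res]
        h_q, n_q, _ = query.entries[res]
        per_residue[res] = math.sqrt(
            (h_q - h_ref) ** 2 + (nitrogen_weight * (n_q - n_ref)) ** 2
        )
    missing = (set(reference.entries) | set(query.entries)) - shared
    return CspProfile(
        per_residue=per_residue,
        nitrogen_weight=nitrogen_weight,
        reference_spectrum=reference.spectrum_id,
        query_spectrum=query.spectrum_id,
        missing=missing,
    )


def hetnoe(
    saturated: Sequence[PeakList],
    reference: Sequence[PeakList],
) -> NoeProfile:
    """Per-residue NOE ratio I_sat/I_ref, mean and sample sd over replicates.

    Saturated and reference lists are paired by position; replicate counts
    must match.  A residue with zero reference intensity in any replicate is
    excluded and reported, since its ratio is undefined; negative ratios are
    legitimate (exchange-broadened, highly flexible residues) and pass
    through.
    """
    if len(saturated) != len(reference) or not saturated:
        raise ValueError(
            f"replicate counts differ or empty: {len(saturated)} saturated "
            f"vs {len(reference)} reference"
        )
    n_rep = len(saturated)
    residues = set(saturated[0].entries)
    for pl in list(saturated) + list(reference):
        residues &= set(pl.entries)
    per_residue = {}
    excluded = {}
    for res in sorted(residues):
        ratios = []
        for sat, ref in zip(saturated, reference):
            i_ref = ref.entries[res][2]
            if i_ref == 0:
                excluded[res] = "zero reference intensity"
                break
            ratios.append(sat.entries[res][2] / i_ref)
        else:
            mean = sum(ratios) / n_rep
            if n_rep > 1:
                sd = math.sqrt(sum((r - mean) ** 2 for r in ratios) / (n_rep - 1))
            else:
                sd = 0.0
            per_residue[res] = (mean, sd)
    return NoeProfile(per_residue=per_residue, n_replicates=n_rep, excluded=excluded)


def flag_flexible(
    profile: NoeProfile, cutoff: float = FLEXIBLE_NOE_CUTOFF
) -> list[int]:
    """Residues with mean NOE strictly below *cutoff*, sorted by number."""
    return sorted(
        res for res, (mean, _) in profile.per_residue.items() if mean < cutoff
    )
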