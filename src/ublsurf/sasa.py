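"""Shrake-Rupley solvent-accessible surface area.

A probe sphere (default radius 1.4 Angstrom) is rolled over the van der
Waals spheres of the selection; each atom's SASA is the fraction of a
deterministic golden-spiral point lattice on its expanded sphere that is
not occluded by any neighbour, times the expanded-sphere area
4*pi*(r_vdw + r_probe)^2.  The lattice is deterministic, so repeated runs
are bit-identical -- no Monte-Carlo sampling is involved.

Relative accessibility divides a residue's SASA by its residue-type maximum
in an extended Gly-X-Gly tripeptide (theoretical values of Tien et al.
2013); exposed/buried calls threshold that fraction (default 0.25, boundary
classified exposed).
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .structio import Residue, Structure

#: Bondi (1964) van der Waals radii, Angstrom, for elements found in proteins.
VDW_RADII = {
    "bondi64": {
        "H": 1.20, "D": 1.20, "C": 1.70, "N": 1.55, "O": 1.52,
        "S": 1.80, "P": 1.80, "F": 1.47, "CL": 1.75, "BR": 1.85,
        "I": 1.98, "SE": 1.90,
    }
}

#: Maximum accessible surface area (Angstrom^2) per residue type in an
#: extended Gly-X-Gly tripeptide; theoretical values of Tien et al. (2013).
MAX_ACC_TIEN2013 = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}


@dataclasses.dataclass
class SasaProfile:
    """Per-atom and per-residue solvent accessibility of one selection."""

    per_atom: dict  # (chain, seq_number, icode, atom_name) -> Angstrom^2
    per_residue: dict  # (chain, seq_number, icode) -> Angstrom^2
    residue_names: dict  # (chain, seq_number, icode) -> 3-letter code
    probe_radius: float
    n_points: int
    radii_set: str


@dataclasses.dataclass
class ExposureCall:
    residue: tuple
    res_name: str
    rel_accessibility: float
    call: str  # "exposed" | "buried"
    threshold: float


def golden_spiral(n_points: int) -> np.ndarray:
    """Deterministic, nearly uniform unit-sphere lattice (golden-angle spiral)."""
    i = np.arange(n_points)
    z = 1.0 - (2.0 * i + 1.0) / n_points
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def sasa_of_spheres(
    centers: np.ndarray,
    radii: np.ndarray,
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> np.ndarray:
    """Shrake-Rupley SASA (Angstrom^2) of arbitrary spheres; the numeric core."""
    centers = np.asarray(centers, dtype=float)
    radii = np.asarray(radii, dtype=float)
    lattice = golden_spiral(n_points)
    expanded = radii + probe_radius
    tree = cKDTree(centers)
    out = np.empty(len(centers))
    r_max = expanded.max()
    for i in range(len(centers)):
        pts = centers[i] + expanded[i] * lattice
        neighbors = [
            j for j in tree.query_ball_point(centers[i], expanded[i] + r_max)
            if j != i
        ]
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbors:
            d2 = np.sum((pts - centers[j]) ** 2, axis=1)
            accessible &= d2 > expanded[j] ** 2
        out[i] = accessible.mean() * 4.0 * np.pi * expanded[i] ** 2
    return out


def _gather_atoms(
    structure: Structure,
    chains: Sequence[str] | None,
    model_index: int,
) -> tuple[list[tuple[Residue, str]], np.ndarray, list[str]]:
    keys, coords, elements = [], [], []
    model = structure.models[model_index]
    for chain_id, residues in model.items():
        if chains is not None and chain_id not in chains:
            continue
        for res in residues:
            for atom in res.atoms:
                keys.append((res, atom.name))
                coords.append(atom.coords)
                elements.append(atom.element.upper())
    if not keys:
        raise ValueError("empty selection for SASA")
    return keys, np.array(coords), elements


def shrake_rupley(
    structure: Structure,
    chains: Sequence[str] | None = None,
    model_index: int = 0,
    probe_radius: float = 1.4,
    n_points: int = 960,
    radii_set: str = "bondi64",
) -> SasaProfile:
    """Per-atom and per-residue SASA of (a chain subset of) one model."""
    if radii_set not in VDW_RADII:
        raise ValueError(f"unknown radii set {radii_set!r}")
    table = VDW_RADII[radii_set]
    keys, coords, elements = _gather_atoms(structure, chains, model_index)
    radii = []
    for (res, name), el in zip(keys, elements):
        if el not in table:
            raise ValueError(
                f"no van der Waals radius for element {el!r} "
                f"(atom {name} in {res.res_name}{res.seq_number})"
            )
        radii.append(table[el])
    areas = sasa_of_spheres(coords, np.array(radii), probe_radius, n_points)
    per_atom: dict = {}
    per_residue: dict = {}
    residue_names: dict = {}
    for (res, name), area in zip(keys, areas):
        per_atom[res.key + (name,)] = float(area)
        per_residue[res.key] = per_residue.get(res.key, 0.0) + float(area)
        residue_names[res.key] = res.res_name
    return SasaProfile(
        per_atom=per_atom,
        per_residue=per_residue,
        residue_names=residue_names,
        probe_radius=probe_radius,
        n_points=n_points,
        radii_set=radii_set,
    )


def relative_accessibility(
    profile: SasaProfile,
    max_table: Mapping[str, float] = MAX_ACC_TIEN2013,
) -> dict:
    """Residue SASA / residue-type maximum.  May exceed 1 for termini."""
    out = {}
    for key, area in profile.per_residue.items():
        res_name = profile.residue_names[key]
        if res_name not in max_table:
            raise ValueError(f"no reference maximum for residue type {res_name!r}")
        out[key] = area / max_table[res_name]
    return out


def classify_exposure(
    fractions: Mapping,
    residue_names: Mapping | None = None,
    threshold: float = 0.25,
) -> list[ExposureCall]:
    """Exposed/buried call per residue; the boundary value counts as exposed."""
    calls = []
    for key in sorted(fractions):
        frac = fractions[key]
        calls.append(
            ExposureCall(
                residue=key,
                res_name=(residue_names or {}).get(key, ""),
                rel_accessibility=float(frac),
                call="exposed" if frac >= threshold else "buried",
                threshold=threshold,
            )
        )
    return calls
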