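"""Protein-protein interface detection and interface-occurrence scoring.

A residue's buried SASA in a binary complex is the accessibility it loses
on going from the isolated reference chain (in its complex coordinates) to
the full assembly; the buried fraction divides by the isolated-chain SASA.
Across a panel of complexes sharing a common reference protein (e.g. the 16
ubiquitin complexes used to define ubiquitin's binding surface), each
reference position is scored by the fraction of complexes in which its
buried fraction exceeds 10% -- a 0-1 interface-occurrence ("binding")
score per residue.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

from .sasa import SasaProfile, shrake_rupley
from .structio import Structure
from .superpose import ResidueCorrespondence

BURIED_FRACTION_THRESHOLD = 0.10


@dataclasses.dataclass
class InterfaceRecord:
    """Per-residue buried SASA of one reference chain in one complex."""

    complex_id: str
    reference_chain: str
    partner_chains: tuple[str, ...]
    # residue key -> (sasa_alone, sasa_complex, buried, buried_fraction)
    per_residue: dict
    residue_names: dict
    sasa_params: dict


@dataclasses.dataclass
class BindingScoreProfile:
    """Interface-occurrence score per reference position, scaled to [0, 1]."""

    counts: dict  # position -> number of complexes with buried_fraction > threshold
    score: dict  # position -> fraction in [0, 1]
    threshold: float
    n_complexes: int
    normalization: str  # "fraction" (count/n) or "max" (count/max count)
    unmapped: dict  # complex_id -> positions of that complex with no mapping


def buried_sasa(
    complex_structure: Structure,
    reference_chain: str,
    partner_chains: Sequence[str] | None = None,
    complex_id: str | None = None,
    probe_radius: float = 1.4,
    n_points: int = 960,
    radii_set: str = "bondi64",
    model_index: int = 0,
) -> InterfaceRecord:
    """Buried SASA of every reference-chain residue in a binary complex.

    ``sasa_alone`` is computed on the reference chain extracted at its
    complex coordinates, ``sasa_complex`` on the full assembly, with
    identical SASA parameters.  ``buried_fraction`` is 0 where
    ``sasa_alone`` is 0 (a residue fully buried within the monomer cannot
    be an interface residue).
    """
    chains = complex_structure.chain_ids(model_index)
    if reference_chain not in chains:
        raise ValueError(f"reference chain {reference_chain!r} not in {chains}")
    if partner_chains is None:
        partner_chains = [c for c in chains if c != reference_chain]
    partner_chains = list(partner_chains)
    if not partner_chains:
        raise ValueError("empty partner selection")
    if reference_chain in partner_chains:
        raise ValueError("reference chain cannot be its own partner")
    params = dict(probe_radius=probe_radius, n_points=n_points, radii_set=radii_set)

    alone = shrake_rupley(complex_structure, chains=[reference_chain],
                          model_index=model_index, **params)
    assembly = shrake_rupley(
        complex_structure, chains=[reference_chain] + partner_chains,
        model_index=model_index, **params,
    )
    per_residue = {}
    for key, sasa_alone in alone.per_residue.items():
        sasa_cplx = assembly.per_residue[key]
        buried = sasa_alone - sasa_cplx
        fraction = buried / sasa_alone if sasa_alone > 0 else 0.0
        per_residue[key] = (sasa_alone, sasa_cplx, buried, fraction)
    return InterfaceRecord(
        complex_id=complex_id or complex_structure.id,
        reference_chain=reference_chain,
        partner_chains=tuple(partner_chains),
        per_residue=per_residue,
        residue_names=dict(alone.residue_names),
        sasa_params=params,
    )


def binding_score(
    records: Sequence[InterfaceRecord],
    mappings: Mapping[str, ResidueCorrespondence] | None = None,
    threshold: float = BURIED_FRACTION_THRESHOLD,
    normalization: str = "fraction",
) -> BindingScoreProfile:
    """Interface-occurrence score across a set of complexes.

    For each complex, every reference position whose buried fraction is
    strictly greater than *threshold* increments that position's count once.
    ``mappings`` translate each complex's reference-chain numbering to the
    common reference numbering (side A = complex residue number, side B =
    reference position); omitted complexes map identically.  Scores are
    count / n_complexes ("fraction", the default) or count / max count
    ("max").
    """
    if normalization not in ("fraction", "max"):
        raise ValueError(f"unknown normalization {normalization!r}")
    seen: set[str] = set()
    counts: dict[int, int] = {}
    unmapped: dict[str, list[int]] = {}
    for rec in records:
        if rec.complex_id in seen:
            raise ValueError(f"duplicate complex_id {rec.complex_id!r}")
        seen.add(rec.complex_id)
        mapping = None
        if mappings is not None and rec.complex_id in mappings:
            mapping = mappings[rec.complex_id].mapping()
        for key, (_, _, _, fraction) in rec.per_residue.items():
            number = key[1]
            if mapping is not None:
                if number not in mapping:
                    unmapped.setdefault(rec.complex_id, []).append(number)
                    continue
                number = mapping[number]
            counts.setdefault(number, 0)
            if fraction > threshold:
                counts[number] += 1
    n = len(records)
    if normalization == "fraction":
        denom = n
    else:
        denom = max(counts.values()) if counts and max(counts.values()) else 1
    score = {pos: c / denom for pos, c in counts.items()}
    return BindingScoreProfile(
        counts=counts,
        score=score,
        threshold=threshold,
        n_complexes=n,
        normalization=normalization,
        unmapped=unmapped,
    )


@dataclasses.dataclass
class PatchRow:
    """Equivalence of one reference surface position on another structure."""

    position_a: int
    name_a: str
    position_b: int | None  # None = gap in the correspondence
    name_b: str
    annotation_a: float | None = None
    annotation_b: float | None = None


def surface_patch_compare(
    positions: Sequence[int],
    correspondence: ResidueCorrespondence,
    annotation_a: Mapping[int, float] | None = None,
    annotation_b: Mapping[int, float] | None = None,
) -> list[PatchRow]:
    """Map named reference positions (side A) to their equivalents on side B.

    Unmapped query positions are reported as gaps, not errors.  Residue
    identities come from the correspondence; annotations (e.g. SASA or a
    binding score) are attached when given.
    """
    mapping = correspondence.mapping()
    rows = []
    for pos in positions:
        equiv = mapping.get(pos)
        rows.append(
            PatchRow(
                position_a=pos,
                name_a=correspondence.names_a.get(pos, ""),
                position_b=equiv,
                name_b=correspondence.names_b.get(equiv, "") if equiv is not None else "-",
                annotation_a=(annotation_a or {}).get(pos),
                annotation_b=(annotation_b or {}).get(equiv) if equiv is not None else None,
            )
        )
    return rows
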