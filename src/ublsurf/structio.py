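"""Coordinate and sequence file I/O.

Reads PDB/mmCIF files (via gemmi) into a small hierarchical model --
``Structure`` -> models -> chains -> ``Residue`` -> ``Atom`` -- that every
other module consumes.  Author (PDB) residue numbering is authoritative
throughout; ranges are 1-based and inclusive.

Policy decisions baked in here:

* alternate locations are resolved to the highest-occupancy conformer
  (ties broken by file order);
* hydrogens, waters and heteroatoms are excluded by default, since the
  crystallographic entries this package targets lack hydrogens and the
  geometry modules (SASA, RMSD) must stay comparable across inputs;
* "backbone" means the four heavy atoms N, CA, C, O.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np

BACKBONE_ATOMS = ("N", "CA", "C", "O")

#: canonical intra-residue atom ordering used by select_atoms
_CANONICAL_ORDER = {name: i for i, name in enumerate(("N", "CA", "C", "O", "CB"))}

_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}


@dataclasses.dataclass
class Atom:
    """A single atom: label, element, position (Angstrom), occupancy, B-factor."""

    name: str
    element: str
    coords: np.ndarray
    occupancy: float = 1.0
    b_factor: float = 0.0
    altloc: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: coordinates must be a finite 3-vector")


@dataclasses.dataclass
class Residue:
    """One residue identified by (chain_id, seq_number, insertion_code)."""

    chain_id: str
    seq_number: int
    res_name: str
    atoms: list[Atom] = dataclasses.field(default_factory=list)
    insertion_code: str = ""

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_number, self.insertion_code)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


#: a model is an ordered mapping chain_id -> list of residues
Model = dict


@dataclasses.dataclass
class Structure:
    """Hierarchical coordinate model: >=1 models of chain -> residue lists."""

    id: str
    models: list[Model]
    source_format: str = "pdb"

    @property
    def n_models(self) -> int:
        return len(self.models)

    def chain_ids(self, model_index: int = 0) -> list[str]:
        return list(self.models[model_index].keys())

    def chain(self, chain_id: str, model_index: int = 0) -> list[Residue]:
        model = self.models[model_index]
        if chain_id not in model:
            raise KeyError(
                f"chain {chain_id!r} not in structure {self.id} "
                f"(has {sorted(model)})"
            )
        return model[chain_id]

    def n_residues(self, model_index: int = 0) -> int:
        return sum(len(r) for r in self.models[model_index].values())

    def iter_residues(self, model_index: int = 0) -> Iterable[Residue]:
        for residues in self.models[model_index].values():
            yield from residues

    def one_letter_sequence(self, chain_id: str, model_index: int = 0) -> str:
        return "".join(
            three_to_one(r.res_name) for r in self.chain(chain_id, model_index)
        )


def three_to_one(res_name: str) -> str:
    """3-letter residue code to 1-letter; unknown codes become 'X'."""
    code = gemmi.find_tabulated_residue(res_name)
    if code is not None and code.is_amino_acid():
        return gemmi.find_tabulated_residue(res_name).one_letter_code.upper()
    return "X"


def _resolve_altlocs(atoms: list[Atom]) -> list[Atom]:
    """Keep one conformer per atom name: highest occupancy, ties by file order."""
    best: dict[str, Atom] = {}
    order: list[str] = []
    for atom in atoms:
        if atom.name not in best:
            best[atom.name] = atom
            order.append(atom.name)
        elif atom.occupancy > best[atom.name].occupancy:
            best[atom.name] = atom
    out = []
    for name in order:
        a = best[name]
        a.altloc = ""
        out.append(a)
    return out


_FORMATS = {
    "pdb": gemmi.CoorFormat.Pdb,
    "mmcif": gemmi.CoorFormat.Mmcif,
    "auto": gemmi.CoorFormat.Detect,
}


def read_structure(
    path: str | Path,
    format: str = "auto",
    include_het: bool = False,
    include_waters: bool = False,
    include_hydrogens: bool = False,
) -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure`.

    All models are returned.  Waters/heteroatoms and hydrogens are dropped
    unless the corresponding flag is set.  Alternate locations are resolved
    to the highest-occupancy conformer.

    Raises
    ------
    FileNotFoundError
        if *path* does not exist.
    ValueError
        on parse failure (message names the file and the parser error) or
        if no coordinates survive filtering.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(path)
    if format not in _FORMATS:
        raise ValueError(f"unknown format {format!r}; expected pdb|mmcif|auto")
    try:
        st = gemmi.read_structure(str(path), format=_FORMATS[format])
    except (RuntimeError, ValueError) as exc:  # gemmi raises RuntimeError
        raise ValueError(f"cannot parse {path}: {exc}") from exc
    st.setup_entities()
    source_format = "mmcif" if st.input_format == gemmi.CoorFormat.Mmcif else "pdb"

    models: list[Model] = []
    for gmodel in st:
        model: Model = {}
        for gchain in gmodel:
            residues: list[Residue] = []
            for gres in gchain:
                if gres.name in _WATER_NAMES and not include_waters:
                    continue
                if gres.het_flag == "H" and gres.name not in _WATER_NAMES \
                        and not include_het:
                    continue
                atoms = []
                for gatom in gres:
                    if gatom.element.is_hydrogen and not include_hydrogens:
                        continue
                    atoms.append(
                        Atom(
                            name=gatom.name,
                            element=gatom.element.name,
                            coords=np.array([gatom.pos.x, gatom.pos.y, gatom.pos.z]),
                            occupancy=gatom.occ,
                            b_factor=gatom.b_iso,
                            altloc=gatom.altloc or "",
                        )
                    )
                if not atoms:
                    continue
                residues.append(
                    Residue(
                        chain_id=gchain.name,
                        seq_number=gres.seqid.num,
                        res_name=gres.name,
                        atoms=_resolve_altlocs(atoms),
                        insertion_code=(gres.seqid.icode or "").strip(),
                    )
                )
            if residues:
                model[gchain.name] = residues
        if model:
            models.append(model)
    if not models:
        raise ValueError(f"{path}: no coordinates after filtering")
    return Structure(id=st.name or path.stem, models=models, source_format=source_format)


def select_atoms(
    structure: Structure,
    chain_id: str,
    residue_range: tuple[int, int],
    atom_names: Sequence[str] = BACKBONE_ATOMS,
    model_index: int = 0,
    strict: bool = False,
) -> np.ndarray:
    """Return an (N, 3) coordinate array for the selection.

    Atoms are ordered by (seq_number, canonical atom order).  With
    ``strict=True`` a residue in range missing any requested atom raises,
    naming the offending residues; otherwise missing atoms are skipped.
    """
    lo, hi = residue_range
    if hi < lo:
        raise ValueError(f"empty residue range {residue_range}")
    residues = structure.chain(chain_id, model_index)
    wanted = list(atom_names)
    order = {n: _CANONICAL_ORDER.get(n, 100 + i) for i, n in enumerate(sorted(wanted))}
    coords: list[np.ndarray] = []
    missing: list[str] = []
    for res in residues:
        if not (lo <= res.seq_number <= hi):
            continue
        present = {a.name: a for a in res.atoms}
        for name in sorted(wanted, key=order.get):
            if name in present:
                coords.append(present[name].coords)
            else:
                missing.append(f"{res.chain_id}/{res.res_name}{res.seq_number}:{name}")
    if strict and missing:
        raise ValueError("missing atoms in selection: " + ", ".join(missing))
    if not coords:
        raise ValueError(
            f"selection chain {chain_id} residues {lo}-{hi} atoms {wanted} is empty"
        )
    return np.array(coords)


# PDB B-factor field is %6.2f
_BFACTOR_MIN, _BFACTOR_MAX = -99.99, 999.99


def write_structure(
    structure: Structure,
    path: str | Path,
    per_residue_annotation: Mapping | None = None,
) -> None:
    """Write *structure* as PDB, optionally stamping an annotation into B-factors.

    ``per_residue_annotation`` maps residue keys -- ``(chain_id, seq_number)``
    or bare seq_number for single-chain structures -- to a value written into
    the B-factor column of every atom of that residue (the standard trick for
    colouring surfaces by an external score).  Values outside the field width
    and unknown residues raise ``ValueError``.
    """
    path = Path(path)
    annotation = _normalise_annotation(structure, per_residue_annotation)

    st = gemmi.Structure()
    st.name = structure.id
    for i, model in enumerate(structure.models):
        gmodel = gemmi.Model(i + 1)
        for chain_id, residues in model.items():
            gchain = gemmi.Chain(chain_id)
            for res in residues:
                gres = gemmi.Residue()
                gres.name = res.res_name
                gres.het_flag = "A"  # everything we model is written as ATOM
                gres.seqid = gemmi.SeqId(res.seq_number, res.insertion_code or " ")
                value = annotation.get((res.chain_id, res.seq_number, res.insertion_code))
                for atom in res.atoms:
                    gatom = gemmi.Atom()
                    gatom.name = atom.name
                    gatom.element = gemmi.Element(atom.element)
                    gatom.pos = gemmi.Position(*atom.coords)
                    gatom.occ = atom.occupancy
                    gatom.b_iso = atom.b_factor if value is None else value
                    gres.add_atom(gatom)
                gchain.add_residue(gres)
            gmodel.add_chain(gchain)
        st.add_model(gmodel)
    st.setup_entities()
    st.write_pdb(str(path))


def _normalise_annotation(
    structure: Structure, annotation: Mapping | None
) -> dict[tuple[str, int, str], float]:
    if not annotation:
        return {}
    known = {res.key for res in structure.iter_residues()}
    by_number: dict[int, tuple[str, int, str]] = {}
    single_chain = len(structure.chain_ids()) == 1
    if single_chain:
        by_number = {key[1]: key for key in known}
    out: dict[tuple[str, int, str], float] = {}
    for raw_key, value in annotation.items():
        value = float(value)
        if not (_BFACTOR_MIN <= value <= _BFACTOR_MAX):
            raise ValueError(
                f"annotation value {value} for {raw_key} outside the "
                f"B-factor field range [{_BFACTOR_MIN}, {_BFACTOR_MAX}]"
            )
        if isinstance(raw_key, int):
            if raw_key not in by_number:
                raise ValueError(f"annotation names unknown residue {raw_key}")
            key = by_number[raw_key]
        else:
            key = tuple(raw_key)
            if len(key) == 2:
                key = (key[0], key[1], "")
            if key not in known:
                raise ValueError(f"annotation names unknown residue {raw_key}")
        out[key] = value
    return out


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into ordered (id, sequence) pairs."""
    from Bio import SeqIO

    records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    return records
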