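"""Least-squares superposition and backbone r.m.s.d. of ubiquitin-like domains.

The workhorse is the Kabsch algorithm (SVD-based optimal rotation, with the
reflection branch excluded), used for pairwise r.m.s.d. between corresponded
residues, for the precision of multi-model ensembles (mean +/- sd of
per-model r.m.s.d. to an iteratively refined mean structure, the standard
NMR-ensemble convention), and inside the iterative structure-based sequence
alignment that pairs residues of two beta-grasp domains by spatial proximity
rather than sequence similarity.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np

from .structio import BACKBONE_ATOMS, Structure, select_atoms, three_to_one


@dataclasses.dataclass
class SuperpositionResult:
    """Optimal rigid transform: x_fit = rotation @ x_mobile + translation."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_atoms: int


@dataclasses.dataclass
class ResidueCorrespondence:
    """Gapped residue pairing between two chains (by author numbering).

    ``pairs`` holds (number_a, number_b) tuples ordered by side A; ``None``
    marks a gap.  ``names_a``/``names_b`` carry one-letter identities for
    reporting.
    """

    pairs: list[tuple[int | None, int | None]]
    method: str = "sequence"
    names_a: dict[int, str] = dataclasses.field(default_factory=dict)
    names_b: dict[int, str] = dataclasses.field(default_factory=dict)

    def matched(self) -> list[tuple[int, int]]:
        return [(a, b) for a, b in self.pairs if a is not None and b is not None]

    def mapping(self) -> dict[int, int]:
        return dict(self.matched())

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("# method=%s\n" % self.method)
            for a, b in self.pairs:
                fh.write("%s\t%s\n" % ("-" if a is None else a, "-" if b is None else b))

    @classmethod
    def read_tsv(cls, path: str | Path) -> "ResidueCorrespondence":
        pairs: list[tuple[int | None, int | None]] = []
        method = "sequence"
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "method=" in line:
                    method = line.split("method=")[1].strip()
                continue
            a, b = line.split("\t")
            pairs.append(
                (None if a == "-" else int(a), None if b == "-" else int(b))
            )
        return cls(pairs=pairs, method=method)


@dataclasses.dataclass
class EnsembleRmsd:
    """Ensemble precision: mean +/- sd of per-model r.m.s.d. to the mean structure."""

    mean: float
    sd: float
    per_model: list[float]
    residue_range: tuple[int, int]
    atom_set: tuple[str, ...]


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> SuperpositionResult:
    """Optimal (proper) rigid superposition of *mobile* onto *reference*.

    Returns the rotation/translation minimising the r.m.s.d. over all rigid
    transforms, with reflections excluded (det = +1).  Requires two equally
    sized, non-degenerate sets of >= 3 points.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError(
            f"coordinate sets differ in shape: {mobile.shape} vs {reference.shape}"
        )
    if mobile.ndim != 2 or mobile.shape[1] != 3 or mobile.shape[0] < 3:
        raise ValueError("need >= 3 points of dimension 3")
    cm = mobile.mean(axis=0)
    cr = reference.mean(axis=0)
    x = mobile - cm
    y = reference - cr
    h = x.T @ y
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rotation = vt.T @ diag @ u.T
    fitted = x @ rotation.T
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - y) ** 2, axis=1))))
    translation = cr - rotation @ cm
    return SuperpositionResult(
        rotation=rotation, translation=translation, rmsd=rmsd, n_atoms=len(mobile)
    )


def apply_transform(coords: np.ndarray, result: SuperpositionResult) -> np.ndarray:
    return coords @ result.rotation.T + result.translation


def _corresponded_coords(
    struct_a: Structure,
    struct_b: Structure,
    correspondence: ResidueCorrespondence,
    chain_a: str,
    chain_b: str,
    atom_set: Sequence[str],
    model_a: int = 0,
    model_b: int = 0,
) -> tuple[np.ndarray, np.ndarray, int, list[tuple[int, int]]]:
    res_a = {r.seq_number: r for r in struct_a.chain(chain_a, model_a)}
    res_b = {r.seq_number: r for r in struct_b.chain(chain_b, model_b)}
    xa, xb, used, dropped = [], [], [], []
    for a, b in correspondence.matched():
        ra, rb = res_a.get(a), res_b.get(b)
        if ra is None or rb is None:
            dropped.append((a, b))
            continue
        atoms_a = {at.name: at for at in ra.atoms}
        atoms_b = {at.name: at for at in rb.atoms}
        if not all(n in atoms_a and n in atoms_b for n in atom_set):
            dropped.append((a, b))
            continue
        for n in atom_set:
            xa.append(atoms_a[n].coords)
            xb.append(atoms_b[n].coords)
        used.append((a, b))
    if dropped:
        import warnings

        warnings.warn(
            f"{len(dropped)} residue pairs dropped (missing atoms): {dropped[:5]}...",
            stacklevel=3,
        )
    return np.array(xa), np.array(xb), len(used), used


def pairwise_rmsd(
    struct_a: Structure,
    struct_b: Structure,
    correspondence: ResidueCorrespondence,
    atom_set: Sequence[str] = BACKBONE_ATOMS,
    chain_a: str | None = None,
    chain_b: str | None = None,
    model_a: int = 0,
    model_b: int = 0,
) -> SuperpositionResult:
    """Backbone r.m.s.d. between two structures over a residue correspondence.

    Pairs lacking any atom of *atom_set* on either side are dropped with a
    warning; fewer than 3 usable pairs is an error.
    """
    chain_a = chain_a or struct_a.chain_ids(model_a)[0]
    chain_b = chain_b or struct_b.chain_ids(model_b)[0]
    xa, xb, n_pairs, _ = _corresponded_coords(
        struct_a, struct_b, correspondence, chain_a, chain_b, atom_set, model_a, model_b
    )
    if n_pairs < 3:
        raise ValueError(f"only {n_pairs} usable residue pairs (< 3)")
    return kabsch(xb, xa)


def ensemble_rmsd(
    ensemble: Structure,
    residue_range: tuple[int, int],
    atom_set: Sequence[str] = BACKBONE_ATOMS,
    chain_id: str | None = None,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> EnsembleRmsd:
    """Precision of a multi-model ensemble over a residue range.

    Each model is superposed onto the mean structure; the mean structure is
    recomputed from the fitted models and the procedure iterated until it
    shifts by < *tol* Angstrom (r.m.s.).  Reported are mean and sample sd of
    the per-model r.m.s.d. values to the converged mean.
    """
    if ensemble.n_models < 2:
        raise ValueError("ensemble needs >= 2 models")
    chain_id = chain_id or ensemble.chain_ids(0)[0]
    coords = []
    for i in range(ensemble.n_models):
        c = select_atoms(ensemble, chain_id, residue_range, atom_set, model_index=i,
                         strict=True)
        coords.append(c)
    shapes = {c.shape for c in coords}
    if len(shapes) != 1:
        raise ValueError(f"models have differing atom sets in range: shapes {shapes}")
    frames = np.array(coords)
    mean = frames[0].copy()
    for _ in range(max_iter):
        fitted = []
        for f in frames:
            r = kabsch(f, mean)
            fitted.append(apply_transform(f, r))
        fitted = np.array(fitted)
        new_mean = fitted.mean(axis=0)
        shift = float(np.sqrt(np.mean(np.sum((new_mean - mean) ** 2, axis=1))))
        mean = new_mean
        frames = fitted
        if shift < tol:
            break
    per_model = [kabsch(f, mean).rmsd for f in frames]
    mean_rmsd = float(np.mean(per_model))
    sd = float(np.std(per_model, ddof=1)) if len(per_model) > 1 else 0.0
    return EnsembleRmsd(
        mean=mean_rmsd,
        sd=sd,
        per_model=per_model,
        residue_range=tuple(residue_range),
        atom_set=tuple(atom_set),
    )


def _monotone_match(
    ca_a: np.ndarray, ca_b: np.ndarray, cutoff: float
) -> list[tuple[int, int]]:
    """Order-preserving matching of two CA traces.

    Dynamic programme maximising the number of pairs within *cutoff* and,
    among those, minimising the total CA-CA distance.  Returns index pairs.
    """
    n, m = len(ca_a), len(ca_b)
    dist = np.linalg.norm(ca_a[:, None, :] - ca_b[None, :, :], axis=2)
    NEG = (-1, 0.0)  # (pairs, -total_dist) lexicographic value
    # score[i][j]: best over prefixes a[:i], b[:j]
    score = [[(0, 0.0)] * (m + 1) for _ in range(n + 1)]
    move = [[0] * (m + 1) for _ in range(n + 1)]  # 1=match, 2=skip a, 3=skip b
    for i in range(n + 1):
        for j in range(m + 1):
            if i == 0 and j == 0:
                continue
            best, bm = NEG, 0
            if i > 0 and j > 0 and dist[i - 1, j - 1] <= cutoff:
                p, d = score[i - 1][j - 1]
                cand = (p + 1, d - dist[i - 1, j - 1])
                if cand > best:
                    best, bm = cand, 1
            if i > 0:
                cand = score[i - 1][j]
                if cand > best:
                    best, bm = cand, 2
            if j > 0:
                cand = score[i][j - 1]
                if cand > best:
                    best, bm = cand, 3
            score[i][j], move[i][j] = best, bm
    pairs = []
    i, j = n, m
    while i > 0 or j > 0:
        mv = move[i][j]
        if mv == 1:
            pairs.append((i - 1, j - 1))
            i, j = i - 1, j - 1
        elif mv == 2:
            i -= 1
        else:
            j -= 1
    pairs.reverse()
    return pairs


def structure_align(
    struct_a: Structure,
    struct_b: Structure,
    chain_a: str | None = None,
    chain_b: str | None = None,
    seed_alignment: ResidueCorrespondence | None = None,
    cutoff: float = 4.5,
    max_iter: int = 20,
) -> ResidueCorrespondence:
    """Structure-based residue correspondence between two single-chain domains.

    Starting from a sequence-alignment seed, iterate: superpose B onto A on
    the CA atoms of the current pairs, then re-pair residues by an
    order-preserving (monotone) nearest-CA matching with a 4.5 Angstrom
    cutoff, until the pairing is stable or *max_iter* iterations.  Insertions
    in either chain are left unpaired.  The procedure is idempotent: feeding
    its output back as seed returns the same pairing.
    """
    chain_a = chain_a or struct_a.chain_ids(0)[0]
    chain_b = chain_b or struct_b.chain_ids(0)[0]
    res_a = [r for r in struct_a.chain(chain_a) if r.atom("CA") is not None]
    res_b = [r for r in struct_b.chain(chain_b) if r.atom("CA") is not None]
    num_a = [r.seq_number for r in res_a]
    num_b = [r.seq_number for r in res_b]
    ca_a = np.array([r.atom("CA").coords for r in res_a])
    ca_b = np.array([r.atom("CA").coords for r in res_b])

    if seed_alignment is None:
        from .seqcons import sequence_correspondence

        seq_a = "".join(three_to_one(r.res_name) for r in res_a)
        seq_b = "".join(three_to_one(r.res_name) for r in res_b)
        seed_alignment = sequence_correspondence(
            seq_a, seq_b, numbers_a=num_a, numbers_b=num_b
        )
    idx_a = {n: i for i, n in enumerate(num_a)}
    idx_b = {n: i for i, n in enumerate(num_b)}
    pairs = [
        (idx_a[a], idx_b[b])
        for a, b in seed_alignment.matched()
        if a in idx_a and b in idx_b
    ]
    if len(pairs) < 3:
        raise ValueError("no initial pairing found (seed alignment too sparse)")

    for _ in range(max_iter):
        ia = [p[0] for p in pairs]
        ib = [p[1] for p in pairs]
        sup = kabsch(ca_b[ib], ca_a[ia])
        ca_b_fit = apply_transform(ca_b, sup)
        new_pairs = _monotone_match(ca_a, ca_b_fit, cutoff)
        if new_pairs == pairs:
            break
        pairs = new_pairs
        if len(pairs) < 3:
            raise ValueError("structure alignment collapsed below 3 pairs")

    matched_a = {p[0] for p in pairs}
    matched_b = {p[1] for p in pairs}
    full: list[tuple[int | None, int | None]] = []
    pi = 0
    bi = 0
    for i in range(len(res_a)):
        while pi < len(pairs) and bi < pairs[pi][1]:
            if bi not in matched_b:
                full.append((None, num_b[bi]))
            bi += 1
        if pi < len(pairs) and pairs[pi][0] == i:
            full.append((num_a[i], num_b[pairs[pi][1]]))
            bi = pairs[pi][1] + 1
            pi += 1
        elif i not in matched_a:
            full.append((num_a[i], None))
    while bi < len(res_b):
        if bi not in matched_b:
            full.append((None, num_b[bi]))
        bi += 1
    return ResidueCorrespondence(
        pairs=full,
        method="structure",
        names_a={n: three_to_one(r.res_name) for n, r in zip(num_a, res_a)},
        names_b={n: three_to_one(r.res_name) for n, r in zip(num_b, res_b)},
    )
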