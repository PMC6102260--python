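"""Seeded generators for every input class the analysis stages consume.

Each generator is a pure function of (seed, parameters): the same call
produces byte-identical output, and each returns a *truth* record rich
enough to score the downstream recovery test it serves (planted interface
memberships, per-column modal frequencies, melt midpoints, per-residue
fluctuation amplitudes).  Fixtures are geometric, not energetic -- backbone
geometry uses ideal bond lengths/angles with per-class (helix/strand/coil)
dihedrals, and "partners" in synthetic complexes are small occluding atom
clusters, not folded proteins.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .structio import Atom, Residue, Structure

# ideal backbone geometry (Engh & Huber-style averages), Angstrom / degrees
_BOND_N_CA = 1.458
_BOND_CA_C = 1.525
_BOND_C_N = 1.329
_BOND_C_O = 1.231
_ANG_N_CA_C = 111.2
_ANG_CA_C_N = 116.2
_ANG_C_N_CA = 121.7
_ANG_CA_C_O = 120.8

_DIHEDRALS = {"helix": (-57.0, -47.0), "strand": (-139.0, 135.0)}
_COIL_CHOICES = [(-70.0, 140.0), (-100.0, 120.0), (-60.0, -40.0), (-120.0, 160.0)]

_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
           bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """NeRF atom placement: position D from A-B-C with internal coordinates."""
    angle = np.radians(angle_deg)
    torsion = np.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(angle),
        bond * np.sin(angle) * np.cos(torsion),
        bond * np.sin(angle) * np.sin(torsion),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _build_backbone(phi_psi: Sequence[tuple[float, float]]) -> list[dict]:
    """Backbone N/CA/C/O coordinates for a list of (phi, psi) per residue."""
    n_res = len(phi_psi)
    residues: list[dict] = []
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([_BOND_N_CA, 0.0, 0.0])
    ang = np.radians(180.0 - _ANG_N_CA_C)
    c0 = ca0 + _BOND_CA_C * np.array([np.cos(ang), np.sin(ang), 0.0])
    residues.append({"N": n0, "CA": ca0, "C": c0})
    for i in range(1, n_res):
        prev = residues[-1]
        phi_i = phi_psi[i][0]
        psi_prev = phi_psi[i - 1][1]
        n_i = _place(prev["N"], prev["CA"], prev["C"], _BOND_C_N, _ANG_CA_C_N,
                     psi_prev)
        ca_i = _place(prev["CA"], prev["C"], n_i, _BOND_N_CA, _ANG_C_N_CA, 180.0)
        c_i = _place(prev["C"], n_i, ca_i, _BOND_CA_C, _ANG_N_CA_C, phi_i)
        residues.append({"N": n_i, "CA": ca_i, "C": c_i})
    for i, res in enumerate(residues):
        res["O"] = _place(res["N"], res["CA"], res["C"], _BOND_C_O, _ANG_CA_C_O,
                          phi_psi[i][1] + 180.0)
    return residues


def _fold_classes(n_residues: int, fold, rng: np.random.Generator) -> list[str]:
    if isinstance(fold, str):
        classes = [fold] * n_residues
    else:
        classes = list(fold)
        if len(classes) != n_residues:
            raise ValueError("fold class list length != n_residues")
    for c in classes:
        if c not in ("helix", "strand", "coil"):
            raise ValueError(f"unknown fold token {c!r}")
    return classes


def make_structure(
    n_residues: int,
    fold: str | Sequence[str] = "helix",
    seed: int = 0,
    sequence: str | None = None,
    chain_id: str = "A",
    structure_id: str = "synthetic",
) -> tuple[Structure, dict]:
    """Synthetic single-chain backbone with known secondary-structure classes.

    ``fold`` is a single class (helix|strand|coil) or a per-residue list.
    Coil dihedrals are drawn (seeded) from a small allowed set.  Truth
    records the per-residue class and the (phi, psi) actually used.
    """
    if n_residues < 3:
        raise ValueError("need >= 3 residues")
    rng = np.random.default_rng(seed)
    classes = _fold_classes(n_residues, fold, rng)
    phi_psi = []
    for c in classes:
        if c == "coil":
            base = _COIL_CHOICES[rng.integers(len(_COIL_CHOICES))]
            phi_psi.append((base[0] + rng.uniform(-10, 10),
                            base[1] + rng.uniform(-10, 10)))
        else:
            phi_psi.append(_DIHEDRALS[c])
    backbone = _build_backbone(phi_psi)
    if sequence is not None and len(sequence) != n_residues:
        raise ValueError("sequence length != n_residues")
    residues = []
    for i, coords in enumerate(backbone):
        res_name = _ONE_TO_THREE[sequence[i].upper()] if sequence else "ALA"
        atoms = [
            Atom(name=name, element=name[0], coords=coords[name])
            for name in ("N", "CA", "C", "O")
        ]
        residues.append(
            Residue(chain_id=chain_id, seq_number=i + 1, res_name=res_name,
                    atoms=atoms)
        )
    structure = Structure(id=structure_id, models=[{chain_id: residues}])
    truth = {"classes": classes, "phi_psi": phi_psi}
    return structure, truth


def _copy_model(model) -> dict:
    out = {}
    for chain_id, residues in model.items():
        out[chain_id] = [
            Residue(
                chain_id=r.chain_id, seq_number=r.seq_number, res_name=r.res_name,
                insertion_code=r.insertion_code,
                atoms=[Atom(a.name, a.element, a.coords.copy(), a.occupancy,
                            a.b_factor) for a in r.atoms],
            )
            for r in residues
        ]
    return out


def _occlusion_direction(residues: dict, num: int) -> np.ndarray:
    """Outward direction at residue *num*: carbonyl-O vector made perpendicular
    to the local chain axis, so a partner placed along it shadows mainly this
    residue and not its chain neighbours."""
    res = residues[num]
    ca = res.atom("CA").coords
    prv = residues.get(num - 1) or res
    nxt = residues.get(num + 1) or res
    axis = nxt.atom("CA").coords - prv.atom("CA").coords
    norm = np.linalg.norm(axis)
    axis = axis / norm if norm > 1e-6 else np.array([1.0, 0.0, 0.0])
    d = res.atom("O").coords - ca
    d = d - (d @ axis) * axis
    norm = np.linalg.norm(d)
    return d / norm if norm > 1e-6 else np.array([0.0, 0.0, 1.0])


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


def make_complex(
    reference: Structure,
    interface_spec: Sequence[int],
    seed: int = 0,
    threshold: float = 0.10,
    complex_id: str = "synthetic-complex",
    max_retries: int = 40,
    sasa_params: Mapping | None = None,
) -> tuple[Structure, dict]:
    """Binary complex occluding exactly the named reference residues.

    Partner chains (single occluding atoms, one chain per target residue)
    are placed against the reference chain so that each residue in
    ``interface_spec`` -- and no other -- ends up with a buried-SASA
    fraction strictly above *threshold*.  The plant is self-certifying: the
    emitted fixture is verified with this package's own buried-SASA scorer
    (same parameters the downstream analysis uses) before it is returned;
    placement that cannot be certified within ``max_retries`` raises with a
    suggestion to pick different residues.
    """
    from .interface import buried_sasa

    rng = np.random.default_rng(seed)
    params = dict(probe_radius=1.4, n_points=960, radii_set="bondi64")
    if sasa_params:
        params.update(sasa_params)
    ref_chain = reference.chain_ids(0)[0]
    residues = {r.seq_number: r for r in reference.chain(ref_chain)}
    for num in interface_spec:
        if num not in residues:
            raise ValueError(f"interface residue {num} not in reference chain")
    all_coords = np.array([
        a.coords for r in reference.chain(ref_chain) for a in r.atoms
    ])
    centroid = all_coords.mean(axis=0)

    partner_names = [c for c in "BCDEFGHIJKLMNOPQRSTUVWXYZ" if c != ref_chain]
    targets = sorted(set(interface_spec))

    if not targets:
        model = _copy_model(reference.models[0])
        far = centroid + np.array([150.0, 0.0, 0.0])
        model["Z"] = [_cluster_residue("Z", far[None, :])]
        candidate = Structure(id=complex_id, models=[model])
        record = buried_sasa(candidate, ref_chain, ["Z"], complex_id, **params)
        achieved = {k[1] for k, v in record.per_residue.items() if v[3] > threshold}
        if achieved:
            raise RuntimeError("distant partner unexpectedly buried residues")
        return candidate, {"interface": [], "fractions": {
            k[1]: v[3] for k, v in record.per_residue.items()}}

    for attempt in range(max_retries):
        model = _copy_model(reference.models[0])
        for t_i, num in enumerate(targets):
            res = residues[num]
            res_centroid = np.mean([a.coords for a in res.atoms], axis=0)
            direction = _occlusion_direction(residues, num)
            jitter = rng.normal(scale=0.1 * attempt, size=3)
            dist = 3.0 + 0.25 * (attempt % 5)
            center = res_centroid + direction * dist + jitter
            chain_name = partner_names[t_i]
            model[chain_name] = [_cluster_residue(chain_name, center[None, :])]
        candidate = Structure(id=complex_id, models=[model])
        partner_chains = [partner_names[i] for i in range(len(targets))]
        record = buried_sasa(candidate, ref_chain, partner_chains, complex_id,
                             **params)
        achieved = {k[1] for k, v in record.per_residue.items() if v[3] > threshold}
        if achieved == set(targets):
            truth = {
                "interface": targets,
                "fractions": {k[1]: v[3] for k, v in record.per_residue.items()},
            }
            return candidate, truth
    raise RuntimeError(
        f"could not certify interface plant {targets} after {max_retries} tries; "
        "try residues farther apart or nearer the surface"
    )


def _cluster_residue(chain_id: str, coords: np.ndarray) -> Residue:
    atoms = [
        Atom(name=f"C{i + 1}", element="C", coords=c) for i, c in enumerate(coords)
    ]
    return Residue(chain_id=chain_id, seq_number=1, res_name="UNK", atoms=atoms)


def make_msa(
    n_seqs: int,
    length: int,
    conservation: Sequence[float],
    seed: int = 0,
) -> tuple["Msa", dict]:
    """MSA with exact planted per-column modal frequencies.

    For each column, a modal residue is chosen and planted in exactly
    ``round(p * n_seqs)`` sequences; the remaining sequences receive other
    residues, re-drawn so that no competitor exceeds the modal count.  The
    identity-conservation score of every column therefore equals the
    planted count / n_seqs exactly, which the truth records.
    """
    from .seqcons import Msa

    conservation = list(conservation)
    if len(conservation) != length:
        raise ValueError("conservation vector length != alignment length")
    if any(not (1.0 / 20.0 <= p <= 1.0) for p in conservation):
        raise ValueError("modal frequencies must lie in [1/20, 1]")
    rng = np.random.default_rng(seed)
    columns = []
    truth_freqs = []
    for p in conservation:
        k = max(1, round(p * n_seqs))
        modal = AMINO_ACIDS[rng.integers(20)]
        carriers = rng.choice(n_seqs, size=k, replace=False)
        col = [""] * n_seqs
        others = [a for a in AMINO_ACIDS if a != modal]
        for attempt in range(100):
            counts: dict[str, int] = {}
            trial = list(col)
            for s in range(n_seqs):
                if s in carriers:
                    trial[s] = modal
                else:
                    aa = others[rng.integers(19)]
                    trial[s] = aa
                    counts[aa] = counts.get(aa, 0) + 1
            if not counts or max(counts.values()) <= k:
                col = trial
                break
        else:
            raise RuntimeError("could not keep the planted residue modal")
        columns.append(col)
        truth_freqs.append(k / n_seqs)
    records = [
        (f"seq{s + 1}", "".join(columns[c][s] for c in range(length)))
        for s in range(n_seqs)
    ]
    return Msa(records=records), {"modal_frequency": truth_freqs}


def make_melt(
    tm: float,
    steepness: float = 1.0,
    noise_sd: float = 0.0,
    t_min: float = 20.0,
    t_max: float = 95.0,
    step: float = 0.036,
    baseline: tuple[float, float] = (1.0, 2.0),
    seed: int = 0,
    replicate_id: str | None = None,
) -> tuple["MeltCurve", dict]:
    """Two-state sigmoid melt curve plus Gaussian noise; truth is the midpoint.

    The temperature grid mirrors a nanoDSF run: *step* degC increments
    (default 0.036) between *t_min* and *t_max*.  The noiseless derivative
    maximum sits exactly at ``tm`` (the sigmoid inflection).
    """
    from .stability_md import MeltCurve

    if not (t_min < tm < t_max):
        raise ValueError(f"tm {tm} outside grid [{t_min}, {t_max}]")
    rng = np.random.default_rng(seed)
    t = np.arange(t_min, t_max + step / 2, step)
    low, high = baseline
    signal = low + (high - low) / (1.0 + np.exp(-(t - tm) / steepness))
    if noise_sd > 0:
        signal = signal + rng.normal(scale=noise_sd * abs(high - low), size=len(t))
    curve = MeltCurve(temperature=t, signal=signal, replicate_id=replicate_id)
    return curve, {"tm": tm, "steepness": steepness, "noise_sd": noise_sd}


def make_ensemble(
    base: Structure,
    sigma_profile: float | Mapping[int, float],
    n_models: int,
    disordered_tail: tuple[int, int] | None = None,
    tail_sigma: float = 2.0,
    seed: int = 0,
) -> tuple[Structure, dict]:
    """Multi-model ensemble: base coordinates plus per-residue Gaussian jitter.

    ``sigma_profile`` is a scalar or a residue-number -> sigma map (Angstrom
    per coordinate).  Residues inside ``disordered_tail`` emulate a
    disordered terminus: they additionally receive ``tail_sigma`` jitter,
    i.e. large, uncorrelated displacements.  Truth records the per-residue
    sigma actually applied.
    """
    if n_models < 2:
        raise ValueError("need >= 2 models")
    chain_id = base.chain_ids(0)[0]
    residues = base.chain(chain_id)
    sigmas: dict[int, float] = {}
    for r in residues:
        if isinstance(sigma_profile, Mapping):
            s = float(sigma_profile.get(r.seq_number, 0.0))
        else:
            s = float(sigma_profile)
        if disordered_tail and disordered_tail[0] <= r.seq_number <= disordered_tail[1]:
            s = max(s, tail_sigma)
        if s < 0:
            raise ValueError(f"negative sigma for residue {r.seq_number}")
        sigmas[r.seq_number] = s
    rng = np.random.default_rng(seed)
    models = []
    for _ in range(n_models):
        model = _copy_model(base.models[0])
        for r in model[chain_id]:
            s = sigmas[r.seq_number]
            if s > 0:
                for a in r.atoms:
                    a.coords = a.coords + rng.normal(scale=s, size=3)
        models.append(model)
    ensemble = Structure(id=base.id + "-ensemble", models=models)
    return ensemble, {"sigma": sigmas}
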