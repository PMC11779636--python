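"""Coarse-grained structure I/O and rigid-body geometry.

A conformer is one bead-per-residue model of an RNA molecule (by default the
phosphorus atom stands in for the residue).  An ensemble is an ordered set of
conformers sharing one residue numbering — the object every downstream stage
(SAXS back-calculation, invariant-core search, PCA, r.m.s.f.) consumes.

Residue numbers are kept verbatim from the input file (1-based); every matrix
or vector output of this package is positional (0-based) over the ensemble's
``residue_numbers`` order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio.PDB import PDBParser
from scipy.spatial.transform import Rotation

__all__ = [
    "Conformer",
    "ConformerEnsemble",
    "read_conformer",
    "write_conformer",
    "write_ensemble_pdb",
    "load_ensemble",
    "kabsch_superpose",
    "pairwise_rmsd_matrix",
]


@dataclass(frozen=True)
class Conformer:
    """One coarse-grained structure: bead coordinates in Å plus optional B-factors.

    Parameters
    ----------
    id : str
        Label, typically the source filename stem.
    residue_numbers : ndarray of int
        Strictly increasing residue numbers, one per bead.
    coords : ndarray, shape (N, 3)
        Bead coordinates in Å.
    bfactors : ndarray of float, optional
        Crystallographic B-factors (Å²-scaled) per bead.
    """

    id: str
    residue_numbers: np.ndarray
    coords: np.ndarray
    bfactors: np.ndarray | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "residue_numbers", np.asarray(self.residue_numbers, dtype=int))
        object.__setattr__(self, "coords", np.asarray(self.coords, dtype=float))
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be an (N, 3) array")
        n = len(self.residue_numbers)
        if self.coords.shape[0] != n:
            raise ValueError("one coordinate row per residue number required")
        if n < 3:
            raise ValueError("a conformer needs at least 3 residues")
        if np.any(np.diff(self.residue_numbers) <= 0):
            raise ValueError("residue numbers must be strictly increasing")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        if self.bfactors is not None:
            b = np.asarray(self.bfactors, dtype=float)
            if b.shape != (n,):
                raise ValueError("bfactors must have one value per residue")
            object.__setattr__(self, "bfactors", b)

    @property
    def n_residues(self) -> int:
        return len(self.residue_numbers)

    def subset(self, residue_numbers: Iterable[int]) -> "Conformer":
        """Restrict to the given residue numbers (kept in structure order)."""
        wanted = set(int(r) for r in residue_numbers)
        mask = np.array([int(r) in wanted for r in self.residue_numbers])
        if mask.sum() == 0:
            raise ValueError("subset selects no residues")
        return Conformer(
            id=self.id,
            residue_numbers=self.residue_numbers[mask],
            coords=self.coords[mask],
            bfactors=None if self.bfactors is None else self.bfactors[mask],
        )


@dataclass
class ConformerEnsemble:
    """Ordered conformers on a common residue index.

    All members must share identical residue numbering; ``reference_index``
    names the member used as superposition reference by default.
    """

    members: list[Conformer]
    reference_index: int = 0

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("an ensemble needs at least 2 members")
        if not 0 <= self.reference_index < len(self.members):
            raise ValueError("reference_index out of range")
        ref = self.members[0].residue_numbers
        for m in self.members[1:]:
            if not np.array_equal(m.residue_numbers, ref):
                raise ValueError(
                    f"conformer {m.id!r} has a residue set inconsistent with {self.members[0].id!r}"
                )

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    def __getitem__(self, i: int) -> Conformer:
        return self.members[i]

    @property
    def residue_numbers(self) -> np.ndarray:
        return self.members[0].residue_numbers

    @property
    def n_residues(self) -> int:
        return self.members[0].n_residues

    def coordinate_array(self) -> np.ndarray:
        """Stack member coordinates into an (M, N, 3) array."""
        return np.stack([m.coords for m in self.members])

    def superposed(self, subset: Sequence[int] | None = None) -> "ConformerEnsemble":
        """Superpose every member on the reference over ``subset`` residues."""
        ref = self.members[self.reference_index]
        fitted = [
            m if i == self.reference_index else kabsch_superpose(m, ref, subset)[0]
            for i, m in enumerate(self.members)
        ]
        return ConformerEnsemble(fitted, reference_index=self.reference_index)


# --- PDB I/O --------------------------------------------------------------

def read_conformer(path: str | Path, atom_name: str = "P") -> Conformer:
    """Read one bead-per-residue conformer from a PDB file.

    Picks the atom named ``atom_name`` (default ``"P"``, one per RNA residue)
    from each residue; residues lacking it are skipped.  The B-factor column
    is captured when present.  First altloc wins; insertion codes are
    rejected because coarse-grained models do not use them.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(path.stem, str(path))
    model = next(structure.get_models())
    records: dict[int, tuple[np.ndarray, float]] = {}
    for chain in model:
        for residue in chain:
            _, resseq, icode = residue.id
            if icode.strip():
                raise ValueError(f"{path.name}: insertion code at residue {resseq} not supported")
            for atom in residue:
                if atom.get_name() != atom_name:
                    continue
                if resseq in records:
                    raise ValueError(f"{path.name}: duplicated atom {atom_name!r} for residue {resseq}")
                records[resseq] = (np.array(atom.get_coord(), dtype=float), float(atom.get_bfactor()))
    if not records:
        raise ValueError(f"{path.name}: no matching atoms named {atom_name!r}")
    resnums = np.array(sorted(records), dtype=int)
    coords = np.array([records[r][0] for r in resnums])
    bfactors = np.array([records[r][1] for r in resnums])
    return Conformer(id=path.stem, residue_numbers=resnums, coords=coords, bfactors=bfactors)


_ATOM_FMT = (
    "ATOM  {serial:>5d} {name:^4s}{altloc:1s}{resname:>3s} {chain:1s}"
    "{resseq:>4d}{icode:1s}   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          {element:>2s}\n"
)


def _atom_lines(conformer: Conformer, atom_name: str, resname: str, chain: str) -> list[str]:
    b = conformer.bfactors if conformer.bfactors is not None else np.zeros(conformer.n_residues)
    lines = []
    for serial, (rn, xyz, bf) in enumerate(zip(conformer.residue_numbers, conformer.coords, b), 1):
        lines.append(
            _ATOM_FMT.format(
                serial=serial, name=atom_name, altloc=" ", resname=resname, chain=chain,
                resseq=int(rn), icode=" ", x=xyz[0], y=xyz[1], z=xyz[2],
                occ=1.0, b=float(bf), element=atom_name[0],
            )
        )
    return lines


def write_conformer(
    conformer: Conformer,
    path: str | Path,
    atom_name: str = "P",
    resname: str = "N",
    chain: str = "A",
) -> None:
    """Write minimal wwPDB v3.3 ATOM records (occupancy 1.00, stored B-factor)."""
    with open(path, "w") as fh:
        fh.writelines(_atom_lines(conformer, atom_name, resname, chain))
        fh.write("END\n")


def write_ensemble_pdb(ensemble: ConformerEnsemble, path: str | Path, atom_name: str = "P") -> None:
    """Write an ensemble as a multi-model PDB (one MODEL per member)."""
    with open(path, "w") as fh:
        for i, conf in enumerate(ensemble, 1):
            fh.write(f"MODEL     {i:>4d}\n")
            fh.writelines(_atom_lines(conf, atom_name, "N", "A"))
            fh.write("ENDMDL\n")
        fh.write("END\n")


def load_ensemble(dir_path: str | Path, atom_name: str = "P", pattern: str = "*.pdb") -> ConformerEnsemble:
    """Load every PDB file in a directory (sorted by filename) as an ensemble.

    Residue-number consistency across files is enforced; a mismatching file
    is reported by name.
    """
    dir_path = Path(dir_path)
    files = sorted(dir_path.glob(pattern))
    if len(files) < 2:
        raise ValueError(f"{dir_path}: need at least 2 structure files, found {len(files)}")
    members = [read_conformer(f, atom_name=atom_name) for f in files]
    return ConformerEnsemble(members)


# --- superposition --------------------------------------------------------

def _check_not_collinear(points: np.ndarray) -> None:
    centered = points - points.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise ValueError("superposition subset has fewer than 3 non-collinear points")


def kabsch_superpose(
    mobile: Conformer,
    reference: Conformer,
    subset: Sequence[int] | None = None,
) -> tuple[Conformer, float]:
    """Rigidly fit ``mobile`` onto ``reference``, minimizing r.m.s.d. over ``subset``.

    The optimal proper rotation (Kabsch, reflection-corrected) is found over
    the subset residues; the transform is then applied to the whole mobile
    conformer.  Returns the fitted conformer and the minimum r.m.s.d. in Å
    computed over the subset.
    """
    if subset is None:
        sub_mob, sub_ref = mobile, reference
    else:
        sub_mob, sub_ref = mobile.subset(subset), reference.subset(subset)
        if not np.array_equal(sub_mob.residue_numbers, sub_ref.residue_numbers):
            raise ValueError("subset residues differ between mobile and reference")
    if sub_mob.n_residues < 3:
        raise ValueError("superposition needs at least 3 subset residues")
    _check_not_collinear(sub_mob.coords)

    mob_center = sub_mob.coords.mean(axis=0)
    ref_center = sub_ref.coords.mean(axis=0)
    with warnings.catch_warnings():
        # align_vectors warns for exact (zero-residual) alignments
        warnings.simplefilter("ignore", UserWarning)
        rot, _ = Rotation.align_vectors(sub_ref.coords - ref_center, sub_mob.coords - mob_center)
    fitted_subset = rot.apply(sub_mob.coords - mob_center) + ref_center
    rmsd = float(np.sqrt(np.mean(np.sum((fitted_subset - sub_ref.coords) ** 2, axis=1))))
    fitted_coords = rot.apply(mobile.coords - mob_center) + ref_center
    return replace(mobile, coords=fitted_coords), rmsd


def pairwise_rmsd_matrix(
    ensemble: ConformerEnsemble, subset: Sequence[int] | None = None
) -> np.ndarray:
    """Symmetric M×M matrix of superposed pairwise r.m.s.d. values (Å)."""
    m = len(ensemble)
    out = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            _, rmsd = kabsch_superpose(ensemble[j], ensemble[i], subset)
            out[i, j] = out[j, i] = rmsd
    return out
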