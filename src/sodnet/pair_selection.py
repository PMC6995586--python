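"""Contact maps, minimum-separation filtering, and ranked pair selection.

High MI/DI scores between sequence neighbours are trivial (they reflect
local structure of the alignment, not 3D contacts), so candidate pairs
must be at least ``min_separation`` positions apart along the sequence
(default 5).  The top-ranked surviving pairs are then checked against a
structural contact map: a pair "imposes a contact" when its residues'
Cbeta atoms (Calpha for glycine) lie within a distance cutoff, 8 A by
default — the standard convention for evaluating coevolution-based
contact prediction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import biotite.structure as bst
import biotite.structure.io.pdb as bpdb

logger = logging.getLogger(__name__)

DEFAULT_CONTACT_CUTOFF = 8.0
DEFAULT_MIN_SEPARATION = 5


@dataclass
class Structure:
    """Per-residue coordinates of one chain of a 3D model.

    ``cb`` holds the Cbeta coordinate where present and the Calpha
    coordinate otherwise (glycine, or missing atoms) — i.e. exactly the
    point used by the contact definition.
    """

    res_ids: np.ndarray  # (n,) residue numbers
    res_names: list[str]  # 3-letter or 1-letter residue names
    ca: np.ndarray  # (n, 3)
    cb: np.ndarray  # (n, 3)

    @property
    def n_residues(self) -> int:
        return len(self.res_ids)


@dataclass
class ContactMap:
    n_residues: int
    contacts: np.ndarray  # boolean, symmetric, False diagonal
    definition: dict = field(default_factory=dict)
    res_ids: np.ndarray | None = None

    def in_contact(self, res_i: int, res_j: int) -> bool | None:
        """Contact status in residue numbering; None if not covered."""
        if self.res_ids is None:
            idx = {r: r - 1 for r in range(1, self.n_residues + 1)}
        else:
            idx = {int(r): k for k, r in enumerate(self.res_ids)}
        if res_i not in idx or res_j not in idx:
            return None
        return bool(self.contacts[idx[res_i], idx[res_j]])


@dataclass
class PairSelection:
    """Ranked list of (i, j, score) pairs in reference numbering, i < j."""

    pairs: list[tuple[int, int, float]]
    min_separation: int
    top_n: int
    in_contact: list[bool | None] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def residues(self) -> list[int]:
        """Distinct residues covered by the selection, sorted."""
        return sorted({r for i, j, _ in self.pairs for r in (i, j)})


def read_structure(path: str | Path, chain: str | None = None, model: int = 1) -> Structure:
    """Read one chain of a PDB file into per-residue CA/CB coordinates.

    Residues without a Calpha coordinate are excluded with a warning.
    """
    pdb_file = bpdb.PDBFile.read(str(path))
    atoms = pdb_file.get_structure(model=model, altloc="first")
    atoms = atoms[bst.filter_amino_acids(atoms)]
    if chain is None:
        chain = atoms.chain_id[0]
    atoms = atoms[atoms.chain_id == chain]
    res_ids, res_names, ca_list, cb_list = [], [], [], []
    for res_id in np.unique(atoms.res_id):
        res = atoms[atoms.res_id == res_id]
        ca = res.coord[res.atom_name == "CA"]
        if len(ca) == 0:
            warnings.warn(f"residue {int(res_id)} has no CA atom; excluded")
            continue
        cb = res.coord[res.atom_name == "CB"]
        res_ids.append(int(res_id))
        res_names.append(str(res.res_name[0]))
        ca_list.append(ca[0])
        cb_list.append(cb[0] if len(cb) else ca[0])
    if not res_ids:
        raise ValueError(f"no residues with coordinates in {path}")
    return Structure(
        res_ids=np.array(res_ids),
        res_names=res_names,
        ca=np.array(ca_list, dtype=float),
        cb=np.array(cb_list, dtype=float),
    )


def contact_map(structure: Structure, cutoff: float = DEFAULT_CONTACT_CUTOFF) -> ContactMap:
    """Boolean residue-residue contact matrix at a Cbeta distance cutoff."""
    if structure.n_residues < 2:
        raise ValueError("contact map needs a structure with >= 2 residues")
    pts = structure.cb
    diff = pts[:, None, :] - pts[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=2))
    contacts = dist <= cutoff
    np.fill_diagonal(contacts, False)
    return ContactMap(
        n_residues=structure.n_residues,
        contacts=contacts,
        definition={"atom_rule": "CB (CA for GLY/missing CB)", "cutoff_angstrom": cutoff},
        res_ids=structure.res_ids,
    )


def select_top_pairs(
    scores: np.ndarray,
    top_n: int,
    min_separation: int = DEFAULT_MIN_SEPARATION,
    column_map: dict[int, int] | None = None,
) -> PairSelection:
    """Top-n highest-scoring pairs at least ``min_separation`` apart.

    The separation filter is applied in sequence (reference) numbering.
    Sorting is by descending score with deterministic lexicographic (i, j)
    tie-breaking.  If fewer eligible pairs exist than requested, all are
    returned with a warning.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    L = scores.shape[0]
    cmap = column_map or {c: c + 1 for c in range(L)}
    eligible = []
    for ci in range(L):
        if ci not in cmap:
            continue
        for cj in range(ci + 1, L):
            if cj not in cmap:
                continue
            i, j = cmap[ci], cmap[cj]
            if abs(i - j) >= min_separation:
                eligible.append((i, j, float(scores[ci, cj])))
    eligible.sort(key=lambda p: (-p[2], p[0], p[1]))
    if len(eligible) < top_n:
        warnings.warn(
            f"only {len(eligible)} eligible pairs for top_n={top_n}; returning all"
        )
    return PairSelection(
        pairs=eligible[:top_n], min_separation=min_separation, top_n=top_n
    )


def flag_contacts(sel: PairSelection, cmap: ContactMap) -> PairSelection:
    """Mark each selected pair as contact-imposing or not.

    Pairs with a residue outside the structure's coverage are flagged
    ``None`` (unknown) and excluded from the contact counts.
    """
    flags: list[bool | None] = []
    unknown = 0
    for i, j, _ in sel.pairs:
        f = cmap.in_contact(i, j)
        if f is None:
            unknown += 1
        flags.append(f)
    if unknown:
        warnings.warn(f"{unknown} pairs fall outside the structure coverage")
    n_contact = sum(1 for f in flags if f)
    logger.info("%d of %d selected pairs impose contacts", n_contact, len(flags))
    return PairSelection(
        pairs=sel.pairs,
        min_separation=sel.min_separation,
        top_n=sel.top_n,
        in_contact=flags,
    )


def write_selection(sel: PairSelection, path: str | Path) -> None:
    """TSV of the selected pairs with contact flags."""
    with open(path, "w") as fh:
        fh.write("i\tj\tscore\tin_contact\n")
        flags = sel.in_contact or [None] * len(sel)
        for (i, j, s), f in zip(sel.pairs, flags):
            fh.write(f"{i}\t{j}\t{s:.6g}\t{'' if f is None else int(f)}\n")
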