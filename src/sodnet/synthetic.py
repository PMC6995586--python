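"""Synthetic inputs for exercising and validating the pipeline end to end.

Three generators, all seed-deterministic, all emitting the exact formats
the pipeline reads:

* :func:`sample_potts_msa` — alignments Gibbs-sampled from a Potts model
  with *planted* pairwise couplings, optionally padded with near-duplicate
  rows to exercise sequence reweighting.  Ground truth (which pairs are
  coupled) is known, so contact-prediction-style recovery can be scored.
* :func:`make_toy_chain` — deterministic Calpha chains (extended strand,
  ideal alpha-helix, two-helix dimer) with known elastic-network spectra;
  a pseudo-atom "cross-link" can be added to mimic a bound metal bridging
  loop residues.
* :func:`make_disorder_fixture` — multi-predictor per-residue disorder
  score tables with planted disordered stretches.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import biotite.structure as bst
import biotite.structure.io.pdb as bpdb

from .msa_io import ALPHABET, Alignment

CA_SPACING = 3.8  # A, consecutive Calpha distance
HELIX_RADIUS = 2.3  # A, ideal alpha-helix
HELIX_RISE = 1.5  # A per residue
HELIX_TWIST = np.deg2rad(100.0)  # per residue

_ONE_TO_THREE = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR",
}


@dataclass
class PottsSpec:
    """Sampling specification for a planted-coupling Potts alignment."""

    L: int = 50
    q: int = 8
    planted_pairs: list[tuple[int, int, float]] = field(default_factory=list)
    fields: np.ndarray | None = None  # (L, q) per-site biases
    M: int = 4000
    seed: int = 0
    n_sweeps: int = 50
    duplication_fraction: float = 0.0

    def __post_init__(self):
        if not 2 <= self.q <= 20:
            raise ValueError("q must be in [2, 20] (gap is reserved)")
        for i, j, s in self.planted_pairs:
            if not (0 <= i < self.L and 0 <= j < self.L):
                raise ValueError(f"planted pair ({i}, {j}) outside [0, L)")
            if abs(i - j) < 5:
                raise ValueError(
                    f"planted pair ({i}, {j}) closer than the minimum separation 5"
                )


def plant_random_pairs(
    L: int, n_pairs: int, strength: float, seed: int, min_separation: int = 5
) -> list[tuple[int, int, float]]:
    """Disjoint random site pairs at least ``min_separation`` apart."""
    rng = np.random.default_rng(seed)
    pairs: list[tuple[int, int, float]] = []
    used: set[int] = set()
    attempts = 0
    while len(pairs) < n_pairs:
        attempts += 1
        if attempts > 10000:
            raise RuntimeError("could not place the requested number of pairs")
        i, j = sorted(rng.integers(0, L, size=2).tolist())
        if j - i < min_separation or i in used or j in used:
            continue
        pairs.append((i, j, strength))
        used.update((i, j))
    return sorted(pairs)


def sample_potts_msa(spec: PottsSpec) -> tuple[Alignment, dict]:
    """Gibbs-sample an alignment from the planted-coupling Potts model.

    ``P(s) ~ exp(sum_i h_i(s_i) + sum_(i,j) J_ij(s_i, s_j))`` with
    ``J_ij = strength * I_q`` for each planted pair (same-state
    preference).  Each of the M rows is an independent chain run for
    ``n_sweeps`` full Gibbs sweeps from a random start (chains are
    vectorized across rows, never reused).  Near-duplicates (5% positions
    re-randomized) are appended afterwards to create redundancy.

    Returns the alignment and a ground-truth dict with the planted pairs
    in 1-based numbering.
    """
    rng = np.random.default_rng(spec.seed)
    L, q, M = spec.L, spec.q, spec.M
    h = np.zeros((L, q)) if spec.fields is None else np.asarray(spec.fields, float)

    neighbors: dict[int, list[tuple[int, float]]] = {i: [] for i in range(L)}
    for i, j, s in spec.planted_pairs:
        neighbors[i].append((j, s))
        neighbors[j].append((i, s))

    states = rng.integers(0, q, size=(M, L))
    for _ in range(spec.n_sweeps):
        for i in range(L):
            logits = np.broadcast_to(h[i], (M, q)).copy()
            for j, s in neighbors[i]:
                # identity coupling: bonus s for matching the partner state
                logits[np.arange(M), states[:, j]] += s
            logits -= logits.max(axis=1, keepdims=True)
            p = np.exp(logits)
            p /= p.sum(axis=1, keepdims=True)
            u = rng.random((M, 1))
            states[:, i] = (p.cumsum(axis=1) < u).sum(axis=1)

    n_dup = int(round(spec.duplication_fraction * M))
    if n_dup:
        parents = rng.integers(0, M, size=n_dup)
        dup = states[parents].copy()
        n_mut = max(1, int(round(0.05 * L)))
        for k in range(n_dup):
            pos = rng.choice(L, size=n_mut, replace=False)
            dup[k, pos] = rng.integers(0, q, size=n_mut)
        states = np.vstack([states, dup])

    aln = Alignment(
        matrix=states.astype(np.uint8),  # states 0..q-1 index ALPHABET directly
        ids=[f"seq{k + 1}" for k in range(states.shape[0])],
    )
    truth = {
        "planted_pairs": [[i + 1, j + 1] for i, j, _ in sorted(spec.planted_pairs)],
        "L": L,
        "q": q,
        "M": M,
        "n_duplicates": n_dup,
        "seed": spec.seed,
    }
    return aln, truth


def make_toy_chain(
    n: int, geometry: str = "extended", seed: int = 0
) -> tuple[np.ndarray, str]:
    """Deterministic Calpha coordinates plus a paired reference sequence.

    ``extended``: collinear chain at 3.8 A spacing.  ``helix``: ideal
    alpha-helix (radius 2.3 A, rise 1.5 A, 100 deg/residue).  ``dimer``:
    two identical parallel helices of n/2 residues, 9 A apart.
    """
    if n < 2:
        raise ValueError("need at least 2 residues")
    if geometry == "extended":
        coords = np.zeros((n, 3))
        coords[:, 0] = CA_SPACING * np.arange(n)
    elif geometry == "helix":
        coords = _helix(n)
    elif geometry == "dimer":
        # second monomer is the mirror image across the inter-monomer plane,
        # so for even n the label swap i <-> i + n/2 is an exact symmetry
        half = n // 2
        a = _helix(half)
        b = _helix(n - half)
        b = b * np.array([1.0, -1.0, 1.0]) + np.array([0.0, 9.0, 0.0])
        coords = np.vstack([a, b])
    else:
        raise ValueError(f"unknown geometry {geometry!r}")
    alphabet = "ACDEFGHIKLMNPQRSTVWY"
    sequence = "".join(alphabet[k % len(alphabet)] for k in range(n))
    return coords, sequence


def _helix(n: int) -> np.ndarray:
    k = np.arange(n)
    return np.column_stack(
        [
            HELIX_RADIUS * np.cos(HELIX_TWIST * k),
            HELIX_RADIUS * np.sin(HELIX_TWIST * k),
            HELIX_RISE * k,
        ]
    )


def add_crosslink(coords: np.ndarray, attach: list[int]) -> np.ndarray:
    """Append a pseudo-atom at the centroid of the attached residues.

    Mimics a bound metal ion bridging loop residues: the extra network
    node adds springs to everything within the ENM cutoff around the
    attachment centroid, stiffening the cross-linked stretch.
    """
    if len(attach) < 2:
        raise ValueError("a cross-link needs at least 2 attachment residues")
    centroid = coords[list(attach)].mean(axis=0)
    return np.vstack([coords, centroid])


def write_ca_pdb(coords: np.ndarray, sequence: str, path: str | Path) -> None:
    """Write a Calpha-only chain as PDB (residues numbered from 1)."""
    n = coords.shape[0]
    atoms = bst.AtomArray(n)
    atoms.coord = np.asarray(coords, dtype=np.float32)
    atoms.chain_id = np.full(n, "A")
    atoms.res_id = np.arange(1, n + 1)
    atoms.res_name = np.array(
        [_ONE_TO_THREE.get(sequence[k], "GLY") for k in range(n)]
    )
    atoms.atom_name = np.full(n, "CA")
    atoms.element = np.full(n, "C")
    atoms.hetero = np.full(n, False)
    pdb_file = bpdb.PDBFile()
    pdb_file.set_structure(atoms)
    pdb_file.write(str(path))


def make_disorder_fixture(
    n: int,
    disordered_ranges: list[tuple[int, int]],
    n_predictors: int = 6,
    seed: int = 0,
    high: float = 0.7,
    low: float = 0.15,
) -> pd.DataFrame:
    """Multi-predictor disorder score table with planted disordered stretches.

    Scores inside the (1-based, inclusive) ranges centre on ``high``,
    outside on ``low``, with predictor-level jitter, clipped to [0, 1].
    Overlapping ranges are merged with a warning.
    """
    rng = np.random.default_rng(seed)
    merged: list[list[int]] = []
    for a, b in sorted(disordered_ranges):
        if not 1 <= a <= b <= n:
            raise ValueError(f"range ({a}, {b}) outside [1, {n}]")
        if merged and a <= merged[-1][1] + 1:
            warnings.warn(f"overlapping disordered ranges merged at {a}-{b}")
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    base = np.full(n, low)
    for a, b in merged:
        base[a - 1 : b] = high
    data = {}
    for p in range(n_predictors):
        offset = rng.normal(0.0, 0.03)
        scores = base + offset + rng.normal(0.0, 0.06, size=n)
        data[f"predictor_{p + 1}"] = np.clip(scores, 0.0, 1.0)
    return pd.DataFrame(data, index=pd.Index(np.arange(1, n + 1), name="residue"))


def write_fixture_bundle(
    out_dir: str | Path,
    potts: PottsSpec,
    chain_n: int = 60,
    chain_geometry: str = "helix",
    disordered_ranges: list[tuple[int, int]] | None = None,
) -> dict:
    """Write a complete input bundle: MSA + structure + disorder TSV + truth JSON."""
    from .msa_io import write_alignment

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    aln, truth = sample_potts_msa(potts)
    write_alignment(aln, out / "msa.fasta", "fasta")
    coords, seq = make_toy_chain(chain_n, chain_geometry, seed=potts.seed)
    write_ca_pdb(coords, seq, out / "chain.pdb")
    ranges = disordered_ranges or [(max(1, chain_n // 4), max(2, chain_n // 2))]
    table = make_disorder_fixture(chain_n, ranges, seed=potts.seed)
    table.to_csv(out / "disorder.tsv", sep="\t", float_format="%.6g")
    truth["disordered_ranges"] = [list(r) for r in ranges]
    truth["chain"] = {"n": chain_n, "geometry": chain_geometry}
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
    return truth
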