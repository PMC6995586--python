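"""Structure-space dynamics: variants, Calpha elastic-network modes,
cross-correlated motions, correlation networks, and centrality profiles.

The workflow mirrors a standard coarse-grained protein dynamics analysis:

* point/stretch **variants** of a reference sequence (e.g. the metal-site
  substitutions of SOD1) are constructed by validated substitution;
* an **anisotropic elastic network model** (ENM) places identical springs
  between all Calpha pairs within a cutoff (default 10 A, spring constant
  1.0) and diagonalizes the 3n x 3n Hessian; the six zero-frequency
  rigid-body modes are excluded from all statistics;
* the **cross-correlation matrix** ``c_ij`` is the normalized covariance
  of residue displacement fluctuations from the non-rigid modes with
  equal-temperature weighting ``1/lambda_k`` (the Hessian pseudo-inverse);
* the **correlation network** links residues that are both in spatial
  contact and dynamically correlated (``|c_ij| >= cutoff``, default 0.35),
  with edge distance ``-log|c_ij|``; communities (Girvan-Newman) and node
  betweenness on that metric summarize the protein's dynamic architecture.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import scipy.linalg

from .graphs import CommunityPartition, community_graph, girvan_newman
from .pair_selection import ContactMap

DEFAULT_ENM_CUTOFF = 10.0
DEFAULT_SPRING_CONSTANT = 1.0
DEFAULT_CORRELATION_CUTOFF = 0.35

_MUTATION_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")


@dataclass
class VariantSpec:
    """A named set of point substitutions (wild-type, 1-based position, mutant)."""

    name: str
    mutations: list[tuple[str, int, str]] = field(default_factory=list)

    @classmethod
    def parse(cls, name: str, mutation_string: str) -> "VariantSpec":
        """Parse e.g. ``"N65S, L67P"`` (empty string = wild type)."""
        muts = []
        for token in filter(None, (t.strip() for t in mutation_string.split(","))):
            m = _MUTATION_RE.match(token)
            if not m:
                raise ValueError(f"cannot parse mutation {token!r}")
            muts.append((m.group(1), int(m.group(2)), m.group(3)))
        return cls(name=name, mutations=muts)


def apply_variant(sequence: str, spec: VariantSpec) -> str:
    """Apply a variant's substitutions to a 1-based reference sequence.

    Hard error if any stated wild-type residue does not match the
    sequence; the length never changes.
    """
    seq = list(sequence)
    for wt, pos, mut in spec.mutations:
        if not 1 <= pos <= len(seq):
            raise ValueError(f"{spec.name}: position {pos} outside sequence")
        if seq[pos - 1] != wt:
            raise ValueError(
                f"{spec.name}: expected {wt} at position {pos}, found {seq[pos - 1]}"
            )
        seq[pos - 1] = mut
    return "".join(seq)


@dataclass
class NormalModeSet:
    """ENM eigenpairs: ascending eigenvalues, orthonormal 3n-vectors (columns)."""

    eigenvalues: np.ndarray  # (3n,)
    eigenvectors: np.ndarray  # (3n, 3n)
    cutoff: float
    n_zero_modes: int

    @property
    def n_particles(self) -> int:
        return self.eigenvalues.shape[0] // 3


def enm_hessian(coords: np.ndarray, cutoff: float, spring_constant: float) -> np.ndarray:
    """Anisotropic-network Hessian of the harmonic pair potential.

    For each pair within the cutoff the off-diagonal 3x3 block is
    ``-k * (d d^T) / |d|^2`` (d = equilibrium separation vector); diagonal
    blocks make rows sum to zero.
    """
    n = coords.shape[0]
    H = np.zeros((3 * n, 3 * n))
    for i in range(n):
        for j in range(i + 1, n):
            d = coords[j] - coords[i]
            r2 = float(d @ d)
            if r2 == 0.0 or np.sqrt(r2) > cutoff:
                continue
            block = -spring_constant * np.outer(d, d) / r2
            H[3 * i : 3 * i + 3, 3 * j : 3 * j + 3] += block
            H[3 * j : 3 * j + 3, 3 * i : 3 * i + 3] += block
            H[3 * i : 3 * i + 3, 3 * i : 3 * i + 3] -= block
            H[3 * j : 3 * j + 3, 3 * j : 3 * j + 3] -= block
    return H


def _connected(coords: np.ndarray, cutoff: float) -> bool:
    n = coords.shape[0]
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=2))
    adj = (dist <= cutoff) & ~np.eye(n, dtype=bool)
    g = nx.from_numpy_array(adj)
    return nx.is_connected(g)


def enm_modes(
    coords: np.ndarray,
    cutoff: float = DEFAULT_ENM_CUTOFF,
    spring_constant: float = DEFAULT_SPRING_CONSTANT,
) -> NormalModeSet:
    """Normal modes of the Calpha elastic network.

    The spring network must be connected at the cutoff (hard error
    suggesting a larger cutoff otherwise).  A connected non-collinear
    structure has exactly 6 near-zero (rigid-body) eigenvalues; exactly
    collinear ones have 5.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] < 2:
        raise ValueError("coords must be an (n, 3) array with n >= 2")
    if not _connected(coords, cutoff):
        raise ValueError(
            f"elastic network is disconnected at cutoff {cutoff} A; "
            "increase the cutoff"
        )
    H = enm_hessian(coords, cutoff, spring_constant)
    evals, evecs = scipy.linalg.eigh(H)
    evals = np.where(np.abs(evals) < 1e-12, 0.0, evals)
    tol = 1e-8 * max(evals.max(), 1.0)
    n_zero = int(np.sum(np.abs(evals) < tol))
    return NormalModeSet(
        eigenvalues=evals, eigenvectors=evecs, cutoff=cutoff, n_zero_modes=n_zero
    )


@dataclass
class CrossCorrelation:
    c: np.ndarray  # (n, n) in [-1, 1], unit diagonal

    @property
    def n_residues(self) -> int:
        return self.c.shape[0]


def cross_correlation(modes: NormalModeSet) -> CrossCorrelation:
    """Normalized residue fluctuation covariance from the non-rigid modes.

    ``<dr_i . dr_j>`` is the 3x3-block trace of the Hessian pseudo-inverse
    ``sum_k (1/lambda_k) v_k v_k^T`` over non-rigid modes (equal-temperature
    weighting); ``c_ij`` normalizes by the residue fluctuation amplitudes.
    """
    n = modes.n_particles
    nz = modes.n_zero_modes
    if nz >= len(modes.eigenvalues):
        raise ValueError("all modes are rigid-body modes; no internal dynamics")
    lam = modes.eigenvalues[nz:]
    vec = modes.eigenvectors[:, nz:]
    cov3 = (vec / lam) @ vec.T  # (3n, 3n) pseudo-inverse of the Hessian
    blocks = cov3.reshape(n, 3, n, 3)
    cij = np.einsum("idjd->ij", blocks)
    amp = np.sqrt(np.diag(cij))
    c = cij / np.outer(amp, amp)
    np.fill_diagonal(c, 1.0)
    return CrossCorrelation(c=np.clip(0.5 * (c + c.T), -1.0, 1.0))


def correlation_network(
    corr: CrossCorrelation,
    cmap: ContactMap,
    correlation_cutoff: float = DEFAULT_CORRELATION_CUTOFF,
) -> nx.Graph:
    """Graph linking residues in contact with |c_ij| above the cutoff.

    Edge attributes: ``weight = |c_ij|`` (affinity, used for modularity)
    and ``length = -log|c_ij|`` (distance, used for betweenness and
    community detection).  Node labels are residue numbers (the contact
    map's numbering when available, else 1..n).
    """
    n = corr.n_residues
    if cmap.contacts.shape[0] != n:
        raise ValueError("correlation matrix and contact map sizes disagree")
    labels = (
        [int(r) for r in cmap.res_ids]
        if cmap.res_ids is not None
        else list(range(1, n + 1))
    )
    g = nx.Graph(kind="structure-correlation")
    g.add_nodes_from(labels)
    for i in range(n):
        for j in range(i + 1, n):
            a = abs(float(corr.c[i, j]))
            if cmap.contacts[i, j] and a >= correlation_cutoff:
                g.add_edge(labels[i], labels[j], weight=a, length=-np.log(a))
    return g


def community_clusters(g: nx.Graph) -> tuple[CommunityPartition, nx.Graph]:
    """Girvan-Newman communities plus the coarse-grained community graph."""
    part = girvan_newman(g)
    return part, community_graph(g, part)


@dataclass
class CentralityProfile:
    """Normalized node betweenness per residue."""

    values: dict[int, float]

    def as_array(self, residues: list[int]) -> np.ndarray:
        return np.array([self.values.get(r, 0.0) for r in residues])


def betweenness_profile(g: nx.Graph) -> CentralityProfile:
    """Node betweenness with edge length as the path metric, normalized
    by (n-1)(n-2)/2; all zeros for graphs with fewer than 3 nodes."""
    if g.number_of_nodes() < 3:
        return CentralityProfile(values={n: 0.0 for n in g.nodes()})
    bc = nx.betweenness_centrality(g, weight="length", normalized=True)
    return CentralityProfile(values={n: float(v) for n, v in bc.items()})


def write_centrality(profile: CentralityProfile, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("residue\tbetweenness\n")
        for r in sorted(profile.values):
            fh.write(f"{r}\t{profile.values[r]:.6g}\n")


def write_matrix(m: np.ndarray, path: str | Path) -> None:
    np.savetxt(path, m, fmt="%.6g", delimiter="\t")


def plot_centrality(profiles: dict[str, CentralityProfile], path: str | Path) -> None:
    """Centrality-vs-residue line plot, one line per variant."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4))
    for name, prof in profiles.items():
        residues = sorted(prof.values)
        ax.plot(residues, prof.as_array(residues), label=name, lw=1)
    ax.set_xlabel("residue")
    ax.set_ylabel("betweenness centrality")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
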