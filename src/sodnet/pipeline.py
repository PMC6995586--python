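"""End-to-end orchestration of the sequence and structure tracks.

The sequence track goes alignment -> reweighting -> MI/DI -> separation
filter and top-pair selection -> contact flags -> coupling graphs ->
communities + maximal cliques -> disorder annotation.  The structure
track goes, per variant structure, ENM modes -> cross-correlation ->
correlation network -> communities -> betweenness profile, then compares
variants against the wild type.  Both emit TSV/GraphML artifacts and a
versioned machine-readable summary.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import coupling, disorder, graphs, msa_io, pair_selection, structure

logger = logging.getLogger(__name__)

REPORT_VERSION = 1


@dataclass
class RunConfig:
    """Parameters and input locations for a full run.

    Defaults mirror the per-module conventions: identity threshold 0.8,
    pseudocount lambda = M_eff (``lam = None``), minimum sequence
    separation 5, contact cutoff 8 A, ENM cutoff 10 A, correlation
    cutoff 0.35.
    """

    msa_path: str | None = None
    structure_paths: dict[str, str] = field(default_factory=dict)  # variant -> PDB
    disorder_path: str | None = None
    ref_id: str | None = None
    ref_offset: int = 1
    identity_threshold: float = coupling.DEFAULT_IDENTITY_THRESHOLD
    lam: float | None = None
    min_separation: int = pair_selection.DEFAULT_MIN_SEPARATION
    top_n: int = 100
    contact_cutoff: float = pair_selection.DEFAULT_CONTACT_CUTOFF
    enm_cutoff: float = structure.DEFAULT_ENM_CUTOFF
    correlation_cutoff: float = structure.DEFAULT_CORRELATION_CUTOFF
    seed: int = 0
    out_dir: str = "results/run"

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as err:
                raise StageError(f"stage '{name}' failed: {err}") from err
            logger.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
            return out
        return wrapper
    return deco


def run_sequence_track(cfg: RunConfig) -> dict:
    """Run the coevolution track; returns (and writes) the summary report."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    aln = _stage("read_alignment")(msa_io.read_alignment)(cfg.msa_path, "fasta")
    if cfg.ref_id is not None:
        aln = _stage("map_columns")(msa_io.map_columns)(aln, cfg.ref_id, cfg.ref_offset)
    scores = _stage("couplings")(coupling.compute_couplings)(
        aln, identity_threshold=cfg.identity_threshold, lam=cfg.lam
    )
    coupling.write_pair_scores(scores, aln, out / "pair_scores.tsv")

    cmap = None
    if cfg.structure_paths:
        ref_struct = next(iter(cfg.structure_paths.values()))
        struct = _stage("read_structure")(pair_selection.read_structure)(ref_struct)
        cmap = pair_selection.contact_map(struct, cfg.contact_cutoff)

    summary: dict = {
        "report_version": REPORT_VERSION,
        "parameters": {
            "identity_threshold": cfg.identity_threshold,
            "lambda": scores.params["lambda"],
            "m_eff": scores.params["m_eff"],
            "min_separation": cfg.min_separation,
            "top_n": cfg.top_n,
            "contact_cutoff": cfg.contact_cutoff,
            "seed": cfg.seed,
        },
        "tracks": {},
    }
    for kind, matrix in (("mi", scores.mi), ("di", scores.di)):
        sel = _stage(f"select_{kind}")(pair_selection.select_top_pairs)(
            matrix, cfg.top_n, cfg.min_separation, aln.column_map or None
        )
        if cmap is not None:
            sel = pair_selection.flag_contacts(sel, cmap)
        pair_selection.write_selection(sel, out / f"top_{kind}_pairs.tsv")
        g = _stage(f"graph_{kind}")(graphs.build_graph)(sel, kind=f"G_{kind.upper()}")
        part = _stage(f"communities_{kind}")(graphs.girvan_newman)(g)
        cliques = graphs.maximal_cliques(g)
        graphs.write_graphml(g, out / f"graph_{kind}.graphml")
        graphs.write_edge_list(g, out / f"graph_{kind}.tsv", part)
        track = {
            "n_pairs": len(sel),
            "n_contact_pairs": sum(1 for f in sel.in_contact if f)
            if sel.in_contact
            else None,
            "n_distinct_residues": len(sel.residues),
            "n_communities": part.n_communities,
            "modularity": round(part.modularity, 6),
            "max_clique_size": cliques.maximum_size,
            "max_cliques": [sorted(c) for c in cliques.maximum_cliques()],
        }
        if cfg.disorder_path:
            table = disorder.read_predictor_table(cfg.disorder_path)
            profile = _stage("disorder")(disorder.consensus_profile)(table)
            ann = disorder.annotate_pairs(sel, profile)
            disorder.write_profile(profile, out / "disorder_profile.tsv")
            track["disorder"] = {
                "n_pairs_counted": ann.n_pairs_counted,
                "n_both_disordered": ann.n_both_disordered,
                "n_at_least_one_disordered": ann.n_at_least_one_disordered,
                "n_any_above_0.3": ann.n_any_above_03,
            }
        summary["tracks"][kind] = track

    with open(out / "sequence_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary


def pair_cluster_location(
    part: graphs.CommunityPartition, coarse, pairs: list[tuple[int, int]]
) -> dict[str, str]:
    """Label residue pairs as same-cluster / connected-cluster / distant.

    Pairs with a residue outside the partition are labelled unknown.
    """
    out = {}
    for i, j in pairs:
        key = f"{i}-{j}"
        if i not in part.assignment or j not in part.assignment:
            out[key] = "unknown"
            continue
        ci, cj = part.assignment[i], part.assignment[j]
        if ci == cj:
            out[key] = "same-cluster"
        elif coarse.has_edge(ci, cj):
            out[key] = "connected-cluster"
        else:
            out[key] = "distant"
    return out


def run_structure_track(cfg: RunConfig, coupled_pairs: list[tuple[int, int]] | None = None) -> dict:
    """Run the dynamics track on every variant structure; compare to WT.

    ``coupled_pairs`` (reference numbering) are located within each
    variant's community partition (same vs connected cluster).
    """
    if not cfg.structure_paths:
        raise StageError("stage 'inputs' failed: no structure paths configured")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    summary: dict = {
        "report_version": REPORT_VERSION,
        "parameters": {
            "enm_cutoff": cfg.enm_cutoff,
            "contact_cutoff": cfg.contact_cutoff,
            "correlation_cutoff": cfg.correlation_cutoff,
            "seed": cfg.seed,
        },
        "variants": {},
    }
    profiles: dict[str, structure.CentralityProfile] = {}
    for name, path in cfg.structure_paths.items():
        struct = _stage(f"read_structure[{name}]")(pair_selection.read_structure)(path)
        modes = _stage(f"enm[{name}]")(structure.enm_modes)(
            struct.ca, cfg.enm_cutoff
        )
        corr = _stage(f"cross_correlation[{name}]")(structure.cross_correlation)(modes)
        cmap = pair_selection.contact_map(struct, cfg.contact_cutoff)
        net = _stage(f"correlation_network[{name}]")(structure.correlation_network)(
            corr, cmap, cfg.correlation_cutoff
        )
        part, coarse = _stage(f"communities[{name}]")(structure.community_clusters)(net)
        prof = structure.betweenness_profile(net)
        profiles[name] = prof
        structure.write_matrix(corr.c, out / f"correlation_{name}.tsv")
        structure.write_centrality(prof, out / f"centrality_{name}.tsv")
        graphs.write_graphml(net, out / f"network_{name}.graphml")
        entry = {
            "n_residues": struct.n_residues,
            "n_zero_modes": modes.n_zero_modes,
            "n_network_edges": net.number_of_edges(),
            "n_communities": part.n_communities,
            "modularity": round(part.modularity, 6),
        }
        if coupled_pairs:
            entry["pair_locations"] = pair_cluster_location(part, coarse, coupled_pairs)
        summary["variants"][name] = entry

    wt_name = next(iter(cfg.structure_paths))
    comparison = []
    wt_prof = profiles[wt_name]
    for name, prof in profiles.items():
        shared = sorted(set(prof.values) & set(wt_prof.values))
        delta = float(
            np.mean([prof.values[r] - wt_prof.values[r] for r in shared])
        ) if shared else 0.0
        comparison.append(
            {
                "variant": name,
                "n_communities": summary["variants"][name]["n_communities"],
                "mean_centrality_delta_vs_wt": round(delta, 6),
            }
        )
    summary["comparison"] = comparison
    structure.plot_centrality(profiles, out / "centrality_profiles.png")
    with open(out / "structure_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
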