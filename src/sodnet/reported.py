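"""Published SOD1 reference data shipped with the package.

Small literature-derived tables for human Cu/Zn superoxide dismutase
(UniProt P00441, mature 153-residue chain, Pfam family PF00080):

* the top-ranked MI and DI coupled residue pairs with their mean
  predicted disorder scores (PDS +/- sd over six disorder predictors),
  as published for the ~4000-sequence family alignment;
* the metal-site and ALS-loop variant definitions (point and stretch
  substitutions);
* the wild-type mature sequence.

These serve as worked-example inputs: pair lists feed the graph/clique
and disorder-annotation machinery without re-running the family-scale
coupling inference.  The ``highlighted`` column carries the published
emphasis flags verbatim.
"""

from __future__ import annotations

import importlib.resources as resources
import warnings

import numpy as np
import pandas as pd

from .disorder import DisorderProfile, classify
from .pair_selection import PairSelection
from .structure import VariantSpec


def _data_path(name: str):
    return resources.files("sodnet").joinpath("data", name)


def sod1_sequence() -> str:
    """Mature human SOD1 sequence (153 residues, 1-based numbering)."""
    return _data_path("sod1_sequence.txt").read_text().strip()


def sod1_variants() -> dict[str, VariantSpec]:
    """Named variant specs (WT = empty mutation list).

    Note: the literature is internally inconsistent about whether H120F
    removes the Cu or the Zn site (and H71F the other); the tabulated
    assignment used here is Cu-SOD1 = H120F, Zn-SOD1 = H71F.
    """
    df = pd.read_csv(_data_path("sod1_variants.tsv"), sep="\t", keep_default_na=False)
    return {
        row["name"]: VariantSpec.parse(row["name"], row["mutations"])
        for _, row in df.iterrows()
    }


def top_mi_pairs() -> pd.DataFrame:
    return pd.read_csv(_data_path("sod1_top_mi_pairs.tsv"), sep="\t")


def top_di_pairs() -> pd.DataFrame:
    return pd.read_csv(_data_path("sod1_top_di_pairs.tsv"), sep="\t")


def pairs_as_selection(df: pd.DataFrame, score_col: str) -> PairSelection:
    """Published pair table -> :class:`PairSelection` (already filtered/ranked)."""
    pairs = sorted(
        ((int(r["i"]), int(r["j"]), float(r[score_col])) for _, r in df.iterrows()),
        key=lambda p: (-p[2], p[0], p[1]),
    )
    return PairSelection(pairs=pairs, min_separation=5, top_n=len(pairs))


def profile_from_pairs(df: pd.DataFrame) -> DisorderProfile:
    """Per-residue disorder profile reconstructed from the printed pair PDS.

    Residues repeated across rows must agree on their printed mean; a
    disagreement (rounding artefact) would be averaged with a warning.
    """
    means: dict[int, list[float]] = {}
    sds: dict[int, float] = {}
    for _, row in df.iterrows():
        for side in ("i", "j"):
            r = int(row[side])
            means.setdefault(r, []).append(float(row[f"pds_{side}"]))
            sds[r] = float(row[f"sd_{side}"])
    residues = sorted(means)
    mean_arr = []
    for r in residues:
        vals = means[r]
        if max(vals) - min(vals) > 1e-9:
            warnings.warn(f"residue {r} printed with inconsistent PDS values {vals}")
        mean_arr.append(float(np.mean(vals)))
    mean_arr = np.array(mean_arr)
    return DisorderProfile(
        residues=np.array(residues),
        mean_pds=mean_arr,
        sd=np.array([sds[r] for r in residues]),
        classes=[classify(m) for m in mean_arr],
        per_predictor=None,
    )
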