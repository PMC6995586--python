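"""Consensus intrinsic-disorder profiles and annotation of coupled pairs.

Per-residue disorder propensities from several external predictors (e.g.
the PONDR family and IUPred variants) are averaged into a mean predicted
disorder score (PDS) with a standard deviation across predictors.  The
classification follows the common convention: mean PDS > 0.5 =>
*disordered*; 0.2 <= mean PDS <= 0.5 => *flexible*; below 0.2 =>
*ordered* (boundaries 0.2 and 0.5 are inclusive on the flexible side).

Input format: a TSV with one row per residue, a ``residue`` column and
one column per predictor.  Missing scores (empty / NaN) are simply left
out of that residue's mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .pair_selection import PairSelection

ORDERED = "ordered"
FLEXIBLE = "flexible"
DISORDERED = "disordered"

DISORDER_THRESHOLD = 0.5
FLEXIBLE_THRESHOLD = 0.2


def classify(mean_pds: float) -> str:
    """Three-way class of a mean predicted disorder score in [0, 1]."""
    if not 0.0 <= mean_pds <= 1.0:
        raise ValueError(f"mean PDS {mean_pds} outside [0, 1]")
    if mean_pds > DISORDER_THRESHOLD:
        return DISORDERED
    if mean_pds >= FLEXIBLE_THRESHOLD:
        return FLEXIBLE
    return ORDERED


@dataclass
class DisorderProfile:
    """Mean PDS, spread, and class per residue; raw per-predictor scores kept."""

    residues: np.ndarray
    mean_pds: np.ndarray
    sd: np.ndarray
    classes: list[str]
    per_predictor: pd.DataFrame = field(repr=False, default=None)

    def __post_init__(self):
        self._index = {int(r): k for k, r in enumerate(self.residues)}

    def __contains__(self, residue: int) -> bool:
        return residue in self._index

    def mean(self, residue: int) -> float:
        return float(self.mean_pds[self._index[residue]])

    def cls(self, residue: int) -> str:
        return self.classes[self._index[residue]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "residue": self.residues,
                "mean_pds": self.mean_pds,
                "sd": self.sd,
                "class": self.classes,
            }
        )


def read_predictor_table(path: str | Path) -> pd.DataFrame:
    """TSV with a ``residue`` column and one column per predictor."""
    df = pd.read_csv(path, sep="\t")
    if "residue" not in df.columns:
        raise ValueError("predictor table must have a 'residue' column")
    return df.set_index("residue")


def consensus_profile(tables: pd.DataFrame | list[pd.DataFrame]) -> DisorderProfile:
    """Average the per-predictor profiles into a consensus PDS profile.

    Accepts a single wide table (one column per predictor) or a list of
    such tables sharing residue numbering; residues missing from every
    predictor are dropped with a warning.  The spread is the standard
    deviation (ddof=0) over the predictors that scored the residue.
    """
    if isinstance(tables, list):
        if not tables:
            raise ValueError("need at least one predictor table")
        wide = pd.concat(tables, axis=1)
    else:
        wide = tables
    if wide.shape[1] == 0:
        raise ValueError("need at least one predictor column")
    values = wide.to_numpy(dtype=float)
    n_scores = np.sum(~np.isnan(values), axis=1)
    covered = n_scores > 0
    if not covered.all():
        missing = wide.index[~covered].tolist()
        warnings.warn(f"residues with no predictor score dropped: {missing}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        means = np.nanmean(values[covered], axis=1)
        sds = np.nanstd(values[covered], axis=1)
    residues = wide.index.to_numpy()[covered].astype(int)
    classes = [classify(m) for m in means]
    return DisorderProfile(
        residues=residues,
        mean_pds=means,
        sd=sds,
        classes=classes,
        per_predictor=wide[covered],
    )


@dataclass
class PairDisorderAnnotation:
    """Per-pair disorder classes plus the summary counts over a selection."""

    pair_classes: list[tuple[str, str] | None]  # None = residue not covered
    n_pairs_counted: int
    n_both_disordered: int
    n_at_least_one_disordered: int
    n_any_above_03: int


def annotate_pairs(sel: PairSelection, profile: DisorderProfile) -> PairDisorderAnnotation:
    """Disorder classes of both members of every selected pair + counts.

    Pairs with a residue missing from the profile are annotated unknown
    and excluded from the counts (with a warning).
    """
    pair_classes: list[tuple[str, str] | None] = []
    n_counted = n_both = n_one = n_above = 0
    n_unknown = 0
    for i, j, _ in sel.pairs:
        if i not in profile or j not in profile:
            pair_classes.append(None)
            n_unknown += 1
            continue
        ci, cj = profile.cls(i), profile.cls(j)
        pair_classes.append((ci, cj))
        n_counted += 1
        if ci == DISORDERED and cj == DISORDERED:
            n_both += 1
        if ci == DISORDERED or cj == DISORDERED:
            n_one += 1
        if profile.mean(i) > 0.3 or profile.mean(j) > 0.3:
            n_above += 1
    if n_unknown:
        warnings.warn(f"{n_unknown} pairs not covered by the disorder profile")
    return PairDisorderAnnotation(
        pair_classes=pair_classes,
        n_pairs_counted=n_counted,
        n_both_disordered=n_both,
        n_at_least_one_disordered=n_one,
        n_any_above_03=n_above,
    )


def write_profile(profile: DisorderProfile, path: str | Path) -> None:
    profile.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")
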