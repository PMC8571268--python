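"""Consensus aggregation-propensity scoring (0–5) from five predictors.

TANGO, WALTZ, FoldAmyloid, Aggrescan and PASTA each assign every residue
of a protein a program-specific aggregation potential. Each program's
output is binarized by a published threshold rule; the consensus score of
a residue is the number of programs (0–5) that flag it. Runs of score-5
residues mark aggregation-prone segments; score-0 runs mark segments with
no predicted propensity. The predictor programs themselves are external:
this module consumes their per-residue output tables.

Default threshold rules
-----------------------
========== ========= ========== ==========
predictor  direction threshold  min_run
========== ========= ========== ==========
tango       above      0.0        1
waltz       above      0.0        1
foldamyloid above      0.062      5
aggrescan   above     -0.02       1
pasta       below     -2.8        1
========== ========= ========== ==========

All inequalities are strict. FoldAmyloid only flags residues inside runs
of at least five consecutive above-threshold positions (the whole run is
flagged).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PREDICTORS",
    "PredictorRule",
    "DEFAULT_RULES",
    "ConsensusProfile",
    "load_predictions",
    "binarize",
    "consensus",
    "consensus_from_table",
    "segments_with_score",
]

PREDICTORS = ("tango", "waltz", "foldamyloid", "aggrescan", "pasta")


@dataclass(frozen=True)
class PredictorRule:
    """Binarization rule for one predictor's per-residue values."""

    predictor: str
    direction: str  # "above" | "below"
    threshold: float
    min_run: int = 1

    def __post_init__(self) -> None:
        if self.direction not in ("above", "below"):
            raise ValueError(f"direction must be 'above' or 'below', got {self.direction!r}")
        if self.min_run < 1:
            raise ValueError("min_run must be >= 1")


DEFAULT_RULES: dict[str, PredictorRule] = {
    "tango": PredictorRule("tango", "above", 0.0),
    "waltz": PredictorRule("waltz", "above", 0.0),
    "foldamyloid": PredictorRule("foldamyloid", "above", 0.062, min_run=5),
    "aggrescan": PredictorRule("aggrescan", "above", -0.02),
    "pasta": PredictorRule("pasta", "below", -2.8),
}


@dataclass
class ConsensusProfile:
    """Per-residue consensus scores for one protein (1-based residues)."""

    protein_id: str
    scores: np.ndarray  # int, length = protein length
    predictors: tuple[str, ...]

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=int)
        if np.any(self.scores < 0) or np.any(self.scores > len(self.predictors)):
            raise ValueError(
                f"scores must lie in [0, {len(self.predictors)}] for {len(self.predictors)} predictors"
            )

    def __len__(self) -> int:
        return len(self.scores)


def load_predictions(path) -> pd.DataFrame:
    """Read and validate a normalized predictions TSV.

    Expected columns: ``protein_id, predictor, residue_index, value``.
    For each (protein, predictor) the residue indices must form a
    contiguous 1..N block with no duplicates.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"protein_id", "predictor", "residue_index", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"predictions table missing columns: {sorted(missing)}")
    unknown = set(df["predictor"]) - set(PREDICTORS)
    if unknown:
        raise ValueError(f"unknown predictor id(s): {sorted(unknown)}")
    for (prot, pred), grp in df.groupby(["protein_id", "predictor"]):
        idx = np.sort(np.asarray(grp["residue_index"], dtype=int))
        expected = np.arange(1, len(idx) + 1)
        if not np.array_equal(idx, expected):
            gaps = sorted(set(expected) - set(idx))
            raise ValueError(
                f"({prot}, {pred}): residue indices not a contiguous 1..{len(idx)} block; "
                f"missing {gaps[:10]}"
            )
    return df


def binarize(values, rule: PredictorRule) -> np.ndarray:
    """Flag residues whose value lies strictly on the rule's side of the threshold.

    When ``min_run > 1``, flags survive only inside maximal runs of at
    least ``min_run`` consecutive flagged residues; shorter runs reset
    to 0 (run filtering never adds flags).
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1:
        raise ValueError("values must be a 1-D residue-ordered vector")
    if rule.direction == "above":
        flags = (v > rule.threshold).astype(int)
    else:
        flags = (v < rule.threshold).astype(int)
    if rule.min_run > 1 and flags.any():
        filtered = np.zeros_like(flags)
        for start, end in _runs(flags == 1):
            if end - start + 1 >= rule.min_run:
                filtered[start : end + 1] = 1
        flags = filtered
    return flags


def consensus(flags_by_predictor: dict[str, np.ndarray], protein_id: str = "") -> ConsensusProfile:
    """Sum per-predictor flag vectors into a 0–k consensus profile."""
    if not flags_by_predictor:
        raise ValueError("need at least one predictor's flags")
    lengths = {name: len(np.asarray(f)) for name, f in flags_by_predictor.items()}
    if len(set(lengths.values())) != 1:
        raise ValueError(f"flag vectors have mismatched lengths: {lengths}")
    names = tuple(sorted(flags_by_predictor))
    total = np.sum([np.asarray(flags_by_predictor[n], dtype=int) for n in names], axis=0)
    return ConsensusProfile(protein_id=protein_id, scores=total, predictors=names)


def consensus_from_table(
    df: pd.DataFrame,
    protein_id: str,
    rules: dict[str, PredictorRule] | None = None,
    waltz_mode: str = "per_residue",
) -> ConsensusProfile:
    """Binarize every predictor's values for one protein and take the consensus.

    ``waltz_mode="whole_sequence"`` implements the alternative reading of
    the WALTZ rule: all residues are flagged iff the summed sequence score
    exceeds the threshold. The default per-residue reading is the only one
    compatible with a residue-resolved score and is used unless asked.
    """
    if waltz_mode not in ("per_residue", "whole_sequence"):
        raise ValueError(f"unknown waltz_mode {waltz_mode!r}")
    rules = dict(DEFAULT_RULES if rules is None else rules)
    sub = df[df["protein_id"] == protein_id]
    if sub.empty:
        raise ValueError(f"no predictions for protein {protein_id!r}")
    flags: dict[str, np.ndarray] = {}
    for pred, grp in sub.groupby("predictor"):
        if pred not in rules:
            raise ValueError(f"no rule supplied for predictor {pred!r}")
        grp = grp.sort_values("residue_index")
        values = np.asarray(grp["value"], dtype=float)
        rule = rules[pred]
        if pred == "waltz" and waltz_mode == "whole_sequence":
            total = float(values.sum())
            hit = total > rule.threshold if rule.direction == "above" else total < rule.threshold
            flags[pred] = np.full(len(values), int(hit))
        else:
            flags[pred] = binarize(values, rule)
    return consensus(flags, protein_id=protein_id)


def _runs(mask: np.ndarray):
    """Yield (start, end) index pairs (0-based inclusive) of maximal True runs."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(padded[1:] != padded[:-1])
    for start, stop in zip(edges[::2], edges[1::2]):
        yield int(start), int(stop) - 1


def segments_with_score(
    profile: ConsensusProfile, target_score: int, min_len: int = 1
) -> list[tuple[int, int]]:
    """Maximal runs of residues at a given consensus score, 1-based inclusive.

    For the top score the run condition is ``score >= target`` (equivalent
    to equality when the target equals the number of predictors); for any
    other target it is exact equality. Runs shorter than ``min_len`` are
    dropped.
    """
    k = len(profile.predictors)
    if not 0 <= target_score <= k:
        raise ValueError(f"target score must be in [0, {k}], got {target_score}")
    if target_score == k:
        mask = profile.scores >= target_score
    else:
        mask = profile.scores == target_score
    return [
        (start + 1, end + 1)
        for start, end in _runs(mask)
        if end - start + 1 >= min_len
    ]
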