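"""Ordered-core annotations, mutation mapping, and sequence utilities.

Cryo-EM maps of ex vivo fibrils resolve only part of the protein chain:
the ordered fibril core (one or more residue ranges) versus structurally
disordered flanks and loops. This module represents those annotations,
computes the fraction of residues in the ordered core and how many somatic
mutations fall inside it, aggregates the statistics across fibril
structures, and provides the Gill–von Hippel molar extinction coefficient
used for protein-concentration measurements.

Residue coordinates are 1-based inclusive throughout, matching the
"Ser9 to Thr52" convention of structural annotations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CoreAnnotation",
    "SegmentStats",
    "FOR001_ANNOTATION",
    "ordered_fraction",
    "mutations_in_ordered",
    "aggregate_stats",
    "extinction_coefficient",
    "GILL_VON_HIPPEL_COEFFICIENTS",
]


@dataclass
class CoreAnnotation:
    """Ordered-core ranges and mutation positions for one fibril protein."""

    protein_id: str
    seq_length: int
    ordered_ranges: list[tuple[int, int]] = field(default_factory=list)
    mutation_positions: frozenset[int] = field(default_factory=frozenset)
    sequence: str | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ordered_ranges = [(int(a), int(b)) for a, b in self.ordered_ranges]
        self.mutation_positions = frozenset(int(p) for p in self.mutation_positions)
        self.validate()

    def validate(self) -> None:
        if self.seq_length < 1:
            raise ValueError(f"{self.protein_id}: seq_length must be >= 1")
        prev_end = 0
        for start, end in sorted(self.ordered_ranges):
            if not (1 <= start <= end <= self.seq_length):
                raise ValueError(
                    f"{self.protein_id}: range [{start}, {end}] outside 1..{self.seq_length}"
                )
            if start <= prev_end:
                raise ValueError(
                    f"{self.protein_id}: range [{start}, {end}] overlaps a previous range"
                )
            prev_end = end
        for pos in self.mutation_positions:
            if not 1 <= pos <= self.seq_length:
                raise ValueError(
                    f"{self.protein_id}: mutation position {pos} outside 1..{self.seq_length}"
                )
        if self.sequence is not None and len(self.sequence) != self.seq_length:
            raise ValueError(
                f"{self.protein_id}: sequence length {len(self.sequence)} != seq_length {self.seq_length}"
            )


#: The FOR001 lambda-1 fibril protein (Gln1–Ser118): ordered core
#: Ser9–Thr52 and Ser68–Thr108; six mutational changes vs the germ line
#: (Lys17Asn, Asn52Thr, Asn53Asp, Gly82Ala, Asp93Glu, Xaa99Gly).
FOR001_ANNOTATION = CoreAnnotation(
    protein_id="FOR001",
    seq_length=118,
    ordered_ranges=[(9, 52), (68, 108)],
    mutation_positions=frozenset({17, 52, 53, 82, 93, 99}),
    metadata={
        "ptms": {
            "disulfide": (22, 89),
            "n_glycosylation": 17,
            "pyroglutamate": 1,
        }
    },
)


def ordered_fraction(annotation: CoreAnnotation) -> float:
    """Fraction of residues inside the ordered fibril core."""
    annotation.validate()
    total = sum(end - start + 1 for start, end in annotation.ordered_ranges)
    return total / annotation.seq_length


def mutations_in_ordered(annotation: CoreAnnotation) -> tuple[int, float]:
    """Count and fraction of mutation positions inside any ordered range."""
    annotation.validate()
    if not annotation.mutation_positions:
        raise ValueError(
            f"{annotation.protein_id}: no mutation positions — fraction undefined"
        )
    count = sum(
        any(start <= pos <= end for start, end in annotation.ordered_ranges)
        for pos in annotation.mutation_positions
    )
    return count, count / len(annotation.mutation_positions)


@dataclass(frozen=True)
class SegmentStats:
    """Per-protein and aggregate ordered-core / mutation statistics.

    Aggregate dispersion is the sample standard deviation (n-1); it is
    None when only one annotation is supplied.
    """

    per_protein: list[dict]
    mean_ordered_fraction: float
    sd_ordered_fraction: float | None
    mean_mut_ordered_fraction: float
    sd_mut_ordered_fraction: float | None

    def as_percent(self) -> dict:
        """Display form: percentages rounded to whole numbers."""
        rounded = lambda x: None if x is None else round(100.0 * x)
        return {
            "ordered_residues_pct": f"{rounded(self.mean_ordered_fraction)}"
            + (f" +/- {rounded(self.sd_ordered_fraction)}" if self.sd_ordered_fraction is not None else ""),
            "mutations_in_ordered_pct": f"{rounded(self.mean_mut_ordered_fraction)}"
            + (
                f" +/- {rounded(self.sd_mut_ordered_fraction)}"
                if self.sd_mut_ordered_fraction is not None
                else ""
            ),
        }


def aggregate_stats(annotations: list[CoreAnnotation]) -> SegmentStats:
    """Mean and sample SD of the ordered-core statistics across proteins."""
    if not annotations:
        raise ValueError("need at least one annotation")
    per_protein = []
    of, mf = [], []
    for ann in annotations:
        frac = ordered_fraction(ann)
        n_in, mut_frac = mutations_in_ordered(ann)
        per_protein.append(
            {
                "protein_id": ann.protein_id,
                "ordered_residue_fraction": frac,
                "n_mut_ordered": n_in,
                "n_mut_total": len(ann.mutation_positions),
                "mut_ordered_fraction": mut_frac,
            }
        )
        of.append(frac)
        mf.append(mut_frac)
    n = len(annotations)
    sd = (lambda v: float(np.std(v, ddof=1))) if n >= 2 else (lambda v: None)
    return SegmentStats(
        per_protein=per_protein,
        mean_ordered_fraction=float(np.mean(of)),
        sd_ordered_fraction=sd(of),
        mean_mut_ordered_fraction=float(np.mean(mf)),
        sd_mut_ordered_fraction=sd(mf),
    )


#: Gill & von Hippel molar extinction coefficients at 280 nm (M^-1 cm^-1):
#: per tryptophan, per tyrosine, per disulfide bond (cystine).
GILL_VON_HIPPEL_COEFFICIENTS = {"W": 5550.0, "Y": 1340.0, "SS": 150.0}

_STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")


def extinction_coefficient(
    sequence: str,
    n_disulfides: int = 0,
    coefficients: dict[str, float] | None = None,
) -> float:
    """Theoretic molar extinction coefficient at 280 nm (M^-1 cm^-1).

    epsilon = c_W * nTrp + c_Y * nTyr + c_SS * n_disulfides, with the
    Gill–von Hippel coefficient set by default.
    """
    if n_disulfides < 0:
        raise ValueError("n_disulfides must be >= 0")
    coeff = GILL_VON_HIPPEL_COEFFICIENTS if coefficients is None else coefficients
    seq = sequence.upper()
    unknown = set(seq) - _STANDARD_AA
    if unknown:
        raise ValueError(f"unknown residue letter(s): {sorted(unknown)}")
    return (
        coeff["W"] * seq.count("W")
        + coeff["Y"] * seq.count("Y")
        + coeff["SS"] * n_disulfides
    )
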