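"""Escape-behavior contingency statistics and in-silico restriction digests.

Count tables of escape-response classes (normal / mild / severe) per
injection condition are summarized as largest-remainder integer percentages
(the only rounding scheme that keeps each row summing to 100) and compared
pairwise with per-category 2x2 Pearson chi-square tests without continuity
correction.  A small helper performs an in-silico restriction digest for
genotyping (default site TG^CA).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EscapeTable",
    "DigestResult",
    "load_table1",
    "class_percentages",
    "largest_remainder",
    "pairwise_chi_square",
    "full_table_chi_square",
    "significance_stars",
    "insilico_digest",
    "reverse_complement",
    "read_fasta_sequence",
]

CATEGORIES = ("normal", "mild", "severe")


@dataclass
class EscapeTable:
    """Condition x {normal, mild, severe} counts."""

    conditions: list[str]
    counts: np.ndarray  # shape (n_conditions, 3), non-negative integers
    categories: tuple[str, ...] = CATEGORIES

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.ndim != 2 or self.counts.shape != (
            len(self.conditions),
            len(self.categories),
        ):
            raise ValueError("counts shape must be (n_conditions, n_categories)")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @classmethod
    def from_csv(cls, path: str | Path) -> "EscapeTable":
        df = pd.read_csv(path)
        missing = [c for c in ("condition", *CATEGORIES) if c not in df.columns]
        if missing:
            raise ValueError(f"count table misses columns {missing}")
        return cls(
            conditions=df["condition"].astype(str).tolist(),
            counts=df[list(CATEGORIES)].to_numpy(),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=list(self.categories))
        df.insert(0, "condition", self.conditions)
        df["total"] = self.totals
        return df


def load_table1() -> EscapeTable:
    """Packaged fixture of the published zebrafish escape-behavior counts."""
    ref = importlib.resources.files("glyrfluct").joinpath("data/table1.csv")
    with importlib.resources.as_file(ref) as path:
        return EscapeTable.from_csv(path)


# ----------------------------------------------------------------------
# percentages


def largest_remainder(counts: Sequence[int], total: int | None = None) -> np.ndarray:
    """Integer percentages by Hamilton (largest-remainder) allocation.

    Floors 100*count/total, then hands the leftover points to the largest
    fractional remainders; ties go to the larger count, then lower index.
    The result always sums to 100.
    """
    counts = np.asarray(counts, dtype=float)
    if total is None:
        total = counts.sum()
    if not total > 0:
        raise ValueError("total must be > 0")
    exact = 100.0 * counts / total
    floors = np.floor(exact).astype(int)
    remainder = exact - floors
    missing = 100 - int(floors.sum())
    order = sorted(
        range(counts.size),
        key=lambda i: (-remainder[i], -counts[i], i),
    )
    out = floors.copy()
    for i in order[:missing]:
        out[i] += 1
    return out


def class_percentages(table: EscapeTable) -> np.ndarray:
    """Per-condition integer percentages, each row summing to 100."""
    if np.any(table.totals == 0):
        raise ValueError("every condition needs a positive total")
    return np.vstack([largest_remainder(row) for row in table.counts])


# ----------------------------------------------------------------------
# chi-square


def significance_stars(p: float, alpha: float = 0.05, strong: float = 0.001) -> str:
    if p < strong:
        return "***"
    if p < alpha:
        return "*"
    return "n.s."


def pairwise_chi_square(
    table: EscapeTable, category: str, collapse: bool = True
) -> pd.DataFrame:
    """Pairwise condition comparisons for one response category.

    With ``collapse=True`` (the four-field reading of the published
    "quadrate test") each pair is reduced to a 2x2 table of category versus
    all other responses and tested by Pearson chi-square with 1 df and no
    continuity correction.  With ``collapse=False`` the full
    category-distribution (2 x n_categories) test is used instead.
    Rows with any expected cell below 1 carry a warning flag.
    """
    if category not in table.categories:
        raise ValueError(f"unknown category {category!r}")
    if len(table.conditions) < 2:
        raise ValueError("need >= 2 conditions")
    k = table.categories.index(category)
    rows = []
    for i in range(len(table.conditions)):
        for j in range(i + 1, len(table.conditions)):
            if collapse:
                obs = np.array(
                    [
                        [table.counts[i, k], table.totals[i] - table.counts[i, k]],
                        [table.counts[j, k], table.totals[j] - table.counts[j, k]],
                    ]
                )
            else:
                obs = table.counts[[i, j]]
            res = stats.chi2_contingency(obs, correction=False)
            expected = res.expected_freq
            rows.append(
                {
                    "condition_a": table.conditions[i],
                    "condition_b": table.conditions[j],
                    "chi2": float(res.statistic),
                    "p": float(res.pvalue),
                    "stars": significance_stars(float(res.pvalue)),
                    "low_expected": bool(np.any(expected < 1.0)),
                }
            )
    return pd.DataFrame(rows)


def full_table_chi_square(table: EscapeTable) -> tuple[float, float, int]:
    """Chi-square over the full condition x category table."""
    res = stats.chi2_contingency(table.counts, correction=False)
    return float(res.statistic), float(res.pvalue), int(res.dof)


# ----------------------------------------------------------------------
# restriction digest


@dataclass
class DigestResult:
    fragment_lengths: list[int]
    cut_positions: list[int]  # 0-based offsets into the sequence
    genotype_call: str  # "cut" | "uncut"
    recognition: str = "TGCA"

    def __post_init__(self) -> None:
        if (self.genotype_call == "uncut") != (len(self.cut_positions) == 0):
            raise ValueError("genotype_call inconsistent with cut positions")


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(sequence: str) -> str:
    return sequence.upper().translate(_COMPLEMENT)[::-1]


def insilico_digest(
    sequence: str, recognition: str = "TGCA", cut_offset: int = 2
) -> DigestResult:
    """Digest a nucleotide sequence at every (possibly overlapping) site.

    The cut is placed ``cut_offset`` bases into each recognition site
    (TG^CA by default); fragments are returned 5'->3' and always sum to the
    input length.
    """
    seq = sequence.strip().upper()
    if not seq:
        raise ValueError("empty sequence")
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValueError(f"non-nucleotide characters in sequence: {sorted(bad)}")
    recognition = recognition.upper()
    if not (0 <= cut_offset <= len(recognition)):
        raise ValueError("cut_offset outside recognition site")

    sites = []
    start = seq.find(recognition)
    while start != -1:
        sites.append(start)
        start = seq.find(recognition, start + 1)  # overlaps allowed

    cuts = sorted({s + cut_offset for s in sites if 0 < s + cut_offset < len(seq)})
    edges = [0, *cuts, len(seq)]
    fragments = [b - a for a, b in zip(edges[:-1], edges[1:])]
    return DigestResult(
        fragment_lengths=fragments,
        cut_positions=cuts,
        genotype_call="cut" if sites else "uncut",
        recognition=recognition,
    )


def read_fasta_sequence(path: str | Path) -> str:
    """First record of a FASTA file, or the whole file if headerless."""
    path = Path(path)
    text = path.read_text()
    if text.lstrip().startswith(">"):
        from Bio import SeqIO

        record = next(SeqIO.parse(path, "fasta"))
        return str(record.seq)
    return "".join(text.split())
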