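"""Methylation variables: single-position and linked (paired-position) C/T statuses.

A *variable* is the per-sample percentage of accepted molecules of a locus
matching a status pattern: ``GSTP1.C3`` is the percentage of molecules
methylated at the third CpG of the GSTP1 locus; ``RNF219.C4.T10`` the
percentage methylated at position 4 AND unmethylated at position 10 of the
same molecule.  For loci with n1, n2, ... CpGs the canonical set contains
sum(n) single-C variables plus C(n,2) x 4 pair-status variables per locus
(statuses CC, CT, TC, TT) -- 1167 for CpG counts (17, 17, 5).
"""

from __future__ import annotations

import itertools
import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .locus_model import LocusSpec
from .read_processing import SampleMethylome

__all__ = [
    "VariableDef",
    "VariableMatrix",
    "enumerate_variables",
    "parse_variable_name",
    "compute_proportions",
    "enumerate_profiles",
    "iter_profiles",
    "correlation_matrix",
    "summarize_boxplot",
]

logger = logging.getLogger(__name__)

_PAIR_STATUSES = (("C", "C"), ("C", "T"), ("T", "C"), ("T", "T"))


@dataclass(frozen=True)
class VariableDef:
    """One variable: locus, one or two CpG indices, and required statuses."""

    locus: str
    positions: tuple[int, ...]
    statuses: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.positions) != len(self.statuses):
            raise ValueError("positions and statuses must align")
        if len(self.positions) == 2 and not self.positions[0] < self.positions[1]:
            raise ValueError("pair positions must satisfy i < j")
        if any(s not in ("C", "T") for s in self.statuses):
            raise ValueError("statuses must be C or T")

    @property
    def kind(self) -> str:
        return "single" if len(self.positions) == 1 else "pair"

    @property
    def name(self) -> str:
        parts = [self.locus] + [
            f"{s}{p}" for p, s in zip(self.positions, self.statuses)
        ]
        return ".".join(parts)


def parse_variable_name(name: str) -> VariableDef:
    """Inverse of ``VariableDef.name`` (e.g. ``"RNF219.C4.T10"``)."""
    locus, *terms = name.split(".")
    positions = tuple(int(t[1:]) for t in terms)
    statuses = tuple(t[0] for t in terms)
    return VariableDef(locus=locus, positions=positions, statuses=statuses)


def _locus_items(loci: Sequence) -> list[tuple[str, int]]:
    items = []
    for i, entry in enumerate(loci):
        if isinstance(entry, LocusSpec):
            items.append((entry.name, entry.n_cpg))
        elif isinstance(entry, int):
            items.append((f"L{i + 1}", entry))
        else:
            name, n = entry
            items.append((name, int(n)))
    return items


def enumerate_variables(loci: Sequence) -> list[VariableDef]:
    """The canonical variable set for the given loci.

    ``loci`` may be LocusSpec objects, (name, n_cpg) tuples, or bare CpG
    counts.  Per locus with n CpGs: n single-C variables (T-singles are
    the complement 100 - C and are not enumerated separately), then for
    every ordered pair i < j the four pair-status variables CC, CT, TC,
    TT.  Order is deterministic: locus input order, singles by position,
    pairs by (i, j) then status.
    """
    defs: list[VariableDef] = []
    for name, n in _locus_items(loci):
        if n <= 0:
            raise ValueError(f"locus {name!r} has no CpG positions")
        for i in range(1, n + 1):
            defs.append(VariableDef(locus=name, positions=(i,), statuses=("C",)))
        for i, j in itertools.combinations(range(1, n + 1), 2):
            for s1, s2 in _PAIR_STATUSES:
                defs.append(VariableDef(locus=name, positions=(i, j), statuses=(s1, s2)))
    return defs


def enumerate_profiles(n_cpg: int) -> int:
    """Number of possible methylation profiles over n CpGs (2**n)."""
    if n_cpg < 0:
        raise ValueError("n_cpg must be non-negative")
    return 2 ** n_cpg


def iter_profiles(n_cpg: int) -> Iterator[str]:
    """Iterate all C/T profile strings of length n (guard: n <= 20)."""
    if n_cpg > 20:
        raise ValueError("refusing to iterate more than 2^20 profiles")
    for bits in itertools.product("CT", repeat=n_cpg):
        yield "".join(bits)


# ---------------------------------------------------------------------------
# Proportion matrix
# ---------------------------------------------------------------------------


@dataclass
class VariableMatrix:
    """Samples x variables table of proportions (percent), with group labels."""

    values: pd.DataFrame            # index: sample ids, columns: variable names
    groups: pd.Series               # sample id -> group label
    defs: list[VariableDef]

    def group_values(self, name: str, group: str) -> np.ndarray:
        """Non-missing values of one variable within one group."""
        samples = self.groups[self.groups == group].index
        v = self.values.loc[samples, name]
        return v.dropna().to_numpy(dtype=float)

    def to_tsv(self, path: str | Path) -> None:
        out = self.values.copy()
        out.insert(0, "group", self.groups.reindex(out.index))
        out.to_csv(path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "VariableMatrix":
        df = pd.read_csv(path, sep="\t", index_col="sample_id")
        df.index.name = None
        groups = df.pop("group")
        defs = [parse_variable_name(c) for c in df.columns]
        return cls(values=df, groups=groups, defs=defs)


def _normalize_methylomes(
    methylomes: Mapping,
) -> dict[tuple[str, str], Counter]:
    out = {}
    for key, value in methylomes.items():
        out[key] = value.profile_counts if isinstance(value, SampleMethylome) else value
    return out


def compute_proportions(
    methylomes: Mapping[tuple[str, str], Counter | SampleMethylome],
    defs: Sequence[VariableDef],
    groups: Mapping[str, str],
) -> VariableMatrix:
    """Per-sample percentages of accepted molecules matching each variable.

    A sample with zero accepted molecules for a locus gets missing (NaN)
    values for that locus's variables and is excluded from downstream
    group tests on them.
    """
    counts = _normalize_methylomes(methylomes)
    samples = sorted({s for s, _ in counts})
    loci = sorted({l for _, l in counts})
    names = [d.name for d in defs]
    values = pd.DataFrame(np.nan, index=samples, columns=names)

    by_locus: dict[str, list[tuple[int, VariableDef]]] = {}
    for col, d in enumerate(defs):
        by_locus.setdefault(d.locus, []).append((col, d))

    row_index = {s: i for i, s in enumerate(samples)}
    for sid in samples:
        for locus in loci:
            counter = counts.get((sid, locus))
            if not counter:
                continue
            total = sum(counter.values())
            if total == 0:
                logger.warning("sample %s has zero accepted molecules for %s", sid, locus)
                continue
            profs = sorted(counter)
            A = np.array([[ch == "C" for ch in p] for p in profs], dtype=float)
            w = np.array([counter[p] for p in profs], dtype=float)
            Aw = A * w[:, None]
            Bw = (1.0 - A) * w[:, None]
            singles = Aw.sum(axis=0)                   # count methylated per position
            cc = Aw.T @ A
            ct = Aw.T @ (1.0 - A)
            tc = Bw.T @ A
            tt = Bw.T @ (1.0 - A)
            joint = {("C", "C"): cc, ("C", "T"): ct, ("T", "C"): tc, ("T", "T"): tt}
            r = row_index[sid]
            for col, d in by_locus.get(locus, []):
                if d.kind == "single":
                    count = singles[d.positions[0] - 1]
                else:
                    i, j = d.positions
                    count = joint[d.statuses][i - 1, j - 1]
                values.iat[r, col] = 100.0 * count / total
    group_series = pd.Series({s: groups[s] for s in samples})
    return VariableMatrix(values=values, groups=group_series, defs=list(defs))


# ---------------------------------------------------------------------------
# Correlation and boxplot summaries
# ---------------------------------------------------------------------------


def correlation_matrix(
    matrix: VariableMatrix,
    group: str,
    variables: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Pairwise Pearson r of log2-transformed variables within one group.

    Zeros are handled with a per-variable pseudocount: half the smallest
    positive value of that variable across *all* samples, added only when
    the variable actually contains zeros (strictly positive variables are
    transformed exactly).  Variables that are constant after the
    transform yield NaN correlations.
    """
    names = list(variables) if variables is not None else list(matrix.values.columns)
    samples = matrix.groups[matrix.groups == group].index
    if len(samples) < 3:
        raise ValueError("need at least 3 samples in the group for correlations")
    sub = matrix.values.loc[samples, names].astype(float)
    transformed = pd.DataFrame(index=sub.index, columns=names, dtype=float)
    for name in names:
        col_all = matrix.values[name].astype(float)
        positive = col_all[col_all > 0]
        if (col_all.dropna() > 0).all():
            eps = 0.0
        else:
            eps = positive.min() / 2.0 if not positive.empty else 1.0
        transformed[name] = np.log2(sub[name] + eps)
    return transformed.corr(method="pearson")


def summarize_boxplot(matrix: VariableMatrix, group: str) -> pd.DataFrame:
    """Five-number summary (median, Q1, Q3, min, max) per variable, one group.

    Quartiles use linear interpolation between order statistics (the
    common statistical convention).
    """
    samples = matrix.groups[matrix.groups == group].index
    if len(samples) == 0:
        raise ValueError(f"group {group!r} has no samples")
    sub = matrix.values.loc[samples].astype(float)
    return pd.DataFrame({
        "median": sub.median(),
        "q1": sub.quantile(0.25),
        "q3": sub.quantile(0.75),
        "min": sub.min(),
        "max": sub.max(),
    })
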