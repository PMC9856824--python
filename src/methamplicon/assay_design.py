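"""Search for diagnostic cytosine-status combinations within primer/probe regions.

A methylation-specific PCR assay needs every targeted CpG of the forward
primer, probe and reverse primer footprints to carry the tumor status on
the same molecule.  This module enumerates cytosine-status combinations
inside each designated region of a locus, scores each by the per-group
average percentage of molecules matching all constraints, and admits
those that both separate the groups completely (100% sensitivity at 100%
specificity) and are represented above 0.5% of case molecules on average.
Admitted per-region combinations are concatenated into composite
candidates that are re-evaluated from scratch on the molecule level.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import diagnostic_stats as ds
from .locus_model import LocusSpec
from .variable_builder import _normalize_methylomes

__all__ = [
    "Combination",
    "CombinationResult",
    "CandidateReport",
    "enumerate_region_combinations",
    "evaluate_combination",
    "select_candidates",
    "combination_values",
    "REPRESENTATION_THRESHOLD",
]

#: minimum case-group mean representation (%) for an admissible combination
REPRESENTATION_THRESHOLD = 0.5

_MAX_COMBINATIONS = 2 ** 16


@dataclass(frozen=True)
class Combination:
    """Ordered (CpG index, required status) constraints within a region."""

    locus: str
    region: str  # forward | probe | reverse | composite
    constraints: tuple[tuple[int, str], ...]

    def __post_init__(self) -> None:
        positions = [p for p, _ in self.constraints]
        if positions != sorted(set(positions)):
            raise ValueError("constraint positions must be strictly increasing")
        if any(s not in ("C", "T") for _, s in self.constraints):
            raise ValueError("statuses must be C or T")

    @property
    def name(self) -> str:
        return ".".join([self.locus] + [f"{s}{p}" for p, s in self.constraints])

    @property
    def size(self) -> int:
        return len(self.constraints)


@dataclass
class CombinationResult:
    combination: Combination
    mean_case: float
    mean_control: float
    cutoff: float
    ratio: float | None
    separates: bool
    representation_ok: bool


def enumerate_region_combinations(
    locus: LocusSpec,
    region: str,
    max_size: int | None = None,
    min_size: int = 2,
    single_t_variants: bool = False,
) -> list[Combination]:
    """All status combinations over a region's CpG indices.

    Default pattern is all-C (fully methylated); with
    ``single_t_variants`` each all-C combination additionally spawns the
    variants with exactly one position flipped to T (the deliberate
    "error" designs).  Sizes range ``min_size..max_size`` (default: the
    region width).  Deterministic order; refuses to enumerate more than
    2^16 combinations.
    """
    indices = locus.region_indices(region)
    if not indices:
        raise ValueError(f"region {region!r} of locus {locus.name} is empty")
    width = len(indices)
    if max_size is None:
        max_size = width
    max_size = min(max_size, width)
    n_subsets = sum(
        len(list(itertools.combinations(range(width), k)))
        for k in range(min_size, max_size + 1)
    )
    if n_subsets * (1 + (width if single_t_variants else 0)) > _MAX_COMBINATIONS:
        raise ValueError("region enumeration exceeds the 2^16 combination guard")
    combos: list[Combination] = []
    for k in range(min_size, max_size + 1):
        for subset in itertools.combinations(indices, k):
            combos.append(Combination(
                locus=locus.name, region=region,
                constraints=tuple((p, "C") for p in subset),
            ))
            if single_t_variants:
                for flip in subset:
                    combos.append(Combination(
                        locus=locus.name, region=region,
                        constraints=tuple(
                            (p, "T" if p == flip else "C") for p in subset
                        ),
                    ))
    return combos


def combination_values(
    combination: Combination,
    methylomes: Mapping,
    samples: Sequence[str],
) -> dict[str, float]:
    """Per-sample percentage of accepted molecules matching every constraint.

    Samples with zero accepted molecules for the locus are omitted.
    """
    counts = _normalize_methylomes(methylomes)
    out: dict[str, float] = {}
    for sid in samples:
        counter: Counter | None = counts.get((sid, combination.locus))
        if not counter:
            continue
        total = sum(counter.values())
        if total == 0:
            continue
        matching = 0
        for prof, c in counter.items():
            for p, status in combination.constraints:
                if p > len(prof):
                    raise ValueError(
                        f"constraint position {p} outside locus {combination.locus}"
                    )
                if prof[p - 1] != status:
                    break
            else:
                matching += c
        out[sid] = 100.0 * matching / total
    return out


def evaluate_combination(
    combination: Combination,
    methylomes: Mapping,
    groups: Mapping[str, str],
    case_group: str,
    control_group: str,
) -> CombinationResult:
    """Group means, separation flag, cutoff/ratio and representation check."""
    case_samples = [s for s, g in groups.items() if g == case_group]
    ctrl_samples = [s for s, g in groups.items() if g == control_group]
    values = combination_values(combination, methylomes, list(groups))
    x = np.array([values[s] for s in case_samples if s in values], dtype=float)
    y = np.array([values[s] for s in ctrl_samples if s in values], dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError(f"no covered samples for {combination.name} in one group")
    separates = ds.is_completely_separated(x, y, ds.CASE_HIGH)
    cutoff, ratio = ds.cutoff_and_ratio(x, y, ds.CASE_HIGH)
    mean_case = float(x.mean())
    return CombinationResult(
        combination=combination,
        mean_case=mean_case,
        mean_control=float(y.mean()),
        cutoff=cutoff,
        ratio=ratio,
        separates=separates,
        representation_ok=mean_case > REPRESENTATION_THRESHOLD,
    )


@dataclass
class CandidateReport:
    """Admitted combinations per region plus jointly re-evaluated composites."""

    by_region: dict[str, list[CombinationResult]]
    composites: list[CombinationResult]


def select_candidates(
    results_by_region: Mapping[str, Sequence[CombinationResult]],
    methylomes: Mapping,
    groups: Mapping[str, str],
    case_group: str,
    control_group: str,
    top_k: int = 5,
) -> CandidateReport:
    """Filter, rank and combine per-region results.

    Admission requires complete separation AND case-mean representation
    above 0.5%.  Ranking within a region: case mean descending, then
    fewer constraints, then name.  Composites concatenate one of the top
    ``top_k`` admitted combinations per region (positions merged; status
    conflicts at shared positions discard the composite) and are
    re-evaluated per molecule, never as products of means.  A region with
    no admissible combination is reported empty.
    """
    admitted: dict[str, list[CombinationResult]] = {}
    for region, results in results_by_region.items():
        ok = [r for r in results if r.separates and r.representation_ok]
        ok.sort(key=lambda r: (-r.mean_case, r.combination.size, r.combination.name))
        admitted[region] = ok

    composites: list[CombinationResult] = []
    pools = [admitted[region][:top_k] for region in admitted]
    if all(pools) and len(pools) > 1:
        seen: set[tuple] = set()
        for chosen in itertools.product(*pools):
            merged: dict[int, str] = {}
            conflict = False
            for res in chosen:
                for p, s in res.combination.constraints:
                    if merged.setdefault(p, s) != s:
                        conflict = True
                        break
                if conflict:
                    break
            if conflict:
                continue
            constraints = tuple(sorted(merged.items()))
            if constraints in seen:
                continue
            seen.add(constraints)
            composite = Combination(
                locus=chosen[0].combination.locus,
                region="composite",
                constraints=constraints,
            )
            composites.append(evaluate_combination(
                composite, methylomes, groups, case_group, control_group
            ))
        composites.sort(
            key=lambda r: (-r.mean_case, r.combination.size, r.combination.name)
        )
    return CandidateReport(by_region=admitted, composites=composites)


def results_to_frame(results: Sequence[CombinationResult]) -> pd.DataFrame:
    records = []
    for r in results:
        cutoff_ratio = f"{r.cutoff:.3g}"
        if r.ratio is not None:
            cutoff_ratio += f" ({r.ratio:.3g})"
        records.append({
            "combination": r.combination.name,
            "region": r.combination.region,
            "mean_control": r.mean_control,
            "mean_case": r.mean_case,
            "cutoff_ratio": cutoff_ratio,
            "separates": r.separates,
            "representation_ok": r.representation_ok,
        })
    return pd.DataFrame.from_records(records)


def write_results(results: Sequence[CombinationResult], path: str | Path) -> None:
    results_to_frame(results).to_csv(path, sep="\t", index=False)
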