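"""From paired reads to QC-filtered per-molecule methylation profiles.

Stages, per read pair: overlap-merge the mates into the amplicon-orientation
product; demultiplex on the two 8-bp barcode fields with exact matching,
discarding chimeric pairs (both barcodes known but the combination never
used in any library) and unassigned ones; trim barcodes and call the C/T
state at every CpG position against the pre-bisulfite reference; reject
reads with unrecognized sites (non-C/T at a CpG), excessive reference
mismatches, or a bisulfite conversion rate below 0.95 (inclusive: a rate
of exactly 0.95 passes).  Accepted molecules are tallied into per-sample
profile-count tables.

The matcher is fixed-length (no indels): amplicon inserts are
constant-length products of known primers, so a merged product must be
exactly ``16 + locus length``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO

from .locus_model import BarcodeScheme, LocusSpec, revcomp
from .synthetic_data import _open_fastq

__all__ = [
    "MoleculeProfile",
    "SampleMethylome",
    "PipelineResult",
    "merge_pair",
    "demultiplex",
    "call_methylation",
    "aggregate",
    "process_reads",
    "write_profile_counts",
    "read_profile_counts",
    "write_qc_report",
    "CHIMERIC",
    "UNASSIGNED",
]

CHIMERIC = "CHIMERIC"
UNASSIGNED = "UNASSIGNED"

MIN_CONVERSION = 0.95
MIN_OVERLAP = 20
MAX_MISMATCH_FRAC = 0.10


@dataclass(frozen=True)
class MoleculeProfile:
    """Binary methylation states of one molecule (1 = C retained = methylated)."""

    locus: str
    sample: str
    states: tuple[int, ...]
    conversion_rate: float

    @property
    def profile_string(self) -> str:
        return "".join("C" if s else "T" for s in self.states)


@dataclass
class SampleMethylome:
    """Profile-count table plus QC counters for one sample x locus."""

    sample: str
    locus: str
    profile_counts: Counter = field(default_factory=Counter)
    qc: Counter = field(default_factory=Counter)

    @property
    def accepted(self) -> int:
        return sum(self.profile_counts.values())


@dataclass
class PipelineResult:
    methylomes: dict[tuple[str, str], SampleMethylome]
    qc_global: Counter


# ---------------------------------------------------------------------------
# Pair merging
# ---------------------------------------------------------------------------


def merge_pair(
    read1: str,
    read2: str,
    min_overlap: int = MIN_OVERLAP,
    max_mismatch_frac: float = MAX_MISMATCH_FRAC,
) -> tuple[str | None, str]:
    """Overlap-merge two mates; returns (merged, reason).

    ``read2`` is reverse-complemented and slid against ``read1``; candidate
    product lengths are scanned from shortest (maximal overlap) upward and
    the first candidate with >= ``min_overlap`` overlapping bases and a
    mismatch fraction <= ``max_mismatch_frac`` in the overlap is accepted.
    Disagreeing overlap positions take the read1 base.
    """
    if not read1 or not read2:
        return None, "empty_read"
    r2rc = revcomp(read2)
    n1, n2 = len(read1), len(r2rc)
    for total in range(max(n1, n2), n1 + n2 - min_overlap + 1):
        ov = n1 + n2 - total
        start = total - n2  # read1 index where r2rc begins
        allowed = int(max_mismatch_frac * ov)
        mism = 0
        for a, b in zip(read1[start:n1], r2rc[: ov]):
            if a != b:
                mism += 1
                if mism > allowed:
                    break
        else:
            return read1 + r2rc[ov:], "ok"
    return None, "no_overlap"


# ---------------------------------------------------------------------------
# Demultiplexing
# ---------------------------------------------------------------------------


def demultiplex(
    merged: str, scheme: BarcodeScheme, locus: str
) -> tuple[str, str | None]:
    """Classify a merged product by its barcode pair.

    Returns (sample_id, None) for a valid pair, or (CHIMERIC, None) /
    (UNASSIGNED, None)-style sentinels: the first element is the sample id
    when assignment succeeds, else the sentinel; the second element is the
    sentinel reason or None.  Matching is exact (8 bp, 0 mismatches):
    tolerance would blur the group-disjointness guarantee that chimera
    exclusion rests on.
    """
    if len(merged) < 16:
        return UNASSIGNED, "too_short"
    fwd_seq = merged[:8]
    rev_seq = revcomp(merged[-8:])
    fwd_table = scheme.forward_table(locus)
    rev_table = scheme.reverse_table(locus)
    fwd_name = next((n for n, s in fwd_table.items() if s == fwd_seq), None)
    rev_name = next((n for n, s in rev_table.items() if s == rev_seq), None)
    if fwd_name is None or rev_name is None:
        return UNASSIGNED, "unknown_barcode"
    fwd_is_x = scheme.forward_family.get(locus, "X") == "X"
    pair = (fwd_name, rev_name) if fwd_is_x else (rev_name, fwd_name)
    valid = set().union(*(
        pairs for (l, _), pairs in scheme.assignment.items() if l == locus
    )) if scheme.assignment else set()
    if pair not in valid:
        return CHIMERIC, "invalid_combination"
    sample = scheme.sample_index.get(pair)
    if sample is None:
        return UNASSIGNED, "pair_without_sample"
    return sample, None


# ---------------------------------------------------------------------------
# Methylation calling
# ---------------------------------------------------------------------------


def call_methylation(
    insert: str,
    locus: LocusSpec,
    sample: str = "",
    min_conversion: float = MIN_CONVERSION,
    max_mismatch_frac: float = MAX_MISMATCH_FRAC,
) -> tuple[MoleculeProfile | None, str]:
    """Call per-CpG C/T states on a barcode-trimmed insert; returns (profile, reason).

    Rejection reasons: ``length_mismatch``, ``unrecognized_site`` (non-C/T
    base at a CpG position), ``ref_mismatch`` (> ``max_mismatch_frac`` of
    positions disagree with the converted reference), ``low_conversion``
    (conversion rate strictly below ``min_conversion``).

    The conversion rate is the fraction of the locus's non-CpG reference
    cytosines read as T; a locus without non-CpG cytosines yields rate 1.
    """
    insert = insert.upper()
    if len(insert) != locus.length:
        return None, "length_mismatch"
    states = []
    for p in locus.cpg_positions:
        base = insert[p - 1]
        if base == "C":
            states.append(1)
        elif base == "T":
            states.append(0)
        else:
            return None, "unrecognized_site"

    non_cpg_c = locus.non_cpg_c_positions()
    converted = sum(1 for p in non_cpg_c if insert[p - 1] == "T")
    rate = converted / len(non_cpg_c) if non_cpg_c else 1.0

    cpg_c = set(locus.cpg_positions)
    mismatches = 0
    for p in range(1, locus.length + 1):
        if p in cpg_c:
            continue
        ref = locus.sequence[p - 1]
        obs = insert[p - 1]
        if ref == "C":
            if obs not in ("C", "T"):
                mismatches += 1
        elif obs != ref:
            mismatches += 1
    if mismatches > max_mismatch_frac * locus.length:
        return None, "ref_mismatch"
    if rate < min_conversion:
        return None, "low_conversion"
    return MoleculeProfile(locus=locus.name, sample=sample,
                           states=tuple(states), conversion_rate=rate), "ok"


# ---------------------------------------------------------------------------
# Aggregation and the full pipeline
# ---------------------------------------------------------------------------


def aggregate(profiles: Iterable[MoleculeProfile]) -> dict[tuple[str, str], SampleMethylome]:
    """Tally accepted molecules into per-(sample, locus) profile counts."""
    out: dict[tuple[str, str], SampleMethylome] = {}
    for prof in profiles:
        key = (prof.sample, prof.locus)
        if key not in out:
            out[key] = SampleMethylome(sample=prof.sample, locus=prof.locus)
        meth = out[key]
        meth.profile_counts[prof.profile_string] += 1
        meth.qc["total"] += 1
        meth.qc["accepted"] += 1
    return out


def _iter_fastq_pairs(r1_path: str | Path, r2_path: str | Path) -> Iterator[tuple[str, str]]:
    with _open_fastq(r1_path, "rt") as f1, _open_fastq(r2_path, "rt") as f2:
        for rec1, rec2 in zip(SeqIO.parse(f1, "fastq"), SeqIO.parse(f2, "fastq")):
            yield str(rec1.seq), str(rec2.seq)


def process_reads(
    r1_path: str | Path,
    r2_path: str | Path,
    loci: Sequence[LocusSpec],
    scheme: BarcodeScheme,
    min_conversion: float = MIN_CONVERSION,
    min_overlap: int = MIN_OVERLAP,
) -> PipelineResult:
    """Run merge -> demultiplex -> call -> aggregate over paired FASTQ files.

    The locus of a merged product is identified by its length
    (16 barcode bases + insert); when several loci share a length the one
    with the fewest reference mismatches wins.  Identical read pairs are
    memoized, which collapses the heavy per-read work on amplicon data
    where a handful of molecules dominate.
    """
    by_length: dict[int, list[LocusSpec]] = {}
    for locus in loci:
        by_length.setdefault(16 + locus.length, []).append(locus)

    methylomes: dict[tuple[str, str], SampleMethylome] = {}
    qc_global: Counter = Counter()
    cache: dict[tuple[str, str], tuple] = {}

    def classify(r1: str, r2: str) -> tuple:
        merged, reason = merge_pair(r1, r2, min_overlap=min_overlap)
        if merged is None:
            return ("merge_failed", None, None, None, None)
        candidates = by_length.get(len(merged), [])
        if not candidates:
            return ("no_locus", None, None, None, None)
        best: tuple | None = None
        for locus in candidates:
            sample, why = demultiplex(merged, scheme, locus.name)
            if sample == UNASSIGNED:
                outcome = ("unassigned", None, locus.name, None, None)
            elif sample == CHIMERIC:
                outcome = ("chimeric", None, locus.name, None, None)
            else:
                prof, call_reason = call_methylation(
                    merged[8:-8], locus, sample=sample, min_conversion=min_conversion
                )
                if prof is None:
                    outcome = (call_reason, sample, locus.name, None, None)
                else:
                    outcome = ("accepted", sample, locus.name,
                               prof.profile_string, prof.conversion_rate)
            if best is None or _outcome_rank(outcome[0]) < _outcome_rank(best[0]):
                best = outcome
            if outcome[0] == "accepted":
                break
        return best

    for r1, r2 in _iter_fastq_pairs(r1_path, r2_path):
        qc_global["total_pairs"] += 1
        key = (r1, r2)
        outcome = cache.get(key)
        if outcome is None:
            outcome = classify(r1, r2)
            cache[key] = outcome
        disposition, sample, locus_name, profile, _rate = outcome
        qc_global[disposition] += 1
        if sample is not None and locus_name is not None:
            mkey = (sample, locus_name)
            if mkey not in methylomes:
                methylomes[mkey] = SampleMethylome(sample=sample, locus=locus_name)
            meth = methylomes[mkey]
            meth.qc["total"] += 1
            meth.qc[disposition] += 1
            if disposition == "accepted":
                meth.profile_counts[profile] += 1
    return PipelineResult(methylomes=methylomes, qc_global=qc_global)


_OUTCOME_ORDER = {
    "accepted": 0, "low_conversion": 1, "unrecognized_site": 2,
    "ref_mismatch": 3, "length_mismatch": 4, "chimeric": 5, "unassigned": 6,
}


def _outcome_rank(disposition: str) -> int:
    return _OUTCOME_ORDER.get(disposition, 9)


# ---------------------------------------------------------------------------
# TSV output
# ---------------------------------------------------------------------------


def write_profile_counts(
    methylomes: dict[tuple[str, str], SampleMethylome], path: str | Path
) -> None:
    """TSV: sample, locus, profile (C/T string), count."""
    lines = ["sample\tlocus\tprofile\tcount"]
    for (sid, locus), meth in sorted(methylomes.items()):
        for prof in sorted(meth.profile_counts):
            lines.append(f"{sid}\t{locus}\t{prof}\t{meth.profile_counts[prof]}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_profile_counts(path: str | Path) -> dict[tuple[str, str], Counter]:
    counts: dict[tuple[str, str], Counter] = {}
    for line in Path(path).read_text().strip().splitlines()[1:]:
        sid, locus, prof, c = line.split("\t")
        counts.setdefault((sid, locus), Counter())[prof] = int(c)
    return counts


def write_qc_report(result: PipelineResult, path: str | Path) -> None:
    """TSV of global and per-sample QC counters."""
    lines = ["scope\tsample\tlocus\tcounter\tvalue"]
    for counter, value in sorted(result.qc_global.items()):
        lines.append(f"global\t-\t-\t{counter}\t{value}")
    for (sid, locus), meth in sorted(result.methylomes.items()):
        for counter, value in sorted(meth.qc.items()):
            lines.append(f"sample\t{sid}\t{locus}\t{counter}\t{value}")
    Path(path).write_text("\n".join(lines) + "\n")
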