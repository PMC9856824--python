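"""Synthetic bisulfite amplicon cohorts.

Emulates the data the pipeline consumes: two groups of donors (default
19 case / 18 control), per-molecule binary methylation profiles over each
locus's CpG positions, and barcoded paired-end reads derived from them.

The generative model for case/control contrast is a latent *tumor
fraction*: each case sample draws f ~ Uniform(0.06, 0.13); every molecule
of that sample is tumor-derived with probability f.  Tumor molecules are
methylated jointly (all-or-none) at each designated CpG block, background
molecules methylate each position independently at the low control rate.
This yields near-zero control methylation, case means tracking E[f], and
r > 0.9 co-methylation among block positions within the case group.

Read synthesis applies in-silico bisulfite conversion (unmethylated
C -> T, methylated CpG C stays C, per-cytosine conversion failures leave
C), attaches the sample's 8-bp barcodes on both ends, emits 150-nt mates,
and injects substitution errors and invalid-barcode chimeras.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .locus_model import BarcodeScheme, CohortDesign, LocusSpec, make_default_cohort, revcomp

__all__ = [
    "SimulationConfig",
    "SimulatedTruth",
    "simulate_profiles",
    "profiles_to_reads",
    "write_ground_truth",
    "read_ground_truth",
    "expected_case_rate",
]

_QUAL = "I"  # constant Phred 40; quality-aware processing is out of scope


@dataclass
class SimulationConfig:
    """Knobs of the generator; defaults are the study-scale conditions."""

    seed: int = 17
    n_case: int = 19
    n_control: int = 18
    molecules_per_sample: int = 10_000
    #: per-position background (control) methylation probability
    control_rate: float = 0.003
    #: latent per-sample tumor fraction range for case samples
    tumor_fraction_range: tuple[float, float] = (0.06, 0.13)
    #: locus name -> tuple of CpG-index blocks methylated all-or-none on
    #: tumor molecules; None = one block covering every position
    blocks: Mapping[str, tuple[tuple[int, ...], ...]] | None = None
    #: probability an unmethylated cytosine escapes conversion (stays C)
    conversion_failure_rate: float = 0.005
    #: per-base substitution error probability on each mate
    sequencing_error_rate: float = 0.001
    #: probability a molecule's reverse barcode is swapped for an invalid one
    chimera_rate: float = 0.01
    read_length: int = 150

    def validate(self) -> list[str]:
        problems = []
        for name in ("control_rate", "conversion_failure_rate",
                     "sequencing_error_rate", "chimera_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                problems.append(f"{name}={v} outside [0, 1]")
        lo, hi = self.tumor_fraction_range
        if not 0.0 <= lo <= hi <= 1.0:
            problems.append(f"tumor_fraction_range {self.tumor_fraction_range} invalid")
        if self.molecules_per_sample <= 0:
            problems.append("molecules_per_sample must be positive")
        if self.read_length < 30:
            problems.append("read_length too short to carry barcodes and insert")
        return problems

    def locus_blocks(self, locus: LocusSpec) -> tuple[tuple[int, ...], ...]:
        if self.blocks is not None and locus.name in self.blocks:
            blocks = tuple(tuple(b) for b in self.blocks[locus.name])
        else:
            blocks = (tuple(range(1, locus.n_cpg + 1)),)
        for block in blocks:
            bad = set(block) - set(range(1, locus.n_cpg + 1))
            if bad:
                raise ValueError(f"block positions {sorted(bad)} outside C1..C{locus.n_cpg}")
        return blocks


@dataclass
class SimulatedTruth:
    """Ground truth of one simulated cohort."""

    cohort: CohortDesign
    tumor_fractions: dict[str, float]
    #: (sample, locus) -> Counter of C/T profile strings
    profile_counts: dict[tuple[str, str], Counter]

    def molecules(self, sample: str, locus: str) -> int:
        return sum(self.profile_counts[sample, locus].values())


def expected_case_rate(config: SimulationConfig, f: float) -> float:
    """Expected per-molecule methylation at a block position given tumor fraction f."""
    p0 = config.control_rate
    return f + (1.0 - f) * p0


def simulate_profiles(
    config: SimulationConfig,
    loci: Sequence[LocusSpec],
    cohort: CohortDesign | None = None,
) -> SimulatedTruth:
    """Draw per-molecule binary profiles for every sample x locus.

    Case samples mix tumor molecules (block positions methylated jointly)
    into the background at their latent fraction; control samples are pure
    background.  Deterministic given ``config.seed``.
    """
    problems = config.validate()
    if problems:
        raise ValueError("; ".join(problems))
    if cohort is None:
        cohort = make_default_cohort(
            config.n_case, config.n_control, config.molecules_per_sample
        )
    ss = np.random.SeedSequence(config.seed)
    rng = np.random.default_rng(ss.spawn(2)[0])

    fractions = {
        sid: float(rng.uniform(*config.tumor_fraction_range))
        for sid in cohort.case_samples
    }
    m = config.molecules_per_sample
    counts: dict[tuple[str, str], Counter] = {}
    for locus in loci:
        k = locus.n_cpg
        blocks = config.locus_blocks(locus)
        for sid in cohort.samples():
            states = rng.random((m, k)) < config.control_rate
            if sid in fractions:
                tumor = rng.random(m) < fractions[sid]
                for block in blocks:
                    cols = [p - 1 for p in block]
                    states[np.ix_(tumor, cols)] = True
            chars = np.where(states, "C", "T")
            counts[sid, locus.name] = Counter(
                "".join(row) for row in chars
            )
    return SimulatedTruth(cohort=cohort, tumor_fractions=fractions, profile_counts=counts)


# ---------------------------------------------------------------------------
# Read synthesis
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def _converted_template(locus: LocusSpec) -> np.ndarray:
    """Insert after complete conversion of every unmethylated C, as char array.

    CpG positions are left as 'C' placeholders; per-molecule states decide.
    """
    arr = np.array(list(locus.sequence), dtype="<U1")
    cpg = np.zeros(locus.length, dtype=bool)
    cpg[[p - 1 for p in locus.cpg_positions]] = True
    arr[(arr == "C") & ~cpg] = "T"
    return arr


def _synthesize_sample_reads(
    rng: np.random.Generator,
    locus: LocusSpec,
    profiles: Counter,
    fwd_bc: str,
    rev_bc: str,
    invalid_rev_bcs: Sequence[str],
    config: SimulationConfig,
) -> list[tuple[str, str]]:
    """Paired reads (r1, r2 sequences) for one sample x locus, in profile order."""
    order = sorted(profiles)
    n = sum(profiles.values())
    if n == 0:
        return []
    states = np.zeros((n, locus.n_cpg), dtype=bool)
    row = 0
    for prof in order:
        c = profiles[prof]
        states[row: row + c] = np.array([ch == "C" for ch in prof], dtype=bool)
        row += c

    template = _converted_template(locus)
    inserts = np.tile(template, (n, 1))
    cpg_cols = np.array([p - 1 for p in locus.cpg_positions])
    # methylated CpG stays C, unmethylated converts to T
    for j, col in enumerate(cpg_cols):
        inserts[~states[:, j], col] = "T"
    # conversion failures: any originally-C position now reading T may stay C
    orig_c = np.array([b == "C" for b in locus.sequence])
    convertible = (inserts == "T") & orig_c[np.newaxis, :]
    fail = convertible & (rng.random(inserts.shape) < config.conversion_failure_rate)
    inserts[fail] = "C"

    # chimeras: swap the reverse barcode for an invalid one
    chimeric = rng.random(n) < config.chimera_rate
    rev_choices = np.full(n, rev_bc, dtype=object)
    if chimeric.any():
        if not invalid_rev_bcs:
            raise ValueError("chimera requested but no invalid reverse barcode available")
        picks = rng.integers(0, len(invalid_rev_bcs), size=int(chimeric.sum()))
        rev_choices[chimeric] = [invalid_rev_bcs[i] for i in picks]

    L = config.read_length
    fwd_arr = np.array(list(fwd_bc), dtype="<U1")
    pairs: list[tuple[str, str]] = []
    err_rate = config.sequencing_error_rate
    for i in range(n):
        product = np.concatenate([
            fwd_arr, inserts[i], np.array(list(revcomp(rev_choices[i])), dtype="<U1")
        ])
        top = product
        bottom = np.array(list(revcomp("".join(product))), dtype="<U1")
        r1 = top[:L].copy()
        r2 = bottom[:L].copy()
        for read in (r1, r2):
            errs = np.nonzero(rng.random(read.shape[0]) < err_rate)[0]
            for e in errs:
                alt = [b for b in "ACGT" if b != read[e]]
                read[e] = alt[rng.integers(0, 3)]
        pairs.append(("".join(r1), "".join(r2)))
    return pairs


def profiles_to_reads(
    truth: SimulatedTruth,
    loci: Sequence[LocusSpec],
    scheme: BarcodeScheme,
    config: SimulationConfig,
    r1_path: str | Path,
    r2_path: str | Path,
) -> int:
    """Write barcoded paired-end FASTQ for a simulated cohort.

    Returns the number of read pairs written (= molecules simulated).
    Deterministic given ``config.seed``; gzip output (``.gz`` suffix) is
    written with a zeroed timestamp so identical runs are byte-identical.
    """
    ss = np.random.SeedSequence(config.seed)
    rng = np.random.default_rng(ss.spawn(2)[1])
    name_by_sample = {sid: pair for pair, sid in scheme.sample_index.items()}

    n_written = 0
    with _open_fastq(r1_path) as f1, _open_fastq(r2_path) as f2:
        for locus in loci:
            fwd_is_x = scheme.forward_family.get(locus.name, "X") == "X"
            fwd_table = scheme.forward_table(locus.name)
            rev_table = scheme.reverse_table(locus.name)
            valid_pairs = set().union(*(
                pairs for (l, _), pairs in scheme.assignment.items() if l == locus.name
            ))
            for sid in truth.cohort.samples():
                if sid not in name_by_sample:
                    raise KeyError(f"sample {sid!r} has no barcode assignment")
                x_name, y_name = name_by_sample[sid]
                fwd_name, rev_name = (x_name, y_name) if fwd_is_x else (y_name, x_name)
                # reverse-side names whose substitution makes the pair invalid
                invalid = []
                for cand in rev_table:
                    # sample_index pairs are (X-name, Y-name)
                    pair_names = (x_name, cand) if fwd_is_x else (cand, y_name)
                    if pair_names not in valid_pairs:
                        invalid.append(rev_table[cand])
                pairs = _synthesize_sample_reads(
                    rng, locus, truth.profile_counts[sid, locus.name],
                    fwd_table[fwd_name], rev_table[rev_name], invalid, config,
                )
                for i, (r1, r2) in enumerate(pairs):
                    rid = f"{locus.name}:{sid}:{i}"
                    f1.write(f"@{rid}/1\n{r1}\n+\n{_QUAL * len(r1)}\n")
                    f2.write(f"@{rid}/2\n{r2}\n+\n{_QUAL * len(r2)}\n")
                n_written += len(pairs)
    return n_written


def _open_fastq(path: str | Path, mode: str = "wt"):
    path = Path(path)
    if path.suffix == ".gz":
        if "w" in mode:
            # fileobj + zeroed mtime: no filename/timestamp in the gzip
            # header, so identical runs are byte-identical
            import io
            raw = gzip.GzipFile(filename="", fileobj=open(path, "wb"),
                                mode="wb", mtime=0)
            return io.TextIOWrapper(raw)
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# Ground truth TSV
# ---------------------------------------------------------------------------


def write_ground_truth(truth: SimulatedTruth, path: str | Path) -> None:
    """TSV: sample, locus, profile (C/T string), count."""
    lines = ["sample\tlocus\tprofile\tcount"]
    for (sid, locus), counter in sorted(truth.profile_counts.items()):
        for prof in sorted(counter):
            lines.append(f"{sid}\t{locus}\t{prof}\t{counter[prof]}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_ground_truth(path: str | Path) -> dict[tuple[str, str], Counter]:
    counts: dict[tuple[str, str], Counter] = {}
    lines = Path(path).read_text().strip().splitlines()
    for line in lines[1:]:
        sid, locus, prof, c = line.split("\t")
        counts.setdefault((sid, locus), Counter())[prof] = int(c)
    return counts
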