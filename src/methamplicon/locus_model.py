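"""Domain model for locus-specific bisulfite amplicon sequencing.

A *locus* is a short PCR amplicon (primer-trimmed, top strand, 5'->3')
containing an ordered set of CpG dinucleotides numbered C1..Cn.  Molecules
are tagged with a pair of 8-bp barcodes (one on each primer) that encode
the donor, with case and control cohorts drawing from disjoint barcode
sets so that PCR chimeras crossing the groups can be recognised and
discarded.

Coordinates are 1-based and inclusive throughout: ``cpg_positions[k-1]``
is the position of the C of the k-th CpG (the field's "Ck" notation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml
from Bio import SeqIO

__all__ = [
    "LocusSpec",
    "BarcodeScheme",
    "CohortDesign",
    "make_fixture_loci",
    "make_default_scheme",
    "make_default_cohort",
    "validate_locus",
    "load_reference_fasta",
    "load_config",
    "save_config",
    "read_sample_sheet",
    "write_sample_sheet",
    "X_BARCODES",
    "Y_BARCODES",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LocusSpec:
    """One amplicon locus.

    Parameters
    ----------
    name
        Locus identifier (e.g. ``"GSTP1"``), also the FASTA record id.
    sequence
        Pre-bisulfite amplicon sequence, primer-trimmed, top strand.
    cpg_positions
        1-based positions of the C of each CpG, strictly increasing.
    forward_region, probe_region, reverse_region
        Inclusive CpG-*index* ranges (1-based Ck indices) delimiting the
        forward-primer, hydrolysis-probe and reverse-primer candidate
        regions used by the assay-design search; ``None`` when the locus
        has no designated regions.
    """

    name: str
    sequence: str
    cpg_positions: tuple[int, ...]
    forward_region: tuple[int, int] | None = None
    probe_region: tuple[int, int] | None = None
    reverse_region: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "cpg_positions", tuple(self.cpg_positions))
        object.__setattr__(self, "sequence", self.sequence.upper())

    @property
    def n_cpg(self) -> int:
        return len(self.cpg_positions)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def region_indices(self, region: str) -> tuple[int, ...]:
        """CpG indices (1-based) belonging to a named region."""
        bounds = {
            "forward": self.forward_region,
            "probe": self.probe_region,
            "reverse": self.reverse_region,
        }.get(region)
        if bounds is None:
            raise ValueError(f"locus {self.name!r} has no {region!r} region")
        lo, hi = bounds
        return tuple(range(lo, hi + 1))

    def non_cpg_c_positions(self) -> tuple[int, ...]:
        """1-based positions of cytosines outside the tracked CpG sites.

        These positions should read T after complete bisulfite conversion;
        the per-read conversion rate is computed over them.
        """
        cpg = set(self.cpg_positions)
        return tuple(
            p for p in range(1, self.length + 1)
            if self.sequence[p - 1] == "C" and p not in cpg
        )


@dataclass
class BarcodeScheme:
    """Dual 8-bp barcode scheme with group-disjoint assignments.

    ``x_barcodes``/``y_barcodes`` are the two barcode families; which
    family sits on the forward primer is locus-specific
    (``forward_family``).  ``assignment`` maps ``(locus, group)`` to the
    set of valid (X-name, Y-name) pairs and ``sample_index`` maps an
    (X-name, Y-name) pair to a sample id.
    """

    x_barcodes: dict[str, str]
    y_barcodes: dict[str, str]
    forward_family: dict[str, str]  # locus name -> "X" | "Y"
    assignment: dict[tuple[str, str], frozenset[tuple[str, str]]]
    sample_index: dict[tuple[str, str], str]

    def forward_table(self, locus: str) -> dict[str, str]:
        return self.x_barcodes if self.forward_family.get(locus, "X") == "X" else self.y_barcodes

    def reverse_table(self, locus: str) -> dict[str, str]:
        return self.y_barcodes if self.forward_family.get(locus, "X") == "X" else self.x_barcodes

    def pair_for_sample(self, sample: str) -> tuple[str, str]:
        for pair, sid in self.sample_index.items():
            if sid == sample:
                return pair
        raise KeyError(f"sample {sample!r} has no barcode assignment")

    def validate(self) -> list[str]:
        problems = []
        for name, seq in {**self.x_barcodes, **self.y_barcodes}.items():
            if len(seq) != 8:
                problems.append(f"barcode {name} is not 8 bp: {seq}")
        loci = {locus for locus, _ in self.assignment}
        for locus in loci:
            groups = sorted({g for l, g in self.assignment if l == locus})
            for i, g1 in enumerate(groups):
                for g2 in groups[i + 1:]:
                    shared = self.assignment[locus, g1] & self.assignment[locus, g2]
                    if shared:
                        problems.append(
                            f"locus {locus}: groups {g1}/{g2} share barcode pairs {sorted(shared)}"
                        )
        all_pairs = set().union(*self.assignment.values()) if self.assignment else set()
        for pair in self.sample_index:
            if pair not in all_pairs:
                problems.append(f"sample_index pair {pair} not in any assignment")
        return problems


@dataclass
class CohortDesign:
    """Two-group study design: sample ids per group and expected coverage."""

    case_group: str = "PCa"
    control_group: str = "HD"
    case_samples: tuple[str, ...] = ()
    control_samples: tuple[str, ...] = ()
    molecules_per_sample: int = 10_000

    @property
    def groups(self) -> tuple[str, str]:
        return (self.case_group, self.control_group)

    def samples(self) -> tuple[str, ...]:
        return self.case_samples + self.control_samples

    def group_of(self, sample: str) -> str:
        if sample in self.case_samples:
            return self.case_group
        if sample in self.control_samples:
            return self.control_group
        raise KeyError(f"unknown sample {sample!r}")

    def validate(self) -> list[str]:
        problems = []
        if not self.case_samples or not self.control_samples:
            problems.append("both groups must be non-empty")
        ids = self.samples()
        if len(set(ids)) != len(ids):
            problems.append("sample ids are not unique")
        return problems


# ---------------------------------------------------------------------------
# Published barcode tables
# ---------------------------------------------------------------------------

X_BARCODES: dict[str, str] = {
    "X1": "TAGATCGC", "X2": "CTCTCTAT", "X3": "TATCCTCT", "X4": "AGAGTAGA",
    "X5": "ACTGCATA", "X6": "AAGGAGTA", "X7": "CTAAGCCT", "X8": "CCTCTCTG",
}

Y_BARCODES: dict[str, str] = {
    "Y1": "TCGCCTTA", "Y2": "CTAGTACG", "Y3": "TTCTGCCT", "Y4": "GCTCAGGA",
    "Y5": "AGGAGTCC", "Y6": "CATGCCTA", "Y7": "GTAGAGAG", "Y8": "CCTCTCTG",
    "Y9": "AGCGTAGC", "Y10": "CAGCCTCG", "Y11": "TGCCTCTT", "Y12": "TCCTCTAC",
}

# Which family sits on the forward primer, per fixture locus.
_FORWARD_FAMILY = {"RNF219": "Y", "KIAA1539": "X", "GSTP1": "Y"}


# ---------------------------------------------------------------------------
# Fixture loci
# ---------------------------------------------------------------------------

# (length, n_cpg) per fixture locus; GSTP1 additionally carries the
# forward/probe/reverse CpG-index regions used by the assay-design search.
_FIXTURE_GEOMETRY = {
    "GSTP1": (142, 17),
    "RNF219": (161, 17),
    "KIAA1539": (89, 5),
}
_FIXTURE_SEED = 20230109  # fixed: fixture sequences are part of the package


def _synthesize_locus_sequence(
    rng: np.random.Generator, length: int, n_cpg: int
) -> tuple[str, tuple[int, ...]]:
    """Random amplicon with CG exactly at ``n_cpg`` chosen positions.

    Filler bases avoid creating unintended CG dinucleotides (no G ever
    follows a C outside the designated sites) and are biased toward C/G
    for a CpG-island-like composition.  Retries until the sequence has at
    least 10 non-CpG cytosines so that conversion-rate QC is informative.
    """
    while True:
        # spread CpGs with >= 3 bp gaps, away from the very ends
        slots = np.arange(3, length - 3)
        positions = np.sort(rng.choice(slots, size=n_cpg * 3, replace=False))
        picked: list[int] = []
        for p in positions:
            if not picked or p - picked[-1] >= 3:
                picked.append(int(p))
            if len(picked) == n_cpg:
                break
        if len(picked) < n_cpg:
            continue
        seq = [""] * length
        for p in picked:
            seq[p - 1] = "C"
            seq[p] = "G"
        for i in range(length):
            if seq[i]:
                continue
            prev = seq[i - 1] if i > 0 else ""
            alphabet = "ACT" if prev == "C" else "ACGT"
            # if the next base is a fixed G, do not place a C before it
            nxt = seq[i + 1] if i + 1 < length else ""
            if nxt == "G":
                alphabet = alphabet.replace("C", "")
            weights = np.array([3.0 if b in "GC" else 2.0 for b in alphabet])
            seq[i] = str(rng.choice(list(alphabet), p=weights / weights.sum()))
        s = "".join(seq)
        if len([p for p in range(1, length + 1)
                if s[p - 1] == "C" and p not in set(picked)]) >= 10:
            return s, tuple(picked)


def make_fixture_loci(fasta: str | Path | None = None) -> list[LocusSpec]:
    """The three bundled loci matching the studied amplicon geometry.

    Lengths/CpG counts are 142/17 (GSTP1), 161/17 (RNF219) and 89/5
    (KIAA1539).  Sequence content is synthetic (deterministically
    generated); supply ``fasta`` to override sequences by record id, in
    which case CpG positions are re-derived from the provided sequence.
    """
    rng = np.random.default_rng(_FIXTURE_SEED)
    overrides = dict(load_reference_fasta(fasta)) if fasta else {}
    loci = []
    for name, (length, n_cpg) in _FIXTURE_GEOMETRY.items():
        if name in overrides:
            seq = overrides[name].upper()
            positions = tuple(
                p for p in range(1, len(seq))
                if seq[p - 1: p + 1] == "CG"
            )
        else:
            seq, positions = _synthesize_locus_sequence(rng, length, n_cpg)
        regions: dict[str, tuple[int, int] | None] = dict(
            forward_region=None, probe_region=None, reverse_region=None
        )
        if name == "GSTP1" and len(positions) >= 17:
            regions = dict(
                forward_region=(1, 6), probe_region=(6, 15), reverse_region=(11, 17)
            )
        loci.append(LocusSpec(name=name, sequence=seq, cpg_positions=positions, **regions))
    return loci


def validate_locus(spec: LocusSpec) -> list[str]:
    """Check LocusSpec invariants; returns a list of violations (empty = valid)."""
    problems = []
    for k, p in enumerate(spec.cpg_positions, start=1):
        if not (1 <= p < spec.length):
            problems.append(f"C{k}: position {p} outside sequence (length {spec.length})")
        elif spec.sequence[p - 1: p + 1] != "CG":
            problems.append(
                f"C{k}: position {p} is {spec.sequence[p - 1:p + 1]!r}, expected 'CG'"
            )
    if list(spec.cpg_positions) != sorted(set(spec.cpg_positions)):
        problems.append("cpg_positions are not strictly increasing")
    for region in ("forward", "probe", "reverse"):
        bounds = getattr(spec, f"{region}_region")
        if bounds is not None:
            lo, hi = bounds
            if not (1 <= lo <= hi <= spec.n_cpg):
                problems.append(f"{region}_region {bounds} outside C1..C{spec.n_cpg}")
    return problems


# ---------------------------------------------------------------------------
# Default cohort / scheme
# ---------------------------------------------------------------------------


def make_default_cohort(
    n_case: int = 19, n_control: int = 18, molecules_per_sample: int = 10_000
) -> CohortDesign:
    """The study-sized cohort: 19 case (PCa) vs 18 control (HD) samples."""
    return CohortDesign(
        case_samples=tuple(f"PCa{str(i + 1).zfill(2)}" for i in range(n_case)),
        control_samples=tuple(f"HD{str(i + 1).zfill(2)}" for i in range(n_control)),
        molecules_per_sample=molecules_per_sample,
    )


def make_default_scheme(
    loci: Sequence[LocusSpec], cohort: CohortDesign
) -> BarcodeScheme:
    """Assign disjoint barcode pairs to the two groups.

    Cases draw X from {X1..X4} x Y from {Y1..Y6}; controls from
    {X5..X8} x {Y7..Y12}: the groups share no individual barcode, so any
    cross-group chimera is detectable from its barcode pair alone.
    """
    case_pairs = [(f"X{i}", f"Y{j}") for i in range(1, 5) for j in range(1, 7)]
    ctrl_pairs = [(f"X{i}", f"Y{j}") for i in range(5, 9) for j in range(7, 13)]
    if len(cohort.case_samples) > len(case_pairs) or len(cohort.control_samples) > len(ctrl_pairs):
        raise ValueError("cohort larger than the default barcode capacity (24 per group)")
    sample_index: dict[tuple[str, str], str] = {}
    for sid, pair in zip(cohort.case_samples, case_pairs):
        sample_index[pair] = sid
    for sid, pair in zip(cohort.control_samples, ctrl_pairs):
        sample_index[pair] = sid
    assignment: dict[tuple[str, str], frozenset] = {}
    for locus in loci:
        assignment[locus.name, cohort.case_group] = frozenset(
            case_pairs[: len(cohort.case_samples)]
        )
        assignment[locus.name, cohort.control_group] = frozenset(
            ctrl_pairs[: len(cohort.control_samples)]
        )
    return BarcodeScheme(
        x_barcodes=dict(X_BARCODES),
        y_barcodes=dict(Y_BARCODES),
        forward_family={l.name: _FORWARD_FAMILY.get(l.name, "X") for l in loci},
        assignment=assignment,
        sample_index=sample_index,
    )


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------


def load_reference_fasta(path: str | Path) -> dict[str, str]:
    """Reference amplicons: one record per locus, record id = locus name."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def save_config(path: str | Path, loci: Sequence[LocusSpec], scheme: BarcodeScheme,
                cohort: CohortDesign) -> None:
    """Write the run configuration (loci, barcodes, cohort) as YAML."""
    doc = {
        "loci": [
            {
                "name": l.name,
                "sequence": l.sequence,
                "cpg_positions": list(l.cpg_positions),
                "forward_region": list(l.forward_region) if l.forward_region else None,
                "probe_region": list(l.probe_region) if l.probe_region else None,
                "reverse_region": list(l.reverse_region) if l.reverse_region else None,
            }
            for l in loci
        ],
        "barcodes": {
            "X": scheme.x_barcodes,
            "Y": scheme.y_barcodes,
            "forward_family": scheme.forward_family,
        },
        "assignment": {
            f"{locus}|{group}": sorted(f"{x}+{y}" for x, y in pairs)
            for (locus, group), pairs in scheme.assignment.items()
        },
        "samples": {
            f"{x}+{y}": sid for (x, y), sid in scheme.sample_index.items()
        },
        "cohort": {
            "case_group": cohort.case_group,
            "control_group": cohort.control_group,
            "case_samples": list(cohort.case_samples),
            "control_samples": list(cohort.control_samples),
            "molecules_per_sample": cohort.molecules_per_sample,
        },
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_config(path: str | Path) -> tuple[list[LocusSpec], BarcodeScheme, CohortDesign]:
    doc = yaml.safe_load(Path(path).read_text())
    loci = [
        LocusSpec(
            name=d["name"],
            sequence=d["sequence"],
            cpg_positions=tuple(d["cpg_positions"]),
            forward_region=tuple(d["forward_region"]) if d.get("forward_region") else None,
            probe_region=tuple(d["probe_region"]) if d.get("probe_region") else None,
            reverse_region=tuple(d["reverse_region"]) if d.get("reverse_region") else None,
        )
        for d in doc["loci"]
    ]
    scheme = BarcodeScheme(
        x_barcodes=dict(doc["barcodes"]["X"]),
        y_barcodes=dict(doc["barcodes"]["Y"]),
        forward_family=dict(doc["barcodes"]["forward_family"]),
        assignment={
            (key.split("|")[0], key.split("|")[1]): frozenset(
                tuple(p.split("+")) for p in pairs
            )
            for key, pairs in doc["assignment"].items()
        },
        sample_index={tuple(k.split("+")): v for k, v in doc["samples"].items()},
    )
    c = doc["cohort"]
    cohort = CohortDesign(
        case_group=c["case_group"],
        control_group=c["control_group"],
        case_samples=tuple(c["case_samples"]),
        control_samples=tuple(c["control_samples"]),
        molecules_per_sample=c["molecules_per_sample"],
    )
    return loci, scheme, cohort


def write_sample_sheet(path: str | Path, scheme: BarcodeScheme, cohort: CohortDesign) -> None:
    """Sample sheet TSV: sample_id, group, forward_barcode, reverse_barcode.

    The barcode columns hold the X- and Y-family names; which family sits
    on the forward primer of a given locus is recorded in the scheme.
    """
    lines = ["sample_id\tgroup\tforward_barcode\treverse_barcode"]
    for (x, y), sid in sorted(scheme.sample_index.items(), key=lambda kv: kv[1]):
        lines.append(f"{sid}\t{cohort.group_of(sid)}\t{x}\t{y}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_sample_sheet(path: str | Path) -> dict[str, dict[str, str]]:
    """Parse the sample sheet into {sample_id: {group, forward_barcode, reverse_barcode}}."""
    rows: dict[str, dict[str, str]] = {}
    lines = Path(path).read_text().strip().splitlines()
    header = lines[0].split("\t")
    for line in lines[1:]:
        vals = dict(zip(header, line.split("\t")))
        rows[vals["sample_id"]] = vals
    return rows
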