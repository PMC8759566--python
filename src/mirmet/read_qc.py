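"""Read-level filters and sample/study exclusion gates for small-RNA-seq.

Reads pass, in order: a quality filter (discard when fewer than half of the
bases exceed Phred 20), 3' adapter trimming, a length filter (discard below
18 nt) and a low-complexity filter (tandem 1-3-mer repeats).  Retained reads
are classified against the mature miRNA reference.  Samples are excluded when
fewer than 25% of retained reads fall in the 20-25 nt miRNA length band, when
more than 75% of input reads were discarded, or when fewer than 10% of
retained reads are identified as miRNA; a study is excluded when more than
half its samples fail or when clade-level contamination is detected.  All
boundary comparisons are strict.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .core import MiRNAReference, ReadRecord

__all__ = [
    "ReadRecord",
    "QCConfig",
    "QCReport",
    "StudyVerdict",
    "filter_read_quality",
    "trim_adapter",
    "filter_read_length",
    "filter_low_complexity",
    "classify_read",
    "qc_sample",
    "qc_study",
    "read_fastq",
]


@dataclass(frozen=True)
class QCConfig:
    """Tunable thresholds; the defaults are the pipeline's published gates."""

    min_frac_hq_bases: float = 0.5     # quality filter: frac of bases Phred>20
    phred_threshold: int = 20
    min_length: int = 18
    min_overlap: int = 6               # adapter prefix overlap
    max_adapter_mismatch_rate: float = 0.10
    complexity_motif_max: int = 3      # tandem motif lengths screened
    complexity_coverage: float = 0.80  # discard when repeat covers >= this
    classify_max_mismatch: int = 1
    classify_max_len_diff: int = 2     # 3' length tolerance
    gate_frac_20_25: float = 0.25      # fail when below (strict <)
    gate_discard_frac: float = 0.75    # fail when above (strict >)
    gate_mirna_frac: float = 0.10      # fail when below (strict <)
    study_fail_frac: float = 0.5       # exclude study when above (strict >)
    contamination_threshold: float = 0.10


@dataclass
class QCReport:
    sample_id: str
    n_input: int
    n_discarded: int
    n_retained: int
    frac_20_25: float
    frac_mirna: float
    category_tally: dict[str, int]
    discard_tally: dict[str, int]
    contamination_frac: float
    passed: bool
    fail_reasons: list[str] = field(default_factory=list)


@dataclass
class StudyVerdict:
    study_id: str
    n_samples: int
    n_failed: int
    contamination_flag: bool
    include: bool


# ---------------------------------------------------------------------------
# per-read filters


def filter_read_quality(read: ReadRecord, config: QCConfig = QCConfig()) -> bool:
    """Keep iff at least half of the bases have Phred > 20 (strict <50% discards)."""
    if len(read) == 0:
        return False
    frac_hq = np.mean(read.qual > config.phred_threshold)
    return not (frac_hq < config.min_frac_hq_bases)


def trim_adapter(read: ReadRecord, adapter: str,
                 config: QCConfig = QCConfig()) -> ReadRecord:
    """Remove the 3' adapter, quality string trimmed in lockstep.

    The suffix starting at the leftmost position where a prefix of the adapter
    aligns with >= min_overlap bases and <= 10% mismatches is removed; with no
    such position the read is returned unchanged.
    """
    if len(adapter) < config.min_overlap:
        raise ValueError(
            f"adapter length {len(adapter)} < min_overlap {config.min_overlap}")
    seq = read.seq
    for start in range(0, len(seq) - config.min_overlap + 1):
        overlap = min(len(adapter), len(seq) - start)
        mismatches = sum(seq[start + i] != adapter[i] for i in range(overlap))
        if mismatches <= config.max_adapter_mismatch_rate * overlap:
            return ReadRecord(read.read_id, seq[:start], read.qual[:start])
    return read


def filter_read_length(read: ReadRecord, config: QCConfig = QCConfig()) -> bool:
    """Keep iff the (adapter-trimmed) read is at least 18 nt."""
    return len(read) >= config.min_length


def filter_low_complexity(read: ReadRecord,
                          config: QCConfig = QCConfig()) -> bool:
    """Discard reads dominated by a tandem 1-3-mer repeat.

    A read is low-complexity when some single motif of length 1-3, repeated
    back-to-back from some start position, covers >= 80% of the read.
    """
    seq = read.seq
    n = len(seq)
    if n == 0:
        return False
    min_cover = config.complexity_coverage * n
    codes = np.frombuffer(seq.encode(), dtype=np.uint8)
    for k in range(1, config.complexity_motif_max + 1):
        if n <= k:
            continue
        # a run of length r where seq[i] == seq[i-k] means a tandem k-mer
        # repeat covering r + k positions
        match = codes[k:] == codes[:-k]
        run, best = 0, 0
        for m in match:
            run = run + 1 if m else 0
            best = max(best, run)
        if best + k >= min_cover:
            return False
    return True


def classify_read(read: ReadRecord, refs: list[MiRNAReference],
                  other_refs: dict[str, list[str]] | None = None,
                  config: QCConfig = QCConfig()) -> str:
    """Assign a retained, trimmed read to a reference class.

    5'-anchored comparison allowing <= 1 mismatch over the shared length and
    <= 2 nt of 3' length difference; priority mirna_target > mirna_contaminant
    > other_rna, else unknown.
    """
    matches = _matching_refs(read.seq, refs, config)
    if any(refs[i].clade_tag == "target" for i in matches):
        return "mirna_target"
    if matches:
        return "mirna_contaminant"
    for cls, seqs in (other_refs or {}).items():
        for ref_seq in seqs:
            if _seq_matches(read.seq, ref_seq, config):
                return "other_rna"
    return "unknown"


def _seq_matches(seq: str, ref_seq: str, config: QCConfig) -> bool:
    if abs(len(seq) - len(ref_seq)) > config.classify_max_len_diff:
        return False
    n = min(len(seq), len(ref_seq))
    mism = 0
    for a, b in zip(seq[:n], ref_seq[:n]):
        if a != b:
            mism += 1
            if mism > config.classify_max_mismatch:
                return False
    return True


def _matching_refs(seq: str, refs: list[MiRNAReference],
                   config: QCConfig) -> list[int]:
    return [i for i, r in enumerate(refs)
            if _seq_matches(seq, r.mature_seq, config)]


# ---------------------------------------------------------------------------
# FASTQ input


def read_fastq(path: str | Path) -> list[ReadRecord]:
    """Parse a Phred+33 FASTQ file into ReadRecords."""
    reads = []
    try:
        for i, rec in enumerate(SeqIO.parse(str(path), "fastq")):
            reads.append(ReadRecord(
                rec.id, str(rec.seq),
                np.asarray(rec.letter_annotations["phred_quality"])))
    except ValueError as exc:
        raise ValueError(
            f"malformed FASTQ at record index {len(reads)}: {exc}") from exc
    return reads


# ---------------------------------------------------------------------------
# sample and study gates


def qc_sample(
    reads: list[ReadRecord] | str | Path,
    refs: list[MiRNAReference],
    adapter: str,
    config: QCConfig = QCConfig(),
    other_refs: dict[str, list[str]] | None = None,
    sample_id: str = "sample",
) -> QCReport:
    """Run the full per-sample QC and compute the exclusion gates.

    Filters apply in order quality -> adapter trim -> length -> complexity.
    frac_20_25 and frac_mirna denominate over retained reads; the discard
    fraction over input reads.  Classified miRNA reads from non-target clades
    count toward contamination_frac.
    """
    if not isinstance(reads, list):
        reads = read_fastq(reads)
    n_input = len(reads)
    discard_tally = {"low_quality": 0, "short": 0, "low_complexity": 0}
    category_tally = {"mirna_target": 0, "mirna_contaminant": 0,
                      "other_rna": 0, "unknown": 0}
    n_20_25 = 0
    for read in reads:
        if not filter_read_quality(read, config):
            discard_tally["low_quality"] += 1
            continue
        trimmed = trim_adapter(read, adapter, config)
        if not filter_read_length(trimmed, config):
            discard_tally["short"] += 1
            continue
        if not filter_low_complexity(trimmed, config):
            discard_tally["low_complexity"] += 1
            continue
        if 20 <= len(trimmed) <= 25:
            n_20_25 += 1
        category_tally[classify_read(trimmed, refs, other_refs, config)] += 1
    n_discarded = sum(discard_tally.values())
    n_retained = n_input - n_discarded
    n_mirna = category_tally["mirna_target"] + category_tally["mirna_contaminant"]
    frac_20_25 = n_20_25 / n_retained if n_retained else 0.0
    frac_mirna = n_mirna / n_retained if n_retained else 0.0
    contamination = (category_tally["mirna_contaminant"] / n_mirna
                     if n_mirna else 0.0)
    discard_frac = n_discarded / n_input if n_input else 1.0
    reasons = []
    if frac_20_25 < config.gate_frac_20_25:
        reasons.append("length_fraction")
    if discard_frac > config.gate_discard_frac:
        reasons.append("discard_fraction")
    if frac_mirna < config.gate_mirna_frac:
        reasons.append("mirna_fraction")
    return QCReport(
        sample_id=sample_id,
        n_input=n_input,
        n_discarded=n_discarded,
        n_retained=n_retained,
        frac_20_25=frac_20_25,
        frac_mirna=frac_mirna,
        category_tally=category_tally,
        discard_tally=discard_tally,
        contamination_frac=contamination,
        passed=not reasons,
        fail_reasons=reasons,
    )


def qc_study(reports: list[QCReport], config: QCConfig = QCConfig(),
             study_id: str = "study") -> StudyVerdict:
    """Study-level gate: exclude when >50% of samples fail or any sample shows
    contamination above threshold."""
    if not reports:
        raise ValueError("empty report list")
    n = len(reports)
    n_failed = sum(not r.passed for r in reports)
    contamination = any(r.contamination_frac > config.contamination_threshold
                       for r in reports)
    include = not (n_failed / n > config.study_fail_frac) and not contamination
    return StudyVerdict(study_id, n, n_failed, contamination, include)
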