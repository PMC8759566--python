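"""Annotation merging, read counting and RPM normalization.

Mature miRNA genes with very similar sequences cross-map, so near-identical
annotations are merged into one counting unit before quantification: two
annotations are linked when their mature sequences are identical, one is a
5' sub/superstring of the other with at most 2 nt of 3' difference, or they
are within Hamming distance 1 after 5' alignment over the shorter length.
Connected components of that relation become merged annotation groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import CountMatrix, MiRNAReference, ReadRecord
from .read_qc import QCConfig, _matching_refs

__all__ = [
    "CountMatrix",
    "MergedAnnotation",
    "MergeConfig",
    "merge_annotations",
    "count_reads",
    "rpm",
]


@dataclass(frozen=True)
class MergeConfig:
    """Which clauses of the similarity relation are active."""

    merge_identical: bool = True
    merge_substring: bool = True
    max_3p_diff: int = 2
    merge_hamming: bool = True
    max_hamming: int = 1


@dataclass
class MergedAnnotation:
    group_id: str              # member ids joined by "/" (sorted)
    members: list[str]
    representative_seq: str    # longest member sequence, ties by id


def _similar(a: str, b: str, cfg: MergeConfig) -> bool:
    if cfg.merge_identical and a == b:
        return True
    n = min(len(a), len(b))
    diff = abs(len(a) - len(b))
    if cfg.merge_substring and a[:n] == b[:n] and diff <= cfg.max_3p_diff:
        return True
    if cfg.merge_hamming:
        ham = sum(x != y for x, y in zip(a[:n], b[:n]))
        if ham <= cfg.max_hamming and diff == 0:
            return True
    return False


def merge_annotations(refs: list[MiRNAReference],
                      config: MergeConfig = MergeConfig()) -> list[MergedAnnotation]:
    """Union-find over the sequence-similarity relation; groups are its
    connected components (so similarity propagates transitively)."""
    ids = [r.annotation_id for r in refs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate annotation IDs")
    n = len(refs)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if _similar(refs[i].mature_seq, refs[j].mature_seq, config):
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[ri] = rj
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    merged = []
    for members_idx in groups.values():
        members = sorted(refs[i].annotation_id for i in members_idx)
        rep = max((refs[i].mature_seq for i in members_idx),
                  key=lambda s: (len(s), s))
        merged.append(MergedAnnotation("/".join(members), members, rep))
    merged.sort(key=lambda g: g.group_id)
    return merged


def count_reads(
    reads: list[ReadRecord],
    merged: list[MergedAnnotation],
    config: QCConfig = QCConfig(),
) -> tuple[pd.Series, int, int]:
    """Count QC-retained, trimmed reads against merged annotations.

    Each read increments exactly one group when it matches one group under
    the classification tolerance; reads matching two or more groups are
    ambiguous and dropped, unmatched reads are unassigned.  Returns
    (counts, n_ambiguous, n_unassigned); counts + ambiguous + unassigned
    conserve the input read number exactly.
    """
    if not merged:
        raise ValueError("empty merged reference")
    as_refs = [MiRNAReference(g.group_id, g.representative_seq)
               for g in merged]
    counts = pd.Series(0, index=[g.group_id for g in merged], dtype=np.int64)
    ambiguous = unassigned = 0
    for read in reads:
        hits = _matching_refs(read.seq, as_refs, config)
        if len(hits) == 1:
            counts.iloc[hits[0]] += 1
        elif len(hits) > 1:
            ambiguous += 1
        else:
            unassigned += 1
    return counts, ambiguous, unassigned


def rpm(counts: pd.Series | np.ndarray) -> pd.Series | np.ndarray:
    """Reads per million mapped miRNA reads: counts / total * 1e6."""
    total = np.asarray(counts).sum()
    if total == 0:
        raise ValueError("all-zero count vector")
    return counts / total * 1e6
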