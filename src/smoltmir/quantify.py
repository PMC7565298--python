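"""Small-RNA read processing: adapter trimming, size filtering, counting.

Reads are trimmed at the leftmost occurrence of the 3' sequencing
adapter (exact prefix match, minimum overlap configurable), kept when
the trimmed insert is 18-25 nt inclusive, and then compared end-to-end
against a mature-miRNA reference. A read is counted for a feature only
when it matches exactly one reference entry within ``max_mismatches``
(default 0); multi-mapping and unmapped reads go to the mapping stats
instead. Matching is done in DNA space, case-insensitively, with U/T
treated as equivalent.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio.SeqIO import parse as seqio_parse
from Bio.SeqIO.QualityIO import FastqGeneralIterator

DEFAULT_ADAPTER = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCAC"
UNTRIMMED = None  # marker for reads with no adapter match


@dataclass(frozen=True)
class MiRNAReference:
    """Mature miRNA reference: (id, family, sequence) entries."""

    ids: tuple[str, ...]
    families: tuple[str, ...]
    sequences: tuple[str, ...]  # stored in DNA space, uppercase

    def __post_init__(self):
        if len(set(self.ids)) != len(self.ids):
            dupes = [m for m, c in Counter(self.ids).items() if c > 1]
            raise ValueError(f"duplicate reference ids: {dupes}")
        for mid, fam, seq in zip(self.ids, self.families, self.sequences):
            if not fam:
                raise ValueError(f"empty family id for {mid}")
            if not 16 <= len(seq) <= 30:
                raise ValueError(f"reference {mid} length {len(seq)} outside 16-30 nt")

    @classmethod
    def from_entries(cls, entries: Iterable[tuple[str, str, str]]) -> "MiRNAReference":
        ids, fams, seqs = [], [], []
        for mid, fam, seq in entries:
            ids.append(mid)
            fams.append(fam)
            seqs.append(_to_dna(seq))
        return cls(tuple(ids), tuple(fams), tuple(seqs))

    @classmethod
    def from_fasta(cls, path: str | Path) -> "MiRNAReference":
        """FASTA with headers '>mature_id family' (family defaults to id)."""
        entries = []
        for rec in seqio_parse(str(path), "fasta"):
            parts = rec.description.split()
            family = parts[1] if len(parts) > 1 else rec.id
            entries.append((rec.id, family, str(rec.seq)))
        return cls.from_entries(entries)

    def family_of(self) -> dict[str, str]:
        return dict(zip(self.ids, self.families))


def _to_dna(seq: str) -> str:
    return seq.strip().upper().replace("U", "T")


def trim_adapter(read: str, adapter: str = DEFAULT_ADAPTER, min_overlap: int = 3) -> str | None:
    """Truncate at the leftmost adapter (prefix) match; None if absent.

    A match at position p requires read[p:p+L] == adapter[:L] where
    L = min(len(adapter), len(read) - p) and L >= min_overlap, so a
    partial adapter running off the 3' end still trims.
    """
    if not read:
        raise ValueError("empty read")
    if not 3 <= min_overlap <= len(adapter):
        raise ValueError("require adapter length >= min_overlap >= 3")
    r = _to_dna(read)
    a = _to_dna(adapter)
    for p in range(0, len(r) - min_overlap + 1):
        L = min(len(a), len(r) - p)
        if r[p : p + L] == a[:L]:
            return r[:p]
    return UNTRIMMED


def filter_by_length(reads: Iterable[str], min_len: int = 18, max_len: int = 25) -> tuple[list[str], int]:
    """Keep reads with min_len <= length <= max_len; return discard tally."""
    kept, discarded = [], 0
    for r in reads:
        if min_len <= len(r) <= max_len:
            kept.append(r)
        else:
            discarded += 1
    return kept, discarded


@dataclass
class MappingStats:
    total_reads: int = 0
    adapter_discarded: int = 0
    length_discarded: int = 0
    no_hit: int = 0
    multi_hit: int = 0
    counted: int = 0
    retained_length_sum: int = 0

    @property
    def mean_retained_length(self) -> float:
        n = self.counted + self.no_hit + self.multi_hit
        return self.retained_length_sum / n if n else float("nan")

    def conserves(self) -> bool:
        return self.total_reads == (
            self.adapter_discarded + self.length_discarded + self.no_hit + self.multi_hit + self.counted
        )


def _hamming_within(a: str, b: str, limit: int) -> bool:
    mism = 0
    for x, y in zip(a, b):
        if x != y:
            mism += 1
            if mism > limit:
                return False
    return True


def map_and_count(
    reads: Iterable[str],
    reference: MiRNAReference,
    max_mismatches: int = 0,
    stats: MappingStats | None = None,
) -> tuple[Counter, MappingStats]:
    """Count size-filtered reads uniquely matching one reference entry."""
    if not reference.ids:
        raise ValueError("empty reference")
    stats = stats or MappingStats()
    counts: Counter = Counter()
    exact = {}
    for mid, seq in zip(reference.ids, reference.sequences):
        exact.setdefault(seq, []).append(mid)
    by_length: dict[int, list[tuple[str, str]]] = {}
    for mid, seq in zip(reference.ids, reference.sequences):
        by_length.setdefault(len(seq), []).append((mid, seq))
    for read in reads:
        stats.retained_length_sum += len(read)
        if max_mismatches == 0:
            owners = exact.get(read, [])
        else:
            owners = [mid for mid, seq in by_length.get(len(read), []) if _hamming_within(read, seq, max_mismatches)]
        if len(owners) == 1:
            counts[owners[0]] += 1
            stats.counted += 1
        elif len(owners) == 0:
            stats.no_hit += 1
        else:
            stats.multi_hit += 1
    return counts, stats


def _read_fastq_sequences(path: str | Path) -> Iterator[str]:
    with open(path) as handle:
        for _title, seq, _qual in FastqGeneralIterator(handle):
            yield seq


def quantify_sample(
    fastq_path: str | Path,
    reference: MiRNAReference,
    adapter: str = DEFAULT_ADAPTER,
    min_overlap: int = 3,
    min_len: int = 18,
    max_len: int = 25,
    max_mismatches: int = 0,
) -> tuple[Counter, MappingStats]:
    """Full FASTQ -> per-feature counts for one sample."""
    stats = MappingStats()
    retained = []
    for seq in _read_fastq_sequences(fastq_path):
        stats.total_reads += 1
        trimmed = trim_adapter(seq, adapter, min_overlap)
        if trimmed is UNTRIMMED:
            stats.adapter_discarded += 1
            continue
        if min_len <= len(trimmed) <= max_len:
            retained.append(trimmed)
        else:
            stats.length_discarded += 1
    counts, stats = map_and_count(retained, reference, max_mismatches, stats)
    return counts, stats


def quantify_samples(
    fastq_paths: dict[str, str | Path],
    reference: MiRNAReference,
    **kwargs,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Count matrix (features x samples) and per-sample stats table."""
    count_cols = {}
    stat_rows = []
    for sample, path in fastq_paths.items():
        counts, stats = quantify_sample(path, reference, **kwargs)
        count_cols[sample] = counts
        stat_rows.append(
            {
                "sample": sample,
                "total_reads": stats.total_reads,
                "adapter_discarded": stats.adapter_discarded,
                "length_discarded": stats.length_discarded,
                "no_hit": stats.no_hit,
                "multi_hit": stats.multi_hit,
                "counted": stats.counted,
                "mean_retained_length": stats.mean_retained_length,
            }
        )
    matrix = pd.DataFrame(count_cols, index=list(reference.ids)).fillna(0).astype(int)
    matrix.index.name = "feature"
    return matrix, pd.DataFrame(stat_rows).set_index("sample")
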