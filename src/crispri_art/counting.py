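"""Spacer extraction and counting from pooled-screen sequencing reads.

Reads are expected to carry the crRNA spacer between two fixed flanking
anchors (the repeat/terminator junctions of the expression cassette).
Extraction locates the upstream anchor, takes the following ``match_len``
bases as the candidate, requires the downstream anchor immediately after,
and applies a per-base Phred floor.  Candidates are assigned to the guide
library by minimal Hamming distance over the first ``match_len`` bases of
each library spacer, tolerating up to ``max_mismatch`` mismatches; ties
at the minimal distance are left unassigned as ambiguous.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from ._util import hamming, revcomp

logger = logging.getLogger(__name__)

REJECTION_REASONS = ("no_upstream", "no_downstream", "low_quality", "truncated",
                     "unassigned", "ambiguous", "merge_failed")


@dataclass(frozen=True)
class ExtractionParams:
    """Spacer-extraction settings (defaults follow the screen's read layout)."""

    upstream_anchor: str = "GGTTTGAAAC"
    downstream_anchor: str = "ATGCTTGGGC"
    match_len: int = 30
    max_mismatch: int = 2
    min_phred: int = 20
    #: adapter pair used when trimming raw paired reads (repeat / terminator)
    trim_adapters: tuple[str, str] = ("GTTTCAAACCCCGACCAGTT", "ATGCTTGGGCCCGAA")
    #: allow <=1 mismatch when locating anchors (fallback after exact search)
    anchor_mismatch_fallback: bool = True
    #: per-base minimum ("min") or mean quality ("mean") reading of the Phred floor
    phred_mode: str = "min"

    def __post_init__(self) -> None:
        if self.max_mismatch < 0:
            raise ValueError("max_mismatch must be >= 0")
        if self.phred_mode not in ("min", "mean"):
            raise ValueError("phred_mode must be 'min' or 'mean'")


def _find_anchor(seq: str, anchor: str, allow_mismatch: bool) -> int:
    """Left-most anchor position; exact first, then <=1 mismatch. -1 if absent."""
    i = seq.find(anchor)
    if i != -1 or not allow_mismatch:
        return i
    L = len(anchor)
    for i in range(len(seq) - L + 1):
        if hamming(anchor, seq[i:i + L], limit=1) <= 1:
            return i
    return -1


def phred_from_string(qual: str) -> np.ndarray:
    return np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(int) - 33


def extract_spacer(
    seq: str,
    qual: str | None,
    params: ExtractionParams,
) -> tuple[str | None, str]:
    """Extract the candidate spacer from one read.

    Returns ``(candidate, "ok")`` or ``(None, reason)`` with reason one of
    ``no_upstream``, ``truncated``, ``no_downstream``, ``low_quality``.
    """
    up = _find_anchor(seq, params.upstream_anchor, params.anchor_mismatch_fallback)
    if up == -1:
        return None, "no_upstream"
    cstart = up + len(params.upstream_anchor)
    cend = cstart + params.match_len
    if cend > len(seq):
        return None, "truncated"
    candidate = seq[cstart:cend]
    # The downstream anchor may sit a few bases past the candidate when the
    # library spacer is longer than match_len (e.g. 31-nt spacers compared
    # over their first 30 bases); search for it anywhere after the candidate.
    ds = params.downstream_anchor
    if _find_anchor(seq[cend:], ds, params.anchor_mismatch_fallback) == -1:
        return None, "no_downstream"
    if qual is not None and params.min_phred > 0:
        q = phred_from_string(qual)[cstart:cend]
        bad = (q.min() < params.min_phred if params.phred_mode == "min"
               else q.mean() < params.min_phred)
        if bad:
            return None, "low_quality"
    return candidate, "ok"


class LibraryIndex:
    """Guide library prepared for fast exact and Hamming assignment.

    Library spacers are truncated to ``match_len`` bases for comparison
    (mirroring extraction, which also takes ``match_len`` bases).
    """

    def __init__(self, guide_ids: list[str], spacers: list[str], match_len: int = 30):
        if len(guide_ids) != len(spacers):
            raise ValueError("guide_ids and spacers must have equal length")
        if not guide_ids:
            raise ValueError("library is empty")
        short = [s for s in spacers if len(s) < match_len]
        if short:
            raise ValueError(f"{len(short)} library spacers shorter than match_len={match_len}")
        self.guide_ids = list(guide_ids)
        self.match_len = match_len
        self.trunc = [s[:match_len].upper() for s in spacers]
        self._exact: dict[str, list[int]] = {}
        for i, s in enumerate(self.trunc):
            self._exact.setdefault(s, []).append(i)
        self._matrix = np.frombuffer(
            "".join(self.trunc).encode("ascii"), dtype=np.uint8
        ).reshape(len(self.trunc), match_len)

    @classmethod
    def from_table(cls, table: pd.DataFrame, match_len: int = 30) -> "LibraryIndex":
        return cls(table["guide_id"].tolist(), table["spacer"].tolist(), match_len)

    def __len__(self) -> int:
        return len(self.guide_ids)

    def assign(self, candidate: str, max_mismatch: int = 2) -> tuple[str | None, str]:
        """Assign a candidate to the unique nearest library spacer.

        Returns ``(guide_id, "ok")``, ``(None, "ambiguous")`` when two or
        more spacers tie at the minimal distance, or ``(None,
        "unassigned")`` when no spacer is within ``max_mismatch``.
        """
        cand = candidate[:self.match_len].upper()
        if len(cand) < self.match_len:
            return None, "unassigned"
        exact = self._exact.get(cand)
        if exact is not None:
            if len(exact) == 1:
                return self.guide_ids[exact[0]], "ok"
            return None, "ambiguous"
        if max_mismatch == 0:
            return None, "unassigned"
        vec = np.frombuffer(cand.encode("ascii"), dtype=np.uint8)
        dists = (self._matrix != vec).sum(axis=1)
        dmin = int(dists.min())
        if dmin > max_mismatch:
            return None, "unassigned"
        idx = np.flatnonzero(dists == dmin)
        if len(idx) > 1:
            return None, "ambiguous"
        return self.guide_ids[int(idx[0])], "ok"


def assign_to_library(candidate: str, library: LibraryIndex,
                      max_mismatch: int = 2) -> tuple[str | None, str]:
    """Functional wrapper around :meth:`LibraryIndex.assign`."""
    return library.assign(candidate, max_mismatch)


def merge_pairs(
    seq1: str, qual1: str, seq2: str, qual2: str,
    min_overlap: int = 10,
    max_overlap_mismatch_frac: float = 0.1,
) -> tuple[str, str] | None:
    """Greedy best-overlap merge of a read pair.

    The mate is reverse-complemented, the longest overlap whose mismatch
    fraction passes the threshold is taken, and disagreeing bases resolve
    to the higher-quality call.  Returns ``(sequence, quality)`` or
    ``None`` on failure.
    """
    r2 = revcomp(seq2)
    q2 = qual2[::-1]
    max_ov = min(len(seq1), len(r2))
    for ov in range(max_ov, min_overlap - 1, -1):
        a, b = seq1[-ov:], r2[:ov]
        mism = sum(1 for x, y in zip(a, b) if x != y)
        if mism / ov <= max_overlap_mismatch_frac:
            qa, qb = qual1[-ov:], q2[:ov]
            merged_ov = "".join(
                x if x == y or qx >= qy else y
                for x, y, qx, qy in zip(a, b, qa, qb)
            )
            merged_q = "".join(max(qx, qy) for qx, qy in zip(qa, qb))
            return (seq1[:-ov] + merged_ov + r2[ov:],
                    qual1[:-ov] + merged_q + q2[ov:])
    return None


def _open_fastq(path: str | Path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def iter_fastq(path: str | Path):
    with _open_fastq(path) as fh:
        yield from FastqGeneralIterator(fh)


def count_sample(
    fastq: str | Path | tuple[str | Path, str | Path],
    library: LibraryIndex,
    params: ExtractionParams | None = None,
) -> tuple[pd.Series, dict]:
    """Count spacers of one sample; returns (per-guide counts, QC report).

    ``fastq`` is a single merged-read file or a ``(read1, read2)`` pair to
    be overlap-merged first.  The QC report tallies every rejection reason
    and satisfies ``assigned_reads + sum(rejections) == total_reads``.
    """
    params = params or ExtractionParams()
    tallies: dict[str, int] = {}
    qc = {r: 0 for r in REJECTION_REASONS}
    total = 0
    assigned = 0

    if isinstance(fastq, (tuple, list)):
        reads = _iter_merged(fastq[0], fastq[1], params, qc)
    else:
        reads = ((seq, qual) for _t, seq, qual in iter_fastq(fastq))

    for seq, qual in reads:
        total += 1
        if seq is None:  # merge failure placeholder
            continue
        candidate, reason = extract_spacer(seq, qual, params)
        if candidate is None:
            qc[reason] += 1
            continue
        guide_id, reason = library.assign(candidate, params.max_mismatch)
        if guide_id is None:
            qc[reason] += 1
            continue
        tallies[guide_id] = tallies.get(guide_id, 0) + 1
        assigned += 1

    if total == 0:
        logger.warning("empty FASTQ input: zero counts reported")
    qc["total_reads"] = total
    qc["assigned_reads"] = assigned
    counts = pd.Series(
        [tallies.get(g, 0) for g in library.guide_ids],
        index=pd.Index(library.guide_ids, name="guide_id"),
        dtype=int,
    )
    return counts, qc


def _iter_merged(path1, path2, params: ExtractionParams, qc: dict):
    for (t1, s1, q1), (t2, s2, q2) in zip(iter_fastq(path1), iter_fastq(path2)):
        merged = merge_pairs(s1, q1, s2, q2)
        if merged is None:
            qc["merge_failed"] += 1
            yield None, None
        else:
            yield merged


@dataclass
class CountMatrix:
    """Guide x sample integer counts with per-sample metadata.

    ``counts``: DataFrame (guides as rows, samples as columns).
    ``sample_meta``: DataFrame indexed by sample id with columns
    ``condition``, ``replicate``, ``baseline`` (bool) and optionally
    ``total_reads`` / ``assigned_reads``.
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        missing = set(self.counts.columns) - set(self.sample_meta.index)
        if missing:
            raise ValueError(f"samples missing from sample sheet: {sorted(missing)}")
        if "baseline" not in self.sample_meta.columns:
            raise ValueError("sample sheet needs a 'baseline' column")

    @property
    def baseline_samples(self) -> list[str]:
        meta = self.sample_meta.loc[list(self.counts.columns)]
        return list(meta.index[meta["baseline"].astype(bool)])

    def require_baseline(self) -> None:
        if not self.baseline_samples:
            raise ValueError(
                "no baseline (MOI-0 / T0 / crRNA-only) sample declared in the "
                "sample sheet; fitness analysis needs one"
            )

    def condition_samples(self, condition: str) -> list[str]:
        meta = self.sample_meta.loc[list(self.counts.columns)]
        return list(meta.index[meta["condition"] == condition])

    def write_tsv(self, counts_path: str | Path, sheet_path: str | Path) -> None:
        self.counts.to_csv(counts_path, sep="\t", index_label="guide_id")
        self.sample_meta.to_csv(sheet_path, sep="\t", index_label="sample_id")

    @classmethod
    def read_tsv(cls, counts_path: str | Path, sheet_path: str | Path) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col="guide_id")
        meta = pd.read_csv(sheet_path, sep="\t", index_col="sample_id")
        return cls(counts, meta)


def build_count_matrix(
    sample_fastqs: dict[str, str | Path | tuple],
    library: LibraryIndex,
    sample_meta: pd.DataFrame,
    params: ExtractionParams | None = None,
) -> tuple[CountMatrix, dict]:
    """Count every sample and assemble the guide x sample matrix."""
    columns = {}
    qc_all = {}
    for sample_id, fq in sample_fastqs.items():
        col, qc = count_sample(fq, library, params)
        columns[sample_id] = col
        qc_all[sample_id] = qc
    counts = pd.DataFrame(columns)
    meta = sample_meta.copy()
    meta["total_reads"] = [qc_all[s]["total_reads"] for s in counts.columns]
    meta["assigned_reads"] = [qc_all[s]["assigned_reads"] for s in counts.columns]
    return CountMatrix(counts, meta), qc_all
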