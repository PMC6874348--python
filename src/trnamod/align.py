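"""Read-to-reference assignment and per-position base pileups.

tRNA-seq reads are near-full-length copies of very short references, so reads
are aligned *glocally*: the whole read must be accounted for (read-global)
while the alignment may start and end anywhere on the reference (reference-
local).  Scoring is affine-gap (Gotoh three-state dynamic programming): match
+1, mismatch -1, first gap base ``gap_open`` (-3), each further gap base
``gap_extend`` (-1).  A read is assigned to the reference with the single
strictly best score, provided that score reaches ``min_score_fraction`` of
the read length; ties across references are discarded as multimapped rather
than fractionally assigned, which is conservative for downstream proportion
estimates.

Two entry points share the same scoring engine:

* :func:`align_read` — one read, full traceback, returns a
  :class:`ReadAlignment` or :class:`UnassignedRead`.
* :func:`align_and_pileup` — vectorised batch scoring of many reads with
  direct accumulation into a :class:`PileupMatrix`; per-read alignments whose
  optimum is achieved by an ungapped placement (the overwhelming majority for
  substitution-only data) are accumulated without traceback, the rest fall
  back to the single-read path.  Equality of the two routes is property-
  tested.

External alignments in SAM format (primary records) can be ingested with
:func:`read_sam`.
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam

from .errors import AlignmentError, PileupError
from .reference import TRNAGene, canonical_position

__all__ = [
    "Scoring",
    "ReadAlignment",
    "UnassignedRead",
    "PileupMatrix",
    "align_read",
    "align_reads",
    "align_and_pileup",
    "read_sam",
    "build_pileup",
    "revcomp",
]

_NEG = -1.0e9
_CODE = {65: 0, 67: 1, 71: 2, 84: 3, 78: 4}  # A C G T N
_COLS = ("A", "C", "G", "T", "del")
_MIN_READ_LEN = 20


@dataclass(frozen=True)
class Scoring:
    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -3.0
    gap_extend: float = -1.0


def revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    out = np.full(arr.size, 4, dtype=np.uint8)
    for code, val in _CODE.items():
        out[arr == code] = val
    if not np.isin(arr, list(_CODE)).all():
        raise AlignmentError("read contains characters outside A/C/G/T/N")
    return out


@dataclass
class ReadAlignment:
    """A read placed on one reference.

    ``aligned_pairs`` lists ``(read_offset, ref_offset)`` tuples in reference
    order; a ``None`` read offset marks a deletion (gap in the read), a
    ``None`` reference offset an insertion (extra read base).
    """

    read_id: str
    gene_id: str
    ref_start: int
    aligned_pairs: list[tuple[int | None, int | None]]
    read_sequence: str
    n_mismatches: int
    score: float
    unique: bool = True
    strand: str = "+"
    qualities: list[int] | None = None


@dataclass(frozen=True)
class UnassignedRead:
    read_id: str
    reason: str  # low_score | multimapped | too_short | unmapped


@dataclass
class PileupMatrix:
    """Per-gene, per-position counts of observed A/C/G/T and deletions.

    ``counts[gene_id]`` is an ``(L, 5)`` integer matrix with columns A, C, G,
    T, del.  QC counters track reads that were not assigned.
    """

    counts: dict[str, np.ndarray]
    n_assigned: int = 0
    n_multimapped: int = 0
    n_low_score: int = 0
    n_too_short: int = 0
    n_unmapped: int = 0

    @classmethod
    def empty(cls, genes: Iterable[TRNAGene]) -> "PileupMatrix":
        return cls(counts={g.gene_id: np.zeros((len(g.sequence), 5), dtype=np.int64) for g in genes})

    def base_counts(self, gene_id: str, offset: int) -> dict[str, int]:
        mat = self.counts[gene_id]
        if not (0 <= offset < mat.shape[0]):
            raise PileupError(f"{gene_id}: position {offset} outside pileup")
        return {c: int(mat[offset, i]) for i, c in enumerate(_COLS)}

    def to_frame(self, genes: Sequence[TRNAGene]) -> pd.DataFrame:
        """Export as the standard pileup table (1-based positions)."""
        rows = []
        for g in genes:
            mat = self.counts[g.gene_id]
            for pos in range(mat.shape[0]):
                a, c, gg, t, d = (int(x) for x in mat[pos])
                rows.append(
                    {
                        "gene_id": g.gene_id,
                        "position": pos + 1,
                        "canonical_label": canonical_position(g, pos),
                        "ref_base": g.sequence[pos],
                        "count_A": a, "count_C": c, "count_G": gg,
                        "count_T": t, "count_del": d,
                        "coverage": a + c + gg + t + d,
                    }
                )
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "PileupMatrix":
        counts = {}
        for gene_id, sub in frame.groupby("gene_id", sort=False):
            sub = sub.sort_values("position")
            mat = np.zeros((int(sub["position"].max()), 5), dtype=np.int64)
            pos = sub["position"].to_numpy() - 1
            for i, col in enumerate(("count_A", "count_C", "count_G", "count_T", "count_del")):
                mat[pos, i] = sub[col].to_numpy()
            counts[str(gene_id)] = mat
        return cls(counts=counts)


# ---------------------------------------------------------------------------
# Dynamic programming engine
# ---------------------------------------------------------------------------

def _batch_scores(reads: np.ndarray, ref: np.ndarray, sc: Scoring) -> np.ndarray:
    """Best glocal score of each encoded read (rows) against one reference.

    Three-state affine DP vectorised over reference columns and reads; the
    within-row deletion recurrence is computed as a running maximum (the
    affine gap cost is linear in run length, so the best run start can be
    carried as a prefix maximum).
    """
    n, read_len = reads.shape
    L = ref.size
    ma, mi, go, ge = sc.match, sc.mismatch, sc.gap_open, sc.gap_extend
    jidx = np.arange(L + 1, dtype=np.float64)

    M = np.zeros((n, L + 1))
    Ix = np.full((n, L + 1), _NEG)
    Iy = np.full((n, L + 1), _NEG)
    is_n_ref = ref == 4
    for i in range(1, read_len + 1):
        rb = reads[:, i - 1][:, None]
        sub = np.where((rb == ref[None, :]) & ~is_n_ref[None, :] & (rb != 4), ma, mi)
        best_prev = np.maximum(np.maximum(M, Ix), Iy)
        M_new = np.full((n, L + 1), _NEG)
        M_new[:, 1:] = best_prev[:, :-1] + sub
        Ix_new = np.maximum(np.maximum(M, Iy) + go, Ix + ge)
        base = np.maximum(M_new, Ix_new)
        u = base - ge * jidx[None, :]
        cm = np.maximum.accumulate(u, axis=1)
        Iy_new = np.full((n, L + 1), _NEG)
        Iy_new[:, 1:] = go + ge * (jidx[1:] - 1) + cm[:, :-1]
        M, Ix, Iy = M_new, Ix_new, Iy_new
    return np.maximum(np.maximum(M, Ix), Iy).max(axis=1)


def _single_alignment(read: np.ndarray, ref: np.ndarray, sc: Scoring):
    """Full DP with traceback for one read; returns (score, pairs, ref_start,
    n_mismatches).  Tie-breaks prefer match states and smaller reference end,
    which reproduces an ungapped placement whenever one is optimal."""
    read_len, L = read.size, ref.size
    ma, mi, go, ge = sc.match, sc.mismatch, sc.gap_open, sc.gap_extend
    jidx = np.arange(L + 1, dtype=np.float64)
    M = np.full((read_len + 1, L + 1), _NEG)
    Ix = np.full((read_len + 1, L + 1), _NEG)
    Iy = np.full((read_len + 1, L + 1), _NEG)
    M[0, :] = 0.0
    is_n_ref = ref == 4
    for i in range(1, read_len + 1):
        rb = read[i - 1]
        sub = np.where((ref == rb) & ~is_n_ref & (rb != 4), ma, mi)
        best_prev = np.maximum(np.maximum(M[i - 1], Ix[i - 1]), Iy[i - 1])
        M[i, 1:] = best_prev[:-1] + sub
        Ix[i] = np.maximum(np.maximum(M[i - 1], Iy[i - 1]) + go, Ix[i - 1] + ge)
        base = np.maximum(M[i], Ix[i])
        cm = np.maximum.accumulate(base - ge * jidx)
        Iy[i, 1:] = go + ge * (jidx[1:] - 1) + cm[:-1]

    final = np.stack([M[read_len], Ix[read_len], Iy[read_len]])
    score = float(final.max())
    # smallest reference end among optima; prefer M, then Ix, then Iy
    j = int(np.flatnonzero(final.max(axis=0) == score)[0])
    state = int(np.flatnonzero(final[:, j] == score)[0])

    pairs: list[tuple[int | None, int | None]] = []
    i = read_len
    n_mm = 0
    while i > 0:
        if state == 0:  # M consumed read i-1 and ref j-1
            pairs.append((i - 1, j - 1))
            if not (read[i - 1] == ref[j - 1] and read[i - 1] != 4 and not is_n_ref[j - 1]):
                n_mm += 1
            val = M[i, j] - (ma if (read[i - 1] == ref[j - 1] and read[i - 1] != 4 and not is_n_ref[j - 1]) else mi)
            i, j = i - 1, j - 1
            for s, mat in ((0, M), (1, Ix), (2, Iy)):
                if mat[i, j] == val:
                    state = s
                    break
        elif state == 1:  # Ix: read base unmatched (insertion)
            pairs.append((i - 1, None))
            val = Ix[i, j]
            if M[i - 1, j] + go == val:
                state = 0
            elif Iy[i - 1, j] + go == val:
                state = 2
            i -= 1
        else:  # Iy: reference base skipped (deletion)
            pairs.append((None, j - 1))
            val = Iy[i, j]
            if M[i, j - 1] + go == val:
                state = 0
            elif Ix[i, j - 1] + go == val:
                state = 1
            j -= 1
    pairs.reverse()
    return score, pairs, j, n_mm


def _ungapped_best(reads: np.ndarray, ref: np.ndarray, sc: Scoring):
    """Best ungapped placement of each read row: (score, offset).

    Only valid when the read fits inside the reference; N bases and N
    reference positions count as mismatches, matching the DP scoring.
    """
    n, read_len = reads.shape
    L = ref.size
    n_off = L - read_len + 1
    if n_off <= 0:
        return np.full(n, _NEG), np.zeros(n, dtype=np.int64)
    scores = np.empty((n, n_off))
    for off in range(n_off):
        window = ref[off : off + read_len]
        match = (reads == window[None, :]) & (reads != 4) & (window[None, :] != 4)
        m = match.sum(axis=1)
        scores[:, off] = m * sc.match + (read_len - m) * sc.mismatch
    best_off = scores.argmax(axis=1)
    return scores[np.arange(n), best_off], best_off


# ---------------------------------------------------------------------------
# Assignment
# ---------------------------------------------------------------------------

def _candidate_refs(genes: Sequence[TRNAGene], try_revcomp: bool):
    """(label, gene, strand, encoded reference) candidates."""
    cands = []
    for g in genes:
        cands.append((g, "+", _encode(g.sequence)))
        if try_revcomp:
            cands.append((g, "-", _encode(revcomp(g.sequence))))
    return cands


def align_read(
    read: str,
    genes: Sequence[TRNAGene],
    read_id: str = "read",
    scoring: Scoring = Scoring(),
    min_score_fraction: float = 0.7,
    try_revcomp: bool = False,
) -> ReadAlignment | UnassignedRead:
    """Glocally align one read against every reference.

    Returns the highest-scoring alignment if its score reaches
    ``min_score_fraction`` times the read length *and* is strictly greater
    than the best score on every other reference; otherwise an
    :class:`UnassignedRead` with reason ``low_score`` or ``multimapped``.
    Reads shorter than 20 nt are rejected as ``too_short``.
    """
    read = read.upper()
    if len(read) < _MIN_READ_LEN:
        return UnassignedRead(read_id, "too_short")
    enc = _encode(read)
    cands = _candidate_refs(genes, try_revcomp)
    if not cands:
        raise AlignmentError("no references supplied")
    scores = np.array([_batch_scores(enc[None, :], ref_enc, scoring)[0] for _, _, ref_enc in cands])
    order = np.argsort(-scores, kind="stable")
    best = order[0]
    if scores[best] < min_score_fraction * len(read):
        return UnassignedRead(read_id, "low_score")
    if len(cands) > 1 and scores[order[1]] == scores[best]:
        return UnassignedRead(read_id, "multimapped")
    gene, strand, ref_enc = cands[best]
    query = enc if strand == "+" else _encode(revcomp(read))
    ref_full = _encode(gene.sequence)
    # ties between gapped and ungapped optima resolve toward the ungapped
    # placement (smallest offset), matching the batch pileup route
    ug_score, ug_off = _ungapped_best(query[None, :], ref_full, scoring)
    if ug_score[0] == scores[best]:
        off = int(ug_off[0])
        pairs = [(i, off + i) for i in range(len(read))]
        ref_start = off
        n_mm = int(((query != ref_full[off : off + len(read)]) | (query == 4)).sum())
        score = float(ug_score[0])
    else:
        score, pairs, ref_start, n_mm = _single_alignment(query, ref_full, scoring)
    seq_for_pileup = read if strand == "+" else revcomp(read)
    return ReadAlignment(
        read_id=read_id,
        gene_id=gene.gene_id,
        ref_start=ref_start,
        aligned_pairs=pairs,
        read_sequence=seq_for_pileup,
        n_mismatches=n_mm,
        score=score,
        unique=True,
        strand=strand,
    )


def align_reads(
    reads: Iterable[tuple[str, str]],
    genes: Sequence[TRNAGene],
    scoring: Scoring = Scoring(),
    min_score_fraction: float = 0.7,
    try_revcomp: bool = False,
) -> list[ReadAlignment | UnassignedRead]:
    """Align a collection of ``(read_id, sequence)`` pairs (object-returning
    counterpart of :func:`align_and_pileup`, intended for moderate input
    sizes)."""
    return [
        align_read(seq, genes, read_id=rid, scoring=scoring,
                   min_score_fraction=min_score_fraction, try_revcomp=try_revcomp)
        for rid, seq in reads
    ]


def align_and_pileup(
    reads: Iterable[tuple[str, str]],
    genes: Sequence[TRNAGene],
    scoring: Scoring = Scoring(),
    min_score_fraction: float = 0.7,
    try_revcomp: bool = False,
) -> PileupMatrix:
    """Batch-align reads and accumulate a pileup without per-read objects.

    Reads are grouped by length and scored against every reference with the
    vectorised DP.  For each assigned read the best ungapped placement is
    computed; when it attains the DP optimum (ties broken toward the ungapped
    placement) its bases are accumulated directly, otherwise the read falls
    back to single-read traceback.  Produces the same pileup as
    :func:`build_pileup` over :func:`align_reads`.
    """
    pile = PileupMatrix.empty(genes)
    cands = _candidate_refs(genes, try_revcomp)
    by_len: dict[int, list[tuple[str, str]]] = {}
    for rid, seq in reads:
        seq = seq.upper()
        if len(seq) < _MIN_READ_LEN:
            pile.n_too_short += 1
            continue
        by_len.setdefault(len(seq), []).append((rid, seq))

    for read_len, group in by_len.items():
        n = len(group)
        enc = np.empty((n, read_len), dtype=np.uint8)
        for i, (_, seq) in enumerate(group):
            enc[i] = _encode(seq)
        score_mat = np.stack([_batch_scores(enc, ref_enc, scoring) for _, _, ref_enc in cands])
        best_idx = score_mat.argmax(axis=0)
        best = score_mat[best_idx, np.arange(n)]
        if len(cands) > 1:
            tmp = score_mat.copy()
            tmp[best_idx, np.arange(n)] = _NEG
            second = tmp.max(axis=0)
        else:
            second = np.full(n, _NEG)
        low = best < min_score_fraction * read_len
        multi = (~low) & (second == best)
        assigned = ~(low | multi)
        pile.n_low_score += int(low.sum())
        pile.n_multimapped += int(multi.sum())
        pile.n_assigned += int(assigned.sum())

        for ci, (gene, strand, ref_enc) in enumerate(cands):
            sel = assigned & (best_idx == ci)
            if not sel.any():
                continue
            sub = enc[sel] if strand == "+" else _encode_revcomp_batch(enc[sel])
            ug_score, ug_off = _ungapped_best(sub, _encode(gene.sequence), scoring)
            fast = ug_score == best[sel]
            mat = pile.counts[gene.gene_id]
            if fast.any():
                rows = sub[fast]
                offs = ug_off[fast]
                pos = offs[:, None] + np.arange(read_len)[None, :]
                codes = rows.astype(np.int64)
                keep = codes < 4  # N bases are not counted
                np.add.at(mat, (pos[keep], codes[keep]), 1)
            if (~fast).any():
                ref_full = _encode(gene.sequence)
                idxs = np.flatnonzero(sel)[~fast]
                for i in idxs:
                    _, pairs, _, _ = _single_alignment(
                        enc[i] if strand == "+" else _encode_revcomp_batch(enc[i][None, :])[0],
                        ref_full, scoring)
                    seq_codes = enc[i] if strand == "+" else _encode_revcomp_batch(enc[i][None, :])[0]
                    for q, r in pairs:
                        if r is None:
                            continue
                        if q is None:
                            mat[r, 4] += 1
                        elif seq_codes[q] < 4:
                            mat[r, seq_codes[q]] += 1
    return pile


def _encode_revcomp_batch(enc: np.ndarray) -> np.ndarray:
    comp = np.array([3, 2, 1, 0, 4], dtype=np.uint8)
    return comp[enc][:, ::-1]


# ---------------------------------------------------------------------------
# SAM ingestion and pileup construction
# ---------------------------------------------------------------------------

@dataclass
class SamIngest:
    alignments: list[ReadAlignment]
    n_secondary: int = 0
    n_supplementary: int = 0
    n_unmapped: int = 0


def read_sam(sam_text: str, genes: Sequence[TRNAGene]) -> SamIngest:
    """Convert primary mapped SAM records to :class:`ReadAlignment` objects.

    Secondary (0x100) and supplementary (0x800) records are dropped and
    counted; unmapped records are counted.  Reference names must match gene
    identifiers.
    """
    gene_by_id = {g.gene_id: g for g in genes}
    result = SamIngest(alignments=[])
    with tempfile.NamedTemporaryFile("w", suffix=".sam", delete=False) as fh:
        fh.write(sam_text)
        path = fh.name
    try:
        with pysam.AlignmentFile(path, "r", check_sq=False) as sam:
            for rec in sam:
                if rec.is_unmapped:
                    result.n_unmapped += 1
                    continue
                if rec.is_secondary:
                    result.n_secondary += 1
                    continue
                if rec.is_supplementary:
                    result.n_supplementary += 1
                    continue
                if rec.reference_name not in gene_by_id:
                    raise AlignmentError(f"SAM reference {rec.reference_name!r} not in gene set")
                gene = gene_by_id[rec.reference_name]
                seq = rec.query_sequence or ""
                # soft-clipped query bases appear as (q, None) pairs and are
                # skipped by the pileup, like insertions
                pairs = [(q, r) for q, r in rec.get_aligned_pairs() if not (q is None and r is None)]
                n_mm = 0
                for q, r in pairs:
                    if q is not None and r is not None and seq and seq[q] != gene.sequence[r]:
                        n_mm += 1
                result.alignments.append(
                    ReadAlignment(
                        read_id=rec.query_name,
                        gene_id=gene.gene_id,
                        ref_start=rec.reference_start,
                        aligned_pairs=pairs,
                        read_sequence=seq,
                        n_mismatches=n_mm,
                        score=0.0,
                        unique=True,
                        strand="-" if rec.is_reverse else "+",
                        qualities=list(rec.query_qualities) if rec.query_qualities is not None else None,
                    )
                )
    finally:
        os.unlink(path)
    return result


def build_pileup(
    alignments: Iterable[ReadAlignment | UnassignedRead],
    genes: Sequence[TRNAGene],
    min_base_quality: int = 0,
) -> PileupMatrix:
    """Tally observed bases per reference position.

    Every aligned read base increments its (position, base) cell; deletions
    increment the ``del`` column; insertions relative to the reference are
    skipped.  Base-quality filtering applies only when an alignment carries
    qualities.
    """
    pile = PileupMatrix.empty(genes)
    lengths = {g.gene_id: len(g.sequence) for g in genes}
    for aln in alignments:
        if isinstance(aln, UnassignedRead):
            if aln.reason == "multimapped":
                pile.n_multimapped += 1
            elif aln.reason == "too_short":
                pile.n_too_short += 1
            elif aln.reason == "unmapped":
                pile.n_unmapped += 1
            else:
                pile.n_low_score += 1
            continue
        if aln.gene_id not in pile.counts:
            raise PileupError(f"alignment references unknown gene {aln.gene_id!r}")
        mat = pile.counts[aln.gene_id]
        L = lengths[aln.gene_id]
        pile.n_assigned += 1
        for q, r in aln.aligned_pairs:
            if r is None:
                continue
            if not (0 <= r < L):
                raise PileupError(f"{aln.read_id}: alignment exceeds {aln.gene_id} bounds")
            if q is None:
                mat[r, 4] += 1
                continue
            if aln.qualities is not None and min_base_quality > 0 and aln.qualities[q] < min_base_quality:
                continue
            base = aln.read_sequence[q]
            idx = {"A": 0, "C": 1, "G": 2, "T": 3}.get(base)
            if idx is not None:
                mat[r, idx] += 1
    return pile
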