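"""Local alignment hits, interval algebra, and merged-region ANI.

Hits can be read from BLAST tabular (``-outfmt 6``) files or computed by
the built-in aligner: a k-mer-seeded, banded Smith-Waterman with affine
gap penalties that searches both strands and reports multiple HSPs by
masking the query span of each reported HSP before re-searching. It is a
desk-scale stand-in for blastn: the scoring defaults are blastn-like and
E-values use the Karlin-Altschul form E = K*m*n*exp(-lambda*S) with
documented ungapped constants, not constants fitted to BLAST output.

ANI here is the coverage-based quantity used for viral catalogs: the
percentage of the query genome covered by the union of alignment regions
with identity >= 90% and length >= 500 bp.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from numba import njit

# --------------------------------------------------------------------------
# data types
# --------------------------------------------------------------------------

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_MASK_CODE = 4  # sentinel: never matches anything


@dataclass(frozen=True)
class AlignmentHit:
    """One HSP in BLAST-tabular semantics (1-based inclusive coordinates).

    ``s_start > s_end`` marks a minus-strand subject hit.
    """

    query_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.q_start > self.q_end:
            raise ValueError(f"q_start > q_end for {self.query_id}")
        if self.aln_length < 1:
            raise ValueError("aln_length must be >= 1")
        if not 0.0 <= self.pct_identity <= 100.0:
            raise ValueError("pct_identity outside [0, 100]")

    @property
    def minus_strand(self) -> bool:
        return self.s_start > self.s_end


@dataclass(frozen=True)
class ScoringParams:
    """Toy-aligner scoring; blastn-like defaults.

    Penalties are positive magnitudes. ``lambda_`` and ``karlin_k`` are the
    ungapped Karlin-Altschul constants used for E-values and bit scores.
    """

    match: int = 2
    mismatch: int = 3
    gap_open: int = 5
    gap_extend: int = 2
    word_size: int = 11
    lambda_: float = 1.28
    karlin_k: float = 0.46


DEFAULT_SCORING = ScoringParams()


@dataclass(frozen=True)
class IntervalSet:
    """Disjoint, sorted, non-empty 0-based half-open intervals on one sequence."""

    intervals: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        prev_end = None
        for start, end in self.intervals:
            if end <= start:
                raise ValueError(f"empty or inverted interval [{start}, {end})")
            if prev_end is not None and start <= prev_end:
                raise ValueError("intervals overlap or are unsorted")
            prev_end = end

    @property
    def covered_bp(self) -> int:
        return sum(end - start for start, end in self.intervals)


# --------------------------------------------------------------------------
# BLAST tabular I/O
# --------------------------------------------------------------------------

def read_hits_tabular(path: str | Path) -> list[AlignmentHit]:
    """Read BLAST ``-outfmt 6`` (12 tab-separated columns) into hits.

    Malformed lines are rejected with their 1-based line number.
    """
    hits: list[AlignmentHit] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ValueError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, "
                    f"got {len(fields)}"
                )
            try:
                hits.append(
                    AlignmentHit(
                        query_id=fields[0],
                        subject_id=fields[1],
                        pct_identity=float(fields[2]),
                        aln_length=int(fields[3]),
                        mismatches=int(fields[4]),
                        gap_opens=int(fields[5]),
                        q_start=int(fields[6]),
                        q_end=int(fields[7]),
                        s_start=int(fields[8]),
                        s_end=int(fields[9]),
                        evalue=float(fields[10]),
                        bitscore=float(fields[11]),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return hits


def write_hits_tabular(hits: Iterable[AlignmentHit], path: str | Path) -> None:
    """Write hits as BLAST ``-outfmt 6``; round-trips with :func:`read_hits_tabular`."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    [
                        h.query_id,
                        h.subject_id,
                        f"{h.pct_identity:.3f}",
                        str(h.aln_length),
                        str(h.mismatches),
                        str(h.gap_opens),
                        str(h.q_start),
                        str(h.q_end),
                        str(h.s_start),
                        str(h.s_end),
                        f"{h.evalue:.3g}",
                        f"{h.bitscore:.1f}",
                    ]
                )
                + "\n"
            )


# --------------------------------------------------------------------------
# sequence encoding / seeding
# --------------------------------------------------------------------------

def encode_seq(seq: str) -> np.ndarray:
    """Encode an ACGT string as int8 codes; reject other characters."""
    if not seq:
        raise ValueError("empty sequence")
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    codes = np.full(arr.shape, -1, dtype=np.int8)
    for base, code in _BASE_CODE.items():
        codes[arr == ord(base)] = code
    if (codes < 0).any():
        bad = seq[int(np.argmax(codes < 0))]
        raise ValueError(f"non-ACGT character {bad!r} in sequence")
    return codes


def revcomp(seq: str) -> str:
    return seq.upper().translate(str.maketrans("ACGT", "TGCA"))[::-1]


def _kmer_ints(codes: np.ndarray, k: int) -> np.ndarray:
    """Packed k-mer integers per window; -1 where the window touches a mask."""
    n = codes.shape[0]
    if n < k:
        return np.empty(0, dtype=np.int64)
    valid = codes < _MASK_CODE
    acc = np.zeros(n - k + 1, dtype=np.int64)
    ok = np.ones(n - k + 1, dtype=bool)
    for t in range(k):
        acc = acc * 4 + codes[t : n - k + 1 + t]
        ok &= valid[t : n - k + 1 + t]
    acc[~ok] = -1
    return acc


def _seed_diagonals(q_codes: np.ndarray, s_codes: np.ndarray, k: int) -> list[int]:
    """Sorted unique diagonals (j - i) with at least one shared k-mer."""
    s_kmers = _kmer_ints(s_codes, k)
    index: dict[int, list[int]] = {}
    for j, km in enumerate(s_kmers):
        if km >= 0:
            index.setdefault(int(km), []).append(j)
    diags: set[int] = set()
    q_kmers = _kmer_ints(q_codes, k)
    for i, km in enumerate(q_kmers):
        if km >= 0:
            for j in index.get(int(km), ()):
                diags.add(j - i)
    return sorted(diags)


def _cluster_diagonals(diags: Sequence[int], gap: int = 64) -> list[tuple[int, int]]:
    """Group nearby diagonals into (lo, hi) bands."""
    bands: list[tuple[int, int]] = []
    lo = hi = diags[0]
    for d in diags[1:]:
        if d - hi > gap:
            bands.append((lo, hi))
            lo = d
        hi = d
    bands.append((lo, hi))
    return bands


# --------------------------------------------------------------------------
# banded affine Smith-Waterman (numba kernel)
# --------------------------------------------------------------------------

_NEG = np.int64(-(10**12))


@njit(cache=False)
def _sw_banded(q, s, lo, hi, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    """Affine-gap Smith-Waterman restricted to diagonals j - i in [lo, hi].

    Returns (score, qs, qe, ss, se, matches, mismatches, gap_opens, aln_len)
    with 0-based half-open spans; score 0 means no positive-scoring cell.
    """
    m = q.shape[0]
    n = s.shape[0]
    W = hi - lo + 1
    H = np.full((m + 1, W + 2), _NEG, dtype=np.int64)
    E = np.full((m + 1, W + 2), _NEG, dtype=np.int64)
    F = np.full((m + 1, W + 2), _NEG, dtype=np.int64)
    src = np.zeros((m + 1, W + 2), dtype=np.uint8)
    esrc = np.zeros((m + 1, W + 2), dtype=np.uint8)
    fsrc = np.zeros((m + 1, W + 2), dtype=np.uint8)

    best = np.int64(0)
    bi = -1
    bc = -1
    for i in range(0, m + 1):
        jlo = i + lo
        jhi = i + hi
        if jlo < 0:
            jlo = 0
        if jhi > n:
            jhi = n
        for j in range(jlo, jhi + 1):
            c = j - i - lo + 1
            if i == 0 or j == 0:
                H[i, c] = 0
                continue
            sub = match if q[i - 1] == s[j - 1] else -mismatch
            if q[i - 1] >= 4 or s[j - 1] >= 4:
                sub = -mismatch
            # E: gap in query axis (consume subject base), move left
            e_open = H[i, c - 1] - gap_open - gap_extend
            e_ext = E[i, c - 1] - gap_extend
            if e_open >= e_ext:
                E[i, c] = e_open
                esrc[i, c] = 1
            else:
                E[i, c] = e_ext
                esrc[i, c] = 0
            # F: gap in subject axis (consume query base), move up
            f_open = H[i - 1, c + 1] - gap_open - gap_extend
            f_ext = F[i - 1, c + 1] - gap_extend
            if f_open >= f_ext:
                F[i, c] = f_open
                fsrc[i, c] = 1
            else:
                F[i, c] = f_ext
                fsrc[i, c] = 0
            diag = H[i - 1, c]
            h = np.int64(0)
            b = np.uint8(0)
            if diag > _NEG // 2 and diag + sub > h:
                h = diag + sub
                b = 1
            if E[i, c] > h:
                h = E[i, c]
                b = 2
            if F[i, c] > h:
                h = F[i, c]
                b = 3
            H[i, c] = h
            src[i, c] = b
            if h > best:
                best = h
                bi = i
                bc = c

    if best <= 0:
        return (np.int64(0), 0, 0, 0, 0, 0, 0, 0, 0)

    # traceback
    i = bi
    c = bc
    matches = 0
    mism = 0
    gopens = 0
    alen = 0
    state = 0  # 0 = H, 1 = E, 2 = F
    while True:
        j = i + c + lo - 1
        if state == 0:
            b = src[i, c]
            if b == 0 or H[i, c] <= 0:
                break
            if b == 1:
                alen += 1
                if q[i - 1] == s[j - 1] and q[i - 1] < 4:
                    matches += 1
                else:
                    mism += 1
                i -= 1
            elif b == 2:
                state = 1
            else:
                state = 2
        elif state == 1:
            alen += 1
            opened = esrc[i, c]
            c -= 1
            if opened == 1:
                gopens += 1
                state = 0
        else:
            alen += 1
            opened = fsrc[i, c]
            i -= 1
            c += 1
            if opened == 1:
                gopens += 1
                state = 0
    qs = i
    qe = bi
    ss = i + c + lo - 1
    se = bi + bc + lo - 1
    return (best, qs, qe, ss, se, matches, mism, gopens, alen)


# --------------------------------------------------------------------------
# multi-HSP local alignment
# --------------------------------------------------------------------------

_BAND_PAD = 24


def _best_hsp_one_strand(
    q_codes: np.ndarray, s_codes: np.ndarray, params: ScoringParams
) -> tuple | None:
    """Best-scoring HSP between the (possibly masked) query and subject codes."""
    diags = _seed_diagonals(q_codes, s_codes, params.word_size)
    if not diags:
        return None
    best = None
    for lo, hi in _cluster_diagonals(diags):
        res = _sw_banded(
            q_codes,
            s_codes,
            lo - _BAND_PAD,
            hi + _BAND_PAD,
            params.match,
            params.mismatch,
            params.gap_open,
            params.gap_extend,
        )
        if res[0] > 0 and (best is None or res[0] > best[0]):
            best = res
    return best


def _hit_from_raw(
    raw: tuple,
    strand: str,
    query_id: str,
    subject_id: str,
    m: int,
    n: int,
    params: ScoringParams,
) -> AlignmentHit:
    score, qs, qe, ss, se, matches, mism, gopens, alen = raw
    pct = 100.0 * matches / alen
    bitscore = (params.lambda_ * score - math.log(params.karlin_k)) / math.log(2.0)
    evalue = params.karlin_k * m * n * math.exp(-params.lambda_ * float(score))
    if strand == "+":
        s_start, s_end = ss + 1, se
    else:
        # coordinates were computed on the reverse complement
        s_start, s_end = n - ss, n - se + 1
    return AlignmentHit(
        query_id=query_id,
        subject_id=subject_id,
        pct_identity=pct,
        aln_length=int(alen),
        mismatches=int(mism),
        gap_opens=int(gopens),
        q_start=int(qs) + 1,
        q_end=int(qe),
        s_start=int(s_start),
        s_end=int(s_end),
        evalue=float(evalue),
        bitscore=float(bitscore),
    )


def local_align_pair(
    query: str,
    subject: str,
    params: ScoringParams = DEFAULT_SCORING,
    max_hsps: int = 25,
    query_id: str = "query",
    subject_id: str = "subject",
) -> list[AlignmentHit]:
    """Local alignments between two sequences, blastn-style.

    Both strands are searched; after each reported HSP its query span is
    masked and the search repeats, up to ``max_hsps`` HSPs. Hits are ordered
    by bitscore (desc), then query start (asc), then subject id.
    """
    q_codes = encode_seq(query)
    s_plus = encode_seq(subject)
    s_minus = encode_seq(revcomp(subject))
    m, n = len(query), len(subject)

    hits: list[AlignmentHit] = []
    work = q_codes.copy()
    while len(hits) < max_hsps:
        cand = []
        raw_p = _best_hsp_one_strand(work, s_plus, params)
        if raw_p is not None:
            cand.append(("+", raw_p))
        raw_m = _best_hsp_one_strand(work, s_minus, params)
        if raw_m is not None:
            cand.append(("-", raw_m))
        if not cand:
            break
        strand, raw = max(cand, key=lambda t: t[1][0])
        hits.append(_hit_from_raw(raw, strand, query_id, subject_id, m, n, params))
        work[raw[1] : raw[2]] = _MASK_CODE
    hits.sort(key=lambda h: (-h.bitscore, h.q_start, h.subject_id))
    return hits


# --------------------------------------------------------------------------
# hit filtering, interval merging, ANI
# --------------------------------------------------------------------------

def qualifying_hits(
    hits: Iterable[AlignmentHit],
    min_identity: float = 90.0,
    min_len: int = 500,
) -> list[AlignmentHit]:
    """Hits with identity >= ``min_identity`` and length >= ``min_len`` (inclusive)."""
    return [
        h for h in hits if h.pct_identity >= min_identity and h.aln_length >= min_len
    ]


def _span_on_axis(hit: AlignmentHit, axis: str) -> tuple[int, int]:
    """0-based half-open span of a hit on the query or subject axis."""
    if axis == "query":
        return hit.q_start - 1, hit.q_end
    if axis == "subject":
        lo, hi = sorted((hit.s_start, hit.s_end))
        return lo - 1, hi
    raise ValueError(f"axis must be 'query' or 'subject', got {axis!r}")


def union_intervals(spans: Iterable[tuple[int, int]]) -> IntervalSet:
    """Union of 0-based half-open spans as a canonical IntervalSet."""
    ordered = sorted((s, e) for s, e in spans if e > s)
    merged: list[tuple[int, int]] = []
    for s, e in ordered:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return IntervalSet(intervals=tuple(merged))


def merge_intervals(hits: Sequence[AlignmentHit], axis: str = "query") -> IntervalSet:
    """Union of hit spans on one axis; all hits must share the id on that axis."""
    if hits:
        key = "query_id" if axis == "query" else "subject_id"
        ids = {getattr(h, key) for h in hits}
        if len(ids) > 1:
            raise ValueError(f"mixed ids on {axis} axis: {sorted(ids)}")
    return union_intervals(_span_on_axis(h, axis) for h in hits)


def compute_ani(
    hits: Sequence[AlignmentHit],
    query_len: int,
    min_identity: float = 90.0,
    min_len: int = 500,
) -> float:
    """Coverage-based ANI: percent of the query covered by merged qualifying hits."""
    if query_len < 1:
        raise ValueError("query_len must be >= 1")
    kept = qualifying_hits(hits, min_identity=min_identity, min_len=min_len)
    covered = merge_intervals(kept, axis="query").covered_bp
    return 100.0 * covered / query_len
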