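"""Phage-host network inference from CRISPR spacers and sequence homology.

Spacer evidence: a spacer links its MAG to a phage when it matches the
phage genome full-length (either strand) with at most one mismatch — for
typical <= 50 bp spacers this realizes the ">95% of spacer length" rule
as full-length ungapped matching. Homology evidence: an alignment hit
with identity strictly above 90% over strictly more than 500 bp.

A minimal exact-repeat CRISPR detector is included for synthetic MAGs;
spacers from a dedicated detector can also be supplied directly, which is
the fidelity-preserving path for real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .alignment import AlignmentHit, encode_seq, revcomp
from .constants import METHANOGEN_GENERA
from .lifestyle import is_lytic


@dataclass(frozen=True)
class Spacer:
    spacer_id: str
    mag_id: str
    sequence: str
    source: str = "detected"  # or "provided"

    def __post_init__(self) -> None:
        if not self.sequence or set(self.sequence.upper()) - set("ACGT"):
            raise ValueError(f"{self.spacer_id}: sequence must be non-empty ACGT")


@dataclass(frozen=True)
class SpacerMatch:
    spacer_id: str
    mag_id: str
    phage_id: str
    position: int  # 0-based start on the phage plus strand
    strand: str
    mismatches: int


@dataclass(frozen=True)
class HomologyMatch:
    phage_id: str
    mag_id: str
    pct_identity: float
    aln_length: int


@dataclass(frozen=True)
class HostAssignment:
    phage_id: str
    mag_id: str
    genus: str
    method: str  # spacer | homology | both
    evidence: tuple = field(default=())

    def __post_init__(self) -> None:
        if self.method not in ("spacer", "homology", "both"):
            raise ValueError(f"unknown method {self.method!r}")


# --------------------------------------------------------------------------
# CRISPR array detection (exact repeats)
# --------------------------------------------------------------------------

def detect_crispr_arrays(
    mag_id: str,
    mag_seq: str,
    repeat_len: tuple[int, int] = (23, 47),
    spacer_len: tuple[int, int] = (20, 50),
    min_units: int = 3,
) -> list[Spacer]:
    """Find CRISPR-like arrays of >= ``min_units`` exact repeat copies.

    Repeat copies must be identical within an array and separated by
    spacers whose lengths lie in ``spacer_len``; spacers are emitted in
    genomic order. Longer repeats are preferred: once an array is found,
    shorter-repeat shadows of the same region are suppressed.
    """
    seq = mag_seq.upper()
    n = len(seq)
    rmin, rmax = repeat_len
    smin, smax = spacer_len
    used = np.zeros(n, dtype=bool)
    spacers: list[Spacer] = []
    candidates: list[tuple[int, list[int]]] = []  # (repeat_len, repeat starts)

    for r in range(min(rmax, n), rmin - 1, -1):
        occ: dict[str, list[int]] = {}
        for i in range(n - r + 1):
            occ.setdefault(seq[i : i + r], []).append(i)
        for positions in occ.values():
            if len(positions) < min_units:
                continue
            # maximal runs with spacer-sized gaps between consecutive copies
            run = [positions[0]]
            runs = []
            for p in positions[1:]:
                gap = p - (run[-1] + r)
                if smin <= gap <= smax:
                    run.append(p)
                else:
                    runs.append(run)
                    run = [p]
            runs.append(run)
            for run in runs:
                if len(run) >= min_units:
                    candidates.append((r, run))

    # a repeat extended into a shared spacer prefix (or truncated) shadows the
    # true array with fewer or equal copies, so prefer more units, then longer
    # repeats, and suppress overlaps greedily
    candidates.sort(key=lambda a: (-len(a[1]), -a[0], a[1][0]))
    arrays: list[tuple[int, list[int]]] = []
    for r, run in candidates:
        lo, hi = run[0], run[-1] + r
        if used[lo:hi].any():
            continue
        used[lo:hi] = True
        arrays.append((r, run))

    arrays.sort(key=lambda a: a[1][0])
    for r, run in arrays:
        for a, b in zip(run, run[1:]):
            start, end = a + r, b
            spacers.append(
                Spacer(
                    spacer_id=f"{mag_id}_sp{len(spacers) + 1}",
                    mag_id=mag_id,
                    sequence=seq[start:end],
                    source="detected",
                )
            )
    return spacers


# --------------------------------------------------------------------------
# spacer and homology matching
# --------------------------------------------------------------------------

def _hamming_scan(spacer_codes: np.ndarray, genome_codes: np.ndarray) -> np.ndarray:
    """Mismatch count of the spacer at every start position of the genome."""
    k = spacer_codes.size
    n = genome_codes.size
    if n < k:
        return np.empty(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(genome_codes, k)
    return (windows != spacer_codes).sum(axis=1)


def spacer_match(
    spacers: Iterable[Spacer],
    phages: Mapping[str, str],
    max_mismatch: int = 1,
) -> list[SpacerMatch]:
    """Full-length ungapped spacer scan against both strands of each phage.

    A match is retained iff its Hamming mismatch count is <= ``max_mismatch``.
    Spacers longer than a phage genome simply yield no match there.
    """
    encoded = {pid: encode_seq(seq) for pid, seq in phages.items()}
    matches: list[SpacerMatch] = []
    for sp in spacers:
        fwd = encode_seq(sp.sequence)
        rev = encode_seq(revcomp(sp.sequence))
        for pid in sorted(encoded):
            genome = encoded[pid]
            for strand, codes in (("+", fwd), ("-", rev)):
                mm = _hamming_scan(codes, genome)
                for pos in np.flatnonzero(mm <= max_mismatch):
                    matches.append(
                        SpacerMatch(
                            spacer_id=sp.spacer_id,
                            mag_id=sp.mag_id,
                            phage_id=pid,
                            position=int(pos),
                            strand=strand,
                            mismatches=int(mm[pos]),
                        )
                    )
    return matches


def homology_match(
    hits: Iterable[AlignmentHit],
    min_identity: float = 90.0,
    min_len: int = 500,
) -> list[HomologyMatch]:
    """Phage-MAG links from hits with identity > ``min_identity`` and
    length > ``min_len`` (both strict); one link per (phage, MAG) pair,
    keeping the longest qualifying hit as evidence."""
    best: dict[tuple[str, str], AlignmentHit] = {}
    for h in hits:
        if h.pct_identity > min_identity and h.aln_length > min_len:
            key = (h.query_id, h.subject_id)
            if key not in best or h.aln_length > best[key].aln_length:
                best[key] = h
    return [
        HomologyMatch(
            phage_id=q, mag_id=s, pct_identity=h.pct_identity, aln_length=h.aln_length
        )
        for (q, s), h in sorted(best.items())
    ]


# --------------------------------------------------------------------------
# evidence combination and reports
# --------------------------------------------------------------------------

def combine_evidence(
    spacer_links: Iterable[SpacerMatch],
    homology_links: Iterable[HomologyMatch],
    genus_of_mag: Mapping[str, str],
) -> list[HostAssignment]:
    """One assignment per (phage, MAG) pair, labelled by evidence method."""
    spacer_pairs: dict[tuple[str, str], list[SpacerMatch]] = {}
    for m in spacer_links:
        spacer_pairs.setdefault((m.phage_id, m.mag_id), []).append(m)
    homol_pairs: dict[tuple[str, str], list[HomologyMatch]] = {}
    for m in homology_links:
        homol_pairs.setdefault((m.phage_id, m.mag_id), []).append(m)

    assignments = []
    for phage_id, mag_id in sorted(spacer_pairs.keys() | homol_pairs.keys()):
        if mag_id not in genus_of_mag:
            raise KeyError(f"no genus for MAG {mag_id}")
        in_sp = (phage_id, mag_id) in spacer_pairs
        in_ho = (phage_id, mag_id) in homol_pairs
        method = "both" if (in_sp and in_ho) else ("spacer" if in_sp else "homology")
        evidence = tuple(spacer_pairs.get((phage_id, mag_id), [])) + tuple(
            homol_pairs.get((phage_id, mag_id), [])
        )
        assignments.append(
            HostAssignment(
                phage_id=phage_id,
                mag_id=mag_id,
                genus=genus_of_mag[mag_id],
                method=method,
                evidence=evidence,
            )
        )
    return assignments


@dataclass(frozen=True)
class HostRange:
    category: str  # specialist | generalist
    n_genera: int


def host_range(assignments: Iterable[HostAssignment]) -> dict[str, HostRange]:
    """Specialist (one host genus) vs generalist (two or more) per phage.

    MAG-level links collapse to genus level here; phages without any
    assignment are absent from the result.
    """
    genera: dict[str, set[str]] = {}
    for a in assignments:
        genera.setdefault(a.phage_id, set()).add(a.genus)
    return {
        pid: HostRange(
            category="specialist" if len(g) == 1 else "generalist", n_genera=len(g)
        )
        for pid, g in sorted(genera.items())
    }


def methanogen_lytic_report(
    assignments: Iterable[HostAssignment],
    scores: Mapping[str, float],
    methanogen_genera: frozenset[str] = METHANOGEN_GENERA,
) -> pd.DataFrame:
    """Assignments whose host genus is a methanogen, with lytic flags.

    Lytic iff the phage's lifestyle score is >= 0.5. A listed phage without
    a score is an error.
    """
    rows = []
    for a in sorted(assignments, key=lambda a: (a.phage_id, a.mag_id)):
        if a.genus not in methanogen_genera:
            continue
        if a.phage_id not in scores:
            raise KeyError(f"no lifestyle score for phage {a.phage_id}")
        score = scores[a.phage_id]
        rows.append(
            {
                "phage_id": a.phage_id,
                "mag_id": a.mag_id,
                "genus": a.genus,
                "method": a.method,
                "score": score,
                "lytic": is_lytic(score),
            }
        )
    return pd.DataFrame(
        rows, columns=["phage_id", "mag_id", "genus", "method", "score", "lytic"]
    )


def export_network(
    assignments: Iterable[HostAssignment], path: str | Path | None = None
) -> pd.DataFrame:
    """Bipartite phage-MAG edge list, stably sorted by phage then MAG."""
    rows = [
        {"phage_id": a.phage_id, "mag_id": a.mag_id, "genus": a.genus,
         "method": a.method}
        for a in sorted(assignments, key=lambda a: (a.phage_id, a.mag_id))
    ]
    df = pd.DataFrame(rows, columns=["phage_id", "mag_id", "genus", "method"])
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df


def read_network(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str)
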