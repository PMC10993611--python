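"""Viral catalog construction: contig filtering, dereplication into
species-level viral populations (VPs) at 95% ANI, novelty calling against
reference catalogs, and catalog summaries.

Dereplication is greedy and longest-first, using the same coverage-based
ANI throughout: a genome joins the first viral population whose
representative it covers at >= the ANI threshold (computed with the member
as query, mirroring identity relative to the shorter sequence), otherwise
it founds a new population. Representatives are therefore always the
longest member of their population.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .alignment import (
    AlignmentHit,
    DEFAULT_SCORING,
    ScoringParams,
    compute_ani,
    local_align_pair,
)
from .constants import ANIMAL_HOSTS, GIT_SITES


@dataclass(frozen=True)
class PhageRecord:
    """Per-genome metadata for one phage contig."""

    id: str
    length: int
    completeness: float
    animal_host: str
    git_site: str
    lifestyle_score: float
    taxonomy: str | None = None

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError(f"{self.id}: length must be >= 1")
        if not 0.0 <= self.completeness <= 100.0:
            raise ValueError(f"{self.id}: completeness outside [0, 100]")
        if self.animal_host not in ANIMAL_HOSTS:
            raise ValueError(f"{self.id}: unknown animal host {self.animal_host!r}")
        if self.git_site not in GIT_SITES:
            raise ValueError(f"{self.id}: unknown GIT site {self.git_site!r}")
        if not 0.0 <= self.lifestyle_score <= 1.0:
            raise ValueError(f"{self.id}: lifestyle score outside [0, 1]")


@dataclass
class ViralPopulation:
    """A species-level cluster (>= 95% ANI) with one representative genome."""

    vp_id: str
    representative: str
    members: set[str]
    animal_hosts: set[str] = field(default_factory=set)
    git_sites: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"{self.vp_id}: empty member set")
        if self.representative not in self.members:
            raise ValueError(f"{self.vp_id}: representative not among members")


# --------------------------------------------------------------------------
# filtering and dereplication
# --------------------------------------------------------------------------

def filter_contigs(
    records: Iterable[PhageRecord],
    min_len: int = 1500,
    min_completeness: float = 50.0,
) -> list[PhageRecord]:
    """Keep contigs with length >= ``min_len`` and completeness strictly
    greater than ``min_completeness``."""
    return [
        r for r in records if r.length >= min_len and r.completeness > min_completeness
    ]


def _word_set(seq: str, k: int) -> set[int]:
    from .alignment import _kmer_ints, encode_seq

    return {int(v) for v in _kmer_ints(encode_seq(seq), k) if v >= 0}


def dereplicate(
    genomes: Mapping[str, str],
    ani_threshold: float = 95.0,
    scoring: ScoringParams = DEFAULT_SCORING,
    max_hsps: int = 8,
    prescreen_word_frac: float = 0.1,
) -> list[ViralPopulation]:
    """Greedy longest-first dereplication at ``ani_threshold`` % ANI.

    Genomes are processed by length (desc, ties by id asc); each joins the
    first existing population whose representative it matches at
    >= ``ani_threshold`` ANI (member as query), else founds a new one.

    A CD-HIT-style short-word filter skips the alignment for pairs whose
    shared-word fraction (distinct aligner words of the member found in the
    representative) is below ``prescreen_word_frac``: a 95%-ANI pair built
    from >= 90%-identity regions covering >= 95% of the member shares, under
    roughly uniform substitution, at least ~0.95 * 0.9^k = 0.30 of its
    words, so the default 0.1 rejects only hopeless pairs. Set to 0 to
    disable (e.g. when divergence may be strongly clustered).
    """
    if not genomes:
        raise ValueError("no genomes to dereplicate")
    ids = list(genomes)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate genome ids")

    k = scoring.word_size
    order = sorted(ids, key=lambda g: (-len(genomes[g]), g))
    vps: list[ViralPopulation] = []
    rep_words: dict[str, set[int]] = {}
    for gid in order:
        seq = genomes[gid]
        words = _word_set(seq, k) if prescreen_word_frac > 0 else set()
        placed = False
        for vp in vps:
            if prescreen_word_frac > 0 and words:
                shared = len(words & rep_words[vp.representative]) / len(words)
                if shared < prescreen_word_frac:
                    continue
            rep_seq = genomes[vp.representative]
            hits = local_align_pair(
                seq,
                rep_seq,
                params=scoring,
                max_hsps=max_hsps,
                query_id=gid,
                subject_id=vp.representative,
            )
            if compute_ani(hits, query_len=len(seq)) >= ani_threshold:
                vp.members.add(gid)
                placed = True
                break
        if not placed:
            vps.append(
                ViralPopulation(
                    vp_id=f"VP_{len(vps) + 1:05d}",
                    representative=gid,
                    members={gid},
                )
            )
            if prescreen_word_frac > 0:
                rep_words[gid] = words or _word_set(seq, k)
    return vps


def annotate_populations(
    vps: Sequence[ViralPopulation], records: Mapping[str, PhageRecord]
) -> list[ViralPopulation]:
    """Fill animal-host and GIT-site unions from member metadata."""
    out = []
    for vp in vps:
        missing = vp.members - records.keys()
        if missing:
            raise KeyError(f"{vp.vp_id}: no metadata for {sorted(missing)}")
        out.append(
            replace(
                vp,
                members=set(vp.members),
                animal_hosts={records[m].animal_host for m in vp.members},
                git_sites={records[m].git_site for m in vp.members},
            )
        )
    return out


def assess_novelty(
    vps: Sequence[ViralPopulation],
    reference_hits: Sequence[AlignmentHit],
    query_lengths: Mapping[str, int],
    ani_threshold: float = 95.0,
) -> dict[str, str]:
    """Call each population ``novel`` or ``known`` against reference genomes.

    Hits must have VP representatives as queries and reference genomes as
    subjects. A population is novel iff its best per-reference ANI is
    below ``ani_threshold``.
    """
    by_query: dict[str, dict[str, list[AlignmentHit]]] = {}
    for h in reference_hits:
        by_query.setdefault(h.query_id, {}).setdefault(h.subject_id, []).append(h)

    verdicts: dict[str, str] = {}
    for vp in vps:
        rep = vp.representative
        if rep not in query_lengths:
            raise KeyError(f"no length for representative {rep}")
        best = 0.0
        for hits in by_query.get(rep, {}).values():
            best = max(best, compute_ani(hits, query_len=query_lengths[rep]))
        verdicts[vp.vp_id] = "novel" if best < ani_threshold else "known"
    return verdicts


# --------------------------------------------------------------------------
# summaries
# --------------------------------------------------------------------------

def proportion(count: int, total: int, dp: int = 2) -> float:
    """``100 * count / total`` rounded half-up to ``dp`` decimals."""
    if total < 1:
        raise ValueError("total must be >= 1")
    if not 0 <= count <= total:
        raise ValueError("count must be in [0, total]")
    q = Decimal(100) * Decimal(count) / Decimal(total)
    return float(q.quantize(Decimal(1).scaleb(-dp), rounding=ROUND_HALF_UP))


def specificity_summary(vps: Sequence[ViralPopulation]) -> dict:
    """Host-specificity summary: VP counts by number of animal hosts, plus
    per-host exclusive/shared counts (UpSet-style) with percentages."""
    for vp in vps:
        if not vp.animal_hosts:
            raise ValueError(f"{vp.vp_id}: empty animal-host set")
    total = len(vps)
    by_n: dict[int, int] = {}
    per_host: dict[str, dict[str, int]] = {}
    for vp in vps:
        n = len(vp.animal_hosts)
        by_n[n] = by_n.get(n, 0) + 1
        for host in vp.animal_hosts:
            d = per_host.setdefault(host, {"exclusive": 0, "shared": 0})
            d["exclusive" if n == 1 else "shared"] += 1
    return {
        "total": total,
        "by_host_count": dict(sorted(by_n.items())),
        "pct_by_host_count": {
            n: proportion(c, total) for n, c in sorted(by_n.items())
        },
        "per_host": {h: dict(d) for h, d in sorted(per_host.items())},
    }


def rarefaction_curve(
    incidence: Mapping[str, set[str]],
    n_perm: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Accumulation curve of unique VPs over random sample orderings.

    Returns a table with columns ``n_samples``, ``mean_vps``, ``sd_vps``.
    """
    if not incidence:
        raise ValueError("empty incidence map")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    samples = sorted(incidence)
    rng = np.random.default_rng(seed)
    n = len(samples)
    counts = np.zeros((n_perm, n), dtype=np.int64)
    for p in range(n_perm):
        order = rng.permutation(n)
        seen: set[str] = set()
        for k, idx in enumerate(order):
            seen |= incidence[samples[idx]]
            counts[p, k] = len(seen)
    return pd.DataFrame(
        {
            "n_samples": np.arange(1, n + 1),
            "mean_vps": counts.mean(axis=0),
            "sd_vps": counts.std(axis=0, ddof=0),
        }
    )
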