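"""Seeded synthetic phage communities with known ground truth.

Every generator is a pure function of its parameters and an explicit
integer seed, so outputs (including serialized FASTA/TSV) are
byte-identical across runs. The generators plant:

* genome families at controlled divergence (species at ``within_div``
  inside, ancestors effectively at random-sequence divergence between),
* organism-specific animal-host and GIT-site labels,
* MAGs carrying CRISPR arrays whose spacers are copied from phage
  genomes with 0, 1, or 3 mismatches (3-mismatch copies are decoys that
  a <=1-mismatch matcher must not recover),
* host-clustered ("coevolved") versus label-permuted ("null") trees, and
* bimodal lifestyle scores.

Mutation is substitution-only (no indels), so realized identity follows
the binomial expectation exactly and downstream ANI oracles stay exact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .constants import ANIMAL_HOSTS, DNA_ALPHABET, GIT_SITES, METHANOGEN_GENERA

_BASES = np.frombuffer(DNA_ALPHABET.encode(), dtype=np.uint8)

DEFAULT_GENUS_POOL = tuple(sorted(METHANOGEN_GENERA)) + (
    "Bacteroides",
    "Butyrivibrio",
    "Fibrobacter",
    "Prevotella",
    "Ruminococcus",
    "Treponema",
)


@dataclass
class SimTruth:
    """Ground truth for a simulated community."""

    species_of_genome: dict[str, str] = field(default_factory=dict)
    host_of_genome: dict[str, str] = field(default_factory=dict)
    planted_links: list[tuple[str, str, int]] = field(default_factory=list)
    tree_condition: dict[str, str] = field(default_factory=dict)
    lifestyle_truth: dict[str, str] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "species_of_genome": self.species_of_genome,
            "host_of_genome": self.host_of_genome,
            "planted_links": self.planted_links,
            "tree_condition": self.tree_condition,
            "lifestyle_truth": self.lifestyle_truth,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


# --------------------------------------------------------------------------
# sequences
# --------------------------------------------------------------------------

def random_genome(length: int, rng: np.random.Generator) -> str:
    """Uniform random ACGT sequence."""
    if length < 1:
        raise ValueError("length must be >= 1")
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


def mutate_genome(seq: str, divergence: float, seed: int) -> str:
    """Substitute each site independently with probability ``divergence``.

    Substituted sites change uniformly to one of the three other bases;
    length is preserved. Non-ACGT input is rejected.
    """
    if not 0.0 <= divergence <= 1.0:
        raise ValueError("divergence must be in [0, 1]")
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    codes = np.full(arr.shape, -1, dtype=np.int64)
    for k, b in enumerate(_BASES):
        codes[arr == b] = k
    if (codes < 0).any():
        raise ValueError("non-ACGT character in sequence")
    rng = np.random.default_rng(seed)
    hit = rng.random(codes.size) < divergence
    # uniform over the 3 other bases: add 1..3 mod 4
    shift = rng.integers(1, 4, size=codes.size)
    codes[hit] = (codes[hit] + shift[hit]) % 4
    return _BASES[codes].tobytes().decode()


# --------------------------------------------------------------------------
# phage catalog
# --------------------------------------------------------------------------

def simulate_catalog(
    n_species: int,
    members_per_species: int,
    genome_len: tuple[int, int] = (5000, 50000),
    within_div: float = 0.02,
    between_div: float = 0.25,
    n_hosts: int = len(ANIMAL_HOSTS),
    host_specificity: float = 1.0,
    lytic_fraction_true: float = 0.596,
    seed: int = 0,
) -> tuple[dict[str, str], pd.DataFrame, SimTruth]:
    """Planted-species phage catalog with metadata and ground truth.

    Each species descends from one independent random ancestor (pairwise
    divergence of random sequences is ~75%, far above ``between_div``);
    members are the ancestor mutated at ``within_div``. With probability
    ``host_specificity`` a species is single-host, else member hosts are
    drawn uniformly. Completeness is uniform on (50, 100] (inputs are
    post-filter by construction); lifestyle scores come from the bimodal
    score generator with lytic weight ``lytic_fraction_true``.
    """
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    if members_per_species < 1:
        raise ValueError("members_per_species must be >= 1")
    if not within_div < between_div:
        raise ValueError("require within_div < between_div (separable species)")
    if between_div > 0.7:
        raise ValueError("between_div above ~0.7 is not separable for random ancestors")
    if not 2 <= n_hosts <= len(ANIMAL_HOSTS):
        raise ValueError(f"n_hosts must be in [2, {len(ANIMAL_HOSTS)}]")

    rng = np.random.default_rng(seed)
    hosts = list(ANIMAL_HOSTS[:n_hosts])
    genomes: dict[str, str] = {}
    truth = SimTruth()
    rows = []
    n_total = n_species * members_per_species
    scores, lifestyles = simulate_lifestyle_scores(
        n_total,
        lytic_fraction=lytic_fraction_true,
        seed=int(rng.integers(0, 2**31)),
        return_truth=True,
    )
    gi = 0
    for si in range(n_species):
        species_id = f"sp{si + 1:04d}"
        length = int(rng.integers(genome_len[0], genome_len[1] + 1))
        ancestor = random_genome(length, rng)
        single_host = rng.random() < host_specificity
        species_host = hosts[rng.integers(0, len(hosts))]
        for mi in range(members_per_species):
            gid = f"{species_id}_g{mi + 1:03d}"
            genomes[gid] = mutate_genome(
                ancestor, within_div, seed=int(rng.integers(0, 2**31))
            )
            host = (
                species_host if single_host else hosts[rng.integers(0, len(hosts))]
            )
            truth.species_of_genome[gid] = species_id
            truth.host_of_genome[gid] = host
            truth.lifestyle_truth[gid] = lifestyles[gi]
            rows.append(
                {
                    "id": gid,
                    "length": length,
                    # (1 - U) with U in [0, 1) gives completeness on (50, 100]
                    "completeness": float(50.0 + (1.0 - rng.random()) * 50.0),
                    "animal_host": host,
                    "git_site": GIT_SITES[rng.integers(0, len(GIT_SITES))],
                    "lifestyle_score": scores[gi],
                }
            )
            gi += 1
    metadata = pd.DataFrame(rows)
    return genomes, metadata, truth


# --------------------------------------------------------------------------
# MAGs with CRISPR arrays
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedSpacer:
    spacer_id: str
    mag_id: str
    sequence: str
    phage_id: str
    phage_position: int
    mismatches: int


def simulate_mag_set(
    phages: Mapping[str, str],
    n_mags: int,
    spacers_per_mag: int = 4,
    repeat_len: int = 30,
    spacer_len: int = 32,
    mismatch_weights: Mapping[int, float] | None = None,
    genus_labels: Sequence[str] = DEFAULT_GENUS_POOL,
    mag_background_len: int = 20000,
    seed: int = 0,
) -> tuple[dict[str, str], list[PlantedSpacer], pd.DataFrame]:
    """MAGs carrying one CRISPR array each, spacers copied from phages.

    Spacer mismatch counts are drawn from ``mismatch_weights`` over
    {0, 1, 3}; 3-mismatch copies are decoys that a <=1-mismatch matcher
    must not recover. Arrays are (repeat, spacer) x k with k =
    ``spacers_per_mag`` identical repeat copies separating the spacers.
    Returns MAG sequences, planted-spacer truth, and the genus table.
    """
    if not phages:
        raise ValueError("phage set must be non-empty")
    if not 23 <= repeat_len <= 47:
        raise ValueError("repeat_len must be in [23, 47]")
    if not 20 <= spacer_len <= 50:
        raise ValueError("spacer_len must be in [20, 50]")
    if spacers_per_mag < 3:
        raise ValueError("need >= 3 spacers per array")
    if min(len(s) for s in phages.values()) < spacer_len:
        raise ValueError("spacers longer than the shortest source phage")
    weights = dict(mismatch_weights or {0: 0.6, 1: 0.2, 3: 0.2})
    if set(weights) - {0, 1, 3}:
        raise ValueError("mismatch counts must be in {0, 1, 3}")

    rng = np.random.default_rng(seed)
    mm_values = sorted(weights)
    mm_probs = np.array([weights[v] for v in mm_values], dtype=float)
    mm_probs /= mm_probs.sum()
    phage_ids = sorted(phages)

    mags: dict[str, str] = {}
    planted: list[PlantedSpacer] = []
    genus_rows = []
    for k in range(n_mags):
        mag_id = f"mag{k + 1:04d}"
        repeat = random_genome(repeat_len, rng)
        units = [repeat]
        for si in range(spacers_per_mag):
            pid = phage_ids[rng.integers(0, len(phage_ids))]
            pos = int(rng.integers(0, len(phages[pid]) - spacer_len + 1))
            clean = phages[pid][pos : pos + spacer_len]
            n_mm = mm_values[rng.choice(len(mm_values), p=mm_probs)]
            spacer = _apply_mismatches(clean, n_mm, rng)
            spacer_id = f"{mag_id}_sp{si + 1}"
            planted.append(
                PlantedSpacer(
                    spacer_id=spacer_id,
                    mag_id=mag_id,
                    sequence=spacer,
                    phage_id=pid,
                    phage_position=pos,
                    mismatches=n_mm,
                )
            )
            units.append(spacer)
            units.append(repeat)
        array = "".join(units)
        background = random_genome(mag_background_len, rng)
        insert_at = int(rng.integers(0, mag_background_len + 1))
        mags[mag_id] = background[:insert_at] + array + background[insert_at:]
        genus_rows.append(
            {
                "mag_id": mag_id,
                "genus": genus_labels[rng.integers(0, len(genus_labels))],
            }
        )
    genus_table = pd.DataFrame(genus_rows)
    genus_table["is_methanogen"] = genus_table["genus"].isin(METHANOGEN_GENERA)
    return mags, planted, genus_table


def _apply_mismatches(seq: str, n_mm: int, rng: np.random.Generator) -> str:
    if n_mm == 0:
        return seq
    positions = rng.choice(len(seq), size=n_mm, replace=False)
    out = list(seq)
    for pos in positions:
        alternatives = [b for b in DNA_ALPHABET if b != out[pos]]
        out[pos] = alternatives[rng.integers(0, 3)]
    return "".join(out)


# --------------------------------------------------------------------------
# labeled trees
# --------------------------------------------------------------------------

class _Node:
    __slots__ = ("name", "children")

    def __init__(self, name: str | None = None, children=None):
        self.name = name
        self.children = children or []  # list of (child, branch_length)

    def newick(self) -> str:
        return self._nwk() + ";"

    def _nwk(self) -> str:
        if not self.children:
            return self.name
        inner = ",".join(f"{c._nwk()}:{bl:.6f}" for c, bl in self.children)
        return f"({inner})"


def _random_binary_tree(
    tips: list[str], rng: np.random.Generator, mean_bl: float = 1.0
) -> _Node:
    """Random binary topology over ``tips`` with Exp(mean) branch lengths."""
    nodes = [_Node(name=t) for t in tips]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        parent = _Node(
            children=[
                (a, float(rng.exponential(mean_bl))),
                (b, float(rng.exponential(mean_bl))),
            ]
        )
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)]
        nodes.append(parent)
    return nodes[0]


def simulate_labeled_trees(
    n_trees: int,
    hosts: Sequence[str],
    tips_per_host: int,
    coevolution_strength: float,
    seed: int = 0,
    condition: str = "coevolved",
) -> tuple[list[str], list[dict[str, str]], SimTruth]:
    """Host-labeled Newick trees under a coevolved or null condition.

    Coevolved: one random binary subtree per host (exponential branch
    lengths, mean 1) joined by stems of length ``coevolution_strength``.
    Null: identical construction, then tip -> host labels are randomly
    permuted across all tips.
    """
    if len(hosts) < 3:
        raise ValueError("need >= 3 hosts")
    if tips_per_host < 2:
        raise ValueError("need >= 2 tips per host (no within-host pairs otherwise)")
    if coevolution_strength < 0:
        raise ValueError("coevolution_strength must be >= 0")
    if condition not in ("coevolved", "null"):
        raise ValueError("condition must be 'coevolved' or 'null'")

    rng = np.random.default_rng(seed)
    newicks: list[str] = []
    tip_maps: list[dict[str, str]] = []
    truth = SimTruth()
    for t in range(n_trees):
        tree_id = f"tree{t + 1:04d}"
        tip_hosts: dict[str, str] = {}
        subtrees = []
        for host in hosts:
            tips = [f"{tree_id}_{host}_{i + 1}" for i in range(tips_per_host)]
            for tip in tips:
                tip_hosts[tip] = host
            subtrees.append(_random_binary_tree(tips, rng))
        # join host subtrees pairwise; every join edge is a stem of length
        # coevolution_strength
        acc = subtrees[0]
        for sub in subtrees[1:]:
            acc = _Node(
                children=[(acc, coevolution_strength), (sub, coevolution_strength)]
            )
        if condition == "null":
            tips = sorted(tip_hosts)
            labels = [tip_hosts[t_] for t_ in tips]
            perm = rng.permutation(len(tips))
            tip_hosts = {tips[i]: labels[perm[i]] for i in range(len(tips))}
        newicks.append(acc.newick())
        tip_maps.append(tip_hosts)
        truth.tree_condition[tree_id] = condition
        for tip, host in tip_hosts.items():
            truth.host_of_genome[tip] = host
    return newicks, tip_maps, truth


# --------------------------------------------------------------------------
# lifestyle scores
# --------------------------------------------------------------------------

def simulate_lifestyle_scores(
    n: int,
    lytic_fraction: float,
    seed: int = 0,
    return_truth: bool = False,
):
    """Bimodal lifestyle scores in [0, 1].

    A mixture of two unimodal components: lytic scores are
    0.5 + 0.5*Beta(2, 2) (entirely >= 0.5, weight ``lytic_fraction``) and
    temperate scores are 0.5*Beta(2, 2) (entirely < 0.5). Component
    membership is drawn per phage (binomial sampling).
    """
    if not 0.0 <= lytic_fraction <= 1.0:
        raise ValueError("lytic_fraction must be in [0, 1]")
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    lytic = rng.random(n) < lytic_fraction
    beta = rng.beta(2.0, 2.0, size=n)
    scores = np.where(lytic, 0.5 + 0.5 * beta, 0.5 * beta)
    score_list = [float(s) for s in scores]
    if return_truth:
        labels = ["lytic" if flag else "temperate" for flag in lytic]
        return score_list, labels
    return score_list


# --------------------------------------------------------------------------
# serialization
# --------------------------------------------------------------------------

def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    """Plain FASTA writer with deterministic ordering (sorted ids)."""
    with open(path, "w") as fh:
        for name in sorted(sequences):
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_metadata(metadata: pd.DataFrame, path: str | Path) -> None:
    metadata.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_metadata(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
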