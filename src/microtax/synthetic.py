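"""Synthetic 16S-like communities, read fragments and sequencing errors.

Real genus-level 16S training collections have many taxa with wildly
unequal sequence counts (down to singletons), full-length sequences of
roughly 1500 bases, and a nested similarity structure: sequences cluster
tightly around a genus centroid, genus centroids cluster within higher
ranks.  The generator emulates that structure with a simple substitution
process: a random ancestor, optional order-like group centroids mutated
from it, genus centroids mutated from their group (or the ancestor), and
per-sequence i.i.d. substitutions away from the genus centroid.

Typical 16S identities motivate the defaults of :func:`default_community`:
genera within an order at roughly 94% identity (genus centroids 3% from
the group centroid), sequences within a genus at 97-98.5% identity
(within-genus rate 1.5%), and lognormal genus sizes with a median around
six sequences, singletons included.

Corruption operators mimic read errors: substitutions hit an exact
round(rate*n) number of positions with a base different from the original,
and indels insert or delete (50/50) a fixed-length block at round(rate*n)
anchor positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SyntheticCommunitySpec",
    "generate_community",
    "default_community",
    "sample_fragment",
    "corrupt_substitutions",
    "corrupt_indels",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _BASE_INDEX[_b] = _i


@dataclass
class SyntheticCommunitySpec:
    """Parameters of a synthetic community.

    sequences_per_genus may be a single int (all genera equal) or a
    per-genus array of counts (allowing singletons).  With n_groups set,
    genera are organised into order-like groups: group centroids diverge
    from a shared ancestor at group_divergence and genus centroids from
    their group centroid at centroid_divergence; without groups, genus
    centroids diverge from the ancestor directly at centroid_divergence.

    Two optional features emulate real 16S structure.  With
    variable_fraction < 1, between-taxon divergence is confined to
    n_variable_blocks evenly spaced variable regions (the V-region
    architecture of the gene: reads landing in conserved stretches carry
    little taxonomic signal, so short reads misclassify more often).
    With branch_length_model="exponential", each genus draws its own
    divergence from an exponential with mean centroid_divergence, giving
    a heavy tail of near-identical sister genera — the borderline taxa
    that dominate real misclassification.  With crowded_clade_size > 0,
    the last that many genera of every group form a clade of barely
    distinguishable genera, each diverging from a shared clade centroid
    at only crowded_divergence of the variable sites; real taxonomies
    always contain such borderline genera and they are what produces the
    read-length-dependent error gradient.  With n_twin_pairs > 0, the
    last clade member of that many groups becomes a sequence-level twin
    of its neighbour: its training sequences are near-copies (at
    twin_divergence per base) of the neighbour's, emulating the
    near-identical 16S sequences deposited under different genus names
    (Escherichia/Shigella-like) that put a floor under the error rate
    even for long reads.  Within-genus substitutions are
    always uniform over the whole sequence (strain and sequencing noise
    are not region-structured).
    """

    n_genera: int = 50
    sequences_per_genus: int | list[int] | np.ndarray = 10
    sequence_length: int = 1500
    centroid_divergence: float = 0.05
    within_genus_rate: float = 0.02
    n_groups: int | None = None
    group_divergence: float = 0.0
    variable_fraction: float = 1.0
    n_variable_blocks: int = 9
    branch_length_model: str = "fixed"
    crowded_clade_size: int = 0
    crowded_divergence: float = 0.012
    n_twin_pairs: int = 0
    twin_divergence: float = 0.003
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "centroid_divergence",
            "within_genus_rate",
            "group_divergence",
            "crowded_divergence",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 0.75):
                raise ValueError(f"{name} must be in [0, 0.75], got {v}")
        if not (0.0 < self.variable_fraction <= 1.0):
            raise ValueError("variable_fraction must be in (0, 1]")
        if not (0.0 <= self.twin_divergence <= 0.75):
            raise ValueError("twin_divergence must be in [0, 0.75]")
        if self.n_twin_pairs > 0:
            if self.crowded_clade_size < 2:
                raise ValueError("twin pairs require crowded clades of size >= 2")
            if self.n_twin_pairs > (self.n_groups or 1):
                raise ValueError("at most one twin pair per group")
        if self.branch_length_model not in ("fixed", "exponential"):
            raise ValueError("branch_length_model must be 'fixed' or 'exponential'")
        if self.sequence_length < 200:
            raise ValueError("sequence_length must be at least 200")
        if self.n_genera < 1:
            raise ValueError("need at least one genus")

    def variable_positions(self) -> np.ndarray:
        """Positions where between-taxon divergence may occur."""
        L = self.sequence_length
        if self.variable_fraction >= 1.0:
            return np.arange(L)
        block = max(1, int(L * self.variable_fraction / self.n_variable_blocks))
        margin = min(60, L // 20)
        starts = np.linspace(margin, L - margin - block, self.n_variable_blocks)
        mask = np.zeros(L, dtype=bool)
        for s in starts.astype(int):
            mask[s : s + block] = True
        return np.flatnonzero(mask)

    def genus_sizes(self) -> np.ndarray:
        if np.isscalar(self.sequences_per_genus):
            return np.full(self.n_genera, int(self.sequences_per_genus), dtype=np.int64)
        sizes = np.asarray(self.sequences_per_genus, dtype=np.int64)
        if sizes.size != self.n_genera or (sizes < 1).any():
            raise ValueError("per-genus sizes must give a positive count per genus")
        return sizes


def _mutate(
    seq: np.ndarray,
    rate: float,
    rng: np.random.Generator,
    positions: np.ndarray | None = None,
) -> np.ndarray:
    """I.i.d. substitutions: each eligible position flips to a different base
    with probability `rate`.  With `positions`, only those sites are eligible."""
    out = seq.copy()
    if positions is None:
        hit = np.flatnonzero(rng.random(seq.size) < rate)
    else:
        hit = positions[rng.random(positions.size) < rate]
    if hit.size:
        out[hit] = (out[hit] + rng.integers(1, 4, size=hit.size)) % 4
    return out


def generate_community(
    spec: SyntheticCommunitySpec,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Draw a community: FASTA-style records and a taxonomy table.

    Returns ``(records, taxonomy)`` where records are (id, sequence)
    pairs and the taxonomy has columns sequence_id, genus and (with
    groups) group.  Deterministic under the spec's seed.
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.sequence_length
    ancestor = rng.integers(0, 4, size=L)
    var_pos = spec.variable_positions()
    genus_names = [f"G{i + 1:03d}" for i in range(spec.n_genera)]
    groups: list[str] | None = None
    if spec.n_groups:
        group_centroids = [
            _mutate(ancestor, spec.group_divergence, rng, var_pos)
            for _ in range(spec.n_groups)
        ]
        groups = [f"O{(i % spec.n_groups) + 1}" for i in range(spec.n_genera)]
        parents = [group_centroids[i % spec.n_groups] for i in range(spec.n_genera)]
    else:
        parents = [ancestor] * spec.n_genera
    if spec.branch_length_model == "exponential":
        branch = np.minimum(
            rng.exponential(spec.centroid_divergence, size=spec.n_genera), 0.3
        )
    else:
        branch = np.full(spec.n_genera, spec.centroid_divergence)
    # crowded clades: per group, the last crowded_clade_size genera share a
    # clade centroid and diverge from it at crowded_divergence only
    clade_of: dict[int, int] = {}
    if spec.crowded_clade_size > 0:
        n_groups = spec.n_groups or 1
        for j in range(n_groups):
            members = [i for i in range(spec.n_genera) if i % n_groups == j]
            for i in members[-spec.crowded_clade_size :]:
                clade_of[i] = j
    centroids: list[np.ndarray] = []
    clade_centroids: dict[int, np.ndarray] = {}
    for i, (p, b) in enumerate(zip(parents, branch)):
        if i in clade_of:
            key = clade_of[i]
            if key not in clade_centroids:
                clade_centroids[key] = _mutate(p, b, rng, var_pos)
            centroids.append(
                _mutate(clade_centroids[key], spec.crowded_divergence, rng, var_pos)
            )
        else:
            centroids.append(_mutate(p, b, rng, var_pos))
    # twin pairs: in the first n_twin_pairs groups, the last clade member
    # becomes a sequence-level twin of the member before it — its training
    # sequences are near-copies of the other genus's sequences, emulating
    # (near-)identical 16S deposited under different genus names
    # (Escherichia/Shigella-like)
    twin_source: dict[int, int] = {}
    if spec.n_twin_pairs > 0:
        for t in range(spec.n_twin_pairs):
            members = sorted(i for i, j in clade_of.items() if j == t)
            a, b = members[-2], members[-1]
            twin_source[b] = a
            centroids[b] = centroids[a]
    sizes = spec.genus_sizes()
    records: list[tuple[str, str]] = []
    rows = []
    by_genus: dict[int, list[np.ndarray]] = {}
    for g, (name, centroid) in enumerate(zip(genus_names, centroids)):
        seqs: list[np.ndarray] = []
        source = by_genus.get(twin_source[g], []) if g in twin_source else []
        for j in range(sizes[g]):
            if j < len(source):
                seq = _mutate(source[j], spec.twin_divergence, rng)
            else:
                seq = _mutate(centroid, spec.within_genus_rate, rng)
            seqs.append(seq)
            sid = f"{name}_s{j + 1}"
            records.append((sid, _BASES[seq].tobytes().decode("ascii")))
            row = {"sequence_id": sid, "genus": name}
            if groups is not None:
                row["group"] = groups[g]
            rows.append(row)
        by_genus[g] = seqs
    return records, pd.DataFrame(rows)


def default_community(seed: int = 0) -> SyntheticCommunitySpec:
    """Study-condition community used throughout the evaluation suite.

    Fifty genera in five order-like groups, full-length 1500-base
    sequences, lognormal genus sizes (median about six sequences,
    singletons retained).  Divergence between taxa is confined to nine
    variable regions covering 35% of the gene, mirroring the V-region
    architecture of 16S; group centroids differ at 25% of variable sites
    and each genus draws its own branch length from an exponential with
    mean 5% of variable sites.  Each group additionally ends in a crowded
    clade of four genera only 0.6% of variable sites away from a shared
    clade centroid — the borderline taxa that dominate misclassification
    in real reference sets — and in two groups the last clade member is a
    sequence-level twin of its neighbour (near-identical 16S under two
    genus names).  Within-genus substitutions (strain diversity plus
    residual sequencing noise) hit 1.5% of all positions; genus sizes are
    lognormal with median about twelve sequences, matching the roughly
    20-sequences-per-genus balance of curated full-length collections,
    with singletons retained.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5EED]))
    sizes = np.clip(
        np.rint(rng.lognormal(mean=np.log(12.0), sigma=0.9, size=50)), 1, 60
    ).astype(np.int64)
    return SyntheticCommunitySpec(
        n_genera=50,
        sequences_per_genus=sizes,
        sequence_length=1500,
        centroid_divergence=0.05,
        within_genus_rate=0.015,
        n_groups=5,
        group_divergence=0.25,
        variable_fraction=0.35,
        n_variable_blocks=9,
        branch_length_model="exponential",
        crowded_clade_size=4,
        crowded_divergence=0.006,
        n_twin_pairs=2,
        twin_divergence=0.005,
        seed=seed,
    )


def _to_u8(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()


def sample_fragment(
    seq: str, min_len: int, max_len: int, rng: np.random.Generator
) -> str:
    """Contiguous forward-strand fragment: length ~ U[min_len, max_len],
    start uniform over valid positions."""
    n = len(seq)
    if min_len < 1 or min_len > max_len:
        raise ValueError("need 1 <= min_len <= max_len")
    if min_len > n:
        raise ValueError(f"min_len {min_len} exceeds sequence length {n}")
    length = int(rng.integers(min_len, min(max_len, n) + 1))
    start = int(rng.integers(0, n - length + 1))
    return seq[start : start + length]


def corrupt_substitutions(
    seq: str, rate: float, rng: np.random.Generator, exact: bool = True
) -> str:
    """Substitute bases with a base different from the original.

    With ``exact`` (default), exactly round(rate*n) distinct positions are
    hit, making the effect size deterministic; otherwise each position is
    hit independently with probability `rate`.
    """
    if not (0.0 <= rate <= 1.0):
        raise ValueError("rate must be in [0, 1]")
    arr = _to_u8(seq)
    enc = _BASE_INDEX[arr]
    if (enc < 0).any():
        raise ValueError("corruption requires a pure A/C/G/T sequence")
    if exact:
        k = int(round(rate * arr.size))
        pos = rng.choice(arr.size, size=k, replace=False) if k else np.empty(0, int)
    else:
        pos = np.flatnonzero(rng.random(arr.size) < rate)
    if pos.size:
        enc[pos] = (enc[pos] + rng.integers(1, 4, size=pos.size)) % 4
    return _BASES[enc].tobytes().decode("ascii")


def corrupt_indels(
    seq: str, position_rate: float, indel_len: int, rng: np.random.Generator
) -> str:
    """Insert or delete (50/50 per event) fixed-length blocks.

    round(position_rate*n) anchor positions are drawn on the original
    sequence and processed right-to-left so earlier events do not shift
    later anchors.  Deletions are truncated at the sequence end.
    """
    if not (0.0 <= position_rate <= 1.0):
        raise ValueError("position_rate must be in [0, 1]")
    if indel_len < 1:
        raise ValueError("indel_len must be >= 1")
    arr = _to_u8(seq)
    n = arr.size
    k = int(round(position_rate * n))
    if k == 0:
        return seq
    anchors = np.sort(rng.choice(n, size=k, replace=False))[::-1]
    inserts = rng.random(k) < 0.5
    pieces = arr
    for pos, ins in zip(anchors, inserts):
        if ins:
            block = _BASES[rng.integers(0, 4, size=indel_len)].astype(np.uint8)
            pieces = np.concatenate([pieces[:pos], block, pieces[pos:]])
        else:
            pieces = np.concatenate([pieces[:pos], pieces[pos + indel_len :]])
    if pieces.size < 1:
        raise ValueError("corruption deleted the entire sequence")
    return pieces.tobytes().decode("ascii")
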