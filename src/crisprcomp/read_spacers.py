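"""Spacer recovery from unassembled reads (crass-style), with host filtering.

The miner never assembles: a read is CRISPR-bearing when it contains two
instances of the same 23-mer at least 26 bp apart (the classic two-
repeat signature).  Such reads are clustered across the sample by their
recurring k-mers, a consensus repeat is called per cluster by column
voting over every repeat instance, and spacers are read off as the
sequences between located repeat instances within each read.  Groups
from separate read files (e.g. left and right mates, or samples) are
merged on identical / reverse-complement repeats, and a rescue pass can
sweep reads for repeats already known from assemblies, contributing
flanking partial spacers.

Host decontamination mirrors paired-end both-unmapped filtering: a pair
is kept only when *neither* mate maps to the host, with mapping decided
by sharing at least one exact 31-mer (either strand) with the host
genome — a deliberate desk-scale surrogate for a read aligner, adequate
for substitution-free host reads and documented as swappable.
"""

from __future__ import annotations

import dataclasses
from collections import Counter, defaultdict

from .seqs import canonical, revcomp

HOST_KMER = 31


@dataclasses.dataclass
class SpacerHit:
    """One spacer occurrence recovered from a read."""

    seq: str
    sample_id: str
    partial: bool  # True when not bounded by repeat instances on both sides


@dataclasses.dataclass
class ReadSpacerGroup:
    """Spacers sharing one consensus repeat within/across samples."""

    sample_id: str
    consensus_repeat: str
    spacers: list[SpacerHit]
    n_repeat_instances: int

    def spacer_seqs(self, include_partial: bool = True) -> list[str]:
        return [s.seq for s in self.spacers if include_partial or not s.partial]


@dataclasses.dataclass
class ReadMinerParams:
    k: int = 23
    min_sep: int = 26  # bp between the starts of the two k-mer instances
    min_repeats: int = 2  # repeat instances needed to keep a group
    min_spacers: int = 2  # distinct spacers needed to keep a group
    min_partial: int = 16  # discard spacers shorter than this
    max_repeat_len: int = 48
    min_flank: int = 8  # overlap needed to call a partial repeat instance at a read end


# ---------------------------------------------------------------------------
# host filtering


def host_kmer_index(host: str | dict[str, str], k: int = HOST_KMER) -> set[str]:
    """Exact k-mers of the host genome, both strands."""
    seqs = host.values() if isinstance(host, dict) else [host]
    kmers: set[str] = set()
    for seq in seqs:
        for i in range(len(seq) - k + 1):
            km = seq[i : i + k]
            kmers.add(km)
            kmers.add(revcomp(km))
    return kmers


def _maps_to_host(read: str, index: set[str], k: int) -> bool:
    return any(read[i : i + k] in index for i in range(len(read) - k + 1))


def host_filter(
    pairs: list[tuple[str, str, str]],
    host: str | dict[str, str] | set[str],
    k: int = HOST_KMER,
) -> list[tuple[str, str, str]]:
    """Keep only pairs where neither mate maps to the host.

    ``pairs`` are ``(pair_id, r1, r2)``; ``host`` is a genome (string or
    contig dict) or a prebuilt k-mer index.  A mate "maps" when it
    shares any exact k-mer with the host, so a pair with even one mapped
    mate is excluded — the both-unmapped keep rule.
    """
    for p in pairs:
        if len(p) != 3:
            raise ValueError("pairs must be (pair_id, read1, read2) triples")
    index = host if isinstance(host, set) else host_kmer_index(host, k)
    return [
        (pid, r1, r2)
        for pid, r1, r2 in pairs
        if not _maps_to_host(r1, index, k) and not _maps_to_host(r2, index, k)
    ]


# ---------------------------------------------------------------------------
# mining


def _recurring_kmers(read: str, k: int, min_sep: int) -> set[str]:
    """K-mers occurring at least twice with starts >= min_sep apart."""
    first: dict[str, int] = {}
    out: set[str] = set()
    for i in range(len(read) - k + 1):
        km = read[i : i + k]
        if "N" in km:
            continue
        if km in first:
            if i - first[km] >= min_sep:
                out.add(km)
        else:
            first[km] = i
    return out


class _UnionFind:
    def __init__(self):
        self.parent: dict[str, str] = {}

    def find(self, x: str) -> str:
        self.parent.setdefault(x, x)
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def _call_cluster_repeat(
    reads: list[str], anchor: str, params: ReadMinerParams
) -> str | None:
    """Consensus repeat of a cluster by column voting around the anchor k-mer.

    Each read is oriented so the anchor occurs forward; every anchor
    occurrence contributes one vote per column at each offset.  Columns
    extend outward from the anchor while at least 75% of votes agree,
    mirroring the assembly-side boundary rule.
    """
    k = params.k
    votes: dict[int, Counter] = defaultdict(Counter)
    n_instances = 0
    for read in reads:
        oriented = read if anchor in read else revcomp(read)
        start = 0
        while True:
            i = oriented.find(anchor, start)
            if i < 0:
                break
            n_instances += 1
            for off in range(-params.max_repeat_len + k, params.max_repeat_len):
                pos = i + off
                if 0 <= pos < len(oriented):
                    votes[off][oriented[pos]] += 1
            start = i + 1
    if n_instances == 0:
        return None

    def agrees(off: int) -> bool:
        c = votes.get(off)
        if not c:
            return False
        total = sum(c.values())
        return c.most_common(1)[0][1] >= 0.75 * total and total >= 2

    left = 0
    right = k - 1
    while (
        left - 1 >= -params.max_repeat_len + k
        and right - left + 2 <= params.max_repeat_len
        and agrees(left - 1)
    ):
        left -= 1
    while right - left + 2 <= params.max_repeat_len and agrees(right + 1):
        right += 1
    cons = []
    for off in range(left, right + 1):
        c = votes[off]
        best = max(c.items(), key=lambda kv: (kv[1], -ord(kv[0])))
        cons.append(best[0])
    return "".join(cons)


def _locate_instances(
    read: str, repeat: str, min_flank: int
) -> list[tuple[int, int]]:
    """Full and read-end-partial occurrences of a repeat in one read."""
    hits = []
    start = 0
    while True:
        i = read.find(repeat, start)
        if i < 0:
            break
        hits.append((i, i + len(repeat)))
        start = i + 1
    # partial at read start: a suffix of the repeat prefixes the read
    for length in range(len(repeat) - 1, min_flank - 1, -1):
        if read.startswith(repeat[-length:]):
            if not any(s == 0 for s, _ in hits):
                hits.append((0, length))
            break
    # partial at read end: a prefix of the repeat suffixes the read
    for length in range(len(repeat) - 1, min_flank - 1, -1):
        if read.endswith(repeat[:length]):
            if not any(e == len(read) for _, e in hits):
                hits.append((len(read) - length, len(read)))
            break
    hits.sort()
    # drop overlapping partials swallowed by full hits
    out: list[tuple[int, int]] = []
    for h in hits:
        if out and h[0] < out[-1][1]:
            continue
        out.append(h)
    return out


def extract_read_spacers(
    reads: list[tuple[str, str]] | list[str],
    params: ReadMinerParams | None = None,
    sample_id: str = "",
) -> list[ReadSpacerGroup]:
    """Mine one read file for repeat-spacer structure.

    ``reads`` are ``(read_id, seq)`` pairs or bare sequences.  Returned
    groups have their consensus repeat normalised to the canonical
    strand (lexicographically smallest of the two orientations), spacers
    reoriented accordingly, exact duplicates removed, and the group-size
    cutoffs applied (``min_repeats`` instances, ``min_spacers`` distinct
    spacers, no spacer shorter than ``min_partial``).
    """
    params = params or ReadMinerParams()
    seqs = [r if isinstance(r, str) else r[1] for r in reads]

    uf = _UnionFind()
    read_kmers: list[set[str]] = []
    for seq in seqs:
        kms = {canonical(km) for km in _recurring_kmers(seq, params.k, params.min_sep)}
        read_kmers.append(kms)
        kms_list = sorted(kms)
        for a, b in zip(kms_list, kms_list[1:]):
            uf.union(a, b)

    clusters: dict[str, list[int]] = defaultdict(list)
    cluster_kmer_count: dict[str, Counter] = defaultdict(Counter)
    for ri, kms in enumerate(read_kmers):
        if not kms:
            continue
        root = uf.find(next(iter(sorted(kms))))
        clusters[root].append(ri)
        for km in kms:
            cluster_kmer_count[root][km] += 1

    groups: list[ReadSpacerGroup] = []
    for root in sorted(clusters):
        members = clusters[root]
        anchor = min(
            cluster_kmer_count[root],
            key=lambda km: (-cluster_kmer_count[root][km], km),
        )
        cluster_reads = [seqs[ri] for ri in members]
        # orientation: the canonical anchor may not literally occur; pick
        # whichever orientation occurs in reads
        anchor_fwd = anchor if any(anchor in s or anchor in revcomp(s) for s in cluster_reads) else revcomp(anchor)
        cons = _call_cluster_repeat(cluster_reads, anchor_fwd, params)
        if cons is None:
            continue
        group = _harvest_group(cluster_reads, cons, params, sample_id)
        if group is not None:
            groups.append(group)
    groups.sort(key=lambda g: g.consensus_repeat)
    return groups


def _harvest_group(
    cluster_reads: list[str],
    cons: str,
    params: ReadMinerParams,
    sample_id: str,
) -> ReadSpacerGroup | None:
    n_instances = 0
    raw_spacers: list[str] = []
    for read in cluster_reads:
        oriented = read if cons in read or revcomp(cons) not in read else revcomp(read)
        hits = _locate_instances(oriented, cons, params.min_flank)
        n_instances += len(hits)
        for (s0, e0), (s1, _) in zip(hits, hits[1:]):
            sp = oriented[e0:s1]
            if len(sp) >= params.min_partial and cons not in sp and revcomp(cons) not in sp:
                raw_spacers.append(sp)
    return _finish_group(cons, raw_spacers, n_instances, params, sample_id)


def _finish_group(
    cons: str,
    raw_spacers: list[str],
    n_instances: int,
    params: ReadMinerParams,
    sample_id: str,
    partial_flags: list[bool] | None = None,
) -> ReadSpacerGroup | None:
    flags = partial_flags or [False] * len(raw_spacers)
    crep = canonical(cons)
    flip = crep != cons
    seen: dict[str, SpacerHit] = {}
    for sp, partial in zip(raw_spacers, flags):
        if flip:
            sp = revcomp(sp)
        if sp not in seen:
            seen[sp] = SpacerHit(seq=sp, sample_id=sample_id, partial=partial)
        elif not partial:
            seen[sp].partial = False
    spacers = [seen[s] for s in sorted(seen)]
    if n_instances < params.min_repeats:
        return None
    if len({s.seq for s in spacers}) < params.min_spacers:
        return None
    return ReadSpacerGroup(
        sample_id=sample_id,
        consensus_repeat=crep,
        spacers=spacers,
        n_repeat_instances=n_instances,
    )


def rescue_known_repeats(
    reads: list[tuple[str, str]] | list[str],
    known_repeats: list[str],
    params: ReadMinerParams | None = None,
    sample_id: str = "",
) -> list[ReadSpacerGroup]:
    """Sweep reads for repeats already known from assemblies.

    Any read containing a full known repeat (either strand) contributes
    the sequences between instances as spacers and its terminal flanks
    as *partial* spacers, subject to the ``min_partial`` length floor.
    No group-size cutoffs apply: the point is recovering material the
    de-novo miner missed.
    """
    params = params or ReadMinerParams()
    if not known_repeats:
        raise ValueError("rescue requires at least one known repeat")
    seqs = [r if isinstance(r, str) else r[1] for r in reads]
    groups: list[ReadSpacerGroup] = []
    for rep in known_repeats:
        raw: list[str] = []
        flags: list[bool] = []
        n_instances = 0
        for read in seqs:
            oriented = read if rep in read else revcomp(read)
            if rep not in oriented:
                continue
            hits = []
            start = 0
            while True:
                i = oriented.find(rep, start)
                if i < 0:
                    break
                hits.append((i, i + len(rep)))
                start = i + 1
            n_instances += len(hits)
            lead = oriented[: hits[0][0]]
            if len(lead) >= params.min_partial:
                raw.append(lead)
                flags.append(True)
            for (s0, e0), (s1, _) in zip(hits, hits[1:]):
                sp = oriented[e0:s1]
                if len(sp) >= params.min_partial:
                    raw.append(sp)
                    flags.append(False)
            tail = oriented[hits[-1][1] :]
            if len(tail) >= params.min_partial:
                raw.append(tail)
                flags.append(True)
        if not raw:
            continue
        crep = canonical(rep)
        flip = crep != rep
        spacer_hits: dict[str, SpacerHit] = {}
        for sp, fl in zip(raw, flags):
            if flip:
                sp = revcomp(sp)
            if sp not in spacer_hits:
                spacer_hits[sp] = SpacerHit(seq=sp, sample_id=sample_id, partial=fl)
            elif not fl:
                spacer_hits[sp].partial = False
        groups.append(
            ReadSpacerGroup(
                sample_id=sample_id,
                consensus_repeat=crep,
                spacers=[spacer_hits[s] for s in sorted(spacer_hits)],
                n_repeat_instances=n_instances,
            )
        )
    groups.sort(key=lambda g: g.consensus_repeat)
    return groups


def merge_groups(groups: list[ReadSpacerGroup]) -> list[ReadSpacerGroup]:
    """Consolidate groups sharing a repeat (exact or reverse complement).

    Spacer lists are unioned with exact-duplicate removal; a spacer seen
    as both full and partial counts as full, and partial spacers that
    are substrings (either strand) of a full spacer in the same merged
    group are absorbed by it.  Sample provenance is retained per spacer.
    """
    merged: dict[str, dict] = {}
    for g in groups:
        key = canonical(g.consensus_repeat)
        flip = key != g.consensus_repeat
        slot = merged.setdefault(
            key, {"spacers": {}, "n": 0, "samples": set()}
        )
        slot["n"] += g.n_repeat_instances
        slot["samples"].add(g.sample_id)
        for hit in g.spacers:
            seq = revcomp(hit.seq) if flip else hit.seq
            prev = slot["spacers"].get(seq)
            if prev is None:
                slot["spacers"][seq] = SpacerHit(
                    seq=seq, sample_id=hit.sample_id, partial=hit.partial
                )
            else:
                prev.partial = prev.partial and hit.partial
                if hit.sample_id not in prev.sample_id.split(","):
                    prev.sample_id = ",".join(
                        sorted(set(prev.sample_id.split(",")) | {hit.sample_id})
                    )
    out = []
    for key in sorted(merged):
        slot = merged[key]
        hits = list(slot["spacers"].values())
        fulls = [h.seq for h in hits if not h.partial]
        full_set = set(fulls) | {revcomp(f) for f in fulls}
        kept = []
        for h in hits:
            if h.partial and any(
                h.seq in f or revcomp(h.seq) in f for f in full_set
            ):
                continue
            kept.append(h)
        kept.sort(key=lambda h: h.seq)
        out.append(
            ReadSpacerGroup(
                sample_id=",".join(sorted(slot["samples"])),
                consensus_repeat=key,
                spacers=kept,
                n_repeat_instances=slot["n"],
            )
        )
    return out
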