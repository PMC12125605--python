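"""Scaffold end-overlap detection and curation into super-scaffolds.

Adjacent scaffolds produced by a fragmenting assembler often share a
near-identical suffix-prefix overlap. Detection anchors shared k-mers inside
the terminal ``end_window`` of each oriented scaffold end and evaluates each
implied gap-free diagonal: the longest overlap of length >= ``min_len`` with
identity >= ``min_identity`` is reported for each pair of scaffold ends.
Accepted joins are then resolved into simple chains (greedy maximum-weight
matching on scaffold ends; cycles rejected) and merged, taking the left
member's copy of each overlap. Junction reports carry 1-based coordinates
and a predicted validation-amplicon interval (junction +/- flank) mirroring
a PCR check across each junction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import kmers
from .seqio import SeqRecord


@dataclass
class OverlapJoin:
    """A suffix(left)-prefix(right) overlap between two oriented scaffolds."""

    left_id: str
    right_id: str
    left_orient: str
    right_orient: str
    overlap_len: int
    identity: float
    left_junction: tuple[int, int]  # 1-based inclusive, on the oriented left scaffold
    right_junction: tuple[int, int]

    def end_nodes(self) -> frozenset:
        """The two scaffold ends (in + frame) this join consumes."""
        left_end = (self.left_id, "R" if self.left_orient == "+" else "L")
        right_end = (self.right_id, "L" if self.right_orient == "+" else "R")
        return frozenset((left_end, right_end))

    def flipped(self) -> "OverlapJoin":
        flip = {"+": "-", "-": "+"}
        return OverlapJoin(
            left_id=self.right_id,
            right_id=self.left_id,
            left_orient=flip[self.right_orient],
            right_orient=flip[self.left_orient],
            overlap_len=self.overlap_len,
            identity=self.identity,
            left_junction=self.right_junction,
            right_junction=self.left_junction,
        )


def _oriented_codes(scaffolds: list[SeqRecord]) -> dict[str, dict[str, np.ndarray]]:
    out = {}
    for rec in scaffolds:
        fwd = kmers.encode(rec.seq)
        out[rec.id] = {"+": fwd, "-": kmers.revcomp_codes(fwd)}
    return out


def find_end_overlaps(
    scaffolds: list[SeqRecord],
    min_len: int = 1500,
    min_identity: float = 0.99,
    end_window: int = 20000,
    candidates: list[tuple[str, str]] | None = None,
    k: int = 21,
) -> list[OverlapJoin]:
    """Detect suffix-prefix overlaps between scaffold ends.

    With ``candidates`` given, only those scaffold pairs are examined
    (guided curation); pairs are effectively unordered since all four
    orientation combinations are searched. Otherwise all pairs are searched
    (exhaustive curation). Joins are sorted by (overlap_len desc,
    identity desc, id pair).
    """
    if end_window < min_len:
        raise ValueError("end_window must be >= min_len")
    if len(scaffolds) < 2:
        raise ValueError("need at least two scaffolds")
    codes = _oriented_codes(scaffolds)
    lengths = {rec.id: len(rec.seq) for rec in scaffolds}
    ids = [rec.id for rec in scaffolds]
    if candidates is not None:
        pairs = list(candidates)
    else:
        pairs = [(a, b) for a in ids for b in ids if a != b]

    # pre-index each oriented prefix window once
    prefix_index: dict[tuple[str, str], tuple[np.ndarray, np.ndarray, int]] = {}
    for sid in ids:
        for o in "+-":
            w = min(end_window, lengths[sid])
            pref = codes[sid][o][:w]
            sc, sp = kmers.sorted_kmer_index(pref, k)
            prefix_index[(sid, o)] = (sc, sp, w)

    best: dict[frozenset, OverlapJoin] = {}
    for left, right in pairs:
        if left not in lengths or right not in lengths:
            raise ValueError(f"unknown scaffold id in candidate pair ({left}, {right})")
        for ox in "+-":
            a = codes[left][ox]
            w1 = min(end_window, lengths[left])
            suffix = a[-w1:]
            sk, sv = kmers.kmer_codes(suffix, k)
            for oy in "+-":
                sc, sp, _w2 = prefix_index[(right, oy)]
                si, pj = kmers.match_hits(sk, sv, sc, sp)
                if si.size == 0:
                    continue
                diags = np.unique(si - pj)
                diags = diags[diags >= 0]
                ovs = w1 - diags
                ovs = ovs[(ovs >= min_len) & (ovs <= min(lengths[left], lengths[right]))]
                b = codes[right][oy]
                join = None
                for ov in sorted((int(v) for v in ovs), reverse=True):
                    nm = int(np.count_nonzero(a[-ov:] != b[:ov]))
                    identity = 1.0 - nm / ov
                    if identity >= min_identity:
                        join = OverlapJoin(
                            left_id=left,
                            right_id=right,
                            left_orient=ox,
                            right_orient=oy,
                            overlap_len=ov,
                            identity=identity,
                            left_junction=(lengths[left] - ov + 1, lengths[left]),
                            right_junction=(1, ov),
                        )
                        break
                if join is None:
                    continue
                key = join.end_nodes()
                prev = best.get(key)
                if prev is None or (join.overlap_len, join.identity) > (
                    prev.overlap_len,
                    prev.identity,
                ):
                    # canonical direction: lexicographically smaller left id
                    if join.left_id > join.right_id:
                        join = join.flipped()
                    best[key] = join
    joins = sorted(
        best.values(),
        key=lambda j: (-j.overlap_len, -j.identity, j.left_id, j.right_id),
    )
    return joins


@dataclass
class Chain:
    """An ordered path of oriented scaffolds with the joins between them."""

    members: list[tuple[str, str]]
    joins: list[OverlapJoin] = field(default_factory=list)

    @property
    def ids(self) -> list[str]:
        return [m[0] for m in self.members]


@dataclass
class ChainSet:
    chains: list[Chain]
    conflicts: list[OverlapJoin] = field(default_factory=list)
    cycles: list[OverlapJoin] = field(default_factory=list)


def build_join_chains(joins: list[OverlapJoin], scaffold_ids: list[str] | None = None) -> ChainSet:
    """Resolve joins into simple chains by greedy maximum-weight end matching.

    Joins are considered in (overlap_len desc, identity desc, ids) order;
    a join losing a scaffold end to an earlier join is reported as a
    conflict, and a join that would close a cycle is reported and skipped.
    Scaffolds without accepted joins become singleton chains.
    """
    joins = sorted(joins, key=lambda j: (-j.overlap_len, -j.identity, j.left_id, j.right_id))
    ids = list(scaffold_ids) if scaffold_ids is not None else []
    for j in joins:
        for sid in (j.left_id, j.right_id):
            if sid not in ids:
                ids.append(sid)

    parent = {sid: sid for sid in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    used_ends: set[tuple[str, str]] = set()
    accepted: list[OverlapJoin] = []
    conflicts: list[OverlapJoin] = []
    cycles: list[OverlapJoin] = []
    for j in joins:
        e1, e2 = sorted(j.end_nodes())
        if e1 in used_ends or e2 in used_ends:
            conflicts.append(j)
            continue
        if find(j.left_id) == find(j.right_id):
            cycles.append(j)
            continue
        parent[find(j.left_id)] = find(j.right_id)
        used_ends.update((e1, e2))
        accepted.append(j)

    # adjacency: oriented end -> (join, neighbour id, neighbour entry end)
    adj: dict[tuple[str, str], tuple[OverlapJoin, str, str]] = {}
    for j in accepted:
        le = (j.left_id, "R" if j.left_orient == "+" else "L")
        re = (j.right_id, "L" if j.right_orient == "+" else "R")
        adj[le] = (j, j.right_id, re[1])
        adj[re] = (j, j.left_id, le[1])

    degree = {sid: 0 for sid in ids}
    for j in accepted:
        degree[j.left_id] += 1
        degree[j.right_id] += 1

    visited: set[str] = set()
    chains: list[Chain] = []

    def walk(start: str, exit_end: str) -> Chain:
        members = []
        chain_joins = []
        sid, out_end = start, exit_end
        while True:
            visited.add(sid)
            members.append((sid, "+" if out_end == "R" else "-"))
            hop = adj.get((sid, out_end))
            if hop is None:
                break
            join, nxt, entry = hop
            chain_joins.append(join)
            sid = nxt
            out_end = "R" if entry == "L" else "L"
        return Chain(members, chain_joins)

    endpoints = sorted(sid for sid in ids if degree[sid] <= 1)
    for sid in endpoints:
        if sid in visited:
            continue
        if degree[sid] == 0:
            visited.add(sid)
            chains.append(Chain([(sid, "+")]))
            continue
        # the free end is the one with no join; exit through the used end
        free_r = (sid, "R") not in adj
        chains.append(walk(sid, "R" if not free_r else "L"))
    return ChainSet(chains, conflicts, cycles)


def merge_scaffolds(
    scaffolds: list[SeqRecord],
    chains: ChainSet | list[Chain],
    min_identity: float = 0.99,
    flank: int = 2500,
) -> tuple[list[SeqRecord], pd.DataFrame]:
    """Merge chained scaffolds; return merged records and a junction report.

    Merged length is the sum of member lengths minus the sum of overlap
    lengths. The overlap sequence is taken from the left member; bases where
    the two copies disagree are counted in the report, not resolved. A chain
    whose overlap identity falls below ``min_identity`` at merge time is
    aborted: its members pass through unmerged and the report notes it.
    """
    chain_list = chains.chains if isinstance(chains, ChainSet) else chains
    seqs = {rec.id: rec for rec in scaffolds}
    merged: list[SeqRecord] = []
    rows = []

    def oriented(sid: str, orient: str) -> str:
        rec = seqs[sid]
        return rec.seq if orient == "+" else rec.reverse_complement().seq

    for chain in chain_list:
        if len(chain.members) == 1:
            sid, _ = chain.members[0]
            merged.append(seqs[sid])
            continue
        name = "+".join(chain.ids)
        cur = oriented(*chain.members[0])
        junctions = []
        aborted = False
        for (sid, orient), join in zip(chain.members[1:], chain.joins):
            nxt = oriented(sid, orient)
            ov = join.overlap_len
            a = np.frombuffer(cur[-ov:].encode(), np.uint8)
            b = np.frombuffer(nxt[:ov].encode(), np.uint8)
            n_disagree = int(np.count_nonzero(a != b))
            identity = 1.0 - n_disagree / ov
            if identity < min_identity:
                rows.append(
                    {
                        "chain": name,
                        "left": join.left_id,
                        "right": sid,
                        "status": "aborted",
                        "overlap_len": ov,
                        "identity": round(identity, 6),
                    }
                )
                aborted = True
                break
            junctions.append((len(cur) - ov + 1, len(cur), ov, identity, n_disagree, sid))
            cur = cur + nxt[ov:]
        if aborted:
            for sid, _ in chain.members:
                merged.append(seqs[sid])
            continue
        merged.append(SeqRecord(name, cur, description=f"merged from {len(chain.members)} scaffolds"))
        for (js, je, ov, identity, n_disagree, sid), (lid, _) in zip(
            junctions, chain.members[:-1]
        ):
            rows.append(
                {
                    "chain": name,
                    "left": lid,
                    "right": sid,
                    "status": "merged",
                    "junction_start": js,
                    "junction_end": je,
                    "overlap_len": ov,
                    "identity": round(identity, 6),
                    "n_disagree": n_disagree,
                    "amplicon_start": max(1, js - flank),
                    "amplicon_end": min(len(cur), je + flank),
                }
            )
    report = pd.DataFrame(rows)
    return merged, report
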