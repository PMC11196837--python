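"""COI-COII haplotype classification, deduplication, and parsimony network.

The COI-COII intergenic region is maternally inherited and highly polymorphic
in *Apis mellifera*; one sequence per colony identifies the colony's maternal
evolutionary lineage (African A, Western European M, Eastern European C,
Asian O, Arabian Peninsula / African Horn Y).  Classification assigns each
query the lineage of its nearest reference by unit-cost global-alignment edit
distance; ties across lineages are reported as ``unknown`` with an ambiguity
flag.  Identical normalized sequences collapse to one haplotype, and
haplotypes are connected into a minimum-spanning parsimony-style network with
a user-set mutational-step ceiling.

Apiary-level mitochondrial Africanization is the percentage of colonies in
the apiary whose maternal lineage is A, among colonies with a known lineage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import edlib
import networkx as nx
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")
GAP_CHARS = frozenset("-.")
# N is an ambiguous base call, not a variant: it matches any base at no cost
_N_EQUALITIES = [("N", "A"), ("N", "C"), ("N", "G"), ("N", "T")]


@dataclass
class HaplotypeRecord:
    """One deduplicated haplotype with its carriers."""

    haplotype_id: str
    sequence: str
    lineage: str = "unknown"
    member_colony_ids: list[str] = field(default_factory=list)

    @property
    def count(self) -> int:
        return len(self.member_colony_ids)


@dataclass
class NetworkEdge:
    h1: str
    h2: str
    steps: int
    alternate: bool = False  # tied alternative to a retained spanning edge


@dataclass
class HaplotypeNetwork:
    nodes: list[HaplotypeRecord]
    edges: list[NetworkEdge]
    max_steps: int

    def components(self) -> list[set[str]]:
        g = nx.Graph()
        g.add_nodes_from(r.haplotype_id for r in self.nodes)
        g.add_edges_from((e.h1, e.h2) for e in self.edges)
        return [set(c) for c in nx.connected_components(g)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "h1": [e.h1 for e in self.edges],
                "h2": [e.h2 for e in self.edges],
                "steps": [e.steps for e in self.edges],
                "alternate_flag": [e.alternate for e in self.edges],
            }
        )


def normalize_sequence(raw: str) -> str:
    """Uppercase, strip alignment gaps, reject non-IUPAC-DNA characters.

    Positions in error messages are 1-based indices into the raw input.
    """
    if not raw:
        raise ValueError("empty sequence")
    out = []
    for pos, ch in enumerate(raw, start=1):
        up = ch.upper()
        if up in GAP_CHARS:
            continue
        if up not in VALID_BASES:
            raise ValueError(f"illegal character {ch!r} at position {pos}")
        out.append(up)
    if not out:
        raise ValueError("sequence contains only gap characters")
    return "".join(out)


def edit_distance(s1: str, s2: str) -> int:
    """Unit-cost global-alignment distance (substitutions + indels).

    ``N`` matches any base at zero cost, so ambiguous base calls do not create
    spurious mutational steps.
    """
    if s1 == s2:
        return 0
    return int(
        edlib.align(s1, s2, mode="NW", task="distance", additionalEqualities=_N_EQUALITIES)[
            "editDistance"
        ]
    )


def classify_lineage(
    query: str,
    references: Mapping[str, Sequence[str]] | Sequence[tuple[str, str]],
) -> tuple[str, int, bool]:
    """Assign the lineage of the nearest reference sequence.

    ``references`` maps lineage label -> sequences (or is a list of
    ``(lineage, sequence)`` pairs).  Returns ``(lineage, distance,
    ambiguous)``; when two or more lineages tie for the minimum distance the
    lineage is ``unknown`` and the flag is set.
    """
    if isinstance(references, Mapping):
        pairs = [(lin, s) for lin, seqs in references.items() for s in seqs]
    else:
        pairs = list(references)
    if not pairs:
        raise ValueError("empty reference set")
    best: dict[str, int] = {}
    for lineage, ref in pairs:
        d = edit_distance(query, ref)
        if lineage not in best or d < best[lineage]:
            best[lineage] = d
    d_min = min(best.values())
    winners = sorted(lin for lin, d in best.items() if d == d_min)
    if len(winners) > 1:
        return "unknown", d_min, True
    return winners[0], d_min, False


def dedupe_haplotypes(
    sequences: Iterable[tuple[str, str]],
    lineages: Mapping[str, str] | None = None,
) -> list[HaplotypeRecord]:
    """Collapse identical normalized sequences into haplotype records.

    ``sequences`` yields ``(colony_id, raw_sequence)``.  Haplotype ids are
    assigned by descending carrier count, ties broken by first-seen order;
    the record set and counts themselves are input-order invariant.  When
    ``lineages`` maps colony ids to lineage labels, each record takes the
    label of its first member.
    """
    by_seq: dict[str, list[str]] = {}
    first_seen: dict[str, int] = {}
    for i, (cid, raw) in enumerate(sequences):
        seq = normalize_sequence(raw)
        if seq not in by_seq:
            by_seq[seq] = []
            first_seen[seq] = i
        by_seq[seq].append(cid)
    ordered = sorted(by_seq, key=lambda s: (-len(by_seq[s]), first_seen[s]))
    records = []
    for idx, seq in enumerate(ordered, start=1):
        members = by_seq[seq]
        lineage = "unknown"
        if lineages is not None:
            lineage = lineages.get(members[0], "unknown")
        records.append(
            HaplotypeRecord(
                haplotype_id=f"H{idx}",
                sequence=seq,
                lineage=lineage,
                member_colony_ids=members,
            )
        )
    return records


def build_network(records: Sequence[HaplotypeRecord], max_steps: int = 10) -> HaplotypeNetwork:
    """Minimum-spanning parsimony-style haplotype network.

    All pairwise edit distances are computed; pairs farther apart than
    ``max_steps`` are never connected (the network splits into components,
    standing in for a statistical-parsimony connection limit).  Within the
    remaining graph a minimum-total-distance spanning forest is retained;
    non-tree edges that could replace a retained edge at equal total weight
    are kept too, flagged as alternates.
    """
    if not records:
        raise ValueError("no haplotype records")
    g = nx.Graph()
    for r in records:
        g.add_node(r.haplotype_id)
    recs = list(records)
    for i in range(len(recs)):
        for j in range(i + 1, len(recs)):
            d = edit_distance(recs[i].sequence, recs[j].sequence)
            if 1 <= d <= max_steps:
                g.add_edge(recs[i].haplotype_id, recs[j].haplotype_id, weight=d)

    forest = nx.minimum_spanning_tree(g, weight="weight")  # forest if disconnected
    edges: list[NetworkEdge] = []
    for u, v, data in forest.edges(data=True):
        edges.append(NetworkEdge(*sorted((u, v)), steps=int(data["weight"])))
    # a non-tree edge is a tied alternate iff its weight equals the maximum
    # edge weight on the forest path between its endpoints (cycle property)
    for u, v, data in g.edges(data=True):
        if forest.has_edge(u, v):
            continue
        try:
            path = nx.shortest_path(forest, u, v)
        except nx.NetworkXNoPath:
            continue
        path_max = max(
            forest[a][b]["weight"] for a, b in zip(path[:-1], path[1:])
        )
        if int(data["weight"]) == int(path_max):
            edges.append(NetworkEdge(*sorted((u, v)), steps=int(data["weight"]), alternate=True))
    edges.sort(key=lambda e: (e.alternate, e.h1, e.h2))
    return HaplotypeNetwork(nodes=recs, edges=edges, max_steps=max_steps)


def mito_africanization(
    colony_lineages: Mapping[str, str],
    colony_apiaries: Mapping[str, str],
) -> pd.Series:
    """Percentage of African-lineage colonies per apiary.

    Computed over colonies with a known lineage; an apiary where every colony
    is ``unknown`` gets a missing value (and a warning).
    """
    rows = []
    for cid, apiary in colony_apiaries.items():
        rows.append((apiary, colony_lineages.get(cid, "unknown")))
    df = pd.DataFrame(rows, columns=["apiary_id", "lineage"])
    out = {}
    for apiary, grp in df.groupby("apiary_id", sort=True):
        known = grp[grp["lineage"] != "unknown"]
        if known.empty:
            logger.warning("apiary %s has no colonies with known lineage", apiary)
            out[apiary] = float("nan")
        else:
            out[apiary] = 100.0 * (known["lineage"] == "A").mean()
    return pd.Series(out, name="pct_african_mtdna")


# ---------------------------------------------------------------------------
# FASTA I/O
# ---------------------------------------------------------------------------

def read_colony_fasta(path: str | Path) -> dict[str, str]:
    """Colony FASTA: record ids are colony ids."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_reference_fasta(path: str | Path) -> dict[str, list[str]]:
    """Reference FASTA with ``lineage|name`` headers -> lineage -> sequences."""
    refs: dict[str, list[str]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if "|" not in rec.id:
            raise ValueError(
                f"reference header {rec.id!r} lacks the 'lineage|name' format"
            )
        lineage = rec.id.split("|", 1)[0]
        refs.setdefault(lineage, []).append(normalize_sequence(str(rec.seq)))
    return refs
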