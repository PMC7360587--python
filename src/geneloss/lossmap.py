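"""Shared-disruption clustering and minimum loss-event counting.

An identical inactivating mutation (same kind, same homologous reference
position, same allele) carried by several species is strong evidence for a
single ancestral inactivation. Loss events are therefore counted as
connected components of the "shares a disruption" graph over inactivated
tips — not by plain Dollo presence/absence parsimony, which would merge
adjacent lineages inactivated by distinct mutations. Each component is
placed on the edge above the MRCA of its members; any coding tip inside that
clade triggers a Dollo-consistency warning.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .annotate import DisruptionEvent, GeneStatusCall
from .trees import SpeciesTree


class LossMapError(ValueError):
    pass


@dataclass
class SharedCluster:
    """Species carrying one identical disruption."""

    cluster_id: str
    member_species: frozenset[str]
    kind: str
    cds_nt_pos: int
    allele: str | None
    indel_len: int = 0


@dataclass
class LossEvent:
    edge_tips: frozenset[str]         # descendant tip set of the event edge
    members: frozenset[str]           # inactivated tips covered by this event
    clusters: list[str] = field(default_factory=list)


@dataclass
class LossEventSet:
    events: list[LossEvent]
    warnings: list[str] = field(default_factory=list)

    @property
    def n_events(self) -> int:
        return len(self.events)


def cluster_shared(events: Sequence[DisruptionEvent]) -> list[SharedCluster]:
    """Group identical disruptions across species into shared clusters.

    Two events share a cluster iff they have the same kind, the same
    homologous reference coordinate and the same allele (stop-codon identity,
    or indel length plus inserted/deleted string). Singletons are allowed.
    """
    groups: dict[tuple, set[str]] = {}
    for e in events:
        key = (e.kind, e.cds_nt_pos, e.indel_len, e.allele)
        groups.setdefault(key, set()).add(e.species)
    out = []
    for i, (key, members) in enumerate(sorted(groups.items(),
                                              key=lambda kv: str(kv[0]))):
        kind, pos, ilen, allele = key
        out.append(SharedCluster(
            cluster_id=f"c{i:03d}:{kind}@{pos}",
            member_species=frozenset(members),
            kind=kind, cds_nt_pos=pos, allele=allele, indel_len=ilen))
    return out


def count_loss_events(tree: SpeciesTree,
                      statuses: Sequence[GeneStatusCall],
                      clusters: Sequence[SharedCluster],
                      include_polymorphic: bool = False,
                      dollo: bool = False) -> LossEventSet:
    """Count independent gene-inactivation events on the species tree.

    Inactivated tips (status ``pseudogene``, plus ``polymorphic_pseudogene``
    when requested) are joined by an edge whenever they share at least one
    disruption cluster; each connected component is one event, placed above
    the MRCA of its members. ``dollo=True`` instead computes the plain Dollo
    minimum (fewest edges covering all inactivated and no coding tips),
    offered for comparison only.
    """
    wanted = {"pseudogene"}
    if include_polymorphic:
        wanted.add("polymorphic_pseudogene")
    inactive = sorted({s.species for s in statuses if s.status in wanted})
    coding = {s.species for s in statuses if s.status == "coding"}
    tipset = set(tree.taxa)
    missing = [t for t in inactive if t not in tipset]
    if missing:
        raise LossMapError(f"inactivated tips absent from tree: {missing}")

    if not inactive:
        return LossEventSet(events=[])

    if dollo:
        return _dollo_events(tree, inactive, coding)

    # union-find over inactivated tips, joined by shared clusters
    parent = {t: t for t in inactive}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    cluster_members: dict[str, list[str]] = {}
    for cl in clusters:
        members = [t for t in cl.member_species if t in parent]
        cluster_members[cl.cluster_id] = members
        for a, b in zip(members, members[1:]):
            union(a, b)

    components: dict[str, set[str]] = {}
    for t in inactive:
        components.setdefault(find(t), set()).add(t)

    events, warnings = [], []
    for comp in sorted(components.values(), key=lambda c: sorted(c)[0]):
        mrca = tree.mrca(comp)
        clade = tree.subtree_tips(mrca)
        if not comp <= clade:
            raise LossMapError("component not contained in its MRCA clade")
        inside_coding = sorted(clade & coding)
        if inside_coding:
            warnings.append(
                f"coding tip(s) {inside_coding} inside loss clade of "
                f"{sorted(comp)} (Dollo-consistency / homoplasy warning)"
            )
        supporting = [cid for cid, mem in cluster_members.items()
                      if len(set(mem) & comp) >= 1 and set(mem) <= comp]
        events.append(LossEvent(edge_tips=clade, members=frozenset(comp),
                                clusters=supporting))
    return LossEventSet(events=events, warnings=warnings)


def _dollo_events(tree: SpeciesTree, inactive: list[str],
                  coding: set[str]) -> LossEventSet:
    """Plain Dollo: greedily take the highest admissible edges."""
    inactive_set = set(inactive)
    # candidate nodes whose clade contains only inactivated/unresolved tips
    admissible = []
    for v in range(tree.n_nodes):
        clade = tree.subtree_tips(v)
        if clade and not (clade & coding) and (clade & inactive_set):
            admissible.append((len(clade), v, clade))
    admissible.sort(key=lambda x: -x[0])
    covered: set[str] = set()
    events = []
    for _, v, clade in admissible:
        hits = (clade & inactive_set) - covered
        if not hits:
            continue
        if clade & covered:
            continue
        covered |= clade & inactive_set
        events.append(LossEvent(edge_tips=clade,
                                members=frozenset(clade & inactive_set)))
        if covered == inactive_set:
            break
    return LossEventSet(events=events)
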