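"""Synthetic-data generators with the statistical structure each pipeline
stage assumes: codon alignments evolved under branch-specific dN/dS, genomic
loci with planted ORF disruptions, read-evidence pileups, genotype panels
under HWE or inbreeding, and neutral coalescent haplotypes.

Every generator is deterministic given (scenario, seed): a single seed fans
out to labelled substreams, so adding one generator call never perturbs the
draws of another.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .annotate import DisruptionEvent, ReadEvidence
from .codonmodel import (
    CODONS,
    CODON_INDEX,
    CodonAlignment,
    CodonModelParams,
    BranchModelSpec,
    transition_kernels,
    rate_matrix,
    STOPS,
)
from .genemodel import GeneModel, STOP_CODONS, left_align_indel
from .trees import SpeciesTree


def substream(seed: int, label: str) -> np.random.Generator:
    """Deterministic per-purpose random stream derived from one global seed."""
    return np.random.default_rng(
        np.random.SeedSequence([seed & 0x7FFFFFFF, zlib.crc32(label.encode())])
    )


@dataclass
class SimTruth:
    scenario: str
    seed: int
    params: dict = field(default_factory=dict)
    events: list[DisruptionEvent] = field(default_factory=list)


# --------------------------------------------------------------------------
# codon alignments under branch models
# --------------------------------------------------------------------------

def sim_codon_alignment(tree: SpeciesTree, spec: BranchModelSpec,
                        params: CodonModelParams, n_codons: int,
                        seed: int, log_events: bool = False):
    """Evolve codon sequences down the tree under per-edge omega classes.

    Root codons are drawn from the stationary distribution pi; each branch
    applies the transition kernel expm(t*Q) of its omega class. With
    ``log_events`` the branch process is simulated event by event (Gillespie)
    so the substitution log (synonymous vs nonsynonymous counts) is exact.
    """
    rng = substream(seed, "codon-alignment")
    pi = np.asarray(params.pi)
    class_arr = spec.class_array(tree)
    omegas = [params.omega_by_class[c] for c in range(spec.n_classes)]
    kernels = [transition_kernels(pi, params.kappa, w) for w in omegas]
    qs = [rate_matrix(pi, params.kappa, w) for w in omegas]

    states: dict[int, np.ndarray] = {}
    root = tree.root
    states[root] = rng.choice(len(CODONS), size=n_codons, p=pi)
    event_log: list[tuple[str, int, int, int]] = []  # (branch, site, from, to)

    order = list(reversed(range(tree.n_nodes)))  # root-first traversal
    for v in order:
        for c in tree.children[v]:
            t = params.branch_lengths.get(c, tree.lengths[c])
            cls = int(class_arr[c])
            parent_state = states[v]
            if log_events:
                child = parent_state.copy()
                q = qs[cls]
                for site in range(n_codons):
                    s = int(child[site])
                    remaining = t
                    while True:
                        rate = -q[s, s]
                        if rate <= 0:
                            break
                        wait = rng.exponential(1.0 / rate)
                        if wait > remaining:
                            break
                        remaining -= wait
                        probs = q[s].copy()
                        probs[s] = 0.0
                        probs /= probs.sum()
                        s_new = int(rng.choice(len(CODONS), p=probs))
                        event_log.append((c, site, s, s_new))
                        s = s_new
                    child[site] = s
                states[c] = child
            else:
                p = kernels[cls](float(t))
                cum = np.cumsum(p, axis=1)
                u = rng.random(n_codons)
                states[c] = np.array([
                    int(np.searchsorted(cum[s], ui, side="right"))
                    for s, ui in zip(parent_state, u)
                ]).clip(0, len(CODONS) - 1)

    taxa, rows = [], []
    for v in range(tree.n_nodes):
        name = tree.node_taxon[v]
        if name is not None:
            taxa.append(name)
            rows.append(states[v])
    aln = CodonAlignment(taxa=taxa, codons=np.vstack(rows))
    truth = SimTruth(scenario="codon-alignment", seed=seed,
                     params={"spec": spec, "model": params,
                             "event_log": event_log})
    return aln, truth


def sim_reference_gene(exon_lengths: Sequence[int] = (276, 171, 417, 276, 267),
                       gene_id: str = "GBA3", species: str = "Homo_sapiens",
                       donor_dialect: Sequence[str] | None = None,
                       intergenic: int = 1000, seed: int = 0) -> GeneModel:
    """Synthetic reference gene model with a stop-free random CDS.

    Defaults mirror the human GBA3 geometry: five exons totalling a 1407-bp
    ORF encoding 469 residues, with a GC donor dialect at intron 2.
    """
    from .codonmodel import AMINO, CODONS as SENSE_CODONS

    total = sum(exon_lengths)
    if total % 3 != 0:
        raise ValueError("exon lengths must sum to a multiple of 3")
    rng = substream(seed, "reference-gene")
    by_aa: dict[str, list[str]] = {}
    for c, a in zip(SENSE_CODONS, AMINO):
        by_aa.setdefault(a, []).append(c)
    aas = sorted(set(AMINO))
    prot = "".join(rng.choice(aas, size=total // 3))
    cds = "".join(str(rng.choice(by_aa[a])) for a in prot)
    exons, off = [], 0
    for L in exon_lengths:
        exons.append((off + intergenic, off + intergenic + L))
        off += L + intergenic
    if donor_dialect is None and len(exon_lengths) == 5:
        donor_dialect = ["GT", "GC", "GT", "GT"]
    return GeneModel(gene_id=gene_id, species=species, contig_id="contig1",
                     strand="+", exons=exons, cds_seq=cds,
                     donor_dialect=list(donor_dialect or []))


def random_disruption_plan(model: GeneModel, rng: np.random.Generator,
                           max_edits: int = 3,
                           boundary_margin: int = 6) -> list[PlannedEdit]:
    """Random mix of planted stops, indels and splice losses for one locus.

    Edits stay inside a single exon and keep ``boundary_margin`` bases away
    from exon boundaries: a substitution or indel touching the first or last
    bases of an exon is annotationally ambiguous (it can equally be read as
    a moved splice boundary), which even manual curation cannot resolve.
    """
    cds_len = len(model.cds_seq)
    exon_bounds = []
    off = 0
    for s, e in model.exons:
        exon_bounds.append((off + 1 + boundary_margin,
                            off + (e - s) - boundary_margin))
        off += e - s
    interior_codons = [c for c in range(2, cds_len // 3)
                       if any(lo <= 3 * c - 2 and 3 * c <= hi
                              for lo, hi in exon_bounds)]
    plan: list[PlannedEdit] = []
    n = int(rng.integers(1, max_edits + 1))
    for _ in range(n):
        kind = str(rng.choice(["stop", "deletion", "insertion",
                               "splice_loss"]))
        if kind == "stop":
            codon = int(rng.choice(interior_codons))
            plan.append(PlannedEdit(
                kind="stop", cds_nt_pos=3 * codon - 2,
                stop_codon=str(rng.choice(["TAA", "TAG", "TGA"]))))
        elif kind == "deletion":
            length = int(rng.choice([1, 2, 3, 4, 10, 13]))
            lo, hi = exon_bounds[int(rng.integers(0, len(exon_bounds)))]
            if hi - length <= lo:
                continue
            pos = int(rng.integers(lo, hi - length + 1))
            plan.append(PlannedEdit(kind="deletion", cds_nt_pos=pos,
                                    length=length))
        elif kind == "insertion":
            length = int(rng.choice([1, 2, 3, 4, 10]))
            lo, hi = exon_bounds[int(rng.integers(0, len(exon_bounds)))]
            pos = int(rng.integers(lo, hi))
            seq = "".join(rng.choice(list("ACGT"), size=length))
            plan.append(PlannedEdit(kind="insertion", cds_nt_pos=pos,
                                    insert_seq=seq))
        else:
            intron = int(rng.integers(1, model.n_exons))
            side = str(rng.choice(["donor", "acceptor"]))
            plan.append(PlannedEdit(
                kind="splice_loss", intron_index=intron, splice_site=side,
                new_dinucleotide=str(rng.choice(["AT", "TT", "CC", "GA"]))))
    return plan


def sim_relax_alignment(tree: SpeciesTree, test_labels: Sequence[str],
                        omegas: Sequence[float], weights: Sequence[float],
                        K: float, n_codons: int, kappa: float = 2.0,
                        pi: np.ndarray | None = None, seed: int = 0):
    """Site-mixture alignment for selection-intensity testing.

    Each codon site draws an omega category; background branches use
    ``omega_i`` and the test branches ``omega_i ** K`` (K = 1 is the null of
    no shift in selection intensity).
    """
    if len(omegas) != len(weights):
        raise ValueError("omegas and weights must have equal length")
    if abs(sum(weights) - 1.0) > 1e-8:
        raise ValueError("weights must sum to 1")
    rng = substream(seed, "relax-mixture")
    if pi is None:
        pi = np.full(len(CODONS), 1.0 / len(CODONS))
    test_edges: set[int] = set()
    for label in test_labels:
        test_edges |= tree.label_edges(label)
    cats = rng.choice(len(omegas), size=n_codons, p=np.asarray(weights))
    mat = np.zeros((tree.n_tips, n_codons), dtype=int)
    taxa: list[str] | None = None
    for cat, om in enumerate(omegas):
        idx = np.where(cats == cat)[0]
        if idx.size == 0:
            continue
        om_test = om ** K
        spec = BranchModelSpec(
            f"relax-cat{cat}",
            {v: (1 if v in test_edges else 0)
             for v in range(tree.n_nodes - 1)}, 2)
        params = CodonModelParams(
            kappa=kappa, pi=pi, omega_by_class={0: om, 1: om_test},
            branch_lengths={v: tree.lengths[v]
                            for v in range(tree.n_nodes - 1)})
        sub, _ = sim_codon_alignment(tree, spec, params, int(idx.size),
                                     seed=(seed * 31 + cat) & 0x7FFFFFFF)
        if taxa is None:
            taxa = sub.taxa
        for r, t in enumerate(taxa):
            mat[r, idx] = sub.codons[sub.taxa.index(t)]
    aln = CodonAlignment(taxa=taxa or list(tree.taxa), codons=mat)
    truth = SimTruth(scenario="relax-mixture", seed=seed,
                     params={"omegas": list(omegas), "weights": list(weights),
                             "K": K, "categories": cats})
    return aln, truth


# --------------------------------------------------------------------------
# gene loci with planted disruptions
# --------------------------------------------------------------------------

@dataclass
class PlannedEdit:
    """One planted mutation, in reference CDS coordinates (1-based)."""

    kind: str                      # stop | insertion | deletion | splice_loss | missing
    cds_nt_pos: int = 0            # anchor for stop/indel edits
    length: int = 0                # deletion length
    insert_seq: str = ""           # insertion content
    stop_codon: str = "TAA"
    intron_index: int = 0          # 1-based, for splice_loss
    splice_site: str = "donor"     # donor | acceptor
    new_dinucleotide: str = "AT"
    exon_index: int = 0            # for missing-data masking


def sim_gene_locus(model: GeneModel, plan: Sequence[PlannedEdit],
                   intron_len: int = 500, seed: int = 0):
    """Build a genomic slice containing the gene with planted disruptions.

    Exons (edited per the plan) are joined by random introns carrying the
    model's declared splice dialects; the expected disruption events —
    including premature stops induced downstream of frameshifting indels —
    are computed by brute force (apply edits to the CDS, then re-translate)
    and returned in the truth table.
    """
    rng = substream(seed, "gene-locus")
    cds_len = len(model.cds_seq)
    exon_offsets, off = [], 0
    for s, e in model.exons:
        exon_offsets.append(off)
        off += e - s

    def exon_of(pos1: int) -> int:
        for i in range(len(exon_offsets) - 1, -1, -1):
            if pos1 > exon_offsets[i]:
                return i + 1
        return 1

    # items: (char, ref_pos or None) in CDS space
    items: list[tuple[str, int | None]] = [
        (ch, i + 1) for i, ch in enumerate(model.cds_seq)
    ]
    truth_events: list[DisruptionEvent] = []
    missing_exons = {p.exon_index for p in plan if p.kind == "missing"}
    splice_edits: dict[tuple[int, str], str] = {}

    def index_of(pos1: int) -> int:
        for k, (_c, rp) in enumerate(items):
            if rp == pos1:
                return k
        raise ValueError(f"edit position {pos1} outside CDS")

    for edit in sorted([p for p in plan if p.kind in {"insertion", "deletion"}],
                       key=lambda p: -p.cds_nt_pos):
        if not 1 <= edit.cds_nt_pos <= cds_len:
            raise ValueError(f"edit outside CDS at {edit.cds_nt_pos}")
        if edit.kind == "deletion":
            if edit.cds_nt_pos + edit.length - 1 > cds_len:
                raise ValueError("deletion runs past CDS end")
            if exon_of(edit.cds_nt_pos) != exon_of(
                    edit.cds_nt_pos + edit.length - 1):
                raise ValueError(
                    "deletion crosses an exon boundary: not representable "
                    "as a single genomic deletion")
            raw = model.cds_seq[edit.cds_nt_pos - 1:
                                edit.cds_nt_pos - 1 + edit.length]
            # apply at the canonical (left-aligned) placement so the edited
            # sequence matches what alignment-based detection reconstructs
            pos, dstr = left_align_indel(model.cds_seq, edit.cds_nt_pos,
                                         raw, "deletion")
            k = index_of(pos)
            del items[k: k + edit.length]
            truth_events.append(DisruptionEvent(
                species=model.species, gene_id=model.gene_id, kind="deletion",
                exon_index=exon_of(pos), cds_nt_pos=pos,
                codon_index=(pos + 2) // 3,
                indel_len=edit.length, allele=dstr))
        else:
            if not edit.insert_seq:
                raise ValueError("insertion needs insert_seq")
            pos, istr = left_align_indel(model.cds_seq, edit.cds_nt_pos,
                                         edit.insert_seq.upper(), "insertion")
            k = index_of(pos)
            items[k:k] = [(ch, None) for ch in istr]
            truth_events.append(DisruptionEvent(
                species=model.species, gene_id=model.gene_id, kind="insertion",
                exon_index=exon_of(pos), cds_nt_pos=pos,
                codon_index=(pos + 2) // 3,
                indel_len=len(edit.insert_seq), allele=istr))

    for edit in plan:
        if edit.kind == "stop":
            codon = (edit.cds_nt_pos + 2) // 3
            start1 = 3 * (codon - 1) + 1
            if start1 + 2 > cds_len:
                raise ValueError("stop edit outside CDS")
            if edit.stop_codon not in STOP_CODONS:
                raise ValueError(f"not a stop codon: {edit.stop_codon}")
            for off3 in range(3):
                k = index_of(start1 + off3)
                items[k] = (edit.stop_codon[off3], items[k][1])
        elif edit.kind == "splice_loss":
            if not 1 <= edit.intron_index <= model.n_exons - 1:
                raise ValueError("intron index out of range")
            splice_edits[(edit.intron_index, edit.splice_site)] = \
                edit.new_dinucleotide.upper()

    # expected premature stops via brute-force re-translation
    chars = [c for c, _ in items]
    refs = [r for _, r in items]
    for cstart in range(0, len(chars) - len(chars) % 3, 3):
        codon = "".join(chars[cstart: cstart + 3])
        codon_refs = [r for r in refs[cstart: cstart + 3] if r is not None]
        ref_nt = codon_refs[0] if codon_refs else None
        if ref_nt is None:
            prev = [r for r in refs[:cstart] if r is not None]
            ref_nt = prev[-1] if prev else 1
        exon_idx = exon_of(ref_nt)
        if exon_idx in missing_exons:
            continue
        if codon in STOP_CODONS:
            ref_codon = (ref_nt + 2) // 3
            if ref_codon <= len(model.protein_seq):
                truth_events.append(DisruptionEvent(
                    species=model.species, gene_id=model.gene_id,
                    kind="premature_stop", exon_index=exon_idx,
                    cds_nt_pos=ref_nt, codon_index=ref_codon, allele=codon))

    for (intron, site), dinuc in sorted(splice_edits.items()):
        if site == "donor":
            pos = exon_offsets[intron - 1] + (
                model.exons[intron - 1][1] - model.exons[intron - 1][0])
            expected = model.donor_dialect[intron - 1]
            exon_idx = intron
        else:
            pos = exon_offsets[intron] + 1
            expected = "AG"
            exon_idx = intron + 1
        if dinuc != expected:
            truth_events.append(DisruptionEvent(
                species=model.species, gene_id=model.gene_id,
                kind="splice_loss", exon_index=exon_idx, cds_nt_pos=pos,
                codon_index=(pos + 2) // 3, splice_site=site,
                observed_site=dinuc, allele=dinuc))

    # assemble the slice: edited exons joined by introns
    exon_edits: list[list[str]] = [[] for _ in model.exons]
    last_exon = 1
    for ch, rp in items:
        if rp is not None:
            last_exon = exon_of(rp)
        # insertions attach to the exon of the previous reference base
        exon_edits[last_exon - 1].append(ch)
    exon_strs = ["".join(x) for x in exon_edits]
    for i in range(len(exon_strs)):
        if (i + 1) in missing_exons:
            exon_strs[i] = "N" * len(exon_strs[i])
    parts = []
    for i, ex in enumerate(exon_strs):
        parts.append(ex)
        if i < len(exon_strs) - 1:
            donor = splice_edits.get((i + 1, "donor"), model.donor_dialect[i])
            acceptor = splice_edits.get((i + 1, "acceptor"), "AG")
            interior = "".join(rng.choice(list("ACGT"),
                                          size=max(0, intron_len - 4)))
            parts.append(donor + interior + acceptor)
    slice_seq = "".join(parts)
    truth_events.sort(key=lambda e: (e.cds_nt_pos, e.kind))
    truth = SimTruth(scenario="gene-locus", seed=seed,
                     params={"plan": list(plan)}, events=truth_events)
    return slice_seq, truth


# --------------------------------------------------------------------------
# read evidence, genotypes, coalescent haplotypes
# --------------------------------------------------------------------------

def sim_read_evidence(events: Sequence[DisruptionEvent], depth: int,
                      disrupted_allele_freq: float, n_projects: int,
                      seed: int = 0) -> list[ReadEvidence]:
    """Binomial pileup summaries per event per sequencing project."""
    if not 0.0 <= disrupted_allele_freq <= 1.0:
        raise ValueError("allele frequency outside [0,1]")
    rng = substream(seed, "read-evidence")
    out = []
    for event in events:
        for p in range(n_projects):
            d = int(rng.binomial(depth, disrupted_allele_freq))
            out.append(ReadEvidence(
                project_id=f"proj{p + 1}", species=event.species,
                event_key=event.key(), reads_disrupted=d,
                reads_intact=depth - d))
    return out


def sim_genotypes(pop_freqs: dict[str, float], n_per_pop: int,
                  inbreeding_f: float = 0.0,
                  seed: int = 0) -> dict[str, tuple[int, int, int]]:
    """Genotype panels under HWE with optional inbreeding coefficient f.

    Genotype probabilities are (p^2 + f p q, 2 p q (1 - f), q^2 + f p q).
    """
    if not 0.0 <= inbreeding_f <= 1.0:
        raise ValueError("inbreeding coefficient outside [0,1]")
    rng = substream(seed, "genotypes")
    out = {}
    for pop, q in pop_freqs.items():
        if not 0.0 <= q <= 1.0:
            raise ValueError(f"allele frequency {q} outside [0,1]")
        p = 1.0 - q
        probs = [p * p + inbreeding_f * p * q,
                 2 * p * q * (1 - inbreeding_f),
                 q * q + inbreeding_f * p * q]
        counts = rng.multinomial(n_per_pop, probs)
        out[pop] = (int(counts[0]), int(counts[1]), int(counts[2]))
    return out


def sim_coalescent_haplotypes(n: int, theta: float, region_bp: int,
                              seed: int = 0):
    """Standard neutral coalescent with infinite-sites mutation.

    Time is in units of 2N generations: while k lineages remain the waiting
    time is Exp(k(k-1)/2), a random pair merges, and mutations fall on each
    branch as Poisson(theta/2 * length), placed uniformly in the region.
    Returns (haplotype matrix (n, S), positions, tmrca).
    """
    if n < 2:
        raise ValueError("need n >= 2")
    rng = substream(seed, "coalescent")
    lineages: list[tuple[frozenset[int], float]] = [
        (frozenset([i]), 0.0) for i in range(n)
    ]  # (descendant tips, branch start time)
    t = 0.0
    branches: list[tuple[frozenset[int], float]] = []  # (tips, length)
    while len(lineages) > 1:
        k = len(lineages)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        tips_i, start_i = lineages[i]
        tips_j, start_j = lineages[j]
        branches.append((tips_i, t - start_i))
        branches.append((tips_j, t - start_j))
        merged = (tips_i | tips_j, t)
        lineages = [lineages[m] for m in range(k) if m not in (i, j)]
        lineages.append(merged)
    tmrca = t
    sites, positions = [], []
    for tips, length in branches:
        n_mut = rng.poisson(theta / 2.0 * length)
        for _ in range(n_mut):
            col = np.zeros(n, dtype=int)
            col[list(tips)] = 1
            sites.append(col)
            positions.append(float(rng.uniform(0, region_bp)))
    if sites:
        order = np.argsort(positions)
        hap = np.vstack([sites[i] for i in order]).T
        pos = np.array([positions[i] for i in order])
    else:
        hap = np.zeros((n, 0), dtype=int)
        pos = np.array([])
    return hap, pos, tmrca
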