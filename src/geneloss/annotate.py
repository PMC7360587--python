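"""Reference-guided gene annotation: exon mapping, ORF-disruption calling,
read-evidence validation and gene-status classification.

The workflow mirrors how pseudogenes are annotated by hand: each reference
exon is located in the target genomic slice by pairwise alignment, the
reconstructed coding sequence is re-translated in the reference frame
(tracking frame through indels), and every premature stop, frameshifting
indel and non-canonical splice site becomes a :class:`DisruptionEvent`.
Events are then validated against read-level evidence (pileup summaries from
independent sequencing projects) and the gene is classified as coding,
pseudogene, polymorphic pseudogene or unresolved.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from Bio import Align

from .genemodel import GeneModel, STOP_CODONS, left_align_indel

VALID_STATUSES = ("validated_fixed", "validated_polymorphic", "unvalidated")

#: affine alignment scores used for exon mapping (match, mismatch, open, extend)
ALIGN_SCORES = (2.0, -3.0, -8.0, -2.0)
#: an exon mapping is accepted when identity >= 0.6 over >= 60% of its length
MIN_IDENTITY = 0.6
MIN_COVERAGE = 0.6
#: splice boundaries may slide this many bases to restore dialect conformity
SPLICE_REFINE_WINDOW = 12


class AnnotationError(ValueError):
    pass


@dataclass
class ExonAlignment:
    """One reference exon aligned into the target genomic slice."""

    exon_index: int                      # 1-based
    ref_aligned: str
    tgt_aligned: str
    tgt_interval: tuple[int, int]        # 0-based half-open in the slice
    identity: float
    acceptor_obs: str | None = None      # dinucleotide before the exon
    donor_obs: str | None = None         # dinucleotide after the exon
    missing_data: bool = False

    def __post_init__(self) -> None:
        if len(self.ref_aligned) != len(self.tgt_aligned):
            raise AnnotationError("gapped strings must have equal length")


@dataclass
class DisruptionEvent:
    """One ORF-disrupting mutation in a target gene copy."""

    species: str
    gene_id: str
    kind: str                            # premature_stop | insertion | deletion | splice_loss
    exon_index: int
    cds_nt_pos: int                      # 1-based, reference frame
    codon_index: int                     # 1-based, reference frame
    indel_len: int = 0
    frameshift: bool = False
    splice_site: str | None = None       # acceptor | donor
    observed_site: str | None = None
    stop_context: str | None = None      # e.g. "DSLFX"
    allele: str | None = None            # stop codon or inserted/deleted string
    cluster_id: str | None = None
    validation: str = "unvalidated"
    n_supporting_projects: int = 0

    def __post_init__(self) -> None:
        if self.kind in {"insertion", "deletion"}:
            expect_fs = self.indel_len % 3 != 0
            if self.frameshift != expect_fs:
                self.frameshift = expect_fs
        elif self.frameshift or self.indel_len:
            raise AnnotationError(
                f"{self.kind} events carry no indel length/frameshift flag"
            )
        if self.stop_context is not None and not self.stop_context.endswith("X"):
            raise AnnotationError("stop_context must end in 'X'")
        if self.validation not in VALID_STATUSES:
            raise AnnotationError(f"bad validation status {self.validation!r}")

    @property
    def disrupting(self) -> bool:
        """In-frame indels preserve the reading frame and do not disrupt."""
        if self.kind in {"premature_stop", "splice_loss"}:
            return True
        return self.frameshift

    def key(self) -> str:
        """Locus key used to join read evidence and shared clusters."""
        return f"{self.kind}:{self.exon_index}:{self.cds_nt_pos}:{self.indel_len}"


@dataclass
class ReadEvidence:
    """Pileup summary for one event locus in one sequencing project."""

    project_id: str
    species: str
    event_key: str
    reads_disrupted: int
    reads_intact: int

    def __post_init__(self) -> None:
        if self.reads_disrupted < 0 or self.reads_intact < 0:
            raise AnnotationError("read counts must be non-negative")


@dataclass
class GeneStatusCall:
    species: str
    gene_id: str
    status: str                          # coding | pseudogene | polymorphic_pseudogene | unresolved
    events: list[DisruptionEvent] = field(default_factory=list)


# --------------------------------------------------------------------------
# exon mapping
# --------------------------------------------------------------------------

def _make_aligner() -> Align.PairwiseAligner:
    match, mismatch, gap_open, gap_extend = ALIGN_SCORES
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    # free end gaps on the genomic slice: semi-global alignment so the full
    # exon is aligned (terminal mismatches included) at its best location
    aligner.open_end_deletion_score = 0.0
    aligner.extend_end_deletion_score = 0.0
    return aligner


def _gapped_strings(alignment, target: str, query: str):
    """Rebuild gapped strings over the aligned target span from block pairs."""
    t_blocks, q_blocks = alignment.aligned
    if len(t_blocks) == 0:
        return "", "", (0, 0)
    ref_parts, tgt_parts = [], []
    prev_t, prev_q = None, None
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        if prev_t is not None:
            dt, dq = ts - prev_t, qs - prev_q
            tgt_parts.append(target[prev_t:ts] + "-" * dq)
            ref_parts.append("-" * dt + query[prev_q:qs])
        tgt_parts.append(target[ts:te])
        ref_parts.append(query[qs:qe])
        prev_t, prev_q = te, qe
    start, end = int(t_blocks[0][0]), int(t_blocks[-1][1])
    return "".join(ref_parts), "".join(tgt_parts), (start, end)


def _identity(ref_aln: str, tgt_aln: str) -> float:
    pairs = [(r, t) for r, t in zip(ref_aln, tgt_aln) if r != "-" and t != "-"]
    if not pairs:
        return 0.0
    matches = sum(r == t for r, t in pairs if r != "N" and t != "N")
    return matches / len(pairs)


def _alignment_score(ref_aln: str, tgt_aln: str) -> float:
    match, mismatch, gap_open, gap_extend = ALIGN_SCORES
    score, in_gap = 0.0, False
    for r, t in zip(ref_aln, tgt_aln):
        if r == "-" or t == "-":
            score += gap_extend if in_gap else gap_open
            in_gap = True
        else:
            score += match if r == t else mismatch
            in_gap = False
    return score


def map_exons(model: GeneModel, genomic: str) -> list[ExonAlignment]:
    """Locate each reference exon in a genomic slice, in reference order.

    Exons are sought left to right in the remainder of the slice, each via a
    semi-global affine alignment. Mappings with identity below
    ``MIN_IDENTITY`` over ``MIN_COVERAGE`` of the exon are flagged
    ``missing_data``. The two bases flanking each mapped exon are extracted
    as the observed splice dinucleotides, with boundaries refined within
    +/- ``SPLICE_REFINE_WINDOW`` bp when a score-neutral shift restores the
    declared dialect (placement ambiguity at junctions, not true losses).
    """
    if not genomic:
        raise AnnotationError("empty genomic slice")
    genomic = genomic.upper()
    aligner = _make_aligner()
    out: list[ExonAlignment] = []
    cursor = 0
    exon_seqs = model.exon_seqs
    n = len(exon_seqs)
    for idx, exon_seq in enumerate(exon_seqs, start=1):
        window = genomic[cursor:]
        if not window:
            out.append(ExonAlignment(idx, exon_seq, "-" * len(exon_seq),
                                     (len(genomic), len(genomic)), 0.0,
                                     missing_data=True))
            continue
        aln = aligner.align(window, exon_seq)[0]
        ref_aln, tgt_aln, (s, e) = _gapped_strings(aln, window, exon_seq)
        s, e = s + cursor, e + cursor
        identity = _identity(ref_aln, tgt_aln)
        covered = sum(1 for r, t in zip(ref_aln, tgt_aln)
                      if r != "-" and t != "-") / len(exon_seq)
        # spurious gap-riddled placements reach the identity threshold on
        # random sequence but always score negative under the affine scheme
        missing = (identity < MIN_IDENTITY or covered < MIN_COVERAGE
                   or _alignment_score(ref_aln, tgt_aln) <= 0)
        ea = ExonAlignment(idx, ref_aln, tgt_aln, (s, e), identity,
                           missing_data=missing)
        if not missing:
            cursor = e
        out.append(ea)
    if all(ea.missing_data for ea in out):
        raise AnnotationError("locus not found: no exon could be mapped")
    # splice boundary refinement + flanking dinucleotides
    for i, ea in enumerate(out):
        if ea.missing_data:
            continue
        s, e = ea.tgt_interval
        if i > 0:
            s = _refine_boundary(genomic, ea, side="acceptor",
                                 expected=model.acceptor_dialect[i - 1])
            ea.acceptor_obs = genomic[max(0, s - 2): s] if s >= 2 else None
        if i < n - 1:
            e = _refine_boundary(genomic, ea, side="donor",
                                 expected=model.donor_dialect[i])
            ea.donor_obs = genomic[e: e + 2] if e + 2 <= len(genomic) else None
    return out


def _refine_boundary(genomic: str, ea: ExonAlignment, side: str,
                     expected: str) -> int:
    """Slide an exon boundary to a score-neutral, dialect-conforming spot."""
    s, e = ea.tgt_interval
    pos = s if side == "acceptor" else e
    current = genomic[pos - 2: pos] if side == "acceptor" else genomic[pos: pos + 2]
    if current == expected:
        return pos
    base_score = _alignment_score(ea.ref_aligned, ea.tgt_aligned)
    ref_ungapped = ea.ref_aligned.replace("-", "")
    for shift in sorted(range(-SPLICE_REFINE_WINDOW, SPLICE_REFINE_WINDOW + 1),
                        key=abs):
        if shift == 0:
            continue
        if side == "acceptor":
            ns, ne = s + shift, e
        else:
            ns, ne = s, e + shift
        if ns < 0 or ne > len(genomic) or ne <= ns:
            continue
        dinuc = (genomic[ns - 2: ns] if side == "acceptor"
                 else genomic[ne: ne + 2])
        if dinuc != expected:
            continue
        # score-neutral check: re-score the reference exon against the
        # shifted target span; only placement-ambiguous shifts qualify
        cand = _quick_rescore(ref_ungapped, genomic[ns:ne])
        if cand is not None and cand[0] >= base_score:
            ea.tgt_interval = (ns, ne)
            ea.ref_aligned, ea.tgt_aligned = cand[1], cand[2]
            return ns if side == "acceptor" else ne
    return pos


def _quick_rescore(ref_seq: str, tgt_seq: str) -> tuple[float, str, str] | None:
    if not tgt_seq:
        return None
    aligner = _make_aligner()
    aln = aligner.align(tgt_seq, ref_seq)[0]
    ref_aln, tgt_aln, (s, e) = _gapped_strings(aln, tgt_seq, ref_seq)
    if s != 0 or e != len(tgt_seq):
        return None  # the shifted span is not fully used: not score-neutral
    return _alignment_score(ref_aln, tgt_aln), ref_aln, tgt_aln


# --------------------------------------------------------------------------
# disruption detection
# --------------------------------------------------------------------------

def detect_disruptions(alignments: Sequence[ExonAlignment],
                       model: GeneModel,
                       context_k: int = 4) -> list[DisruptionEvent]:
    """Call ORF-disrupting mutations from per-exon alignments.

    The target CDS is reconstructed exon by exon (reference sequence is
    substituted for exons flagged missing so the reading frame stays
    anchored), indel runs become insertion/deletion events, the edited CDS
    is re-translated codon by codon to find premature stops (frame tracked
    through upstream indels), and observed splice dinucleotides are checked
    against the model's declared dialect. Codons containing N are skipped
    for stop detection.
    """
    events: list[DisruptionEvent] = []
    exon_seqs = model.exon_seqs
    exon_offsets = []
    off = 0
    for seq in exon_seqs:
        exon_offsets.append(off)
        off += len(seq)

    edited: list[str] = []            # reconstructed CDS characters
    edited_ref_pos: list[int | None] = []   # 1-based ref coord per char
    edited_exon: list[int] = []       # exon index per char
    edited_missing: list[bool] = []   # char comes from a missing-data exon

    for ea in alignments:
        i = ea.exon_index - 1
        base = exon_offsets[i]
        if ea.missing_data:
            for j, ch in enumerate(exon_seqs[i]):
                edited.append(ch)
                edited_ref_pos.append(base + j + 1)
                edited_exon.append(ea.exon_index)
                edited_missing.append(True)
            continue
        ref_pos = base            # 0-based count of ref bases consumed
        col = 0
        ncols = len(ea.ref_aligned)
        while col < ncols:
            r, t = ea.ref_aligned[col], ea.tgt_aligned[col]
            if r != "-" and t != "-":
                edited.append(t)
                edited_ref_pos.append(ref_pos + 1)
                edited_exon.append(ea.exon_index)
                edited_missing.append(False)
                ref_pos += 1
                col += 1
            elif t == "-":        # deletion in target
                run = 0
                first = ref_pos + 1
                deleted = []
                while col < ncols and ea.tgt_aligned[col] == "-":
                    deleted.append(ea.ref_aligned[col])
                    ref_pos += 1
                    run += 1
                    col += 1
                first, dstr = left_align_indel(
                    model.cds_seq, first, "".join(deleted), "deletion")
                events.append(DisruptionEvent(
                    species=model.species, gene_id=model.gene_id,
                    kind="deletion", exon_index=ea.exon_index,
                    cds_nt_pos=first, codon_index=(first + 2) // 3,
                    indel_len=run, allele=dstr))
            else:                 # insertion in target
                run = 0
                inserted = []
                while col < ncols and ea.ref_aligned[col] == "-":
                    inserted.append(ea.tgt_aligned[col])
                    edited.append(ea.tgt_aligned[col])
                    edited_ref_pos.append(None)
                    edited_exon.append(ea.exon_index)
                    edited_missing.append(False)
                    run += 1
                    col += 1
                first = min(ref_pos + 1, len(model.cds_seq))
                first, istr = left_align_indel(
                    model.cds_seq, first, "".join(inserted), "insertion")
                events.append(DisruptionEvent(
                    species=model.species, gene_id=model.gene_id,
                    kind="insertion", exon_index=ea.exon_index,
                    cds_nt_pos=first, codon_index=(first + 2) // 3,
                    indel_len=run, allele=istr))

    # premature stops in the edited CDS, reference frame tracked via indels
    seq = "".join(edited)
    from Bio.Seq import Seq

    prot_parts: list[str] = []
    ref_len_aa = len(model.protein_seq)
    for cstart in range(0, len(seq) - len(seq) % 3, 3):
        codon = seq[cstart: cstart + 3]
        if any(edited_missing[cstart: cstart + 3]):
            prot_parts.append("?")
            continue
        if "N" in codon:
            prot_parts.append("?")
            continue
        aa = str(Seq(codon).translate())
        prot_parts.append(aa)
        if codon in STOP_CODONS:
            refs = [p for p in edited_ref_pos[cstart: cstart + 3] if p is not None]
            ref_nt = refs[0] if refs else _nearest_ref(edited_ref_pos, cstart)
            ref_codon = (ref_nt + 2) // 3
            if ref_codon <= ref_len_aa:
                ctx = "".join(
                    prot_parts[max(0, len(prot_parts) - 1 - context_k):-1])
                events.append(DisruptionEvent(
                    species=model.species, gene_id=model.gene_id,
                    kind="premature_stop", exon_index=edited_exon[cstart],
                    cds_nt_pos=ref_nt, codon_index=ref_codon,
                    stop_context=ctx.replace("?", "") + "X", allele=codon))

    # splice-site losses
    n = len(alignments)
    for ea in alignments:
        if ea.missing_data:
            continue
        i = ea.exon_index
        if i > 1 and ea.acceptor_obs is not None:
            if ea.acceptor_obs != "AG" and "N" not in ea.acceptor_obs:
                first = exon_offsets[i - 1] + 1
                events.append(DisruptionEvent(
                    species=model.species, gene_id=model.gene_id,
                    kind="splice_loss", exon_index=i, cds_nt_pos=first,
                    codon_index=(first + 2) // 3, splice_site="acceptor",
                    observed_site=ea.acceptor_obs, allele=ea.acceptor_obs))
        if i < n and ea.donor_obs is not None:
            expected = model.donor_dialect[i - 1]
            if ea.donor_obs != expected and "N" not in ea.donor_obs:
                last = exon_offsets[i - 1] + len(exon_seqs[i - 1])
                events.append(DisruptionEvent(
                    species=model.species, gene_id=model.gene_id,
                    kind="splice_loss", exon_index=i, cds_nt_pos=last,
                    codon_index=(last + 2) // 3, splice_site="donor",
                    observed_site=ea.donor_obs, allele=ea.donor_obs))

    events.sort(key=lambda e: (e.cds_nt_pos, e.kind))
    return events


def _nearest_ref(ref_pos: list[int | None], idx: int) -> int:
    for j in range(idx, -1, -1):
        if ref_pos[j] is not None:
            return ref_pos[j]
    return 1


def stop_context(protein: str, codon_index: int, k: int = 3) -> str:
    """The ``k`` residues preceding a stop at ``codon_index``, plus 'X'.

    ``codon_index`` may be ``len(protein) + 1`` (stop immediately after the
    last residue). Near the N-terminus the context is left-truncated.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not 1 <= codon_index <= len(protein) + 1:
        raise ValueError(
            f"codon_index {codon_index} out of range 1..{len(protein) + 1}"
        )
    return protein[max(0, codon_index - 1 - k): codon_index - 1] + "X"


# --------------------------------------------------------------------------
# validation and status calls
# --------------------------------------------------------------------------

def validate_events(events: Sequence[DisruptionEvent],
                    evidence: Iterable[ReadEvidence],
                    min_reads: int = 3) -> list[DisruptionEvent]:
    """Set each event's validation status from independent project pileups.

    ``validated_fixed`` requires >=2 projects each showing >= ``min_reads``
    disrupted reads with no intact read anywhere; ``validated_polymorphic``
    requires one project showing both alleles at >= ``min_reads`` reads, or
    different projects fixed for different alleles.
    """
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    evidence = list(evidence)
    known = {(e.species, e.key()) for e in events}
    for ev in evidence:
        if (ev.species, ev.event_key) not in known:
            raise AnnotationError(
                f"evidence references unknown event {ev.species}/{ev.event_key}"
            )
    out = []
    for event in events:
        evs = [e for e in evidence
               if e.species == event.species and e.event_key == event.key()]
        both = [e for e in evs if e.reads_disrupted >= min_reads
                and e.reads_intact >= min_reads]
        fixed_d = [e for e in evs if e.reads_disrupted >= min_reads
                   and e.reads_intact == 0]
        fixed_i = [e for e in evs if e.reads_intact >= min_reads
                   and e.reads_disrupted == 0]
        any_intact = any(e.reads_intact > 0 for e in evs)
        n_support = sum(e.reads_disrupted >= min_reads for e in evs)
        if both or (fixed_d and fixed_i):
            status = "validated_polymorphic"
        elif len(fixed_d) >= 2 and not any_intact:
            status = "validated_fixed"
        else:
            status = "unvalidated"
        out.append(replace(event, validation=status,
                           n_supporting_projects=n_support))
    return out


def call_status(species: str, gene_id: str,
                events: Sequence[DisruptionEvent],
                coverage_complete: bool = True) -> GeneStatusCall:
    """Classify a gene copy from its validated disruption events.

    coding: no disrupting event and complete coverage. pseudogene: at least
    one fixed, validated disrupting event. polymorphic_pseudogene: validated
    polymorphic disruption(s) but nothing fixed. unresolved otherwise
    (unvalidated disruptions, or no events with incomplete coverage).
    """
    disrupting = [e for e in events if e.disrupting]
    if any(e.validation == "validated_fixed" for e in disrupting):
        status = "pseudogene"
    elif any(e.validation == "validated_polymorphic" for e in disrupting):
        status = "polymorphic_pseudogene"
    elif not disrupting:
        status = "coding" if coverage_complete else "unresolved"
    else:
        status = "unresolved"
    return GeneStatusCall(species=species, gene_id=gene_id, status=status,
                          events=list(events))
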