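"""Gene models: exon structure plus reference CDS and protein.

Coordinates are 0-based half-open internally; HGVS-style positions
(c.1368, p.Y456X) are 1-based and produced only in reports. The reference
CDS excludes the terminal stop codon, so a 1407-bp ORF encodes 469
residues.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from Bio.Seq import Seq

from .readwrite import ParseError, read_fasta

STOP_CODONS = {"TAA", "TAG", "TGA"}


class InvariantError(ValueError):
    """A domain-type invariant does not hold."""


@dataclass
class GeneModel:
    """Exon structure and reference coding sequence of one gene.

    ``exons`` are genomic ``(start, end)`` intervals, 0-based half-open,
    sorted and non-overlapping, given on the gene's strand ordering
    (exon 1 first). ``donor_dialect[i]`` is the expected donor dinucleotide
    (GT or GC) of the intron following exon ``i+1``; acceptors are always AG.
    """

    gene_id: str
    species: str
    contig_id: str
    strand: str
    exons: list[tuple[int, int]]
    cds_seq: str
    donor_dialect: list[str] = field(default_factory=list)
    acceptor_dialect: list[str] = field(default_factory=list)
    protein_seq: str = ""

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise InvariantError(f"strand must be + or -, got {self.strand!r}")
        srt = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(srt, srt[1:]):
            if e1 > s2:
                raise InvariantError(f"overlapping exons {(s1, e1)} and {(s2, e2)}")
        for s, e in self.exons:
            if e <= s:
                raise InvariantError(f"empty exon interval {(s, e)}")
        total = sum(e - s for s, e in self.exons)
        if total != len(self.cds_seq):
            raise InvariantError(
                f"CDS length {len(self.cds_seq)} != sum of exon lengths {total}"
            )
        if len(self.cds_seq) % 3 != 0:
            raise InvariantError(
                f"reference CDS length {len(self.cds_seq)} not a multiple of 3"
            )
        self.cds_seq = self.cds_seq.upper()
        for i in range(0, len(self.cds_seq) - 3, 3):
            if self.cds_seq[i : i + 3] in STOP_CODONS:
                raise InvariantError(
                    f"internal in-frame stop at codon {i // 3 + 1} in reference CDS"
                )
        if self.cds_seq[-3:] in STOP_CODONS:
            raise InvariantError("reference CDS must not include the terminal stop")
        n_introns = len(self.exons) - 1
        if not self.donor_dialect:
            self.donor_dialect = ["GT"] * n_introns
        if not self.acceptor_dialect:
            self.acceptor_dialect = ["AG"] * n_introns
        if len(self.donor_dialect) != n_introns or len(self.acceptor_dialect) != n_introns:
            raise InvariantError("splice dialect lists must have one entry per intron")
        for d in self.donor_dialect:
            if d not in {"GT", "GC"}:
                raise InvariantError(f"donor dialect must be GT or GC, got {d!r}")
        if not self.protein_seq:
            self.protein_seq = str(Seq(self.cds_seq).translate())
        if len(self.protein_seq) != len(self.cds_seq) // 3:
            raise InvariantError("protein length != CDS length / 3")

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def exon_seqs(self) -> list[str]:
        """CDS split back into per-exon pieces (CDS orientation)."""
        out, offset = [], 0
        for s, e in self.exons:
            out.append(self.cds_seq[offset : offset + (e - s)])
            offset += e - s
        return out


def codon_of_cdna(cdna_pos: int) -> int:
    """1-based codon index of a 1-based coding-nucleotide position.

    c.1368 lies in codon 456, the position mutated to a premature stop in
    the human GBA3 pseudogene allele (p.Y456X).
    """
    if cdna_pos < 1:
        raise ValueError(f"cDNA position must be >= 1, got {cdna_pos}")
    return (cdna_pos + 2) // 3


def protein_length(orf_bp: int) -> int:
    """Number of residues encoded by an ORF of ``orf_bp`` coding nucleotides."""
    if orf_bp % 3 != 0:
        raise ValueError(f"ORF length {orf_bp} not a multiple of 3")
    return orf_bp // 3


def left_align_indel(ref: str, pos: int, allele: str,
                     kind: str) -> tuple[int, str]:
    """Canonical (left-most) placement of an indel in a reference sequence.

    ``pos`` is the 1-based first deleted base (deletions) or the 1-based
    reference base before which the insertion occurs. Shift-equivalent
    placements (the usual repeat ambiguity) are normalized so planted and
    detected events are comparable.
    """
    allele = allele.upper()
    L = len(allele)
    if kind == "deletion":
        while pos > 1 and ref[pos - 2] == allele[-1]:
            allele = ref[pos - 2] + allele[:-1]
            pos -= 1
    elif kind == "insertion":
        while pos > 1 and ref[pos - 2] == allele[-1]:
            allele = allele[-1] + allele[:-1]
            pos -= 1
    return pos, allele


def read_gene_model(gff_path: str | Path, fasta_path: str | Path) -> GeneModel:
    """Load one gene model from a GFF3-like exon table plus a contig FASTA.

    Only ``exon`` features are used; all rows must belong to a single gene
    (attribute ``gene_id=`` or ``ID=``). Minus-strand genes are returned in
    CDS orientation (exon 1 first, sequences reverse-complemented).
    """
    gff_path = Path(gff_path)
    contigs = read_fasta(fasta_path)
    rows = []
    gene_id = species = None
    with open(gff_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 9:
                raise ParseError(f"{gff_path}:{lineno}: expected 9 GFF columns")
            seqid, source, ftype, start, end, _score, strand, _phase, attrs = parts[:9]
            if ftype != "exon":
                continue
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            gid = attr.get("gene_id") or attr.get("ID") or "gene"
            if gene_id is None:
                gene_id = gid
            elif gid != gene_id:
                raise ParseError(f"{gff_path}:{lineno}: multiple genes in file")
            species = attr.get("species", source) if species is None else species
            rows.append((seqid, int(start) - 1, int(end), strand, attr))
    if not rows:
        raise ParseError(f"{gff_path}: no exon features found")
    contig_id = rows[0][0]
    strand = rows[0][3]
    if contig_id not in contigs:
        raise ParseError(f"{gff_path}: contig '{contig_id}' not in FASTA")
    contig = contigs[contig_id]
    ivs = sorted((s, e) for _, s, e, _, _ in rows)
    pieces = [contig[s:e] for s, e in ivs]
    donors = []
    # flanking dinucleotides straight from the contig, in genomic order
    for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
        donors.append((contig[e1 : e1 + 2], contig[max(0, s2 - 2) : s2]))
    if strand == "-":
        pieces = [str(Seq(p).reverse_complement()) for p in reversed(pieces)]
        ivs = list(reversed(ivs))
        donors = [
            (str(Seq(acc).reverse_complement()), str(Seq(don).reverse_complement()))
            for don, acc in reversed(donors)
        ]
    cds = "".join(pieces).upper()
    donor_dialect = []
    for don, _acc in donors:
        donor_dialect.append("GC" if don.upper() == "GC" else "GT")
    return GeneModel(
        gene_id=gene_id or "gene",
        species=species or "unknown",
        contig_id=contig_id,
        strand=strand,
        exons=ivs,
        cds_seq=cds,
        donor_dialect=donor_dialect,
    )
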