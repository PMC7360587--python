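"""Packaged in-study data: the disruption matrix, the labelled species tree,
the human population variant table, and the 14-model LRT ladder.

Genotype panels are synthetic stand-ins constructed to reproduce the
published per-population allele frequencies, the East Asian homozygote
frequency and the pooled non-African homozygote (HMA) frequency exactly at
the printed precision; PolyPhen/SIFT scores for missense rows are likewise
synthetic values inside the damaging ranges the original filter required
(the real per-variant scores are inputs to, not outputs of, this package).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import yaml

from ..annotate import DisruptionEvent, GeneStatusCall, call_status
from ..popgen import VariantRecord
from ..readwrite import read_tsv
from ..trees import SpeciesTree

#: GBA3-like reference geometry: 5 exons, 1407 coding bp, 469 residues
GBA3_EXON_LENGTHS = (276, 171, 417, 276, 267)
GBA3_CDS_LEN = sum(GBA3_EXON_LENGTHS)
#: species whose genomic coverage did not span the full ORF
INCOMPLETE_COVERAGE = {"Trichechus_manatus_latirostris"}


@dataclass
class FixtureBundle:
    events: list[DisruptionEvent]
    statuses: list[GeneStatusCall]
    tree: SpeciesTree
    variants: list[VariantRecord]
    genotype_panels: dict[str, tuple[int, int, int]]
    models: dict[str, dict[str, int]]
    ladder: list[dict]
    omegas_best: dict[str, float] = field(default_factory=dict)
    best_model: str = "M"


def _data(name: str):
    return resources.files("geneloss.fixtures").joinpath("data", name)


def load_fixtures() -> FixtureBundle:
    """Load and validate the packaged fixture bundle."""
    with resources.as_file(_data("species_tree.nwk")) as p:
        newick = p.read_text()
    with resources.as_file(_data("clade_labels.yaml")) as p:
        labels = yaml.safe_load(p.read_text())
    tree = SpeciesTree.from_newick_string(
        newick, labels.get("clades", {}), labels.get("branches", {}))

    with resources.as_file(_data("disruption_matrix.tsv")) as p:
        rows = read_tsv(p)
    events = []
    for r in rows:
        events.append(DisruptionEvent(
            species=r["species"], gene_id=r["gene_id"], kind=r["kind"],
            exon_index=int(r["exon_index"]), cds_nt_pos=int(r["cds_nt_pos"]),
            codon_index=int(r["codon_index"]), indel_len=int(r["indel_len"]),
            splice_site=r["splice_site"] or None,
            observed_site=r["observed_site"] or None,
            stop_context=r["stop_context"] or None,
            allele=r["allele"] or None,
            cluster_id=r["cluster_id"] or None,
            validation=r["validation"],
            n_supporting_projects=int(r["n_supporting_projects"])))

    tipset = set(tree.taxa)
    by_species: dict[str, list[DisruptionEvent]] = {}
    for e in events:
        if e.species not in tipset:
            raise ValueError(f"fixture species {e.species} not a tree tip")
        by_species.setdefault(e.species, []).append(e)
    statuses = []
    for sp in tree.taxa:
        evs = by_species.get(sp, [])
        statuses.append(call_status(
            sp, "GBA3", evs,
            coverage_complete=sp not in INCOMPLETE_COVERAGE))

    with resources.as_file(_data("human_variants.tsv")) as p:
        vrows = read_tsv(p)
    variants = []
    pops = ("African", "American", "EastAsian", "European", "SouthAsian")
    for r in vrows:
        freqs = {p_: float(r[p_]) for p_ in pops if r[p_]}
        variants.append(VariantRecord(
            variant_id=r["variant_id"], gene_id=r["gene_id"],
            consequence=r["consequence"], cdna_pos=int(r["cdna_pos"]),
            protein_change=r["protein_change"], pop_freqs=freqs,
            polyphen=float(r["polyphen"]) if r["polyphen"] else None,
            sift=float(r["sift"]) if r["sift"] else None))

    with resources.as_file(_data("genotype_panels.tsv")) as p:
        grows = read_tsv(p)
    panels = {r["population"]: (int(r["n_AA"]), int(r["n_Aa"]), int(r["n_aa"]))
              for r in grows}

    with resources.as_file(_data("model_ladder.yaml")) as p:
        spec = yaml.safe_load(p.read_text())
    models = {str(k): dict(v or {}) for k, v in spec["models"].items()}
    known_labels = set(tree.clade_labels) | set(tree.branch_labels)
    for mid, mapping in models.items():
        bad = set(mapping) - known_labels
        if bad:
            raise ValueError(f"model {mid} references unknown labels {bad}")
    ladder = list(spec["ladder"])
    if len(models) != 14:
        raise ValueError("expected the 14 models A..N")
    return FixtureBundle(
        events=events, statuses=statuses, tree=tree, variants=variants,
        genotype_panels=panels, models=models, ladder=ladder,
        omegas_best=dict(spec.get("omegas_best", {})),
        best_model=str(spec.get("best_model", "M")))
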