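import numpy as np
import pytest

from geneloss.annotate import validate_events
from geneloss.codonmodel import (
    CODONS,
    CodonModelParams,
    N_CODONS,
    rate_matrix,
    spec_from_labels,
)
from geneloss.popgen import hwe_test, tajima_constants
from geneloss.simulate import (
    PlannedEdit,
    sim_coalescent_haplotypes,
    sim_codon_alignment,
    sim_gene_locus,
    sim_genotypes,
    sim_read_evidence,
    sim_reference_gene,
    substream,
)


class TestDeterminism:
    def test_same_seed_reproduces_every_generator(self, six_taxon_tree,
                                                  uniform_pi, gba3_model):
        spec = spec_from_labels(six_taxon_tree, "A", {})
        params = CodonModelParams(
            kappa=2.0, pi=uniform_pi, omega_by_class={0: 0.4},
            branch_lengths={v: six_taxon_tree.lengths[v]
                            for v in range(six_taxon_tree.n_nodes - 1)})
        a1, _ = sim_codon_alignment(six_taxon_tree, spec, params, 50, seed=7)
        a2, _ = sim_codon_alignment(six_taxon_tree, spec, params, 50, seed=7)
        assert np.array_equal(a1.codons, a2.codons)
        s1, _ = sim_gene_locus(gba3_model, [], seed=7)
        s2, _ = sim_gene_locus(gba3_model, [], seed=7)
        assert s1 == s2
        h1, p1, t1 = sim_coalescent_haplotypes(6, 4.0, 1000, seed=7)
        h2, p2, t2 = sim_coalescent_haplotypes(6, 4.0, 1000, seed=7)
        assert np.array_equal(h1, h2) and np.array_equal(p1, p2) and t1 == t2
        assert (sim_genotypes({"p": 0.2}, 100, seed=7)
                == sim_genotypes({"p": 0.2}, 100, seed=7))

    def test_substreams_are_independent_of_label_order(self):
        a = substream(5, "x").integers(0, 1000, 5)
        _ = substream(5, "y").integers(0, 1000, 5)
        b = substream(5, "x").integers(0, 1000, 5)
        assert np.array_equal(a, b)


class TestCodonAlignmentGenerator:
    def test_zero_branch_lengths_copy_root(self, uniform_pi):
        from geneloss.trees import SpeciesTree

        tree = SpeciesTree.from_newick_string("((a:0,b:0):0,c:0);")
        spec = spec_from_labels(tree, "A", {})
        params = CodonModelParams(
            kappa=2.0, pi=uniform_pi, omega_by_class={0: 0.4},
            branch_lengths={v: 0.0 for v in range(tree.n_nodes - 1)})
        aln, _ = sim_codon_alignment(tree, spec, params, 80, seed=3)
        assert np.array_equal(aln.codons[0], aln.codons[1])
        assert np.array_equal(aln.codons[0], aln.codons[2])

    def test_long_simulation_converges_to_stationary_frequencies(self,
                                                                 uniform_pi):
        from geneloss.trees import SpeciesTree

        rng = np.random.default_rng(4)
        pi = rng.dirichlet(np.full(N_CODONS, 10.0))
        pi /= pi.sum()
        tree = SpeciesTree.from_newick_string("(a:0.5,b:0.5);")
        spec = spec_from_labels(tree, "A", {})
        params = CodonModelParams(
            kappa=2.0, pi=pi, omega_by_class={0: 0.5},
            branch_lengths={0: 0.5, 1: 0.5})
        aln, _ = sim_codon_alignment(tree, spec, params, 50_000, seed=5)
        counts = np.bincount(aln.codons.ravel(), minlength=N_CODONS)
        emp = counts / counts.sum()
        assert 0.5 * np.abs(emp - pi).sum() < 0.02  # total variation

    def test_event_log_nonsynonymous_fraction_matches_rate_matrix(self,
                                                                  uniform_pi):
        """Under omega=1, kappa=1 the share of nonsynonymous substitutions
        equals the neutral expectation computed from Q."""
        from geneloss.codonmodel import _IS_NONSYN, _ROWS, _COLS
        from geneloss.trees import SpeciesTree

        tree = SpeciesTree.from_newick_string("(a:1.5,b:1.5);")
        spec = spec_from_labels(tree, "A", {})
        params = CodonModelParams(
            kappa=1.0, pi=uniform_pi, omega_by_class={0: 1.0},
            branch_lengths={0: 1.5, 1: 1.5})
        aln, truth = sim_codon_alignment(tree, spec, params, 800, seed=6,
                                         log_events=True)
        log = truth.params["event_log"]
        assert log
        q = rate_matrix(uniform_pi, 1.0, 1.0)
        flux = uniform_pi[_ROWS] * q[_ROWS, _COLS]
        expected = float(flux[_IS_NONSYN].sum() / flux.sum())
        codon_index = {c: i for i, c in enumerate(CODONS)}
        from geneloss.codonmodel import AMINO

        n_nonsyn = sum(AMINO[a] != AMINO[b] for _, _, a, b in log)
        frac = n_nonsyn / len(log)
        se = np.sqrt(expected * (1 - expected) / len(log))
        assert abs(frac - expected) < 4 * se


class TestGeneLocusGenerator:
    def test_edit_outside_cds_errors(self, gba3_model):
        with pytest.raises(ValueError, match="outside CDS"):
            sim_gene_locus(gba3_model,
                           [PlannedEdit(kind="deletion", cds_nt_pos=99999,
                                        length=2)])

    def test_thirteen_nt_deletion_recovered_in_truth(self, gba3_model):
        plan = [PlannedEdit(kind="deletion", cds_nt_pos=700, length=13)]
        _, truth = sim_gene_locus(gba3_model, plan, seed=1)
        dels = [e for e in truth.events if e.kind == "deletion"]
        assert len(dels) == 1
        assert dels[0].indel_len == 13
        assert dels[0].frameshift
        assert dels[0].exon_index == 3


class TestReadEvidenceGenerator:
    def _event(self):
        from geneloss.annotate import DisruptionEvent

        return DisruptionEvent(species="sp", gene_id="g",
                               kind="premature_stop", exon_index=3,
                               cds_nt_pos=598, codon_index=200, allele="TAA")

    def test_fixed_allele_validates_fixed(self):
        event = self._event()
        ev = sim_read_evidence([event], depth=20, disrupted_allele_freq=1.0,
                               n_projects=2, seed=1)
        out = validate_events([event], ev)
        assert out[0].validation == "validated_fixed"

    def test_intermediate_frequency_validates_polymorphic(self):
        event = self._event()
        ev = sim_read_evidence([event], depth=20, disrupted_allele_freq=0.5,
                               n_projects=2, seed=2)
        out = validate_events([event], ev)
        assert out[0].validation == "validated_polymorphic"

    def test_no_projects_leaves_unvalidated(self):
        event = self._event()
        out = validate_events([event], sim_read_evidence(
            [event], 20, 1.0, n_projects=0, seed=3))
        assert out[0].validation == "unvalidated"

    def test_invalid_frequency_errors(self):
        with pytest.raises(ValueError):
            sim_read_evidence([self._event()], 20, 1.5, 2)


class TestGenotypeGenerator:
    def test_monomorphic_when_q_zero(self):
        panels = sim_genotypes({"p": 0.0}, 200, seed=1)
        assert panels["p"] == (200, 0, 0)

    def test_inbreeding_produces_detectable_het_deficit(self):
        """f=0.5 at q=0.2, n=500: the HWE chi-square test rejects with high
        power."""
        rejected = 0
        for rep in range(60):
            panels = sim_genotypes({"p": 0.2}, 500, inbreeding_f=0.5,
                                   seed=rep)
            rejected += hwe_test(panels["p"]) < 0.05
        assert rejected / 60 > 0.8

    def test_invalid_parameters_error(self):
        with pytest.raises(ValueError):
            sim_genotypes({"p": 1.5}, 10)
        with pytest.raises(ValueError):
            sim_genotypes({"p": 0.5}, 10, inbreeding_f=-0.1)


class TestCoalescentGenerator:
    def test_pair_tmrca_mean_is_one(self):
        tm = [sim_coalescent_haplotypes(2, 1.0, 100, seed=s)[2]
              for s in range(1500)]
        assert np.mean(tm) == pytest.approx(1.0, abs=0.08)

    def test_watterson_and_pairwise_expectations(self):
        """E[S] = theta * a1 and E[pi] = theta per locus under neutrality."""
        theta, n, reps = 5.0, 10, 800
        a1 = tajima_constants(n)["a1"]
        s_vals, pi_vals = [], []
        for seed in range(reps):
            hap, pos, _ = sim_coalescent_haplotypes(n, theta, 1000, seed=seed)
            k = hap.sum(axis=0)
            seg = (k > 0) & (k < n)
            s_vals.append(int(seg.sum()))
            pi_vals.append(float((k * (n - k)).sum() / (n * (n - 1) / 2)))
        assert np.mean(s_vals) == pytest.approx(theta * a1, rel=0.05)
        assert np.mean(pi_vals) == pytest.approx(theta, rel=0.05)

    def test_agrees_with_independent_coalescent_simulator(self):
        """Cross-check mean segregating sites against msprime."""
        msprime = pytest.importorskip("msprime")
        theta, n, reps = 4.0, 8, 300
        ours = []
        for seed in range(reps):
            hap, _, _ = sim_coalescent_haplotypes(n, theta, 1000, seed=seed)
            k = hap.sum(axis=0)
            ours.append(int(((k > 0) & (k < n)).sum()))
        ts_s = []
        for seed in range(1, reps + 1):
            ts = msprime.sim_ancestry(samples=n, ploidy=1,
                                      sequence_length=1000,
                                      random_seed=seed)
            mts = msprime.sim_mutations(ts, rate=theta / 2 / 1000,
                                        random_seed=seed,
                                        discrete_genome=False)
            ts_s.append(mts.num_sites)
        assert np.mean(ours) == pytest.approx(np.mean(ts_s), rel=0.08)

    def test_tajimas_d_mean_agrees_with_independent_simulator(self):
        """The generator's mean Tajima's D equals msprime's within
        Monte-Carlo error at identical parameters (the statistic's exact
        finite-sample mean is slightly negative; both simulators show it)."""
        msprime = pytest.importorskip("msprime")
        from geneloss.popgen import diversity_scan

        n, theta, L, reps = 20, 10.0, 10_000, 300
        ours = []
        for seed in range(reps):
            hap, pos, _ = sim_coalescent_haplotypes(n, theta, L, seed=seed)
            if hap.shape[1] == 0:
                continue
            w = diversity_scan(hap, pos, window_bp=L, region_bp=L)[0]
            if w.tajima_d is not None:
                ours.append(w.tajima_d)
        theirs = []
        for seed in range(1, reps + 1):
            ts = msprime.sim_ancestry(samples=n, ploidy=1,
                                      sequence_length=L, random_seed=seed)
            mts = msprime.sim_mutations(ts, rate=theta / 2 / L,
                                        random_seed=seed,
                                        discrete_genome=False)
            if mts.num_sites == 0:
                continue
            hap = (mts.genotype_matrix().T > 0).astype(int)
            pos = [s.position for s in mts.sites()]
            w = diversity_scan(hap, pos, window_bp=L, region_bp=L)[0]
            if w.tajima_d is not None:
                theirs.append(w.tajima_d)
        diff = abs(float(np.mean(ours)) - float(np.mean(theirs)))
        se = np.sqrt(np.var(ours) / len(ours) + np.var(theirs) / len(theirs))
        assert diff < 3.5 * se + 1e-9

    def test_n_below_two_errors(self):
        with pytest.raises(ValueError):
            sim_coalescent_haplotypes(1, 1.0, 100)
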