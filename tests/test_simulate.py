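import numpy as np
import pandas as pd
import pytest

from coldclade.composition import composition_profile
from coldclade.contrasts import rank_sum_test
from coldclade.genome_qc import AAIMatrix, filter_genomes, read_metadata
from coldclade.pangenome import PresenceAbsenceMatrix, categorize_genes, rarefy_pan
from coldclade.phylo import GroupedPhylogeny, is_monophyletic, read_groups
from coldclade.simulate import (
    StudyScenario,
    codon_distribution,
    gen_genome,
    gen_pangenome,
    gen_phenotypes,
    gen_tree,
    simulate_study,
    write_fasta,
    write_gff3,
    write_study,
)


class TestGenGenome:
    def test_same_seed_byte_identical_files(self, tmp_path):
        for name in ("a", "b"):
            g = gen_genome("x", target_arg_lys=1.3, target_gc=60.0, n_genes=10,
                           gene_length_codons=40, seed=123)
            write_fasta(g, tmp_path / f"{name}.fasta", seed=123)
            write_gff3(g, tmp_path / f"{name}.gff3", seed=123)
        assert (tmp_path / "a.fasta").read_bytes() == (tmp_path / "b.fasta").read_bytes()
        assert (tmp_path / "a.gff3").read_bytes() == (tmp_path / "b.gff3").read_bytes()

    def test_infeasible_gc_under_lysine_constraint(self):
        with pytest.raises(ValueError, match="feasible range"):
            codon_distribution(1.0, 1.0)
        with pytest.raises(ValueError, match="target_gc"):
            gen_genome("x", target_arg_lys=1.0, target_gc=100.0)

    def test_composition_targets_hit(self):
        # moderate size here; the 1e5-codon check lives in the acceptance suite
        g = gen_genome("x", target_arg_lys=2.0, target_gc=65.0, n_genes=100,
                       gene_length_codons=150, seed=11)
        prof = composition_profile(g)
        n_rk = prof.arg_count + prof.lys_count
        p0 = 2.0 / 3.0
        se = np.sqrt(p0 * (1 - p0) / n_rk)
        assert abs(prof.arg_count / n_rk - p0) <= 3 * se
        assert abs(prof.gc_genome - 65.0) < 1.0
        assert not np.isnan(prof.gc_rrna) and not np.isnan(prof.gc_intergenic)


class TestGenPangenome:
    def test_core_only_is_all_strict_core(self):
        m = gen_pangenome(n_genomes=10, core_size=50, n_accessory=0, seed=1)
        cats = categorize_genes(m)
        assert cats.counts["strict_core"] == 50 and cats.total == 50
        pan = rarefy_pan(m, 20, seed=2)
        assert (pan.curve.median_values == 50).all()

    def test_open_pangenome_signature_default_law(self):
        from coldclade.pangenome import fit_heaps

        m = gen_pangenome(seed=3)
        fit = fit_heaps(rarefy_pan(m, 100, seed=4).step_change_medians[1:])
        assert fit.open and 0 < fit.alpha < 1


class TestGenPhenotypes:
    def assignment(self):
        return {f"g{i}": ("polar2" if i < 5 else "nonpolar") for i in range(20)}

    def means(self):
        return {"polar2": (0.0, 20.0, 27.0), "nonpolar": (10.0, 30.0, 37.0)}

    def test_zero_sd_returns_group_means(self):
        df = gen_phenotypes(self.assignment(), self.means(), sd=0.0, seed=1)
        assert (df.loc["g0"] == [0.0, 20.0, 27.0]).all()
        assert (df.loc["g19"] == [10.0, 30.0, 37.0]).all()

    def test_row_ordering_enforced(self):
        df = gen_phenotypes(self.assignment(), self.means(), sd=15.0, seed=2)
        assert (df["t_min"] <= df["t_opt"]).all() and (df["t_opt"] <= df["t_max"]).all()

    def test_same_seed_identical(self):
        a = gen_phenotypes(self.assignment(), self.means(), sd=2.0, seed=3)
        b = gen_phenotypes(self.assignment(), self.means(), sd=2.0, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_unordered_means_rejected(self):
        with pytest.raises(ValueError, match="t_min <= t_opt"):
            gen_phenotypes(self.assignment(), {"polar2": (30, 20, 27), "nonpolar": (1, 2, 3)}, seed=1)

    def test_cold_shift_power(self):
        # -10 degC shift, sd 2, 10 vs 40 genomes: detected in >= 95% of 500 seeds
        assignment = {f"g{i}": ("polar" if i < 10 else "nonpolar") for i in range(50)}
        means = {"polar": (0.0, 20.0, 27.0), "nonpolar": (10.0, 30.0, 37.0)}
        hits = 0
        for seed in range(500):
            df = gen_phenotypes(assignment, means, sd=2.0, seed=seed)
            polar = df.loc[[g for g, lab in assignment.items() if lab == "polar"], "t_opt"]
            ref = df.loc[[g for g, lab in assignment.items() if lab == "nonpolar"], "t_opt"]
            r = rank_sum_test(polar, ref, alternative="less")
            hits += r.p < 0.05
        assert hits / 500 >= 0.95


class TestGenTree:
    def leaves(self):
        return {
            "polar2": [f"p{i}" for i in range(4)],
            "polar3": [f"q{i}" for i in range(3)],
            "nonpolar": [f"n{i}" for i in range(12)],
        }

    def test_requested_groups_are_monophyletic(self):
        phy = gen_tree(self.leaves(), ["polar2", "polar3"], ["o1", "o2"], seed=5)
        assert is_monophyletic(phy.tree, self.leaves()["polar2"])
        assert is_monophyletic(phy.tree, self.leaves()["polar3"])

    def test_neighbour_sets_form_parent_clade(self):
        nbs = {"polar2": [f"n{i}" for i in range(6)]}
        phy = gen_tree(self.leaves(), ["polar2"], ["o1", "o2"], seed=6, neighbour_sets=nbs)
        found = phy.neighbours_of("polar2")
        assert found.neighbour_ids == sorted(nbs["polar2"])

    def test_unrequested_group_not_always_monophyletic(self):
        mono = [
            is_monophyletic(
                gen_tree(self.leaves(), ["polar2"], ["o1", "o2"], seed=s).tree,
                self.leaves()["polar3"],
            )
            for s in range(30)
        ]
        assert not all(mono)

    def test_same_seed_identical_newick(self):
        a = gen_tree(self.leaves(), ["polar2"], ["o1", "o2"], seed=7)
        b = gen_tree(self.leaves(), ["polar2"], ["o1", "o2"], seed=7)
        assert a.tree.as_string(schema="newick") == b.tree.as_string(schema="newick")


class TestStudyRoundtrip:
    def test_files_pass_every_reader(self, tmp_path):
        scenario = StudyScenario(
            group_sizes={"polar1": 1, "polar2": 4, "polar3": 3, "nonpolar": 20},
            neighbour_counts={"polar2": 6, "polar3": 4},
            core_size=100,
            n_accessory=500,
            n_soft_accessory=50,
            seed=13,
        )
        study = simulate_study(scenario)
        write_study(study, tmp_path)
        metadata = read_metadata(tmp_path / "metadata.tsv")
        kept, removed = filter_genomes(metadata)
        assert len(kept) == 28 and removed == []
        aai = AAIMatrix.from_tsv(tmp_path / "aai.tsv")
        assert aai.genome_ids == [m.genome_id for m in metadata]
        phy = GroupedPhylogeny.load(tmp_path / "tree.nwk", tmp_path / "groups.tsv")
        assert phy.members("polar2") == study.phylogeny.members("polar2")
        matrix = PresenceAbsenceMatrix.from_tsv(tmp_path / "matrix.tsv")
        assert np.array_equal(matrix.occupancy, study.matrix.occupancy)
        metrics = pd.read_csv(tmp_path / "metrics.tsv", sep="\t", index_col=0, comment="#")
        assert set(metrics.columns) >= {"t_min", "t_opt", "t_max", "arg_lys_ratio", "gc_genome"}
        groups = read_groups(tmp_path / "groups.tsv")
        assert groups["polar2_001"] == "polar2"
        scenario_json = (tmp_path / "scenario.json").read_text()
        assert '"seed": 13' in scenario_json

    def test_same_seed_reproducible(self):
        a = simulate_study(StudyScenario.paperlike(seed=99))
        b = simulate_study(StudyScenario.paperlike(seed=99))
        pd.testing.assert_frame_equal(a.metrics, b.metrics)
        assert np.array_equal(a.matrix.occupancy, b.matrix.occupancy)
        assert a.phylogeny.tree.as_string(schema="newick") == b.phylogeny.tree.as_string(
            schema="newick"
        )
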