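"""Generators: reproducibility, planted structure, and stated laws."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import endotrio as et
from endotrio import synthetic_data as syn
from endotrio.cohort import CHILD, FATHER, HET, HOM_REF, MOTHER
from endotrio.synthetic_data import InvalidSpecError


class TestGeneUniverse:
    def test_postconditions(self):
        u = et.generate_gene_universe(10, seed=0)
        assert len(u) == 10
        assert u["gene"].is_unique
        assert (u["cds_length"] >= 150).all()

    def test_deterministic(self):
        a = et.generate_gene_universe(50, seed=9)
        b = et.generate_gene_universe(50, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_length_law_median(self):
        u = et.generate_gene_universe(5000, length_law=(1500, 0.8), seed=3)
        assert 1200 <= u["cds_length"].median() <= 1800

    def test_expression_fraction(self):
        u = et.generate_gene_universe(5000, seed=3)
        frac = (u["rpkm"] > 1).mean()
        assert 0.80 <= frac <= 0.90

    def test_too_few_genes(self):
        with pytest.raises(InvalidSpecError):
            et.generate_gene_universe(9)


class TestNetwork:
    def test_basic_shape(self):
        g = et.generate_network(100, seed=1)
        assert g.number_of_nodes() == 100
        assert nx.number_of_selfloops(g) == 0
        assert nx.number_connected_components(g) >= 1

    def test_planted_module_density(self):
        module = [f"G{i:05d}" for i in range(10)]
        g = et.generate_network(200, planted_module=module, seed=2)
        inside = g.subgraph(module).number_of_edges()
        density_in = inside / (10 * 9 / 2)
        density_bg = g.number_of_edges() / (200 * 199 / 2)
        assert density_in >= 5 * density_bg

    def test_deterministic(self):
        e1 = set(et.generate_network(80, seed=5).edges)
        e2 = set(et.generate_network(80, seed=5).edges)
        assert e1 == e2

    def test_module_too_large(self):
        with pytest.raises(InvalidSpecError):
            et.generate_network(5, planted_module=[f"G{i:05d}" for i in range(9)])


class TestTrioCohort:
    def test_null_cohort_has_no_mendelian_violations(self, universe):
        spec = et.CohortSpec(
            n_trios=30, n_genes=300, dnv_rate=0, ch_rate=0, hom_rate=0, seed=7
        )
        cohort, truth = et.generate_trio_cohort(spec, universe)
        assert truth.dnv_list == () and truth.ch_list == ()
        assert et.detect_dnv(cohort) == []

    def test_planted_ch_has_opposite_origins(self, universe):
        spec = et.CohortSpec(
            n_trios=50, n_genes=300, dnv_rate=0, ch_rate=1.0, hom_rate=0,
            background_sites_per_gene=0, seed=11,
        )
        cohort, truth = et.generate_trio_cohort(spec, universe)
        assert truth.ch_list
        origin = et.phase_by_transmission(cohort)
        from endotrio.cohort import variant_ids
        from endotrio.rav import MATERNAL, PATERNAL

        vids = list(variant_ids(cohort.variants))
        trio_col = {t: i for i, t in enumerate(cohort.trios["trio_id"])}
        for trio, gene, (v1, v2) in truth.ch_list:
            ti = trio_col[trio]
            codes = {origin[vids.index(v1), ti], origin[vids.index(v2), ti]}
            assert codes == {PATERNAL, MATERNAL}

    def test_transmission_distortion_rate(self, universe):
        genes = tuple(universe["gene"][:4])
        spec = et.CohortSpec(
            n_trios=300, n_genes=300, dnv_rate=0, ch_rate=0, hom_rate=0,
            transmission_prob=0.85, background_sites_per_gene=0,
            distorted_genes=genes, distorted_sites_per_gene=16, seed=13,
        )
        cohort, truth = et.generate_trio_cohort(spec, universe)
        assert set(truth.distorted_genes) == set(genes)
        counts = et.count_transmissions(cohort, genes, dscore_min=4)
        assert counts.total >= 200
        frac = counts.transmitted / counts.total
        assert 0.79 <= frac <= 0.91  # binomial 99% interval around 0.85

    def test_deterministic(self, universe):
        spec = et.CohortSpec(n_trios=10, n_genes=300, seed=21)
        a, ta = et.generate_trio_cohort(spec, universe)
        b, tb = et.generate_trio_cohort(spec, universe)
        pd.testing.assert_frame_equal(a.variants, b.variants)
        assert (a.gt == b.gt).all() and (a.dp == b.dp).all()
        assert ta == tb

    def test_spec_validation(self):
        with pytest.raises(InvalidSpecError):
            et.CohortSpec(transmission_prob=0.0)
        with pytest.raises(InvalidSpecError):
            et.CohortSpec(dnv_rate=-1)
        with pytest.raises(InvalidSpecError):
            et.CohortSpec(maf_range=(0.0, 0.01))
        with pytest.raises(InvalidSpecError):
            et.CohortSpec(high5ht_fraction=1.2)

    def test_vcf_roundtrip(self, small_cohort, tmp_path):
        cohort, _ = small_cohort
        paths = syn.write_cohort(cohort, tmp_path)
        back = et.read_trio_cohort(paths["vcf"], paths["ped"], paths["annotation"])
        assert back.n_sites == cohort.n_sites
        assert (back.gt == cohort.gt).all()
        assert (back.dp == cohort.dp).all()
        cols = ["chrom", "pos", "ref", "alt", "gene", "func_class", "dscore"]
        pd.testing.assert_frame_equal(back.variants[cols], cohort.variants[cols])

    def test_low_depth_fraction_exercises_masking(self, universe):
        spec = et.CohortSpec(n_trios=20, n_genes=300, low_depth_fraction=0.2, seed=3)
        cohort, _ = et.generate_trio_cohort(spec, universe)
        assert (cohort.dp < 6).mean() > 0.1
        masked = et.mask_low_depth(cohort)
        assert (masked.gt[cohort.dp < 6] == -1).all()


class TestSerotonin:
    def _pheno(self, n, norms, frac, seed=0):
        fam = [f"fam{i:04d}" for i in range(n)]
        trios = pd.DataFrame(
            {"trio_id": fam, "father_id": [f + ".fa" for f in fam],
             "mother_id": [f + ".mo" for f in fam],
             "child_id": [f + ".p1" for f in fam], "child_sex": "male"}
        )
        subjects = syn.make_subjects(trios, norms, seed=seed)
        return syn.generate_serotonin(subjects, norms, frac, seed=seed)

    def test_null_fraction_matches_reference_tail(self, norms):
        pheno = et.normalize_serotonin(self._pheno(200, norms, 0.0), norms)
        probands = pheno[pheno["role"] == "proband"]
        assert (probands["z"] > 1.75).mean() < 0.05

    def test_mixture_fraction(self, norms):
        pheno = et.normalize_serotonin(self._pheno(500, norms, 0.3, seed=5), norms)
        probands = pheno[pheno["role"] == "proband"]
        assert 0.20 <= (probands["z"] > 1.75).mean() <= 0.45

    def test_deterministic(self, norms):
        a = self._pheno(30, norms, 0.3, seed=9)
        b = self._pheno(30, norms, 0.3, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_unknown_ancestry_raises(self, norms):
        subjects = pd.DataFrame(
            [{"subject_id": "s1", "trio_id": "f1", "role": "proband",
              "ancestries": "martian", "age_months": 100, "tanner": np.nan}]
        )
        from endotrio.serotonin import MissingReferenceError

        with pytest.raises(MissingReferenceError):
            syn.generate_serotonin(subjects, norms, 0.0)
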