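"""Phasing, compound-het/homozygote calls, burden, per-gene Fisher."""

import numpy as np
import pandas as pd
import pytest

import endotrio as et
from endotrio import rav as rav_mod
from endotrio.rav import AMBIGUOUS, BOTH, INCONSISTENT, MATERNAL, PATERNAL

from conftest import build_cohort
from oracles import brute_force_ravs, fisher_two_sided_exact

HOM_REF, HET, HOM_ALT, MISS = 0, 1, 2, -1


class TestPhasing:
    @pytest.mark.parametrize(
        "fa,mo,ch,expected",
        [
            (HET, HOM_REF, HET, PATERNAL),
            (HOM_REF, HET, HET, MATERNAL),
            (HET, HET, HET, AMBIGUOUS),
            (HET, HET, HOM_ALT, BOTH),
            (HOM_REF, HOM_REF, HOM_ALT, INCONSISTENT),
            (HOM_REF, HET, HOM_ALT, INCONSISTENT),
            (MISS, HOM_REF, HET, AMBIGUOUS),
            (HOM_ALT, HOM_REF, HET, PATERNAL),
        ],
    )
    def test_single_site(self, fa, mo, ch, expected):
        c = build_cohort([{}], [[[fa, mo, ch]]])
        assert et.phase_by_transmission(c)[0, 0] == expected


class TestDetectRavs:
    def _gene_cohort(self, sites, gene="GENE1"):
        rows = [{"gene": gene, **r} for r, _ in sites]
        gt = [[g] for _, g in sites]
        return build_cohort(rows, gt)

    def test_trans_pair_is_ch(self):
        c = self._gene_cohort(
            [
                ({"func_class": "LoF", "dscore": 9}, [HET, HOM_REF, HET]),
                ({"func_class": "missense", "dscore": 3}, [HOM_REF, HET, HET]),
            ]
        )
        calls = et.detect_ravs(c)
        assert len(calls) == 1 and calls[0].kind == "CH"
        assert set(calls[0].origins) == {"paternal", "maternal"}

    def test_cis_pair_is_not_ch(self):
        c = self._gene_cohort(
            [({}, [HET, HOM_REF, HET]), ({}, [HET, HOM_REF, HET])]
        )
        assert et.detect_ravs(c) == []

    def test_one_ch_per_gene(self):
        c = self._gene_cohort(
            [
                ({}, [HET, HOM_REF, HET]),
                ({}, [HET, HOM_REF, HET]),
                ({}, [HOM_REF, HET, HET]),
            ]
        )
        calls = et.detect_ravs(c)
        assert len(calls) == 1 and calls[0].kind == "CH"

    def test_ambiguous_never_supports_ch(self):
        c = self._gene_cohort(
            [({}, [HET, HET, HET]), ({}, [HOM_REF, HET, HET])]
        )
        assert et.detect_ravs(c) == []

    def test_homozygote(self):
        c = self._gene_cohort([({}, [HET, HET, HOM_ALT])])
        calls = et.detect_ravs(c)
        assert len(calls) == 1 and calls[0].kind == "homozygote"

    def test_x_excluded(self):
        c = build_cohort(
            [{"chrom": "X", "pos": 5_000_000, "gene": "GX"},
             {"chrom": "X", "pos": 5_000_100, "gene": "GX"}],
            [[[HET, HOM_REF, HET]], [[HOM_REF, HET, HET]]],
        )
        assert et.detect_ravs(c) == []

    def test_maf_and_class_filters(self):
        c = self._gene_cohort(
            [
                ({"maf": 0.02}, [HET, HOM_REF, HET]),               # too common
                ({"func_class": "missense", "dscore": 1}, [HOM_REF, HET, HET]),  # below Mis-D2
            ]
        )
        assert et.detect_ravs(c) == []

    def test_output_satisfies_filters(self, small_cohort):
        cohort, _ = small_cohort
        vinfo = cohort.variants.set_index(
            pd.Index(
                cohort.variants["chrom"].astype(str) + ":" + cohort.variants["pos"].astype(str)
                + ":" + cohort.variants["ref"] + ":" + cohort.variants["alt"]
            )
        )
        for call in et.detect_ravs(cohort):
            for vid in call.variant_ids:
                v = vinfo.loc[vid]
                assert v["maf"] < 0.01
                assert str(v["chrom"]) in {str(i) for i in range(1, 23)}
                assert v["func_class"] == "LoF" or (
                    v["func_class"] == "missense" and v["dscore"] >= 2
                )

    def test_matches_brute_force_oracle(self, universe):
        got, want = set(), set()
        for seed in range(8):
            spec = et.CohortSpec(
                n_trios=40, n_genes=300, dnv_rate=0.5, ch_rate=1.5, hom_rate=0.5,
                background_sites_per_gene=3.0, seed=400 + seed,
            )
            cohort, _ = et.generate_trio_cohort(spec, universe)
            got |= {(c.trio_id, c.gene, c.kind, seed) for c in et.detect_ravs(cohort)}
            want |= {(t, g, k, seed) for t, g, k in brute_force_ravs(cohort)}
        assert got == want and len(got) > 50


class TestBurden:
    def test_pseudo_count_ratio(self):
        # 20 functional + 40 synonymous qualifying genotypes -> 21/41
        rows, gts = [], []
        for i in range(20):
            rows.append({"pos": 1000 + i, "func_class": "missense", "dscore": 5})
            gts.append([[HOM_REF, HOM_REF, HET]])
        for i in range(40):
            rows.append({"pos": 3000 + i, "func_class": "synonymous", "dscore": 0,
                         "consequence": "synonymous SNV"})
            gts.append([[HOM_REF, HOM_REF, HET]])
        c = build_cohort(rows, gts)
        table, _, _ = et.burden_normalized(c)
        proband = table[table["role"] == "proband"]["ratio"].iloc[0]
        assert proband == pytest.approx(21 / 41)

    def test_degenerate_all_zero(self):
        c = build_cohort([{}], [[[HOM_REF, HOM_REF, HOM_REF]] * 3], )
        table, _, p = et.burden_normalized(c)
        assert (table["ratio"] == 1.0).all()
        assert p == 1.0

    def test_null_comparison_p_not_extreme(self, universe):
        # probands and parents drawn from the same background law
        ps = []
        for seed in range(10):
            spec = et.CohortSpec(
                n_trios=60, n_genes=300, dnv_rate=0, ch_rate=0, hom_rate=0,
                background_sites_per_gene=4.0, seed=800 + seed,
            )
            cohort, _ = et.generate_trio_cohort(spec, universe)
            _, _, p = et.burden_normalized(cohort)
            ps.append(p)
        assert min(ps) > 0.001 and max(ps) > 0.1


class TestFisher:
    def test_symmetric_diagonal_table(self):
        # carriers 2/2 in High vs 0/2 in Normal: two-sided p = 1/3
        odds, p = et.per_gene_fisher(2, 2, 0, 2)
        assert p == pytest.approx(1 / 3)
        assert odds > 1

    def test_balanced_table(self):
        _, p = et.per_gene_fisher(1, 2, 1, 2)
        assert p == pytest.approx(1.0)

    def test_association_sign(self):
        odds, _ = et.per_gene_fisher(3, 25, 0, 38)
        assert odds > 1

    def test_matches_enumeration_oracle(self):
        for n_high in (3, 7, 12):
            for n_normal in (4, 9):
                for k in range(n_high + 1):
                    for m in range(n_normal + 1):
                        _, p = et.per_gene_fisher(k, n_high, m, n_normal)
                        want = fisher_two_sided_exact(k, n_high - k, m, n_normal - m)
                        assert p == pytest.approx(want, rel=1e-9), (k, n_high, m, n_normal)


class TestSplitByOr:
    def test_partition_with_boundary(self):
        frame = pd.DataFrame(
            {"gene": ["A", "B", "C"], "odds_ratio": [5.0, 0.2, 1.0]}
        )
        cand, ctrl = et.split_by_or(frame)
        assert cand == ["A"] and ctrl == ["B"]  # OR == 1 joins neither
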