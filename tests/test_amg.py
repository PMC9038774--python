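"""Core/AMG gene partitioning, positional validation, abundance contrasts."""

import numpy as np
import pandas as pd
import pytest

from viromine import AnnotationHit, GeneRecord, Parameters
from viromine.amg import (amg_abundance, classify_genes, cooccurrence_network,
                          default_amg_families, validate_all, validate_context)


def gene(i, contig="c1"):
    return GeneRecord(f"{contig}_g{i}", contig, i, 1 + i * 100, 90 + i * 100,
                      "+", f"{contig}_p{i}")


class TestClassify:
    def test_xr_gene_is_core(self):
        g = [gene(0)]
        hits = [AnnotationHit("c1_p0", "VOG", "VOG1", "Xr")]
        assert classify_genes(g, hits)[0].klass == "core"

    def test_curated_pfam_is_amg_with_category(self):
        g = [gene(0)]
        hits = [AnnotationHit("c1_p0", "PFAM", "HAD_2", "HAD_2")]
        gc = classify_genes(g, hits)[0]
        assert gc.klass == "AMG" and gc.amg_category == "pesticide"

    def test_core_precedence_over_amg(self):
        g = [gene(0)]
        hits = [AnnotationHit("c1_p0", "VOG", "VOG1", "Xs"),
                AnnotationHit("c1_p0", "PFAM", "ALDH", "ALDH")]
        assert classify_genes(g, hits)[0].klass == "core"

    def test_unannotated_gene_is_other(self):
        assert classify_genes([gene(0)], [])[0].klass == "other"

    def test_partition_matches_counting_oracle(self, rng):
        fams = list(default_amg_families())
        genes, hits, expected = [], [], []
        for i in range(300):
            g = gene(i)
            genes.append(g)
            is_core = rng.random() < 0.3
            is_amg = rng.random() < 0.3
            if is_core:
                hits.append(AnnotationHit(g.protein_id, "VOG", f"V{i}",
                                          rng.choice(["Xr", "Xs"])))
            if is_amg:
                hits.append(AnnotationHit(g.protein_id, "PFAM",
                                          fams[rng.integers(0, len(fams))], "x"))
            expected.append("core" if is_core else "AMG" if is_amg else "other")
        got = [gc.klass for gc in classify_genes(genes, hits)]
        assert got == expected


class TestValidation:
    def _flags(self, layout_m, idx, params, n=None):
        """layout_m: indexes carrying the M flag."""
        n = n or (max(layout_m | {idx}) + 1 if layout_m else idx + 1)
        genes = [gene(i) for i in range(n)]
        input_flags = {f"c1_g{i}": {"M"} for i in layout_m}
        return validate_context(genes[idx], genes, set(), params, input_flags)

    def test_flanked_by_hallmarks_on_both_sides(self, params):
        genes = [gene(i) for i in range(10)]
        hall = {"c1_g2", "c1_g9"}
        v = validate_context(genes[5], genes, hall, params)
        assert v.flanked_both_sides

    def test_first_gene_not_flanked_and_gets_F(self, params):
        genes = [gene(i) for i in range(10)]
        v = validate_context(genes[0], genes, {"c1_g5"}, params)
        assert not v.flanked_both_sides and "F" in v.flags

    def test_three_consecutive_M_all_get_B_two_do_not(self, params):
        for m_set, expect_b in [({3, 4, 5}, True), ({3, 4}, False)]:
            for idx in m_set:
                v = self._flags(m_set, idx, params, n=10)
                assert ("B" in v.flags) is expect_b

    def test_gene_off_contig_is_error(self, params):
        genes = [gene(i) for i in range(3)]
        stranger = gene(0, contig="c2")
        with pytest.raises(ValueError):
            validate_context(stranger, genes, set(), params)

    def test_fb_flags_match_brute_force_on_random_layouts(self, params, rng):
        for _ in range(300):
            n = int(rng.integers(1, 15))
            genes = [gene(i) for i in range(n)]
            m_idx = {int(i) for i in np.nonzero(rng.random(n) < 0.4)[0]}
            input_flags = {f"c1_g{i}": {"M"} for i in m_idx}
            for idx in range(n):
                v = validate_context(genes[idx], genes, set(), params, input_flags)
                # brute-force oracle: scan every window explicitly
                exp_f = idx < params.end_flag_window_genes \
                    or idx >= n - params.end_flag_window_genes
                exp_b = False
                if idx in m_idx:
                    for lo in range(n):
                        for hi in range(lo + params.consecutive_M_for_B - 1, n):
                            if (lo <= idx <= hi
                                    and all(j in m_idx for j in range(lo, hi + 1))):
                                exp_b = True
                assert ("F" in v.flags) == exp_f, (n, idx)
                assert ("B" in v.flags) == exp_b, (n, idx, m_idx)

    def test_planted_amgs_validate_and_stripped_hallmarks_fail(
            self, default_dataset, params):
        from viromine import perturb
        ds, truth = default_dataset
        classes = classify_genes(ds.genes, ds.hits)
        amg_ids = {gc.gene_id for gc in classes if gc.klass == "AMG"}
        assert set(truth.amg_genes) == amg_ids
        vals = validate_all(ds.genes, classes, ds.hits, params)
        assert vals and all(v.flanked_both_sides for v in vals)
        stripped = perturb(ds, "strip_hallmarks")
        vals2 = validate_all(stripped.genes, classes, stripped.hits, params)
        assert vals2 and not any(v.flanked_both_sides for v in vals2)


class TestAbundance:
    def _classes(self, n_amg, n_other):
        cats = ["pesticide", "C", "N", "S", "P"]
        from viromine.amg import GeneClass
        cl = [GeneClass(f"a{i}", "AMG", "HAD_2", cats[i % 5]) for i in range(n_amg)]
        cl += [GeneClass(f"o{i}", "other") for i in range(n_other)]
        return cl

    def test_all_zero_amg_rows(self):
        classes = self._classes(3, 2)
        tpm = pd.DataFrame(0.0, index=["C1", "C2", "S1", "S2"],
                           columns=[c.gene_id for c in classes])
        groups = {"C1": "clean", "C2": "clean", "S1": "heavy", "S2": "heavy"}
        res = amg_abundance(classes, tpm, groups)
        assert (res.per_sample["amg_tpm_sum"] == 0).all()
        assert (res.per_sample["amg_category_diversity"] == 0).all()

    def test_single_sample_group_skips_tests(self):
        classes = self._classes(2, 0)
        tpm = pd.DataFrame(1.0, index=["C1", "S1", "S2"],
                           columns=["a0", "a1"])
        with pytest.warns(UserWarning):
            res = amg_abundance(classes, tpm,
                                {"C1": "clean", "S1": "heavy", "S2": "heavy"})
        assert res.tpm_rank_sum is None

    def test_planted_multiplier_separates_groups(self, rng):
        classes = self._classes(50, 50)
        cols = [c.gene_id for c in classes]
        samples = [f"C{i}" for i in range(3)] + [f"S{i}" for i in range(6)]
        groups = dict(zip(samples, ["clean"] * 3 + ["light"] * 3 + ["heavy"] * 3))
        wins = 0
        for _ in range(30):
            base = rng.lognormal(3, 0.5, (9, 100))
            mult = np.array([1] * 3 + [2] * 3 + [4] * 3)[:, None]
            base[:, :50] *= mult
            tpm = pd.DataFrame(base, index=samples, columns=cols)
            res = amg_abundance(classes, tpm, groups)
            heavy = res.per_sample.loc[["S3", "S4", "S5"], "amg_tpm_sum"].mean()
            clean = res.per_sample.loc[["C0", "C1", "C2"], "amg_tpm_sum"].mean()
            if heavy > clean and res.tpm_rank_sum[1] < 0.05:
                wins += 1
        assert wins >= 29

    def test_null_rank_sum_calibration(self, rng):
        classes = self._classes(50, 50)
        cols = [c.gene_id for c in classes]
        samples = [f"C{i}" for i in range(3)] + [f"S{i}" for i in range(6)]
        groups = dict(zip(samples, ["clean"] * 3 + ["light"] * 3 + ["heavy"] * 3))
        rejections = 0
        for _ in range(60):
            tpm = pd.DataFrame(rng.lognormal(3, 0.5, (9, 100)),
                               index=samples, columns=cols)
            res = amg_abundance(classes, tpm, groups)
            if res.tpm_rank_sum[1] < 0.05:
                rejections += 1
        # exact 3-vs-6 rank-sum has attainable alpha 8/84 ~ 0.095;
        # 12 is mean + 3 sd for 60 replicates
        assert rejections <= 12


class TestCooccurrence:
    def test_perfect_correlation_is_edge(self):
        x = np.arange(9, dtype=float)
        tpm = pd.DataFrame({"a": x, "b": 2 * x + 1, "c": [5] * 9})
        edges = cooccurrence_network(tpm)
        assert list(edges.itertuples(index=False))[0][:2] == ("a", "b")
        assert edges.iloc[0]["r"] == pytest.approx(1.0)

    def test_r_exactly_at_threshold_is_no_edge(self):
        p = Parameters(pearson_p_threshold=1.0)
        rng = np.random.default_rng(3)
        for _ in range(50):
            a = rng.normal(size=12)
            b = rng.normal(size=12)
            tpm = pd.DataFrame({"a": a, "b": b})
            edges = cooccurrence_network(tpm, p)
            r = np.corrcoef(a, b)[0, 1]
            assert (abs(r) > 0.6) == (len(edges) == 1)

    def test_too_few_samples_error(self):
        tpm = pd.DataFrame({"a": [1, 2], "b": [2, 1]})
        with pytest.raises(ValueError):
            cooccurrence_network(tpm)

    def test_edge_set_matches_brute_force_oracle(self, rng):
        from scipy import stats as ss
        tpm = pd.DataFrame(rng.lognormal(1, 1, (8, 20)),
                           columns=[f"f{i}" for i in range(20)])
        edges = cooccurrence_network(tpm)
        got = {tuple(sorted(e)) for e in
               zip(edges["feature_a"], edges["feature_b"])}
        expected = set()
        for i in range(20):
            for j in range(i + 1, 20):
                r, p = ss.pearsonr(tpm.iloc[:, i], tpm.iloc[:, j])
                if abs(r) > 0.6 and p < 0.05:
                    expected.add(tuple(sorted((f"f{i}", f"f{j}"))))
        assert got == expected
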