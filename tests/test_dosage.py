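"""Dosage statistics: frozen toy values, naive-loop oracles, invariances."""

import numpy as np
import pandas as pd
import pytest

from xdosage import (
    ValidationError,
    chromosome_contribution,
    chromosome_log2_fm,
    chromosome_relative_profile,
    fm_of_xa,
    fm_profile,
    paired_ttest,
    per_gene_fm_track,
    stage_fold_changes,
    two_sample_ttest,
    xa_gene_normalized,
    xa_per_embryo,
    xa_stage_ratio,
)

from conftest import make_annotation, make_samples


@pytest.fixture
def fm_toy():
    """Three X genes, two embryos per sex, one stage; ratios worked by hand."""
    ann = make_annotation([("g1", "X", 1000), ("g2", "X", 1000),
                           ("g3", "X", 1000), ("a1", "1", 1000)])
    samples = make_samples([
        ("f1", "4-cell", "WT", "female"), ("f2", "4-cell", "WT", "female"),
        ("m1", "4-cell", "WT", "male"), ("m2", "4-cell", "WT", "male"),
    ])
    fpkm = pd.DataFrame(
        {"f1": [4.0, 9.0, 1.0, 5.0], "f2": [6.0, 11.0, 3.0, 5.0],
         "m1": [2.0, 5.0, 4.0, 5.0], "m2": [2.0, 5.0, 4.0, 5.0]},
        index=["g1", "g2", "g3", "a1"],
    )
    return fpkm, samples, ann


class TestFmProfile:
    def test_hand_computed_mean_of_ratios(self, fm_toy):
        # per-gene ratios: g1 5/2=2.5, g2 10/5=2.0, g3 2/4=0.5
        # mean = 5/3; sd = sqrt(((2.5-5/3)^2+(2-5/3)^2+(.5-5/3)^2)/2)
        fpkm, samples, ann = fm_toy
        profile = fm_profile(fpkm, samples, ann, "WT")
        assert profile.loc["4-cell", "value"] == pytest.approx(5.0 / 3.0)
        sd = np.sqrt(((2.5 - 5 / 3) ** 2 + (2.0 - 5 / 3) ** 2
                      + (0.5 - 5 / 3) ** 2) / 2)
        assert profile.loc["4-cell", "sem"] == pytest.approx(sd / np.sqrt(3))
        assert profile.loc["4-cell", "n_genes"] == 3

    def test_identical_expression_gives_unity(self, fm_toy):
        fpkm, samples, ann = fm_toy
        flat = fpkm.copy()
        flat[:] = 2.0
        profile = fm_profile(flat, samples, ann, "WT")
        assert profile.loc["4-cell", "value"] == pytest.approx(1.0)

    def test_sex_swap_gives_reciprocal_ratios(self, fm_toy):
        fpkm, samples, ann = fm_toy
        swapped = samples.copy()
        swapped["sex"] = swapped["sex"].map({"female": "male", "male": "female"})
        from xdosage.dosage import fm_gene_ratios
        genes = pd.Index(["g1", "g2", "g3"])
        fwd = fm_gene_ratios(fpkm, samples, genes, "4-cell", "WT")
        rev = fm_gene_ratios(fpkm, swapped, genes, "4-cell", "WT",
                             male_floor=0.0)
        pd.testing.assert_series_equal(rev, 1.0 / fwd)

    def test_male_floor_excludes_silent_genes(self, fm_toy):
        fpkm, samples, ann = fm_toy
        fpkm = fpkm.copy()
        fpkm.loc["g3", ["m1", "m2"]] = 0.05  # below the 0.1 FPKM floor
        profile = fm_profile(fpkm, samples, ann, "WT")
        assert profile.loc["4-cell", "n_genes"] == 2
        assert profile.loc["4-cell", "value"] == pytest.approx((2.5 + 2.0) / 2)

    def test_empty_gene_set_after_floor_is_error(self, fm_toy):
        fpkm, samples, ann = fm_toy
        dead = fpkm.copy()
        dead.loc[["g1", "g2", "g3"], ["m1", "m2"]] = 0.0
        with pytest.raises(ValidationError, match="floor"):
            fm_profile(dead, samples, ann, "WT")

    def test_invariant_to_common_rescaling(self, fm_toy):
        fpkm, samples, ann = fm_toy
        base = fm_profile(fpkm, samples, ann, "WT")
        scaled = fm_profile(fpkm * 37.5, samples, ann, "WT")
        pd.testing.assert_frame_equal(base, scaled)


class TestPerGeneTrack:
    def test_identical_expression_gives_zero_track(self, fm_toy):
        fpkm, samples, ann = fm_toy
        flat = fpkm.copy()
        flat[:] = 3.0
        ann = ann.copy()
        ann["position"] = [1, 2, 3, 1]
        track = per_gene_fm_track(flat, samples, ann, stages=["4-cell"])
        assert track["4-cell"].tolist() == [0.0, 0.0, 0.0]

    def test_values_clipped_to_display_range(self, fm_toy):
        fpkm, samples, ann = fm_toy
        ann = ann.copy()
        ann["position"] = [1, 2, 3, 1]
        wild = fpkm.copy()
        wild.loc["g1", ["f1", "f2"]] = 1000.0   # log2 ratio ~ 9, clips to 4.5
        wild.loc["g2", ["f1", "f2"]] = 0.01     # log2 ratio ~ -9, clips to -2
        track = per_gene_fm_track(wild, samples, ann, stages=["4-cell"])
        assert track.loc["g1", "4-cell"] == 4.5
        assert track.loc["g2", "4-cell"] == -2.0


class TestStageFoldChanges:
    @pytest.fixture
    def fc_toy(self):
        ann = make_annotation([("x1", "X", 1000), ("x2", "X", 1000),
                               ("a1", "1", 1000), ("a2", "2", 1000)])
        samples = make_samples(
            [(f"a{i}", "8-cell", "WT", "female") for i in range(3)]
            + [(f"b{i}", "E3.0", "WT", "female") for i in range(3)]
        )
        counts = pd.DataFrame(
            {**{f"a{i}": [100, 50, 1000, 1000] for i in range(3)},
             **{f"b{i}": [400, 50, 2000, 2000] for i in range(3)}},
            index=["x1", "x2", "a1", "a2"],
        )
        return counts, samples, ann

    def test_same_stage_gives_zero(self, fc_toy):
        counts, samples, ann = fc_toy
        fc, summary = stage_fold_changes(counts, samples, ann, "8-cell", "8-cell")
        assert (fc == 0).all()
        assert summary["median"] == 0.0

    def test_autosome_anchored_fold_change(self, fc_toy):
        # x1 doubles relative to autosomal totals: 400/4000 vs 100/2000
        counts, samples, ann = fc_toy
        fc, summary = stage_fold_changes(counts, samples, ann, "E3.0", "8-cell")
        assert fc["x1"] == pytest.approx(1.0)   # log2 of 2
        assert fc["x2"] == pytest.approx(-1.0)  # halves relative to autosomes
        assert summary["n_genes"] == 2

    def test_min_samples_rule(self, fc_toy):
        counts, samples, ann = fc_toy
        counts = counts.copy()
        counts.loc["x2", ["a1", "a2"]] = 0  # >1 cpm in only 1 8-cell sample
        fc, _ = stage_fold_changes(counts, samples, ann, "E3.0", "8-cell")
        assert "x2" not in fc.index


class TestXaMetrics:
    @pytest.fixture
    def uniform_world(self):
        """2 chromosomes x 3 genes + X x 3 genes, every gene at FPKM 2."""
        rows = [(f"g{c}{i}", c, 1000) for c in ("1", "2", "X") for i in range(3)]
        ann = make_annotation(rows)
        samples = make_samples([("e1", "4-cell", "WT", "male"),
                                ("e2", "E4.5", "WT", "male")])
        fpkm = pd.DataFrame(2.0, index=ann.index, columns=samples.index)
        return fpkm, samples, ann

    def test_xa_counting_argument(self, uniform_world):
        fpkm, samples, ann = uniform_world
        xa = xa_per_embryo(fpkm, ann)
        # X carries 3 of 9 genes, all equally expressed: X/A = 3/6
        assert xa.tolist() == pytest.approx([0.5, 0.5])

    def test_contribution_uniform_is_one(self, uniform_world):
        fpkm, samples, ann = uniform_world
        contrib = chromosome_contribution(fpkm, ann, samples)
        np.testing.assert_allclose(contrib.to_numpy(), 1.0)

    def test_contribution_autosome_average_is_exactly_one(self, tiny_dataset):
        from xdosage import preprocess
        counts, ann, samples = tiny_dataset
        norm = preprocess(counts, ann, samples, min_total_reads=100_000)
        contrib = chromosome_contribution(norm.fpkm, ann, norm.samples)
        ann_used = ann.loc[ann.index.intersection(norm.fpkm.index)]
        weights = ann_used.groupby("chromosome").size()
        autosomes = [c for c in contrib.index if c not in ("X", "Y", "MT")]
        for stage in contrib.columns:
            avg = np.average(contrib.loc[autosomes, stage],
                             weights=weights[autosomes])
            assert avg == pytest.approx(1.0, abs=1e-10)

    def test_relative_profile_constant_world(self, uniform_world):
        fpkm, samples, ann = uniform_world
        rel = chromosome_relative_profile(fpkm, ann, samples)
        np.testing.assert_allclose(rel.to_numpy(), 1.0)

    def test_stage_ratio_identical_stages(self, uniform_world):
        fpkm, samples, ann = uniform_world
        xa = xa_per_embryo(fpkm, ann)
        out = xa_stage_ratio(xa, samples, "E4.5", "4-cell")
        assert out["ratio"] == pytest.approx(1.0)
        assert out["p_value"] == pytest.approx(1.0)

    def test_fm_of_xa_sex_identical_world(self, uniform_world):
        fpkm, samples, ann = uniform_world
        samples = make_samples([("e1", "4-cell", "WT", "male"),
                                ("e2", "4-cell", "WT", "female")])
        xa = xa_per_embryo(fpkm, ann)
        out = fm_of_xa(xa, samples, "WT")
        assert out.loc["4-cell", "value"] == pytest.approx(1.0)

    def test_zero_autosomal_total_is_error(self, uniform_world):
        fpkm, samples, ann = uniform_world
        dead = fpkm.copy()
        dead.loc[["g10", "g11", "g12", "g20", "g21", "g22"]] = 0.0
        with pytest.raises(ValidationError, match="autosomal"):
            xa_per_embryo(dead, ann)


def build_random_world(seed=42):
    rng = np.random.default_rng(seed)
    rows = []
    chroms = ["1"] * 15 + ["2"] * 15 + ["X"] * 14 + ["Y"] * 3 + ["MT"] * 3
    for i, c in enumerate(chroms):
        rows.append((f"g{i:02d}", c, int(rng.integers(500, 5000))))
    ann = make_annotation(rows)
    ann.loc["g30", "role"] = "xist"  # first X gene doubles as Xist
    ann["position"] = ann.groupby("chromosome").cumcount() + 1
    samples = make_samples(
        [(f"f{i}", "4-cell", "WT", "female") for i in range(3)]
        + [(f"m{i}", "4-cell", "WT", "male") for i in range(2)]
        + [(f"F{i}", "E4.5", "WT", "female") for i in range(3)]
        + [(f"M{i}", "E4.5", "WT", "male") for i in range(2)]
    )
    fpkm = pd.DataFrame(rng.lognormal(1.0, 1.0, size=(len(ann), 10)),
                        index=ann.index, columns=samples.index)
    return fpkm, samples, ann


class TestAggregateOracles:
    """Every aggregate equals a naive double-loop recomputation."""

    @pytest.fixture(scope="module")
    def random_world(self):
        return build_random_world()

    def test_fm_profile_matches_double_loop(self, random_world):
        fpkm, samples, ann = random_world
        profile = fm_profile(fpkm, samples, ann, "WT")
        for stage in ("4-cell", "E4.5"):
            f_cols = [s for s in samples.index
                      if samples.loc[s, "stage"] == stage
                      and samples.loc[s, "sex"] == "female"]
            m_cols = [s for s in samples.index
                      if samples.loc[s, "stage"] == stage
                      and samples.loc[s, "sex"] == "male"]
            ratios = []
            for g in ann.index:
                if ann.loc[g, "chromosome"] != "X" or ann.loc[g, "role"] == "xist":
                    continue
                f_mean = sum(fpkm.loc[g, s] for s in f_cols) / len(f_cols)
                m_mean = sum(fpkm.loc[g, s] for s in m_cols) / len(m_cols)
                if m_mean >= 0.1:
                    ratios.append(f_mean / m_mean)
            assert profile.loc[stage, "value"] == pytest.approx(
                sum(ratios) / len(ratios), abs=1e-10)

    def test_chromosome_log2_fm_matches_double_loop(self, random_world):
        fpkm, samples, ann = random_world
        heat = chromosome_log2_fm(fpkm, samples, ann, "WT")
        assert "Y" not in heat.index
        for chrom in ("1", "2", "X"):
            genes = [g for g in ann.index if ann.loc[g, "chromosome"] == chrom
                     and ann.loc[g, "role"] != "xist"]
            f_cols = [s for s in samples.index
                      if samples.loc[s, "stage"] == "4-cell"
                      and samples.loc[s, "sex"] == "female"]
            m_cols = [s for s in samples.index
                      if samples.loc[s, "stage"] == "4-cell"
                      and samples.loc[s, "sex"] == "male"]
            ratios = []
            for g in genes:
                f_mean = np.mean([fpkm.loc[g, s] for s in f_cols])
                m_mean = np.mean([fpkm.loc[g, s] for s in m_cols])
                if m_mean >= 0.1:
                    ratios.append(f_mean / m_mean)
            assert heat.loc[chrom, "4-cell"] == pytest.approx(
                np.log2(np.mean(ratios)), abs=1e-10)

    def test_xa_and_contribution_match_double_loop(self, random_world):
        fpkm, samples, ann = random_world
        xa = xa_per_embryo(fpkm, ann)
        contrib = chromosome_contribution(fpkm, ann, samples)
        x_genes = [g for g in ann.index if ann.loc[g, "chromosome"] == "X"
                   and ann.loc[g, "role"] != "xist"]
        a_genes = [g for g in ann.index
                   if ann.loc[g, "chromosome"] in ("1", "2")]
        for s in samples.index:
            x_total = sum(fpkm.loc[g, s] for g in x_genes)
            a_total = sum(fpkm.loc[g, s] for g in a_genes)
            assert xa[s] == pytest.approx(x_total / a_total, abs=1e-10)
        for stage in ("4-cell", "E4.5"):
            cols = samples.index[samples["stage"] == stage]
            per_embryo = []
            for s in cols:
                x_pg = sum(fpkm.loc[g, s] for g in x_genes) / len(x_genes)
                a_pg = sum(fpkm.loc[g, s] for g in a_genes) / len(a_genes)
                per_embryo.append(x_pg / a_pg)
            assert contrib.loc["X", stage] == pytest.approx(
                np.mean(per_embryo), abs=1e-10)

    def test_relative_profile_matches_double_loop(self, random_world):
        fpkm, samples, ann = random_world
        rel = chromosome_relative_profile(fpkm, ann, samples)
        a_genes = [g for g in ann.index
                   if ann.loc[g, "chromosome"] in ("1", "2")]
        shares = {}
        for stage in ("4-cell", "E4.5"):
            cols = samples.index[samples["stage"] == stage]
            vals = []
            for s in cols:
                chrom1 = sum(fpkm.loc[g, s] for g in ann.index
                             if ann.loc[g, "chromosome"] == "1")
                a_total = sum(fpkm.loc[g, s] for g in a_genes)
                vals.append(chrom1 / a_total)
            shares[stage] = np.mean(vals)
        assert rel.loc["1", "E4.5"] == pytest.approx(
            shares["E4.5"] / shares["4-cell"], abs=1e-10)

    def test_gene_normalized_xa_matches_contribution_for_males(self, random_world):
        fpkm, samples, ann = random_world
        table = xa_gene_normalized(fpkm, ann, samples)
        contrib = chromosome_contribution(
            fpkm[samples.index[samples["sex"] == "male"]], ann,
            samples[samples["sex"] == "male"])
        males = table[table["sex"] == "male"].set_index("stage")
        for stage in ("4-cell", "E4.5"):
            assert males.loc[stage, "value"] == pytest.approx(
                contrib.loc["X", stage], abs=1e-12)


class TestTtests:
    def test_identical_samples_give_null_result(self):
        assert two_sample_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])[0] == \
            pytest.approx(0.0)
        assert two_sample_ttest([2.0, 2.0], [2.0, 2.0]) == (0.0, 1.0)
        assert paired_ttest([1.0, 2.0], [1.0, 2.0]) == (0.0, 1.0)

    def test_welch_t_matches_closed_form(self):
        # a=(1,2,3), b=(2,4,6): t = (2-4)/sqrt(1/3 + 4/3)
        t, p = two_sample_ttest([1.0, 2.0, 3.0], [2.0, 4.0, 6.0])
        assert t == pytest.approx(-2.0 / np.sqrt(5.0 / 3.0))
        assert 0.0 < p < 1.0

    def test_p_value_agrees_with_permutation_oracle(self):
        from itertools import combinations
        a = [3.1, 4.2, 2.8, 3.9]
        b = [5.6, 6.1, 5.2, 6.4]
        t_obs, p = two_sample_ttest(a, b)
        pooled = a + b
        n_extreme = 0
        n_total = 0
        for idx in combinations(range(8), 4):
            left = [pooled[i] for i in idx]
            right = [pooled[i] for i in range(8) if i not in idx]
            t_perm, _ = two_sample_ttest(left, right)
            n_total += 1
            if abs(t_perm) >= abs(t_obs) - 1e-12:
                n_extreme += 1
        p_perm = n_extreme / n_total
        assert p == pytest.approx(p_perm, abs=0.05)

    def test_paired_test_detects_constant_shift(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        t, p = paired_ttest(a + 0.5, a)
        assert p < 1e-6  # zero-variance differences, huge t
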