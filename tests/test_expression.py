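import numpy as np
import pytest

from floraltse.expression import (
    NormalizedProfile,
    call_presence,
    count_reads,
    normalize_to_reference,
    rpkm_table,
    validate_against_qpcr,
)

from conftest import mk_hit, random_hits


class TestCountReads:
    def test_single_best_hit_counted(self):
        hits = [
            mk_hit(query="r1", subject="g1", bitscore=100),
            mk_hit(query="r1", subject="g2", bitscore=90),
        ]
        counts, n = count_reads(hits)
        assert counts == {"g1": 1} and n == 1

    def test_hitless_reads_unmapped(self):
        counts, n = count_reads([])
        assert counts == {} and n == 0

    def test_exclusion_reroutes_or_unmaps(self):
        hits = [
            mk_hit(query="r1", subject="g1", bitscore=100),
            mk_hit(query="r1", subject="g2", bitscore=90),
            mk_hit(query="r2", subject="g1", bitscore=50),
        ]
        counts, n = count_reads(hits, exclude_subjects={"g1"})
        assert counts == {"g2": 1} and n == 1

    def test_matches_per_read_argmax_oracle(self, rng):
        for _ in range(30):
            hits = random_hits(rng, n_queries=25, n_subjects=6, n_hits=80)
            counts, n = count_reads(hits)
            expected = {}
            for q in {h.query_id for h in hits}:
                best = sorted(
                    (h for h in hits if h.query_id == q),
                    key=lambda h: (-h.bitscore, h.evalue, h.subject_id),
                )[0]
                expected[best.subject_id] = expected.get(best.subject_id, 0) + 1
            assert counts == expected
            assert n == sum(counts.values())


class TestRpkm:
    def test_unit_case(self):
        table = rpkm_table({"g": 10}, {"g": 1000}, 10**6)
        assert table.df.loc["g", "rpkm"] == pytest.approx(10.0)

    def test_formula_evaluation(self):
        table = rpkm_table({"g": 50}, {"g": 2000}, 5 * 10**6)
        assert table.df.loc["g", "rpkm"] == pytest.approx(5.0)

    def test_contig_vs_cds_length_normalization_gap(self):
        # equal counts under the two strategies: the ratio of the resulting
        # RPKM values is the inverse ratio of the model lengths
        # (a 629 nt contig vs a 2406 nt ortholog CDS)
        tse1 = rpkm_table({"SPL7": 40}, {"SPL7": 2406}, 10**5)
        tse2 = rpkm_table({"SPL7": 40}, {"SPL7": 629}, 10**5)
        ratio = tse2.df.loc["SPL7", "rpkm"] / tse1.df.loc["SPL7", "rpkm"]
        assert ratio == pytest.approx(2406 / 629)
        assert ratio == pytest.approx(3.825, abs=5e-3)

    def test_zero_count_gene_included_with_zero_rpkm(self):
        table = rpkm_table({"a": 10}, {"a": 500, "g": 500}, 10)
        assert table.df.loc["g", "read_count"] == 0
        assert table.df.loc["g", "rpkm"] == 0.0

    def test_zero_mappable_is_error(self):
        with pytest.raises(ValueError, match="N_mappable"):
            rpkm_table({}, {"g": 100}, 0)

    def test_missing_length_is_error(self):
        with pytest.raises(ValueError, match="length"):
            rpkm_table({"g": 1}, {}, 1)

    def test_count_conservation_enforced(self, rng):
        counts = {f"g{i}": int(rng.integers(0, 50)) for i in range(20)}
        lengths = {g: 500 for g in counts}
        n = sum(counts.values())
        table = rpkm_table(counts, lengths, n)
        assert int(table.df["read_count"].sum()) == n

    def test_scale_invariance(self, rng):
        counts = {f"g{i}": int(rng.integers(1, 50)) for i in range(10)}
        lengths = {g: int(rng.integers(200, 3000)) for g in counts}
        n = sum(counts.values())
        base = rpkm_table(counts, lengths, n)
        k = 7
        scaled = rpkm_table({g: k * c for g, c in counts.items()}, lengths, k * n)
        np.testing.assert_allclose(
            base.df["rpkm"].to_numpy(), scaled.df["rpkm"].to_numpy()
        )


class TestNormalize:
    def _table(self):
        return rpkm_table({"ref": 10, "a": 20, "b": 5}, {"ref": 1000, "a": 1000, "b": 1000}, 35)

    def test_reference_ratio_is_one(self):
        prof = normalize_to_reference(self._table(), "ref")
        assert prof.ratios["ref"] == pytest.approx(1.0)

    def test_double_rpkm_gives_two(self):
        prof = normalize_to_reference(self._table(), "ref")
        assert prof.ratios["a"] == pytest.approx(2.0)

    def test_profile_scale_invariant(self):
        t1 = self._table()
        t2 = rpkm_table({"ref": 20, "a": 40, "b": 10}, {"ref": 1000, "a": 1000, "b": 1000}, 70)
        p1 = normalize_to_reference(t1, "ref")
        p2 = normalize_to_reference(t2, "ref")
        for g in p1.ratios:
            assert p1.ratios[g] == pytest.approx(p2.ratios[g])

    def test_unexpressed_reference_is_error(self):
        table = rpkm_table({"a": 5}, {"a": 100, "ref": 100}, 5)
        with pytest.raises(ValueError, match="unexpressed"):
            normalize_to_reference(table, "ref")


class TestPresence:
    def test_threshold_behaviour(self):
        table = rpkm_table({"a": 1, "b": 4}, {"a": 100, "b": 100, "c": 100}, 5)
        assert call_presence(table, 1) == {"a", "b"}
        assert call_presence(table, 2) == {"b"}

    def test_monotone_in_min_count(self):
        table = rpkm_table({"a": 3, "b": 7, "c": 1}, {"a": 10, "b": 10, "c": 10}, 11)
        sets = [call_presence(table, k) for k in (1, 3, 5, 8)]
        for small, large in zip(sets[1:], sets):
            assert small <= large


class TestValidation:
    def test_identical_profiles(self):
        prof = NormalizedProfile("ref", {f"g{i}": float(i + 1) for i in range(5)})
        report = validate_against_qpcr(prof, prof)
        assert report.r_squared == pytest.approx(1.0)
        assert report.slope == pytest.approx(1.0)
        assert report.intercept == pytest.approx(0.0, abs=1e-9)

    def test_exact_doubling(self):
        x = NormalizedProfile("ref", {f"g{i}": float(i + 1) for i in range(5)})
        y = NormalizedProfile("ref", {f"g{i}": 2.0 * (i + 1) for i in range(5)})
        report = validate_against_qpcr(y, x)
        assert report.r_squared == pytest.approx(1.0)
        assert report.slope == pytest.approx(2.0)

    def test_outlier_removal_increases_r_squared(self, rng):
        # 14 concordant genes, one of which is planted 8-fold discordant
        ratios = {f"g{i:02d}": float(v) for i, v in enumerate(rng.uniform(0.05, 10.0, 14))}
        qpcr = NormalizedProfile("ref", dict(ratios))
        tse = {g: v * float(rng.normal(1.0, 0.03)) for g, v in ratios.items()}
        outlier = max(ratios, key=ratios.get)
        tse[outlier] = ratios[outlier] * 8.0
        tse_prof = NormalizedProfile("ref", tse)
        r_all = validate_against_qpcr(tse_prof, qpcr).r_squared
        r_excl = validate_against_qpcr(tse_prof, qpcr, exclude={outlier}).r_squared
        assert r_excl > r_all
        assert r_excl > 0.98

    def test_too_few_points_is_error(self):
        prof = NormalizedProfile("ref", {"a": 1.0, "b": 2.0})
        with pytest.raises(ValueError, match="3"):
            validate_against_qpcr(prof, prof)

    def test_log_scale_requires_positive(self):
        a = NormalizedProfile("ref", {"a": 1.0, "b": 0.0, "c": 2.0})
        with pytest.raises(ValueError, match="positive"):
            validate_against_qpcr(a, a, log_scale=True)
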