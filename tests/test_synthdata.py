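import math

import numpy as np
import pytest
from scipy import stats

from floraltse.annotate import flag_chimeras, reciprocal_best_hits
from floraltse.lineages import TAXA, decompose_sets, presence_vectors
from floraltse.synthdata import (
    expected_dollo_counts,
    generate_abundances,
    generate_annotation_hits,
    generate_contigs,
    generate_hit_tables,
    generate_read_hit_tables,
    generate_reads,
    generate_universe,
)


@pytest.fixture(scope="module")
def universe():
    families = generate_universe(n_families=400, seed=123)
    return generate_abundances(families, seed=124)


class TestUniverse:
    def test_zero_loss_root_births_are_everywhere(self):
        fams = generate_universe(
            n_families=50, birth_probs={"root": 1.0}, loss_probs=0.0, seed=1
        )
        assert all(f.mask == (1, 1, 1, 1) for f in fams)

    def test_focal_terminal_births_are_focal_specific(self):
        fams = generate_universe(
            n_families=50, birth_probs={"Th": 1.0}, loss_probs=0.5, seed=1
        )
        assert all(f.mask == (0, 0, 0, 0) for f in fams)

    def test_same_seed_identical(self):
        a = generate_universe(n_families=80, seed=7)
        b = generate_universe(n_families=80, seed=7)
        assert a == b

    def test_presence_consistent_with_events(self, universe):
        for f in universe:
            lost = set(f.loss_branches)
            if f.birth_branch == "Th":
                assert f.mask == (0, 0, 0, 0)
            if f.birth_branch == "root" and not lost:
                assert f.mask == (1, 1, 1, 1)
            if "Brassicaceae" in lost:
                assert not f.presence["At"] and not f.presence["Br"]

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError, match="probability"):
            generate_universe(n_families=5, birth_probs={"root": 1.5})


class TestAbundances:
    def test_zero_fraction_binomial(self):
        fams = generate_universe(n_families=1000, seed=5)
        fams = generate_abundances(fams, zero_fraction=0.3, seed=6)
        n_zero = sum(1 for f in fams if not f.expressed)
        # 99.7% binomial band around 300
        sd = math.sqrt(1000 * 0.3 * 0.7)
        assert abs(n_zero - 300) < 3 * sd

    def test_sigma_zero_degenerates_to_exp_mu(self):
        fams = generate_universe(n_families=30, seed=2)
        fams = generate_abundances(fams, lognormal_mu=1.0, lognormal_sigma=0.0,
                                   zero_fraction=0.0, seed=3)
        for f in fams:
            assert f.true_abundance == pytest.approx(math.e)

    def test_seeded_reproducibility(self):
        fams = generate_universe(n_families=40, seed=9)
        a = generate_abundances(fams, seed=10)
        b = generate_abundances(fams, seed=10)
        assert a == b


class TestReads:
    def test_mean_length_close_to_configured(self, universe):
        _, layout = generate_reads(universe, n_reads=10_000, seed=42)
        mean = layout["length"].mean()
        se = layout["length"].std() / math.sqrt(len(layout))
        assert abs(mean - 316.0) <= 3 * se + 1.0

    def test_single_family_gets_all_reads(self, universe):
        solo = [max(universe, key=lambda f: f.true_abundance)]
        _, layout = generate_reads(solo, n_reads=200, seed=0)
        assert set(layout["family_id"]) == {solo[0].family_id}

    def test_replicates_disjoint_and_complete(self, universe):
        reads, layout = generate_reads(universe, n_reads=3000, n_replicates=2, seed=8)
        ids1 = {r.id for r in reads["rep1"]}
        ids2 = {r.id for r in reads["rep2"]}
        assert not (ids1 & ids2)
        assert len(ids1 | ids2) == 3000

    def test_read_is_substring_of_transcript(self, universe):
        reads, layout = generate_reads(universe, n_reads=500, seed=4)
        seqs = {f.family_id: f.sequence for f in universe}
        by_id = {r.id: r.sequence for recs in reads.values() for r in recs}
        for row in layout.itertuples(index=False):
            assert by_id[row.read_id] == seqs[row.family_id][row.start : row.start + row.length]

    def test_count_expectation_proportional_to_abundance_times_length(self, universe):
        # chi-square goodness of fit of family read counts against
        # abundance x transcript-length weights at 10^5 reads
        _, layout = generate_reads(universe, n_reads=100_000, seed=77)
        expressed = [f for f in universe if f.expressed]
        weights = np.array([f.true_abundance * f.transcript_length for f in expressed])
        probs = weights / weights.sum()
        counts = layout["family_id"].value_counts()
        observed = np.array([counts.get(f.family_id, 0) for f in expressed])
        # pool tiny-expectation families to keep the test valid
        expected = probs * 100_000
        keep = expected >= 5
        obs = np.append(observed[keep], observed[~keep].sum())
        exp = np.append(expected[keep], expected[~keep].sum())
        chi2 = stats.chisquare(obs, exp * obs.sum() / exp.sum())
        assert chi2.pvalue > 1e-3


class TestContigs:
    def test_no_chimeras_single_constituents(self, universe):
        _, constituents = generate_contigs(universe, chimera_fraction=0.0, seed=1)
        assert all(len(s) == 1 for s in constituents.values())

    def test_true_utr_padding_full_transcript_length(self, universe):
        contigs, constituents = generate_contigs(
            universe, chimera_fraction=0.0, utr_padding="true_utr", seed=1
        )
        lengths = {f.family_id: f.transcript_length for f in universe}
        for contig in contigs:
            ((fam, start, end),) = constituents[contig.id]
            assert contig.length == lengths[fam] == end - start + 1

    def test_chimera_count_binomial(self):
        fams = generate_abundances(
            generate_universe(n_families=1100, seed=3), zero_fraction=0.09, seed=4
        )
        n_expressed = sum(1 for f in fams if f.expressed)
        _, constituents = generate_contigs(fams, chimera_fraction=0.1, seed=5)
        n_chim = sum(1 for s in constituents.values() if len(s) == 2)
        assert n_chim == round(0.1 * n_expressed)
        assert abs(n_chim - 100) <= 15

    def test_noise_free_rbh_annotates_every_clean_contig(self, universe):
        contigs, constituents = generate_contigs(universe, chimera_fraction=0.05, seed=6)
        fwd, rev = generate_annotation_hits(constituents, universe, seed=7)
        pairs = {(p.contig_id, p.ref_gene_id) for p in reciprocal_best_hits(fwd, rev)}
        by_id = {f.family_id: f for f in universe}
        for cid, spans in constituents.items():
            if len(spans) == 1:
                assert (cid, by_id[spans[0][0]].gene_id) in pairs

    def test_noise_free_chimera_flags_equal_planted(self, universe):
        contigs, constituents = generate_contigs(universe, chimera_fraction=0.05, seed=6)
        fwd, _ = generate_annotation_hits(constituents, universe, seed=7)
        flagged = {c.contig_id for c in flag_chimeras(fwd)}
        planted = {cid for cid, s in constituents.items() if len(s) > 1}
        assert flagged == planted


class TestTaxonHitTables:
    def test_noise_free_presence_recovers_truth(self, universe):
        _, constituents = generate_contigs(universe, chimera_fraction=0.0, seed=11)
        fwd, _ = generate_hit_tables(constituents, universe, seed=12)
        vectors = presence_vectors(sorted(constituents), fwd)
        truth = {f.family_id: f.mask for f in universe}
        for v in vectors:
            ((fam, _, _),) = constituents[v.contig_id]
            assert v.mask == truth[fam]

    def test_full_miss_rate_empties_tables(self, universe):
        _, constituents = generate_contigs(universe, chimera_fraction=0.0, seed=11)
        fwd, _ = generate_hit_tables(constituents, universe, miss_rate=1.0, seed=12)
        assert all(len(hits) == 0 for hits in fwd.values())

    def test_seeded_reproducibility(self, universe):
        _, constituents = generate_contigs(universe, chimera_fraction=0.0, seed=11)
        a, _ = generate_hit_tables(constituents, universe, miss_rate=0.2,
                                   spurious_rate=0.05, seed=13)
        b, _ = generate_hit_tables(constituents, universe, miss_rate=0.2,
                                   spurious_rate=0.05, seed=13)
        assert a == b

    def test_reverse_tables_mirror_forward(self, universe):
        _, constituents = generate_contigs(universe, chimera_fraction=0.0, seed=11)
        fwd, rev = generate_hit_tables(constituents, universe, seed=12)
        for taxon in TAXA:
            assert [h.flipped() for h in rev[taxon]] == fwd[taxon]


class TestReadHitTables:
    def test_contig_target_maps_every_read_under_utr_padding(self, universe):
        _, layout = generate_reads(universe, n_reads=2000, seed=21)
        _, constituents = generate_contigs(universe, chimera_fraction=0.0, seed=22)
        hits = generate_read_hit_tables(
            layout, universe, constituents, target="contig", seed=23
        )
        assert len(hits) == len(layout)

    def test_cds_target_drops_utr_reads(self, universe):
        _, layout = generate_reads(universe, n_reads=5000, seed=24)
        hits = generate_read_hit_tables(layout, universe, target="ref_cds", seed=25)
        assert 0 < len(hits) <= len(layout)
        mapped = {h.query_id for h in hits}
        cds = {f.family_id: f.th_cds_length for f in universe}
        for row in layout.itertuples(index=False):
            expected = (row.start + row.length / 2.0) < cds[row.family_id]
            assert (row.read_id in mapped) == expected


class TestExpectedDolloCounts:
    def test_matches_simulation_within_ci(self):
        n = 2000
        fams = generate_universe(n_families=n, seed=31)
        from floraltse.lineages import PresenceVector, summarize_births_losses

        # presence vectors straight from planted masks
        vectors = decompose_sets(
            [
                PresenceVector(contig_id=f.family_id, flags=tuple(bool(b) for b in f.mask))
                for f in fams
            ]
        )

        observed = summarize_births_losses(vectors)
        expected = expected_dollo_counts(n)
        for branch in expected.index:
            for col in ("gains", "losses"):
                mu = expected.loc[branch, col]
                sd = math.sqrt(max(mu * (1 - mu / n), 1e-12))
                assert abs(observed.loc[branch, col] - mu) <= 2.807 * sd + 1e-9
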