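import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ligrseq import (SimConfig, SimConfigError, SimSizeError, draw_abundances,
                     emit_truth_alignments, generate_features, generate_genome,
                     reads_from_truth, simulate_ligation, simulate_truth,
                     toy_align, truth_segments_frame)
from ligrseq.assign import write_sam


def _equal_abundances(features):
    ann = features.df[features.df["ftype"] != "UA"]
    return pd.Series(1.0 / len(ann), index=ann["id"].to_numpy())


class TestGenerateGenome:
    def test_minimal_two_srnas(self):
        config = SimConfig(genome_length=5000, n_genes=0, n_srnas=2, seed=1)
        genome, features = generate_genome(config)
        assert genome.length == 5000
        assert sorted(features.df["ftype"].unique()) == ["sRNA"]
        assert len(features) == 2

    def test_deterministic_output_files(self, tmp_path):
        config = SimConfig(genome_length=20_000, n_genes=8, n_srnas=2, seed=5)
        paths = []
        for tag in ("a", "b"):
            genome, features = generate_genome(config)
            fa, gff = tmp_path / f"{tag}.fa", tmp_path / f"{tag}.gff3"
            genome.write_fasta(fa)
            features.to_gff3(gff)
            paths.append((fa.read_bytes(), gff.read_bytes()))
        assert paths[0] == paths[1]

    def test_fifty_features_placed_disjoint(self):
        """Exhaustive pairwise interval sweep over a densely packed genome."""
        config = SimConfig(genome_length=100_000, n_genes=50, n_srnas=0, seed=3)
        _, features = generate_genome(config)
        assert len(features) == 50
        rows = list(features.df.itertuples(index=False))
        for i, a in enumerate(rows):
            for b in rows[i + 1:]:
                assert a.end < b.start or b.end < a.start

    def test_infeasible_sizing_rejected(self):
        config = SimConfig(genome_length=5000, n_genes=50, n_srnas=0, seed=0)
        with pytest.raises(SimSizeError):
            generate_genome(config)

    def test_unique_kmers_outside_repeats(self):
        config = SimConfig(genome_length=30_000, n_genes=10, n_srnas=2,
                           seed=11, n_repeats=1)
        genome, _ = generate_genome(config)
        from Bio.Seq import reverse_complement
        k = 20
        exempt = np.zeros(genome.length, dtype=bool)
        for s, e in genome.repeat_regions:
            exempt[s - 1:e] = True
        seen = set()
        for i in range(genome.length - k + 1):
            if exempt[i:i + k].any():
                continue
            kmer = genome.seq[i:i + k]
            canon = min(kmer, reverse_complement(kmer))
            assert canon not in seen
            seen.add(canon)

    def test_some_pairs_beyond_distance_threshold(self):
        _, features = generate_genome(SimConfig(seed=2))
        df = features.df
        assert df["start"].max() - df["end"].min() > 2000

    def test_invalid_fractions_rejected(self):
        with pytest.raises(SimConfigError):
            SimConfig(frac_chimeric=1.5).validate()
        with pytest.raises(SimConfigError):
            SimConfig(fragment_length_range=(10, 60)).validate()
        with pytest.raises(SimConfigError):
            SimConfig(planted_pairs=(("a", "b", 0.5),)).validate()


class TestSimulateTruth:
    def test_no_chimeras_only_non_chimeric(self, small_config):
        from dataclasses import replace
        config = replace(small_config, frac_chimeric=0.0)
        features = generate_features(config)
        truth = simulate_truth(config, features, draw_abundances(features, config))
        assert set(truth["cls"]) == {"non_chimeric"}
        assert truth["feat2"].isna().all()

    def test_read_truth_conservation(self, small_config):
        features = generate_features(small_config)
        abundances = draw_abundances(features, small_config)
        for rep in (1, 2):
            truth = simulate_truth(small_config, features, abundances, rep)
            assert len(truth) == small_config.n_reads
            assert truth["read_id"].is_unique

    def test_determinism_per_replicate(self, small_config):
        features = generate_features(small_config)
        abundances = draw_abundances(features, small_config)
        t1 = simulate_truth(small_config, features, abundances, 1)
        t2 = simulate_truth(small_config, features, abundances, 1)
        pd.testing.assert_frame_equal(t1, t2)
        t3 = simulate_truth(small_config, features, abundances, 2)
        assert not t1["feat1"].equals(t3["feat1"])

    def test_positive_abundances_required(self, small_config):
        features = generate_features(small_config)
        a = draw_abundances(features, small_config)
        a.iloc[0] = 0.0
        with pytest.raises(SimConfigError):
            simulate_truth(small_config, features, a)

    def test_unknown_planted_feature_rejected(self, small_config):
        from dataclasses import replace
        config = replace(small_config, planted_pairs=(("nope", "gene001", 5.0),))
        features = generate_features(config)
        with pytest.raises(SimConfigError):
            simulate_truth(config, features, draw_abundances(features, config))

    def test_fragments_within_features(self, small_config):
        features = generate_features(small_config)
        truth = simulate_truth(small_config, features,
                               draw_abundances(features, small_config))
        span = features.df.set_index("id")
        for k in ("1", "2"):
            sub = truth[truth[f"feat{k}"].notna()]
            s = span.loc[sub[f"feat{k}"]]
            assert (sub[f"start{k}"].to_numpy() >= s["start"].to_numpy()).all()
            assert (sub[f"end{k}"].to_numpy() <= s["end"].to_numpy()).all()

    def test_enrichment_one_is_background(self):
        """A pair planted at fold 1 is indistinguishable from background:
        aggregated pair counts over 10 seeds pass a chi-square GOF against
        the abundance-product multinomial."""
        base = SimConfig(genome_length=60_000, n_genes=10, n_srnas=0,
                         n_reads=2_000, frac_chimeric=1.0,
                         frac_intramolecular_of_chimeric=0.0, seed=0)
        features = generate_features(base)
        abundances = _equal_abundances(features)
        ids = list(abundances.index)
        planted = ((ids[0], ids[1], 1.0),)
        counts = {}
        for seed in range(10):
            from dataclasses import replace
            config = replace(base, seed=seed * 100, planted_pairs=planted)
            truth = simulate_truth(config, features, abundances)
            for f1, f2 in zip(truth["feat1"], truth["feat2"]):
                pair = tuple(sorted((f1, f2)))
                counts[pair] = counts.get(pair, 0) + 1
        n_pairs = len(ids) * (len(ids) - 1) // 2
        obs = np.zeros(n_pairs)
        pairs = [tuple(sorted((a, b))) for i, a in enumerate(ids)
                 for b in ids[i + 1:]]
        for i, pair in enumerate(pairs):
            obs[i] = counts.get(pair, 0)
        expected = np.full(n_pairs, obs.sum() / n_pairs)  # equal abundances
        _, p = sps.chisquare(obs, expected)
        assert p > 0.05

    def test_twentyfold_enrichment_matches_multinomial_oracle(self):
        """Planted count ~ 20x the equal-abundance background mean, within
        3 SD of the multinomial sampling oracle."""
        base = SimConfig(genome_length=60_000, n_genes=6, n_srnas=0,
                         n_reads=10_000, frac_chimeric=1.0,
                         frac_intramolecular_of_chimeric=0.0, seed=9)
        features = generate_features(base)
        abundances = _equal_abundances(features)
        ids = list(abundances.index)
        from dataclasses import replace
        config = replace(base, planted_pairs=((ids[0], ids[1], 20.0),))
        truth = simulate_truth(config, features, abundances)
        n_pairs = 15
        w = np.ones(n_pairs)
        w[0] = 20.0
        p_planted = w[0] / w.sum()
        n = len(truth)
        expected = n * p_planted
        sd = np.sqrt(n * p_planted * (1 - p_planted))
        observed = (truth["cls"] == "planted_pair").sum()
        assert abs(observed - expected) <= 3 * sd
        background_mean = (n - observed) / (n_pairs - 1)
        assert observed == pytest.approx(20 * background_mean, rel=0.15)

    def test_background_frequencies_match_multinomial(self):
        """Chi-square GOF of background pair frequencies against the
        a_i*a_j product measure at 1e5 reads."""
        config = SimConfig(genome_length=100_000, n_genes=12, n_srnas=0,
                           n_reads=100_000, frac_chimeric=1.0,
                           frac_intramolecular_of_chimeric=0.0, seed=21)
        features = generate_features(config)
        abundances = draw_abundances(features, config)
        truth = simulate_truth(config, features, abundances)
        ids = list(abundances.index)
        a = abundances.to_numpy()
        pairs, weights = [], []
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                pairs.append(tuple(sorted((ids[i], ids[j]))))
                weights.append(a[i] * a[j])
        weights = np.array(weights) / np.sum(weights)
        observed = truth.groupby(
            [np.minimum(truth["feat1"], truth["feat2"]),
             np.maximum(truth["feat1"], truth["feat2"])]).size()
        obs = np.array([observed.get(p, 0) for p in pairs], dtype=float)
        exp = weights * obs.sum()
        keep = exp >= 5  # standard GOF validity binning
        obs_b, exp_b = obs[keep], exp[keep]
        if (~keep).any():
            obs_b = np.append(obs_b, obs[~keep].sum())
            exp_b = np.append(exp_b, exp[~keep].sum())
        _, p = sps.chisquare(obs_b, exp_b)
        assert p > 0.01

    def test_fragment_order_randomised(self, small_config):
        features = generate_features(small_config)
        truth = simulate_truth(small_config, features,
                               draw_abundances(features, small_config))
        chim = truth[truth["cls"].isin(["background_pair", "planted_pair"])]
        frac_sorted = (chim["feat1"] < chim["feat2"]).mean()
        assert 0.4 < frac_sorted < 0.6


@pytest.fixture(scope="module")
def aligned_run():
    config = SimConfig(genome_length=20_000, n_genes=8, n_srnas=2,
                       n_reads=150, frac_chimeric=0.5,
                       frac_intramolecular_of_chimeric=0.2,
                       replicate_count=1, seed=13)
    genome, features = generate_genome(config)
    abundances = draw_abundances(features, config)
    truth = simulate_truth(config, features, abundances)
    reads = reads_from_truth(truth, genome)
    alignments = toy_align(reads, genome)
    return genome, features, truth, reads, alignments


class TestToyAlign:
    def test_non_chimeric_single_segment(self, aligned_run):
        _, _, truth, _, alignments = aligned_run
        by_id = {a.read_id: a for a in alignments}
        for row in truth[truth["cls"] == "non_chimeric"].itertuples():
            aln = by_id[row.read_id]
            assert len(aln.segments) == 1
            seg = aln.segments[0]
            assert (seg.start, seg.end, seg.strand) == \
                (row.start1, row.end1, row.strand1)

    def test_chimera_segments_at_truth_coordinates(self, aligned_run):
        """Noise-free chimeras resolve into two segments at the truth
        fragments (allowing chance extension a few nt past the junction)."""
        _, _, truth, _, alignments = aligned_run
        by_id = {a.read_id: a for a in alignments}
        chim = truth[truth["cls"].isin(["background_pair", "planted_pair"])]
        assert len(chim) > 10
        for row in chim.itertuples():
            aln = by_id[row.read_id]
            assert len(aln.segments) == 2
            want = sorted([(int(row.start1), int(row.end1)),
                           (int(row.start2), int(row.end2))])
            got = sorted((s.start, s.end) for s in aln.segments)
            for (ws, we), (gs, ge) in zip(want, got):
                assert abs(gs - ws) <= 5 and abs(ge - we) <= 5

    def test_repeat_read_flagged_ambiguous(self):
        config = SimConfig(genome_length=20_000, n_genes=6, n_srnas=1,
                           seed=17, n_repeats=1, repeat_length=80)
        genome, _ = generate_genome(config)
        s, e = genome.repeat_regions[0]
        read = genome.fetch(s, s + 39)
        [aln] = toy_align([("rep_read", read)], genome)
        assert not aln.segments or all(seg.is_ambiguous for seg in aln.segments)

    def test_unique_read_maps_unambiguously(self, aligned_run):
        genome, _, _, _, _ = aligned_run
        read = genome.fetch(501, 560)
        [aln] = toy_align([("u", read)], genome)
        assert len(aln.segments) == 1
        assert aln.segments[0].start == 501 and not aln.segments[0].is_ambiguous

    def test_reverse_strand_fragment_located(self, aligned_run):
        genome, _, _, _, _ = aligned_run
        read = genome.fetch(701, 760, strand="-")
        [aln] = toy_align([("rc", read)], genome)
        assert len(aln.segments) == 1
        seg = aln.segments[0]
        assert (seg.start, seg.end, seg.strand) == (701, 760, "-")


class TestEmitTruthAlignments:
    def test_empty_truth_header_only_sam(self, tmp_path, small_config):
        features = generate_features(small_config)
        truth = simulate_truth(small_config, features,
                               draw_abundances(features, small_config)).iloc[:0]
        alignments = emit_truth_alignments(truth, features)
        assert alignments == []
        path = tmp_path / "empty.sam"
        write_sam(alignments, {"chr": small_config.genome_length}, path)
        lines = path.read_text().splitlines()
        assert all(l.startswith("@") for l in lines)

    def test_intramolecular_row_two_segments_one_feature(self, small_config):
        features = generate_features(small_config)
        truth = simulate_truth(small_config, features,
                               draw_abundances(features, small_config))
        row = truth[truth["cls"] == "intramolecular"].iloc[[0]]
        [aln] = emit_truth_alignments(row, features)
        assert len(aln.segments) == 2
        assert row.iloc[0]["feat1"] == row.iloc[0]["feat2"]

    def test_unknown_feature_rejected(self, small_config):
        features = generate_features(small_config)
        truth = simulate_truth(small_config, features,
                               draw_abundances(features, small_config))
        truth.loc[0, "feat1"] = "ghost"
        with pytest.raises(ValueError, match="unknown feature"):
            emit_truth_alignments(truth.iloc[[0]], features)
        with pytest.raises(ValueError, match="unknown feature"):
            truth_segments_frame(truth, features)

    def test_frame_matches_per_read_alignments(self, small_config):
        features = generate_features(small_config)
        truth = simulate_truth(small_config, features,
                               draw_abundances(features, small_config)).head(200)
        alignments = emit_truth_alignments(truth, features)
        frame = truth_segments_frame(truth, features)
        flat = sorted(
            (a.read_id, s.start, s.end) for a in alignments for s in a.segments)
        from_frame = sorted(zip(frame["read_id"], frame["start"], frame["end"]))
        assert flat == from_frame


def test_simulate_ligation_replicates(small_config, tmp_path):
    genome, features = generate_genome(small_config)
    reads, truth = simulate_ligation(small_config, genome, features)
    assert set(reads) == {1, 2}
    for rep in (1, 2):
        rep_truth = truth[truth["replicate"] == rep]
        assert len(reads[rep]) == len(rep_truth) == small_config.n_reads
    # read sequence length equals the summed fragment lengths
    lens = {r.id: len(r.seq) for r in reads[1]}
    t1 = truth[truth["replicate"] == 1]
    frag = (t1["end1"] - t1["start1"] + 1).to_numpy()
    frag2 = (t1["end2"] - t1["start2"] + 1).fillna(0).to_numpy()
    want = frag + frag2
    got = np.array([lens[r] for r in t1["read_id"]])
    assert (got == want).all()
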