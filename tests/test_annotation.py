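import math

import numpy as np
import pytest
from scipy import stats

from seedscan import (
    ConservationTrack,
    GeneRecord,
    GenomicInterval,
    OrthologMap,
    classify_flanking,
    compare_conservation,
    gene_environment,
    motif_conservation,
    random_motif_sets,
)
from seedscan.annotation import (
    DOUBLE_FLANKED,
    NEAR_FLANK,
    NOT_FLANKED,
    NOT_ORTHOLOGOUS,
    SINGLE_FLANKED,
    flanking_genes,
    read_bedgraph,
    read_genes_bed,
    read_genes_gff3,
    read_ortholog_tsv,
    read_wiggle,
)


def genes_at(positions, chrom="c", prefix="g"):
    return [GeneRecord(f"{prefix}{i}", chrom, p) for i, p in enumerate(positions)]


ANCHOR = GenomicInterval("c", 3_000_000, 3_001_000)


class TestGeneEnvironment:
    def test_even_spacing_no_extension(self):
        # 200 kb spacing: 7 genes per side within 1.5 Mb
        ups = [ANCHOR.start - i * 200_000 for i in range(1, 13)]
        downs = [ANCHOR.end + i * 200_000 for i in range(1, 13)]
        up, down = gene_environment(ANCHOR, genes_at(sorted(ups + downs)))
        assert len(up) == 7 and len(down) == 7

    def test_extension_to_minimum(self):
        ups = [ANCHOR.start - d for d in (100_000, 200_000, 300_000,
                                          1_600_000, 1_700_000, 1_800_000, 1_900_000)]
        downs = [ANCHOR.end + i * 100_000 for i in range(1, 8)]
        up, down = gene_environment(ANCHOR, genes_at(sorted([p for p in ups + downs])))
        assert len(up) == 5  # 3 within margin + 2 nearest beyond

    def test_exhausted_side(self):
        ups = [ANCHOR.start - d for d in (100_000, 2_000_000, 2_500_000)]
        downs = [ANCHOR.end + i * 100_000 for i in range(1, 8)]
        up, down = gene_environment(ANCHOR, genes_at(sorted(ups + downs)))
        assert len(up) == 3

    def test_order_insensitive(self, rng):
        positions = list(rng.integers(0, 6_000_000, size=30))
        g = genes_at(positions)
        shuffled = list(g)
        rng.shuffle(shuffled)
        a = gene_environment(ANCHOR, g)
        b = gene_environment(ANCHOR, shuffled)
        assert [x.gene_id for x in a[0]] == [x.gene_id for x in b[0]]
        assert [x.gene_id for x in a[1]] == [x.gene_id for x in b[1]]


class TestFlankingGenes:
    def test_nearest_each_side(self):
        g = genes_at([1_000_000, 2_900_000, 3_200_000, 4_000_000])
        up, down = flanking_genes(ANCHOR, g)
        assert up.tss == 2_900_000
        assert down.tss == 3_200_000

    def test_inside_anchor_assigned_to_nearer_side(self):
        g = genes_at([3_000_100, 3_500_000])
        up, down = flanking_genes(ANCHOR, g)
        assert up.tss == 3_000_100  # near the start boundary -> upstream

    def test_chromosome_end(self):
        up, down = flanking_genes(ANCHOR, genes_at([3_200_000]))
        assert up is None and down.tss == 3_200_000


def _fixture(status):
    """Hand-built minimal scenario per class."""
    q_anchor = GenomicInterval("qc", 2_000_000, 2_001_000)
    t_pred = GenomicInterval("tc", 2_000_000, 2_001_000)
    qg = genes_at(
        [2_000_000 - (i + 1) * 150_000 for i in range(6)]
        + [2_001_000 + (i + 1) * 150_000 for i in range(6)],
        chrom="qc", prefix="q",
    )
    tg = genes_at(
        [2_000_000 - (i + 1) * 150_000 for i in range(6)]
        + [2_001_000 + (i + 1) * 150_000 for i in range(6)],
        chrom="tc", prefix="t",
    )
    # nearest upstream is q0/t0; nearest downstream is q6/t6
    omap = OrthologMap()
    if status == DOUBLE_FLANKED:
        omap.add("q0", "t0")
        omap.add("q6", "t6")
    elif status == SINGLE_FLANKED:
        omap.add("q0", "t0")
    elif status == NEAR_FLANK:
        omap.add("q0", "t2")
    elif status == NOT_FLANKED:
        omap.add("q2", "t3")
    return q_anchor, qg, t_pred, tg, omap


class TestClassifyFlanking:
    @pytest.mark.parametrize(
        "status",
        [DOUBLE_FLANKED, SINGLE_FLANKED, NEAR_FLANK, NOT_FLANKED, NOT_ORTHOLOGOUS],
    )
    def test_constructed_cases(self, status):
        q_anchor, qg, t_pred, tg, omap = _fixture(status)
        assert classify_flanking(q_anchor, qg, t_pred, tg, omap) == status

    def test_missing_chromosome_warns(self):
        q_anchor, qg, t_pred, tg, omap = _fixture(DOUBLE_FLANKED)
        other = GenomicInterval("nowhere", 10, 20)
        with pytest.warns(UserWarning):
            assert classify_flanking(q_anchor, qg, other, tg, omap) == NOT_ORTHOLOGOUS

    def test_order_insensitive(self, rng):
        q_anchor, qg, t_pred, tg, omap = _fixture(NEAR_FLANK)
        qg2, tg2 = list(qg), list(tg)
        rng.shuffle(qg2)
        rng.shuffle(tg2)
        assert classify_flanking(q_anchor, qg2, t_pred, tg2, omap) == NEAR_FLANK

    def test_matches_bruteforce_reference(self, rng):
        margin, min_side = 600_000, 2

        def oracle(q_anchor, qg, t_pred, tg, omap):
            def side(anchor, g):
                if g.tss < anchor.start:
                    return "up"
                if g.tss >= anchor.end:
                    return "down"
                return "up" if g.tss - anchor.start <= anchor.end - 1 - g.tss else "down"

            def dist(anchor, g):
                s = side(anchor, g)
                if s == "up":
                    return max(0, anchor.start - g.tss)
                return max(0, g.tss - (anchor.end - 1))

            def flankers(anchor, genes):
                out = []
                for want in ("up", "down"):
                    pool = [g for g in genes if g.seq_id == anchor.seq_id and side(anchor, g) == want]
                    if pool:
                        out.append(min(pool, key=lambda g: abs(dist(anchor, g))))
                return out

            def env(anchor, genes):
                ids = set()
                for want in ("up", "down"):
                    pool = [g for g in genes if g.seq_id == anchor.seq_id and side(anchor, g) == want]
                    near = [g for g in pool if abs(dist(anchor, g)) <= margin]
                    if len(near) < min_side:
                        near = sorted(pool, key=lambda g: abs(dist(anchor, g)))[:min_side]
                    ids |= {g.gene_id for g in near}
                return ids

            qf = flankers(q_anchor, qg)
            t_flank = {g.gene_id for g in flankers(t_pred, tg)}
            t_env = env(t_pred, tg)
            q_env = env(q_anchor, qg)
            n = sum(1 for g in qf if omap.targets_of(g.gene_id) & t_flank)
            if n >= 2:
                return DOUBLE_FLANKED
            if n == 1:
                return SINGLE_FLANKED
            if any(omap.targets_of(g.gene_id) & t_env for g in qf):
                return NEAR_FLANK
            qf_ids = {g.gene_id for g in qf}
            rest = [g for g in qg if g.gene_id in q_env and g.gene_id not in qf_ids]
            if any(omap.targets_of(g.gene_id) & t_env for g in rest):
                return NOT_FLANKED
            return NOT_ORTHOLOGOUS

        for _ in range(100):
            n_q = int(rng.integers(4, 12))
            n_t = int(rng.integers(4, 12))
            qg = genes_at(sorted(rng.integers(0, 4_000_000, size=n_q)), chrom="qc", prefix="q")
            tg = genes_at(sorted(rng.integers(0, 4_000_000, size=n_t)), chrom="tc", prefix="t")
            qa = int(rng.integers(0, 3_999_000))
            ta = int(rng.integers(0, 3_999_000))
            q_anchor = GenomicInterval("qc", qa, qa + 1000)
            t_pred = GenomicInterval("tc", ta, ta + 1000)
            omap = OrthologMap()
            for g in qg:
                for h in tg:
                    if rng.random() < 0.08:
                        omap.add(g.gene_id, h.gene_id)
            assert classify_flanking(
                q_anchor, qg, t_pred, tg, omap, margin, min_side
            ) == oracle(q_anchor, qg, t_pred, tg, omap)


class TestRandomMotifSets:
    REGION = GenomicInterval("c", 0, 1000)

    def test_contract(self):
        sets = random_motif_sets(self.REGION, [20, 30], n_sets=10, rng_seed=7)
        assert len(sets) == 10
        for s in sets:
            assert sorted(iv.length() for iv in s) == [20, 30]
            a, b = sorted(s, key=lambda iv: iv.start)
            assert a.end <= b.start
            assert all(0 <= iv.start and iv.end <= 1000 for iv in s)

    def test_cannot_fit(self):
        with pytest.raises(ValueError):
            random_motif_sets(self.REGION, [600, 600])

    def test_reproducible(self):
        a = random_motif_sets(self.REGION, [15, 25, 35], rng_seed=3)
        b = random_motif_sets(self.REGION, [15, 25, 35], rng_seed=3)
        assert a == b

    def test_single_segment_uniform_start(self):
        region = GenomicInterval("c", 0, 100)
        sets = random_motif_sets(region, [10], n_sets=10_000, rng_seed=11)
        starts = [s[0].start for s in sets]
        counts = np.bincount(starts, minlength=91)
        assert len(counts) == 91
        chi2 = ((counts - len(starts) / 91) ** 2 / (len(starts) / 91)).sum()
        assert chi2 < stats.chi2.ppf(0.99, df=90)


class TestMotifConservation:
    def _track(self):
        t = ConservationTrack()
        for pos, score in enumerate([0.2, 0.4, 0.6, 0.8]):
            t.set_score("c", pos, score)
        return t

    def test_mean(self):
        means = motif_conservation([GenomicInterval("c", 0, 4)], self._track())
        assert means == [pytest.approx(0.5)]

    def test_uncovered_missing(self):
        means = motif_conservation([GenomicInterval("c", 100, 110)], self._track())
        assert math.isnan(means[0])

    def test_partial_coverage_uses_available(self):
        means = motif_conservation([GenomicInterval("c", 2, 10)], self._track())
        assert means == [pytest.approx(0.7)]

    def test_matches_direct_summation(self, rng):
        t = ConservationTrack()
        for pos in range(500):
            if rng.random() < 0.7:
                t.set_score("c", pos, float(rng.random()))
        for _ in range(20):
            s = int(rng.integers(0, 450))
            iv = GenomicInterval("c", s, s + int(rng.integers(1, 50)))
            vals = [t.get("c", p) for p in range(iv.start, iv.end)]
            vals = [v for v in vals if v is not None]
            expected = sum(vals) / len(vals) if vals else math.nan
            got = motif_conservation([iv], t)[0]
            assert (math.isnan(got) and math.isnan(expected)) or got == pytest.approx(expected)


class TestCompareConservation:
    def test_identical_lists(self):
        stat, p = compare_conservation([0.5] * 10, [0.5] * 10)
        assert p > 0.9

    def test_maximal_separation(self):
        stat, p = compare_conservation([1.0] * 8, [0.0] * 80)
        assert p < 0.01

    def test_empty_after_nan_drop(self):
        with pytest.raises(ValueError):
            compare_conservation([math.nan], [0.5])

    def test_agrees_with_permutation_reference(self, rng):
        real = rng.normal(0.6, 0.1, size=15)
        rand = rng.normal(0.5, 0.1, size=60)
        stat, p = compare_conservation(list(real), list(rand))
        # permutation null on the rank-sum statistic
        pooled = np.concatenate([real, rand])
        obs = stats.rankdata(pooled)[: len(real)].sum()
        n_perm, hits = 10_000, 0
        prng = np.random.default_rng(0)
        for _ in range(n_perm):
            perm = prng.permutation(pooled)
            w = stats.rankdata(perm)[: len(real)].sum()
            if abs(w - len(real) * (len(pooled) + 1) / 2) >= abs(obs - len(real) * (len(pooled) + 1) / 2):
                hits += 1
        p_perm = hits / n_perm
        assert p == pytest.approx(p_perm, abs=0.02)


class TestReaders:
    def test_genes_bed(self, tmp_path):
        path = tmp_path / "genes.bed"
        path.write_text("c\t100\t500\tgA\t0\t+\nc\t800\t1200\tgB\t0\t-\n")
        genes = read_genes_bed(path)
        assert genes[0] == GeneRecord("gA", "c", 100, "+")
        assert genes[1] == GeneRecord("gB", "c", 1199, "-")

    def test_genes_gff3(self, tmp_path):
        path = tmp_path / "genes.gff3"
        path.write_text(
            "##gff-version 3\n"
            "c\tsrc\tgene\t101\t500\t.\t+\t.\tID=gA\n"
            "c\tsrc\tmRNA\t101\t500\t.\t+\t.\tID=mA;Parent=gA\n"
            "c\tsrc\tgene\t801\t1200\t.\t-\t.\tID=gB\n"
        )
        genes = read_genes_gff3(path)
        assert [g.gene_id for g in genes] == ["gA", "gB"]
        assert genes[0].tss == 100
        assert genes[1].tss == 1199

    def test_ortholog_tsv(self, tmp_path):
        path = tmp_path / "orth.tsv"
        path.write_text("# header\nqA\ttA\nqA\ttB\n")
        omap = read_ortholog_tsv(path)
        assert omap.targets_of("qA") == {"tA", "tB"}
        assert omap.queries_of("tB") == {"qA"}

    def test_bedgraph(self, tmp_path):
        path = tmp_path / "t.bedgraph"
        path.write_text("c\t0\t3\t0.5\nc\t3\t5\t0.9\n")
        track = read_bedgraph(path)
        assert track.get("c", 0) == 0.5
        assert track.get("c", 4) == 0.9
        assert track.get("c", 5) is None

    def test_wiggle_fixed_step(self, tmp_path):
        path = tmp_path / "t.wig"
        path.write_text("fixedStep chrom=c start=11 step=2\n0.1\n0.2\n")
        track = read_wiggle(path)
        assert track.get("c", 10) == 0.1
        assert track.get("c", 12) == 0.2

    def test_score_out_of_range(self):
        t = ConservationTrack()
        with pytest.raises(ValueError):
            t.set_score("c", 0, 1.5)
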