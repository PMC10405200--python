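"""Breakend graph construction, proximity walks (vs an exhaustive-path
oracle), fusion calling, and copy-number oscillation flagging."""
import numpy as np
import pytest

from leukotype.graph import (
    EnhancerAnchor,
    build_graph,
    call_fusions,
    detect_cn_oscillation,
    enhancer_walks,
)
from leukotype.model import (
    HEAD,
    TAIL,
    BreakendEnd,
    BreakendPair,
    CopyNumberSegment,
    GenomicInterval,
)

CHROMS = {"chrA": 1_000_000, "chrB": 1_000_000}
ANCHOR = EnhancerAnchor("E", GenomicInterval("chrA", 500_000, 501_000))


def sv(i, c1, p1, o1, c2, p2, o2, ins=""):
    return BreakendPair(f"s{i}", BreakendEnd(c1, p1, o1), BreakendEnd(c2, p2, o2), inserted_seq=ins)


class TestBuildGraph:
    def test_no_svs_one_segment_per_chromosome(self):
        g = build_graph([], CHROMS)
        assert all(len(segs) == 1 for segs in g.segments.values())
        assert g.n_nodes == 4  # two chromosomes, two orientations
        assert g.variant_edges == []

    def test_one_deletion_three_segments_one_junction(self):
        g = build_graph([sv(0, "chrA", 100_000, TAIL, "chrA", 200_000, HEAD)], CHROMS)
        assert len(g.segments["chrA"]) == 3
        assert g.segments["chrA"] == [(1, 100_000), (100_001, 199_999), (200_000, 1_000_000)]
        assert len({e[3] for e in g.variant_edges}) == 1
        assert len(g.variant_edges) == 2  # one junction plus its orientation mirror

    def test_reciprocal_translocation_four_variant_edges(self):
        svs = [
            sv(0, "chrA", 100_000, TAIL, "chrB", 300_000, HEAD),
            sv(1, "chrB", 299_999, TAIL, "chrA", 100_001, HEAD),
        ]
        g = build_graph(svs, CHROMS)
        assert len(g.variant_edges) == 4

    def test_breakend_beyond_contig_end_errors(self):
        with pytest.raises(ValueError, match="beyond contig end"):
            build_graph([sv(0, "chrA", 100, TAIL, "chrA", 2_000_000, HEAD)], CHROMS)


def _walk(svs, genes, **kw):
    bodies = {k: v for k, v in genes.items()}
    g = build_graph(svs, CHROMS, landmarks=(ANCHOR.interval,) + tuple(bodies.values()))
    return {w.gene: w for w in enhancer_walks(g, ANCHOR, bodies, **kw)}


class TestEnhancerWalks:
    def test_translocation_places_gene_at_known_distance(self):
        # junction 20 kb right of the anchor; gene body 20 kb past the partner end
        gene = GenomicInterval("chrB", 120_000, 160_000, "+")
        svs = [sv(0, "chrA", 521_000, TAIL, "chrB", 100_000, HEAD)]
        walks = _walk(svs, {"G": gene})
        assert walks["G"].walk_length_bp == 40_000
        assert walks["G"].n_variant_edges == 1
        assert walks["G"].sv_ids == ("s0",)

    def test_threshold_is_strict(self):
        gene = GenomicInterval("chrB", 200_000, 240_000, "+")
        svs = [sv(0, "chrA", 525_000, TAIL, "chrB", 74_000, HEAD)]
        # 24,000 + 126,000 = 150,000 >= 100,000
        assert _walk(svs, {"G": gene}) == {}
        assert "G" in _walk(svs, {"G": gene}, max_len_bp=200_000)

    def test_two_hop_walk_through_inserted_fragment(self):
        # anchor -> SV1 -> 10 kb fragment on chrB -> SV2 -> gene
        gene = GenomicInterval("chrA", 700_000, 740_000, "+")
        svs = [
            sv(0, "chrA", 506_000, TAIL, "chrB", 50_000, HEAD),
            sv(1, "chrB", 60_000, TAIL, "chrA", 693_000, HEAD),
        ]
        walks = _walk(svs, {"G": gene})
        # 5 kb to SV1, 10,001 bp fragment, 7 kb to the gene
        assert walks["G"].walk_length_bp == 5_000 + 10_001 + 7_000
        assert walks["G"].n_variant_edges == 2

    def test_candidate_set_nested_in_threshold(self):
        rng = np.random.default_rng(3)
        svs, genes = _random_config(rng, n_svs=5)
        lengths = [40_000, 80_000, 120_000, 300_000]
        sets = [set(_walk(svs, genes, max_len_bp=L)) for L in lengths]
        for small, big in zip(sets, sets[1:]):
            assert small <= big

    def test_graph_symmetry_under_end_reversal(self):
        rng = np.random.default_rng(11)
        svs, genes = _random_config(rng, n_svs=6)
        fwd = {g: w.walk_length_bp for g, w in _walk(svs, genes).items()}
        rev = {g: w.walk_length_bp for g, w in _walk([s.reversed() for s in svs], genes).items()}
        assert fwd == rev

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_exhaustive_path_oracle_on_random_graphs(self, seed):
        rng = np.random.default_rng(seed)
        svs, genes = _random_config(rng, n_svs=int(rng.integers(1, 7)))
        bodies = dict(genes)
        g = build_graph(svs, CHROMS, landmarks=(ANCHOR.interval,) + tuple(bodies.values()))
        fast = {
            w.gene: w.walk_length_bp
            for w in enhancer_walks(g, ANCHOR, bodies, max_len_bp=150_000, max_variant_edges=3)
        }
        slow = _oracle_walks(g, ANCHOR.interval, bodies, 150_000, 3, 50_000)
        assert fast == slow


def _random_config(rng, n_svs):
    svs = []
    for i in range(n_svs):
        c1, c2 = rng.choice(["chrA", "chrB"], size=2)
        p1 = int(rng.integers(10_000, 990_000))
        p2 = int(rng.integers(10_000, 990_000))
        o1, o2 = rng.choice([TAIL, HEAD], size=2)
        try:
            svs.append(sv(i, c1, p1, o1, c2, p2, o2))
        except ValueError:  # degenerate deletion ordering; skip
            continue
    genes = {
        "G1": GenomicInterval("chrB", 400_000, 430_000, "+"),
        "G2": GenomicInterval("chrA", 100_000, 130_000, "-"),
    }
    return svs, genes


def _oracle_walks(graph, anchor_iv, genes, max_len, max_var, max_pre):
    """Exhaustive DFS over simple paths; independent cost accounting."""

    def node_cost(n):
        s, e = graph.seg(n)
        if anchor_iv.chrom == n.chrom and anchor_iv.start <= s and e <= anchor_iv.end:
            return 0
        return e - s + 1

    def gene_hits(n):
        s, e = graph.seg(n)
        return [name for name, b in genes.items() if b.chrom == n.chrom and s <= b.end and b.start <= e]

    best: dict[str, int] = {}

    def dfs(node, k, cost, visited):
        if cost >= max_len:
            return
        if k >= 1:
            for name in gene_hits(node):
                if cost < best.get(name, max_len):
                    best[name] = cost
        step = node_cost(node)
        for nxt in graph.ref_successors(node):
            if nxt not in visited:
                dfs(nxt, k, cost + step, visited | {nxt})
        if k < max_var:
            for nxt, ins, _sid in graph.var_successors(node):
                if nxt not in visited and (k > 0 or cost + step <= max_pre):
                    dfs(nxt, k + 1, cost + step + ins, visited | {nxt})

    for start in graph.nodes_overlapping(anchor_iv):
        dfs(start, 0, 0, frozenset([start]))
    return best


class TestFusions:
    G5 = GenomicInterval("chrA", 100_000, 150_000, "+")
    G3 = GenomicInterval("chrB", 300_000, 360_000, "+")

    def test_compatible_translocation_is_a_fusion(self):
        svs = [sv(0, "chrA", 120_000, TAIL, "chrB", 320_000, HEAD)]
        out = call_fusions(svs, {"A": self.G5, "B": self.G3})
        assert [(f[0], f[1]) for f in out] == [("A", "B")]

    def test_incompatible_orientation_is_not(self):
        svs = [sv(0, "chrA", 120_000, TAIL, "chrB", 320_000, TAIL)]
        assert call_fusions(svs, {"A": self.G5, "B": self.G3}) == []

    def test_chained_fusion_via_inversion_and_deletion(self):
        """A two-junction derivative (interstitial jump through an intergenic
        fragment) is only recovered in chained mode."""
        g5 = GenomicInterval("chrA", 700_000, 740_000, "-")
        g3 = GenomicInterval("chrA", 500_000, 560_000, "+")
        svs = [
            BreakendPair("inv", BreakendEnd("chrA", 715_000, HEAD), BreakendEnd("chrA", 460_500, HEAD)),
            BreakendPair("dele", BreakendEnd("chrA", 468_000, TAIL), BreakendEnd("chrA", 530_000, HEAD)),
        ]
        models = {"M": g5, "B": g3}
        assert call_fusions(svs, models) == []
        chained = call_fusions(svs, models, CHROMS, chained=True)
        assert [(f[0], f[1]) for f in chained] == [("M", "B")]
        assert set(chained[0][2]) == {"inv", "dele"}


class TestCnOscillation:
    @staticmethod
    def _segs(chrom, cns, start=1, length=10_000):
        out = []
        for i, cn in enumerate(cns):
            s = start + i * length
            out.append(CopyNumberSegment(GenomicInterval(chrom, s, s + length - 1), cn, min(1, cn)))
        return out

    def test_flat_diploid_genome_not_flagged(self):
        flagged, chroms = detect_cn_oscillation(self._segs("chr1", [2] * 12))
        assert not flagged and chroms == []

    def test_alternating_twelve_segments_flags_chromosome(self):
        segs = self._segs("chr1", [2, 1] * 6)  # 11 switches between two states
        flagged, chroms = detect_cn_oscillation(segs)
        assert chroms == ["chr1"]
        assert not flagged  # a single chromosome is not enough for the case flag

    def test_two_oscillating_chromosomes_flag_the_case(self):
        segs = self._segs("chr1", [2, 1] * 6) + self._segs("chr4", [3, 2] * 6)
        flagged, chroms = detect_cn_oscillation(segs)
        assert flagged and chroms == ["chr1", "chr4"]
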