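"""QC gating, ploidy classification, biallelic logic, the precedence ladder,
RNA consensus and WGS/RNA reconciliation."""
import pytest

from leukotype.dux4 import Dux4Call
from leukotype.genome import default_genome
from leukotype.graph import WalkCandidate
from leukotype.model import (
    Case,
    CopyNumberSegment,
    GenomicInterval,
    RnaEvidence,
    SmallVariant,
)
from leukotype.subtypes import (
    Detections,
    SubtypeCall,
    assess_biallelic,
    assign_subtype,
    classify_ploidy,
    qc_gate,
    reconcile,
    rna_consensus,
)

GENES = default_genome().genes
CONTIGS = default_genome().contig_lengths


def _snvs(n, vaf=0.45):
    return [SmallVariant(("chr2", 1000 + i), "A", "C", vaf) for i in range(n)]


class TestQcGate:
    @pytest.mark.parametrize("n,expected", [(99, "excluded_low_burden"), (100, "included")])
    def test_boundary(self, n, expected):
        assert qc_gate(Case("c", 40, small_variants=_snvs(n))) == expected

    def test_roster_excludes_exactly_five(self, report):
        assert report.summary["n_excluded_low_burden"] == 5
        excluded = report.calls[report.calls.qc_status != "included"]
        assert set(excluded.case_id) == {"B053", "B054", "B055", "B056", "B057"}


def _flat_segments(states):
    """states: chrom -> (total, minor); every contig fully covered."""
    return [
        CopyNumberSegment(GenomicInterval(c, 1, L), *states.get(c, (2, 1)))
        for c, L in CONTIGS.items()
    ]


class TestPloidy:
    def test_uniform_diploid(self):
        p = classify_ploidy(_flat_segments({}), CONTIGS)
        assert (p.label, p.modal_chromosomes) == ("diploid-range", 46)

    def test_twenty_six_retained_is_near_haploid(self):
        kept = {"chr2", "chr3", "chr21"}
        states = {c: (1, 0) for c in CONTIGS if c not in kept}
        p = classify_ploidy(_flat_segments(states), CONTIGS)
        assert (p.label, p.modal_chromosomes) == ("near-haploid", 26)

    def test_doubled_hypodiploid_is_near_triploid(self):
        loh = ["chr1", "chr2", "chr3", "chr4", "chr5", "chr7", "chr9", "chr12",
               "chr13", "chr17", "chr19", "chr22", "chrX"]
        states = {c: (2, 0) for c in loh}
        states.update({c: (4, 2) for c in CONTIGS if c not in loh})
        p = classify_ploidy(_flat_segments(states), CONTIGS)
        assert p.label == "near-triploid"
        assert p.modal_chromosomes == 66
        assert p.loh_fraction > 0.5

    def test_incomplete_cover_errors(self):
        segs = _flat_segments({})[:-1]
        with pytest.raises(ValueError, match="incomplete"):
            classify_ploidy(segs, CONTIGS)


def _pax5_case(variants=(), segments=None, case_id="c"):
    segs = segments if segments is not None else _flat_segments({})
    return Case(case_id, 40, small_variants=list(variants), segments=segs)


def _pax5_variant(protein_change, pos_offset=0):
    iv = GENES["PAX5"]
    return SmallVariant((iv.chrom, iv.start + 500 + pos_offset), "A", "C", 0.45, "PAX5", protein_change)


class TestBiallelic:
    def test_two_mutations(self):
        case = _pax5_case([_pax5_variant("R38H"), _pax5_variant("R140L", 100)])
        assert assess_biallelic("PAX5", case, GENES["PAX5"]).mechanism == "two_mutations"

    def test_mutation_plus_arm_level_loh(self):
        segs = [CopyNumberSegment(GenomicInterval("chr9", 1, 950_000), 2, 0)] + [
            s for s in _flat_segments({}) if s.interval.chrom != "chr9"
        ] + [CopyNumberSegment(GenomicInterval("chr9", 950_001, CONTIGS["chr9"]), 2, 1)]
        case = _pax5_case([_pax5_variant("P80R")], segments=segs)
        assert assess_biallelic("PAX5", case, GENES["PAX5"]).mechanism == "mutation_plus_LOH"

    def test_mutation_plus_deletion(self):
        iv = GENES["PAX5"]
        segs = [s for s in _flat_segments({}) if s.interval.chrom != "chr9"]
        segs += [
            CopyNumberSegment(GenomicInterval("chr9", 1, iv.start - 1), 2, 1),
            CopyNumberSegment(GenomicInterval("chr9", iv.start, iv.end), 1, 0),
            CopyNumberSegment(GenomicInterval("chr9", iv.end + 1, CONTIGS["chr9"]), 2, 1),
        ]
        case = _pax5_case([_pax5_variant("M335fs*68")], segments=segs)
        assert assess_biallelic("PAX5", case, GENES["PAX5"]).mechanism == "mutation_plus_deletion"

    def test_fusion_plus_loh(self):
        iv = GENES["PAX5"]
        segs = [s for s in _flat_segments({}) if s.interval.chrom != "chr9"]
        segs += [
            CopyNumberSegment(GenomicInterval("chr9", 1, iv.start - 1), 2, 1),
            CopyNumberSegment(GenomicInterval("chr9", iv.start, iv.end), 1, 0),
            CopyNumberSegment(GenomicInterval("chr9", iv.end + 1, CONTIGS["chr9"]), 2, 1),
        ]
        case = _pax5_case(segments=segs)
        st = assess_biallelic("PAX5", case, GENES["PAX5"], fusions=[("ETV6", "PAX5", ("sv1",))])
        assert st.mechanism == "fusion_plus_LOH" and st.biallelic

    def test_single_deletion_is_monoallelic(self):
        iv = GENES["PAX5"]
        segs = [s for s in _flat_segments({}) if s.interval.chrom != "chr9"]
        segs += [
            CopyNumberSegment(GenomicInterval("chr9", 1, iv.start - 1), 2, 1),
            CopyNumberSegment(GenomicInterval("chr9", iv.start, iv.end), 1, 0),
            CopyNumberSegment(GenomicInterval("chr9", iv.end + 1, CONTIGS["chr9"]), 2, 1),
        ]
        st = assess_biallelic("PAX5", _pax5_case(segments=segs), GENES["PAX5"])
        assert st.mechanism == "monoallelic" and not st.biallelic

    def test_untouched_gene_is_none(self):
        assert assess_biallelic("PAX5", _pax5_case(), GENES["PAX5"]).mechanism == "none"


def _det(**kw):
    from leukotype.subtypes import PloidyClass

    kw.setdefault("ploidy", PloidyClass("diploid-range", 46, 0.0))
    return Detections(**kw)


def _walk(gene, anchor="IGH-Emu", length=30_000):
    return WalkCandidate(anchor, gene, [], length, 1, ("sv1",))


class TestLadder:
    def test_dux4_wins_over_cooccurring_zeb2(self):
        iv = GENES["ZEB2"]
        case = Case("c", 40, small_variants=[
            SmallVariant((iv.chrom, iv.start + 10), "A", "C", 0.20, "ZEB2", "H1038R")
        ], segments=_flat_segments({}))
        det = _det(dux4=Dux4Call("c", "IGH", "paired_breakend", "direct", ("j",)))
        call = assign_subtype(case, det, GENES)
        assert call.label == "DUX4-r"
        assert any("ZEB2" in e for e in call.evidence)  # co-occurrence recorded

    def test_ep300_znf384_fusion(self):
        case = Case("c", 40, segments=_flat_segments({}))
        call = assign_subtype(case, _det(fusions=[("EP300", "ZNF384", ("s",))]), GENES)
        assert call.label == "ZNF384-r"

    def test_ubtf_deletion_fusion(self):
        case = Case("c", 40, segments=_flat_segments({}))
        call = assign_subtype(case, _det(fusions=[("UBTF", "ATXN7L3", ("s",))]), GENES)
        assert call.label == "UBTF::ATXN7L3"

    def test_standalone_igh_cebpa_is_its_own_subtype(self):
        case = Case("c", 40, segments=_flat_segments({}))
        assert assign_subtype(case, _det(walks=[_walk("CEBPA")]), GENES).label == "IGH::CEBPA"

    def test_igh_cebpb_with_zeb2_is_zeb2_cebp(self):
        iv = GENES["ZEB2"]
        case = Case("c", 40, small_variants=[
            SmallVariant((iv.chrom, iv.start + 10), "A", "C", 0.45, "ZEB2", "H1038R")
        ], segments=_flat_segments({}))
        assert assign_subtype(case, _det(walks=[_walk("CEBPB")]), GENES).label == "ZEB2/CEBP"

    def test_no_detections_is_no_driver(self):
        case = Case("c", 40, segments=_flat_segments({}))
        call = assign_subtype(case, _det(), GENES)
        assert call.label == "no-driver" and call.evidence == []

    def test_lesion_order_invariance(self):
        """Permuting input lesion order never changes the call."""
        iv = GENES["ZEB2"]
        variants = [
            SmallVariant((iv.chrom, iv.start + 10), "A", "C", 0.45, "ZEB2", "H1038R"),
            SmallVariant((GENES["IDH2"].chrom, GENES["IDH2"].start + 10), "A", "C", 0.4, "IDH2", "R140Q"),
        ]
        fusions = [("EP300", "ZNF384", ("a",)), ("UBTF", "ATXN7L3", ("b",))]
        base = None
        for vs, fs in [(variants, fusions), (variants[::-1], fusions[::-1])]:
            case = Case("c", 40, small_variants=list(vs), segments=_flat_segments({}))
            call = assign_subtype(case, _det(fusions=list(fs)), GENES)
            if base is None:
                base = call.label
            assert call.label == base == "ZNF384-r"

    def test_ladder_totality_on_roster(self, report):
        included = report.calls[report.calls.qc_status == "included"]
        assert included.subtype.ne("").all()
        assert len(included) == 52


class TestRnaConsensus:
    def test_majority_of_two(self):
        rna = RnaEvidence({"c1": "PAX5alt", "c2": "PAX5alt", "c3": "Ph-like"})
        assert rna_consensus(rna) == "PAX5alt"

    def test_all_distinct_falls_back_to_cluster(self):
        rna = RnaEvidence({"c1": "A", "c2": "B", "c3": "C"}, cluster_label="DUX4-r")
        assert rna_consensus(rna) == "DUX4-r"

    def test_contamination_voids_rna(self):
        rna = RnaEvidence({"c1": "A", "c2": "A", "c3": "A"}, quality_flags={"contamination"})
        assert rna_consensus(rna) is None


class TestReconcile:
    def _call(self, label, evidence=()):
        return SubtypeCall("c", label, list(evidence), 5)

    def test_idh2_vs_pax5alt_discordant_wgs_retained(self):
        rna = RnaEvidence({"c1": "PAX5alt", "c2": "PAX5alt", "c3": "PAX5alt"})
        call = reconcile(self._call("IDH1/2"), rna)
        assert call.label == "IDH1/2" and call.rna_agreement == "discordant"

    def test_classifier_agreement_without_fusion_is_concordant(self):
        rna = RnaEvidence({"c1": "DUX4-r", "c2": "DUX4-r", "c3": "B-other"}, fusions=[])
        assert reconcile(self._call("DUX4-r"), rna).rna_agreement == "concordant"

    def test_fusion_match_counts_as_concordant(self):
        rna = RnaEvidence({"c1": "B-other", "c2": "x", "c3": "y"}, cluster_label="B-other",
                          fusions=[("EP300", "ZNF384")])
        call = reconcile(self._call("ZNF384-r", ["fusion:EP300::ZNF384"]), rna)
        assert call.rna_agreement == "concordant"

    def test_no_rna_is_na(self):
        assert reconcile(self._call("DUX4-r"), None).rna_agreement == "na"
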