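"""Catalog construction, NNLS refitting, cosine properties, the robust
mutation clock, and RAG RSS-motif annotation (vs a sliding-window oracle)."""
import numpy as np
import pytest

from leukotype.genome import default_genome
from leukotype.model import HEAD, TAIL, BreakendEnd, BreakendPair, SmallVariant
from leukotype.sequtils import revcomp
from leukotype.signatures import (
    CONTEXT_LABELS,
    RSS_HEPTAMER,
    annotate_rag,
    bin_index,
    build_catalog,
    cosine,
    fit_clock,
    flag_hypermutator,
    load_reference,
    refit,
    rss_at_breakpoint,
)
from leukotype.simulate import simulate_mutations


@pytest.fixture(scope="module")
def sigs():
    return load_reference()


class TestCatalog:
    def test_reference_matrix_shape_and_normalization(self, sigs):
        assert sigs.shape == (96, 7)
        assert np.allclose(sigs.sum(axis=0), 1.0)
        assert list(sigs.index) == list(CONTEXT_LABELS)

    def test_single_mutation_fills_one_bin(self, reference):
        # find an A[C]G context on a mutation chromosome
        pos = int(reference.trinuc_positions("chr2")["ACG"][0])
        tri = reference.fetch("chr2", pos - 1, pos + 1)
        alt = "T" if tri[1] in "CT" else "A"
        v = SmallVariant(("chr2", pos), tri[1], alt, 0.5)
        catalog = build_catalog([v], reference)
        assert catalog.sum() == 1
        assert catalog[bin_index(tri, alt)] == 1

    def test_purine_reference_folds_to_pyrimidine_bin(self):
        # G-reference SNV folds to the reverse-complement pyrimidine context
        assert bin_index("AGT", "A") == bin_index(revcomp("AGT"), "T")

    def test_ref_mismatch_raises_with_locus(self, reference):
        pos = 5000
        base = reference.base("chr2", pos)
        wrong = "A" if base != "A" else "C"
        v = SmallVariant(("chr2", pos), wrong, "T" if wrong != "T" else "G", 0.5)
        with pytest.raises(ValueError, match=f"chr2:{pos}"):
            build_catalog([v], reference)

    def test_pure_signature_sampling_recovers_profile(self, sigs, reference):
        rng = np.random.default_rng(7)
        snvs = simulate_mutations({"SBS18": 1.0}, 5000, rng, reference)
        catalog = build_catalog(snvs, reference)
        assert cosine(catalog, sigs["SBS18"]) >= 0.98


class TestRefit:
    def test_identity_recovery(self, sigs):
        catalog = 1000 * sigs["SBS9"].to_numpy()
        exp = refit(catalog, sigs)
        assert exp.exposures[list(sigs.columns).index("SBS9")] == pytest.approx(1000, rel=1e-6)
        assert exp.reconstruction_cosine == pytest.approx(1.0)

    def test_zero_catalog_flagged(self, sigs):
        exp = refit(np.zeros(96), sigs)
        assert exp.fractions is None and np.isnan(exp.reconstruction_cosine)

    def test_sixty_forty_mixture_recovered(self, sigs, reference):
        rng = np.random.default_rng(2024)
        snvs = simulate_mutations({"SBS18": 0.6, "SBS9": 0.4}, 20_000, rng, reference)
        exp = refit(build_catalog(snvs, reference), sigs)
        frac = dict(zip(exp.signature_names, exp.fractions))
        assert frac["SBS18"] == pytest.approx(0.6, abs=0.03)
        assert frac["SBS9"] == pytest.approx(0.4, abs=0.03)

    @pytest.mark.parametrize("seed", range(50))
    def test_residual_bounded_by_random_grid_oracle(self, sigs, seed):
        rng = np.random.default_rng(seed)
        catalog = rng.integers(0, 100, size=96).astype(float)
        S = sigs.to_numpy()
        exp = refit(catalog, sigs)
        nnls_resid = np.linalg.norm(catalog - S @ exp.exposures)
        scale = catalog.sum()
        for _ in range(40):
            e = rng.uniform(0, 2, size=7) * scale / 7
            assert nnls_resid <= np.linalg.norm(catalog - S @ e) + 1e-9

    def test_exposures_nonneg_fractions_normalized_on_cohort(self, report):
        df = report.exposures
        sig_cols = [c for c in df.columns if c not in ("case_id", "n_snvs", "reconstruction_cosine")]
        assert (df[sig_cols] >= 0).all().all()
        assert np.allclose(df[sig_cols].sum(axis=1), 1.0, atol=1e-3)


class TestCosine:
    def test_self_similarity(self):
        v = np.arange(1, 97, dtype=float)
        assert cosine(v, v) == pytest.approx(1.0)

    def test_orthogonal_one_hot(self):
        a, b = np.zeros(96), np.zeros(96)
        a[0], b[1] = 1, 1
        assert cosine(a, b) == 0.0

    def test_zero_vector_errors(self):
        with pytest.raises(ValueError):
            cosine(np.zeros(3), np.ones(3))

    def test_hypermutator_profile_prefers_thio_mmr_over_clock_cpg(self, report, reference, sigs):
        """The hypermutator catalog fits the thiopurine/MMR-deficiency shape
        better than the CpG deamination signature (ordering property)."""
        case = next(r.case for r in report.results if r.case.case_id == "B008")
        catalog = build_catalog(case.snvs, reference)
        assert cosine(catalog, sigs["thioMMR"]) > cosine(catalog, sigs["SBS1"])


class TestClock:
    def test_noiseless_line_recovered_exactly(self):
        ages = {f"c{i}": 25.0 + i for i in range(20)}
        burden = {k: round(16 * v) for k, v in ages.items()}
        fit = fit_clock(burden, ages)
        assert fit.slope == pytest.approx(16.0, abs=0.01)
        assert fit.ci_low <= fit.slope <= fit.ci_high

    def test_planted_hypermutator_does_not_move_slope(self):
        rng = np.random.default_rng(8)
        ages = {f"c{i}": float(a) for i, a in enumerate(rng.uniform(25, 65, 52))}
        clean = {k: int(16 * v + rng.normal(0, 80)) for k, v in ages.items()}
        fit_clean = fit_clock(clean, ages, exclude_outliers=False)
        dirty = dict(clean)
        dirty["c0"] = 70_000
        fit_dirty = fit_clock(dirty, ages)
        assert fit_dirty.outliers == ("c0",)
        assert fit_dirty.slope == pytest.approx(fit_clean.slope, abs=0.5)

    def test_too_few_cases_errors(self):
        with pytest.raises(ValueError):
            fit_clock({"a": 100}, {"a": 30.0})


class TestHypermutatorFlag:
    def test_uniform_cohort_unflagged(self):
        assert flag_hypermutator({f"c{i}": 700 + i for i in range(20)}) == []

    def test_twenty_fold_outlier_flagged(self):
        burdens = {f"c{i}": 700 for i in range(20)}
        burdens["hot"] = 14_000
        assert flag_hypermutator(burdens) == ["hot"]

    def test_roster_flags_only_the_msh6_case(self, report):
        assert report.summary["hypermutators"] == ["B008"]


def _deletion(case, p, q, i=0):
    return BreakendPair(f"d{i}", BreakendEnd("chr10", p, TAIL), BreakendEnd("chr10", q, HEAD))


class TestRagAnnotation:
    def test_heptamer_at_exact_breakpoint_flagged(self, reference):
        site = int(reference.heptamer_sites("chr10")[0])
        ann = annotate_rag([_deletion(None, site, site + 50_000)], reference)
        assert ann.flags["d0"] and ann.burden == 1

    def test_motif_just_outside_window_not_flagged(self, reference):
        """A breakpoint placed window+1 bp past a heptamer with no other motif
        nearby is not attributed to RAG."""
        window = 25
        for site in map(int, reference.heptamer_sites("chr10")[:50]):
            p = site + len(RSS_HEPTAMER) - 1 + window + 1
            q = p + 40_000
            if not _oracle_hit(reference, "chr10", p, window, 1) and not _oracle_hit(
                reference, "chr10", q, window, 1
            ):
                ann = annotate_rag([_deletion(None, p, q)], reference)
                assert not ann.flags["d0"]
                return
        pytest.skip("no isolated heptamer found")

    @pytest.mark.parametrize("seed", range(10))
    def test_equals_sliding_window_oracle(self, reference, seed):
        rng = np.random.default_rng(seed)
        dels = []
        for i in range(20):
            p = int(rng.integers(10_000, 1_300_000))
            dels.append(_deletion(None, p, p + int(rng.integers(1_000, 90_000)), i))
        ann = annotate_rag(dels, reference, window=25, max_mismatch=1)
        for sv in dels:
            expected = _oracle_hit(reference, "chr10", sv.end1.pos, 25, 1) or _oracle_hit(
                reference, "chr10", sv.end2.pos, 25, 1
            )
            assert ann.flags[sv.id] == expected

    def test_plant_and_recover_on_roster(self, roster, reference, report):
        """Planted RAG deletions are recovered exactly; the outlier hijack case
        carries 49 of 69 attributable deletions."""
        gt = roster.ground_truth
        planted = gt[gt.category.isin(["rag_deletion", "nonrag_deletion"])]
        for cid, sub in planted.groupby("case_id"):
            case = roster.case(cid)
            ids = set(sub.name)
            dels = [sv for sv in case.svs if sv.id in ids]
            ann = annotate_rag(dels, reference)
            expected_rag = int((sub.category == "rag_deletion").sum())
            assert (ann.burden, ann.total_deletions) == (expected_rag, len(sub))
        by_case = report.rag.set_index("case_id")
        row = by_case.loc["B046"]
        assert (row.rag_deletions, row.total_deletions) == (49, 69)
        assert row.rag_fraction == pytest.approx(49 / 69, abs=1e-3)


def _oracle_hit(reference, chrom, pos, window, max_mm):
    """Naive per-position scan, independent of the vectorized matcher."""
    seq = reference.seq(chrom)
    motifs = (RSS_HEPTAMER, revcomp(RSS_HEPTAMER))
    for start in range(pos - window, pos + window + 1):
        frag = seq[start - 1 : start + 6]
        if len(frag) < 7:
            continue
        for motif in motifs:
            if sum(a != b for a, b in zip(frag, motif)) <= max_mm:
                return True
    return False
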