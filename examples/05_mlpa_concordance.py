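"""Compare simulated MLPA deletion calls against the WGS copy-number arm.

MLPA reports probe dosage ratios against a diploid normal; low tumor purity,
subclonality, or a deletion falling between probes all push the ratio above
the calling threshold while the WGS segmentation still sees the event. The
comparator categorizes every WGS-only deletion accordingly.
"""
from leukotype.genome import default_genome
from leukotype.mlpa import PANEL_GENES, ProbePanel, cohort_concordance
from leukotype.simulate import generate_cohort, paper_roster_config

ref = default_genome()
cohort = generate_cohort(paper_roster_config(seed=1))
included = [c for c in cohort.cases if len(c.snvs) >= 100]
df = cohort_concordance(included, ProbePanel.packaged(), {g: ref.genes[g] for g in PANEL_GENES})

mlpa_del = df[df.mlpa_call == "deleted"]
wgs_only = df[(df.wgs_call == "deleted") & (df.mlpa_call == "normal")]
print(f"MLPA deletions          : {len(mlpa_del)}")
print(f"  also seen by WGS      : {(mlpa_del.wgs_call == 'deleted').sum()} (100% expected)")
print(f"WGS-only deletions      : {len(wgs_only)}")
print(wgs_only.discrepancy_category.value_counts().to_string())
# purity_ploidy: dosage washed out by admixture; subclonal: cell fraction
# below MLPA sensitivity; probe_placement: deletion between probe positions.
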