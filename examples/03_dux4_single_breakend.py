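"""Call a DUX4 rearrangement from a single breakend.

DUX4 sits inside the D4Z4 macrosatellite, so the partner side of an
IGH::DUX4 rearrangement is often an SV anchored at only one placeable locus,
with the unplaced mate sequence attached. Mapping that sequence onto the
packaged repeat contig by exact 15-mer seeding is the decision surface.
"""
from leukotype import Case, RepeatReference, SingleBreakend, call_dux4, map_sequence
from leukotype.model import HEAD, TAIL, BreakendEnd

repeat = RepeatReference.packaged()

attached = repeat.sequence[4000:4100]  # 100 nt of D4Z4-like sequence
report = map_sequence(attached, repeat)
print(f"k-mer mapping: {report.hits}/{report.total_kmers} seeds hit "
      f"(fraction {report.fraction:.2f}, strand {report.strand}) -> matched={report.matched}")

case = Case("demo", age=41, single_breakends=[
    SingleBreakend("sb1", BreakendEnd("chr14", 1_250_000, TAIL), attached)
])
call = call_dux4(case, repeat)
print(f"call: partner={call.partner} evidence={call.evidence} configuration={call.configuration}")
# A single breakend inside the IGH window whose attached sequence maps to the
# repeat contig is sufficient for an IGH::DUX4 call - no mated breakend needed.
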