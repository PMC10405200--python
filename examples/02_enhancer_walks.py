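"""Detect an IGH enhancer hijack with a breakend-graph proximity walk.

A translocation drops an intact oncogene a short derivative-chromosome
distance from the Emu IGH superenhancer. The walk caller splits chromosomes
into oriented segments at every breakpoint, then finds the minimum-cost
orientation-consistent path from the enhancer anchor to each candidate gene;
candidates under 100 kb are emitted.
"""
from leukotype import BreakendEnd, BreakendPair, EnhancerAnchor, build_graph, enhancer_walks
from leukotype.genome import IGH_EMU_ANCHOR, default_genome
from leukotype.model import HEAD, TAIL

ref = default_genome()
epor = ref.genes["EPOR"]

# junction: 12 kb downstream of the Emu anchor joined to 8 kb past EPOR's 3' end
sv = BreakendPair(
    "t(14;19)",
    BreakendEnd("chr14", IGH_EMU_ANCHOR.end + 12_000, TAIL),
    BreakendEnd(epor.chrom, epor.end + 8_000, TAIL),
)
graph = build_graph([sv], ref.contig_lengths, landmarks=(IGH_EMU_ANCHOR, epor))
anchor = EnhancerAnchor("IGH-Emu", IGH_EMU_ANCHOR)
for walk in enhancer_walks(graph, anchor, {"EPOR": epor}):
    print(f"{walk.anchor} -> {walk.gene}: {walk.walk_length_bp:,} bp over "
          f"{walk.n_variant_edges} junction(s), via {walk.sv_ids}")
# The walk length (12,000 + 8,000 = 20,000 bp) is the intervening DNA between
# enhancer and gene on the derivative chromosome - well under the 100 kb rule,
# so this SV is reclassified as a candidate IGH::EPOR enhancer hijack.
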