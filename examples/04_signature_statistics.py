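"""Ping-pong, phasing and nucleotide-bias statistics.

The ping-pong signature is an enrichment of 10-nt 5'-5' overlaps between
sense and antisense piRNAs (reported as a leave-one-out z-score at
overlap 10); phasing is an enrichment of head-to-tail 3'->5' distances
at 0 nt (Z0); primary piRNAs start with U (1U) and secondary piRNAs
carry A at position 10 (10A).
"""

from pirnakit import (
    FeatureIndex,
    SimulationConfig,
    base_frequency_matrix,
    paired_fraction,
    phasing_signature,
    pingpong_histogram,
    simulate_sample,
    split_by_te_strand,
)

_, annotations, library, _ = simulate_sample(
    SimulationConfig(seed=4, n_reads=8_000, pingpong_fraction=0.3,
                     phasing_fraction=0.3)
)
pirna = [r for r in library.reads if 24 <= r.length <= 32]
te_index = FeatureIndex([a for a in annotations if a.feature_class == "TE"])
sense, antisense = split_by_te_strand(pirna, te_index)

pp = pingpong_histogram(sense, antisense)
print(f"ping-pong: z(10) = {pp.focal:.1f}, strongest overlap = "
      f"{pp.argmax_offset()} nt")
print(f"paired piRNAs: {100 * paired_fraction(pirna):.1f}%")

ph = phasing_signature(pirna)
print(f"phasing: Z0 = {ph.focal:.1f}, strongest distance = "
      f"{ph.argmax_offset()} nt")

_, u1_anti, _ = base_frequency_matrix(antisense)
_, _, a10_sense = base_frequency_matrix(sense)
print(f"antisense 1U = {u1_anti:.2f}, sense 10A = {a10_sense:.2f}")
# z above ~3 marks a real register; u1/a10 well above 0.25 mark biases.
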