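"""Classify reads into small-RNA classes and count them fractionally.

A read overlapping a contamination feature (miRNA, rRNA, ...) is excluded
from the piRNA pool; TE-overlapping reads of 24-32 nt are piRNAs and
18-23 nt siRNA candidates.  Multi-mapping reads contribute 1/k per
mapping, further split across overlapping features, so total counted
mass equals the number of distinct reads.
"""

from pirnakit import (
    FeatureIndex,
    SimulationConfig,
    class_summary,
    length_histogram,
    simulate_sample,
)

_, annotations, library, _ = simulate_sample(SimulationConfig(seed=2, n_reads=5_000))
index = FeatureIndex(annotations)

print("class profile (apportioned read mass):")
for label, row in class_summary(library.reads, index).items():
    print(f"  {label:16s} {row['count']:8.1f} reads  {row['percent']:5.1f}%")

hist = length_histogram(library.reads, library.mapped_total)
peak = max(hist, key=hist.get)
print(f"\nlength histogram peak: {peak} nt at {hist[peak]:,.0f} RPM")
print("RPM per length sums to 1e6 over the whole library:",
      f"{sum(hist.values()):,.0f}")
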