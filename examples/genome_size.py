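"""Flow-cytometry genome size: peak ratios, picograms and megabases.

A sample's 2C DNA content is the ratio of its G0/G1 fluorescence peak to
that of a co-chopped internal standard of known genome size, times the
standard's 2C value. Picograms convert to megabase pairs at 978 Mbp/pg.
"""

import knobscan as ks

standard_2c_pg = 5.43  # the internal standard's 2C value, supplied by the user

for label, sample_peak, standard_peak in [
    ("hybrid pool", 206.3, 200.0),
    ("inbred pool", 198.9, 200.0),
]:
    pg = ks.genome_size_from_peaks(sample_peak, standard_peak, standard_2c_pg)
    print(f"{label}: peak ratio {sample_peak / standard_peak:.3f} "
          f"-> 2C = {pg:.2f} pg = {ks.pg_to_mbp(pg)} Mbp")

print(f"\nReference points: 2C = 5.6 pg -> {ks.pg_to_mbp(5.6)} Mbp, "
      f"2C = 5.4 pg -> {ks.pg_to_mbp(5.4)} Mbp")
print("A ~0.2 pg difference between hybrids and inbreds (~200 Mbp) is of "
      "the same order as the spread knob content could produce, which is "
      "why genome size is analysed as a quantitative trait.")
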