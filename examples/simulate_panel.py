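"""Simulate the assay-1 knob panel: 8 inbred lines and 35 hybrids.

Each line descends from a single seed heterozygous at the four knob loci
(K3L, K5L, K7S, K9S) and is selfed to the S9 generation, so it is fixed
(0 or 2 presence alleles) at every locus; hybrids are crosses between two
panel lines and can be heterozygous (1). The phenotype table holds one row
per plant: male/female flowering time in days and 2C genome size in pg.
"""

import knobscan as ks
from knobscan.simulate import panel_to_frame, records_to_frame

params = ks.GeneratorParams(seed=1)
panel = ks.generate_panel(params)
records = ks.simulate_phenotypes(panel, params)

geno = panel_to_frame(panel)
print(geno.head(10).to_string(index=False))
print(f"\n{sum(e.entry_type == 'line' for e in panel)} lines, "
      f"{sum(e.entry_type == 'hybrid' for e in panel)} hybrids, "
      f"{len(records)} plants "
      f"(3 replicates per line, 5 per hybrid)")

pheno = records_to_frame(records)
print("\nFirst plants:")
print(pheno.head(4).round(2).to_string(index=False))
print("\nThe 0/1/2 codes count knob-presence alleles; lines carry no 1s "
      "because nine selfing generations leave only ~0.2% residual "
      "heterozygosity per locus.")
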