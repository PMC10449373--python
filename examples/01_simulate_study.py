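"""Generate a synthetic five-lake plankton time series and inspect it.

The generator emulates a fortnightly sampling campaign over three seasons:
a shared core community, lake-specific taxa, seasonal abundance bumps, two
lakes with desiccation gaps, and multinomial read sampling at fixed depth.
"""

from sodanet import generate_study

study = generate_study(n_core=30, n_noncore_per_lake=10, depth=5000, seed=42)

print(f"lakes: {list(study.tables)}")
for lake, table in study.tables.items():
    miss, phi = study.truth.desiccation.get(lake, (frozenset(), 0.0))
    print(
        f"  {lake}: {len(table.sample_ids)} samples x {len(table.otu_ids)} OTUs"
        + (f"  (dry at times {sorted(miss)}, replacement phi={phi})" if miss else "")
    )
print(f"planted core OTUs shared by all lakes: {len(study.truth.core_otus)}")

# Every sample holds exactly `depth` reads; dry dates have no sample at all.
sums = study.tables["L1"].row_sums()
print(f"reads per sample (L1): min={sums.min()}, max={sums.max()}")
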