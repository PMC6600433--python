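"""Set-algebra summaries over the packaged concordant-gene tables.

The package ships six transcribed reference tables of concordant genes
(mouse lung/blood x SAEC/HMVEC, mRNA and miRNA). The reporting stage
recomputes all headline counts from them: per-table record and
direction tallies, unique-gene unions per compartment, and the
cross-compartment intersection requiring a consistent direction.
"""

from concordx import load_fixture_records, summarize_sets

mrna = summarize_sets(load_fixture_records("mrna"))
mirna = summarize_sets(load_fixture_records("mirna"))

print("mRNA records by (compartment, cell type):")
for (comp, cell), v in mrna["per_pair"].items():
    print(f"  {comp:5s} x {cell:5s}: {v['records']:2d} records "
          f"({v['up']} up, {v['down']} down, {v['unique_genes']} unique genes)")

print("\nunique concordant mRNAs per compartment:", mrna["unique_by_compartment"])
print("genes concordant in lung AND blood (same direction):",
      mrna["cross_compartment_intersection"])
print("\nunique concordant miRNAs per compartment:", mirna["unique_by_compartment"])
# the lung-and-blood intersection is the strongest biomarker candidate
# set: those genes respond in the same direction in tissue, circulating
# blood, and cultured human cells.
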