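"""Merge heterogeneous chemical-activity tables into the 3-table schema.

Three synthetic sources with different column layouts (a binary assay
table, a numeric toxicity-value table, a screening library) are reduced to
substances / properties / activities. Compounds shared across sources by
identical InChI strings collapse to one substance id; unmappable rows
surface in a rejections table, so every input row is accounted for.
"""

from brickyard import count_activities_by_source, harmonize, major_properties, validate_harmony
from brickyard.fixtures import ChemSpec, make_chem_sources

spec = ChemSpec(seed=0, rows=(40, 30, 20), overlap=5, invalid_rows=(2, 1, 0))
sources = make_chem_sources(spec)
for adapter, table in sources:
    print(f"source {adapter.name!r}: {len(table)} rows, columns {list(table.columns)}")

tables = harmonize(sources)
print(f"\nsubstances: {len(tables.substances)}  properties: {len(tables.properties)}  "
      f"activities: {len(tables.activities)}  rejections: {len(tables.rejections)}")
# rows in == activities + rejections per source (conservation)

print("\nactivities by source:")
print(count_activities_by_source(tables.activities).to_string(index=False))

print("\nmajor properties (> 10 activities):", len(major_properties(tables.activities, 10)))
print("schema violations:", len(validate_harmony(tables)))
print("\nfirst activity row:")
print(tables.activities.iloc[0].to_string())
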