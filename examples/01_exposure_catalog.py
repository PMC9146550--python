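"""Build a chemical x exposure-source presence matrix from list-presence records.

Generates synthetic list-presence records (chemical, keyword) with a
keyword -> exposure-source-category map, collapses keywords to
categories, builds the 0/1 presence matrix and applies the >= 2-category
filter that co-occurrence analysis requires.
"""

from coexmix.catalog import build_presence_matrix, filter_min_categories, map_keywords
from coexmix.simulate import gen_presence

records, keyword_map, truth = gen_presence(seed=1)
print(f"{len(records)} list-presence records, "
      f"{len({r.keyword for r in records})} distinct keywords, "
      f"{len(set(keyword_map.values()))} exposure-source categories")

pairs = map_keywords(records, keyword_map)
matrix = build_presence_matrix(pairs)
result = filter_min_categories(matrix, min_count=2)

print(f"presence matrix: {result.matrix.shape[0]} chemicals x "
      f"{result.matrix.shape[1]} categories "
      f"({result.matrix.to_numpy().sum()} presence cells)")
print(f"removed for < 2 categories: {len(result.removed_chemicals)}")
print()
print("corner of the matrix (1 = chemical recorded in that exposure source):")
print(result.matrix.iloc[:5, :6].to_string())
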