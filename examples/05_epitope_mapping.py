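"""Map known epitopes onto query proteins: exact and similarity-based.

Exact mapping reports every (possibly overlapping) occurrence of each
database epitope in the query. Similarity mapping runs Smith-Waterman
local alignment (BLOSUM62, gap open 10 / extend 0.5) so epitopes with a
few substitutions are still found, with coordinates, score, and identity.
"""

from il17pred import Peptide, exact_map, sim_search

epitope_db = [
    Peptide("epi_exact", "LLSKGW"),
    Peptide("epi_variant", "LLSKGWNRLK"),
]
query = [Peptide("antigen", "AAPLLSKGWPAALLSKGANRLKWW")]

print("exact occurrences:")
for m in exact_map(epitope_db, query):
    print(f"  {m.epitope_id} at {m.start}..{m.end} (identity {m.identity:.0%})")

print("\nSmith-Waterman hits:")
for h in sim_search(epitope_db, query, min_score=15):
    print(
        f"  {h.epitope_id} at {h.start}..{h.end}  score={h.score:.1f}  "
        f"identity={h.identity:.0%}"
    )
    print(f"    epitope {h.aligned_epitope}")
    print(f"    query   {h.aligned_query}")

print(
    "\nThe variant epitope has no exact occurrence, but local alignment"
    "\nstill places it on the query with high identity."
)
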