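"""Homology-transferred GO vectors and functional-domain vectors.

Filters a toy BLAST hit table into a homology set, transfers the homologs'
GO annotations to the query, and switches on domain indicators from
significant conserved-domain hits.
"""

import pandas as pd

from subcell import build_homology_set, fund_vector, go_vector, is_productive

hits = pd.DataFrame(
    [
        ("query", "P10001", 82.0, 1e-40),
        ("query", "P10002", 61.0, 1e-25),
        ("query", "P10003", 58.0, 1e-20),  # below the 60% identity floor
        ("query", "P10004", 91.0, 0.5),    # E-value too weak
    ],
    columns=["qseqid", "sseqid", "pident", "evalue"],
)
hset = build_homology_set(hits, "query", identity_min=60.0, evalue_max=1e-3)
print("homology set:", sorted(hset.accessions))

annotations = {"P10001": frozenset({120, 77}), "P10002": frozenset({77, 3051})}
vec = go_vector(hset, annotations, dimension=60020)
print("transferred GO indices:", sorted(vec.nonzero_indices))
print("productive for a library containing term 77?",
      is_productive(vec, {77, 900}))

fund = fund_vector([(412, 1e-9), (9001, 0.2)], evalue_max=1e-3, dimension=17402)
print("significant domains:", sorted(fund.nonzero_indices))
# The query inherits {77, 120, 3051} from its two accepted homologs and hits
# domain 412; the weak domain hit (E = 0.2) is ignored.
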