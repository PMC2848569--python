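"""Evidential K-nearest-neighbor voting step by step.

Each neighbor contributes belief mass m({c}) = alpha * exp(-gamma_c d^2) to
its class; Dempster's rule fuses the masses; the vote goes to the class
with the largest combined belief.
"""

import numpy as np

from subcell import (
    ReferenceLibrary,
    combine_masses,
    etknn_vote,
    fit_gammas,
    neighbor_masses,
)

points = [[0.1], [0.25], [0.9], [1.0], [1.1]]
labels = [1, 1, 2, 2, 2]
library = ReferenceLibrary(
    [np.array(p) for p in points], np.array(labels),
    [f"ref{i}" for i in range(5)], "psepssm",
)
gammas = fit_gammas(library)
print("fitted per-class scales:", {c: round(g, 2) for c, g in gammas.items()})

query = np.array([0.5])
distances = library.distances_to(query)
masses = neighbor_masses(
    [(float(distances[i]), labels[i]) for i in range(3)],
    alpha=0.95, gammas=gammas,
)
beliefs = combine_masses(masses)
print("combined beliefs over 3 nearest:",
      {c: round(b, 3) for c, b in sorted(beliefs.items())})
print("K=3 vote:", etknn_vote(query, library, k=3, gammas=gammas))
# The query at 0.5 sits between the clusters; class 1's two closer
# neighbors outweigh class 2's single nearby one.
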