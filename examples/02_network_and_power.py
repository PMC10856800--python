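"""Build the signed weighted network and choose the soft threshold.

The adjacency is a_ij = ((1 + cor_ij)/2)^beta; beta is the lowest power
whose scale-free topology fit index reaches 0.90 (falling back to the best
fit when no candidate reaches it).  The topological overlap matrix (TOM)
then measures how much two features share neighbours.
"""

from metabonet import (NetworkConfig, adjacency, correlation_matrix,
                       paper_shaped_fixture, pick_soft_threshold, preprocess,
                       topological_overlap)
from metabonet.io import PreprocessConfig

table, traits, _ = paper_shaped_fixture()
table = preprocess(table, PreprocessConfig(transform="log2"))

power, fit_table, reached = pick_soft_threshold(
    table, candidate_powers=range(1, 21), target_fit=0.90)
print(fit_table.head(8).round(3).to_string(index=False))
print(f"\nchosen power: {power:g} "
      f"({'target reached' if reached else 'best available fit'})")

cor = correlation_matrix(table)
adj = adjacency(cor, NetworkConfig(power=4, network_type="signed"))
tom = topological_overlap(adj)
off = tom.values.to_numpy()[~(tom.values.to_numpy() == 1.0)]
print(f"TOM off-diagonal range: {off.min():.4f}..{off.max():.4f}, "
      f"mean {off.mean():.4f}")
# High TOM pairs are features that are both correlated and share the same
# neighbourhood; 1 - TOM is the dissimilarity clustered in the next step.
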