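# report.json schema

The JSON report written by `render_report` (and by `mibp analyze`)
mirrors the cluster-tree serialization exactly; re-rendering a parsed
report reproduces every SVG byte for byte.

Top level:

| key | type | meaning |
| --- | --- | --- |
| `sequence` | string | the RNA sequence (A/C/G/U) |
| `sequence_name` | string | FASTA identifier, may be empty |
| `n_samples` | int | number of sampled structures |
| `config` | object | tree-construction parameters (cutoff_bits, low_frac, high_frac, max_conflicting, min_node_samples, include_self, max_splits) |
| `ensemble_entropy_bits` | float | summed per-pair entropy at the root |
| `conditional_entropy_bits` | float | leaf-probability-weighted summed entropy |
| `n_leaves` | int | number of clusters |
| `root` | node | recursive node object (below) |

Written by `mibp analyze` in addition:

| key | type | meaning |
| --- | --- | --- |
| `run_config` | object | the fully resolved CLI configuration |
| `counting` | object | `log10_structures_unconstrained` / `_constrained`, exact counts as decimal strings, `n_forced`, `n_forbidden`, `retained_mass` |
| `reference` | object | present only with `--ref`: `leaf_id`, `leaf_probability` |

Node object:

| key | type | meaning |
| --- | --- | --- |
| `id` | int | preorder node identifier (`node_<id>.svg`) |
| `constraints` | list | path from the root: `{"pair": [i, j], "present": bool}` |
| `n_members` | int | samples in the cluster |
| `probability` | float | absolute mass relative to the root |
| `entropy_bits` | float | summed pair entropy of the conditional marginals |
| `mibp` | `[i, j]` or null | the node's most informative basepair |
| `mibp_mi_sum_bits` | float | its mutual-information sum |
| `conflicting_pairs` | list of `[i, j]` | greedy mutually conflicting alternatives, most probable first |
| `marginals` | list of `[i, j, p]` | node-conditional pairing probability of every candidate |
| `children` | `[present, absent]` or null | recursive; present-child first |
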