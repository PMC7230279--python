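"""Train an Auto Contractive Map and extract the semantic connectivity map.

The Auto-CM turns multivariate association into weights; the minimum
spanning tree over (1 - strength) distances shows each variable hanging
off its strongest associate, and leaf-pruning yields the central hub.
"""

from pedree import CohortConfig, generate_cohort, semantic_map
from pedree.anthropometry import FEATURE_NAMES, derive_features_frame
from pedree.synthetic import synthetic_bmi_reference, synthetic_wfl_reference

cohort = generate_cohort(CohortConfig(n=300, seed=2))
feats = derive_features_frame(cohort, synthetic_bmi_reference(),
                              synthetic_wfl_reference())

model, cmap = semantic_map(feats[FEATURE_NAMES])
print(f"converged after {model.epochs_run} epochs")
for a, b, s in sorted(cmap.edges, key=lambda e: -e[2]):
    print(f"  {a:18s} -- {b:18s} strength {s:.3f}")
print(f"central node: {cmap.central_node}")

# Strongly coupled anthropometry (weight/BMI/arm areas) clusters together;
# the central node is the variable left after recursively pruning leaves -
# the hub of the association tree.
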