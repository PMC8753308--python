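"""Run the expert-panel consensus pipeline on the packaged synthetic fixture.

The fixture reconstructs the published exercise shape: 4 panelists, a
31-variable registry (14 unique + 17 derived, 93 EX1 cells each), three
negation-phrased variables merged into existing ones, and the two reported
inconsistencies — one conformance drop and one rating-based exclusion
retained by domain-expert override.
"""

from collections import Counter

from gmfpm import build_model_from_panel, load_packaged_fixture

grids, registry, merges, overrides = load_packaged_fixture()
print(f"registry: {len(registry.variables)} variables "
      f"({registry.n_unique} unique, {registry.n_derived} derived)")
print(f"panelists: {len(grids)}, EX1 cells each: {grids[0].n_cells}")

result = build_model_from_panel(grids, registry, merges=merges, overrides=overrides)
audit = result.audit_frame()

print(f"\nbuilt model: {result.model.n_variables} variables")
print("audit statuses:", dict(Counter(s.split(':')[0] for s in audit['status'])))

print("\nnon-retained variables:")
for _, row in audit[audit["status"] != "retained"].iterrows():
    print(f"  {row['variable']:38s} {row['decision']:14s} -> {row['status']}")

print("\nThe conformance drop is the variable whose panel-assigned values were "
      "identical in all three classes despite an inclusion-level rating; the "
      "override retains Elbow Tone although its ratings (2, 2, declined, 3) "
      "excluded it by rule.")
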