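"""Load the packaged GMF phenotype model and inspect its structure.

Prints the model's shape (variables / data element concepts / domains), the
per-domain variable breakdown, and one full logic statement, showing how the
declarative rules-as-data document is exposed through the API.
"""

from gmfpm import GmfClass, load_packaged_model

model = load_packaged_model()

print(f"model: {model.name}, age band {model.age_band[0]}-{model.age_band[1]} years")
print(f"{model.n_variables} variables, {model.n_elements} data elements, "
      f"{model.n_domains} domains")
print(f"validation: {'clean' if model.validate_invariants().ok else 'ERRORS'}\n")

for domain in model.domains:
    names = [v.name for v in model.variables_in_domain(domain)]
    print(f"  {domain}: {len(names)} variables ({', '.join(names)})")

st = model.statements_for("Elbow Tone", GmfClass.C2)[0]
print("\nexample logic statement (Elbow Tone, GMF Class 2):")
print(f"  stem:      {st.stem}")
print(f"  rule:      {st.rule}")
print(f"  qualifier: {st.qualifier}")
print(f"  predicate: value in {{{', '.join(st.predicate.tokens)}}} "
      f"(provenance: {st.provenance})")

# The 20 variables split into unique (one concept) and derived (several
# concepts sharing one value-set structure).
n_unique = sum(1 for v in model.variables if v.kind == "unique")
print(f"\n{n_unique} unique and {model.n_variables - n_unique} derived variables")
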