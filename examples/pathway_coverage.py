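"""Report coumarin-biosynthesis pathway coverage from a screening run.

Screens noiseless spectra of the starter-library compounds, then checks
which intermediates of the phenylpropanoid -> coumarin pathway the
annotations cover.
"""

from coumascreen import SpectrumRecipe, default_pathway, pathway_coverage, screen_corpus, starter_library, synth_spectrum

lib = starter_library()
spectra = [
    synth_spectrum(SpectrumRecipe(compound=c, seed=i), node_id=f"n{i}")[0]
    for i, c in enumerate(lib)
]
results, _ = screen_corpus(spectra, lib)

graph = default_pathway()
report = pathway_coverage(results, graph)
print(f"pathway intermediates covered: {report.n_covered}/{len(graph.nodes)}")
print(f"  covered: {', '.join(report.covered)}")
print(f"  not covered: {', '.join(report.uncovered)}")
print(f"fully covered enzymatic steps: {len(report.covered_edges)}")
for u, v, enzyme, auth in report.covered_edges:
    tag = enzyme or "unlabeled"
    flag = "" if auth else " [unauthenticated]"
    print(f"  {u} -> {v} ({tag}){flag}")
print()
print("A step counts as covered when both its substrate and product were")
print("annotated; unauthenticated steps are proposed, not enzyme-verified.")
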