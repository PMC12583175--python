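# coumascreen

Diagnostic-ion and neutral-loss screening of **coumarins and cinnamic
acids** in untargeted, positive-mode LC-MS/MS metabolomics — with
molecular networking, in-house-library matching, and differential
statistics. Built for natural-products and metabolomics researchers who
need to annotate hundreds of MS2 nodes against a curated compound
library without re-running web platforms.

## What it does

Positive-mode coumarins fragment from the protonated molecular ion
[M+H]⁺ by sequential neutral losses — CH₃· (15.023 Da), CHO (29.003),
CO (27.995), CO₂ (43.990), C₂H₂ (26.016) — producing characteristic
fragment-ion *ladders*. Cinnamic acids lose H₂O and CO (with
[M+H−H₂O]⁺ typically more intense than [M+H−CO]⁺), plus a 15 Da CH₃
loss when methoxylated. `coumascreen` turns that chemistry into a
screening pipeline:

1. **Library matching** — precursor m/z vs the in-house library's [M+H]⁺
   values at 10 ppm; [M+H]⁺ = M + 1.0072765 (proton mass, electron
   accounted for).
2. **Diagnostic-ion confirmation** — the spectrum must contain strictly
   more than 60% of the candidate's theoretical ladder rungs
   (fragment tolerance: wider of 20 ppm / 0.01 Da).
3. **Neutral-loss class calls** — a class is called when all its
   required losses (coumarin: CH₃ + CO; cinnamic acid: H₂O + CO) are
   detected between the precursor and peaks or between peak pairs.
4. **Modification inference** — unmatched precursors are explained as a
   library base plus up to two structural-unit shifts (hexosylation
   +162.0528, methylation +14.0157, hydroxylation +15.9949,
   methoxylation +30.0106, acetylation +42.0106).
5. **Molecular networking** — modified-cosine similarity (√-intensity
   weighting, optimal one-to-one peak assignment, precursor-shift
   matching); edges above cosine 0.6 with ≥ 5 matched peaks; connected
   components are molecular families.
6. **Dimer linkage** — C–O-linked coumarin dimers show a continuous
   CH₃/CH₂/CO₂ small-loss ladder from the precursor; C–C-linked dimers
   fragment like a single coumarin unit.
7. **Differential statistics** — PCA, PLS-DA with VIP
   (VIPⱼ = √(p·Σₐ SSYₐ·w²ⱼₐ / Σₐ SSYₐ)), and volcano selection
   (FC ≥ 2, Welch p < 0.05 on log areas) intersected with VIP > 1.
8. **Pathway coverage** — which intermediates of the phenylpropanoid →
   coumarin biosynthetic route (phenylalanine/tyrosine → cinnamic acids
   → umbelliferone/scopoletin → scopolin/fraxetin/isofraxidin) a
   screening run has annotated.

A seeded synthetic-data module generates ladder spectra, decoys and
multi-group feature tables with known ground truth, so the entire
pipeline is testable without instrument data.

## Worked example

```python
from coumascreen import (adduct_mz, display_round, generate_ladder,
                         monoisotopic_mass, parse_formula,
                         SpectrumRecipe, synth_spectrum,
                         screen_spectrum, starter_library)

mh = adduct_mz(monoisotopic_mass(parse_formula("C10H8O4")))   # scopoletin
print(display_round(mh))                                      # 193.05
print(generate_ladder(mh, ["CH3", "CHO", "CO2"]).display_rungs())
# (178.03, 149.02, 105.03)

lib = starter_library()
spec, _ = synth_spectrum(SpectrumRecipe(compound=lib.get("scopoletin")))
result = screen_spectrum(spec, lib)
print(result.tier, result.best_match, result.diagnostic_score)
# library_confirmed scopoletin 1.0
```

The ladder output means: after losing CH₃· the scopoletin [M+H]⁺ at
193.05 yields the 178.03 ion, then 149.02 after CHO, then 105.03 after
CO₂ — all of the ladder is found in the synthetic spectrum, so the node
is confirmed as scopoletin at diagnostic score 1.0.

Longer narrative examples live in `examples/` (fragment ladders,
corpus screening, dimer-linkage calls, molecular networking,
differential analysis, pathway coverage); each prints its numbers with
an explanation. A thin CLI wraps the same functions:

```bash
coumascreen simulate spectra --out corpus.mgf
coumascreen screen --mgf corpus.mgf --out report.tsv
coumascreen run --mgf corpus.mgf --out results/
```

## Layout

- `src/coumascreen/chem.py` — formulas, monoisotopic masses, adducts, tolerances
- `src/coumascreen/spectra.py` — MGF and feature-table I/O, core containers
- `src/coumascreen/library.py` — in-house library build/merge/lookup (+ packaged starter library)
- `src/coumascreen/fragments.py` — loss catalog, ladders, diagnostic scoring, class & dimer calls
- `src/coumascreen/screen.py` — per-node screening pipeline and tier assignment
- `src/coumascreen/network.py` — modified cosine, families, GraphML export
- `src/coumascreen/stats.py` — PCA, PLS-DA/VIP, volcano, joint selection
- `src/coumascreen/pathway.py` — coumarin-biosynthesis graph and coverage report
- `src/coumascreen/simulate.py` — seeded synthetic spectra and feature tables
- `src/coumascreen/cli.py` — `coumascreen` command-line entry point

See `docs/methods.md` for the scientific and numerical choices.
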