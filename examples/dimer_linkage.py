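"""Discriminate C-O- from C-C-linked coumarin dimers by MS2 pattern.

A C-O-linked dimer strips small neutrals (CH3, CH2, CO2) continuously from
the precursor; a C-C-linked dimer's spectrum instead looks like a single
coumarin because the C-C bridge resists cleavage.
"""

from coumascreen import classify_dimer_linkage, generate_ladder, starter_library
from coumascreen.fragments import DIMER_SMALL_LOSS_STEPS, MONOMER_LOSS_SEQUENCES, default_loss_catalog
from coumascreen.spectra import Spectrum

catalog = default_loss_catalog()
lib = starter_library()
scopoletin_mh = lib.get("scopoletin").mh_mz

# C-O type: descending CH3 / CH2 / CO2 ladder from the precursor (413.09)
co_prec = lib.get("chimsalicifoliusin A").mh_mz
co_rungs = generate_ladder(co_prec, DIMER_SMALL_LOSS_STEPS, catalog).rungs
co_spec = Spectrum("A-type", co_prec, peaks=tuple((r, 100.0) for r in co_rungs))

# C-C type: dominant fragments reproduce the scopoletin monomer ladder (383.08)
cc_prec = lib.get("chimsalicifoliusin B").mh_mz
cc_targets = [scopoletin_mh] + list(
    generate_ladder(scopoletin_mh, MONOMER_LOSS_SEQUENCES[0], catalog).rungs
)
cc_spec = Spectrum("B-type", cc_prec, peaks=tuple((t, 100.0) for t in cc_targets))

for spec in (co_spec, cc_spec):
    call, evidence = classify_dimer_linkage(spec, [scopoletin_mh], catalog)
    print(
        f"{spec.node_id} (precursor {spec.precursor_mz:.2f}): {call} "
        f"(small-loss intensity fraction {evidence['co_fraction']:.2f}, "
        f"monomer-ladder fraction {evidence['cc_fraction']:.2f})"
    )

print()
print("The fraction >0.5 decides the call: which fragmentation regime")
print("carries most of the spectrum's intensity.")
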