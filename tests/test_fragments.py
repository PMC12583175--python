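"""Neutral-loss ladders, loss detection, diagnostic scoring, class and
dimer-linkage calls."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from coumascreen.chem import FRAGMENT_TOLERANCE, MassTolerance, adduct_mz
from coumascreen.fragments import (
    DIMER_SMALL_LOSS_STEPS,
    LossCatalog,
    MONOMER_LOSS_SEQUENCES,
    candidate_diagnostic_set,
    classify_class,
    classify_dimer_linkage,
    default_class_rules,
    default_loss_catalog,
    detect_neutral_losses,
    diagnostic_ion_score,
    generate_ladder,
)
from coumascreen.simulate import SpectrumRecipe, synth_spectrum
from coumascreen.spectra import Spectrum

SCOPOLETIN_MH = 193.0495
ISOFRAXIDIN_MH = 223.0601


def test_catalog_masses_match_compositions(catalog):
    expected = {
        "CH3": 15.02348,
        "CHO": 29.00274,
        "CO": 27.99491,
        "CO2": 43.98983,
        "C2H2": 26.01565,
        "H2O": 18.01056,
        "CH2": 14.01565,
    }
    for label, mass in expected.items():
        assert catalog.mass(label) == pytest.approx(mass, abs=1e-5)


def test_catalog_rejects_duplicate_labels(catalog):
    with pytest.raises(ValueError, match="duplicate"):
        LossCatalog(catalog.losses + (catalog.losses[0],))


def test_catalog_from_file(tmp_path, catalog):
    path = tmp_path / "losses.txt"
    path.write_text("CH3 CH3\nCO CO\n# comment\nH2O H2O\n")
    custom = LossCatalog.from_file(path)
    assert custom.labels() == ["CH3", "CO", "H2O"]
    assert custom.mass("CO") == pytest.approx(catalog.mass("CO"))


def test_isofraxidin_ladders_reproduce_printed_ions(catalog):
    # 223.06 -> 208.04 -> 179.03 -> 135.04 -> 107.05
    lad = generate_ladder(ISOFRAXIDIN_MH, ["CH3", "CHO", "CO2", "CO"], catalog)
    assert lad.display_rungs() == (208.04, 179.03, 135.04, 107.05)
    # 223.06 -> 208.04 -> 164.05 -> 149.02 -> 123.01
    lad2 = generate_ladder(ISOFRAXIDIN_MH, ["CH3", "CO2", "CH3", "C2H2"], catalog)
    assert lad2.display_rungs() == (208.04, 164.05, 149.02, 123.01)


def test_scopoletin_ladder_reproduces_printed_ions(catalog):
    lad = generate_ladder(SCOPOLETIN_MH, ["CH3", "CHO", "CO2"], catalog)
    assert lad.display_rungs() == (178.03, 149.02, 105.03)


def test_empty_ladder(catalog):
    lad = generate_ladder(SCOPOLETIN_MH, [], catalog)
    assert lad.rungs == ()


def test_ladder_error_when_losses_exceed_start(catalog):
    with pytest.raises(ValueError, match="step"):
        generate_ladder(50.0, ["CO2", "CO2"], catalog)


def test_ladder_final_rung_independent_of_step_order(catalog):
    steps = ["CH3", "CO2", "CHO", "C2H2"]
    finals = {
        round(generate_ladder(300.0, perm, catalog).rungs[-1], 9)
        for perm in itertools.permutations(steps)
    }
    assert len(finals) == 1


def test_detect_losses_precursor_to_peak(catalog):
    spec = Spectrum("n", 223.0601, peaks=((208.0366, 100.0),))
    assert set(detect_neutral_losses(spec, catalog)) == {"CH3"}


def test_detect_losses_between_fragments(catalog):
    spec = Spectrum("n", 400.0, peaks=((179.0339, 50.0), (135.0441, 40.0)))
    detected = detect_neutral_losses(spec, catalog)
    assert "CO2" in detected
    ev = detected["CO2"][0]
    assert not ev.from_precursor
    assert ev.from_mz == pytest.approx(179.0339)


def test_detect_losses_none_for_unrelated_peak(catalog):
    spec = Spectrum("n", 400.0, peaks=((123.456, 10.0),))
    assert detect_neutral_losses(spec, catalog) == {}


def test_detect_losses_agrees_with_all_pairs_oracle(catalog):
    rng = np.random.default_rng(5)
    tol = FRAGMENT_TOLERANCE
    for _ in range(50):
        n = int(rng.integers(2, 30))
        mzs = rng.uniform(50, 400, n)
        spec = Spectrum("n", 420.0, peaks=tuple(zip(mzs.tolist(), [1.0] * n)))
        detected = set(detect_neutral_losses(spec, catalog, tol))
        points = [420.0] + sorted(spec.mz.tolist())
        brute = set()
        for loss in catalog:
            for hi in points:
                for lo in spec.mz:
                    if lo < hi and abs((hi - lo) - loss.mass) <= tol.window(
                        0.5 * (lo + hi - loss.mass)
                    ):
                        brute.add(loss.label)
        assert detected == brute


def test_diagnostic_score_fraction(catalog):
    diagnostics = [100.0, 150.0, 200.0, 250.0, 300.0]
    spec = Spectrum("n", 400.0, peaks=((100.0, 1.0), (150.0, 1.0), (200.0, 1.0)))
    assert diagnostic_ion_score(spec, diagnostics) == pytest.approx(0.6)
    full = Spectrum("n", 400.0, peaks=tuple((d, 1.0) for d in diagnostics))
    assert diagnostic_ion_score(full, diagnostics) == 1.0


def test_diagnostic_score_empty_set_rejected():
    spec = Spectrum("n", 400.0, peaks=((100.0, 1.0),))
    with pytest.raises(ValueError):
        diagnostic_ion_score(spec, [])


def test_diagnostic_score_self_consistency_with_ladder(isofraxidin, catalog):
    ladder = candidate_diagnostic_set(isofraxidin.mh_mz, "coumarin", catalog)
    spec = Spectrum("n", isofraxidin.mh_mz, peaks=tuple((r, 10.0) for r in ladder))
    assert diagnostic_ion_score(spec, ladder) == 1.0


def test_diagnostic_score_monotone_in_peaks_and_tolerance(catalog):
    rng = np.random.default_rng(9)
    diagnostics = rng.uniform(100, 300, 6).tolist()
    peaks = [(float(m), 1.0) for m in rng.uniform(100, 300, 8)]
    spec = Spectrum("n", 400.0, peaks=tuple(peaks))
    more = Spectrum("n", 400.0, peaks=tuple(peaks + [(diagnostics[0], 1.0)]))
    narrow = MassTolerance(ppm=5)
    wide = MassTolerance(ppm=50)
    assert diagnostic_ion_score(more, diagnostics, narrow) >= diagnostic_ion_score(
        spec, diagnostics, narrow
    )
    assert diagnostic_ion_score(spec, diagnostics, wide) >= diagnostic_ion_score(
        spec, diagnostics, narrow
    )


def test_classify_coumarin_from_ch3_and_co_losses(catalog, rules):
    mh = 223.0601
    peaks = ((mh - catalog.mass("CH3"), 100.0), (mh - catalog.mass("CO"), 60.0))
    calls = classify_class(Spectrum("n", mh, peaks=peaks), rules, catalog)
    assert [c for c, _ in calls] == ["coumarin"]


def test_classify_cinnamic_acid_with_intensity_ordering(catalog, rules):
    mh = 181.0495  # caffeic acid [M+H]+
    peaks = ((mh - catalog.mass("H2O"), 100.0), (mh - catalog.mass("CO"), 40.0))
    calls = classify_class(Spectrum("n", mh, peaks=peaks), rules, catalog)
    assert calls[0][0] == "cinnamic_acid"
    assert "water_loss_dominates_co" in calls[0][1]["soft_features"]


def test_classify_no_call_without_catalog_losses(catalog, rules):
    spec = Spectrum("n", 300.0, peaks=((111.111, 1.0), (222.222, 1.0)))
    assert classify_class(spec, rules, catalog) == []


def test_every_library_coumarin_self_recovers_class(lib, catalog, rules):
    # a spectrum synthesized from a coumarin's own ladder scores 1.0 and
    # is called coumarin
    for compound in lib.by_class("coumarin"):
        spec, _ = synth_spectrum(SpectrumRecipe(compound=compound))
        diagnostics = candidate_diagnostic_set(compound.mh_mz, "coumarin", catalog)
        assert diagnostic_ion_score(spec, diagnostics) == 1.0
        assert "coumarin" in [c for c, _ in classify_class(spec, rules, catalog)]


def _co_linked_spectrum(catalog, precursor=413.0867):
    # descending small-loss ladder: -CH3, -(CH3+CH2), -(CH3+CH2+CO2)
    steps = DIMER_SMALL_LOSS_STEPS
    rungs = generate_ladder(precursor, steps, catalog).rungs
    return Spectrum("co", precursor, peaks=tuple((r, 100.0) for r in rungs))


def test_dimer_co_linkage(catalog):
    call, ev = classify_dimer_linkage(_co_linked_spectrum(catalog), [193.0495], catalog)
    assert call == "CO_linked"
    assert ev["co_fraction"] > 0.5


def test_dimer_cc_linkage(catalog, scopoletin):
    # dominant fragments reproduce the scopoletin-like monomer ladder region
    monomer_mh = scopoletin.mh_mz
    targets = [monomer_mh] + list(
        generate_ladder(monomer_mh, MONOMER_LOSS_SEQUENCES[0], catalog).rungs
    )
    spec = Spectrum("cc", 383.0761, peaks=tuple((t, 100.0) for t in targets))
    call, ev = classify_dimer_linkage(spec, [monomer_mh], catalog)
    assert call == "CC_linked"
    assert ev["cc_fraction"] > 0.5


def test_dimer_undetermined(catalog):
    spec = Spectrum("x", 400.0, peaks=((111.0, 50.0), (222.0, 50.0)))
    call, _ = classify_dimer_linkage(spec, [193.0495], catalog)
    assert call == "undetermined"


def test_dimer_gate_on_small_precursors(catalog):
    spec = _co_linked_spectrum(catalog, precursor=250.0)
    call, ev = classify_dimer_linkage(spec, [], catalog)
    assert call == "undetermined"
    assert "gate" in ev["reason"]
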