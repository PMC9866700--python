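"""Four-gate MS2 screening and chromatographic scan grouping."""

import numpy as np
import pytest

from chemopheno.io import MS2Scan, read_mgf
from chemopheno.screening import (
    GroupedSpectrum,
    ScreeningConfig,
    group_scans,
    match_spectrum,
    mass_tolerance,
    rt_tolerance,
    screen_run,
)


def _scan_from(record, rt=None, precursor=None, scale=1000.0):
    """A scan that is an exact copy of the record's reference spectrum."""
    mz = np.array([m for m, _r in record.fragments])
    inten = np.array([r for _m, r in record.fragments]) * scale / 100.0
    return MS2Scan(
        rt_min=record.rt_min if rt is None else rt,
        precursor_mz=record.exact_mz if precursor is None else precursor,
        mz=mz,
        intensity=inten,
    )


def test_identity_scan_passes_all_gates(library):
    rec = library[9]  # neochlorogenic acid, 10 fragments
    m = match_spectrum(_scan_from(rec), rec)
    assert m.passed
    assert m.matched_fraction == 1.0
    assert m.max_intensity_err == pytest.approx(0.0, abs=1e-9)
    assert m.precursor_ppm == pytest.approx(0.0, abs=1e-9)


def test_sparse_fragment_overlap_fails_recall_gate(library):
    rec = library[9]
    refs = [f for f in rec.fragments if f[1] >= 1]  # non-trace reference ions
    keep = refs[:3]
    scan = MS2Scan(
        rt_min=rec.rt_min,
        precursor_mz=rec.exact_mz,
        mz=np.array([m for m, _r in keep]),
        intensity=np.array([r for _m, r in keep]),
    )
    m = match_spectrum(scan, rec)
    assert m.matched_fraction == pytest.approx(3 / len(refs))
    assert m.matched_fraction < 2 / 3
    assert not m.passed


def test_da_floor_dominates_at_low_mass():
    # at m/z 100 the 15 ppm band is 0.0015 Da, above the 0.0010 Da floor;
    # a +0.0009 Da offset (9 ppm) must pass the precursor gate
    cfg = ScreeningConfig()
    assert mass_tolerance(100.0, cfg.precursor_ppm_max, cfg.precursor_da_floor) == pytest.approx(0.0015)
    assert 0.0009 < 0.0015
    # at m/z 50 the floor takes over
    assert mass_tolerance(50.0, cfg.precursor_ppm_max, cfg.precursor_da_floor) == pytest.approx(0.0010)


def test_rt_tolerance_clamps_to_band():
    cfg = ScreeningConfig()
    assert rt_tolerance(1.0, cfg) == pytest.approx(0.05)    # 2% = 0.02, floored
    assert rt_tolerance(5.0, cfg) == pytest.approx(0.10)    # inside the band
    assert rt_tolerance(12.0, cfg) == pytest.approx(0.15)   # 2% = 0.24, capped


def test_reference_spectra_without_100_percent_base_peak_still_match(library):
    """A few published fragment lists top out below 100%; matching
    renormalizes both sides to their own base peak."""
    rec = library[16]  # gentisic acid: strongest listed ion is 46.7%
    assert max(r for _m, r in rec.fragments) < 100
    m = match_spectrum(_scan_from(rec), rec)
    assert m.passed and m.max_intensity_err < 1e-9


def test_screening_recovers_planted_and_rejects_decoys(library, run_dir, low_noise_truth):
    hits = screen_run(run_dir / "S_rupestris.mgf", library)
    planted = set(
        low_noise_truth.abundance.index[low_noise_truth.abundance["S_rupestris"] > 0]
    )
    assert {h.compound_id for h in hits} >= planted
    assert all("decoy" not in h.scan.title for h in hits)


def test_empty_run_yields_no_hits(library, tmp_path):
    p = tmp_path / "empty.mgf"
    p.write_text("")
    assert screen_run(p, library) == []


def test_screening_is_order_invariant(library, run_dir):
    scans = read_mgf(run_dir / "J_pancicii.mgf")
    fwd = screen_run(scans, library)
    rev = screen_run(list(reversed(scans)), library)
    key = lambda m: (m.compound_id, m.scan.rt_min, m.scan.precursor_mz)
    assert [key(m) for m in fwd] == [key(m) for m in rev]


def test_gate_monotonicity_under_random_relaxation(library, run_dir):
    """Loosening any threshold never removes a passed match."""
    scans = read_mgf(run_dir / "S_hercynicus.mgf")
    base_cfg = ScreeningConfig()
    base = {(m.compound_id, m.scan.title) for m in screen_run(scans, library, base_cfg)}
    rng = np.random.default_rng(42)
    for _ in range(25):
        f = float(rng.uniform(1.0, 2.0))
        relaxed = {(m.compound_id, m.scan.title)
                   for m in screen_run(scans, library, base_cfg.scaled(f))}
        assert base <= relaxed


def test_grouping_weighted_mean_examples():
    s1 = MS2Scan(rt_min=5.00, precursor_mz=400.0,
                 mz=np.array([100.0000]), intensity=np.array([3000.0]))
    s2 = MS2Scan(rt_min=5.02, precursor_mz=400.0,
                 mz=np.array([100.0004]), intensity=np.array([1000.0]))
    matches = [
        match_spectrum(s, _rec_stub(), _loose_cfg()) for s in (s1, s2)
    ]
    g = group_scans(matches, rt_window=0.1)
    assert len(g.fragments) == 1
    mz, inten = g.fragments[0]
    assert mz == pytest.approx(100.0001, abs=1e-6)
    assert inten == pytest.approx(4000.0)
    # equal intensities -> arithmetic mean
    s2b = MS2Scan(rt_min=5.02, precursor_mz=400.0,
                  mz=np.array([100.0004]), intensity=np.array([3000.0]))
    g2 = group_scans([matches[0], match_spectrum(s2b, _rec_stub(), _loose_cfg())])
    assert g2.fragments[0][0] == pytest.approx(100.0002, abs=1e-7)


def _rec_stub():
    """Minimal compound record for grouping tests."""
    from chemopheno.formula import parse_formula
    from chemopheno.library import CompoundRecord

    return CompoundRecord(
        id=99, name="stub", formula=parse_formula("C20H32O8"),
        exact_mz=400.0, theoretical_mz=400.0,
        fragments=((100.0, 100.0),), rt_min=5.0,
        compound_class="flavonoid", has_standard=False,
        distribution=frozenset("A"),
    )


def _loose_cfg():
    return ScreeningConfig(fragment_ppm_max=50.0)


def test_single_scan_group_is_identity(library):
    rec = library[27]
    scan = _scan_from(rec)
    g = group_scans([match_spectrum(scan, rec)])
    assert isinstance(g, GroupedSpectrum)
    assert g.apex_rt == scan.rt_min
    assert len(g.fragments) == len(rec.fragments)
    np.testing.assert_allclose(
        sorted(m for m, _i in g.fragments), np.sort(scan.mz), atol=1e-9
    )
    assert sum(i for _m, i in g.fragments) == pytest.approx(scan.intensity.sum())


def test_grouped_mz_bounded_and_intensity_conserved(library, run_dir):
    hits = screen_run(run_dir / "S_ovatus.mgf", library)
    by_compound = {}
    for h in hits:
        by_compound.setdefault(h.compound_id, []).append(h)
    for cid, matches in by_compound.items():
        g = group_scans(matches)
        pooled = np.concatenate([m.scan.mz for m in g.members])
        total = sum(m.scan.intensity.sum() for m in g.members)
        for mz, _i in g.fragments:
            assert pooled.min() - 1e-9 <= mz <= pooled.max() + 1e-9
        assert sum(i for _m, i in g.fragments) == pytest.approx(total, rel=1e-9)


def test_group_rejects_mixed_compounds(library):
    a = match_spectrum(_scan_from(library[27]), library[27])
    b = match_spectrum(_scan_from(library[5]), library[5])
    with pytest.raises(ValueError, match="share one compound"):
        group_scans([a, b])
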