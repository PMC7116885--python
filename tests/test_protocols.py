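import numpy as np
import pytest

from fibroclefts import make_grid_2d, make_slab_3d
from fibroclefts.monodomain import ActivationMap, ConductivityField
from fibroclefts.protocols import (
    BracketError,
    detect_new_wave,
    detect_reentry,
    erp_binary_search,
    run_pes,
    run_tat_protocol,
)


def _map_with(n, events):
    amap = ActivationMap(n)
    for vertex, t in events:
        amap.add(np.array([vertex]), np.array([float(t)]))
    return amap


@pytest.fixture
def line_coords():
    return np.column_stack([np.arange(0.0, 100.0, 1.0),
                            np.zeros(100), np.zeros(100)])


def test_detect_new_wave_window_and_radius(line_coords):
    site = (0.0, 0.0, 0.0)
    # refractory tissue: no activations at all
    assert not detect_new_wave(_map_with(100, []), line_coords, site, 0.0)
    # captured beat: activation at 30 mm, 115 ms
    amap = _map_with(100, [(30, 115.0)])
    assert detect_new_wave(amap, line_coords, site, 0.0)
    # activation outside the time window
    assert not detect_new_wave(_map_with(100, [(30, 125.0)]), line_coords,
                               site, 0.0)
    # activation beyond the 4.2 cm radius
    assert not detect_new_wave(_map_with(100, [(50, 115.0)]), line_coords,
                               site, 0.0)


def test_detect_reentry_cases(line_coords):
    site = (0.0, 0.0, 0.0)
    # single outward wave, everything early
    early = _map_with(100, [(5, 20.0), (9, 50.0)])
    assert not detect_reentry(early, line_coords, site, 0.0)
    # late re-activation at the site
    assert detect_reentry(_map_with(100, [(5, 400.0)]), line_coords, site, 0.0)
    # late activation outside the 1 cm radius does not count
    assert not detect_reentry(_map_with(100, [(15, 400.0)]), line_coords,
                              site, 0.0)


def test_erp_bisection_against_threshold_oracles():
    calls = []

    def oracle(threshold):
        def runner(ci):
            calls.append(ci)
            return ci >= threshold
        return runner

    assert erp_binary_search(oracle(310.0), (200, 450), 10) == (300.0, 310.0)
    assert erp_binary_search(oracle(450.0), (200, 450), 10) == (440.0, 450.0)
    assert erp_binary_search(oracle(201.0), (200, 450), 10) == (200.0, 210.0)
    # every probe stays on the coupling-interval grid
    assert all(c == round(c / 10) * 10 for c in calls if c not in (200, 450))


def test_erp_bisection_bracket_errors():
    with pytest.raises(BracketError, match="capture at the lower bound"):
        erp_binary_search(lambda ci: True, (200, 450), 10)
    with pytest.raises(BracketError, match="no capture at the upper bound"):
        erp_binary_search(lambda ci: False, (200, 450), 10)


def test_pes_control_mesh_runs_out_without_reentry(ms_model):
    mesh = make_grid_2d(20, 0.5)
    out = run_pes(
        mesh,
        ConductivityField.isotropic(1.0),
        (5.0, 5.0, 0.0),
        ms_model,
        new_wave_window=(5.0, 50.0),
    )
    assert out.beats_delivered == 3  # all extrastimuli delivered, no reentry
    assert not out.reentry and out.reentry_beat is None
    lo, hi = out.erp_bracket
    assert 200.0 <= lo < hi <= 450.0
    assert hi - lo == pytest.approx(10.0)
    assert len(out.brackets) == 3


def test_pes_rejects_short_observation(ms_model):
    mesh = make_grid_2d(4, 0.5)
    with pytest.raises(ValueError, match="horizon"):
        run_pes(mesh, ConductivityField.isotropic(1.0), (1.0, 1.0, 0.0),
                ms_model, observe_ms=200.0)


def test_tat_control_matches_transmural_transit(ms_model):
    slab = make_slab_3d((8.0, 8.0, 4.0), 0.8)
    rec = run_tat_protocol(
        slab, ConductivityField.isotropic(1.0), (4.0, 4.0, 0.0),
        (4.0, 4.0, 4.0), ms_model, stim_radius=1.5,
    )
    assert rec.coupling_intervals == [600.0, 350.0, 270.0]
    assert len(rec.tat) == 3
    assert all(np.isfinite(t) for t in rec.tat)
    # a 4 mm wall at a few tens of cm/s: transit in the tens of ms
    assert 5.0 < rec.tat[0] < 60.0
    # rate-dependent slowing: the premature beats are never faster
    assert rec.tat[1] >= rec.tat[0] - 1.0
    assert rec.tat[2] >= rec.tat[1] - 1.0


def test_tat_warns_when_site_unreachable(ms_model):
    # conductivity so low the wave dies before crossing the slab
    slab = make_slab_3d((8.0, 8.0, 4.0), 0.8)
    with pytest.warns(UserWarning, match="never activated"):
        rec = run_tat_protocol(
            slab, ConductivityField.isotropic(0.001), (4.0, 4.0, 0.0),
            (4.0, 4.0, 4.0), ms_model, stim_radius=1.5,
        )
    assert any(np.isnan(t) for t in rec.tat)
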