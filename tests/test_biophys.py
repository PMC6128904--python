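"""Compartmental model: stability, synaptic responses, rebound, and
point-source extracellular potentials."""

import numpy as np
import pytest

from thetalab import cfc
from thetalab.biophys import (
    CellModel,
    LFPProbe,
    SimResult,
    SynapseSpec,
    csd_of_simulation,
    extracellular_potential,
    olm_train,
    poisson_train,
    simulate,
)
from thetalab.csd import band_csd_amplitude


@pytest.fixture(scope="module")
def resting():
    model = CellModel()
    return model, simulate(model, [], 0.8)


def hold_at(model, target=-65.0):
    """Somatic holding current that keeps the resting potential at target."""
    lo, hi = -0.05, 0.15

    def rest(i):
        inj = np.zeros(model.n_comp)
        inj[0] = i
        return simulate(model, [], 0.4, i_inj=inj).v[0, -1], inj

    for _ in range(20):
        mid = (lo + hi) / 2
        v, inj = rest(mid)
        if abs(v - target) < 0.05:
            return inj
        if v < target:
            lo = mid
        else:
            hi = mid
    return inj


class TestDynamics:
    def test_resting_stability(self, resting):
        _, res = resting
        dt = res.t[1] - res.t[0]
        late = res.v[:, res.t > 500.0]
        assert np.max(np.abs(np.diff(late, axis=1))) / dt < 0.01  # mV/ms
        assert np.all(late[:, -1] > -75) and np.all(late[:, -1] < -55)

    def test_single_excitatory_event_transient(self):
        model = CellModel()
        res = simulate(model, [(SynapseSpec.excitatory(model.distal_index), [0.3])], 0.9)
        pre = res.v[0][(res.t > 280) & (res.t < 298)].mean()
        assert res.v[0][(res.t > 300) & (res.t < 340)].max() > pre + 1.0
        # returns to rest
        assert res.v[0][res.t > 800].mean() == pytest.approx(pre, abs=1.0)

    def test_dt_refinement_changes_peak_vm_little(self):
        model = CellModel()
        inputs = [(SynapseSpec.olm(model.distal_index), olm_train(7.0, 0.4, events_per_cycle=5))]
        coarse = simulate(model, inputs, 0.4, dt=0.025, record_stride=1)
        fine = simulate(model, inputs, 0.4, dt=0.0125, record_stride=2)
        span = np.ptp(coarse.v[0])
        assert abs(coarse.v[0].min() - fine.v[0].min()) < 0.01 * max(span, 1.0)

    def test_event_beyond_duration_raises(self):
        model = CellModel()
        with pytest.raises(ValueError, match="beyond"):
            simulate(model, [(SynapseSpec.olm(model.distal_index), [2.0])], 1.0)

    def test_large_dt_raises(self):
        with pytest.raises(ValueError, match="dt"):
            simulate(CellModel(), [], 0.1, dt=0.1)


class TestRebound:
    def test_ih_knockout_monotonically_reduces_rebound(self):
        """Post-inhibitory rebound grows with the Ih conductance when the
        resting potential is held fixed by a somatic holding current."""
        rebounds = []
        for gih in [0.0, 0.005, 0.01]:
            model = CellModel()
            model.channels["ih"]["g_soma_uS"] = gih
            model.channels["ih"]["g_distal_uS"] = gih
            inj = hold_at(model, -65.0)
            burst = olm_train(7.0, 0.35, events_per_cycle=10, start=0.3)
            res = simulate(
                model, [(SynapseSpec.olm(model.distal_index), burst)] * 10,
                0.6, i_inj=inj,
            )
            v = res.v[0]
            pre = v[(res.t > 280) & (res.t < 298)].mean()
            post = v[(res.t > 335) & (res.t < 450)].max()
            rebounds.append(post - pre)
        assert rebounds[0] < rebounds[1] < rebounds[2]
        assert rebounds[2] > 0.5  # full Ih produces a clear rebound

    def test_rhythmic_inhibition_phase_locks_rebound(self):
        """7 Hz OLM bursts entrain theta-periodic membrane-potential peaks."""
        model = CellModel()
        res = simulate(
            model,
            [(SynapseSpec.olm(model.distal_index), olm_train(7.0, 1.0, events_per_cycle=10))] * 10,
            1.0,
        )
        v = res.v[0][res.t > 200]
        dt = res.t[1] - res.t[0]
        fs = 1e3 / dt
        spec = np.abs(np.fft.rfft(v - v.mean())) ** 2
        freqs = np.fft.rfftfreq(len(v), 1 / fs)
        peak = freqs[(freqs > 2) & (freqs < 20)][
            np.argmax(spec[(freqs > 2) & (freqs < 20)])
        ]
        assert peak == pytest.approx(7.0, abs=1.0)


class TestExtracellular:
    def test_point_source_closed_form(self):
        """1 nA at 100 µm in sigma = 0.3 S/m gives ~2.65 µV."""
        model = CellModel(n_dend=1)
        res = SimResult(
            t=np.array([0.0]),
            v=np.zeros((2, 1)),
            i_membrane=np.array([[1.0], [0.0]]),  # 1 nA at the soma
            model=model,
        )
        probe = LFPProbe(positions=((100.0, 0.0, 0.0),), sigma=0.3)
        phi = extracellular_potential(res, probe)
        expected = 1e3 / (4 * np.pi * 0.3 * 100.0)
        assert phi[0, 0] == pytest.approx(expected, rel=1e-9)
        assert expected == pytest.approx(2.65, abs=0.01)

    def test_inverse_distance_decay(self):
        model = CellModel(n_dend=1)
        res = SimResult(
            t=np.array([0.0]), v=np.zeros((2, 1)),
            i_membrane=np.array([[1.0], [0.0]]), model=model,
        )
        near = extracellular_potential(res, LFPProbe(positions=((100.0, 0.0, 0.0),)))
        far = extracellular_potential(res, LFPProbe(positions=((200.0, 0.0, 0.0),)))
        assert near[0, 0] == pytest.approx(2 * far[0, 0], rel=1e-9)

    def test_electrode_on_compartment_raises(self):
        model = CellModel()
        res = simulate(model, [], 0.05)
        with pytest.raises(ValueError, match="coincides"):
            extracellular_potential(res, LFPProbe(positions=((0.0, 0.0, 0.0),)))

    def test_charge_bookkeeping(self):
        """Total membrane current is ~0 at every step (dipolar source)."""
        model = CellModel()
        res = simulate(
            model,
            [(SynapseSpec.olm(model.distal_index), olm_train(7.0, 0.5, events_per_cycle=10))] * 10,
            0.5,
        )
        net = np.abs(res.i_membrane.sum(axis=0))
        assert net.max() < 0.01 * np.abs(res.i_membrane).max()


@pytest.fixture(scope="module")
def olm_driven():
    """Theta-rhythmic OLM inhibition on a cell held at a realistic operating
    point by aperiodic background excitation."""
    model = CellModel()
    olm = olm_train(7.0, 2.0, events_per_cycle=10)
    exc = poisson_train(12.0, 2.0, seed=5)
    inputs = [(SynapseSpec.olm(model.distal_index), olm)] * 10 + [
        (SynapseSpec.excitatory(5), exc)
    ]
    return model, simulate(model, inputs, 2.0)


class TestLaminarThetaSource:
    def test_perisomatic_theta_dominates_distal(self, olm_driven):
        _, res = olm_driven
        dt = res.t[1] - res.t[0]
        fs = 1e3 / dt
        probe = LFPProbe(positions=((50.0, 0.0, 0.0), (50.0, 0.0, 165.0)))
        pots = extracellular_potential(res, probe)
        start = int(0.2 * fs)
        peri = np.std(cfc.bandpass(pots[0][start:], fs, 5.0, 9.0))
        distal = np.std(cfc.bandpass(pots[1][start:], fs, 5.0, 9.0))
        assert peri > distal

    def test_csd_source_at_perisomatic_channel(self, olm_driven):
        _, res = olm_driven
        dt = res.t[1] - res.t[0]
        fs = 1e3 / dt
        cmap, zs = csd_of_simulation(res)
        amp = band_csd_amplitude(cmap, (5.0, 9.0), fs)
        depths = cmap.depths + zs[0]
        assert abs(depths[np.argmax(amp)]) <= 25.0  # at/next to the soma
        # an attenuated secondary source sits at the distal (SLM-like) end
        distal_amp = amp[np.argmax(depths >= 140.0)]
        assert 0 < distal_amp < amp.max()

    def test_passive_no_input_zero_csd(self):
        model = CellModel()
        res = simulate(model, [], 0.4)
        dt = res.t[1] - res.t[0]
        cmap, _ = csd_of_simulation(res)
        late = cmap.csd[:, res.t > 300]
        assert np.max(np.abs(late - late.mean(axis=1, keepdims=True))) < 1e-6

    def test_distal_excitation_makes_distal_sink(self):
        """Strong distal excitatory drive turns the distal compartment into
        a current sink (net inward membrane current while the synapse is
        active) — oracle: the sign of the distal compartment current."""
        model = CellModel()
        events = np.arange(0.2, 0.4, 0.005)
        res = simulate(model, [(SynapseSpec.excitatory(model.distal_index), events)], 0.5)
        active = (res.t > 200) & (res.t < 400)
        assert res.i_membrane[model.distal_index, active].mean() < 0

    def test_too_few_electrodes_raises(self, olm_driven):
        _, res = olm_driven
        with pytest.raises(ValueError, match="at least 3"):
            csd_of_simulation(res, n_electrodes=2)
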