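from collections import deque

import numpy as np
import pytest
import scipy.ndimage as ndi
from hypothesis import given, settings
from hypothesis import strategies as st

from simscope import simio
from simscope.microscope import (_blur, default_illumination,
                                 simulate_multichannel_sequence, simulate_raw_set)
from simscope.model import FRAMES_PER_SET, FrameRecord
from simscope.phantoms import make_phantom
from simscope.reconstruction import ReconSettings, reconstruct_set
from simscope.stream import (HEADER_SIZE, FrameMessageError, RingBuffer,
                             RingBufferEmpty, SetAssembler, apply_registration,
                             decode_frame_message, encode_frame_message,
                             estimate_registration_affine, group_into_sets,
                             run_live_pipeline, serve_stream, socket_source)


def _frame(i, channel=0, shape=(16, 16)):
    img = np.full(shape, i, dtype=np.uint16)
    return FrameRecord(image=img, channel_id=channel, sequence_index=i,
                       angle_index=(i % 9) // 3, phase_index=(i % 9) % 3,
                       timestamp_ns=1000 + i)


class TestWireProtocol:
    def test_roundtrip_bit_exact(self, rng):
        img = rng.integers(0, 0xFFFF, (64, 64), dtype=np.uint16)
        f = FrameRecord(image=img, channel_id=2, sequence_index=12345,
                        angle_index=1, phase_index=2, timestamp_ns=987654321)
        g = decode_frame_message(encode_frame_message(f))
        assert np.array_equal(f.image, g.image)
        assert (g.channel_id, g.sequence_index, g.angle_index, g.phase_index,
                g.timestamp_ns) == (2, 12345, 1, 2, 987654321)

    def test_payload_size_512(self):
        msg = encode_frame_message(_frame(0, shape=(512, 512)))
        assert len(msg) - HEADER_SIZE == 2 * 512 * 512  # 524,288 bytes

    def test_truncated_payload_rejected(self):
        msg = encode_frame_message(_frame(0))
        with pytest.raises(FrameMessageError, match="length"):
            decode_frame_message(msg[:-1])

    def test_bad_magic_rejected(self):
        msg = bytearray(encode_frame_message(_frame(0)))
        msg[0] = ord("X")
        with pytest.raises(FrameMessageError, match="magic"):
            decode_frame_message(bytes(msg))

    def test_bad_version_rejected(self):
        msg = bytearray(encode_frame_message(_frame(0)))
        msg[4] = 99
        with pytest.raises(FrameMessageError, match="version"):
            decode_frame_message(bytes(msg))


class TestGrouping:
    def test_two_complete_sets(self):
        asm = SetAssembler()
        sets = list(group_into_sets((_frame(i) for i in range(18)), asm))
        assert len(sets) == 2
        assert asm.sets_dropped == 0 and asm.frames_discarded == 0

    def test_missing_frame_drops_first_set_only(self):
        frames = [_frame(i) for i in range(18) if i != 7]
        asm = SetAssembler()
        sets = list(group_into_sets(frames, asm))
        assert len(sets) == 1
        assert asm.sets_dropped == 1
        assert np.all(sets[0].frames[0] == 9)  # the second set survived

    def test_interleaved_channels_independent(self):
        frames = []
        for i in range(9):
            frames.append(_frame(i, channel=0))
            frames.append(_frame(i, channel=1))
        sets = list(group_into_sets(frames))
        assert len(sets) == 2
        assert {s.channel_id for s in sets} == {0, 1}

    def test_set_timestamps_recorded(self):
        sets = list(group_into_sets(_frame(i) for i in range(9)))
        assert sets[0].meta["first_timestamp_ns"] == 1000
        assert list(sets[0].timestamps_ns) == [1000 + i for i in range(9)]


class TestRingBuffer:
    def test_overflow_evicts_oldest(self):
        rb = RingBuffer(2)
        for x in "abc":
            rb.push(x)
        assert rb.pop() == "b" and rb.pop() == "c"
        assert rb.drop_count == 1

    def test_pop_empty_signals(self):
        with pytest.raises(RingBufferEmpty):
            RingBuffer(1).pop()

    def test_invalid_capacity(self):
        with pytest.raises(ValueError):
            RingBuffer(0)

    @settings(deadline=None, max_examples=30)
    @given(st.lists(st.one_of(st.integers(0, 1000), st.none()), min_size=1,
                    max_size=400),
           st.integers(min_value=1, max_value=8))
    def test_conservation_against_deque_oracle(self, ops, capacity):
        rb = RingBuffer(capacity)
        oracle: deque = deque(maxlen=capacity)
        for op in ops:
            if op is None:
                try:
                    got = rb.pop()
                except RingBufferEmpty:
                    assert not oracle
                else:
                    assert got == oracle.popleft()
            else:
                rb.push(op)
                oracle.append(op)
            assert rb.pushed == rb.delivered + rb.drop_count + rb.occupancy
            assert list(rb._items) == list(oracle)


@pytest.fixture(scope="module")
def bead_field(otf256=None):
    from simscope.optics import OtfModel
    otf = OtfModel(na=1.33, em_wavelength=0.515, pixel_size=0.08,
                   grid_shape=(256, 256))
    ph = make_phantom("bead_clusters", (256, 256), seed=5, n_clusters=10,
                      beads_per_cluster=1, cluster_sigma_px=0)
    return _blur(ph.image, otf.otf_grid())


class TestRegistration:
    def test_identity(self, bead_field):
        t = estimate_registration_affine(bead_field, bead_field)
        assert np.allclose(t.matrix, np.eye(2), atol=1e-6)
        assert np.allclose(t.translation, 0.0, atol=1e-6)
        assert t.rms_residual < 1e-6

    def test_known_shift_recovered(self, bead_field):
        mov = np.fft.ifftn(ndi.fourier_shift(np.fft.fftn(bead_field),
                                             (3.0, -1.5))).real
        t = estimate_registration_affine(bead_field, mov)
        assert np.max(np.abs(t.translation - [3.0, -1.5])) < 0.05
        assert np.max(np.abs(t.matrix - np.eye(2))) < 1e-3

    def test_rotation_plus_shift_recovered(self, bead_field):
        th = np.radians(0.5)
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        c = np.array([128.0, 128.0])
        off = c - R @ c + np.array([2.0, 1.0])
        mov = ndi.affine_transform(bead_field, R, offset=off, order=3)
        t = estimate_registration_affine(bead_field, mov)
        # compare the fitted ref->mov map against the analytic inverse warp
        Rinv = np.linalg.inv(R)
        pts = np.array([[60, 60], [60, 200], [200, 60], [200, 200]], float)
        true_map = (pts - off) @ Rinv.T
        est_map = pts @ t.matrix.T + t.translation
        assert np.max(np.abs(true_map - est_map)) < 0.05
        assert t.rms_residual < 0.05

    def test_too_few_beads(self):
        blank = np.zeros((128, 128))
        with pytest.raises(ValueError):
            estimate_registration_affine(blank, blank)

    def test_registration_reduces_interchannel_offset(self, bead_field):
        from skimage.registration import phase_cross_correlation
        mov = np.fft.ifftn(ndi.fourier_shift(np.fft.fftn(bead_field),
                                             (2.0, 1.0))).real
        t = estimate_registration_affine(bead_field, mov)
        aligned = apply_registration(mov, t)
        resid, _, _ = phase_cross_correlation(bead_field, aligned,
                                              upsample_factor=50,
                                              normalization=None)
        assert np.max(np.abs(resid)) < 0.2


@pytest.fixture(scope="module")
def small_scene():
    from simscope.optics import OtfModel
    otf = OtfModel(na=1.33, em_wavelength=0.515, pixel_size=0.08,
                   grid_shape=(128, 128))
    ph = make_phantom("bead_clusters", (128, 128), seed=2, n_clusters=15,
                      beads_per_cluster=3)
    illum = default_illumination(otf, k_fraction=0.7, modulation=0.9)
    return otf, ph, illum


class TestLivePipeline:
    def _stream(self, small_scene, n_sets, as_bytes=True):
        otf, ph, illum = small_scene
        frames = list(simulate_multichannel_sequence([ph], [illum], [otf], n_sets,
                                                     seed=1))
        return [encode_frame_message(f) if as_bytes else f for f in frames]

    def test_twenty_sets_no_drops(self, small_scene):
        otf, _, illum = small_scene
        msgs = self._stream(small_scene, 20)
        outputs = []
        rep = run_live_pipeline(msgs, {0: illum}, {0: otf}, sink=outputs.append,
                                ring_capacity=8, clock_ns=lambda: 0)
        assert rep.reconstructed == 20
        assert rep.sets_dropped_in_ring == 0
        assert len(outputs) == 20

    def test_slow_consumer_drops_oldest_never_stalls(self, small_scene):
        otf, _, illum = small_scene
        msgs = self._stream(small_scene, 8)
        outputs = []
        rep = run_live_pipeline(msgs, {0: illum}, {0: otf}, sink=outputs.append,
                                ring_capacity=3, drain_interval=100,
                                clock_ns=lambda: 0)
        assert rep.reconstructed == 3  # only the newest capacity-sized backlog
        assert rep.sets_dropped_in_ring == 5
        # newest sets survive
        assert outputs[-1].timestamp_ns > outputs[0].timestamp_ns

    def test_frame_conservation(self, small_scene):
        otf, _, illum = small_scene
        msgs = self._stream(small_scene, 6)
        rep = run_live_pipeline(msgs, {0: illum}, {0: otf}, ring_capacity=2,
                                drain_interval=100, clock_ns=lambda: 0)
        asm = rep.assembler
        total_frames = len(msgs)
        assert total_frames == (FRAMES_PER_SET * (rep.reconstructed
                                                  + rep.sets_dropped_in_ring)
                                + asm.frames_discarded)

    def test_missing_parameters_refused(self, small_scene):
        otf, _, illum = small_scene
        msgs = self._stream(small_scene, 1)
        with pytest.raises(ValueError, match="no reconstruction parameters"):
            run_live_pipeline(msgs, {}, {}, clock_ns=lambda: 0)

    def test_live_equals_offline_bit_for_bit(self, small_scene, tmp_path):
        otf, _, illum = small_scene
        msgs = self._stream(small_scene, 3)
        outputs = []
        rep = run_live_pipeline(msgs, {0: illum}, {0: otf}, sink=outputs.append,
                                archive=True, clock_ns=lambda: 0)
        path = tmp_path / "archive.tif"
        simio.write_raw_stack(path, rep.archived_sets)
        offline_sets = simio.read_raw_stack(path)
        assert len(offline_sets) == 3
        for live, raw in zip(outputs, offline_sets):
            sim, _ = reconstruct_set(raw, illum, otf, ReconSettings())
            assert np.array_equal(live.image, sim)

    def test_latency_uses_injected_clock(self, small_scene):
        otf, _, illum = small_scene
        msgs = self._stream(small_scene, 2)
        ticks = iter(range(10 ** 9, 10 ** 10, 10 ** 6))
        rep = run_live_pipeline(msgs, {0: illum}, {0: otf},
                                clock_ns=lambda: next(ticks))
        assert rep.latency_ms_summary["n"] == 2
        assert all(lat > 0 for lat in rep.latencies_ns)


class TestSockets:
    def test_tcp_roundtrip_multilink(self, small_scene):
        otf, _, illum = small_scene
        msgs = self._encode(small_scene, 2)
        host, port, thread = serve_stream(msgs, n_links=2)
        received = list(socket_source(host, port, n_links=2))
        thread.join(timeout=10)
        assert len(received) == len(msgs)
        outputs = []
        rep = run_live_pipeline(received, {0: illum}, {0: otf},
                                sink=outputs.append, clock_ns=lambda: 0)
        assert rep.reconstructed == 2

    def _encode(self, small_scene, n_sets):
        otf, ph, illum = small_scene
        frames = list(simulate_multichannel_sequence([ph], [illum], [otf], n_sets,
                                                     seed=1))
        return [encode_frame_message(f) for f in frames]
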