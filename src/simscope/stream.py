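"""Real-time plumbing: wire protocol, set assembly, ring buffers, channel
registration and the live reconstruction loop.

The wire format is a fixed little-endian header followed by the raw pixel
payload (2 bytes per pixel, row-major, unsigned 16-bit)::

    magic 'SIMF' | version u8 | width u16 | height u16 | channel u8 |
    sequence u32 | angle u8 | phase u8 | timestamp_ns u64 | payload

Transport is length-prefixed messages over TCP; multiple sockets may feed
one logical stream and are reassembled by sequence index.  The default test
path is in-process (no sockets).
"""

from __future__ import annotations

import socket
import struct
import threading
import time
from collections import deque
from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator, Sequence

import numpy as np
import scipy.ndimage as ndi
from skimage import measure
from skimage.registration import phase_cross_correlation

from simscope.model import (FRAMES_PER_SET, N_PHASES, FrameRecord,
                            IlluminationParams, RawSimSet)
from simscope.optics import OtfModel
from simscope.reconstruction import ReconSettings, reconstruct_set

__all__ = [
    "FrameMessageError",
    "RegistrationTransform",
    "RingBuffer",
    "RingBufferEmpty",
    "SetAssembler",
    "apply_registration",
    "decode_frame_message",
    "detect_bead_centroids",
    "encode_frame_message",
    "estimate_registration_affine",
    "group_into_sets",
    "run_live_pipeline",
    "serve_stream",
    "socket_source",
]

MAGIC = b"SIMF"
VERSION = 1
_HEADER = struct.Struct("<4sBHHBIBBQ")
HEADER_SIZE = _HEADER.size


class FrameMessageError(ValueError):
    pass


def encode_frame_message(frame: FrameRecord) -> bytes:
    """Serialize a frame to wire bytes (header + u16-LE pixel payload)."""
    img = np.ascontiguousarray(frame.image, dtype="<u2")
    h, w = img.shape
    header = _HEADER.pack(MAGIC, VERSION, w, h, frame.channel_id,
                          frame.sequence_index, frame.angle_index,
                          frame.phase_index, frame.timestamp_ns)
    return header + img.tobytes()


def decode_frame_message(data: bytes) -> FrameRecord:
    """Parse wire bytes; bit-exact inverse of :func:`encode_frame_message`."""
    if len(data) < HEADER_SIZE:
        raise FrameMessageError(f"message too short: {len(data)} bytes")
    magic, version, w, h, channel, seq, angle, phase, ts = _HEADER.unpack_from(data)
    if magic != MAGIC:
        raise FrameMessageError(f"bad magic {magic!r}")
    if version != VERSION:
        raise FrameMessageError(f"unsupported version {version}")
    expected = HEADER_SIZE + 2 * w * h
    if len(data) != expected:
        raise FrameMessageError(
            f"payload length mismatch: got {len(data)} bytes, expected {expected}")
    img = np.frombuffer(data, dtype="<u2", offset=HEADER_SIZE).reshape(h, w)
    return FrameRecord(image=img.copy(), channel_id=channel, sequence_index=seq,
                       angle_index=angle, phase_index=phase, timestamp_ns=ts)


@dataclass
class SetAssembler:
    """Groups a per-channel message stream into complete 9-frame sets.

    A set starts only at (angle 0, phase 0) with consecutive sequence
    indices; on a gap or ordering violation the partial set is discarded and
    counted.
    """

    sets_emitted: int = 0
    sets_dropped: int = 0
    frames_discarded: int = 0
    _buffers: dict[int, list[FrameRecord]] = field(default_factory=dict)
    _expected_seq: dict[int, int | None] = field(default_factory=dict)

    def _discard(self, channel: int) -> None:
        buf = self._buffers.get(channel, [])
        if buf:
            self.frames_discarded += len(buf)
            self.sets_dropped += 1
            self._buffers[channel] = []
        self._expected_seq[channel] = None

    def push(self, frame: FrameRecord) -> RawSimSet | None:
        ch = frame.channel_id
        buf = self._buffers.setdefault(ch, [])
        expected = self._expected_seq.setdefault(ch, None)
        if buf and (expected is None or frame.sequence_index != expected):
            self._discard(ch)
            buf = self._buffers[ch]
        pos = len(buf)
        if not buf and (frame.angle_index != 0 or frame.phase_index != 0):
            self.frames_discarded += 1  # stray mid-set frame, no partial to drop
            return None
        if (frame.angle_index, frame.phase_index) != (pos // N_PHASES, pos % N_PHASES):
            self._discard(ch)
            self.frames_discarded += 1
            return None
        buf.append(frame)
        self._expected_seq[ch] = frame.sequence_index + 1
        if len(buf) == FRAMES_PER_SET:
            frames = np.stack([f.image for f in buf])
            ts = np.asarray([f.timestamp_ns for f in buf], dtype=np.int64)
            self._buffers[ch] = []
            self._expected_seq[ch] = frame.sequence_index + 1
            self.sets_emitted += 1
            return RawSimSet(frames=frames, channel_id=ch, timestamps_ns=ts,
                             meta={"first_timestamp_ns": int(ts[0])})
        return None


def group_into_sets(messages: Iterable[FrameRecord],
                    assembler: SetAssembler | None = None) -> Iterator[RawSimSet]:
    """Stream adaptor over :class:`SetAssembler`; channels are independent."""
    assembler = assembler if assembler is not None else SetAssembler()
    for msg in messages:
        out = assembler.push(msg)
        if out is not None:
            yield out


class RingBufferEmpty(IndexError):
    pass


class RingBuffer:
    """Fixed-capacity FIFO that never blocks the producer.

    On overflow the oldest item is evicted and counted.  The conservation
    invariant ``pushed == delivered + dropped + occupancy`` always holds.
    """

    def __init__(self, capacity: int):
        if capacity < 1:
            raise ValueError("capacity must be >= 1")
        self.capacity = capacity
        self._items: deque = deque()
        self.pushed = 0
        self.delivered = 0
        self.drop_count = 0

    @property
    def occupancy(self) -> int:
        return len(self._items)

    def push(self, item) -> None:
        if len(self._items) >= self.capacity:
            self._items.popleft()
            self.drop_count += 1
        self._items.append(item)
        self.pushed += 1

    def pop(self):
        if not self._items:
            raise RingBufferEmpty("ring buffer is empty")
        self.delivered += 1
        return self._items.popleft()


@dataclass
class RegistrationTransform:
    """Affine map from reference-image coordinates to moving-image coordinates
    (row, col convention); the reference channel's transform is identity.
    """

    matrix: np.ndarray  # (2, 2)
    translation: np.ndarray  # (2,)
    rms_residual: float = 0.0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float).reshape(2, 2)
        self.translation = np.asarray(self.translation, dtype=float).reshape(2)
        if abs(np.linalg.det(self.matrix)) < 1e-12:
            raise ValueError("registration matrix must be invertible")

    @classmethod
    def identity(cls) -> "RegistrationTransform":
        return cls(matrix=np.eye(2), translation=np.zeros(2))


def detect_bead_centroids(image: np.ndarray, threshold_rel: float = 0.3,
                          min_area: int = 2) -> np.ndarray:
    """Intensity-weighted centroids of bright blobs, as (row, col)."""
    img = np.asarray(image, dtype=float)
    thr = img.min() + threshold_rel * (img.max() - img.min())
    labels = measure.label(img > thr)
    props = measure.regionprops(labels, intensity_image=img)
    return np.asarray([p.centroid_weighted for p in props if p.area >= min_area],
                      dtype=float).reshape(-1, 2)


def estimate_registration_affine(reference: np.ndarray, moving: np.ndarray, *,
                                 threshold_rel: float = 0.3,
                                 match_radius_px: float = 5.0) -> RegistrationTransform:
    """Least-squares affine registration on matched bead centroids.

    Centroids are matched nearest-neighbour after removing the coarse global
    shift (phase correlation).  Requires ≥ 3 non-collinear matches.
    """
    ref_pts = detect_bead_centroids(reference, threshold_rel)
    mov_pts = detect_bead_centroids(moving, threshold_rel)
    if len(ref_pts) < 3 or len(mov_pts) < 3:
        raise ValueError(
            f"need >= 3 beads in both images (found {len(ref_pts)}/{len(mov_pts)})")
    coarse, _, _ = phase_cross_correlation(reference, moving, upsample_factor=10,
                                           normalization=None)
    # per-bead sub-pixel displacement by patch phase correlation (centroids
    # alone carry threshold/pixelation bias of ~0.1 px)
    win = 10
    pairs_ref, pairs_mov = [], []
    for rp in ref_pts:
        others = ref_pts[np.any(ref_pts != rp, axis=1)]
        if len(others) and np.min(np.linalg.norm(others - rp, axis=1)) < 1.5 * win:
            continue  # neighbour would contaminate the correlation patch
        guess = rp - coarse
        d = np.linalg.norm(mov_pts - guess, axis=1)
        if d.min() > match_radius_px:
            continue
        r0 = np.round(rp).astype(int)
        m0 = np.round(guess).astype(int)
        if (np.any(r0 - win < 0) or np.any(m0 - win < 0)
                or np.any(r0 + win + 1 > np.asarray(reference.shape))
                or np.any(m0 + win + 1 > np.asarray(moving.shape))):
            continue
        ref_patch = reference[r0[0] - win:r0[0] + win + 1, r0[1] - win:r0[1] + win + 1]
        mov_patch = moving[m0[0] - win:m0[0] + win + 1, m0[1] - win:m0[1] + win + 1]
        local, _, _ = phase_cross_correlation(ref_patch, mov_patch,
                                              upsample_factor=100,
                                              normalization=None)
        pairs_ref.append(rp)
        pairs_mov.append(rp + (m0 - r0) - local)
    if len(pairs_ref) < 3:
        raise ValueError(f"only {len(pairs_ref)} centroid matches; need >= 3")
    R = np.asarray(pairs_ref)
    Mv = np.asarray(pairs_mov)
    centered = R - R.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-6) < 2:
        raise ValueError("matched beads are collinear; affine fit is degenerate")

    def _fit(Rp, Mp):
        A = np.hstack([Rp, np.ones((len(Rp), 1))])
        sol, *_ = np.linalg.lstsq(A, Mp, rcond=None)
        res = np.linalg.norm(A @ sol - Mp, axis=1)
        return sol, res

    sol, res = _fit(R, Mv)
    # one robust trimming pass against contaminated patches
    keep = res <= max(0.15, 3.0 * float(np.median(res)))
    if keep.sum() >= 3 and keep.sum() < len(R):
        sol, res = _fit(R[keep], Mv[keep])
    matrix = sol[:2].T
    translation = sol[2]
    rms = float(np.sqrt(np.mean(res ** 2)))
    return RegistrationTransform(matrix=matrix, translation=translation, rms_residual=rms)


def apply_registration(image: np.ndarray, transform: RegistrationTransform) -> np.ndarray:
    """Warp a moving-channel image onto the reference grid (inverse warping,
    bilinear interpolation)."""
    return ndi.affine_transform(np.asarray(image, dtype=float), transform.matrix,
                                offset=transform.translation, order=1,
                                mode="constant", cval=0.0)


@dataclass
class ReconstructedFrame:
    image: np.ndarray
    widefield: np.ndarray
    channel_id: int
    timestamp_ns: int
    latency_ns: int


@dataclass
class PipelineReport:
    reconstructed: int = 0
    sets_dropped_in_ring: int = 0
    assembler: SetAssembler | None = None
    latencies_ns: list[int] = field(default_factory=list)
    archived_sets: list[RawSimSet] = field(default_factory=list)

    @property
    def latency_ms_summary(self) -> dict:
        if not self.latencies_ns:
            return {"n": 0}
        arr = np.asarray(self.latencies_ns) / 1e6
        return {"n": len(arr), "mean_ms": float(arr.mean()), "max_ms": float(arr.max()),
                "min_ms": float(arr.min())}


def run_live_pipeline(source: Iterable[FrameRecord | bytes],
                      params: dict[int, IlluminationParams],
                      otfs: dict[int, OtfModel],
                      settings: ReconSettings | None = None, *,
                      sink: Callable[[ReconstructedFrame], None] | None = None,
                      registrations: dict[int, RegistrationTransform] | None = None,
                      ring_capacity: int = 8, drain_interval: int = 1,
                      archive: bool = False,
                      clock_ns: Callable[[], int] | None = None) -> PipelineReport:
    """Decode → group → ring-buffer → reconstruct → register → sink.

    ``drain_interval=n`` reconstructs after every n assembled sets (larger
    values emulate a slow consumer: the ring then drops oldest sets instead
    of stalling).  ``clock_ns`` is injectable for deterministic latency
    accounting.  Raises if a channel appears without parameters.
    """
    settings = settings or ReconSettings()
    registrations = registrations or {}
    clock = clock_ns or time.time_ns
    ring = RingBuffer(ring_capacity)
    assembler = SetAssembler()
    report = PipelineReport(assembler=assembler)

    def drain() -> None:
        while True:
            try:
                raw = ring.pop()
            except RingBufferEmpty:
                return
            ch = raw.channel_id
            if ch not in params or ch not in otfs:
                raise ValueError(
                    f"no reconstruction parameters for channel {ch}; run estimation "
                    "(fit_channel_params) or provide a parameter file first")
            sim, wf = reconstruct_set(raw, params[ch], otfs[ch], settings)
            reg = registrations.get(ch)
            if reg is not None:
                sim = apply_registration(sim, reg)
            latency = clock() - int(raw.timestamps_ns[-1])
            report.latencies_ns.append(latency)
            report.reconstructed += 1
            if sink is not None:
                sink(ReconstructedFrame(image=sim, widefield=wf, channel_id=ch,
                                        timestamp_ns=int(raw.timestamps_ns[-1]),
                                        latency_ns=latency))

    pushed_since_drain = 0
    for msg in source:
        frame = decode_frame_message(msg) if isinstance(msg, (bytes, bytearray)) else msg
        raw = assembler.push(frame)
        if raw is None:
            continue
        if archive:
            report.archived_sets.append(raw)
        ring.push(raw)
        pushed_since_drain += 1
        if pushed_since_drain >= drain_interval:
            drain()
            pushed_since_drain = 0
    drain()
    report.sets_dropped_in_ring = ring.drop_count
    return report


# --- TCP transport -----------------------------------------------------------

_LEN_PREFIX = struct.Struct("<I")


def serve_stream(messages: Sequence[bytes], host: str = "127.0.0.1", port: int = 0,
                 n_links: int = 1) -> tuple[str, int, threading.Thread]:
    """Serve encoded messages over TCP (length-prefixed), round-robin over
    ``n_links`` client connections.  Returns (host, port, server thread).
    """
    srv = socket.socket(socket.AF_INET, socket.SOCK_STREAM)
    srv.setsockopt(socket.SOL_SOCKET, socket.SO_REUSEADDR, 1)
    srv.bind((host, port))
    srv.listen(n_links)
    bound_host, bound_port = srv.getsockname()

    def run() -> None:
        conns = [srv.accept()[0] for _ in range(n_links)]
        try:
            for i, msg in enumerate(messages):
                conn = conns[i % n_links]
                conn.sendall(_LEN_PREFIX.pack(len(msg)) + msg)
        finally:
            for c in conns:
                c.close()
            srv.close()

    thread = threading.Thread(target=run, daemon=True)
    thread.start()
    return bound_host, bound_port, thread


def _recv_exact(sock: socket.socket, n: int) -> bytes | None:
    chunks = []
    got = 0
    while got < n:
        chunk = sock.recv(n - got)
        if not chunk:
            return None
        chunks.append(chunk)
        got += len(chunk)
    return b"".join(chunks)


def socket_source(host: str, port: int, n_links: int = 1,
                  reorder_window: int = 64) -> Iterator[FrameRecord]:
    """Connect ``n_links`` sockets to a stream server and yield frames in
    per-channel sequence order (bundled links are merged by sequence index).
    """
    socks = []
    for _ in range(n_links):
        s = socket.create_connection((host, port))
        socks.append(s)

    def reader(sock: socket.socket, out: list, lock: threading.Lock) -> None:
        while True:
            head = _recv_exact(sock, _LEN_PREFIX.size)
            if head is None:
                return
            (length,) = _LEN_PREFIX.unpack(head)
            payload = _recv_exact(sock, length)
            if payload is None:
                return
            with lock:
                out.append(decode_frame_message(payload))

    collected: list[FrameRecord] = []
    lock = threading.Lock()
    threads = [threading.Thread(target=reader, args=(s, collected, lock), daemon=True)
               for s in socks]
    for t in threads:
        t.start()
    for t in threads:
        t.join()
    for s in socks:
        s.close()
    collected.sort(key=lambda f: (f.timestamp_ns, f.channel_id, f.sequence_index))
    yield from collected
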