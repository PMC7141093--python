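"""Minimal native Matroska (MKV) writer and reader.

Matroska is an EBML-based container holding video, audio and subtitle
tracks plus non-temporal attachments — exactly the layout used here to
bundle a stimulus video with per-subject gaze subtitle tracks, sonified
EEG audio, and the raw recordings as attachments.  This module implements
the small subset of the format the bundling workflow needs, in pure
Python:

* one Segment with Info, Tracks, Attachments and Cluster elements;
* track types video (V_MJPEG frames), audio (A_PCM/INT/LIT) and subtitle
  (S_TEXT/ASS with codec-private header and per-event blocks);
* millisecond timestamp scale; BlockGroups with BlockDuration for
  subtitles, SimpleBlocks elsewhere; no lacing.

Files written here are regular Matroska files; mkvinfo/ffprobe/players
that handle MJPEG+PCM can read them.  The reader accepts this module's
own output and other plainly-structured MKV files using the same subset.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from typing import Optional

__all__ = ["MKVTrack", "MKVBlock", "MKVAttachment", "MKVFile", "write_mkv", "read_mkv"]

# --- EBML element IDs (Matroska v4 subset) ---------------------------------
EBML = 0x1A45DFA3
EBML_VERSION = 0x4286
EBML_READ_VERSION = 0x42F7
EBML_MAX_ID_LENGTH = 0x42F2
EBML_MAX_SIZE_LENGTH = 0x42F3
DOCTYPE = 0x4282
DOCTYPE_VERSION = 0x4287
DOCTYPE_READ_VERSION = 0x4285
SEGMENT = 0x18538067
INFO = 0x1549A966
TIMESTAMP_SCALE = 0x2AD7B1
DURATION = 0x4489
MUXING_APP = 0x4D80
WRITING_APP = 0x5741
TRACKS = 0x1654AE6B
TRACK_ENTRY = 0xAE
TRACK_NUMBER = 0xD7
TRACK_UID = 0x73C5
TRACK_TYPE = 0x83
FLAG_LACING = 0x9C
NAME = 0x536E
LANGUAGE = 0x22B59C
CODEC_ID = 0x86
CODEC_PRIVATE = 0x63A2
DEFAULT_DURATION = 0x23E383
VIDEO = 0xE0
PIXEL_WIDTH = 0xB0
PIXEL_HEIGHT = 0xBA
AUDIO = 0xE1
SAMPLING_FREQUENCY = 0xB5
CHANNELS = 0x9F
BIT_DEPTH = 0x6264
ATTACHMENTS = 0x1941A469
ATTACHED_FILE = 0x61A7
FILE_NAME = 0x466E
FILE_MIMETYPE = 0x4660
FILE_DATA = 0x465C
FILE_UID = 0x46AE
CLUSTER = 0x1F43B675
TIMESTAMP = 0xE7
SIMPLE_BLOCK = 0xA3
BLOCK_GROUP = 0xA0
BLOCK = 0xA1
BLOCK_DURATION = 0x9B

TRACK_TYPE_CODES = {"video": 1, "audio": 2, "subtitle": 17}
TRACK_TYPE_NAMES = {v: k for k, v in TRACK_TYPE_CODES.items()}

_MASTER_IDS = {
    EBML, SEGMENT, INFO, TRACKS, TRACK_ENTRY, VIDEO, AUDIO,
    ATTACHMENTS, ATTACHED_FILE, CLUSTER, BLOCK_GROUP,
}

# timestamp scale: 1 ms per Matroska tick
_SCALE_NS = 1_000_000
# clusters are cut so int16 relative block timestamps cannot overflow
_CLUSTER_SPAN_MS = 30_000


@dataclass
class MKVTrack:
    number: int
    type: str  # video | audio | subtitle
    codec_id: str
    name: str = ""
    language: str = "und"
    codec_private: bytes = b""
    # video
    width: Optional[int] = None
    height: Optional[int] = None
    default_duration_ns: Optional[int] = None
    # audio
    sampling_frequency: Optional[float] = None
    channels: Optional[int] = None
    bit_depth: Optional[int] = None


@dataclass
class MKVBlock:
    track_number: int
    timestamp_ms: int
    data: bytes
    duration_ms: Optional[int] = None  # present -> BlockGroup, absent -> SimpleBlock


@dataclass
class MKVAttachment:
    name: str
    mime: str
    data: bytes


@dataclass
class MKVFile:
    tracks: list[MKVTrack] = field(default_factory=list)
    blocks: list[MKVBlock] = field(default_factory=list)
    attachments: list[MKVAttachment] = field(default_factory=list)
    duration_ms: Optional[float] = None
    writing_app: str = "gazemux"

    def track_blocks(self, number: int) -> list[MKVBlock]:
        return [b for b in self.blocks if b.track_number == number]


# --- encoding ---------------------------------------------------------------

def _encode_id(eid: int) -> bytes:
    return eid.to_bytes((eid.bit_length() + 7) // 8, "big")


def _encode_size(n: int) -> bytes:
    for length in range(1, 9):
        if n < (1 << (7 * length)) - 1:
            return ((1 << (7 * length)) | n).to_bytes(length, "big")
    raise ValueError(f"size too large: {n}")


def _elem(eid: int, payload: bytes) -> bytes:
    return _encode_id(eid) + _encode_size(len(payload)) + payload


def _uint(eid: int, v: int) -> bytes:
    return _elem(eid, v.to_bytes(max(1, (v.bit_length() + 7) // 8), "big"))


def _float(eid: int, v: float) -> bytes:
    return _elem(eid, struct.pack(">d", v))


def _string(eid: int, s: str) -> bytes:
    return _elem(eid, s.encode("utf-8"))


def _track_entry(tr: MKVTrack) -> bytes:
    payload = (
        _uint(TRACK_NUMBER, tr.number)
        + _uint(TRACK_UID, tr.number)
        + _uint(TRACK_TYPE, TRACK_TYPE_CODES[tr.type])
        + _uint(FLAG_LACING, 0)
        + _string(LANGUAGE, tr.language)
        + _string(CODEC_ID, tr.codec_id)
    )
    if tr.name:
        payload += _string(NAME, tr.name)
    if tr.codec_private:
        payload += _elem(CODEC_PRIVATE, tr.codec_private)
    if tr.default_duration_ns:
        payload += _uint(DEFAULT_DURATION, tr.default_duration_ns)
    if tr.type == "video":
        payload += _elem(VIDEO, _uint(PIXEL_WIDTH, tr.width) + _uint(PIXEL_HEIGHT, tr.height))
    elif tr.type == "audio":
        audio = _float(SAMPLING_FREQUENCY, tr.sampling_frequency)
        audio += _uint(CHANNELS, tr.channels or 1)
        if tr.bit_depth:
            audio += _uint(BIT_DEPTH, tr.bit_depth)
        payload += _elem(AUDIO, audio)
    return _elem(TRACK_ENTRY, payload)


def _block_frame(b: MKVBlock, cluster_ts: int, flags: int) -> bytes:
    rel = b.timestamp_ms - cluster_ts
    if not -32768 <= rel <= 32767:
        raise ValueError("relative block timestamp overflows int16")
    return bytes([0x80 | b.track_number]) + struct.pack(">h", rel) + bytes([flags]) + b.data


def write_mkv(mkv: MKVFile, path) -> None:
    """Write the container to ``path``."""
    header = _elem(
        EBML,
        _uint(EBML_VERSION, 1) + _uint(EBML_READ_VERSION, 1)
        + _uint(EBML_MAX_ID_LENGTH, 4) + _uint(EBML_MAX_SIZE_LENGTH, 8)
        + _string(DOCTYPE, "matroska")
        + _uint(DOCTYPE_VERSION, 4) + _uint(DOCTYPE_READ_VERSION, 2),
    )
    blocks = sorted(mkv.blocks, key=lambda b: (b.timestamp_ms, b.track_number))
    duration = mkv.duration_ms
    if duration is None and blocks:
        duration = float(max(b.timestamp_ms + (b.duration_ms or 0) for b in blocks))
    info = _uint(TIMESTAMP_SCALE, _SCALE_NS)
    if duration is not None:
        info += _float(DURATION, float(duration))
    info += _string(MUXING_APP, mkv.writing_app) + _string(WRITING_APP, mkv.writing_app)
    segment = _elem(INFO, info)
    segment += _elem(TRACKS, b"".join(_track_entry(t) for t in mkv.tracks))
    if mkv.attachments:
        files = b"".join(
            _elem(
                ATTACHED_FILE,
                _string(FILE_NAME, a.name) + _string(FILE_MIMETYPE, a.mime)
                + _uint(FILE_UID, i + 1) + _elem(FILE_DATA, a.data),
            )
            for i, a in enumerate(mkv.attachments)
        )
        segment += _elem(ATTACHMENTS, files)

    i = 0
    while i < len(blocks):
        cluster_ts = blocks[i].timestamp_ms
        payload = _uint(TIMESTAMP, cluster_ts)
        while i < len(blocks) and blocks[i].timestamp_ms - cluster_ts < _CLUSTER_SPAN_MS:
            b = blocks[i]
            if b.duration_ms is not None:
                grp = _elem(BLOCK, _block_frame(b, cluster_ts, 0x00))
                grp += _uint(BLOCK_DURATION, b.duration_ms)
                payload += _elem(BLOCK_GROUP, grp)
            else:
                payload += _elem(SIMPLE_BLOCK, _block_frame(b, cluster_ts, 0x80))
            i += 1
        segment += _elem(CLUSTER, payload)

    with open(path, "wb") as fh:
        fh.write(header + _elem(SEGMENT, segment))


# --- decoding ---------------------------------------------------------------

def _read_vint(buf: bytes, pos: int, keep_marker: bool) -> tuple[int, int]:
    first = buf[pos]
    if first == 0:
        raise ValueError(f"invalid EBML varint at byte {pos}")
    length = 1
    mask = 0x80
    while not first & mask:
        mask >>= 1
        length += 1
    value = int.from_bytes(buf[pos : pos + length], "big")
    if not keep_marker:
        value &= (1 << (7 * length)) - 1
    return value, pos + length


def _iter_children(buf: bytes, start: int, end: int):
    pos = start
    while pos < end:
        eid, pos = _read_vint(buf, pos, keep_marker=True)
        size, pos = _read_vint(buf, pos, keep_marker=False)
        yield eid, pos, pos + size
        pos += size


def _child_map(buf: bytes, start: int, end: int) -> dict[int, list[tuple[int, int]]]:
    out: dict[int, list[tuple[int, int]]] = {}
    for eid, s, e in _iter_children(buf, start, end):
        out.setdefault(eid, []).append((s, e))
    return out


def _u(buf, span) -> int:
    s, e = span
    return int.from_bytes(buf[s:e], "big")


def _s(buf, span) -> str:
    s, e = span
    return buf[s:e].rstrip(b"\x00").decode("utf-8", errors="replace")


def _parse_track(buf, start, end) -> MKVTrack:
    ch = _child_map(buf, start, end)
    ttype = TRACK_TYPE_NAMES.get(_u(buf, ch[TRACK_TYPE][0]), "other")
    tr = MKVTrack(
        number=_u(buf, ch[TRACK_NUMBER][0]),
        type=ttype,
        codec_id=_s(buf, ch[CODEC_ID][0]) if CODEC_ID in ch else "",
        name=_s(buf, ch[NAME][0]) if NAME in ch else "",
        language=_s(buf, ch[LANGUAGE][0]) if LANGUAGE in ch else "und",
        codec_private=buf[ch[CODEC_PRIVATE][0][0] : ch[CODEC_PRIVATE][0][1]]
        if CODEC_PRIVATE in ch else b"",
    )
    if DEFAULT_DURATION in ch:
        tr.default_duration_ns = _u(buf, ch[DEFAULT_DURATION][0])
    if VIDEO in ch:
        v = _child_map(buf, *ch[VIDEO][0])
        tr.width = _u(buf, v[PIXEL_WIDTH][0])
        tr.height = _u(buf, v[PIXEL_HEIGHT][0])
    if AUDIO in ch:
        a = _child_map(buf, *ch[AUDIO][0])
        if SAMPLING_FREQUENCY in a:
            s, e = a[SAMPLING_FREQUENCY][0]
            raw = buf[s:e]
            tr.sampling_frequency = struct.unpack(">d" if len(raw) == 8 else ">f", raw)[0]
        if CHANNELS in a:
            tr.channels = _u(buf, a[CHANNELS][0])
        if BIT_DEPTH in a:
            tr.bit_depth = _u(buf, a[BIT_DEPTH][0])
    return tr


def _parse_block_frame(buf, start, end, cluster_ts, to_ms=1.0) -> MKVBlock:
    track, pos = _read_vint(buf, start, keep_marker=False)
    rel = struct.unpack(">h", buf[pos : pos + 2])[0]
    flags = buf[pos + 2]
    lacing = (flags >> 1) & 0x03
    if lacing:
        raise ValueError("laced blocks are not supported")
    return MKVBlock(track_number=track, timestamp_ms=cluster_ts + round(rel * to_ms),
                    data=buf[pos + 3 : end])


def read_mkv(path) -> MKVFile:
    """Parse a Matroska file into tracks, blocks and attachments.

    Raises ``ValueError`` for files that are not EBML/Matroska or use
    features outside the written subset (lacing, unknown sizes).
    """
    with open(path, "rb") as fh:
        buf = fh.read()
    if len(buf) < 4 or buf[:4] != _encode_id(EBML):
        raise ValueError(f"{path}: not an EBML/Matroska file")
    mkv = MKVFile(writing_app="")
    top = _child_map(buf, 0, len(buf))
    ebml = _child_map(buf, *top[EBML][0])
    if DOCTYPE in ebml and _s(buf, ebml[DOCTYPE][0]) not in ("matroska", "webm"):
        raise ValueError(f"{path}: doctype is not matroska")
    if SEGMENT not in top:
        raise ValueError(f"{path}: no Segment element")
    seg = _child_map(buf, *top[SEGMENT][0])
    scale = _SCALE_NS
    if INFO in seg:
        info = _child_map(buf, *seg[INFO][0])
        if TIMESTAMP_SCALE in info:
            scale = _u(buf, info[TIMESTAMP_SCALE][0])
        if WRITING_APP in info:
            mkv.writing_app = _s(buf, info[WRITING_APP][0])
        if DURATION in info:
            s, e = info[DURATION][0]
            raw = buf[s:e]
            ticks = struct.unpack(">d" if len(raw) == 8 else ">f", raw)[0]
            mkv.duration_ms = ticks * scale / _SCALE_NS
    if scale != _SCALE_NS and scale <= 0:
        raise ValueError("invalid timestamp scale")
    to_ms = scale / _SCALE_NS
    for span in seg.get(TRACKS, []):
        for eid, s, e in _iter_children(buf, *span):
            if eid == TRACK_ENTRY:
                mkv.tracks.append(_parse_track(buf, s, e))
    for span in seg.get(ATTACHMENTS, []):
        for eid, s, e in _iter_children(buf, *span):
            if eid != ATTACHED_FILE:
                continue
            ch = _child_map(buf, s, e)
            mkv.attachments.append(MKVAttachment(
                name=_s(buf, ch[FILE_NAME][0]),
                mime=_s(buf, ch[FILE_MIMETYPE][0]) if FILE_MIMETYPE in ch else "",
                data=buf[ch[FILE_DATA][0][0] : ch[FILE_DATA][0][1]],
            ))
    for span in seg.get(CLUSTER, []):
        ch = _child_map(buf, *span)
        cluster_ts = round(_u(buf, ch[TIMESTAMP][0]) * to_ms) if TIMESTAMP in ch else 0
        for eid, s, e in _iter_children(buf, *span):
            if eid == SIMPLE_BLOCK:
                mkv.blocks.append(_parse_block_frame(buf, s, e, cluster_ts, to_ms))
            elif eid == BLOCK_GROUP:
                grp = _child_map(buf, s, e)
                blk = _parse_block_frame(buf, *grp[BLOCK][0], cluster_ts, to_ms)
                if BLOCK_DURATION in grp:
                    blk.duration_ms = round(_u(buf, grp[BLOCK_DURATION][0]) * to_ms)
                mkv.blocks.append(blk)
    mkv.blocks.sort(key=lambda b: (b.timestamp_ms, b.track_number))
    return mkv
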