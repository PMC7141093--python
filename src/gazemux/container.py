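"""Mux/demux/inspect Matroska bundles of video, subtitles, audio and raw data.

A :class:`ContainerManifest` declares what goes into one MKV: the stimulus
video, one ASS subtitle track per subject (the playable gaze
visualization), optional WAV audio tracks (EEG sonification), and
attachments (the raw gaze CSVs, the USF carrier, the run config) so the
original data travels with the visualization in a single file.

Three interchangeable backends are provided: ``mkvmerge`` (MKVToolNix,
preferred when installed — mkvextract handles the demux side), ``ffmpeg``,
and ``native`` (this package's own Matroska subset writer/reader, always
available).  ``backend="auto"`` picks the first available in that order.
"""

from __future__ import annotations

import json
import mimetypes
import shutil
import subprocess
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import ass as ass_mod
from . import mkv as mkvlib

__all__ = [
    "ContainerManifest",
    "TrackInfo",
    "Inventory",
    "MuxerError",
    "MuxerNotFoundError",
    "mux",
    "demux",
    "inspect",
    "get_backend",
]


class MuxerError(RuntimeError):
    pass


class MuxerNotFoundError(MuxerError):
    def __init__(self, binary: str):
        super().__init__(
            f"required external muxer binary {binary!r} was not found on PATH; "
            f"install it or use backend='native'"
        )
        self.binary = binary


@dataclass
class ContainerManifest:
    """Declaration of one output container."""

    video: Path
    output: Path
    subtitles: list[tuple[Path, str]] = field(default_factory=list)  # (path, track name)
    audio: list[tuple[Path, str]] = field(default_factory=list)
    attachments: list[Path] = field(default_factory=list)

    def validate(self) -> None:
        paths = [self.video, *(p for p, _ in self.subtitles), *(p for p, _ in self.audio),
                 *self.attachments]
        for p in paths:
            if not Path(p).exists():
                raise FileNotFoundError(f"manifest references missing file: {p}")
        names = [n for _, n in self.subtitles] + [n for _, n in self.audio]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ValueError(f"duplicate track names in manifest: {sorted(dupes)}")


@dataclass
class TrackInfo:
    type: str  # video | audio | subtitle
    codec: str
    name: str
    n_blocks: Optional[int] = None  # frame/event/chunk count (native backend)


@dataclass
class Inventory:
    tracks: list[TrackInfo]
    attachments: list[str]

    def of_type(self, type_: str) -> list[TrackInfo]:
        return [t for t in self.tracks if t.type == type_]


# ---------------------------------------------------------------------------
# native backend

def _ass_codec_private(text: str) -> tuple[bytes, list]:
    """Split an ASS script into the Matroska codec-private header and events."""
    doc = ass_mod.parse_ass(text)
    header_lines = []
    for line in text.splitlines():
        if line.strip().startswith("Dialogue:"):
            continue
        header_lines.append(line)
    return ("\n".join(header_lines) + "\n").encode("utf-8"), doc.events


def _wav_read(path) -> tuple[int, np.ndarray]:
    from scipy.io import wavfile

    rate, data = wavfile.read(path)
    if data.dtype != np.int16:
        if np.issubdtype(data.dtype, np.floating):
            data = (np.clip(data, -1.0, 1.0) * 32767).astype(np.int16)
        else:
            data = data.astype(np.int16)
    if data.ndim > 1:
        data = data[:, 0]
    return rate, data


class NativeBackend:
    """Pure-Python Matroska subset backend; always available."""

    name = "native"

    @staticmethod
    def available() -> bool:
        return True

    def mux(self, manifest: ContainerManifest) -> Path:
        manifest.validate()
        src = mkvlib.read_mkv(manifest.video)
        video_tracks = [t for t in src.tracks if t.type == "video"]
        if not video_tracks:
            raise MuxerError(f"{manifest.video} contains no video track")
        out = mkvlib.MKVFile()
        vt = video_tracks[0]
        next_num = 1
        renum = {vt.number: next_num}
        vt_copy = mkvlib.MKVTrack(**{**vt.__dict__, "number": next_num})
        out.tracks.append(vt_copy)
        for b in src.track_blocks(vt.number):
            out.blocks.append(mkvlib.MKVBlock(next_num, b.timestamp_ms, b.data, b.duration_ms))
        next_num += 1

        for path, name in manifest.subtitles:
            text = Path(path).read_text(encoding="utf-8")
            private, events = _ass_codec_private(text)
            out.tracks.append(mkvlib.MKVTrack(
                number=next_num, type="subtitle", codec_id="S_TEXT/ASS",
                name=name, codec_private=private,
            ))
            for order, ev in enumerate(events):
                payload = f"{order},0,{ev.style_name},,0,0,0,,{ev.draw_text}".encode("utf-8")
                out.blocks.append(mkvlib.MKVBlock(
                    next_num, ev.start_cs * 10, payload,
                    duration_ms=(ev.end_cs - ev.start_cs) * 10,
                ))
            next_num += 1

        for path, name in manifest.audio:
            rate, data = _wav_read(path)
            out.tracks.append(mkvlib.MKVTrack(
                number=next_num, type="audio", codec_id="A_PCM/INT/LIT", name=name,
                sampling_frequency=float(rate), channels=1, bit_depth=16,
            ))
            chunk = max(1, int(rate // 10))  # ~100 ms PCM chunks
            for i in range(0, len(data), chunk):
                seg = data[i : i + chunk]
                out.blocks.append(mkvlib.MKVBlock(
                    next_num, round(i * 1000.0 / rate), seg.astype("<i2").tobytes(),
                ))
            next_num += 1

        for path in manifest.attachments:
            p = Path(path)
            mime = mimetypes.guess_type(p.name)[0] or "application/octet-stream"
            out.attachments.append(mkvlib.MKVAttachment(p.name, mime, p.read_bytes()))

        out.duration_ms = src.duration_ms
        mkvlib.write_mkv(out, manifest.output)
        return Path(manifest.output)

    def demux(self, container: Path, out_dir: Path) -> dict[str, list[Path]]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        try:
            mkv = mkvlib.read_mkv(container)
        except (OSError, ValueError) as exc:
            raise MuxerError(f"cannot read container {container}: {exc}") from exc
        result: dict[str, list[Path]] = {"video": [], "subtitle": [], "audio": [],
                                         "attachment": []}
        for tr in mkv.tracks:
            blocks = mkv.track_blocks(tr.number)
            stem = tr.name or f"track{tr.number}"
            if tr.type == "subtitle":
                path = out_dir / f"{stem}.ass"
                lines = [tr.codec_private.decode("utf-8").rstrip("\n")]
                dialogues = []
                for b in blocks:
                    fields = b.data.decode("utf-8").split(",", 8)
                    order, layer, style = fields[0], fields[1], fields[2]
                    rest = ",".join(fields[3:])
                    start_cs = b.timestamp_ms // 10
                    end_cs = start_cs + (b.duration_ms or 10) // 10
                    dialogues.append((int(order),
                                      f"Dialogue: {layer},{ass_mod._fmt_time(start_cs)},"
                                      f"{ass_mod._fmt_time(end_cs)},{style},{rest}"))
                lines += [d for _, d in sorted(dialogues)]
                path.write_text("\n".join(lines) + "\n", encoding="utf-8")
                result["subtitle"].append(path)
            elif tr.type == "audio":
                from scipy.io import wavfile

                path = out_dir / f"{stem}.wav"
                pcm = np.frombuffer(b"".join(b.data for b in blocks), dtype="<i2")
                wavfile.write(path, int(tr.sampling_frequency), pcm)
                result["audio"].append(path)
            elif tr.type == "video":
                path = out_dir / f"{stem}.mjpeg"  # concatenated JPEG frames
                path.write_bytes(b"".join(b.data for b in blocks))
                result["video"].append(path)
        for att in mkv.attachments:
            path = out_dir / att.name
            path.write_bytes(att.data)
            result["attachment"].append(path)
        return result

    def inspect(self, container: Path) -> Inventory:
        try:
            mkv = mkvlib.read_mkv(container)
        except (OSError, ValueError) as exc:
            raise MuxerError(f"cannot identify {container}: {exc}") from exc
        tracks = [
            TrackInfo(t.type, t.codec_id, t.name, len(mkv.track_blocks(t.number)))
            for t in mkv.tracks
        ]
        return Inventory(tracks=tracks, attachments=[a.name for a in mkv.attachments])


# ---------------------------------------------------------------------------
# external backends

def _run(cmd: Sequence[str]) -> str:
    proc = subprocess.run(cmd, capture_output=True, text=True)
    if proc.returncode != 0:
        raise MuxerError(
            f"{cmd[0]} exited with status {proc.returncode}:\n{proc.stderr.strip()}"
        )
    return proc.stdout


class MkvmergeBackend:
    """MKVToolNix orchestration (mkvmerge for mux, mkvextract for demux)."""

    name = "mkvmerge"

    @staticmethod
    def available() -> bool:
        return shutil.which("mkvmerge") is not None and shutil.which("mkvextract") is not None

    def _require(self, binary: str) -> str:
        path = shutil.which(binary)
        if path is None:
            raise MuxerNotFoundError(binary)
        return path

    def mux(self, manifest: ContainerManifest) -> Path:
        manifest.validate()
        cmd = [self._require("mkvmerge"), "-o", str(manifest.output), str(manifest.video)]
        for path, name in manifest.subtitles:
            cmd += ["--track-name", f"0:{name}", str(path)]
        for path, name in manifest.audio:
            cmd += ["--track-name", f"0:{name}", str(path)]
        for path in manifest.attachments:
            cmd += ["--attach-file", str(path)]
        _run(cmd)
        return Path(manifest.output)

    def demux(self, container: Path, out_dir: Path) -> dict[str, list[Path]]:
        mkvextract = self._require("mkvextract")
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        inv = self.inspect(container)
        result: dict[str, list[Path]] = {"video": [], "subtitle": [], "audio": [],
                                         "attachment": []}
        ext = {"subtitle": "ass", "audio": "wav", "video": "mkv"}
        specs = []
        for i, tr in enumerate(inv.tracks):
            path = out_dir / f"{tr.name or f'track{i}'}.{ext.get(tr.type, 'bin')}"
            specs.append(f"{i}:{path}")
            result.setdefault(tr.type, []).append(path)
        if specs:
            _run([mkvextract, str(container), "tracks", *specs])
        att_specs = []
        for j, name in enumerate(inv.attachments, start=1):
            path = out_dir / name
            att_specs.append(f"{j}:{path}")
            result["attachment"].append(path)
        if att_specs:
            _run([mkvextract, str(container), "attachments", *att_specs])
        return result

    def inspect(self, container: Path) -> Inventory:
        mkvmerge = self._require("mkvmerge")
        if not Path(container).exists():
            raise MuxerError(f"no such file: {container}")
        ident = json.loads(_run([mkvmerge, "-J", str(container)]))
        type_map = {"video": "video", "audio": "audio", "subtitles": "subtitle"}
        tracks = [
            TrackInfo(
                type=type_map.get(t.get("type"), t.get("type", "other")),
                codec=t.get("properties", {}).get("codec_id", t.get("codec", "")),
                name=t.get("properties", {}).get("track_name", ""),
            )
            for t in ident.get("tracks", [])
        ]
        attachments = [a.get("file_name", "") for a in ident.get("attachments", [])]
        return Inventory(tracks=tracks, attachments=attachments)


class FfmpegBackend:
    """ffmpeg/ffprobe orchestration; attachments via -attach."""

    name = "ffmpeg"

    @staticmethod
    def available() -> bool:
        return shutil.which("ffmpeg") is not None and shutil.which("ffprobe") is not None

    def _require(self, binary: str) -> str:
        path = shutil.which(binary)
        if path is None:
            raise MuxerNotFoundError(binary)
        return path

    def mux(self, manifest: ContainerManifest) -> Path:
        manifest.validate()
        ffmpeg = self._require("ffmpeg")
        cmd = [ffmpeg, "-y", "-i", str(manifest.video)]
        for path, _ in manifest.subtitles:
            cmd += ["-i", str(path)]
        for path, _ in manifest.audio:
            cmd += ["-i", str(path)]
        for i in range(1 + len(manifest.subtitles) + len(manifest.audio)):
            cmd += ["-map", str(i)]
        for i, (_, name) in enumerate(manifest.subtitles):
            cmd += [f"-metadata:s:s:{i}", f"title={name}"]
        for i, (_, name) in enumerate(manifest.audio):
            cmd += [f"-metadata:s:a:{i}", f"title={name}"]
        for path in manifest.attachments:
            mime = mimetypes.guess_type(str(path))[0] or "application/octet-stream"
            cmd += ["-attach", str(path), "-metadata:s:t", f"mimetype={mime}"]
        cmd += ["-c", "copy", str(manifest.output)]
        _run(cmd)
        return Path(manifest.output)

    def demux(self, container: Path, out_dir: Path) -> dict[str, list[Path]]:
        ffmpeg = self._require("ffmpeg")
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        inv = self.inspect(container)
        result: dict[str, list[Path]] = {"video": [], "subtitle": [], "audio": [],
                                         "attachment": []}
        ext = {"subtitle": "ass", "audio": "wav", "video": "mkv"}
        for sel, type_ in (("s", "subtitle"), ("a", "audio"), ("v", "video")):
            for i, tr in enumerate(inv.of_type(type_)):
                path = out_dir / f"{tr.name or f'{type_}{i}'}.{ext[type_]}"
                _run([ffmpeg, "-y", "-i", str(container), "-map", f"0:{sel}:{i}",
                      *([] if type_ == "subtitle" else ["-c", "copy"]), str(path)])
                result[type_].append(path)
        if inv.attachments:
            _run([ffmpeg, "-y", "-dump_attachment:t", "", "-i", str(container)])
        return result

    def inspect(self, container: Path) -> Inventory:
        ffprobe = self._require("ffprobe")
        if not Path(container).exists():
            raise MuxerError(f"no such file: {container}")
        out = _run([ffprobe, "-v", "quiet", "-print_format", "json",
                    "-show_streams", str(container)])
        ident = json.loads(out)
        type_map = {"video": "video", "audio": "audio", "subtitle": "subtitle"}
        tracks = []
        attachments = []
        for s in ident.get("streams", []):
            ctype = s.get("codec_type")
            if ctype == "attachment":
                attachments.append(s.get("tags", {}).get("filename", ""))
                continue
            tracks.append(TrackInfo(
                type=type_map.get(ctype, ctype or "other"),
                codec=s.get("codec_name", ""),
                name=s.get("tags", {}).get("title", ""),
            ))
        return Inventory(tracks=tracks, attachments=attachments)


_BACKENDS = {"native": NativeBackend, "mkvmerge": MkvmergeBackend, "ffmpeg": FfmpegBackend}


def get_backend(name: str = "auto"):
    """Resolve a backend by name; ``auto`` prefers mkvmerge, then ffmpeg,
    then the built-in native writer."""
    if name == "auto":
        for cls in (MkvmergeBackend, FfmpegBackend, NativeBackend):
            if cls.available():
                return cls()
        return NativeBackend()
    try:
        return _BACKENDS[name]()
    except KeyError:
        raise ValueError(f"unknown backend {name!r}; choose from "
                         f"{sorted(_BACKENDS)} or 'auto'") from None


def mux(manifest: ContainerManifest, backend: str = "auto") -> Path:
    return get_backend(backend).mux(manifest)


def demux(container: Path, out_dir: Path, backend: str = "auto") -> dict[str, list[Path]]:
    return get_backend(backend).demux(container, out_dir)


def inspect(container: Path, backend: str = "auto") -> Inventory:
    return get_backend(backend).inspect(container)
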