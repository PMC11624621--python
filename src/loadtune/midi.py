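"""Minimal Standard MIDI File (SMF) reader/writer.

Supports the subset of SMF needed for monophonic melody manipulation:
format 0 and format 1 files, channel voice messages, meta events and
sysex. Running status and the note_on-velocity-0-as-note-off dialect are
handled on read; events are preserved verbatim so that a read/write
round trip reproduces the original event sequence.

Pitch-bend values are exposed as signed integers in [-8192, 8191]
(0 = no bend), the 14-bit signed convention of the MIDI standard.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field, replace
from typing import Iterator, Optional, Sequence, Tuple

PITCH_BEND_MIN = -8192
PITCH_BEND_MAX = 8191

#: channel voice status nibbles -> (event name, number of data bytes)
_CHANNEL_STATUS = {
    0x80: ("note_off", 2),
    0x90: ("note_on", 2),
    0xA0: ("polytouch", 2),
    0xB0: ("control_change", 2),
    0xC0: ("program_change", 1),
    0xD0: ("aftertouch", 1),
    0xE0: ("pitch_bend", 2),
}
_STATUS_FOR = {name: status for status, (name, _) in _CHANNEL_STATUS.items()}


class MidiFormatError(ValueError):
    """Raised for malformed or unsupported MIDI data."""


@dataclass(frozen=True)
class MidiEvent:
    """One timed MIDI event.

    ``delta`` is the time in ticks since the previous event in the same
    track. Channel events carry ``channel`` plus type-specific fields;
    meta events carry ``meta_type`` and raw ``data``.
    """

    delta: int
    type: str
    channel: Optional[int] = None
    note: Optional[int] = None
    velocity: Optional[int] = None
    pitch: Optional[int] = None  # signed pitch-bend value
    data: Tuple[int, ...] = field(default_factory=tuple)
    meta_type: Optional[int] = None

    def is_note_onset(self) -> bool:
        """True for a note_on with nonzero velocity (a sounding onset)."""
        return self.type == "note_on" and (self.velocity or 0) > 0

    def is_note_end(self) -> bool:
        """True for note_off or the note_on-velocity-0 release dialect."""
        if self.type == "note_off":
            return True
        return self.type == "note_on" and (self.velocity or 0) == 0

    def with_delta(self, delta: int) -> "MidiEvent":
        return replace(self, delta=delta)


def pitch_bend_event(value: int, channel: int, delta: int = 0) -> MidiEvent:
    """Build a pitch-bend event with a signed value in [-8192, 8191]."""
    if not PITCH_BEND_MIN <= value <= PITCH_BEND_MAX:
        raise ValueError(f"pitch-bend value {value} outside [{PITCH_BEND_MIN}, {PITCH_BEND_MAX}]")
    return MidiEvent(delta=delta, type="pitch_bend", channel=channel, pitch=int(value))


def meta_event(meta_type: int, data: Sequence[int], delta: int = 0) -> MidiEvent:
    return MidiEvent(delta=delta, type="meta", meta_type=meta_type, data=tuple(data))


def tempo_event(microseconds_per_beat: int, delta: int = 0) -> MidiEvent:
    return meta_event(0x51, struct.pack(">I", microseconds_per_beat)[1:], delta=delta)


def end_of_track(delta: int = 0) -> MidiEvent:
    return meta_event(0x2F, (), delta=delta)


# ---------------------------------------------------------------------------
# variable-length quantities

def encode_varlen(value: int) -> bytes:
    if value < 0:
        raise ValueError("variable-length quantity must be nonnegative")
    out = [value & 0x7F]
    value >>= 7
    while value:
        out.append(0x80 | (value & 0x7F))
        value >>= 7
    return bytes(reversed(out))


def decode_varlen(data: bytes, offset: int) -> Tuple[int, int]:
    """Decode a varint at ``offset``; return (value, next offset)."""
    value = 0
    for _ in range(4):
        byte = data[offset]
        offset += 1
        value = (value << 7) | (byte & 0x7F)
        if not byte & 0x80:
            return value, offset
    raise MidiFormatError("variable-length quantity longer than 4 bytes")


# ---------------------------------------------------------------------------
# reading

def _parse_track(data: bytes) -> list[MidiEvent]:
    events: list[MidiEvent] = []
    offset = 0
    running_status: Optional[int] = None
    while offset < len(data):
        delta, offset = decode_varlen(data, offset)
        status = data[offset]
        if status >= 0x80:
            offset += 1
            if status < 0xF0:
                running_status = status
        else:
            if running_status is None:
                raise MidiFormatError("data byte with no running status")
            status = running_status

        if status == 0xFF:
            meta_type = data[offset]
            length, offset = decode_varlen(data, offset + 1)
            payload = tuple(data[offset:offset + length])
            offset += length
            events.append(MidiEvent(delta=delta, type="meta", meta_type=meta_type, data=payload))
            running_status = None
        elif status in (0xF0, 0xF7):
            length, offset = decode_varlen(data, offset)
            payload = tuple(data[offset:offset + length])
            offset += length
            events.append(MidiEvent(delta=delta, type="sysex", data=payload))
            running_status = None
        else:
            kind, n_data = _CHANNEL_STATUS.get(status & 0xF0, (None, 0))
            if kind is None:
                raise MidiFormatError(f"unsupported status byte 0x{status:02X}")
            channel = status & 0x0F
            payload = data[offset:offset + n_data]
            offset += n_data
            if kind in ("note_off", "note_on", "polytouch"):
                events.append(MidiEvent(delta=delta, type=kind, channel=channel,
                                        note=payload[0], velocity=payload[1]))
            elif kind == "pitch_bend":
                value = (payload[0] | (payload[1] << 7)) - 8192
                events.append(MidiEvent(delta=delta, type=kind, channel=channel, pitch=value))
            else:
                events.append(MidiEvent(delta=delta, type=kind, channel=channel,
                                        data=tuple(payload)))
    return events


def read_smf(path) -> Tuple[int, int, list[list[MidiEvent]]]:
    """Read an SMF file; return (format, ticks_per_beat, tracks)."""
    with open(path, "rb") as fh:
        data = fh.read()
    if data[:4] != b"MThd":
        raise MidiFormatError("not a Standard MIDI File (missing MThd)")
    header_len = struct.unpack(">I", data[4:8])[0]
    fmt, n_tracks, division = struct.unpack(">HHH", data[8:14])
    if fmt not in (0, 1):
        raise MidiFormatError(f"unsupported SMF format {fmt}")
    if division & 0x8000:
        raise MidiFormatError("SMPTE time division is not supported")
    offset = 8 + header_len
    tracks: list[list[MidiEvent]] = []
    for _ in range(n_tracks):
        if data[offset:offset + 4] != b"MTrk":
            raise MidiFormatError("missing MTrk chunk")
        length = struct.unpack(">I", data[offset + 4:offset + 8])[0]
        chunk = data[offset + 8:offset + 8 + length]
        tracks.append(_parse_track(chunk))
        offset += 8 + length
    return fmt, division, tracks


# ---------------------------------------------------------------------------
# writing

def _encode_event(event: MidiEvent) -> bytes:
    out = encode_varlen(event.delta)
    if event.type == "meta":
        payload = bytes(event.data)
        return out + bytes([0xFF, event.meta_type]) + encode_varlen(len(payload)) + payload
    if event.type == "sysex":
        payload = bytes(event.data)
        return out + bytes([0xF0]) + encode_varlen(len(payload)) + payload
    status = _STATUS_FOR[event.type] | (event.channel & 0x0F)
    if event.type in ("note_off", "note_on", "polytouch"):
        return out + bytes([status, event.note, event.velocity])
    if event.type == "pitch_bend":
        raw = event.pitch + 8192
        if not 0 <= raw <= 0x3FFF:
            raise ValueError(f"pitch-bend value {event.pitch} out of range")
        return out + bytes([status, raw & 0x7F, raw >> 7])
    return out + bytes([status]) + bytes(event.data)


def write_smf(path, fmt: int, ticks_per_beat: int, tracks: Sequence[Sequence[MidiEvent]]) -> None:
    """Write tracks to a Standard MIDI File, appending end-of-track markers
    where absent."""
    chunks = [b"MThd" + struct.pack(">IHHH", 6, fmt, len(tracks), ticks_per_beat)]
    for track in tracks:
        events = list(track)
        if not events or not (events[-1].type == "meta" and events[-1].meta_type == 0x2F):
            events.append(end_of_track())
        body = b"".join(_encode_event(e) for e in events)
        chunks.append(b"MTrk" + struct.pack(">I", len(body)) + body)
    with open(path, "wb") as fh:
        fh.write(b"".join(chunks))


def iter_onsets(events: Sequence[MidiEvent]) -> Iterator[int]:
    """Yield indices of note onsets (note_on with velocity > 0)."""
    for i, event in enumerate(events):
        if event.is_note_onset():
            yield i
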