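"""Map per-scaffold realised-load profiles to pitch-bend detuning of a melody.

The auditory analogy: each scaffold of the genome corresponds to one
note of a familiar melody, and the realised load on that scaffold
detunes the note downward. A load score is first rounded to the nearest
multiple of 5 (so low loads leave the note in tune), then multiplied by
-20 to give a 14-bit MIDI pitch-bend value (0 = in tune, more negative
= more detuned, floor -8192 ≈ two semitones flat under the General MIDI
default bend range). The first four notes of the melody are left
untouched as an in-tune frame of reference for the listener.

Pitch-bend is channel-wide, so the melody must be monophonic on a
single channel; a bend inserted before an onset would otherwise detune
a still-sounding neighbour.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence

import numpy as np

from . import midi
from .midi import MidiEvent, MidiFormatError, pitch_bend_event

logger = logging.getLogger(__name__)

PITCH_BEND_FLOOR = -8192


class InsufficientNotesError(ValueError):
    """The melody has fewer onsets than the profile needs."""


class PolyphonyError(ValueError):
    """Overlapping notes: channel-wide pitch-bend would detune neighbours."""


@dataclass(frozen=True)
class DetuneMap:
    """Load-to-detuning mapping parameters.

    ``quantum`` (default 5): loads are rounded to the nearest multiple,
    ties away from zero, so sub-quantum loads produce no detuning.
    ``scale`` (default -20): multiplier turning the rounded load into a
    downward pitch-bend. ``skip_prefix`` (default 4): leading onsets
    left undetuned as a tuning reference.
    """

    scores: Sequence[float] = field(default_factory=tuple)
    quantum: int = 5
    scale: int = -20
    skip_prefix: int = 4

    def __post_init__(self) -> None:
        if self.quantum <= 0:
            raise ValueError(f"quantum must be positive, got {self.quantum}")
        if self.scale >= 0:
            raise ValueError(f"scale must be negative, got {self.scale}")
        if self.skip_prefix < 0:
            raise ValueError(f"skip_prefix must be >= 0, got {self.skip_prefix}")
        object.__setattr__(self, "scores", tuple(float(s) for s in self.scores))
        if any(s < 0 for s in self.scores):
            raise ValueError("load scores must be nonnegative")


def quantize_load(score: float, quantum: int = 5) -> int:
    """Round a load score to the nearest multiple of ``quantum``; exact
    half-quantum ties round away from zero."""
    if score < 0:
        raise ValueError(f"load score must be >= 0, got {score}")
    if quantum <= 0:
        raise ValueError(f"quantum must be positive, got {quantum}")
    return int(math.floor(score / quantum + 0.5)) * quantum


def load_to_pitchbend(score: float, detune: DetuneMap = DetuneMap()) -> int:
    """Pitch-bend value for one load score: ``scale * quantize_load(score)``,
    clamped at the -8192 floor. Always <= 0."""
    value = detune.scale * quantize_load(score, detune.quantum)
    if value < PITCH_BEND_FLOOR:
        logger.warning("pitch-bend %d clamped to %d (load %g)", value, PITCH_BEND_FLOOR, score)
        value = PITCH_BEND_FLOOR
    return value


@dataclass
class MelodyTrack:
    """A monophonic single-channel melody within a Standard MIDI File.

    All SMF tracks are retained for lossless round trips;
    ``melody_index`` marks the one carrying the channel events.
    """

    tracks: List[List[MidiEvent]]
    melody_index: int = 0
    ticks_per_beat: int = 480
    fmt: int = 0

    @property
    def melody_events(self) -> List[MidiEvent]:
        return self.tracks[self.melody_index]

    @property
    def channel(self) -> Optional[int]:
        for event in self.melody_events:
            if event.channel is not None:
                return event.channel
        return None

    def note_onsets(self) -> List[int]:
        """Indices of note_on events with velocity > 0."""
        return list(midi.iter_onsets(self.melody_events))

    @property
    def n_onsets(self) -> int:
        return len(self.note_onsets())


def _check_single_channel(events: Sequence[MidiEvent]) -> None:
    channels = {e.channel for e in events if e.channel is not None}
    if len(channels) > 1:
        raise MidiFormatError(f"melody must use a single channel, found {sorted(channels)}")


def _check_monophonic(events: Sequence[MidiEvent]) -> None:
    sounding: set = set()
    for event in events:
        if event.is_note_onset():
            if sounding:
                raise PolyphonyError(
                    f"note {event.note} starts while notes {sorted(sounding)} still sound; "
                    "channel-wide pitch-bend would detune them"
                )
            sounding.add(event.note)
        elif event.is_note_end():
            sounding.discard(event.note)


def read_melody(path) -> MelodyTrack:
    """Read a format-0 or single-melody-track format-1 SMF as a melody."""
    fmt, ticks_per_beat, tracks = midi.read_smf(path)
    melody_indices = [
        i for i, track in enumerate(tracks)
        if any(e.channel is not None for e in track)
    ]
    if len(melody_indices) != 1:
        raise MidiFormatError(
            f"expected exactly one track with channel events, found {len(melody_indices)}"
        )
    melody_index = melody_indices[0]
    _check_single_channel(tracks[melody_index])
    return MelodyTrack(tracks=tracks, melody_index=melody_index,
                       ticks_per_beat=ticks_per_beat, fmt=fmt)


def write_melody(track: MelodyTrack, path) -> None:
    midi.write_smf(path, track.fmt, track.ticks_per_beat, track.tracks)


# RPN 0,0: pitch-bend sensitivity; data entry MSB = semitone range
_RPN_BEND_RANGE_SEMITONES = 2


def _rpn_setup_events(channel: int) -> List[MidiEvent]:
    def cc(control: int, value: int) -> MidiEvent:
        return MidiEvent(delta=0, type="control_change", channel=channel,
                         data=(control, value))
    return [cc(101, 0), cc(100, 0), cc(6, _RPN_BEND_RANGE_SEMITONES), cc(38, 0),
            cc(101, 127), cc(100, 127)]


def detune_melody(track: MelodyTrack, detune: DetuneMap, emit_rpn: bool = False) -> MelodyTrack:
    """Insert one pitch-bend per load score before successive note onsets.

    Onset k (1-based): for k <= skip_prefix the onset is untouched; for
    k = skip_prefix + i the onset is immediately preceded (zero time
    delta) by a bend of value ``load_to_pitchbend(scores[i])``. All
    original events keep their order, timing, pitch and velocity. A
    melody with fewer onsets than ``skip_prefix + len(scores)`` is an
    error, as is any polyphonic overlap.
    """
    events = track.melody_events
    _check_single_channel(events)
    _check_monophonic(events)
    onsets = [i for i, e in enumerate(events) if e.is_note_onset()]
    needed = detune.skip_prefix + len(detune.scores)
    if len(onsets) < needed:
        raise InsufficientNotesError(
            f"melody has {len(onsets)} note onsets but skip_prefix + |scores| = "
            f"{detune.skip_prefix} + {len(detune.scores)} = {needed} are required"
        )
    channel = track.channel if track.channel is not None else 0
    bend_at = {
        onsets[detune.skip_prefix + i]: load_to_pitchbend(score, detune)
        for i, score in enumerate(detune.scores)
    }
    new_events: List[MidiEvent] = []
    if emit_rpn:
        new_events.extend(_rpn_setup_events(channel))
    for i, event in enumerate(events):
        if i in bend_at:
            # the bend inherits the onset's delta; the onset follows at delta 0
            new_events.append(pitch_bend_event(bend_at[i], channel, delta=event.delta))
            new_events.append(event.with_delta(0))
        else:
            new_events.append(event)
    tracks = [list(t) for t in track.tracks]
    tracks[track.melody_index] = new_events
    return replace(track, tracks=tracks)


def strip_pitch_bends(track: MelodyTrack) -> MelodyTrack:
    """Remove all pitch-bend events, folding their deltas into the next
    event so note timing is preserved. Inverse of ``detune_melody`` on
    bend-free inputs."""
    new_events: List[MidiEvent] = []
    carry = 0
    for event in track.melody_events:
        if event.type == "pitch_bend":
            carry += event.delta
            continue
        new_events.append(event.with_delta(event.delta + carry))
        carry = 0
    tracks = [list(t) for t in track.tracks]
    tracks[track.melody_index] = new_events
    return replace(track, tracks=tracks)


def inserted_bends(track: MelodyTrack) -> List[int]:
    """Pitch-bend values immediately preceding note onsets, in order."""
    events = track.melody_events
    values = []
    for i, event in enumerate(events):
        if event.is_note_onset() and i > 0 and events[i - 1].type == "pitch_bend":
            values.append(events[i - 1].pitch)
    return values


def sonify_profile(
    track: MelodyTrack,
    scores: Sequence[float],
    quantum: int = 5,
    scale: int = -20,
    skip_prefix: int = 4,
    emit_rpn: bool = False,
) -> MelodyTrack:
    """Convenience wrapper: detune ``track`` with a per-scaffold profile."""
    detune = DetuneMap(scores=tuple(np.asarray(scores, dtype=float)),
                       quantum=quantum, scale=scale, skip_prefix=skip_prefix)
    return detune_melody(track, detune, emit_rpn=emit_rpn)
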