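"""Annotation tiers and stimulus regressors.

This module turns time-aligned word/phoneme annotations and speech audio
into the sampled regressors consumed by the forward encoding model:

* :class:`AnnotationTier` -- validated, ordered (onset, offset, label)
  segments for one linguistic tier (word or phoneme).
* :func:`build_onset_regressor` -- unit impulse trains at segment onsets.
* :func:`extract_envelope` -- magnitude of the analytic signal, zero-phase
  Butterworth low-passed at 8 Hz and resampled to the EEG rate.
* :func:`stimulus_statistics` -- median / quartile segment durations.

Annotations are read and written as plain TSV (columns: tier, onset_s,
offset_s, label) or as a minimal two-tier interval TextGrid dialect, the
format produced by forced-alignment pipelines.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

logger = logging.getLogger(__name__)

WORD_TIER = "word"
PHONEME_TIER = "phoneme"

ENVELOPE_LOWPASS_HZ = 8.0
ENVELOPE_FILTER_ORDER = 4


class Event(NamedTuple):
    """One labelled segment: ``onset <= t < offset`` in seconds."""

    onset: float
    offset: float
    label: str

    @property
    def duration(self) -> float:
        return self.offset - self.onset


class AnnotationError(ValueError):
    """Raised when annotation content violates tier invariants."""


@dataclass
class AnnotationTier:
    """Ordered, non-overlapping labelled segments of one tier.

    Parameters
    ----------
    tier_name:
        Either ``"word"`` or ``"phoneme"``.
    events:
        Segments sorted by onset with ``onset < offset``.
    source_id:
        Free-form stream/trial identifier used in exports.
    validate:
        If true (default) the tier invariants are checked on construction.
        Permutation machinery constructs intentionally overlapping word
        tiers and disables this.
    """

    tier_name: str
    events: list[Event]
    source_id: str = ""
    validate: bool = True

    def __post_init__(self) -> None:
        self.events = [Event(float(o), float(f), str(l)) for o, f, l in self.events]
        if self.validate:
            self._check()

    def _check(self) -> None:
        prev_offset = -np.inf
        prev_onset = -np.inf
        for ev in self.events:
            if not (np.isfinite(ev.onset) and np.isfinite(ev.offset)):
                raise AnnotationError(f"non-finite event in tier {self.tier_name!r}: {ev}")
            if ev.onset >= ev.offset:
                raise AnnotationError(
                    f"event with onset >= offset in tier {self.tier_name!r}: {ev}"
                )
            if ev.onset < prev_onset:
                raise AnnotationError(
                    f"unsorted events in tier {self.tier_name!r} at {ev}"
                )
            if ev.onset < prev_offset:
                raise AnnotationError(
                    f"overlapping events in tier {self.tier_name!r} at {ev}"
                )
            prev_onset, prev_offset = ev.onset, ev.offset

    def __len__(self) -> int:
        return len(self.events)

    @property
    def onsets(self) -> np.ndarray:
        return np.array([ev.onset for ev in self.events], dtype=float)

    @property
    def offsets(self) -> np.ndarray:
        return np.array([ev.offset for ev in self.events], dtype=float)

    @property
    def durations(self) -> np.ndarray:
        return self.offsets - self.onsets

    @property
    def labels(self) -> list[str]:
        return [ev.label for ev in self.events]


def validate_tier_pair(word_tier: AnnotationTier, phoneme_tier: AnnotationTier) -> None:
    """Check that every phoneme lies within exactly one word's ``[onset, offset)``.

    Raises
    ------
    AnnotationError
        Naming the first offending phoneme event.
    """
    word_on = word_tier.onsets
    word_off = word_tier.offsets
    for ev in phoneme_tier.events:
        idx = np.searchsorted(word_on, ev.onset, side="right") - 1
        tol = 1e-9
        if idx < 0 or ev.onset < word_on[idx] - tol or ev.offset > word_off[idx] + tol:
            raise AnnotationError(
                f"phoneme event {ev} lies outside every word segment"
            )


# ---------------------------------------------------------------------------
# annotation IO: TSV and a minimal interval-TextGrid dialect
# ---------------------------------------------------------------------------

def read_annotations(path, dialect: str = "tsv", source_id: str = "") -> list[AnnotationTier]:
    """Read word/phoneme tiers from ``path``.

    ``dialect`` is ``"tsv"`` (columns tier, onset_s, offset_s, label) or
    ``"textgrid-subset"`` (interval tiers named word/phoneme of the long
    TextGrid text format; empty-label intervals are silences and dropped).
    Returns tiers in file order; the word/phoneme containment invariant is
    enforced whenever both tiers are present.
    """
    if dialect == "tsv":
        tiers = _read_tsv(path, source_id)
    elif dialect == "textgrid-subset":
        tiers = _read_textgrid(path, source_id)
    else:
        raise ValueError(f"unknown annotation dialect: {dialect!r}")
    by_name = {t.tier_name: t for t in tiers}
    if WORD_TIER in by_name and PHONEME_TIER in by_name:
        validate_tier_pair(by_name[WORD_TIER], by_name[PHONEME_TIER])
    return tiers


def _read_tsv(path, source_id: str) -> list[AnnotationTier]:
    df = pd.read_csv(path, sep="\t", dtype={"label": str})
    required = {"tier", "onset_s", "offset_s", "label"}
    if not required.issubset(df.columns):
        raise AnnotationError(
            f"TSV annotation file must have columns {sorted(required)}, got {list(df.columns)}"
        )
    tiers = []
    for name, grp in df.groupby("tier", sort=False):
        events = [
            Event(row.onset_s, row.offset_s, row.label)
            for row in grp.itertuples(index=False)
        ]
        tiers.append(AnnotationTier(str(name), events, source_id=source_id))
    return tiers


def write_annotations_tsv(path, tiers: Iterable[AnnotationTier]) -> None:
    rows = []
    for tier in tiers:
        for ev in tier.events:
            rows.append((tier.tier_name, ev.onset, ev.offset, ev.label))
    df = pd.DataFrame(rows, columns=["tier", "onset_s", "offset_s", "label"])
    df.to_csv(path, sep="\t", index=False)


_TG_FLOAT = re.compile(r"(xmin|xmax)\s*=\s*([-\d.eE+]+)")
_TG_TEXT = re.compile(r'(text|name)\s*=\s*"(.*)"')
_TG_CLASS = re.compile(r'class\s*=\s*"(.*)"')


def _read_textgrid(path, source_id: str) -> list[AnnotationTier]:
    """Parse the minimal interval-tier subset of the long TextGrid format."""
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    tiers: list[AnnotationTier] = []
    # split at 'item [k]:' headers; first chunk is the file header
    chunks = re.split(r"item\s*\[\d+\]\s*:", text)[1:]
    for chunk in chunks:
        m = _TG_CLASS.search(chunk)
        if m is None or m.group(1) != "IntervalTier":
            continue
        name_m = _TG_TEXT.search(chunk)
        if name_m is None or name_m.group(1) != "name":
            raise AnnotationError("TextGrid tier without a name entry")
        tier_name = name_m.group(2)
        events = []
        for ival in re.split(r"intervals\s*\[\d+\]\s*:", chunk)[1:]:
            bounds = {m.group(1): float(m.group(2)) for m in _TG_FLOAT.finditer(ival)}
            text_m = _TG_TEXT.search(ival)
            label = text_m.group(2) if text_m else ""
            if label.strip() == "":
                continue  # silence interval
            events.append(Event(bounds["xmin"], bounds["xmax"], label))
        tiers.append(AnnotationTier(tier_name, events, source_id=source_id))
    if not tiers:
        raise AnnotationError(f"no interval tiers found in {path}")
    return tiers


def write_annotations_textgrid(path, tiers: Sequence[AnnotationTier]) -> None:
    """Write tiers in the minimal TextGrid dialect (no silence intervals)."""
    xmax = max(t.offsets.max() for t in tiers if len(t))
    lines = [
        'File type = "ooTextFile"',
        'Object class = "TextGrid"',
        "",
        "xmin = 0",
        f"xmax = {xmax}",
        "tiers? <exists>",
        f"size = {len(tiers)}",
        "item []:",
    ]
    for ti, tier in enumerate(tiers, 1):
        lines += [
            f"    item [{ti}]:",
            '        class = "IntervalTier"',
            f'        name = "{tier.tier_name}"',
            "        xmin = 0",
            f"        xmax = {xmax}",
            f"        intervals: size = {len(tier)}",
        ]
        for ei, ev in enumerate(tier.events, 1):
            lines += [
                f"        intervals [{ei}]:",
                f"            xmin = {ev.onset}",
                f"            xmax = {ev.offset}",
                f'            text = "{ev.label}"',
            ]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# regressors
# ---------------------------------------------------------------------------

def onset_samples(onsets: np.ndarray, fs: float) -> np.ndarray:
    """Map onset times to 0-based sample indices by round-half-up of onset*fs."""
    return np.floor(np.asarray(onsets, dtype=float) * fs + 0.5).astype(np.int64)


def build_onset_regressor(
    tier: AnnotationTier, fs: float, n_samples: int, clip: bool = False
) -> np.ndarray:
    """Unit impulse train with 1 at each event onset sample.

    Impulses are binary: two events rounding to the same sample keep value 1
    (event presence, not count); collisions are logged. An onset at or past
    ``n_samples / fs`` is an error unless ``clip`` is set (used for permuted
    tiers, where a rearranged word's phonemes may overrun the trial end).
    """
    out = np.zeros(int(n_samples), dtype=float)
    if len(tier) == 0:
        return out
    idx = onset_samples(tier.onsets, fs)
    if idx.max() >= n_samples:
        if clip:
            idx = idx[idx < n_samples]
            if idx.size == 0:
                return out
        else:
            bad = tier.events[int(np.argmax(idx))]
            raise ValueError(
                f"onset beyond trial end: {bad} maps to sample {idx.max()} >= {n_samples}"
            )
    if len(np.unique(idx)) < len(idx):
        logger.warning(
            "tier %r: %d onset collisions at fs=%g kept as binary impulses",
            tier.tier_name, len(idx) - len(np.unique(idx)), fs,
        )
    out[idx] = 1.0
    return out


def extract_envelope(audio: np.ndarray, audio_fs: float, target_fs: float) -> np.ndarray:
    """Speech amplitude envelope at the EEG sampling rate.

    The envelope is the magnitude of the analytic signal, low-pass filtered
    at 8 Hz with a zero-phase order-4 Butterworth (forward-backward), then
    polyphase-resampled to ``target_fs``. The zero-phase filter may leave
    small negative ripple; values are returned unclipped.
    """
    audio = np.asarray(audio, dtype=float)
    if audio.ndim != 1:
        raise ValueError("audio must be one-dimensional")
    if not np.all(np.isfinite(audio)):
        raise ValueError("audio contains non-finite samples")
    if audio_fs <= 2 * ENVELOPE_LOWPASS_HZ:
        raise ValueError(f"audio_fs={audio_fs} too low for an {ENVELOPE_LOWPASS_HZ} Hz low-pass")
    env = np.abs(sps.hilbert(audio))
    sos = sps.butter(ENVELOPE_FILTER_ORDER, ENVELOPE_LOWPASS_HZ, fs=audio_fs, output="sos")
    env = sps.sosfiltfilt(sos, env)
    if target_fs != audio_fs:
        frac = Fraction(target_fs / audio_fs).limit_denominator(10_000)
        env = sps.resample_poly(env, frac.numerator, frac.denominator)
    return env


def stimulus_statistics(
    word_tier: AnnotationTier, phoneme_tier: AnnotationTier
) -> dict[str, float]:
    """Median and 25th/75th quantile segment durations, in seconds."""
    out: dict[str, float] = {}
    for name, tier in ((WORD_TIER, word_tier), (PHONEME_TIER, phoneme_tier)):
        if len(tier) == 0:
            raise ValueError(f"empty {name} tier")
        dur = tier.durations
        out[f"{name}_median_s"] = float(np.median(dur))
        out[f"{name}_q25_s"] = float(np.quantile(dur, 0.25))
        out[f"{name}_q75_s"] = float(np.quantile(dur, 0.75))
    return out


# ---------------------------------------------------------------------------
# sampled feature sets
# ---------------------------------------------------------------------------

ONSET_FEATURE_SUFFIX = "_onset"


@dataclass
class StimulusFeatureSet:
    """Named regressor channels at the EEG rate for one trial of one stream.

    ``features`` maps names (``word_onset``, ``phoneme_onset``,
    ``envelope``) to arrays of length ``n_samples``; insertion order fixes
    the design-matrix column order.
    """

    fs: float
    n_samples: int
    features: dict[str, np.ndarray] = field(default_factory=dict)
    stream_id: int = 0
    trial_id: int = 0

    def __post_init__(self) -> None:
        for name, arr in self.features.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != (self.n_samples,):
                raise ValueError(
                    f"feature {name!r} has shape {arr.shape}, expected ({self.n_samples},)"
                )
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"feature {name!r} contains non-finite values")
            self.features[name] = arr

    @property
    def feature_names(self) -> list[str]:
        return list(self.features)

    def onset_feature_names(self) -> list[str]:
        return [n for n in self.features if n.endswith(ONSET_FEATURE_SUFFIX)]

    def subset(self, names: Sequence[str]) -> "StimulusFeatureSet":
        return StimulusFeatureSet(
            fs=self.fs,
            n_samples=self.n_samples,
            features={n: self.features[n] for n in names},
            stream_id=self.stream_id,
            trial_id=self.trial_id,
        )


def feature_set_from_tiers(
    word_tier: AnnotationTier,
    phoneme_tier: AnnotationTier,
    fs: float,
    n_samples: int,
    envelope: np.ndarray | None = None,
    stream_id: int = 0,
    trial_id: int = 0,
) -> StimulusFeatureSet:
    """Assemble word/phoneme impulse trains (and optionally an envelope)."""
    feats: dict[str, np.ndarray] = {
        "word_onset": build_onset_regressor(word_tier, fs, n_samples),
        "phoneme_onset": build_onset_regressor(phoneme_tier, fs, n_samples),
    }
    if envelope is not None:
        envelope = np.asarray(envelope, dtype=float)
        if envelope.shape != (n_samples,):
            raise ValueError("envelope length does not match n_samples")
        feats["envelope"] = envelope
    return StimulusFeatureSet(
        fs=fs, n_samples=n_samples, features=feats,
        stream_id=stream_id, trial_id=trial_id,
    )
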