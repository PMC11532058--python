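"""Beat detection, abnormal-beat rejection and multi-lead QRS delineation.

The segmentation strategy fuses information from all twelve leads twice:
R peaks are detected on the cross-lead RMS envelope of the per-lead
z-scored signals, and the QRS window of each beat is the union (earliest
onset, latest offset) of per-lead derivative-threshold walk-outs, so that
Q and S waves visible in only some leads are still included.  One
representative segment per lead is produced by averaging the retained
beats aligned on R and resampling to a fixed length.

Sample index conventions are 0-based and half-open throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import DegenerateRecordError, NoBeatsError, TooShortError
from .synth_ecg import EcgRecord

logger = logging.getLogger(__name__)

#: resampled segment length (~1 kHz equivalent for a 128 ms window)
SEGMENT_LENGTH = 128

_REFRACTORY_S = 0.200
_SEARCH_HALF_S = 0.150      # delineation search span around R
_QUIET_S = 0.012            # required quiet run to declare on/offset
_DERIV_FRACTION = 0.03      # walk-out threshold vs max |derivative| in span
_ONSET_GUARD_S = 0.008      # pad onset: Q and R flank slopes partly cancel
_CORR_WINDOW_S = 0.100      # half-window for beat-template correlation


@dataclass
class BeatSet:
    """Detected R peaks with keep/reject bookkeeping."""

    r_indices: np.ndarray                  # 0-based sample indices, increasing
    kept: np.ndarray                       # bool per beat
    reject_reasons: list[str | None]

    def __post_init__(self) -> None:
        self.r_indices = np.asarray(self.r_indices, dtype=int)
        self.kept = np.asarray(self.kept, dtype=bool)
        if np.any(np.diff(self.r_indices) <= 0):
            raise ValueError("R indices must be strictly increasing")
        if len(self.reject_reasons) != len(self.r_indices):
            raise ValueError("one reject reason slot per beat required")

    @property
    def kept_indices(self) -> np.ndarray:
        return self.r_indices[self.kept]

    @property
    def n_kept(self) -> int:
        return int(self.kept.sum())


@dataclass
class QrsSegment:
    """One representative, resampled QRS waveform for a single lead."""

    lead: str
    waveform: np.ndarray                   # length SEGMENT_LENGTH, mV
    onset: int                             # record sample index, half-open
    offset: int
    n_beats: int                           # beats averaged
    r_position: int                        # R-peak ordinal in the waveform
    source_fs: float

    def __post_init__(self) -> None:
        self.waveform = np.asarray(self.waveform, dtype=float)
        if self.offset <= self.onset:
            raise ValueError("offset must exceed onset")
        if self.waveform.shape != (SEGMENT_LENGTH,):
            raise ValueError(
                f"waveform must have length {SEGMENT_LENGTH}"
            )
        if not np.all(np.isfinite(self.waveform)):
            raise ValueError("waveform must be finite")


def detect_r_peaks(record: EcgRecord) -> BeatSet:
    """Locate R peaks on the cross-lead RMS envelope.

    Leads are z-scored first, so detection is invariant to per-lead gain.
    Peaks closer than 200 ms (ventricular refractory period) are merged by
    the peak finder; candidate peaks below 60% of the 90th-percentile peak
    height are discarded, which rejects P/T-wave envelope bumps while
    tolerating isolated outsized beats.

    Raises
    ------
    TooShortError
        If the record is shorter than 3 s.
    NoBeatsError
        If the record is flat or no peak survives thresholding.
    """
    if record.duration < 3.0:
        raise TooShortError("R detection needs at least 3 s of signal")
    x = record.data
    if np.max(np.abs(x)) < 1e-9:
        raise NoBeatsError("record is flat")
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd < 1e-12] = 1.0
    z = (x - mu) / sd
    envelope = np.sqrt(np.mean(z**2, axis=0))

    distance = max(1, int(round(_REFRACTORY_S * record.sampling_rate)))
    peaks, props = sps.find_peaks(envelope, distance=distance)
    if peaks.size == 0:
        raise NoBeatsError("no envelope peaks found")
    heights = envelope[peaks]
    thr = 0.6 * np.quantile(heights, 0.9)
    peaks = peaks[heights >= thr]
    if peaks.size == 0:
        raise NoBeatsError("no peaks above amplitude threshold")
    return BeatSet(
        r_indices=peaks,
        kept=np.ones(peaks.size, dtype=bool),
        reject_reasons=[None] * peaks.size,
    )


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa < 1e-12 and sb < 1e-12:
        return 1.0
    if sa < 1e-12 or sb < 1e-12:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def reject_abnormal_beats(
    record: EcgRecord, beats: BeatSet, min_correlation: float = 0.90
) -> BeatSet:
    """Flag beats that deviate from the beat-wise median template.

    A beat is rejected when, in at least one lead, its QRS window (R
    +/- 100 ms) correlates below ``min_correlation`` with the median
    waveform of all beats in that lead.  Beats whose window overruns the
    record edges are rejected with reason ``"edge"``.

    Raises
    ------
    DegenerateRecordError
        If fewer than 3 beats were detected or no beat survives.
    """
    if len(beats.r_indices) < 3:
        raise DegenerateRecordError("need at least 3 detected beats")
    half = int(round(_CORR_WINDOW_S * record.sampling_rate))
    n = record.n_samples
    reasons: list[str | None] = [None] * len(beats.r_indices)
    kept = np.ones(len(beats.r_indices), dtype=bool)

    in_range = []
    for b, r in enumerate(beats.r_indices):
        if r - half < 0 or r + half >= n:
            kept[b] = False
            reasons[b] = "edge"
        else:
            in_range.append(b)
    if len(in_range) == 0:
        raise DegenerateRecordError("all beats fall on record edges")

    # stack windows per lead: (n_leads, n_beats, window)
    idx = np.asarray(in_range)
    windows = np.stack(
        [
            np.stack(
                [record.data[li, r - half : r + half + 1]
                 for r in beats.r_indices[idx]]
            )
            for li in range(record.data.shape[0])
        ]
    )
    median_tpl = np.median(windows, axis=1)  # (n_leads, window)
    for j, b in enumerate(idx):
        worst = min(
            _safe_corr(windows[li, j], median_tpl[li])
            for li in range(windows.shape[0])
        )
        if worst < min_correlation:
            kept[b] = False
            reasons[b] = f"morphology (corr {worst:.3f} < {min_correlation})"
    if not kept.any():
        raise DegenerateRecordError("all beats rejected as abnormal")
    return BeatSet(r_indices=beats.r_indices, kept=kept, reject_reasons=reasons)


def _walk_out(
    quiet: np.ndarray, start: int, step: int, run: int
) -> int:
    """From ``start`` move by ``step`` until ``run`` consecutive quiet samples
    are seen; return the index where activity last ended (run edge nearest
    ``start``).  Falls back to the span edge if no quiet run exists."""
    count = 0
    i = start
    last = start
    while 0 <= i < quiet.size:
        if quiet[i]:
            count += 1
            if count >= run:
                return last
        else:
            count = 0
            last = i + step  # activity at i; boundary just beyond it
        i += step
    return int(np.clip(last, 0, quiet.size - 1))


def delineate_qrs(
    record: EcgRecord,
    beats: BeatSet,
    clamp_ms: tuple[float, float] = (40.0, 200.0),
) -> list[tuple[int, int]]:
    """Per-beat QRS windows fused across leads, half-open [onset, offset).

    For every kept beat and every lead, onset and offset are found by
    walking outward from R until the absolute derivative stays below a
    fraction of its in-span maximum for 12 ms in a row.  The fused onset
    is then padded left by a fixed 8 ms guard: near the Q onset the
    opposing Q and R flank slopes partially cancel, so the derivative
    criterion systematically fires late there, whereas near the offset
    the S and T slopes add and the criterion is already conservative.
    The beat's window is the earliest per-lead onset to the latest
    per-lead offset, then clamped to ``clamp_ms`` about R.  A warning is
    logged if more than half the beats hit the clamp.
    """
    if beats.n_kept == 0:
        raise DegenerateRecordError("no kept beats to delineate")
    fs = record.sampling_rate
    span = int(round(_SEARCH_HALF_S * fs))
    run = max(3, int(round(_QUIET_S * fs)))
    lo_w = int(round(clamp_ms[0] / 1000.0 * fs))
    hi_w = int(round(clamp_ms[1] / 1000.0 * fs))
    n = record.n_samples

    windows: list[tuple[int, int]] = []
    n_clamped = 0
    for r in beats.kept_indices:
        a, b = max(0, r - span), min(n, r + span + 1)
        onset_rec, offset_rec = r, r + 1
        for li in range(record.data.shape[0]):
            x = record.data[li, a:b]
            if x.size < 5:
                continue
            d = np.gradient(x)
            dmax = np.max(np.abs(d))
            if dmax < 1e-12:
                continue
            # noise floor: in-span median |d| estimates the derivative of the
            # noise, which would otherwise keep the walk from ever going quiet
            thr = max(_DERIV_FRACTION * dmax, 4.0 * float(np.median(np.abs(d))))
            quiet = np.abs(d) < thr
            rloc = r - a
            on = _walk_out(quiet, max(rloc - 1, 0), -1, run)
            off = _walk_out(quiet, min(rloc + 1, quiet.size - 1), +1, run)
            onset_rec = min(onset_rec, a + on)
            offset_rec = max(offset_rec, a + off)
        onset_rec -= int(round(_ONSET_GUARD_S * fs))
        width = offset_rec - onset_rec
        if width < lo_w or width > hi_w:
            n_clamped += 1
            target = int(np.clip(width, lo_w, hi_w))
            left = r - onset_rec
            right = offset_rec - r
            scale = target / width
            onset_rec = r - int(round(left * scale))
            offset_rec = onset_rec + target
        onset_rec = max(0, onset_rec)
        offset_rec = min(n, offset_rec)
        windows.append((int(onset_rec), int(offset_rec)))
    if n_clamped > 0.5 * len(windows):
        logger.warning(
            "QRS window clamp hit on %d/%d beats", n_clamped, len(windows)
        )
    return windows


def fuse_record_window(
    beats: BeatSet, windows: list[tuple[int, int]]
) -> tuple[int, int]:
    """Record-level QRS window relative to R: median per-beat extents."""
    rs = beats.kept_indices
    rel_on = int(round(np.median([w[0] - r for w, r in zip(windows, rs)])))
    rel_off = int(round(np.median([w[1] - r for w, r in zip(windows, rs)])))
    return rel_on, rel_off


def representative_segment(
    record: EcgRecord,
    beats: BeatSet,
    window: tuple[int, int],
    lead: str,
    m: int = SEGMENT_LENGTH,
) -> QrsSegment:
    """Average the kept beats of one lead and resample to ``m`` samples.

    ``window`` is (onset, offset) relative to R in source samples.  Each
    beat's baseline -- the mean of the 20 ms preceding its onset -- is
    subtracted before averaging; the average is then resampled by
    band-limited (FFT) interpolation.
    """
    rel_on, rel_off = window
    if rel_off <= rel_on:
        raise ValueError("window must satisfy offset > onset")
    fs = record.sampling_rate
    x = record.lead_signal(lead)
    base_n = max(1, int(round(0.020 * fs)))
    rows = []
    first_abs: tuple[int, int] | None = None
    for r in beats.kept_indices:
        a, b = r + rel_on, r + rel_off
        if a - base_n < 0 or b > x.size:
            continue
        seg = x[a:b] - x[a - base_n : a].mean()
        rows.append(seg)
        if first_abs is None:
            first_abs = (int(a), int(b))
    if not rows or first_abs is None:
        raise DegenerateRecordError(
            f"no beat window of lead {lead} fits inside the record"
        )
    avg = np.mean(rows, axis=0)
    wave = sps.resample(avg, m)
    r_pos = int(round((-rel_on) * m / (rel_off - rel_on)))
    return QrsSegment(
        lead=lead,
        waveform=wave,
        onset=first_abs[0],
        offset=first_abs[1],
        n_beats=len(rows),
        r_position=int(np.clip(r_pos, 0, m - 1)),
        source_fs=fs,
    )


def segment_record(
    record: EcgRecord, min_correlation: float = 0.90
) -> dict[str, QrsSegment]:
    """Full chain: detect -> reject -> delineate -> one segment per lead."""
    beats = detect_r_peaks(record)
    if len(beats.r_indices) >= 3:
        beats = reject_abnormal_beats(record, beats, min_correlation)
    windows = delineate_qrs(record, beats)
    window = fuse_record_window(beats, windows)
    return {
        lead: representative_segment(record, beats, window, lead)
        for lead in record.leads
    }
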