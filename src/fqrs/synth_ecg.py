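"""Synthetic 12-lead ECG generation with controllable QRS fragmentation.

Beats are modelled as sums of Gaussian waves (P, Q, R, S, T).  The twelve
leads are coherent projections of a three-component dipole: each wave has a
3-vector moment and each lead a fixed projection row, so amplitudes are
correlated across leads as in a real surface ECG.  Fragmentation is injected
as narrow extra Gaussian deflections strictly inside the QRS support, with
amplitude scaled by a severity parameter in [0, 1]; a panel of five binary
annotators with logistic response in severity produces the 0-5 agreement
scores used as classifier ground truth.

All generators are pure functions of their parameters and a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InvalidParameterError, TooShortError

LEAD_NAMES: tuple[str, ...] = (
    "I", "II", "III", "aVR", "aVL", "aVF",
    "V1", "V2", "V3", "V4", "V5", "V6",
)

# Lead projection rows of the dipole model: columns are (x = leftward,
# y = inferior, z = anterior).  Limb leads lie in the frontal (x, y) plane at
# their conventional angles; precordial rows rotate from right-anterior (V1)
# to left-lateral (V6).
LEAD_PROJECTION: dict[str, tuple[float, float, float]] = {
    "I": (1.00, 0.00, 0.00),
    "II": (0.50, 0.87, 0.00),
    "III": (-0.50, 0.87, 0.00),
    "aVR": (-0.75, -0.43, 0.00),
    "aVL": (0.75, -0.43, 0.00),
    "aVF": (0.00, 1.00, 0.00),
    "V1": (-0.52, 0.06, 0.85),
    "V2": (-0.26, 0.10, 0.96),
    "V3": (0.10, 0.18, 0.98),
    "V4": (0.45, 0.27, 0.85),
    "V5": (0.73, 0.25, 0.63),
    "V6": (0.90, 0.20, 0.38),
}

# Dipole moments (mV per unit projection), centers (s relative to the R peak)
# and Gaussian widths (s) of the five waves.
WAVE_MOMENTS: dict[str, tuple[tuple[float, float, float], float, float]] = {
    "P": ((0.10, 0.22, 0.05), -0.200, 0.025),
    "Q": ((-0.16, -0.18, -0.08), -0.028, 0.009),
    "R": ((0.91, 0.98, 0.42), 0.000, 0.016),
    "S": ((-0.08, -0.12, -0.50), 0.030, 0.012),
    "T": ((0.30, 0.30, 0.25), 0.320, 0.060),
}

QRS_WAVES = ("Q", "R", "S")
_SUPPORT_SIGMA = 3.0  # QRS support extends 3 sigma beyond outermost Q/S wave


@dataclass(frozen=True)
class Wave:
    """One Gaussian component: ``amplitude * exp(-(t - center)^2 / 2 width^2)``."""

    amplitude: float  # mV
    center: float     # s relative to R peak
    width: float      # s (Gaussian sigma)

    def __post_init__(self) -> None:
        if not np.isfinite(self.amplitude):
            raise InvalidParameterError("wave amplitude must be finite")
        if not (self.width > 0):
            raise InvalidParameterError(
                f"wave width must be > 0, got {self.width}"
            )


@dataclass(frozen=True)
class LeadTemplate:
    """Single-beat waveform template for one lead.

    ``waves`` holds the named P/Q/R/S/T components; ``notches`` holds extra
    intra-QRS deflections from fragmentation injection.  Notches are windowed
    to the QRS support so that fragmentation never alters samples outside it.
    """

    lead: str
    waves: dict[str, Wave]
    notches: tuple[Wave, ...] = ()

    def __post_init__(self) -> None:
        if self.lead not in LEAD_NAMES:
            raise InvalidParameterError(f"unknown lead name {self.lead!r}")
        if "R" not in self.waves or self.waves["R"].amplitude == 0:
            raise InvalidParameterError("R component amplitude must be nonzero")

    def qrs_support(self) -> tuple[float, float]:
        """Analytic QRS support [onset, offset] in seconds relative to R.

        The support spans 3 sigma around every nonzero Q/R/S component.
        """
        lo, hi = np.inf, -np.inf
        for name in QRS_WAVES:
            w = self.waves.get(name)
            if w is None or w.amplitude == 0:
                continue
            lo = min(lo, w.center - _SUPPORT_SIGMA * w.width)
            hi = max(hi, w.center + _SUPPORT_SIGMA * w.width)
        return float(lo), float(hi)

    def qrs_peak_to_peak(self) -> float:
        lo, hi = self.qrs_support()
        t = np.linspace(lo, hi, 2049)
        y = self.evaluate(t)
        return float(y.max() - y.min())

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        """Evaluate the template (mV) on a time grid (s relative to R)."""
        t = np.asarray(t, dtype=float)
        y = np.zeros_like(t)
        for w in self.waves.values():
            y += w.amplitude * np.exp(-0.5 * ((t - w.center) / w.width) ** 2)
        if self.notches:
            lo, hi = self.qrs_support()
            inside = (t >= lo) & (t <= hi)
            for w in self.notches:
                y[inside] += w.amplitude * np.exp(
                    -0.5 * ((t[inside] - w.center) / w.width) ** 2
                )
        return y


@dataclass(frozen=True)
class FragmentationSpec:
    """Ground-truth description of injected QRS fragmentation.

    severity scales notch amplitude; severity 0 means no fragmentation and
    therefore no notches (and vice versa).
    """

    severity: float = 0.0
    n_notches: int = 0
    notch_width: float = 0.0025         # s; sharp enough to outrun QRS flanks
    notch_fraction: float = 0.15        # of QRS peak-to-peak, at severity 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.severity <= 1.0):
            raise InvalidParameterError("severity must be in [0, 1]")
        if self.n_notches < 0:
            raise InvalidParameterError("n_notches must be >= 0")
        if (self.severity == 0) != (self.n_notches == 0):
            raise InvalidParameterError(
                "severity = 0 if and only if n_notches = 0 "
                f"(got severity={self.severity}, n_notches={self.n_notches})"
            )
        if self.notch_width <= 0 or not (0 < self.notch_fraction <= 1):
            raise InvalidParameterError("invalid notch geometry")

    @staticmethod
    def from_severity(severity: float, seed: int = 0) -> "FragmentationSpec":
        """Convenience constructor: 3 notches whenever severity > 0."""
        n = 0 if severity == 0 else 3
        return FragmentationSpec(severity=severity, n_notches=n, seed=seed)


def generate_beat_template(
    morphology_params: dict[str, tuple[float, float, float]],
    lead: str = "II",
) -> LeadTemplate:
    """Build a LeadTemplate from ``{wave name: (amplitude, center, width)}``.

    Raises
    ------
    InvalidParameterError
        On non-positive widths or non-finite amplitudes.
    """
    waves = {
        name: Wave(amplitude=a, center=c, width=w)
        for name, (a, c, w) in morphology_params.items()
    }
    return LeadTemplate(lead=lead, waves=waves)


def default_templates(
    amplitude_scale: float = 1.0,
) -> dict[str, LeadTemplate]:
    """The standard coherent 12-lead template set from the dipole projection."""
    out: dict[str, LeadTemplate] = {}
    for lead in LEAD_NAMES:
        row = np.asarray(LEAD_PROJECTION[lead])
        waves = {}
        for name, (moment, center, width) in WAVE_MOMENTS.items():
            amp = amplitude_scale * float(row @ np.asarray(moment))
            if name == "R" and amp == 0.0:
                amp = 1e-3  # dipole row orthogonal to R moment; keep R nonzero
            waves[name] = Wave(amplitude=amp, center=center, width=width)
        out[lead] = LeadTemplate(lead=lead, waves=waves)
    return out


def inject_fragmentation(
    template: LeadTemplate, spec: FragmentationSpec
) -> LeadTemplate:
    """Return a new template with intra-QRS notches added per ``spec``.

    Notch centers are drawn without collision strictly inside the QRS
    support (3 notch-widths from either edge); signs alternate starting from
    a random sign; amplitude is ``notch_fraction * severity * QRS
    peak-to-peak``.  The input template is not modified.
    """
    if spec.n_notches == 0:
        return template
    lo, hi = template.qrs_support()
    if not np.isfinite(lo) or hi <= lo:
        raise InvalidParameterError("template has no QRS support")
    p2p = template.qrs_peak_to_peak()
    if p2p <= 0:
        raise InvalidParameterError("template QRS is flat")

    rng = np.random.default_rng(spec.seed)
    margin = 3.0 * spec.notch_width
    a, b = lo + margin, hi - margin
    if b <= a:
        a, b = lo + 0.1 * (hi - lo), hi - 0.1 * (hi - lo)
    # stratified draw -> distinct, well-separated centers
    edges = np.linspace(a, b, spec.n_notches + 1)
    centers = edges[:-1] + rng.uniform(0.15, 0.85, spec.n_notches) * np.diff(edges)
    first_sign = rng.choice([-1.0, 1.0])
    amp = spec.notch_fraction * spec.severity * p2p
    notches = tuple(
        Wave(
            amplitude=first_sign * (-1.0) ** k * amp,
            center=float(c),
            width=spec.notch_width,
        )
        for k, c in enumerate(centers)
    )
    return replace(template, notches=template.notches + notches)


@dataclass(frozen=True)
class NoiseParams:
    """Additive disturbances: baseline wander, powerline hum, white noise."""

    baseline_amplitude: float = 0.05   # mV
    baseline_frequency: float = 0.30   # Hz, must stay below 0.5 Hz
    powerline_amplitude: float = 0.01  # mV
    powerline_frequency: float = 50.0  # Hz
    white_sd: float = 0.01             # mV

    def __post_init__(self) -> None:
        if self.baseline_frequency >= 0.5:
            raise InvalidParameterError("baseline wander must be < 0.5 Hz")
        if min(self.baseline_amplitude, self.powerline_amplitude,
               self.white_sd) < 0:
            raise InvalidParameterError("noise amplitudes must be >= 0")

    @staticmethod
    def none() -> "NoiseParams":
        return NoiseParams(0.0, 0.3, 0.0, 50.0, 0.0)


@dataclass
class EcgRecord:
    """A synchronized 12-lead recording with optional fragmentation truth."""

    sampling_rate: float                       # Hz
    duration: float                            # s
    data: np.ndarray                           # (12, N) mV
    leads: tuple[str, ...] = LEAD_NAMES
    mean_rr: float = 1.0                       # s
    fragmentation: dict[str, FragmentationSpec] = field(default_factory=dict)
    r_times: np.ndarray | None = None          # true R-peak times (s), if known
    record_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape[0] != len(self.leads):
            raise InvalidParameterError("one data row per lead required")
        if np.isnan(self.data).any():
            raise InvalidParameterError("record contains NaN samples")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def lead_signal(self, lead: str) -> np.ndarray:
        return self.data[self.leads.index(lead)]

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate


def generate_ecg12(
    templates: dict[str, LeadTemplate],
    frag: dict[str, FragmentationSpec] | None = None,
    noise: NoiseParams = NoiseParams(),
    duration: float = 10.0,
    fs: float = 250.0,
    mean_rr: float = 1.0,
    rr_jitter: float = 0.03,
    seed: int = 0,
    record_id: str = "",
) -> EcgRecord:
    """Generate a 12-lead record by tiling beats at jittered RR intervals.

    Beats start ~0.5 s into the record and stop 0.35 s before its end so the
    T wave fits.  Fragmentation specs, when given, replace the clean template
    of the corresponding lead via :func:`inject_fragmentation`.

    Raises
    ------
    TooShortError
        If the duration holds fewer than 3 RR intervals.
    InvalidParameterError
        If fs < 100 Hz or a lead template is missing.
    """
    if fs < 100:
        raise InvalidParameterError("sampling rate must be >= 100 Hz")
    if duration < 3 * mean_rr:
        raise TooShortError(
            f"duration {duration} s holds fewer than 3 RR intervals of {mean_rr} s"
        )
    missing = [ld for ld in LEAD_NAMES if ld not in templates]
    if missing:
        raise InvalidParameterError(f"missing templates for leads {missing}")

    rng = np.random.default_rng(seed)
    frag = frag or {}

    # R-peak placement: fixed start, jittered intervals
    r_times = [0.5]
    while True:
        rr = mean_rr * (1.0 + rr_jitter * float(np.clip(rng.standard_normal(), -3, 3)))
        nxt = r_times[-1] + rr
        if nxt > duration - 0.35:
            break
        r_times.append(nxt)
    r_times_arr = np.asarray(r_times)

    n = int(round(duration * fs))
    t = np.arange(n) / fs
    data = np.empty((len(LEAD_NAMES), n))
    frag_truth: dict[str, FragmentationSpec] = {}
    for i, lead in enumerate(LEAD_NAMES):
        tpl = templates[lead]
        spec = frag.get(lead)
        if spec is not None and spec.n_notches > 0:
            tpl = inject_fragmentation(tpl, spec)
        if spec is not None:
            frag_truth[lead] = spec
        sig = np.zeros(n)
        for r in r_times_arr:
            sig += tpl.evaluate(t - r)
        if noise.baseline_amplitude > 0:
            sig += noise.baseline_amplitude * np.sin(
                2 * np.pi * noise.baseline_frequency * t + rng.uniform(0, 2 * np.pi)
            )
        if noise.powerline_amplitude > 0:
            sig += noise.powerline_amplitude * np.sin(
                2 * np.pi * noise.powerline_frequency * t + rng.uniform(0, 2 * np.pi)
            )
        if noise.white_sd > 0:
            sig += noise.white_sd * rng.standard_normal(n)
        data[i] = sig

    return EcgRecord(
        sampling_rate=fs,
        duration=duration,
        data=data,
        mean_rr=mean_rr,
        fragmentation=frag_truth,
        r_times=r_times_arr,
        record_id=record_id,
    )


# ---------------------------------------------------------------------------
# Annotator panel
# ---------------------------------------------------------------------------

def _logit(p: float) -> float:
    p = min(max(p, 1e-12), 1 - 1e-12)
    return float(np.log(p / (1 - p)))


@dataclass(frozen=True)
class AnnotatorModel:
    """Five binary annotators with logistic response to fragmentation severity.

    Each annotator i votes "fragmented" with probability that interpolates,
    linearly on the logit scale, from a false-positive rate ``1 -
    specificity_i`` at severity 0 up to ``sensitivity_i`` at severity 1.
    The defaults bracket the operating range of trained human readers of
    fragmentation (sensitivity ~0.76, specificity ~0.92).
    """

    sensitivities: tuple[float, ...] = (0.80, 0.76, 0.72, 0.85, 0.78)
    specificities: tuple[float, ...] = (0.92, 0.94, 0.90, 0.93, 0.91)

    def __post_init__(self) -> None:
        if len(self.sensitivities) != 5 or len(self.specificities) != 5:
            raise InvalidParameterError("exactly five annotators required")
        for v in (*self.sensitivities, *self.specificities):
            if not (0.0 < v <= 1.0):
                raise InvalidParameterError(
                    "operating points must lie in (0, 1]"
                )

    @staticmethod
    def perfect() -> "AnnotatorModel":
        return AnnotatorModel((1.0,) * 5, (1.0,) * 5)

    def vote_probabilities(self, severity: float) -> np.ndarray:
        """P(vote = 1 | severity) for each annotator; exact at the endpoints."""
        if not (0.0 <= severity <= 1.0):
            raise InvalidParameterError("severity must be in [0, 1]")
        out = np.empty(5)
        for i, (sens, spec) in enumerate(
            zip(self.sensitivities, self.specificities)
        ):
            p0, p1 = 1.0 - spec, sens
            if severity == 0.0:
                out[i] = p0
            elif severity == 1.0:
                out[i] = p1
            else:
                l0, l1 = _logit(p0), _logit(p1)
                out[i] = 1.0 / (1.0 + np.exp(-(l0 + severity * (l1 - l0))))
        return out


@dataclass(frozen=True)
class AgreementLabel:
    """Per-lead annotation: five binary votes and their sum (0-5)."""

    votes: tuple[int, ...]
    score: int

    def __post_init__(self) -> None:
        if len(self.votes) != 5 or any(v not in (0, 1) for v in self.votes):
            raise InvalidParameterError("exactly five binary votes required")
        if self.score != sum(self.votes):
            raise InvalidParameterError("score must equal the sum of votes")

    @property
    def full_agreement(self) -> bool:
        """True for the scores (0 or 5) used as classifier ground truth."""
        return self.score in (0, 5)


def simulate_annotators(
    frag: FragmentationSpec | float,
    model: AnnotatorModel = AnnotatorModel(),
    seed: int = 0,
) -> AgreementLabel:
    """Draw five binary votes for one lead given its fragmentation severity."""
    severity = frag.severity if isinstance(frag, FragmentationSpec) else float(frag)
    rng = np.random.default_rng(seed)
    p = model.vote_probabilities(severity)
    votes = tuple(int(v) for v in (rng.random(5) < p))
    return AgreementLabel(votes=votes, score=sum(votes))
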