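"""Multi-subject synthetic PPG generator.

Each subject owns a beat template built from two Gaussian bumps on a
positive baseline: a systolic upstroke and a smaller diastolic bump that
stands in for the dicrotic-notch region.  Records concatenate beats with
per-beat period and amplitude jitter, add a slow sinusoidal baseline drift
and white noise, and stay strictly positive so the detrending division is
always safe.  Ground-truth beat onsets are returned alongside each record
for test oracles only; the processing pipeline never sees them.

The defaults emulate short wearable-style recordings: 6 s at 50 Hz, resting
heart rates, mild drift and noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from ._rng import substream
from .records import DatasetManifest, ManifestEntry, SignalRecord, save_manifest, write_record

# Population beat template; per-subject parameters are drawn in windows of
# width separability * (half-range) around these centres.
# The subject draw is parameterised by the systolic bump, the systolic-to-
# diastolic *gap* and the diastolic/systolic amplitude *ratio* (rather than
# independent diastolic position and amplitude): with these ranges the
# dicrotic notch stays a shoulder above the local mean for every admissible
# subject, as in real wrist PPG, so detrending never turns it into a false
# foot.
_POP = dict(
    sys_amp=1.0, sys_center=0.28, sys_width=0.14, sys_skew=0.25,
    gap=0.27, dia_ratio=0.45, dia_width=0.20,
    baseline=3.6, period=0.72,
)
_HALF_RANGE = dict(
    sys_amp=0.50, sys_center=0.08, sys_width=0.03, sys_skew=0.20,
    gap=0.05, dia_ratio=0.20, dia_width=0.06,
    baseline=0.9, period=0.08,
)
_NOTCH_WIDTH_FLOOR = 0.42  # dia_width >= floor * gap keeps the notch shallow


@dataclass(frozen=True)
class SubjectTemplate:
    """Beat morphology of one synthetic subject.

    Centers and widths are fractions of the heart period; amplitudes share
    the (arbitrary) unit of the baseline level.  ``sys_skew`` in [0, 1)
    makes the systolic bump asymmetric — upstroke width w·(1−skew), decay
    width w·(1+skew) — emulating the fast anacrotic rise and slower
    catacrotic fall of real pulses.
    """

    subject_id: str
    systolic: tuple[float, float, float]   # (amplitude, center frac, width frac)
    diastolic: tuple[float, float, float]
    baseline_level: float
    mean_period_s: float
    sys_skew: float = 0.25

    def __post_init__(self):
        s_amp, s_c, s_w = self.systolic
        d_amp, d_c, d_w = self.diastolic
        if not (0.0 < s_c < d_c < 1.0):
            raise ValueError("need 0 < systolic center < diastolic center < 1")
        if min(s_amp, d_amp, s_w, d_w) <= 0:
            raise ValueError("amplitudes and widths must be positive")
        if not 0.0 <= self.sys_skew < 1.0:
            raise ValueError("sys_skew must lie in [0, 1)")
        if not self.baseline_level > s_amp + d_amp:
            raise ValueError("baseline must exceed the total pulse amplitude")
        if not self.mean_period_s > 0:
            raise ValueError("mean_period_s must be positive")


@dataclass(frozen=True)
class NoiseSpec:
    """Additive and timing disturbances applied when rendering a record."""

    white_sd: float = 0.02
    drift_amplitude: float = 0.15
    drift_period_s: float = 5.0
    period_jitter_sd_s: float = 0.02
    amplitude_jitter_frac: float = 0.05

    def __post_init__(self):
        vals = (self.white_sd, self.drift_amplitude, self.period_jitter_sd_s,
                self.amplitude_jitter_frac)
        if any(v < 0 for v in vals) or not self.drift_period_s > 0:
            raise ValueError("noise parameters must be non-negative (drift period positive)")

    @classmethod
    def silent(cls) -> "NoiseSpec":
        return cls(0.0, 0.0, 5.0, 0.0, 0.0)


def sample_subject(rng: np.random.Generator, subject_id: str, separability: float = 0.8) -> SubjectTemplate:
    """Draw one subject's beat parameters.

    ``separability`` in [0, 1] scales the width of every parameter window:
    0 gives the identical population template to all subjects, 1 the widest
    morphological spread.
    """
    if not 0.0 <= separability <= 1.0:
        raise ValueError("separability must lie in [0, 1]")
    draw = {k: _POP[k] + separability * _HALF_RANGE[k] * rng.uniform(-1.0, 1.0) for k in _POP}
    dia_center = draw["sys_center"] + draw["gap"]
    dia_amp = draw["dia_ratio"] * draw["sys_amp"]
    dia_width = max(draw["dia_width"], _NOTCH_WIDTH_FLOOR * draw["gap"])
    return SubjectTemplate(
        subject_id=subject_id,
        systolic=(draw["sys_amp"], draw["sys_center"], draw["sys_width"]),
        diastolic=(dia_amp, dia_center, dia_width),
        baseline_level=draw["baseline"],
        mean_period_s=draw["period"],
        sys_skew=draw["sys_skew"],
    )


def _beat_contribution(t: np.ndarray, onset: float, period: float,
                       template: SubjectTemplate, scale: float) -> np.ndarray:
    """Pulse waveform of a single beat evaluated at times ``t`` (baseline-free)."""
    s_amp, s_c, s_w = template.systolic
    mu = onset + s_c * period
    sd = np.where(t < mu, s_w * (1.0 - template.sys_skew),
                  s_w * (1.0 + template.sys_skew)) * period
    out = scale * s_amp * np.exp(-0.5 * ((t - mu) / sd) ** 2)
    d_amp, d_c, d_w = template.diastolic
    mu_d = onset + d_c * period
    out += scale * d_amp * np.exp(-0.5 * ((t - mu_d) / (d_w * period)) ** 2)
    return out


def render_record(template: SubjectTemplate, noise: NoiseSpec, duration_s: float,
                  sampling_rate_hz: float, rng: np.random.Generator,
                  record_id: str = "rec") -> tuple[SignalRecord, np.ndarray]:
    """Render one record and its ground-truth beat onsets.

    Beats are laid down from t = 0 with per-beat period jitter and
    amplitude jitter; each sample receives contributions from its own beat
    and both neighbours (Gaussian tails), then sinusoidal drift and white
    noise are added on top of the subject baseline.

    Returns ``(record, onset_sample_indices)``.  Each onset marks the foot
    of one beat inside the record: the local minimum of the *clean* pulse
    train (no drift, no noise) near the beat's nominal start, which is the
    ground truth a foot detector should recover.
    """
    if not duration_s > template.mean_period_s:
        raise ValueError("duration must exceed one heart period")
    n = int(round(duration_s * sampling_rate_hz))
    t = np.arange(n) / sampling_rate_hz

    onsets = [0.0]
    while onsets[-1] <= duration_s + template.mean_period_s:
        jitter = rng.normal(0.0, noise.period_jitter_sd_s) if noise.period_jitter_sd_s else 0.0
        onsets.append(onsets[-1] + max(template.mean_period_s + jitter, 0.25))

    clean = np.full(n, template.baseline_level)
    scales = 1.0 + (rng.normal(0.0, noise.amplitude_jitter_frac, len(onsets) - 1)
                    if noise.amplitude_jitter_frac else np.zeros(len(onsets) - 1))
    for k in range(len(onsets) - 1):
        period_k = onsets[k + 1] - onsets[k]
        clean += _beat_contribution(t, onsets[k], period_k, template, scales[k])

    # ground-truth feet: clean-signal minima within a fifth of a period of
    # each nominal beat start
    half = 0.2 * template.mean_period_s
    feet: list[int] = []
    for o in onsets:
        lo = max(int(round((o - half) * sampling_rate_hz)), 0)
        hi = min(int(round((o + half) * sampling_rate_hz)) + 1, n)
        if hi - lo < 1:
            continue
        idx = lo + int(np.argmin(clean[lo:hi]))
        if idx < n and (not feet or idx > feet[-1]):
            feet.append(idx)

    signal = clean.copy()
    if noise.drift_amplitude:
        phase = rng.uniform(0.0, 2.0 * np.pi)
        signal += noise.drift_amplitude * np.sin(2.0 * np.pi * t / noise.drift_period_s + phase)
    if noise.white_sd:
        signal += rng.normal(0.0, noise.white_sd, n)

    record = SignalRecord(signal, sampling_rate_hz, template.subject_id, record_id)
    return record, np.asarray(feet, dtype=int)


def complete_beats(template: SubjectTemplate, onset_idx: np.ndarray,
                   duration_s: float, sampling_rate_hz: float) -> int:
    """Number of beats whose full period fits inside the record."""
    ends = onset_idx / sampling_rate_hz + template.mean_period_s
    return int(np.sum(ends <= duration_s + 1e-9))


def template_cycle(template: SubjectTemplate, n_points: int) -> np.ndarray:
    """The noiseless foot-to-foot beat waveform sampled at ``n_points``.

    The exact periodic pulse train (with the Gaussian tails of the
    neighbouring beats) is evaluated on a fine grid, its foot minimum is
    located, and one full period starting at that foot is sampled — the
    same span segmentation extracts from a rendered record.  Used as the
    ground-truth reference in round-trip tests.
    """
    p = template.mean_period_s

    def train_at(t):
        out = np.full_like(t, template.baseline_level)
        for onset in (-p, 0.0, p, 2.0 * p):
            out += _beat_contribution(t, onset, p, template, 1.0)
        return out

    fine = np.linspace(-0.3 * p, 0.3 * p, 2001)
    t_foot = fine[int(np.argmin(train_at(fine)))]
    return train_at(np.linspace(t_foot, t_foot + p, n_points))


def generate_dataset(out_dir, n_subjects: int, records_per_subject_train: int,
                     records_per_subject_test: int, noise: NoiseSpec | None = None,
                     separability: float = 0.8, seed: int = 0,
                     duration_s: float = 6.0, sampling_rate_hz: float = 50.0) -> DatasetManifest:
    """Write a full synthetic dataset: record files, manifest, onset sidecar.

    The split is within-subject across records — every subject appears in
    both train and test — because verification pairing needs each enrolled
    subject represented in the test gallery.  Deterministic per seed,
    byte for byte.

    Subject heart periods are capped so that every 6 s record contains at
    least six complete cycles (enough for a five-cycle average); longer
    durations relax nothing.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    noise = noise if noise is not None else NoiseSpec()
    out_dir = Path(out_dir)
    rec_dir = out_dir / "records"
    rec_dir.mkdir(parents=True, exist_ok=True)
    rng = substream(seed, "data")

    entries: list[ManifestEntry] = []
    onsets_by_record: dict[str, list[int]] = {}
    max_period = duration_s / 7.5  # >= 6 complete cycles per record
    for s in range(n_subjects):
        sid = f"S{s:03d}"
        template = sample_subject(rng, sid, separability)
        if template.mean_period_s > max_period:
            template = replace(template, mean_period_s=max_period)
        for split, count in (("train", records_per_subject_train), ("test", records_per_subject_test)):
            for r in range(count):
                rid = f"{sid}_{split}{r:03d}"
                record, onset_idx = render_record(template, noise, duration_s,
                                                  sampling_rate_hz, rng, rid)
                path = rec_dir / f"{rid}.txt"
                write_record(record, path)
                entries.append(ManifestEntry(path, sid, rid, split))
                onsets_by_record[rid] = [int(i) for i in onset_idx]

    manifest = DatasetManifest(entries)
    save_manifest(manifest, out_dir / "manifest.tsv")
    (out_dir / "onsets.json").write_text(json.dumps(onsets_by_record, indent=0, sort_keys=True),
                                         encoding="utf-8")
    return manifest
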