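"""Parametric synthetic 12-lead ECG generator with exact ground truth.

Each heartbeat is a sum of five Gaussian bumps (P, Q, R, S, T) plus an
ST-segment plateau with raised-cosine edges.  Because the beat is a closed
form, the true fiducial sample indices (QRS onset "I point", Q, R, S,
J point, T onset/peak/end, P) are known exactly, which makes delineation
and feature-recovery tests possible without annotated clinical data.

Myocardial-infarction classes differ by *which leads* carry an abnormal
morphology (abnormal Q, ST elevation/depression, hyperacute or inverted T),
mirroring the clinical lead groupings used to localize an infarct.  The
lead assignment is a documented constant, not a claim of clinical fidelity.

Classes: 8 infarct localizations (A anterior, AL anterolateral,
AS anteroseptal, I inferior, IL inferolateral, IP inferoposterior,
IPL inferoposterolateral, P posterior) plus H (healthy) and O (other
cardiac disease, non-MI).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np

LEAD_NAMES = ["I", "II", "III", "aVR", "aVL", "aVF",
              "V1", "V2", "V3", "V4", "V5", "V6"]

#: Fixed class order (matches the reporting convention of the evaluator).
CLASS_LABELS = ["A", "AS", "AL", "I", "IL", "IP", "IPL", "P", "H", "O"]

FIDUCIAL_NAMES = ["P", "I", "Q", "R", "S", "J", "Tstart", "T", "Tend"]


@dataclass(frozen=True)
class Wave:
    """One Gaussian bump: ``amp * exp(-(t - center)^2 / (2 width^2))``.

    ``center`` is in seconds relative to the R peak; ``amp`` in mV (signed);
    ``width`` is the Gaussian sigma in seconds.
    """

    center: float
    amp: float
    width: float

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError("wave width must be positive")


@dataclass(frozen=True)
class BeatMorphology:
    """Complete parametric description of one beat on one lead."""

    p: Wave
    q: Wave
    r: Wave
    s: Wave
    t: Wave
    st_offset: float  # mV, plateau height between J point and T end
    label: str

    def __post_init__(self):
        if self.r.amp <= 0:
            raise ValueError("R amplitude must be positive")
        if self.label == "H":
            if self.st_offset != 0:
                raise ValueError("healthy beats have no ST shift")
            if abs(self.q.amp) >= 0.25 * self.r.amp:
                raise ValueError("healthy Q must stay below 25% of R")
            if self.t.amp <= 0:
                raise ValueError("healthy T must be upright")


@dataclass(frozen=True)
class RecordConfig:
    """Knobs for a multi-beat, multi-lead synthetic record."""

    n_beats: int = 10
    fs: float = 1000.0
    mean_rr: float = 0.8
    rr_jitter_sd: float = 0.0
    lead_gain: tuple = (1.0,) * 12
    baseline_amp: float = 0.0   # mV
    baseline_freq: float = 0.3  # Hz
    noise_sd: float = 0.0       # mV
    seed: int = 0

    def __post_init__(self):
        if self.fs < 250:
            raise ValueError("sampling rate must be at least 250 Hz")
        if self.mean_rr <= 0:
            raise ValueError("mean RR must be positive")
        if self.n_beats < 1:
            raise ValueError("need at least one beat")
        if len(self.lead_gain) != len(LEAD_NAMES):
            raise ValueError("lead_gain must have 12 entries")


# --------------------------------------------------------------------------
# Archetypes.  Baseline (normal) wave parameters, then named overrides for
# the abnormal morphologies: ste = ST elevation + hyperacute (tall) T,
# ste_ti = ST elevation + inverted T, qab = abnormal (deep, wide) Q,
# q_ti = abnormal Q + inverted T, q_ste = abnormal Q + ST elevation,
# std = ST depression + tall R + tall T (the reciprocal posterior pattern),
# other = non-MI abnormality (broadened QRS, flattened T).
# --------------------------------------------------------------------------

NORMAL_WAVES = {
    "p": Wave(-0.200, 0.12, 0.025),
    "q": Wave(-0.048, -0.10, 0.010),
    "r": Wave(0.000, 1.00, 0.016),
    "s": Wave(0.048, -0.15, 0.012),
    "t": Wave(0.300, 0.30, 0.055),
}

ARCHETYPES: dict[str, dict] = {
    "normal": {},
    "ste":    {"st_offset": 0.25, "t_amp": 0.55},
    "ste_ti": {"st_offset": 0.15, "t_amp": -0.50},
    "qab":    {"q_amp": -0.45, "q_width": 0.020, "q_center": -0.055},
    "q_ti":   {"q_amp": -0.45, "q_width": 0.020, "q_center": -0.055,
               "t_amp": -0.40},
    "q_ste":  {"q_amp": -0.45, "q_width": 0.020, "q_center": -0.055,
               "st_offset": 0.25, "t_amp": 0.55},
    "std":    {"st_offset": -0.20, "t_amp": 0.55, "r_amp": 1.30},
    "other":  {"s_width": 0.020, "t_amp": 0.18},
}

#: Which abnormal archetype appears on which leads, per class.  Leads not
#: listed carry the normal morphology of the same beat.
LEAD_PATTERNS: dict[str, dict[str, str]] = {
    "A":   {ld: "ste" for ld in ("V1", "V2", "V3", "V4")},
    "AS":  {ld: "q_ste" for ld in ("V1", "V2", "V3")},
    "AL":  {ld: "ste_ti" for ld in ("I", "aVL", "V4", "V5", "V6")},
    "I":   {ld: "q_ti" for ld in ("II", "III", "aVF")},
    "IL":  {ld: "ste" for ld in ("II", "III", "aVF", "V5", "V6")},
    "IP":  {**{ld: "ste" for ld in ("II", "III", "aVF")},
            **{ld: "std" for ld in ("V1", "V2")}},
    "IPL": {**{ld: "q_ste" for ld in ("II", "III", "aVF", "V5", "V6")},
            **{ld: "std" for ld in ("V1", "V2")}},
    "P":   {ld: "std" for ld in ("V1", "V2", "V3")},
    "H":   {},
    "O":   {ld: "other" for ld in LEAD_NAMES},
}

#: The archetype reported by :func:`morphology_for_class` — the abnormality
#: carried by the class's affected leads ("normal" for H).
PRIMARY_ARCHETYPE = {
    "A": "ste", "AS": "q_ste", "AL": "ste_ti", "I": "q_ti", "IL": "ste",
    "IP": "ste", "IPL": "q_ste", "P": "std", "H": "normal", "O": "other",
}

# ST plateau edge widths (s): raised-cosine rise finishing exactly at the
# J point and fall starting at T end, so the plateau holds its full height
# on [J, Tend] and J-point elevation equals st_offset.
ST_RISE = 0.030
ST_FALL = 0.030


def _check_label(label: str) -> None:
    if label not in CLASS_LABELS:
        raise ValueError(
            f"unknown beat class {label!r}; expected one of {CLASS_LABELS}")


def _apply_archetype(waves: dict[str, Wave], arch: str) -> tuple[dict, float]:
    over = ARCHETYPES[arch]
    out = dict(waves)
    for wname in ("p", "q", "r", "s", "t"):
        kw = {}
        for attr in ("center", "amp", "width"):
            key = f"{wname}_{attr}"
            if key in over:
                kw[attr] = over[key]
        if kw:
            out[wname] = replace(out[wname], **kw)
    return out, over.get("st_offset", 0.0)


def _jitter_waves(waves: dict[str, Wave], timing_f: dict, amp_f: dict):
    """Apply shared per-beat multiplicative jitter factors."""
    return {
        name: Wave(w.center * timing_f["center"],
                   w.amp * amp_f[name],
                   w.width * timing_f["width"])
        for name, w in waves.items()
    }


def _draw_jitter(rng: np.random.Generator):
    timing_f = {"center": 1.0 + rng.uniform(-0.05, 0.05),
                "width": 1.0 + rng.uniform(-0.08, 0.08)}
    amp_f = {n: 1.0 + rng.uniform(-0.10, 0.10) for n in ("p", "q", "r", "s", "t")}
    return timing_f, amp_f


def morphology_for_class(label: str, rng: np.random.Generator) -> BeatMorphology:
    """Draw a randomized beat morphology from the class archetype.

    Returns the morphology carried by the class's *affected* leads (for H
    the normal morphology).  Randomization jitters timing by ±5–8% and
    amplitudes by ±10%, shared across waves of the beat.
    """
    _check_label(label)
    timing_f, amp_f = _draw_jitter(rng)
    waves, st = _apply_archetype(NORMAL_WAVES, PRIMARY_ARCHETYPE[label])
    waves = _jitter_waves(waves, timing_f, amp_f)
    return BeatMorphology(**waves, st_offset=st, label=label)


def beat_morphologies(label: str, rng: np.random.Generator
                      ) -> dict[str, BeatMorphology]:
    """Per-lead morphologies for one beat, sharing the same jitter.

    Wave timing is identical across leads; only amplitudes, widths and the
    ST offset differ where the class's lead pattern prescribes an
    abnormality.  This keeps the true fiducials consistent per lead while
    leaving unaffected leads looking normal.
    """
    _check_label(label)
    timing_f, amp_f = _draw_jitter(rng)
    pattern = LEAD_PATTERNS[label]
    out = {}
    for lead in LEAD_NAMES:
        arch = pattern.get(lead, "normal")
        waves, st = _apply_archetype(NORMAL_WAVES, arch)
        waves = _jitter_waves(waves, timing_f, amp_f)
        out[lead] = BeatMorphology(**waves, st_offset=st, label=label)
    return out


def _raised_cosine_step(t: np.ndarray, start: float, width: float) -> np.ndarray:
    """0 before ``start``, 1 after ``start + width``, cosine ramp between."""
    if width <= 0:
        return (t >= start).astype(float)
    u = np.clip((t - start) / width, 0.0, 1.0)
    return 0.5 * (1.0 - np.cos(np.pi * u))


def true_fiducials(morph: BeatMorphology, fs: float, r_time: float) -> dict[str, int]:
    """Closed-form fiducial sample indices for a beat whose R peak sits at
    ``r_time`` seconds from the beat start.

    QRS onset (I point) is defined at Q center − 2 Q widths, the J point at
    S center + 2 S widths, T onset/end at T center ∓ 2 T widths.
    """
    m = morph
    times = {
        "P": r_time + m.p.center,
        "I": r_time + m.q.center - 2 * m.q.width,
        "Q": r_time + m.q.center,
        "R": r_time,
        "S": r_time + m.s.center,
        "J": r_time + m.s.center + 2 * m.s.width,
        "Tstart": r_time + m.t.center - 2 * m.t.width,
        "T": r_time + m.t.center,
        "Tend": r_time + m.t.center + 2 * m.t.width,
    }
    return {k: int(round(v * fs)) for k, v in times.items()}


def make_beat(morph: BeatMorphology, fs: float, rr: float
              ) -> tuple[np.ndarray, dict[str, int]]:
    """Render one noiseless beat of duration ``rr`` seconds on one lead.

    Returns the sample vector (length ``round(rr*fs)``) and the true
    fiducial indices relative to the beat start.  The R peak is placed at
    ``max(0.25*rr, 0.27)`` s so the P wave fits before and the T wave after.
    """
    n = int(round(rr * fs))
    t = np.arange(n) / fs
    r_time = max(0.25 * rr, 0.27)
    fid = true_fiducials(morph, fs, r_time)
    # every bump must fit inside the beat with a 2-sigma margin
    for w in (morph.p, morph.q, morph.r, morph.s, morph.t):
        c = r_time + w.center
        if c - 2 * w.width < 0 or c + 2 * w.width > rr:
            raise ValueError(
                f"bump at {w.center:+.3f}s relative to R does not fit in an "
                f"RR interval of {rr:.3f}s")
    x = np.zeros(n)
    for w in (morph.p, morph.q, morph.r, morph.s, morph.t):
        c = r_time + w.center
        x += w.amp * np.exp(-0.5 * ((t - c) / w.width) ** 2)
    if morph.st_offset != 0.0:
        j_t = fid["J"] / fs
        tend_t = fid["Tend"] / fs
        plateau = (_raised_cosine_step(t, j_t - ST_RISE, ST_RISE)
                   - _raised_cosine_step(t, tend_t, ST_FALL))
        x += morph.st_offset * plateau
    return x, fid


@dataclass
class BeatTruth:
    """Ground truth for one beat of a synthetic record."""

    label: str
    start: int              # sample index of beat start in the record
    rr: float               # seconds
    fiducials: dict[str, dict[str, int]]  # lead -> name -> absolute index
    st_offset: dict[str, float]           # lead -> mV


@dataclass
class SyntheticRecord:
    """A multi-lead synthetic ECG with per-beat ground truth."""

    samples: np.ndarray     # (n_samples, 12), mV
    fs: float
    lead_names: list[str]
    beats: list[BeatTruth]
    labels: list[str]
    config: RecordConfig

    def truth_r_positions(self, lead: str = "II") -> np.ndarray:
        return np.array([b.fiducials[lead]["R"] for b in self.beats])

    def truth_json(self) -> str:
        payload = {
            "fs": self.fs,
            "lead_names": self.lead_names,
            "labels": self.labels,
            "beats": [
                {"label": b.label, "start": b.start, "rr": b.rr,
                 "fiducials": b.fiducials, "st_offset": b.st_offset}
                for b in self.beats
            ],
        }
        return json.dumps(payload, indent=1)


def make_record(config: RecordConfig, class_sequence: list[str]
                ) -> SyntheticRecord:
    """Concatenate beats into a 12-lead record with wander and noise.

    Reproducible from ``config.seed``; identical inputs give bit-identical
    output.  Per-beat truth is recorded per lead because abnormal
    archetypes shift Q/S widths and therefore QRS onset/offset slightly.
    """
    if len(class_sequence) != config.n_beats:
        raise ValueError("class_sequence length must equal n_beats")
    for lab in class_sequence:
        _check_label(lab)
    rng = np.random.default_rng(config.seed)
    fs = config.fs
    lead_chunks = {ld: [] for ld in LEAD_NAMES}
    beats: list[BeatTruth] = []
    pos = 0
    for lab in class_sequence:
        rr = config.mean_rr + (rng.normal(0.0, config.rr_jitter_sd)
                               if config.rr_jitter_sd > 0 else 0.0)
        rr = max(rr, 0.72)  # keep the T wave inside even at worst jitter
        morphs = beat_morphologies(lab, rng)
        fid_by_lead = {}
        st_by_lead = {}
        n_beat = None
        for ld in LEAD_NAMES:
            x, fid = make_beat(morphs[ld], fs, rr)
            lead_chunks[ld].append(x)
            fid_by_lead[ld] = {k: v + pos for k, v in fid.items()}
            st_by_lead[ld] = morphs[ld].st_offset
            n_beat = len(x)
        beats.append(BeatTruth(lab, pos, rr, fid_by_lead, st_by_lead))
        pos += n_beat
    n = pos
    t = np.arange(n) / fs
    samples = np.column_stack([np.concatenate(lead_chunks[ld])
                               for ld in LEAD_NAMES])
    samples *= np.asarray(config.lead_gain)[None, :]
    if config.baseline_amp > 0:
        phase = rng.uniform(0, 2 * np.pi)
        wander = config.baseline_amp * np.sin(
            2 * np.pi * config.baseline_freq * t + phase)
        samples += wander[:, None]
    if config.noise_sd > 0:
        samples += rng.normal(0.0, config.noise_sd, size=samples.shape)
    return SyntheticRecord(samples=samples, fs=fs, lead_names=list(LEAD_NAMES),
                           beats=beats, labels=list(class_sequence),
                           config=config)


def generate_study(n_per_class: int,
                   classes: list[str] | None = None,
                   fs: float = 1000.0,
                   noise_sd: float = 0.02,
                   baseline_amp: float = 0.1,
                   beats_per_record: int = 20,
                   rr_jitter_sd: float = 0.03,
                   seed: int = 0) -> list[SyntheticRecord]:
    """Generate a labelled multi-record dataset, one class per record.

    ``n_per_class`` beats of every class are spread over records of
    ``beats_per_record`` beats each.  Seeds for individual records are
    drawn from a generator seeded with ``seed`` so the whole study is
    reproducible from one integer.
    """
    classes = list(classes) if classes is not None else list(CLASS_LABELS)
    master = np.random.default_rng(seed)
    records = []
    for lab in classes:
        remaining = n_per_class
        while remaining > 0:
            # avoid trailing records too short to delineate
            nb = (remaining if remaining < beats_per_record + 4
                  else beats_per_record)
            cfg = RecordConfig(
                n_beats=nb, fs=fs, mean_rr=0.8, rr_jitter_sd=rr_jitter_sd,
                baseline_amp=baseline_amp, noise_sd=noise_sd,
                seed=int(master.integers(0, 2**31 - 1)))
            records.append(make_record(cfg, [lab] * nb))
            remaining -= nb
    return records


def write_csv(record: SyntheticRecord, path) -> None:
    """Write samples as CSV (header row = lead names, values in mV)."""
    header = ",".join(record.lead_names)
    np.savetxt(path, record.samples, delimiter=",", header=header,
               comments="", fmt="%.6f")


def write_truth_json(record: SyntheticRecord, path) -> None:
    with open(path, "w") as fh:
        fh.write(record.truth_json())
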