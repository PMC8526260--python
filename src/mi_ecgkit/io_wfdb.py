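"""Minimal WFDB (.hea/.dat) and CSV record IO.

Supports single-segment records with all signals in one format-16 .dat
file (16-bit little-endian, interleaved) — the layout used by the PTB
Diagnostic ECG Database.  Amplitudes are converted to mV with the header
gain and baseline.  The 12 conventional leads are selected by name; Frank
leads (vx, vy, vz) and anything else are dropped.

Conventions used throughout the package: all sample indices 0-based, all
amplitudes mV.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from mi_ecgkit.synthetic import LEAD_NAMES

_CANONICAL = {ld.lower(): ld for ld in LEAD_NAMES}

#: PTB header-comment phrasing -> beat class.  Editable mapping data; the
#: eight kept infarct localizations, plus healthy controls and a catch-all
#: "other disease" bucket.
PTB_LOCALIZATION_MAP = {
    "anterior": "A",
    "antero-lateral": "AL",
    "anterolateral": "AL",
    "antero-septal": "AS",
    "anteroseptal": "AS",
    "inferior": "I",
    "infero-lateral": "IL",
    "inferolateral": "IL",
    "infero-posterior": "IP",
    "inferoposterior": "IP",
    "infero-postero-lateral": "IPL",
    "inferoposterolateral": "IPL",
    "posterior": "P",
}


@dataclass
class ECGRecord:
    """Multi-lead sample matrix in mV with its sampling rate."""

    samples: np.ndarray          # (n_samples, n_leads)
    fs: float
    lead_names: list[str]
    comments: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if np.isnan(self.samples).any():
            raise ValueError("record contains NaNs")
        if not 1 <= self.samples.shape[1] <= 15:
            raise ValueError("expected between 1 and 15 leads")


def read_wfdb(path) -> ECGRecord:
    """Read a .hea/.dat pair; keep the 12 conventional leads in mV."""
    path = Path(path)
    hea = path.with_suffix(".hea")
    if not hea.exists():
        raise FileNotFoundError(hea)
    lines = [ln.rstrip() for ln in hea.read_text().splitlines() if ln.strip()]
    comments = [ln.lstrip("# ").strip() for ln in lines if ln.startswith("#")]
    spec_lines = [ln for ln in lines if not ln.startswith("#")]
    head = spec_lines[0].split()
    if len(head) < 4:
        raise ValueError(f"corrupt header line: {spec_lines[0]!r}")
    n_sig = int(head[1])
    fs = float(head[2])
    n_samp = int(head[3])
    sig_specs = spec_lines[1:1 + n_sig]
    if len(sig_specs) < n_sig:
        raise ValueError("header declares more signals than it describes")
    names, gains, baselines, fmts, files = [], [], [], [], []
    for ln in sig_specs:
        parts = ln.split()
        files.append(parts[0])
        fmts.append(parts[1].split("x")[0].split(":")[0].split("+")[0])
        gain_field = parts[2] if len(parts) > 2 else "200"
        m = re.match(r"([-\d.eE]+)(?:\(([-\d]+)\))?(?:/(\S+))?", gain_field)
        gain = float(m.group(1)) if m and m.group(1) else 200.0
        baseline = int(m.group(2)) if m and m.group(2) else 0
        gains.append(gain if gain != 0 else 200.0)
        baselines.append(baseline)
        names.append(parts[-1])
    if any(f != "16" for f in fmts):
        raise ValueError("only format-16 WFDB records are supported")
    if len(set(files)) != 1:
        raise ValueError("only single-.dat records are supported")
    raw = np.fromfile(path.parent / files[0], dtype="<i2")
    raw = raw[: n_samp * n_sig].reshape(-1, n_sig).astype(float)
    mv = (raw - np.asarray(baselines)) / np.asarray(gains)
    keep, keep_names = [], []
    for want in LEAD_NAMES:
        for i, nm in enumerate(names):
            if nm.lower() == want.lower():
                keep.append(i)
                keep_names.append(want)
                break
    if not keep:
        raise ValueError(f"no conventional leads found among {names}")
    return ECGRecord(mv[:, keep], fs, keep_names, comments)


def write_wfdb(record: ECGRecord, path, gain: float = 2000.0) -> None:
    """Write a format-16 .hea/.dat pair (values quantized to 1/gain mV)."""
    path = Path(path)
    name = path.stem
    n, L = record.samples.shape
    raw = np.round(record.samples * gain).astype("<i2")
    raw.tofile(path.with_suffix(".dat"))
    lines = [f"{name} {L} {record.fs:g} {n}"]
    for j, ld in enumerate(record.lead_names):
        first = int(raw[0, j]) if n else 0
        lines.append(f"{name}.dat 16 {gain:g}(0)/mV 16 0 {first} 0 0 {ld}")
    lines += [f"# {c}" for c in record.comments]
    path.with_suffix(".hea").write_text("\n".join(lines) + "\n")


def read_csv(path, fs: float) -> ECGRecord:
    """CSV of samples x leads (header row = lead names), amplitudes in mV."""
    df = pd.read_csv(path)
    return ECGRecord(df.values.astype(float), fs, list(df.columns))


def write_csv(record: ECGRecord, path) -> None:
    pd.DataFrame(record.samples, columns=record.lead_names).to_csv(
        path, index=False, float_format="%.6f")


def ptb_class_from_comments(comments: list[str]) -> str | None:
    """Map PTB header comments to a beat class, or None if excluded.

    Healthy controls -> H; myocardial infarctions are mapped through
    :data:`PTB_LOCALIZATION_MAP` (unmapped localizations excluded);
    every other stated diagnosis -> O.
    """
    text = " ".join(comments).lower()
    if "healthy control" in text:
        return "H"
    if "myocardial infarction" in text:
        m = re.search(r"localization[^:]*:\s*([a-z\- ]+)", text)
        if m:
            key = m.group(1).strip().replace(" ", "-")
            return PTB_LOCALIZATION_MAP.get(key)
        return None
    if "n/a" in text or not text:
        return None
    return "O"


def load_truth_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
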