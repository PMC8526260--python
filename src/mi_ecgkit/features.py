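"""Rule features and the QT ventricular-activity feature.

Seven clinically grounded scalars are computed per lead-beat from the
fiducial amplitudes/positions, all relative to the beat's own baseline
(the QRS-onset "I point"), which makes them exactly invariant to constant
amplitude shifts:

* ``J_relative   = J_amp - I_amp``        (J-point/ST elevation, mV)
* ``ST_relative  = Tstart_amp - J_amp``   (ST-segment course, mV)
* ``Q_ratio      = (Q_amp - I_amp) / (R_amp - I_amp)``  (abnormal-Q depth)
* ``Q_interval   = (Q_pos - I_pos) / SR`` (abnormal-Q width, s)
* ``T_ratio      = (T_amp - I_amp) / (R_amp - I_amp)``  (tall/flat T)
* ``Tstart_relative = T_amp - Tstart_amp`` (T upright vs inverted, mV)
* ``Tend_relative   = T_amp - Tend_amp``   (mV)

The ventricular-activity feature is the full QT span [I point, T end]
resampled to exactly 1000 samples by linear interpolation, a total record
of ventricular de- and repolarization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from mi_ecgkit.delineate import Fiducials, match_beats_across_leads
from mi_ecgkit.synthetic import LEAD_NAMES

RULE_FEATURE_NAMES = ["J_relative", "ST_relative", "Q_ratio", "Q_interval",
                      "T_ratio", "Tstart_relative", "Tend_relative"]

QT_LENGTH = 1000


class DegenerateBeatError(ValueError):
    """Raised when a beat cannot yield valid features (e.g. R_amp == I_amp)."""


def rule_features(fid: Fiducials, sr: float) -> dict[str, float]:
    """The seven rule features for one lead-beat.

    Raises :class:`DegenerateBeatError` when ``R_amp == I_amp`` (zero
    denominator for the two ratios); such beats are dropped by callers.
    """
    r_rel = fid.R_amp - fid.I_amp
    if r_rel == 0:
        raise DegenerateBeatError("R amplitude equals baseline; beat dropped")
    return {
        "J_relative": fid.J_amp - fid.I_amp,
        "ST_relative": fid.Tstart_amp - fid.J_amp,
        "Q_ratio": (fid.Q_amp - fid.I_amp) / r_rel,
        "Q_interval": (fid.Q_pos - fid.I_pos) / sr,
        "T_ratio": (fid.T_amp - fid.I_amp) / r_rel,
        "Tstart_relative": fid.T_amp - fid.Tstart_amp,
        "Tend_relative": fid.T_amp - fid.Tend_amp,
    }


def extract_qt(x: np.ndarray, fid: Fiducials, length: int = QT_LENGTH
               ) -> np.ndarray:
    """QT span [I_pos, Tend_pos] resampled to ``length`` samples.

    Linear interpolation on a uniform grid including both endpoints.
    """
    i0, i1 = fid.I_pos, fid.Tend_pos
    if i1 <= i0:
        raise DegenerateBeatError("T end does not follow QRS onset")
    if i1 - i0 + 1 < 8:
        raise DegenerateBeatError("QT span shorter than 8 samples")
    grid = np.linspace(i0, i1, length)
    return np.interp(grid, np.arange(i0, i1 + 1), x[i0:i1 + 1])


@dataclass
class FeatureTable:
    """Per-beat features for a set of leads.

    ``rule``: DataFrame with ``{lead}_{feature}`` columns (7 per lead);
    ``qt``: array of shape (n_beats, n_leads, 1000);
    ``labels``: optional per-beat class labels.
    """

    rule: pd.DataFrame
    qt: np.ndarray
    lead_names: list[str]
    labels: list[str] | None = None

    def __len__(self) -> int:
        return len(self.rule)

    def to_frame(self) -> pd.DataFrame:
        """The wide per-beat CSV contract: ``{lead}_{feat}`` rule columns,
        ``{lead}_qt_0000 .. _0999`` QT columns, plus ``label``."""
        blocks = [self.rule.reset_index(drop=True)]
        for li, lead in enumerate(self.lead_names):
            cols = [f"{lead}_qt_{k:04d}" for k in range(self.qt.shape[2])]
            blocks.append(pd.DataFrame(self.qt[:, li, :], columns=cols))
        out = pd.concat(blocks, axis=1)
        if self.labels is not None:
            out["label"] = self.labels
        return out


def concat_feature_tables(tables: list[FeatureTable]) -> FeatureTable:
    tables = [t for t in tables if len(t)]
    rule = pd.concat([t.rule for t in tables], ignore_index=True)
    qt = np.concatenate([t.qt for t in tables], axis=0)
    labels = None
    if all(t.labels is not None for t in tables):
        labels = sum((list(t.labels) for t in tables), [])
    return FeatureTable(rule, qt, tables[0].lead_names, labels)


def features_for_record(samples: np.ndarray, fs: float,
                        per_lead_fiducials: dict[str, list[Fiducials]],
                        lead_names: list[str] | None = None,
                        labels_by_beat: list[str] | None = None
                        ) -> FeatureTable:
    """Assemble the per-beat feature table for a whole record.

    Beats are matched across leads by nearest R peak; beats missing any
    lead's fiducials, or degenerate on any lead, are dropped whole.  When
    ``labels_by_beat`` is given (one label per *detected* reference beat,
    e.g. from generator truth), labels follow the kept beats.
    """
    lead_names = lead_names or list(LEAD_NAMES)
    matched = match_beats_across_leads(per_lead_fiducials, fs)
    rows, qt_rows, kept = [], [], []
    for b, row in enumerate(matched):
        try:
            feats = {}
            qts = np.empty((len(lead_names), QT_LENGTH))
            for li, lead in enumerate(lead_names):
                fid = row[lead]
                x = samples[:, li]
                for k, v in rule_features(fid, fs).items():
                    feats[f"{lead}_{k}"] = v
                qts[li] = extract_qt(x, fid)
        except DegenerateBeatError:
            continue
        rows.append(feats)
        qt_rows.append(qts)
        kept.append(b)
    rule = pd.DataFrame(rows)
    qt = (np.stack(qt_rows) if qt_rows
          else np.empty((0, len(lead_names), QT_LENGTH)))
    labels = None
    if labels_by_beat is not None:
        labels = [labels_by_beat[min(b, len(labels_by_beat) - 1)]
                  for b in kept]
    return FeatureTable(rule, qt, lead_names, labels)
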