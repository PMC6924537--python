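"""Head-motion summary statistic and cohort-level exclusion rules.

Motion is summarized per scan as the average root-mean-squared (RMS)
displacement over successive volume pairs, computed from the three rigid-body
translation parameters only.  Two exclusion rules operate on these values:
an absolute rule (RMS displacement more than 2 SD above the cohort mean) and,
for patients in a crossover design, a paired rule on the placebo-minus-drug
difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["MotionTrace", "rms_displacement", "exclude_by_motion", "MOTION_COLUMNS"]

MOTION_COLUMNS = [
    "trans_x_mm",
    "trans_y_mm",
    "trans_z_mm",
    "rot_x_rad",
    "rot_y_rad",
    "rot_z_rad",
]


@dataclass
class MotionTrace:
    """Rigid-body motion parameters: translations (mm) and rotations (rad).

    Both arrays have one row per volume and three columns (x, y, z).
    """

    translations: np.ndarray
    rotations: np.ndarray

    def __post_init__(self) -> None:
        self.translations = np.asarray(self.translations, dtype=float).reshape(-1, 3)
        self.rotations = np.asarray(self.rotations, dtype=float).reshape(-1, 3)
        if self.translations.shape != self.rotations.shape:
            raise ValueError("translations and rotations must have the same shape")
        if self.translations.shape[0] < 2:
            raise ValueError("motion trace needs at least 2 volumes")
        if not (np.isfinite(self.translations).all() and np.isfinite(self.rotations).all()):
            raise ValueError("motion parameters must be finite")

    @property
    def n_volumes(self) -> int:
        return self.translations.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            np.hstack([self.translations, self.rotations]), columns=MOTION_COLUMNS
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MotionTrace":
        missing = [c for c in MOTION_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"motion table missing columns: {missing}")
        a = df[MOTION_COLUMNS].to_numpy(dtype=float)
        return cls(a[:, :3], a[:, 3:])


def rms_displacement(trace: MotionTrace) -> float:
    """Average RMS displacement (mm) from the translation parameters.

    Mean over successive volume pairs (t, t+1) of the Euclidean norm of the
    translation difference.  Rotations are ignored, and a constant offset of
    the whole trace leaves the value unchanged.
    """
    diffs = np.diff(trace.translations, axis=0)
    return float(np.linalg.norm(diffs, axis=1).mean())


def exclude_by_motion(
    values: pd.Series | dict,
    paired_diffs: pd.Series | dict | None = None,
    k: float = 2.0,
) -> pd.DataFrame:
    """Apply the motion exclusion rules, returning per-subject flags.

    Parameters
    ----------
    values : mapping subject id -> RMS displacement (mm)
        One value per subject (for patients, e.g. the session mean).
    paired_diffs : mapping subject id -> placebo-minus-drug RMS difference (mm), optional
        Patients only; absolute differences are screened against
        ``mean + k*SD`` of the |difference| distribution.
    k : float
        SD multiplier (default 2).

    Returns
    -------
    DataFrame indexed by subject id with columns ``value``, ``exclude``
    (bool) and ``reason`` (empty string when kept).  The absolute rule is
    one-sided: only *high* motion excludes.  Mean and SD include every
    candidate (single pass).
    """
    vals = pd.Series(values, dtype=float)
    if vals.empty:
        raise ValueError("no motion values supplied")
    if len(vals) < 3:
        raise ValueError("need at least 3 subjects for SD-based screening")
    mean, sd = vals.mean(), vals.std(ddof=1)
    out = pd.DataFrame({"value": vals, "exclude": False, "reason": ""})
    high = vals > mean + k * sd
    out.loc[high, "exclude"] = True
    out.loc[high, "reason"] = f"rms displacement > mean + {k} SD"

    if paired_diffs is not None:
        diffs = pd.Series(paired_diffs, dtype=float).abs()
        if not diffs.empty and len(diffs) >= 3:
            dmean, dsd = diffs.mean(), diffs.std(ddof=1)
            bad = diffs[diffs > dmean + k * dsd].index
            for sid in bad:
                if sid in out.index:
                    out.loc[sid, "exclude"] = True
                    prev = out.loc[sid, "reason"]
                    msg = f"|placebo-drug| displacement > mean + {k} SD"
                    out.loc[sid, "reason"] = f"{prev}; {msg}" if prev else msg
                else:
                    out.loc[sid] = [np.nan, True, f"|placebo-drug| displacement > mean + {k} SD"]
    return out
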