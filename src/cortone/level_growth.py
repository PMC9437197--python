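"""COR level-growth fitting and conversion of COR masking to threshold shifts.

The unmasked COR amplitude (in dB re 1 uV) grows roughly linearly with probe
level on dB/dB coordinates.  A shared-slope linear model

    COR_dB = x * level + a_subject (+ b_subject * log10(freq))

is fitted across subjects by least squares, with a subject-resampling
bootstrap for the 95 % CI of the shared slope x.  Dividing a masker-induced
COR reduction (dB re unmasked) by x converts it into the reduction of probe
level in quiet that would produce the same COR reduction, i.e. an equivalent
psychophysical threshold shift in dB.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GrowthFit",
    "fit_growth",
    "masking_to_threshold_shift",
    "compare_estimates",
]


@dataclass
class GrowthFit:
    slope_db_per_db: float
    per_subject_intercepts: dict
    per_subject_freq_terms: dict | None
    ci95_slope: tuple[float, float]
    level_range_db: tuple[float, float]
    n_boot: int


def _design(df: pd.DataFrame, subjects: np.ndarray, freq_term: bool) -> np.ndarray:
    """[level | subject dummies | (subject dummies * log10 freq)]."""
    n = len(df)
    cols = [df["level_db_spl"].to_numpy(dtype=float)]
    subj = df["subject"].to_numpy()
    for s in subjects:
        cols.append((subj == s).astype(float))
    if freq_term:
        logf = np.log10(df["freq_hz"].to_numpy(dtype=float))
        for s in subjects:
            cols.append((subj == s) * logf)
    X = np.column_stack(cols)
    assert X.shape == (n, len(cols))
    return X


def _fit_slope(df: pd.DataFrame, subjects: np.ndarray, freq_term: bool):
    X = _design(df, subjects, freq_term)
    y = df["cor_db_re_1uv"].to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return beta


def fit_growth(data: pd.DataFrame, include_freq_term: bool = False,
               n_boot: int = 1000, seed: int | np.random.Generator = 0) -> GrowthFit:
    """Fit the shared-slope growth model.

    data: columns subject, freq_hz, level_db_spl, cor_db_re_1uv; each subject
    must contribute >= 3 levels.  With `include_freq_term` each subject also
    gets a b_s * log10(freq) term (only identifiable with > 1 frequency).
    The slope CI is a percentile bootstrap over subjects.
    """
    required = {"subject", "freq_hz", "level_db_spl", "cor_db_re_1uv"}
    if not required.issubset(data.columns):
        raise ValueError(f"data must have columns {sorted(required)}")
    n_levels = data.groupby("subject")["level_db_spl"].nunique()
    if (n_levels < 3).any():
        raise ValueError("every subject needs at least 3 probe levels")
    if include_freq_term and data["freq_hz"].nunique() < 2:
        raise ValueError("frequency term needs more than one probe frequency")
    subjects = np.array(sorted(data["subject"].unique()))
    beta = _fit_slope(data, subjects, include_freq_term)
    slope = float(beta[0])
    intercepts = dict(zip(subjects, beta[1:1 + len(subjects)]))
    freq_terms = (dict(zip(subjects, beta[1 + len(subjects):]))
                  if include_freq_term else None)

    rng = np.random.default_rng(seed)
    groups = {s: g for s, g in data.groupby("subject")}
    boots = np.empty(n_boot)
    for b in range(n_boot):
        pick = rng.choice(subjects, size=len(subjects), replace=True)
        frames = []
        names = []
        for j, s in enumerate(pick):
            g = groups[s].copy()
            g["subject"] = j  # resampled copies are distinct subjects
            frames.append(g)
            names.append(j)
        bdf = pd.concat(frames, ignore_index=True)
        boots[b] = _fit_slope(bdf, np.array(names), include_freq_term)[0]
    ci = (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5)))
    levels = data["level_db_spl"]
    return GrowthFit(slope, intercepts, freq_terms, ci,
                     (float(levels.min()), float(levels.max())), n_boot)


def masking_to_threshold_shift(cor_masking_db: float, slope_db_per_db: float) -> float:
    """Equivalent threshold shift (dB) = |COR masking| / growth slope."""
    if slope_db_per_db <= 0:
        raise ValueError("growth slope must be positive")
    return abs(float(cor_masking_db)) / slope_db_per_db


def compare_estimates(cor_masking_db: pd.DataFrame, psychophysical_shift_db: pd.DataFrame,
                      slopes=(0.13, 0.16, 0.19)) -> pd.DataFrame:
    """Per-frequency comparison of COR-derived and psychophysical shifts.

    Both inputs: columns freq_hz plus one value column (cor_masking_db /
    shift_db).  Returns a table with one COR-estimate column per slope in the
    sensitivity sweep and the discrepancy at the middle slope.
    """
    a = cor_masking_db.sort_values("freq_hz").reset_index(drop=True)
    b = psychophysical_shift_db.sort_values("freq_hz").reset_index(drop=True)
    if not np.allclose(a["freq_hz"].to_numpy(), b["freq_hz"].to_numpy()):
        raise ValueError("frequency grids do not match")
    out = pd.DataFrame({"freq_hz": a["freq_hz"],
                        "psychophysical_shift_db": b["shift_db"]})
    for s in slopes:
        out[f"cor_estimate_slope_{s:g}_db"] = [
            masking_to_threshold_shift(m, s) for m in a["cor_masking_db"]
        ]
    mid = slopes[len(slopes) // 2]
    out["discrepancy_db"] = out[f"cor_estimate_slope_{mid:g}_db"] - out["psychophysical_shift_db"]
    return out
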