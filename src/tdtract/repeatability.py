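"""Test-retest agreement statistics for fascicle-length measurements.

Bland-Altman analysis of paired sessions, with the coefficient of
variation CV = 100 * SD / Mean (SD of the paired differences, Mean of all
repeated measurements) and the minimal detectable difference
MDD = 1.96 * SD of the paired differences — the smallest change
attributable, at 95% confidence, to a true effect rather than measurement
error.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

Z_95 = 1.96  # two-sided 95% normal quantile used for LoA and MDD


@dataclasses.dataclass
class RepeatabilityResult:
    """Bland-Altman summary for one set of paired measurements (units of
    the input, cm by convention)."""

    bias: float  # mean paired difference (session1 - session2)
    sd_diff: float  # SD of paired differences
    loa_low: float
    loa_high: float
    grand_mean: float  # mean of all 2n measurements
    cv: float  # percent
    mdd: float
    n_pairs: int
    plot_means: np.ndarray = dataclasses.field(default_factory=lambda: np.empty(0))
    plot_diffs: np.ndarray = dataclasses.field(default_factory=lambda: np.empty(0))

    def to_dict(self) -> dict:
        return {
            "bias": self.bias,
            "sd_diff": self.sd_diff,
            "loa_low": self.loa_low,
            "loa_high": self.loa_high,
            "grand_mean": self.grand_mean,
            "cv_percent": self.cv,
            "mdd": self.mdd,
            "n_pairs": self.n_pairs,
        }


def bland_altman(session1, session2) -> RepeatabilityResult:
    """Bland-Altman agreement between two measurement sessions.

    Incomplete pairs (NaN in either session) are excluded with a warning.
    The SD of the differences uses the sample (n-1) denominator.
    """
    s1 = np.asarray(session1, dtype=float)
    s2 = np.asarray(session2, dtype=float)
    if s1.shape != s2.shape:
        raise ValueError("sessions must have the same length")
    complete = np.isfinite(s1) & np.isfinite(s2)
    if complete.sum() < s1.size:
        warnings.warn(
            f"excluding {int(s1.size - complete.sum())} incomplete pair(s)",
            stacklevel=2,
        )
    s1, s2 = s1[complete], s2[complete]
    n = len(s1)
    if n < 2:
        raise ValueError("need at least 2 complete pairs")

    d = s1 - s2
    m = (s1 + s2) / 2.0
    bias = float(d.mean())
    sd_diff = float(d.std(ddof=1))
    grand_mean = float(np.concatenate([s1, s2]).mean())
    cv = 100.0 * sd_diff / grand_mean if grand_mean != 0 else np.nan
    mdd = Z_95 * sd_diff
    return RepeatabilityResult(
        bias=bias,
        sd_diff=sd_diff,
        loa_low=bias - Z_95 * sd_diff,
        loa_high=bias + Z_95 * sd_diff,
        grand_mean=grand_mean,
        cv=float(cv),
        mdd=float(mdd),
        n_pairs=n,
        plot_means=m,
        plot_diffs=d,
    )


def synthetic_paired_cohort(
    n_subjects: int = 100,
    muscles: tuple[str, ...] = ("SOL", "FL", "EDL", "TA"),
    conditions: tuple[str, ...] = ("neutral",),
    mean_cm: float = 6.0,
    between_subject_sd_cm: float = 0.7,
    session_sd_cm: float = 0.35,
    seed: int = 0,
) -> pd.DataFrame:
    """Tidy synthetic test-retest dataset with known session noise.

    Each subject x muscle x condition has a true value drawn around
    ``mean_cm``; each session observes it with independent Gaussian noise
    of SD ``session_sd_cm``, so the SD of paired differences has
    expectation ``session_sd_cm * sqrt(2)``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for muscle in muscles:
        for condition in conditions:
            true = mean_cm + between_subject_sd_cm * rng.standard_normal(n_subjects)
            for session in (1, 2):
                obs = true + session_sd_cm * rng.standard_normal(n_subjects)
                for subj, v in enumerate(obs):
                    rows.append(
                        {
                            "muscle": muscle,
                            "condition": condition,
                            "subject": subj,
                            "session": session,
                            "value": float(v),
                        }
                    )
    return pd.DataFrame(rows)


def repeatability_table(measurements: pd.DataFrame) -> pd.DataFrame:
    """Per muscle x condition summary in the style of a repeatability table.

    ``measurements`` is tidy with columns ``muscle``, ``condition``,
    ``subject``, ``session`` (1 or 2) and ``value`` (cm).  Emits mean and
    between-subject SD of per-subject means, CV (%), MDD and the pair
    count; conditions with no complete pair are omitted with a warning.
    """
    required = {"muscle", "condition", "subject", "session", "value"}
    missing = required - set(measurements.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    rows = []
    for (muscle, condition), grp in measurements.groupby(
        ["muscle", "condition"], sort=True
    ):
        wide = grp.pivot_table(index="subject", columns="session", values="value")
        if 1 not in wide.columns or 2 not in wide.columns:
            warnings.warn(
                f"{muscle}/{condition}: no complete session pair; omitted",
                stacklevel=2,
            )
            continue
        wide = wide.dropna(subset=[1, 2])
        if len(wide) < 2:
            warnings.warn(
                f"{muscle}/{condition}: fewer than 2 complete pairs; omitted",
                stacklevel=2,
            )
            continue
        res = bland_altman(wide[1].to_numpy(), wide[2].to_numpy())
        subject_means = wide[[1, 2]].mean(axis=1)
        rows.append(
            {
                "muscle": muscle,
                "condition": condition,
                "mean_cm": float(subject_means.mean()),
                "sd_between_subjects_cm": (
                    float(subject_means.std(ddof=1)) if len(wide) > 1 else np.nan
                ),
                "cv_percent": res.cv,
                "mdd_cm": res.mdd,
                "bias_cm": res.bias,
                "n_pairs": res.n_pairs,
            }
        )
    return pd.DataFrame(rows)
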