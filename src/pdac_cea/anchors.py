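"""Survival anchors and synthetic survival-curve fixtures.

Calibration targets are *anchor points* — (time, survival) pairs per arm and
endpoint built from the published survival summaries (median, 5-year and
10-year overall and progression-free survival).  The packaged ``anchors.csv``
transcribes those summaries; :func:`generate_synthetic_anchors` produces
anchor sets from *known* piecewise-constant hazards so that calibration can
be tested by parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .params import ARMS, data_path

__all__ = [
    "OS",
    "PFS",
    "SurvivalAnchorSet",
    "build_anchor_set",
    "load_anchor_table",
    "generate_synthetic_anchors",
    "piecewise_survival",
    "load_life_table",
    "monthly_background_mortality",
]

OS = "OS"
PFS = "PFS"
_ENDPOINTS = (OS, PFS)


@dataclass(frozen=True)
class SurvivalAnchorSet:
    """Anchor points for one arm and endpoint, sorted by time.

    Invariants: times strictly increasing starting at 0, survival values
    non-increasing in [0, 1] with S(0) = 1.
    """

    arm: str
    endpoint: str
    anchors: tuple  # of (time_months, survival)

    def __post_init__(self):
        if self.endpoint not in _ENDPOINTS:
            raise ValueError(f"unknown endpoint {self.endpoint!r}")
        t = np.array([a[0] for a in self.anchors], dtype=float)
        s = np.array([a[1] for a in self.anchors], dtype=float)
        if len(t) == 0 or t[0] != 0.0 or s[0] != 1.0:
            raise ValueError("first anchor must be (0, 1.0)")
        if np.any(np.diff(t) <= 0):
            raise ValueError("anchor times must be strictly increasing")
        if np.any(np.diff(s) > 1e-12):
            raise ValueError("survival must be non-increasing")
        if np.any(s < 0) or np.any(s > 1):
            raise ValueError("survival must lie in [0, 1]")

    @property
    def times(self) -> np.ndarray:
        return np.array([a[0] for a in self.anchors], dtype=float)

    @property
    def survival(self) -> np.ndarray:
        return np.array([a[1] for a in self.anchors], dtype=float)


def load_anchor_table(path: Path | str | None = None) -> pd.DataFrame:
    """The packaged anchor transcription as a tidy DataFrame."""
    path = data_path("anchors.csv") if path is None else path
    return pd.read_csv(path, comment="#")


def build_anchor_set(
    arm: str, endpoint: str, path: Path | str | None = None
) -> SurvivalAnchorSet:
    """Anchor set {(0, 1), (median, 0.5), (60, 5-yr), (120, 10-yr)} for an arm.

    Values are read from the packaged transcription of the published survival
    summaries.  Unknown arm or endpoint raises ``ValueError``.
    """
    if arm not in ARMS:
        raise ValueError(f"unknown arm {arm!r}; expected one of {ARMS}")
    if endpoint not in _ENDPOINTS:
        raise ValueError(f"unknown endpoint {endpoint!r}; expected one of {_ENDPOINTS}")
    df = load_anchor_table(path)
    sub = df[(df["arm"] == arm) & (df["endpoint"] == endpoint)]
    if sub.empty:
        raise ValueError(f"no anchors for ({arm}, {endpoint})")
    sub = sub.sort_values("time_months")
    anchors = tuple(zip(sub["time_months"].astype(float), sub["survival"].astype(float)))
    return SurvivalAnchorSet(arm=arm, endpoint=endpoint, anchors=anchors)


def piecewise_survival(
    knots: np.ndarray, probs: np.ndarray, times: np.ndarray
) -> np.ndarray:
    """Exact survival of a piecewise-constant monthly event probability.

    ``knots`` are segment boundaries ``[k0, k1, ..., kn]`` (months) and
    ``probs`` the per-cycle event probability on each of the n segments.
    Survival is ``prod (1 - p_j)^(months spent in segment j)``, continuous in
    t (fractional exponents), i.e. the piecewise-exponential closed form.
    """
    knots = np.asarray(knots, dtype=float)
    probs = np.asarray(probs, dtype=float)
    if len(probs) != len(knots) - 1:
        raise ValueError("need one probability per segment")
    times = np.atleast_1d(np.asarray(times, dtype=float))
    log1m = np.log1p(-np.minimum(probs, 1 - 1e-300))
    out = np.empty_like(times)
    for i, t in enumerate(times):
        dur = np.clip(np.minimum(t, knots[1:]) - knots[:-1], 0.0, None)
        out[i] = np.exp(np.dot(dur, log1m))
    return out


def generate_synthetic_anchors(
    knots,
    probs,
    times,
    noise_sd: float = 0.0,
    seed: int = 0,
    arm: str = "synthetic",
    endpoint: str = OS,
) -> SurvivalAnchorSet:
    """Anchor set computed exactly from known piecewise-constant hazards.

    With ``noise_sd > 0`` each anchor is perturbed by truncated zero-mean
    Gaussian noise (deterministic given ``seed``) and monotonicity is
    re-enforced by a running minimum.  The time-0 anchor is always (0, 1).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    times = np.sort(np.asarray(times, dtype=float))
    if np.any(times <= 0):
        raise ValueError("anchor times must be positive")
    surv = piecewise_survival(np.asarray(knots, float), np.asarray(probs, float), times)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        surv = np.clip(surv + rng.normal(0.0, noise_sd, size=surv.shape), 0.0, 1.0)
        surv = np.minimum.accumulate(surv)
    anchors = ((0.0, 1.0),) + tuple(zip(times, surv))
    return SurvivalAnchorSet(arm=arm, endpoint=endpoint, anchors=anchors)


def load_life_table(path: Path | str | None = None) -> pd.DataFrame:
    """Packaged abridged all-cause mortality table (age, annual probability)."""
    path = data_path("life_table.csv") if path is None else path
    return pd.read_csv(path, comment="#")


def monthly_background_mortality(
    start_age: float, horizon_cycles: int, life_table: pd.DataFrame | None = None
) -> np.ndarray:
    """Per-cycle all-cause death probability over the horizon.

    The annual probability at the (integer) attained age is converted to a
    monthly probability via ``1 - (1 - q)^(1/12)``.  Ages beyond the table are
    held at the last tabulated value.
    """
    lt = load_life_table() if life_table is None else life_table
    ages = lt["age"].to_numpy(dtype=float)
    q_annual = lt["annual_mortality"].to_numpy(dtype=float)
    attained = start_age + np.arange(horizon_cycles) / 12.0
    idx = np.clip(np.searchsorted(ages, np.floor(attained), side="right") - 1, 0, len(ages) - 1)
    return 1.0 - (1.0 - q_annual[idx]) ** (1.0 / 12.0)
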