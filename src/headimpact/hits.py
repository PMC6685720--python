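"""Exposure features from helmet-accelerometer hit logs.

A hit log is a tidy table with one row per registered impact:

====================  =========================================================
column                meaning
====================  =========================================================
``player_id``         player identifier
``session_type``      ``practice``, ``game`` or ``other``
``linear_g``          peak linear acceleration of the head, in g
``rotational_rad_s2`` peak rotational acceleration, in rad/s^2
``azimuth_deg``       impact longitude; 0 deg at the back of the head,
                      +90 deg the right side, -90 deg the left side
``elevation_deg``     impact latitude; -90 deg pointing down, +90 deg up
====================  =========================================================

This module computes every per-cohort and per-player exposure feature used
downstream: session summaries, the cohort mean + 1 SD force thresholds,
suprathreshold and exclusive-threshold hit counts, decile threshold sweeps,
and the per-player "spatial fingerprint" -- a normalized spherical histogram
of hit locations over 10-degree azimuth x elevation bins (36 x 18 = 648 bins
at the default resolution).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

SESSION_TYPES = ("practice", "game", "other")

#: hit-log column holding each acceleration metric
METRIC_COLUMNS = {"linear": "linear_g", "rotational": "rotational_rad_s2"}

HIT_LOG_COLUMNS = (
    "player_id",
    "session_type",
    "linear_g",
    "rotational_rad_s2",
    "azimuth_deg",
    "elevation_deg",
)


def _metric_values(log: pd.DataFrame, metric: str) -> np.ndarray:
    if metric not in METRIC_COLUMNS:
        raise ValueError(
            f"metric must be one of {sorted(METRIC_COLUMNS)}, got {metric!r}"
        )
    return np.asarray(log[METRIC_COLUMNS[metric]], dtype=float)


def canonicalize_session(session_type: Iterable[str]) -> pd.Series:
    """Map free-form session labels onto practice / game / other.

    Anything that is not ``practice`` or ``game`` (scrimmages, meetings, ...)
    is grouped as ``other``.
    """
    s = pd.Series(session_type, dtype="string").str.strip().str.lower()
    return s.where(s.isin(["practice", "game"]), "other")


# ---------------------------------------------------------------------------
# angular canonicalization and binning
# ---------------------------------------------------------------------------

def canonicalize_angles(azimuth_deg, elevation_deg):
    """Map arbitrary (azimuth, elevation) pairs onto the canonical ranges.

    Azimuth is wrapped into [-180, 180); elevation is reflected across the
    poles into [-90, 90] (a reflection flips the azimuth by 180 degrees, as
    on any sphere). Both inputs may be scalars or arrays.

    Raises
    ------
    ValueError
        if any angle is non-finite.
    """
    az = np.asarray(azimuth_deg, dtype=float)
    el = np.asarray(elevation_deg, dtype=float)
    if not (np.all(np.isfinite(az)) and np.all(np.isfinite(el))):
        raise ValueError("angles must be finite")
    scalar = az.ndim == 0 and el.ndim == 0
    az, el = np.atleast_1d(az).copy(), np.atleast_1d(el).copy()

    el = (el + 180.0) % 360.0 - 180.0  # into [-180, 180)
    over = el > 90.0
    el[over] = 180.0 - el[over]
    az[over] += 180.0
    under = el < -90.0
    el[under] = -180.0 - el[under]
    az[under] += 180.0
    az = (az + 180.0) % 360.0 - 180.0
    if scalar:
        return float(az[0]), float(el[0])
    return az, el


def bin_index(azimuth_deg, elevation_deg, az_bin_deg: float = 10.0,
              el_bin_deg: float = 10.0):
    """Flat histogram bin index for a hit location.

    Bins are half-open ``[edge, edge + width)`` in both coordinates, starting
    at azimuth -180 and elevation -90; elevation exactly +90 falls in the top
    bin. Flattening is azimuth-major: ``index = az_bin * n_el_bins + el_bin``.
    At the default 10-degree resolution there are 36 x 18 = 648 bins and
    (azimuth -180, elevation -90) maps to index 0.
    """
    if 360.0 % az_bin_deg or 180.0 % el_bin_deg:
        raise ValueError("bin widths must divide 360 (azimuth) and 180 (elevation)")
    n_el = int(round(180.0 / el_bin_deg))
    az, el = canonicalize_angles(azimuth_deg, elevation_deg)
    scalar = np.isscalar(az)
    az, el = np.atleast_1d(az), np.atleast_1d(el)
    az_bin = np.floor((az + 180.0) / az_bin_deg).astype(np.int64)
    el_bin = np.floor((el + 90.0) / el_bin_deg).astype(np.int64)
    el_bin = np.minimum(el_bin, n_el - 1)  # closed top edge at +90
    idx = az_bin * n_el + el_bin
    return int(idx[0]) if scalar else idx


@dataclass
class Fingerprint:
    """Normalized spherical histogram of one player's hits.

    ``weights`` sums to 1 whenever ``n_hits > 0``; a player with no hits gets
    the all-zero vector (flagged by ``n_hits == 0``).
    """

    weights: np.ndarray
    n_hits: int
    az_bin_deg: float = 10.0
    el_bin_deg: float = 10.0

    @property
    def n_bins(self) -> int:
        return self.weights.size

    def as_grid(self) -> np.ndarray:
        """Reshape to an (azimuth-bin, elevation-bin) grid for plotting."""
        n_el = int(round(180.0 / self.el_bin_deg))
        return self.weights.reshape(-1, n_el)


def compute_fingerprint(player_hits: pd.DataFrame, az_bin_deg: float = 10.0,
                        el_bin_deg: float = 10.0) -> Fingerprint:
    """Per-player hit-location histogram, normalized to sum to 1."""
    n_az = int(round(360.0 / az_bin_deg))
    n_el = int(round(180.0 / el_bin_deg))
    n_bins = n_az * n_el
    counts = np.zeros(n_bins, dtype=float)
    n = len(player_hits)
    if n:
        idx = bin_index(player_hits["azimuth_deg"], player_hits["elevation_deg"],
                        az_bin_deg, el_bin_deg)
        np.add.at(counts, idx, 1.0)
        counts /= n
    return Fingerprint(counts, n, az_bin_deg, el_bin_deg)


class FingerprintBinner(BaseEstimator, TransformerMixin):
    """Transformer from a hit log to a players x bins fingerprint matrix.

    Parameters
    ----------
    az_bin_deg, el_bin_deg : float
        Angular bin widths in degrees; must divide 360 and 180. Defaults give
        the 36 x 18 = 648-bin resolution.
    suprathreshold_only : bool
        If True, build fingerprints only from hits at or above
        ``rotational_threshold`` (all hits by default).
    rotational_threshold : float or None
        Threshold used when ``suprathreshold_only`` is set.
    roster : sequence or None
        Cohort roster fixing the output rows. By default the players seen in
        the log at ``fit`` time; pass the full roster explicitly when some
        players may have no logged hits (they get all-zero rows).
    """

    def __init__(self, az_bin_deg: float = 10.0, el_bin_deg: float = 10.0,
                 suprathreshold_only: bool = False,
                 rotational_threshold: float | None = None,
                 roster=None):
        self.az_bin_deg = az_bin_deg
        self.el_bin_deg = el_bin_deg
        self.suprathreshold_only = suprathreshold_only
        self.rotational_threshold = rotational_threshold
        self.roster = roster

    @property
    def n_bins(self) -> int:
        return int(round(360.0 / self.az_bin_deg)) * int(round(180.0 / self.el_bin_deg))

    def fit(self, X: pd.DataFrame, y=None):
        if 360.0 % self.az_bin_deg or 180.0 % self.el_bin_deg:
            raise ValueError("bin widths must divide 360 and 180")
        if self.suprathreshold_only and self.rotational_threshold is None:
            raise ValueError("suprathreshold_only requires rotational_threshold")
        if self.roster is not None:
            self.players_ = np.asarray(sorted(self.roster))
        else:
            self.players_ = np.asarray(sorted(pd.unique(X["player_id"])))
        self.n_features_out_ = self.n_bins
        return self

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        """Return a (n_players, n_bins) row-stochastic matrix.

        Rows follow the sorted player order seen in ``fit`` (``players_``);
        players absent from ``X`` get zero rows.
        """
        check_is_fitted(self, "players_")
        log = X
        if self.suprathreshold_only:
            log = log[log["rotational_rad_s2"] >= self.rotational_threshold]
        mats = []
        grouped = dict(tuple(log.groupby("player_id", sort=False)))
        for pid in self.players_:
            sub = grouped.get(pid, log.iloc[0:0])
            mats.append(compute_fingerprint(sub, self.az_bin_deg, self.el_bin_deg).weights)
        return np.vstack(mats)


# ---------------------------------------------------------------------------
# summaries and force thresholds
# ---------------------------------------------------------------------------

def summarize_hit_log(log: pd.DataFrame) -> pd.DataFrame:
    """Per-session-type hit summary.

    Returns one row per session type (practice, game, other) with the hit
    count, the percentage of all hits, and the median and mean of each
    acceleration metric. An empty log yields zero counts and NaN medians.
    """
    session = canonicalize_session(log["session_type"]) if len(log) else pd.Series([], dtype="string")
    total = len(log)
    rows = []
    for st in SESSION_TYPES:
        sel = np.asarray(session == st) if total else np.zeros(0, bool)
        n = int(sel.sum())
        row = {"session_type": st, "n_hits": n,
               "percent": 100.0 * n / total if total else 0.0}
        for metric, col in METRIC_COLUMNS.items():
            vals = np.asarray(log[col], dtype=float)[sel] if total else np.array([])
            row[f"{metric}_median"] = float(np.median(vals)) if n else np.nan
            row[f"{metric}_mean"] = float(np.mean(vals)) if n else np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("session_type")


@dataclass
class ThresholdSet:
    """Force thresholds (one per loading type) with provenance."""

    linear_threshold: float | None = None
    rotational_threshold: float | None = None
    provenance: str = "user-supplied"

    def __post_init__(self):
        for name in ("linear_threshold", "rotational_threshold"):
            v = getattr(self, name)
            if v is not None and not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be positive and finite, got {v}")


def cohort_sd_threshold(log: pd.DataFrame, metric: str) -> float:
    """Cohort force threshold: mean + 1 sample SD over all pooled hits.

    The SD uses the n-1 denominator. Requires at least 2 hits.
    """
    values = _metric_values(log, metric)
    if values.size < 2:
        raise ValueError("cohort threshold needs at least 2 hits")
    return float(values.mean() + values.std(ddof=1))


def cohort_thresholds(log: pd.DataFrame) -> ThresholdSet:
    """Mean + 1 SD thresholds for both loading types at once."""
    return ThresholdSet(
        linear_threshold=cohort_sd_threshold(log, "linear"),
        rotational_threshold=cohort_sd_threshold(log, "rotational"),
        provenance="cohort mean + 1 sample SD",
    )


def count_suprathreshold(player_hits: pd.DataFrame, metric: str,
                         threshold: float, inclusive: bool = True) -> int:
    """Number of hits with the metric at or above ``threshold``.

    Boundary hits count as exposure by default (``>=``); pass
    ``inclusive=False`` for a strict ``>`` comparison. A zero threshold is
    allowed and counts every hit.
    """
    if not (np.isfinite(threshold) and threshold >= 0):
        raise ValueError("threshold must be non-negative and finite")
    values = _metric_values(player_hits, metric)
    return int((values >= threshold).sum() if inclusive else (values > threshold).sum())


def count_exclusive(player_hits: pd.DataFrame, rot_threshold: float,
                    lin_threshold: float, mode: str) -> int:
    """Hits exceeding one force threshold but not the other.

    ``mode='rot_only'`` counts hits with rotational acceleration >=
    ``rot_threshold`` and linear acceleration < ``lin_threshold``;
    ``'lin_only'`` is the mirror image. Together with the both-suprathreshold
    and neither counts these partition the log.
    """
    if not (rot_threshold > 0 and lin_threshold > 0):
        raise ValueError("thresholds must be positive")
    rot = _metric_values(player_hits, "rotational") >= rot_threshold
    lin = _metric_values(player_hits, "linear") >= lin_threshold
    if mode == "rot_only":
        return int((rot & ~lin).sum())
    if mode == "lin_only":
        return int((lin & ~rot).sum())
    raise ValueError(f"mode must be 'rot_only' or 'lin_only', got {mode!r}")


def decile_thresholds(log: pd.DataFrame, metric: str) -> np.ndarray:
    """The 9 interior decile boundaries of the pooled metric distribution.

    Returns the 10th..90th percentiles (linear interpolation), a
    non-decreasing vector used as the threshold sweep of the dose-response
    sensitivity analysis. Requires at least 10 hits.
    """
    values = _metric_values(log, metric)
    if values.size < 10:
        raise ValueError("decile thresholds need at least 10 hits")
    return np.percentile(values, np.arange(10, 100, 10), method="linear")


def suprathreshold_counts_by_player(
    log: pd.DataFrame, metric: str, threshold: float,
    players: Sequence | None = None, inclusive: bool = True,
) -> pd.Series:
    """Per-player suprathreshold hit counts.

    ``players`` fixes the cohort roster; players without any logged hits get
    a count of zero (exposure is observed to be absent, not missing).
    """
    if players is None:
        players = sorted(pd.unique(log["player_id"]))
    out = pd.Series(0, index=pd.Index(players, name="player_id"), dtype=int)
    for pid, sub in log.groupby("player_id", sort=False):
        if pid in out.index:
            out[pid] = count_suprathreshold(sub, metric, threshold, inclusive)
    return out


def read_hit_log(path) -> pd.DataFrame:
    """Read a hit-log CSV, canonicalizing session labels and angle ranges."""
    log = pd.read_csv(path)
    missing = [c for c in HIT_LOG_COLUMNS if c not in log.columns]
    if missing:
        raise ValueError(f"hit log missing columns: {missing}")
    log["session_type"] = canonicalize_session(log["session_type"])
    az, el = canonicalize_angles(log["azimuth_deg"], log["elevation_deg"])
    log["azimuth_deg"], log["elevation_deg"] = az, el
    if (log[["linear_g", "rotational_rad_s2"]] < 0).any().any():
        raise ValueError("accelerations must be non-negative")
    return log
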