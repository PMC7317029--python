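"""Single-cell trajectory metrics: path length, displacement, speed,
directionality verdicts, and the polarized-actin vs invasion correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (DegenerateInputError, InsufficientDataError,
                         InvalidArgumentError)

TRACK_COLUMNS = ["track_id", "genotype", "t_min", "x_um", "y_um", "z_um"]


@dataclass
class Track:
    """Time-stamped 3-D trajectory of one cell (2-D inputs zero-fill z)."""

    track_id: str
    t_min: np.ndarray
    xyz_um: np.ndarray  # shape (n, 3)
    genotype: str = ""
    n_actin_spots: int | None = None

    def __post_init__(self):
        self.t_min = np.asarray(self.t_min, dtype=float)
        self.xyz_um = np.asarray(self.xyz_um, dtype=float)
        if self.xyz_um.ndim != 2 or self.xyz_um.shape[1] not in (2, 3):
            raise InvalidArgumentError("xyz_um must be (n, 2) or (n, 3)")
        if self.xyz_um.shape[1] == 2:
            self.xyz_um = np.column_stack(
                [self.xyz_um, np.zeros(len(self.xyz_um))])
        if len(self.t_min) != len(self.xyz_um):
            raise InvalidArgumentError("time and position lengths differ")
        if len(self.t_min) < 2:
            raise InvalidArgumentError("a track needs >= 2 samples")
        if np.any(np.diff(self.t_min) <= 0):
            raise InvalidArgumentError(
                f"track {self.track_id}: times not strictly increasing")


@dataclass
class TrackStats:
    track_id: str
    length_um: float
    displacement_um: float
    speed_um_min: float
    straightness: float  # displacement / length, NaN if length == 0
    genotype: str = ""
    n_actin_spots: int | None = None


def track_stats(track: Track) -> TrackStats:
    """Path length, start-to-end displacement, speed, and straightness.

    Mathematically displacement <= length (triangle inequality); floating
    rounding on exactly collinear tracks is clamped so the invariant holds
    and a perfectly straight track has straightness exactly 1.
    """
    steps = np.diff(track.xyz_um, axis=0)
    length = float(np.sum(np.linalg.norm(steps, axis=1)))
    displacement = float(np.linalg.norm(track.xyz_um[-1] - track.xyz_um[0]))
    # collinear tracks should have displacement == length exactly; float
    # rounding in the segment-wise sum can break the identity either way
    if abs(displacement - length) <= 1e-9 * max(length, 1.0):
        displacement = length
    elif displacement > length:
        displacement = length
    elapsed = float(track.t_min[-1] - track.t_min[0])
    speed = length / elapsed
    straightness = displacement / length if length > 0 else float("nan")
    return TrackStats(track_id=track.track_id, length_um=length,
                      displacement_um=displacement, speed_um_min=speed,
                      straightness=straightness, genotype=track.genotype,
                      n_actin_spots=track.n_actin_spots)


def stats_frame(tracks) -> pd.DataFrame:
    """TrackStats for an iterable of tracks, as a DataFrame."""
    rows = [track_stats(t).__dict__ for t in tracks]
    return pd.DataFrame(rows)


def directionality_test(track_stats_group, alpha: float = 0.05,
                        mode: str = "paired-t",
                        straightness_cutoff: float = 0.6) -> dict:
    """Directionality verdict for a group of tracks.

    ``paired-t`` (default): paired two-sided t-test of length vs displacement;
    the group is directional iff the difference is NOT significant (p >=
    alpha).  This is an inverse test, so two alternative operationalizations
    are offered: ``tost`` (equivalence of length and displacement within 20%
    of mean length) where directional iff equivalence IS significant, and
    ``straightness`` where directional iff mean straightness >= the cutoff.
    """
    group = list(track_stats_group)
    if len(group) < 3:
        raise InsufficientDataError("need >= 3 tracks")
    lengths = np.array([t.length_um for t in group])
    disps = np.array([t.displacement_um for t in group])
    straight = np.array([t.straightness for t in group])
    out = {"n": len(group), "mean_length_um": float(lengths.mean()),
           "mean_displacement_um": float(disps.mean()),
           "mean_straightness": float(np.nanmean(straight)),
           "mode": mode, "alpha": alpha,
           "note": "directional = failure to reject length == displacement"
                   if mode == "paired-t" else ""}
    diffs = lengths - disps
    if mode == "paired-t":
        if np.allclose(diffs, 0.0):
            p = 1.0
        else:
            p = float(stats.ttest_rel(lengths, disps).pvalue)
        out["p"] = p
        out["directional"] = bool(p >= alpha)
    elif mode == "tost":
        bound = 0.2 * float(lengths.mean())
        se = diffs.std(ddof=1) / np.sqrt(len(diffs)) if len(diffs) > 1 else 0.0
        if se == 0:
            p = 0.0 if abs(diffs.mean()) < bound else 1.0
        else:
            df = len(diffs) - 1
            t_low = (diffs.mean() + bound) / se
            t_high = (diffs.mean() - bound) / se
            p = max(1 - stats.t.cdf(t_low, df), stats.t.cdf(t_high, df))
        out["p"] = float(p)
        out["directional"] = bool(p < alpha)
    elif mode == "straightness":
        out["p"] = float("nan")
        out["directional"] = bool(out["mean_straightness"] >= straightness_cutoff)
    else:
        raise InvalidArgumentError(f"unknown directionality mode: {mode!r}")
    return out


def group_speed(track_stats_all, grouping: str = "genotype") -> dict:
    """Per-group mean +/- SEM of speed with a two-group Welch comparison.

    ``grouping`` is ``genotype`` or ``n_actin_spots`` (the latter is binned
    into 'single' vs 'multiple').  With exactly two groups the fold change of
    the larger over the smaller mean and a two-sided Welch t p-value are
    reported.
    """
    if grouping not in ("genotype", "n_actin_spots"):
        raise InvalidArgumentError(f"unknown grouping: {grouping!r}")
    groups: dict[str, list] = {}
    for t in track_stats_all:
        if grouping == "genotype":
            key = t.genotype
        else:
            if t.n_actin_spots is None:
                continue
            key = "single" if t.n_actin_spots <= 1 else "multiple"
        groups.setdefault(key, []).append(t.speed_um_min)
    if len(groups) < 2:
        raise InsufficientDataError("need >= 2 groups")
    for key, speeds in groups.items():
        if len(speeds) < 2:
            raise InsufficientDataError(f"group {key!r} has < 2 tracks")
    summary = {key: {"n": len(v), "mean": float(np.mean(v)),
                     "sem": float(np.std(v, ddof=1) / np.sqrt(len(v)))}
               for key, v in groups.items()}
    out = {"groups": summary}
    if len(groups) == 2:
        (ka, va), (kb, vb) = sorted(groups.items())
        ma, mb = np.mean(va), np.mean(vb)
        hi, lo = (ma, mb) if ma >= mb else (mb, ma)
        out["fold_change"] = float(hi / lo) if lo > 0 else float("inf")
        if np.allclose(va, np.mean(va)) and np.allclose(vb, np.mean(vb)) \
                and np.isclose(ma, mb):
            out["p"] = 1.0
        else:
            out["p"] = float(stats.ttest_ind(va, vb, equal_var=False).pvalue)
        out["comparison"] = (ka, kb)
    return out


def spot_invasion_correlation(pct_polarized, pct_invading) -> dict:
    """Midrank Spearman rho, its square, and the two-sided p-value for the
    per-animal polarized-actin fraction vs invading fraction."""
    x = np.asarray(pct_polarized, dtype=float)
    y = np.asarray(pct_invading, dtype=float)
    if len(x) != len(y):
        raise InvalidArgumentError("paired vectors differ in length")
    if len(x) < 3:
        raise InsufficientDataError("need >= 3 animals")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise DegenerateInputError("constant vector: Spearman rho undefined")
    rho, p = stats.spearmanr(x, y)
    return {"rho": float(rho), "r_s2": float(rho) ** 2, "p": float(p),
            "n": len(x)}


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_tracks(path) -> list[Track]:
    """Read a track CSV (``track_id,genotype,t_min,x_um,y_um,z_um
    [,n_actin_spots]``) into Track objects, ordered by time."""
    df = pd.read_csv(path)
    tracks = []
    for tid, grp in df.groupby("track_id", sort=True):
        grp = grp.sort_values("t_min")
        spots = None
        if "n_actin_spots" in grp.columns and grp["n_actin_spots"].notna().all():
            spots = int(grp["n_actin_spots"].iloc[0])
        z = grp["z_um"].to_numpy() if "z_um" in grp.columns else \
            np.zeros(len(grp))
        tracks.append(Track(
            track_id=str(tid), t_min=grp["t_min"].to_numpy(),
            xyz_um=np.column_stack([grp["x_um"], grp["y_um"], z]),
            genotype=str(grp["genotype"].iloc[0]) if "genotype" in grp.columns
            else "", n_actin_spots=spots))
    return tracks


def tracks_from_frame(df: pd.DataFrame) -> list[Track]:
    """Build Track objects from a long-form DataFrame (same columns as CSV)."""
    out = []
    for tid, grp in df.groupby("track_id", sort=True):
        grp = grp.sort_values("t_min")
        spots = None
        if "n_actin_spots" in grp.columns and grp["n_actin_spots"].notna().all():
            spots = int(grp["n_actin_spots"].iloc[0])
        out.append(Track(
            track_id=str(tid), t_min=grp["t_min"].to_numpy(),
            xyz_um=grp[["x_um", "y_um", "z_um"]].to_numpy(),
            genotype=str(grp["genotype"].iloc[0]) if "genotype" in grp.columns
            else "", n_actin_spots=spots))
    return out


def write_tracks(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)
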