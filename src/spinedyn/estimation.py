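"""Binned moment estimation of spine-volume drift and diffusion.

From longitudinal volume tables this module extracts session-to-session
transitions, pools them into fixed-count volume bins, and estimates per-bin
SD and mean of the volume change.  The per-2-day SD is then decomposed into
fast (minute-scale) and slow (day-scale) components in quadrature, and the
slow SD and the drift are fitted as linear functions of ``V**(2/3)``:

    sigma_j^2 = sum (dV_i - mu_j)^2 / N_j        (population divisor)
    mu_j      = sum dV_i / N_j
    sigma^2   = sigma_fast^2 + sigma_slow^2
    sigma_slow(V) = a (V**(2/3) - anchor_v**(2/3)) + anchor_sigma
    mu(V)         = c V**(2/3) + d

The slow fit is anchored through the smallest-bin point so that the
behaviour of very small spines -- which dominates turnover -- constrains
the line.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .model import VOLUME_EXPONENT

__all__ = [
    "TRAJECTORY_COLUMNS",
    "BinnedMoments",
    "read_trajectories",
    "validate_trajectories",
    "pair_transitions",
    "bin_and_moment",
    "fit_fast",
    "decompose_slow",
    "fit_anchored_slope",
    "fit_drift",
    "drift_zero_crossing",
    "compare_slopes",
    "elimination_by_dendrite",
]

TRAJECTORY_COLUMNS = [
    "animal_id", "dendrite_id", "spine_id", "group",
    "session", "volume_um3", "eliminated",
]

#: anchor of the slow-SD fit: median volume of the smallest bin and the
#: average SD observed there.
ANCHOR_V = 0.015
ANCHOR_SIGMA = 0.02

DEFAULT_BIN_SIZE = 32


@dataclass
class BinnedMoments:
    """Per-bin summary of volume-change moments.

    One row per bin: representative volume (median of member start
    volumes), SD and mean of the changes, member count, chi-square 95%
    interval for the SD and standard error of the mean.
    """

    table: pd.DataFrame  # volume, sigma, mu, n, sigma_lo, sigma_hi, mu_sem
    bin_size: int

    def __post_init__(self) -> None:
        t = self.table
        if not t["volume"].is_monotonic_increasing:
            raise ValueError("bins must be ordered by representative volume")
        if (t["sigma"] < 0).any():
            raise ValueError("sigma must be non-negative")

    @property
    def volume(self) -> np.ndarray:
        return self.table["volume"].to_numpy()

    @property
    def sigma(self) -> np.ndarray:
        return self.table["sigma"].to_numpy()

    @property
    def mu(self) -> np.ndarray:
        return self.table["mu"].to_numpy()

    def __len__(self) -> int:
        return len(self.table)


# ---------------------------------------------------------------------------
# table handling

def validate_trajectories(table: pd.DataFrame) -> pd.DataFrame:
    """Check schema and per-spine structure of a longitudinal volume table."""
    missing = set(TRAJECTORY_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"trajectory table missing columns: {sorted(missing)}")
    if (table["volume_um3"] < 0).any():
        raise ValueError("volumes must be >= 0")
    bad_groups = set(table["group"].unique()) - {"WT", "KO"}
    if bad_groups:
        raise ValueError(f"unknown group labels: {sorted(bad_groups)}")
    key = ["animal_id", "dendrite_id", "spine_id"]
    g = table.groupby(key, sort=False)
    if (g["session"].apply(lambda s: not s.is_monotonic_increasing or s.duplicated().any())).any():
        raise ValueError("sessions must be strictly increasing within each spine")
    # an elimination flag terminates the series
    after_elim = g.apply(
        lambda d: bool(d["eliminated"].to_numpy()[:-1].any()), include_groups=False
    )
    if after_elim.any():
        raise ValueError("eliminated=True must be the last record of a spine")
    return table


def read_trajectories(path: str | Path) -> pd.DataFrame:
    """Read and validate a trajectory CSV (schema ``TRAJECTORY_COLUMNS``)."""
    table = pd.read_csv(path)
    table["eliminated"] = table["eliminated"].astype(bool)
    return validate_trajectories(table)


def pair_transitions(
    table: pd.DataFrame, interval: int = 1, min_session: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Extract per-spine transitions separated by ``interval`` sessions.

    Returns ``(transitions, eliminations)``.  ``transitions`` has columns
    ``v_start, v_end, dv`` plus the identifying keys; pairs whose endpoint
    is an elimination are excluded from the moment sample (the volume is
    undefined there) and returned separately with their starting volume.
    ``min_session`` optionally drops observations from earlier sessions
    (e.g. to exclude the first post-surgery imaging day).
    """
    if interval < 1:
        raise ValueError("interval must be >= 1")
    if min_session is not None:
        table = table[table["session"] >= min_session]
    key = ["animal_id", "dendrite_id", "spine_id", "group"]
    trans, elim = [], []
    for ids, d in table.groupby(key, sort=False):
        sess = d["session"].to_numpy()
        vol = d["volume_um3"].to_numpy()
        gone = d["eliminated"].to_numpy()
        pos = {s: i for i, s in enumerate(sess)}
        for i, s in enumerate(sess):
            j = pos.get(s + interval)
            if j is None or gone[i]:
                continue
            rec = dict(zip(key, ids))
            if gone[j]:
                elim.append({**rec, "session": s, "v_start": vol[i]})
            else:
                trans.append({**rec, "session": s, "v_start": vol[i],
                              "v_end": vol[j], "dv": vol[j] - vol[i]})
    cols_t = key + ["session", "v_start", "v_end", "dv"]
    cols_e = key + ["session", "v_start"]
    return (
        pd.DataFrame(trans, columns=cols_t),
        pd.DataFrame(elim, columns=cols_e),
    )


# ---------------------------------------------------------------------------
# moments

def bin_and_moment(
    transitions: pd.DataFrame, bin_size: int = DEFAULT_BIN_SIZE
) -> BinnedMoments:
    """Fixed-count volume bins with per-bin SD/mean of the volume change.

    Transitions are sorted by starting volume and grouped into consecutive
    bins of ``bin_size``; a final remainder smaller than ``bin_size/2`` is
    merged into the previous bin.  The SD uses the population divisor
    ``N_j``; its 95% interval comes from the chi-square pivot
    ``N_j sigma_j^2 / sigma^2 ~ chi2(N_j - 1)``.
    """
    if len(transitions) < bin_size:
        raise ValueError(
            f"need at least one full bin ({bin_size} transitions), got {len(transitions)}"
        )
    s = transitions.sort_values("v_start", kind="mergesort")
    v = s["v_start"].to_numpy()
    dv = s["dv"].to_numpy()
    edges = list(range(0, v.size, bin_size)) + [v.size]
    if edges[-1] - edges[-2] < max(bin_size // 2, 1) and len(edges) > 2:
        del edges[-2]  # merge short remainder into previous bin
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        d = dv[lo:hi]
        n = d.size
        mu = d.mean()
        sigma = float(np.sqrt(np.mean((d - mu) ** 2)))  # divisor N
        if n > 1:
            chi_hi, chi_lo = stats.chi2.ppf([0.975, 0.025], df=n - 1)
            sig_lo = sigma * np.sqrt(n / chi_hi)
            sig_hi = sigma * np.sqrt(n / chi_lo)
            sem = d.std(ddof=1) / np.sqrt(n)
        else:
            sig_lo = sig_hi = sigma
            sem = np.nan
        rows.append(dict(volume=float(np.median(v[lo:hi])), sigma=sigma, mu=float(mu),
                         n=n, sigma_lo=float(sig_lo), sigma_hi=float(sig_hi),
                         mu_sem=float(sem)))
    return BinnedMoments(table=pd.DataFrame(rows), bin_size=bin_size)


# ---------------------------------------------------------------------------
# fits

def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    X = sm.add_constant(x)
    res = sm.OLS(y, X).fit()
    return float(res.params[1]), float(res.params[0])


def fit_fast(moments_10min: BinnedMoments) -> tuple[float, float]:
    """Fit the fast-fluctuation SD law from 10-min-spacing moments.

    Unconstrained least squares of per-bin SD against ``V**(2/3)``; the
    drift at this timescale is fitted as zero.  Returns
    ``(slope, intercept)``.
    """
    if len(moments_10min) < 2:
        raise ValueError("need at least 2 bins to fit the fast SD line")
    slope, intercept = _ols_line(
        moments_10min.volume ** VOLUME_EXPONENT, moments_10min.sigma
    )
    return slope, intercept


def decompose_slow(
    moments_2d: BinnedMoments, fast: tuple[float, float]
) -> BinnedMoments:
    """Quadrature subtraction of the fast component from per-2-d SDs.

    ``sigma_slow_j = sqrt(max(sigma_j^2 - sigma_fast(V_j)^2, 0))``; bins
    where the subtraction clips to zero are flagged in column ``clipped``.
    """
    e, f = fast
    t = moments_2d.table.copy()
    sf = e * t["volume"].to_numpy() ** VOLUME_EXPONENT + f
    s2 = t["sigma"].to_numpy() ** 2 - sf**2
    t["clipped"] = s2 < 0
    t["sigma"] = np.sqrt(np.clip(s2, 0.0, None))
    # chi-square interval no longer applies after subtraction; propagate the
    # clipping to the interval columns so they stay ordered
    t["sigma_lo"] = np.minimum(t["sigma_lo"], t["sigma"])
    t["sigma_hi"] = np.maximum(t["sigma_hi"], t["sigma"])
    return BinnedMoments(table=t, bin_size=moments_2d.bin_size)


def fit_anchored_slope(
    slow_moments: BinnedMoments,
    anchor_v: float = ANCHOR_V,
    anchor_sigma: float = ANCHOR_SIGMA,
) -> tuple[float, tuple[float, float]]:
    """One-parameter slope of sigma_slow vs ``V**(2/3)`` through the anchor.

    Least squares of ``sigma_slow - anchor_sigma`` on
    ``V**(2/3) - anchor_v**(2/3)`` without intercept.  Returns
    ``(slope, (ci_low, ci_high))`` with a 95% interval.
    """
    if len(slow_moments) < 2:
        raise ValueError("need at least 2 bins for the anchored fit")
    x = slow_moments.volume ** VOLUME_EXPONENT - anchor_v**VOLUME_EXPONENT
    y = slow_moments.sigma - anchor_sigma
    res = sm.OLS(y, x[:, None]).fit()
    lo, hi = res.conf_int()[0]
    return float(res.params[0]), (float(lo), float(hi))


def fit_drift(moments_2d: BinnedMoments) -> tuple[float, float]:
    """Unconstrained line of per-bin mean change against ``V**(2/3)``.

    Pools whatever transitions the moments were built from (drift is shared
    between groups).  Returns ``(slope, intercept)``.
    """
    if len(moments_2d) < 2:
        raise ValueError("need at least 2 bins to fit the drift line")
    return _ols_line(moments_2d.volume ** VOLUME_EXPONENT, moments_2d.mu)


def drift_zero_crossing(drift: tuple[float, float]) -> float:
    """Volume where the fitted drift line crosses zero: ``(d/-c)**(3/2)``."""
    c, d = drift
    if c >= 0 or d <= 0:
        raise ValueError(f"drift line has no zero crossing: slope={c}, intercept={d}")
    return float((d / -c) ** 1.5)


def compare_slopes(
    slow_moments_a: BinnedMoments,
    slow_moments_b: BinnedMoments,
    anchor_v: float = ANCHOR_V,
    anchor_sigma: float = ANCHOR_SIGMA,
) -> tuple[float, float]:
    """Group difference of anchored slow-SD slopes, as a linear model.

    Pools both groups in anchored coordinates and fits
    ``y ~ x + x:group`` without intercept; returns the interaction's
    ``(t_statistic, p_value)`` (two-sided).
    """
    xs, ys, gs = [], [], []
    for g, m in ((0.0, slow_moments_a), (1.0, slow_moments_b)):
        if len(m) < 2:
            raise ValueError("both groups need at least 2 bins")
        xs.append(m.volume ** VOLUME_EXPONENT - anchor_v**VOLUME_EXPONENT)
        ys.append(m.sigma - anchor_sigma)
        gs.append(np.full(len(m), g))
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    g = np.concatenate(gs)
    X = np.column_stack([x, x * g])
    res = sm.OLS(y, X).fit()
    return float(res.tvalues[1]), float(res.pvalues[1])


def elimination_by_dendrite(
    table: pd.DataFrame, interval: int = 1
) -> pd.DataFrame:
    """Per-dendrite elimination fraction over ``interval``-session pairs.

    The unit of the group comparison (Mann-Whitney U) is the dendrite, not
    the spine.  Returns columns ``animal_id, dendrite_id, group, n_pairs,
    n_eliminated, fraction``.
    """
    trans, elim = pair_transitions(table, interval=interval)
    key = ["animal_id", "dendrite_id", "group"]
    n_t = trans.groupby(key).size() if len(trans) else pd.Series(dtype=int)
    n_e = elim.groupby(key).size() if len(elim) else pd.Series(dtype=int)
    idx = n_t.index.union(n_e.index)
    out = pd.DataFrame(index=idx)
    out["n_pairs"] = n_t.reindex(idx, fill_value=0) + n_e.reindex(idx, fill_value=0)
    out["n_eliminated"] = n_e.reindex(idx, fill_value=0)
    out["fraction"] = out["n_eliminated"] / out["n_pairs"]
    return out.reset_index()
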