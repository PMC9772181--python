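"""Striola vs extrastriola paired comparison of response vector lengths.

Cells are grouped by hair-bundle polarity — the orientation of their tilt
response vector — in 10° bins over the circle, separately per utricle.
Within every (utricle × bin) group the mean vector length is computed for
striolar and extrastriolar cells; groups whose extrastriolar compartment
is empty (the medial-down preferring cells live only in the striola) are
excluded, and the remaining paired means are compared with a two-sided
Wilcoxon signed-rank test (exact null by sign-flip enumeration up to
n = 15, normal approximation with tie correction above).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

__all__ = [
    "PairedTestResult",
    "polarity_groups",
    "exclude_striola_only",
    "wilcoxon_signed_rank",
    "compare_striola_extrastriola",
]


@dataclass
class PairedTestResult:
    """Wilcoxon signed-rank outcome on paired group means."""

    n_pairs: int
    statistic: float       # W+ = sum of ranks of positive differences
    p_two_sided: float
    direction: str         # sign of the median difference (first − second)
    method: str            # 'exact' or 'approx'


def polarity_groups(
    vectors: pd.DataFrame,
    bin_deg: float = 10.0,
    *,
    length_col: str = "length",
) -> tuple[pd.DataFrame, int]:
    """Bin cells into polarity groups and average lengths per compartment.

    ``vectors`` needs columns utricle_id, pref_rc, pref_ml, striolar and a
    length column (tilt vector length or vibration combined length).  The
    polarity angle is the preferred-vector angle, binned into [0°, 10°),
    [10°, 20°), … with 0° = rostral.  Returns the per-(utricle × bin) table
    and the number of zero-length vectors excluded.
    """
    df = vectors.copy()
    norm = np.hypot(df.pref_rc, df.pref_ml)
    n_excluded = int((norm == 0).sum())
    df = df[norm > 0].copy()
    angle = np.degrees(np.arctan2(df.pref_ml, df.pref_rc)) % 360.0
    n_bins = int(round(360.0 / bin_deg))
    df["bin_index"] = np.minimum((angle / bin_deg).astype(int), n_bins - 1)
    df["bin_center_deg"] = (df.bin_index + 0.5) * bin_deg
    rows = []
    for (uid, _), grp in df.groupby(["utricle_id", "bin_index"], sort=True):
        s = grp[grp.striolar]
        e = grp[~grp.striolar]
        rows.append(dict(
            utricle_id=uid,
            bin_center_deg=float(grp.bin_center_deg.iloc[0]),
            striolar_mean_length=float(s[length_col].mean()) if len(s) else np.nan,
            extrastriolar_mean_length=float(e[length_col].mean()) if len(e) else np.nan,
            n_striolar=len(s),
            n_extrastriolar=len(e),
        ))
    return pd.DataFrame(rows), n_excluded


def exclude_striola_only(groups: pd.DataFrame) -> pd.DataFrame:
    """Drop polarity groups that lack extrastriolar members.

    These are the medial-down preferring groups, which exist only inside
    the striola and therefore cannot be paired.
    """
    return groups[groups.n_extrastriolar > 0].reset_index(drop=True)


def _signed_ranks(diffs: np.ndarray):
    d = diffs[diffs != 0]
    ranks = pd.Series(np.abs(d)).rank(method="average").to_numpy()
    w_plus = float(ranks[d > 0].sum())
    return d, ranks, w_plus


def wilcoxon_signed_rank(first, second=None, *, exact_max_n: int = 15,
                         warn_all_zero: bool = True) -> PairedTestResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped; tied magnitudes get mid-ranks.  For
    n ≤ ``exact_max_n`` the null distribution of W+ is enumerated over all
    2^n sign assignments (valid with ties); larger samples use the normal
    approximation with tie correction, without continuity correction.
    """
    first = np.asarray(first, dtype=float)
    if second is not None:
        diffs = first - np.asarray(second, dtype=float)
    else:
        diffs = first
    d, ranks, w_plus = _signed_ranks(diffs)
    n = len(d)
    if n == 0:
        if warn_all_zero:
            import warnings

            warnings.warn("all paired differences are zero; p = 1")
        return PairedTestResult(n_pairs=0, statistic=0.0, p_two_sided=1.0,
                                direction="none", method="degenerate")
    med = np.median(d)
    direction = "first_greater" if med > 0 else (
        "second_greater" if med < 0 else "none")
    if n <= exact_max_n:
        # enumerate W+ over every sign assignment of the ranked magnitudes
        total = 0
        le = 0
        ge = 0
        for signs in product((0.0, 1.0), repeat=n):
            w = float(np.dot(signs, ranks))
            total += 1
            le += w <= w_plus + 1e-9
            ge += w >= w_plus - 1e-9
        p = min(1.0, 2.0 * min(le, ge) / total)
        method = "exact"
    else:
        mu = n * (n + 1) / 4.0
        tie_counts = pd.Series(np.abs(d)).round(12).value_counts().to_numpy()
        var = n * (n + 1) * (2 * n + 1) / 24.0 - \
            float(((tie_counts**3 - tie_counts) / 48.0).sum())
        z = (w_plus - mu) / np.sqrt(var)
        from scipy.stats import norm

        p = min(1.0, 2.0 * norm.sf(abs(z)))
        method = "approx"
    return PairedTestResult(n_pairs=n, statistic=w_plus, p_two_sided=float(p),
                            direction=direction, method=method)


def compare_striola_extrastriola(
    groups: pd.DataFrame,
    modality: str = "tilt",
) -> tuple[PairedTestResult, pd.DataFrame]:
    """Paired striolar-vs-extrastriolar test over retained polarity groups.

    Returns the test result (direction reported as striolar vs
    extrastriolar) and the paired table used.
    """
    kept = groups[(groups.n_striolar > 0) & (groups.n_extrastriolar > 0)]
    pairs = kept[["utricle_id", "bin_center_deg",
                  "striolar_mean_length", "extrastriolar_mean_length"]].copy()
    res = wilcoxon_signed_rank(pairs.striolar_mean_length.to_numpy(),
                               pairs.extrastriolar_mean_length.to_numpy())
    direction = {"first_greater": "striolar_greater",
                 "second_greater": "extrastriolar_greater",
                 "none": "none"}[res.direction]
    res = PairedTestResult(n_pairs=res.n_pairs, statistic=res.statistic,
                           p_two_sided=res.p_two_sided, direction=direction,
                           method=res.method)
    pairs.insert(0, "modality", modality)
    return res, pairs
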