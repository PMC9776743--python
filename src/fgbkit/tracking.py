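"""Longitudinal clone-fate analytics over per-code fraction time series.

A clone time series is a DataFrame with one row per timepoint (passage or
day, strictly increasing index) and one column per ``bc_id``; rows are
fraction vectors. The analytics are:

* size classes per timepoint — minor (<= 2%), intermediate, large (> 5%),
  dominant (> 10%), with strict inequalities at the printed cutoffs;
* trajectory patterns — longitudinal extinction, continuous expansion,
  transient expansion and collapse, delayed expansion, plus a catch-all
  persisting class for clones meeting none of the four named criteria;
* paired-sample correlation (squared Pearson R^2 on fractions), the
  statistic used to compare aliquots of one mix measured in two assays;
* relative fitness per clone from the log-linear slope of
  ``log(f_i / f_ref)`` against passage (exact for replicator dynamics);
* per-code fold change of a treated culture against its vehicle control at
  the endpoint, reporting expansion (> 1) and collapse (< 1).

The four named patterns have no published numerical definition; the rule
set and default parameters here are this package's operationalization and
are fully exposed in :class:`TrajectoryParams`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

SIZE_CLASS_LABELS = ("minor", "intermediate", "large", "dominant")
TRAJECTORY_PATTERNS = (
    "longitudinal_extinction",
    "continuous_expansion",
    "transient_expansion_collapse",
    "delayed_expansion",
    "persisting",
)

#: size-class cutoffs on clone fraction (strict inequalities as printed:
#: minor <= 2%; large > 5%; dominant > 10%)
MINOR_MAX = 0.02
LARGE_MIN = 0.05
DOMINANT_MIN = 0.10


def normalize_to_baseline(series: pd.Series | Sequence[float]) -> pd.Series:
    """Series relative to its first timepoint (the day-0 normalization used
    for gene-marking trajectories); the first entry is exactly 1.0."""
    s = pd.Series(series, dtype=float) if not isinstance(series, pd.Series) else series.astype(float)
    if len(s) == 0:
        raise ValueError("empty series")
    baseline = s.iloc[0]
    if baseline <= 0:
        raise ValueError("undefined baseline: first timepoint value must be > 0")
    return s / baseline


def fold_change(series: pd.Series | Sequence[float]) -> float:
    """Fold change between the first and last timepoint."""
    s = normalize_to_baseline(series)
    return float(s.iloc[-1])


def size_classes(fractions: Mapping[int, float] | pd.Series) -> pd.DataFrame:
    """Classify each code's fraction at one timepoint.

    Returns a DataFrame indexed by bc_id with the fraction and its class;
    ``.attrs['counts']`` carries the per-class tally. Dominant clones are a
    subset of large by value, but the classes partition [0, 1]: a dominant
    clone is labeled dominant, not large.
    """
    f = pd.Series(dict(fractions), dtype=float) if not isinstance(fractions, pd.Series) else fractions.astype(float)
    if ((f < 0) | (f > 1)).any():
        raise ValueError("fractions must be in [0, 1]")
    labels = pd.Series("intermediate", index=f.index, dtype=object)
    labels[f <= MINOR_MAX] = "minor"
    labels[f > LARGE_MIN] = "large"
    labels[f > DOMINANT_MIN] = "dominant"
    out = pd.DataFrame({"fraction": f, "size_class": labels})
    out.index.name = "bc_id"
    counts = labels.value_counts().reindex(SIZE_CLASS_LABELS, fill_value=0)
    out.attrs["counts"] = counts.to_dict()
    return out


@dataclass
class TrajectoryParams:
    """Decision rules for the trajectory-pattern classifier.

    ``extinct_below`` is the absolute fraction floor below which a clone is
    gone; ``expand_factor`` the final/initial ratio calling expansion;
    ``peak_factor`` and ``collapse_factor`` the rise to and fall from the
    peak calling a transient; ``late_window_fraction`` the trailing share of
    the observation window to which growth must be confined for a delayed
    call (the clone must stay within a factor 2 of its initial size through
    the early window).
    """

    extinct_below: float = 0.001
    expand_factor: float = 3.0
    peak_factor: float = 3.0
    collapse_factor: float = 3.0
    late_window_fraction: float = 0.5


def classify_trajectory(
    series: pd.Series | Sequence[float],
    params: TrajectoryParams | None = None,
) -> str:
    """Assign one of the five trajectory patterns to a clone's series.

    Rules, evaluated in order on initial value ``f0``, final value ``fT``
    and maximum ``fmax``:

    1. longitudinal extinction — ``fT <= extinct_below < f0``;
    2. transient expansion and collapse — ``fmax >= peak_factor * f0`` and
       ``fT <= fmax / collapse_factor`` and ``fT < expand_factor * f0``;
    3. delayed expansion — ``fT >= expand_factor * f0`` with the series
       confined to ``[f0 / 2, 2 * f0]`` through the early window;
    4. continuous expansion — ``fT >= expand_factor * f0`` with the
       maximum at or adjacent to the final timepoint;
    5. persisting — everything else.
    """
    params = params or TrajectoryParams()
    s = np.asarray(series, dtype=float)
    if s.ndim != 1 or len(s) < 4:
        raise ValueError("trajectory classification needs a 1-D series of >= 4 timepoints")
    f0, fT, fmax = s[0], s[-1], s.max()

    if fT <= params.extinct_below < f0:
        return "longitudinal_extinction"

    expanded = fT >= params.expand_factor * f0
    if (
        fmax >= params.peak_factor * f0
        and fT <= fmax / params.collapse_factor
        and not expanded
    ):
        return "transient_expansion_collapse"

    if expanded:
        n_early = int(np.floor(len(s) * (1.0 - params.late_window_fraction)))
        early = s[:n_early]
        confined = n_early > 0 and np.all((early >= f0 / 2.0) & (early <= 2.0 * f0))
        if confined:
            return "delayed_expansion"
        if int(np.argmax(s)) >= len(s) - 2:
            return "continuous_expansion"

    return "persisting"


def classify_trajectories(
    series: pd.DataFrame, params: TrajectoryParams | None = None
) -> pd.Series:
    """Pattern label per column of a timepoint x bc_id fraction matrix."""
    return pd.Series(
        {col: classify_trajectory(series[col], params) for col in series.columns},
        name="pattern",
    ).rename_axis("bc_id")


def paired_correlation(
    fractions_a: Mapping[int, float] | pd.Series | Sequence[float],
    fractions_b: Mapping[int, float] | pd.Series | Sequence[float],
) -> float:
    """Squared Pearson correlation of paired per-code fractions.

    The statistic used to compare population sizes of the same clones
    measured in two assays (e.g. a 24-code parent mix against the combined
    48-code mix, or replicate aliquots at day 0). Returns NaN with a
    warning when either vector has zero variance.
    """
    a = pd.Series(dict(fractions_a), dtype=float) if isinstance(fractions_a, Mapping) else pd.Series(fractions_a, dtype=float)
    b = pd.Series(dict(fractions_b), dtype=float) if isinstance(fractions_b, Mapping) else pd.Series(fractions_b, dtype=float)
    if isinstance(fractions_a, Mapping) or isinstance(fractions_b, Mapping):
        common = a.index.intersection(b.index)
        a, b = a.loc[common], b.loc[common]
    if len(a) != len(b) or len(a) < 3:
        raise ValueError("paired correlation needs >= 3 shared codes")
    if a.std() == 0 or b.std() == 0:
        warnings.warn("zero variance in one fraction vector; R^2 undefined", UserWarning, stacklevel=2)
        return float("nan")
    r, _ = stats.pearsonr(a.to_numpy(), b.to_numpy())
    return float(r**2)


def estimate_fitness(
    series: pd.DataFrame,
    reference_code: int,
) -> pd.Series:
    """Per-clone relative fitness from log-ratio slopes.

    Under replicator dynamics ``log(f_i(t) / f_ref(t))`` is linear in the
    passage number with slope ``log(w_i / w_ref)``; the estimate is the
    exponentiated least-squares slope, so the reference clone's fitness is
    exactly 1. Clones with a zero fraction at any timepoint cannot be
    fitted and are returned as NaN with a warning.
    """
    if reference_code not in series.columns:
        raise ValueError(f"reference code {reference_code} not in series")
    t = np.asarray(series.index, dtype=float)
    if len(t) < 2:
        raise ValueError("fitness estimation needs >= 2 timepoints")
    ref = series[reference_code].to_numpy(float)
    if (ref <= 0).any():
        raise ValueError("reference clone hits zero fraction; choose another reference")
    out = {}
    skipped = []
    for col in series.columns:
        f = series[col].to_numpy(float)
        if (f <= 0).any():
            out[col] = float("nan")
            skipped.append(col)
            continue
        slope = np.polyfit(t, np.log(f / ref), 1)[0]
        out[col] = float(np.exp(slope))
    if skipped:
        warnings.warn(
            f"clones with zero fractions skipped in fitness fit: {skipped}",
            UserWarning,
            stacklevel=2,
        )
    result = pd.Series(out, name="relative_fitness")
    result.index.name = "bc_id"
    return result


def perturbagen_response(
    treated: pd.DataFrame | pd.Series | Mapping[int, float],
    control: pd.DataFrame | pd.Series | Mapping[int, float],
) -> pd.DataFrame:
    """Per-code fold change of a treated culture over its vehicle control.

    Series/mapping inputs are endpoint fraction vectors; DataFrame inputs
    are time series, of which the final common timepoint is used. Codes at
    zero in the control have an undefined fold change (NaN, flagged).
    Fold change > 1 reads as clonal expansion under treatment, < 1 as
    collapse.
    """

    def endpoint(x) -> pd.Series:
        if isinstance(x, pd.DataFrame):
            return x.iloc[-1].astype(float)
        return pd.Series(dict(x), dtype=float) if isinstance(x, Mapping) else x.astype(float)

    if isinstance(treated, pd.DataFrame) and isinstance(control, pd.DataFrame):
        shared = treated.index.intersection(control.index)
        if len(shared) == 0:
            raise ValueError("no common timepoints between treated and control")
        treated = treated.loc[shared]
        control = control.loc[shared]
    t = endpoint(treated)
    c = endpoint(control)
    if not t.index.equals(c.index):
        common = t.index.intersection(c.index)
        if len(common) == 0:
            raise ValueError("treated and control share no codes")
        t, c = t.loc[common], c.loc[common]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = t / c
    ratio[c == 0] = np.nan
    out = pd.DataFrame(
        {
            "fold_change": ratio,
            "response": pd.cut(
                ratio,
                bins=[-np.inf, 1.0 - 1e-12, 1.0 + 1e-12, np.inf],
                labels=["collapsing", "stable", "expanding"],
            ),
            "flagged": (c == 0).to_numpy(),
        }
    )
    out.index.name = "bc_id"
    return out
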