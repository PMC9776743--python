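"""Hierarchical gating deconvolution of color-coded cytometry events.

The gating follows the bench strategy: scatter gate (debris out), singlet
gate on the FSC-A/FSC-H pulse relation (doublets out), DAPI viability gate
(dead cells out), EGFRt pre-gate on vector-bearing cells, then boolean
classification of the three fluorescent-protein channels into one of the
six valid combos and of the three CAAR tag channels into one of the eight
permutations; the (combo, permutation) pair indexes the code registry.

All gates are axis-aligned thresholds on log10 intensity — reproducible and
sufficient for the combinatorial code structure; 2-D polygon gates are out
of scope. Ties exactly at a threshold resolve as negative (positivity is a
strict inequality).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde, norm
from sklearn.mixture import GaussianMixture

from fgbkit.registry import (
    CAAR_CHANNELS,
    CHANNELS,
    FLUOR_CHANNELS,
    CaarPermutation,
    CodeRegistry,
    FluorCombo,
    fluor_combo_from_positives,
)

MARKER_CHANNELS = CHANNELS  # 7 thresholded marker channels

#: non-code event labels
VECTOR_NEGATIVE = "vector_negative"
UNASSIGNED_FLUOR = "unassigned_fluor"
DEBRIS = "debris"
DOUBLET = "doublet"
DEAD = "dead"


class ThresholdWarning(UserWarning):
    """Signals a fallback (e.g. unimodal channel under the mixture method)."""


@dataclass
class GateThresholds:
    """Fitted gate positions (log10 intensity unless noted).

    ``marker_cutoffs`` holds one positive/negative cutoff per marker
    channel; an event is positive on a channel iff its log10 intensity is
    strictly above the cutoff. ``fsc_a_min`` is the scatter (debris) gate;
    ``singlet_ratio`` the expected FSC-A/FSC-H ratio of single cells with
    relative tolerance ``singlet_tolerance``; ``dapi_max`` the viability
    cutoff; the EGFRt bright cutoff lives in ``marker_cutoffs['EGFRt']``.
    """

    marker_cutoffs: dict[str, float] = field(default_factory=dict)
    fsc_a_min: float = -np.inf
    singlet_ratio: float = 1.0
    singlet_tolerance: float = 0.35
    dapi_max: float = np.inf
    method: dict[str, str] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "marker_cutoffs": self.marker_cutoffs,
            "fsc_a_min": self.fsc_a_min,
            "singlet_ratio": self.singlet_ratio,
            "singlet_tolerance": self.singlet_tolerance,
            "dapi_max": self.dapi_max,
            "method": self.method,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GateThresholds":
        payload = json.loads(Path(path).read_text())
        return cls(**payload)


def _mixture_threshold(log_values: np.ndarray, seed: int = 0) -> float | None:
    """Equal-posterior cutoff of a two-component Gaussian mixture on log
    intensities; None when the channel is effectively unimodal (a single
    component is preferred by BIC, or the fitted components overlap)."""
    x = log_values.reshape(-1, 1)
    gm1 = GaussianMixture(n_components=1, random_state=seed).fit(x)
    gm = GaussianMixture(n_components=2, n_init=3, random_state=seed).fit(x)
    if gm.bic(x) >= gm1.bic(x):
        return None
    means = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.ravel())
    weights = gm.weights_.ravel()
    lo, hi = np.argsort(means)
    if means[hi] - means[lo] < (sds[lo] + sds[hi]) or min(weights) < 1e-3:
        return None
    # solve equal posterior on a grid between the component means
    grid = np.linspace(means[lo], means[hi], 2001)
    post_lo = weights[lo] * norm.pdf(grid, means[lo], sds[lo])
    post_hi = weights[hi] * norm.pdf(grid, means[hi], sds[hi])
    crossing = np.where(np.diff(np.sign(post_lo - post_hi)) != 0)[0]
    if len(crossing) == 0:
        return float(grid[np.argmin(np.abs(post_lo - post_hi))])
    return float(grid[crossing[0]])


def _valley_threshold(log_values: np.ndarray) -> float | None:
    """Minimum of a smoothed density between the two outermost modes."""
    kde = gaussian_kde(log_values)
    grid = np.linspace(log_values.min(), log_values.max(), 512)
    dens = kde(grid)
    # local maxima
    peaks = np.where((dens[1:-1] > dens[:-2]) & (dens[1:-1] > dens[2:]))[0] + 1
    if len(peaks) < 2:
        return None
    left, right = peaks[0], peaks[-1]
    valley = left + int(np.argmin(dens[left : right + 1]))
    return float(grid[valley])


def fit_thresholds(
    events: pd.DataFrame,
    method: str = "mixture2",
    controls: pd.DataFrame | None = None,
    percentile: float = 99.9,
    singlet_tolerance: float = 0.35,
    seed: int = 0,
) -> GateThresholds:
    """Fit per-channel positive/negative cutoffs and pre-gates from data.

    Methods: ``mixture2`` (two-component Gaussian mixture on log10
    intensities, cutoff at equal posterior; falls back to ``percentile``
    with a :class:`ThresholdWarning` on unimodal channels), ``valley``
    (minimum of the smoothed log-density between modes), ``percentile``
    (stated quantile of the negative control — or of the sample itself when
    no control is given).

    The scatter gate and DAPI cutoff are fitted with the same machinery on
    FSC-A and DAPI; the singlet ratio is the median FSC-A/FSC-H.
    """
    if method not in ("mixture2", "valley", "percentile"):
        raise ValueError(f"unknown threshold method {method!r}")
    if method == "mixture2" and len(events) < 500:
        raise ValueError("mixture2 needs >= 500 events per channel")

    thresholds = GateThresholds(singlet_tolerance=singlet_tolerance)

    def log_of(frame: pd.DataFrame, channel: str) -> np.ndarray:
        return np.log10(np.clip(frame[channel].to_numpy(float), 1e-6, None))

    def split(log_values: np.ndarray) -> float | None:
        if method == "valley":
            return _valley_threshold(log_values)
        return _mixture_threshold(log_values, seed=seed)

    # Marker channels with a single mode (an all-bright shared anchor like
    # EGFRt, or an unused fluorochrome) carry no internal contrast, so the
    # fallback pools the log intensities of every marker channel: the
    # negative (autofluorescence) component is common across channels and
    # the pooled mixture locates it.
    pooled_cut: float | None = None

    def pooled_marker_cut() -> float:
        nonlocal pooled_cut
        if pooled_cut is None:
            pooled = np.concatenate([log_of(events, ch) for ch in MARKER_CHANNELS])
            cut = split(pooled)
            pooled_cut = cut if cut is not None else float(np.percentile(pooled, percentile))
        return pooled_cut

    def marker_channel(channel: str) -> float:
        if method == "percentile":
            source = controls if controls is not None else events
            thresholds.method[channel] = "percentile"
            return float(np.percentile(log_of(source, channel), percentile))
        cut = split(log_of(events, channel))
        if cut is None:
            warnings.warn(
                f"channel {channel}: no bimodal structure under {method}; "
                "falling back to the pooled marker-channel cutoff",
                ThresholdWarning,
                stacklevel=2,
            )
            thresholds.method[channel] = f"{method}_pooled_fallback"
            return pooled_marker_cut()
        thresholds.method[channel] = method
        return cut

    def gate_channel(channel: str, tail: str) -> float:
        """Scatter/viability cutoffs: a unimodal channel means the gated
        population is absent, so the fallback keeps all but the stated tail."""
        log_values = log_of(controls if method == "percentile" and controls is not None else events, channel)
        if method != "percentile":
            cut = split(log_values)
            if cut is not None:
                thresholds.method[channel] = method
                return cut
            warnings.warn(
                f"channel {channel}: no bimodal structure under {method}; "
                "falling back to a tail percentile of the sample",
                ThresholdWarning,
                stacklevel=2,
            )
        thresholds.method[channel] = "percentile" if method == "percentile" else "percentile_fallback"
        q = percentile if tail == "upper" else 100.0 - percentile
        return float(np.percentile(log_values, q))

    for channel in MARKER_CHANNELS:
        thresholds.marker_cutoffs[channel] = marker_channel(channel)

    thresholds.dapi_max = gate_channel("DAPI", tail="upper")
    thresholds.fsc_a_min = gate_channel("FSC-A", tail="lower")

    ratio = events["FSC-A"].to_numpy(float) / np.clip(events["FSC-H"].to_numpy(float), 1e-6, None)
    thresholds.singlet_ratio = float(np.median(ratio))
    return thresholds


# ---------------------------------------------------------------------------
# gates
# ---------------------------------------------------------------------------

def _gate_masks(events: pd.DataFrame, thresholds: GateThresholds):
    """Boolean masks of the three pre-gates, applied in order
    debris -> doublet -> dead on the surviving events."""
    log_fsc = np.log10(np.clip(events["FSC-A"].to_numpy(float), 1e-6, None))
    debris = log_fsc <= thresholds.fsc_a_min

    ratio = events["FSC-A"].to_numpy(float) / np.clip(
        events["FSC-H"].to_numpy(float), 1e-6, None
    )
    off_singlet = (
        np.abs(ratio - thresholds.singlet_ratio)
        > thresholds.singlet_tolerance * thresholds.singlet_ratio
    )
    doublet = off_singlet & ~debris

    log_dapi = np.log10(np.clip(events["DAPI"].to_numpy(float), 1e-6, None))
    dead = (log_dapi > thresholds.dapi_max) & ~debris & ~doublet
    return debris, doublet, dead


def pregate(
    events: pd.DataFrame, thresholds: GateThresholds
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Remove debris, doublets and dead cells, in that order.

    Returns the surviving events and a tally of removals per gate; tallies
    plus survivors partition the input.
    """
    debris, doublet, dead = _gate_masks(events, thresholds)
    keep = ~(debris | doublet | dead)
    tally = {
        "debris": int(debris.sum()),
        "doublet": int(doublet.sum()),
        "dead": int(dead.sum()),
        "survivors": int(keep.sum()),
    }
    survivors = events.loc[keep]
    if len(survivors) == 0:
        raise ValueError("degenerate sample: no events survive the pre-gates")
    return survivors, tally


def _positive(events: pd.DataFrame, channel: str, cutoff: float) -> np.ndarray:
    return np.log10(np.clip(events[channel].to_numpy(float), 1e-6, None)) > cutoff


def classify_fluor(
    event: pd.Series | pd.DataFrame, thresholds: GateThresholds
) -> FluorCombo | str | list:
    """Map an event's fluorescent-protein booleans to one of the six valid
    combos, or ``unassigned_fluor`` for the all-negative and
    triple-positive patterns. Accepts a single event (Series) or a table."""
    frame = event.to_frame().T if isinstance(event, pd.Series) else event
    calls = []
    bools = np.column_stack(
        [_positive(frame, ch, thresholds.marker_cutoffs[ch]) for ch in FLUOR_CHANNELS]
    )
    for row in bools:
        positives = {ch for ch, b in zip(FLUOR_CHANNELS, row) if b}
        combo = fluor_combo_from_positives(positives)
        calls.append(combo if combo is not None else UNASSIGNED_FLUOR)
    return calls[0] if isinstance(event, pd.Series) else calls


def classify_caar(
    event: pd.Series | pd.DataFrame, thresholds: GateThresholds
) -> CaarPermutation | str | list:
    """Read the three CAAR tag booleans of an EGFRt-bright event as one of
    the eight permutations; EGFRt-negative events are ``vector_negative``
    and never receive a CAAR call."""
    frame = event.to_frame().T if isinstance(event, pd.Series) else event
    egfrt = _positive(frame, "EGFRt", thresholds.marker_cutoffs["EGFRt"])
    bools = np.column_stack(
        [_positive(frame, ch, thresholds.marker_cutoffs[ch]) for ch in CAAR_CHANNELS]
    )
    calls = []
    for ok, row in zip(egfrt, bools):
        if not ok:
            calls.append(VECTOR_NEGATIVE)
        else:
            calls.append(CaarPermutation(bool(row[0]), bool(row[1]), bool(row[2])))
    return calls[0] if isinstance(event, pd.Series) else calls


@dataclass
class CodeAssignment:
    """Per-event deconvolution result.

    ``labels`` is one string per input event, from {'1'..'48'} and the
    non-code labels {vector_negative, unassigned_fluor, debris, doublet,
    dead}. ``fractions`` are per-code shares with the coded events (events
    assigned to any of the 48 codes) as denominator; ``live_fractions``
    uses all live singlets instead. ``accuracy`` and ``confusion`` are
    filled when the input carried hidden truth labels.
    """

    labels: pd.Series
    counts: pd.Series
    fractions: pd.Series
    live_fractions: pd.Series
    tally: dict[str, int]
    accuracy: float | None = None
    confusion: pd.DataFrame | None = None

    @property
    def n_codes_detected(self) -> int:
        return int((self.counts > 0).sum())


def deconvolute(
    events: pd.DataFrame,
    thresholds: GateThresholds,
    registry: CodeRegistry,
) -> CodeAssignment:
    """Deconvolute an event table into per-event code assignments.

    Gate order: debris -> singlet -> dead -> EGFRt -> fluorescent combo ->
    CAAR permutation -> (combo, permutation) lookup in the registry. The
    per-code fraction table uses coded events as denominator; when the
    input has a ``truth`` column, per-event accuracy over coded truth and a
    confusion matrix are computed.
    """
    labels = np.empty(len(events), dtype=object)
    debris, doublet, dead = _gate_masks(events, thresholds)
    labels[debris] = DEBRIS
    labels[doublet] = DOUBLET
    labels[dead] = DEAD
    live = ~(debris | doublet | dead)
    tally = {
        "debris": int(debris.sum()),
        "doublet": int(doublet.sum()),
        "dead": int(dead.sum()),
        "survivors": int(live.sum()),
    }

    survivors = events.loc[live]
    egfrt = _positive(survivors, "EGFRt", thresholds.marker_cutoffs["EGFRt"])
    marker_bools = {
        ch: _positive(survivors, ch, thresholds.marker_cutoffs[ch])
        for ch in MARKER_CHANNELS
    }

    live_labels = np.empty(len(survivors), dtype=object)
    live_labels[~egfrt] = VECTOR_NEGATIVE

    fluor_bools = np.column_stack([marker_bools[ch] for ch in FLUOR_CHANNELS])
    caar_bools = np.column_stack([marker_bools[ch] for ch in CAAR_CHANNELS])
    # vectorized joint lookup: encode the 6 boolean marker calls as an
    # integer and map through the registry's (combo, permutation) table
    lookup: dict[int, str] = {}
    for code in registry:
        sig = code.signature()
        key = sum(int(b) << i for i, b in enumerate(sig[:6]))
        lookup[key] = str(code.bc_id)
    keys = np.zeros(len(survivors), dtype=int)
    for i, col in enumerate(np.column_stack([fluor_bools, caar_bools]).T):
        keys |= col.astype(int) << i
    for j in np.where(egfrt)[0]:
        live_labels[j] = lookup.get(keys[j], UNASSIGNED_FLUOR)

    labels[live] = live_labels
    label_series = pd.Series(labels, index=events.index, name="label")

    coded = label_series[label_series.str.fullmatch(r"\d+")]
    counts = (
        coded.astype(int).value_counts().reindex(registry.bc_ids, fill_value=0).sort_index()
    )
    counts.index.name = "bc_id"
    total_coded = counts.sum()
    fractions = counts / total_coded if total_coded > 0 else counts.astype(float)
    n_live = tally["survivors"]
    live_fractions = counts / n_live if n_live > 0 else counts.astype(float)

    accuracy = None
    confusion = None
    if "truth" in events.columns:
        truth = events["truth"].astype(str)
        coded_pred = label_series.str.fullmatch(r"\d+")
        if coded_pred.any():
            accuracy = float(
                (label_series[coded_pred] == truth[coded_pred]).mean()
            )
        confusion = pd.crosstab(
            truth, label_series, rownames=["truth"], colnames=["assigned"]
        )

    assignment = CodeAssignment(
        labels=label_series,
        counts=counts,
        fractions=fractions,
        live_fractions=live_fractions,
        tally=tally,
        accuracy=accuracy,
        confusion=confusion,
    )
    return assignment
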