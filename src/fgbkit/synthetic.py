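"""Synthetic inputs for the color-code tracking pipeline.

Three generators with the statistical structure the downstream analysis
assumes:

* :func:`simulate_competition` — clonal competition of color-coded clones
  across serial passages: a deterministic replicator update on relative
  fitness, a multinomial bottleneck at every 1:10 split (genetic drift),
  and rare spontaneous fitness jumps modeling growth-promoting mutations.
* :func:`simulate_marking` — gene-marking trajectories (fraction of cells
  with intact vector expression) under vector silencing and the three
  selection regimes of DHFR-addiction culture: no selection, full selection
  after hypoxanthine/thymidine (HT) withdrawal, and partial selection while
  the HT salvage pathway rescues unmarked cells.
* :func:`generate_events` — event-level cytometry tables: log-normal
  positive/negative channel intensities per code signature, plus debris,
  doublet, dead-cell and dim (variegated) contamination, with hidden truth
  labels for benchmarking the gating.
* :func:`generate_bc_reads` — barcode-amplicon FASTQ reads with a
  sample index, fixed flanks around the vector DNA barcode, and i.i.d.
  substitution sequencing error.

The time unit of all trajectories is the passage, not the day;
``split_interval_days`` is metadata for axis labeling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from fgbkit.registry import CodeRegistry

EVENT_COLUMNS = (
    "FSC-A",
    "FSC-H",
    "SSC-A",
    "DAPI",
    "hmAG3",
    "YFP",
    "mChEY",
    "HA",
    "cMyc",
    "Thy1.1",
    "EGFRt",
)

#: default amplicon flanks around the vector barcode (read layout:
#: sample index + FLANK5 + barcode + FLANK3)
FLANK5 = "TCGATTGACTGC"
FLANK3 = "GATCCGGTTAAC"

SELECTION_MODES = ("none", "dhfr_addiction_noHT", "dhfr_addiction_HT")


@dataclass
class CloneState:
    """State of one clone in a competition mix."""

    bc_id: int
    fraction: float
    fitness: float = 1.0
    marked: bool = True


@dataclass
class SimulationConfig:
    """Passage-level culture parameters.

    ``n_cells_at_passage`` is the post-split bottleneck size (cells reseeded
    after each 1:10 split); ``None`` disables drift (infinite-population
    replicator dynamics). ``mutation_rate`` is the per-clone per-passage
    probability of a spontaneous fitness jump whose multiplier is log-normal
    around ``mutation_multiplier`` (default 1.2, enough for late dominance
    within a few tens of passages at the default bottleneck).
    ``initial_marking`` is the day-0 gene marking rate for
    :func:`simulate_marking`; ``ht_rescue`` the per-passage survival of
    unmarked cells when the HT supplement partially rescues DHFR loss.
    """

    n_cells_at_passage: int | None = 10_000
    split_interval_days: float = 2.5
    n_passages: int = 20
    mutation_rate: float = 0.0
    mutation_multiplier: float = 1.2
    mutation_log_sd: float = 0.05
    silencing_rate: float = 0.0
    selection_mode: str = "none"
    ht_rescue: float = 0.5
    initial_marking: float = 0.4
    seed: int = 0

    def validate(self) -> None:
        for name in ("mutation_rate", "silencing_rate", "ht_rescue", "initial_marking"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_cells_at_passage is not None and self.n_cells_at_passage < 1:
            raise ValueError("n_cells_at_passage must be >= 1 (or None for no drift)")
        if self.selection_mode not in SELECTION_MODES:
            raise ValueError(
                f"selection_mode must be one of {SELECTION_MODES}, got {self.selection_mode!r}"
            )
        if self.n_passages < 0:
            raise ValueError("n_passages must be >= 0")


@dataclass
class MeasurementModel:
    """Log-normal intensity model for the cytometer readout.

    All location/scale parameters are on log10 fluorescence. Marker channels
    (the three fluorescent proteins, three CAAR tags and EGFRt) share a
    negative and a positive component; variegated (dim) cells express their
    positive channels at ``dim_logmean``, between the two. Scatter channels
    place intact single cells high in FSC-A with a tight FSC-A/FSC-H ratio;
    debris is low-FSC/high-SSC; doublets are sums of two singlets sharing
    one parent's FSC-H; dead cells are DAPI-bright.
    """

    neg_logmean: float = 2.0
    pos_logmean: float = 4.0
    marker_logsd: float = 0.3
    dim_logmean: float = 3.0
    dim_fraction: float = 0.0
    debris_fraction: float = 0.0
    doublet_fraction: float = 0.0
    dead_fraction: float = 0.0
    fsc_logmean: float = 5.0
    fsc_logsd: float = 0.1
    fsc_h_ratio: float = 1.0
    fsc_h_logsd: float = 0.02
    ssc_logmean: float = 4.5
    ssc_logsd: float = 0.15
    debris_fsc_logmean: float = 4.0
    debris_ssc_logmean: float = 5.1
    debris_logsd: float = 0.15
    dapi_neg_logmean: float = 2.0
    dapi_pos_logmean: float = 4.0
    dapi_logsd: float = 0.3
    spillover: np.ndarray | None = None  # 3x3 over (hmAG3, YFP, mChEY)

    def validate(self) -> None:
        if self.pos_logmean <= self.neg_logmean:
            raise ValueError("positive log-mean must exceed negative log-mean")
        contamination = self.debris_fraction + self.doublet_fraction + self.dead_fraction
        if contamination >= 1.0:
            raise ValueError("contamination fractions must sum to < 1")
        for name in ("dim_fraction", "debris_fraction", "doublet_fraction", "dead_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.spillover is not None:
            s = np.asarray(self.spillover, dtype=float)
            if s.shape != (3, 3):
                raise ValueError("spillover must be a 3x3 matrix over the fluorescent channels")


def _as_fraction_series(fractions: Mapping[int, float] | pd.Series) -> pd.Series:
    s = pd.Series(dict(fractions), dtype=float) if not isinstance(fractions, pd.Series) else fractions.astype(float)
    if len(s) == 0:
        raise ValueError("empty clone mix")
    if (s < 0).any():
        raise ValueError("fractions must be non-negative")
    return s


# ---------------------------------------------------------------------------
# clonal competition
# ---------------------------------------------------------------------------

def simulate_competition(
    initial: Sequence[CloneState] | Mapping[int, float] | pd.Series,
    config: SimulationConfig,
) -> pd.DataFrame:
    """Simulate clone fractions across serial passages.

    Each passage applies, in order: the replicator update
    ``f_i <- f_i * w_i / sum_j f_j * w_j`` on relative fitness ``w``;
    a multinomial bottleneck of ``config.n_cells_at_passage`` cells (omitted
    when ``None``); and per-clone fitness jumps with probability
    ``config.mutation_rate`` (multiplier log-normal around
    ``config.mutation_multiplier``).

    Returns a DataFrame with one row per passage (0..n_passages, passage 0
    is the input mix) and one column per ``bc_id``; rows sum to 1.
    """
    config.validate()
    if isinstance(initial, (Mapping, pd.Series)):
        fractions = _as_fraction_series(initial)
        fitness = pd.Series(1.0, index=fractions.index)
    else:
        states = list(initial)
        if not states:
            raise ValueError("empty clone mix")
        fractions = pd.Series({s.bc_id: s.fraction for s in states}, dtype=float)
        fitness = pd.Series({s.bc_id: s.fitness for s in states}, dtype=float)
    if (fitness <= 0).any():
        raise ValueError("fitness must be positive")
    total = fractions.sum()
    if not math.isclose(total, 1.0, abs_tol=1e-6):
        raise ValueError(f"initial fractions must sum to 1, got {total}")
    fractions = fractions / total

    rng = np.random.default_rng(config.seed)
    f = fractions.to_numpy()
    w = fitness.to_numpy().copy()
    trajectory = [f.copy()]
    for _ in range(config.n_passages):
        f = f * w
        f = f / f.sum()
        if config.n_cells_at_passage is not None:
            counts = rng.multinomial(config.n_cells_at_passage, f)
            f = counts / counts.sum()
        if config.mutation_rate > 0:
            jumps = rng.random(len(w)) < config.mutation_rate
            if jumps.any():
                multipliers = np.exp(
                    rng.normal(
                        math.log(config.mutation_multiplier),
                        config.mutation_log_sd,
                        size=int(jumps.sum()),
                    )
                )
                w[jumps] *= multipliers
        trajectory.append(f.copy())
    out = pd.DataFrame(
        trajectory,
        index=pd.RangeIndex(config.n_passages + 1, name="passage"),
        columns=fractions.index,
    )
    out.columns.name = "bc_id"
    return out


def simulate_marking(config: SimulationConfig, n_passages: int | None = None) -> pd.DataFrame:
    """Gene-marking trajectory under silencing and DHFR-addiction selection.

    Expectation dynamics per passage: a ``silencing_rate`` share of marked
    cells loses vector expression; unmarked cells then survive the passage
    with probability 1 (no selection), 0 (DHFR addiction after HT
    withdrawal) or ``ht_rescue`` (HT salvage partially rescues them); the
    culture renormalizes. Returns a DataFrame indexed by passage with
    columns ``marking`` (raw marked fraction, passage 0 equals
    ``initial_marking``) and ``normalized`` (marking relative to passage 0,
    the day-0-normalized gene marking rate).
    """
    config.validate()
    n = config.n_passages if n_passages is None else n_passages
    rescue = {
        "none": 1.0,
        "dhfr_addiction_noHT": 0.0,
        "dhfr_addiction_HT": config.ht_rescue,
    }[config.selection_mode]
    m = config.initial_marking
    if m <= 0:
        raise ValueError("initial_marking must be > 0")
    values = [m]
    for _ in range(n):
        marked = m * (1.0 - config.silencing_rate)
        unmarked = (1.0 - m) + m * config.silencing_rate
        denom = marked + unmarked * rescue
        if denom <= 0:
            raise ValueError("entire culture died: no marked cells under full selection")
        m = marked / denom
        values.append(m)
    marking = pd.Series(values, index=pd.RangeIndex(n + 1, name="passage"), name="marking")
    return pd.DataFrame({"marking": marking, "normalized": marking / marking.iloc[0]})


def apply_perturbation(
    fractions: Mapping[int, float] | pd.Series,
    survival: Mapping[int, float] | pd.Series | Sequence[float],
) -> pd.Series:
    """Differential survival of clones under a perturbagen pulse.

    ``f_i <- f_i * s_i / sum_j f_j * s_j`` for per-clone survival
    probabilities ``s`` in [0, 1].
    """
    f = _as_fraction_series(fractions)
    if not math.isclose(f.sum(), 1.0, abs_tol=1e-6):
        raise ValueError("fractions must sum to 1")
    if isinstance(survival, (Mapping, pd.Series)):
        s = pd.Series(dict(survival), dtype=float).reindex(f.index)
        if s.isna().any():
            raise ValueError("survival missing for some clones")
    else:
        s = pd.Series(list(survival), index=f.index, dtype=float)
    if ((s < 0) | (s > 1)).any():
        raise ValueError("survival must be in [0, 1]")
    weighted = f * s
    total = weighted.sum()
    if total <= 0:
        raise ValueError("degenerate mix: no clone survives the perturbation")
    return weighted / total


# ---------------------------------------------------------------------------
# cytometry events
# ---------------------------------------------------------------------------

def _sample_marker_block(
    rng: np.random.Generator,
    signatures: np.ndarray,
    model: MeasurementModel,
    dim: np.ndarray,
) -> np.ndarray:
    """Log10 intensities for the 7 marker channels given boolean signatures.

    ``signatures`` is (n, 7) boolean; ``dim`` flags events whose positive
    channels express at the variegated intermediate level.
    """
    n = signatures.shape[0]
    means = np.where(signatures, model.pos_logmean, model.neg_logmean).astype(float)
    if dim.any():
        means[dim] = np.where(signatures[dim], model.dim_logmean, model.neg_logmean)
    return rng.normal(means, model.marker_logsd, size=(n, 7))


def generate_events(
    fractions: Mapping[int, float] | pd.Series,
    n_events: int,
    model: MeasurementModel,
    registry: CodeRegistry,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate an event-level cytometry table.

    ``fractions`` maps bc_id to its share of intact single cells and may sum
    to <= 1; the remainder is vector-negative cells (all marker channels
    negative). Contamination classes (debris, doublet, dead) are drawn at
    the model's fractions on top. Returns a DataFrame with the 11 channel
    columns of :data:`EVENT_COLUMNS` (linear intensities) plus a hidden
    ``truth`` column over {'1'..'48', 'negative', 'debris', 'doublet',
    'dead'}.
    """
    if n_events <= 0:
        raise ValueError("n_events must be positive")
    model.validate()
    f = _as_fraction_series(fractions)
    total = f.sum()
    if total > 1.0 + 1e-9:
        raise ValueError("fractions must sum to <= 1 (remainder is vector-negative)")
    rng = np.random.default_rng(seed)

    # event classes
    p_classes = np.array(
        [model.debris_fraction, model.doublet_fraction, model.dead_fraction], dtype=float
    )
    p_live = 1.0 - p_classes.sum()
    class_draw = rng.choice(4, size=n_events, p=np.append(p_classes, p_live))
    n_debris = int((class_draw == 0).sum())
    n_doublet = int((class_draw == 1).sum())
    n_dead = int((class_draw == 2).sum())
    n_live = n_events - n_debris - n_doublet - n_dead

    sig_matrix = registry.marker_matrix  # (48, 7) indexed by bc_id
    code_ids = np.asarray(f.index, dtype=int)
    p_code = np.append(f.to_numpy(), max(0.0, 1.0 - total))
    p_code = p_code / p_code.sum()

    def draw_cells(n: int) -> tuple[np.ndarray, np.ndarray]:
        """Draw n cell identities; returns (truth index array, signature bools).
        Truth index -1 encodes vector-negative."""
        which = rng.choice(len(code_ids) + 1, size=n, p=p_code)
        truth = np.where(which < len(code_ids), code_ids[np.minimum(which, len(code_ids) - 1)], -1)
        sigs = np.zeros((n, 7), dtype=bool)
        coded = truth >= 0
        if coded.any():
            sigs[coded] = sig_matrix.loc[truth[coded]].to_numpy()
        return truth, sigs

    def cell_block(n: int, dead: bool) -> tuple[pd.DataFrame, np.ndarray]:
        truth, sigs = draw_cells(n)
        dim = np.zeros(n, dtype=bool)
        if model.dim_fraction > 0:
            dim = (rng.random(n) < model.dim_fraction) & (truth >= 0)
        markers = _sample_marker_block(rng, sigs, model, dim)
        fsc_a = rng.normal(model.fsc_logmean, model.fsc_logsd, n)
        fsc_h = fsc_a - math.log10(model.fsc_h_ratio) + rng.normal(0, model.fsc_h_logsd, n)
        ssc = rng.normal(model.ssc_logmean, model.ssc_logsd, n)
        dapi_mean = model.dapi_pos_logmean if dead else model.dapi_neg_logmean
        dapi = rng.normal(dapi_mean, model.dapi_logsd, n)
        block = np.column_stack([fsc_a, fsc_h, ssc, dapi, markers])
        return pd.DataFrame(10.0 ** block, columns=list(EVENT_COLUMNS)), truth

    frames: list[pd.DataFrame] = []
    truths: list[np.ndarray] = []

    if n_live:
        live, truth = cell_block(n_live, dead=False)
        frames.append(live)
        truths.append(np.where(truth >= 0, truth.astype(str), "negative"))
    if n_dead:
        dead, _ = cell_block(n_dead, dead=True)
        frames.append(dead)
        truths.append(np.full(n_dead, "dead"))
    if n_doublet:
        # sum of two independent singlets; pulse height from one parent only
        a, _ = cell_block(n_doublet, dead=False)
        b, _ = cell_block(n_doublet, dead=False)
        doublet = a.add(b)
        doublet["FSC-H"] = a["FSC-H"].to_numpy()
        frames.append(doublet)
        truths.append(np.full(n_doublet, "doublet"))
    if n_debris:
        markers = 10.0 ** rng.normal(
            model.neg_logmean, model.marker_logsd, size=(n_debris, 7)
        )
        fsc_a = 10.0 ** rng.normal(model.debris_fsc_logmean, model.debris_logsd, n_debris)
        fsc_h = fsc_a * 10.0 ** rng.normal(0, model.fsc_h_logsd, n_debris)
        ssc = 10.0 ** rng.normal(model.debris_ssc_logmean, model.debris_logsd, n_debris)
        dapi = 10.0 ** rng.normal(model.dapi_neg_logmean, model.dapi_logsd, n_debris)
        debris = pd.DataFrame(
            np.column_stack([fsc_a, fsc_h, ssc, dapi, markers]), columns=list(EVENT_COLUMNS)
        )
        frames.append(debris)
        truths.append(np.full(n_debris, "debris"))

    events = pd.concat(frames, ignore_index=True)
    events["truth"] = np.concatenate(truths)
    # shuffle so contamination is interleaved like a real acquisition
    order = rng.permutation(len(events))
    events = events.iloc[order].reset_index(drop=True)

    if model.spillover is not None:
        fluor = events[["hmAG3", "YFP", "mChEY"]].to_numpy()
        events[["hmAG3", "YFP", "mChEY"]] = fluor @ np.asarray(model.spillover, dtype=float).T
    return events


# ---------------------------------------------------------------------------
# barcode amplicon reads
# ---------------------------------------------------------------------------

def generate_bc_reads(
    fractions: Mapping[int, float] | pd.Series,
    depth: int,
    registry: CodeRegistry,
    sample_index: str = "ACGTACGT",
    error_rate: float = 0.0,
    seed: int = 0,
    flank5: str = FLANK5,
    flank3: str = FLANK3,
) -> list[SeqRecord]:
    """Simulate barcode-amplicon reads for one sample.

    Each read is ``sample_index + flank5 + dna_barcode + flank3`` with
    i.i.d. substitution errors at ``error_rate`` over the whole read; read
    counts per barcode are multinomial in the (renormalized) clone
    fractions. Qualities are a constant Phred placeholder (Q40).
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if not 0.0 <= error_rate <= 0.05:
        raise ValueError("error_rate must be in [0, 0.05]")
    if not sample_index or any(c not in "ACGT" for c in sample_index):
        raise ValueError("sample_index must be a non-empty A/C/G/T string")
    f = _as_fraction_series(fractions)
    p = f.to_numpy() / f.sum()
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(depth, p)

    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    records: list[SeqRecord] = []
    read_no = 0
    for bc_id, count in zip(f.index, counts):
        if count == 0:
            continue
        template = sample_index + flank5 + registry.code(int(bc_id)).dna_barcode + flank3
        base = np.frombuffer(template.encode(), dtype=np.uint8)
        reads = np.tile(base, (count, 1))
        if error_rate > 0:
            err = rng.random(reads.shape) < error_rate
            if err.any():
                # substitute with a uniformly random *different* base
                offsets = rng.integers(1, 4, size=int(err.sum()))
                idx = np.searchsorted(alphabet, reads[err])
                reads[err] = alphabet[(idx + offsets) % 4]
        qual = [40] * reads.shape[1]
        for row in reads:
            read_no += 1
            rec = SeqRecord(
                Seq(row.tobytes().decode()),
                id=f"read_{read_no}",
                description=f"truth_bc={bc_id}",
            )
            rec.letter_annotations["phred_quality"] = qual
            records.append(rec)
    return records


def write_fastq(records: list[SeqRecord], path) -> None:
    from Bio import SeqIO

    with open(path, "w") as handle:
        SeqIO.write(records, handle, "fastq")
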