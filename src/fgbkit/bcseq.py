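"""Barcode-amplicon read counting and flow/sequencing concordance.

Reads are expected to carry a sample index at the 5' end followed by a
fixed flank, the vector DNA barcode, and a second fixed flank. Only the
informatic consequence of the amplicon design is modeled here: reads are
demultiplexed on the index (Hamming tolerance), the barcode is located by
the flank anchors, and each barcode is assigned to the nearest registry
barcode within a mismatch budget. Because registry barcodes are built at
pairwise Hamming distance >= 3, single-substitution errors decode uniquely;
the ambiguity rule (a read within the budget of two registry barcodes is
never force-assigned) guards user-supplied registries without that
guarantee.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
from Bio import SeqIO
from Bio.SeqRecord import SeqRecord

from fgbkit.registry import CodeRegistry
from fgbkit.synthetic import FLANK3, FLANK5


class IndexConfigError(ValueError):
    """Sample indices too close for the requested mismatch tolerance."""


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _read_sequences(reads) -> list[str]:
    """Accept SeqRecords, plain strings, or a FASTQ path (gzip-transparent)."""
    if isinstance(reads, (str, Path)):
        path = Path(reads)
        opener = gzip.open if path.suffix == ".gz" else open
        with opener(path, "rt") as handle:
            return [str(rec.seq) for rec in SeqIO.parse(handle, "fastq")]
    out = []
    for r in reads:
        out.append(str(r.seq) if isinstance(r, SeqRecord) else str(r))
    return out


def demultiplex(
    reads,
    index_map: Mapping[str, str],
    max_index_mismatch: int = 1,
) -> tuple[dict[str, list[str]], int]:
    """Assign reads to samples by their 5' index.

    Indices must be pairwise Hamming distance > 2 * ``max_index_mismatch``
    so that every read matches at most one sample. Returns per-sample read
    lists (sequences, index retained) and the count of unassigned reads.
    """
    indices = list(index_map.items())
    if not indices:
        raise IndexConfigError("empty index map")
    lengths = {len(ix) for _, ix in indices}
    if len(lengths) != 1:
        raise IndexConfigError("all sample indices must share one length")
    for i, (sa, ia) in enumerate(indices):
        for sb, ib in indices[i + 1 :]:
            if _hamming(ia, ib) <= 2 * max_index_mismatch:
                raise IndexConfigError(
                    f"indices for {sa!r} and {sb!r} are within 2*max_index_mismatch"
                )
    index_len = lengths.pop()

    by_sample: dict[str, list[str]] = {sample: [] for sample in index_map}
    exact = {ix: sample for sample, ix in indices}
    unassigned = 0
    for seq in _read_sequences(reads):
        prefix = seq[:index_len]
        sample = exact.get(prefix)
        if sample is None and max_index_mismatch > 0:
            for candidate, ix in indices:
                if _hamming(prefix, ix) <= max_index_mismatch:
                    sample = candidate
                    break
        if sample is None:
            unassigned += 1
        else:
            by_sample[sample].append(seq)
    return by_sample, unassigned


@dataclass
class BarcodeCountTable:
    """Per-sample barcode read counts and fractions."""

    sample: str
    counts: pd.Series  # indexed by bc_id
    n_unmatched_index: int = 0
    n_unmatched_flank: int = 0
    n_ambiguous_barcode: int = 0
    n_unmatched_barcode: int = 0

    @property
    def fractions(self) -> pd.Series:
        total = self.counts.sum()
        return self.counts / total if total > 0 else self.counts.astype(float)

    @property
    def total_reads(self) -> int:
        return int(
            self.counts.sum()
            + self.n_unmatched_index
            + self.n_unmatched_flank
            + self.n_ambiguous_barcode
            + self.n_unmatched_barcode
        )

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame({"count": self.counts, "fraction": self.fractions})
        df.index.name = "bc_id"
        df.to_csv(path, sep="\t")

    def tallies(self) -> dict[str, int]:
        return {
            "sample": self.sample,
            "matched": int(self.counts.sum()),
            "unmatched_index": self.n_unmatched_index,
            "unmatched_flank": self.n_unmatched_flank,
            "ambiguous_barcode": self.n_ambiguous_barcode,
            "unmatched_barcode": self.n_unmatched_barcode,
        }

    def tallies_to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.tallies(), indent=1))


def _find_with_mismatch(seq: str, anchor: str, expected: int, budget: int) -> int | None:
    """Offset of ``anchor`` in ``seq`` within ``budget`` substitutions,
    trying the expected offset first, then scanning."""
    k = len(anchor)
    if len(seq) >= expected + k and _hamming(seq[expected : expected + k], anchor) <= budget:
        return expected
    best = None
    for off in range(0, len(seq) - k + 1):
        if off == expected:
            continue
        if _hamming(seq[off : off + k], anchor) <= budget:
            best = off
            break
    return best


def count_barcodes(
    reads,
    registry: CodeRegistry,
    max_flank_mismatch: int = 1,
    max_bc_mismatch: int = 1,
    sample: str = "sample",
    index_length: int | None = None,
    flank5: str = FLANK5,
    flank3: str = FLANK3,
    n_unmatched_index: int = 0,
) -> BarcodeCountTable:
    """Count reads per registry barcode.

    The barcode is located between the two flank anchors (each matched with
    <= ``max_flank_mismatch`` substitutions, at the expected layout offset
    first, elsewhere otherwise) and assigned to the unique registry barcode
    within ``max_bc_mismatch``. Reads whose flanks cannot be found are
    tallied as unmatched-flank; barcodes matching no registry entry as
    unmatched-barcode; barcodes within budget of several entries as
    ambiguous. Fractions normalize over matched reads.
    """
    if max_bc_mismatch > 1:
        raise ValueError("max_bc_mismatch must be <= 1 for a distance-3 registry")
    sequences = _read_sequences(reads)
    bc_len = registry.barcode_length
    counts = pd.Series(0, index=pd.Index(registry.bc_ids, name="bc_id"), dtype=int)
    n_flank = 0
    n_ambig = 0
    n_unmatched = 0

    if index_length is None and sequences:
        # infer from layout: index occupies everything before the 5' flank
        guess = sequences[0].find(flank5)
        index_length = guess if guess >= 0 else 0
    expected5 = index_length or 0

    exact = {registry.code(i).dna_barcode: i for i in registry.bc_ids}
    registry_barcodes = [(i, registry.code(i).dna_barcode) for i in registry.bc_ids]

    for seq in sequences:
        off5 = _find_with_mismatch(seq, flank5, expected5, max_flank_mismatch)
        if off5 is None:
            n_flank += 1
            continue
        bc_start = off5 + len(flank5)
        bc_end = bc_start + bc_len
        if len(seq) < bc_end + len(flank3) or _hamming(
            seq[bc_end : bc_end + len(flank3)], flank3
        ) > max_flank_mismatch:
            n_flank += 1
            continue
        barcode = seq[bc_start:bc_end]
        bc_id = exact.get(barcode)
        if bc_id is None and max_bc_mismatch > 0:
            hits = [
                i for i, ref in registry_barcodes if _hamming(barcode, ref) <= max_bc_mismatch
            ]
            if len(hits) == 1:
                bc_id = hits[0]
            elif len(hits) > 1:
                n_ambig += 1
                continue
        if bc_id is None:
            n_unmatched += 1
        else:
            counts.loc[bc_id] += 1

    return BarcodeCountTable(
        sample=sample,
        counts=counts,
        n_unmatched_index=n_unmatched_index,
        n_unmatched_flank=n_flank,
        n_ambiguous_barcode=n_ambig,
        n_unmatched_barcode=n_unmatched,
    )


@dataclass
class ConcordanceResult:
    """Per-code sequencing/flow fraction ratios and their summary.

    Codes absent from both inputs are omitted; codes with a zero flow
    fraction but non-zero sequencing fraction have an undefined ratio and
    are listed in ``flagged`` rather than silently dropped.
    """

    ratios: pd.Series
    flagged: list[int] = field(default_factory=list)

    @property
    def median_ratio(self) -> float:
        return float(self.ratios.median())

    @property
    def fraction_within_twofold(self) -> float:
        if len(self.ratios) == 0:
            return float("nan")
        within = (self.ratios >= 0.5) & (self.ratios <= 2.0)
        return float(within.mean())

    def to_tsv(self, path: str | Path) -> None:
        df = self.ratios.rename("seq_over_flow_ratio").to_frame()
        df.index.name = "bc_id"
        df["flagged"] = df.index.isin(self.flagged)
        df.to_csv(path, sep="\t")


def concordance(
    seq: BarcodeCountTable | pd.Series,
    flow: Mapping[int, float] | pd.Series,
) -> ConcordanceResult:
    """Per-code ratio of sequencing-derived to flow-derived fractions.

    Both inputs must be fraction vectors over the same registry codes (a
    :class:`BarcodeCountTable` contributes its fraction column).
    """
    seq_frac = seq.fractions if isinstance(seq, BarcodeCountTable) else pd.Series(dict(seq), dtype=float)
    flow_frac = pd.Series(dict(flow), dtype=float) if not isinstance(flow, pd.Series) else flow.astype(float)
    codes = seq_frac.index.union(flow_frac.index)
    seq_frac = seq_frac.reindex(codes, fill_value=0.0)
    flow_frac = flow_frac.reindex(codes, fill_value=0.0)

    present = (seq_frac > 0) | (flow_frac > 0)
    flagged = sorted(int(c) for c in codes[(flow_frac == 0) & (seq_frac > 0)])
    defined = present & (flow_frac > 0)
    ratios = (seq_frac[defined] / flow_frac[defined]).sort_index()
    ratios.index.name = "bc_id"
    return ConcordanceResult(ratios=ratios, flagged=flagged)
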